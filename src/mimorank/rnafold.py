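"""Reverse translation and hairpin detection on candidate transcripts.

Each candidate peptide is reverse-translated with an organism-preference
codon table (default: Lactococcus lactis, the intended expression host) and
its coding RNA is folded by Nussinov-style base-pair maximisation — a
dynamic programme that finds a nested structure with the maximum number of
Watson-Crick (optionally G.U wobble) pairs subject to a minimum loop size.
A transcript is called hairpin-forming when the maximising structure
contains a stem of at least ``min_stem`` stacked pairs closing a terminal
loop of 3-8 unpaired bases.  This is a deliberately simple, fully
documented surrogate for thermodynamic or centroid folding: the ranking
scheme consumes only the binary hairpin/no-hairpin outcome.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

import pandas as pd
from Bio.Seq import Seq

from .candidates import AMINO_ACIDS, Peptide
from .errors import AlphabetError, CodonTableError, ConfigurationError

RNA_ALPHABET = frozenset("ACGU")

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class CodonTable:
    """One preferred RNA codon per amino acid."""

    name: str
    codon_of: Mapping[str, str]
    source: str = ""

    def __post_init__(self) -> None:
        table = MappingProxyType(dict(self.codon_of))
        if set(table) != set(AMINO_ACIDS):
            raise CodonTableError(
                f"codon table {self.name!r} must cover the 20 canonical residues"
            )
        for aa, codon in table.items():
            if len(codon) != 3 or set(codon) - RNA_ALPHABET:
                raise CodonTableError(f"invalid codon {codon!r} for {aa}")
            back = str(Seq(codon).translate())
            if back != aa:
                raise CodonTableError(
                    f"codon {codon} translates to {back}, not {aa}"
                )
        object.__setattr__(self, "codon_of", table)


def load_codon_table(name_or_path) -> CodonTable:
    """Load a shipped table by name (``llactis``, ``human``) or a TSV path."""
    builtin = {"llactis": "codons_llactis.tsv", "human": "codons_human.tsv"}
    if str(name_or_path) in builtin:
        ref = resources.files("mimorank.data") / builtin[str(name_or_path)]
        with resources.as_file(ref) as path:
            return _read_codon_tsv(path, str(name_or_path))
    path = Path(name_or_path)
    if not path.exists():
        raise ConfigurationError(
            f"unknown codon table {name_or_path!r} (shipped: {sorted(builtin)})"
        )
    return _read_codon_tsv(path, path.stem)


def _read_codon_tsv(path: Path, name: str) -> CodonTable:
    source = ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            source = first.lstrip("#").strip()
    table = pd.read_csv(path, sep="\t", comment="#")
    return CodonTable(name=name, codon_of=dict(zip(table["aa"], table["codon"])), source=source)


@lru_cache(maxsize=None)
def _shipped(name: str) -> CodonTable:
    return load_codon_table(name)


def shipped_codon_tables() -> dict[str, CodonTable]:
    return {name: _shipped(name) for name in ("llactis", "human")}


def reverse_translate(
    peptide: Peptide | str,
    table: CodonTable | None = None,
    context5: str = "",
    context3: str = "",
) -> str:
    """Concatenate preferred codons, with optional fixed flanking RNA."""
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    if not seq:
        raise AlphabetError("empty peptide")
    table = table or _shipped("llactis")
    for ctx in (context5, context3):
        if set(ctx) - RNA_ALPHABET:
            raise AlphabetError(f"context contains non-RNA characters: {ctx!r}")
    try:
        body = "".join(table.codon_of[aa] for aa in seq)
    except KeyError as exc:
        raise CodonTableError(f"amino acid {exc.args[0]!r} absent from table") from None
    return context5 + body + context3


@dataclass(frozen=True)
class Stem:
    """A maximal run of stacked pairs, outermost first (0-based positions).

    ``terminal_loop`` is the number of unpaired bases enclosed by the
    innermost pair when nothing else is paired inside it (a hairpin loop),
    else ``None`` (the stem closes a multi-branched region).
    """

    pairs: tuple[tuple[int, int], ...]
    terminal_loop: int | None

    @property
    def length(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class FoldResult:
    rna: str
    structure: str
    pair_count: int
    hairpin: bool
    stems: tuple[Stem, ...]


def _can_pair(a: str, b: str, allow_wobble: bool) -> bool:
    return (a, b) in _WC or (allow_wobble and (a, b) in _WOBBLE)


def fold_max_pairs(
    rna: str, min_loop: int = 3, allow_wobble: bool = True
) -> FoldResult:
    """Maximise nested base pairs by dynamic programming.

    Traceback is deterministic: at each subinterval the leftmost partner of
    the 3' base that attains the optimum is paired first, which recovers
    stacked helices for palindromic stems.  ``min_loop`` (default 3) is the
    steric minimum number of unpaired bases inside any pair.
    """
    rna = rna.upper()
    bad = set(rna) - RNA_ALPHABET
    if bad or not rna:
        raise AlphabetError(
            f"invalid nucleotides {sorted(bad)!r}" if bad else "empty RNA"
        )
    n = len(rna)
    # pairable[j] lists every k < j that can pair with base j
    pairable = [
        [k for k in range(j) if _can_pair(rna[k], rna[j], allow_wobble)]
        for j in range(n)
    ]
    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            row_i = dp[i]
            best = row_i[j - 1]
            hi = j - min_loop
            for k in pairable[j]:
                if k < i:
                    continue
                if k >= hi:
                    break
                v = 1 + dp[k + 1][j - 1]
                if k > i:
                    v += row_i[k - 1]
                if v > best:
                    best = v
            row_i[j] = best

    # deterministic traceback: try pairing j with its leftmost optimal partner
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop or dp[i][j] == 0:
            continue
        target = dp[i][j]
        paired = False
        for k in pairable[j]:
            if k < i or k >= j - min_loop:
                continue
            v = 1 + dp[k + 1][j - 1] + (dp[i][k - 1] if k > i else 0)
            if v == target:
                pairs.append((k, j))
                if k > i:
                    stack.append((i, k - 1))
                stack.append((k + 1, j - 1))
                paired = True
                break
        if not paired:
            stack.append((i, j - 1))

    pairs.sort()
    structure = ["."] * n
    for a, b in pairs:
        structure[a], structure[b] = "(", ")"
    stems = _extract_stems(pairs)
    hairpin = classify_hairpin_stems(stems)
    return FoldResult(
        rna=rna,
        structure="".join(structure),
        pair_count=len(pairs),
        hairpin=hairpin,
        stems=stems,
    )


def _extract_stems(pairs: list[tuple[int, int]]) -> tuple[Stem, ...]:
    pair_set = set(pairs)
    stems = []
    for a, b in pairs:
        if (a - 1, b + 1) in pair_set:
            continue  # not the outermost pair of a stacked run
        run = [(a, b)]
        while (run[-1][0] + 1, run[-1][1] - 1) in pair_set:
            run.append((run[-1][0] + 1, run[-1][1] - 1))
        inner_a, inner_b = run[-1]
        enclosed = any(inner_a < x < inner_b for x, _ in pairs)
        loop = None if enclosed else inner_b - inner_a - 1
        stems.append(Stem(pairs=tuple(run), terminal_loop=loop))
    return tuple(stems)


def classify_hairpin_stems(
    stems: tuple[Stem, ...],
    min_stem: int = 4,
    loop_min: int = 3,
    loop_max: int = 8,
) -> bool:
    return any(
        s.length >= min_stem
        and s.terminal_loop is not None
        and loop_min <= s.terminal_loop <= loop_max
        for s in stems
    )


def classify_hairpin(
    fold: FoldResult,
    min_stem: int = 4,
    loop_min: int = 3,
    loop_max: int = 8,
) -> bool:
    """True iff some stem of >= ``min_stem`` stacked pairs closes a terminal
    loop whose length lies in ``[loop_min, loop_max]``."""
    return classify_hairpin_stems(fold.stems, min_stem, loop_min, loop_max)


def transcript_forms_hairpin(
    peptide: Peptide | str,
    table: CodonTable | None = None,
    context5: str = "",
    context3: str = "",
    **classify_kwargs,
) -> bool:
    """Convenience: reverse-translate, fold, classify."""
    rna = reverse_translate(peptide, table, context5, context3)
    fold = fold_max_pairs(rna)
    return classify_hairpin(fold, **classify_kwargs)
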