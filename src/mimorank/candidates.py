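"""Epitope region handling and saturation-substitution candidate libraries.

The design target is the mutant K-ras neoepitope: a 15-mer window of the
K-Ras protein (codons 4-18, ``YKLVVVGAGGVGKSA``) carrying one of the
oncogenic codon-12/13 "anchor" substitutions (G12A/C/D/R/S/V, G13D).
Candidate mimotopes are generated by saturation substitution: one additional
amino-acid change at a single flanking codon, drawn from the 20-letter
alphabet, while the anchor mutation is always preserved.

All coordinates in this module are 1-based protein codon numbers, the same
convention used in mutation shorthand such as ``G12V`` or ``V7D``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlphabetError,
    ConfigurationError,
    ConsistencyError,
    CoordinateError,
    FastaError,
)

log = logging.getLogger(__name__)

#: Canonical amino acids in the fixed enumeration order used throughout.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: The K-ras epitope region manipulated by the design procedure.
WILDTYPE_REGION_SEQ = "YKLVVVGAGGVGKSA"
REGION_START_CODON = 4
REGION_END_CODON = 18

#: Codons whose substitution defines the oncogenic variant, never a flank.
ANCHOR_CODONS = frozenset({12, 13})

#: Default flanking codons: every region codon except the anchors and codon
#: 14.  With the full 20-letter alphabet this yields 12 x 20 = 240 candidates
#: per anchor library.
DEFAULT_FLANK_CODONS = (4, 5, 6, 7, 8, 9, 10, 11, 15, 16, 17, 18)

#: The seven oncogenic anchor variants covered by default.
DEFAULT_ANCHORS = ("G12A", "G12C", "G12D", "G12R", "G12S", "G12V", "G13D")

GENERATION_MODES = ("paper_compat", "strict_19")

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class MutationSpec:
    """A single amino-acid substitution in ``<from><codon><to>`` shorthand."""

    codon: int
    from_aa: str
    to_aa: str

    def __post_init__(self) -> None:
        for aa in (self.from_aa, self.to_aa):
            if aa not in AMINO_ACIDS:
                raise AlphabetError(f"non-canonical amino acid {aa!r} in mutation spec")
        if self.codon < 1:
            raise CoordinateError(f"codon must be >= 1, got {self.codon}")

    @property
    def notation(self) -> str:
        return f"{self.from_aa}{self.codon}{self.to_aa}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.notation

    @classmethod
    def parse(cls, text: str) -> "MutationSpec":
        """Parse shorthand like ``G12V`` into a spec."""
        m = _MUTATION_RE.match(text.strip())
        if not m:
            raise ConfigurationError(f"cannot parse mutation notation {text!r}")
        return cls(codon=int(m.group(2)), from_aa=m.group(1), to_aa=m.group(3))

    def reversed(self) -> "MutationSpec":
        return MutationSpec(self.codon, self.to_aa, self.from_aa)


@dataclass(frozen=True)
class Peptide:
    """A candidate or control peptide with its substitution annotations.

    ``region_start_codon`` anchors the sequence in protein coordinates so
    that 1-based codon numbers (as in ``G12V``) address residues directly.
    """

    sequence: str
    display_id: str = ""
    region_start_codon: int = REGION_START_CODON
    anchor_mutation: MutationSpec | None = None
    flank_substitution: MutationSpec | None = None

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad or not self.sequence:
            raise AlphabetError(
                f"sequence contains non-canonical characters {sorted(bad)!r}"
                if bad
                else "empty sequence"
            )
        if self.flank_substitution and self.flank_substitution.codon in ANCHOR_CODONS:
            raise ConsistencyError(
                "flank substitution may not touch anchor codons 12/13"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def region_end_codon(self) -> int:
        return self.region_start_codon + len(self.sequence) - 1

    def _index(self, codon: int) -> int:
        if not self.region_start_codon <= codon <= self.region_end_codon:
            raise CoordinateError(
                f"codon {codon} outside region "
                f"{self.region_start_codon}..{self.region_end_codon}"
            )
        return codon - self.region_start_codon

    def residue_at(self, codon: int) -> str:
        """Residue at a 1-based protein codon coordinate."""
        return self.sequence[self._index(codon)]


def extract_region(
    full_protein: str, start_codon: int, end_codon: int, display_id: str = ""
) -> Peptide:
    """Slice a contiguous region out of a full protein sequence.

    Coordinates are 1-based and inclusive on both ends; the returned peptide
    remembers ``start_codon`` so downstream mutation shorthand keeps using
    protein coordinates.
    """
    seq = full_protein.strip().upper()
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise AlphabetError(f"non-amino-acid characters in input: {sorted(bad)!r}")
    if not (1 <= start_codon <= end_codon <= len(seq)):
        raise CoordinateError(
            f"region {start_codon}..{end_codon} out of bounds for length {len(seq)}"
        )
    return Peptide(
        sequence=seq[start_codon - 1 : end_codon],
        display_id=display_id,
        region_start_codon=start_codon,
    )


def apply_mutation(p: Peptide, spec: MutationSpec | str) -> Peptide:
    """Apply one substitution, checking the ``from`` residue first.

    The ``from`` check guards against off-by-one coordinate bugs: the spec's
    source residue must equal the peptide's current residue at that codon.
    Substitutions at codons 12/13 are recorded as the anchor mutation; all
    others as the flank substitution.
    """
    if isinstance(spec, str):
        spec = MutationSpec.parse(spec)
    idx = p._index(spec.codon)
    current = p.sequence[idx]
    if current != spec.from_aa:
        raise ConsistencyError(
            f"mutation {spec.notation}: residue at codon {spec.codon} is "
            f"{current!r}, not {spec.from_aa!r}"
        )
    seq = p.sequence[:idx] + spec.to_aa + p.sequence[idx + 1 :]
    if spec.codon in ANCHOR_CODONS:
        return replace(p, sequence=seq, anchor_mutation=spec)
    return replace(p, sequence=seq, flank_substitution=spec)


@dataclass(frozen=True)
class CandidateLibrary:
    """All single-flank-substitution candidates for one anchor variant."""

    anchor: MutationSpec
    candidates: tuple[Peptide, ...]
    generation_mode: str
    flank_codons: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)


def _check_flank_codons(flank_codons: Iterable[int]) -> tuple[int, ...]:
    codons = tuple(dict.fromkeys(flank_codons))
    if not codons:
        raise ConfigurationError("empty flank codon set")
    if ANCHOR_CODONS & set(codons):
        raise ConfigurationError("flank codon set may not contain codons 12/13")
    return tuple(sorted(codons))


def enumerate_library(
    base: Peptide,
    flank_codons: Iterable[int] = DEFAULT_FLANK_CODONS,
    mode: str = "paper_compat",
) -> CandidateLibrary:
    """Enumerate one candidate per (flank codon, amino acid) pair.

    ``paper_compat`` keeps the full 20-letter alphabet at every flank codon,
    so a substitution back to the base residue is retained as a distinct
    (no-op) catalog entry; ``strict_19`` omits the base residue, leaving 19
    true substitutions per codon.  Enumeration order is deterministic:
    codons ascending, then amino acids in :data:`AMINO_ACIDS` order.
    """
    if base.anchor_mutation is None:
        raise ConfigurationError("library base must carry an anchor mutation")
    if mode not in GENERATION_MODES:
        raise ConfigurationError(f"unknown generation mode {mode!r}")
    codons = _check_flank_codons(flank_codons)
    anchor = base.anchor_mutation
    out: list[Peptide] = []
    for codon in codons:
        original = base.residue_at(codon)
        for aa in AMINO_ACIDS:
            if mode == "strict_19" and aa == original:
                continue
            cand = apply_mutation(base, MutationSpec(codon, original, aa))
            cand = replace(cand, display_id=f"{len(out) + 1}-{anchor.to_aa}")
            out.append(cand)
    return CandidateLibrary(
        anchor=anchor,
        candidates=tuple(out),
        generation_mode=mode,
        flank_codons=codons,
    )


def enumerate_all(
    anchors: Sequence[Union[MutationSpec, str]] = DEFAULT_ANCHORS,
    flank_codons: Iterable[int] = DEFAULT_FLANK_CODONS,
    mode: str = "paper_compat",
    wildtype: Peptide | None = None,
) -> list[CandidateLibrary]:
    """Enumerate one library per anchor variant from the wild-type region."""
    if not anchors:
        raise ConfigurationError("at least one anchor variant is required")
    specs = [a if isinstance(a, MutationSpec) else MutationSpec.parse(a) for a in anchors]
    if len({s.notation for s in specs}) != len(specs):
        raise ConfigurationError("duplicate anchor variants")
    wt = wildtype if wildtype is not None else wildtype_region()
    libraries = []
    for spec in specs:
        base = apply_mutation(wt, spec)
        libraries.append(enumerate_library(base, flank_codons, mode))
    return libraries


def assign_display_id(c: Peptide, library: CandidateLibrary) -> str:
    """Recompute the ``<index>-<anchor residue>`` identifier of a candidate.

    The numeric part is the 1-based position in the library's deterministic
    enumeration order; the suffix is the anchor's substituted residue (the
    ``-D`` in e.g. ``164-D``).
    """
    for i, member in enumerate(library.candidates, start=1):
        if member == c:
            return f"{i}-{library.anchor.to_aa}"
    raise ConfigurationError("candidate does not belong to the library")


def wildtype_region() -> Peptide:
    """The unmutated K-ras codon 4-18 region."""
    return Peptide(sequence=WILDTYPE_REGION_SEQ, display_id="wtKRAS")


def load_wildtype_protein() -> str:
    """Full-length canonical human K-Ras protein shipped with the package."""
    ref = resources.files("mimorank.data") / "kras_human.fasta"
    with resources.as_file(ref) as path:
        records = read_fasta(path)
    return records[0][1]


def fasta_header(p: Peptide) -> str:
    anchor = p.anchor_mutation.notation if p.anchor_mutation else "-"
    flank = p.flank_substitution.notation if p.flank_substitution else "-"
    return f"{p.display_id or 'peptide'}|{anchor}|{flank}"


def write_fasta(records: Iterable[Union[Peptide, tuple[str, str]]], path) -> None:
    """Write peptides (or plain ``(id, sequence)`` pairs) as FASTA."""
    seqrecords = []
    for rec in records:
        if isinstance(rec, Peptide):
            seqrecords.append(
                SeqRecord(Seq(rec.sequence), id=fasta_header(rec), description="")
            )
        else:
            ident, seq = rec
            seqrecords.append(SeqRecord(Seq(seq), id=ident, description=""))
    SeqIO.write(seqrecords, str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA into ``(identifier, uppercase sequence)`` pairs.

    Lowercase residues are normalised to uppercase with a logged warning; a
    file whose first non-blank line is not a header raises a parse error
    carrying the offending line number.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaError(f"{path}:{lineno}: expected FASTA header, got {line!r}")
            break
    out = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq)
        if seq != seq.upper():
            log.warning("record %s: lowercase residues normalised to uppercase", record.id)
            seq = seq.upper()
        out.append((record.id, seq))
    return out
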