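"""Amino-acid propensity scales vendored from their original publications.

Each scale maps the 20 canonical residues to a real number: Emini's
fractional surface probabilities, Parker's HPLC hydrophilicity values,
Kolaskar-Tongaonkar antigenic propensities, and Levitt's reverse-turn
preferences.  Values live in two-column TSV data files whose header comment
names the source; nothing numeric is defined in code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

import pandas as pd

from .candidates import AMINO_ACIDS
from .errors import AlphabetError, ConfigurationError


@dataclass(frozen=True)
class PropensityScale:
    """An immutable per-residue propensity table."""

    name: str
    values: Mapping[str, float]
    source: str = ""

    def __post_init__(self) -> None:
        vals = MappingProxyType(dict(self.values))
        if set(vals) != set(AMINO_ACIDS):
            missing = sorted(set(AMINO_ACIDS) - set(vals))
            extra = sorted(set(vals) - set(AMINO_ACIDS))
            raise ConfigurationError(
                f"scale {self.name!r} must cover exactly the 20 canonical "
                f"residues (missing {missing}, unexpected {extra})"
            )
        object.__setattr__(self, "values", vals)

    def __getitem__(self, residue: str) -> float:
        try:
            return self.values[residue]
        except KeyError:
            raise AlphabetError(f"residue {residue!r} not in scale {self.name!r}")

    def mean(self) -> float:
        """Arithmetic mean over the 20 residues (uniform composition)."""
        return sum(self.values.values()) / len(self.values)


def load_scale(path, name: str | None = None) -> PropensityScale:
    """Load a two-column (residue, value) TSV; ``#`` lines hold the source."""
    path = Path(path)
    source = ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            source = first.lstrip("#").strip()
            if source.lower().startswith("source:"):
                source = source[len("source:"):].strip()
    table = pd.read_csv(path, sep="\t", comment="#")
    values = dict(zip(table["residue"], table["value"].astype(float)))
    return PropensityScale(name=name or path.stem, values=values, source=source)


def _load_builtin(filename: str, name: str) -> PropensityScale:
    ref = resources.files("mimorank.data") / filename
    with resources.as_file(ref) as path:
        return load_scale(path, name=name)


@lru_cache(maxsize=None)
def emini_surface() -> PropensityScale:
    return _load_builtin("emini_surface.tsv", "emini_surface")


@lru_cache(maxsize=None)
def parker_hydrophilicity() -> PropensityScale:
    return _load_builtin("parker_hydrophilicity.tsv", "parker_hydrophilicity")


@lru_cache(maxsize=None)
def kolaskar_tongaonkar() -> PropensityScale:
    return _load_builtin("kolaskar_tongaonkar.tsv", "kolaskar_tongaonkar")


@lru_cache(maxsize=None)
def levitt_turn() -> PropensityScale:
    return _load_builtin("levitt_turn.tsv", "levitt_turn")


def registry() -> dict[str, PropensityScale]:
    """All shipped scales keyed by name."""
    return {
        s.name: s
        for s in (
            emini_surface(),
            parker_hydrophilicity(),
            kolaskar_tongaonkar(),
            levitt_turn(),
        )
    }
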