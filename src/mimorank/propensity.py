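"""Sequence-propensity B-cell epitope predictors.

Four peptide-level raw scores feed the B-cell half of the ranking scheme:

* **SA** — Emini surface accessibility: per hexapeptide window, the product
  of the six residues' fractional surface probabilities divided by a
  normalisation constant raised to the window size.
* **HY** — Parker hydrophilicity: sliding-window arithmetic mean.
* **AT** — Kolaskar-Tongaonkar antigenicity: sliding-window mean of
  antigenic propensities; 1.0 is the conventional high/low boundary.
* **LE** — linear-epitope score: a weighted combination of the Parker
  hydrophilicity and Levitt reverse-turn window means, the two propensity
  scales underlying profile-based linear B-cell epitope prediction.

Profiles are indexed by window start; positions whose window would run off
the end are simply absent rather than zero-filled.  The peptide-level
summary is the maximum over defined windows (the best epitope region),
configurable to the mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np

from .candidates import AMINO_ACIDS, Peptide
from .errors import AlphabetError, ConfigurationError, WindowError
from .scales import (
    PropensityScale,
    emini_surface,
    kolaskar_tongaonkar,
    levitt_turn,
    parker_hydrophilicity,
)

#: Historical divisor of the Emini surface-probability product.
EMINI_PUBLISHED_CONSTANT = 0.37

_SUMMARIES = ("max", "mean")


@dataclass(frozen=True)
class ResidueProfile:
    """Per-window scores for one sequence/method/window combination.

    ``per_position[i]`` is the score of the window starting at residue ``i``
    (0-based); only full windows are defined, so the profile holds
    ``len(sequence) - window + 1`` values.
    """

    sequence: str
    method: str
    window: int
    per_position: tuple[float, ...]

    def __post_init__(self) -> None:
        expected = len(self.sequence) - self.window + 1
        if len(self.per_position) != expected:
            raise ConfigurationError(
                f"profile holds {len(self.per_position)} values, expected {expected}"
            )

    def summary(self, how: str = "max") -> float:
        if how not in _SUMMARIES:
            raise ConfigurationError(f"unknown summary {how!r}")
        return (max if how == "max" else (lambda v: sum(v) / len(v)))(self.per_position)


def _residue_values(sequence: str, scale: PropensityScale) -> np.ndarray:
    bad = set(sequence) - set(AMINO_ACIDS)
    if bad:
        raise AlphabetError(f"non-canonical residues {sorted(bad)!r}")
    return np.array([scale[aa] for aa in sequence], dtype=float)


def _check_window(sequence: str, window: int) -> None:
    if window < 1:
        raise WindowError(f"window must be >= 1, got {window}")
    if window > len(sequence):
        raise WindowError(
            f"window {window} exceeds sequence length {len(sequence)}"
        )


def sliding_window_mean(
    sequence: str, scale: PropensityScale, window: int
) -> ResidueProfile:
    """Arithmetic mean of scale values over each full window."""
    _check_window(sequence, window)
    vals = _residue_values(sequence, scale)
    means = np.convolve(vals, np.ones(window) / window, mode="valid")
    return ResidueProfile(
        sequence=sequence,
        method=f"window_mean[{scale.name}]",
        window=window,
        per_position=tuple(float(x) for x in means),
    )


def emini_accessibility(
    sequence: str,
    window: int = 6,
    normalization: Union[str, float] = "published",
) -> tuple[ResidueProfile, float]:
    """Emini surface-accessibility profile and peptide score.

    Each window scores ``prod(scale values) / c**window``.  With
    ``normalization="published"`` the historical constant c = 0.37 is used,
    matching the score ranges produced by the standard web implementation.
    ``"calibrated"`` instead sets c to the scale's mean surface fraction, so
    a window of uniformly random composition has expected score 1.0 (the
    published constant predates the present scale values and does not have
    that property for them).  A float fixes c explicitly.
    """
    _check_window(sequence, window)
    scale = emini_surface()
    if normalization == "published":
        c = EMINI_PUBLISHED_CONSTANT
    elif normalization == "calibrated":
        c = scale.mean()
    elif isinstance(normalization, (int, float)):
        c = float(normalization)
    else:
        raise ConfigurationError(f"unknown normalization {normalization!r}")
    vals = _residue_values(sequence, scale)
    logs = np.log(vals)
    window_logs = np.convolve(logs, np.ones(window), mode="valid")
    scores = np.exp(window_logs) / c**window
    profile = ResidueProfile(
        sequence=sequence,
        method="emini_accessibility",
        window=window,
        per_position=tuple(float(x) for x in scores),
    )
    return profile, profile.summary("max")


def kolaskar_antigenicity(
    sequence: str, window: int = 7
) -> tuple[ResidueProfile, float]:
    """Kolaskar-Tongaonkar antigenic-propensity profile and peptide score."""
    profile = sliding_window_mean(sequence, kolaskar_tongaonkar(), window)
    return profile, profile.summary("max")


def parker_profile(sequence: str, window: int = 7) -> tuple[ResidueProfile, float]:
    """Parker hydrophilicity profile and peptide score (the HY parameter)."""
    profile = sliding_window_mean(sequence, parker_hydrophilicity(), window)
    return profile, profile.summary("max")


def linear_epitope_score(
    sequence: str,
    parker_weight: float = 0.5,
    levitt_weight: float = 0.5,
    window: int = 7,
) -> tuple[ResidueProfile, float]:
    """Two-scale linear-epitope profile: Parker + Levitt window means.

    Per position, ``parker_weight * Parker mean + levitt_weight * Levitt
    mean``; equal weights by default.  Externally computed per-residue
    linear-epitope scores may be used instead of this combination wherever a
    raw LE value is accepted downstream.
    """
    for w in (parker_weight, levitt_weight):
        if not math.isfinite(w):
            raise ConfigurationError("weights must be finite")
    p = sliding_window_mean(sequence, parker_hydrophilicity(), window)
    l = sliding_window_mean(sequence, levitt_turn(), window)
    combined = tuple(
        parker_weight * a + levitt_weight * b
        for a, b in zip(p.per_position, l.per_position)
    )
    profile = ResidueProfile(
        sequence=sequence,
        method="linear_epitope[parker+levitt]",
        window=window,
        per_position=combined,
    )
    return profile, profile.summary("max")


@dataclass
class RawScores:
    """Per-candidate raw values for the seven immunological parameters.

    MHC fields hold the per-candidate aggregate of external binding
    predictions (class I in IC50 nM; class II on the unitless
    percentile-like scale) and stay ``None`` until such predictions are
    attached.
    """

    candidate_id: str
    sa: float | None = None
    hy: float | None = None
    at: float | None = None
    le: float | None = None
    rna_hairpin: bool | None = None
    mhc1_human: float | None = None
    mhc2_human: float | None = None
    mhc1_mouse: float | None = None
    mhc2_mouse: float | None = None


def score_candidate_bcell(
    p: Peptide | str,
    emini_window: int = 6,
    window: int = 7,
    summary: str = "max",
) -> RawScores:
    """Compute the four sequence-propensity raw scores for one peptide."""
    seq = p.sequence if isinstance(p, Peptide) else p
    ident = p.display_id if isinstance(p, Peptide) else ""
    sa_profile, _ = emini_accessibility(seq, window=emini_window)
    hy_profile, _ = parker_profile(seq, window=window)
    at_profile, _ = kolaskar_antigenicity(seq, window=window)
    le_profile, _ = linear_epitope_score(seq, window=window)
    return RawScores(
        candidate_id=ident,
        sa=sa_profile.summary(summary),
        hy=hy_profile.summary(summary),
        at=at_profile.summary(summary),
        le=le_profile.summary(summary),
    )
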