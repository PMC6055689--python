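"""Synthetic inputs and curated reference rows for offline testing.

Two kinds of fixtures live here.  Seeded generators produce synthetic MHC
prediction tables (with controllable bin occupancy) and random peptides so
every pipeline stage can be exercised without external prediction services.
A curated reference shortlist — 20 ranked mimotope candidates plus three
controls, with their published converted weights per parameter — serves as
the regression surface for sequence construction, bin conversion and
category totals.  Reference rows carry *converted* weights only: the
underlying raw prediction values are external and are synthesised inside
the implied bins when raw inputs are needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .candidates import AMINO_ACIDS
from .errors import ConfigurationError
from .mhc import MhcPrediction, write_prediction_table
from .scoring import Scorecard, category_totals

#: Raw-value ranges implied by each conversion bin, for synthesising raw
#: scores that land in a chosen bin.  The open-ended bins are capped at a
#: finite sampling bound.
BIN_RANGES = {
    ("MHC_I", "high"): (1.0, 50.0),
    ("MHC_I", "intermediate"): (51.0, 500.0),
    ("MHC_I", "low"): (501.0, 5000.0),
    ("MHC_II", "high"): (0.01, 4.65),
    ("MHC_II", "intermediate"): (4.66, 9.28),
    ("MHC_II", "low"): (9.29, 50.0),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic MHC prediction table."""

    seed: int
    n_candidates: int
    bin_occupancy: Mapping[str, float]  # bin label -> probability
    dialect: str = "generic"
    parameter: str = "MHC_I"
    species: str = "human"
    subpeptide_length: int = 9
    n_decoy_alleles: int = 2

    def __post_init__(self) -> None:
        total = sum(self.bin_occupancy.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"bin occupancy sums to {total}, not 1")
        for label in self.bin_occupancy:
            if (self.parameter, label) not in BIN_RANGES:
                raise ConfigurationError(
                    f"unknown bin {label!r} for {self.parameter}"
                )


def synth_mhc_table(spec: FixtureSpec, path) -> list[MhcPrediction]:
    """Write a seeded synthetic prediction table with controlled bins.

    Each candidate's *best* (minimum) score is drawn uniformly inside the
    bin chosen from ``bin_occupancy``; decoy allele rows with strictly
    larger scores are added so the per-candidate minimum is exercised.
    Identical specs produce byte-identical files.
    """
    rng = np.random.default_rng(spec.seed)
    labels = sorted(spec.bin_occupancy)
    probs = [spec.bin_occupancy[l] for l in labels]
    mhc_class = "I" if spec.parameter == "MHC_I" else "II"
    units = "ic50_nM" if mhc_class == "I" else "percentile"
    preds: list[MhcPrediction] = []
    for i in range(spec.n_candidates):
        ident = f"cand{i + 1}"
        label = labels[int(rng.choice(len(labels), p=probs))]
        lo, hi = BIN_RANGES[(spec.parameter, label)]
        best = float(rng.uniform(lo, hi))
        subpeptide = "".join(rng.choice(list(AMINO_ACIDS), size=spec.subpeptide_length))
        preds.append(
            MhcPrediction(
                candidate_id=ident,
                allele="allele-0",
                mhc_class=mhc_class,
                species=spec.species,
                subpeptide=subpeptide,
                score=best,
                score_units=units,
                method="fixture (synthetic)",
            )
        )
        for d in range(spec.n_decoy_alleles):
            preds.append(
                MhcPrediction(
                    candidate_id=ident,
                    allele=f"allele-{d + 1}",
                    mhc_class=mhc_class,
                    species=spec.species,
                    subpeptide=subpeptide,
                    score=best * float(rng.uniform(1.5, 4.0)),
                    score_units=units,
                    method="fixture (synthetic)",
                )
            )
    write_prediction_table(preds, path)
    return preds


def random_peptides(seed: int, n: int, length: int) -> list[tuple[str, str]]:
    """Uniform random peptides over the 20-letter alphabet, seeded."""
    if n < 0 or (n > 0 and length < 7):
        raise ConfigurationError("need n >= 0 and length >= 7")
    rng = np.random.default_rng(seed)
    alphabet = list(AMINO_ACIDS)
    return [
        (f"rand{i + 1}", "".join(rng.choice(alphabet, size=length)))
        for i in range(n)
    ]


@dataclass(frozen=True)
class GoldenRow:
    """One entry of the curated 23-row reference shortlist.

    ``human_tcell`` holds (MHC_II, MHC_I) converted weights, ``mouse_tcell``
    likewise, ``bcell`` holds (SA, HY, AT, LE, RNA2).  ``alt_sequence``
    records a second, conflicting published sequence for the same id, with
    ``discrepant=True``; the primary ``sequence`` is the one consistent with
    the row's own anchor + modified-residue annotations.
    """

    display_id: str
    sequence: str
    anchor: str | None
    modified_residue: str | None
    human_tcell: tuple[int, int]
    mouse_tcell: tuple[int, int]
    bcell: tuple[int, int, int, int, int]
    alt_sequence: str | None = None
    discrepant: bool = False


GOLDEN_SHORTLIST: tuple[GoldenRow, ...] = (
    GoldenRow("68-D", "YKLDVVGADGVGKSA", "G12D", "V7D", (58, 42), (20, 28), (23, 29, 13, 12, 6)),
    GoldenRow("68-A", "YKLDVVGAAGVGKSA", "G12A", "V7D", (58, 42), (20, 42), (12, 19, 19, 12, 6)),
    GoldenRow("68-S", "YKLDVVGASGVGKSA", "G12S", "V7D", (58, 42), (20, 42), (12, 29, 19, 12, 6)),
    GoldenRow("68-V", "YKLDVVGAVGVGKSA", "G12V", "V7D", (58, 42), (20, 42), (12, 9, 19, 8, 6)),
    GoldenRow("93-V", "YKLVLVGAVGVGKSA", "G12V", "V8L", (58, 42), (39, 28), (12, 9, 19, 8, 6)),
    GoldenRow("139-A", "YKLVVVPAAGVGKSA", "G12A", "G10P", (58, 42), (39, 28), (12, 19, 19, 12, 6)),
    GoldenRow("64-D", "YKLYVVGADGVGKSA", "G12D", "V7Y", (58, 42), (20, 42), (23, 29, 13, 12, 6)),
    GoldenRow("103-R", "YKLVVAGARGVGKSA", "G12R", "V9A", (58, 42), (20, 42), (23, 19, 13, 12, 6)),
    GoldenRow("116-R", "YKLVVHGARGVGKSA", "G12R", "V9H", (58, 42), (20, 28), (23, 19, 13, 12, 6)),
    GoldenRow("135-D", "YKLVVVIADGVGKSA", "G12D", "G10I", (58, 42), (20, 28), (34, 29, 19, 8, 6)),
    GoldenRow("138-S", "YKLVVVKASGVGKSA", "G12S", "G10K", (58, 42), (58, 28), (12, 29, 19, 8, 6)),
    GoldenRow("112-A", "YKLVVNGAAGVGKSA", "G12A", "V9N", (58, 42), (20, 42), (12, 29, 13, 12, 6)),
    GoldenRow("164-D", "YKLVVVGAGDVYKSA", "G13D", "G15Y", (58, 42), (39, 28), (34, 19, 19, 8, 6)),
    GoldenRow("133-S", "YKLVVVLASGVGKSA", "G12S", "G10L", (58, 42), (20, 28), (23, 29, 19, 8, 6)),
    GoldenRow("135-A", "YKLVVVIAAGVGKSA", "G12A", "G10I", (58, 42), (39, 28), (23, 19, 19, 8, 6)),
    GoldenRow("84-S", "YKLVYVGASGVGKSA", "G12S", "V8Y", (58, 42), (39, 42), (12, 29, 19, 12, 6)),
    GoldenRow(
        "78-D",
        "YKLDVVGAGDVGKSA",
        "G13D",
        "V7D",
        (58, 42),
        (39, 28),
        (12, 29, 13, 12, 6),
        alt_sequence="YKLDVVGAVDVGKSA",
        discrepant=True,
    ),
    GoldenRow("224-D", "YKLVVVGAGDVGKSY", "G13D", "A18Y", (58, 42), (20, 28), (34, 29, 13, 12, 6)),
    GoldenRow("67-D", "YKLTVVGAGDVGKSA", "G13D", "V7T", (58, 42), (20, 42), (23, 29, 13, 12, 6)),
    GoldenRow("194-D", "YKLVVVGAGDVGQSA", "G13D", "K16Q", (58, 42), (20, 28), (23, 29, 13, 12, 6)),
    GoldenRow("Control 1", "YKLVVVGAVGVGKSA", "G12V", None, (58, 42), (20, 28), (12, 9, 19, 8, 6)),
    GoldenRow("Control 2", "YKLVVVGAGDVGKSA", "G13D", None, (58, 42), (20, 28), (23, 29, 13, 12, 6)),
    GoldenRow("wtKRAS", "YKLVVVGAGGVGKSA", None, None, (58, 42), (20, 28), (23, 29, 13, 12, 6)),
)


def golden_scorecards() -> list[Scorecard]:
    """Scorecards whose converted weights equal the reference rows.

    Category totals are recomputed from the members, giving an exact
    regression surface for the conversion/totalling code.
    """
    cards = []
    for row in GOLDEN_SHORTLIST:
        converted = {
            "MHC_II_human": row.human_tcell[0],
            "MHC_I_human": row.human_tcell[1],
            "MHC_II_mouse": row.mouse_tcell[0],
            "MHC_I_mouse": row.mouse_tcell[1],
            "SA": row.bcell[0],
            "HY": row.bcell[1],
            "AT": row.bcell[2],
            "LE": row.bcell[3],
            "RNA2": row.bcell[4],
        }
        sc = Scorecard(candidate_id=row.display_id, converted=converted)
        cards.append(category_totals(sc))
    return cards
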