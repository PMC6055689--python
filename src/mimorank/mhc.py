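"""Ingestion and aggregation of external MHC binding predictions.

Trained MHC class I/II predictors are not re-implemented here; their
exported tables (one row per candidate x allele x subpeptide) are parsed,
filtered to the allele set of interest, and collapsed to one raw score per
candidate.  For both IC50 (nM) and percentile-rank conventions *lower is
stronger*, so the default per-candidate aggregate is the minimum — the
strongest predicted binder.  A deliberately synthetic position-weight-matrix
predictor is included so the full pipeline runs offline; its output is
flagged as synthetic and carries no biological meaning.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from pathlib import Path
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .candidates import AMINO_ACIDS, Peptide
from .errors import (
    ConfigurationError,
    MissingDataError,
    SchemaError,
    TableRowError,
    UnitError,
)

SPECIES = ("human", "mouse")
MHC_CLASSES = ("I", "II")
SCORE_UNITS = ("ic50_nM", "percentile")

#: Subpeptide length ranges presented by each MHC class.
CLASS_LENGTHS = {"I": (8, 11), "II": (13, 17)}

#: Balb/c mice carry only the d haplotype, so mouse predictions default to
#: these allele sets.
MOUSE_CLASS_I_ALLELES = frozenset({"H-2Dd", "H-2Kd", "H-2Ld"})
MOUSE_CLASS_II_ALLELES = frozenset({"I-Ad", "I-Ed"})


@dataclass(frozen=True)
class MhcPrediction:
    """One predicted (candidate, allele, subpeptide) binding score."""

    candidate_id: str
    allele: str
    mhc_class: str
    species: str
    subpeptide: str
    score: float
    score_units: str
    method: str = ""

    def __post_init__(self) -> None:
        if self.mhc_class not in MHC_CLASSES:
            raise ConfigurationError(f"mhc_class must be one of {MHC_CLASSES}")
        if self.species not in SPECIES:
            raise ConfigurationError(f"species must be one of {SPECIES}")
        if self.score_units not in SCORE_UNITS:
            raise ConfigurationError(f"score_units must be one of {SCORE_UNITS}")
        if not (self.score > 0 and math.isfinite(self.score)):
            raise TableRowError(f"score must be positive and finite, got {self.score}")
        lo, hi = CLASS_LENGTHS[self.mhc_class]
        if not lo <= len(self.subpeptide) <= hi:
            raise TableRowError(
                f"class {self.mhc_class} subpeptide length {len(self.subpeptide)} "
                f"outside {lo}-{hi}"
            )


@dataclass(frozen=True)
class AlleleFilter:
    species: str
    mhc_class: str
    allowed_alleles: frozenset[str]

    @classmethod
    def mouse_default(cls, mhc_class: str) -> "AlleleFilter":
        alleles = MOUSE_CLASS_I_ALLELES if mhc_class == "I" else MOUSE_CLASS_II_ALLELES
        return cls(species="mouse", mhc_class=mhc_class, allowed_alleles=alleles)


@dataclass(frozen=True)
class Dialect:
    """Column mapping for one delimited-table flavour."""

    name: str
    candidate_id: str
    allele: str
    subpeptide: str
    score: str
    score_units: str  # fixed unit for the whole table

    @property
    def required_columns(self) -> tuple[str, ...]:
        return (self.candidate_id, self.allele, self.subpeptide, self.score)


DIALECTS: dict[str, Dialect] = {
    "iedb_mhci": Dialect(
        name="iedb_mhci",
        candidate_id="seq_num",
        allele="allele",
        subpeptide="peptide",
        score="ic50",
        score_units="ic50_nM",
    ),
    "iedb_mhcii": Dialect(
        name="iedb_mhcii",
        candidate_id="seq_num",
        allele="allele",
        subpeptide="peptide",
        score="percentile_rank",
        score_units="percentile",
    ),
    "generic": Dialect(
        name="generic",
        candidate_id="candidate_id",
        allele="allele",
        subpeptide="peptide",
        score="score",
        score_units="ic50_nM",
    ),
}


def parse_prediction_table(
    path,
    dialect: str | Dialect = "generic",
    species: str = "human",
    mhc_class: str = "I",
    score_units: str | None = None,
    lenient: bool = False,
) -> list[MhcPrediction]:
    """Parse a delimited (comma or tab, sniffed) prediction table.

    Species and class are metadata of the prediction run, not columns of
    the export, so they are supplied by the caller.  Unparseable rows raise
    a collected :class:`TableRowError` naming every offending row; with
    ``lenient=True`` they are skipped instead.
    """
    if isinstance(dialect, str):
        try:
            dialect = DIALECTS[dialect]
        except KeyError:
            raise ConfigurationError(
                f"unknown dialect {dialect!r} (shipped: {sorted(DIALECTS)})"
            ) from None
    table = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in dialect.required_columns if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    units = score_units or dialect.score_units
    out: list[MhcPrediction] = []
    problems: list[str] = []
    for row_num, rec in enumerate(table.to_dict(orient="records"), start=2):
        try:
            score = float(rec[dialect.score])
            if not (score > 0 and math.isfinite(score)):
                raise ValueError(f"non-positive score {score}")
            out.append(
                MhcPrediction(
                    candidate_id=str(rec[dialect.candidate_id]),
                    allele=str(rec[dialect.allele]),
                    mhc_class=mhc_class,
                    species=species,
                    subpeptide=str(rec[dialect.subpeptide]),
                    score=score,
                    score_units=units,
                    method=dialect.name,
                )
            )
        except (ValueError, TableRowError) as exc:
            problems.append(f"row {row_num}: {exc}")
    if problems and not lenient:
        raise TableRowError(f"{path}: {len(problems)} bad row(s): " + "; ".join(problems))
    return out


def write_prediction_table(preds: Sequence[MhcPrediction], path, delimiter: str = ",") -> None:
    """Write predictions in the generic dialect (byte-stable given input)."""
    d = DIALECTS["generic"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow([d.candidate_id, d.allele, d.subpeptide, d.score])
        for p in preds:
            writer.writerow([p.candidate_id, p.allele, p.subpeptide, f"{p.score:.6g}"])


def filter_alleles(
    preds: Iterable[MhcPrediction], f: AlleleFilter
) -> list[MhcPrediction]:
    """Keep records matching the filter's species, class and allele set."""
    return [
        p
        for p in preds
        if p.species == f.species
        and p.mhc_class == f.mhc_class
        and p.allele in f.allowed_alleles
    ]


def aggregate_best(
    preds: Iterable[MhcPrediction],
    candidate_id: str,
    reduction: str = "min",
) -> float:
    """Collapse a candidate's predictions to one raw score.

    ``min`` (default) takes the strongest predicted binder across alleles
    and subpeptides — lower is stronger for both IC50 and percentile
    conventions; ``median`` is available as a robust alternative.
    """
    mine = [p for p in preds if p.candidate_id == candidate_id]
    if not mine:
        raise MissingDataError(f"no predictions for candidate {candidate_id!r}")
    units = {p.score_units for p in mine}
    if len(units) > 1:
        raise UnitError(f"mixed units for {candidate_id!r}: {sorted(units)}")
    scores = [p.score for p in mine]
    if reduction == "min":
        return min(scores)
    if reduction == "median":
        return float(median(scores))
    raise ConfigurationError(f"unknown reduction {reduction!r}")


def toy_matrix_predict(
    peptide: Peptide | str,
    matrix: pd.DataFrame,
    k: int | None = None,
    candidate_id: str | None = None,
    allele: str = "TOY",
    species: str = "human",
    mhc_class: str = "I",
    score_units: str = "ic50_nM",
) -> list[MhcPrediction]:
    """Synthetic position-weight-matrix scorer (not a biological predictor).

    ``matrix`` has k rows (positions) and the 20 amino acids as columns;
    each k-mer scores ``exp(sum of position weights)`` so all scores are
    positive.  Output records are flagged ``synthetic`` in their method
    field.  Exists solely so the pipeline and its tests run with no external
    prediction service.
    """
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    ident = candidate_id or (peptide.display_id if isinstance(peptide, Peptide) else "")
    if sorted(matrix.columns) != sorted(AMINO_ACIDS):
        raise ConfigurationError("matrix columns must be the 20 canonical amino acids")
    if k is None:
        k = len(matrix)
    if k != len(matrix):
        raise ConfigurationError(f"k={k} but matrix has {len(matrix)} positions")
    if k > len(seq):
        raise ConfigurationError(f"k={k} exceeds peptide length {len(seq)}")
    weights = matrix[list(AMINO_ACIDS)].to_numpy(dtype=float)
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    out = []
    for start in range(len(seq) - k + 1):
        kmer = seq[start : start + k]
        total = float(sum(weights[pos, aa_index[aa]] for pos, aa in enumerate(kmer)))
        out.append(
            MhcPrediction(
                candidate_id=ident,
                allele=allele,
                mhc_class=mhc_class,
                species=species,
                subpeptide=kmer,
                score=math.exp(total),
                score_units=score_units,
                method="toy-matrix (synthetic)",
            )
        )
    return out


def random_toy_matrix(
    rng: np.random.Generator, k: int, mean: float, sd: float
) -> pd.DataFrame:
    """Draw a k x 20 synthetic weight matrix with i.i.d. normal weights."""
    data = rng.normal(loc=mean, scale=sd, size=(k, len(AMINO_ACIDS)))
    return pd.DataFrame(data, columns=list(AMINO_ACIDS))
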