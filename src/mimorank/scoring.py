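"""Priority-weighted conversion of raw scores and candidate ranking.

Seven immunological parameters are each reduced to a weighted percentage by
a fixed bin scheme; weights decrease with parameter priority (MHC class II
> MHC class I > surface accessibility > hydrophilicity > antigenicity >
epitope linearity > RNA secondary structure).  The default scheme is:

========  =====================  =====================  ==================
param     high                   intermediate           low
========  =====================  =====================  ==================
MHC_II    0.01-4.65  -> 58       4.66-9.28 -> 39        >= 9.29  -> 20
MHC_I     0-50 nM    -> 42       51-500 nM -> 28        >= 501   -> 14
SA        >= 2.531   -> 34       1.913-2.530 -> 23      1.294-1.912 -> 12
HY        >= 3.444   -> 29       2.615-3.443 -> 19      0-2.614  -> 9
AT        >= 1.0     -> 19       < 1.0 -> 13            (two bins only)
LE        >= 5.82    -> 12       0.36-5.81 -> 8         0-0.35   -> 4
RNA2      no hairpin -> 6        --                     hairpin  -> 4
========  =====================  =====================  ==================

MHC bins are lower-is-better (IC50 nM for class I, a unitless
percentile-like score for class II); the rest are higher-is-better.  Bins
are implemented as half-open intervals on the published lower edges, so every
real value maps to exactly one bin; a value below a parameter's lowest edge
is clamped into the nearest bin with a logged diagnostic.  T-cell (per
species) and B-cell category totals each max out at 100.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .candidates import Peptide
from .errors import (
    BinningError,
    CalibrationError,
    CompletenessError,
    ConfigurationError,
)
from .propensity import RawScores

log = logging.getLogger(__name__)

NUMERIC_PARAMETERS = ("MHC_II", "MHC_I", "SA", "HY", "AT", "LE")
PARAMETERS = NUMERIC_PARAMETERS + ("RNA2",)

#: Tie-breaking priority over converted fields, most important first.
DEFAULT_PRIORITY = (
    "MHC_II_human",
    "MHC_II_mouse",
    "MHC_I_human",
    "MHC_I_mouse",
    "SA",
    "HY",
    "AT",
    "LE",
    "RNA2",
)

CATEGORY_MEMBERS = {
    "tcell_human": ("MHC_II_human", "MHC_I_human"),
    "tcell_mouse": ("MHC_II_mouse", "MHC_I_mouse"),
    "bcell": ("SA", "HY", "AT", "LE", "RNA2"),
}


@dataclass(frozen=True)
class ScoreBin:
    """Half-open interval ``[lower, upper)`` carrying a weight percentage."""

    label: str
    lower: float
    upper: float  # math.inf for the open-ended bin
    weight: int


@dataclass(frozen=True)
class ConversionTable:
    """Bin boundaries and weights for the six numeric parameters + RNA2.

    ``bins[param]`` is ordered most-favourable first.  ``lower_is_better``
    marks the MHC parameters, where small raw scores mean strong binding.
    """

    bins: Mapping[str, tuple[ScoreBin, ...]]
    lower_is_better: Mapping[str, bool]
    rna_no_hairpin_weight: int = 6
    rna_hairpin_weight: int = 4
    clamp: bool = True

    def __post_init__(self) -> None:
        if set(self.bins) != set(NUMERIC_PARAMETERS):
            raise ConfigurationError(
                f"conversion table must define bins for {NUMERIC_PARAMETERS}"
            )


def default_conversion_table(clamp: bool = True) -> ConversionTable:
    """The default weighted conversion scheme (weights sum to 100 per
    category at their maxima: 58+42 T-cell, 34+29+19+12+6 B-cell)."""
    inf = math.inf
    bins = {
        "MHC_II": (
            ScoreBin("high", 0.01, 4.66, 58),
            ScoreBin("intermediate", 4.66, 9.29, 39),
            ScoreBin("low", 9.29, inf, 20),
        ),
        "MHC_I": (
            ScoreBin("high", 0.0, 51.0, 42),
            ScoreBin("intermediate", 51.0, 501.0, 28),
            ScoreBin("low", 501.0, inf, 14),
        ),
        "SA": (
            ScoreBin("high", 2.531, inf, 34),
            ScoreBin("intermediate", 1.913, 2.531, 23),
            ScoreBin("low", 1.294, 1.913, 12),
        ),
        "HY": (
            ScoreBin("high", 3.444, inf, 29),
            ScoreBin("intermediate", 2.615, 3.444, 19),
            ScoreBin("low", 0.0, 2.615, 9),
        ),
        "AT": (
            ScoreBin("high", 1.0, inf, 19),
            ScoreBin("intermediate", -inf, 1.0, 13),
        ),
        "LE": (
            ScoreBin("high", 5.82, inf, 12),
            ScoreBin("intermediate", 0.36, 5.82, 8),
            ScoreBin("low", 0.0, 0.36, 4),
        ),
    }
    lower_is_better = {p: p.startswith("MHC") for p in NUMERIC_PARAMETERS}
    return ConversionTable(bins=bins, lower_is_better=lower_is_better, clamp=clamp)


def convert_raw(
    parameter: str,
    raw_value: float | bool,
    table: ConversionTable | None = None,
) -> int:
    """Map one raw value to its weight percentage.

    ``RNA2`` takes the hairpin boolean; the numeric parameters take a finite
    real.  Out-of-range values are clamped into the nearest bin (with a
    debug-level diagnostic) unless the table disables clamping.
    """
    table = table or default_conversion_table()
    if parameter == "RNA2":
        return table.rna_hairpin_weight if raw_value else table.rna_no_hairpin_weight
    if parameter not in NUMERIC_PARAMETERS:
        raise ConfigurationError(f"unknown parameter {parameter!r}")
    value = float(raw_value)
    if not math.isfinite(value):
        raise BinningError(f"{parameter}: raw value must be finite, got {value}")
    param_bins = table.bins[parameter]
    for b in param_bins:
        if b.lower <= value < b.upper:
            return b.weight
    if not table.clamp:
        raise BinningError(f"{parameter}: value {value} falls in no bin")
    # below every published lower edge: clamp to the bin with the lowest edge
    nearest = min(param_bins, key=lambda b: b.lower)
    log.debug(
        "%s: raw value %s below lowest bin edge, clamped to %r (%d%%)",
        parameter,
        value,
        nearest.label,
        nearest.weight,
    )
    return nearest.weight


def calibrate_equal_width_bins(
    observed_min: float, observed_max: float, k: int = 3
) -> list[tuple[float, float]]:
    """Split ``[min, max]`` into k contiguous equal-width intervals.

    Offered as an alternative way to derive bin edges from an observed raw
    score range; returns intervals in ascending order.
    """
    if k < 2:
        raise ConfigurationError(f"k must be >= 2, got {k}")
    if not (observed_min < observed_max):
        raise CalibrationError(
            f"degenerate range [{observed_min}, {observed_max}]"
        )
    width = (observed_max - observed_min) / k
    edges = [observed_min + i * width for i in range(k)] + [observed_max]
    return [(edges[i], edges[i + 1]) for i in range(k)]


@dataclass
class Scorecard:
    """Converted weights and category totals for one candidate."""

    candidate_id: str
    raw: RawScores | None = None
    peptide: Peptide | None = None
    converted: dict[str, int] = field(default_factory=dict)
    totals: dict[str, int] = field(default_factory=dict)
    grand_total: int | None = None


def score_raw(
    raw: RawScores,
    table: ConversionTable | None = None,
    peptide: Peptide | None = None,
) -> Scorecard:
    """Convert every available raw field of one candidate."""
    table = table or default_conversion_table()
    converted: dict[str, int] = {}
    numeric = {
        "MHC_II_human": ("MHC_II", raw.mhc2_human),
        "MHC_I_human": ("MHC_I", raw.mhc1_human),
        "MHC_II_mouse": ("MHC_II", raw.mhc2_mouse),
        "MHC_I_mouse": ("MHC_I", raw.mhc1_mouse),
        "SA": ("SA", raw.sa),
        "HY": ("HY", raw.hy),
        "AT": ("AT", raw.at),
        "LE": ("LE", raw.le),
    }
    for key, (param, value) in numeric.items():
        if value is not None:
            converted[key] = convert_raw(param, value, table)
    if raw.rna_hairpin is not None:
        converted["RNA2"] = convert_raw("RNA2", raw.rna_hairpin, table)
    sc = Scorecard(
        candidate_id=raw.candidate_id,
        raw=raw,
        peptide=peptide,
        converted=converted,
    )
    return category_totals(sc, require_all=False)


def category_totals(sc: Scorecard, require_all: bool = True) -> Scorecard:
    """Sum each category's converted weights into its total.

    A category with every member present is totalled; one with no members
    is skipped.  A partially present category — or, with ``require_all``,
    any absent category — raises a completeness error naming the missing
    fields.  The grand total is the sum of the computed category totals.
    """
    totals: dict[str, int] = {}
    for category, members in CATEGORY_MEMBERS.items():
        present = [m for m in members if m in sc.converted]
        if not present:
            if require_all:
                raise CompletenessError(
                    f"{sc.candidate_id}: category {category!r} missing fields {list(members)}"
                )
            continue
        if len(present) != len(members):
            missing = [m for m in members if m not in sc.converted]
            raise CompletenessError(
                f"{sc.candidate_id}: category {category!r} missing fields {missing}"
            )
        totals[category] = sum(sc.converted[m] for m in members)
    sc.totals = totals
    sc.grand_total = sum(totals.values()) if totals else None
    return sc


@dataclass(frozen=True)
class RankedTable:
    """Scorecards in rank order, with the ordering fully described."""

    entries: tuple[Scorecard, ...]
    ranking_key: str
    tie_break: str

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


RANKING_KEYS = ("grand_total", "tcell_human", "tcell_mouse", "bcell")


def rank_candidates(
    scorecards: Iterable[Scorecard],
    key: str = "grand_total",
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> RankedTable:
    """Order candidates by a total, descending, with deterministic ties.

    Ties on the ranking total are broken by the converted weights in
    priority order (a candidate strong on a higher-priority parameter ranks
    first), then by candidate id.  The result is a total order: permuting
    the input never changes the output.
    """
    cards = list(scorecards)
    if key not in RANKING_KEYS:
        raise ConfigurationError(f"unknown ranking key {key!r}")

    def total(sc: Scorecard) -> int:
        value = sc.grand_total if key == "grand_total" else sc.totals.get(key)
        if value is None:
            raise CompletenessError(f"{sc.candidate_id}: no {key!r} total")
        return value

    def sort_key(sc: Scorecard):
        return (
            -total(sc),
            tuple(-sc.converted.get(p, 0) for p in priority),
            sc.candidate_id,
        )

    ordered = tuple(sorted(cards, key=sort_key))
    return RankedTable(
        entries=ordered,
        ranking_key=key,
        tie_break="converted weights in priority order "
        + " > ".join(priority)
        + ", then candidate_id",
    )


def shortlist(ranked: RankedTable, n: int = 20) -> RankedTable:
    """First n entries of a ranked table (all entries if fewer)."""
    if n < 1:
        raise ConfigurationError(f"shortlist size must be >= 1, got {n}")
    return replace(ranked, entries=ranked.entries[:n])


REPORT_STYLES = {
    "human_tcell": (
        ("MHC class II", "MHC_II_human"),
        ("MHC class I", "MHC_I_human"),
    ),
    "mouse_tcell": (
        ("MHC class II", "MHC_II_mouse"),
        ("MHC class I", "MHC_I_mouse"),
    ),
    "bcell": (
        ("SA", "SA"),
        ("HY", "HY"),
        ("AT", "AT"),
        ("LE", "LE"),
        ("RNA 2", "RNA2"),
    ),
}

_STYLE_TOTAL = {
    "human_tcell": "tcell_human",
    "mouse_tcell": "tcell_mouse",
    "bcell": "bcell",
}


def report_frame(ranked: RankedTable, style: str = "combined") -> pd.DataFrame:
    """Tabulate a ranked table in one of the report layouts."""
    id_cols = ("Sequence ID", "Full sequence", "KRAS mutation", "Modified residue")

    def id_values(sc: Scorecard):
        p = sc.peptide
        return (
            sc.candidate_id,
            p.sequence if p else "",
            p.anchor_mutation.notation if p and p.anchor_mutation else "-",
            p.flank_substitution.notation if p and p.flank_substitution else "-",
        )

    rows = []
    if style in REPORT_STYLES:
        score_cols = REPORT_STYLES[style]
        total_key = _STYLE_TOTAL[style]
        for sc in ranked:
            rows.append(
                dict(
                    zip(id_cols, id_values(sc)),
                    **{label: sc.converted.get(f, "") for label, f in score_cols},
                    **{"Total score": sc.totals.get(total_key, "")},
                )
            )
        columns = list(id_cols) + [label for label, _ in score_cols] + ["Total score"]
    elif style == "combined":
        for sc in ranked:
            row = dict(zip(id_cols, id_values(sc)))
            for f in DEFAULT_PRIORITY:
                row[f] = sc.converted.get(f, "")
            for cat in CATEGORY_MEMBERS:
                row[cat] = sc.totals.get(cat, "")
            row["grand_total"] = sc.grand_total
            rows.append(row)
        columns = (
            list(id_cols)
            + list(DEFAULT_PRIORITY)
            + list(CATEGORY_MEMBERS)
            + ["grand_total"]
        )
    else:
        raise ConfigurationError(f"unknown report style {style!r}")
    return pd.DataFrame(rows, columns=columns)


def write_report(ranked: RankedTable, style: str, path) -> None:
    """Write a tab-separated report; byte-stable for identical input."""
    frame = report_frame(ranked, style)
    if frame.empty:
        log.warning("writing header-only report: ranked table is empty")
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
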