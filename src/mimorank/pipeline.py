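"""End-to-end orchestration: generate -> predict -> fold -> convert -> rank.

A flat configuration (dict or ``key = value`` file) names the wild-type
source, anchor variants, MHC input mode and ranking options; the pipeline
is deterministic given the configuration and seed, logging record counts at
every stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import candidates as cg
from . import mhc, rnafold, scoring
from .errors import ConfigurationError
from .propensity import RawScores, score_candidate_bcell
from .scoring import RankedTable, Scorecard

log = logging.getLogger(__name__)

#: Toy-matrix sampling parameters per MHC class: (k, weight mean, weight sd).
#: Chosen once so that per-candidate best scores spread over all three bins
#: of each class's conversion row.
TOY_MATRIX_PARAMS = {
    "I": (9, 0.85, 0.50),
    "II": (13, 0.17, 0.30),
}


@dataclass
class PipelineConfig:
    """Flat pipeline configuration with the study defaults."""

    wildtype: str | None = None  # FASTA path or inline sequence; None = shipped K-ras
    region: tuple[int, int] = (cg.REGION_START_CODON, cg.REGION_END_CODON)
    anchors: tuple[str, ...] = cg.DEFAULT_ANCHORS
    mode: str = "paper_compat"
    flank_codons: tuple[int, ...] = cg.DEFAULT_FLANK_CODONS
    codon_table: str = "llactis"
    mhc_source: str = "toy"  # "toy" or "import"
    mhc_tables: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    top_n: int = 20
    ranking_key: str = "grand_total"
    out: str | None = None
    report_style: str = "combined"


_TUPLE_INT_KEYS = {"flank_codons"}


def load_config(path) -> PipelineConfig:
    """Parse a flat ``key = value`` configuration file.

    ``anchors`` and ``flank_codons`` take comma-separated values; ``region``
    takes ``start:end``; ``mhc_table.<slot>`` keys collect import paths
    (slots: mhc1_human, mhc2_human, mhc1_mouse, mhc2_mouse).
    """
    cfg = PipelineConfig()
    tables: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigurationError(f"{path}:{lineno}: expected key = value")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "region":
                start, _, end = value.partition(":")
                cfg.region = (int(start), int(end))
            elif key == "anchors":
                cfg.anchors = tuple(v.strip() for v in value.split(",") if v.strip())
            elif key in _TUPLE_INT_KEYS:
                cfg.flank_codons = tuple(int(v) for v in value.split(","))
            elif key.startswith("mhc_table."):
                tables[key.split(".", 1)[1]] = value
            elif key in ("seed", "top_n"):
                setattr(cfg, key, int(value))
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
            else:
                raise ConfigurationError(f"{path}:{lineno}: unknown key {key!r}")
    cfg.mhc_tables = tables
    return cfg


_MHC_SLOTS = {
    "mhc1_human": ("human", "I"),
    "mhc2_human": ("human", "II"),
    "mhc1_mouse": ("mouse", "I"),
    "mhc2_mouse": ("mouse", "II"),
}


def _resolve_wildtype(cfg: PipelineConfig) -> cg.Peptide:
    start, end = cfg.region
    if cfg.wildtype is None:
        full = cg.load_wildtype_protein()
    elif Path(str(cfg.wildtype)).exists():
        records = cg.read_fasta(cfg.wildtype)
        full = records[0][1]
    else:
        full = str(cfg.wildtype).strip().upper()
    if len(full) == end - start + 1:
        # already the region itself
        return cg.Peptide(sequence=full, region_start_codon=start)
    return cg.extract_region(full, start, end)


def _toy_mhc_scores(
    sequences: Mapping[str, str], seed: int
) -> dict[str, dict[str, float]]:
    """Per-candidate aggregate scores from seeded synthetic matrices."""
    out: dict[str, dict[str, float]] = {ident: {} for ident in sequences}
    for offset, (slot, (species, mhc_class)) in enumerate(_MHC_SLOTS.items()):
        k, mean, sd = TOY_MATRIX_PARAMS[mhc_class]
        rng = np.random.default_rng((seed + offset) % 2**31)
        matrix = mhc.random_toy_matrix(rng, k, mean, sd)
        units = "ic50_nM" if mhc_class == "I" else "percentile"
        for ident, seq in sequences.items():
            preds = mhc.toy_matrix_predict(
                seq,
                matrix,
                candidate_id=ident,
                species=species,
                mhc_class=mhc_class,
                score_units=units,
            )
            out[ident][slot] = mhc.aggregate_best(preds, ident)
    return out


def _imported_mhc_scores(
    cfg: PipelineConfig, idents: list[str]
) -> dict[str, dict[str, float]]:
    missing = sorted(set(_MHC_SLOTS) - set(cfg.mhc_tables))
    if missing:
        raise ConfigurationError(
            f"mhc_source=import requires table paths for slots {missing}"
        )
    out: dict[str, dict[str, float]] = {ident: {} for ident in idents}
    for slot, (species, mhc_class) in _MHC_SLOTS.items():
        preds = mhc.parse_prediction_table(
            cfg.mhc_tables[slot],
            dialect="generic",
            species=species,
            mhc_class=mhc_class,
            score_units="ic50_nM" if mhc_class == "I" else "percentile",
        )
        if species == "mouse":
            preds = mhc.filter_alleles(preds, mhc.AlleleFilter.mouse_default(mhc_class))
        for ident in idents:
            out[ident][slot] = mhc.aggregate_best(preds, ident)
    return out


def run_pipeline(config: PipelineConfig | Mapping | None = None) -> RankedTable:
    """Run the full design-and-rank pipeline; returns the full ranked table.

    When ``config.out`` is set, the shortlist (``top_n`` entries) is also
    written there in the configured report style.
    """
    if config is None:
        cfg = PipelineConfig()
    elif isinstance(config, PipelineConfig):
        cfg = config
    else:
        cfg = PipelineConfig(**dict(config))
    if cfg.mhc_source not in ("toy", "import"):
        raise ConfigurationError(
            f"mhc_source must be 'toy' or 'import', got {cfg.mhc_source!r}"
        )

    wildtype = _resolve_wildtype(cfg)
    libraries = cg.enumerate_all(
        cfg.anchors, flank_codons=cfg.flank_codons, mode=cfg.mode, wildtype=wildtype
    )
    members: list[tuple[str, cg.Peptide]] = []
    for lib in libraries:
        for cand in lib:
            # library-qualified id: anchors can share the suffix letter
            members.append((f"{lib.anchor.notation}:{cand.display_id}", cand))
    log.info("generate: %d libraries, %d candidates", len(libraries), len(members))

    codon_table = rnafold.load_codon_table(cfg.codon_table)
    bcell_cache: dict[str, RawScores] = {}
    fold_cache: dict[str, bool] = {}
    sequences = {ident: cand.sequence for ident, cand in members}

    if cfg.mhc_source == "toy":
        mhc_scores = _toy_mhc_scores(sequences, cfg.seed)
    else:
        mhc_scores = _imported_mhc_scores(cfg, list(sequences))
    log.info("mhc: aggregated scores for %d candidates", len(mhc_scores))

    cards: list[Scorecard] = []
    table = scoring.default_conversion_table()
    for ident, cand in members:
        seq = cand.sequence
        if seq not in bcell_cache:
            bcell_cache[seq] = score_candidate_bcell(seq)
        if seq not in fold_cache:
            rna = rnafold.reverse_translate(seq, codon_table)
            fold_cache[seq] = rnafold.fold_max_pairs(rna).hairpin
        b = bcell_cache[seq]
        slots = mhc_scores[ident]
        raw = RawScores(
            candidate_id=ident,
            sa=b.sa,
            hy=b.hy,
            at=b.at,
            le=b.le,
            rna_hairpin=fold_cache[seq],
            mhc1_human=slots["mhc1_human"],
            mhc2_human=slots["mhc2_human"],
            mhc1_mouse=slots["mhc1_mouse"],
            mhc2_mouse=slots["mhc2_mouse"],
        )
        cards.append(scoring.score_raw(raw, table, peptide=cand))
    log.info("score: %d scorecards (%d unique sequences)", len(cards), len(bcell_cache))

    ranked = scoring.rank_candidates(cards, key=cfg.ranking_key)
    if cfg.out:
        top = scoring.shortlist(ranked, cfg.top_n)
        scoring.write_report(top, cfg.report_style, cfg.out)
        log.info("report: wrote top %d to %s", len(top), cfg.out)
    return ranked
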