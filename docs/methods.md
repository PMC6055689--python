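# Methods

This note records the models, defaults and design choices behind
`mimorank`, in the order the pipeline applies them.

## Candidate enumeration

The design region is the K-ras codon 4–18 15-mer `YKLVVVGAGGVGKSA`
(extracted from the shipped canonical human K-Ras protein; all coordinates
are 1-based protein codon numbers, matching mutation shorthand like
`G12V`). An *anchor* mutation at codon 12 or 13 defines the oncogenic
variant and is preserved in every candidate; a single *flank* substitution
at one of the default flank codons {4–11, 15–18} defines the mimotope.

Two enumeration modes exist because the natural description of the
procedure ("19 substitutions at each of the 13 non-anchor codons") does
not produce round library sizes. The default `paper_compat` mode uses 12
flank codons (codon 14 excluded) × the full 20-letter alphabet, keeping
substitutions back to the base residue as distinct no-op entries — 240
candidates per library and 1,680 over the seven default anchors.
`strict_19` omits the base residue at each codon (228/library). Both the
flank set and the alphabet handling are configurable; the codon-14
exclusion is a reverse-engineered compatibility choice, not a biological
statement. Enumeration order is fixed (codons ascending, residues in
`ACDEFGHIKLMNPQRSTVWY` order), so candidate identifiers
`<index>-<anchor residue>` and FASTA output are byte-reproducible.
Published candidate ids cannot be reconstructed exactly because the
original within-codon residue order is unknown; the curated reference
rows therefore match on sequences and annotations, not on our indices.

## Sequence-propensity predictors

Four per-candidate raw scores come from sliding-window statistics over
vendored literature scales (each shipped as a two-column TSV citing its
source; no values are defined in code):

| parameter | scale | window | statistic |
|---|---|---|---|
| SA | Emini fractional surface probabilities (1985) | 6 | product / c⁶ |
| HY | Parker hydrophilicity (1986) | 7 | mean |
| AT | Kolaskar–Tongaonkar antigenic propensity (1990) | 7 | mean |
| LE | 0.5·Parker + 0.5·Levitt turn preference (1978) | 7 | weighted mean |

Window sizes follow the methods' original publications. Only full windows
are scored; edge positions are absent rather than zero-filled, so the
peptide-level summary — the **maximum** over windows, i.e. the best
epitope region (configurable to the mean) — is not biased by padding.

Two Emini normalisations are offered. `published` (default) divides the
six-residue product by 0.37⁶, the historical constant, which reproduces
the score ranges the default SA conversion bins expect. `calibrated`
divides by the scale mean (0.6225) instead; that is the constant for which
a window of uniformly random composition has expected score exactly 1.0 —
a property the historical constant does not have for the present scale
values (it yields ≈ 22.6). The tests verify the closed form under
`published` and the expectation property under `calibrated`.

The LE score stands in for HMM-based linear-epitope predictors using the
two propensity scales such predictors combine; the weights are
configurable and externally computed per-residue scores can be supplied
wherever a raw LE value is accepted. The conventional low/intermediate
boundary of 0.35 is treated as unitless.

## Transcript hairpin flag

Candidates are reverse-translated with one preferred codon per amino acid
(default table: *Lactococcus lactis*, the intended expression host; a
human table and user TSVs are also accepted — any complete table
round-trips under the standard genetic code, which the tests enforce).
The coding RNA is folded alone by default; fixed 5′/3′ context strings
may be supplied.

Folding is Nussinov-style base-pair maximisation: a dynamic programme
over nested structures with Watson–Crick and (by default) G·U wobble
pairs and a minimum loop of 3 unpaired bases (the steric minimum).
Traceback is deterministic — the 3′ base of each subinterval pairs with
its leftmost optimal partner — which recovers stacked helices for
palindromic stems. A transcript is hairpin-forming when some stem of at
least 4 stacked pairs closes a terminal loop of 3–8 bases; all three
thresholds are arguments. This is a deliberately simple, fully specified
rule rather than a thermodynamic or posterior-decoding folder: the
ranking scheme consumes only the binary outcome, and the rule's behaviour
is verified against exhaustive structure enumeration at small lengths.

## MHC ingestion

Trained MHC predictors are never re-implemented. Exported tables (comma
or tab, dialects for class I IC50 and class II percentile exports plus a
generic layout) are parsed with row-level diagnostics, filtered by
species/class/allele — mouse defaults to the Balb/c *d*-haplotype sets
{H-2Dd, H-2Kd, H-2Ld} and {I-Ad, I-Ed} — and collapsed to one raw score
per candidate. The reduction is the **minimum** (strongest predicted
binder; lower is stronger for both IC50 and percentile conventions),
configurable to the median. Class II scores are treated as unitless; unit
labels are metadata only. Class I subpeptides must be 8–11 residues and
class II 13–17, per the peptide lengths each class presents.

A synthetic position-weight-matrix scorer (`exp` of summed position
weights, so scores are positive) exists solely so the pipeline and tests
run offline; its records are flagged `synthetic` and it models nothing.

## Conversion, totals and ranking

Raw values map to weighted percentages through fixed bins (see the README
table). Bins are half-open intervals on the published lower edges, so
every real value lands in exactly one bin; printed upper edges are
treated as display rounding. The extreme bin of each parameter is
open-ended (e.g. any IC50 ≥ 501 nM converts to 14, however large), and a
value below a parameter's lowest edge is clamped into the nearest bin
with a logged diagnostic — the scheme is exhaustive in intent. Clamping
can be disabled, in which case such values raise.

An equal-width tercile calibrator is provided as an alternative way to
derive numeric bin edges from an observed score range (the default SA
edges are consistent with terciles of [1.294, 3.149]); the fixed bins
remain the default.

Category totals are plain sums: T-cell = MHC II + MHC I per species
(max 58 + 42 = 100), B-cell = SA + HY + AT + LE + RNA (max
34 + 29 + 19 + 12 + 6 = 100). The default ranking key is the grand total
(human T + mouse T + B); per-table keys and report styles reproduce each
category table independently, since no single combination rule is
canonical. Ties break by converted weights in priority order
(MHC II human, MHC II mouse, MHC I human, MHC I mouse, SA, HY, AT, LE,
RNA), then by candidate id — making the ranking a reproducible total
order, which the tests check by permutation.

## Synthetic data and what the tests show

The fixture generators define the test conditions: uniform random
peptides over the 20-letter alphabet, and seeded MHC tables whose
per-candidate best scores land in conversion bins with controllable
occupancy (decoy allele rows exercise the minimum reduction). The
end-to-end pipeline's default synthetic MHC stage draws one weight matrix
per species/class (class I: k = 9, weights N(0.85, 0.50); class II:
k = 13, N(0.17, 0.30)), chosen once so aggregated scores occupy all three
bins of each class. None of this reproduces real binding-affinity
distributions, allele structure, or correlations between parameters —
passing tests demonstrate the correctness and determinism of the
machinery, not predictive accuracy on real epitopes.

A curated 23-row reference shortlist (20 ranked candidates + 3 controls,
with converted weights per parameter) is the regression surface for
sequence construction and totalling. It stores *converted* weights only;
the raw prediction values behind them are external, so raw-level
regression feeds representative values drawn from the implied bins. One
reference id (78-D) was published with two conflicting sequences; the
fixture keeps both, flags the discrepancy, and treats the variant
consistent with its own anchor/substitution annotations as primary.

## Problem sizes and runtime

The full default run — 1,680 candidates, four propensity profiles, a
45-nt fold each (cached per unique sequence), synthetic MHC scoring,
conversion and ranking — completes in a few seconds on one CPU; the fold
oracle comparison in the tests uses 500 random sequences of length ≤ 12,
where exhaustive enumeration is exact. These sizes are the full study
conditions, not reductions.

## Known limitations

- The hairpin rule is a structural surrogate; it does not model folding
  thermodynamics, pseudoknots or ensembles.
- The LE combination approximates trained linear-epitope predictors only
  up to their propensity components.
- Published candidate numbering cannot be regenerated; our ids are
  internally consistent but not comparable across tools.
- Bin edges outside the published ranges rely on the documented
  clamping/open-end conventions.
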