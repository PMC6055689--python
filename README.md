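# mimorank

Design and priority-weighted ranking of single-substitution **mimotopes**
of mutant K-ras epitopes.

Oncogenic *KRAS* point mutations concentrate at codons 12/13, where glycine
is replaced by another residue (G12A/C/D/R/S/V, G13D). Peptide vaccines
built directly on these neoepitopes are often weakly immunogenic; one way
to improve them is to engineer *mimotopes* — variants of the natural
epitope that carry one additional amino-acid substitution flanking the
disease-defining "anchor" mutation, chosen to improve predicted MHC
presentation and B-cell epitope properties while preserving the anchor.

`mimorank` implements that design loop for the K-ras codon 4–18 region
(`YKLVVVGAGGVGKSA`):

1. **Enumerate** — for each anchor variant, every single substitution at
   the flanking codons {4–11, 15–18} over the 20-letter alphabet:
   12 × 20 = 240 candidates per anchor library, 1,680 over seven anchors
   (a strict 19-substitution mode, 228/library, is also available).
2. **Predict** — seven immunological parameters per candidate:
   - MHC class II and class I binding, human and mouse (ingested from
     external prediction exports, or a clearly-labelled synthetic
     offline stand-in); lower score = stronger binding,
   - surface accessibility (Emini hexapeptide products), hydrophilicity
     (Parker window means), antigenicity (Kolaskar–Tongaonkar window
     means), and a linear-epitope score (Parker + Levitt combination),
   - a binary RNA-hairpin flag on the candidate's coding transcript
     (reverse-translated with *L. lactis*-preferred codons, folded by
     Nussinov base-pair maximisation, stem ≥ 4 pairs closing a 3–8 nt
     loop).
3. **Convert & rank** — each raw value maps to a weighted percentage via a
   fixed bin scheme whose weights fall with parameter priority
   (MHC II 58/39/20 > MHC I 42/28/14 > SA 34/23/12 > HY 29/19/9 >
   AT 19/13 > LE 12/8/4 > RNA 6/4). T-cell (per species) and B-cell
   category totals each max out at 100; candidates are ranked by the
   summed total with deterministic, priority-ordered tie-breaking, and the
   top N (default 20) are shortlisted.

## Worked example

```python
import mimorank as mr

wt = mr.wildtype_region()                      # YKLVVVGAGGVGKSA, codons 4-18
p = mr.apply_mutation(mr.apply_mutation(wt, "G13D"), "G15Y")
print(p.sequence)                              # YKLVVVGAGDVYKSA

raw = mr.score_candidate_bcell(p)              # SA/HY/AT/LE raw scores
rna = mr.reverse_translate(p)                  # L. lactis preferred codons
fold = mr.fold_max_pairs(rna)

from mimorank.propensity import RawScores
sc = mr.score_raw(RawScores(
    candidate_id="example",
    sa=raw.sa, hy=raw.hy, at=raw.at, le=raw.le, rna_hairpin=fold.hairpin,
    mhc2_human=2.0, mhc1_human=30.0,           # external MHC aggregates
    mhc2_mouse=6.0, mhc1_mouse=200.0,
))
print(sc.totals, sc.grand_total)
```

prints

```
YKLVVVGAGDVYKSA
{'tcell_human': 100, 'tcell_mouse': 67, 'bcell': 94} 261
```

The B-cell raw scores here are `SA=26.685, HY=3.486, AT=1.195, LE=2.287`
and the transcript folds into a hairpin, so the five B-cell members
convert to 34 + 29 + 19 + 8 + 4 = 94. The supplied human MHC II score of
2.0 lies in the high bin (58) and the class I IC50 of 30 nM in the high
bin (42), giving the human T-cell maximum of 100; the mouse scores land
one bin lower each (39 + 28 = 67).

The same flow is available from the shell:

```sh
mimorank generate --anchors G12V,G13D --out candidates.fasta
mimorank predict-bcell --in candidates.fasta --out bcell.tsv
mimorank fold --in candidates.fasta --codon-table llactis --out folds.tsv
mimorank rank --top 20 --style bcell --out shortlist.tsv
```

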