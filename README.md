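# paskit

Analysis toolkit for **antisense (PAS-gene) transcription in the plant cold
response**: genes whose antisense transcription initiates near their poly(A)
site are disproportionately stress-responsive transcription factors whose
mRNAs turn over quickly — so their cold induction is conspicuous in nascent
(NET-seq-style) data yet nearly invisible at the steady-state (RNA-seq)
level. `paskit` implements the full desk-scale analysis chain for this
phenomenon and ships a kinetic simulator so every stage is testable without
sequencing data.

## What it computes

- **PAS-gene calling** (`paskit.pas_caller`): segments strand-specific
  per-base coverage into transcription units and classifies a gene as a PAS
  gene when an antisense unit's 5′ end (asTSS) falls in the gene's 3′-half
  `[s + ⌈L/2⌉, e)` or in the 20 %-of-length downstream window
  `[e, e + ⌈0.2 L⌉)` (minus-strand genes are the exact mirror).
- **Differential expression** (`paskit.expression_compare`): median-of-ratios
  size factors, a negative-binomial Wald test on log₂ fold changes
  (method-of-moments dispersion), Benjamini–Hochberg FDR, and calls at
  FDR < 0.05 with |log₂FC| ≥ 0.5; cross-assay overlap summaries, the
  transient-induction screen (UP at 3 h, DOWN between 3 and 12 h), and
  Mann–Whitney gene-class comparisons.
- **Decay kinetics** (`paskit.decay_kinetics`): half-lives
  t₁/₂ = ln 2 / slope from Cq time courses after transcription inhibition
  (0/15/30/60/120 min), 22 °C vs 4 °C stability tests, ΔΔCq fold changes
  (fold = E^(−ΔΔCq)), and the closed-form steady-state model
  dM/dt = α(t) − k(T)·M whose solution
  M(t) = (α₄/k₄)(1 − e^(−k₄t)) + M₀e^(−k₄t) explains the *muting law*:
  the asymptotic steady-state fold change is f·k₂₂/k₄ — strictly below the
  nascent fold change f whenever cold accelerates decay.
- **Metagene profiles** (`paskit.metagene`): strand-aware matrices over
  anchored windows (e.g. 500 bp centred on the +1 nucleosome at
  TSS + 150 bp) or rescaled gene bodies, with exact per-gene signal
  conservation and mean ± 95 % CI summaries.
- **Freezing tolerance** (`paskit.freeze_tolerance`): electrolyte leakage
  (100·conductivity before/after flash freeze), 4-parameter logistic LT50
  fits EL(T) = bottom + (top − bottom)/(1 + e^(hill(T − LT50))), and the
  extra sum-of-squares F-test for comparing genotypes' curves.
- **Synthetic data** (`paskit.synthetic_data`): a toy chromosome of
  non-overlapping stranded genes, kinetic ground truth per gene, Poisson
  nascent coverage with a +1-nucleosome stall peak, NB count matrices for
  22 °C / 3 h / 12 h at 4 °C, Cq decay series, and sigmoidal leakage curves.

## Worked example

The numbered drivers under `analysis/` run the whole study
(`python analysis/01_simulate_study.py` … `06_freeze_tolerance.py`), or use
the CLI directly:

```sh
paskit simulate --outdir study
paskit call-pas --plus study/nascent_22C_plus.bedgraph \
    --minus study/nascent_22C_minus.bedgraph \
    --genes study/genes.gff3 --out study/pas_calls.tsv
paskit de --counts study/counts.tsv --a 22C --b 4C_3h --out study/de_3h.tsv
```

On the default study the drivers print:

```
50 of 200 genes called PAS (truth: 50)
precision 1.000, recall 1.000 vs simulated truth

3 h vs 22 C: 45 UP, 26 DOWN of 200 genes
transient screen (UP at 3 h, DOWN 3->12 h): 25 genes; designed 25; exact recovery: True

25 transient genes: median t1/2 31.7 min at 22 C vs 19.9 min at 4 C; 25 significantly destabilised in cold
median nascent fold at 3 h 9.40 vs steady-state fold 5.99 (decay-driven muting of the cold response)

WT: LT50 -6.17 C (50% leakage crossed at -6.14 C)
mutant: LT50 -3.76 C (50% leakage crossed at -3.73 C)
WT vs mutant: F(4,52) = 286.94, p = 9.39e-35
```

Reading the numbers: all 50 genes carrying simulated antisense units are
recovered by the geometric rule with no false calls; the 25 genes designed
with a transient synthesis burst are recovered exactly by chaining the two
DE contrasts; their fitted half-lives shorten from ~32 to ~20 min in cold,
which mutes a ~9-fold nascent induction to ~6-fold at steady state; and the
two genotypes' leakage curves differ decisively (ΔLT50 ≈ 2.4 °C).

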