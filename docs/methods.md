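# Methods

## The kinetic model

Every synthetic readout derives from one per-gene model of mRNA balance,

    dM/dt = alpha(t) − k(T) · M,

with synthesis rate `alpha` and first-order decay rate `k` switching from
their 22 °C to their 4 °C values at cold onset (t = 0). The pre-cold steady
state is M₀ = α₂₂/k₂₂ and the post-onset solution is the exact closed form

    M(t) = (α₄/k₄)(1 − e^(−k₄ t)) + M₀ e^(−k₄ t),

so no numerical integration is involved anywhere. Two consequences are
load-bearing:

- **Muting law.** The nascent (synthesis) fold change f = α₄/α₂₂ is
  instantaneous, while the steady-state fold change M(t)/M₀ converges to
  f·k₂₂/k₄. Whenever cold also destabilises the transcript (k₄ > k₂₂), the
  steady-state response is strictly smaller than the nascent one — the
  mechanism by which strongly induced, fast-turnover transcription factors
  look unremarkable in steady-state data.
- **Transient induction.** A single step change makes M(t) monotone, which
  can never produce the "UP at 3 h, DOWN between 3 and 12 h" pattern that
  defines the rapidly responding TF class. The generator therefore allows an
  optional second synthesis phase: for transient-designated genes alone,
  `alpha` switches again at t = 180 min (`alpha_4_late`, default back to the
  baseline steady-state-equivalent rate). All other genes follow the plain
  single-step model. This is the package's own minimal extension; with only
  two cold timepoints no richer dynamics would be identifiable, so nothing
  beyond one extra phase is modelled.

## The synthetic study and its defaults

The default study is one 2-Mb chromosome with 200 non-overlapping genes
(lengths uniform 1–3 kb, intergenic gaps 3–6 kb so antisense units, which
extend 1 kb past their host's TSS, never collide with neighbours), 25 % PAS
genes, 30 % transcription factors with 3-fold enriched odds of being PAS
hosts, 3 biological replicates at 22 °C, 3 h 4 °C and 12 h 4 °C, and
2 × 10⁶ expected counts per library. DE classes: 25 transient genes (peak
fold 6 at 3 h, return to baseline by 12 h, cold-destabilised with
t₁/₂ ≈ 30 min warm → ≈ 20 min cold), 20 sustained UP (fold 4) and
20 sustained DOWN (fold 0.25) genes; the remaining genes are null. Baseline
synthesis rates are log-normal (σ = 0.5); decay rates are ln2/30 min for
TF/PAS genes and ln2/60 min otherwise, jittered log-normally (σ = 0.15).
These sizes and rates are chosen to be realistic for Arabidopsis seedling
transcriptomes (TF mRNA half-lives of tens of minutes; cold time course at
3 h and 12 h; triplicate libraries) while keeping the whole study
desk-scale.

Noise models match each data type's support: Poisson for per-base nascent
coverage (mean 10 reads/base over gene bodies at 22 °C, stall peak ×3 over
150 bp at TSS + 150 bp, antisense amplitude 0.5× the host body level —
exposed as a parameter because no quantitative initiation strength is
established in the literature), negative binomial (dispersion 0.05) for
counts, Gaussian on Cq (sd 0.1 cycles) and on leakage percentages (sd 3 %,
clamped to [0, 100]).

What the generator does **not** emulate: read-level artefacts (mapping,
GC/length bias), splicing and isoforms, diurnal expression, composition
shifts beyond the simulated DE classes, chromatin state, or any correlation
between antisense activity and host induction. Passing tests therefore
demonstrate the correctness and calibration of the algorithms under the
stated generative model, not performance on real sequencing libraries.

## PAS classification

Coordinates are 0-based half-open internally (GFF3 I/O converts at the
boundary). For a + gene [s, e) of length L, the 3′-half is [s + ⌈L/2⌉, e)
and the downstream window [e, e + ⌈0.2 L⌉); − genes are the exact
reflection. Ceilings give deterministic, testable edges (no rounding rule is
established for the original definition); the downstream window is anchored
at the annotated gene end, and the degenerate L = 1 gene still has a
width-1 downstream window. "Initiation" is operationalised as the unit's
5′-most base, and a unit on the gene's own strand is never an antisense
candidate. Unit detection is maximal runs of coverage ≥ `min_signal`
(default 1 read/base) tolerating internal gaps ≤ 50 bp, minimum span
200 bp; among several matching units the highest mean signal wins, ties to
the leftmost asTSS.

## Differential expression

Size factors are median-of-ratios against the geometric-mean reference over
genes expressed in all samples. The per-gene test is a Wald z on
log₂((m_b + ½)/(m_a + ½)) of normalised condition means (pseudocount ½
avoids log 0; it is the documented constant, not tunable at call sites).
Dispersion comes from method-of-moments on normalised counts; the pooled
default uses the moment-ratio estimator Σ(var − Poisson term)/Σ(mean²) over
expressed genes, which is nearly unbiased at 3 replicates where the median
of per-gene estimates is badly biased low; `per_gene` shrinks each gene's
raw estimate toward the pooled value with a prior weight of 6. The
delta-method SE uses Var(q) = μ/sf + disp·μ² on the normalised scale.
P-values are two-sided normal, BH-adjusted (in-repo step-up implementation,
cross-checked against an independent reference in the tests); calls require
FDR < 0.05 **and** |log₂FC| ≥ 0.5, with the published one-sided phrasing of
the fold-change threshold read as a two-sided rule since both UP and DOWN
sets are reported. This is deliberately a simplified in-repo NB test rather
than a DESeq2 wrapper: the contract is type-I calibration on simulations
(verified at 0.035–0.065 under the NB null), not numerical equality with
any external tool.

Gene-class comparisons use the two-sided Mann–Whitney U, exact when both
classes have ≤ 8 tie-free members, tie-corrected normal approximation
otherwise. Fold-change concordance between assays is Pearson's r over genes
DE in the same direction in both (the quantity plotted in fold-change
correlation figures); fewer than two shared genes yields a null, not NaN.

## Decay kinetics

Replicate Cq values are averaged before fitting (averaging Cq is the
log-scale mean of abundances); per-replicate fits are used only for the
stability test. The default `abundance` mode fits ln R(t), with
R(t) = E^(−(Cq(t) − Cq(0))), through the origin — forced by R(0) = 1 — and
returns t₁/₂ = ln 2/slope exactly on noise-free exponentials. The `literal`
mode reproduces the published transform y(t) = ln(Cq(t)/Cq(0))·(−10) with an
ordinary least-squares slope; the transform acts on Cq *ratios* and its −10
constant has no stated derivation, so the mode exists for auditability (its
t₁/₂ is a strictly monotone function of the truth but not equal to it) and
is not the default. A non-positive fitted slope reports t₁/₂ = +∞ with a
flag instead of raising. Stability comparisons are equal-variance Student
t-tests on replicate slopes (Welch available via flag), matching the
published test choice; ΔΔCq folds use E^(−ΔΔCq) with the primer efficiency
E ∈ (1, 2], default 2.

## Metagene profiles

Anchored matrices read each gene's own strand in a fixed window (default
500 bp total) around TSS + offset; the +1-nucleosome offset defaults to
150 bp — canonical Arabidopsis +1 positioning, exposed as a parameter
because anchor derivation from nucleosome data is out of scope. Rows of −
genes are reversed so bins run 5′→3′. Genes whose window leaves the
chromosome are excluded (recorded in metadata) rather than zero-padded,
which would bias means. Scaled-body matrices read the body in transcript
orientation, partition it into nbins with remainder bases spread 5′→3′
(length 10 into 3 bins → 4, 3, 3), and keep bin sums alongside means so
per-gene total signal is conserved exactly and genome reversal is a
bit-exact symmetry. Summaries are per-bin mean ± 1.96·sd/√n, flagged
degenerate at n = 1. Raw (not per-gene-normalised) binning is the default;
profiles are plain mean signal.

## Freezing tolerance

EL(T) = bottom + (top − bottom)/(1 + e^(hill(T − LT50))) with hill > 0 so
leakage rises as temperature falls — the standard 4PL in its temperature
orientation. Fitting is multi-start nonlinear least squares over an LT50
grid of −2…−10 °C with bottom/top initialised from the data extremes;
bounded to [0, 100] by default with a free variant available, since the
original constraint setting is not recorded. Both the inflection LT50 and
the absolute 50 %-crossing temperature are reported (they coincide for
symmetric curves). The genotype comparison is the extra sum-of-squares
F-test: one shared curve (df = N − 4) against separate curves (df = N − 8),
F with (4, N − 8) df; the separate fits are additionally seeded with the
shared optimum so the nesting inequality rss_shared ≥ rss_separate holds by
construction rather than by optimizer luck. Simulated assays follow the
ramp design (−1 °C per 30 min from −2 °C, sampled each degree from −1 to
−10 °C, triplicate).

## Problem sizes

The default study is 200 genes on 2 Mb; recovery and calibration statistics
use 10 simulated studies (PAS calling), 5 × 2000 genes (DE null), 200 decay
series, and 200 + 500 + 100 leakage simulations (LT50 recovery, null
uniformity, power). These sizes give stable estimates of every reported
rate while the full suite plus the acceptance script completes in a few
minutes on one CPU.

## Known limitations

- Headline dataset-scale numbers from the motivating biology (thousands of
  PAS genes, specific DE overlap counts, genotype LT50s) depend on deposited
  sequencing data and raw assay measurements; this package reproduces the
  *methods* and validates them on synthetic ground truth instead.
- The NB test has no covariates, batch terms, or fold-change shrinkage.
- Antisense units are simulated and detected as contiguous blocks; nested or
  overlapping same-strand units are not modelled, and exosome sensitivity of
  antisense transcripts is out of scope.
- The decay model assumes complete, instantaneous transcription shut-off at
  inhibitor addition.
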