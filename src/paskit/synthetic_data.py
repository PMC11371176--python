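"""Synthetic genome, kinetics and assay readouts for the cold-response pipeline.

Generates a toy chromosome of non-overlapping stranded genes, a subset of
which host antisense transcription initiating near their 3′ end (PAS genes),
then derives every downstream readout from one explicit kinetic model

    dM/dt = alpha(t) − k(T) · M

with synthesis alpha and first-order decay k switching from their 22 °C to
their 4 °C values at cold onset (t = 0).  Readouts: strand-specific nascent
coverage with a +1-nucleosome stall peak (Poisson), negative-binomial count
matrices for the 22 °C / 3 h 4 °C / 12 h 4 °C design, qPCR Cq decay series
after transcription inhibition, and sigmoidal electrolyte-leakage curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .models import (
    CONDITION_TIMES,
    ConditionSchedule,
    CountMatrix,
    CoverageTrack,
    GeneModel,
    GeneTruth,
    KineticParams,
    PlacementError,
    TruthTable,
)
from .pas_caller import pas_windows

__all__ = [
    "simulate_genome",
    "solve_mrna_level",
    "mrna_level",
    "simulate_nascent_coverage",
    "simulate_counts",
    "simulate_decay_series",
    "simulate_leakage",
    "DecaySeries",
    "LeakageCurve",
    "AS_EXTENSION",
]

#: antisense units run from their TSS to this many bases past the host TSS
AS_EXTENSION = 1000

# designed asymptotic steady-state fold changes by DE class
_FC_UP = 4.0
_FC_DOWN = 0.25
_FC_TRANSIENT_PEAK = 6.0

# decay rates (1/min): fast-turnover TF-like mRNAs vs ordinary mRNAs
_K_FAST = math.log(2) / 30.0
_K_SLOW = math.log(2) / 60.0
_K_COLD_TRANSIENT = math.log(2) / 20.0  # destabilised in cold


# ---------------------------------------------------------------------------
# kinetic model
# ---------------------------------------------------------------------------

def solve_mrna_level(kin: KineticParams, t: float) -> float:
    """Closed-form mRNA abundance M(t) after a step change at t = 0.

    M(t) = (alpha_4/k_4)(1 − e^{−k_4 t}) + M0 e^{−k_4 t} with the pre-cold
    steady state M0 = alpha_22/k_22.  Exact; no numerical integration.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    m0 = kin.m0
    e = math.exp(-kin.k_4 * t)
    return (kin.alpha_4 / kin.k_4) * (1.0 - e) + m0 * e


def mrna_level(kin: KineticParams, t: float) -> float:
    """M(t) allowing the optional late synthesis phase (transient genes).

    Identical to :func:`solve_mrna_level` when ``kin.alpha_4_late`` is unset;
    otherwise synthesis switches to ``alpha_4_late`` at ``t_late`` and decay
    continues from M(t_late) in closed form.
    """
    if kin.alpha_4_late is None or t <= kin.t_late:
        return solve_mrna_level(kin, t)
    m_switch = solve_mrna_level(kin, kin.t_late)
    dt = t - kin.t_late
    e = math.exp(-kin.k_4 * dt)
    return (kin.alpha_4_late / kin.k_4) * (1.0 - e) + m_switch * e


def synthesis_rate(kin: KineticParams, t: float) -> float:
    """Instantaneous synthesis rate alpha(t) under the step/late-phase model."""
    if t <= 0:
        return kin.alpha_22
    if kin.alpha_4_late is not None and t > kin.t_late:
        return kin.alpha_4_late
    return kin.alpha_4


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _antisense_window(gene: GeneModel) -> tuple[int, int]:
    """Union of the 3′-half and the 20%-downstream window (contiguous)."""
    half, down = pas_windows(gene)
    if gene.strand == "+":
        return half[0], down[1]
    return down[0], half[1]


def _antisense_span(gene: GeneModel, as_tss: int, chrom_len: int) -> tuple[int, int]:
    """Span of the antisense unit: from as_tss to 1 kb past the host TSS."""
    if gene.strand == "+":
        lo = max(0, gene.tss - AS_EXTENSION)
        return lo, as_tss + 1
    hi = min(chrom_len, gene.tss + AS_EXTENSION + 1)
    return as_tss, hi


def simulate_genome(
    n_genes: int,
    frac_pas: float = 0.25,
    frac_tf: float = 0.3,
    chrom_len: int = 2_000_000,
    seed: int = 0,
    *,
    chrom: str = "chrS",
    min_gene_len: int = 1000,
    max_gene_len: int = 3000,
    min_gap: int = 3000,
    max_gap: int = 6000,
    n_transient: int = 25,
    n_up: int = 20,
    n_down: int = 20,
    tf_pas_enrichment: float = 3.0,
) -> tuple[list[GeneModel], TruthTable]:
    """Place non-overlapping genes on a toy chromosome and assign ground truth.

    Exactly ``round(n_genes * frac_pas)`` genes are flagged as PAS hosts; each
    gets an antisense TSS drawn uniformly from the union of its 3′-half and
    20%-downstream window, so truth satisfies the PAS classification rule by
    construction.  TF flags are drawn with ``tf_pas_enrichment``-fold higher
    odds for PAS genes, mirroring the observed enrichment of transcription
    factors among antisense hosts.  DE classes: ``n_transient`` genes (drawn
    preferentially from PAS TFs) peak at 3 h and fall back by 12 h;
    ``n_up``/``n_down`` change persistently; the rest are null.
    """
    if not (0 <= frac_pas <= 1 and 0 <= frac_tf <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if n_genes == 0:
        return [], TruthTable()

    rng = np.random.default_rng(seed)
    margin = AS_EXTENSION + 500  # room for antisense extensions at the edges

    lengths = rng.integers(min_gene_len, max_gene_len + 1, size=n_genes)
    gaps = rng.integers(min_gap, max_gap + 1, size=n_genes)
    strands = rng.choice(["+", "-"], size=n_genes)

    genes: list[GeneModel] = []
    pos = margin + int(gaps[0] % 1000)
    for i in range(n_genes):
        start = pos
        end = start + int(lengths[i])
        if end > chrom_len - margin:
            raise PlacementError(
                f"chrom_len={chrom_len} too small to place {n_genes} genes "
                f"(failed at gene {i})"
            )
        genes.append(
            GeneModel(
                gene_id=f"g{i + 1:04d}",
                chrom=chrom,
                start=start,
                end=end,
                strand=str(strands[i]),
            )
        )
        pos = end + int(gaps[i])

    n_pas = int(round(n_genes * frac_pas))
    pas_idx = set(rng.choice(n_genes, size=n_pas, replace=False).tolist())

    # TF flags: weighted sampling without replacement, PAS genes upweighted
    n_tf = int(round(n_genes * frac_tf))
    weights = np.array(
        [tf_pas_enrichment if i in pas_idx else 1.0 for i in range(n_genes)]
    )
    tf_idx = set(
        rng.choice(n_genes, size=n_tf, replace=False, p=weights / weights.sum()).tolist()
    )
    genes = [
        GeneModel(
            gene_id=g.gene_id,
            chrom=g.chrom,
            start=g.start,
            end=g.end,
            strand=g.strand,
            is_tf=(i in tf_idx),
        )
        for i, g in enumerate(genes)
    ]

    # DE class assignment: transient genes preferentially from PAS TFs
    pas_tf = [i for i in range(n_genes) if i in pas_idx and i in tf_idx]
    pas_other = [i for i in range(n_genes) if i in pas_idx and i not in tf_idx]
    rest = [i for i in range(n_genes) if i not in pas_idx]
    pool = pas_tf + pas_other + rest  # priority order for transient picks
    n_transient = min(n_transient, n_genes)
    transient = set(pool[:n_transient])
    remaining = [i for i in range(n_genes) if i not in transient]
    rng.shuffle(remaining)
    up = set(remaining[:n_up])
    down = set(remaining[n_up : n_up + n_down])

    truth = TruthTable()
    for i, g in enumerate(genes):
        alpha_22 = float(rng.lognormal(mean=0.0, sigma=0.5))
        fast = g.is_tf or (i in pas_idx)
        k_22 = (_K_FAST if fast else _K_SLOW) * float(
            rng.lognormal(mean=0.0, sigma=0.15)
        )
        if i in transient:
            k_4 = _K_COLD_TRANSIENT * float(rng.lognormal(mean=0.0, sigma=0.1))
            fc_peak, fc_late = _FC_TRANSIENT_PEAK, 1.0
        elif i in up:
            k_4 = k_22
            fc_peak = fc_late = _FC_UP
        elif i in down:
            k_4 = k_22
            fc_peak = fc_late = _FC_DOWN
        else:
            k_4 = k_22
            fc_peak = fc_late = 1.0
        m0 = alpha_22 / k_22
        alpha_4 = fc_peak * k_4 * m0
        alpha_4_late = None if fc_late == fc_peak else fc_late * k_4 * m0
        kin = KineticParams(
            alpha_22=alpha_22,
            alpha_4=alpha_4,
            k_22=k_22,
            k_4=k_4,
            alpha_4_late=alpha_4_late,
        )

        if i in pas_idx:
            lo, hi = _antisense_window(g)
            as_tss = int(rng.integers(lo, hi))
            span = _antisense_span(g, as_tss, chrom_len)
        else:
            as_tss, span = None, None

        if i in transient:
            de_0_3, de_3_12 = "UP", "DOWN"
        elif i in up:
            de_0_3, de_3_12 = "UP", "nonDE"
        elif i in down:
            de_0_3, de_3_12 = "DOWN", "nonDE"
        else:
            de_0_3 = de_3_12 = "nonDE"

        truth.records[g.gene_id] = GeneTruth(
            gene_id=g.gene_id,
            is_pas=(i in pas_idx),
            as_tss=as_tss,
            as_unit_span=span,
            kinetics=kin,
            de_0_3=de_0_3,
            de_3_12=de_3_12,
        )

    return genes, truth


# ---------------------------------------------------------------------------
# nascent coverage
# ---------------------------------------------------------------------------

def simulate_nascent_coverage(
    genes: Sequence[GeneModel],
    truth: TruthTable,
    condition: str,
    depth: float = 10.0,
    stall_amp: float = 3.0,
    seed: int = 0,
    *,
    chrom_len: Optional[int] = None,
    plus1_offset: int = 150,
    stall_width: int = 150,
    antisense_ratio: float = 0.5,
) -> tuple[CoverageTrack, CoverageTrack]:
    """Strand-specific nascent (polymerase occupancy) coverage, Poisson noise.

    Expected per-base sense signal is proportional to the gene's current
    synthesis rate, scaled so the genome-wide 22 °C body mean is ``depth``
    reads/base, and multiplied by ``stall_amp`` over a ``stall_width``-base
    window at the +1 nucleosome (TSS + ``plus1_offset`` in gene direction).
    PAS genes add ``antisense_ratio`` × their body level on the opposite
    strand over the true antisense span.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if condition not in CONDITION_TIMES:
        raise ValueError(f"unknown condition {condition!r}")
    t = CONDITION_TIMES[condition]
    if chrom_len is None:
        chrom_len = (max(g.end for g in genes) + AS_EXTENSION + 500) if genes else 1000
    chrom = genes[0].chrom if genes else "chrS"

    expected = {"+": np.zeros(chrom_len), "-": np.zeros(chrom_len)}
    alphas22 = [truth[g.gene_id].kinetics.alpha_22 for g in genes]
    scale = depth / float(np.mean(alphas22)) if alphas22 else depth

    for g in genes:
        kin = truth[g.gene_id].kinetics
        level = scale * synthesis_rate(kin, t)
        body = expected[g.strand]
        body[g.start : g.end] += level
        if stall_amp != 1.0:
            if g.strand == "+":
                lo = g.tss + plus1_offset
                hi = min(lo + stall_width, g.end)
            else:
                hi = g.tss - plus1_offset + 1
                lo = max(hi - stall_width, g.start)
            if lo < hi:
                body[lo:hi] += level * (stall_amp - 1.0)
        tr = truth[g.gene_id]
        if tr.is_pas:
            s, e = tr.as_unit_span
            anti = "-" if g.strand == "+" else "+"
            expected[anti][s:e] += antisense_ratio * level

    rng = np.random.default_rng(seed)
    plus = rng.poisson(expected["+"]).astype(float)
    minus = rng.poisson(expected["-"]).astype(float)
    return (
        CoverageTrack(chrom=chrom, strand="+", values=plus, condition=condition),
        CoverageTrack(chrom=chrom, strand="-", values=minus, condition=condition),
    )


def expected_nascent_profile(
    genes: Sequence[GeneModel],
    truth: TruthTable,
    condition: str,
    depth: float = 10.0,
    stall_amp: float = 3.0,
    **kwargs,
) -> dict[str, np.ndarray]:
    """Noise-free expectation of :func:`simulate_nascent_coverage` (both strands)."""
    # reuse the sampling routine's deterministic expectation path by
    # regenerating with Poisson replaced: run with a throwaway seed and
    # recompute expectation analytically instead.
    t = CONDITION_TIMES[condition]
    chrom_len = kwargs.get("chrom_len") or (
        (max(g.end for g in genes) + AS_EXTENSION + 500) if genes else 1000
    )
    plus1_offset = kwargs.get("plus1_offset", 150)
    stall_width = kwargs.get("stall_width", 150)
    antisense_ratio = kwargs.get("antisense_ratio", 0.5)
    expected = {"+": np.zeros(chrom_len), "-": np.zeros(chrom_len)}
    alphas22 = [truth[g.gene_id].kinetics.alpha_22 for g in genes]
    scale = depth / float(np.mean(alphas22)) if alphas22 else depth
    for g in genes:
        kin = truth[g.gene_id].kinetics
        level = scale * synthesis_rate(kin, t)
        expected[g.strand][g.start : g.end] += level
        if stall_amp != 1.0:
            if g.strand == "+":
                lo = g.tss + plus1_offset
                hi = min(lo + stall_width, g.end)
            else:
                hi = g.tss - plus1_offset + 1
                lo = max(hi - stall_width, g.start)
            if lo < hi:
                expected[g.strand][lo:hi] += level * (stall_amp - 1.0)
        tr = truth[g.gene_id]
        if tr.is_pas:
            s, e = tr.as_unit_span
            anti = "-" if g.strand == "+" else "+"
            expected[anti][s:e] += antisense_ratio * level
    return expected


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def simulate_counts(
    genes: Sequence[GeneModel],
    truth: TruthTable,
    schedule: ConditionSchedule = ConditionSchedule(),
    lib_sizes: Optional[Sequence[float]] = None,
    dispersion: float = 0.05,
    seed: int = 0,
) -> CountMatrix:
    """Negative-binomial steady-state counts for the cold time-course design.

    Per gene g and sample j at time t, the expected count is
    ``lib_size_j · M_g(t) / Σ_g M_g(t)``; counts are NB with
    ``var = mu + dispersion · mu²`` (Poisson at dispersion 0).
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    n_samples = schedule.n_samples
    if lib_sizes is None:
        lib_sizes = [2_000_000.0] * n_samples
    if len(lib_sizes) != n_samples:
        raise ValueError("need one library size per sample")

    gene_ids = [g.gene_id for g in genes]
    times = [t for t in schedule.timepoints for _ in range(schedule.n_replicates)]
    m = np.array(
        [[mrna_level(truth[gid].kinetics, t) for t in times] for gid in gene_ids]
    )
    totals = m.sum(axis=0)
    mu = m / totals * np.asarray(lib_sizes, dtype=float)

    rng = np.random.default_rng(seed)
    if dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    return CountMatrix(
        gene_ids=gene_ids,
        sample_ids=schedule.sample_ids(),
        counts=counts.astype(np.int64),
        conditions=schedule.sample_conditions(),
    )


def expected_counts(
    genes: Sequence[GeneModel],
    truth: TruthTable,
    schedule: ConditionSchedule = ConditionSchedule(),
    lib_sizes: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """Noise-free expectation path of :func:`simulate_counts`."""
    n_samples = schedule.n_samples
    if lib_sizes is None:
        lib_sizes = [2_000_000.0] * n_samples
    gene_ids = [g.gene_id for g in genes]
    times = [t for t in schedule.timepoints for _ in range(schedule.n_replicates)]
    m = np.array(
        [[mrna_level(truth[gid].kinetics, t) for t in times] for gid in gene_ids]
    )
    return m / m.sum(axis=0) * np.asarray(lib_sizes, dtype=float)


# ---------------------------------------------------------------------------
# decay series (qPCR after transcription inhibition)
# ---------------------------------------------------------------------------

DECAY_TIMES = (0.0, 15.0, 30.0, 60.0, 120.0)


@dataclass
class DecaySeries:
    """Cq time course after transcription inhibition, replicates × timepoints."""

    times: np.ndarray
    cq: np.ndarray  # shape (n_replicates, n_times)
    temperature: float = 22.0
    gene_id: str = ""
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cq = np.atleast_2d(np.asarray(self.cq, dtype=float))
        if self.times[0] != 0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing and start at 0")
        if self.cq.shape[1] != self.times.size:
            raise ValueError("cq must have one column per timepoint")
        if not (1.0 < self.efficiency <= 2.0):
            raise ValueError("amplification efficiency must lie in (1, 2]")


def simulate_decay_series(
    kin: KineticParams,
    temperature: float = 22.0,
    cq0: float = 20.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    *,
    n_replicates: int = 3,
    gene_id: str = "",
) -> DecaySeries:
    """Cq series under pure exponential decay after transcription shut-off.

    M(t) = M0 e^{−kt} with k = k_22 or k_4 by temperature, so the noise-free
    Cq rises linearly: Cq(t) = cq0 + k t / ln 2 (one cycle per halving).
    """
    if temperature not in (22, 4, 22.0, 4.0):
        raise ValueError("temperature must be 22 or 4")
    k = kin.k_22 if temperature == 22 else kin.k_4
    t = np.asarray(DECAY_TIMES)
    clean = cq0 + k * t / math.log(2)
    rng = np.random.default_rng(seed)
    cq = clean[None, :] + rng.normal(0.0, noise_sd, size=(n_replicates, t.size))
    return DecaySeries(times=t, cq=cq, temperature=float(temperature), gene_id=gene_id)


# ---------------------------------------------------------------------------
# electrolyte leakage
# ---------------------------------------------------------------------------

#: the freezing ramp: −2 °C start, −1 °C per 30 min, sampled each degree
DEFAULT_LEAKAGE_TEMPS = tuple(float(t) for t in range(-1, -11, -1))


@dataclass
class LeakageCurve:
    """% electrolyte leakage vs temperature, long form over replicates."""

    genotype: str
    temperatures: np.ndarray  # one entry per observation
    el_percent: np.ndarray
    replicates: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.el_percent = np.asarray(self.el_percent, dtype=float)
        if self.temperatures.shape != self.el_percent.shape:
            raise ValueError("temperatures and el_percent must align")
        if np.any((self.el_percent < 0) | (self.el_percent > 100)):
            raise ValueError("el_percent must lie in [0, 100]")


def logistic_el(
    temp: np.ndarray, bottom: float, top: float, lt50: float, hill: float
) -> np.ndarray:
    """4-parameter logistic leakage model, rising as temperature falls."""
    return bottom + (top - bottom) / (1.0 + np.exp(hill * (np.asarray(temp) - lt50)))


def simulate_leakage(
    lt50_true: float,
    hill: float = 1.0,
    bottom: float = 5.0,
    top: float = 95.0,
    temps: Sequence[float] = DEFAULT_LEAKAGE_TEMPS,
    n_reps: int = 3,
    noise_sd: float = 3.0,
    seed: int = 0,
    *,
    genotype: str = "WT",
) -> LeakageCurve:
    """Sigmoidal leakage-vs-temperature observations with Gaussian noise.

    EL(T) = bottom + (top − bottom) / (1 + exp(hill (T − lt50))); replicate
    noise is clamped into [0, 100].
    """
    temps = np.asarray(temps, dtype=float)
    clean = logistic_el(temps, bottom, top, lt50_true, hill)
    rng = np.random.default_rng(seed)
    obs = clean[None, :] + rng.normal(0.0, noise_sd, size=(n_reps, temps.size))
    obs = np.clip(obs, 0.0, 100.0)
    reps = np.repeat(np.arange(1, n_reps + 1), temps.size)
    return LeakageCurve(
        genotype=genotype,
        temperatures=np.tile(temps, n_reps),
        el_percent=obs.ravel(),
        replicates=reps,
    )
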