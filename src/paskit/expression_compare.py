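"""Differential expression and cross-assay concordance.

Counts are normalised by median-of-ratios size factors and tested per gene
with a negative-binomial Wald test on the log2 fold change (method-of-moments
dispersion, pooled across genes or shrunk per gene).  Genes are called UP /
DOWN at FDR < 0.05 and |log2FC| ≥ 0.5, the thresholds used throughout the
cold-response comparison; nascent and steady-state result tables are then
intersected to quantify their (dis)agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .models import CountMatrix

__all__ = [
    "DEResult",
    "OverlapSummary",
    "estimate_size_factors",
    "test_differential",
    "bh_adjust",
    "overlap_de",
    "match_induction_pattern",
    "compare_gene_classes",
    "classify_cold_responsive",
    "FDR_THRESHOLD",
    "LFC_THRESHOLD",
]

FDR_THRESHOLD = 0.05
LFC_THRESHOLD = 0.5
_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    log2fc: float
    p: float
    fdr: float
    call: str  # UP | DOWN | nonDE


@dataclass(frozen=True)
class OverlapSummary:
    n_up_a: int
    n_down_a: int
    n_up_b: int
    n_down_b: int
    n_up_both: int
    n_down_both: int
    fc_correlation: Optional[float]


def estimate_size_factors(m: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors.

    Each sample's factor is the median, over genes expressed in every sample,
    of that sample's count divided by the gene's geometric mean across
    samples.  Stored on the matrix and returned.
    """
    counts = m.counts.astype(float)
    if counts.shape[1] == 1:
        m.size_factors = np.ones(1)
        return m.size_factors
    allpos = np.all(counts > 0, axis=1)
    if not np.any(allpos):
        raise ValueError("no gene has nonzero counts in all samples")
    ref = counts[allpos]
    log_geomean = np.mean(np.log(ref), axis=1)
    factors = np.exp(np.median(np.log(ref) - log_geomean[:, None], axis=0))
    m.size_factors = factors
    return factors


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.clip(adjusted, 0.0, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


def _call(log2fc: float, fdr: float) -> str:
    if fdr < FDR_THRESHOLD and log2fc >= LFC_THRESHOLD:
        return "UP"
    if fdr < FDR_THRESHOLD and log2fc <= -LFC_THRESHOLD:
        return "DOWN"
    return "nonDE"


def test_differential(
    m: CountMatrix,
    cond_a: str,
    cond_b: str,
    dispersion_mode: str = "pooled",
) -> list[DEResult]:
    """NB Wald test of cond_b vs cond_a per gene.

    log2FC is computed from size-factor-normalised condition means with a
    0.5 pseudocount.  Gene-wise dispersions come from a method-of-moments
    estimate on normalised counts; ``pooled`` uses a single genome-wide
    median, ``per_gene`` shrinks each gene's estimate toward that median.
    The Wald z uses a delta-method standard error of the log ratio; p-values
    are two-sided and BH-adjusted across genes.
    """
    if dispersion_mode not in ("pooled", "per_gene"):
        raise ValueError("dispersion_mode must be 'pooled' or 'per_gene'")
    idx_a, idx_b = m.samples_for(cond_a), m.samples_for(cond_b)
    if idx_a.size < 2 or idx_b.size < 2:
        raise ValueError("need >= 2 replicates per condition")
    if m.size_factors is None:
        estimate_size_factors(m)
    sf = m.size_factors
    q = m.counts.astype(float) / sf[None, :]

    qa, qb = q[:, idx_a], q[:, idx_b]
    ma, mb = qa.mean(axis=1), qb.mean(axis=1)
    log2fc = np.log2((mb + _PSEUDOCOUNT) / (ma + _PSEUDOCOUNT))

    # method-of-moments dispersion on normalised counts: within-condition
    # variance of a normalised count is mu/sf + disp * mu^2, so
    # E[var_w - poisson_term] = disp * mu2_term gene by gene
    na, nb = idx_a.size, idx_b.size
    inv_sf_a = float(np.mean(1.0 / sf[idx_a]))
    inv_sf_b = float(np.mean(1.0 / sf[idx_b]))
    wa, wb = (na - 1) / (na + nb - 2), (nb - 1) / (na + nb - 2)
    var_w = qa.var(axis=1, ddof=1) * wa + qb.var(axis=1, ddof=1) * wb
    poisson_term = ma * inv_sf_a * wa + mb * inv_sf_b * wb
    mu2_term = ma**2 * wa + mb**2 * wb
    mean_w = (ma * na + mb * nb) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_raw = (var_w - poisson_term) / mu2_term
    disp_raw = np.where(np.isfinite(disp_raw), disp_raw, 0.0)
    disp_raw = np.clip(disp_raw, 0.0, None)
    expressed = mean_w > 1.0
    if np.any(expressed):
        # moment-ratio pooled estimate; far less biased at small replicate
        # number than a median of the noisy per-gene estimates
        pooled = max(
            0.0,
            float(
                np.sum(var_w[expressed] - poisson_term[expressed])
                / np.sum(mu2_term[expressed])
            ),
        )
    else:
        pooled = 0.0
    if dispersion_mode == "pooled":
        disp = np.full(m.n_genes, pooled)
    else:
        # moderate each gene toward the pooled value (prior weight ~ 6 genes)
        n0 = 6.0
        n_eff = na + nb
        disp = (disp_raw * n_eff + pooled * n0) / (n_eff + n0)

    # delta-method variance of log2 of the normalised condition mean:
    # Var(q_gj) = mu/sf_j + disp * mu^2 on the normalised scale
    inv_sf_a = float(np.mean(1.0 / sf[idx_a]))
    inv_sf_b = float(np.mean(1.0 / sf[idx_b]))
    var_mean_a = (ma * inv_sf_a + disp * ma**2) / na
    var_mean_b = (mb * inv_sf_b + disp * mb**2) / nb
    se2 = (var_mean_a / (ma + _PSEUDOCOUNT) ** 2 + var_mean_b / (mb + _PSEUDOCOUNT) ** 2)
    se_log2 = np.sqrt(se2) / np.log(2)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se_log2 > 0, log2fc / se_log2, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    informative = (ma + mb) > 0
    p = np.where(informative, p, 1.0)
    log2fc = np.where(informative, log2fc, 0.0)
    fdr = bh_adjust(p)

    return [
        DEResult(
            gene_id=gid,
            log2fc=float(log2fc[i]),
            p=float(p[i]),
            fdr=float(fdr[i]),
            call=_call(float(log2fc[i]), float(fdr[i])),
        )
        for i, gid in enumerate(m.gene_ids)
    ]


def overlap_de(a: Sequence[DEResult], b: Sequence[DEResult]) -> OverlapSummary:
    """Same-direction overlap of two DE tables + fold-change correlation.

    The correlation (Pearson by default at the call site) is computed over
    genes called DE in the same direction in both tables; with fewer than two
    such genes it is reported as None.
    """
    calls_a = {r.gene_id: r for r in a}
    calls_b = {r.gene_id: r for r in b}
    up_a = {g for g, r in calls_a.items() if r.call == "UP"}
    down_a = {g for g, r in calls_a.items() if r.call == "DOWN"}
    up_b = {g for g, r in calls_b.items() if r.call == "UP"}
    down_b = {g for g, r in calls_b.items() if r.call == "DOWN"}
    both = sorted(up_a & up_b) + sorted(down_a & down_b)
    if len(both) >= 2:
        x = np.array([calls_a[g].log2fc for g in both])
        y = np.array([calls_b[g].log2fc for g in both])
        if np.std(x) > 0 and np.std(y) > 0:
            r = float(stats.pearsonr(x, y).statistic)
        else:
            r = None
    else:
        r = None
    return OverlapSummary(
        n_up_a=len(up_a),
        n_down_a=len(down_a),
        n_up_b=len(up_b),
        n_down_b=len(down_b),
        n_up_both=len(up_a & up_b),
        n_down_both=len(down_a & down_b),
        fc_correlation=r,
    )


def match_induction_pattern(
    de_0_3: Sequence[DEResult], de_3_12: Sequence[DEResult]
) -> list[str]:
    """Genes UP in the early contrast and DOWN in the late one (transient peak),
    sorted by gene id."""
    up = {r.gene_id for r in de_0_3 if r.call == "UP"}
    down = {r.gene_id for r in de_3_12 if r.call == "DOWN"}
    return sorted(up & down)


def compare_gene_classes(
    values: dict[str, float], class_a: Sequence[str], class_b: Sequence[str]
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U comparing a metric between two gene classes.

    Exact null distribution when both classes have ≤ 8 members and the data
    are tie-free; tie-corrected normal approximation otherwise.  Returns
    (U statistic for class_a, p).
    """
    a = np.array([values[g] for g in class_a], dtype=float)
    b = np.array([values[g] for g in class_b], dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both classes must be non-empty")
    no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def classify_cold_responsive(
    tables: Sequence[Sequence[DEResult]],
) -> dict[str, bool]:
    """Per gene: DE (UP or DOWN) in at least one of the given tables.

    Typically four tables: {nascent, steady-state} × {3 h, 12 h}.
    """
    out: dict[str, bool] = {}
    for table in tables:
        for r in table:
            out[r.gene_id] = out.get(r.gene_id, False) or r.call != "nonDE"
    return out
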