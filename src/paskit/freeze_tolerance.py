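"""Freezing tolerance from electrolyte-leakage assays.

Leakage percentages are fitted to a four-parameter logistic in temperature,
EL(T) = bottom + (top − bottom)/(1 + exp(hill (T − lt50))), whose inflection
LT50 summarises freezing tolerance; genotypes are compared with the extra
sum-of-squares F-test (one shared curve vs separate curves).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .synthetic_data import LeakageCurve, logistic_el

__all__ = [
    "LT50Fit",
    "FTestResult",
    "electrolyte_leakage",
    "fit_lt50",
    "compare_curves",
]


class FitError(RuntimeError):
    """Raised when the logistic fit fails to converge from every start."""


@dataclass(frozen=True)
class LT50Fit:
    bottom: float
    top: float
    lt50: float  # inflection temperature, °C
    hill: float  # steepness, 1/°C
    rss: float
    n_params: int = 4
    el50_abs: Optional[float] = None  # T where the fitted curve crosses 50%

    def predict(self, temps) -> np.ndarray:
        return logistic_el(np.asarray(temps, float), self.bottom, self.top, self.lt50, self.hill)


@dataclass(frozen=True)
class FTestResult:
    rss_shared: float
    rss_separate: float
    df_shared: int
    df_separate: int
    F: float
    p: float


def electrolyte_leakage(cond_before: float, cond_after: float) -> float:
    """% leakage = 100 · conductivity(before flash freeze)/conductivity(after).

    Values outside [0, 100] (before > after) are clamped with a warning.
    """
    if cond_after <= 0:
        raise ValueError("cond_after must be > 0")
    el = 100.0 * cond_before / cond_after
    if el > 100.0 or el < 0.0:
        warnings.warn("electrolyte leakage outside [0, 100]; clamped", stacklevel=2)
        el = min(max(el, 0.0), 100.0)
    return el


_LT50_START_GRID = tuple(float(t) for t in range(-2, -11, -1))


def _fit_once(temps, el, p0, bounds) -> Optional[tuple[np.ndarray, float]]:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                logistic_el, temps, el, p0=p0, bounds=bounds, maxfev=10000
            )
    except (RuntimeError, ValueError):
        return None
    rss = float(np.sum((el - logistic_el(temps, *popt)) ** 2))
    return popt, rss


def fit_lt50(
    c: LeakageCurve,
    constrain: bool = True,
    extra_starts: Sequence[Sequence[float]] = (),
) -> LT50Fit:
    """Fit the 4-parameter logistic leakage curve by multi-start least squares.

    Starts span an LT50 grid from −2 to −10 °C with bottom/top initialised
    from the data extremes; ``constrain=True`` bounds bottom/top to [0, 100]
    and hill to be positive, ``False`` fits all four parameters freely (hill
    still positive to fix the orientation).  ``extra_starts`` lets callers
    seed additional (bottom, top, lt50, hill) vectors, which
    :func:`compare_curves` uses to guarantee nesting.
    """
    temps = np.asarray(c.temperatures, float)
    el = np.asarray(c.el_percent, float)
    if np.unique(temps).size < 5:
        raise ValueError("need >= 5 distinct temperatures")
    lo_el, hi_el = float(el.min()), float(el.max())
    if constrain:
        bounds = ([0.0, 0.0, -60.0, 1e-3], [100.0, 100.0, 40.0, 50.0])
    else:
        bounds = ([-np.inf, -np.inf, -np.inf, 1e-3], [np.inf, np.inf, np.inf, np.inf])

    best: Optional[tuple[np.ndarray, float]] = None
    starts = [[lo_el, hi_el, g, 1.0] for g in _LT50_START_GRID]
    starts += [list(s) for s in extra_starts]
    for p0 in starts:
        p0 = [
            min(max(p0[0], bounds[0][0]), bounds[1][0]),
            min(max(p0[1], bounds[0][1]), bounds[1][1]),
            min(max(p0[2], bounds[0][2]), bounds[1][2]),
            min(max(p0[3], bounds[0][3]), bounds[1][3]),
        ]
        res = _fit_once(temps, el, p0, bounds)
        if res is not None and (best is None or res[1] < best[1]):
            best = res
    if best is None:
        raise FitError(
            f"logistic fit failed from all {len(starts)} starts "
            f"(n={temps.size}, EL range [{lo_el:.1f}, {hi_el:.1f}])"
        )
    (bottom, top, lt50, hill), rss = best
    el50 = None
    if bottom < 50.0 < top:
        el50 = lt50 + math.log((top - bottom) / (50.0 - bottom) - 1.0) / hill
    return LT50Fit(
        bottom=float(bottom),
        top=float(top),
        lt50=float(lt50),
        hill=float(hill),
        rss=rss,
        el50_abs=el50,
    )


def extra_ss_ftest(
    rss_shared: float, rss_separate: float, df_shared: int, df_separate: int
) -> FTestResult:
    """Extra sum-of-squares F statistic and upper-tail p for nested fits."""
    if df_shared <= df_separate or df_separate <= 0:
        raise ValueError("invalid degrees of freedom")
    rss_shared = max(rss_shared, rss_separate)  # nesting guard
    num = (rss_shared - rss_separate) / (df_shared - df_separate)
    den = rss_separate / df_separate
    f = num / den if den > 0 else math.inf
    p = float(stats.f.sf(f, df_shared - df_separate, df_separate))
    return FTestResult(
        rss_shared=rss_shared,
        rss_separate=rss_separate,
        df_shared=df_shared,
        df_separate=df_separate,
        F=float(f),
        p=p,
    )


def compare_curves(a: LeakageCurve, b: LeakageCurve, constrain: bool = True) -> FTestResult:
    """Do two genotypes share one leakage curve?  Extra sum-of-squares F-test.

    Null: one shared 4-parameter logistic for the pooled data (df = N − 4);
    alternative: separate curves per genotype (df = N − 8).  F has (4, N − 8)
    degrees of freedom.
    """
    n = a.el_percent.size + b.el_percent.size
    if n <= 8:
        raise ValueError("need more than 8 observations for residual df")
    pooled = LeakageCurve(
        genotype="pooled",
        temperatures=np.concatenate([a.temperatures, b.temperatures]),
        el_percent=np.concatenate([a.el_percent, b.el_percent]),
    )
    shared = fit_lt50(pooled, constrain=constrain)
    shared_p = [shared.bottom, shared.top, shared.lt50, shared.hill]
    # seed separate fits with the shared optimum so rss_separate <= rss_shared
    fit_a = fit_lt50(a, constrain=constrain, extra_starts=[shared_p])
    fit_b = fit_lt50(b, constrain=constrain, extra_starts=[shared_p])
    return extra_ss_ftest(
        rss_shared=shared.rss,
        rss_separate=fit_a.rss + fit_b.rss,
        df_shared=n - 4,
        df_separate=n - 8,
    )
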