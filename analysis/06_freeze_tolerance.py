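#!/usr/bin/env python
"""LT50 freezing tolerance per genotype and the nested-curve comparison.

Fits the 4-parameter logistic leakage curve for each genotype in the
simulated electrolyte-leakage assay and tests whether the genotypes share one
curve with the extra sum-of-squares F-test.  Writes results/lt50_fits.tsv and
results/lt50_comparison.json.
"""

import json
from itertools import combinations
from pathlib import Path

import pandas as pd

from paskit import io as pio
from paskit.freeze_tolerance import compare_curves, fit_lt50

ROOT = Path(__file__).resolve().parents[1] / "results"
STUDY = ROOT / "study"


def run() -> None:
    curves = pio.read_leakage(STUDY / "leakage.tsv")
    rows = []
    for name, curve in sorted(curves.items()):
        fit = fit_lt50(curve)
        rows.append(dict(genotype=name, lt50=fit.lt50, hill=fit.hill,
                         bottom=fit.bottom, top=fit.top, rss=fit.rss,
                         el50_abs=fit.el50_abs))
        print(f"{name}: LT50 {fit.lt50:.2f} C "
              f"(50% leakage crossed at {fit.el50_abs:.2f} C)")
    pd.DataFrame(rows).to_csv(ROOT / "lt50_fits.tsv", sep="\t", index=False)

    comparisons = {}
    for a, b in combinations(sorted(curves), 2):
        res = compare_curves(curves[a], curves[b])
        comparisons[f"{a}_vs_{b}"] = res.__dict__
        print(f"{a} vs {b}: F({res.df_shared - res.df_separate},"
              f"{res.df_separate}) = {res.F:.2f}, p = {res.p:.2e}")
    with open(ROOT / "lt50_comparison.json", "w") as fh:
        json.dump(comparisons, fh, indent=2)


if __name__ == "__main__":
    run()
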