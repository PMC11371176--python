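#!/usr/bin/env python
"""Metagene profiles around the +1 nucleosome, PAS vs non-PAS genes.

Builds strand-aware 500-bp windows centred 150 bp downstream of each TSS
(the +1-nucleosome stall site) for every condition and contrasts the mean
profile of PAS genes with the remaining genes; the stall peak and its cold
response are the diagnostic features.  Writes
results/metagene_<condition>_<class>.tsv (bin, mean, ci_lo, ci_hi).
"""

from pathlib import Path

import pandas as pd

from paskit import io as pio
from paskit.metagene import anchored_matrix, make_plus1_anchors, profile_summary
from paskit.models import CONDITIONS

ROOT = Path(__file__).resolve().parents[1] / "results"
STUDY = ROOT / "study"


def run() -> None:
    genes = pio.read_gff3(STUDY / "genes.gff3")
    chrom_len = max(g.end for g in genes) + 5000
    truth = pd.read_csv(STUDY / "truth.tsv", sep="\t").set_index("gene_id")
    classes = {
        "pas": [g for g in genes if truth.loc[g.gene_id, "is_pas"]],
        "nonpas": [g for g in genes if not truth.loc[g.gene_id, "is_pas"]],
    }
    for cond in CONDITIONS:
        plus = pio.read_bedgraph(STUDY / f"nascent_{cond}_plus.bedgraph", "+",
                                 chrom_len, condition=cond)
        minus = pio.read_bedgraph(STUDY / f"nascent_{cond}_minus.bedgraph", "-",
                                  chrom_len, condition=cond)
        for label, subset in classes.items():
            anchors = make_plus1_anchors(subset, offset=150)
            m = anchored_matrix(plus, minus, anchors)
            s = profile_summary(m)
            pd.DataFrame(
                {"bin": range(m.n_bins), "mean": s["mean"],
                 "ci_lo": s["ci_lo"], "ci_hi": s["ci_hi"]}
            ).to_csv(ROOT / f"metagene_{cond}_{label}.tsv", sep="\t", index=False)
            centre = s["mean"][m.n_bins // 2 - 8 : m.n_bins // 2 + 8].max()
            body = s["mean"][-5:].mean()  # gene body downstream of the stall
            print(f"{cond} {label}: stall peak / body ratio "
                  f"{centre / body:.2f} over {len(m.gene_ids)} genes")


if __name__ == "__main__":
    run()
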