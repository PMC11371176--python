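#!/usr/bin/env python
"""Generate the default synthetic cold-response study.

Writes the toy genome (GFF3/BED6), per-gene kinetic ground truth, strand-
specific nascent coverage for 22 °C / 3 h 4 °C / 12 h 4 °C, the steady-state
count matrix (3 replicates per condition), decay Cq series for the
transient-induction genes, and electrolyte-leakage observations for a
freezing-tolerant and a sensitive genotype.  All downstream analysis scripts
read from results/study/.
"""

from pathlib import Path

from click.testing import CliRunner

from paskit.cli import main

OUT = Path(__file__).resolve().parents[1] / "results" / "study"


def run() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    result = CliRunner().invoke(
        main, ["simulate", "--outdir", str(OUT)], catch_exceptions=False
    )
    print(result.output.strip())
    print(f"study files in {OUT}")


if __name__ == "__main__":
    run()
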