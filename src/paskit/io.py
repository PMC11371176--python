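"""Flat-file I/O for the pipeline's tables and tracks.

Genes travel as GFF3 (1-based inclusive on disk, converted to 0-based
half-open in memory) or BED6; coverage as 4-column bedGraph (already 0-based
half-open); counts, truth, decay series and leakage observations as TSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .models import CountMatrix, CoverageTrack, GeneModel, TruthTable
from .pas_caller import PASCall
from .synthetic_data import DecaySeries, LeakageCurve

GFF_SOURCE = "paskit"


# -- genes ------------------------------------------------------------------

def write_gff3(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};is_tf={'1' if g.is_tf else '0'}"
            fh.write(
                f"{g.chrom}\t{GFF_SOURCE}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def read_gff3(path) -> list[GeneModel]:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "source", "type", "start", "end", "score", "strand", "phase", "attrs"],
    )
    genes = []
    for row in df.itertuples():
        fields = dict(kv.split("=", 1) for kv in row.attrs.split(";") if "=" in kv)
        genes.append(
            GeneModel(
                gene_id=fields.get("ID", f"{row.chrom}:{row.start}"),
                chrom=row.chrom,
                start=int(row.start) - 1,
                end=int(row.end),
                strand=row.strand,
                is_tf=fields.get("is_tf", "0") == "1",
            )
        )
    return genes


def write_bed6(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_bed6(path) -> list[GeneModel]:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    return [
        GeneModel(
            gene_id=str(r.name), chrom=r.chrom, start=int(r.start),
            end=int(r.end), strand=r.strand,
        )
        for r in df.itertuples(index=False)
    ]


# -- coverage ---------------------------------------------------------------

def write_bedgraph(track: CoverageTrack, path) -> None:
    """Run-length-compressed 4-column bedGraph; zero runs are omitted."""
    v = track.values
    change = np.flatnonzero(np.diff(v) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [v.size]))
    keep = v[starts] != 0
    df = pd.DataFrame(
        {
            "chrom": track.chrom,
            "start": starts[keep],
            "end": ends[keep],
            "value": v[starts[keep]],
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%g")


def read_bedgraph(path, strand: str, chrom_len: int | None = None,
                  condition: str = "22C") -> CoverageTrack:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"])
    if df.empty:
        if chrom_len is None:
            raise ValueError("empty bedGraph needs explicit chrom_len")
        return CoverageTrack(chrom="chrS", strand=strand,
                             values=np.zeros(chrom_len), condition=condition)
    length = chrom_len if chrom_len is not None else int(df["end"].max())
    values = np.zeros(length)
    starts = df["start"].to_numpy(np.int64)
    lens = (df["end"] - df["start"]).to_numpy(np.int64)
    # expand run-length intervals without a Python-level loop
    offs = np.arange(lens.sum()) - np.repeat(np.cumsum(lens) - lens, lens)
    values[np.repeat(starts, lens) + offs] = np.repeat(
        df["value"].to_numpy(float), lens
    )
    return CoverageTrack(chrom=str(df["chrom"].iloc[0]), strand=strand,
                         values=values, condition=condition)


# -- counts -----------------------------------------------------------------

def write_counts(m: CountMatrix, path) -> None:
    df = pd.DataFrame(m.counts, index=m.gene_ids, columns=m.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_counts(path, conditions: Sequence[str] | None = None) -> CountMatrix:
    """Counts TSV; condition labels default to the sample-id prefix before
    the trailing ``_repN``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    samples = list(df.columns)
    if conditions is None:
        conditions = [s.rsplit("_rep", 1)[0] for s in samples]
    return CountMatrix(
        gene_ids=list(df.index.astype(str)),
        sample_ids=samples,
        counts=df.to_numpy(dtype=np.int64),
        conditions=list(conditions),
    )


# -- truth / calls ----------------------------------------------------------

def truth_frame(truth: TruthTable) -> pd.DataFrame:
    rows = []
    for t in truth:
        k = t.kinetics
        rows.append(
            dict(
                gene_id=t.gene_id,
                is_pas=t.is_pas,
                as_tss=-1 if t.as_tss is None else t.as_tss,
                as_start=-1 if t.as_unit_span is None else t.as_unit_span[0],
                as_end=-1 if t.as_unit_span is None else t.as_unit_span[1],
                alpha_22=k.alpha_22,
                alpha_4=k.alpha_4,
                alpha_4_late=np.nan if k.alpha_4_late is None else k.alpha_4_late,
                k_22=k.k_22,
                k_4=k.k_4,
                de_0_3=t.de_0_3,
                de_3_12=t.de_3_12,
            )
        )
    return pd.DataFrame(rows)


def write_truth(truth: TruthTable, path) -> None:
    truth_frame(truth).to_csv(path, sep="\t", index=False)


def write_pas_calls(calls: Sequence[PASCall], path) -> None:
    rows = []
    for c in calls:
        rows.append(
            dict(
                gene_id=c.gene_id,
                is_pas=c.is_pas,
                window_hit=c.window_hit,
                as_tss=-1 if c.matched_unit is None else c.matched_unit.as_tss,
                unit_start=-1 if c.matched_unit is None else c.matched_unit.span[0],
                unit_end=-1 if c.matched_unit is None else c.matched_unit.span[1],
                mean_signal=0.0 if c.matched_unit is None else c.matched_unit.mean_signal,
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_units_bed(calls: Sequence[PASCall], path) -> None:
    """Matched antisense units as BED6 (name=gene_id, score=mean_signal)."""
    with open(path, "w") as fh:
        for c in calls:
            if c.matched_unit is None:
                continue
            u = c.matched_unit
            fh.write(
                f"{u.chrom}\t{u.span[0]}\t{u.span[1]}\t{c.gene_id}\t"
                f"{u.mean_signal:.3f}\t{u.strand}\n"
            )


# -- decay / leakage --------------------------------------------------------

def write_decay_series(series: Sequence[DecaySeries], path) -> None:
    rows = []
    for s in series:
        for rep in range(s.cq.shape[0]):
            for j, t in enumerate(s.times):
                rows.append(
                    dict(gene_id=s.gene_id, temperature=s.temperature,
                         time_min=t, replicate=rep + 1, cq=s.cq[rep, j])
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_decay_series(path) -> list[DecaySeries]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for (gid, temp), grp in df.groupby(["gene_id", "temperature"], sort=True):
        piv = grp.pivot_table(index="replicate", columns="time_min", values="cq")
        piv = piv.sort_index(axis=1)
        out.append(
            DecaySeries(times=piv.columns.to_numpy(float),
                        cq=piv.to_numpy(float), temperature=float(temp),
                        gene_id=str(gid))
        )
    return out


def write_leakage(curves: Sequence[LeakageCurve], path) -> None:
    rows = []
    for c in curves:
        reps = c.replicates if c.replicates is not None else np.ones(c.el_percent.size, int)
        for temp, rep, el in zip(c.temperatures, reps, c.el_percent):
            rows.append(dict(genotype=c.genotype, temperature_C=temp,
                             replicate=int(rep), el_percent=el))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_leakage(path) -> dict[str, LeakageCurve]:
    df = pd.read_csv(path, sep="\t")
    if "el_percent" not in df.columns:
        df["el_percent"] = 100.0 * df["cond_before"] / df["cond_after"]
        df["el_percent"] = df["el_percent"].clip(0.0, 100.0)
    out = {}
    for gt, grp in df.groupby("genotype", sort=True):
        out[str(gt)] = LeakageCurve(
            genotype=str(gt),
            temperatures=grp["temperature_C"].to_numpy(float),
            el_percent=grp["el_percent"].to_numpy(float),
            replicates=grp["replicate"].to_numpy(int) if "replicate" in grp else None,
        )
    return out


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
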