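"""PAS-gene calling: antisense transcription-unit detection and classification.

A PAS gene is a protein-coding gene whose antisense transcription initiates in
its 3′-half or within 20% of its length downstream of its poly(A) site.  This
module segments strand-specific coverage into transcription units and applies
that geometric rule.  Window arithmetic uses ceilings and half-open intervals:
for a + gene [s, e) of length L the 3′-half is [s + ⌈L/2⌉, e) and the
downstream window [e, e + ⌈0.2 L⌉); − genes are the exact mirror image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .models import CoverageTrack, GeneModel

__all__ = [
    "TranscriptionUnit",
    "PASCall",
    "pas_windows",
    "detect_units",
    "classify_pas",
    "call_pas_genes",
]


@dataclass(frozen=True)
class TranscriptionUnit:
    """A contiguous transcribed segment on one strand.

    ``as_tss`` is the unit's 5′-most base in its own orientation:
    ``span[0]`` on the + strand, ``span[1] - 1`` on the − strand.
    """

    chrom: str
    strand: str
    span: tuple[int, int]
    mean_signal: float

    def __post_init__(self) -> None:
        if self.span[0] >= self.span[1]:
            raise ValueError("unit span must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")

    @property
    def as_tss(self) -> int:
        return self.span[0] if self.strand == "+" else self.span[1] - 1


@dataclass(frozen=True)
class PASCall:
    gene_id: str
    is_pas: bool
    matched_unit: Optional[TranscriptionUnit]
    window_hit: str  # 3prime_half | downstream_20pct | none

    def __post_init__(self) -> None:
        if self.is_pas != (self.matched_unit is not None):
            raise ValueError("matched_unit must be set iff is_pas")
        if (self.window_hit == "none") == self.is_pas:
            raise ValueError("window_hit must be 'none' iff not is_pas")


def pas_windows(gene: GeneModel) -> tuple[tuple[int, int], tuple[int, int]]:
    """(3′-half, 20%-downstream) windows of a gene, half-open, strand-aware."""
    s, e, length = gene.start, gene.end, gene.length
    half = math.ceil(length / 2)
    down = math.ceil(0.2 * length)
    if gene.strand == "+":
        return (s + half, e), (e, e + down)
    return (s, e - half), (s - down, s)


def classify_pas(gene: GeneModel, as_tss: int, antisense_strand: str) -> str:
    """Which PAS window (if any) an antisense TSS falls in.

    Returns ``"3prime_half"``, ``"downstream_20pct"`` or ``"none"``.  Raises
    if the putative antisense unit lies on the gene's own strand.
    """
    if antisense_strand not in ("+", "-"):
        raise ValueError("antisense_strand must be '+' or '-'")
    if antisense_strand == gene.strand:
        raise ValueError(
            f"unit on strand {antisense_strand!r} is not antisense to "
            f"{gene.gene_id} ({gene.strand})"
        )
    half, down = pas_windows(gene)
    if half[0] <= as_tss < half[1]:
        return "3prime_half"
    if down[0] <= as_tss < down[1]:
        return "downstream_20pct"
    return "none"


def _segment(values: np.ndarray, min_signal: float, max_gap: int, min_len: int):
    """Maximal above-threshold runs allowing internal gaps <= max_gap."""
    above = np.flatnonzero(values >= min_signal)
    if above.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(above) > max_gap + 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [above.size - 1]))
    spans = [(int(above[i]), int(above[j]) + 1) for i, j in zip(starts, ends)]
    return [(s, e) for s, e in spans if e - s >= min_len]


def detect_units(
    cov_plus: CoverageTrack,
    cov_minus: CoverageTrack,
    min_signal: float = 1.0,
    min_len: int = 200,
    max_gap: int = 50,
) -> list[TranscriptionUnit]:
    """Segment both strand tracks into transcription units.

    A unit is a maximal run of bases with signal ≥ ``min_signal``, tolerating
    internal sub-threshold gaps of at most ``max_gap`` bases, whose span is at
    least ``min_len`` long.  Deterministic; units are returned + strand first,
    left to right.
    """
    if len(cov_plus) != len(cov_minus):
        raise ValueError("plus and minus tracks must have equal length")
    if cov_plus.chrom != cov_minus.chrom:
        raise ValueError("tracks must cover the same chromosome")
    units: list[TranscriptionUnit] = []
    for track in (cov_plus, cov_minus):
        for s, e in _segment(track.values, min_signal, max_gap, min_len):
            units.append(
                TranscriptionUnit(
                    chrom=track.chrom,
                    strand=track.strand,
                    span=(s, e),
                    mean_signal=float(track.values[s:e].mean()),
                )
            )
    return units


def call_pas_genes(
    genes: Sequence[GeneModel], units: Sequence[TranscriptionUnit]
) -> list[PASCall]:
    """One PASCall per gene, matching antisense-strand units to PAS windows.

    Among multiple matching units the one with the highest mean signal wins;
    ties break to the leftmost antisense TSS.
    """
    calls = []
    for gene in genes:
        anti = "-" if gene.strand == "+" else "+"
        best: Optional[tuple[TranscriptionUnit, str]] = None
        for unit in units:
            if unit.strand != anti or unit.chrom != gene.chrom:
                continue
            hit = classify_pas(gene, unit.as_tss, unit.strand)
            if hit == "none":
                continue
            if (
                best is None
                or unit.mean_signal > best[0].mean_signal
                or (
                    unit.mean_signal == best[0].mean_signal
                    and unit.as_tss < best[0].as_tss
                )
            ):
                best = (unit, hit)
        if best is None:
            calls.append(PASCall(gene.gene_id, False, None, "none"))
        else:
            calls.append(PASCall(gene.gene_id, True, best[0], best[1]))
    return calls
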