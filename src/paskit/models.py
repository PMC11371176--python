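"""Core domain types shared across the pipeline.

Coordinates are 0-based, half-open everywhere in memory; GFF3 I/O converts
from/to the 1-based inclusive convention at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

CONDITIONS = ("22C", "4C_3h", "4C_12h")
#: minutes since cold onset for each condition label
CONDITION_TIMES = {"22C": 0.0, "4C_3h": 180.0, "4C_12h": 720.0}


class PlacementError(ValueError):
    """Raised when genes cannot be placed on the requested chromosome."""


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene interval with TSS/poly(A)-site landmarks.

    ``tss`` is the first transcribed base (``start`` on +, ``end - 1`` on −);
    ``pas`` is the last (``end - 1`` on +, ``start`` on −).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    is_tf: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(
                f"{self.gene_id}: empty interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def pas(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class KineticParams:
    """First-order transcription–decay kinetics with a step change at cold onset.

    dM/dt = alpha(t) − k(T)·M, with synthesis alpha and decay k switching from
    their 22 °C to their 4 °C values at t = 0.  ``alpha_4_late``, when set,
    replaces ``alpha_4`` from ``t_late`` minutes onward and models genes whose
    cold induction is transient (a second synthesis phase); it is ``None`` for
    the plain single-step model.
    """

    alpha_22: float
    alpha_4: float
    k_22: float
    k_4: float
    alpha_4_late: Optional[float] = None
    t_late: float = 180.0

    def __post_init__(self) -> None:
        for name in ("alpha_22", "alpha_4", "k_22", "k_4"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.alpha_4_late is not None and not self.alpha_4_late > 0:
            raise ValueError("alpha_4_late must be > 0 when set")

    @property
    def induction_fold(self) -> float:
        """Nascent (synthesis-rate) fold change f = alpha_4 / alpha_22."""
        return self.alpha_4 / self.alpha_22

    @property
    def m0(self) -> float:
        """Pre-cold steady-state abundance alpha_22 / k_22."""
        return self.alpha_22 / self.k_22


@dataclass(frozen=True)
class GeneTruth:
    """Ground truth for one simulated gene."""

    gene_id: str
    is_pas: bool
    as_tss: Optional[int]
    as_unit_span: Optional[tuple[int, int]]
    kinetics: KineticParams
    de_0_3: str  # contrast 22C -> 4C_3h: UP / DOWN / nonDE
    de_3_12: str  # contrast 4C_3h -> 4C_12h

    def __post_init__(self) -> None:
        if self.is_pas != (self.as_tss is not None):
            raise ValueError("as_tss must be set iff is_pas")
        if self.is_pas != (self.as_unit_span is not None):
            raise ValueError("as_unit_span must be set iff is_pas")


@dataclass
class TruthTable:
    """Per-gene ground truth for a simulated genome."""

    records: dict[str, GeneTruth] = field(default_factory=dict)

    def __getitem__(self, gene_id: str) -> GeneTruth:
        return self.records[gene_id]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    @property
    def pas_gene_ids(self) -> list[str]:
        return [t.gene_id for t in self if t.is_pas]

    def genes_with_pattern(self, de_0_3: str, de_3_12: str) -> list[str]:
        return sorted(
            t.gene_id for t in self if t.de_0_3 == de_0_3 and t.de_3_12 == de_3_12
        )


@dataclass
class CoverageTrack:
    """Per-base, strand-specific signal over one chromosome for one condition."""

    chrom: str
    strand: str
    values: np.ndarray
    condition: str = "22C"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be non-negative")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class ConditionSchedule:
    """Timepoints and replication of the cold time course."""

    timepoints: tuple[float, ...] = (0.0, 180.0, 720.0)
    labels: tuple[str, ...] = CONDITIONS
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if list(self.timepoints) != sorted(set(self.timepoints)):
            raise ValueError("timepoints must be strictly increasing")
        if len(self.timepoints) != len(self.labels):
            raise ValueError("one label per timepoint required")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per condition")

    @property
    def n_samples(self) -> int:
        return len(self.timepoints) * self.n_replicates

    def sample_ids(self) -> list[str]:
        return [
            f"{lab}_rep{r + 1}"
            for lab in self.labels
            for r in range(self.n_replicates)
        ]

    def sample_conditions(self) -> list[str]:
        return [lab for lab in self.labels for _ in range(self.n_replicates)]


@dataclass
class CountMatrix:
    """Gene × sample integer counts with condition labels and size factors."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    conditions: list[str]
    size_factors: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("counts shape must be (n_genes, n_samples)")
        if len(self.conditions) != len(self.sample_ids):
            raise ValueError("one condition label per sample required")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.size_factors is not None:
            self.size_factors = np.asarray(self.size_factors, dtype=float)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def samples_for(self, condition: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.conditions) == condition)
        if idx.size == 0:
            raise ValueError(f"condition {condition!r} absent from labels")
        return idx
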