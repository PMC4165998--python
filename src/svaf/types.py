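"""Domain containers shared across the estimation pipeline.

The estimator works on three evidence channels extracted from a paired-end
alignment around a candidate structural variant (SV):

* binned **normal read-pair** depth (copy-number signal, GC-annotated),
* **discordant read pairs** (DRP) spanning each novel junction,
* **soft-clipped reads** (SR) whose clip coordinate hits a junction.

Everything downstream (rate model, maximum-likelihood VAF, genotyping)
consumes these containers; nothing in here touches files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

SV_TYPES = ("DEL", "DUP", "INV", "TRA")


@dataclass(frozen=True)
class SVCall:
    """One candidate structural variant: two breakpoint loci and a type.

    Positions are 1-based inclusive (SAM / BreakDancer convention). For
    intra-chromosomal events ``pos1 < pos2`` and ``size == pos2 - pos1``;
    translocations carry no size.
    """

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    sv_type: str
    size: Optional[int] = None
    name: Optional[str] = None

    def __post_init__(self):
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.sv_type in ("DEL", "DUP", "INV"):
            if self.chrom1 != self.chrom2:
                raise ValueError(f"{self.sv_type} must be intra-chromosomal")
            if not self.pos1 < self.pos2:
                raise ValueError("pos1 must be < pos2 for intra-chromosomal SVs")
            expected = self.pos2 - self.pos1
            if self.size is None:
                object.__setattr__(self, "size", expected)
            elif self.size != expected:
                raise ValueError(
                    f"size {self.size} inconsistent with pos2-pos1={expected}"
                )
        else:  # TRA
            if (self.chrom1, self.pos1) == (self.chrom2, self.pos2):
                raise ValueError("TRA breakpoints must differ")

    @property
    def is_balanced(self) -> bool:
        """Balanced SVs (INV, TRA) leave read depth unchanged."""
        return self.sv_type in ("INV", "TRA")

    @property
    def n_junctions(self) -> int:
        return 2 if self.is_balanced else 1


@dataclass
class LibraryParams:
    """Per-library sequencing parameters.

    ``inserts_per_bp_c`` is the genome-wide mean number of read pairs whose
    leftmost base falls on a given bp — i.e. pairs / surveyed bp. The channel
    offsets ``offset_vd``/``offset_vs`` absorb the systematic shortfall of
    observed discordant-pair and soft-clip counts relative to the idealized
    span/sequence-coverage rates (aligner behaviour, imperfect clipping);
    typical short-insert WGS sits near 0.8 and 0.7.
    """

    library_id: str = "lib0"
    read_length_r: float = 100.0
    insert_median_t: float = 500.0
    insert_spread: float = 50.0
    inserts_per_bp_c: float = 0.025
    offset_vd: float = 0.8
    offset_vs: float = 0.7

    def __post_init__(self):
        if self.read_length_r <= 0:
            raise ValueError("read_length_r must be positive")
        if self.inserts_per_bp_c <= 0:
            raise ValueError("inserts_per_bp_c must be positive")
        for name in ("offset_vd", "offset_vs"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.insert_median_t < 2 * self.read_length_r:
            warnings.warn(
                f"insert median {self.insert_median_t} < 2x read length "
                f"{self.read_length_r}: span coverage is non-positive and the "
                "discordant-pair channel will be dropped",
                stacklevel=2,
            )

    @property
    def span_per_pair(self) -> float:
        """Physical (span) coverage contribution of one pair: t - 2r."""
        return self.insert_median_t - 2 * self.read_length_r


class GCRateTable:
    """Lookup of expected normal-pair rate per bp vs integer GC percent.

    GC percent theta ranges 0..100. Strata observed in fewer than
    ``min_support`` bins fall back to the global mean rate, so the table is
    total: ``rate(theta)`` is defined for every theta.
    """

    def __init__(
        self,
        rate_by_gc: np.ndarray,
        support_by_gc: np.ndarray,
        global_rate: float,
        min_support: int = 50,
    ):
        rate_by_gc = np.asarray(rate_by_gc, dtype=float)
        support_by_gc = np.asarray(support_by_gc, dtype=int)
        if rate_by_gc.shape != (101,) or support_by_gc.shape != (101,):
            raise ValueError("rate/support tables must have 101 entries (0..100)")
        if global_rate < 0 or np.any(rate_by_gc[support_by_gc > 0] < 0):
            raise ValueError("rates must be non-negative")
        self.rate_by_gc = rate_by_gc
        self.support_by_gc = support_by_gc
        self.global_rate = float(global_rate)
        self.min_support = int(min_support)

    @classmethod
    def flat(cls, rate: float) -> "GCRateTable":
        """A GC-independent table: every stratum at the global rate."""
        return cls(np.full(101, rate), np.zeros(101, dtype=int), rate)

    def rate(self, theta) -> np.ndarray | float:
        """Expected normal pairs per bp at GC percent ``theta`` (scalar or array)."""
        theta = np.asarray(theta, dtype=int)
        supported = self.support_by_gc[theta] >= self.min_support
        out = np.where(supported, self.rate_by_gc[theta], self.global_rate)
        return float(out) if out.ndim == 0 else out

    @property
    def supported_thetas(self) -> np.ndarray:
        return np.nonzero(self.support_by_gc >= self.min_support)[0]


@dataclass
class BinCount:
    """Normal-pair count in one depth bin, with its GC percent and the
    fraction of mapping-quality-zero reads (ambiguity indicator)."""

    gc_theta: int
    width: int
    n_i: int
    mq0_fraction: float = 0.0

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("bin width must be positive")
        if self.n_i < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.mq0_fraction <= 1.0:
            raise ValueError("mq0_fraction must lie in [0, 1]")


@dataclass
class ObservedCounts:
    """The evidence D = {n_i bins, (d, s) per junction} for one SV.

    ``bins`` is empty for balanced SVs (depth is uninformative there).
    DEL/DUP carry one junction; INV and reciprocal TRA carry two.
    ``junction_gc`` optionally records the GC percent at each breakpoint so
    junction rates can be GC-normalized; absent, the global rate is used.
    """

    bins: list = field(default_factory=list)
    junctions: list = field(default_factory=list)
    library_id: str = "lib0"
    junction_gc: Optional[list] = None

    def __post_init__(self):
        for d, s in self.junctions:
            if d < 0 or s < 0:
                raise ValueError("junction counts must be non-negative")
        if self.junction_gc is not None and len(self.junction_gc) != len(self.junctions):
            raise ValueError("junction_gc length must match junctions")

    def flat_counts(self) -> np.ndarray:
        """Canonical channel order: bins, then (d, s) per junction."""
        vals = [b.n_i for b in self.bins]
        for d, s in self.junctions:
            vals.extend((d, s))
        return np.asarray(vals, dtype=float)

    @property
    def total_normal(self) -> int:
        return int(sum(b.n_i for b in self.bins))
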