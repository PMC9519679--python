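"""Shared domain types for the SV pipeline.

Coordinates are 0-based half-open throughout the package; VCF I/O converts
to/from the 1-based inclusive convention at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

log = logging.getLogger("svharvest")

#: Structural-variant types handled by the pipeline.  INDEL covers the
#: 2-49 bp size range that dedicated small-variant callers report.
SV_TYPES = ("DEL", "INS", "DUP", "INV", "TRA", "INDEL")

#: Length-category bins (bp, inclusive bounds).  The A/B boundary at 300 bp
#: is resolved A-inclusive, so the bins are [2,49], [50,300], (300,5e3],
#: (5e3,5e4], (5e4,2.5e5], (2.5e5,1e6].
CATEGORY_BOUNDS: dict[str, tuple[int, int]] = {
    "INDEL": (2, 49),
    "A": (50, 300),
    "B": (301, 5_000),
    "C": (5_001, 50_000),
    "D": (50_001, 250_000),
    "E": (250_001, 1_000_000),
}

#: Categories applicable to each SV type.  Translocations have no length,
#: so they form the single pooled class "ABCDE".
TYPE_CATEGORIES: dict[str, tuple[str, ...]] = {
    "DEL": ("A", "B", "C", "D", "E"),
    "INS": ("A", "B", "C", "D", "E"),
    "DUP": ("A", "B", "C", "D", "E"),
    "INV": ("A", "B", "C", "D", "E"),
    "TRA": ("ABCDE",),
    "INDEL": ("INDEL",),
}

#: Per-category event rates (events per bp of genome), the defaults used by
#: the truth simulator: 1.9e-6 for A-C and INDELs, 3.8e-6 for D, 1.9e-7
#: for E.
DEFAULT_MUTATION_RATES: dict[str, float] = {
    "INDEL": 1.9e-6,
    "A": 1.9e-6,
    "B": 1.9e-6,
    "C": 1.9e-6,
    "D": 3.8e-6,
    "E": 1.9e-7,
}


@dataclass
class SVRecord:
    """One SV call (or truth event) of one sample/caller.

    ``start``/``end`` are 0-based half-open.  Insertions are point variants
    (``end == start``) whose ``length`` is the inserted size (``None`` when
    the caller did not report one).  Translocations are breakpoint pairs:
    ``start``(==``end``) is the first breakpoint and ``mate`` the second.
    """

    chrom: str
    start: int
    end: int
    sv_type: str
    length: Optional[int] = None
    sample: str = ""
    caller: str = ""
    genotype: str = "1/1"
    filter_pass: bool = True
    tag: str = ""
    mate: Optional[tuple[str, int]] = None
    id: str = ""
    category_hint: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"end < start for record {self}")
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.sv_type == "TRA" and self.mate is None:
            raise ValueError("TRA record requires a mate breakpoint")

    @property
    def span(self) -> int:
        """Reference footprint in bp (0 for insertion points)."""
        return self.end - self.start

    def interval(self) -> tuple[int, int]:
        """Effective half-open interval; point variants get width 1."""
        return (self.start, max(self.end, self.start + 1))


@dataclass
class CallSet:
    """Records of one caller, possibly spanning several samples."""

    caller: str
    records: list[SVRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def of_type(self, sv_type: str) -> list[SVRecord]:
        return [r for r in self.records if r.sv_type == sv_type]


@dataclass
class TruthSet:
    """Simulated ground-truth events plus the rates that generated them."""

    records: list[SVRecord] = field(default_factory=list)
    rates: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def of_type(self, sv_type: str) -> list[SVRecord]:
        return [r for r in self.records if r.sv_type == sv_type]


@dataclass
class ReferenceSkeleton:
    """Coordinate skeleton of a genome: chromosome sizes plus N-mask and
    pericentromere tracks.  No nucleotide sequence is represented."""

    chromosomes: list[tuple[str, int]]
    n_mask: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    pericentromere: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    centromere: dict[str, int] = field(default_factory=dict)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def genome_length(self) -> int:
        return sum(l for _, l in self.chromosomes)


@dataclass
class CallerProfile:
    """Call-level error model of one SV caller.

    ``sensitivity`` and ``precision`` are keyed by ``(sv_type, category)``;
    missing keys fall back to ``default_sensitivity``/``default_precision``.
    Jitter SDs are in bp; het miscalls and filter failures are per-record
    Bernoulli events.
    """

    caller_name: str
    sensitivity: dict[tuple[str, str], float] = field(default_factory=dict)
    precision: dict[tuple[str, str], float] = field(default_factory=dict)
    default_sensitivity: float = 0.8
    default_precision: float = 0.99
    breakpoint_jitter_sd: float = 2.0
    length_jitter_sd: float = 2.0
    het_miscall_rate: float = 0.0
    fail_filter_rate: float = 0.0
    unknown_ins_length_rate: float = 0.0

    def __post_init__(self) -> None:
        for d in (self.sensitivity, self.precision):
            for key, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"probability out of [0,1] for {key}: {v}")
        if self.breakpoint_jitter_sd < 0 or self.length_jitter_sd < 0:
            raise ValueError("jitter SDs must be >= 0")
        for name in ("default_sensitivity", "default_precision",
                     "het_miscall_rate", "fail_filter_rate",
                     "unknown_ins_length_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0,1]: {v}")

    def sens(self, sv_type: str, category: str) -> float:
        return self.sensitivity.get((sv_type, category), self.default_sensitivity)

    def prec(self, sv_type: str, category: str) -> float:
        return self.precision.get((sv_type, category), self.default_precision)


@dataclass
class CohortSpec:
    """Allele-frequency and relatedness model of the inbred cohort.

    An event is a singleton with probability ``p_singleton`` (half of real
    SV clusters appear in a single inbred); otherwise its cohort frequency
    is Beta(``beta_a``, ``beta_b``).  Non-singleton carriers follow a
    founder-haplotype model: the cohort descends from ``n_founders``
    ancestral lineages, each sample inherits its founder's carrier state and
    flips it with probability ``founder_flip_rate`` — this reproduces the
    block relatedness of a diversity panel, without which neither kinship
    models nor genomic prediction have anything to work with.
    """

    n_samples: int = 23
    p_singleton: float = 0.5
    beta_a: float = 0.6
    beta_b: float = 2.0
    n_founders: int = 6
    founder_flip_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not 0.0 <= self.p_singleton <= 1.0:
            raise ValueError("p_singleton must lie in [0,1]")
        if self.n_founders < 1:
            raise ValueError("n_founders must be >= 1")
        if not 0.0 <= self.founder_flip_rate <= 0.5:
            raise ValueError("founder_flip_rate must lie in [0, 0.5]")

    @property
    def sample_ids(self) -> list[str]:
        return [f"inbred{i + 1:02d}" for i in range(self.n_samples)]


@dataclass
class SVCluster:
    """Cross-sample merged SV genotyped as presence/absence."""

    id: str
    chrom: str
    start: int
    end: int
    sv_type: str
    members: list[SVRecord] = field(default_factory=list)
    length: Optional[int] = None
    presence: Optional[np.ndarray] = None
    maf: Optional[float] = None
    te_flag: Optional[bool] = None
    gene_context: frozenset[str] = frozenset()
    mate: Optional[tuple[str, int]] = None

    @property
    def samples(self) -> set[str]:
        return {m.sample for m in self.members}

    def interval(self) -> tuple[int, int]:
        return (self.start, max(self.end, self.start + 1))


@dataclass
class Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def tss(self) -> int:
        # TSS = start on the + strand, (end - 1) on the - strand
        return self.start if self.strand == "+" else self.end - 1

    def introns(self) -> list[tuple[int, int]]:
        if not self.exons:
            return [(self.start, self.end)]
        ex = sorted(self.exons)
        out = []
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out


@dataclass
class GenomeAnnotation:
    """Gene models, TE intervals, pericentromere track and chromosome sizes."""

    genes: list[Gene]
    te_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    pericentromere: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def genes_by_chrom(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        for lst in out.values():
            lst.sort(key=lambda g: g.start)
        return out


def as_interval_arrays(
    intervals: Sequence[tuple[int, int]],
) -> tuple[np.ndarray, np.ndarray]:
    """Sorted start/end arrays for vectorised interval queries."""
    if not intervals:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    arr = np.asarray(sorted(intervals), dtype=np.int64)
    return arr[:, 0], arr[:, 1]


def merge_intervals(
    intervals: Iterable[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted non-overlapping list."""
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out
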