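"""Genomic context of SV clusters: gene association, TE overlap, hotspot
detection and TSS-centred positional profiles.

Gene context uses five labels — up5k, down5k, intron, exon, intergenic —
where the 5 kb windows are strand-aware (up5k off the 5' end, down5k off
the 3' end) and a cluster can carry several gene-associated labels;
"intergenic" applies exactly when no gene-associated label does.

TE overlap follows reciprocal-overlap rules: length-resolved clusters are
TE if some TE interval covers >= 80% of both the cluster and the TE;
unknown-length insertions if their breakpoint falls inside a TE;
translocations if either breakpoint does.

Hotspots are non-overlapping 1 Mb windows whose cluster count exceeds the
99% quantile of a Poisson distribution with the chromosome's mean window
count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .benchmark import record_length
from .types import (GenomeAnnotation, SVCluster, as_interval_arrays, log)

__all__ = ["classify_gene_association", "annotate_te", "detect_hotspots",
           "poisson_q99", "hotspots_from_counts", "tss_profile",
           "HotspotReport", "TSSProfile"]

GENE_FLANK = 5_000
RECIPROCAL_OVERLAP = 0.8


# ---------------------------------------------------------------------------
# gene context
# ---------------------------------------------------------------------------

def classify_gene_association(
    cluster: SVCluster,
    annotation: GenomeAnnotation,
    _gene_index: Optional[dict] = None,
) -> frozenset[str]:
    """Gene-context labels of one cluster (also stored on the cluster)."""
    by_chrom = (_gene_index if _gene_index is not None
                else annotation.genes_by_chrom())
    if annotation.chrom_lengths and cluster.chrom not in annotation.chrom_lengths:
        raise KeyError(f"chromosome {cluster.chrom!r} absent from annotation")
    s, e = cluster.interval()
    labels: set[str] = set()
    for g in by_chrom.get(cluster.chrom, []):
        if g.start - GENE_FLANK >= e:
            break
        if g.end + GENE_FLANK <= s:
            continue
        if g.strand == "+":
            up = (g.start - GENE_FLANK, g.start)
            down = (g.end, g.end + GENE_FLANK)
        else:
            up = (g.end, g.end + GENE_FLANK)
            down = (g.start - GENE_FLANK, g.start)
        if s < up[1] and e > up[0]:
            labels.add("up5k")
        if s < down[1] and e > down[0]:
            labels.add("down5k")
        for xs, xe in g.exons:
            if s < xe and e > xs:
                labels.add("exon")
                break
        for is_, ie in g.introns():
            if s < ie and e > is_:
                labels.add("intron")
                break
    if not labels:
        labels = {"intergenic"}
    cluster.gene_context = frozenset(labels)
    return cluster.gene_context


def classify_all(clusters: Sequence[SVCluster],
                 annotation: GenomeAnnotation) -> None:
    idx = annotation.genes_by_chrom()
    for cl in clusters:
        classify_gene_association(cl, annotation, _gene_index=idx)


# ---------------------------------------------------------------------------
# transposable elements
# ---------------------------------------------------------------------------

def _point_in_intervals(pos: int, starts: np.ndarray, ends: np.ndarray) -> bool:
    if starts.size == 0:
        return False
    i = int(np.searchsorted(starts, pos, side="right")) - 1
    return bool(i >= 0 and starts[i] <= pos < ends[i])


def annotate_te(
    cluster: SVCluster,
    te_intervals: Mapping[str, Sequence[tuple[int, int]]],
) -> bool:
    """TE flag of one cluster (also stored on the cluster)."""
    starts, ends = as_interval_arrays(list(te_intervals.get(cluster.chrom, [])))
    flag = False
    if cluster.sv_type == "TRA":
        flag = _point_in_intervals(cluster.start, starts, ends)
        if not flag and cluster.mate is not None:
            ms, me = as_interval_arrays(
                list(te_intervals.get(cluster.mate[0], [])))
            flag = _point_in_intervals(cluster.mate[1], ms, me)
    elif cluster.sv_type == "INS" and record_length_of(cluster) is None:
        flag = _point_in_intervals(cluster.start, starts, ends)
    else:
        length = record_length_of(cluster)
        if cluster.sv_type == "INS":
            # known-length insertion: compare the inserted length against the
            # TE footprint anchored at the insertion point
            s = cluster.start
            e = cluster.start + int(length or 1)
        else:
            s, e = cluster.start, max(cluster.end, cluster.start + 1)
            length = e - s
        if starts.size and length:
            ov = np.minimum(ends, e) - np.maximum(starts, s)
            te_len = ends - starts
            mask = (ov >= RECIPROCAL_OVERLAP * length) & \
                   (ov >= RECIPROCAL_OVERLAP * te_len)
            flag = bool(mask.any())
    cluster.te_flag = flag
    return flag


def record_length_of(cluster: SVCluster) -> Optional[int]:
    if cluster.length is not None:
        return cluster.length
    if cluster.sv_type in ("INS", "TRA"):
        return None
    return cluster.end - cluster.start


def annotate_te_brute_force(
    cluster: SVCluster,
    te_intervals: Mapping[str, Sequence[tuple[int, int]]],
) -> bool:
    """All-pairs reference implementation of the TE rules (test oracle)."""
    ivs = list(te_intervals.get(cluster.chrom, []))
    if cluster.sv_type == "TRA":
        if any(s <= cluster.start < e for s, e in ivs):
            return True
        if cluster.mate is not None:
            m_ivs = te_intervals.get(cluster.mate[0], [])
            return any(s <= cluster.mate[1] < e for s, e in m_ivs)
        return False
    length = record_length_of(cluster)
    if cluster.sv_type == "INS" and length is None:
        return any(s <= cluster.start < e for s, e in ivs)
    if cluster.sv_type == "INS":
        s0, e0 = cluster.start, cluster.start + int(length)
    else:
        s0, e0 = cluster.start, max(cluster.end, cluster.start + 1)
        length = e0 - s0
    for s, e in ivs:
        ov = min(e, e0) - max(s, s0)
        if ov >= RECIPROCAL_OVERLAP * length and ov >= RECIPROCAL_OVERLAP * (e - s):
            return True
    return False


# ---------------------------------------------------------------------------
# hotspots
# ---------------------------------------------------------------------------

def poisson_q99(lam: float, q: float = 0.99) -> int:
    """Smallest k with Poisson CDF(k; lam) >= q."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    return int(stats.poisson.ppf(q, lam)) if lam > 0 else 0


@dataclass
class HotspotReport:
    window: int
    lam: dict[str, float]
    q99: dict[str, int]
    counts: dict[str, np.ndarray]
    hotspots: list[tuple[str, int, int, int]] = field(default_factory=list)
    pericentromeric_fraction: Optional[float] = None

    @property
    def n_windows(self) -> int:
        return int(sum(len(c) for c in self.counts.values()))

    @property
    def hotspot_fraction(self) -> float:
        n = self.n_windows
        return len(self.hotspots) / n if n else 0.0


def hotspots_from_counts(
    counts: Mapping[str, np.ndarray],
    window: int = 1_000_000,
    q: float = 0.99,
) -> HotspotReport:
    """Flag windows whose count exceeds the Poisson Q99 of the chromosome's
    mean window count (count > q99)."""
    lam: dict[str, float] = {}
    q99: dict[str, int] = {}
    hotspots: list[tuple[str, int, int, int]] = []
    counts = {c: np.asarray(v) for c, v in counts.items()}
    for chrom, v in counts.items():
        l = float(v.mean()) if v.size else 0.0
        k = poisson_q99(l, q)
        lam[chrom] = l
        q99[chrom] = k
        for wi in np.nonzero(v > k)[0]:
            hotspots.append((chrom, int(wi) * window,
                             (int(wi) + 1) * window, int(v[wi])))
    return HotspotReport(window=window, lam=lam, q99=q99, counts=counts,
                         hotspots=hotspots)


def detect_hotspots(
    clusters: Sequence[SVCluster],
    chrom_lengths: Mapping[str, int],
    window: int = 1_000_000,
    q: float = 0.99,
    pericentromere: Optional[Mapping[str, Sequence[tuple[int, int]]]] = None,
) -> HotspotReport:
    """Count clusters (by representative start) in non-overlapping windows
    per chromosome and flag hotspots; optionally report the fraction of
    hotspots whose window midpoint lies in a pericentromeric interval."""
    counts: dict[str, np.ndarray] = {}
    for chrom, length in chrom_lengths.items():
        n_win = max(1, -(-length // window))
        if length < window:
            log.info("chromosome %s shorter than one %d bp window", chrom,
                     window)
        counts[chrom] = np.zeros(n_win, dtype=int)
    for cl in clusters:
        if cl.chrom in counts:
            wi = min(cl.start // window, len(counts[cl.chrom]) - 1)
            counts[cl.chrom][wi] += 1
    report = hotspots_from_counts(counts, window=window, q=q)
    if pericentromere is not None and report.hotspots:
        inside = 0
        for chrom, ws, we, _ in report.hotspots:
            mid = (ws + we) // 2
            if any(s <= mid < e for s, e in pericentromere.get(chrom, [])):
                inside += 1
        report.pericentromeric_fraction = inside / len(report.hotspots)
    return report


# ---------------------------------------------------------------------------
# TSS profile
# ---------------------------------------------------------------------------

@dataclass
class TSSProfile:
    offsets: np.ndarray            # -flank .. +flank
    sv_counts: np.ndarray
    snv_counts: np.ndarray

    def proportion_difference(self, track: str = "sv") -> np.ndarray:
        """1 - count/max(count); 0 where the track peaks."""
        c = self.sv_counts if track == "sv" else self.snv_counts
        m = c.max()
        return 1.0 - c / m if m > 0 else np.zeros_like(c, dtype=float)


def tss_profile(
    clusters: Sequence[SVCluster],
    snv_positions: Mapping[str, np.ndarray],
    annotation: GenomeAnnotation,
    flank: int = 5_000,
) -> TSSProfile:
    """Aggregate SV-cluster coverage and SNV density around gene TSSs.

    Offsets are strand-oriented (upstream negative).  An SV cluster
    contributes to every offset its interval covers; an SNV contributes to
    the single offset of its position.
    """
    size = 2 * flank + 1
    sv_counts = np.zeros(size, dtype=np.int64)
    snv_counts = np.zeros(size, dtype=np.int64)
    by_chrom: dict[str, list[SVCluster]] = {}
    for cl in clusters:
        by_chrom.setdefault(cl.chrom, []).append(cl)
    for lst in by_chrom.values():
        lst.sort(key=lambda c: c.start)
    starts_by_chrom = {c: np.array([cl.start for cl in lst])
                       for c, lst in by_chrom.items()}
    for g in annotation.genes:
        tss = g.tss
        lo, hi = tss - flank, tss + flank + 1
        lst = by_chrom.get(g.chrom, [])
        if lst:
            starts = starts_by_chrom[g.chrom]
            # clusters with start < hi; filter by end afterwards
            j_hi = int(np.searchsorted(starts, hi))
            for cl in lst[:j_hi]:
                s, e = cl.interval()
                if e <= lo:
                    continue
                a, b = max(s, lo), min(e, hi)
                if a >= b:
                    continue
                if g.strand == "+":
                    sv_counts[a - tss + flank:b - tss + flank] += 1
                else:
                    sv_counts[tss - (b - 1) + flank:tss - a + flank + 1] += 1
        pos = snv_positions.get(g.chrom)
        if pos is not None and len(pos):
            pos = np.asarray(pos)
            sel = pos[(pos >= lo) & (pos < hi)]
            off = (sel - tss) if g.strand == "+" else (tss - sel)
            np.add.at(snv_counts, off + flank, 1)
    return TSSProfile(offsets=np.arange(-flank, flank + 1),
                      sv_counts=sv_counts, snv_counts=snv_counts)
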