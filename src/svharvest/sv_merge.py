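"""Per-sample call filtering and cross-sample merging into SV clusters.

Filtering keeps PASS, homozygous-alternative (1/1), non-RPL calls that do
not sit in all-N reference regions; among same-sample calls with
overlapping footprints only the smallest survives; calls larger than 1 Mb
are dropped.

Clustering scans one (SV type, chromosome) track in coordinate order and
joins a record to an open cluster when (a) the distance to the cluster's
nearest member start is below 20 bp (category A / INDEL) or 50 bp (B-E)
and (b) both breakpoints differ from the cluster representative (the
member-wise median) by less than 10 bp (A / INDEL) or 50 bp (B-E).
Unknown-length insertions cluster on the start position alone (10 bp);
translocations require both breakpoints to agree within 50 bp.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .benchmark import classify_length_category, record_length, OUT_OF_RANGE
from .types import CallSet, ReferenceSkeleton, SVCluster, SVRecord

__all__ = ["filter_sample_calls", "cluster_svs", "genotype_clusters",
           "summarize_clusters", "summary_report"]

MAX_SV_LENGTH = 1_000_000

DEFAULT_CALLER_PRIORITY = ("Manta", "GRIDSS", "Pindel", "Delly", "Lumpy",
                           "NGSEP", "GATK")


def _inside_n_region(rec: SVRecord,
                     n_mask: Sequence[tuple[int, int]]) -> bool:
    """True when the record's footprint lies entirely within an N-run."""
    if not n_mask:
        return False
    s, e = rec.interval()
    idx = bisect.bisect_right([iv[0] for iv in n_mask], s) - 1
    if idx < 0:
        return False
    ns, ne = n_mask[idx]
    return ns <= s and e <= ne


def filter_sample_calls(
    calls: Iterable[SVRecord] | CallSet,
    ref: Optional[ReferenceSkeleton] = None,
    caller_priority: Sequence[str] = DEFAULT_CALLER_PRIORITY,
) -> list[SVRecord]:
    """Apply the per-sample retention rules to one sample's calls.

    Retains PASS + genotype 1/1 + non-RPL records outside all-N regions,
    drops records longer than 1 Mb, and resolves same-sample overlapping
    footprints by keeping only the smallest record (ties: leftmost, then
    caller priority).
    """
    records = calls.records if isinstance(calls, CallSet) else list(calls)
    samples = {r.sample for r in records}
    if len(samples) > 1:
        raise ValueError(f"calls must belong to one sample, got {samples}")
    n_mask = ref.n_mask if ref is not None else {}
    rank = {c: i for i, c in enumerate(caller_priority)}

    kept_stage1 = []
    for r in records:
        if not r.filter_pass or r.genotype != "1/1" or r.tag == "RPL":
            continue
        length = record_length(r)
        if length is not None and length > MAX_SV_LENGTH:
            continue
        if r.span > MAX_SV_LENGTH:
            continue
        if _inside_n_region(r, n_mask.get(r.chrom, [])):
            continue
        kept_stage1.append(r)

    # smallest-SV conflict resolution: greedy by increasing footprint
    def size_key(r: SVRecord) -> tuple:
        length = record_length(r)
        span = r.span if r.span > 0 else (length or 0)
        return (span, r.start, rank.get(r.caller, len(rank)))

    kept: list[SVRecord] = []
    by_chrom_kept: dict[str, list[tuple[int, int]]] = {}
    for r in sorted(kept_stage1, key=size_key):
        s, e = r.interval()
        conflict = any(ks < e and ke > s
                       for ks, ke in by_chrom_kept.get(r.chrom, []))
        if conflict:
            continue
        by_chrom_kept.setdefault(r.chrom, []).append((s, e))
        kept.append(r)
    kept.sort(key=lambda r: (r.chrom, r.start))
    return kept


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _thresholds(rec: SVRecord) -> tuple[int, int]:
    """(gap threshold, breakpoint threshold) for one record's category."""
    cat = classify_length_category(rec)
    if cat in ("A", "INDEL"):
        return 20, 10
    return 50, 50


@dataclass
class _OpenCluster:
    records: list[SVRecord]
    starts: list[int]
    ends: list[int]
    mates: list[int]

    @property
    def rep_start(self) -> float:
        return median(self.starts)

    @property
    def rep_end(self) -> float:
        return median(self.ends)

    @property
    def rep_mate(self) -> float:
        return median(self.mates) if self.mates else 0.0


def _joins(cl: _OpenCluster, rec: SVRecord) -> bool:
    gap_thr, bp_thr = _thresholds(rec)
    if rec.sv_type == "INS" and record_length(rec) is None:
        gap_thr, bp_thr = 20, 10
    if min(abs(rec.start - s) for s in cl.starts) >= gap_thr:
        return False
    if rec.sv_type == "TRA":
        assert rec.mate is not None
        return (abs(rec.start - cl.rep_start) < 50
                and abs(rec.mate[1] - cl.rep_mate) < 50)
    if rec.sv_type == "INS" and record_length(rec) is None:
        return abs(rec.start - cl.rep_start) < 10
    return (abs(rec.start - cl.rep_start) < bp_thr
            and abs(rec.end - cl.rep_end) < bp_thr)


def cluster_svs(
    filtered: Mapping[str, Sequence[SVRecord]] | Sequence[SVRecord],
) -> list[SVCluster]:
    """Merge filtered per-sample records into cross-sample SV clusters.

    Input may be a mapping sample -> records or a flat record sequence.
    Every record lands in exactly one cluster; representative coordinates
    are member-wise medians (rounded to bp).
    """
    if isinstance(filtered, Mapping):
        records = [r for recs in filtered.values() for r in recs]
    else:
        records = list(filtered)
    records = [r for r in records
               if classify_length_category(r) != OUT_OF_RANGE]

    # group tracks; TRA additionally by mate chromosome
    tracks: dict[tuple, list[SVRecord]] = {}
    for r in records:
        key = (r.sv_type, r.chrom,
               r.mate[0] if (r.sv_type == "TRA" and r.mate) else "")
        tracks.setdefault(key, []).append(r)

    clusters: list[SVCluster] = []
    cid = 0
    for key in sorted(tracks):
        recs = sorted(tracks[key], key=lambda r: (r.start, r.end,
                                                  r.sample, r.caller))
        open_clusters: list[_OpenCluster] = []
        closed: list[_OpenCluster] = []
        for rec in recs:
            # clusters whose nearest member start is out of gap range can
            # never be joined by a later (sorted) record: close them
            still_open = []
            for c in open_clusters:
                if rec.start - max(c.starts) >= 50:
                    closed.append(c)
                else:
                    still_open.append(c)
            open_clusters = still_open
            target = None
            for c in open_clusters:
                if _joins(c, rec):
                    target = c
                    break
            if target is None:
                target = _OpenCluster([], [], [], [])
                open_clusters.append(target)
            target.records.append(rec)
            target.starts.append(rec.start)
            target.ends.append(rec.end)
            if rec.sv_type == "TRA" and rec.mate is not None:
                target.mates.append(rec.mate[1])
        for c in closed + open_clusters:
            cid += 1
            clusters.append(_finalise(c, key, cid))
    clusters.sort(key=lambda c: (c.chrom, c.start, c.sv_type))
    for i, c in enumerate(clusters, start=1):
        c.id = f"cluster{i:06d}"
    return clusters


def _finalise(c: _OpenCluster, key: tuple, cid: int) -> SVCluster:
    sv_type, chrom, mate_chrom = key
    rep_start = int(round(median(c.starts)))
    rep_end = int(round(median(c.ends)))
    lengths = [record_length(r) for r in c.records]
    known = [l for l in lengths if l is not None]
    length = int(round(median(known))) if known else None
    mate = (mate_chrom, int(round(median(c.mates)))) if c.mates else None
    return SVCluster(id=f"cluster{cid:06d}", chrom=chrom, start=rep_start,
                     end=rep_end, sv_type=sv_type, members=list(c.records),
                     length=length, mate=mate)


# ---------------------------------------------------------------------------
# genotyping and summary reporting
# ---------------------------------------------------------------------------

def genotype_clusters(
    clusters: Sequence[SVCluster],
    sample_ids: Sequence[str],
) -> pd.DataFrame:
    """Presence/absence genotypes and MAF per cluster.

    Fills each cluster's ``presence`` vector (1 iff the sample contributed a
    member) and ``maf = min(f, 1 - f)`` in place, and returns a tidy table
    (cluster id x sample columns plus ``maf``).
    """
    sample_pos = {s: i for i, s in enumerate(sample_ids)}
    rows = []
    for cl in clusters:
        pres = np.zeros(len(sample_ids), dtype=np.int8)
        for m in cl.members:
            if m.sample not in sample_pos:
                raise ValueError(
                    f"member sample {m.sample!r} missing from sample_ids")
            pres[sample_pos[m.sample]] = 1
        cl.presence = pres
        f = pres.mean()
        cl.maf = float(min(f, 1.0 - f))
        rows.append([cl.id, cl.chrom, cl.start, cl.end, cl.sv_type,
                     cl.maf, *pres.tolist()])
    return pd.DataFrame(
        rows, columns=["cluster_id", "chrom", "start", "end", "sv_type",
                       "maf", *sample_ids])


def summarize_clusters(
    clusters: Sequence[SVCluster],
    n_samples: int,
) -> pd.DataFrame:
    """Per-type summary: cluster counts, call counts, singleton counts and
    mean MAF (requires :func:`genotype_clusters` to have run)."""
    rows = []
    for sv_type in sorted({c.sv_type for c in clusters}):
        sub = [c for c in clusters if c.sv_type == sv_type]
        n_singleton = sum(1 for c in sub
                          if c.presence is not None and c.presence.sum() == 1)
        mafs = [c.maf for c in sub if c.maf is not None]
        rows.append([sv_type, len(sub), sum(len(c.members) for c in sub),
                     n_singleton, float(np.mean(mafs)) if mafs else np.nan])
    return pd.DataFrame(rows, columns=["sv_type", "n_clusters", "n_calls",
                                       "n_singleton", "mean_maf"])


def singleton_percentage(n_singleton: int, n_total: int) -> float:
    """Share of clusters private to one sample, as a percentage rounded to
    one decimal (the precision the summary tables report)."""
    if n_total <= 0:
        return float("nan")
    return round(100.0 * n_singleton / n_total, 1)


def summary_report(table: pd.DataFrame) -> dict[str, float]:
    """Headline numbers from a per-type cluster-count table.

    Expects columns ``sv_type``, ``n_clusters`` and optionally
    ``n_singleton``; INDELs are reported separately from the SV total, as is
    conventional.  Returns the total SV cluster count and the singleton
    percentage (one decimal, e.g. 50.6).
    """
    sv = table[table["sv_type"] != "INDEL"]
    total = int(sv["n_clusters"].sum())
    out: dict[str, float] = {"total_sv_clusters": total}
    if "n_singleton" in table.columns:
        singletons = int(sv["n_singleton"].sum())
        out["singleton_clusters"] = singletons
        out["singleton_pct"] = singleton_percentage(singletons, total)
    if "INDEL" in set(table["sv_type"]):
        out["indel_clusters"] = int(
            table.loc[table["sv_type"] == "INDEL", "n_clusters"].sum())
    return out
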