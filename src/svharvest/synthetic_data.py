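"""Synthetic inputs for the whole pipeline.

Read-level simulation and the external SV callers are emulated at the call
level: a truth set of SV coordinates is drawn from per-category mutation
rates, and each "caller" is a stochastic corruption of that truth governed
by a :class:`~svharvest.types.CallerProfile` (per type x category
sensitivity and precision, Gaussian breakpoint jitter, genotype miscalls,
filter failures).  No nucleotide sequence is generated; nothing downstream
needs it.

The cohort generator layers on top of this: a pool of cross-sample SV
events with a singleton-heavy allele-frequency spectrum, an FPKM-like
expression matrix in which a fraction of gene-associated events shift the
expression of their gene, and replicated multi-environment phenotypes
``y_ijk = mu + E_j + G_i + (GxE)_ij + eps_ijk`` whose genetic component is a
sparse linear combination of SV presence scaled to a target entry-mean
heritability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .benchmark import classify_length_category
from .types import (CATEGORY_BOUNDS, DEFAULT_MUTATION_RATES, TYPE_CATEGORIES,
                    CallerProfile, CallSet, CohortSpec, Gene, GenomeAnnotation,
                    ReferenceSkeleton, SVRecord, TruthSet, log, merge_intervals)

__all__ = [
    "simulate_reference", "simulate_annotation", "simulate_truth_svs",
    "simulate_callset", "simulate_cohort_omics", "CohortSim",
]


# ---------------------------------------------------------------------------
# reference skeleton
# ---------------------------------------------------------------------------

def simulate_reference(
    chrom_lengths: Sequence[int],
    n_block_density: float = 2e-6,
    pericentromere_fraction: float = 0.257,
    seed: int = 0,
    n_block_size: tuple[int, int] = (200, 2_000),
) -> ReferenceSkeleton:
    """Coordinate skeleton with an N-mask and a centred pericentromere.

    N-runs are placed as a Poisson process of ``n_block_density`` blocks per
    bp with uniform block sizes; the pericentromeric track is one interval
    per chromosome covering ``pericentromere_fraction`` of its length,
    centred on the midpoint.  The default fraction matches the 25.7% genome
    share of barley pericentromeres.
    """
    if any(l < 1e5 for l in chrom_lengths):
        raise ValueError("chromosome lengths must be >= 1e5 bp")
    if not 0.0 <= pericentromere_fraction < 1.0:
        raise ValueError("pericentromere_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    chroms = [(f"chr{i + 1}H", int(l)) for i, l in enumerate(chrom_lengths)]
    n_mask: dict[str, list[tuple[int, int]]] = {}
    pericen: dict[str, list[tuple[int, int]]] = {}
    centromere: dict[str, int] = {}
    for name, length in chroms:
        n_blocks = rng.poisson(n_block_density * length)
        blocks = []
        for _ in range(n_blocks):
            size = int(rng.integers(n_block_size[0], n_block_size[1] + 1))
            start = int(rng.integers(0, max(1, length - size)))
            blocks.append((start, min(start + size, length)))
        n_mask[name] = merge_intervals(blocks)
        mid = length // 2
        centromere[name] = mid
        half = int(round(pericentromere_fraction * length / 2))
        pericen[name] = ([(mid - half, mid + half)] if half > 0 else [])
    return ReferenceSkeleton(chromosomes=chroms, n_mask=n_mask,
                             pericentromere=pericen, centromere=centromere)


# ---------------------------------------------------------------------------
# gene / TE annotation
# ---------------------------------------------------------------------------

def simulate_annotation(
    ref: ReferenceSkeleton,
    gene_density: float = 2e-5,
    te_density: float = 1e-5,
    seed: int = 0,
    gene_size: tuple[int, int] = (1_000, 8_000),
    te_size: tuple[int, int] = (300, 8_000),
    max_exons: int = 6,
) -> GenomeAnnotation:
    """Random gene models (with exon structure and strand) plus TE
    intervals, for annotation and expression simulation."""
    rng = np.random.default_rng(seed)
    genes: list[Gene] = []
    te: dict[str, list[tuple[int, int]]] = {}
    gi = 0
    for chrom, length in ref.chromosomes:
        n_genes = rng.poisson(gene_density * length)
        starts = np.sort(rng.integers(0, length - gene_size[1], size=n_genes))
        prev_end = -10_000
        for s in starts:
            size = int(rng.integers(gene_size[0], gene_size[1] + 1))
            s = int(s)
            if s < prev_end + 200:  # keep genes disjoint
                continue
            e = min(s + size, length)
            n_ex = int(rng.integers(1, max_exons + 1))
            cuts = np.sort(rng.choice(
                np.arange(s + 50, e - 50), size=2 * n_ex - 2, replace=False)) \
                if n_ex > 1 else np.empty(0, dtype=int)
            bounds = [s, *cuts.tolist(), e]
            exons = [(int(bounds[2 * k]), int(bounds[2 * k + 1]))
                     for k in range(n_ex)]
            strand = "+" if rng.random() < 0.5 else "-"
            gi += 1
            genes.append(Gene(gene_id=f"GENE{gi:05d}", chrom=chrom, start=s,
                              end=e, strand=strand, exons=exons))
            prev_end = e
        n_te = rng.poisson(te_density * length)
        blocks = []
        for _ in range(n_te):
            size = int(rng.integers(te_size[0], te_size[1] + 1))
            start = int(rng.integers(0, max(1, length - size)))
            blocks.append((start, start + size))
        te[chrom] = merge_intervals(blocks)
    return GenomeAnnotation(genes=genes, te_intervals=te,
                            pericentromere=dict(ref.pericentromere),
                            chrom_lengths=ref.chrom_lengths)


# ---------------------------------------------------------------------------
# truth sets
# ---------------------------------------------------------------------------

_PLACEMENT_TRIES = 50


def _overlaps(placed: dict[str, list[tuple[int, int]]], chrom: str,
              start: int, end: int) -> bool:
    import bisect
    ivs = placed.get(chrom, [])
    idx = bisect.bisect_left(ivs, (start, start))
    for k in (idx - 1, idx):
        if 0 <= k < len(ivs):
            s, e = ivs[k]
            if s < end and e > start:
                return True
    return False


def _place(placed: dict[str, list[tuple[int, int]]], chrom: str,
           start: int, end: int) -> None:
    import bisect
    ivs = placed.setdefault(chrom, [])
    bisect.insort(ivs, (start, end))


def simulate_truth_svs(
    ref: ReferenceSkeleton,
    rates: Optional[Mapping[str, float]] = None,
    seed: int = 0,
    sv_types: Sequence[str] = ("DEL", "INS", "DUP", "INV", "TRA", "INDEL"),
    sample: str = "sample1",
) -> TruthSet:
    """Draw a non-overlapping truth set of SV events.

    Event counts per (type, category) are Poisson with mean
    ``rate x genome length``; event lengths are uniform within the category
    bounds (the within-category distribution is not otherwise constrained,
    so uniform is assumed); positions are uniform with rejection of overlaps
    against previously placed events of the same sample.  Translocations are
    breakpoint pairs whose span is drawn from the pooled 50 bp - 1 Mb range
    of the category being simulated.
    """
    if rates is None:
        rates = DEFAULT_MUTATION_RATES
    if any(v < 0 for v in rates.values()):
        raise ValueError("mutation rates must be >= 0")
    rng = np.random.default_rng(seed)
    genome_len = ref.genome_length
    chrom_names = [c for c, _ in ref.chromosomes]
    chrom_sizes = np.array([l for _, l in ref.chromosomes], dtype=float)
    chrom_p = chrom_sizes / chrom_sizes.sum()
    placed: dict[str, list[tuple[int, int]]] = {}
    records: list[SVRecord] = []
    skipped: dict[tuple[str, str], int] = {}
    rid = 0
    for sv_type in sv_types:
        for cat in TYPE_CATEGORIES[sv_type]:
            if cat == "ABCDE":  # translocations pool all categories
                per_cat = [(c, rates.get(c, 0.0)) for c in "ABCDE"]
            else:
                per_cat = [(cat, rates.get(cat, 0.0))]
            for len_cat, rate in per_cat:
                n_events = rng.poisson(rate * genome_len)
                lo, hi = CATEGORY_BOUNDS[len_cat]
                for _ in range(n_events):
                    length = int(rng.integers(lo, hi + 1))
                    ok = False
                    for _try in range(_PLACEMENT_TRIES):
                        ci = rng.choice(len(chrom_names), p=chrom_p)
                        chrom = chrom_names[ci]
                        chrom_len = int(chrom_sizes[ci])
                        span = 1 if sv_type in ("INS", "TRA") else length
                        if chrom_len - span - 1 <= 1:
                            continue
                        start = int(rng.integers(1, chrom_len - span - 1))
                        end = start + span
                        if _overlaps(placed, chrom, start, end):
                            continue
                        mate = None
                        if sv_type == "TRA":
                            m_ci = rng.choice(len(chrom_names), p=chrom_p)
                            m_chrom = chrom_names[m_ci]
                            m_pos = int(rng.integers(
                                1, int(chrom_sizes[m_ci]) - 1))
                            if m_chrom == chrom and abs(m_pos - start) < 200:
                                continue
                            mate = (m_chrom, m_pos)
                        rid += 1
                        records.append(SVRecord(
                            chrom=chrom, start=start,
                            end=start if sv_type in ("INS", "TRA") else end,
                            sv_type=sv_type, length=length, sample=sample,
                            caller="truth", id=f"truth{rid:06d}",
                            mate=mate))
                        _place(placed, chrom, start, end)
                        ok = True
                        break
                    if not ok:
                        skipped[(sv_type, len_cat)] = \
                            skipped.get((sv_type, len_cat), 0) + 1
    if skipped:
        log.warning("genome too crowded for %d events (by type/category: %s)",
                    sum(skipped.values()),
                    {f"{t}/{c}": n for (t, c), n in sorted(skipped.items())})
    records.sort(key=lambda r: (r.chrom, r.start))
    return TruthSet(records=records, rates=dict(rates))


# ---------------------------------------------------------------------------
# call sets
# ---------------------------------------------------------------------------

def simulate_callset(
    truth: TruthSet,
    profile: CallerProfile,
    seed: int = 0,
    ref: Optional[ReferenceSkeleton] = None,
) -> CallSet:
    """Corrupt a truth set into one caller's call set.

    Each truth record is emitted with the profile's sensitivity for its
    (type, category); emitted breakpoints receive independent Gaussian
    jitter rounded to bp.  False positives are added per (type, category) at
    an expected count of ``n_emitted x (1 - p) / p`` so the expected
    precision equals the profile's target ``p``; they are placed uniformly
    on the chromosomes of the truth set (or ``ref`` if given).
    """
    rng = np.random.default_rng(seed)
    if ref is not None:
        chrom_sizes = ref.chrom_lengths
    else:
        chrom_sizes = {}
        for r in truth.records:
            chrom_sizes[r.chrom] = max(chrom_sizes.get(r.chrom, 0),
                                       r.end + 1_100_000)
    chrom_names = sorted(chrom_sizes)
    records: list[SVRecord] = []
    emitted_per_key: dict[tuple[str, str], int] = {}
    rid = 0

    def jitter(x: int, sd: float) -> int:
        return int(round(x + rng.normal(0.0, sd))) if sd > 0 else x

    for t in truth.records:
        cat = classify_length_category(t)
        key = (t.sv_type, cat)
        if rng.random() >= profile.sens(*key):
            continue
        bp_sd = profile.breakpoint_jitter_sd
        gt = "0/1" if rng.random() < profile.het_miscall_rate else "1/1"
        passed = rng.random() >= profile.fail_filter_rate
        rid += 1
        cid = f"{profile.caller_name}_{rid:06d}"
        if t.sv_type == "TRA":
            assert t.mate is not None
            pos = jitter(t.start, bp_sd)
            mpos = jitter(t.mate[1], bp_sd)
            rec = SVRecord(chrom=t.chrom, start=pos, end=pos, sv_type="TRA",
                           length=None, sample=t.sample,
                           caller=profile.caller_name, genotype=gt,
                           filter_pass=passed, mate=(t.mate[0], mpos), id=cid)
        elif t.sv_type == "INS":
            pos = jitter(t.start, bp_sd)
            length: Optional[int] = max(
                2, jitter(int(t.length or 2), profile.length_jitter_sd))
            hint = cat
            if rng.random() < profile.unknown_ins_length_rate:
                length = None
            rec = SVRecord(chrom=t.chrom, start=pos, end=pos, sv_type="INS",
                           length=length, sample=t.sample,
                           caller=profile.caller_name, genotype=gt,
                           filter_pass=passed, id=cid, category_hint=hint)
        else:
            s = jitter(t.start, bp_sd)
            e = jitter(t.end, bp_sd)
            if e <= s:
                s, e = min(s, e), min(s, e) + 1
            rec = SVRecord(chrom=t.chrom, start=s, end=e, sv_type=t.sv_type,
                           length=e - s, sample=t.sample,
                           caller=profile.caller_name, genotype=gt,
                           filter_pass=passed, id=cid)
        records.append(rec)
        emitted_per_key[key] = emitted_per_key.get(key, 0) + 1

    # false positives per (type, category)
    sample = truth.records[0].sample if truth.records else "sample1"
    for (sv_type, cat), n_emit in emitted_per_key.items():
        p = profile.prec(sv_type, cat)
        if p >= 1.0 or n_emit == 0:
            continue
        n_fp = rng.poisson(n_emit * (1.0 - p) / p)
        len_cats = list("ABCDE") if cat == "ABCDE" else [cat]
        for _ in range(n_fp):
            len_cat = len_cats[int(rng.integers(0, len(len_cats)))]
            lo, hi = CATEGORY_BOUNDS[len_cat]
            length = int(rng.integers(lo, hi + 1))
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            climit = chrom_sizes[chrom]
            span = 1 if sv_type in ("INS", "TRA") else length
            if climit - span - 1 <= 1:
                continue
            start = int(rng.integers(1, climit - span - 1))
            rid += 1
            mate = None
            end = start + span
            if sv_type in ("INS", "TRA"):
                end = start
            if sv_type == "TRA":
                m_chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
                mate = (m_chrom, int(rng.integers(1, chrom_sizes[m_chrom] - 1)))
            records.append(SVRecord(
                chrom=chrom, start=start, end=end, sv_type=sv_type,
                length=None if sv_type == "TRA" else length, sample=sample,
                caller=profile.caller_name, genotype="1/1", filter_pass=True,
                id=f"{profile.caller_name}_{rid:06d}", mate=mate,
                category_hint=len_cat if sv_type == "INS" else ""))
    records.sort(key=lambda r: (r.chrom, r.start))
    return CallSet(caller=profile.caller_name, records=records)


# ---------------------------------------------------------------------------
# cohort: genotypes, expression, phenotypes
# ---------------------------------------------------------------------------

@dataclass
class CohortSim:
    """Bundle returned by :func:`simulate_cohort_omics`."""

    sample_ids: list[str]
    cluster_events: list[SVRecord]        # one representative per event
    presence: pd.DataFrame                # events x samples, 0/1
    truth_sets: dict[str, TruthSet]       # per-sample truth
    expression: pd.DataFrame              # genes x samples, FPKM-like
    phenotypes: pd.DataFrame              # long: genotype, environment, replicate, trait, value
    expr_effects: pd.DataFrame            # event_id, gene_id, effect (log2 scale)
    genetic_values: pd.DataFrame          # traits x samples true G_i
    causal_weights: dict[str, np.ndarray] = field(default_factory=dict)


def _draw_presence(n_events: int, spec: CohortSpec,
                   rng: np.random.Generator) -> np.ndarray:
    """Presence matrix (events x samples) under the cohort's AF spectrum
    and founder-haplotype relatedness."""
    n = spec.n_samples
    founder_of = rng.integers(0, spec.n_founders, size=n)
    pres = np.zeros((n_events, n), dtype=np.int8)
    for i in range(n_events):
        if rng.random() < spec.p_singleton:
            pres[i, rng.integers(0, n)] = 1
        else:
            while True:
                f = min(max(rng.beta(spec.beta_a, spec.beta_b), 0.02), 0.98)
                founder_state = (rng.random(spec.n_founders) < f)
                row = founder_state[founder_of]
                flip = rng.random(n) < spec.founder_flip_rate
                row = np.where(flip, ~row, row).astype(np.int8)
                if row.sum() >= 1:
                    pres[i] = row
                    break
    return pres


def simulate_cohort_omics(
    ref: ReferenceSkeleton,
    spec: CohortSpec,
    annotation: GenomeAnnotation,
    sv_expr_effect: float = 1.0,
    h2: float | Mapping[str, float] = 0.6,
    n_env: int = 7,
    n_rep: int = 3,
    seed: int = 0,
    rates: Optional[Mapping[str, float]] = None,
    expr_effect_fraction: float = 0.3,
    n_causal: int = 50,
    traits: Optional[Sequence[str]] = None,
) -> CohortSim:
    """Full multi-omics cohort from one shared SV event pool.

    SV presence vectors follow the cohort's allele-frequency spectrum; a
    fraction of gene-associated events adds ``sv_expr_effect x N(0,1)``
    (log2 scale) to the expression of their gene in carrier samples; each
    trait's genetic values are a sparse linear combination of event presence
    standardised so the plot-level heritability is ``h2`` (replication then
    sharpens the adjusted entry means towards the true genetic values).
    """
    h2_map = ({t: float(h2) for t in (traits or ["trait1"])}
              if np.isscalar(h2) else dict(h2))  # type: ignore[arg-type]
    if traits is None:
        traits = list(h2_map)
    for t, v in h2_map.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"h2 for {t} must lie in [0,1], got {v}")
    rng = np.random.default_rng(seed)
    samples = spec.sample_ids

    # shared SV event pool and presence
    pool = simulate_truth_svs(ref, rates=rates,
                              seed=int(rng.integers(2**31)), sample="pool")
    events = pool.records
    presence = _draw_presence(len(events), spec, rng)
    pres_df = pd.DataFrame(presence, columns=samples,
                           index=[e.id for e in events])

    truth_sets: dict[str, TruthSet] = {}
    for si, s in enumerate(samples):
        recs = []
        for e, row in zip(events, presence):
            if row[si]:
                r = SVRecord(chrom=e.chrom, start=e.start, end=e.end,
                             sv_type=e.sv_type, length=e.length, sample=s,
                             caller="truth", id=f"{e.id}_{s}", mate=e.mate)
                recs.append(r)
        truth_sets[s] = TruthSet(records=recs, rates=dict(pool.rates))

    # expression: log2 baseline per gene + sample noise + SV effects
    genes = annotation.genes
    n_genes = len(genes)
    base = rng.normal(3.0, 2.0, size=n_genes)
    log2x = base[:, None] + rng.normal(0.0, 0.25, size=(n_genes, len(samples)))

    gene_idx_by_chrom: dict[str, list[int]] = {}
    for gi, g in enumerate(genes):
        gene_idx_by_chrom.setdefault(g.chrom, []).append(gi)
    effects = []
    for ei, e in enumerate(events):
        hit_gene = None
        for gi in gene_idx_by_chrom.get(e.chrom, []):
            g = genes[gi]
            s, en = e.start, max(e.end, e.start + 1)
            if s < g.end + 5_000 and en > g.start - 5_000:
                hit_gene = gi
                break
        if hit_gene is None or rng.random() >= expr_effect_fraction:
            continue
        eff = sv_expr_effect * rng.normal()
        log2x[hit_gene] += eff * presence[ei]
        effects.append((e.id, genes[hit_gene].gene_id, eff))
    expr = pd.DataFrame(np.power(2.0, log2x),
                        index=[g.gene_id for g in genes], columns=samples)
    effects_df = pd.DataFrame(effects, columns=["event_id", "gene_id", "effect"])

    # phenotypes under y_ijk = mu + E_j + G_i + (GxE)_ij + eps_ijk
    env_ids = [f"env{j + 1}" for j in range(n_env)]
    pheno_rows = []
    gvals = {}
    causal = {}
    for trait in traits:
        t_h2 = h2_map[trait]
        w = np.zeros(len(events))
        # causal variants are drawn among non-rare events: the heritable,
        # cross-validatable part of a trait rides on shared variation
        common = np.nonzero(presence.sum(axis=1) >= 3)[0]
        if len(common) and t_h2 > 0:
            idx = rng.choice(common, size=min(n_causal, len(common)),
                             replace=False)
            w[idx] = rng.normal(size=len(idx))
        g_raw = w @ presence  # per sample
        sd = g_raw.std()
        if sd > 0 and t_h2 > 0:
            g = (g_raw - g_raw.mean()) / sd * np.sqrt(t_h2)
        else:
            g = np.zeros(len(samples))
        causal[trait] = w
        gvals[trait] = g
        # h2 is plot-level: per-observation non-genetic variance (1 - h2)
        # split evenly between GxE and residual, so replication across
        # environments and replicates sharpens the adjusted entry means
        v_ge = 0.5 * (1.0 - t_h2)
        v_e = 0.5 * (1.0 - t_h2)
        mu = 10.0
        env_eff = rng.normal(0.0, 1.0, size=n_env)
        gxe = rng.normal(0.0, np.sqrt(v_ge), size=(len(samples), n_env))
        for si, s in enumerate(samples):
            for j, env in enumerate(env_ids):
                for k in range(n_rep):
                    y = (mu + env_eff[j] + g[si] + gxe[si, j]
                         + rng.normal(0.0, np.sqrt(v_e)))
                    pheno_rows.append((s, env, k + 1, trait, y))
    pheno = pd.DataFrame(pheno_rows, columns=["genotype", "environment",
                                              "replicate", "trait", "value"])
    gvals_df = pd.DataFrame(gvals, index=samples).T
    return CohortSim(sample_ids=samples, cluster_events=events,
                     presence=pres_df, truth_sets=truth_sets, expression=expr,
                     phenotypes=pheno, expr_effects=effects_df,
                     genetic_values=gvals_df, causal_weights=causal)
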