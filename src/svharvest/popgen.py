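"""Linkage disequilibrium and windowed nucleotide diversity for the inbred
cohort.

Inbred lines are treated as haploid haplotypes: a variant is a 0/1
presence vector over samples, so r-squared equals the squared Pearson
correlation of the two vectors, and per-site diversity uses the unbiased
estimator ``pi_site = n/(n-1) * 2 p (1-p)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .types import log

__all__ = ["ld_r2", "ld_linkage_summary", "pi_windows", "pi_site",
           "pi_track_correlation"]


def ld_r2(a: np.ndarray, b: np.ndarray) -> Optional[float]:
    """Hill-Robertson r-squared between two biallelic 0/1 vectors.

    Computed from haplotype frequencies: ``D = p_AB - p_A p_B`` and
    ``r2 = D^2 / (p_A(1-p_A) p_B(1-p_B))``.  Missing entries (NaN) are
    dropped pairwise; monomorphic input on the shared non-missing samples
    yields ``None`` (undefined), never 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have identical length")
    mask = ~(np.isnan(a) | np.isnan(b))
    if mask.sum() < 2:
        return None
    x, y = a[mask], b[mask]
    p_a, p_b = x.mean(), y.mean()
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom <= 0:
        return None
    d = (x * y).mean() - p_a * p_b
    return float(d * d / denom)


def ld_linkage_summary(
    sv_positions: np.ndarray,
    sv_presence: np.ndarray,
    snv_positions: np.ndarray,
    snv_genotypes: np.ndarray,
    window: int = 1_000,
    threshold: float = 0.6,
) -> tuple[Optional[float], Optional[float]]:
    """Fraction of SV clusters (and, as a baseline, of their closest SNVs)
    with at least one SNV within ``window`` bp reaching ``r2 >= threshold``.

    All inputs are per one chromosome; positions must be sorted for the
    SNVs.  Focal variants with no SNV in range are excluded from the
    denominator.
    """
    order = np.argsort(snv_positions)
    snv_positions = np.asarray(snv_positions)[order]
    snv_genotypes = np.asarray(snv_genotypes)[order]

    def fraction(f_positions: np.ndarray, f_geno: np.ndarray,
                 exclude_self: bool) -> Optional[float]:
        num = den = 0
        for pos, g in zip(f_positions, f_geno):
            lo = int(np.searchsorted(snv_positions, pos - window, "left"))
            hi = int(np.searchsorted(snv_positions, pos + window, "right"))
            hit = False
            any_partner = False
            for j in range(lo, hi):
                if exclude_self and snv_positions[j] == pos and \
                        np.array_equal(snv_genotypes[j], g):
                    continue
                any_partner = True
                r2 = ld_r2(g, snv_genotypes[j])
                if r2 is not None and r2 >= threshold:
                    hit = True
                    break
            if not any_partner:
                log.debug("focal variant at %d has no SNV within %d bp",
                          pos, window)
                continue
            den += 1
            num += int(hit)
        return num / den if den else None

    sv_frac = fraction(np.asarray(sv_positions), np.asarray(sv_presence),
                       exclude_self=False)

    # baseline: for each SV, its closest SNV becomes the focal variant
    closest_pos = []
    closest_geno = []
    for pos in np.asarray(sv_positions):
        if len(snv_positions) == 0:
            continue
        j = int(np.argmin(np.abs(snv_positions - pos)))
        closest_pos.append(snv_positions[j])
        closest_geno.append(snv_genotypes[j])
    snv_frac = fraction(np.asarray(closest_pos), np.asarray(closest_geno),
                        exclude_self=True) if closest_pos else None
    return sv_frac, snv_frac


def pi_site(n_carriers: int, n: int) -> float:
    """Unbiased per-site nucleotide diversity for haploid 0/1 calls."""
    if n < 2:
        raise ValueError("need at least two samples")
    p = n_carriers / n
    return n / (n - 1) * 2.0 * p * (1.0 - p)


def pi_windows(
    positions: Mapping[str, np.ndarray],
    carrier_counts: Mapping[str, np.ndarray],
    n: int,
    chrom_lengths: Mapping[str, int],
    window: int = 100_000,
) -> pd.DataFrame:
    """Windowed nucleotide diversity: per-site pi summed over the variants
    of each non-overlapping window, divided by the window length."""
    if n < 2:
        raise ValueError("need at least two samples")
    rows = []
    factor = n / (n - 1) * 2.0
    for chrom, length in chrom_lengths.items():
        n_win = max(1, -(-length // window))
        acc = np.zeros(n_win)
        pos = np.asarray(positions.get(chrom, []), dtype=int)
        cnt = np.asarray(carrier_counts.get(chrom, []), dtype=float)
        if pos.size:
            p = cnt / n
            site_pi = factor * p * (1.0 - p)
            wi = np.minimum(pos // window, n_win - 1)
            np.add.at(acc, wi, site_pi)
        for k in range(n_win):
            w_len = min(window, length - k * window)
            rows.append((chrom, k * window, k * window + w_len,
                         acc[k] / w_len))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "pi"])


def pi_track_correlation(track_a: pd.DataFrame,
                         track_b: pd.DataFrame) -> float:
    """Pearson correlation of two windowed pi tracks over shared windows."""
    merged = track_a.merge(track_b, on=["chrom", "start", "end"],
                           suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise ValueError("need at least three shared windows")
    return float(np.corrcoef(merged["pi_a"], merged["pi_b"])[0, 1])
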