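"""Pairwise linkage disequilibrium (r²) and distance-binned LD decay.

r² between two haploid sites is computed over the samples called at both:

    r² = (p_AB − p_A p_B)² / (p_A(1−p_A) p_B(1−p_B))

which equals the squared Pearson correlation of the 0/1-coded calls.
Decay curves bin pairs by distance on the same chromosome; the genome-wide
mean r² is the unweighted average of per-chromosome means, matching the
convention of computing r² per chromosome and then averaging across the
genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants_io import ALT, HET, MISSING, REF, GenotypeMatrix

__all__ = ["pairwise_r2", "LdDecayCurve", "ld_decay"]


def pairwise_r2(calls_a: np.ndarray, calls_b: np.ndarray) -> float:
    """r² of two haploid call vectors over co-called samples.

    Returns NaN when fewer than two samples are co-called or either site
    is monomorphic among them.
    """
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    ok = ((a == REF) | (a == ALT)) & ((b == REF) | (b == ALT))
    if ok.sum() < 2:
        return float("nan")
    x = (a[ok] == ALT).astype(float)
    y = (b[ok] == ALT).astype(float)
    pa = x.mean()
    pb = y.mean()
    va = pa * (1 - pa)
    vb = pb * (1 - pb)
    if va == 0 or vb == 0:
        return float("nan")
    pab = (x * y).mean()
    return float((pab - pa * pb) ** 2 / (va * vb))


@dataclass
class LdDecayCurve:
    """Distance-binned mean r² plus per-chromosome and genome summaries."""

    bin_edges: np.ndarray  # length n_bins+1, covering (0, max_dist]
    mean_r2: np.ndarray
    pair_counts: np.ndarray
    per_chrom_mean: pd.Series
    genome_mean: float
    max_dist: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dist_lo": self.bin_edges[:-1],
                "dist_hi": self.bin_edges[1:],
                "mean_r2": self.mean_r2,
                "n_pairs": self.pair_counts,
            }
        )


def _site_filters(gm, sample_idx, min_maf, max_het, max_miss):
    calls = gm.calls[:, sample_idx]
    n = len(sample_idx)
    n_het = (calls == HET).sum(axis=1)
    n_miss = (calls == MISSING).sum(axis=1)
    hap = (calls == REF) | (calls == ALT)
    n_called = hap.sum(axis=1)
    n_alt = (calls == ALT).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, n_alt / np.maximum(n_called, 1), np.nan)
    maf = np.minimum(p, 1 - p)
    keep = (
        (n_het / n <= max_het)
        & (n_miss / n <= max_miss)
        & (n_called >= 2)
        & (maf >= min_maf)
    )
    return keep


def ld_decay(
    gm: GenotypeMatrix,
    sample_idx: np.ndarray,
    min_maf: float = 0.01,
    max_het: float = 0.8,
    max_miss: float = 0.8,
    max_dist: int = 1_000_000,
    bin_width: int = 1_000,
    max_pairs: int = 10_000_000,
    seed: int = 0,
) -> LdDecayCurve:
    """LD decay within one group.

    Sites are pre-filtered by within-group MAF, heterozygous-call fraction
    and missing fraction.  Only same-chromosome pairs within ``max_dist``
    bp enter; when more than ``max_pairs`` candidate pairs exist they are
    subsampled uniformly with the recorded ``seed``.
    """
    keep = _site_filters(gm, sample_idx, min_maf, max_het, max_miss)
    sub = gm.take_sites(keep)
    edges = np.arange(0, max_dist + bin_width, bin_width, dtype=np.int64)
    n_bins = len(edges) - 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    per_chrom: dict[str, tuple[float, int]] = {}

    chroms = pd.unique(sub.sites["chrom"])
    pair_lists = []
    any_chrom_usable = False
    for chrom in chroms:
        rows = np.flatnonzero(sub.sites["chrom"].to_numpy() == chrom)
        if len(rows) < 2:
            continue
        any_chrom_usable = True
        pos = sub.sites["pos"].to_numpy()[rows]
        order = np.argsort(pos)
        rows, pos = rows[order], pos[order]
        i_idx, j_idx = np.triu_indices(len(rows), k=1)
        dist = pos[j_idx] - pos[i_idx]
        within = dist <= max_dist
        pair_lists.append((chrom, rows[i_idx[within]], rows[j_idx[within]], dist[within]))
    if not any_chrom_usable:
        raise ValueError("no chromosome has >= 2 usable SNPs for this group")
    total_pairs = sum(len(p[3]) for p in pair_lists)
    rng = np.random.default_rng(seed)
    frac = min(1.0, max_pairs / total_pairs) if total_pairs else 1.0

    hap = (sub.calls[:, sample_idx] == ALT).astype(float)
    called = (sub.calls[:, sample_idx] == REF) | (sub.calls[:, sample_idx] == ALT)
    for chrom, ii, jj, dist in pair_lists:
        if frac < 1.0:
            pick = rng.random(len(dist)) < frac
            ii, jj, dist = ii[pick], jj[pick], dist[pick]
        r2s = np.empty(len(dist))
        for k in range(len(dist)):
            a, b = ii[k], jj[k]
            ok = called[a] & called[b]
            nok = ok.sum()
            if nok < 2:
                r2s[k] = np.nan
                continue
            x = hap[a, ok]
            y = hap[b, ok]
            pa, pb = x.mean(), y.mean()
            va, vb = pa * (1 - pa), pb * (1 - pb)
            if va == 0 or vb == 0:
                r2s[k] = np.nan
                continue
            r2s[k] = ((x * y).mean() - pa * pb) ** 2 / (va * vb)
        good = ~np.isnan(r2s)
        if good.any():
            b = np.minimum((dist[good] - 1) // bin_width, n_bins - 1)
            sums += np.bincount(b, weights=r2s[good], minlength=n_bins)
            counts += np.bincount(b, minlength=n_bins)
            per_chrom[str(chrom)] = (float(r2s[good].mean()), int(good.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    chrom_means = pd.Series({c: v[0] for c, v in per_chrom.items()}, dtype=float)
    return LdDecayCurve(
        bin_edges=edges,
        mean_r2=mean_r2,
        pair_counts=counts,
        per_chrom_mean=chrom_means,
        genome_mean=float(chrom_means.mean()),
        max_dist=max_dist,
    )
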