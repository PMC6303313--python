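"""Haploid diversity statistics: π, Watterson's θ, H_E, Tajima's D, MAF spectra.

All statistics are computed on haploid-coded calls.  At a site with n
non-missing haplotypes and ALT frequency p:

    H_E   = 1 − p² − (1−p)²                (Nei's gene diversity)
    π     = H_E · n/(n−1)                  (unbiased mean pairwise difference)
    θ_W   = 1/a_n per segregating site,    a_n = Σ_{i<n} 1/i

Per-bp values divide the summed site contributions by the effective covered
length (of the mask, or of the masked part of a window), never by the
nominal span — coverage-aware normalization.  Sites with fewer than two
non-missing calls in the group are skipped entirely, including for the
segregating-site count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants_io import ALT, GenotypeMatrix, REF, RegionMask

__all__ = [
    "site_diversity_arrays",
    "WindowStat",
    "windowed_diversity",
    "GroupSummary",
    "group_summary",
    "tajimas_d",
    "tajima_constants",
    "maf_spectrum",
]


def _harmonic(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n)))


def site_diversity_arrays(gm: GenotypeMatrix, sample_idx: np.ndarray | None = None):
    """Per-site diversity contributions for one group.

    Returns a DataFrame with n, p, he_site, pi_site, theta_site and a
    ``segregating`` flag.  Sites with n < 2 contribute zeros and are not
    segregating.
    """
    p, n = gm.alt_freq(sample_idx)
    usable = n >= 2
    seg = usable & (p > 0) & (p < 1)
    he = np.where(seg, 1.0 - p**2 - (1.0 - p) ** 2, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(seg, he * n / np.maximum(n - 1, 1), 0.0)
    a_n = np.zeros_like(p)
    if seg.any():
        # 1/a_n per segregating site, a_n evaluated at that site's n
        uniq = np.unique(n[seg])
        harm = {int(k): _harmonic(int(k)) for k in uniq}
        a_n[seg] = np.array([harm[int(k)] for k in n[seg]])
    theta = np.where(seg, 1.0 / np.where(a_n > 0, a_n, 1.0), 0.0)
    return pd.DataFrame(
        {
            "chrom": gm.sites["chrom"],
            "pos": gm.sites["pos"],
            "n": n,
            "p": np.where(usable, p, np.nan),
            "he_site": he,
            "pi_site": pi,
            "theta_site": theta,
            "segregating": seg,
        }
    )


@dataclass
class WindowStat:
    chrom: str
    start: int
    end: int
    effective_length: int
    n_snps: int
    pi: float
    theta_w: float
    he: float


def windowed_diversity(
    gm: GenotypeMatrix,
    mask: RegionMask,
    sample_idx: np.ndarray | None = None,
    window: int = 10_000,
    step: int = 2_000,
    min_effective: int = 2_000,
) -> pd.DataFrame:
    """Sliding-window per-bp diversity, normalized by masked length.

    Windows of ``window`` bp every ``step`` bp tile each chromosome from
    base 0 to the mask's span; windows whose effective (masked) length is
    below ``min_effective`` are omitted.
    """
    if window < step:
        raise ValueError("window must be >= step")
    site = site_diversity_arrays(gm, sample_idx)
    out = []
    for chrom in mask.chroms():
        span = mask.span(chrom)
        sub = site[site["chrom"] == chrom]
        pos = sub["pos"].to_numpy()  # 1-based
        order = np.argsort(pos)
        pos = pos[order]
        pis = sub["pi_site"].to_numpy()[order]
        thetas = sub["theta_site"].to_numpy()[order]
        hes = sub["he_site"].to_numpy()[order]
        segs = sub["segregating"].to_numpy()[order]
        for start in range(0, max(span, 1), step):
            end = start + window
            eff = mask.overlap_length(chrom, start, end)
            if eff < min_effective:
                continue
            lo = np.searchsorted(pos, start + 1)  # pos > start (0-based start)
            hi = np.searchsorted(pos, end, side="right")
            sl = slice(lo, hi)
            n_snps = int(segs[sl].sum())
            out.append(
                (
                    chrom,
                    start,
                    end,
                    eff,
                    n_snps,
                    pis[sl].sum() / eff,
                    thetas[sl].sum() / eff,
                    hes[sl].sum() / eff,
                )
            )
    return pd.DataFrame(
        out,
        columns=[
            "chrom",
            "start",
            "end",
            "effective_length",
            "n_snps",
            "pi",
            "theta_w",
            "he",
        ],
    )


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalization constants for sample size n."""
    if n < 2:
        raise ValueError("Tajima constants require n >= 2")
    a1 = float(np.sum(1.0 / np.arange(1, n)))
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(
    gm: GenotypeMatrix,
    sample_idx: np.ndarray | None = None,
    fixed_n: int | None = None,
) -> float:
    """Tajima's D for haploid-coded data.

    D = (Π − S/a₁) / sqrt(e₁S + e₂S(S−1)) with Π the summed per-site π
    contributions and S the segregating-site count.  The constants are
    evaluated at ``fixed_n`` if given, otherwise at the rounded mean number
    of non-missing calls over segregating sites.  Returns NaN when S = 0
    (undefined, as opposed to 0).
    """
    site = site_diversity_arrays(gm, sample_idx)
    seg = site["segregating"].to_numpy()
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    Pi = float(site["pi_site"].sum())
    n = fixed_n if fixed_n is not None else int(round(site["n"][seg].mean()))
    if n < 2:
        return float("nan")
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (Pi - S / c["a1"]) / np.sqrt(var)


@dataclass
class GroupSummary:
    """Per-group genome-wide diversity, Table-1-style."""

    group: str
    n_samples: int
    S: int
    pi: float
    theta_w: float
    he: float
    tajimas_d: float


def group_summary(
    gm: GenotypeMatrix,
    mask: RegionMask,
    sample_idx: np.ndarray,
    group: str = "",
) -> GroupSummary:
    """Genome-wide per-bp π, θ_W, H_E and Tajima's D over the mask."""
    L = mask.total_length
    if L == 0:
        raise ValueError("zero-length mask")
    site = site_diversity_arrays(gm, sample_idx)
    S = int(site["segregating"].sum())
    return GroupSummary(
        group=group,
        n_samples=len(sample_idx),
        S=S,
        pi=float(site["pi_site"].sum()) / L,
        theta_w=float(site["theta_site"].sum()) / L,
        he=float(site["he_site"].sum()) / L,
        tajimas_d=tajimas_d(gm, sample_idx) if S else float("nan"),
    )


def maf_spectrum(
    gm: GenotypeMatrix,
    sample_idx: np.ndarray | None = None,
    bins: int | np.ndarray = 10,
):
    """Folded site-frequency spectrum over segregating sites.

    MAF = min(p, 1−p) from non-missing calls; the histogram is normalized
    to sum to 1.  Returns ``(bin_edges, proportions)``.
    """
    p, n = gm.alt_freq(sample_idx)
    seg = (n >= 2) & (p > 0) & (p < 1)
    maf = np.minimum(p[seg], 1 - p[seg])
    if isinstance(bins, int):
        edges = np.linspace(0, 0.5, bins + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    counts, edges = np.histogram(maf, bins=edges)
    total = counts.sum()
    props = counts / total if total else np.zeros_like(counts, dtype=float)
    return edges, props
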