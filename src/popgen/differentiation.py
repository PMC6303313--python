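"""Hudson's F_ST between groups, windowed scans, and candidate selective regions.

Per-SNP F_ST uses Hudson's estimator in the explicit two-population form

    num = (p1 − p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)
    den = p1(1−p2) + p2(1−p1)

which is unbiased with respect to unequal sample sizes.  Windows combine
SNPs either as a ratio of averages (Σnum/Σden, the recommended estimator
and the default) or as a mean of per-SNP ratios.  Windows with F_ST above
a threshold are merged into candidate selective regions and intersected
with gene annotation (±flank).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .variants_io import GenotypeMatrix, RegionMask

__all__ = [
    "hudson_fst_site",
    "fst_sites",
    "windowed_fst",
    "CandidateRegion",
    "call_candidate_regions",
    "candidate_genes",
]


def hudson_fst_site(p1, n1, p2, n2):
    """Hudson F_ST components at one site: ``(num, den, fst)``.

    Requires n1, n2 ≥ 2.  ``fst`` is NaN when den = 0 (both groups fixed
    for the same allele); negative values are legitimate and retained.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    num = (
        (p1 - p2) ** 2
        - p1 * (1 - p1) / (n1 - 1)
        - p2 * (1 - p2) / (n2 - 1)
    )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return num, den, fst


def fst_sites(
    gm: GenotypeMatrix, idx1: np.ndarray, idx2: np.ndarray
) -> pd.DataFrame:
    """Per-SNP Hudson F_ST table for two sample groups.

    Sites with fewer than two non-missing calls in either group, or with
    den = 0, are skipped.
    """
    p1, n1 = gm.alt_freq(idx1)
    p2, n2 = gm.alt_freq(idx2)
    ok = (n1 >= 2) & (n2 >= 2)
    num, den, fst = hudson_fst_site(p1[ok], n1[ok], p2[ok], n2[ok])
    keep = den > 0
    sites = gm.sites.loc[ok, ["chrom", "pos"]].reset_index(drop=True)[keep]
    return pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy(),
            "pos": sites["pos"].to_numpy(),
            "p1": p1[ok][keep],
            "p2": p2[ok][keep],
            "n1": n1[ok][keep],
            "n2": n2[ok][keep],
            "num": num[keep],
            "den": den[keep],
            "fst": fst[keep],
        }
    )


def windowed_fst(
    sites: pd.DataFrame,
    mask: RegionMask,
    window: int = 10_000,
    step: int = 2_000,
    min_density: float = 5.0,
    mode: str = "ratio_of_averages",
    density_against: str = "effective",
) -> pd.DataFrame:
    """Sliding-window F_ST; windows need ≥ ``min_density`` SNPs per kb.

    Density is assessed against the window's effective (masked) length by
    default, or against the nominal window span with
    ``density_against="nominal"``.
    """
    if mode not in ("ratio_of_averages", "mean_of_ratios"):
        raise ValueError(f"unknown mode {mode!r}")
    out = []
    for chrom in mask.chroms():
        sub = sites[sites["chrom"] == chrom].sort_values("pos")
        pos = sub["pos"].to_numpy()
        num = sub["num"].to_numpy()
        den = sub["den"].to_numpy()
        fst = sub["fst"].to_numpy()
        span = mask.span(chrom)
        for start in range(0, max(span, 1), step):
            end = start + window
            eff = mask.overlap_length(chrom, start, end)
            basis = eff if density_against == "effective" else min(window, max(span - start, 0))
            lo = np.searchsorted(pos, start + 1)
            hi = np.searchsorted(pos, end, side="right")
            n_snps = hi - lo
            if basis <= 0 or n_snps < min_density * (basis / 1000.0):
                continue
            if mode == "ratio_of_averages":
                d = den[lo:hi].sum()
                f = num[lo:hi].sum() / d if d > 0 else np.nan
            else:
                f = float(np.nanmean(fst[lo:hi]))
            out.append((chrom, start, end, eff, int(n_snps), f))
    df = pd.DataFrame(
        out, columns=["chrom", "start", "end", "effective_length", "n_snps", "fst"]
    )
    if df.empty:
        warnings.warn("no windows passed the SNP-density rule", stacklevel=2)
    df.attrs["mode"] = mode
    return df


@dataclass
class CandidateRegion:
    """A merged run of high-F_ST windows with its overlapping genes."""

    chrom: str
    start: int
    end: int
    peak_fst: float
    window_count: int
    genes: list[str] = field(default_factory=list)


def call_candidate_regions(
    windows: pd.DataFrame, threshold: float = 0.6
) -> list[CandidateRegion]:
    """Merge windows with F_ST ≥ threshold into candidate selective regions.

    Overlapping or exactly adjacent (bookended) qualifying windows merge;
    a gap of ≥ 1 bp separates regions.
    """
    hits = windows[windows["fst"] >= threshold]
    regions: list[CandidateRegion] = []
    for chrom, sub in hits.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur = None
        for row in sub.itertuples(index=False):
            if cur is not None and row.start <= cur.end:
                cur.end = max(cur.end, row.end)
                cur.peak_fst = max(cur.peak_fst, row.fst)
                cur.window_count += 1
            else:
                cur = CandidateRegion(
                    chrom=str(chrom),
                    start=int(row.start),
                    end=int(row.end),
                    peak_fst=float(row.fst),
                    window_count=1,
                )
                regions.append(cur)
    return regions


def candidate_genes(
    regions: list[CandidateRegion], gff_path, flank: int = 2_000
) -> list[CandidateRegion]:
    """Attach genes overlapping each region within ±``flank`` bp.

    ``gff_path`` is a GFF3 file; features of type ``gene`` are used.  The
    gene interval extended by the flank must intersect the region.
    Modifies and returns ``regions``.
    """
    import gffutils
    from gffutils.exceptions import EmptyInputError

    genes = []
    try:
        db = gffutils.create_db(
            str(gff_path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except EmptyInputError:
        db = None
    if db is not None:
        for g in db.features_of_type("gene"):
            gid = g.attributes.get("ID", [g.id])[0]
            # GFF is 1-based inclusive; convert to 0-based half-open
            genes.append((g.seqid, g.start - 1, g.end, gid))
    for region in regions:
        region.genes = [
            gid
            for chrom, gs, ge, gid in genes
            if chrom == region.chrom
            and gs - flank < region.end
            and ge + flank > region.start
        ]
    return regions
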