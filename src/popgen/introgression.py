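"""Four-population Patterson's D with block-jackknife standard errors.

Per usable site with ALT frequencies p1..p4 in populations P1..P4
(P4 the outgroup):

    num = (p1 − p2)(p3 − p4)
    den = (p1 + p2 − 2 p1 p2)(p3 + p4 − 2 p3 p4)
    D   = Σnum / Σden

Positive D means P1 shares more derived alleles with P3 than P2 does.
Standard errors come from a weighted delete-one block jackknife over
contiguous genomic blocks (weights = per-block denominator sums), the
standard treatment for linked sites.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .variants_io import GenotypeMatrix

__all__ = [
    "patterson_d_sites",
    "patterson_d",
    "jackknife_se",
    "DstatResult",
    "dstat_table",
]


def patterson_d_sites(
    gm: GenotypeMatrix,
    idx: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    outgroup_fixed_only: bool = False,
):
    """Per-site D-statistic numerators/denominators.

    Sites where any population is entirely missing are skipped; with
    ``outgroup_fixed_only`` sites where the outgroup is polymorphic are
    skipped as well.  Returns (chrom, pos, num, den) arrays.
    """
    ps = []
    ns = []
    for i in idx:
        p, n = gm.alt_freq(i)
        ps.append(p)
        ns.append(n)
    ok = (ns[0] > 0) & (ns[1] > 0) & (ns[2] > 0) & (ns[3] > 0)
    if outgroup_fixed_only:
        ok &= (ps[3] == 0) | (ps[3] == 1)
    p1, p2, p3, p4 = (p[ok] for p in ps)
    num = (p1 - p2) * (p3 - p4)
    den = (p1 + p2 - 2 * p1 * p2) * (p3 + p4 - 2 * p3 * p4)
    return (
        gm.sites["chrom"].to_numpy()[ok],
        gm.sites["pos"].to_numpy()[ok],
        num,
        den,
    )


def patterson_d(
    gm: GenotypeMatrix,
    idx1: np.ndarray,
    idx2: np.ndarray,
    idx3: np.ndarray,
    idx4: np.ndarray,
    outgroup_fixed_only: bool = False,
):
    """Genome-wide D = Σnum/Σden; returns ``(num_sum, den_sum, D)``."""
    _, _, num, den = patterson_d_sites(
        gm, (idx1, idx2, idx3, idx4), outgroup_fixed_only
    )
    num_sum = float(num.sum())
    den_sum = float(den.sum())
    if den_sum == 0:
        raise ValueError("D undefined: denominator sum is zero")
    return num_sum, den_sum, num_sum / den_sum


def jackknife_se(block_num: np.ndarray, block_den: np.ndarray):
    """Weighted delete-one block jackknife for D = Σnum/Σden.

    ``block_num``/``block_den`` are per-block sums over contiguous genomic
    blocks.  Weights are the block denominator sums.  Returns ``(se, z)``;
    se = 0 is degenerate (all blocks identical) and flagged with a warning.
    """
    block_num = np.asarray(block_num, dtype=float)
    block_den = np.asarray(block_den, dtype=float)
    nonempty = block_den != 0
    block_num = block_num[nonempty]
    block_den = block_den[nonempty]
    g = len(block_num)
    if g < 2:
        raise ValueError("jackknife needs >= 2 non-empty blocks")
    tot_num = block_num.sum()
    tot_den = block_den.sum()
    theta = tot_num / tot_den
    theta_j = (tot_num - block_num) / (tot_den - block_den)
    m = block_den  # block weights
    n = tot_den
    h = n / m
    # Busing et al. (1999) weighted delete-one jackknife
    theta_J = g * theta - ((1 - m / n) * theta_j).sum()
    tau = h * theta - (h - 1) * theta_j
    var = np.sum((tau - theta_J) ** 2 / (h - 1)) / g
    se = float(np.sqrt(max(var, 0.0)))
    if se <= abs(theta) * 1e-9 + 1e-15:  # numerically zero spread
        warnings.warn("degenerate jackknife: all blocks identical", stacklevel=2)
        return 0.0, float("inf") if theta != 0 else 0.0
    return se, float(theta / se)


@dataclass
class DstatResult:
    p1: str
    p2: str
    p3: str
    p4: str
    num_sum: float
    den_sum: float
    d: float
    se: float
    z: float
    n_blocks: int
    n_sites_used: int

    @property
    def ci1(self) -> tuple[float, float]:
        return (self.d - self.se, self.d + self.se)

    @property
    def ci3(self) -> tuple[float, float]:
        return (self.d - 3 * self.se, self.d + 3 * self.se)


def _blocks_by_coordinate(chrom, pos, block_size):
    """Block ids from contiguous genomic segments of ``block_size`` bp."""
    ids = np.empty(len(chrom), dtype=object)
    for i in range(len(chrom)):
        ids[i] = (chrom[i], pos[i] // block_size)
    _, inv = np.unique(ids, return_inverse=True)
    return inv


def dstat(
    gm: GenotypeMatrix,
    idx1, idx2, idx3, idx4,
    labels=("P1", "P2", "P3", "P4"),
    block_size: int | None = 5_000_000,
    block_by_chrom: bool = False,
    outgroup_fixed_only: bool = False,
) -> DstatResult:
    """D with jackknife SE.  Blocks are ``block_size``-bp segments, or one
    block per chromosome/locus with ``block_by_chrom`` (the natural choice
    for simulated independent loci)."""
    chrom, pos, num, den = patterson_d_sites(
        gm, (idx1, idx2, idx3, idx4), outgroup_fixed_only
    )
    if len(num) == 0 or den.sum() == 0:
        raise ValueError("D undefined: no usable sites")
    if block_by_chrom:
        _, block_id = np.unique(chrom.astype(str), return_inverse=True)
    else:
        block_id = _blocks_by_coordinate(chrom, pos, block_size)
    g = block_id.max() + 1
    bn = np.bincount(block_id, weights=num, minlength=g)
    bd = np.bincount(block_id, weights=den, minlength=g)
    se, z = jackknife_se(bn, bd)
    return DstatResult(
        p1=labels[0], p2=labels[1], p3=labels[2], p4=labels[3],
        num_sum=float(num.sum()), den_sum=float(den.sum()),
        d=float(num.sum() / den.sum()), se=se, z=z,
        n_blocks=int((bd != 0).sum()), n_sites_used=len(num),
    )


def dstat_table(
    gm: GenotypeMatrix,
    groups,
    quadruples: list[tuple[str, str, str, str]],
    **kwargs,
) -> pd.DataFrame:
    """One D-statistic row per (P1, P2, P3, P4) quadruple of group labels.

    ``groups`` maps group label → sample index array.  Emits D, ±1 SE and
    ±3 SE interval endpoints, ready for a forest-style panel.
    """
    rows = []
    for quad in quadruples:
        try:
            idx = [groups[q] for q in quad]
        except KeyError as exc:
            raise KeyError(f"unknown group {exc.args[0]!r}") from None
        r = dstat(gm, *idx, labels=quad, **kwargs)
        rows.append(
            {
                "p1": r.p1, "p2": r.p2, "p3": r.p3, "p4": r.p4,
                "d": r.d, "se": r.se, "z": r.z,
                "d_lo1": r.ci1[0], "d_hi1": r.ci1[1],
                "d_lo3": r.ci3[0], "d_hi3": r.ci3[1],
                "n_blocks": r.n_blocks, "n_sites": r.n_sites_used,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "p1", "p2", "p3", "p4", "d", "se", "z",
            "d_lo1", "d_hi1", "d_lo3", "d_hi3", "n_blocks", "n_sites",
        ],
    )
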