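"""Genotype- and site-level filters, haploid coding, and group assignment.

Barley is tightly inbred, so genotype calls are treated as haploid: after
filtering, every heterozygous call is recoded as missing and each accession
contributes a single haplotype to all downstream statistics.

The site filters mirror the standard five-rule pipeline for resequencing
data of an inbred crop:

1. keep only variants inside the effective covered region;
2. keep only bi-allelic, polymorphic variants;
3. mask genotype calls outside the accepted depth/quality range
   (WGS: depth in [2, 50]; exome: depth and GQ both ≥ 10);
4. drop sites with > 80% heterozygous or > 20% missing calls;
5. require both alleles to occur homozygous in at least one accession.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants_io import ALT, HET, MISSING, REF, GenotypeMatrix, RegionMask

__all__ = [
    "FilterConfig",
    "FilterReport",
    "GroupAssignment",
    "genotype_level_filter",
    "site_filter",
    "haploidize",
    "sample_het_proportion",
    "assign_groups",
]


@dataclass
class FilterConfig:
    """Thresholds for the genotype- and site-level filters.

    ``mode`` selects the genotype-level rule: "WGS" masks calls with depth
    outside [min_dp, max_dp]; "ES" (exome) masks calls unless depth and
    genotype quality are both at or above their minima.
    """

    mode: str = "WGS"
    min_dp: int = 2
    max_dp: int = 50
    min_dp_es: int = 10
    min_gq_es: int = 10
    max_het_fraction: float = 0.8
    max_missing_fraction: float = 0.2
    require_homozygous_both_alleles: bool = True
    # denominator of the het/missing fractions: all samples (plain reading)
    # or only non-missing ("called") samples
    fraction_denominator: str = "all"

    def __post_init__(self) -> None:
        if self.mode not in ("WGS", "ES"):
            raise ValueError(f"mode must be WGS or ES, got {self.mode!r}")
        if not (0 < self.max_het_fraction <= 1 and 0 < self.max_missing_fraction <= 1):
            raise ValueError("fractions must be in (0, 1]")
        if self.min_dp > self.max_dp:
            raise ValueError("min_dp > max_dp")


@dataclass
class FilterReport:
    """Number of sites removed by each site-level rule, in application order."""

    input_sites: int = 0
    removed_outside_mask: int = 0
    removed_multiallelic: int = 0
    removed_monomorphic: int = 0
    removed_het_fraction: int = 0
    removed_missing_fraction: int = 0
    removed_no_homozygote: int = 0
    retained: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(k, v) for k, v in self.__dict__.items()], columns=["rule", "sites"]
        )


def genotype_level_filter(gm: GenotypeMatrix, cfg: FilterConfig) -> GenotypeMatrix:
    """Mask individual genotype calls failing the depth/quality rule.

    Failing calls become MISSING; no sites are dropped here.  Calls whose
    DP (or GQ, in ES mode) is absent (coded negative) are treated as
    failing whenever the rule needs the value.
    """
    calls = gm.calls.copy()
    if cfg.mode == "WGS":
        if gm.depth is None:
            if cfg.min_dp <= 0 and not math.isfinite(cfg.max_dp):
                return gm
            raise ValueError("WGS genotype filter requires per-call DP")
        bad = (gm.depth < cfg.min_dp) | (gm.depth > cfg.max_dp)
    else:
        if gm.gq is None:
            raise ValueError("ES genotype filter requires per-call GQ")
        if gm.depth is None:
            raise ValueError("ES genotype filter requires per-call DP")
        bad = (gm.depth < cfg.min_dp_es) | (gm.gq < cfg.min_gq_es)
    calls[bad] = MISSING
    out = GenotypeMatrix(
        sites=gm.sites, samples=gm.samples, calls=calls, depth=gm.depth, gq=gm.gq
    )
    return out


def site_filter(
    gm: GenotypeMatrix,
    mask: RegionMask,
    cfg: FilterConfig,
    report: FilterReport | None = None,
) -> GenotypeMatrix:
    """Apply the site-level rules in order; returns the retained sites.

    Expects :func:`genotype_level_filter` to have been applied first, so
    "polymorphic" is evaluated on the masked calls.  Sites are only ever
    removed, never modified.
    """
    rep = report if report is not None else FilterReport()
    rep.input_sites = gm.n_sites
    if mask.total_length == 0:
        import warnings

        warnings.warn("empty mask: all sites removed", stacklevel=2)

    keep = np.ones(gm.n_sites, dtype=bool)

    # (1) effective covered region
    in_mask = np.zeros(gm.n_sites, dtype=bool)
    for chrom in pd.unique(gm.sites["chrom"]):
        rows = gm.sites["chrom"].to_numpy() == chrom
        in_mask[rows] = mask.contains(str(chrom), gm.sites["pos"].to_numpy()[rows])
    rep.removed_outside_mask = int((keep & ~in_mask).sum())
    keep &= in_mask

    # (2a) bi-allelic
    multi = gm.sites["multiallelic"].to_numpy(dtype=bool)
    rep.removed_multiallelic = int((keep & multi).sum())
    keep &= ~multi

    # (2b) polymorphic: ≥2 distinct non-missing alleles among calls
    # (HET carries both alleles)
    has_ref = ((gm.calls == REF) | (gm.calls == HET)).any(axis=1)
    has_alt = ((gm.calls == ALT) | (gm.calls == HET)).any(axis=1)
    poly = has_ref & has_alt
    rep.removed_monomorphic = int((keep & ~poly).sum())
    keep &= poly

    # (4) het / missing fractions
    n_het = (gm.calls == HET).sum(axis=1)
    n_miss = (gm.calls == MISSING).sum(axis=1)
    if cfg.fraction_denominator == "all":
        denom_het = denom_miss = np.full(gm.n_sites, gm.n_samples)
    else:
        called = gm.n_samples - n_miss
        denom_het = np.maximum(called, 1)
        denom_miss = np.full(gm.n_sites, gm.n_samples)
    het_bad = n_het / denom_het > cfg.max_het_fraction
    miss_bad = n_miss / denom_miss > cfg.max_missing_fraction
    rep.removed_het_fraction = int((keep & het_bad).sum())
    keep &= ~het_bad
    rep.removed_missing_fraction = int((keep & miss_bad).sum())
    keep &= ~miss_bad

    # (5) both alleles homozygous in ≥1 individual
    if cfg.require_homozygous_both_alleles:
        hom_both = (gm.calls == REF).any(axis=1) & (gm.calls == ALT).any(axis=1)
        rep.removed_no_homozygote = int((keep & ~hom_both).sum())
        keep &= hom_both

    rep.retained = int(keep.sum())
    return gm.take_sites(keep)


def haploidize(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Haploid coding: recode every HET call as MISSING (idempotent)."""
    calls = gm.calls.copy()
    calls[calls == HET] = MISSING
    return GenotypeMatrix(
        sites=gm.sites, samples=gm.samples, calls=calls, depth=gm.depth, gq=gm.gq
    )


def sample_het_proportion(gm: GenotypeMatrix) -> pd.Series:
    """Per-sample fraction of heterozygous calls among non-missing calls.

    A QC statistic computed before haploidization; for a tightly inbred
    species it should sit below a few percent in most accessions.  Samples
    with no non-missing calls get NaN.
    """
    n_het = (gm.calls == HET).sum(axis=0)
    n_called = (gm.calls != MISSING).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_called > 0, n_het / np.maximum(n_called, 1), np.nan)
    return pd.Series(frac, index=gm.samples, name="het_proportion")


DEFAULT_THRESHOLDS = {"wild": 0.65, "western": 0.65, "eastern": 0.5}


@dataclass
class GroupAssignment:
    """Sample → analysis-group labels plus the minimum-size policy."""

    labels: dict[str, str]
    min_group_size: int = 20

    def members(self, group: str, enforce_min: bool = True) -> list[str]:
        m = [s for s, g in self.labels.items() if g == group]
        if not m:
            raise KeyError(f"no samples in group {group!r}")
        if enforce_min and len(m) < self.min_group_size:
            raise ValueError(
                f"group {group!r} has {len(m)} samples, below the size floor "
                f"{self.min_group_size}; pass enforce_min=False to override"
            )
        return m

    def groups(self) -> list[str]:
        return sorted(set(self.labels.values()))


def assign_groups(
    q: pd.DataFrame,
    major_cluster: dict[str, str] | pd.Series,
    component_groups: list[str],
    thresholds: dict[str, float] | None = None,
    default_threshold: float = 0.65,
    min_group_size: int = 20,
) -> GroupAssignment:
    """Assign samples to pure groups from an ancestry-coefficient (Q) matrix.

    ``q`` is samples × K (rows sum to 1); ``component_groups`` maps each Q
    column to a major group; ``major_cluster`` gives each sample's major
    group (from the tree/PCA clade).  A sample is assigned to its major
    group iff its maximum component among that group's columns meets the
    group-specific threshold (wild/western 0.65, eastern 0.5 by default);
    otherwise it is labelled "admixed".  Samples whose major cluster has no
    Q columns (e.g. an outgroup) keep their cluster label.
    """
    thresholds = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    if len(component_groups) != q.shape[1]:
        raise ValueError("component_groups must name every Q column")
    sums = q.sum(axis=1).to_numpy()
    if np.any(np.abs(sums - 1.0) > 1e-6):
        bad = q.index[np.abs(sums - 1.0) > 1e-6][0]
        raise ValueError(f"Q rows must sum to 1 (sample {bad!r})")
    comp_groups = np.asarray(component_groups)
    major = dict(major_cluster)
    labels = {}
    for sample in q.index:
        grp = major[sample]
        cols = comp_groups == grp
        if not cols.any():
            labels[sample] = grp
            continue
        thr = thresholds.get(grp, default_threshold)
        if q.loc[sample].to_numpy()[cols].max() >= thr:
            labels[sample] = grp
        else:
            labels[sample] = "admixed"
    return GroupAssignment(labels=labels, min_group_size=min_group_size)
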