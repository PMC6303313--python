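"""Reading/writing of VCF, BED and samtools-depth tables, and coverage masks.

The in-memory containers used across the pipeline live here:

* :class:`GenotypeMatrix` — a sites × samples matrix of haploid-codable
  genotype calls with optional per-call depth (DP) and genotype quality (GQ).
* :class:`DepthTrack` — per-sample read depth at every covered position of a
  chromosome set (as produced by ``samtools depth``).
* :class:`RegionMask` — per-chromosome disjoint intervals in 0-based
  half-open coordinates; the "effective covered region" used as the
  denominator of all per-bp statistics.

Coordinate conventions: VCF/site positions are 1-based; BED and RegionMask
are 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "REF",
    "ALT",
    "HET",
    "MISSING",
    "GenotypeMatrix",
    "DepthTrack",
    "RegionMask",
    "read_vcf",
    "write_vcf",
    "read_depth_table",
    "compute_effective_region",
    "intersect_masks",
    "read_bed",
    "write_bed",
]

# Genotype codes. Haploid-coded data never contains HET after haploidization.
REF = 0
ALT = 1
HET = 2
MISSING = -1

_GT_STR = {REF: "0/0", ALT: "1/1", HET: "0/1", MISSING: "./."}


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


@dataclass
class GenotypeMatrix:
    """Bi-allelic-codable genotype calls for a set of sites and samples.

    ``sites`` is a DataFrame with columns ``chrom, pos, ref, alt, id,
    multiallelic``; positions are 1-based and strictly increasing within a
    chromosome.  ``calls`` holds one of REF/ALT/HET/MISSING per cell.
    """

    sites: pd.DataFrame
    samples: list[str]
    calls: np.ndarray  # (n_sites, n_samples) int8
    depth: np.ndarray | None = None  # (n_sites, n_samples) int32, -1 = absent
    gq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, names: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown sample {exc.args[0]!r}") from None

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Row-subset the matrix (boolean or integer index)."""
        return replace(
            self,
            sites=self.sites.iloc[index].reset_index(drop=True),
            calls=self.calls[index],
            depth=None if self.depth is None else self.depth[index],
            gq=None if self.gq is None else self.gq[index],
        )

    def alt_freq(self, sample_idx: np.ndarray | None = None):
        """Per-site ALT allele frequency and non-missing haploid count.

        HET calls, if any remain, are excluded (haploid coding treats them
        as missing).  Returns ``(p, n)`` with ``p`` NaN where ``n == 0``.
        """
        calls = self.calls if sample_idx is None else self.calls[:, sample_idx]
        n = ((calls == REF) | (calls == ALT)).sum(axis=1)
        n_alt = (calls == ALT).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, n_alt / np.maximum(n, 1), np.nan)
        return p, n


@dataclass
class DepthTrack:
    """Per-sample read depth along chromosomes.

    ``depths[chrom]`` is an (L, n_samples) array covering positions
    ``1..L``; positions absent from the source table have depth 0 in every
    sample (the ``samtools depth`` convention without ``-a``).
    """

    samples: list[str]
    depths: dict[str, np.ndarray]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def chrom_length(self, chrom: str) -> int:
        return self.depths[chrom].shape[0]

    def genome_mean_depth(self) -> np.ndarray:
        """Mean depth per sample over every position in the track."""
        total = np.zeros(self.n_samples)
        n = 0
        for arr in self.depths.values():
            total += arr.sum(axis=0)
            n += arr.shape[0]
        if n == 0:
            raise ValueError("empty depth track")
        return total / n


@dataclass
class RegionMask:
    """Disjoint sorted intervals per chromosome, 0-based half-open."""

    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for chrom, iv in self.intervals.items():
            iv = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
            if len(iv):
                iv = _merge_intervals(iv)
            clean[chrom] = iv
        self.intervals = clean

    @property
    def total_length(self) -> int:
        return int(
            sum((iv[:, 1] - iv[:, 0]).sum() for iv in self.intervals.values())
        )

    def chroms(self) -> list[str]:
        return list(self.intervals)

    def contains(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Membership of 1-based positions ``pos`` in the mask."""
        iv = self.intervals.get(chrom)
        pos = np.asarray(pos)
        if iv is None or not len(iv):
            return np.zeros(pos.shape, dtype=bool)
        zero_based = pos - 1
        idx = np.searchsorted(iv[:, 0], zero_based, side="right") - 1
        ok = idx >= 0
        ok[ok] &= zero_based[ok] < iv[idx[ok], 1]
        return ok

    def overlap_length(self, chrom: str, start: int, end: int) -> int:
        """Masked bp inside [start, end) (0-based half-open)."""
        iv = self.intervals.get(chrom)
        if iv is None or not len(iv):
            return 0
        lo = np.maximum(iv[:, 0], start)
        hi = np.minimum(iv[:, 1], end)
        return int(np.maximum(hi - lo, 0).sum())

    def span(self, chrom: str) -> int:
        """End of the last interval on ``chrom`` (0 if absent)."""
        iv = self.intervals.get(chrom)
        return int(iv[-1, 1]) if iv is not None and len(iv) else 0


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, region: str | None = None, samples: list[str] | None = None) -> GenotypeMatrix:
    """Read a VCF 4.x file into a :class:`GenotypeMatrix`.

    Diploid genotypes are coded 0/0→REF, 1/1→ALT, 0/1 or 1/0→HET,
    ./.→MISSING; haploid GTs map 0→REF, 1→ALT.  Records with more than one
    ALT allele are retained with ``multiallelic=True`` so the bi-allelic
    site filter can drop them later.  ``region`` is ``"chrom"`` or
    ``"chrom:start-end"`` (1-based inclusive).
    """
    vcf = VCF(str(path))
    all_samples = list(vcf.samples)
    if samples is not None:
        missing = set(samples) - set(all_samples)
        if missing:
            raise KeyError(f"unknown sample(s) in VCF: {sorted(missing)}")
        keep = np.array([all_samples.index(s) for s in samples])
        out_samples = list(samples)
    else:
        keep = np.arange(len(all_samples))
        out_samples = all_samples

    chrom_q, lo, hi = _parse_region(region)

    header = vcf.raw_header
    fmt_has_dp = "##FORMAT=<ID=DP," in header
    fmt_has_gq = "##FORMAT=<ID=GQ," in header
    rows, call_rows, dp_rows, gq_rows = [], [], [], []
    has_dp = has_gq = False
    for line_no, var in enumerate(vcf, start=1):
        try:
            if chrom_q is not None:
                if var.CHROM != chrom_q or not (lo <= var.POS <= hi):
                    continue
            alts = var.ALT
            rows.append(
                (
                    var.CHROM,
                    var.POS,
                    var.REF,
                    alts[0] if alts else ".",
                    var.ID or ".",
                    len(alts) > 1,
                )
            )
            # gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN/missing, 3=HOM_ALT
            gt = var.gt_types[keep]
            codes = np.full(gt.shape, MISSING, dtype=np.int8)
            codes[gt == 0] = REF
            codes[gt == 1] = HET
            codes[gt == 3] = ALT
            call_rows.append(codes)
            dp = var.format("DP") if fmt_has_dp else None
            if dp is not None:
                has_dp = True
                dp_rows.append(np.where(dp < 0, -1, dp).reshape(-1)[keep])
            else:
                dp_rows.append(np.full(len(keep), -1, dtype=np.int32))
            gq = var.format("GQ") if fmt_has_gq else None
            if gq is not None:
                has_gq = True
                gq_rows.append(np.where(gq < 0, -1, gq).reshape(-1)[keep])
            else:
                gq_rows.append(np.full(len(keep), -1, dtype=np.int32))
        except Exception as exc:  # pragma: no cover - defensive
            raise VcfParseError(f"malformed VCF record #{line_no}: {exc}") from exc

    sites = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "id", "multiallelic"]
    )
    if not rows:
        sites = sites.astype(
            {"chrom": str, "pos": np.int64, "multiallelic": bool}
        )
    n = len(sites)
    return GenotypeMatrix(
        sites=sites,
        samples=out_samples,
        calls=np.array(call_rows, dtype=np.int8).reshape(n, len(out_samples)),
        depth=np.array(dp_rows, dtype=np.int32).reshape(n, len(out_samples)) if has_dp else None,
        gq=np.array(gq_rows, dtype=np.int32).reshape(n, len(out_samples)) if has_gq else None,
    )


def _parse_region(region):
    if region is None:
        return None, None, None
    if ":" in region:
        chrom, rng = region.split(":", 1)
        lo, hi = rng.replace(",", "").split("-")
        return chrom, int(lo), int(hi)
    return region, 1, np.iinfo(np.int64).max


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT (and DP/GQ when present).

    Haploid-coded calls are serialized as homozygous diploid genotypes
    (REF→``0/0``, ALT→``1/1``), the way an inbred barley VCF looks upstream.
    """
    fmt_keys = ["GT"]
    if gm.depth is not None:
        fmt_keys.append("DP")
    if gm.gq is not None:
        fmt_keys.append("GQ")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if gm.depth is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if gm.gq is not None:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        for chrom in pd.unique(gm.sites["chrom"]):
            sub = gm.sites[gm.sites["chrom"] == chrom]
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for i, row in enumerate(gm.sites.itertuples(index=False)):
            cells = []
            for j in range(gm.n_samples):
                parts = [_GT_STR[int(gm.calls[i, j])]]
                if gm.depth is not None:
                    d = int(gm.depth[i, j])
                    parts.append("." if d < 0 else str(d))
                if gm.gq is not None:
                    q = int(gm.gq[i, j])
                    parts.append("." if q < 0 else str(q))
                cells.append(":".join(parts))
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\t.\t.\t"
                + ":".join(fmt_keys)
                + "\t"
                + "\t".join(cells)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Depth tables and masks
# ---------------------------------------------------------------------------

def read_depth_table(path, samples: list[str] | None = None) -> DepthTrack:
    """Read a samtools-depth-style TSV (chrom, pos, depth per sample).

    Positions absent from the table get depth 0 in every sample.  A header
    line starting with ``chrom`` or ``#`` names the samples; otherwise they
    are auto-named ``s1..sN`` unless ``samples`` is given.
    """
    df = pd.read_csv(path, sep="\t")
    first = df.columns[0].lstrip("#")
    if first.lower() not in {"chrom", "chr", "chromosome"}:
        # headerless file: re-read without header
        df = pd.read_csv(path, sep="\t", header=None)
        ncols = df.shape[1] - 2
        names = samples if samples is not None else [f"s{i+1}" for i in range(ncols)]
        df.columns = ["chrom", "pos"] + list(names)
    else:
        df = df.rename(columns={df.columns[0]: "chrom", df.columns[1]: "pos"})
    sample_names = list(df.columns[2:])
    depth_cols = df[sample_names]
    if not all(np.issubdtype(t, np.integer) for t in depth_cols.dtypes):
        raise ValueError("non-integer depth values in depth table")
    depths = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        length = int(sub["pos"].max())
        arr = np.zeros((length, len(sample_names)), dtype=np.int32)
        arr[sub["pos"].to_numpy() - 1] = sub[sample_names].to_numpy()
        depths[str(chrom)] = arr
    return DepthTrack(samples=sample_names, depths=depths)


def write_depth_table(track: DepthTrack, path, omit_zero_rows: bool = True) -> None:
    """Write a DepthTrack back to a samtools-depth-style TSV with header."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\t" + "\t".join(track.samples) + "\n")
        for chrom, arr in track.depths.items():
            nz = arr.any(axis=1) if omit_zero_rows else np.ones(len(arr), bool)
            for i in np.flatnonzero(nz):
                fh.write(f"{chrom}\t{i + 1}\t" + "\t".join(map(str, arr[i])) + "\n")


def compute_effective_region(
    track: DepthTrack, min_depth: int = 2, min_sample_fraction: float = 0.8
) -> RegionMask:
    """Coverage mask: positions covered ≥ ``min_depth`` in ≥ ``min_sample_fraction``
    of the samples, merged into intervals.

    The defaults implement the "at least two reads in ≥80% of the WGS
    accessions" definition of the effective covered region.
    """
    if not (0 < min_sample_fraction <= 1):
        raise ValueError("min_sample_fraction must be in (0, 1]")
    intervals = {}
    for chrom, arr in track.depths.items():
        frac = (arr >= min_depth).sum(axis=1) / track.n_samples
        good = frac >= min_sample_fraction
        intervals[chrom] = _runs_to_intervals(good)
    return RegionMask(intervals=intervals)


def _runs_to_intervals(good: np.ndarray) -> np.ndarray:
    if not good.any():
        return np.empty((0, 2), dtype=np.int64)
    padded = np.concatenate([[False], good, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return np.column_stack([starts, ends]).astype(np.int64)


def intersect_masks(a: RegionMask, b: RegionMask) -> RegionMask:
    """Interval intersection of two masks."""
    out = {}
    for chrom in a.intervals:
        if chrom not in b.intervals:
            continue
        ia, ib = a.intervals[chrom], b.intervals[chrom]
        res = []
        i = j = 0
        while i < len(ia) and j < len(ib):
            s = max(ia[i, 0], ib[j, 0])
            e = min(ia[i, 1], ib[j, 1])
            if s < e:
                res.append((s, e))
            if ia[i, 1] <= ib[j, 1]:
                i += 1
            else:
                j += 1
        out[chrom] = np.array(res, dtype=np.int64).reshape(-1, 2)
    return RegionMask(intervals=out)


def read_bed(path) -> RegionMask:
    """Read BED3 into a mask; overlapping intervals are merged with a warning."""
    intervals: dict[str, list] = {}
    overlapped = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            intervals.setdefault(chrom, []).append((int(start), int(end)))
    for chrom, iv in intervals.items():
        iv.sort()
        for k in range(1, len(iv)):
            if iv[k][0] < iv[k - 1][1]:
                overlapped = True
    if overlapped:
        warnings.warn("overlapping BED intervals merged", stacklevel=2)
    return RegionMask(
        intervals={c: np.array(iv, dtype=np.int64) for c, iv in intervals.items()}
    )


def write_bed(mask: RegionMask, path) -> None:
    with open(path, "w") as fh:
        for chrom, iv in mask.intervals.items():
            for s, e in iv:
                fh.write(f"{chrom}\t{s}\t{e}\n")
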