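"""Gene-region haplotypes, median-joining networks, and depth-based deletion calls.

Haplotypes of a gene region are the distinct allele strings over the
region's common variants (MAF ≥ 5% by default) among samples with complete
calls.  The median-joining network (Bandelt et al.) connects observed
haplotypes through a minimum-spanning network, augmented by inferred
median vectors (majority consensus of triples) wherever they shorten the
connection, then pruned of obsolete medians.

Structural deletions (the classic hulless-barley ~1.6 kb dropout) are
called per sample from read depth: a region is "deleted" when its mean
depth falls below a fraction of the sample's genome-wide mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .variants_io import ALT, DepthTrack, GenotypeMatrix, MISSING, REF

__all__ = [
    "HaplotypeSet",
    "extract_haplotypes",
    "median_joining_network",
    "depth_deletion_scan",
]


@dataclass
class HaplotypeSet:
    """Distinct haplotypes of one gene region with carrier bookkeeping."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    site_pos: np.ndarray  # 1-based positions of the MAF-filtered sites
    haplotypes: list[str]  # 0/1 strings, one char per site
    counts: list[int]
    composition: list[dict[str, int]]  # per-haplotype group → carriers
    excluded_samples: list[str] = field(default_factory=list)

    @property
    def n_carriers(self) -> int:
        return sum(self.counts)


def extract_haplotypes(
    gm: GenotypeMatrix,
    region: tuple[str, int, int],
    min_maf: float = 0.05,
    sample_groups: dict[str, str] | None = None,
    sample_idx: np.ndarray | None = None,
) -> HaplotypeSet:
    """Haplotypes over the MAF-filtered sites of ``region`` (0-based half-open).

    Samples with any missing (or residual heterozygous) call at the
    region's sites are excluded and reported.  With no qualifying site,
    every complete sample carries the single trivial (empty) haplotype.
    """
    chrom, start, end = region
    if sample_idx is None:
        sample_idx = np.arange(gm.n_samples)
    pos = gm.sites["pos"].to_numpy()
    in_region = (
        (gm.sites["chrom"].to_numpy() == chrom) & (pos > start) & (pos <= end)
    )
    calls = gm.calls[np.ix_(in_region, sample_idx)]
    p, n = GenotypeMatrix(
        sites=gm.sites[in_region].reset_index(drop=True),
        samples=[gm.samples[i] for i in sample_idx],
        calls=calls,
    ).alt_freq()
    maf = np.minimum(p, 1 - p)
    qualifying = (n >= 1) & ~np.isnan(maf) & (maf >= min_maf)
    calls = calls[qualifying]
    site_pos = pos[in_region][qualifying]

    names = [gm.samples[i] for i in sample_idx]
    complete = ((calls == REF) | (calls == ALT)).all(axis=0)
    excluded = [names[j] for j in np.flatnonzero(~complete)]
    strings: dict[str, list[str]] = {}
    for j in np.flatnonzero(complete):
        h = "".join("1" if c == ALT else "0" for c in calls[:, j])
        strings.setdefault(h, []).append(names[j])
    haps = sorted(strings, key=lambda h: (-len(strings[h]), h))
    comp = []
    for h in haps:
        groups: dict[str, int] = {}
        for s in strings[h]:
            g = (sample_groups or {}).get(s, "ungrouped")
            groups[g] = groups.get(g, 0) + 1
        comp.append(groups)
    return HaplotypeSet(
        chrom=chrom,
        start=start,
        end=end,
        site_pos=site_pos,
        haplotypes=haps,
        counts=[len(strings[h]) for h in haps],
        composition=comp,
        excluded_samples=excluded,
    )


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _msn(nodes: list[str], epsilon: int = 0) -> nx.Graph:
    """ε-relaxed minimum spanning network (union of all MSTs at ε=0).

    Edges are added in ascending weight classes; an edge joins the network
    iff its endpoints lie in different components with respect to strictly
    smaller weights.  After the graph first becomes connected, classes up
    to ``epsilon`` beyond the connecting weight are still considered.
    """
    g = nx.Graph()
    g.add_nodes_from(nodes)
    dists = {}
    for u, v in combinations(nodes, 2):
        dists.setdefault(_hamming(u, v), []).append((u, v))
    comp = {n: n for n in nodes}

    def find(x):
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    connected_at = None
    for w in sorted(dists):
        if connected_at is not None and w > connected_at + epsilon:
            break
        for u, v in dists[w]:
            if find(u) != find(v):
                g.add_edge(u, v, weight=w)
        for u, v in dists[w]:
            comp[find(u)] = find(v)
        if connected_at is None and nx.is_connected(g):
            connected_at = w
    return g


def _majority_median(a: str, b: str, c: str) -> str:
    return "".join(
        "1" if (x + y + z).count("1") >= 2 else "0" for x, y, z in zip(a, b, c)
    )


def median_joining_network(hs: HaplotypeSet, epsilon: int = 0) -> nx.Graph:
    """Bandelt median-joining network of the observed haplotypes.

    Iterates: build the ε-relaxed minimum spanning network over the
    current node set; for every path u–v–w in it, propose the majority
    median of (u, v, w) and accept it when it strictly shortens the
    triple's connection; stop when no new median helps, then drop obsolete
    (degree ≤ 2, carrier-free) medians.  Node attributes: ``count``,
    ``composition``, ``is_median``.
    """
    observed = list(hs.haplotypes)
    if len(observed) < 2:
        g = nx.Graph()
        for h in observed:
            g.add_node(h)
        _decorate(g, hs)
        return g
    nodes = list(observed)
    while True:
        net = _msn(nodes, epsilon)
        new = set()
        for v in net.nodes:
            for u, w in combinations(net.neighbors(v), 2):
                m = _majority_median(u, v, w)
                if m in nodes or m in new:
                    continue
                star = _hamming(u, m) + _hamming(v, m) + _hamming(w, m)
                duv, dvw, duw = _hamming(u, v), _hamming(v, w), _hamming(u, w)
                mst_cost = duv + dvw + duw - max(duv, dvw, duw)
                if star < mst_cost:
                    new.add(m)
        if not new:
            break
        nodes.extend(sorted(new))
    # prune obsolete median vectors
    while True:
        net = _msn(nodes, epsilon)
        obsolete = [
            n for n in nodes
            if n not in observed and net.degree(n) <= 2
        ]
        if not obsolete:
            break
        nodes = [n for n in nodes if n not in obsolete]
    _decorate(net, hs)
    return net


def _decorate(g: nx.Graph, hs: HaplotypeSet) -> None:
    count = dict(zip(hs.haplotypes, hs.counts))
    comp = dict(zip(hs.haplotypes, hs.composition))
    for n in g.nodes:
        g.nodes[n]["count"] = count.get(n, 0)
        g.nodes[n]["composition"] = comp.get(n, {})
        g.nodes[n]["is_median"] = n not in count


def depth_deletion_scan(
    track: DepthTrack,
    region: tuple[str, int, int],
    rel_threshold: float = 0.2,
    genome_mean: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-sample presence/absence call of ``region`` from read depth.

    A sample is called deleted when its mean depth over the region
    (0-based half-open) is below ``rel_threshold`` × its genome-wide mean
    depth.  Samples with zero genome-wide depth are uncallable (status
    "uncallable").
    """
    chrom, start, end = region
    if end - start < 100:
        raise ValueError("region must be at least 100 bp")
    arr = track.depths[chrom][start:end]
    region_mean = arr.mean(axis=0)
    if genome_mean is None:
        genome_mean = track.genome_mean_depth()
    status = np.where(
        genome_mean == 0,
        "uncallable",
        np.where(region_mean < rel_threshold * genome_mean, "deleted", "present"),
    )
    return pd.DataFrame(
        {
            "sample": track.samples,
            "region_mean_depth": region_mean,
            "genome_mean_depth": genome_mean,
            "status": status,
        }
    )
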