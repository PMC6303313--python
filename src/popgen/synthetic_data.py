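"""Coalescent generator of multi-population barley-like study datasets.

Produces genotype matrices (and the surrounding artifacts: depth tracks,
coverage masks, ancestry-coefficient matrices, group tables, gene
annotation) with a fully known truth, so that every stage of the pipeline
— mask construction, genotype/site filtering, diversity and
differentiation scans, D statistics, LD, trees, haplotype networks,
deletion calling — can be exercised and checked against the generating
model.

The model is the standard backward-in-time n-coalescent with
piecewise-constant population sizes, population mergers, and admixture
pulses, simulated per independent locus with msprime (haploid lineages:
each inbred accession contributes one haplotype; residual heterozygosity
is injected afterwards as call noise, not simulated biologically).
Mutations are binary, one site per position (infinite-sites in practice at
these densities), at a default rate of 6.5 × 10⁻⁹ per site per generation
with a generation time of one year, so event times in calendar years map
1:1 onto generations.

``preset_qingke`` encodes the inferred history of Tibetan hulless barley:
a deep outgroup, a large wild population, a domestication bottleneck, a
western/eastern landrace split ~8000 generations ago, and a qingke founder
bottleneck between 4500 and 2000 generations ago during which the eastern
population size stays ≈ 4400.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import msprime
import numpy as np
import pandas as pd

from .variants_io import (
    ALT,
    HET,
    MISSING,
    REF,
    DepthTrack,
    GenotypeMatrix,
    compute_effective_region,
    write_bed,
    write_depth_table,
    write_vcf,
)

__all__ = [
    "PopulationConfig",
    "DemographyConfig",
    "TruthRecord",
    "simulate",
    "preset_qingke",
    "single_population_config",
    "add_noise",
    "simulate_depth",
    "plant_sweep",
    "emit_dataset",
]


@dataclass
class PopulationConfig:
    """One population: name, sample size, and piecewise-constant N_e.

    ``sizes`` is a list of ``(time_generations_ago, size)`` pairs with
    non-decreasing times; the first entry must have time 0.  The size at
    time t is the entry with the largest time ≤ t.
    """

    name: str
    n_samples: int
    sizes: list[tuple[float, float]]

    def size_between(self, t_lo: float, t_hi: float) -> float:
        """Size on the epoch containing [t_lo, t_hi) (first matching entry)."""
        current = self.sizes[0][1]
        for t, s in self.sizes:
            if t <= t_lo:
                current = s
        return current


@dataclass
class DemographyConfig:
    """Full demographic model plus the sampling/locus plan."""

    populations: list[PopulationConfig]
    splits: list[tuple[float, str, str]] = field(default_factory=list)
    # (time, derived, ancestral): at `time` generations ago the derived
    # population merges into the ancestral one (forward: ancestral → derived)
    pulses: list[tuple[float, str, str, float]] = field(default_factory=list)
    # (time, source, dest, fraction): forward in time, at `time` a fraction
    # of `dest` ancestry is replaced by migrants from `source`
    mutation_rate: float = 6.5e-9
    generation_time: float = 1.0
    n_loci: int = 100
    locus_length: int = 10_000

    def __post_init__(self) -> None:
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")
        for p in self.populations:
            if p.sizes[0][0] != 0:
                raise ValueError(f"population {p.name}: first size epoch must start at 0")
            times = [t for t, _ in p.sizes]
            if times != sorted(times):
                raise ValueError(f"population {p.name}: epoch times must be non-decreasing")
        for t, der, anc in self.splits:
            if der not in names or anc not in names:
                raise ValueError(f"split references unknown population: {der}/{anc}")
            if t <= 0:
                raise ValueError("split times must be positive")
        for t, src, dst, f in self.pulses:
            if not (0 < f < 1):
                raise ValueError("pulse fractions must be in (0, 1)")
            if src not in names or dst not in names:
                raise ValueError(f"pulse references unknown population: {src}/{dst}")
        # every sampled population must not have merged away before time 0
        merged_at = {der: t for t, der, anc in self.splits}
        for p in self.populations:
            if p.n_samples > 0 and merged_at.get(p.name, np.inf) <= 0:
                raise ValueError(f"sampled population {p.name} does not exist at time 0")

    @property
    def pop(self) -> dict[str, PopulationConfig]:
        return {p.name: p for p in self.populations}

    def to_msprime(self) -> msprime.Demography:
        demog = msprime.Demography()
        for p in self.populations:
            demog.add_population(name=p.name, initial_size=p.sizes[0][1])
            for t, s in p.sizes[1:]:
                demog.add_population_parameters_change(
                    time=t, population=p.name, initial_size=s
                )
        for t, der, anc in self.splits:
            demog.add_mass_migration(time=t, source=der, dest=anc, proportion=1.0)
        for t, src, dst, f in self.pulses:
            # backward in time, lineages in dst move to src
            demog.add_mass_migration(time=t, source=dst, dest=src, proportion=f)
        demog.sort_events()
        return demog

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DemographyConfig":
        pops = [
            PopulationConfig(
                name=p["name"],
                n_samples=p["n_samples"],
                sizes=[tuple(x) for x in p["sizes"]],
            )
            for p in d["populations"]
        ]
        return cls(
            populations=pops,
            splits=[tuple(x) for x in d.get("splits", [])],
            pulses=[tuple(x) for x in d.get("pulses", [])],
            mutation_rate=d.get("mutation_rate", 6.5e-9),
            generation_time=d.get("generation_time", 1.0),
            n_loci=d.get("n_loci", 100),
            locus_length=d.get("locus_length", 10_000),
        )


@dataclass
class TruthRecord:
    """Everything needed to regenerate the dataset and to score recovery."""

    seed: int
    config: DemographyConfig
    labels: dict[str, str]  # sample → true population
    locus_seeds: list[tuple[int, int]]  # (ancestry seed, mutation seed)
    sweep: dict | None = None  # {"chrom": ..., "group": ...}
    deletion: dict | None = None  # {"chrom", "start", "end", "samples"}
    admixture: list[tuple[float, str, str, float]] = field(default_factory=list)


def simulate(config: DemographyConfig, seed: int) -> tuple[GenotypeMatrix, TruthRecord]:
    """Simulate haploid genotypes at ``config.n_loci`` independent loci.

    Each locus is one chromosome (``chr1..chrN``) with no intra-locus
    recombination.  Deterministic under ``(config, seed)``.
    """
    rng = np.random.default_rng(seed)
    demog = config.to_msprime()
    sampled = [p for p in config.populations if p.n_samples > 0]
    sample_sets = [
        msprime.SampleSet(p.n_samples, population=p.name, ploidy=1) for p in sampled
    ]
    samples = [
        f"{p.name}_{k:02d}" for p in sampled for k in range(1, p.n_samples + 1)
    ]
    labels = {s: s.rsplit("_", 1)[0] for s in samples}

    locus_seeds = [
        (int(rng.integers(1, 2**31 - 1)), int(rng.integers(1, 2**31 - 1)))
        for _ in range(config.n_loci)
    ]
    bases = np.array(list("ACGT"))
    rows = []
    call_blocks = []
    for locus, (s_anc, s_mut) in enumerate(locus_seeds):
        chrom = f"chr{locus + 1}"
        ts = msprime.sim_ancestry(
            samples=sample_sets,
            demography=demog,
            sequence_length=config.locus_length,
            ploidy=1,
            discrete_genome=True,
            random_seed=s_anc,
        )
        # infinite-sites mutations: continuous positions guarantee one
        # mutation per site (no recurrence); rare integer collisions when
        # flooring to bp coordinates are dropped
        mts = msprime.sim_mutations(
            ts,
            rate=config.mutation_rate,
            model=msprime.BinaryMutationModel(),
            discrete_genome=False,
            random_seed=s_mut,
        )
        last_pos = -1
        for var in mts.variants():
            pos = int(var.site.position) + 1
            ref_i = int(rng.integers(0, 4))
            alt_i = (ref_i + int(rng.integers(1, 4))) % 4
            if pos <= last_pos:
                continue
            last_pos = pos
            derived = np.array([a == "1" for a in var.alleles])[var.genotypes]
            rows.append((chrom, pos, bases[ref_i], bases[alt_i], ".", False))
            call_blocks.append(np.where(derived, ALT, REF).astype(np.int8))

    sites = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "id", "multiallelic"]
    )
    if not rows:
        sites = sites.astype({"chrom": str, "pos": np.int64, "multiallelic": bool})
    calls = (
        np.array(call_blocks, dtype=np.int8).reshape(len(rows), len(samples))
        if rows
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    gm = GenotypeMatrix(sites=sites, samples=samples, calls=calls)
    truth = TruthRecord(
        seed=seed,
        config=config,
        labels=labels,
        locus_seeds=locus_seeds,
        admixture=list(config.pulses),
    )
    return gm, truth


def single_population_config(
    ne: float,
    n_samples: int,
    n_loci: int = 100,
    locus_length: int = 10_000,
    mutation_rate: float = 6.5e-9,
    name: str = "pop",
) -> DemographyConfig:
    """Constant-size single-population model (the neutral null)."""
    return DemographyConfig(
        populations=[PopulationConfig(name, n_samples, [(0.0, ne)])],
        n_loci=n_loci,
        locus_length=locus_length,
        mutation_rate=mutation_rate,
    )


def preset_qingke(
    n_loci: int = 100,
    locus_length: int = 10_000,
    samples: dict[str, int] | None = None,
) -> DemographyConfig:
    """The qingke domestication history as a simulation preset.

    Backward in time: qingke merges into eastern at 4500 generations, with
    a founder bottleneck over 4500–2000 generations ago (N_e 2500, well
    below eastern's contemporaneous 4400) deepening to N_e 1000 near the
    present; eastern holds N_e = 4400 over the 4500–2000 span; eastern
    merges into western (the common domesticated ancestor) at 8000
    generations; the domesticated lineage merges into wild at 10500; a
    small outgroup merges at 30000.  A 10% admixture pulse from eastern
    into qingke at 1000 generations ago maintains their extra affinity.

    Wild is large near the present and smaller deep in the past (recent
    expansion → negative Tajima's D in wild), while the domesticated
    groups are small against a large shared ancestry (decline-shaped
    genealogies → positive D on average).  By construction the preset
    reproduces the qualitative study pattern: diversity wild > western ≈
    eastern > qingke, qingke with the fewest low-frequency alleles and
    the strongest LD, and D statistics tying qingke to eastern.  The
    wild, western, outgroup and present-day qingke/eastern sizes are free
    parameters of the generator, not observed quantities.
    """
    n = {
        "wild": 25,
        "western": 25,
        "eastern": 25,
        "qingke": 30,
        "outgroup": 4,
        **(samples or {}),
    }
    pops = [
        PopulationConfig("wild", n["wild"], [(0, 100_000), (12_000, 20_000)]),
        PopulationConfig("western", n["western"], [(0, 5_500), (8_000, 4_000)]),
        PopulationConfig(
            "eastern", n["eastern"], [(0, 8_000), (2_000, 4_400), (4_500, 15_000)]
        ),
        PopulationConfig("qingke", n["qingke"], [(0, 1_000), (2_000, 2_500)]),
        PopulationConfig("outgroup", n["outgroup"], [(0, 5_000)]),
    ]
    splits = [
        (4_500.0, "qingke", "eastern"),
        (8_000.0, "eastern", "western"),
        (10_500.0, "western", "wild"),
        (30_000.0, "outgroup", "wild"),
    ]
    return DemographyConfig(
        populations=pops,
        splits=splits,
        pulses=[(1_000.0, "eastern", "qingke", 0.1)],
        n_loci=n_loci,
        locus_length=locus_length,
    )


# ---------------------------------------------------------------------------
# Noise, depth, and dataset emission
# ---------------------------------------------------------------------------

def add_noise(
    gm: GenotypeMatrix,
    het_error_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Inject residual heterozygous calls and missingness into clean calls."""
    if not (0 <= het_error_rate < 1 and 0 <= missing_rate < 1):
        raise ValueError("rates must be in [0, 1)")
    rng = np.random.default_rng(seed)
    calls = gm.calls.copy()
    u = rng.random(calls.shape)
    present = calls != MISSING
    calls[present & (u < het_error_rate)] = HET
    calls[present & (u >= het_error_rate) & (u < het_error_rate + missing_rate)] = MISSING
    return GenotypeMatrix(
        sites=gm.sites, samples=gm.samples, calls=calls, depth=gm.depth, gq=gm.gq
    )


def simulate_depth(
    samples: list[str],
    chrom_lengths: dict[str, int],
    mean_coverage: float = 10.0,
    coverage_sd_frac: float = 0.2,
    dropout_density: float = 0.0,
    dropout_mean_length: int = 500,
    deletion: dict | None = None,
    seed: int = 0,
) -> DepthTrack:
    """Per-sample Poisson depth with optional dropout segments and a
    planted deletion (``{"chrom", "start", "end", "samples"}``, 0-based
    half-open).  ``dropout_density`` is the expected number of zero-depth
    segments per bp per sample."""
    rng = np.random.default_rng(seed)
    lam = np.maximum(rng.normal(mean_coverage, mean_coverage * coverage_sd_frac, len(samples)), 0.5)
    depths = {}
    for chrom, L in chrom_lengths.items():
        arr = np.empty((L, len(samples)), dtype=np.int16)
        for j in range(len(samples)):
            arr[:, j] = np.minimum(rng.poisson(lam[j], L), np.iinfo(np.int16).max)
            k = rng.poisson(dropout_density * L)
            for _ in range(k):
                s = int(rng.integers(0, L))
                e = min(L, s + int(rng.exponential(dropout_mean_length)) + 1)
                arr[s:e, j] = 0
        depths[chrom] = arr
    if deletion is not None:
        idx = [samples.index(s) for s in deletion["samples"]]
        arr = depths[deletion["chrom"]]
        arr[deletion["start"] : deletion["end"], idx] = 0
    return DepthTrack(samples=list(samples), depths=depths)


def plant_sweep(gm: GenotypeMatrix, focal_samples: np.ndarray, chrom: str) -> GenotypeMatrix:
    """Drive the focal group to fixation for the derived allele over one locus.

    A crude stand-in for a completed hard sweep: every call of the focal
    samples on ``chrom`` becomes ALT, creating high-F_ST windows there.
    """
    calls = gm.calls.copy()
    rows = gm.sites["chrom"].to_numpy() == chrom
    calls[np.ix_(rows, focal_samples)] = ALT
    return GenotypeMatrix(
        sites=gm.sites, samples=gm.samples, calls=calls, depth=gm.depth, gq=gm.gq
    )


def _surrogate_q(truth: TruthRecord, rng: np.random.Generator) -> pd.DataFrame:
    """Truth-based ancestry-coefficient surrogate (one component per
    non-outgroup population, own component ≈ 0.85–0.99)."""
    groups = [p.name for p in truth.config.populations if p.name != "outgroup"]
    q = {}
    for sample, grp in truth.labels.items():
        row = rng.uniform(0, 0.02, len(groups))
        if grp in groups:
            row[groups.index(grp)] = 0.85 + rng.uniform(0, 0.14)
        row /= row.sum()
        q[sample] = row
    return pd.DataFrame.from_dict(q, orient="index", columns=groups)


def _write_gff(path, chrom_lengths: dict[str, int], deletion: dict | None) -> list[tuple]:
    """A toy annotation: two genes per chromosome; if a deletion is planted,
    one gene sits inside it (the nud-locus analog)."""
    genes = []
    for chrom, L in chrom_lengths.items():
        a = max(1, L // 10)
        genes.append((chrom, a, min(a + 1500, L), f"gene_{chrom}_1"))
        b = L // 2
        genes.append((chrom, b, min(b + 2000, L), f"gene_{chrom}_2"))
    if deletion is not None:
        genes.append(
            (
                deletion["chrom"],
                deletion["start"] + 101,
                deletion["end"] - 100,
                "gene_nud_analog",
            )
        )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, s, e, gid in genes:
            fh.write(
                f"{chrom}\tpopgen\tgene\t{s}\t{e}\t.\t+\t.\tID={gid}\n"
            )
    return genes


def emit_dataset(
    gm: GenotypeMatrix,
    truth: TruthRecord,
    outdir,
    het_error_rate: float = 0.02,
    missing_rate: float = 0.02,
    mean_coverage: float = 10.0,
    dropout_density: float = 0.0,
    deletion: dict | None = None,
    overwrite: bool = False,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write the full artifact set: VCF, depth TSV, effective-region BED,
    groups TSV, Q-matrix TSV, GFF3, and a truth JSON.

    Noise is injected first; per-call DP is taken from the simulated depth
    track and GQ is a monotone function of DP, so the genotype-level
    filters are genuinely exercised.  Deterministic under
    ``(gm, truth, seed)``; ``seed`` defaults to ``truth.seed + 1``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        k: outdir / v
        for k, v in {
            "vcf": "data.vcf",
            "depth": "depth.tsv",
            "bed": "effective.bed",
            "groups": "groups.tsv",
            "q": "q.tsv",
            "gff": "genes.gff3",
            "truth": "truth.json",
        }.items()
    }
    if not overwrite:
        clashes = [str(p) for p in paths.values() if p.exists()]
        if clashes:
            raise FileExistsError(f"output exists (pass overwrite=True): {clashes}")
    if seed is None:
        seed = truth.seed + 1
    rng = np.random.default_rng(seed)

    noisy = add_noise(gm, het_error_rate, missing_rate, seed=int(rng.integers(2**31 - 1)))
    chrom_lengths = {
        f"chr{i + 1}": truth.config.locus_length for i in range(truth.config.n_loci)
    }
    track = simulate_depth(
        gm.samples,
        chrom_lengths,
        mean_coverage=mean_coverage,
        dropout_density=dropout_density,
        deletion=deletion,
        seed=int(rng.integers(2**31 - 1)),
    )
    if deletion is not None:
        truth.deletion = dict(deletion)

    # attach DP/GQ from the depth track
    dp = np.zeros_like(noisy.calls, dtype=np.int32)
    chroms = noisy.sites["chrom"].to_numpy()
    positions = noisy.sites["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        rows = np.flatnonzero(chroms == chrom)
        dp[rows] = track.depths[str(chrom)][positions[rows] - 1]
    gq = np.minimum(99, 3 * dp).astype(np.int32)
    noisy = GenotypeMatrix(
        sites=noisy.sites, samples=noisy.samples, calls=noisy.calls, depth=dp, gq=gq
    )

    write_vcf(noisy, paths["vcf"])
    write_depth_table(track, paths["depth"])
    write_bed(compute_effective_region(track), paths["bed"])
    pd.DataFrame(
        {"sample": list(truth.labels), "group": list(truth.labels.values())}
    ).to_csv(paths["groups"], sep="\t", index=False)
    _surrogate_q(truth, rng).rename_axis("sample").to_csv(paths["q"], sep="\t")
    _write_gff(paths["gff"], chrom_lengths, deletion)
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "seed": truth.seed,
                "emit_seed": seed,
                "config": truth.config.to_dict(),
                "labels": truth.labels,
                "sweep": truth.sweep,
                "deletion": truth.deletion,
            },
            fh,
            indent=1,
        )
    return paths
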