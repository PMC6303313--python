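# Methods

This note documents the statistical procedures implemented in `popgen`,
the parameter defaults and why they were chosen, the design decisions
made where conventions genuinely diverge, and what the synthetic-data
generator does and does not emulate.

## Haploid coding

Barley self-pollinates; residual heterozygosity in resequencing panels
is a few percent and is dominated by calling error and recent
outcrossing. All statistics therefore treat each accession as one
haplotype: heterozygous calls are recoded as missing
(`filtering.haploidize`), and downstream allele frequencies, r², D and
distances are computed on {REF, ALT, MISSING} calls only.
`sample_het_proportion` is provided as the QC statistic to verify the
assumption (expected ≲ 2% per accession for a true inbreeder).

## Coverage masks and per-bp normalization

Short-read panels of large genomes leave a substantial fraction of
positions under-covered, and dividing by the nominal genome length would
bias every per-bp statistic downward. The *effective covered region* is
the set of positions with depth ≥ `min_depth` (default 2 reads) in at
least `min_sample_fraction` (default 0.8) of the samples, stored as
0-based half-open intervals. All genome-wide values divide by the mask's
total length; windowed values divide by the masked length inside the
window, and windows with fewer than `min_effective` = 2000 masked bp (in
a 10 kb window sliding by 2 kb) are dropped as unestimable.

Coordinate conventions are fixed explicitly: VCF and site tables are
1-based; BED and `RegionMask` are 0-based half-open. Depth-table rows
absent from the input mean zero depth in all samples (the
`samtools depth` default without `-a`).

## Site filters

The five site-level rules are applied in a fixed order after
genotype-level masking: (1) inside the effective region; (2) bi-allelic
— multi-allelic records are read and flagged rather than rejected at
parse time, so upstream caller output is consumable — and polymorphic
*after* depth masking; (3) per-call depth in [2, 50] for WGS data, or
depth and genotype quality both ≥ 10 for exome data, failing calls
becoming missing; (4) sites with > 80% heterozygous or > 20% missing
calls dropped; (5) both alleles required homozygous in ≥ 1 accession.
The het/missing denominators use all samples (the plain reading of the
rule), with a flag for the called-samples alternative. Filtering only
removes sites, never edits calls; per-rule removal counts are reported.

Group assignment consumes an externally estimated ancestry-coefficient
(Q) matrix rather than re-estimating ancestry: a sample joins its major
group when its largest component within that group's columns meets the
group threshold (wild/western 0.65, eastern 0.5), and is `admixed`
otherwise. Groups below 20 members are refused by default (override
available) because small groups make the frequency-based statistics
unstable.

## Diversity statistics

At a site with `n` non-missing haploid calls and ALT frequency `p`:

* gene diversity (Nei): `H_E = 1 − p² − (1−p)²`
* nucleotide diversity: `π = H_E · n/(n−1)` — the unbiased mean pairwise
  difference; equality with explicit pair enumeration is a test oracle
* Watterson: each segregating site contributes `1/a_n`,
  `a_n = Σ_{i<n} 1/i`, evaluated at that site's own `n` so missingness
  is handled per site

`H_E` is deliberately left without a small-sample correction: the
`n/(n−1)` factor then makes π > H_E strictly, the ordering real barley
panels show. Sites with `n < 2` contribute nothing, including to the
segregating-site count S.

Tajima's D is computed once per group over all retained sites,
`D = (Π − S/a₁)/√(e₁S + e₂S(S−1))`, with the 1989 constants evaluated at
the rounded mean non-missing `n` over segregating sites (a fixed-n
override exists). D is NaN — distinct from 0 — when S = 0 or the
variance term degenerates (which happens identically at n ≤ 3).

## Hudson F_ST and the sweep scan

Per-SNP differentiation uses Hudson's estimator in the two-population
form that is unbiased under unequal sample sizes (requires n ≥ 2 in each
group). Windows default to the ratio-of-averages Σnum/Σden, the
recommended combination for this estimator; a mean-of-ratios mode exists
because "average F_ST of a window" is ambiguous in common usage. Negative
per-SNP values are retained in the sums. A window qualifies only with
≥ 5 SNPs per kb of *effective* length (flag to use nominal length).
Windows at F_ST ≥ 0.6 merge into candidate regions when overlapping or
exactly adjacent; genes overlap a region when the gene interval extended
by ± 2 kb intersects it.

## Patterson's D and the block jackknife

The frequency-based four-population D is summed over sites where all
four groups have ≥ 1 non-missing call; sites with a polymorphic outgroup
are kept (their frequencies enter the formula; a flag restricts to
outgroup-fixed sites). On haploid single-genome populations the formula
reduces exactly to (BABA − ABBA)/(BABA + ABBA) — a test oracle. Standard
errors come from a weighted delete-one jackknife over contiguous blocks
(weights = block denominator sums; Busing's formula); blocks are 5 Mb
segments on genomic coordinates or one block per chromosome/locus for
simulated data, where loci are exchangeable and independent. The
jackknife is well calibrated when many blocks contribute; with few loci
and no intra-locus recombination the per-block contributions are heavy
tailed and the SE runs ~20% low — the test suite pins this behaviour at
250 loci where calibration is within tolerance.

## LD

r² between two sites is computed over samples called at both, and equals
the squared Pearson correlation of 0/1-coded calls (an exact identity
used as the test oracle). Site pre-filters mirror the common
PopLDdecay settings (MAF ≥ 0.01, het fraction ≤ 0.8, missing ≤ 0.8);
pairs are restricted to the same chromosome within `max_dist` (default
1 Mb, i.e. 1000 kb). The genome-wide value is the *unweighted* mean of
per-chromosome mean r² — matching the convention of computing per
chromosome then averaging — with a pair-count-weighted mode available.
Above 10⁷ candidate pairs, pairs are uniformly subsampled with a
recorded seed.

## Trees and haplotype networks

The pairwise distance is the mismatch proportion over co-called sites
(p-distance) — the simplest allele-sharing distance, chosen because the
upstream convention (a PHYLIP distance) is not otherwise pinned down.
Neighbor joining follows Saitou–Nei with two deterministic choices:
Q-criterion ties break on the lowest index pair, and negative branch
lengths are clamped to zero with the deficit moved to the sister branch.
On additive matrices NJ reproduces the input path lengths exactly (a
test property). Output is an unrooted trifurcating root serialized to
Newick.

Gene-region haplotypes use sites at MAF ≥ 5%; samples with any missing
call in the region are excluded (no imputation — phasing is unnecessary
for haploid-coded inbreds, and small indels can be coded as binary
sites upstream). The median-joining network iterates: build the
ε-relaxed minimum spanning network (union of all MSTs at ε = 0) over the
current nodes; for every path u–v–w, propose the majority-consensus
median and accept it when it strictly shortens the triple's Steiner
cost; finally prune carrier-free medians of degree ≤ 2. Collinear chains
yield no medians; the classic three-haplotype triangle resolves through
the single median vector; tree-like (homoplasy-free) inputs reproduce
the generating tree exactly. Note that the final network is the MSN over
the *augmented* node set: direct long edges between observed haplotypes
can be replaced by median paths, so the observed-haplotype MSN is not in
general a subgraph of the result.

Deletion presence/absence (the hulless-barley *nud*-type dropout) is
called per sample when mean read depth over the region falls below
`rel_threshold` (default 0.2) times that sample's genome-wide mean; the
threshold is a free parameter since no standard value exists, and 0.2
cleanly separates a homozygous deletion (expected depth ≈ 0) from
coverage fluctuation at ≥ 5×.

## The synthetic-data generator

`synthetic_data.simulate` draws, per independent locus, a haploid
backward-in-time coalescent with piecewise-constant population sizes,
population mergers and admixture pulses (msprime provides the engine),
then places infinite-sites binary mutations at
μ = 6.5 × 10⁻⁹ /site/generation. Generation time is 1 year, so event
times in calendar years are entered directly as generations. There is no
intra-locus recombination: independence across loci supplies the
replication structure for jackknives and window statistics instead.
Everything is deterministic under `(config, seed)`, including the
emitted files.

`preset_qingke` encodes the qingke history: a western/eastern split at
8000 generations, qingke branching from eastern at 4500 with a founder
bottleneck spanning 4500→2000 generations ago, eastern held at
N_e = 4400 over that same span, a domesticated ancestor merging into
wild at 10500, and a small outgroup at 30000, plus a 10% eastern→qingke
pulse at 1000 generations maintaining their affinity. The sizes that no
observation pins down — wild (100 000 recent / 20 000 ancestral),
western (5500/4000), eastern's recent and pre-split sizes (8000 and
15 000), qingke's present size (1000) and the outgroup (5000) — are free
parameters of the generator, chosen by simulation screening so that the
preset robustly reproduces the qualitative study pattern: diversity
wild > western ≈ eastern > qingke, Tajima's D negative in wild and
positive in the domesticated groups, qingke with the fewest
low-frequency alleles and the strongest LD, and D statistics tying
qingke to eastern. At 200 × 10 kb loci all of these orderings held in
12/12 screening replicates.

`emit_dataset` layers observation noise on the clean calls: residual
heterozygous calls and missingness at configurable rates, per-sample
Poisson depth with lognormal-ish between-sample coverage variation,
optional zero-depth dropout segments, a plantable gene-region deletion,
depth-derived DP and a monotone depth→GQ map (solely to exercise the
exome filter path), a truth-based surrogate Q matrix and a toy GFF3.
`plant_sweep` fixes the derived allele across one locus in a focal group
as a completed-sweep stand-in for the F_ST positive control.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: intra-locus recombination
and realistic LD block structure; reference/mapping bias and
paralog-collapse artifacts; base-calling error models beyond symmetric
het/missing noise; variable mutation and gene-conversion rates;
selection beyond the planted fixed-difference locus; and real ancestry
estimation (the Q matrix is a truth-derived surrogate, so group
assignment is exercised mechanically, not validated against sNMF-type
inference).

## Problem sizes in the tests and acceptance script

Simulation-backed checks use sizes at which their expectations are
sharp but the suite stays quick: 500 × 10 kb loci (n = 20) for Watterson
recovery at θ = 3 × 10⁻³/bp, 200 loci for the Tajima null, 250-locus
quadruples for D-statistic power/null rates (50 replicates each),
15-locus two-population panels for the sweep scan (50 replicates), and
20 replicates of the 200-locus qingke preset for the end-to-end
directional checks. The acceptance script runs one 150-locus preset
study end to end plus the calibration experiments, in about a minute.

## Known limitations

* Windowed Tajima's D is available but off by default; the per-group
  value matches the single-number-per-group reporting convention.
* The ρ (population recombination rate) column of diversity tables is
  out of scope by design (no recombination in the generator, no
  composite-likelihood estimator).
* `windowed_fst` requires ≥ 5 SNPs/kb; at realistic whole-genome SNP
  densities for small groups this rule can reject every window — the
  scan is designed for dense (e.g. exome-ascertained) site sets.
* The block-jackknife SE is anticonservative when fewer than ~100
  independent blocks carry the signal (heavy-tailed block weights).
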