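# Methods

This note records the models the package implements, the assumptions behind
the synthetic data generator, the defaults and why they were chosen, and the
numerical decisions a maintainer would need to know.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The synthetic panel generator

The generator emulates a resequenced core collection of a highly selfing
crop.  Its output is the package's only test substrate, so its assumptions
bound what passing tests demonstrate.

**Mutation model.** All sequence variation is i.i.d. per-base substitution
with a uniform choice among the three alternative bases; there are no
indels.  This keeps k-mer coordinates and SNP positions aligned to the
ancestral sequence, which doubles as the mapping reference.  The mutation
process that separates real redundancy-group members (residual
heterozygosity, seed-lot drift, genotyping error) is unknown; i.i.d.
substitution is the simplest process with the right distance semantics, and
it is an assumption of this package, not an observation.

**Panel structure and defaults.** 40 accessions on two 30 kb chromosomes:
six redundancy groups of 2–5 members (intra-group rate 0.002/bp, i.e.
expected pairwise distance 0.004/bp, safely below the 0.005 grouping
threshold with > 0.99 probability at this genome size), founders diverged at
0.05/bp (an order of magnitude above the threshold), one seed-mixture
accession, one introgression carrier.  Genome size is a desk-scale choice:
every planted contrast (intra vs inter distances, shared-state rates,
heterozygosity classes) is a *rate*, so the structure is scale-invariant;
smaller genomes only widen the sampling noise, which the chosen size keeps
well clear of every threshold.

**Seed mixtures** are emitted as two haplotypes from different founders,
each carrying 0.04/bp extra divergence (mixtures typically involve off-types
from outside the sampled core).  On raw genotype calls this yields ~20%
apparent heterozygosity versus ~0% for pure accessions — the same an-order-
of-magnitude-above-baseline signature that motivates the 10% absolute
exclusion cutoff.  Note the elevated het sites are mostly singletons, which
the MAF filter removes; the pipeline therefore measures heterozygosity on
the *unfiltered* call set.

**Introgression** replaces a contiguous 10% of one singlet accession's
genome with novel random sequence and additionally attaches an equal amount
of unplaced novel sequence.  The replacement produces the depressed
shared-k-mer-state signature (the carrier disagrees wherever other
accessions share ancestral k-mers); the unplaced content produces the
inflated distinct-k-mer count.  In genotype calling the replaced region is
treated as unaligned (missing calls), as reads from novel sequence would not
map — which is exactly why such introgressions are invisible to SNP
distances and only k-mers expose them.

**Causal loci** are swept haplotypes: all carrier accessions share the
ancestral (reference) segment exactly, the way a major allele rides a
conserved haplotype (cf. structural-variant-driven associations).  Carriers
are drawn at the unit level so redundancy-group members share carrier
status.  This design gives the k-mer scan a realistic target: the segment's
k-mers are carried by every carrier, map exactly to the reference, and
separate carriers from non-carriers up to the "clean-window" contamination
of non-carriers without local founder mutations.

**Trial phenotypes** follow the fitted model exactly: plot value =
f⁻¹(intercept + location + block + genotype + 2·effect·carrier + residual),
with block and genotype effects drawn at the configured variances and
group members sharing one genotype effect (clones).  Default variance
components σ²_g = 1, σ²_block = 0.25, σ²_e = 0.25 give a replicated
multi-location trial with H² near 0.9 — the upper-middle of the 0.14–0.97
range typical for such trials; the major-gene trait uses σ²_g = 0.1,
σ²_e = 0.1 and effect 3, emulating a near-qualitative trait like grain
colour (H² ≈ 0.97).  The augmented design sows every entry once per
location and the designated controls four times.

**Metabolite tables** are log-normal per feature (baseline log10 intensity
uniform on [3, 6], noise SD 0.2 log10 units) with a configurable fraction
of features shifted in the alphabetically first class.

**What is not emulated:** read-level data (coverage, sequencing error,
mapping bias), recombination (accessions are clonal lineages, so linkage
disequilibrium does not decay along the genome — see the GWAS section),
population structure, genotype-by-environment interaction, and spatial
field trends beyond the block effect.  Passing tests therefore demonstrate
correctness of the *computations* under clean conditions, not robustness to
these real-data complications.

## Genotype stage

Site filters retain biallelic SNPs with ≥ 90% call rate and MAF ≥ 0.025
(allele counting from non-missing calls, het = one of each; the MAF bound is
inclusive, so a single homozygous-ALT accession among 40 sits exactly at
0.025 and is kept).  LD pruning is the plink-style 20-SNP/5-step/r² > 0.5
sliding window on 0/1/2 dosage with pairwise-complete observations; the
removed member of a pair is the one with lower MAF (tie: larger position —
plink's own rule is undocumented, this one is fixed for determinism), and
passes repeat until no within-window pair exceeds the threshold.  LD decay
is the binned mean r² curve against physical distance with linear
interpolation at the crossing of the r² = 0.2 reference line; the exact
curve-fitting used with real data is not specified anywhere, so binned-mean
interpolation is this package's choice, and dense chromosomes are thinned
to ≤ 1500 evenly spaced sites to keep the pair count tractable.

**Distances.** `p_distance` scores 0 for identical calls, 1 for opposite
homozygotes, 0.5 for hom/het, normalised by shared non-missing sites —
units are substitutions per *variant* site.  The redundancy threshold,
however, is stated per base pair (tree branch lengths with
ascertainment-style correction are on that scale), so the pipeline applies
a constant-site correction: distances are multiplied by
(variant sites / genome length), equivalent to counting the monomorphic
sites in the denominator.  Neighbour-joining trees come from scikit-bio's
standard Q-criterion implementation; negative reconstructed branch lengths
are clamped to zero with the deficit moved to the sister branch, and leaf
path lengths are branch-length sums.  NJ path distance is a stand-in for
maximum-likelihood phylogram branch lengths, which are out of scope; on the
near-additive matrices of a redundancy analysis the two are close, and the
raw p-distance backend is available as a config switch.

## Redundancy stage

"Every pair in a group closer than the threshold" is exactly
complete-linkage agglomerative clustering cut strictly below 0.005;
`scipy.cluster.hierarchy` provides the linkage and the cut uses
`nextafter(threshold, 0)` to make the strict inequality explicit.  Greedy
clique merging is a documented alternative; complete linkage is chosen
because it is deterministic and order-free.  k-mer validation counts
intra-group pairs at/above the 96% shared-state rate and flags discordant
ones; a non-group pair above the rate threshold is promoted to a new
two-member group only when its distance is also below 0.01 — the promotion
precedent had distance 0.007, and the ceiling generalises that single case
while guarding against rate/distance disagreement.  Promotion only ever
joins two current singlets, so existing groups are never merged or split.
Pooling is unanimous-consensus at genotype level (het member calls treated
as missing first; any disagreement → missing) — the read-level pooling and
re-calling used with raw data is out of scope, and the consensus rule is
the genotype-level analogue.

## Minimal marker panels

Greedy maximum-coverage set cover: a site distinguishes a pair iff both
calls are non-missing homozygous and different (heterozygous calls are
converted to missing first — het loci segregate between generations in a
selfer and cannot fingerprint reliably); each step takes the site resolving
the most unresolved pairs, ties broken by (chromosome, position); round 2
re-runs on the remaining sites.  Greedy set cover is the classic
log-factor approximation; on instances small enough for exhaustive search
the package also reports the exact minimum (`brute_force_minimum_panel`),
and the acceptance suite checks greedy ≤ optimum + 1 across random
instances.  Member consistency flags a group member only when its
non-missing *homozygous* call contradicts the group's panel call, judged
against the pooled matrix the panel was selected from.

## Mixed model, BLUP and heritability

The model is y = Xβ + Z_b u_b + Z_g u_g + e with V = σ²_b Z_bZ_b' +
σ²_g Z_gZ_g' + σ²_e I.  REML maximises −½(log|V| + log|X'V⁻¹X| + y'Py)
by Nelder–Mead over log variance components (exact dense evaluation via
Cholesky; function tolerance 1e-8; estimates below 1e-8 of the response
variance are snapped to an exact zero boundary).  Derivative-free search
over three parameters is robust here because the problems are small
(hundreds of plots); the mixed-model machinery is implemented directly
because the genotype-BLUP prediction-error covariance matrix — required by
the Cullis estimator — is not exposed by the general-purpose fitters, which
instead serve as an independent cross-check in the tests.  BLUPs are
û_g = σ̂²_g Z_g'Py with PEV = G − GZ_g'PZ_gG; BLUEs come from a
genotype-as-fixed GLS refit whose block and residual components are
re-estimated by a two-parameter REML.  A single-location table drops the
location term; a single-level random factor is dropped with a warning.

Heritability: Cullis H² = 1 − v̄_Δ/(2σ̂²_g) with v̄_Δ the mean over genotype
pairs of Var(û_i − û_j) from the full PEV matrix (the pairwise-difference
formulation; the average-PEV variant is a documented alternative), and the
regression (Walsh–Lynch) form as the slope of BLUPs on mean-centred BLUEs;
both are clamped to [0, 1] and defined as 0 when σ̂²_g = 0.  Per-trait
transformations f ∈ {none, sqrt, ln} are config-driven, with an `auto` mode
that picks the member minimising |skewness| of within-genotype residuals;
trait-specific location exclusions are config lists.  Adding the global
intercept to BLUPs is an output option for presentation only and never
feeds GWAS.

## k-mer GWAS

The association statistic is ordinary regression of the phenotype on the
presence indicator with a two-sided t-test on the slope (equivalent to a
pooled two-sample t-test); the external pipeline this emulates does not
document its statistic, and single-indicator OLS is the minimal choice
consistent with "no clear population structure" (optional covariate columns
exist but default off).  k-mers present or absent in fewer than
`min_class = 5` accessions are untested; zero-residual / perfect-separation
fits are capped at score 300 and flagged.

The threshold is p_adj = 0.05/(n/k) with n the number of *tested* k-mers:
dividing by k treats a block of overlapping k-mers covering one variant as
one effective test.  That accounting is valid when presence patterns are
locally constant over at least k consecutive k-mers — true for real panels,
where LD extends tens of kilobases, but *not* for the i.i.d. substitution
generator, where patterns decorrelate within a few bases.  Two consequences
are worth stating precisely.  First, for any exact test the expected number
of super-threshold *k-mers* under the null is n·p_adj = 0.05·k regardless
of structure, so null calibration must count distinct presence patterns
(effective tests), not k-mers.  Second, the pattern-level bound
E[hits] ≤ 0.05 holds exactly in the block-LD regime, which is how the
acceptance suite tests it (a null matrix with block-constant patterns,
block = 2k); on i.i.d. panels the same threshold is mildly anti-
conservative at the pattern level, which the region caller's minimum
k-mer count absorbs (isolated null exceedances never reach it).

Significant k-mers are projected by exact canonical match against both
reference strands (all hits reported; multi-mapping k-mers count in every
matched bin, first-match-only is a switch), counted per 10 kb bin by
rounded score level and slope sign, and merged into regions: a region opens
at the first bin containing a significant k-mer and closes when the next
one starts more than 500 kb after the current end (the gap is measured
between bin boundaries; the prose rule is ambiguous below bin resolution).
Regions with ≥ `min_kmers` significant k-mers are flagged trait-associated
with their majority direction.  The full-scale default is 750; synthetic
desk runs use 50, scaled to the ~2000 k-mers a planted 2 kb causal
haplotype can contribute.  Association uses raw BLUPs (not rank
transforms).  A naive per-SNP dosage regression with the plain Bonferroni
threshold 0.05/n is included as a stand-in only; multi-model SNP-GWAS and
kinship correction are out of scope.

## Metabolite statistics

Per feature: log10 transform, Pareto scaling ((x − mean)/√SD across
samples), pooled-variance t-test between the two grain-colour classes,
Benjamini–Hochberg q-values (scipy), differential iff q < 0.05.  Fold
change is mean(class1 raw)/mean(class2 raw) with class1 the brown-grain
class; volcano categories compare log2 FC against log2(0.83) and log2(1.2).
Zero-variance features are skipped and logged; non-positive intensities are
an error.

## Determinism and problem sizes

All randomness flows from a single integer seed per run; regeneration from
(config, seed) is bit-identical, and the end-to-end report is
checksum-stable across repeated runs.  Test and acceptance problem sizes —
40-accession panels on 60 kb genomes, 10–20 replicate loops, 40-genotype
balanced trials — were chosen so the full suite exercises every stage at
comfortable statistical margins; they are the package's desk-scale study
conditions, not tuning knobs.

## Known limitations

* No recombination: every accession is a clonal founder lineage, so LD does
  not decay with distance in default panels (LD-decay correctness is
  instead tested on a constructed AR(1) panel with a closed-form decay
  length).
* The k-mer stage starts from assembled sequences, so the per-accession
  minimum k-mer frequency filter of read-based pipelines (-L 4) is a
  config no-op, logged; read-scale external-memory counting is out of
  scope.
* Quality/depth VCF filters (minQ, minGQ, depth bounds) are accepted in
  config but are no-ops on synthetic genotype-only data, logged as skipped.
* NJ path distance replaces ML phylogram branch lengths; pooling is
  genotype-consensus rather than read pooling; both are documented
  substitutions.
* The greedy panel is not guaranteed globally minimal (the exact minimum is
  reported on small instances only).
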