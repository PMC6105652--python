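# Methods

## Study design and model

The pipeline targets a three-stage time-course design: replicate log2
expression intensities for groups C (baseline), M (early) and E (advanced),
an undirected gene–gene interaction network, and per-group sequencing reads
over promoter regions. Three evidence layers are computed independently and
intersected; the intent is that a candidate gene must show (i) a coherent
temporal expression trajectory shared by many genes, (ii) topological
centrality among co-regulated genes, and (iii) a large, significant
expression change in at least one pairwise stage contrast.

## Differential expression

Fold change is oriented second-named-minus-first on the log2 scale (MvC
means mean(M) − mean(C)), so "up" always means higher at the later stage.
The screen requires |log2 FC| ≥ 2.0 (a 4-fold linear change, inclusive
bound) and t-test p ≤ 0.05 on raw, uncorrected p-values — a deliberate
design choice of the screening stage, documented here prominently: the DEG
layer is a coarse filter that the profile and hub layers further restrict,
not a standalone inference. Welch's t-test is the default (safer than the
pooled-variance form at n = 3 per group); Student's variant is available via
`equal_var=True`. Zero variance in both groups yields p = 1 at equal means
(no evidence) and p = 0 at unequal means (the zero-noise limit), which makes
noiseless synthetic data behave correctly. Quantile normalization maps each
sample's sorted values onto the across-sample mean of sorted values; ties
receive the reference value at their averaged rank, making the transform
deterministic and idempotent. The detection filter retains genes flagged in
at least 6 of 9 samples by default.

## Temporal model profiles

Candidate profiles are all integer level sequences of length T starting at
0 with per-step change at most c; there are (2c+1)^(T−1) of them, and ids
follow lexicographic order of the level tuples (the documented enumeration
convention — external profile numberings must be matched by level pattern,
not by id). Defaults are T = 3 and c = 2 (25 candidates) with all
candidates retained; a greedy max-min selection (start at the flat profile,
repeatedly add the candidate farthest from the chosen set, ties to the
lowest id) is provided for m < (2c+1)^(T−1). Genes are assigned to the
profile minimizing 1 − Pearson correlation; this distance is scale-free, so
proportional profiles such as (0,1,1) and (0,2,2) are equivalent and the
lowest-id member of each shape class collects the assignments. Flat gene
vectors go to the flat profile by convention. Profiles with undefined
correlation (the flat profile) are unreachable for non-flat genes; profile
selection falls back to Euclidean level distance when the flat profile is
involved.

Significance uses the exact permutation null over all T! time orders (6 at
T = 3; no sampling, hence no seed): each permuted dataset is re-zeroed at
its new first point and fully re-assigned, the expected count per profile
is the mean over permutations, and p_raw is the binomial upper tail
P(X ≥ n_assigned) with X ~ Bin(n_genes, n_expected/n_genes), Bonferroni
corrected over the selected profiles at α = 0.05. When n_expected is zero
with a non-zero observed count, p_raw is floored at 1/(n_genes + 1). Note
the null's validity requires exchangeability of the *raw* time points;
simulated null data must be drawn i.i.d. over all T coordinates and then
re-zeroed, not generated with a structurally zero first coordinate.

## Hub scoring

MCC(v) = Σ over maximal cliques C containing v of (|C| − 1)!, computed from
an exact maximal-clique enumeration (Bron–Kerbosch with pivoting, via
networkx) in exact integer arithmetic. Conventions, fixed and
test-asserted: a truly isolated node is its own singleton maximal clique
and scores (1−1)! = 1; a node whose neighborhood contains no edges scores
its degree automatically, because each incident edge is then its own
maximal clique contributing 1! = 1. Hub status requires MCC ≥ 10
(inclusive). Clique enumeration is exponential in the worst case, so graphs
beyond a configurable node/edge budget raise an explicit resource error
rather than being silently truncated. Hubs are computed per DEG subset on
the subgraph of the reference interactome induced by that subset's genes —
the package's interpretation of selecting hub-gene subsets by expression
pattern.

## Integration

A profile with levels (0, l1, l2) is concordant with DEG subsets by sign:
sign(l1) → MvC direction, sign(l2) → EvC, sign(l2 − l1) → EvM; zero
differences contribute nothing. A gene assigned to a significant profile is
a candidate when **any** concordant subset contains it both as a hub and as
a DEG (the published candidate table lists genes carrying a single subset
entry under a two-subset profile, which is only consistent with the "any"
rule); a strict `require_all` mode demands every concordant subset qualify.
The stagewise hub contrast is a Pearson chi-square without continuity
correction on (early-stage DE hubs, early-stage total DEGs; advanced-stage
DE hubs, advanced-stage total DEGs) — the second column is the *total* DEG
count of the comparison, the only convention that reproduces the reference
statistic of 6.08 on (35, 2339; 19, 2539); Yates correction is available as
a flag. Enrichment tests: hypergeometric upper tail, one-sided Fisher
exact, and EASE (Fisher with the overlap reduced by one, floor 0), always
over an explicit background; EASE is never smaller than Fisher.

## Promoter methylation

Reads are extended to 300 bp from their 5′ end (within the
fragment-size range of typical immunoprecipitation libraries; configurable),
clipped at coordinate 0 for minus-strand reads. The methylation score of a
region is extended reads overlapping by ≥ 1 bp per kb of region length.
Coordinates are 0-based half-open (BED) throughout. DMR calls compare
replicate score vectors between two groups: linear fold change
max/min ≥ 1.5 (inclusive) on pseudocounted scores (0.5 reads added before
per-kb scaling, stabilizing ratios at low coverage) and Welch t-test
p ≤ 0.05. Regions with zero reads everywhere are skipped (fold change
undefined). Promoters default to TSS −2000/+500 bp when derived from a gene
BED, or may be supplied directly. Candidate annotation takes the minimum
p-value over a gene's tested promoter regions across the three pairwise
contrasts; untested candidates are marked missing and never significant.

## Validation statistics

2^−ΔΔCt: ΔCt = Ct_target − Ct_reference per sample, ΔΔCt relative to the
mean ΔCt of a calibrator group, so the calibrator is exactly 1.0. One-way
ANOVA is the classical F = MS_between/MS_within; degenerate zero
within-variance inputs give F = 0, p = 1 at equal means and F = ∞, p = 0
otherwise. The staining index Ri integrates red-channel pixel counts over
bins [200, 255] of a 256-bin histogram (image-to-histogram extraction is
out of scope; a plain 256-line count file is accepted). Positivity versus
the negative-control mean uses a one-sided Welch t-test on field-level Ri
values at α = 0.05 — the specific test is this package's choice, since
"statistically different from the control mean" does not pin one down.

## Synthetic data

The generator emulates the assumed data structure, not platform physics:
i.i.d. Gaussian noise on log2 intensities (makes t-test assumptions exact;
no probe-level or background model), planted cliques over profile-planted
genes plus Erdős–Rényi background (gives known-MCC ground truth; real
interactomes are scale-free, which this does not reproduce),
fixed-length reads with Poisson counts per region (the simplest model
satisfying the reads-per-kb score's assumptions; no sequencing error or GC
bias), and Ct tables whose target Ct drops one cycle per planted doubling.
Defaults: 1000 genes, 3 replicates per group, 40% of genes on the
up-then-flat pattern (0, 1, 1), effect size 3 log2 units per level, noise
sd 0.3, clique sizes (6, 5), background edge probability 0.01, 200 regions
at mean coverage 60 with a 4-fold shift in 20% of regions. Effect size and
noise are chosen for testability — large effect-to-noise so that planted
recovery is near-deterministic — because the emulated design publishes no
variance estimates; passing recovery tests therefore demonstrates
correctness of the machinery, not power on real data. All randomness flows
through one seeded generator; a config + seed pair reproduces every output
file byte-for-byte.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale: oracle equivalence
on ≤ 12-node graphs (exhaustive subset enumeration) and a 50-node graph
(independent igraph enumeration), permutation-null calibration over 200
datasets of 500 genes, planted recovery at 200–1000 genes, and null
calibration at 1000–10000 genes/regions — sizes at which every check is
exact or has negligible Monte-Carlo error. Assignment distances are rounded
to 12 decimals before argmin so exact correlation ties break
deterministically toward the lowest profile id. Factorials in MCC are exact
integers. Boundary conventions are inclusive throughout (|log2 FC| ≥ 2.0,
FC ≥ 1.5, MCC ≥ 10, p ≤ 0.05, detection ≥ 6).

## Known limitations

The expression screen uses raw p-values by design; the profile layer's
binomial null treats genes as independent, which real co-expression
violates (the Bonferroni correction and the intersection with the hub and
DEG layers are the guard rails); the network model does not emulate
scale-free topology, so MCC behavior on hub-and-spoke biological networks
is validated only through the oracle-equivalence tests; and the packaged
candidate/pathway tables carry their GO/pathway annotation counts as fixed
fixture columns — they depend on annotation-database versions and are never
recomputed.
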