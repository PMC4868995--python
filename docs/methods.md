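# Methods

## Ranking

Genes are ranked by the signal-to-noise metric
r = (A_test − A_ref) / (sd′_test + sd′_ref), where A and sd are the mean
and sample standard deviation (n−1 denominator) over biological replicates
and the first declared phenotype class is the test condition. Because the
ratio is undefined for genes whose replicates are (near-)constant, each
group standard deviation is floored at
sd′ = max(sd, sd_floor_fraction·|mean|, 1e−8); the default
`sd_floor_fraction = 0.2` is the conventional stabilization for this
metric, and 0 disables the relative floor. Ties in r are broken by
lexicographic gene id so that runs are bit-reproducible. Each class needs
at least two replicates; the metric is invariant to a common positive
rescaling of the data when the floor is not triggered and antisymmetric
under swapping the class roles.

## Enrichment statistic

For a gene set with N_H members among the N ranked genes, the running sum
adds |r_j|^p / N_R at members (N_R = Σ_hits |r_j|^p) and 1/(N − N_H) at
non-members; the enrichment score ES is the deviation of largest magnitude,
signed, and the statistic is exactly conserved (the deviation ends at 0).
The weight exponent defaults to p = 1; p = 0 reduces to the classic
two-sample KS D statistic on ranks, which the tests exploit as an
independent exact-rational oracle. If every member's metric is exactly 0
(N_R = 0), hits fall back to uniform weights with a log entry. Ties in the
extreme (a positive and a negative deviation of equal magnitude) resolve to
the earliest list position. Sets with no overlap with the list, or covering
it entirely, are rejected.

The leading edge comprises the members at positions ≤ peak for ES > 0 and
≥ peak for ES < 0, in list order; an exactly zero ES yields an empty
leading edge with a warning. The negative-ES convention mirrors the
positive definition, which is the only one the original description spells
out.

## Permutation null, p, NES, FDR

The default null permutes gene identity: each permutation draws a random
same-size gene set from the ranked universe (1000 draws by default; one
null serves all sets of the same effective size). Phenotype-label
permutation with full re-ranking is available (`permutation="phenotype"`)
and is preferable when replicate counts allow; it is quadratically more
expensive.

The nominal p is one-sided on the observed sign with add-one smoothing,
renormalized by the same-sign null count:
p = (1 + #{same-sign null at least as extreme}) / (1 + #{same-sign null}).
Renormalizing by the same-sign count keeps p uniform conditional on the
sign — without it the sign choice doubles the type-I rate. The add-one
form never returns 0 and is conservative by up to ~1/#same-sign at a given
level; at 200 permutations the measured null rejection rate at α = 0.05
is ≈ 0.045, converging to 0.05 as the permutation count grows.

NES divides ES by the mean magnitude of the same-sign null scores; if a
sign has no null mass the NES is flagged NaN and the set is excluded from
the FDR. The default FDR is the empirical NES-based construction: pool the
per-size null scores normalized the same way, then for each observed NES*
take q = [fraction of pooled null NES ≥ NES*] / [fraction of observed
NES ≥ NES*] (mirrored for negative), clipped to [0, 1] and made monotone
by a cumulative minimum from the least extreme end of each sign's
ordering. Benjamini–Hochberg on the nominal p is available as
`fdr_method="bh"`.

Gene sets are filtered to an effective size window of 15–500 after
intersection with the ranked list (configurable); the per-study
significance filter defaults to p < 0.01 and q < 0.25, and the looser
cross-study filter to p < 0.05 with |NES| ≥ 1 (the notion of a "high"
NES is not quantified in the source analyses; 1.0 — the null scale — is
this package's operational choice, exposed as `nes_min`).

## Consensus NMF and cophenetic model selection

The expression submatrix of the pooled leading-edge genes (upregulated and
downregulated pools clustered separately; positivity asserted, never
silently coerced) is factorized as M ≈ Y·Z by multiplicative updates
minimizing the generalized KL divergence (Frobenius optional), run for a
fixed 2000 iterations from a seeded uniform-(0,1] initialization scaled by
mean(M). The objective is recorded every iteration and is non-increasing;
zero rows/columns are lifted by 1e−12 with a log entry. Genes are assigned
to the argmax component of Y, ties to the lowest index.

For each k in 2–20 the connectivity matrices of `n_restarts = 50` seeded
restarts are averaged into a consensus matrix; its cophenetic coefficient
ρ(k) is the Pearson correlation between the consensus distances 1 − C and
the cophenetic distances of their average-linkage dendrogram (the linkage
used by the consensus-clustering lineage is not documented; average
linkage is this package's choice). ρ is undefined (flagged NaN) when all
pairs are equally similar. The stable k is the largest k before the
curve's first decline exceeding `drop_threshold` (default 0.05), provided
the curve has stayed within the threshold of its value at k_min; with no
such drop the scan returns k_max with a warning. The final assignment cuts
the consensus dendrogram at k_stable rather than re-running a single NMF,
because the consensus cut is the quantity whose stability was just
measured.

A caveat the test suite documents deliberately: on cleanly planted block
matrices, the over-clusterings at k above the planted number are
*themselves* reproducible across restarts (the extra component either
splits a block the same way every time or collapses onto a duplicate), so
ρ(k) declines only by ~0.001–0.03 per step beyond the planted k — the
curve peaks at the planted k but rarely shows a single-step drop larger
than the 0.05 default. The sharp-drop rule therefore tends to return k_max
on such synthetic data while the curve's argmax identifies the planted k
(~90% of seeds at 10% noise); the acceptance suite measures both and the
recovery-by-drop-rule check fails honestly. On real expression data, where
restarts disagree more, the drop rule behaves as intended; users clustering
synthetic or very clean data should inspect `cophenetic_` directly.

## Cluster annotation

Pathway over-representation per cluster is the upper-tail hypergeometric
test P(X ≥ x) for x overlap genes between a cluster of size n and a
pathway of size K in a universe of U genes, with the universe defaulting
to all genes measured in the dataset (what was testable), not the union of
the GMT. Following the source procedure the raw threshold p < 1e−5 flags
significance with no multiplicity correction; Benjamini–Hochberg can be
applied downstream. PPI subnetworks are induced on the cluster's genes
from a user-supplied edge list at a confidence cutoff of 0.4 (the common
medium-confidence convention); genes absent from the edge list stay as
isolated nodes, and the summary reports node/edge counts, density
2E/(V(V−1)) and component sizes.

## Synthetic data

`generate_gsea_fixture` emulates a triplicate two-condition microarray
design: 2000 genes, 3 replicates per group, values
base_level + N(0, noise_sd) with base_level = 100 and noise_sd = 10,
truncated at zero (a >10σ event at these defaults, so the noise model is
effectively Gaussian and all values are non-negative by construction —
the NMF positivity precondition). Gene sets are 50 disjoint blocks of 30
genes; planted up-sets (5 by default) add effect_size·noise_sd
(effect_size = 2) to the test group, planted down-sets mirror it. The
generator writes byte-identical GCT/CLS/GMT under a fixed seed and
round-trips through the parsers unchanged.

`generate_block_matrix` plants k gene clusters sharing distinct positive
sample profiles (high 10 on the block's sample segment, low 1 elsewhere,
per-gene amplitude uniform 0.8–1.2) plus truncated additive noise; at
noise_sd = 0 the matrix has exact rank k. `generate_ppi_fixture` draws a
planted-partition graph (edge probability p_within inside truth blocks,
p_between across, scores uniform 0.4–1.0).

What the fixtures do not emulate: probe-level artifacts, batch structure,
heavy-tailed or intensity-dependent noise, and gene–gene correlation
beyond the planted sets. Passing the recovery tests therefore shows the
statistics behave correctly under their own assumptions, not that any
particular real dataset meets those assumptions.

## Pipeline

`run_pipeline` executes the stages from one YAML config with a single
seed; per-stage seeds derive from it in a fixed order, all TSVs are
written with a fixed float format, and the manifest records parameters and
SHA-256 checksums of every output, so identical configs reproduce
byte-identical run directories. Defaults mirror the source analysis:
1000 permutations, k = 2–20 with 2000 NMF iterations, significance
p < 0.01 & q < 0.25, cross-study filter p < 0.05, cluster enrichment
p < 1e−5, overlap over ≥ 3 studies. The test suite and acceptance script
run reduced problem sizes (hundreds of genes, 150–200 permutations, 60–200
NMF iterations, 4–15 restarts, k scanned to 3–7) chosen so the full
battery of simulations completes in minutes while leaving every
statistical property measurable.

## Known limitations

- Exact-string gene identifiers; probe collapsing and id mapping are out
  of scope.
- Two-phenotype categorical designs only.
- Gene-identity permutation ignores inter-gene correlation; use phenotype
  permutation when replicate counts allow.
- The sharp-drop quantification of cophenetic model selection is
  insensitive on data whose over-clusterings are stable (see above).
- The hypergeometric cluster test applies the raw p < 1e−5 rule of the
  source procedure with no multiplicity correction; it is
  anti-conservative under multiple testing.
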