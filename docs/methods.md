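# Methods

## Scope and data model

The package operates on five plain-text inputs: a log2 feature × sample
expression matrix with a sample→group annotation (one for miRNAs, one for
mRNAs), a GMT gene-set collection, a miRNA→target pair table, a STRING-style
PPI edge list with a `combined_score` column, and a drug→target table.
Expression values are assumed already log2-transformed and normalized
(array-style data); missing or non-finite values are a hard input error, not
silently imputed.

## Differential expression

Two-group contrasts use a moderated *t*: per-feature pooled residual
variances s_g² (d_g = n₁+n₂−2 df) are shrunk toward a prior s₀² with d₀
prior df, s̃² = (d₀s₀² + d_g s_g²)/(d₀+d_g), and the statistic
(x̄₁−x̄₂)/√(s̃²(1/n₁+1/n₂)) is referred to t with d₀+d_g df. The prior is
fitted by moment matching on the log sample variances (digamma/trigamma
moments of the scaled-F model); when the observed spread of log variances
is no larger than expected under a common variance the prior df is infinite
and all features share s₀². At d₀ = 0 the statistic reduces exactly to the
ordinary pooled-variance t — this limit is tested, and the whole fit is
cross-checked against an independent reference fit in the test suite's
design (identical sensitivity/FDP on shared fixtures).

Thresholds are strict as printed: |log2FC| > 1 together with FDR < 0.05
(miRNA contrasts) or raw p < 0.05 (mRNA contrasts). The three mRNA
contrasts (acute vs healthy, chronic vs healthy, pooled HF vs healthy) are
merged by union; a feature significant in several contrasts keeps the
direction of its smallest-p contrast, and disagreeing directions raise a
conflict flag (the tie rule is our choice; nothing in the procedure depends
on it downstream beyond reporting).

## Enrichment and per-sample scores

Over-representation is the upper-tail hypergeometric test P(X ≥ k) with the
expression matrix as universe, BH-adjusted across sets. Per-sample pathway
activity uses the rank-weighted running-sum score: genes are ranked within
each sample (average ties), sorted descending, and the score is
Σᵢ (P_in(i) − P_out(i)) with in-set steps weighted by rank^α (α = 0.25) and
out-of-set steps uniform. One scorer is used everywhere scores appear; the
score matrix is normalized by its global range. Scores depend only on
within-sample ranks, so any strictly increasing per-sample transform leaves
them unchanged — this invariance, and agreement with a direct evaluation of
the running-sum definition, are tested.

## Gene prioritization

Composite scores: hypoxia = the designated hypoxia set's score row; energy
metabolism = the sample-wise arithmetic mean of the three metabolism set
rows; inflammation = six receptor/signaling set rows kept separate. Genes in
the regulatory network are screened against each composite by Pearson
correlation with the t-transform p-value (t = r√((m−2)/(1−r²))); composite
screens use |r| > 0.4, p < 0.05 (associations of either sign count), and a
gene counts as inflammation-associated when significant against at least
one of the six rows (the combination rule is our choice). Candidates are
the intersection of the three evidence categories, then filtered by a
strict monotone trend of group means along acute → chronic → healthy
combined with one-way ANOVA p < 0.05, then by ROC AUC > 0.7 (case = pooled
HF; the threshold is applied to max(AUC, 1−AUC) so strongly case-low genes
also qualify, with the orientation reported rather than silently flipped).

Among the surviving genes present in the miRNA–mRNA network, the anchor is
the one with the highest network degree, ties broken by the smallest merged
DE p-value. The anchor's co-expression neighborhood — genes with signed
r > 0.4 at p < 0.001 against the anchor (median ties and zero-variance
genes handled explicitly) — becomes the disease gene set S for the drug
screen.

## Proximity screen

d(S,T) averages, over targets, the shortest-path hop count to the nearest
disease gene plus the hub weight ω (0 for targets inside S, −ln(degree+1)
otherwise; degree taken in the score-filtered PPI). The ω term is applied
inside the per-target sum because it is a per-target quantity. Targets
absent from the PPI or unreachable from S are dropped and counted, never
treated as infinite. Implementation: a single multi-source BFS from S gives
min-distances for every node, so the observed distance and the whole null
reduce to lookups into one precomputed per-node term array.

The null draws size-|T| node sets without replacement — uniformly over
nodes by default, or matched to the targets' degree bins (bin widths
doubling from 1) since ω is degree-dependent — and is fully seeded.
z = (d_obs − μ)/σ with the sample (n−1) standard deviation; the one-sided
empirical p uses the add-one rule (1 + #{d(S,R) ≤ d_obs})/(n_reps + 1), so
it can never be exactly zero. The screen BH-adjusts empirical p across
drugs and keeps fdr < 0.001 with z < 0; a parametric normal-tail p derived
from z is emitted alongside for comparison but is not the default screening
column. With the default 10,000 repetitions the empirical-p floor is
1/10001, which still clears the 0.001 screen after BH adjustment across a
small drug panel; substantially fewer repetitions would push the floor
above the screen threshold, so the repetition count should not be reduced
below a few thousand when the 0.001 screen is used.

## Synthetic studies

The generator emulates the five inputs at desk scale: 2,000 genes and 300
miRNAs (9 HF vs 7 healthy miRNA samples; 9/9/9 acute/chronic/healthy mRNA
samples), i.i.d. Gaussian log2 baselines (mean 7, SD 2), additive planted
shifts of ±2 log2 units with unit noise, 100 planted DE genes and 30
planted DE miRNAs. One anchor gene follows a per-sample latent factor
(group shifts 3/1.5/0 plus unit sample noise) shared with a 20-gene
co-expressed block; the block doubles as the PPI disease module, the
hypoxia/energy/inflammation set cores draw on block and up-shifted genes so
the composite scores track the latent factor, and the anchor is the
most-targeted gene of the planted DE miRNAs in the pair table. One planted
miRNA deliberately has no targets, exercising the regulator-without-targets
path.

The PPI is a preferential-attachment graph. Attachment of one edge per new
node (a scale-free tree) is the default: degree heterogeneity is preserved
(hubs of degree ≳ 20 at 500 nodes), while typical shortest distances stay
above typical ln(degree+1) hub bonuses, so the ω-weighted distance of a
module-targeted drug (exactly 0) separates cleanly from the random-set null
(mean ≈ 2.2, SD ≈ 0.5 at the default sizes). On denser graphs the hub
bonus drags random terms toward and below zero and the contrast between a
module drug and chance shrinks — a property of the weighted distance
itself, worth remembering when applying it to dense interactomes. All
generated edge scores are ≥ 400 so the medium-confidence STRING filter is a
pass-through unless a test lowers them. One drug's targets are sampled
inside the module; comparison drugs are sampled uniformly outside.

What the generator does not emulate: microarray normalization artifacts,
batch effects, count-based sequencing noise, correlated gene-gene structure
beyond the single planted block, realistic PPI clustering/motifs, and
drug-target promiscuity patterns. Passing tests therefore demonstrate that
the pipeline recovers signals of the planted form at these noise levels,
not that it is robust to real-data pathologies.

## Numerical and policy choices

- Strict inequalities at every printed threshold (">" and "<" taken
  literally), so boundary values are excluded.
- BH adjustment preserves input order and caps at 1; empty input yields
  empty output.
- Pearson p-values use the exact t transform; |r| = 1 maps to p = 0, and
  zero-variance features are emitted with a flag.
- Median splits assign ties to the low-expression group.
- Duplicate PPI edges keep the maximum score; self-loops are dropped;
  the score floor is inclusive (≥ 400).
- Identifier namespaces are opaque; an optional two-column alias table maps
  protein ids to gene symbols at PPI load time.
- Every stochastic routine takes an explicit seed; the pipeline fans one
  global seed out per stage via a counter-keyed seed sequence, and reruns
  with the same config are byte-identical (fixed float formatting, sorted
  node/edge emission, no timestamps in the manifest).

## Problem sizes

Defaults run comfortably on one CPU: the full pipeline on a default study
takes a few seconds, dominated by the per-sample scoring stage; a
10,000-repetition null for a five-drug panel takes well under a second
thanks to the precomputed term array. The acceptance script uses 20 DE
replicates, 25 drug-screen studies and 10 prioritization studies, chosen to
give stable rate estimates at interactive runtimes.

## Known limitations

- The moderated-t fit assumes a common variance model across features
  within a contrast; covariates, paired designs and array preprocessing are
  out of scope.
- The single-scorer policy (one running-sum scorer everywhere) is a
  simplification; kernel-smoothed per-sample scorers can rank samples
  slightly differently.
- The evidence-intersection and trend filters are deliberately literal
  (all three categories AND strict monotonicity AND ANOVA), which is
  conservative when group means are nearly tied.
- The proximity null treats targets as exchangeable nodes; the
  degree-binned mode mitigates, but does not eliminate, degree confounding
  in the ω term.
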