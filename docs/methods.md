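# Methods

## Model and procedure

The method treats a phenotype comparison as a signal on a fixed interaction
network. Let G be the *global graph*: the union of all gene–gene
interactions across all pathways of a database, deduplicated by unordered
gene pair (self-loops excluded; the score of a self-loop degenerates to
2·FC·(1−p) and carries no interaction information). For genes A and B with
log2 fold changes FC and two-sided p-values p between the two groups, each
edge receives

    EdgeScore_AB = |FC_A|·(1 − p_A) + |FC_B|·(1 − p_B).

The score is symmetric, non-negative, bounded by |FC_A| + |FC_B|, linear in
the fold changes and decreasing in the p-values. The absolute-value
transform is the default because a signed sum would let an up- and a
down-regulated endpoint cancel, while an interaction between two strongly
changed genes is exactly what the method is after; a signed mode is kept for
sensitivity analysis. Because the score cannot distinguish direction, the
graph is scored as undirected and the original direction/type annotations
are carried along purely for display. Edges with an unmeasured endpoint are
dropped and counted rather than imputed with FC = 0, which would silently
halve their scores and bias selection.

### Per-gene statistics

Fold changes and p-values come from an empirical-Bayes moderated t-test.
With n₁/n₂ samples per group, pooled gene variance s² on df = n₁ + n₂ − 2
degrees of freedom, and a scaled-inverse-chi-square prior with d₀ degrees of
freedom and scale s₀², the posterior variance is

    s²_post = (d₀·s₀² + df·s²) / (d₀ + df),

and t = ΔFC / sqrt(s²_post·(1/n₁ + 1/n₂)) is referred to a t distribution
with d₀ + df degrees of freedom (standard normal when d₀ = ∞). The prior is
fitted by the method of moments on log s²: the excess variance of
e = log s² − ψ(df/2) + log(df/2) over the sampling term ψ′(df/2) determines
d₀ through the trigamma inverse, and the mean of e determines s₀². Zero
excess variance yields d₀ = ∞ (complete shrinkage); d₀ = 0 recovers the
ordinary pooled t-test exactly, which is one of the test oracles. Genes with
zero pooled variance receive the smallest positive observed variance as a
floor before shrinkage so constant genes cannot produce infinite statistics.
Raw (unadjusted) p-values enter the edge score: the score already multiplies
per-gene evidence, and FDR-adjusted values would compress it nonlinearly.

### Threshold selection

Edge scores in a two-group comparison form a large low-score bulk with, when
a coherent mechanism exists, a sparse high-score tail. The critical score is
found with a change-point analysis on the descending sorted score sequence:
the single change point in mean minimising the two-segment residual sum of
squares (computed in O(n) with prefix sums; equivalent to the optimal 1-D
two-means partition). The threshold is the midpoint between the two scores
flanking the split, so "score ≥ threshold" keeps exactly the high segment.
Splits between tied values are not eligible, keeping the threshold well
defined; all-equal scores raise a no-change-point error, and fewer than 20
scores are rejected with a suggestion to use a direct percentile cut.

A least-squares split always exists, even on pure noise, so a detection
guard is applied: the mean of the high segment must exceed the mean of the
bulk by at least 4.5 bulk standard deviations. The optimal two-means split
of a unimodal sample separates its own upper tail by roughly 3.5–4.5 bulk
SDs, while a genuinely planted signal under this package's synthetic design
separates by 5 or more; 4.5 sits between the regimes, so null inputs yield
"no change point" instead of an arbitrary top slice. The guard is a
parameter (`min_separation`, 0 disables). A score histogram
(Freedman–Diaconis bins, floor of 30) is returned alongside as a diagnostic
and written by the TSV exporter.

Of the K edges at or above the threshold only the top k = ⌈f·K⌉ are kept,
with safety fraction f = 0.75 by default — a margin against borderline false
positives. The cut is count-based and extended to include any edge tied with
the k-th score, so the selection is a prefix of the deterministically sorted
score table (score descending, then lexicographic gene pair) and never
depends on input order. Raising f yields a nested superset. The selected
edges and their endpoints form the mechanism, reported with connected
components and exported as GraphML (nodes annotated with log2FC and p, edges
with score/type/source pathways), SIF and TSV.

## Evaluation harness

Knockout (KO) experiments provide pathway-level ground truth: pathways
containing the KO gene are positives, all others negatives. A gene list is
turned into pathway calls by over-representation analysis — the one-sided
hypergeometric upper tail P(X ≥ overlap) against the universe of measured
genes annotated to at least one pathway, Benjamini–Hochberg FDR across the
tested pathways, significance at FDR < 0.1. The same universe restriction is
applied to both methods under comparison, so neither is penalised for genes
the database does not know. Calls are summarised as TPR, FPR and the
positive likelihood ratio TPR/FPR (+∞ when FPR = 0 and TPR > 0, preferred
over any finite ratio when ranking; 0 when both are 0).

The classical baseline selects genes with |log2 FC| ≥ fc_cut and
−log10 p ≥ p_cut and is swept over a grid (defaults: fc from 0.5 to the data
maximum in steps of 0.25, −log10 p from 0.5 to 5 in steps of 0.5 — step
sizes are configurable since no canonical values exist), reporting each
cell's DE count and rates plus the best cell by likelihood ratio (ties:
higher TPR, then more stringent cuts). Its gene lists are rendered
comparable to a network method by inducing the subgraph of the global graph
on the list, keeping isolated genes as singleton components. The edge-score
method is swept over score cutoffs from the change point to the maximum
score, with the default change-point + margin selection flagged. External
pathway rankers can be compared on the same truth through an adapter that
accepts any pathway/p-value table.

## Synthetic knockout experiments

The generator emulates the kind of study that can validate mechanism
inference: a single-gene knockout with known downstream targets.

* **Database.** 10 pathways of 30 genes; each pathway is a uniform random
  spanning tree plus extra edges at density 0.02 (mean degree ≈ 2.5, the
  sparsity of typical signaling pathways), hence connected by construction;
  10% of each pathway's genes are reused from earlier pathways. One
  designated KO candidate — a modest-degree gene of the first pathway — is
  made a member of 3 pathways in total with 3 interactions in each,
  attached to the highest-local-degree members ("core machinery"): real KO
  genes are multi-pathway signaling genes whose direct targets are
  themselves regulators, and a leaf target would truncate the cascade after
  one hop. The candidate is excluded from the overlap pool so its membership
  count is exact.
* **Truth.** The planted mechanism is the breadth-first tree from the KO
  gene to depth 2 (deterministic: neighbours visited in sorted order). The
  KO gene is shifted by −3 log2 units (a strong knockdown rather than literal
  zero expression, keeping variances finite); a gene at depth d is shifted by
  3·0.6^d with a sign that flips at random per edge (activation vs
  inhibition — scoring is sign-insensitive under the default transform, so
  this is free realism).
* **Expression.** Gene baselines uniform in [6, 10] log2 units; Gaussian
  noise with SD 0.4 per measurement (normalised microarray intensities match
  the moderated-t assumptions); 5 case vs 5 control samples; 50 additional
  background genes outside every pathway, mimicking the measured-but-
  unannotated majority of an array. Everything is bit-reproducible per seed,
  and experiment-level seeds spawn independent sub-streams for database,
  truth and expression.

What the generator does *not* model: probe-level artifacts, batch effects,
correlated noise, RNA-seq counts, feedback loops, or partial knockdowns.
Passing tests therefore demonstrate the pipeline's statistical machinery and
selection logic under its own assumptions, not robustness to real-data
pathologies.

## Numerical and design notes

* Change point on the sorted scores rather than on histogram bin counts: a
  least-squares split of raw bin counts of a decaying distribution lands
  inside the bulk (the near-peak bins dominate the RSS), while the
  sorted-score split lands in the gap between signal and background
  whenever one exists; the histogram remains as a diagnostic.
* Tie handling is explicit everywhere a count-based rule could depend on
  order: score sorting uses a stable key with a lexicographic tie-break, the
  margin extends across ties, and change-point splits between equal values
  are skipped.
* The moment estimator for (d₀, s₀²) uses a Newton iteration for the
  trigamma inverse with the asymptotic branches 1/√y (y large) and 1/y
  (y small); d₀ recovery on simulated variances is accurate to well within
  ±20% at 10,000 genes.
* With every observed variance equal to c the moment equations give d₀ = ∞
  and s₀² = c·exp(log(df/2) − ψ(df/2)) (the log-scale bias correction), not
  s₀² = c; the implementation follows the moment equations.
* A safety-fraction sweep can only leave the mechanism unchanged when the
  above-threshold set has at most two edges or is tied at the boundary —
  ⌈0.6K⌉ = ⌈0.9K⌉ forces K ≤ 2. Minimal two-edge mechanisms are exactly the
  regime where margin-independence is observed and tested.
* Default problem sizes in tests and the acceptance script (50 simulated
  experiments of ~270 genes and ~390 interactions) keep full runs in the
  seconds-to-minutes range while leaving the planted signal realistically
  sized relative to the network.

## Known limitations

* The edge score is direction-blind; an inhibition that *raises* a target's
  expression scores identically to an activation.
* ORA on compact databases (few, similarly sized pathways) has limited
  power: a mechanism of ~40 genes against a universe of ~270 needs overlaps
  of roughly 9+ genes per pathway to clear FDR < 0.1 across 10 tests, so
  pathway-level recall degrades gracefully, not sharply, with weaker
  penetration.
* The change-point guard trades a small chance of missing a weakly
  separated real signal for silence on noise; lower `min_separation` when
  screening permissively.
* KGML parsing covers gene entries, groups and relations (plus optional
  reaction chaining through shared compounds); map links between pathways
  are ignored.
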