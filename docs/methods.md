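# Methods

## Scope

mitonet re-implements, as a tested and reusable pipeline, a network-assisted
analysis of differential proteomes measured on 2D gels: reference-spot
normalization and bootstrap logFC effect sizes, construction of a
protein–protein interaction (PPI) network over the differential proteins,
a permutation test of its internal connectivity, Markov clustering,
hypergeometric overrepresentation of clusters against annotation gene sets,
and extension with a regulatory TF→target catalogue followed by a screen for
transcription factors whose targets are regulated in opposite directions by
two reperfusion strategies. All stages run on plain text formats (CSV/TSV,
GMT, GraphML) and on synthetic data with planted ground truth.

## Quantification model

Each gel carries an unknown multiplicative loading/staining factor shared by
every spot on that gel. On the log2 scale an observation is modeled as

    log2 I(s, g) = mu_s + beta_{s, group(g)} + gamma_g + eps_{s,g}

with spot baseline `mu_s`, additive group effect `beta` (the quantity of
interest), gel factor `gamma_g`, and residual noise `eps`. Dividing every
intensity by the same gel's reference (albumin) spot cancels `gamma_g`
exactly. The generator treats the reference spot as an ideal loading
control — it carries the gel factor but no residual noise — because an
abundant reference is measured with negligible *relative* error; under that
assumption reference normalization is exactly the right correction rather
than a noise-injecting approximation. This is the one feature of real data
the generator deliberately idealizes: on real gels the albumin spot has some
measurement error of its own, which propagates (correlated within gel) into
every normalized value.

The group difference is summarized as

    logFC(a, b) = log2( median_a / median_b )

of normalized intensities, computed as `log2(median_a) − log2(median_b)` so
that antisymmetry is exact in floating point. Zero medians raise an error;
no pseudocount is ever applied silently.

## Bootstrap effect size

Gels are the independent biological units, so the bootstrap resamples gels
with replacement within each group (resample size = group size),
independently for the two groups, and recomputes the median-based logFC per
replicate. The reported effect size is the *median* of the replicate
distribution (mirroring the median-based point estimate), with a (2.5,
97.5) percentile interval. Replicates whose resampled median is zero are
excluded and counted. Defaults: `n_boot = 1000`, log base 2 (switchable for
cross-checks). A protein is differential when |effect| strictly exceeds the
threshold (default 0.5 log2 units); the comparison is strict, so an effect
of exactly 0.5 is not called.

With three gels per group the percentile bootstrap is expected to
under-cover: the test suite bounds coverage of the 95% interval to the
80–100% band rather than asserting nominal coverage. A related intrinsic
limit: the difference of group medians-of-3 has standard deviation
≈ `noise_sd × 0.67 × √2`, so at `noise_sd = 0.25` no estimator of this form
concentrates within ±0.3 of the truth 95% of the time (the achievable rate
is ≈ 80%); the acceptance suite documents this honestly.

## Synthetic-data defaults (the study conditions)

* 4 groups (sham, Isch, I/R, PostC), 3 gels each — the emulated design.
* `noise_sd = 0.2` log2 units (~15% CV). Chosen a priori by power analysis:
  with 3 replicates the null logFC SD is ≈ 0.19, which puts the 0.5
  threshold at ≈ 2.6 null SDs — the regime in which a median-based test on
  triplicates can call 2-fold changes with high sensitivity and a false
  discovery proportion below 10%. Larger residual CVs make triplicate 2D-gel
  designs unable to separate 2-fold changes at this threshold at all, which
  is precisely why such studies keep technical variation tight.
* `gel_scale_sd = 1.0` log2 units — a deliberately large gel-loading spread
  that normalization must remove completely.
* Default study: 300 spots, 26 planted differential proteins at
  |logFC| ≥ 1 arranged in three dense interactome modules (9/9/8,
  within-module edge probability 0.6) inside a sparse background
  (p = 0.02); STRING-style combined scores uniform in 400–999; 20 TFs with
  3 in-network targets each, of which 3 TFs draw all targets from a pool of
  six proteins planted with sign-flipping effects between the I/R-vs-Isch
  and PostC-vs-Isch contrasts (±1 in each, via Isch = ±1, I/R = 0,
  PostC = ±2 relative to sham). The non-flipping differential proteins move
  the same way in both contrasts, so they can never be spuriously
  "opposite" by design, only by estimation noise.
* Annotations: one term per planted module plus 20 random decoy terms.

What the generator does *not* emulate: spot-detection and matching errors,
saturation and dynamic-range compression of fluorescent stains, missing
spots, correlated biological covariates between animals, and identifier
ambiguity from MS identification. Passing tests therefore demonstrate the
statistical machinery under the stated model, not robustness to those
artifacts.

## Interactome handling

STRING-download dialect TSV (`protein1`, `protein2`, integer
`combined_score` 0–1000). Scores are rescaled to [0, 1]; duplicate pairs
collapse to the maximum score; self-pairs are dropped; the retention rule is
`score/1000 ≥ cutoff` with a default cutoff of 0.4 ("medium confidence"),
the caller's choice thereafter. Identifier matching is exact and
case-sensitive — any ortholog/alias mapping must happen upstream.

## PPI edge enrichment

The connectivity of the differential set is tested by permutation: the null
draws node sets of the same size uniformly from the background interactome
and counts induced edges; `p = (1 + #{null ≥ observed}) / (n_perm + 1)`,
never zero and exact under exchangeability. A degree-matched variant
(sampling within degree-decile bins) is available for backgrounds with
skewed degree distributions; the uniform null is the default and is the
calibrated one in the tests.

## Markov clustering

MCL is implemented from scratch on the weighted adjacency matrix:

1. self-loops are added per column (weight = the column's maximum edge
   weight, the standard stabilization; isolated nodes get 1.0);
2. columns are normalized to a stochastic matrix;
3. iterate expansion (matrix power, default 2) then inflation (entrywise
   power, default 1.4, with column renormalization), zeroing entries below
   `pruning_threshold = 1e-5`;
4. stop when the maximum entrywise change falls below `1e-8` or after 200
   iterations (non-convergence sets a flag and warns — never silent);
5. clusters are the connected components of the limit matrix's nonzero
   structure; cluster ids are dense integers ordered by decreasing size,
   ties broken by smallest member id, making the labeling invariant to node
   input order.

The implementation is deterministic (no randomness anywhere) and is checked
against an independent dense reference (no pruning, tolerance 1e-12) on
hundreds of random small graphs. A caution documented by the acceptance
suite: at inflation 1.4 MCL is a *coarse* clustering — planted blocks
bridged by even two or three chance inter-block edges merge in a sizeable
fraction of random stochastic-block-model draws. Separation at that
inflation is only reliable when between-module connectivity is very sparse
(roughly p_between ≲ 0.005 for 10-node blocks), as it is in the default
study's interactome.

## Overrepresentation analysis

For a query of `n` universe members of which `k` carry a term, with `K`
carriers among `N` universe members, the p-value is the exact upper
hypergeometric tail P[X ≥ k] (`scipy.stats.hypergeom.sf`). "Strength" is
`log10((k/n)/(K/N))`, the log10 observed/expected ratio. FDR is
Benjamini–Hochberg across all tested terms (statsmodels backend, verified
against a hand-rolled step-up in the tests). The default universe is the
set of background-interactome nodes carrying at least one annotation; terms
with no universe members are skipped rather than assigned p = 1, keeping
the BH family size meaningful. No GO-graph propagation is performed.

## Regulatory extension and the opposite-regulation screen

TF→target edges are added only for targets already in the PPI network; the
PPI edge set is never altered and TFs without in-network targets never
appear, so extension is idempotent. A target is *opposite-regulated* when
its two contrast logFCs (I/R vs Isch, PostC vs Isch) have opposite signs
and both magnitudes strictly exceed the threshold (default 0.5). A TF is a
candidate when at least one of its in-network targets is opposite; per-TF
counts are reported so stricter rules (e.g. all targets) can be applied
downstream. Candidates are ranked by the number of opposite targets, then
by TF id, for determinism. Targets lacking a logFC in either contrast are
skipped with a warning, never treated as zero.

## Pipeline and reproducibility

Each stage reads and writes files in the configured output directory,
writing atomically (temp file + rename) with a commented metadata header
(tool version, stage, master seed, config hash — no timestamps). One master
seed deterministically spawns per-stage seeds (`SeedSequence` with fixed
spawn keys), and per-spot bootstrap seeds are spawned in spot-major order,
so a single spot recomputed in isolation reproduces its table-wide result
and two identical runs are byte-identical. When no protein passes the
threshold the pipeline stops cleanly after the differential table with an
explanatory log message.

Problem sizes were chosen so the whole test suite and the end-to-end script
run comfortably on one CPU: the default study uses 300 spots and
1000 bootstrap replicates; oracle comparisons use 500 random graphs of ≤ 7
nodes; calibration uses 1000 permutation trials of 199 permutations each.

## Known limitations

* The bootstrap with 3 gels/group has a granular replicate distribution
  (10 distinct multisets per group) and under-covers; intervals are
  descriptive, not exact.
* The permutation null for edge enrichment is uniform over node sets, not
  degree-matched, by default; for hub-heavy backgrounds use the
  degree-matched option.
* MCL at low inflation merges weakly bridged modules (see above).
* Reproducing any particular published enrichment table additionally
  depends on the annotation source, background and database version used
  there; this package fixes none of those choices.
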