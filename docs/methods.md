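# Methods

## Count model and differential expression

Counts are modeled as negative binomial: gene *g* in sample *j* has mean
`s_j · μ_g(cond(j))` and variance `μ + α μ²`, with `s_j` a per-sample size
factor and `α` the gene-level dispersion. The DEG caller is a deliberately
transparent implementation of the familiar count-based workflow:

* **Normalization** — median-of-ratios: for genes with strictly positive
  counts in every sample, `s_j = median_g (x_gj / geomean_g)`. Factors are
  invariant to gene permutation and equivariant to per-sample scaling.
* **Effect size** — `log2fc = log2(μ̂_trt / μ̂_ctrl)` on normalized
  condition means; positive = upregulated under treatment. Genes with a
  zero mean in either condition have an undefined ratio and are excluded
  from testing (flagged, not pseudocounted — a pseudocount would silently
  pick an arbitrary effect scale).
* **Test** — Wald statistic `z = log2fc / SE` with the delta-method error
  `SE² = (1/ln2)² Σ_cond (1/n_cond)(c_cond/μ_cond + α̂)`, where `c_cond` is
  the mean inverse size factor of that condition's samples (the variance of
  a mean of normalized counts is `(μ·c + αμ²)/n`). Two-sided p from the
  standard normal; BH step-up q-values; DEG ⇔ q ≤ 0.05 (inclusive).
* **Dispersion** — per-group method of moments
  `α̂ = max(0, (s² − m̄)/m̄²)` (ddof = 1), averaged over the two groups,
  then stabilized toward the parametric dispersion–mean trend
  `α(μ) = a₀ + a₁/μ` — the asymptotic form for NB counts with a
  mean-independent biological dispersion plus shot noise. The trend is
  fitted by variance-weighted least squares (weights `1/(1/μ + α)²`,
  iterated twice); a *mean* fit is deliberate, because the moments are
  right-skewed and robust location fits (median or Huber) sit below the
  mean and therefore underestimate dispersion, inflating the test. The
  default combination is empirical-Bayes: each gene weights its own moment
  by `τ²/(τ² + v_g)` with `v_g ≈ (2/df)(1/μ + α)²` the moment's sampling
  variance and `τ²` the positive-part estimate of the between-gene spread
  of true dispersions around the trend, guarded by one standard error so
  sampling noise is not mistaken for heterogeneity. When dispersions are
  homogeneous the estimate collapses to the trend and the test is
  calibrated through its far tail; when genes genuinely differ, per-gene
  information is retained. A fixed-weight mode (`shrink`, default weight
  0.5) and the raw moments (`mom`) remain available; the fixed-weight
  variant was measured noticeably anticonservative at five replicates
  (empirical size ≈ 0.069 at the nominal 0.05, and ≈ 1 in 5 global-null
  runs produced a spurious DEG call), which is why it is not the default.

Measured behavior under the simulation's study conditions (2000 genes,
5 replicates/group, α = 0.1): empirical size ≈ 0.051 at nominal 0.05;
under a global null the fraction of runs with any DEG call is ≈ 0.06,
against the theoretical floor of 0.05 (under a global null BH's chance of
any rejection equals q exactly, so "no false calls in ≥95% of runs" is the
boundary even for a perfect test). With planted |log2FC| = 2 and baseline
means ≥ 100, power ≥ 0.99 at q ≤ 0.05 with empirical FDR ≤ 0.10.

Not implemented on purpose: fold-change shrinkage, Cook's-distance outlier
replacement, independent filtering, multi-factor designs.

## Interaction network

Edge lists follow the STRING "detailed" dialect (per-channel scores,
integer 0–1000 or floats in [0,1]; the header spelling `cooccurence` is
preserved on output). The published combined score cannot be decomposed,
so channel exclusion recombines from the per-channel scores with the
prior-correction convention:

```
s'_c = max(0, (s_c − p₀)/(1 − p₀));  S' = 1 − Π_allowed (1 − s'_c);
S = S' + p₀ (1 − S')
```

with prior p₀ = 0.041 (configurable). Properties relied on and tested:
single-channel idempotence (|S − s| ≤ 10⁻³), monotonicity in every allowed
channel, independence of excluded channels, and floor S = p₀ with no
allowed evidence — hence an edge supported only by text-mining can never
reach the 0.900 threshold. The default exclusion set is text-mining,
neighborhood, fusion and co-occurrence; co-expression, experimental and
database evidence remain. A homology channel is not modeled.

The analysis graph is the induced subgraph on DEGs with recombined score
≥ 0.900 (inclusive — "highest confidence" band semantics); isolated DEGs
stay as degree-0 nodes. Component diameters use unweighted BFS distances;
the highest-diameter component is selected with deterministic tie-breaks
(larger node count, then lexicographically smallest node set). Group
removal (e.g. ribosomal-protein genes, supplied as a plain text file — no
live nomenclature query) takes the induced subgraph and deliberately does
*not* re-select components afterwards. Betweenness is Brandes' algorithm
on unweighted shortest paths, endpoints excluded, normalized by
(n−1)(n−2)/2 with *n* the node count of the analyzed graph — the hub
threshold 0.5 only makes sense on a [0,1] scale. Hubs require strictly
betweenness > 0.5 **and** degree > 2.

## Over-representation analysis

Gene sets come from GMT files; each set is intersected with the background
universe before testing. The default universe is (genes measured in the
count matrix) ∩ (genes annotated in the collection) — the choice is
configurable, and fold enrichment depends on it. Per term:
upper-tail hypergeometric `p = P(X ≥ k)` with population N, successes K,
draws n; BH FDR across all tested terms; fold enrichment (k/n)/(K/N). The
report filters at FDR ≤ 0.05 and sorts by fold enrichment descending (ties:
FDR, then term id). Term clustering / redundancy reduction is out of scope.

## Synthetic data: what it emulates, and what it does not

`simulate_counts` draws NB counts (gamma–Poisson, shape 1/α) with one
shared dispersion, baseline means log-uniform (default e^[log 50, log 5000]
≈ 50–5000, the bulk of a realistic expressed-gene range), per-sample size
factors log-uniform in [0.5, 2] so normalization does real work, and a
planted fraction (default 10%) of genes whose treated mean is multiplied
by 2^(±effect). Two replicates per group mirrors the motivating
experimental design and is the configuration default, but two-replicate NB
testing is underpowered, so recovery experiments use five.

`simulate_interactome` wires, over genes sampled from a candidate pool
(the planted DE genes, so structures survive DEG restriction):

* a hub **star** (default 6 genes) with optional leaf–leaf chords;
* short **chains** (default 4 × 2 genes) hanging off distinct leaves —
  they stretch the hub component's diameter (default 6) so that
  highest-diameter selection is robust even if one chain gene drops out
  of the DEG call, while keeping chain nodes at degree ≤ 2 so the hub
  stays the unique node passing both hub thresholds;
* a **ribosomal clique** (default 8 genes) bridged to one leaf;
* **decoys** (default 20) with high text-mining scores only; and
* sparse **background** edges between non-structural genes with
  direct-evidence scores uniform in [0.5, 0.99], straddling the 0.900
  threshold.

Structural edges carry experimental scores in [0.92, 0.985], comfortably
above threshold after recombination. `simulate_genesets` plants one term
drawn ≥ 80% from a designated gene list (the expected post-pruning
subnetwork) among uniform random terms.

What the generators do **not** emulate: GC/length biases, library-specific
mean–dispersion curves, correlated genes, scale-free interactome topology,
overlapping/hierarchical annotation structure, identifier-mapping noise.
Passing recovery tests therefore demonstrates the pipeline's mechanics —
filtering, selection, ranking, calibration under the stated model — not
performance on any particular organism's data.

## Numerical and reproducibility choices

* All randomness flows through `numpy.random.default_rng(seed)`; the
  pipeline derives stage seeds as seed, seed+1, seed+2. Identical config +
  seed ⇒ byte-identical reports (tested).
* Worked-example comparison rounds half-away-from-zero to 2 decimals.
* Integer score files are detected by column dtype; scores divide by 1000.
* Degenerate paths: zero DEGs yields an empty-but-valid report; graphs
  with < 3 nodes have betweenness 0; singleton components have diameter 0.
* Test problem sizes (2000-gene simulations, 200 random graphs ≤ 7 nodes,
  N ≤ 25 enumeration grids) are chosen so the whole suite runs in well
  under a minute while keeping Monte-Carlo standard errors far from the
  asserted bounds; the null-size check pools three simulations for the
  same reason.

## Known limitations

* The Wald test retains a small anticonservative residual (size ≈ 0.051 at
  five replicates); at two replicates per group power is very low and
  calibration degrades — the test is reported, but conclusions at n = 2
  rest on the fold-change ranking more than on q-values.
* The hypergeometric ORA treats genes as exchangeable; no term-term
  correlation or annotation bias correction.
* Betweenness normalization follows the analyzed (sub)graph's node count;
  comparing hub thresholds across graphs of very different sizes is not
  meaningful.
* The evidence-recombination formula assumes channel independence, as the
  source database's convention does.
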