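# Methods

## Model and procedure

The toolkit treats a protein–protein interaction network as a simple,
undirected, binary graph over gene-symbol nodes.  Edge confidences (STRING
combined scores rescaled to [0, 1], or scores supplied in a generic edge
TSV) are used only for admission thresholds (strictly `score > min_score`,
default 0.7) and for connectivity-ranked expansion; all downstream
computation ignores them.  Node identity is an exact case-sensitive string
match — symbol harmonization is deliberately out of scope and must happen
upstream.

### Random-failure resilience

For a network of size `N`, at failure rate `f` we remove `round(f·N)`
distinct nodes uniformly at random (half-up rounding, so the removal count
is monotone in `f`) and measure the component entropy

    H = − Σ_i (C_i/N) · log_N(C_i/N),

counting each removed node as a singleton component so the size
distribution always sums to `N`.  Two properties motivate these choices:

* **Base-`N` logarithm.**  This is the only base for which both endpoint
  conventions hold for every network size: one intact component gives
  `H = 0` and `N` singletons give `H = 1` (each singleton contributes
  `(1/N)·log_N N = 1/N`).
* **Removed nodes as singletons.**  Keeping `Σ C_i = N` at every failure
  rate makes the denominators of the index coherent across the sweep and
  gives the exact endpoint `H(f=1) = 1` without a special case.

`H` is averaged over `iterations` independent removal draws (default 500,
the point at which the per-rate mean is stable to ~1% on the network sizes
we target).  The endpoints are deterministic and bypass sampling: `f = 0`
returns the intact graph's component entropy — nonzero for a disconnected
input, which is documented behaviour, the curve simply does not start at
0 — and `f = 1` returns exactly 1.

The failure-rate grid is either *exact* (`{i/N}`, every achievable rate) or
*binned* (`n_bins + 1` equally spaced edge points including 0 and 1; the
entropy is evaluated at the bin edges, not averaged within bins).  `auto`
uses the exact grid up to `N = 1000` and 200 bins above, trading grid
resolution for run time on large networks; on a 300-node test network the
exact-grid and 200-bin resilience agree to within 0.001.  The accumulated
entropy `H_msh` is the composite trapezoidal integral of the mean-entropy
curve over `f`, and `resilience = 1 − H_msh`, so an entropy curve that
stays flat at 0 until late failure gives resilience near 1.

Reproducibility: a master seed spawns one child RNG stream per grid point
(`numpy` `SeedSequence.spawn`), so a fixed (network, grid, iterations,
seed) tuple yields a bitwise-identical curve regardless of evaluation
order.

Across a series of serially expanded networks, resilience values are
min–max normalized (an all-equal series is an error rather than a silent
0/0) and the optimal size is the smallest from which every successive
normalized change stays below `plateau_tol` (default 0.07).  If the final
step still exceeds the tolerance there is no plateau and the caller is told
to expand further.

### Topology

* **Characteristic path length** is reported in *intermediate-node units*:
  shortest-path edge count minus one, averaged over unordered node pairs
  within the largest connected component (pairwise distances between
  components are undefined; restricting to the LCC is our choice for
  disconnected inputs).  This convention makes two proteins that interact
  only through one shared partner sit at distance 1.  The conventional
  edge-count CPL is exported alongside as `cpl_edges` to avoid ambiguity.
* **Clustering** is the mean local clustering coefficient with degree-<2
  nodes contributing 0; **density** is `2E/(N(N−1))`; **mean degree** is
  `2E/N`.
* **Power-law exponent.**  γ of `p(k) ∝ k^−γ` is estimated by ordinary
  least squares of `log10(count)` on `log10(k)` over nonzero counts with
  `k ≥ 1` (at least three distinct degrees required).  A
  maximum-likelihood (Clauset-style) fit is deliberately not used: the
  exponent is meant to describe the visual degree plot, and the regression
  estimate is what that describes.  On binned preferential-attachment
  degree counts the regression underestimates the asymptotic exponent —
  that bias is a property of the estimator, not a defect, and is why only
  a broad plausibility range is asserted for generated networks.
* **Hub detection.**  Nodes are ranked by descending degree (symbol as the
  deterministic tie-break) and the kneedle algorithm locates the elbow of
  the rank-vs-degree curve.  A heavy-tailed descending degree curve is
  convex-decreasing, so the curve is min–max normalized and flipped
  vertically into kneedle's canonical concave-increasing form; the elbow
  is the first local maximum of the difference curve `d = (1−y_n) − x_n`
  that decays below `d_max − sensitivity/(n−1)` before the next local
  maximum (sensitivity default 1.0).  No smoothing spline is applied —
  the input curve is already monotone.  Hubs are the nodes ranked strictly
  before the elbow, extended by any ties at the lowest included degree
  (`elbow_k`), which guarantees hub degrees dominate non-hub degrees.  A
  flat curve (regular graph) has no knee and yields an empty hub set with
  a warning.

### Candidate prioritization (adapted MaxLink)

Seed genes present in the network are tagged; the candidates are the
immediate neighbours of tagged nodes, minus the seeds themselves.  Two
sequential filters follow, and candidate status only moves forward
(`candidate → removed_annotation / removed_connectivity / final`):

1. **Annotation filter.**  A candidate is removed if any of its Disease
   Ontology term names or slim tags contains any of the keywords
   `glioma`, `cancer`, `tumor`, `cancer_DO_slim` (case-insensitive
   substring match; the keyword list is configurable).  Matching is on
   term text, not DOID numeric codes.  Candidates without a DO record are
   retained.
2. **Connectivity filter.**  Seed-connectivity is regressed on total
   degree with a loess smoother: tricube weights over the
   `ceil(span·n)` nearest neighbours (span 0.75), local polynomial of
   degree 2 (reduced where the window lacks distinct abscissae), followed
   by two Cleveland bisquare robustness iterations that down-weight
   outlying points.  The robustness step matters: the filter exists to
   expose outliers, and without it a contingent of strong outliers
   inflates both the trend and the residual scale until it masks itself.
   The pointwise band is `fit ± z(ci_level)·scale` with `scale` the local
   (robustness-weighted) residual standard deviation and `ci_level`
   default 0.95.  Candidates *inside* the band — those whose
   seed-connectivity is explained by their overall degree — are
   eliminated; outliers survive.  By default outliers on either side
   survive (`keep="both"`); `keep="above"` restricts survival to
   above-band candidates.  At least 10 active candidates are required,
   and a degenerate degree range (all equal) is an error.

### Differential expression and hit calling

Tumour samples are staged from TNM codes: any `TX/NX/MX` field excludes
the sample; `N0 ∧ M0` (any T) is primary; `N ∈ {N1, N2, N3}` (any M) is
metastasized.  Sub-stage suffixes (`N1b`, `T2a`) are accepted; only the
first character after the letter is interpreted.  The leftover combination
`N0 ∧ M1` matches no rule: the default (`strict`) mode excludes it with a
warning, an `inclusive` mode counts it as metastasized.  Normal-tissue
samples are whatever the metadata flags as `source = normal`, regardless
of TNM — combining GTEx and TCGA normals is the caller's concern.

Per gene, cancer type and transition (normal→primary,
primary→metastatic), the fold change of cohort means is
`(mean_b + ε)/(mean_a + ε)` with ε = 10⁻³ FPKM guarding zero means
(configurable; its use on a zero mean is logged), and significance is a
two-group Kruskal–Wallis test (tie-corrected, χ² reference; fully tied
data return `H = 0, p = 1` by convention).  We test each transition as its
own two-group contrast rather than one three-group test per gene, because
the quantity being stratified is the per-transition fold change and its
per-transition significance.  A cancer type lacking a required cohort has
that transition skipped with a warning.

Tiers use the printed strict inequalities exactly: high (`|log2FC| > 2`
and `P < 0.001`), medium (`1 < |log2FC| < 2` and `0.001 < P < 0.01`), low
(`1 < |log2FC| < 2` and `0.01 < P < 0.05`), non-significant (`P > 0.05`);
every other combination — e.g. `|log2FC| > 2` with `P = 0.005` — is
`unclassified` rather than silently assigned to a widened band.  A gene is
a hit when its primary→metastatic tier is high or medium.  No
multiple-testing correction enters tier assignment; a Benjamini–Hochberg
column is emitted for information only.

## Synthetic data: what it emulates and what it does not

The generator is a pure function of a `SynthConfig`; every output is
reproducible from the seed.

* **Network**: preferential attachment starting from a complete graph on
  `m` nodes, `m = n_edges_per_node = 4` by default, 200 nodes — edge count
  exactly `m(m−1)/2 + (n−m)·m`.  This reproduces the heavy-tailed,
  weakly scale-free degree regime of curated PPI networks.  `m = 4` (mean
  degree ≈ 8) is used rather than a sparser setting so that the mid-degree
  range — where the connectivity filter must distinguish planted outliers
  from the trend — has dense natural support.  Edge confidences are
  uniform on [0.5, 1].  A disjoint pool of 40 extra nodes with 1–5
  candidate edges each (degree-weighted attachment) supports expansion
  tests.
* **Seeds and annotations**: 17.5% of nodes are tagged as seed (disease)
  genes, mirroring the proportion of experimentally verified EMT genes in
  an optimally sized Rab interactome (346/1971).  30% of candidates
  receive a cancer-containing DO term; planted nodes never do.
* **Planted ground truth**: ten *planted hit genes* and one *planted
  specific neighbour* are low-degree nodes wired to extra randomly chosen
  seed genes (link counts spread over [4, 12] so the planted genes
  scatter along the degree axis instead of forming a cluster the loess
  would adopt as its local trend); one *planted promiscuous hub* is the
  best-connected non-seed node, left with its natural, degree-explained
  seed-connectivity.  By construction the planted genes are candidates
  that survive both filters, the hub is a candidate the connectivity
  filter should remove, and the specific neighbour survives.
* **Expression**: per-gene log-means are normal around `fpkm_logmean = 2`
  (≈ 7 FPKM medians), per-sample FPKM is log-normal with
  `fpkm_logsd = 0.5` — within the realistic range for within-cohort
  log-FPKM spread, and small enough that a null gene's empirical
  |log2FC| at cohort size 30 stays below 0.5 in ≥ 95% of draws, which is
  the sampling-noise behaviour the null-recovery checks assume.  Cohorts
  of 30 (normal/primary/metastatic) for one synthetic cancer type;
  planted effects shift the later-stage cohorts' log-mean by
  `log2FC·ln 2` and persist through subsequent stages (a gene induced at
  incidence stays induced in metastasis, so a normal→primary effect does
  not masquerade as a primary→metastatic one).  An extra 5% of tumour
  samples carry an X field to exercise the exclusion rule without
  shrinking the cohorts.  TNM codes are generated consistent with cohort
  membership.

Not emulated — and therefore not demonstrated by passing tests: realistic
correlation structure between genes or tissues, batch effects, the true
topology of the Disease Ontology, literature-curated interaction biases,
and any particular value of the degree exponent γ (which in real data
depends on the source database).  Passing the planted-recovery suite shows
the pipeline's machinery is correct and well-calibrated on data matching
its own assumptions; it does not certify performance on real cohorts.

## Numerical choices and degenerate inputs

* Removal counts use half-up rounding of `f·N`.
* Entropy values are clipped to [0, 1] against floating-point underflow.
* The Monte-Carlo inner loop masks the edge list and runs
  `scipy.sparse.csgraph.connected_components` on the resulting adjacency;
  removed nodes come out as isolated vertices, i.e. exactly the singleton
  components the index requires.
* `component_entropy` rejects `n_total < 2` (log base undefined) and
  non-positive component sizes; `normalize_series` rejects all-equal
  input; `select_optimal` requires a sorted series.
* Loess reduces the local polynomial degree when a window has too few
  distinct x values, and keeps boundary weights at a small positive floor;
  a zero median absolute residual (perfect fit) short-circuits the
  robustness iterations — in that limit the band is degenerate and every
  point is "inside", which is the documented perfect-trend behaviour.
* Expansion ranking ties break by summed confidence, then lexicographic
  symbol, making expansion deterministic for a fixed input.

## Problem sizes used by the test suite

The suite exercises exhaustive-enumeration oracles on graphs of ≤ 8 nodes
(all `C(N, k)` removal sets), grid-consistency on 300-node networks at 500
iterations, Kruskal–Wallis calibration on 500 null simulations of two
20-sample cohorts, and end-to-end planted recovery over 20 generator seeds
at the default 200-gene / 30-per-cohort conditions.  These sizes keep the
full suite to a few minutes while leaving every statistical check
well-powered.

## Known limitations

* Resilience is defined for *random* failure only; targeted dismantling
  (by degree or centrality order) is out of scope.
* The power-law fit is a descriptive regression, not an MLE with a
  goodness-of-fit test; do not over-interpret γ.
* The connectivity filter's band is a pointwise scale band, not a
  simultaneous confidence band; its "95%" is per-candidate.
* Exact string matching of gene symbols means upstream identifier
  harmonization failures silently reduce overlap; off-network seeds are
  only logged.
* With `keep="both"`, below-trend outliers survive the connectivity
  filter; whether such under-connected candidates are biologically
  interesting is for the caller to decide (`keep="above"` is available).
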