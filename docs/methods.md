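# Methods note

This document records the statistical definitions, parameter defaults
and numerical choices implemented in `phylodistricts`, so results can be
interpreted and reproduced without reading the source.

## Data model

- **Phylogeny**: a rooted tree with branch lengths (interpreted as time,
  e.g. Myr).  Trees without dates can be dated with **BLADJ**: node ages
  fixed by a calibration table are honoured, and undated nodes on each
  root-ward path segment between two calibrated ages are spaced evenly.
  The traversal interpolates segment-wise from the root down; when a
  node lies on several calibrated paths the first (root-ward)
  assignment wins.  Calibrations violating ancestry (a child older than
  its parent) are rejected rather than silently clipped.
- **Community matrix**: plots × species integer stem counts.  Blank
  CSV cells are zeros; duplicate plot ids, negative or fractional
  counts and empty plots are errors.  Tree and matrix are reconciled to
  their shared species set before analysis (`align_tree_matrix`), with
  the original root kept so root-to-tip path lengths are unchanged.

## Alpha diversity

- **Fisher's alpha** solves `S = α ln(1 + N/α)` by bracketed Brent
  root-finding plus a Newton polish (`|residual| < 1e-9`); requires
  `1 ≤ S < N`.
- **Faith PD** is *rooted*: the spanning path includes the stem edges up
  to the root, so a single-species plot has PD equal to that species'
  root path.
- **MPD** is the mean pairwise patristic distance over distinct species
  pairs (unweighted) or over individual pairs of distinct species
  (abundance-weighted).
- **ses.MPD** = (MPD_obs − mean MPD_null) / sd(MPD_null), with the
  sample standard deviation (ddof = 1) over 999 null draws by default
  (minimum 99).  |ses| > 1.96 is flagged.  **Sign convention**: the
  reported labels follow the convention that *positive* values are
  called "clustered".  Communities confined to one clade have *low*
  MPD, hence strongly *negative* ses, and are therefore labelled
  "overdispersed" under this convention even though they are
  phylogenetically clustered in the usual ecological sense.  The
  convention is explicit in `SesConventions(positive_is_clustered=...)`
  and can be flipped; quantitative work should interpret the signed
  `ses` column, not the label.

## Null model

The **independent swap** randomizes a presence/absence matrix by 2×2
checkerboard flips (`[[1,0],[0,1]] ↔ [[0,1],[1,0]]`), exactly
preserving row sums (plot richness) and column sums (species
occupancy).  The kernel samples two occupied cells uniformly and flips
when they form a checkerboard; this proposal is symmetric and the
resulting chain is uniform over the margin-preserving class (verified
by enumeration on small matrices in the test suite).  Each null
replicate is an independent chain burnt in from the observed matrix
with `10 × (number of presences)` successful swaps.  Matrices with no
swappable submatrix (e.g. all-ones) are returned unchanged with a flag.

## Beta diversity

- **TBD** = 1 − Sorenson = Dice dissimilarity on presences.
- **PBD** = 1 − PhyloSorenson: for plots 1 and 2 with spanning branch
  lengths BL₁, BL₂ and shared spanning length BL₁₂, similarity is
  `2·BL₁₂ / (BL₁ + BL₂)`.  Spanning paths include the stem to the root,
  consistent with rooted Faith PD (this matches picante's `phylosor`,
  cross-checked in the tests).
- **Null PBD**: each replicate swaps the whole presence matrix once and
  recomputes the full PBD matrix, so all plot pairs share the
  replicate's co-occurrence structure.  Reported per pair: null mean
  (expected PBD), deviation = observed − expected, and the
  `+1`-corrected quantile of the observed value in the null.

## Inference

- **NMDS**: non-metric SMACOF (scikit-learn) minimizing Kruskal's
  stress-1 with isotonic-regression disparities; `eps = 1e-6`,
  `max_iter = 500`.  Start 1 is classical (Torgerson) scaling of the
  input; remaining starts are random with per-start seeds drawn from a
  nested seed sequence, so raising `n_starts` at a fixed seed can only
  improve the best stress.  Output configurations are centred.
- **MRPP**: δ = Σ_g (n_g/N) · (mean within-group dissimilarity of group
  g); A = 1 − δ_obs/δ_exp; p = (#{δ_perm ≤ δ_obs} + 1)/(n_perm + 1)
  under random relabelings (999 by default), or exact enumeration of
  all label permutations for small instances.
- **Mantel**: Pearson correlation of lower-triangle entries; one-tailed
  (greater) p by simultaneous row/column permutation of the second
  matrix, `+1`-corrected; exact enumeration available.  No
  multiple-testing correction is applied across tests.
- **k-medoids** (PAM-style, greedy deterministic initialization)
  provides *provisional* district labels when the analyst supplies
  none; confirmed districts should come from the analyst.

## Endemism

- **WPE**(plot) = Σ over spanning edges e of λ_e / R_e, where R_e is
  the number of occupied spatial units (plots, or 0.5° grid cells when
  coordinates are given) of the clade under e.  WPE ≤ PD, with equality
  when every range is 1.
- **AED**_i = Σ over edges on species i's root path of λ_e / n_e, with
  n_e the plot abundance under e.  Identity: Σ_i n_i·AED_i = Faith PD
  exactly (enforced to 1e-9 in the acceptance tests).
- **IAC**: expected abundances split a plot's N evenly at every node of
  the plot-pruned tree (polytomies split 1/d); IAC = Σ_i |n_i − n̂_i|/v
  with v the number of nodes with ≥ 2 retained children.

## Spatial interpolation

Per-plot metrics are interpolated at 0.5°-cell centres (cells anchored
at integer multiples of the cell size, half-open, `floor(coord/size)`
indexing) by **Loess**: the `ceil(span·n)` nearest plots (Euclidean in
degrees; acceptable for windows of a few degrees near the equator) get
tricube weights `(1 − (d/d_max)³)³` and a weighted least-squares
degree-2 polynomial centred on the query; the intercept is the
prediction.  Centring makes predictions exactly translation-invariant.
Rank-deficient neighbourhoods (e.g. collinear plots) fall back to
degree 1 and then to the weighted mean, with the fallback recorded.
Cells outside the convex hull of the plots are flagged `extrapolated`.
Defaults: span 0.75, degree 2, ≥ 10 plots required.

## Synthetic landscapes

`SimulationConfig` defaults describe the intended study scale: 62
plots, 1,687 species, 3 districts, clade bias β = 0.9, N = 600 stems
per plot at Fisher's alpha 150, in the box 78–75° W, 5° S–0.5° N.

- The phylogeny is a **Yule** (pure-birth) tree grown lineage-by-
  lineage with exponential waiting times, rescaled to root age 100.
- Districts get preferred **deep clades** by cutting the tree at the
  shallowest level yielding enough subtrees (district d receives the
  d-th largest clade).
- Per plot, richness S comes from the target alpha via
  `S = α ln(1 + N/α)`; species are drawn from the preferred clade with
  probability β (clamped by clade size) and from the remainder
  otherwise; abundances are log-series draws whose mean matches N/S
  (the log-series parameter solved from its mean by Brent).
- Plots sit uniformly in district-specific latitudinal bands.
- All randomness flows from a single seed through spawned
  `SeedSequence`s; written bundles are byte-identical across reruns.

Realism limits: independent log-series draws only approximate a target
per-plot alpha (realized median within ~15% at the defaults); district
geography is a caricature (clean latitudinal bands, uniform scatter);
and the clade bias is binary (preferred clade vs everything else), so
between-district turnover is sharper than in real gradients.  None of
these idealizations are load-bearing for the correctness tests, which
are oracle- and invariant-based.

## Reproducibility

Every stochastic routine takes a seed; the pipeline and
`scripts/acceptance.py` derive one sub-seed per stage from the master
seed, so stages are independently reproducible and results are
byte-identical across reruns on the same inputs.
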