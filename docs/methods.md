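# Methods

## The measurement model

The package treats a colony as a planar marked point pattern: each traced
nucleus contributes a centroid (x, y) in µm, an area α in µm², and
optionally an outline polygon; the colony contributes a boundary polygon,
area A (mm²), perimeter P (mm) and imaging day.  Coordinates follow the
image convention (origin top-left, y down); only import touches pixels,
where lengths scale with the pixel size s (µm/px) and areas with s².  The
two magnifications supported by default correspond to s = 1.36 and
s = 0.67 µm/px.

"Neighbour" always means Delaunay neighbour.  The Voronoi diagram assigns
each nucleus the region of the colony closer to it than to any other
nucleus; the Delaunay triangulation joins nuclei whose regions share an
edge.  For the quasi-two-dimensional, tightly packed epithelium-like
colonies this analysis targets, Delaunay adjacency is a good proxy for
physical cell–cell contact.

Per-colony statistics are ⟨α⟩ with sample SD σ (n−1 denominator) and
standard error σ/√N_c, the mean neighbour count ⟨N_n⟩ = 2E/N_c, the
intercellular distance ⟨ℓ_n⟩, and the mean area per cell A/N_c.  ⟨ℓ_n⟩
is aggregated per cell first — each node's mean distance to its Delaunay
neighbours, then an unweighted mean over nodes — so that every cell
contributes equally regardless of its degree; an alternative mean over
unique edges is available (`aggregation="per_edge"`), and the two differ
slightly on irregular patterns.

## Boundary handling and edge pruning

Voronoi cells of peripheral nuclei are unbounded, so cells are clipped to
the colony boundary polygon when one is supplied, else to the convex hull.
Clipping is implemented with four distant ghost generators (making every
real region finite) followed by polygon intersection; the clipped cells
tile the clip region exactly, and this area conservation is tested to
1e−6 relative tolerance.

Neighbour statistics use the full Delaunay graph, hull cells included, so
that colony means cover all cells.  An `interior_only` option restricts
averages to bulk nodes, defined geometrically as nodes more than
1.1 × the median edge length inside the convex-hull boundary — i.e.
deeper than one cell row.  A vertex-of-the-hull definition is too weak:
lattice border nodes collinear with hull edges, and border nodes in
shallow concavities of a jagged colony edge, are not hull vertices yet
have incomplete neighbourhoods.  With the geometric definition, interior
nodes of a triangular lattice have exactly 6 neighbours at exactly the
lattice spacing, which the tests assert as integers/exact floats.

Delaunay triangulations of non-convex colonies bridge concavities with
long spurious edges.  The default prune policy removes edges longer than
3 × the median edge length; dense near-convex colonies are insensitive to
it (no edge approaches the cutoff), but two-clump stress tests are not.
`prune="none"` disables pruning, and is used wherever a test compares
against the brute-force empty-circumcircle oracle.

## The segregation order parameter

An area threshold α* splits cells into small type A (α < α*, boundary
inclusive on the B side) and large type B (α ≥ α*).  The order parameter

    δ = 1 − N_c·N_AB / (N_n·N_A·N_B)

uses N_AB = the number of Delaunay edges with one A and one B endpoint,
each mixed edge counted once (an A cell adjacent to several B cells is
counted once per adjacency).  With this counting the mixed-limit algebra
closes exactly: for any fixed split (N_A, N_B), a uniformly random
labelling gives E[N_AB] = 2·E·N_A·N_B/(N_c(N_c−1)) and hence
E[δ] = −1/(N_c−1), independent of both the graph and the split.  The test
suite verifies this identity by exhaustive enumeration of all labelings on
graphs with up to 12 nodes, and the mixed-limit acceptance check measures
it on a 2,500-cell lattice.  δ ≤ 1 always, with δ < 1 strict on connected
graphs; checkerboard-like arrangements give δ < 0.

The default threshold grid is 100–325 µm² in steps of 25 µm² (10 points),
spanning from just above the size of freshly divided nuclei (~150 µm²,
half of the ~300 µm² pre-division size) to clearly pre-mitotic sizes.
Thresholds where one class is empty yield missing values during sweeps;
a direct single-threshold call raises instead.  δ is most informative on
dense colonies; ⟨N_n⟩ ≤ 5 triggers an advisory log, not an error.

### Bootstrap null

The no-segregation reference is position-preserving: each replicate
permutes the observed areas uniformly at random across the fixed centroid
positions and recomputes δ(α*) on the unchanged graph.  This holds both
the geometry and the marginal area distribution fixed and randomises only
the spatial arrangement of sizes — precisely the hypothesis δ tests.
Sampling areas with replacement is available as `mode="resample"`.
Defaults: 1,000 replicates (minimum 100), band quantiles 2.5/50/97.5%,
one integer seed; fixed seeds give byte-identical profiles.

## Count–area scaling

N_c = κ·A^β is fitted by OLS of log10 N_c on log10 A, with κ = 10^intercept
and R² in log space; A is in mm², so κ is in cells/mm^(2β).  A nonlinear
least-squares fit in natural space is provided as an option — the two
estimators differ under heteroscedastic noise and neither is canonical.
Outlying colonies (e.g. partly differentiated ones with oversized nuclei)
are flagged by the Tukey rule, values outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR]
with linear-interpolation (type-7) quartiles; exclusion from the fit is the
caller's choice, default off.

## Shape descriptors

ImageJ's published formulas are adopted: circularity 4πA/P², roundness
4A/(π·major²), solidity A/A_hull, aspect ratio major/minor.  The fitted
ellipse comes from the second area moments of the polygon interior
(closed-form shoelace sums), not the vertex cloud — a w×h rectangle then
has axis ratio exactly w/h, which the tests assert.  The Feret diameter is
the exact maximum over convex-hull vertex pairs, not a rotating-step
approximation.  Bounded descriptors are clamped at 1 to absorb float
round-off; a zero-thickness outline reports aspect ratio +inf with a
warning rather than failing.

## The synthetic generator

`SyntheticSpec` defaults encode the observed regimes of dense pluripotent
colonies: 22 µm lattice spacing, i.e. one cell per ~419 µm² site and
≈2,400 cells/mm², inside the measured 1,800–2,600 cells/mm² range; a
lognormal nucleus-area field with mean 212 µm² and SD 104 µm² (mid-range
of the reported day-wise means 184–269 µm² and SDs 82–111 µm²); jitter
0.15 of the spacing.  Lognormal was chosen for positive support and the
right skew of observed area distributions (tails beyond 600 µm²).
Infeasible recipes (mean nucleus area exceeding the per-site area) raise a
generation error.

Spatial patterns of the small-cell class are produced by rank-matching:
areas are drawn first, and the smallest areas are assigned to positions
with the highest affinity score, where the score mixes a patch/gradient
field with uniform noise in proportion `cluster_strength`.  Strength 0 is
exact random mixing, strength 1 a deterministic arrangement, and mean δ
is strictly increasing in between (property-tested over seeds).  Because
only the assignment, not the draw, depends on the pattern, the marginal
area distribution is identical across patterns.

What the generator does **not** emulate: cell motility and colony drift,
mitotic doublets (paired half-size nuclei in contact), the gaps between
cells seen in small colonies, boundary fencing effects, and day-to-day
growth dynamics.  Passing tests therefore demonstrate correctness of the
measurement pipeline on patterns with known structure, not biological
fidelity of any particular colony.

`generate_colony_series` produces (A, N_c) pairs with A log-uniform,
N_c = round(κ·A^β·10^ε), ε ~ N(0, noise_sd in log10 units); rounding can
be disabled for closed-form checks of the fitting stage.

## Numerical and interface choices

- The tabulated Area column is authoritative when an outline disagrees
  (tracing software rounds); discrepancies above 1% are logged.
- Mitotic cells are retained by default — their inflated areas are part
  of the measured variability — with an exclusion flag.
- Co-circular point quartets (e.g. the four corners of a square) admit two
  valid triangulations; the underlying triangulator's symbolic
  perturbation picks one deterministically, and tests compare against the
  oracle's admissible-edge superset in that case.
- Degenerate inputs raise typed errors: collinear point sets and zero-area
  polygons are degenerate-geometry errors, self-intersections and
  duplicate points validation errors (with the offending indices), empty
  label classes an undefined-statistic error.
- Graphs are stored as canonical lexicographically sorted (i < j) edge
  arrays, so equal graphs are array-equal and runs are deterministic.

## Problem sizes

The validation suite works at desk scale: lattice colonies of 400–2,500
cells (the mixed-limit average uses a 50×50 lattice and 200 relabelings),
segregated-limit fields up to 10,000 cells, brute-force oracle
cross-checks on ≥100 random instances of up to 60 points, exhaustive
labelling enumeration up to 12 nodes, and 200-replicate recovery studies
for the scaling exponent.  The full suite runs in well under a minute on
one core.

## Limitations

Headline numbers from any particular culture (day-wise ⟨α⟩, fitted κ and
β, δ profiles of individual colonies) depend on the data and are not
reproduced here; the package validates the machinery against analytic
limits, closed forms and independent brute-force oracles instead.  The
segregation statistic assumes a single connected colony; pruning can
disconnect pathological configurations, in which case isolated nodes are
excluded from distance averages and logged.  All analysis is strictly
two-dimensional.
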