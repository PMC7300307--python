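# Methods

## Alpha filtration

A snapshot is an ordered 3-D point cloud (&Aring;).  Its Delaunay
tetrahedralization is computed with Qhull (via `scipy.spatial.Delaunay`)
and every simplex receives an alpha filtration value on the *radius*
scale: a tetrahedron's value is its circumradius; a triangle or edge
keeps its own circumradius if its circumscribing sphere is empty of the
opposite vertices of its cofaces (the Gabriel condition), and otherwise
inherits the minimum value over the cofaces that carry it in.  Values
are computed as squared radii internally and exposed as radii, so
births, deaths and the reduced coordinates h all share the &Aring;
length scale of the input.  Exposing radii rather than squared radii is
a deliberate convention choice; absolute agreement of h magnitudes with
analyses made under the squared-radius convention is not expected.

The filtration order sorts by (alpha, dimension, lexicographic vertex
tuple), which guarantees faces precede cofaces and makes every
downstream computation bit-reproducible.  Small clouds (n &le; 3) are
handled directly (their Delaunay complex is the full simplex on the
points).  Degenerate configurations — coplanar, cocircular or
cospherical point sets that Qhull rejects or triangulates incompletely —
are resolved by adding a deterministic Gaussian jitter of magnitude
1e-9 &Aring; seeded from a CRC-32 hash of the coordinate bytes
(escalating tenfold per retry, at most four attempts); each event is
logged.  Identical input bytes therefore always yield the identical
complex.  Exactly duplicate (or < 1e-9 &Aring; separated) points are an
error.

## Persistence and volume-optimal cycles

Degree-1 pairs come from the standard mod-2 boundary-matrix column
reduction restricted to the edge/triangle block, with columns stored as
integer bitmasks.  Pairs with birth = death are dropped; tiny positive
lifetimes are kept.  The first Betti number at radius r counts pairs
with b &le; r < d (closed at birth, open at death — the convention is
fixed here because the prose definition does not decide strictness).

A pair's optimal volume minimizes the *count* of triangles V subject
to: the death triangle is in V, all other triangles of V precede it in
the filtration, and the mod-2 boundary of V contains the birth edge and
no edge later than it.  Two exact solvers are provided:

* exhaustive enumeration by increasing chain size (default for &le; 20
  candidate triangles), which returns the lexicographically smallest
  optimum;
* a 0/1 integer program in which each constrained edge's parity is
  encoded as (sum of incident triangle indicators) &minus; 2&middot;slack
  = 0 (or 1 for the birth edge), solved with HiGHS through
  `scipy.optimize.milp`.  Ties among equal-size optima are broken by a
  cardinality-preserving index-sum perturbation of the objective
  (coefficients 1 + &epsilon;&middot;rank with
  &epsilon; = 0.5/(m&sup2;+1)), which is deterministic; it prefers
  early-filtration triangles but is not guaranteed to equal the
  exhaustive solver's lexicographic rule when several optima exist.
  Such ties require non-generic geometry and do not arise in the
  package's fixtures.

The optimum *size* is unique and both solvers agree on it (tested
against independent exhaustive search).  Triangles are never weighted
by alpha: minimality is by count.

## TFV and comparison features

The slot layout is slot(i,j) = i&middot;n &minus; i(i+1)/2 + (j&minus;i&minus;1),
0-based, i < j; it is recorded in every output header and shared by the
flattened contact map.  The default edge weight is the generator's
death; birth and lifetime are options (death &ge; birth elementwise for
the same generators).  Comparison features: binary contact maps with a
*strict* < threshold (default 8 &Aring;), flattened 3n Cartesian vectors
with optional least-squares rigid superposition onto a reference
(Kabsch; enabled by passing a reference, since raw coordinates are
translation-dominated — whether to align is genuinely open, so it is a
caller choice), full distance maps, and the accumulated bar length
(sum of lifetimes).

## NMF, rank selection, PCA

NMF minimizes the Frobenius residual with scikit-learn's coordinate
descent, NNDSVD initialization in the zero-preserving variant, relative
tolerance 1e-4 and at most 200 sweeps — fully deterministic, no random
restarts.  After convergence each basis column is rescaled to unit
Euclidean norm with the inverse factor absorbed into the corresponding
H row; WH is unchanged (relative error < 1e-12), the bases become
dimensionless and h carries &Aring; units.  RSS is the squared Frobenius
norm of the residual.  The rank scan subsamples columns without
replacement (default 1000, seeded), fits L = 1..L_max (default 10), and
selects the interior rank maximizing the discrete second difference of
RSS — the inflection of the curve, which is linear for structureless
data.  The full curve is always returned for manual override.  PCA
uses a full SVD on mean-centered data with each component's sign fixed
so its largest-magnitude loading is positive (signs are otherwise
arbitrary and would break regression tests).  The basis report lists
edges with weight > 0.2 per basis; a basis is named by its top
non-backbone edge (sequence separation &ge; 2).

## Flow field and fixed points

Displacements &delta;h(t) = h(t+&delta;t) &minus; h(t) are attributed to
the grid cell containing the *source* frame (origin at 0, default cell
1.5 &Aring;) and averaged; cells with fewer than `min_count` samples
(default 10) are masked, because unaveraged single-sample cells are
noise.  Candidate fixed points are unmasked local minima of the
mean-flow magnitude.  Around each candidate an affine map
&delta;h &asymp; J(x&minus;c) + r is fitted over the unmasked 5&times;5
neighborhood by inverse-variance weighted least squares (weights from
per-cell standard errors of the mean).  A candidate is classified
stable (both eigenvalue real parts negative) or saddle (mixed signs)
only if each deciding eigenvalue clears both an absolute tolerance of
0.02 per step and three times its own sampling standard error, and only
if the fitted map's zero lies within 1.5 cells of the candidate — a
distant zero marks a valley of weak flow, not a fixed point.  The
reported location is that zero.  Same-kind candidates closer than two
cells are merged, keeping the weaker flow.  Everything else is reported
as unclassified; an isotropic random walk therefore yields candidates
but no classifications.  One caveat: *reflecting boundaries* induce a
genuine inward drift layer roughly one step-deviation wide, whose
zero-line a classifier may legitimately flag; conclusions about
boundary-adjacent fixed points should be drawn with care.

## Synthetic generator

The trajectory generator emulates a 10-residue hairpin miniprotein
near its folding transition, as phenomenology rather than physics:

* **states** — native closes contact (1, 8) (0-based; the residue-2-to-
  residue-9 loop of the real hairpin), misfolded closes (1, 7), and an
  unfolded state is an extended gently curving chain that closes no
  loop.  Hairpin templates place the loop beads on a closed polygon
  (bond length 3.8 &Aring;, contact chord 5.0 &Aring;) with an
  alternating &plusmn;0.3 &Aring; out-of-plane pucker, and extend the
  tails radially; state switching is a discrete Markov chain.
* **dwell means** — 50 frames per state, so the default 2000-frame run
  crosses states ~40 times; runs much longer than the mixing time are
  the precondition for a meaningful state-recovery experiment (with
  long dwells a short run can leave a state unsampled, and a rank-2
  factorization then spends its second basis on the native state's
  secondary end-to-end tail loop instead).
* **noise** — isotropic Gaussian, default &sigma; = 0.2 &Aring; per
  coordinate (bond-length sd &radic;2&sigma;); frame interval 10 ps.
* **seeding** — mandatory; identical specs give identical frames.

What the generator does *not* emulate: force-field energetics, water,
temperature, realistic transition paths (switches are instantaneous),
sequence effects, or the slow diffusive exploration of a real unfolded
ensemble.  Passing the recovery tests therefore shows the pipeline
identifies planted loop states under coordinate noise — not that it
resolves the thermodynamics of any real peptide.

The double-well generator plants reduced-space dynamics directly:
Langevin steps in a potential quartic along the inter-well axis (wells
at (20, 5) and (5, 20) &Aring;, barrier curvature 0.1 per step at the
midpoint saddle), harmonic transverse (0.15 per step), noise 1.5
&Aring;/step, reflected at the axes, 120,000 frames.  These defaults
put a few hundred samples per 1.5 &Aring; cell near the saddle so the
flow there is measurable while barrier crossings remain frequent.

The six-point worked-example cloud places five points on a circle
(chords 4.6, 4.6, 4.6, 4.6 and 4.0 &Aring;) and a sixth point 2.8
&Aring; outside the short chord, with a small deterministic z-offset
against coplanarity: a small three-edge loop is born at 2.0 &Aring;
and dies at 2.11 &Aring;, then the pentagonal loop born at 2.3 &Aring;
has a minimal volume of exactly 3 triangles bounded by 5 edges (the
6-edge alternative through the sixth point would need 4).

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
data at desk scale: 2000-frame trajectories of 10 beads for the
end-to-end study, 50 random 5&ndash;10-point clouds &times; 20 radii
for the Betti oracle, ~30 generators on 7&ndash;9-point clouds for
volume minimality, and 120,000 2-D steps for the flow study.  The full
suite runs in well under a minute on one CPU; the acceptance script in
~15 s.

## Limitations

Degree-0 and degree-2 persistence, Vietoris&ndash;Rips filtrations and
non-mod-2 coefficients are out of scope.  The TFV cost grows with the
Delaunay complex, so all-atom featurization of large molecules is
impractical (the intended input is a coarse chain such as the C&alpha;
trace).  The ILP tie-break caveat above applies only to degenerate
geometries.  Readers are provided for multi-model PDB and multi-frame
XYZ only; convert other trajectory formats externally.
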