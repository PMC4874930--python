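# Methods

This note records the model implemented by `petseg`, the choices made where
the design was genuinely open, and what the synthetic experiments do and do
not demonstrate.

## Segmentation model

A lesion boundary is modeled as a star-shaped closed surface around a seed
center `ce_k`: one sample node chosen per radial column. Columns point along
the vertices of a recursively subdivided octahedron projected to the unit
sphere (level 4: 1026 directions, the only standard subdivision family whose
vertex count `4·4^k + 2` matches the method's operating point; an icosphere
would give 642 or 2562). Nodes sit at radii `gap·(j+1)`, j = 0…59, so the
innermost node is one gap from the center and the outermost at r = 60 mm.
There is deliberately no node at the center: a zero-radius "surface" is not a
boundary.

The discrete objective is the sum of per-node costs plus `sp·|Δj|` per
adjacent column pair, under the hard constraint `|Δj| ≤ sc`. Defaults
(r = 60 mm, gap = 1 mm, sc = 5, sp = 0.005) are the method's published
operating point for head-and-neck lesions; `sc` bounds how fast the radius
may change between neighboring directions (5 mm per ~7° at level 4), and the
small `sp` biases toward smooth surfaces without fighting genuine shape.

### Solver

The optimum is found exactly by the closure/min-cut transform of optimal
surface finding: per-node closure weights are the along-column cost
differences `c[i,j] − c[i,j−1]` (base nodes get a large negative weight so
every column is occupied), intracolumn and hard-constraint arcs carry
effectively infinite capacity, soft-constraint arcs carry `sp`, and the
minimum s–t cut is computed with igraph's max-flow. Because weights are cost
*differences*, negative node costs — which refinement notches create — need
no shifting; all capacities remain non-negative by construction.

Among co-optimal surfaces the solver returns the *minimal closed set* (the
source side reachable in the residual network). Optimal closed sets are
closed under intersection, so this solution is pointwise minimal in every
column level simultaneously — equivalently the lexicographically smallest
optimum — giving bit-reproducible results without tie-breaking noise.
`resolve_with_updates` re-solves from scratch; warm-starting would be a
performance optimization with identical semantics, and a full solve of the
default graph (61 560 nodes, ~0.9 M arcs) takes on the order of a second.

The test suite checks exactness against four independent routes: true
brute-force enumeration (6 columns × 4 levels), min-sum variable elimination,
a one-hot MILP, and a threshold/level-set LP whose constraint matrix is
totally unimodular (LP optimum = integer optimum). The LP route is the one
used at scale (18 columns × 8 levels, 200 random fields); the others validate
it on the enumerable graphs.

## Shell statistics and adaptive threshold

Shell `Ω_j` is the set of nodes at level j; its median uptake `up_Ω(j)` is a
robust radial profile. Landmarks:

- `pe`: maximum shell median (interior shells only — the innermost and
  outermost shells are extreme solutions and excluded from all scans);
- `j_low`: argmin of the center-bias-weighted central difference
  `((n_node−(j+1))/n_node)·up′_Ω(j)` — the steepest descent, with the linear
  weight guarding against outside objects appearing far out in the profile;
- `ũp′_Ω`: the gradient made non-decreasing beyond `j_low` (running maximum),
  so later dips from unrelated structures cannot masquerade as the edge;
- `j_hi`: first level where `ũp′_Ω` reaches `min(0, its maximum)`;
- `j_knee`: where `ũp′_Ω` is closest to `0.75·ũp′_Ω(j_hi) + 0.25·ũp′_Ω(j_low)`,
  i.e. where the descent has recovered 75 % of the way to flat; `kn = up_Ω(j_knee)`.

All argmin/argmax ties take the smallest index, for determinism. A profile
whose total range is below `1e−9` of its scale carries no boundary evidence
and raises a degenerate-profile error (pure-background seeds fail loudly
rather than segmenting float dust). A non-positive knee (possible on
noise-free zero background) is clamped to `1e−6` to keep γ finite.

`Th = kn + Th%·(pe − kn)` with `Th% = 0.8·exp(−0.15·γ^1.5)` is strictly
decreasing in γ with range (0, 0.8]: contrast-2 lesions get ≈ 52 %,
high-contrast lesions proportionally less, emulating margin-conscious expert
tracing. Fixed 40 %/50 % variants are interpreted on the same `(kn, pe)`
scale. The landmark pipeline is scale-invariant: multiplying the volume by
s > 0 scales `pe`, `kn`, `Th` by s and leaves all indices and γ unchanged.

Note on knee geometry: for a PSF-blurred sphere the knee sits where the
profile levels off, i.e. ~1.7 σ_PSF *outside* the true radius (+3 mm at
FWHM 4, +5 mm at FWHM 7). This is the definition working as intended, not an
estimation error; the parameter-recovery test therefore pins the ±3-gap band
at FWHM 4 mm.

## Cost field

Above `Th` the base cost rises linearly from 0 (at `Th`) to 1 (at the center
uptake); below `Th` it equals the right-to-left monotone envelope `H̃` of the
normalized uptake histogram of the search sphere — the likeliness of the
value being background. The histogram uses 100 uniform bins on [0, regional
max] over a 1 mm isotropic resampling of the sphere (matching `gap`; the
paper-level description fixes neither count nor resolution). The regional
median for the rejection term uses the same sample set. An uptake within
`1e−12` of `Th` takes the exact-zero branch.

Rejection adds `rej = 6` — far above the 0–1 base range — for `j < j_min = 3`
(trivial shrinkage) and, past `j_min`, wherever the running minimum of the
column's uptake has fallen below the regional median (the surface may not
re-emerge beyond background or a cold gap). The running minimum includes the
current level, so rejection starts at the first dipping node itself and is
monotone outward.

On *noise-free* synthetic backgrounds both guards weaken: the background
histogram collapses into a single spike bin, so `H̃` is near zero between
background and `Th`, and a noiseless background never dips below the regional
median. The boundary then rests at the threshold crossing but may admit ~1–2
extra gaps of sub-threshold margin. Real PET backgrounds are broad-histogram
and noisy, which is the regime the envelope and median tests were designed
for — phantom results therefore bound the geometry machinery, not the cost
function's discrimination on clinical data.

## Refinement

Global: `Th ← up(R_Th)` (must be below the center uptake), the column nearest
the point gets cost 1000 everywhere except the node nearest the point, and
the whole problem is re-solved. Repeats override previous global settings.

Local: the nearest node `(i_Lp, j_Lp)` is pinned the same way; a BFS over
column adjacency (geodesic ds ≤ 5) collects columns whose uptake pattern in a
±3-level window matches the anchor's (L1 distance below 5 % of the
candidate's own window norm, candidate levels limited to `|j − j_Lp| ≤ ds`).
Holes left by the similarity test are closed when ≥ 2/3 of a column's mesh
neighbors matched. Matched columns receive a triangular notch
`−3·max(0, 1 − |j − j̃|/(ds+1))`: full depth 3 at the matched level, support
widening with graph distance — certainty near the click, latitude further
away. The ±3 window clamps at column ends. Columns already pinned by a user
point never have their costs changed again. Anchoring uses the constant 1000,
orders of magnitude above any achievable objective on default graphs, so
anchored levels always win; the suite asserts this rather than assuming it.

Undo restores the pre-action threshold, cost deltas and solution snapshot
bit-exactly; replaying a serialized action log reproduces levels exactly.

## Modes

- **Label avoidance**: walking outward, the first node inside a voxel of a
  different nonzero label starts a permanent `+rej` tail on that column.
- **Splitting**: voxels below `Th` are discarded; marker-based watershed on
  the inverted uptake separates the remainder. Markers are local maxima of
  the 3 mm-smoothed volume ("strong") and of the raw volume ("weak"); nodes
  in basins not containing the seed get `+rej` and `+rej/2` respectively, so
  the strong partition dominates and the weak one biases. The smoothing
  scale, marker rules and the two penalty magnitudes are this package's
  reconstruction of behavior that is only described qualitatively at the
  source; they are stated here so they can be revisited.
- **Necrotic mode**: disables recentering (the hottest voxel is on the rim)
  and the running-minimum rejection (which misfires inside the cold core),
  keeping the inner-level rejection. Because a cold center cannot normalize
  the foreground cost, necrotic mode also substitutes `max(up(ce_k), pe)` for
  the center uptake in the linear branch; for hot-cored lesions this changes
  nothing.

## Voxelization

The deformed mesh is star-shaped by construction, so voxel membership is
radial: find the spherical triangle containing the voxel's direction (the
cone of a triangle's deformed vertices equals the cone of its unit
directions, positive radial scaling preserving cones), intersect the ray with
the deformed triangle's plane, and compare distances with an inclusive
`1e−6` mm tolerance — a voxel center exactly on the surface is inside.
Cleanup keeps the 6-connected component containing the seed; multi-seed
results merge with logical OR; optional gap closing fills one-voxel gaps per
label (cross-structured closing, erosion border treated as foreground so
volume edges do not unfill) and never bridges different labels.

## Phantoms

The generator emulates what drives this method's statistics: spheres or
ellipsoids of configurable radius and uptake on a uniform background,
optional cold cores, Gaussian PSF blur (FWHM 5–7 mm as in clinical OSEM
reconstructions; σ = FWHM/2.3548), optional additive Gaussian noise (Poisson
resampling available, not default), on a 96³ grid at 2 mm spacing with
background 1.0 and lesion peaks 4–8. Ground truth is the pre-blur mask, one
label per lesion; overlapping truths with distinct labels are an error.
Lesion centers snap to voxel centers so "seed at the center" carries no
sub-voxel offset. The two-lesion scene takes a center-to-center separation;
its default radius `min(5, 0.45·separation)` guarantees non-overlapping
truths at any separation.

Not emulated: scanner forward projection and reconstruction artifacts,
anatomical background heterogeneity, respiratory motion. Passing phantom
tests validates geometry, statistics and optimization — not clinical
accuracy.

## Problem sizes used in tests

The acceptance checks run one full-size solve (1026 × 60 nodes) for boundary
recovery; all other pipeline tests use a reduced graph (258 columns × 30
nodes, r = 30 mm) and solver stress tests use 18 × 8 graphs where exhaustive
or LP verification is feasible. These sizes are the package's choice of
smallest configurations that still exercise every code path (multi-ring
adjacency, BFS radii, rejection tails).

## Known limitations

- The adaptive threshold intentionally places the boundary outside the 50 %
  partial-volume contour: on a 4:1-contrast blurred sphere the recovered
  radius is ~1 mm beyond the pre-blur truth (Dice ≈ 0.82 vs 0.976 for the
  fixed-50 % mode). Against expert-consensus references this margin is the
  desired behavior; against geometric truth it reads as over-segmentation.
- Star-shaped topology: one surface crossing per ray from the seed. Strongly
  non-convex lesions need multiple seeds and OR-merging.
- Oblique (non-axis-aligned) volumes are rejected rather than resampled.
- The splitting and label-sealing behaviors beyond first-contact rejection
  are reconstructions (see Modes) and deliberately conservative.
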