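# Methods

This note documents the models implemented in growlite, the parameters that
matter, the synthetic benchmarks, and the design choices made where the
design was genuinely open.

## Problem setting

Fragment growing extends a crystallographically observed core ligand by one
new single bond into an adjacent sub-pocket. The core's coordinates are
trusted; the task is to choose a fragment and its pose. All structures —
binding sites, cores, references, ensemble members — are assumed to sit in
one pre-aligned frame; the package never superposes anything. Protonation
states are taken as given (no assignment is attempted).

## Shape descriptor

Pose generation rests on a ray-length description that is symmetric between
pockets and fragments, cast from the core's attachment point:

- **Directions.** `n_rays` (default 128) unit vectors on a deterministic
  Fibonacci sphere. A single-origin direction fan is used; the direction set
  is injectable everywhere, so a multi-origin / multi-shell variant can
  replace it behind the same interface.
- **Pocket rays** stop at the first receptor heavy-atom vdW surface
  (analytic ray–sphere intersection; waters are stripped first), capped at
  `max_range` (10 Å). An empty neighbourhood yields an all-max "open pocket"
  descriptor with a warning.
- **Fragment rays** report the last exit from the posed fragment's vdW
  volume (0 when the ray misses the fragment).

Two descriptors over the same directions are compared as
`filled = Σ min(f, p)` (an interior-coverage proxy for filled volume) and
`clash = Σ max(0, f − p − τ)` with clash tolerance `τ = 0.75 Å`. The combined
pose score is `filled − w_clash·clash + w_contact·contacts` with
`w_clash = 3`, `w_contact = 0.3`, and `contacts` the number of
fragment–receptor heavy-atom pairs at 3.2–4.0 Å. The tolerance is generous
on purpose: pose generation should survive minor steric friction and leave
repairs to the restrained optimizer. The descriptor is purely steric and
carries no electrostatic information; directing polar contacts is the job of
search points.

Correctness is checked against an independent dense-marching oracle (0.01 Å
steps along each ray): agreement is ≤ 0.02 Å on 20 seeded random fixtures,
plus analytic single-sphere and closed-cavity cases.

## Pose enumeration

The fragment-side attachment atom is the lowest-index heavy atom with an
open valence (an explicit hydrogen or missing valence); a different atom can
be named explicitly. The new bond takes the covalent-radii sum as its
length. If the attachment geometry is defined by an explicit hydrogen, the
former X–H direction is reused; otherwise an idealized direction is built
from the remaining bonds, and a junction with a single heavy neighbour is
tilted to the idealized tetrahedral (109.47°, saturated) or trigonal (120°,
unsaturated) angle — the torsion scan sweeps the azimuth, so only the angle
matters. Torsions about the new bond are sampled every 30°; fragments
supplied as a single conformer additionally get a coarse 120° scan of up to
two acyclic internal torsions. Near-duplicates are merged at 0.1 Å
fragment-heavy-atom RMSD and enumeration is capped at 600 poses per
fragment. Duplicate detection uses heavy atoms only, so a methyl (one heavy
atom on the torsion axis) collapses to a single pose.

Hard filters before scoring: any fragment–receptor heavy-atom pair whose vdW
penetration fraction `(r₁+r₂−d)/(r₁+r₂)` exceeds 60 % rejects the pose (the
same rule that detects water displacement, for internal consistency); if
search points are given, every point must be matched. One best pose per
fragment enters the hit list (`top_k` configurable), sorted by combined
score with lexicographic fragment-id tie-breaks. The whole pipeline is
deterministic: no randomness is used anywhere in growing.

## Search points

A search point is a typed constraint — donor, acceptor or hydrophobic — with
a position and tolerance radius (default 2.0 Å), placed on the ligand side
of the interaction. Generation from a posed ligand:

- **Donor:** ligand N/O bearing ≥ 1 H whose heavy-atom distance to a
  receptor N/O lies in [2.5, 3.5] Å with a D–H⋯A angle ≥ 120° (explicit
  hydrogens when present, an idealized H direction otherwise).
- **Acceptor:** ligand N/O with an available lone pair (any uncharged O; N
  only when it carries no hydrogen, so pyrrole-type NH stays donor-only)
  near a receptor nitrogen. PDB receptors carry neither bonds nor reliable
  protons, so the receptor side of an acceptor interaction is
  distance-gated only.
- **Hydrophobic:** centroids of fully hydrophobic rings (all ring atoms C/S,
  no polar substituent) and terminal hydrophobic heavy atoms, with a
  receptor C/S at 3.5–4.5 Å. A permissive mode (every apolar C/S atom) is
  available but the restrictive definition is the validation-grade default,
  since permissive hydrophobic features otherwise dominate the point counts.

The hydrogen-bond windows are fixed config defaults; the literature
geometries they approximate are not reproduced numerically here, which is a
known citation gap. Two points of the same type within 2 Å of each other are
treated as the same interaction: that radius defines both cross-structure
*stability* (greedy one-to-one nearest matching, symmetric in matched
cardinality) and *maintenance* (a grown pose regenerates an input point
within 2 Å). Matching of poses against query points requires **all** points
to be satisfied; best-effort partial matching is deliberately not offered.

Water replacement: a water whose maximal vdW overlap with a ligand heavy
atom exceeds 60 % is considered displaced. It emits donor, acceptor and
dummy hydrophobic points at its oxygen; only points corroborated by a
same-type ligand-derived point within 2 Å survive, and displaced waters are
removed from the site used for growing. The overlap metric is the linear
penetration fraction by default; a sphere-intersection-volume alternative
sits behind `overlap_metric` for sensitivity checks.

## Restrained optimization

The energy is a small empirical interaction score in the ChemScore/PLANTS
tradition, with analytic gradients (verified against central finite
differences at 1e-5):

| term | form | default |
|---|---|---|
| clash | `w·pen²` per heavy pair, `pen = max(0, r₁+r₂−d)` | w = 5 |
| H-bond | `−w·exp(−(d−2.9)²/2·0.4²)·g(θ)` | w = 2 |
| hydrophobic | `−w·exp(−(d−3.9)²/2·0.6²)` per C/S pair | w = 0.05 |
| bond maintenance | `w·(d−d₀)²` per covalent bond | w = 50 |
| core restraint | `k·max(0, |x−x₀|−0.5)²` per core atom | k = 10 |

`g(θ)` ramps from 0 at a 120° D–H⋯A angle to 1 at 180° when the donor has an
explicit hydrogen, and is 1 otherwise. The hydrophobic well is shallow by
design: tens of receptor neighbours contribute per atom in a closed pocket,
and the cumulative pull must stay well inside the restraint's elastic range
so that the restrained-core contract (free movement up to 0.5 Å, quadratic
penalty beyond, per atom) governs. The bond-maintenance term is required
because optimization is plain per-atom Cartesian descent; without it the
interaction wells would stretch covalent bonds. Angle/torsion strain and
electrostatics are deliberately absent.

The optimizer is first-order steepest descent with the step scaled so no
atom moves more than `max_step = 0.1 Å` per iteration, step halving (≤ 10×)
on any energy increase, and convergence at |ΔE| < 1e-4 or 500 iterations.
Energy is non-increasing over accepted steps and the receptor never moves.
The limited step keeps the optimization stable and deterministic; no line
search or momentum is used. Across the planted-case suite the
95th-percentile core RMSD after optimization is ≈ 0.16 Å, comfortably inside
the 0.6 Å contract (flat bottom plus a small elastic excursion).

The restraint threshold (0.5 Å flat bottom), the limited-step philosophy and
the rigid receptor are fixed behavioral anchors of the workflow; every well
depth and width is this package's own parameterization and is exposed on
`EnergyModel`. The restraint is applied per core atom; a centroid variant
would admit rigid drift of the core and was rejected.

## Ensemble screening

2–5 pre-aligned binding-site conformations (two is the minimum that makes an
ensemble, five the cap) are screened independently and each fragment keeps
the single best-scoring pose across members, tagged with the member's
frame id; ties resolve to the lexicographically smallest frame id. A
fragment survives the ensemble iff it survives in at least one member, so
the ensemble hit set is exactly the union of the member hit sets and the
ensemble score is exactly the member maximum — both are enforced as exact
properties in the tests. Scores are not normalized across members.
Selecting and aligning the ensemble members is upstream of this package.

## Validation machinery

- **Cross-growing cases.** Two aligned complexes form a case iff ligand B
  equals ligand A plus exactly one connected substituent attached through
  one acyclic single bond (exact element- and bond-order-aware graph
  matching, limited to 40 heavy atoms; ring fusions, multi-substituent
  differences and non-growing pairs are rejected with coded reasons). The
  core is posed from A; B's pose is held out as reference.
- **Fragment RMSD** is computed in place over fragment heavy atoms,
  minimized over all graph automorphisms so symmetric fragments (e.g. a
  flipped para-substituted ring) are not spuriously penalized.
- **Success statistics.** Success is RMSD < 2.0 Å. Rates carry 95 %
  confidence half-widths from the normal approximation to the binomial,
  `1.96·√(p(1−p)/n)`. Recomputing from the published (rate, n) pairs
  reproduces ten of the published half-widths to 0.1 percentage points; one
  published value (28.6 ± 19.4 %, n = 21) recomputes to ±19.3 and is
  excluded from the frozen set.
- **Enrichment.** AUC is the normalized Mann–Whitney rank statistic with
  mid-ranks on ties (equal to brute-force pair counting, which the tests
  enforce); confidence intervals are percentile intervals over 1000
  stratified bootstrap replicates (actives and decoys resampled separately,
  seeded). Baselines: descending molecular weight, and decoys
  property-matched to actives by greedy nearest-neighbour in z-scored
  Rule-of-Three space (MW, donors, acceptors, cLogP, rotatable bonds, TPSA
  via RDKit).

## Synthetic benchmarks

The fixture generator builds closed cavities from quasi-uniform shells of
wall atoms (spherical, two-lobe, channel), plants cross-growing cases by
carving a cavity (wall standoff 3.5 Å) around one exactly-representable pose
of a built-in fragment chosen by the seed, and assembles labeled screening
libraries whose actives fit the carved channel while decoys are branched or
truncated shapes with similar Rule-of-Three properties. Everything is a
pure function of the seed, byte-identical across runs.

These fixtures emulate the *structure* of a growing validation — recoverable
planted poses, a 2 Å success criterion, labeled enrichment — at desk scale:
25 planted recovery cases, 12 optimization cases, 10 two-member ensembles
and a 48-fragment screening library, all running in seconds. They are
geometric, not chemical: walls are isolated carbon spheres without secondary
structure, fragments are idealized alkane/ether/amine chains, pockets hug
the answer by construction, and reference noise is isotropic Gaussian.
Passing them demonstrates the internal consistency and geometric correctness
of the machinery, not pose-prediction accuracy on real proteins; published
large-scale success rates on crystallographic cross-growing sets are not
reproducible from synthetic data, which is why the statistics layer is
validated by exact arithmetic instead.

## Degenerate inputs and tie-breaks

Empty fragment libraries and single-class enrichment labels are errors;
all-fragments-filtered is a warning with an empty hit list. Unknown elements
fall back to a 1.70 Å vdW radius with a logged warning. Hit-list ties break
on fragment id, ensemble ties on frame id. A saturated attachment atom is a
valence error. Non-finite starting energy returns the pose unmodified with
an error flag. vdW radii come from a fixed element table (C 1.70, N 1.55,
O 1.52, S 1.80, H 1.09, P 1.80 Å) so every geometric quantity is
reproducible.

## Known limitations

- Receptor perception is minimal: no bond orders, no protons, no residue
  chemistry beyond element identity; acceptor-type search points are
  therefore distance-gated on the receptor side.
- The energy model is a didactic stand-in for a production scoring
  function: no electrostatics, torsional strain or desolvation, and its
  absolute values are not calibrated to affinity.
- Conformer handling is torsion-grid based; ring conformers and concerted
  internal motions are not sampled.
- The MCS-based case builder requires ligand A to *be* the common core
  (the transferred-core construction); trimming a differing substituent
  from A is out of scope.
- mmCIF input, protonation assignment and binding-site alignment are out of
  scope by design.
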