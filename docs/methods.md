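# Methods

## Model

A motif's helices are rigid A-form duplexes; its loops are flexible
coarse-grained chains.  The conformational freedom of the motif is reduced
to the rigid-body placement of the helices, and a placement is *allowed*
when every loop of interest can close between its two helix anchors
without steric overlap.  The fraction of allowed placements,
`F_x = N_x / N_tot`, measures the topological constraint exerted by loop
subset `x`; the full subsets give `F_PK` (loops 1–3) and `F_KISS` (loops
1–6).

### Helix model

Idealized A-form geometry with rise 2.81 Å and twist 32.7°/bp, carried at
two beads per nucleotide (P at 8.7 Å radius, C4′ at 9.2 Å radius).  The
two C4′ beads of a base pair are placed diametrically so the pair's
geometric center lies exactly on the helix axis — a deliberate
simplification of the asymmetric A-form cross-section that makes the
base-pair frame exact (center spacing = rise, frame twist = twist) at bead
resolution.  The base-pair "geometric center" is defined as the mean of
the two C4′ beads (an alternative — all heavy atoms — would shift centers
by ~1 Å and all counts with them).  Base-pair frames store z along the
helix axis in the 5′→3′ direction of the reference strand, so transforms
between frames of one helix compose per-step twists.  All helix
parameters are pinned in `RunConfig`; changing them changes every `N_x`.

### Rigid-body configurations

A configuration is (θ, φ, α, dx, dy, dz): rotation of the mobile helix
about the axis (θ, φ) through its interface base-pair center by α,
followed by translation of that center to a grid point.  Parameter
extraction from a pair of frames is canonicalized by requiring
cos θ ≥ 0 (with α → 2π − α under axis negation) and θ = φ = 0 at the
identity, making extraction unique and round-trippable to 1e-9 over
random transforms.

Rotation axes come from a deterministic spherical Fibonacci lattice — no
seed, so exhaustive enumerations are exactly reproducible.  At n = 100
the nearest-neighbor spacing has coefficient of variation ≈ 0.02 and the
vector mean has norm < 0.001.  Rotation angles are uniform in [0, 2π)
(default 18), giving R = 1800 at the full-scale profile.

### Minimal bounding box

The translation domain is the axis-aligned box, centered at the fixed
helix's terminal base-pair center, that contains every placement of the
mobile helix's terminal base-pair center realizable by the connecting
linker.  We derive it from the exact reach bound — fixed-anchor offset +
(2L+1)·3.9 Å + closure tolerance + mobile-anchor offset for an L-nt
linker — rather than by sweeping chain conformations; the resulting box
provably contains every viable displacement, at the cost of a somewhat
larger grid total T than a swept box would give (absolute T values are
therefore implementation-defined; fractions, not counts, are the
reportable quantities).  Grid spacing follows the adaptive (L+1) Å rule,
multiplied by the profile's coarsening factor; one spacing of padding is
added per face so boundary-viable placements are never clipped.

### Loop closure

Loops are P–C4′ virtual-bond chains: two 3.9 Å bonds per nucleotide, a
fixed 105° virtual-bond angle, and 9 uniformly spaced dihedral choices
per extension (diamond-lattice style; the dihedral frame is built
deterministically from the previous bond direction).  A loop of n nt
grows 2n beads depth-first from the 3′ C4′ anchor of one helix; closure
succeeds when the final bead lies within one bond plus the closure
tolerance (3.9 Å, i.e. the closure bond replaces the last virtual bond)
of the 5′ P anchor of the next helix.  Excluded volume: 4.0 Å minimum
distance between a chain bead and any helix bead or non-bonded chain
bead; the loop's own two anchor beads are bonded termini and are excluded
from the context.  Three accelerations never change an answer on small
instances (property-tested against an unpruned brute-force oracle):
branches are discarded when the remaining bonds cannot reach the target,
candidates are explored nearest-target-first, and the reach bound
(2n+1)·bond + tolerance is applied before any growth.

One approximation can: the search carries a node budget (default 20 000
candidate beads per viability test) so that geometrically blocked but
within-reach placements cannot trigger exponential search; an exhausted
budget counts as not viable.  With greedy ordering, viable placements are
found in far fewer nodes, so the budget bites only on configurations that
are (at least nearly) infeasible.

Loops in a subset are tested independently — helix–loop, not loop–loop,
excluded volume — matching the per-loop definition of viability; a strict
mode (`loop_loop_exclusion`) additionally feeds each accepted loop's
beads into the context of the loops tested after it, for sensitivity
analysis.  Helix–helix overlap below the same 4 Å cutoff disallows a
configuration outright.

### PK counting and KISS sampling

For a PK, the H1–L2–H2 unit is enumerated exhaustively: every rotation ×
translation is screened by the L2 reach bound and helix clash, then
tested for L2 closure (N_2), then for L1 (N_12), L3 (N_23) and all three
(N_123).  Counts are monotone by construction (adding a loop never
increases a count) and independent of enumeration order.

For a KISS, the two units H1–L2–H2 and H2–L4–H3 are sampled: each draw
takes one uniform grid configuration per unit (two six-parameter
transforms), tests L2 and L4 first (N_24), then each remaining loop among
the survivors (N_124, N_234, N_245, N_246) and all six (N_123456).
`n_total` is the number of draws (default 1e5); results are
bit-reproducible for a fixed seed and two seeds agree within binomial
error.  When a kissing motif is not enclosed (no L6 circuit), L6 imposes
no constraint and is skipped.

### Motif decomposition

Dot-bracket input may use four bracket families; families may cross.
Helices are maximal stacks of nested pairs (1-bp helices count).  Two
helices cross when their pairs interleave (i<k<j<l).  Crossing components
of two helices with segment order H1a–H2a–H1b–H2b classify as PK; of
three helices with order H1a–H2a–H1b–H3a–H2b–H3b as KISS; anything else
raises an explicit unsupported-topology error rather than guessing.
Substructures hanging off a tertiary motif's loops are reduced to their
terminal base pair (+2 nt to the host loop, recorded as a substitution);
an enclosing helix reduces to the effective loop L6 = La + Lb + 2.
Non-crossing regions decompose into helices, hairpin/internal/bulge
loops, junctions, and exterior single strands; the motif set partitions
the sequence exactly.  A `HELIX` motif type (beyond the loop-centric
types) keeps that partition exact.  All indices are 1-based.

### Template scoring and placement

`S = a·Σ|ΔH| + Σ b·|ΔL|`, a = 2, b = 5 for L2 (PK) and L2/L4 (KISS), 1
otherwise, elements compared positionally.  Ties rank by smaller
strong-loop difference, then lexicographic template id — a documented
convention chosen to prefer templates matching where the topology is
stiffest.  Templates store transforms of each helix relative to helix 1;
placement applies them to freshly built A-form helices of the query's
sizes (helix geometry is preserved exactly; only the transforms come from
the template) and reports per-loop anchor gaps against the reach bound.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n_axes` × `n_alphas` | 100 × 18 | rotation grid (R = 1800) |
| `grid_coarsen` | 1.0 | multiplier on the (L+1) Å translation spacing |
| `bond_length` | 3.9 Å | P–C4′ virtual bond |
| `bond_angle_deg` | 105° | virtual-bond angle |
| `n_dihedrals` | 9 | discrete dihedral choices per extension |
| `ev_cutoff` | 4.0 Å | excluded-volume cutoff |
| `closure_tol` | 3.9 Å | closure-bond tolerance |
| `max_nodes` | 20 000 | DFS node budget per viability test |
| `rise`, `twist_deg` | 2.81 Å, 32.7° | A-form step |
| `kiss_samples` | 100 000 | KISS sample count |

Two named profiles ship: `full` (the full-scale grid above; exhaustive
PK enumeration at this profile is an hours-long run) and `reduced`
(26 axes × 6 angles, 2× coarser translations; minutes).  The test suite
and the worked examples use still coarser grids (14 × 4 with 4× coarser
translations, node budget 2000) so the full suite runs in about two
minutes; these sizes are stated in the tests themselves.

## What the toy data does and does not show

Fixtures are generated, not downloaded: dot-bracket strings realizing
each reference motif size, a toy template database with plausible
(hand-set, not fitted) transforms, and idealized helix PDBs.  The
reference table of published constraint fractions for 20 PK and 7 KISS
crystal-structure motifs ships as data and exercises the summary,
grouping, and rendering paths end to end.

Passing tests therefore demonstrate: exact fraction arithmetic and
rendering against published counts; internal consistency of the engine
(oracle equivalence of the pruned search, exact reach bounds, subset
monotonicity, order invariance, seed stability); and the qualitative
physics (longer L1/L3 weaken the constraint; tilted-flip configurations
are correctly found for marginal zero-length linkers).  They do not
demonstrate agreement of absolute `N_x` with enumeration based on a
different torsion dictionary, box sweep, or helix parameterization —
those choices set the absolute scale of counts, which is why fractions
and trends, not counts, are the quantities this package reports.
Likewise the coarse chain model ignores sequence, base pairing geometry
of non-canonical pairs, and electrostatics; it bounds what chain
connectivity and sterics allow, not what thermodynamics prefers.

## Numerical choices and edge cases

- Averages in summary tables are taken over unrounded fractions and
  rounded only at rendering (round-half-away-from-zero at two significant
  figures, ASCII `4.3E-3`).  A zero fraction renders `0` and decomposes
  as mantissa 0, exponent 0.
- Rotation-extraction ties (α = π with an equatorial axis) canonicalize
  to x ≥ 0, then y > 0.
- A degenerate 0×0 joint between two stacks classifies as an internal
  loop of size (0, 0).
- An unenclosed KISS keeps six loop slots with `l6_closed = False`; L6
  then never constrains.
- Landscape cells with no allowed configuration are stored as 0 (the
  resolution floor is 1/N_tot per marginalized combination).

## Known limitations

- Only H-type pseudoknots and three-helix kissing wirings are
  auto-classified; deeper pseudoknots and the extended kissing motifs
  (hairpin–internal-loop, hairpin–stem-loop) raise errors by design.
- The node budget makes near-infeasible viability tests conservative
  (biased toward "not viable") in a deterministic, documented way.
- Scaffold output is coarse-grained (beads, not atoms); all-atom loop
  building and refinement are out of scope.
- KISS landscape sweeps are not implemented (PK only).
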