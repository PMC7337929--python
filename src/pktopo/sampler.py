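"""Coarse-grained loop sampling and helix-configuration viability counting.

Loops are grown as P-C4' virtual-bond chains (two beads per nucleotide,
fixed 3.9 A bonds, a fixed virtual-bond angle with a discrete dihedral set),
anchored on the flanking helices.  A helix configuration is *allowed* for a
loop subset when every loop in the subset admits at least one self-avoiding
closure given all placed helices as excluded-volume context.

For a pseudoknot the helix-loop-helix motif H1-L2-H2 is enumerated
exhaustively on a rotation grid (quasi-uniform axes x uniform angles) times
a translation grid inside the minimal bounding box (MBB); for a kissing
motif the two helix-loop-helix units H1-L2-H2 and H2-L4-H3 are sampled
randomly from their grids.  Counts N_x per loop subset divide by the total
enumerated (or sampled) configurations to give constraint fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .config import RunConfig, REDUCED_PROFILE
from .geometry import (HelixModel, RigidTransform, _rodrigues,
                       _axis_from_angles, build_a_form_helix,
                       quasi_uniform_axes, transform_from_matrix)
from .motifs import MotifSpec

__all__ = [
    "MBB",
    "ConfigurationGrid",
    "ViabilityCounts",
    "LoopChain",
    "loop_reach",
    "enumerate_loop_conformations",
    "loop_viable",
    "compute_mbb",
    "build_grid",
    "count_pk",
    "sample_kiss",
    "check_config_viability",
]

PK_SUBSETS = ("2", "12", "23", "123")
KISS_SUBSETS = ("24", "124", "234", "245", "246", "123456")


# ---------------------------------------------------------------------------
# loop chains
# ---------------------------------------------------------------------------

@dataclass
class LoopChain:
    """One accepted loop conformation: 2*n_nt beads between two anchors."""

    n_nt: int
    beads: np.ndarray              # (2*n_nt, 3), P/C4' alternating
    anchor_start: np.ndarray
    anchor_end: np.ndarray | None


def loop_reach(n_nt: int, config: RunConfig) -> float:
    """Maximum anchor-anchor distance an n-nt loop can bridge:
    (2n + 1) bonds plus the closure tolerance."""
    return (2 * n_nt + 1) * config.bond_length + config.closure_tol


def _perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(u[0]) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(u, e1)


def extension_directions(prev_dir: np.ndarray, config: RunConfig
                         ) -> np.ndarray:
    """Discrete direction set for the next virtual bond.

    Diamond-lattice style: the new bond deviates from the previous bond
    direction by (pi - bond_angle), with ``n_dihedrals`` uniformly spaced
    dihedral choices about it.  Deterministic given the previous direction.
    """
    u = prev_dir / np.linalg.norm(prev_dir)
    dev = math.pi - config.bond_angle
    e1, e2 = _perp_basis(u)
    k = np.arange(config.n_dihedrals)
    ang = 2.0 * math.pi * k / config.n_dihedrals
    return (math.cos(dev) * u[None, :]
            + math.sin(dev) * (np.cos(ang)[:, None] * e1[None, :]
                               + np.sin(ang)[:, None] * e2[None, :]))


def enumerate_loop_conformations(
    n_nt: int,
    anchor_start: np.ndarray,
    anchor_prev: np.ndarray | None,
    anchor_end: np.ndarray | None,
    context: np.ndarray | cKDTree | None,
    config: RunConfig,
    *,
    prune: bool = True,
    max_nodes: int | None = None,
    extra_context: np.ndarray | None = None,
) -> Iterator[np.ndarray]:
    """Depth-first generator of accepted loop conformations.

    Grows 2*n_nt beads (one P and one C4' per nucleotide) from
    ``anchor_start``; ``anchor_prev`` supplies the incoming bond direction
    (defaults to +z).  A conformation is accepted when the final bead lies
    within one bond length plus ``closure_tol`` of ``anchor_end`` (no
    closure test when ``anchor_end`` is None) and no bead comes within the
    excluded-volume cutoff of the context or of a non-bonded chain bead.
    Anchor beads are bonded chain termini and are never part of the context.

    With ``prune`` the search discards branches whose remaining bonds cannot
    reach the end anchor; pruning never changes the set of conformations.
    ``max_nodes`` bounds the number of candidate beads examined (defaults to
    ``config.max_nodes``); an exhausted budget silently ends the stream.
    """
    if n_nt < 0:
        raise ValueError("loop length must be >= 0")
    b = config.bond_length
    cutoff = config.ev_cutoff
    close_r = b + config.closure_tol
    budget = config.max_nodes if max_nodes is None else max_nodes
    start = np.asarray(anchor_start, dtype=float)
    end = None if anchor_end is None else np.asarray(anchor_end, dtype=float)
    if context is None:
        tree = None
    elif isinstance(context, cKDTree):
        tree = context
    else:
        ctx = np.asarray(context, dtype=float).reshape(-1, 3)
        tree = cKDTree(ctx) if len(ctx) else None
    extra = (None if extra_context is None or not len(extra_context)
             else np.asarray(extra_context, dtype=float).reshape(-1, 3))

    if n_nt == 0:
        ok = end is None or np.linalg.norm(start - end) <= close_r
        if ok:
            yield np.empty((0, 3))
        return

    n_beads = 2 * n_nt
    prev = (np.array([0.0, 0.0, -1.0]) + start if anchor_prev is None
            else np.asarray(anchor_prev, dtype=float))
    chain = np.empty((n_beads, 3))
    counter = [0]

    def grow(depth: int, cur: np.ndarray, prev_pt: np.ndarray):
        dirs = extension_directions(cur - prev_pt, config)
        cand = cur + b * dirs
        if end is not None:
            dist_end = np.linalg.norm(cand - end, axis=1)
            if prune:
                reach_left = (n_beads - depth - 1) * b + close_r
                keep = dist_end <= reach_left
                cand, dist_end = cand[keep], dist_end[keep]
            order = np.argsort(dist_end)
            cand = cand[order]
        for pt in cand:
            counter[0] += 1
            if counter[0] > budget:
                return True
            if tree is not None and tree.query(pt)[0] < cutoff:
                continue
            if extra is not None and \
                    np.min(np.linalg.norm(extra - pt, axis=1)) < cutoff:
                continue
            # self-avoidance against non-bonded chain beads (the immediate
            # predecessor chain[depth-1] is bonded)
            if depth >= 2 and np.min(
                    np.linalg.norm(chain[:depth - 1] - pt, axis=1)) < cutoff:
                continue
            chain[depth] = pt
            if depth == n_beads - 1:
                if end is None or np.linalg.norm(pt - end) <= close_r:
                    yield chain.copy()
            else:
                exhausted = yield from grow(depth + 1, pt, cur)
                if exhausted:
                    return True
        return False

    yield from grow(0, start, prev)


def loop_viable(n_nt, anchor_start, anchor_prev, anchor_end, context,
                config, **kw) -> bool:
    """True iff at least one accepted conformation exists (first hit)."""
    for _ in enumerate_loop_conformations(n_nt, anchor_start, anchor_prev,
                                          anchor_end, context, config, **kw):
        return True
    return False


# ---------------------------------------------------------------------------
# minimal bounding box and configuration grid
# ---------------------------------------------------------------------------

@dataclass
class MBB:
    """Axis-aligned translation box for the mobile helix's terminal
    base-pair center, with its loop-size adaptive grid."""

    center: np.ndarray
    half_extents: np.ndarray    # reach-bound extent, before padding
    grid_spacing: float
    padding: float = 0.0        # extra margin per face, A

    @property
    def axis_points(self) -> list[np.ndarray]:
        out = []
        for ax in range(3):
            m = int(math.ceil((self.half_extents[ax] + self.padding)
                              / self.grid_spacing))
            out.append(self.center[ax]
                       + self.grid_spacing * np.arange(-m, m + 1))
        return out

    @property
    def grid_points(self) -> np.ndarray:
        gx, gy, gz = np.meshgrid(*self.axis_points, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    @property
    def T(self) -> int:
        return int(np.prod([len(a) for a in self.axis_points]))

    def contains(self, pts: np.ndarray) -> np.ndarray:
        return np.all(np.abs(pts - self.center)
                      <= self.half_extents + self.padding, axis=-1)


def _hlh_anchors(fixed: HelixModel, mobile: HelixModel):
    """Linker anchors of a helix-loop-helix unit: the loop runs from the
    mobile helix's strand-5 3' terminus to the fixed helix's strand-3 5'
    terminus (both at the interface base pairs)."""
    start = mobile.nt_beads("5", mobile.n_bp)[1]       # C4', mobile
    start_prev = mobile.nt_beads("5", mobile.n_bp)[0]  # its P
    end = fixed.nt_beads("3", 1)[0]                    # P, fixed
    return start, start_prev, end


def compute_mbb(h1: int, l2: int, h2: int,
                config: RunConfig = REDUCED_PROFILE) -> MBB:
    """MBB of the H1-L2-H2 unit: the box around the fixed helix's terminal
    base-pair center containing every placement of the mobile helix's
    terminal base-pair center that the L2 linker can realize.

    The box is derived from the exact reach bound: fixed-anchor offset +
    (2*L2 + 1) bonds + closure tolerance + mobile-anchor offset, so every
    viable displacement lies inside it; one grid spacing of padding is added
    per face.  Grid spacing follows the (L + 1) A adaptive rule scaled by
    the profile's coarsening factor.
    """
    fixed = build_a_form_helix(h1, config)
    fixed = fixed.in_frame(fixed.frame_last)
    mobile = build_a_form_helix(h2, config)
    mobile = mobile.in_frame(mobile.frame_last)
    start, _, end = _hlh_anchors(fixed, mobile)
    r_fix = float(np.linalg.norm(end))
    r_mob = float(np.linalg.norm(start))
    s = config.grid_spacing(l2)
    half = r_fix + loop_reach(l2, config) + r_mob
    return MBB(center=np.zeros(3), half_extents=np.full(3, half),
               grid_spacing=s, padding=config.mbb_padding_grids * s)


@dataclass
class ConfigurationGrid:
    """Discrete rotation x translation enumeration domain."""

    axes: list            # (theta, phi) pairs
    alphas: np.ndarray    # rotation angles
    mbb: MBB

    @property
    def R(self) -> int:
        return len(self.axes) * len(self.alphas)

    @property
    def T(self) -> int:
        return self.mbb.T

    @property
    def N_tot(self) -> int:
        return self.R * self.T

    def rotations(self) -> Iterator[tuple[float, float, float, np.ndarray]]:
        for theta, phi in self.axes:
            axis = _axis_from_angles(theta, phi)
            for alpha in self.alphas:
                yield theta, phi, float(alpha), _rodrigues(axis, alpha)


def build_grid(h1: int, l2: int, h2: int,
               config: RunConfig = REDUCED_PROFILE) -> ConfigurationGrid:
    alphas = 2.0 * math.pi * np.arange(config.n_alphas) / config.n_alphas
    return ConfigurationGrid(axes=quasi_uniform_axes(config.n_axes),
                             alphas=alphas,
                             mbb=compute_mbb(h1, l2, h2, config))


# ---------------------------------------------------------------------------
# viability counts
# ---------------------------------------------------------------------------

@dataclass
class ViabilityCounts:
    """Allowed-configuration counts N_x per loop subset."""

    motif_type: str
    subset_counts: dict
    n_total: int
    meta: dict = field(default_factory=dict)
    records: list | None = None

    def __post_init__(self):
        for label, n in self.subset_counts.items():
            if not 0 <= n <= self.n_total:
                raise ValueError(f"count N_{label}={n} outside "
                                 f"[0, {self.n_total}]")

    def fraction(self, label: str) -> float:
        return self.subset_counts[label] / self.n_total

    def fractions(self) -> dict:
        return {k: v / self.n_total for k, v in self.subset_counts.items()}

    @property
    def f_total(self) -> float:
        """F for the full loop subset (F_PK or F_KISS)."""
        key = "123" if self.motif_type == "PK" else "123456"
        return self.fraction(key)


# ---------------------------------------------------------------------------
# scenes: placed helices + loop anchor wiring
# ---------------------------------------------------------------------------

class _Scene:
    """Helices of a PK or KISS motif in their interface frames, with the
    loop anchor wiring needed for viability tests.

    Every loop runs between a C4' 3'-terminus on one helix and a P
    5'-terminus on another; the two anchor beads of each loop (and of every
    other loop of the motif) are excluded from the excluded-volume context
    as bonded termini.
    """

    def __init__(self, spec: MotifSpec, config: RunConfig):
        self.spec = spec
        self.config = config
        nh = len(spec.helix_sizes)
        self.helices = []
        for n_bp in spec.helix_sizes:
            h = build_a_form_helix(n_bp, config)
            self.helices.append(h.in_frame(h.frame_last))
        # loop wiring: label -> (n_nt, (helix, strand, nt) start,
        #                        (helix, strand, nt) end)
        L = spec.loop_sizes
        if spec.motif_type == "PK":
            self.wiring = {
                "1": (L[0], (0, "5", spec.helix_sizes[0]), (1, "5", 1)),
                "2": (L[1], (1, "5", spec.helix_sizes[1]), (0, "3", 1)),
                "3": (L[2], (0, "3", spec.helix_sizes[0]), (1, "3", 1)),
            }
        elif spec.motif_type == "KISS":
            h1, h2, h3 = spec.helix_sizes
            self.wiring = {
                "1": (L[0], (0, "5", h1), (1, "5", 1)),
                "2": (L[1], (1, "5", h2), (0, "3", 1)),
                "3": (L[2], (0, "3", h1), (2, "5", 1)),
                "4": (L[3], (2, "5", h3), (1, "3", 1)),
                "5": (L[4], (1, "3", h2), (2, "3", 1)),
                "6": (L[5], (2, "3", h3), (0, "5", 1)),
            }
        else:
            raise ValueError(f"no sampling scene for {spec.motif_type}")
        # bead indices of all anchor beads, per helix, to drop from context
        drop: dict[int, set] = {i: set() for i in range(nh)}
        for n_nt, (hs, ss, ns), (he, se, ne) in self.wiring.values():
            drop[hs].add(self._bead_index(hs, ss, ns, "C4"))
            drop[he].add(self._bead_index(he, se, ne, "P"))
        self.context_masks = []
        for i, h in enumerate(self.helices):
            keep = np.ones(4 * h.n_bp, dtype=bool)
            keep[list(drop[i])] = False
            self.context_masks.append(keep)

    def _bead_index(self, helix: int, strand: str, nt: int, kind: str) -> int:
        h = self.helices[helix]
        base = 0 if strand == "5" else 2 * h.n_bp
        return base + 2 * (nt - 1) + (0 if kind == "P" else 1)

    def helix_beads_local(self, i: int) -> np.ndarray:
        return self.helices[i].beads

    def place(self, placements: list) -> "_PlacedScene":
        """``placements[i]`` is (Rmat, shift) taking helix i local beads to
        global coordinates; helix 0 is the fixed reference (identity)."""
        return _PlacedScene(self, placements)


class _PlacedScene:
    def __init__(self, scene: _Scene, placements: list):
        self.scene = scene
        self.config = scene.config
        self.beads = []
        for h, (R, t) in zip(scene.helices, placements):
            self.beads.append(h.beads @ R.T + t)
        self.placements = placements
        ctx = np.vstack([b[m] for b, m in
                         zip(self.beads, scene.context_masks)])
        self.tree = cKDTree(ctx)

    def anchor(self, helix: int, strand: str, nt: int, kind: str
               ) -> np.ndarray:
        idx = self.scene._bead_index(helix, strand, nt, kind)
        return self.beads[helix][idx]

    def loop_anchors(self, label: str):
        n_nt, (hs, ss, ns), (he, se, ne) = self.scene.wiring[label]
        start = self.anchor(hs, ss, ns, "C4")
        prev = self.anchor(hs, ss, ns, "P")
        end = self.anchor(he, se, ne, "P")
        return n_nt, start, prev, end

    def loop_gap(self, label: str) -> float:
        n_nt, start, _, end = self.loop_anchors(label)
        return float(np.linalg.norm(start - end))

    def loop_in_reach(self, label: str) -> bool:
        n_nt, start, _, end = self.loop_anchors(label)
        return (np.linalg.norm(start - end)
                <= loop_reach(n_nt, self.config))

    def loop_ok(self, label: str, extra: np.ndarray | None = None) -> bool:
        n_nt, start, prev, end = self.loop_anchors(label)
        if np.linalg.norm(start - end) > loop_reach(n_nt, self.config):
            return False
        return loop_viable(n_nt, start, prev, end, self.tree, self.config,
                           extra_context=extra)

    def loop_first_chain(self, label: str) -> np.ndarray | None:
        n_nt, start, prev, end = self.loop_anchors(label)
        for beads in enumerate_loop_conformations(
                n_nt, start, prev, end, self.tree, self.config):
            return beads
        return None

    def helix_clash(self) -> bool:
        """True when any two placed helices overlap below the EV cutoff."""
        cutoff = self.config.ev_cutoff
        trees = {}
        n = len(self.beads)
        for i in range(n):
            for j in range(i + 1, n):
                if i not in trees:
                    trees[i] = cKDTree(self.beads[i])
                if trees[i].query(self.beads[j])[0].min() < cutoff:
                    return True
        return False

    def subset_ok(self, labels: Sequence[str]) -> bool:
        """All loops in the subset viable.  In strict mode each accepted
        loop's beads join the context of the loops tested after it."""
        if self.config.loop_loop_exclusion:
            extra = np.empty((0, 3))
            for lab in labels:
                n_nt, start, prev, end = self.loop_anchors(lab)
                if np.linalg.norm(start - end) > loop_reach(n_nt,
                                                            self.config):
                    return False
                found = None
                for beads in enumerate_loop_conformations(
                        n_nt, start, prev, end, self.tree, self.config,
                        extra_context=extra):
                    found = beads
                    break
                if found is None:
                    return False
                if len(found):
                    extra = np.vstack([extra, found])
            return True
        return all(self.loop_ok(lab) for lab in labels)


def _active_labels(spec: MotifSpec, labels: Sequence[str]) -> list:
    """Drop L6 from a KISS subset when the L6 circuit is open."""
    if spec.motif_type == "KISS" and not spec.l6_closed:
        return [l for l in labels if l != "6"]
    return list(labels)


# ---------------------------------------------------------------------------
# counting operations
# ---------------------------------------------------------------------------

def check_config_viability(transforms, spec: MotifSpec,
                           subset: Sequence[str],
                           config: RunConfig = REDUCED_PROFILE) -> bool:
    """True iff every loop in ``subset`` admits a closure for the helix
    configuration given by ``transforms`` (one RigidTransform for PK, two
    for KISS; helix 1 is the fixed reference).

    Subset labels are loop numbers as strings ("1".."3" for PK, "1".."6"
    for KISS); an empty subset is vacuously viable.
    """
    if isinstance(transforms, RigidTransform):
        transforms = [transforms]
    scene = _Scene(spec, config)
    for lab in subset:
        if lab not in scene.wiring:
            raise ValueError(f"unknown loop label {lab!r} for "
                             f"{spec.motif_type}")
    placed = _place_from_transforms(scene, transforms)
    return placed.subset_ok(_active_labels(spec, subset))


def _place_from_transforms(scene: _Scene, transforms) -> _PlacedScene:
    placements = [(np.eye(3), np.zeros(3))]
    R_acc, t_acc = np.eye(3), np.zeros(3)
    for t in transforms:
        R_acc, t_acc = R_acc @ t.rotation, R_acc @ t.translation + t_acc
        placements.append((R_acc.copy(), t_acc.copy()))
    if len(placements) != len(scene.helices):
        raise ValueError(f"{len(scene.helices) - 1} transforms required")
    return scene.place(placements)


def count_pk(spec: MotifSpec, grid: ConfigurationGrid | None = None,
             config: RunConfig = REDUCED_PROFILE,
             record: bool = False) -> ViabilityCounts:
    """Exhaustively enumerate two-helix configurations of a pseudoknot and
    count the allowed ones per loop subset.

    For every rotation x translation of H2 relative to H1 the L2 linker is
    tested first (subset "2"); surviving configurations are tested for L1
    ("12"), L3 ("23") and all three loops ("123").  Configurations where the
    rigid helices themselves overlap are disallowed.  Returns counts with
    ``n_total = R * T``.
    """
    if spec.motif_type != "PK":
        raise ValueError("count_pk needs a PK MotifSpec")
    scene = _Scene(spec, config)
    if grid is None:
        grid = build_grid(spec.helix_sizes[0], spec.loop_sizes[1],
                          spec.helix_sizes[1], config)
    h2_local = scene.helix_beads_local(1)
    l2_n, (hs, ss, ns), (he, se, ne) = scene.wiring["2"]
    a2_start_loc = h2_local[scene._bead_index(1, ss, ns, "C4")]
    a2_end = scene.helix_beads_local(0)[scene._bead_index(0, se, ne, "P")]
    reach2 = loop_reach(l2_n, config)
    tpts = grid.mbb.grid_points
    counts = dict.fromkeys(PK_SUBSETS, 0)
    records = [] if record else None

    for theta, phi, alpha, R in grid.rotations():
        rot_start = R @ a2_start_loc
        gaps = np.linalg.norm(tpts + rot_start - a2_end, axis=1)
        for t in tpts[gaps <= reach2]:
            placed = scene.place([(np.eye(3), np.zeros(3)), (R, t)])
            if placed.helix_clash():
                continue
            ok2 = placed.subset_ok(["2"])
            if not ok2:
                continue
            counts["2"] += 1
            ok1 = placed.subset_ok(["1"])
            ok3 = placed.subset_ok(["3"])
            counts["12"] += ok1
            counts["23"] += ok3
            counts["123"] += ok1 and ok3
            if record:
                records.append({"theta": theta, "phi": phi, "alpha": alpha,
                                "dx": t[0], "dy": t[1], "dz": t[2],
                                "ok2": True, "ok12": bool(ok1),
                                "ok23": bool(ok3),
                                "ok123": bool(ok1 and ok3)})
    meta = {"R": grid.R, "T": grid.T, "config": config.digest(),
            "size": spec.size_string}
    return ViabilityCounts("PK", counts, grid.N_tot, meta=meta,
                           records=records)


def sample_kiss(spec: MotifSpec, n_samples: int | None = None,
                seed: int | None = None,
                config: RunConfig = REDUCED_PROFILE,
                record: bool = False) -> ViabilityCounts:
    """Randomly sample three-helix configurations of a kissing motif from
    the configuration grids of its two helix-loop-helix units and count the
    allowed ones per loop subset.

    Each sample draws one (rotation, translation) configuration per unit
    uniformly from its grid; loops L2 and L4 are tested first (subset "24"),
    then each remaining loop against the survivors, then all six
    ("123456").  Reproducible for a fixed seed; ``n_total`` is the number of
    samples.  When the motif's L6 circuit is open (``l6_closed`` False) L6
    imposes no constraint.
    """
    if spec.motif_type != "KISS":
        raise ValueError("sample_kiss needs a KISS MotifSpec")
    n_samples = config.kiss_samples if n_samples is None else n_samples
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    scene = _Scene(spec, config)
    h1, h2, h3 = spec.helix_sizes
    grid1 = build_grid(h1, spec.loop_sizes[1], h2, config)
    grid2 = build_grid(h2, spec.loop_sizes[3], h3, config)
    counts = dict.fromkeys(KISS_SUBSETS, 0)
    records = [] if record else None

    tp_cache = {id(grid1): grid1.mbb.grid_points,
                id(grid2): grid2.mbb.grid_points}

    def draw(grid):
        axes = grid.axes
        i = rng.integers(len(axes))
        a = rng.integers(len(grid.alphas))
        tp = tp_cache[id(grid)]
        j = rng.integers(len(tp))
        theta, phi = axes[i]
        alpha = float(grid.alphas[a])
        R = _rodrigues(_axis_from_angles(theta, phi), alpha)
        return (theta, phi, alpha), R, tp[j]

    subsets_extra = {"124": ["1"], "234": ["3"], "245": ["5"],
                     "246": ["6"]}
    for _ in range(n_samples):
        p1, R1, t1 = draw(grid1)
        p2, R2, t2 = draw(grid2)
        placed = scene.place([
            (np.eye(3), np.zeros(3)),
            (R1, t1),
            (R1 @ R2, R1 @ t2 + t1),
        ])
        # cheap reach screen before any chain growth
        base = _active_labels(spec, ["2", "4"])
        if not all(placed.loop_in_reach(l) for l in base):
            ok24 = False
        elif placed.helix_clash():
            ok24 = False
        else:
            ok24 = placed.subset_ok(base)
        rec = {"ok24": bool(ok24)}
        if ok24:
            counts["24"] += 1
            loop_ok = {}
            for lab in ("1", "3", "5", "6"):
                active = _active_labels(spec, [lab])
                loop_ok[lab] = (placed.subset_ok(active) if active
                                else True)
            for key, labs in subsets_extra.items():
                good = all(loop_ok[l] for l in labs)
                counts[key] += good
                rec[f"ok{key}"] = bool(good)
            all_ok = all(loop_ok.values())
            counts["123456"] += all_ok
            rec["ok123456"] = bool(all_ok)
        if record:
            rec.update({"p1": p1, "t1": tuple(t1), "p2": p2,
                        "t2": tuple(t2)})
            records.append(rec)
    meta = {"R1": grid1.R, "T1": grid1.T, "R2": grid2.R, "T2": grid2.T,
            "seed": seed, "config": config.digest(),
            "size": spec.size_string}
    return ViabilityCounts("KISS", counts, n_samples, meta=meta,
                           records=records)
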