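"""Run configuration for the topological-constraint engine.

All tunable geometry and sampling parameters live here so that every count
produced by the sampler is reproducible from a single :class:`RunConfig`.
Angles are stored in radians internally; degrees appear only at the CLI
boundary.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, replace

__all__ = ["RunConfig", "FULL_PROFILE", "REDUCED_PROFILE", "get_profile"]


@dataclass(frozen=True)
class RunConfig:
    """Parameters controlling helix geometry, loop sampling and enumeration.

    The rotation grid defaults (100 quasi-uniform axes x 18 rotation angles,
    R = 1800 rotations) and the loop-size adaptive translation grid
    ((L + 1) A spacing for an L-nt linker) define the full-scale enumeration
    profile.  ``grid_coarsen`` scales the translation spacing up for
    desk-scale runs.

    A-form helix geometry (rise, twist, bead radii) is idealized and pinned
    here: changing it changes every viability count.
    """

    # rotation grid
    n_axes: int = 100            # quasi-uniform rotation-axis directions
    n_alphas: int = 18           # rotation angles, uniform in [0, 2pi)
    # translation grid
    grid_coarsen: float = 1.0    # multiplier on the (L+1) A adaptive spacing
    mbb_padding_grids: float = 1.0   # padding, in grid spacings, per box face
    # coarse-grained chain geometry
    bond_length: float = 3.9     # P-C4' virtual-bond length, A
    bond_angle_deg: float = 105.0    # virtual-bond angle at each bead
    n_dihedrals: int = 9         # discrete dihedral choices per extension
    ev_cutoff: float = 4.0       # excluded-volume cutoff, non-bonded beads, A
    closure_tol: float = 3.9     # closure tolerance onto the end anchor, A
    max_nodes: int = 20000       # DFS node budget per loop viability test
    loop_loop_exclusion: bool = False   # strict mode: loops also avoid loops
    # A-form helix geometry
    rise: float = 2.81           # axial rise per base pair, A
    twist_deg: float = 32.7      # helical twist per base pair, degrees
    c4_radius: float = 9.2       # C4' bead radial distance from axis, A
    p_radius: float = 8.7        # P bead radial distance from axis, A
    # KISS sampling
    kiss_samples: int = 100_000
    seed: int = 0

    @property
    def twist(self) -> float:
        """Helical twist per base pair, radians."""
        return math.radians(self.twist_deg)

    @property
    def bond_angle(self) -> float:
        """Virtual-bond angle, radians."""
        return math.radians(self.bond_angle_deg)

    @property
    def n_rotations(self) -> int:
        """R: total rotations enumerated (axes x angles)."""
        return self.n_axes * self.n_alphas

    def grid_spacing(self, loop_nt: int) -> float:
        """Adaptive translation-grid spacing for an ``loop_nt``-nt linker.

        The full-scale rule is (L + 1) A for an L-nt loop; ``grid_coarsen``
        scales it for reduced profiles.
        """
        if loop_nt < 0:
            raise ValueError(f"loop_nt must be >= 0, got {loop_nt}")
        return (loop_nt + 1) * self.grid_coarsen

    def validate(self) -> "RunConfig":
        if self.n_axes < 1 or self.n_alphas < 1:
            raise ValueError("axis and alpha counts must be >= 1")
        for name in ("grid_coarsen", "bond_length", "ev_cutoff",
                     "closure_tol", "rise", "c4_radius", "p_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_dihedrals < 1:
            raise ValueError("n_dihedrals must be >= 1")
        return self

    def with_(self, **kw) -> "RunConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw).validate()

    def digest(self) -> str:
        """Short stable hash of the configuration, for log provenance."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


#: Full-scale enumeration profile: R = 100 x 18 = 1800 rotations and the
#: (L+1) A translation grid.  Exhaustive PK enumeration at this profile is an
#: hours-long computation.
FULL_PROFILE = RunConfig()

#: Desk-scale profile: 26 axes x 6 angles with a 2x coarser translation grid.
REDUCED_PROFILE = RunConfig(n_axes=26, n_alphas=6, grid_coarsen=2.0)

_PROFILES = {"full": FULL_PROFILE, "reduced": REDUCED_PROFILE}


def get_profile(name: str) -> RunConfig:
    try:
        return _PROFILES[name]
    except KeyError:
        raise KeyError(
            f"unknown profile {name!r}; choose from {sorted(_PROFILES)}"
        ) from None
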