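"""Rigid-body transforms, rotation-axis sampling, and A-form helix models.

The spatial configuration of a two-helix system is described by six
parameters (theta, phi, alpha, dx, dy, dz): a rotation about the unit axis
(sin(theta)cos(phi), sin(theta)sin(phi), cos(theta)) by angle alpha, followed
by a translation (dx, dy, dz).  The rotation axis passes through the
geometric center of the reference base pair, which the sampler places at the
global origin.

Helices are idealized A-form duplexes carried at coarse-grained resolution:
one P and one C4' bead per nucleotide, with base-pair reference frames at the
two terminal base pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .config import RunConfig, FULL_PROFILE

__all__ = [
    "RigidTransform",
    "BasePairFrame",
    "HelixModel",
    "make_transform",
    "extract_params",
    "apply_transform",
    "quasi_uniform_axes",
    "build_a_form_helix",
]

_TWO_PI = 2.0 * math.pi


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------

def _axis_from_angles(theta: float, phi: float) -> np.ndarray:
    st = math.sin(theta)
    return np.array([st * math.cos(phi), st * math.sin(phi), math.cos(theta)])


def _rodrigues(axis: np.ndarray, alpha: float) -> np.ndarray:
    """Rotation matrix about a unit axis by angle alpha (Rodrigues form)."""
    x, y, z = axis
    c, s = math.cos(alpha), math.sin(alpha)
    C = 1.0 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


@dataclass(frozen=True)
class RigidTransform:
    """Six-parameter helix-helix transform and its cached 4x4 matrix.

    ``theta``/``phi`` give the rotation axis (polar/azimuthal, radians),
    ``alpha`` the rotation angle about it, and ``d`` the translation in A.
    """

    theta: float
    phi: float
    alpha: float
    dx: float
    dy: float
    dz: float
    matrix: np.ndarray = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        if self.matrix is None:
            object.__setattr__(self, "matrix", self._build_matrix())
        self.matrix.setflags(write=False)

    def _build_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = _rodrigues(_axis_from_angles(self.theta, self.phi),
                               self.alpha)
        m[:3, 3] = (self.dx, self.dy, self.dz)
        return m

    @property
    def rotation(self) -> np.ndarray:
        """The 3x3 rotation submatrix."""
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    @property
    def params(self) -> tuple[float, float, float, float, float, float]:
        return (self.theta, self.phi, self.alpha, self.dx, self.dy, self.dz)

    def inverse(self) -> "RigidTransform":
        R = self.rotation
        d = self.translation
        return transform_from_matrix(R.T, -R.T @ d)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first."""
        m = self.matrix @ other.matrix
        return transform_from_matrix(m[:3, :3], m[:3, 3])


def make_transform(theta: float, phi: float, alpha: float,
                   d: Sequence[float]) -> RigidTransform:
    """Build the transform for rotation axis (theta, phi), angle alpha and
    translation ``d``.

    Raises ``ValueError`` naming the offending parameter when an angle lies
    outside its domain (theta in [0, pi]; phi, alpha in [0, 2pi)).
    """
    if not (0.0 <= theta <= math.pi):
        raise ValueError(f"theta={theta} outside [0, pi]")
    if not (0.0 <= phi < _TWO_PI):
        raise ValueError(f"phi={phi} outside [0, 2*pi)")
    if not (0.0 <= alpha < _TWO_PI):
        raise ValueError(f"alpha={alpha} outside [0, 2*pi)")
    dx, dy, dz = (float(v) for v in d)
    return RigidTransform(float(theta), float(phi), float(alpha), dx, dy, dz)


def _canonical_axis_angle(R: np.ndarray) -> tuple[float, float, float]:
    """(theta, phi, alpha) for rotation matrix R, canonicalized.

    The axis-negation ambiguity (axis, alpha) ~ (-axis, 2*pi - alpha) is
    resolved by requiring cos(theta) >= 0; the identity maps to all zeros.
    """
    rv = Rotation.from_matrix(R).as_rotvec()
    alpha = float(np.linalg.norm(rv))
    if alpha < 1e-12:
        return 0.0, 0.0, 0.0
    axis = rv / alpha
    flip = False
    if axis[2] < -1e-12:
        flip = True
    elif abs(axis[2]) <= 1e-12:
        # axis in the equatorial plane: pick the representative with
        # x > 0, breaking the remaining tie by y > 0
        if axis[0] < -1e-12 or (abs(axis[0]) <= 1e-12 and axis[1] < 0):
            flip = True
    if flip:
        axis = -axis
        alpha = _TWO_PI - alpha
    theta = math.acos(min(1.0, max(-1.0, axis[2])))
    phi = math.atan2(axis[1], axis[0]) % _TWO_PI
    if theta < 1e-12:
        phi = 0.0
    return theta, phi, alpha


def transform_from_matrix(R: np.ndarray, d: np.ndarray) -> RigidTransform:
    """Canonical six-parameter transform from a rotation matrix and shift."""
    theta, phi, alpha = _canonical_axis_angle(np.asarray(R, dtype=float))
    d = np.asarray(d, dtype=float)
    return RigidTransform(theta, phi, alpha, float(d[0]), float(d[1]),
                          float(d[2]))


def apply_transform(t: RigidTransform, coords: np.ndarray) -> np.ndarray:
    """Map a point or point set through the homogeneous matrix."""
    coords = np.asarray(coords, dtype=float)
    return coords @ t.rotation.T + t.translation


# ---------------------------------------------------------------------------
# base-pair frames
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BasePairFrame:
    """Orthonormal right-handed frame at a base-pair geometric center.

    ``origin`` is the mean of the two C4' bead positions of the paired
    nucleotides; ``z_axis`` runs along the helix axis in the 5'->3' direction
    of the reference strand, ``x_axis`` points toward the reference-strand
    C4' bead.
    """

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self):
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            v = np.asarray(getattr(self, name), dtype=float)
            v.setflags(write=False)
            object.__setattr__(self, name, v)
        self.validate()

    def validate(self, tol: float = 1e-9) -> None:
        M = self.axes
        if not np.allclose(M.T @ M, np.eye(3), atol=tol):
            raise ValueError("frame axes are not orthonormal")
        if not np.allclose(np.cross(self.x_axis, self.y_axis), self.z_axis,
                           atol=tol):
            raise ValueError("frame is not right-handed (x cross y != z)")

    @property
    def axes(self) -> np.ndarray:
        """3x3 matrix whose columns are (x, y, z) axes."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])

    def transformed(self, t: RigidTransform) -> "BasePairFrame":
        R = t.rotation
        return BasePairFrame(
            origin=apply_transform(t, self.origin),
            x_axis=R @ self.x_axis,
            y_axis=R @ self.y_axis,
            z_axis=R @ self.z_axis,
        )


def extract_params(frame_ref: BasePairFrame,
                   frame_mov: BasePairFrame) -> RigidTransform:
    """The unique canonical transform mapping ``frame_ref`` onto ``frame_mov``.

    Applying the result to ``frame_ref`` (rotation about the global origin
    followed by translation) reproduces ``frame_mov``; the rotation-axis
    ambiguity is resolved as in :func:`transform_from_matrix`.
    """
    frame_ref.validate()
    frame_mov.validate()
    R = frame_mov.axes @ frame_ref.axes.T
    d = frame_mov.origin - R @ frame_ref.origin
    return transform_from_matrix(R, d)


# ---------------------------------------------------------------------------
# quasi-uniform rotation-axis sampling
# ---------------------------------------------------------------------------

def quasi_uniform_axes(n: int) -> list[tuple[float, float]]:
    """``n`` quasi-uniform axis directions from a spherical Fibonacci lattice.

    Deterministic (no seed); n=1 degenerates to the +z pole.  Returns a list
    of (theta, phi) pairs.
    """
    if n < 1:
        raise ValueError(f"axis count must be >= 1, got {n}")
    if n == 1:
        return [(0.0, 0.0)]
    golden_angle = math.pi * (3.0 - math.sqrt(5.0))
    out = []
    for i in range(n):
        z = 1.0 - (2.0 * i + 1.0) / n
        theta = math.acos(min(1.0, max(-1.0, z)))
        phi = (i * golden_angle) % _TWO_PI
        out.append((theta, phi))
    return out


def axes_to_vectors(axes: Iterable[tuple[float, float]]) -> np.ndarray:
    """Unit vectors for a list of (theta, phi) directions."""
    return np.array([_axis_from_angles(t, p) for t, p in axes])


# ---------------------------------------------------------------------------
# A-form helix model
# ---------------------------------------------------------------------------

@dataclass
class HelixModel:
    """Idealized A-form duplex at coarse-grained (P/C4' bead) resolution.

    ``strand5`` holds the reference strand (running 5'->3' with increasing
    base-pair index), ``strand3`` the complementary strand in its own 5'->3'
    order (its nt j pairs with base pair n_bp + 1 - j).  Both are arrays of
    shape (n_bp, 2, 3) with bead order (P, C4') per nucleotide.
    """

    n_bp: int
    strand5: np.ndarray
    strand3: np.ndarray
    frame_first: BasePairFrame
    frame_last: BasePairFrame
    config: RunConfig = FULL_PROFILE
    atoms: np.ndarray | None = None

    # alternative field names
    @property
    def strand5_coords(self) -> np.ndarray:
        return self.strand5

    @property
    def strand3_coords(self) -> np.ndarray:
        return self.strand3

    @property
    def beads(self) -> np.ndarray:
        """All beads of both strands, shape (4 * n_bp, 3)."""
        return np.vstack([self.strand5.reshape(-1, 3),
                          self.strand3.reshape(-1, 3)])

    def bp_center(self, i: int) -> np.ndarray:
        """Geometric center (mean of the two C4' beads) of base pair i."""
        self._check_bp(i)
        a = self.strand5[i - 1, 1]
        b = self.strand3[self.n_bp - i, 1]
        return 0.5 * (a + b)

    def frame_at(self, i: int) -> BasePairFrame:
        """Base-pair frame at bp ``i`` (z along the strand5 5'->3' axis)."""
        self._check_bp(i)
        o = self.bp_center(i)
        z = self._axis_dir()
        x = self.strand5[i - 1, 1] - o
        x = x - (x @ z) * z
        x = x / np.linalg.norm(x)
        return BasePairFrame(origin=o, x_axis=x, y_axis=np.cross(z, x),
                             z_axis=z)

    def _axis_dir(self) -> np.ndarray:
        if self.n_bp == 1:
            return self.frame_first.z_axis
        v = self.bp_center(self.n_bp) - self.bp_center(1)
        return v / np.linalg.norm(v)

    def _check_bp(self, i: int) -> None:
        if not 1 <= i <= self.n_bp:
            raise IndexError(f"base pair {i} outside 1..{self.n_bp}")

    def nt_beads(self, strand: str, nt: int) -> np.ndarray:
        """(P, C4') bead pair for nucleotide ``nt`` (1-based) of a strand."""
        arr = self.strand5 if strand == "5" else self.strand3
        return arr[nt - 1]

    def in_frame(self, frame: BasePairFrame) -> "HelixModel":
        """Coordinates rebased so that ``frame`` becomes the identity frame."""
        M = frame.axes
        o = frame.origin

        def reb(X):
            return (X.reshape(-1, 3) - o) @ M

        return HelixModel(
            n_bp=self.n_bp,
            strand5=reb(self.strand5).reshape(self.strand5.shape),
            strand3=reb(self.strand3).reshape(self.strand3.shape),
            frame_first=_rebase_frame(self.frame_first, M, o),
            frame_last=_rebase_frame(self.frame_last, M, o),
            config=self.config,
        )

    def transformed(self, t: RigidTransform) -> "HelixModel":
        return HelixModel(
            n_bp=self.n_bp,
            strand5=apply_transform(t, self.strand5.reshape(-1, 3)).reshape(
                self.strand5.shape),
            strand3=apply_transform(t, self.strand3.reshape(-1, 3)).reshape(
                self.strand3.shape),
            frame_first=self.frame_first.transformed(t),
            frame_last=self.frame_last.transformed(t),
            config=self.config,
        )


def _rebase_frame(f: BasePairFrame, M: np.ndarray, o: np.ndarray
                  ) -> BasePairFrame:
    return BasePairFrame(
        origin=(f.origin - o) @ M,
        x_axis=f.x_axis @ M,
        y_axis=f.y_axis @ M,
        z_axis=f.z_axis @ M,
    )


def build_a_form_helix(n_bp: int, config: RunConfig = FULL_PROFILE
                       ) -> HelixModel:
    """Idealized A-form duplex of ``n_bp`` base pairs in its local frame.

    Base pair i sits at z = (i - 1) * rise with reference azimuth
    beta_i = (i - 1) * twist.  The two C4' beads of a pair are placed
    diametrically at radius ``c4_radius`` so that the pair's geometric center
    lies exactly on the helix axis (a deliberate idealization of A-form
    geometry at bead resolution); P beads sit at ``p_radius`` half a step
    behind their C4' along each strand.  Deterministic for a fixed config.
    """
    if n_bp < 1:
        raise ValueError(f"n_bp must be >= 1, got {n_bp}")
    rise, twist = config.rise, config.twist
    rc, rp = config.c4_radius, config.p_radius

    def cyl(r, az, z):
        return (r * math.cos(az), r * math.sin(az), z)

    s5 = np.empty((n_bp, 2, 3))
    s3 = np.empty((n_bp, 2, 3))
    for i in range(1, n_bp + 1):
        beta = (i - 1) * twist
        z = (i - 1) * rise
        # strand5 nt i: P precedes C4' along 5'->3' (increasing z)
        s5[i - 1, 0] = cyl(rp, beta - 0.5 * twist, z - 0.5 * rise)
        s5[i - 1, 1] = cyl(rc, beta, z)
        # strand3 nt j pairs bp i = n_bp + 1 - j; its 5'->3' runs down in z
        j = n_bp + 1 - i
        s3[j - 1, 0] = cyl(rp, beta + math.pi + 0.5 * twist, z + 0.5 * rise)
        s3[j - 1, 1] = cyl(rc, beta + math.pi, z)

    z_axis = np.array([0.0, 0.0, 1.0])

    def frame(i):
        beta = (i - 1) * twist
        x = np.array([math.cos(beta), math.sin(beta), 0.0])
        return BasePairFrame(
            origin=np.array([0.0, 0.0, (i - 1) * rise]),
            x_axis=x, y_axis=np.cross(z_axis, x), z_axis=z_axis)

    return HelixModel(n_bp=n_bp, strand5=s5, strand3=s3,
                      frame_first=frame(1), frame_last=frame(n_bp),
                      config=config)
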