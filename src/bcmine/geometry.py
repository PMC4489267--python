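"""Coordinate-level math for Cα fragments.

This module implements the geometric primitives everything else is built on:
centering, the Binet-Cauchy (BC) similarity score, the companion rigidity
score, reflection (mirror images), Kabsch least-squares superposition and
RMSD.

The BC score between two equal-length Cα coordinate sets, stored as N x 3
matrices ``X`` and ``Y`` centered at the origin, is

    BC(X, Y) = det(XᵀY) / sqrt(det(XᵀX) det(XᵀX))

i.e. the cosine between the Grassmann vectors of the two point sets.  It is
rotation independent, equals 1 for identical shapes, is near 0 for unrelated
conformations and equals -1 for mirror images.  Because BC is blind to
uniform scaling and to some shape-preserving distortions, a second score is
used to bound the admissible flexibility: the rigidity score

    R'(X, Y) = max_i | ||X_i|| - ||Y_i|| |
    R(X, Y)  = max( R'(X, Y), | ||X_N - X_1|| - ||Y_N - Y_1|| | )

the maximum variation of residue-to-centroid distances and of the
terminal-to-terminal distance, in Å.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

log = logging.getLogger("bcmine")

#: relative degeneracy floor: a point set is degenerate (collinear/coplanar)
#: when det(XᵀX) < DEGENERACY_REL_FLOOR * (tr(XᵀX)/3)^3.  The criterion is
#: scale-free, so it behaves identically in Å or nm.
DEGENERACY_REL_FLOOR = 1e-6

#: clamping excursions of |BC| beyond 1 larger than this trigger a warning
CLAMP_WARN = 1e-6

#: BC needs at least 4 points: 3 or fewer centered points span at most a
#: plane and the 3x3 Gram matrix is singular.
MIN_BC_POINTS = 4


class GeometryError(ValueError):
    """Base class for coordinate-level errors."""


class ShapeMismatchError(GeometryError):
    """Operands have incompatible lengths or shapes."""


class DegenerateFragmentError(GeometryError):
    """Fragment is (near-)collinear or coplanar; BC is undefined."""


class InvalidCoordinatesError(GeometryError):
    """Coordinates contain NaN or infinity."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

def _as_coord_array(coords) -> np.ndarray:
    arr = np.asarray(coords, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ShapeMismatchError(f"expected an (N, 3) coordinate array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidCoordinatesError("coordinates contain non-finite values")
    return arr


@dataclass(eq=False)
class Fragment:
    """An ordered run of N Cα positions with provenance.

    Parameters
    ----------
    coords : (N, 3) array, Å
    source_id : identifier of the source structure (file stem or domain id)
    chain_id : chain the run was taken from
    start_res, end_res : residue labels of the first/last position (number +
        optional insertion code, as printed in the source file)
    sequence : N one-letter codes, 'X' for nonstandard residues
    """

    coords: np.ndarray
    source_id: str = ""
    chain_id: str = ""
    start_res: str = ""
    sequence: str = ""
    end_res: str = ""

    def __post_init__(self):
        self.coords = _as_coord_array(self.coords)
        if not self.sequence:
            self.sequence = "X" * len(self.coords)
        if len(self.sequence) != len(self.coords):
            raise ShapeMismatchError(
                f"sequence length {len(self.sequence)} != {len(self.coords)} coordinates"
            )

    def __len__(self) -> int:
        return len(self.coords)


@dataclass(eq=False)
class CenteredFragment:
    """A fragment translated so its centroid sits at the origin.

    ``origin_offset`` records the subtracted centroid so the translation is
    invertible.
    """

    coords: np.ndarray
    origin_offset: np.ndarray
    source_id: str = ""
    chain_id: str = ""
    start_res: str = ""
    sequence: str = ""
    end_res: str = ""

    def __post_init__(self):
        self.coords = _as_coord_array(self.coords)
        self.origin_offset = np.asarray(self.origin_offset, dtype=float).reshape(3)

    def __len__(self) -> int:
        return len(self.coords)


@dataclass(frozen=True)
class Superposition:
    """A proper rigid-body transform plus the RMSD it achieves.

    ``rotation`` maps centered source points onto centered target points;
    ``translation`` completes the map in the original frames:
    ``x -> rotation @ x + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


# ---------------------------------------------------------------------------
# Centering
# ---------------------------------------------------------------------------

def center(frag: Fragment | CenteredFragment | np.ndarray) -> CenteredFragment:
    """Translate a fragment so its centroid is the origin.

    Idempotent: centering an already-centered fragment keeps the original
    ``origin_offset``.
    """
    if isinstance(frag, CenteredFragment):
        return frag
    if isinstance(frag, Fragment):
        coords, meta = frag.coords, frag
    else:
        coords = _as_coord_array(frag)
        meta = None
    if len(coords) < 1:
        raise ShapeMismatchError("cannot center an empty fragment")
    centroid = coords.mean(axis=0)
    out = CenteredFragment(coords=coords - centroid, origin_offset=centroid)
    if meta is not None:
        out.source_id = meta.source_id
        out.chain_id = meta.chain_id
        out.start_res = meta.start_res
        out.sequence = meta.sequence
        out.end_res = meta.end_res
    return out


def _centered_coords(obj) -> np.ndarray:
    """Centered (N, 3) coordinates of a Fragment/CenteredFragment/array."""
    return center(obj).coords


# ---------------------------------------------------------------------------
# BC score
# ---------------------------------------------------------------------------

def gram_det(centered: np.ndarray) -> float:
    """det(XᵀX) of centered coordinates (3x3 Gram determinant)."""
    g = centered.T @ centered
    return float(np.linalg.det(g))


def is_degenerate(centered: np.ndarray) -> bool:
    """True when the centered point set is too flat for BC (see floor)."""
    g = centered.T @ centered
    tr = float(np.trace(g))
    return float(np.linalg.det(g)) < DEGENERACY_REL_FLOOR * (tr / 3.0) ** 3


def bc_score(X, Y) -> float:
    """Binet-Cauchy similarity between two equal-length fragments.

    Both arguments are centered internally, so raw fragments may be passed.
    Returns a value in [-1, 1]: 1 for identical shapes (up to rotation and
    scale), -1 for mirror images, near 0 for unrelated conformations.

    Raises
    ------
    ShapeMismatchError
        unequal lengths or fewer than 4 points.
    DegenerateFragmentError
        either operand is (near-)collinear or coplanar.
    """
    Xc = _centered_coords(X)
    Yc = _centered_coords(Y)
    if len(Xc) != len(Yc):
        raise ShapeMismatchError(f"length mismatch: {len(Xc)} vs {len(Yc)}")
    if len(Xc) < MIN_BC_POINTS:
        raise ShapeMismatchError(f"BC needs >= {MIN_BC_POINTS} points, got {len(Xc)}")
    dx = gram_det(Xc)
    dy = gram_det(Yc)
    if is_degenerate(Xc) or is_degenerate(Yc):
        raise DegenerateFragmentError("degenerate (collinear/coplanar) fragment")
    raw = float(np.linalg.det(Xc.T @ Yc)) / np.sqrt(dx * dy)
    return _clamp_score(raw)


def _clamp_score(raw: float) -> float:
    if abs(raw) > 1.0 + CLAMP_WARN:
        log.warning("BC score %.12g clamped to [-1, 1]; excursion %.3g", raw, abs(raw) - 1.0)
    return float(min(1.0, max(-1.0, raw)))


# ---------------------------------------------------------------------------
# Rigidity score
# ---------------------------------------------------------------------------

def rigidity_score(X, Y) -> float:
    """Maximum variation of intra-distances between two fragments, in Å.

    The larger of (a) the maximum over residues of the absolute difference
    of distances to the geometric center and (b) the absolute difference of
    the terminal Cα-Cα distances.  Zero for rigidly superposable fragments;
    invariant to rotation and reflection of either argument.
    """
    Xc = _centered_coords(X)
    Yc = _centered_coords(Y)
    if len(Xc) != len(Yc):
        raise ShapeMismatchError(f"length mismatch: {len(Xc)} vs {len(Yc)}")
    if len(Xc) < 2:
        raise ShapeMismatchError("rigidity needs >= 2 points")
    radial = float(np.max(np.abs(np.linalg.norm(Xc, axis=1) - np.linalg.norm(Yc, axis=1))))
    ends = abs(
        float(np.linalg.norm(Xc[-1] - Xc[0])) - float(np.linalg.norm(Yc[-1] - Yc[0]))
    )
    return max(radial, ends)


# ---------------------------------------------------------------------------
# Reflection
# ---------------------------------------------------------------------------

def mirror(frag: Fragment | CenteredFragment | np.ndarray):
    """Reflect a fragment through the xy-plane (negate z).

    Any fixed reflection is equivalent up to a rotation and BC is rotation
    invariant, so the choice of plane is immaterial.  Chirality is inverted,
    all pairwise distances are preserved, and mirror(mirror(X)) == X exactly.
    Returns the same type as its argument.
    """
    if isinstance(frag, (Fragment, CenteredFragment)):
        flipped = frag.coords.copy()
        flipped[:, 2] *= -1.0
        if isinstance(frag, CenteredFragment):
            off = frag.origin_offset.copy()
            off[2] *= -1.0
            return replace(frag, coords=flipped, origin_offset=off)
        return replace(frag, coords=flipped)
    arr = _as_coord_array(frag).copy()
    arr[:, 2] *= -1.0
    return arr


def rotate(frag, R: np.ndarray):
    """Apply a rotation matrix to a fragment (convenience, mainly for tests)."""
    R = np.asarray(R, dtype=float)
    if isinstance(frag, (Fragment, CenteredFragment)):
        out = replace(frag, coords=frag.coords @ R.T)
        if isinstance(out, CenteredFragment):
            out.origin_offset = R @ frag.origin_offset
        return out
    return _as_coord_array(frag) @ R.T


# ---------------------------------------------------------------------------
# Kabsch superposition and RMSD
# ---------------------------------------------------------------------------

def superpose_kabsch(X, Y) -> Superposition:
    """Least-squares proper superposition of X onto Y.

    Uses the SVD form of the Kabsch algorithm; when the unconstrained
    optimum is a reflection, the singular direction with the smallest
    singular value is flipped so the returned rotation has determinant +1.
    """
    Xf = center(X)
    Yf = center(Y)
    if len(Xf) != len(Yf):
        raise ShapeMismatchError(f"length mismatch: {len(Xf)} vs {len(Yf)}")
    if len(Xf) < 3:
        raise ShapeMismatchError("superposition needs >= 3 points")
    Xc, Yc = Xf.coords, Yf.coords
    H = Xc.T @ Yc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = Xc @ R.T - Yc
    value = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    translation = Yf.origin_offset - R @ Xf.origin_offset
    return Superposition(rotation=R, translation=translation, rmsd=value)


def rmsd(X, Y) -> float:
    """Minimum RMSD between two fragments after centering + Kabsch rotation."""
    return superpose_kabsch(X, Y).rmsd
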