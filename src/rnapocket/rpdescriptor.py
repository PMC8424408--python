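"""NPR shape descriptors and sphere/disc/rod classification of pockets.

A pocket mask is treated as a uniform-density body: unit mass at the center
of every occupied voxel.  The inertia tensor about the center of mass gives
principal moments I11 ≤ I22 ≤ I33, and the normalized ratios

    rpd1 = I11 / I33,   rpd2 = I22 / I33

place the pocket inside an isosceles triangle with vertices

    rod (0, 1),   sphere (1, 1),   disc (1/2, 1/2),

geometric center O = (1/2, 5/6).  Shape scores

    s1 = rpd1 + rpd2 - 1   (sphere-likeness)
    s2 = 2 - 2·rpd2        (disc-likeness)
    s3 = rpd2 - rpd1       (rod-likeness)

sum to 1 everywhere; the similarity score s_i = max(s1, s2, s3) lies in
[1/3, 1] (1/3 at O — maximally irregular; 1 at a vertex — a perfect sphere,
disc or rod).  Classification by largest score coincides with the geometric
partition of the triangle by the three lines through O and each vertex
(each such line is a locus where two scores tie).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pocket_detection import VoxelGrid

__all__ = [
    "InertiaResult",
    "ShapeDescriptor",
    "DegenerateShapeError",
    "TriangleDomainError",
    "inertia",
    "npr",
    "shape_scores",
    "classify",
    "describe_pocket",
    "resample_mask",
    "VERTEX_ROD",
    "VERTEX_SPHERE",
    "VERTEX_DISC",
    "CENTER_O",
]

VERTEX_ROD = (0.0, 1.0)
VERTEX_SPHERE = (1.0, 1.0)
VERTEX_DISC = (0.5, 0.5)
CENTER_O = (0.5, 5.0 / 6.0)

#: default grid spacing (Å) for descriptor calculations
DESCRIPTOR_SPACING = 1.0

_SNAP_TOL = 1e-9
_TIE_TOL = 1e-12
#: boundary-tie preference, most symmetric shape first
_TIE_ORDER = ("sphere", "disc", "rod")


class DegenerateShapeError(ValueError):
    """Too few (or collinear-to-a-point) voxels for an inertia tensor."""


class TriangleDomainError(ValueError):
    """(rpd1, rpd2) lies outside the NPR triangle."""


@dataclass(frozen=True)
class InertiaResult:
    """Principal moments of inertia (ascending) about the center of mass."""

    center_of_mass: np.ndarray  # (3,), Å
    principal_moments: np.ndarray  # (I11, I22, I33), ascending


@dataclass(frozen=True)
class ShapeDescriptor:
    """NPR point, shape scores, class label and similarity score."""

    rpd1: float
    rpd2: float
    s1: float
    s2: float
    s3: float
    shape_class: str  # "sphere" | "disc" | "rod"
    similarity: float  # s_i = max(s1, s2, s3), in [1/3, 1]
    boundary_flag: bool


def inertia(mask: VoxelGrid) -> InertiaResult:
    """Inertia tensor of unit masses at occupied voxel centers.

    I_ab = Σ (|r|² δ_ab − r_a r_b) about the center of mass; eigenvalues
    are returned in ascending order.
    """
    pts = mask.voxel_centers()
    return inertia_of_points(pts)


def inertia_of_points(pts: np.ndarray) -> InertiaResult:
    """Inertia of unit point masses (used directly for analytic point sets)."""
    pts = np.asarray(pts, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise DegenerateShapeError("need at least 2 occupied voxels")
    com = pts.mean(axis=0)
    r = pts - com
    if not np.any(np.abs(r) > 0):
        raise DegenerateShapeError("all voxel centers coincide")
    r2 = (r**2).sum(axis=1)
    tensor = np.eye(3) * r2.sum() - r.T @ r
    moments = np.linalg.eigvalsh(tensor)
    moments = np.clip(moments, 0.0, None)
    return InertiaResult(center_of_mass=com, principal_moments=moments)


def npr(mask: VoxelGrid) -> tuple[float, float]:
    """Normalized PMI ratios (rpd1, rpd2) = (I11/I33, I22/I33)."""
    res = inertia(mask)
    i11, i22, i33 = res.principal_moments
    if not i33 > 0:
        raise DegenerateShapeError("I33 = 0: degenerate shape")
    return float(i11 / i33), float(i22 / i33)


def _snap_to_triangle(rpd1: float, rpd2: float) -> tuple[float, float]:
    """Validate the point and snap tiny numerical violations to the boundary."""
    violations = (
        (1.0 - (rpd1 + rpd2)),  # below lower-left edge
        (rpd2 - 1.0),  # above top edge
        (rpd1 - rpd2),  # right of the rpd1 = rpd2 edge
    )
    worst = max(violations)
    if worst > _SNAP_TOL:
        raise TriangleDomainError(
            f"({rpd1}, {rpd2}) outside the NPR triangle by {worst:.3g}"
        )
    if rpd1 + rpd2 < 1.0:
        deficit = 1.0 - (rpd1 + rpd2)
        rpd1 += deficit / 2.0
        rpd2 += deficit / 2.0
    rpd2 = min(rpd2, 1.0)
    rpd1 = min(rpd1, rpd2)
    return rpd1, rpd2


def shape_scores(rpd1: float, rpd2: float) -> tuple[float, float, float]:
    """Shape scores (s1, s2, s3): sphere-, disc-, rod-likeness; sum = 1."""
    rpd1, rpd2 = _snap_to_triangle(float(rpd1), float(rpd2))
    s1 = rpd1 + rpd2 - 1.0
    s2 = 2.0 - 2.0 * rpd2
    s3 = rpd2 - rpd1
    return s1, s2, s3


def _classify_by_score(
    s1: float, s2: float, s3: float
) -> tuple[str, float, bool]:
    scores = {"sphere": s1, "disc": s2, "rod": s3}
    best = max(scores.values())
    winners = [c for c in _TIE_ORDER if scores[c] >= best - _TIE_TOL]
    return winners[0], best, len(winners) > 1


def _side(p, a, b) -> float:
    """Signed area cross product: >0 when p is left of the ray a→b."""
    return (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])


def _classify_by_region(rpd1: float, rpd2: float) -> tuple[str, float, bool]:
    """Locate the point in the partition cut by the three O–vertex lines.

    Each line through O and a vertex is extended across the triangle; the
    three lines meet only at O and carve three regions, one per vertex.
    The similarity score is still reported from the score formulas, but the
    class decision here is purely geometric.
    """
    p = (rpd1, rpd2)
    lines = {
        "sphere": (CENTER_O, VERTEX_SPHERE),
        "disc": (CENTER_O, VERTEX_DISC),
        "rod": (CENTER_O, VERTEX_ROD),
    }
    # signed side of p w.r.t. each O–vertex line, and of the vertex itself
    winners = []
    for cls in _TIE_ORDER:
        ok = True
        on_boundary = False
        for other, (a, b) in lines.items():
            if other == cls:
                continue
            sp = _side(p, a, b)
            sv = _side(lines[cls][1], a, b)  # the class vertex
            if abs(sp) <= _TIE_TOL:
                on_boundary = True
            elif sp * sv < 0:
                ok = False
                break
        if ok:
            winners.append((cls, on_boundary))
    s1, s2, s3 = shape_scores(rpd1, rpd2)
    best = max(s1, s2, s3)
    cls, on_boundary = winners[0]
    boundary = on_boundary or len(winners) > 1
    return cls, best, boundary


def classify(
    rpd1: float, rpd2: float, method: str = "score"
) -> tuple[str, float, bool]:
    """Classify an NPR point as sphere-, disc- or rod-like.

    ``method="score"`` takes the argmax of (s1, s2, s3); ``method="region"``
    locates the point geometrically among the regions cut by the three
    lines through O and the triangle vertices.  The two agree everywhere;
    exact ties on a boundary are flagged and broken sphere > disc > rod.

    Returns ``(shape_class, s_i, boundary_flag)``.
    """
    rpd1, rpd2 = _snap_to_triangle(float(rpd1), float(rpd2))
    if method == "score":
        return _classify_by_score(*shape_scores(rpd1, rpd2))
    if method == "region":
        return _classify_by_region(rpd1, rpd2)
    raise ValueError(f"unknown method {method!r}")


def resample_mask(mask: VoxelGrid, spacing: float = DESCRIPTOR_SPACING) -> VoxelGrid:
    """Nearest-neighbour resampling of a mask onto a new grid spacing."""
    if abs(mask.spacing - spacing) < 1e-12:
        return mask
    lo = mask.origin
    extent = np.array(mask.dims) * mask.spacing
    dims = np.maximum(np.ceil(extent / spacing).astype(int), 1)
    ii, jj, kk = np.meshgrid(*(np.arange(d) for d in dims), indexing="ij")
    centers = lo + spacing * (np.stack([ii, jj, kk], axis=-1) + 0.5)
    src = np.floor((centers - lo) / mask.spacing).astype(int)
    valid = np.all((src >= 0) & (src < np.array(mask.dims)), axis=-1)
    occ = np.zeros(tuple(dims), dtype=bool)
    sv = src[valid]
    occ[valid] = mask.occupancy[sv[:, 0], sv[:, 1], sv[:, 2]]
    return VoxelGrid(lo.copy(), spacing, occ)


def describe_pocket(
    mask: VoxelGrid, spacing: float = DESCRIPTOR_SPACING
) -> ShapeDescriptor:
    """Full descriptor workflow: resample → inertia → NPR → scores → class."""
    work = resample_mask(mask, spacing) if spacing else mask
    if work.n_occupied < 2:
        # resampling a tiny mask to a coarser grid can starve it of voxels
        work = mask
    rpd1, rpd2 = npr(work)
    rpd1, rpd2 = _snap_to_triangle(rpd1, rpd2)
    s1, s2, s3 = shape_scores(rpd1, rpd2)
    cls, s_i, boundary = classify(rpd1, rpd2, method="score")
    return ShapeDescriptor(
        rpd1=rpd1,
        rpd2=rpd2,
        s1=s1,
        s2=s2,
        s3=s3,
        shape_class=cls,
        similarity=s_i,
        boundary_flag=boundary,
    )
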