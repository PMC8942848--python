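"""Superposition and inter-state displacement / kink / axial-rotation metrics.

Conventions: "global alignment" means Kabsch superposition on all common
C-alpha atoms of one protomer (receptor chains only); helix axes are oriented
N->C; angles are reported in degrees in [0, 180].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateGeometryError,
    NoCommonResiduesError,
    PairingError,
)
from .model import ResidueRef, StructureModel

__all__ = [
    "Superposition",
    "HelixAxis",
    "DisplacementReport",
    "kabsch_superpose",
    "pair_common_calpha",
    "aligned_rmsd",
    "residue_displacement",
    "fit_helix_axis",
    "fit_axis_points",
    "kink_angle",
    "axial_rotation_angle",
]


@dataclass
class Superposition:
    """Optimal rigid transform mapping a mobile point set onto a reference."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int
    atom_selection: list[ResidueRef] | None = None

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


@dataclass
class HelixAxis:
    centroid: np.ndarray
    direction: np.ndarray  # unit vector, oriented N->C
    residue_range: tuple[int, int]
    fit_residual: float  # rms perpendicular distance, A


@dataclass
class DisplacementReport:
    """Per-residue C-alpha displacements after global alignment."""

    align_protomer: str
    n_aligned: int
    rmsd: float
    entries: list[tuple[ResidueRef, float | None, bool]] = field(default_factory=list)

    def value(self, res_id: int) -> float | None:
        for ref, val, missing in self.entries:
            if ref.res_id == res_id and not missing:
                return val
        return None

    def as_dict(self) -> dict:
        return {
            "align_protomer": self.align_protomer,
            "n_aligned": self.n_aligned,
            "rmsd": self.rmsd,
            "displacements": [
                {"residue": str(ref), "res_id": ref.res_id, "value": val, "missing": missing}
                for ref, val, missing in self.entries
            ],
        }


def kabsch_superpose(mobile, reference) -> Superposition:
    """Least-squares optimal rigid superposition (SVD Kabsch).

    Returns the transform that maps ``mobile`` onto ``reference`` as
    ``x @ R.T + t``, with proper rotation (det = +1).
    """
    mob = np.asarray(mobile, float)
    ref = np.asarray(reference, float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise PairingError(f"point sets differ in shape: {mob.shape} vs {ref.shape}")
    if len(mob) < 3:
        raise PairingError(f"need >= 3 paired points, got {len(mob)}")
    cm, cr = mob.mean(axis=0), ref.mean(axis=0)
    p, q = mob - cm, ref - cr
    # collinear / coincident sets leave the rotation underdetermined
    if min(np.linalg.matrix_rank(p, tol=1e-8), np.linalg.matrix_rank(q, tol=1e-8)) < 2:
        raise DegenerateGeometryError("point set is collinear or degenerate")
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cr - rot @ cm
    moved = mob @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd, n_atoms=len(mob))


def _calpha_table(model: StructureModel, protomer: str) -> dict[tuple[int, str], int]:
    mask = model.calpha_mask(protomer)
    table: dict[tuple[int, str], int] = {}
    for i in np.flatnonzero(mask):
        key = (int(model.res_ids[i]), str(model.ins_codes[i]))
        table.setdefault(key, int(i))
    return table


def pair_common_calpha(
    a: StructureModel,
    b: StructureModel,
    protomer: str = "A",
    selection=None,
):
    """C-alpha pairs for residues modelled in both structures.

    Pairing is by (author residue number, insertion code) within the named
    protomer, ordered by residue number.  Returns
    ``(coords_a, coords_b, refs)``.
    """
    ta, tb = _calpha_table(a, protomer), _calpha_table(b, protomer)
    common = sorted(set(ta) & set(tb))
    if selection is not None:
        wanted = {(r, "") if isinstance(r, int) else r for r in selection}
        common = [k for k in common if k in wanted or k[0] in {w[0] for w in wanted}]
    if not common:
        raise NoCommonResiduesError(
            f"no common protomer-{protomer} residues between "
            f"{a.source_id!r} and {b.source_id!r}"
        )
    ia = [ta[k] for k in common]
    ib = [tb[k] for k in common]
    refs = [
        a.residue_ref(str(a.chain_ids[i]), int(a.res_ids[i]), str(a.ins_codes[i]))
        for i in ia
    ]
    return a.coords[ia], b.coords[ib], refs


def aligned_rmsd(a: StructureModel, b: StructureModel, protomer: str = "A") -> Superposition:
    """Kabsch RMSD over the common C-alpha pairing of one protomer."""
    ca, cb, refs = pair_common_calpha(a, b, protomer)
    sup = kabsch_superpose(cb, ca)  # transform maps b onto a
    sup.atom_selection = refs
    return sup


def _target_key(target):
    if isinstance(target, ResidueRef):
        return (target.res_id, target.ins_code)
    if isinstance(target, int):
        return (target, "")
    return (int(target[0]), str(target[1]))


def residue_displacement(
    a: StructureModel,
    b: StructureModel,
    align_protomer: str = "A",
    targets=(),
    target_protomer: str | None = None,
) -> DisplacementReport:
    """C-alpha displacement of target residues after global alignment.

    ``b`` is superposed onto ``a`` over the common C-alpha set of
    ``align_protomer``; the report holds the Euclidean distance between
    corresponding target C-alpha positions.  Unmodelled targets are flagged
    per-target, never a global failure.
    """
    sup = aligned_rmsd(a, b, align_protomer)
    protomer = target_protomer or align_protomer
    ta, tb = _calpha_table(a, protomer), _calpha_table(b, protomer)
    report = DisplacementReport(
        align_protomer=align_protomer, n_aligned=sup.n_atoms, rmsd=sup.rmsd
    )
    for target in targets:
        key = _target_key(target)
        ref = ResidueRef(protomer=protomer, res_id=key[0], ins_code=key[1])
        if key not in ta or key not in tb:
            report.entries.append((ref, None, True))
            continue
        ia, ib = ta[key], tb[key]
        ref = a.residue_ref(
            str(a.chain_ids[ia]), int(a.res_ids[ia]), str(a.ins_codes[ia])
        )
        moved = sup.apply(b.coords[ib])
        dist = float(np.linalg.norm(a.coords[ia] - moved))
        report.entries.append((ref, dist, False))
    return report


def _pca_direction(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-10:
        raise DegenerateGeometryError("coincident points: no axis")
    return vt[0]


def fit_axis_points(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares helix axis of an ordered C-alpha trace.

    Direction comes from second-difference cross products (exact for an
    ideal helix, where plain PCA of a few turns is biased); the axis point
    is the center of a circle fitted to the points projected onto the
    perpendicular plane.  Falls back to PCA for short or degenerate traces.
    Returns ``(axis_point, unit_direction, residual)`` with the direction
    oriented first -> last point and the residual the rms spread of radial
    distances (cylindricity, A).
    """
    coords = np.asarray(coords, float)
    n = len(coords)
    if n < 4:
        raise DegenerateGeometryError(f"need >= 4 points for an axis fit, got {n}")
    direction = None
    if n >= 6:
        v = coords[:-2] - 2 * coords[1:-1] + coords[2:]
        w = np.cross(v[:-1], v[1:])
        norms = np.linalg.norm(w, axis=1)
        good = norms > 1e-8
        if good.sum() >= 2:
            chord = coords[-1] - coords[0]
            w = w[good] / norms[good][:, None]
            w *= np.sign(w @ chord)[:, None]
            mean = w.mean(axis=0)
            if np.linalg.norm(mean) > 0.5:
                direction = mean / np.linalg.norm(mean)
    if direction is None:
        direction = _pca_direction(coords)
    if np.dot(direction, coords[-1] - coords[0]) < 0:
        direction = -direction

    # axis point: circle fit in the plane perpendicular to the direction
    basis = np.linalg.svd(np.eye(3) - np.outer(direction, direction))[0][:, :2]
    q = coords @ basis  # (n, 2) projections
    a = np.column_stack([2 * q, np.ones(n)])
    try:
        sol, _, rank, _ = np.linalg.lstsq(a, np.sum(q**2, axis=1), rcond=None)
    except np.linalg.LinAlgError:
        rank = 0
    centroid = coords.mean(axis=0)
    if rank == 3 and np.isfinite(sol[:2]).all():
        center2d = sol[:2]
        axis_point = basis @ center2d + np.dot(centroid, direction) * direction
    else:
        axis_point = centroid
    radial = np.linalg.norm(
        (coords - axis_point)
        - np.outer((coords - axis_point) @ direction, direction),
        axis=1,
    )
    residual = float(np.sqrt(np.mean((radial - radial.mean()) ** 2)))
    return axis_point, direction, residual


def fit_helix_axis(
    model: StructureModel, protomer: str, residue_range: tuple[int, int]
) -> HelixAxis:
    """Least-squares axis of the C-alpha trace of a helix segment."""
    coords = _segment_calphas(model, protomer, residue_range)
    centroid, direction, residual = fit_axis_points(coords)
    return HelixAxis(
        centroid=centroid,
        direction=direction,
        residue_range=tuple(residue_range),
        fit_residual=residual,
    )


def _segment_calphas(model, protomer, residue_range):
    table = _calpha_table(model, protomer)
    lo, hi = residue_range
    keys = sorted(k for k in table if lo <= k[0] <= hi)
    if len(keys) < 4:
        raise DegenerateGeometryError(
            f"segment {residue_range} has only {len(keys)} C-alpha atoms"
        )
    return model.coords[[table[k] for k in keys]]


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    cosang = float(np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1))
    return float(np.degrees(np.arccos(cosang)))


def kink_angle(
    model_a: StructureModel,
    model_b: StructureModel,
    protomer: str,
    segment: tuple[int, int],
    align_protomer: str | None = "A",
) -> float:
    """Angle between the two states' segment axes after global alignment."""
    if align_protomer is not None:
        sup = aligned_rmsd(model_a, model_b, align_protomer)
        model_b = model_b.transformed(sup.rotation, sup.translation)
    axis_a = fit_helix_axis(model_a, protomer, segment)
    axis_b = fit_helix_axis(model_b, protomer, segment)
    return _angle_between(axis_a.direction, axis_b.direction)


def _minimal_rotation(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Smallest rotation taking unit vector src to dst (Rodrigues)."""
    v = np.cross(src, dst)
    c = float(np.dot(src, dst))
    s = np.linalg.norm(v)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any perpendicular axis
        perp = np.cross(src, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(src, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return rotation_about_axis(perp, 180.0)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def rotation_about_axis(axis, degrees: float) -> np.ndarray:
    """Rotation matrix about a unit axis through the origin."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    theta = np.radians(degrees)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(theta) * k + (1 - np.cos(theta)) * (k @ k)


def axial_rotation_angle(
    model_a: StructureModel,
    model_b: StructureModel,
    protomer: str,
    segment: tuple[int, int],
) -> float:
    """Rotation of a helix segment about its own axis between two states.

    The tilt component is removed by rotating state B's segment so its axis
    matches state A's; the axial component is then the circular mean of the
    per-residue angular shifts of the C-alpha positions projected onto the
    plane perpendicular to the axis.  Returned in [0, 180].
    """
    ca = _segment_calphas(model_a, protomer, segment)
    cb = _segment_calphas(model_b, protomer, segment)
    if len(ca) != len(cb):
        # pair on common residues instead
        coords_a, coords_b, _ = pair_common_calpha(
            model_a, model_b, protomer, selection=range(segment[0], segment[1] + 1)
        )
        ca, cb = coords_a, coords_b
    cen_a, dir_a, _ = fit_axis_points(ca)
    cen_b, dir_b, _ = fit_axis_points(cb)
    r_align = _minimal_rotation(dir_b, dir_a)
    pb = (cb - cen_b) @ r_align.T
    pa = ca - cen_a
    n = dir_a
    proj = lambda v: v - np.outer(v @ n, n)
    qa, qb = proj(pa), proj(pb)
    angles = []
    for va, vb in zip(qa, qb):
        if np.linalg.norm(va) < 0.1 or np.linalg.norm(vb) < 0.1:
            continue
        ang = np.arctan2(np.dot(n, np.cross(va, vb)), np.dot(va, vb))
        angles.append(ang)
    if not angles:
        raise DegenerateGeometryError("no off-axis points to measure axial rotation")
    mean = np.angle(np.mean(np.exp(1j * np.asarray(angles))))
    return float(abs(np.degrees(mean)))
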