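"""Synthetic inputs with known ground truth.

Everything here is seed-deterministic: toy dimer structures with planted
rigid sub-segment motions, coupled-torsion trajectories whose coordinates
are rebuilt by NeRF chain extension (so torsion extraction inverts the
generator exactly), and contact time series with planted presence
frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .geometry import fit_axis_points, rotation_about_axis
from .model import StructureModel
from .trajectory import Trajectory, TorsionSeries, wrap_angle

__all__ = [
    "SyntheticSpec",
    "PlantedTransform",
    "make_ideal_helix",
    "make_toy_dimer_states",
    "simulate_coupled_torsion_trajectory",
    "plant_contact_series",
    "nerf_place",
]

CA_CA_DISTANCE = 3.8  # A, consecutive alpha carbons


@dataclass
class PlantedTransform:
    """Rigid motion applied to an inclusive residue segment of one chain."""

    chain: str
    start: int
    end: int
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    hinge_deg: float = 0.0
    hinge_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    axial_deg: float = 0.0


@dataclass
class SyntheticSpec:
    """Parameters for the synthetic generators (CLI/config container)."""

    n_residues: int = 30
    rise: float = 1.5
    twist: float = 100.0
    transforms: list[PlantedTransform] = field(default_factory=list)
    planted_chain: list[int] = field(default_factory=list)
    kappa: float = 8.0
    mode_offset_deg: float = 120.0
    n_modes: int = 2
    mode_stay_prob: float | None = None  # None -> i.i.d. mode switching
    n_frames: int = 1000
    contact_plants: list[tuple[float]] = field(default_factory=list)  # frequencies
    noise_sigma: float = 0.0
    seed: int = 0


def helix_radius(rise: float, twist_deg: float, ca_ca: float = CA_CA_DISTANCE) -> float:
    """Closed-form helix radius giving the requested CA-CA bond length."""
    theta = np.radians(twist_deg)
    num = ca_ca**2 - rise**2
    if num <= 0:
        raise ConfigurationError("rise exceeds the CA-CA distance; no helix exists")
    return float(np.sqrt(num / (2.0 * (1.0 - np.cos(theta)))))


def make_ideal_helix(
    n: int,
    rise: float = 1.5,
    twist: float = 100.0,
    chain_id: str = "R",
    start_res: int = 1,
    res_name: str = "ALA",
    with_cb: bool = False,
    origin=(0.0, 0.0, 0.0),
) -> StructureModel:
    """Ideal alpha-helical C-alpha trace along +z (optionally with CB stubs)."""
    if n < 4:
        raise ConfigurationError(f"need >= 4 residues for a helix, got {n}")
    r = helix_radius(rise, twist)
    theta = np.radians(twist) * np.arange(n)
    ca = np.column_stack([r * np.cos(theta), r * np.sin(theta), rise * np.arange(n)])
    ca += np.asarray(origin, float)
    coords, names, elements, res_ids = [], [], [], []
    axis_point = np.asarray(origin, float)
    for i in range(n):
        coords.append(ca[i])
        names.append("CA")
        elements.append("C")
        res_ids.append(start_res + i)
        if with_cb:
            radial = ca[i] - np.array([axis_point[0], axis_point[1], ca[i][2]])
            radial /= np.linalg.norm(radial)
            coords.append(ca[i] + 1.53 * radial)
            names.append("CB")
            elements.append("C")
            res_ids.append(start_res + i)
    n_atoms = len(coords)
    return StructureModel(
        chain_ids=[chain_id] * n_atoms,
        res_ids=res_ids,
        ins_codes=[""] * n_atoms,
        res_names=[res_name] * n_atoms,
        atom_names=names,
        elements=elements,
        coords=np.asarray(coords),
        protomer_map={chain_id: "A"},
        source_id="ideal-helix",
    )


def make_toy_dimer_states(spec: SyntheticSpec):
    """Two-state toy dimer with planted rigid sub-segment motions.

    Returns ``(state_a, state_b, ground_truth)`` where the ground truth
    records the exact per-residue C-alpha displacement and the planted
    hinge/axial angles per transform.
    """
    helix_a = make_ideal_helix(spec.n_residues, spec.rise, spec.twist, chain_id="R")
    helix_b = make_ideal_helix(
        spec.n_residues, spec.rise, spec.twist, chain_id="S", origin=(12.0, 0.0, 0.0)
    )
    from .model import concatenate

    state_a = concatenate([helix_a, helix_b], source_id="toy-dimer-A")
    state_a.protomer_map = {"R": "A", "S": "B"}

    # validate segment disjointness per chain
    by_chain: dict[str, list] = {}
    for t in spec.transforms:
        by_chain.setdefault(t.chain, []).append((t.start, t.end, t))
    for chain, spans in by_chain.items():
        spans.sort()
        for (s1, e1, _), (s2, e2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ConfigurationError(f"overlapping planted segments on chain {chain}")

    coords = state_a.coords.copy()
    truth: dict = {"transforms": [], "displacement": {}}
    for t in spec.transforms:
        seg_mask = (
            (state_a.chain_ids == t.chain)
            & (state_a.res_ids >= t.start)
            & (state_a.res_ids <= t.end)
        )
        idx = np.flatnonzero(seg_mask)
        if len(idx) == 0:
            raise ConfigurationError(f"planted segment {t.chain}:{t.start}-{t.end} is empty")
        seg = coords[idx]
        ca_mask = state_a.atom_names[idx] == "CA"
        if t.axial_deg:
            centroid, direction, _ = fit_axis_points(seg[ca_mask])
            rot = rotation_about_axis(direction, t.axial_deg)
            seg = (seg - centroid) @ rot.T + centroid
        if t.hinge_deg:
            pivot = coords[idx[0]]
            rot = rotation_about_axis(np.asarray(t.hinge_axis, float), t.hinge_deg)
            seg = (seg - pivot) @ rot.T + pivot
        seg = seg + np.asarray(t.translation, float)
        coords[idx] = seg
        truth["transforms"].append(
            {
                "chain": t.chain,
                "segment": [t.start, t.end],
                "translation": list(t.translation),
                "hinge_deg": t.hinge_deg,
                "axial_deg": t.axial_deg,
            }
        )
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        coords = coords + rng.normal(0.0, spec.noise_sigma, coords.shape)
    state_b = state_a.with_coords(coords)
    state_b.source_id = "toy-dimer-B"
    ca_all = state_a.atom_names == "CA"
    for i in np.flatnonzero(ca_all):
        key = (str(state_a.chain_ids[i]), int(state_a.res_ids[i]))
        truth["displacement"][key] = float(
            np.linalg.norm(state_b.coords[i] - state_a.coords[i])
        )
    return state_a, state_b, truth


# ----------------------------------------------------------------------- NeRF
def nerf_place(a, b, c, bond: float, angle_deg: float, torsion_deg):
    """Place atom D given three predecessors so that |CD| = bond,
    angle(B,C,D) = angle_deg and dihedral(A,B,C,D) = torsion_deg (IUPAC).

    Inputs may be (3,) or (F, 3) arrays; torsion may be scalar or (F,).
    """
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    theta = np.radians(angle_deg)
    phi = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    phi = np.broadcast_to(np.asarray(phi, float), bc.shape[:-1])
    d_bc = -bond * np.cos(theta)
    d_m = bond * np.sin(theta) * np.cos(phi)
    d_n = bond * np.sin(theta) * np.sin(phi)
    return c + d_bc * bc + d_m[..., None] * m + d_n[..., None] * n


# internal geometry constants for the serine-like rebuild chain
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.0, 116.6, 121.9
_B_CA_CB, _A_N_CA_CB, _T_C_N_CA_CB = 1.530, 110.5, 122.5
_B_CB_OG, _A_CA_CB_OG = 1.417, 110.8
_OMEGA = 180.0


def _rebuild_chain(phi, psi, chi1) -> np.ndarray:
    """NeRF rebuild of an all-SER chain from torsions.

    ``phi/psi/chi1``: (F, n_res) arrays in degrees.  phi[ :, 0] and
    psi[:, -1] are ignored (undefined at termini).  Returns coordinates
    (F, n_res * 5, 3) with atom order N, CA, C, CB, OG per residue.
    """
    f, n_res = phi.shape
    atoms = np.zeros((f, n_res, 5, 3))
    # residue 1 in a canonical pose
    atoms[:, 0, 0] = [0.0, 0.0, 0.0]
    atoms[:, 0, 1] = [_B_N_CA, 0.0, 0.0]
    ang = np.radians(180.0 - _A_N_CA_C)
    atoms[:, 0, 2] = atoms[:, 0, 1] + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(n_res):
        n_i, ca_i, c_i = atoms[:, i, 0], atoms[:, i, 1], atoms[:, i, 2]
        if i > 0:
            prev_n, prev_ca, prev_c = atoms[:, i - 1, 0], atoms[:, i - 1, 1], atoms[:, i - 1, 2]
            n_i = nerf_place(prev_n, prev_ca, prev_c, _B_C_N, _A_CA_C_N, psi[:, i - 1])
            ca_i = nerf_place(prev_ca, prev_c, n_i, _B_N_CA, _A_C_N_CA, _OMEGA)
            c_i = nerf_place(prev_c, n_i, ca_i, _B_CA_C, _A_N_CA_C, phi[:, i])
            atoms[:, i, 0], atoms[:, i, 1], atoms[:, i, 2] = n_i, ca_i, c_i
        cb = nerf_place(c_i, n_i, ca_i, _B_CA_CB, _A_N_CA_CB, _T_C_N_CA_CB)
        og = nerf_place(n_i, ca_i, cb, _B_CB_OG, _A_CA_CB_OG, chi1[:, i])
        atoms[:, i, 3], atoms[:, i, 4] = cb, og
    return atoms.reshape(f, n_res * 5, 3)


def _chain_topology(n_res: int, chain_id: str = "T") -> StructureModel:
    names = ["N", "CA", "C", "CB", "OG"] * n_res
    elements = ["N", "C", "C", "C", "O"] * n_res
    res_ids = np.repeat(np.arange(1, n_res + 1), 5)
    return StructureModel(
        chain_ids=[chain_id] * (5 * n_res),
        res_ids=res_ids,
        ins_codes=[""] * (5 * n_res),
        res_names=["SER"] * (5 * n_res),
        atom_names=names,
        elements=elements,
        coords=np.zeros((5 * n_res, 3)),
        protomer_map={chain_id: "A"},
        source_id="synthetic-torsion-chain",
    )


def simulate_coupled_torsion_trajectory(spec: SyntheticSpec):
    """Torsion trajectory with a planted chain of mode-coupled residues.

    Null residues draw phi/psi/chi1 independently from von Mises
    distributions; residues listed in ``spec.planted_chain`` (1-based residue
    numbers) share a hidden mode sequence that offsets all three torsion
    means by ``mode * mode_offset_deg``, inducing mutual information along
    the chain.  Coordinates are rebuilt with NeRF so that torsion extraction
    recovers the generated angles exactly.

    Returns ``(trajectory, ground_truth_series, modes)``.
    """
    if spec.n_frames < 100:
        raise ConfigurationError("need >= 100 frames for a torsion trajectory")
    n_res = spec.n_residues
    for r in spec.planted_chain:
        if not 1 <= r <= n_res:
            raise ConfigurationError(f"planted residue {r} outside 1..{n_res}")
    rng = np.random.default_rng(spec.seed)
    f = spec.n_frames

    # hidden mode sequence shared by the planted chain
    if spec.mode_stay_prob is None:
        modes = rng.integers(0, spec.n_modes, size=f)
    else:
        modes = np.empty(f, dtype=int)
        modes[0] = rng.integers(0, spec.n_modes)
        for t in range(1, f):
            if rng.random() < spec.mode_stay_prob:
                modes[t] = modes[t - 1]
            else:
                modes[t] = rng.integers(0, spec.n_modes)

    base_mu = rng.uniform(-150.0, 150.0, size=(n_res, 3))
    angles = np.empty((f, n_res, 3))
    planted = set(spec.planted_chain)
    for r in range(n_res):
        for t in range(3):
            mu = np.full(f, base_mu[r, t])
            if (r + 1) in planted:
                mu = mu + modes * spec.mode_offset_deg
            angles[:, r, t] = np.degrees(
                rng.vonmises(np.radians(mu), spec.kappa)
            )
    angles = wrap_angle(angles)

    coords = _rebuild_chain(angles[:, :, 0], angles[:, :, 1], angles[:, :, 2])
    topo = _chain_topology(n_res)
    topo = topo.with_coords(coords[0])
    traj = Trajectory(topo, coords, source="synthetic-coupled-torsions")

    mask = np.ones((n_res, 3), bool)
    mask[0, 0] = False  # phi undefined at N terminus
    mask[-1, 1] = False  # psi undefined at C terminus
    truth = TorsionSeries(
        residues=[("T", r + 1, "") for r in range(n_res)],
        angles=angles,
        mask=mask,
        res_names=["SER"] * n_res,
    )
    return traj, truth, modes


def plant_contact_series(spec: SyntheticSpec):
    """Trajectory in which planted residue pairs meet exact contact frequencies.

    ``spec.contact_plants`` is a list of frequencies; pair ``k`` couples
    residue ``k+1`` of chain R with residue ``k+1`` of chain S.  Frequencies
    must be exactly representable with ``n_frames`` frames.  Returns
    ``(trajectory, ground_truth)``.
    """
    n_pairs = len(spec.contact_plants)
    if n_pairs == 0:
        raise ConfigurationError("no contact plants specified")
    f = spec.n_frames
    rng = np.random.default_rng(spec.seed)
    counts = []
    for freq in spec.contact_plants:
        if not 0.0 <= freq <= 1.0:
            raise ConfigurationError(f"contact frequency {freq} outside [0, 1]")
        k = freq * f
        if abs(k - round(k)) > 1e-9:
            raise ConfigurationError(
                f"frequency {freq} not representable with {f} frames"
            )
        counts.append(int(round(k)))

    spacing = 10.0
    xs = spacing * np.arange(n_pairs)
    coords_r = np.column_stack([xs, np.zeros(n_pairs), np.zeros(n_pairs)])
    far = np.column_stack([xs, np.full(n_pairs, 50.0), np.zeros(n_pairs)])
    near = coords_r + np.array([3.0, 0.0, 0.0])

    topo = StructureModel(
        chain_ids=["R"] * n_pairs + ["S"] * n_pairs,
        res_ids=list(range(1, n_pairs + 1)) * 2,
        ins_codes=[""] * (2 * n_pairs),
        res_names=["ALA"] * (2 * n_pairs),
        atom_names=["CA"] * (2 * n_pairs),
        elements=["C"] * (2 * n_pairs),
        coords=np.vstack([coords_r, far]),
        protomer_map={"R": "A", "S": "B"},
        source_id="synthetic-contacts",
    )
    coords = np.tile(topo.coords, (f, 1, 1))
    truth = {}
    for k, n_contact in enumerate(counts):
        contact_frames = rng.permutation(f)[:n_contact]
        coords[contact_frames, n_pairs + k, :] = near[k]
        truth[(("R", k + 1), ("S", k + 1))] = n_contact / f
    return Trajectory(topo, coords, source="synthetic-contacts"), truth
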