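"""Dimer-interface analysis: SASA, buried area, typed contacts, persistence
over trajectories and a reduced inter-group interaction energy.

Contact criteria (geometric, heavy-atom based):

* van der Waals: d <= r_vdw(i) + r_vdw(j) + 0.5 A
* hydrogen bond: donor-acceptor N/O (or S) pair <= 3.5 A; when an explicit
  hydrogen is bonded to the donor, the D-H...A angle must be >= 110 deg
* salt bridge: charged-group nitrogen/oxygen pair <= 4.0 A
* cation-pi: cationic nitrogen <= 6.0 A from an aromatic ring centroid, at
  most 60 deg off the ring normal
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError, DimerRequiredError, DimerStateError
from .model import StructureModel, concatenate, residue_key
from .params import COULOMB_CONSTANT, ForcefieldParams, vdw_radius_array

__all__ = [
    "SasaResult",
    "ContactRecord",
    "InterfaceReport",
    "PersistenceResult",
    "shrake_rupley_sasa",
    "buried_interface_area",
    "detect_contacts",
    "contact_persistence",
    "interface_interaction_energy",
    "ligand_contact_residues",
    "interface_report",
]

VDW_MARGIN = 0.5
HBOND_CUTOFF = 3.5
HBOND_MIN_ANGLE = 110.0
SALT_BRIDGE_CUTOFF = 4.0
CATION_PI_CUTOFF = 6.0
CATION_PI_MAX_OFFNORMAL = 60.0

# donor/acceptor capability by residue and atom name; backbone N/O handled
# separately.  Sulfur donors/acceptors intentionally omitted.
_SIDECHAIN_DONORS = {
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("LYS", "NZ"),
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"), ("HIS", "ND1"),
    ("HIS", "NE2"), ("ASN", "ND2"), ("GLN", "NE2"), ("TRP", "NE1"),
}
_SIDECHAIN_ACCEPTORS = {
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("ASN", "OD1"),
    ("GLN", "OE1"), ("HIS", "ND1"), ("HIS", "NE2"),
}
_CATIONIC = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
             ("HIS", "ND1"), ("HIS", "NE2")}
_ANIONIC = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_AROMATIC_RINGS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}


# ----------------------------------------------------------------------- SASA
@dataclass
class SasaResult:
    atom_area: np.ndarray  # A^2 per atom
    residue_area: dict[tuple, float]
    probe: float
    n_points: int

    @property
    def total(self) -> float:
        return float(self.atom_area.sum())


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic near-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def shrake_rupley_sasa(
    model: StructureModel,
    probe: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
) -> SasaResult:
    """Shrake-Rupley solvent-accessible surface area by sphere-point sampling."""
    r = vdw_radius_array(model.elements, radii)
    coords = model.coords
    unit = _sphere_points(n_points)
    expanded = r + probe
    tree = cKDTree(coords)
    max_reach = 2 * expanded.max()
    neighbors = tree.query_ball_point(coords, max_reach)
    areas = np.zeros(len(model))
    for i in range(len(model)):
        nb = [j for j in neighbors[i] if j != i]
        pts = coords[i] + expanded[i] * unit
        if nb:
            d = np.linalg.norm(pts[:, None, :] - coords[nb][None, :, :], axis=2)
            accessible = np.all(d >= expanded[nb][None, :], axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * frac
    residue_area: dict[tuple, float] = {}
    for key, idx in model.residue_atom_indices().items():
        residue_area[key] = float(areas[idx].sum())
    return SasaResult(atom_area=areas, residue_area=residue_area, probe=probe, n_points=n_points)


def _protomer_submodels(model: StructureModel):
    chains_a = model.protomer_chains("A")
    chains_b = model.protomer_chains("B")
    if not chains_a or not chains_b:
        raise DimerRequiredError("both protomers A and B must be assigned")
    base = ~model.hetero
    sub_a = model.subset(model.chain_mask(chains_a) & base)
    sub_b = model.subset(model.chain_mask(chains_b) & base)
    return sub_a, sub_b


def buried_interface_area(
    model: StructureModel, probe: float = 1.4, n_points: int = 960
) -> float:
    """Buried dimer-interface area, (SASA_A + SASA_B - SASA_AB) / 2 in A^2."""
    sub_a, sub_b = _protomer_submodels(model)
    s_a = shrake_rupley_sasa(sub_a, probe, n_points).total
    s_b = shrake_rupley_sasa(sub_b, probe, n_points).total
    s_ab = shrake_rupley_sasa(concatenate([sub_a, sub_b]), probe, n_points).total
    return max(0.0, float((s_a + s_b - s_ab) / 2.0))


# ------------------------------------------------------------------- contacts
@dataclass(frozen=True)
class ContactRecord:
    res_a: tuple  # (chain, res_id, ins_code)
    res_b: tuple
    type: str  # hydrogen_bond | van_der_waals | salt_bridge | cation_pi
    distance: float
    frame: int | str = "static"


def _normalize_group(model: StructureModel, group) -> np.ndarray:
    """Residue set -> atom index array.  Accepts (chain, res_id) pairs."""
    wanted = set()
    for item in group:
        chain, res_id = item[0], item[1]
        wanted.add((str(chain), int(res_id)))
    mask = np.zeros(len(model), bool)
    for i in range(len(model)):
        if (str(model.chain_ids[i]), int(model.res_ids[i])) in wanted:
            mask[i] = True
    return np.flatnonzero(mask)


def _attached_hydrogens(model, coords, donor_idx, all_h_idx):
    if len(all_h_idx) == 0:
        return np.empty(0, int)
    d = np.linalg.norm(coords[all_h_idx] - coords[donor_idx], axis=1)
    return all_h_idx[d <= 1.3]


def detect_contacts(model: StructureModel, group_a, group_b) -> list[ContactRecord]:
    """Typed residue-residue contacts between two disjoint residue groups."""
    ia = _normalize_group(model, group_a)
    ib = _normalize_group(model, group_b)
    if len(ia) == 0 or len(ib) == 0:
        warnings.warn("empty contact group; returning no contacts")
        return []
    keys_a = {residue_key(model.chain_ids[i], model.res_ids[i], model.ins_codes[i]) for i in ia}
    keys_b = {residue_key(model.chain_ids[i], model.res_ids[i], model.ins_codes[i]) for i in ib}
    if keys_a & keys_b:
        raise ConfigurationError("contact groups are not disjoint")

    coords = model.coords
    heavy = model.heavy_mask()
    radii = vdw_radius_array(np.where(heavy, model.elements, "C"))
    h_idx = np.flatnonzero(~heavy)

    def res_of(i):
        return residue_key(model.chain_ids[i], model.res_ids[i], model.ins_codes[i])

    def is_donor(i):
        name, res = str(model.atom_names[i]), str(model.res_names[i])
        if name == "N" and res != "PRO":
            return True
        return (res, name) in _SIDECHAIN_DONORS

    def is_acceptor(i):
        name, res = str(model.atom_names[i]), str(model.res_names[i])
        if name in ("O", "OXT"):
            return True
        return (res, name) in _SIDECHAIN_ACCEPTORS

    ha = ia[heavy[ia]]
    hb = ib[heavy[ib]]
    tree_b = cKDTree(coords[hb])
    found: dict[tuple, ContactRecord] = {}

    max_cut = max(2 * radii.max() + VDW_MARGIN, SALT_BRIDGE_CUTOFF, HBOND_CUTOFF)
    pairs = tree_b.query_ball_point(coords[ha], max_cut)
    for ai_local, blist in enumerate(pairs):
        i = ha[ai_local]
        for bj_local in blist:
            j = hb[bj_local]
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if d <= 0:
                continue
            pair = (res_of(i), res_of(j))
            # van der Waals
            if d <= radii[i] + radii[j] + VDW_MARGIN:
                rec = found.get((pair, "van_der_waals"))
                if rec is None or d < rec.distance:
                    found[(pair, "van_der_waals")] = ContactRecord(*pair, "van_der_waals", d)
            # hydrogen bond (either direction)
            if d <= HBOND_CUTOFF:
                for don, acc in ((i, j), (j, i)):
                    if not (is_donor(don) and is_acceptor(acc)):
                        continue
                    hydrogens = _attached_hydrogens(model, coords, don, h_idx)
                    ok = True
                    if len(hydrogens):
                        ok = False
                        for h in hydrogens:
                            v1 = coords[don] - coords[h]
                            v2 = coords[acc] - coords[h]
                            cosang = np.dot(v1, v2) / (
                                np.linalg.norm(v1) * np.linalg.norm(v2)
                            )
                            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                            if ang >= HBOND_MIN_ANGLE:
                                ok = True
                                break
                    if ok:
                        rec = found.get((pair, "hydrogen_bond"))
                        if rec is None or d < rec.distance:
                            found[(pair, "hydrogen_bond")] = ContactRecord(
                                *pair, "hydrogen_bond", d
                            )
                        break
            # salt bridge
            if d <= SALT_BRIDGE_CUTOFF:
                ri, ni = str(model.res_names[i]), str(model.atom_names[i])
                rj, nj = str(model.res_names[j]), str(model.atom_names[j])
                if ((ri, ni) in _CATIONIC and (rj, nj) in _ANIONIC) or (
                    (ri, ni) in _ANIONIC and (rj, nj) in _CATIONIC
                ):
                    rec = found.get((pair, "salt_bridge"))
                    if rec is None or d < rec.distance:
                        found[(pair, "salt_bridge")] = ContactRecord(*pair, "salt_bridge", d)

    # cation-pi: ring centroids vs cationic nitrogens, both directions
    def _rings(indices):
        rings = []
        by_res = {}
        for i in indices:
            by_res.setdefault(res_of(i), []).append(i)
        for key, idx in by_res.items():
            res = str(model.res_names[idx[0]])
            if res not in _AROMATIC_RINGS:
                continue
            names = {str(model.atom_names[i]): i for i in idx}
            ring_idx = [names[n] for n in _AROMATIC_RINGS[res] if n in names]
            if len(ring_idx) >= 5:
                pts = coords[ring_idx]
                centroid = pts.mean(axis=0)
                _, _, vt = np.linalg.svd(pts - centroid)
                rings.append((key, centroid, vt[2]))
        return rings

    def _cations(indices):
        return [
            i
            for i in indices
            if (str(model.res_names[i]), str(model.atom_names[i])) in _CATIONIC
        ]

    for (cat_group, ring_group) in ((ha, hb), (hb, ha)):
        swap = cat_group is hb
        for i in _cations(cat_group):
            for ring_key, centroid, normal in _rings(ring_group):
                v = coords[i] - centroid
                d = float(np.linalg.norm(v))
                if d > CATION_PI_CUTOFF or d <= 0:
                    continue
                off = np.degrees(np.arccos(np.clip(abs(np.dot(v / d, normal)), 0, 1)))
                if off <= CATION_PI_MAX_OFFNORMAL:
                    pair = (ring_key, res_of(i)) if swap else (res_of(i), ring_key)
                    rec = found.get((pair, "cation_pi"))
                    if rec is None or d < rec.distance:
                        found[(pair, "cation_pi")] = ContactRecord(*pair, "cation_pi", d)
    return sorted(found.values(), key=lambda r: (r.res_a, r.res_b, r.type))


# ---------------------------------------------------------------- persistence
@dataclass
class PersistenceResult:
    frequencies: dict[tuple, float]  # (res_a, res_b) -> fraction of frames
    threshold: float
    n_frames: int

    @property
    def persistent(self) -> list[tuple[tuple, float]]:
        """Pairs with frequency strictly greater than the threshold."""
        return sorted(
            ((pair, f) for pair, f in self.frequencies.items() if f > self.threshold),
            key=lambda x: (-x[1], x[0]),
        )


def contact_persistence(
    frames, group_a, group_b, threshold: float = 0.60
) -> PersistenceResult:
    """Contact frequency over trajectory frames.

    ``frames`` is a :class:`~dimerstate.trajectory.Trajectory` or an iterable
    of :class:`StructureModel`.  A pair counts as in contact in a frame when
    any contact type links it; persistence requires frequency > threshold
    (strict inequality).
    """
    frame_models = frames.iter_frames() if hasattr(frames, "iter_frames") else frames
    counts: dict[tuple, int] = {}
    n = 0
    for frame in frame_models:
        n += 1
        seen = {(r.res_a, r.res_b) for r in detect_contacts(frame, group_a, group_b)}
        for pair in seen:
            counts[pair] = counts.get(pair, 0) + 1
    if n == 0:
        raise DimerStateError("zero trajectory frames")
    freqs = {pair: c / n for pair, c in counts.items()}
    return PersistenceResult(frequencies=freqs, threshold=threshold, n_frames=n)


# --------------------------------------------------------------------- energy
def interface_interaction_energy(
    model: StructureModel,
    group_a,
    group_b,
    params: ForcefieldParams | None = None,
    cutoff: float = 12.0,
) -> tuple[float, float, float]:
    """Reduced pairwise 12-6 LJ + Coulomb inter-group energy in kcal/mol.

    Returns ``(vdw, coulomb, total)``.  This is a simplified stand-in
    parameterised from :mod:`dimerstate.params`, not a production forcefield.
    """
    params = params or ForcefieldParams()
    q, eps, sig = params.assign(model)
    ia = _normalize_group(model, group_a)
    ib = _normalize_group(model, group_b)
    if len(ia) == 0 or len(ib) == 0:
        raise ConfigurationError("empty group for interaction energy")
    diff = model.coords[ia][:, None, :] - model.coords[ib][None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    within = (dist <= cutoff) & (dist > 0)
    if not within.any():
        return 0.0, 0.0, 0.0
    qq = np.outer(q[ia], q[ib])[within]
    r = dist[within]
    e_coul = float(COULOMB_CONSTANT * np.sum(qq / r))
    eps_ij = np.sqrt(np.outer(eps[ia], eps[ib]))[within]
    sig_ij = (0.5 * (sig[ia][:, None] + sig[ib][None, :]))[within]
    sr6 = (sig_ij / r) ** 6
    e_vdw = float(np.sum(4.0 * eps_ij * (sr6**2 - sr6)))
    return e_vdw, e_coul, e_vdw + e_coul


# ----------------------------------------------------------- ligand contacts
def ligand_contact_residues(
    model: StructureModel, ligand_chain: str, margin: float = VDW_MARGIN
) -> list[tuple]:
    """Receptor residues with a heavy atom within the vdW criterion of the ligand."""
    lig_mask = model.chain_mask(ligand_chain) & model.heavy_mask()
    if not lig_mask.any():
        raise ConfigurationError(f"no ligand chain {ligand_chain!r} in model")
    rec_mask = model.receptor_mask() & model.heavy_mask()
    if not rec_mask.any():
        raise DimerRequiredError("no receptor chains assigned")
    radii = vdw_radius_array(model.elements)
    li = np.flatnonzero(lig_mask)
    ri = np.flatnonzero(rec_mask)
    tree = cKDTree(model.coords[li])
    max_cut = 2 * radii.max() + margin
    residues = set()
    hits = tree.query_ball_point(model.coords[ri], max_cut)
    for k, lig_hits in enumerate(hits):
        i = ri[k]
        for lj in lig_hits:
            j = li[lj]
            d = np.linalg.norm(model.coords[i] - model.coords[j])
            if d <= radii[i] + radii[j] + margin:
                residues.add(residue_key(model.chain_ids[i], model.res_ids[i], model.ins_codes[i]))
                break
    return sorted(residues)


# --------------------------------------------------------------------- report
@dataclass
class InterfaceReport:
    buried_area: float
    interfacial_residues: dict[str, list]
    contact_counts: dict[str, int]
    persistent_contacts: list
    energy: dict[str, float]

    def as_dict(self) -> dict:
        return {
            "buried_interface_area_A2": self.buried_area,
            "interfacial_residues": self.interfacial_residues,
            "contact_counts": self.contact_counts,
            "persistent_contacts": [
                {"pair": [list(a), list(b)], "frequency": f}
                for (a, b), f in self.persistent_contacts
            ],
            "interaction_energy_kcal_mol": self.energy,
        }


def interface_report(
    model: StructureModel,
    frames=None,
    threshold: float = 0.60,
    params: ForcefieldParams | None = None,
) -> InterfaceReport:
    """Full static + (optional) dynamic characterization of the dimer interface."""
    sub_a, sub_b = _protomer_submodels(model)
    group_a = [(c, r) for c, r, _ in sub_a.residue_ids()]
    group_b = [(c, r) for c, r, _ in sub_b.residue_ids()]
    area = buried_interface_area(model)
    contacts = detect_contacts(model, group_a, group_b)
    counts: dict[str, int] = {}
    for rec in contacts:
        counts[rec.type] = counts.get(rec.type, 0) + 1
    res_a = sorted({r.res_a for r in contacts})
    res_b = sorted({r.res_b for r in contacts})
    persistent = []
    if frames is not None:
        persistent = contact_persistence(frames, group_a, group_b, threshold).persistent
    vdw, coul, total = interface_interaction_energy(model, group_a, group_b, params)
    return InterfaceReport(
        buried_area=area,
        interfacial_residues={"A": res_a, "B": res_b},
        contact_counts=counts,
        persistent_contacts=persistent,
        energy={
            "vdw": vdw,
            "coulomb": coul,
            "total": total,
            "forcefield": "reduced_forcefield",
        },
    )
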