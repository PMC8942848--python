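"""Multi-frame coordinate handling and torsion-angle extraction.

Multi-model PDB files are parsed with biotite; DCD/XTC via MDAnalysis (which
converts nm-storing formats to Angstrom).  Torsions follow the IUPAC sign
convention and are wrapped to (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io import pdb as bt_pdb

from .errors import DimerStateError, FormatError, FrameBoundaryError, TopologyError
from .model import StructureModel
from .structure_io import read_structure

__all__ = [
    "Trajectory",
    "TorsionSeries",
    "load_trajectory",
    "compute_torsions",
    "dihedral",
    "wrap_angle",
    "circular_mean_deg",
]

#: chi1 gamma-atom name by residue (fallback "CG"); ALA/GLY have no chi1
CHI1_GAMMA = {
    "SER": "OG",
    "THR": "OG1",
    "VAL": "CG1",
    "ILE": "CG1",
    "CYS": "SG",
}
NO_CHI1 = {"GLY", "ALA"}
TORSION_NAMES = ("phi", "psi", "chi1")


@dataclass
class Trajectory:
    topology: StructureModel
    coords: np.ndarray  # (n_frames, n_atoms, 3), Angstrom
    stride_ps: float | None = None
    source: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 3 or self.coords.shape[0] < 1:
            raise TopologyError("trajectory needs >= 1 frame of (n_atoms, 3) coords")
        if self.coords.shape[1] != len(self.topology):
            raise TopologyError(
                f"frame atom count {self.coords.shape[1]} != topology {len(self.topology)}"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> StructureModel:
        return self.topology.with_coords(self.coords[i])

    def iter_frames(self):
        for i in range(self.n_frames):
            yield self.frame(i)

    def mean_coords(self) -> np.ndarray:
        return self.coords.mean(axis=0)


def load_trajectory(
    topology_path, trajectory_path=None, format: str | None = None
) -> Trajectory:
    """Load a trajectory; a lone structure file becomes a 1-frame trajectory."""
    topology_path = Path(topology_path)
    if trajectory_path is None:
        suffix = topology_path.suffix.lower()
        if suffix in (".pdb", ".ent"):
            return _load_multimodel_pdb(topology_path)
        model = read_structure(topology_path, format=format)
        return Trajectory(model, model.coords[None, :, :], source=str(topology_path))

    trajectory_path = Path(trajectory_path)
    fmt = (format or trajectory_path.suffix.lstrip(".")).lower()
    if fmt in ("pdb", "multi-model pdb", "multimodel-pdb"):
        topo = _load_multimodel_pdb(trajectory_path)
        ref = read_structure(topology_path)
        if len(ref) != len(topo.topology):
            raise TopologyError(
                f"topology has {len(ref)} atoms, trajectory frames have {len(topo.topology)}"
            )
        return Trajectory(ref, topo.coords, source=str(trajectory_path))
    if fmt in ("dcd", "xtc", "trr"):
        return _load_mdanalysis(topology_path, trajectory_path, fmt)
    raise FormatError(f"unsupported trajectory format {fmt!r}")


def _load_multimodel_pdb(path: Path) -> Trajectory:
    try:
        f = bt_pdb.PDBFile.read(str(path))
        stack = f.get_structure(extra_fields=["occupancy", "b_factor"], altloc="occupancy")
    except Exception as exc:
        raise FormatError(f"{path}: unparsable multi-model PDB: {exc}") from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    topo = read_structure(path)  # first model
    coords = np.asarray(stack.coord, float)
    if coords.shape[1] != len(topo):
        raise TopologyError(f"{path}: inconsistent atom counts across models")
    return Trajectory(topo, coords, source=str(path))


def _load_mdanalysis(topology_path, trajectory_path, fmt) -> Trajectory:
    import MDAnalysis as mda

    topo = read_structure(topology_path)
    try:
        u = mda.Universe(str(topology_path), str(trajectory_path))
    except Exception as exc:
        raise FormatError(f"{trajectory_path}: cannot open {fmt} file: {exc}") from exc
    if len(u.atoms) != len(topo):
        raise TopologyError(
            f"topology atom count {len(topo)} != trajectory {len(u.atoms)}"
        )
    frames = []
    stride = None
    try:
        for ts in u.trajectory:
            frames.append(ts.positions.copy().astype(float))  # MDAnalysis yields A
            stride = getattr(ts, "dt", None)
    except (EOFError, OSError, ValueError) as exc:
        raise FrameBoundaryError(f"{trajectory_path}: truncated trajectory: {exc}") from exc
    return Trajectory(topo, np.asarray(frames), stride_ps=stride, source=str(trajectory_path))


# ------------------------------------------------------------------- torsions
def wrap_angle(deg):
    """Wrap degrees to (-180, 180]."""
    wrapped = np.asarray(deg, float) % 360.0
    wrapped = np.where(wrapped > 180.0, wrapped - 360.0, wrapped)
    return np.where(wrapped == -180.0, 180.0, wrapped)


def circular_mean_deg(deg) -> float:
    rad = np.radians(np.asarray(deg, float))
    return float(wrap_angle(np.degrees(np.angle(np.mean(np.exp(1j * rad))))))


def dihedral(p0, p1, p2, p3):
    """IUPAC-signed dihedral angle(s) in degrees; inputs (..., 3)."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


@dataclass
class TorsionSeries:
    """phi/psi/chi1 time series per residue, degrees in (-180, 180]."""

    residues: list  # (chain, res_id, ins_code) keys
    angles: np.ndarray  # (n_frames, n_residues, 3)
    mask: np.ndarray  # (n_residues, 3) bool, True = valid
    names: tuple = TORSION_NAMES
    res_names: list = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    @property
    def n_residues(self) -> int:
        return self.angles.shape[1]

    def to_frame_table(self):
        """(frame x residue-angle) pandas DataFrame for TSV export."""
        import pandas as pd

        cols, data = [], []
        for r, key in enumerate(self.residues):
            for t, name in enumerate(self.names):
                if self.mask[r, t]:
                    cols.append(f"{key[0]}{key[1]}{key[2]}:{name}")
                    data.append(self.angles[:, r, t])
        return pd.DataFrame(np.column_stack(data) if data else np.empty((self.n_frames, 0)), columns=cols)


def _atom_lookup(topology: StructureModel) -> dict[tuple, dict[str, int]]:
    lookup: dict[tuple, dict[str, int]] = {}
    for i in range(len(topology)):
        key = (str(topology.chain_ids[i]), int(topology.res_ids[i]), str(topology.ins_codes[i]))
        lookup.setdefault(key, {}).setdefault(str(topology.atom_names[i]), i)
    return lookup


def compute_torsions(traj: Trajectory | StructureModel) -> TorsionSeries:
    """Extract phi (C-N-CA-C), psi (N-CA-C-N) and chi1 (N-CA-CB-G) series.

    Missing atoms (chain termini, GLY/ALA chi1, chain breaks detected by a
    C-N peptide-bond distance over 2.5 A in the first frame) are masked, not
    fatal.
    """
    if isinstance(traj, StructureModel):
        traj = Trajectory(traj, traj.coords[None, :, :])
    topo = traj.topology
    lookup = _atom_lookup(topo)
    protein_keys = [
        k for k in topo.residue_ids(~topo.hetero) if "CA" in lookup.get((k[0], k[1], k[2]), {})
    ]
    n_res = len(protein_keys)
    if n_res == 0:
        raise DimerStateError("no protein residues with CA atoms in topology")
    angles = np.zeros((traj.n_frames, n_res, 3))
    mask = np.zeros((n_res, 3), bool)
    quads: list[tuple[int, int, tuple]] = []  # (res_index, torsion_index, atom idx 4-tuple)
    first = traj.coords[0]

    def bonded(i, j, lim=2.5):
        return np.linalg.norm(first[i] - first[j]) <= lim

    for r, key in enumerate(protein_keys):
        chain = key[0]
        atoms = lookup[key]
        prev_key = protein_keys[r - 1] if r > 0 and protein_keys[r - 1][0] == chain else None
        next_key = (
            protein_keys[r + 1] if r + 1 < n_res and protein_keys[r + 1][0] == chain else None
        )
        # phi
        if prev_key and all(n in atoms for n in ("N", "CA", "C")):
            pc = lookup[prev_key].get("C")
            if pc is not None and bonded(pc, atoms["N"]):
                quads.append((r, 0, (pc, atoms["N"], atoms["CA"], atoms["C"])))
        # psi
        if next_key and all(n in atoms for n in ("N", "CA", "C")):
            nn = lookup[next_key].get("N")
            if nn is not None and bonded(atoms["C"], nn):
                quads.append((r, 1, (atoms["N"], atoms["CA"], atoms["C"], nn)))
        # chi1
        res_name = str(topo.res_names[atoms["CA"]])
        if res_name not in NO_CHI1:
            gamma = CHI1_GAMMA.get(res_name, "CG")
            if all(n in atoms for n in ("N", "CA", "CB")) and gamma in atoms:
                quads.append((r, 2, (atoms["N"], atoms["CA"], atoms["CB"], atoms[gamma])))

    if quads:
        idx = np.array([q[2] for q in quads])
        vals = dihedral(
            traj.coords[:, idx[:, 0]],
            traj.coords[:, idx[:, 1]],
            traj.coords[:, idx[:, 2]],
            traj.coords[:, idx[:, 3]],
        )
        for col, (r, t, _) in enumerate(quads):
            angles[:, r, t] = vals[:, col]
            mask[r, t] = True
    res_names = [str(topo.res_names[lookup[k]["CA"]]) for k in protein_keys]
    return TorsionSeries(residues=protein_keys, angles=angles, mask=mask, res_names=res_names)
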