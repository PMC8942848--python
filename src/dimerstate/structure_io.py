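"""Reading/writing structures and protomer/generic-number assignment.

PDB and mmCIF parsing is delegated to ``biotite``; this module adapts its
atom arrays to :class:`~dimerstate.model.StructureModel` and owns the
protomer and generic-numbering conventions.  Altlocs are resolved by highest
occupancy (biotite's ``altloc="occupancy"``).
"""

from __future__ import annotations

import tomllib
from importlib import resources
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io import pdb as bt_pdb
from biotite.structure.io import pdbx as bt_pdbx

from .errors import ConfigurationError, DimerRequiredError, EmptyStructureError, FormatError
from .model import ResidueRef, SegmentTable, StructureModel

__all__ = [
    "read_structure",
    "write_structure",
    "assign_protomers",
    "map_generic_numbers",
    "load_segment_table",
    "default_segment_table",
]

_EXT_FORMATS = {
    ".pdb": "pdb",
    ".ent": "pdb",
    ".cif": "mmcif",
    ".mmcif": "mmcif",
    ".pdbx": "mmcif",
}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        aliases = {"pdb": "pdb", "mmcif": "mmcif", "cif": "mmcif", "pdbx": "mmcif"}
        try:
            return aliases[fmt.lower()]
        except KeyError:
            raise ConfigurationError(f"unknown structure format {fmt!r}") from None
    try:
        return _EXT_FORMATS[path.suffix.lower()]
    except KeyError:
        raise ConfigurationError(
            f"cannot infer format from suffix {path.suffix!r}; pass format="
        ) from None


def _from_atom_array(atoms: struc.AtomArray, source_id: str) -> StructureModel:
    if atoms.array_length() == 0:
        raise EmptyStructureError(f"{source_id}: no atoms in model")
    occ = (
        atoms.occupancy
        if "occupancy" in atoms.get_annotation_categories()
        else np.ones(atoms.array_length())
    )
    bf = (
        atoms.b_factor
        if "b_factor" in atoms.get_annotation_categories()
        else np.zeros(atoms.array_length())
    )
    return StructureModel(
        chain_ids=atoms.chain_id,
        res_ids=atoms.res_id,
        ins_codes=atoms.ins_code,
        res_names=atoms.res_name,
        atom_names=atoms.atom_name,
        elements=atoms.element,
        coords=atoms.coord,
        occupancies=occ,
        b_factors=bf,
        hetero=atoms.hetero,
        source_id=source_id,
    )


def read_structure(path, format: str | None = None, model: int = 1) -> StructureModel:
    """Read a single-model structure from a PDB or mmCIF file.

    HETATM records (waters, ligands, sterols) are retained and flagged via
    the ``hetero`` column.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if fmt == "pdb":
            f = bt_pdb.PDBFile.read(str(path))
            atoms = f.get_structure(
                model=model, extra_fields=["occupancy", "b_factor"], altloc="occupancy"
            )
        else:
            f = bt_pdbx.CIFFile.read(str(path))
            atoms = bt_pdbx.get_structure(
                f, model=model, extra_fields=["occupancy", "b_factor"], altloc="occupancy"
            )
    except EmptyStructureError:
        raise
    except Exception as exc:  # normalise parser errors
        raise FormatError(f"{path}: unparsable {fmt} file: {exc}") from exc
    if atoms.array_length() == 0:
        raise EmptyStructureError(f"{path}: empty model")
    return _from_atom_array(atoms, source_id=path.stem)


def _to_atom_array(model: StructureModel) -> struc.AtomArray:
    atoms = struc.AtomArray(len(model))
    atoms.chain_id = model.chain_ids
    atoms.res_id = model.res_ids
    atoms.ins_code = model.ins_codes
    atoms.res_name = model.res_names
    atoms.atom_name = model.atom_names
    atoms.element = model.elements
    atoms.coord = model.coords
    atoms.hetero = model.hetero
    atoms.set_annotation("occupancy", model.occupancies)
    atoms.set_annotation("b_factor", model.b_factors)
    return atoms


def write_structure(model: StructureModel, path, format: str | None = None) -> None:
    """Write to PDB (3-decimal coordinates) or mmCIF."""
    path = Path(path)
    fmt = _infer_format(path, format)
    atoms = _to_atom_array(model)
    if fmt == "pdb":
        f = bt_pdb.PDBFile()
        f.set_structure(atoms)
        f.write(str(path))
    else:
        f = bt_pdbx.CIFFile()
        bt_pdbx.set_structure(f, atoms, data_block=model.source_id or "model")
        f.write(str(path))


def write_multi_model_pdb(models: list[np.ndarray], topology: StructureModel, path) -> None:
    """Write frames (list/array of (n_atoms, 3) coords) as a multi-model PDB."""
    atoms = _to_atom_array(topology)
    stack = struc.from_template(atoms, np.asarray(models, float))
    f = bt_pdb.PDBFile()
    f.set_structure(stack)
    f.write(str(Path(path)))


def assign_protomers(model: StructureModel, receptor_chains) -> StructureModel:
    """Label the first listed chain protomer ``A``, the second ``B``.

    Non-receptor chains (ligands, G-protein subunits) stay outside the
    protomer map and are excluded from receptor analyses.  Pure relabelling:
    coordinates are untouched.
    """
    receptor_chains = list(receptor_chains)
    present = set(np.unique(model.chain_ids))
    missing = [c for c in receptor_chains if c not in present]
    if missing:
        raise ConfigurationError(f"receptor chains not in model: {missing}")
    if not 1 <= len(receptor_chains) <= 2:
        raise DimerRequiredError(
            f"expected 1 or 2 receptor chains, got {len(receptor_chains)}"
        )
    out = model.copy()
    out.protomer_map = {
        chain: label for chain, label in zip(receptor_chains, ("A", "B"))
    }
    return out


def map_generic_numbers(
    model: StructureModel, table: SegmentTable
) -> list[ResidueRef]:
    """Attach generic numbers / region labels to every receptor residue."""
    refs = []
    mask = model.receptor_mask()
    for chain_id, res_id, ins_code in model.residue_ids(mask):
        base = model.residue_ref(chain_id, res_id, ins_code)
        refs.append(
            ResidueRef(
                protomer=base.protomer,
                res_id=res_id,
                ins_code=ins_code,
                res_name=base.res_name,
                generic=table.generic_number(res_id),
            )
        )
    return refs


def load_segment_table(path) -> SegmentTable:
    """Load a TOML segment table ``{segments: {name: [start, end]}, anchors}``."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    segments = {
        name: (int(rng[0]), int(rng[1])) for name, rng in data.get("segments", {}).items()
    }
    anchors = {int(res): gen for res, gen in data.get("anchors", {}).items()}
    return SegmentTable(segments=segments, anchors=anchors)


def default_segment_table() -> SegmentTable:
    """The packaged receptor segment table (anchored generic numbering)."""
    ref = resources.files("dimerstate").joinpath("data/segments.toml")
    with resources.as_file(ref) as path:
        return load_segment_table(path)
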