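"""Core structure representation.

A :class:`StructureModel` holds atoms in columnar numpy arrays (one entry per
atom) plus a protomer map assigning receptor chains to the two copies of the
dimer, labelled ``"A"`` and ``"B"``.  Coordinates are always in Angstrom and
residue numbers are 1-based author numbering; insertion codes are honoured as
part of the residue key.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DimerRequiredError, EmptyStructureError

__all__ = [
    "StructureModel",
    "ResidueRef",
    "SegmentTable",
    "residue_key",
]

_GENERIC_RE = re.compile(r"^[1-7]x\d{2}$")
_REGION_LABELS = ("N-term", "C-term", "ECL1", "ECL2", "ECL3", "ICL1", "ICL2", "ICL3")

#: residues treated as water when flagging solvent
WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


@dataclass(frozen=True)
class ResidueRef:
    """Reference to a residue by protomer label and author number."""

    protomer: str
    res_id: int
    ins_code: str = ""
    res_name: str = ""
    generic: str | None = None

    def __post_init__(self):
        if self.generic is not None and not (
            _GENERIC_RE.match(self.generic) or self.generic in _REGION_LABELS
        ):
            raise ConfigurationError(
                f"generic number {self.generic!r} is neither 'NxMM' nor a region label"
            )

    def key(self) -> tuple[int, str]:
        return (self.res_id, self.ins_code)

    def __str__(self) -> str:
        label = f"{self.res_name or 'UNK'}{self.res_id}{self.ins_code}"
        if self.generic:
            label += f"({self.generic})"
        return f"{self.protomer}:{label}"


def residue_key(chain_id: str, res_id: int, ins_code: str = "") -> tuple[str, int, str]:
    return (str(chain_id), int(res_id), str(ins_code))


class StructureModel:
    """Columnar atom container with protomer labelling.

    Parameters mirror PDB atom records.  ``hetero`` flags waters, ligands and
    other HETATM entries; receptor analyses operate on non-hetero atoms of
    chains present in ``protomer_map``.
    """

    def __init__(
        self,
        chain_ids,
        res_ids,
        ins_codes,
        res_names,
        atom_names,
        elements,
        coords,
        occupancies=None,
        b_factors=None,
        hetero=None,
        protomer_map: dict[str, str] | None = None,
        source_id: str = "",
    ):
        n = len(atom_names)
        self.chain_ids = np.asarray(chain_ids, dtype="U4")
        self.res_ids = np.asarray(res_ids, dtype=np.int64)
        self.ins_codes = np.asarray(ins_codes, dtype="U1")
        self.res_names = np.asarray(res_names, dtype="U5")
        self.atom_names = np.asarray(atom_names, dtype="U6")
        self.elements = np.char.upper(np.asarray(elements, dtype="U2"))
        self.coords = np.asarray(coords, dtype=np.float64).reshape(n, 3)
        self.occupancies = (
            np.ones(n) if occupancies is None else np.asarray(occupancies, float)
        )
        self.b_factors = (
            np.zeros(n) if b_factors is None else np.asarray(b_factors, float)
        )
        self.hetero = (
            np.zeros(n, bool) if hetero is None else np.asarray(hetero, bool)
        )
        self.protomer_map = dict(protomer_map or {})
        self.source_id = source_id
        if n == 0:
            raise EmptyStructureError("structure contains no atoms")
        if not np.all(np.isfinite(self.coords)):
            raise ConfigurationError("non-finite coordinates in structure")

    # ------------------------------------------------------------------ basics
    def __len__(self) -> int:
        return len(self.atom_names)

    @property
    def n_atoms(self) -> int:
        return len(self)

    def copy(self) -> "StructureModel":
        return StructureModel(
            self.chain_ids.copy(),
            self.res_ids.copy(),
            self.ins_codes.copy(),
            self.res_names.copy(),
            self.atom_names.copy(),
            self.elements.copy(),
            self.coords.copy(),
            self.occupancies.copy(),
            self.b_factors.copy(),
            self.hetero.copy(),
            dict(self.protomer_map),
            self.source_id,
        )

    def subset(self, mask) -> "StructureModel":
        mask = np.asarray(mask)
        return StructureModel(
            self.chain_ids[mask],
            self.res_ids[mask],
            self.ins_codes[mask],
            self.res_names[mask],
            self.atom_names[mask],
            self.elements[mask],
            self.coords[mask],
            self.occupancies[mask],
            self.b_factors[mask],
            self.hetero[mask],
            dict(self.protomer_map),
            self.source_id,
        )

    def with_coords(self, coords) -> "StructureModel":
        out = self.copy()
        out.coords = np.asarray(coords, float).reshape(len(self), 3)
        return out

    def transformed(self, rotation, translation) -> "StructureModel":
        """Return a copy with ``x -> x @ R.T + t`` applied to all atoms."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return self.with_coords(self.coords @ R.T + t)

    # -------------------------------------------------------------- selections
    def chain_mask(self, chain_ids) -> np.ndarray:
        chain_ids = {chain_ids} if isinstance(chain_ids, str) else set(chain_ids)
        return np.isin(self.chain_ids, sorted(chain_ids))

    def protomer_chains(self, label: str) -> list[str]:
        return [c for c, p in self.protomer_map.items() if p == label]

    def receptor_mask(self) -> np.ndarray:
        """Non-hetero atoms of chains assigned to a protomer."""
        if not self.protomer_map:
            return ~self.hetero
        return self.chain_mask(self.protomer_map) & ~self.hetero

    def water_mask(self) -> np.ndarray:
        return np.isin(self.res_names, sorted(WATER_NAMES))

    def heavy_mask(self) -> np.ndarray:
        return self.elements != "H"

    def calpha_mask(self, protomer: str | None = None) -> np.ndarray:
        mask = (self.atom_names == "CA") & (self.elements == "C") & ~self.hetero
        if protomer is not None:
            chains = self.protomer_chains(protomer)
            if not chains:
                raise DimerRequiredError(
                    f"no chains assigned to protomer {protomer!r}"
                )
            mask &= self.chain_mask(chains)
        return mask

    def residue_ids(self, mask=None):
        """Unique ``(chain, res_id, ins_code)`` keys in file order."""
        idx = np.arange(len(self)) if mask is None else np.flatnonzero(mask)
        seen: dict[tuple, int] = {}
        for i in idx:
            key = residue_key(self.chain_ids[i], self.res_ids[i], self.ins_codes[i])
            seen.setdefault(key, i)
        return list(seen)

    def residue_atom_indices(self, mask=None) -> dict[tuple, np.ndarray]:
        idx = np.arange(len(self)) if mask is None else np.flatnonzero(mask)
        groups: dict[tuple, list[int]] = {}
        for i in idx:
            key = residue_key(self.chain_ids[i], self.res_ids[i], self.ins_codes[i])
            groups.setdefault(key, []).append(i)
        return {k: np.asarray(v) for k, v in groups.items()}

    def residue_ref(self, chain_id: str, res_id: int, ins_code: str = "") -> ResidueRef:
        sel = (
            (self.chain_ids == chain_id)
            & (self.res_ids == res_id)
            & (self.ins_codes == ins_code)
        )
        name = self.res_names[sel][0] if sel.any() else ""
        return ResidueRef(
            protomer=self.protomer_map.get(chain_id, chain_id),
            res_id=res_id,
            ins_code=ins_code,
            res_name=str(name),
        )


# ---------------------------------------------------------------------- table
@dataclass
class SegmentTable:
    """Helix/loop residue ranges plus generic-number anchors.

    ``segments`` maps names like ``"H6"`` or ``"ECL3"`` to inclusive author
    residue ranges; ``anchors`` maps an author residue number to its generic
    number (e.g. ``{243: "6x35"}``), fixing the offset of every residue in
    that helix.  Ranges apply identically to both protomers of the symmetric
    dimer.
    """

    segments: dict[str, tuple[int, int]] = field(default_factory=dict)
    anchors: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        spans = []
        for name, (start, end) in self.segments.items():
            if end < start:
                raise ConfigurationError(f"segment {name}: empty range {start}-{end}")
            spans.append((start, end, name))
        spans.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ConfigurationError(f"segments {n1} and {n2} overlap")

    def helix_number(self, name: str) -> int | None:
        if len(name) == 2 and name[0] in "Hh" and name[1].isdigit():
            return int(name[1])
        return None

    def segment_of(self, res_id: int) -> str | None:
        for name, (start, end) in self.segments.items():
            if start <= res_id <= end:
                return name
        return None

    def generic_number(self, res_id: int) -> str | None:
        """Generic number ``NxMM`` for helix residues, region label for loops."""
        name = self.segment_of(res_id)
        if name is None:
            return None
        helix = self.helix_number(name)
        if helix is None:
            return name  # loop/terminal region label
        start, end = self.segments[name]
        anchor_res, anchor_offset = start, 1
        for a_res, a_gen in self.anchors.items():
            if start <= a_res <= end:
                a_helix, a_off = a_gen.split("x")
                if int(a_helix) != helix:
                    raise ConfigurationError(
                        f"anchor {a_res}->{a_gen} lies in segment {name}"
                    )
                anchor_res, anchor_offset = a_res, int(a_off)
                break
        offset = anchor_offset + (res_id - anchor_res)
        if offset < 0:
            return None
        return f"{helix}x{offset:02d}"

    def range_for(self, name: str) -> tuple[int, int]:
        try:
            return self.segments[name]
        except KeyError:
            raise ConfigurationError(f"unknown segment {name!r}") from None


def concatenate(models: list[StructureModel], source_id: str = "") -> StructureModel:
    """Concatenate atom tables; protomer maps are merged left to right."""
    pmap: dict[str, str] = {}
    for m in models:
        pmap.update(m.protomer_map)
    return StructureModel(
        np.concatenate([m.chain_ids for m in models]),
        np.concatenate([m.res_ids for m in models]),
        np.concatenate([m.ins_codes for m in models]),
        np.concatenate([m.res_names for m in models]),
        np.concatenate([m.atom_names for m in models]),
        np.concatenate([m.elements for m in models]),
        np.concatenate([m.coords for m in models]),
        np.concatenate([m.occupancies for m in models]),
        np.concatenate([m.b_factors for m in models]),
        np.concatenate([m.hetero for m in models]),
        pmap,
        source_id or (models[0].source_id if models else ""),
    )
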