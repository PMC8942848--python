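"""Helpers for working with the deposited receptor coordinate files.

The deposited entries are not bundled (they must be fetched once with
``scripts/fetch_structures.py``); these helpers identify the receptor chains
in a parsed entry so the dimer can be labelled protomer A/B even when the
file also contains peptide ligands or G-protein subunits.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import DimerRequiredError
from .model import StructureModel
from .structure_io import assign_protomers, read_structure

#: (author residue number, residue name) pairs unique to the receptor chain
RECEPTOR_FINGERPRINT = (
    (149, "GLN"),
    (204, "PHE"),
    (258, "PRO"),
    (267, "SER"),
    (290, "PRO"),
)

#: accessions used across the study's state comparisons
STATE_ACCESSIONS = {
    "ligand_free": "7qb9",
    "antagonist": "7qa8",
    "inactive_like_agonist": "7qbc",
    "active_like_agonist": "7qbi",
    "g_protein_coupled": "7ad3",
}


def identify_receptor_chains(model: StructureModel, min_matches: int = 4) -> list[str]:
    """Chains matching the receptor residue fingerprint, alphabetical order."""
    scores: dict[str, int] = {}
    mask = ~model.hetero
    for chain in np.unique(model.chain_ids[mask]):
        sel = mask & (model.chain_ids == chain)
        table = {
            int(r): str(n) for r, n in zip(model.res_ids[sel], model.res_names[sel])
        }
        scores[str(chain)] = sum(
            1 for res_id, res_name in RECEPTOR_FINGERPRINT if table.get(res_id) == res_name
        )
    chains = sorted(c for c, s in scores.items() if s >= min_matches)
    if len(chains) < 2:
        raise DimerRequiredError(
            f"found {len(chains)} receptor chain(s) by fingerprint; need 2 "
            f"(scores: {scores})"
        )
    return chains[:2]


def load_receptor_dimer(path) -> StructureModel:
    """Read a deposited entry and assign its two receptor chains as A/B."""
    model = read_structure(path)
    return assign_protomers(model, identify_receptor_chains(model))


def find_structure(data_dir, accession: str) -> Path | None:
    data_dir = Path(data_dir)
    for suffix in (".pdb", ".cif", ".ent"):
        path = data_dir / f"{accession.lower()}{suffix}"
        if path.exists():
            return path
    return None
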