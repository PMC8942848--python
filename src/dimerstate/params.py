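"""Shared parameter tables: vdW radii and the reduced nonbonded forcefield.

The energy parameters are deliberately generic (one LJ class per element,
formal charges on ionizable groups only) and every energy output is labelled
``reduced_forcefield``; they support ordering/trend comparisons, not
absolute-energy parity with any production forcefield.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

#: Bondi-style van der Waals radii in Angstrom, keyed by element symbol.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "NA": 2.27,
    "K": 2.75,
    "MG": 1.73,
    "ZN": 1.39,
    "CA": 2.31,
    "MN": 1.61,
    "FE": 1.56,
}

#: Coulomb conversion constant, kcal mol^-1 A e^-2.
COULOMB_CONSTANT = 332.0636

#: formal charges on ionizable side-chain atoms, keyed "RES:ATOM" (units e).
FORMAL_CHARGES: dict[str, float] = {
    "LYS:NZ": 1.0,
    "ARG:NH1": 0.5,
    "ARG:NH2": 0.5,
    "ASP:OD1": -0.5,
    "ASP:OD2": -0.5,
    "GLU:OE1": -0.5,
    "GLU:OE2": -0.5,
}

#: generic 12-6 LJ parameters per element: (epsilon kcal/mol, sigma A).
LJ_BY_ELEMENT: dict[str, tuple[float, float]] = {
    "H": (0.030, 2.40),
    "C": (0.100, 3.40),
    "N": (0.170, 3.25),
    "O": (0.210, 2.96),
    "S": (0.250, 3.55),
    "P": (0.200, 3.70),
}


def vdw_radius_array(elements, radii: dict[str, float] | None = None) -> np.ndarray:
    """Per-atom radii; raises :class:`ConfigurationError` naming unknown elements."""
    table = dict(VDW_RADII)
    if radii:
        table.update({k.upper(): v for k, v in radii.items()})
    elements = np.asarray(elements)
    missing = sorted({e for e in np.unique(elements) if e not in table})
    if missing:
        raise ConfigurationError(f"no vdW radius for elements: {', '.join(missing)}")
    return np.array([table[e] for e in elements], float)


@dataclass
class ForcefieldParams:
    """Reduced nonbonded parameter set with per-atom override hooks.

    ``charge_overrides`` / ``lj_overrides`` are keyed ``"RES:ATOM"`` and take
    precedence over the shipped tables; tests use them to build closed-form
    two-atom systems.
    """

    charges: dict[str, float] = field(default_factory=lambda: dict(FORMAL_CHARGES))
    lj: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(LJ_BY_ELEMENT)
    )
    charge_overrides: dict[str, float] = field(default_factory=dict)
    lj_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)

    def assign(self, model) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return per-atom (charge, epsilon, sigma) arrays for ``model``."""
        n = len(model)
        q = np.zeros(n)
        eps = np.zeros(n)
        sig = np.zeros(n)
        missing = []
        for i in range(n):
            key = f"{model.res_names[i]}:{model.atom_names[i]}"
            q[i] = self.charge_overrides.get(key, self.charges.get(key, 0.0))
            if key in self.lj_overrides:
                eps[i], sig[i] = self.lj_overrides[key]
            elif model.elements[i] in self.lj:
                eps[i], sig[i] = self.lj[model.elements[i]]
            else:
                missing.append(model.elements[i])
        if missing:
            raise ConfigurationError(
                f"no LJ parameters for elements: {', '.join(sorted(set(missing)))}"
            )
        return q, eps, sig
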