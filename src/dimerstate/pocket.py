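"""Grid/probe estimation of ligand-binding-pocket volume.

A cubic grid is laid over a bounding sphere around a seed point; voxels
farther than (r_vdw + probe) from every protein heavy atom are empty, and the
pocket is the empty region flood-fill-connected (face connectivity) to the
seed.  Volume = voxel count x spacing^3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, SeedBuriedError
from .geometry import aligned_rmsd
from .model import StructureModel

__all__ = ["PocketGrid", "pocket_volume", "pocket_contraction", "ligand_centroid"]


@dataclass
class PocketGrid:
    spacing: float
    seed: np.ndarray
    bounding_radius: float
    probe: float
    n_pocket_voxels: int
    volume: float  # A^3
    origin: np.ndarray | None = None
    pocket_mask: np.ndarray | None = None  # 3-D bool array when keep_grid=True


def ligand_centroid(model: StructureModel, ligand_chain: str) -> np.ndarray:
    mask = model.chain_mask(ligand_chain) & model.heavy_mask()
    if not mask.any():
        raise ConfigurationError(f"no ligand chain {ligand_chain!r} in model")
    return model.coords[mask].mean(axis=0)


def _protein_heavy_coords(model: StructureModel):
    mask = model.heavy_mask()
    rec = model.receptor_mask()
    if rec.any():
        mask &= rec
    else:
        mask &= ~model.hetero
    return model.coords[mask], mask


def pocket_volume(
    model: StructureModel | None,
    seed,
    spacing: float = 0.5,
    probe: float = 1.4,
    bounding_radius: float = 15.0,
    radii: dict[str, float] | None = None,
    keep_grid: bool = False,
) -> PocketGrid:
    """Pocket volume in A^3 around ``seed`` (A triple).

    ``model=None`` (or a model with no protein atoms near the seed) returns
    the full bounding-sphere volume on the grid.
    """
    if spacing > 1.0:
        raise ConfigurationError(f"grid spacing {spacing} A too coarse (max 1.0)")
    seed = np.asarray(seed, float)
    n_side = int(np.floor(2 * bounding_radius / spacing)) + 1
    origin = seed - (n_side - 1) / 2 * spacing
    axes = [origin[k] + spacing * np.arange(n_side) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    inside = (np.sum((pts - seed) ** 2, axis=1) <= bounding_radius**2).reshape(
        (n_side,) * 3
    )

    # signed distance to the solvent-expanded protein envelope (positive =
    # outside every expanded atom); +inf when there is no protein
    sdf = np.full((n_side,) * 3, np.inf)
    if model is not None:
        from scipy.spatial import cKDTree

        from .params import vdw_radius_array

        coords, mask = _protein_heavy_coords(model)
        if len(coords):
            atom_r = vdw_radius_array(model.elements[mask], radii) + probe
            tree = cKDTree(coords)
            k = min(16, len(coords))
            dist, idx = tree.query(pts, k=k, workers=-1)
            dist = dist.reshape(-1, k)
            idx = idx.reshape(-1, k)
            sdf = np.min(dist - atom_r[idx], axis=1).reshape((n_side,) * 3)
    occupied = sdf <= 0.0

    free = inside & ~occupied
    seed_idx = tuple(np.round((seed - origin) / spacing).astype(int))
    if not all(0 <= seed_idx[k] < n_side for k in range(3)):
        raise ConfigurationError("seed outside bounding grid")
    if occupied[seed_idx]:
        raise SeedBuriedError("seed point lies inside the protein volume")
    labels, _ = ndimage.label(free)  # default structure: face connectivity
    seed_label = labels[seed_idx]
    pocket = labels == seed_label if seed_label else np.zeros_like(free)
    n_vox = int(pocket.sum())

    # boundary antialiasing: fractional slab weights at the protein envelope
    # and the bounding sphere, applied to the pocket plus its one-voxel rim
    dist_seed = np.linalg.norm(pts - seed, axis=1).reshape((n_side,) * 3)
    frac_empty = np.clip(0.5 + sdf / spacing, 0.0, 1.0)
    frac_bound = np.clip(0.5 + (bounding_radius - dist_seed) / spacing, 0.0, 1.0)
    region = ndimage.binary_dilation(pocket) if n_vox else pocket
    volume = float(np.sum(frac_empty[region] * frac_bound[region]) * spacing**3)
    return PocketGrid(
        spacing=spacing,
        seed=seed,
        bounding_radius=bounding_radius,
        probe=probe,
        n_pocket_voxels=n_vox,
        volume=volume,
        origin=origin if keep_grid else None,
        pocket_mask=pocket if keep_grid else None,
    )


def pocket_contraction(
    state_a: StructureModel,
    state_b: StructureModel,
    seed_a,
    seed_b=None,
    align_protomer: str = "A",
    **grid_kwargs,
) -> tuple[float, float]:
    """Volume change between two states sharing a seed definition.

    When ``seed_b`` is omitted, ``seed_a`` is carried into state B's frame by
    superposing state A onto state B (common protomer C-alpha atoms), keeping
    the cavity definition consistent across states.  Returns
    ``(V_b - V_a, (V_a - V_b) / V_a)``.
    """
    seed_a = np.asarray(seed_a, float)
    if seed_b is None:
        sup = aligned_rmsd(state_b, state_a, align_protomer)  # maps a -> b frame
        seed_b = sup.apply(seed_a)
    v_a = pocket_volume(state_a, seed_a, **grid_kwargs).volume
    v_b = pocket_volume(state_b, seed_b, **grid_kwargs).volume
    if v_a == 0:
        raise ConfigurationError("state A pocket volume is zero; contraction undefined")
    return v_b - v_a, (v_a - v_b) / v_a
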