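"""Torsion mutual-information network, allosteric pipelines and hubscores.

Residue-pair MI is computed per torsion-channel pair on equal-width circular
bins (default 24 x 15 deg), bias-corrected by subtracting the mean MI of
seeded permutation shuffles (floored at zero) and aggregated as the maximum
over the <= 9 channel pairs.  Edges of the pathway graph are restricted to
residue pairs whose mean C-alpha separation is within a proximity cutoff, so
pipelines are spatially contiguous chains; the edge weight
``-log(MI / MI_max + eps)`` (normalised so the strongest edge has weight 0)
turns highest-MI paths into minimum-weight paths.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import ConfigurationError, DimerStateError
from .interface import contact_persistence
from .model import StructureModel
from .trajectory import TorsionSeries, Trajectory

__all__ = [
    "MINetwork",
    "AllostericPipeline",
    "HubScoreTable",
    "torsion_mutual_information",
    "build_mi_graph",
    "define_site_residues",
    "shortest_pipelines",
    "hubscores",
    "binned_mutual_information",
    "mi_path_weight",
]

log = logging.getLogger(__name__)

PATH_WEIGHT_EPS = 1e-6


def mi_path_weight(mi: float, mi_max: float, eps: float = PATH_WEIGHT_EPS) -> float:
    """Additive path weight for an MI edge, normalised so the strongest edge
    has weight exactly 0 (keeps all weights non-negative for Dijkstra)."""
    scale = mi_max if mi_max > 0 else 1.0
    return float(-np.log((mi / scale + eps) / (1.0 + eps)))


@dataclass
class MINetwork:
    residues: list  # residue keys (chain, res_id, ins_code)
    mi: np.ndarray  # (n, n) symmetric, bits, zero diagonal
    bins: int
    n_permutations: int
    seed: int

    def pair_mi(self, i: int, j: int) -> float:
        return float(self.mi[i, j])


@dataclass
class AllostericPipeline:
    path: list  # ordered residue keys
    source: object
    target: object
    strength: float  # sum of edge MI along the path, bits
    rank: int | None = None


@dataclass
class HubScoreTable:
    counts: dict
    n_pipelines: int

    def top(self, n: int = 10) -> list[tuple[object, int]]:
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], str(kv[0])))[:n]


def _digitize_circular(angles_deg: np.ndarray, bins: int) -> np.ndarray:
    """Map angles in (-180, 180] to integer bins 0..bins-1 (equal width)."""
    frac = (np.asarray(angles_deg, float) + 180.0) % 360.0 / 360.0
    return np.minimum((frac * bins).astype(np.int64), bins - 1)


def binned_mutual_information(x_codes, y_codes, bins: int) -> float:
    """Plug-in MI (bits) of two integer code series on ``bins`` levels."""
    x_codes = np.asarray(x_codes)
    y_codes = np.asarray(y_codes)
    n = len(x_codes)
    joint = np.bincount(x_codes * bins + y_codes, minlength=bins * bins).reshape(bins, bins)
    p = joint / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (px[:, None] * py[None, :])[nz])))


def _mi_batch(x_variants: np.ndarray, y: np.ndarray, bins: int) -> np.ndarray:
    """MI of each row of ``x_variants`` against ``y`` via one bincount."""
    k, n = x_variants.shape
    codes = x_variants * bins + y[None, :] + (np.arange(k)[:, None] * bins * bins)
    joint = np.bincount(codes.ravel(), minlength=k * bins * bins).reshape(k, bins, bins)
    p = joint / n
    px = p.sum(axis=2)
    py = p.sum(axis=1)
    denom = px[:, :, None] * py[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p * np.log2(p / denom)
    return np.nansum(term, axis=(1, 2))


def torsion_mutual_information(
    series: TorsionSeries,
    bins: int = 24,
    n_permutations: int = 20,
    seed: int = 0,
) -> MINetwork:
    """Bias-corrected residue-pair MI network from torsion time series."""
    if bins < 6:
        raise ConfigurationError(f"need >= 6 circular bins, got {bins}")
    if series.n_frames < 100:
        warnings.warn(
            f"only {series.n_frames} frames; MI estimates will be noisy (>=100 recommended)"
        )
    rng = np.random.default_rng(seed)
    valid_residues = [r for r in range(series.n_residues) if series.mask[r].any()]
    dropped = series.n_residues - len(valid_residues)
    if dropped:
        warnings.warn(f"dropped {dropped} residues with no valid torsions from MI network")
    residues = [series.residues[r] for r in valid_residues]
    n = len(residues)
    n_frames = series.n_frames

    # digitized codes and their permuted variants, per residue channel
    codes: list[list[np.ndarray]] = []
    perms: list[list[np.ndarray]] = []
    for r in valid_residues:
        ch_codes, ch_perms = [], []
        for t in range(series.angles.shape[2]):
            if not series.mask[r, t]:
                ch_codes.append(None)
                ch_perms.append(None)
                continue
            c = _digitize_circular(series.angles[:, r, t], bins)
            ch_codes.append(c)
            if n_permutations > 0:
                pm = np.empty((n_permutations, n_frames), dtype=np.int64)
                for k in range(n_permutations):
                    pm[k] = c[rng.permutation(n_frames)]
                ch_perms.append(pm)
            else:
                ch_perms.append(None)
        codes.append(ch_codes)
        perms.append(ch_perms)

    mi = np.zeros((n, n))
    n_channels = series.angles.shape[2]
    for i in range(n):
        for j in range(i + 1, n):
            best = 0.0
            for ti in range(n_channels):
                if codes[i][ti] is None:
                    continue
                for tj in range(n_channels):
                    if codes[j][tj] is None:
                        continue
                    if perms[i][ti] is not None:
                        stackx = np.vstack([codes[i][ti][None, :], perms[i][ti]])
                        vals = _mi_batch(stackx, codes[j][tj], bins)
                        corrected = max(0.0, float(vals[0] - vals[1:].mean()))
                    else:
                        corrected = binned_mutual_information(
                            codes[i][ti], codes[j][tj], bins
                        )
                    best = max(best, corrected)
            mi[i, j] = mi[j, i] = best
    return MINetwork(
        residues=residues, mi=mi, bins=bins, n_permutations=n_permutations, seed=seed
    )


def _mean_ca_positions(topology_or_traj, residues):
    if isinstance(topology_or_traj, Trajectory):
        topo = topology_or_traj.topology
        coords = topology_or_traj.mean_coords()
    elif isinstance(topology_or_traj, StructureModel):
        topo = topology_or_traj
        coords = topo.coords
    else:
        raise ConfigurationError("expected StructureModel or Trajectory for proximity rule")
    pos = {}
    for i in range(len(topo)):
        if str(topo.atom_names[i]) != "CA":
            continue
        key = (str(topo.chain_ids[i]), int(topo.res_ids[i]), str(topo.ins_codes[i]))
        pos.setdefault(key, coords[i])
    out = []
    for key in residues:
        if key not in pos:
            raise ConfigurationError(f"no CA position for residue {key}")
        out.append(pos[key])
    return np.asarray(out)


def build_mi_graph(
    network: MINetwork,
    topology,
    proximity_cutoff: float = 10.0,
    eps: float = PATH_WEIGHT_EPS,
) -> nx.Graph:
    """MI-weighted graph with proximity-eligible edges.

    Edge weight ``-log(MI_ij / MI_max + eps)`` so that minimum-weight paths
    are the highest-MI paths; the raw MI is kept as edge attribute ``mi``.
    """
    ca = _mean_ca_positions(topology, network.residues)
    n = len(network.residues)
    mi_max = float(network.mi.max())
    g = nx.Graph()
    g.add_nodes_from(network.residues)
    diff = ca[:, None, :] - ca[None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=2))
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] > proximity_cutoff:
                continue
            mi_ij = float(network.mi[i, j])
            g.add_edge(
                network.residues[i],
                network.residues[j],
                mi=mi_ij,
                distance=float(dist[i, j]),
                weight=mi_path_weight(mi_ij, mi_max, eps),
            )
    return g


def define_site_residues(
    traj: Trajectory, partner_chain: str, threshold: float = 0.60
) -> set:
    """Receptor residues in contact with ``partner_chain`` in > threshold of frames."""
    topo = traj.topology
    partner_mask = topo.chain_mask(partner_chain)
    if not partner_mask.any():
        raise ConfigurationError(f"chain {partner_chain!r} absent from topology")
    rec_mask = topo.receptor_mask() if topo.protomer_map else (~topo.hetero & ~partner_mask)
    rec_mask &= ~partner_mask
    group_a = sorted({(str(topo.chain_ids[i]), int(topo.res_ids[i])) for i in np.flatnonzero(rec_mask)})
    group_b = sorted({(str(topo.chain_ids[i]), int(topo.res_ids[i])) for i in np.flatnonzero(partner_mask)})
    result = contact_persistence(traj, group_a, group_b, threshold)
    site = set()
    for (res_a, _res_b), freq in result.frequencies.items():
        if freq > threshold:
            site.add(res_a)
    return site


def shortest_pipelines(
    graph: nx.Graph, sources, targets, top_n: int | None = 10
) -> list[AllostericPipeline]:
    """Minimal-weight (highest-MI) path for every (source, target) pair.

    Pipelines are sorted by strength (sum of edge MI, descending), ties
    broken by shorter path then lexicographic residue order; the top ``top_n``
    are retained and ranked from 1.
    """
    sources = sorted(set(sources), key=str)
    targets = sorted(set(targets), key=str)
    if not sources or not targets:
        raise ConfigurationError("source and target sets must be non-empty")
    pipelines = []
    for s in sources:
        if s not in graph:
            log.warning("source %s not in graph; skipped", s)
            continue
        lengths, paths = nx.single_source_dijkstra(graph, s, weight="weight")
        for t in targets:
            if t == s:
                continue
            if t not in paths:
                log.warning("no path %s -> %s; skipped", s, t)
                continue
            path = paths[t]
            strength = sum(graph[u][v]["mi"] for u, v in zip(path, path[1:]))
            pipelines.append(
                AllostericPipeline(path=path, source=s, target=t, strength=float(strength))
            )
    pipelines.sort(key=lambda p: (-p.strength, len(p.path), [str(x) for x in p.path]))
    if top_n is not None:
        pipelines = pipelines[:top_n]
    for rank, p in enumerate(pipelines, start=1):
        p.rank = rank
    return pipelines


def hubscores(pipelines: list[AllostericPipeline]) -> HubScoreTable:
    """Per-residue count of retained pipelines passing through it (endpoints included)."""
    if not pipelines:
        raise DimerStateError("need at least one pipeline for hubscores")
    counts: dict = {}
    for p in pipelines:
        for res in set(p.path):
            counts[res] = counts.get(res, 0) + 1
    return HubScoreTable(counts=counts, n_pipelines=len(pipelines))
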