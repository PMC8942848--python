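"""Stage orchestration: state-comparison and allosteric-analysis reports.

Every report embeds the full parameter set (audit trail) so reruns with the
same config and seed reproduce outputs exactly.  Exit-code convention at the
CLI: 0 success, 2 partial (some stages failed), 1 fatal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .allosteric import (
    build_mi_graph,
    define_site_residues,
    hubscores,
    shortest_pipelines,
    torsion_mutual_information,
)
from .errors import DimerStateError
from .geometry import aligned_rmsd, axial_rotation_angle, kink_angle, residue_displacement
from .interface import buried_interface_area
from .pocket import ligand_centroid, pocket_volume
from .structure_io import assign_protomers, load_segment_table, read_structure
from .trajectory import compute_torsions, load_trajectory

log = logging.getLogger(__name__)


@dataclass
class StateComparisonReport:
    states: dict
    pairs: list = field(default_factory=list)
    interface_areas: dict = field(default_factory=dict)
    pocket_volumes: dict = field(default_factory=dict)
    errors: list = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "tool": {"name": "dimerstate", "version": __version__},
            "parameters": self.parameters,
            "states": self.states,
            "pairs": self.pairs,
            "interface_areas_A2": self.interface_areas,
            "pocket_volumes_A3": self.pocket_volumes,
            "errors": self.errors,
        }


def _load_state(entry: dict):
    model = read_structure(entry["path"], format=entry.get("format"))
    chains = entry.get("receptor_chains")
    if chains is None:
        chains = sorted(set(model.chain_ids[~model.hetero]))[:2]
    return assign_protomers(model, chains)


def run_state_comparison(config: dict) -> StateComparisonReport:
    """Execute geometry/interface/pocket stages over configured state pairs.

    Config keys: ``states`` ({name: {path, receptor_chains, ligand_chain}}),
    ``pairs`` ([[ref, alt], ...]; default all consecutive), ``measure``
    (residue numbers), ``segments`` (path or name->range map),
    ``align_protomer``, ``interface`` (bool), ``pocket`` (bool).
    """
    states_cfg = config["states"]
    if len(states_cfg) < 2 and not (config.get("interface") or config.get("pocket")):
        raise DimerStateError("need >= 2 states for a comparison report")
    align = config.get("align_protomer", "A")
    measure = [int(r) for r in config.get("measure", [])]
    segments = {}
    if config.get("segments"):
        seg = config["segments"]
        table = load_segment_table(seg) if isinstance(seg, (str, Path)) else None
        if table is not None:
            segments = {k: v for k, v in table.segments.items()}
        else:
            segments = {k: tuple(v) for k, v in seg.items()}
    kink_segments = {k: v for k, v in segments.items() if config.get("angles", True)}

    report = StateComparisonReport(
        states={name: entry["path"] for name, entry in states_cfg.items()},
        parameters={
            "align_protomer": align,
            "measure": measure,
            "segments": {k: list(v) for k, v in segments.items()},
            "config": {k: v for k, v in config.items() if k != "states"},
        },
    )
    models = {}
    for name, entry in states_cfg.items():
        try:
            models[name] = (_load_state(entry), entry)
        except Exception as exc:
            log.error("loading state %s failed: %s", name, exc)
            report.errors.append({"stage": "load", "state": name, "error": str(exc)})

    names = [n for n in states_cfg if n in models]
    pairs = config.get("pairs") or [[names[i], names[i + 1]] for i in range(len(names) - 1)]
    for ref_name, alt_name in pairs:
        if ref_name not in models or alt_name not in models:
            continue
        ref, _ = models[ref_name]
        alt, _ = models[alt_name]
        entry = {"ref": ref_name, "alt": alt_name}
        try:
            sup = aligned_rmsd(ref, alt, align)
            entry["rmsd"] = round(sup.rmsd, 3)
            entry["n_atoms"] = sup.n_atoms
            if measure:
                disp = residue_displacement(ref, alt, align, measure)
                entry["displacements"] = {
                    str(r.res_id): (None if m else round(v, 2))
                    for r, v, m in disp.entries
                }
            angles = {}
            for seg_name, rng in kink_segments.items():
                if not seg_name.upper().startswith("H"):
                    continue
                try:
                    angles[seg_name] = {
                        "kink_deg": round(kink_angle(ref, alt, align, rng, align), 1),
                        "axial_deg": round(
                            axial_rotation_angle(ref, alt, align, rng), 1
                        ),
                    }
                except DimerStateError as exc:
                    angles[seg_name] = {"error": str(exc)}
            if angles:
                entry["segment_angles"] = angles
        except Exception as exc:
            log.error("pair %s/%s failed: %s", ref_name, alt_name, exc)
            report.errors.append(
                {"stage": "compare", "pair": [ref_name, alt_name], "error": str(exc)}
            )
        report.pairs.append(entry)

    if config.get("interface"):
        for name, (model, _) in models.items():
            try:
                report.interface_areas[name] = round(buried_interface_area(model), 1)
            except Exception as exc:
                report.errors.append({"stage": "interface", "state": name, "error": str(exc)})
    if config.get("pocket"):
        for name, (model, entry) in models.items():
            lig = entry.get("ligand_chain")
            if not lig:
                continue
            try:
                seed = ligand_centroid(model, lig)
                report.pocket_volumes[name] = round(
                    pocket_volume(model, seed).volume, 1
                )
            except Exception as exc:
                report.errors.append({"stage": "pocket", "state": name, "error": str(exc)})
    return report


def write_state_comparison(report: StateComparisonReport, out_prefix) -> list[Path]:
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    json_path = out_prefix.with_suffix(".json")
    json_path.write_text(json.dumps(report.as_dict(), indent=2, sort_keys=True))
    rows = []
    for pair in report.pairs:
        row = {
            "ref": pair.get("ref"),
            "alt": pair.get("alt"),
            "rmsd_A": pair.get("rmsd"),
            "n_atoms": pair.get("n_atoms"),
        }
        for res, val in (pair.get("displacements") or {}).items():
            row[f"disp_{res}_A"] = val
        rows.append(row)
    tsv_path = out_prefix.with_suffix(".tsv")
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    return [json_path, tsv_path]


def run_allosteric_analysis(config: dict) -> dict:
    """Trajectory -> torsions -> MI -> graph -> pipelines -> hubscores.

    Config keys: ``topology``, ``trajectory``, ``ligand_chain`` /
    ``partner_chain`` or explicit ``sources`` / ``targets`` residue lists,
    ``bins``, ``permutations``, ``seed``, ``proximity_cutoff``, ``top``,
    ``site_threshold``.
    """
    seed = int(config.get("seed", 0))
    bins = int(config.get("bins", 24))
    perms = int(config.get("permutations", 20))
    cutoff = float(config.get("proximity_cutoff", 10.0))
    top = int(config.get("top", 10))
    threshold = float(config.get("site_threshold", 0.60))

    traj = load_trajectory(config["topology"], config.get("trajectory"))
    series = compute_torsions(traj)
    network = torsion_mutual_information(series, bins=bins, n_permutations=perms, seed=seed)
    graph = build_mi_graph(network, traj, proximity_cutoff=cutoff)

    def _residues(value):
        return {("T" if isinstance(r, int) else r[0], r if isinstance(r, int) else int(r[1]), "")
                for r in value}

    if config.get("sources"):
        sources = _residues(config["sources"])
    else:
        sources = {(c, r, "") for c, r in define_site_residues(traj, config["ligand_chain"], threshold)}
    if config.get("targets"):
        targets = _residues(config["targets"])
    else:
        targets = {(c, r, "") for c, r in define_site_residues(traj, config["partner_chain"], threshold)}

    pipelines = shortest_pipelines(graph, sources, targets, top_n=top)
    table = hubscores(pipelines) if pipelines else None
    return {
        "parameters": {
            "bins": bins,
            "permutations": perms,
            "seed": seed,
            "proximity_cutoff_A": cutoff,
            "top": top,
            "site_threshold": threshold,
        },
        "network": network,
        "graph": graph,
        "sources": sorted(sources),
        "targets": sorted(targets),
        "pipelines": pipelines,
        "hubscores": table,
    }


def write_allosteric_outputs(result: dict, out_prefix) -> list[Path]:
    import networkx as nx

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []

    graph = result["graph"]
    export = nx.Graph()
    for node in graph.nodes:
        export.add_node("{}:{}{}".format(*node))
    for u, v, data in graph.edges(data=True):
        export.add_edge(
            "{}:{}{}".format(*u),
            "{}:{}{}".format(*v),
            mi=float(data["mi"]),
            weight=float(data["weight"]),
        )
    graphml = out_prefix.with_suffix(".graphml")
    nx.write_graphml(export, graphml)
    written.append(graphml)

    rows = [
        {
            "rank": p.rank,
            "source": "{}:{}{}".format(*p.source),
            "target": "{}:{}{}".format(*p.target),
            "strength_bits": round(p.strength, 6),
            "path": "->".join("{}:{}{}".format(*r) for r in p.path),
        }
        for p in result["pipelines"]
    ]
    pipe_path = out_prefix.parent / (out_prefix.name + "_pipelines.tsv")
    pd.DataFrame(rows).to_csv(pipe_path, sep="\t", index=False)
    written.append(pipe_path)

    hub_rows = []
    if result["hubscores"] is not None:
        for res, count in result["hubscores"].top(len(result["hubscores"].counts)):
            hub_rows.append({"residue": "{}:{}{}".format(*res), "hubscore": count})
    hub_path = out_prefix.parent / (out_prefix.name + "_hubscores.tsv")
    pd.DataFrame(hub_rows).to_csv(hub_path, sep="\t", index=False)
    written.append(hub_path)

    meta = out_prefix.parent / (out_prefix.name + "_params.json")
    meta.write_text(json.dumps(result["parameters"], indent=2, sort_keys=True))
    written.append(meta)
    return written
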