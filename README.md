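# dimerstate

Structural analysis of dimeric receptor conformational states:

- **structure I/O** — PDB/mmCIF reading and writing (biotite-backed), protomer
  labelling (A/B) of the receptor homodimer, and generic residue numbering
  from an anchored helix segment table;
- **geometry** — Kabsch superposition, common-Cα pairing between states,
  per-residue Cα displacements after global (protomer-A) alignment, helix
  axis fitting, and kink / axial-rotation angles of helix segments;
- **interface** — Shrake–Rupley SASA, buried dimer-interface area
  ((SASA_A + SASA_B − SASA_AB)/2), typed residue contacts (hydrogen bond,
  van der Waals, salt bridge, cation–π), contact persistence over
  trajectories (strict >60 % rule), and a reduced 12-6 LJ + Coulomb
  inter-protomer interaction energy;
- **pocket** — grid/flood-fill ligand-binding-pocket volume with
  signed-distance boundary correction, and pocket contraction between states;
- **trajectory** — multi-model PDB / DCD / XTC loading and φ/ψ/χ1 torsion
  extraction (IUPAC convention, circular statistics);
- **allosteric** — torsion mutual-information network (24 circular bins,
  permutation bias correction), proximity-constrained MI-weighted graph,
  highest-MI shortest pipelines between ligand-site and partner-site
  residues, and per-residue hubscores;
- **synthetic** — seed-deterministic generators: ideal helices, toy dimer
  states with planted rigid sub-segment motions, coupled-torsion trajectories
  rebuilt by NeRF chain extension (torsion extraction inverts the generator
  exactly), and contact series with exact planted frequencies.

## CLI

Installed as `dimerstate` (also `python -m dimerstate.cli`):

```sh
# synthetic inputs (dimer states / torsion trajectory / contact series)
dimerstate simulate dimer --spec spec.toml --seed 1 --out out/

# state comparison: RMSD, named-residue displacements, segment angles
dimerstate compare --ref A.pdb --alt B.pdb --align-protomer A \
    --receptor-chains R,S --measure 243,267,273,301 --out report

# dimer interface report (optionally with a trajectory for persistence)
dimerstate interface --model dimer.pdb --threshold 0.6 --out interface.json

# pocket volume around a seed point or ligand centroid
dimerstate pocket --model x.pdb --seed auto --ligand-chain P --out pocket.json

# torsion-MI allosteric pipelines and hubscores
dimerstate allosteer --topology top.pdb --traj traj.xtc \
    --ligand-chain P --partner-chain G --bins 24 --perms 20 --seed 17 \
    --top 10 --out allosteer
```

Exit codes: 0 success, 2 partial (some stages failed, see the report's
`errors` list), 1 fatal.

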