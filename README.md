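# mtlminer

Mine a directory of protein–ligand crystal structures (legacy PDB text) for
**multiple-target ligands (MTLs)** — chemical components observed bound to two
or more proteins that remain distinct after sequence-identity redundancy
removal — and annotate them chemically.

The pipeline, stage by stage:

1. **Structure filter** — X-ray structures with resolution strictly < 3.0 Å.
2. **Ligand extraction** — hetero residues with strictly > 8 heavy atoms
   (waters always excluded).
3. **Binding-site extraction** — all amino-acid protein residues with any
   atom within 6.0 Å (inclusive) of any ligand atom; whole residues are kept;
   sites with strictly > 5 residues pass.
4. **Multi-structure gate** — only components seen in ≥ 2 distinct structures.
5. **Identity filtration** — primary binding chains clustered by
   single-linkage at ≥ 35 % global-alignment identity (BLOSUM62, gap open 10 /
   extend 0.5, identity over the shorter sequence); a ligand is an MTL when
   ≥ 2 non-redundant targets remain. Filtration can be switched off to get
   the full target list.
6. **Conformer analysis** — heavy atoms matched by name, Kabsch superposition,
   pairwise RMSD matrix; a ligand is *rigid* when the maximum RMSD ≤ 2.0 Å.
7. **Chemical annotation** — bond perception from coordinates, molecular
   weight, Lipinski rule-of-five descriptors (drug-like = ≤ 1 violation), an
   FP2-style 1024-bit path fingerprint, Tanimoto similarity search
   (default cutoff 0.8), connectivity-level SMILES.
8. **Statistics + export** — target-count bins (2 / 3–5 / 6–10 / >10), MW and
   RMSD histograms, deterministic per-record export with a hashed manifest.

A fixtures module generates synthetic PDB corpora with declared ground truth
(planted ligand–residue distances, sequence families, conformer RMSDs), so
everything is testable without downloading the PDB.

## CLI

```sh
# generate a synthetic corpus with ground truth
mtlminer fixtures --out corpus/ --seed 7

# run the pipeline and export the database
mtlminer run --pdb-dir corpus/ --out db/ \
    [--max-resolution 3.0] [--min-heavy-atoms 8] [--site-radius 6.0] \
    [--min-site-residues 5] [--identity-threshold 35] \
    [--no-identity-filtration] [--config cfg.json]

mtlminer stats --db db/
mtlminer search --db db/ --smiles '[C][C][N][C][C]' --cutoff 0.8
mtlminer annotate --db db/ --list drugs=approved_ids.txt
```

Each exported record directory contains the five information classes:
ligand conformer PDBs, SMILES, binding-site PDBs (+ residue TSVs with
minimum distances), the record JSON (source structures, clusters, RMSDs,
descriptors), and a FASTA of cluster-representative target sequences.

## Library

```python
from mtlminer import PipelineConfig, run_pipeline, export_database

db = run_pipeline("corpus/", PipelineConfig(identity_threshold=35.0))
print(db.mtl_count, db.stage_counts)
export_database(db, "db/")
```

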