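# sitescan

Analysis toolkit for classifying docked ligand poses into binding sites of
an ABC-transporter-style homodimer and for the accompanying
molecular-dynamics read-outs. It covers:

- **structio** — PDB (multi-model, doubling as a trajectory dialect),
  docking-output PDBQT (`REMARK VINA RESULT` multi-MODEL files) and FASTA
  I/O over one uniform coordinate model.
- **seqtools** — deterministic affine-gap global alignment (BLOSUM62,
  gap open 10 / extend 0.5 by default), percent identity/similarity under
  documented denominator conventions, and CRAC cholesterol-motif scanning
  `(L/V)-X(1..5)-Y-X(1..5)-(R/K)`.
- **geometry** — Kabsch superposition (plus an iterative outlier-rejection
  variant), per-frame RMSD series, Cα–Cα distance series, non-overlapping
  block averaging, membrane-depth annotation from a user-supplied
  hydrophobic slab, and GLY/ALA side-chain truncation mutants.
- **sites** — heavy-atom residue-contact detection (default cutoff 4.5 Å,
  inclusive) and assignment of each pose to Site 1–4 or an overlap region
  (S1-2, S2-3, S1-3) by contacted-residue counts; the four built-in site
  residue lists ship with the package.
- **stats** — site × category occupancy tables normalized by
  molecules × poses × conformations, per-category affinity summaries with
  Silverman-rule densities, and descriptive WT-vs-mutant distance-dynamics
  comparison (no p-values: MD frames are autocorrelated).
- **synth** — a fully deterministic synthetic-data generator (helix-bundle
  receptor, pose clouds with known target sites, scripted distance series)
  so every stage runs and is testable offline.

## CLI

All stages are exposed through one entry point; every run writes a
`manifest.json` (package version, config hash, per-file SHA-256) into its
output directory, and reruns on unchanged inputs are byte-identical.

```sh
sitescan simulate --seed 1 --out sim/                    # synthetic dataset
sitescan assign-poses --receptor sim/receptor.pdb --poses sim/poses \
    --sites sim/sites.tsv --categories sim/categories.tsv --out assign/
sitescan site-stats --assignments assign/assignments.tsv --out stats/
sitescan traj-distances --traj sim/trajectory.pdb --pair A:5,A:35 --out td/
sitescan traj-rmsd --traj sim/trajectory.pdb --chain A --out tr/
sitescan align-stats --fasta two_seqs.fasta --out al/
sitescan crac-scan --fasta seqs.fasta --out cs/
sitescan depth-annotate --structure sim/receptor.pdb \
    --z-lower -15 --z-upper 15 --out da/
```

Use `--sites builtin` with `assign-poses` to classify against the four
built-in binding-site residue lists (author numbering).

## Reference data

A few analyses (full-length identity/similarity percentages, template
chain A/B RMSD, the CRAC scan of the real sequence) consume public
reference data: three UniProt sequences (ABCG2_HUMAN, ABCG5_HUMAN,
ABCG8_HUMAN) and PDB entry 5DO7. These are not redistributed; on a
networked machine run

```sh
python scripts/fetch_data.py
```

to place them under `src/sitescan/data/`. Without them, the affected
tests and acceptance targets report a clear `MissingDataError` and are
skipped from the acceptance report; everything else is generated
synthetically and runs offline.

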