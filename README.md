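# plbind

Automatic generation of sequence-based protein–ligand binding-residue
predictors: from protein–ligand complex structures to tuned, evaluated
classifiers.

The pipeline:

1. **`plbind.structure`** — parse fixed-column PDB text, index atoms with an
   octree, and extract ligand-binding residues (any residue with an atom
   within a cutoff, default 5 Å, of any ligand atom), excluding ligands
   covalently bonded to the polymer or to another ligand.
2. **`plbind.dataset`** — remove sequence redundancy (greedy clustering at
   90 % identity / 50 % coverage of the shorter sequence, exact global
   alignment with BLOSUM62), then label residues: contacts are positives,
   residues 5–25 positions away from a positive are negatives.
3. **`plbind.profiles`** — position-specific scoring profiles, either parsed
   from PSI-BLAST ASCII PSSM files or computed from a multiple sequence
   alignment, encoded per residue as a `w × 21` sliding window (20 profile
   scores + 1 terminal-spacer flag per slot).
4. **`plbind.learners`** — RBF-kernel SVM, single-hidden-layer sigmoid
   neural network, and random forest behind one train/score contract.
5. **`plbind.hyperopt`** — hyperparameter search (including `w`) by genetic
   algorithm (tournament selection, single-point crossover 0.8, point
   mutation 0.05, elitism) or exhaustive grid, with mean cross-validated AUC
   as fitness and an SQLite evaluation cache that never retrains a genotype.
6. **`plbind.evaluate`** — ROC/AUC, MCC, sensitivity/specificity under
   stratified k-fold cross-validation (default 5-fold), report writers and
   ROC plotting.
7. **`plbind.fixtures`** — deterministic toy generators (complexes with
   planted contact geometry, sequence families with controlled identity,
   Gaussian-separated feature sets) so everything runs offline.

## CLI

```sh
plbind fixtures make --kind complex --seed 1 --out fx/
plbind extract   --pdb fx/complex.pdb --cutoff 5.0 --out annotations.tsv
plbind dataset   --annotations annotations.tsv --fasta seqs.fasta --ligands LIG
plbind featurize --dataset dataset.tsv --from-msa msa_dir/ --w 9 --out features.npz
plbind tune      --features features.npz --algorithm svm --method ga --seed 42 --out-dir tuned/
plbind evaluate  --features features.npz --params tuned/best.json --out-dir eval/
```

`tune --config config.yaml` accepts gene `bounds`, a `grid` section (for
`--method grid`), `folds`, and `ga` constants.

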