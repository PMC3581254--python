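# ctxflex

Structural-context flexibility profiles and catalytic-residue prediction from
protein structures.

## The problem

Enzyme catalytic residues are a tiny fraction of all residues (typically well
under 1%), yet they sit in distinctive structural surroundings: they and
their neighbors are usually packed into the most rigid parts of the fold.
`ctxflex` quantifies that structural context from a single Cα trace — no
homologs, no sequence profiles required — and uses it to rank and classify
candidate catalytic residues.

## The model

For residue *i* of an *N*-residue chain, the **weighted contact number**

```
wcn_i = Σ_{j≠i} 1 / r_ij²        (r_ij = Cα–Cα distance, Å)
```

is a packing-density proxy: high WCN means buried and rigid. Its inverse
`wcn_i⁻¹` is oriented like a crystallographic B-factor (high = flexible).
Two context profiles average inverse WCN over a residue's neighborhood:

* **SEQ** — over residues *i−n … i+n* along the sequence (window half-width
  *n*, default 1; indices beyond the termini are ignored),
* **STR** — over residue *i* plus every residue strictly within a spatial
  cutoff (default 3 Å).

Each profile, and the Cα B-factor column, is standardized per protein
(`z = (x − x̄)/σ`), giving the dimensionless **Z_SEQ**, **Z_STR** and
**Z_B** tracks. Catalytic residues show strongly negative Z_SEQ/Z_STR —
typically below −1 — even where their experimental Z_B is misleadingly high.

For classification, per-residue feature vectors (any combination of a 20-bit
amino-acid code, Z_SEQ, Z_STR, Z_B, and an optional PSI-BLAST conservation
column) feed a C-SVC with RBF kernel. The extreme class imbalance is handled
by **balanced subsampling** (all positives + an equal-sized random draw of
negatives) on the training side; `cost` and `gamma` are grid-tuned by inner
stratified 5-fold CV on the Matthews correlation coefficient (MCC).
Evaluation uses protein-level 5-fold cross-validation (no chain appears on
both sides of a fold), balanced test subsets for sensitivity/specificity/MCC,
and unbalanced per-protein ROC curves averaged vertically on a common
false-positive-rate grid.

## Worked example

Generate four synthetic 60-residue proteins with three catalytic sites each
planted at structurally rigid positions, then profile one chain:

```
$ ctxflex synth --n-proteins 4 --n-residues 60 --seed 3 --out-dir demo
wrote 4 chains and 12 labels to demo
$ ctxflex profile --pdb demo/syn000.pdb --chain A --labels demo/labels.tsv --out demo/profile.tsv
wrote 60 residues to demo/profile.tsv
```

The catalytic rows of `demo/profile.tsv`:

```
 res_seq aa  b_factor    z_seq    z_str       z_b
       8  T     13.72 -1.31030 -1.03193 -1.433360
      19  D     19.53 -1.31302 -1.18531 -0.380115
      29  Q     15.88 -1.33087 -1.32836 -1.041790
```

All three planted sites have Z_SEQ below −1.3: they sit in this chain's most
rigid sequence context, which is exactly the signal the classifier exploits.
`ctxflex train` / `ctxflex predict` then fit the SVM on a feature TSV
(written by `ctxflex.build_feature_table`) and emit per-residue
probabilities plus a per-protein rank, rank 1 being the most probable
catalytic residue.

For real structures, `ctxflex profile --pdb 1bwz.pdb --chain A --n 1` works
directly on a PDB file; heteroatoms, waters and ligands are removed on read,
and labels can come from a Catalytic Site Atlas flat file or a simple TSV.

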