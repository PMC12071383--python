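# mutpocket

Structural profiling of missense mutation sites on protein structures:
per-atom **exposed-volume depth indices**, classification of each site into
three topological layers by side-chain position and orientation, and
prioritization of substitutions likely to **open new surface pockets**.

The package is aimed at structural bioinformaticians triaging large panels of
missense variants (e.g. from monogenic rare-disease catalogues): most
pathogenic substitutions either destabilize the buried core or remodel the
surface, and the surface-remodelling subset — where a bulky, outward-pointing
residue is replaced by a much smaller one — is the subset where a
small-molecule binding site may appear and a pharmacological rescue becomes
conceivable.

## Model

**Depth index.** For heavy atom *i*, place a reference sphere of radius *r*
(default 10 Å) on the atom and measure the fraction of that sphere not
occupied by the protein body:

    D_i = 2 · V_exposed(i, r) / V_sphere(r)

so a fully exposed atom approaches 2, an atom on a flat surface is ≈ 1, and a
deeply buried atom approaches 0. The protein body is the union of van der
Waals spheres rasterized on a cubic grid (default 0.5 Å), with
solvent-inaccessible cavities — voxels a 1.4 Å probe cannot reach from bulk
solvent — counted as body. This is the exposed-volume depth-index family
popularized by the SADIC tool.

**Orientation.** Per residue the package compares the Cα depth `D_iα` with
the mean side-chain heavy-atom depth `D_iSC` (Cβ included; for Gly
`D_iSC := D_iα`). `D_iSC > D_iα` means the side chain points toward the
solvent (*outward*); ties and the reverse are *inward*.

**Topological clusters.** Each mutation site is assigned by the wild-type
residue and its depth profile:

| cluster | rule | amino acids |
|---|---|---|
| 1 (inner layer) | `D_iα ≤ 0.2` and `D_iSC < D_iα` | Ala, Cys, Gly, Ile, Leu, Met, Phe, Val |
| 2 (outer layer) | `D_iSC > 0.5` and `D_iSC > D_iα` | Tyr, Phe, Leu, Ile, Val, Trp, Met, Asp, Glu, His, Lys, Arg |
| 3 (intermediate) | all other cases | all |

**Pocket candidates.** With *V* the wild-type and *v* the mutant residue
volume (Zamyatnin volumes by default, fully configurable), a cluster-2 site
with `V/v > 1.3` removes enough outward-pointing bulk to be flagged as a
potential new-surface-pocket site.

Sites on predicted models are profiled only when the model passes the
confidence gate (mean pLDDT > 0.8 over the chain *and* pLDDT > 0.8 at the
site; B-factor column, 0–100 or 0–1 scale autodetected).

## Worked example

The package ships a synthetic-data module that builds a helix bundle with
planted side-chain orientations plus a variant table with known ground truth
(no downloads needed):

```sh
mutpocket fixtures demo --seed 0
mutpocket profile --variants demo/variants.tsv --structures demo -o demo/profile.tsv
mutpocket summarize demo/profile.tsv -o demo/summary.json
```

which prints

```
profiled sites: 10
  cluster 1: 3 (30.0%)
  cluster 2: 3 (30.0%)
  cluster 3: 4 (40.0%)
  pocket candidates: 2 (66.7% of cluster 2)
```

and the head of `demo/profile.tsv` reads

```
gene   uniprot  mutation   cluster orientation D_ia  D_isc ratio v_ratio pocket_candidate status
SYNT1  P99999   Val341Phe  1       inward      0.143 0.109 0.763 0.74    False            profiled
SYNT1  P99999   Met358Trp  1       inward      0.107 0.007 0.070 0.72    False            profiled
SYNT1  P99999   Met347Trp  1       inward      0.136 0.008 0.059 0.72    False            profiled
SYNT1  P99999   Lys8Gly    2       outward     0.428 0.775 1.809 2.81    True             profiled
```

Reading a row: `Lys8Gly` sits at a surface position (`D_iα 0.428`), its side
chain points outward (`D_iSC 0.775 > D_iα`), the wild-type residue belongs to
the bulky/charged outer-layer set, and replacing lysine by glycine removes
2.81× the residue volume — a pocket candidate. The eleventh input row is
reported with status `plddt_filtered`: its planted model confidence is below
the 0.8 gate, so no structural call is made. One record mutates a glycine,
exercising the `D_iSC := D_iα` convention (orientation `inward` by the tie
rule).

`mutpocket depth structure.pdb -o structure_depth.pdb --tsv depths.tsv`
writes a copy of a structure with each atom's depth index in the B-factor
column, plus a per-atom table.

## Library use

```python
from mutpocket import (DepthParams, compute_residue_depths, classify_site,
                       read_structure)

structure = read_structure("model.pdb", source="predicted-model")
depths = compute_residue_depths(structure, DepthParams(reference_radius=10.0))
rd = depths[(149, "")]                       # author residue number 149
print(rd.d_alpha, rd.d_sidechain, rd.ratio)  # D_ia, D_isc, D_isc/D_ia
print(classify_site("VAL", "GLY", rd))       # cluster, orientation, V/v, flag
```

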