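# Methods

## Depth index

The depth index of a heavy atom is `D_i = 2 · V_exposed / V_sphere`, where
`V_sphere` is a reference sphere of radius `r` centered on the atom and
`V_exposed` its part outside the protein body. The normalization makes the
scale easy to read: an isolated atom scores just under 2 (its own van der
Waals sphere occupies `(r_vdw/r)³` of the reference sphere), an atom on a
flat surface scores ≈ 1, and an atom whose whole reference sphere is protein
scores 0. The classification thresholds (0.2 on Cα depth for the inner
layer, 0.5 on side-chain depth for the outer layer) presuppose this [0, 2]
scale.

### Parameters

| parameter | default | units | role |
|---|---|---|---|
| `reference_radius` (r) | 10.0 | Å | horizon of the burial measurement; must exceed the largest vdW radius |
| `grid_spacing` (h) | 0.5 | Å | voxel edge; validated `h ≤ r/10` |
| `probe_radius` | 1.4 | Å | solvent probe for the cavity flood fill (water) |
| `fill_cavities` | true | — | count solvent-inaccessible voids as body |
| vdW radii | C 1.70, N 1.55, O 1.52, S 1.80, Se 1.90, else 1.70 | Å | Bondi-type values; configurable table |

The reference implementation of this depth-index family (the SADIC tool used
in the source study) does not publish its v2.0 defaults; `r = 10 Å` is chosen
because it reproduces the qualitative regime the thresholds assume
(flat-surface atoms ≈ 1, exposed side chains > 1, core atoms ≪ 0.2). All
parameters are exposed (`DepthParams`, CLI flags) precisely so results can be
recalibrated against any published depth output; depth ratios quoted by other
tools at unknown settings should be expected to differ in detail.

### Voxelization and cavity handling

A voxel belongs to the body when its center lies within the vdW radius of
any atom (voxel-center containment, no partial-volume weighting; the
quantization error this admits is bounded by the grid-convergence check
below). With cavity filling on, solvent is defined constructively: voxel
centers at least `probe_radius` from every atom surface are *free*; the free
region 6-connected to the box boundary is bulk solvent; re-expanding it by
the probe radius (a morphological dilation clipped to non-body voxels)
yields the solvent-accessible region, and **everything else counts as body**
— internal cavities, solvent-inaccessible channels, and reentrant crevices
narrower than the probe. This prevents internal voids from inflating the
apparent exposure of atoms lining them. With `probe_radius = 0` the
construction degenerates to plain flood-fill hole filling.

One numerical subtlety: free-voxel centers sit up to `√3/2·h` away from the
continuous free-space boundary, so the re-expansion uses a dilation ball of
radius `probe_radius + √3/2·h`. Without the slack the body systematically
keeps a spurious shell (~0.3–0.4 Å at h = 0.5) on open surfaces, which
depresses flat-surface depths by ~0.06.

The grid box extends `r + max(r_vdw)` beyond every atom so each reference
sphere lies inside the grid; a configurable voxel budget (default 4·10⁸,
≈ 400 MB of booleans) guards against accidental huge boxes and the error
message suggests increasing the spacing.

### Numerical behaviour (verified in the test suite)

* isolated atom: D = 1.990 ± 0.02 (analytic);
* center of a solid 5 Å ball at r = 10: D = 1.75 ± 0.05 (analytic);
* atom on a wide slab face: D = 1.00 ± 0.05 (half-space symmetry);
* atom enclosed by a 12 Å ball: D ≤ 0.02;
* agreement with an independent Monte-Carlo estimator (10⁵ points,
  point-in-union test) within 3σ on ≤ 200-atom bodies;
* halving h from 0.5 to 0.25 moves D by ≤ 0.02 on these fixtures;
* rigid motions change any D by ≤ 0.05 at h = 0.5; adding atoms never
  increases any existing atom's depth.

## Per-residue profile and orientation

`D_iα` is the Cα depth; `D_iSC` is the arithmetic mean over side-chain heavy
atoms, where the side chain is every heavy atom outside {N, CA, C, O, OXT}
(Cβ included — the convention is a package decision; the rule's source does
not state whether Cβ counts). Glycine has no side-chain heavy atom and gets
`D_iSC := D_iα`. A side chain is *outward* iff `D_iSC > D_iα` strictly; ties
are inward. The ratio `D_iSC/D_iα` is reported when `D_iα > 0` and is
undefined otherwise.

## Cluster rules and pocket candidates

Cluster 1 requires `D_iα ≤ 0.2` (inclusive, following the tabulated rule
over looser prose), `D_iSC < D_iα` (strict) and membership in the
small/hydrophobic set; cluster 2 requires `D_iSC > 0.5` and `D_iSC > D_iα`
(both strict) and membership in the bulky/charged set; everything else is
cluster 3. The two rule sets are disjoint since cluster 1 forces
`D_iSC < 0.2 < 0.5`. Because the glycine convention makes `D_iSC < D_iα`
unsatisfiable, and glycine is explicitly part of the inner-layer set, glycine
sites are cluster-1 eligible whenever `D_iα ≤ 0.2` (the strict inequality is
relaxed for Gly only).

Volume ratios `V/v` use Zamyatnin (1972) residue volumes by default
(`VolumeTable`, JSON-configurable). The study this package operationalizes
prints ratios from an unidentified volume reference; against Zamyatnin the
printed worked examples run up to ~3% higher (Val→Gly 2.37 vs 2.33, Trp→Gly
3.89 vs 3.79, Ile→Thr 1.45 vs 1.44). The table is configuration, not code,
so an exact match is a matter of supplying the right JSON. A pocket candidate
is a cluster-2 site with `V/v > 1.3` strictly.

Classification always uses the wild-type residue's depth profile on the
wild-type structure; no mutant modelling is attempted.

## Variant ingestion

Mutations use `Aaa<N>Bbb` notation (case-insensitive three-letter codes,
1-based position). Structure numbering is reconciled through an explicit
per-record offset (author resseq = position + offset); no remote numbering
services are consulted, keeping runs fully offline. The residue found at the
mapped position must equal the annotated wild type; a mismatch is a hard
per-row failure (`residue_mismatch`), never a silent re-guess — profiling
the wrong residue is the worst failure mode of this analysis class. Other
row statuses: `missing_structure` (file unreadable), `missing_residue`
(position absent from the model), `plddt_filtered` (confidence gate). The
pLDDT gate applies to predicted models only and is strict on both
conditions; the 0–100 vs 0–1 storage scale is detected by any B-factor
exceeding 1.5.

## Synthetic fixtures

The geometric fixtures are carbon pseudo-atom bodies with closed-form
expected depths: a single atom; a solid ball (cubic lattice interior plus a
golden-spiral shell exactly `r_C` under the nominal radius, so the
union-of-spheres surface sits at the nominal radius in every direction); a
slab whose top sphere surface is the z = 0 plane with the probe atom resting
on it; and a hollow shell enclosing a cavity for the flood-fill tests.

The helix bundle emulates a predicted monomer with planted ground truth:
ideal helices (rise 1.5 Å, 100°/residue, Cα 2.3 Å off the helix axis) on a
circle of radius 8 Å, side chains reduced to a single Cβ pseudo-atom 2.6 Å
from the Cα pointing toward the bundle axis or away from it, so orientation
ground truth is unambiguous. Three additional helices on a 3 Å inner circle
give the bundle a genuinely buried core — at r = 10 Å an atom is deeply
buried only when ~90% of a 10 Å sphere around it is protein, which a single
thin ring of helices cannot provide. B-factors carry a pLDDT-like profile
(0.95, with a seeded 5% of residues at 0.60). Fixture coordinates are
rounded to 3 decimals at construction so the PDB round trip is lossless and
the whole pipeline is bit-stable.

Variant fixtures choose sites whose expected labels clear every threshold
with a safety margin (0.05 on depth indices, 0.1 on V/v): expected cluster-2
rows come from planted-outward bulky residues mutated to Gly/Ser (pocket
candidates) or to a near-isosteric residue (contrast case), cluster-1 rows
from core small/hydrophobic residues mutated upward in size, cluster-3 rows
from exposed Ala/Cys (excluded from the outer set regardless of depth), plus
one glycine-convention site and one low-confidence site. The margins make
the expected table stable under grid quantization; orientation recovery
against the *planted* labels (≥ 90% required, 100% observed) is the
implementation-independent part of the check, and the exact reproduction of
the expected table through disk round trips checks integration and
determinism.

What the fixtures do **not** emulate: real side-chain rotamers and packing,
irregular folds, missing density, alternate conformations at scale, or the
numbering quirks of deposited entries. Passing on fixtures therefore
validates the geometry engine and the rules, not agreement with any
particular published depth tool on real structures.

## Structure I/O conventions

PDB parsing/writing is delegated to biotite behind the package's own model.
Hydrogens, HETATM groups (waters, ligands), and non-standard residues are
excluded everywhere — depth and side-chain means are heavy-atom,
protein-only quantities, and the experimental entries this analysis targets
generally lack hydrogens, so one convention is applied uniformly. Only the
first MODEL and, by default, the first chain are used (monomeric view;
`--chain` selects another). For alternate locations the highest-occupancy
conformer wins. Element symbols come from columns 77–78 with a fallback
guess from the atom name. Depth-annotated output writes D_i in the B-factor
column at 2 decimals; coordinates round-trip to 10⁻³ Å.

## Problem sizes and determinism

Default test and acceptance runs use the fixture sizes above (bundle of 13
helices × 28 residues ≈ 1 800 atoms; slabs ≤ 21 000 atoms; grids of a few
million voxels) — each depth computation takes seconds on one CPU. All
randomness flows through seeded `numpy` generators; every fixture, profile
table, summary and CLI output is byte-reproducible for fixed inputs and
flags.

## Known limitations

* The depth scale matches the published tool family qualitatively; absolute
  per-residue ratios on deposited entries (e.g. the printed 3.77 for a
  tryptophan spot check) can only be reproduced once the reference tool's
  radius/normalization are known — the spot-check test reports the parameter
  set used alongside any deviation.
* Voxel-center containment with h = 0.5 Å leaves ~0.02 quantization jitter
  on individual depths; classifications near a threshold can flip under
  re-gridding. The variant fixtures deliberately keep a margin; real
  borderline sites should be re-run at h = 0.25.
* No SASA, no mutant-structure modelling, no pocket-geometry or druggability
  scoring: the package flags candidates for such downstream analyses.
* Sequence-to-structure numbering is the user's responsibility via the
  offset column; there is no SIFTS/alignment fallback.
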