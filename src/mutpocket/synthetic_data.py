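"""Synthetic structures and variant tables with known ground truth.

Two families of fixtures make every pipeline stage testable without any
download:

* Geometric bodies built from carbon pseudo-atoms (single atom, solid
  lattice ball, slab, hollow shell) whose depth indices have closed-form
  expected values. Bodies are unions of vdW spheres: a "solid ball of
  radius R" places atom centers out to R - r_C so the union fills the ball.

* A helix bundle whose side chains are single CB pseudo-atoms planted to
  point toward the bundle core or toward solvent, giving unambiguous
  orientation ground truth, plus variant tables whose expected cluster
  labels and pocket flags are constructed with safety margins around every
  classification threshold.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import DEFAULT_VDW_RADIUS
from .classify import (
    INNER_AA_SET,
    OUTER_AA_SET,
    ClassifierConfig,
    VolumeTable,
    classify_site,
)
from .dataset import STATUS_PLDDT, STATUS_PROFILED, MutationRecord
from .depth import DepthParams, compute_residue_depths
from .structure_io import PREDICTED, Atom, ProteinStructure, Residue

_CARBON = DEFAULT_VDW_RADIUS  # 1.70 A

FIXTURE_KINDS = ("single_atom", "lattice_ball", "slab", "shell_with_cavity", "helix_bundle")


@dataclass
class FixtureSpec:
    """Parameters of a synthetic fixture (see :func:`make_geometric_fixture`)."""

    kind: str = "single_atom"
    radius: float = 5.0
    spacing: float = 1.0
    half_extent: float = 25.0
    cavity_radius: float = 2.0
    shell_thickness: float = 4.0
    n_helices: int = 10
    length: int = 28
    seed: int = 0
    reference_radius: float = 10.0

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        for name in ("radius", "spacing", "half_extent", "cavity_radius",
                     "shell_thickness", "reference_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _carbon_structure(coords: np.ndarray, structure_id: str) -> ProteinStructure:
    """One-atom-per-residue carbon pseudo-structure (atom name CA, GLY)."""
    coords = np.round(np.atleast_2d(coords), 3)  # lossless through PDB text
    residues = [
        Residue(
            chain="A",
            resseq=i + 1,
            icode="",
            resname="GLY",
            atoms=[
                Atom(
                    serial=i + 1,
                    name="CA",
                    element="C",
                    coords=c,
                    vdw_radius=_CARBON,
                    bfactor=0.0,
                )
            ],
        )
        for i, c in enumerate(coords)
    ]
    return ProteinStructure(id=structure_id, residues=residues)


def _cubic_lattice(bound: float, spacing: float) -> np.ndarray:
    ax = np.arange(-np.floor(bound / spacing), np.floor(bound / spacing) + 1) * spacing
    grid = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    return grid


def make_single_atom(reference_radius: float = 10.0):
    """Isolated carbon atom; only its own volume occupies the sphere."""
    structure = _carbon_structure(np.zeros((1, 3)), "single_atom")
    expected = 2.0 * (1.0 - (_CARBON / reference_radius) ** 3)
    return structure, {"probe_serial": 1, "expected_depth": expected}


def _fibonacci_sphere(radius: float, n: int) -> np.ndarray:
    """Roughly uniform points on a sphere (golden-angle spiral)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    return radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def make_lattice_ball(
    radius: float = 5.0, spacing: float = 1.0, reference_radius: float = 10.0
):
    """Solid ball of body radius ``radius``; probe atom at the center.

    Atom centers fill a cubic lattice out to ``radius`` minus the carbon vdW
    radius, and a dense spherical shell of centers sits exactly at that
    distance so the union-of-spheres surface reaches ``radius`` in every
    direction (a bare lattice would leave the surface up to one spacing
    short). Expected center-atom depth: 2 * (1 - (radius / r)^3), clipped
    at 0 for radius >= r.
    """
    if spacing > 2 * _CARBON / np.sqrt(3):
        import warnings

        warnings.warn("lattice spacing too coarse for a solid union of spheres")
    core_radius = radius - _CARBON
    pts = _cubic_lattice(radius, spacing)
    pts = pts[np.linalg.norm(pts, axis=1) <= core_radius]
    n_shell = int(np.ceil(4.0 * np.pi * core_radius**2 / (spacing / 2.0) ** 2))
    shell = _fibonacci_sphere(core_radius, n_shell)
    pts = np.vstack([pts, shell])
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0], np.linalg.norm(pts, axis=1)))
    pts = pts[order]  # center atom first
    structure = _carbon_structure(pts, "lattice_ball")
    expected = max(0.0, 2.0 * (1.0 - min(1.0, (radius / reference_radius) ** 3)))
    return structure, {"probe_serial": 1, "expected_depth": expected}


def make_slab(
    half_extent: float = 25.0,
    spacing: float = 1.0,
    reference_radius: float = 10.0,
):
    """Flat slab filling z <= 0, with a probe atom resting at the origin.

    Lattice layers start one carbon radius below the surface so the sphere
    union reaches z = 0; the slab is thick enough that the whole lower half
    of the probe's reference sphere is body. Expected probe depth:
    1 - (r_C / r)^3 (half-space, minus the buried half of its own sphere).
    """
    n_layers = int(np.ceil(reference_radius - 2 * _CARBON)) + 1
    ax = np.arange(-np.floor(half_extent / spacing), np.floor(half_extent / spacing) + 1)
    xy = np.stack(np.meshgrid(ax * spacing, ax * spacing, indexing="ij"), axis=-1)
    xy = xy.reshape(-1, 2)
    layers = -_CARBON - np.arange(n_layers) * spacing
    coords = [np.zeros((1, 3))]  # probe first, serial 1
    for z in layers:
        coords.append(np.column_stack([xy, np.full(len(xy), z)]))
    structure = _carbon_structure(np.vstack(coords), "slab")
    expected = 1.0 - (_CARBON / reference_radius) ** 3
    return structure, {"probe_serial": 1, "expected_depth": expected}


def make_shell_with_cavity(
    cavity_radius: float = 2.0,
    shell_thickness: float = 4.0,
    spacing: float = 1.0,
):
    """Hollow spherical shell enclosing an empty cavity around the origin."""
    inner = cavity_radius + _CARBON
    outer = inner + shell_thickness
    pts = _cubic_lattice(outer, spacing)
    dist = np.linalg.norm(pts, axis=1)
    pts = pts[(dist >= inner) & (dist <= outer)]
    structure = _carbon_structure(pts, "shell_with_cavity")
    return structure, {"cavity_center": np.zeros(3), "cavity_radius": cavity_radius}


def make_geometric_fixture(spec: FixtureSpec):
    """Dispatch on ``spec.kind``; returns (structure, ground-truth dict)."""
    if spec.kind == "single_atom":
        return make_single_atom(spec.reference_radius)
    if spec.kind == "lattice_ball":
        return make_lattice_ball(spec.radius, spec.spacing, spec.reference_radius)
    if spec.kind == "slab":
        return make_slab(spec.half_extent, spec.spacing, spec.reference_radius)
    if spec.kind == "shell_with_cavity":
        return make_shell_with_cavity(spec.cavity_radius, spec.shell_thickness, spec.spacing)
    if spec.kind == "helix_bundle":
        return make_helix_bundle(spec.n_helices, spec.length, spec.seed)
    raise ValueError(spec.kind)  # pragma: no cover


# Residue vocabularies used when planting labels on the bundle.
_OUTWARD_NAMES = ("TRP", "TYR", "LYS", "ARG", "GLU", "HIS")
_INWARD_NAMES = ("ALA", "VAL", "LEU", "ILE", "MET", "CYS")

_HELIX_RISE = 1.5  # A per residue
_HELIX_TWIST = np.deg2rad(100.0)  # per residue
_CA_RADIUS = 2.3  # A, CA distance from the helix axis
_CB_LENGTH = 2.6  # A, CB pseudo-atom offset from CA


def make_helix_bundle(
    n_helices: int = 10,
    length: int = 28,
    seed: int = 0,
    *,
    ring_radius: float = 8.0,
    core_helices: int = 3,
    core_ring_radius: float = 3.0,
    plddt_high: float = 95.0,
    plddt_low: float = 60.0,
    low_plddt_fraction: float = 0.05,
):
    """Idealized helix bundle with planted side-chain orientations.

    ``n_helices`` (>= 3) ideal alpha-helices (rise 1.5 A, 100 deg per
    residue, CA 2.3 A off the helix axis) stand parallel on a circle of
    radius ``ring_radius``; ``core_helices`` further helices stand on a small
    inner circle so that the bundle has a genuinely buried core (an atom is
    deeply buried only when most of the reference sphere around it is
    protein, which a single thin ring cannot provide).

    Each residue carries approximate backbone N/C/O positions and, except
    for glycine, a single CB pseudo-atom placed 2.6 A from the CA along the
    horizontal normal through the bundle axis. For outer-ring residues the
    CB points outward (toward solvent) or inward (toward the core) following
    a seeded planted pattern and the residue is labelled accordingly;
    residue names are drawn from bulky/charged vocabulary for outward labels
    and small/hydrophobic vocabulary for inward labels, with occasional
    glycines (labelled inward: with no side chain the orientation convention
    is a tie). Core-helix residues always point their CB at the bundle axis
    and are labelled ``core`` (both directions are buried there, so they
    carry no orientation ground truth). B-factors hold a pLDDT-like profile:
    ``plddt_high`` everywhere except a seeded ``low_plddt_fraction`` of
    residues set to ``plddt_low``.

    Returns (structure, labels): labels is a DataFrame with one row per
    residue (resseq, resname, helix, label, plddt).
    """
    if n_helices < 3:
        raise ValueError("need at least 3 helices so that a core exists")
    rng = np.random.default_rng(seed)
    residues: list[Residue] = []
    label_rows = []
    serial = 0
    resseq = 0
    z0 = -(length - 1) * _HELIX_RISE / 2.0

    def helix_point(axis_xy: np.ndarray, phase: float, t: float, radius: float) -> np.ndarray:
        ang = phase + t * _HELIX_TWIST
        return np.array(
            [
                axis_xy[0] + radius * np.cos(ang),
                axis_xy[1] + radius * np.sin(ang),
                z0 + t * _HELIX_RISE,
            ]
        )

    helix_specs = [
        (ring_radius, 2 * np.pi * k / n_helices, False) for k in range(n_helices)
    ] + [
        (core_ring_radius, 2 * np.pi * (k + 0.5) / max(core_helices, 1), True)
        for k in range(core_helices)
    ]

    for k, (radius_k, psi, is_core) in enumerate(helix_specs):
        axis_xy = radius_k * np.array([np.cos(psi), np.sin(psi)])
        phase = psi + np.pi  # start facing the core
        for j in range(length):
            resseq += 1
            ca = helix_point(axis_xy, phase, j, _CA_RADIUS)
            n_at = helix_point(axis_xy, phase, j - 0.35, 1.7)
            c_at = helix_point(axis_xy, phase, j + 0.45, 1.7)
            o_at = c_at + np.array([0.0, 0.0, 1.23])

            is_gly = rng.random() < 0.10
            outward = bool(rng.random() < 0.5) and not is_gly and not is_core
            if is_gly:
                resname = "GLY"
                label = "core" if is_core else "inward"
            elif is_core:
                resname = str(rng.choice(_INWARD_NAMES))
                label = "core"
            elif outward:
                resname = str(rng.choice(_OUTWARD_NAMES))
                label = "outward"
            else:
                resname = str(rng.choice(_INWARD_NAMES))
                label = "inward"

            plddt = plddt_low if rng.random() < low_plddt_fraction else plddt_high
            atoms = []
            for name, element, xyz in (
                ("N", "N", n_at), ("CA", "C", ca), ("C", "C", c_at), ("O", "O", o_at)
            ):
                serial += 1
                atoms.append(
                    Atom(serial=serial, name=name, element=element,
                         coords=np.round(xyz, 3),  # lossless through PDB text
                         vdw_radius={"C": 1.70, "N": 1.55, "O": 1.52}[element],
                         bfactor=plddt)
                )
            if not is_gly:
                radial = ca[:2] / np.linalg.norm(ca[:2])
                direction = np.array([radial[0], radial[1], 0.0])
                if not outward:
                    direction = -direction
                cb = ca + _CB_LENGTH * direction
                serial += 1
                atoms.append(
                    Atom(serial=serial, name="CB", element="C",
                         coords=np.round(cb, 3), vdw_radius=1.70, bfactor=plddt)
                )
            residues.append(
                Residue(chain="A", resseq=resseq, icode="", resname=resname, atoms=atoms)
            )
            label_rows.append(
                {"resseq": resseq, "resname": resname, "helix": k,
                 "label": label, "plddt": plddt / 100.0}
            )

    structure = ProteinStructure(id="helix_bundle", residues=residues, source=PREDICTED)
    labels = pd.DataFrame(label_rows)
    return structure, labels


def make_variant_fixture(
    structure: ProteinStructure,
    labels: pd.DataFrame,
    seed: int = 0,
    *,
    n_per_cluster: int = 3,
    depth_params: DepthParams | None = None,
    gene: str = "SYNT1",
    uniprot: str = "P99999",
):
    """Variant table over a labelled bundle with known expected profile.

    Sites are chosen so every expected cluster label clears its threshold
    with a safety margin (0.05 on depth indices, 0.1 on V/v), making the
    expected table stable under grid quantization:

    * cluster 1: core/inward-labelled small/hydrophobic residues with
      D_ialpha <= 0.15 and D_iSC < D_ialpha - 0.02, mutated to a larger residue;
    * cluster 2: outward-labelled bulky/charged residues with D_iSC > 0.55
      and D_iSC > D_ialpha + 0.05; mutated to Gly or Ser (pocket candidates,
      V/v > 1.4) and, for contrast, to a near-isosteric residue (V/v < 1.2);
    * cluster 3: Ala/Cys sites with D_ialpha >= 0.3 (too exposed for the
      inner layer, excluded from the outer amino-acid set);
    * one glycine site exercising the D_iSC := D_ialpha convention;
    * one low-confidence site expected to be pLDDT-filtered.

    Returns (records, expected): the mutation records and the expected
    profile table (same layout as :func:`mutpocket.dataset.profile_variants`).
    """
    rng = np.random.default_rng(seed)
    depth_params = depth_params or DepthParams()
    cfg = ClassifierConfig()
    volumes = VolumeTable.default()
    rdepths = compute_residue_depths(structure, depth_params)

    info = labels.set_index("resseq")
    ok_plddt = info["plddt"] > 0.8

    def depth_of(resseq):
        return rdepths[(int(resseq), "")]

    candidates = {"c1": [], "c2": [], "c3": [], "gly": [], "lowp": []}
    for resseq in info.index:
        rd = depth_of(resseq)
        name = info.at[resseq, "resname"]
        label = info.at[resseq, "label"]
        if not ok_plddt.at[resseq]:
            candidates["lowp"].append(resseq)
            continue
        if name == "GLY":
            if rd.d_alpha <= 0.15 or rd.d_alpha >= 0.25:
                candidates["gly"].append(resseq)
        elif (
            label in ("inward", "core")
            and name in INNER_AA_SET
            and rd.d_alpha <= cfg.inner_depth_max - 0.05
            and rd.d_sidechain < rd.d_alpha - 0.02
        ):
            candidates["c1"].append(resseq)
        elif (
            label == "outward"
            and name in OUTER_AA_SET
            and rd.d_sidechain > cfg.outer_depth_min + 0.05
            and rd.d_sidechain > rd.d_alpha + 0.05
        ):
            candidates["c2"].append(resseq)
        elif name in ("ALA", "CYS") and rd.d_alpha >= 0.3:
            candidates["c3"].append(resseq)

    shortages = {
        k: (len(candidates[k]), need)
        for k, need in (("c1", n_per_cluster), ("c2", n_per_cluster),
                        ("c3", n_per_cluster), ("gly", 1), ("lowp", 1))
        if len(candidates[k]) < need
    }
    if shortages:
        raise ValueError(
            f"bundle geometry yields too few candidate sites: {shortages}; "
            "use a larger bundle or more helices"
        )

    bigger = {"ALA": "VAL", "VAL": "PHE", "LEU": "TRP", "ILE": "TRP",
              "MET": "TRP", "CYS": "PHE", "PHE": "TRP"}
    smaller_iso = {"TRP": "TYR", "TYR": "PHE", "LYS": "ARG", "ARG": "LYS",
                   "GLU": "GLN", "HIS": "ASN", "LEU": "ILE", "ILE": "LEU",
                   "MET": "LEU", "PHE": "HIS", "VAL": "THR"}

    picks: list[tuple[int, str]] = []
    for resseq in rng.choice(candidates["c1"], n_per_cluster, replace=False):
        picks.append((int(resseq), bigger[info.at[resseq, "resname"]]))
    c2 = rng.choice(candidates["c2"], n_per_cluster, replace=False)
    for i, resseq in enumerate(c2):
        wild = info.at[resseq, "resname"]
        # mostly large-to-small (pocket candidates), one near-isosteric contrast
        mutant = smaller_iso[wild] if i == n_per_cluster - 1 else "GLY"
        picks.append((int(resseq), mutant))
    for resseq in rng.choice(candidates["c3"], n_per_cluster, replace=False):
        picks.append((int(resseq), "SER"))
    gly_site = int(rng.choice(candidates["gly"]))
    picks.append((gly_site, "ALA"))
    low_site = int(rng.choice(candidates["lowp"]))
    low_wild = info.at[low_site, "resname"]
    picks.append((low_site, "GLY" if low_wild != "GLY" else "ALA"))

    records = []
    expected_rows = []
    for resseq, mutant in picks:
        wild = info.at[resseq, "resname"]
        rec = MutationRecord(
            gene=gene, uniprot=uniprot, wild_aa=wild, position=int(resseq),
            mutant_aa=mutant, structure_id=structure.id,
        )
        records.append(rec)
        row = {
            "gene": gene, "uniprot": uniprot, "mutation": rec.mutation,
            "cluster": pd.NA, "orientation": "", "D_ia": np.nan, "D_isc": np.nan,
            "ratio": np.nan, "v_ratio": np.nan, "pocket_candidate": pd.NA,
            "status": STATUS_PROFILED,
        }
        if not ok_plddt.at[resseq]:
            row["status"] = STATUS_PLDDT
        else:
            rd = depth_of(resseq)
            assignment = classify_site(wild, mutant, rd, cfg, volumes)
            row.update(
                cluster=assignment.cluster,
                orientation=assignment.orientation,
                D_ia=rd.d_alpha,
                D_isc=rd.d_sidechain,
                ratio=np.nan if rd.ratio is None else rd.ratio,
                v_ratio=assignment.v_ratio,
                pocket_candidate=assignment.pocket_candidate,
            )
        expected_rows.append(row)

    from .dataset import PROFILE_COLUMNS

    expected = pd.DataFrame(expected_rows, columns=PROFILE_COLUMNS)
    return records, expected


def variant_records_to_tsv(records: list[MutationRecord]) -> pd.DataFrame:
    """Mutation records as a variant-table DataFrame (TSV layout)."""
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "uniprot": r.uniprot,
                "mutation": r.mutation,
                "structure": r.structure_id,
                "chain": r.chain or "",
                "offset": r.offset,
            }
            for r in records
        ],
        columns=["gene", "uniprot", "mutation", "structure", "chain", "offset"],
    )
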