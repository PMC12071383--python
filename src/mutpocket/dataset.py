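"""Variant-table ingestion and end-to-end per-site profiling.

A variant table is a TSV with columns ``gene``, ``uniprot``, ``mutation``
(Aaa<N>Bbb notation, e.g. ``Val149Gly``), ``structure`` (basename of a PDB
file), and optional ``chain`` and ``offset`` columns. The offset reconciles
sequence numbering with author numbering in the structure: the site is
looked up at author resseq = position + offset. The residue found there must
match the annotated wild-type residue; a mismatch fails that row rather than
silently profiling the wrong residue.

Sites on predicted models are profiled only when the model passes the
confidence gate: mean per-residue pLDDT over the chain > 0.8 and pLDDT at
the mutation site > 0.8 (both strict). Experimental structures pass
automatically.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .chem import normalize_aa
from .classify import ClassifierConfig, VolumeTable, classify_site
from .depth import DepthParams, ResidueDepth, compute_residue_depths
from .structure_io import PREDICTED, ProteinStructure, Residue, extract_plddt, read_structure

# Row statuses of a profile table.
STATUS_PROFILED = "profiled"
STATUS_PLDDT = "plddt_filtered"
STATUS_MISMATCH = "residue_mismatch"
STATUS_NO_STRUCTURE = "missing_structure"
STATUS_NO_RESIDUE = "missing_residue"

PROFILE_COLUMNS = [
    "gene", "uniprot", "mutation", "cluster", "orientation",
    "D_ia", "D_isc", "ratio", "v_ratio", "pocket_candidate", "status",
]

_MUTATION_RE = re.compile(r"^\s*([A-Za-z]{3})([0-9]+)([A-Za-z]{3})\s*$")


class MutationParseError(ValueError):
    pass


class SiteLookupError(LookupError):
    """Site position absent from the structure."""


class ResidueMismatchError(ValueError):
    """Residue at the mapped position does not match the annotated wild type."""

    def __init__(self, expected: str, found: str, resseq: int):
        self.expected, self.found, self.resseq = expected, found, resseq
        super().__init__(
            f"expected {expected} at resseq {resseq}, found {found}"
        )


@dataclass(frozen=True)
class MutationRecord:
    """One missense mutation site tied to a structure."""

    gene: str
    uniprot: str
    wild_aa: str
    position: int
    mutant_aa: str
    structure_id: str
    chain: str | None = None
    offset: int = 0

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.wild_aa == self.mutant_aa:
            raise ValueError("wild-type and mutant residues must differ")

    @property
    def mutation(self) -> str:
        return (
            self.wild_aa.capitalize() + str(self.position) + self.mutant_aa.capitalize()
        )


def parse_mutation_notation(s: str) -> tuple[str, int, str]:
    """Parse ``Aaa<N>Bbb`` notation, e.g. ``Val149Gly`` -> (VAL, 149, GLY)."""
    match = _MUTATION_RE.match(s)
    if not match:
        raise MutationParseError(f"malformed mutation notation {s!r}")
    wild, pos_str, mutant = match.groups()
    try:
        wild = normalize_aa(wild)
    except ValueError:
        raise MutationParseError(f"unknown residue code {wild!r} in {s!r}") from None
    try:
        mutant = normalize_aa(mutant)
    except ValueError:
        raise MutationParseError(f"unknown residue code {mutant!r} in {s!r}") from None
    position = int(pos_str)
    if position < 1:
        raise MutationParseError(f"position must be positive in {s!r}")
    return wild, position, mutant


def read_variant_table(path: str | Path) -> list[MutationRecord]:
    """Read a variant TSV into mutation records (see module docstring)."""
    df = pd.read_csv(path, sep="\t", dtype={"chain": "string"})
    required = {"gene", "uniprot", "mutation", "structure"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        wild, pos, mutant = parse_mutation_notation(row.mutation)
        chain = getattr(row, "chain", None)
        if chain is not None and (pd.isna(chain) or chain == ""):
            chain = None
        offset = getattr(row, "offset", 0)
        offset = 0 if pd.isna(offset) else int(offset)
        records.append(
            MutationRecord(
                gene=str(row.gene),
                uniprot=str(row.uniprot),
                wild_aa=wild,
                position=pos,
                mutant_aa=mutant,
                structure_id=str(row.structure),
                chain=None if chain is None else str(chain),
                offset=offset,
            )
        )
    return records


def map_site_to_structure(rec: MutationRecord, structure: ProteinStructure) -> Residue:
    """Locate the residue at author resseq = position + offset and verify it.

    Raises :class:`SiteLookupError` when the position is absent and
    :class:`ResidueMismatchError` when the residue found there is not the
    annotated wild type (a check, never a guess).
    """
    resseq = rec.position + rec.offset
    residue = structure.find_residue(resseq)
    if residue is None:
        raise SiteLookupError(
            f"residue {resseq} not found in structure {structure.id}"
        )
    if residue.resname != rec.wild_aa:
        raise ResidueMismatchError(rec.wild_aa, residue.resname, resseq)
    return residue


def apply_plddt_filter(
    structure: ProteinStructure,
    residue: Residue,
    *,
    mean_min: float = 0.8,
    site_min: float = 0.8,
) -> bool:
    """Confidence gate for predicted models; experimental structures pass.

    True iff mean per-residue pLDDT over the chain > ``mean_min`` and the
    site residue's pLDDT > ``site_min`` (both strict).
    """
    if structure.source != PREDICTED:
        return True
    plddt = extract_plddt(structure)
    mean_conf = float(np.mean(list(plddt.values())))
    site_conf = plddt[(residue.resseq, residue.icode)]
    return mean_conf > mean_min and site_conf > site_min


class StructureStore:
    """Lazy, cached access to structures in a directory of ``<id>.pdb`` files."""

    def __init__(
        self,
        directory: str | Path,
        *,
        source: str = PREDICTED,
        radii: dict[str, float] | None = None,
    ):
        self.directory = Path(directory)
        self.source = source
        self.radii = radii
        self._cache: dict[tuple[str, str | None], ProteinStructure] = {}

    def get(self, structure_id: str, chain: str | None = None) -> ProteinStructure:
        key = (structure_id, chain)
        if key not in self._cache:
            path = self.directory / f"{structure_id}.pdb"
            if not path.is_file():
                raise FileNotFoundError(path)
            self._cache[key] = read_structure(
                path,
                structure_id=structure_id,
                chain=chain,
                source=self.source,
                radii=self.radii,
            )
        return self._cache[key]


def profile_variants(
    records: list[MutationRecord],
    structures: StructureStore | Mapping[str, ProteinStructure],
    *,
    depth_params: DepthParams | None = None,
    classifier: ClassifierConfig | None = None,
    volumes: VolumeTable | None = None,
    plddt_min: float = 0.8,
) -> pd.DataFrame:
    """Profile every record: depth summary, cluster, V/v, pocket flag, status.

    Returns one row per input record, in input order. Depth profiles are
    computed once per structure and cached, which never changes results
    (the computation is deterministic for fixed parameters).
    """
    depth_params = depth_params or DepthParams()
    classifier = classifier or ClassifierConfig()
    volumes = volumes or VolumeTable.default()
    depth_cache: dict[str, dict[tuple[int, str], ResidueDepth]] = {}

    def get_structure(rec: MutationRecord) -> ProteinStructure:
        if isinstance(structures, StructureStore):
            return structures.get(rec.structure_id, rec.chain)
        return structures[rec.structure_id]

    rows = []
    for rec in records:
        row = {
            "gene": rec.gene,
            "uniprot": rec.uniprot,
            "mutation": rec.mutation,
            "cluster": pd.NA,
            "orientation": "",
            "D_ia": np.nan,
            "D_isc": np.nan,
            "ratio": np.nan,
            "v_ratio": np.nan,
            "pocket_candidate": pd.NA,
            "status": STATUS_PROFILED,
        }
        try:
            structure = get_structure(rec)
        except (FileNotFoundError, KeyError, ValueError):
            row["status"] = STATUS_NO_STRUCTURE
            rows.append(row)
            continue
        try:
            residue = map_site_to_structure(rec, structure)
        except SiteLookupError:
            row["status"] = STATUS_NO_RESIDUE
            rows.append(row)
            continue
        except ResidueMismatchError:
            row["status"] = STATUS_MISMATCH
            rows.append(row)
            continue
        if not apply_plddt_filter(
            structure, residue, mean_min=plddt_min, site_min=plddt_min
        ):
            row["status"] = STATUS_PLDDT
            rows.append(row)
            continue
        cache_key = structure.id + (f":{rec.chain}" if rec.chain else "")
        if cache_key not in depth_cache:
            depth_cache[cache_key] = compute_residue_depths(structure, depth_params)
        rd = depth_cache[cache_key][(residue.resseq, residue.icode)]
        assignment = classify_site(rec.wild_aa, rec.mutant_aa, rd, classifier, volumes)
        row.update(
            cluster=assignment.cluster,
            orientation=assignment.orientation,
            D_ia=rd.d_alpha,
            D_isc=rd.d_sidechain,
            ratio=np.nan if rd.ratio is None else rd.ratio,
            v_ratio=assignment.v_ratio,
            pocket_candidate=assignment.pocket_candidate,
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def write_profile_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a profile table with fixed formatting (byte-stable output)."""
    out = table.copy()
    for col, fmt in (("D_ia", "{:.3f}"), ("D_isc", "{:.3f}"), ("ratio", "{:.3f}"),
                     ("v_ratio", "{:.2f}")):
        out[col] = [
            "" if pd.isna(v) else fmt.format(v) for v in out[col]
        ]
    out["cluster"] = ["" if pd.isna(v) else str(int(v)) for v in out["cluster"]]
    out["pocket_candidate"] = [
        "" if pd.isna(v) else str(bool(v)) for v in out["pocket_candidate"]
    ]
    out.to_csv(path, sep="\t", index=False)


def read_profile_tsv(path: str | Path) -> pd.DataFrame:
    """Read a profile table written by :func:`write_profile_tsv`."""
    df = pd.read_csv(path, sep="\t")
    df["cluster"] = df["cluster"].astype("Int64")

    def to_bool(v):
        if pd.isna(v):
            return pd.NA
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        return {"True": True, "False": False}[str(v)]

    df["pocket_candidate"] = df["pocket_candidate"].map(to_bool)
    return df
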