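"""PDB structure input/output.

Reads protein structures from PDB-format text (experimental entries or
predicted models carrying pLDDT in the B-factor column) into a light
heavy-atom model, and writes depth-annotated PDB output with the per-atom
depth index in the B-factor column.

Parsing is delegated to :mod:`biotite.structure.io.pdb`; this module applies
the conventions used throughout the package: hydrogens and HETATM groups are
excluded, only the highest-occupancy alternate conformer is kept, only the
first MODEL and (by default) the first chain are used, and non-standard
residues are skipped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Iterator

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb_io

from .chem import NON_SIDECHAIN_ATOMS, STANDARD_AA, vdw_radius

EXPERIMENTAL = "experimental"
PREDICTED = "predicted-model"


class PDBParseError(ValueError):
    """Raised when PDB text cannot be parsed into a protein structure."""


@dataclass
class Atom:
    """One heavy atom of a protein structure."""

    serial: int
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    vdw_radius: float
    bfactor: float = 0.0
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coordinates must be 3 finite values")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial}: vdW radius must be positive")


@dataclass
class Residue:
    """One standard amino-acid residue with its heavy atoms."""

    chain: str
    resseq: int
    icode: str
    resname: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def ca(self) -> Atom | None:
        for atom in self.atoms:
            if atom.name == "CA":
                return atom
        return None

    def sidechain_atoms(self) -> list[Atom]:
        """Heavy atoms outside {N, CA, C, O, OXT}; CB is included."""
        return [a for a in self.atoms if a.name not in NON_SIDECHAIN_ATOMS]

    def mean_bfactor(self) -> float:
        return float(np.mean([a.bfactor for a in self.atoms]))


@dataclass
class ProteinStructure:
    """A single-model, single-chain heavy-atom protein structure."""

    id: str
    residues: list[Residue]
    source: str = EXPERIMENTAL  # "experimental" or "predicted-model"

    def __post_init__(self) -> None:
        if self.source not in (EXPERIMENTAL, PREDICTED):
            raise ValueError(f"unknown structure source {self.source!r}")
        if not any(res.ca is not None for res in self.residues):
            raise ValueError("structure must contain at least one residue with a CA atom")

    def atoms(self) -> Iterator[Atom]:
        for res in self.residues:
            yield from res.atoms

    @property
    def n_atoms(self) -> int:
        return sum(len(res.atoms) for res in self.residues)

    def coordinates(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms()], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms()], dtype=float)

    def find_residue(self, resseq: int, icode: str = "") -> Residue | None:
        for res in self.residues:
            if res.resseq == resseq and res.icode == icode:
                return res
        return None


def _prevalidate(text: str) -> None:
    """Check ATOM/HETATM coordinate fields so errors can name the line."""
    n_atom_records = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        n_atom_records += 1
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated ATOM record")
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            fld = line[lo:hi]
            try:
                value = float(fld)
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: malformed {what}-coordinate field {fld!r}"
                ) from None
            if not math.isfinite(value):
                raise PDBParseError(f"line {lineno}: non-finite {what} coordinate")
    if n_atom_records == 0:
        raise PDBParseError("no ATOM records found")


def parse_structure(
    text: str,
    structure_id: str = "structure",
    *,
    chain: str | None = None,
    source: str = EXPERIMENTAL,
    radii: dict[str, float] | None = None,
    skip_nonstandard: bool = True,
) -> ProteinStructure:
    """Parse PDB-format text into a :class:`ProteinStructure`.

    Hydrogens, deuteriums and HETATM records are dropped; for alternate
    locations only the highest-occupancy conformer is kept (ties: first
    encountered); only the first MODEL is read. ``chain`` selects a chain id,
    defaulting to the first protein chain encountered. Non-standard residues
    are skipped when ``skip_nonstandard`` is true, otherwise they raise.
    """
    _prevalidate(text)
    with warnings.catch_warnings():
        # biotite warns when it guesses elements from atom names; that
        # fallback is exactly the behaviour we want for element-less files.
        warnings.simplefilter("ignore", UserWarning)
        try:
            pdb_file = pdb_io.PDBFile.read(StringIO(text))
            arr = pdb_io.get_structure(
                pdb_file,
                model=1,
                altloc="occupancy",
                extra_fields=["b_factor", "occupancy", "atom_id"],
            )
        except PDBParseError:
            raise
        except Exception as exc:  # malformed non-coordinate content
            raise PDBParseError(f"could not parse PDB text: {exc}") from exc

    keep = ~arr.hetero
    keep &= ~np.isin(arr.element, ("H", "D"))
    arr = arr[keep]
    if arr.array_length() == 0:
        raise PDBParseError("no protein heavy atoms after filtering")

    if chain is None:
        chain = str(arr.chain_id[0])
    arr = arr[arr.chain_id == chain]
    if arr.array_length() == 0:
        raise PDBParseError(f"chain {chain!r} not present")

    residues: list[Residue] = []
    current_key: tuple | None = None
    current: Residue | None = None
    for i in range(arr.array_length()):
        resname = str(arr.res_name[i])
        if resname not in STANDARD_AA:
            if skip_nonstandard:
                continue
            raise PDBParseError(f"non-standard residue {resname}")
        icode = str(arr.ins_code[i]) if "ins_code" in arr.get_annotation_categories() else ""
        key = (int(arr.res_id[i]), icode, resname)
        if key != current_key:
            current = Residue(
                chain=chain, resseq=key[0], icode=icode, resname=resname, atoms=[]
            )
            residues.append(current)
            current_key = key
        element = str(arr.element[i])
        assert current is not None
        current.atoms.append(
            Atom(
                serial=int(arr.atom_id[i]),
                name=str(arr.atom_name[i]),
                element=element,
                coords=arr.coord[i],
                vdw_radius=vdw_radius(element, radii),
                bfactor=float(arr.b_factor[i]),
                occupancy=float(arr.occupancy[i]),
            )
        )

    residues = [r for r in residues if r.atoms]
    if not residues:
        raise PDBParseError("no standard amino-acid residues found")
    return ProteinStructure(id=structure_id, residues=residues, source=source)


def read_structure(path, **kwargs) -> ProteinStructure:
    """Read a PDB file from disk; see :func:`parse_structure`."""
    with open(path) as handle:
        text = handle.read()
    kwargs.setdefault("structure_id", str(path))
    return parse_structure(text, **kwargs)


def _to_atom_array(structure: ProteinStructure, bfactors: np.ndarray) -> struc.AtomArray:
    n = structure.n_atoms
    arr = struc.AtomArray(n)
    arr.add_annotation("b_factor", float)
    arr.add_annotation("occupancy", float)
    arr.add_annotation("atom_id", int)
    i = 0
    for res in structure.residues:
        for atom in res.atoms:
            arr.chain_id[i] = res.chain
            arr.res_id[i] = res.resseq
            arr.ins_code[i] = res.icode
            arr.res_name[i] = res.resname
            arr.atom_name[i] = atom.name
            arr.element[i] = atom.element
            arr.hetero[i] = False
            arr.coord[i] = atom.coords
            arr.b_factor[i] = bfactors[i]
            arr.occupancy[i] = atom.occupancy
            arr.atom_id[i] = atom.serial
            i += 1
    return arr


def write_pdb(structure: ProteinStructure, bfactors: Iterable[float] | None = None) -> str:
    """Render a structure as PDB text, optionally overriding B-factors."""
    if bfactors is None:
        bfactors = [a.bfactor for a in structure.atoms()]
    bfac = np.asarray(list(bfactors), dtype=float)
    arr = _to_atom_array(structure, bfac)
    pdb_file = pdb_io.PDBFile()
    pdb_io.set_structure(pdb_file, arr)
    buf = StringIO()
    pdb_file.write(buf)
    return buf.getvalue()


def write_depth_annotated(structure: ProteinStructure, depths: dict[int, float]) -> str:
    """PDB text with the depth index of each atom in the B-factor column.

    ``depths`` maps atom serial to depth index; every atom of the structure
    must be covered, otherwise the offending serials are reported.
    """
    missing = [a.serial for a in structure.atoms() if a.serial not in depths]
    if missing:
        raise ValueError(f"missing depth values for atom serials: {missing}")
    return write_pdb(structure, [depths[a.serial] for a in structure.atoms()])


def extract_plddt(structure: ProteinStructure) -> dict[tuple[int, str], float]:
    """Per-residue pLDDT confidence on a 0-1 scale, keyed by (resseq, icode).

    The per-residue confidence is the mean B-factor over the residue's heavy
    atoms. Files storing pLDDT on the conventional 0-100 scale are detected
    (any B-factor > 1.5) and rescaled by 1/100.
    """
    if structure.source != PREDICTED:
        raise ValueError("pLDDT extraction requires a predicted-model structure")
    all_b = np.array([a.bfactor for a in structure.atoms()])
    if np.any(all_b < 0):
        raise ValueError("negative B-factor encountered; not a pLDDT-annotated model")
    scale = 0.01 if np.any(all_b > 1.5) else 1.0
    return {
        (res.resseq, res.icode): res.mean_bfactor() * scale
        for res in structure.residues
    }
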