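"""Topological classification of mutation sites and pocket-candidate flagging.

Each mutation site is assigned to one of three clusters from the wild-type
residue identity and its depth profile (D_ialpha, D_iSC):

* Cluster 1 (inner layer): D_ialpha <= 0.2 and D_iSC < D_ialpha, restricted
  to small/hydrophobic residues (Ala, Cys, Gly, Ile, Leu, Met, Phe, Val).
* Cluster 2 (outer layer): D_iSC > 0.5 and D_iSC > D_ialpha, restricted to
  bulky/charged residues (Tyr, Phe, Leu, Ile, Val, Trp, Met, Asp, Glu, His,
  Lys, Arg).
* Cluster 3 (intermediate): everything else.

Clusters 1 and 2 are disjoint by construction (cluster 1 forces
D_iSC < 0.2 < 0.5). A substitution replacing a larger residue with a smaller
one (wild-type/mutant volume ratio V/v > 1.3) at a cluster-2 site is flagged
as a pocket candidate: removing outward-pointing bulk at the surface can
open a new, potentially druggable cavity.

Glycine carries the convention D_iSC := D_ialpha, so it can never satisfy
the strict D_iSC < D_ialpha of cluster 1; since Gly is explicitly part of
the inner-layer amino-acid set, Gly sites are treated as cluster-1 eligible
whenever D_ialpha <= 0.2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .chem import STANDARD_AA, ZAMYATNIN_VOLUMES, normalize_aa
from .depth import ResidueDepth

INWARD = "inward"
OUTWARD = "outward"

INNER_AA_SET = frozenset({"ALA", "CYS", "GLY", "ILE", "LEU", "MET", "PHE", "VAL"})
OUTER_AA_SET = frozenset(
    {"TYR", "PHE", "LEU", "ILE", "VAL", "TRP", "MET", "ASP", "GLU", "HIS", "LYS", "ARG"}
)


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds and amino-acid sets of the cluster rules."""

    inner_depth_max: float = 0.2
    outer_depth_min: float = 0.5
    volume_ratio_min: float = 1.3
    inner_aa_set: frozenset[str] = INNER_AA_SET
    outer_aa_set: frozenset[str] = OUTER_AA_SET

    def __post_init__(self) -> None:
        if not self.inner_depth_max < self.outer_depth_min:
            raise ValueError("inner_depth_max must be below outer_depth_min")
        for aa_set in (self.inner_aa_set, self.outer_aa_set):
            unknown = set(aa_set) - STANDARD_AA
            if unknown:
                raise ValueError(f"non-standard amino acids in set: {sorted(unknown)}")


@dataclass(frozen=True)
class VolumeTable:
    """Amino-acid residue volumes (cubic Angstrom) for V/v ratios."""

    volumes: dict[str, float] = field(default_factory=lambda: dict(ZAMYATNIN_VOLUMES))

    def __post_init__(self) -> None:
        missing = STANDARD_AA - set(self.volumes)
        if missing:
            raise ValueError(f"volume table missing residues: {sorted(missing)}")
        if any(v <= 0 for v in self.volumes.values()):
            raise ValueError("all residue volumes must be positive")
        if min(self.volumes, key=self.volumes.get) != "GLY":
            raise ValueError("glycine must be the smallest residue in the table")

    @classmethod
    def default(cls) -> "VolumeTable":
        return cls()

    @classmethod
    def from_json(cls, path: str | Path) -> "VolumeTable":
        """Load {three-letter code: volume} from a JSON file."""
        data = json.loads(Path(path).read_text())
        return cls(volumes={normalize_aa(k): float(v) for k, v in data.items()})

    def volume(self, aa: str) -> float:
        return self.volumes[normalize_aa(aa)]


@dataclass(frozen=True)
class ClusterAssignment:
    """Cluster label, orientation, volume ratio and pocket flag of one site."""

    cluster: int
    orientation: str
    v_ratio: float
    pocket_candidate: bool


def orientation(rd: ResidueDepth) -> str:
    """Side-chain orientation: outward iff D_iSC > D_ialpha (ties inward)."""
    return OUTWARD if rd.d_sidechain > rd.d_alpha else INWARD


def assign_cluster(
    wild_aa: str, rd: ResidueDepth, cfg: ClassifierConfig | None = None
) -> int:
    """Assign a mutation site to cluster 1, 2 or 3 (see module docstring)."""
    cfg = cfg or ClassifierConfig()
    aa = normalize_aa(wild_aa)
    d_a, d_sc = rd.d_alpha, rd.d_sidechain
    if aa == "GLY":
        inward_buried = d_a <= cfg.inner_depth_max
    else:
        inward_buried = d_a <= cfg.inner_depth_max and d_sc < d_a
    if inward_buried and aa in cfg.inner_aa_set:
        return 1
    if d_sc > cfg.outer_depth_min and d_sc > d_a and aa in cfg.outer_aa_set:
        return 2
    return 3


def volume_ratio(
    wild_aa: str, mutant_aa: str, table: VolumeTable | None = None
) -> float:
    """V/v: wild-type residue volume over mutant residue volume."""
    table = table or VolumeTable.default()
    return table.volume(wild_aa) / table.volume(mutant_aa)


def flag_pocket_candidate(
    cluster: int, v_ratio: float, cfg: ClassifierConfig | None = None
) -> bool:
    """True iff the site is cluster 2 and V/v strictly exceeds the threshold."""
    cfg = cfg or ClassifierConfig()
    return cluster == 2 and v_ratio > cfg.volume_ratio_min


def classify_site(
    wild_aa: str,
    mutant_aa: str,
    rd: ResidueDepth,
    cfg: ClassifierConfig | None = None,
    table: VolumeTable | None = None,
) -> ClusterAssignment:
    """Full per-site classification: cluster, orientation, V/v, pocket flag."""
    cfg = cfg or ClassifierConfig()
    cluster = assign_cluster(wild_aa, rd, cfg)
    v_ratio = volume_ratio(wild_aa, mutant_aa, table)
    return ClusterAssignment(
        cluster=cluster,
        orientation=orientation(rd),
        v_ratio=v_ratio,
        pocket_candidate=flag_pocket_candidate(cluster, v_ratio, cfg),
    )
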