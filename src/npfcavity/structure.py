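"""Structure-guided selection of substrate-cavity residues.

Transporter binding cavities are delineated from 3D coordinates in two ways:
residues near a co-crystallized ligand (inward-facing structures with a bound
substrate analogue) and residues near fixed cavity probe atoms (outward-facing
models without a ligand).  In both cases only *surface-exposed* residues count,
where exposure is relative per-residue solvent accessibility computed by the
Shrake–Rupley rolling-probe method and normalized by per-residue-type maximal
accessible areas.  Distances are minima over heavy-atom pairs; hydrogens are
ignored because crystal structures generally lack them.  Residues at exactly
the cutoff distance are included (``<=``).

Per-structure selections are merged into a single ordered set of alignment
columns through each structure's :class:`~npfcavity.alignment.PositionMap`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .alignment import PositionMap
from .errors import MissingLigandError, PairingError, ProbeError

#: Tien et al. (2013) theoretical maximal accessible surface areas (Å²),
#: side-chain inclusive, used to normalize per-residue Shrake–Rupley areas.
MAX_ASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLU": 223.0, "GLN": 225.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
_DEFAULT_MAX_ASA = 200.0  # fallback for non-standard residue names


@dataclass
class StructureModel:
    """Atomic model with an optional ligand flag per atom.

    Residue numbers are assumed unique over the protein portion (single chain,
    or pre-filtered to one chain via :meth:`from_pdb`).
    """

    res_id: np.ndarray        # (n,) int residue numbers
    res_name: np.ndarray      # (n,) 3-letter codes
    atom_name: np.ndarray     # (n,) str
    element: np.ndarray       # (n,) str, e.g. "C", "N", "O"
    coord: np.ndarray         # (n, 3) float Å
    chain_id: np.ndarray      # (n,) str
    ligand_mask: np.ndarray   # (n,) bool

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("non-finite coordinates in structure")

    @property
    def n_atoms(self) -> int:
        return len(self.res_id)

    @property
    def protein_mask(self) -> np.ndarray:
        return ~self.ligand_mask

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.char.upper(self.element.astype(str)) != "H"

    def residue_numbers(self) -> list[int]:
        seen: dict[int, None] = {}
        for r in self.res_id[self.protein_mask]:
            seen.setdefault(int(r))
        return list(seen)

    @classmethod
    def from_pdb(
        cls,
        path,
        ligand_resnames: Sequence[str] = (),
        chain: str | None = None,
    ) -> "StructureModel":
        """Read a PDB file; atoms whose residue name is in ``ligand_resnames``
        are flagged as ligand.  ``chain`` restricts to one chain id."""
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1)
        arr = arr[arr.element != "H"]  # heavy atoms only, by convention
        if chain is not None:
            arr = arr[arr.chain_id == chain]
        lig = np.isin(arr.res_name, list(ligand_resnames))
        return cls(
            res_id=np.asarray(arr.res_id, dtype=int),
            res_name=np.asarray(arr.res_name, dtype=str),
            atom_name=np.asarray(arr.atom_name, dtype=str),
            element=np.asarray(arr.element, dtype=str),
            coord=np.asarray(arr.coord, dtype=float),
            chain_id=np.asarray(arr.chain_id, dtype=str),
            ligand_mask=lig,
        )

    def to_atom_array(self, protein_only: bool = True) -> struc.AtomArray:
        mask = self.protein_mask if protein_only else np.ones(self.n_atoms, bool)
        n = int(mask.sum())
        arr = struc.AtomArray(n)
        arr.coord = self.coord[mask]
        arr.res_id = self.res_id[mask]
        arr.res_name = self.res_name[mask]
        arr.atom_name = self.atom_name[mask]
        arr.element = np.char.upper(self.element[mask].astype(str))
        arr.chain_id = self.chain_id[mask]
        arr.hetero = np.zeros(n, dtype=bool)
        return arr

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        return StructureModel(
            res_id=self.res_id.copy(),
            res_name=self.res_name.copy(),
            atom_name=self.atom_name.copy(),
            element=self.element.copy(),
            coord=self.coord @ rotation.T + translation,
            chain_id=self.chain_id.copy(),
            ligand_mask=self.ligand_mask.copy(),
        )


@dataclass
class CavityReference:
    """Probe atoms marking the cavity centre, as (residue_number, atom_name)."""

    reference_atoms: list[tuple[int, str]]


@dataclass
class SelectionParams:
    ligand_cutoff: float = 8.0        # Å, to ligand heavy atoms
    cavity_cutoff: float = 12.0       # Å, to cavity probe atoms
    exposure_threshold: float = 0.05  # relative accessibility
    distance_mode: str = "min-heavy-atom"

    def __post_init__(self) -> None:
        if self.ligand_cutoff <= 0 or self.cavity_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if not 0.0 <= self.exposure_threshold <= 1.0:
            raise ValueError("exposure_threshold must lie in [0, 1]")


@dataclass
class ResidueSelection:
    structure_id: str
    residues: set[int]
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)
    params: SelectionParams | None = None


@dataclass
class MergedPositions:
    """Union of per-structure selections expressed in alignment columns."""

    columns: list[int]
    provenance: pd.DataFrame
    unmapped: list[tuple[str, int]]


def _ca_coords(s: StructureModel, residues: Iterable[int]) -> np.ndarray:
    out = []
    for r in residues:
        mask = (s.res_id == r) & (s.atom_name == "CA") & s.protein_mask
        if not mask.any():
            raise PairingError(f"residue {r} has no CA atom")
        out.append(s.coord[mask][0])
    return np.asarray(out)


def superpose(
    mobile: StructureModel,
    target: StructureModel,
    pairing: Sequence[tuple[int, int]],
) -> tuple[StructureModel, float]:
    """Rigid least-squares (Kabsch) superposition of ``mobile`` onto ``target``.

    ``pairing`` lists (mobile residue number, target residue number) pairs;
    the optimal rotation+translation minimizing Cα RMSD over the pairing is
    applied to all mobile atoms.  Returns the transformed copy and the Cα RMSD
    in Å.
    """
    if len(pairing) < 3:
        raise PairingError("at least 3 residue pairs are required for superposition")
    mob = _ca_coords(mobile, [p[0] for p in pairing])
    tgt = _ca_coords(target, [p[1] for p in pairing])
    mob_c, tgt_c = mob.mean(axis=0), tgt.mean(axis=0)
    rot, _ = Rotation.align_vectors(tgt - tgt_c, mob - mob_c)
    rmat = rot.as_matrix()
    translation = tgt_c - mob_c @ rmat.T
    moved = mobile.transformed(rmat, translation)
    moved_ca = _ca_coords(moved, [p[0] for p in pairing])
    rmsd = float(np.sqrt(np.mean(np.sum((moved_ca - tgt) ** 2, axis=1))))
    return moved, rmsd


def residue_exposure(s: StructureModel, point_number: int = 960) -> dict[int, float]:
    """Relative per-residue solvent accessibility in [0, 1].

    Shrake–Rupley accessible surface (probe radius 1.4 Å, ``point_number``
    sphere points, element-based radii) summed per residue and divided by the
    Tien-style per-residue-type maximum, clamped to [0, 1].  Ligand atoms are
    excluded.  Residues with no heavy atoms are skipped with a warning.
    """
    arr = s.to_atom_array(protein_only=True)
    atom_sasa = struc.sasa(
        arr, probe_radius=1.4, point_number=point_number, vdw_radii="Single"
    )
    atom_sasa = np.nan_to_num(atom_sasa, nan=0.0)
    exposure: dict[int, float] = {}
    for r in s.residue_numbers():
        mask = arr.res_id == r
        if not mask.any():
            warnings.warn(f"residue {r} has no heavy atoms; skipped")
            continue
        res_name = str(arr.res_name[mask][0])
        max_asa = MAX_ASA.get(res_name, _DEFAULT_MAX_ASA)
        exposure[r] = float(np.clip(atom_sasa[mask].sum() / max_asa, 0.0, 1.0))
    return exposure


def _min_distances(
    s: StructureModel, points: np.ndarray
) -> dict[int, float]:
    """Minimum heavy-atom distance from each protein residue to any point."""
    tree = cKDTree(points)
    mask = s.protein_mask & s.heavy_mask
    dists, _ = tree.query(s.coord[mask])
    res = s.res_id[mask]
    out: dict[int, float] = {}
    for r, d in zip(res, dists):
        r = int(r)
        if r not in out or d < out[r]:
            out[r] = float(d)
    return out


def _select(
    s: StructureModel,
    points: np.ndarray,
    cutoff: float,
    p: SelectionParams,
    rule: str,
    structure_id: str,
) -> ResidueSelection:
    dists = _min_distances(s, points)
    expo = residue_exposure(s)
    rows = []
    selected = set()
    for r, d in dists.items():
        e = expo.get(r, 0.0)
        if d <= cutoff and e >= p.exposure_threshold:
            selected.add(r)
            rows.append({"residue": r, "distance": d, "exposure": e, "rule": rule})
    prov = pd.DataFrame(rows, columns=["residue", "distance", "exposure", "rule"])
    if not prov.empty:
        prov = prov.sort_values("residue").reset_index(drop=True)
    return ResidueSelection(
        structure_id=structure_id, residues=selected, provenance=prov, params=p
    )


def select_near_ligand(
    s: StructureModel,
    p: SelectionParams | None = None,
    structure_id: str = "structure",
) -> ResidueSelection:
    """Surface-exposed residues within ``ligand_cutoff`` of any ligand heavy atom."""
    p = p or SelectionParams()
    lig_mask = s.ligand_mask & s.heavy_mask
    if not lig_mask.any():
        raise MissingLigandError("structure has no ligand atoms")
    return _select(s, s.coord[lig_mask], p.ligand_cutoff, p, "ligand", structure_id)


def select_near_cavity(
    s: StructureModel,
    ref: CavityReference,
    p: SelectionParams | None = None,
    structure_id: str = "structure",
) -> ResidueSelection:
    """Surface-exposed residues within ``cavity_cutoff`` of any probe atom."""
    p = p or SelectionParams()
    points = []
    for resnum, atomname in ref.reference_atoms:
        mask = (s.res_id == resnum) & (s.atom_name == atomname) & s.protein_mask
        n = int(mask.sum())
        if n != 1:
            raise ProbeError(
                f"probe {resnum}:{atomname} resolves to {n} atoms (expected 1)"
            )
        points.append(s.coord[mask][0])
    return _select(s, np.asarray(points), p.cavity_cutoff, p, "cavity", structure_id)


def merge_selections(
    selections: Sequence[ResidueSelection],
    maps: Mapping[str, PositionMap],
) -> MergedPositions:
    """Union per-structure selections after mapping residues to alignment columns.

    Each structure needs a :class:`PositionMap` onto the shared alignment;
    residues without a mapping are reported in ``unmapped`` rather than
    silently dropped.  Result columns are sorted ascending.
    """
    columns: set[int] = set()
    unmapped: list[tuple[str, int]] = []
    rows = []
    for sel in selections:
        pmap = maps[sel.structure_id]
        inv = pmap.residue_to_column
        for r in sorted(sel.residues):
            if r in inv:
                col = inv[r]
                columns.add(col)
                rows.append(
                    {"column": col, "structure_id": sel.structure_id, "residue": r}
                )
            else:
                unmapped.append((sel.structure_id, r))
    prov = pd.DataFrame(rows, columns=["column", "structure_id", "residue"])
    if not prov.empty:
        prov = prov.sort_values(["column", "structure_id"]).reset_index(drop=True)
    return MergedPositions(columns=sorted(columns), provenance=prov, unmapped=unmapped)
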