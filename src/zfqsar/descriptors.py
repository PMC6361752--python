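"""Stage 2: the five molecular descriptors of the absorption model.

The final uptake model uses five descriptors: the hydrogen-bond-donor
count, the surface-weighted positive partial surface area (Jurs WPSA-1),
the number of aliphatic single bonds, the number of aromatic bonds, and
the molecular-weight desirability component of the QED drug-likeness
score. Four are 2D graph counts; WPSA-1 is a 3D charged-partial-surface-
area descriptor and needs an embedded, minimized conformer.

Conventions are fixed and documented here rather than matched to any
proprietary descriptor engine:

* aromaticity: RDKit's default aromaticity model;
* partial charges: Gasteiger-Marsili, hydrogens explicit;
* solvent-accessible surface: Shrake-Rupley with probe radius 1.4 A,
  960 sample points per atom, Bondi-style van der Waals radii;
* WPSA-1 = PPSA-1 * TMSA / 100, with PPSA-1 the summed accessible
  surface of positively charged atoms and TMSA the total surface;
* hydrogen-bond donors are counted per donor atom (an N or O bearing at
  least one hydrogen counts once, however many hydrogens it carries);
* aliphatic single bonds are heavy-atom single bonds that are not
  aromatic; bonds to hydrogen are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors as RDDescriptors, rdMolDescriptors
from rdkit.Chem.QED import ads, adsParameters

from .datasets import read_smiles_file
from .errors import (
    ConformerError,
    EmptyMatrixError,
    JoinError,
    StructureError,
)

#: Canonical column order of the five model descriptors.
DESCRIPTOR_NAMES: tuple[str, ...] = (
    "HBD_Count",
    "Jurs_WPSA_1",
    "Num_AliphaticSingleBonds",
    "Num_AromaticBonds",
    "QED_MW",
)

PROBE_RADIUS = 1.4  # water-probe radius in Angstrom
SPHERE_POINTS = 960  # Shrake-Rupley sample points per atom


@dataclass(frozen=True)
class DescriptorVector:
    """The five model descriptor values for one compound."""

    hbd_count: int
    jurs_wpsa_1: float
    num_aliphatic_single_bonds: int
    num_aromatic_bonds: int
    qed_mw: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.hbd_count,
                self.jurs_wpsa_1,
                self.num_aliphatic_single_bonds,
                self.num_aromatic_bonds,
                self.qed_mw,
            ],
            dtype=float,
        )


@dataclass
class DescriptorMatrix:
    """Dense compounds-by-descriptors grid with ordered labels."""

    compound_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.compound_ids), len(self.descriptor_names)):
            raise JoinError(
                f"grid shape {self.values.shape} does not match "
                f"{len(self.compound_ids)} compounds x "
                f"{len(self.descriptor_names)} descriptors"
            )
        if len(set(self.descriptor_names)) != len(self.descriptor_names):
            raise JoinError("duplicated descriptor names")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.compound_ids, columns=self.descriptor_names
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DescriptorMatrix":
        return cls(
            compound_ids=[str(i) for i in frame.index],
            descriptor_names=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
        )

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.descriptor_names.index(name)]


# ---------------------------------------------------------------------------
# structure I/O


def mol_from_smiles(smiles: str, name: str = "") -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"cannot parse SMILES for {name or smiles!r}")
    if name:
        mol.SetProp("_Name", name)
    return mol


def read_structures(path: str | Path) -> list[tuple[str, Chem.Mol]]:
    """Load named molecules from a name<TAB>SMILES file or an SDF."""
    path = Path(path)
    if path.suffix.lower() == ".sdf":
        out = []
        for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
            if mol is None:
                raise StructureError(f"{path}: unparsable record {i + 1}")
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i + 1}"
            out.append((name, mol))
        return out
    return [
        (name, mol_from_smiles(smi, name))
        for name, smi in read_smiles_file(path).items()
    ]


# ---------------------------------------------------------------------------
# 2D descriptors


def hbd_count(mol: Chem.Mol) -> int:
    """Number of hydrogen-bond-donating N/O atoms (each counted once)."""
    return int(rdMolDescriptors.CalcNumHBD(mol))


def count_aliphatic_single_bonds(mol: Chem.Mol) -> int:
    """Heavy-atom single bonds outside aromatic systems."""
    n = 0
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.GetIsAromatic():
            continue
        if bond.GetBeginAtom().GetAtomicNum() > 1 and bond.GetEndAtom().GetAtomicNum() > 1:
            n += 1
    return n


def count_aromatic_bonds(mol: Chem.Mol) -> int:
    """Bonds flagged aromatic under the perceived aromaticity model."""
    return sum(1 for bond in mol.GetBonds() if bond.GetIsAromatic())


def qed_mw(mol: Chem.Mol) -> float:
    """Molecular-weight desirability of the QED drug-likeness scheme.

    The asymmetric-double-sigmoid desirability of the average molecular
    weight, normalized so its supremum over MW is 1 (Bickerton et al.
    2012 parameters as shipped with RDKit).
    """
    return float(ads(RDDescriptors.MolWt(mol), adsParameters["MW"]))


def qed_mw_from_weight(molecular_weight: float) -> float:
    """The same desirability evaluated directly at a molecular weight."""
    return float(ads(float(molecular_weight), adsParameters["MW"]))


# ---------------------------------------------------------------------------
# 3D: conformer generation and the Jurs WPSA-1 descriptor


def embed_and_minimize(mol: Chem.Mol, seed: int = 0) -> Chem.Mol:
    """Embed one 3D conformer (ETKDGv3) and force-field minimize it.

    MMFF94 is used when parameters cover the molecule, otherwise UFF.
    Deterministic for a fixed seed. The pre- and post-minimization
    energies are stored as properties ``E_initial`` / ``E_minimized``
    (kcal/mol in the chosen force field).
    """
    name = mol.GetProp("_Name") if mol.HasProp("_Name") else Chem.MolToSmiles(mol)
    mol3d = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    if AllChem.EmbedMolecule(mol3d, params) != 0:
        # fall back to random coordinates for congested ring systems
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(mol3d, params) != 0:
            raise ConformerError(f"3D embedding failed for {name}")
    if AllChem.MMFFHasAllMoleculeParams(mol3d):
        props = AllChem.MMFFGetMoleculeProperties(mol3d)
        ff = AllChem.MMFFGetMoleculeForceField(mol3d, props)
    else:
        ff = AllChem.UFFGetMoleculeForceField(mol3d)
    e0 = float(ff.CalcEnergy())
    ff.Minimize(maxIts=5000)
    e1 = float(ff.CalcEnergy())
    mol3d.SetDoubleProp("E_initial", e0)
    mol3d.SetDoubleProp("E_minimized", min(e0, e1))
    return mol3d


def _sphere_points(n: int) -> np.ndarray:
    """Near-uniform points on the unit sphere (Fibonacci lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def shrake_rupley_sasa(
    coords: np.ndarray,
    radii: Sequence[float],
    probe_radius: float = PROBE_RADIUS,
    n_points: int = SPHERE_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible surface areas (A^2), Shrake-Rupley.

    Each atom's accessible sphere (vdW radius + probe) is sampled at
    ``n_points`` lattice points; points falling inside any neighbour's
    accessible sphere are buried.
    """
    coords = np.asarray(coords, dtype=float)
    expanded = np.asarray(radii, dtype=float) + probe_radius
    unit = _sphere_points(n_points)
    n_atoms = coords.shape[0]
    areas = np.empty(n_atoms)
    for i in range(n_atoms):
        pts = coords[i] + expanded[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        d_centers = np.linalg.norm(coords - coords[i], axis=1)
        neighbours = np.nonzero(
            (d_centers < expanded + expanded[i]) & (np.arange(n_atoms) != i)
        )[0]
        for j in neighbours:
            accessible &= (
                np.linalg.norm(pts - coords[j], axis=1) >= expanded[j]
            )
            if not accessible.any():
                break
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * accessible.mean()
    return areas


def atom_partial_charges(mol3d: Chem.Mol) -> np.ndarray:
    """Gasteiger-Marsili partial charges, one per atom (hydrogens included)."""
    AllChem.ComputeGasteigerCharges(mol3d)
    charges = np.array(
        [a.GetDoubleProp("_GasteigerCharge") for a in mol3d.GetAtoms()], dtype=float
    )
    if not np.all(np.isfinite(charges)):
        raise StructureError("Gasteiger charges did not converge to finite values")
    return charges


def jurs_wpsa1(
    mol3d: Chem.Mol,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = SPHERE_POINTS,
) -> float:
    """Surface-weighted positive partial surface area, WPSA-1 (A^4 / 100).

    WPSA-1 = PPSA-1 * TMSA / 100 where PPSA-1 sums the solvent-accessible
    surface of atoms with positive Gasteiger charge and TMSA is the total
    solvent-accessible surface.
    """
    if mol3d.GetNumConformers() == 0:
        raise ConformerError("jurs_wpsa1 needs a molecule with 3D coordinates")
    conf = mol3d.GetConformer()
    coords = conf.GetPositions()
    table = Chem.GetPeriodicTable()
    radii = [table.GetRvdw(a.GetAtomicNum()) for a in mol3d.GetAtoms()]
    areas = shrake_rupley_sasa(coords, radii, probe_radius, n_points)
    charges = atom_partial_charges(mol3d)
    ppsa1 = float(areas[charges > 0].sum())
    tmsa = float(areas.sum())
    return ppsa1 * tmsa / 100.0


# ---------------------------------------------------------------------------
# matrix assembly and pruning


def compute_descriptor_vector(mol: Chem.Mol, seed: int = 0) -> DescriptorVector:
    """All five model descriptors for one molecule (embeds a conformer)."""
    mol3d = embed_and_minimize(mol, seed=seed)
    return DescriptorVector(
        hbd_count=hbd_count(mol),
        jurs_wpsa_1=jurs_wpsa1(mol3d),
        num_aliphatic_single_bonds=count_aliphatic_single_bonds(mol),
        num_aromatic_bonds=count_aromatic_bonds(mol),
        qed_mw=qed_mw(mol),
    )


def build_descriptor_matrix(
    structures: Iterable[tuple[str, Chem.Mol]],
    seed: int = 0,
    extra: DescriptorMatrix | None = None,
) -> DescriptorMatrix:
    """Five model descriptors per compound, plus optional precomputed columns.

    ``extra`` must be indexed by exactly the same compound names; its
    columns are appended after the five computed ones in their given
    order. Each compound's conformer seed is derived from ``seed`` and
    its position, so the matrix is deterministic as a whole.
    """
    names: list[str] = []
    rows: list[np.ndarray] = []
    for i, (name, mol) in enumerate(structures):
        if name in names:
            raise JoinError(f"duplicate compound name {name!r}")
        names.append(name)
        rows.append(compute_descriptor_vector(mol, seed=seed + i).as_array())
    matrix = DescriptorMatrix(
        compound_ids=names,
        descriptor_names=list(DESCRIPTOR_NAMES),
        values=np.vstack(rows) if rows else np.empty((0, len(DESCRIPTOR_NAMES))),
    )
    if extra is not None:
        missing = sorted(set(names) - set(extra.compound_ids))
        surplus = sorted(set(extra.compound_ids) - set(names))
        if missing or surplus:
            raise JoinError(
                f"extra descriptor matrix does not align: missing={missing}, "
                f"surplus={surplus}"
            )
        order = [extra.compound_ids.index(n) for n in names]
        matrix = DescriptorMatrix(
            compound_ids=names,
            descriptor_names=matrix.descriptor_names + extra.descriptor_names,
            values=np.hstack([matrix.values, extra.values[order]]),
        )
    return matrix


def prune_descriptors(
    matrix: DescriptorMatrix,
    variance_floor: float = 1e-8,
    dominance_ceiling: float = 0.9,
) -> DescriptorMatrix:
    """Drop uninformative columns; rows are never touched.

    A column is dropped when it contains non-finite entries, its variance
    is below ``variance_floor``, or its most frequent value accounts for
    more than ``dominance_ceiling`` of the rows (under-represented
    variation). Idempotent by construction.
    """
    n_rows = len(matrix.compound_ids)
    keep: list[int] = []
    for j in range(matrix.values.shape[1]):
        col = matrix.values[:, j]
        if not np.all(np.isfinite(col)):
            continue
        if float(np.var(col)) < variance_floor:
            continue
        _, counts = np.unique(col, return_counts=True)
        if n_rows > 0 and counts.max() / n_rows > dominance_ceiling:
            continue
        keep.append(j)
    if not keep:
        raise EmptyMatrixError("pruning removed every descriptor column")
    return DescriptorMatrix(
        compound_ids=list(matrix.compound_ids),
        descriptor_names=[matrix.descriptor_names[j] for j in keep],
        values=matrix.values[:, keep],
    )
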