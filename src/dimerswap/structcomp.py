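"""C-alpha structure comparison for capsid-domain dimers.

Residue-number-matched superposition in a shared reference numbering (the
Gag coordinate convention) replaces full structural alignment: for these
near-identical folds the sequence/number correspondence is exact, so the
optimal rigid superposition (Kabsch, proper rotation enforced) and its
RMSD quantify the structural difference directly.  Interface analysis is
a distance-cutoff heavy-atom contact list between the two chains of a
dimer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree


@dataclass
class Residue:
    number: int
    name: str
    atoms: dict  # atom name -> (3,) coordinate array, Angstrom

    def coord(self, atom: str = "CA") -> np.ndarray:
        if atom not in self.atoms:
            raise KeyError(f"atom {atom!r} missing from residue {self.number}")
        return self.atoms[atom]


@dataclass
class StructureModel:
    """Chains of residues with coordinates in the Gag numbering convention."""

    chains: dict  # chain name -> list[Residue], ascending residue number
    label: str = ""

    def __post_init__(self) -> None:
        for name, residues in self.chains.items():
            numbers = [r.number for r in residues]
            if len(numbers) != len(set(numbers)):
                raise ValueError(f"duplicate residue numbers in chain {name}")
            for r in residues:
                for xyz in r.atoms.values():
                    if not np.all(np.isfinite(xyz)):
                        raise ValueError("non-finite coordinates")
            residues.sort(key=lambda r: r.number)

    def residue(self, chain: str, number: int) -> Residue:
        for r in self.chains[chain]:
            if r.number == number:
                return r
        raise KeyError(f"residue {number} not in chain {chain}")


@dataclass
class SuperposeResult:
    rotation: np.ndarray  # (3, 3), proper rotation (det = +1)
    translation: np.ndarray  # (3,); maps b as R @ x + t onto a
    rmsd: float  # Angstrom


def from_pdb(path: str, label: str = "") -> StructureModel:
    """Read a (minimal) PDB file into a StructureModel via gemmi."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    chains: dict = {}
    model = st[0]
    for chain in model:
        residues = []
        for res in chain:
            atoms = {
                atom.name: np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                for atom in res
            }
            residues.append(Residue(res.seqid.num, res.name, atoms))
        chains[chain.name] = residues
    return StructureModel(chains=chains, label=label or st.name)


def to_pdb(struct: StructureModel, path: str) -> None:
    """Write ATOM records for all residues (CA and any other atoms present)."""
    st = gemmi.Structure()
    st.name = struct.label or "model"
    model = gemmi.Model("1")
    for chain_name, residues in struct.chains.items():
        chain = gemmi.Chain(chain_name)
        for r in residues:
            res = gemmi.Residue()
            res.name = r.name
            res.seqid = gemmi.SeqId(r.number, " ")
            for atom_name, xyz in r.atoms.items():
                atom = gemmi.Atom()
                atom.name = atom_name
                atom.element = gemmi.Element(atom_name[0])
                atom.pos = gemmi.Position(*xyz)
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def kabsch_superpose(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> SuperposeResult:
    """Least-squares optimal rigid superposition of paired point sets.

    Returns the proper rotation and translation that map ``coords_b`` onto
    ``coords_a`` and the post-superposition RMSD.  Reflections are excluded
    by sign-correcting the smallest singular vector.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("paired (N, 3) coordinate arrays required")
    if a.shape[0] < 3:
        raise ValueError("at least 3 atom pairs are required")
    cen_a = a.mean(axis=0)
    cen_b = b.mean(axis=0)
    aa = a - cen_a
    bb = b - cen_b
    if np.linalg.matrix_rank(aa, tol=1e-8) < 2 or np.linalg.matrix_rank(bb, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) geometry")
    h = bb.T @ aa
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    rotation = vt.T @ correction @ u.T
    translation = cen_a - rotation @ cen_b
    moved = b @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1))))
    return SuperposeResult(rotation=rotation, translation=translation, rmsd=rmsd)


def pair_atoms(
    struct_a: StructureModel,
    struct_b: StructureModel,
    chains: Sequence[str] | None = None,
    residue_range: tuple[int, int] | None = None,
    atom: str = "CA",
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pair atoms of residues present in both structures by (chain, number).

    Both structures must use the same (Gag) numbering.  Pairs are returned
    in ascending (chain, residue-number) order together with their count.
    """
    if chains is None:
        chains = sorted(set(struct_a.chains) & set(struct_b.chains))
    coords_a, coords_b = [], []
    for chain in chains:
        in_a = {
            r.number: r for r in struct_a.chains.get(chain, []) if atom in r.atoms
        }
        in_b = {
            r.number: r for r in struct_b.chains.get(chain, []) if atom in r.atoms
        }
        for number in sorted(set(in_a) & set(in_b)):
            if residue_range is not None and not (
                residue_range[0] <= number <= residue_range[1]
            ):
                continue
            coords_a.append(in_a[number].coord(atom))
            coords_b.append(in_b[number].coord(atom))
    if len(coords_a) < 3:
        raise ValueError("fewer than 3 common residues to pair")
    return np.array(coords_a), np.array(coords_b), len(coords_a)


def residue_distance(
    struct: StructureModel,
    chain_i: str,
    res_i: int,
    chain_j: str,
    res_j: int,
    atom: str = "CA",
) -> float:
    """Euclidean distance in Angstrom between two named atoms."""
    xyz_i = struct.residue(chain_i, res_i).coord(atom)
    xyz_j = struct.residue(chain_j, res_j).coord(atom)
    return float(np.linalg.norm(xyz_i - xyz_j))


def _heavy_atoms(residues: Iterable[Residue]):
    for r in residues:
        for name, xyz in r.atoms.items():
            if not name.startswith("H"):
                yield r.number, xyz


def interface_contacts(
    dimer: StructureModel,
    chain_a: str,
    chain_b: str,
    cutoff: float = 4.5,
) -> list[tuple[int, int]]:
    """Residue pairs with any inter-chain heavy-atom distance below cutoff."""
    atoms_a = list(_heavy_atoms(dimer.chains[chain_a]))
    atoms_b = list(_heavy_atoms(dimer.chains[chain_b]))
    if not atoms_a or not atoms_b:
        raise ValueError("both chains need coordinates")
    xyz_a = np.array([xyz for _, xyz in atoms_a])
    xyz_b = np.array([xyz for _, xyz in atoms_b])
    tree = cKDTree(xyz_b)
    pairs = set()
    for (res_a, xyz), hits in zip(atoms_a, tree.query_ball_point(xyz_a, cutoff)):
        for j in hits:
            if np.linalg.norm(xyz - xyz_b[j]) < cutoff:
                pairs.add((res_a, atoms_b[j][0]))
    return sorted(pairs)
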