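"""Protein-ligand complex ingestion, pocket extraction, hydrogen-bond
detection and interaction-particle placement.

Coordinates are Cartesian angstroms throughout.  Residue numbering is
1-based as read from file; internal array indices are 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "AMINO_ACIDS",
    "ELEMENT_VOCAB",
    "PARTICLE_CLASSES",
    "CalphaPocket",
    "ComplexRecord",
    "FullAtomProtein",
    "HBondCriteria",
    "HydrogenBond",
    "InteractionParticle",
    "LigandMolecule",
    "detect_hydrogen_bonds",
    "extract_pocket",
    "load_complex",
    "place_interaction_particles",
    "to_calpha",
]

#: The 20 standard amino acids; anything else maps to the trailing "UNK" class.
AMINO_ACIDS = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)
RESIDUE_CLASSES = AMINO_ACIDS + ("UNK",)

#: Default heavy-element vocabulary for ligand atoms.
ELEMENT_VOCAB = ("C", "N", "O", "F", "P", "S", "Cl", "Br", "I", "B")

#: Order of the interaction-particle label one-hot.
PARTICLE_CLASSES = ("acceptor", "donor")

# Covalent radii (angstrom) used both for heavy-neighbor perception and for
# distance-based bond inference on generated point clouds.
COVALENT_RADII = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}

_BOND_SLACK = 0.45  # bond iff d < r_i + r_j + slack


class ComplexParseError(ValueError):
    """Raised when an input structure file cannot be interpreted."""


class EmptyPocketError(ValueError):
    """Raised when no protein residue lies within the pocket radius."""


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria.

    ``max_da_distance`` bounds the donor-acceptor heavy-atom distance and
    ``min_donor_angle`` (degrees) bounds the neighbor-donor-acceptor angle,
    applied to every heavy neighbor of the donor when such geometry exists.
    """

    max_da_distance: float = 3.5
    min_donor_angle: float = 120.0


@dataclass
class FullAtomProtein:
    """Full-atom protein: parallel per-atom arrays."""

    elements: list[str]
    atom_names: list[str]
    res_types: list[str]
    res_indices: np.ndarray  # (N,) int, 1-based as in the source file
    chain_ids: list[str]
    positions: np.ndarray  # (N, 3) float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.res_indices = np.asarray(self.res_indices, dtype=int)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("protein coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def residue_keys(self) -> list[tuple[str, int]]:
        """Unique (chain, residue index) pairs in order of first appearance."""
        seen: dict[tuple[str, int], None] = {}
        for cid, ridx in zip(self.chain_ids, self.res_indices):
            seen.setdefault((cid, int(ridx)), None)
        return list(seen)

    def atom_residue_key(self, i: int) -> tuple[str, int]:
        return (self.chain_ids[i], int(self.res_indices[i]))

    def subset(self, atom_idx: np.ndarray) -> "FullAtomProtein":
        atom_idx = np.asarray(atom_idx, dtype=int)
        return FullAtomProtein(
            elements=[self.elements[i] for i in atom_idx],
            atom_names=[self.atom_names[i] for i in atom_idx],
            res_types=[self.res_types[i] for i in atom_idx],
            res_indices=self.res_indices[atom_idx],
            chain_ids=[self.chain_ids[i] for i in atom_idx],
            positions=self.positions[atom_idx],
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "FullAtomProtein":
        out = replace(self)
        out.positions = self.positions @ np.asarray(rotation).T + np.asarray(translation)
        return out

    def heavy_neighbors(self, i: int) -> list[int]:
        """Indices of atoms covalently bonded to atom ``i`` (distance rule)."""
        ri = COVALENT_RADII.get(self.elements[i], 0.77)
        d = np.linalg.norm(self.positions - self.positions[i], axis=1)
        out = []
        for j in range(self.n_atoms):
            if j == i or self.elements[j] == "H":
                continue
            rj = COVALENT_RADII.get(self.elements[j], 0.77)
            if d[j] < ri + rj + _BOND_SLACK:
                out.append(j)
        return out


@dataclass
class CalphaPocket:
    """One node per pocket residue at its Calpha position."""

    positions: np.ndarray  # (R, 3)
    one_hot: np.ndarray  # (R, 21) residue type over AMINO_ACIDS + UNK
    residue_ids: list[tuple[str, int, str]]  # (chain, index, res_type)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.one_hot = np.asarray(self.one_hot, dtype=float)
        if self.one_hot.shape != (len(self.residue_ids), len(RESIDUE_CLASSES)):
            raise ValueError("one-hot shape mismatch")
        if len(self.residue_ids) and not np.allclose(self.one_hot.sum(axis=1), 1.0):
            raise ValueError("one-hot rows must sum to 1")

    @property
    def n_nodes(self) -> int:
        return len(self.residue_ids)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "CalphaPocket":
        return CalphaPocket(
            positions=self.positions @ np.asarray(rotation).T + np.asarray(translation),
            one_hot=self.one_hot.copy(),
            residue_ids=list(self.residue_ids),
        )


@dataclass
class LigandMolecule:
    """Heavy-atom ligand with element one-hots and an explicit bond list.

    ``h_counts`` records, per heavy atom, how many hydrogens it carried on
    ingest (explicit plus implicit) so donor perception survives H stripping.
    """

    elements: list[str]
    positions: np.ndarray  # (M, 3)
    bonds: list[tuple[int, int, float]]  # (i, j, order)
    h_counts: list[int] = field(default_factory=list)
    vocab: tuple[str, ...] = ELEMENT_VOCAB

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(self.elements) == 0:
            raise ValueError("ligand must have at least one heavy atom")
        if not self.h_counts:
            self.h_counts = [0] * len(self.elements)
        for el in self.elements:
            if el == "H":
                raise ValueError("ligand must contain heavy atoms only")
        for i, j, _ in self.bonds:
            if not (0 <= i < len(self.elements) and 0 <= j < len(self.elements)):
                raise ValueError(f"bond index ({i},{j}) out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def one_hot(self) -> np.ndarray:
        out = np.zeros((self.n_atoms, len(self.vocab)))
        for i, el in enumerate(self.elements):
            if el not in self.vocab:
                raise ValueError(f"element {el!r} not in ligand vocabulary {self.vocab}")
            out[i, self.vocab.index(el)] = 1.0
        return out

    def heavy_neighbors(self, i: int) -> list[int]:
        out = []
        for a, b, _ in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(set(out))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LigandMolecule":
        return LigandMolecule(
            elements=list(self.elements),
            positions=self.positions @ np.asarray(rotation).T + np.asarray(translation),
            bonds=list(self.bonds),
            h_counts=list(self.h_counts),
            vocab=self.vocab,
        )

    def to_rdkit(self):
        """RDKit mol with a 3D conformer (not sanitized here)."""
        from rdkit import Chem
        from rdkit.Geometry import Point3D

        bt = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE, 3.0: Chem.BondType.TRIPLE}
        mol = Chem.RWMol()
        for el in self.elements:
            mol.AddAtom(Chem.Atom(el))
        for i, j, order in self.bonds:
            mol.AddBond(int(i), int(j), bt.get(float(order), Chem.BondType.SINGLE))
        conf = Chem.Conformer(self.n_atoms)
        for k, pos in enumerate(self.positions):
            conf.SetAtomPosition(k, Point3D(*map(float, pos)))
        out = mol.GetMol()
        out.AddConformer(conf)
        return out


@dataclass(frozen=True)
class HydrogenBond:
    """A detected protein-ligand hydrogen bond.

    ``ligand_role`` is the role of the ligand atom; the protein atom plays
    the complementary role.
    """

    protein_atom_index: int
    ligand_atom_index: int
    ligand_role: str  # "donor" | "acceptor"
    donor_acceptor_distance: float

    def __post_init__(self) -> None:
        if self.ligand_role not in PARTICLE_CLASSES:
            raise ValueError(f"ligand_role must be one of {PARTICLE_CLASSES}")
        if not self.donor_acceptor_distance > 0:
            raise ValueError("donor-acceptor distance must be positive")


@dataclass(frozen=True)
class InteractionParticle:
    """Pseudoparticle at one of the two trisection points of a hydrogen bond.

    Particle ``j`` sits at ``x_P + (j/3) * (x_L - x_P)`` so j=1 is adjacent
    to the protein atom.  The label matches the ligand atom's role.
    """

    position: tuple[float, float, float]
    label: str  # "acceptor" | "donor" (ligand-side role)
    bond_id: int
    j: int

    def __post_init__(self) -> None:
        if self.j not in (1, 2):
            raise ValueError("j must be 1 or 2")
        if self.label not in PARTICLE_CLASSES:
            raise ValueError(f"label must be one of {PARTICLE_CLASSES}")

    @property
    def one_hot(self) -> np.ndarray:
        out = np.zeros(len(PARTICLE_CLASSES))
        out[PARTICLE_CLASSES.index(self.label)] = 1.0
        return out


@dataclass
class ComplexRecord:
    """One protein-ligand pair with derived pocket, bonds and particles."""

    id: str
    protein: FullAtomProtein
    ligand: LigandMolecule
    pocket: CalphaPocket | None = None
    hbonds: list[HydrogenBond] = field(default_factory=list)
    particles: list[InteractionParticle] = field(default_factory=list)

    def particle_positions(self) -> np.ndarray:
        if not self.particles:
            return np.zeros((0, 3))
        return np.array([p.position for p in self.particles], dtype=float)

    def particle_one_hot(self) -> np.ndarray:
        if not self.particles:
            return np.zeros((0, len(PARTICLE_CLASSES)))
        return np.stack([p.one_hot for p in self.particles])

    def sidecar_dict(self) -> dict:
        return {
            "id": self.id,
            "hbonds": [
                {
                    "bond_id": k,
                    "protein_atom": hb.protein_atom_index,
                    "ligand_atom": hb.ligand_atom_index,
                    "ligand_role": hb.ligand_role,
                    "distance": hb.donor_acceptor_distance,
                }
                for k, hb in enumerate(self.hbonds)
            ],
            "particles": [
                {
                    "bond_id": p.bond_id,
                    "j": p.j,
                    "label": p.label,
                    "position": list(p.position),
                }
                for p in self.particles
            ],
        }

    def write_sidecar(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.sidecar_dict(), fh, indent=1)

    def tensor_bundle(self) -> dict[str, np.ndarray]:
        """Training tensors: positions, one-hots and node-kind flags."""
        if self.pocket is None:
            raise ValueError("pocket not extracted; run the preparation pipeline first")
        return {
            "ligand_x": self.ligand.positions,
            "ligand_h": self.ligand.one_hot,
            "pocket_x": self.pocket.positions,
            "pocket_h": self.pocket.one_hot,
            "particle_x": self.particle_positions(),
            "particle_h": self.particle_one_hot(),
        }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_protein_pdb(path) -> FullAtomProtein:
    """Read a PDB file into a :class:`FullAtomProtein` (hydrogens dropped)."""
    import biotite.structure.io.pdb as pdbio

    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        atoms = pdb_file.get_structure(model=1)
    except Exception as exc:  # pragma: no cover - message formatting only
        raise ComplexParseError(f"cannot parse PDB file {path}: {exc}") from exc
    mask = ~atoms.hetero & (atoms.element != "H") & (atoms.element != "D")
    atoms = atoms[mask]
    if atoms.array_length() == 0:
        raise ComplexParseError(f"no protein atoms found in {path}")
    elements = [el.capitalize() for el in atoms.element]
    return FullAtomProtein(
        elements=elements,
        atom_names=list(atoms.atom_name),
        res_types=list(atoms.res_name),
        res_indices=np.asarray(atoms.res_id, dtype=int),
        chain_ids=list(atoms.chain_id),
        positions=np.asarray(atoms.coord, dtype=float),
    )


def load_ligand_sdf(path, vocab: tuple[str, ...] = ELEMENT_VOCAB) -> LigandMolecule:
    """Read the first record of an SDF/MOL file, stripping hydrogens.

    Per-heavy-atom hydrogen counts are recorded before stripping so that
    donor perception does not depend on explicit protons.
    """
    from rdkit import Chem

    mol = Chem.MolFromMolFile(str(path), removeHs=False, sanitize=False)
    if mol is None:
        raise ComplexParseError(f"cannot parse ligand file {path}")
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        # tolerate valence quirks; coordinates and elements are still usable
        mol.UpdatePropertyCache(strict=False)
    return ligand_from_rdkit(mol, vocab=vocab)


def ligand_from_rdkit(mol, vocab: tuple[str, ...] = ELEMENT_VOCAB) -> LigandMolecule:
    """Convert an RDKit mol (with a conformer) to a heavy-atom ligand."""
    from rdkit import Chem

    if mol.GetNumConformers() == 0:
        raise ComplexParseError("ligand molecule has no 3D coordinates")
    conf = mol.GetConformer()
    heavy_idx = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    if not heavy_idx:
        raise ValueError("ligand has no heavy atoms")
    remap = {old: new for new, old in enumerate(heavy_idx)}
    elements, positions, h_counts = [], [], []
    for old in heavy_idx:
        atom = mol.GetAtomWithIdx(old)
        elements.append(atom.GetSymbol())
        p = conf.GetAtomPosition(old)
        positions.append([p.x, p.y, p.z])
        n_h = atom.GetTotalNumHs(includeNeighbors=True)
        h_counts.append(int(n_h))
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in remap and j in remap:
            order = b.GetBondTypeAsDouble()
            bonds.append((remap[i], remap[j], float(order)))
    return LigandMolecule(
        elements=elements,
        positions=np.asarray(positions, dtype=float),
        bonds=bonds,
        h_counts=h_counts,
        vocab=vocab,
    )


def load_complex(protein_path, ligand_path, complex_id: str | None = None) -> ComplexRecord:
    """Load a protein-ligand pair; hbonds/particles are left for detection."""
    protein = load_protein_pdb(protein_path)
    ligand = load_ligand_sdf(ligand_path)
    if complex_id is None:
        import os

        complex_id = os.path.splitext(os.path.basename(str(protein_path)))[0]
    return ComplexRecord(id=complex_id, protein=protein, ligand=ligand)


# ---------------------------------------------------------------------------
# Pocket extraction and Calpha reduction
# ---------------------------------------------------------------------------

def extract_pocket(
    protein: FullAtomProtein, ligand: LigandMolecule, radius: float = 10.0
) -> FullAtomProtein:
    """Retain whole residues with any atom within ``radius`` of the ligand."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    tree = cKDTree(ligand.positions)
    dmin, _ = tree.query(protein.positions, k=1)
    keep_res = {
        protein.atom_residue_key(i) for i in range(protein.n_atoms) if dmin[i] <= radius
    }
    if not keep_res:
        raise EmptyPocketError(f"no residue within {radius} A of the ligand")
    idx = np.array(
        [i for i in range(protein.n_atoms) if protein.atom_residue_key(i) in keep_res],
        dtype=int,
    )
    return protein.subset(idx)


def to_calpha(pocket: FullAtomProtein) -> CalphaPocket:
    """Reduce a pocket to one node per residue at the Calpha position."""
    ca_pos: dict[tuple[str, int], np.ndarray] = {}
    res_type: dict[tuple[str, int], str] = {}
    order = pocket.residue_keys()
    for i in range(pocket.n_atoms):
        key = pocket.atom_residue_key(i)
        res_type[key] = pocket.res_types[i]
        if pocket.atom_names[i] == "CA":
            ca_pos[key] = pocket.positions[i]
    missing = [key for key in order if key not in ca_pos]
    if missing:
        raise ValueError(f"residues lacking a Calpha atom: {missing}")
    positions = np.stack([ca_pos[key] for key in order])
    one_hot = np.zeros((len(order), len(RESIDUE_CLASSES)))
    ids = []
    for r, key in enumerate(order):
        rt = res_type[key]
        cls = AMINO_ACIDS.index(rt) if rt in AMINO_ACIDS else len(AMINO_ACIDS)
        one_hot[r, cls] = 1.0
        ids.append((key[0], key[1], rt))
    return CalphaPocket(positions=positions, one_hot=one_hot, residue_ids=ids)


# ---------------------------------------------------------------------------
# Donor / acceptor perception
# ---------------------------------------------------------------------------

def _protein_roles(protein: FullAtomProtein, i: int) -> tuple[bool, bool]:
    """(is_donor, is_acceptor) for protein atom ``i``.

    Perception is element + heavy-valence based (no explicit hydrogens):
    O with one heavy neighbor is a donor unless its bond length marks it as
    a carbonyl; N donates up to three heavy neighbors and accepts up to two.
    """
    el = protein.elements[i]
    if el not in ("N", "O"):
        return False, False
    nbrs = protein.heavy_neighbors(i)
    if el == "O":
        if len(nbrs) == 0:
            return True, True  # water-like
        if len(nbrs) == 1:
            d = np.linalg.norm(protein.positions[i] - protein.positions[nbrs[0]])
            if d < 1.30:  # carbonyl / carboxylate C=O
                return False, True
            return True, True  # hydroxyl
        return False, True  # bridging O: acceptor only
    # nitrogen
    if len(nbrs) <= 2:
        return True, True
    if len(nbrs) == 3:
        return True, False
    return False, False


def _ligand_roles(ligand: LigandMolecule, i: int) -> tuple[bool, bool]:
    """(is_donor, is_acceptor) for ligand heavy atom ``i``."""
    el = ligand.elements[i]
    if el not in ("N", "O"):
        return False, False
    donor = ligand.h_counts[i] >= 1
    if el == "O":
        return donor, True
    heavy = len(ligand.heavy_neighbors(i))
    acceptor = heavy + ligand.h_counts[i] <= 3  # lone pair available
    return donor, acceptor


def _angles_ok(
    donor_pos: np.ndarray,
    acceptor_pos: np.ndarray,
    neighbor_positions: list[np.ndarray],
    min_angle_deg: float,
) -> bool:
    """Every heavy neighbor of the donor must subtend >= min_angle at it."""
    for npos in neighbor_positions:
        v1 = npos - donor_pos
        v2 = acceptor_pos - donor_pos
        n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if n1 < 1e-9 or n2 < 1e-9:
            continue
        cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
        if np.degrees(np.arccos(cosang)) < min_angle_deg:
            return False
    return True


def detect_hydrogen_bonds(
    protein: FullAtomProtein,
    ligand: LigandMolecule,
    criteria: HBondCriteria | None = None,
) -> list[HydrogenBond]:
    """Geometric protein-ligand hydrogen-bond detection.

    A bond is reported when one side is a perceived donor, the other a
    perceived acceptor, the heavy-atom distance is within the cutoff, and
    (when the donor has heavy neighbors) every neighbor-donor-acceptor
    angle meets the minimum.  The result is independent of scan order.
    """
    criteria = criteria or HBondCriteria()
    p_cand = [
        (i, *_protein_roles(protein, i))
        for i in range(protein.n_atoms)
        if protein.elements[i] in ("N", "O")
    ]
    l_cand = [
        (k, *_ligand_roles(ligand, k))
        for k in range(ligand.n_atoms)
        if ligand.elements[k] in ("N", "O")
    ]
    if not p_cand or not l_cand:
        return []
    out: list[HydrogenBond] = []
    for pi, p_don, p_acc in p_cand:
        xp = protein.positions[pi]
        for li, l_don, l_acc in l_cand:
            xl = ligand.positions[li]
            d = float(np.linalg.norm(xp - xl))
            if d > criteria.max_da_distance or d < 1e-9:
                continue
            # ligand donor -> protein acceptor
            if l_don and p_acc:
                nbr = [ligand.positions[j] for j in ligand.heavy_neighbors(li)]
                if _angles_ok(xl, xp, nbr, criteria.min_donor_angle):
                    out.append(HydrogenBond(pi, li, "donor", d))
            # protein donor -> ligand acceptor
            if p_don and l_acc:
                nbr = [protein.positions[j] for j in protein.heavy_neighbors(pi)]
                if _angles_ok(xp, xl, nbr, criteria.min_donor_angle):
                    out.append(HydrogenBond(pi, li, "acceptor", d))
    out.sort(key=lambda hb: (hb.protein_atom_index, hb.ligand_atom_index, hb.ligand_role))
    return out


# ---------------------------------------------------------------------------
# Interaction particles
# ---------------------------------------------------------------------------

def place_interaction_particles(
    hbond: HydrogenBond,
    protein: FullAtomProtein,
    ligand: LigandMolecule,
    bond_id: int = 0,
) -> list[InteractionParticle]:
    """Two pseudoparticles at the trisection points of the donor-acceptor axis.

    Particle j sits at ``x_P + (j/3) (x_L - x_P)``; both carry the ligand
    atom's donor/acceptor role as their label.
    """
    xp = protein.positions[hbond.protein_atom_index]
    xl = ligand.positions[hbond.ligand_atom_index]
    delta = xl - xp
    if np.linalg.norm(delta) < 1e-9:
        raise ValueError("degenerate hydrogen bond: coincident endpoints")
    particles = []
    for j in (1, 2):
        pos = xp + (j / 3.0) * delta
        particles.append(
            InteractionParticle(
                position=(float(pos[0]), float(pos[1]), float(pos[2])),
                label=hbond.ligand_role,
                bond_id=bond_id,
                j=j,
            )
        )
    return particles


def annotate_complex(
    record: ComplexRecord,
    radius: float = 10.0,
    criteria: HBondCriteria | None = None,
) -> ComplexRecord:
    """Full preparation: pocket, Calpha graph, hbonds and particles in place."""
    pocket_atoms = extract_pocket(record.protein, record.ligand, radius=radius)
    record.pocket = to_calpha(pocket_atoms)
    record.hbonds = detect_hydrogen_bonds(record.protein, record.ligand, criteria)
    record.particles = []
    for k, hb in enumerate(record.hbonds):
        record.particles.extend(
            place_interaction_particles(hb, record.protein, record.ligand, bond_id=k)
        )
    return record
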