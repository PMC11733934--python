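"""Deterministic synthetic protein-ligand complexes with planted hydrogen bonds.

A toy complex is a short carbon-chain ligand decorated with pendant
oxygens, surrounded by minimal backbone-only residues on a shell.  For
each planted bond, a residue is oriented so its backbone N (protein
donor) or carbonyl O (protein acceptor) sits at a drawn donor-acceptor
distance from a ligand oxygen, collinear with the pendant bond so the
default geometric criteria are satisfied by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hbdiff.complexes import (
    AMINO_ACIDS,
    ComplexRecord,
    FullAtomProtein,
    HBondCriteria,
    LigandMolecule,
    annotate_complex,
    detect_hydrogen_bonds,
)

__all__ = ["FixtureSpec", "make_fixture_suite", "make_toy_complex", "write_fixture_files"]

_CHAIN_STEP = np.array([1.3, 0.6, 0.0])
_PENDANT_LEN = 1.43
_CLEARANCE = 4.5  # min distance of non-planted residue atoms to ligand atoms


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic complex; the seed fixes everything."""

    n_pocket_residues: int = 8
    n_ligand_atoms: int = 10
    n_planted_hbonds: int = 2
    da_range: tuple[float, float] = (2.7, 3.3)
    seed: int = 0
    complex_id: str = "toy"

    def validate(self) -> None:
        if self.n_ligand_atoms < 1:
            raise ValueError("ligand needs at least one atom")
        if self.n_planted_hbonds > self.n_pocket_residues:
            raise ValueError("more planted bonds than pocket residues")
        if self.n_planted_hbonds > self.n_ligand_atoms // 2:
            # every planted bond needs a pendant atom plus a chain anchor
            raise ValueError("more planted bonds than eligible ligand atoms")
        if not (0 < self.da_range[0] <= self.da_range[1] <= 3.5):
            raise ValueError("da_range must sit inside (0, 3.5]")


def _rotation_from_rng(rng) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _perp(u: np.ndarray, rng) -> np.ndarray:
    """A unit vector perpendicular to u."""
    while True:
        v = rng.standard_normal(3)
        v -= u * np.dot(u, v)
        n = np.linalg.norm(v)
        if n > 1e-6:
            return v / n


def _build_ligand(spec: FixtureSpec, rng):
    """Chain of carbons plus one pendant oxygen per planted bond.

    Returns the ligand, the pendant atom indices and per-pendant ligand
    roles ("donor"/"acceptor", alternating).
    """
    n_pend = spec.n_planted_hbonds
    n_chain = spec.n_ligand_atoms - n_pend
    pos = [np.zeros(3)]
    for i in range(1, n_chain):
        step = _CHAIN_STEP * np.array([1.0, (-1.0) ** i, 1.0])
        pos.append(pos[-1] + step + np.array([0, 0, rng.uniform(-0.1, 0.1)]))
    bonds = [(i, i + 1, 1.0) for i in range(n_chain - 1)]
    elements = ["C"] * n_chain
    pendants, roles = [], []
    if n_pend:
        anchors = np.linspace(0, n_chain - 1, n_pend).round().astype(int)
        # keep anchors distinct even for short chains
        anchors = sorted(set(int(a) for a in anchors))
        while len(anchors) < n_pend:
            extra = [i for i in range(n_chain) if i not in anchors]
            anchors.append(extra[0])
            anchors = sorted(anchors)
        for k in range(n_pend):
            a = anchors[k]
            side = 1.0 if k % 2 == 0 else -1.0
            direction = np.array([0.0, 0.0, side])
            direction += 0.15 * rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            idx = len(elements)
            elements.append("O")
            pos.append(pos[a] + _PENDANT_LEN * direction)
            role = "donor" if k % 2 == 0 else "acceptor"
            order = 1.0 if role == "donor" else 2.0  # C-OH vs C=O
            bonds.append((a, idx, order))
            pendants.append(idx)
            roles.append(role)
    # hydrogen counts from leftover carbon valence; O: 1 for hydroxyl, 0 for C=O
    deg = np.zeros(len(elements))
    for i, j, order in bonds:
        deg[i] += order
        deg[j] += order
    h_counts = []
    for i, el in enumerate(elements):
        cap = {"C": 4, "O": 2}[el]
        h_counts.append(int(max(0, cap - deg[i])) if el == "C" else (1 if deg[i] < 2 else 0))
    ligand = LigandMolecule(
        elements=elements,
        positions=np.array(pos),
        bonds=bonds,
        h_counts=h_counts,
    )
    return ligand, pendants, roles


def _planted_residue(xl, anchor, role, d, rng):
    """Backbone atoms for a residue realizing one planted bond.

    ``xl`` is the ligand pendant position, ``anchor`` its chain neighbor.
    The protein partner atom lies at distance ``d`` from ``xl`` along the
    continuation of the pendant bond, and the rest of the residue trails
    away from the ligand.
    """
    u = xl - anchor
    u /= np.linalg.norm(u)
    w = _perp(u, rng)
    xp = xl + d * u
    tilt = 0.94 * u + 0.34 * w  # ~20 degrees off-axis, still receding
    tilt /= np.linalg.norm(tilt)
    if role == "acceptor":  # protein N donates to the ligand carbonyl O
        n = xp
        ca = n + 1.46 * u
        c = ca + 1.52 * tilt
        o = c + 1.23 * u
        partner_name = "N"
    else:  # ligand hydroxyl donates to the protein carbonyl O
        o_pos = xp
        c = o_pos + 1.23 * u
        ca = c + 1.52 * tilt
        n = ca + 1.46 * u
        o = o_pos
        partner_name = "O"
    atoms = [("N", "N", n), ("CA", "C", ca), ("C", "C", c), ("O", "O", o)]
    return atoms, partner_name


def _template_residue() -> list[tuple[str, str, np.ndarray]]:
    return [
        ("N", "N", np.array([1.46, 0.0, 0.0])),
        ("CA", "C", np.array([0.0, 0.0, 0.0])),
        ("C", "C", np.array([-0.76, 1.32, 0.0])),
        ("O", "O", np.array([-0.65, 2.31, 0.71])),
    ]


def make_toy_complex(
    spec: FixtureSpec,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
) -> ComplexRecord:
    """Build and fully annotate one synthetic complex.

    Detection under default criteria is guaranteed (asserted) to recover
    every planted bond.  An optional rigid transform is applied to the
    finished geometry before annotation, so outputs are covariant.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ligand, pendants, roles = _build_ligand(spec, rng)
    centroid = ligand.positions.mean(axis=0)

    elements, names, res_types, res_indices, chains, coords = [], [], [], [], [], []
    planted_partner_atoms: list[tuple[int, int, str]] = []  # (atom idx, ligand idx, role)

    def push_residue(atoms, res_idx, res_type):
        start = len(elements)
        for name, el, xyz in atoms:
            names.append(name)
            elements.append(el)
            res_types.append(res_type)
            res_indices.append(res_idx)
            chains.append("A")
            coords.append(np.asarray(xyz, float))
        return start

    res_idx = 0
    type_cycle = list(AMINO_ACIDS)
    # planted residues first
    for k, (pend, role) in enumerate(zip(pendants, roles)):
        res_idx += 1
        anchor_atom = next(i for i, j, _ in ligand.bonds if j == pend)
        d = rng.uniform(*spec.da_range)
        atoms, partner_name = _planted_residue(
            ligand.positions[pend], ligand.positions[anchor_atom], role, d, rng
        )
        start = push_residue(atoms, res_idx, type_cycle[(res_idx - 1) % len(type_cycle)])
        partner_offset = next(i for i, a in enumerate(atoms) if a[0] == partner_name)
        planted_partner_atoms.append((start + partner_offset, pend, role))

    # filler residues on a shell, clear of the ligand and of each other
    template = _template_residue()
    n_filler = spec.n_pocket_residues - spec.n_planted_hbonds
    placed = 0
    attempts = 0
    while placed < n_filler:
        attempts += 1
        if attempts > 4000:
            raise RuntimeError("could not place filler residues without clashes")
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        radius = rng.uniform(6.5, 9.0)
        anchor = centroid + radius * direction
        rot = _rotation_from_rng(rng)
        atoms = [(nm, el, anchor + rot @ xyz) for nm, el, xyz in template]
        pts = np.array([a[2] for a in atoms])
        dl = np.linalg.norm(pts[:, None, :] - ligand.positions[None, :, :], axis=2)
        if dl.min() < _CLEARANCE:
            continue
        if coords:
            dp = np.linalg.norm(pts[:, None, :] - np.array(coords)[None, :, :], axis=2)
            if dp.min() < 2.4:
                continue
        res_idx += 1
        push_residue(atoms, res_idx, type_cycle[(res_idx - 1) % len(type_cycle)])
        placed += 1

    protein = FullAtomProtein(
        elements=elements,
        atom_names=names,
        res_types=res_types,
        res_indices=np.array(res_indices),
        chain_ids=chains,
        positions=np.array(coords).reshape(-1, 3),
    )

    if rotation is not None or translation is not None:
        R = np.eye(3) if rotation is None else np.asarray(rotation, float)
        b = np.zeros(3) if translation is None else np.asarray(translation, float)
        protein = protein.transformed(R, b)
        ligand = ligand.transformed(R, b)

    record = ComplexRecord(id=spec.complex_id, protein=protein, ligand=ligand)
    annotate_complex(record)

    detected = {
        (hb.protein_atom_index, hb.ligand_atom_index, hb.ligand_role)
        for hb in record.hbonds
    }
    missing = [p for p in planted_partner_atoms if p not in detected]
    if missing:
        raise AssertionError(f"planted bonds not recovered by detection: {missing}")
    record.planted = list(planted_partner_atoms)  # type: ignore[attr-defined]
    return record


def make_fixture_suite(seed: int = 0, n_train: int = 8, n_test: int = 2):
    """A small train/test suite with hydrogen-bond counts spanning 0..6."""
    rng = np.random.default_rng(seed)
    specs = []
    total = n_train + n_test
    for k in range(total):
        n_hb = k % 7  # 0..6
        n_lig = max(8, 2 * n_hb + 2) + int(rng.integers(0, 5))
        n_res = max(7, n_hb + 4) + int(rng.integers(0, 4))
        specs.append(
            FixtureSpec(
                n_pocket_residues=n_res,
                n_ligand_atoms=n_lig,
                n_planted_hbonds=n_hb,
                seed=int(rng.integers(0, 2**31)),
                complex_id=f"fix{k:02d}",
            )
        )
    records = [make_toy_complex(s) for s in specs]
    return records[:n_train], records[n_train:]


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_fixture_files(record: ComplexRecord, outdir) -> dict:
    """Write <id>.pdb, <id>.sdf and <id>_hbonds.json; returns the paths."""
    import os

    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio
    from rdkit import Chem

    os.makedirs(outdir, exist_ok=True)
    p = record.protein
    arr = struc.AtomArray(p.n_atoms)
    arr.coord = p.positions.astype(np.float32)
    arr.chain_id = np.array(p.chain_ids)
    arr.res_id = p.res_indices
    arr.res_name = np.array(p.res_types)
    arr.atom_name = np.array(p.atom_names)
    arr.element = np.array([e.upper() for e in p.elements])
    arr.hetero = np.zeros(p.n_atoms, dtype=bool)
    pdb_path = os.path.join(str(outdir), f"{record.id}.pdb")
    pf = pdbio.PDBFile()
    pf.set_structure(arr)
    pf.write(pdb_path)

    m = record.ligand.to_rdkit()
    Chem.SanitizeMol(m)
    sdf_path = os.path.join(str(outdir), f"{record.id}.sdf")
    w = Chem.SDWriter(sdf_path)
    m.SetProp("_Name", record.id)
    w.write(m)
    w.close()

    sidecar_path = os.path.join(str(outdir), f"{record.id}_hbonds.json")
    record.write_sidecar(sidecar_path)
    return {"pdb": pdb_path, "sdf": sdf_path, "sidecar": sidecar_path}
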