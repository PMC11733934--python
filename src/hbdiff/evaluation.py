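"""Desk-computable metrics for generated molecule sets.

Hydrogen-bond reconstruction is scored against the full-atom protein in
the generated pose as-is (no minimization); chemistry metrics use RDKit
descriptors; substructure bond/dihedral angles come straight from the
coordinates.
"""

from __future__ import annotations

import csv
import json
import os
import sys
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from hbdiff.complexes import (
    FullAtomProtein,
    HBondCriteria,
    LigandMolecule,
    _ligand_roles,
    detect_hydrogen_bonds,
    ligand_from_rdkit,
)

__all__ = [
    "MetricsReport",
    "PocketExcluded",
    "bond_angle",
    "dihedral_angle",
    "diversity",
    "donor_acceptor_fractions",
    "drug_properties",
    "evaluate_pocket",
    "hbond_reconstruction",
    "substructure_angles",
]

BOND_ANGLE_PATTERNS = ("CCC", "CCO", "CNC", "OPO", "NCC", "CC=O", "COC")
DIHEDRAL_PATTERNS = ("CCCC", "cccc", "CCCO", "OCCO", "Cccc", "CC=CC")


class PocketExcluded(ValueError):
    """Signal that a pocket has no reference hydrogen bonds to score."""


def _as_ligand(molecule) -> LigandMolecule:
    if isinstance(molecule, LigandMolecule):
        return molecule
    if hasattr(molecule, "as_ligand"):  # GeneratedLigand
        return molecule.as_ligand()
    return ligand_from_rdkit(molecule)


def _as_rdkit(molecule):
    from rdkit import Chem

    if isinstance(molecule, Chem.Mol):
        return molecule
    mol = molecule.to_rdkit()
    Chem.SanitizeMol(mol)
    return mol


def hbond_reconstruction(
    generated,
    reference_hbonds,
    protein: FullAtomProtein,
    criteria: HBondCriteria | None = None,
) -> float:
    """Fraction of reference bonds whose protein atom is re-engaged.

    Every detected bond from the generated pose counts if its protein
    atom appears among the reference bonds' protein atoms, so one atom
    gaining several bonds can push the score above 1.
    """
    reference_hbonds = list(reference_hbonds)
    if not reference_hbonds:
        raise PocketExcluded("pocket has no reference hydrogen bonds")
    ref_atoms = {hb.protein_atom_index for hb in reference_hbonds}
    ligand = _as_ligand(generated)
    detected = detect_hydrogen_bonds(protein, ligand, criteria)
    matched = sum(1 for hb in detected if hb.protein_atom_index in ref_atoms)
    return matched / len(reference_hbonds)


def diversity(molecules) -> float:
    """Mean pairwise (1 - Tanimoto) over topological path fingerprints."""
    from rdkit import Chem, DataStructs

    mols = [_as_rdkit(m) for m in molecules]
    if len(mols) < 2:
        raise ValueError("diversity needs at least two molecules")
    fps = [Chem.RDKFingerprint(m) for m in mols]
    dis = [1.0 - DataStructs.TanimotoSimilarity(a, b) for a, b in combinations(fps, 2)]
    return float(np.mean(dis))


_sascorer = None


def _get_sascorer():
    global _sascorer
    if _sascorer is None:
        from rdkit.Chem import RDConfig

        sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
        import sascorer  # type: ignore

        _sascorer = sascorer
    return _sascorer


def drug_properties(molecule) -> tuple[float, float, float, int]:
    """(QED, SA normalized to 0-1 higher-is-easier, logP, Lipinski count)."""
    from rdkit.Chem import Crippen, Descriptors, Lipinski, QED

    mol = _as_rdkit(molecule)
    qed = float(QED.qed(mol))
    sa_raw = float(_get_sascorer().calculateScore(mol))  # 1 easy .. 10 hard
    sa = (10.0 - sa_raw) / 9.0
    logp = float(Crippen.MolLogP(mol))
    rules = [
        Descriptors.MolWt(mol) <= 500,
        logp <= 5,
        Lipinski.NumHDonors(mol) <= 5,
        Lipinski.NumHAcceptors(mol) <= 10,
        Lipinski.NumRotatableBonds(mol) <= 10,
    ]
    return qed, sa, logp, int(sum(rules))


def donor_acceptor_fractions(molecules) -> tuple[float, float]:
    """Pooled donor and acceptor heavy-atom fractions over a molecule set.

    Uses the same perception rules as hydrogen-bond detection, so the
    fractions are consistent with the reconstruction metric.
    """
    n_heavy = n_don = n_acc = 0
    for m in molecules:
        lig = _as_ligand(m)
        n_heavy += lig.n_atoms
        for i in range(lig.n_atoms):
            don, acc = _ligand_roles(lig, i)
            n_don += bool(don)
            n_acc += bool(acc)
    if n_heavy == 0:
        return 0.0, 0.0
    return n_don / n_heavy, n_acc / n_heavy


# ---------------------------------------------------------------------------
# Substructure geometry
# ---------------------------------------------------------------------------

def bond_angle(p0, p1, p2) -> float:
    """Angle at p1 in degrees."""
    v1 = np.asarray(p0, float) - np.asarray(p1, float)
    v2 = np.asarray(p2, float) - np.asarray(p1, float)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Torsion angle in degrees in (-180, 180], atan2 formulation."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def _pattern_to_smarts(pattern: str) -> str:
    """Element pattern like 'CC=O' or 'cccc' -> a SMARTS string.

    Uppercase means aliphatic, lowercase aromatic; '=' forces a double
    bond, aromatic-aromatic neighbors get ':' and everything else '-'.
    """
    atoms: list[str] = []
    bonds: list[str] = []
    forced = False
    for ch in pattern:
        if ch == "=":
            forced = True
            continue
        atoms.append(ch)
        if len(atoms) > 1:
            if forced:
                bonds.append("=")
            elif atoms[-2].islower() and atoms[-1].islower():
                bonds.append(":")
            else:
                bonds.append("-")
        forced = False
    out = atoms[0]
    for b, a in zip(bonds, atoms[1:]):
        out += b + a
    return out


def substructure_angles(molecules, patterns) -> dict[str, np.ndarray]:
    """Per-pattern arrays of bond angles (3 atoms) or dihedrals (4 atoms)."""
    from rdkit import Chem

    out: dict[str, list[float]] = {p: [] for p in patterns}
    for m in molecules:
        mol = _as_rdkit(m)
        conf = mol.GetConformer()
        pos = conf.GetPositions()
        for pattern in patterns:
            patt = Chem.MolFromSmarts(_pattern_to_smarts(pattern))
            if patt is None:
                raise ValueError(f"bad pattern {pattern!r}")
            n_atoms = patt.GetNumAtoms()
            for match in mol.GetSubstructMatches(patt, uniquify=True):
                pts = [pos[i] for i in match]
                if n_atoms == 3:
                    out[pattern].append(bond_angle(*pts))
                elif n_atoms == 4:
                    out[pattern].append(dihedral_angle(*pts))
    return {p: np.asarray(v) for p, v in out.items()}


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Per-pocket metric rows plus mean/sd aggregates across pockets."""

    per_pocket: list[dict] = field(default_factory=list)
    n_invalid: int = 0

    _NUMERIC = (
        "hbond_reconstruction",
        "diversity",
        "qed",
        "sa",
        "logp",
        "lipinski_count",
        "donor_fraction",
        "acceptor_fraction",
    )

    def aggregate(self) -> dict:
        agg = {}
        for key in self._NUMERIC:
            vals = [r[key] for r in self.per_pocket if r.get(key) is not None]
            if vals:
                agg[key] = {"mean": float(np.mean(vals)), "sd": float(np.std(vals))}
        agg["n_pockets"] = len(self.per_pocket)
        agg["n_invalid_molecules"] = self.n_invalid
        return agg

    def write_csv(self, path) -> None:
        cols = ["pocket_id", *self._NUMERIC, "n_molecules"]
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=cols, extrasaction="ignore")
            writer.writeheader()
            for row in self.per_pocket:
                writer.writerow(row)

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.aggregate(), fh, indent=1)


def evaluate_pocket(
    generated,
    record,
    criteria: HBondCriteria | None = None,
) -> dict:
    """All metrics for one pocket's generated molecules.

    Molecules failing RDKit sanitization are excluded from the chemistry
    panel but counted; reconstruction uses every decodable pose.
    """
    from rdkit import Chem

    row: dict = {"pocket_id": record.id, "n_molecules": len(generated)}
    recon = []
    for g in generated:
        try:
            recon.append(hbond_reconstruction(g, record.hbonds, record.protein, criteria))
        except PocketExcluded:
            recon = None
            break
    row["hbond_reconstruction"] = float(np.mean(recon)) if recon else None

    sane, n_invalid = [], 0
    for g in generated:
        try:
            sane.append(_as_rdkit(g))
        except Exception:
            n_invalid += 1
    row["n_invalid"] = n_invalid
    if len(sane) >= 2:
        row["diversity"] = diversity(sane)
    else:
        row["diversity"] = None
    if sane:
        props = np.array([drug_properties(m) for m in sane])
        row["qed"], row["sa"], row["logp"] = map(float, props[:, :3].mean(axis=0))
        row["lipinski_count"] = float(props[:, 3].mean())
        don, acc = donor_acceptor_fractions(sane)
        row["donor_fraction"], row["acceptor_fraction"] = don, acc
    else:
        for key in ("qed", "sa", "logp", "lipinski_count", "donor_fraction", "acceptor_fraction"):
            row[key] = None
    return row
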