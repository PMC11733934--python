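"""Training loop, ligand-size sampling and reverse-diffusion generation.

The reference frame for diffusion is conditions-centered: before noising
or generating, the whole system is translated so the fixed nodes (pocket
Calpha atoms plus interaction particles) have zero mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from hbdiff.autodiff import Tensor
from hbdiff.complexes import (
    COVALENT_RADII,
    ELEMENT_VOCAB,
    ComplexRecord,
    LigandMolecule,
)
from hbdiff.diffusion import (
    NoiseSchedule,
    as_rng,
    forward_diffuse,
    posterior_params,
    predict_clean,
    sample_com_free_noise,
)
from hbdiff.egnn import ConditionedGraph, EGNNDenoiser

__all__ = [
    "Adam",
    "GeneratedLigand",
    "SizeSampler",
    "decode_molecule",
    "fit_size_distribution",
    "generate",
    "sample_ligand_size",
    "train",
    "training_step",
]

_MAX_VALENCE = {"C": 4, "N": 3, "O": 2, "F": 1, "P": 5, "S": 6, "Cl": 1, "Br": 1, "I": 1, "B": 3}
_BOND_UPPER_SLACK = 0.45  # bond window: [0.6*(ri+rj), ri+rj+slack]


class Adam:
    """Adam over the model's flat parameter list."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _condition_offset(pocket_x: np.ndarray, particle_x: np.ndarray) -> np.ndarray:
    """Mean position of the fixed conditioning nodes."""
    stacked = [np.asarray(pocket_x, float).reshape(-1, 3)]
    particle_x = np.asarray(particle_x, float).reshape(-1, 3)
    if len(particle_x):
        stacked.append(particle_x)
    allx = np.concatenate(stacked)
    if len(allx) == 0:
        raise ValueError("cannot center on an empty condition set")
    return allx.mean(axis=0)


def _record_tensors(record: ComplexRecord):
    b = record.tensor_bundle()
    return (
        b["ligand_x"],
        b["ligand_h"],
        b["pocket_x"],
        b["pocket_h"],
        b["particle_x"],
        b["particle_h"],
    )


def training_step(
    batch: list[ComplexRecord],
    model: EGNNDenoiser,
    schedule: NoiseSchedule,
    rng,
    optimizer: Adam | None = None,
) -> float:
    """One optimization step of the simplified noise-matching objective.

    Per sample, a step t ~ Uniform{1..T} is drawn, the ligand alone is
    noised in the conditions-centered frame, and the loss is half the
    mean squared error between true and predicted noise over coordinate
    and feature components.  Parameters are updated when an optimizer is
    supplied.
    """
    if not batch:
        raise ValueError("batch must be non-empty")
    rng = as_rng(rng)
    total: Tensor | None = None
    n_comp = 0
    for record in batch:
        lx, lh, px, ph, qx, qh = _record_tensors(record)
        offset = _condition_offset(px, qx)
        t = int(rng.integers(1, schedule.T + 1))
        z, (eps_x, eps_h) = forward_diffuse(
            lx - offset, model.config.feature_scale * lh, t, schedule, rng,
            com_free=model.config.zero_com_output,
        )
        graph = ConditionedGraph.assemble(
            z.z_x, z.z_h, px - offset, ph,
            (qx - offset) if len(qx) else qx, qh,
            tfrac=t / schedule.T, cutoff=model.config.cutoff,
        )
        eps_x_hat, eps_h_hat = model.forward(graph)
        dx = eps_x_hat - Tensor(eps_x)
        dh = eps_h_hat - Tensor(eps_h)
        sse = dx.square().sum() + dh.square().sum()
        total = sse if total is None else total + sse
        n_comp += eps_x.size + eps_h.size
    loss = total * (0.5 / n_comp)
    value = float(loss.data)
    if not np.isfinite(value):
        raise RuntimeError(
            f"non-finite training loss {value} (batch of {len(batch)}, T={schedule.T})"
        )
    if optimizer is not None:
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
    return value


def train(
    records: list[ComplexRecord],
    model: EGNNDenoiser,
    schedule: NoiseSchedule,
    n_steps: int,
    rng,
    lr: float = 1e-3,
    batch_size: int = 64,
    lr_decay: bool = False,
    log_every: int = 0,
) -> list[float]:
    """Minibatch training over complexes; returns the loss trajectory.

    With ``lr_decay`` the learning rate follows a cosine ramp down to 10%
    of its initial value over the run.
    """
    rng = as_rng(rng)
    opt = Adam(model.parameters(), lr=lr)
    losses = []
    for step in range(n_steps):
        if lr_decay:
            opt.lr = lr * (0.1 + 0.9 * 0.5 * (1 + np.cos(np.pi * step / n_steps)))
        idx = rng.integers(0, len(records), size=min(batch_size, len(records)))
        batch = [records[i] for i in idx]
        losses.append(training_step(batch, model, schedule, rng, opt))
        if log_every and (step + 1) % log_every == 0:
            print(f"step {step + 1}/{n_steps}  loss {losses[-1]:.5f}")
    return losses


# ---------------------------------------------------------------------------
# Ligand-size distribution
# ---------------------------------------------------------------------------

@dataclass
class SizeSampler:
    """Conditional P(n_ligand | n_pocket) from a smoothed joint histogram."""

    table: np.ndarray  # (n_pocket_bins, n_ligand_bins), rows normalized
    pocket_offset: int
    ligand_offset: int
    sigma: float

    def __post_init__(self) -> None:
        sums = self.table.sum(axis=1)
        if np.any(np.abs(sums[sums > 0] - 1.0) > 1e-9):
            raise ValueError("conditional rows must sum to 1")

    def row(self, n_pocket: int) -> np.ndarray:
        r = n_pocket - self.pocket_offset
        valid = np.flatnonzero(self.table.sum(axis=1) > 0)
        if r not in valid:
            nearest = valid[np.argmin(np.abs(valid - r))]
            warnings.warn(
                f"n_pocket={n_pocket} outside fitted range; using nearest row "
                f"{nearest + self.pocket_offset}",
                stacklevel=2,
            )
            r = nearest
        return self.table[r]


def fit_size_distribution(pairs, sigma: float = 1.0) -> SizeSampler:
    """Joint (n_pocket, n_ligand) histogram, Gaussian-blurred, row-normalized."""
    pairs = [(int(p), int(l)) for p, l in pairs]
    if not pairs:
        raise ValueError("need at least one (n_pocket, n_ligand) pair")
    spill = int(np.ceil(3 * sigma))
    ps = [p for p, _ in pairs]
    ls = [l for _, l in pairs]
    p0, p1 = min(ps) - spill, max(ps) + spill
    l0, l1 = max(0, min(ls) - spill), max(ls) + spill
    hist = np.zeros((p1 - p0 + 1, l1 - l0 + 1))
    for p, l in pairs:
        hist[p - p0, l - l0] += 1.0
    if sigma > 0:
        hist = gaussian_filter(hist, sigma=sigma, mode="constant")
    sums = hist.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        table = np.where(sums > 0, hist / np.maximum(sums, 1e-300), 0.0)
    return SizeSampler(table=table, pocket_offset=p0, ligand_offset=l0, sigma=sigma)


def sample_ligand_size(sampler: SizeSampler, n_pocket: int, rng) -> int:
    """Draw a ligand atom count conditioned on the pocket node count."""
    rng = as_rng(rng)
    row = sampler.row(n_pocket)
    k = int(rng.choice(len(row), p=row))
    return max(1, k + sampler.ligand_offset)


# ---------------------------------------------------------------------------
# Decoding and generation
# ---------------------------------------------------------------------------

@dataclass
class GeneratedLigand:
    """Decoded output of the reverse diffusion for one sample."""

    coordinates: np.ndarray
    elements: list[str]
    bonds: list[tuple[int, int, float]]
    pocket_id: str = ""
    seed: int | None = None
    n_steps: int = 0
    valence_flags: list[int] = field(default_factory=list)
    valid: bool = True

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def as_ligand(self, vocab=ELEMENT_VOCAB) -> LigandMolecule:
        """View as a LigandMolecule for hydrogen-bond detection.

        Donor hydrogens are assigned implicitly from leftover valence.
        """
        h_counts = []
        deg = np.zeros(self.n_atoms, dtype=int)
        for i, j, order in self.bonds:
            deg[i] += int(round(order))
            deg[j] += int(round(order))
        for k, el in enumerate(self.elements):
            h_counts.append(max(0, _MAX_VALENCE.get(el, 4) - int(deg[k])))
        return LigandMolecule(
            elements=list(self.elements),
            positions=self.coordinates.copy(),
            bonds=list(self.bonds),
            h_counts=h_counts,
            vocab=vocab,
        )

    def to_rdkit(self):
        """Build an RDKit mol (may fail sanitization; caller decides)."""
        from rdkit import Chem
        from rdkit.Geometry import Point3D

        mol = Chem.RWMol()
        for el in self.elements:
            mol.AddAtom(Chem.Atom(el))
        for i, j, order in self.bonds:
            bt = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE, 3.0: Chem.BondType.TRIPLE}
            mol.AddBond(int(i), int(j), bt.get(float(order), Chem.BondType.SINGLE))
        conf = Chem.Conformer(self.n_atoms)
        for k, pos in enumerate(self.coordinates):
            conf.SetAtomPosition(k, Point3D(*map(float, pos)))
        m = mol.GetMol()
        m.AddConformer(conf)
        return m


def decode_molecule(
    coords: np.ndarray,
    type_one_hots: np.ndarray,
    vocab=ELEMENT_VOCAB,
    **provenance,
) -> GeneratedLigand:
    """Point cloud -> molecule: argmax elements and distance-based bonds.

    An element is the argmax of its (possibly noisy) one-hot, ties broken
    toward the lowest vocabulary index.  A single bond is assigned when the
    interatomic distance falls inside the covalent window for the element
    pair; valence overflows are flagged, never silently fixed.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    type_one_hots = np.asarray(type_one_hots, dtype=float)
    if len(coords) < 1:
        raise ValueError("need at least one atom")
    elements = [vocab[int(k)] for k in np.argmax(type_one_hots, axis=1)]
    bonds: list[tuple[int, int, float]] = []
    n = len(elements)
    for i in range(n):
        ri = COVALENT_RADII.get(elements[i], 0.77)
        for j in range(i + 1, n):
            rj = COVALENT_RADII.get(elements[j], 0.77)
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if 0.6 * (ri + rj) <= d <= ri + rj + _BOND_UPPER_SLACK:
                bonds.append((i, j, 1.0))
    deg = np.zeros(n, dtype=int)
    for i, j, _ in bonds:
        deg[i] += 1
        deg[j] += 1
    flags = [k for k in range(n) if deg[k] > _MAX_VALENCE.get(elements[k], 4)]
    return GeneratedLigand(
        coordinates=coords,
        elements=elements,
        bonds=bonds,
        valence_flags=flags,
        valid=np.all(np.isfinite(coords)) and not flags,
        **provenance,
    )


def generate(
    pocket,
    particles,
    model: EGNNDenoiser,
    schedule: NoiseSchedule,
    n_samples: int,
    rng,
    size_sampler: SizeSampler | None = None,
    n_atoms: int | None = None,
    pocket_id: str = "",
    seed: int | None = None,
    noise_scale: float = 1.0,
    noise_rotation: np.ndarray | None = None,
) -> list[GeneratedLigand]:
    """Reverse-diffusion ligand generation inside a fixed pocket.

    Conditions (pocket nodes and interaction particles, possibly empty)
    are frozen; each sample starts from a standard-normal latent and is
    denoised T -> 0, with the final step taken deterministically.
    ``noise_rotation`` rotates every coordinate noise draw, which together
    with rotated conditions realizes the seed-matched equivariance
    property.
    """
    rng = as_rng(rng)
    px = np.asarray(pocket.positions, dtype=float)
    ph = np.asarray(pocket.one_hot, dtype=float)
    if particles:
        qx = np.array([p.position for p in particles], dtype=float)
        qh = np.stack([p.one_hot for p in particles])
    else:
        qx = np.zeros((0, 3))
        qh = np.zeros((0, 2))
    offset = _condition_offset(px, qx)
    px_c = px - offset
    qx_c = qx - offset if len(qx) else qx
    vocab = model.config.ligand_vocab
    out: list[GeneratedLigand] = []
    for _ in range(n_samples):
        if n_atoms is not None:
            n = n_atoms
        elif size_sampler is not None:
            n = sample_ligand_size(size_sampler, pocket.n_nodes, rng)
        else:
            raise ValueError("provide either n_atoms or a size_sampler")
        if model.config.zero_com_output:
            z_x = sample_com_free_noise((n, 3), rng)
        else:
            z_x = rng.standard_normal((n, 3))
        if noise_rotation is not None:
            z_x = z_x @ np.asarray(noise_rotation).T
        z_h = rng.standard_normal((n, len(vocab)))
        for t in range(schedule.T, 0, -1):
            graph = ConditionedGraph.assemble(
                z_x, z_h, px_c, ph, qx_c, qh,
                tfrac=t / schedule.T, cutoff=model.config.cutoff,
            )
            eps_x_hat, eps_h_hat = model.predict(graph)
            s = t - 1
            x_hat = predict_clean(z_x, eps_x_hat, t, schedule)
            h_hat = predict_clean(z_h, eps_h_hat, t, schedule)
            mu_x, sig = posterior_params(z_x, x_hat, s, t, schedule)
            mu_h, _ = posterior_params(z_h, h_hat, s, t, schedule)
            if s > 0 and sig > 0:
                if model.config.zero_com_output:
                    nx = sample_com_free_noise((n, 3), rng)
                else:
                    nx = rng.standard_normal((n, 3))
                if noise_rotation is not None:
                    nx = nx @ np.asarray(noise_rotation).T
                z_x = mu_x + noise_scale * sig * nx
                z_h = mu_h + noise_scale * sig * rng.standard_normal((n, len(vocab)))
            else:  # final step adds no noise so decoding is stable
                z_x, z_h = mu_x, mu_h
        mol = decode_molecule(
            z_x + offset, z_h, vocab=vocab,
            pocket_id=pocket_id, seed=seed, n_steps=schedule.T,
        )
        out.append(mol)
    return out


def write_sdf(ligands: list[GeneratedLigand], path) -> int:
    """Write generated molecules to an SDF file; returns records written."""
    from rdkit import Chem

    writer = Chem.SDWriter(str(path))
    n = 0
    for k, lig in enumerate(ligands):
        mol = lig.to_rdkit()
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            mol.UpdatePropertyCache(strict=False)
        mol.SetProp("_Name", f"{lig.pocket_id or 'sample'}_{k}")
        mol.SetProp("pocket_id", str(lig.pocket_id))
        mol.SetProp("seed", str(lig.seed))
        mol.SetProp("valid", str(lig.valid))
        writer.write(mol)
        n += 1
    writer.close()
    return n
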