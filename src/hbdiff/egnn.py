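"""E(3)-equivariant graph network that predicts diffusion noise.

Nodes are the noised ligand atoms plus the fixed conditions (pocket
Calpha nodes and interaction particles).  Messages see only invariant
quantities (features, squared distances, edge-kind features); coordinate
updates move along relative directions and touch ligand nodes only, so
coordinate outputs are SE(3)-equivariant and feature outputs invariant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from hbdiff.autodiff import Tensor, concat, gather_rows, segment_sum
from hbdiff.complexes import ELEMENT_VOCAB, RESIDUE_CLASSES, PARTICLE_CLASSES

__all__ = ["ConditionedGraph", "EGNNDenoiser", "ModelConfig", "build_edges"]

KIND_LIGAND, KIND_POCKET, KIND_PARTICLE = 0, 1, 2
_KIND_PAIRS = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))


def build_edges(positions: np.ndarray, cutoff: float = 5.0) -> np.ndarray:
    """Undirected edges (i < j) between nodes closer than ``cutoff``."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    positions = np.asarray(positions, dtype=float)
    if len(positions) < 2:
        return np.zeros((0, 2), dtype=int)
    pairs = cKDTree(positions).query_pairs(r=cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return np.zeros((0, 2), dtype=int)
    # query_pairs includes pairs at exactly r; contract is strict inequality
    d = np.linalg.norm(positions[pairs[:, 0]] - positions[pairs[:, 1]], axis=1)
    pairs = pairs[d < cutoff]
    pairs.sort(axis=1)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return pairs[order]


@dataclass
class ConditionedGraph:
    """Joint ligand/pocket/particle graph fed to the denoiser."""

    x: np.ndarray  # (N, 3)
    h: np.ndarray  # (N, D) block features: ligand | pocket | particle | kind | t/T
    kinds: np.ndarray  # (N,) 0=ligand 1=pocket 2=particle
    edges: np.ndarray  # (E, 2) undirected, i < j
    edge_features: np.ndarray  # (E, 6) unordered kind-pair one-hot
    tfrac: float

    @property
    def n_nodes(self) -> int:
        return len(self.kinds)

    @property
    def ligand_mask(self) -> np.ndarray:
        return self.kinds == KIND_LIGAND

    @classmethod
    def assemble(
        cls,
        ligand_x: np.ndarray,
        ligand_h: np.ndarray,
        pocket_x: np.ndarray,
        pocket_h: np.ndarray,
        particle_x: np.ndarray,
        particle_h: np.ndarray,
        tfrac: float,
        cutoff: float = 5.0,
    ) -> "ConditionedGraph":
        """Stack node blocks, pad features and build distance edges."""
        blocks = [
            (np.asarray(ligand_x, float), np.asarray(ligand_h, float), KIND_LIGAND),
            (np.asarray(pocket_x, float), np.asarray(pocket_h, float), KIND_POCKET),
            (np.asarray(particle_x, float), np.asarray(particle_h, float), KIND_PARTICLE),
        ]
        dims = [blocks[0][1].shape[1], blocks[1][1].shape[1], blocks[2][1].shape[1]]
        rows_x, rows_h, kinds = [], [], []
        for b, (bx, bh, kind) in enumerate(blocks):
            bx = bx.reshape(-1, 3)
            for i in range(len(bx)):
                feat = [np.zeros(d) for d in dims]
                feat[b] = bh[i]
                flags = np.zeros(3)
                flags[kind] = 1.0
                rows_h.append(np.concatenate(feat + [flags, [tfrac]]))
                rows_x.append(bx[i])
                kinds.append(kind)
        x = np.array(rows_x, dtype=float).reshape(-1, 3)
        h = np.array(rows_h, dtype=float)
        kinds = np.array(kinds, dtype=int)
        edges = build_edges(x, cutoff=cutoff)
        ef = np.zeros((len(edges), len(_KIND_PAIRS)))
        for e, (i, j) in enumerate(edges):
            pair = tuple(sorted((kinds[i], kinds[j])))
            ef[e, _KIND_PAIRS.index(pair)] = 1.0
        return cls(x=x, h=h, kinds=kinds, edges=edges, edge_features=ef, tfrac=tfrac)

    def directed(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Receiver/sender index arrays and per-edge features, both ways."""
        if len(self.edges) == 0:
            z = np.zeros(0, dtype=int)
            return z, z, np.zeros((0, self.edge_features.shape[1]))
        row = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
        col = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
        ef = np.concatenate([self.edge_features, self.edge_features])
        return row, col, ef


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; defaults follow the training setting."""

    n_layers: int = 6
    hidden: int = 256
    cutoff: float = 5.0
    ligand_vocab: tuple[str, ...] = ELEMENT_VOCAB
    use_edge_features: bool = True
    #: one-hot features are diffused at this amplitude; argmax decoding is
    #: scale-invariant but a larger signal survives noising far better
    feature_scale: float = 4.0
    #: project predicted coordinate noise onto the zero-CoM subspace over
    #: ligand nodes.  Off by default: the fixed conditions break translation
    #: symmetry, and a pinned ligand CoM cannot track the pocket offset.
    zero_com_output: bool = False

    @property
    def ligand_dim(self) -> int:
        return len(self.ligand_vocab)

    @property
    def feature_dim(self) -> int:
        return self.ligand_dim + len(RESIDUE_CLASSES) + len(PARTICLE_CLASSES) + 3 + 1

    @property
    def edge_dim(self) -> int:
        return len(_KIND_PAIRS) if self.use_edge_features else 0


class _MLP:
    """Linear stack with SiLU between layers (optionally after the last)."""

    def __init__(self, dims, rng, final_activation=False, zero_last=False):
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        self.final_activation = final_activation
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            w = rng.standard_normal((d_in, d_out)) / np.sqrt(d_in)
            self.weights.append(Tensor(w, requires_grad=True))
            self.biases.append(Tensor(np.zeros(d_out), requires_grad=True))
        if zero_last:
            self.weights[-1].data[:] = 0.0

    def __call__(self, x: Tensor) -> Tensor:
        n = len(self.weights)
        for k, (w, b) in enumerate(zip(self.weights, self.biases)):
            x = x @ w + b
            if k < n - 1 or self.final_activation:
                x = x.silu()
        return x

    def parameters(self) -> list[Tensor]:
        return self.weights + self.biases


class _EGCL:
    """One equivariant graph convolutional layer."""

    def __init__(self, hidden: int, edge_dim: int, rng):
        self.phi_e = _MLP([2 * hidden + 1 + edge_dim, hidden, hidden], rng, final_activation=True)
        self.phi_att = _MLP([hidden, 1], rng)
        self.phi_h = _MLP([2 * hidden, hidden, hidden], rng)
        # zero-init the final coordinate head: the untrained network starts
        # as (near) the identity on positions
        self.phi_r = _MLP([hidden, hidden, 1], rng, zero_last=True)

    def __call__(self, x, h, row, col, edge_feat, update_mask):
        n = h.shape[0]
        if len(row) == 0:
            return x, h
        h_row = gather_rows(h, row)
        h_col = gather_rows(h, col)
        diff = gather_rows(x, row) - gather_rows(x, col)
        d2 = diff.square().sum(axis=1, keepdims=True)
        parts = [h_row, h_col, d2]
        if edge_feat.shape[1] > 0:
            parts.append(Tensor(edge_feat))
        m = self.phi_e(concat(parts, axis=1))
        att = self.phi_att(m).sigmoid()
        m = m * att
        agg = segment_sum(m, row, n)
        h = h + self.phi_h(concat([h, agg], axis=1))
        d = (d2 + 1e-12).sqrt()
        coef = self.phi_r(m) / (d + 1.0)  # (E,1); /(d+1) for stability
        upd = segment_sum(diff * coef, row, n)
        x = x + upd * Tensor(update_mask.astype(float).reshape(-1, 1))
        return x, h

    def parameters(self) -> list[Tensor]:
        out = []
        for mlp in (self.phi_e, self.phi_att, self.phi_h, self.phi_r):
            out.extend(mlp.parameters())
        return out


class EGNNDenoiser:
    """Stacked EGCLs with a feature embedding and a noise output head."""

    CHECKPOINT_VERSION = 1

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        rng = np.random.default_rng(seed)
        c = self.config
        self.embed = _MLP([c.feature_dim, c.hidden], rng)
        self.layers = [_EGCL(c.hidden, c.edge_dim, rng) for _ in range(c.n_layers)]
        self.head = _MLP([c.hidden, c.hidden, c.ligand_dim], rng)

    # -- forward ---------------------------------------------------------
    def forward(self, graph: ConditionedGraph) -> tuple[Tensor, Tensor]:
        """Differentiable pass; returns ligand-node noise predictions."""
        lig = np.flatnonzero(graph.ligand_mask)
        if len(lig) == 0:
            raise ValueError("graph has no ligand nodes")
        if graph.h.ndim != 2 or graph.h.shape[1] != self.config.feature_dim:
            raise ValueError(
                f"graph feature dim {graph.h.shape} does not match model "
                f"config (expected {self.config.feature_dim})"
            )
        x0 = Tensor(graph.x)
        h = self.embed(Tensor(graph.h))
        x = x0
        row, col, ef = graph.directed()
        if not self.config.use_edge_features:
            ef = ef[:, :0]
        for layer in self.layers:
            x, h = layer(x, h, row, col, ef, graph.ligand_mask)
        eps_x = gather_rows(x, lig) - gather_rows(x0, lig)
        if self.config.zero_com_output:
            eps_x = eps_x - eps_x.mean(axis=0, keepdims=True)
        eps_h = self.head(gather_rows(h, lig))
        return eps_x, eps_h

    def predict(self, graph: ConditionedGraph) -> tuple[np.ndarray, np.ndarray]:
        """Inference-only pass returning plain arrays."""
        eps_x, eps_h = self.forward(graph)
        return eps_x.data.copy(), eps_h.data.copy()

    def parameters(self) -> list[Tensor]:
        out = self.embed.parameters()
        for layer in self.layers:
            out.extend(layer.parameters())
        out.extend(self.head.parameters())
        return out

    # -- checkpointing ---------------------------------------------------
    def save(self, path) -> None:
        payload = {
            "version": self.CHECKPOINT_VERSION,
            "config": {
                "n_layers": self.config.n_layers,
                "hidden": self.config.hidden,
                "cutoff": self.config.cutoff,
                "ligand_vocab": list(self.config.ligand_vocab),
                "use_edge_features": self.config.use_edge_features,
                "feature_scale": self.config.feature_scale,
                "zero_com_output": self.config.zero_com_output,
            },
            "params": [p.data.tolist() for p in self.parameters()],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "EGNNDenoiser":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("version") != cls.CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {payload.get('version')!r}")
        cfg = payload["config"]
        model = cls(
            ModelConfig(
                n_layers=cfg["n_layers"],
                hidden=cfg["hidden"],
                cutoff=cfg["cutoff"],
                ligand_vocab=tuple(cfg["ligand_vocab"]),
                use_edge_features=cfg["use_edge_features"],
                feature_scale=cfg.get("feature_scale", 4.0),
                zero_com_output=cfg.get("zero_com_output", False),
            )
        )
        params = model.parameters()
        if len(params) != len(payload["params"]):
            raise ValueError("checkpoint parameter count does not match config")
        for p, stored in zip(params, payload["params"]):
            arr = np.asarray(stored, dtype=float)
            if arr.shape != p.data.shape:
                raise ValueError("checkpoint parameter shape does not match config")
            p.data = arr
        return model
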