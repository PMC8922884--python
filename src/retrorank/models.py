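"""Energy-based models for re-ranking retrosynthesis candidates.

Each model maps a (product, reactant-set) pair to one scalar "energy" —
lower is better; candidates are re-ranked ascending by energy. Two
architectures:

* :class:`FFEBM` — feedforward over Morgan count fingerprints. Three input
  networks embed the product fingerprint ``P_in``, summed reactant
  fingerprint ``R_in`` and signed difference ``D_in = P_in - R_in`` into
  ``P_out, R_out, D_out`` of shared width d; the output network reads the
  interaction vector ``[P‖R‖D‖P*R‖R*D‖P*D‖cos(P,R)]``.
* :class:`GraphEBM` — two message-passing encoders with separate
  parameters (one for the product graph, one for reactant graphs),
  attention pooling to graph embeddings, reactant embeddings summed then
  projected; the output network reads ``[P_G‖R_G‖P_G-R_G‖P_G*R_G]``.

Both energies are exactly invariant to reactant-list permutations because
reactants are canonically ordered before any summation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .autodiff import Tensor, concat, gather_rows, relu, segment_sum
from .featurization import (
    FingerprintConfig,
    GraphFeatureConfig,
    MolGraph,
)
from . import reaction_io

__all__ = [
    "FFEBMConfig",
    "GraphEBMConfig",
    "FFEBM",
    "GraphEBM",
    "interaction_features",
    "attention_pool",
    "mpnn_encode",
    "GraphBatch",
    "load_model",
]


class Linear:
    """Dense layer with Glorot-uniform weights and zero bias."""

    def __init__(self, name: str, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(rng.uniform(-limit, limit, (n_in, n_out)),
                        requires_grad=True, name=f"{name}.W")
        self.b = Tensor(np.zeros(n_out), requires_grad=True, name=f"{name}.b")

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def tensors(self) -> list[Tensor]:
        return [self.W, self.b]


class MLP:
    """Stack of Linear layers with ReLU between (not after) them."""

    def __init__(self, name: str, dims: Sequence[int], rng: np.random.Generator):
        self.layers = [
            Linear(f"{name}.{i}", dims[i], dims[i + 1], rng)
            for i in range(len(dims) - 1)
        ]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = relu(x)
        return x

    @property
    def tensors(self) -> list[Tensor]:
        return [t for layer in self.layers for t in layer.tensors]


def _check_finite(x: Tensor, where: str) -> Tensor:
    if not np.all(np.isfinite(x.data)):
        raise FloatingPointError(f"non-finite activation in {where}")
    return x


# ---------------------------------------------------------------------------
# FF-EBM
# ---------------------------------------------------------------------------

def interaction_features(p_out: Tensor, r_out: Tensor, d_out: Tensor) -> Tensor:
    """Concatenate embeddings, their pairwise elementwise products and the
    product/reactants cosine similarity: width 6d+1.

    The cosine is guarded to exactly 0 when either embedding is the zero
    vector (the numerator is exactly 0 and the denominator is kept
    positive), avoiding NaN on degenerate embeddings.
    """
    if not (p_out.shape == r_out.shape == d_out.shape):
        raise ValueError(
            f"embedding width mismatch: {p_out.shape} / {r_out.shape} / {d_out.shape}"
        )
    dot = (p_out * r_out).sum(axis=1, keepdims=True)
    nsq_p = (p_out * p_out).sum(axis=1, keepdims=True)
    nsq_r = (r_out * r_out).sum(axis=1, keepdims=True)
    sim = dot / (nsq_p * nsq_r + 1e-24).sqrt()
    return concat(
        [p_out, r_out, d_out, p_out * r_out, r_out * d_out, p_out * d_out, sim],
        axis=1,
    )


@dataclass(frozen=True)
class FFEBMConfig:
    fingerprint: FingerprintConfig = FingerprintConfig()
    embed_dim: int = 300
    hidden_dim: int = 300
    out_hidden_dim: int = 300

    def to_json(self) -> dict:
        d = asdict(self)
        d["fingerprint"] = self.fingerprint.to_json()
        return d

    @staticmethod
    def from_json(d: dict) -> "FFEBMConfig":
        d = dict(d)
        d["fingerprint"] = FingerprintConfig.from_json(d["fingerprint"])
        return FFEBMConfig(**d)


class FFEBM:
    """Fingerprint-feedforward energy model."""

    variant = "ff"

    def __init__(self, config: FFEBMConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        L, h, d = config.fingerprint.length, config.hidden_dim, config.embed_dim
        self.net_p = MLP("net_p", [L, h, d], rng)
        self.net_r = MLP("net_r", [L, h, d], rng)
        self.net_d = MLP("net_d", [L, h, d], rng)
        self.net_out = MLP("net_out", [6 * d + 1, config.out_hidden_dim, 1], rng)

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[Tensor]:
        return (self.net_p.tensors + self.net_r.tensors
                + self.net_d.tensors + self.net_out.tensors)

    def param_dict(self) -> dict[str, np.ndarray]:
        return {t.name: t.data for t in self.parameters()}

    def load_param_dict(self, params: dict[str, np.ndarray]) -> None:
        for t in self.parameters():
            t.data = np.array(params[t.name], dtype=np.float64)

    # -- forward ------------------------------------------------------------

    def energies(self, p_in: np.ndarray, r_in: np.ndarray,
                 d_in: np.ndarray) -> Tensor:
        """Batched energies: inputs are dense (B, L) arrays; returns (B,)."""
        p_out = self.net_p(Tensor(p_in))
        r_out = self.net_r(Tensor(r_in))
        d_out = self.net_d(Tensor(d_in))
        feats = interaction_features(p_out, r_out, d_out)
        e = self.net_out(feats)
        return _check_finite(e.reshape(-1), "FFEBM output")

    def save(self, path: str | Path) -> None:
        reaction_io.save_checkpoint(
            path, self.param_dict(),
            {"variant": self.variant, "config": self.config.to_json()},
        )

    @classmethod
    def load(cls, path: str | Path) -> "FFEBM":
        params, cfg = reaction_io.load_checkpoint(path, expect_variant=cls.variant)
        model = cls(FFEBMConfig.from_json(cfg["config"]))
        model.load_param_dict(params)
        return model


# ---------------------------------------------------------------------------
# Graph-EBM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GraphEBMConfig:
    features: GraphFeatureConfig = GraphFeatureConfig()
    hidden_dim: int = 300
    embed_dim: int = 300
    out_hidden_dim: int = 300
    t_steps: int = 4

    def to_json(self) -> dict:
        d = asdict(self)
        d["features"] = self.features.to_json()
        return d

    @staticmethod
    def from_json(d: dict) -> "GraphEBMConfig":
        d = dict(d)
        d["features"] = GraphFeatureConfig.from_json(d["features"])
        return GraphEBMConfig(**d)


class GraphBatch:
    """Several molecular graphs stacked for joint encoding.

    Directed edges (both orientations per bond) carry bond features;
    per-atom molecule ids route pooling. Batch composition cannot leak
    between molecules: messages travel only along in-molecule edges and
    pooling sums only within a molecule.
    """

    def __init__(self, graphs: Sequence[MolGraph]):
        if not graphs:
            raise ValueError("empty graph batch")
        if any(g.n_atoms == 0 for g in graphs):
            raise ValueError("cannot encode an empty (atom-less) graph")
        offsets = np.cumsum([0] + [g.n_atoms for g in graphs])
        self.atom_features = np.concatenate([g.atom_features for g in graphs])
        src, dst, bf = [], [], []
        for g, off in zip(graphs, offsets):
            if g.n_bonds:
                u, v = g.bonds[:, 0] + off, g.bonds[:, 1] + off
                src.extend([u, v])
                dst.extend([v, u])
                bf.extend([g.bond_features, g.bond_features])
        bond_dim = graphs[0].bond_features.shape[1] if graphs[0].bond_features.ndim == 2 else 0
        self.edge_src = np.concatenate(src) if src else np.empty(0, np.int64)
        self.edge_dst = np.concatenate(dst) if dst else np.empty(0, np.int64)
        self.edge_features = (
            np.concatenate(bf) if bf else np.empty((0, bond_dim))
        )
        self.mol_ids = np.concatenate(
            [np.full(g.n_atoms, i, dtype=np.int64) for i, g in enumerate(graphs)]
        )
        self.n_mols = len(graphs)
        self.n_atoms = int(offsets[-1])


class _MPNNEncoder:
    """Message-passing encoder: T rounds of bond-wise messages, then
    attention pooling to one embedding per molecule."""

    def __init__(self, name: str, cfg: GraphEBMConfig, rng: np.random.Generator):
        d = cfg.hidden_dim
        self.cfg = cfg
        self.lin_in = Linear(f"{name}.in", cfg.features.atom_dim, d, rng)
        self.lin_msg = Linear(f"{name}.msg", d + cfg.features.bond_dim, d, rng)
        self.lin_self = Linear(f"{name}.self", d, d, rng)
        self.lin_agg = Linear(f"{name}.agg", d, d, rng)
        self.att = MLP(f"{name}.att", [d, d, 1], rng)
        self.proj = MLP(f"{name}.proj", [d, cfg.embed_dim, cfg.embed_dim], rng)

    def atom_reps(self, batch: GraphBatch, t_steps: int | None = None) -> Tensor:
        t_steps = self.cfg.t_steps if t_steps is None else t_steps
        h = relu(self.lin_in(Tensor(batch.atom_features)))
        edge_feats = Tensor(batch.edge_features)
        for _ in range(t_steps):
            if batch.edge_src.size:
                h_src = gather_rows(h, batch.edge_src)
                msgs = relu(self.lin_msg(concat([h_src, edge_feats], axis=1)))
                m = segment_sum(msgs, batch.edge_dst, batch.n_atoms)
            else:
                m = Tensor(np.zeros_like(h.data))
            h = relu(self.lin_self(h) + self.lin_agg(m))
        return h

    def __call__(self, batch: GraphBatch, t_steps: int | None = None) -> Tensor:
        h = self.atom_reps(batch, t_steps)
        pooled, _ = attention_pool(h, self.att, batch.mol_ids, batch.n_mols)
        return self.proj(pooled)

    @property
    def tensors(self) -> list[Tensor]:
        return (self.lin_in.tensors + self.lin_msg.tensors + self.lin_self.tensors
                + self.lin_agg.tensors + self.att.tensors + self.proj.tensors)


def mpnn_encode(graph: MolGraph, encoder: _MPNNEncoder,
                t_steps: int | None = None) -> np.ndarray:
    """Per-atom representations of one graph; with ``t_steps=0`` each
    representation depends on its own atom features alone."""
    if graph.n_atoms == 0:
        raise ValueError("cannot encode an empty graph")
    return encoder.atom_reps(GraphBatch([graph]), t_steps).data


def attention_pool(
    atom_reps: Tensor,
    att_net: MLP,
    segment_ids: np.ndarray,
    num_segments: int,
) -> tuple[Tensor, np.ndarray]:
    """Per-graph attention-weighted sum of atom representations.

    Weights are a softmax (over the atoms of each graph) of a feedforward
    network's per-atom logits: nonnegative, summing to 1 per graph. Returns
    (pooled embeddings, attention weights as a plain array).
    """
    if atom_reps.shape[0] == 0:
        raise ValueError("attention pooling over zero atoms")
    logits = att_net(atom_reps)  # (n_atoms, 1)
    # max-shift per segment for numerical stability (shift is a constant
    # wrt the softmax value, so gradients are unaffected)
    seg_max = np.full(num_segments, -np.inf)
    np.maximum.at(seg_max, segment_ids, logits.data[:, 0])
    shifted = logits - Tensor(seg_max[segment_ids][:, None])
    ex = shifted.exp()
    denom = segment_sum(ex, segment_ids, num_segments)
    weights = ex / gather_rows(denom, segment_ids)
    pooled = segment_sum(weights * atom_reps, segment_ids, num_segments)
    return pooled, weights.data[:, 0]


class GraphEBM:
    """Graph-MPNN energy model; product and reactant encoders share no
    parameters."""

    variant = "graph"

    def __init__(self, config: GraphEBMConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.product_encoder = _MPNNEncoder("prod", config, rng)
        self.reactant_encoder = _MPNNEncoder("react", config, rng)
        d = config.embed_dim
        self.net_out = MLP("net_out", [4 * d, config.out_hidden_dim, 1], rng)

    def parameters(self) -> list[Tensor]:
        return (self.product_encoder.tensors + self.reactant_encoder.tensors
                + self.net_out.tensors)

    def param_dict(self) -> dict[str, np.ndarray]:
        return {t.name: t.data for t in self.parameters()}

    def load_param_dict(self, params: dict[str, np.ndarray]) -> None:
        for t in self.parameters():
            t.data = np.array(params[t.name], dtype=np.float64)

    def energies(
        self,
        product_graph: MolGraph,
        reactant_graph_lists: Sequence[Sequence[MolGraph]],
    ) -> Tensor:
        """Energies of B candidate reactant-sets against one product.

        Reactant graph lists must already be in canonical molecule order
        (the assembly layer guarantees this), so the embedding sum — and
        therefore the energy — is bitwise reactant-order invariant.
        """
        if any(len(gs) == 0 for gs in reactant_graph_lists):
            raise ValueError("candidate with no reactant graphs")
        n_cand = len(reactant_graph_lists)
        all_graphs = [g for gs in reactant_graph_lists for g in gs]
        cand_ids = np.concatenate(
            [np.full(len(gs), i, dtype=np.int64)
             for i, gs in enumerate(reactant_graph_lists)]
        )
        r_g = self._candidate_embeddings(all_graphs, cand_ids, n_cand)
        p_g = self._product_embedding(product_graph)
        p_rep = gather_rows(p_g, np.zeros(n_cand, dtype=np.int64))
        feats = concat([p_rep, r_g, p_rep - r_g, p_rep * r_g], axis=1)
        e = self.net_out(feats)
        return _check_finite(e.reshape(-1), "GraphEBM output")

    def _product_embedding(self, product_graph: MolGraph) -> Tensor:
        enc = self.product_encoder
        batch = GraphBatch([product_graph])
        h = enc.atom_reps(batch)
        pooled, _ = attention_pool(h, enc.att, batch.mol_ids, batch.n_mols)
        return enc.proj(pooled)

    def _candidate_embeddings(self, all_graphs: Sequence[MolGraph],
                              cand_ids: np.ndarray, n_cand: int) -> Tensor:
        enc = self.reactant_encoder
        batch = GraphBatch(all_graphs)
        h = enc.atom_reps(batch)
        pooled, _ = attention_pool(h, enc.att, batch.mol_ids, batch.n_mols)
        summed = segment_sum(pooled, cand_ids, n_cand)
        return enc.proj(summed)

    def save(self, path: str | Path) -> None:
        reaction_io.save_checkpoint(
            path, self.param_dict(),
            {"variant": self.variant, "config": self.config.to_json()},
        )

    @classmethod
    def load(cls, path: str | Path) -> "GraphEBM":
        params, cfg = reaction_io.load_checkpoint(path, expect_variant=cls.variant)
        model = cls(GraphEBMConfig.from_json(cfg["config"]))
        model.load_param_dict(params)
        return model


def load_model(path: str | Path):
    """Load either EBM variant from a checkpoint file."""
    _, cfg = reaction_io.load_checkpoint(path)
    if cfg.get("variant") == FFEBM.variant:
        return FFEBM.load(path)
    if cfg.get("variant") == GraphEBM.variant:
        return GraphEBM.load(path)
    raise reaction_io.CheckpointMismatchError(
        f"unknown model variant {cfg.get('variant')!r} in {path}"
    )
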