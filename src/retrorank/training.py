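"""Contrastive training of the energy models on proposer candidates.

For each product the proposer's top-K candidate reactant-sets act as hard
negatives; the published reactant-set is the positive. The listwise loss is
the negative log of the softmax (over candidates) of negated energies,

    L = -log( exp(-E_pos) / sum_k exp(-E_k) ),

which pushes the positive's energy below the negatives'. At train time the
ground truth is appended to the candidate list if the proposer missed it;
at evaluation time it never is — a product whose pool lacks the truth is
unrankable and counts as a failure at every N.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, asdict
from typing import Literal, Sequence

import numpy as np

from .featurization import (
    CountFingerprint,
    FingerprintConfig,
    GraphFeatureConfig,
    MolGraph,
    fingerprint_reactant_set,
    morgan_count_fingerprint,
    mol_to_graph,
)
from .models import FFEBM, FFEBMConfig, GraphEBM, GraphEBMConfig
from .reaction_io import (
    Candidate,
    CandidateSet,
    ProposalTable,
    Provenance,
    Reaction,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "AssembledItem",
    "assemble_candidates",
    "batch_loss",
    "batch_loss_and_grad",
    "pool_multi_proposer",
    "FeatureCache",
    "candidate_energies",
    "Adam",
    "train_ebm",
]


# ---------------------------------------------------------------------------
# Candidate assembly
# ---------------------------------------------------------------------------

@dataclass
class AssembledItem:
    """Top-K candidates of one product, ready for the model.

    In train mode the positive is always present (injected if the proposer
    missed it) and ``positive_index`` points at it. In eval mode the truth
    is never injected; ``truth_absent`` records an unrankable product.
    """

    product_key: str
    product_smiles: str
    candidates: list[Candidate]
    positive_index: int | None
    truth_absent: bool
    injected: bool = False


def assemble_candidates(
    candidate_set: CandidateSet,
    true_key: str | None,
    k: int,
    mode: Literal["train", "eval"],
    true_reactants: Sequence[str] | None = None,
) -> AssembledItem:
    """Take the proposer's top-K candidates; in train mode guarantee the
    positive is among them by appending it when absent (item size K+1)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if mode not in ("train", "eval"):
        raise ValueError(f"unknown mode {mode!r}")
    top = list(candidate_set.candidates[:k])
    pos = next((i for i, c in enumerate(top) if c.key == true_key), None)
    injected = False
    if mode == "train":
        if true_key is None:
            raise ValueError(
                f"train-mode assembly for {candidate_set.product_key} "
                "requires a ground-truth key"
            )
        if pos is None:
            reactants = (
                tuple(true_reactants) if true_reactants is not None
                else tuple(true_key.split("."))
            )
            top.append(
                Candidate(key=true_key, reactant_smiles=reactants,
                          provenance=[Provenance("ground_truth", k + 1)])
            )
            pos = len(top) - 1
            injected = True
    return AssembledItem(
        product_key=candidate_set.product_key,
        product_smiles=candidate_set.product_smiles,
        candidates=top,
        positive_index=pos,
        truth_absent=(pos is None),
        injected=injected,
    )


# ---------------------------------------------------------------------------
# Listwise loss
# ---------------------------------------------------------------------------

def batch_loss_and_grad(energies: np.ndarray,
                        positive_index: int) -> tuple[float, np.ndarray]:
    """Loss value and its exact gradient wrt the energy vector.

    Computed in the energy-gap form L = logsumexp_k(E_pos - E_k), which is
    algebraically identical to -log softmax(-E)[pos], max-shifted for
    stability, and shift-invariant to rounding level. With
    p = softmax(-E), dL/dE = e_pos - p.
    """
    e = np.asarray(energies, dtype=np.float64)
    if e.ndim != 1 or e.size < 2:
        raise ValueError("need a 1-D vector of >= 2 candidate energies")
    if not (0 <= positive_index < e.size):
        raise ValueError(f"positive_index {positive_index} out of range")
    if not np.all(np.isfinite(e)):
        raise FloatingPointError("non-finite candidate energies")
    gaps = e[positive_index] - e
    m = gaps.max()
    ex = np.exp(gaps - m)
    z = ex.sum()
    loss = float(m + np.log(z))
    grad = -ex / z
    grad[positive_index] += 1.0
    return loss, grad


def batch_loss(energies: np.ndarray, positive_index: int) -> float:
    """Listwise contrastive loss over one product's candidates (scalar)."""
    return batch_loss_and_grad(energies, positive_index)[0]


# ---------------------------------------------------------------------------
# Multi-proposer pooling
# ---------------------------------------------------------------------------

def pool_multi_proposer(
    tables: Sequence[ProposalTable], per_model_k: int
) -> ProposalTable:
    """Union of several proposers' candidate lists.

    Each table's per-product list is truncated to ``per_model_k`` before the
    union; duplicates merge provenance; the pooled order is ascending by
    best (minimum) original rank with proposer-name tie-break.
    """
    if not tables:
        raise ValueError("need at least one proposal table")
    pooled: ProposalTable = {}
    for table in tables:
        for product_key, cs in table.items():
            out = pooled.get(product_key)
            if out is None:
                out = CandidateSet(product_key=product_key,
                                   product_smiles=cs.product_smiles,
                                   true_key=cs.true_key)
                pooled[product_key] = out
            if out.true_key is None:
                out.true_key = cs.true_key
            for cand in cs.candidates[:per_model_k]:
                for prov in cand.provenance:
                    out.add(cand.reactant_smiles, prov)
    for cs in pooled.values():
        cs.sort()
    return pooled


# ---------------------------------------------------------------------------
# Feature cache
# ---------------------------------------------------------------------------

class FeatureCache:
    """Memoized featurization keyed by canonical SMILES.

    Candidate reactant lists are featurized through their canonical key, so
    every downstream sum runs in a fixed (sorted) molecule order — the root
    of the models' exact permutation invariance.
    """

    def __init__(
        self,
        fingerprint: FingerprintConfig | None = None,
        graph_features: GraphFeatureConfig | None = None,
    ):
        self.fingerprint = fingerprint
        self.graph_features = graph_features
        self._fp: dict[str, CountFingerprint] = {}
        self._set_fp: dict[str, CountFingerprint] = {}
        self._graph: dict[str, MolGraph] = {}

    def product_fp(self, smiles_or_key: str) -> CountFingerprint:
        fp = self._fp.get(smiles_or_key)
        if fp is None:
            cfg = self.fingerprint
            fp = morgan_count_fingerprint(smiles_or_key, cfg.radius, cfg.length,
                                          cfg.chirality)
            self._fp[smiles_or_key] = fp
        return fp

    def reactant_set_fp(self, key: str) -> CountFingerprint:
        fp = self._set_fp.get(key)
        if fp is None:
            fp = fingerprint_reactant_set(key.split("."), self.fingerprint)
            self._set_fp[key] = fp
        return fp

    def graph(self, smiles: str) -> MolGraph:
        g = self._graph.get(smiles)
        if g is None:
            g = mol_to_graph(smiles, self.graph_features)
            self._graph[smiles] = g
        return g

    def ff_inputs(self, product_smiles: str, candidates: Sequence[Candidate]):
        """Dense (B, L) arrays (P_in, R_in, D_in) for one product's batch."""
        p_dense = self.product_fp(product_smiles).to_dense()
        r = np.stack([self.reactant_set_fp(c.key).to_dense() for c in candidates])
        p = np.broadcast_to(p_dense, r.shape).copy()
        return p, r, p - r

    def graph_inputs(self, product_smiles: str, candidates: Sequence[Candidate]):
        """(product MolGraph, per-candidate reactant MolGraph lists)."""
        pg = self.graph(product_smiles)
        lists = [[self.graph(s) for s in c.key.split(".")] for c in candidates]
        return pg, lists

    @staticmethod
    def for_model(model) -> "FeatureCache":
        if isinstance(model, FFEBM):
            return FeatureCache(fingerprint=model.config.fingerprint)
        if isinstance(model, GraphEBM):
            return FeatureCache(graph_features=model.config.features)
        raise TypeError(f"unknown model type {type(model)!r}")


def candidate_energies(model, cache: FeatureCache, product_smiles: str,
                       candidates: Sequence[Candidate]):
    """Autodiff energies (Tensor, shape (B,)) of one product's candidates."""
    if isinstance(model, FFEBM):
        p, r, d = cache.ff_inputs(product_smiles, candidates)
        return model.energies(p, r, d)
    if isinstance(model, GraphEBM):
        pg, lists = cache.graph_inputs(product_smiles, candidates)
        return model.energies(pg, lists)
    raise TypeError(f"unknown model type {type(model)!r}")


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Knobs of the contrastive training run.

    ``k_train`` candidates enter each product's loss (the ground truth is
    appended when the proposer missed it); ``k_eval`` candidates are
    re-ranked at validation/test time, never with truth injection.
    """

    k_train: int = 50
    k_eval: int = 200
    epochs: int = 5
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0
    model: str = "ff"
    validation_fraction: float = 0.1

    def __post_init__(self):
        if self.k_train < 1:
            raise ValueError("k_train must be >= 1")
        if self.k_eval < self.k_train:
            raise ValueError("k_eval must be >= k_train")

    def to_json(self) -> dict:
        return asdict(self)


def _validation_top1(model, cache, items: list[AssembledItem]) -> float:
    hits = 0
    for item in items:
        if item.truth_absent:
            continue
        e = candidate_energies(model, cache, item.product_smiles,
                               item.candidates).data
        order = np.argsort(e, kind="stable")
        if int(order[0]) == item.positive_index:
            hits += 1
    return hits / len(items) if items else 0.0


def train_ebm(
    reactions: Sequence[Reaction],
    proposal_table: ProposalTable,
    config: TrainConfig,
    model=None,
    val_reactions: Sequence[Reaction] | None = None,
):
    """Train an EBM on proposer candidates; returns (model, history).

    ``model`` may be a pre-built :class:`FFEBM`/:class:`GraphEBM`; when
    omitted a default of the variant named in ``config.model`` is built.
    Model selection is by best validation top-1 across epochs; the
    returned model carries the best-epoch parameters. Fully reproducible
    given (seed, config, data).
    """
    rng = np.random.default_rng(config.seed)
    if model is None:
        if config.model == "ff":
            model = FFEBM(FFEBMConfig(), seed=config.seed)
        elif config.model == "graph":
            model = GraphEBM(GraphEBMConfig(), seed=config.seed)
        else:
            raise ValueError(f"unknown model variant {config.model!r}")
    cache = FeatureCache.for_model(model)

    true_keys = {r.product_key: r.reactant_key for r in reactions}
    true_reactants = {r.product_key: r.reactant_smiles for r in reactions}

    # deterministic train/validation split over products with proposals
    keys = sorted(k for k in true_keys if k in proposal_table
                  and proposal_table[k].candidates)
    if val_reactions is not None:
        val_keys = sorted(
            r.product_key for r in val_reactions
            if r.product_key in proposal_table
            and proposal_table[r.product_key].candidates
        )
        for r in val_reactions:
            true_keys.setdefault(r.product_key, r.reactant_key)
            true_reactants.setdefault(r.product_key, r.reactant_smiles)
        train_keys = keys
    else:
        perm = rng.permutation(len(keys))
        n_val = max(1, int(round(config.validation_fraction * len(keys))))
        val_keys = [keys[i] for i in perm[:n_val]]
        train_keys = [keys[i] for i in perm[n_val:]]
    if not train_keys:
        raise ValueError("no training products with candidates")

    train_items = [
        assemble_candidates(proposal_table[k], true_keys[k], config.k_train,
                            "train", true_reactants[k])
        for k in train_keys
    ]
    train_items = [it for it in train_items if len(it.candidates) >= 2]
    val_items = [
        assemble_candidates(proposal_table[k], true_keys[k], config.k_eval, "eval")
        for k in val_keys
    ]

    params = model.parameters()
    opt = Adam(params, lr=config.learning_rate)
    history: list[dict] = []
    best_top1, best_params = -1.0, None
    order = np.arange(len(train_items))
    for epoch in range(config.epochs):
        rng.shuffle(order)
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            opt.zero_grad()
            for j in idx:
                item = train_items[j]
                e = candidate_energies(model, cache, item.product_smiles,
                                       item.candidates)
                loss, grad = batch_loss_and_grad(e.data, item.positive_index)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"loss diverged at epoch {epoch}, product "
                        f"{item.product_key}"
                    )
                e.backward(seed=grad / len(idx))
                losses.append(loss)
            opt.step()
        val_top1 = _validation_top1(model, cache, val_items)
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)),
             "val_top1": val_top1}
        )
        logger.info("epoch %d: loss %.4f  val top-1 %.4f",
                    epoch, history[-1]["train_loss"], val_top1)
        if val_top1 > best_top1:
            best_top1 = val_top1
            best_params = copy.deepcopy(model.param_dict())
    if best_params is not None:
        model.load_param_dict(best_params)
    return model, history
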