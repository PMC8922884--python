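"""Re-ranking by energy and ranking metrics.

Candidates are sorted ascending by energy (lowest energy = top re-ranked
prediction); exact energy ties fall back to the proposer's original order.
Metrics: top-N accuracy, mean reciprocal rank (MRR), area under the top-N
curve, and cross-model rank cross-tabulation. Products whose candidate
pool lacks the published reactant-set stay in every denominator — they are
failures the re-ranker cannot fix, which is exactly how a proposer's
top-K recall bounds re-ranked accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .reaction_io import CandidateSet
from .training import FeatureCache, assemble_candidates, candidate_energies

__all__ = [
    "RerankResult",
    "MetricsReport",
    "rerank",
    "rerank_table",
    "top_n_accuracy",
    "mean_reciprocal_rank",
    "top_n_auc",
    "evaluate",
    "rank_crosstab",
    "format_metrics_table",
]

DEFAULT_N_LIST = (1, 3, 5, 10, 20, 50)


@dataclass
class RerankResult:
    """One product's candidates in ascending-energy order."""

    product_key: str
    candidate_keys: list[str]
    energies: list[float]
    true_rank: int | None = None
    original_true_rank: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "product_key": self.product_key,
            "candidate_keys": self.candidate_keys,
            "energies": self.energies,
            "true_rank": self.true_rank,
            "original_true_rank": self.original_true_rank,
        }

    @staticmethod
    def from_json(d: dict) -> "RerankResult":
        return RerankResult(
            product_key=d["product_key"],
            candidate_keys=list(d["candidate_keys"]),
            energies=[float(e) for e in d["energies"]],
            true_rank=d.get("true_rank"),
            original_true_rank=dict(d.get("original_true_rank") or {}),
        )


def rerank(
    model,
    candidate_set: CandidateSet,
    cache: FeatureCache | None = None,
    k: int | None = None,
) -> RerankResult:
    """Order one product's candidates by model energy (ascending).

    ``model=None`` is the identity re-ranker: candidates keep the
    proposer's order and the "energy" is the best original rank, so
    baseline metrics are the proposer's own. ``k`` truncates the pool
    (eval-mode assembly; the truth is never injected).
    """
    if not candidate_set.candidates:
        raise ValueError(f"no candidates for {candidate_set.product_key}")
    item = assemble_candidates(
        candidate_set, candidate_set.true_key,
        k if k is not None else len(candidate_set.candidates), "eval",
    )
    cands = item.candidates
    if model is None:
        energies = np.array([float(c.best_rank) for c in cands])
    else:
        if cache is None:
            cache = FeatureCache.for_model(model)
        energies = candidate_energies(
            model, cache, item.product_smiles, cands
        ).data
    # ascending energy; exact ties broken by the proposer's original order
    order = sorted(
        range(len(cands)),
        key=lambda i: (energies[i], cands[i].best_rank, cands[i].best_proposer,
                       cands[i].key),
    )
    keys = [cands[i].key for i in order]
    true_rank = None
    original = {}
    if candidate_set.true_key is not None:
        if candidate_set.true_key in keys:
            true_rank = keys.index(candidate_set.true_key) + 1
        for cand in cands:
            if cand.key == candidate_set.true_key:
                for prov in cand.provenance:
                    best = original.get(prov.proposer)
                    if best is None or prov.rank < best:
                        original[prov.proposer] = prov.rank
    return RerankResult(
        product_key=candidate_set.product_key,
        candidate_keys=keys,
        energies=[float(energies[i]) for i in order],
        true_rank=true_rank,
        original_true_rank=original,
    )


def rerank_table(model, table, cache: FeatureCache | None = None,
                 k: int | None = None) -> list[RerankResult]:
    """Re-rank every product of a proposal table (sorted product order)."""
    if model is not None and cache is None:
        cache = FeatureCache.for_model(model)
    return [rerank(model, table[key], cache, k) for key in sorted(table)]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _check_nonempty(results: Sequence[RerankResult]) -> None:
    if not results:
        raise ValueError("no rerank results to score")


def top_n_accuracy(
    results: Sequence[RerankResult], n_list: Sequence[int] = DEFAULT_N_LIST
) -> dict[int, float]:
    """Fraction of products whose true rank is <= N, for each N.

    Truth-absent products count as failures at every N.
    """
    _check_nonempty(results)
    ranks = [r.true_rank for r in results]
    return {
        n: sum(1 for r in ranks if r is not None and r <= n) / len(ranks)
        for n in n_list
    }


def mean_reciprocal_rank(results: Sequence[RerankResult]) -> float:
    """Mean of 1/true_rank over products (0 where the truth is absent)."""
    _check_nonempty(results)
    return float(
        np.mean([0.0 if r.true_rank is None else 1.0 / r.true_rank
                 for r in results])
    )


def top_n_auc(results: Sequence[RerankResult], n_max: int = 50) -> float:
    """Normalized area under the top-N accuracy curve.

    Convention: the mean of acc(N) over N = 1..n_max (normalized
    step-function area). 1.0 for a perfect ranker, 0.0 when the truth is
    absent everywhere.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    acc = top_n_accuracy(results, range(1, n_max + 1))
    return float(np.mean([acc[n] for n in range(1, n_max + 1)]))


@dataclass
class MetricsReport:
    top_n: dict[int, float]
    mrr: float
    auc: float
    n_products: int
    truth_absent: int

    def to_json(self) -> dict:
        return {
            "top_n": {str(n): v for n, v in self.top_n.items()},
            "mrr": self.mrr,
            "auc": self.auc,
            "n_products": self.n_products,
            "truth_absent": self.truth_absent,
        }


def evaluate(
    results: Sequence[RerankResult],
    n_list: Sequence[int] = DEFAULT_N_LIST,
    auc_n_max: int = 50,
) -> MetricsReport:
    """Full metrics report over a set of rerank results."""
    _check_nonempty(results)
    return MetricsReport(
        top_n=top_n_accuracy(results, n_list),
        mrr=mean_reciprocal_rank(results),
        auc=top_n_auc(results, auc_n_max),
        n_products=len(results),
        truth_absent=sum(1 for r in results if r.true_rank is None),
    )


def format_metrics_table(reports: Mapping[str, MetricsReport]) -> str:
    """Plain-text table: rows = model variants, columns = top-N + MRR."""
    if not reports:
        return ""
    n_list = list(next(iter(reports.values())).top_n)
    header = ["Model"] + [f"Top-{n}" for n in n_list] + ["MRR"]
    rows = [header]
    for name, rep in reports.items():
        rows.append(
            [name]
            + [f"{100 * rep.top_n[n]:.1f}" for n in n_list]
            + [f"{rep.mrr:.3f}"]
        )
    widths = [max(len(r[i]) for r in rows) for i in range(len(header))]
    lines = [
        "  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip()
        for row in rows
    ]
    lines.insert(1, "-" * len(lines[0]))
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Cross-model rank cross-tabulation
# ---------------------------------------------------------------------------

def _bucket(rank: int | None, k: int) -> str:
    if rank is None:
        return "absent"
    if rank <= k:
        return str(rank)
    return f">{k}"


def rank_crosstab(
    results_a: Sequence[RerankResult],
    results_b: Sequence[RerankResult],
    class_labels: Mapping[str, int] | None = None,
    max_rank: int = 10,
) -> dict[int | str, pd.DataFrame]:
    """Per-class contingency matrices of bucketed ranks of two rankers.

    Buckets are {1, 2, ..., max_rank, ">max_rank", "absent"}. Both result
    lists must cover the same products; a mismatch raises with the
    symmetric difference. Each class's matrix sums to the class size.
    """
    a_by = {r.product_key: r for r in results_a}
    b_by = {r.product_key: r for r in results_b}
    if set(a_by) != set(b_by):
        diff = sorted(set(a_by) ^ set(b_by))
        raise ValueError(f"product sets differ; symmetric difference: {diff}")
    buckets = [str(i) for i in range(1, max_rank + 1)] + [f">{max_rank}", "absent"]
    tables: dict[int | str, pd.DataFrame] = {}
    for key in sorted(a_by):
        cls = class_labels.get(key, "all") if class_labels else "all"
        if cls not in tables:
            tables[cls] = pd.DataFrame(
                np.zeros((len(buckets), len(buckets)), dtype=int),
                index=pd.Index(buckets, name="rank_a"),
                columns=pd.Index(buckets, name="rank_b"),
            )
        tables[cls].loc[
            _bucket(a_by[key].true_rank, max_rank),
            _bucket(b_by[key].true_rank, max_rank),
        ] += 1
    return tables
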