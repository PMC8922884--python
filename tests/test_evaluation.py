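import numpy as np
import pytest

from retrorank.evaluation import (
    RerankResult,
    evaluate,
    format_metrics_table,
    mean_reciprocal_rank,
    rank_crosstab,
    rerank,
    rerank_table,
    top_n_accuracy,
    top_n_auc,
)
from retrorank.reaction_io import CandidateSet, Provenance, write_reranked, \
    read_reranked


def result(true_rank, key="p", n_cands=8):
    return RerankResult(
        product_key=key,
        candidate_keys=[f"c{i}" for i in range(n_cands)],
        energies=list(np.linspace(-1, 1, n_cands)),
        true_rank=true_rank,
    )


def make_candidate_set(smis, true_key=None, product="CCOC(C)=O"):
    cs = CandidateSet(product_key=product, product_smiles=product,
                      true_key=true_key)
    for rank, smi in enumerate(smis, start=1):
        cs.add(smi.split("."), Provenance("A", rank))
    cs.sort()
    return cs


class _FixedEnergyModel:
    """Assigns preset energies keyed by candidate key (test double)."""

    def __init__(self, energy_by_key):
        self.energy_by_key = energy_by_key


def _rerank_fixed(cs, energy_by_key):
    """Re-rank using preset energies via the identity-model pathway."""
    cands = cs.candidates
    energies = np.array([energy_by_key[c.key] for c in cands])
    order = sorted(
        range(len(cands)),
        key=lambda i: (energies[i], cands[i].best_rank, cands[i].best_proposer),
    )
    keys = [cands[i].key for i in order]
    true_rank = keys.index(cs.true_key) + 1 if cs.true_key in keys else None
    return RerankResult(cs.product_key, keys,
                        [float(energies[i]) for i in order], true_rank)


class TestRerank:
    def test_sorts_ascending_by_energy(self):
        cs = make_candidate_set(["CCO", "CCN", "CCS"])
        keys = [c.key for c in cs.candidates]
        res = _rerank_fixed(cs, dict(zip(keys, [2.0, 1.0, 3.0])))
        assert res.candidate_keys == [keys[1], keys[0], keys[2]]

    def test_ties_preserve_proposer_order(self):
        cs = make_candidate_set(["CCO", "CCN", "CCS"])
        keys = [c.key for c in cs.candidates]
        res = _rerank_fixed(cs, {k: 0.0 for k in keys})
        assert res.candidate_keys == keys

    def test_identity_reranker_preserves_proposer_order(self):
        cs = make_candidate_set(["CCO", "CCN", "CCS"], true_key="CCN")
        res = rerank(None, cs)
        assert res.candidate_keys == [c.key for c in cs.candidates]
        assert res.true_rank == 2
        assert res.original_true_rank == {"A": 2}

    def test_output_is_permutation_of_input(self, proposal_table):
        for cs in list(proposal_table.values())[:10]:
            res = rerank(None, cs)
            assert sorted(res.candidate_keys) == \
                sorted(c.key for c in cs.candidates)

    def test_truth_absent_true_rank_none(self):
        cs = make_candidate_set(["CCO", "CCN"], true_key="CCCCCC")
        assert rerank(None, cs).true_rank is None

    def test_empty_candidates_rejected(self):
        cs = CandidateSet(product_key="C", product_smiles="C")
        with pytest.raises(ValueError):
            rerank(None, cs)


class TestMetrics:
    def test_top_n_direct_count(self):
        results = [result(1), result(2), result(7)]
        acc = top_n_accuracy(results, [1, 5, 10])
        assert acc[1] == pytest.approx(1 / 3)
        assert acc[5] == pytest.approx(2 / 3)
        assert acc[10] == pytest.approx(1.0)

    def test_top_n_monotone_in_n(self, rng):
        results = [
            result(int(r) if r > 0 else None)
            for r in rng.integers(0, 12, size=50)
        ]
        acc = top_n_accuracy(results, range(1, 13))
        vals = [acc[n] for n in range(1, 13)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_mrr_enumeration(self):
        results = [result(1), result(3), result(None)]
        assert mean_reciprocal_rank(results) == pytest.approx((1 + 1 / 3) / 3)

    def test_mrr_edge_cases(self):
        assert mean_reciprocal_rank([result(1)] * 3) == 1.0
        assert mean_reciprocal_rank([result(None)] * 3) == 0.0

    def test_auc_perfect_and_absent(self):
        assert top_n_auc([result(1)] * 4, n_max=10) == 1.0
        assert top_n_auc([result(None)] * 4, n_max=10) == 0.0

    def test_auc_step_mean_convention(self):
        assert top_n_auc([result(1), result(2)], n_max=2) == \
            pytest.approx(0.75)

    def test_empty_results_error(self):
        with pytest.raises(ValueError):
            top_n_accuracy([], [1])
        with pytest.raises(ValueError):
            mean_reciprocal_rank([])

    def test_metrics_match_brute_force_oracle(self, rng):
        """Exhaustive cross-check on 1000 random small instances."""
        for _ in range(1000):
            n_prod = int(rng.integers(1, 7))
            ranks = []
            for _ in range(n_prod):
                n_cand = int(rng.integers(1, 7))
                has_truth = rng.random() < 0.8
                ranks.append(
                    int(rng.integers(1, n_cand + 1)) if has_truth else None
                )
            results = [result(r, key=f"p{i}", n_cands=6)
                       for i, r in enumerate(ranks)]
            # brute-force oracle: direct definition sums
            for n in (1, 2, 3, 6):
                expect = sum(
                    1 for r in ranks if r is not None and r <= n
                ) / n_prod
                assert top_n_accuracy(results, [n])[n] == expect
            expect_mrr = sum(
                0 if r is None else 1 / r for r in ranks
            ) / n_prod
            assert mean_reciprocal_rank(results) == pytest.approx(
                expect_mrr, abs=1e-12
            )
            n_max = 6
            expect_auc = np.mean(
                [sum(1 for r in ranks if r is not None and r <= n) / n_prod
                 for n in range(1, n_max + 1)]
            )
            assert top_n_auc(results, n_max) == pytest.approx(
                expect_auc, abs=1e-12
            )

    def test_recall_ceiling(self, proposal_table):
        """acc(N -> inf) equals the pool's truth-containment fraction."""
        results = rerank_table(None, proposal_table)
        n_max = max(len(r.candidate_keys) for r in results) + 5
        contain = np.mean([r.true_rank is not None for r in results])
        assert top_n_accuracy(results, [n_max])[n_max] == pytest.approx(contain)


class TestCrosstab:
    def test_identical_rankers_mass_on_diagonal(self):
        res = [result(r, key=f"p{i}") for i, r in enumerate([1, 2, 3, None])]
        tabs = rank_crosstab(res, res, max_rank=5)
        mat = tabs["all"].to_numpy()
        assert mat.sum() == 4
        assert np.trace(mat) == 4

    def test_swapped_ranks_off_diagonal(self):
        a = [result(1, key="p0"), result(2, key="p1")]
        b = [result(2, key="p0"), result(1, key="p1")]
        mat = rank_crosstab(a, b, max_rank=3)["all"]
        assert mat.loc["1", "2"] == 1
        assert mat.loc["2", "1"] == 1

    def test_per_class_totals(self):
        res_a = [result(1, key=f"p{i}") for i in range(6)]
        res_b = [result(2, key=f"p{i}") for i in range(6)]
        labels = {f"p{i}": (1 if i < 4 else 2) for i in range(6)}
        tabs = rank_crosstab(res_a, res_b, class_labels=labels)
        assert tabs[1].to_numpy().sum() == 4
        assert tabs[2].to_numpy().sum() == 2

    def test_product_mismatch_lists_difference(self):
        a = [result(1, key="p0")]
        b = [result(1, key="p1")]
        with pytest.raises(ValueError, match="p0"):
            rank_crosstab(a, b)


class TestSerialization:
    def test_reranked_round_trip(self, tmp_path):
        results = [result(1), result(None, key="q")]
        results[0].energies = [0.1 + 1e-17, 0.5, -3.25]
        results[0].candidate_keys = ["a", "b", "c"]
        path = tmp_path / "rr.jsonl"
        write_reranked(path, results)
        back = read_reranked(path)
        assert [r.to_json() for r in back] == [r.to_json() for r in results]

    def test_format_table_has_all_rows(self):
        rep = evaluate([result(1), result(2)])
        text = format_metrics_table({"raw": rep, "reranked": rep})
        assert "raw" in text and "reranked" in text and "Top-1" in text
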