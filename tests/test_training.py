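import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from retrorank.models import FFEBM, FFEBMConfig
from retrorank.featurization import FingerprintConfig
from retrorank.reaction_io import Candidate, CandidateSet, Provenance, \
    canonical_reactant_set_key
from retrorank.training import (
    Adam,
    FeatureCache,
    TrainConfig,
    assemble_candidates,
    batch_loss,
    batch_loss_and_grad,
    candidate_energies,
    pool_multi_proposer,
    train_ebm,
)


def make_candidate_set(n, true_at=None, proposer="A", product="CCOC(C)=O"):
    """n distinct single-reactant candidates; optionally the truth at a
    given 1-based rank (truth = ethanol + acetic acid)."""
    cs = CandidateSet(product_key=product, product_smiles=product)
    decoys = iter(
        ["CC(=O)Cl.OCC", "CC(=O)OC.O", "CC(=O)O.OC", "CC(=O)Br.OCC",
         "CC(=O)O.OCCC", "CC(=O)I.OCC", "CC(=O)F.OCC", "OCC.OC(=O)CC"]
    )
    for rank in range(1, n + 1):
        smi = "CC(=O)O.OCC" if rank == true_at else next(decoys)
        cs.add(smi.split("."), Provenance(proposer, rank))
    cs.sort()
    if true_at is not None:
        cs.true_key = canonical_reactant_set_key(["CC(=O)O", "OCC"])
    return cs


TRUE_KEY = canonical_reactant_set_key(["CC(=O)O", "OCC"])


class TestAssembly:
    def test_truth_present_no_injection(self):
        cs = make_candidate_set(5, true_at=3)
        item = assemble_candidates(cs, TRUE_KEY, k=5, mode="train")
        assert len(item.candidates) == 5
        assert item.positive_index == 2
        assert not item.injected

    def test_truth_absent_appended_in_train_mode(self):
        cs = make_candidate_set(6, true_at=None)
        item = assemble_candidates(
            cs, TRUE_KEY, k=6, mode="train", true_reactants=("CC(=O)O", "OCC")
        )
        assert len(item.candidates) == 7
        assert item.positive_index == 6
        assert item.injected

    def test_eval_mode_never_injects(self):
        cs = make_candidate_set(6, true_at=None)
        item = assemble_candidates(cs, TRUE_KEY, k=6, mode="eval")
        assert len(item.candidates) == 6
        assert item.truth_absent and item.positive_index is None

    def test_truth_beyond_k_injected(self):
        cs = make_candidate_set(6, true_at=6)
        item = assemble_candidates(cs, TRUE_KEY, k=3, mode="train")
        assert len(item.candidates) == 4  # top-3 + injected truth
        assert item.positive_index == 3

    def test_size_is_min_k_available_plus_injection(self):
        for avail in (2, 5, 8):
            for k in (1, 3, 10):
                for true_at in (1, None):
                    cs = make_candidate_set(avail, true_at=true_at)
                    item = assemble_candidates(
                        cs, TRUE_KEY, k=k, mode="train",
                        true_reactants=("CC(=O)O", "OCC"),
                    )
                    expected = min(k, avail) + (
                        0 if (true_at is not None and true_at <= k) else 1
                    )
                    assert len(item.candidates) == expected

    def test_train_mode_without_truth_is_contract_error(self):
        cs = make_candidate_set(3)
        with pytest.raises(ValueError):
            assemble_candidates(cs, None, k=3, mode="train")


class TestBatchLoss:
    def test_uniform_energies_log_k(self):
        for k in (2, 5, 17):
            assert batch_loss(np.zeros(k), 0) == pytest.approx(
                math.log(k), abs=1e-12
            )

    def test_hand_evaluated_two_candidate_case(self):
        loss = batch_loss(np.array([0.0, math.log(3)]), 0)
        assert loss == pytest.approx(math.log(4 / 3), abs=1e-12)

    @given(
        st.integers(2, 8),
        st.floats(-100.0, 100.0, allow_nan=False),
        st.integers(0, 10**6),
    )
    def test_shift_invariance(self, k, c, seed):
        rng = np.random.default_rng(seed)
        e = rng.normal(scale=5.0, size=k)
        assert batch_loss(e + c, 1) == pytest.approx(
            batch_loss(e, 1), abs=1e-9
        )

    def test_monotone_in_energy_gaps(self):
        e = np.array([1.0, 2.0, 3.0])
        base = batch_loss(e, 0)
        assert batch_loss(np.array([0.5, 2.0, 3.0]), 0) < base  # E_pos down
        assert batch_loss(np.array([1.0, 2.5, 3.0]), 0) < base  # E_neg up

    def test_gradient_matches_softmax_identity(self):
        rng = np.random.default_rng(0)
        e = rng.normal(size=6)
        _, grad = batch_loss_and_grad(e, 2)
        p = np.exp(-e) / np.exp(-e).sum()
        expected = -p
        expected[2] += 1.0
        np.testing.assert_allclose(grad, expected, atol=1e-12)
        assert grad.sum() == pytest.approx(0.0, abs=1e-12)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            batch_loss(np.array([1.0]), 0)
        with pytest.raises(FloatingPointError):
            batch_loss(np.array([np.nan, 0.0]), 0)


class TestPooling:
    def test_disjoint_candidates_concatenate(self):
        a = {"CCOC(C)=O": make_candidate_set(3, proposer="A")}
        b = CandidateSet(product_key="CCOC(C)=O", product_smiles="CCOC(C)=O")
        b.add(["CCBr", "OCC"], Provenance("B", 1))
        b.add(["CCCl", "OCC"], Provenance("B", 2))
        pooled = pool_multi_proposer([a, {"CCOC(C)=O": b}], per_model_k=50)
        assert len(pooled["CCOC(C)=O"].candidates) == 5

    def test_shared_candidate_merges_provenance(self):
        a = {"CCOC(C)=O": make_candidate_set(2, true_at=1, proposer="A")}
        b = {"CCOC(C)=O": make_candidate_set(2, true_at=1, proposer="B")}
        pooled = pool_multi_proposer([a, b], per_model_k=50)
        top = pooled["CCOC(C)=O"].candidates[0]
        assert {p.proposer for p in top.provenance} == {"A", "B"}

    def test_per_model_truncation(self):
        a = {"CCOC(C)=O": make_candidate_set(6, proposer="A")}
        pooled = pool_multi_proposer([a], per_model_k=2)
        assert len(pooled["CCOC(C)=O"].candidates) == 2

    def test_empty_second_table_is_identity(self):
        a = {"CCOC(C)=O": make_candidate_set(4, proposer="A")}
        pooled = pool_multi_proposer([a, {}], per_model_k=3)
        assert [c.key for c in pooled["CCOC(C)=O"].candidates] == \
            [c.key for c in a["CCOC(C)=O"].candidates[:3]]


class TestOptimization:
    def _toy_model(self):
        return FFEBM(
            FFEBMConfig(fingerprint=FingerprintConfig(length=256),
                        embed_dim=8, hidden_dim=8, out_hidden_dim=8),
            seed=0,
        )

    def test_one_adam_step_reduces_energy_gap(self):
        model = self._toy_model()
        cache = FeatureCache(fingerprint=model.config.fingerprint)
        cs = make_candidate_set(2, true_at=1)
        item_cands = cs.candidates

        def gap():
            e = candidate_energies(model, cache, cs.product_smiles, item_cands)
            return e, float(e.data[0] - e.data[1])

        e, before = gap()
        from retrorank.training import batch_loss_and_grad

        _, grad = batch_loss_and_grad(e.data, 0)
        opt = Adam(model.parameters(), lr=1e-2)
        e.backward(seed=grad)
        opt.step()
        _, after = gap()
        assert after < before  # E_pos - E_neg shrinks

    def test_overfit_single_product_loss_decreases_monotonically(self):
        from retrorank.reaction_io import Reaction

        model = self._toy_model()
        rxn = Reaction("r0", "CCOC(C)=O", ("CC(=O)O", "OCC"))
        table = {rxn.product_key: make_candidate_set(2, true_at=1)}
        cfg = TrainConfig(k_train=2, k_eval=2, epochs=40, batch_size=1,
                          learning_rate=1e-2, seed=0,
                          validation_fraction=0.0)
        model, history = train_ebm([rxn], table, cfg, model=model,
                                   val_reactions=[])
        losses = [h["train_loss"] for h in history]
        assert all(b < a for a, b in zip(losses, losses[1:]))
        assert losses[-1] < 0.1

    def test_same_seed_identical_history(self, reactions, proposal_table):
        def run():
            model = self._toy_model()
            cfg = TrainConfig(k_train=6, k_eval=6, epochs=2, batch_size=8,
                              seed=11)
            return train_ebm(reactions, proposal_table, cfg, model=model)[1]

        assert run() == run()
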