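"""Jaccard-emission HMMs: observation building, counts, forward, classify."""

import itertools

import numpy as np
import pytest

from cosparse_eeg import hmm_classifier as hc


class TestObservationVector:
    def test_column_means(self):
        M = hc.TermFeatureMatrix(M=[[1.0, 2.0], [3.0, 4.0]])
        obs = hc.build_observation_vector(M)
        np.testing.assert_array_equal(obs.w, [2.0, 3.0])

    def test_single_row_identity(self):
        M = hc.TermFeatureMatrix(M=[[5.0, -1.0, 2.0]])
        np.testing.assert_array_equal(hc.build_observation_vector(M).w,
                                      [5.0, -1.0, 2.0])

    def test_matches_loop_mean_oracle(self, rng):
        M = rng.standard_normal((5, 3))
        obs = hc.build_observation_vector(hc.TermFeatureMatrix(M=M))
        expect = [sum(M[j, l] for j in range(5)) / 5 for l in range(3)]
        np.testing.assert_allclose(obs.w, expect, atol=1e-12)

    def test_terms_from_code_partitions_everything(self, rng):
        code = rng.standard_normal(10)
        tm = hc.terms_from_code(code, h=3, extractors=("mean",))
        # 3 terms: 3 + 3 + 4 entries; overall mean preserved via weighted sum
        assert tm.M.shape == (3, 1)
        np.testing.assert_allclose(
            tm.M[:, 0],
            [code[:3].mean(), code[3:6].mean(), code[6:].mean()])

    def test_observation_matrix_consistent_with_per_sample(self, rng):
        codes = rng.standard_normal((16, 7))
        batch = hc.observation_matrix(codes, h=4)
        single = np.vstack([
            hc.build_observation_vector(hc.terms_from_code(codes[:, i], 4)).w
            for i in range(7)])
        np.testing.assert_allclose(batch, single, atol=1e-12)


class TestTransitions:
    def test_successor_case(self):
        assert hc.transition_prob(3, 2, n_states=4) == 1.0

    def test_self_loop_forbidden(self):
        assert hc.transition_prob(2, 2, n_states=4) == 0.0

    def test_each_nonfinal_state_has_one_successor(self):
        n = 5
        for m in range(1, n):
            total = sum(hc.transition_prob(p, m, n) for p in range(1, n + 1))
            assert total == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hc.transition_prob(0, 1, n_states=3)


class TestAssociation:
    def test_first_inequality(self):
        assert hc.is_associated(1.0, 1.05, 9.0, 0.1)

    def test_neither_holds(self):
        assert not hc.is_associated(1.0, 5.0, 5.0, 0.1)

    def test_boundary_equality_with_zero_delta(self):
        assert hc.is_associated(3.0, 7.0, 3.0, 0.0)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            hc.is_associated(0.0, 0.0, 0.0, -0.1)


class TestFitAndEmission:
    def test_single_sample_both_associated(self):
        model = hc.FeatureHMM(family="f", V=np.array([1.0]),
                              delta=np.array([0.5]))
        hc.fit_model(model, np.array([[1.1]]), reference=np.array([1.0]))
        np.testing.assert_array_equal(model.counts, [[1, 0, 0]])
        assert hc.emission_prob(model, 1) == 1.0

    def test_two_samples_hand_count(self):
        # reference w = 0, V = 1, delta = 0.3
        # sample 0.1: near w only; sample 0.9: near V only; sample 1.05 would
        # be... choose: samples {0.15, 0.9}: first -> H01, second -> H10
        # and add 0.5? With delta 0.6: 0.15 near both? |0.15-0|=.15<=.6,
        # |0.15-1|=.85>no; keep simple: samples both-associated and V-only.
        model = hc.FeatureHMM(family="f", V=np.array([1.0]),
                              delta=np.array([0.6]))
        train = np.array([[0.5], [1.5]])   # 0.5 near w=0? |0.5|<=0.6 yes,
        # |0.5-1|=0.5<=0.6 yes -> both; 1.5: |1.5|>0.6, |1.5-1|=0.5 -> V only
        hc.fit_model(model, train, reference=np.array([0.0]))
        np.testing.assert_array_equal(model.counts, [[1, 1, 0]])
        assert hc.emission_prob(model, 1) == 0.5

    def test_no_associations_flagged_and_scoring_raises(self):
        model = hc.FeatureHMM(family="f", V=np.array([100.0]),
                              delta=np.array([0.1]))
        hc.fit_model(model, np.array([[0.0], [1.0]]),
                     reference=np.array([50.0]))
        np.testing.assert_array_equal(model.counts, [[0, 0, 0]])
        with pytest.raises(ZeroDivisionError, match="state 1"):
            hc.emission_prob(model, 1)

    def test_empty_training_set_rejected(self):
        model = hc.FeatureHMM(family="f", V=np.array([0.0]),
                              delta=np.array([1.0]))
        with pytest.raises(ValueError):
            hc.fit_model(model, np.empty((0, 1)))

    @pytest.mark.parametrize("counts,expected", [
        ((2, 1, 1), 0.5),
        ((5, 0, 0), 1.0),
        ((0, 3, 2), 0.0),
    ])
    def test_jaccard_formula(self, counts, expected):
        model = hc.FeatureHMM(family="f", V=np.array([0.0]),
                              delta=np.array([1.0]))
        model.counts = np.array([counts])
        model.trained = True
        assert hc.emission_prob(model, 1) == expected

    def test_adding_both_associated_sample_never_decreases_emission(self, rng):
        V = np.array([0.0, 1.0])
        delta = np.array([0.5, 0.5])
        base = rng.standard_normal((20, 2))
        model = hc.FeatureHMM(family="f", V=V, delta=delta)
        hc.fit_model(model, base, reference=V)
        before = [model.counts[l, 0] / max(model.counts[l].sum(), 1)
                  for l in range(2)]
        # a sample exactly at V is associated with both (reference = V)
        hc.fit_model(model, np.vstack([base, V]), reference=V)
        after = [model.counts[l, 0] / max(model.counts[l].sum(), 1)
                 for l in range(2)]
        assert all(a >= b for a, b in zip(after, before))


def forward_oracle(emissions: np.ndarray) -> float:
    """Exhaustive path enumeration with the deterministic chain.

    Initial distribution: mass 1 on state 1; transition p<-m is 1 iff
    p == m+1.  Sums the probability of every state path of length n.
    """
    n = len(emissions)
    total = 0.0
    for path in itertools.product(range(1, n + 1), repeat=n):
        prob = 1.0 if path[0] == 1 else 0.0
        for step in range(1, n):
            prob *= 1.0 if path[step] == path[step - 1] + 1 else 0.0
        for step in range(n):
            prob *= emissions[path[step] - 1]
        total += prob
    return total


class TestForward:
    def _model_with_obs(self, rng, n):
        """A trained model plus an observation; returns both and the
        per-state emissions recomputed independently."""
        train = rng.standard_normal((30, n))
        V = train.mean(axis=0) + rng.uniform(-0.5, 0.5, n)
        delta = rng.uniform(0.2, 1.5, n)
        model = hc.FeatureHMM(family="f", V=V, delta=delta)
        hc.fit_model(model, train)
        w = rng.standard_normal(n)
        em = np.zeros(n)
        for l in range(n):
            A = np.abs(train[:, l] - w[l]) <= delta[l]
            B = np.abs(train[:, l] - V[l]) <= delta[l]
            union = np.count_nonzero(A | B)
            em[l] = np.count_nonzero(A & B) / union if union else 0.0
        return model, hc.ObservationVector(w=w, family="f"), em

    def test_all_unit_emissions_give_one(self):
        model = hc.FeatureHMM(family="f", V=np.zeros(3),
                              delta=np.full(3, 10.0))
        hc.fit_model(model, np.zeros((4, 3)))
        obs = hc.ObservationVector(w=np.zeros(3), family="f")
        assert hc.forward_probability(model, obs) == pytest.approx(1.0)

    def test_product_of_emissions(self, rng):
        model, obs, em = self._model_with_obs(rng, 2)
        assert hc.forward_probability(model, obs) == pytest.approx(
            np.prod(em), abs=1e-12)

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_matches_path_enumeration_oracle(self, n):
        r = np.random.default_rng(100 + n)
        for _ in range(25):
            model, obs, em = TestForward()._model_with_obs(r, n)
            assert hc.forward_probability(model, obs) == pytest.approx(
                forward_oracle(em), abs=1e-12)

    def test_untrained_model_rejected(self):
        model = hc.FeatureHMM(family="f", V=np.zeros(2), delta=np.ones(2))
        with pytest.raises(ValueError, match="not trained"):
            hc.forward_probability(model, hc.ObservationVector(w=np.zeros(2)))


class TestClassify:
    def _trained(self, family, center, rng, n=2, spread=0.3):
        train = center + spread * rng.standard_normal((40, n))
        return hc.initialize_model(family, train)

    def test_argmax_family(self, rng):
        a = self._trained("a", np.array([0.0, 0.0]), rng)
        b = self._trained("b", np.array([5.0, 5.0]), rng)
        obs = hc.ObservationVector(w=np.array([0.05, -0.02]))
        assert hc.classify([a, b], obs) == "a"
        obs2 = hc.ObservationVector(w=np.array([5.1, 4.9]))
        assert hc.classify([a, b], obs2) == "b"

    def test_exact_tie_lexicographic(self):
        train = np.zeros((5, 1))
        a = hc.FeatureHMM(family="b_family", V=np.zeros(1), delta=np.ones(1))
        b = hc.FeatureHMM(family="a_family", V=np.zeros(1), delta=np.ones(1))
        hc.fit_model(a, train)
        hc.fit_model(b, train)
        obs = hc.ObservationVector(w=np.zeros(1))
        assert hc.classify([a, b], obs) == "a_family"

    def test_all_zero_uses_fallback(self, rng):
        a = self._trained("a", np.array([0.0]), rng, n=1, spread=0.1)
        b = self._trained("b", np.array([1.0]), rng, n=1, spread=0.1)
        far = hc.ObservationVector(w=np.array([500.0]))
        assert hc.classify([a, b], far, fallback="b") == "b"

    def test_matches_max_scan_oracle(self, rng):
        models = [self._trained(f"f{i}", np.array([float(i), float(i)]), rng,
                                spread=0.4)
                  for i in range(4)]
        for _ in range(10):
            w = rng.uniform(-0.5, 3.5, 2)
            obs = hc.ObservationVector(w=w)
            probs = {m.family: hc.forward_probability(m, obs) for m in models}
            got = hc.classify(models, obs)
            assert probs[got] == max(probs.values())

    def test_batch_agrees_with_scalar_path(self, rng):
        a = self._trained("a", np.array([0.0, 0.0]), rng)
        b = self._trained("b", np.array([2.0, 2.0]), rng)
        W = rng.uniform(-1, 3, size=(30, 2))
        batch = hc.classify_batch([a, b], W)
        scalar = [hc.classify([a, b], hc.ObservationVector(w=w)) for w in W]
        assert list(batch) == scalar

    def test_needs_two_models(self, rng):
        a = self._trained("a", np.array([0.0]), rng, n=1)
        with pytest.raises(ValueError):
            hc.classify([a], hc.ObservationVector(w=np.zeros(1)))
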