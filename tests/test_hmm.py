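"""Li-Stephens HMM: parameters, forward-backward, haploid/diploid imputation."""

import numpy as np
import pytest

from panelimpute import (
    HMMParams,
    best_guess,
    emission_epsilon,
    forward_backward,
    impute_diploid,
    impute_haploid,
    theta_watterson,
    transition,
    uniform_map,
)

from _oracles import enumerate_posteriors, posterior_alt_mixture
from conftest import make_panel


class TestParameters:
    @pytest.mark.parametrize("k,expected", [(2, 1.0), (3, 2.0 / 3.0)])
    def test_watterson_theta_closed_form(self, k, expected):
        assert theta_watterson(k) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("k,expected", [(2, 1.0 / 6.0), (3, 1.0 / 11.0)])
    def test_emission_epsilon_closed_form(self, k, expected):
        assert emission_epsilon(k) == pytest.approx(expected, abs=1e-12)

    def test_single_reference_is_an_error(self):
        with pytest.raises(ValueError, match="two reference"):
            theta_watterson(1)
        with pytest.raises(ValueError):
            emission_epsilon(1)

    def test_epsilon_strictly_decreases_with_panel_size(self):
        eps = [emission_epsilon(k) for k in range(2, 1001)]
        assert all(a > b for a, b in zip(eps, eps[1:]))

    def test_transition_at_zero_distance(self):
        p_nr, p_each = transition(0.0, 20_000, 100)
        assert p_nr == 1.0
        assert p_each == 0.0

    def test_transition_closed_form(self):
        # rho = 4 * 20000 * 0.0001 Morgans = 8; p_norecomb = exp(-8/100)
        p_nr, p_each = transition(0.01, 20_000, 100)
        assert p_nr == pytest.approx(np.exp(-0.08), rel=1e-12)
        assert 100 * p_each == pytest.approx(1 - np.exp(-0.08), rel=1e-12)

    def test_transition_limit_is_uniform(self):
        p_nr, p_each = transition(1e6, 20_000, 50)
        assert p_nr == pytest.approx(0.0, abs=1e-12)
        assert p_each == pytest.approx(1.0 / 50)

    def test_negative_distance_is_an_error(self):
        with pytest.raises(ValueError):
            transition(-0.1, 20_000, 10)


class TestForwardBackward:
    def test_identical_reference_dominates(self):
        obs = np.array([0, 1, 1])
        refs = np.array([[0, 1, 1], [1, 0, 0]])
        gamma = forward_backward(obs, refs, np.array([0.05, 0.05]))
        assert (gamma[:, 0] > 0.5).all()

    def test_matches_exhaustive_path_enumeration(self):
        rng = np.random.default_rng(123)
        for _ in range(30):
            k = int(rng.integers(2, 4))
            t = int(rng.integers(1, 5))
            refs = rng.integers(0, 2, (k, t))
            obs = rng.integers(0, 2, t)
            dists = rng.random(max(t - 1, 0)) * 0.05
            gamma = forward_backward(obs, refs, dists, HMMParams(ne=20_000))
            oracle = enumerate_posteriors(obs, refs, dists, ne=20_000)
            np.testing.assert_allclose(gamma, oracle, atol=1e-10)

    def test_uninformative_emissions_give_uniform_posterior(self):
        obs = np.array([0, 1, 0, 1])
        rng = np.random.default_rng(3)
        refs = rng.integers(0, 2, (3, 4))
        gamma = forward_backward(
            obs, refs, np.full(3, 0.01), HMMParams(epsilon=0.499999)
        )
        np.testing.assert_allclose(gamma, 1.0 / 3.0, atol=1e-5)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(17)
        refs = rng.integers(0, 2, (5, 40))
        obs = rng.integers(0, 2, 40)
        gamma = forward_backward(obs, refs, rng.random(39) * 0.1)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-9)
        assert (gamma >= 0).all()

    def test_reversal_symmetry(self):
        """Reversing the legend and distances reverses the posterior."""
        rng = np.random.default_rng(29)
        refs = rng.integers(0, 2, (4, 25))
        obs = rng.integers(0, 2, 25)
        dists = rng.random(24) * 0.2
        fwd = forward_backward(obs, refs, dists)
        rev = forward_backward(obs[::-1], refs[:, ::-1], dists[::-1])
        np.testing.assert_allclose(fwd, rev[::-1], atol=1e-9)

    def test_dimension_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            forward_backward(np.zeros(3), np.zeros((2, 4), dtype=int), np.zeros(3))
        with pytest.raises(ValueError):
            forward_backward(np.zeros(4), np.zeros((2, 4), dtype=int), np.zeros(2))


class TestImputeHaploid:
    def _toy(self, seed=0, n_refs=6, n_sites=30):
        rng = np.random.default_rng(seed)
        alleles = rng.integers(0, 2, (n_refs, n_sites), dtype=np.uint8)
        panel = make_panel(alleles, positions=np.arange(1, n_sites + 1) * 1000)
        gmap = uniform_map((0, (n_sites + 1) * 1000))
        typed = np.zeros(n_sites, dtype=bool)
        typed[::3] = True
        return panel, gmap, typed

    def test_perfect_copy_limit(self):
        """With negligible copying error and recombination, the posterior
        locks onto the one reference matching every typed allele."""
        panel, gmap, typed = self._toy(seed=1)
        study = panel.alleles[2, typed]
        p = impute_haploid(
            study, panel, typed, gmap, HMMParams(ne=0.01, epsilon=1e-6)
        )
        np.testing.assert_allclose(p, panel.alleles[2], atol=1e-3)

    def test_unanimous_alt_gives_one_minus_epsilon_exactly(self):
        panel, gmap, typed = self._toy(seed=2)
        j = int(np.flatnonzero(~typed)[0])
        panel.alleles[:, j] = 1
        eps = 0.01
        study = panel.alleles[0, typed]
        p = impute_haploid(study, panel, typed, gmap, HMMParams(epsilon=eps))
        assert p[j] == pytest.approx(1.0 - eps, abs=1e-12)

    def test_typed_site_posterior_matches_path_oracle(self):
        """2-reference 3-typed-site instance: typed-site P(ALT) equals the
        emission mixture under exhaustively enumerated posteriors."""
        alleles = np.array([[0, 1, 1, 0, 1], [1, 1, 0, 0, 0]], dtype=np.uint8)
        panel = make_panel(alleles, positions=[1000, 2000, 3000, 4000, 5000])
        gmap = uniform_map((0, 6000))
        typed = np.array([True, False, True, False, True])
        study = np.array([0, 1, 1])
        eps = 0.05
        p = impute_haploid(study, panel, typed, gmap, HMMParams(epsilon=eps))
        refs_typed = alleles[:, typed]
        cm = gmap.cm_at(panel.positions[typed])
        oracle_gamma = enumerate_posteriors(
            study, refs_typed, np.diff(cm), ne=20_000, epsilon=eps
        )
        for t_i, j in enumerate(np.flatnonzero(typed)):
            expected = posterior_alt_mixture(oracle_gamma[t_i], alleles[:, j], eps)
            assert p[j] == pytest.approx(expected, abs=1e-10)

    def test_selection_restricts_the_conditioning_set(self):
        panel, gmap, typed = self._toy(seed=3)
        study = panel.alleles[0, typed]
        full = impute_haploid(study, panel, typed, gmap)
        sub = impute_haploid(study, panel, typed, gmap, selection=np.array([0, 1]))
        assert not np.allclose(full, sub)

    def test_missing_typed_sites_are_an_error(self):
        panel, gmap, typed = self._toy()
        with pytest.raises(ValueError):
            impute_haploid(np.zeros(3), panel, typed, gmap)  # wrong length

    def test_monotone_information_loss(self):
        """A study haplotype with one flipped typed allele is imputed at
        least as well, on average, as the same haplotype with two flips."""
        diffs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            panel, gmap, typed = self._toy(seed=seed + 100, n_refs=8, n_sites=36)
            source = 3
            study1 = panel.alleles[source, typed].copy()
            study2 = study1.copy()
            flip = rng.choice(study1.size, size=2, replace=False)
            study1[flip[0]] ^= 1
            study2[flip] ^= 1
            truth = panel.alleles[source]
            untyped = ~typed
            p1 = impute_haploid(study1, panel, typed, gmap)
            p2 = impute_haploid(study2, panel, typed, gmap)
            acc1 = np.where(truth[untyped] == 1, p1[untyped], 1 - p1[untyped]).mean()
            acc2 = np.where(truth[untyped] == 1, p2[untyped], 1 - p2[untyped]).mean()
            diffs.append(acc1 - acc2)
        assert np.mean(diffs) >= 0


class TestDiploidCalls:
    def test_certain_homozygote(self):
        calls = impute_diploid(np.array([0.0]), np.array([0.0]))
        assert (calls.p0[0], calls.p1[0], calls.p2[0]) == (1.0, 0.0, 0.0)
        assert calls.dosage[0] == 0.0

    def test_independent_halves(self):
        calls = impute_diploid(np.array([0.5]), np.array([0.5]))
        assert calls.p0[0] == pytest.approx(0.25)
        assert calls.p1[0] == pytest.approx(0.5)
        assert calls.p2[0] == pytest.approx(0.25)
        assert calls.dosage[0] == pytest.approx(1.0)

    def test_worked_example(self):
        calls = impute_diploid(np.array([0.1]), np.array([0.7]))
        assert calls.p2[0] == pytest.approx(0.07)
        assert calls.p0[0] == pytest.approx(0.27)
        assert calls.p1[0] == pytest.approx(0.66)
        assert calls.dosage[0] == pytest.approx(0.8)

    def test_triples_sum_to_one_and_dosage_in_range(self):
        rng = np.random.default_rng(5)
        a, b = rng.random(200), rng.random(200)
        calls = impute_diploid(a, b)
        np.testing.assert_allclose(calls.p0 + calls.p1 + calls.p2, 1.0, atol=1e-9)
        assert ((calls.dosage >= 0) & (calls.dosage <= 2)).all()
        np.testing.assert_allclose(calls.dosage, a + b, atol=1e-12)

    def test_out_of_range_input_is_an_error(self):
        with pytest.raises(ValueError):
            impute_diploid(np.array([1.2]), np.array([0.5]))


class TestBestGuess:
    @pytest.mark.parametrize("p,expected", [(0.9, 1), (0.1, 0), (0.5, 0)])
    def test_threshold_and_tie_rule(self, p, expected):
        assert best_guess(p) == expected

    def test_vectorized(self):
        out = best_guess(np.array([0.2, 0.5, 0.8]))
        assert out.tolist() == [0, 0, 1]
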