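"""Info score, true r², MAF, and the evaluation harnesses."""

import numpy as np
import pandas as pd
import pytest
from panelimpute import (
    HMMParams,
    SelectionSpec,
    impute_haploid,
    info_score,
    leave_one_out_eval,
    maf_of,
    pseudo_gwas_eval,
    true_r2,
    uniform_map,
)
from panelimpute.evaluate import compare_configs
from panelimpute.select import select_references
from panelimpute.simulate import SimConfig, make_scenario

from conftest import make_panel


class TestInfoScore:
    def test_certain_polymorphic_genotypes_score_one(self):
        probs = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
        assert info_score(probs) == pytest.approx(1.0)

    def test_maximally_uncertain_genotypes_score_zero(self):
        probs = np.tile([0.25, 0.5, 0.25], (8, 1))
        assert info_score(probs) == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_three_sample_instance(self):
        probs = np.array([[0.05, 0.8, 0.15], [0.0, 1.0, 0.0], [0.8, 0.2, 0.0]])
        e = np.array([1.1, 1.0, 0.2])  # p1 + 2*p2 per sample
        f = np.array([1.4, 1.0, 0.2])  # p1 + 4*p2 per sample
        theta = e.sum() / 6.0
        expected = 1.0 - (f - e**2).sum() / (6.0 * theta * (1 - theta))
        assert info_score(probs) == pytest.approx(expected, abs=1e-12)

    def test_monomorphic_scores_one(self):
        probs = np.tile([1.0, 0.0, 0.0], (5, 1))
        assert info_score(probs) == 1.0

    def test_allele_label_symmetry(self):
        rng = np.random.default_rng(2)
        raw = rng.random((20, 3))
        probs = raw / raw.sum(axis=1, keepdims=True)
        assert info_score(probs) == pytest.approx(
            info_score(probs[:, ::-1]), abs=1e-12
        )

    def test_malformed_triples_are_an_error(self):
        with pytest.raises(ValueError):
            info_score(np.array([[0.5, 0.5, 0.5]]))


class TestTrueR2:
    def test_exact_dosages_score_one(self):
        truth = np.array([0, 1, 2, 1])
        assert true_r2(truth.astype(float), truth) == pytest.approx(1.0)

    def test_sign_invariance(self):
        truth = np.array([0, 1, 2, 1])
        assert true_r2(2.0 - truth, truth) == pytest.approx(1.0)

    def test_worked_example_matches_covariance_formula(self):
        truth = np.array([0, 1, 2, 1], dtype=float)
        dosages = np.array([0.1, 0.9, 1.8, 1.2])
        expected = float(np.corrcoef(dosages, truth)[0, 1] ** 2)
        assert true_r2(dosages, truth) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_is_undefined(self):
        assert np.isnan(true_r2(np.array([1.0, 1.0, 1.0]), np.array([0, 1, 2])))
        assert np.isnan(true_r2(np.array([0.1, 0.5, 0.9]), np.array([1, 1, 1])))

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            true_r2(np.array([1.0, 2.0]), np.array([1]))


class TestMafOf:
    def test_folds_to_minor_frequency(self):
        assert maf_of(np.array([1] * 7 + [0] * 3)) == pytest.approx(0.3)

    def test_monomorphic_is_zero(self):
        assert maf_of(np.zeros(10)) == 0.0

    def test_count_arithmetic(self):
        v = np.zeros(200)
        v[0] = 1
        assert maf_of(v) == pytest.approx(0.005)


class TestLeaveOneOut:
    @staticmethod
    def _twin_panel():
        """Every sample has an identical twin elsewhere in the panel."""
        rng = np.random.default_rng(4)
        base = rng.integers(0, 2, (8, 120), dtype=np.uint8)
        alleles = np.vstack([base, base])  # 8 samples, twinned
        keep = (alleles.mean(axis=0) > 0) & (alleles.mean(axis=0) < 1)
        alleles = alleles[:, keep]
        return make_panel(alleles, positions=np.arange(1, keep.sum() + 1) * 800)

    def test_twin_copy_limit(self):
        panel = self._twin_panel()
        typed = np.zeros(panel.n_sites, dtype=bool)
        typed[::3] = True
        gmap = uniform_map((0, 900 * panel.n_sites))
        report = leave_one_out_eval(
            panel, typed, gmap, HMMParams(ne=0.01, epsilon=1e-6)
        )
        means = report.mean_true_r2_by_bin()
        assert (means.dropna() > 0.99).all()

    def test_empty_typed_mask_is_an_error(self):
        panel = self._twin_panel()
        with pytest.raises(ValueError):
            leave_one_out_eval(
                panel, np.zeros(panel.n_sites, dtype=bool), uniform_map((0, 1000))
            )

    def test_zero_eval_samples_is_an_error(self):
        panel = self._twin_panel()
        typed = np.zeros(panel.n_sites, dtype=bool)
        typed[::3] = True
        with pytest.raises(ValueError):
            leave_one_out_eval(
                panel, typed, uniform_map((0, 1000)), n_eval_samples=0
            )

    def test_matches_independently_scripted_loop(self, toy_scenario):
        """The harness agrees with a plainly written leave-one-out loop
        built directly on the haploid imputation primitive."""
        scen = toy_scenario
        panel = scen.ref_a
        typed = np.isin(
            panel.positions, scen.study_truth.positions[scen.typed_mask]
        )
        gmap = scen.gmap
        params = HMMParams()
        spec = SelectionSpec("all")
        report = leave_one_out_eval(
            panel, typed, gmap, params, spec, n_eval_samples=4, seed=9
        )
        # independent reference loop (same sample subset, same seed logic)
        rng = np.random.default_rng(9)
        samples = np.sort(
            rng.choice(np.arange(panel.n_samples), size=4, replace=False)
        )
        typed_cols = np.flatnonzero(typed)
        j = int(np.flatnonzero(~typed)[5])
        dosages = []
        for sample in samples:
            keep = np.ones(panel.n_haplotypes, dtype=bool)
            keep[2 * sample : 2 * sample + 2] = False
            ref = panel.subset_haplotypes(keep)
            post = [
                impute_haploid(
                    panel.alleles[h, typed_cols], ref, typed, gmap, params,
                    select_references(
                        panel.alleles[h, typed_cols], ref.alleles[:, typed_cols], spec
                    ),
                )
                for h in (2 * sample, 2 * sample + 1)
            ]
            dosages.append(float(post[0][j] + post[1][j]))
        truth = panel.genotypes()[samples, j]
        expected = true_r2(np.array(dosages), truth)
        got = float(report.sites.loc[j, "true_r2"])
        assert got == pytest.approx(expected, abs=1e-9)


class TestPseudoGwas:
    def test_fully_typed_study_reproduces_truth_at_typed_sites(self, toy_scenario):
        scen = toy_scenario
        shared = np.isin(
            scen.study_truth.positions, scen.ref_a.positions
        )
        study = scen.study_truth.subset_sites(shared)
        typed_mask = np.ones(study.n_sites, dtype=bool)
        ref = scen.ref_a.subset_sites(
            np.isin(scen.ref_a.positions, study.positions)
        )
        report = pseudo_gwas_eval(study, typed_mask, ref, scen.gmap)
        typed_r2 = report.sites.loc[report.sites["typed"], "true_r2"].dropna()
        # typed-site posteriors are copying mixtures, not raw observations:
        # agreement is near-perfect except at rare alleles the panel lacks,
        # which the model shrinks toward the reference consensus
        assert typed_r2.mean() > 0.95
        assert typed_r2.median() > 0.99

    def test_generating_panel_outperforms_its_strict_subset(self):
        """Imputing from the full generating panel is at least as accurate,
        averaged over seeds, as imputing from a half-size subset."""
        full_scores, sub_scores = [], []
        for seed in range(10):
            cfg = SimConfig(
                n_founders=12, n_sites=250, region_bp=500_000,
                n_ref_a=60, n_ref_b=2, n_study=30,
                typed_fraction=0.3, private_fraction=0.0, seed=seed,
            )
            scen = make_scenario(cfg)
            full = pseudo_gwas_eval(
                scen.study_truth, scen.typed_mask, scen.ref_a, scen.gmap
            )
            sub_panel = scen.ref_a.subset_haplotypes(np.arange(20))
            sub = pseudo_gwas_eval(
                scen.study_truth, scen.typed_mask, sub_panel, scen.gmap
            )
            full_scores.append(full.mean_true_r2(0.5))
            sub_scores.append(sub.mean_true_r2(0.5))
        assert np.mean(full_scores) >= np.mean(sub_scores)

    def test_missing_typed_site_in_reference_is_an_error(self, toy_scenario):
        scen = toy_scenario
        # drop one typed site from the reference
        typed_pos = scen.study_truth.positions[scen.typed_mask]
        keep = scen.ref_a.positions != typed_pos[0]
        ref = scen.ref_a.subset_sites(keep)
        with pytest.raises(ValueError, match=str(typed_pos[0])):
            pseudo_gwas_eval(
                scen.study_truth, scen.typed_mask, ref, scen.gmap
            )

    def test_report_conserves_site_counts(self, toy_scenario):
        scen = toy_scenario
        report = pseudo_gwas_eval(
            scen.study_truth, scen.typed_mask, scen.ref_a, scen.gmap
        )
        report.validate()
        counts = report.counts_by_maf_info(maf_source="maf")
        in_range = report.sites[
            (report.sites["maf"] > 0) & (report.sites["maf"] <= 0.5)
        ]
        assert counts.to_numpy().sum() == len(in_range)


class TestCompareConfigs:
    def test_identical_configs_give_identical_reports(self, toy_scenario):
        scen = toy_scenario
        spec = SelectionSpec("hamming", k=10)
        reports, summary = compare_configs(
            scen,
            [("x", scen.ref_a, spec), ("y", scen.ref_a, spec)],
        )
        pd.testing.assert_frame_equal(reports["x"].sites, reports["y"].sites)

    def test_single_config_is_an_error(self, toy_scenario):
        with pytest.raises(ValueError):
            compare_configs(
                toy_scenario,
                [("x", toy_scenario.ref_a, SelectionSpec("all"))],
            )
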