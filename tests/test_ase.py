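"""Allele-specific transcription statistics: fold deviations, the
mixed-model template contrast, nuisance ANOVAs and the per-locus report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caninascope.ase import (
    anova_nuisance_test,
    ase_report,
    benjamini_hochberg,
    fold_deviation,
    glm_template_test,
)
from caninascope.copy_number import CopyNumberCall
from caninascope.pyroseq_sim import (
    AssayNoise,
    ExperimentDesign,
    ExpressionProfile,
    SNPAssay,
    observations_to_frame,
    simulate_assay,
    simulate_experiment,
)

NOISE = AssayNoise(read_depth=500, rho=0.005)


def _design(gdna_mean, cdna_mean, rng, individuals=("i1", "i2", "i3"),
            n_g=2, n_c=3, noise=NOISE):
    assay = SNPAssay("a1", "L", 0, "G", frozenset({"A"}))
    rows = []
    for ind in individuals:
        rows += simulate_assay(gdna_mean, noise, n_g, rng, assay=assay,
                               template="gDNA", individual=ind)
        for stage in ("small", "large"):
            rows += simulate_assay(cdna_mean, noise, n_c, rng, assay=assay,
                                   template="cDNA", individual=ind, bud_stage=stage)
    return observations_to_frame(rows)


class TestFoldDeviation:
    def test_leafy3_two_point_three_fold_lower(self):
        fd = fold_deviation([0.174], 0.4, n_boot=0)
        assert fd.direction == "down"
        assert fd.reported_fold == pytest.approx(2.3, abs=0.01)

    def test_equal_means_fold_one(self):
        fd = fold_deviation([0.4, 0.4], 0.4)
        assert fd.fold == pytest.approx(1.0)
        assert fd.direction == "null"

    def test_cgapdh1_one_point_two_fold_higher(self):
        fd = fold_deviation([0.24], 0.2, n_boot=0)
        assert fd.direction == "up"
        assert fd.reported_fold == pytest.approx(1.2)

    def test_bootstrap_ci_brackets_point_estimate(self, rng):
        x = rng.normal(0.3, 0.02, size=12)
        fd = fold_deviation(x, 0.4, seed=1)
        assert fd.ci_low <= fd.fold <= fd.ci_high

    def test_bootstrap_is_seeded(self):
        x = [0.18, 0.2, 0.22, 0.17, 0.21, 0.19]
        a = fold_deviation(x, 0.2, seed=3)
        b = fold_deviation(x, 0.2, seed=3)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            fold_deviation([0.1], 0.0)


class TestGlmTemplateTest:
    def test_identical_templates_give_null_result(self):
        rows = []
        for ind in ("i1", "i2"):
            for t, stage in (("gDNA", "NA"), ("cDNA", "small")):
                for rep in (1, 2):
                    rows.append({"assay_id": "a", "locus": "L", "template": t,
                                 "individual": ind, "bud_stage": stage,
                                 "replicate": rep, "fraction": 0.4, "depth": None})
        p, effect = glm_template_test(pd.DataFrame(rows))
        assert p == 1.0
        assert effect == 0.0

    def test_invariant_to_individual_relabeling(self, rng):
        d = _design(0.4, 0.3, rng)
        p1, e1 = glm_template_test(d)
        relabeled = d.replace({"individual": {"i1": "zz", "i2": "aa", "i3": "mm"}})
        p2, e2 = glm_template_test(relabeled)
        assert p1 == pytest.approx(p2)
        assert e1 == pytest.approx(e2)

    def test_invariant_to_row_shuffling(self, rng):
        d = _design(0.4, 0.25, rng)
        p1, _ = glm_template_test(d)
        shuffled = d.sample(frac=1.0, random_state=5)
        p2, _ = glm_template_test(shuffled)
        assert p1 == pytest.approx(p2)

    def test_power_against_strong_shift(self):
        # the two-copy-allele shift (0.4 -> 0.174) should essentially
        # always be detected at the instrument's noise level
        rng = np.random.default_rng(21)
        rejections = sum(
            glm_template_test(_design(0.4, 0.174, rng))[0] < 0.05 for _ in range(100)
        )
        assert rejections >= 95

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(22)
        rejections = sum(
            glm_template_test(_design(0.4, 0.4, rng))[0] < 0.05 for _ in range(400)
        )
        assert 0.02 <= rejections / 400 <= 0.09

    def test_single_template_rejected(self, rng):
        d = _design(0.4, 0.4, rng)
        with pytest.raises(ValueError):
            glm_template_test(d[d["template"] == "cDNA"])

    def test_single_individual_falls_back_with_warning(self, rng):
        d = _design(0.4, 0.2, rng, individuals=("solo",))
        with pytest.warns(UserWarning, match="single individual"):
            p, effect = glm_template_test(d)
        assert 0 <= p <= 1
        assert effect < 0


class TestAnovaNuisance:
    def test_no_stage_effect_rarely_significant(self):
        rng = np.random.default_rng(31)
        n_sig = 0
        runs = 300
        for _ in range(runs):
            d = _design(0.4, 0.4, rng)
            n_sig += anova_nuisance_test(d, "bud_stage") < 0.05
        assert n_sig / runs <= 0.07  # mirrors the absence of a bud-age effect

    def test_planted_individual_offset_detected(self):
        rng = np.random.default_rng(32)
        sd = np.sqrt(0.4 * 0.6 * (1 + 499 * 0.005) / 500)
        n_sig = 0
        for _ in range(100):
            assay = SNPAssay("a1", "L", 0, "G", frozenset({"A"}))
            rows = []
            for j, ind in enumerate(("i1", "i2", "i3")):
                mean = 0.4 + (3 * sd if j == 0 else 0.0)
                rows += simulate_assay(mean, NOISE, 6, rng, assay=assay,
                                       template="cDNA", individual=ind,
                                       bud_stage="small")
            n_sig += anova_nuisance_test(observations_to_frame(rows), "individual") < 0.05
        assert n_sig >= 95

    def test_degenerate_zero_variance_flagged(self):
        rows = [{"assay_id": "a", "locus": "L", "template": "cDNA",
                 "individual": "i1", "bud_stage": s, "replicate": r,
                 "fraction": 0.4, "depth": None}
                for s in ("small", "large") for r in (1, 2)]
        with pytest.warns(UserWarning, match="zero variance"):
            p = anova_nuisance_test(pd.DataFrame(rows), "bud_stage")
        assert np.isnan(p)

    def test_single_level_rejected(self, rng):
        d = _design(0.4, 0.4, rng)
        with pytest.raises(ValueError):
            anova_nuisance_test(d[d["bud_stage"] == "small"], "bud_stage")


class TestBenjaminiHochberg:
    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20))
    def test_adjusted_never_below_raw_and_order_preserved(self, ps):
        adj = benjamini_hochberg(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestAseReport:
    def _calls_and_assays(self):
        copies = {"LEAFY-1": 1, "LEAFY-2": 1, "LEAFY-3": 2, "LEAFY-4": 1}
        assays = [
            SNPAssay("s1", "LEAFY", 0, "G", frozenset({"LEAFY-3"})),
            SNPAssay("s2", "LEAFY", 1, "T", frozenset({"LEAFY-1"})),
            SNPAssay("s3", "LEAFY", 2, "A", frozenset({"LEAFY-4"})),
        ]
        calls = [CopyNumberCall("LEAFY", ind, copies, 0.0, {}, np.inf)
                 for ind in ("H13", "H19", "H20")]
        return copies, assays, calls

    def test_null_simulation_folds_near_one(self):
        copies, assays, calls = self._calls_and_assays()
        near_one = 0
        runs = 300
        for seed in range(runs):
            obs = simulate_experiment(copies, assays, NOISE, seed=seed,
                                      profile=ExpressionProfile.null(copies))
            results = ase_report(calls, obs, assays, seed=seed)
            if all(abs(r.fold.fold - 1) < 0.1 for r in results) and not any(
                r.p_adjusted < 0.05 for r in results
            ):
                near_one += 1
        assert near_one >= 0.9 * runs

    def test_expected_null_fractions_printed(self):
        copies, assays, calls = self._calls_and_assays()
        obs = simulate_experiment(copies, assays, NOISE, seed=4,
                                  profile=ExpressionProfile.null(copies))
        results = ase_report(calls, obs, assays)
        assert [r.expected for r in results] == [0.4, 0.2, 0.2]

    def test_target_mode_folds_recovered(self):
        copies, assays, calls = self._calls_and_assays()
        targets = {"s1": 0.174, "s2": 0.58, "s3": 0.58}
        obs = simulate_experiment(copies, assays, NOISE, seed=5, cdna_targets=targets)
        by_assay = {r.assay_id: r for r in ase_report(calls, obs, assays)}
        assert by_assay["s1"].fold.fold == pytest.approx(1 / 2.3, abs=0.15)
        assert by_assay["s2"].fold.fold == pytest.approx(2.9, abs=0.15)
        assert by_assay["s3"].fold.fold == pytest.approx(2.9, abs=0.15)

    def test_individuals_with_differing_compositions_split(self):
        # the nrITS case: one individual carries a different composition,
        # so its null fraction differs and it is reported separately
        assays = [SNPAssay("s1", "nrITS", 0, "G", frozenset({"C1", "C2"}))]
        copies_a = {"C1": 3, "C2": 1, "R": 1}   # H13/H20-like
        copies_b = {"C1": 1, "C2": 2, "R": 2}   # H19-like: carriers sum differs
        calls = [
            CopyNumberCall("nrITS", "H13", copies_a, 0.0, {}, np.inf),
            CopyNumberCall("nrITS", "H19", copies_b, 0.0, {}, np.inf),
            CopyNumberCall("nrITS", "H20", copies_a, 0.0, {}, np.inf),
        ]
        rows = []
        rng = np.random.default_rng(6)
        assay = assays[0]
        for ind, mean in (("H13", 0.8), ("H19", 0.6), ("H20", 0.8)):
            rows += simulate_assay(mean, NOISE, 2, rng, assay=assay,
                                   template="gDNA", individual=ind)
            rows += simulate_assay(mean, NOISE, 6, rng, assay=assay,
                                   template="cDNA", individual=ind, bud_stage="small")
        results = ase_report(calls, observations_to_frame(rows), assays)
        assert len(results) == 2
        groups = {r.expected: set(r.individuals) for r in results}
        assert groups[0.8] == {"H13", "H20"}
        assert groups[0.6] == {"H19"}

    def test_missing_template_skipped_with_warning(self):
        copies, assays, calls = self._calls_and_assays()
        obs = simulate_experiment(copies, assays, NOISE, seed=7,
                                  profile=ExpressionProfile.null(copies))
        obs = obs[~((obs["assay_id"] == "s1") & (obs["template"] == "cDNA"))]
        with pytest.warns(UserWarning, match="missing template"):
            results = ase_report(calls, obs, assays)
        assert {r.assay_id for r in results} == {"s2", "s3"}
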