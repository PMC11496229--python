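"""Bootstrap significance, all-pairs analysis, and stratified re-analysis."""

import dataclasses
import logging

import numpy as np
import pytest

from siakit import (
    BootstrapConfig,
    OutcomeMatrix,
    analyze_all_pairs,
    bootstrap_pair,
    generate_cohort,
    generate_independence,
    results_to_frame,
    stratified_analysis,
    write_results_csv,
)
from siakit.inference import RESULT_COLUMNS
from siakit.simulate import LinkSpec, StratumSpec, SyntheticCohortSpec

CFG = BootstrapConfig(n_replicates=500, seed=11)


def planted_spec(epsilon=0.0, q=0.5, n=200, **kw):
    return SyntheticCohortSpec(
        n=n, outcomes=("A", "B"), baselines={"A": 0.5},
        links=(LinkSpec("A", "B", epsilon=epsilon, q=q),), **kw)


class TestBootstrapPair:
    def test_perfect_implication_is_significant(self):
        m = generate_cohort(planted_spec(), seed=5)
        r = bootstrap_pair(m, "A", "B", CFG)
        assert r.b == 0  # no counterexamples planted
        assert r.significant and r.ci_low > 0
        assert r.gras_intensity == 1.0

    def test_deterministic_given_seed(self):
        m = generate_cohort(planted_spec(epsilon=0.1), seed=6)
        r1 = bootstrap_pair(m, "A", "B", CFG)
        r2 = bootstrap_pair(m, "A", "B", CFG)
        assert r1 == r2  # bit-identical dataclasses

    def test_ci_is_ordered_and_brackets_iota_typically(self):
        m = generate_cohort(planted_spec(epsilon=0.1), seed=6)
        r = bootstrap_pair(m, "A", "B", CFG)
        assert r.ci_low <= r.ci_high
        assert r.ci_low <= r.iota <= r.ci_high

    def test_too_few_rows_rejected(self):
        m = OutcomeMatrix(["a"], ["x", "y"], np.array([[1.0, 0.0]]))
        with pytest.raises(ValueError, match="at least 2"):
            bootstrap_pair(m, "x", "y", CFG)

    def test_degenerate_column_flagged_not_fatal(self):
        vals = np.column_stack([np.ones(30), np.r_[np.ones(20), np.zeros(10)]])
        m = OutcomeMatrix([f"s{i}" for i in range(30)], ["x", "y"], vals)
        r = bootstrap_pair(m, "x", "y", CFG)
        assert r.degenerate_margin
        assert r.degenerate_fraction == 1.0  # x constant in every resample
        assert np.isfinite(r.iota)

    def test_gras_nan_when_target_constant(self):
        # y constant 1: counterexamples impossible (b+d margin empty)
        vals = np.column_stack([np.r_[np.ones(15), np.zeros(15)], np.ones(30)])
        m = OutcomeMatrix([f"s{i}" for i in range(30)], ["x", "y"], vals)
        r = bootstrap_pair(m, "x", "y", CFG)
        assert np.isnan(r.gras_intensity)
        assert np.isfinite(r.iota)

    def test_ci_width_shrinks_with_n(self):
        widths = {}
        for n in (200, 800):
            m = generate_cohort(planted_spec(epsilon=0.1, n=n), seed=2)
            r = bootstrap_pair(m, "A", "B", CFG)
            widths[n] = r.ci_high - r.ci_low
        assert widths[800] < widths[200]


class TestAnalyzeAllPairs:
    def test_ordered_pair_count(self):
        m = generate_independence(60, {k: 0.5 for k in "wxyz"}, seed=3)
        results = analyze_all_pairs(m, CFG)
        assert len(results) == 12
        assert len({(r.source, r.target) for r in results}) == 12

    def test_two_outcomes_generally_asymmetric(self):
        m = generate_cohort(planted_spec(epsilon=0.05, n=400), seed=9)
        fwd, bwd = analyze_all_pairs(m, CFG)
        assert {fwd.source, fwd.target} == {"A", "B"}
        assert fwd.iota != bwd.iota

    def test_adding_an_outcome_leaves_existing_pairs_untouched(self):
        rng = np.random.default_rng(0)
        vals3 = rng.integers(0, 2, size=(100, 3)).astype(float)
        ids = [f"s{i}" for i in range(100)]
        m3 = OutcomeMatrix(ids, ["x", "y", "z"], vals3)
        m2 = OutcomeMatrix(ids, ["x", "y"], vals3[:, :2])
        res3 = {(r.source, r.target): r for r in analyze_all_pairs(m3, CFG)}
        res2 = {(r.source, r.target): r for r in analyze_all_pairs(m2, CFG)}
        for key, r2 in res2.items():
            assert res3[key] == r2

    def test_single_outcome_rejected(self):
        m = generate_independence(20, {"x": 0.5}, seed=1)
        with pytest.raises(ValueError, match="at least 2"):
            analyze_all_pairs(m, CFG)

    def test_bonferroni_widens_intervals(self):
        m = generate_independence(150, {k: 0.5 for k in "wxyz"}, seed=4)
        plain = analyze_all_pairs(m, CFG)
        adj = analyze_all_pairs(m, dataclasses.replace(CFG, bonferroni=True))
        for p, a in zip(plain, adj):
            assert (a.ci_high - a.ci_low) >= (p.ci_high - p.ci_low)


class TestStratifiedAnalysis:
    def make_stratified(self, seed=0):
        spec = SyntheticCohortSpec(
            n=300, outcomes=("A", "B"),
            baselines={"A": 0.5, "B": 0.5},  # B baseline used where unlinked
            stratum=StratumSpec(
                name="base", prevalence=0.5,
                links_by_level={
                    0: (LinkSpec("A", "B", epsilon=0.02, q=0.5),),
                    1: (),  # no dependence in stratum 1
                }),
        )
        return generate_cohort(spec, seed=seed)

    def test_per_stratum_results_and_conservation(self):
        m = self.make_stratified()
        out = stratified_analysis(m, CFG)
        assert set(out) == {"base=0", "base=1"}
        assert sum(out[k][0].n for k in out) == m.n
        for label, results in out.items():
            assert all(r.stratum == label for r in results)

    def test_structure_only_in_one_stratum(self):
        m = self.make_stratified(seed=14)
        out = stratified_analysis(m, CFG)
        fwd0 = next(r for r in out["base=0"] if (r.source, r.target) == ("A", "B"))
        fwd1 = next(r for r in out["base=1"] if (r.source, r.target) == ("A", "B"))
        assert fwd0.significant
        assert not fwd1.significant

    def test_constant_stratum_skips_with_warning(self, caplog):
        m = OutcomeMatrix(
            [f"s{i}" for i in range(40)], ["x", "y"],
            np.random.default_rng(2).integers(0, 2, (40, 2)).astype(float),
            strata_name="base", strata=np.ones(40),
        )
        with caplog.at_level(logging.WARNING, logger="siakit.inference"):
            out = stratified_analysis(m, CFG)
        assert set(out) == {"base=1"}
        assert any("skipped" in rec.message for rec in caplog.records)

    def test_requires_stratum(self, small_matrix):
        with pytest.raises(ValueError, match="no stratum"):
            stratified_analysis(small_matrix, CFG)


class TestResultsTable:
    def test_canonical_column_order(self):
        m = generate_independence(50, {"x": 0.5, "y": 0.5}, seed=8)
        frame = results_to_frame(analyze_all_pairs(m, CFG))
        assert list(frame.columns) == RESULT_COLUMNS

    def test_csv_round_trip_and_provenance(self, tmp_path):
        import pandas as pd
        m = generate_independence(50, {"x": 0.5, "y": 0.5}, seed=8)
        results = analyze_all_pairs(m, CFG)
        path = tmp_path / "res.csv"
        write_results_csv(results, path, provenance={"seed": CFG.seed})
        text = path.read_text()
        assert text.startswith("# seed=11\n")
        back = pd.read_csv(path, comment="#")
        assert list(back.columns) == RESULT_COLUMNS
        assert len(back) == 2

    def test_reproducible_csv_bytes(self, tmp_path):
        m = generate_independence(80, {"x": 0.4, "y": 0.6}, seed=8)
        paths = []
        for name in ("a.csv", "b.csv"):
            p = tmp_path / name
            write_results_csv(analyze_all_pairs(m, CFG), p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]
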