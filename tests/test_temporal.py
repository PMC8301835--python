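"""Temporal profile normalization, averaging, envelopes and comparisons."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import couplonscan as cs
from couplonscan.simulate import PROGRAMS
from couplonscan.temporal import DegenerateProfileError

TP = [60, 120, 180, 300, 420]


def _tc(rows: dict[str, list[float]]) -> cs.ExpressionTimecourse:
    return cs.ExpressionTimecourse(
        pd.DataFrame.from_dict(rows, orient="index", columns=TP)
    )


class TestNormalizeUnit:
    def test_simple_curve(self):
        np.testing.assert_allclose(
            cs.normalize_unit([2, 4, 6, 4, 2]), [0, 0.5, 1, 0.5, 0]
        )

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateProfileError):
            cs.normalize_unit([3, 3, 3, 3, 3])

    @given(
        x=st.lists(st.floats(-100, 100), min_size=3, max_size=8),
        a=st.floats(0.01, 50),
        b=st.floats(-100, 100),
    )
    def test_positive_affine_invariance(self, x, a, b):
        x = np.asarray(x)
        if np.ptp(x) < 1e-6:
            return
        np.testing.assert_allclose(
            cs.normalize_unit(a * x + b), cs.normalize_unit(x), atol=1e-9
        )


class TestSetProfile:
    def test_shared_pattern_recovered_exactly(self):
        p = [2.0, 4.0, 6.0, 4.0, 2.0]
        tc = _tc({f"g{i}": [v * (i + 1) for v in p] for i in range(5)})
        prof = cs.set_profile(tc, [f"g{i}" for i in range(5)])
        np.testing.assert_allclose(prof.values, cs.normalize_unit(p))
        assert (prof.pre_norm_min, prof.pre_norm_max) == (0.0, 1.0)
        assert prof.n_genes_used == 5

    def test_mirror_genes_degenerate_to_half(self):
        tc = _tc({"up": [0, 1, 2, 3, 4], "down": [4, 3, 2, 1, 0]})
        with pytest.warns(UserWarning, match="constant"):
            prof = cs.set_profile(tc, ["up", "down"])
        assert prof.degenerate
        np.testing.assert_allclose(prof.values, 0.5)
        assert prof.pre_norm_min == prof.pre_norm_max

    def test_constant_genes_excluded_and_counted(self):
        tc = _tc({"var": [0, 1, 2, 3, 4], "const": [5, 5, 5, 5, 5]})
        prof = cs.set_profile(tc, ["var", "const"])
        assert prof.n_genes_used == 1
        assert prof.n_constant_excluded == 1

    def test_empty_usable_set_is_error(self):
        tc = _tc({"g": [1, 2, 3, 4, 5]})
        with pytest.raises(ValueError, match="no members"):
            cs.set_profile(tc, ["ghost"])

    def test_nondegenerate_profile_attains_zero_and_one(self, small_dataset):
        _, _, rs, tc = small_dataset
        for reg in rs:
            prof = cs.set_profile(tc, reg.gene_ids, reg.regulator)
            assert prof.values.min() == 0.0 and prof.values.max() == 1.0

    def test_invariant_to_per_gene_affine_rescaling(self, small_dataset):
        _, _, rs, tc = small_dataset
        rng = np.random.default_rng(0)
        scaled = tc.values.mul(rng.uniform(0.1, 10, size=len(tc.values)), axis=0)
        scaled = scaled.add(rng.uniform(-5, 5, size=len(tc.values)), axis=0)
        tc2 = cs.ExpressionTimecourse(scaled)
        for name in ("SigA", "SigB"):
            a = cs.set_profile(tc, rs[name].gene_ids)
            b = cs.set_profile(tc2, rs[name].gene_ids)
            np.testing.assert_allclose(a.values, b.values, atol=1e-10)

    def test_planted_program_recovery(self):
        """50 noisy copies of a program average back to it (r > 0.95)."""
        from scipy import stats

        program = np.array(PROGRAMS["wt"]["late"])
        rng = np.random.default_rng(123)
        rows = {
            f"g{i}": program + rng.normal(0, 0.2 * np.ptp(program), size=5)
            for i in range(50)
        }
        tc = _tc({k: list(v) for k, v in rows.items()})
        prof = cs.set_profile(tc, rows.keys())
        assert stats.pearsonr(prof.values, program).statistic > 0.95


class TestProfileCorrelation:
    def _profile(self, values):
        return cs.TemporalProfile("p", np.array(TP), np.asarray(values, float), 0, 1, 3)

    def test_self_is_one_and_symmetry(self):
        p = self._profile([0, 0.2, 1, 0.4, 0.1])
        q = self._profile([0.3, 0.1, 0.9, 1, 0])
        assert cs.profile_correlation(p, p) == pytest.approx(1.0)
        assert cs.profile_correlation(p, q) == pytest.approx(cs.profile_correlation(q, p))

    def test_mirror_is_minus_one(self):
        p = self._profile([0, 0.2, 1, 0.4, 0.1])
        q = self._profile(1 - np.array([0, 0.2, 1, 0.4, 0.1]))
        assert cs.profile_correlation(p, q) == pytest.approx(-1.0)

    def test_constant_profile_is_nan(self):
        p = self._profile([0.5] * 5)
        q = self._profile([0, 0.2, 1, 0.4, 0.1])
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(cs.profile_correlation(p, q))

    def test_mismatched_timepoints_rejected(self):
        p = self._profile([0, 1, 0.5, 0.2, 0.1])
        q = cs.TemporalProfile("q", np.array([1, 2, 3, 4, 5]), p.values, 0, 1, 3)
        with pytest.raises(ValueError, match="timepoints"):
            cs.profile_correlation(p, q)


class TestRegulatorVsRegulon:
    def test_identical_patterns_give_one(self):
        p = [1, 3, 5, 3, 1.0]
        tc = _tc({"reg": p, "m1": [2 * v for v in p], "m2": [v + 1 for v in p]})
        assert cs.regulator_vs_regulon(tc, "reg", ["m1", "m2"]) == pytest.approx(1.0)

    def test_mirrored_regulon_gives_minus_one(self):
        p = np.array([1, 3, 5, 3, 1.0])
        tc = _tc({"reg": list(p), "m1": list(6 - p), "m2": list(12 - 2 * p)})
        assert cs.regulator_vs_regulon(tc, "reg", ["m1", "m2"]) == pytest.approx(-1.0)

    def test_absent_regulator_gene_is_error(self):
        tc = _tc({"m1": [0, 1, 2, 3, 4]})
        with pytest.raises(KeyError):
            cs.regulator_vs_regulon(tc, "ghost", ["m1"])

    def test_noisy_driver_recovers(self, small_dataset):
        _, _, rs, tc = small_dataset
        r = cs.regulator_vs_regulon(tc, rs.regulator_genes["SigB"], rs["SigB"])
        assert r > 0.8


class TestRemapEnvelope:
    def test_fraction_zero_gives_zero_envelope(self, small_dataset):
        _, _, rs, tc = small_dataset
        with pytest.warns(UserWarning, match="0 replaced"):
            env = cs.remap_envelope(tc, rs["SigB"].gene_ids, fraction=0.0, n_reps=10, seed=1)
        assert (env.sd == 0).all()

    def test_identical_genome_patterns_give_zero_envelope(self):
        p = [1.0, 2, 4, 3, 1]
        tc = _tc({f"g{i}": [v * (i + 1) for v in p] for i in range(30)})
        env = cs.remap_envelope(tc, [f"g{i}" for i in range(10)], n_reps=10, seed=2)
        np.testing.assert_allclose(env.sd, 0, atol=1e-12)

    def test_envelope_matches_direct_sd_of_replicates(self, small_dataset):
        """Brute-force oracle: SD recomputed from the stored replicate curves."""
        _, _, rs, tc = small_dataset
        env = cs.remap_envelope(tc, rs["SigB"].gene_ids, n_reps=25, seed=3)
        np.testing.assert_allclose(env.sd, env.replicates.std(axis=0, ddof=1))
        assert env.replicates.shape == (25, 5)

    def test_seed_reproducibility(self, small_dataset):
        _, _, rs, tc = small_dataset
        a = cs.remap_envelope(tc, rs["SigB"].gene_ids, n_reps=10, seed=9)
        b = cs.remap_envelope(tc, rs["SigB"].gene_ids, n_reps=10, seed=9)
        np.testing.assert_array_equal(a.replicates, b.replicates)

    def test_permute_mode_runs(self, small_dataset):
        _, _, rs, tc = small_dataset
        env = cs.remap_envelope(tc, rs["SigB"].gene_ids, n_reps=5, seed=4, mode="permute")
        assert env.sd.shape == (5,)
        assert (env.sd >= 0).all()


class TestCompareConditions:
    def test_identical_conditions_give_r_one(self, small_dataset):
        _, _, rs, tc = small_dataset
        profs = {n: cs.set_profile(tc, rs[n].gene_ids, n) for n in rs.names}
        table = cs.compare_conditions(profs, profs)
        np.testing.assert_allclose(table["r"], 1.0)

    def test_empty_set_list_gives_empty_table(self):
        table = cs.compare_conditions({}, {})
        assert len(table) == 0
        assert list(table.columns) == ["set", "r", "n_genes_a", "n_genes_b"]

    def test_mismatched_sets_rejected(self, small_dataset):
        _, _, rs, tc = small_dataset
        p = {"A": cs.set_profile(tc, rs["SigA"].gene_ids, "A")}
        with pytest.raises(ValueError, match="different sets"):
            cs.compare_conditions(p, {})

    def test_planted_perturbation_lowers_affected_correlation(self, small_spec, small_dataset):
        _, _, rs, tc = small_dataset
        tc_mut = cs.generate_timecourse(small_spec, rs, seed=777, condition="fis_mutant")
        profs_wt = {n: cs.set_profile(tc, rs[n].gene_ids, n) for n in ("SigA", "SigB")}
        profs_mut = {n: cs.set_profile(tc_mut, rs[n].gene_ids, n) for n in ("SigA", "SigB")}
        table = cs.compare_conditions(profs_wt, profs_mut).set_index("set")
        # SigB carries the late program whose repression the mutant loses
        assert table.loc["SigB", "r"] < table.loc["SigA", "r"]


def test_timecourse_drops_rows_with_gaps():
    df = pd.DataFrame.from_dict(
        {"ok": [1, 2, 3, 4, 5], "gap": [1, np.nan, 3, 4, 5]}, orient="index", columns=TP
    )
    tc = cs.ExpressionTimecourse(df)
    assert tc.gene_ids == {"ok"}
    assert tc.n_dropped == 1


def test_timecourse_round_trip(tmp_path, small_dataset):
    _, _, _, tc = small_dataset
    cs.write_timecourse(tc, tmp_path / "expr.tsv")
    back = cs.load_timecourse(tmp_path / "expr.tsv")
    assert np.array_equal(back.timepoints, tc.timepoints)
    assert back.gene_ids == tc.gene_ids
    np.testing.assert_allclose(
        back.values.sort_index().to_numpy(), tc.values.sort_index().to_numpy(), rtol=1e-4
    )
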