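"""Window grids, resampling nulls and Z-profiles on the circle."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import couplonscan as cs
from couplonscan.spatial import _count_sorted, write_zprofile


def _uniform_ann(n, length, seed=0, prefix="g"):
    rng = np.random.default_rng(seed)
    genes = pd.DataFrame(
        {
            "gene_id": [f"{prefix}{i:03d}" for i in range(n)],
            "tss": np.sort(rng.choice(length, size=n, replace=False)),
            "strand": "+",
        }
    )
    return cs.GenomeAnnotation(length, genes)


class TestGrid:
    def test_tiling(self):
        grid = cs.make_grid(10_000, 1_000, 1_000)
        assert grid.n_windows == 10
        assert grid.intervals()[0] == (0, 1_000)
        assert grid.intervals()[-1] == (9_000, 10_000)

    def test_sliding_covers_each_position_twice(self):
        grid = cs.make_grid(10_000, 1_000, 500)
        assert grid.n_windows == 20
        covered = np.zeros(10_000, dtype=int)
        for s, e in grid.intervals():
            idx = np.arange(s, e) % 10_000
            covered[idx] += 1
        assert (covered == 2).all()

    def test_wrap_window_contains_both_sides_of_origin(self):
        genes = pd.DataFrame(
            {"gene_id": ["near_end", "near_start"], "tss": [9_900, 100], "strand": "+"}
        )
        ann = cs.GenomeAnnotation(10_000, genes)
        grid = cs.make_grid(10_000, 1_000, 500)
        counts = cs.window_counts(ann, ["near_end", "near_start"], grid)
        # window [9500, 10500) == [9500, 500) holds both genes
        i = list(grid.starts).index(9_500)
        assert counts[i] == 2

    def test_window_larger_than_chromosome_rejected(self):
        with pytest.raises(ValueError):
            cs.make_grid(1_000, 2_000, 100)
        with pytest.raises(ValueError):
            cs.make_grid(1_000, 100, 0)


class TestWindowCounts:
    def test_conservation_on_tiling_grid(self, tiny_ann):
        grid = cs.make_grid(1_000, 100, 100)
        counts = cs.window_counts(tiny_ann, tiny_ann.gene_ids, grid)
        assert counts.sum() == len(tiny_ann)

    def test_single_gene_single_window(self):
        ann = cs.GenomeAnnotation(
            10_000, pd.DataFrame({"gene_id": ["g"], "tss": [0], "strand": "+"})
        )
        grid = cs.make_grid(10_000, 1_000, 1_000)
        counts = cs.window_counts(ann, ["g"], grid)
        assert counts[0] == 1 and counts.sum() == 1

    def test_sliding_multiplicity(self):
        """On a sliding grid each gene is counted window/step times in total."""
        ann = _uniform_ann(57, 50_000, seed=4)
        grid = cs.make_grid(50_000, 5_000, 1_000)
        counts = cs.window_counts(ann, ann.gene_ids, grid)
        assert counts.sum() == 57 * 5

    def test_empty_set_warns(self, tiny_ann):
        grid = cs.make_grid(1_000, 100, 100)
        with pytest.warns(UserWarning, match="empty"):
            counts = cs.window_counts(tiny_ann, [], grid)
        assert (counts == 0).all()

    def test_unknown_gene_raises(self, tiny_ann):
        grid = cs.make_grid(1_000, 100, 100)
        with pytest.raises(KeyError):
            cs.window_counts(tiny_ann, ["ghost"], grid)


class TestNullMoments:
    def test_full_genome_set_has_zero_sd(self, tiny_ann):
        grid = cs.make_grid(1_000, 250, 250)
        k = cs.window_counts(tiny_ann, tiny_ann.gene_ids, grid)
        with pytest.warns(UserWarning, match="sd"):
            null = cs.null_moments(20, grid, tiny_ann, seed=0)
        np.testing.assert_array_equal(null.mean, k)
        assert (null.sd == 0).all()

    def test_analytic_matches_scipy_hypergeom(self, tiny_ann):
        grid = cs.make_grid(1_000, 250, 250)
        null = cs.null_moments(5, grid, tiny_ann, method="analytic")
        k = cs.window_counts(tiny_ann, tiny_ann.gene_ids, grid)
        for w, kw in enumerate(k):
            rv = stats.hypergeom(20, int(kw), 5)
            assert null.mean[w] == pytest.approx(rv.mean())
            assert null.sd[w] == pytest.approx(rv.std())

    def test_monte_carlo_matches_analytic_within_3se(self):
        ann = _uniform_ann(30, 3_000, seed=1)
        grid = cs.make_grid(3_000, 500, 500)
        mc = cs.null_moments(5, grid, ann, n_samples=10_000, seed=7)
        an = cs.null_moments(5, grid, ann, method="analytic")
        se = an.sd / np.sqrt(10_000)
        assert (np.abs(mc.mean - an.mean) <= 3 * se).all()
        # sd estimate: generous bound via SE of the sd ~ sd/sqrt(2(m-1))
        assert (np.abs(mc.sd - an.sd) <= 4 * an.sd / np.sqrt(2 * 9_999)).all() or (
            np.abs(mc.sd - an.sd) <= 0.05 * an.sd
        ).all()

    def test_two_seeds_agree_within_4se(self):
        ann = _uniform_ann(40, 4_000, seed=2)
        grid = cs.make_grid(4_000, 500, 500)
        a = cs.null_moments(8, grid, ann, n_samples=10_000, seed=1)
        b = cs.null_moments(8, grid, ann, n_samples=10_000, seed=2)
        se = np.sqrt(a.sd**2 + b.sd**2) / np.sqrt(10_000)
        assert (np.abs(a.mean - b.mean) <= 4 * np.maximum(se, 1e-12)).all()

    def test_small_sample_count_warns(self, tiny_ann):
        grid = cs.make_grid(1_000, 250, 250)
        with pytest.warns(UserWarning, match="small"):
            cs.null_moments(5, grid, tiny_ann, n_samples=50, seed=0)


class TestZProfile:
    def test_observed_equal_mean_gives_ns(self, tiny_ann):
        grid = cs.make_grid(1_000, 250, 250)
        null = cs.null_moments(5, grid, tiny_ann, method="analytic")
        zp = cs.z_profile(null.mean.round(), null, grid)
        assert (np.abs(zp.z) < 2).all()
        assert set(zp.calls) <= {"ns"}

    def test_threshold_calls(self):
        grid = cs.make_grid(1_000, 250, 250)
        null = cs.NullMoments(
            mean=np.zeros(4), sd=np.ones(4), set_size=4, total_genes=20, method="analytic"
        )
        zp = cs.z_profile(np.array([2.5, -2.5, 1.9, 0.0]), null, grid)
        assert list(zp.calls) == ["enriched", "depleted", "ns", "ns"]

    def test_zero_sd_windows_are_undefined(self):
        grid = cs.make_grid(1_000, 250, 250)
        null = cs.NullMoments(
            mean=np.array([1.0, 1.0]).repeat(2),
            sd=np.array([0.0, 0.0, 1.0, 1.0]),
            set_size=4,
            total_genes=20,
            method="analytic",
        )
        zp = cs.z_profile(np.array([1.0, 2.0, 1.0, 1.0]), null, grid)
        assert zp.calls[0] == "undefined" and zp.z[0] == 0.0
        assert zp.calls[1] == "undefined" and np.isnan(zp.z[1])

    def test_exhaustive_enumeration_oracle(self):
        """Analytic z equals z from complete subset enumeration (C(12,3))."""
        ann = _uniform_ann(12, 1_200, seed=5)
        grid = cs.make_grid(1_200, 300, 300)
        counts = np.array(
            [
                _count_sorted(np.sort(ann.positions([ann.gene_ids[i] for i in sub])), grid)
                for sub in itertools.combinations(range(12), 3)
            ],
            dtype=float,
        )
        ex_mean, ex_sd = counts.mean(axis=0), counts.std(axis=0, ddof=0)
        an = cs.null_moments(3, grid, ann, method="analytic")
        np.testing.assert_allclose(an.mean, ex_mean, atol=1e-10)
        np.testing.assert_allclose(an.sd, ex_sd, atol=1e-10)

    def test_rotation_equivariance(self):
        ann = _uniform_ann(60, 12_000, seed=6)
        delta = 3_217
        rotated = ann.genes.copy()
        rotated["tss"] = (rotated["tss"] + delta) % 12_000
        ann_rot = cs.GenomeAnnotation(12_000, rotated)
        genes = ann.gene_ids[::3]
        zp = cs.set_z_profile(ann, genes, cs.make_grid(12_000, 2_000, 500), method="analytic")
        zp_rot = cs.set_z_profile(
            ann_rot, genes, cs.make_grid(12_000, 2_000, 500, origin=delta), method="analytic"
        )
        np.testing.assert_array_equal(zp.observed, zp_rot.observed)
        np.testing.assert_array_equal(zp.z, zp_rot.z)
        np.testing.assert_array_equal(zp.calls, zp_rot.calls)


class TestSpatialCorrelation:
    def _profile(self, z):
        grid = cs.make_grid(1_000, 100, 100)
        null = cs.NullMoments(
            mean=np.zeros(len(z)), sd=np.ones(len(z)), set_size=5, total_genes=50,
            method="analytic",
        )
        return cs.z_profile(np.asarray(z, dtype=float), null, grid)

    def test_self_correlation_is_one(self):
        zp = self._profile([1, 2, 3, -1, 0, 2, 1, 0, -2, 1])
        assert cs.spatial_correlation(zp, zp).r == pytest.approx(1.0)

    def test_negation_gives_minus_one(self):
        z = [1, 2, 3, -1, 0, 2, 1, 0, -2, 1]
        a, b = self._profile(z), self._profile([-v for v in z])
        assert cs.spatial_correlation(a, b).r == pytest.approx(-1.0)

    def test_too_few_windows_rejected(self):
        grid = cs.make_grid(1_000, 500, 500)
        null = cs.NullMoments(
            mean=np.zeros(2), sd=np.zeros(2), set_size=5, total_genes=50, method="analytic"
        )
        zp = cs.z_profile(np.zeros(2), null, grid)
        with pytest.raises(ValueError, match="usable windows"):
            cs.spatial_correlation(zp, zp)

    def test_zero_variance_flagged(self):
        a = self._profile([1.0] * 10)
        b = self._profile([1, 2, 3, 4, 5, 6, 7, 8, 9, 10])
        with pytest.warns(UserWarning, match="zero variance"):
            res = cs.spatial_correlation(a, b)
        assert not res.defined and np.isnan(res.r)

    def test_mismatched_grids_rejected(self):
        a = self._profile([1, 2, 3, 4, 5, 6, 7, 8, 9, 10])
        grid = cs.make_grid(1_000, 200, 100)
        null = cs.NullMoments(np.zeros(10), np.ones(10), 5, 50, "analytic")
        b = cs.z_profile(np.zeros(10), null, grid)
        with pytest.raises(ValueError, match="grid"):
            cs.spatial_correlation(a, b)


def test_zprofile_tsv_and_bed(tmp_path):
    ann = _uniform_ann(30, 3_000, seed=9)
    grid = cs.make_grid(3_000, 1_000, 400)
    zp = cs.set_z_profile(ann, ann.gene_ids[:6], grid, method="analytic")
    write_zprofile(zp, tmp_path / "z.tsv", tmp_path / "z.bed")
    df = pd.read_csv(tmp_path / "z.tsv", sep="\t")
    assert list(df.columns) == ["start", "end", "observed", "null_mean", "null_sd", "z", "call"]
    assert len(df) == grid.n_windows
    bed_lines = (tmp_path / "z.bed").read_text().splitlines()
    n_wrap = sum(1 for _, e in grid.intervals() if e > 3_000)
    assert len(bed_lines) == grid.n_windows + n_wrap  # wrap windows on two lines
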