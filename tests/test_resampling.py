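import numpy as np
import pytest

from nestedpls.dataset import DatasetError, average_replicates, subset_design
from nestedpls.npls import FitSettings, fit
from nestedpls.resampling import (
    ResamplingScheme,
    align_signs,
    jackknife_draw,
    paired_draw,
    rmse_comparison,
    robust_fractions,
    run_ensemble,
    subsample_draw,
    summarize_robustness,
)
from nestedpls.standardize import standardize
from nestedpls.synthetic import generate, paper_shaped_fixture, random_planted
from nestedpls.weights import weight_coordinates
from nestedpls.crossval import loo_crossvalidate


@pytest.fixture
def noisy_dataset():
    planted = random_planted(
        4, 3, 3, 3, 3, n_lvs=2, seed=5, x_replicates=3, y_replicates=3
    ).with_noise(0.4, 0.1)
    ds, _ = generate(planted)
    return ds


@pytest.fixture
def noiseless_dataset(planted2):
    ds, _ = generate(planted2)
    return ds


@pytest.fixture
def paired_dataset():
    planted = random_planted(
        4, 3, 3, 3, 3, n_lvs=2, seed=5, x_replicates=3, y_replicates=3, paired=True
    ).with_noise(0.4)
    ds, _ = generate(planted)
    return ds


class TestJackknifeDraw:
    def test_exactly_one_removed_per_cell(self, noisy_dataset, rng):
        draw, log = jackknife_draw(noisy_dataset, rng)
        before = noisy_dataset.replicate_map()
        after = draw.replicate_map()
        for cell, ids in before.items():
            assert len(after[cell]) == len(ids) - 1
            removed = set(ids) - set(after[cell])
            assert len(removed) == 1

    def test_identical_replicates_mean_invariance(self, noiseless_dataset, rng):
        global_avg = average_replicates(noiseless_dataset)
        draw, _ = jackknife_draw(noiseless_dataset, rng)
        avg = average_replicates(draw)
        np.testing.assert_allclose(avg.X, global_avg.X, atol=1e-12)
        np.testing.assert_allclose(avg.Y, global_avg.Y, atol=1e-12)

    def test_uniform_omission(self, noisy_dataset):
        rng = np.random.default_rng(77)
        cell = ("X", "c1", 0.0)
        counts = {rid: 0 for rid in noisy_dataset.replicate_map()[cell]}
        n = 6000
        for _ in range(n):
            _, log = jackknife_draw(noisy_dataset, rng)
            dropped = next(r for (b, c, t, r) in log if (b, c, t) == cell)
            counts[dropped] += 1
        p = 1 / 3
        sigma = np.sqrt(n * p * (1 - p))
        for count in counts.values():
            assert abs(count - n * p) < 3 * sigma

    def test_single_replicate_cell_errors(self, rng):
        planted = random_planted(3, 2, 2, 2, 2, n_lvs=1, seed=0,
                                 x_replicates=1, y_replicates=2)
        ds, _ = generate(planted)
        with pytest.raises(DatasetError, match="jackknife undefined"):
            jackknife_draw(ds, rng)

    def test_exhaustive_two_replicate_mean_equals_global(self):
        # enumeration: the mean over both leave-one-out configurations of a
        # 2-replicate cell equals the cell's global average
        planted = random_planted(3, 2, 2, 2, 2, n_lvs=1, seed=3,
                                 x_replicates=2, y_replicates=2).with_noise(1.0)
        ds, _ = generate(planted)
        global_avg = average_replicates(ds)
        cell = ("X", "c1", 0.0)
        ids = ds.replicate_map()[cell]
        loo_means = []
        for rid in ids:
            kept = ds.drop_replicates([cell + (rid,)])
            loo_means.append(average_replicates(kept).X[0, 0, :])
        np.testing.assert_allclose(
            np.mean(loo_means, axis=0), global_avg.X[0, 0, :], atol=1e-12
        )


class TestSubsampleDraw:
    def test_single_replicate_identity(self, rng):
        planted = random_planted(4, 2, 2, 2, 2, n_lvs=1, seed=0,
                                 x_replicates=1, y_replicates=1).with_noise(0.5)
        ds, _ = generate(planted)
        draw, _ = subsample_draw(ds, rng)
        assert draw.equals(ds)

    def test_one_kept_per_cell(self, noisy_dataset, rng):
        draw, _ = subsample_draw(noisy_dataset, rng)
        for cell, ids in draw.replicate_map().items():
            assert len(ids) == 1

    def test_deterministic(self, noisy_dataset):
        d1, log1 = subsample_draw(noisy_dataset, np.random.default_rng(9))
        d2, log2 = subsample_draw(noisy_dataset, np.random.default_rng(9))
        assert log1 == log2
        assert d1.equals(d2)


class TestPairedDraw:
    def test_requires_matching_grids(self, rng):
        planted = paper_shaped_fixture("bersi", seed=0, replicate_noise_sd=0.2,
                                       y_replicates=2, paired=True)
        ds, _ = generate(planted)
        with pytest.raises(DatasetError, match="matching X and Y time grids"):
            paired_draw(ds, "subsample", rng)
        sub = subset_design(ds, keep_Y_times=(0.0, 4.0, 14.0, 28.0))
        draw, log = paired_draw(sub, "subsample", rng)
        assert draw.design.y.times == (0.0, 4.0, 14.0, 28.0)

    def test_coupling_contract(self, paired_dataset, rng):
        draw, log = paired_draw(paired_dataset, "subsample", rng)
        pair_map = draw.pairing_map()
        d = draw.design
        for cond in d.conditions:
            for t in d.x.times:
                x_pairs = set(pair_map[("X", cond, t)])
                y_pairs = set(pair_map[("Y", cond, t)])
                assert x_pairs == y_pairs
                assert len(x_pairs) == 1

    def test_unpaired_draws_independently(self, paired_dataset):
        # coupling frequency under independent draws ~ 1/3 per cell
        rng = np.random.default_rng(11)
        n, coupled = 400, 0
        for _ in range(n):
            draw, log = subsample_draw(paired_dataset, rng)
            picks = {(b, c, t): r for (b, c, t, r) in log}
            x_pick = picks[("X", "c1", 0.0)]
            y_pick = picks[("Y", "c1", 0.0)]
            # replicate ids are block-prefixed; compare animal numbers
            if x_pick[2:] == y_pick[2:]:
                coupled += 1
        p = 1 / 3
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(coupled - n * p) < 3.5 * sigma

    def test_missing_pairing_rejected(self, noisy_dataset, rng):
        with pytest.raises(DatasetError, match="pairing"):
            paired_draw(noisy_dataset, "subsample", rng)


class TestRunEnsemble:
    def _settings(self):
        return FitSettings(n_lvs=2, seed=0)

    def test_two_member_reproducible(self, noisy_dataset, identity_spec):
        scheme = ResamplingScheme(method="jackknife", n_iter=2, seed=4, n_lvs=2)
        e1 = run_ensemble(noisy_dataset, scheme, identity_spec, self._settings(),
                          compute_cv=False)
        e2 = run_ensemble(noisy_dataset, scheme, identity_spec, self._settings(),
                          compute_cv=False)
        assert e1.n_members == 2
        np.testing.assert_array_equal(
            e1.members["y_combined"], e2.members["y_combined"]
        )
        assert e1.iteration_log == e2.iteration_log

    @pytest.mark.parametrize("method", ["jackknife", "subsample"])
    def test_zero_variance_degeneracy(self, noiseless_dataset, identity_spec, method):
        raw = average_replicates(noiseless_dataset)
        std, _ = standardize(raw, identity_spec)
        global_model = fit(std.X, std.Y, self._settings())
        scheme = ResamplingScheme(method=method, n_iter=5, seed=1, n_lvs=2)
        ens = run_ensemble(noiseless_dataset, scheme, identity_spec, self._settings(),
                           reference_model=global_model, compute_cv=False)
        ref = weight_coordinates(global_model)
        for axis in ("x_combined", "y_combined"):
            np.testing.assert_allclose(ens.mean(axis), ref[axis], atol=1e-12)
            np.testing.assert_allclose(ens.sd(axis), 0.0, atol=1e-12)

    def test_single_replicate_subsample_equals_global(self, identity_spec):
        planted = random_planted(5, 3, 3, 3, 3, n_lvs=2, seed=2,
                                 x_replicates=1, y_replicates=1).with_noise(0.5)
        ds, _ = generate(planted)
        raw = average_replicates(ds)
        std, _ = standardize(raw, identity_spec)
        global_model = fit(std.X, std.Y, self._settings())
        scheme = ResamplingScheme(method="subsample", n_iter=3, seed=0, n_lvs=2)
        ens = run_ensemble(ds, scheme, identity_spec, self._settings(),
                           reference_model=global_model, compute_cv=False)
        ref = weight_coordinates(global_model)
        for axis in ("x_combined", "y_combined"):
            assert np.max(np.abs(ens.members[axis] - ref[axis][None])) <= 1e-12

    def test_nesting_never_broken(self, noisy_dataset, identity_spec):
        # every draw in the log removes/keeps whole replicates only
        scheme = ResamplingScheme(method="jackknife", n_iter=3, seed=8, n_lvs=2)
        ens = run_ensemble(noisy_dataset, scheme, identity_spec, self._settings(),
                           compute_cv=False)
        n_vars = {b: len(noisy_dataset.design.block(b).variables) for b in ("X", "Y")}
        for log in ens.iteration_log:
            draw = noisy_dataset.drop_replicates(log)
            counts = draw.obs.groupby(
                ["block", "condition", "time", "replicate_id"]
            ).size()
            for (block, *_), size in counts.items():
                assert size == n_vars[block]


class TestMonotoneDiscrimination:
    def test_robust_count_non_increasing_with_noise(self, identity_spec):
        # averaged over seeds, the number of robust coordinates can only
        # shrink as replicate noise grows (all else fixed)
        counts = {noise: 0.0 for noise in (0.0, 0.4, 1.5)}
        for seed in (0, 1):
            for noise in counts:
                planted = random_planted(
                    5, 3, 3, 3, 3, n_lvs=2, seed=6, strengths=(1.0, 0.4),
                    x_replicates=4, y_replicates=4,
                ).with_noise(noise, seed=seed + 50)
                ds, _ = generate(planted)
                scheme = ResamplingScheme(method="subsample", n_iter=60,
                                          seed=seed, n_lvs=2)
                ens = run_ensemble(ds, scheme, identity_spec,
                                   FitSettings(n_lvs=2, seed=0), compute_cv=False)
                counts[noise] += int(ens.robust("y_combined").sum())
        assert counts[0.0] >= counts[0.4] >= counts[1.5]
        assert counts[1.5] < counts[0.0]


class TestAlignSigns:
    def test_constructed_flip_restored(self, noisy_dataset, identity_spec, rng):
        raw = average_replicates(noisy_dataset)
        std, _ = standardize(raw, identity_spec)
        model = fit(std.X, std.Y, FitSettings(n_lvs=2, seed=0))
        ref = weight_coordinates(model)
        model.latent_variables[1] = model.latent_variables[1].flipped()
        flipped = weight_coordinates(model)
        aligned, signs = align_signs(flipped, ref)
        np.testing.assert_array_equal(signs, [1.0, -1.0])
        for axis in ref:
            np.testing.assert_allclose(aligned[axis], ref[axis], atol=1e-12)

    def test_bimodality_collapse(self, rng):
        # ensemble of reference +/- noise with random wholesale flips:
        # alignment must shrink per-coordinate SDs to the noise scale
        ref_w = rng.standard_normal(12)
        ref_w /= np.linalg.norm(ref_w)
        ref = {"x_combined": ref_w[None, :], "y_combined": ref_w[None, :]}
        members = []
        for _ in range(200):
            noise = 0.05 * rng.standard_normal(12)
            sign = rng.choice([-1.0, 1.0])
            members.append(sign * (ref_w + noise))
        members = np.array(members)
        pre_sd = members.std(axis=0)
        aligned = []
        for row in members:
            coords = {"x_combined": row[None, :], "y_combined": row[None, :]}
            out, _ = align_signs(coords, ref)
            aligned.append(out["x_combined"][0])
        post_sd = np.array(aligned).std(axis=0)
        # brute-force fold: flipping every member toward positive correlation
        folded = np.array([
            row if row @ ref_w > 0 else -row for row in members
        ])
        np.testing.assert_allclose(post_sd, folded.std(axis=0), atol=1e-12)
        assert post_sd.mean() < pre_sd.mean()


class TestSummaries:
    def _tiny_ensemble(self, noisy_dataset, identity_spec):
        scheme = ResamplingScheme(method="jackknife", n_iter=4, seed=0, n_lvs=2)
        return run_ensemble(noisy_dataset, scheme, identity_spec,
                            FitSettings(n_lvs=2, seed=0), compute_cv=False)

    def test_robust_flag_rules(self):
        from nestedpls.resampling import ResamplingEnsemble

        members = np.array([
            # coordinate values across 2 members chosen to give
            # (mean, sd) = (1.0, 0.5), (0.3, 0.5), (0.5, 0.5)
            [[0.5, -0.2, 0.0]],
            [[1.5, 0.8, 1.0]],
        ])
        ens = ResamplingEnsemble(
            scheme=ResamplingScheme(method="jackknife", n_iter=2, n_lvs=1),
            reference={}, members={"y_var": members}, signs=np.ones((2, 1)),
            cv_curves=None, iteration_log=[], n_failed=0,
        )
        np.testing.assert_allclose(ens.mean("y_var")[0], [1.0, 0.3, 0.5])
        np.testing.assert_allclose(ens.sd("y_var")[0], [0.5, 0.5, 0.5])
        assert ens.robust("y_var")[0].tolist() == [True, False, False]

    def test_summary_table(self, noisy_dataset, identity_spec):
        ens = self._tiny_ensemble(noisy_dataset, identity_spec)
        raw = average_replicates(noisy_dataset)
        table = summarize_robustness(ens, raw)
        assert {"block", "lv", "axis", "label", "mean", "sd", "robust"} <= set(table.columns)
        fr = robust_fractions(ens, "y_var")
        assert len(fr) == 2
        assert ((fr["robust_fraction"] >= 0) & (fr["robust_fraction"] <= 1)).all()


class TestRmseComparison:
    def test_zero_variance_curves_identical(self, noiseless_dataset, identity_spec):
        raw = average_replicates(noiseless_dataset)
        settings = FitSettings(n_lvs=2, seed=0)
        cv = loo_crossvalidate(raw, identity_spec, settings, max_lvs=3)
        ensembles = {}
        for method in ("jackknife", "subsample"):
            scheme = ResamplingScheme(method=method, n_iter=3, seed=0, n_lvs=2)
            ensembles[method] = run_ensemble(
                noiseless_dataset, scheme, identity_spec, settings,
                compute_cv=True, max_lvs=3,
            )
        table = rmse_comparison(cv, ensembles)
        np.testing.assert_allclose(table["jackknife_mean_rmse"], table["global_rmse"], atol=1e-10)
        np.testing.assert_allclose(table["subsample_mean_rmse"], table["global_rmse"], atol=1e-10)

    def test_reproducible(self, noisy_dataset, identity_spec):
        settings = FitSettings(n_lvs=2, seed=0)
        raw = average_replicates(noisy_dataset)
        cv = loo_crossvalidate(raw, identity_spec, settings, max_lvs=2)
        tables = []
        for _ in range(2):
            scheme = ResamplingScheme(method="subsample", n_iter=4, seed=3, n_lvs=2)
            ens = run_ensemble(noisy_dataset, scheme, identity_spec, settings,
                               compute_cv=True, max_lvs=2)
            tables.append(rmse_comparison(cv, {"subsample": ens}))
        np.testing.assert_array_equal(
            tables[0]["subsample_mean_rmse"], tables[1]["subsample_mean_rmse"]
        )
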