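"""Material sampling, FEA sweep tables, splitting and normalization."""

import numpy as np
import pytest
from scipy import stats

from spinepinn.dataset import (
    LoadSweep,
    SamplingRanges,
    TrainingDataset,
    build_dataset,
    largest_remainder_sizes,
    sample_materials,
    split_and_normalize,
)
from spinepinn.materials import isotropic_relations


class TestSampleMaterials:
    def test_paper_scale_draw_within_bounds(self, ranges):
        mats = sample_materials(ranges, 404, seed=0)
        assert len(mats) == 404
        for m in mats:
            assert ranges.E_bone[0] <= m.E_bone <= ranges.E_bone[1]
            assert ranges.E_disc[0] <= m.E_disc <= ranges.E_disc[1]
            assert ranges.nu_bone[0] <= m.nu_bone <= ranges.nu_bone[1]
            assert ranges.nu_disc[0] <= m.nu_disc <= ranges.nu_disc[1]
            assert m.consistent

    def test_degenerate_range_collapses(self):
        r = SamplingRanges(E_bone=(15e9, 15e9))
        mats = sample_materials(r, 20, seed=1)
        assert all(m.E_bone == 15e9 for m in mats)

    def test_draws_are_uniform(self, ranges):
        mats = sample_materials(ranges, 10_000, seed=4)
        nu = np.array([m.nu_bone for m in mats])
        p = stats.kstest(nu, stats.uniform(loc=0.1, scale=0.3).cdf).pvalue
        assert p > 1e-3

    def test_deterministic_per_seed(self, ranges):
        a = sample_materials(ranges, 10, seed=5)
        b = sample_materials(ranges, 10, seed=5)
        c = sample_materials(ranges, 10, seed=6)
        assert all(np.array_equal(x.as_vector(), y.as_vector()) for x, y in zip(a, b))
        assert not np.array_equal(a[0].as_vector(), c[0].as_vector())

    def test_density_monotone_in_modulus(self, ranges):
        mats = sample_materials(ranges, 200, seed=2)
        E = np.array([m.E_bone for m in mats])
        rho = np.array([m.rho_bone for m in mats])
        order = np.argsort(E)
        assert np.all(np.diff(rho[order]) >= 0)

    def test_rho_independent_breaks_coupling(self):
        r = SamplingRanges(rho_independent=True)
        mats = sample_materials(r, 200, seed=2)
        E = np.array([m.E_bone for m in mats])
        rho = np.array([m.rho_bone for m in mats])
        assert abs(np.corrcoef(E, rho)[0, 1]) < 0.5

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            SamplingRanges(E_bone=(25e9, 10e9))
        with pytest.raises(ValueError):
            SamplingRanges(nu_disc=(0.45, 0.5))
        with pytest.raises(ValueError):
            sample_materials(SamplingRanges(), 0, seed=0)


class TestBuildDataset:
    def test_row_count_is_materials_times_magnitudes(self, dataset406):
        assert dataset406.n_samples == 29 * 14 == 406

    def test_single_case_targets_equal_draw(self, phantom_mesh, fea_model, ranges):
        sweep = LoadSweep(magnitudes=(1.4,))
        ds = build_dataset(phantom_mesh, ranges, sweep, 1, seed=3, model=fea_model)
        assert ds.n_samples == 1
        truth = sample_materials(ranges, 1, seed=3)[0]
        np.testing.assert_array_equal(ds.Y[0], truth.as_vector())

    def test_byte_identical_csv_for_equal_seeds(self, tmp_path, phantom_mesh, fea_model, ranges):
        sweep = LoadSweep(magnitudes=(0.6, 1.4))
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        for p in (pa, pb):
            ds = build_dataset(phantom_mesh, ranges, sweep, 3, seed=9, model=fea_model)
            ds.save_csv(p)
        assert pa.read_bytes() == pb.read_bytes()

    def test_exact_scaling_equals_resolving(self, phantom_mesh, fea_model, ranges):
        sweep = LoadSweep(magnitudes=(0.4, 1.2))
        a = build_dataset(phantom_mesh, ranges, sweep, 2, seed=8, model=fea_model)
        b = build_dataset(
            phantom_mesh, ranges, sweep, 2, seed=8, model=fea_model, exact_scaling=False
        )
        # shear columns are cancellation residues ~1e-12 of the dominant
        # component, i.e. solver roundoff; compare each physical group
        # against its dominant scale
        groups = [slice(0, 1), slice(1, 4), slice(4, 10), slice(10, 16)]
        for g in groups:
            scale = np.abs(a.X[:, g]).max()
            np.testing.assert_allclose(
                a.X[:, g], b.X[:, g], rtol=1e-9, atol=1e-11 * scale
            )

    def test_targets_consistent_with_isotropic_relations(self, dataset406):
        Y = dataset406.Y
        for (iE, iNu, iK, iMu) in ((0, 2, 4, 6), (1, 3, 5, 7)):
            k, mu = isotropic_relations(Y[:, iE], Y[:, iNu])
            np.testing.assert_allclose(Y[:, iK], k, rtol=1e-10)
            np.testing.assert_allclose(Y[:, iMu], mu, rtol=1e-10)

    def test_reaction_force_increases_with_magnitude(self, dataset406):
        # rows come in per-material blocks sweeping increasing magnitudes
        F = dataset406.X[:, 0].reshape(29, 14)
        assert np.all(np.diff(F, axis=1) > 0)

    def test_csv_roundtrip(self, tmp_path, dataset406):
        p = tmp_path / "ds.csv"
        dataset406.save_csv(p, p.with_suffix(".manifest.json"))
        back = TrainingDataset.load_csv(p)
        np.testing.assert_allclose(back.X, dataset406.X, rtol=1e-15)
        np.testing.assert_allclose(back.Y, dataset406.Y, rtol=1e-15)


class TestSplitAndNormalize:
    def test_largest_remainder_on_678_rows(self):
        assert largest_remainder_sizes(678, (0.7, 0.15, 0.15)) == [474, 102, 102]

    def test_splits_disjoint_and_exhaustive(self, dataset406):
        idx = np.concatenate([dataset406.splits[k] for k in ("train", "val", "test")])
        assert len(idx) == dataset406.n_samples
        assert len(np.unique(idx)) == dataset406.n_samples

    def test_normalize_denormalize_roundtrip(self, dataset406):
        Yn = dataset406.normalize_Y(dataset406.Y)
        back = dataset406.denormalize_Y(Yn)
        np.testing.assert_allclose(back, dataset406.Y, rtol=1e-12)

    def test_statistics_fitted_on_train_only(self, dataset406):
        np.testing.assert_allclose(
            dataset406.x_mean, dataset406.X[dataset406.splits["train"]].mean(axis=0)
        )
        # corrupting val/test rows must not move the fitted statistics
        corrupted = TrainingDataset(
            X=dataset406.X.copy(), Y=dataset406.Y.copy(),
            metadata=dict(dataset406.metadata),
        )
        held = np.concatenate([dataset406.splits["val"], dataset406.splits["test"]])
        corrupted.X[held] *= 3.7
        refit = split_and_normalize(corrupted, seed=1)
        np.testing.assert_array_equal(refit.splits["train"], dataset406.splits["train"])
        np.testing.assert_allclose(refit.x_mean, dataset406.x_mean, rtol=1e-15)
        np.testing.assert_allclose(refit.x_std, dataset406.x_std, rtol=1e-15)

    def test_empty_split_rejected(self, dataset406):
        tiny = TrainingDataset(X=dataset406.X[:3], Y=dataset406.Y[:3])
        with pytest.raises(ValueError):
            split_and_normalize(tiny, (0.7, 0.15, 0.15), seed=0)

    def test_bad_fractions_rejected(self, dataset406):
        with pytest.raises(ValueError):
            split_and_normalize(dataset406, (0.5, 0.2, 0.2), seed=0)


class TestLoadSweep:
    def test_default_sweep_is_fourteen_magnitudes(self, load_sweep):
        mags = np.asarray(load_sweep.magnitudes)
        assert len(mags) == 14
        assert mags[0] == pytest.approx(0.2) and mags[-1] == pytest.approx(2.8)
        assert load_sweep.n_steps == 10

    def test_invalid_sweeps_rejected(self):
        with pytest.raises(ValueError):
            LoadSweep(magnitudes=(0.4, 0.2))
        with pytest.raises(ValueError):
            LoadSweep(magnitudes=(-0.2, 0.4))
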