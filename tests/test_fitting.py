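"""Least-squares estimation, bootstrap identifiability, goodness of fit."""

import numpy as np
import pytest

import fiberwall as fw


@pytest.fixture(scope="module")
def small_protocols():
    # shorter paths keep the resample-heavy tests quick
    return fw.make_protocols(1.3, 1.3, n_steps=10)


class TestObjective:
    def test_zero_at_truth(self, noise_free_dataset, two_fiber_truth):
        assert fw.objective(two_fiber_truth, noise_free_dataset) == pytest.approx(0.0)

    def test_single_point_arithmetic(self, structural):
        params = fw.TwoFiberParams(10.0, 0.0, 1.0)
        pred = fw.cauchy_two_fiber(fw.DeformationState(1.2, 1.2), params, structural)
        ds = fw.BiaxialDataset(
            np.array(["p"]), np.array([1.2]), np.array([1.2]),
            np.array([float(pred.sigma_theta) + 1.0]),
            np.array([float(pred.sigma_z) + 2.0]),
            structural,
        )
        assert fw.objective(params, ds) == pytest.approx(5.0)

    def test_matches_per_point_loop(self, noise_free_dataset, structural):
        params = fw.TwoFiberParams(8.0, 5.0, 2.0)
        total = 0.0
        ds = noise_free_dataset
        for i in range(ds.n_points):
            p = fw.cauchy_two_fiber(
                fw.DeformationState(ds.lambda_theta[i], ds.lambda_z[i]),
                params, structural,
            )
            total += (ds.sigma_theta[i] - p.sigma_theta) ** 2
            total += (ds.sigma_z[i] - p.sigma_z) ** 2
        assert fw.objective(params, ds) == pytest.approx(total, rel=1e-12)

    def test_invariant_to_record_order(self, noise_free_dataset):
        params = fw.TwoFiberParams(8.0, 5.0, 2.0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(noise_free_dataset.n_points)
        shuffled = noise_free_dataset.subset(perm)
        assert fw.objective(params, shuffled) == pytest.approx(
            fw.objective(params, noise_free_dataset), rel=1e-12
        )


class TestRSquared:
    def test_perfect_fit(self, noise_free_dataset, two_fiber_truth):
        r2t, r2z = fw.r_squared(noise_free_dataset, two_fiber_truth)
        assert r2t == pytest.approx(1.0)
        assert r2z == pytest.approx(1.0)

    def test_matches_definition_oracle(self, noise_free_dataset):
        params = fw.TwoFiberParams(10.0, 6.0, 1.0)
        pred = fw.predict_stresses(params, noise_free_dataset)
        exp = noise_free_dataset.sigma_theta
        oracle = 1.0 - np.sum((exp - pred.sigma_theta) ** 2) / np.sum(
            (exp - exp.mean()) ** 2
        )
        r2t, _ = fw.r_squared(noise_free_dataset, params)
        assert r2t == pytest.approx(oracle, rel=1e-12)

    def test_constant_experimental_stress_flagged(self, structural):
        ds = fw.BiaxialDataset(
            np.array(["p", "p"]), np.array([1.1, 1.2]), np.array([1.1, 1.2]),
            np.array([5.0, 5.0]), np.array([1.0, 2.0]), structural,
        )
        with pytest.raises(ValueError):
            fw.r_squared(ds, fw.TwoFiberParams(1.0, 1.0, 1.0))


class TestFit:
    def test_noise_free_recovery_within_1pct(self, noise_free_dataset, two_fiber_truth):
        res = fw.fit(noise_free_dataset, "two_fiber", n_starts=10, seed=1)
        assert res.params.c2 == pytest.approx(two_fiber_truth.c2, rel=0.01)
        assert res.params.k1 == pytest.approx(two_fiber_truth.k1, rel=0.01)
        assert res.params.k2 == pytest.approx(two_fiber_truth.k2, rel=0.01)
        assert res.r2_theta > 0.9999 and res.r2_z > 0.9999

    def test_noisy_median_recovery_within_10pct(
        self, structural, two_fiber_truth, protocols
    ):
        recovered = []
        for s in range(20):
            noisy = fw.simulate_biaxial(
                two_fiber_truth, structural, protocols, fw.NoiseModel(0.02, 0.5, s)
            )
            r = fw.fit(noisy, "two_fiber", n_starts=6, seed=s)
            recovered.append([r.params.c2, r.params.k1, r.params.k2])
        med = np.median(recovered, axis=0)
        truth = np.array([two_fiber_truth.c2, two_fiber_truth.k1, two_fiber_truth.k2])
        assert np.all(np.abs(med - truth) / truth < 0.10)

    def test_four_fiber_noise_free_recovery(self, structural, protocols):
        truth = fw.FourFiberParams(6.0, 18.0, 3.0, 11.0, 2.0, 3.5, 5.0)
        ds = fw.simulate_biaxial(truth, structural, protocols)
        res = fw.fit(ds, "four_fiber", n_starts=15, seed=2)
        for got, want in zip(
            fw.fitting._vector_from_params(res.params),
            fw.fitting._vector_from_params(truth),
        ):
            assert got == pytest.approx(want, rel=0.01)

    def test_richer_model_fits_no_worse(self, structural, small_protocols,
                                        two_fiber_truth):
        noisy = fw.simulate_biaxial(
            two_fiber_truth, structural, small_protocols, fw.NoiseModel(0.02, 0.5, 3)
        )
        r2 = fw.fit(noisy, "two_fiber", n_starts=6, seed=0)
        mapped = [r2.params.c2, 2.0 * r2.params.k1, r2.params.k2, 0, 0, 0, 0]
        r4 = fw.fit(noisy, "four_fiber", n_starts=6, seed=0, x0=mapped)
        assert r4.r2_theta >= r2.r2_theta - 1e-9
        assert r4.r2_z >= r2.r2_z - 1e-9

    def test_structural_constants_never_modified(self, noise_free_dataset):
        before = noise_free_dataset.structural
        fw.fit(noise_free_dataset, "two_fiber", n_starts=3, seed=0)
        assert noise_free_dataset.structural == before


class TestBootstrap:
    def test_seeding_contract(self, structural, two_fiber_truth, small_protocols):
        noisy = fw.simulate_biaxial(
            two_fiber_truth, structural, small_protocols, fw.NoiseModel(0.02, 0.5, 1)
        )
        a = fw.bootstrap(noisy, "two_fiber", n_iter=2, seed=42, n_starts_point=3)
        b = fw.bootstrap(noisy, "two_fiber", n_iter=2, seed=42, n_starts_point=3)
        for k in a.bootstrap_samples:
            np.testing.assert_array_equal(a.bootstrap_samples[k], b.bootstrap_samples[k])

    def test_n_iter_validation(self, noise_free_dataset):
        with pytest.raises(ValueError):
            fw.bootstrap(noise_free_dataset, n_iter=1)

    def test_noise_free_bootstrap_degenerates_to_point_fit(
        self, structural, two_fiber_truth, small_protocols
    ):
        ds = fw.simulate_biaxial(two_fiber_truth, structural, small_protocols)
        res = fw.bootstrap(ds, "two_fiber", n_iter=5, seed=0, n_starts_point=5)
        truth = np.array([two_fiber_truth.c2, two_fiber_truth.k1, two_fiber_truth.k2])
        for j, name in enumerate(("c2", "k1", "k2")):
            np.testing.assert_allclose(
                res.bootstrap_samples[name], truth[j], rtol=1e-4
            )

    def test_coverage_of_central_interval(self, structural, two_fiber_truth,
                                          small_protocols):
        # 2% noise, 200 bootstrap iterations: the true parameter should fall
        # inside the central 95% interval in >= 90% of seeded replicates
        truth = np.array([two_fiber_truth.c2, two_fiber_truth.k1, two_fiber_truth.k2])
        n_rep = 20
        hits = np.zeros(3)
        for s in range(n_rep):
            noisy = fw.simulate_biaxial(
                two_fiber_truth, structural, small_protocols,
                fw.NoiseModel(0.02, 0.5, 1000 + s),
            )
            res = fw.bootstrap(noisy, "two_fiber", n_iter=200, seed=s,
                               n_starts_point=5)
            for j, name in enumerate(("c2", "k1", "k2")):
                lo, hi = np.percentile(res.bootstrap_samples[name], [2.5, 97.5])
                hits[j] += lo <= truth[j] <= hi
        assert np.all(hits / n_rep >= 0.9)
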