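"""Planning posteriors and the random-walk Metropolis sampler."""

import numpy as np
import pytest
from scipy import stats

from speechplan.planner import (
    LowAcceptanceError,
    PlanningModel,
    SamplerConfig,
    dispersion_ellipse,
    random_walk_metropolis,
)
from speechplan.preference import PreferenceParams
from speechplan.targets import mahalanobis


class TestLogPosterior:
    def test_fusion_factorises_into_modalities(self, setup, rng):
        """Fusion log density = auditory-only + somatosensory-only (+ const)."""
        t = setup.inventory["ɔ"]
        fus = PlanningModel(t, setup.maps, setup.plant.bounds)
        aud = PlanningModel(t, setup.maps, setup.plant.bounds, modalities=("auditory",))
        som = PlanningModel(t, setup.maps, setup.plant.bounds, modalities=("somatosensory",))
        M = rng.uniform(-1, 1, size=(100, 6))
        gaps = np.array([fus.loglike(m) - aud.loglike(m) - som.loglike(m) for m in M])
        assert np.max(np.abs(gaps - gaps[0])) <= 1e-12

    def test_auditory_only_ignores_somatosensory_map(self, setup, rng):
        from speechplan.internal_models import SensoryMap

        t = setup.inventory["ɔ"]
        other_som = SensoryMap.from_affine(
            np.zeros((3, 6)), np.array([99.0, 99.0, 99.0]), "somatosensory", setup.plant.bounds
        )
        a1 = PlanningModel(t, setup.maps, setup.plant.bounds, modalities=("auditory",))
        a2 = PlanningModel(
            t,
            {"auditory": setup.maps["auditory"], "somatosensory": other_som},
            setup.plant.bounds,
            modalities=("auditory",),
        )
        for m in rng.uniform(-1, 1, size=(20, 6)):
            assert a1.loglike(m) == a2.loglike(m)

    def test_no_active_modality_is_rejected(self, setup):
        with pytest.raises(ValueError):
            PlanningModel(setup.inventory["ɔ"], setup.maps, setup.plant.bounds, modalities=())

    def test_mismatched_map_modality_is_rejected(self, setup):
        swapped = {
            "auditory": setup.maps["somatosensory"],
            "somatosensory": setup.maps["auditory"],
        }
        with pytest.raises(ValueError):
            PlanningModel(setup.inventory["ɔ"], swapped, setup.plant.bounds)

    def test_comparison_fusion_matches_convolution_quadrature(self, setup, rng):
        """The soft-match fusion density equals the explicit Gaussian
        convolution integral, computed by Gauss–Hermite quadrature."""
        t = setup.inventory["ɔ"]
        sA = float(np.sqrt(np.diag(t.Gamma_a).mean()))
        eta = 0.8 * sA
        prefs = PreferenceParams.comparison_based(eta_a=eta, eta_s=0.0)
        model = PlanningModel(t, setup.maps, setup.plant.bounds, preference=prefs)
        plain = PlanningModel(t, setup.maps, setup.plant.bounds)

        nodes, weights = np.polynomial.hermite_e.hermegauss(40)
        for m in rng.uniform(-1, 1, size=(20, 6)):
            x = setup.maps["auditory"].predict(m)
            # E_{a ~ N(x, eta^2 I)} [ N(a; mu, Gamma) ] via tensor quadrature
            pts = np.stack(np.meshgrid(*([nodes] * 3), indexing="ij"), axis=-1).reshape(-1, 3)
            w = np.prod(
                np.stack(np.meshgrid(*([weights] * 3), indexing="ij"), axis=-1).reshape(-1, 3),
                axis=1,
            )
            a = x + eta * pts
            integral = np.sum(
                w * stats.multivariate_normal.pdf(a, t.mu_a, t.Gamma_a)
            ) / (2 * np.pi) ** 1.5
            # compare the auditory factor of the fusion density
            log_aud_factor = model.loglike(m) - (
                plain.loglike(m)
                - stats.multivariate_normal.logpdf(x, t.mu_a, t.Gamma_a)
            )
            assert np.exp(log_aud_factor) == pytest.approx(integral, rel=1e-4)


class TestSampler:
    def test_recovers_standard_gaussian_moments(self):
        """On a known 2-D Gaussian target the sampler reproduces mean and
        covariance within Monte-Carlo error."""
        logpdf = lambda x: float(-0.5 * x @ x)
        bounds = [[-6.0, 6.0]] * 2
        cfg = SamplerConfig(chains=20, burn=1000, draws=1000, seed=12)
        samples, acc = random_walk_metropolis(logpdf, bounds, cfg)
        assert samples.shape == (20, 1000, 2)
        flat = samples.reshape(-1, 2)
        se = samples.mean(axis=1).std(axis=0, ddof=1) / np.sqrt(20)
        assert np.all(np.abs(flat.mean(axis=0)) <= 3 * se)
        assert np.allclose(np.cov(flat.T), np.eye(2), atol=0.05)
        assert np.all(acc > 0.01)

    def test_bit_identical_reruns(self):
        logpdf = lambda x: float(-0.5 * x @ x)
        cfg = SamplerConfig(chains=4, burn=200, draws=200, seed=77)
        s1, a1 = random_walk_metropolis(logpdf, [[-5, 5]] * 2, cfg)
        s2, a2 = random_walk_metropolis(logpdf, [[-5, 5]] * 2, cfg)
        assert np.array_equal(s1, s2) and np.array_equal(a1, a2)

    def test_default_protocol_retains_twenty_thousand(self):
        cfg = SamplerConfig()
        assert cfg.chains * cfg.draws == 20000
        assert cfg.burn == 1000
        logpdf = lambda x: float(-0.5 * x @ x)
        samples, _ = random_walk_metropolis(logpdf, [[-5, 5]] * 2, cfg)
        assert samples.reshape(-1, 2).shape[0] == 20000

    def test_draws_stay_in_bounds(self, setup, fast_sampler):
        res = PlanningModel(
            setup.inventory["i"], setup.maps, setup.plant.bounds
        ).fit(fast_sampler)
        lo, hi = setup.plant.bounds[:, 0], setup.plant.bounds[:, 1]
        assert np.all(res.lambdas >= lo) and np.all(res.lambdas <= hi)

    def test_low_acceptance_raises(self):
        # sharply peaked target with a frozen, enormous proposal scale
        logpdf = lambda x: float(-0.5 * (x @ x) / 1e-8)
        cfg = SamplerConfig(
            chains=3, burn=100, draws=100, proposal_scale=1.0, adapt_interval=10**9, seed=0
        )
        with pytest.raises(LowAcceptanceError):
            random_walk_metropolis(logpdf, [[-5, 5]] * 2, cfg)

    def test_grid_oracle_marginals(self):
        """On a reduced 2-D nonlinear problem, MCMC marginal CDFs match the
        grid-normalised posterior CDFs (Kolmogorov–Smirnov <= 0.05)."""
        W = np.array([[0.9, 0.4], [-0.5, 0.8]])
        target_mu = np.array([0.3, -0.2])
        var = 0.05**2

        def forward(m):
            return np.tanh(m @ W.T)

        def logpdf(m):
            r = forward(np.atleast_2d(m))[0] - target_mu
            return float(-0.5 * r @ r / var)

        cfg = SamplerConfig(chains=20, burn=1000, draws=1000, seed=3)
        samples, _ = random_walk_metropolis(logpdf, [[-1, 1]] * 2, cfg)
        flat = samples.reshape(-1, 2)

        g = np.linspace(-1, 1, 401)
        G1, G2 = np.meshgrid(g, g, indexing="ij")
        pts = np.stack([G1.ravel(), G2.ravel()], axis=-1)
        r = forward(pts) - target_mu
        dens = np.exp(-0.5 * (r**2).sum(axis=1) / var).reshape(401, 401)
        dens /= dens.sum()
        for axis in (0, 1):
            marg = dens.sum(axis=1 - axis)
            cdf = np.cumsum(marg)
            emp = np.searchsorted(np.sort(flat[:, axis]), g, side="right") / len(flat)
            assert np.max(np.abs(emp - cdf)) <= 0.05


class TestResults:
    def test_summary_and_frame_shapes(self, setup, fast_sampler):
        res = PlanningModel(setup.inventory["ɔ"], setup.maps, setup.plant.bounds).fit(fast_sampler)
        df = res.summary()
        assert list(df.index) == [f"lambda_{i}" for i in range(1, 7)]
        assert {"mean", "sd", "mcse_mean"} <= set(df.columns)
        frame = res.to_frame()
        assert len(frame) == fast_sampler.chains * fast_sampler.draws
        assert {"chain", "draw", "lambda_1", "f1", "pc1"} <= set(frame.columns)

    def test_target_regions_reached_in_both_spaces(self, setup, fast_sampler):
        """Unperturbed planning puts >= 90% of mapped posterior samples
        (through the internal models, as the planner sees its own output)
        inside the order-3 target ellipsoids of both sensory spaces, for
        every phoneme and every planning mode."""
        for phoneme in setup.inventory.labels():
            t = setup.inventory[phoneme]
            for modalities in (("auditory",), ("somatosensory",), ("auditory", "somatosensory")):
                res = PlanningModel(
                    t, setup.maps, setup.plant.bounds, modalities=modalities
                ).fit(fast_sampler)
                A = res.predicted("auditory")
                S = res.predicted("somatosensory")
                in_aud = np.array([mahalanobis(a, t.mu_a, t.Gamma_a) <= 3 for a in A]).mean()
                in_som = np.array([mahalanobis(s, t.mu_s, t.Gamma_s) <= 3 for s in S]).mean()
                assert in_aud >= 0.90, (phoneme, modalities, in_aud)
                assert in_som >= 0.90, (phoneme, modalities, in_som)


class TestDispersionEllipse:
    def test_circle_grid_axes(self):
        th = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        pts = np.stack([np.cos(th), np.sin(th)], axis=1)
        center, axes, _ = dispersion_ellipse(pts, order=2.0)
        assert np.allclose(center, 0, atol=1e-12)
        assert np.allclose(axes, 2 * np.sqrt(0.5), rtol=5e-3)

    def test_translation_equivariance(self, rng):
        pts = rng.normal(size=(500, 2)) @ np.array([[2.0, 0.3], [0.0, 0.7]])
        c0, a0, ang0 = dispersion_ellipse(pts)
        c1, a1, ang1 = dispersion_ellipse(pts + np.array([5.0, -3.0]))
        assert np.allclose(c1 - c0, [5.0, -3.0], atol=1e-9)
        assert np.allclose(a0, a1) and ang0 == pytest.approx(ang1, abs=1e-9)

    def test_angle_in_half_open_interval(self, rng):
        for _ in range(5):
            pts = rng.normal(size=(200, 2)) @ rng.normal(size=(2, 2))
            _, _, ang = dispersion_ellipse(pts)
            assert -90.0 < ang <= 90.0

    def test_degenerate_input_rejected(self):
        line = np.stack([np.arange(10.0), 2 * np.arange(10.0)], axis=1)
        with pytest.raises(ValueError):
            dispersion_ellipse(line)
        with pytest.raises(ValueError):
            dispersion_ellipse(np.zeros((2, 2)))
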