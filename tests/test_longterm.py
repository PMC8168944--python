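"""Mixture selection by AIC, trajectory ensembles and the reference curve."""

import numpy as np
import pytest
from sklearn.mixture import GaussianMixture

from adcascade.dynamics import Trajectory, integrate
from adcascade.longterm import (
    LatentMixture,
    _n_mixture_params,
    build_reference,
    decode_reference,
    disease_course,
    fit_mixture,
    project_onto_course,
    sample_ensemble,
)
from adcascade.observation import DecoderParams, ModalitySchema
from adcascade.synthetic import canonical_config, canonical_dynamics


def point_mixture(mean, sd=0.0):
    mean = np.asarray(mean, float)
    cov = (sd**2) * np.eye(len(mean))
    return LatentMixture(weights=np.array([1.0]), means=mean[None, :],
                         covariances=cov[None, :, :], structure="spherical",
                         n_components=1, aic=0.0)


def mid_course_state(t=6.0):
    cfg = canonical_config()
    return integrate(np.asarray(cfg.anchor_state, float), 0.0, np.array([t]),
                     canonical_dynamics()).states[0]


class TestFitMixture:
    def test_single_tight_gaussian_selects_one_component(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0.0, 0.1, size=(500, 4))
        mix = fit_mixture(X, rng=0)
        assert mix.n_components == 1

    def test_two_separated_gaussians_select_two_components(self):
        rng = np.random.default_rng(5)
        X = np.concatenate([rng.normal(0, 0.1, size=(250, 4)),
                            rng.normal(1.0, 0.1, size=(250, 4))])
        assert fit_mixture(X, rng=0).n_components == 2

    def test_selection_is_brute_force_enumeration(self):
        """The chosen candidate minimizes AIC over the full grid, recomputed
        independently with sklearn."""
        rng = np.random.default_rng(9)
        X = np.concatenate([rng.normal(0, 0.2, size=(120, 3)),
                            rng.normal(1.5, 0.2, size=(120, 3))])
        mix = fit_mixture(X, component_range=range(1, 4),
                          structure_set=("full", "diagonal"), rng=0)
        best = np.inf
        for k in range(1, 4):
            for cov in ("full", "diag"):
                gm = GaussianMixture(n_components=k, covariance_type=cov,
                                     random_state=0, n_init=2, reg_covar=1e-9).fit(X)
                best = min(best, gm.aic(X))
        assert np.isclose(mix.aic, best)

    def test_parameter_counts_match_sklearn(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 3))
        for structure, sk_cov in [("full", "full"), ("diagonal", "diag"),
                                  ("tied", "tied"), ("spherical", "spherical")]:
            gm = GaussianMixture(n_components=2, covariance_type=sk_cov,
                                 random_state=0).fit(X)
            assert _n_mixture_params(2, 3, structure) == gm._n_parameters()

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_mixture(np.zeros((3, 4)))


class TestSampleEnsemble:
    def test_zero_variance_exact_equals_direct_integration(self):
        mid = mid_course_state()
        mix = point_mixture(mid, sd=0.0)
        grid = np.arange(-3.0, 3.0 + 1e-9, 0.5)
        ens = sample_ensemble(mix, 1, canonical_dynamics(), grid, rng=0,
                              method="exact")
        direct = integrate(mid, 0.0, grid, canonical_dynamics())
        np.testing.assert_allclose(ens[0].states, direct.states, atol=1e-12)

    def test_ensemble_mean_converges_to_mixture_mean(self):
        """Exact-method anchor-time mean approaches the mixture mean ~ n^-1/2."""
        mid = mid_course_state()
        mix = point_mixture(mid, sd=0.03)
        grid = np.arange(-3.0, 3.0 + 1e-9, 0.5)
        i0 = int(np.argmin(np.abs(grid)))
        errs = []
        for n in (10, 1000):
            ens = sample_ensemble(mix, n, canonical_dynamics(), grid, rng=42,
                                  method="exact")
            mean = np.mean([tr.states[i0] for tr in ens], axis=0)
            errs.append(np.abs(mean - mid).max())
        assert errs[1] < errs[0]
        assert errs[1] < 3 * 0.03 / np.sqrt(1000)

    def test_same_seed_gives_identical_ensembles(self):
        mix = point_mixture(mid_course_state(), sd=0.05)
        grid = np.arange(-2.0, 2.0 + 1e-9, 0.5)
        e1 = sample_ensemble(mix, 20, canonical_dynamics(), grid, rng=7)
        e2 = sample_ensemble(mix, 20, canonical_dynamics(), grid, rng=7)
        assert all(np.array_equal(a.states, b.states) for a, b in zip(e1, e2))

    def test_projected_members_lie_on_the_course(self):
        mix = point_mixture(mid_course_state(), sd=0.05)
        grid = np.arange(-5.0, 5.0 + 1e-9, 0.5)
        params = canonical_dynamics()
        ens = sample_ensemble(mix, 10, params, grid, rng=3, method="projected")
        course = disease_course(params)
        for tr in ens:
            tau = project_onto_course(tr.states, course)
            onto = np.stack([np.interp(tau, course.times, course.states[:, m])
                             for m in range(4)], axis=1)
            assert np.abs(tr.states - onto).max() < 1e-8


class TestBuildReference:
    def grid_ensemble(self, n=5, jitter=0.0):
        mid = mid_course_state()
        grid = np.arange(-4.0, 4.0 + 1e-9, 0.5)
        tr = integrate(mid, 0.0, grid, canonical_dynamics())
        rng = np.random.default_rng(0)
        return [Trajectory(times=grid,
                           states=tr.states + jitter * rng.normal(size=tr.states.shape))
                for _ in range(n)]

    def test_identical_members_have_zero_sd(self):
        ref = build_reference(self.grid_ensemble(), anchor_rule=0.0)
        assert ref.sd.max() < 1e-12  # identical members up to mean round-off

    def test_anchor_shift_is_pure_translation(self):
        ens = self.grid_ensemble(jitter=0.01)
        unshifted = build_reference(ens, anchor_rule=0.0)
        shifted = build_reference(ens, anchor_rule=1.5)
        np.testing.assert_allclose(shifted.times, unshifted.times - 1.5)
        np.testing.assert_array_equal(shifted.mean, unshifted.mean)

    def test_threshold_anchor_places_crossing_at_zero(self):
        ens = self.grid_ensemble()
        ref = build_reference(ens, ("threshold", "cli", 0.2),
                              schema=canonical_config().schema)
        i0 = int(np.argmin(np.abs(ref.times)))
        assert ref.mean[i0, 3] >= 0.2
        assert ref.mean[max(i0 - 1, 0), 3] < 0.2 or i0 == 0

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            build_reference([], anchor_rule=0.0)

    def test_mismatched_grids_rejected(self):
        ens = self.grid_ensemble()
        bad = Trajectory(times=ens[0].times[:-1], states=ens[0].states[:-1])
        with pytest.raises(ValueError):
            build_reference(ens + [bad], anchor_rule=0.0)


class TestDecodeReference:
    def identity_decoder(self, schema):
        import math
        return DecoderParams(
            loadings={m: np.ones(schema.dim(m)) for m in schema.names},
            offsets={m: np.zeros(schema.dim(m)) for m in schema.names},
            log_sigma2={m: math.log(0.1) for m in schema.names},
        )

    def test_identity_decoder_reproduces_reference(self):
        schema = ModalitySchema(names=("amy", "met", "atr", "cli"), dims=(1, 1, 1, 1))
        mid = mid_course_state()
        grid = np.arange(-4.0, 4.0 + 1e-9, 0.5)
        tr = integrate(mid, 0.0, grid, canonical_dynamics())
        ref = build_reference([Trajectory(times=grid, states=tr.states)] * 3,
                              anchor_rule=0.0)
        out = decode_reference(ref, self.identity_decoder(schema), schema)
        for i, m in enumerate(schema.names):
            np.testing.assert_allclose(out[m]["mean"][:, 0], ref.mean[:, i])
            assert out[m]["sd"].max() < 1e-12

    def test_monotone_decoder_preserves_saturation_order(self):
        """A monotone per-coordinate map cannot change which coordinate
        reaches 90% of its own asymptote first."""
        schema = ModalitySchema(names=("amy", "met", "atr", "cli"), dims=(1, 1, 1, 1))
        cfg = canonical_config()
        grid = np.arange(0.0, 45.0 + 1e-9, 0.1)
        tr = integrate(np.asarray(cfg.anchor_state, float), 0.0, grid,
                       canonical_dynamics())
        ref = build_reference([Trajectory(times=grid - 40.0, states=tr.states)],
                              anchor_rule=0.0)
        dec = self.identity_decoder(schema)
        for m in schema.names:  # positive affine map, different per modality
            dec.loadings[m] = dec.loadings[m] * 2.5
            dec.offsets[m] = dec.offsets[m] + 1.0
        out = decode_reference(ref, dec, schema)

        def t90(y):
            y = np.asarray(y, float)
            lo, hi = y[0], y[-1]
            return ref.times[np.argmax(y >= lo + 0.9 * (hi - lo))]

        latent_order = [t90(ref.mean[:, i]) for i in range(4)]
        decoded_order = [t90(out[m]["mean"][:, 0]) for m in schema.names]
        assert np.argsort(latent_order).tolist() == np.argsort(decoded_order).tolist()
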