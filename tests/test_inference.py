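"""Variational fit: exact gradients, masking, determinism, model comparison."""

import dataclasses
import math
import warnings

import numpy as np
import pytest

from adcascade.dynamics import DynamicsParams, integrate
from adcascade.inference import (
    FittedModel,
    TrainingConfig,
    _Batch,
    _elbo_and_grads,
    _init_params,
    _params_to_dict,
    elbo,
    fit,
)
from adcascade.observation import (
    DecoderParams,
    EncoderParams,
    ModalitySchema,
    ObservationSet,
    Standardizer,
    Visit,
)
from adcascade.synthetic import GeneratorConfig, canonical_config, generate


def tiny_cohort(rng, n=6, schema=None):
    """Hand-built 2-modality cohort with an incomplete pre-anchor visit."""
    schema = schema or ModalitySchema(names=("a", "b"), dims=(1, 1))
    cohort = []
    for i in range(n):
        visits = [
            Visit(time=0.0, blocks={"a": rng.normal(size=1), "b": None}),
            Visit(time=1.0, blocks={m: rng.normal(size=1) for m in schema.names}),
            Visit(time=2.6, blocks={"a": rng.normal(size=1),
                                    "b": rng.normal(size=1) if i % 2 else None}),
        ]
        cohort.append(ObservationSet(subject_id=f"t{i}", visits=visits))
    return schema, cohort


class TestGradients:
    @pytest.mark.parametrize("squash", ["linear", "softplus"])
    def test_analytic_gradients_match_central_differences(self, squash):
        rng = np.random.default_rng(0)
        schema, cohort = tiny_cohort(rng)
        std = Standardizer.fit(cohort, schema)
        batch = _Batch(cohort, schema, std, 0.1)
        assert batch.i0 > 0  # the pre-anchor visit exercises the backward chain
        P = _init_params(batch, "affine")
        P["W"] = np.array([[0.3, 0.05], [-0.1, 0.2]])
        eps = rng.standard_normal((batch.N, schema.M))
        _, _, _, grads = _elbo_and_grads(batch, P, eps, 0.7, "affine", squash)

        def value(Q):
            v, _, _, _ = _elbo_and_grads(batch, Q, eps, 0.7, "affine", squash)
            return v

        worst = 0.0
        for key in P:
            arr = np.atleast_1d(np.asarray(P[key], float))
            g = np.atleast_1d(np.asarray(grads[key], float))
            for idx in np.ndindex(arr.shape):
                h = 1e-6 * max(1.0, abs(arr[idx]))
                for sign, store in ((+1, "hi"), (-1, "lo")):
                    Q = {k: np.array(v, float, copy=True) for k, v in P.items()}
                    q = np.atleast_1d(Q[key])
                    q[idx] += sign * h
                    Q[key] = q.reshape(np.shape(P[key]))
                    if sign > 0:
                        hi = value(Q)
                    else:
                        lo = value(Q)
                fd = (hi - lo) / (2 * h)
                worst = max(worst, abs(fd - g[idx]) / max(1.0, abs(fd)))
        assert worst < 1e-4

    def test_sigmoid_decoder_gradients(self):
        rng = np.random.default_rng(1)
        schema, cohort = tiny_cohort(rng)
        std = Standardizer.fit(cohort, schema)
        batch = _Batch(cohort, schema, std, 0.1)
        P = _init_params(batch, "sigmoid")
        eps = rng.standard_normal((batch.N, schema.M))
        _, _, _, grads = _elbo_and_grads(batch, P, eps, 1.0, "sigmoid", "linear")
        for key in ("W", "a_a", "w_b", "log_s"):
            arr = np.atleast_1d(np.asarray(P[key], float))
            g = np.atleast_1d(np.asarray(grads[key], float))
            idx = (0,) * arr.ndim
            h = 1e-6
            Q = {k: np.array(v, float, copy=True) for k, v in P.items()}
            q = np.atleast_1d(Q[key]); q[idx] += h; Q[key] = q.reshape(np.shape(P[key]))
            hi, _, _, _ = _elbo_and_grads(batch, Q, eps, 1.0, "sigmoid", "linear")
            Q = {k: np.array(v, float, copy=True) for k, v in P.items()}
            q = np.atleast_1d(Q[key]); q[idx] -= h; Q[key] = q.reshape(np.shape(P[key]))
            lo, _, _, _ = _elbo_and_grads(batch, Q, eps, 1.0, "sigmoid", "linear")
            fd = (hi - lo) / (2 * h)
            assert abs(fd - g[idx]) / max(1.0, abs(fd)) < 1e-4


class TestMaskingAndContracts:
    def test_absent_blocks_never_enter_the_objective(self):
        """The flattened batch carries rows only for present blocks, so absent
        measurements cannot influence the objective by construction."""
        rng = np.random.default_rng(2)
        schema, cohort = tiny_cohort(rng)
        std = Standardizer.fit(cohort, schema)
        batch = _Batch(cohort, schema, std, 0.1)
        n_present = {m: sum(v.blocks.get(m) is not None
                            for s in cohort for v in s.visits)
                     for m in schema.names}
        for m in schema.names:
            assert batch.Xv[m].shape[0] == n_present[m]
        # and masking one modality changes the ELBO only through its own term
        P = _init_params(batch, "affine")
        eps = np.zeros((batch.N, schema.M))
        masked = [ObservationSet(s.subject_id,
                                 [Visit(v.time, dict(v.blocks, b=None), v.diagnosis)
                                  if i == 2 else v
                                  for i, v in enumerate(s.visits)])
                  for s in cohort]
        bm = _Batch(masked, schema, std, 0.1)
        full, _, _, _ = _elbo_and_grads(batch, P, eps, 0.0, "affine")
        part, _, _, _ = _elbo_and_grads(bm, P, eps, 0.0, "affine")
        assert not math.isclose(full, part)  # the dropped term was real

    def test_subject_without_complete_visit_rejected(self):
        schema = ModalitySchema(names=("a", "b"), dims=(1, 1))
        s = ObservationSet("x", [Visit(0.0, {"a": np.array([1.0]), "b": None})])
        with pytest.raises(ValueError, match="x"):
            elbo_subject_check(s, schema)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            fit([], TrainingConfig(epochs=1))


def elbo_subject_check(subject, schema):
    _Batch([subject], schema, Standardizer.identity(schema), 0.1)


class TestElbo:
    def make_model(self, k, schema):
        return FittedModel(
            schema=schema,
            standardizer=Standardizer.identity(schema),
            encoder=EncoderParams(weights={"m": np.array([1.0])}, biases={"m": 0.0},
                                  log_scales={"m": math.log(0.05)},
                                  squash="softplus"),
            decoder=DecoderParams(loadings={"m": np.array([1.0])},
                                  offsets={"m": np.array([0.0])},
                                  log_sigma2={"m": math.log(0.05**2)}),
            dynamics=DynamicsParams(W=np.array([[k]])),
            config=TrainingConfig(),
            final_elbo=0.0,
        )

    def test_single_visit_elbo_is_loglik_minus_kl(self):
        """With one visit there is no integration: ELBO(eps=0) decomposes."""
        schema = ModalitySchema(names=("m",), dims=(1,))
        model = self.make_model(0.3, schema)
        x = np.array([0.4])
        subject = ObservationSet("s", [Visit(0.0, {"m": x})])
        batch = _Batch([subject], schema, model.standardizer, 0.1)
        P = _params_to_dict(model.encoder, model.decoder, model.dynamics, schema)
        val, recon, kl, _ = _elbo_and_grads(batch, P, np.zeros((1, 1)), 1.0,
                                            "affine", "softplus")
        from adcascade.observation import _squash, log_likelihood

        pre = float(x[0])  # identity encoder
        z = _squash(np.array([pre]), "softplus")
        ll = log_likelihood({"m": x}, z, model.decoder, schema)
        s = 0.05
        kl_manual = 0.5 * (pre**2 + s**2 - 1.0 - 2.0 * math.log(s))
        assert abs(recon - ll) < 1e-10
        assert abs(kl - kl_manual) < 1e-10
        assert abs(val - (ll - kl_manual)) < 1e-10

    def test_mc_variance_shrinks_with_samples(self):
        schema = ModalitySchema(names=("m",), dims=(1,))
        model = self.make_model(0.3, schema)
        subject = ObservationSet("s", [Visit(t, {"m": np.array([0.1 + 0.1 * t])})
                                       for t in (0.0, 1.0, 2.0)])
        def spread(mc):
            vals = [elbo(subject, model, mc_samples=mc,
                         rng=np.random.default_rng(seed)) for seed in range(40)]
            return np.std(vals)
        assert spread(16) < spread(1)

    def test_generating_rate_beats_doubled_rate(self):
        """The ELBO prefers the generating k over 2k in >=95% of 100 seeds."""
        schema = ModalitySchema(names=("m",), dims=(1,))
        k = 0.3
        true_model = self.make_model(k, schema)
        wrong_model = self.make_model(2 * k, schema)
        grid = np.arange(0.0, 6.0 + 1e-9, 1.0)
        wins = 0
        for s in range(100):
            rng = np.random.default_rng(1000 + s)
            z0 = rng.uniform(0.1, 0.4)
            zt = integrate(np.array([z0]), 0.0, grid,
                           DynamicsParams(W=np.array([[k]]))).states[:, 0]
            subject = ObservationSet(
                f"s{s}",
                [Visit(float(t), {"m": np.array([zv + rng.normal(0, 0.05)])})
                 for t, zv in zip(grid, zt)],
            )
            et = elbo(subject, true_model, mc_samples=8, rng=np.random.default_rng(s))
            ew = elbo(subject, wrong_model, mc_samples=8, rng=np.random.default_rng(s))
            wins += et > ew
        assert wins >= 95


class TestFit:
    def test_same_seed_reproduces_training_bitwise(self):
        config = dataclasses.replace(canonical_config(seed=7), n_subjects=25)
        cohort, _ = generate(config)
        tc = TrainingConfig(epochs=40, seed=3, encoder_squash="softplus")
        m1 = fit(cohort, tc)
        m2 = fit(cohort, tc)
        assert np.array_equal(m1.dynamics.W, m2.dynamics.W)
        assert m1.history.equals(m2.history)
        for m in config.schema.names:
            assert np.array_equal(m1.encoder.weights[m], m2.encoder.weights[m])
            assert m1.decoder.log_sigma2[m] == m2.decoder.log_sigma2[m]

    def test_coupling_ablation_hurts_heldout_reconstruction(self):
        """Data generated WITH couplings is reconstructed worse when the fit
        pins the couplings to zero (paired over 3 replicates)."""
        schema = ModalitySchema(names=("amy", "met", "atr", "cli"), dims=(1, 1, 1, 1))
        W = np.diag([0.35, 0.25, 0.25, 0.30])
        W[1, 0], W[2, 1], W[3, 2] = 0.15, 0.10, 0.10
        base = dict(
            schema=schema, W=W,
            loadings={n: np.array([1.0]) for n in schema.names},
            offsets={n: np.array([0.0]) for n in schema.names},
            sigmas={n: 0.08 for n in schema.names},
            anchor_state=np.array([0.12, 0.015, 0.01, 0.005]),
            n_subjects=80, missing_rates={}, stage_thresholds=(0.2, 1.2),
        )
        wins = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for rep in range(3):
                cohort, _ = generate(GeneratorConfig(**base, seed=100 + rep))
                held, _ = generate(GeneratorConfig(**base, seed=200 + rep))
                tc = TrainingConfig(epochs=400, seed=rep, encoder_squash="softplus")
                full = fit(cohort, tc)
                nocp = fit(cohort, dataclasses.replace(tc, coupling_prior_sd=1e-4))
                assert np.abs(nocp.dynamics.couplings).max() < 1e-2

                def heldout_recon(model):
                    b = _Batch(held, schema, model.standardizer, model.config.step)
                    P = _params_to_dict(model.encoder, model.decoder,
                                        model.dynamics, schema)
                    _, rec, _, _ = _elbo_and_grads(
                        b, P, np.zeros((b.N, schema.M)), 0.0,
                        model.decoder.link, model.encoder.squash)
                    return rec

                wins += heldout_recon(full) > heldout_recon(nocp)
        assert wins >= 2

    def test_encoded_baselines_track_generating_latents(self, canonical_cohort,
                                                        canonical_model):
        """Parameter-recovery surrogate: encoded baseline z-scores correlate
        with the generating latents at r > 0.95 per coordinate."""
        config, cohort, truth = canonical_cohort
        Z = canonical_model.baseline_latents(cohort)
        for i, name in enumerate(config.schema.names):
            zt = truth.table[f"z_{name}_baseline"].to_numpy()
            assert np.corrcoef(zt, Z[:, i])[0, 1] > 0.95

    def test_reload_reproduces_model_outputs(self, tmp_path, canonical_model):
        from adcascade.io import load_model, save_model
        from adcascade.dynamics import vector_field

        path = tmp_path / "model.json"
        save_model(canonical_model, path)
        again = load_model(path)
        z = np.array([0.3, 0.2, 0.15, 0.1])
        np.testing.assert_array_equal(
            vector_field(z, canonical_model.dynamics), vector_field(z, again.dynamics)
        )
        blocks = {m: np.linspace(0.1, 0.4, canonical_model.schema.dim(m))
                  for m in canonical_model.schema.names}
        np.testing.assert_array_equal(
            canonical_model.encode_visit(blocks).mean, again.encode_visit(blocks).mean
        )
        np.testing.assert_array_equal(
            canonical_model.decode_latent(z)["cli"], again.decode_latent(z)["cli"]
        )
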