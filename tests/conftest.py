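"""Shared fixtures: the canonical synthetic cohort, one fitted model, and the
downstream long-term reference, built once per session (the fit dominates the
suite's runtime)."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from adcascade.inference import TrainingConfig, fit
from adcascade.longterm import build_reference, fit_mixture, sample_ensemble
from adcascade.synthetic import canonical_config, generate

#: the training configuration used for every canonical-cohort fit
CANONICAL_FIT = TrainingConfig(epochs=2000, seed=0, encoder_squash="softplus")


@pytest.fixture(scope="session")
def canonical_cohort():
    config = canonical_config(seed=0)
    cohort, truth = generate(config)
    return config, cohort, truth


@pytest.fixture(scope="session")
def canonical_model(canonical_cohort):
    _, cohort, _ = canonical_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit(cohort, CANONICAL_FIT)


@pytest.fixture(scope="session")
def canonical_pipeline(canonical_cohort, canonical_model):
    """Mixture over AD latents, the projected ensemble and anchored reference."""
    _, cohort, _ = canonical_cohort
    model = canonical_model
    ad = [s for s in cohort if s.visits[0].diagnosis == "AD"]
    rng = np.random.default_rng(0)
    mix = fit_mixture(model.baseline_latents(ad), rng=rng)
    grid = np.arange(-30.0, 10.0 + 1e-9, 0.1)
    ensemble = sample_ensemble(mix, 1000, model.dynamics, grid, rng=rng)
    ref = build_reference(ensemble, ("threshold", "cli", 0.5), schema=model.schema)
    return {"mixture": mix, "reference": ref, "ensemble": ensemble}
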