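"""Synthetic longitudinal cohort generator with known ground truth.

Emulates an ADNI-like amyloid-positive cohort: each subject is a window onto
one common long-term disease course.  A subject's *time-shift* (how far along
the disease they are at baseline) is drawn uniformly; short irregular
follow-up visits are sampled; the true coupled-logistic latent trajectory is
decoded into modality blocks with Gaussian noise; follow-up modalities drop
out at random (baseline is always complete, as model estimation requires);
and five clinical-group labels (NL stable/converter, MCI stable/converter,
AD) are assigned from the true clinical z-score via fixed thresholds, with
converter status read off the last follow-up visit.

The canonical configuration (see :func:`canonical_config`) is the fixture all
package-level experiments run on: reduced 2/2/2/2 feature dimensions for
speed, a positive coupling chain amy -> met -> atr -> cli reproducing the
amyloid-cascade ordering (amyloid saturates first, clinical score accelerates
last).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import DynamicsParams, integrate
from .observation import (
    ModalitySchema,
    ObservationSet,
    Visit,
    _link,
)

__all__ = ["GeneratorConfig", "GroundTruth", "generate", "canonical_config", "canonical_dynamics"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth parameters and sampling plan for a synthetic cohort.

    Noise ``sigmas`` are standard deviations on the observation scale; the
    ``stage_thresholds`` (theta_mci, theta_ad) cut the true clinical z-score
    into NL / MCI / AD states.  ``time_shift_span`` is the width (years) of
    the uniform baseline time-shift distribution along the disease course.
    """

    schema: ModalitySchema
    W: np.ndarray
    loadings: dict[str, np.ndarray]
    offsets: dict[str, np.ndarray]
    link: str = "affine"
    sigmas: dict[str, float] = field(default_factory=dict)
    n_subjects: int = 300
    anchor_state: np.ndarray = field(default_factory=lambda: np.array([0.12, 0.015, 0.01, 0.005]))
    time_shift_span: float = 25.0
    visit_count_range: tuple[int, int] = (1, 8)
    visit_spacing_mean: float = 1.0
    visit_spacing_sd: float = 0.2
    min_spacing: float = 0.3
    max_followup: float = 16.0
    missing_rates: dict[str, float] = field(default_factory=dict)
    stage_thresholds: tuple[float, float] = (0.20, 1.20)
    seed: int = 0

    def validate(self) -> None:
        M = self.schema.M
        W = np.asarray(self.W, dtype=float)
        if W.shape != (M, M):
            raise ValueError("W shape must match the schema")
        if np.asarray(self.anchor_state).shape != (M,):
            raise ValueError("anchor_state must be an M-vector")
        lo, hi = self.visit_count_range
        if not (1 <= lo <= hi):
            raise ValueError("visit_count_range must satisfy 1 <= lo <= hi")
        if not 0 <= self.max_followup <= 16.0:
            raise ValueError("follow-up span must lie within 0-16 years")
        for n in self.schema.names:
            if self.missing_rates.get(n, 0.0) >= 1.0 or self.missing_rates.get(n, 0.0) < 0.0:
                raise ValueError("missingness rates must lie in [0, 1)")
            if self.sigmas.get(n, 0.0) < 0.0:
                raise ValueError("noise sd must be non-negative")
        if not self.stage_thresholds[0] < self.stage_thresholds[1]:
            raise ValueError("stage thresholds must be increasing")


@dataclass
class GroundTruth:
    """Per-subject generating quantities (the test oracle).

    ``table`` columns: subject_id, time_shift (years along the disease
    course at baseline), stage (one of the five group labels), z_<m>_baseline
    per modality.  ``latents`` maps subject_id to the true latent states at
    each visit, ``config`` is the generating configuration.
    """

    table: pd.DataFrame
    latents: dict[str, np.ndarray]
    config: GeneratorConfig


def _stage_state(z_cli: float, thresholds: tuple[float, float]) -> str:
    if z_cli < thresholds[0]:
        return "NL"
    if z_cli < thresholds[1]:
        return "MCI"
    return "AD"


def _group_label(base: str, last: str) -> str:
    """Five-group label from baseline and last-visit disease states."""
    if base == "AD":
        return "AD"
    if base == "MCI":
        return "MCI converter" if last == "AD" else "MCI stable"
    return "NL stable" if last == "NL" else "NL converter"


def generate(config: GeneratorConfig) -> tuple[list[ObservationSet], GroundTruth]:
    """Sample a cohort and its ground truth from ``config`` (fully seeded)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    schema = config.schema
    params = DynamicsParams(W=config.W)

    # one master latent course, interpolated per subject at visit times
    horizon = config.time_shift_span + config.max_followup + 1.0
    grid = np.arange(0.0, horizon + 1e-9, 0.05)
    course = integrate(np.asarray(config.anchor_state, float), 0.0, grid, params).states

    cohort: list[ObservationSet] = []
    rows = []
    latents: dict[str, np.ndarray] = {}
    for i in range(config.n_subjects):
        sid = f"S{i:04d}"
        shift = rng.uniform(0.0, config.time_shift_span)
        lo, hi = config.visit_count_range
        n_vis = int(rng.integers(lo, hi + 1))
        gaps = np.maximum(
            rng.normal(config.visit_spacing_mean, config.visit_spacing_sd, size=n_vis - 1),
            config.min_spacing,
        )
        offsets = np.concatenate([[0.0], np.cumsum(gaps)])
        offsets = offsets[offsets <= config.max_followup]
        times = shift + offsets

        z = np.stack([np.interp(times, grid, course[:, m]) for m in range(schema.M)], axis=1)
        latents[sid] = z

        visits = []
        for j, t in enumerate(times):
            blocks: dict[str, np.ndarray | None] = {}
            for mi, name in enumerate(schema.names):
                absent = (
                    j > 0
                    and rng.uniform() < config.missing_rates.get(name, 0.0)
                )
                if absent:
                    blocks[name] = None
                    continue
                u = _link(z[j, mi], config.link)
                mu = u * config.loadings[name] + config.offsets[name]
                noise = rng.normal(0.0, config.sigmas.get(name, 0.0), size=schema.dim(name))
                blocks[name] = mu + noise
            visits.append(Visit(time=float(offsets[j]), blocks=blocks))

        icli = schema.index("cli")
        base_state = _stage_state(z[0, icli], config.stage_thresholds)
        last_state = _stage_state(z[-1, icli], config.stage_thresholds)
        label = _group_label(base_state, last_state)
        for v in visits:
            v.diagnosis = label

        subj = ObservationSet(subject_id=sid, visits=visits)
        subj.validate(schema)
        cohort.append(subj)
        rows.append(
            {"subject_id": sid, "time_shift": shift, "stage": label}
            | {f"z_{n}_baseline": z[0, schema.index(n)] for n in schema.names}
        )

    truth = GroundTruth(table=pd.DataFrame(rows), latents=latents, config=config)
    return cohort, truth


def canonical_dynamics() -> DynamicsParams:
    """The frozen ground-truth coupled-logistic system of the canonical cohort.

    Rates k = (0.35, 0.25, 0.25, 0.30)/year for (amy, met, atr, cli) and a
    positive coupling chain amy->met, amy->atr, met->atr, met->cli, atr->cli,
    giving the cascade ordering: amyloid saturates first, clinical last.
    """
    W = np.zeros((4, 4))
    np.fill_diagonal(W, [0.35, 0.25, 0.25, 0.30])
    W[1, 0] = 0.15  # amy -> met
    W[2, 0] = 0.05  # amy -> atr
    W[2, 1] = 0.10  # met -> atr
    W[3, 1] = 0.05  # met -> cli
    W[3, 2] = 0.05  # atr -> cli
    return DynamicsParams(W=W)


def _reduced_schema() -> ModalitySchema:
    return ModalitySchema(names=("amy", "met", "atr", "cli"), dims=(2, 2, 2, 2))


def canonical_config(full_dims: bool = False, n_subjects: int = 300, seed: int = 0) -> GeneratorConfig:
    """The frozen canonical synthetic-cohort configuration.

    Reduced 2-dimensional blocks by default; ``full_dims=True`` switches to
    the 41/41/41/7 schema with seeded per-feature loadings for integration
    tests.  Two calls with equal arguments return identical configs.
    """
    if full_dims:
        from .observation import canonical_schema

        schema = canonical_schema()
        lrng = np.random.default_rng(20240117)
        loadings = {n: lrng.uniform(0.7, 1.3, size=schema.dim(n)) for n in schema.names}
        offsets = {n: lrng.uniform(-0.2, 0.2, size=schema.dim(n)) for n in schema.names}
    else:
        schema = _reduced_schema()
        loadings = {n: np.array([0.9, 1.1]) for n in schema.names}
        offsets = {n: np.array([-0.1, 0.1]) for n in schema.names}
    return GeneratorConfig(
        schema=schema,
        W=canonical_dynamics().W,
        loadings=loadings,
        offsets=offsets,
        link="affine",
        sigmas={n: 0.08 for n in schema.names},
        n_subjects=n_subjects,
        anchor_state=np.array([0.12, 0.015, 0.01, 0.005]),
        time_shift_span=25.0,
        visit_count_range=(1, 8),
        visit_spacing_mean=1.0,
        visit_spacing_sd=0.2,
        min_spacing=0.3,
        max_followup=16.0,
        missing_rates={"amy": 0.3, "met": 0.3, "atr": 0.3, "cli": 0.1},
        stage_thresholds=(0.20, 1.20),
        seed=seed,
    )
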