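"""Long-term reference disease trajectory.

Short-term follow-up only covers a few years per subject; the long-term
course is reconstructed by projecting the AD subjects into the latent space,
fitting a Gaussian mixture to their latent distribution (components and
covariance structure selected by AIC), sampling anchor states from it, and
integrating each backward and forward in time.  The pointwise mean +/- sd of
the resulting trajectory ensemble is the reference curve; its time axis is
shifted so that t = 0 marks conversion to AD dementia (by default the mean
staging time of MCI-converter subjects; a clinical-score threshold crossing
is the fallback for pure simulation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

from .dynamics import (
    DynamicsParams,
    IntegrationDivergedError,
    Trajectory,
    integrate,
    vector_field,
)
from .observation import DecoderParams, ModalitySchema

__all__ = [
    "LatentMixture",
    "ReferenceTrajectory",
    "fit_mixture",
    "disease_course",
    "project_onto_course",
    "sample_ensemble",
    "build_reference",
    "decode_reference",
]

STRUCTURES = ("full", "diagonal", "tied", "spherical")


@dataclass(frozen=True)
class LatentMixture:
    """Gaussian mixture over pathological latent states.

    Covariances are stored in full form regardless of the fitted structure;
    ``structure``, ``n_components`` and the achieved ``aic`` record the
    AIC-selected candidate.
    """

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    structure: str
    n_components: int
    aic: float

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("mixture weights must be positive and sum to 1")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` latent states (seeded; handles degenerate covariances)."""
        comp = rng.choice(self.n_components, size=n, p=self.weights)
        M = self.means.shape[1]
        out = np.empty((n, M))
        for c in range(self.n_components):
            sel = comp == c
            if not sel.any():
                continue
            cov = self.covariances[c]
            try:
                L = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                vals, vecs = np.linalg.eigh(cov)
                L = vecs * np.sqrt(np.clip(vals, 0.0, None))
            out[sel] = self.means[c] + rng.standard_normal((int(sel.sum()), M)) @ L.T
        return out


@dataclass(frozen=True)
class ReferenceTrajectory:
    """Ensemble mean +/- sd latent curve on a grid anchored at conversion (t=0).

    ``members`` retains the individual latent trajectories (n, T, M) so that
    decoded uncertainty bands can be computed on the decoded ensemble rather
    than by linearization.  ``anchor_delta`` is the time translation applied
    by the anchor rule.
    """

    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    members: np.ndarray | None = None
    anchor_delta: float = 0.0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if not (t.min() < 0.0 <= t.max()):
            raise ValueError("reference grid must cover both sides of t=0")
        if np.any(np.asarray(self.sd) < 0):
            raise ValueError("sd must be non-negative")

    @property
    def n_members(self) -> int:
        return 0 if self.members is None else self.members.shape[0]


def _n_mixture_params(k: int, M: int, structure: str) -> int:
    cov = {"full": k * M * (M + 1) // 2, "diagonal": k * M,
           "tied": M * (M + 1) // 2, "spherical": k}[structure]
    return (k - 1) + k * M + cov


def fit_mixture(
    latents: np.ndarray,
    component_range: range | tuple = range(1, 6),
    structure_set: tuple[str, ...] = STRUCTURES,
    rng: np.random.Generator | int | None = None,
) -> LatentMixture:
    """AIC-selected Gaussian mixture over latent states.

    Enumerates every (component count, covariance structure) candidate,
    fits each by EM, and keeps the one minimizing AIC = 2p - 2 log L-hat;
    exact ties break toward fewer free parameters.  Candidates that fail to
    fit (singular covariance) are skipped with a warning.
    """
    X = np.asarray(latents, dtype=float)
    if X.ndim != 2 or X.shape[0] < X.shape[1] + 1:
        raise ValueError("need at least M+1 latent points")
    comps = list(component_range)
    if not comps:
        raise ValueError("component_range is empty")
    seed = rng if isinstance(rng, int) else (
        int(rng.integers(2**31)) if isinstance(rng, np.random.Generator) else 0
    )
    candidates = []
    import warnings

    for k in comps:
        for structure in structure_set:
            sk_cov = "diag" if structure == "diagonal" else structure
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    gm = GaussianMixture(
                        n_components=k, covariance_type=sk_cov,
                        random_state=seed, n_init=2, reg_covar=1e-9,
                    ).fit(X)
                aic = float(gm.aic(X))
            except (ValueError, np.linalg.LinAlgError) as err:
                warnings.warn(f"mixture candidate k={k} {structure} skipped: {err}")
                continue
            if not np.isfinite(aic):
                continue
            candidates.append((aic, _n_mixture_params(k, X.shape[1], structure), k, structure, gm))
    if not candidates:
        raise RuntimeError("every mixture candidate failed to fit")
    aic, _, k, structure, gm = min(candidates, key=lambda c: (c[0], c[1]))
    M = X.shape[1]
    cov = gm.covariances_
    if structure == "full":
        full = cov
    elif structure == "diagonal":
        full = np.stack([np.diag(c) for c in cov])
    elif structure == "tied":
        full = np.stack([cov] * k)
    else:  # spherical
        full = np.stack([np.eye(M) * c for c in cov])
    return LatentMixture(
        weights=gm.weights_, means=gm.means_, covariances=full,
        structure=structure, n_components=k, aic=aic,
    )


def disease_course(
    params: DynamicsParams,
    step: float = 0.1,
    horizon: float = 150.0,
    seed_state: np.ndarray | None = None,
) -> Trajectory:
    """The model's long-term disease course (healthy state -> attractor).

    Integrates forward from a small near-origin state (default ``1e-3`` in
    every coordinate), tracing the heteroclinic orbit that connects the
    healthy fixed point to the pathological attractor.  Forward integration
    is numerically stable everywhere along it; its time parametrization is
    internal (only differences matter).  The plateau is trimmed once the
    field magnitude drops below ``1e-4``/year so that states beyond the
    attractor project to the end of the active course rather than to an
    arbitrarily long flat tail.
    """
    from .dynamics import rk4_step

    M = params.M
    z = np.full(M, 1e-3) if seed_state is None else np.asarray(seed_state, float)
    states = [z]
    n_steps = int(round(horizon / step))
    for _ in range(n_steps):
        z = rk4_step(z, step, params)
        # truncate if the fitted system has no bounded attractor along the orbit
        if not np.all(np.isfinite(z)) or np.abs(z).max() > 10.0:
            break
        states.append(z)
    traj = Trajectory(times=np.arange(len(states)) * step, states=np.asarray(states))
    speed = np.abs(vector_field(traj.states, params)).sum(axis=1)
    moving = np.nonzero(speed >= 1e-4)[0]
    if len(moving) and moving[-1] + 2 < len(traj):
        end = int(moving[-1]) + 2  # keep one settled point past the active course
        traj = Trajectory(times=traj.times[:end], states=traj.states[:end])
    return traj


def project_onto_course(states: np.ndarray, course: Trajectory) -> np.ndarray:
    """Course time of each state: argmin_s of the L1 distance to the course.

    ``states`` is (B, M); returns (B,) times on the course's internal axis.
    Chunked so that large batches stay within memory.
    """
    states = np.atleast_2d(np.asarray(states, float))
    C = course.states  # (S, M)
    out = np.empty(len(states))
    chunk = max(1, int(2e7 // max(C.size, 1)))
    for i in range(0, len(states), chunk):
        d = np.abs(states[i:i + chunk, None, :] - C[None, :, :]).sum(axis=2)
        out[i:i + chunk] = course.times[np.argmin(d, axis=1)]
    return out


def _course_at(course: Trajectory, s: np.ndarray) -> np.ndarray:
    """Course states at (possibly out-of-range) times, clamped to endpoints."""
    s = np.clip(np.asarray(s, float), course.times[0], course.times[-1])
    out = np.empty(s.shape + (course.states.shape[1],))
    for m in range(course.states.shape[1]):
        out[..., m] = np.interp(s, course.times, course.states[:, m])
    return out


def sample_ensemble(
    mix: LatentMixture,
    n: int,
    params: DynamicsParams,
    t_grid: np.ndarray,
    rng: np.random.Generator | int = 0,
    anchor_time: float = 0.0,
    step: float = 0.1,
    method: str = "projected",
) -> list[Trajectory]:
    """Extend ``n`` mixture draws backward and forward over ``t_grid``.

    Every draw is anchored at ``anchor_time``.  With the default
    ``method='projected'`` each draw is positioned on the model's disease
    course by L1 projection and carried along the flow in both directions —
    numerically stable for any horizon, because reversing the exact flow
    from an off-course state is exponentially ill-posed (noise components
    transverse to the orbit grow like exp(k t) backward and the quadratic
    field then diverges in finite time).  ``method='exact'`` integrates each
    raw draw backward/forward directly and propagates any blow-up.
    Reproducible given the rng seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if method not in ("projected", "exact"):
        raise ValueError("method must be 'projected' or 'exact'")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    z0 = mix.sample(n, rng)  # (n, M)
    t_grid = np.asarray(t_grid, float)
    if method == "exact":
        try:
            traj = integrate(z0, anchor_time, t_grid, params, step=step)
        except IntegrationDivergedError as err:
            raise IntegrationDivergedError(err.time) from err
        return [Trajectory(times=traj.times, states=traj.states[:, i, :]) for i in range(n)]
    course = disease_course(params, step=step)
    tau = project_onto_course(z0, course)  # (n,)
    # member i at grid time t sits at course time tau_i + (t - anchor_time)
    s = tau[:, None] + (t_grid[None, :] - anchor_time)  # (n, T)
    states = _course_at(course, s)  # (n, T, M)
    return [Trajectory(times=t_grid, states=states[i]) for i in range(n)]


def build_reference(
    ensemble: list[Trajectory],
    anchor_rule: tuple | float = ("threshold", "cli", 0.5),
    schema: ModalitySchema | None = None,
) -> ReferenceTrajectory:
    """Pointwise mean/sd across the ensemble, time-anchored at conversion.

    ``anchor_rule`` is either an explicit shift ``delta`` (years; e.g. the
    mean staging time of MCI converters at diagnosis, computed with
    :mod:`adcascade.staging`), or ``("threshold", modality, value)``: t = 0
    is placed where the ensemble-mean coordinate first crosses ``value``.
    """
    if not ensemble:
        raise ValueError("ensemble is empty")
    t0 = ensemble[0].times
    for tr in ensemble[1:]:
        if len(tr.times) != len(t0) or not np.allclose(tr.times, t0):
            raise ValueError("all ensemble trajectories must share a time grid")
    members = np.stack([tr.states for tr in ensemble])  # (n, T, M)
    mean = members.mean(axis=0)
    sd = members.std(axis=0)
    if isinstance(anchor_rule, (int, float)):
        delta = float(anchor_rule)
    else:
        kind, name, value = anchor_rule
        if kind != "threshold":
            raise ValueError(f"unknown anchor rule {anchor_rule!r}")
        mi = schema.index(name) if schema is not None else ("amy", "met", "atr", "cli").index(name)
        above = mean[:, mi] >= value
        if not above.any():
            raise ValueError(f"mean {name} trajectory never reaches {value}")
        delta = float(t0[int(np.argmax(above))])
    return ReferenceTrajectory(
        times=t0 - delta, mean=mean, sd=sd, members=members, anchor_delta=delta
    )


def decode_reference(
    ref: ReferenceTrajectory,
    decoder: DecoderParams,
    schema: ModalitySchema,
    standardizer=None,
) -> dict[str, dict[str, np.ndarray]]:
    """Biomarker-space trajectories: decode each ensemble member, then aggregate.

    Returns per modality ``{"mean": (T, D_m), "sd": (T, D_m)}``; the sd is the
    spread of the decoded ensemble (not a linearization).  Falls back to
    decoding the mean curve alone (sd 0) when members were not retained.
    """
    from .observation import decode

    if ref.members is not None:
        decoded = decode(ref.members, decoder, schema)  # blocks of (n, T, D)
        out = {}
        for m in schema.names:
            block = decoded[m]
            if standardizer is not None:
                block = standardizer.inverse(m, block)
            out[m] = {"mean": block.mean(axis=0), "sd": block.std(axis=0)}
        return out
    decoded = decode(ref.mean, decoder, schema)
    out = {}
    for m in schema.names:
        block = decoded[m]
        if standardizer is not None:
            block = standardizer.inverse(m, block)
        out[m] = {"mean": block, "sd": np.zeros_like(block)}
    return out
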