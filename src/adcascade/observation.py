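"""Observation model: multimodal measurements <-> latent z-scores.

Each modality block ``x_m`` (e.g. 41 regional amyloid-PET SUVRs, or 7
neuropsychological scores) is generated independently given the latent state:

    x_m | z ~ Normal(mu_m(z_m), sigma_m^2 I)

The decoder ``mu_m`` maps the single latent coordinate of its modality to the
block (keeping every latent coordinate interpretable as one modality), as an
affine map optionally composed with a sigmoid saturation.  The encoder ``f_m``
is the reverse map, block -> one coordinate, affine, with a per-modality
posterior scale used as the amortized variational standard deviation.

All maps operate on standardized features (see :class:`Standardizer`);
clinical scores whose native polarity decreases with severity (MMSE, RAVLT
immediate/learning) are sign-flipped at ingest so that every feature increases
with pathology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModalitySchema",
    "Visit",
    "ObservationSet",
    "Standardizer",
    "EncoderParams",
    "DecoderParams",
    "EncodedVisit",
    "encode",
    "decode",
    "log_likelihood",
    "CANONICAL_CLINICAL_LABELS",
    "CANONICAL_FLIPPED_LABELS",
    "DIAGNOSIS_LABELS",
]

#: the 7 clinical scores in canonical order
CANONICAL_CLINICAL_LABELS = (
    "ADAS11",
    "MMSE",
    "RAVLT_immediate",
    "RAVLT_learning",
    "RAVLT_forgetting",
    "FAQ",
    "CDRSB",
)

#: clinical scores that decrease with severity (sign-flipped at ingest)
CANONICAL_FLIPPED_LABELS = ("MMSE", "RAVLT_immediate", "RAVLT_learning")

#: allowed diagnosis labels, healthy -> pathological
DIAGNOSIS_LABELS = ("NL stable", "NL converter", "MCI stable", "MCI converter", "AD")


@dataclass(frozen=True)
class ModalitySchema:
    """Names and dimensions of the modality blocks, in fixed order.

    ``feature_labels`` optionally names the features of a modality (used for
    the clinical block); unnamed features are labelled ``<modality>_<i>``.
    ``flips`` lists features whose native polarity decreases with severity.
    """

    names: tuple[str, ...] = ("amy", "met", "atr", "cli")
    dims: tuple[int, ...] = (41, 41, 41, 7)
    feature_labels: tuple[tuple[str, ...] | None, ...] | None = None
    flips: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.names) != len(self.dims):
            raise ValueError("names and dims must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("modality names must be unique")
        if any(d <= 0 for d in self.dims):
            raise ValueError("modality dimensions must be positive")
        if self.feature_labels is not None and len(self.feature_labels) != len(self.names):
            raise ValueError("feature_labels must align with names")

    @property
    def M(self) -> int:
        return len(self.names)

    def dim(self, name: str) -> int:
        return self.dims[self.index(name)]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def columns(self, name: str) -> list[str]:
        """CSV column labels of modality ``name``."""
        i = self.index(name)
        if self.feature_labels is not None and self.feature_labels[i] is not None:
            labels = self.feature_labels[i]
            if len(labels) != self.dims[i]:
                raise ValueError(f"feature_labels for {name} must have {self.dims[i]} entries")
            return [f"{name}_{lab}" for lab in labels]
        return [f"{name}_{j}" for j in range(self.dims[i])]

    def flip_mask(self, name: str) -> np.ndarray:
        """Boolean mask of sign-flipped features within modality ``name``."""
        cols = self.columns(name)
        return np.array([c.split(f"{name}_", 1)[1] in self.flips for c in cols])


def canonical_schema(dims: tuple[int, ...] = (41, 41, 41, 7)) -> ModalitySchema:
    """The amy/met/atr/cli schema; full dims get named clinical features."""
    labels = None
    flips: tuple[str, ...] = ()
    if dims[-1] == len(CANONICAL_CLINICAL_LABELS):
        labels = (None, None, None, CANONICAL_CLINICAL_LABELS)
        flips = CANONICAL_FLIPPED_LABELS
    return ModalitySchema(names=("amy", "met", "atr", "cli"), dims=dims,
                          feature_labels=labels, flips=flips)


@dataclass
class Visit:
    """One subject-visit: time in years, per-modality blocks (None = absent)."""

    time: float
    blocks: dict[str, np.ndarray | None]
    diagnosis: str = "NL stable"

    def is_complete(self, schema: ModalitySchema) -> bool:
        return all(self.blocks.get(n) is not None for n in schema.names)


@dataclass
class ObservationSet:
    """Longitudinal multimodal observations of one subject."""

    subject_id: str
    visits: list[Visit]

    def validate(self, schema: ModalitySchema) -> None:
        for v in self.visits:
            for name in schema.names:
                b = v.blocks.get(name)
                if b is not None and np.asarray(b).shape != (schema.dim(name),):
                    raise ValueError(
                        f"subject {self.subject_id} t={v.time}: block {name} has wrong shape"
                    )
        if self.anchor_index(schema) is None:
            raise ValueError(
                f"subject {self.subject_id} has no visit with all modalities present"
            )

    def anchor_index(self, schema: ModalitySchema) -> int | None:
        """Index of the earliest visit with every modality present."""
        order = np.argsort([v.time for v in self.visits], kind="stable")
        for i in order:
            if self.visits[i].is_complete(schema):
                return int(i)
        return None

    @property
    def times(self) -> np.ndarray:
        return np.array([v.time for v in self.visits])


@dataclass(frozen=True)
class Standardizer:
    """Per-feature centring/scaling statistics, stored per modality."""

    means: dict[str, np.ndarray]
    sds: dict[str, np.ndarray]

    @classmethod
    def fit(cls, cohort: list[ObservationSet], schema: ModalitySchema) -> "Standardizer":
        means, sds = {}, {}
        for name in schema.names:
            rows = [v.blocks[name] for s in cohort for v in s.visits
                    if v.blocks.get(name) is not None]
            X = np.asarray(rows, dtype=float)
            mu = X.mean(axis=0)
            sd = X.std(axis=0)
            sd[sd < 1e-12] = 1.0
            means[name], sds[name] = mu, sd
        return cls(means=means, sds=sds)

    def transform(self, name: str, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.means[name]) / self.sds[name]

    def inverse(self, name: str, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) * self.sds[name] + self.means[name]

    @classmethod
    def identity(cls, schema: ModalitySchema) -> "Standardizer":
        return cls(
            means={n: np.zeros(schema.dim(n)) for n in schema.names},
            sds={n: np.ones(schema.dim(n)) for n in schema.names},
        )


@dataclass
class EncoderParams:
    """Modality-wise encoders: z_m = squash(w_m . x_m + b_m).

    ``squash`` is ``'linear'`` (plain affine, the default) or ``'softplus'``
    (a monotone saturating map that floors the latent just above the unstable
    negative branch of the logistic dynamics).  ``log_scales[m]`` is the log
    posterior standard deviation of coordinate m on the pre-squash scale
    (the uncertainty head of the amortized variational family).
    """

    weights: dict[str, np.ndarray]
    biases: dict[str, float]
    log_scales: dict[str, float]
    squash: str = "linear"

    def __post_init__(self):
        if self.squash not in ("linear", "softplus"):
            raise ValueError("squash must be 'linear' or 'softplus'")


@dataclass
class DecoderParams:
    """Per-coordinate monotone decoders: mu_m(z) = a_m * s(z_m) + d_m.

    ``s`` is the identity (``link='affine'``) or the logistic sigmoid
    (``link='sigmoid'``).  ``log_sigma2[m]`` is the log Gaussian noise
    variance shared across the features of modality m.
    """

    loadings: dict[str, np.ndarray]
    offsets: dict[str, np.ndarray]
    log_sigma2: dict[str, float]

    link: str = "affine"

    def __post_init__(self):
        if self.link not in ("affine", "sigmoid"):
            raise ValueError("link must be 'affine' or 'sigmoid'")

    def sigma2(self, name: str) -> float:
        return math.exp(self.log_sigma2[name])


#: sharpness of the softplus encoder squash (effectively identity above ~0.2)
SOFTPLUS_BETA = 10.0


def _squash(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "softplus":
        return np.logaddexp(0.0, SOFTPLUS_BETA * np.asarray(x, dtype=float)) / SOFTPLUS_BETA
    return np.asarray(x, dtype=float)


def _dsquash(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "softplus":
        return 1.0 / (1.0 + np.exp(-SOFTPLUS_BETA * np.asarray(x, dtype=float)))
    return np.ones_like(np.asarray(x, dtype=float))


def _link(z: np.ndarray, link: str) -> np.ndarray:
    if link == "sigmoid":
        return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))
    return np.asarray(z, dtype=float)


def _dlink(z: np.ndarray, link: str) -> np.ndarray:
    if link == "sigmoid":
        s = _link(z, "sigmoid")
        return s * (1.0 - s)
    return np.ones_like(np.asarray(z, dtype=float))


@dataclass(frozen=True)
class EncodedVisit:
    """Encoder output: posterior mean/scale per coordinate plus presence mask.

    Coordinates of absent modalities are NaN in ``mean``/``scale`` and False
    in ``mask``; downstream sums must respect the mask.
    """

    mean: np.ndarray
    scale: np.ndarray
    mask: np.ndarray


def encode(
    blocks: dict[str, np.ndarray | None],
    params: EncoderParams,
    schema: ModalitySchema,
) -> EncodedVisit:
    """Encode available modality blocks into latent coordinates.

    Coordinate m depends only on block m; absent blocks are masked out.
    """
    M = schema.M
    mean = np.full(M, np.nan)
    scale = np.full(M, np.nan)
    mask = np.zeros(M, dtype=bool)
    for i, name in enumerate(schema.names):
        x = blocks.get(name)
        if x is None:
            continue
        x = np.asarray(x, dtype=float)
        if x.shape != (schema.dim(name),):
            raise ValueError(f"block {name} has shape {x.shape}, expected ({schema.dim(name)},)")
        pre = float(params.weights[name] @ x + params.biases[name])
        mean[i] = float(_squash(pre, params.squash))
        scale[i] = math.exp(params.log_scales[name])
        mask[i] = True
    if not mask.any():
        raise ValueError("cannot encode a visit with every modality absent")
    return EncodedVisit(mean=mean, scale=scale, mask=mask)


def decode(
    z: np.ndarray, params: DecoderParams, schema: ModalitySchema
) -> dict[str, np.ndarray]:
    """Gaussian mean blocks ``mu_m(z_m)`` for every modality.

    ``z`` may be batched ``(..., M)``; each returned block then has shape
    ``(..., D_m)``.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("latent state must be finite")
    out = {}
    for i, name in enumerate(schema.names):
        u = _link(z[..., i], params.link)
        out[name] = u[..., None] * params.loadings[name] + params.offsets[name]
    return out


def log_likelihood(
    blocks: dict[str, np.ndarray | None],
    z: np.ndarray,
    params: DecoderParams,
    schema: ModalitySchema,
) -> float:
    """Gaussian log-density of the present blocks given the latent state.

    Sum over present modalities of independent ``Normal(mu_m(z_m), sigma_m^2)``
    log-densities per feature; absent blocks contribute zero.
    """
    mu = decode(z, params, schema)
    total = 0.0
    any_present = False
    for name in schema.names:
        x = blocks.get(name)
        if x is None:
            continue
        any_present = True
        s2 = params.sigma2(name)
        if s2 <= 0:
            raise ValueError(f"noise variance for {name} must be positive")
        r = np.asarray(x, dtype=float) - mu[name]
        total += -0.5 * float(r @ r) / s2 - 0.5 * r.size * math.log(2.0 * math.pi * s2)
    if not any_present:
        raise ValueError("log_likelihood needs at least one present block")
    return total
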