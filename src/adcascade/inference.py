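"""Variational estimation of all model parameters from a longitudinal cohort.

For each subject the earliest visit with every modality present is the
encoding anchor: the modality-wise encoder produces a Gaussian posterior
q(z(t0) | X(t0)) over the latent state there, a sample of which is propagated
to every other visit time by integrating the coupled-logistic ODE forward and
backward; follow-up observations are scored under the Gaussian decoder
(absent blocks contribute nothing) and the posterior is regularized toward a
standard-normal prior.  The evidence lower bound

    ELBO = E_q[ sum_visits sum_present_m log N(x_m | mu_m(z(t)), sigma_m^2) ]
           - KL(q(z(t0)) || N(0, I))

is maximized by stochastic gradient ascent with adaptive moments (Adam).

Gradients are computed by hand-written reverse-mode differentiation through
the fixed-step RK4 integrator (discretize-then-optimize): the adjoint of one
RK4 step is assembled from vector-Jacobian products of the polynomial field
g(z) = W z - V z**2, which also yields the exact gradient with respect to W.
All subjects are integrated simultaneously on one shared step grid (visit
times are snapped to the nearest multiple of the integrator step), which is
what makes the fit fast on a single CPU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import DynamicsParams
from .observation import (
    DecoderParams,
    EncodedVisit,
    EncoderParams,
    ModalitySchema,
    ObservationSet,
    Standardizer,
    _dlink,
    _link,
    encode,
)

__all__ = ["TrainingConfig", "FittedModel", "elbo", "fit"]


@dataclass(frozen=True)
class TrainingConfig:
    """Hyper-parameters of the variational fit.

    ``batch_size=None`` uses the full cohort per gradient step (default;
    fastest with the vectorised integrator), any integer enables minibatch
    SGD.  ``kl_warmup_frac`` linearly anneals the KL weight from 0 to
    ``kl_weight`` over the first fraction of epochs.  ``tol`` stops training
    early when the relative objective change over 50 epochs falls below it
    (0 disables).  The seed controls every random draw and is recorded in
    all outputs.
    """

    learning_rate: float = 1e-2
    epochs: int = 2000
    batch_size: int | None = None
    kl_weight: float = 1.0
    kl_warmup_frac: float = 0.1
    step: float = 0.1
    mc_samples: int = 1
    seed: int = 0
    tol: float = 0.0
    grad_clip: float = 100.0
    link: str = "affine"
    encoder_squash: str = "linear"
    lr_decay: str = "cosine"
    coupling_prior_sd: float | None = 0.1
    param_avg_frac: float = 0.15

    def __post_init__(self):
        if min(self.learning_rate, self.epochs, self.step, self.mc_samples) <= 0:
            raise ValueError("learning_rate, epochs, step and mc_samples must be positive")
        if self.kl_weight < 0 or not 0 <= self.kl_warmup_frac <= 1 or self.tol < 0:
            raise ValueError("invalid KL schedule or tolerance")
        if self.lr_decay not in ("cosine", "none"):
            raise ValueError("lr_decay must be 'cosine' or 'none'")


# ---------------------------------------------------------------------------
# cohort -> flat arrays
# ---------------------------------------------------------------------------

class _Batch:
    """Cohort flattened onto one shared RK4 step grid.

    ``X0[m]``: (N, D_m) anchor blocks.  Per modality, the present follow-up
    (and anchor) observations are stacked into ``Xv[m]`` with parallel
    subject indices ``sub[m]`` and grid indices ``gi[m]``.  ``i0`` is the
    anchor position on the grid (grid index k=0).
    """

    def __init__(self, cohort, schema: ModalitySchema, std: Standardizer, h: float):
        if not cohort:
            raise ValueError("cohort is empty")
        self.schema, self.h = schema, h
        self.N = len(cohort)
        names = schema.names
        anchors, rel_steps = [], []
        for s in cohort:
            ai = s.anchor_index(schema)
            if ai is None:
                raise ValueError(f"subject {s.subject_id} has no complete visit")
            t0 = s.visits[ai].time
            anchors.append(ai)
            rel_steps.append([round((v.time - t0) / h) for v in s.visits])
        kmin = min(min(ks) for ks in rel_steps)
        kmax = max(max(ks) for ks in rel_steps)
        self.i0 = -kmin
        self.n_grid = kmax - kmin + 1
        self.X0 = {}
        self.Xv, self.sub, self.gi = {}, {}, {}
        rows_by_subject = {m: [[] for _ in range(self.N)] for m in names}
        for m in names:
            xs, subs, gis = [], [], []
            for si, s in enumerate(cohort):
                for vi, v in enumerate(s.visits):
                    b = v.blocks.get(m)
                    if b is None:
                        continue
                    rows_by_subject[m][si].append(len(xs))
                    xs.append(std.transform(m, b))
                    subs.append(si)
                    gis.append(rel_steps[si][vi] - kmin)
            self.Xv[m] = np.asarray(xs, dtype=float).reshape(len(xs), schema.dim(m))
            self.sub[m] = np.asarray(subs, dtype=int)
            self.gi[m] = np.asarray(gis, dtype=int)
            self.X0[m] = np.stack(
                [std.transform(m, cohort[si].visits[anchors[si]].blocks[m]) for si in range(self.N)]
            )
        self._rows_by_subject = rows_by_subject
        self._span_from_steps(rel_steps, kmin)

    def _span_from_steps(self, rel_steps, kmin):
        # per-subject observed span on the grid: states beyond it are frozen
        # during integration (no likelihood term lives there, and the frozen
        # identity step keeps runaway trajectories of unobserved futures from
        # contaminating the batch)
        self.first_gi = np.array([min(ks) - kmin for ks in rel_steps], dtype=int)
        self.last_gi = np.array([max(ks) - kmin for ks in rel_steps], dtype=int)

    def subset(self, idx: np.ndarray) -> "_Batch":
        """Minibatch view over a subject index subset."""
        sb = _Batch.__new__(_Batch)
        sb.schema, sb.h = self.schema, self.h
        sb.N = len(idx)
        sb.i0, sb.n_grid = self.i0, self.n_grid
        remap = {int(s): i for i, s in enumerate(idx)}
        sb.X0 = {m: self.X0[m][idx] for m in self.schema.names}
        sb.Xv, sb.sub, sb.gi = {}, {}, {}
        for m in self.schema.names:
            rows = np.concatenate(
                [self._rows_by_subject[m][int(s)] for s in idx if self._rows_by_subject[m][int(s)]]
                or [np.array([], dtype=int)]
            ).astype(int)
            sb.Xv[m] = self.Xv[m][rows]
            sb.sub[m] = np.array([remap[int(s)] for s in self.sub[m][rows]], dtype=int)
            sb.gi[m] = self.gi[m][rows]
        sb._rows_by_subject = None
        sb.first_gi = self.first_gi[idx]
        sb.last_gi = self.last_gi[idx]
        return sb


# ---------------------------------------------------------------------------
# field, RK4 step and their vector-Jacobian products
# ---------------------------------------------------------------------------

def _g(z, W, k):
    return z @ W.T - k * z * z


def _jt(z, W, k, v):
    """(dg/dz)^T v for batched z, v of shape (N, M)."""
    return v @ W - 2.0 * k * z * v


def _gw(z, v):
    """d(sum v.g)/dW for batched z, v: outer sum with the diagonal correction."""
    G = v.T @ z
    G[np.diag_indices_from(G)] -= np.einsum("nm,nm->m", v, z * z)
    return G


def _rk4(z, h, W, k):
    k1 = _g(z, W, k)
    k2 = _g(z + 0.5 * h * k1, W, k)
    k3 = _g(z + 0.5 * h * k2, W, k)
    k4 = _g(z + h * k3, W, k)
    return z + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def _rk4_vjp(z, h, W, k, lam_out):
    """Adjoint of one RK4 step: returns (dL/dz_in, dL/dW) given dL/dz_out."""
    k1 = _g(z, W, k)
    y2 = z + 0.5 * h * k1
    k2 = _g(y2, W, k)
    y3 = z + 0.5 * h * k2
    k3 = _g(y3, W, k)
    y4 = z + h * k3

    gW = np.zeros_like(W)
    m4 = (h / 6.0) * lam_out
    l4 = _jt(y4, W, k, m4)
    gW += _gw(y4, m4)
    m3 = (h / 3.0) * lam_out + h * l4
    l3 = _jt(y3, W, k, m3)
    gW += _gw(y3, m3)
    m2 = (h / 3.0) * lam_out + 0.5 * h * l3
    l2 = _jt(y2, W, k, m2)
    gW += _gw(y2, m2)
    m1 = (h / 6.0) * lam_out + 0.5 * h * l2
    l1 = _jt(z, W, k, m1)
    gW += _gw(z, m1)
    return lam_out + l1 + l2 + l3 + l4, gW


# ---------------------------------------------------------------------------
# ELBO forward + reverse pass
# ---------------------------------------------------------------------------

def _elbo_and_grads(batch: _Batch, P: dict, eps: np.ndarray, beta: float, link: str,
                    squash: str = "linear"):
    """One-sample ELBO and its exact gradients for a preprocessed batch.

    Returns ``(elbo, recon, kl, grads)`` with ``grads`` holding dELBO/dtheta
    for every entry of the parameter dict ``P``.  With the softplus squash
    the posterior sample is ``squash(pre + s*eps)`` and prior and posterior
    live on the pre-squash scale, where the KL is the usual Gaussian one.
    """
    from .observation import _dsquash, _squash

    names = batch.schema.names
    M = batch.schema.M
    W = P["W"]
    kdiag = np.diag(W).copy()
    h, i0, n_grid, N = batch.h, batch.i0, batch.n_grid, batch.N

    pre = np.stack([batch.X0[m] @ P[f"w_{m}"] + P[f"b_{m}"] for m in names], axis=1)
    s = np.exp(P["log_s"])  # (M,)
    u0 = pre + s * eps
    z0 = _squash(u0, squash)

    Z = np.empty((n_grid, N, M))
    Z[i0] = z0
    for i in range(i0, n_grid - 1):
        alive = (batch.last_gi > i)[:, None]
        Z[i + 1] = np.where(alive, _rk4(Z[i], h, W, kdiag), Z[i])
    for i in range(i0, 0, -1):
        alive = (batch.first_gi < i)[:, None]
        Z[i - 1] = np.where(alive, _rk4(Z[i], -h, W, kdiag), Z[i])

    recon = 0.0
    dZ = np.zeros_like(Z)
    grads = {key: np.zeros_like(val) for key, val in P.items()}
    for mi, m in enumerate(names):
        if batch.Xv[m].shape[0] == 0:
            continue
        a, d = P[f"a_{m}"], P[f"d_{m}"]
        s2 = math.exp(P[f"ls2_{m}"])
        zv = Z[batch.gi[m], batch.sub[m], mi]
        u = _link(zv, link)
        resid = batch.Xv[m] - (u[:, None] * a + d)
        recon += -0.5 * float(np.sum(resid * resid)) / s2 \
            - 0.5 * resid.size * math.log(2.0 * math.pi * s2)
        # decoder gradients
        rs = resid / s2
        grads[f"a_{m}"] += rs.T @ u
        grads[f"d_{m}"] += rs.sum(axis=0)
        grads[f"ls2_{m}"] += 0.5 * float(np.sum(resid * resid)) / s2 - 0.5 * resid.size
        dzv = (rs @ a) * _dlink(zv, link)
        np.add.at(dZ, (batch.gi[m], batch.sub[m], np.full(len(zv), mi)), dzv)

    gW = np.zeros_like(W)
    lam = dZ[n_grid - 1].copy()
    for i in range(n_grid - 2, i0 - 1, -1):
        # frozen subjects (beyond their own span) took an identity step:
        # their adjoint passes through unchanged and contributes no gW
        act = (batch.last_gi > i)[:, None] * lam
        lam_new, gWi = _rk4_vjp(Z[i], h, W, kdiag, act)
        gW += gWi
        lam = lam_new + (lam - act) + dZ[i]
    lam0 = lam  # includes dZ[i0]
    if i0 > 0:
        lam_b = dZ[0].copy()
        for i in range(1, i0 + 1):
            act = (batch.first_gi < i)[:, None] * lam_b
            lam_new, gWi = _rk4_vjp(Z[i], -h, W, kdiag, act)
            gW += gWi
            lam_b = lam_new + (lam_b - act)
            if i < i0:
                lam_b += dZ[i]
        lam0 = lam0 + lam_b
    grads["W"] += gW

    kl = 0.5 * float(np.sum(pre * pre) + N * np.sum(s * s - 1.0 - 2.0 * P["log_s"]))
    du0 = lam0 * _dsquash(u0, squash)
    dpre = du0 - beta * pre
    ds = (du0 * eps).sum(axis=0) - beta * N * (s - 1.0 / s)
    grads["log_s"] += ds * s
    for mi, m in enumerate(names):
        grads[f"w_{m}"] += batch.X0[m].T @ dpre[:, mi]
        grads[f"b_{m}"] += dpre[:, mi].sum()

    return recon - beta * kl, recon, kl, grads


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

def _params_to_dict(enc: EncoderParams, dec: DecoderParams, dyn: DynamicsParams,
                    schema: ModalitySchema) -> dict:
    P = {"W": np.array(dyn.W, dtype=float),
         "log_s": np.array([enc.log_scales[m] for m in schema.names], dtype=float)}
    for m in schema.names:
        P[f"w_{m}"] = np.array(enc.weights[m], dtype=float)
        P[f"b_{m}"] = np.float64(enc.biases[m])
        P[f"a_{m}"] = np.array(dec.loadings[m], dtype=float)
        P[f"d_{m}"] = np.array(dec.offsets[m], dtype=float)
        P[f"ls2_{m}"] = np.float64(dec.log_sigma2[m])
    return P


def _dict_to_params(P: dict, schema: ModalitySchema, link: str, squash: str = "linear"):
    enc = EncoderParams(
        weights={m: P[f"w_{m}"].copy() for m in schema.names},
        biases={m: float(P[f"b_{m}"]) for m in schema.names},
        log_scales={m: float(P["log_s"][i]) for i, m in enumerate(schema.names)},
        squash=squash,
    )
    dec = DecoderParams(
        loadings={m: P[f"a_{m}"].copy() for m in schema.names},
        offsets={m: P[f"d_{m}"].copy() for m in schema.names},
        log_sigma2={m: float(P[f"ls2_{m}"]) for m in schema.names},
        link=link,
    )
    return enc, dec, DynamicsParams(W=P["W"].copy())


def _init_params(batch: _Batch, link: str) -> dict:
    """Data-driven warm start: mean-feature encoders, OLS decoders, weak dynamics."""
    schema = batch.schema
    P: dict = {}
    z0 = {}
    for m in schema.names:
        D = schema.dim(m)
        w = np.full(D, 0.25 / D)
        b = 0.5
        P[f"w_{m}"] = w
        P[f"b_{m}"] = np.float64(b)
        z0[m] = batch.X0[m] @ w + b
    for m in schema.names:
        u = _link(z0[m], link)
        uc = u - u.mean()
        denom = float(uc @ uc) or 1.0
        a = (batch.X0[m] - batch.X0[m].mean(axis=0)).T @ uc / denom
        d = batch.X0[m].mean(axis=0) - a * u.mean()
        resid = batch.X0[m] - (u[:, None] * a + d)
        P[f"a_{m}"] = a
        P[f"d_{m}"] = d
        P[f"ls2_{m}"] = np.float64(math.log(max(float(np.mean(resid**2)), 1e-3)))
    M = schema.M
    W = np.zeros((M, M)) + 0.0
    np.fill_diagonal(W, 0.2)
    P["W"] = W
    P["log_s"] = np.full(M, math.log(0.05))
    return P


@dataclass
class FittedModel:
    """All estimated parameters plus the preprocessing statistics.

    Serializable to a versioned JSON archive (see :mod:`adcascade.io`);
    reloading reproduces encode/decode/vector-field outputs exactly.
    """

    schema: ModalitySchema
    standardizer: Standardizer
    encoder: EncoderParams
    decoder: DecoderParams
    dynamics: DynamicsParams
    config: TrainingConfig
    final_elbo: float
    history: pd.DataFrame | None = None

    def encode_visit(self, blocks: dict, standardize: bool = True) -> EncodedVisit:
        """Encode raw-scale modality blocks (None = absent) into latent coordinates."""
        if standardize:
            blocks = {
                m: (None if blocks.get(m) is None else self.standardizer.transform(m, blocks[m]))
                for m in self.schema.names
            }
        return encode(blocks, self.encoder, self.schema)

    def decode_latent(self, z: np.ndarray, raw: bool = True) -> dict:
        """Decode latent states to modality blocks, on the raw scale by default."""
        from .observation import decode as _decode

        out = _decode(z, self.decoder, self.schema)
        if raw:
            out = {m: self.standardizer.inverse(m, out[m]) for m in out}
        return out

    def baseline_latents(self, cohort: list[ObservationSet]) -> np.ndarray:
        """Anchor-visit posterior means, one row per subject."""
        zs = []
        for s in cohort:
            ai = s.anchor_index(self.schema)
            if ai is None:
                raise ValueError(f"subject {s.subject_id} has no complete visit")
            zs.append(self.encode_visit(s.visits[ai].blocks).mean)
        return np.asarray(zs)


def elbo(
    subject: ObservationSet,
    model: FittedModel,
    mc_samples: int = 1,
    rng: np.random.Generator | None = None,
    kl_weight: float = 1.0,
) -> float:
    """Monte-Carlo ELBO of one subject under a fitted model.

    The variance of the estimate vanishes as ``mc_samples`` grows.
    """
    if mc_samples < 1:
        raise ValueError("mc_samples must be >= 1")
    if subject.anchor_index(model.schema) is None:
        raise ValueError(f"subject {subject.subject_id} has no complete visit; cannot evaluate")
    rng = rng or np.random.default_rng(0)
    batch = _Batch([subject], model.schema, model.standardizer, model.config.step)
    P = _params_to_dict(model.encoder, model.decoder, model.dynamics, model.schema)
    vals = []
    for _ in range(mc_samples):
        eps = rng.standard_normal((1, model.schema.M))
        val, _, _, _ = _elbo_and_grads(batch, P, eps, kl_weight, model.decoder.link,
                                       model.encoder.squash)
        vals.append(val)
    return float(np.mean(vals))


def fit(cohort: list[ObservationSet], config: TrainingConfig,
        schema: ModalitySchema | None = None, verbose: bool = False) -> FittedModel:
    """Estimate encoder, decoder, noise and dynamics by stochastic variational inference.

    Deterministic given ``config.seed``.  Returns the parameters achieving
    the best objective seen after KL warm-up; the per-epoch objective trace
    is attached as ``FittedModel.history``.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    if schema is None:
        schema = _infer_schema(cohort)
    for s in cohort:
        s.validate(schema)
    std = Standardizer.fit(cohort, schema)
    batch = _Batch(cohort, schema, std, config.step)
    rng = np.random.default_rng(config.seed)
    P = _init_params(batch, config.link)

    mstate = {key: np.zeros_like(np.asarray(val, dtype=float)) for key, val in P.items()}
    vstate = {key: np.zeros_like(np.asarray(val, dtype=float)) for key, val in P.items()}
    b1, b2, adameps = 0.9, 0.999, 1e-8
    warm = int(round(config.kl_warmup_frac * config.epochs))
    best_val, best_P = -math.inf, None
    log = []
    t_adam = 0
    offdiag = ~np.eye(schema.M, dtype=bool)
    prior_prec = (
        0.0 if config.coupling_prior_sd is None else 1.0 / config.coupling_prior_sd**2
    )
    avg_start = config.epochs - max(1, int(round(config.param_avg_frac * config.epochs)))
    avg_P: dict | None = None
    avg_n = 0
    for epoch in range(config.epochs):
        beta = config.kl_weight * (min(1.0, (epoch + 1) / warm) if warm > 0 else 1.0)
        if config.lr_decay == "cosine":
            lr = config.learning_rate * 0.5 * (1.0 + math.cos(math.pi * epoch / config.epochs))
        else:
            lr = config.learning_rate
        if config.batch_size is None or config.batch_size >= batch.N:
            parts = [np.arange(batch.N)]
        else:
            perm = rng.permutation(batch.N)
            parts = [perm[i:i + config.batch_size] for i in range(0, batch.N, config.batch_size)]
        ep_elbo = ep_recon = ep_kl = 0.0
        for idx in parts:
            sub = batch if len(idx) == batch.N else batch.subset(idx)
            val = rec = kl = 0.0
            acc = None
            for _ in range(config.mc_samples):
                eps = rng.standard_normal((sub.N, schema.M))
                v, r, k_, g = _elbo_and_grads(sub, P, eps, beta, config.link,
                                              config.encoder_squash)
                val += v / config.mc_samples
                rec += r / config.mc_samples
                kl += k_ / config.mc_samples
                if acc is None:
                    acc = g
                else:
                    for key in acc:
                        acc[key] = acc[key] + g[key]
            if not math.isfinite(val):
                raise RuntimeError(
                    f"objective diverged (non-finite) at epoch {epoch}, "
                    f"subjects {idx[:5].tolist()}..."
                )
            # weak Gaussian prior on the off-diagonal couplings (MAP fit):
            # resolves the rate/coupling trade-off of near-collinear latents
            if prior_prec:
                acc["W"] = acc["W"] - (len(idx) / batch.N) * prior_prec * P["W"] * offdiag
                val -= 0.5 * prior_prec * float(np.sum((P["W"] * offdiag) ** 2)) \
                    * (len(idx) / batch.N)
            scale = (batch.N / len(idx)) / config.mc_samples
            gnorm = math.sqrt(sum(float(np.sum(np.square(acc[key]))) for key in acc)) * scale
            clip = min(1.0, config.grad_clip / gnorm) if gnorm > 0 else 1.0
            t_adam += 1
            for key in P:
                gk = np.asarray(acc[key], dtype=float) * scale * clip
                mstate[key] = b1 * mstate[key] + (1 - b1) * gk
                vstate[key] = b2 * vstate[key] + (1 - b2) * gk * gk
                mhat = mstate[key] / (1 - b1**t_adam)
                vhat = vstate[key] / (1 - b2**t_adam)
                P[key] = P[key] + lr * mhat / (np.sqrt(vhat) + adameps)
            ep_elbo += val
            ep_recon += rec
            ep_kl += kl
        log.append({"epoch": epoch, "elbo": ep_elbo, "recon": ep_recon, "kl": ep_kl})
        if verbose and epoch % 100 == 0:
            print(f"epoch {epoch:5d}  elbo {ep_elbo:.1f}  kl {ep_kl:.1f}")
        if epoch >= warm and ep_elbo > best_val:
            best_val = ep_elbo
            best_P = {key: np.copy(val_) for key, val_ in P.items()}
        if epoch >= avg_start:
            # iterate averaging over the final window damps SVI gradient noise
            if avg_P is None:
                avg_P = {key: np.array(val_, dtype=float, copy=True) for key, val_ in P.items()}
            else:
                for key in avg_P:
                    avg_P[key] = avg_P[key] + P[key]
            avg_n += 1
        if config.tol > 0 and epoch > warm + 100:
            prev = log[-51]["elbo"]
            if abs(ep_elbo - prev) < config.tol * max(1.0, abs(prev)):
                break
    if best_P is None:
        best_P, best_val = P, log[-1]["elbo"]
    if avg_P is not None and avg_n > 0:
        for key in avg_P:
            avg_P[key] = avg_P[key] / avg_n
        # pick whichever of (averaged, best-epoch) parameters scores better
        # under a deterministic objective (posterior-mean sample, eps = 0)
        eps0 = np.zeros((batch.N, schema.M))
        v_avg, _, _, _ = _elbo_and_grads(batch, avg_P, eps0, config.kl_weight,
                                         config.link, config.encoder_squash)
        v_best, _, _, _ = _elbo_and_grads(batch, best_P, eps0, config.kl_weight,
                                          config.link, config.encoder_squash)
        if v_avg >= v_best:
            best_P, best_val = avg_P, v_avg
        else:
            best_val = v_best
    enc, dec, dyn = _dict_to_params(best_P, schema, config.link, config.encoder_squash)
    return FittedModel(
        schema=schema, standardizer=std, encoder=enc, decoder=dec, dynamics=dyn,
        config=config, final_elbo=float(best_val), history=pd.DataFrame(log),
    )


def _infer_schema(cohort: list[ObservationSet]) -> ModalitySchema:
    """Schema from the first complete visit found in the cohort."""
    for s in cohort:
        for v in s.visits:
            if all(b is not None for b in v.blocks.values()) and v.blocks:
                names = tuple(v.blocks.keys())
                dims = tuple(int(np.asarray(v.blocks[n]).shape[0]) for n in names)
                return ModalitySchema(names=names, dims=dims)
    raise ValueError("cannot infer schema: no complete visit in cohort")
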