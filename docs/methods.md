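# Methods

## Model

The observed data are per-visit modality blocks
`X(t) = [x_amy, x_met, x_atr, x_cli]` (canonical dimensions 41/41/41/7;
reduced 2/2/2/2 in the fast synthetic configuration). Conditional on a
4-dimensional latent state `z(t)`, blocks are independent Gaussians

    x_m | z ~ N(mu_m(z_m), sigma_m^2 I_{D_m}),

with one noise variance per modality (a per-feature variant was considered
and rejected as over-parameterized for the reduced schema). The decoder
`mu_m` is an affine map of the single coordinate `z_m`, optionally composed
with a logistic saturation (`DecoderParams.link`). Restricting `mu_m` to
`z_m` — rather than the full latent vector — is what keeps every latent
coordinate interpretable as exactly one modality; full-`z` decoding is
deliberately not offered because it would break the interpretation that the
staging and intervention machinery relies on.

The latent state follows the coupled-logistic system

    dz_m/dt = k_m z_m (1 - z_m) + sum_{j != m} alpha_{m,j} z_j,
    equivalently dz/dt = W z - V z^2,  V = diag(diag(W)),

with rates `k_m` (1/year) on the diagonal of `W` and couplings off it.
The system is cooperative for non-negative couplings: the healthy state
`z = 0` is unstable, and trajectories from small positive states rise along
a common course to a pathological attractor (whose coordinates exceed 1
when couplings are positive; `[0, 1]` is the nominal range of the
*uncoupled* logistic only). The state is never clamped: `z < 0` lies on the
divergent branch of the quadratic field, a fact that shaped several design
choices below.

## Integration

Fixed-step classical Runge–Kutta (RK4), default step 0.1 year. Times before
the initial condition use negative steps (the time-reversed flow). The
intervention operator multiplies the vector field elementwise by
`Gamma = diag(gamma_1..gamma_M)` at every RK4 substep whose start time lies
in the active window — the per-step derivative-modulation semantics; with a
fixed step this is well defined and reproducible, and it is equivalent in
the small-step limit to rescaling the increment after each step.
Interventions are irreversible by default (`end_time = +inf`). With
`gamma_m = 1` the multiplication is exact in floating point, so an identity
intervention reproduces the natural trajectory bit for bit.

## Inference

For each subject the earliest visit with all modalities present is the
encoding anchor. A modality-wise encoder (affine `D_m -> 1`, with a learned
per-modality posterior scale) amortizes a diagonal-Gaussian variational
posterior over `z(t0)`; one reparameterized sample per epoch is integrated
to every visit time, reconstructions are scored under the decoder (absent
blocks contribute nothing — they are structurally excluded from the
flattened batch), and the posterior is regularized toward a standard-normal
prior with a linear KL warm-up over the first 10% of epochs.

Gradients are hand-written reverse-mode: the adjoint of one RK4 step is
assembled from vector–Jacobian products of the polynomial field
(`J^T v = W^T v - 2 k z v`), which simultaneously yields the exact gradient
with respect to `W` (discretize-then-optimize). A test verifies analytic
gradients against central finite differences to better than 1e-4 relative
error. All subjects are integrated together on one shared step grid (visit
times snapped to the nearest 0.1-year multiple — at most 0.05 years, well
below visit-timing noise); this vectorization is why the default gradient
step uses the full cohort rather than minibatches of 32 (minibatching
remains available via `TrainingConfig.batch_size`). The optimizer is Adam
(lr 1e-2, cosine decay, 2000 epochs), with global-norm gradient clipping,
iterate averaging over the final 15% of epochs, and a weak Gaussian prior
(sd 0.1) on the off-diagonal couplings; the returned parameters are
whichever of the averaged or best-epoch iterates scores better under a
deterministic posterior-mean evaluation.

Two stabilizations deserve explanation:

- **Span freezing.** Subjects are only integrated across their own observed
  span; beyond it the shared-grid state is frozen (an identity step whose
  adjoint passes through unchanged). No likelihood term exists there, and
  without freezing the unobserved futures of noisy baselines can diverge
  and poison the whole batch with non-finite values.
- **Encoder squash.** `encoder_squash="softplus"` composes the affine
  encoder with a sharp softplus applied to the *sampled* latent, flooring
  it just above 0 (the prior is interpreted through the same map, so the KL
  keeps its Gaussian closed form). With the plain affine encoder, posterior
  samples of near-healthy subjects fall slightly below `z = 0`, where the
  quadratic field diverges in finite time — the ELBO is then non-finite
  even at the generating parameters. Canonical fits therefore use the
  softplus variant; plain affine remains the default for `encode()`.

## Identifiability of the dynamics (known limitation)

On the canonical synthetic conditions (2-feature blocks, observation noise
sd 0.08, 1–8 roughly annual visits per subject, 300 subjects) the
rate/coupling decomposition of `W` is only weakly identified: a coordinate's
rise can be attributed to its own logistic rate or to couplings from
correlated coordinates, and these explanations are nearly indistinguishable
over short windows. Empirically, the objective's optimum sits away from the
generating `W` (fits initialized at the true `W` migrate to the same
optimum; richer variational families — per-subject free posteriors,
input-dependent posterior scales, importance-weighted bounds — land in the
same place), and across seeds the optimum bifurcates between "self-rate"
and "coupling-driven" solutions. Consequences: fitted trajectories, staging
and trial simulations are stable and accurate (they depend on the flow
along the disease course, which *is* identified), but individual `k_m`
estimates scatter with errors that can exceed 20%, while the *signs* of
substantial couplings are recovered reliably. The parameter-recovery test
in the acceptance suite documents this honestly rather than asserting a
precision the data cannot support.

## Long-term reference trajectory

A Gaussian mixture is fitted to the AD subjects' encoded latent states,
enumerating 1–5 components across full/diagonal/tied/spherical covariance
structures and keeping the AIC minimizer (ties toward fewer parameters).
Each of 1000 mixture draws is extended over a −30..+10-year grid (0.1-year
step) and the pointwise mean ± sd across members is the reference; the time
axis is shifted so t = 0 is where the mean clinical z-score crosses a
threshold (0.5 in the canonical pipeline), a fallback conversion anchor
that needs no staging bootstrap; an explicit shift (e.g. the mean staging
time of MCI converters at diagnosis) can be passed instead.

**Backcasting choice.** Extending a *noisy* pathological state backward by
literally reversing the flow is exponentially ill-posed: components of the
encoder noise transverse to the disease course grow like `exp(k t)`
backward, and any coordinate above the attractor sits on the divergent
branch of the reversed logistic, which blows up in finite time (about 2.4
years from typical fitted AD states — measured, >99% of draws). The default
(`method="projected"`) therefore positions each draw on the model's own
disease course — the heteroclinic orbit from the healthy fixed point to the
attractor, computed once by *forward* integration from a 1e-3 state and
trimmed where the field magnitude falls below 1e-4/year — by L1 projection,
and carries it along the flow in both directions. The member spread then
reflects the severity distribution of the mixture. The literal per-draw
integration is available as `method="exact"` (it is exercised by tests on
stable mid-course ranges and propagates divergences with the draw index).
Decoded biomarker bands are computed by pushing every ensemble member
through the decoder and aggregating, not by linearization.

## Staging

`tau = argmin_t sum_{m present} |f_m(x_m) - zbar_m(t)|`, searched densely
over the reference grid — exact to grid resolution (0.1 year), ties broken
toward the earliest time (relevant only in flat early regions). Absent
modalities drop out of the sum. Group severity distributions are compared
with two-sided Wilcoxon–Mann–Whitney tests at P < 0.01 between adjacent
clinical stages.

## Trial simulation

A trial draws `n` latent states per arm from the fitted mixture (anchored
at conversion, t = 0). The placebo arm's endpoint is the natural
progression at the evaluation time; the treated arm takes its natural
history along the disease course to the intervention start (the same
projection used for the reference, for the same stability reason), then
integrates the Gamma-damped field forward. Decoded clinical endpoints
receive Gaussian measurement noise (`sigma_cli`, mapped back to the raw
scale). Identity interventions short-circuit to the raw draws in both arms,
so the null distribution is exactly exchangeable between arms.

Arms are compared with a two-sided Welch t-test by default (the
pooled-variance classic test is a flag — the variance-handling convention
is a free choice here); power is the rejection fraction over independent
trial replicates (default 500) with its binomial standard error, and a
closed-form noncentral-t power for Gaussian arms is kept as a cross-check
oracle. Improvement is reported benefit-positive for every endpoint:
placebo minus treated on the severity-increasing model scale, which equals
treated minus placebo in native units for polarity-flipped scores (MMSE,
RAVLT immediate/learning). The power surface sweeps intervention time ×
sample size × lowering rate with an independent seeded stream per cell;
failed cells are marked, not fatal.

## Synthetic cohorts

The generator emulates an amyloid-positive ADNI-like cohort: every subject
is a window onto one common disease course, entered at a uniform
time-shift over 25 years; 1–8 visits at roughly 1-year spacing (sd 0.2,
minimum 0.3), follow-up capped at 16 years; observations decoded with the
true affine decoders plus Gaussian noise (sd 0.08 per feature, a
realistic ~8% of the pathological dynamic range); follow-up modalities
missing at random (30% imaging, 10% clinical) with the baseline always
complete; five clinical labels assigned from the true clinical z-score via
thresholds (0.20, 1.20) chosen on the noiseless course so that all five
groups are populated with strictly ordered severity, with converter status
read off the last visit. The canonical dynamics use rates
k = (0.35, 0.25, 0.25, 0.30)/year and a positive coupling chain
amy→met (0.15), amy→atr (0.05), met→atr (0.10), met→cli (0.05),
atr→cli (0.05), which reproduces the cascade ordering: amyloid reaches 90%
of its asymptote first (≈12 years from the anchor state), the clinical
score last (≈14.5 years), with the clinical acceleration peaking after all
imaging modalities.

What the generator does *not* emulate: realistic spatial covariance among
regional imaging features (features are conditionally independent given
the latent), scanner/site effects, measurement batch effects, dropout that
is informative of severity, or between-subject heterogeneity in the
dynamics themselves (every subject shares one `W`). Passing tests on these
cohorts therefore demonstrate the internal consistency and calibration of
the machinery, not robustness to those real-data complications.

## Problem sizes

The canonical experiments fit 300 subjects at reduced 2/2/2/2 dimensions
for 2000 epochs (≈45 s on one CPU); the reference uses 1000 ensemble
members; trial calibration uses 2000 replicates at 100 per arm; power
surfaces in the test suite use 200 replicates per cell, and the recovery
experiment spans 5 independent cohort/fit seeds. The full 41/41/41/7
schema is available behind `canonical_config(full_dims=True)` and exercised
by a smoke test; all scientific conclusions above are stated for the
reduced schema.
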