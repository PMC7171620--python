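# Methods

This note documents the models, numerical choices and limitations behind
`morenet`: the MORE matrix-conjugation cryptosystem over floats, the
scalar-generic neural-network engine that trains on ciphertexts, the
closed-loop circulation model used as ground-truth generator, the synthetic
image generators, and the known-plaintext attack that bounds the scheme's
security.

## The MORE scheme over floating-point scalars

A scalar message `m` is encrypted as the 2×2 real matrix

    C = S · diag(m, r) · S⁻¹

with a secret invertible `S` and a fresh random filler `r` per encryption
(symmetric key; nondeterministic; noise free).  Decryption reads
`(S⁻¹ C S)[0,0]`.  Because conjugation is an algebra isomorphism, matrix
addition/subtraction/multiplication and multiplication by `inv(C)` decrypt to
the corresponding scalar operations exactly, and any scalar function `f` can
be applied through the eigenstructure: `f(C) = V f(Λ) V⁻¹`, where the
eigenvalues are exactly `(m, r)`.  Plaintext constants enter as the key-free
lift `s·I`.  Both routes for the logistic sigmoid are implemented — the
eigenvalue route and the direct matrix function `(I + expm(−C))⁻¹` — and are
cross-checked to 1e-8 entrywise; encrypted comparisons against a plain scalar
apply a step function to the eigenvalues and return a ciphertext, so they
cannot drive plaintext control flow.

Numerical choices:

* **Key generation.** Entries of `S` i.i.d. uniform [−1, 1], rejected until
  `|det S| > 1e-6` and 2-norm condition number ≤ 50 (at most 1000 draws).
  Conditioning bounds the error amplification of repeated conjugation; with
  cond ≤ 50 a single encrypt/compute/decrypt chain stays within ~1e-12
  relative and long training runs within ~1e-9.
* **Eigenvalues** come from the closed-form quadratic; the smaller-magnitude
  root is refined through `λ₁λ₂ = det C`, which avoids the cancellation in
  `(tr ∓ √disc)/2` when the two tracks differ by many orders of magnitude.
  Repeated eigenvalues (|λ₁−λ₂| below `eig_tol·(1+‖C‖)`) mean `C` is a
  scalar matrix; then `f(C) := f(tr/2)·I`.
* **Opaque errors.** Domain violations (log of a non-positive eigenvalue,
  division by a singular ciphertext) raise errors that do not say whether
  the message or the filler track was responsible.
* **Exact ties.** An encrypted comparison at exactly `m = s` under a
  non-identity key can flip by one ulp, because conjugation recovers the
  eigenvalue only to floating-point precision; tie semantics are exact under
  the identity key and to 1 ulp otherwise.

### The filler is a numerical constraint, not only a privacy knob

The filler track undergoes the *same dataflow* as the message ("shadow
computation").  Both tracks share the four matrix entries, so whenever the
filler track grows (or shrinks) many orders of magnitude beyond the message
track, float64 loses the message inside the shared entries.  Deep pipelines
amplify this: a 784-term weighted sum adds ~√784 filler standard deviations,
softmax exponentiates them, and over many SGD epochs the filler's own shadow
optimisation can diverge even when the message optimisation converges.

The remedy is the same policy that privacy demands: draw fillers
*statistically indiscernible from the messages*.  On standardised data that
means `r ∈ [−1, 1]`-ish, which keeps every intermediate filler value within
a few orders of the message and preserves ~1e-8 end-to-end agreement even
through convolutional stacks.  The library default stays at the configurable
interval [−10, 10] (switched to [1e-3, 10] under `positive_only`, required
ahead of log/sqrt); the choice is deliberately the caller's, and all
shipped pipelines pick message-scale fillers.

## Scalar-generic network engine

Tensors carry either float64 scalars (shape `s`) or one 2×2 ciphertext block
per scalar (shape `s+(2,2)`); every layer is written once against a small
dispatch layer (`engine`), so the plaintext and ciphertext runs are the same
program.  Supported layers are exactly those that avoid plaintext branching:
dense, 3×3 stride-1 zero-("same"-)padded convolution, 2×2/stride-2 average
pooling (max pooling would need comparisons), sigmoid/tanh through the
eigenvalue route, softmax from encrypted `exp` and ciphertext division, and
inverted dropout with *plaintext* Bernoulli masks from a dedicated seeded
stream (multiplying a ciphertext by plain `0` or `1/(1−rate)` is scalar).
Padded convolution positions contribute zero blocks — the zero matrix is a
valid encryption of 0 under every key, so this is exact and key-free.

Backpropagation is the standard chain rule.  The softmax+cross-entropy and
sigmoid+binary-cross-entropy pairs use the combined gradient `(ŷ − y)` taken
at the pre-activation, so no ciphertext log appears in the backward path
(log is needed only for loss monitoring); mean-squared error uses the
`1/(2n)` convention with gradient `(ŷ − y)/n`, `n` the number of outputs.
Losses and gradients are *summed* over the minibatch (the epoch log divides
by the sample count for readability).  The optimizer is minibatch SGD with
momentum, `v ← μv − η g`, `w ← w + v`, one of the textbook variants.
Weights are Xavier-initialised: uniform in ±√(6/(fan_in+fan_out)), with
convolution fans counting kernel taps (9·channels); biases start at zero.

Training runs a *fixed* number of epochs: an encrypted loss cannot feed a
stopping rule, because a ciphertext cannot be used in a conditional.  The
shuffle and dropout streams are seeded and plaintext, so a ciphertext run
and a plaintext run sharing seeds and initial parameters follow the same
dataflow; decrypted parameters, losses and predictions agree to ~1e-6
relative (they differ only by floating-point reordering under conjugation,
scaled by the key's condition number).  Dropout sits in the angiographic
classifier per its reference topology; the hyperparameter table's dropout
column is attached there.

Task presets reproduce the reference topologies exactly (digit CNN with
8/16 filters, 784-flatten, 100-unit head; 9-40-40-40-12 regression FCNN
with tanh/tanh/sigmoid hidden activations and a linear head; 4-stage
angiography CNN with 8192-flatten and 25% dropout) and hyperparameters
(learning rate 0.01, momentum 0.9, batch sizes 32/16/32, epochs
100/4500/100).  A `scale` knob shrinks widths for desk-scale experiments
without changing the layer pattern.

## Whole-body circulation model

Chambers are time-varying elastance elements
`P = E(t)(V−V₀) − K_s E(t)(V−V₀) Q` with `dV/dt = Q_in − Q_out`; valves are
diode–resistance–inertance elements (`L dQ/dt = ΔP − RQ` while conducting,
opening on positive upstream gradient, flow clamped at zero when integration
drives it negative); the systemic and pulmonary arteries are three-element
Windkessel compartments `dP/dt = R_p dQ/dt + Q(R_p+R_d)/(R_d C) −
(P−P_ven)/(R_d C)`; the venous returns are two-element compartments.  The
distal Windkessel outflow is taken at the compliance node `P − R_p Q`, which
makes stored volume exactly consistent with the pressure ODE; closed-loop
blood volume is conserved to <0.5% per cycle (typically ~0.006%).

The elastance waveform is not dictated by the framework; we use a normalised
double-Hill product (exponents 1.9 and 21.9, shape constants 0.303/0.508 of
normalised time), time-scaled so its peak lands exactly at the requested
time-at-maximum-elastance and normalised to max 1.  Atria reuse the same
machinery with small elastances, activation advanced 0.12·T ahead of the
ventricles and a 0.10·T time-to-peak.  Any single-peaked normalised waveform
would serve; these constants give physiological pressure traces at the
resting baseline (≈147/81 mmHg aortic, ≈5.5 L/min cardiac output, matched
left/right stroke volumes).

Integration is fixed-step RK4 at `dt = 1e-4 s` (the per-cycle step count is
rounded so the cycle is an integer number of steps), run cycle by cycle
until the state at cycle start changes by less than 1e-4 relative (cap 30
cycles; ~12 from the shipped initial state).  Valve flows are clamped at
zero after each full step.  Halving `dt` moves the extracted measurements by
<0.2%.  The inner loop is numba-compiled with per-sample elastance lookup
tables at half-step times; a pure-Python right-hand side (`derivatives`) is
kept in lockstep and cross-checked against the compiled core in the tests.

Measurements are read off the final periodic cycle: systolic pressures are
trace maxima, end-diastolic pressures are the arterial pressures at the
instant the outflow valve opens, EDV/ESV are volume extrema, ejection time
is the total valve-open time.  The target vector read off the parameters has
six entries per circulation: dead volume, time at maximum elastance, total
arterial resistance `R_p+R_d`, compliance, ratio `R_p/R_d`, and maximum
elastance.

## Synthetic cohorts and datasets

**Hemodynamic regression.**  Parameter sets are drawn uniformly from
physiological ranges and *forward-simulated*; the (measurement, parameter)
pair becomes a sample.  Forward sampling gives exactly the
measurement/parameter consistency that a calibrate-then-simulate pipeline
enforces, at a fraction of the cost.  Free draws: systemic E_max 1–4
mmHg/mL, LV V₀ 5–30 mL, activation-time fraction 0.25–0.40, total systemic
resistance 0.7–1.7 mmHg·s/mL with R_p/R_d 0.03–0.10, compliance 0.5–2.5
mL/mmHg, plus pulmonary V₀, timing fraction and resistance split; remaining
pulmonary parameters are scaled deterministically from the systemic draws
(resistance ÷14, elastance ÷4, compliance ×3.5) so pulmonary pressures sit
near one sixth of systemic.  Degenerate draws (blow-up, non-convergence, a
valve that never opens, volume drift) are rejected and redrawn (~10%
rejection at the defaults; >50% raises a configuration error).

The heart period is **fixed at 0.9 s** by default rather than sampled.  The
ten listed measurements contain no period, and cardiac output — hence
absolute resistance — is unidentifiable from them when the period varies:
with a sampled period both a random forest and a large adam-trained MLP cap
near Pearson 0.91 for systemic resistance, while near-perfect recovery is
expected of this experiment.  Clinically the heart rate is always known; a
fixed-rate cohort is the cleanest way to encode that knowledge without
adding an input.  A (low, high) range for `T` remains available in the
sampling configuration.  With the period fixed there remain 9 free
dimensions against 9–10 measurements; recovery is then limited mostly by
the optimizer (plain SGD at fixed learning rate plateaus around 2–3% MAPE
on resistance, Pearson ≈0.99, where stronger optimizers reach ~1%).

The default input vector carries all ten measurements; a switch drops the
right-ventricular ejection time to reproduce the reference nine-input
topology (used by the acceptance experiment).  Normalisation statistics
(mean/std or min/max) are fitted on the training split only; the standard
split is 70/10/20.

**Digit images.**  28×28 glyphs rendered from per-class stroke skeletons
with random affine jitter, blur and noise, balanced over ten classes,
one-hot labels, pixels scaled to [0, 1].  They stand in for scanned
handwritten digits so the multiclass pipeline is testable offline; an IDX
reader accepts externally supplied corpora in the standard format.

**Vessel trees.**  Two balanced classes of recursive branching trees with
mirrored root orientation and different branching statistics (dense
wide-spread "left-type" vs sparse C-shaped "right-type"), min-max scaled
per image, plaintext 0/1 labels.  A small CNN separates held-out samples at
>90% accuracy.  These capture view-dependent geometry only — not contrast
dynamics, background anatomy or acquisition noise of real angiography — so
passing tests demonstrate pipeline correctness, not clinical performance.

**Augmentation.**  Offline: originals plus `factor−1` jittered copies per
image (rotation ±10°, shift ±10% of the side, zoom 0.9–1.1), labels copied;
1996 inputs at factor 4 give exactly 7984.

## Known-plaintext attack

Decryption is linear in the ciphertext entries: `m = aᵀ C b = Σ G[j,k]
C[j,k]` with `G = a bᵀ`, `a` the first row of `S⁻¹`, `b` the first column of
`S`, `aᵀb = 1`.  Recovery is a 4-unknown least-squares fit over known
(ciphertext, plaintext) pairs.  In fact every ciphertext under one key is
`C = m P₁ + r P₂` for fixed projectors `P₁, P₂` — a 2-dimensional plane — so
the minimum-norm solution pins `⟨G,P₁⟩ = 1`, `⟨G,P₂⟩ = 0` and decrypts
*every* ciphertext of that key exactly once the pairs span the plane: two
generic pairs suffice, and `trace(G) = ⟨G, P₁+P₂⟩ = ⟨G, I⟩ = 1` holds for
any exact functional.  The empirical sweep confirms success rate 0 at one
pair and ≥0.99 from two generic pairs on; recovery tolerates 1e-9 message
perturbation with linearly degrading error.  This is why the scheme is
suitable only for workflows in which plaintext never leaves the data owner.

## Problem sizes and acceptance experiment

`scripts/acceptance.py` regenerates the surrogate experiment from scratch:
a 4000-sample cohort (2800/400/800 split) at `dt = 1e-4`, the reference
9-input network and hyperparameters with 1000 epochs, then reports the
test-split MAPE and Pearson correlation of systemic resistance and the
Pearson correlation of systemic time-at-maximum-elastance, in physical
units, plus the four-fold augmentation count for a 1996-image training set.
These sizes are the package's reference configuration; the generator and
trainer accept larger ones unchanged.

## Known limitations

* Security is deliberately weak (linear scheme); see the attack module.
* Ciphertext order is fixed at n = 2; integer/modular MORE variants, SEAL or
  HELib interoperability are out of scope.
* ReLU/max-pooling and any data-dependent control flow are unsupported on
  ciphertexts by construction.
* Filler ranges far wider than the message scale degrade float64 fidelity
  in deep pipelines (see the filler section); the library does not try to
  detect this automatically.
* The circulation model is lumped (0-D): no wave propagation, no valve
  regurgitation or stenosis states, no autonomic regulation; atrial timing
  is a fixed fraction of the cycle.
* Synthetic images are stand-ins; results on them say nothing about real
  scanned digits or angiograms.
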