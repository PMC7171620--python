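# morenet — deep learning on MORE-encrypted floating-point data

`morenet` is a research library for privacy-preserving machine learning on
medical data.  It implements the MORE (Matrix Operation for Randomization or
Encryption) homomorphic scheme directly over floating-point numbers and a
neural-network engine whose layers run *unchanged* on plaintext scalars or
on ciphertexts — training included — together with the tooling around the
three reference experiments: digit classification, regression of whole-body
circulation (WBC) model parameters from clinical measurements, and binary
classification of coronary-angiography-like vessel images.

It is aimed at researchers studying the utility/security trade-off of
linear-transformation homomorphic schemes, and at anyone who needs a
self-contained, dependency-light testbed for encrypted neural-network
training.

## The core idea

A scalar `m` is encrypted as a 2×2 matrix with secret invertible `S` and a
fresh random filler `r`:

    C = S · diag(m, r) · S⁻¹,        decrypt(C) = (S⁻¹ C S)₁,₁ = m

Conjugation preserves the algebra, so for ciphertexts `C₁, C₂`:

    C₁ + C₂ = S · diag(m₁+m₂, r₁+r₂) · S⁻¹,     C₁C₂ = S · diag(m₁m₂, r₁r₂) · S⁻¹

and likewise subtraction and division — noise free and unlimited in depth.
Nonlinear activations use the eigenstructure: `f(C) = V f(Λ) V⁻¹`, the
message being one of the eigenvalues.  A network therefore trains on
ciphertexts by running its ordinary forward/backward passes in matrix
arithmetic; with shared seeds the decrypted result equals the plaintext run
up to floating-point reordering (~1e-6 relative over full training runs).

The price is security: decryption is a linear functional of the ciphertext,
so a few known plaintext–ciphertext pairs recover an equivalent key
(`morenet.attack` demonstrates this).  The scheme fits workflows where
plaintext never leaves the data owner and the server only ever sees
ciphertexts.

The package also contains a closed-loop lumped-parameter circulation model
(time-varying-elastance chambers, diode–resistance–inertance valves,
three/two-element Windkessel compartments, RK4 to periodic steady state)
that generates the regression experiment's ground truth, plus procedural
digit and vessel-tree image generators, so every experiment runs offline
from nothing but a seed.

## Worked example

```bash
python examples/encrypted_arithmetic.py
```

```
decrypt(a)      = 6.0
decrypt(a * b)  = 41.99999999999999  (6 * 7)
decrypt(a + 3)  = 9.0  (plaintext scalar lift)
decrypt(a / b)  = 0.8571428571428573  (6 / 7 = 0.8571428571428571 )
sigmoid(E(1))   = 0.7310585786300048  (expected 0.7310585786300049 )
matrix-function route agrees: True
nondeterministic: True | both decrypt to 0.9999999999999998 1.0
```

Encrypted arithmetic reproduces plaintext arithmetic to the last few ulps,
and repeated encryptions of the same value give different matrices that
decrypt identically.  Training end-to-end on ciphertexts
(`examples/train_encrypted_regression.py`) prints matching loss curves:

```
epoch  plaintext-loss  decrypted-ciphertext-loss
    1      0.56192365      0.56192365
   10      0.17771448      0.17771448
   20      0.13717833      0.13717833
worst relative parameter gap after decryption: 1.51e-12
```

The circulation simulator (`examples/simulate_circulation.py`) settles a
resting-adult baseline into a periodic state with physiological numbers:

```
converged in 12 cycles (volume drift 0.006%/cycle)
aortic pressure       146.8 /   80.7 mmHg (sys/end-dia)
LV volume             150.7 /   67.9 mL (EDV/ESV)
stroke volume          82.8 mL  -> cardiac output 5.52 L/min
```

And the attack (`examples/key_recovery_attack.py`) decrypts fresh
ciphertexts to 1e-14 from a handful of known pairs — the scheme's stated
security limit.

## Command line

A thin CLI wraps the library for shell workflows, with strict key custody:
`train`/`predict` never read a key file.

```bash
morenet keygen --seed 5 --out key.json
morenet gen-data wbc --n 1000 --seed 3 --normalize meanstd --out cohort/
morenet encrypt --key key.json --data cohort/ --out cohort_enc/
morenet train-encrypted --config run.yaml --data cohort_enc/ --init init_ck/ --out model/
morenet predict --checkpoint model/ --data cohort_enc/ --out preds.mct
morenet decrypt --key key.json --tensor preds.mct --out preds_plain.mct
morenet evaluate --predictions preds_plain.mct --data cohort/ --task regression --out metrics.json
morenet simulate-wbc --out sim/          # circulation time series + measurements
morenet attack --key key.json --out atk/ # key-recovery report and sweep
```

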