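"""Encrypt scalars, compute on the ciphertexts, decrypt the results.

Every arithmetic result decrypts to the plaintext result to ~1e-9 relative:
the scheme is noise free, so chains of operations never degrade.
"""

import numpy as np

from morenet import crypto

config = crypto.EncryptionConfig(rng_seed=7)
key = crypto.generate_secret_key(config)

a = crypto.encrypt(6.0, key, config)
b = crypto.encrypt(7.0, key, config)

print("a ciphertext:\n", np.round(a.data, 4))
print("decrypt(a)      =", crypto.decrypt(a, key))
print("decrypt(a * b)  =", crypto.decrypt(a * b, key), " (6 * 7)")
print("decrypt(a + 3)  =", crypto.decrypt(a + 3.0, key), " (plaintext scalar lift)")
print("decrypt(a / b)  =", crypto.decrypt(a / b, key), " (6 / 7 =", 6.0 / 7.0, ")")

s = crypto.apply_unary("sigmoid", crypto.encrypt(1.0, key, config))
print("sigmoid(E(1))   =", crypto.decrypt(s, key), " (expected", 1 / (1 + np.exp(-1.0)), ")")

d = crypto.sigmoid_direct(crypto.encrypt(1.0, key, config))
print("matrix-function route agrees:", abs(crypto.decrypt(d, key) - crypto.decrypt(s, key)) < 1e-8)

# two encryptions of the same value are different matrices, same plaintext
c1, c2 = crypto.encrypt(1.0, key, config), crypto.encrypt(1.0, key, config)
print("nondeterministic:", not np.allclose(c1.data, c2.data),
      "| both decrypt to", crypto.decrypt(c1, key), crypto.decrypt(c2, key))
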