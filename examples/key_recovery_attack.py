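"""Demonstrate the known-plaintext weakness of the scheme.

Decryption is a linear functional of the ciphertext entries, so a handful of
matched (ciphertext, plaintext) pairs recovers an equivalent decryption map
by least squares -- after which every ciphertext under that key is open.
The sweep shows the success rate jumping to 1 as soon as the pairs span the
key's ciphertext plane.
"""

import numpy as np

from morenet import attack, crypto

config = crypto.EncryptionConfig(rng_seed=1)
key = crypto.generate_secret_key(config)

rng = np.random.default_rng(2)
msgs = rng.uniform(-100, 100, 4)
pairs = list(zip(crypto.encrypt_array(msgs, key, config), msgs))
G = attack.recover_decryption_functional(pairs)

fresh = rng.uniform(-100, 100, 100)
cts = crypto.encrypt_array(fresh, key, config)
err = max(abs(attack.attack_decrypt(G, c) - m) for c, m in zip(cts, fresh))
print(f"recovered functional from {len(pairs)} pairs: trace(G) = {np.trace(G.G):.6f}")
print(f"max decryption error on 100 fresh ciphertexts: {err:.2e} (no key used)")

print("\npairs  attack success rate (200 trials)")
for n, rate in attack.pairs_requirement_sweep(key, [1, 2, 3, 4, 8], trials=200, seed=3):
    print(f"{n:5d}  {rate:.2f}")
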