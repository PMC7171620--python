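"""Known-plaintext key recovery against the MORE scheme.

Decryption is linear in the ciphertext entries: with a = first row of S^-1
and b = first column of S, m = a^T C b = sum_jk G[j,k] C[j,k] where
G = a b^T has trace a^T b = 1.  An attacker holding matched (ciphertext,
plaintext) pairs recovers an equivalent decryption functional by solving a
4-unknown linear least-squares problem.

The attack is even stronger than the unknown count suggests: every
ciphertext under one key is C = m P1 + r P2 with the fixed spectral
projectors P1 = S e11 S^-1 and P2 = S e22 S^-1, so all same-key ciphertexts
live in a 2-dimensional subspace.  The minimum-norm least-squares solution
pins <G, P1> = 1 and <G, P2> = 0 on that subspace, which decrypts *every*
ciphertext under the key exactly -- two pairs with distinct (m, r)
directions already suffice, and trace(G) = <G, P1 + P2> = <G, I> = 1 holds
for any exact functional.  This is the scheme's security limit, quantified
empirically by the pair-count sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import crypto

__all__ = [
    "DecryptionFunctional",
    "DegenerateDesignError",
    "recover_decryption_functional",
    "attack_decrypt",
    "pairs_requirement_sweep",
]


class DegenerateDesignError(RuntimeError):
    """The supplied pairs do not span the key's 2-D ciphertext plane."""

    def __init__(self, rank: int):
        super().__init__(
            f"design matrix rank {rank} < 2: the pairs do not span the key's "
            "ciphertext plane (non-generic)")
        self.rank = rank


@dataclass
class DecryptionFunctional:
    """Recovered linear decryption map m = sum G[j,k] * C[j,k]."""

    G: np.ndarray
    residual: float
    n_pairs: int
    rank_estimate: int


def recover_decryption_functional(pairs, require_full_rank: bool = True) -> DecryptionFunctional:
    """Least-squares fit of G from (Ciphertext, plaintext) pairs.

    ``pairs`` is an iterable of (Ciphertext | 2x2 array, float).  With
    generic pairs the minimum-norm solution is exact on every ciphertext of
    the attacked key.  Genericity is judged by the singular values of the
    design matrix (relative threshold 1e-10): same-key ciphertexts span at
    most 2 dimensions, and fewer than 2 raises
    :class:`DegenerateDesignError` (suppress with ``require_full_rank=False``
    to inspect the rank-deficient fit).
    """
    C = []
    m = []
    for ct, msg in pairs:
        mat = ct.data if isinstance(ct, crypto.Ciphertext) else np.asarray(ct, dtype=float)
        C.append(mat.ravel())
        m.append(float(msg))
    A = np.asarray(C)
    y = np.asarray(m)
    if A.shape[0] < 2:
        raise ValueError("need at least 2 plaintext-ciphertext pairs")
    sv = np.linalg.svd(A, compute_uv=False)
    rank = int(np.sum(sv > 1e-10 * sv[0]))
    if rank < 2 and require_full_rank:
        raise DegenerateDesignError(rank)
    g, res, _, _ = np.linalg.lstsq(A, y, rcond=None)
    residual = float(np.sqrt(res[0])) if res.size else float(np.linalg.norm(A @ g - y))
    return DecryptionFunctional(G=g.reshape(2, 2), residual=residual,
                                n_pairs=A.shape[0], rank_estimate=rank)


def attack_decrypt(G: DecryptionFunctional, C) -> float:
    """Decrypt without the key: m = sum G[j,k] * C[j,k]."""
    mat = C.data if isinstance(C, crypto.Ciphertext) else np.asarray(C, dtype=float)
    return float(np.sum(G.G * mat))


def pairs_requirement_sweep(key, n_values, trials: int = 200, seed: int = 0,
                            config: crypto.EncryptionConfig | None = None,
                            success_tol: float = 1e-6):
    """Empirical success rate of the attack as a function of pair count.

    For each ``n`` in ``n_values`` the attack is mounted ``trials`` times on
    fresh random pairs; a trial succeeds when the recovered functional
    decrypts 100 fresh ciphertexts with maximum error below ``success_tol``.
    Returns a list of (n, success_rate) rows.
    """
    if trials < 1:
        raise ValueError("need trials >= 1")
    rng = np.random.default_rng(seed)
    config = config or crypto.EncryptionConfig(rng_seed=int(rng.integers(2**31)))
    rows = []
    for n in n_values:
        successes = 0
        for _ in range(trials):
            msgs = rng.uniform(-100.0, 100.0, size=int(n))
            cts = crypto.encrypt_array(msgs, key, config)
            try:
                G = recover_decryption_functional(list(zip(cts, msgs)))
            except (DegenerateDesignError, ValueError):
                continue
            fresh = rng.uniform(-100.0, 100.0, size=100)
            fresh_ct = crypto.encrypt_array(fresh, key, config)
            rec = np.einsum("jk,njk->n", G.G, fresh_ct)
            if np.max(np.abs(rec - fresh)) < success_tol:
                successes += 1
        rows.append((int(n), successes / trials))
    return rows
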