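"""MORE matrix-conjugation homomorphic encryption over floating-point scalars.

A plaintext scalar ``m`` is hidden as the eigenvalue of a 2x2 real matrix

    C = S @ diag(m, r) @ S^{-1}

where ``S`` is the secret (an invertible 2x2 matrix) and ``r`` is a random
"filler" occupying the second eigenvalue.  Because conjugation by ``S`` is an
algebra homomorphism, sums, differences, products and quotients of ciphertext
matrices decrypt to the corresponding operations on the hidden scalars -- the
scheme is noise free, nondeterministic (fresh ``r`` per encryption) and closed
under an unlimited number of operations.  Nonlinear functions are evaluated on
the eigenvalues: ``f(C) = V f(L) V^{-1}`` with ``C = V L V^{-1}``, which keeps
the result a valid ciphertext under the same key.

Security is deliberately limited: decryption is a *linear* functional of the
ciphertext entries, so a handful of known plaintext-ciphertext pairs recovers
an equivalent key (see :mod:`morenet.attack`).  The scheme trades semantic
security for exact floating-point arithmetic on encrypted data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

__all__ = [
    "MoreCryptoError",
    "KeyGenerationError",
    "CiphertextDomainError",
    "SingularCiphertextError",
    "CorruptedCiphertextError",
    "EncryptionConfig",
    "SecretKey",
    "Ciphertext",
    "generate_secret_key",
    "encrypt",
    "decrypt",
    "encrypt_array",
    "decrypt_array",
    "lift",
    "lift_array",
    "ct_arith",
    "eigendecompose_2x2",
    "apply_unary",
    "apply_fn_array",
    "sigmoid_direct",
    "compare_plain",
    "cipher_add",
    "cipher_mul",
    "cipher_div",
    "cipher_reciprocal",
    "save_key",
    "load_key",
]


class MoreCryptoError(Exception):
    """Base class for errors raised by the MORE cryptosystem."""


class KeyGenerationError(MoreCryptoError):
    pass


class CiphertextDomainError(MoreCryptoError):
    """An eigenvalue fell outside the domain of the requested function.

    The message intentionally does not say whether the offending eigenvalue
    was the message or the filler.
    """


class SingularCiphertextError(MoreCryptoError):
    """Division by a ciphertext with an eigenvalue at (numerical) zero."""


class CorruptedCiphertextError(MoreCryptoError):
    """Ciphertext eigenvalues are complex beyond tolerance."""


# ---------------------------------------------------------------------------
# configuration and keys
# ---------------------------------------------------------------------------

_DEFAULT_R_LOW = -10.0
_DEFAULT_R_HIGH = 10.0
_POSITIVE_R_LOW = 1e-3


@dataclass
class EncryptionConfig:
    """Policy knobs for encryption.

    r_low, r_high : bounds of the uniform filler distribution.  When
        ``positive_only`` is set the default interval switches to
        ``[1e-3, 10]`` so that log/sqrt pipelines stay within domain on the
        filler track as well.
    cond_max : rejection bound on the 2-norm condition number of the secret
        matrix; conditioning controls floating-point error growth under
        repeated conjugation.
    eig_tol : tolerance used for eigenvalue realness/degeneracy decisions.
    rng_seed : seed of the filler stream (and of key generation when a key is
        generated from this config).
    """

    r_low: float = _DEFAULT_R_LOW
    r_high: float = _DEFAULT_R_HIGH
    positive_only: bool = False
    cond_max: float = 50.0
    eig_tol: float = 1e-9
    rng_seed: int = 0
    _rng: np.random.Generator | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.positive_only and self.r_low <= 0.0:
            if (self.r_low, self.r_high) == (_DEFAULT_R_LOW, _DEFAULT_R_HIGH):
                self.r_low, self.r_high = _POSITIVE_R_LOW, 10.0
            else:
                raise ValueError("positive_only requires r_low > 0")
        if not self.r_low < self.r_high:
            raise ValueError("need r_low < r_high")

    @property
    def rng(self) -> np.random.Generator:
        if self._rng is None:
            self._rng = np.random.default_rng(self.rng_seed)
        return self._rng


@dataclass
class SecretKey:
    """Invertible 2x2 secret matrix with cached inverse."""

    S: np.ndarray
    S_inv: np.ndarray
    cond: float
    seed: int

    def check(self) -> None:
        if abs(np.linalg.det(self.S)) <= 1e-6:
            raise KeyGenerationError("secret matrix is numerically singular")
        if np.max(np.abs(self.S @ self.S_inv - np.eye(2))) >= 1e-12:
            raise KeyGenerationError("cached inverse is inconsistent")


def generate_secret_key(config: EncryptionConfig) -> SecretKey:
    """Draw S with i.i.d. uniform[-1, 1] entries, rejecting ill-conditioned
    candidates, until ``|det S| > 1e-6`` and ``cond(S) <= cond_max``."""
    rng = np.random.default_rng(config.rng_seed)
    for _ in range(1000):
        S = rng.uniform(-1.0, 1.0, size=(2, 2))
        det = np.linalg.det(S)
        if abs(det) <= 1e-6:
            continue
        cond = float(np.linalg.cond(S, 2))
        if cond > config.cond_max:
            continue
        S_inv = np.linalg.inv(S)
        key = SecretKey(S=S, S_inv=S_inv, cond=cond, seed=config.rng_seed)
        key.check()
        return key
    raise KeyGenerationError("no acceptable key in 1000 draws")


def save_key(key: SecretKey, path) -> None:
    """Key file: JSON with S entries as 17-significant-digit decimal strings."""
    doc = {
        "version": 1,
        "seed": int(key.seed),
        "cond": float(key.cond),
        "S": [f"{v:.17g}" for v in key.S.ravel()],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_key(path) -> SecretKey:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("version") != 1:
        raise MoreCryptoError("unsupported key-file version")
    S = np.array([float(v) for v in doc["S"]], dtype=float).reshape(2, 2)
    key = SecretKey(S=S, S_inv=np.linalg.inv(S), cond=float(doc["cond"]), seed=int(doc["seed"]))
    key.check()
    return key


# ---------------------------------------------------------------------------
# ciphertexts
# ---------------------------------------------------------------------------


class Ciphertext:
    """A single encrypted scalar: a real 2x2 matrix with real eigenvalues."""

    __slots__ = ("data",)

    def __init__(self, data: np.ndarray):
        data = np.asarray(data, dtype=float)
        if data.shape != (2, 2):
            raise ValueError("ciphertext must be a 2x2 matrix")
        self.data = data

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Ciphertext({self.data.tolist()})"

    @property
    def trace(self) -> float:
        return float(self.data[0, 0] + self.data[1, 1])

    @property
    def det(self) -> float:
        return float(self.data[0, 0] * self.data[1, 1] - self.data[0, 1] * self.data[1, 0])

    # operator sugar; semantics live in ct_arith
    def __add__(self, other):
        return ct_arith("add", self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return ct_arith("sub", self, other)

    def __rsub__(self, other):
        return ct_arith("sub", other, self)

    def __mul__(self, other):
        return ct_arith("mul", self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return ct_arith("div", self, other)

    def __rtruediv__(self, other):
        return ct_arith("div", other, self)

    def __neg__(self):
        return Ciphertext(-self.data)


def lift(s: float) -> Ciphertext:
    """Lift a plaintext scalar into ciphertext arithmetic as s*I.

    Exact and key-free: s*I = S @ diag(s, s) @ S^{-1} under every key.
    """
    return Ciphertext(float(s) * np.eye(2))


def lift_array(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    out = np.zeros(values.shape + (2, 2))
    out[..., 0, 0] = values
    out[..., 1, 1] = values
    return out


def encrypt(m: float, key: SecretKey, config: EncryptionConfig, r: float | None = None) -> Ciphertext:
    """Encrypt one scalar.  ``r`` may be pinned for reproducible tests."""
    if not math.isfinite(m):
        raise ValueError("cannot encrypt a non-finite value")
    if r is None:
        r = float(config.rng.uniform(config.r_low, config.r_high))
    M = np.diag([float(m), float(r)])
    return Ciphertext(key.S @ M @ key.S_inv)


def encrypt_array(
    values: np.ndarray, key: SecretKey, config: EncryptionConfig, r: np.ndarray | None = None
) -> np.ndarray:
    """Vectorised encryption of an array of scalars -> array of shape s+(2,2).

    Uses C = m*P1 + r*P2 with the spectral projectors P1 = S e11 S^-1 and
    P2 = S e22 S^-1, which is algebraically identical to conjugating diag(m,r).
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("cannot encrypt non-finite values")
    if r is None:
        r = config.rng.uniform(config.r_low, config.r_high, size=values.shape)
    else:
        r = np.broadcast_to(np.asarray(r, dtype=float), values.shape)
    P1 = key.S @ np.diag([1.0, 0.0]) @ key.S_inv
    P2 = key.S @ np.diag([0.0, 1.0]) @ key.S_inv
    return values[..., None, None] * P1 + r[..., None, None] * P2


def decrypt(C: Ciphertext, key: SecretKey) -> float:
    """Message recovery: (S^{-1} C S)[0, 0]."""
    K = key.S_inv @ C.data @ key.S
    return float(K[0, 0])


def decrypt_array(values: np.ndarray, key: SecretKey) -> np.ndarray:
    """Vectorised decryption of an array of 2x2 ciphertext blocks."""
    a = key.S_inv[0, :]
    b = key.S[:, 0]
    return np.einsum("i,...ij,j->...", a, values, b)


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------


def cipher_add(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return a + b


def cipher_mul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elementwise ciphertext product = 2x2 matrix product (broadcasting)."""
    return np.matmul(a, b)


def _inv2x2(b: np.ndarray, eig_tol: float) -> np.ndarray:
    det = b[..., 0, 0] * b[..., 1, 1] - b[..., 0, 1] * b[..., 1, 0]
    scale = 1.0 + np.max(np.abs(b), axis=(-2, -1))
    if np.any(np.abs(det) <= eig_tol * scale):
        # deliberately silent about which eigenvalue vanished
        raise SingularCiphertextError("division by a singular ciphertext operand")
    inv = np.empty_like(b)
    inv[..., 0, 0] = b[..., 1, 1]
    inv[..., 1, 1] = b[..., 0, 0]
    inv[..., 0, 1] = -b[..., 0, 1]
    inv[..., 1, 0] = -b[..., 1, 0]
    return inv / det[..., None, None]


def cipher_reciprocal(b: np.ndarray, eig_tol: float = 1e-9) -> np.ndarray:
    return _inv2x2(b, eig_tol)


def cipher_div(a: np.ndarray, b: np.ndarray, eig_tol: float = 1e-9) -> np.ndarray:
    return np.matmul(a, _inv2x2(b, eig_tol))


def ct_arith(op: str, A, B, eig_tol: float = 1e-9) -> Ciphertext:
    """Key-free arithmetic on ciphertexts; plaintext scalars lift to s*I."""
    if not isinstance(A, Ciphertext) and not isinstance(B, Ciphertext):
        raise TypeError("at least one operand must be a Ciphertext")
    a = A.data if isinstance(A, Ciphertext) else lift(A).data
    b = B.data if isinstance(B, Ciphertext) else lift(B).data
    if op == "add":
        return Ciphertext(a + b)
    if op == "sub":
        return Ciphertext(a - b)
    if op == "mul":
        return Ciphertext(a @ b)
    if op == "div":
        return Ciphertext(cipher_div(a[None], b[None], eig_tol)[0])
    raise ValueError(f"unknown op {op!r}")


# ---------------------------------------------------------------------------
# eigenstructure and nonlinear functions
# ---------------------------------------------------------------------------


def _eig_batch(C: np.ndarray, eig_tol: float):
    """Closed-form eigendecomposition of a batch of 2x2 matrices.

    Returns (lam1, lam2, V, degenerate, diagonal) where ``degenerate`` marks
    (numerically) repeated eigenvalues and ``diagonal`` marks matrices that
    are already diagonal (for which lam = (a, d) and V = I exactly).
    """
    a = C[..., 0, 0]
    b = C[..., 0, 1]
    c = C[..., 1, 0]
    d = C[..., 1, 1]
    tr = a + d
    det = a * d - b * c
    disc = tr * tr - 4.0 * det
    scale = 1.0 + np.abs(tr) + np.abs(det)
    if np.any(disc < -eig_tol * scale):
        raise CorruptedCiphertextError("ciphertext eigenvalues are complex beyond tolerance")
    sq = np.sqrt(np.maximum(disc, 0.0))
    lam1 = 0.5 * (tr + sq)
    lam2 = 0.5 * (tr - sq)
    # refine the smaller-magnitude root through lam1*lam2 = det, which avoids
    # the cancellation in (tr -/+ sq)/2 when the eigenvalue magnitudes differ
    # by many orders (e.g. the filler track of softmax outputs)
    big_is_1 = np.abs(lam1) >= np.abs(lam2)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam2 = np.where(big_is_1 & (lam1 != 0.0), det / np.where(lam1 != 0.0, lam1, 1.0), lam2)
        lam1 = np.where(~big_is_1 & (lam2 != 0.0), det / np.where(lam2 != 0.0, lam2, 1.0), lam1)
    norm = np.max(np.abs(C), axis=(-2, -1))
    degenerate = sq < eig_tol * (1.0 + norm)
    diagonal = np.maximum(np.abs(b), np.abs(c)) < eig_tol * (1.0 + norm)
    # eigenvectors from the row with the larger off-diagonal entry
    use_b = np.abs(b) >= np.abs(c)
    V = np.empty_like(C)
    V[..., 0, 0] = np.where(use_b, b, lam1 - d)
    V[..., 0, 1] = np.where(use_b, b, lam2 - d)
    V[..., 1, 0] = np.where(use_b, lam1 - a, c)
    V[..., 1, 1] = np.where(use_b, lam2 - a, c)
    # diagonal matrices: eigenvalues in storage order, eigenvectors = I
    lam1 = np.where(diagonal, a, lam1)
    lam2 = np.where(diagonal, d, lam2)
    eye = np.broadcast_to(np.eye(2), C.shape)
    V = np.where(diagonal[..., None, None], eye, V)
    V = np.where(degenerate[..., None, None] & ~diagonal[..., None, None], eye, V)
    return lam1, lam2, V, degenerate, diagonal


def eigendecompose_2x2(C: Ciphertext, eig_tol: float = 1e-9):
    """Closed-form eigenvalues/eigenvectors of one ciphertext.

    Repeated eigenvalues (scalar matrices) return V = I and
    lam1 = lam2 = trace/2.
    """
    lam1, lam2, V, degenerate, _ = _eig_batch(C.data[None], eig_tol)
    if degenerate[0]:
        t = C.trace / 2.0
        return t, t, np.eye(2)
    return float(lam1[0]), float(lam2[0]), V[0]


_F = {
    "identity": (lambda x: x, None),
    "sigmoid": (lambda x: 1.0 / (1.0 + np.exp(-x)), None),
    "tanh": (np.tanh, None),
    "exp": (np.exp, None),
    "log": (np.log, lambda lam: lam > 0.0),
    "sqrt": (np.sqrt, lambda lam: lam >= 0.0),
    "reciprocal": (lambda x: 1.0 / x, lambda lam: np.abs(lam) > 0.0),
}


def apply_fn_array(f, C: np.ndarray, eig_tol: float = 1e-9) -> np.ndarray:
    """Vectorised f(C) = V f(L) V^{-1} over an array of 2x2 ciphertexts.

    ``f`` is a name from the supported set or a vectorised callable.  The
    function is applied independently to both eigenvalue tracks, so the
    filler undergoes the same dataflow as the message ("shadow computation").
    """
    if isinstance(f, str):
        try:
            fn, domain = _F[f]
        except KeyError:
            raise ValueError(f"unsupported function {f!r}") from None
    else:
        fn, domain = f, None
    lam1, lam2, V, degenerate, _ = _eig_batch(C, eig_tol)
    if domain is not None and not (np.all(domain(lam1)) and np.all(domain(lam2))):
        raise CiphertextDomainError("a ciphertext eigenvalue lies outside the function domain")
    f1 = fn(lam1)
    f2 = fn(lam2)
    detV = V[..., 0, 0] * V[..., 1, 1] - V[..., 0, 1] * V[..., 1, 0]
    detV = np.where(degenerate, 1.0, detV)
    out = np.empty_like(C)
    # V @ diag(f1, f2) @ V^{-1}, expanded entrywise
    v00, v01, v10, v11 = V[..., 0, 0], V[..., 0, 1], V[..., 1, 0], V[..., 1, 1]
    out[..., 0, 0] = (f1 * v00 * v11 - f2 * v01 * v10) / detV
    out[..., 0, 1] = (f2 - f1) * v00 * v01 / detV
    out[..., 1, 0] = (f1 - f2) * v10 * v11 / detV
    out[..., 1, 1] = (f2 * v00 * v11 - f1 * v01 * v10) / detV
    if np.any(degenerate):
        mid = fn(0.5 * (C[..., 0, 0] + C[..., 1, 1]))
        scalar = lift_array(mid)
        out = np.where(degenerate[..., None, None], scalar, out)
    return out


def apply_unary(f, C: Ciphertext, eig_tol: float = 1e-9) -> Ciphertext:
    """Apply a scalar function to one ciphertext through its eigenvalues."""
    return Ciphertext(apply_fn_array(f, C.data[None], eig_tol)[0])


def sigmoid_direct(C: Ciphertext) -> Ciphertext:
    """Sigmoid as a matrix function: (I + expm(-C))^{-1}.

    Cross-checks the eigendecomposition route; for real eigenvalues the
    matrix I + expm(-C) has eigenvalues 1 + e^{-lam} > 1 and is invertible.
    """
    A = np.eye(2) + expm(-C.data)
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    assert abs(det) > 0.0, "I + expm(-C) singular: ciphertext had complex eigenvalues"
    inv = np.array([[A[1, 1], -A[0, 1]], [-A[1, 0], A[0, 0]]]) / det
    return Ciphertext(inv)


def compare_plain(C: Ciphertext, s: float, mode: str, eig_tol: float = 1e-9) -> Ciphertext:
    """Encrypted comparison of a ciphertext with a plain scalar.

    The result is itself a ciphertext decrypting to 1.0 or 0.0 -- it cannot
    drive plaintext control flow.  Ties at m == s follow the strict/inclusive
    semantics of the requested mode.
    """
    s = float(s)
    preds = {
        "lt": lambda lam: lam < s,
        "le": lambda lam: lam <= s,
        "gt": lambda lam: lam > s,
        "ge": lambda lam: lam >= s,
    }
    try:
        pred = preds[mode]
    except KeyError:
        raise ValueError(f"unknown comparison mode {mode!r}") from None
    return apply_unary(lambda lam: pred(lam).astype(float), C, eig_tol)
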