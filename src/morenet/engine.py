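"""Scalar-generic array operations shared by the plaintext and ciphertext paths.

A plain tensor stores float64 scalars with shape ``s``; a cipher tensor stores
one 2x2 MORE ciphertext block per scalar with shape ``s + (2, 2)``.  Every
helper here dispatches on the kind so that the network code above it is
written once and runs unchanged on both representations -- the property the
homomorphic scheme is built to deliver.

Plaintext constants participate in cipher arithmetic through the exact,
key-free lift ``s -> s*I``; multiplying a ciphertext by a plain scalar is
therefore an ordinary scalar-matrix product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import crypto

PLAIN = "plain"
CIPHER = "cipher"


@dataclass
class Tensor:
    """Homogeneous array of plain scalars or ciphertext blocks."""

    values: np.ndarray
    kind: str = PLAIN

    def __post_init__(self):
        if self.kind not in (PLAIN, CIPHER):
            raise ValueError(f"unknown scalar kind {self.kind!r}")
        if self.kind == CIPHER and (self.values.ndim < 2 or self.values.shape[-2:] != (2, 2)):
            raise ValueError("cipher tensor values must end in a (2, 2) axis pair")

    @property
    def shape(self) -> tuple:
        return self.values.shape[:-2] if self.kind == CIPHER else self.values.shape

    @property
    def size(self) -> int:
        return int(np.prod(self.shape, dtype=int)) if self.shape else 1

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        tail = (2, 2) if self.kind == CIPHER else ()
        return Tensor(self.values.reshape(tuple(shape) + tail), self.kind)

    def copy(self) -> "Tensor":
        return Tensor(self.values.copy(), self.kind)


def zeros(shape, kind: str) -> Tensor:
    tail = (2, 2) if kind == CIPHER else ()
    return Tensor(np.zeros(tuple(shape) + tail), kind)


def from_plain(values: np.ndarray) -> Tensor:
    return Tensor(np.asarray(values, dtype=float), PLAIN)


def encrypt_tensor(t: Tensor, key, config) -> Tensor:
    if t.kind == CIPHER:
        raise ValueError("tensor is already encrypted")
    return Tensor(crypto.encrypt_array(t.values, key, config), CIPHER)


def decrypt_tensor(t: Tensor, key) -> Tensor:
    if t.kind == PLAIN:
        return t.copy()
    return Tensor(crypto.decrypt_array(t.values, key), PLAIN)


def _check_same_kind(a: Tensor, b: Tensor):
    if a.kind != b.kind:
        raise ValueError("mixed plain/cipher operands; lift the plain one explicitly")


# -- elementwise arithmetic (broadcasting over the scalar shape) ------------


def add(a: Tensor, b: Tensor) -> Tensor:
    _check_same_kind(a, b)
    return Tensor(a.values + b.values, a.kind)


def sub(a: Tensor, b: Tensor) -> Tensor:
    _check_same_kind(a, b)
    return Tensor(a.values - b.values, a.kind)


def mul(a: Tensor, b: Tensor) -> Tensor:
    _check_same_kind(a, b)
    if a.kind == CIPHER:
        return Tensor(np.matmul(a.values, b.values), CIPHER)
    return Tensor(a.values * b.values, PLAIN)


def div(a: Tensor, b: Tensor, eig_tol: float = 1e-9) -> Tensor:
    _check_same_kind(a, b)
    if a.kind == CIPHER:
        return Tensor(crypto.cipher_div(a.values, b.values, eig_tol), CIPHER)
    return Tensor(a.values / b.values, PLAIN)


def neg(a: Tensor) -> Tensor:
    return Tensor(-a.values, a.kind)


def add_plain(a: Tensor, p) -> Tensor:
    """a + p*I with p a plain scalar or array broadcastable to a's shape."""
    p = np.asarray(p, dtype=float)
    if a.kind == CIPHER:
        return Tensor(a.values + crypto.lift_array(np.broadcast_to(p, a.shape)), CIPHER)
    return Tensor(a.values + p, PLAIN)


def mul_plain(a: Tensor, p) -> Tensor:
    """a * p with p plain; for cipher this is entrywise scaling (p*I commutes)."""
    p = np.asarray(p, dtype=float)
    if a.kind == CIPHER:
        return Tensor(a.values * p[..., None, None], CIPHER)
    return Tensor(a.values * p, PLAIN)


def sub_mixed(a: Tensor, b) -> Tensor:
    """a - b where b may be a Tensor of either kind or a plain array."""
    if isinstance(b, Tensor):
        if b.kind == a.kind:
            return sub(a, b)
        if a.kind == CIPHER and b.kind == PLAIN:
            return add_plain(a, -b.values)
        raise ValueError("cannot subtract cipher from plain")
    return add_plain(a, -np.asarray(b, dtype=float))


def fsum(a: Tensor, axis, keepdims: bool = False) -> Tensor:
    """Sum over scalar axes (the trailing 2x2 block axes are preserved)."""
    if a.kind == CIPHER:
        ax = axis if axis >= 0 else axis - 2
        return Tensor(np.sum(a.values, axis=ax, keepdims=keepdims), CIPHER)
    return Tensor(np.sum(a.values, axis=axis, keepdims=keepdims), PLAIN)


def total(a: Tensor) -> Tensor:
    """Sum of all scalars -> 0-d tensor."""
    if a.kind == CIPHER:
        n = a.values.ndim
        return Tensor(np.sum(a.values, axis=tuple(range(n - 2))), CIPHER)
    return Tensor(np.asarray(np.sum(a.values)), PLAIN)


def apply_fn(name, a: Tensor, eig_tol: float = 1e-9) -> Tensor:
    """Elementwise nonlinear function; cipher path goes through eigenvalues."""
    if a.kind == CIPHER:
        return Tensor(crypto.apply_fn_array(name, a.values, eig_tol), CIPHER)
    fn = crypto._F[name][0] if isinstance(name, str) else name
    return Tensor(fn(a.values), PLAIN)


# -- contractions used by the layers ----------------------------------------


def dense_forward(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """x: (B, n_in), W: (n_in, n_out), b: (n_out) -> (B, n_out)."""
    _check_same_kind(x, W)
    if x.kind == CIPHER:
        out = np.einsum("bixy,ioyz->boxz", x.values, W.values)
        return Tensor(out + b.values, CIPHER)
    return Tensor(x.values @ W.values + b.values, PLAIN)


def dense_backward_x(g: Tensor, W: Tensor) -> Tensor:
    if g.kind == CIPHER:
        return Tensor(np.einsum("boxy,ioyz->bixz", g.values, W.values), CIPHER)
    return Tensor(g.values @ W.values.T, PLAIN)


def dense_backward_w(x: Tensor, g: Tensor) -> Tensor:
    if g.kind == CIPHER:
        return Tensor(np.einsum("bixy,boyz->ioxz", x.values, g.values), CIPHER)
    return Tensor(x.values.T @ g.values, PLAIN)


def conv_patches(x: Tensor) -> Tensor:
    """Zero-padded 3x3 "same" patches: (B, C, H, W) -> (B, C, 9, H, W).

    Padded positions are zero blocks, which is exact for ciphertexts
    (the zero matrix encrypts 0 under every key).
    """
    tail = (2, 2) if x.kind == CIPHER else ()
    B, C, H, W = x.shape
    padded = np.zeros((B, C, H + 2, W + 2) + tail)
    padded[:, :, 1 : H + 1, 1 : W + 1] = x.values
    patches = np.empty((B, C, 9, H, W) + tail)
    for p in range(9):
        i, j = divmod(p, 3)
        patches[:, :, p] = padded[:, :, i : i + H, j : j + W]
    return Tensor(patches, x.kind)


def conv_forward(patches: Tensor, K: Tensor, b: Tensor) -> Tensor:
    """patches: (B, C, 9, H, W), K: (O, C, 9), b: (O,) -> (B, O, H, W)."""
    if patches.kind == CIPHER:
        out = np.einsum("bcphwxy,ocpyz->bohwxz", patches.values, K.values)
        return Tensor(out + b.values[:, None, None], CIPHER)
    out = np.einsum("bcphw,ocp->bohw", patches.values, K.values)
    return Tensor(out + b.values[:, None, None], PLAIN)


def conv_backward_k(patches: Tensor, g: Tensor) -> Tensor:
    if g.kind == CIPHER:
        return Tensor(np.einsum("bcphwxy,bohwyz->ocpxz", patches.values, g.values), CIPHER)
    return Tensor(np.einsum("bcphw,bohw->ocp", patches.values, g.values), PLAIN)


def conv_backward_x(g: Tensor, K: Tensor, in_channels: int) -> Tensor:
    """Scatter the 9 shifted contributions back onto the (padded) input grid."""
    tail = (2, 2) if g.kind == CIPHER else ()
    B = g.shape[0]
    H, W = g.shape[2], g.shape[3]
    dpad = np.zeros((B, in_channels, H + 2, W + 2) + tail)
    for p in range(9):
        i, j = divmod(p, 3)
        if g.kind == CIPHER:
            contrib = np.einsum("bohwxy,ocyz->bchwxz", g.values, K.values[:, :, p])
        else:
            contrib = np.einsum("bohw,oc->bchw", g.values, K.values[:, :, p])
        dpad[:, :, i : i + H, j : j + W] += contrib
    return Tensor(dpad[:, :, 1 : H + 1, 1 : W + 1], g.kind)


def avgpool_forward(x: Tensor) -> Tensor:
    """2x2 stride-2 average pooling (spatial dims must be even)."""
    tail = (2, 2) if x.kind == CIPHER else ()
    B, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError("average pooling requires even spatial dimensions")
    v = x.values.reshape((B, C, H // 2, 2, W // 2, 2) + tail)
    out = (v.sum(axis=3).sum(axis=4)) * 0.25
    return Tensor(out, x.kind)


def avgpool_backward(g: Tensor) -> Tensor:
    v = g.values * 0.25
    v = np.repeat(np.repeat(v, 2, axis=2), 2, axis=3)
    return Tensor(v, g.kind)
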