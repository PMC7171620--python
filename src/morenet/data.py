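"""Self-contained dataset generators, preprocessing and dataset encryption.

Three experiment families are served:

* hemodynamic regression -- circulation-model parameter sets are drawn
  uniformly from physiological ranges, each is forward-simulated to periodic
  steady state, and the (measurement vector, parameter vector) pair becomes a
  training sample.  Forward sampling guarantees measurement/parameter
  consistency by construction, the same consistency a calibrate-then-simulate
  pipeline enforces at far greater cost.
* digit-like images -- procedurally rendered 28x28 glyphs (stroke skeleton
  per digit class, affine jitter, blur, noise) standing in for scanned
  handwritten digits so the multiclass pipeline is testable offline.
* vessel-tree images -- two classes of curvilinear branching trees with
  mirrored root orientation and different branching statistics, standing in
  for left/right coronary angiographic views.

Plus offline augmentation (rotation, shift, zoom), feature normalisation
with train-split statistics, elementwise dataset encryption, and an IDX
reader/writer for externally supplied digit corpora.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from . import crypto, engine, wbc

__all__ = [
    "SamplingRanges",
    "Dataset",
    "sample_wbc_dataset",
    "generate_digits",
    "generate_vessel_trees",
    "augment_images",
    "normalize",
    "encrypt_dataset",
    "decrypt_dataset",
    "read_idx",
    "write_idx",
    "read_pgm",
    "write_pgm",
]

GENERATOR_VERSION = "1.0"


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    """Inputs/targets with named splits and provenance.

    Normalisation statistics, when present, were fitted on the training
    split only and reused verbatim on validation/test.
    """

    inputs: engine.Tensor
    targets: engine.Tensor | np.ndarray
    splits: dict  # name -> index array
    input_names: list = field(default_factory=list)
    target_names: list = field(default_factory=list)
    norm_stats: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def split(self, name: str):
        idx = self.splits[name]
        x = engine.Tensor(self.inputs.values[idx], self.inputs.kind)
        if isinstance(self.targets, engine.Tensor):
            y = engine.Tensor(self.targets.values[idx], self.targets.kind)
        else:
            y = self.targets[idx]
        return x, y

    @property
    def n(self) -> int:
        return self.inputs.shape[0]


def _make_splits(n: int, fractions=(0.7, 0.1, 0.2)) -> dict:
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    idx = np.arange(n)
    return {
        "train": idx[:n_train],
        "validation": idx[n_train : n_train + n_val],
        "test": idx[n_train + n_val :],
    }


# ---------------------------------------------------------------------------
# hemodynamic regression pairs
# ---------------------------------------------------------------------------


@dataclass
class SamplingRanges:
    """Uniform bounds of the freely drawn circulation parameters.

    The systemic side varies dead volume, maximum elastance, activation
    timing (as a fraction of the heart period), total arterial resistance
    with its proximal/distal split, and arterial compliance.  The pulmonary
    side draws its own dead volume, timing and resistance split, while its
    maximum elastance, total resistance and compliance are scaled
    deterministically from the systemic draws so pulmonary pressures sit at
    roughly one sixth of systemic ones.

    The heart period is fixed at ``T_fixed`` by default: the measurement
    vector carries no period (it is known clinically but not among the ten
    listed measurements), and absolute resistances and timings are only
    identifiable from the measurements when the period is known.  Set ``T``
    to a (low, high) range to sample it instead.
    """

    lv_emax: tuple = (1.0, 4.0)
    lv_v0: tuple = (5.0, 30.0)
    lv_tau_frac: tuple = (0.25, 0.40)  # fraction of T
    sys_r_total: tuple = (0.7, 1.7)
    sys_ratio: tuple = (0.03, 0.10)  # R_p / R_d
    csys: tuple = (0.5, 2.5)
    T_fixed: float = 0.9
    T: tuple | None = None
    rv_v0: tuple = (5.0, 25.0)
    rv_tau_frac: tuple = (0.25, 0.40)
    pul_ratio: tuple = (0.03, 0.15)
    # deterministic pulmonary scalings
    pul_resistance_scale: float = 1.0 / 14.0
    pul_emax_scale: float = 0.25
    pul_compliance_scale: float = 3.5

    def validate(self):
        names = ["lv_emax", "lv_v0", "lv_tau_frac", "sys_r_total", "sys_ratio",
                 "csys", "rv_v0", "rv_tau_frac", "pul_ratio"]
        if self.T is not None:
            names.append("T")
        elif self.T_fixed <= 0:
            raise ValueError("T_fixed must be positive")
        for name in names:
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: need low < high")
            if lo <= 0 and name not in ("lv_v0", "rv_v0"):
                raise ValueError(f"{name}: bounds must be positive")


def params_from_draw(draw: np.ndarray, ranges: SamplingRanges) -> wbc.WBCParameters:
    """Map one uniform draw vector (10 components in [0, 1]) to parameters."""

    def u(lo_hi, x):
        return lo_hi[0] + (lo_hi[1] - lo_hi[0]) * x

    emax = u(ranges.lv_emax, draw[0])
    v0 = u(ranges.lv_v0, draw[1])
    tau_f = u(ranges.lv_tau_frac, draw[2])
    r_tot = u(ranges.sys_r_total, draw[3])
    ratio = u(ranges.sys_ratio, draw[4])
    csys = u(ranges.csys, draw[5])
    T = u(ranges.T, draw[6]) if ranges.T is not None else ranges.T_fixed
    rv_v0 = u(ranges.rv_v0, draw[7])
    rv_tau_f = u(ranges.rv_tau_frac, draw[8])
    pratio = u(ranges.pul_ratio, draw[9])

    r_pul_tot = r_tot * ranges.pul_resistance_scale
    return replace(
        wbc.WBCParameters(),
        lv_emax=emax, lv_v0=v0, lv_tau=tau_f * T,
        rv_emax=emax * ranges.pul_emax_scale, rv_v0=rv_v0, rv_tau=rv_tau_f * T,
        la_tau=0.1 * T, ra_tau=0.1 * T,
        rsys_p=r_tot * ratio / (1.0 + ratio), rsys_d=r_tot / (1.0 + ratio),
        csys=csys,
        rpul_p=r_pul_tot * pratio / (1.0 + pratio), rpul_d=r_pul_tot / (1.0 + pratio),
        cpul=csys * ranges.pul_compliance_scale,
        T=T,
    )


def sample_wbc_dataset(n: int, ranges: SamplingRanges | None = None, seed: int = 0,
                       dt: float = 1e-4, max_cycles: int = 30,
                       periodicity_tol: float = 1e-4,
                       drop_rv_et: bool = False,
                       fractions=(0.7, 0.1, 0.2)) -> Dataset:
    """Forward-sampled (measurement, parameter) regression pairs.

    Parameters are drawn uniformly inside ``ranges``, simulated to periodic
    steady state, and degenerate runs (blow-up, non-convergence, a valve
    that never opens, volume drift) are rejected and redrawn.  With
    ``drop_rv_et`` the right-ventricular ejection time is removed from the
    inputs, reducing the measurement vector from 10 to 9 components.
    """
    if n < 10:
        raise ValueError("need n >= 10")
    ranges = ranges or SamplingRanges()
    ranges.validate()
    rng = np.random.default_rng(seed)
    inputs = np.empty((n, 10))
    targets = np.empty((n, 12))
    filled = 0
    attempted = 0
    rejected = 0
    batch = max(64, n // 8)
    while filled < n:
        want = min(batch, 2 * (n - filled) + 32)
        draws = rng.random((want, 10))
        plist = [params_from_draw(d, ranges) for d in draws]
        meas, ok, _ = wbc.simulate_measurements_batch(
            plist, dt=dt, max_cycles=max_cycles, periodicity_tol=periodicity_tol)
        attempted += want
        rejected += int(want - ok.sum())
        if attempted >= max(200, 2 * n) and rejected > 0.5 * attempted:
            raise RuntimeError(
                f"rejection rate {rejected / attempted:.0%} exceeds 50%; "
                "the sampling ranges produce mostly degenerate circulations")
        for i in np.nonzero(ok)[0]:
            if filled >= n:
                break
            inputs[filled] = meas[i]
            targets[filled] = wbc.targets_from_params(plist[i]).as_array()
            filled += 1
    input_names = list(wbc.MEASUREMENT_NAMES)
    if drop_rv_et:
        keep = [i for i, nm in enumerate(input_names) if nm != "rv_et"]
        inputs = inputs[:, keep]
        input_names = [input_names[i] for i in keep]
    return Dataset(
        inputs=engine.from_plain(inputs),
        targets=engine.from_plain(targets),
        splits=_make_splits(n, fractions),
        input_names=input_names,
        target_names=list(wbc.TARGET_NAMES),
        provenance={
            "generator": "wbc-forward-sampling",
            "version": GENERATOR_VERSION,
            "seed": int(seed),
            "n": int(n),
            "dt": float(dt),
            "rejected": int(rejected),
            "attempted": int(attempted),
        },
    )


# ---------------------------------------------------------------------------
# digit-like images
# ---------------------------------------------------------------------------

# stroke skeletons on the unit square, (x, y) with y growing downward
_DIGIT_STROKES = {
    0: [[(0.5, 0.08), (0.82, 0.3), (0.82, 0.7), (0.5, 0.92), (0.18, 0.7), (0.18, 0.3), (0.5, 0.08)]],
    1: [[(0.35, 0.25), (0.55, 0.1), (0.55, 0.9)], [(0.35, 0.9), (0.75, 0.9)]],
    2: [[(0.2, 0.3), (0.35, 0.12), (0.65, 0.12), (0.8, 0.3), (0.75, 0.5), (0.25, 0.85), (0.2, 0.9),
         (0.8, 0.9)]],
    3: [[(0.22, 0.15), (0.7, 0.12), (0.78, 0.3), (0.5, 0.48), (0.78, 0.65), (0.7, 0.88),
         (0.22, 0.85)]],
    4: [[(0.65, 0.9), (0.65, 0.1), (0.2, 0.62), (0.85, 0.62)]],
    5: [[(0.75, 0.12), (0.25, 0.12), (0.25, 0.45), (0.65, 0.45), (0.8, 0.65), (0.65, 0.88),
         (0.22, 0.85)]],
    6: [[(0.7, 0.1), (0.35, 0.35), (0.22, 0.65), (0.4, 0.9), (0.7, 0.85), (0.78, 0.62),
         (0.5, 0.5), (0.25, 0.6)]],
    7: [[(0.18, 0.12), (0.82, 0.12), (0.45, 0.9)], [(0.35, 0.5), (0.7, 0.5)]],
    8: [[(0.5, 0.1), (0.75, 0.25), (0.5, 0.48), (0.25, 0.25), (0.5, 0.1)],
        [(0.5, 0.48), (0.8, 0.7), (0.5, 0.92), (0.2, 0.7), (0.5, 0.48)]],
    9: [[(0.75, 0.35), (0.5, 0.48), (0.25, 0.32), (0.45, 0.1), (0.75, 0.18), (0.75, 0.35),
         (0.68, 0.9)]],
}


def _render_strokes(strokes, size: int) -> np.ndarray:
    img = np.zeros((size, size))
    for poly in strokes:
        pts = np.asarray(poly)
        for a, b in zip(pts[:-1], pts[1:]):
            length = np.linalg.norm(b - a)
            steps = max(2, int(length * size * 3))
            ts = np.linspace(0.0, 1.0, steps)
            xs = (a[0] + ts * (b[0] - a[0])) * (size - 1)
            ys = (a[1] + ts * (b[1] - a[1])) * (size - 1)
            img[np.clip(np.round(ys).astype(int), 0, size - 1),
                np.clip(np.round(xs).astype(int), 0, size - 1)] = 1.0
    return img


def generate_digits(n: int, classes: int = 10, size: int = 28, seed: int = 0) -> Dataset:
    """Balanced procedural digit glyphs with one-hot labels.

    Each image is a stroke skeleton jittered by a random affine transform
    (rotation, shift, scale), blurred and noised, then min-max scaled from
    the synthetic 0-255 intensity range to [0, 1].
    """
    if n % classes:
        raise ValueError("n must be a multiple of the class count")
    rng = np.random.default_rng(seed)
    per = n // classes
    images = np.empty((n, 1, size, size))
    labels = np.zeros((n, classes))
    order = np.tile(np.arange(classes), per)
    for i, cls in enumerate(order):
        base = _render_strokes(_DIGIT_STROKES[int(cls) % 10], size)
        angle = rng.uniform(-12.0, 12.0)
        zoom = rng.uniform(0.85, 1.1)
        shift = rng.uniform(-1.8, 1.8, size=2)
        img = ndimage.rotate(base, angle, reshape=False, order=1)
        img = ndimage.zoom(img, zoom, order=1)
        img = _center_crop_or_pad(img, size)
        img = ndimage.shift(img, shift, order=1)
        img = ndimage.gaussian_filter(img, sigma=rng.uniform(0.6, 0.9))
        img = img / max(img.max(), 1e-9)
        img = np.clip(img * 255.0 + rng.normal(0.0, 6.0, img.shape), 0.0, 255.0)
        images[i, 0] = img
        labels[i, int(cls)] = 1.0
    images /= 255.0
    return Dataset(
        inputs=engine.from_plain(images),
        targets=engine.from_plain(labels),
        splits=_make_splits(n),
        target_names=[str(c) for c in range(classes)],
        provenance={"generator": "procedural-digits", "version": GENERATOR_VERSION,
                    "seed": int(seed), "n": int(n)},
    )


def _center_crop_or_pad(img: np.ndarray, size: int) -> np.ndarray:
    out = np.zeros((size, size))
    h, w = img.shape
    if h >= size:
        o = (h - size) // 2
        img = img[o : o + size, o : o + size] if w >= size else img[o : o + size, :]
        h, w = img.shape
    if w >= size and h <= size:
        o = (w - size) // 2
        img = img[:, o : o + size]
        h, w = img.shape
    oy, ox = (size - h) // 2, (size - w) // 2
    out[oy : oy + h, ox : ox + w] = img
    return out


# ---------------------------------------------------------------------------
# vessel-tree images
# ---------------------------------------------------------------------------


def _draw_segment(img, x0, y0, x1, y1, width):
    size = img.shape[0]
    steps = max(2, int(np.hypot(x1 - x0, y1 - y0) * 2.5))
    ts = np.linspace(0.0, 1.0, steps)
    xs = x0 + ts * (x1 - x0)
    ys = y0 + ts * (y1 - y0)
    r = max(1, int(round(width)))
    for x, y in zip(xs, ys):
        xi, yi = int(round(x)), int(round(y))
        img[max(0, yi - r) : min(size, yi + r + 1), max(0, xi - r) : min(size, xi + r + 1)] = 1.0


def _grow_tree(img, rng, x, y, angle, length, width, depth, branch_prob, spread):
    size = img.shape[0]
    if depth <= 0 or length < 2 or not (0 <= x < size and 0 <= y < size):
        return
    # wiggly main segment
    seg = 4
    for _ in range(seg):
        nx = x + np.cos(angle) * length / seg
        ny = y + np.sin(angle) * length / seg
        _draw_segment(img, x, y, nx, ny, width)
        x, y = nx, ny
        angle += rng.normal(0.0, 0.08)
    if rng.random() < branch_prob:
        da = rng.uniform(0.35, spread)
        _grow_tree(img, rng, x, y, angle - da, length * rng.uniform(0.6, 0.85),
                   max(width * 0.7, 0.8), depth - 1, branch_prob, spread)
        _grow_tree(img, rng, x, y, angle + da, length * rng.uniform(0.6, 0.85),
                   max(width * 0.7, 0.8), depth - 1, branch_prob, spread)
    else:
        _grow_tree(img, rng, x, y, angle + rng.normal(0.0, 0.15),
                   length * rng.uniform(0.75, 0.9), width, depth - 1, branch_prob, spread)


def generate_vessel_trees(n: int, size: int = 256, seed: int = 0) -> Dataset:
    """Two balanced classes of branching vessel-like trees.

    Class 0 ("left-type") roots at the upper-left and branches densely with
    wide spread; class 1 ("right-type") roots at the upper-right as a
    sparser, C-shaped dominant trunk.  Labels are plaintext scalars 0/1.
    Pixel intensities are min-max scaled to [0, 1] per image.
    """
    if n % 2:
        raise ValueError("n must be even for a 1:1 class balance")
    rng = np.random.default_rng(seed)
    images = np.empty((n, 1, size, size))
    labels = np.empty(n)
    for i in range(n):
        cls = i % 2
        img = np.zeros((size, size))
        if cls == 0:
            x0, y0 = size * rng.uniform(0.12, 0.25), size * rng.uniform(0.1, 0.2)
            angle = rng.uniform(0.5, 0.9)
            _grow_tree(img, rng, x0, y0, angle, size * 0.3, size / 110, 6, 0.75, 0.8)
        else:
            x0, y0 = size * rng.uniform(0.75, 0.88), size * rng.uniform(0.1, 0.2)
            angle = np.pi - rng.uniform(0.3, 0.6)
            _grow_tree(img, rng, x0, y0, angle, size * 0.42, size / 90, 5, 0.35, 0.55)
        img = ndimage.gaussian_filter(img, sigma=size / 128)
        img += rng.normal(0.0, 0.03, img.shape)
        lo, hi = img.min(), img.max()
        images[i, 0] = (img - lo) / max(hi - lo, 1e-9)
        labels[i] = cls
    return Dataset(
        inputs=engine.from_plain(images),
        targets=engine.from_plain(labels[:, None]),
        splits=_make_splits(n),
        target_names=["is_right_type"],
        provenance={"generator": "vessel-trees", "version": GENERATOR_VERSION,
                    "seed": int(seed), "n": int(n), "size": int(size)},
    )


# ---------------------------------------------------------------------------
# augmentation and normalisation
# ---------------------------------------------------------------------------


def augment_images(images: np.ndarray, labels: np.ndarray, factor: int = 4, seed: int = 0):
    """Offline augmentation: originals plus ``factor - 1`` jittered copies.

    Each copy applies a rotation uniform in +/-10 degrees, a shift uniform
    within +/-10% of the image side, and a zoom uniform in [0.9, 1.1];
    labels are copied verbatim.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    images = np.asarray(images, dtype=float)
    labels = np.asarray(labels)
    if factor == 1:
        return images.copy(), labels.copy()
    rng = np.random.default_rng(seed)
    out_imgs = [images]
    out_labels = [labels]
    side = images.shape[-1]
    for _ in range(factor - 1):
        batch = np.empty_like(images)
        for i in range(images.shape[0]):
            img = images[i, 0] if images.ndim == 4 else images[i]
            angle = rng.uniform(-10.0, 10.0)
            shift = rng.uniform(-0.1, 0.1, size=2) * side
            zoom = rng.uniform(0.9, 1.1)
            t = ndimage.rotate(img, angle, reshape=False, order=1)
            t = ndimage.zoom(t, zoom, order=1)
            t = _center_crop_or_pad(t, side)
            t = ndimage.shift(t, shift, order=1)
            if images.ndim == 4:
                batch[i, 0] = t
            else:
                batch[i] = t
        out_imgs.append(batch)
        out_labels.append(labels.copy())
    return np.concatenate(out_imgs, axis=0), np.concatenate(out_labels, axis=0)


def normalize(data: np.ndarray, method: str, stats: dict | None = None):
    """Per-feature normalisation of a 2-D feature table.

    ``minmax`` maps the fitted min to 0 and max to 1 (constant features map
    to 0); ``meanstd`` standardises to zero mean, unit variance (zero-spread
    features are centred only).  When ``stats`` is given it is applied
    verbatim (validation/test path); otherwise statistics are fitted on
    ``data`` and returned for reuse.
    """
    data = np.asarray(data, dtype=float)
    if data.size == 0:
        raise ValueError("empty data")
    if stats is None:
        if method == "minmax":
            stats = {"method": "minmax", "min": data.min(axis=0), "max": data.max(axis=0)}
        elif method == "meanstd":
            stats = {"method": "meanstd", "mean": data.mean(axis=0), "std": data.std(axis=0)}
        else:
            raise ValueError(f"unknown normalisation method {method!r}")
    if stats["method"] != method:
        raise ValueError("statistics were fitted for a different method")
    if method == "minmax":
        span = stats["max"] - stats["min"]
        safe = np.where(span > 0, span, 1.0)
        return (data - stats["min"]) / safe, stats
    mean, std = stats["mean"], stats["std"]
    safe = np.where(std > 0, std, 1.0)
    return (data - mean) / safe, stats


def denormalize(data: np.ndarray, stats: dict) -> np.ndarray:
    if stats["method"] == "minmax":
        span = stats["max"] - stats["min"]
        return data * np.where(span > 0, span, 1.0) + stats["min"]
    return data * np.where(stats["std"] > 0, stats["std"], 1.0) + stats["mean"]


def normalize_dataset(ds: Dataset, input_method: str, target_method: str | None = None) -> Dataset:
    """Fit normalisation on the training split; apply everywhere."""
    xin = ds.inputs.values.reshape(ds.n, -1)
    tr = ds.splits["train"]
    _, xstats = normalize(xin[tr], input_method)
    xnorm, _ = normalize(xin, input_method, xstats)
    stats = {"inputs": xstats}
    targets = ds.targets
    if target_method is not None:
        yv = ds.targets.values if isinstance(ds.targets, engine.Tensor) else ds.targets
        _, ystats = normalize(yv[tr], target_method)
        ynorm, _ = normalize(yv, target_method, ystats)
        stats["targets"] = ystats
        targets = engine.from_plain(ynorm)
    return Dataset(
        inputs=engine.from_plain(xnorm.reshape(ds.inputs.values.shape)),
        targets=targets,
        splits=ds.splits,
        input_names=ds.input_names,
        target_names=ds.target_names,
        norm_stats=stats,
        provenance=dict(ds.provenance),
    )


# ---------------------------------------------------------------------------
# dataset encryption
# ---------------------------------------------------------------------------


def encrypt_dataset(ds: Dataset, key, config, encrypt_targets: bool = True) -> Dataset:
    """Elementwise MORE encryption of the inputs (and optionally targets).

    With ``encrypt_targets=False`` the targets are passed through untouched
    (the plaintext-label setting of the binary classification task).
    """
    targets = ds.targets
    if encrypt_targets:
        if isinstance(targets, engine.Tensor):
            targets = engine.encrypt_tensor(targets, key, config)
        else:
            targets = engine.Tensor(crypto.encrypt_array(targets, key, config), engine.CIPHER)
    return Dataset(
        inputs=engine.encrypt_tensor(ds.inputs, key, config),
        targets=targets,
        splits=ds.splits,
        input_names=ds.input_names,
        target_names=ds.target_names,
        norm_stats=ds.norm_stats,
        provenance=dict(ds.provenance, encrypted=True),
    )


def decrypt_dataset(ds: Dataset, key) -> Dataset:
    targets = ds.targets
    if isinstance(targets, engine.Tensor) and targets.kind == engine.CIPHER:
        targets = engine.decrypt_tensor(targets, key)
    return Dataset(
        inputs=engine.decrypt_tensor(ds.inputs, key),
        targets=targets,
        splits=ds.splits,
        input_names=ds.input_names,
        target_names=ds.target_names,
        norm_stats=ds.norm_stats,
        provenance={k: v for k, v in ds.provenance.items() if k != "encrypted"},
    )


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

_IDX_IMAGE_MAGIC = 2051
_IDX_LABEL_MAGIC = 2049


def read_idx(path) -> np.ndarray:
    """Read an IDX file (big-endian magic, dims, unsigned-byte payload).

    Image files (magic 2051) return (n, rows, cols) arrays; label files
    (magic 2049) return (n,) arrays.
    """
    with open(path, "rb") as fh:
        head = fh.read(4)
        if len(head) < 4:
            raise ValueError("truncated IDX header")
        (magic,) = struct.unpack(">i", head)
        if magic == _IDX_IMAGE_MAGIC:
            n, rows, cols = struct.unpack(">iii", fh.read(12))
            payload = fh.read(n * rows * cols)
            if len(payload) != n * rows * cols:
                raise ValueError("truncated IDX image payload")
            return np.frombuffer(payload, dtype=np.uint8).reshape(n, rows, cols)
        if magic == _IDX_LABEL_MAGIC:
            (n,) = struct.unpack(">i", fh.read(4))
            payload = fh.read(n)
            if len(payload) != n:
                raise ValueError("truncated IDX label payload")
            return np.frombuffer(payload, dtype=np.uint8)
        raise ValueError(f"unrecognised IDX magic {magic}")


def write_idx(path, array: np.ndarray) -> None:
    array = np.asarray(array)
    with open(path, "wb") as fh:
        if array.ndim == 3:
            fh.write(struct.pack(">iiii", _IDX_IMAGE_MAGIC, *array.shape))
        elif array.ndim == 1:
            fh.write(struct.pack(">ii", _IDX_LABEL_MAGIC, array.shape[0]))
        else:
            raise ValueError("IDX writer handles (n,) labels or (n, r, c) images")
        fh.write(array.astype(np.uint8).tobytes())


def write_pgm(path, image: np.ndarray) -> None:
    """Binary PGM (P5) with 8-bit depth; input values in [0, 1]."""
    img = np.clip(np.asarray(image, dtype=float) * 255.0, 0, 255).astype(np.uint8)
    if img.ndim != 2:
        raise ValueError("PGM writer takes one 2-D image")
    with open(path, "wb") as fh:
        fh.write(f"P5\n{img.shape[1]} {img.shape[0]}\n255\n".encode())
        fh.write(img.tobytes())


def read_pgm(path) -> np.ndarray:
    with open(path, "rb") as fh:
        data = fh.read()
    if not data.startswith(b"P5"):
        raise ValueError("not a binary PGM (P5) file")
    parts = data.split(maxsplit=4)
    w, h, maxval = int(parts[1]), int(parts[2]), int(parts[3])
    payload = parts[4][: w * h]
    if len(payload) != w * h:
        raise ValueError("truncated PGM payload")
    return np.frombuffer(payload, dtype=np.uint8).reshape(h, w) / float(maxval)
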