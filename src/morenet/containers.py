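"""On-disk container formats: encrypted/plain tensors and model checkpoints.

Tensor container layout (all integers 64-bit little-endian unsigned):

    bytes 0-5   magic "MOREv1"
    byte  6     scalar kind tag: 0x50 'P' plain, 0x43 'C' cipher
    byte  7     reserved (zero)
    8 bytes     ndim
    8*ndim      shape
    payload     float64 little-endian values, row-major; cipher tensors
                carry a trailing axis of 4 with each ciphertext's entries
                in order (1,1), (1,2), (2,1), (2,2)

Checkpoints are a directory holding a JSON model/config description plus one
container per parameter tensor.  A ciphertext checkpoint never references
the key: an external party can load it and keep computing on ciphertexts.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np

from . import engine, nn

__all__ = [
    "ContainerFormatError",
    "write_tensor",
    "read_tensor",
    "save_checkpoint",
    "load_checkpoint",
    "spec_to_dict",
    "spec_from_dict",
]

_MAGIC = b"MOREv1"
_KIND_TAGS = {engine.PLAIN: b"P", engine.CIPHER: b"C"}
_TAG_KINDS = {v: k for k, v in _KIND_TAGS.items()}


class ContainerFormatError(ValueError):
    pass


def write_tensor(path, t: engine.Tensor) -> None:
    shape = t.shape
    vals = np.ascontiguousarray(t.values, dtype="<f8")
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(_KIND_TAGS[t.kind])
        fh.write(b"\x00")
        fh.write(struct.pack("<Q", len(shape)))
        for s in shape:
            fh.write(struct.pack("<Q", s))
        fh.write(vals.tobytes())


def read_tensor(path) -> engine.Tensor:
    with open(path, "rb") as fh:
        data = fh.read()
    if data[:6] != _MAGIC:
        raise ContainerFormatError("bad magic: not a MORE tensor container")
    tag = data[6:7]
    if tag not in _TAG_KINDS:
        raise ContainerFormatError(f"unknown scalar-kind tag {tag!r}")
    kind = _TAG_KINDS[tag]
    (ndim,) = struct.unpack_from("<Q", data, 8)
    shape = struct.unpack_from(f"<{ndim}Q", data, 16) if ndim else ()
    off = 16 + 8 * ndim
    count = int(np.prod(shape, dtype=int)) if shape else 1
    if kind == engine.CIPHER:
        count *= 4
    payload = data[off : off + 8 * count]
    if len(payload) != 8 * count:
        raise ContainerFormatError("truncated tensor payload")
    vals = np.frombuffer(payload, dtype="<f8").astype(float)
    tail = (2, 2) if kind == engine.CIPHER else ()
    return engine.Tensor(vals.reshape(tuple(int(s) for s in shape) + tail), kind)


# ---------------------------------------------------------------------------
# model spec serialisation
# ---------------------------------------------------------------------------


def spec_to_dict(spec: nn.ModelSpec) -> dict:
    layers = []
    for layer in spec.layers:
        if layer.kind == "dense":
            layers.append({"kind": "dense", "units": layer.units})
        elif layer.kind == "conv2d":
            layers.append({"kind": "conv2d", "filters": layer.filters})
        elif layer.kind == "dropout":
            layers.append({"kind": "dropout", "rate": layer.rate})
        elif layer.kind == "activation":
            layers.append({"kind": "activation", "fn": layer.fn})
        else:
            layers.append({"kind": layer.kind})
    return {"name": spec.name, "input_shape": list(spec.input_shape), "layers": layers}


def spec_from_dict(doc: dict) -> nn.ModelSpec:
    layers = []
    for d in doc["layers"]:
        k = d["kind"]
        if k == "dense":
            layers.append(nn.Dense(int(d["units"])))
        elif k == "conv2d":
            layers.append(nn.Conv2D(int(d["filters"])))
        elif k == "avgpool":
            layers.append(nn.AvgPool())
        elif k == "flatten":
            layers.append(nn.Flatten())
        elif k == "dropout":
            layers.append(nn.Dropout(float(d.get("rate", 0.25))))
        elif k == "activation":
            layers.append(nn.Activation(d["fn"]))
        else:
            raise ContainerFormatError(f"unknown layer kind {k!r}")
    return nn.ModelSpec(input_shape=tuple(doc["input_shape"]), layers=layers,
                        name=doc.get("name", "custom"))


def save_checkpoint(directory, spec: nn.ModelSpec, params: nn.ParameterSet) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tensors = []
    for i, entry in enumerate(params.layers):
        if entry is None:
            continue
        for name, t in entry.items():
            fname = f"layer{i:02d}_{name}.mct"
            write_tensor(directory / fname, t)
            tensors.append({"layer": i, "param": name, "file": fname})
    doc = {"model": spec_to_dict(spec), "scalar_kind": params.kind, "tensors": tensors}
    (directory / "checkpoint.json").write_text(json.dumps(doc, indent=1))


def load_checkpoint(directory):
    directory = Path(directory)
    doc = json.loads((directory / "checkpoint.json").read_text())
    spec = spec_from_dict(doc["model"])
    layers = [None] * len(spec.layers)
    for rec in doc["tensors"]:
        i = int(rec["layer"])
        if layers[i] is None:
            layers[i] = {}
        layers[i][rec["param"]] = read_tensor(directory / rec["file"])
    params = nn.ParameterSet(layers=layers, kind=doc["scalar_kind"])
    params.init_velocities()
    # structural audit: every parameterised layer must have its tensors
    for i, layer in enumerate(spec.layers):
        if layer.kind in ("dense", "conv2d") and layers[i] is None:
            raise ContainerFormatError(f"checkpoint is missing tensors for layer {i}")
    return spec, params
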