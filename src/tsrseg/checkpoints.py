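"""Single-file checkpoint archives (NumPy .npz with a JSON meta record)."""
from __future__ import annotations

import json

import numpy as np


def save_checkpoint(path, arrays: list[np.ndarray], meta: dict) -> None:
    named = {f"arr_{i:05d}": a for i, a in enumerate(arrays)}
    named["__meta__"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8)
    np.savez(path, **named)


def load_checkpoint(path) -> tuple[list[np.ndarray], dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode("utf-8"))
        keys = sorted(k for k in data.files if k.startswith("arr_"))
        arrays = [data[k] for k in keys]
    return arrays, meta
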