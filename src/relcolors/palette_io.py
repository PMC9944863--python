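"""Reading and writing palettes and label maps.

Palettes are written as GIMP .gpl palette files and as JSON; label maps as
indexed PNG images so a quantization can be reconstructed exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .quantize import Quantization

__all__ = ["write_palette_gpl", "write_palette_json", "write_label_png", "read_label_png"]


def write_palette_gpl(quant: Quantization, path: str | Path, name: str = "relevant colors") -> None:
    """GIMP palette file: one 'R G B  name' line per relevant color."""
    rgb = np.clip(np.round(quant.palette), 0, 255).astype(int)
    lines = [f"GIMP Palette\nName: {name}\nColumns: {min(quant.n, 16)}\n#"]
    for i, (r, g, b) in enumerate(rgb):
        lines.append(f"{r:3d} {g:3d} {b:3d}\tcolor-{i}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_palette_json(quant: Quantization, path: str | Path) -> None:
    payload = {
        "method": quant.method_tag,
        "n": quant.n,
        "palette_rgb": [[float(c) for c in row] for row in quant.palette],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_label_png(quant: Quantization, path: str | Path) -> None:
    """Label map as an indexed PNG with the palette embedded (n <= 256)."""
    if quant.n > 256:
        raise ValueError("indexed PNG supports at most 256 labels")
    labels = np.asarray(quant.labels, dtype=np.uint8)
    img = Image.fromarray(labels, mode="P")
    flat = np.zeros(768, dtype=np.uint8)
    rgb = np.clip(np.round(quant.palette), 0, 255).astype(np.uint8)
    flat[: rgb.size] = rgb.reshape(-1)
    img.putpalette(flat.tolist())
    img.save(path)


def read_label_png(path: str | Path) -> Quantization:
    img = Image.open(path)
    if img.mode != "P":
        raise ValueError("expected an indexed PNG label map")
    labels = np.asarray(img)
    palette = np.array(img.getpalette(), dtype=np.float64).reshape(-1, 3)
    n = int(labels.max()) + 1
    return Quantization(palette=palette[:n], labels=labels, n=n, method_tag="from_png")
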