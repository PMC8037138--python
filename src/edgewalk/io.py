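"""Readers and writers: contour text files, PNG images/masks, manifests.

Contour files follow the Sunnybrook dialect: one ``x y`` pair per line,
whitespace-separated, floats accepted. In files x is the column and y
the row; in memory everything is (row, col).
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .metrics import Contour


def load_contour_file(path: str | Path) -> Contour:
    path = Path(path)
    points = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'x y', got {raw!r}")
        try:
            x, y = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric coordinate in {raw!r}") from exc
        points.append((int(round(y)), int(round(x))))
    if not points:
        raise ValueError(f"{path}: no contour points found")
    return Contour(np.array(points), closed=True)


def write_contour_file(contour: Contour, path: str | Path) -> None:
    lines = [f"{c} {r}" for r, c in contour.points]
    Path(path).write_text("\n".join(lines) + "\n")


def write_gray_png(path: str | Path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 8-bit grayscale PNG."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 255).round().astype(np.uint8))


def load_gray_png(path: str | Path) -> np.ndarray:
    """Read a grayscale PNG as floats in [0, 1]."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    return arr.astype(np.float64) / 255.0


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def load_mask_png(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 127).astype(np.uint8)


def load_manifest(path: str | Path) -> list[tuple[Path, Path, Path]]:
    """Read a tab-separated manifest of (image, contour, mask) triples.

    Paths are resolved relative to the manifest's directory.
    """
    path = Path(path)
    base = path.parent
    triples = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated paths, got {raw!r}")
        triples.append(tuple(base / p for p in parts))
    if not triples:
        raise ValueError(f"{path}: empty manifest")
    return triples
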