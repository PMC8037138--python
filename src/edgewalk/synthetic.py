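"""Synthetic left-ventricle-like phantoms with exact ground truth.

Each phantom is a roughly circular bright blood pool on a darker
background, wrapped in a darker ring, with optional boundary notches
mimicking papillary muscles, smooth intensity inhomogeneity, blur and
noise. The boundary is star-convex: r(theta) = R + sum_k a_k sin(k
theta + phi_k) minus notch depressions, sampled densely into an ordered
counterclockwise contour whose rasterization is the ground-truth mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .metrics import Contour, rasterize_contour


@dataclass
class PhantomSpec:
    size: int = 96
    center_jitter: float = 4.0
    base_radius: float = 28.0
    harmonic_amplitudes: tuple[float, ...] = (2.0, 1.5)
    pool_intensity: float = 0.85
    ring_intensity: float = 0.30
    background_intensity: float = 0.12
    ring_width: float = 7.0
    inhomogeneity_amplitude: float = 0.08
    blur_sigma: float = 1.0
    noise_sigma: float = 0.02
    n_depressions: int = 1
    depression_depth: float = 4.0
    depression_width: float = 0.35  # radians
    n_boundary_samples: int = 720
    seed: int = 0

    def __post_init__(self):
        max_pert = sum(abs(a) for a in self.harmonic_amplitudes) + self.depression_depth
        if self.base_radius + max_pert + self.center_jitter >= self.size / 2:
            raise ValueError("radius + perturbations must fit inside the image")
        if self.base_radius - max_pert <= 1:
            raise ValueError("depressions/harmonics would collapse the boundary")


def _boundary_radius(spec: PhantomSpec, theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    r = np.full_like(theta, spec.base_radius)
    for k, amp in enumerate(spec.harmonic_amplitudes, start=1):
        phase = rng.uniform(0, 2 * np.pi)
        r = r + amp * np.sin(k * theta + phase)
    for _ in range(spec.n_depressions):
        center = rng.uniform(0, 2 * np.pi)
        depth = spec.depression_depth * rng.uniform(0.6, 1.0)
        delta = np.angle(np.exp(1j * (theta - center)))
        r = r - depth * np.exp(-0.5 * (delta / spec.depression_width) ** 2)
    return r


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, Contour]:
    """Return (image in [0, 1], binary mask, ordered gt contour)."""
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    cy = size / 2 + rng.uniform(-spec.center_jitter, spec.center_jitter)
    cx = size / 2 + rng.uniform(-spec.center_jitter, spec.center_jitter)

    theta = np.linspace(0.0, 2 * np.pi, spec.n_boundary_samples, endpoint=False)
    radius = _boundary_radius(spec, theta, rng)
    # col = cx + r cos(theta), row = cy - r sin(theta): counterclockwise on screen
    rows = np.round(cy - radius * np.sin(theta)).astype(int)
    cols = np.round(cx + radius * np.cos(theta)).astype(int)
    pts = np.stack([rows, cols], axis=1)
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(pts[1:] != pts[:-1], axis=1)
    contour = Contour(pts[keep], closed=True)
    mask = rasterize_contour(contour, (size, size))

    # intensity model: pool, surrounding darker ring, background
    inside = mask.astype(bool)
    dist_out = ndimage.distance_transform_edt(~inside)
    image = np.full((size, size), spec.background_intensity, dtype=np.float64)
    ring = (~inside) & (dist_out <= spec.ring_width)
    image[ring] = spec.ring_intensity
    image[inside] = spec.pool_intensity

    if spec.inhomogeneity_amplitude > 0:
        yy, xx = np.mgrid[0:size, 0:size] / size
        fy, fx = rng.uniform(0.5, 1.5, size=2)
        py, px = rng.uniform(0, 2 * np.pi, size=2)
        field_map = np.sin(2 * np.pi * fy * yy + py) * np.cos(2 * np.pi * fx * xx + px)
        image = image + spec.inhomogeneity_amplitude * field_map
    if spec.blur_sigma > 0:
        image = ndimage.gaussian_filter(image, spec.blur_sigma)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0, spec.noise_sigma, size=image.shape)
    return np.clip(image, 0.0, 1.0), mask, contour


def perturb_contour(
    gt: Contour, shift: float, seed: int, shape: tuple[int, int]
) -> Contour:
    """Displace every point by iid Gaussian noise of scale ``shift``."""
    if shift < 0:
        raise ValueError("shift must be non-negative")
    if shift == 0:
        return Contour(gt.points.copy(), closed=gt.closed)
    rng = np.random.default_rng(seed)
    pts = gt.points + np.round(rng.normal(0, shift, size=gt.points.shape)).astype(int)
    pts[:, 0] = np.clip(pts[:, 0], 0, shape[0] - 1)
    pts[:, 1] = np.clip(pts[:, 1], 0, shape[1] - 1)
    return Contour(pts, closed=gt.closed)


def sample_spec(rng: np.random.Generator, size: int = 96, seed: int = 0) -> PhantomSpec:
    """Draw a phantom spec with moderate shape/intensity variation."""
    scale = size / 96.0
    return PhantomSpec(
        size=size,
        center_jitter=3.0 * scale,
        base_radius=rng.uniform(24.0, 32.0) * scale,
        harmonic_amplitudes=(
            rng.uniform(0.5, 2.5) * scale,
            rng.uniform(0.3, 1.5) * scale,
        ),
        pool_intensity=rng.uniform(0.75, 0.95),
        ring_intensity=rng.uniform(0.25, 0.4),
        background_intensity=rng.uniform(0.05, 0.2),
        ring_width=rng.uniform(5.0, 9.0) * scale,
        inhomogeneity_amplitude=rng.uniform(0.02, 0.1),
        blur_sigma=rng.uniform(0.6, 1.4) * scale,
        noise_sigma=rng.uniform(0.01, 0.03),
        n_depressions=int(rng.integers(0, 3)),
        depression_depth=rng.uniform(2.0, 4.0) * scale,
        depression_width=rng.uniform(0.25, 0.45),
        seed=seed,
    )


def generate_dataset(
    n: int,
    out_dir: str | Path,
    seed: int = 0,
    size: int = 96,
) -> Path:
    """Write ``n`` phantom triples (image/mask PNG + contour text) plus a manifest.

    Returns the manifest path. Per-item seeds are spawned from the master
    seed so each triple is reproducible in isolation.
    """
    from . import io as ew_io

    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    lines = []
    for i in range(n):
        item_seed = int(master.integers(0, 2**31 - 1))
        spec = sample_spec(np.random.default_rng(item_seed), size=size, seed=item_seed)
        image, mask, contour = generate_phantom(spec)
        img_name, con_name, msk_name = (
            f"phantom_{i:04d}.png",
            f"phantom_{i:04d}_contour.txt",
            f"phantom_{i:04d}_mask.png",
        )
        ew_io.write_gray_png(out_dir / img_name, image)
        ew_io.write_mask_png(out_dir / msk_name, mask)
        ew_io.write_contour_file(contour, out_dir / con_name)
        lines.append(f"{img_name}\t{con_name}\t{msk_name}")
    manifest = out_dir / "manifest.tsv"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest
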