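"""Synthetic lens-free shadow-image generation with known ground truth.

Renders the in-line hologram ("shadow pattern") of single cells under
semi-coherent plane-wave illumination using scalar angular-spectrum
propagation, composites them into full sensor frames, and generates
labeled two-class cohorts (CD34+ vs residual mononuclear cells) whose
shadow statistics mimic those observed on a lens-free imaging device:
a bright central maximum surrounded by concentric dark/bright rings
whose contrast and spacing vary with cell size and optical density.

Physical model
--------------
A cell is a circular object of radius ``radius_um`` with complex
transmittance ``a * exp(i * phase)`` inside the disk and 1 outside
(anti-aliased at the rim by fractional pixel coverage). The field is
propagated to the sensor plane over ``propagation_distance`` with the
band-limited angular-spectrum kernel, and the recorded intensity is
``background_level * |U|**2`` plus Gaussian read noise, clipped and
quantized to the sensor bit depth.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CD34_POS = "CD34_POS"
RESIDUAL = "RESIDUAL"

__all__ = [
    "CD34_POS",
    "RESIDUAL",
    "OpticalConfig",
    "CellSpec",
    "SyntheticFrame",
    "ClassRegime",
    "DEFAULT_CLASS_PARAMS",
    "SamplingError",
    "render_cell_pattern",
    "render_frame",
    "generate_cohort",
    "cohort_crops",
    "first_ring_radius_px",
    "write_cohort",
]


class SamplingError(ValueError):
    """Raised when the diffraction rings are undersampled by the pixel grid."""


@dataclass(frozen=True)
class OpticalConfig:
    """Geometry and sensor parameters of the simulated imaging device.

    Lengths are in meters. Defaults follow a blue-LED (470 nm) lens-free
    imager with a 2592 x 2592-range CMOS sensor; pixel pitch and
    chip-to-sensor distance are simulator choices placing the shadow
    statistics in a realistic range.
    """

    wavelength: float = 470e-9
    pixel_pitch: float = 2.2e-6
    propagation_distance: float = 1.0e-3
    frame_shape: tuple[int, int] = (1944, 2592)
    bit_depth: int = 8
    background_level: float = 100.0
    noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError(f"wavelength must be > 0, got {self.wavelength}")
        if self.pixel_pitch <= 0:
            raise ValueError(f"pixel_pitch must be > 0, got {self.pixel_pitch}")
        if self.propagation_distance <= 0:
            raise ValueError(
                f"propagation_distance must be > 0, got {self.propagation_distance}"
            )
        if min(self.frame_shape) < 64:
            raise ValueError(f"frame dimensions must be >= 64, got {self.frame_shape}")
        if not 0 <= self.background_level < 2**self.bit_depth:
            raise ValueError(
                f"background_level {self.background_level} outside "
                f"[0, {2**self.bit_depth})"
            )

    @property
    def max_count(self) -> int:
        return 2**self.bit_depth - 1


@dataclass(frozen=True)
class CellSpec:
    """Ground-truth description of one simulated cell.

    ``center`` is the (row, col) pixel of the pattern center; ``radius_um``
    the physical cell radius; ``phase_shift`` the optical phase delay through
    the cell (radians); ``amplitude_transmittance`` its absorption factor.
    """

    center: tuple[int, int]
    radius_um: float
    phase_shift: float = 1.8
    amplitude_transmittance: float = 0.95
    class_label: str = CD34_POS

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError(f"radius_um must be > 0, got {self.radius_um}")
        if not 0.0 <= self.amplitude_transmittance <= 1.0:
            raise ValueError(
                "amplitude_transmittance must be in [0, 1], got "
                f"{self.amplitude_transmittance}"
            )


@dataclass
class SyntheticFrame:
    """A rendered sensor frame plus the ground truth that produced it."""

    image: np.ndarray
    cells: list[CellSpec]
    config: OpticalConfig


@dataclass(frozen=True)
class ClassRegime:
    """Per-class distributions over cell radius and optical phase.

    Radii and phases are drawn i.i.d. normal (truncated to stay physical).
    """

    radius_um_mean: float
    radius_um_sd: float
    phase_mean: float
    phase_sd: float
    amplitude_transmittance: float = 0.95


# CD34+ hematopoietic stem/progenitor cells are small (~8-9 um diameter)
# and optically homogeneous; the residual mononuclear fraction is larger.
# These regimes put the CD34+ peak-to-peak distance (PPD) inside the 40-60
# count gate and the residual population well above it.
DEFAULT_CLASS_PARAMS: dict[str, ClassRegime] = {
    CD34_POS: ClassRegime(4.2, 0.25, 1.8, 0.12),
    RESIDUAL: ClassRegime(6.3, 0.5, 1.8, 0.15),
}


def first_ring_radius_px(config: OpticalConfig) -> float:
    """Estimated radius (pixels) of the first dark diffraction ring.

    The first minimum of an in-line point hologram sits near the first
    Fresnel zone, r ~ sqrt(lambda * z).
    """
    return math.sqrt(config.wavelength * config.propagation_distance) / config.pixel_pitch


def _check_sampling(config: OpticalConfig) -> None:
    r1 = first_ring_radius_px(config)
    if r1 < 2.0:
        raise SamplingError(
            f"first dark ring radius {r1:.2f} px < 2 px: pattern undersampled at "
            f"wavelength={config.wavelength}, z={config.propagation_distance}, "
            f"pixel_pitch={config.pixel_pitch}"
        )


def _angular_spectrum_kernel(n: int, config: OpticalConfig) -> np.ndarray:
    fx = np.fft.fftfreq(n, config.pixel_pitch)
    fx2 = (config.wavelength * fx) ** 2
    arg = 1.0 - fx2[:, None] - fx2[None, :]
    kz = 2.0 * np.pi / config.wavelength * np.sqrt(np.maximum(arg, 0.0))
    h = np.exp(1j * config.propagation_distance * kz)
    h[arg <= 0] = 0.0  # drop evanescent components
    return h


def render_cell_pattern(
    config: OpticalConfig, cell: CellSpec, patch_size: int = 64
) -> np.ndarray:
    """Render one cell's shadow pattern as a float intensity patch.

    The cell sits on the pixel ``(patch_size // 2, patch_size // 2)``.
    The returned patch is un-noised and un-quantized, normalized so that
    an empty field equals ``config.background_level`` exactly.
    """
    _check_sampling(config)
    n = 2 * patch_size  # padding suppresses FFT wrap-around
    coords = (np.arange(n) - n // 2) * config.pixel_pitch
    rr = np.hypot(coords[:, None], coords[None, :])
    # fractional pixel coverage at the disk rim (anti-aliased edge)
    cover = np.clip((cell.radius_um * 1e-6 - rr) / config.pixel_pitch + 0.5, 0.0, 1.0)
    t_inside = cell.amplitude_transmittance * np.exp(1j * cell.phase_shift)
    transmittance = 1.0 + cover * (t_inside - 1.0)
    if np.all(cover == 0.0) or t_inside == 1.0:
        # no scattering: uniform background, skip the transform
        return np.full((patch_size, patch_size), config.background_level)
    u = np.fft.ifft2(np.fft.fft2(transmittance) * _angular_spectrum_kernel(n, config))
    intensity = np.abs(u) ** 2 * config.background_level
    c, h = n // 2, patch_size // 2
    return intensity[c - h : c + h, c - h : c + h]


def _min_separation_px(config: OpticalConfig) -> int:
    # two rings out, twice over: keeps neighboring patterns from overlapping
    return math.ceil(3.0 * first_ring_radius_px(config))


def render_frame(
    config: OpticalConfig,
    cells: list[CellSpec],
    patch_size: int = 64,
    rng: np.random.Generator | None = None,
) -> SyntheticFrame:
    """Composite cell patterns additively on the background and digitize.

    Each cell's pattern delta (patch minus background) is added onto a flat
    background, Gaussian read noise of ``config.noise_sigma`` counts is
    added, and the result is clipped and rounded to the sensor bit depth.
    """
    _check_sampling(config)
    rows, cols = config.frame_shape
    half = patch_size // 2
    for i, cell in enumerate(cells):
        r, c = cell.center
        if not (0 <= r < rows and 0 <= c < cols):
            raise ValueError(
                f"cell {i} center {cell.center} outside frame of shape {config.frame_shape}"
            )
    min_sep = _min_separation_px(config)
    centers = np.array([c.center for c in cells], dtype=float)
    for i in range(len(cells)):
        d = np.hypot(*(centers[i] - centers[i + 1 :]).T)
        if len(d) and d.min() < min_sep:
            j = i + 1 + int(np.argmin(d))
            raise ValueError(
                f"cells {i} and {j} are {d.min():.1f} px apart; "
                f"minimum separation is {min_sep} px"
            )

    frame = np.full(config.frame_shape, config.background_level, dtype=np.float64)
    for cell in cells:
        patch = render_cell_pattern(config, cell, patch_size=patch_size)
        r, c = cell.center
        r0, c0 = r - half, c - half
        rs = slice(max(r0, 0), min(r0 + patch_size, rows))
        cs = slice(max(c0, 0), min(c0 + patch_size, cols))
        frame[rs, cs] += (patch - config.background_level)[
            rs.start - r0 : rs.stop - r0, cs.start - c0 : cs.stop - c0
        ]
    if config.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        frame += rng.normal(0.0, config.noise_sigma, size=frame.shape)
    dtype = np.uint8 if config.bit_depth <= 8 else np.uint16
    image = np.clip(np.rint(frame), 0, config.max_count).astype(dtype)
    return SyntheticFrame(image=image, cells=list(cells), config=config)


def _draw_cells(
    config: OpticalConfig,
    class_params: dict[str, ClassRegime],
    n_per_class: int,
    rng: np.random.Generator,
    total: int,
) -> list[CellSpec]:
    """Draw per-cell optical parameters (placement is assigned later)."""
    labels = [lab for lab in class_params for _ in range(n_per_class)]
    rng.shuffle(labels)
    cells = []
    for label in labels[:total]:
        reg = class_params[label]
        radius = max(rng.normal(reg.radius_um_mean, reg.radius_um_sd), 1.0)
        phase = float(np.clip(rng.normal(reg.phase_mean, reg.phase_sd), 0.1, math.pi))
        cells.append(
            CellSpec(
                center=(0, 0),
                radius_um=float(radius),
                phase_shift=phase,
                amplitude_transmittance=reg.amplitude_transmittance,
                class_label=label,
            )
        )
    return cells


def generate_cohort(
    config: OpticalConfig,
    class_params: dict[str, ClassRegime] | None = None,
    n_per_class: int = 10_000,
    seed: int | None = None,
) -> tuple[list[SyntheticFrame], pd.DataFrame]:
    """Generate a labeled two-class cohort of shadow frames.

    Cells are drawn from the per-class radius/phase regimes, packed onto
    as many frames as needed, and rendered. Returns the frames and a
    ground-truth manifest with one row per cell (columns ``frame_index,
    cell_id, row, col, radius_um, phase_rad, class_label``).
    """
    if n_per_class < 0:
        raise ValueError(f"n_per_class must be >= 0, got {n_per_class}")
    if class_params is None:
        class_params = DEFAULT_CLASS_PARAMS
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    columns = ["frame_index", "cell_id", "row", "col", "radius_um", "phase_rad", "class_label"]
    total = n_per_class * len(class_params)
    if total == 0:
        return [], pd.DataFrame(columns=columns)

    margin = 16  # keeps a 30x30 crop window in bounds
    sites = _grid_sites(config, margin)
    if not sites:
        raise ValueError(f"frame shape {config.frame_shape} too small to place cells")
    all_cells = _draw_cells(config, class_params, n_per_class, rng, total)

    frames: list[SyntheticFrame] = []
    records: list[tuple] = []
    per_frame = len(sites)
    for fi in range(math.ceil(total / per_frame)):
        chunk = all_cells[fi * per_frame : (fi + 1) * per_frame]
        chunk = [replace(cell, center=site) for cell, site in zip(chunk, sites)]
        frame = render_frame(config, chunk, rng=rng)
        frames.append(frame)
        for cell in chunk:
            records.append(
                (fi, len(records), cell.center[0], cell.center[1],
                 cell.radius_um, cell.phase_shift, cell.class_label)
            )
    manifest = pd.DataFrame(records, columns=columns)
    return frames, manifest


def _grid_sites(config: OpticalConfig, margin: int) -> list[tuple[int, int]]:
    rows, cols = config.frame_shape
    step = max(_min_separation_px(config) + 8, 2 * margin + 2)
    grid_r = range(margin + step // 2, rows - margin, step)
    grid_c = range(margin + step // 2, cols - margin, step)
    return [(r, c) for r in grid_r for c in grid_c]


def cohort_crops(
    frames: list[SyntheticFrame], manifest: pd.DataFrame, size: int = 30
) -> np.ndarray:
    """Cut ground-truth-centered crops out of cohort frames.

    Returns an array of shape (n_cells, size, size) with the pattern center
    on pixel (size//2 - 1, size//2 - 1), matching the detection pipeline's
    crop convention.
    """
    half = size // 2 - 1
    out = np.empty((len(manifest), size, size), dtype=frames[0].image.dtype if frames else np.uint8)
    for i, rec in enumerate(manifest.itertuples(index=False)):
        img = frames[rec.frame_index].image
        r, c = int(rec.row), int(rec.col)
        out[i] = img[r - half : r - half + size, c - half : c - half + size]
    return out


def write_cohort(
    frames: list[SyntheticFrame],
    manifest: pd.DataFrame,
    out_dir: str | Path,
    fmt: str = "png",
) -> Path:
    """Write frames as 8-bit grayscale images plus CSV manifest and config JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, fr in enumerate(frames):
        p = out / f"frame_{i:04d}.{fmt}"
        iio.imwrite(p, fr.image)
        paths.append(p.name)
    man = manifest.copy()
    man.insert(0, "frame_path", [paths[i] for i in manifest["frame_index"]] if len(manifest) else [])
    man = man.drop(columns=["frame_index"])
    man.to_csv(out / "manifest.csv", index=False)
    if frames:
        cfg = frames[0].config
        (out / "config.json").write_text(
            json.dumps(
                {
                    "wavelength": cfg.wavelength,
                    "pixel_pitch": cfg.pixel_pitch,
                    "propagation_distance": cfg.propagation_distance,
                    "frame_shape": list(cfg.frame_shape),
                    "bit_depth": cfg.bit_depth,
                    "background_level": cfg.background_level,
                    "noise_sigma": cfg.noise_sigma,
                    "seed": cfg.seed,
                },
                indent=2,
            )
        )
    return out / "manifest.csv"
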