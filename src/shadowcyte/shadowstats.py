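"""Radial shadow-pattern statistics: CMV, PPD, MMD, SMD.

A cell's shadow pattern is a bright central maximum ringed by dark and
bright fringes. Its discriminative summary statistics are:

* **CMV** (central maxima value): intensity at the pattern center.
* **MMD** (maxima-to-minima distance): radius, in pixels, of the first
  dark ring — the first local minimum of the radial intensity profile.
* **PPD** (peak-to-peak distance): CMV minus the profile intensity at the
  first dark ring. Despite the historical name it is an intensity
  difference, in counts.
* **SMD**: standard deviation of MMD measured independently in 8 angular
  sectors — an asphericity measure.

CD34+ cells concentrate in a PPD band of 40-60 counts, which ``ppd_gate``
uses to purify training labels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .detect import CellCrop

logger = logging.getLogger(__name__)

N_SECTORS = 8
PPD_GATE_LO = 40.0
PPD_GATE_HI = 60.0

__all__ = [
    "RadialProfile",
    "ShadowParams",
    "BoxplotSummary",
    "radial_profile",
    "compute_params",
    "analyze_crop",
    "ppd_gate",
    "summarize",
    "PPD_GATE_LO",
    "PPD_GATE_HI",
]


@dataclass(frozen=True)
class RadialProfile:
    """Mean intensity at each integer radius from the crop center."""

    radius: np.ndarray
    intensity: np.ndarray
    center: tuple[int, int] = (14, 14)

    def __post_init__(self) -> None:
        if len(self.radius) != len(self.intensity):
            raise ValueError("radius and intensity must be parallel")
        if len(self.radius) and not (np.diff(self.radius) > 0).all():
            raise ValueError("radius must be strictly increasing")


@dataclass(frozen=True)
class ShadowParams:
    """Per-cell shadow statistics; ``valid`` is False when no dark ring exists."""

    cmv: float
    ppd: float
    mmd: int
    smd: float
    valid: bool


@dataclass(frozen=True)
class BoxplotSummary:
    q1: float
    median: float
    q3: float
    iqr: float
    lower_fence: float
    upper_fence: float
    outliers: list


def radial_profile(crop: CellCrop | np.ndarray) -> RadialProfile:
    """Bin crop pixels by rounded Euclidean distance from pixel (14, 14).

    A 30x30 crop yields 15 bins, r = 0..14; pixels farther than 14 px
    (the window corners) are ignored.
    """
    patch = crop.patch if isinstance(crop, CellCrop) else np.asarray(crop)
    if patch.shape != (30, 30):
        raise ValueError(f"expected a 30x30 crop, got {patch.shape}")
    n_bins = 15
    yy, xx = np.indices(patch.shape)
    rr = np.rint(np.hypot(yy - 14, xx - 14)).astype(int)
    sums = np.bincount(rr.ravel(), weights=patch.ravel().astype(np.float64))
    counts = np.bincount(rr.ravel())
    intensity = sums[:n_bins] / counts[:n_bins]
    return RadialProfile(radius=np.arange(n_bins), intensity=intensity)


def _smooth3(values: np.ndarray) -> np.ndarray:
    """3-point moving average; endpoints kept raw."""
    out = values.astype(np.float64).copy()
    if len(values) >= 3:
        out[1:-1] = (values[:-2] + values[1:-1] + values[2:]) / 3.0
    return out


def _first_minimum(intensity: np.ndarray, r_lo: int = 2) -> int | None:
    """First strict local minimum of the smoothed profile, searched outward."""
    sm = _smooth3(np.asarray(intensity, dtype=np.float64))
    for r in range(r_lo, len(sm) - 1):
        if sm[r] < sm[r - 1] and sm[r] < sm[r + 1]:
            return r
    return None


def _sector_profiles(patch: np.ndarray) -> list[np.ndarray]:
    """Radial profiles restricted to 8 equal angular sectors about (14, 14).

    The center pixel (r = 0) belongs to every sector. Empty bins carry NaN.
    """
    yy, xx = np.indices(patch.shape)
    dy, dx = yy - 14.0, xx - 14.0
    rr = np.rint(np.hypot(dy, dx)).astype(int)
    theta = np.arctan2(dy, dx)  # [-pi, pi]
    sector = ((theta + np.pi) / (2 * np.pi / N_SECTORS)).astype(int) % N_SECTORS
    profiles = []
    vals = patch.astype(np.float64)
    for s in range(N_SECTORS):
        sel = (sector == s) | (rr == 0)
        prof = np.full(15, np.nan)
        for r in range(15):
            pix = vals[sel & (rr == r)]
            if pix.size:
                prof[r] = pix.mean()
        profiles.append(prof)
    return profiles


def compute_params(
    profile: RadialProfile, crop: CellCrop | np.ndarray | None = None
) -> ShadowParams:
    """Shadow statistics from a radial profile.

    MMD is localized on the 3-point-smoothed profile (robust to single-bin
    noise) over r in [2, r_max); PPD is read off the RAW profile at that
    radius. When no local minimum exists (e.g. a flat or monotone profile)
    the parameters are returned as zero sentinels with ``valid=False``.
    SMD needs per-sector profiles and is therefore only computed when the
    originating crop is supplied; it is 0.0 otherwise.
    """
    intensity = np.asarray(profile.intensity, dtype=np.float64)
    cmv = float(intensity[0])
    mmd = _first_minimum(intensity)
    if mmd is None:
        return ShadowParams(cmv=cmv, ppd=0.0, mmd=0, smd=0.0, valid=False)
    ppd = cmv - float(intensity[mmd])

    smd = 0.0
    if crop is not None:
        patch = crop.patch if isinstance(crop, CellCrop) else np.asarray(crop)
        sector_mmds = []
        for s, prof in enumerate(_sector_profiles(patch)):
            present = np.flatnonzero(~np.isnan(prof))
            idx = _first_minimum(prof[present], r_lo=int(np.searchsorted(present, 2)))
            if idx is None:
                logger.debug("sector %d has no ring minimum; excluded from SMD", s)
                continue
            sector_mmds.append(int(present[idx]))  # radius, not position
        if sector_mmds:
            smd = float(np.std(sector_mmds))  # population SD
    return ShadowParams(cmv=cmv, ppd=float(ppd), mmd=int(mmd), smd=smd, valid=True)


def analyze_crop(crop: CellCrop | np.ndarray) -> ShadowParams:
    """Convenience: radial profile + parameters (including SMD) of one crop."""
    return compute_params(radial_profile(crop), crop=crop)


def ppd_gate(
    params_list: list[ShadowParams],
    lo: float = PPD_GATE_LO,
    hi: float = PPD_GATE_HI,
) -> list[ShadowParams]:
    """Keep parameter records with lo <= PPD <= hi (closed interval)."""
    return [p for p in params_list if lo <= p.ppd <= hi]


def summarize(values) -> BoxplotSummary:
    """Tukey boxplot summary: type-7 quartiles, fences at 1.5 IQR."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("summarize requires at least one value")
    q1, median, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = values[(values < lo) | (values > hi)].tolist()
    return BoxplotSummary(
        q1=float(q1), median=float(median), q3=float(q3), iqr=float(iqr),
        lower_fence=float(lo), upper_fence=float(hi), outliers=outliers,
    )
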