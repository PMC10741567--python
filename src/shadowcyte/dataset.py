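"""Labeled training-set assembly: PPD label gating, 8:1:1 split, preprocessing.

Positive (CD34+) training crops come from enriched samples of imperfect
purity, so the positive class is purified by keeping only crops whose PPD
falls in the 40-60 count gate; the residual class is taken as-is. Records
are split into train/validation/test at an 8:1:1 ratio, and crops are
bilinearly resized from 30x30 to 50x50 and scaled to [0, 1] for the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import CellCrop
from .shadowstats import PPD_GATE_HI, PPD_GATE_LO, ShadowParams
from .simshadow import CD34_POS, RESIDUAL

LABELS = (CD34_POS, RESIDUAL)
SPLITS = ("train", "val", "test", "unassigned")
MANIFEST_COLUMNS = ["crop_path", "label", "split", "ppd", "source_id"]

__all__ = [
    "DatasetManifest",
    "SplitSpec",
    "build_manifest",
    "split",
    "preprocess",
    "MANIFEST_COLUMNS",
]


@dataclass
class DatasetManifest:
    """Labeled crop records with split assignments, backed by a DataFrame."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = set(MANIFEST_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"manifest missing columns {sorted(missing)}")
        if df["crop_path"].duplicated().any():
            dup = df.loc[df["crop_path"].duplicated(), "crop_path"].iloc[0]
            raise ValueError(f"duplicate crop path: {dup!r}")
        bad = set(df["label"].unique()) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}; expected {LABELS}")
        bad = set(df["split"].unique()) - set(SPLITS)
        if bad:
            raise ValueError(f"unknown splits {sorted(bad)}; expected {SPLITS}")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, split_name: str) -> pd.DataFrame:
        return self.records[self.records["split"] == split_name]

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DatasetManifest":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class SplitSpec:
    """Train/val/test ratio (8:1:1 by default) and shuffling seed."""

    ratios: tuple[float, float, float] = (8, 1, 1)
    seed: int = 0
    stratified: bool = False

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.ratios):
            raise ValueError(f"ratios must be positive, got {self.ratios}")


def build_manifest(
    crop_paths: list[str],
    labels: list[str],
    params: list[ShadowParams],
    source_ids: list[str] | None = None,
    gate: tuple[float, float] = (PPD_GATE_LO, PPD_GATE_HI),
) -> DatasetManifest:
    """Assemble a manifest, PPD-gating the positive class only.

    CD34+ records are kept iff their PPD is inside the closed gate
    interval; residual records are kept unconditionally (the negative
    class needs no purification).
    """
    if not (len(crop_paths) == len(labels) == len(params)):
        raise ValueError("crop_paths, labels and params must be parallel lists")
    if source_ids is None:
        source_ids = [""] * len(crop_paths)
    lo, hi = gate
    rows = []
    for path, label, p, src in zip(crop_paths, labels, params, source_ids):
        if label == CD34_POS and not (lo <= p.ppd <= hi):
            continue
        rows.append((path, label, "unassigned", p.ppd, src))
    return DatasetManifest(pd.DataFrame(rows, columns=MANIFEST_COLUMNS))


def _allocate(n: int, ratios: tuple[float, float, float]) -> tuple[int, int, int]:
    """Floor allocation for val and test; the remainder goes to train."""
    total = sum(ratios)
    n_val = int(n * ratios[1] / total)
    n_test = int(n * ratios[2] / total)
    return n - n_val - n_test, n_val, n_test


def split(manifest: DatasetManifest, spec: SplitSpec = SplitSpec()) -> DatasetManifest:
    """Assign train/val/test splits, reproducibly and order-invariantly.

    Records are sorted by crop path before the seeded shuffle so the
    assignment does not depend on input row order. With ``stratified``,
    allocation is done per label.
    """
    df = manifest.records.sort_values("crop_path", kind="stable").reset_index(drop=True)
    rng = np.random.default_rng(spec.seed)

    def assign(idx: np.ndarray) -> pd.Series:
        order = rng.permutation(len(idx))
        n_train, n_val, n_test = _allocate(len(idx), spec.ratios)
        names = np.empty(len(idx), dtype=object)
        names[order < n_train] = "train"
        names[(order >= n_train) & (order < n_train + n_val)] = "val"
        names[order >= n_train + n_val] = "test"
        return pd.Series(names, index=idx)

    if spec.stratified:
        parts = [assign(df.index[df["label"] == lab].to_numpy()) for lab in LABELS
                 if (df["label"] == lab).any()]
        assigned = pd.concat(parts).sort_index()
    else:
        assigned = assign(df.index.to_numpy())
    out = df.copy()
    out["split"] = assigned
    return DatasetManifest(out)


def preprocess(crop: CellCrop | np.ndarray, bit_depth: int = 8) -> np.ndarray:
    """Bilinear 30x30 -> 50x50 resize, scaled to [0, 1].

    Uses half-pixel sample centers (weights sum to 1, so constant images
    and means are preserved); intensities are divided by 2**bit_depth - 1.
    """
    patch = crop.patch if isinstance(crop, CellCrop) else np.asarray(crop)
    if patch.shape != (30, 30):
        raise ValueError(f"expected a 30x30 crop, got {patch.shape}")
    out = _bilinear_resize(patch.astype(np.float64), 50, 50)
    return out / (2**bit_depth - 1)


def _bilinear_resize(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    h, w = img.shape
    ys = np.clip((np.arange(out_h) + 0.5) * h / out_h - 0.5, 0, h - 1)
    xs = np.clip((np.arange(out_w) + 0.5) * w / out_w - 0.5, 0, w - 1)
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    wy = (ys - y0)[:, None]
    wx = (xs - x0)[None, :]
    return (
        img[np.ix_(y0, x0)] * (1 - wy) * (1 - wx)
        + img[np.ix_(y0, x1)] * (1 - wy) * wx
        + img[np.ix_(y1, x0)] * wy * (1 - wx)
        + img[np.ix_(y1, x1)] * wy * wx
    )
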