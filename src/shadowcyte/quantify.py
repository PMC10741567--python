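"""Per-sample CD34+ quantification and method-agreement analysis.

``classify_sample`` runs the full pipeline (detect -> crop -> preprocess
-> classify) over a sample's frames and reports the CD34+ percentage.
``compare_to_reference`` compares such percentages against a reference
method (e.g. FACS) with ordinary least squares R-squared and a
Bland-Altman analysis: bias = mean(measured - reference) and 95% limits
of agreement at bias +/- 1.96 * SD of the differences.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import detect
from .dataset import preprocess

logger = logging.getLogger(__name__)

__all__ = ["SampleResult", "AgreementReport", "classify_sample", "compare_to_reference",
           "plot_agreement"]


@dataclass(frozen=True)
class SampleResult:
    """CD34+ count and percentage for one sample."""

    sample_id: str
    n_cells: int
    n_positive: int

    def __post_init__(self) -> None:
        if self.n_positive > self.n_cells:
            raise ValueError("n_positive cannot exceed n_cells")

    @property
    def percent_positive(self) -> float:
        return 100.0 * self.n_positive / self.n_cells


@dataclass(frozen=True)
class AgreementReport:
    """Paired-percentage agreement: OLS R^2 plus Bland-Altman statistics."""

    n_pairs: int
    r_squared: float  # NaN when the reference has zero variance
    mean_abs_diff: float
    bias: float
    loa_lower: float
    loa_upper: float

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {k: getattr(self, k) for k in
             ("n_pairs", "r_squared", "mean_abs_diff", "bias", "loa_lower", "loa_upper")},
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def classify_sample(
    model, frames, sample_id: str = "", k_sigma: float = 3.0
) -> SampleResult:
    """Detect, crop and classify every cell in a sample's frames.

    ``model`` needs a ``predict(x) -> class indices`` method (1 = CD34+);
    a plain callable is accepted too. Raises when no cell is detected in
    any frame of the sample.
    """
    inputs = []
    for frame in frames:
        image = frame.image if hasattr(frame, "image") else np.asarray(frame)
        for crop in detect.find_cells(image, k_sigma=k_sigma, source_id=sample_id):
            inputs.append(preprocess(crop))
    if not inputs:
        raise ValueError(f"no cells detected in sample {sample_id!r}")
    x = np.stack(inputs)
    predict = model.predict if hasattr(model, "predict") else model
    pred = np.asarray(predict(x))
    return SampleResult(
        sample_id=sample_id, n_cells=len(pred), n_positive=int((pred == 1).sum())
    )


def compare_to_reference(pairs) -> AgreementReport:
    """Agreement statistics for (reference %, measured %) pairs.

    R^2 is from simple OLS of measured on reference (identical in either
    direction); differences are measured - reference; limits of agreement
    use the sample (n-1) standard deviation. A zero-variance reference
    makes R^2 undefined: it is reported as NaN, not raised.
    """
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (reference, measured) tuples")
    if len(arr) < 2:
        raise ValueError(f"need at least 2 pairs, got {len(arr)}")
    if arr.min() < 0 or arr.max() > 100:
        raise ValueError("percentages must lie in [0, 100]")
    ref, meas = arr[:, 0], arr[:, 1]
    d = meas - ref
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if np.ptp(ref) == 0:
        logger.warning("reference values are constant; R^2 undefined")
        r2 = float("nan")
    elif np.ptp(meas) == 0:
        r2 = 0.0  # flat measurement explains none of the reference spread
    else:
        r2 = float(stats.linregress(ref, meas).rvalue ** 2)
    return AgreementReport(
        n_pairs=len(arr),
        r_squared=r2,
        mean_abs_diff=float(np.abs(d).mean()),
        bias=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
    )


def plot_agreement(pairs, report: AgreementReport, out_dir) -> list:
    """Scatter-plus-identity and Bland-Altman plots as PNG files."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(pairs, dtype=np.float64)
    ref, meas = arr[:, 0], arr[:, 1]

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(ref, meas, c="tab:blue")
    lim = [0, max(100.0, arr.max() * 1.05)]
    ax.plot(lim, lim, "k--", lw=1, label="identity")
    ax.set_xlabel("reference CD34+ (%)")
    ax.set_ylabel("measured CD34+ (%)")
    r2txt = "undefined" if math.isnan(report.r_squared) else f"{report.r_squared:.2f}"
    ax.set_title(f"R² = {r2txt}")
    ax.legend()
    scatter_path = out / "scatter.png"
    fig.savefig(scatter_path, dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((ref + meas) / 2, meas - ref, c="tab:blue")
    for y, style, lab in [(report.bias, "-", f"bias {report.bias:.2f}"),
                          (report.loa_upper, "--", f"+1.96 SD {report.loa_upper:.2f}"),
                          (report.loa_lower, "--", f"-1.96 SD {report.loa_lower:.2f}")]:
        ax.axhline(y, ls=style, c="tab:red")
        ax.annotate(lab, (0.02, y), xycoords=("axes fraction", "data"), fontsize=8)
    ax.set_xlabel("mean of methods (%)")
    ax.set_ylabel("measured − reference (%)")
    ax.set_title("Bland–Altman")
    ba_path = out / "bland_altman.png"
    fig.savefig(ba_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return [scatter_path, ba_path]
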