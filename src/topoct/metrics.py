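"""Reconstruction and organ-overlap evaluation.

Voxel-wise quality is scored with PSNR (dB, data range 1.0 on normalized
volumes), SSIM (3D, Gaussian-weighted local windows), and RMSE expressed in
Hounsfield units by inverting the normalization window.  Anatomical quality
is scored with the per-organ Dice similarity coefficient under a dual
protocol: the reconstructed volume is segmented by the frozen organ
segmenter and compared once against the phantom's ground-truth labels
(M-analog, the counterpart of manual annotation) and once against the
segmenter's own labeling of the true volume (S-analog).  The S-analog
removes the segmenter's own error from the comparison, so it is typically
the more favorable reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.metrics import structural_similarity

from topoct.network import SegNet, segment_labels
from topoct.phantom import LABELS, LabeledPhantom

ORGANS = ("lung", "liver", "bone")
PSNR_INF_SENTINEL = float("inf")


@dataclass(frozen=True)
class MetricsReport:
    """Metric bundle for one reconstructed volume."""

    psnr_db: float
    ssim: float
    rmse_hu: float
    dsc_per_organ: dict = field(default_factory=dict)
    dsc_mean: float = float("nan")
    reference_kind: str = "M_analog"

    def __post_init__(self) -> None:
        if self.rmse_hu < 0:
            raise ValueError("rmse_hu must be >= 0")
        if self.reference_kind not in ("M_analog", "S_analog"):
            raise ValueError(f"unknown reference_kind {self.reference_kind!r}")
        for organ, v in self.dsc_per_organ.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"DSC for {organ} outside [0, 1]: {v}")


def psnr(y_pred: np.ndarray, y_true: np.ndarray, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; identical volumes report infinity."""
    y_pred, y_true = np.asarray(y_pred), np.asarray(y_true)
    if y_pred.shape != y_true.shape:
        raise ValueError(f"shape mismatch: {y_pred.shape} vs {y_true.shape}")
    mse = float(np.mean((y_pred - y_true) ** 2))
    if mse == 0.0:
        return PSNR_INF_SENTINEL
    return float(10.0 * np.log10(data_range**2 / mse))


def rmse_hu(
    y_pred: np.ndarray, y_true: np.ndarray, hu_window: tuple[float, float]
) -> float:
    """Root-mean-square error in HU between two normalized volumes."""
    if hu_window is None:
        raise ValueError("hu_window is required to express RMSE in HU")
    lo, hi = hu_window
    if hi <= lo:
        raise ValueError(f"inverted HU window: {hu_window}")
    y_pred, y_true = np.asarray(y_pred), np.asarray(y_true)
    if y_pred.shape != y_true.shape:
        raise ValueError(f"shape mismatch: {y_pred.shape} vs {y_true.shape}")
    diff_hu = (y_pred - y_true) * (hi - lo)
    return float(np.sqrt(np.mean(diff_hu**2)))


def ssim(y_pred: np.ndarray, y_true: np.ndarray, data_range: float = 1.0) -> float:
    """Mean local SSIM in 3D with an 11-wide Gaussian window (sigma 1.5)."""
    y_pred, y_true = np.asarray(y_pred, float), np.asarray(y_true, float)
    if y_pred.shape != y_true.shape:
        raise ValueError(f"shape mismatch: {y_pred.shape} vs {y_true.shape}")
    if min(y_pred.shape) < 11:
        raise ValueError("volume smaller than the 11-voxel SSIM window")
    return float(
        structural_similarity(
            y_true,
            y_pred,
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
        )
    )


def dsc(mask_pred: np.ndarray, mask_ref: np.ndarray) -> dict:
    """Per-organ Dice coefficients 2|A∩B|/(|A|+|B|) between hard label maps.

    A class absent from both masks scores 1.0; absent from exactly one, 0.0.
    """
    mask_pred, mask_ref = np.asarray(mask_pred), np.asarray(mask_ref)
    if mask_pred.shape != mask_ref.shape:
        raise ValueError(f"shape mismatch: {mask_pred.shape} vs {mask_ref.shape}")
    valid = set(LABELS.values())
    found = set(np.unique(mask_pred)) | set(np.unique(mask_ref))
    if not found <= valid:
        raise ValueError(f"unknown label codes: {sorted(found - valid)}")
    out = {}
    for organ in ORGANS:
        code = LABELS[organ]
        a = mask_pred == code
        b = mask_ref == code
        na, nb = int(a.sum()), int(b.sum())
        if na == 0 and nb == 0:
            out[organ] = 1.0
        elif na == 0 or nb == 0:
            out[organ] = 0.0
        else:
            out[organ] = float(2.0 * np.logical_and(a, b).sum() / (na + nb))
    return out


def evaluate_reconstruction(
    y_pred: np.ndarray,
    phantom: LabeledPhantom,
    segnet: SegNet,
    hu_window: tuple[float, float],
    y_true: np.ndarray | None = None,
) -> tuple[MetricsReport | None, MetricsReport]:
    """Score one reconstruction under the dual-reference DSC protocol.

    ``y_pred`` is the normalized reconstructed volume; the normalized ground
    truth is derived from the phantom (or passed explicitly).  Returns an
    (M-analog, S-analog) report pair: segmenter labels of the prediction are
    compared against the phantom's label mask and against the segmenter's
    labels of the true volume, respectively.  Without a label mask, the
    M-analog report is omitted with a warning.
    """
    import warnings

    lo, hi = hu_window
    if y_true is None:
        from topoct.preprocess import normalize_hu

        y_true = normalize_hu(phantom.hu_volume, lo, hi).values
    base = {
        "psnr_db": psnr(y_pred, y_true),
        "ssim": ssim(y_pred, y_true),
        "rmse_hu": rmse_hu(y_pred, y_true, hu_window),
    }
    pred_labels = segment_labels(segnet, y_pred)

    def report(ref_labels: np.ndarray, kind: str) -> MetricsReport:
        per_organ = dsc(pred_labels, ref_labels)
        return MetricsReport(
            **base,
            dsc_per_organ=per_organ,
            dsc_mean=float(np.mean(list(per_organ.values()))),
            reference_kind=kind,
        )

    if phantom.labels.any():
        m_report = report(phantom.labels, "M_analog")
    else:
        warnings.warn("phantom has no labels: M-analog DSC omitted")
        m_report = None
    s_report = report(segment_labels(segnet, y_true), "S_analog")
    return m_report, s_report


def write_reports(reports: list[dict], path: Path) -> None:
    """One-row-per-volume delimited report file with a header line."""
    if not reports:
        raise ValueError("no reports to write")
    keys = list(reports[0].keys())
    with open(path, "w") as fh:
        fh.write("\t".join(keys) + "\n")
        for r in reports:
            fh.write("\t".join(str(r[k]) for k in keys) + "\n")


def aggregate_reports(reports: list[MetricsReport]) -> dict:
    """Mean and standard deviation per metric over an evaluation set."""
    if not reports:
        raise ValueError("no reports to aggregate")
    out = {}
    for name in ("psnr_db", "ssim", "rmse_hu", "dsc_mean"):
        vals = [getattr(r, name) for r in reports]
        finite = [v for v in vals if np.isfinite(v)]
        out[name] = {
            "mean": float(np.mean(finite)) if finite else float("nan"),
            "std": float(np.std(finite)) if finite else float("nan"),
        }
    for organ in ORGANS:
        vals = [r.dsc_per_organ[organ] for r in reports if organ in r.dsc_per_organ]
        if vals:
            out[f"dsc_{organ}"] = {"mean": float(np.mean(vals)), "std": float(np.std(vals))}
    return out
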