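"""Full-reference quality metrics between original and segmented images.

The segmented image here is the class-mean reconstruction of the original
(each pixel replaced by its class's mean gray level), so RMSE/PSNR/SSIM/
FSIM quantify how much intensity structure a threshold set preserves.

* RMSE — root mean squared pixel difference.
* PSNR — ``20 log10(255 / RMSE)`` in dB (infinite for identical images).
* SSIM — the structural similarity index evaluated with whole-image
  statistics, ``(2 mu_a mu_b + C1)(2 cov_ab + C2) /
  ((mu_a^2 + mu_b^2 + C1)(var_a + var_b + C2))`` with the 8-bit
  stabilizers ``C1 = (0.01*255)^2 = 6.5025`` and
  ``C2 = (0.03*255)^2 = 58.5225``. A windowed mean-SSIM mode (delegating
  to scikit-image) is available for cross-checking.
* FSIM — phase-congruency/gradient feature similarity:
  ``S_PC = (2 PC1 PC2 + T1)/(PC1^2 + PC2^2 + T1)``,
  ``S_G = (2 G1 G2 + T2)/(G1^2 + G2^2 + T2)``, pooled as
  ``sum(S_PC S_G PCm) / sum(PCm)`` with ``PCm = max(PC1, PC2)``,
  ``T1 = 0.85`` and ``T2 = 160`` (8-bit defaults), Scharr gradients.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy.ndimage import convolve

from .image import ValidationError, as_gray_image
from .phasecong import phase_congruency

SSIM_C1 = 6.5025
SSIM_C2 = 58.5225
FSIM_T1 = 0.85
FSIM_T2 = 160.0

# Scharr kernel, 3/10/3 weighting normalized by 16
_SCHARR_X = np.array([[3.0, 0.0, -3.0], [10.0, 0.0, -10.0], [3.0, 0.0, -3.0]]) / 16.0


class UndefinedMetricError(ValueError):
    """Raised when a metric has no defined value (e.g. FSIM of flat images)."""


@dataclass(frozen=True)
class QualityReport:
    """RMSE, PSNR (dB; ``inf`` for identical images), SSIM and FSIM."""

    rmse: float
    psnr: float
    ssim: float
    fsim: float

    def to_json(self) -> str:
        d = asdict(self)
        if math.isinf(d["psnr"]):
            d["psnr"] = "inf"
        return json.dumps(d)

    def as_row(self) -> dict:
        return asdict(self)


def _pair(a, b):
    a = as_gray_image(a).astype(float)
    b = as_gray_image(b).astype(float)
    if a.shape != b.shape:
        raise ValidationError(f"image shapes differ: {a.shape} vs {b.shape}")
    return a, b


def rmse(a, b) -> float:
    """Root mean squared difference."""
    a, b = _pair(a, b)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def psnr(a, b) -> float:
    """Peak signal-to-noise ratio, ``20 log10(255 / RMSE)`` dB."""
    r = rmse(a, b)
    if r == 0.0:
        return float("inf")
    return 20.0 * math.log10(255.0 / r)


def ssim_global(a, b, windowed: bool = False) -> float:
    """SSIM with whole-image statistics (or windowed mean-SSIM)."""
    a, b = _pair(a, b)
    if windowed:
        from skimage.metrics import structural_similarity

        return float(structural_similarity(a, b, data_range=255.0))
    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = a.var(), b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    return float(
        (2 * mu_a * mu_b + SSIM_C1) * (2 * cov + SSIM_C2)
        / ((mu_a ** 2 + mu_b ** 2 + SSIM_C1) * (var_a + var_b + SSIM_C2))
    )


def _gradient_magnitude(img: np.ndarray) -> np.ndarray:
    gx = convolve(img, _SCHARR_X, mode="reflect")
    gy = convolve(img, _SCHARR_X.T, mode="reflect")
    return np.hypot(gx, gy)


def fsim(a, b, t1: float = FSIM_T1, t2: float = FSIM_T2) -> float:
    """Feature similarity index in [0, 1]."""
    a, b = _pair(a, b)
    pc1 = phase_congruency(a)
    pc2 = phase_congruency(b)
    pcm = np.maximum(pc1, pc2)
    total = float(pcm.sum())
    if total < 1e-12:
        raise UndefinedMetricError(
            "FSIM undefined: no phase-congruent structure in either image"
        )
    g1 = _gradient_magnitude(a)
    g2 = _gradient_magnitude(b)
    s_pc = (2 * pc1 * pc2 + t1) / (pc1 ** 2 + pc2 ** 2 + t1)
    s_g = (2 * g1 * g2 + t2) / (g1 ** 2 + g2 ** 2 + t2)
    return float((s_pc * s_g * pcm).sum() / total)


def quality_report(original, segmented) -> QualityReport:
    """All four metrics between an original and its reconstruction."""
    return QualityReport(
        rmse=rmse(original, segmented),
        psnr=psnr(original, segmented),
        ssim=ssim_global(original, segmented),
        fsim=fsim(original, segmented),
    )
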