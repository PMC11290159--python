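"""Grayscale image I/O, histograms, and threshold application.

Images are plain 2-D ``numpy`` integer arrays with values in ``[0, L-1]``
(``L = 256`` throughout). A :class:`Histogram` carries the per-level pixel
counts ``n_i`` and probabilities ``p_i = n_i / N``; it is the sole input to
both thresholding objectives.

Thresholds follow the inclusive-upper convention: a pixel with gray level
``g`` belongs to class ``j`` when ``th[j-1] < g <= th[j]`` (with sentinels
``th[-1] = -1`` and ``th[k] = L-1``), so a threshold value itself falls in
the lower class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np

DEFAULT_LEVELS = 256

# Rec.601 luminance weights for color-to-gray conversion.
_REC601 = np.array([0.299, 0.587, 0.114])


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class Histogram:
    """Normalized gray-level histogram.

    Attributes
    ----------
    p : ndarray, shape (levels,)
        Probability of each gray level, ``p[i] = counts[i] / n_total``.
    counts : ndarray, shape (levels,)
        Number of pixels at each gray level.
    n_total : int
        Total pixel count ``M * N``.
    """

    p: np.ndarray
    counts: np.ndarray = field(repr=False)
    n_total: int = 0

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 1:
            raise ValidationError("histogram probabilities must be 1-D")
        if np.any(p < 0):
            raise ValidationError("histogram probabilities must be non-negative")
        if abs(float(p.sum()) - 1.0) > 1e-12:
            raise ValidationError("histogram probabilities must sum to 1")
        object.__setattr__(self, "p", p)

    @property
    def levels(self) -> int:
        return self.p.shape[0]

    @classmethod
    def from_probabilities(cls, p, n_total: int = 0) -> "Histogram":
        """Build a histogram from a probability vector (counts synthesized)."""
        p = np.asarray(p, dtype=float)
        total = float(p.sum())
        if total <= 0:
            raise ValidationError("probability vector must have positive mass")
        p = p / total
        counts = np.rint(p * max(n_total, 1)).astype(np.int64)
        return cls(p=p, counts=counts, n_total=n_total)


def as_gray_image(pixels, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Validate and coerce *pixels* to a 2-D integer gray image."""
    arr = np.asarray(pixels)
    if arr.ndim != 2 or arr.size == 0:
        raise ValidationError(f"expected a non-empty 2-D image, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.rint(arr)):
            raise ValidationError("gray image pixels must be integers")
        arr = np.rint(arr).astype(np.int64)
    if arr.min() < 0 or arr.max() > levels - 1:
        raise ValidationError(f"pixel values must lie in [0, {levels - 1}]")
    return arr.astype(np.int64)


def load_gray_image(path) -> np.ndarray:
    """Read a PNG/TIFF/PGM file as an 8-bit gray image.

    Color inputs are converted with Rec.601 luminance weights and rounded
    half-up; an alpha channel, if present, is dropped.
    """
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder errors vary by plugin
        raise IOError(f"could not read image file {path!r}: {exc}") from exc
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            arr = np.floor(arr[:, :, :3].astype(float) @ _REC601 + 0.5)
    if arr.ndim != 2 or arr.size == 0:
        raise ValidationError(f"file {path!r} does not contain a 2-D image")
    arr = np.clip(np.asarray(arr, dtype=float), 0, 255)
    return as_gray_image(arr)


def save_gray_image(img, path) -> None:
    """Write a gray image as PNG or PGM (chosen by file extension)."""
    arr = as_gray_image(img).astype(np.uint8)
    iio.imwrite(path, arr)


def compute_histogram(img) -> Histogram:
    """Per-level counts and probabilities of a gray image."""
    arr = as_gray_image(img)
    counts = np.bincount(arr.ravel(), minlength=DEFAULT_LEVELS).astype(np.int64)
    n_total = int(arr.size)
    return Histogram(p=counts / n_total, counts=counts, n_total=n_total)


def validate_thresholds(th, levels: int = DEFAULT_LEVELS, k_min: int = 0) -> np.ndarray:
    """Check a threshold vector: integers, strictly increasing, in [0, L-2]."""
    th = np.asarray(th, dtype=np.int64).ravel()
    if th.size < k_min:
        raise ValidationError(f"need at least {k_min} thresholds, got {th.size}")
    if th.size:
        if np.any(np.diff(th) <= 0):
            raise ValidationError(f"thresholds must be strictly increasing: {th.tolist()}")
        if th[0] < 0 or th[-1] > levels - 2:
            raise ValidationError(
                f"thresholds must lie in [0, {levels - 2}]: {th.tolist()}"
            )
    return th


def class_labels(img, th, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Class index of every pixel under the inclusive-upper convention."""
    arr = as_gray_image(img, levels)
    th = validate_thresholds(th, levels)
    return np.digitize(arr, th, right=True)


def apply_thresholds(img, th, mode: str = "class-mean",
                     levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Segment *img* with threshold vector *th*.

    Parameters
    ----------
    mode : {"labels", "class-mean", "class-midpoint"}
        ``labels`` writes the class index; ``class-mean`` writes the rounded
        mean gray level of each class (the reconstruction used for the
        quality metrics); ``class-midpoint`` writes the rounded midpoint of
        each class interval.
    """
    arr = as_gray_image(img, levels)
    th = validate_thresholds(th, levels)
    labels = np.digitize(arr, th, right=True)
    if mode == "labels":
        return labels.astype(np.int64)
    k = th.size
    edges_lo = np.concatenate(([0], th + 1))
    edges_hi = np.concatenate((th, [levels - 1]))
    values = np.zeros(k + 1, dtype=np.int64)
    if mode == "class-mean":
        for j in range(k + 1):
            mask = labels == j
            if mask.any():
                values[j] = int(np.floor(arr[mask].mean() + 0.5))
            else:
                values[j] = int(np.floor((edges_lo[j] + edges_hi[j]) / 2 + 0.5))
    elif mode == "class-midpoint":
        values = np.floor((edges_lo + edges_hi) / 2 + 0.5).astype(np.int64)
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return values[labels]
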