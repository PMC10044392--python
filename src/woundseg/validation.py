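"""Accept/discard validation of predicted masks.

In the clinical workflow, reviewers judge each predicted segmentation
against three binary criteria before it may enter the training pool:

(i)   the mask must cover the entire wound area;
(ii)  the mask must cover only the wound — no holes, no spurious parts;
(iii) the mask shape must follow the correct wound boundaries.

These are qualitative judgments.  The *simulated oracle* here makes them
computable against a ground-truth mask, so the whole loop can run
unattended on synthetic data: criterion (i) becomes a recall floor,
criterion (ii) a precision floor plus explicit hole-area and
connected-component topology checks, and criterion (iii) a bound on the
symmetric mean contour distance.  Every numeric threshold is a package
decision, exposed in ``ValidationThresholds``.

The oracle consumes only masks, never image pixels, so it is a pure and
reproducible stand-in for the human decision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .metrics import compare_masks

__all__ = [
    "ValidationThresholds",
    "ValidationResult",
    "check_coverage",
    "check_only_wound",
    "check_boundary",
    "oracle_validate",
    "mean_boundary_distance",
]


@dataclass(frozen=True)
class ValidationThresholds:
    """Numeric operating points of the simulated reviewer.

    min_coverage_recall : float
        Criterion (i): recall of the prediction against truth must be at
        least this.
    min_precision : float
        Criterion (ii), over-segmentation arm: precision floor.
    max_hole_area_fraction : float
        Criterion (ii), topology arm: enclosed background area allowed,
        as a fraction of the predicted mask area.
    max_spurious_components : int
        Criterion (ii): foreground components allowed beyond the largest.
    max_mean_boundary_distance : float
        Criterion (iii): symmetric mean contour distance bound, as a
        fraction of the image diagonal.
    """

    min_coverage_recall: float = 0.90
    min_precision: float = 0.90
    max_hole_area_fraction: float = 0.01
    max_spurious_components: int = 0
    max_mean_boundary_distance: float = 0.02

    def __post_init__(self) -> None:
        for name in ("min_coverage_recall", "min_precision", "max_hole_area_fraction",
                     "max_mean_boundary_distance"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.max_spurious_components < 0:
            raise ValueError("max_spurious_components must be >= 0")


@dataclass(frozen=True)
class ValidationResult:
    """Outcome of the three criteria for one predicted mask."""

    covers_wound: bool
    only_wound: bool
    boundary_ok: bool

    @property
    def accepted(self) -> bool:
        return self.covers_wound and self.only_wound and self.boundary_ok


def _binary(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask).astype(bool)


def check_coverage(
    pred: np.ndarray, truth: np.ndarray, th: ValidationThresholds | None = None
) -> bool:
    """Criterion (i): does the prediction cover the whole wound?

    One-sided: a dilated (over-large) prediction still covers.
    """
    th = th or ValidationThresholds()
    p, t = _binary(pred), _binary(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if not t.any():
        raise ValueError("truth mask is empty: nothing to cover")
    return compare_masks(p, t).recall >= th.min_coverage_recall


def check_only_wound(
    pred: np.ndarray, truth: np.ndarray, th: ValidationThresholds | None = None
) -> bool:
    """Criterion (ii): no over-segmentation, no holes, no spurious parts."""
    th = th or ValidationThresholds()
    p, t = _binary(pred), _binary(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if not p.any():
        # an empty prediction covers nothing but asserts nothing false either;
        # precision 0/0 -> 0 under the metrics convention, so it fails
        return False
    if compare_masks(p, t).precision < th.min_precision:
        return False
    # holes: background components not touching the raster border
    labels, n = ndimage.label(~p)
    if n > 0:
        border = np.zeros_like(p, dtype=bool)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        border_labels = set(np.unique(labels[border & ~p]))
        hole_area = sum(
            int((labels == lab).sum()) for lab in range(1, n + 1) if lab not in border_labels
        )
        if hole_area > th.max_hole_area_fraction * int(p.sum()):
            return False
    _, n_fg = ndimage.label(p)
    return (n_fg - 1) <= th.max_spurious_components


def _contour(mask: np.ndarray) -> np.ndarray:
    """Boundary pixels: foreground pixels with a 4-neighbour background."""
    eroded = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(2, 1),
                                    border_value=0)
    return mask & ~eroded


def mean_boundary_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric mean contour distance between two non-empty masks, px."""
    ca, cb = _contour(_binary(a)), _contour(_binary(b))
    if not ca.any() or not cb.any():
        raise ValueError("boundary distance requires two non-empty masks")
    d_to_b = ndimage.distance_transform_edt(~cb)
    d_to_a = ndimage.distance_transform_edt(~ca)
    return 0.5 * (float(d_to_b[ca].mean()) + float(d_to_a[cb].mean()))


def check_boundary(
    pred: np.ndarray, truth: np.ndarray, th: ValidationThresholds | None = None
) -> bool:
    """Criterion (iii): does the contour follow the true wound boundary?"""
    th = th or ValidationThresholds()
    p, t = _binary(pred), _binary(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if not t.any():
        raise ValueError("truth mask is empty")
    if not p.any():
        return False
    diag = float(np.hypot(*p.shape))
    return mean_boundary_distance(p, t) <= th.max_mean_boundary_distance * diag


def oracle_validate(
    pred: np.ndarray, truth: np.ndarray, th: ValidationThresholds | None = None
) -> ValidationResult:
    """Evaluate all three criteria; acceptance is their conjunction."""
    th = th or ValidationThresholds()
    return ValidationResult(
        covers_wound=check_coverage(pred, truth, th),
        only_wound=check_only_wound(pred, truth, th),
        boundary_ok=check_boundary(pred, truth, th),
    )
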