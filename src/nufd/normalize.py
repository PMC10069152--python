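"""Normalization strategies for longitudinal map reproducibility.

Two strategies:

* **Diaphragm-amplitude scaling factor** — exploits the linear relation
  between the mean lung ventilation signal S and the relative diaphragm
  position x. For scan i against a reference scan::

      factor_i = |dS_i/dx_i| * (x_ref_max - x_ref_min) / (S_i_max - S_i_min)

  where dS_i/dx_i is the slope of the linear S-vs-x fit, S_i_max/min are the
  mean per-cycle extrema of the scan's filtered ventilation signal, and
  x_ref_max/min the mean per-cycle extrema of the *reference* diaphragm
  trace. Multiplying the ventilation signal by this factor before the
  per-pixel transform rescales the map to the reference breathing amplitude.
  The slope magnitude is used so the factor is positive regardless of the
  sign of the signal/position coupling (parenchymal signal falls with
  inspiration, so the raw slope is typically negative).

* **ROI normalization** — divides a map by its mean within a chosen ROI
  placed on presumably healthy parenchyma; removes any global multiplicative
  difference between scans exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .core import FunctionalMap, TemporalSignal
from .diaphragm import DiaphragmTrace, _cycle_extrema
from .io_formats import RoiSpec

__all__ = [
    "NormalizationFactor",
    "fit_signal_position_slope",
    "scaling_factor",
    "apply_factor",
    "roi_normalize",
    "standard_roi_grid",
]

FACTOR_CLAMP = (0.2, 5.0)


@dataclass
class NormalizationFactor:
    """Diaphragm-amplitude scaling factor and its provenance components."""

    factor: float
    slope: float  # dS/dx, signal units per mm (signed, as fitted)
    s_max: float  # mean cycle maxima of the filtered ventilation signal
    s_min: float
    x_ref_max: float  # mm, from the reference diaphragm trace
    x_ref_min: float
    fit_r: float
    clamped: bool = False

    def components_identity(self) -> float:
        """Recompute the factor from its stored components."""
        return abs(self.slope) * (self.x_ref_max - self.x_ref_min) / (self.s_max - self.s_min)


def fit_signal_position_slope(
    signal: TemporalSignal | np.ndarray,
    trace: DiaphragmTrace | np.ndarray,
) -> tuple[float, float, float]:
    """Ordinary least squares of the ventilation signal S on the diaphragm
    position x. Returns ``(slope, intercept, r)``; warns when |r| < 0.7."""
    s = signal.values if isinstance(signal, TemporalSignal) else np.asarray(signal, dtype=float)
    x = trace.x if isinstance(trace, DiaphragmTrace) else np.asarray(trace, dtype=float)
    if s.size != x.size:
        raise ValueError("signal and trace lengths differ")
    if s.size < 10:
        raise ValueError("need at least 10 points for the slope fit")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in diaphragm position: slope undefined")
    res = stats.linregress(x, s)
    if abs(res.rvalue) < 0.7:
        warnings.warn(
            f"signal/position correlation |r|={abs(res.rvalue):.2f} < 0.7: slope fit unreliable",
            stacklevel=2,
        )
    return float(res.slope), float(res.intercept), float(res.rvalue)


def scaling_factor(
    scan_signal: TemporalSignal,
    scan_trace: DiaphragmTrace,
    reference_trace: DiaphragmTrace,
    clamp: tuple[float, float] = FACTOR_CLAMP,
) -> NormalizationFactor:
    """Diaphragm-amplitude normalization factor for one scan.

    ``scan_signal`` is the scan's filtered (low-pass) mean lung ventilation
    signal; its per-cycle extrema are found with the same prominence-based
    peak detection as the diaphragm trace. Factors outside ``clamp`` are
    clamped with a warning (a far-out factor usually signals drift or a bad
    fit, not physiology).
    """
    slope, _, r = fit_signal_position_slope(scan_signal, scan_trace)
    maxima, minima = _cycle_extrema(scan_signal.values, scan_signal.frame_interval)
    s_max = float(maxima.mean())
    s_min = float(minima.mean())
    if s_max <= s_min or s_max == s_min:
        raise ValueError("degenerate ventilation signal: equal mean maxima and minima")
    x_range = reference_trace.x_max - reference_trace.x_min
    if x_range <= 0:
        raise ValueError("reference trace has nonpositive excursion")
    factor = abs(slope) * x_range / (s_max - s_min)
    clamped = False
    if not clamp[0] <= factor <= clamp[1]:
        warnings.warn(
            f"scaling factor {factor:.3g} outside {clamp}: clamping "
            "(check for signal drift or an unreliable slope fit)",
            stacklevel=2,
        )
        factor = float(np.clip(factor, *clamp))
        clamped = True
    return NormalizationFactor(
        factor=factor,
        slope=slope,
        s_max=s_max,
        s_min=s_min,
        x_ref_max=reference_trace.x_max,
        x_ref_min=reference_trace.x_min,
        fit_r=r,
        clamped=clamped,
    )


def apply_factor(ventilation_signals: np.ndarray, factor: float | NormalizationFactor) -> np.ndarray:
    """Scale filtered per-pixel ventilation signals by the factor (applied
    before the per-pixel transform; by linearity the map scales equally)."""
    f = factor.factor if isinstance(factor, NormalizationFactor) else float(factor)
    if not f > 0:
        raise ValueError("normalization factor must be positive")
    return np.asarray(ventilation_signals, dtype=float) * f


def roi_normalize(fmap: FunctionalMap, roi: RoiSpec) -> FunctionalMap:
    """Divide the map by its mean within ``roi`` (ROI mean of the result is 1).

    The ROI must lie fully inside the map's mask and have positive mean.
    Idempotent: normalizing an already-normalized map changes nothing (to
    floating-point precision).
    """
    roi.check_inside_mask(fmap.mask)
    roi_mean = float(fmap.values[roi.rows, roi.cols].mean())
    if roi_mean <= 0:
        raise ValueError(f"ROI mean {roi_mean:g} must be positive for normalization")
    return FunctionalMap(
        values=fmap.values / roi_mean,
        mask=fmap.mask,
        kind=fmap.kind,
        normalized_by=("roi", roi.label, roi.height),
        scan_id=fmap.scan_id,
        meta={**fmap.meta, "roi_origin": roi.origin, "roi_mean": roi_mean},
    )


def standard_roi_grid(mask: np.ndarray, size: int = 12) -> list[RoiSpec]:
    """Six square ROIs, three per lung, for the ROI-normalization analysis.

    Per connected lung component the squares are centred at 20%, 50% and 80%
    of the component's vertical extent, horizontally at its centroid, and
    shifted minimally to lie fully inside the mask. Labels run 1-3 down the
    right lung (smaller column centroid) and 4-6 down the left lung.
    """
    mask = np.asarray(mask) > 0.5
    labels, n = ndimage.label(mask)
    if n < 2:
        raise ValueError(f"need two lung components in the mask, found {n}")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    two = np.argsort(sizes)[::-1][:2] + 1
    cents = ndimage.center_of_mass(mask, labels, two)
    order = np.argsort([c[1] for c in cents])  # right lung (smaller col) first
    rois: list[RoiSpec] = []
    label = 1
    for which in order:
        comp = labels == two[which]
        rows = np.nonzero(comp.any(axis=1))[0]
        r_lo, r_hi = rows[0], rows[-1]
        c_centroid = int(round(ndimage.center_of_mass(comp)[1]))
        for frac in (0.2, 0.5, 0.8):
            rc = int(round(r_lo + frac * (r_hi - r_lo)))
            origin = _fit_square_inside(comp, rc, c_centroid, size)
            if origin is None:
                raise ValueError(
                    f"cannot place a fully-interior {size}x{size} ROI at "
                    f"{frac:.0%} of lung component {label // 4 + 1}"
                )
            rois.append(RoiSpec(origin=origin, size=size, label=label))
            label += 1
    return rois


def _fit_square_inside(mask: np.ndarray, rc: int, cc: int, size: int) -> tuple[int, int] | None:
    """Top-left origin of a size^2 square inside ``mask``, as close as
    possible to centre (rc, cc); None when no placement fits.

    The search first keeps vertical shifts within 3 px — the three squares
    per lung sit ~30% of the lung extent apart, so this bound keeps them
    non-overlapping — and only widens vertically if no placement exists.
    """
    H, W = mask.shape
    r0 = int(np.clip(rc - size // 2, 0, H - size))
    c0 = int(np.clip(cc - size // 2, 0, W - size))
    max_shift = size + 6
    for dr_cap in (3, max_shift):
        best: tuple[int, tuple[int, int]] | None = None
        for dr in range(-dr_cap, dr_cap + 1):
            for dc in range(-max_shift, max_shift + 1):
                r, c = r0 + dr, c0 + dc
                if r < 0 or c < 0 or r + size > H or c + size > W:
                    continue
                if mask[r : r + size, c : c + size].all():
                    d = 3 * abs(dr) + abs(dc)
                    if best is None or d < best[0]:
                        best = (d, (r, c))
        if best is not None:
            return best[1]
    return None
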