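"""Per-frame diaphragm position from a sigmoid fit of a vertical line profile.

The lung parenchyma is much darker than the abdomen below the diaphragm, so
a vertical intensity profile through the diaphragm is a step-like transition.
Each frame's profile is fitted with a 4-parameter logistic; the row of the
maximum absolute derivative of the fit — for a logistic, its centre — is the
diaphragm position. Positions are sub-pixel, which matters at coarse pixel
spacing where the whole tidal excursion can be only a few pixels.

Sign convention: larger row index = more caudal = inspiration; relative
positions x are therefore positive in inspiration and negative in expiration,
consistent with increasing lung volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.optimize import curve_fit

from .io_formats import ImageSeries, RoiSpec

__all__ = [
    "DiaphragmTrace",
    "SigmoidFitError",
    "extract_line_profile",
    "fit_sigmoid",
    "diaphragm_position",
    "track_series",
    "relative_trace",
    "auto_roi",
]


class SigmoidFitError(RuntimeError):
    pass


@dataclass
class DiaphragmTrace:
    """Relative diaphragm positions per frame.

    ``x`` is in mm relative to the mid-position (mean of cycle maxima and
    minima), positive = inspiration. ``raw`` is the absolute position in mm
    from the image top (row 0).
    """

    x: np.ndarray
    raw: np.ndarray
    fit_rms: np.ndarray
    x_max: float  # mean of per-cycle maxima (mm, > 0)
    x_min: float  # mean of per-cycle minima (mm, < 0)
    frame_interval: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if not (np.isfinite(self.x_max) and np.isfinite(self.x_min)):
            raise ValueError("trace extrema must be finite")

    @property
    def amplitude(self) -> float:
        """Peak-to-peak excursion estimate x_max - x_min (mm)."""
        return self.x_max - self.x_min


def extract_line_profile(frame: np.ndarray, roi: RoiSpec, column: int | None = None) -> np.ndarray:
    """1-D intensity vs row along a vertical line through the ROI.

    ``column`` is an absolute column index; defaults to the ROI centre
    column. Only the ROI's rows are returned.
    """
    frame = np.asarray(frame)
    roi.check_inside(frame.shape)
    if column is None:
        column = roi.origin[1] + roi.width // 2
    if not (roi.origin[1] <= column < roi.origin[1] + roi.width):
        raise ValueError(f"column {column} outside ROI columns {roi.origin[1]}..{roi.origin[1] + roi.width - 1}")
    return frame[roi.rows, column].astype(float)


def _logistic(r, baseline, amplitude, center, steepness):
    return baseline + amplitude / (1.0 + np.exp(-(r - center) / steepness))


def fit_sigmoid(profile: np.ndarray, max_restarts: int = 4) -> tuple[float, float, float, float, float]:
    """Least-squares 4-parameter logistic fit of an intensity profile.

    Returns ``(baseline, amplitude, center, steepness, rms_residual)`` with
    ``center`` in sample (row) units relative to the profile start. Raises
    :class:`SigmoidFitError` for flat profiles (no transition above 3x the
    local noise level) or non-convergence after bounded restarts.
    """
    y = np.asarray(profile, dtype=float)
    n = y.size
    if n < 8:
        raise SigmoidFitError(f"profile too short for a sigmoid fit ({n} < 8 samples)")
    noise = np.std(np.diff(y)) / np.sqrt(2.0) if n > 2 else 0.0
    span = y.max() - y.min()
    if span <= max(3.0 * noise, 1e-12):
        raise SigmoidFitError("flat profile: no intensity transition to fit")
    r = np.arange(n, dtype=float)
    grad = np.gradient(y)
    c0 = float(np.argmax(np.abs(grad)))
    amp0 = y[-1] - y[0]
    inits = [
        (y[0], amp0, c0, 1.5),
        (y.min(), span * np.sign(amp0 if amp0 else 1.0), n / 2.0, 2.0),
        (y[0], amp0, n / 3.0, 1.0),
        (y[0], amp0, 2 * n / 3.0, 3.0),
    ]
    last_err: Exception | None = None
    for p0 in inits[: max_restarts + 1]:
        try:
            popt, _ = curve_fit(
                _logistic,
                r,
                y,
                p0=p0,
                bounds=([-np.inf, -np.inf, -n, 0.05], [np.inf, np.inf, 2.0 * n, n]),
                maxfev=5000,
            )
        except (RuntimeError, ValueError) as err:  # pragma: no cover - rare
            last_err = err
            continue
        resid = y - _logistic(r, *popt)
        rms = float(np.sqrt(np.mean(resid**2)))
        if rms < 0.5 * span:  # reject degenerate flat fits
            baseline, amplitude, center, steepness = (float(v) for v in popt)
            return baseline, amplitude, center, steepness, rms
        last_err = RuntimeError(f"fit residual {rms:.3g} too large")
    raise SigmoidFitError(f"sigmoid fit did not converge: {last_err}")


def diaphragm_position(
    frame: np.ndarray,
    roi: RoiSpec,
    column: int | None = None,
    pixel_spacing: float = 1.0,
) -> tuple[float, float]:
    """Diaphragm position (mm from image top) in one frame.

    The position is the row maximizing |d/dr| of the fitted sigmoid — its
    centre for a logistic. Returns ``(position_mm, fit_rms)``.
    """
    profile = extract_line_profile(frame, roi, column)
    _, _, center, _, rms = fit_sigmoid(profile)
    return (roi.origin[0] + center) * pixel_spacing, rms


def track_series(
    series: ImageSeries,
    roi: RoiSpec,
    column: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw diaphragm positions (mm) and fit residuals for every frame."""
    raw = np.empty(series.n_frames)
    rms = np.empty(series.n_frames)
    for i, frame in enumerate(series.frames):
        try:
            raw[i], rms[i] = diaphragm_position(frame, roi, column, series.pixel_spacing[0])
        except SigmoidFitError as err:
            raise SigmoidFitError(f"frame {i}: {err}") from err
    return raw, rms


def _cycle_extrema(values: np.ndarray, frame_interval: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle maxima/minima via prominence-based peak detection.

    Prominence threshold: 25% of the trace range; minimum peak separation:
    half the dominant (respiratory) period.
    """
    v = np.asarray(values, dtype=float)
    rng = v.max() - v.min()
    if rng <= 0:
        raise ValueError("constant trace: no breathing cycles")
    spec = np.abs(np.fft.rfft(v - v.mean()))
    freqs = np.fft.rfftfreq(v.size, frame_interval)
    f0 = freqs[1:][np.argmax(spec[1:])]  # dominant nonzero frequency
    min_dist = max(1, int(round(0.5 / max(f0, 1e-6) / frame_interval)))
    prom = 0.25 * rng
    peaks, _ = sps.find_peaks(v, prominence=prom, distance=min_dist)
    troughs, _ = sps.find_peaks(-v, prominence=prom, distance=min_dist)
    if peaks.size < 2 or troughs.size < 2:
        raise ValueError(
            f"fewer than 2 breathing cycles detected ({peaks.size} maxima, {troughs.size} minima)"
        )
    return v[peaks], v[troughs]


def relative_trace(
    raw_positions: np.ndarray,
    frame_interval: float,
    fit_rms: np.ndarray | None = None,
) -> DiaphragmTrace:
    """Relative diaphragm trace from raw (mm-from-top) positions.

    The mid-position is ``(mean cycle maxima + mean cycle minima) / 2``; the
    relative position ``x = raw - mid`` is positive in inspiration (caudal
    displacement). Requires at least two detected maxima and minima.
    """
    raw = np.asarray(raw_positions, dtype=float)
    maxima, minima = _cycle_extrema(raw, frame_interval)
    mean_max = float(maxima.mean())
    mean_min = float(minima.mean())
    mid = 0.5 * (mean_max + mean_min)
    x = raw - mid
    if fit_rms is None:
        fit_rms = np.zeros_like(raw)
    return DiaphragmTrace(
        x=x,
        raw=raw,
        fit_rms=np.asarray(fit_rms, dtype=float),
        x_max=mean_max - mid,
        x_min=mean_min - mid,
        frame_interval=frame_interval,
    )


def trace_from_series(series: ImageSeries, roi: RoiSpec, column: int | None = None) -> DiaphragmTrace:
    """Convenience: track every frame and build the relative trace."""
    raw, rms = track_series(series, roi, column)
    return relative_trace(raw, series.frame_interval, fit_rms=rms)


def auto_roi(
    reference_frame: np.ndarray,
    lung_mask: np.ndarray,
    height: int = 16,
    width: int = 8,
) -> RoiSpec:
    """Auto-place a diaphragm ROI spanning the right-lung diaphragm edge.

    The right lung is the connected mask component with the smaller column
    centroid (radiological convention: patient right on image left). The ROI
    is centred horizontally on that component's centroid column and
    vertically on the row of maximum vertical intensity gradient below the
    component (the lung/abdomen edge) in the reference frame.
    """
    from scipy import ndimage

    lung_mask = np.asarray(lung_mask) > 0.5
    labels, n = ndimage.label(lung_mask)
    if n == 0:
        raise ValueError("empty lung mask")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    keep = np.argsort(sizes)[::-1][: min(2, n)] + 1
    centroids = ndimage.center_of_mass(lung_mask, labels, keep)
    right_label = keep[int(np.argmin([c[1] for c in centroids]))]
    comp = labels == right_label
    col = int(round(ndimage.center_of_mass(comp)[1]))
    comp_rows = np.nonzero(comp[:, col])[0]
    if comp_rows.size == 0:
        comp_rows = np.nonzero(comp.any(axis=1))[0]
    bottom = comp_rows[-1]
    # search the strongest upward intensity step below the parenchyma
    profile = np.asarray(reference_frame, dtype=float)[:, col]
    search = slice(bottom, min(bottom + 3 * height, profile.size - 1))
    grad = np.gradient(profile)[search]
    edge_row = bottom + int(np.argmax(grad))
    r0 = int(np.clip(edge_row - height // 2, 0, reference_frame.shape[0] - height))
    c0 = int(np.clip(col - width // 2, 0, reference_frame.shape[1] - width))
    return RoiSpec(origin=(r0, c0), size=(height, width), label="diaphragm")
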