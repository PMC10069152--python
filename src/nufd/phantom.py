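"""Dynamic 2D+t lung phantom with ground truth.

The phantom emulates the signal content a free-breathing coronal bSSFP lung
series carries for Fourier-decomposition processing:

* a parenchymal signal oscillating at the respiratory frequency, with the
  oscillation amplitude proportional to the diaphragm displacement — so the
  mean lung signal is, by construction, an affine function of diaphragm
  position (the premise of the diaphragm-amplitude scaling factor),
* bright intra-pulmonary vessels carrying a cardiac-frequency oscillation
  (plus a tiny capillary cardiac component on the parenchyma),
* a diaphragm edge modelled as a logistic intensity transition whose centre
  moves with breathing — sub-pixel diaphragm motion, exactly matching the
  sigmoid model the tracker fits,
* optional linear frequency chirps, additive Gaussian noise and slow drift.

It does not simulate MR physics (bSSFP banding, coils, through-plane motion);
the parenchyma is static in-plane apart from the moving boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .io_formats import ImageSeries

__all__ = ["PhantomConfig", "PhantomTruth", "generate_phantom"]

# Tissue intensities in arbitrary signal units (order of a low-field bSSFP
# magnitude image): air ~0, lung parenchyma dark, soft tissue/abdomen bright.
BODY_INTENSITY = 180.0
LUNG_BASELINE = 60.0
ABDOMEN_INTENSITY = 220.0
HEART_INTENSITY = 200.0
VESSEL_BASELINE = 100.0


@dataclass
class PhantomConfig:
    """Study conditions for one synthetic scan.

    Defaults mirror the acquisition protocol the package targets: 240 frames
    of a 128x128 matrix at 310 ms/frame with 3.91 mm pixels. ``breathing_depth``
    scales the diaphragm excursion (1.0 = reference scan; 1.25 = "25% deeper"
    instructed breathing; 0.8 = shallow).
    """

    grid_size: tuple[int, int] = (128, 128)
    n_frames: int = 240
    frame_interval: float = 0.310
    pixel_spacing: float = 3.91
    respiratory_freq: float | tuple[float, float] = 0.25
    cardiac_freq: float | tuple[float, float] = 1.1
    breathing_depth: float = 1.0
    diaphragm_excursion_ref: float = 15.0
    ventilation_amplitude_field: np.ndarray | float | None = None
    perfusion_amplitude_field: np.ndarray | float | None = None
    parenchymal_perfusion_amplitude: float = 0.1
    noise_sigma: float = 2.0
    drift_slope: float = 0.0
    waveform: str = "sinusoid"  # or "raised_cosine"
    seed: int = 0
    # anatomy (vessel layout) seed; None => use `seed`. Repeated scans of the
    # same "subject" share anatomy_seed while varying `seed` for the noise.
    anatomy_seed: int | None = None

    def validate(self) -> None:
        if self.n_frames <= 20:
            raise ValueError(
                "n_frames must exceed 20 (the steady-state discard would remove the whole series)"
            )
        resp = np.atleast_1d(np.asarray(self.respiratory_freq, dtype=float))
        card = np.atleast_1d(np.asarray(self.cardiac_freq, dtype=float))
        if (resp <= 0).any() or (card <= 0).any():
            raise ValueError("frequencies must be positive")
        if resp.max() >= card.min():
            raise ValueError(
                f"respiratory band (max {resp.max():g} Hz) must lie strictly below "
                f"the cardiac band (min {card.min():g} Hz)"
            )
        if not self.breathing_depth > 0:
            raise ValueError("breathing_depth must be positive")
        if self.waveform not in ("sinusoid", "raised_cosine"):
            raise ValueError(f"unknown waveform {self.waveform!r}")
        for name in ("ventilation_amplitude_field", "perfusion_amplitude_field"):
            f = getattr(self, name)
            if f is not None and np.any(np.asarray(f, dtype=float) < 0):
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated series."""

    lung_mask: np.ndarray  # parenchyma only (heart and vessels excluded)
    vessel_mask: np.ndarray
    diaphragm_position_per_frame: np.ndarray  # mm, + = inspiration
    ventilation_amplitude_field: np.ndarray  # fractional, on lung_mask
    perfusion_amplitude_field: np.ndarray  # signal units, vessels + parenchyma
    respiratory_freq_per_frame: np.ndarray
    cardiac_freq_per_frame: np.ndarray
    lung_baseline: float = LUNG_BASELINE
    diaphragm_rest_row: float = 0.0  # px
    signal_position_slope: float = 0.0  # d(mean lung signal)/dx, units/mm
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def perfusion_mask(self) -> np.ndarray:
        """Mask for perfusion maps: parenchyma plus vessels."""
        return self.lung_mask | self.vessel_mask


def _instantaneous_freq(freq: float | tuple[float, float], t: np.ndarray) -> np.ndarray:
    f = np.atleast_1d(np.asarray(freq, dtype=float))
    if f.size == 1:
        return np.full_like(t, f[0])
    f0, f1 = float(f[0]), float(f[1])
    T = t[-1] if t[-1] > 0 else 1.0
    return f0 + (f1 - f0) * t / T


def _phase(freq: float | tuple[float, float], t: np.ndarray) -> np.ndarray:
    """Exact instantaneous phase 2*pi*integral(f dt) for constant or linearly
    chirped frequency."""
    f = np.atleast_1d(np.asarray(freq, dtype=float))
    if f.size == 1:
        return 2 * np.pi * f[0] * t
    f0, f1 = float(f[0]), float(f[1])
    T = t[-1] if t[-1] > 0 else 1.0
    return 2 * np.pi * (f0 * t + (f1 - f0) * t**2 / (2 * T))


def _breathing_waveform(phase: np.ndarray, kind: str) -> np.ndarray:
    """Unit-amplitude breathing waveform in [-1, 1]."""
    if kind == "sinusoid":
        return np.sin(phase)
    # raised-cosine (cos^4) profile: brief inspiratory excursions with a
    # longer end-expiratory plateau, as real tidal breathing shows; in [-1, 1]
    return 2.0 * np.cos(phase / 2.0) ** 4 - 1.0


def _ellipse(H: int, W: int, cr: float, cc: float, ar: float, ac: float) -> np.ndarray:
    r, c = np.ogrid[:H, :W]
    return ((r - cr) / ar) ** 2 + ((c - cc) / ac) ** 2 <= 1.0


def _draw_vessels(lung: np.ndarray, hilum: tuple[float, float], rng: np.random.Generator):
    """4-6 straight bright vessel segments per lung radiating from the hilum,
    1-2 px wide. Returns (vessel_mask, amplitude_scale_image)."""
    from skimage.draw import line

    H, W = lung.shape
    mask = np.zeros_like(lung)
    amp = np.zeros(lung.shape)
    n = int(rng.integers(4, 7))
    r0, c0 = int(hilum[0]), int(hilum[1])
    for k in range(n):
        ang = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(0.3, 0.65) * min(H, W) * 0.3
        r1 = int(np.clip(r0 + length * np.sin(ang), 0, H - 1))
        c1 = int(np.clip(c0 + length * np.cos(ang), 0, W - 1))
        rr, cc = line(r0, c0, r1, c1)
        keep = lung[rr, cc]
        rr, cc = rr[keep], cc[keep]
        scale = 0.7 + 0.3 * rng.random()
        mask[rr, cc] = True
        amp[rr, cc] = scale
        if rng.random() < 0.25 and cc.size:  # widen to 2 px
            cc2 = np.clip(cc + 1, 0, W - 1)
            keep2 = lung[rr, cc2]
            mask[rr[keep2], cc2[keep2]] = True
            amp[rr[keep2], cc2[keep2]] = scale
    return mask, amp


def generate_phantom(config: PhantomConfig) -> tuple[ImageSeries, PhantomTruth]:
    """Generate a synthetic free-breathing series and its ground truth.

    The pixel model on lung parenchyma is

    ``I(p, t) = B * (1 - a_v(p) * x(t) / x_ref) + a_q(p) * s_card(t) + drift*t + noise``

    with ``x(t)`` the diaphragm displacement (mm, + = inspiration),
    ``x_ref`` the reference-depth displacement amplitude, ``a_v`` the
    fractional ventilation amplitude and ``s_card`` a unit cardiac
    oscillation. Same seed, same config => bit-identical output.
    """
    config.validate()
    H, W = config.grid_size
    T = config.n_frames
    rng = np.random.default_rng(config.seed)
    anat_seed = config.seed if config.anatomy_seed is None else config.anatomy_seed
    rng_anat = np.random.default_rng(anat_seed)
    t = np.arange(T) * config.frame_interval
    ps = config.pixel_spacing

    # breathing / cardiac temporal signals
    resp_phase = _phase(config.respiratory_freq, t)
    s_resp = _breathing_waveform(resp_phase, config.waveform)
    s_card = np.sin(_phase(config.cardiac_freq, t))
    x_ref = config.diaphragm_excursion_ref / 2.0  # mm amplitude at depth 1
    x = config.breathing_depth * x_ref * s_resp  # mm, + = inspiration

    # ---- static anatomy -------------------------------------------------
    body = _ellipse(H, W, 0.52 * H, 0.50 * W, 0.46 * H, 0.44 * W)
    right_lung = _ellipse(H, W, 0.42 * H, 0.31 * W, 0.30 * H, 0.155 * W)
    left_lung = _ellipse(H, W, 0.42 * H, 0.69 * W, 0.30 * H, 0.155 * W)
    heart = _ellipse(H, W, 0.58 * H, 0.56 * W, 0.15 * H, 0.12 * W)
    lung_field = (right_lung | left_lung) & ~heart

    diaphragm_rest_row = 0.66 * H
    # most cranial boundary row the parenchyma must clear; fixed allowance of
    # 2x the reference amplitude so the mask is identical across repeated
    # scans with breathing_depth <= 2 (deviation metrics need a shared mask)
    rd_min = diaphragm_rest_row - max(2.0, config.breathing_depth) * x_ref / ps

    rows = np.arange(H, dtype=float)
    cols_in_lung = lung_field.any(axis=0)

    vessels_r, amp_r = _draw_vessels(right_lung & ~heart, (0.48 * H, 0.40 * W), rng_anat)
    vessels_l, amp_l = _draw_vessels(left_lung & ~heart, (0.48 * H, 0.60 * W), rng_anat)
    vessel_mask = vessels_r | vessels_l
    vessel_amp_scale = amp_r + amp_l

    # ground-truth masks: parenchyma above the diaphragm's sigmoid zone
    margin_px = 4.0  # logistic tail clearance below the most cranial boundary
    above_diaphragm = rows[:, None] < (rd_min - margin_px)
    lung_mask = lung_field & above_diaphragm & ~vessel_mask
    vessel_mask = vessel_mask & above_diaphragm & lung_field
    if not lung_mask.any():
        raise ValueError("degenerate geometry: empty lung mask")

    # ---- amplitude fields ----------------------------------------------
    a_v = config.ventilation_amplitude_field
    if a_v is None:
        # smooth apico-basal gradient (base ventilates more than apex)
        rr_lung = np.nonzero(lung_field.any(axis=1))[0]
        r_lo, r_hi = rr_lung[0], rr_lung[-1]
        grad = (rows - r_lo) / max(r_hi - r_lo, 1)
        a_v = (0.06 + 0.08 * np.clip(grad, 0, 1))[:, None] * np.ones((1, W))
    elif np.isscalar(a_v):
        a_v = np.full((H, W), float(a_v))
    else:
        a_v = np.asarray(a_v, dtype=float)
    a_v = np.where(lung_mask, a_v, 0.0)

    a_q = config.perfusion_amplitude_field
    if a_q is None:
        a_q = 20.0 * vessel_amp_scale
    elif np.isscalar(a_q):
        a_q = float(a_q) * vessel_mask
    else:
        a_q = np.asarray(a_q, dtype=float)
    a_q = np.where(vessel_mask, a_q, 0.0) + np.where(
        lung_mask, config.parenchymal_perfusion_amplitude, 0.0
    )

    # ---- static base image ----------------------------------------------
    base = np.zeros((H, W))
    base[body] = BODY_INTENSITY
    base[lung_field] = LUNG_BASELINE
    base[heart & body] = HEART_INTENSITY
    base[vessel_mask] = VESSEL_BASELINE

    # ---- frames ----------------------------------------------------------
    frames = np.empty((T, H, W))
    # logistic diaphragm transition (steepness ~1 px => transition over ~2 px)
    steep = 1.0
    resp_mod = x / x_ref  # dimensionless, depth-scaled
    lungs = lung_mask | vessel_mask
    # diaphragm blend zone: body tissue in lung-field columns below the
    # protected parenchyma, heart excluded; stays at abdomen intensity all the
    # way down so a vertical line profile is a clean single sigmoid
    blend_rows = rows >= rd_min - margin_px
    blend_region = body & ~heart & blend_rows[:, None] & cols_in_lung[None, :]
    for n in range(T):
        f = base.copy()
        f[lungs] = base[lungs] * (1.0 - a_v[lungs] * resp_mod[n]) + a_q[lungs] * s_card[n]
        rd = diaphragm_rest_row + x[n] / ps
        w = 1.0 / (1.0 + np.exp(-(rows - rd) / steep))
        blend = np.broadcast_to(
            LUNG_BASELINE * (1.0 - w[:, None]) + ABDOMEN_INTENSITY * w[:, None], (H, W)
        )
        f[blend_region] = blend[blend_region]
        frames[n] = f
    if config.drift_slope:
        frames += config.drift_slope * t[:, None, None]
    if config.noise_sigma:
        frames += rng.normal(0.0, config.noise_sigma, frames.shape)
    np.clip(frames, 0.0, None, out=frames)

    series = ImageSeries(
        frames,
        config.frame_interval,
        (ps, ps),
        slice_label="phantom",
        meta={"phantom_seed": config.seed, "breathing_depth": config.breathing_depth},
    )
    slope = -float((base[lung_mask] * a_v[lung_mask]).mean()) / x_ref
    truth = PhantomTruth(
        lung_mask=lung_mask,
        vessel_mask=vessel_mask,
        diaphragm_position_per_frame=x,
        ventilation_amplitude_field=a_v,
        perfusion_amplitude_field=a_q,
        respiratory_freq_per_frame=_instantaneous_freq(config.respiratory_freq, t),
        cardiac_freq_per_frame=_instantaneous_freq(config.cardiac_freq, t),
        lung_baseline=LUNG_BASELINE,
        diaphragm_rest_row=diaphragm_rest_row,
        signal_position_slope=slope,
        meta={"x_ref_mm": x_ref, "cardiac_signal": s_card},
    )
    return series, truth
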