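"""End-to-end orchestration: phantom -> preprocess -> maps -> normalization
-> deviation report, driven by one YAML config.

Config schema (YAML mapping)::

    seed: 12345                  # master seed; per-scan seeds derive from it
    output_dir: artifacts        # default; CLI --out overrides
    phantom: {...}               # PhantomConfig field overrides (shared)
    scans:                       # scan protocol; exactly one reference
      - id: reference
        breathing: NB
        breathing_depth: 1.0
        reference: true
      - {id: NB2, breathing: NB, breathing_depth: 1.0}
      - {id: IB, breathing: IB, breathing_depth: 1.25}
      - {id: IB_aB, breathing: "IB aB", breathing_depth: 0.8}
    processing:
      discard: 20
      registration: none         # none | translation | external
      cutoff: auto               # or a number in Hz
      filter_order: 4
    normalization:
      methods: [uncorrected, factor, roi]
      roi_label: 6
      roi_size: 12
      perfusion_roi_label: 5
    evaluate: {alpha: 0.05}

The run is deterministic given the config: re-running writes byte-identical
CSV/JSON artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    FunctionalMap,
    TemporalSignal,
    amplitude_map,
    determine_cutoff,
    mean_lung_signal,
    separate_components,
)
from .diaphragm import DiaphragmTrace, auto_roi, trace_from_series
from .evaluate import DeviationReport, reproducibility_report
from .io_formats import LungMask, RoiSpec, write_map, write_mask, write_series
from .normalize import roi_normalize, scaling_factor, standard_roi_grid
from .phantom import PhantomConfig, generate_phantom
from .preprocess import discard_steady_state, register_series, select_reference_frame

__all__ = ["ConfigError", "ScanResult", "run_pipeline", "process_scan", "validate_config"]


class ConfigError(ValueError):
    pass


@dataclass
class ScanResult:
    """Everything the pipeline derives from one scan."""

    scan_id: str
    slice_label: str
    is_reference: bool
    cutoff: float
    reference_frame: int
    trace: DiaphragmTrace | None
    vent_signal: TemporalSignal
    factor: Any = None  # NormalizationFactor once computed
    maps: dict[tuple[str, str], FunctionalMap] = field(default_factory=dict)


_ALLOWED_METHODS = {"uncorrected", "factor", "roi"}


def validate_config(cfg: dict) -> dict:
    """Validate/normalize the pipeline config; raises :class:`ConfigError`
    with the offending field path."""

    def fail(path: str, msg: str):
        raise ConfigError(f"config field '{path}': {msg}")

    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    out = dict(cfg)
    if "seed" not in out or not isinstance(out["seed"], int):
        fail("seed", "required integer")
    scans = out.get("scans")
    if not isinstance(scans, list) or not scans:
        fail("scans", "required non-empty list")
    seen = set()
    n_ref = 0
    for i, s in enumerate(scans):
        if not isinstance(s, dict) or "id" not in s:
            fail(f"scans[{i}].id", "required")
        if s["id"] in seen:
            fail(f"scans[{i}].id", f"duplicate scan id {s['id']!r}")
        seen.add(s["id"])
        depth = s.get("breathing_depth", 1.0)
        if not (isinstance(depth, (int, float)) and depth > 0):
            fail(f"scans[{i}].breathing_depth", "must be a positive number")
        n_ref += bool(s.get("reference", False))
    if n_ref != 1:
        fail("scans", f"exactly one scan must set reference: true (found {n_ref})")
    proc = out.setdefault("processing", {})
    proc.setdefault("discard", 20)
    proc.setdefault("registration", "none")
    proc.setdefault("cutoff", "auto")
    proc.setdefault("filter_order", 4)
    if proc["registration"] not in {"none", "translation", "external"}:
        fail("processing.registration", f"unknown backend {proc['registration']!r}")
    norm = out.setdefault("normalization", {})
    norm.setdefault("methods", ["uncorrected", "factor", "roi"])
    norm.setdefault("roi_label", 6)
    norm.setdefault("roi_size", 12)
    norm.setdefault("perfusion_roi_label", 5)
    bad = set(norm["methods"]) - _ALLOWED_METHODS
    if bad:
        fail("normalization.methods", f"unknown method(s) {sorted(bad)}")
    if norm["roi_size"] not in (8, 12):
        fail("normalization.roi_size", "must be 8 or 12")
    out.setdefault("evaluate", {}).setdefault("alpha", 0.05)
    out.setdefault("phantom", {})
    return out


def _phantom_for_scan(cfg: dict, scan: dict, index: int) -> PhantomConfig:
    base = dict(cfg.get("phantom", {}))
    if "grid_size" in base:
        base["grid_size"] = tuple(base["grid_size"])
    for key in ("respiratory_freq", "cardiac_freq"):
        if key in base and isinstance(base[key], list):
            base[key] = tuple(base[key])
    base["breathing_depth"] = float(scan.get("breathing_depth", 1.0))
    master = cfg["seed"]
    base.setdefault("anatomy_seed", master % (2**31 - 1))
    base["seed"] = int(scan.get("seed", (master * 1000 + 7919 * index) % (2**31 - 1)))
    return PhantomConfig(**base)


def process_scan(
    series,
    vw_mask: LungMask,
    qw_mask: LungMask,
    scan_id: str = "",
    slice_label: str = "",
    is_reference: bool = False,
    discard: int = 20,
    registration: str = "none",
    cutoff: float | str = "auto",
    filter_order: int = 4,
    diaphragm_roi: RoiSpec | None = None,
    track_diaphragm: bool = True,
) -> ScanResult:
    """Run the per-scan NuFD chain: discard, register, cutoff, diaphragm
    trace, uncorrected Vw/Qw maps."""
    series = discard_steady_state(series, discard)
    ref_idx = select_reference_frame(series)
    series = register_series(series, ref_idx, backend=registration)

    mean_sig = mean_lung_signal(series, vw_mask)
    cut = determine_cutoff(mean_sig) if cutoff == "auto" else float(cutoff)
    vent_mean, _ = separate_components(mean_sig, cut, order=filter_order)
    vent_signal = TemporalSignal(
        vent_mean, series.frame_interval, component="ventilation", source="lung-mean"
    )

    trace = None
    if track_diaphragm:
        roi = diaphragm_roi or auto_roi(series.frames[ref_idx], vw_mask.mask)
        trace = trace_from_series(series, roi)

    result = ScanResult(
        scan_id=scan_id,
        slice_label=slice_label,
        is_reference=is_reference,
        cutoff=cut,
        reference_frame=ref_idx,
        trace=trace,
        vent_signal=vent_signal,
    )
    result.maps[("Vw", "uncorrected")] = amplitude_map(
        series, vw_mask, "ventilation", cutoff=cut, order=filter_order, scan_id=scan_id
    )
    result.maps[("Qw", "uncorrected")] = amplitude_map(
        series, qw_mask, "perfusion", cutoff=cut, order=filter_order, scan_id=scan_id
    )
    result._series = series  # kept for factor-normalized map regeneration
    result._masks = (vw_mask, qw_mask)
    return result


def run_pipeline(config: dict | str | Path, output_dir: str | Path | None = None) -> DeviationReport:
    """Execute the full protocol described by ``config`` (path or mapping);
    writes maps, traces, factors, reports and a provenance log to the
    artifact directory and returns the :class:`DeviationReport`."""
    if not isinstance(config, dict):
        from .io_formats import read_config

        config_raw = read_config(config)
    else:
        config_raw = config
    cfg = validate_config(config_raw)
    out = Path(output_dir or cfg.get("output_dir", "artifacts"))
    out.mkdir(parents=True, exist_ok=True)

    proc = cfg["processing"]
    norm = cfg["normalization"]
    scans_cfg = list(cfg["scans"])
    # process the reference first: the factor needs its diaphragm trace
    scans_cfg.sort(key=lambda s: not s.get("reference", False))

    results: list[ScanResult] = []
    reference_trace = None
    masks = None
    # the cutoff is subject-specific, not scan-specific: determined on the
    # reference scan and reused for its repeats so the component split is
    # identical across scans being compared
    subject_cutoff = proc["cutoff"]
    roi_v = roi_q = None
    stage = "phantom"
    for i, scan in enumerate(scans_cfg):
        sid = scan["id"]
        try:
            stage = "phantom"
            pconf = _phantom_for_scan(cfg, scan, i)
            series, truth = generate_phantom(pconf)
            if masks is None:
                masks = (
                    LungMask(truth.lung_mask, excludes_heart_vessels=True),
                    LungMask(truth.perfusion_mask, excludes_heart_vessels=False),
                )
                write_mask(masks[0], out / "mask_ventilation.nii.gz")
                write_mask(masks[1], out / "mask_perfusion.nii.gz")
            stage = "process"
            res = process_scan(
                series,
                masks[0],
                masks[1],
                scan_id=sid,
                slice_label=scan.get("slice", "phantom"),
                is_reference=bool(scan.get("reference", False)),
                discard=proc["discard"],
                registration=proc["registration"],
                cutoff=subject_cutoff,
                filter_order=proc["filter_order"],
                track_diaphragm="factor" in norm["methods"],
            )
            if res.is_reference:
                reference_trace = res.trace
                subject_cutoff = res.cutoff
            stage = "normalize"
            if "factor" in norm["methods"]:
                res.factor = scaling_factor(res.vent_signal, res.trace, reference_trace)
                res.maps[("Vw", "factor")] = amplitude_map(
                    res._series,
                    masks[0],
                    "ventilation",
                    cutoff=res.cutoff,
                    order=proc["filter_order"],
                    signal_scale=res.factor.factor,
                    scan_id=sid,
                )
            if "roi" in norm["methods"]:
                if roi_v is None:
                    roi_v = standard_roi_grid(masks[0].mask, size=norm["roi_size"])[
                        int(norm["roi_label"]) - 1
                    ]
                    roi_q = standard_roi_grid(masks[1].mask, size=norm["roi_size"])[
                        int(norm["perfusion_roi_label"]) - 1
                    ]
                res.maps[("Vw", "roi")] = roi_normalize(res.maps[("Vw", "uncorrected")], roi_v)
                res.maps[("Qw", "roi")] = roi_normalize(res.maps[("Qw", "uncorrected")], roi_q)
            results.append(res)
        except Exception as err:
            raise RuntimeError(f"stage '{stage}' failed for scan '{sid}': {err}") from err

    stage = "evaluate"
    report = reproducibility_report(
        [
            {
                "scan_id": r.scan_id,
                "slice_label": r.slice_label,
                "is_reference": r.is_reference,
                "maps": r.maps,
            }
            for r in results
        ],
        alpha=cfg["evaluate"]["alpha"],
    )
    _write_artifacts(out, cfg, results, report)
    return report


def _write_artifacts(out: Path, cfg: dict, results: list[ScanResult], report: DeviationReport) -> None:
    factors = {}
    for r in results:
        sdir = out / r.scan_id
        sdir.mkdir(exist_ok=True)
        write_series(r._series, sdir / "registered.nii.gz")
        for (kind, method), fmap in r.maps.items():
            write_map(fmap, sdir / f"{kind}_{method}.nii.gz")
        if r.trace is not None:
            pd.DataFrame(
                {
                    "frame": np.arange(r.trace.x.size),
                    "raw_mm": r.trace.raw,
                    "relative_mm": r.trace.x,
                    "fit_rms": r.trace.fit_rms,
                }
            ).to_csv(sdir / "diaphragm_trace.csv", index=False)
        if r.factor is not None:
            factors[r.scan_id] = {
                "factor": r.factor.factor,
                "slope": r.factor.slope,
                "s_max": r.factor.s_max,
                "s_min": r.factor.s_min,
                "x_ref_max": r.factor.x_ref_max,
                "x_ref_min": r.factor.x_ref_min,
                "fit_r": r.factor.fit_r,
                "clamped": r.factor.clamped,
            }
    with open(out / "factors.json", "w") as fh:
        json.dump(factors, fh, indent=2, sort_keys=True)
    report.write(out, stem="report")

    canonical = json.dumps(cfg, sort_keys=True, default=str).encode()
    provenance = {
        "nufd_version": __version__,
        "numpy_version": np.__version__,
        "config_sha256": hashlib.sha256(canonical).hexdigest(),
        "config": json.loads(json.dumps(cfg, default=str)),
        "scan_parameters": {
            r.scan_id: {
                "cutoff_hz": r.cutoff,
                "reference_frame": int(r.reference_frame),
                "is_reference": r.is_reference,
            }
            for r in results
        },
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
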