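"""Reproducibility metrics and statistics.

The reproducibility metric is the absolute relative deviation of the masked
map mean of a scan j from the reference scan::

    delta = |(mean_ref - mean_j) / mean_ref|

Method comparisons use a Wilcoxon signed-rank test on paired absolute
deviations: zero differences are dropped, tied absolute differences are
mid-ranked; for n <= 12 remaining pairs the p-value comes from exhaustive
enumeration of all 2^n sign assignments, otherwise from the normal
approximation with tie correction (no continuity correction).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import FunctionalMap

__all__ = [
    "DeviationReport",
    "deviation",
    "wilcoxon_signed_rank",
    "reproducibility_report",
    "display_map",
]

EXACT_WILCOXON_MAX_N = 12


def deviation(map_ref: FunctionalMap, map_j: FunctionalMap) -> tuple[float, float]:
    """Absolute and signed relative deviation of masked means.

    Returns ``(delta, signed)`` with ``signed = (mean_ref - mean_j)/mean_ref``
    and ``delta = |signed|``.
    """
    if map_ref.kind != map_j.kind:
        raise ValueError(f"map kinds differ: {map_ref.kind} vs {map_j.kind}")
    if map_ref.mask.shape != map_j.mask.shape or not np.array_equal(map_ref.mask, map_j.mask):
        raise ValueError("maps must share the same mask")
    g_ref = map_ref.masked_mean()
    if g_ref == 0:
        raise ValueError("reference map mean is zero: deviation undefined")
    signed = (g_ref - map_j.masked_mean()) / g_ref
    return abs(signed), signed


def wilcoxon_signed_rank(
    a: np.ndarray,
    b: np.ndarray | None = None,
    alternative: str = "two-sided",
) -> float:
    """Wilcoxon signed-rank p-value for paired samples (or differences).

    Zero differences are removed; |differences| are mid-ranked; W is the sum
    of ranks of positive differences. Exact enumeration of the 2^n null for
    n <= 12, normal approximation with tie correction beyond. Tail
    probabilities are inclusive; the two-sided p is twice the smaller tail,
    capped at 1.
    """
    d = np.asarray(a, dtype=float)
    if b is not None:
        d = d - np.asarray(b, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    if d.size < 5:
        raise ValueError(f"need at least 5 nonzero paired differences, got {d.size}")
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    n = d.size
    if n <= EXACT_WILCOXON_MAX_N:
        # all 2^n sign assignments of the ranks
        signs = np.array(list(itertools.product((0.0, 1.0), repeat=n)))
        w_null = signs @ ranks
        total = w_null.size
        p_ge = np.count_nonzero(w_null >= w - 1e-12) / total
        p_le = np.count_nonzero(w_null <= w + 1e-12) / total
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(counts**3 - counts) / 48.0
        z = (w - mean) / np.sqrt(var)
        p_ge = float(stats.norm.sf(z))
        p_le = float(stats.norm.cdf(z))
    if alternative == "greater":
        return min(p_ge, 1.0)
    if alternative == "less":
        return min(p_le, 1.0)
    if alternative == "two-sided":
        return min(2.0 * min(p_ge, p_le), 1.0)
    raise ValueError(f"unknown alternative {alternative!r}")


@dataclass
class DeviationReport:
    """Per-scan deviations, group medians and method-pair statistics."""

    deviations: pd.DataFrame  # scan_id, slice_label, kind, method, delta, signed
    medians: pd.DataFrame  # kind, method, median_delta, n
    pvalues: pd.DataFrame  # kind, method_a, method_b, p, n, note
    alpha: float = 0.05
    notes: list[str] = field(default_factory=list)

    def write(self, directory: str | Path, stem: str = "report") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.deviations.to_csv(directory / f"{stem}_deviations.csv", index=False)
        self.medians.to_csv(directory / f"{stem}_medians.csv", index=False)
        block = {
            "alpha": self.alpha,
            "notes": self.notes,
            "pvalues": self.pvalues.to_dict(orient="records"),
            "medians": self.medians.to_dict(orient="records"),
        }
        with open(directory / f"{stem}_statistics.json", "w") as fh:
            json.dump(block, fh, indent=2, sort_keys=True, default=float)


def reproducibility_report(
    scans: list[dict],
    alpha: float = 0.05,
) -> DeviationReport:
    """Deviation report over a set of scans.

    Each entry of ``scans`` is a mapping with keys ``scan_id``,
    ``slice_label``, ``is_reference`` and ``maps``: a dict keyed by
    ``(kind, method)`` -> :class:`FunctionalMap` (e.g. ``("Vw", "factor")``).
    Scans are grouped by slice label; each group needs exactly one reference.
    Medians are computed per (kind, method) over absolute deviations; every
    method pair present for a kind gets a Wilcoxon p-value on the paired
    absolute deviations.
    """
    rows = []
    notes: list[str] = []
    by_slice: dict[str, list[dict]] = {}
    for s in scans:
        by_slice.setdefault(s.get("slice_label", ""), []).append(s)
    for label, group in by_slice.items():
        refs = [s for s in group if s.get("is_reference")]
        if len(refs) != 1:
            raise ValueError(
                f"slice group {label!r} needs exactly one reference scan, found {len(refs)}"
            )
        ref = refs[0]
        others = [s for s in group if s is not ref]
        if not others:
            raise ValueError(f"slice group {label!r} has no non-reference scans")
        for s in others:
            for (kind, method), fmap in s["maps"].items():
                ref_map = ref["maps"][(kind, method)]
                delta, signed = deviation(ref_map, fmap)
                rows.append(
                    {
                        "scan_id": s["scan_id"],
                        "slice_label": label,
                        "kind": kind,
                        "method": method,
                        "delta": delta,
                        "signed": signed,
                    }
                )
    dev = pd.DataFrame(rows).sort_values(["kind", "method", "slice_label", "scan_id"]).reset_index(drop=True)
    med = (
        dev.groupby(["kind", "method"], as_index=False)
        .agg(median_delta=("delta", "median"), n=("delta", "size"))
        .sort_values(["kind", "method"])
        .reset_index(drop=True)
    )
    prow = []
    for kind, kgroup in dev.groupby("kind"):
        methods = sorted(kgroup["method"].unique())
        pivot = kgroup.pivot_table(index=["slice_label", "scan_id"], columns="method", values="delta")
        for ma, mb in itertools.combinations(methods, 2):
            pair = pivot[[ma, mb]].dropna()
            note = ""
            try:
                p = wilcoxon_signed_rank(pair[ma].to_numpy(), pair[mb].to_numpy())
            except ValueError as err:
                p = float("nan")
                note = f"degenerate statistics: {err}"
                notes.append(f"{kind} {ma} vs {mb}: {note}")
            prow.append(
                {"kind": kind, "method_a": ma, "method_b": mb, "p": p, "n": len(pair), "note": note}
            )
    pvals = pd.DataFrame(prow, columns=["kind", "method_a", "method_b", "p", "n", "note"])
    if (dev["delta"] == 0).all():
        notes.append("degenerate statistics: all deviations are exactly zero")
    return DeviationReport(deviations=dev, medians=med, pvalues=pvals, alpha=alpha, notes=notes)


def display_map(
    fmap: FunctionalMap,
    path: str | Path,
    gaussian_sigma: float = 1.0,
    log_scale: bool = True,
    cmap: str = "inferno",
) -> Path:
    """Presentation-only rendering: Gaussian-smoothed, optionally
    log-scaled map image. Never feeds back into any quantitative output;
    the input map is left untouched."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from scipy.ndimage import gaussian_filter

    values = fmap.values.copy()
    if gaussian_sigma > 0:
        values = gaussian_filter(values, gaussian_sigma)
    shown = np.ma.masked_where(~fmap.mask, values)
    if log_scale:
        positive = shown.compressed()
        floor = positive[positive > 0].min() if (positive > 0).any() else 1.0
        shown = np.ma.log10(np.ma.maximum(shown, floor))
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(shown, cmap=cmap, interpolation="nearest")
    ax.set_title(f"{fmap.kind} map ({fmap.scan_id})" if fmap.scan_id else f"{fmap.kind} map")
    ax.axis("off")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return Path(path)
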