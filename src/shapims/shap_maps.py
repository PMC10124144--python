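"""Spatial explanation layer: SHAP maps, direction calls, top-k reports.

A SHAP map places one feature's per-pixel Shapley values on the tissue
grid. Its sign field shows *where* the feature pushes the classifier
toward (+) or away from (-) the class of interest; its magnitude shows how
strongly. Read jointly with the feature's ion image, it distinguishes
correlative markers (high intensity coincides with positive attribution —
the feature's presence indicates the class) from anticorrelative ones
(high intensity coincides with negative attribution — its absence
indicates the class). That visual judgement is operationalized here as a
Spearman rank correlation between intensity and attribution with a
symmetric verdict threshold.

Maps are rendered with a symmetric diverging scale anchored at zero
(blue = negative, white = zero, red = positive) so sign is never visually
distorted, and without any smoothing — spatial filtering would fabricate
structure the model did not produce.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from .ims_data import IMSDataset, SpatialImage, ion_image, values_image
from .shapley import FeatureRanking, ShapleyMatrix

__all__ = [
    "DirectionCall",
    "shap_map",
    "symmetric_limit",
    "diverging_rgba",
    "render_diverging",
    "render_sequential",
    "direction_call",
    "relevance_region",
    "report_topk",
]

CORRELATIVE = "CORRELATIVE"
ANTICORRELATIVE = "ANTICORRELATIVE"
INDETERMINATE = "INDETERMINATE"


@dataclass(frozen=True)
class DirectionCall:
    """Direction of a feature's association with the class of interest."""

    verdict: str
    association_statistic: float
    n_pixels_evaluated: int

    def __post_init__(self) -> None:
        if self.verdict not in (CORRELATIVE, ANTICORRELATIVE, INDETERMINATE):
            raise ValueError(f"unknown verdict {self.verdict!r}")
        if not -1.0 <= self.association_statistic <= 1.0:
            raise ValueError("association statistic must be in [-1, 1]")


def shap_map(sm: ShapleyMatrix, feature_index: int,
             ds: IMSDataset) -> SpatialImage:
    """One feature's Shapley values on the pixel grid (uncovered = NaN)."""
    if not 0 <= feature_index < sm.values.shape[1]:
        raise IndexError(f"feature index {feature_index} out of range")
    mz = ds.mz_values[feature_index]
    return values_image(
        ds, sm.values[:, feature_index],
        legend=f"SHAP map m/z {mz:.4f} (log-odds)",
        pixel_indices=sm.pixel_indices,
    )


def symmetric_limit(values: np.ndarray) -> float:
    """Colour limit +-max|value| over covered cells; +-1 for an all-zero map."""
    vmax = float(np.nanmax(np.abs(values)))
    return vmax if vmax > 0.0 else 1.0


def diverging_rgba(values: np.ndarray) -> np.ndarray:
    """RGBA grid of the diverging scale used by :func:`render_diverging`.

    Zero maps to the neutral midpoint, positive values to red hues,
    negative to blue; negation therefore swaps the red and blue sides.
    """
    vmax = symmetric_limit(values)
    cmap = plt.get_cmap("RdBu_r").copy()
    cmap.set_bad("0.85")
    return cmap((np.asarray(values, float) + vmax) / (2 * vmax))


def render_diverging(img: SpatialImage, out: str | Path) -> Path:
    """Render a signed map with a symmetric blue-white-red scale.

    Colour limits are +-max|value| over covered cells so that zero always
    maps to the neutral midpoint; an all-zero map falls back to +-1.
    Missing cells render in a distinct background grey.
    """
    out = Path(out)
    vmax = symmetric_limit(img.values)
    fig, ax = plt.subplots(figsize=(5, 4))
    cmap = plt.get_cmap("RdBu_r").copy()
    cmap.set_bad("0.85")
    im = ax.imshow(img.values, cmap=cmap, vmin=-vmax, vmax=vmax,
                   interpolation="nearest")
    fig.colorbar(im, ax=ax, label=img.legend or "value")
    ax.set_title(img.legend)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out


def render_sequential(img: SpatialImage, out: str | Path) -> Path:
    """Render a non-negative map (e.g. an ion image) with a sequential scale."""
    out = Path(out)
    fig, ax = plt.subplots(figsize=(5, 4))
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("0.85")
    im = ax.imshow(img.values, cmap=cmap, interpolation="nearest")
    fig.colorbar(im, ax=ax, label=img.legend or "value")
    ax.set_title(img.legend)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out


def direction_call(ds: IMSDataset, sm: ShapleyMatrix, feature_index: int,
                   eval_pixels: np.ndarray | None = None,
                   threshold: float = 0.3) -> DirectionCall:
    """Classify a feature as correlative or anticorrelative for the class.

    Spearman rank correlation between measured intensity and Shapley value
    over the evaluated pixels (all covered pixels by default). Verdict is
    CORRELATIVE above +threshold, ANTICORRELATIVE below -threshold, else
    INDETERMINATE. Degenerate inputs (fewer than 10 pixels, or constant
    intensity or attribution) are INDETERMINATE with statistic 0.
    """
    if not 0 <= feature_index < sm.values.shape[1]:
        raise IndexError(f"feature index {feature_index} out of range")
    rows = np.arange(len(sm.pixel_indices))
    if eval_pixels is not None:
        lookup = {int(p): r for r, p in enumerate(sm.pixel_indices)}
        rows = np.array([lookup[int(p)] for p in eval_pixels], dtype=int)
    inten = ds.intensities[sm.pixel_indices[rows], feature_index]
    phi = sm.values[rows, feature_index]
    n = len(rows)
    if n < 10 or np.ptp(inten) == 0 or np.ptp(phi) == 0:
        return DirectionCall(INDETERMINATE, 0.0, n)
    rho = float(stats.spearmanr(inten, phi).statistic)
    if np.isnan(rho):
        return DirectionCall(INDETERMINATE, 0.0, n)
    if rho > threshold:
        verdict = CORRELATIVE
    elif rho < -threshold:
        verdict = ANTICORRELATIVE
    else:
        verdict = INDETERMINATE
    return DirectionCall(verdict, rho, n)


def relevance_region(sm: ShapleyMatrix, feature_index: int,
                     quantile: float) -> np.ndarray:
    """Pixels where the feature's |Shapley value| exceeds the given quantile.

    Returns dataset pixel indices; the region where the feature is most
    relevant to recognising the class.
    """
    if not 0.0 <= quantile < 1.0:
        raise ValueError("quantile must be in [0, 1)")
    mag = np.abs(sm.values[:, feature_index])
    cut = np.quantile(mag, quantile)
    return sm.pixel_indices[mag > cut]


def report_topk(ds: IMSDataset, sm: ShapleyMatrix, ranking: FeatureRanking,
                k: int, outdir: str | Path,
                direction_threshold: float = 0.3) -> dict:
    """Write ion image + SHAP map rasters and a summary row for each of the
    top-k ranked features; returns a manifest of everything written."""
    if not 1 <= k <= len(ranking.table):
        raise ValueError(f"k must be in [1, {len(ranking.table)}]")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows, files = [], []
    for rec in ranking.top(k).itertuples():
        j = int(rec.feature_index)
        ion_path = outdir / f"rank{rec.rank:02d}_ion_f{j}.png"
        map_path = outdir / f"rank{rec.rank:02d}_shap_f{j}.png"
        render_sequential(ion_image(ds, j), ion_path)
        render_diverging(shap_map(sm, j, ds), map_path)
        call = direction_call(ds, sm, j, threshold=direction_threshold)
        files += [str(ion_path), str(map_path)]
        rows.append({
            "rank": int(rec.rank),
            "feature_index": j,
            "mz": float(rec.mz),
            "global_shap_score": float(rec.global_shap_score),
            "verdict": call.verdict,
            "association_statistic": call.association_statistic,
        })
    summary = outdir / "topk_summary.csv"
    pd.DataFrame(rows).to_csv(summary, index=False, float_format="%.12g")
    manifest = {
        "k": k,
        "summary": str(summary),
        "rasters": files,
        "rows": rows,
    }
    with open(outdir / "topk_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
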