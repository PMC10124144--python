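"""Synthetic IMS phantom generator with planted ground truth.

Real IMS datasets of the kind this package targets (whole-body sections,
kidney sections) are rarely shareable, so every downstream stage is
exercised on synthetic phantoms: region-structured pixel grids with
log-normal intensity noise, planted over/under-expressed marker features,
optional correlated feature pairs, and an optional artifact that bleeds a
marker's signal into a foreign region (emulating sample-preparation
confounds such as visceral fat delocalization).

The generative model, per pixel ``i`` and feature ``j``::

    X[i, j] = exp( mu + delta[i, j] + sigma * Z[i, j] )

where ``mu`` is the baseline log-mean, ``delta`` holds the planted region
effects (+effect_size inside the region for UP markers, -effect_size for
DOWN markers, plus any artifact bleed), and ``Z`` is standard Gaussian
noise, optionally correlated within configured feature pairs. Multiplicative
(log-normal) noise is the standard behaviour of ion-count data.

Regions are geometric primitives resolved in listed order (first match
wins), so an ellipse may sit inside a full-grid background region. Each
region's annotation mask labels that region POS, pixels of other regions
NEG, and a 1-pixel ring along region boundaries EXCLUDED, mirroring the
practice of excluding hard-to-annotate border pixels from training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ims_data import AnnotationMask, IMSDataset, Label

__all__ = [
    "Rect",
    "Ellipse",
    "Marker",
    "Artifact",
    "PhantomConfig",
    "GroundTruth",
    "generate_phantom",
    "region_mask",
    "config_from_text",
    "config_to_text",
    "demo_config",
    "artifact_demo_config",
]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle; rows ``row0 <= r < row1``, same for cols."""

    row0: int
    col0: int
    row1: int
    col1: int

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return (
            (rows >= self.row0) & (rows < self.row1)
            & (cols >= self.col0) & (cols < self.col1)
        )


@dataclass(frozen=True)
class Ellipse:
    """Filled ellipse with centre ``(cr, cc)`` and semi-axes ``(rr, rc)``."""

    cr: float
    cc: float
    rr: float
    rc: float

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return (
            ((rows - self.cr) / self.rr) ** 2
            + ((cols - self.cc) / self.rc) ** 2
        ) <= 1.0


@dataclass(frozen=True)
class Marker:
    """A feature planted as over- (UP) or under-expressed (DOWN) in a region.

    ``effect_size`` is the fold-change on the natural-log scale.
    """

    feature_index: int
    region: str
    direction: str  # "UP" | "DOWN"
    effect_size: float

    def __post_init__(self) -> None:
        if self.direction not in ("UP", "DOWN"):
            raise ValueError(f"direction must be UP or DOWN, got {self.direction}")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")

    @property
    def signed_effect(self) -> float:
        return self.effect_size if self.direction == "UP" else -self.effect_size


@dataclass(frozen=True)
class Artifact:
    """Bleed of marker signal from a source region into a foreign area.

    For every affected marker feature of ``source_region``, the fraction
    ``bleed_fraction`` of its signed log-scale effect is added to pixels of
    ``bleed_region`` (a geometric primitive, typically inside another
    region).
    """

    source_region: str
    bleed_region: Rect | Ellipse
    affected_features: tuple[int, ...]
    bleed_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.bleed_fraction <= 1.0:
            raise ValueError("bleed_fraction must be in [0, 1]")


@dataclass(frozen=True)
class PhantomConfig:
    grid_h: int
    grid_w: int
    regions: tuple[tuple[str, Rect | Ellipse], ...]
    n_features: int
    markers: tuple[Marker, ...]
    baseline_log_mean: float = 1.0
    noise_sigma: float = 0.3
    correlated_pairs: tuple[tuple[int, int, float], ...] = ()
    artifact: Artifact | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_h <= 0 or self.grid_w <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        idx = [m.feature_index for m in self.markers]
        if len(set(idx)) != len(idx):
            raise ValueError("marker feature indices must be distinct")
        if idx and (max(idx) >= self.n_features or min(idx) < 0):
            raise ValueError("marker feature index out of range")
        names = [n for n, _ in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        for m in self.markers:
            if m.region not in names:
                raise ValueError(f"marker region {m.region!r} not defined")
        for a, b, rho in self.correlated_pairs:
            if not -1.0 <= rho <= 1.0:
                raise ValueError("correlation must be in [-1, 1]")
            if not (0 <= a < self.n_features and 0 <= b < self.n_features):
                raise ValueError("correlated feature index out of range")


@dataclass(frozen=True)
class GroundTruth:
    """Planted-truth record: marker table and per-pixel region membership."""

    markers: pd.DataFrame  # feature_index, region, direction, effect_size
    region_of_pixel: np.ndarray  # (m,) region names ("" = no region)
    pixel_coords: np.ndarray  # (m, 2)
    grid_shape: tuple[int, int]
    region_names: tuple[str, ...]

    def region_pixels(self, region: str) -> np.ndarray:
        if region not in self.region_names:
            raise KeyError(f"unknown region {region!r}")
        return np.flatnonzero(self.region_of_pixel == region)

    def marker_features(self) -> np.ndarray:
        return self.markers["feature_index"].to_numpy()


def _membership(cfg: PhantomConfig,
                rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Region name per pixel; first listed region wins on overlap."""
    member = np.full(rows.shape, "", dtype=object)
    unclaimed = np.ones(rows.shape, dtype=bool)
    for name, prim in cfg.regions:
        inside = prim.contains(rows, cols) & unclaimed
        if not inside.any():
            raise ValueError(f"region {name!r} covers no pixels")
        member[inside] = name
        unclaimed &= ~inside
    return member


def generate_phantom(
    cfg: PhantomConfig,
) -> tuple[IMSDataset, dict[str, AnnotationMask], GroundTruth]:
    """Generate a phantom dataset, one mask per region, and ground truth.

    Deterministic: identical config (including seed) gives bit-identical
    output.
    """
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.grid_h, cfg.grid_w
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    rows, cols = rr.ravel(), cc.ravel()  # row-major pixel order
    m = rows.size
    member = _membership(cfg, rows, cols)

    # m/z axis: sorted uniform draws over a typical MALDI acquisition range
    mz = np.sort(rng.uniform(300.0, 1200.0, size=cfg.n_features))
    while not (np.diff(mz) > 0).all():  # vanishing probability, exact guard
        mz = np.sort(rng.uniform(300.0, 1200.0, size=cfg.n_features))

    log_mean = np.full((m, cfg.n_features), cfg.baseline_log_mean)
    for mk in cfg.markers:
        inside = member == mk.region
        log_mean[inside, mk.feature_index] += mk.signed_effect

    if cfg.artifact is not None:
        art = cfg.artifact
        by_index = {mk.feature_index: mk for mk in cfg.markers}
        bleed = art.bleed_region.contains(rows, cols)
        if not bleed.any():
            raise ValueError("artifact bleed region covers no pixels")
        for j in art.affected_features:
            mk = by_index.get(j)
            if mk is None or mk.region != art.source_region:
                raise ValueError(
                    f"artifact feature {j} is not a marker of region "
                    f"{art.source_region!r}"
                )
            log_mean[bleed, j] += art.bleed_fraction * mk.signed_effect

    Z = rng.standard_normal((m, cfg.n_features))
    for a, b, rho in cfg.correlated_pairs:
        Z[:, b] = rho * Z[:, a] + np.sqrt(1.0 - rho**2) * Z[:, b]

    X = np.exp(log_mean + cfg.noise_sigma * Z)
    ds = IMSDataset(X, np.column_stack([rows, cols]), mz,
                    name=f"phantom(seed={cfg.seed})")

    gt = GroundTruth(
        markers=pd.DataFrame(
            [
                {
                    "feature_index": mk.feature_index,
                    "region": mk.region,
                    "direction": mk.direction,
                    "effect_size": mk.effect_size,
                }
                for mk in cfg.markers
            ]
        ),
        region_of_pixel=member,
        pixel_coords=ds.pixel_coords,
        grid_shape=(H, W),
        region_names=tuple(n for n, _ in cfg.regions),
    )
    masks = {name: region_mask(gt, name) for name in gt.region_names}
    return ds, masks, gt


def _boundary_ring(gt: GroundTruth) -> np.ndarray:
    """Pixels whose 8-neighbourhood crosses a region boundary."""
    H, W = gt.grid_shape
    grid = np.full((H, W), "", dtype=object)
    rows, cols = gt.pixel_coords[:, 0], gt.pixel_coords[:, 1]
    grid[rows, cols] = gt.region_of_pixel
    ring = np.zeros((H, W), dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            r0, r1 = max(dr, 0), H + min(dr, 0)
            c0, c1 = max(dc, 0), W + min(dc, 0)
            a = grid[r0:r1, c0:c1]
            b = grid[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
            ring[r0:r1, c0:c1] |= a != b
    return ring[rows, cols]


def region_mask(gt: GroundTruth, region: str) -> AnnotationMask:
    """One-vs-all mask for a region with a 1-pixel EXCLUDED boundary ring.

    POS = region pixels off the ring; NEG = pixels of other regions off the
    ring; EXCLUDED = the ring and any pixel belonging to no region.
    """
    if region not in gt.region_names:
        raise KeyError(f"unknown region {region!r}")
    ring = _boundary_ring(gt)
    labels = np.full(gt.region_of_pixel.shape, int(Label.EXCLUDED))
    is_reg = gt.region_of_pixel == region
    is_other = (gt.region_of_pixel != region) & (gt.region_of_pixel != "")
    labels[is_reg & ~ring] = int(Label.POS)
    labels[is_other & ~ring] = int(Label.NEG)
    return AnnotationMask(region, labels)


# ---------------------------------------------------------------------------
# Flat key/value config text format
#
#   grid_h = 32
#   grid_w = 32
#   n_features = 50
#   regions = target:ellipse:15.5,11,9,7 | background:rect:0,0,32,32
#   markers = 5:target:UP:2.0 | 23:target:DOWN:1.8
#   baseline_log_mean = 1.0
#   noise_sigma = 0.3
#   correlated_pairs = 8:9:0.7
#   artifact = target:ellipse:6,26,4,4:5+7:0.8
#   seed = 0
#
# Primitives: rect:row0,col0,row1,col1 (half-open) and
# ellipse:centre_row,centre_col,semi_axis_row,semi_axis_col. Artifact
# affected features are '+'-separated.
# ---------------------------------------------------------------------------

def _parse_primitive(kind: str, args: str) -> Rect | Ellipse:
    vals = [float(v) for v in args.split(",")]
    if kind == "rect":
        return Rect(*(int(v) for v in vals))
    if kind == "ellipse":
        return Ellipse(*vals)
    raise ValueError(f"unknown primitive {kind!r}")


def _fmt_primitive(p: Rect | Ellipse) -> str:
    if isinstance(p, Rect):
        return f"rect:{p.row0},{p.col0},{p.row1},{p.col1}"
    return f"ellipse:{p.cr:g},{p.cc:g},{p.rr:g},{p.rc:g}"


def config_from_text(text: str) -> PhantomConfig:
    """Parse the flat key/value phantom config format."""
    kv: dict[str, str] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad config line: {line!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        kv[key] = val

    def items(key):
        return [s.strip() for s in kv.get(key, "").split("|") if s.strip()]

    regions = []
    for spec in items("regions"):
        name, kind, args = spec.split(":", 2)
        regions.append((name.strip(), _parse_primitive(kind.strip(), args)))
    markers = []
    for spec in items("markers"):
        j, region, direction, eff = (s.strip() for s in spec.split(":"))
        markers.append(Marker(int(j), region, direction, float(eff)))
    pairs = []
    for spec in items("correlated_pairs"):
        a, b, rho = (s.strip() for s in spec.split(":"))
        pairs.append((int(a), int(b), float(rho)))
    artifact = None
    if "artifact" in kv and kv["artifact"]:
        src, kind, args, feats, frac = (s.strip()
                                        for s in kv["artifact"].split(":"))
        artifact = Artifact(
            src, _parse_primitive(kind, args),
            tuple(int(f) for f in feats.split("+")), float(frac),
        )
    try:
        return PhantomConfig(
            grid_h=int(kv["grid_h"]),
            grid_w=int(kv["grid_w"]),
            regions=tuple(regions),
            n_features=int(kv["n_features"]),
            markers=tuple(markers),
            baseline_log_mean=float(kv.get("baseline_log_mean", 1.0)),
            noise_sigma=float(kv.get("noise_sigma", 0.3)),
            correlated_pairs=tuple(pairs),
            artifact=artifact,
            seed=int(kv.get("seed", 0)),
        )
    except KeyError as exc:
        raise ValueError(f"phantom config missing key {exc}") from None


def config_to_text(cfg: PhantomConfig) -> str:
    lines = [
        f"grid_h = {cfg.grid_h}",
        f"grid_w = {cfg.grid_w}",
        f"n_features = {cfg.n_features}",
        "regions = " + " | ".join(
            f"{name}:{_fmt_primitive(p)}" for name, p in cfg.regions),
        "markers = " + " | ".join(
            f"{m.feature_index}:{m.region}:{m.direction}:{m.effect_size:g}"
            for m in cfg.markers),
        f"baseline_log_mean = {cfg.baseline_log_mean:g}",
        f"noise_sigma = {cfg.noise_sigma:g}",
    ]
    if cfg.correlated_pairs:
        lines.append("correlated_pairs = " + " | ".join(
            f"{a}:{b}:{rho:g}" for a, b, rho in cfg.correlated_pairs))
    if cfg.artifact is not None:
        a = cfg.artifact
        feats = "+".join(str(j) for j in a.affected_features)
        lines.append(
            f"artifact = {a.source_region}:{_fmt_primitive(a.bleed_region)}:"
            f"{feats}:{a.bleed_fraction:g}")
    lines.append(f"seed = {cfg.seed}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Canonical demo phantoms
# ---------------------------------------------------------------------------

def demo_config(seed: int = 0, *, noise_sigma: float = 0.3) -> PhantomConfig:
    """Two-region 32x32 phantom, 50 features, 5 planted target markers.

    The target region is an ellipse embedded in a full-grid background;
    three markers are over-expressed and two under-expressed in the target,
    with one correlated non-marker feature pair as a distractor. Marker
    effects span 0.6-1.0 on the natural-log scale (fold changes of about
    1.8-2.7x): individually informative at the configured noise level but
    only jointly separating, so a classifier must combine them.
    """
    return PhantomConfig(
        grid_h=32,
        grid_w=32,
        regions=(
            ("target", Ellipse(15.5, 11.0, 9.0, 7.0)),
            ("background", Rect(0, 0, 32, 32)),
        ),
        n_features=50,
        markers=(
            Marker(5, "target", "UP", 0.9),
            Marker(12, "target", "UP", 0.7),
            Marker(23, "target", "DOWN", 0.8),
            Marker(31, "target", "UP", 1.0),
            Marker(40, "target", "DOWN", 0.6),
        ),
        baseline_log_mean=1.0,
        noise_sigma=noise_sigma,
        correlated_pairs=((8, 9, 0.7),),
        seed=seed,
    )


def artifact_demo_config(seed: int = 0) -> PhantomConfig:
    """Demo phantom plus an artifact bleeding one UP marker outside.

    Feature 5 (an UP marker of the target region) bleeds 80% of its
    log-scale effect into an ellipse inside the background region,
    emulating an analyte-delocalization confound.
    """
    base = demo_config(seed)
    return PhantomConfig(
        grid_h=base.grid_h,
        grid_w=base.grid_w,
        regions=base.regions,
        n_features=base.n_features,
        markers=base.markers,
        baseline_log_mean=base.baseline_log_mean,
        noise_sigma=base.noise_sigma,
        correlated_pairs=base.correlated_pairs,
        artifact=Artifact(
            source_region="target",
            bleed_region=Ellipse(6.0, 26.0, 4.0, 4.0),
            affected_features=(5,),
            bleed_fraction=0.8,
        ),
        seed=seed,
    )
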