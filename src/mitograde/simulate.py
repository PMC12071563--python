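"""Synthetic slides and simulated reader studies.

Two generators make the whole pipeline testable without any whole-slide
image:

* a spatial point-pattern generator — a homogeneous Poisson background of
  mitoses over a tumor polygon plus planted Gaussian clusters (the
  "hotspots" the engine should recover), with Beta-distributed detection
  confidences;
* a reader simulator — ordinal scores drawn per slide/reader through a
  row-stochastic 3×3 confusion kernel K (K[t][s] = P(report s | truth t)),
  with counting zones placed at the true hotspot center plus isotropic
  Gaussian jitter.

Both are fully reproducible from their seed. The expected confusion matrix
of two kernel-driven readers has a closed form (a mixture of outer products
of kernel rows over the truth prior), which gives an analytic weighted
kappa to check the empirical one against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box
from shapely.prepared import prep

from .geometry import CircleZone, PointUm, SlideFrame, area_to_radius
from .hotspots import MitosisDetection

__all__ = [
    "Cluster",
    "SlideSimConfig",
    "ReaderSimConfig",
    "generate_point_pattern",
    "simulate_reader_scores",
    "expected_confusion",
    "kappa_linear_expected",
    "rectangle_mm",
]


def rectangle_mm(width_mm: float, height_mm: float) -> Polygon:
    """Axis-aligned rectangular tumor region in microns, origin at (0, 0)."""
    return box(0.0, 0.0, width_mm * 1000.0, height_mm * 1000.0)


@dataclass(frozen=True)
class Cluster:
    """A planted mitotic hotspot: isotropic Gaussian around a center."""

    center: PointUm
    sigma_um: float
    n_points: int

    def __post_init__(self) -> None:
        if not (self.sigma_um > 0):
            raise ValueError("sigma_um must be positive")
        if self.n_points < 0:
            raise ValueError("n_points must be non-negative")


@dataclass(frozen=True)
class SlideSimConfig:
    """Configuration of one synthetic slide.

    lambda_bg is the homogeneous background intensity in mitoses per mm²
    (typical routine breast slides sit around a few per mm²); clusters plant
    localized density excesses. Confidences of the generated detections are
    drawn from Beta(conf_alpha, conf_beta), defaulting to a right-skewed
    Beta(5, 1.5) so most simulated detections survive a 0.5 threshold.
    """

    frame: SlideFrame
    region: Polygon
    lambda_bg: float = 2.0
    clusters: tuple[Cluster, ...] = ()
    conf_alpha: float = 5.0
    conf_beta: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_bg < 0:
            raise ValueError("lambda_bg must be non-negative")


def _rejection_uniform(
    rng: np.random.Generator, region: Polygon, n: int
) -> np.ndarray:
    """n uniform points inside the polygon by bounding-box rejection."""
    from shapely.geometry import Point

    prepared = prep(region)
    minx, miny, maxx, maxy = region.bounds
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(16, int((n - got) * 2.5))
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        for x, y in zip(xs, ys):
            if prepared.covers(Point(x, y)):
                out[got] = (x, y)
                got += 1
                if got == n:
                    break
    return out


def _truncated_gaussian(
    rng: np.random.Generator, region: Polygon, center: PointUm,
    sigma: float, n: int,
) -> np.ndarray:
    """n Gaussian draws truncated to the polygon (redraw, not clip)."""
    from shapely.geometry import Point

    prepared = prep(region)
    out = np.empty((n, 2))
    got = 0
    attempts = 0
    while got < n:
        attempts += 1
        if attempts > 10000:
            raise RuntimeError(
                "cluster truncation failed: center too far outside the region?"
            )
        m = max(16, (n - got) * 2)
        pts = rng.normal(loc=(center[0], center[1]), scale=sigma, size=(m, 2))
        for x, y in pts:
            if prepared.covers(Point(x, y)):
                out[got] = (x, y)
                got += 1
                if got == n:
                    break
    return out


def generate_point_pattern(
    cfg: SlideSimConfig,
) -> tuple[list[MitosisDetection], np.ndarray]:
    """Generate one slide's mitosis detections with ground-truth labels.

    Returns (detections, labels) where labels[i] = −1 for a background
    point and the cluster index otherwise. The background count is
    Poisson(lambda_bg · area_mm2); background positions are uniform over
    the polygon; cluster points are isotropic Gaussians truncated to the
    polygon. Confidences are i.i.d. Beta draws. Byte-identical output for
    the same config and seed.
    """
    rng = np.random.default_rng(cfg.seed)
    area_mm2 = cfg.region.area / 1e6
    n_bg = int(rng.poisson(cfg.lambda_bg * area_mm2)) if cfg.lambda_bg > 0 else 0

    coords: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    if n_bg > 0:
        coords.append(_rejection_uniform(rng, cfg.region, n_bg))
        labels.append(np.full(n_bg, -1))
    for ci, cl in enumerate(cfg.clusters):
        if cl.n_points == 0:
            continue
        coords.append(
            _truncated_gaussian(rng, cfg.region, cl.center, cl.sigma_um, cl.n_points)
        )
        labels.append(np.full(cl.n_points, ci))

    if not coords:
        return [], np.empty(0, dtype=int)
    pts = np.vstack(coords)
    lab = np.concatenate(labels).astype(int)
    conf = rng.beta(cfg.conf_alpha, cfg.conf_beta, size=len(pts))
    dets = [
        MitosisDetection(
            pos=PointUm(float(x), float(y)),
            confidence=float(c),
            id=f"{cfg.frame.slide_id}_m{i}",
        )
        for i, ((x, y), c) in enumerate(zip(pts, conf))
    ]
    return dets, lab


@dataclass(frozen=True)
class ReaderSimConfig:
    """Configuration of a two-reader crossover score simulation.

    true_scores: consensus score per slide. kernels: per (reader, condition)
    row-stochastic 3×3 confusion kernel; a kernel closer to the identity
    means a more reliable reader, and the with-AI kernels are typically set
    closer to identity than the without-AI ones. zone_jitter_um: standard
    deviation of the displacement of a reader's counting-zone center from
    the true hotspot center; zone_area_mm2 sizes the counting circle.
    """

    true_scores: tuple[int, ...]
    kernels: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    true_centers: tuple[PointUm, ...] | None = None
    zone_jitter_um: dict[tuple[str, str], float] = field(default_factory=dict)
    zone_area_mm2: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for s in self.true_scores:
            if s not in (1, 2, 3):
                raise ValueError("true scores must be in {1, 2, 3}")
        for key, k in self.kernels.items():
            arr = np.asarray(k, dtype=float)
            if arr.shape != (3, 3) or (arr < 0).any():
                raise ValueError(f"kernel {key} must be a non-negative 3x3 matrix")
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-12):
                raise ValueError(f"kernel {key} rows must sum to 1")


def simulate_reader_scores(cfg: ReaderSimConfig) -> pd.DataFrame:
    """Simulate the two-reader, two-condition score table.

    Returns a records DataFrame (slide_id, reader_id, condition, score, and
    zone columns when true centers are provided) with one row per
    (slide, reader, condition), drawn independently through the kernels.
    """
    rng = np.random.default_rng(cfg.seed)
    readers = sorted({r for r, _ in cfg.kernels})
    conditions = sorted({c for _, c in cfg.kernels})
    if not readers:
        raise ValueError("no kernels supplied")
    radius = area_to_radius(cfg.zone_area_mm2)
    rows = []
    for reader in readers:
        for cond in conditions:
            kernel = np.asarray(cfg.kernels[(reader, cond)], dtype=float)
            jitter = cfg.zone_jitter_um.get((reader, cond), 0.0)
            for i, t in enumerate(cfg.true_scores):
                score = int(rng.choice(3, p=kernel[t - 1]) + 1)
                row = {
                    "slide_id": f"s{i:04d}",
                    "reader_id": reader,
                    "condition": cond,
                    "score": score,
                }
                if cfg.true_centers is not None:
                    cx, cy = cfg.true_centers[i]
                    dx, dy = rng.normal(0.0, max(jitter, 1e-12), 2)
                    row.update(
                        zone_x=cx + dx, zone_y=cy + dy, zone_radius_um=radius
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def expected_confusion(
    prior: Sequence[float],
    kernel_a: np.ndarray,
    kernel_b: np.ndarray,
) -> np.ndarray:
    """Expected 3×3 confusion matrix of two conditionally independent readers.

    P(a = i, b = j) = Σ_t prior[t] · K_a[t, i] · K_b[t, j].
    """
    prior = np.asarray(prior, dtype=float)
    prior = prior / prior.sum()
    ka = np.asarray(kernel_a, dtype=float)
    kb = np.asarray(kernel_b, dtype=float)
    return np.einsum("t,ti,tj->ij", prior, ka, kb)


def kappa_linear_expected(p: np.ndarray) -> float:
    """Closed-form linear weighted kappa of a probability confusion matrix.

    Direct application of κ_w = 1 − Σ w_ij p_ij / Σ w_ij e_ij with
    w_ij = |i − j| / (k − 1); independent of the table-based estimator used
    on observed counts.
    """
    p = np.asarray(p, dtype=float)
    p = p / p.sum()
    k = p.shape[0]
    idx = np.arange(k)
    w = np.abs(idx[:, None] - idx[None, :]) / (k - 1)
    row, col = p.sum(axis=1), p.sum(axis=0)
    e = np.outer(row, col)
    denom = (w * e).sum()
    if denom == 0:
        raise ValueError("kappa undefined: no expected disagreement")
    return float(1.0 - (w * p).sum() / denom)
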