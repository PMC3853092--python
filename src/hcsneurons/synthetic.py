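"""Synthetic multi-neuron fluorescence scenes with exact geometric ground truth.

Real high-content screens image hundreds of neurons per frame: bright,
roughly disk-shaped somata connected to thin, branching neurites, with the
neurite compartment shrinking as a depolymerizing drug dose rises.  This
module renders simplified scenes of that kind -- filled disks for somata,
rasterized polyline strokes for neurites -- and returns, alongside each
image, the morphometric ground truth computed *from the geometric
specifications* (never from the rendering).  That ground truth is the
oracle against which the segmentation/feature-extraction chain is tested.

A dose-series generator builds a labelled multi-class dataset whose
per-class means follow configurable trend functions of log-dose: a
quadratic arc in soma count, a monotone decline in neurite abundance and
length, and a rising probability of soma clustering at high dose.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from skimage.draw import line as _bresenham_line

__all__ = [
    "SomaSpec",
    "NeuriteSpec",
    "SceneGroundTruth",
    "DoseSeriesConfig",
    "generate_scene",
    "sample_scene_specs",
    "generate_dose_series",
    "write_dataset",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = [
    "filename",
    "dose_ng_per_ml",
    "soma_count",
    "soma_area_px",
    "neurite_length_px",
    "neurite_area_px",
    "n_attachment",
    "n_ending",
    "n_branch",
]


@dataclass
class SomaSpec:
    """A soma rendered as a filled disk of constant intensity."""

    center: tuple[float, float]  # (row, col), pixels
    radius: float  # pixels, >= 3
    peak_intensity: float = 600.0

    def __post_init__(self) -> None:
        if self.radius < 3:
            raise ValueError(f"soma radius must be >= 3 px, got {self.radius}")


@dataclass
class NeuriteSpec:
    """A neurite stroke: a polyline anchored on a soma perimeter.

    ``branches`` holds ``(vertex_index, sub_polyline)`` pairs; each
    sub-polyline starts at ``path[vertex_index]`` so the junction lies on
    the parent path.  ``width`` is the full stroke width in pixels.
    """

    attachment_soma: int
    path: np.ndarray  # (k, 2) float array of (row, col) vertices
    branches: list[tuple[int, np.ndarray]] = field(default_factory=list)
    width: int = 3
    intensity: float = 300.0

    def __post_init__(self) -> None:
        self.path = np.asarray(self.path, dtype=float)
        if self.path.ndim != 2 or self.path.shape[1] != 2 or len(self.path) < 2:
            raise ValueError("neurite path must be a (k>=2, 2) array")
        if self.width < 1:
            raise ValueError("neurite width must be >= 1 px")
        self.branches = [
            (int(i), np.asarray(b, dtype=float)) for i, b in self.branches
        ]
        for i, b in self.branches:
            # a branch anchored at a path terminus is a kink, not a junction
            if not (1 <= i <= len(self.path) - 2):
                raise ValueError("branch must attach at an interior path vertex")
            if b.ndim != 2 or b.shape[1] != 2 or len(b) < 2:
                raise ValueError("branch sub-polyline must be (k>=2, 2)")

    def arc_length(self) -> float:
        """Euclidean arc length of the main path plus all branches."""
        total = float(np.sum(np.linalg.norm(np.diff(self.path, axis=0), axis=1)))
        for _, b in self.branches:
            total += float(np.sum(np.linalg.norm(np.diff(b, axis=0), axis=1)))
        return total


@dataclass
class SceneGroundTruth:
    """Spec-derived morphometric truth for one scene (oracle for extraction)."""

    soma_count: int
    soma_area_px: int
    neurite_length_px: float
    neurite_area_px: int
    n_attachment: int
    n_ending: int
    n_branch: int

    def as_dict(self) -> dict:
        return {
            "soma_count": self.soma_count,
            "soma_area_px": self.soma_area_px,
            "neurite_length_px": self.neurite_length_px,
            "neurite_area_px": self.neurite_area_px,
            "n_attachment": self.n_attachment,
            "n_ending": self.n_ending,
            "n_branch": self.n_branch,
        }


def _default_soma_count_trend(x: float) -> float:
    # Quadratic arc in log-dose (rise then fall), scaled to ~8-17 per frame.
    return (-35.3 * x**2 + 80.4 * x + 219.3) / 15.0


def _default_neurites_per_soma_trend(x: float) -> float:
    return max(1.0, 2.6 - 0.5 * x)


def _default_neurite_length_trend(x: float) -> float:
    # Mean per-neurite stroke length in px; monotone decline with dose.
    return 85.0 - 20.0 * x


def _default_clustering_trend(x: float) -> float:
    return min(0.9, max(0.0, 0.2 * x))


@dataclass
class DoseSeriesConfig:
    """Conditions for a six-dose, 36-image-per-dose synthetic study.

    Trend functions map x = log10(dose), control dose 0 mapped to x = 0,
    to the per-image mean of each geometric parameter.  ``noise_cv`` is
    the coefficient of variation applied to those means per image.
    """

    doses: tuple[float, ...] = (0.0, 10.0, 50.0, 100.0, 200.0, 1000.0)
    images_per_dose: int = 36
    shape: tuple[int, int] = (512, 512)
    soma_count_trend: Callable[[float], float] = _default_soma_count_trend
    neurites_per_soma_trend: Callable[[float], float] = _default_neurites_per_soma_trend
    neurite_length_trend: Callable[[float], float] = _default_neurite_length_trend
    clustering_trend: Callable[[float], float] = _default_clustering_trend
    branch_prob: float = 0.45
    noise_cv: float = 0.15
    background_level: float = 80.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.doses) < 2 or any(
            b <= a for a, b in zip(self.doses, self.doses[1:])
        ):
            raise ValueError("doses must be strictly increasing")
        if self.images_per_dose < 1:
            raise ValueError("images_per_dose must be >= 1")


def log_dose(dose: float) -> float:
    """x = log10(dose in ng/mL); the 0-dose control maps to x = 0."""
    return 0.0 if dose <= 0 else math.log10(dose)


# ---------------------------------------------------------------------------
# rasterization


def _disk_pixels(center: tuple[float, float], radius: float, shape) -> tuple:
    """Brute-force rasterization: all integer pixels within ``radius``."""
    r0, c0 = center
    rmin = max(int(math.floor(r0 - radius)), 0)
    rmax = min(int(math.ceil(r0 + radius)), shape[0] - 1)
    cmin = max(int(math.floor(c0 - radius)), 0)
    cmax = min(int(math.ceil(c0 + radius)), shape[1] - 1)
    rr, cc = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
    keep = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    return rr[keep], cc[keep]


def _polyline_pixels(path: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bresenham rasterization of a polyline (integer-rounded vertices)."""
    verts = np.rint(path).astype(int)
    rows, cols = [], []
    for (r0, c0), (r1, c1) in zip(verts[:-1], verts[1:]):
        rr, cc = _bresenham_line(r0, c0, r1, c1)
        rows.append(rr)
        cols.append(cc)
    return np.concatenate(rows), np.concatenate(cols)


def _stroke_mask(neurite: NeuriteSpec, shape: tuple[int, int]) -> np.ndarray:
    """Binary stroke: Bresenham polyline dilated to the given width."""
    mask = np.zeros(shape, dtype=bool)
    polys = [neurite.path] + [b for _, b in neurite.branches]
    for poly in polys:
        rr, cc = _polyline_pixels(poly)
        mask[rr.clip(0, shape[0] - 1), cc.clip(0, shape[1] - 1)] = True
    radius = (neurite.width - 1) / 2.0
    if radius > 0:
        from scipy import ndimage as ndi

        # disk structuring element of radius floor(width/2)
        r = int(radius + 0.5)
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        selem = yy**2 + xx**2 <= r**2 + 1e-9
        mask = ndi.binary_dilation(mask, structure=selem)
    return mask


def _check_inside(somata, neurites, shape) -> None:
    h, w = shape
    for s in somata:
        r0, c0 = s.center
        if not (s.radius <= r0 <= h - 1 - s.radius and s.radius <= c0 <= w - 1 - s.radius):
            raise ValueError(f"soma at {s.center} (r={s.radius}) outside {shape} frame")
    for n in neurites:
        for poly in [n.path] + [b for _, b in n.branches]:
            if (
                poly[:, 0].min() < 0
                or poly[:, 1].min() < 0
                or poly[:, 0].max() > h - 1
                or poly[:, 1].max() > w - 1
            ):
                raise ValueError("neurite polyline outside frame")


def generate_scene(
    somata: Sequence[SomaSpec],
    neurites: Sequence[NeuriteSpec],
    shape: tuple[int, int] = (512, 512),
    background_level: float = 80.0,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> tuple[np.ndarray, SceneGroundTruth]:
    """Render a 16-bit grayscale scene and its spec-derived ground truth.

    Somata are filled disks at ``peak_intensity``; neurites are polyline
    strokes dilated to their width; additive Gaussian noise is clipped to
    the 16-bit range.  Ground truth comes from the input specifications:
    disk-union pixel counts for soma area, stroke-union (minus somata) for
    neurite area, Euclidean arc length for neurite length, and landmark
    counts straight from the polyline topology.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    for n in neurites:
        if not (0 <= n.attachment_soma < len(somata)):
            raise ValueError("neurite attachment_soma index out of range")
    _check_inside(somata, neurites, shape)

    rng = np.random.default_rng(seed)
    img = np.full(shape, float(background_level))

    soma_union = np.zeros(shape, dtype=bool)
    for s in somata:
        rr, cc = _disk_pixels(s.center, s.radius, shape)
        soma_union[rr, cc] = True

    neurite_union = np.zeros(shape, dtype=bool)
    for n in neurites:
        m = _stroke_mask(n, shape)
        neurite_union |= m
        img[m] = np.maximum(img[m], n.intensity)
    for s in somata:
        rr, cc = _disk_pixels(s.center, s.radius, shape)
        img[rr, cc] = np.maximum(img[rr, cc], s.peak_intensity)

    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=shape)
    img = np.clip(img, 0, 65535).astype(np.uint16)

    truth = SceneGroundTruth(
        soma_count=len(somata),
        soma_area_px=int(soma_union.sum()),
        neurite_length_px=float(sum(n.arc_length() for n in neurites)),
        neurite_area_px=int((neurite_union & ~soma_union).sum()),
        n_attachment=len(neurites),
        n_ending=sum(1 + len(n.branches) for n in neurites),
        n_branch=sum(len(n.branches) for n in neurites),
    )
    return img, truth


# ---------------------------------------------------------------------------
# random scene sampling


def _walk_path(
    start: np.ndarray,
    direction: float,
    length: float,
    rng: np.random.Generator,
    shape: tuple[int, int],
    wobble: float = 0.12,
    step: float = 12.0,
) -> np.ndarray:
    """Piecewise-linear path with small heading jitter, clipped to frame."""
    h, w = shape
    pts = [start.astype(float)]
    remaining = length
    theta = direction
    while remaining > 1e-6:
        seg = min(step, remaining)
        theta += rng.normal(0.0, wobble) if wobble > 0 else 0.0
        nxt = pts[-1] + seg * np.array([math.sin(theta), math.cos(theta)])
        if not (2 <= nxt[0] <= h - 3 and 2 <= nxt[1] <= w - 3):
            break
        pts.append(nxt)
        remaining -= seg
    if len(pts) < 2:  # degenerate: force a minimal straight stub inward
        center = np.array([h / 2, w / 2])
        d = center - pts[0]
        d /= np.linalg.norm(d) + 1e-9
        pts.append(pts[0] + 6.0 * d)
    return np.vstack(pts)


def sample_scene_specs(
    rng: np.random.Generator,
    shape: tuple[int, int] = (512, 512),
    soma_count: int = 12,
    neurites_per_soma: float = 2.0,
    neurite_length_mean: float = 70.0,
    branch_prob: float = 0.4,
    clustering_prob: float = 0.0,
    noise_cv: float = 0.15,
    separated: bool = False,
) -> tuple[list[SomaSpec], list[NeuriteSpec]]:
    """Sample soma/neurite geometry for one scene.

    With ``separated=True``, somata sit on a jittered grid and each
    neurite is a straight stroke confined to its cell, with one direction
    sector per neurite -- structures never touch, so every landmark count
    is exactly recoverable.  The default layout places somata by rejection
    sampling with a minimum separation; with probability
    ``clustering_prob`` a soma is planted overlapping a previous one, so
    disks merge into single connected components (soma clustering).
    """
    h, w = shape
    somata: list[SomaSpec] = []
    neurites: list[NeuriteSpec] = []

    if separated:
        cell = 128
        gr, gc = h // cell, w // cell
        cells = [(i, j) for i in range(gr) for j in range(gc)]
        rng.shuffle(cells)
        soma_count = min(soma_count, len(cells))
        occupied = np.zeros(shape, dtype=bool)
        from scipy import ndimage as ndi

        clearance = np.ones((5, 5), dtype=bool)  # 2-px stand-off between strokes
        for i, j in cells[:soma_count]:
            cr = i * cell + cell / 2 + rng.uniform(-8, 8)
            cc_ = j * cell + cell / 2 + rng.uniform(-8, 8)
            radius = rng.uniform(8, 12)
            somata.append(SomaSpec((cr, cc_), radius, peak_intensity=600.0))
            k = int(rng.integers(1, 4))
            sector = 2 * math.pi / k
            base = rng.uniform(0, 2 * math.pi)
            for q in range(k):
                theta = base + q * sector + rng.uniform(-0.05, 0.05) * sector
                d = np.array([math.sin(theta), math.cos(theta)])
                start = np.array([cr, cc_]) + radius * d
                length = rng.uniform(30, 52)
                end = start + length * d
                path = np.vstack([start, end])
                branches = []
                if rng.random() < branch_prob:
                    t = rng.uniform(0.45, 0.7)
                    joint = start + t * length * d
                    phi = theta + rng.choice([-1, 1]) * math.radians(42)
                    bd = np.array([math.sin(phi), math.cos(phi)])
                    blen = rng.uniform(14, 22)
                    branch = np.vstack([joint, joint + blen * bd])
                    path = np.vstack([start, joint, end])
                    branches = [(1, branch)]
                for attempt_branches in (branches, []):
                    try:
                        spec = NeuriteSpec(
                            attachment_soma=len(somata) - 1,
                            path=path if attempt_branches else np.vstack([start, end]),
                            branches=attempt_branches,
                            width=3,
                            intensity=300.0,
                        )
                        _check_inside([], [spec], shape)
                    except ValueError:
                        continue
                    stroke = _stroke_mask(spec, shape)
                    if (ndi.binary_dilation(stroke, structure=clearance) & occupied).any():
                        continue  # would touch an earlier stroke: try simpler/skip
                    occupied |= stroke
                    neurites.append(spec)
                    break
        return somata, neurites

    margin = 20
    attempts = 0
    while len(somata) < soma_count and attempts < soma_count * 80:
        attempts += 1
        radius = max(5.0, rng.normal(9.0, 1.5))
        is_cluster = bool(somata) and rng.random() < clustering_prob
        if is_cluster:
            host = somata[int(rng.integers(len(somata)))]
            ang = rng.uniform(0, 2 * math.pi)
            dist = (host.radius + radius) * rng.uniform(0.4, 0.8)
            center = (
                host.center[0] + dist * math.sin(ang),
                host.center[1] + dist * math.cos(ang),
            )
        else:
            center = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
        if not (
            radius + 1 <= center[0] <= h - 2 - radius
            and radius + 1 <= center[1] <= w - 2 - radius
        ):
            continue
        if not is_cluster:
            # somata either overlap deliberately (clustering) or stay apart
            too_close = any(
                math.hypot(center[0] - s.center[0], center[1] - s.center[1])
                < radius + s.radius + 6
                for s in somata
            )
            if too_close:
                continue
        somata.append(SomaSpec(center, radius, peak_intensity=600.0))

    for idx, s in enumerate(somata):
        k = max(0, int(round(rng.normal(neurites_per_soma, noise_cv * max(neurites_per_soma, 1)))))
        for _ in range(k):
            theta = rng.uniform(0, 2 * math.pi)
            d = np.array([math.sin(theta), math.cos(theta)])
            start = np.array(s.center) + s.radius * d
            if not (2 <= start[0] <= h - 3 and 2 <= start[1] <= w - 3):
                continue
            length = max(12.0, rng.normal(neurite_length_mean, noise_cv * neurite_length_mean))
            path = _walk_path(start, theta, length, rng, shape)
            branches = []
            if rng.random() < branch_prob and len(path) >= 3:
                bi = int(rng.integers(1, len(path) - 1))
                seg = path[min(bi + 1, len(path) - 1)] - path[bi]
                base_theta = math.atan2(seg[0], seg[1])
                phi = base_theta + rng.choice([-1, 1]) * math.radians(50)
                blen = max(10.0, 0.4 * length)
                bpath = _walk_path(path[bi], phi, blen, rng, shape)
                if len(bpath) >= 2:
                    branches.append((bi, bpath))
            neurites.append(
                NeuriteSpec(
                    attachment_soma=idx,
                    path=path,
                    branches=branches,
                    width=3,
                    intensity=300.0,
                )
            )
    return somata, neurites


def generate_dose_series(
    config: DoseSeriesConfig,
) -> list[tuple[np.ndarray, SceneGroundTruth, float]]:
    """Generate ``images_per_dose x len(doses)`` labelled scenes.

    Deterministic for a fixed ``config.seed``.  Per-image geometric
    parameters are drawn around the trend-function means with coefficient
    of variation ``noise_cv`` (zero CV gives every image of a class the
    trend mean exactly).
    """
    rng = np.random.default_rng(config.seed)
    records: list[tuple[np.ndarray, SceneGroundTruth, float]] = []
    for dose in config.doses:
        x = log_dose(dose)
        mean_count = config.soma_count_trend(x)
        mean_npn = config.neurites_per_soma_trend(x)
        mean_len = config.neurite_length_trend(x)
        p_clust = config.clustering_trend(x)
        for _ in range(config.images_per_dose):
            cv = config.noise_cv
            count = max(1, int(round(rng.normal(mean_count, cv * mean_count) if cv > 0 else mean_count)))
            npn = max(0.0, rng.normal(mean_npn, cv * mean_npn) if cv > 0 else mean_npn)
            nlen = max(10.0, rng.normal(mean_len, cv * mean_len) if cv > 0 else mean_len)
            somata, neurites = sample_scene_specs(
                rng,
                shape=config.shape,
                soma_count=count,
                neurites_per_soma=npn,
                neurite_length_mean=nlen,
                branch_prob=config.branch_prob,
                clustering_prob=p_clust,
                noise_cv=cv,
            )
            img, truth = generate_scene(
                somata,
                neurites,
                shape=config.shape,
                background_level=config.background_level,
                noise_sd=config.noise_sd,
                seed=int(rng.integers(2**31)),
            )
            records.append((img, truth, dose))
    return records


def write_dataset(
    records: Sequence[tuple[np.ndarray, SceneGroundTruth, float]],
    outdir: str | Path,
    provenance: dict | None = None,
) -> Path:
    """Write scenes as 16-bit TIFFs plus a CSV manifest; returns manifest path."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}: {val}\n")
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for i, (img, truth, dose) in enumerate(records):
            name = f"scene_{i:04d}_dose{dose:g}.tif"
            tifffile.imwrite(outdir / name, img)
            t = truth.as_dict()
            writer.writerow(
                [
                    name,
                    dose,
                    t["soma_count"],
                    t["soma_area_px"],
                    f"{t['neurite_length_px']:.3f}",
                    t["neurite_area_px"],
                    t["n_attachment"],
                    t["n_ending"],
                    t["n_branch"],
                ]
            )
    return manifest
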