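"""Synthetic TEM-like micrographs and qPCR plates with analytic ground truth.

Mitochondria in transmission electron micrographs appear as dark (electron
dense) roughly elliptical profiles on a brighter, textured cytoplasmic
background.  This module plants ellipses with exactly known geometry into
images that carry the nuisance structure the real pipeline must cope with —
slow illumination gradients, additive noise, vertical scan-line stripes and,
optionally, a large high-contrast membrane band that region-of-interest
polygons are expected to exclude.  Because every particle's area, perimeter,
Feret diameter and axis ratio are known analytically, the full segmentation
and morphometry chain can be validated without any external data.

A companion generator produces qPCR Ct plates (triplicate technical
replicates per gene/sample) with known fold changes and optional injected
replicate outliers, for testing the relative-expression module.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ParticleSpec",
    "SceneSpec",
    "CtTableSpec",
    "ellipse_perimeter",
    "particle_ground_truth",
    "render_scene",
    "generate_experiment",
    "render_experiment",
    "generate_ct_table",
    "scene_roi_polygons",
]

# Default scene geometry.  256 px square 8-bit frames keep the full chain fast
# while leaving every planted particle comfortably above the 600 px analysis
# floor (control semi-major axes 22-30 px; see generate_experiment).
DEFAULT_WIDTH = 256
DEFAULT_HEIGHT = 256
DEFAULT_BIT_DEPTH = 8
BACKGROUND_LEVEL = 0.78     # fraction of dynamic range
MEMBRANE_LEVEL = 0.08       # dark, high-contrast band
MEMBRANE_WIDTH = 22         # px, along the top edge
# Gap between the membrane band and the ROI polygon.  Manual ROIs exclude the
# membrane together with its high-contrast surroundings; the synthetic ROI
# stays clear of the band's filter-scale halo (the bandpass kernel extends
# ~half the large-structure cut, 60 px, beyond any sharp edge).
MEMBRANE_MARGIN = 40
_SUPERSAMPLE = 4            # anti-aliasing subpixel grid (per axis)
_MAX_PLACEMENT_TRIES = 1000


@dataclass(frozen=True)
class ParticleSpec:
    """One planted elliptical particle.

    center is (x, y) in pixel coordinates; ``a`` and ``b`` are the semi-major
    and semi-minor axes in px (a >= b > 0); ``theta`` the major-axis
    orientation in radians; ``intensity`` the particle gray level as a
    fraction of the dynamic range (dark-on-bright TEM polarity, so it should
    be well below the background level).
    """

    center: tuple[float, float]
    a: float
    b: float
    theta: float = 0.0
    intensity: float = 0.3

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError(f"require a >= b > 0, got a={self.a}, b={self.b}")
        if not (0.0 <= self.intensity <= 1.0):
            raise ValueError("intensity must be a fraction of dynamic range")


@dataclass(frozen=True)
class SceneSpec:
    """Parametric description of one synthetic micrograph."""

    width: int = DEFAULT_WIDTH
    height: int = DEFAULT_HEIGHT
    bit_depth: int = 8
    particles: tuple[ParticleSpec, ...] = ()
    gradient_amplitude: float = 0.08    # fraction of dynamic range, corner-to-corner
    noise_sd: float = 0.03              # fraction of dynamic range
    stripe_amplitude: float = 0.0       # fraction of dynamic range
    stripe_period: float = 12.0         # px, vertical stripes (intensity varies with x)
    membrane_band: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.stripe_period <= 0:
            raise ValueError("stripe_period must be > 0")
        if self.width < 8 or self.height < 8:
            raise ValueError("scene too small")
        object.__setattr__(self, "particles", tuple(self.particles))
        for p in self.particles:
            self._check_inside(p)

    def _check_inside(self, p: ParticleSpec) -> None:
        x, y = p.center
        if not (p.a <= x <= self.width - 1 - p.a and p.a <= y <= self.height - 1 - p.a):
            raise ValueError(
                f"particle at {p.center} with a={p.a} extends outside the "
                f"{self.width}x{self.height} frame"
            )

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1


def ellipse_perimeter(a: float, b: float) -> float:
    """Ellipse circumference by Ramanujan's second approximation.

    Relative error is below 1e-6 for aspect ratios up to ~10, far inside the
    pixelation noise of any digital measurement.
    """
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


def particle_ground_truth(p: ParticleSpec) -> dict[str, float]:
    """Analytic morphology of one planted ellipse.

    Mirrors the measured parameter set: area (px^2), perimeter (px), full
    major/minor axes (px), Feret diameter (= major axis), aspect ratio,
    circularity 4*pi*A/P^2, roundness 4A/(pi*major^2) (= b/a for an ellipse),
    form factor P^2/(4*pi*A) and squared area.
    """
    area = math.pi * p.a * p.b
    perim = ellipse_perimeter(p.a, p.b)
    circ = 4.0 * math.pi * area / perim**2
    return {
        "x": p.center[0],
        "y": p.center[1],
        "area": area,
        "area_sq": area**2,
        "perimeter": perim,
        "major": 2.0 * p.a,
        "minor": 2.0 * p.b,
        "feret": 2.0 * p.a,
        "aspect_ratio": p.a / p.b,
        "circularity": min(1.0, circ),
        "roundness": p.b / p.a,
        "form_factor": perim**2 / (4.0 * math.pi * area),
    }


def _coverage(spec: SceneSpec, p: ParticleSpec) -> tuple[slice, slice, np.ndarray]:
    """Anti-aliased pixel coverage of an ellipse, restricted to its bbox.

    Each pixel is subdivided into a _SUPERSAMPLE^2 grid of sample points at
    subpixel centers; coverage is the fraction of samples inside the ellipse.
    Pixel-counted area therefore converges to the analytic area.
    """
    x0, y0 = p.center
    r = p.a + 1.5
    c0 = max(int(math.floor(x0 - r)), 0)
    c1 = min(int(math.ceil(x0 + r)) + 1, spec.width)
    r0 = max(int(math.floor(y0 - r)), 0)
    r1 = min(int(math.ceil(y0 + r)) + 1, spec.height)
    n = _SUPERSAMPLE
    # subpixel sample coordinates relative to pixel index
    off = (np.arange(n) + 0.5) / n - 0.5
    xs = (np.arange(c0, c1)[:, None] + off[None, :]).ravel()   # (W*n,)
    ys = (np.arange(r0, r1)[:, None] + off[None, :]).ravel()   # (H*n,)
    dx = xs[None, :] - x0
    dy = ys[:, None] - y0
    ct, st = math.cos(p.theta), math.sin(p.theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / p.a) ** 2 + (v / p.b) ** 2 <= 1.0
    cov = inside.reshape(r1 - r0, n, c1 - c0, n).mean(axis=(1, 3))
    return slice(r0, r1), slice(c0, c1), cov


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Rasterize a scene; return the image and the ground-truth table.

    The image is uint8/uint16 per ``spec.bit_depth``.  Ground-truth rows align
    1:1 (in order) with ``spec.particles``.  Determinism: identical specs
    produce byte-identical rasters.
    """
    rng = np.random.default_rng(spec.seed)
    maxv = float(spec.max_value)
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w]

    img = np.full((h, w), BACKGROUND_LEVEL * maxv, dtype=np.float64)
    img += spec.gradient_amplitude * maxv * (xx + yy) / (w + h)
    if spec.stripe_amplitude:
        img += spec.stripe_amplitude * maxv * np.sin(2.0 * np.pi * xx / spec.stripe_period)
    if spec.membrane_band:
        img[:MEMBRANE_WIDTH, :] = MEMBRANE_LEVEL * maxv

    for p in spec.particles:
        rs, cs, cov = _coverage(spec, p)
        level = p.intensity * maxv
        img[rs, cs] = img[rs, cs] * (1.0 - cov) + level * cov

    if spec.noise_sd:
        img += rng.normal(0.0, spec.noise_sd * maxv, size=img.shape)

    img = np.clip(np.round(img), 0, maxv)
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    gt = pd.DataFrame([particle_ground_truth(p) for p in spec.particles])
    return img.astype(dtype), gt


def scene_roi_polygons(spec: SceneSpec) -> list[np.ndarray]:
    """Analysis ROI for a scene: the whole frame, minus any membrane band.

    Returns a list of (N, 2) float arrays of (x, y) polygon vertices, the
    format consumed by :func:`mitomorph.morphometry.apply_roi`.
    """
    y_top = MEMBRANE_WIDTH + MEMBRANE_MARGIN if spec.membrane_band else 0
    w, h = spec.width, spec.height
    poly = np.array(
        [[0.0, float(y_top)], [w - 1.0, float(y_top)], [w - 1.0, h - 1.0], [0.0, h - 1.0]]
    )
    return [poly]


# ---------------------------------------------------------------------------
# Multi-condition experiments
# ---------------------------------------------------------------------------

#: Study-like defaults for per-cell scenes: semi-major axis range (px) and
#: shape ratio b/a range of control-condition particles.  With these, every
#: control particle area lies in [pi*22*14.3, pi*30*28.5] ~ [988, 2686] px^2,
#: above the 600 px analysis floor even after a 30% treated-area reduction.
CONTROL_A_RANGE = (22.0, 30.0)
SHAPE_RATIO_RANGE = (0.65, 0.95)
PARTICLES_PER_CELL = 5


def _place_particles(
    rng: np.random.Generator,
    spec_kw: dict,
    n: int,
    a_range: tuple[float, float],
    ratio_range: tuple[float, float],
    intensity: float = 0.3,
) -> list[ParticleSpec]:
    """Rejection-sample non-overlapping particles inside the frame."""
    w = spec_kw.get("width", DEFAULT_WIDTH)
    h = spec_kw.get("height", DEFAULT_HEIGHT)
    y_min = MEMBRANE_WIDTH + MEMBRANE_MARGIN if spec_kw.get("membrane_band") else 0
    placed: list[ParticleSpec] = []
    for _ in range(n):
        for attempt in range(_MAX_PLACEMENT_TRIES):
            a = rng.uniform(*a_range)
            b = a * rng.uniform(*ratio_range)
            theta = rng.uniform(0.0, np.pi)
            x = rng.uniform(a + 1, w - 2 - a)
            y = rng.uniform(max(a + 1, y_min + a + 1), h - 2 - a)
            ok = all(
                math.hypot(x - q.center[0], y - q.center[1]) > a + q.a + 2.0
                for q in placed
            )
            if ok:
                placed.append(ParticleSpec((x, y), a, b, theta, intensity))
                break
        else:
            raise RuntimeError(
                f"could not place particle {len(placed) + 1}/{n} without overlap "
                f"after {_MAX_PLACEMENT_TRIES} tries"
            )
    return placed


def generate_experiment(
    n_cells_per_condition: int,
    size_shift: float,
    seed: int,
    *,
    conditions: tuple[str, str] = ("control", "treated"),
    n_particles: int = PARTICLES_PER_CELL,
    membrane_prob: float = 0.2,
    noise_sd: float = 0.03,
    stripe_amplitude: float = 0.04,
    width: int = DEFAULT_WIDTH,
    height: int = DEFAULT_HEIGHT,
) -> list[dict]:
    """Specify a two-condition experiment of per-cell scenes.

    One scene is one cell (the statistical unit).  The treated condition draws
    semi-axes scaled by sqrt(1 - size_shift), so its expected particle area is
    (1 - size_shift) times the control's.  Per-image seeds are derived
    deterministically from the master seed, so the same master seed always
    yields the same experiment.

    Returns a list of records ``{"condition", "cell_id", "scene": SceneSpec,
    "ground_truth": DataFrame}``; call :func:`render_scene` (or
    :func:`render_experiment`) to rasterize.
    """
    if n_cells_per_condition < 2:
        raise ValueError("need at least 2 cells per condition")
    if not (0.0 <= size_shift < 1.0):
        raise ValueError("size_shift must be in [0, 1)")
    scale = math.sqrt(1.0 - size_shift)
    records: list[dict] = []
    idx = 0
    for cond_i, cond in enumerate(conditions):
        s = scale if cond_i else 1.0
        a_range = (CONTROL_A_RANGE[0] * s, CONTROL_A_RANGE[1] * s)
        for cell in range(n_cells_per_condition):
            # independent, reproducible stream per image
            ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(idx,))
            rng = np.random.default_rng(ss)
            membrane = bool(rng.random() < membrane_prob)
            kw = dict(width=width, height=height, membrane_band=membrane)
            particles = _place_particles(rng, kw, n_particles, a_range, SHAPE_RATIO_RANGE)
            scene = SceneSpec(
                width=width,
                height=height,
                particles=tuple(particles),
                noise_sd=noise_sd,
                stripe_amplitude=stripe_amplitude,
                membrane_band=membrane,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            gt = pd.DataFrame([particle_ground_truth(p) for p in particles])
            gt["condition"] = cond
            gt["cell_id"] = f"{cond}_cell{cell:03d}"
            records.append(
                {
                    "condition": cond,
                    "cell_id": f"{cond}_cell{cell:03d}",
                    "scene": scene,
                    "ground_truth": gt,
                }
            )
            idx += 1
    return records


def render_experiment(records: list[dict]) -> list[dict]:
    """Rasterize every scene of :func:`generate_experiment` in place.

    Adds ``"image"`` (ndarray) and ``"rois"`` (polygon list) keys.
    """
    for rec in records:
        img, _ = render_scene(rec["scene"])
        rec["image"] = img
        rec["rois"] = scene_roi_polygons(rec["scene"])
    return records


# ---------------------------------------------------------------------------
# qPCR Ct plates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CtTableSpec:
    """Specification of a synthetic qPCR plate.

    ``delta_ct`` maps gene -> condition -> true mean (Ct_target - Ct_reference)
    in cycles; the reference gene runs at ``reference_ct`` in every condition.
    ``outlier_rate`` is the per-triplicate probability that exactly one of the
    three technical replicates is displaced by ``outlier_magnitude`` cycles.
    """

    genes: tuple[str, ...]
    conditions: tuple[str, ...]
    delta_ct: dict = field(default_factory=dict)   # gene -> {condition: cycles}
    samples_per_condition: int = 3
    reference_gene: str = "B2M"
    reference_ct: float = 18.0
    noise_sd: float = 0.1
    outlier_rate: float = 0.0
    outlier_magnitude: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "conditions", tuple(self.conditions))
        if self.samples_per_condition < 1:
            raise ValueError("need at least one sample per condition")
        for g in self.genes:
            if g not in self.delta_ct:
                raise ValueError(f"missing delta_ct entry for gene {g!r}")
            for c in self.conditions:
                if c not in self.delta_ct[g]:
                    raise ValueError(f"missing delta_ct[{g!r}][{c!r}]")


def generate_ct_table(spec: CtTableSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a long-format Ct table and its ground truth.

    Returns ``(table, truth)`` where ``table`` has columns (gene, sample,
    condition, replicate, ct) — three technical replicates per gene/sample,
    reference gene included — and ``truth`` has one row per target
    gene x non-control condition with the expected ΔΔCt and fold change
    2^-ΔΔCt relative to the first condition in ``spec.conditions``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    control = spec.conditions[0]
    all_genes = list(spec.genes)
    if spec.reference_gene not in all_genes:
        all_genes.append(spec.reference_gene)
    for cond in spec.conditions:
        for s in range(spec.samples_per_condition):
            sample = f"{cond}_s{s + 1}"
            for gene in all_genes:
                if gene == spec.reference_gene:
                    mean_ct = spec.reference_ct
                else:
                    mean_ct = spec.reference_ct + spec.delta_ct[gene][cond]
                cts = mean_ct + rng.normal(0.0, spec.noise_sd, size=3)
                if spec.outlier_rate and rng.random() < spec.outlier_rate:
                    j = int(rng.integers(0, 3))
                    cts[j] += spec.outlier_magnitude
                for r, ct in enumerate(cts):
                    rows.append(
                        {
                            "gene": gene,
                            "sample": sample,
                            "condition": cond,
                            "replicate": r + 1,
                            "ct": float(ct),
                        }
                    )
    table = pd.DataFrame(rows)
    truth_rows = []
    for gene in spec.genes:
        for cond in spec.conditions[1:]:
            ddct = spec.delta_ct[gene][cond] - spec.delta_ct[gene][control]
            truth_rows.append(
                {
                    "gene": gene,
                    "condition": cond,
                    "ddct": ddct,
                    "fold_change": 2.0 ** (-ddct),
                }
            )
    return table, pd.DataFrame(truth_rows)


def scene_to_dict(spec: SceneSpec) -> dict:
    """Plain-dict form of a SceneSpec (for YAML/JSON round-tripping)."""
    d = dataclasses.asdict(spec)
    d["particles"] = [dataclasses.asdict(p) for p in spec.particles]
    return d


def scene_from_dict(d: dict) -> SceneSpec:
    d = dict(d)
    d["particles"] = tuple(
        ParticleSpec(tuple(p["center"]), p["a"], p["b"], p["theta"], p["intensity"])
        for p in d.get("particles", [])
    )
    return SceneSpec(**d)
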