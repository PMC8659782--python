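"""Synthetic grade-labeled root images and planted-signal feature tables.

No public image corpus of graded taproots exists, so every downstream stage
is exercised on synthetic specimens instead. The image generator emulates the properties the
four commercial grades actually differ in — projected size, outline
irregularity (lobedness), surface color, and surface texture — as a lobed
star-convex blob on a bright uniform background, bright enough relative to the
root that Otsu thresholding is well posed. The table generator plants a known
informative/noise split so the feature-selection algorithms can be scored
against ground truth.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .exceptions import SpecError
from .grading import DEFAULT_GRADING, GRADES, GradingSpec, assign_grade, grade_to_code

__all__ = [
    "SyntheticImageSpec",
    "PlantedTableSpec",
    "SyntheticImage",
    "generate_root_image",
    "generate_image_dataset",
    "generate_feature_table",
    "write_image_dataset",
]


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Parameters of the synthetic root renderer.

    Per-grade tuples are ordered grade I..IV. Sizes are in pixels on an 8-bit
    canvas; colors are RGB triples in [0, 255]. Grade I roots are rendered
    largest and smoothest, grade IV smallest and most lobed, mirroring how the
    grades differ jointly in size, shape irregularity, color, and texture.
    """

    canvas: int = 256
    #: mean major-axis length per grade (px); must strictly decrease I -> IV
    axis_mean: tuple[float, float, float, float] = (150.0, 122.0, 96.0, 74.0)
    axis_sd: float = 12.0
    #: minor/major aspect-ratio range shared by all grades
    aspect_range: tuple[float, float] = (0.55, 0.85)
    #: inclusive lobe-count range per grade (shape irregularity)
    lobes: tuple[tuple[int, int], ...] = ((3, 4), (4, 6), (5, 7), (6, 9))
    #: relative radial lobe amplitude per grade
    lobe_amp: tuple[float, ...] = (0.06, 0.08, 0.10, 0.13)
    #: surface base color per grade (RGB)
    base_color: tuple[tuple[float, float, float], ...] = (
        (152.0, 122.0, 88.0),
        (136.0, 106.0, 74.0),
        (121.0, 92.0, 66.0),
        (108.0, 82.0, 58.0),
    )
    #: per-grade iid channel noise scale (intensity units)
    color_noise: tuple[float, ...] = (6.0, 6.0, 7.0, 8.0)
    #: per-grade amplitude of the sinusoidal surface banding (intensity units)
    texture_amp: tuple[float, ...] = (6.0, 10.0, 14.0, 18.0)
    #: per-grade spatial frequency of the banding (cycles per px)
    texture_freq: tuple[float, ...] = (0.04, 0.07, 0.11, 0.16)
    background: int = 230
    grading: GradingSpec = field(default_factory=GradingSpec)

    def __post_init__(self) -> None:
        if self.canvas < 128:
            raise SpecError("canvas must be at least 128 px")
        means = self.axis_mean
        if not all(a > b for a, b in zip(means, means[1:])):
            raise SpecError("axis_mean must strictly decrease grade I -> IV")
        positive = (
            (self.axis_sd,)
            + self.lobe_amp
            + self.color_noise
            + self.texture_amp
            + self.texture_freq
        )
        if any(v <= 0 for v in positive):
            raise SpecError("all scale parameters must be positive")


@dataclass(frozen=True)
class PlantedTableSpec:
    """Parameters of the planted-signal feature-table generator.

    Each informative column is a noisy linear encoding of the numeric grade
    code (1..n_classes): ``X[:, j] = code * a_j + noise_sd * eps``. Noise
    columns are independent Gaussian draws carrying no label information.
    With ``noise_sd = 0`` any single informative column determines the label
    exactly (the label is a linear function of it), which pins down the
    ground truth that selection algorithms are scored against.
    """

    n_samples: int = 200
    n_informative: int = 5
    n_noise: int = 35
    noise_sd: float = 0.5
    n_classes: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative + self.n_noise < 1:
            raise SpecError("need at least one feature column")
        if self.n_samples < 4 * self.n_classes:
            raise SpecError("sample count must be at least 4 x class count")


@dataclass(frozen=True)
class SyntheticImage:
    """One rendered specimen with its ground truth."""

    image: np.ndarray  # H x W x 3 uint8
    mask: np.ndarray  # H x W bool, True on the root
    grade: str
    weight_g: float
    seed: int


def _radial_profile(phi: np.ndarray, a: float, b: float, exponent: float,
                    n_lobes: int, amp: float, phase: float) -> np.ndarray:
    """Superellipse radius with sinusoidal lobes, as a function of angle."""
    c = np.abs(np.cos(phi)) / (a / 2.0)
    s = np.abs(np.sin(phi)) / (b / 2.0)
    r0 = (c**exponent + s**exponent) ** (-1.0 / exponent)
    return r0 * (1.0 + amp * np.cos(n_lobes * phi + phase))


def generate_root_image(
    spec: SyntheticImageSpec, grade: str, seed: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """Render one synthetic taproot of the requested grade.

    Returns ``(rgb_image, foreground_mask, weight_g)`` where the weight is
    drawn uniformly inside the grade's weight interval so that
    ``assign_grade(weight_g) == grade``. Identical ``(spec, grade, seed)``
    yield bit-identical output.
    """
    if grade not in GRADES:
        raise SpecError(f"unknown grade {grade!r}")
    g = GRADES.index(grade)
    rng = np.random.default_rng(seed)

    a = float(np.clip(rng.normal(spec.axis_mean[g], spec.axis_sd),
                      0.5 * spec.axis_mean[g], 1.5 * spec.axis_mean[g]))
    b = a * rng.uniform(*spec.aspect_range)
    exponent = rng.uniform(2.0, 3.0)
    lo, hi = spec.lobes[g]
    n_lobes = int(rng.integers(lo, hi + 1))
    amp = spec.lobe_amp[g]
    phase = rng.uniform(0.0, 2.0 * np.pi)
    theta0 = rng.uniform(0.0, np.pi)
    center = spec.canvas / 2.0 + rng.uniform(-4.0, 4.0, size=2)

    max_r = (a / 2.0) * (1.0 + amp)
    if max_r > spec.canvas / 2.0 - 4.0:
        raise SpecError(
            f"blob radius {max_r:.1f} px exceeds canvas {spec.canvas} px"
        )

    yy, xx = np.mgrid[0 : spec.canvas, 0 : spec.canvas]
    dy = yy - center[0]
    dx = xx - center[1]
    phi = np.arctan2(dy, dx) - theta0
    r = np.hypot(dy, dx)
    mask = r <= _radial_profile(phi, a, b, exponent, n_lobes, amp, phase)

    # surface banding: one dominant oriented sinusoid plus a weaker harmonic
    alpha = rng.uniform(0.0, np.pi)
    ph2, ph3 = rng.uniform(0.0, 2.0 * np.pi, size=2)
    f = spec.texture_freq[g]
    u = xx * np.cos(alpha) + yy * np.sin(alpha)
    v = -xx * np.sin(alpha) + yy * np.cos(alpha)
    band = np.sin(2.0 * np.pi * f * u + ph2) + 0.5 * np.sin(
        2.0 * np.pi * 1.7 * f * v + ph3
    )

    img = np.full((spec.canvas, spec.canvas, 3), float(spec.background))
    n_fg = int(mask.sum())
    for ch in range(3):
        vals = (
            spec.base_color[g][ch]
            + spec.texture_amp[g] * band[mask]
            + rng.normal(0.0, spec.color_noise[g], size=n_fg)
        )
        img[mask, ch] = vals
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    low, high = spec.grading.weight_interval(grade)
    weight = float(rng.uniform(low, high))
    assert assign_grade(weight, spec.grading) == grade
    return img, mask, weight


def generate_image_dataset(
    spec: SyntheticImageSpec, n_per_grade: int, seed: int
) -> list[SyntheticImage]:
    """Render a balanced labeled dataset: ``4 * n_per_grade`` specimens.

    Per-image seeds are drawn once from a master generator, so the label
    sequence and every image are reproducible from ``seed`` alone.
    """
    if n_per_grade < 1:
        raise SpecError("n_per_grade must be >= 1")
    master = np.random.default_rng(seed)
    sub_seeds = master.integers(0, 2**31 - 1, size=4 * n_per_grade)
    records: list[SyntheticImage] = []
    i = 0
    for grade in GRADES:
        for _ in range(n_per_grade):
            s = int(sub_seeds[i])
            img, mask, w = generate_root_image(spec, grade, s)
            records.append(SyntheticImage(img, mask, grade, w, s))
            i += 1
    return records


def write_image_dataset(records: list[SyntheticImage], out_dir: str | Path) -> Path:
    """Write PNG images + masks and a CSV manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "grade", "weight_g", "seed"])
        for k, rec in enumerate(records):
            name = f"root_{k:04d}_{rec.grade}.png"
            Image.fromarray(rec.image).save(out / name)
            Image.fromarray((rec.mask * np.uint8(255))).save(
                out / name.replace(".png", "_mask.png")
            )
            writer.writerow([name, rec.grade, f"{rec.weight_g:.4f}", rec.seed])
    return manifest


def generate_feature_table(spec: PlantedTableSpec) -> pd.DataFrame:
    """Build a planted-signal feature table.

    Returns a DataFrame with ``n_informative`` columns named ``inf01..`` that
    carry the label signal, ``n_noise`` columns named ``noise01..`` that do
    not, and a ``grade`` label column. Ground-truth informative names are
    recorded in ``df.attrs["informative"]``.
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_samples, spec.n_classes
    codes = np.arange(n) % k + 1  # balanced 1..k
    rng.shuffle(codes)

    cols: dict[str, np.ndarray] = {}
    loadings = rng.uniform(0.8, 1.2, size=spec.n_informative)
    for j in range(spec.n_informative):
        eps = rng.normal(0.0, 1.0, size=n)
        cols[f"inf{j + 1:02d}"] = codes * loadings[j] + spec.noise_sd * eps
    for j in range(spec.n_noise):
        cols[f"noise{j + 1:02d}"] = rng.normal(2.5, 1.2, size=n)

    if k == 4:
        labels = [GRADES[c - 1] for c in codes]
    else:
        labels = [f"C{c}" for c in codes]
    df = pd.DataFrame(cols)
    df["grade"] = labels
    df.attrs["informative"] = [f"inf{j + 1:02d}" for j in range(spec.n_informative)]
    return df
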