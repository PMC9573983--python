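"""Colour conversion and scoring-chart reliability.

Objective shrimp colour is recorded as per-pixel RGB and expressed in
CIE L*a*b* (1976): ``L*`` lightness 0-100, ``a*`` red-green, ``b*``
yellow-blue.  Conversion follows sRGB (IEC 61966-2-1 gamma decoding),
the D65 reference white and the 2 degree standard observer.

Subjective colour scoring against a reference chart is assessed by the
confusion matrix of two scoring replicates of the same images and by
repeatability, the Pearson correlation of the paired category codes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LabColor",
    "ScoreChart",
    "ConfusionMatrix",
    "UNCOOKED_CHART",
    "COOKED_CHART",
    "rgb_to_lab",
    "summarize_pixels",
    "confusion_matrix",
    "repeatability",
    "format_confusion_matrix",
    "read_pixel_csv",
]

# sRGB -> XYZ (D65, 2 deg observer), IEC 61966-2-1
_M_RGB_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_WHITE_D65 = np.array([0.95047, 1.0, 1.08883])
_DELTA = 6.0 / 29.0


@dataclass(frozen=True)
class LabColor:
    """A CIE L*a*b* triple; L in [0, 100] for any valid sRGB input."""

    L: float
    a: float
    b: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.L, self.a, self.b)


@dataclass(frozen=True)
class ScoreChart:
    """An ordinal colour-scoring chart with categories coded 1..c."""

    name: str
    n_categories: int
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        if self.n_categories < 2:
            raise ValueError("a score chart needs at least 2 categories")
        if self.labels and len(self.labels) != self.n_categories:
            raise ValueError("labels must match n_categories")

    @property
    def categories(self) -> list[int]:
        return list(range(1, self.n_categories + 1))


#: 4-point chart for uncooked shrimp (1 = lightest/pale, 4 = darkest).
UNCOOKED_CHART = ScoreChart(
    "uncooked", 4, ("light", "black-1", "black-2", "black-3")
)
#: 3-point chart for cooked shrimp (1 = light orange, 3 = bright orange).
COOKED_CHART = ScoreChart(
    "cooked", 3, ("light orange", "medium orange", "bright orange")
)


@dataclass
class ConfusionMatrix:
    """Cross-tabulation of two scoring replicates of the same images."""

    categories: list[int]
    counts: np.ndarray  # rows = replicate A, cols = replicate B

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        c = len(self.categories)
        if self.counts.shape != (c, c):
            raise ValueError("counts must be c x c")
        if (self.counts < 0).any():
            raise ValueError("negative count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def expand_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Reconstruct the per-image (score_a, score_b) pair list."""
        a, b = [], []
        cats = self.categories
        for i, ci in enumerate(cats):
            for j, cj in enumerate(cats):
                n = int(self.counts[i, j])
                a.extend([ci] * n)
                b.extend([cj] * n)
        return np.asarray(a, dtype=float), np.asarray(b, dtype=float)


def _srgb_to_linear(channels: np.ndarray) -> np.ndarray:
    c = channels / 255.0
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def _f_lab(t: np.ndarray) -> np.ndarray:
    return np.where(t > _DELTA**3, np.cbrt(t), t / (3 * _DELTA**2) + 4.0 / 29.0)


def _rgb_array_to_lab(rgb: np.ndarray) -> np.ndarray:
    """Vectorised sRGB (0-255) -> Lab over the last axis of length 3."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape[-1] != 3:
        raise ValueError("last axis must hold (r, g, b)")
    if (rgb < 0).any() or (rgb > 255).any():
        raise ValueError("RGB channels must lie in [0, 255]")
    xyz = _srgb_to_linear(rgb) @ _M_RGB_XYZ.T
    f = _f_lab(xyz / _WHITE_D65)
    # the standard conversion matrix rows sum to the white point only to
    # ~1e-7, so clamp the guaranteed-range axis
    L = np.clip(116.0 * f[..., 1] - 16.0, 0.0, 100.0)
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def rgb_to_lab(r: int, g: int, b: int) -> LabColor:
    """Convert one sRGB pixel (integer channels 0-255) to CIE L*a*b*."""
    lab = _rgb_array_to_lab(np.array([r, g, b], dtype=float))
    return LabColor(*map(float, lab))


def summarize_pixels(
    pixels: Sequence[Sequence[float]] | np.ndarray,
    mask: Sequence[bool] | None = None,
) -> LabColor:
    """Per-animal colour summary: mean of per-pixel Lab values.

    Each retained pixel is converted to Lab and the arithmetic mean is
    taken per axis (averaging in the perceptual space, not mean RGB
    then convert).
    """
    px = np.asarray(pixels, dtype=float)
    if px.ndim != 2 or px.shape[1] != 3:
        raise ValueError("pixels must be an (n, 3) array of RGB triples")
    if mask is not None:
        px = px[np.asarray(mask, dtype=bool)]
    if px.shape[0] == 0:
        raise ValueError("no pixels retained")
    lab = _rgb_array_to_lab(px)
    return LabColor(*map(float, lab.mean(axis=0)))


def confusion_matrix(
    scores_a: Sequence[int],
    scores_b: Sequence[int],
    chart: ScoreChart,
) -> ConfusionMatrix:
    """Cross-tabulate two scoring replicates on the same images."""
    a = np.asarray(scores_a, dtype=np.int64)
    b = np.asarray(scores_b, dtype=np.int64)
    if a.size == 0:
        raise ValueError("empty score lists")
    if a.shape != b.shape:
        raise ValueError(f"replicate lengths differ: {a.size} vs {b.size}")
    c = chart.n_categories
    if ((a < 1) | (a > c) | (b < 1) | (b > c)).any():
        raise ValueError(f"scores must lie in 1..{c} for chart {chart.name!r}")
    counts = np.zeros((c, c), dtype=np.int64)
    np.add.at(counts, (a - 1, b - 1), 1)
    return ConfusionMatrix(categories=chart.categories, counts=counts)


def repeatability(cm: ConfusionMatrix) -> float:
    """Scoring repeatability: Pearson r of the paired category codes.

    Category codes are treated as numeric; the pairs are reconstructed
    from the confusion-matrix counts.
    """
    if cm.total < 2:
        raise ValueError("need at least 2 doubly-scored images")
    a, b = cm.expand_pairs()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("undefined correlation: a replicate has zero variance")
    return float(np.corrcoef(a, b)[0, 1])


def format_confusion_matrix(cm: ConfusionMatrix, r: float | None = None) -> str:
    """Aligned text table, replicate A in rows and replicate B in columns."""
    head = "".join(f"{'Score=' + str(c):>10}" for c in cm.categories)
    lines = [f"{'':>10}{head}" + ("" if r is None else f"{'r':>8}")]
    for i, ci in enumerate(cm.categories):
        row = "".join(f"{int(v):>10}" for v in cm.counts[i])
        tail = f"{r:>8.2f}" if (r is not None and i == 0) else ""
        lines.append(f"{'Score=' + str(ci):>10}{row}{tail}")
    return "\n".join(lines)


def read_pixel_csv(path: str | Path) -> dict[str, np.ndarray]:
    """Read `animal,pixel_r,pixel_g,pixel_b` CSV into per-animal arrays."""
    df = pd.read_csv(path)
    need = {"animal", "pixel_r", "pixel_g", "pixel_b"}
    if not need.issubset(df.columns):
        raise ValueError(f"pixel CSV must have columns {sorted(need)}")
    return {
        str(animal): grp[["pixel_r", "pixel_g", "pixel_b"]].to_numpy(dtype=float)
        for animal, grp in df.groupby("animal", sort=False)
    }
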