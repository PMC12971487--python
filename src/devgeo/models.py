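"""Hypothesis RSMs: perceptual image features and categorical distinctions.

Perceptual models are built from four scalar image features — size
(foreground minus background pixel count), elongation (bounding-box aspect
ratio), color (grand mean of the three channels) and compactness (shape
area relative to the disc with the same perimeter, the isoperimetric
quotient 4*pi*A/P^2). Each feature's RSM is 1 minus the max-normalized
pairwise absolute differences, so entries lie in [0, 1] with 1 on the
diagonal.

Categorical models: identity (within versus between image); category
generalization (within-exemplar 0, within-category/across-exemplar +1,
across-category -1); the tripartite animate / inanimate-small /
inanimate-large distinction; and two binary class contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from devgeo.rsm import RSM
from devgeo.stimuli import StimulusSet

FEATURE_NAMES = ("size", "elongation", "color", "compactness")


@dataclass
class FeatureVector:
    """Scalar perceptual features of one stimulus image."""

    size: float
    elongation: float
    color: float
    compactness: float

    def as_dict(self) -> dict[str, float]:
        return {
            "size": self.size,
            "elongation": self.elongation,
            "color": self.color,
            "compactness": self.compactness,
        }


@dataclass
class ModelRSM:
    """A hypothesis RSM with a name and model family."""

    name: str
    family: str  # perceptual | categorical | dnn-layer
    rsm: RSM
    degenerate: bool = False

    @property
    def values(self) -> np.ndarray:
        return self.rsm.values


def _contour_perimeter(mask: np.ndarray, smooth_window: int = 5) -> float:
    """Foreground perimeter from the marching-squares contour.

    The raw subpixel contour of a binary mask staircases along curved
    boundaries, inflating lengths by ~5%; a short circular moving average
    over contour vertices removes the staircase while barely rounding
    true corners (within ~1% of the analytic perimeter for discs,
    ellipses and rectangles larger than ~50 px).
    """
    padded = np.pad(mask.astype(float), 1)
    total = 0.0
    k = smooth_window
    for c in measure.find_contours(padded, 0.5):
        if len(c) >= 2 * k:
            kernel = np.ones(k) / k
            c = np.column_stack(
                [
                    np.convolve(
                        np.r_[c[-(k // 2):, i], c[:, i], c[: k // 2, i]],
                        kernel,
                        mode="valid",
                    )
                    for i in range(2)
                ]
            )
        total += float(np.sum(np.linalg.norm(np.diff(c, axis=0), axis=1)))
    return total


def extract_perceptual_features(
    image: np.ndarray, foreground_mask: np.ndarray
) -> FeatureVector:
    """Measure size, elongation, color and compactness from an image.

    size counts foreground minus background pixels over the full canvas;
    elongation is the aspect ratio of the foreground bounding box (>= 1);
    color averages the three channel means over the whole image;
    compactness is 4*pi*area/perimeter^2 with the perimeter measured on
    the marching-squares contour of the mask.
    """
    mask = np.asarray(foreground_mask, dtype=bool)
    img = np.asarray(image, dtype=float)
    if img.shape[:2] != mask.shape:
        raise ValueError("image and mask shapes differ")
    n_fg = int(mask.sum())
    if n_fg == 0:
        raise ValueError("empty foreground mask")
    n_bg = mask.size - n_fg

    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    h = int(rows.sum() and (np.flatnonzero(rows)[-1] - np.flatnonzero(rows)[0] + 1))
    w = int(cols.sum() and (np.flatnonzero(cols)[-1] - np.flatnonzero(cols)[0] + 1))
    elongation = max(h / w, w / h)

    if img.ndim == 2:
        color = float(img.mean())
    else:
        color = float(img.reshape(-1, img.shape[-1]).mean())

    perim = _contour_perimeter(mask)
    compactness = 4.0 * np.pi * n_fg / perim**2

    return FeatureVector(
        size=float(n_fg - n_bg),
        elongation=float(elongation),
        color=color,
        compactness=float(compactness),
    )


def feature_rsm(values: np.ndarray, name: str = "feature") -> ModelRSM:
    """RSM from one scalar feature per condition.

    Pairwise absolute differences are scaled by their maximum into [0, 1];
    the RSM entry is 1 minus the scaled distance (diagonal exactly 1). An
    all-equal feature yields a constant model, flagged degenerate.
    """
    v = np.asarray(values, dtype=float).ravel()
    d = np.abs(v[:, None] - v[None, :])
    dmax = d.max()
    degenerate = dmax == 0
    if not degenerate:
        d = d / dmax
    sim = 1.0 - d
    return ModelRSM(
        name=name,
        family="perceptual",
        rsm=RSM(values=sim, metric="pearson-similarity", provenance="model"),
        degenerate=bool(degenerate),
    )


def perceptual_feature_rsms(feature_table) -> dict[str, ModelRSM]:
    """Feature RSMs for each of the four perceptual features.

    ``feature_table`` is a DataFrame with one row per condition (in
    condition order) and columns size, elongation, color, compactness.
    """
    return {
        name: feature_rsm(feature_table[name].to_numpy(), name=name)
        for name in FEATURE_NAMES
    }


def categorical_rsms(
    stimulus_set: StimulusSet, duck_as_animate: bool = False
) -> dict[str, ModelRSM]:
    """Categorical hypothesis RSMs for a stimulus set.

    identity: I_n (within versus between image). category: 0 on the
    diagonal, +1 within category across exemplars, -1 across categories.
    animacy_tripartite: +1 same animacy class, -1 different, 0 diagonal.
    animate_vs_inanimate: the binary animate contrast with the same weight
    scheme. small_vs_large: +/-1 among inanimate conditions only, 0
    elsewhere (animate conditions are neutral).

    ``duck_as_animate`` regroups the rubber-duck category with the animate
    class (its representational grouping in visual cortex); the default is
    the taxonomic labeling (inanimate-small).
    """
    n = stimulus_set.n_conditions
    cat = stimulus_set.category_index
    cls = np.array([c.animacy_class for c in stimulus_set.conditions], dtype=object)
    if duck_as_animate:
        cls = cls.copy()
        cls[[c.category == "rubber-duck" for c in stimulus_set.conditions]] = "animate"

    same_cat = cat[:, None] == cat[None, :]
    category = np.where(same_cat, 1.0, -1.0)
    np.fill_diagonal(category, 0.0)

    same_cls = cls[:, None] == cls[None, :]
    tripartite = np.where(same_cls, 1.0, -1.0)
    np.fill_diagonal(tripartite, 0.0)

    animate = np.array([c == "animate" for c in cls])
    same_anim = animate[:, None] == animate[None, :]
    anim_model = np.where(same_anim, 1.0, -1.0)
    np.fill_diagonal(anim_model, 0.0)

    inanimate = ~animate
    small = np.array([c == "inanimate-small" for c in cls])
    size_model = np.zeros((n, n))
    both_inan = inanimate[:, None] & inanimate[None, :]
    same_size = small[:, None] == small[None, :]
    size_model[both_inan] = np.where(same_size, 1.0, -1.0)[both_inan]
    np.fill_diagonal(size_model, 0.0)

    labels = stimulus_set.labels

    def wrap(name: str, m: np.ndarray) -> ModelRSM:
        return ModelRSM(
            name=name,
            family="categorical",
            rsm=RSM(values=m, labels=labels, provenance="model"),
        )

    return {
        "identity": wrap("identity", np.eye(n)),
        "category": wrap("category", category),
        "animacy_tripartite": wrap("animacy_tripartite", tripartite),
        "animate_vs_inanimate": wrap("animate_vs_inanimate", anim_model),
        "small_vs_large": wrap("small_vs_large", size_model),
    }
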