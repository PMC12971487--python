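"""Stimulus sets, pseudorandom event schedules and parametric stimulus images.

The experimental design nests conditions by animacy class (animate,
inanimate-small, inanimate-large), then category (four per class), then
exemplar (three per category), giving 36 conditions by default. Event
schedules honor the pseudorandom constraint that one exemplar of every
category is shown before any category gets a second one.

Rendered stimuli are parametric shapes (ellipses and rectangles) whose
area, perimeter, bounding box and mean color are known in closed form, so
perceptual feature extraction can be validated against analytic ground
truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_CLASSES = ("animate", "inanimate-small", "inanimate-large")

# The 12 basic-level categories, grouped by animacy class.
DEFAULT_CATEGORIES = {
    "animate": ("cat", "crab", "bird", "squirrel"),
    "inanimate-small": ("rubber-duck", "dishware", "food", "towel"),
    "inanimate-large": ("fence", "shelves", "shopping-cart", "tree"),
}

DEFAULT_CANVAS = (640, 360)  # width x height in pixels


@dataclass(frozen=True)
class Condition:
    """One experimental condition: a (class, category, exemplar) triple."""

    index: int
    animacy_class: str
    category: str
    exemplar: int

    @property
    def label(self) -> str:
        return f"{self.category}-{self.exemplar + 1}"


@dataclass(frozen=True)
class StimulusSet:
    """Nested class -> category -> exemplar condition structure.

    Conditions are flattened in deterministic nested order: classes in the
    given order, categories within class, exemplars within category.
    """

    classes: tuple[str, ...]
    categories: tuple[tuple[str, str], ...]  # (category, class) pairs
    n_exemplars: int
    conditions: tuple[Condition, ...] = field(repr=False)

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.conditions]

    @property
    def category_index(self) -> np.ndarray:
        """Integer category id per condition, in condition order."""
        cats = [c for c, _ in self.categories]
        return np.array([cats.index(c.category) for c in self.conditions])

    @property
    def class_index(self) -> np.ndarray:
        """Integer animacy-class id per condition, in condition order."""
        return np.array(
            [self.classes.index(c.animacy_class) for c in self.conditions]
        )

    def condition(self, index: int) -> Condition:
        return self.conditions[index]


def make_stimulus_set(
    n_classes: int = 3,
    n_categories_per_class: int = 4,
    n_exemplars: int = 3,
    class_names: tuple[str, ...] | None = None,
    category_names: dict[str, tuple[str, ...]] | None = None,
) -> StimulusSet:
    """Build a nested stimulus set.

    The default (3, 4, 3) reproduces the 36-condition design. Custom sizes
    get generic labels unless names are supplied.
    """
    if n_classes < 1 or n_categories_per_class < 1 or n_exemplars < 1:
        raise ValueError(
            "all of n_classes, n_categories_per_class, n_exemplars must be >= 1"
        )

    if class_names is None:
        if n_classes == len(DEFAULT_CLASSES):
            class_names = DEFAULT_CLASSES
        else:
            class_names = tuple(f"class-{i + 1}" for i in range(n_classes))
    if len(class_names) != n_classes:
        raise ValueError("class_names length must equal n_classes")

    categories: list[tuple[str, str]] = []
    for cls in class_names:
        if category_names is not None:
            names = category_names[cls]
        elif (
            cls in DEFAULT_CATEGORIES
            and n_categories_per_class == len(DEFAULT_CATEGORIES[cls])
        ):
            names = DEFAULT_CATEGORIES[cls]
        else:
            names = tuple(f"{cls}-cat{i + 1}" for i in range(n_categories_per_class))
        if len(names) != n_categories_per_class:
            raise ValueError(f"need {n_categories_per_class} categories for {cls}")
        categories.extend((name, cls) for name in names)

    conditions = []
    idx = 0
    for cat, cls in categories:
        for ex in range(n_exemplars):
            conditions.append(Condition(idx, cls, cat, ex))
            idx += 1
    return StimulusSet(
        classes=tuple(class_names),
        categories=tuple(categories),
        n_exemplars=n_exemplars,
        conditions=tuple(conditions),
    )


@dataclass
class EventTable:
    """Presentation events for one or more runs.

    ``events`` has columns onset (s), duration (s), condition (index into
    the stimulus set), trial_type (condition label) and run.
    """

    events: pd.DataFrame
    tr: float
    n_frames: int

    def for_run(self, run: int) -> pd.DataFrame:
        return self.events[self.events["run"] == run].reset_index(drop=True)

    @property
    def runs(self) -> list[int]:
        return sorted(self.events["run"].unique())


def make_events(
    stimulus_set: StimulusSet,
    n_repetitions_per_run: int = 2,
    soa_range: tuple[float, float] = (3.5, 4.5),
    duration: float = 3.0,
    seed: int | None = None,
    n_runs: int = 1,
    tr: float = 0.656,
    start_offset: float = 2.0,
    n_frames: int | None = None,
) -> EventTable:
    """Generate pseudorandom event schedules.

    Each run shows every exemplar exactly ``n_repetitions_per_run`` times.
    Presentation order is organized in category sweeps: every sweep shows
    one exemplar from each category in shuffled category order, and a
    category never reaches occurrence k+1 until all categories have had k
    occurrences. Within each block of ``n_exemplars`` sweeps, a category's
    exemplars are assigned without replacement (a random permutation), so
    all exemplars of a category appear before any repeats.

    Onsets start at ``start_offset`` with successive gaps drawn uniformly
    from ``soa_range``.
    """
    if n_repetitions_per_run < 1:
        raise ValueError("n_repetitions_per_run must be >= 1")
    if soa_range[0] > soa_range[1]:
        raise ValueError("soa_range must be (low, high) with low <= high")
    if soa_range[0] < duration:
        raise ValueError("soa low bound must be >= stimulus duration")
    rng = np.random.default_rng(seed)

    n_cat = len(stimulus_set.categories)
    n_ex = stimulus_set.n_exemplars
    # condition ids grouped per category, in condition order
    by_cat = [
        [c.index for c in stimulus_set.conditions if c.category == cat]
        for cat, _ in stimulus_set.categories
    ]

    rows = []
    for run in range(n_runs):
        order: list[int] = []
        # per-category exemplar streams: repetitions of shuffled permutations
        streams = []
        for cat_conds in by_cat:
            seq: list[int] = []
            for _ in range(n_repetitions_per_run):
                seq.extend(rng.permutation(cat_conds).tolist())
            streams.append(seq)
        n_sweeps = n_ex * n_repetitions_per_run
        for sweep in range(n_sweeps):
            for cat in rng.permutation(n_cat):
                order.append(streams[cat][sweep])
        onset = float(start_offset)
        for cond in order:
            rows.append(
                {
                    "onset": onset,
                    "duration": duration,
                    "condition": cond,
                    "trial_type": stimulus_set.conditions[cond].label,
                    "run": run,
                }
            )
            onset += float(rng.uniform(*soa_range))

    events = pd.DataFrame(rows)
    if n_frames is None:
        run_end = events.groupby("run")["onset"].max().max() + duration + 20.0
        n_frames = int(math.ceil(run_end / tr))
    return EventTable(events=events, tr=tr, n_frames=n_frames)


def check_sweep_constraint(events: pd.DataFrame, stimulus_set: StimulusSet) -> bool:
    """True when, at every prefix of a run, cumulative per-category counts
    differ by at most one (the pseudorandom ordering constraint)."""
    cat_of = stimulus_set.category_index
    for _, run_events in events.groupby("run"):
        counts = np.zeros(len(stimulus_set.categories), dtype=int)
        for cond in run_events.sort_values("onset")["condition"]:
            counts[cat_of[cond]] += 1
            if counts.max() - counts.min() > 1:
                return False
    return True


# ---------------------------------------------------------------------------
# Parametric stimulus images with analytic feature ground truth
# ---------------------------------------------------------------------------


def _ellipse_perimeter(a: float, b: float) -> float:
    # Ramanujan's second approximation; relative error < 1e-6 for the
    # aspect ratios rendered here.
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))


@dataclass
class ShapeSpec:
    """A parametric shape with closed-form geometry.

    kind 'ellipse': semi_axes = (a, b) in pixels (a horizontal).
    kind 'rectangle': semi_axes = (half_width, half_height).
    """

    kind: str
    semi_axes: tuple[float, float]
    center: tuple[float, float]  # (x, y) pixels
    color: tuple[int, int, int]

    def area(self) -> float:
        a, b = self.semi_axes
        if self.kind == "ellipse":
            return math.pi * a * b
        return 4.0 * a * b

    def perimeter(self) -> float:
        a, b = self.semi_axes
        if self.kind == "ellipse":
            return _ellipse_perimeter(a, b)
        return 4.0 * (a + b)

    def bbox_wh(self) -> tuple[float, float]:
        a, b = self.semi_axes
        return 2.0 * a, 2.0 * b


def analytic_features(
    shape: ShapeSpec, image_size: tuple[int, int] = DEFAULT_CANVAS
) -> dict[str, float]:
    """Closed-form perceptual features of a rendered shape.

    size = foreground minus background pixel count; elongation = bounding
    box aspect ratio (>= 1); color = grand mean of the three channels over
    the full canvas (background is black); compactness = 4*pi*A / P^2, the
    area of the shape relative to the disc with the same perimeter.
    """
    w_canvas, h_canvas = image_size
    area = shape.area()
    n_pix = w_canvas * h_canvas
    bw, bh = shape.bbox_wh()
    return {
        "size": 2.0 * area - n_pix,
        "elongation": max(bw / bh, bh / bw),
        "color": float(np.mean(shape.color)) * area / n_pix,
        "compactness": 4.0 * math.pi * area / shape.perimeter() ** 2,
    }


def _raster_mask(shape: ShapeSpec, image_size: tuple[int, int]) -> np.ndarray:
    w, h = image_size
    # pixel centers at integer + 0.5
    yy, xx = np.mgrid[0:h, 0:w]
    xx = xx + 0.5 - shape.center[0]
    yy = yy + 0.5 - shape.center[1]
    a, b = shape.semi_axes
    if shape.kind == "ellipse":
        return (xx / a) ** 2 + (yy / b) ** 2 <= 1.0
    if shape.kind == "rectangle":
        return (np.abs(xx) <= a) & (np.abs(yy) <= b)
    raise ValueError(f"unknown shape kind {shape.kind!r}")


def render_shape(
    shape: ShapeSpec, image_size: tuple[int, int] = DEFAULT_CANVAS
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize a shape on a black canvas. Returns (image HxWx3 uint8,
    boolean foreground mask HxW)."""
    w, h = image_size
    a, b = shape.semi_axes
    cx, cy = shape.center
    if cx - a < 0 or cx + a > w or cy - b < 0 or cy + b > h:
        raise ValueError("shape exceeds canvas bounds")
    mask = _raster_mask(shape, image_size)
    img = np.zeros((h, w, 3), dtype=np.uint8)
    img[mask] = np.asarray(shape.color, dtype=np.uint8)
    return img, mask


def render_stimulus_images(
    stimulus_set: StimulusSet,
    image_size: tuple[int, int] = DEFAULT_CANVAS,
    seed: int | None = None,
    min_extent: float = 50.0,
) -> tuple[list[np.ndarray], list[np.ndarray], pd.DataFrame, list[ShapeSpec]]:
    """Render one parametric shape per condition.

    Returns (images, masks, ground-truth feature table, shape specs). The
    feature table rows align with condition order and carry the analytic
    values of size, elongation, color and compactness for each rendered
    shape, against which image-based extraction can be checked.

    Shapes vary systematically with the condition structure so that
    features correlate with category membership: categories share a shape
    family and base size; exemplars jitter the parameters.
    """
    if image_size[0] <= 0 or image_size[1] <= 0:
        raise ValueError("image_size must be positive")
    rng = np.random.default_rng(seed)
    w, h = image_size
    images, masks, rows, specs = [], [], [], []
    kinds = ("ellipse", "rectangle")
    for cond in stimulus_set.conditions:
        cat_id = int(stimulus_set.category_index[cond.index])
        kind = kinds[cat_id % 2]
        base = min_extent / 2.0 + 8.0 * cat_id
        a = base * (1.0 + 0.15 * cond.exemplar) * float(rng.uniform(0.9, 1.1))
        aspect = 1.0 + 0.4 * (cat_id % 3) + 0.1 * cond.exemplar
        b = a / aspect
        a = min(a, w / 2.0 - 2)
        b = min(b, h / 2.0 - 2)
        color = tuple(int(v) for v in rng.integers(60, 256, size=3))
        shape = ShapeSpec(
            kind=kind, semi_axes=(a, b), center=(w / 2.0, h / 2.0), color=color
        )
        img, mask = render_shape(shape, image_size)
        feats = analytic_features(shape, image_size)
        feats["condition"] = cond.index
        images.append(img)
        masks.append(mask)
        rows.append(feats)
        specs.append(shape)
    table = pd.DataFrame(rows).set_index("condition")
    return images, masks, table, specs
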