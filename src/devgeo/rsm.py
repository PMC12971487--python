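"""Cross-subject representational similarity matrices and noise ceilings.

Similarity is computed *across* measurements: for every unordered pair of
units (subject/run from different subjects, or whole subjects), entry
(p, q) is the Pearson correlation between unit A's pattern for condition p
and unit B's pattern for condition q, symmetrized over the two orderings.
Averaging these pair RSMs restricts the group representation to signal
that is shared across the cohort; the diagonal is the cross-measurement
same-condition correlation and is not forced to 1. Group reliability is a
split-half noise ceiling: Spearman correlation of group RSMs from random
subject halves, stepped up with the Spearman–Brown prophecy formula
2r/(1+r).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from devgeo.cohort import SyntheticCohort


@dataclass
class RSM:
    """A condition-by-condition similarity matrix.

    metric is 'pearson-similarity' or 'covariance'; provenance records the
    contributing measurement pairs (or 'model').
    """

    values: np.ndarray
    metric: str = "pearson-similarity"
    labels: list[str] | None = None
    provenance: list | str = field(default_factory=list)
    symmetric: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("RSM must be square")
        if self.symmetric and np.abs(self.values - self.values.T).max() > 1e-10:
            raise ValueError("RSM flagged symmetric but is not")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self, include_diagonal: bool = False) -> np.ndarray:
        iu = np.triu_indices(self.n, k=0 if include_diagonal else 1)
        return self.values[iu]


@dataclass
class NoiseCeiling:
    """Split-half group-RSM reliability, Spearman–Brown corrected."""

    corrected: float
    raw: float
    n_splits: int
    valid: bool


def spearman_brown(r: float) -> float:
    """Step a split-half correlation up to full test length: 2r/(1+r)."""
    if r <= -1.0:
        raise ValueError("Spearman-Brown undefined at r = -1")
    if r > 1.0:
        raise ValueError("correlation must be <= 1")
    return 2.0 * r / (1.0 + r)


def enumerate_pairs(
    cohort_or_units, level: str = "run"
) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    """All unordered cross-subject pairs of sampling units.

    At 'run' level every (subject, run) is a unit and within-subject pairs
    are excluded; at 'subject' level runs are aggregated so a cohort of n
    subjects yields C(n, 2) pairs. Ordering is deterministic (input
    order).
    """
    if isinstance(cohort_or_units, SyntheticCohort):
        ids = [uid for uid, _ in cohort_or_units.units(level)]
    else:
        ids = list(cohort_or_units)
    subjects = {uid[0] for uid in ids}
    if len(subjects) < 2:
        raise ValueError("pair enumeration needs >= 2 subjects")
    return [(a, b) for a, b in combinations(ids, 2) if a[0] != b[0]]


def _standardize(patterns: np.ndarray) -> np.ndarray:
    """Row-standardize patterns over voxels (for Pearson via dot product)."""
    p = patterns - patterns.mean(axis=1, keepdims=True)
    sd = p.std(axis=1, keepdims=True)
    sd[sd == 0] = np.nan
    return p / sd


def pair_rsm(
    patterns_a: np.ndarray,
    patterns_b: np.ndarray,
    voxel_mask: np.ndarray | None = None,
    labels: list[str] | None = None,
    provenance=None,
) -> RSM:
    """Cross-measurement pattern-correlation RSM for one unit pair.

    Entry (p, q) = [corr(A_p, B_q) + corr(A_q, B_p)] / 2 over the shared
    valid voxels. The diagonal is the same-condition cross-measurement
    correlation (not identically 1).
    """
    a = np.asarray(patterns_a, dtype=float)
    b = np.asarray(patterns_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("pattern matrices must have identical shape")
    if voxel_mask is not None:
        voxel_mask = np.asarray(voxel_mask, dtype=bool)
        a = a[:, voxel_mask]
        b = b[:, voxel_mask]
    if a.shape[1] < 3:
        raise ValueError("need >= 3 shared valid voxels")
    v = a.shape[1]
    cross = (_standardize(a) @ _standardize(b).T) / v
    return RSM(
        values=(cross + cross.T) / 2.0,
        metric="pearson-similarity",
        labels=labels,
        provenance=[provenance] if provenance is not None else [],
    )


def group_rsm(rsms: list[RSM], weights: np.ndarray | None = None) -> RSM:
    """(Weighted) element-wise mean of pair RSMs; provenance is the union."""
    if not rsms:
        raise ValueError("group_rsm needs at least one RSM")
    stack = np.stack([r.values for r in rsms])
    if weights is None:
        mean = stack.mean(axis=0)
    else:
        w = np.asarray(weights, dtype=float)
        if w.size != len(rsms):
            raise ValueError("one weight per RSM required")
        w = w / w.sum()
        mean = np.tensordot(w, stack, axes=1)
    prov: list = []
    for r in rsms:
        prov.extend(r.provenance if isinstance(r.provenance, list) else [r.provenance])
    return RSM(
        values=mean, metric=rsms[0].metric, labels=rsms[0].labels, provenance=prov
    )


def zscore_rsm(rsm: RSM, include_diagonal: bool = True) -> RSM:
    """Standardize RSM entries (mean 0, s.d. 1) to focus on relational
    geometry rather than correlation magnitude; symmetry is preserved."""
    v = rsm.values.copy()
    if include_diagonal:
        sel = np.triu_indices(rsm.n, k=0)
    else:
        sel = np.triu_indices(rsm.n, k=1)
    vals = v[sel]
    sd = vals.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant RSM")
    z = (v - vals.mean()) / sd
    if not include_diagonal:
        np.fill_diagonal(z, v.diagonal())
    z = (z + z.T) / 2.0
    return RSM(values=z, metric=rsm.metric, labels=rsm.labels, provenance=rsm.provenance)


def cohort_group_rsm(
    cohort: SyntheticCohort, level: str = "run", labels: list[str] | None = None
) -> tuple[RSM, list[RSM]]:
    """Group RSM of a cohort: average of all cross-subject pair RSMs.

    Computed with one blocked matrix product over standardized unit
    patterns, which is algebraically identical to looping `pair_rsm` over
    `enumerate_pairs` but much faster on large cohorts.
    """
    units = cohort.units(level)
    pairs = enumerate_pairs([uid for uid, _ in units], level)
    index = {uid: k for k, (uid, _) in enumerate(units)}
    n = units[0][1].shape[0]
    v = units[0][1].shape[1]
    z = np.stack([_standardize(p) for _, p in units])  # U x n x V
    flat = z.reshape(-1, v)
    gram = (flat @ flat.T) / v  # (U*n) x (U*n)
    rsms = []
    for a, b in pairs:
        i, j = index[a], index[b]
        block = gram[i * n : (i + 1) * n, j * n : (j + 1) * n]
        rsms.append(
            RSM(values=(block + block.T) / 2.0, labels=labels, provenance=[(a, b)])
        )
    return group_rsm(rsms), rsms


def split_half_noise_ceiling(
    cohort: SyntheticCohort,
    level: str = "run",
    n_splits: int = 100,
    seed: int | None = None,
    floor: float = 0.1,
) -> NoiseCeiling:
    """Split-half reliability of the group RSM, Spearman–Brown corrected.

    Subjects are randomly partitioned into halves (runs travel with their
    subject); each half yields a cross-subject group RSM; the Spearman
    correlation of the two upper triangles is averaged over ``n_splits``
    random partitions before the 2r/(1+r) correction. The valid flag goes
    false below ``floor`` — too unreliable to normalize against.
    """
    if cohort.n_subjects < 4:
        raise ValueError("noise ceiling needs >= 4 subjects (2 per half)")
    rng = np.random.default_rng(seed)
    subj_ids = [s.subject_id for s in cohort.subjects]
    units = cohort.units(level)
    by_subject: dict[str, list[np.ndarray]] = {}
    for (sid, _), pat in units:
        by_subject.setdefault(sid, []).append(pat)

    raws = []
    half = len(subj_ids) // 2
    iu = np.triu_indices(units[0][1].shape[0], k=1)
    for _ in range(n_splits):
        perm = rng.permutation(subj_ids)
        halves = []
        for ids in (perm[:half], perm[half:]):
            sub_units = [
                ((sid, k), p)
                for sid in ids
                for k, p in enumerate(by_subject[sid])
            ]
            halves.append(_units_group_rsm(sub_units))
        rho = stats.spearmanr(halves[0][iu], halves[1][iu]).statistic
        raws.append(rho)
    raw = float(np.mean(raws))
    corrected = spearman_brown(raw) if raw > -1.0 else float("nan")
    return NoiseCeiling(
        corrected=corrected, raw=raw, n_splits=n_splits, valid=bool(corrected >= floor)
    )


def _units_group_rsm(units: list[tuple[tuple[str, int], np.ndarray]]) -> np.ndarray:
    """Mean cross-subject pair RSM over a list of (id, patterns) units."""
    pairs = enumerate_pairs([uid for uid, _ in units])
    index = {uid: k for k, (uid, _) in enumerate(units)}
    n, v = units[0][1].shape
    z = np.stack([_standardize(p) for _, p in units])
    flat = z.reshape(-1, v)
    gram = (flat @ flat.T) / v
    acc = np.zeros((n, n))
    for a, b in pairs:
        i, j = index[a], index[b]
        block = gram[i * n : (i + 1) * n, j * n : (j + 1) * n]
        acc += (block + block.T) / 2.0
    return acc / len(pairs)
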