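"""Variance partitioning of representational signal via covariance traces.

Correlation-based RSMs hide where signal strength comes from. Using
covariance as the similarity metric instead makes the RSM additive over
independent signal components, so the average trace of covariance RSMs
computed over three tiers of comparisons —

1. across pairs of subjects            -> group-shared variance,
2. within subject, across runs         -> + individual variance,
3. within subject/run, across halves   -> + session variance,

— identifies the nested components by subtraction: group = T1,
individual = T2 - T1, session = T3 - T2. Patterns are voxel-mean-centered
across conditions first (run-level mean centering), so traces are reported
per condition with an (n-1) denominator, which makes an injected isotropic
component of variance sigma^2 come back as exactly sigma^2 in expectation.
Estimates are differences of noisy traces and may come out negative by
sampling error; they are reported as-is, not clipped.

The category-level GLM variant re-estimates patterns at the 12-category
level with occurrences split into two within-run repetition halves (six
events per category per run give 3 + 3), which is what makes the
within-run tier well defined without correlating an estimate with itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from devgeo.cohort import SyntheticCohort
from devgeo.rsm import RSM


@dataclass
class VarianceComponents:
    """Nested variance components in pattern-covariance units."""

    group: float
    individual: float
    session: float
    traces: dict[str, float]
    ci: dict[str, tuple[float, float]] | None = None

    def as_dict(self) -> dict[str, float]:
        return {
            "group": self.group,
            "individual": self.individual,
            "session": self.session,
        }


def _center(patterns: np.ndarray) -> np.ndarray:
    """Voxel-mean-center across conditions (run-level mean centering)."""
    return patterns - patterns.mean(axis=0, keepdims=True)


def covariance_rsm(
    patterns_u: np.ndarray,
    patterns_v: np.ndarray,
    labels: list[str] | None = None,
    center: bool = True,
) -> RSM:
    """Covariance-metric RSM between two pattern sets.

    Entry (p, q) is the cross-voxel covariance of U_p and V_q,
    symmetrized over the two orderings. Patterns are voxel-mean-centered
    across conditions first by default.
    """
    u = np.asarray(patterns_u, dtype=float)
    v = np.asarray(patterns_v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("pattern sets must have identical shape")
    if u.shape[1] < 2:
        raise ValueError("covariance needs >= 2 voxels")
    if center:
        u, v = _center(u), _center(v)
    nv = u.shape[1]
    uc = u - u.mean(axis=1, keepdims=True)
    vc = v - v.mean(axis=1, keepdims=True)
    cross = (uc @ vc.T) / (nv - 1)
    return RSM(values=(cross + cross.T) / 2.0, metric="covariance", labels=labels)


def _trace_per_condition(patterns_u: np.ndarray, patterns_v: np.ndarray) -> float:
    """Trace of the covariance RSM divided by (n_conditions - 1).

    The (n-1) denominator undoes the shrinkage that condition-mean
    centering applies to an isotropic component.
    """
    rsm = covariance_rsm(patterns_u, patterns_v)
    return float(np.trace(rsm.values) / (rsm.n - 1))


def repetition_split_patterns(
    events,
    timeseries: np.ndarray,
    stimulus_set,
    motion=None,
    run: int = 0,
    tr: float | None = None,
    n_frames: int | None = None,
    fwd_threshold: float = 1.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Category-level patterns for two within-run repetition halves.

    Events are regrouped from exemplar to category level; each category's
    occurrences are split odd/even into two halves; a GLM with
    2 x n_categories condition regressors (plus the usual nuisance terms)
    yields one pattern per category per half. Requires >= 2 events per
    category in the run.
    """
    from devgeo.glm import build_design_matrix, censor_and_qc, fit_glm, mean_center_runs

    if hasattr(events, "for_run"):
        tr = events.tr if tr is None else tr
        n_frames = events.n_frames if n_frames is None else n_frames
        run_events = events.for_run(run).copy()
    else:
        run_events = events.copy()
    cat_of = stimulus_set.category_index
    n_cat = len(stimulus_set.categories)
    run_events["category"] = cat_of[run_events["condition"].to_numpy()]
    counts = run_events.groupby("category").size()
    if (counts < 2).any() or len(counts) < n_cat:
        raise ValueError("every category needs >= 2 events in the run")

    # odd/even occurrence split per category -> 2*n_cat pseudo-conditions
    run_events = run_events.sort_values("onset").reset_index(drop=True)
    occ = run_events.groupby("category").cumcount()
    half = (occ % 2).to_numpy()
    run_events["condition"] = run_events["category"] * 2 + half

    censor_mask = None
    if motion is not None:
        _, censor_mask = censor_and_qc(motion, fwd_threshold=fwd_threshold)
    design = build_design_matrix(
        run_events,
        tr=tr,
        n_frames=n_frames,
        censor_mask=censor_mask,
        n_conditions=2 * n_cat,
    )
    betas = mean_center_runs(fit_glm(timeseries, design))
    b = betas.betas
    return b[0::2], b[1::2]  # halves: (n_cat x V) each


def partition_variance(
    cohort: SyntheticCohort,
    n_boot: int = 0,
    seed: int | None = None,
) -> VarianceComponents:
    """Estimate group / individual / session variance components.

    Uses the repetition halves stored on each run: the within-run tier
    covaries half 1 with half 2; the within-subject tier covaries run
    means across a subject's runs; the group tier covaries run means
    across subjects. Components are the nested differences of the three
    mean traces. When a tier is missing (e.g. all subjects single-run)
    the dependent components are NaN. Optional bootstrap CIs resample
    subjects.
    """
    subs = cohort.subjects
    if len(subs) < 2:
        raise ValueError("variance partitioning needs >= 2 subjects")

    def traces(subjects) -> dict[str, float]:
        t_sess = [
            _trace_per_condition(r.halves[0], r.halves[1])
            for s in subjects
            for r in s.runs
            if r.halves is not None
        ]
        t_indiv = [
            _trace_per_condition(ra.patterns, rb.patterns)
            for s in subjects
            for ra, rb in combinations(s.runs, 2)
        ]
        t_group = [
            _trace_per_condition(sa.patterns, sb.patterns)
            for sa, sb in combinations(subjects, 2)
            if sa.subject_id != sb.subject_id  # bootstrap duplicates excluded
        ]
        return {
            "session_tier": float(np.mean(t_sess)) if t_sess else float("nan"),
            "individual_tier": float(np.mean(t_indiv)) if t_indiv else float("nan"),
            "group_tier": float(np.mean(t_group)) if t_group else float("nan"),
        }

    def components(tr: dict[str, float]) -> tuple[float, float, float]:
        g = tr["group_tier"]
        i = tr["individual_tier"] - tr["group_tier"]
        s = tr["session_tier"] - tr["individual_tier"]
        return g, i, s

    tr = traces(subs)
    g, i, s = components(tr)

    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boot = {"group": [], "individual": [], "session": []}
        for _ in range(n_boot):
            idx = rng.choice(len(subs), size=len(subs))
            resampled = [subs[k] for k in idx]
            bt = traces(resampled)
            bg, bi, bs = components(bt)
            boot["group"].append(bg)
            boot["individual"].append(bi)
            boot["session"].append(bs)
        ci = {
            k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
            for k, v in boot.items()
        }

    return VarianceComponents(group=g, individual=i, session=s, traces=tr, ci=ci)


def components_table(vc: VarianceComponents) -> pd.DataFrame:
    rows = []
    for comp, value in vc.as_dict().items():
        lo, hi = (vc.ci or {}).get(comp, (float("nan"), float("nan")))
        rows.append({"component": comp, "value": value, "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows)
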