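"""RSA inference: rank correlations, partial correlations, bootstrap CIs
with motion-matched importance reweighting, group contrasts, ceiling
normalization, maturity and longitudinal tests.

All test statistics are computed on resampled group averages: sampling
units (pair RSMs, or runs/subjects) are drawn with replacement — with
probabilities proportional to importance weights when matching a motion
distribution across groups — averaged into a group RSM, and the statistic
of interest (a Spearman or partial Spearman correlation with a hypothesis
RSM) is evaluated on each resample. Confidence intervals are percentile
95% intervals of the resulting sampling distribution; group differences
test whether the CI of the difference distribution excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from devgeo.rsm import RSM, NoiseCeiling


@dataclass
class BootstrapResult:
    """Point estimate plus bootstrap sampling distribution and 95% CI."""

    point: float
    distribution: np.ndarray
    ci: tuple[float, float]
    n_boot: int
    seed: int | None
    weighting: str = "uniform"
    n_failures: int = 0
    flagged: bool = False

    def __post_init__(self) -> None:
        self.distribution = np.asarray(self.distribution, dtype=float)
        if self.distribution.size != self.n_boot:
            raise ValueError("distribution length must equal n_boot")
        if not (self.ci[0] - 1e-12 <= self.point <= self.ci[1] + 1e-12):
            self.flagged = True


@dataclass
class ImportanceWeights:
    """Per-unit resampling weights matching a target motion distribution."""

    weights: np.ndarray
    bin_edges: np.ndarray
    source_group: str = "source"
    target_group: str = "target"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        total = self.weights.sum()
        if total == 0:
            raise ValueError("no overlap between source and target motion bins")
        self.weights = self.weights / total


def _vectorize(m, include_diagonal: bool) -> np.ndarray:
    v = m.values if isinstance(m, RSM) else np.asarray(m, dtype=float)
    iu = np.triu_indices(v.shape[0], k=0 if include_diagonal else 1)
    return v[iu]


def rsa_correlation(brain, model, include_diagonal: bool = True) -> float:
    """Spearman correlation of the vectorized upper triangles of a brain
    RSM and a model RSM (diagonal included by default, the convention for
    feature RSA; exclude it for network-layer RSA)."""
    x = _vectorize(brain, include_diagonal)
    y = _vectorize(model, include_diagonal)
    if x.shape != y.shape:
        raise ValueError("RSMs are not conformable")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


def partial_rsa(
    brain,
    model,
    covariates: Sequence,
    include_diagonal: bool = True,
) -> float:
    """Partial Spearman correlation controlling for covariate RSMs.

    All vectors are rank-transformed; brain and model ranks are
    residualized on the covariate ranks (plus intercept) by least squares;
    the Pearson correlation of the residuals is returned. With no
    covariates this equals the plain Spearman correlation.
    """
    x = stats.rankdata(_vectorize(brain, include_diagonal))
    y = stats.rankdata(_vectorize(model, include_diagonal))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("partial Spearman undefined for a constant vector")
    covs = []
    for c in covariates:
        vc = _vectorize(c, include_diagonal)
        if np.ptp(vc) == 0:
            continue  # degenerate covariate dropped
        covs.append(stats.rankdata(vc))
    if not covs:
        r = np.corrcoef(x, y)[0, 1]
        return float(r)
    z = np.column_stack([np.ones_like(x)] + covs)
    rx = x - z @ np.linalg.lstsq(z, x, rcond=None)[0]
    ry = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
    if rx.std() < 1e-8 * x.std() or ry.std() < 1e-8 * y.std():
        raise ValueError("model is collinear with the covariates")
    return float(np.corrcoef(rx, ry)[0, 1])


def recover_mixture_weights(
    brain,
    models: dict[str, np.ndarray],
    include_diagonal: bool = True,
) -> dict[str, float]:
    """Least-squares mixture weights of model RSMs for a brain RSM.

    Regresses the vectorized brain RSM on the model RSMs jointly (with an
    intercept). Unlike a rank correlation — which saturates on block
    structure and is not monotone in generative weight — the regression
    coefficients estimate the additive mixture weights directly, so their
    rank ordering recovers the generative ordering.
    """
    y = _vectorize(brain, include_diagonal)
    names = list(models)
    x = np.column_stack(
        [np.ones_like(y)] + [_vectorize(models[n], include_diagonal) for n in names]
    )
    coef = np.linalg.lstsq(x, y, rcond=None)[0]
    return {n: float(c) for n, c in zip(names, coef[1:])}


def importance_weights(
    source_fwd: np.ndarray,
    target_fwd: np.ndarray,
    n_bins: int = 10,
    source_group: str = "source",
    target_group: str = "target",
) -> ImportanceWeights:
    """Motion-matching resampling weights.

    Units are binned by FWD on decile edges of the pooled source+target
    sample; a source unit in bin b gets weight proportional to
    target_count(b) / source_count(b), so resampling the source with these
    probabilities reproduces the target motion distribution. Units in bins
    absent from the target get weight 0.
    """
    src = np.asarray(source_fwd, dtype=float)
    tgt = np.asarray(target_fwd, dtype=float)
    if src.size == 0 or tgt.size == 0:
        raise ValueError("source and target samples must be non-empty")
    pooled = np.concatenate([src, tgt])
    uniq = np.unique(pooled)
    if uniq.size <= n_bins:
        # discrete motion summaries: each distinct value is its own bin
        edges = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]])
    else:
        edges = np.quantile(pooled, np.linspace(0, 1, n_bins + 1))
        edges = np.unique(edges)
        edges[0], edges[-1] = -np.inf, np.inf
    s_bin = np.digitize(src, edges[1:-1])
    t_bin = np.digitize(tgt, edges[1:-1])
    n_eff = edges.size - 1
    s_count = np.bincount(s_bin, minlength=n_eff).astype(float)
    t_count = np.bincount(t_bin, minlength=n_eff).astype(float)
    ratio = np.zeros(n_eff)
    nonzero = s_count > 0
    ratio[nonzero] = t_count[nonzero] / s_count[nonzero]
    return ImportanceWeights(
        weights=ratio[s_bin],
        bin_edges=edges,
        source_group=source_group,
        target_group=target_group,
    )


def bootstrap_statistic(
    units: Sequence,
    statistic: Callable[[np.ndarray], float],
    n_boot: int = 1000,
    seed: int | None = None,
    weights: ImportanceWeights | np.ndarray | None = None,
    exclude: np.ndarray | None = None,
    return_draws: bool = False,
) -> BootstrapResult:
    """Bootstrap a statistic of the unit-averaged RSM.

    Each resample draws len(units) units with replacement (probabilities
    proportional to ``weights`` when given; units flagged in ``exclude``
    — e.g. NICU graduates during motion matching — are removed first),
    averages them, and applies ``statistic`` to the averaged matrix. The
    CI is the percentile 95% interval. A statistic failure on a resample
    is recorded and the resample redrawn.
    """
    mats = np.stack(
        [u.values if isinstance(u, RSM) else np.asarray(u, dtype=float) for u in units]
    )
    n_units = mats.shape[0]
    if weights is not None:
        p = weights.weights if isinstance(weights, ImportanceWeights) else np.asarray(
            weights, dtype=float
        )
        p = p.copy()
        weighting = "importance"
    else:
        p = np.ones(n_units)
        weighting = "uniform"
    if exclude is not None:
        keep = ~np.asarray(exclude, dtype=bool)
        mats = mats[keep]
        p = p[keep]
        n_units = mats.shape[0]
    if n_units < 2:
        raise ValueError("bootstrap needs >= 2 units")
    p = p / p.sum()

    rng = np.random.default_rng(seed)
    shape = mats.shape[1:]
    flat = mats.reshape(n_units, -1)
    point = float(statistic((p @ flat).reshape(shape)))

    dist = np.empty(n_boot)
    draws = np.empty((n_boot, n_units), dtype=np.int64) if return_draws else None
    n_failures = 0
    b = 0
    while b < n_boot:
        idx = rng.choice(n_units, size=n_units, p=p)
        mean = flat[idx].mean(axis=0).reshape(shape)
        try:
            dist[b] = statistic(mean)
        except Exception:
            n_failures += 1
            if n_failures > 100 * n_boot:
                raise RuntimeError("statistic failed on too many resamples")
            continue
        if return_draws:
            draws[b] = idx
        b += 1
    ci = (float(np.percentile(dist, 2.5)), float(np.percentile(dist, 97.5)))
    res = BootstrapResult(
        point=point,
        distribution=dist,
        ci=ci,
        n_boot=n_boot,
        seed=seed,
        weighting=weighting,
        n_failures=n_failures,
    )
    if return_draws:
        res.draws = draws
    return res


def bootstrap_statistic_subjects(
    pair_rsms: Sequence,
    statistic: Callable[[np.ndarray], float],
    n_boot: int = 1000,
    seed: int | None = None,
    subject_weights: dict[str, float] | None = None,
) -> BootstrapResult:
    """Bootstrap a pair-averaged statistic by resampling *subjects*.

    Pair RSMs are dependent (two pairs can share a subject), so treating
    them as i.i.d. resampling units understates the sampling variance of
    their average. Here whole subjects are drawn with replacement and the
    group RSM is recomputed as the multiplicity-weighted average of the
    pair RSMs among resampled subjects (same-subject duplicates
    contribute no pair). Pair provenance must carry subject identities.
    """
    subs = sorted(
        {
            uid[0]
            for pr in pair_rsms
            for pair in (pr.provenance if isinstance(pr.provenance, list) else [])
            for uid in pair
        }
    )
    if len(subs) < 2:
        raise ValueError("pair RSMs must carry subject provenance (>= 2 subjects)")
    index = {sid: k for k, sid in enumerate(subs)}
    n_sub = len(subs)
    flat = np.stack(
        [
            (pr.values if isinstance(pr, RSM) else np.asarray(pr)).ravel()
            for pr in pair_rsms
        ]
    )
    shape = (
        pair_rsms[0].values.shape
        if isinstance(pair_rsms[0], RSM)
        else np.asarray(pair_rsms[0]).shape
    )
    ii = np.array([index[pr.provenance[0][0][0]] for pr in pair_rsms])
    jj = np.array([index[pr.provenance[0][1][0]] for pr in pair_rsms])
    if subject_weights is not None:
        p = np.array([subject_weights.get(sid, 0.0) for sid in subs], dtype=float)
        if p.sum() == 0:
            raise ValueError("all subject weights are zero")
        p = p / p.sum()
        weighting = "importance"
    else:
        p = np.full(n_sub, 1.0 / n_sub)
        weighting = "uniform"

    point = float(statistic(flat.mean(axis=0).reshape(shape)))
    rng = np.random.default_rng(seed)
    dist = np.empty(n_boot)
    n_failures = 0
    b = 0
    while b < n_boot:
        counts = np.bincount(rng.choice(n_sub, size=n_sub, p=p), minlength=n_sub)
        w = (counts[ii] * counts[jj]).astype(float)
        total = w.sum()
        if total == 0:  # all mass on one subject: no cross-subject pair
            n_failures += 1
            continue
        try:
            dist[b] = statistic(((w @ flat) / total).reshape(shape))
        except Exception:
            n_failures += 1
            if n_failures > 100 * n_boot:
                raise RuntimeError("statistic failed on too many resamples")
            continue
        b += 1
    ci = (float(np.percentile(dist, 2.5)), float(np.percentile(dist, 97.5)))
    return BootstrapResult(
        point=point,
        distribution=dist,
        ci=ci,
        n_boot=n_boot,
        seed=seed,
        weighting=weighting,
        n_failures=n_failures,
    )


def group_difference(
    result_a: BootstrapResult, result_b: BootstrapResult, seed: int | None = None
) -> tuple[tuple[float, float], bool, np.ndarray]:
    """Difference of two bootstrap sampling distributions.

    Returns the percentile 95% CI of (A - B), whether it excludes zero,
    and the difference distribution. Distributions of unequal length are
    resampled to a common length first.
    """
    a, b = result_a.distribution, result_b.distribution
    if a.size != b.size:
        rng = np.random.default_rng(seed)
        m = max(a.size, b.size)
        a = rng.choice(a, size=m)
        b = rng.choice(b, size=m)
    diff = a - b
    ci = (float(np.percentile(diff, 2.5)), float(np.percentile(diff, 97.5)))
    significant = bool(ci[0] > 0 or ci[1] < 0)
    return ci, significant, diff


def normalize_by_ceiling(
    rho: float, ceiling: NoiseCeiling, floor: float = 0.1
) -> tuple[float, bool]:
    """Express a correlation as a proportion of the noise ceiling.

    When the ceiling is unreliable (below ``floor``, as in regions lacking
    consistent group signal) the raw value is returned, flagged invalid —
    dividing by a near-zero ceiling would be meaningless.
    """
    if ceiling.corrected >= floor:
        return rho / ceiling.corrected, True
    return rho, False


def maturity_correlation(
    infant_units: Sequence,
    adult_group_rsm,
    n_boot: int = 1000,
    seed: int | None = None,
    include_diagonal: bool = False,
    weights: ImportanceWeights | np.ndarray | None = None,
) -> BootstrapResult:
    """Correlation of the (resampled) infant group RSM with the fixed
    adult group RSM — resampling across infants only."""
    adult = (
        adult_group_rsm.values
        if isinstance(adult_group_rsm, RSM)
        else np.asarray(adult_group_rsm)
    )

    def stat(mean_rsm: np.ndarray) -> float:
        return rsa_correlation(mean_rsm, adult, include_diagonal=include_diagonal)

    return bootstrap_statistic(
        infant_units, stat, n_boot=n_boot, seed=seed, weights=weights
    )


def longitudinal_permutation_test(
    rsms_t1: dict[str, np.ndarray],
    rsms_t2: dict[str, np.ndarray],
    links: dict[str, str],
    n_perm: int = 1000,
    seed: int | None = None,
    include_diagonal: bool = False,
) -> tuple[float, float, np.ndarray]:
    """Within-subject representational stability across two timepoints.

    Observed statistic: mean over linked subjects of the Spearman
    correlation between a subject's RSM at t1 and the same subject's RSM
    at t2. The null relinks t1 subjects to random t2 subjects (derangement
    not enforced); p = (1 + #{null >= observed}) / (1 + n_perm), the
    add-one Monte Carlo rule. Returns (p, observed, null distribution).
    """
    if len(set(links.values())) != len(links):
        raise ValueError("duplicate longitudinal links")
    ids1 = sorted(links)
    if len(ids1) < 5:
        raise ValueError("permutation test needs >= 5 linked subjects")
    v1 = [stats.rankdata(_vectorize(rsms_t1[i], include_diagonal)) for i in ids1]
    v2 = [
        stats.rankdata(_vectorize(rsms_t2[links[i]], include_diagonal)) for i in ids1
    ]
    v1 = np.stack(v1)
    v2 = np.stack(v2)

    def mean_rho(perm: np.ndarray) -> float:
        a = v1 - v1.mean(axis=1, keepdims=True)
        b = v2[perm] - v2[perm].mean(axis=1, keepdims=True)
        num = (a * b).sum(axis=1)
        den = np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
        return float(np.mean(num / den))

    observed = mean_rho(np.arange(len(ids1)))
    rng = np.random.default_rng(seed)
    null = np.array(
        [mean_rho(rng.permutation(len(ids1))) for _ in range(n_perm)]
    )
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return float(p), observed, null
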