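"""Stress-minimizing MDS with hierarchical alignment across conditions.

Embeddings are fit with the SMACOF majorization algorithm (metric stress,
Guttman transform), which guarantees monotonically non-increasing stress
across iterations. To make embeddings comparable across regions and age
groups, fits are aligned hierarchically: a global configuration is fit on
the mean dissimilarity over all (region, age) cells, then refined per
region (collapsed over ages), then per (region, age) — each refinement
warm-started from its parent configuration rather than re-randomized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from devgeo.rsm import RSM


@dataclass
class Embedding:
    """A 2-D (or k-D) configuration with its stress trajectory."""

    coords: np.ndarray
    stress: float  # normalized stress-1
    raw_stress_history: list[float] = field(default_factory=list)
    n_iter: int = 0
    parent: str | None = None


def rsm_to_dissimilarity(rsm) -> np.ndarray:
    """max-minus conversion of a similarity RSM to dissimilarities.

    d = max(M) - M, diagonal zeroed; preserves the rank order of
    similarities and yields a symmetric non-negative matrix.
    """
    m = rsm.values if isinstance(rsm, RSM) else np.asarray(rsm, dtype=float)
    if np.abs(m - m.T).max() > 1e-10:
        raise ValueError("RSM must be symmetric")
    d = m.max() - m
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def _stress(d_target: np.ndarray, coords: np.ndarray) -> tuple[float, np.ndarray]:
    diff = coords[:, None, :] - coords[None, :, :]
    d_emb = np.sqrt((diff**2).sum(axis=-1))
    iu = np.triu_indices(d_target.shape[0], k=1)
    raw = float(((d_target[iu] - d_emb[iu]) ** 2).sum())
    return raw, d_emb


def classical_mds(dissimilarity: np.ndarray, n_dim: int = 2) -> np.ndarray:
    """Torgerson classical scaling: eigendecomposition of the
    double-centered squared dissimilarities. Exact for Euclidean inputs;
    the standard SMACOF initialization otherwise."""
    d = np.asarray(dissimilarity, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:n_dim]
    return vecs[:, order] * np.sqrt(np.clip(vals[order], 0.0, None))


def smacof_embed(
    dissimilarity: np.ndarray,
    n_dim: int = 2,
    init: np.ndarray | str | None = "classical",
    max_iter: int = 300,
    tol: float = 1e-9,
    seed: int | None = None,
    parent: str | None = None,
) -> Embedding:
    """Metric SMACOF: minimize stress by iterated Guttman transforms.

    Starts from ``init``: an explicit configuration (warm start),
    'classical' for Torgerson scaling (the default), or None for a seeded
    random configuration. Stops when the relative drop in raw stress
    falls below ``tol`` or after ``max_iter`` iterations. Reports
    normalized stress-1 = sqrt(raw stress / sum of squared
    dissimilarities).
    """
    d = np.asarray(dissimilarity, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("dissimilarity must be square")
    if n_dim >= n:
        raise ValueError("n_dim must be smaller than the number of points")
    if isinstance(init, str):
        if init != "classical":
            raise ValueError("init must be an array, 'classical' or None")
        x = classical_mds(d, n_dim)
    elif init is not None:
        x = np.array(init, dtype=float)
        if x.shape != (n, n_dim):
            raise ValueError("init has the wrong shape")
    else:
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((n, n_dim)) * d.max() / max(n, 1)

    iu = np.triu_indices(n, k=1)
    denom = float((d[iu] ** 2).sum())
    history = []
    raw, d_emb = _stress(d, x)
    for it in range(max_iter):
        history.append(raw)
        # Guttman transform with uniform weights: X <- (1/n) B(X) X
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d_emb > 0, d / d_emb, 0.0)
        b = -ratio
        np.fill_diagonal(b, 0.0)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = (b @ x) / n
        new_raw, d_emb = _stress(d, x)
        if raw - new_raw < tol * max(raw, 1e-30):
            raw = new_raw
            history.append(raw)
            break
        raw = new_raw
    stress1 = float(np.sqrt(raw / denom)) if denom > 0 else 0.0
    return Embedding(
        coords=x,
        stress=stress1,
        raw_stress_history=history,
        n_iter=len(history) - 1,
        parent=parent,
    )


def hierarchical_embed(
    rsms: dict[tuple[str, str], RSM | np.ndarray],
    n_dim: int = 2,
    seed: int | None = 0,
    max_iter: int = 300,
    tol: float = 1e-9,
) -> dict[str, dict]:
    """Three-stage aligned embeddings over (region, age) cells.

    Stage 1 fits one global configuration on the mean dissimilarity over
    all cells; stage 2 refines per region on the mean over that region's
    ages, warm-started from stage 1; stage 3 refines per (region, age),
    warm-started from its region's stage-2 configuration. Returns
    {'global': Embedding, 'roi': {roi: Embedding},
    'cell': {(roi, age): Embedding}}.
    """
    if not rsms:
        raise ValueError("no RSMs given")
    diss = {key: rsm_to_dissimilarity(m) for key, m in rsms.items()}
    shapes = {d.shape for d in diss.values()}
    if len(shapes) != 1:
        raise ValueError("all RSMs must share the condition set")

    global_d = np.mean(list(diss.values()), axis=0)
    stage1 = smacof_embed(
        global_d, n_dim=n_dim, seed=seed, max_iter=max_iter, tol=tol
    )

    rois = sorted({roi for roi, _ in diss})
    stage2: dict[str, Embedding] = {}
    for roi in rois:
        roi_d = np.mean([d for (r, _), d in diss.items() if r == roi], axis=0)
        stage2[roi] = smacof_embed(
            roi_d,
            n_dim=n_dim,
            init=stage1.coords,
            max_iter=max_iter,
            tol=tol,
            parent="global",
        )

    stage3: dict[tuple[str, str], Embedding] = {}
    for (roi, age), d in diss.items():
        stage3[(roi, age)] = smacof_embed(
            d,
            n_dim=n_dim,
            init=stage2[roi].coords,
            max_iter=max_iter,
            tol=tol,
            parent=f"roi:{roi}",
        )
    return {"global": stage1, "roi": stage2, "cell": stage3}


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Disparity between two configurations after optimal similarity
    alignment (translation, rotation/reflection, scale)."""
    from scipy.spatial import procrustes

    _, _, disparity = procrustes(a, b)
    return float(disparity)
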