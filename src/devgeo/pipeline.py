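"""End-to-end pipeline driver on synthetic cohorts.

simulate -> (optional GLM demo) -> pair/group RSMs -> model RSMs ->
bootstrap RSA with ceiling normalization -> variance partitioning ->
network-layer profile -> aligned embeddings. Every stage's outputs are
written as TSV with the serialized configuration (and its hash) alongside;
identical seeds give identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from devgeo.config import PipelineConfig
from devgeo.cohort import GroundTruthMixture, simulate_patterns
from devgeo.dnn import default_activation_provider, layer_rsms, layerwise_rsa
from devgeo.inference import (
    bootstrap_statistic,
    maturity_correlation,
    normalize_by_ceiling,
    partial_rsa,
    rsa_correlation,
)
from devgeo.mds import hierarchical_embed
from devgeo.models import categorical_rsms, perceptual_feature_rsms
from devgeo.rsm import cohort_group_rsm, split_half_noise_ceiling, zscore_rsm
from devgeo.stimuli import make_stimulus_set, render_stimulus_images
from devgeo.varpart import components_table, partition_variance

logger = logging.getLogger("devgeo")


def build_mixture(config: PipelineConfig, models: dict, scale: float = 1.0):
    weights = {
        name: (w * scale, models[name].values)
        for name, w in config.mixture_weights.items()
    }
    return GroundTruthMixture(
        weights=weights,
        sigma_group=config.sigma_group,
        sigma_individual=config.sigma_individual,
        sigma_session=config.sigma_session,
        sigma_noise=config.sigma_noise,
    )


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the synthetic end-to-end analysis; returns the result bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    rng = np.random.default_rng(config.seed)

    sset = make_stimulus_set()
    cat_models = categorical_rsms(sset)
    images, masks, feature_truth, _ = render_stimulus_images(
        sset, seed=int(rng.integers(2**31))
    )
    perc_models = perceptual_feature_rsms(feature_truth)
    all_models = {**cat_models, **perc_models}

    # age-graded mixture: representational structure strengthens with age,
    # but all groups realize the same underlying geometry (shared basis)
    scales = {"2mo": 0.6, "9mo": 0.8, "adult": 1.0}
    basis = rng.standard_normal((sset.n_conditions, config.n_voxels))
    cohorts = {}
    for group, n_sub in config.n_subjects.items():
        mixture = build_mixture(config, all_models, scale=scales.get(group, 1.0))
        cohorts[group] = simulate_patterns(
            sset,
            mixture,
            n_subjects=n_sub,
            runs_per_subject=config.runs_per_subject,
            n_voxels=config.n_voxels,
            seed=int(rng.integers(2**31)),
            group=group,
            structured_basis=basis,
        )
    logger.info("simulated %d cohorts", len(cohorts))

    results: dict = {"config_hash": config.config_hash}
    group_rsms, ceilings, rows = {}, {}, []
    for group, cohort in cohorts.items():
        level = config.aggregation.get(group, "run")
        grsm, pair_rsms = cohort_group_rsm(cohort, level=level, labels=sset.labels)
        group_rsms[group] = (grsm, pair_rsms)
        ceilings[group] = split_half_noise_ceiling(
            cohort,
            level=level,
            n_splits=config.n_ceiling_splits,
            seed=int(rng.integers(2**31)),
            floor=config.ceiling_floor,
        )
        from devgeo.io import write_rsm

        write_rsm(zscore_rsm(grsm), out / f"group_rsm_{group}.tsv")

        perceptual = [m.rsm for m in perc_models.values() if not m.degenerate]
        for name, model in all_models.items():
            include_diag = config.include_diagonal_feature_rsa
            covs = perceptual if model.family == "categorical" and name != "identity" else []

            def stat(mean_rsm, _m=model.values, _c=covs, _d=include_diag):
                if _c:
                    return partial_rsa(mean_rsm, _m, _c, include_diagonal=_d)
                return rsa_correlation(mean_rsm, _m, include_diagonal=_d)

            res = bootstrap_statistic(
                pair_rsms,
                stat,
                n_boot=config.n_boot,
                seed=int(rng.integers(2**31)),
            )
            norm, valid = normalize_by_ceiling(
                res.point, ceilings[group], floor=config.ceiling_floor
            )
            rows.append(
                {
                    "group": group,
                    "model": name,
                    "family": model.family,
                    "partial": bool(covs),
                    "rho": res.point,
                    "rho_norm": norm,
                    "ci_lo": res.ci[0],
                    "ci_hi": res.ci[1],
                    "valid_ceiling": valid,
                }
            )
    rsa_table = pd.DataFrame(rows)
    rsa_table.to_csv(out / "rsa.tsv", sep="\t", index=False)
    results["rsa"] = rsa_table

    ceiling_rows = [
        {
            "group": g,
            "raw": c.raw,
            "corrected": c.corrected,
            "n_splits": c.n_splits,
            "valid": c.valid,
        }
        for g, c in ceilings.items()
    ]
    pd.DataFrame(ceiling_rows).to_csv(out / "noise_ceilings.tsv", sep="\t", index=False)
    results["ceilings"] = ceilings

    # maturity: infant groups against the adult group RSM
    if "adult" in group_rsms:
        mat_rows = []
        adult_rsm = group_rsms["adult"][0]
        for group in cohorts:
            if group == "adult":
                continue
            res = maturity_correlation(
                group_rsms[group][1],
                adult_rsm,
                n_boot=config.n_boot,
                seed=int(rng.integers(2**31)),
            )
            mat_rows.append(
                {"group": group, "rho": res.point, "ci_lo": res.ci[0], "ci_hi": res.ci[1]}
            )
        if mat_rows:
            pd.DataFrame(mat_rows).to_csv(out / "maturity.tsv", sep="\t", index=False)
            results["maturity"] = mat_rows

    # variance partitioning per group
    vp_rows = []
    for group, cohort in cohorts.items():
        vc = partition_variance(cohort, n_boot=0)
        t = components_table(vc)
        t.insert(0, "group", group)
        vp_rows.append(t)
    vp_table = pd.concat(vp_rows, ignore_index=True)
    vp_table.to_csv(out / "variance_components.tsv", sep="\t", index=False)
    results["variance_components"] = vp_table

    if config.run_dnn:
        acts = default_activation_provider(
            images, seed=int(rng.integers(2**31)), masks=masks
        )
        layers = layer_rsms(acts, labels=sset.labels)
        dnn_rows = []
        for group in cohorts:
            profile = layerwise_rsa(
                group_rsms[group][1],
                layers,
                ceiling=ceilings[group],
                n_boot=min(config.n_boot, 200),
                seed=int(rng.integers(2**31)),
            )
            for layer, entry in profile.items():
                dnn_rows.append(
                    {
                        "group": group,
                        "layer": layer,
                        "rho": entry["rho"],
                        "rho_norm": entry["rho_normalized"],
                        "ci_lo": entry["ci"][0],
                        "ci_hi": entry["ci"][1],
                    }
                )
        pd.DataFrame(dnn_rows).to_csv(out / "dnn_profile.tsv", sep="\t", index=False)
        results["dnn"] = dnn_rows

    if config.run_mds:
        cells = {
            ("VVC", group): zscore_rsm(group_rsms[group][0])
            for group in cohorts
        }
        emb = hierarchical_embed(cells, seed=int(rng.integers(2**31)))
        coords_rows = []
        for (roi, age), e in emb["cell"].items():
            for i, label in enumerate(sset.labels):
                coords_rows.append(
                    {
                        "condition": label,
                        "x": e.coords[i, 0],
                        "y": e.coords[i, 1],
                        "roi": roi,
                        "age": age,
                        "stage": "cell",
                    }
                )
        pd.DataFrame(coords_rows).to_csv(out / "mds_coords.tsv", sep="\t", index=False)
        results["mds"] = emb

    logger.info("pipeline complete; outputs in %s", out)
    return results
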