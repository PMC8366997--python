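"""End-to-end pipeline: simulate -> preprocess -> network -> cluster ->
outcomes -> variable networks -> validation, with a content-hash manifest.

Every stage writes its artifacts into the run directory and records a
SHA-256 hash in ``manifest.json``; re-running with the same config
reproduces the hashes of all deterministic stages.  A single global seed
is fanned out to the stages through a counter-based scheme so each stage
is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from psnrisk._seeds import child_seed
from psnrisk.clustering import fit_kmeans, select_k, stability_analysis
from psnrisk.config import RunConfig
from psnrisk.network import build_network, select_density_cutoff, similarity_matrix
from psnrisk.outcomes import (
    NT_PROBNP_BINS,
    TROPONIN_T_BINS,
    biomarker_km,
    chi2_enrichment,
    classify_events,
    cox_hr,
    cumulative_hazard_by_group,
    encode_subgroups,
    km_by_group,
    period_breakdown,
)
from psnrisk.preprocess import build_feature_matrix, impute_and_scale, remove_outliers
from psnrisk.synthetic import VARIABLES, generate_cohort, variable_categories
from psnrisk.validation import SplitPlan, run_split_validation
from psnrisk.varnet import (
    aggregate_derived_family,
    cluster_pcc,
    cluster_variables,
    collinearity_summary,
    topk_edges,
)

log = logging.getLogger(__name__)

CONFOUNDERS = ["age", "sex_female", "tumor_hematologic", "tumor_stage"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig, outdir: str | Path) -> dict[str, str]:
    """Run every stage, writing artifacts and a hash manifest to ``outdir``.

    Returns the manifest (relative artifact path -> SHA-256).  On stage
    failure the partial manifest is still written before the exception
    propagates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def record(path: Path) -> None:
        manifest[str(path.relative_to(outdir))] = _sha256(path)

    def flush() -> None:
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )

    try:
        # --- simulate -----------------------------------------------------
        cohort_cfg = dataclasses.replace(
            config.cohort, seed=child_seed(config.seed, "cohort", config.cohort.seed)
        )
        cohort = generate_cohort(cohort_cfg)
        for p in cohort.write(outdir).values():
            record(p)
        log.info("simulated %d patients", cohort_cfg.n_patients)

        # --- preprocess ---------------------------------------------------
        raw = build_feature_matrix(
            cohort.measurements, cohort.static, window_days=config.window_days
        )
        features = impute_and_scale(remove_outliers(raw, config.z_limit))
        features.write(outdir / "features.csv", outdir / "features_meta.json")
        record(outdir / "features.csv")
        record(outdir / "features_meta.json")

        # --- patient network ----------------------------------------------
        sim = similarity_matrix(features, config.metric)
        np.save(outdir / "similarity.npy", sim.values)
        record(outdir / "similarity.npy")
        lo, hi, step = config.cutoff_grid
        cutoff, profile = select_density_cutoff(sim, grid_step=step, grid_range=(lo, hi))
        profile.to_csv(outdir / "density_profile.csv", index=False)
        record(outdir / "density_profile.csv")
        net = build_network(sim, cutoff)
        net.write(outdir)
        record(outdir / "patient_network_edges.tsv")
        record(outdir / "patient_network.graphml")
        log.info("density-argmin cutoff %.2f (density %.4g)", cutoff, net.density)

        # --- clustering ---------------------------------------------------
        outcome_table = classify_events(
            cohort.events, cohort.static.set_index("patient_id")["cancer_dx_days"]
        )
        if config.k == "auto":
            k_sel, k_report = select_k(
                sim,
                outcome_table,
                k_range=config.k_range,
                alpha=config.alpha,
                seed=child_seed(config.seed, "select_k"),
            )
            k_report.to_csv(outdir / "k_selection.csv", index=False)
            record(outdir / "k_selection.csv")
            if k_sel is None:
                raise RuntimeError("no K qualified in select_k (strict mode)")
            k = k_sel
        else:
            k = int(config.k)
        model = fit_kmeans(sim, k, seed=child_seed(config.seed, "kmeans"))
        model.labels.rename_axis("patient_id").to_csv(outdir / "clusters.csv")
        model.to_json(outdir / "model.json")
        record(outdir / "clusters.csv")
        record(outdir / "model.json")
        stab = stability_analysis(
            sim, k, n_runs=config.n_stability_runs,
            base_seed=child_seed(config.seed, "stability"),
        )
        stab.runs.to_csv(outdir / "stability.csv", index=False)
        record(outdir / "stability.csv")
        ari_truth = float(
            adjusted_rand_score(
                cohort.truth_labels.loc[model.labels.index].to_numpy(),
                model.labels.to_numpy(),
            )
        )

        # --- outcomes -------------------------------------------------
        frame = outcome_table.frame.loc[model.labels.index]
        groups = model.labels.to_numpy()
        os_res = km_by_group(
            frame["os_time_years"].to_numpy(), frame["death"].to_numpy(), groups
        )
        dn_res = cumulative_hazard_by_group(
            frame["denovo_time_years"].to_numpy(), frame["denovo_event"].to_numpy(), groups
        )
        curve_rows = []
        for endpoint, res in (("survival", os_res), ("denovo_cumhaz", dn_res)):
            for lev, cdf in res.curves.items():
                c = cdf.copy()
                c.insert(0, "cluster", lev)
                c.insert(0, "endpoint", endpoint)
                curve_rows.append(c)
        pd.concat(curve_rows).to_csv(outdir / "survival_curves.csv", index=False)
        record(outdir / "survival_curves.csv")

        # reference subgroup = lowest de novo event rate
        rates = frame.groupby(groups)["de_novo_ctrcd"].mean()
        reference = rates.idxmin()
        hr_rows = []
        for endpoint, dur, evt in (
            ("denovo", "denovo_time_years", "denovo_event"),
            ("survival", "os_time_years", "death"),
        ):
            data = pd.concat(
                [
                    frame[[dur, evt]],
                    encode_subgroups(model.labels, reference),
                    cohort.static.set_index("patient_id").loc[frame.index, CONFOUNDERS],
                ],
                axis=1,
            )
            for est in cox_hr(data, dur, evt):
                hr_rows.append(
                    {
                        "endpoint": endpoint,
                        "covariate": est.covariate,
                        "hr": est.hr,
                        "ci_lo": est.ci95[0],
                        "ci_hi": est.ci95[1],
                        "p": est.p,
                    }
                )
        pd.DataFrame(hr_rows).to_csv(outdir / "hazard_ratios.csv", index=False)
        record(outdir / "hazard_ratios.csv")

        chi2_enrichment(groups, frame["de_novo_ctrcd"].to_numpy()).to_csv(
            outdir / "enrichment.csv", index=False
        )
        record(outdir / "enrichment.csv")
        period_breakdown(outcome_table, model.labels).to_csv(
            outdir / "period_breakdown.csv", index=False
        )
        record(outdir / "period_breakdown.csv")

        bm_rows = []
        for bm_col, edges_def, bm_name in (
            ("nt_probnp__max", NT_PROBNP_BINS, "nt_probnp"),
            ("troponin_t__max", TROPONIN_T_BINS, "troponin_t"),
        ):
            if bm_col not in raw.values.columns:
                continue
            bm = raw.values[bm_col].dropna()
            _, hrs = biomarker_km(outcome_table, bm, edges_def)
            for est in hrs:
                bm_rows.append(
                    {
                        "biomarker": bm_name,
                        "bin": est.covariate,
                        "hr": est.hr,
                        "ci_lo": est.ci95[0],
                        "ci_hi": est.ci95[1],
                        "p": est.p,
                    }
                )
        pd.DataFrame(bm_rows).to_csv(outdir / "biomarker_hr.csv", index=False)
        record(outdir / "biomarker_hr.csv")

        # --- variable networks ----------------------------------------
        cats = variable_categories()
        indicator_cols = {"sex_female", "tumor_hematologic"}
        noncat = [c for c in features.values.columns if c.split("__")[0] not in indicator_cols]
        families = {
            base: [f"{base}__{s}" for s in ("max", "min", "slope", "max_increase_3mo", "max_decrease_3mo")]
            for base in VARIABLES
        }
        degree_profiles = {}
        for lev in sorted(model.labels.unique()):
            sub = features.values.loc[model.labels.index[model.labels == lev], noncat]
            r, p = cluster_pcc(sub)
            r2, p2 = aggregate_derived_family(r, p, families)
            vn = topk_edges(r2, p2, fraction=config.varnet_fraction,
                            categories=cats, cluster_id=lev)
            vn.write(outdir)
            record(outdir / f"varnet_{lev}_edges.tsv")
            record(outdir / f"varnet_{lev}.graphml")
            degree_profiles[f"cluster_{lev}"] = vn.nodes["degree"]
        deg = pd.DataFrame(degree_profiles).fillna(0)
        z, leaves, _ = cluster_variables(deg)
        (outdir / "variable_dendrogram.json").write_text(
            json.dumps({"linkage": z.tolist(), "leaf_order": leaves}, indent=2) + "\n"
        )
        record(outdir / "variable_dendrogram.json")
        frac_low, corr = collinearity_summary(features.values)
        corr.round(6).to_csv(outdir / "collinearity.csv")
        record(outdir / "collinearity.csv")

        # --- validation -----------------------------------------------
        plan = SplitPlan(
            mode=config.split_mode,
            fractions=config.split_fractions,
            n_repeats=config.split_repeats,
            seed=child_seed(config.seed, "validation"),
        )
        vrep = run_split_validation(
            cohort, outcome_table, plan, k=k, metric=config.metric,
            window_days=config.window_days, z_limit=config.z_limit,
        )
        summary = {
            "k": k,
            "density_cutoff": cutoff,
            "density_at_cutoff": net.density,
            "ari_vs_truth": ari_truth,
            "stability_n_stable": stab.n_stable,
            "stability_n_runs": int(config.n_stability_runs),
            "omnibus_logrank_p_survival": os_res.omnibus_p,
            "omnibus_logrank_p_denovo": dn_res.omnibus_p,
            "collinearity_fraction_below_0.25": frac_low,
            "validation": vrep.to_frame().to_dict(orient="records"),
        }
        (outdir / "validation_report.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=float) + "\n"
        )
        record(outdir / "validation_report.json")
        config.to_json(outdir / "run_config.json")
        record(outdir / "run_config.json")
    finally:
        flush()
    return manifest
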