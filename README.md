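# psnrisk

Unsupervised cardiovascular-risk stratification of cancer patients from
longitudinal clinical records, using patient–patient similarity
networks.

Cancer therapy can injure the heart; a sizeable fraction of cancer
survivors develop cardiac dysfunction (atrial fibrillation, coronary
disease, heart failure, myocardial infarction, stroke) during or after
treatment, and single echo measures such as a drop in LVEF flag the risk
too late. `psnrisk` addresses the question a cardio-oncology service
actually faces: given routinely collected longitudinal labs and
echocardiograms, can patients be grouped — without outcome labels — into
subgroups whose subsequent cardiac-event and survival experience differs
enough to guide surveillance?

The pipeline, for a cohort of n patients with p derived clinical
variables:

1. **Features.** Each longitudinal variable is summarized per patient by
   max, min, the OLS slope against time, and the maximum increase and
   decrease within any 3-month window; features are outlier-blanked,
   mean-imputed and z-scored.
2. **Similarity.** Pairwise cosine similarity
   `cos(A, B) = Σᵢ AᵢBᵢ / (√Σ Aᵢ² √Σ Bᵢ²)` over the p-dimensional
   feature vectors gives a dense n×n matrix; a density-minimizing cutoff
   is scanned for network export.
3. **Subgroups.** K-means on each patient's *similarity profile* (their
   row of the full matrix), with SSE `Σᵢ (Xᵢ − X̄)²`, K selected by
   clinical separability (omnibus + BH-adjusted pairwise log-rank on
   both endpoints across a range of K), and stability checked over 100
   random restarts (ARI/AMI against the lowest-SSE run).
4. **Clinical validation.** Kaplan–Meier and Nelson–Aalen curves,
   log-rank tests with Benjamini–Hochberg adjustment, Cox hazard ratios
   against the lowest-risk subgroup, chi-square enrichment, period
   breakdowns and biomarker-threshold (NT-proBNP, Troponin T) survival.
5. **Interpretation.** Per-subgroup variable–variable correlation
   networks (top 15% of |PCC| pairs), ranked by degree and betweenness
   centrality.
6. **Generalizability.** Random- and time-split train/test validation
   with strict train-only preprocessing, plus IPCW time-dependent AUROC.

A seeded synthetic-cohort generator (`psnrisk.synthetic`) emulates the
statistical structure such an analysis assumes — latent subgroups with
graded biomarker levels and cause-specific hazards, irregular visit
schedules, MCAR missingness, right censoring — so the whole pipeline is
verifiable end to end. See `docs/methods.md` for the model and every
default.

## Worked example

Run the full pipeline on a 500-patient synthetic cohort:

```python
from psnrisk.config import CohortConfig, RunConfig
from psnrisk.pipeline import run_all

cfg = RunConfig(cohort=CohortConfig(n_patients=500), seed=7,
                n_stability_runs=20, split_repeats=1)
run_all(cfg, "demo_run")
```

(the same run from the shell: save `cfg.to_json("run.json")` and invoke
`psnrisk all --config run.json --out demo_run`).

`demo_run/validation_report.json` then contains (actual output):

```json
{
  "k": 4,
  "ari_vs_truth": 0.8496,
  "stability_n_stable": 20,
  "stability_n_runs": 20,
  "density_cutoff": 0.45,
  "omnibus_logrank_p_survival": 5.6e-17,
  "omnibus_logrank_p_denovo": 8.5e-26,
  "validation": [{"split": "random_0", "n_test": 250,
                  "logrank_p_survival": 3.4e-10,
                  "logrank_p_denovo": 2.2e-11,
                  "ari_vs_truth": 0.7496}]
}
```

Reading this: k-means on the similarity profiles recovered the four
planted subgroups with adjusted Rand index 0.85 against the generator's
truth labels; all 20 random-restart fits agreed with the best fit; the
four subgroups' overall survival and de novo cardiac-event curves
separate at vanishing log-rank p; and on a held-out random half of the
cohort — preprocessed and profiled strictly against the training half —
the subgroup assignment still separates both endpoints (p < 1e-9).
The run directory also holds the fitted cluster model, survival curves,
hazard ratios, per-subgroup variable networks (GraphML + edge lists)
and a SHA-256 manifest; re-running with the same config reproduces the
manifest byte for byte.

Individual stages are available as subcommands (`simulate`,
`preprocess`, `network`, `cluster`, `outcomes`, `validate`) and as plain
library functions.

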