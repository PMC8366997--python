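# Methods

`psnrisk` implements unsupervised cardiovascular-risk stratification for
cancer cohorts with patient–patient similarity networks, together with a
synthetic cohort generator that makes every stage testable without
access to protected health data. This note records the model, the
default parameters and the design decisions, in the order the pipeline
runs them.

## Synthetic cohort model

Each patient belongs to one of `n_subgroups` latent subgroups (default
4, multinomial with equal proportions). A subgroup determines three
things: the mean levels of a set of signal variables, the cause-specific
hazards of five cardiac event types (AF, CAD, HF, MI, stroke), and the
all-cause death hazard.

**Longitudinal trajectories.** Every longitudinal variable follows a
per-patient linear trajectory

    value(t) = baseline + slope * t + noise(t),

with `baseline ~ N(mu_v + shift_gv, sigma_v^2)` and visit-level Gaussian
noise (`measurement_noise`, default 0.30 in units of `sigma_v`). The
subgroup mean shift is `shift_gv = feature_shift * P[g, v] * sigma_v`,
where `P` is a fixed pattern matrix and `feature_shift` (default 1.5,
z-units of the within-subgroup sd) is the master effect-size dial; at
`feature_shift = 0` no structure is planted (including the subgroup
slope drift, which scales with it).

The pattern matrix deserves comment because it is where the planted
geometry lives. The two cardiac biomarkers (NT-proBNP, Troponin T) rise
monotonically with subgroup event risk (multipliers −1.5, −0.5, 0.5,
1.5), which keeps guideline-threshold analyses meaningful. The
remaining signal variables (creatinine, LVEF, BMI, and weaker loadings
on LV volumes, E/e′, left-atrial diameter, heart rate and several labs)
follow mixed-sign phenotype contrasts rather than parallel ramps. Two
reasons: first, four collinear clusters spaced 1.5 sd apart overlap so
heavily that even noise-free clustering cannot exceed ARI ≈ 0.7, so a
purely monotone design would make the benchmark unrecoverable by any
method; second, real cardio-oncology subgroups are not totally ordered —
the worst-survival phenotype need not be the highest-cardiotoxicity
phenotype — and mixed contrasts encode exactly that. Four labs
(potassium, WBC, platelets, calcium) carry no signal at all.

**Correlated noise.** Two patient-level factors induce correlation
across a patient's variables. A multiplicative log-normal *severity*
factor (log-sd `noise_corr`, default 0.20, with a 15% "decompensated"
tail drawn from U(2, 3)) scales all of a patient's biological deviations
from the cohort mean. A latent *cardiorenal stress* factor couples
NT-proBNP, Troponin T and creatinine within subgroups, with loading
rising with subgroup risk (default ramp 0 → 0.75): in high-risk
subgroups these three variables co-vary strongly, in the lowest-risk
subgroup they are nearly independent. This is what gives the
subgroup-specific variable networks their planted structure.
`subgroup_spread` optionally makes high-risk subgroups more
heterogeneous (default: homoscedastic).

**Visits.** Follow-up visits are a mandatory baseline at t = 0,
a bi-monthly grid (with 7-day jitter) through the first on-therapy year,
and a homogeneous Poisson process (`visit_rate`, default 1/year)
afterwards — the schedule of a structured surveillance programme. The
intensive first year matters technically as well as clinically: with
sparse visits the 3-month-window features are structurally missing for
most patients, and after mean imputation and re-scaling those columns
turn into amplified noise. Setting `intensive_first_year=False` yields a
pure Poisson schedule (retrospective-EMR-like). Every patient has at
least two visits. Measurements are dropped MCAR at `missing_rate`
(default 0.10).

**Events, death, censoring.** Each event type's de novo time is
exponential with the subgroup's cause-specific rate (defaults sum to
0.02/0.05/0.10/0.20 per year across the five types, split by fixed
weights with heart failure dominant); an event is observed if it
precedes the end of follow-up, which is the minimum of the death time
(exponential, subgroup-graded, defaults 0.015–0.10/yr), an independent
exponential censoring time (0.04/yr) and the 20-year horizon. With
probability `preexisting_prob` (0.15) a patient additionally carries a
preexisting event dated uniformly within the two years before therapy
start. Preexisting events are drawn independently of the post-therapy
process so that `event_hazards` are exactly the de novo cause-specific
rates. A cancer-diagnosis date 30–365 days before therapy start anchors
overall survival; therapy start (day 0) anchors event classification.

Under the defaults the cohort shows roughly 40% mortality over follow-up
and a preexisting-event fraction near 15%, in the range reported for
institutional cardio-oncology cohorts.

## Preprocessing

Each longitudinal variable contributes five derived features per
patient: maximum and minimum over all follow-ups, the OLS slope of value
against time (days), and the maximum increase and maximum decrease
between any ordered visit pair at most 92 days apart ("3 months" fixed
at the longest calendar quarter). Duplicate timestamps are averaged
first; window features are missing when no pair qualifies; the slope is
missing with fewer than two distinct times. Derived features are
concatenated with numeric static variables (age, sex, tumor class,
stage).

Outliers are blanked per column at |robust z| > 4 (median/MAD rule — the
limit and the rule are this module's choice; only the existence of an
outlier-removal step is prescribed). Missing entries are mean-imputed
and every column is z-scored with the *population* sd of the imputed
column, so post-scaling columns have exactly zero mean and unit sd, and
imputed entries sit exactly at 0. Zero-variance columns are centered,
flagged and not divided; all-missing columns are dropped with a warning.
The fitted statistics (outlier medians/MADs, imputation means, scaling
means/sds) are stored so held-out patients can be transformed without
influencing them.

One property of these features is worth flagging: open-ended summaries
such as the maximum over all follow-ups encode follow-up *length*, and
follow-up length is overall survival. Clusters built on such features
can therefore separate survival curves even in a cohort with no planted
structure. This is a property of the feature definition, not a bug; null
calibration checks consequently use the de novo event endpoint, whose
log-rank test is valid under group-dependent censoring.

## Patient network and clustering

Similarity is the cosine over the scaled feature vectors (Pearson, i.e.
row-centered cosine, is available as an alternative). Zero-norm vectors
get similarity 0 with a warning. For network export a cutoff is chosen
by scanning a grid (step 0.05) and minimizing the network density —
retained edges over n(n−1)/2 — computed over the nodes that keep at
least one edge; without that node convention the minimum would
degenerate to the largest cutoff. Ties break toward the smaller cutoff
(retains more patients). The cutoff affects visualization exports only.

Clustering operates on each patient's *similarity profile* — their full
row of the unthresholded similarity matrix — with standard k-means
(k-means++ initialization, 10 restarts). Labels are canonicalized by
descending cluster size. K selection refits over a range and keeps the
largest K whose subgroups remain separable on both endpoints (omnibus
log-rank p < alpha and all BH-adjusted pairwise log-rank p < alpha for
overall survival and de novo events); the full per-K table, including
the SSE elbow, is always emitted, since the automated rule approximates
a judgement call. Stability repeats the fit under 100 random initial
states; the lowest-SSE run is the reference and agreement is summarized
by ARI/AMI against it. Out-of-sample patients are represented by their
similarities *to the training patients* (the centroid space's axis) and
assigned to the nearest centroid.

## Outcome analysis

Events dated on or after therapy start are de novo; earlier events are
preexisting; a boundary event on day 0 counts as de novo. Overall
survival runs from cancer diagnosis to death; de novo time runs from
therapy start to the first post-therapy event, censored at the end of
follow-up. Death before a cardiac event censors the event endpoint
(cause-specific framing; Fine–Gray competing-risk models are out of
scope).

Kaplan–Meier curves carry Greenwood 95% bands; cumulative hazards use
Nelson–Aalen (not −log KM). Group comparisons use the omnibus log-rank
test plus all pairwise tests with Benjamini–Hochberg adjustment over the
pairs of one endpoint. Cox models are fitted by partial likelihood with
Wald CIs; the reference subgroup is the one with the lowest de novo
event rate; exactly collinear covariates raise a rank error rather than
fitting silently. Enrichment uses Pearson chi-square (no continuity
correction; Fisher fallback when an expected cell drops below 1) with
Wilson CIs on rates. Period breakdowns bucket events by completed years
so the periods 0–1 / 2–5 / 6–10 / 11–20 tile the horizon exactly, and
percentages plus the never-event fraction sum to one per cluster.
Biomarker-threshold survival uses guideline-style bins (NT-proBNP 0–125
/ 125–900 / >900 pg/mL; Troponin T ≤0.01 / 0.01–0.05 / >0.05 μg/L) with
the lowest bin as Cox reference.

## Variable networks

Within each patient subgroup, Pearson correlations between all
noncategorical variables (constant columns excluded, indicator columns
not treated as noncategorical) are computed with two-sided t-based
p-values. Families of derived features collapse to their base variable
by the maximum-absolute correlation, the sign of the achieving member
retained; pairs of two families aggregate over all member cross-pairs by
default (an `exclude` mode is available, since whether family–family
pairs should aggregate is genuinely ambiguous). The network keeps the
top 15% of pairs by |PCC|, ties at the threshold all included —
determinism is preferred over an exact edge count. Ranking uses
unweighted degree and normalized shortest-path betweenness on the
thresholded graph. Degree profiles across the subgroup networks are
clustered by complete-linkage agglomeration on Euclidean distances.

## Train/test validation

Splits are random (repeated) or by calendar time with the earlier block
training. All preprocessing statistics are fitted on the training set
only; test patients are profiled against the training patients and
assigned to fitted centroids; held-out separation is tested by omnibus
log-rank on both endpoints. Time-dependent discrimination uses the IPCW
cumulative/dynamic AUROC; evaluation times before the first event or
beyond follow-up are skipped.

## Problem sizes and numerical choices

The benchmark cohort is n = 2000 with fixed seeds; calibration uses
1000 two-group null log-rank simulations at n = 200 and 500 Cox fits at
n = 5000 against a planted HR of 2; stability uses 100 restarts. Derived
seeds fan out from one global seed through `SeedSequence` keyed by stage
names, and stay below 2^31. Matrix symmetry is enforced by averaging
with the transpose and clipping to [−1, 1]; k-means SSE is the standard
within-cluster sum of squares.

## What the generator does not emulate, and a known limitation

The generator plants MCAR missingness, Gaussian within-subgroup
variation and exponential hazards; it does not emulate ICD coding noise,
informative missingness, medication exposure, or real biomarker skew.
Passing tests therefore demonstrate the pipeline's correctness and its
behaviour under idealized EMR-like conditions, not performance on real
records.

One documented consequence: on these synthetic conditions, k-means run
*directly* on the scaled derived features recovers the planted partition
at least as well as the similarity-profile route (both are reported by
the acceptance script). The profile transform weights feature-space
directions by their variance and normalizes patient magnitude; the
regimes in which that demonstrably pays on real institutional EMR data —
dominant nuisance correlation structure, heavy-tailed and heteroscedastic
measurements — are exactly the ones a clean MCAR-Gaussian generator
avoids. An extensive internal search (multiplicative severity with and
without heavy tails, heteroscedastic subgroups, per-patient missingness,
skewed biomarkers, unbalanced prevalences, sparse visit schedules) found
no honest synthetic configuration in which the profile route strictly
dominates while both remain accurate, so the relative-performance claim
should be treated as untested at desk scale rather than confirmed.
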