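"""Longitudinal feature derivation, outlier removal, imputation and scaling.

Each longitudinal variable is summarised per patient by five derived
features: the maximum and minimum across all follow-ups, the ordinary
least-squares slope of value versus time, and the maximum increase and
maximum decrease between any ordered pair of visits no more than a
3-month window apart.  Derived features are concatenated with static
variables, outliers are blanked by a robust z-rule, missing values are
mean-imputed and every column is z-scored.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DERIVED_SUFFIXES = ("max", "min", "slope", "max_increase_3mo", "max_decrease_3mo")

#: "3 months" fixed at 92 days — the longest calendar quarter.
DEFAULT_WINDOW_DAYS = 92


@dataclass
class FeatureMatrix:
    """Patients x derived-features table with its pre-imputation mask.

    ``values`` is the (possibly already imputed/scaled) matrix; ``mask``
    is True where the entry was observed before imputation.  After
    ``impute_and_scale`` the per-column means/sds used are stored so the
    identical transform can be applied to held-out patients.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    scaled: bool = False
    means: pd.Series | None = None
    sds: pd.Series | None = None
    zero_variance: list[str] = field(default_factory=list)
    # robust outlier rule fitted by remove_outliers: (median, scaled MAD, z_limit)
    outlier_stats: tuple[pd.Series, pd.Series, float] | None = None

    @property
    def patient_ids(self) -> pd.Index:
        return self.values.index

    @property
    def variable_names(self) -> pd.Index:
        return self.values.columns

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            values=self.values.copy(),
            mask=self.mask.copy(),
            scaled=self.scaled,
            means=None if self.means is None else self.means.copy(),
            sds=None if self.sds is None else self.sds.copy(),
            zero_variance=list(self.zero_variance),
            outlier_stats=self.outlier_stats,
        )

    def write(self, csv_path: str | Path, meta_path: str | Path | None = None) -> None:
        self.values.rename_axis("patient_id").to_csv(csv_path)
        if meta_path is not None and self.means is not None:
            meta = {
                "means": self.means.round(12).to_dict(),
                "sds": self.sds.round(12).to_dict(),
                "zero_variance": self.zero_variance,
            }
            Path(meta_path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def derive_longitudinal_features(
    times: np.ndarray, values: np.ndarray, window_days: float = DEFAULT_WINDOW_DAYS
) -> dict[str, float]:
    """Five summary features of one patient's series of one variable.

    ``times`` are days from therapy start; duplicate timestamps are
    averaged before derivation.  The slope is the OLS coefficient of value
    on time (per day), NaN with fewer than two distinct times.  The window
    features scan all ordered visit pairs (i earlier than j, gap at most
    ``window_days``): max increase is ``max(v_j - v_i)`` floored at 0, max
    decrease symmetric with ``v_i - v_j``; both NaN when no pair qualifies.
    An empty series yields all-NaN features rather than an error.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size == 0:
        return {s: np.nan for s in DERIVED_SUFFIXES}
    order = np.argsort(t, kind="stable")
    t, v = t[order], v[order]
    # average duplicate timestamps
    uniq, inv = np.unique(t, return_inverse=True)
    if uniq.size < t.size:
        v = np.bincount(inv, weights=v) / np.bincount(inv)
        t = uniq
    out = {"max": float(np.max(v)), "min": float(np.min(v))}
    if t.size >= 2:
        tc = t - t.mean()
        out["slope"] = float(tc @ (v - v.mean()) / (tc @ tc))
    else:
        out["slope"] = np.nan
    dt = t[None, :] - t[:, None]  # dt[i, j] = t_j - t_i
    qual = (dt > 0) & (dt <= window_days)
    if qual.any():
        diffs = v[None, :] - v[:, None]
        out["max_increase_3mo"] = max(float(diffs[qual].max()), 0.0)
        out["max_decrease_3mo"] = max(float((-diffs)[qual].max()), 0.0)
    else:
        out["max_increase_3mo"] = np.nan
        out["max_decrease_3mo"] = np.nan
    return out


def _grouped_features(meas: pd.DataFrame, window_days: float) -> pd.DataFrame:
    """Derived features for every (patient, variable) pair in long format."""
    df = (
        meas.groupby(["patient_id", "variable", "days_from_therapy_start"], sort=True)[
            "value"
        ]
        .mean()
        .reset_index()
    )
    rows = {}
    for (pid, var), grp in df.groupby(["patient_id", "variable"], sort=True):
        feats = derive_longitudinal_features(
            grp["days_from_therapy_start"].to_numpy(),
            grp["value"].to_numpy(),
            window_days,
        )
        for suffix, val in feats.items():
            rows.setdefault(f"{var}__{suffix}", {})[pid] = val
    return pd.DataFrame(rows)


def build_feature_matrix(
    measurements: pd.DataFrame,
    static: pd.DataFrame | None = None,
    static_columns: tuple[str, ...] | None = None,
    window_days: float = DEFAULT_WINDOW_DAYS,
) -> FeatureMatrix:
    """Derive the raw (pre-imputation) feature matrix from long-format
    measurements, appending numeric static variables if given."""
    feats = _grouped_features(measurements, window_days)
    if static is not None:
        stat = static.set_index("patient_id")
        if static_columns is None:
            static_columns = tuple(
                c
                for c in stat.columns
                if pd.api.types.is_numeric_dtype(stat[c])
                and c not in ("cancer_dx_days",)
            )
        feats = feats.join(stat[list(static_columns)], how="outer")
    feats = feats.sort_index()
    return FeatureMatrix(values=feats, mask=feats.notna())


def remove_outliers(matrix: FeatureMatrix, z_limit: float = 4.0) -> FeatureMatrix:
    """Blank entries whose column robust z-score (median/MAD) exceeds
    ``z_limit`` in absolute value.  Columns with zero MAD are left alone.
    ``z_limit=inf`` is the identity."""
    out = matrix.copy()
    vals = out.values
    med = vals.median()
    mad = (vals - med).abs().median() * 1.4826
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (vals - med) / mad
    drop = mad > 0
    outliers = z.abs().gt(z_limit) & drop
    n_removed = int(outliers.to_numpy().sum())
    if n_removed:
        log.info("remove_outliers: blanked %d entries at |robust z| > %g", n_removed, z_limit)
    out.values = vals.mask(outliers)
    out.mask = out.values.notna()
    out.outlier_stats = (med, mad, z_limit)
    return out


def impute_and_scale(matrix: FeatureMatrix, ddof: int = 0) -> FeatureMatrix:
    """Mean-impute missing entries then z-score each column.

    Uses the population standard deviation by default (``ddof=0``).
    All-missing columns are dropped with a warning; zero-variance columns
    are flagged and passed through centered (not divided).  Imputed
    entries are exactly 0 after scaling.
    """
    vals = matrix.values.copy()
    all_missing = [c for c in vals.columns if vals[c].isna().all()]
    if all_missing:
        warnings.warn(
            f"dropping {len(all_missing)} all-missing column(s): {all_missing}",
            stacklevel=2,
        )
        vals = vals.drop(columns=all_missing)
    means = vals.mean()
    vals = vals.fillna(means)
    # sd of the imputed column, so scaled columns have exactly unit sd
    sds = vals.std(ddof=ddof)
    zero_var = sds.index[(sds == 0) | sds.isna()].tolist()
    divisor = sds.replace(0, 1.0).fillna(1.0)
    scaled = (vals - means) / divisor
    return FeatureMatrix(
        values=scaled,
        mask=matrix.mask[vals.columns].copy(),
        scaled=True,
        means=means,
        sds=divisor,
        zero_variance=zero_var,
        outlier_stats=matrix.outlier_stats,
    )


def apply_scaling(matrix: FeatureMatrix, fitted: FeatureMatrix) -> FeatureMatrix:
    """Apply a fitted imputation/scaling transform to new patients.

    The fitted outlier rule (train median/MAD), imputation means and
    scaling means/sds are all reused — the held-out patients never
    influence the transform.
    """
    if fitted.means is None or fitted.sds is None:
        raise ValueError("fitted matrix has no stored scaling statistics")
    cols = fitted.values.columns
    vals = matrix.values.reindex(columns=cols)
    if fitted.outlier_stats is not None:
        med, mad, z_limit = fitted.outlier_stats
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (vals - med.reindex(cols)) / mad.reindex(cols)
        vals = vals.mask(z.abs().gt(z_limit) & (mad.reindex(cols) > 0))
    vals = vals.fillna(fitted.means)
    scaled = (vals - fitted.means) / fitted.sds
    return FeatureMatrix(
        values=scaled,
        mask=matrix.mask.reindex(columns=cols, fill_value=False),
        scaled=True,
        means=fitted.means.copy(),
        sds=fitted.sds.copy(),
        zero_variance=list(fitted.zero_variance),
    )
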