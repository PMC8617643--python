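"""Preprocessing chain from raw GC-MS peak areas to the model-ready matrix.

Order of operations: internal-standard normalization, per-sample median
normalization, Dixon outlier exclusion within replicate groups, log2
transform, group-aware KNN imputation, per-feature autoscaling.  Imputation
runs before scaling (scaling needs complete columns); each step records what
it excluded, imputed or dropped in a provenance dict.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import MetaboliteTable, replicate_groups

# Two-sided critical values of Dixon's r10 (Q) ratio statistic for n = 3..30
# (Rorabacher 1991), at 95% and 99% confidence.
DIXON_Q_CRIT = {
    0.05: {
        3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568, 8: 0.526, 9: 0.493,
        10: 0.466, 11: 0.444, 12: 0.426, 13: 0.410, 14: 0.396, 15: 0.384,
        16: 0.374, 17: 0.365, 18: 0.356, 19: 0.349, 20: 0.342, 21: 0.337,
        22: 0.331, 23: 0.326, 24: 0.321, 25: 0.317, 26: 0.312, 27: 0.308,
        28: 0.305, 29: 0.301, 30: 0.298,
    },
    0.01: {
        3: 0.994, 4: 0.926, 5: 0.821, 6: 0.740, 7: 0.680, 8: 0.634, 9: 0.598,
        10: 0.568, 11: 0.542, 12: 0.522, 13: 0.503, 14: 0.488, 15: 0.475,
        16: 0.463, 17: 0.452, 18: 0.442, 19: 0.433, 20: 0.425, 21: 0.418,
        22: 0.411, 23: 0.404, 24: 0.399, 25: 0.393, 26: 0.388, 27: 0.384,
        28: 0.380, 29: 0.376, 30: 0.372,
    },
}


def normalize_internal_standard(table: MetaboliteTable, standard_feature_id: str) -> MetaboliteTable:
    """Divide every sample by its internal-standard area; drop the standard.

    Removes per-sample loading factors exactly: if every area carries a
    multiplicative factor L_i so does the standard, and the ratio is free
    of it.
    """
    table.require_state("raw")
    if standard_feature_id not in table.values.columns:
        raise ValueError(f"internal standard {standard_feature_id!r} not in table")
    std = table.values[standard_feature_id]
    bad = std.index[~(std > 0)].tolist()
    if bad:
        raise ValueError(
            f"internal standard missing or non-positive in samples {bad[:5]}"
        )
    values = table.values.drop(columns=[standard_feature_id]).div(std, axis=0)
    return MetaboliteTable(values, "is_normalized")


def normalize_sample_median(table: MetaboliteTable) -> MetaboliteTable:
    """Divide each sample by the median of its non-missing values."""
    table.require_state("is_normalized")
    med = table.values.median(axis=1, skipna=True)
    bad = med.index[~med.notna()].tolist()
    if bad:
        raise ValueError(f"samples with all-missing values: {bad}")
    if (med <= 0).any():
        raise ValueError("non-positive sample median")
    return MetaboliteTable(table.values.div(med, axis=0), "median_normalized")


def dixon_filter(
    table: MetaboliteTable, metadata: pd.DataFrame, alpha: float = 0.05
) -> tuple[MetaboliteTable, pd.DataFrame]:
    """Exclude one extreme value per (feature, replicate group) by Dixon's Q.

    Within each (treatment, das) group the two-sided r10 statistic
    ``Q = gap / range`` is computed for the most extreme value; values with
    Q above the critical value at ``alpha`` are set missing.  Groups with
    fewer than 3 observed values are skipped with a warning.
    """
    table.require_state("median_normalized", "is_normalized")
    try:
        crit_table = DIXON_Q_CRIT[alpha]
    except KeyError:
        raise ValueError(f"no Dixon critical values for alpha={alpha}; use 0.05 or 0.01") from None
    values = table.values.copy()
    mask = pd.DataFrame(False, index=values.index, columns=values.columns)
    warned = False
    for (treatment, das), sample_ids in replicate_groups(metadata):
        sub = values.loc[sample_ids]
        arr = sub.to_numpy()
        for j, feature in enumerate(values.columns):
            col = arr[:, j]
            obs = np.flatnonzero(~np.isnan(col))
            n = obs.size
            if n < 3:
                if n > 0 and not warned:
                    warnings.warn(
                        f"replicate group ({treatment}, {das}) has < 3 observed "
                        "values for some features; Dixon test skipped there",
                        stacklevel=2,
                    )
                    warned = True
                continue
            if n > 30:
                raise ValueError("Dixon test defined for group sizes 3..30")
            x = np.sort(col[obs])
            rng_ = x[-1] - x[0]
            # guard against zero and numerically-degenerate ranges
            if rng_ <= 1e-9 * max(abs(x[0]), abs(x[-1])):
                continue
            q_high = (x[-1] - x[-2]) / rng_
            q_low = (x[1] - x[0]) / rng_
            q = max(q_high, q_low)
            if q > crit_table[n]:
                target = x[-1] if q_high >= q_low else x[0]
                # flag the (single) most extreme value in this group
                hit = obs[np.flatnonzero(col[obs] == target)[0]]
                sid = sub.index[hit]
                mask.at[sid, feature] = True
    out = values.mask(mask)
    return MetaboliteTable(out, "filtered"), mask


def log2_transform(table: MetaboliteTable) -> MetaboliteTable:
    table.require_state("filtered", "median_normalized", "is_normalized")
    values = table.values
    nonpos = values.le(0)
    if nonpos.any().any():
        i, j = np.argwhere(nonpos.to_numpy())[0]
        raise ValueError(
            f"non-positive value at sample {values.index[i]!r}, "
            f"feature {values.columns[j]!r}; cannot log-transform"
        )
    return MetaboliteTable(np.log2(values), "log2")


def knn_impute(
    table: MetaboliteTable,
    metadata: pd.DataFrame,
    k: int | None = None,
) -> tuple[MetaboliteTable, dict]:
    """Group-aware KNN imputation on the log2 scale.

    A missing cell is treated as a *technical* dropout — and imputed from the
    ``k`` nearest features (Euclidean distance over samples where both are
    observed, value = mean of the neighbours in that sample) — only if the
    feature is observed in at least one other replicate of the same
    (treatment, das) group.  Cells missing in *all* replicates of their group
    are treated as structural absences and filled with the feature's
    half-minimum.  Observed entries are never altered.
    """
    table.require_state("log2")
    values = table.values.copy()
    arr = values.to_numpy()
    n, j = arr.shape
    if j < 2:
        raise ValueError("need at least 2 features for KNN imputation")
    k = min(10, j - 1) if k is None else int(k)
    if k < 1:
        raise ValueError("k must be >= 1")
    no_obs = np.flatnonzero(np.isnan(arr).all(axis=0))
    if no_obs.size:
        raise ValueError(
            f"features with no observed values anywhere: {list(values.columns[no_obs])[:5]}"
        )

    group_of = {}
    for key, sample_ids in replicate_groups(metadata):
        for sid in sample_ids:
            group_of[sid] = key

    missing = np.isnan(arr)
    technical = np.zeros_like(missing)
    structural = np.zeros_like(missing)
    sample_ids = list(values.index)
    group_rows: dict = {}
    for i, sid in enumerate(sample_ids):
        group_rows.setdefault(group_of[sid], []).append(i)
    for rows in group_rows.values():
        sub = missing[rows]
        any_obs = ~sub.all(axis=0)  # feature observed in >= 1 replicate
        for local, i in enumerate(rows):
            technical[i] = sub[local] & any_obs
            structural[i] = sub[local] & ~any_obs

    # pairwise feature distances over jointly observed samples
    if technical.any():
        obs = ~missing
        filled0 = np.where(obs, arr, 0.0)
        counts = obs.T.astype(float) @ obs.astype(float)
        sq = (filled0**2).T @ obs + obs.T.astype(float) @ (filled0**2) - 2.0 * (filled0.T @ filled0)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist2 = np.where(counts > 0, sq / counts, np.inf)
        np.fill_diagonal(dist2, np.inf)

        for i, jj in zip(*np.nonzero(technical)):
            cand = np.flatnonzero(obs[i])  # features observed in this sample
            if cand.size == 0:
                continue
            order = cand[np.argsort(dist2[jj, cand], kind="stable")][:k]
            arr[i, jj] = float(np.mean(arr[i, order]))

    # structural absences: half of the feature minimum on the raw scale,
    # i.e. (min log2) - 1
    if structural.any():
        col_min = np.nanmin(np.where(missing, np.nan, arr), axis=0)
        for i, jj in zip(*np.nonzero(structural)):
            arr[i, jj] = col_min[jj] - 1.0

    out = pd.DataFrame(arr, index=values.index, columns=values.columns)
    record = {
        "imputed_cells": _cells(values.index, values.columns, technical),
        "structural_cells": _cells(values.index, values.columns, structural),
        "k": k,
    }
    return MetaboliteTable(out, "imputed"), record


def _cells(index, columns, mask) -> list[list[str]]:
    rows, cols = np.nonzero(mask)
    return [[str(index[i]), str(columns[j])] for i, j in zip(rows, cols)]


def autoscale(
    table: MetaboliteTable, subset: list[str] | None = None
) -> tuple[MetaboliteTable, dict]:
    """Per-feature centering and unit-variance scaling (population SD).

    Scaling vectors are computed over the ``subset`` sample ids (default:
    all) and applied to every row.  Zero-variance features are dropped with a
    warning and recorded.
    """
    table.require_state("imputed", "log2", "scaled")
    values = table.values
    ref = values.loc[subset] if subset is not None else values
    mean = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=0)
    dropped = list(sd.index[sd <= 0])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance features", stacklevel=2)
    keep = [c for c in values.columns if c not in set(dropped)]
    scaled = (values[keep] - mean[keep]) / sd[keep]
    record = {
        "mean": mean[keep].to_dict(),
        "sd": sd[keep].to_dict(),
        "dropped_features": dropped,
        "subset": list(subset) if subset is not None else None,
    }
    return MetaboliteTable(scaled, "scaled"), record


def preprocess_pipeline(
    raw_table: MetaboliteTable,
    metadata: pd.DataFrame,
    standard_feature_id: str = "IS_tricosane",
    dixon_alpha: float = 0.05,
    knn_k: int | None = None,
) -> tuple[MetaboliteTable, dict]:
    """IS -> median -> Dixon -> log2 -> impute -> autoscale, with provenance."""
    t = normalize_internal_standard(raw_table, standard_feature_id)
    t = normalize_sample_median(t)
    t, dixon_mask = dixon_filter(t, metadata, alpha=dixon_alpha)
    t = log2_transform(t)
    t, impute_record = knn_impute(t, metadata, k=knn_k)
    t, scale_record = autoscale(t)
    provenance = {
        "internal_standard": standard_feature_id,
        "dixon_alpha": dixon_alpha,
        "dixon_excluded_cells": _cells(
            dixon_mask.index, dixon_mask.columns, dixon_mask.to_numpy()
        ),
        "imputation": impute_record,
        "scaling": {k: v for k, v in scale_record.items() if k != "mean" and k != "sd"},
    }
    return t, provenance
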