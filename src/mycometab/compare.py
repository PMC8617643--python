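"""Cross-model comparison: SUS plots, loading correlations, random-forest
mean-decrease-accuracy ranking, and the stage-vs-age discriminant contrast.

A SUS (shared-and-unique-structures) comparison pairs the predictive-component
loadings of two discriminant models over a common feature universe: features
responding the same way in both models fall on the diagonal (shared), features
responding in only one model fall along an axis (unique).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeClassifier

from .projection import ProjectionModel, fit_plsda


@dataclass
class SusResult:
    table: pd.DataFrame        # feature, p_A, p_B, sector
    spearman_rho: float
    p_value: float
    threshold_A: float
    threshold_B: float

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class ContrastResult:
    scores: pd.DataFrame             # samples x 2 predictive components + class
    centroids: pd.DataFrame          # class x components
    dev_component: int               # development-associated component (0/1)
    d_same_stage: float
    d_same_age: float
    verdict: bool | None             # True: same-stage groups closer; None: indeterminate


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with the t-approximation p-value (df = n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 4:
        raise ValueError("need >= 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def sus_compare(model_A: ProjectionModel, model_B: ProjectionModel,
                magnitude_quantile: float = 0.75) -> SusResult:
    """Pair the predictive loadings of two models and classify features.

    Sectors: ``shared_up``/``shared_down`` when both loadings exceed their
    model's magnitude threshold with equal signs, ``unique_A``/``unique_B``
    when only one does, ``null`` otherwise (including sign-discordant pairs
    above both thresholds, which are unique to the pair, not shared).
    """
    pa = model_A.predictive_loadings()
    pb = model_B.predictive_loadings()
    common = [f for f in pa.index if f in set(pb.index)]
    if not common:
        raise ValueError("models share no features")
    pa = pa.loc[common]
    pb = pb.loc[common]
    rho, p = spearman_rho(pa.to_numpy(), pb.to_numpy())
    thr_a = float(np.quantile(np.abs(pa), magnitude_quantile))
    thr_b = float(np.quantile(np.abs(pb), magnitude_quantile))
    sectors = []
    for a, b in zip(pa, pb):
        big_a = abs(a) >= thr_a
        big_b = abs(b) >= thr_b
        if big_a and big_b and np.sign(a) == np.sign(b):
            sectors.append("shared_up" if a > 0 else "shared_down")
        elif big_a and not big_b:
            sectors.append("unique_A")
        elif big_b and not big_a:
            sectors.append("unique_B")
        else:
            sectors.append("null")
    table = pd.DataFrame(
        {"feature": common, "p_A": pa.to_numpy(), "p_B": pb.to_numpy(), "sector": sectors}
    )
    return SusResult(table=table, spearman_rho=rho, p_value=p,
                     threshold_A=thr_a, threshold_B=thr_b)


def rf_mda_importance(X, labels, n_trees: int = 500, seed: int = 0) -> pd.Series:
    """Out-of-bag permutation importance (mean decrease accuracy).

    A bagged ensemble of CART trees (sqrt(J) features per split); for each
    tree the accuracy on its out-of-bag samples is compared with the accuracy
    after permuting one feature at a time, and the decreases are averaged
    over trees.  Deterministic given ``seed``.
    """
    if isinstance(X, pd.DataFrame):
        feature_ids = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        feature_ids = list(range(Xm.shape[1]))
    y = np.asarray(list(labels))
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    if counts.min() < 2:
        raise ValueError("need >= 2 samples per class")
    n, j = Xm.shape
    rng = np.random.default_rng(seed)
    totals = np.zeros(j)
    used = np.zeros(j)
    for _ in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size == 0:
            continue
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(2**31))
        )
        tree.fit(Xm[boot], y[boot])
        base = float(np.mean(tree.predict(Xm[oob]) == y[oob]))
        X_oob = Xm[oob]
        for f in range(j):
            perm = rng.permutation(oob.size)
            Xp = X_oob.copy()
            Xp[:, f] = Xp[perm, f]
            acc = float(np.mean(tree.predict(Xp) == y[oob]))
            totals[f] += base - acc
            used[f] += 1
    mda = np.where(used > 0, totals / np.maximum(used, 1), 0.0)
    return pd.Series(mda, index=feature_ids, name="mda")


def _loo_scores(X: np.ndarray, labels: list[str], n_comp: int) -> np.ndarray:
    """Leave-one-out predicted PLS-DA scores, aligned to the full model.

    With few samples and many features the in-sample scores of a
    discriminant model separate *any* labelling; the held-out predicted
    scores only separate structure that generalizes.  Each fold's weight
    basis is rotated onto the full-data basis (orthogonal Procrustes) so the
    score columns are comparable across folds.
    """
    full = fit_plsda(X, labels, n_comp=n_comp)
    n = X.shape[0]
    out = np.empty((n, n_comp))
    for i in range(n):
        keep = np.arange(n) != i
        m = fit_plsda(X[keep], [l for k, l in enumerate(labels) if k != i], n_comp=n_comp)
        t = m.predict_scores(X[i : i + 1])
        u, _, vt = np.linalg.svd(m.W.T @ full.W)
        out[i] = t @ (u @ vt)
    return out


def stage_age_contrast(table, metadata: pd.DataFrame, triple_spec: dict,
                       eps: float = 1e-9, cross_validated: bool = True) -> ContrastResult:
    """The stage-vs-age discriminant design on three observation classes.

    ``triple_spec['classes']`` names three (treatment, das, stage) groups:
    (t1, das_a, stage_X), (t1, das_b, stage_Y), (t2, das_a, stage_Y), so that
    one pair shares the calendar age and the other shares the phenophase.
    A two-component PLS-DA is fitted; the development-associated component is
    the one separating the stage_X and stage_Y centroids most, and the
    distances between same-stage vs same-age centroids are compared on it.
    By default centroids are computed from leave-one-out predicted scores
    (see :func:`_loo_scores`); set ``cross_validated=False`` for the raw
    in-sample scores.  A verdict of ``True`` means phenophase dominates
    calendar age.
    """
    values = table.values if hasattr(table, "values") and hasattr(table, "state") else table
    spec = list(triple_spec["classes"])
    if len(spec) != 3:
        raise ValueError("triple_spec must name exactly three classes")
    (t1, das_a, stage_x), (t1b, das_b, stage_y), (t2, das_a2, stage_y2) = spec
    if t1 != t1b or das_a != das_a2 or stage_y != stage_y2 or das_a == das_b or stage_x == stage_y:
        raise ValueError(
            "triple must be (t1, das_a, X), (t1, das_b, Y), (t2, das_a, Y) "
            "with das_a != das_b and X != Y"
        )
    sel = {}
    for key in spec:
        treatment, das, stage = key
        ids = metadata.index[(metadata["treatment"] == treatment) & (metadata["das"] == das)]
        if len(ids) == 0:
            raise ValueError(f"no samples for class {key}")
        sel[key] = list(ids)
    sample_ids = [sid for key in spec for sid in sel[key]]
    labels = [f"{k[0]}|d{k[1]}|{k[2]}" for k in spec for _ in sel[k]]
    X = values.loc[sample_ids]
    try:
        if cross_validated:
            T = _loo_scores(X.to_numpy(dtype=float), labels, n_comp=2)
        else:
            T = fit_plsda(X, labels, n_comp=2).T
    except ValueError:  # degenerate input (no X variation to model)
        T = np.zeros((len(sample_ids), 2))
    scores = pd.DataFrame(T, index=sample_ids, columns=["comp1", "comp2"])
    scores["class"] = labels
    centroids = scores.groupby("class", sort=False)[["comp1", "comp2"]].mean()
    lab = [f"{k[0]}|d{k[1]}|{k[2]}" for k in spec]
    cen = centroids.loc[lab].to_numpy()
    # development-associated component: separates stage_X from the stage_Y pair
    sep = np.abs(cen[0] - (cen[1] + cen[2]) / 2.0)
    dev = int(np.argmax(sep))
    d_same_stage = float(abs(cen[1, dev] - cen[2, dev]))   # (t1,das_b,Y) vs (t2,das_a,Y)
    d_same_age = float(abs(cen[0, dev] - cen[2, dev]))     # (t1,das_a,X) vs (t2,das_a,Y)
    if max(d_same_stage, d_same_age, float(sep[dev])) < eps:
        verdict = None
    else:
        verdict = d_same_stage < d_same_age
    return ContrastResult(
        scores=scores, centroids=centroids, dev_component=dev,
        d_same_stage=d_same_stage, d_same_age=d_same_age, verdict=verdict,
    )
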