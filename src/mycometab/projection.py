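"""Latent-variable models: PCA, classical MDS, NIPALS PLS/OPLS and the
discriminant (-DA) variants, with cross-validated Q2Y, permutation
significance and VIP.

Conventions
-----------
* All fits center X and Y internally; scaling is the caller's job (the
  preprocessing chain autoscales features).
* Predictive weight vectors are unit length; component signs are anchored so
  that the response loading ``c`` is positive for supervised models (a
  positive X-loading then means "higher in the positive class" or
  "accumulates with the response"), and so that the largest-magnitude
  loading is positive for PCA.
* OPLS follows the orthogonal-signal-correction scheme: orthogonal
  components capture X variation uncorrelated with the (single-column)
  response, then exactly one predictive component is extracted.
* R2Y is the cumulative fraction of Y variance explained, Q2Y its
  cross-validated counterpart (1 - PRESS/SS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_NIPALS_TOL = 1e-12
_NIPALS_MAXIT = 500


@dataclass
class ProjectionModel:
    kind: str                      # PCA | PLS | OPLS | PLSDA | OPLSDA
    T: np.ndarray                  # predictive scores (n x A)
    P: np.ndarray                  # predictive X loadings (J x A)
    W: np.ndarray                  # predictive weights (J x A), orthonormal
    C: np.ndarray | None = None    # response loadings (K x A)
    T_o: np.ndarray | None = None  # orthogonal scores
    P_o: np.ndarray | None = None
    W_o: np.ndarray | None = None
    r2x: list[float] = field(default_factory=list)   # per component (pred first, then orth)
    r2y: float | None = None       # cumulative R2Y
    q2y: float | None = None
    vip: np.ndarray | None = None
    perm_p_r2y: float | None = None
    perm_p_q2y: float | None = None
    x_mean: np.ndarray | None = None
    y_mean: np.ndarray | None = None
    feature_ids: list[str] | None = None
    classes: list | None = None
    positive_class: object = None
    n_pred: int = 0
    n_orth: int = 0

    # -- accessors ---------------------------------------------------------
    def predictive_loadings(self) -> pd.Series:
        """First predictive-component X loadings, indexed by feature."""
        idx = self.feature_ids if self.feature_ids is not None else range(self.P.shape[0])
        return pd.Series(self.P[:, 0], index=idx, name="p")

    def vip_series(self) -> pd.Series:
        idx = self.feature_ids if self.feature_ids is not None else range(self.P.shape[0])
        return pd.Series(self.vip, index=idx, name="vip")

    def predict_scores(self, X) -> np.ndarray:
        """Predictive-component scores for new samples."""
        X = np.asarray(X, dtype=float) - self.x_mean
        if self.kind in ("OPLS", "OPLSDA") and self.n_orth:
            for a in range(self.n_orth):
                t_o = X @ self.W_o[:, a]
                X = X - np.outer(t_o, self.P_o[:, a])
        if self.kind == "PCA":
            return X @ self.W
        return X @ self.W @ np.linalg.inv(self.P.T @ self.W)

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float) - self.x_mean
        if self.kind in ("OPLS", "OPLSDA") and self.n_orth:
            for a in range(self.n_orth):
                t_o = X @ self.W_o[:, a]
                X = X - np.outer(t_o, self.P_o[:, a])
        if self.kind == "PCA":
            return X @ self.W
        B = self.W @ np.linalg.solve(self.P.T @ self.W, self.C.T)
        return X @ B + self.y_mean

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.round(np.asarray(a, float), 10).tolist()

        return {
            "kind": self.kind,
            "n_pred": self.n_pred,
            "n_orth": self.n_orth,
            "r2x": [round(float(v), 10) for v in self.r2x],
            "r2y": None if self.r2y is None else round(float(self.r2y), 10),
            "q2y": None if self.q2y is None else round(float(self.q2y), 10),
            "perm_p_r2y": self.perm_p_r2y,
            "perm_p_q2y": self.perm_p_q2y,
            "scores": arr(self.T),
            "loadings": arr(self.P),
            "weights": arr(self.W),
            "response_loadings": arr(self.C),
            "orth_scores": arr(self.T_o),
            "orth_loadings": arr(self.P_o),
            "orth_weights": arr(self.W_o),
            "vip": arr(self.vip),
            "x_mean": arr(self.x_mean),
            "y_mean": arr(self.y_mean),
            "feature_ids": self.feature_ids,
            "classes": None if self.classes is None else [str(c) for c in self.classes],
            "positive_class": None if self.positive_class is None else str(self.positive_class),
        }


@dataclass(frozen=True)
class Embedding:
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    distance_kind: str


def _as_matrix(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    return np.asarray(X, dtype=float), None


def _as_y(Y) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    return Y[:, None] if Y.ndim == 1 else Y


# ---------------------------------------------------------------------------
# PCA / MDS

def fit_pca(X, n_comp: int) -> ProjectionModel:
    """Principal component analysis via SVD of the centered matrix."""
    Xm, feature_ids = _as_matrix(X)
    n, j = Xm.shape
    if not 1 <= n_comp <= min(n - 1, j):
        raise ValueError(f"n_comp={n_comp} out of range for shape {Xm.shape}")
    x_mean = Xm.mean(axis=0)
    Xc = Xm - x_mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(Xc**2))
    W = Vt[:n_comp].T.copy()
    T = U[:, :n_comp] * s[:n_comp]
    # sign: largest-magnitude loading positive
    for a in range(n_comp):
        if W[np.argmax(np.abs(W[:, a])), a] < 0:
            W[:, a] *= -1
            T[:, a] *= -1
    r2x = [float(s[a] ** 2 / total) for a in range(n_comp)] if total > 0 else [0.0] * n_comp
    return ProjectionModel(
        kind="PCA", T=T, P=W.copy(), W=W, r2x=r2x, x_mean=x_mean,
        feature_ids=feature_ids, n_pred=n_comp,
    )


def pairwise_distance(X, kind: str = "euclidean") -> np.ndarray:
    """Sample-by-sample distance matrix: Euclidean or Pearson (1 - r)."""
    Xm, _ = _as_matrix(X)
    if kind == "euclidean":
        sq = np.sum(Xm**2, axis=1)
        d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * Xm @ Xm.T, 0.0)
        return np.sqrt(d2)
    if kind == "pearson":
        r = np.corrcoef(Xm)
        return 1.0 - r
    raise ValueError(f"unknown distance kind {kind!r}")


def classical_mds(
    X=None, D=None, n_dim: int = 2, distance_kind: str = "euclidean"
) -> Embedding:
    """Torgerson scaling: double-center -D^2/2, eigendecompose, scale."""
    if D is None:
        if X is None:
            raise ValueError("provide X or D")
        D = pairwise_distance(X, distance_kind)
    D = np.asarray(D, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if np.any(evals[:n_dim] < -1e-8 * max(1.0, np.abs(evals).max())):
        import warnings

        warnings.warn("negative eigenvalues truncated (non-Euclidean distances)", stacklevel=2)
    lam = np.clip(evals[:n_dim], 0.0, None)
    coords = evecs[:, :n_dim] * np.sqrt(lam)
    return Embedding(coordinates=coords, eigenvalues=evals, distance_kind=distance_kind)


# ---------------------------------------------------------------------------
# PLS / OPLS (NIPALS)

def _nipals_component(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, ...]:
    """One NIPALS PLS component on centered X, Y. Returns (w, t, c, p)."""
    u = Y[:, int(np.argmax(np.var(Y, axis=0)))].copy()
    if np.allclose(u, u[0]):
        raise ValueError("zero-variance response")
    w_old = None
    for _ in range(_NIPALS_MAXIT):
        w = X.T @ u
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError("degenerate component: X'u vanished")
        w /= nw
        t = X @ w
        tt = float(t @ t)
        c = Y.T @ t / tt
        u = Y @ c / float(c @ c)
        if w_old is not None and np.linalg.norm(w - w_old) < _NIPALS_TOL:
            break
        w_old = w
    p = X.T @ t / tt
    return w, t, c, p


def _fix_sign_supervised(w, t, c, p):
    """Anchor sign so the dominant response loading is positive."""
    if c[int(np.argmax(np.abs(c)))] < 0:
        return -w, -t, -c, -p
    return w, t, c, p


def fit_pls(X, Y, n_comp: int = 1, kind: str = "PLS") -> ProjectionModel:
    """NIPALS PLS(2) with X and Y deflation after each component."""
    Xm, feature_ids = _as_matrix(X)
    Ym = _as_y(Y)
    if Xm.shape[0] != Ym.shape[0]:
        raise ValueError("X and Y sample counts differ")
    if np.all(np.std(Ym, axis=0) == 0):
        raise ValueError("zero-variance Y")
    x_mean = Xm.mean(axis=0)
    y_mean = Ym.mean(axis=0)
    Xc = Xm - x_mean
    Yc = Ym - y_mean
    ssx = float(np.sum(Xc**2))
    ssy = float(np.sum(Yc**2))
    W, T, C, P, r2x = [], [], [], [], []
    for _ in range(n_comp):
        w, t, c, p = _nipals_component(Xc, Yc)
        w, t, c, p = _fix_sign_supervised(w, t, c, p)
        W.append(w); T.append(t); C.append(c); P.append(p)
        r2x.append(float(np.sum(np.outer(t, p) ** 2)) / ssx if ssx else 0.0)
        Xc = Xc - np.outer(t, p)
        Yc = Yc - np.outer(t, c)
    r2y = 1.0 - float(np.sum(Yc**2)) / ssy if ssy else 0.0
    model = ProjectionModel(
        kind=kind,
        T=np.column_stack(T), P=np.column_stack(P), W=np.column_stack(W),
        C=np.column_stack(C), r2x=r2x, r2y=r2y,
        x_mean=x_mean, y_mean=y_mean, feature_ids=feature_ids, n_pred=n_comp,
    )
    model.vip = compute_vip(model)
    return model


def fit_opls(X, y, n_orth: int = 1, auto_select: bool = False, kind: str = "OPLS",
             cv_folds: int = 7, seed: int = 0, labels=None) -> ProjectionModel:
    """OPLS with a single-column response.

    Orthogonal components (X variation uncorrelated with y) are stripped
    first, then one predictive component is extracted.  With ``auto_select``
    orthogonal components are added while cross-validated Q2Y improves by
    more than 0.01 (cap 3).
    """
    if auto_select:
        best, best_q2 = None, -np.inf
        for k in range(0, 4):
            m = fit_opls(X, y, n_orth=k, auto_select=False, kind=kind)
            q2 = cross_validate_q2(
                X, y, {"kind": kind, "n_orth": k}, n_folds=cv_folds, seed=seed, labels=labels
            )
            m.q2y = q2
            if q2 > best_q2 + 0.01:
                best, best_q2 = m, q2
            else:
                break
        return best

    Xm, feature_ids = _as_matrix(X)
    Ym = _as_y(y)
    if Ym.shape[1] != 1:
        raise ValueError("OPLS requires a single-column response; use PLS-DA for >2 classes")
    x_mean = Xm.mean(axis=0)
    y_mean = Ym.mean(axis=0)
    Xc = Xm - x_mean
    yc = (Ym - y_mean)[:, 0]
    if np.std(yc) == 0:
        raise ValueError("zero-variance Y")
    ssx = float(np.sum(Xc**2))
    ssy = float(np.sum(yc**2))

    W_o, T_o, P_o, r2x_orth = [], [], [], []
    for _ in range(n_orth):
        w = Xc.T @ yc
        w /= np.linalg.norm(w)
        t = Xc @ w
        p = Xc.T @ t / float(t @ t)
        w_orth = p - float(w @ p) * w
        nw = np.linalg.norm(w_orth)
        if nw < 1e-12:
            break  # no orthogonal variation left
        w_orth /= nw
        t_orth = Xc @ w_orth
        p_orth = Xc.T @ t_orth / float(t_orth @ t_orth)
        if p_orth[int(np.argmax(np.abs(p_orth)))] < 0:
            w_orth, t_orth, p_orth = -w_orth, -t_orth, -p_orth
        W_o.append(w_orth); T_o.append(t_orth); P_o.append(p_orth)
        r2x_orth.append(float(np.sum(np.outer(t_orth, p_orth) ** 2)) / ssx if ssx else 0.0)
        Xc = Xc - np.outer(t_orth, p_orth)

    w = Xc.T @ yc
    w /= np.linalg.norm(w)
    t = Xc @ w
    tt = float(t @ t)
    p = Xc.T @ t / tt
    c = np.array([float(yc @ t) / tt])
    w, t, c, p = _fix_sign_supervised(w, t, c, p)
    r2x_pred = float(np.sum(np.outer(t, p) ** 2)) / ssx if ssx else 0.0
    resid = yc - t * c[0]
    r2y = 1.0 - float(resid @ resid) / ssy

    k_orth = len(W_o)
    model = ProjectionModel(
        kind=kind,
        T=t[:, None], P=p[:, None], W=w[:, None], C=c[None, :],
        T_o=np.column_stack(T_o) if k_orth else None,
        P_o=np.column_stack(P_o) if k_orth else None,
        W_o=np.column_stack(W_o) if k_orth else None,
        r2x=[r2x_pred] + r2x_orth, r2y=r2y,
        x_mean=x_mean, y_mean=y_mean, feature_ids=feature_ids,
        n_pred=1, n_orth=k_orth,
    )
    model.vip = compute_vip(model)
    return model


def encode_classes(labels) -> pd.DataFrame:
    """Dummy-code class labels: one column per class, rows sum to 1."""
    labels = pd.Series(list(labels))
    classes = sorted(labels.unique(), key=str)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    Y = pd.DataFrame(
        {c: (labels == c).astype(float).values for c in classes}, index=labels.index
    )
    return Y


def fit_plsda(X, labels, n_comp: int = 2) -> ProjectionModel:
    Y = encode_classes(labels)
    model = fit_pls(X, Y.to_numpy(), n_comp=n_comp, kind="PLSDA")
    model.classes = list(Y.columns)
    return model


def fit_oplsda(X, labels, positive_class=None, n_orth: int = 1,
               auto_select: bool = False, cv_folds: int = 7, seed: int = 0) -> ProjectionModel:
    """Two-class OPLS-DA; positive loadings mean higher in ``positive_class``."""
    labels = pd.Series(list(labels))
    classes = sorted(labels.unique(), key=str)
    if len(classes) != 2:
        raise ValueError(f"OPLS-DA requires exactly 2 classes, got {classes}")
    positive_class = classes[-1] if positive_class is None else positive_class
    if positive_class not in classes:
        raise ValueError(f"positive_class {positive_class!r} not among {classes}")
    y = (labels == positive_class).astype(float).to_numpy()
    model = fit_opls(X, y, n_orth=n_orth, auto_select=auto_select, kind="OPLSDA",
                     cv_folds=cv_folds, seed=seed, labels=labels.to_numpy())
    model.classes = classes
    model.positive_class = positive_class
    return model


# ---------------------------------------------------------------------------
# validation

def _make_folds(n: int, n_folds: int, seed: int, labels=None) -> np.ndarray:
    """Seeded venetian-blind fold assignment, stratified when labels given."""
    rng = np.random.default_rng(seed)
    fold = np.empty(n, dtype=int)
    if labels is None:
        order = rng.permutation(n)
        fold[order] = np.arange(n) % n_folds
    else:
        labels = np.asarray(labels)
        counter = 0
        for cls in sorted(pd.unique(labels), key=str):
            idx = np.flatnonzero(labels == cls)
            idx = idx[rng.permutation(len(idx))]
            for i in idx:
                fold[i] = counter % n_folds
                counter += 1
    return fold


def _fit_spec(X, Y, model_spec: dict):
    spec = dict(model_spec)
    kind = spec.get("kind", "PLS").upper()
    if kind in ("OPLS", "OPLSDA"):
        return fit_opls(X, Y, n_orth=spec.get("n_orth", 1), kind=kind)
    return fit_pls(X, Y, n_comp=spec.get("n_comp", 1), kind=kind)


def cross_validate_q2(X, Y, model_spec: dict, n_folds: int = 7, seed: int = 0,
                      labels=None) -> float:
    """Q2Y = 1 - PRESS/SS over held-out folds (stratified for DA labels)."""
    Xm, _ = _as_matrix(X)
    Ym = _as_y(Y)
    n = Xm.shape[0]
    if not 2 <= n_folds <= n:
        n_folds = min(max(n_folds, 2), n)
    fold = _make_folds(n, n_folds, seed, labels=labels)
    press = 0.0
    ss = 0.0
    for f in range(n_folds):
        test = fold == f
        if not test.any():
            continue
        train = ~test
        if labels is not None and len(pd.unique(np.asarray(labels)[train])) < 2:
            raise ValueError(f"fold {f} leaves a single class in training")
        model = _fit_spec(Xm[train], Ym[train], model_spec)
        pred = model.predict(Xm[test])
        press += float(np.sum((Ym[test] - pred) ** 2))
        ss += float(np.sum((Ym[test] - Ym[train].mean(axis=0)) ** 2))
    return 1.0 - press / ss if ss > 0 else float("nan")


def permutation_significance(X, Y, model_spec: dict, n_perm: int = 199, seed: int = 0,
                             n_folds: int = 7, labels=None) -> tuple[float, float]:
    """Permutation p-values for R2Y and Q2Y.

    Y rows (and stratification labels) are permuted jointly;
    p = (1 + #{permuted statistic >= observed}) / (n_perm + 1).
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19")
    Xm, _ = _as_matrix(X)
    Ym = _as_y(Y)
    obs = _fit_spec(Xm, Ym, model_spec)
    obs_q2 = cross_validate_q2(Xm, Ym, model_spec, n_folds=n_folds, seed=seed, labels=labels)
    rng = np.random.default_rng(seed)
    ge_r2 = 0
    ge_q2 = 0
    for _ in range(n_perm):
        perm = rng.permutation(Xm.shape[0])
        Yp = Ym[perm]
        lp = None if labels is None else np.asarray(labels)[perm]
        m = _fit_spec(Xm, Yp, model_spec)
        if m.r2y >= obs.r2y - 1e-12:
            ge_r2 += 1
        q2 = cross_validate_q2(Xm, Yp, model_spec, n_folds=n_folds, seed=seed, labels=lp)
        if q2 >= obs_q2 - 1e-12:
            ge_q2 += 1
    p_r2y = (1 + ge_r2) / (n_perm + 1)
    p_q2y = (1 + ge_q2) / (n_perm + 1)
    return p_r2y, p_q2y


def compute_vip(model: ProjectionModel) -> np.ndarray:
    """Variable importance in projection over the predictive components.

    VIP_j = sqrt( J * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a );
    mean(VIP^2) = 1 exactly.
    """
    if model.kind == "PCA":
        raise ValueError("VIP is undefined for PCA (no response)")
    W = model.W
    J, A = W.shape
    if model.kind in ("OPLS", "OPLSDA") or A == 1:
        w = W[:, 0] / np.linalg.norm(W[:, 0])
        return np.sqrt(J) * np.abs(w)
    # per-component Y variance explained: use score-based SSY increments
    ssy = []
    for a in range(A):
        t = model.T[:, a]
        c = model.C[:, a]
        ssy.append(float(t @ t) * float(c @ c))
    ssy = np.asarray(ssy)
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    num = (wn**2) @ ssy
    return np.sqrt(J * num / ssy.sum())
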