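"""PCA exploration and OPLS-DA classification in predictive score space.

OPLS-DA (orthogonal partial least squares discriminant analysis) splits the
systematic variation of a centred feature matrix X into a part correlated
with class membership (the predictive components) and a part orthogonal to
it.  Orthogonal components are removed first by the O-PLS filtering
recursion; predictive components are then extracted from the filtered matrix
by the two-block NIPALS recursion against the one-hot class indicator matrix
Y.  New spectra are classified by the Mahalanobis distance of their
predictive scores to each class centroid, using the pooled within-class
score covariance.

All component signs follow a fixed convention (largest-magnitude weight
element positive) so repeated fits are bit-for-bit identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .spectra import BinAxis, FeatureMatrix

NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 500
COV_RIDGE = 1e-8

__all__ = [
    "PcaModel",
    "OplsDaModel",
    "ClassPrediction",
    "fit_pca",
    "fit_oplsda",
    "project",
    "classify_mahalanobis",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class PcaModel:
    mean: np.ndarray
    loadings: np.ndarray  # (k, n_features), rows orthonormal
    explained_variance_ratio: np.ndarray
    k: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.mean) @ self.loadings.T


def _fix_sign(v: np.ndarray) -> float:
    """Sign making the largest-magnitude element of ``v`` positive."""
    i = int(np.argmax(np.abs(v)))
    return 1.0 if v[i] >= 0 else -1.0


def fit_pca(m: FeatureMatrix, k: int) -> PcaModel:
    """Mean-centred PCA by singular value decomposition.

    Requires ``stage == 'logged'`` input and ``k <= min(rows - 1, bins)``.
    """
    if m.stage != "logged":
        raise ValueError(f"expected stage 'logged', got {m.stage!r}")
    n, p = m.X.shape
    if not (1 <= k <= min(n - 1, p)):
        raise ValueError(f"k={k} out of range for {n} x {p} matrix")
    mean = m.X.mean(axis=0)
    Xc = m.X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / max(n - 1, 1)
    total = Xc.var(axis=0, ddof=1).sum()
    loadings = Vt[:k].copy()
    for i in range(k):
        loadings[i] *= _fix_sign(loadings[i])
    return PcaModel(
        mean=mean,
        loadings=loadings,
        explained_variance_ratio=var[:k] / total,
        k=k,
    )


@dataclass
class OplsDaModel:
    """A fitted OPLS-DA classifier.

    ``W_orth``/``P_orth`` are the orthogonal filter weights/loadings (one row
    per orthogonal component), ``W_pred``/``P_pred``/``C_pred`` the predictive
    weights, X-loadings and Y-loadings.  ``class_centroids`` holds the mean
    training predictive score per class and ``pooled_cov`` the regularised
    pooled within-class covariance of those scores.
    """

    class_labels: list[str]
    x_mean: np.ndarray
    n_pred: int
    n_orth: int
    W_orth: np.ndarray  # (n_orth, p)
    P_orth: np.ndarray
    W_pred: np.ndarray  # (n_pred, p)
    P_pred: np.ndarray
    C_pred: np.ndarray  # (n_pred, n_classes)
    class_centroids: dict[str, np.ndarray]
    pooled_cov: np.ndarray
    training_scores: np.ndarray  # (n, n_pred)
    orth_scores: np.ndarray  # (n, n_orth)
    axis: BinAxis | None = None
    fit_meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ClassPrediction:
    spectrum_id: str
    predicted_label: str
    distances: dict[str, float]
    scores: np.ndarray


def _one_hot(labels: list[str]) -> tuple[np.ndarray, list[str]]:
    classes = sorted(set(labels))
    Y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        Y[i, classes.index(lab)] = 1.0
    return Y, classes


def _nipals_component(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int, bool]:
    """One two-block NIPALS PLS component: returns (w, t, p, c, iters, conv)."""
    u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
    if not np.any(u):
        u = Y[:, 0].copy()
    t_old = None
    converged = False
    for it in range(1, NIPALS_MAX_ITER + 1):
        w = X.T @ u
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w /= nw
        t = X @ w
        tt = t @ t
        if tt == 0:
            break
        c = Y.T @ t / tt
        cc = c @ c
        if cc == 0:
            break
        u = Y @ c / cc
        if t_old is not None and np.linalg.norm(t - t_old) <= NIPALS_TOL * max(
            np.linalg.norm(t), 1e-300
        ):
            converged = True
            break
        t_old = t
    p = X.T @ t / (t @ t)
    sign = _fix_sign(w)
    return sign * w, sign * t, sign * p, sign * c, it, converged


def fit_oplsda(
    m: FeatureMatrix,
    labels: list[str] | None = None,
    n_pred: int | None = None,
    n_orth: int = 1,
) -> OplsDaModel:
    """Fit an OPLS-DA model on a logged feature matrix.

    Parameters
    ----------
    labels
        Class label per row; defaults to the matrix's tissue labels.
    n_pred
        Number of predictive components; defaults to ``n_classes - 1``.
    n_orth
        Number of orthogonal (class-uncorrelated) components removed before
        the predictive extraction.

    Each orthogonal component is found by running one NIPALS step on the
    current matrix, projecting its X-loading off the span of the X-Y
    covariance directions, and deflating X by the resulting score/loading
    pair.  This leaves orthogonal scores exactly decorrelated from every
    class-indicator column.
    """
    if m.stage != "logged":
        raise ValueError(f"expected stage 'logged', got {m.stage!r}")
    labels = list(labels) if labels is not None else list(m.tissue_labels)
    if len(labels) != m.n_spectra:
        raise ValueError("labels length != row count")
    Y_raw, classes = _one_hot(labels)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    counts = Y_raw.sum(axis=0)
    small = [c for c, n in zip(classes, counts) if n < 2]
    if small:
        raise ValueError(f"classes with < 2 rows: {small}")
    if n_pred is None:
        n_pred = len(classes) - 1
    if n_pred < 1 or n_orth < 0:
        raise ValueError("need n_pred >= 1 and n_orth >= 0")

    x_mean = m.X.mean(axis=0)
    X = m.X - x_mean
    Y = Y_raw - Y_raw.mean(axis=0)

    p_feat = X.shape[1]
    W_orth = np.zeros((n_orth, p_feat))
    P_orth = np.zeros((n_orth, p_feat))
    T_orth = np.zeros((X.shape[0], n_orth))
    meta: dict = {"nipals_iterations": [], "converged": []}

    for j in range(n_orth):
        # basis of the current predictive (X'Y covariance) subspace
        cov_basis, _ = np.linalg.qr(X.T @ Y)
        w, t, p, c, iters, conv = _nipals_component(X, Y)
        meta["nipals_iterations"].append(iters)
        meta["converged"].append(conv)
        w_o = p - cov_basis @ (cov_basis.T @ p)
        nw = np.linalg.norm(w_o)
        if nw < 1e-12:
            # no orthogonal variation left; stop early
            W_orth = W_orth[:j]
            P_orth = P_orth[:j]
            T_orth = T_orth[:, :j]
            n_orth = j
            break
        w_o /= nw
        sign = _fix_sign(w_o)
        w_o *= sign
        t_o = X @ w_o
        p_o = X.T @ t_o / (t_o @ t_o)
        W_orth[j], P_orth[j], T_orth[:, j] = w_o, p_o, t_o
        X = X - np.outer(t_o, p_o)

    W_pred = np.zeros((n_pred, p_feat))
    P_pred = np.zeros((n_pred, p_feat))
    C_pred = np.zeros((n_pred, len(classes)))
    T_pred = np.zeros((X.shape[0], n_pred))
    Yd = Y.copy()
    for a in range(n_pred):
        w, t, p, c, iters, conv = _nipals_component(X, Yd)
        meta["nipals_iterations"].append(iters)
        meta["converged"].append(conv)
        if not conv and iters >= NIPALS_MAX_ITER:
            meta.setdefault("warnings", []).append(
                f"predictive component {a}: NIPALS hit {NIPALS_MAX_ITER} iterations"
            )
        W_pred[a], P_pred[a], C_pred[a], T_pred[:, a] = w, p, c, t
        X = X - np.outer(t, p)
        Yd = Yd - np.outer(t, c)

    lab_arr = np.array(labels)
    centroids = {c: T_pred[lab_arr == c].mean(axis=0) for c in classes}
    pooled = np.zeros((n_pred, n_pred))
    dof = 0
    for c in classes:
        tc = T_pred[lab_arr == c] - centroids[c]
        pooled += tc.T @ tc
        dof += tc.shape[0] - 1
    pooled /= max(dof, 1)
    pooled += np.eye(n_pred) * (COV_RIDGE * np.trace(pooled) / n_pred + 1e-300)

    return OplsDaModel(
        class_labels=classes,
        x_mean=x_mean,
        n_pred=n_pred,
        n_orth=n_orth,
        W_orth=W_orth,
        P_orth=P_orth,
        W_pred=W_pred,
        P_pred=P_pred,
        C_pred=C_pred,
        class_centroids=centroids,
        pooled_cov=pooled,
        training_scores=T_pred,
        orth_scores=T_orth,
        axis=m.axis,
        fit_meta=meta,
    )


def project(model: OplsDaModel, x: np.ndarray) -> np.ndarray:
    """Predictive score vector(s) of preprocessed feature vector(s).

    Centres by the training mean, strips each orthogonal component in fit
    order, then applies the predictive weight/loading recursion.  Accepts a
    single vector or a (n, p) matrix.
    """
    X = np.atleast_2d(np.asarray(x, dtype=float))
    if X.shape[1] != model.x_mean.size:
        raise ValueError(
            f"feature length {X.shape[1]} != training bins {model.x_mean.size}"
        )
    Xc = X - model.x_mean
    for j in range(model.n_orth):
        t_o = Xc @ model.W_orth[j]
        Xc = Xc - np.outer(t_o, model.P_orth[j])
    T = np.zeros((X.shape[0], model.n_pred))
    for a in range(model.n_pred):
        t = Xc @ model.W_pred[a]
        T[:, a] = t
        Xc = Xc - np.outer(t, model.P_pred[a])
    return T[0] if np.ndim(x) == 1 else T


def classify_mahalanobis(
    model: OplsDaModel, x: np.ndarray, spectrum_id: str = ""
) -> ClassPrediction:
    """Assign the class whose centroid is nearest in Mahalanobis distance.

    Distances use the pooled within-class covariance of training predictive
    scores; exact ties are broken lexicographically by class label.
    """
    t = project(model, np.asarray(x, dtype=float))
    if t.ndim != 1:
        raise ValueError("classify_mahalanobis takes a single feature vector")
    cov_inv = np.linalg.inv(model.pooled_cov)
    distances: dict[str, float] = {}
    for c in model.class_labels:
        d = t - model.class_centroids[c]
        distances[c] = float(np.sqrt(d @ cov_inv @ d))
    predicted = min(distances, key=lambda c: (distances[c], c))
    return ClassPrediction(
        spectrum_id=spectrum_id,
        predicted_label=predicted,
        distances=distances,
        scores=t,
    )


# ---------------------------------------------------------------------------
# model archive (the "uploaded spectral library" of the recognition software)

ARCHIVE_VERSION = 1


def save_model(model: OplsDaModel, path: str | Path, config_hash: str | None = None) -> None:
    """Serialise a fitted model to a single versioned JSON archive."""
    payload = {
        "format": "reims-oplsda",
        "version": ARCHIVE_VERSION,
        "config_hash": config_hash,
        "class_labels": model.class_labels,
        "n_pred": model.n_pred,
        "n_orth": model.n_orth,
        "x_mean": model.x_mean.tolist(),
        "W_orth": model.W_orth.tolist(),
        "P_orth": model.P_orth.tolist(),
        "W_pred": model.W_pred.tolist(),
        "P_pred": model.P_pred.tolist(),
        "C_pred": model.C_pred.tolist(),
        "class_centroids": {c: v.tolist() for c, v in model.class_centroids.items()},
        "pooled_cov": model.pooled_cov.tolist(),
        "axis": None
        if model.axis is None
        else {"low": model.axis.low, "high": model.axis.high, "width": model.axis.width},
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> OplsDaModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "reims-oplsda":
        raise ValueError(f"{path}: not a model archive")
    if payload.get("version") != ARCHIVE_VERSION:
        raise ValueError(f"{path}: unsupported archive version {payload.get('version')}")
    axis = payload.get("axis")
    n_pred = payload["n_pred"]
    return OplsDaModel(
        class_labels=list(payload["class_labels"]),
        x_mean=np.array(payload["x_mean"]),
        n_pred=n_pred,
        n_orth=payload["n_orth"],
        W_orth=np.array(payload["W_orth"]).reshape(payload["n_orth"], -1),
        P_orth=np.array(payload["P_orth"]).reshape(payload["n_orth"], -1),
        W_pred=np.array(payload["W_pred"]).reshape(n_pred, -1),
        P_pred=np.array(payload["P_pred"]).reshape(n_pred, -1),
        C_pred=np.array(payload["C_pred"]).reshape(n_pred, -1),
        class_centroids={
            c: np.array(v) for c, v in payload["class_centroids"].items()
        },
        pooled_cov=np.array(payload["pooled_cov"]).reshape(n_pred, n_pred),
        training_scores=np.zeros((0, n_pred)),
        orth_scores=np.zeros((0, payload["n_orth"])),
        axis=None if axis is None else BinAxis(**axis),
        fit_meta={"config_hash": payload.get("config_hash")},
    )
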