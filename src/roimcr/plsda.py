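"""PLS-DA classification with venetian-blinds CV, permutation validation
and VIP prioritization.

PLS2 regression (NIPALS) onto dummy-coded class membership: two-class
models use a single 0/1 column with a 0.5 decision threshold, multiclass
models use one-hot columns and argmax. Variables are autoscaled by
default. Variable importance in projection satisfies mean(VIP^2) = 1 by
construction; VIP > 1 is the conventional prioritization cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PLSDAModel",
    "plsda_fit",
    "predict",
    "venetian_folds",
    "venetian_cv",
    "permutation_validate",
    "vip_scores",
    "label_schemes",
]


def _dummy_code(labels: np.ndarray) -> tuple:
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if len(classes) == 2:
        Y = (labels == classes[1]).astype(float)[:, None]
    else:
        Y = np.stack([(labels == c).astype(float) for c in classes], axis=1)
    return Y, classes


@dataclass
class PLSDAModel:
    classes: list
    n_lv: int
    W: np.ndarray  # X-weights (p x A)
    P: np.ndarray  # X-loadings (p x A)
    Q: np.ndarray  # Y-loadings (q x A)
    T: np.ndarray  # X-scores (n x A)
    ssy_per_lv: np.ndarray  # Y variance captured per LV
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    r2x: float
    r2y: float
    variables: list = field(default_factory=list)

    @property
    def coef(self) -> np.ndarray:
        """Regression coefficients on the scaled X."""
        return self.W @ np.linalg.solve(self.P.T @ self.W, self.Q.T)


def plsda_fit(
    X,
    labels,
    n_lv: int,
    autoscale: bool = True,
    seed: int | None = None,
) -> PLSDAModel:
    """Fit a PLS2 discriminant model (deterministic NIPALS).

    ``seed`` is accepted for interface uniformity; the fit itself has no
    stochastic element.
    """
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
    labels = np.asarray(labels)
    Xv = Xdf.to_numpy(dtype=float)
    n, p = Xv.shape
    Y, classes = _dummy_code(labels)
    counts = [int((labels == c).sum()) for c in classes]
    if min(counts) < 2:
        raise ValueError("each class needs at least 2 samples")
    if n_lv < 1 or n_lv > min(n - 1, p):
        raise ValueError("n_lv out of range for the data rank")

    x_mean = Xv.mean(axis=0)
    x_scale = Xv.std(axis=0, ddof=1) if autoscale else np.ones(p)
    x_scale = np.where(x_scale > 0, x_scale, 1.0)
    E = (Xv - x_mean) / x_scale
    y_mean = Y.mean(axis=0)
    F = Y - y_mean
    ssx_tot = float(np.sum(E**2))
    ssy_tot = float(np.sum(F**2))

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros((F.shape[1], n_lv))
    T = np.zeros((n, n_lv))
    ssy_lv = np.zeros(n_lv)
    for a in range(n_lv):
        u = F[:, np.argmax(np.sum(F**2, axis=0))].copy()
        w = np.zeros(p)
        for _ in range(500):
            w_new = E.T @ u
            nw = np.linalg.norm(w_new)
            if nw == 0:
                break
            w_new /= nw
            t = E @ w_new
            q = F.T @ t / (t @ t)
            u_new = F @ q / (q @ q) if q @ q > 0 else t
            if np.linalg.norm(w_new - w) < 1e-12:
                w = w_new
                u = u_new
                break
            w, u = w_new, u_new
        t = E @ w
        tt = float(t @ t)
        if tt == 0:
            W, P, Q, T, ssy_lv = W[:, :a], P[:, :a], Q[:, :a], T[:, :a], ssy_lv[:a]
            n_lv = a
            break
        pvec = E.T @ t / tt
        q = F.T @ t / tt
        ss_before = float(np.sum(F**2))
        E = E - np.outer(t, pvec)
        F = F - np.outer(t, q)
        ssy_lv[a] = ss_before - float(np.sum(F**2))
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, pvec, q, t
    if n_lv == 0:
        raise ValueError("no usable latent variables (zero Y variance)")
    r2x = 1.0 - float(np.sum(E**2)) / ssx_tot if ssx_tot > 0 else 0.0
    r2y = 1.0 - float(np.sum(F**2)) / ssy_tot if ssy_tot > 0 else 0.0
    return PLSDAModel(
        classes=classes,
        n_lv=n_lv,
        W=W,
        P=P,
        Q=Q,
        T=T,
        ssy_per_lv=ssy_lv,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        r2x=r2x,
        r2y=r2y,
        variables=list(Xdf.columns),
    )


def predict(model: PLSDAModel, X) -> np.ndarray:
    """Class labels by thresholded (2-class) or argmax (multiclass) dummy
    prediction."""
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    E = (Xv - model.x_mean) / model.x_scale
    Yhat = E @ model.coef + model.y_mean
    if len(model.classes) == 2:
        return np.where(Yhat[:, 0] >= 0.5, model.classes[1], model.classes[0])
    return np.asarray(model.classes)[np.argmax(Yhat, axis=1)]


def venetian_folds(n: int, k: int) -> list:
    """Venetian-blinds split on the design-sorted order: fold(i) = i mod k."""
    if k > n:
        raise ValueError("k exceeds the number of samples")
    return [np.arange(n)[np.arange(n) % k == f] for f in range(k)]


def venetian_cv(
    X,
    labels,
    k: int = 5,
    n_lv_grid=None,
    autoscale: bool = True,
) -> dict:
    """k-fold venetian-blinds cross-validation over a latent-variable grid.

    Returns the class-error curve, the chosen number of LVs (minimum CV
    class error, ties resolved toward fewer LVs), per-class sensitivity
    and the confusion table at the chosen size.
    """
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
    labels = np.asarray(labels)
    n, p = Xdf.shape
    folds = venetian_folds(n, k)
    max_lv = min(n - max(len(f) for f in folds) - 1, p, 10)
    grid = list(n_lv_grid) if n_lv_grid is not None else list(range(1, max_lv + 1))
    grid = [a for a in grid if a <= max_lv] or [1]
    pred = {a: np.empty(n, dtype=object) for a in grid}
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold)
        Xtr, ytr = Xdf.iloc[train], labels[train]
        for a in grid:
            try:
                m = plsda_fit(Xtr, ytr, a, autoscale=autoscale)
            except ValueError:
                for i in fold:
                    pred[a][i] = None
                continue
            yp = predict(m, Xdf.iloc[fold])
            for i, y in zip(fold, yp):
                pred[a][i] = y
    errors = {}
    for a in grid:
        ok = np.array([pred[a][i] is not None for i in range(n)])
        errors[a] = float(np.mean([pred[a][i] != labels[i] for i in range(n) if ok[i]])) if ok.any() else 1.0
    best = min(grid, key=lambda a: (errors[a], a))
    ybest = pred[best]
    classes = sorted(set(labels))
    confusion = pd.DataFrame(0, index=classes, columns=classes)
    for i in range(n):
        if ybest[i] is not None:
            confusion.loc[labels[i], ybest[i]] += 1
    sens = {
        c: float(confusion.loc[c, c] / confusion.loc[c].sum()) if confusion.loc[c].sum() else np.nan
        for c in classes
    }
    return {
        "errors": errors,
        "n_lv": best,
        "class_error": errors[best],
        "confusion": confusion,
        "sensitivity": sens,
        "predictions": ybest,
    }


def permutation_validate(
    X,
    labels,
    k: int = 5,
    n_perm: int = 200,
    n_lv_grid=None,
    seed: int | None = None,
    autoscale: bool = True,
) -> dict:
    """Label-permutation validation of the CV class error.

    p = (1 + #{permuted error <= observed}) / (1 + n_perm): the fraction
    of label shufflings that cross-validate at least as well as the real
    labels.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    obs = venetian_cv(X, labels, k=k, n_lv_grid=n_lv_grid, autoscale=autoscale)
    count = 0
    perm_errors = []
    for _ in range(n_perm):
        lp = labels[rng.permutation(len(labels))]
        try:
            e = venetian_cv(X, lp, k=k, n_lv_grid=n_lv_grid, autoscale=autoscale)["class_error"]
        except ValueError:
            e = 1.0
        perm_errors.append(e)
        if e <= obs["class_error"]:
            count += 1
    return {
        "p_value": (1 + count) / (1 + n_perm),
        "observed_error": obs["class_error"],
        "perm_errors": np.array(perm_errors),
        "cv": obs,
    }


def vip_scores(model: PLSDAModel) -> pd.Series:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ),
    where SSY_a is the Y sum of squares captured by latent variable a.
    mean(VIP^2) = 1 over variables, so VIP > 1 marks variables carrying
    more than an equal share of the discrimination.
    """
    ssy = model.ssy_per_lv
    if ssy.sum() <= 0:
        raise ValueError("model captured no Y variance")
    p = model.W.shape[0]
    wnorm2 = np.sum(model.W**2, axis=0)
    wnorm2 = np.where(wnorm2 > 0, wnorm2, 1.0)
    contrib = (model.W**2 / wnorm2) @ ssy
    vip = np.sqrt(p * contrib / ssy.sum())
    return pd.Series(vip, index=model.variables or range(p), name="VIP")


def label_schemes(design, samples: list) -> dict:
    """The three classification labelings used on the mesocosm design:
    control vs treatment; early (S1-S4) vs late (S5-S7); and the 3-class
    scheme {control early, treated early, all late}."""
    info = {s.sample_id: s for s in design.study_samples}
    early = {"S1", "S2", "S3", "S4"}
    schemes = {
        "type": np.array([info[s].sample_type for s in samples]),
        "early_late": np.array(
            ["early" if info[s].time_level in early else "late" for s in samples]
        ),
    }
    three = []
    for s in samples:
        if info[s].time_level not in early:
            three.append("late")
        else:
            three.append("control_early" if info[s].sample_type == "control" else "treated_early")
    schemes["three_class"] = np.array(three)
    return schemes
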