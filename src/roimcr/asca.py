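"""ANOVA-simultaneous component analysis for the two-factor mesocosm design.

ASCA partitions the (pre-processed, variable-centered) area matrix into
additive effect matrices for sample type (F1), time (F2) and their
interaction, then applies PCA per effect. Effect matrices come from a
sum-coded general linear model fit of every variable on the full coding
(type III partial effects, the ASCA+ construction), so the partition is
unbiased when outlier removal leaves the design unbalanced; on a
balanced design it coincides with classical cell-mean ASCA. Effect
significance is assessed by permutation of the tested factor's labels,
and per-variable loading robustness by stratified bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import StudyDesign

__all__ = [
    "ASCAResult",
    "build_design_codes",
    "asca_fit",
    "classical_asca_percents",
    "permutation_test",
    "bootstrap_loadings",
    "pca_explore",
]

EFFECTS = ("type", "time", "interaction")


def _sum_code(labels: list, levels: list) -> np.ndarray:
    """Deviation (sum-to-zero) coding: L levels -> L-1 columns."""
    n, L = len(labels), len(levels)
    M = np.zeros((n, L - 1))
    for i, lab in enumerate(labels):
        j = levels.index(lab)
        if j == L - 1:
            M[i, :] = -1.0
        else:
            M[i, j] = 1.0
    return M


def build_design_codes(design: StudyDesign, samples: list | None = None) -> dict:
    """Sum-to-zero coded design matrices for F1, F2 and F1xF2.

    Operates on the study samples only (blanks/QC are excluded before any
    ASCA). Interaction columns are the element-wise products of the
    main-effect columns. Returns a dict of DataFrames keyed by
    ``intercept``/``type``/``time``/``interaction``.
    """
    infos = [s for s in design.study_samples if samples is None or s.sample_id in samples]
    if samples is not None:
        infos.sort(key=lambda s: samples.index(s.sample_id))
    ids = [s.sample_id for s in infos]
    type_levels = sorted({s.sample_type for s in infos})
    time_levels = sorted({s.time_level for s in infos})
    if len(type_levels) < 2 or len(time_levels) < 2:
        raise ValueError("each factor needs at least 2 observed levels")
    F1 = _sum_code([s.sample_type for s in infos], type_levels)
    F2 = _sum_code([s.time_level for s in infos], time_levels)
    inter = np.einsum("ij,ik->ijk", F1, F2).reshape(len(ids), -1)
    return {
        "sample_ids": ids,
        "intercept": pd.DataFrame(np.ones((len(ids), 1)), index=ids, columns=["mu"]),
        "type": pd.DataFrame(F1, index=ids, columns=[f"type_{l}" for l in type_levels[:-1]]),
        "time": pd.DataFrame(F2, index=ids, columns=[f"time_{l}" for l in time_levels[:-1]]),
        "interaction": pd.DataFrame(
            inter,
            index=ids,
            columns=[f"tx_{i}_{j}" for i in range(F1.shape[1]) for j in range(F2.shape[1])],
        ),
    }


def _effect_matrices(X: np.ndarray, codes: dict, effects, check_rank: bool = True) -> tuple:
    """GLM (type III) effect matrices from the full sum-coded model.

    ``check_rank=False`` tolerates a rank-deficient coding (e.g. a design
    cell emptied by a label permutation) via the minimum-norm solution.
    """
    D = np.hstack([codes["intercept"].to_numpy()] + [codes[e].to_numpy() for e in effects])
    if check_rank and np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("rank-deficient design coding (confounded design)")
    beta, *_ = np.linalg.lstsq(D, X, rcond=None)
    mats = {}
    col = 1
    for e in effects:
        w = codes[e].shape[1]
        mats[e] = codes[e].to_numpy() @ beta[col : col + w]
        col += w
    resid = X - D @ beta
    return mats, resid


@dataclass
class ASCAResult:
    effects: dict  # name -> dict(percent, p_value, effect_matrix, scores, loadings, expl_var)
    residual_percent: float
    sample_ids: list
    variables: list
    total_ss: float

    def percents(self) -> pd.Series:
        s = {e: d["percent"] for e, d in self.effects.items()}
        s["residual"] = self.residual_percent
        return pd.Series(s)

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "effect": e,
                "percent_variation": d["percent"],
                "p_value": d.get("p_value", np.nan),
            }
            for e, d in self.effects.items()
        ]
        rows.append({"effect": "residual", "percent_variation": self.residual_percent, "p_value": np.nan})
        return pd.DataFrame(rows)


def asca_fit(
    X: pd.DataFrame,
    design: StudyDesign,
    effects=EFFECTS,
    max_pcs: int = 3,
    min_pc_fraction: float = 0.05,
) -> ASCAResult:
    """Fit the ASCA(+) decomposition of a samples x variables matrix.

    ``X`` rows must be study-sample ids. Variables are mean-centered; the
    percent variation of an effect is the sum of squares of its effect
    matrix over that of the centered data. Per effect, SCA loadings are
    the right singular vectors of the effect matrix (PCs explaining at
    least ``min_pc_fraction`` of the effect, capped at ``max_pcs``), and
    the reported scores project effect + residual onto them (augmented
    scores, so replicate scatter is visible in score plots).
    """
    codes = build_design_codes(design, samples=list(X.index))
    ids = codes["sample_ids"]
    Xv = X.loc[ids].to_numpy(dtype=float)
    Xc = Xv - Xv.mean(axis=0, keepdims=True)
    total_ss = float(np.sum(Xc**2))
    if total_ss == 0:
        result_effects = {
            e: {"percent": 0.0, "effect_matrix": np.zeros_like(Xc), "scores": None, "loadings": None, "expl_var": None}
            for e in effects
        }
        return ASCAResult(result_effects, 0.0, ids, list(X.columns), 0.0)
    mats, resid = _effect_matrices(Xc, codes, effects)
    out = {}
    for e in effects:
        M = mats[e]
        percent = 100.0 * float(np.sum(M**2)) / total_ss
        U, s, Vt = np.linalg.svd(M, full_matrices=False)
        ev = s**2
        frac = ev / ev.sum() if ev.sum() > 0 else ev
        n_pc = max(1, min(max_pcs, int(np.sum(frac >= min_pc_fraction))))
        P = Vt[:n_pc].T
        out[e] = {
            "percent": percent,
            "effect_matrix": M,
            "loadings": pd.DataFrame(P, index=X.columns, columns=[f"PC{i+1}" for i in range(n_pc)]),
            "scores": pd.DataFrame(
                (M + resid) @ P, index=ids, columns=[f"PC{i+1}" for i in range(n_pc)]
            ),
            "expl_var": frac[:n_pc],
        }
    residual_percent = 100.0 * float(np.sum(resid**2)) / total_ss
    return ASCAResult(out, residual_percent, ids, list(X.columns), total_ss)


def classical_asca_percents(X: pd.DataFrame, design: StudyDesign) -> pd.Series:
    """Cell-mean (classical) ASCA variance partition — the balanced-design
    oracle for the GLM route."""
    infos = [s for s in design.study_samples if s.sample_id in set(X.index)]
    ids = [s.sample_id for s in infos]
    Xv = X.loc[ids].to_numpy(dtype=float)
    Xc = Xv - Xv.mean(axis=0, keepdims=True)
    t_lab = np.array([s.sample_type for s in infos])
    h_lab = np.array([s.time_level for s in infos])
    M1 = np.zeros_like(Xc)
    for l in np.unique(t_lab):
        M1[t_lab == l] = Xc[t_lab == l].mean(axis=0)
    M2 = np.zeros_like(Xc)
    for l in np.unique(h_lab):
        M2[h_lab == l] = Xc[h_lab == l].mean(axis=0)
    M12 = np.zeros_like(Xc)
    for lt in np.unique(t_lab):
        for lh in np.unique(h_lab):
            cell = (t_lab == lt) & (h_lab == lh)
            if cell.any():
                M12[cell] = Xc[cell].mean(axis=0)
    M12 = M12 - M1 - M2
    resid = Xc - M1 - M2 - M12
    tot = float(np.sum(Xc**2))
    return pd.Series(
        {
            "type": 100 * float(np.sum(M1**2)) / tot,
            "time": 100 * float(np.sum(M2**2)) / tot,
            "interaction": 100 * float(np.sum(M12**2)) / tot,
            "residual": 100 * float(np.sum(resid**2)) / tot,
        }
    )


def _effect_ss(X: np.ndarray, codes: dict, effect: str, effects=EFFECTS, check_rank: bool = True) -> float:
    mats, _ = _effect_matrices(X, codes, effects, check_rank=check_rank)
    return float(np.sum(mats[effect] ** 2))


def permutation_test(
    X: pd.DataFrame,
    design: StudyDesign,
    effect: str,
    n_perm: int = 1000,
    seed: int | None = None,
    effects=EFFECTS,
) -> float:
    """Permutation p-value for one effect's sum of squares.

    The tested factor's labels are permuted within the levels of the
    other factor (preserving the cell allocation, so the permutation
    distribution is exact under within-level exchangeability); for the
    interaction the joint cell assignment is permuted freely. The full
    type III model is refit on each permutation.
    p = (1 + #{perm SS >= observed SS}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    infos = [s for s in design.study_samples if s.sample_id in set(X.index)]
    ids = [s.sample_id for s in infos]
    Xv = X.loc[ids].to_numpy(dtype=float)
    Xc = Xv - Xv.mean(axis=0, keepdims=True)
    codes = build_design_codes(design, samples=ids)
    obs = _effect_ss(Xc, codes, effect, effects)
    type_lab = np.array([s.sample_type for s in infos])
    time_lab = np.array([s.time_level for s in infos])
    n = len(ids)

    def strata(other_lab):
        return [np.nonzero(other_lab == lvl)[0] for lvl in np.unique(other_lab)]

    count = 0
    for _ in range(n_perm):
        t_lab, h_lab = type_lab.copy(), time_lab.copy()
        if effect == "type":
            for idx in strata(time_lab):
                t_lab[idx] = t_lab[idx[rng.permutation(idx.size)]]
        elif effect == "time":
            for idx in strata(type_lab):
                h_lab[idx] = h_lab[idx[rng.permutation(idx.size)]]
        else:  # interaction: permute the joint cell assignment
            perm = rng.permutation(n)
            t_lab, h_lab = type_lab[perm], time_lab[perm]
        pcodes = _codes_from_labels(ids, list(t_lab), list(h_lab))
        ss = _effect_ss(Xc, pcodes, effect, effects, check_rank=False)
        if ss >= obs:
            count += 1
    return (1 + count) / (1 + n_perm)


def _codes_from_labels(ids: list, type_lab: list, time_lab: list) -> dict:
    type_levels = sorted(set(type_lab))
    time_levels = sorted(set(time_lab))
    F1 = _sum_code(type_lab, type_levels)
    F2 = _sum_code(time_lab, time_levels)
    inter = np.einsum("ij,ik->ijk", F1, F2).reshape(len(ids), -1)
    return {
        "sample_ids": ids,
        "intercept": pd.DataFrame(np.ones((len(ids), 1)), index=ids),
        "type": pd.DataFrame(F1, index=ids),
        "time": pd.DataFrame(F2, index=ids),
        "interaction": pd.DataFrame(inter, index=ids),
    }


def bootstrap_loadings(
    X: pd.DataFrame,
    design: StudyDesign,
    effect: str,
    n_boot: int = 500,
    alpha: float = 0.05,
    seed: int | None = None,
    pc: int = 0,
) -> pd.DataFrame:
    """Bootstrap robustness of an effect's PC loadings.

    Samples are resampled with replacement within design cells (falling
    back to whole-stratum resampling with a warning if a cell has a
    single sample); the effect SCA is refit per replicate and its PC
    loading vector sign-aligned to the full-data reference. A variable is
    flagged significant when its percentile (1 - alpha) interval excludes
    zero.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    ref = asca_fit(X, design)
    ref_load = ref.effects[effect]["loadings"].iloc[:, pc].to_numpy()
    infos = [s for s in design.study_samples if s.sample_id in set(X.index)]
    cells = {}
    for s in infos:
        cells.setdefault((s.sample_type, s.time_level), []).append(s.sample_id)
    if any(len(v) < 2 for v in cells.values()):
        warnings.warn("cells with a single sample: falling back to whole-stratum resampling")
        cells = {"all": [s.sample_id for s in infos]}
    boots = np.empty((n_boot, X.shape[1]))
    for b in range(n_boot):
        # a resampled sample keeps its design labels but takes a donor's data row
        donor = {}
        for ids in cells.values():
            take = rng.integers(0, len(ids), len(ids))
            for sid, j in zip(ids, take):
                donor[sid] = ids[j]
        Xb = X.loc[[donor[s.sample_id] for s in infos]].copy()
        Xb.index = [s.sample_id for s in infos]
        try:
            res = asca_fit(Xb, design)
        except ValueError:
            boots[b] = np.nan
            continue
        load = res.effects[effect]["loadings"].iloc[:, pc].to_numpy()
        if np.dot(load, ref_load) < 0:
            load = -load
        boots[b] = load
    lo = np.nanpercentile(boots, 100 * alpha / 2, axis=0)
    hi = np.nanpercentile(boots, 100 * (1 - alpha / 2), axis=0)
    sig = (lo > 0) | (hi < 0)
    return pd.DataFrame(
        {"loading": ref_load, "ci_low": lo, "ci_high": hi, "significant": sig},
        index=X.columns,
    )


def pca_explore(X: pd.DataFrame, n_components: int | None = None) -> dict:
    """Mean-centered exploratory PCA of the pre-processed matrix."""
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    from sklearn.decomposition import PCA

    n = min(n_components or min(X.shape) - 1, min(X.shape) - 1, X.shape[1])
    n = max(n, 1)
    pca = PCA(n_components=n)
    scores = pca.fit_transform(X.to_numpy(dtype=float))
    cols = [f"PC{i+1}" for i in range(n)]
    return {
        "scores": pd.DataFrame(scores, index=X.index, columns=cols),
        "loadings": pd.DataFrame(pca.components_.T, index=X.columns, columns=cols),
        "explained_variance_ratio": pca.explained_variance_ratio_,
    }
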