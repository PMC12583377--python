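"""Multivariate curve resolution by alternating least squares.

Resolves the augmented matrix into non-negative elution profiles and
mass spectra, D_aug = C_aug S_MS^T + E. Each ALS half-step is an exact
non-negative least-squares solve (not clip-to-zero), so the lack of fit
is non-increasing over iterations — an invariant the tests assert.

Conventions: spectra are max-normalized every iteration with the
magnitude carried in C, so the integrated C profiles serve directly as
per-sample component areas (quantification surrogate scores). Lack of
fit LOF = 100*sqrt(sum E^2 / sum D^2); explained variance
R2 = 100*(1 - sum E^2 / sum D^2), hence (LOF/100)^2 + R2/100 = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._nnls import nnls_multiple
from .assembly import AugmentedMatrix
from .synthetic import StudyDesign

__all__ = [
    "MCRModel",
    "ComponentAreaMatrix",
    "estimate_rank",
    "initialize_spectra",
    "fit",
    "fit_region_auto",
    "decompose_regions",
    "compute_areas",
    "assemble_area_matrix",
    "clean_components",
]


@dataclass
class MCRModel:
    """Fitted bilinear model of one region's augmented matrix."""

    C: np.ndarray  # (rows, N) elution profiles, >= 0
    S: np.ndarray  # (n_cols, N) spectra, >= 0, max-normalized columns
    col_mz: np.ndarray
    block_index: dict
    rt_axes: dict
    n_components: int
    lof: float
    r2: float
    lof_history: list = field(default_factory=list)
    converged: bool = True
    region_id: int = 0
    rt_window: tuple | None = None

    def residual(self, data: np.ndarray) -> np.ndarray:
        return data - self.C @ self.S.T

    def base_peak_mz(self, k: int) -> float:
        return float(self.col_mz[int(np.argmax(self.S[:, k]))])

    def apex_rt(self, k: int, sample_id: str | None = None) -> float:
        """Apex RT of component k (in the overall-max block by default)."""
        if sample_id is None:
            i = int(np.argmax(self.C[:, k]))
            for sid, sl in self.block_index.items():
                if sl.start <= i < sl.stop:
                    return float(self.rt_axes[sid][i - sl.start])
            return float("nan")
        sl = self.block_index[sample_id]
        prof = self.C[sl, k]
        return float(self.rt_axes[sample_id][int(np.argmax(prof))])


def _lof_r2(data: np.ndarray, C: np.ndarray, S: np.ndarray) -> tuple:
    ss_res = float(np.sum((data - C @ S.T) ** 2))
    ss_tot = float(np.sum(data**2))
    ratio = ss_res / ss_tot if ss_tot > 0 else 0.0
    return 100.0 * np.sqrt(ratio), 100.0 * (1.0 - ratio)


def estimate_rank(data: np.ndarray, rel_floor: float = 1e-10, median_factor: float = 3.0):
    """Singular-value profile with a noise-floor rank suggestion.

    Suggested N counts singular values above ``median_factor`` times the
    median (the median sits in the noise bulk when the matrix is mostly
    noise) and above an absolute floor relative to s1. The final N stays
    user-confirmable; :func:`fit_region_auto` refines it against a target
    lack of fit.
    """
    data = np.asarray(data, dtype=float)
    if data.size == 0 or not data.any():
        raise ValueError("empty region")
    s = np.linalg.svd(data, compute_uv=False)
    floor = max(median_factor * float(np.median(s)), rel_floor * s[0])
    return int(np.sum(s > floor)), s


def initialize_spectra(data: np.ndarray, n_components: int, alpha_frac: float = 0.05) -> np.ndarray:
    """Purest-row (SIMPLISMA-style) initial spectra.

    Selects the N most mutually dissimilar high-purity rows of the region
    matrix: purity is std/(mean + alpha) per row, down-weighted for rows
    correlated (around the origin) with already-selected ones via the
    determinant of the correlation submatrix. With selective elution the
    selected rows are single-component scans, i.e. pure spectra.
    """
    data = np.asarray(data, dtype=float)
    m, n = data.shape
    if n_components > min(m, n):
        raise ValueError("n_components exceeds matrix dimensions")
    mu = data.mean(axis=1)
    sd = data.std(axis=1)
    alpha = alpha_frac * float(mu.max())
    purity = sd / (mu + alpha if alpha > 0 else mu + 1e-12)
    norm = np.sqrt(mu**2 + (sd + alpha) ** 2)
    norm[norm == 0] = 1.0
    Z = data / (norm[:, None] * np.sqrt(n))
    # determinant weight via the Schur complement: for candidate i and
    # selected set S, det(COO[{i} u S]) = det(COO[S]) * (c_ii - v_i' A^-1 v_i)
    diag = np.einsum("ij,ij->i", Z, Z)
    selected: list[int] = []
    for _ in range(n_components):
        if selected:
            Zs = Z[selected]  # (k, n)
            A = Zs @ Zs.T
            V = Zs @ Z.T  # (k, m): v_i columns
            detA = float(np.linalg.det(A))
            schur = diag - np.einsum("km,km->m", np.linalg.solve(A, V), V)
            w = detA * schur
        else:
            w = diag.copy()  # det of the 1x1 COO submatrix
        val = purity * np.maximum(w, 0.0)
        val[selected] = -np.inf
        selected.append(int(np.argmax(val)))
    return data[selected].copy()


def fit(
    region: AugmentedMatrix,
    n_components: int,
    S0: np.ndarray | None = None,
    tol: float = 1e-3,
    max_iter: int = 50,
    region_id: int = 0,
) -> MCRModel:
    """Constrained alternating least squares on one region.

    Alternates exact NNLS solves for C given S and S given C from a
    purest-variable initialization, stopping when the relative LOF change
    drops below ``tol`` (default 0.1%) or at ``max_iter``. Non-negativity
    is the only constraint; shape handling is post hoc in
    :func:`clean_components`.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    D = region.data
    if S0 is None:
        S0 = initialize_spectra(D, n_components)
    S = np.maximum(np.asarray(S0, dtype=float).T, 0.0)  # (n_cols, N)
    smax = S.max(axis=0)
    smax[smax == 0] = 1.0
    S = S / smax

    lof_history = []
    converged = False
    C = np.zeros((D.shape[0], n_components))
    for _ in range(max_iter):
        C = nnls_multiple(S, D.T).T  # rows of D on the spectral basis
        S = nnls_multiple(C, D).T  # columns of D on the elution basis
        # normalize spectra to unit base peak; carry magnitude in C
        smax = S.max(axis=0)
        scale = np.where(smax > 0, smax, 1.0)
        S = S / scale
        C = C * scale
        lof, _ = _lof_r2(D, C, S)
        lof_history.append(lof)
        if len(lof_history) > 1:
            prev = lof_history[-2]
            if prev > 0 and abs(prev - lof) / prev < tol:
                converged = True
                break
            if lof < 1e-6:  # numerically exact factorization
                converged = True
                break
    lof, r2 = _lof_r2(D, C, S)
    return MCRModel(
        C=C,
        S=S,
        col_mz=region.col_mz,
        block_index=region.block_index,
        rt_axes=region.rt_axes,
        n_components=n_components,
        lof=lof,
        r2=r2,
        lof_history=lof_history,
        converged=converged,
        region_id=region_id,
        rt_window=region.rt_window,
    )


def fit_region_auto(
    region: AugmentedMatrix,
    n_components: int | str = "auto",
    target_lof: float = 7.3,
    max_extra: int = 8,
    tol: float = 1e-3,
    max_iter: int = 50,
    region_id: int = 0,
) -> MCRModel:
    """Fit a region, growing N from the rank suggestion until the lack of
    fit reaches the target (or the component budget is exhausted).

    Growing far past the target is deliberately avoided: surplus
    components soak up sample-specific noise as spike profiles and split
    real compounds. Compounds fully coeluting with near-proportional
    abundance patterns remain merged into multi-mass components, which is
    the correct bilinear resolution of such data; downstream comparisons
    therefore work on unfolded spectrum members, not base peaks alone.
    """
    if n_components == "auto":
        n0, _ = estimate_rank(region.data)
        n0 = max(n0, 1)
    else:
        n0 = int(n_components)
    cap = min(region.data.shape[1], region.data.shape[0], n0 + max_extra)
    model = fit(region, n0, tol=tol, max_iter=max_iter, region_id=region_id)
    n = n0

    while model.lof > target_lof and n < cap:
        n += 1
        # warm start: previous spectra plus the worst-fit row's residual
        resid = model.residual(region.data)
        extra = np.maximum(resid[int(np.argmax(np.sum(resid**2, axis=1)))], 0.0)
        S0 = np.vstack([model.S.T, extra])
        model = fit(region, n, S0=S0, tol=tol, max_iter=max_iter, region_id=region_id)
    return model


def decompose_regions(
    regions: list,
    n_components: int | str | list = "auto",
    target_lof: float = 7.3,
    tol: float = 1e-3,
    max_iter: int = 50,
) -> list:
    """Decompose every region; skips regions with no signal columns."""
    models = []
    for r, region in enumerate(regions):
        if region.data.shape[1] == 0 or not region.data.any():
            continue
        n = n_components[r] if isinstance(n_components, list) else n_components
        models.append(
            fit_region_auto(region, n, target_lof=target_lof, tol=tol, max_iter=max_iter, region_id=r)
        )
    return models


@dataclass
class ComponentAreaMatrix:
    """Per-sample integrated areas of resolved components, with metadata."""

    areas: pd.DataFrame  # samples x components
    meta: pd.DataFrame  # per component: base_mz, apex_rt, region, spectrum index
    spectra: dict  # component id -> (col_mz, intensities)

    def select(self, component_ids) -> "ComponentAreaMatrix":
        ids = list(component_ids)
        return ComponentAreaMatrix(
            self.areas[ids].copy(), self.meta.loc[ids].copy(), {k: self.spectra[k] for k in ids}
        )


def compute_areas(model: MCRModel, design: StudyDesign) -> ComponentAreaMatrix:
    """Trapezoid-integrate each component's elution profile per block.

    area(sample, component) = integral of the block's C column over the
    block RT axis; with max-normalized spectra this is the base-peak
    trace area, directly comparable across samples.
    """
    sample_ids = [s for s in design.sample_ids if s in model.block_index]
    comp_ids = [f"r{model.region_id:02d}_c{k}" for k in range(model.n_components)]
    A = np.zeros((len(sample_ids), model.n_components))
    for i, sid in enumerate(sample_ids):
        sl = model.block_index[sid]
        rts = model.rt_axes[sid]
        for k in range(model.n_components):
            A[i, k] = np.trapezoid(model.C[sl, k], rts) if sl.stop > sl.start else 0.0
    areas = pd.DataFrame(A, index=sample_ids, columns=comp_ids)
    meta = pd.DataFrame(
        {
            "base_mz": [model.base_peak_mz(k) for k in range(model.n_components)],
            "apex_rt": [model.apex_rt(k) for k in range(model.n_components)],
            "region": model.region_id,
        },
        index=comp_ids,
    )
    spectra = {cid: (model.col_mz.copy(), model.S[:, k].copy()) for k, cid in enumerate(comp_ids)}
    return ComponentAreaMatrix(areas, meta, spectra)


def assemble_area_matrix(models: list, design: StudyDesign) -> ComponentAreaMatrix:
    parts = [compute_areas(m, design) for m in models]
    if not parts:
        raise ValueError("no fitted models")
    return ComponentAreaMatrix(
        pd.concat([p.areas for p in parts], axis=1),
        pd.concat([p.meta for p in parts], axis=0),
        {k: v for p in parts for k, v in p.spectra.items()},
    )


# ---------------------------------------------------------------------------
# component cleaning


@dataclass
class ShapeRules:
    """Peak-likeness criteria applied to resolved elution profiles."""

    min_width_s: float = 2.0  # FWHM bounds
    max_width_s: float = 60.0
    min_top_to_edge: float = 5.0  # apex over the lower of the two region edges
    min_unimodal_fraction: float = 0.7  # profile mass within +-4 sigma of apex
    n_reference_blocks: int = 5  # score the top blocks by area, take the median


def _profile_shape_score(prof: np.ndarray, rts: np.ndarray, rules: ShapeRules) -> dict:
    """Shape diagnostics of one block's elution profile."""
    apex = float(prof.max())
    if apex <= 0 or prof.size < 5:
        return {"ok": False, "width": np.nan, "top_edge": np.nan, "unimodal": np.nan}
    i_apex = int(np.argmax(prof))
    half = apex / 2.0
    above = prof >= half
    # contiguous half-height run around the apex
    left = i_apex
    while left > 0 and above[left - 1]:
        left -= 1
    right = i_apex
    while right < prof.size - 1 and above[right + 1]:
        right += 1
    width = float(rts[right] - rts[left]) if right > left else float(rts[1] - rts[0])
    n_edge = max(2, prof.size // 20)
    edge = min(float(prof[:n_edge].mean()), float(prof[-n_edge:].mean()))
    top_edge = apex / (edge + 1e-12 * apex) if edge > 0 else np.inf
    sigma_est = width / 2.355
    sel = (rts >= rts[i_apex] - 4 * sigma_est) & (rts <= rts[i_apex] + 4 * sigma_est)
    total = float(prof.sum())
    unimodal = float(prof[sel].sum()) / total if total > 0 else 0.0
    ok = (
        rules.min_width_s <= width <= rules.max_width_s
        and top_edge >= rules.min_top_to_edge
        and unimodal >= rules.min_unimodal_fraction
    )
    return {"ok": ok, "width": width, "top_edge": top_edge, "unimodal": unimodal}


def clean_components(
    cam: ComponentAreaMatrix,
    models: list,
    design: StudyDesign,
    blank_fold: float = 3.0,
    shape_rules: ShapeRules | None = None,
    max_replicate_cv: float = 1.0,
    min_consistent_fraction: float = 0.5,
    min_presence_fraction: float = 0.4,
) -> tuple:
    """Reject background/artifact components; keep mesocosm chemistry.

    Four rules, applied in order and each rejection logged:

    (a) blank criterion — the component's maximum area over study samples
        must reach ``blank_fold`` times its maximum blank area;
    (b) shape criteria — the resolved elution profile must look like a
        chromatographic peak (half-height width within bounds, apex well
        above the region edges, unimodal) in the median of its strongest
        blocks;
    (c) prevalence — a compound of the water system is detectable in most
        runs; a component with area above 1% of its maximum in fewer than
        ``min_presence_fraction`` of the study samples is a sporadic
        artifact (the minimum-samples row filter of feature-profiling
        tools);
    (d) replicate consistency — among the design cells where the
        component is detected (cell mean at least 10% of its maximum cell
        mean), fewer than ``min_consistent_fraction`` have a replicate CV
        within ``max_replicate_cv``: an erratically appearing artifact.

    Returns ``(retained ComponentAreaMatrix, rejection log DataFrame)``.
    """
    rules = shape_rules or ShapeRules()
    blank_ids = [b for b in design.blank_ids if b in cam.areas.index]
    study = [s.sample_id for s in design.study_samples if s.sample_id in cam.areas.index]
    if blank_fold is not None and blank_fold > 0 and not blank_ids:
        raise ValueError("blank rule enabled but design has no blanks")
    model_by_region = {m.region_id: m for m in models}

    records = []
    retained = []
    for cid in cam.areas.columns:
        region = int(cam.meta.loc[cid, "region"])
        k = int(cid.rsplit("_c", 1)[1])
        model = model_by_region[region]
        # (a) blank fold change
        max_study = float(cam.areas.loc[study, cid].max())
        max_blank = float(cam.areas.loc[blank_ids, cid].max()) if blank_ids else 0.0
        if blank_fold and max_study < blank_fold * max_blank:
            records.append({"component": cid, "rule": "blank", "value": max_study / (max_blank + 1e-30)})
            continue
        # (b) shape on the strongest study blocks
        order = cam.areas.loc[study, cid].sort_values(ascending=False).index
        scores = []
        for sid in order[: rules.n_reference_blocks]:
            sl = model.block_index[sid]
            scores.append(_profile_shape_score(model.C[sl, k], model.rt_axes[sid], rules))
        n_ok = sum(s["ok"] for s in scores)
        if not scores or n_ok * 2 < len(scores):  # majority vote
            records.append({"component": cid, "rule": "shape", "value": float(n_ok)})
            continue
        # (c) prevalence across study samples
        vals_all = cam.areas.loc[study, cid].to_numpy()
        presence = float(np.mean(vals_all > 0.01 * vals_all.max())) if vals_all.max() > 0 else 0.0
        if presence < min_presence_fraction:
            records.append({"component": cid, "rule": "prevalence", "value": presence})
            continue
        # (d) replicate consistency across design cells, judged only where
        # the component is actually detected: cells at the noise floor say
        # nothing about reproducibility either way
        cells = {}
        for s in design.study_samples:
            if s.sample_id in cam.areas.index:
                cells.setdefault((s.sample_type, s.time_level), []).append(s.sample_id)
        cell_means = {}
        for key, ids in cells.items():
            if len(ids) >= 2:
                cell_means[key] = float(cam.areas.loc[ids, cid].mean())
        max_mean = max(cell_means.values(), default=0.0)
        cvs = []
        for key, ids in cells.items():
            if len(ids) < 2 or cell_means.get(key, 0.0) < 0.1 * max_mean:
                continue
            vals = cam.areas.loc[ids, cid].to_numpy()
            mean = vals.mean()
            cvs.append(vals.std(ddof=1) / mean if mean > 0 else np.inf)
        if cvs:
            consistent = sum(cv <= max_replicate_cv for cv in cvs) / len(cvs)
            if consistent < min_consistent_fraction:
                records.append({"component": cid, "rule": "replicate-cv", "value": consistent})
                continue
        retained.append(cid)
        records.append({"component": cid, "rule": "retained", "value": np.nan})

    log = pd.DataFrame(records, columns=["component", "rule", "value"])
    return cam.select(retained), log
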