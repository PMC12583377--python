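"""Feature-list correspondence between the two NTS workflows.

Quantifies the overlap between ROI/component-derived mass lists and
feature-profiling feature lists: mass-only matching (0.005 Da), mass+RT
matching (0.005 Da and 0.3 min), unfolding of resolved component spectra
into their constituent masses (above 5% of the base peak), and staged
coverage/Venn summaries. All tolerance comparisons are inclusive (a pair
exactly at the tolerance matches).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MassEntry",
    "CorrespondenceReport",
    "match_by_mass",
    "match_by_mass_rt",
    "match_brute",
    "unfold_component",
    "stage_report",
]


@dataclass(frozen=True)
class MassEntry:
    """One comparable mass: a ROI, an FP feature, or a component member."""

    entry_id: str
    mz: float
    rt: float | None = None  # seconds
    intensity: float = 0.0
    source: str = "roi"  # roi | fp-feature | mcr-component-member

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError("m/z must be positive")


@dataclass
class CorrespondenceReport:
    pairs: pd.DataFrame  # id_a, id_b, delta_mz, delta_rt
    coverage_a: float  # fraction of A entries matched to >= 1 B entry
    coverage_b: float
    unmatched_a: list = field(default_factory=list)
    unmatched_b: list = field(default_factory=list)
    multiple_matches_a: int = 0  # A entries with > 1 match
    multiple_matches_b: int = 0


def _as_arrays(entries, need_rt: bool):
    ids = [e.entry_id for e in entries]
    mz = np.array([e.mz for e in entries], dtype=float)
    rt = np.array([e.rt if e.rt is not None else np.nan for e in entries], dtype=float)
    if need_rt and np.isnan(rt).any():
        raise ValueError("RT required for mass+RT matching but missing")
    return ids, mz, rt


def _build_report(ids_a, ids_b, pair_idx, deltas) -> CorrespondenceReport:
    pairs = pd.DataFrame(
        {
            "id_a": [ids_a[i] for i, _ in pair_idx],
            "id_b": [ids_b[j] for _, j in pair_idx],
            "delta_mz": [d[0] for d in deltas],
            "delta_rt": [d[1] for d in deltas],
        }
    )
    matched_a = set(pairs["id_a"])
    matched_b = set(pairs["id_b"])
    counts_a = pairs["id_a"].value_counts() if len(pairs) else pd.Series(dtype=int)
    counts_b = pairs["id_b"].value_counts() if len(pairs) else pd.Series(dtype=int)
    return CorrespondenceReport(
        pairs=pairs,
        coverage_a=len(matched_a) / len(ids_a),
        coverage_b=len(matched_b) / len(ids_b),
        unmatched_a=[i for i in ids_a if i not in matched_a],
        unmatched_b=[j for j in ids_b if j not in matched_b],
        multiple_matches_a=int((counts_a > 1).sum()),
        multiple_matches_b=int((counts_b > 1).sum()),
    )


def match_by_mass(A: list, B: list, mz_tol: float = 0.005) -> CorrespondenceReport:
    """All-pairs mass matching: a and b match iff |mz_a - mz_b| <= tol.

    Multiple matches are retained (and counted) — one ROI mass can
    legitimately correspond to several features and vice versa.
    """
    if mz_tol < 0:
        raise ValueError("tolerance must be non-negative")
    if not A or not B:
        raise ValueError("both lists must be nonempty")
    ids_a, mz_a, _ = _as_arrays(A, need_rt=False)
    ids_b, mz_b, _ = _as_arrays(B, need_rt=False)
    order = np.argsort(mz_b, kind="stable")
    mz_bs = mz_b[order]
    pair_idx, deltas = [], []
    for i, m in enumerate(mz_a):
        lo = int(np.searchsorted(mz_bs, m - mz_tol, side="left"))
        hi = int(np.searchsorted(mz_bs, m + mz_tol, side="right"))
        for j in order[lo:hi]:
            d = m - mz_b[j]
            if abs(d) <= mz_tol:
                pair_idx.append((i, int(j)))
                deltas.append((float(d), np.nan))
    return _build_report(ids_a, ids_b, pair_idx, deltas)


def match_by_mass_rt(
    A: list, B: list, mz_tol: float = 0.005, rt_tol_min: float = 0.3
) -> CorrespondenceReport:
    """Mass + retention-time matching; the RT tolerance is given in
    minutes (as usually reported) and converted to seconds internally."""
    if mz_tol < 0 or rt_tol_min < 0:
        raise ValueError("tolerance must be non-negative")
    if not A or not B:
        raise ValueError("both lists must be nonempty")
    rt_tol = rt_tol_min * 60.0
    ids_a, mz_a, rt_a = _as_arrays(A, need_rt=True)
    ids_b, mz_b, rt_b = _as_arrays(B, need_rt=True)
    order = np.argsort(mz_b, kind="stable")
    mz_bs = mz_b[order]
    pair_idx, deltas = [], []
    for i, (m, t) in enumerate(zip(mz_a, rt_a)):
        lo = int(np.searchsorted(mz_bs, m - mz_tol, side="left"))
        hi = int(np.searchsorted(mz_bs, m + mz_tol, side="right"))
        for j in order[lo:hi]:
            dm = m - mz_b[j]
            dt = t - rt_b[j]
            if abs(dm) <= mz_tol and abs(dt) <= rt_tol:
                pair_idx.append((i, int(j)))
                deltas.append((float(dm), float(dt)))
    return _build_report(ids_a, ids_b, pair_idx, deltas)


def match_brute(
    A: list, B: list, mz_tol: float = 0.005, rt_tol_min: float | None = None
) -> CorrespondenceReport:
    """O(n*m) reference matcher (oracle for the sorted implementations)."""
    need_rt = rt_tol_min is not None
    ids_a, mz_a, rt_a = _as_arrays(A, need_rt=need_rt)
    ids_b, mz_b, rt_b = _as_arrays(B, need_rt=need_rt)
    rt_tol = (rt_tol_min or 0) * 60.0
    pair_idx, deltas = [], []
    for i in range(len(A)):
        for j in range(len(B)):
            dm = mz_a[i] - mz_b[j]
            if abs(dm) > mz_tol:
                continue
            if need_rt:
                dt = rt_a[i] - rt_b[j]
                if abs(dt) > rt_tol:
                    continue
                pair_idx.append((i, j))
                deltas.append((float(dm), float(dt)))
            else:
                pair_idx.append((i, j))
                deltas.append((float(dm), np.nan))
    return _build_report(ids_a, ids_b, pair_idx, deltas)


def unfold_component(
    component_id: str,
    col_mz: np.ndarray,
    spectrum: np.ndarray,
    apex_rt: float | None = None,
    base_peak_frac: float = 0.05,
    source: str = "mcr-component-member",
) -> list:
    """Unfold a resolved component spectrum into its member masses.

    Returns the union-axis masses whose spectral intensity exceeds
    ``base_peak_frac`` of the base-peak intensity (strictly greater: a
    satellite at exactly the threshold is excluded), each stamped with
    the component's apex RT.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.size == 0 or spectrum.max() <= 0:
        raise ValueError("all-zero spectrum")
    thr = base_peak_frac * spectrum.max()
    keep = np.nonzero(spectrum > thr)[0]
    return [
        MassEntry(f"{component_id}_m{k}", float(col_mz[k]), apex_rt, float(spectrum[k]), source)
        for k in keep
    ]


def _one_to_one(report: CorrespondenceReport) -> pd.DataFrame:
    """Reduce retained multi-matches to nearest-mass one-to-one pairs."""
    pairs = report.pairs.copy()
    if not len(pairs):
        return pairs
    pairs = pairs.sort_values(["delta_mz"], key=lambda c: c.abs(), kind="stable")
    used_a, used_b, keep = set(), set(), []
    for row in pairs.itertuples():
        if row.id_a in used_a or row.id_b in used_b:
            continue
        used_a.add(row.id_a)
        used_b.add(row.id_b)
        keep.append(row.Index)
    return pairs.loc[keep]


def stage_report(
    stages: dict,
    mz_tol: float = 0.005,
    rt_tol_min: float = 0.3,
) -> pd.DataFrame:
    """Per-analysis-stage correspondence summary.

    ``stages`` maps a stage name to ``(A, B, mode)`` with mode ``mass``
    or ``mass_rt``. Coverages count every match (multiple matches
    retained); the Venn triple (A-only, shared, B-only) uses the
    nearest-mass one-to-one reduction, so shared <= min(|A|, |B|).
    """
    rows = []
    for name, (A, B, mode) in stages.items():
        if not A or not B:
            raise ValueError(f"stage {name!r} has an empty list")
        if mode == "mass":
            rep = match_by_mass(A, B, mz_tol)
        elif mode == "mass_rt":
            rep = match_by_mass_rt(A, B, mz_tol, rt_tol_min)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        one = _one_to_one(rep)
        shared = len(one)
        rows.append(
            {
                "stage": name,
                "mode": mode,
                "n_a": len(A),
                "n_b": len(B),
                "coverage_a_by_b": rep.coverage_a,
                "coverage_b_by_a": rep.coverage_b,
                "n_pairs": len(rep.pairs),
                "venn_a_only": len(A) - shared,
                "venn_shared": shared,
                "venn_b_only": len(B) - shared,
            }
        )
    return pd.DataFrame(rows)
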