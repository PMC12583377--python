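"""Feature-table reduction and shared area pre-processing.

The same reductions apply to both workflows: features inside the
injection-peak window are removed, variables not exceeding a fold-change
multiple of the blank signal are removed, and the resulting area matrix
is total-area normalized per sample and log-transformed before any
multivariate analysis. Every step appends a row to a reduction audit so
the row/column trail of an analysis is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ms_io import FeatureTable
from .synthetic import StudyDesign

__all__ = [
    "AreaMatrix",
    "ReductionAudit",
    "drop_injection_features",
    "blank_subtract",
    "preprocess_areas",
    "feature_table_to_matrix",
]


@dataclass
class ReductionAudit:
    """Before/after dimensions of each reduction step."""

    steps: list = field(default_factory=list)

    def record(self, step: str, rows_before: int, rows_after: int, vars_before: int, vars_after: int):
        self.steps.append(
            {
                "step": step,
                "rows_before": rows_before,
                "rows_after": rows_after,
                "vars_before": vars_before,
                "vars_after": vars_after,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "rows_before", "rows_after", "vars_before", "vars_after"])


@dataclass
class AreaMatrix:
    """Samples x variables area matrix with variable metadata.

    ``provenance`` tags the source workflow: ``fp`` (feature profiling)
    or ``mcr`` (resolved components).
    """

    values: pd.DataFrame  # samples x variables, >= 0 (or transformed)
    var_meta: pd.DataFrame  # per variable: mz/rt or component metadata
    provenance: str = "fp"
    transformed: bool = False

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]


def feature_table_to_matrix(table: FeatureTable, provenance: str = "fp") -> AreaMatrix:
    values = table.data[table.sample_ids].T.fillna(0.0).astype(float)
    meta = table.data[["mz", "rt"]].copy()
    return AreaMatrix(values, meta, provenance)


def drop_injection_features(
    table: FeatureTable, cutoff_s: float = 330.0, audit: ReductionAudit | None = None
) -> FeatureTable:
    """Remove features eluting in the injection-peak window (RT < cutoff)."""
    keep = table.data["rt"] >= cutoff_s
    out = FeatureTable(table.data.loc[keep].copy(), list(table.sample_ids))
    if audit is not None:
        audit.record("drop_injection", len(table.data), len(out.data), len(table.data), len(out.data))
    return out


def blank_subtract(
    table: FeatureTable,
    design: StudyDesign,
    fold_change: float = 3.0,
    audit: ReductionAudit | None = None,
) -> FeatureTable:
    """Fold-change blank subtraction; drops blank columns afterwards.

    A feature is retained iff its maximum area over non-blank samples is
    at least ``fold_change`` times its maximum blank area. Features absent
    from blanks (max blank area 0) are always retained.
    """
    blanks = [b for b in design.blank_ids if b in table.sample_ids]
    if not blanks:
        raise ValueError("design identifies no blank samples present in the table")
    non_blank = [s for s in table.sample_ids if s not in blanks]
    areas = table.data[table.sample_ids].fillna(0.0)
    max_sample = areas[non_blank].max(axis=1)
    max_blank = areas[blanks].max(axis=1)
    keep = max_sample >= fold_change * max_blank
    df = table.data.loc[keep, ["mz", "rt", *non_blank]].copy()
    out = FeatureTable(df, non_blank)
    if audit is not None:
        audit.record("blank_subtract", len(table.data), len(out.data), len(table.data), len(out.data))
    return out


def preprocess_areas(
    matrix: AreaMatrix,
    log_first: bool = False,
    epsilon: float | None = None,
) -> AreaMatrix:
    """Total-area normalization per sample followed by log10.

    Default order normalizes first (each sample's areas become
    proportions summing to 1, making the log values scale-free per
    sample), then applies ``log10(x + eps)``. With ``log_first`` the log
    is taken on raw areas and the per-sample total-area factor is removed
    in log space (row-mean centering, the log-space equivalent of
    dividing by a per-sample scale). ``eps`` defaults to 1e-8 times the
    maximum entry of the matrix entering the log, keeping zeros far below
    real signal in log space.
    """
    X = matrix.values.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("areas must be non-negative")
    rowsum = X.sum(axis=1)
    if (rowsum == 0).any():
        bad = matrix.values.index[rowsum == 0].tolist()
        raise ValueError(f"samples with all-zero areas: {bad}")

    def _norm(M):
        return M / M.sum(axis=1, keepdims=True)

    def _log(M):
        eps = epsilon if epsilon is not None else 1e-8 * M.max()
        return np.log10(M + eps)

    if log_first:
        L = _log(X)
        Xt = L - L.mean(axis=1, keepdims=True)
    else:
        Xt = _log(_norm(X))
    out = pd.DataFrame(Xt, index=matrix.values.index, columns=matrix.values.columns)
    return AreaMatrix(out, matrix.var_meta.copy(), matrix.provenance, transformed=True)
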