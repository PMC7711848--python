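"""Parameter-sensitivity analysis and identifiable-subset selection.

Each calibration cycle builds a scaled local sensitivity matrix of the
measured outputs with respect to the estimable parameters, then picks a
parameter subset by greedy orthogonalized forward selection, stopping when
the collinearity index of the selected columns would exceed a threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import MeasurementSet, _simulated_outputs, variable_scales
from .parameters import ESTIMABLE_PARAMETERS, ModelParameters

#: Residual columns whose norm falls below this fraction of the largest
#: initial column norm carry no usable information and end the ranking.
RESIDUAL_FLOOR = 1e-8


@dataclass
class SensitivityMatrix:
    """Scaled local sensitivities: one row per measurement, one column per
    estimable parameter.  Entry (m, j) = (dy_m/dtheta_j) * theta_j / scale of
    the measured variable, so rows from %-scale DOT and g/L concentrations
    are commensurable."""

    matrix: np.ndarray
    row_index: pd.DataFrame  # columns: reactor_id, variable, t_sample_h
    col_index: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


@dataclass
class SubsetSelection:
    """Result of greedy forward selection.

    ``selected`` is always a prefix of ``ranked_parameters``; the
    ``collinearity_index_path`` holds the index of the selected submatrix
    after each accepted step."""

    ranked_parameters: list[str]
    selected: list[str]
    collinearity_index_path: list[float]
    threshold: float
    residual_norms: list[float] = field(default_factory=list)


def sensitivity_matrix(
    params: ModelParameters,
    measurements: MeasurementSet,
    perturbation: float = 1e-4,
    parameter_names: tuple[str, ...] = ESTIMABLE_PARAMETERS,
    rtol: float | None = None,
    atol: float | None = None,
) -> SensitivityMatrix:
    """Central finite-difference sensitivities of simulated outputs at the
    measurement points, relative in the parameter and scaled per variable.

    A parameter currently at zero has an identically zero column (a relative
    perturbation cannot move it), matching its non-identifiability.
    """
    ordered = MeasurementSet(
        measurements.frame.sort_values(["reactor_id", "t_sample_h"], kind="stable"),
        measurements.inputs,
    )
    df = ordered.frame
    scales = variable_scales(ordered)

    def outputs(p: ModelParameters) -> np.ndarray:
        try:
            return _simulated_outputs(p, ordered, rtol, atol)
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            raise RuntimeError(f"simulation failed during perturbation: {exc}") from exc

    from .parameters import YIELD_CAP, _CAPPED_YIELDS

    cols = []
    for name in parameter_names:
        theta = getattr(params, name)
        if theta == 0.0:
            cols.append(np.zeros(len(df)))
            continue
        # central difference, end points pulled inside bounds and caps so a
        # parameter sitting on a bound still gets a (one-sided) column
        hi = theta * (1 + perturbation)
        lo = theta * (1 - perturbation)
        if name in params.bounds:
            b_lo, b_hi = params.bounds[name]
            hi, lo = min(hi, b_hi), max(lo, b_lo)
        if name in _CAPPED_YIELDS:
            hi = min(hi, YIELD_CAP)
        if hi <= lo:
            cols.append(np.zeros(len(df)))
            continue
        try:
            y_hi = outputs(params.with_values([name], [hi]))
            y_lo = outputs(params.with_values([name], [lo]))
        except RuntimeError as exc:
            raise RuntimeError(f"sensitivity of parameter {name!r}: {exc}") from exc
        # (dy/dtheta)*theta / scale, with the actual step in the denominator
        cols.append((y_hi - y_lo) * (theta / (hi - lo)))

    scale_vec = df["variable"].map(scales).to_numpy(dtype=float)
    matrix = np.column_stack(cols) / scale_vec[:, None]
    row_index = df[["reactor_id", "variable", "t_sample_h"]].copy()
    return SensitivityMatrix(matrix=matrix, row_index=row_index, col_index=list(parameter_names))


def collinearity_index(submatrix: np.ndarray) -> float:
    """1 / smallest singular value of the column-normalized submatrix; large
    values mean the columns are nearly linearly dependent."""
    norms = np.linalg.norm(submatrix, axis=0)
    if np.any(norms == 0):
        return np.inf
    s = np.linalg.svd(submatrix / norms, compute_uv=False)
    smin = s[-1]
    return float(1.0 / smin) if smin > 0 else np.inf


def select_subset(S: SensitivityMatrix, threshold: float = 25.0) -> SubsetSelection:
    """Greedy orthogonalized forward selection of identifiable parameters.

    At each step the unselected column with the largest residual norm (after
    projection onto the span of the selected columns) is taken; ties are
    broken by parameter name, so the result is invariant to column order.
    Selection stops when the collinearity index of the would-be selected
    submatrix exceeds ``threshold``, or when the best residual norm falls
    below ``RESIDUAL_FLOOR`` times the largest initial column norm.  The
    full ranking (ignoring the threshold) is reported alongside the
    selected prefix.
    """
    M = np.asarray(S.matrix, dtype=float)
    names = list(S.col_index)
    n_rows, n_cols = M.shape
    if n_cols == 0 or n_rows == 0 or not np.any(M):
        warnings.warn("all-zero sensitivity matrix: no parameter is identifiable")
        return SubsetSelection([], [], [], threshold)

    init_norms = np.linalg.norm(M, axis=0)
    floor = RESIDUAL_FLOOR * init_norms.max()

    residual = M.copy()
    Q: list[np.ndarray] = []
    ranked: list[int] = []
    ranked_norms: list[float] = []
    remaining = list(range(n_cols))

    while remaining:
        norms = {j: float(np.linalg.norm(residual[:, j])) for j in remaining}
        best_norm = max(norms.values())
        if best_norm < floor:
            break
        # stable, order-invariant tie-break: smallest parameter name
        candidates = sorted(j for j in remaining if norms[j] == best_norm)
        j_star = min(candidates, key=lambda j: names[j])
        ranked.append(j_star)
        ranked_norms.append(best_norm)
        remaining.remove(j_star)
        q = residual[:, j_star] / best_norm
        Q.append(q)
        # re-orthogonalize all remaining residual columns against q
        for j in remaining:
            residual[:, j] -= q @ residual[:, j] * q

    gamma_path: list[float] = []
    selected: list[int] = []
    for k in range(1, len(ranked) + 1):
        gamma = collinearity_index(M[:, ranked[:k]])
        if gamma > threshold:
            break
        gamma_path.append(gamma)
        selected = ranked[:k]

    return SubsetSelection(
        ranked_parameters=[names[j] for j in ranked],
        selected=[names[j] for j in selected],
        collinearity_index_path=gamma_path,
        threshold=threshold,
        residual_norms=ranked_norms,
    )


def selection_report(selection: SubsetSelection) -> str:
    """Plain-text report of one subset selection."""
    lines = [f"collinearity threshold: {selection.threshold}"]
    for i, name in enumerate(selection.ranked_parameters):
        mark = "selected" if name in selection.selected else "excluded"
        gamma = (f"{selection.collinearity_index_path[i]:.3f}"
                 if i < len(selection.collinearity_index_path) else "-")
        norm = (f"{selection.residual_norms[i]:.3e}"
                if i < len(selection.residual_norms) else "-")
        lines.append(f"{i + 1:2d}. {name:10s} residual_norm={norm} "
                     f"collinearity={gamma} [{mark}]")
    return "\n".join(lines)
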