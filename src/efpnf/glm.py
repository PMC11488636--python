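"""Offline rt-fMRI-NF analysis: design matrix, GLM fit, Watch-Regulate contrast.

The unit of analysis is a single-ROI (right amygdala) average BOLD time
course.  The design contains the three experimental conditions (Watch,
Regulate, Washout) as HRF-convolved boxcars, optional motion nuisance
terms (six realignment parameters, their temporal derivatives and
quadratic terms), one unit spike column per motion outlier, and an
intercept.  The subject-level statistic is the Watch - Regulate
contrast; a positive value means lower activity during Regulate
(successful down-regulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hrf import canonical_hrf
from .synthetic import BOLDSeries
from .nf import Schedule

CONDITION_NAMES = ("Watch", "Regulate", "Washout")


@dataclass
class DesignMatrix:
    """Named regressors sampled at the volume grid."""

    values: np.ndarray
    columns: list
    tr: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column names inconsistent with matrix width")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.columns.index(name)]


def build_design_matrix(
    schedule: Schedule,
    n_volumes: int,
    tr: float = 3.0,
    motion: np.ndarray | None = None,
    outliers=(),
) -> DesignMatrix:
    """Condition + nuisance design for one NF run.

    Condition columns are {0,1} boxcars over the block intervals
    (half-open ``[onset, onset + duration)``) convolved with the
    canonical HRF sampled at ``tr``.  Motion columns are mean-centred;
    each contributes its derivative (first difference) and the square of
    the centred column.  Each outlier volume index adds a unit spike.
    """
    if tr <= 0:
        raise ValueError("tr must be > 0")
    if schedule.duration > n_volumes * tr + 1e-9:
        raise ValueError(
            f"schedule ({schedule.duration:.0f} s) exceeds scan "
            f"({n_volumes * tr:.0f} s)")
    t = np.arange(n_volumes) * tr
    kernel = canonical_hrf(tr)
    cols, names = [], []
    for cond in CONDITION_NAMES:
        boxcar = np.zeros(n_volumes)
        for _, onset, duration in schedule.blocks_of(cond):
            boxcar[(t >= onset) & (t < onset + duration)] = 1.0
        cols.append(np.convolve(boxcar, kernel)[:n_volumes])
        names.append(cond)
    if motion is not None:
        motion = np.atleast_2d(np.asarray(motion, dtype=float))
        if motion.shape[0] != n_volumes:
            raise ValueError("motion rows must equal n_volumes")
        for j in range(motion.shape[1]):
            centred = motion[:, j] - motion[:, j].mean()
            deriv = np.concatenate([[0.0], np.diff(centred)])
            cols += [centred, deriv, centred**2]
            names += [f"motion{j + 1}", f"motion{j + 1}_deriv", f"motion{j + 1}_sq"]
    for k, vol in enumerate(outliers):
        vol = int(vol)
        if not 0 <= vol < n_volumes:
            raise ValueError(f"outlier volume {vol} out of range [0, {n_volumes})")
        spike = np.zeros(n_volumes)
        spike[vol] = 1.0
        cols.append(spike)
        names.append(f"outlier{k + 1}")
    cols.append(np.ones(n_volumes))
    names.append("intercept")
    return DesignMatrix(values=np.column_stack(cols), columns=names, tr=tr)


@dataclass
class ContrastResult:
    """Watch - Regulate effect with the full beta vector."""

    value: float
    betas: dict
    residual_var: float
    design_columns: list = field(default_factory=list)


def fit_glm(bold: BOLDSeries, design: DesignMatrix) -> ContrastResult:
    """Ordinary least squares fit; contrast = beta_Watch - beta_Regulate.

    Raises on a rank-deficient design, naming the collinear columns.
    """
    y = bold.values
    X = design.values
    if y.size != X.shape[0]:
        raise ValueError(
            f"BOLD length {y.size} does not match design rows {X.shape[0]}")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        collinear = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                collinear.append(design.columns[j])
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(y.size - X.shape[1], 1)
    betas = dict(zip(design.columns, beta))
    return ContrastResult(
        value=float(betas["Watch"] - betas["Regulate"]),
        betas=betas,
        residual_var=float(resid @ resid / dof),
        design_columns=list(design.columns))


__all__ = ["DesignMatrix", "build_design_matrix", "ContrastResult", "fit_glm",
           "CONDITION_NAMES", "canonical_hrf"]
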