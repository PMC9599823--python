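"""Functional-connectivity graph over the eleven ROIs.

Nodes are ROIs; edge weights are group-weighted Pearson correlations between
ROI signals:

    a_ij = omega * P(r_i, r_j),  omega = 3 if i, j share a hierarchy group,
                                         1 across groups, 0 on the diagonal.

The graph classifier consumes the symmetric normalization used by spectral
graph convolution, A_hat = D~^{-1/2} (A + I) D~^{-1/2} with D~ the degree
matrix of A + I.

The correlations are computed from ROI-mean time courses concatenated across
the *training* scans only (three points per scan are statistically
meaningless on their own, and touching held-out subjects would leak); the
adjacency is then frozen for training and inference. By default |P| is used
so that all degrees stay positive and the normalization is always real.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import stats

from .rois import ROI_GROUPS, ROI_NAMES, ROITemplate, roi_mean_timecourse

DEFAULT_OMEGA = 3.0
#: Same-group weight values covered by the built-in sweep.
OMEGA_SWEEP = (1.5, 2.0, 2.5, 3.0, 3.5, 4.0)


class DegenerateSignalError(ValueError):
    """A correlation input is constant; Pearson r is undefined."""


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation coefficient in [-1, 1]."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("pearson needs two equal-length 1D vectors of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateSignalError("constant input: Pearson correlation undefined")
    r = stats.pearsonr(x, y).statistic
    return float(np.clip(r, -1.0, 1.0))


@dataclass
class AdjacencyMatrix:
    """Weighted 11 x 11 functional-connectivity matrix.

    Symmetric, zero diagonal; same-group entries bounded by ``omega``,
    cross-group entries by 1.
    """

    A: np.ndarray
    omega: float = DEFAULT_OMEGA
    signed: bool = False

    def __post_init__(self):
        A = np.asarray(self.A, dtype=np.float64)
        if A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.abs(np.diag(A)).max() > 0:
            raise ValueError("adjacency diagonal must be zero")
        self.A = A

    def to_dataframe(self):
        import pandas as pd

        names = list(ROI_NAMES[: self.A.shape[0]])
        return pd.DataFrame(self.A, index=names, columns=names)

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


def _group_weight(name_i: str, name_j: str, omega: float) -> float:
    return omega if ROI_GROUPS[name_i] == ROI_GROUPS[name_j] else 1.0


def build_adjacency(
    roi_signals: np.ndarray,
    omega: float = DEFAULT_OMEGA,
    signed: bool = False,
    mode: str = "weighted_pearson",
    rng: np.random.Generator | None = None,
    on_degenerate: str = "raise",
) -> AdjacencyMatrix:
    """Build the ROI adjacency from per-ROI signal vectors.

    Parameters
    ----------
    roi_signals
        Array (11, T): one signal per ROI in canonical order.
    omega
        Same-group weight (default 3; the swept values are in
        :data:`OMEGA_SWEEP`). Cross-group weight is 1, diagonal 0.
    signed
        Keep the sign of the correlation. Default False: |P| is used so the
        normalized adjacency is always real.
    mode
        "weighted_pearson" (default), "plain_pearson" (no group weighting,
        equivalent to omega = 1), or "random" (uniform random symmetric
        matrix, ablation baseline; requires ``rng``).
    on_degenerate
        "raise" (default) or "zero": substitute 0 with a warning when an ROI
        signal is constant.
    """
    roi_signals = np.asarray(roi_signals, dtype=np.float64)
    n = roi_signals.shape[0]
    if n != len(ROI_NAMES):
        raise ValueError(f"need {len(ROI_NAMES)} ROI signals, got {n}")
    if mode == "random":
        if rng is None:
            raise ValueError("mode='random' requires an rng")
        R = rng.uniform(0.0, 1.0, size=(n, n))
        A = np.triu(R, 1) + np.triu(R, 1).T
        return AdjacencyMatrix(A=A, omega=omega, signed=signed)
    if mode not in ("weighted_pearson", "plain_pearson"):
        raise ValueError(f"unknown adjacency mode {mode!r}")

    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                r = pearson(roi_signals[i], roi_signals[j])
            except DegenerateSignalError:
                if on_degenerate == "zero":
                    warnings.warn(
                        f"constant signal for pair ({ROI_NAMES[i]}, {ROI_NAMES[j]}); "
                        "substituting correlation 0",
                        stacklevel=2,
                    )
                    r = 0.0
                else:
                    raise
            if not signed:
                r = abs(r)
            w = 1.0 if mode == "plain_pearson" else _group_weight(
                ROI_NAMES[i], ROI_NAMES[j], omega
            )
            A[i, j] = A[j, i] = w * r
    return AdjacencyMatrix(A=A, omega=omega, signed=signed)


def normalize_adjacency(adj: AdjacencyMatrix | np.ndarray) -> np.ndarray:
    """Symmetric normalization A_hat = D~^{-1/2} (A + I) D~^{-1/2}.

    With nonnegative A the result is symmetric with eigenvalues in [-1, 1].
    Raises if any augmented degree is non-positive (no real square root).
    """
    A = adj.A if isinstance(adj, AdjacencyMatrix) else np.asarray(adj, dtype=np.float64)
    A_tilde = A + np.eye(A.shape[0])
    degrees = A_tilde.sum(axis=1)
    if (degrees <= 0).any():
        bad = int(np.argmin(degrees))
        raise ValueError(
            f"non-normalizable adjacency: augmented degree {degrees[bad]:.4g} <= 0 "
            f"at node {bad}"
        )
    d_inv_sqrt = 1.0 / np.sqrt(degrees)
    return d_inv_sqrt[:, None] * A_tilde * d_inv_sqrt[None, :]


def training_roi_signals(
    scans: list, template: ROITemplate, train_subjects: set | None = None
) -> np.ndarray:
    """ROI-mean time courses concatenated across (training) scans.

    Returns (11, 3 * n_scans): for each ROI, the 3-frame mean time course of
    every selected scan, concatenated in scan order. Feeding this to
    :func:`build_adjacency` realizes the frozen training-set connectivity.
    """
    selected = [s for s in scans
                if train_subjects is None or s.subject in train_subjects]
    if not selected:
        raise ValueError("no scans selected for adjacency estimation")
    cols = []
    for scan in selected:
        mat = np.stack([roi_mean_timecourse(scan.data, name, template)
                        for name in ROI_NAMES])
        cols.append(mat)
    return np.concatenate(cols, axis=1)
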