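"""Technical and biological covariates: control-probe PCs and cell fractions.

Batch effects are summarized by principal components of the array's internal
control probes (first five PCs used as regression covariates downstream).
Blood cell composition is estimated by reference-based deconvolution: each
sample's methylation profile over discriminating probes is projected onto
reference cell-type profiles by non-negative least squares (constrained
projection without a sum-to-one constraint; fractions may optionally be
renormalized to sum to one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

CELL_TYPES = ("granulocytes", "monocytes", "bcells", "cd4t", "cd8t", "nk")


@dataclass
class ControlPcScores:
    """Sample x k principal-component scores of the control-probe matrix."""

    scores: pd.DataFrame           # samples x k, columns PC1..PCk
    explained_variance_ratio: np.ndarray

    @property
    def k(self) -> int:
        return self.scores.shape[1]


@dataclass
class CellReference:
    """Reference methylation profiles: probes x cell types, values in [0,1]."""

    profiles: pd.DataFrame

    def __post_init__(self):
        if self.profiles.shape[1] < 2:
            raise ValueError("need at least 2 cell types")
        vals = self.profiles.to_numpy()
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("reference profiles must lie in [0, 1]")

    @property
    def cell_types(self) -> pd.Index:
        return self.profiles.columns


def control_probe_pcs(controls: pd.DataFrame, k: int = 5, scale: bool = True) -> ControlPcScores:
    """Principal components of the control-probe signal matrix.

    Parameters
    ----------
    controls
        control-probe x sample signal matrix (numeric columns only).
    k
        Number of components (default 5, the count used as EWAS covariates).
    scale
        Standardize each control probe to unit variance before the SVD
        (constant probes are left centered only).

    Scores are deterministic: the sign of each component is fixed so that its
    largest-magnitude probe loading is positive.
    """
    X = controls.to_numpy(dtype=float).T  # samples x probes
    n, p = X.shape
    if k > min(n - 1, p):
        raise ValueError(f"k={k} exceeds the rank bound min(n-1, p)={min(n - 1, p)}")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for i in range(k):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    scores = U[:, :k] * s[:k]
    evr = (s**2) / np.sum(s**2)
    return ControlPcScores(
        scores=pd.DataFrame(scores, index=controls.columns,
                            columns=[f"PC{i + 1}" for i in range(k)]),
        explained_variance_ratio=evr[:k],
    )


def houseman_deconvolve(
    beta, ref: CellReference, renormalize: bool = False
) -> pd.DataFrame:
    """Estimate blood cell-type fractions by constrained projection.

    Solves, per sample, ``min || beta_s - R p ||^2 s.t. p >= 0`` over the
    probes shared between the beta matrix and the reference (no sum-to-one
    constraint; set ``renormalize=True`` to divide each row by its sum).

    Parameters
    ----------
    beta
        BetaMatrix or probe x sample DataFrame.
    ref
        CellReference with discriminating probe profiles.

    Returns
    -------
    DataFrame of samples x cell types, plus a ``sum`` column with the raw
    (pre-normalization) row total.
    """
    bmat = beta.beta if hasattr(beta, "beta") else beta
    shared = bmat.index.intersection(ref.profiles.index)
    if len(shared) < 2:
        raise ValueError("fewer than 2 probes shared between beta matrix and reference")
    R = ref.profiles.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(R) < R.shape[1]:
        raise ValueError("reference profile matrix is singular over shared probes")
    B = bmat.loc[shared].to_numpy(dtype=float)
    props = np.empty((B.shape[1], R.shape[1]))
    for j in range(B.shape[1]):
        props[j], _ = nnls(R, B[:, j])
    out = pd.DataFrame(props, index=bmat.columns, columns=ref.cell_types)
    total = out.sum(axis=1)
    if renormalize:
        nz = total > 0
        out.loc[nz] = out.loc[nz].div(total[nz], axis=0)
    out["sum"] = total
    return out
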