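"""Consistence-based resource allocation on the updated tripartite graph.

The scorer propagates a unit resource placed on each known (or recommended)
miRNA-disease edge in two complementary ways and blends them:

Step 1 (miRNA <-> disease).  A two-step allocation M -> D -> M yields a
miRNA-miRNA transfer matrix

    w_kt = 1/deg(m_k) * sum_j A(m_k, d_j) * A(m_t, d_j) / deg(d_j)

with degrees taken in the updated MD layer.  Each connected row of W sums to
1.  The consistence correction rewards mutually consistent flow:

    w'_kt = w_kt + w_tk / sum_s w_sk      (term dropped if the column sum is 0)

and the disease-side score is Rscore_ondisease_1 = W' @ A_u_MD.

Step 2 (disease <-> lncRNA).  The resource on diseases is spread to their
lncRNA partners and gathered back, D -> L -> D, each hop normalised by the
sending node's degree in the (never-updated) DL layer:

    Rscore_ondisease_2 = A_u_MD @ Dd^-1 @ A0_DL @ Dl^-1 @ A0_DL^T

Zero degrees follow the 0/0 := 0 convention throughout, which keeps scores
finite and lets diseases without lncRNA (or miRNA) links be scored.

Final score: Rscore_final = gamma * Rscore1 + (1 - gamma) * Rscore2, with
gamma in [0, 1] (default 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .graph import STAGE_UPDATED, TripartiteGraph

SCORE_KINDS = ("rscore1", "rscore2", "final")


@dataclass
class WeightMatrix:
    """Resource-transfer matrix W and its consistence correction W'."""

    W: np.ndarray
    W_prime: np.ndarray | None = None


@dataclass
class ScoreMatrix:
    """Real n_m x n_d resource scores of one kind."""

    values: np.ndarray
    kind: str
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in SCORE_KINDS:
            raise ValueError(f"kind must be one of {SCORE_KINDS}")
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("score matrix contains non-finite entries")


def _safe_inv(v: np.ndarray) -> np.ndarray:
    """Elementwise pseudo-inverse: 1/v where v > 0, else 0."""
    v = np.asarray(v, dtype=float)
    return np.divide(1.0, v, out=np.zeros_like(v), where=v > 0)


def weight_matrix(g: TripartiteGraph) -> np.ndarray:
    """miRNA-miRNA transfer matrix W from the updated MD layer.

    Rows of miRNAs with at least one disease link sum to 1; rows of isolated
    miRNAs are all zero.  The diagonal (self-transfer) is included.
    """
    if g.stage != STAGE_UPDATED:
        raise ValueError("resource allocation runs on the updated graph Gu")
    a = g.A_MD.astype(float)
    inv_deg_m = _safe_inv(a.sum(axis=1))
    inv_deg_d = _safe_inv(a.sum(axis=0))
    return (a * inv_deg_m[:, None]) @ (a * inv_deg_d[None, :]).T


def consistency_correction(w: np.ndarray) -> np.ndarray:
    """W'_kt = W_kt + W_tk / sum_s W_sk; the ratio is dropped for all-zero columns."""
    w = np.asarray(w, dtype=float)
    inv_colsum = _safe_inv(w.sum(axis=0))
    return w + w.T * inv_colsum[:, None]


def rscore1(w_prime: np.ndarray, g: TripartiteGraph) -> ScoreMatrix:
    """Disease-side score from the corrected miRNA-miRNA transfer: W' @ A_u_MD."""
    return ScoreMatrix(values=np.asarray(w_prime) @ g.A_MD.astype(float), kind="rscore1")


def rscore2(g: TripartiteGraph) -> ScoreMatrix:
    """Two-step D -> L -> D propagation through the disease-lncRNA layer."""
    if g.stage != STAGE_UPDATED:
        raise ValueError("resource allocation runs on the updated graph Gu")
    a_md = g.A_MD.astype(float)
    a_dl = g.A_DL.astype(float)
    inv_deg_d = _safe_inv(a_dl.sum(axis=1))  # lncRNAs per disease
    inv_deg_l = _safe_inv(a_dl.sum(axis=0))  # diseases per lncRNA
    values = (a_md * inv_deg_d[None, :]) @ (a_dl * inv_deg_l[None, :]) @ a_dl.T
    return ScoreMatrix(values=values, kind="rscore2")


def final_score(r1: ScoreMatrix, r2: ScoreMatrix, gamma: float = 0.9) -> ScoreMatrix:
    """Convex blend of the two allocation scores, gamma weighting step 1."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")
    if r1.values.shape != r2.values.shape:
        raise ValueError("score matrices have mismatched shapes")
    return ScoreMatrix(
        values=gamma * r1.values + (1.0 - gamma) * r2.values, kind="final", gamma=gamma
    )


def allocate(g: TripartiteGraph, gamma: float = 0.9) -> ScoreMatrix:
    """Full pipeline W -> W' -> Rscore1/Rscore2 -> final blend."""
    w = weight_matrix(g)
    wp = consistency_correction(w)
    return final_score(rscore1(wp, g), rscore2(g), gamma=gamma)


class ResourceAllocationScorer(BaseEstimator):
    """Scores every miRNA-disease cell of an updated tripartite graph.

    Parameters
    ----------
    gamma : float, default=0.9
        Blend weight of the miRNA-side allocation (step 1) against the
        lncRNA-side allocation (step 2).

    Attributes
    ----------
    W_, W_prime_ : ndarray of shape (n_m, n_m)
        Raw and consistence-corrected transfer matrices.
    rscore1_, rscore2_ : ScoreMatrix
        The two intermediate n_m x n_d score matrices.
    scores_ : ndarray of shape (n_m, n_d)
        Final blended resource scores.
    """

    def __init__(self, gamma: float = 0.9):
        self.gamma = gamma

    def fit(self, X: TripartiteGraph, y=None) -> "ResourceAllocationScorer":
        self.W_ = weight_matrix(X)
        self.W_prime_ = consistency_correction(self.W_)
        self.rscore1_ = rscore1(self.W_prime_, X)
        self.rscore2_ = rscore2(X)
        self.final_ = final_score(self.rscore1_, self.rscore2_, gamma=self.gamma)
        self.scores_ = self.final_.values
        return self

    def predict(self, X=None) -> np.ndarray:
        """Return the fitted score matrix (the graph is scored in full at fit)."""
        return self.scores_
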