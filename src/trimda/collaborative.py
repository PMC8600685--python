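"""Item-based collaborative filtering over the combined lncRNA+disease
neighbourhoods of miRNAs.

lncRNAs and diseases play the role of users, miRNAs the role of items.
miRNA-miRNA similarity is the cosine of their binary rows in the spliced
matrix A0_MLD = [A0_ML, A0_MD]:

    R_nor(m_k, m_r) = |N(m_k) & N(m_r)| / sqrt(|N(m_k)| * |N(m_r)|)

The recommender matrix is A_u_MLD = R_nor @ A0_MLD.  For every column
(lncRNA or disease) that already has at least one known miRNA, each miRNA
whose recommender value strictly exceeds the column's averaged value P and
whose entry is not already known becomes a recommended edge; recommended
edges are added as binary 1s, yielding the densified graph Gu.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .graph import STAGE_INITIAL, STAGE_UPDATED, TripartiteGraph

logger = logging.getLogger(__name__)

P_DENOMINATORS = ("all_rows", "nonzero_rows")


@dataclass
class SimilarityMatrix:
    """Binary co-occurrence R and its cosine normalisation R_nor (both n_m x n_m)."""

    R: np.ndarray
    R_nor: np.ndarray


@dataclass
class RecommenderMatrix:
    """Real-valued recommender scores per (miRNA, lncRNA-or-disease column)."""

    A_u_MLD: np.ndarray
    column_avgs: np.ndarray


@dataclass
class RecommendationSet:
    """New edges to add: (miRNA name, target name, target role, score)."""

    edges: list[tuple[str, str, str, float]]

    def __len__(self) -> int:
        return len(self.edges)


def cooccurrence_similarity(g: TripartiteGraph) -> SimilarityMatrix:
    """Cosine co-occurrence similarity between miRNAs over G0 neighbourhoods.

    Pairs where either miRNA has an empty neighbourhood get similarity 0 (the
    0/0 convention); a miRNA with at least one neighbour has unit diagonal.
    """
    if g.stage != STAGE_INITIAL:
        raise ValueError("similarity is computed on the initial graph G0")
    mld = g.splice_mld().astype(float)
    inter = mld @ mld.T  # |N(m_k) & N(m_r)| for binary rows
    deg = mld.sum(axis=1)
    if deg.sum() == 0:
        logger.warning("all-zero graph: similarity matrix is all zeros")
    denom = np.sqrt(np.outer(deg, deg))
    with np.errstate(divide="ignore", invalid="ignore"):
        r_nor = np.where(denom > 0, inter / np.where(denom > 0, denom, 1.0), 0.0)
    return SimilarityMatrix(R=(inter > 0).astype(np.int8), R_nor=r_nor)


def recommender_matrix(
    sim: SimilarityMatrix,
    g: TripartiteGraph,
    p_denominator: str = "all_rows",
) -> RecommenderMatrix:
    """A_u_MLD = R_nor @ A0_MLD plus the per-column averaged value P.

    ``p_denominator`` selects the P rule: ``all_rows`` divides each column sum
    by n_m; ``nonzero_rows`` divides by the number of nonzero entries in the
    column (sensitivity-analysis variant).
    """
    if p_denominator not in P_DENOMINATORS:
        raise ValueError(f"p_denominator must be one of {P_DENOMINATORS}")
    a_u = sim.R_nor @ g.splice_mld().astype(float)
    colsum = a_u.sum(axis=0)
    if p_denominator == "all_rows":
        avgs = colsum / g.n_m
    else:
        nnz = (a_u > 0).sum(axis=0)
        avgs = np.divide(colsum, nnz, out=np.zeros_like(colsum), where=nnz > 0)
    return RecommenderMatrix(A_u_MLD=a_u, column_avgs=avgs)


def recommend_edges(rec: RecommenderMatrix, g: TripartiteGraph) -> RecommendationSet:
    """Apply the averaged-value-P rule column by column.

    A column is eligible only if it already has at least one known miRNA in
    A0_MLD; within an eligible column every miRNA scoring strictly above P
    whose entry is still 0 is recommended.  Ties at exactly P are not
    recommended.
    """
    a0 = g.splice_mld()
    known_cols = a0.any(axis=0)
    above = (rec.A_u_MLD > rec.column_avgs[None, :]) & (a0 == 0) & known_cols[None, :]
    edges: list[tuple[str, str, str, float]] = []
    rows, cols = np.nonzero(above)
    for k, c in zip(rows, cols):
        if c < g.n_l:
            target, role = g.lncrnas.names[c], "lncRNA"
        else:
            target, role = g.diseases.names[c - g.n_l], "disease"
        edges.append((g.mirnas.names[k], target, role, float(rec.A_u_MLD[k, c])))
    return RecommendationSet(edges=edges)


def update_graph(g: TripartiteGraph, recs: RecommendationSet) -> TripartiteGraph:
    """Add recommended edges (as binary 1s) to A_MD / A_ML, producing Gu.

    The disease-lncRNA layer is never updated.  Existing edges are never
    removed, so Gu >= G0 elementwise.
    """
    if g.stage != STAGE_INITIAL:
        raise ValueError("update_graph expects the initial graph G0")
    gu = g.copy(stage=STAGE_UPDATED)
    n_new = {"lncRNA": 0, "disease": 0}
    for mirna, target, role, _score in recs.edges:
        k = g.mirnas.position(mirna)
        if role == "lncRNA":
            gu.A_ML[k, g.lncrnas.position(target)] = 1
        else:
            gu.A_MD[k, g.diseases.position(target)] = 1
        n_new[role] += 1
    logger.info(
        "updated graph: MD %d known + %d recommended -> %d; ML %d known + %d recommended -> %d",
        int(g.A_MD.sum()), n_new["disease"], int(gu.A_MD.sum()),
        int(g.A_ML.sum()), n_new["lncRNA"], int(gu.A_ML.sum()),
    )
    return gu


def densify(g: TripartiteGraph, p_denominator: str = "all_rows") -> TripartiteGraph:
    """One-shot pipeline: similarity -> recommender -> P rule -> Gu."""
    sim = cooccurrence_similarity(g)
    rec = recommender_matrix(sim, g, p_denominator=p_denominator)
    return update_graph(g, recommend_edges(rec, g))


class CollaborativeFilter(BaseEstimator, TransformerMixin):
    """Graph densifier: recommends new miRNA edges and returns Gu.

    Parameters
    ----------
    p_denominator : {"all_rows", "nonzero_rows"}, default="all_rows"
        Denominator of the per-column averaged value P used as the strict
        recommendation threshold.

    Attributes
    ----------
    similarity_ : SimilarityMatrix
        Binary co-occurrence matrix and its cosine normalisation.
    recommender_ : RecommenderMatrix
        Real-valued recommender scores with per-column P values.
    recommendations_ : RecommendationSet
        Edges added to the graph.
    graph_ : TripartiteGraph
        The updated graph Gu (stage "updated").
    """

    def __init__(self, p_denominator: str = "all_rows"):
        self.p_denominator = p_denominator

    def fit(self, X: TripartiteGraph, y=None) -> "CollaborativeFilter":
        self.similarity_ = cooccurrence_similarity(X)
        self.recommender_ = recommender_matrix(
            self.similarity_, X, p_denominator=self.p_denominator
        )
        self.recommendations_ = recommend_edges(self.recommender_, X)
        self.graph_ = update_graph(X, self.recommendations_)
        return self

    def transform(self, X: TripartiteGraph) -> TripartiteGraph:
        # stateless by construction: the update depends only on X itself
        return densify(X, p_denominator=self.p_denominator)

    def fit_transform(self, X: TripartiteGraph, y=None) -> TripartiteGraph:
        return self.fit(X).graph_
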