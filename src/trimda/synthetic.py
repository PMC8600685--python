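"""Seeded synthetic tripartite graphs with planted cross-layer signal, and
literal nested-loop reference implementations of the model's summations.

The generator is a planted block model: miRNAs, diseases and lncRNAs are
partitioned into blocks, miRNA-disease edges inside a block are drawn much
more densely than background, and the same blocks are echoed in the
miRNA-lncRNA and disease-lncRNA layers (controlled by ``layer_coupling``) so
that co-occurrence over lncRNA neighbourhoods carries real signal about
held-out miRNA-disease edges — the structure the collaborative-filtering and
resource-allocation stages exploit.  A fraction of the planted edges can be
withheld from the returned graph to serve as recoverable ground truth.

The ``oracle_*`` functions transcribe the defining per-entry summations as
plain Python loops.  They are intentionally slow and independent of the
vectorised implementations, which the test suite checks against them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import EntityIndex, STAGE_INITIAL, TripartiteGraph
from .model import MiRNADiseasePredictor


@dataclass
class SyntheticConfig:
    """Parameters of the planted block model.

    Defaults are the package's standard recovery benchmark: 60 miRNAs x 40
    diseases x 20 lncRNAs in 4 blocks, dense (0.5) within-block signal over a
    sparse (0.02) background, lncRNA layers coupled to the blocks at 0.7, and
    30% of planted miRNA-disease edges withheld.
    """

    n_m: int = 60
    n_d: int = 40
    n_l: int = 20
    n_blocks: int = 4
    within_block_prob: float = 0.5
    background_prob: float = 0.02
    layer_coupling: float = 0.7
    holdout_frac: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("within_block_prob", "background_prob", "layer_coupling", "holdout_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.within_block_prob <= self.background_prob:
            raise ValueError("within_block_prob must exceed background_prob")
        for name in ("n_m", "n_d", "n_l", "n_blocks"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def _block_labels(n: int, n_blocks: int) -> np.ndarray:
    return np.sort(np.arange(n) % n_blocks)


def generate(
    cfg: SyntheticConfig,
) -> tuple[TripartiteGraph, list[tuple[str, str]], list[tuple[str, str]]]:
    """Draw one seeded graph; return (graph, planted_pairs, heldout_pairs).

    ``planted_pairs`` are all realised within-block miRNA-disease edges;
    ``heldout_pairs`` is the random ``holdout_frac`` subset of them that was
    removed from the returned A_MD (still present in planted_pairs).
    """
    rng = np.random.default_rng(cfg.seed)
    bm = _block_labels(cfg.n_m, cfg.n_blocks)
    bd = _block_labels(cfg.n_d, cfg.n_blocks)
    bl = _block_labels(cfg.n_l, cfg.n_blocks)

    same_md = bm[:, None] == bd[None, :]
    same_ml = bm[:, None] == bl[None, :]
    same_dl = bd[:, None] == bl[None, :]

    def draw(same: np.ndarray, p_within: float) -> np.ndarray:
        p = np.where(same, p_within, cfg.background_prob)
        return (rng.random(same.shape) < p).astype(np.int8)

    a_md = draw(same_md, cfg.within_block_prob)
    coupled = cfg.layer_coupling * cfg.within_block_prob
    a_ml = draw(same_ml, coupled)
    a_dl = draw(same_dl, coupled)

    mirnas = EntityIndex(tuple(f"m{i:03d}" for i in range(cfg.n_m)), "miRNA")
    diseases = EntityIndex(tuple(f"d{i:03d}" for i in range(cfg.n_d)), "disease")
    lncrnas = EntityIndex(tuple(f"l{i:03d}" for i in range(cfg.n_l)), "lncRNA")

    rows, cols = np.nonzero(a_md * same_md)
    planted = [(mirnas.names[r], diseases.names[c]) for r, c in zip(rows, cols)]
    n_hold = int(round(cfg.holdout_frac * len(planted)))
    hold_idx = rng.choice(len(planted), size=n_hold, replace=False) if n_hold else []
    heldout = [planted[i] for i in sorted(hold_idx)]
    for m, d in heldout:
        a_md[mirnas.position(m), diseases.position(d)] = 0

    graph = TripartiteGraph(
        A_MD=a_md, A_ML=a_ml, A_DL=a_dl,
        mirnas=mirnas, diseases=diseases, lncrnas=lncrnas,
        stage=STAGE_INITIAL,
    )
    return graph, planted, heldout


def heldout_recovery_scores(
    graph: TripartiteGraph,
    heldout: list[tuple[str, str]],
    gamma: float = 0.9,
    use_cf: bool = True,
    seed: int = 0,
    p_denominator: str = "all_rows",
) -> tuple[np.ndarray, np.ndarray]:
    """Score held-out edges against an equal number of random non-edges.

    Returns (scores, labels): label 1 for held-out planted pairs, 0 for the
    sampled non-edges (cells that are 0 in A_MD and not held out).
    """
    model = MiRNADiseasePredictor(
        gamma=gamma, use_cf=use_cf, p_denominator=p_denominator
    ).fit(graph)
    pos_scores = model.pair_scores(heldout)

    held_cells = {
        graph.mirnas.position(m) * graph.n_d + graph.diseases.position(d)
        for m, d in heldout
    }
    zero_cells = np.flatnonzero(graph.A_MD.ravel() == 0)
    candidates = zero_cells[~np.isin(zero_cells, sorted(held_cells))]
    rng = np.random.default_rng(seed)
    neg_cells = rng.choice(candidates, size=len(heldout), replace=False)
    neg_scores = model.scores_.ravel()[neg_cells]

    scores = np.concatenate([pos_scores, neg_scores])
    labels = np.concatenate([np.ones(len(pos_scores)), np.zeros(len(neg_scores))])
    return scores, labels


# ---------------------------------------------------------------------------
# Literal nested-loop oracles
# ---------------------------------------------------------------------------

def oracle_similarity(g: TripartiteGraph) -> np.ndarray:
    """Set-intersection cosine similarity, computed pair by pair."""
    mld = g.splice_mld()
    n_m = g.n_m
    neigh = [set(np.flatnonzero(mld[k])) for k in range(n_m)]
    out = np.zeros((n_m, n_m))
    for k in range(n_m):
        for r in range(n_m):
            denom = np.sqrt(len(neigh[k]) * len(neigh[r]))
            if denom > 0:
                out[k, r] = len(neigh[k] & neigh[r]) / denom
    return out


def oracle_recommender(r_nor: np.ndarray, g: TripartiteGraph) -> np.ndarray:
    """Triple-loop matrix product R_nor @ A0_MLD."""
    mld = g.splice_mld()
    n_m, n_c = mld.shape
    out = np.zeros((n_m, n_c))
    for k in range(n_m):
        for c in range(n_c):
            out[k, c] = sum(r_nor[k, t] * mld[t, c] for t in range(n_m))
    return out


def oracle_weights(g: TripartiteGraph) -> np.ndarray:
    """Per-entry transfer weights w_kt with explicit degree sums."""
    a = g.A_MD
    n_m, n_d = a.shape
    deg_m = a.sum(axis=1)
    deg_d = a.sum(axis=0)
    out = np.zeros((n_m, n_m))
    for k in range(n_m):
        if deg_m[k] == 0:
            continue
        for t in range(n_m):
            s = 0.0
            for j in range(n_d):
                if deg_d[j] > 0:
                    s += a[k, j] * a[t, j] / deg_d[j]
            out[k, t] = s / deg_m[k]
    return out


def oracle_consistency(w: np.ndarray) -> np.ndarray:
    """Elementwise consistence correction w'_kt = w_kt + w_tk / col_sum_k."""
    n = w.shape[0]
    out = np.zeros_like(w, dtype=float)
    for k in range(n):
        colsum = sum(w[s, k] for s in range(n))
        for t in range(n):
            out[k, t] = w[k, t] + (w[t, k] / colsum if colsum > 0 else 0.0)
    return out


def oracle_rscore1(w_prime: np.ndarray, g: TripartiteGraph) -> np.ndarray:
    """Triple-loop product W' @ A_u_MD."""
    a = g.A_MD
    n_m, n_d = a.shape
    out = np.zeros((n_m, n_d))
    for k in range(n_m):
        for j in range(n_d):
            out[k, j] = sum(w_prime[k, t] * a[t, j] for t in range(n_m))
    return out


def oracle_rscore2(g: TripartiteGraph) -> np.ndarray:
    """Path summation of the D -> L -> D propagation, one path at a time."""
    a_md = g.A_MD
    a_dl = g.A_DL
    n_m, n_d = a_md.shape
    n_l = a_dl.shape[1]
    deg_d = a_dl.sum(axis=1)
    deg_l = a_dl.sum(axis=0)
    out = np.zeros((n_m, n_d))
    for k in range(n_m):
        for j in range(n_d):
            total = 0.0
            for jp in range(n_d):
                if a_md[k, jp] == 0 or deg_d[jp] == 0:
                    continue
                for i in range(n_l):
                    if a_dl[jp, i] and a_dl[j, i] and deg_l[i] > 0:
                        total += (1.0 / deg_d[jp]) * (1.0 / deg_l[i])
            out[k, j] = total
    return out
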