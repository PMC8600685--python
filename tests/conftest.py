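import numpy as np
import pytest

from trimda.graph import EntityIndex, TripartiteGraph


def random_graph(
    rng: np.random.Generator,
    n_m: int = 12,
    n_d: int = 8,
    n_l: int = 6,
    p: float = 0.3,
    stage: str = "initial",
) -> TripartiteGraph:
    """Unstructured random binary tripartite graph for equivalence tests."""
    return TripartiteGraph(
        A_MD=(rng.random((n_m, n_d)) < p).astype(np.int8),
        A_ML=(rng.random((n_m, n_l)) < p).astype(np.int8),
        A_DL=(rng.random((n_d, n_l)) < p).astype(np.int8),
        mirnas=EntityIndex(tuple(f"m{i:02d}" for i in range(n_m)), "miRNA"),
        diseases=EntityIndex(tuple(f"d{i:02d}" for i in range(n_d)), "disease"),
        lncrnas=EntityIndex(tuple(f"l{i:02d}" for i in range(n_l)), "lncRNA"),
        stage=stage,
    )


def graph_from_matrices(a_md, a_ml, a_dl, stage="initial") -> TripartiteGraph:
    a_md, a_ml, a_dl = (np.atleast_2d(np.asarray(m)) for m in (a_md, a_ml, a_dl))
    n_m, n_d = a_md.shape
    n_l = a_ml.shape[1]
    return TripartiteGraph(
        A_MD=a_md, A_ML=a_ml, A_DL=a_dl,
        mirnas=EntityIndex(tuple(f"m{i}" for i in range(n_m)), "miRNA"),
        diseases=EntityIndex(tuple(f"d{i}" for i in range(n_d)), "disease"),
        lncrnas=EntityIndex(tuple(f"l{i}" for i in range(n_l)), "lncRNA"),
        stage=stage,
    )


def pair_count_auc(scores, labels) -> float:
    """Concordant-pair (Mann-Whitney) AUC with half credit for tied scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = concordant = 0.0
    for p in pos:
        for n in neg:
            total += 1
            if p > n:
                concordant += 1
            elif p == n:
                concordant += 0.5
    return concordant / total


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_graph():
    """Two miRNAs, one disease, one lncRNA: m1-{l1,d1}, m2-{l1}, d1-l1."""
    return graph_from_matrices([[1], [0]], [[1], [1]], [[1]])
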