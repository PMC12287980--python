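import numpy as np
import pytest

import adrscore as a


@pytest.fixture
def toy():
    """2x2 identity adjacency with hand-set similarity matrices.

    Drugs a, b; side effects x, y; known pairs (a,x) and (b,y).
    Drug similarity off-diagonal 0.8, side-effect off-diagonal 0.5.
    """
    rel = a.RelationTable(pairs=frozenset({("a", "x"), ("b", "y")}))
    adj = a.build_adjacency(rel)
    drug_sim = a.SimilarityMatrix(
        axis=a.Axis.DRUG, metric="cosine",
        S=np.array([[1.0, 0.8], [0.8, 1.0]]), vocab=adj.drug_vocab)
    se_sim = a.SimilarityMatrix(
        axis=a.Axis.SIDE_EFFECT, metric="cosine",
        S=np.array([[1.0, 0.5], [0.5, 1.0]]), vocab=adj.se_vocab)
    return adj, drug_sim, se_sim


@pytest.fixture(scope="session")
def default_run():
    """One fitted model on the reference synthetic benchmark (defaults, seed 7)."""
    data = a.generate(a.SyntheticConfig())
    model = a.RelationScorer().fit(
        data.relations, data.drug_embeddings, data.se_embeddings)
    model.evaluate()
    return data, model


def random_instance(rng, max_drugs=30, max_ses=50):
    """A random adjacency + random symmetric similarity matrices for oracle checks."""
    nd = int(rng.integers(3, max_drugs + 1))
    ns = int(rng.integers(3, max_ses + 1))
    R = (rng.random((nd, ns)) < 0.3).astype(np.int8)
    R[R.sum(axis=1) == 0, 0] = 1
    R[0, R.sum(axis=0) == 0] = 1
    dv = a.Vocabulary.from_terms("drug", [f"d{i:03d}" for i in range(nd)])
    sv = a.Vocabulary.from_terms("side_effect", [f"s{j:03d}" for j in range(ns)])
    adj = a.AdjacencyMatrix(R=R, drug_vocab=dv, se_vocab=sv)
    SD = rng.normal(size=(nd, nd))
    SE = rng.normal(size=(ns, ns))
    drug_sim = a.SimilarityMatrix(axis=a.Axis.DRUG, metric="dot",
                                  S=(SD + SD.T) / 2, vocab=dv)
    se_sim = a.SimilarityMatrix(axis=a.Axis.SIDE_EFFECT, metric="dot",
                                S=(SE + SE.T) / 2, vocab=sv)
    return adj, drug_sim, se_sim


def naive_scores(adj, drug_sim, se_sim):
    """Brute-force quadruple-loop scorer: the independent oracle."""
    nd, ns = adj.shape
    R, SD, SE = adj.R, drug_sim.S, se_sim.S
    out = np.zeros((nd, ns))
    for alpha in range(nd):
        for beta in range(ns):
            rd = [i for i in range(nd) if R[i, beta] == 1 and i != alpha]
            rs = [j for j in range(ns) if R[alpha, j] == 1 and j != beta]
            if not rd or not rs:
                out[alpha, beta] = 0.0
            else:
                sx = max(SD[alpha, i] for i in rd)
                sy = max(SE[beta, j] for j in rs)
                out[alpha, beta] = sx * sy
    return out
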