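"""Simulation benchmark for the network-inference core.

Ground-truth graphs are Erdős–Rényi G(n, p); a covariance matrix is built
with a non-zero entry exactly on connected pairs (unit diagonal, with a
minimum-eigenvalue repair so it stays positive definite); zero-mean
multivariate Gaussian samples are drawn from it; the graphical model ranks
all node pairs by partial-correlation magnitude; and the ranking is scored
against the true graph with an ROC curve. True positive: predicted edge
present in the truth. False positive: predicted edge absent from the truth.
False negative: true edge not predicted; true negative: absent from both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import copula_transform, fit_glasso, GlassoConvergenceError

__all__ = [
    "er_graph",
    "graph_to_covariance",
    "sample_mvn",
    "edge_scores",
    "roc_auc",
    "run_benchmark",
    "read_genenetweaver",
    "ROCResult",
    "SimulatedNetwork",
]


def er_graph(n: int, p: float = 0.2, seed=None) -> np.ndarray:
    """Erdős–Rényi G(n, p) adjacency matrix (symmetric, zero diagonal)."""
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if not 0 <= p <= 1:
        raise ValueError("edge probability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    a = np.zeros((n, n), dtype=np.int8)
    a[iu] = rng.random(len(iu[0])) < p
    return a + a.T


def graph_to_covariance(adjacency: np.ndarray, strength: float = 0.25,
                        min_eig: float = 0.1) -> np.ndarray:
    """Covariance with non-zero entries exactly on connected node pairs.

    Off-diagonal entries are ``strength`` where an edge exists, zero
    elsewhere, with unit diagonal. If the smallest eigenvalue falls below
    ``min_eig`` the matrix is inflated by (min_eig - lambda_min) I and
    rescaled back to a unit diagonal, preserving the zero pattern.
    """
    a = np.asarray(adjacency)
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    S = np.where(a > 0, strength, 0.0).astype(float)
    np.fill_diagonal(S, 1.0)
    lam_min = float(np.linalg.eigvalsh(S)[0])
    if lam_min < min_eig:
        bump = min_eig - lam_min
        S = S + bump * np.eye(len(S))
        S = S / (1.0 + bump)
    return S


def sample_mvn(covariance: np.ndarray, m: int, seed=None) -> np.ndarray:
    """m i.i.d. zero-mean multivariate Gaussian draws (Cholesky sampler)."""
    try:
        L = np.linalg.cholesky(covariance)
    except np.linalg.LinAlgError as e:
        raise ValueError("covariance is not positive definite") from e
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((m, covariance.shape[0]))
    return z @ L.T


@dataclass
class SimulatedNetwork:
    """One benchmark replicate: truth graph, covariance and drawn samples."""

    n: int
    p: float
    adjacency: np.ndarray
    covariance: np.ndarray
    samples: np.ndarray


def simulate_network(n: int, m: int, p: float = 0.2, strength: float = 0.25,
                     seed=None) -> SimulatedNetwork:
    rng = np.random.default_rng(seed)
    adj = er_graph(n, p, seed=rng)
    cov = graph_to_covariance(adj, strength=strength)
    samples = sample_mvn(cov, m, seed=rng)
    return SimulatedNetwork(n=n, p=p, adjacency=adj, covariance=cov,
                            samples=samples)


def edge_scores(samples: np.ndarray, use_copula: bool = False,
                penalty: float = 0.01) -> np.ndarray:
    """Score every node pair by GGM partial-correlation magnitude.

    Fits the graphical lasso at a small, nearly unpenalised ``penalty`` on
    the sample correlation matrix (optionally after the copula transform)
    and returns the symmetric matrix of |partial correlation|. Falls back to
    pseudo-inverse partial correlations if the solver fails.
    """
    X = copula_transform(samples) if use_copula else np.asarray(samples, float)
    S = np.corrcoef(X, rowvar=False)
    try:
        model = fit_glasso(S, penalty=penalty, max_iter=200)
        pc = model.partial_correlations()
    except (GlassoConvergenceError, FloatingPointError):
        warnings.warn("graphical lasso failed; using pseudo-inverse "
                      "partial correlations")
        prec = np.linalg.pinv(S)
        d = np.sqrt(np.diag(prec))
        pc = -prec / np.outer(d, d)
    scores = np.abs(pc)
    np.fill_diagonal(scores, 0.0)
    return (scores + scores.T) / 2.0


@dataclass
class ROCResult:
    """ROC curve points and area under the curve."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores: np.ndarray, true_adjacency: np.ndarray) -> ROCResult:
    """ROC over all node pairs, sweeping the score threshold.

    Equal scores are grouped at a single threshold; the AUC is the
    trapezoidal area, which equals the normalised Mann-Whitney rank
    statistic of true-edge scores versus non-edge scores.
    """
    iu = np.triu_indices(true_adjacency.shape[0], k=1)
    y = np.asarray(true_adjacency)[iu].astype(bool)
    s = np.asarray(scores)[iu].astype(float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("degenerate truth: no edges or all edges present")
    order = np.argsort(-s, kind="mergesort")
    s, y = s[order], y[order]
    # group ties: cumulative counts at distinct-threshold boundaries
    distinct = np.concatenate([np.diff(s) != 0, [True]])
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(~y)[distinct]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr=fpr, tpr=tpr, auc=auc)


def run_benchmark(sizes: list[tuple[int, int]] = ((50, 500), (100, 1000)),
                  replicates: int = 10, p: float = 0.2,
                  strength: float = 0.25, use_copula: bool = False,
                  penalty: float = 0.01, seed=None) -> pd.DataFrame:
    """Full benchmark loop; one row per replicate with its AUC and seed.

    The default configuration matches the benchmark study design: 10
    networks of 50 nodes scored from 500 samples and 10 networks of 100
    nodes scored from 1,000 samples, edge probability 0.2.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for n, m in sizes:
        for r in range(replicates):
            rep_seed = int(rng.integers(0, 2**31 - 1))
            sim = simulate_network(n, m, p=p, strength=strength, seed=rep_seed)
            scores = edge_scores(sim.samples, use_copula=use_copula,
                                 penalty=penalty)
            auc = roc_auc(scores, sim.adjacency).auc
            rows.append({"n": n, "m": m, "replicate": r, "seed": rep_seed,
                         "auc": auc})
    return pd.DataFrame(rows)


def read_genenetweaver(network_file: str, expression_file: str
                       ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read a GeneNetWeaver-style network/expression pair.

    The network file is a 2/3-column tab-separated edge list (directed
    edges are symmetrised); the expression file is a samples x genes
    numeric table with a header of gene names. Returns the undirected
    adjacency, the expression matrix column-matched to the node order, and
    the node names.
    """
    expr = pd.read_csv(expression_file, sep="\t")
    genes = list(expr.columns)
    gene_idx = {g: i for i, g in enumerate(genes)}
    edges = pd.read_csv(network_file, sep="\t", header=None,
                        usecols=[0, 1], names=["src", "dst"], dtype=str)
    missing = sorted(set(edges["src"]) | set(edges["dst"]) - set(genes))
    missing = [g for g in missing if g not in gene_idx]
    if missing:
        raise ValueError(f"network nodes absent from expression header: {missing}")
    adj = np.zeros((len(genes), len(genes)), dtype=np.int8)
    for s, d in zip(edges["src"], edges["dst"]):
        i, j = gene_idx[s], gene_idx[d]
        if i != j:
            adj[i, j] = adj[j, i] = 1
    return adj, expr.to_numpy(dtype=float), genes
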