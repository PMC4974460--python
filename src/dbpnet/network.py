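"""Sparse Gaussian graphical model of DBP cooperation.

Under a multivariate Gaussian model, a zero entry of the precision matrix
(inverse covariance) means the two variables are conditionally independent
given all others, so the support of a sparse precision estimate defines a
network of direct associations. The precision matrix is estimated by the
graphical lasso (L1-penalised maximum likelihood) on the merged 1D/3D
correlation matrix; a rank-based Gaussianising (nonparanormal / copula)
transform is provided for sample-level data that is not Gaussian. Recovered
edges with a non-positive merged correlation are discarded (only positive
co-binding is interpreted as cooperation), and each remaining edge is
classified by comparing its 1D and 3D scores with a cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.covariance import graphical_lasso
from sklearn.utils.validation import check_array, check_is_fitted

from .cooperation import (LoopSet, PairScoreTable, anchor_scores, corr_1d,
                          corr_3d_matrix, merge_scores)
from .layout import BinnedTrack, GenomeLayout
from .signal import EnrichmentMatrix

__all__ = [
    "CopulaTransformer",
    "copula_transform",
    "ensure_valid_correlation",
    "fit_glasso",
    "PrecisionModel",
    "extract_network",
    "classify_edges",
    "CooperationNetworkEstimator",
    "network_from_tracks",
    "null_shuffle_check",
    "EDGE_CLASSES",
]

EDGE_CLASSES = ("1D-dominant", "3D-dominant", "1D-3D", "unclassified")


class CopulaTransformer(TransformerMixin, BaseEstimator):
    """Nonparanormal (copula) marginal Gaussianisation.

    Each column is mapped through its truncated empirical CDF to standard
    normal quantiles: ranks r are scaled to r/n, Winsorised into
    [delta_n, 1 - delta_n] with delta_n = 1 / (4 n^{1/4} sqrt(pi log n)),
    and passed through the standard normal quantile function. The transform
    is invariant to monotone transformations of a column and makes each
    marginal approximately standard normal, relaxing the Gaussianity
    assumption of the graphical model.
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=3)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = check_array(X, ensure_min_samples=3)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count changed between fit and transform")
        n = X.shape[0]
        delta = 1.0 / (4.0 * n ** 0.25 * np.sqrt(np.pi * np.log(n)))
        out = np.empty_like(X, dtype=float)
        for j in range(X.shape[1]):
            col = X[:, j]
            if np.all(col == col[0]):
                warnings.warn(f"constant column {j} mapped to zeros")
                out[:, j] = 0.0
                continue
            u = stats.rankdata(col, method="average") / n
            out[:, j] = stats.norm.ppf(np.clip(u, delta, 1.0 - delta))
        return out


def copula_transform(samples: np.ndarray) -> np.ndarray:
    """Functional wrapper over :class:`CopulaTransformer`."""
    return CopulaTransformer().fit_transform(samples)


def ensure_valid_correlation(S: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Project a symmetric unit-diagonal matrix to the nearest valid correlation.

    Entrywise merging of two correlation matrices can break positive
    semi-definiteness; this clips negative eigenvalues at ``eps`` and
    rescales back to a unit diagonal. A matrix that is already positive
    definite is returned unchanged.
    """
    S = np.asarray(S, dtype=float)
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("matrix is not symmetric")
    w, V = np.linalg.eigh(S)
    if w[0] > eps:
        return S
    w = np.clip(w, eps, None)
    fixed = (V * w) @ V.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    fixed = (fixed + fixed.T) / 2.0
    np.fill_diagonal(fixed, 1.0)
    return fixed


class GlassoConvergenceError(RuntimeError):
    """Graphical lasso failed to converge; carries solver diagnostics."""


@dataclass
class PrecisionModel:
    """Estimated covariance/precision pair from the graphical lasso."""

    dbps: list[str]
    covariance: np.ndarray
    precision: np.ndarray
    penalty: float
    n_iter: int
    dual_gap: float = float("nan")

    def partial_correlations(self) -> np.ndarray:
        """-P_ij / sqrt(P_ii P_jj); diagonal set to 1."""
        d = np.sqrt(np.diag(self.precision))
        pc = -self.precision / np.outer(d, d)
        np.fill_diagonal(pc, 1.0)
        return pc


def fit_glasso(S: np.ndarray, penalty: float = 0.3, dbps: list[str] | None = None,
               tol: float = 1e-4, max_iter: int = 200) -> PrecisionModel:
    """L1-penalised maximum-likelihood precision estimate of a correlation matrix."""
    S = np.asarray(S, dtype=float)
    if dbps is None:
        dbps = [f"v{i}" for i in range(S.shape[0])]
    try:
        cov, prec, costs, n_iter = graphical_lasso(
            S, alpha=penalty, tol=tol, max_iter=max_iter, return_costs=True,
            return_n_iter=True)
    except FloatingPointError as e:  # pragma: no cover - solver instability
        raise GlassoConvergenceError(
            f"graphical lasso failed at penalty={penalty}: {e}") from e
    if n_iter >= max_iter:
        warnings.warn(f"graphical lasso hit max_iter={max_iter}; "
                      f"final dual gap {costs[-1][1]:.3g}")
    return PrecisionModel(dbps=list(dbps), covariance=cov, precision=prec,
                          penalty=penalty, n_iter=int(n_iter),
                          dual_gap=float(costs[-1][1]))


def extract_network(model: PrecisionModel, pairs: PairScoreTable,
                    edge_threshold: float = 1e-8) -> nx.Graph:
    """Turn the precision support into a cooperation network.

    An edge exists where |precision| exceeds ``edge_threshold`` (absorbing
    solver noise) and the merged correlation is positive; each edge stores
    its 1D/3D/merged scores and partial correlation, initially unclassified.
    """
    if list(model.dbps) != list(pairs.dbps):
        raise ValueError("precision model and pair table index different DBPs")
    pc = model.partial_correlations()
    g = nx.Graph()
    g.add_nodes_from(model.dbps)
    n = len(model.dbps)
    for i in range(n):
        for j in range(i + 1, n):
            if abs(model.precision[i, j]) <= edge_threshold:
                continue
            a, b = model.dbps[i], model.dbps[j]
            if pairs.merged.loc[a, b] <= 0:
                continue
            g.add_edge(a, b,
                       corr_1d=float(pairs.corr1d.loc[a, b]),
                       corr_3d=float(pairs.corr3d.loc[a, b]),
                       merged=float(pairs.merged.loc[a, b]),
                       partial_corr=float(pc[i, j]),
                       label="unclassified")
    return g


def classify_edges(net: nx.Graph, cutoff: float = 0.3) -> nx.Graph:
    """Label each edge 1D-dominant, 3D-dominant or 1D-3D by the cutoff rule."""
    for _, _, d in net.edges(data=True):
        c1, c3 = d["corr_1d"], d["corr_3d"]
        if c1 > cutoff and c3 > cutoff:
            d["label"] = "1D-3D"
        elif c1 > cutoff:
            d["label"] = "1D-dominant"
        elif c3 > cutoff:
            d["label"] = "3D-dominant"
        else:
            d["label"] = "unclassified"
    return net


class CooperationNetworkEstimator(BaseEstimator):
    """Graphical-lasso cooperation network over a pair-score table.

    Parameters
    ----------
    penalty : float, default 0.3
        Lasso penalty on the precision matrix; the production default keeps
        edges roughly where pair correlations exceed the penalty scale.
    cutoff : float, default 0.3
        1D/3D classification cutoff on the correlation scores.
    edge_threshold : float, default 1e-8
        Minimum |precision| for an edge, absorbing solver noise.
    rank_correction : bool, default False
        Apply the 2 sin(pi rho / 6) Spearman-to-Pearson correction to the
        merged matrix before fitting.

    Attributes
    ----------
    model_ : PrecisionModel
    network_ : networkx.Graph with classified edges
    """

    def __init__(self, penalty: float = 0.3, cutoff: float = 0.3,
                 edge_threshold: float = 1e-8, rank_correction: bool = False):
        self.penalty = penalty
        self.cutoff = cutoff
        self.edge_threshold = edge_threshold
        self.rank_correction = rank_correction

    def fit(self, X: PairScoreTable, y=None):
        S = X.merged.to_numpy().copy()
        if self.rank_correction:
            S = 2.0 * np.sin(np.pi * S / 6.0)
            np.fill_diagonal(S, 1.0)
        S = ensure_valid_correlation(S)
        self.model_ = fit_glasso(S, penalty=self.penalty, dbps=X.dbps)
        net = extract_network(self.model_, X, edge_threshold=self.edge_threshold)
        self.network_ = classify_edges(net, cutoff=self.cutoff)
        return self

    def predict(self, X: PairScoreTable | None = None) -> nx.Graph:
        check_is_fitted(self, "network_")
        return self.network_


def pair_scores_from_tracks(score_tracks: list[BinnedTrack],
                            layout: GenomeLayout,
                            loops: LoopSet | None,
                            min_sd: float = 1.0,
                            selector: str = "max") -> PairScoreTable:
    """Pair-score table (1D, 3D, merged) from per-bin score tracks.

    Without loops the 3D matrix is NaN off-diagonal and the merged matrix
    falls back to the 1D scores (degraded 1D-only mode).
    """
    scores = np.vstack([t.values for t in score_tracks])
    sd = scores.std(axis=0, ddof=1)
    keep = sd >= min_sd
    mat = EnrichmentMatrix(dbps=[t.name for t in score_tracks],
                           bin_ids=np.flatnonzero(keep).astype(np.int64),
                           scores=scores[:, keep], layout=layout)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        c1d = corr_1d(mat)
    if loops is None or len(loops) == 0:
        c3d = pd.DataFrame(np.full_like(c1d.to_numpy(), np.nan),
                           index=c1d.index, columns=c1d.columns)
        np.fill_diagonal(c3d.values, 1.0)
        merged = c1d.copy()
        table = PairScoreTable(dbps=list(c1d.index), corr1d=c1d, corr3d=c3d,
                               merged=merged,
                               z1d=merge_scores(c1d, c1d).z1d, z3d=c3d.copy())
        return table
    table3 = anchor_scores(score_tracks, loops)
    c3d = corr_3d_matrix(table3, selector=selector)
    return merge_scores(c1d, c3d)


def network_from_tracks(score_tracks: list[BinnedTrack], layout: GenomeLayout,
                        loops: LoopSet | None, penalty: float = 0.3,
                        cutoff: float = 0.3, min_sd: float = 1.0,
                        selector: str = "max") -> tuple[nx.Graph, PairScoreTable]:
    """Full production path: tracks -> pair scores -> glasso -> classified net."""
    pairs = pair_scores_from_tracks(score_tracks, layout, loops,
                                    min_sd=min_sd, selector=selector)
    est = CooperationNetworkEstimator(penalty=penalty, cutoff=cutoff)
    # NaN 3D scores (degraded mode) cannot enter the glasso input
    if pairs.corr3d.isna().to_numpy().any():
        est.fit(PairScoreTable(pairs.dbps, pairs.corr1d, pairs.corr1d,
                               pairs.merged, pairs.z1d, pairs.z1d))
        net = est.network_
        for _, _, d in net.edges(data=True):
            d["corr_3d"] = float("nan")
            d["label"] = "1D-dominant" if d["corr_1d"] > cutoff else "unclassified"
    else:
        est.fit(pairs)
        net = est.network_
    return net, pairs


def null_shuffle_check(score_tracks: list[BinnedTrack], layout: GenomeLayout,
                       loops: LoopSet | None, seed: int,
                       penalty: float = 0.3, cutoff: float = 0.3,
                       min_sd: float = 1.0,
                       permutations: list[np.ndarray] | None = None) -> nx.Graph:
    """False-discovery control: shuffle each DBP's bin scores and re-run.

    Independently permuting every protein's per-bin scores destroys all
    co-binding structure while preserving marginal score distributions; the
    production pipeline applied to the shuffled tracks should return an
    empty network at the production penalty.
    """
    rng = np.random.default_rng(seed)
    shuffled = []
    for k, tr in enumerate(score_tracks):
        perm = (permutations[k] if permutations is not None
                else rng.permutation(layout.n_bins))
        shuffled.append(BinnedTrack(name=tr.name, values=tr.values[perm],
                                    layout=layout))
    net, _ = network_from_tracks(shuffled, layout, loops, penalty=penalty,
                                 cutoff=cutoff, min_sd=min_sd)
    return net
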