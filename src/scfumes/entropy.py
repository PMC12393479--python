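"""Per-cell metabolic signaling-entropy rates.

A cell's transcriptome defines a random walk on a gene-gene interaction
network: from gene i the walk moves to an interacting gene j with
probability proportional to j's expression,

    P_ij = A_ij x_j / sum_k A_ik x_k ,

where A is the binary symmetric adjacency and x the strictly positive
expression vector. The signaling entropy rate is the walk's entropy rate

    SR = sum_i u_i S_i / log(rho),   S_i = -sum_j P_ij log P_ij,

with u the stationary distribution and rho the spectral radius of A.
log(rho) is the maximum entropy rate attainable on the network, so SR lies
in [0, 1]; it equals 1 for a regular graph under uniform expression. The
walk is reversible, giving the closed form u_i ∝ x_i (A x)_i.

High SR reflects promiscuous, high-entropy signaling (high metabolic
activity/plasticity); low SR reflects deterministic routing through a few
strongly expressed partners.
"""

from __future__ import annotations

import logging
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.base import BaseEstimator, TransformerMixin

from ._stats import exact_ranksum_p, fdr_adjust

__all__ = [
    "SignalingEntropy",
    "build_transition_matrix",
    "stationary_distribution",
    "signaling_entropy_rate",
    "cell_entropy_profiles",
    "summarize_entropy_by_group",
]

logger = logging.getLogger(__name__)


def _check_adjacency(adjacency) -> np.ndarray:
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if A.shape[0] < 3:
        raise ValueError("network must have at least 3 nodes")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(A) != 0):
        raise ValueError("adjacency must have a zero diagonal (no self-loops)")
    if np.any(A.sum(axis=1) == 0):
        raise ValueError("network contains isolated nodes; restrict to a "
                         "connected component first")
    return A


def _check_expression(A: np.ndarray, x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != A.shape[0]:
        raise ValueError("expression vector length does not match network size")
    if np.any(x <= 0):
        raise ValueError("expression must be strictly positive on every network "
                         "gene; apply CP10K normalization plus a pseudocount")
    return x


def build_transition_matrix(adjacency, x) -> np.ndarray:
    """Row-stochastic transition matrix of the expression-weighted walk."""
    A = _check_adjacency(adjacency)
    x = _check_expression(A, x)
    w = A * x[None, :]
    return w / w.sum(axis=1, keepdims=True)


def stationary_distribution(adjacency, x) -> np.ndarray:
    """Stationary distribution u_i ∝ x_i (A x)_i of the reversible walk."""
    A = _check_adjacency(adjacency)
    x = _check_expression(A, x)
    u = x * (A @ x)
    return u / u.sum()


def spectral_radius(adjacency) -> float:
    """Largest eigenvalue of the (symmetric) adjacency matrix."""
    A = _check_adjacency(adjacency)
    return float(np.linalg.eigvalsh(A)[-1])


def signaling_entropy_rate(adjacency, x, rho: float | None = None) -> float:
    """Entropy rate of the walk, normalized to [0, 1] by log(rho)."""
    A = _check_adjacency(adjacency)
    x = _check_expression(A, x)
    if rho is None:
        rho = spectral_radius(A)
    log_rho = np.log(rho)
    if log_rho <= 0:
        raise ValueError("degenerate network: maximum entropy rate is zero")
    P = build_transition_matrix(A, x)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(P), 0.0)
    S = -plogp.sum(axis=1)
    u = stationary_distribution(A, x)
    return float(u @ S / log_rho)


class SignalingEntropy(BaseEstimator, TransformerMixin):
    """Per-cell signaling entropy rate over an interaction network.

    ``fit`` intersects the network with the measured genes and restricts it
    to its largest connected component; ``transform`` returns one SR value
    per cell. Counts are CP10K-normalized per cell (using each cell's total
    over all measured genes) and offset by ``pseudocount`` so the walk is
    well defined; SR is invariant to a global rescaling of the expression
    vector, so the normalization only fixes the pseudocount's relative size.

    Parameters
    ----------
    network : networkx.Graph
        Undirected gene interaction graph keyed by gene name.
    pseudocount : float
        Offset added to CP10K values (default 1.0).
    target_sum : float
        Per-cell normalization total (default 10,000).
    normalize : bool
        Set False if the input matrix is already normalized and positive.

    Attributes
    ----------
    genes_ : list of str
        Network genes retained (largest connected component ∩ matrix).
    adjacency_ : ndarray
        Binary adjacency over ``genes_``.
    rho_ : float
        Spectral radius of ``adjacency_``.
    n_dropped_genes_ : int
        Network genes discarded at fit (unmeasured or outside the LCC).
    """

    def __init__(self, network: nx.Graph, pseudocount: float = 1.0,
                 target_sum: float = 1e4, normalize: bool = True):
        self.network = network
        self.pseudocount = pseudocount
        self.target_sum = target_sum
        self.normalize = normalize

    def fit(self, adata, y=None):
        var_names = set(map(str, adata.var_names))
        present = [g for g in self.network.nodes if str(g) in var_names]
        sub = self.network.subgraph(present)
        components = sorted(nx.connected_components(sub),
                            key=lambda c: (-len(c), min(map(str, c))))
        lcc = sorted(map(str, components[0])) if components else []
        if len(lcc) < 3:
            raise ValueError(
                f"only {len(lcc)} network genes present in the matrix after "
                "taking the largest connected component; need at least 3"
            )
        dropped = self.network.number_of_nodes() - len(lcc)
        if dropped:
            logger.info("dropped %d network genes absent from the matrix or "
                        "outside the largest connected component", dropped)
        self.n_dropped_genes_ = dropped
        self.genes_ = lcc
        self.adjacency_ = nx.to_numpy_array(self.network.subgraph(lcc),
                                            nodelist=lcc, dtype=float)
        np.fill_diagonal(self.adjacency_, 0.0)
        self.adjacency_ = (self.adjacency_ > 0).astype(float)
        self.rho_ = spectral_radius(self.adjacency_)
        if np.log(self.rho_) <= 0:
            raise ValueError("degenerate network: maximum entropy rate is zero")
        return self

    def _expression(self, adata) -> np.ndarray:
        X = adata.X
        totals = np.asarray(X.sum(axis=1)).ravel()
        idx = [adata.var_names.get_loc(g) for g in self.genes_]
        Xg = X[:, idx]
        Xg = Xg.toarray() if sparse.issparse(Xg) else np.asarray(Xg, dtype=float)
        if self.normalize:
            if np.any(totals <= 0):
                raise ValueError("cells with zero total counts cannot be normalized")
            Xg = Xg * (self.target_sum / totals[:, None])
        return Xg + self.pseudocount

    def transform(self, adata) -> np.ndarray:
        if not hasattr(self, "adjacency_"):
            raise RuntimeError("SignalingEntropy must be fitted before transform")
        A = self.adjacency_
        log_rho = np.log(self.rho_)
        Xn = self._expression(adata)  # cells x genes, strictly positive
        Z = Xn @ A                    # z_ci = sum_j A_ij x_cj
        T = (Xn * np.log(Xn)) @ A
        S = np.log(Z) - T / Z         # local entropies S_ci
        U = Xn * Z
        U = U / U.sum(axis=1, keepdims=True)
        sr = (U * S).sum(axis=1) / log_rho
        return sr


def cell_entropy_profiles(adata, network: nx.Graph,
                          celltype_col: str = "cell_type",
                          group_col: str = "group",
                          pseudocount: float = 1.0,
                          target_sum: float = 1e4,
                          normalize: bool = True) -> pd.DataFrame:
    """One signaling entropy rate per cell, with its labels."""
    est = SignalingEntropy(network, pseudocount=pseudocount,
                           target_sum=target_sum, normalize=normalize)
    sr = est.fit(adata).transform(adata)
    return pd.DataFrame({
        "cell_id": list(map(str, adata.obs_names)),
        "cell_type": adata.obs[celltype_col].astype(str).to_numpy(),
        "group": adata.obs[group_col].astype(str).to_numpy(),
        "SR": sr,
    })


def summarize_entropy_by_group(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per (cell type, group) SR summary with a cross-group rank-sum test.

    With two groups the two-sided rank-sum p (exact by enumeration on small
    strata, midranks for ties) is computed per cell type and BH-adjusted
    across cell types; a cell type present in a single group gets p = NA.
    More than two groups uses the Kruskal-Wallis test instead.
    """
    groups = sorted(profiles["group"].unique())
    if len(groups) < 2:
        raise ValueError("at least 2 groups are required for a comparison")
    rows = []
    for (ct, grp), sub in profiles.groupby(["cell_type", "group"], sort=True,
                                           observed=True):
        rows.append({"cell_type": ct, "group": grp, "n": len(sub),
                     "median_SR": float(sub["SR"].median()),
                     "mean_SR": float(sub["SR"].mean())})
    summary = pd.DataFrame(rows)

    pvals = {}
    for ct, sub in profiles.groupby("cell_type", sort=True, observed=True):
        present = sorted(sub["group"].unique())
        if len(present) < len(groups):
            pvals[ct] = np.nan
            continue
        samples = [sub.loc[sub["group"] == g, "SR"].to_numpy() for g in present]
        if len(present) == 2:
            pvals[ct] = exact_ranksum_p(samples[0], samples[1])
        else:
            from scipy.stats import kruskal
            pvals[ct] = float(kruskal(*samples).pvalue)
    ptab = pd.DataFrame({"cell_type": list(pvals), "p": list(pvals.values())})
    ptab["q"] = fdr_adjust(ptab["p"].to_numpy())
    return summary.merge(ptab, on="cell_type", how="left")
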