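"""Weighted metabolic pathway-activity scores (PAS).

For each group, a gene's relative expression in a cell type is its mean
expression there divided by its mean over all cells (both groups pooled, so
the groups share one baseline). A pathway's activity score in a cell type
is the occurrence-weighted average of its genes' relative expressions,
with weight w_g = 1 / (number of pathways containing g) so promiscuous
housekeeping-adjacent genes count less. A score of 1 is the neutral
baseline; > 1 marks enrichment.

Before averaging, outlier genes are excluded: quartiles Q1/Q3 are taken
over the pathway's full relative-expression matrix (genes x cell types,
linear-interpolation quantiles), and a gene whose value in ANY cell type
exceeds 3*Q3 or falls below Q1/3 is removed from the pathway in all cell
types, keeping scores comparable across cell types.

Significance comes from shuffling cell-type labels within each group and
recomputing the full chain; a deviation is retained at BH q < 0.05, and a
pathway is called changed between groups when the score difference exceeds
0.1 and it is significant in at least one group.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.base import BaseEstimator

from ._stats import fdr_adjust, label_assignments

__all__ = [
    "PathwayActivityScorer",
    "pathway_weights",
    "relative_expression",
    "pathway_activity_score",
    "pas_significance",
    "pas_group_difference",
]

logger = logging.getLogger(__name__)


def pathway_weights(pathways: dict[str, list[str]]) -> dict[str, float]:
    """Occurrence weights w_g = 1 / (number of pathways containing g)."""
    count: dict[str, int] = {}
    for genes in pathways.values():
        for g in set(genes):
            count[g] = count.get(g, 0) + 1
    return {g: 1.0 / c for g, c in count.items()}


def _dense(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)


def relative_expression(adata, celltype_col: str = "cell_type",
                        group_col: str = "group",
                        shared_baseline: bool = True) -> pd.DataFrame:
    """Relative expression r_{g,k,group}: stratum mean over global mean.

    The global mean pools all cells of both groups by default so the groups
    share one baseline (``shared_baseline=False`` uses per-group means).
    Genes with zero global mean are dropped; empty strata are omitted with
    a warning.
    """
    X = _dense(adata.X)
    genes = np.asarray(adata.var_names, dtype=str)
    cts = adata.obs[celltype_col].astype(str).to_numpy()
    grps = adata.obs[group_col].astype(str).to_numpy()

    global_mean = X.mean(axis=0)
    rows = []
    for grp in sorted(set(grps)):
        gsel = grps == grp
        base = X[gsel].mean(axis=0) if not shared_baseline else global_mean
        nonzero = base > 0
        for ct in sorted(set(cts)):
            sel = gsel & (cts == ct)
            if not sel.any():
                warnings.warn(f"empty stratum ({ct!r}, {grp!r}) omitted")
                continue
            r = X[sel].mean(axis=0)[nonzero] / base[nonzero]
            rows.append(pd.DataFrame({"gene": genes[nonzero], "cell_type": ct,
                                      "group": grp, "r": r}))
    return pd.concat(rows, ignore_index=True)


def _exclude_outliers(R: np.ndarray, factor: float = 3.0) -> np.ndarray:
    """Boolean keep-vector over genes of a pathway's r matrix (genes x K)."""
    q1, q3 = np.quantile(R, [0.25, 0.75])
    bad = (R > factor * q3) | (R < q1 / factor)
    return ~bad.any(axis=1)


def pathway_activity_score(pathway_genes, r: pd.DataFrame,
                           weights: dict[str, float],
                           outlier_factor: float = 3.0) -> pd.Series:
    """Weighted-average activity score per cell type for one pathway.

    ``r`` is a tidy relative-expression table for a single group (columns
    gene, cell_type, r). Outlier genes are excluded first; the result is
    indexed by cell type, NaN if every gene is excluded.
    """
    sub = r[r["gene"].isin(set(pathway_genes))]
    mat = sub.pivot(index="gene", columns="cell_type", values="r").dropna()
    if mat.shape[0] == 0:
        return pd.Series(dtype=float)
    keep = _exclude_outliers(mat.to_numpy(), outlier_factor)
    cts = mat.columns
    if not keep.any():
        return pd.Series(np.nan, index=cts)
    mat = mat[keep]
    w = np.array([weights.get(g, 1.0) for g in mat.index])
    return pd.Series((w @ mat.to_numpy()) / w.sum(), index=cts)


class PathwayActivityScorer(BaseEstimator):
    """Pathway activity scoring with a label-shuffling permutation null.

    Expects a preprocessed matrix (CP10K + log1p, as produced by
    ``fumes.preprocess_counts``). Permutations reshuffle cell-type labels
    within each group independently and recompute the full chain,
    including outlier exclusion; the two-sided p is the proportion of
    shuffles whose score deviates from the neutral baseline of 1 at least
    as much as observed.

    Parameters
    ----------
    pathways : dict
        Pathway name -> gene list (e.g. from ``io.read_gmt``).
    n_permutations, method, random_state :
        Permutation null controls; 'auto' enumerates exhaustively when all
        distinct label assignments number at most ``n_permutations``.
    shared_baseline : bool
        Pool both groups for the global mean (default True).
    outlier_factor : float
        Outlier rule thresholds 3*Q3 and Q1/3 (default 3).
    pseudocount : float
        Added as (1 + p) / (1 + N) to permutation p when > 0 (default 0,
        raw proportions).

    Attributes
    ----------
    results_ : pd.DataFrame
        pathway, cell_type, group, score, n_genes_used, p_perm, q,
        enriched, significant.
    weights_ : dict
        Gene occurrence weights over the supplied pathway collection.
    """

    def __init__(self, pathways: dict[str, list[str]],
                 celltype_col: str = "cell_type", group_col: str = "group",
                 n_permutations: int = 1000, method: str = "auto",
                 shared_baseline: bool = True, outlier_factor: float = 3.0,
                 pseudocount: float = 0.0, random_state: int | None = None):
        self.pathways = pathways
        self.celltype_col = celltype_col
        self.group_col = group_col
        self.n_permutations = n_permutations
        self.method = method
        self.shared_baseline = shared_baseline
        self.outlier_factor = outlier_factor
        self.pseudocount = pseudocount
        self.random_state = random_state

    def _scores_for_labels(self, Xp: np.ndarray, codes: np.ndarray, K: int,
                           base: np.ndarray, path_idx: dict):
        """Scores and gene counts per pathway for one label assignment."""
        nk = np.bincount(codes, minlength=K).astype(float)
        M = np.zeros((K, Xp.shape[0]))
        M[codes, np.arange(Xp.shape[0])] = 1.0 / nk[codes]
        R = (M @ Xp) / base[None, :]          # K x genes relative expression
        scores = {}
        for name, (idx, w) in path_idx.items():
            Rp = R[:, idx].T                  # genes x K
            keep = _exclude_outliers(Rp, self.outlier_factor)
            if not keep.any():
                scores[name] = (np.full(K, np.nan), 0)
                continue
            ww = w[keep]
            scores[name] = ((ww @ Rp[keep]) / ww.sum(), int(keep.sum()))
        return scores

    def fit(self, adata, y=None):
        if self.n_permutations < 100:
            warnings.warn("fewer than 100 permutations gives coarse p-value "
                          "resolution")
        X = _dense(adata.X)
        genes = np.asarray(adata.var_names, dtype=str)
        gpos = {g: j for j, g in enumerate(genes)}
        cts_all = adata.obs[self.celltype_col].astype(str).to_numpy()
        grp_all = adata.obs[self.group_col].astype(str).to_numpy()
        if len(set(cts_all)) < 2:
            raise ValueError("pathway scoring requires >= 2 cell types")

        global_mean = X.mean(axis=0)
        self.weights_ = pathway_weights(self.pathways)

        # measured pathway genes with a nonzero baseline
        path_idx = {}
        for name, pgenes in self.pathways.items():
            idx = [gpos[g] for g in dict.fromkeys(pgenes)
                   if g in gpos and global_mean[gpos[g]] > 0]
            if len(idx) < 2:
                warnings.warn(f"pathway {name!r} has fewer than 2 measured "
                              "genes; skipped")
                continue
            w = np.array([self.weights_[genes[j]] for j in idx])
            path_idx[name] = (np.array(idx), w)
        if not path_idx:
            raise ValueError("no pathway has >= 2 measured genes")

        used = sorted({j for idx, _ in path_idx.values() for j in idx})
        remap = {j: i for i, j in enumerate(used)}
        Xp = X[:, used]
        path_local = {name: (np.array([remap[j] for j in idx]), w)
                      for name, (idx, w) in path_idx.items()}

        rng = np.random.default_rng(self.random_state)
        rows = []
        self.exhaustive_ = {}
        for grp in sorted(set(grp_all)):
            gsel = grp_all == grp
            base = (global_mean if self.shared_baseline
                    else X[gsel].mean(axis=0))[used]
            zero = base == 0
            if zero.any():  # per-group baseline may zero out genes
                base = base.copy()
                base[zero] = np.inf
            cts = cts_all[gsel]
            ct_names = sorted(set(cts))
            codes = np.searchsorted(ct_names, cts)
            K = len(ct_names)
            Xg = Xp[gsel]

            obs = self._scores_for_labels(Xg, codes, K, base, path_local)
            assignments, exhaustive = label_assignments(
                codes, self.n_permutations, rng, self.method)
            self.exhaustive_[grp] = exhaustive
            num = {n: np.zeros(K) for n in path_local}
            den = {n: np.zeros(K) for n in path_local}
            for codes_p in assignments:
                perm = self._scores_for_labels(Xg, codes_p, K, base,
                                               path_local)
                for n in path_local:
                    s_obs, _ = obs[n]
                    s_p, _ = perm[n]
                    valid = np.isfinite(s_p) & np.isfinite(s_obs)
                    # ties are extreme; tolerance keeps tie-breaking
                    # independent of float summation order
                    with np.errstate(invalid="ignore"):
                        extreme = np.abs(s_p - 1.0) >= np.abs(s_obs - 1.0) - 1e-9
                    num[n] += np.where(valid & extreme, 1.0, 0.0)
                    den[n] += valid
            for n in sorted(path_local):
                s_obs, n_used = obs[n]
                with np.errstate(divide="ignore", invalid="ignore"):
                    p = np.where(den[n] > 0, num[n] / den[n], np.nan)
                if self.pseudocount > 0:
                    p = (num[n] + 1.0) / (den[n] + 1.0)
                for k, ct in enumerate(ct_names):
                    rows.append({"pathway": n, "cell_type": ct, "group": grp,
                                 "score": s_obs[k], "n_genes_used": n_used,
                                 "p_perm": p[k]})
        res = pd.DataFrame(rows)
        res["q"] = np.nan
        for grp in res["group"].unique():
            sel = res["group"] == grp
            res.loc[sel, "q"] = fdr_adjust(res.loc[sel, "p_perm"].to_numpy())
        res["enriched"] = res["score"] > 1
        res["significant"] = (res["q"] < 0.05) & (res["score"] != 1)
        self.results_ = res.sort_values(["group", "pathway", "cell_type"]) \
                           .reset_index(drop=True)
        return self


def pas_significance(adata, pathways: dict[str, list[str]],
                     n_perm: int = 1000, seed: int | None = None,
                     **kwargs) -> pd.DataFrame:
    """Pathway activity scores with permutation significance (wrapper)."""
    est = PathwayActivityScorer(pathways, n_permutations=n_perm,
                                random_state=seed, **kwargs)
    return est.fit(adata).results_


def pas_group_difference(results_a: pd.DataFrame, results_b: pd.DataFrame,
                         diff_cutoff: float = 0.1,
                         fdr: float = 0.05) -> pd.DataFrame:
    """Changed (pathway, cell type) calls between two groups.

    Changed requires an absolute score difference above ``diff_cutoff``
    (default 0.1) and significance (q < ``fdr``) in at least one group.
    Mismatched strata are restricted to the intersection with a warning.
    """
    keys = ["pathway", "cell_type"]
    names = []
    for res in (results_a, results_b):
        g = res["group"].unique() if len(res) else ["?"]
        if len(g) > 1:
            raise ValueError("each results table must contain a single group")
        names.append(str(g[0]))
    a = results_a[keys + ["score", "q"]].rename(
        columns={"score": "score_a", "q": "q_a"})
    b = results_b[keys + ["score", "q"]].rename(
        columns={"score": "score_b", "q": "q_b"})
    if len(a.merge(b, on=keys)) < max(len(a), len(b)):
        warnings.warn("groups were scored on different strata; restricting "
                      "to the intersection")
    m = a.merge(b, on=keys, how="inner")
    m["group_a"], m["group_b"] = names
    m["score_diff"] = m["score_a"] - m["score_b"]
    sig = (m["q_a"] < fdr) | (m["q_b"] < fdr)
    m["changed"] = sig & (m["score_diff"].abs() > diff_cutoff)
    m["direction"] = np.where(m["changed"],
                              np.where(m["score_diff"] > 0,
                                       f"up_in_{names[0]}",
                                       f"up_in_{names[1]}"), "")
    m["enriched_a"] = m["score_a"] > 1
    m["enriched_b"] = m["score_b"] > 1
    return m.sort_values(keys).reset_index(drop=True)
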