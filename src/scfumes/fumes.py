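"""Cell-type-specific metabolite-sensor communication scoring.

For each disease group separately, sensor-gene expression is averaged per
cell type (mu_{g,k}), standardized across cell types into a z-score
Z_{g,k} = (mu_{g,k} - mean_k mu_g) / sd_k mu_g (sample sd), and multiplied
by the pair's curated interaction strength A_{g,m} in [0, 1]:

    Score_{g,m,k} = Z_{g,k} * A_{g,m}.

A positive score marks a cell type where the sensor is specifically
elevated and the metabolite binds it strongly; significance comes from a
permutation null that reshuffles cell-type labels within the group and
recomputes the full chain (including the low-expression mask) each time.
P-values are BH-adjusted within each group; differential pairs between two
groups require FDR < 0.05 in at least one group and an absolute score
difference above 0.5.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import scanpy as sc
from scipy import sparse
from sklearn.base import BaseEstimator

from ._stats import fdr_adjust, label_assignments

__all__ = [
    "CommunicationScorer",
    "preprocess_counts",
    "celltype_mean_expression",
    "celltype_zscore",
    "communication_scores",
    "permutation_significance",
    "differential_pairs",
    "intersect_with_mr",
    "fdr_adjust",
]

logger = logging.getLogger(__name__)


def preprocess_counts(adata, min_genes: int = 200, min_cells: int = 10,
                      target_sum: float = 1e4, copy: bool = True):
    """Standard count preprocessing.

    Cells expressing fewer than ``min_genes`` genes and genes expressed in
    fewer than ``min_cells`` cells are removed (each filter applied once, in
    that order); surviving cells are scaled to ``target_sum`` total counts
    and log1p-transformed.
    """
    ad = adata.copy() if copy else adata
    sc.pp.filter_cells(ad, min_genes=min_genes)
    sc.pp.filter_genes(ad, min_cells=min_cells)
    if ad.n_obs == 0 or ad.n_vars == 0:
        raise ValueError(
            f"matrix is empty after filtering (min_genes={min_genes}, "
            f"min_cells={min_cells}); lower the thresholds"
        )
    sc.pp.normalize_total(ad, target_sum=target_sum)
    sc.pp.log1p(ad)
    return ad


def _dense(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)


def _group_means(X: np.ndarray, codes: np.ndarray, K: int):
    """Per-cell-type means: (K x genes) matrix and per-type cell counts."""
    n = X.shape[0]
    nk = np.bincount(codes, minlength=K).astype(float)
    M = np.zeros((K, n))
    M[codes, np.arange(n)] = 1.0 / nk[codes]
    return M @ X, nk


def _chain(X: np.ndarray, codes: np.ndarray, K: int, low_expr_quantile: float):
    """mu -> low-expression mask -> Z for one label assignment.

    Returns ``(mu, mask, Z)``; ``mask`` is True where a (cell type, gene)
    mean falls below the cell type's ``low_expr_quantile`` quantile of the
    sensor-gene mean distribution; Z columns with zero across-type sd are
    NaN.
    """
    mu, _ = _group_means(X, codes, K)
    q = np.quantile(mu, low_expr_quantile, axis=1, keepdims=True)
    mask = mu < q
    sd = mu.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = (mu - mu.mean(axis=0)) / sd
    Z[:, sd == 0] = np.nan
    return mu, mask, Z


def celltype_mean_expression(adata, pairs: pd.DataFrame,
                             celltype_col: str = "cell_type",
                             group_col: str = "group",
                             low_expr_quantile: float = 0.25) -> pd.DataFrame:
    """Per (gene, cell type, group) mean expression profile of sensor genes.

    Returns a tidy table with mean expression ``mu``, the fraction of cells
    with nonzero counts ``prop``, the number of cells ``n_cells``, and a
    ``low_expr`` flag for means below the within-stratum quantile cutoff.
    """
    sensors = _sensor_genes(adata, pairs)
    if not sensors:
        raise ValueError("no sensor from the activity table is present in "
                         "the matrix")
    X = _dense(adata[:, sensors].X)
    nz = X > 0
    rows = []
    for grp, obs_idx in adata.obs.groupby(group_col, observed=True).groups.items():
        pos = adata.obs.index.get_indexer(obs_idx)
        cts = adata.obs[celltype_col].astype(str).to_numpy()[pos]
        ct_names = sorted(set(cts))
        codes = np.searchsorted(ct_names, cts)
        mu, nk = _group_means(X[pos], codes, len(ct_names))
        small = [ct_names[k] for k in range(len(ct_names)) if nk[k] < 3]
        if small:
            warnings.warn(f"cell types with fewer than 3 cells in group "
                          f"{grp!r}: {small}")
        prop, _ = _group_means(nz[pos].astype(float), codes, len(ct_names))
        q = np.quantile(mu, low_expr_quantile, axis=1, keepdims=True)
        mask = mu < q
        for k, ct in enumerate(ct_names):
            for j, g in enumerate(sensors):
                rows.append({"gene": g, "cell_type": ct, "group": str(grp),
                             "mu": mu[k, j], "prop": prop[k, j],
                             "n_cells": int(nk[k]),
                             "low_expr": bool(mask[k, j])})
    return pd.DataFrame(rows)


def celltype_zscore(profile: pd.DataFrame) -> pd.DataFrame:
    """Standardize per-cell-type means across cell types, per gene and group.

    Uses the sample standard deviation (ddof=1); genes whose mean is
    constant across cell types are dropped with a warning. Requires at
    least two cell types.
    """
    out = []
    for (grp, gene), sub in profile.groupby(["group", "gene"], observed=True):
        mu = sub["mu"].to_numpy(dtype=float)
        if len(mu) < 2:
            raise ValueError("z-scoring requires >= 2 cell types")
        sd = mu.std(ddof=1)
        if sd == 0:
            warnings.warn(f"gene {gene!r} has constant mean across cell types "
                          f"in group {grp!r}; dropped")
            continue
        z = (mu - mu.mean()) / sd
        out.append(sub.assign(Z=z))
    if not out:
        return profile.iloc[0:0].assign(Z=np.nan)
    return pd.concat(out, ignore_index=True)


def communication_scores(zmatrix: pd.DataFrame,
                         activities: pd.DataFrame) -> pd.DataFrame:
    """Score_{g,m,k} = Z_{g,k} * A_{g,m}, one row per pair and cell type.

    Low-expression (gene, cell type) entries are excluded; pairs whose
    sensor is absent from the z-matrix are omitted and counted in the log.
    """
    z = zmatrix[~zmatrix["low_expr"]]
    merged = activities.merge(z, left_on="sensor_id", right_on="gene")
    missing = set(activities["sensor_id"]) - set(zmatrix["gene"])
    if missing:
        logger.info("%d sensors in the activity table are absent from the "
                    "matrix", len(missing))
    merged["score"] = merged["Z"] * merged["A"]
    cols = ["metabolite_id", "sensor_id", "cell_type", "group", "Z", "A",
            "score", "prop"]
    return merged[cols].sort_values(cols[:4]).reset_index(drop=True)


def _sensor_genes(adata, pairs: pd.DataFrame) -> list[str]:
    present = set(map(str, adata.var_names))
    return sorted({s for s in pairs["sensor_id"].astype(str) if s in present})


class CommunicationScorer(BaseEstimator):
    """Metabolite-sensor communication scoring with a permutation null.

    Parameters
    ----------
    celltype_col, group_col : str
        Columns of ``adata.obs`` holding cell-type and group labels.
    n_permutations : int
        Shuffles per group (default 1000).
    low_expr_quantile : float
        Within-stratum quantile below which a (gene, cell type) mean is
        masked as low-expressed (default 0.25).
    two_sided : bool
        Two-sided p on \\|Score\\| (default). False gives the literal
        one-sided null (permuted score >= observed), which cannot flag
        depleted (negative-score) pairs.
    method : {'auto', 'exhaustive', 'sampling'}
        'auto' enumerates all distinct within-group label assignments when
        they number at most ``n_permutations``.
    min_prop : float
        Optional expressing-cell-fraction filter on scored entries
        (default 0, inactive).
    preprocess : bool
        Apply :func:`preprocess_counts` in ``fit`` (default True).
    min_genes, min_cells, target_sum :
        Preprocessing thresholds.
    random_state : int or None
        Seed for the permutation stream; if None one is drawn and logged.

    Attributes
    ----------
    results_ : pd.DataFrame
        One row per (metabolite, sensor, cell type, group) with Z, A,
        score, p_perm, q, prop and the number of valid permutations.
    profiles_ : pd.DataFrame
        Per (gene, cell type, group) mean-expression profile.
    coverage_ : dict
        Pair/sensor join coverage per group.
    exhaustive_ : dict
        Whether the null was enumerated exhaustively, per group.
    seed_ : int
        Seed actually used.
    """

    def __init__(self, celltype_col: str = "cell_type", group_col: str = "group",
                 n_permutations: int = 1000, low_expr_quantile: float = 0.25,
                 two_sided: bool = True, method: str = "auto",
                 min_prop: float = 0.0, preprocess: bool = True,
                 min_genes: int = 200, min_cells: int = 10,
                 target_sum: float = 1e4, random_state: int | None = None):
        self.celltype_col = celltype_col
        self.group_col = group_col
        self.n_permutations = n_permutations
        self.low_expr_quantile = low_expr_quantile
        self.two_sided = two_sided
        self.method = method
        self.min_prop = min_prop
        self.preprocess = preprocess
        self.min_genes = min_genes
        self.min_cells = min_cells
        self.target_sum = target_sum
        self.random_state = random_state

    def fit(self, adata, pairs: pd.DataFrame):
        for col in ("metabolite_id", "sensor_id", "A"):
            if col not in pairs.columns:
                raise ValueError(f"pairs table is missing column {col!r}")
        for col in (self.celltype_col, self.group_col):
            if col not in adata.obs.columns:
                raise ValueError(f"adata.obs is missing column {col!r}")
        if self.n_permutations < 100:
            warnings.warn("fewer than 100 permutations gives coarse p-value "
                          "resolution")
        if self.random_state is None:
            self.seed_ = int(np.random.SeedSequence().entropy % (2**31))
            logger.warning("no seed supplied; using generated seed %d",
                           self.seed_)
        else:
            self.seed_ = int(self.random_state)

        ad = preprocess_counts(adata, self.min_genes, self.min_cells,
                               self.target_sum) if self.preprocess else adata
        self.n_cells_, self.n_genes_ = ad.shape

        sensors = _sensor_genes(ad, pairs)
        if not sensors:
            raise ValueError("no sensor from the activity table is present in "
                             "the matrix")
        X = _dense(ad[:, sensors].X)
        nz = (X > 0).astype(float)
        gi = {g: j for j, g in enumerate(sensors)}
        pair_tab = pairs[pairs["sensor_id"].astype(str).isin(gi)].copy()
        self.coverage_ = {
            "n_pairs_in": int(len(pairs)),
            "n_pairs_scored": int(len(pair_tab)),
            "n_sensors_missing": int(pairs["sensor_id"].astype(str)
                                     .nunique() - len(sensors)),
        }

        groups = sorted(ad.obs[self.group_col].astype(str).unique())
        cts_all = ad.obs[self.celltype_col].astype(str).to_numpy()
        grp_all = ad.obs[self.group_col].astype(str).to_numpy()
        rng = np.random.default_rng(self.seed_)

        results, profiles = [], []
        self.exhaustive_ = {}
        for grp in groups:
            pos = np.flatnonzero(grp_all == grp)
            cts = cts_all[pos]
            ct_names = sorted(set(cts))
            if len(ct_names) < 2:
                raise ValueError(f"group {grp!r} has a single cell type; "
                                 "z-scoring requires >= 2 cell types")
            codes = np.searchsorted(ct_names, cts)
            K = len(ct_names)
            Xg = X[pos]
            mu_obs, mask_obs, z_obs = _chain(Xg, codes, K,
                                             self.low_expr_quantile)
            prop, nk = _group_means(nz[pos], codes, K)

            assignments, exhaustive = label_assignments(
                codes, self.n_permutations, rng, self.method)
            self.exhaustive_[grp] = exhaustive
            num = np.zeros_like(z_obs)
            den = np.zeros_like(z_obs)
            obs_cmp = np.abs(z_obs) if self.two_sided else z_obs
            # ties count as extreme; the tolerance makes tie-breaking
            # independent of float summation order
            for codes_p in assignments:
                _, mask_p, z_p = _chain(Xg, codes_p, K, self.low_expr_quantile)
                valid = ~mask_p & np.isfinite(z_p)
                stat = np.abs(z_p) if self.two_sided else z_p
                with np.errstate(invalid="ignore"):
                    extreme = stat >= obs_cmp - 1e-9
                num += np.where(valid & extreme, 1.0, 0.0)
                den += valid
            with np.errstate(divide="ignore", invalid="ignore"):
                pmat = np.where(den > 0, num / den, np.nan)

            for k, ct in enumerate(ct_names):
                for g, j in gi.items():
                    profiles.append({"gene": g, "cell_type": ct, "group": grp,
                                     "mu": mu_obs[k, j], "prop": prop[k, j],
                                     "n_cells": int(nk[k]),
                                     "low_expr": bool(mask_obs[k, j])})

            keep = ~mask_obs & np.isfinite(z_obs)
            if self.min_prop > 0:
                keep &= prop >= self.min_prop
            for _, pr in pair_tab.iterrows():
                j = gi[str(pr["sensor_id"])]
                for k, ct in enumerate(ct_names):
                    if not keep[k, j]:
                        continue
                    results.append({
                        "metabolite_id": pr["metabolite_id"],
                        "sensor_id": pr["sensor_id"],
                        "cell_type": ct, "group": grp,
                        "Z": z_obs[k, j], "A": float(pr["A"]),
                        "score": z_obs[k, j] * float(pr["A"]),
                        "prop": prop[k, j],
                        "p_perm": pmat[k, j],
                        "n_valid_perm": int(den[k, j]),
                    })

        res = pd.DataFrame(results)
        if len(res):
            res["q"] = np.nan
            for grp in groups:
                sel = res["group"] == grp
                res.loc[sel, "q"] = fdr_adjust(res.loc[sel, "p_perm"].to_numpy())
            res = res.sort_values(["group", "metabolite_id", "sensor_id",
                                   "cell_type"]).reset_index(drop=True)
        self.results_ = res
        self.profiles_ = pd.DataFrame(profiles)
        return self


def permutation_significance(adata, pairs: pd.DataFrame, n_perm: int = 1000,
                             seed: int | None = None, **kwargs) -> pd.DataFrame:
    """Scored pairs with permutation p and BH q (thin estimator wrapper)."""
    est = CommunicationScorer(n_permutations=n_perm, random_state=seed,
                              **kwargs)
    return est.fit(adata, pairs).results_


def differential_pairs(results_a: pd.DataFrame, results_b: pd.DataFrame,
                       score_diff: float = 0.5, fdr: float = 0.05,
                       highly_selective: float = 10.0) -> pd.DataFrame:
    """Differential (pair, cell type) calls between two groups.

    A row is differential when FDR q < ``fdr`` in at least one group and
    the absolute score difference exceeds ``score_diff``; the signed
    difference and the group the pair is specific to are reported, plus a
    flag for highly selective pairs (difference above ``highly_selective``).
    """
    keys = ["metabolite_id", "sensor_id", "cell_type"]
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
    m = a.merge(b, on=keys, how="outer")
    m["group_a"], m["group_b"] = names
    m["score_diff"] = m["score_a"] - m["score_b"]
    sig = (m["q_a"] < fdr) | (m["q_b"] < fdr)
    m["differential"] = sig & (m["score_diff"].abs() > score_diff)
    m["specific_group"] = np.where(
        m["differential"],
        np.where(m["score_diff"] > 0, names[0], names[1]), "")
    m["highly_selective"] = m["differential"] & \
        (m["score_diff"].abs() > highly_selective)
    return m.sort_values(keys).reset_index(drop=True)


def intersect_with_mr(results: pd.DataFrame, mr: pd.DataFrame,
                      fdr: float = 0.05) -> pd.DataFrame:
    """Keep pairs whose metabolite has causal genetic support.

    A metabolite passes when its MR FDR is below ``fdr`` and the effect
    estimates of all reported MR methods (columns starting with ``beta``)
    agree in sign; passing metabolites are annotated ``risk`` (positive
    effect) or ``protective``. Unmatched metabolites are logged.
    """
    beta_cols = [c for c in mr.columns if c.startswith("beta")]
    if not beta_cols or "fdr" not in mr.columns:
        raise ValueError("MR table must have an 'fdr' column and >= 1 "
                         "'beta*' column")
    betas = mr[beta_cols].to_numpy(dtype=float)
    signs = np.sign(betas)
    consistent = (np.abs(signs.sum(axis=1)) == signs.shape[1])
    keep = mr[(mr["fdr"] < fdr) & consistent].copy()
    keep["mr_direction"] = np.where(keep[beta_cols[0]] > 0, "risk",
                                    "protective")
    unmatched = set(results["metabolite_id"]) - set(mr["metabolite_id"])
    if unmatched:
        logger.info("%d scored metabolites have no MR record", len(unmatched))
    out = results.merge(keep[["metabolite_id", "fdr", "mr_direction"]]
                        .rename(columns={"fdr": "mr_fdr"}),
                        on="metabolite_id", how="inner")
    return out.reset_index(drop=True)
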