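"""Curation of raw metabolite-sensor activity tables.

A raw table holds one binding or functional activity measurement per row
(Kd, Ki, IC50, EC50, AC50 or potency, with a molar unit). The QC chain
standardizes all values to nM, collapses exact duplicates, drops rows
flagged as pan-assay interference (PAINS) compounds, applies the 1 mM
bioactivity cutoff, removes within-pair outliers whenever a pair's max/min
ratio exceeds 10, and aggregates each (metabolite, sensor) pair to a single
interaction strength A in [0, 1].

The strength is an affine map of pActivity (-log10 molar activity) anchored
at the 1 mM cutoff (A = 0) and 1 pM (A = 1), so values are comparable
across knowledgebases rather than min-max scaled per dataset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ASSAY_TYPES",
    "UNIT_TO_NM",
    "ActivityAggregator",
    "standardize_and_clean",
    "filter_pair_outliers",
    "aggregate_pair_activity",
]

ASSAY_TYPES = frozenset({"kd", "ki", "ic50", "ec50", "ac50", "potency"})

#: molar-unit multipliers to nM (micro sign and 'u' both accepted)
UNIT_TO_NM = {"nm": 1.0, "um": 1e3, "µm": 1e3, "μm": 1e3,
              "mm": 1e6, "m": 1e9}

_RAW_COLUMNS = ["metabolite_id", "sensor_id", "assay_type", "value", "unit"]


def _require_columns(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"activity table is missing columns: {missing}")


def standardize_and_clean(records: pd.DataFrame,
                          cutoff_nm: float = 1e6) -> pd.DataFrame:
    """Standardize units to nM and apply the row-level QC rules.

    Rows flagged as PAINS are dropped, rows at or above ``cutoff_nm``
    (default 1 mM) are dropped, and exact duplicates (same pair, assay type
    and value) are collapsed to one. Unknown units or non-positive values
    raise with the offending rows identified.
    """
    out, _ = _clean_with_report(records, cutoff_nm)
    return out


def _clean_with_report(records: pd.DataFrame, cutoff_nm: float):
    _require_columns(records, _RAW_COLUMNS)
    df = records.reset_index(drop=True).copy()

    value = pd.to_numeric(df["value"], errors="coerce")
    bad = df.index[~(value > 0)].tolist()
    if bad:
        raise ValueError(f"non-positive or unparsable activity values at rows {bad}")

    unit = df["unit"].astype(str).str.strip().str.lower()
    unknown = df.index[~unit.isin(UNIT_TO_NM)].tolist()
    if unknown:
        offenders = df.loc[unknown, ["metabolite_id", "sensor_id", "unit"]]
        raise ValueError(
            f"unknown unit strings at rows {unknown}:\n{offenders.to_string()}"
        )

    assay = df["assay_type"].astype(str).str.strip().str.lower()
    bad_assay = df.index[~assay.isin(ASSAY_TYPES)].tolist()
    if bad_assay:
        raise ValueError(f"unknown assay types at rows {bad_assay}")

    df["assay_type"] = assay
    df["value_nm"] = value.to_numpy(dtype=float) * unit.map(UNIT_TO_NM).to_numpy()
    if "pains_flag" not in df.columns:
        df["pains_flag"] = False
    df["pains_flag"] = df["pains_flag"].fillna(False).astype(bool)

    reason = pd.Series("kept", index=df.index, dtype=object)
    reason[df["pains_flag"]] = "pains"
    ok = reason.eq("kept")
    reason[ok & (df["value_nm"] >= cutoff_nm)] = "activity_cutoff"
    ok = reason.eq("kept")
    dup = df.duplicated(subset=["metabolite_id", "sensor_id", "assay_type", "value_nm"])
    reason[ok & dup] = "duplicate"

    kept = df[reason.eq("kept")].drop(columns=["pains_flag"])
    return kept.reset_index(drop=True), reason


def filter_pair_outliers(records: pd.DataFrame,
                         max_ratio: float = 10.0) -> pd.DataFrame:
    """Drop within-pair outlier measurements.

    For each (metabolite, sensor) pair whose max/min value ratio exceeds
    ``max_ratio``, measurements larger than ``max_ratio`` times the pair
    minimum are removed; pairs within the ratio are untouched. Values must
    already be standardized to nM (``value_nm`` column).
    """
    out, _ = _outliers_with_report(records, max_ratio)
    return out


def _outliers_with_report(records: pd.DataFrame, max_ratio: float):
    _require_columns(records, ["metabolite_id", "sensor_id", "value_nm"])
    df = records.reset_index(drop=True)
    grp = df.groupby(["metabolite_id", "sensor_id"])["value_nm"]
    lo = grp.transform("min")
    hi = grp.transform("max")
    drop = (hi / lo > max_ratio) & (df["value_nm"] > max_ratio * lo)
    reason = pd.Series("kept", index=df.index, dtype=object)
    reason[drop] = "pair_outlier"
    return df[~drop].reset_index(drop=True), reason


def aggregate_pair_activity(records: pd.DataFrame) -> pd.DataFrame:
    """Aggregate cleaned measurements to one interaction strength per pair.

    ``activity_nM`` is the geometric mean of the pair's values (binding
    affinities are log-distributed), ``p_activity`` is -log10 of the molar
    activity, and ``A = clip((p_activity - 3) / 9, 0, 1)`` maps 1 mM to 0
    and 1 pM to 1. Empty input yields an empty table.
    """
    _require_columns(records, ["metabolite_id", "sensor_id", "value_nm"])
    if len(records) == 0:
        return pd.DataFrame(columns=["metabolite_id", "sensor_id", "n_records",
                                     "activity_nM", "p_activity", "A"])
    agg = (
        records.assign(_log=np.log(records["value_nm"].to_numpy(dtype=float)))
        .groupby(["metabolite_id", "sensor_id"], as_index=False)
        .agg(n_records=("_log", "size"), _mean_log=("_log", "mean"))
    )
    agg["activity_nM"] = np.exp(agg["_mean_log"])
    agg["p_activity"] = 9.0 - np.log10(agg["activity_nM"])
    agg["A"] = np.clip((agg["p_activity"] - 3.0) / 9.0, 0.0, 1.0)
    agg = agg.drop(columns="_mean_log")
    return agg.sort_values(["metabolite_id", "sensor_id"]).reset_index(drop=True)


class ActivityAggregator(BaseEstimator, TransformerMixin):
    """Full QC chain from raw activity records to per-pair strengths.

    Parameters
    ----------
    cutoff_nm : float
        Bioactivity cutoff; rows at or above it are dropped (default 1e6 nM,
        i.e. 1 mM).
    max_ratio : float
        Within-pair max/min ratio above which high outliers are removed.

    Attributes
    ----------
    pairs_ : pd.DataFrame
        Aggregated table (metabolite_id, sensor_id, n_records, activity_nM,
        p_activity, A).
    fate_ : pd.Series
        Per input row: 'kept', 'pains', 'activity_cutoff', 'duplicate' or
        'pair_outlier'.
    attrition_ : dict
        Row counts per fate.
    """

    def __init__(self, cutoff_nm: float = 1e6, max_ratio: float = 10.0):
        self.cutoff_nm = cutoff_nm
        self.max_ratio = max_ratio

    def fit(self, X: pd.DataFrame, y=None):
        cleaned, reason1 = _clean_with_report(X, self.cutoff_nm)
        filtered, reason2 = _outliers_with_report(cleaned, self.max_ratio)
        # map the outlier fate back onto the original row index
        fate = reason1.copy()
        kept_idx = fate.index[fate.eq("kept")]
        fate.loc[kept_idx] = reason2.to_numpy()
        self.records_ = filtered
        self.fate_ = fate
        self.attrition_ = fate.value_counts().to_dict()
        self.pairs_ = aggregate_pair_activity(filtered)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self.fit(X)
        return self.pairs_
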