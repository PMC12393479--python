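"""Synthetic single-cell data with planted metabolite-sensor programs.

Counts follow a negative-binomial (gamma-Poisson) model: gene-level
baseline means drawn log-normally around a global baseline, per-cell
log-normal library-size factors, and multiplicative fold changes planted
on chosen (sensor, cell type, group) tuples. The companion activity-table
generator emits raw measurement records whose aggregated interaction
strengths are log-uniform, plus configurable QC violations (exact
duplicates, PAINS-flagged rows, over-cutoff rows, within-pair outliers) in
exact numbers so the curation chain can be tested against hand counts.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "PlantedEffect",
    "GroundTruth",
    "simulate_expression",
    "simulate_activity",
    "evaluate_recovery",
]


@dataclass(frozen=True)
class PlantedEffect:
    """Multiplicative expression change for one (sensor, cell type, group)."""
    sensor: str
    cell_type: str
    group: str
    fold_change: float

    def __post_init__(self):
        if not self.fold_change > 0:
            raise ValueError("fold change must be positive")


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults: negative-binomial baseline mean 2 with dispersion 0.5 and
    log-normal library-size factors of sd 0.3, matching sparse UMI data;
    gene baselines are drawn log-normally (sd 0.5 in log space) around the
    baseline mean so expression filters act on a non-degenerate
    distribution. ``celltype_signature_sd`` optionally gives every gene a
    cell-type expression signature (log-normal) shared by both groups, for
    studies that need baseline cell-type structure; the default of 0 keeps
    the minimal exchangeable model, the correct null for label-permutation
    calibration.
    """
    seed: int
    n_cell_types: int = 4
    n_cells_per_type: int = 100
    n_genes: int = 200
    n_sensor_genes: int = 20
    groups: tuple[str, ...] = ("AD", "nonAD")
    baseline_mean: float = 2.0
    dispersion: float = 0.5
    library_sd: float = 0.3
    gene_mean_log_sd: float = 0.5
    celltype_signature_sd: float = 0.0
    planted_effects: list[PlantedEffect] = field(default_factory=list)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_cell_types < 2:
            raise ValueError("at least 2 cell types are required")
        if len(self.groups) < 1:
            raise ValueError("at least 1 group is required")
        if self.n_sensor_genes > self.n_genes:
            raise ValueError("n_sensor_genes cannot exceed n_genes")

    @property
    def cell_types(self) -> list[str]:
        return [f"CT{i + 1}" for i in range(self.n_cell_types)]

    @property
    def sensor_genes(self) -> list[str]:
        return [f"SENS{i + 1:03d}" for i in range(self.n_sensor_genes)]

    @property
    def gene_names(self) -> list[str]:
        background = [f"GENE{i + 1:04d}"
                      for i in range(self.n_genes - self.n_sensor_genes)]
        return self.sensor_genes + background


@dataclass
class GroundTruth:
    """Planted tuples for power/FDR evaluation."""
    planted_pairs: pd.DataFrame  # metabolite_id, sensor_id, cell_type, group, fold_change
    planted_pathways: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["pathway", "cell_type", "group"]))

    def pair_tuples(self) -> set[tuple]:
        return set(map(tuple, self.planted_pairs[
            ["metabolite_id", "sensor_id", "cell_type"]].itertuples(index=False)))


def metabolite_for(sensor: str) -> str:
    """Canonical one-to-one metabolite id for a simulated sensor."""
    return sensor.replace("SENS", "MET")


def baseline_means(config: SimConfig) -> pd.Series:
    """Gene-level baseline NB means the simulation will use (seed-determined)."""
    rng = np.random.default_rng(config.seed)
    base = np.exp(rng.normal(np.log(config.baseline_mean),
                             config.gene_mean_log_sd,
                             size=len(config.gene_names)))
    return pd.Series(base, index=config.gene_names)


def expected_means(config: SimConfig) -> pd.DataFrame:
    """Expected NB mean per (cell type, gene) before planted effects.

    Replicates the seed-determined baseline and cell-type-signature draws
    without sampling counts. Useful for planting effects on sensors that
    are expressed in the target cell type: a sensor whose mean falls in a
    stratum's bottom expression quartile is low-expression-masked by
    design and cannot be scored there, so power studies plant above it.
    """
    rng = np.random.default_rng(config.seed)
    base = np.exp(rng.normal(np.log(config.baseline_mean),
                             config.gene_mean_log_sd,
                             size=len(config.gene_names)))
    sig = np.exp(rng.normal(0.0, config.celltype_signature_sd,
                            size=(config.n_cell_types, len(config.gene_names))))
    return pd.DataFrame(base[None, :] * sig, index=config.cell_types,
                        columns=config.gene_names)


def choose_planted_tuples(config: SimConfig, n_planted: int,
                          min_stratum_quantile: float = 0.4) -> list[tuple[str, str]]:
    """Pick (sensor, cell type) tuples suitable for planting effects.

    A tuple is eligible when the sensor's expected mean in that cell type
    lies at or above ``min_stratum_quantile`` of the stratum's sensor-mean
    distribution (safely clear of the 25th-percentile low-expression
    mask). Among eligible cell types, the one where the sensor's own
    cross-type expression is mid-ranked is preferred, so the planted
    change is not confounded with an already-extreme signature. Fully
    determined by the config's seed.
    """
    em = expected_means(config)[config.sensor_genes]
    thr = em.quantile(min_stratum_quantile, axis=1)
    chosen: list[tuple[str, str]] = []
    for g in config.sensor_genes:
        col = em[g]
        eligible = [k for k in config.cell_types if em.loc[k, g] >= thr[k]]
        if not eligible:
            continue
        ranks = col.rank()
        mid = (len(col) + 1) / 2
        best = min(abs(ranks[kk] - mid) for kk in eligible)
        tied = sorted(kk for kk in eligible if abs(ranks[kk] - mid) == best)
        k = tied[len(chosen) % len(tied)]  # spread ties across cell types
        chosen.append((g, k))
        if len(chosen) == n_planted:
            break
    if len(chosen) < n_planted:
        raise ValueError(f"only {len(chosen)} of {n_planted} requested planted "
                         "tuples are eligible; increase n_sensor_genes")
    return chosen


def simulate_expression(config: SimConfig):
    """Negative-binomial counts with planted programs.

    Returns ``(adata, truth)``: an AnnData of integer counts with obs
    columns cell_id/cell_type/group/donor, and the ground truth of planted
    (metabolite, sensor, cell type, group) tuples.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names
    gpos = {g: j for j, g in enumerate(genes)}
    for eff in config.planted_effects:
        if eff.sensor not in gpos:
            raise ValueError(f"planted sensor {eff.sensor!r} is not a simulated gene")
        if eff.cell_type not in config.cell_types:
            raise ValueError(f"unknown planted cell type {eff.cell_type!r}")
        if eff.group not in config.groups:
            raise ValueError(f"unknown planted group {eff.group!r}")

    base = np.exp(rng.normal(np.log(config.baseline_mean),
                             config.gene_mean_log_sd, size=len(genes)))
    sig = np.exp(rng.normal(0.0, config.celltype_signature_sd,
                            size=(config.n_cell_types, len(genes))))

    obs_rows, blocks = [], []
    r = 1.0 / config.dispersion  # gamma shape; var = mu + dispersion * mu^2
    for group in config.groups:
        for ci, ct in enumerate(config.cell_types):
            n = config.n_cells_per_type
            mu = np.tile(base * sig[ci], (n, 1))
            for eff in config.planted_effects:
                if eff.cell_type == ct and eff.group == group:
                    mu[:, gpos[eff.sensor]] *= eff.fold_change
            lib = np.exp(rng.normal(0.0, config.library_sd, size=n))
            mu *= lib[:, None]
            lam = rng.gamma(shape=r, scale=mu / r)
            counts = rng.poisson(lam)
            blocks.append(counts)
            for i in range(n):
                obs_rows.append({"cell_type": ct, "group": group,
                                 "donor": f"D{i % 4 + 1}"})

    X = np.vstack(blocks).astype(np.int64)
    obs = pd.DataFrame(obs_rows)
    obs.index = [f"cell{i + 1:05d}" for i in range(len(obs))]
    obs.insert(0, "cell_id", obs.index)
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes))

    planted = pd.DataFrame([
        {"metabolite_id": metabolite_for(e.sensor), "sensor_id": e.sensor,
         "cell_type": e.cell_type, "group": e.group,
         "fold_change": e.fold_change}
        for e in config.planted_effects],
        columns=["metabolite_id", "sensor_id", "cell_type", "group",
                 "fold_change"])
    return adata, GroundTruth(planted_pairs=planted)


def simulate_activity(config: SimConfig, truth: GroundTruth | None = None,
                      n_duplicate_rows: int = 0, n_pains_rows: int = 0,
                      n_over_cutoff_rows: int = 0, n_outlier_rows: int = 0,
                      p_activity_range: tuple[float, float] = (5.0, 9.0),
                      planted_min_A: float = 0.5,
                      records_per_pair: tuple[int, int] = (1, 3)) -> pd.DataFrame:
    """Raw activity records for the simulated sensors, with QC violations.

    Each sensor gets one metabolite partner; the pair's geometric-mean
    activity is drawn so that pActivity is uniform over
    ``p_activity_range`` (log-uniform strength), except that sensors
    carrying planted expression effects are guaranteed an aggregated
    strength of at least ``planted_min_A``. Per-pair records are jittered
    multiplicatively within a max/min ratio well under 10, so only the
    deliberately injected violation rows trigger QC rules; violation counts
    are exact.
    """
    rng = np.random.default_rng(config.seed + 10_007)
    assays = ["kd", "ki", "ic50", "ec50", "ac50", "potency"]
    planted_sensors = (set(truth.planted_pairs["sensor_id"])
                       if truth is not None else set())

    rows = []
    for sensor in config.sensor_genes:
        met = metabolite_for(sensor)
        lo, hi = p_activity_range
        if sensor in planted_sensors:
            lo = max(lo, 3.0 + 9.0 * planted_min_A)
        p_act = rng.uniform(lo, hi)
        target_nm = 10.0 ** (9.0 - p_act)
        k = int(rng.integers(records_per_pair[0], records_per_pair[1] + 1))
        jit = rng.uniform(-np.log(1.8), np.log(1.8), size=k)
        jit -= jit.mean()  # geometric mean hits the target exactly
        for v in target_nm * np.exp(jit):
            rows.append({"metabolite_id": met, "sensor_id": sensor,
                         "assay_type": assays[rng.integers(len(assays))],
                         "value": v, "unit": "nM",
                         "source": "synthetic", "pains_flag": False})
    base = pd.DataFrame(rows)

    extra = []
    for i in range(n_duplicate_rows):
        extra.append(base.iloc[int(rng.integers(len(base)))].to_dict())
    for i in range(n_pains_rows):
        extra.append({"metabolite_id": f"PAINS{i + 1:02d}",
                      "sensor_id": config.sensor_genes[0],
                      "assay_type": "ic50", "value": 100.0, "unit": "nM",
                      "source": "synthetic", "pains_flag": True})
    for i in range(n_over_cutoff_rows):
        extra.append({"metabolite_id": f"WEAK{i + 1:02d}",
                      "sensor_id": config.sensor_genes[0],
                      "assay_type": "kd", "value": 2.0, "unit": "mM",
                      "source": "synthetic", "pains_flag": False})
    # outlier rows: 50x the pair minimum (ratio > 10, still under 1 mM)
    pair_min = base.groupby(["metabolite_id", "sensor_id"])["value"].min()
    pair_keys = list(pair_min.index)
    for i in range(n_outlier_rows):
        met, sensor = pair_keys[i % len(pair_keys)]
        v = min(50.0 * pair_min[(met, sensor)], 9e5)
        extra.append({"metabolite_id": met, "sensor_id": sensor,
                      "assay_type": "potency", "value": v, "unit": "nM",
                      "source": "synthetic", "pains_flag": False})
    out = pd.concat([base, pd.DataFrame(extra)], ignore_index=True) \
        if extra else base
    return out


def evaluate_recovery(results: pd.DataFrame, truth: GroundTruth,
                      keys=("metabolite_id", "sensor_id", "cell_type"),
                      call_col: str = "differential") -> dict:
    """Power and empirical FDR of differential calls against the truth.

    ``results`` must cover a universe including every planted tuple (the
    grid the caller scored); power is the fraction of planted tuples
    called, FDR the fraction of calls that are not planted (NaN when there
    are no calls), with a per-fold-change power breakdown.
    """
    keys = list(keys)
    universe = set(map(tuple, results[keys].itertuples(index=False)))
    planted = set(map(tuple, truth.planted_pairs[keys].itertuples(index=False)))
    if planted and not (planted & universe):
        raise ValueError("results and ground truth cover disjoint universes")
    called = set(map(tuple, results.loc[results[call_col].fillna(False),
                                        keys].itertuples(index=False)))
    power = len(called & planted) / len(planted) if planted else float("nan")
    fdr = (len(called - planted) / len(called)) if called else float("nan")
    by_fc = {}
    if "fold_change" in truth.planted_pairs.columns:
        for fc, sub in truth.planted_pairs.groupby("fold_change"):
            tuples = set(map(tuple, sub[keys].itertuples(index=False)))
            by_fc[float(fc)] = len(called & tuples) / len(tuples)
    return {"power": power, "fdr": fdr, "n_planted": len(planted),
            "n_called": len(called), "power_by_fold_change": by_fc}
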