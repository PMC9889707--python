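"""Single-cell cytotoxicity attribution: which phenotypes kill?

Product-level killing (% cytotoxicity at the 1.25:1 E:T point) is broadcast
onto every single CAR-T cell event of that product; pooled events (per
health-status stratum, CD8 compartment by default) are k-means clustered for
a sweep of k, and for each k a random-forest regression predicts the
cluster-mean cytotoxicity from the cluster-mean marker profile.  The k with
the highest out-of-sample explained variance is selected; cluster-mean
cytotoxicities are then z-scored across clusters and thresholded at +/-1 SD
into high / moderate / low cytotoxic-potential classes.  Each product is
summarised by the share of its events landing in clusters of each class,
and each class by its mean marker expression (heatmap table).

Conventions (stated because the underlying procedure leaves them open):
events are z-scored per marker before clustering; clusters enter the
regression and the z-scoring unweighted (one observation each); explained
variance is leave-one-cluster-out R^2 for k < 10 and out-of-bag R^2
otherwise, since an in-sample forest R^2 is trivially near 1; argmax ties
break toward smaller k; a zero-SD cytotoxicity vector yields z = 0 for all
clusters (all moderate).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestRegressor

from .assay import ATTRIBUTION_ET_RATIO, CytotoxicityCurve
from .gating import GatingStrategy, SingleCellMatrix
from .panel import MarkerPanel


def geometric_k_grid(k_min: int = 2, k_max: int = 320, n_points: int = 25) -> tuple[int, ...]:
    """Roughly geometric subsample of [k_min, k_max] used as the default
    sweep grid (the exhaustive 2..320 sweep is available by override)."""
    raw = np.geomspace(k_min, k_max, n_points)
    grid = sorted({int(round(k)) for k in raw})
    return tuple(k for k in grid if k_min <= k <= k_max)


@dataclass(frozen=True)
class AttributionConfig:
    k_grid: tuple[int, ...] = field(default_factory=geometric_k_grid)
    et_ratio_used: float = ATTRIBUTION_ET_RATIO
    compartment: str = "CD8"  # {CD8, CD4, all}
    event_cap: int = 20_000
    n_estimators: int = 200
    max_depth: int | None = None
    seed: int = 0
    z_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be > 0")
        if any(k < 2 for k in self.k_grid):
            raise ValueError("k_grid entries must be >= 2")
        if self.compartment not in ("CD8", "CD4", "all"):
            raise ValueError("compartment must be CD8, CD4 or all")


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray  # k x markers, standardized space
    assignments: np.ndarray  # per-event cluster index
    cluster_cytotox: np.ndarray  # per-cluster mean assigned % cytotoxicity
    cluster_sizes: np.ndarray
    cluster_features: np.ndarray  # k x markers mean profile (standardized)

    def __post_init__(self) -> None:
        if int(self.cluster_sizes.sum()) != len(self.assignments):
            raise ValueError("cluster sizes must sum to the event count")


@dataclass
class AttributionResult:
    model: ClusterModel
    explained_variance: dict[int, float | None]
    selected_k: int
    cluster_z: np.ndarray
    cluster_class: list[str]
    product_fractions: pd.DataFrame  # index sample_id, columns high/moderate/low
    class_marker_means: pd.DataFrame  # index class, columns markers

    def to_dict(self) -> dict:
        return {
            "selected_k": int(self.selected_k),
            "explained_variance": {
                str(k): (None if v is None else float(v))
                for k, v in self.explained_variance.items()
            },
            "clusters": [
                {
                    "cluster": int(i),
                    "size": int(self.model.cluster_sizes[i]),
                    "mean_cytotoxicity": float(self.model.cluster_cytotox[i]),
                    "z": float(self.cluster_z[i]),
                    "class": self.cluster_class[i],
                }
                for i in range(self.model.k)
            ],
            "product_fractions": {
                str(sid): {c: float(v) for c, v in row.items()}
                for sid, row in self.product_fractions.iterrows()
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def compartment_mask(
    cells: SingleCellMatrix, strategy: GatingStrategy, compartment: str
) -> np.ndarray:
    """Viable CD3+ CAR+ events of the requested compartment."""
    df = cells.data
    base = strategy.viable(df) & strategy.positive(df, "CD3") & strategy.positive(df, "CAR")
    if compartment == "CD8":
        return base & strategy.positive(df, "CD8")
    if compartment == "CD4":
        return base & strategy.positive(df, "CD4") & ~strategy.positive(df, "CD8")
    return base


def assign_cell_cytotoxicity(
    samples: list[SingleCellMatrix],
    product_cytotox: dict[str, float],
    strategy: GatingStrategy | None = None,
    compartment: str = "CD8",
) -> pd.DataFrame:
    """Pool events across products, tagging each event with its product's
    % cytotoxicity.  Returns a frame of marker columns + sample_id + cytotox.

    Healthy and patient products are pooled by the caller separately; this
    function just broadcasts and optionally restricts the compartment.
    """
    strategy = strategy or GatingStrategy()
    frames = []
    for mat in samples:
        if mat.sample_id not in product_cytotox:
            raise KeyError(f"no cytotoxicity value for product {mat.sample_id!r}")
        df = mat.data
        if compartment != "none":
            df = df[compartment_mask(mat, strategy, compartment)]
        if df.empty:
            continue
        df = df.copy()
        df["sample_id"] = mat.sample_id
        df["cytotoxicity"] = float(product_cytotox[mat.sample_id])
        frames.append(df)
    if not frames:
        raise ValueError("no events left after compartment filtering")
    return pd.concat(frames, ignore_index=True)


def standardize_events(pool: pd.DataFrame, markers: list[str]) -> pd.DataFrame:
    """Per-marker z-score of the pooled events (k-means is scale-sensitive)."""
    out = pool.copy()
    for m in markers:
        values = pool[m].to_numpy(dtype=float)
        sd = values.std(ddof=0)
        out[m] = (values - values.mean()) / sd if sd > 0 else 0.0
    return out


def _fit_cluster_model(
    x: np.ndarray, cytotox: np.ndarray, k: int, seed: int
) -> ClusterModel:
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    assign = km.fit_predict(x)
    sizes = np.bincount(assign, minlength=k)
    means = np.zeros(k)
    feats = np.zeros((k, x.shape[1]))
    for i in range(k):
        mask = assign == i
        if mask.any():
            means[i] = cytotox[mask].mean()
            feats[i] = x[mask].mean(axis=0)
        else:  # empty cluster: keep its centroid, flag with nan mean
            means[i] = np.nan
            feats[i] = km.cluster_centers_[i]
    return ClusterModel(
        k=k,
        centroids=km.cluster_centers_,
        assignments=assign,
        cluster_cytotox=means,
        cluster_sizes=sizes,
        cluster_features=feats,
    )


def kmeans_sweep(
    pool: pd.DataFrame,
    markers: list[str],
    config: AttributionConfig,
) -> list[ClusterModel]:
    """Fit one seeded k-means model per k in the grid.

    Events beyond ``event_cap`` are subsampled once (seeded) before the
    sweep; grid values >= the event count are skipped.
    """
    rng = np.random.default_rng(config.seed)
    if len(pool) > config.event_cap:
        idx = rng.choice(len(pool), size=config.event_cap, replace=False)
        pool = pool.iloc[np.sort(idx)].reset_index(drop=True)
    x = pool[markers].to_numpy(dtype=float)
    cytotox = pool["cytotoxicity"].to_numpy(dtype=float)
    models = []
    for k in config.k_grid:
        if k >= len(pool):
            continue
        models.append(_fit_cluster_model(x, cytotox, k, config.seed))
    if not models:
        raise ValueError("k_grid has no value below the event count")
    # stash the (possibly subsampled) pool for product-fraction bookkeeping
    models[0].pool_ = pool  # type: ignore[attr-defined]
    for m in models:
        m.pool_ = pool  # type: ignore[attr-defined]
    return models


def cluster_explained_variance(
    model: ClusterModel, config: AttributionConfig
) -> float | None:
    """Out-of-sample explained variance of cluster-mean cytotoxicity.

    Leave-one-cluster-out R^2 for k < 10 (too few rows for a stable OOB
    estimate), out-of-bag R^2 otherwise.  Returns None (flagged, excluded
    from the argmax) when the cytotoxicity target is effectively constant.
    """
    valid = ~np.isnan(model.cluster_cytotox)
    y = model.cluster_cytotox[valid]
    x = model.cluster_features[valid]
    if np.unique(np.round(y, 9)).size < 2:
        return None
    if len(y) < 10:
        preds = np.empty_like(y)
        for i in range(len(y)):
            mask = np.arange(len(y)) != i
            forest = RandomForestRegressor(
                n_estimators=config.n_estimators,
                max_depth=config.max_depth,
                random_state=config.seed,
            )
            forest.fit(x[mask], y[mask])
            preds[i] = forest.predict(x[i][None, :])[0]
        sse = float(((y - preds) ** 2).sum())
        sst = float(((y - y.mean()) ** 2).sum())
        return 1.0 - sse / sst
    forest = RandomForestRegressor(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        random_state=config.seed,
        oob_score=True,
        bootstrap=True,
    )
    forest.fit(x, y)
    return float(forest.oob_score_)


def argmax_k(trace: dict[int, float | None]) -> int:
    """k with the highest unflagged explained variance; ties -> smaller k."""
    best_k, best_ev = None, -np.inf
    for k in sorted(trace):
        ev = trace[k]
        if ev is not None and ev > best_ev:
            best_k, best_ev = k, ev
    if best_k is None:
        raise ValueError("all sweep results were flagged (constant cytotoxicity)")
    return best_k


def select_optimal_k(
    models: list[ClusterModel], config: AttributionConfig
) -> tuple[ClusterModel, dict[int, float | None]]:
    """Argmax of explained variance over the sweep; ties -> smaller k."""
    trace = {m.k: cluster_explained_variance(m, config) for m in models}
    best_k = argmax_k(trace)
    best = next(m for m in models if m.k == best_k)
    return best, trace


def classify_clusters(
    model: ClusterModel,
    pool: pd.DataFrame,
    markers: list[str],
    z_threshold: float = 1.0,
) -> tuple[np.ndarray, list[str], pd.DataFrame, pd.DataFrame]:
    """z-score cluster cytotoxicity, threshold into classes, and summarise.

    Returns (z, classes, per-product class fractions, per-class marker means).
    z-scores are computed across clusters unweighted with population SD;
    zero SD yields z = 0 (all clusters moderate).
    """
    if model.k < 2:
        raise ValueError("classification needs at least 2 clusters")
    valid = ~np.isnan(model.cluster_cytotox)
    values = model.cluster_cytotox[valid]
    sd = values.std(ddof=0)
    z = np.zeros(model.k)
    if sd > 0:
        z[valid] = (values - values.mean()) / sd
    classes = [
        "high" if zi >= z_threshold else ("low" if zi <= -z_threshold else "moderate")
        for zi in z
    ]
    event_class = pd.Categorical(
        [classes[c] for c in model.assignments],
        categories=["high", "moderate", "low"],
    )
    frac = (
        pd.crosstab(pool["sample_id"], event_class, normalize="index", dropna=False)
        .reindex(columns=["high", "moderate", "low"], fill_value=0.0)
    )
    frac.columns.name = None
    marker_means = (
        pool[markers]
        .groupby(event_class, observed=False)
        .mean()
        .reindex(["high", "moderate", "low"])
    )
    marker_means.index.name = "class"
    return z, classes, frac, marker_means


def attribute(
    samples: list[SingleCellMatrix],
    curves: dict[str, CytotoxicityCurve],
    config: AttributionConfig | None = None,
    strategy: GatingStrategy | None = None,
    panel: MarkerPanel | None = None,
) -> AttributionResult:
    """End-to-end attribution for one pool of products (one stratum)."""
    config = config or AttributionConfig()
    strategy = strategy or GatingStrategy()
    panel = panel or MarkerPanel()
    markers = list(panel)
    cytotox = {
        sid: curve.at(config.et_ratio_used) for sid, curve in curves.items()
    }
    pool = assign_cell_cytotoxicity(samples, cytotox, strategy, config.compartment)
    pool = standardize_events(pool, markers)
    models = kmeans_sweep(pool, markers, config)
    pool_used = models[0].pool_  # type: ignore[attr-defined]
    best, trace = select_optimal_k(models, config)
    z, classes, fractions, heatmap = classify_clusters(
        best, pool_used, markers, config.z_threshold
    )
    return AttributionResult(
        model=best,
        explained_variance=trace,
        selected_k=best.k,
        cluster_z=z,
        cluster_class=classes,
        product_fractions=fractions,
        class_marker_means=heatmap,
    )


def attribute_stratum(cohort, stratum: str, config: AttributionConfig | None = None) -> AttributionResult:
    """Run attribution on one health-status stratum of a generated cohort
    (APC-ms products only), deriving killing curves from its assay readings."""
    from .assay import curves_from_frame

    meta = cohort.manifest
    keep = set(
        meta[
            (meta["status"] == stratum)
            & (meta["stage"] == "product")
            & (meta["stim_type"] == "APC-ms")
        ]["sample_id"]
    )
    samples = [m for sid, m in cohort.samples.items() if sid in keep]
    curves = {
        sid: c for sid, c in curves_from_frame(cohort.readings).items() if sid in keep
    }
    return attribute(samples, curves, config, panel=cohort.config.marker_panel)
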