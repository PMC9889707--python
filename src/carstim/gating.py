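"""Threshold gating of single-cell matrices into subpopulation features.

Event matrices are reduced to the per-sample gated frequencies used by every
downstream model: viable -> CD3+ -> {CD4+, CD8+} -> per-parent memory
(CD45RA x CCR7) and exhaustion (PD1 x TIM3) quadrants plus CD25/CD137/CD95
positivity, the CD4:CD8 ratio and the CAR+ fraction.  Frequencies are
expressed as percent of the parent gate, so sibling quadrants partition the
parent and sum to 100.

Gating is plain scalar thresholding per marker (one threshold, fixed
direction).  Real instruments set gates against fluorescence-minus-one
controls; those do not exist for simulated data, so thresholds are explicit,
serialisable numbers placed between the negative and positive staining modes.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import DEFAULT_MARKERS, MarkerPanel

MEM_QUADS: tuple[str, ...] = (
    "CD45RA+CCR7+",
    "CD45RA+CCR7-",
    "CD45RA-CCR7+",
    "CD45RA-CCR7-",
)
EXH_QUADS: tuple[str, ...] = ("PD1+TIM3+", "PD1+TIM3-", "PD1-TIM3+", "PD1-TIM3-")
SINGLE_GATES: tuple[str, ...] = ("CD25+", "CD137+", "CD95+")

#: Metadata columns carried alongside features in a FeatureTable.
METADATA_COLUMNS: tuple[str, ...] = (
    "sample_id",
    "donor_id",
    "status",
    "stage",
    "stim_type",
    "dose_mol_pct",
    "dose_pg_per_cell",
)


def feature_names() -> list[str]:
    """Canonical ordered feature-column names of a FeatureTable."""
    names = ["pct_CD3", "pct_CD4", "pct_CD8", "pct_CAR", "ratio_CD4_CD8"]
    for parent in ("CD4", "CD8"):
        for quad in MEM_QUADS + EXH_QUADS:
            names.append(f"pct_{parent}_{quad}")
        for single in SINGLE_GATES:
            names.append(f"pct_{parent}_{single}")
    return names


FEATURE_NAMES: tuple[str, ...] = tuple(feature_names())


@dataclass
class SingleCellMatrix:
    """Events x markers intensity table for one sample.

    ``labels`` optionally carries per-event ground-truth annotations
    (simulation only; never consumed by the analysis path).
    """

    sample_id: str
    data: pd.DataFrame
    labels: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.data) < 1:
            raise ValueError("single-cell matrix needs at least one event")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("negative intensities are not allowed")

    @property
    def n_events(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class GatingStrategy:
    """Per-marker scalar thresholds over a hierarchy of parent gates.

    All gates are "intensity > threshold" except viability, where positive
    staining marks dead cells, so the viable gate is "intensity < threshold".
    """

    thresholds: dict[str, float] = field(
        default_factory=lambda: {m: 10.0**2.6 for m in DEFAULT_MARKERS}
    )
    viability_marker: str = "Viability"

    def __post_init__(self) -> None:
        for marker, value in self.thresholds.items():
            if not math.isfinite(value):
                raise ValueError(f"threshold for {marker} must be finite")

    def positive(self, cells: pd.DataFrame, marker: str) -> np.ndarray:
        if marker not in cells.columns:
            raise KeyError(f"marker {marker!r} absent from event matrix")
        if marker not in self.thresholds:
            raise KeyError(f"no threshold configured for marker {marker!r}")
        return cells[marker].to_numpy() > self.thresholds[marker]

    def viable(self, cells: pd.DataFrame) -> np.ndarray:
        marker = self.viability_marker
        if marker not in cells.columns:
            raise KeyError(f"marker {marker!r} absent from event matrix")
        return cells[marker].to_numpy() < self.thresholds[marker]

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema": "carstim.gating/1",
                "viability_marker": self.viability_marker,
                "thresholds": dict(sorted(self.thresholds.items())),
            },
            sort_keys=True,
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GatingStrategy":
        payload = json.loads(text)
        return cls(
            thresholds={k: float(v) for k, v in payload["thresholds"].items()},
            viability_marker=payload.get("viability_marker", "Viability"),
        )


def _pct(count: int, parent: int) -> float:
    return 100.0 * count / parent if parent > 0 else 0.0


def apply_gating(cells: SingleCellMatrix, strategy: GatingStrategy) -> pd.Series:
    """Gate one sample into a feature vector (one FeatureTable row).

    Each frequency is 100 x (events in gate) / (events in parent gate).  An
    empty parent yields frequency 0 and the parent's name is recorded in the
    result's ``attrs["empty_parents"]`` so downstream tables stay rectangular.
    """
    df = cells.data
    empty_parents: list[str] = []
    viable = strategy.viable(df)
    if not viable.any():
        empty_parents.append("viable")
    cd3 = viable & strategy.positive(df, "CD3")
    if not cd3.any():
        empty_parents.append("CD3")
    cd4 = cd3 & strategy.positive(df, "CD4")
    cd8 = cd3 & strategy.positive(df, "CD8")

    out: dict[str, float] = {
        "pct_CD3": _pct(int(cd3.sum()), int(viable.sum())),
        "pct_CD4": _pct(int(cd4.sum()), int(cd3.sum())),
        "pct_CD8": _pct(int(cd8.sum()), int(cd3.sum())),
        "pct_CAR": _pct(int((cd3 & strategy.positive(df, "CAR")).sum()), int(cd3.sum())),
    }
    if cd8.sum() > 0:
        out["ratio_CD4_CD8"] = float(cd4.sum()) / float(cd8.sum())
    else:
        out["ratio_CD4_CD8"] = 0.0
        empty_parents.append("CD8(ratio)")

    for parent_name, parent in (("CD4", cd4), ("CD8", cd8)):
        n_parent = int(parent.sum())
        if n_parent == 0:
            empty_parents.append(parent_name)
        ra = strategy.positive(df, "CD45RA")
        ccr7 = strategy.positive(df, "CCR7")
        pd1 = strategy.positive(df, "PD1")
        tim3 = strategy.positive(df, "TIM3")
        quads = {
            "CD45RA+CCR7+": parent & ra & ccr7,
            "CD45RA+CCR7-": parent & ra & ~ccr7,
            "CD45RA-CCR7+": parent & ~ra & ccr7,
            "CD45RA-CCR7-": parent & ~ra & ~ccr7,
            "PD1+TIM3+": parent & pd1 & tim3,
            "PD1+TIM3-": parent & pd1 & ~tim3,
            "PD1-TIM3+": parent & ~pd1 & tim3,
            "PD1-TIM3-": parent & ~pd1 & ~tim3,
        }
        for quad, mask in quads.items():
            out[f"pct_{parent_name}_{quad}"] = _pct(int(mask.sum()), n_parent)
        for single in SINGLE_GATES:
            mask = parent & strategy.positive(df, single[:-1])
            out[f"pct_{parent_name}_{single}"] = _pct(int(mask.sum()), n_parent)

    series = pd.Series(out, name=cells.sample_id).reindex(list(FEATURE_NAMES))
    series.attrs["empty_parents"] = empty_parents
    return series


def gate_table(
    samples: list[SingleCellMatrix],
    strategy: GatingStrategy,
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Gate many samples into a FeatureTable (rows = samples).

    ``metadata`` (indexed or keyed by sample_id) contributes the donor/
    status/stage/dose columns; missing metadata leaves those columns out.
    """
    rows = []
    for sample in samples:
        vec = apply_gating(sample, strategy)
        row = {"sample_id": sample.sample_id, **vec.to_dict()}
        row["empty_parents"] = ";".join(vec.attrs["empty_parents"])
        rows.append(row)
    table = pd.DataFrame(rows)
    if metadata is not None:
        meta = metadata.reset_index() if metadata.index.name == "sample_id" else metadata
        table = meta.merge(table, on="sample_id", how="right")
    ordered = [c for c in METADATA_COLUMNS if c in table.columns]
    ordered += [c for c in table.columns if c not in ordered]
    return table[ordered]


def is_feature_column(name: str) -> bool:
    return name.startswith("pct_") or name.startswith("ratio_")


def zscore_features(table: pd.DataFrame) -> pd.DataFrame:
    """Standardise each feature column to mean 0, SD 1 (population, ddof=0).

    Metadata columns are untouched.  Zero-variance columns are dropped with a
    warning; the removed names are listed in ``attrs["dropped_features"]``
    and the fitted means/SDs in ``attrs["feature_means"]/["feature_sds"]``.
    """
    if len(table) < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    out = table.copy()
    dropped: list[str] = []
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for col in table.columns:
        if not is_feature_column(col):
            continue
        values = table[col].to_numpy(dtype=float)
        sd = float(values.std(ddof=0))
        if sd == 0.0:
            dropped.append(col)
            out = out.drop(columns=[col])
            continue
        mean = float(values.mean())
        means[col] = mean
        sds[col] = sd
        out[col] = (values - mean) / sd
    if dropped:
        warnings.warn(f"dropped zero-variance features: {dropped}")
    out.attrs["dropped_features"] = dropped
    out.attrs["feature_means"] = means
    out.attrs["feature_sds"] = sds
    out.attrs["zscore_convention"] = "population (ddof=0)"
    return out


def fold_expansion(live_count: float, seeded_count: float) -> float:
    """Fold expansion of a culture: live cells divided by seeded cells."""
    if seeded_count <= 0:
        raise ValueError("seeded_count must be > 0")
    return float(live_count) / float(seeded_count)


def split_train_test(
    table: pd.DataFrame, train_fraction: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded shuffle split with ceil(train_fraction * n) training rows.

    The ceiling convention reproduces 70/30 partitions of 35/49 and 40/56.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(table)
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    n_train = math.ceil(train_fraction * n)
    order = np.random.default_rng(seed).permutation(n)
    train = table.iloc[order[:n_train]]
    test = table.iloc[order[n_train:]]
    return train, test
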