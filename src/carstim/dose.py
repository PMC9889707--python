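"""Stimulation-dose bookkeeping and patient-specific dose prediction.

Anti-CD3/anti-CD28 stimulation is delivered either by lipid-coated scaffolds
(APC-ms), where the dose knob is the mol% of biotinylated lipid in the
bilayer (0.02-0.3 mol%), or by Dynabeads at a bead:cell ratio.  Both are
measured downstream as pg of antibody presented per cell, which is the
continuous dose scale all regression models use.  A conversion table maps
mol% (and bead ratios) to pg/cell; by construction the default table pins
the Dynabead 3:1 condition to the same pg/cell as APC-ms at 0.1 mol%, the
dose-matched pair used for head-to-head comparisons.

The prediction model answers the manufacturing question: given the
phenotype of a patient's T-cell blood sample and the phenotype of the
desired CAR-T product, what stimulation dose (pg/cell) should be applied
during activation?  A random-forest regressor is trained on paired
(blood features, product features) -> dose rows and validated
leave-one-donor-out (LODO): all rows of one donor are held out together,
the model is fit on the remaining donors, and the held-out donor's doses
are predicted across their dose series; the per-donor score is the
coefficient of determination R^2 between predicted and actual pg/cell,
and the headline number is the unweighted mean over donors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import r2_score

APC_MS = "APC-ms"
DYNABEAD = "Dynabead"

#: Default APC-ms mol% levels spanning the studied stimulation range.
DEFAULT_DOSES_MOL_PCT: tuple[float, ...] = (0.02, 0.05, 0.1, 0.15, 0.2, 0.3)


class DoseOutOfRangeError(ValueError):
    """Raised when a queried dose falls outside the conversion-table range."""


@dataclass(frozen=True)
class DoseConversionTable:
    """Monotone mol% <-> pg/cell mapping with optional Dynabead entries.

    mol_pct and pg_per_cell must be strictly increasing and of equal length;
    interpolation between knots is piecewise linear, with no extrapolation.
    """

    mol_pct: tuple[float, ...]
    pg_per_cell: tuple[float, ...]
    dynabead_pg: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.mol_pct, dtype=float)
        p = np.asarray(self.pg_per_cell, dtype=float)
        if m.size != p.size or m.size < 2:
            raise ValueError("table needs >=2 (mol_pct, pg_per_cell) pairs")
        if np.any(np.diff(m) <= 0) or np.any(np.diff(p) <= 0):
            raise ValueError("mol_pct and pg_per_cell must be strictly increasing")

    def to_pg(self, mol_pct: float) -> float:
        m = np.asarray(self.mol_pct)
        if not (m[0] - 1e-12 <= mol_pct <= m[-1] + 1e-12):
            raise DoseOutOfRangeError(
                f"mol% {mol_pct} outside table range [{m[0]}, {m[-1]}]"
            )
        return float(np.interp(mol_pct, self.mol_pct, self.pg_per_cell))

    def to_mol_pct(self, pg: float) -> float:
        p = np.asarray(self.pg_per_cell)
        if not (p[0] - 1e-12 <= pg <= p[-1] + 1e-12):
            raise DoseOutOfRangeError(
                f"pg/cell {pg} outside table range [{p[0]}, {p[-1]}]"
            )
        return float(np.interp(pg, self.pg_per_cell, self.mol_pct))

    def bead_ratio_to_pg(self, ratio: float) -> float:
        if ratio not in self.dynabead_pg:
            raise DoseOutOfRangeError(f"no Dynabead entry for ratio {ratio}:1")
        return float(self.dynabead_pg[ratio])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"stim_type": APC_MS, "mol_pct_or_ratio": m, "pg_per_cell": p}
            for m, p in zip(self.mol_pct, self.pg_per_cell)
        ]
        rows += [
            {"stim_type": DYNABEAD, "mol_pct_or_ratio": r, "pg_per_cell": p}
            for r, p in sorted(self.dynabead_pg.items())
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DoseConversionTable":
        apc = frame[frame["stim_type"] == APC_MS].sort_values("mol_pct_or_ratio")
        dyn = frame[frame["stim_type"] == DYNABEAD]
        return cls(
            mol_pct=tuple(apc["mol_pct_or_ratio"].astype(float)),
            pg_per_cell=tuple(apc["pg_per_cell"].astype(float)),
            dynabead_pg={
                float(r): float(p)
                for r, p in zip(dyn["mol_pct_or_ratio"], dyn["pg_per_cell"])
            },
        )


def default_conversion_table() -> DoseConversionTable:
    """Synthetic conversion table: pg/cell proportional to mol% (100 pg per
    mol%), with Dynabead 3:1 pinned to the APC-ms 0.1 mol% value and 1:1/5:1
    scaled by bead number.  Real assay-measured tables are supplied by the
    user for real data."""
    mol = DEFAULT_DOSES_MOL_PCT
    scale = 100.0
    pg_a01 = 0.1 * scale
    return DoseConversionTable(
        mol_pct=mol,
        pg_per_cell=tuple(scale * m for m in mol),
        dynabead_pg={1.0: pg_a01 / 3.0, 3.0: pg_a01, 5.0: pg_a01 * 5.0 / 3.0},
    )


@dataclass(frozen=True)
class StimulationDose:
    """One stimulation condition: APC-ms at a mol% or Dynabeads at a ratio,
    plus its pg/cell equivalent under the active conversion table."""

    stim_type: str
    pg_per_cell: float
    mol_pct_biotin: float | None = None
    bead_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.stim_type not in (APC_MS, DYNABEAD):
            raise ValueError(f"unknown stim_type {self.stim_type!r}")
        if self.stim_type == APC_MS and (
            self.mol_pct_biotin is None or self.bead_ratio is not None
        ):
            raise ValueError("APC-ms dose must set mol_pct_biotin only")
        if self.stim_type == DYNABEAD and (
            self.bead_ratio is None or self.mol_pct_biotin is not None
        ):
            raise ValueError("Dynabead dose must set bead_ratio only")
        if self.pg_per_cell < 0:
            raise ValueError("pg_per_cell must be >= 0")

    @property
    def label(self) -> str:
        if self.stim_type == APC_MS:
            return f"A{self.mol_pct_biotin:g}"
        return f"D{self.bead_ratio:g}:1"

    @classmethod
    def apc_ms(cls, mol_pct: float, table: DoseConversionTable) -> "StimulationDose":
        return cls(APC_MS, table.to_pg(mol_pct), mol_pct_biotin=mol_pct)

    @classmethod
    def dynabead(cls, ratio: float, table: DoseConversionTable) -> "StimulationDose":
        return cls(DYNABEAD, table.bead_ratio_to_pg(ratio), bead_ratio=ratio)


def mol_pct_to_pg_per_cell(mol_pct: float, table: DoseConversionTable) -> float:
    """Monotone piecewise-linear interpolation of pg/cell at a mol% dose."""
    return table.to_pg(mol_pct)


# ---------------------------------------------------------------------------
# Dose regression


@dataclass
class DoseRegressorConfig:
    n_estimators: int = 400
    max_depth: int | None = 10
    min_samples_leaf: int = 2
    min_samples_split: int = 2
    seed: int = 0


@dataclass
class DonorPrediction:
    donor_id: str
    actual: list[float]
    predicted: list[float]
    r2: float


@dataclass
class DosePredictionReport:
    """Per-held-out-donor predicted-vs-actual doses and the cross-donor mean.

    ``mean_r2`` averages per-donor R^2 values unweighted; it is also echoed
    on the percent scale in ``mean_r2_pct`` because both conventions appear
    in reporting practice."""

    per_donor: list[DonorPrediction]
    excluded_donors: list[str]

    @property
    def mean_r2(self) -> float:
        return float(np.mean([d.r2 for d in self.per_donor]))

    @property
    def mean_r2_pct(self) -> float:
        return 100.0 * self.mean_r2

    def to_dict(self) -> dict:
        return {
            "per_donor": [
                {
                    "donor_id": d.donor_id,
                    "actual_pg_per_cell": list(map(float, d.actual)),
                    "predicted_pg_per_cell": list(map(float, d.predicted)),
                    "r2": float(d.r2),
                }
                for d in self.per_donor
            ],
            "excluded_donors": list(self.excluded_donors),
            "mean_r2": self.mean_r2,
            "mean_r2_pct": self.mean_r2_pct,
        }


def build_regression_rows(
    blood_features: pd.DataFrame,
    product_features: pd.DataFrame,
    feature_columns: list[str],
) -> pd.DataFrame:
    """Pair each product row with its donor's blood row.

    Returns one row per product with columns ``blood_<f>`` and ``prod_<f>``
    for every feature, plus ``donor_id`` and the ``dose_pg_per_cell`` target.
    """
    blood = blood_features.set_index("donor_id")
    rows = []
    for _, prod in product_features.iterrows():
        donor = prod["donor_id"]
        if donor not in blood.index:
            raise KeyError(f"no blood sample for donor {donor!r}")
        b = blood.loc[donor]
        row = {"donor_id": donor, "dose_pg_per_cell": float(prod["dose_pg_per_cell"])}
        for f in feature_columns:
            row[f"blood_{f}"] = float(b[f])
            row[f"prod_{f}"] = float(prod[f])
        rows.append(row)
    return pd.DataFrame(rows)


def _x_columns(rows: pd.DataFrame) -> list[str]:
    return [c for c in rows.columns if c.startswith(("blood_", "prod_"))]


def train_dose_regressor(
    rows: pd.DataFrame, config: DoseRegressorConfig | None = None
) -> RandomForestRegressor:
    """Fit the forest mapping (blood phenotype, product phenotype) -> pg/cell."""
    config = config or DoseRegressorConfig()
    y = rows["dose_pg_per_cell"].to_numpy(dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("need >=2 distinct dose values to fit a regressor")
    reg = RandomForestRegressor(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        min_samples_leaf=config.min_samples_leaf,
        min_samples_split=config.min_samples_split,
        random_state=config.seed,
    )
    reg.fit(rows[_x_columns(rows)].to_numpy(dtype=float), y)
    reg.feature_names_in_carstim_ = _x_columns(rows)
    return reg


def leave_one_donor_out(
    rows: pd.DataFrame, config: DoseRegressorConfig | None = None
) -> DosePredictionReport:
    """LODO validation of the dose regressor.

    Donor exclusivity is enforced: the held-out donor's rows never appear in
    the training set of their own fold.  Donors with fewer than two distinct
    dose levels are excluded with a warning (R^2 over a constant series is
    undefined).  Negative R^2 is reported as-is.
    """
    config = config or DoseRegressorConfig()
    donors = list(dict.fromkeys(rows["donor_id"]))
    if len(donors) < 3:
        raise ValueError("leave-one-donor-out needs at least 3 donors")
    xcols = _x_columns(rows)
    per_donor: list[DonorPrediction] = []
    excluded: list[str] = []
    for donor in donors:
        held = rows[rows["donor_id"] == donor]
        train = rows[rows["donor_id"] != donor]
        assert set(held["donor_id"]).isdisjoint(set(train["donor_id"]))
        y_held = held["dose_pg_per_cell"].to_numpy(dtype=float)
        if np.unique(y_held).size < 2:
            warnings.warn(
                f"donor {donor} has a single dose level; excluded from LODO"
            )
            excluded.append(donor)
            continue
        reg = train_dose_regressor(train, config)
        pred = reg.predict(held[xcols].to_numpy(dtype=float))
        per_donor.append(
            DonorPrediction(
                donor_id=donor,
                actual=[float(v) for v in y_held],
                predicted=[float(v) for v in pred],
                r2=float(r2_score(y_held, pred)),
            )
        )
    if not per_donor:
        raise ValueError("no donor had >=2 distinct dose levels")
    return DosePredictionReport(per_donor=per_donor, excluded_donors=excluded)


@dataclass
class DosePrediction:
    pg_per_cell: float
    mol_pct_biotin: float | None
    in_table_range: bool


def predict_dose(
    regressor: RandomForestRegressor,
    blood_features: pd.Series,
    desired_product_features: pd.Series,
    table: DoseConversionTable,
) -> DosePrediction:
    """Predict the pg/cell stimulation for a desired product phenotype.

    The mol% equivalent is reported via inverse table lookup when the
    prediction lies inside the table range; otherwise it is flagged and no
    mol% is emitted.
    """
    xcols = getattr(regressor, "feature_names_in_carstim_", None)
    if xcols is None:
        raise ValueError("regressor was not trained by train_dose_regressor")
    values = []
    for col in xcols:
        prefix, feat = col.split("_", 1)
        source = blood_features if prefix == "blood" else desired_product_features
        if feat not in source:
            raise KeyError(f"feature {feat!r} missing from {prefix} features")
        values.append(float(source[feat]))
    pg = float(regressor.predict(np.asarray(values)[None, :])[0])
    try:
        mol = table.to_mol_pct(pg)
        return DosePrediction(pg_per_cell=pg, mol_pct_biotin=mol, in_table_range=True)
    except DoseOutOfRangeError:
        return DosePrediction(pg_per_cell=pg, mol_pct_biotin=None, in_table_range=False)
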