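"""Synthetic cohort generator: donors, blood samples, CAR-T products,
cytotoxicity readings, and full ground truth.

The generator emulates the statistical structure of a two-stratum
(healthy vs leukaemia-patient) CAR-T manufacturing study:

* Patient blood T cells are CD8-biased and enriched for CD45RA+CCR7-
  effector cells relative to healthy donors, captured by donor-level latent
  logit offsets drawn from status-conditional Gaussians.
* Products shift with anti-CD3/anti-CD28 stimulation dose: PD1+TIM3+
  co-expression and CD25/CD137 activation rise monotonically with dose,
  CD45RA/CCR7 memory composition drifts, and the CD4:CD8 ratio increases.
* Every product cell carries a latent cytotoxic-potential class
  (high / moderate / low) with class-specific marker phenotypes.  The true
  high-cytotoxic fraction declines *linearly* in dose for healthy donors and
  piecewise (an extra decline term switching on past a donor-specific
  activation threshold) for patients, whose effector-biased T cells are more
  sensitive to overstimulation.
* Product-level killing curves follow from the class mix through a
  saturating effector model, and luminescence triplets are emitted so that
  the standard percent-cytotoxicity formula recovers the truth up to noise.

Randomness flows from one master seed; per-sample substreams are derived by
stable hashing of sample identifiers, so adding a donor leaves every other
sample bit-identical.  ``noise_sd`` is a single global noise scale: 0 makes
donor latents collapse to their status means, staining intensities sit
exactly on their modes, and assay readings become exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .dose import (
    APC_MS,
    DEFAULT_DOSES_MOL_PCT,
    DoseConversionTable,
    StimulationDose,
    default_conversion_table,
)
from .gating import EXH_QUADS, MEM_QUADS, METADATA_COLUMNS, SingleCellMatrix
from .panel import MarkerPanel, child_rng

HEALTHY = "healthy"
PATIENT = "patient"
CLASSES = ("high", "moderate", "low")

DEFAULT_ET_RATIOS: tuple[float, ...] = (20.0, 10.0, 5.0, 2.5, 1.25, 0.0)

# Two-mode log-normal staining model (log10 scale).
LOG10_NEG_MODE = 2.0
LOG10_POS_MODE = 3.2
LOG10_MODE_SD = 0.25

# Luminescence plate constants: live targets emit signal, so the target-only
# (0:1) control reads above the detergent max-lysis control.
LUM_TARGET_ONLY = 10_000.0
LUM_MAX_LYSIS = 500.0
PCT_NOISE_SD = 2.0  # sd of assay noise on the percent-cytotoxicity scale


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _excess(dose: float, threshold: float, width: float = 0.02) -> float:
    """Smooth positive part of (dose - threshold): width * softplus(x/width)."""
    x = (dose - threshold) / width
    return width * float(np.logaddexp(0.0, x))


@dataclass(frozen=True)
class StatusLatents:
    """Latent donor-distribution parameters for one health status."""

    cd8_bias_mean: float
    cd8_bias_sd: float
    effector_bias_mean: float
    effector_bias_sd: float
    threshold_mean: float
    threshold_sd: float
    random_effect_sd: float = 0.15


DEFAULT_STATUS_LATENTS: dict[str, StatusLatents] = {
    HEALTHY: StatusLatents(0.0, 0.35, 0.0, 0.40, 0.22, 0.03),
    PATIENT: StatusLatents(0.85, 0.35, 1.10, 0.40, 0.10, 0.02),
}


@dataclass(frozen=True)
class DonorProfile:
    donor_id: str
    status: str
    latent_cd8_bias: float
    latent_effector_bias: float
    latent_activation_threshold: float
    random_effect_sd: float

    def __post_init__(self) -> None:
        if self.status not in (HEALTHY, PATIENT):
            raise ValueError(f"unknown status {self.status!r}")
        if self.latent_activation_threshold <= 0:
            raise ValueError("latent_activation_threshold must be > 0")


@dataclass(frozen=True)
class GenerationConfig:
    n_healthy: int = 8
    n_patient: int = 8
    doses_mol_pct: tuple[float, ...] = DEFAULT_DOSES_MOL_PCT
    n_events_per_sample: int = 600
    marker_panel: MarkerPanel = field(default_factory=MarkerPanel)
    noise_sd: float = 1.0
    seed: int = 0
    dose_conversion: DoseConversionTable = field(
        default_factory=default_conversion_table
    )
    et_ratios: tuple[float, ...] = DEFAULT_ET_RATIOS
    status_latents: dict[str, StatusLatents] = field(
        default_factory=lambda: dict(DEFAULT_STATUS_LATENTS)
    )
    #: doses (mol%) skipped for particular donors, donor_id -> tuple of mol%.
    dose_dropout: dict[str, tuple[float, ...]] = field(default_factory=dict)
    #: additional Dynabead conditions, donor_id -> tuple of bead ratios.
    extra_dynabead: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_events_per_sample < 100:
            raise ValueError("n_events_per_sample must be >= 100")
        for d in self.doses_mol_pct:
            if not 0.0 < d < 1.0:
                raise ValueError(f"dose {d} mol% outside (0, 1)")
        if 0.0 not in self.et_ratios:
            raise ValueError("et_ratios must include the 0:1 control")


def generate_donor(
    status: str,
    rng: np.random.Generator | int,
    config: GenerationConfig | None = None,
    donor_id: str = "D00",
) -> DonorProfile:
    """Draw one donor from the status-conditional latent distributions.

    ``noise_sd`` in the config scales the latent SDs, so at noise 0 the
    profile equals the status-distribution means exactly.
    """
    config = config or GenerationConfig()
    if status not in config.status_latents:
        raise ValueError(
            f"unknown status {status!r}; expected one of {sorted(config.status_latents)}"
        )
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    lat = config.status_latents[status]
    scale = config.noise_sd
    threshold = lat.threshold_mean + scale * lat.threshold_sd * rng.standard_normal()
    return DonorProfile(
        donor_id=donor_id,
        status=status,
        latent_cd8_bias=lat.cd8_bias_mean
        + scale * lat.cd8_bias_sd * rng.standard_normal(),
        latent_effector_bias=lat.effector_bias_mean
        + scale * lat.effector_bias_sd * rng.standard_normal(),
        latent_activation_threshold=max(threshold, 0.02),
        random_effect_sd=lat.random_effect_sd,
    )


# ---------------------------------------------------------------------------
# Phenotype laws


@dataclass(frozen=True)
class CompartmentLaw:
    """Per-parent (CD4+ or CD8+) subpopulation probabilities."""

    mem: tuple[float, float, float, float]  # CD45RA/CCR7 quadrants
    exh: tuple[float, float, float, float]  # PD1/TIM3 quadrants
    p_cd25: float
    p_cd137: float
    p_cd95: float

    def mixed(self, others: list["CompartmentLaw"], weights: list[float]) -> "CompartmentLaw":
        laws = [self] + others
        w = np.asarray(weights, dtype=float)
        mem = np.sum([np.asarray(l.mem) * wi for l, wi in zip(laws, w)], axis=0)
        exh = np.sum([np.asarray(l.exh) * wi for l, wi in zip(laws, w)], axis=0)
        return CompartmentLaw(
            mem=tuple(mem),
            exh=tuple(exh),
            p_cd25=float(np.dot([l.p_cd25 for l in laws], w)),
            p_cd137=float(np.dot([l.p_cd137 for l in laws], w)),
            p_cd95=float(np.dot([l.p_cd95 for l in laws], w)),
        )


@dataclass(frozen=True)
class PhenotypeLaw:
    """Full event-level sampling law for one sample (one mixture component)."""

    p_viable: float
    p_cd3: float
    p_cd8: float  # among CD3+
    p_car: float  # among CD3+
    cd4: CompartmentLaw
    cd8: CompartmentLaw


def _normalize(w: np.ndarray) -> tuple[float, ...]:
    w = np.asarray(w, dtype=float)
    return tuple(w / w.sum())


def _tilt(probs, tilt, scale: float) -> tuple[float, ...]:
    return _normalize(np.asarray(probs) * np.exp(scale * np.asarray(tilt)))


def build_blood_law(
    donor: DonorProfile, rng: np.random.Generator, noise_sd: float = 1.0
) -> PhenotypeLaw:
    """Blood-sample law from donor latents plus per-sample random effects."""
    re_sd = donor.random_effect_sd * noise_sd

    def re() -> float:
        return float(re_sd * rng.standard_normal())

    patient = donor.status == PATIENT
    p_cd3 = float(_sigmoid(_logit(0.72) + re()))
    p_cd8 = float(_sigmoid(_logit(0.45) + donor.latent_cd8_bias + re()))

    cd8_mem = np.array([0.35, 0.20, 0.25, 0.20])
    cd8_mem[1] *= np.exp(donor.latent_effector_bias + re())
    cd4_mem = np.array([0.45, 0.10, 0.30, 0.15])
    cd4_mem[1] *= np.exp(0.5 * donor.latent_effector_bias + re())

    exh = np.array([0.02, 0.05, 0.06, 0.87])
    if patient:
        exh[:2] *= np.exp(0.3)  # minor PD-1 trend in patient blood

    cd95_cd4 = float(_sigmoid(_logit(0.30) + (0.85 if patient else 0.0) + re()))
    cd8_law = CompartmentLaw(
        mem=_normalize(cd8_mem),
        exh=_normalize(exh),
        p_cd25=0.08,
        p_cd137=0.03,
        p_cd95=0.45,
    )
    cd4_law = CompartmentLaw(
        mem=_normalize(cd4_mem),
        exh=_normalize(exh),
        p_cd25=0.10,
        p_cd137=0.03,
        p_cd95=cd95_cd4,
    )
    return PhenotypeLaw(
        p_viable=0.97, p_cd3=p_cd3, p_cd8=p_cd8, p_car=0.005, cd4=cd4_law, cd8=cd8_law
    )


# Class-conditional CD8 phenotypes: highly cytotoxic cells look effector-like
# and unexhausted; low-cytotoxicity cells look exhausted (PD1+TIM3+) and
# terminally differentiated.
_CLASS_CD8: dict[str, CompartmentLaw] = {
    "high": CompartmentLaw(
        mem=(0.18, 0.55, 0.12, 0.15),
        exh=(0.03, 0.05, 0.12, 0.80),
        p_cd25=0.25,
        p_cd137=0.20,
        p_cd95=0.55,
    ),
    "moderate": CompartmentLaw(
        mem=(0.30, 0.25, 0.25, 0.20),
        exh=(0.15, 0.15, 0.15, 0.55),
        p_cd25=0.40,
        p_cd137=0.30,
        p_cd95=0.50,
    ),
    "low": CompartmentLaw(
        mem=(0.08, 0.12, 0.20, 0.60),
        exh=(0.55, 0.18, 0.12, 0.15),
        p_cd25=0.55,
        p_cd137=0.45,
        p_cd95=0.45,
    ),
}
_CD4_BASE = CompartmentLaw(
    mem=(0.40, 0.12, 0.30, 0.18),
    exh=(0.10, 0.12, 0.10, 0.68),
    p_cd25=0.35,
    p_cd137=0.20,
    p_cd95=0.45,
)

# Dose tilts (per unit mol%): exhaustion quadrants drift toward PD1+TIM3+,
# memory drifts away from CD45RA+ states, activation markers rise.
_EXH_TILT = (3.0, 0.8, 0.8, -1.5)
_MEM_TILT = (-1.0, -0.5, 0.8, 0.7)
_ACT_SLOPE = 5.0


def true_class_fractions(donor: DonorProfile, dose_mol_pct: float) -> dict[str, float]:
    """Ground-truth high/moderate/low cytotoxic-cell fractions at a dose.

    Healthy: high fraction declines linearly, 0.55 - 1.2 * dose.  Patient:
    0.50 - 0.8 * dose minus an extra 1.2 * softplus-excess past the donor's
    activation threshold, i.e. an accelerating decline beyond the threshold.
    """
    d = float(dose_mol_pct)
    if donor.status == HEALTHY:
        h0, high = 0.55, 0.55 - 1.2 * d
    else:
        h0 = 0.50
        high = 0.50 - 0.8 * d - 1.2 * _excess(d, donor.latent_activation_threshold)
    high = float(np.clip(high, 0.02, 0.95))
    low = float(np.clip(0.08 + 0.7 * (h0 - high), 0.02, 0.90))
    moderate = 1.0 - high - low
    if moderate < 0.0:
        raise AssertionError("class fractions left no moderate mass")
    return {"high": high, "moderate": moderate, "low": low}


def _dose_adjust(law: CompartmentLaw, d: float, donor: DonorProfile) -> CompartmentLaw:
    mem = np.asarray(law.mem) * np.exp(d * np.asarray(_MEM_TILT))
    if donor.status == PATIENT:
        # naive/stem-memory and effector CD45RA+ states collapse past threshold
        loss = np.exp(-6.0 * _excess(d, donor.latent_activation_threshold))
        mem[0] *= loss
        mem[1] *= loss**0.5
    exh = np.asarray(law.exh) * np.exp(d * np.asarray(_EXH_TILT))
    if donor.status == PATIENT:
        # TIM-3-positive states run higher in patient-derived products
        exh[0] *= np.exp(0.35)
        exh[2] *= np.exp(0.35)

    def act(p: float) -> float:
        return float(_sigmoid(_logit(p) + _ACT_SLOPE * (d - 0.1)))

    return CompartmentLaw(
        mem=_normalize(mem),
        exh=_normalize(exh),
        p_cd25=act(law.p_cd25),
        p_cd137=act(law.p_cd137),
        p_cd95=law.p_cd95,
    )


@dataclass(frozen=True)
class ProductLaw:
    """Mixture-of-classes sampling law for one CAR-T product."""

    class_fractions: dict[str, float]
    class_laws: dict[str, PhenotypeLaw]

    @property
    def marginal(self) -> PhenotypeLaw:
        weights = [self.class_fractions[c] for c in CLASSES]
        laws = [self.class_laws[c] for c in CLASSES]
        cd8 = laws[0].cd8.mixed([l.cd8 for l in laws[1:]], weights)
        cd4 = laws[0].cd4.mixed([l.cd4 for l in laws[1:]], weights)
        first = laws[0]
        return PhenotypeLaw(
            p_viable=first.p_viable,
            p_cd3=first.p_cd3,
            p_cd8=first.p_cd8,
            p_car=first.p_car,
            cd4=cd4,
            cd8=cd8,
        )


def _donor_tilt(law: CompartmentLaw, donor: DonorProfile, strength: float) -> CompartmentLaw:
    """Donor-intrinsic memory skew carried from blood into the product: the
    effector bias keeps tilting CD45RA+ states after activation."""
    mem = np.asarray(law.mem).copy()
    mem[1] *= np.exp(strength * donor.latent_effector_bias)
    mem[0] *= np.exp(0.4 * strength * donor.latent_effector_bias)
    return CompartmentLaw(
        mem=_normalize(mem),
        exh=law.exh,
        p_cd25=law.p_cd25,
        p_cd137=law.p_cd137,
        p_cd95=law.p_cd95,
    )


def build_product_law(
    donor: DonorProfile,
    dose_mol_pct: float,
    rng: np.random.Generator,
    noise_sd: float = 1.0,
) -> ProductLaw:
    d = float(dose_mol_pct)
    re_sd = donor.random_effect_sd * noise_sd
    re = float(re_sd * rng.standard_normal())
    p_cd8_blood = float(_sigmoid(_logit(0.45) + donor.latent_cd8_bias))
    # CD4:CD8 ratio rises with dose -> CD8 fraction falls
    p_cd8 = float(_sigmoid(_logit(p_cd8_blood) - 2.5 * (d - 0.02) + re))
    p_car = float(
        _sigmoid(_logit(0.40) + (0.8 * d if donor.status == PATIENT else 0.0))
    )
    fractions = true_class_fractions(donor, d)
    class_laws = {}
    for cls in CLASSES:
        cd8_law = _dose_adjust(_donor_tilt(_CLASS_CD8[cls], donor, 0.8), d, donor)
        cd4_law = _dose_adjust(
            _donor_tilt(_CLASS_CD8[cls].mixed([_CD4_BASE], [0.5, 0.5]), donor, 0.4),
            d,
            donor,
        )
        class_laws[cls] = PhenotypeLaw(
            p_viable=0.95,
            p_cd3=0.97,
            p_cd8=p_cd8,
            p_car=p_car,
            cd4=cd4_law,
            cd8=cd8_law,
        )
    return ProductLaw(class_fractions=fractions, class_laws=class_laws)


def true_cytotoxicity(class_fractions: dict[str, float], et_ratio: float) -> float:
    """Saturating killing model: percent lysis at an E:T ratio from the
    per-cell potency of the class mix (high >> moderate >> low)."""
    potency = (
        1.6 * class_fractions["high"]
        + 0.5 * class_fractions["moderate"]
        + 0.05 * class_fractions["low"]
    )
    return 100.0 * (1.0 - float(np.exp(-potency * et_ratio / 1.5)))


# ---------------------------------------------------------------------------
# Event sampling


@dataclass
class GroundTruth:
    """Per-sample truth: expected gated fractions (0-1 scale, keyed like
    FeatureTable columns; the CD4:CD8 ratio key holds the ratio itself),
    cytotoxic-class fractions and the true killing curve (products only)."""

    sample_id: str
    fractions: dict[str, float]
    class_fractions: dict[str, float] | None = None
    cytotoxicity: dict[float, float] | None = None

    def __post_init__(self) -> None:
        for key, value in self.fractions.items():
            if key.startswith("pct_") and not -1e-9 <= value <= 1.0 + 1e-9:
                raise ValueError(f"fraction {key}={value} outside [0, 1]")
        if self.class_fractions is not None:
            total = sum(self.class_fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("class fractions must sum to 1")


def expected_fractions(law: PhenotypeLaw) -> dict[str, float]:
    out = {
        "pct_CD3": law.p_cd3,
        "pct_CD4": 1.0 - law.p_cd8,
        "pct_CD8": law.p_cd8,
        "pct_CAR": law.p_car,
        "ratio_CD4_CD8": (1.0 - law.p_cd8) / law.p_cd8 if law.p_cd8 > 0 else 0.0,
    }
    for name, comp in (("CD4", law.cd4), ("CD8", law.cd8)):
        for quad, p in zip(MEM_QUADS, comp.mem):
            out[f"pct_{name}_{quad}"] = float(p)
        for quad, p in zip(EXH_QUADS, comp.exh):
            out[f"pct_{name}_{quad}"] = float(p)
        out[f"pct_{name}_CD25+"] = comp.p_cd25
        out[f"pct_{name}_CD137+"] = comp.p_cd137
        out[f"pct_{name}_CD95+"] = comp.p_cd95
    return out


def sample_events(
    law: PhenotypeLaw | ProductLaw,
    n_events: int,
    rng: np.random.Generator,
    panel: MarkerPanel | None = None,
    noise_sd: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw an event matrix (intensities) and its per-event label frame."""
    panel = panel or MarkerPanel()
    n = int(n_events)
    if isinstance(law, ProductLaw):
        fracs = np.array([law.class_fractions[c] for c in CLASSES])
        cls_idx = rng.choice(len(CLASSES), size=n, p=fracs / fracs.sum())
        laws = [law.class_laws[c] for c in CLASSES]
        base = laws[0]
    else:
        cls_idx = np.full(n, -1)
        laws = [law]
        base = law

    viable = rng.random(n) < base.p_viable
    cd3 = rng.random(n) < base.p_cd3
    cd8 = cd3 & (rng.random(n) < base.p_cd8)
    cd4 = cd3 & ~cd8
    car = cd3 & (rng.random(n) < base.p_car)

    mem_quad = np.full(n, -1)
    exh_quad = np.full(n, -1)
    cd25 = np.zeros(n, dtype=bool)
    cd137 = np.zeros(n, dtype=bool)
    cd95 = np.zeros(n, dtype=bool)
    for li, sub_law in enumerate(laws):
        cls_mask = np.ones(n, dtype=bool) if cls_idx[0] == -1 and len(laws) == 1 else cls_idx == li
        for comp_mask, comp in ((cd4, sub_law.cd4), (cd8, sub_law.cd8)):
            mask = cls_mask & comp_mask
            m = int(mask.sum())
            if m == 0:
                continue
            mem_quad[mask] = rng.choice(4, size=m, p=np.asarray(comp.mem))
            exh_quad[mask] = rng.choice(4, size=m, p=np.asarray(comp.exh))
            cd25[mask] = rng.random(m) < comp.p_cd25
            cd137[mask] = rng.random(m) < comp.p_cd137
            cd95[mask] = rng.random(m) < comp.p_cd95

    positive = {
        "CD3": cd3,
        "CD4": cd4,
        "CD8": cd8,
        "CD45RA": np.isin(mem_quad, (0, 1)),
        "CCR7": np.isin(mem_quad, (0, 2)),
        "PD1": np.isin(exh_quad, (0, 1)),
        "TIM3": np.isin(exh_quad, (0, 2)),
        "CD25": cd25,
        "CD137": cd137,
        "CD95": cd95,
        "CAR": car,
        "Viability": ~viable,  # dead-cell stain
    }
    mu = np.empty((n, len(panel)))
    for j, marker in enumerate(panel):
        pos = positive.get(marker, np.zeros(n, dtype=bool))
        mu[:, j] = np.where(pos, LOG10_POS_MODE, LOG10_NEG_MODE)
    log10v = mu + LOG10_MODE_SD * noise_sd * rng.standard_normal((n, len(panel)))
    data = pd.DataFrame(10.0**log10v, columns=list(panel))
    labels = pd.DataFrame(
        {
            "viable": viable,
            "cd3": cd3,
            "cd4": cd4,
            "cd8": cd8,
            "mem_quad": mem_quad,
            "exh_quad": exh_quad,
            "cd25": cd25,
            "cd137": cd137,
            "cd95": cd95,
            "car": car,
            "cytotox_class": [
                CLASSES[i] if i >= 0 else "" for i in cls_idx
            ],
        }
    )
    return data, labels


def generate_blood_sample(
    donor: DonorProfile,
    n_events: int,
    rng: np.random.Generator | int,
    config: GenerationConfig | None = None,
) -> tuple[SingleCellMatrix, GroundTruth]:
    """One pre-activation blood sample for a donor, plus its ground truth."""
    config = config or GenerationConfig()
    if n_events < 100:
        raise ValueError("n_events must be >= 100")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    law = build_blood_law(donor, rng, config.noise_sd)
    data, labels = sample_events(law, n_events, rng, config.marker_panel, config.noise_sd)
    sid = f"{donor.donor_id}_blood"
    return (
        SingleCellMatrix(sample_id=sid, data=data, labels=labels),
        GroundTruth(sample_id=sid, fractions=expected_fractions(law)),
    )


def generate_product(
    donor: DonorProfile,
    dose: StimulationDose,
    n_events: int,
    rng: np.random.Generator | int,
    config: GenerationConfig | None = None,
) -> tuple[SingleCellMatrix, GroundTruth]:
    """One CAR-T product for (donor, dose), plus its ground truth."""
    config = config or GenerationConfig()
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if dose.stim_type == APC_MS:
        d_eff = float(dose.mol_pct_biotin)
        lo, hi = min(config.doses_mol_pct), max(config.doses_mol_pct)
        if not lo - 1e-9 <= d_eff <= hi + 1e-9:
            raise ValueError(f"dose {d_eff} mol% outside configured range [{lo}, {hi}]")
    else:
        # Dynabead conditions enter the dose laws at their pg/cell-equivalent
        d_eff = config.dose_conversion.to_mol_pct(dose.pg_per_cell)
    law = build_product_law(donor, d_eff, rng, config.noise_sd)
    data, labels = sample_events(law, n_events, rng, config.marker_panel, config.noise_sd)
    sid = f"{donor.donor_id}_{dose.label}"
    truth = GroundTruth(
        sample_id=sid,
        fractions=expected_fractions(law.marginal),
        class_fractions=dict(law.class_fractions),
        cytotoxicity={
            float(r): true_cytotoxicity(law.class_fractions, r)
            for r in config.et_ratios
        },
    )
    return SingleCellMatrix(sample_id=sid, data=data, labels=labels), truth


def generate_cytotox_readings(
    truth: GroundTruth,
    et_ratios: list[float] | tuple[float, ...],
    rng: np.random.Generator | int,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Luminescence triplets per E:T ratio for one product.

    Emitted so that the percent-cytotoxicity formula recovers the true value
    up to Gaussian noise of sd ``PCT_NOISE_SD * noise_sd`` percentage points.
    """
    if len(et_ratios) == 0:
        raise ValueError("et_ratios must be non-empty")
    if 0.0 not in [float(r) for r in et_ratios]:
        raise ValueError("et_ratios must include the 0:1 control")
    if truth.cytotoxicity is None:
        raise ValueError("ground truth carries no cytotoxicity curve")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    rows = []
    for ratio in et_ratios:
        true_pct = truth.cytotoxicity[float(ratio)]
        observed = true_pct + PCT_NOISE_SD * noise_sd * rng.standard_normal()
        lum_sample = LUM_TARGET_ONLY - observed / 100.0 * (
            LUM_TARGET_ONLY - LUM_MAX_LYSIS
        )
        lum_sample = max(lum_sample, 0.0)  # photon counts cannot go negative
        rows.append(
            {
                "sample_id": truth.sample_id,
                "et_ratio": float(ratio),
                "lum_sample": float(lum_sample),
                "lum_max_lysis": LUM_MAX_LYSIS,
                "lum_target_only": LUM_TARGET_ONLY,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort assembly


@dataclass
class Cohort:
    config: GenerationConfig
    donors: list[DonorProfile]
    samples: dict[str, SingleCellMatrix]
    manifest: pd.DataFrame
    readings: pd.DataFrame
    ground_truth: dict[str, GroundTruth]

    def donor(self, donor_id: str) -> DonorProfile:
        for d in self.donors:
            if d.donor_id == donor_id:
                return d
        raise KeyError(donor_id)

    def manifest_json(self) -> str:
        payload = {
            "schema": "carstim.cohort/1",
            "seed": self.config.seed,
            "noise_sd": self.config.noise_sd,
            "doses_mol_pct": list(self.config.doses_mol_pct),
            "donors": [
                {
                    "donor_id": d.donor_id,
                    "status": d.status,
                    "latent_cd8_bias": d.latent_cd8_bias,
                    "latent_effector_bias": d.latent_effector_bias,
                    "latent_activation_threshold": d.latent_activation_threshold,
                    "random_effect_sd": d.random_effect_sd,
                }
                for d in self.donors
            ],
            "samples": self.manifest.to_dict(orient="records"),
        }
        return json.dumps(payload, sort_keys=True, indent=2)

    def ground_truth_json(self) -> str:
        payload = {
            sid: {
                "fractions": gt.fractions,
                "class_fractions": gt.class_fractions,
                "cytotoxicity": {str(k): v for k, v in (gt.cytotoxicity or {}).items()},
            }
            for sid, gt in self.ground_truth.items()
        }
        return json.dumps(payload, sort_keys=True, indent=2)

    def to_dir(self, path: str | Path) -> None:
        """Write events_<sample_id>.csv per sample plus cohort_manifest.json,
        cytotox.csv and ground_truth.json (the latter is test-only and is not
        consumed by any analysis module)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for sid, mat in self.samples.items():
            frame = mat.data.copy()
            frame.insert(0, "sample_id", sid)
            frame.to_csv(path / f"events_{sid}.csv", index=False)
        (path / "cohort_manifest.json").write_text(self.manifest_json())
        self.readings.to_csv(path / "cytotox.csv", index=False)
        (path / "ground_truth.json").write_text(self.ground_truth_json())

    @staticmethod
    def load_events_dir(path: str | Path) -> tuple[list[SingleCellMatrix], pd.DataFrame]:
        """Read back event CSVs and the sample manifest from a cohort dir."""
        path = Path(path)
        manifest = json.loads((path / "cohort_manifest.json").read_text())
        meta = pd.DataFrame(manifest["samples"])
        samples = []
        for sid in meta["sample_id"]:
            frame = pd.read_csv(path / f"events_{sid}.csv")
            samples.append(
                SingleCellMatrix(sample_id=sid, data=frame.drop(columns=["sample_id"]))
            )
        return samples, meta


def _conditions_for(config: GenerationConfig, donor_id: str) -> list[StimulationDose]:
    dropped = set(config.dose_dropout.get(donor_id, ()))
    doses = [
        StimulationDose.apc_ms(m, config.dose_conversion)
        for m in config.doses_mol_pct
        if m not in dropped
    ]
    doses += [
        StimulationDose.dynabead(r, config.dose_conversion)
        for r in config.extra_dynabead.get(donor_id, ())
    ]
    return doses


def generate_cohort(config: GenerationConfig | None = None) -> Cohort:
    """Full cohort: donors, one blood sample each, one product per condition,
    killing-assay readings per product, and ground truth throughout."""
    config = config or GenerationConfig()
    donors: list[DonorProfile] = []
    for status, count, prefix in (
        (HEALTHY, config.n_healthy, "H"),
        (PATIENT, config.n_patient, "P"),
    ):
        for i in range(count):
            donor_id = f"{prefix}{i + 1:02d}"
            rng = child_rng(config.seed, "donor", donor_id)
            donors.append(generate_donor(status, rng, config, donor_id=donor_id))

    samples: dict[str, SingleCellMatrix] = {}
    truth: dict[str, GroundTruth] = {}
    meta_rows = []
    reading_frames = []
    for donor in donors:
        mat, gt = generate_blood_sample(
            donor,
            config.n_events_per_sample,
            child_rng(config.seed, "blood", donor.donor_id),
            config,
        )
        samples[mat.sample_id] = mat
        truth[mat.sample_id] = gt
        meta_rows.append(
            {
                "sample_id": mat.sample_id,
                "donor_id": donor.donor_id,
                "status": donor.status,
                "stage": "blood",
                "stim_type": "",
                "dose_mol_pct": np.nan,
                "dose_pg_per_cell": np.nan,
            }
        )
        for dose in _conditions_for(config, donor.donor_id):
            mat, gt = generate_product(
                donor,
                dose,
                config.n_events_per_sample,
                child_rng(config.seed, "product", donor.donor_id, dose.label),
                config,
            )
            samples[mat.sample_id] = mat
            truth[mat.sample_id] = gt
            meta_rows.append(
                {
                    "sample_id": mat.sample_id,
                    "donor_id": donor.donor_id,
                    "status": donor.status,
                    "stage": "product",
                    "stim_type": dose.stim_type,
                    "dose_mol_pct": dose.mol_pct_biotin
                    if dose.mol_pct_biotin is not None
                    else np.nan,
                    "dose_pg_per_cell": dose.pg_per_cell,
                }
            )
            reading_frames.append(
                generate_cytotox_readings(
                    gt,
                    config.et_ratios,
                    child_rng(config.seed, "assay", mat.sample_id),
                    config.noise_sd,
                )
            )
    manifest = pd.DataFrame(meta_rows, columns=list(METADATA_COLUMNS))
    readings = (
        pd.concat(reading_frames, ignore_index=True)
        if reading_frames
        else pd.DataFrame(
            columns=["sample_id", "et_ratio", "lum_sample", "lum_max_lysis", "lum_target_only"]
        )
    )
    return Cohort(
        config=config,
        donors=donors,
        samples=samples,
        manifest=manifest,
        readings=readings,
        ground_truth=truth,
    )
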