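"""Luminescence killing-assay arithmetic and E:T dose-response curves.

Luciferised target cells emit light while alive, so killing is read as loss
of signal against two plate controls: a target-only well (0:1, no effectors)
and a detergent max-lysis well.  Percent cytotoxicity is

    100 * (1 - (sample - max_lysis) / (target_only - max_lysis))

which is 0% at the target-only control, 100% at the max-lysis control, and
affine-invariant under common rescaling of all three readings.  Values are
not clipped to [0, 100]: noise can push them slightly outside, and the
attribution analysis wants that structure preserved (displays may clip).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: E:T ratio whose percent cytotoxicity feeds single-cell attribution.
ATTRIBUTION_ET_RATIO = 1.25


@dataclass(frozen=True)
class LuminescenceReading:
    sample_id: str
    et_ratio: float
    lum_sample: float
    lum_max_lysis: float
    lum_target_only: float

    def __post_init__(self) -> None:
        for name in ("lum_sample", "lum_max_lysis", "lum_target_only"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class CytotoxicityCurve:
    """Map E:T ratio -> percent cytotoxicity for one product."""

    sample_id: str
    points: dict[float, float]

    def at(self, et_ratio: float) -> float:
        if float(et_ratio) not in self.points:
            raise KeyError(
                f"curve for {self.sample_id} has no {et_ratio}:1 point"
            )
        return self.points[float(et_ratio)]


def percent_cytotoxicity(
    lum_sample: float, lum_max_lysis: float, lum_target_only: float
) -> float:
    """Percent cytotoxicity from a (sample, max-lysis, target-only) triplet."""
    denom = lum_target_only - lum_max_lysis
    if denom == 0:
        raise ValueError(
            "degenerate controls: target-only "
            f"({lum_target_only}) equals max-lysis ({lum_max_lysis})"
        )
    return 100.0 * (1.0 - (lum_sample - lum_max_lysis) / denom)


def build_curve(
    readings: list[LuminescenceReading] | pd.DataFrame,
) -> CytotoxicityCurve:
    """Assemble one sample's curve; duplicate-ratio readings are averaged."""
    if isinstance(readings, pd.DataFrame):
        readings = [
            LuminescenceReading(
                sample_id=str(r.sample_id),
                et_ratio=float(r.et_ratio),
                lum_sample=float(r.lum_sample),
                lum_max_lysis=float(r.lum_max_lysis),
                lum_target_only=float(r.lum_target_only),
            )
            for r in readings.itertuples()
        ]
    if not readings:
        raise ValueError("no readings supplied")
    sample_ids = {r.sample_id for r in readings}
    if len(sample_ids) != 1:
        raise ValueError(f"readings mix sample_ids: {sorted(sample_ids)}")
    by_ratio: dict[float, list[float]] = {}
    for r in readings:
        pct = percent_cytotoxicity(r.lum_sample, r.lum_max_lysis, r.lum_target_only)
        by_ratio.setdefault(float(r.et_ratio), []).append(pct)
    return CytotoxicityCurve(
        sample_id=next(iter(sample_ids)),
        points={ratio: float(np.mean(v)) for ratio, v in sorted(by_ratio.items())},
    )


def curves_from_frame(readings: pd.DataFrame) -> dict[str, CytotoxicityCurve]:
    """Per-sample curves from a long-format readings table."""
    return {
        str(sid): build_curve(group)
        for sid, group in readings.groupby("sample_id", sort=True)
    }


def curve_table(curves: dict[str, CytotoxicityCurve]) -> pd.DataFrame:
    rows = [
        {"sample_id": sid, "et_ratio": ratio, "pct_cytotoxicity": pct}
        for sid, curve in sorted(curves.items())
        for ratio, pct in curve.points.items()
    ]
    return pd.DataFrame(rows)
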