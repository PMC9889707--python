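"""Marker panel definition for the 12-channel T-cell phenotyping layout.

The panel mirrors a standard T-cell FACS staining layout: lineage (CD3, CD4,
CD8), memory (CD45RA, CCR7), exhaustion (PD1, TIM3), activation (CD25, CD137),
differentiation (CD95), transgene detection (CAR, via a truncated-EGFR tag)
and a fixable viability dye (positive staining marks dead cells).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

#: Default marker order; event matrices carry one column per marker.
DEFAULT_MARKERS: tuple[str, ...] = (
    "CD3",
    "CD4",
    "CD8",
    "PD1",
    "TIM3",
    "CD25",
    "CD45RA",
    "CCR7",
    "CAR",
    "CD95",
    "CD137",
    "Viability",
)


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered, unique marker names defining event-matrix columns."""

    markers: tuple[str, ...] = DEFAULT_MARKERS

    def __post_init__(self) -> None:
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("marker names must be unique")
        if len(self.markers) == 0:
            raise ValueError("panel must contain at least one marker")

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def __contains__(self, name: str) -> bool:
        return name in self.markers

    def index(self, name: str) -> int:
        return self.markers.index(name)


def child_rng(seed: int, *keys: object) -> np.random.Generator:
    """Derive an independent substream from a master seed and string keys.

    Substreams are keyed by stable hashing of the identifiers, so adding a
    donor or sample to a cohort does not perturb the draws of the others.
    """
    token = "|".join([str(int(seed))] + [str(k) for k in keys])
    digest = hashlib.sha256(token.encode("utf-8")).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))
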