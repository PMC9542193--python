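"""AAL-95 region atlas: node definitions for source-space brain networks.

The atlas parcellates the cortex (plus subcortical and a few cerebellar
structures) into 95 labelled regions following the Tzourio-Mazoyer (AAL)
naming and numeric coding scheme.  Regions are the nodes of every network
built by this package; they are always ordered by ascending numeric code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

N_REGIONS = 95


@dataclass(frozen=True)
class ROIAtlas:
    """A region atlas plus a source-to-region assignment.

    Parameters
    ----------
    regions
        One row per region with columns ``code`` (unique integer),
        ``name``, ``hemisphere`` (L/R/M) and ``lobe`` (coarse anatomical
        grouping used when reporting key nodes).  Sorted by code.
    source_to_region
        Integer array mapping each dipole-source index of the companion
        lead field to a region *code*.  Empty until sources are attached.
    """

    regions: pd.DataFrame
    source_to_region: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        codes = self.regions["code"].to_numpy()
        if len(codes) != N_REGIONS:
            raise ValueError(f"atlas must contain exactly {N_REGIONS} regions, got {len(codes)}")
        if len(np.unique(codes)) != len(codes):
            raise ValueError("region codes must be unique")
        if not np.all(np.diff(codes) > 0):
            raise ValueError("regions must be sorted by ascending code")
        if self.source_to_region.size:
            unknown = set(self.source_to_region.tolist()) - set(codes.tolist())
            if unknown:
                raise ValueError(f"source_to_region refers to unknown codes: {sorted(unknown)}")

    @property
    def codes(self) -> np.ndarray:
        return self.regions["code"].to_numpy()

    @property
    def names(self) -> list[str]:
        return self.regions["name"].tolist()

    @property
    def n_sources(self) -> int:
        return int(self.source_to_region.size)

    def name_of(self, code: int) -> str:
        row = self.regions.loc[self.regions["code"] == code, "name"]
        if row.empty:
            raise KeyError(f"unknown region code {code}")
        return str(row.iloc[0])

    def region_indices(self) -> dict[int, np.ndarray]:
        """Map region code -> indices of the sources assigned to it."""
        if not self.source_to_region.size:
            raise ValueError("atlas has no attached sources")
        return {
            int(c): np.flatnonzero(self.source_to_region == c) for c in self.codes
        }

    def with_sources(self, source_to_region: np.ndarray) -> "ROIAtlas":
        return ROIAtlas(self.regions, np.asarray(source_to_region, dtype=int))


def load_aal95() -> ROIAtlas:
    """Load the packaged 95-region AAL atlas table (no sources attached)."""
    with resources.files("comfnet.data").joinpath("aal95.csv").open() as f:
        regions = pd.read_csv(f)
    return ROIAtlas(regions.sort_values("code").reset_index(drop=True))
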