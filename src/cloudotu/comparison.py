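"""Between-sample structure and physical unit conversion.

Shared-OTU (Venn) partitions and per-region read contributions,
Bray–Curtis similarity between normalized columns, and the conversion of
per-mL cell concentrations in sampled cloud water to cells per m³ of
cloudy air via the equivalent air volume of the collector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import OtuTable

__all__ = [
    "VennPartition",
    "venn_partition",
    "bray_curtis_matrix",
    "cells_per_air_volume",
    "round_reported_concentration",
]


@dataclass(frozen=True)
class VennPartition:
    """One region of the presence/absence Venn decomposition."""

    region: frozenset[str]
    otu_count: int
    read_fraction_per_sample: dict[str, float]

    def __hash__(self) -> int:  # read_fraction dict excluded
        return hash((self.region, self.otu_count))


def venn_partition(table: OtuTable, fraction: str = "DNA") -> list[VennPartition]:
    """Partition OTUs by the set of samples where they are present.

    Presence = count > 0 in the chosen fraction, after filtering. Each
    region also reports, per member sample, the fraction of that
    sample's reads carried by the region's OTUs. Regions are returned
    largest-membership first and partition the OTU set (OTUs absent from
    every sample fall in the empty region).
    """
    cols = [
        c for c in table.columns if c.fraction == fraction and not c.is_control
    ]
    if len(cols) < 2:
        raise ValueError(
            f"need at least 2 samples in fraction {fraction!r}, found {len(cols)}"
        )
    sample_ids = [c.sample_id for c in cols]
    counts = np.stack([table.get_column(c) for c in cols], axis=1)
    presence = counts > 0
    totals = counts.sum(axis=0)

    regions: dict[frozenset[str], list[int]] = {}
    for i in range(table.n_otus):
        region = frozenset(
            s for s, present in zip(sample_ids, presence[i]) if present
        )
        regions.setdefault(region, []).append(i)

    out: list[VennPartition] = []
    for region, rows in regions.items():
        fractions = {}
        for j, s in enumerate(sample_ids):
            if s in region and totals[j] > 0:
                fractions[s] = float(counts[rows, j].sum() / totals[j])
        out.append(
            VennPartition(
                region=region,
                otu_count=len(rows),
                read_fraction_per_sample=fractions,
            )
        )
    out.sort(key=lambda p: (-len(p.region), sorted(p.region)))
    return out


def bray_curtis_matrix(proportions: np.ndarray) -> np.ndarray:
    """Bray–Curtis *similarity* matrix between normalized columns.

    similarity(x, y) = 1 - sum|x_i - y_i| / sum(x_i + y_i); symmetric,
    in [0, 1], with 1 on the diagonal.
    """
    x = np.asarray(proportions, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D OTU x column matrix")
    if x.shape[1] < 1:
        raise ValueError("need at least one column")
    dis = squareform(pdist(x.T, metric="braycurtis")) if x.shape[1] > 1 else np.zeros((1, 1))
    return 1.0 - dis


def cells_per_air_volume(
    conc_per_mL: float, water_volume_mL: float, air_volume_m3: float
) -> float:
    """Convert cells per mL of cloud water to cells per m³ of cloudy air.

    The collector samples a known equivalent air volume while filtering a
    known water volume, so cells m^-3 = conc x water / air.
    """
    if air_volume_m3 <= 0:
        raise ValueError("air_volume_m3 must be positive")
    if water_volume_mL <= 0:
        raise ValueError("water_volume_mL must be positive")
    if conc_per_mL < 0:
        raise ValueError("conc_per_mL must be >= 0")
    return conc_per_mL * water_volume_mL / air_volume_m3


def round_reported_concentration(value: float) -> float:
    """Reporting convention for air concentrations: 2 significant figures
    for values >= 100, 1 significant figure below."""
    if value < 0:
        raise ValueError("value must be >= 0")
    if value == 0:
        return 0.0
    sig = 2 if value >= 100 else 1
    exponent = int(np.floor(np.log10(abs(value))))
    factor = 10.0 ** (exponent - sig + 1)
    return float(round(value / factor) * factor)
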