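"""Bundled published characteristics of three cloud-water samples.

These are the printed per-sample measurements from a survey of cloud
water collected at the puy de Dôme mountain-top atmospheric station
(1465 m a.s.l., France): three cloud events — "polluted", "continental"
and "marine" air-mass types — sampled with a droplet impactor of known
equivalent air volume, with flow-cytometry cell counts, plus the
per-fraction community summary statistics (processed reads, observed and
ACE-estimated richness, Shannon H, Gini) computed from the paired
DNA/RNA amplicon sequencing of those samples.

They serve as worked-example inputs for the unit-conversion and coverage
computations; the read-level data behind the summaries are not bundled.
"""

from __future__ import annotations

import pandas as pd

from .core import SampleMetadata

__all__ = ["cloud_sample_metadata", "cloud_community_summary"]


def cloud_sample_metadata() -> dict[str, SampleMetadata]:
    """Per-sample water/air volumes and cell concentrations."""
    rows = [
        # sample_id, water mL, air m3, prok mL^-1, euk mL^-1, LWC g m^-3
        ("polluted", 94.0, 304.0, 8.23e3, 8.67e2, 0.16),
        ("continental", 350.0, 1422.0, 9.49e3, 2.83e2, 0.31),
        ("marine", 420.0, 2457.0, 2.05e3, 4.42e1, 0.40),
    ]
    return {
        sid: SampleMetadata(
            sample_id=sid,
            water_volume_mL=w,
            air_volume_m3=a,
            prok_conc_per_mL=p,
            euk_conc_per_mL=e,
            lwc_g_m3=lwc,
        )
        for sid, w, a, p, e, lwc in rows
    }


def cloud_community_summary() -> pd.DataFrame:
    """Published per-fraction summary statistics of the sequenced communities.

    One row per (domain, sample, fraction) with processed read number,
    observed richness, ACE-estimated richness, Shannon H (nats) and Gini
    coefficient. The marine sample has no RNA fraction.
    """
    cols = [
        "domain",
        "sample_id",
        "fraction",
        "processed_reads",
        "observed_richness",
        "ace",
        "shannon_h",
        "gini",
    ]
    rows = [
        ("prokaryote", "polluted", "DNA", 496_197, 20_432, 20_954, 9.1, 0.74),
        ("prokaryote", "polluted", "RNA", 59_449, 3_428, 4_710, 6.3, 0.98),
        ("prokaryote", "continental", "DNA", 115_515, 7_793, 10_802, 7.2, 0.95),
        ("prokaryote", "continental", "RNA", 81_196, 5_622, 6_468, 7.3, 0.95),
        ("prokaryote", "marine", "DNA", 150_017, 8_970, 11_148, 7.4, 0.94),
        ("eukaryote", "polluted", "DNA", 18_562, 2_061, 2_461, 6.58, 0.75),
        ("eukaryote", "polluted", "RNA", 12_831, 1_527, 1_845, 6.28, 0.81),
        ("eukaryote", "continental", "DNA", 13_978, 1_901, 2_400, 6.48, 0.77),
        ("eukaryote", "continental", "RNA", 24_673, 1_692, 1_834, 6.32, 0.81),
        ("eukaryote", "marine", "DNA", 15_662, 1_877, 2_439, 6.26, 0.79),
    ]
    return pd.DataFrame(rows, columns=cols)
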