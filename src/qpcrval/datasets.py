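"""Bundled reference tables from the assay's analytical validation study.

These small CSVs ship with the package so the full reporting pipeline —
delta-Ct interference, occupancy/dropout, confusion metrics, clinical
detection rates — can be recomputed from published desk-scale numbers
without any laboratory files.  Columns prefixed ``printed_`` carry the
values as originally reported (for cross-checking); everything else is
recomputed by the pipeline.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_dilution_standards",
    "load_wt_interference_means",
    "load_occupancy_counts",
    "load_analytical_performance",
    "load_clinical_specificity",
    "load_lung_detection",
    "load_latam_detection",
]


def _read(name: str, **kwargs) -> pd.DataFrame:
    with resources.files("qpcrval.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, **kwargs)


def load_dilution_standards() -> pd.DataFrame:
    """Seven-level mutant dilution series: nominal copies, WT background, replicates."""
    return _read("dilution_standards.csv")


def load_wt_interference_means() -> pd.DataFrame:
    """Mean Ct per (target, standard) with and without the 14,000-copy WT background."""
    return _read("wt_interference_means.csv")


def load_occupancy_counts() -> pd.DataFrame:
    """Empty-well counts and reference copy numbers per dilution level.

    ``ddpcr_is_calculated`` marks levels whose copy value is a 1:2
    dilution calculation rather than a direct droplet-digital
    measurement.  Occupancy columns are absent for the two highest
    levels, which were not run at replicate depth.
    """
    return _read("occupancy_counts.csv")


def load_analytical_performance() -> pd.DataFrame:
    """Per-assay false-negative/positive counts and printed LoD."""
    return _read("analytical_performance.csv")


def load_clinical_specificity() -> pd.DataFrame:
    """Healthy-donor panel: 20 tests per assay, detections observed."""
    return _read("clinical_specificity.csv")


def load_lung_detection() -> pd.DataFrame:
    """Clinical-experience detection counts per target (lung cohort)."""
    return _read("lung_detection.csv")


def load_latam_detection() -> pd.DataFrame:
    """Detection counts for the Mexico/Columbia cohorts plus tissue references."""
    return _read("latam_detection.csv")
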