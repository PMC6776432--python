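"""Synthetic plate-data generator for the validation pipeline.

Emulates the statistical structure the analysis assumes, so every stage
can be exercised without laboratory data:

* per-well mutant copies k ~ Poisson(nominal mean) — zero-copy wells
  drop out with no Ct;
* a log-linear Ct response on the *realized* copy number,
  Ct = intercept + slope*log10(k) + N(0, sigma_ct), so sampling noise
  widens the Ct spread at low copy input exactly as real single-copy
  wells do;
* a small additive Ct shift when a large WT background is present,
  drawn once per standard level (it is a property of the prepared
  reaction mix, shared by its replicates, not per-well noise); defaults
  taken from the paired delta-Ct panel: mean -0.32, SD 0.52 — WT
  background slightly *advances* amplification;
* specific-product melt peaks for true amplicons, cooler non-specific
  peaks for rare false-positive signals in WT-only wells;
* rare false positives at ``fp_rate`` per WT-only well, most of which
  the melt and sequencing gates should remove.

Every draw flows from a single integer seed through per-target seed
sequences, so identical config + seed reproduces plates byte for byte.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .occupancy import expected_empty_fraction
from .plates import AssayTarget, DilutionStandard, WellRecord

__all__ = [
    "CurveParams",
    "SimulationConfig",
    "default_standards",
    "simulate_dilution_series",
    "simulate_wt_specificity_panel",
    "ground_truth_table",
]


@dataclass(frozen=True)
class CurveParams:
    """Generating log-linear Ct response for one assay."""

    slope: float = -3.45
    intercept: float = 38.6
    sigma_ct: float = 0.3

    def __post_init__(self):
        if self.sigma_ct <= 0:
            raise ConfigurationError("sigma_ct must be positive")
        if self.slope >= 0:
            raise ConfigurationError("slope must be negative (more copies = earlier Ct)")


def default_standards(wt_copies: int = 14_000) -> tuple[DilutionStandard, ...]:
    """The seven-level mutant dilution series used throughout validation.

    Levels A-D descend 8-fold from ~5120 copies to ~10; E, F and G are
    1:2 serial dilutions of D (5, 2.5, 1.25 mean copies), run with 20
    replicates instead of 3 to resolve stochastic occupancy.
    """
    a = DilutionStandard("A", 5120.0, wt_copies=wt_copies, n_replicates=3)
    b = DilutionStandard("B", 640.0, wt_copies=wt_copies, n_replicates=3)
    c = DilutionStandard("C", 80.0, wt_copies=wt_copies, n_replicates=3)
    d = DilutionStandard("D", 10.0, wt_copies=wt_copies, n_replicates=3)
    e = d.halved("E", n_replicates=20)
    f = e.halved("F")
    g = f.halved("G")
    return (a, b, c, d, e, f, g)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions.

    ``wt_shift`` is the (mean, sd) of the additive Ct effect of a WT
    background; ``fp_rate`` the probability a WT-only well emits any
    signal; ``seq_wt_fraction`` the fraction of gate-surviving false
    signals that sequence as wild type.
    """

    seed: int = 0
    curves: Mapping[AssayTarget, CurveParams] = field(
        default_factory=lambda: {t: CurveParams() for t in AssayTarget}
    )
    standards: tuple[DilutionStandard, ...] = field(default_factory=default_standards)
    wt_shift: tuple[float, float] = (-0.32, 0.52)
    fp_rate: float = 0.04
    fp_ct_range: tuple[float, float] = (38.0, 44.0)
    seq_wt_fraction: float = 0.9
    tm_specific: tuple[float, float] = (82.0, 0.4)
    tm_nonspecific: tuple[float, float] = (76.0, 1.5)
    max_cycles: float = 45.0

    def __post_init__(self):
        problems = []
        if not 0 <= self.fp_rate < 1:
            problems.append("fp_rate must lie in [0, 1)")
        if self.wt_shift[1] < 0:
            problems.append("wt_shift sd must be non-negative")
        if not 0 <= self.seq_wt_fraction <= 1:
            problems.append("seq_wt_fraction must lie in [0, 1]")
        if self.max_cycles <= 0:
            problems.append("max_cycles must be positive")
        if not self.fp_ct_range[0] < self.fp_ct_range[1]:
            problems.append("fp_ct_range must be (low, high) with low < high")
        if problems:
            raise ConfigurationError("; ".join(problems))

    def curve_for(self, target: AssayTarget) -> CurveParams:
        try:
            return self.curves[target]
        except KeyError:
            raise ConfigurationError(f"no curve parameters for target {target}") from None


_TARGET_INDEX = {t: i for i, t in enumerate(AssayTarget)}


def _rng(cfg: SimulationConfig, target: AssayTarget, stream: int) -> np.random.Generator:
    # deterministic per (seed, target, purpose) stream
    return np.random.default_rng([cfg.seed, _TARGET_INDEX[target], stream])


def _clip_ct(ct: float, max_cycles: float) -> float:
    return float(min(max(ct, 1e-3), max_cycles - 1e-3))


def simulate_dilution_series(
    cfg: SimulationConfig,
    target: AssayTarget,
    plate_id: str = "P1",
    instrument_id: str = "I1",
    operator_id: str = "O1",
    standards: Sequence[DilutionStandard] | None = None,
    rng: np.random.Generator | None = None,
) -> list[WellRecord]:
    """Simulate one plate's dilution series for one assay target.

    Per well: draw k ~ Poisson(nominal mean copies); k = 0 drops out (no
    Ct, no Tm); k >= 1 amplifies at the curve response of the realized k
    plus Gaussian noise, plus the WT shift when the standard carries a WT
    background.  Melt peaks come from the specific-product distribution.
    """
    curve = cfg.curve_for(target)
    if rng is None:
        rng = _rng(cfg, target, stream=zlib.crc32(plate_id.encode()))
    wells: list[WellRecord] = []
    for std in standards if standards is not None else cfg.standards:
        # the WT-background effect is shared by every replicate of a level
        shift = rng.normal(*cfg.wt_shift) if std.wt_copies > 0 else 0.0
        for rep in range(1, std.n_replicates + 1):
            k = int(rng.poisson(std.nominal_mean_copies))
            if k == 0:
                ct = tm = None
            else:
                ct = curve.intercept + curve.slope * np.log10(k)
                ct += rng.normal(0.0, curve.sigma_ct) + shift
                ct = _clip_ct(ct, cfg.max_cycles)
                tm = float(rng.normal(*cfg.tm_specific))
            wells.append(
                WellRecord(
                    assay_target=target,
                    standard_id=std.name,
                    plate_id=plate_id,
                    instrument_id=instrument_id,
                    operator_id=operator_id,
                    replicate_index=rep,
                    ct=ct,
                    tm=tm,
                    wt_background_copies=std.wt_copies,
                    truth_mutant_copies=std.nominal_mean_copies,
                    sequencing_confirmed=True if ct is not None else None,
                )
            )
    return wells


def simulate_wt_specificity_panel(
    cfg: SimulationConfig,
    n_wells: int,
    target: AssayTarget = AssayTarget.EGFR_T790M,
    plate_id: str = "P1",
    instrument_id: str = "I1",
    operator_id: str = "O1",
    wt_copies: int = 14_000,
    rng: np.random.Generator | None = None,
) -> list[WellRecord]:
    """Simulate WT-only wells for the analytical-specificity panel.

    Each well emits a signal with probability ``fp_rate``; false signals
    get a late Ct and a non-specific (cooler) melt peak so the melt gate
    can catch them.  Signals that would survive gating sequence as wild
    type with probability ``seq_wt_fraction``.  Truth is negative for
    every well.
    """
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    if rng is None:
        rng = _rng(cfg, target, stream=1_000_003)
    wells: list[WellRecord] = []
    for rep in range(1, n_wells + 1):
        ct = tm = None
        confirmed = None
        if rng.random() < cfg.fp_rate:
            ct = _clip_ct(float(rng.uniform(*cfg.fp_ct_range)), cfg.max_cycles)
            tm = float(rng.normal(*cfg.tm_nonspecific))
            confirmed = bool(rng.random() >= cfg.seq_wt_fraction)
        wells.append(
            WellRecord(
                assay_target=target,
                standard_id="WT_ONLY",
                plate_id=plate_id,
                instrument_id=instrument_id,
                operator_id=operator_id,
                replicate_index=rep,
                ct=ct,
                tm=tm,
                wt_background_copies=wt_copies,
                truth_mutant_copies=0.0,
                sequencing_confirmed=confirmed,
            )
        )
    return wells


def ground_truth_table(cfg: SimulationConfig) -> pd.DataFrame:
    """Expected occupancy per (target, standard) under the generator.

    Used as the recovery oracle by tests: expected empty fraction is
    exp(-nominal mean copies).
    """
    rows = [
        {
            "target": str(target),
            "standard": std.name,
            "nominal_mean_copies": std.nominal_mean_copies,
            "expected_empty_fraction": expected_empty_fraction(std.nominal_mean_copies),
        }
        for target in cfg.curves
        for std in cfg.standards
    ]
    return pd.DataFrame(
        rows, columns=["target", "standard", "nominal_mean_copies", "expected_empty_fraction"]
    )
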