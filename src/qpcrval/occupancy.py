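"""Poisson occupancy statistics for limiting-dilution wells.

When a mean of lam mutant copies is pipetted per well, the number of
copies actually landing in a well is Poisson(lam), so a fraction
exp(-lam) of wells receive zero copies and produce no signal ("dropout").
Observed dropout therefore estimates the input: lam = -ln(empty
fraction).  A second estimator uses the full observed distribution — the
empty-well count plus the interpolated copy numbers of the positive
wells — via maximum likelihood.  Both are provided, along with the
theoretical occupancy table and a binomial proficiency check of observed
positives against the Poisson expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "GT10",
    "OccupancyEstimate",
    "expected_empty_fraction",
    "expected_empty_count",
    "theoretical_empty_table",
    "lambda_from_dropout",
    "lambda_mle",
    "zero_truncated_mean",
    "proficiency_check",
    "format_lambda",
]


class _Gt10Sentinel:
    """Rendered ">10": no empty wells were observed, so -ln(0) is undefined
    and the dropout estimator can only bound the input from below."""

    _instance = None
    __slots__ = ()

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return ">10"


GT10 = _Gt10Sentinel()


@dataclass(frozen=True)
class OccupancyEstimate:
    """Dropout-based occupancy summary for one dilution level."""

    n_wells: int
    n_empty: int
    empty_fraction: float
    lambda_dropout: float | _Gt10Sentinel
    lambda_mle: float | None = None
    ci95: tuple[float, float] | None = None

    def __post_init__(self):
        if not 0 <= self.n_empty <= self.n_wells:
            raise ValueError("require 0 <= n_empty <= n_wells")

    @property
    def saturated(self) -> bool:
        """True when no empties were seen and only a lower bound exists."""
        return self.lambda_dropout is GT10


def expected_empty_fraction(lam: float) -> float:
    """Poisson zero-class probability exp(-lam): the expected empty-well fraction."""
    if lam < 0:
        raise ValueError("mean copies per well must be non-negative")
    return math.exp(-lam)


def expected_empty_count(lam: float, n_wells: int) -> int:
    """Expected number of empty wells among n_wells, rounded to the nearest well."""
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    return round(n_wells * expected_empty_fraction(lam))


def theoretical_empty_table(lams: Iterable[float]) -> pd.DataFrame:
    """Theoretical percent of empty replicates by mean copy input.

    Percentages are 100*exp(-lam) rounded to two decimals, the convention
    used in dilution-assay occupancy tables.
    """
    rows = [
        {"mean_copies_per_well": lam, "percent_empty": round(100.0 * expected_empty_fraction(lam), 2)}
        for lam in lams
    ]
    return pd.DataFrame(rows, columns=["mean_copies_per_well", "percent_empty"])


def lambda_from_dropout(n_empty: int, n_wells: int, alpha: float = 0.05) -> OccupancyEstimate:
    """Estimate mean copies per well from the observed dropout fraction.

    lambda = -ln(n_empty / n_wells).  With zero observed empties the point
    estimate is undefined (the input is simply large) and the sentinel
    :data:`GT10` is returned.  The 95% CI inverts exact Clopper-Pearson
    bounds on the empty fraction through -ln; a higher empty fraction
    means a lower lambda, so the bounds swap.
    """
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    if not 0 <= n_empty <= n_wells:
        raise ValueError("require 0 <= n_empty <= n_wells")
    frac = n_empty / n_wells
    p_lo, p_hi = proportion_confint(n_empty, n_wells, alpha=alpha, method="beta")
    lam_hi = math.inf if p_lo == 0 else -math.log(p_lo)
    lam_lo = 0.0 if p_hi >= 1 else -math.log(p_hi)
    if n_empty == 0:
        return OccupancyEstimate(
            n_wells=n_wells,
            n_empty=0,
            empty_fraction=0.0,
            lambda_dropout=GT10,
            ci95=(lam_lo, lam_hi),
        )
    return OccupancyEstimate(
        n_wells=n_wells,
        n_empty=n_empty,
        empty_fraction=frac,
        lambda_dropout=-math.log(frac),
        ci95=(lam_lo, lam_hi),
    )


def _censored_negloglik(lam: float, n_empty: int, counts: np.ndarray) -> float:
    # empty wells: zero-class probability exp(-lam);
    # positive wells: P(occupied) * zero-truncated mass = Poisson mass at k >= 1
    return float(n_empty * lam + counts.size * lam - np.sum(counts * math.log(lam)) + np.sum(special.gammaln(counts + 1)))


def lambda_mle(
    well_copy_obs: Sequence[float],
    mode: str = "censored_positive",
    upper: float = 50.0,
    xtol: float = 1e-8,
) -> float:
    """Maximum-likelihood mean copies per well from per-well observations.

    ``well_copy_obs`` holds 0.0 for empty wells and the interpolated copy
    number for wells that amplified.

    ``rounded_poisson``
        Round every observation to the nearest non-negative integer and
        fit a plain Poisson: the MLE is the sample mean of the rounded
        counts.
    ``censored_positive`` (default)
        Treat empties as the Poisson zero class (probability exp(-lam))
        and amplified wells as zero-truncated draws whose rounded count is
        clamped to at least 1 — using both the dropout rate and the
        interpolated distribution.  Maximised numerically on (0, upper].
    """
    obs = np.asarray(list(well_copy_obs), dtype=float)
    if obs.size == 0:
        raise ValueError("need at least one observation")
    if np.any(obs < 0):
        raise ValueError("copy observations must be non-negative")

    if mode == "rounded_poisson":
        return float(np.mean(np.rint(obs)))
    if mode != "censored_positive":
        raise ValueError(f"unknown mode {mode!r}")

    positive = obs[obs > 0]
    n_empty = obs.size - positive.size
    if positive.size == 0:
        return 0.0
    counts = np.maximum(np.rint(positive), 1.0)
    res = optimize.minimize_scalar(
        _censored_negloglik,
        args=(n_empty, counts),
        bounds=(1e-12, upper),
        method="bounded",
        options={"xatol": xtol},
    )
    if not res.success:
        raise RuntimeError(f"censored Poisson MLE failed to converge: {res.message}")
    return float(res.x)


def zero_truncated_mean(lam: float) -> float:
    """Mean copies among occupied wells: lam / (1 - exp(-lam))."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    return lam / (1.0 - math.exp(-lam))


def proficiency_check(
    n_positive: int, n_wells: int, lam: float, alpha: float = 0.05
) -> tuple[bool, float]:
    """Exact binomial check of observed positives against the Poisson expectation.

    Under input lam, each well is positive with probability 1 - exp(-lam).
    A two-sided exact binomial test (summing outcome probabilities no
    larger than the observed one) compares n_positive with that
    expectation; the level is proficient when p >= alpha.
    """
    if not 0 <= n_positive <= n_wells:
        raise ValueError("require 0 <= n_positive <= n_wells")
    if lam < 0:
        raise ValueError("lam must be non-negative")
    p_positive = 1.0 - expected_empty_fraction(lam)
    result = stats.binomtest(n_positive, n_wells, p_positive, alternative="two-sided")
    return bool(result.pvalue >= alpha), float(result.pvalue)


def format_lambda(value: float | _Gt10Sentinel, decimals: int = 2) -> str:
    """Render a dropout estimate, using ">10" for the saturated sentinel."""
    if value is GT10:
        return ">10"
    text = f"{value:.{decimals}f}"
    # drop a trailing zero so 0.80 prints as 0.8, matching occupancy-table convention
    if decimals == 2 and text.endswith("0"):
        text = text[:-1]
    return text
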