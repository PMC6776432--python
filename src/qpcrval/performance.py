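"""Assay performance metrics: confusion counts, LoD, rates and precision.

Covers the reporting side of an analytical validation: sensitivity and
specificity from truth-labelled calls, the limit of detection expressed
as a mutant allele fraction (MAF) against a fixed wild-type background,
exact binomial (Clopper-Pearson) confidence intervals on detection
rates, and inter-/intra-assay reproducibility of Ct with the 1-Ct
standard-deviation pass rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .occupancy import proficiency_check
from .plates import QcConfig, WellRecord

__all__ = [
    "ConfusionCounts",
    "LodLevel",
    "LodResult",
    "RateWithCi",
    "confusion_metrics",
    "call_well",
    "determine_lod",
    "detection_rate",
    "reproducibility_summary",
]


def _display_rate(value: float | None) -> str:
    # reporting convention: anything >= 99% (including exactly 100%) prints ">99%"
    if value is None:
        return "NA"
    if value >= 0.99:
        return ">99%"
    return f"{100.0 * value:.2f}%"


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FN/FP/TN with formatted sensitivity and specificity."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def sensitivity(self) -> float | None:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else None

    @property
    def specificity(self) -> float | None:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else None

    @property
    def sensitivity_display(self) -> str:
        return _display_rate(self.sensitivity)

    @property
    def specificity_display(self) -> str:
        return _display_rate(self.specificity)

    @property
    def n_calls(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion_metrics(calls: Iterable[tuple[bool, bool]]) -> ConfusionCounts:
    """Tally (predicted_positive, truth_positive) calls into a confusion matrix."""
    tp = fn = fp = tn = 0
    n = 0
    for predicted, truth in calls:
        n += 1
        if truth:
            if predicted:
                tp += 1
            else:
                fn += 1
        else:
            if predicted:
                fp += 1
            else:
                tn += 1
    if n == 0:
        raise ValueError("need at least one call")
    return ConfusionCounts(tp=tp, fn=fn, fp=fp, tn=tn)


def call_well(well: WellRecord, qc: QcConfig) -> bool:
    """Mutation call for one well after all orthogonal gates.

    Positive iff a QC-passing Ct is present, the melt peak falls inside
    the target's specific-product window, and sequencing (when performed)
    confirmed the mutation.  A product that sequences as wild type is a
    negative call regardless of its Ct.
    """
    if well.ct is None:
        return False
    if well.ct <= qc.min_ct or well.ct >= qc.max_ct:
        return False
    if well.tm is None:
        return False
    lo, hi = qc.tm_window(well.assay_target)
    if not lo <= well.tm <= hi:
        return False
    if well.sequencing_confirmed is False:
        return False
    return True


@dataclass(frozen=True)
class LodLevel:
    """Detection outcome at one spiked mutant copy level."""

    mutant_copies: float
    wt_copies: int
    n_detected: int
    n_wells: int


def maf(mutant_copies: float, wt_copies: float) -> float:
    """Mutant allele fraction mut / (mut + wt)."""
    return mutant_copies / (mutant_copies + wt_copies)


def format_maf_percent(fraction: float) -> str:
    """MAF as a percent with 2 decimals, floored at 0.01%.

    The floor keeps a genuinely detected sub-0.01% fraction (e.g. one
    copy in 14,000: 0.0071%) from vanishing to "0.00%" under rounding.
    """
    return f"{max(round(100.0 * fraction, 2), 0.01):.2f}%"


@dataclass(frozen=True)
class LodResult:
    lod_copies: float | None
    wt_copies: int | None

    @property
    def defined(self) -> bool:
        return self.lod_copies is not None

    @property
    def lod_maf(self) -> float | None:
        if not self.defined:
            return None
        return maf(self.lod_copies, self.wt_copies)

    @property
    def lod_maf_display(self) -> str:
        if not self.defined:
            return "not established"
        return format_maf_percent(self.lod_maf)


def determine_lod(
    levels: Sequence[LodLevel],
    rule: Callable[[LodLevel], bool] | None = None,
) -> LodResult:
    """Lowest mutant copy level whose detection satisfies the rule.

    ``levels`` must be sorted by mutant_copies descending.  The default
    rule accepts a level when its positive-well count is consistent with
    the Poisson occupancy expectation at that copy input (exact binomial
    proficiency check).  If no level qualifies the LoD is undefined.
    """
    if not levels:
        raise ValueError("need at least one level")
    if rule is None:
        rule = lambda lv: proficiency_check(lv.n_detected, lv.n_wells, lv.mutant_copies)[0]
    qualifying = [lv for lv in levels if rule(lv)]
    if not qualifying:
        return LodResult(lod_copies=None, wt_copies=None)
    lowest = min(qualifying, key=lambda lv: lv.mutant_copies)
    return LodResult(lod_copies=lowest.mutant_copies, wt_copies=lowest.wt_copies)


@dataclass(frozen=True)
class RateWithCi:
    """Detection rate with exact (Clopper-Pearson) 95% CI."""

    n_tested: int
    n_detected: int
    rate: float
    ci95: tuple[float, float]

    @property
    def percent_display(self) -> str:
        return f"{100.0 * self.rate:.2f}%"


def detection_rate(n_detected: int, n_tested: int, alpha: float = 0.05) -> RateWithCi:
    """Binomial rate n_detected / n_tested with an exact 95% CI."""
    if n_tested < 1:
        raise ValueError("n_tested must be >= 1")
    if not 0 <= n_detected <= n_tested:
        raise ValueError("require 0 <= n_detected <= n_tested")
    lo, hi = proportion_confint(n_detected, n_tested, alpha=alpha, method="beta")
    return RateWithCi(
        n_tested=n_tested,
        n_detected=n_detected,
        rate=n_detected / n_tested,
        ci95=(float(lo), float(hi)),
    )


def reproducibility_summary(
    wells: Iterable[WellRecord],
    mode: str = "intra",
    group_field: str = "plate_id",
    sd_limit: float = 1.0,
) -> pd.DataFrame:
    """Per-(group, standard) Ct precision with the 1-Ct SD pass rule.

    ``intra`` summarises raw replicate Cts within each (group, standard)
    cell; ``inter`` first averages Ct per plate and summarises those
    plate means within each (group, standard) cell, measuring agreement
    between runs.  Cells with fewer than two observations are flagged
    insufficient (pass = NA) and excluded from pass counts.  Empty wells
    carry no Ct and are ignored.
    """
    if mode not in ("intra", "inter"):
        raise ValueError(f"unknown mode {mode!r}")

    rows = []
    for w in wells:
        if w.ct is None:
            continue
        rows.append(
            {
                "group": getattr(w, group_field),
                "standard": w.standard_id,
                "plate": w.plate_id,
                "ct": w.ct,
            }
        )
    frame = pd.DataFrame(rows, columns=["group", "standard", "plate", "ct"])
    if mode == "inter":
        frame = (
            frame.groupby(["group", "standard", "plate"], as_index=False)["ct"].mean()
        )

    out = []
    for (group, standard), cell in frame.groupby(["group", "standard"]):
        n = len(cell)
        mean_ct = float(cell["ct"].mean())
        if n < 2:
            out.append(
                {
                    "group": group,
                    "standard": standard,
                    "n": n,
                    "mean_ct": round(mean_ct, 3),
                    "sd_ct": math.nan,
                    "cv_percent": math.nan,
                    "pass": pd.NA,
                }
            )
            continue
        sd = float(cell["ct"].std(ddof=1))
        out.append(
            {
                "group": group,
                "standard": standard,
                "n": n,
                "mean_ct": round(mean_ct, 3),
                "sd_ct": round(sd, 3),
                "cv_percent": round(100.0 * sd / mean_ct, 3) if mean_ct else math.nan,
                "pass": bool(sd <= sd_limit),
            }
        )
    return pd.DataFrame(out, columns=["group", "standard", "n", "mean_ct", "sd_ct", "cv_percent", "pass"])
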