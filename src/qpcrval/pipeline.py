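"""Full validation run: QC -> curves -> occupancy -> delta-Ct -> performance.

Two entry points:

* :func:`run_validation` executes the whole analysis on either a set of
  plate CSVs or a simulation config (exactly one), and returns a report
  bundle of named tables plus a summary dict.
* :func:`fixture_report` recomputes the desk-scale statistics from the
  bundled validation-study reference tables (delta-Ct summary, dropout
  copies, confusion metrics, clinical rates) without any plate data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import pandas as pd

from . import datasets
from .curves import MasterCurve, build_master_curve, curve_table, interpolate_copies
from .errors import ConfigurationError
from .interference import delta_summary, delta_table, pair_deltas
from .occupancy import format_lambda, lambda_from_dropout, lambda_mle
from .performance import (
    LodLevel,
    call_well,
    confusion_metrics,
    detection_rate,
    determine_lod,
    reproducibility_summary,
)
from .plates import (
    AssayTarget,
    QcConfig,
    WellRecord,
    apply_qc,
    default_qc_config,
    read_plate_table,
    write_report,
)
from .simulate import SimulationConfig, simulate_dilution_series, simulate_wt_specificity_panel

__all__ = ["RunConfig", "ReportBundle", "run_validation", "fixture_report", "simulate_validation_wells"]

log = logging.getLogger("qpcrval")

MUTANT_TARGETS = (
    AssayTarget.EGFR_DEL19,
    AssayTarget.EGFR_L858R,
    AssayTarget.EGFR_T790M,
    AssayTarget.BRAF_V600,
    AssayTarget.KRAS_EX2,
)
HIGH_COPY_STANDARDS = ("A", "B", "C", "D")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full validation run.

    Exactly one of ``plate_paths`` (measured data) or ``simulation``
    (synthetic data) must be given.
    """

    plate_paths: tuple[str, ...] = ()
    simulation: SimulationConfig | None = None
    qc: QcConfig = field(default_factory=default_qc_config)
    n_plates: int = 10
    n_instruments: int = 5
    n_operators: int = 3
    specificity_wells: int = 112
    targets: tuple[AssayTarget, ...] = MUTANT_TARGETS

    def __post_init__(self):
        if bool(self.plate_paths) == (self.simulation is not None):
            raise ConfigurationError(
                "exactly one of plate_paths or simulation must be provided"
            )


@dataclass
class ReportBundle:
    tables: dict[str, pd.DataFrame]
    summary: dict

    def write(self, path, format: str = "tsv") -> None:
        write_report(self.tables, path, format=format)


def simulate_validation_wells(cfg: RunConfig) -> list[WellRecord]:
    """Generate the complete synthetic validation data set.

    Per mutant target: ``n_plates`` dilution-series plates with the WT
    background (instruments and operators assigned round-robin), one
    paired no-background series for the interference analysis, and a
    WT-only specificity panel.
    """
    sim = cfg.simulation
    wells: list[WellRecord] = []
    for target in cfg.targets:
        for i in range(1, cfg.n_plates + 1):
            wells.extend(
                simulate_dilution_series(
                    sim,
                    target,
                    plate_id=f"P{i}",
                    instrument_id=f"I{(i - 1) % cfg.n_instruments + 1}",
                    operator_id=f"O{(i - 1) % cfg.n_operators + 1}",
                )
            )
        no_wt = tuple(replace(std, wt_copies=0) for std in sim.standards)
        wells.extend(
            simulate_dilution_series(
                sim, target, plate_id="P1_noWT", instrument_id="I1", operator_id="O1",
                standards=no_wt,
            )
        )
        wells.extend(
            simulate_wt_specificity_panel(sim, cfg.specificity_wells, target=target)
        )
    return wells


def _standard_copies(sim: SimulationConfig | None) -> dict[str, float]:
    if sim is not None:
        return {s.name: s.nominal_mean_copies for s in sim.standards}
    table = datasets.load_dilution_standards()
    return dict(zip(table["name"], table["nominal_mean_copies"].astype(float)))


def run_validation(cfg: RunConfig) -> ReportBundle:
    """Execute the validation analysis and return the report bundle."""
    if cfg.simulation is not None:
        wells = simulate_validation_wells(cfg)
        log.info("simulated %d wells", len(wells))
    else:
        wells = []
        for path in cfg.plate_paths:
            wells.extend(read_plate_table(path))
        log.info("read %d wells from %d plate files", len(wells), len(cfg.plate_paths))

    copies_of = _standard_copies(cfg.simulation)
    passing, flagged = apply_qc(wells, cfg.qc)
    log.info("QC: %d passing, %d flagged", len(passing), len(flagged))

    tables: dict[str, pd.DataFrame] = {}
    summary: dict = {"n_wells": len(wells), "n_qc_passing": len(passing), "n_qc_flagged": len(flagged)}

    # --- standard + master curves (dilution wells with WT background) ------
    masters: dict[AssayTarget, MasterCurve] = {}
    curve_rows = []
    for target in cfg.targets:
        by_plate: dict[str, list[tuple[float, float]]] = {}
        for w in passing:
            if (
                w.assay_target is target
                and w.standard_id in HIGH_COPY_STANDARDS
                and w.ct is not None
                and w.wt_background_copies > 0
                and w.standard_id in copies_of
            ):
                by_plate.setdefault(w.plate_id, []).append((copies_of[w.standard_id], w.ct))
        if not by_plate:
            continue
        mc = build_master_curve(by_plate, group_id=f"{target}:master")
        masters[target] = mc
        tab = curve_table(mc.members + (mc.master,))
        tab.insert(0, "target", str(target))
        curve_rows.append(tab)
    if curve_rows:
        tables["curves"] = pd.concat(curve_rows, ignore_index=True)
        summary["master_r_squared"] = {
            str(t): mc.master.r_squared for t, mc in masters.items()
        }

    # --- occupancy at limiting dilution ------------------------------------
    occ_rows = []
    for target in cfg.targets:
        master = masters.get(target)
        for std_name, nominal in sorted(copies_of.items()):
            cell = [
                w
                for w in passing
                if w.assay_target is target
                and w.standard_id == std_name
                and w.wt_background_copies > 0
            ]
            if not cell or nominal > 100:
                continue
            n_empty = sum(w.is_empty for w in cell)
            est = lambda_from_dropout(n_empty, len(cell))
            obs = [
                0.0 if w.is_empty else interpolate_copies(w.ct, master.master)
                for w in cell
            ] if master else None
            occ_rows.append(
                {
                    "target": str(target),
                    "standard": std_name,
                    "nominal_copies": nominal,
                    "n_empty": n_empty,
                    "n_wells": len(cell),
                    "percent_empty": round(100.0 * n_empty / len(cell), 1),
                    "lambda_dropout": format_lambda(est.lambda_dropout),
                    "lambda_mle": round(lambda_mle(obs), 2) if obs is not None else None,
                }
            )
    if occ_rows:
        tables["occupancy"] = pd.DataFrame(occ_rows)

    # --- WT-background interference (paired delta Ct) -----------------------
    # paired single-run design: the with-WT plate P1 against its no-WT twin
    interference_wells = [
        w for w in passing if w.plate_id in ("P1", "P1_noWT")
    ] if cfg.simulation is not None else passing
    mean_rows = [
        (str(t), s, "with_wt" if has_wt else "no_wt", m)
        for (t, s, has_wt), m in _group_means(interference_wells)
    ]
    seen = {(t, s, c) for t, s, c, _ in mean_rows}
    paired = [
        row
        for row in mean_rows
        if {(row[0], row[1], "no_wt"), (row[0], row[1], "with_wt")} <= seen
    ]
    if paired:
        pairs = pair_deltas(paired)
        if len(pairs) >= 2:
            ds = delta_summary(pairs)
            tables["delta_ct"] = delta_table(ds)
            summary["delta_ct"] = {
                "mean_signed": round(ds.mean_signed, 2),
                "sd_signed": round(ds.sd_signed, 2),
                "mean_abs": round(ds.mean_abs, 2),
                "n_pairs": len(pairs),
            }

    # --- analytical performance ---------------------------------------------
    perf_rows = []
    for target in cfg.targets:
        sens_calls = [
            (call_well(w, cfg.qc), True)
            for w in wells
            if w.assay_target is target
            and w.standard_id in HIGH_COPY_STANDARDS
            and (w.truth_mutant_copies or 0) > 0
        ]
        spec_calls = [
            (call_well(w, cfg.qc), False)
            for w in wells
            if w.assay_target is target and w.standard_id == "WT_ONLY"
        ]
        if not sens_calls and not spec_calls:
            continue
        cm = confusion_metrics(sens_calls + spec_calls) if (sens_calls or spec_calls) else None
        lod_levels = []
        for std_name, nominal in sorted(copies_of.items(), key=lambda kv: -kv[1]):
            cell = [
                w
                for w in wells
                if w.assay_target is target
                and w.standard_id == std_name
                and w.wt_background_copies > 0
            ]
            if not cell or nominal > 15:
                continue
            lod_levels.append(
                LodLevel(
                    mutant_copies=nominal,
                    wt_copies=cell[0].wt_background_copies,
                    n_detected=sum(call_well(w, cfg.qc) for w in cell),
                    n_wells=len(cell),
                )
            )
        lod = determine_lod(lod_levels) if lod_levels else None
        perf_rows.append(
            {
                "target": str(target),
                "tp": cm.tp,
                "fn": cm.fn,
                "fp": cm.fp,
                "tn": cm.tn,
                "sensitivity": cm.sensitivity_display,
                "specificity": cm.specificity_display,
                "lod_maf": lod.lod_maf_display if lod else "NA",
            }
        )
    if perf_rows:
        tables["performance"] = pd.DataFrame(perf_rows)
        summary["performance"] = {r["target"]: r for r in perf_rows}

    # --- reproducibility -----------------------------------------------------
    # precision cells are per assay, like the intra/inter-assay tables
    intra_frames, inter_frames = [], []
    for target in cfg.targets:
        curve_wells = [
            w
            for w in passing
            if w.assay_target is target
            and w.standard_id in HIGH_COPY_STANDARDS
            and w.wt_background_copies > 0
            and w.plate_id != "P1_noWT"
        ]
        if not curve_wells:
            continue
        for mode, frames, field_name in (
            ("intra", intra_frames, "plate_id"),
            ("inter", inter_frames, "instrument_id"),
        ):
            tab = reproducibility_summary(curve_wells, mode=mode, group_field=field_name)
            tab.insert(0, "target", str(target))
            frames.append(tab)
    if intra_frames:
        intra = pd.concat(intra_frames, ignore_index=True)
        tables["reproducibility_intra"] = intra
        tables["reproducibility_inter"] = pd.concat(inter_frames, ignore_index=True)
        scored = intra[intra["pass"].notna()]
        summary["reproducibility"] = {
            "intra_pass": int(scored["pass"].sum()),
            "intra_cells": int(len(scored)),
        }

    return ReportBundle(tables=tables, summary=summary)


def _group_means(wells: Sequence[WellRecord]):
    """Mean Ct per (target, standard, WT present), amplified wells only."""
    acc: dict[tuple[AssayTarget, str, bool], list[float]] = {}
    for w in wells:
        if w.ct is None or w.standard_id in ("WT_ONLY", "NTC"):
            continue
        acc.setdefault((w.assay_target, w.standard_id, w.wt_background_copies > 0), []).append(w.ct)
    for key, cts in acc.items():
        yield key, sum(cts) / len(cts)


# ---------------------------------------------------------------------------
# Fixture-driven report (published desk-scale numbers)
# ---------------------------------------------------------------------------

def fixture_report() -> dict:
    """Recompute the validation statistics from the bundled reference tables.

    Returns a dict with the delta-Ct summary, the dropout-based copy
    estimates per dilution level, per-assay confusion metrics, the
    clinical specificity and detection rates with exact 95% CIs.
    """
    out: dict = {}

    means = datasets.load_wt_interference_means()
    rows = [
        (r.target, r.standard, cond, ct)
        for r in means.itertuples(index=False)
        for cond, ct in (("no_wt", r.mean_ct_no_wt), ("with_wt", r.mean_ct_with_wt))
    ]
    ds = delta_summary(pair_deltas(rows))
    out["delta_ct"] = {
        "mean_signed": ds.mean_signed,
        "sd_signed": ds.sd_signed,
        "mean_abs": ds.mean_abs,
        "n_pairs": len(ds.pairs),
    }

    occ = datasets.load_occupancy_counts()
    occ_rows = []
    for r in occ.itertuples(index=False):
        if pd.isna(r.n_wells):
            continue
        est = lambda_from_dropout(int(r.n_empty), int(r.n_wells))
        occ_rows.append(
            {
                "target": r.target,
                "standard": r.standard,
                "n_empty": int(r.n_empty),
                "n_wells": int(r.n_wells),
                "lambda_dropout": format_lambda(est.lambda_dropout),
                "printed": r.printed_poisson_copies,
            }
        )
    out["occupancy"] = occ_rows

    perf = datasets.load_analytical_performance()
    perf_out = {}
    for r in perf.itertuples(index=False):
        calls = [(True, True)] * (r.n_positive - r.fn) + [(False, True)] * r.fn
        calls += [(True, False)] * r.fp + [(False, False)] * (r.n_negative - r.fp)
        cm = confusion_metrics(calls)
        perf_out[r.target] = {
            "sensitivity": cm.sensitivity,
            "sensitivity_display": cm.sensitivity_display,
            "specificity": cm.specificity,
            "specificity_display": cm.specificity_display,
            "n_positive": int(r.n_positive),
        }
    perf_out["pooled_positive_tests"] = int(perf["n_positive"].sum())
    out["analytical_performance"] = perf_out

    spec = datasets.load_clinical_specificity()
    out["clinical_specificity"] = {
        r.target: detection_rate(int(r.detected), int(r.tested)) for r in spec.itertuples(index=False)
    }

    lung = datasets.load_lung_detection()
    out["lung_rates"] = {
        r.target: detection_rate(int(r.detected), int(r.tested)) for r in lung.itertuples(index=False)
    }

    latam = datasets.load_latam_detection()
    out["latam_rates"] = {
        (r.cohort, r.source, r.target): detection_rate(int(r.positive), int(r.n))
        for r in latam.itertuples(index=False)
    }
    return out
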