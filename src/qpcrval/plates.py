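"""Plate-level qPCR data model, CSV/TSV I/O and pre-statistics QC.

The unit of observation throughout the package is a *well*: one qPCR
reaction characterised by its threshold cycle (Ct) and the melt-peak
temperature (Tm) of its product.  A well whose fluorescence never crossed
the detection threshold has *no* Ct — that absence is meaningful (it is
the "empty well" the Poisson occupancy statistics are built on) and is
encoded as a blank cell on disk and ``None`` in memory.  A Ct of 0 is
rejected outright so that "no amplification" can never be confused with
"amplified at cycle zero".
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, PlateParseError, SchemaError

__all__ = [
    "AssayTarget",
    "WellRecord",
    "DilutionStandard",
    "QcConfig",
    "read_plate_table",
    "write_plate_table",
    "apply_qc",
    "write_report",
    "PLATE_COLUMNS",
]


class AssayTarget(str, enum.Enum):
    """The mutation hotspot (or wild-type reference) an assay interrogates."""

    EGFR_DEL19 = "EGFR_DEL19"
    EGFR_L858R = "EGFR_L858R"
    EGFR_T790M = "EGFR_T790M"
    BRAF_V600 = "BRAF_V600"
    KRAS_EX2 = "KRAS_EX2"
    EGFR_WT = "EGFR_WT"

    def __str__(self) -> str:  # keeps report files free of the enum repr
        return self.value


#: physically plausible melt-peak range for any amplicon, °C
_TM_RANGE = (50.0, 100.0)
#: hard upper bound on Ct used by the record invariant (a run length cap)
MAX_CYCLES = 45.0


@dataclass(frozen=True)
class WellRecord:
    """One qPCR well.

    ``ct is None`` means the well never amplified (an informative empty
    well, not a QC failure).  ``truth_mutant_copies`` is the nominal mean
    mutant input for control/simulated wells; ``sequencing_confirmed``
    records orthogonal sequence confirmation of an amplified product
    (``None`` = not sequenced).
    """

    assay_target: AssayTarget
    standard_id: str
    plate_id: str
    instrument_id: str
    operator_id: str
    replicate_index: int
    ct: float | None = None
    tm: float | None = None
    wt_background_copies: int = 0
    truth_mutant_copies: float | None = None
    sequencing_confirmed: bool | None = None

    def __post_init__(self):
        if self.replicate_index < 1:
            raise ValueError(f"replicate_index must be >= 1, got {self.replicate_index}")
        if self.ct is not None and not 0.0 < self.ct < MAX_CYCLES:
            raise ValueError(f"ct must lie in (0, {MAX_CYCLES}), got {self.ct}")
        if self.tm is not None:
            if self.ct is None:
                raise ValueError("a well without a Ct cannot carry a melt temperature")
            if not _TM_RANGE[0] <= self.tm <= _TM_RANGE[1]:
                raise ValueError(f"tm outside plausible range {_TM_RANGE}: {self.tm}")
        if self.wt_background_copies < 0:
            raise ValueError("wt_background_copies must be non-negative")
        if self.truth_mutant_copies is not None and self.truth_mutant_copies < 0:
            raise ValueError("truth_mutant_copies must be non-negative")

    @property
    def is_empty(self) -> bool:
        """True when no amplification signal was recorded."""
        return self.ct is None


@dataclass(frozen=True)
class DilutionStandard:
    """One level of the mutant dilution series.

    ``nominal_mean_copies`` is the expected mean mutant input per well and
    may be fractional at the bottom of a halving series (e.g. 0.875).
    ``ddpcr_reference_copies`` is the orthogonal droplet-digital
    quantitation of the same material, when measured.
    """

    name: str
    nominal_mean_copies: float
    ddpcr_reference_copies: float | None = None
    wt_copies: int = 14_000
    n_replicates: int = 3

    def __post_init__(self):
        if self.nominal_mean_copies <= 0:
            raise ValueError("nominal_mean_copies must be positive")
        if self.ddpcr_reference_copies is not None and self.ddpcr_reference_copies <= 0:
            raise ValueError("ddpcr_reference_copies must be positive")
        if self.wt_copies < 0:
            raise ValueError("wt_copies must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def halved(self, name: str, n_replicates: int | None = None) -> "DilutionStandard":
        """The next level of a 1:2 serial dilution of this standard."""
        return replace(
            self,
            name=name,
            nominal_mean_copies=self.nominal_mean_copies / 2.0,
            ddpcr_reference_copies=None,
            n_replicates=self.n_replicates if n_replicates is None else n_replicates,
        )


@dataclass(frozen=True)
class QcConfig:
    """Well-level QC gates applied before any statistics.

    ``tm_windows`` maps each assay target to the (low, high) melt-peak
    window of its *specific* product; a peak outside the window marks a
    non-specific amplicon.  The default window is a configuration value,
    not a measured one, and should be recalibrated per assay.
    """

    min_ct: float = 10.0
    max_ct: float = 45.0
    tm_windows: Mapping[AssayTarget, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if not 0 < self.min_ct < self.max_ct:
            raise ValueError("require 0 < min_ct < max_ct")
        for target, (lo, hi) in self.tm_windows.items():
            if not lo < hi:
                raise ValueError(f"tm window for {target} has low >= high")

    def tm_window(self, target: AssayTarget) -> tuple[float, float]:
        try:
            return self.tm_windows[target]
        except KeyError:
            raise ConfigurationError(
                f"no melt-temperature window configured for assay target {target}"
            ) from None


#: default specific-product window shipped with the simulator defaults (°C)
DEFAULT_TM_WINDOW = (80.5, 83.5)


def default_qc_config() -> QcConfig:
    """QC gates with the simulator's specific-product melt window on every assay."""
    return QcConfig(tm_windows={t: DEFAULT_TM_WINDOW for t in AssayTarget})


# ---------------------------------------------------------------------------
# CSV plate tables
# ---------------------------------------------------------------------------

#: canonical column order of the plate-table CSV dialect
PLATE_COLUMNS = (
    "target",
    "standard",
    "plate",
    "instrument",
    "operator",
    "replicate",
    "ct",
    "tm",
    "wt_copies",
    "truth_copies",
    "seq_confirmed",
)

_REQUIRED = ("target", "standard", "plate", "instrument", "operator", "replicate", "ct")


def _parse_optional_float(cell, name: str, row: int, positive: bool = True) -> float | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or str(cell).strip() == "":
        return None
    try:
        value = float(cell)
    except (TypeError, ValueError):
        raise PlateParseError(f"non-numeric {name} value {cell!r}", row=row) from None
    if positive and value <= 0:
        raise PlateParseError(
            f"{name} must be positive ({name}=0 is not a valid empty-well encoding; "
            "leave the cell blank instead)",
            row=row,
        )
    return value


def _parse_optional_bool(cell, row: int) -> bool | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or str(cell).strip() == "":
        return None
    text = str(cell).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise PlateParseError(f"non-boolean seq_confirmed value {cell!r}", row=row)


def read_plate_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> list[WellRecord]:
    """Read a plate-table CSV into WellRecords, preserving row order.

    Parameters
    ----------
    path
        CSV file with a header row; see ``PLATE_COLUMNS`` for the default
        column names.
    schema
        Optional mapping from canonical names (``"ct"``, ``"target"``, ...)
        to the column names actually present in the file.

    A blank ``ct`` cell yields ``ct=None`` (an empty well).  Missing
    required columns raise :class:`SchemaError`; unparseable numeric cells
    raise :class:`PlateParseError` carrying the 1-based data row number.
    """
    mapping = dict.fromkeys(PLATE_COLUMNS)
    for name in PLATE_COLUMNS:
        mapping[name] = name
    if schema:
        mapping.update(schema)

    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for name in _REQUIRED:
        if mapping[name] not in frame.columns:
            raise SchemaError(f"required column {mapping[name]!r} missing from {path}")

    records: list[WellRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        get = lambda name: getattr(row, mapping[name]) if mapping[name] in frame.columns else ""
        try:
            target = AssayTarget(get("target"))
        except ValueError:
            raise PlateParseError(f"unknown assay target {get('target')!r}", row=i) from None
        try:
            replicate = int(get("replicate"))
        except ValueError:
            raise PlateParseError(f"non-integer replicate {get('replicate')!r}", row=i) from None
        wt_cell = get("wt_copies")
        try:
            wt = int(float(wt_cell)) if str(wt_cell).strip() else 0
        except ValueError:
            raise PlateParseError(f"non-numeric wt_copies {wt_cell!r}", row=i) from None
        try:
            records.append(
                WellRecord(
                    assay_target=target,
                    standard_id=str(get("standard")),
                    plate_id=str(get("plate")),
                    instrument_id=str(get("instrument")),
                    operator_id=str(get("operator")),
                    replicate_index=replicate,
                    ct=_parse_optional_float(get("ct"), "ct", i),
                    tm=_parse_optional_float(get("tm"), "tm", i, positive=False),
                    wt_background_copies=wt,
                    truth_mutant_copies=_parse_optional_float(
                        get("truth_copies"), "truth_copies", i, positive=False
                    ),
                    sequencing_confirmed=_parse_optional_bool(get("seq_confirmed"), i),
                )
            )
        except ValueError as exc:
            raise PlateParseError(str(exc), row=i) from None
    return records


def _format_float(value: float | None, decimals: int = 4) -> str:
    if value is None:
        return ""
    return f"{value:.{decimals}f}".rstrip("0").rstrip(".")


def write_plate_table(wells: Iterable[WellRecord], path: str | Path) -> None:
    """Write WellRecords in the CSV dialect :func:`read_plate_table` reads."""
    rows = []
    for w in wells:
        rows.append(
            {
                "target": str(w.assay_target),
                "standard": w.standard_id,
                "plate": w.plate_id,
                "instrument": w.instrument_id,
                "operator": w.operator_id,
                "replicate": w.replicate_index,
                "ct": _format_float(w.ct),
                "tm": _format_float(w.tm),
                "wt_copies": w.wt_background_copies,
                "truth_copies": _format_float(w.truth_mutant_copies),
                "seq_confirmed": "" if w.sequencing_confirmed is None else str(w.sequencing_confirmed).lower(),
            }
        )
    pd.DataFrame(rows, columns=list(PLATE_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def apply_qc(
    wells: Sequence[WellRecord], qc: QcConfig
) -> tuple[list[WellRecord], list[tuple[WellRecord, str]]]:
    """Partition wells into QC-passing and flagged.

    Rules, applied in fixed precedence order so a well carries exactly one
    primary flag: ``min_ct`` (ct <= min_ct), ``max_ct`` (ct >= max_ct),
    ``tm_out_of_window``.  Wells with no Ct pass — they are informative
    empty wells, not failures.  A well with a measured Tm but no window
    configured for its target raises :class:`ConfigurationError`.
    """
    passing: list[WellRecord] = []
    flagged: list[tuple[WellRecord, str]] = []
    for well in wells:
        if well.ct is None:
            passing.append(well)
            continue
        if well.ct <= qc.min_ct:
            flagged.append((well, "min_ct"))
            continue
        if well.ct >= qc.max_ct:
            flagged.append((well, "max_ct"))
            continue
        if well.tm is not None:
            lo, hi = qc.tm_window(well.assay_target)
            if not lo <= well.tm <= hi:
                flagged.append((well, "tm_out_of_window"))
                continue
        passing.append(well)
    return passing, flagged


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------

def write_report(
    tables: Mapping[str, pd.DataFrame],
    path: str | Path,
    format: str = "tsv",
) -> None:
    """Write named result tables deterministically.

    ``tsv`` writes one ``<path>/<name>.tsv`` per table; ``json`` writes a
    single JSON file keyed by table name.  Rows are sorted by assay target
    then standard level where those columns exist, so identical inputs
    produce byte-identical files.
    """
    if not tables:
        raise ValueError("tables must be non-empty")
    if format not in ("tsv", "json"):
        raise ValueError(f"unknown report format {format!r}")

    def canonical(df: pd.DataFrame) -> pd.DataFrame:
        sort_cols = [c for c in ("target", "standard") if c in df.columns]
        if sort_cols:
            df = df.sort_values(sort_cols, kind="stable").reset_index(drop=True)
        return df

    path = Path(path)
    if format == "tsv":
        path.mkdir(parents=True, exist_ok=True)
        for name in sorted(tables):
            canonical(tables[name]).to_csv(path / f"{name}.tsv", sep="\t", index=False)
    else:
        payload = {name: canonical(tables[name]).to_dict(orient="records") for name in sorted(tables)}
        import json

        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
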