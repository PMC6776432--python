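"""Plate data model, CSV round trips and QC gate behaviour."""

import pytest

from qpcrval import (
    AssayTarget,
    DilutionStandard,
    QcConfig,
    WellRecord,
    apply_qc,
    read_plate_table,
    write_plate_table,
    write_report,
)
from qpcrval.errors import ConfigurationError, PlateParseError, SchemaError

HEADER = "target,standard,plate,instrument,operator,replicate,ct,tm,wt_copies,truth_copies,seq_confirmed\n"


def _well(**overrides) -> WellRecord:
    base = dict(
        assay_target=AssayTarget.BRAF_V600,
        standard_id="C",
        plate_id="P1",
        instrument_id="I1",
        operator_id="O1",
        replicate_index=1,
        ct=33.0,
        tm=82.0,
        wt_background_copies=14_000,
        truth_mutant_copies=80.0,
        sequencing_confirmed=True,
    )
    base.update(overrides)
    return WellRecord(**base)


class TestWellRecord:
    def test_empty_well_has_no_tm(self):
        with pytest.raises(ValueError):
            _well(ct=None, tm=82.0)

    @pytest.mark.parametrize("bad", [dict(ct=0.0), dict(ct=-1.0), dict(ct=50.0),
                                     dict(replicate_index=0), dict(tm=120.0)])
    def test_invariants_rejected(self, bad):
        with pytest.raises(ValueError):
            _well(**bad)

    def test_is_empty(self):
        assert _well(ct=None, tm=None).is_empty
        assert not _well().is_empty


class TestDilutionStandard:
    def test_halving_scheme(self):
        d = DilutionStandard("D", 10.0, n_replicates=3)
        e = d.halved("E", n_replicates=20)
        g = e.halved("F").halved("G")
        assert e.nominal_mean_copies == 5.0
        assert g.nominal_mean_copies == 1.25
        assert g.n_replicates == 20

    def test_rejects_nonpositive_copies(self):
        with pytest.raises(ValueError):
            DilutionStandard("X", 0.0)


class TestReadPlateTable:
    def test_header_only_gives_empty_collection(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text(HEADER)
        assert read_plate_table(p) == []

    def test_blank_ct_maps_to_absent(self, tmp_path):
        p = tmp_path / "one.csv"
        p.write_text(HEADER + "BRAF_V600,G,P1,I1,O1,1,,,14000,1.25,\n")
        (rec,) = read_plate_table(p)
        assert rec.ct is None and rec.tm is None and rec.is_empty

    def test_full_replicate_set_all_amplified(self, tmp_path):
        # 18 numeric-Ct wells at one level: 18 records, none empty
        rows = "".join(
            f"BRAF_V600,C,P1,I1,O1,{i},{33.0 + 0.01 * i},82.1,14000,64,\n"
            for i in range(1, 19)
        )
        p = tmp_path / "stdc.csv"
        p.write_text(HEADER + rows)
        recs = read_plate_table(p)
        assert len(recs) == 18
        assert sum(r.is_empty for r in recs) == 0

    def test_missing_column_names_it(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("target,standard,plate,instrument,operator,replicate\nBRAF_V600,A,P1,I1,O1,1\n")
        with pytest.raises(SchemaError, match="'ct'"):
            read_plate_table(p)

    def test_nonnumeric_ct_reports_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            HEADER
            + "BRAF_V600,C,P1,I1,O1,1,33.0,82.0,14000,,\n"
            + "BRAF_V600,C,P1,I1,O1,2,oops,82.0,14000,,\n"
        )
        with pytest.raises(PlateParseError, match="row 2"):
            read_plate_table(p)

    def test_ct_zero_rejected_as_parse_error(self, tmp_path):
        # Ct=0 is not a valid encoding of "no amplification"
        p = tmp_path / "bad.csv"
        p.write_text(HEADER + "BRAF_V600,C,P1,I1,O1,1,0,,14000,,\n")
        with pytest.raises(PlateParseError):
            read_plate_table(p)

    def test_round_trip_preserves_all_fields(self, tmp_path, small_plate):
        p = tmp_path / "plate.csv"
        write_plate_table(small_plate, p)
        back = read_plate_table(p)
        assert len(back) == len(small_plate)
        for orig, rt in zip(small_plate, back):
            assert rt.assay_target is orig.assay_target
            assert rt.standard_id == orig.standard_id
            assert rt.replicate_index == orig.replicate_index
            assert rt.wt_background_copies == orig.wt_background_copies
            assert rt.sequencing_confirmed == orig.sequencing_confirmed
            if orig.ct is None:
                assert rt.ct is None
            else:
                assert rt.ct == pytest.approx(orig.ct, abs=1e-4)
                assert rt.tm == pytest.approx(orig.tm, abs=1e-4)


class TestApplyQc:
    def test_early_ct_flagged_min_ct(self, qc_config):
        _, flagged = apply_qc([_well(ct=8.0)], qc_config)
        assert flagged[0][1] == "min_ct"

    def test_absent_ct_passes_as_empty(self, qc_config):
        passing, flagged = apply_qc([_well(ct=None, tm=None)], qc_config)
        assert len(passing) == 1 and not flagged

    def test_tm_above_window_flagged(self, qc_config):
        hi = qc_config.tm_window(AssayTarget.BRAF_V600)[1]
        _, flagged = apply_qc([_well(ct=33.0, tm=hi + 6.0)], qc_config)
        assert flagged[0][1] == "tm_out_of_window"

    def test_flag_precedence_min_ct_first(self, qc_config):
        # a well failing both rules carries the first failing flag only
        _, flagged = apply_qc([_well(ct=8.0, tm=95.0)], qc_config)
        assert flagged[0][1] == "min_ct"

    def test_partition_and_idempotence(self, qc_config, small_plate):
        passing, flagged = apply_qc(small_plate, qc_config)
        assert len(passing) + len(flagged) == len(small_plate)
        again, none_flagged = apply_qc(passing, qc_config)
        assert again == passing and none_flagged == []

    def test_unconfigured_target_is_configuration_error(self):
        qc = QcConfig(tm_windows={})
        with pytest.raises(ConfigurationError):
            apply_qc([_well()], qc)


class TestWriteReport:
    def test_deterministic_bytes(self, tmp_path):
        import pandas as pd

        table = pd.DataFrame(
            {"target": ["B", "A"], "standard": ["C", "A"], "mean_ct": [33.0, 25.0]}
        )
        write_report({"deltas": table}, tmp_path / "r1")
        write_report({"deltas": table.copy()}, tmp_path / "r2")
        b1 = (tmp_path / "r1" / "deltas.tsv").read_bytes()
        b2 = (tmp_path / "r2" / "deltas.tsv").read_bytes()
        assert b1 == b2
        # rows sorted by target then standard
        assert b1.splitlines()[1].startswith(b"A\tA")

    def test_saturated_lambda_renders_gt10(self, tmp_path):
        import pandas as pd

        from qpcrval import GT10, lambda_from_dropout
        from qpcrval.occupancy import format_lambda

        est = lambda_from_dropout(0, 18)
        assert est.lambda_dropout is GT10
        table = pd.DataFrame(
            [{"target": "BRAF_V600", "standard": "C", "lambda": format_lambda(est.lambda_dropout)}]
        )
        write_report({"occupancy": table}, tmp_path)
        assert ">10" in (tmp_path / "occupancy.tsv").read_text()

    def test_empty_tables_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_report({}, tmp_path)
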