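"""Normalization, scenarios, fold change, shortlist, secretion classes, sets."""

from __future__ import annotations

import hashlib
from dataclasses import replace

import pytest

from cosecretome.differential_secretome import (
    DifferentialRecord,
    Regulation,
    Scenario,
    SecretionClass,
    annotate_secretion,
    apply_normalization,
    build_differential,
    classify_scenario,
    classify_secretion,
    export_heatmap_matrix,
    fold_change,
    normalization_factor,
    partition_sets,
    shortlist,
    tally_regulation,
)
from cosecretome.protein_rollup import CellOfOrigin, Culture, ProteinQuant
from cosecretome.psm_io import PipelineConfig, SecretionScores


def _quant(accession, areas, condition=Culture.MONO, cell=CellOfOrigin.A549):
    return ProteinQuant(
        accession=accession,
        cell_of_origin=cell,
        condition=condition,
        unique_peptide_count=2,
        psm_count=4,
        area_by_replicate=dict(enumerate(areas, start=1)),
    )


def _record(accession="P1", scenario=Scenario.A549_CO_ONLY, fc=None,
            cv=5.0, shortlisted=False, secretion=SecretionClass.UNSCORED):
    regulation = (
        Regulation.NA if fc is None
        else Regulation.UP if fc > 1 else Regulation.DOWN if fc < 1 else Regulation.FLAT
    )
    return DifferentialRecord(
        accession=accession, cell_of_origin=CellOfOrigin.A549, scenario=scenario,
        fold_change=fc, regulation=regulation, percent_cv=cv,
        shortlisted=shortlisted, secretion_class=secretion,
    )


class TestNormalization:
    def test_ratio_definition(self):
        mono = [_quant("A", [2.0e9])]
        co = [_quant("A", [1.0e9], condition=Culture.CO)]
        report = normalization_factor(mono, co)
        assert report.factor == pytest.approx(2.0)
        assert report.mono_total_area == pytest.approx(2.0e9)

    def test_equal_totals_give_unit_factor(self):
        mono = [_quant("A", [5.0e8]), _quant("B", [5.0e8])]
        co = [_quant("C", [1.0e9], condition=Culture.CO)]
        assert normalization_factor(mono, co).factor == pytest.approx(1.0)

    def test_conservation_after_applying_factor(self):
        mono = [_quant("A", [3.1e8, 2.9e8]), _quant("B", [1.7e9, 1.5e9])]
        co = [_quant("A", [9.0e7, 1.1e8], condition=Culture.CO),
              _quant("C", [4.4e8], condition=Culture.CO)]
        report = normalization_factor(mono, co)
        normalized = apply_normalization(co, report)
        co_total = sum(q.mean_area for q in normalized)
        mono_total = sum(q.mean_area for q in mono)
        assert co_total == pytest.approx(mono_total, rel=1e-9)

    def test_empty_side_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            normalization_factor([], [_quant("A", [1.0])])


def test_scenario_classification():
    assert classify_scenario(True, False) == "MONO_ONLY"
    assert classify_scenario(False, True) == "CO_ONLY"
    assert classify_scenario(True, True) == "CO_MO"
    with pytest.raises(RuntimeError):
        classify_scenario(False, False)


class TestFoldChange:
    def test_division(self):
        assert fold_change(1.0e6, 3.5e6) == pytest.approx(3.5)
        assert fold_change(2.0e6, 2.0e6) == pytest.approx(1.0)

    def test_swap_gives_reciprocal(self):
        assert fold_change(1.0e6, 4.0e6) == pytest.approx(1.0 / fold_change(4.0e6, 1.0e6))

    def test_non_positive_errors(self):
        with pytest.raises(ValueError, match="positive"):
            fold_change(0.0, 1.0)


def test_build_differential_partition_is_exhaustive_and_exclusive():
    mono = [_quant("A", [100.0, 110.0]), _quant("B", [200.0, 210.0])]
    co = [_quant("B", [820.0, 840.0], condition=Culture.CO),
          _quant("C", [50.0, 55.0], condition=Culture.CO)]
    records = build_differential(mono, co, CellOfOrigin.A549)
    by_acc = {r.accession: r for r in records}
    assert by_acc["A"].scenario is Scenario.A549_MONO_ONLY
    assert by_acc["C"].scenario is Scenario.A549_CO_ONLY
    assert by_acc["B"].scenario is Scenario.A549_CO_MO
    assert by_acc["B"].fold_change == pytest.approx((830.0) / (205.0))
    assert by_acc["A"].fold_change is None and by_acc["A"].regulation is Regulation.NA
    assert len(records) == 3  # one record per accession, no overlaps


def test_tally_regulation_partitions_counts():
    records = [
        _record("U", Scenario.A549_CO_MO, fc=3.5),
        _record("D", Scenario.A549_CO_MO, fc=0.2),
        _record("F", Scenario.A549_CO_MO, fc=1.0),
        _record("X", Scenario.A549_MONO_ONLY),  # ignored: not CO_MO
    ]
    assert tally_regulation(records) == (1, 1, 1)
    ups = [_record(str(i), Scenario.THP1_CO_MO, fc=2.0 + i) for i in range(5)]
    assert tally_regulation(ups) == (5, 0, 0)


class TestShortlist:
    def test_cv_boundary_strict(self):
        records = shortlist([
            _record("A", cv=9.99), _record("B", cv=10.0),
        ])
        assert [r.shortlisted for r in records] == [True, False]

    def test_fc_boundary_strict(self):
        records = shortlist([
            _record("A", Scenario.A549_CO_MO, fc=3.01),
            _record("B", Scenario.A549_CO_MO, fc=3.0),
        ])
        assert [r.shortlisted for r in records] == [True, False]

    def test_magnitude_mode_keeps_downregulation(self):
        record = _record("A", Scenario.A549_CO_MO, fc=0.25)  # 1/0.25 = 4 > 3
        assert shortlist([record])[0].shortlisted
        off = PipelineConfig(fc_magnitude_mode=False)
        assert not shortlist([record], off)[0].shortlisted

    def test_monotone_in_thresholds(self):
        records = [
            _record("A", cv=9.0), _record("B", cv=12.0),
            _record("C", Scenario.A549_CO_MO, fc=2.5),
            _record("D", Scenario.A549_CO_MO, fc=4.0),
        ]
        tight = {r.accession for r in shortlist(records) if r.shortlisted}
        relaxed_config = PipelineConfig(shortlist_cv=15.0, shortlist_fc=2.0)
        relaxed = {r.accession for r in shortlist(records, relaxed_config) if r.shortlisted}
        assert tight <= relaxed


class TestSecretionClass:
    @pytest.mark.parametrize(
        "d, nn, expected",
        [
            (0.60, 0.90, SecretionClass.CSP),       # SignalP precedence
            (0.20, 0.55, SecretionClass.NCSP),
            (0.45, 0.10, SecretionClass.CSP),       # inclusive >= 0.45
            (0.20, 0.50, SecretionClass.NCSP),      # inclusive >= 0.5
            (0.20, 0.30, SecretionClass.NON_SECRETORY),
            (0.449, 0.499, SecretionClass.NON_SECRETORY),
        ],
    )
    def test_threshold_table(self, d, nn, expected):
        scores = SecretionScores(accession="P1", signalp_d=d, secretomep_nn=nn)
        assert classify_secretion(_record(), scores) is expected

    def test_missing_row_is_unscored(self):
        assert classify_secretion(_record(), None) is SecretionClass.UNSCORED

    def test_out_of_range_score_errors(self):
        bad = SecretionScores(accession="P1", signalp_d=1.2, secretomep_nn=0.1)
        with pytest.raises(ValueError):
            classify_secretion(_record(), bad)

    def test_annotate_maps_by_accession(self):
        scores_map = {"A": SecretionScores("A", 0.9, 0.1)}
        records = annotate_secretion([_record("A"), _record("B")], scores_map)
        assert records[0].secretion_class is SecretionClass.CSP
        assert records[1].secretion_class is SecretionClass.UNSCORED


class TestPartition:
    def test_disjoint_lists(self):
        records = [
            _record("A", Scenario.A549_MONO_ONLY, shortlisted=True),
            _record("B", Scenario.A549_MONO_ONLY, shortlisted=True),
            _record("C", Scenario.THP1_MONO_ONLY, shortlisted=True),
        ]
        partition = partition_sets(records)
        counts = partition["counts"]["unique"]
        assert counts["A549_MONO_ONLY"] == 2 and counts["THP1_MONO_ONLY"] == 1
        assert partition["counts"]["shared"] == {}
        assert partition["counts"]["total"] == 3

    def test_overlap_goes_to_shared_group(self):
        records = [
            _record("A", Scenario.A549_MONO_ONLY, shortlisted=True),
            _record("B", Scenario.A549_MONO_ONLY, shortlisted=True),
            _record("B", Scenario.THP1_MONO_ONLY, shortlisted=True),
            _record("C", Scenario.THP1_MONO_ONLY, shortlisted=True),
        ]
        partition = partition_sets(records)
        assert partition["counts"]["unique"]["A549_MONO_ONLY"] == 1
        assert partition["counts"]["unique"]["THP1_MONO_ONLY"] == 1
        assert partition["counts"]["shared"] == {"A549_MONO_ONLY+THP1_MONO_ONLY": 1}

    def test_triple_membership_is_flagged(self):
        records = [
            _record("A", s, shortlisted=True)
            for s in (Scenario.A549_MONO_ONLY, Scenario.THP1_MONO_ONLY,
                      Scenario.THP1_CO_ONLY)
        ]
        partition = partition_sets(records)
        assert partition["flagged"] == ["A"]
        assert partition["counts"]["total"] == 1


class TestHeatmapExport:
    def test_rows_match_shortlist_and_column_order(self, tmp_path):
        records = [
            _record("A", Scenario.A549_MONO_ONLY, cv=4.0, shortlisted=True,
                    secretion=SecretionClass.CSP),
            _record("B", Scenario.A549_CO_MO, fc=5.0, shortlisted=True,
                    secretion=SecretionClass.NCSP),
            _record("C", Scenario.A549_CO_ONLY, cv=3.0, shortlisted=True),
            _record("Z", Scenario.A549_CO_ONLY, cv=50.0, shortlisted=False),
        ]
        scores_map = {"A": SecretionScores("A", 0.9, 0.2)}
        frame = export_heatmap_matrix(records, tmp_path / "hm.tsv", scores_map)
        assert list(frame.columns) == [
            "accession", "scenario", "value", "signalp_d", "secretomep_nn",
            "secretion_class",
        ]
        assert len(frame) == sum(r.shortlisted for r in records)
        # %CV keys single-condition rows, fold change keys CO_MO rows
        assert frame.set_index("accession").loc["A", "value"] == 4.0
        assert frame.set_index("accession").loc["B", "value"] == 5.0

    def test_reexport_is_byte_identical(self, tmp_path):
        records = [_record("A", shortlisted=True), _record("B", shortlisted=True)]
        digests = []
        for name in ("a.tsv", "b.tsv"):
            export_heatmap_matrix(records, tmp_path / name)
            digests.append(hashlib.sha256((tmp_path / name).read_bytes()).hexdigest())
        assert digests[0] == digests[1]
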