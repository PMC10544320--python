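"""Peptide uniqueness, %CV, rollup summation and the evidence filter."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st

from cosecretome.protein_rollup import (
    CellOfOrigin,
    Culture,
    ProteinQuant,
    evidence_filter,
    is_unique_peptide,
    percent_cv,
    rollup_proteins,
)
from cosecretome.psm_io import Condition, PipelineConfig

from conftest import make_psm


class TestUniqueness:
    def test_single_protein_peptide_is_unique(self, toy_db):
        assert is_unique_peptide("ELVISK", toy_db)

    def test_paralog_shared_peptide_is_not(self, toy_db):
        assert not is_unique_peptide("AAAAAK", toy_db)

    def test_absent_peptide_warns_and_is_not_unique(self, toy_db):
        with pytest.warns(UserWarning, match="not found"):
            assert not is_unique_peptide("WWWWWK", toy_db)

    def test_empty_database_errors(self):
        with pytest.raises(ValueError, match="empty"):
            is_unique_peptide("ELVISK", {})


class TestPercentCv:
    def test_hand_computed_value(self):
        # mean 200, sample sd 100 -> 50%
        assert percent_cv([100.0, 200.0, 300.0]) == pytest.approx(50.0)

    def test_zero_variance(self):
        assert percent_cv([5.0, 5.0, 5.0]) == 0.0

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(1e-6, 1e6))
    def test_scale_invariance(self, k):
        assert percent_cv([k * 100, k * 200, k * 300]) == pytest.approx(50.0, rel=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            percent_cv([100.0])
        with pytest.raises(ValueError, match="positive"):
            percent_cv([100.0, 0.0])


def test_rollup_sums_unique_peptide_areas_per_replicate(toy_db):
    # PROT1 via two unique peptides; replicate 1 has two PSMs of one peptide
    psms = [
        make_psm(peptide="ELVISK", replicate=1, peak_area=100.0, spectrum_id="a"),
        make_psm(peptide="ELVISK", replicate=1, peak_area=100.0, spectrum_id="b"),
        make_psm(peptide="MSTELVISK", replicate=2, peak_area=250.0, spectrum_id="c"),
        make_psm(peptide="ELVISK", replicate=3, peak_area=150.0, spectrum_id="d"),
    ]
    quants = rollup_proteins(psms, toy_db, CellOfOrigin.A549, Culture.MONO)
    assert len(quants) == 1
    quant = quants[0]
    assert quant.area_by_replicate == {1: 200.0, 2: 250.0, 3: 150.0}
    assert quant.unique_peptide_count == 2
    assert quant.psm_count == 4
    assert quant.mean_area == pytest.approx(200.0)


def test_shared_only_evidence_yields_zero_count_quant(toy_db):
    psms = [make_psm(peptide="AAAAAK", accessions=("PROT2",), spectrum_id="s")]
    quants = rollup_proteins(psms, toy_db, CellOfOrigin.A549, Culture.MONO)
    assert len(quants) == 1
    assert quants[0].unique_peptide_count == 0 and quants[0].psm_count == 0
    retained, rejected = evidence_filter(quants)
    assert retained == [] and rejected[0][1] == "unique_peptides"


def test_rollup_excludes_multi_accession_and_kr_free_psms(toy_db):
    psms = [
        make_psm(peptide="ELVISK", replicate=1, peak_area=100.0, spectrum_id="a"),
        # ambiguous protein identity: excluded from quantification
        make_psm(peptide="ELVISK", accessions=("PROT1", "PROT2"),
                 replicate=1, peak_area=999.0, spectrum_id="b"),
        # no K/R: channel-undecidable, excluded everywhere
        make_psm(peptide="GGTTT", accessions=("PROT3",),
                 replicate=1, peak_area=50.0, spectrum_id="c"),
    ]
    quants = rollup_proteins(psms, toy_db, CellOfOrigin.A549, Culture.MONO)
    by_acc = {q.accession: q for q in quants}
    assert by_acc["PROT1"].area_by_replicate == {1: 100.0}
    assert by_acc["PROT3"].psm_count == 0  # evidenced but unquantifiable


def _quant(unique=2, psms=4, areas=(140.0, 200.0, 260.0), accession="P"):
    return ProteinQuant(
        accession=accession,
        cell_of_origin=CellOfOrigin.A549,
        condition=Culture.MONO,
        unique_peptide_count=unique,
        psm_count=psms,
        area_by_replicate=dict(enumerate(areas, start=1)),
    )


class TestEvidenceFilter:
    def test_cv_boundary_is_inclusive(self):
        # (140, 200, 260): sample sd 60, mean 200 -> %CV exactly 30.0
        retained, rejected = evidence_filter([_quant()])
        assert len(retained) == 1 and not rejected

        over, rejected = evidence_filter([_quant(areas=(139.0, 200.0, 261.0))])
        assert over == [] and rejected[0][1] == "cv"

    def test_first_failing_reason_is_reported(self):
        cases = [
            (_quant(unique=1), "unique_peptides"),
            (_quant(psms=3), "psms"),
            (_quant(areas=(200.0,)), "replicates"),
            (_quant(areas=(10.0, 200.0, 390.0)), "cv"),
        ]
        for quant, expected_reason in cases:
            retained, rejected = evidence_filter([quant])
            assert retained == []
            assert rejected[0][1] == expected_reason

    def test_planted_violations_fixture(self):
        compliant = [_quant(accession=f"OK{i}") for i in range(12)]
        violators = [
            _quant(accession="V1", unique=0),
            _quant(accession="V2", unique=1),
            _quant(accession="V3", psms=2),
            _quant(accession="V4", areas=(250.0,)),
            _quant(accession="V5", areas=(10.0, 500.0, 1000.0)),
        ]
        retained, rejected = evidence_filter(compliant + violators)
        assert len(retained) == len(compliant)
        assert len(rejected) == len(violators)

    def test_idempotence(self):
        quants = [_quant(), _quant(unique=1, accession="X")]
        once, _ = evidence_filter(quants)
        twice, rejected_again = evidence_filter(once)
        assert twice == once and rejected_again == []


def test_area_bookkeeping_conserves_mass(toy_db):
    """Total retained+rejected area equals the input PSM total minus the
    shared-peptide and K/R-free exclusions."""
    psms = [
        make_psm(peptide="ELVISK", replicate=r, peak_area=100.0, spectrum_id=f"u{r}")
        for r in (1, 2, 3)
    ] + [
        make_psm(peptide="MSTELVISK", replicate=1, peak_area=40.0, spectrum_id="u4"),
        make_psm(peptide="AAAAAK", accessions=("PROT2",), peak_area=77.0, spectrum_id="sh"),
        make_psm(peptide="GGTTT", accessions=("PROT3",), peak_area=13.0, spectrum_id="nk"),
    ]
    quants = rollup_proteins(psms, toy_db, CellOfOrigin.A549, Culture.MONO)
    rolled_total = sum(sum(q.area_by_replicate.values()) for q in quants)
    input_total = sum(p.peak_area for p in psms)
    assert rolled_total == pytest.approx(input_total - 77.0 - 13.0)
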