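"""Shared fixtures: a toy protein database and PSM builders."""

from __future__ import annotations

import pytest

from cosecretome.psm_io import Condition, PsmRecord

# PROT1 uniquely contains ELVISK; AAAAAK is shared by PROT2 and PROT3.
TOY_DB = {
    "PROT1": "MSTELVISKR",
    "PROT2": "MAAAAAKLLR",
    "PROT3": "GGAAAAAKTTK",
}


@pytest.fixture
def toy_db() -> dict[str, str]:
    return dict(TOY_DB)


def make_psm(
    peptide: str = "ELVISK",
    condition: Condition = Condition.A549_MONO,
    replicate: int = 1,
    peak_area: float = 100.0,
    accessions: tuple[str, ...] = ("PROT1",),
    modifications: tuple[tuple[int, str], ...] = (),
    search_score: float = 10.0,
    is_decoy: bool = False,
    spectrum_id: str | None = None,
    charge: int = 2,
) -> PsmRecord:
    record = PsmRecord(
        spectrum_id=spectrum_id or f"{condition.value}.{peptide}.r{replicate}.{peak_area}",
        peptide=peptide,
        modifications=modifications,
        charge=charge,
        search_score=search_score,
        is_decoy=is_decoy,
        protein_accessions=accessions,
        peak_area=peak_area,
        condition=condition,
        replicate=replicate,
    )
    record.validate()
    return record


@pytest.fixture
def psm_factory():
    return make_psm
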