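"""Mono- vs co-culture differential analysis of the secretome.

For each cell of origin, co-culture areas are first put on the monoculture
scale with a single multiplicative factor, the ratio of total peak area in
mono- and co-culture (normalizing co-culture to match the monoculture
total).  Evidence-passing proteins then fall into one of three scenarios
per cell — detected only in monoculture, only in co-culture, or in both —
giving six scenarios over the two cell lines.  For proteins detected in
both conditions the fold change FC = normalized co-culture mean area /
monoculture mean area, so up-regulation upon co-culture reads FC > 1.

Candidates are shortlisted with %CV strictly below 10 (single-condition
scenarios) or fold change strictly above 3 (both-condition scenarios; by
default a fold change below 1/3 shortlists as well, keeping strong
down-regulation).  Shortlisted proteins are classified as classically
secreted (CSP, SignalP D-score >= 0.45 — a signal peptide makes a protein
classical by definition, so SignalP takes precedence), non-classically
secreted (NCSP, SecretomeP NN-score >= 0.5), or non-secretory.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .psm_io import PipelineConfig, SecretionScores
from .protein_rollup import CellOfOrigin, Culture, ProteinQuant

__all__ = [
    "Scenario",
    "Regulation",
    "SecretionClass",
    "DifferentialRecord",
    "NormalizationReport",
    "normalization_factor",
    "apply_normalization",
    "classify_scenario",
    "fold_change",
    "build_differential",
    "tally_regulation",
    "shortlist",
    "classify_secretion",
    "annotate_secretion",
    "partition_sets",
    "export_heatmap_matrix",
]


class Scenario(str, enum.Enum):
    A549_MONO_ONLY = "A549_MONO_ONLY"
    A549_CO_ONLY = "A549_CO_ONLY"
    A549_CO_MO = "A549_CO_MO"
    THP1_MONO_ONLY = "THP1_MONO_ONLY"
    THP1_CO_ONLY = "THP1_CO_ONLY"
    THP1_CO_MO = "THP1_CO_MO"

    @property
    def is_co_mo(self) -> bool:
        return self.value.endswith("_CO_MO")


class Regulation(str, enum.Enum):
    UP = "UP"
    DOWN = "DOWN"
    FLAT = "FLAT"
    NA = "NA"


class SecretionClass(str, enum.Enum):
    CSP = "CSP"
    NCSP = "NCSP"
    NON_SECRETORY = "NON_SECRETORY"
    UNSCORED = "UNSCORED"


@dataclass(frozen=True)
class DifferentialRecord:
    """Scenario call, fold change and secretion class for one protein."""

    accession: str
    cell_of_origin: CellOfOrigin
    scenario: Scenario
    fold_change: float | None
    regulation: Regulation
    percent_cv: float | None
    shortlisted: bool = False
    secretion_class: SecretionClass = SecretionClass.UNSCORED


@dataclass(frozen=True)
class NormalizationReport:
    """Total-area normalization of one cell of origin."""

    cell_of_origin: CellOfOrigin
    mono_total_area: float
    co_total_area: float
    factor: float


def normalization_factor(
    mono_quants: Sequence[ProteinQuant], co_quants: Sequence[ProteinQuant]
) -> NormalizationReport:
    """Ratio of total (mean-area) peak area in mono- and co-culture.

    The factor is applied multiplicatively to every co-culture area of the
    same cell of origin, after which the co-culture total matches the
    monoculture total exactly.
    """
    if not mono_quants or not co_quants:
        raise ValueError("normalization requires non-empty mono and co quant sets")
    cell = mono_quants[0].cell_of_origin
    mono_total = sum(q.mean_area for q in mono_quants)
    co_total = sum(q.mean_area for q in co_quants)
    if co_total <= 0:
        raise ValueError(f"{cell.value}: co-culture total area is not positive")
    return NormalizationReport(
        cell_of_origin=cell,
        mono_total_area=mono_total,
        co_total_area=co_total,
        factor=mono_total / co_total,
    )


def apply_normalization(
    co_quants: Iterable[ProteinQuant], report: NormalizationReport
) -> list[ProteinQuant]:
    """Scale every co-culture quant by the normalization factor."""
    return [quant.scaled(report.factor) for quant in co_quants]


def classify_scenario(mono_detected: bool, co_detected: bool) -> str:
    """One of ``MONO_ONLY``, ``CO_ONLY``, ``CO_MO``; (False, False) is a bug."""
    if mono_detected and co_detected:
        return "CO_MO"
    if mono_detected:
        return "MONO_ONLY"
    if co_detected:
        return "CO_ONLY"
    raise RuntimeError(
        "scenario classification reached with a protein detected in neither condition"
    )


def fold_change(mono_mean_area: float, co_mean_area_normalized: float) -> float:
    """Normalized co-culture mean area over monoculture mean area."""
    if not mono_mean_area > 0 or not co_mean_area_normalized > 0:
        raise ValueError(
            f"fold change requires positive areas, got mono={mono_mean_area}, "
            f"co={co_mean_area_normalized}"
        )
    return co_mean_area_normalized / mono_mean_area


def _regulation_of(fc: float | None) -> Regulation:
    if fc is None:
        return Regulation.NA
    if fc > 1.0:
        return Regulation.UP
    if fc < 1.0:
        return Regulation.DOWN
    return Regulation.FLAT  # an exact tie is reported, never silently binned


def build_differential(
    mono_retained: Sequence[ProteinQuant],
    co_retained_normalized: Sequence[ProteinQuant],
    cell: CellOfOrigin,
) -> list[DifferentialRecord]:
    """Assign each evidence-passing protein of one cell to its scenario.

    The scenario partition over the union of mono and co accessions is
    exhaustive and mutually exclusive.  For both-condition proteins the
    carried %CV is the co-culture one (the condition of interest; %CV is
    scale-invariant, so normalization does not change it).
    """
    mono_by_acc = {q.accession: q for q in mono_retained}
    co_by_acc = {q.accession: q for q in co_retained_normalized}
    records = []
    for accession in sorted(set(mono_by_acc) | set(co_by_acc)):
        mono = mono_by_acc.get(accession)
        co = co_by_acc.get(accession)
        kind = classify_scenario(mono is not None, co is not None)
        scenario = Scenario(f"{cell.value}_{kind}")
        fc = None
        if kind == "CO_MO":
            fc = fold_change(mono.mean_area, co.mean_area)
        cv = (co or mono).percent_cv
        records.append(
            DifferentialRecord(
                accession=accession,
                cell_of_origin=cell,
                scenario=scenario,
                fold_change=fc,
                regulation=_regulation_of(fc),
                percent_cv=cv,
            )
        )
    return records


def tally_regulation(records: Iterable[DifferentialRecord]) -> tuple[int, int, int]:
    """(n_up, n_down, n_flat) over both-condition records; a strict partition."""
    n_up = n_down = n_flat = 0
    for record in records:
        if not record.scenario.is_co_mo:
            continue
        if record.regulation is Regulation.UP:
            n_up += 1
        elif record.regulation is Regulation.DOWN:
            n_down += 1
        else:
            n_flat += 1
    return n_up, n_down, n_flat


def shortlist(
    records: Iterable[DifferentialRecord], config: PipelineConfig | None = None
) -> list[DifferentialRecord]:
    """Flag candidates: %CV < 10 (strict) or FC > 3 (strict; or < 1/3).

    Single-condition scenarios are shortlisted on %CV, both-condition
    scenarios on fold change; with ``fc_magnitude_mode`` (default) a fold
    change below ``1/shortlist_fc`` shortlists too.
    """
    config = config or PipelineConfig()
    out = []
    for record in records:
        if record.scenario.is_co_mo:
            fc = record.fold_change
            selected = fc is not None and (
                fc > config.shortlist_fc
                or (config.fc_magnitude_mode and fc < 1.0 / config.shortlist_fc)
            )
        else:
            selected = record.percent_cv is not None and record.percent_cv < config.shortlist_cv
        out.append(replace(record, shortlisted=selected))
    return out


def classify_secretion(
    record: DifferentialRecord,
    scores: SecretionScores | None,
    config: PipelineConfig | None = None,
) -> SecretionClass:
    """CSP / NCSP / NON_SECRETORY from the two scores; UNSCORED without a row.

    SignalP is checked first: D-score >= 0.45 makes the protein a classical
    secretory protein regardless of its SecretomeP score, so CSP and NCSP
    are disjoint by precedence.  Both cut-offs are inclusive.
    """
    config = config or PipelineConfig()
    if scores is None:
        return SecretionClass.UNSCORED
    scores.validate()
    if scores.signalp_d >= config.signalp_d_cutoff:
        return SecretionClass.CSP
    if scores.secretomep_nn >= config.secretomep_nn_cutoff:
        return SecretionClass.NCSP
    return SecretionClass.NON_SECRETORY


def annotate_secretion(
    records: Iterable[DifferentialRecord],
    scores_map: Mapping[str, SecretionScores],
    config: PipelineConfig | None = None,
) -> list[DifferentialRecord]:
    """Attach a secretion class to every record that has a score row."""
    return [
        replace(
            record,
            secretion_class=classify_secretion(
                record, scores_map.get(record.accession), config
            ),
        )
        for record in records
    ]


def partition_sets(records: Iterable[DifferentialRecord]) -> dict:
    """Unique/shared membership of shortlisted accessions across scenarios.

    Each distinct shortlisted accession is assigned either to the single
    scenario it appears in, or to a shared group named after the two
    scenarios it appears in (the same secreted protein can be shortlisted
    once per cell of origin).  Accessions appearing in more than two
    scenarios are flagged rather than silently merged.  Unique + shared +
    flagged counts sum to the number of distinct shortlisted accessions.
    """
    memberships: dict[str, set[Scenario]] = {}
    for record in records:
        if record.shortlisted:
            memberships.setdefault(record.accession, set()).add(record.scenario)

    unique: dict[str, list[str]] = {s.value: [] for s in Scenario}
    shared: dict[str, list[str]] = {}
    flagged: list[str] = []
    for accession in sorted(memberships):
        scenarios = sorted(s.value for s in memberships[accession])
        if len(scenarios) == 1:
            unique[scenarios[0]].append(accession)
        elif len(scenarios) == 2:
            shared.setdefault("+".join(scenarios), []).append(accession)
        else:
            flagged.append(accession)

    return {
        "unique": unique,
        "shared": shared,
        "flagged": flagged,
        "counts": {
            "unique": {k: len(v) for k, v in unique.items()},
            "shared": {k: len(v) for k, v in sorted(shared.items())},
            "flagged": len(flagged),
            "total": len(memberships),
        },
    }


_HEATMAP_COLUMNS = [
    "accession", "scenario", "value", "signalp_d", "secretomep_nn", "secretion_class",
]


def export_heatmap_matrix(
    records: Iterable[DifferentialRecord],
    path: str | Path,
    scores_map: Mapping[str, SecretionScores] | None = None,
) -> pd.DataFrame:
    """Write the shortlist as a matrix-viewer-ready TSV (one row per protein).

    ``value`` is the %CV for single-condition scenarios and the fold change
    for both-condition scenarios, matching how the heat maps are keyed.
    Rows are sorted by accession then scenario, so re-exports are
    byte-identical.
    """
    scores_map = scores_map or {}
    rows = []
    for record in records:
        if not record.shortlisted:
            continue
        scores = scores_map.get(record.accession)
        rows.append({
            "accession": record.accession,
            "scenario": record.scenario.value,
            "value": record.fold_change if record.scenario.is_co_mo else record.percent_cv,
            "signalp_d": scores.signalp_d if scores else None,
            "secretomep_nn": scores.secretomep_nn if scores else None,
            "secretion_class": record.secretion_class.value,
        })
    frame = pd.DataFrame(rows, columns=_HEATMAP_COLUMNS)
    frame = frame.sort_values(["accession", "scenario"], kind="mergesort").reset_index(drop=True)
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return frame


def write_partition(partition: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(partition, fh, indent=2, sort_keys=True)
        fh.write("\n")
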