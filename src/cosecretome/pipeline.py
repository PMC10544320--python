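"""End-to-end orchestration of the SILAC co-culture secretome analysis.

Stage order: per-table target-decoy FDR filtering of PSMs, channel
assignment (monoculture tables keep their condition's cell of origin, the
co-culture table is split into heavy/A549 and light/THP-1), peptide-to-
protein rollup with the evidence filter, total-area normalization of
co-culture to monoculture per cell, six-scenario classification with fold
changes, candidate shortlisting, CSP/NCSP secretion calls, and the set
partition of the shortlist.  :func:`run_pipeline` returns a
:class:`PipelineResult` holding every record plus a run report with the
thresholds used and the counts at each stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields as dataclass_fields
from pathlib import Path
from typing import Mapping, Sequence

from . import decoy_fdr, differential_secretome as diff, protein_rollup, silac_channels
from .differential_secretome import (
    DifferentialRecord,
    NormalizationReport,
    Scenario,
    SecretionClass,
)
from .protein_rollup import CellOfOrigin, Culture, ProteinQuant, UniquenessIndex
from .psm_io import Condition, PipelineConfig, PsmRecord, SecretionScores, write_table
from .silac_channels import Channel

__all__ = ["PipelineResult", "run_pipeline", "run_synthetic"]

_GROUPS = (
    (CellOfOrigin.A549, Culture.MONO),
    (CellOfOrigin.A549, Culture.CO),
    (CellOfOrigin.THP1, Culture.MONO),
    (CellOfOrigin.THP1, Culture.CO),
)


@dataclass
class PipelineResult:
    """All outputs of one pipeline run."""

    config: PipelineConfig
    records: list[DifferentialRecord]
    retained_quants: dict[tuple[CellOfOrigin, Culture], list[ProteinQuant]]
    normalization: dict[CellOfOrigin, NormalizationReport | None]
    partition: dict
    report: dict

    def write_outputs(self, out_dir: str | Path, scores_map: Mapping[str, SecretionScores] | None = None) -> None:
        """Write differential.tsv, shortlist.tsv, partition.json, heatmap.tsv
        and run_report.json into ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        schema = [f.name for f in dataclass_fields(DifferentialRecord)]
        write_table(self.records, out / "differential.tsv", schema=schema)
        write_table(
            [r for r in self.records if r.shortlisted],
            out / "shortlist.tsv", schema=schema,
        )
        diff.write_partition(self.partition, out / "partition.json")
        diff.export_heatmap_matrix(self.records, out / "heatmap.tsv", scores_map)
        with open(out / "run_report.json", "w") as fh:
            json.dump(self.report, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def summary(self) -> str:
        """Human-readable run overview."""
        lines = ["SILAC co-culture secretome pipeline", "=" * 36]
        for condition, stats in self.report["fdr"].items():
            lines.append(
                f"{condition:>10}: {stats['n_input']:>6} PSMs "
                f"({stats['n_decoys']} decoys) -> {stats['n_retained']} at "
                f"q <= {self.config.fdr_alpha}"
            )
        split = self.report["channel_split"]
        lines.append(
            f" co-culture: {split['heavy']} heavy / {split['light']} light / "
            f"{split['ambiguous']} ambiguous"
        )
        for cell, report in self.normalization.items():
            if report is not None:
                lines.append(
                    f"{cell.value:>10}: normalization factor {report.factor:.4f} "
                    f"(mono {report.mono_total_area:.3e} / co {report.co_total_area:.3e})"
                )
        lines.append("scenarios : " + ", ".join(
            f"{scenario.value}={count}"
            for scenario, count in (
                (s, self.report["scenarios"][s.value]) for s in Scenario
            )
        ))
        for cell in (CellOfOrigin.A549, CellOfOrigin.THP1):
            up, down, flat = self.report["regulation"][cell.value]
            lines.append(f"{cell.value:>10}: {up} up / {down} down / {flat} flat (co vs mono)")
        lines.append(
            f"shortlist : {self.report['shortlist']['total']} proteins "
            f"({self.report['secretion']['CSP']} CSP, "
            f"{self.report['secretion']['NCSP']} NCSP, "
            f"{self.report['secretion']['NON_SECRETORY']} non-secretory, "
            f"{self.report['secretion']['UNSCORED']} unscored)"
        )
        return "\n".join(lines)


def run_pipeline(
    psm_tables: Mapping[Condition, Sequence[PsmRecord]],
    protein_db: Mapping[str, str],
    scores_map: Mapping[str, SecretionScores] | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full analysis on the three PSM tables.

    ``psm_tables`` maps each :class:`Condition` to its PSM list (missing
    conditions are treated as empty); ``protein_db`` is the accession ->
    sequence map used for uniqueness decisions; ``scores_map`` the optional
    SignalP/SecretomeP table for secretion calls.
    """
    config = config or PipelineConfig()
    scores_map = scores_map or {}
    report: dict = {"config": json.loads(config.model_dump_json()), "fdr": {}}

    # 1. PSM-level target-decoy FDR, per export table
    filtered: dict[Condition, list[PsmRecord]] = {}
    for condition in Condition:
        table = list(psm_tables.get(condition, ()))
        filtered[condition], stats = decoy_fdr.filter_psms_fdr(table, config.fdr_alpha)
        report["fdr"][condition.value] = stats

    # 2. channel bookkeeping: monocultures bypass splitting but are audited
    report["monoculture_mislabel_fraction"] = {
        Condition.A549_MONO.value: silac_channels.check_monoculture_labeling(
            filtered[Condition.A549_MONO], Channel.HEAVY,
            config.label_names, config.label_tolerance,
        ),
        Condition.THP1_MONO.value: silac_channels.check_monoculture_labeling(
            filtered[Condition.THP1_MONO], Channel.LIGHT,
            config.label_names, config.label_tolerance,
        ),
    }
    heavy_co, light_co, n_ambiguous = silac_channels.split_coculture(
        filtered[Condition.COCULTURE], config.label_names
    )
    report["channel_split"] = {
        "heavy": len(heavy_co), "light": len(light_co), "ambiguous": n_ambiguous,
    }

    # 3. rollup + evidence filter per (cell, culture) group
    index = UniquenessIndex(protein_db)
    group_psms = {
        (CellOfOrigin.A549, Culture.MONO): filtered[Condition.A549_MONO],
        (CellOfOrigin.A549, Culture.CO): heavy_co,
        (CellOfOrigin.THP1, Culture.MONO): filtered[Condition.THP1_MONO],
        (CellOfOrigin.THP1, Culture.CO): light_co,
    }
    retained: dict[tuple[CellOfOrigin, Culture], list[ProteinQuant]] = {}
    report["rollup"] = {}
    for (cell, culture) in _GROUPS:
        quants = protein_rollup.rollup_proteins(
            group_psms[(cell, culture)], index, cell, culture, config
        )
        kept, rejected = protein_rollup.evidence_filter(quants, config)
        retained[(cell, culture)] = kept
        reasons: dict[str, int] = {}
        for _, reason in rejected:
            reasons[reason] = reasons.get(reason, 0) + 1
        report["rollup"][f"{cell.value}_{culture.value}"] = {
            "n_quantified": len(quants),
            "n_retained": len(kept),
            "rejected_by_reason": reasons,
        }

    # 4. normalization (co scaled to match mono) and differential records
    records: list[DifferentialRecord] = []
    normalization: dict[CellOfOrigin, NormalizationReport | None] = {}
    report["regulation"] = {}
    for cell in (CellOfOrigin.A549, CellOfOrigin.THP1):
        mono = retained[(cell, Culture.MONO)]
        co = retained[(cell, Culture.CO)]
        if mono and co:
            norm = diff.normalization_factor(mono, co)
            co = diff.apply_normalization(co, norm)
        else:
            norm = None  # nothing to compare; scenarios still emitted below
        normalization[cell] = norm
        cell_records = diff.build_differential(mono, co, cell)
        report["regulation"][cell.value] = list(diff.tally_regulation(cell_records))
        records.extend(cell_records)

    # 5. shortlist, secretion classes, set partition
    records = diff.shortlist(records, config)
    records = diff.annotate_secretion(records, scores_map, config)
    partition = diff.partition_sets(records)

    scenario_counts = {s.value: 0 for s in Scenario}
    shortlist_counts = {s.value: 0 for s in Scenario}
    secretion_counts = {c.value: 0 for c in SecretionClass}
    for record in records:
        scenario_counts[record.scenario.value] += 1
        if record.shortlisted:
            shortlist_counts[record.scenario.value] += 1
            secretion_counts[record.secretion_class.value] += 1
    shortlist_counts["total"] = sum(
        shortlist_counts[s.value] for s in Scenario
    )
    report["scenarios"] = scenario_counts
    report["shortlist"] = shortlist_counts
    report["secretion"] = secretion_counts
    report["normalization"] = {
        cell.value: (
            {"mono_total_area": n.mono_total_area, "co_total_area": n.co_total_area,
             "factor": n.factor} if n else None
        )
        for cell, n in normalization.items()
    }
    report["partition_counts"] = partition["counts"]

    return PipelineResult(
        config=config,
        records=records,
        retained_quants=retained,
        normalization=normalization,
        partition=partition,
        report=report,
    )


def run_synthetic(generator_config=None, pipeline_config: PipelineConfig | None = None):
    """Generate a synthetic experiment and analyse it.

    Returns ``(result, experiment)`` so recovered scenarios and fold
    changes can be compared with the planted truth.
    """
    from .synthetic_data import generate_experiment

    experiment = generate_experiment(generator_config)
    result = run_pipeline(
        experiment.psm_tables,
        experiment.protein_db,
        experiment.scores_map,
        pipeline_config or PipelineConfig(),
    )
    return result, experiment
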