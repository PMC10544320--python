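"""Synthetic SILAC co-culture experiments with planted ground truth.

Emulates the study design the pipeline assumes — a heavy-labeled A549
monoculture, a light-labeled THP-1 monoculture and a 1:10 co-culture with
mixed channels, three replicate runs each — at the PSM level: tryptic
peptides (ending in K/R except at the protein C-terminus), log-normal
per-replicate peak areas, ~99% isotope incorporation, decoy PSMs drawn
from a score distribution overlapping the targets', shared peptides,
replicate missingness, and per-accession secretion scores drawn from
class-conditional distributions straddling the CSP/NCSP cut-offs.

Each cell line carries five planted protein classes: detected only in
monoculture, only in co-culture, up- or down-regulated in both (fold
change 3.5-8, reciprocal for the down class), plus a flat background that
provides the bulk of the total peak area.  Planted single- and
both-condition candidates are generated with low replicate noise (clean
signals the shortlist thresholds should recover); the background spans the
realistic %CV range.  Co-culture areas are multiplied by a global scale so
the total-area normalization step is non-trivial, and the planted
composition is mass-balanced per cell (equal true mono and co totals), the
assumption total-area normalization itself relies on.

The whole experiment is drawn from one seeded pseudo-random stream in a
fixed order, so a seed fixes every output byte.  Decoys are drawn last:
configurations differing only in ``decoy_fraction`` emit identical target
PSMs.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from pydantic import BaseModel, field_validator, model_validator

from .differential_secretome import Scenario, SecretionClass
from .protein_rollup import CellOfOrigin
from .psm_io import (
    Condition,
    PsmRecord,
    SecretionScores,
    psms_to_table,
    scores_to_table,
    write_table,
)

__all__ = [
    "PlantedClass",
    "GeneratorConfig",
    "SyntheticTruth",
    "SyntheticExperiment",
    "RecoveryMetrics",
    "generate_experiment",
    "generate_study_scale",
    "study_scale_config",
    "noiseless_config",
    "score_recovery",
]

_AA_NO_KR = "ACDEFGHILMNPQSTVWY"  # interior tryptic residues


class PlantedClass(str, enum.Enum):
    MONO_ONLY = "MONO_ONLY"
    CO_ONLY = "CO_ONLY"
    CO_MO_UP = "CO_MO_UP"
    CO_MO_DOWN = "CO_MO_DOWN"
    BACKGROUND = "BACKGROUND"

    @property
    def is_candidate(self) -> bool:
        """Planted signal classes, as opposed to the flat background."""
        return self is not PlantedClass.BACKGROUND


class GeneratorConfig(BaseModel):
    """Study conditions of the simulated experiment.

    Class counts are per cell line; the defaults plant 15 + 15 + 6 + 6
    candidates over a 160-protein flat background per cell, ~404 proteins
    in total — the approximate scale of the real study.  ``replicate_sigma``
    is the (low, high) range of the per-protein log-normal scale for
    background proteins (sigma ~ %CV/100, so the default spans ~5-25% CV);
    planted candidates use the single ``candidate_sigma``.
    """

    seed: int = 0
    n_mono_only: int = 15
    n_co_only: int = 15
    n_co_mo_up: int = 6
    n_co_mo_down: int = 6
    n_background_shared: int = 160
    planted_fc_range: tuple[float, float] = (3.5, 8.0)
    replicate_sigma: tuple[float, float] = (0.05, 0.25)
    candidate_sigma: float = 0.05
    n_replicates: int = 3
    peptides_per_protein: tuple[int, int] = (2, 6)
    psms_per_peptide: tuple[int, int] = (1, 4)
    shared_peptide_fraction: float = 0.05
    decoy_fraction: float = 0.1
    target_score_mean: float = 3.5
    target_score_sd: float = 1.0
    decoy_score_mean: float = 0.0
    decoy_score_sd: float = 1.0
    label_incorporation: float = 0.99
    missing_replicate_rate: float = 0.05
    co_culture_scale: float = 0.6
    base_log_area_mean: float = math.log(1e6)
    base_log_area_sd: float = 0.5
    candidate_secretion_probs: tuple[float, float, float, float] = (0.35, 0.35, 0.2, 0.1)
    background_secretion_probs: tuple[float, float, float, float] = (0.05, 0.10, 0.65, 0.20)
    balance_totals: bool = True

    model_config = {"frozen": True}

    @field_validator(
        "n_mono_only", "n_co_only", "n_co_mo_up", "n_co_mo_down",
        "n_background_shared",
    )
    @classmethod
    def _non_negative(cls, v):
        if v < 0:
            raise ValueError("class counts must be >= 0")
        return v

    @field_validator(
        "shared_peptide_fraction", "decoy_fraction", "label_incorporation",
        "missing_replicate_rate",
    )
    @classmethod
    def _fraction(cls, v):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"fractions must lie in [0, 1], got {v}")
        return v

    @model_validator(mode="after")
    def _ranges(self):
        for name in ("planted_fc_range", "replicate_sigma",
                     "peptides_per_protein", "psms_per_peptide"):
            low, high = getattr(self, name)
            if high < low:
                raise ValueError(f"{name}: max {high} < min {low}")
        if self.peptides_per_protein[0] < 1 or self.psms_per_peptide[0] < 1:
            raise ValueError("peptides_per_protein and psms_per_peptide minima must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.decoy_fraction >= 1.0:
            raise ValueError("decoy_fraction must be < 1")
        return self


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted properties of one simulated protein, for recovery testing."""

    accession: str
    cell_of_origin: CellOfOrigin
    planted_class: PlantedClass
    planted_scenario: Scenario
    planted_fc: float | None
    planted_secretion_class: SecretionClass
    detectable_mono: bool
    detectable_co: bool


@dataclass
class _SimProtein:
    accession: str
    cell: CellOfOrigin
    klass: PlantedClass
    peptides: list[str]
    weights: np.ndarray
    psms_per_peptide: np.ndarray
    extra_sequence: list[str] = field(default_factory=list)
    shared_idx: set[int] = field(default_factory=set)
    abundance: float = 0.0
    sigma: float = 0.0
    fc: float = 1.0
    secretion: SecretionClass = SecretionClass.UNSCORED

    @property
    def sequence(self) -> str:
        return "".join(self.peptides) + "".join(self.extra_sequence)

    def quantifiable_weight(self) -> float:
        """Weight fraction the rollup can use: K/R-bearing, unshared peptides."""
        return float(sum(
            w for j, (pep, w) in enumerate(zip(self.peptides, self.weights))
            if j not in self.shared_idx and any(r in "KR" for r in pep)
        ))

    @property
    def present_mono(self) -> bool:
        return self.klass is not PlantedClass.CO_ONLY

    @property
    def present_co(self) -> bool:
        return self.klass is not PlantedClass.MONO_ONLY


@dataclass
class SyntheticExperiment:
    """Everything :func:`generate_experiment` emits, plus the ground truth."""

    config: GeneratorConfig
    psm_tables: dict[Condition, list[PsmRecord]]
    protein_db: dict[str, str]
    scores_map: dict[str, SecretionScores]
    truth: list[SyntheticTruth]

    def truth_by_accession(self) -> dict[str, SyntheticTruth]:
        return {t.accession: t for t in self.truth}

    def write(self, out_dir: str | Path) -> None:
        """Emit the fixture files in the dialects the readers consume."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for condition, table in self.psm_tables.items():
            psms_to_table(table, out / f"psm_{condition.value.lower()}.tsv")
        with open(out / "proteins.fasta", "w") as fh:
            for accession in sorted(self.protein_db):
                fh.write(f">{accession}\n{self.protein_db[accession]}\n")
        scores_to_table(self.scores_map, out / "secretion_scores.tsv")
        write_table(
            self.truth, out / "truth.tsv",
            schema=["accession", "cell_of_origin", "planted_class",
                    "planted_scenario", "planted_fc", "planted_secretion_class",
                    "detectable_mono", "detectable_co"],
        )


def _random_peptide(rng: np.random.Generator, seen: set[str], tryptic: bool) -> str:
    """A fresh random peptide, ending in K/R when tryptic."""
    while True:
        length = int(rng.integers(7, 15))
        interior = "".join(rng.choice(list(_AA_NO_KR), size=length - 1))
        last = str(rng.choice(["K", "R"])) if tryptic else str(
            rng.choice(list(_AA_NO_KR))
        )
        peptide = interior + last
        if peptide not in seen:
            seen.add(peptide)
            return peptide


_CLASS_ORDER = (
    (PlantedClass.MONO_ONLY, "n_mono_only"),
    (PlantedClass.CO_ONLY, "n_co_only"),
    (PlantedClass.CO_MO_UP, "n_co_mo_up"),
    (PlantedClass.CO_MO_DOWN, "n_co_mo_down"),
    (PlantedClass.BACKGROUND, "n_background_shared"),
)

_SECRETION_CHOICES = (
    SecretionClass.CSP, SecretionClass.NCSP,
    SecretionClass.NON_SECRETORY, SecretionClass.UNSCORED,
)


def _build_proteins(config: GeneratorConfig, rng: np.random.Generator) -> list[_SimProtein]:
    seen_peptides: set[str] = set()
    proteins: list[_SimProtein] = []
    for cell in (CellOfOrigin.A549, CellOfOrigin.THP1):
        index = 0
        for klass, count_attr in _CLASS_ORDER:
            for _ in range(getattr(config, count_attr)):
                index += 1
                n_pep = int(rng.integers(
                    config.peptides_per_protein[0], config.peptides_per_protein[1] + 1
                ))
                peptides = [
                    _random_peptide(rng, seen_peptides, tryptic=True)
                    for _ in range(n_pep)
                ]
                # half the proteins expose a C-terminal peptide without K/R;
                # it is channel-undecidable and must be excluded downstream
                if rng.random() < 0.5:
                    peptides.append(_random_peptide(rng, seen_peptides, tryptic=False))
                n_pep = len(peptides)
                weights = rng.uniform(0.5, 1.5, size=n_pep)
                weights /= weights.sum()
                n_psm = rng.integers(
                    config.psms_per_peptide[0], config.psms_per_peptide[1] + 1,
                    size=n_pep,
                )
                if klass is PlantedClass.CO_MO_UP:
                    fc = float(rng.uniform(*config.planted_fc_range))
                elif klass is PlantedClass.CO_MO_DOWN:
                    fc = 1.0 / float(rng.uniform(*config.planted_fc_range))
                else:
                    fc = 1.0
                sigma = (
                    config.candidate_sigma if klass.is_candidate
                    else float(rng.uniform(*config.replicate_sigma))
                )
                probs = (
                    config.candidate_secretion_probs if klass.is_candidate
                    else config.background_secretion_probs
                )
                secretion = _SECRETION_CHOICES[int(rng.choice(4, p=np.asarray(probs)))]
                proteins.append(_SimProtein(
                    accession=f"SYN{cell.value}{index:04d}",
                    cell=cell,
                    klass=klass,
                    peptides=peptides,
                    weights=weights,
                    psms_per_peptide=n_psm,
                    abundance=float(rng.lognormal(
                        config.base_log_area_mean, config.base_log_area_sd
                    )),
                    sigma=sigma,
                    fc=fc,
                    secretion=secretion,
                ))
    return proteins


def _plant_shared_peptides(
    config: GeneratorConfig, rng: np.random.Generator, proteins: list[_SimProtein]
) -> None:
    """Copy some background peptides into other proteins' sequences.

    The donor's peptide then matches two database proteins and must be
    excluded from quantification.  Donors are background proteins with at
    least three peptides, so no donor is pushed below the two-unique-peptide
    evidence floor by the donation itself.
    """
    if config.shared_peptide_fraction == 0:
        return

    def tryptic_unshared(p: _SimProtein) -> list[int]:
        return [
            j for j, pep in enumerate(p.peptides)
            if j not in p.shared_idx and any(r in "KR" for r in pep)
        ]

    total_peptides = sum(len(p.peptides) for p in proteins)
    n_shared = int(round(config.shared_peptide_fraction * total_peptides))
    for _ in range(n_shared):
        # donors keep at least two quantifiable peptides after donating
        donors = [
            p for p in proteins
            if p.klass is PlantedClass.BACKGROUND and len(tryptic_unshared(p)) >= 3
        ]
        if not donors:
            break
        donor = donors[int(rng.integers(len(donors)))]
        candidates = tryptic_unshared(donor)
        j = candidates[int(rng.integers(len(candidates)))]
        recipient = proteins[int(rng.integers(len(proteins)))]
        if recipient is donor:
            continue
        donor.shared_idx.add(j)
        recipient.extra_sequence.append(donor.peptides[j])


def _balance_totals(proteins: list[_SimProtein]) -> None:
    """Equalize true per-cell mono and co totals by rescaling the
    single-condition pools, so total-area normalization is unbiased by
    construction (its own modelling assumption).

    Totals are taken over the quantifiable (K/R-bearing, unshared) peptide
    fraction of each protein — the signal the rollup actually sums.
    """
    for cell in (CellOfOrigin.A549, CellOfOrigin.THP1):
        mono_only = [p for p in proteins if p.cell is cell and p.klass is PlantedClass.MONO_ONLY]
        co_only = [p for p in proteins if p.cell is cell and p.klass is PlantedClass.CO_ONLY]
        shared = [
            p for p in proteins
            if p.cell is cell and p.present_mono and p.present_co
        ]
        imbalance = sum(
            p.abundance * p.quantifiable_weight() * (p.fc - 1.0) for p in shared
        )
        mono_pool = sum(p.abundance * p.quantifiable_weight() for p in mono_only)
        co_pool = sum(p.abundance * p.quantifiable_weight() for p in co_only)
        if mono_pool == co_pool + imbalance:
            continue  # already balanced (e.g. background-only compositions)
        if mono_only and co_pool + imbalance > 0:
            scale = (co_pool + imbalance) / mono_pool
            for p in mono_only:
                p.abundance *= scale
        elif co_only and mono_pool - imbalance > 0:
            scale = (mono_pool - imbalance) / co_pool
            for p in co_only:
                p.abundance *= scale
        else:
            warnings.warn(
                f"{cell.value}: cannot mass-balance mono/co totals with this "
                f"planted composition; fold-change estimates will be biased",
                stacklevel=3,
            )


def _emit_protein_psms(
    config: GeneratorConfig,
    rng: np.random.Generator,
    protein: _SimProtein,
    condition: Condition,
    heavy: bool,
) -> list[PsmRecord]:
    mean = protein.abundance
    if condition is Condition.COCULTURE:
        mean *= protein.fc * config.co_culture_scale
    records: list[PsmRecord] = []
    for replicate in range(1, config.n_replicates + 1):
        if rng.random() < config.missing_replicate_rate:
            continue
        factor = math.exp(rng.normal(0.0, protein.sigma)) if protein.sigma > 0 else 1.0
        for j, peptide in enumerate(protein.peptides):
            n_psm = int(protein.psms_per_peptide[j])
            area = mean * factor * float(protein.weights[j]) / n_psm
            kr_positions = [
                i + 1 for i, residue in enumerate(peptide) if residue in "KR"
            ]
            for k in range(n_psm):
                mods: tuple[tuple[int, str], ...] = ()
                if heavy:
                    mods = tuple(
                        (pos, "Label:13C(6)") for pos in kr_positions
                        if rng.random() < config.label_incorporation
                    )
                records.append(PsmRecord(
                    spectrum_id=f"{condition.value}.{protein.accession}.r{replicate}.p{j}.{k}",
                    peptide=peptide,
                    modifications=mods,
                    charge=int(rng.choice([2, 3, 4], p=[0.6, 0.3, 0.1])),
                    search_score=float(rng.normal(
                        config.target_score_mean, config.target_score_sd
                    )),
                    is_decoy=False,
                    protein_accessions=(protein.accession,),
                    peak_area=area,
                    condition=condition,
                    replicate=replicate,
                ))
    return records


def _emit_decoys(
    config: GeneratorConfig,
    rng: np.random.Generator,
    condition: Condition,
    n_targets: int,
) -> list[PsmRecord]:
    if config.decoy_fraction == 0 or n_targets == 0:
        return []
    n_decoys = int(round(
        config.decoy_fraction / (1.0 - config.decoy_fraction) * n_targets
    ))
    seen: set[str] = set()
    records = []
    for i in range(n_decoys):
        peptide = _random_peptide(rng, seen, tryptic=True)
        records.append(PsmRecord(
            spectrum_id=f"{condition.value}.DECOY.{i}",
            peptide=peptide,
            modifications=(),
            charge=int(rng.choice([2, 3, 4], p=[0.6, 0.3, 0.1])),
            search_score=float(rng.normal(
                config.decoy_score_mean, config.decoy_score_sd
            )),
            is_decoy=True,
            protein_accessions=(f"DECOY_{condition.value}_{i}",),
            peak_area=float(rng.lognormal(config.base_log_area_mean - 2.0, 1.0)),
            condition=condition,
            replicate=int(rng.integers(1, config.n_replicates + 1)),
        ))
    return records


def _draw_scores(
    config: GeneratorConfig, rng: np.random.Generator, proteins: list[_SimProtein]
) -> dict[str, SecretionScores]:
    """Class-conditional score draws straddling the 0.45 / 0.5 cut-offs."""
    scores: dict[str, SecretionScores] = {}
    for protein in proteins:
        if protein.secretion is SecretionClass.UNSCORED:
            continue
        if protein.secretion is SecretionClass.CSP:
            d = float(rng.uniform(0.45, 0.98))
            nn = float(rng.uniform(0.02, 0.98))
        elif protein.secretion is SecretionClass.NCSP:
            d = float(rng.uniform(0.02, 0.44))
            nn = float(rng.uniform(0.50, 0.98))
        else:
            d = float(rng.uniform(0.02, 0.44))
            nn = float(rng.uniform(0.02, 0.49))
        scores[protein.accession] = SecretionScores(
            accession=protein.accession, signalp_d=d, secretomep_nn=nn
        )
    return scores


_SCENARIO_OF_CLASS = {
    PlantedClass.MONO_ONLY: "MONO_ONLY",
    PlantedClass.CO_ONLY: "CO_ONLY",
    PlantedClass.CO_MO_UP: "CO_MO",
    PlantedClass.CO_MO_DOWN: "CO_MO",
    PlantedClass.BACKGROUND: "CO_MO",
}


def generate_experiment(config: GeneratorConfig | None = None) -> SyntheticExperiment:
    """Draw one full synthetic experiment from the configured conditions.

    Emits the three PSM tables, the protein FASTA map, the secretion-score
    table and the ground-truth table.  All randomness comes from one
    ``numpy`` Generator seeded with ``config.seed``, consumed in a fixed
    order (proteins, shared peptides, balancing, target PSMs per condition,
    decoys, secretion scores), so equal seeds give identical outputs.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)

    proteins = _build_proteins(config, rng)
    _plant_shared_peptides(config, rng, proteins)
    if config.balance_totals:
        _balance_totals(proteins)

    tables: dict[Condition, list[PsmRecord]] = {c: [] for c in Condition}
    for protein in proteins:
        if protein.cell is CellOfOrigin.A549 and protein.present_mono:
            tables[Condition.A549_MONO].extend(_emit_protein_psms(
                config, rng, protein, Condition.A549_MONO, heavy=True
            ))
    for protein in proteins:
        if protein.cell is CellOfOrigin.THP1 and protein.present_mono:
            tables[Condition.THP1_MONO].extend(_emit_protein_psms(
                config, rng, protein, Condition.THP1_MONO, heavy=False
            ))
    for protein in proteins:
        if protein.present_co:
            tables[Condition.COCULTURE].extend(_emit_protein_psms(
                config, rng, protein, Condition.COCULTURE,
                heavy=protein.cell is CellOfOrigin.A549,
            ))
    for condition in Condition:
        tables[condition].extend(
            _emit_decoys(config, rng, condition, len(tables[condition]))
        )

    scores = _draw_scores(config, rng, proteins)
    truth = [
        SyntheticTruth(
            accession=p.accession,
            cell_of_origin=p.cell,
            planted_class=p.klass,
            planted_scenario=Scenario(f"{p.cell.value}_{_SCENARIO_OF_CLASS[p.klass]}"),
            planted_fc=p.fc if _SCENARIO_OF_CLASS[p.klass] == "CO_MO" else None,
            planted_secretion_class=p.secretion,
            detectable_mono=p.present_mono,
            detectable_co=p.present_co,
        )
        for p in proteins
    ]
    protein_db = {p.accession: p.sequence for p in proteins}
    return SyntheticExperiment(
        config=config,
        psm_tables=tables,
        protein_db=protein_db,
        scores_map=scores,
        truth=truth,
    )


def study_scale_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Preset at the real study's approximate scale (~400 proteins)."""
    return GeneratorConfig(seed=seed, **overrides)


def noiseless_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Zero noise, zero missingness, full incorporation, no decoys.

    Under this preset the pipeline recovers every planted scenario and
    every planted fold change exactly.
    """
    defaults = dict(
        seed=seed,
        replicate_sigma=(0.0, 0.0),
        candidate_sigma=0.0,
        shared_peptide_fraction=0.0,
        decoy_fraction=0.0,
        label_incorporation=1.0,
        missing_replicate_rate=0.0,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


def generate_study_scale(seed: int = 0) -> SyntheticExperiment:
    """Convenience: one experiment from :func:`study_scale_config`."""
    return generate_experiment(study_scale_config(seed))


@dataclass(frozen=True)
class RecoveryMetrics:
    """How well the pipeline recovered the planted truth.

    ``scenario_recall`` is computed over the planted candidate classes (the
    signals the generator plants as clean, shortlistable effects); an
    undetected candidate counts as a miss.  ``fc_rel_errors`` are the
    relative fold-change errors of recovered up/down-regulated candidates;
    ``secretion_accuracy`` compares the called secretion class of every
    shortlisted candidate against the planted one.
    """

    n_candidates: int
    n_scenario_correct: int
    fc_rel_errors: tuple[float, ...]
    n_secretion_evaluated: int
    n_secretion_correct: int

    @property
    def scenario_recall(self) -> float:
        return self.n_scenario_correct / self.n_candidates if self.n_candidates else 1.0

    @property
    def median_fc_rel_error(self) -> float:
        if not self.fc_rel_errors:
            return 0.0
        return float(np.median(self.fc_rel_errors))

    @property
    def max_fc_rel_error(self) -> float:
        return max(self.fc_rel_errors, default=0.0)

    @property
    def secretion_accuracy(self) -> float:
        if not self.n_secretion_evaluated:
            return 1.0
        return self.n_secretion_correct / self.n_secretion_evaluated


def score_recovery(records: Sequence, truth: Sequence[SyntheticTruth]) -> RecoveryMetrics:
    """Compare emitted :class:`DifferentialRecord` rows with the truth table."""
    by_accession = {r.accession: r for r in records}
    n_candidates = 0
    n_correct = 0
    fc_errors: list[float] = []
    n_secr = 0
    n_secr_ok = 0
    for entry in truth:
        if not entry.planted_class.is_candidate:
            continue
        n_candidates += 1
        record = by_accession.get(entry.accession)
        if record is None:
            continue
        if record.scenario is entry.planted_scenario:
            n_correct += 1
        if (
            entry.planted_class in (PlantedClass.CO_MO_UP, PlantedClass.CO_MO_DOWN)
            and record.fold_change is not None
            and entry.planted_fc
        ):
            fc_errors.append(
                abs(record.fold_change - entry.planted_fc) / entry.planted_fc
            )
        if record.shortlisted:
            n_secr += 1
            if record.secretion_class is entry.planted_secretion_class:
                n_secr_ok += 1
    return RecoveryMetrics(
        n_candidates=n_candidates,
        n_scenario_correct=n_correct,
        fc_rel_errors=tuple(fc_errors),
        n_secretion_evaluated=n_secr,
        n_secretion_correct=n_secr_ok,
    )
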