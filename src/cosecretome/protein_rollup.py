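"""Peptide-to-protein rollup and the evidence filter.

FDR-passing, channel-assigned PSMs are aggregated per protein and
condition: only peptides mapping to exactly one database protein are
quantified (shared peptides carry no unambiguous protein identity), peak
areas of their PSMs are summed within each replicate, and a protein is
documented in a condition only with at least two unique peptides, four
PSMs, detection in at least two replicates and a replicate %CV of at most
30.  A replicate without any unique-peptide PSM for a protein counts as
*not detected* there (missingness is not zero abundance).

%CV is the percent coefficient of variation, 100 * sd / mean, with the
sample (n-1) standard deviation, computed on raw per-replicate areas
within a condition (before any mono/co normalization).
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .psm_io import PipelineConfig, PsmRecord

__all__ = [
    "CellOfOrigin",
    "Culture",
    "ProteinQuant",
    "UniquenessIndex",
    "is_unique_peptide",
    "percent_cv",
    "rollup_proteins",
    "evidence_filter",
    "quants_to_frame",
    "write_quants",
]

_LABELABLE = frozenset("KR")


class CellOfOrigin(str, enum.Enum):
    A549 = "A549"
    THP1 = "THP1"


class Culture(str, enum.Enum):
    MONO = "MONO"
    CO = "CO"


@dataclass(frozen=True)
class ProteinQuant:
    """Per-protein, per-condition, per-cell-of-origin quantification."""

    accession: str
    cell_of_origin: CellOfOrigin
    condition: Culture
    unique_peptide_count: int
    psm_count: int
    area_by_replicate: Mapping[int, float] = field(default_factory=dict)

    @property
    def n_replicates_detected(self) -> int:
        return len(self.area_by_replicate)

    @property
    def mean_area(self) -> float:
        if not self.area_by_replicate:
            raise ValueError(f"{self.accession}: no replicate areas present")
        return sum(self.area_by_replicate.values()) / len(self.area_by_replicate)

    @property
    def percent_cv(self) -> float | None:
        """Replicate %CV; undefined (None) below two detected replicates."""
        if self.n_replicates_detected < 2:
            return None
        return percent_cv(list(self.area_by_replicate.values()))

    def scaled(self, factor: float) -> "ProteinQuant":
        """A copy with every replicate area multiplied by ``factor``."""
        return replace(
            self,
            area_by_replicate={r: a * factor for r, a in self.area_by_replicate.items()},
        )


def percent_cv(areas: Sequence[float]) -> float:
    """100 * sample standard deviation / mean of per-replicate areas."""
    if len(areas) < 2:
        raise ValueError(f"%CV undefined for fewer than 2 values (got {len(areas)})")
    for area in areas:
        if not area > 0:
            raise ValueError(f"%CV requires positive areas, got {area}")
    mean = sum(areas) / len(areas)
    sd = math.sqrt(sum((a - mean) ** 2 for a in areas) / (len(areas) - 1))
    return 100.0 * sd / mean


class UniquenessIndex:
    """Cached peptide-uniqueness lookups against a protein database.

    A peptide is *unique* when it occurs as a substring of exactly one
    database protein (I and L are treated as distinct residues).
    """

    def __init__(self, protein_db: Mapping[str, str]):
        if not protein_db:
            raise ValueError("protein database is empty")
        self._db = protein_db
        self._cache: dict[str, int] = {}

    def match_count(self, peptide: str) -> int:
        """Number of database proteins containing the peptide (capped at 2)."""
        cached = self._cache.get(peptide)
        if cached is not None:
            return cached
        count = 0
        for sequence in self._db.values():
            if peptide in sequence:
                count += 1
                if count > 1:
                    break
        self._cache[peptide] = count
        return count

    def is_unique(self, peptide: str) -> bool:
        count = self.match_count(peptide)
        if count == 0:
            warnings.warn(
                f"peptide {peptide!r} not found in the protein database",
                stacklevel=2,
            )
        return count == 1


def is_unique_peptide(peptide: str, protein_db: Mapping[str, str]) -> bool:
    """True iff ``peptide`` occurs in exactly one database protein."""
    return UniquenessIndex(protein_db).is_unique(peptide)


def rollup_proteins(
    psms: Iterable[PsmRecord],
    protein_db: Mapping[str, str] | UniquenessIndex,
    cell_of_origin: CellOfOrigin,
    condition: Culture,
    config: PipelineConfig | None = None,
    exclude_unlabelable: bool = True,
) -> list[ProteinQuant]:
    """Aggregate PSMs of one condition/cell group into protein quantities.

    PSMs mapping to multiple accessions and peptides that are not unique in
    the database are excluded from quantification; with
    ``exclude_unlabelable`` (default) peptides without any K/R residue are
    excluded too, keeping the quantified peptide space identical between
    monoculture tables (which bypass channel splitting) and the split
    co-culture tables (where such peptides are channel-ambiguous).
    """
    index = (
        protein_db
        if isinstance(protein_db, UniquenessIndex)
        else UniquenessIndex(protein_db)
    )
    # accession -> replicate -> area; peptide sets and PSM tallies alongside
    areas: dict[str, dict[int, float]] = {}
    peptides: dict[str, set[str]] = {}
    psm_counts: dict[str, int] = {}
    evidenced: set[str] = set()
    with warnings.catch_warnings():
        # absent-peptide warnings are per-peptide diagnostics, not per-PSM noise
        warnings.simplefilter("once")
        for psm in psms:
            if psm.is_decoy:
                continue
            evidenced.update(psm.protein_accessions)
            if len(psm.protein_accessions) != 1:
                continue
            if exclude_unlabelable and not any(r in _LABELABLE for r in psm.peptide):
                continue
            if not index.is_unique(psm.peptide):
                continue
            accession = psm.protein_accessions[0]
            areas.setdefault(accession, {})
            areas[accession][psm.replicate] = (
                areas[accession].get(psm.replicate, 0.0) + psm.peak_area
            )
            peptides.setdefault(accession, set()).add(psm.peptide)
            psm_counts[accession] = psm_counts.get(accession, 0) + 1

    quants = [
        ProteinQuant(
            accession=accession,
            cell_of_origin=cell_of_origin,
            condition=condition,
            unique_peptide_count=len(peptides[accession]),
            psm_count=psm_counts[accession],
            area_by_replicate=dict(sorted(areas[accession].items())),
        )
        for accession in sorted(areas)
    ]
    # proteins whose only evidence was shared/ambiguous peptides stay visible
    # with zero counts, so the evidence filter can reject them with a reason
    quants.extend(
        ProteinQuant(
            accession=accession,
            cell_of_origin=cell_of_origin,
            condition=condition,
            unique_peptide_count=0,
            psm_count=0,
            area_by_replicate={},
        )
        for accession in sorted(evidenced - set(areas))
    )
    return quants


def evidence_filter(
    quants: Iterable[ProteinQuant],
    config: PipelineConfig | None = None,
) -> tuple[list[ProteinQuant], list[tuple[ProteinQuant, str]]]:
    """Apply the documentation rule; returns (retained, rejected-with-reason).

    Retained iff unique_peptide_count >= 2, psm_count >= 4, detection in
    >= 2 replicates and %CV <= 30 (boundaries from the configuration; all
    comparisons at the stated thresholds, %CV inclusive).  Each rejection
    carries its first failing rule: ``unique_peptides``, ``psms``,
    ``replicates`` or ``cv``.  The filter is idempotent.
    """
    config = config or PipelineConfig()
    retained: list[ProteinQuant] = []
    rejected: list[tuple[ProteinQuant, str]] = []
    for quant in quants:
        if quant.unique_peptide_count < config.min_unique_peptides:
            rejected.append((quant, "unique_peptides"))
        elif quant.psm_count < config.min_psms:
            rejected.append((quant, "psms"))
        elif quant.n_replicates_detected < config.min_replicates:
            rejected.append((quant, "replicates"))
        elif quant.percent_cv > config.max_percent_cv:
            rejected.append((quant, "cv"))
        else:
            retained.append(quant)
    return retained, rejected


def quants_to_frame(quants: Sequence[ProteinQuant]) -> pd.DataFrame:
    """One row per protein per condition: counts, replicate areas, %CV."""
    replicates = sorted({r for q in quants for r in q.area_by_replicate})
    rows = []
    for quant in sorted(quants, key=lambda q: (q.accession, q.condition.value)):
        row = {
            "accession": quant.accession,
            "cell_of_origin": quant.cell_of_origin.value,
            "condition": quant.condition.value,
            "unique_peptide_count": quant.unique_peptide_count,
            "psm_count": quant.psm_count,
            "n_replicates_detected": quant.n_replicates_detected,
        }
        for r in replicates:
            row[f"area_rep{r}"] = quant.area_by_replicate.get(r)
        row["mean_area"] = quant.mean_area if quant.area_by_replicate else None
        row["percent_cv"] = quant.percent_cv
        rows.append(row)
    return pd.DataFrame(rows)


def write_quants(quants: Sequence[ProteinQuant], path) -> None:
    quants_to_frame(quants).to_csv(path, sep="\t", index=False, lineterminator="\n")
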