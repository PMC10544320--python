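"""Reading and writing of PSM exports, FASTA databases and score tables.

The pipeline consumes the tab-separated peptide-spectrum-match (PSM) export
of a database search engine (one row per PSM with its peak area), a protein
FASTA used for peptide-uniqueness decisions, and a per-accession secretion
score table (SignalP D-score, SecretomeP NN-score).  Search engines disagree
on column names and on how decoy hits are encoded, so every reader accepts a
:class:`TableDialect` that maps the canonical column names onto the file's
and selects between a boolean decoy column and a decoy accession prefix.

All tabular output is plain TSV with a single header line, written in a
deterministic row order so repeated runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from pydantic import BaseModel, Field, field_validator

__all__ = [
    "Condition",
    "PsmRecord",
    "SecretionScores",
    "PipelineConfig",
    "TableDialect",
    "RowDiagnostic",
    "PsmParseError",
    "SchemaError",
    "read_psm_table",
    "read_fasta_db",
    "read_secretion_scores",
    "write_table",
    "read_table",
]

_PEPTIDE_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")


class Condition(str, enum.Enum):
    """Sample condition of a PSM table."""

    A549_MONO = "A549_MONO"
    THP1_MONO = "THP1_MONO"
    COCULTURE = "COCULTURE"


class SchemaError(ValueError):
    """A required column is missing or a table is structurally invalid."""


class PsmParseError(ValueError):
    """Raised when more than the tolerated fraction of rows fail to parse."""

    def __init__(self, message: str, diagnostics: list["RowDiagnostic"]):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class RowDiagnostic:
    """One rejected input row with the reason for its rejection."""

    row_number: int
    message: str


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match with label modifications and provenance.

    ``modifications`` is a tuple of ``(position, name)`` pairs with 1-based
    residue positions; SILAC labels appear here (default name
    ``Label:13C(6)``).  ``protein_accessions`` holds every accession the
    search engine mapped the peptide to; PSMs with more than one are later
    excluded from quantification.
    """

    spectrum_id: str
    peptide: str
    modifications: tuple[tuple[int, str], ...]
    charge: int
    search_score: float
    is_decoy: bool
    protein_accessions: tuple[str, ...]
    peak_area: float
    condition: Condition
    replicate: int

    def validate(self) -> None:
        """Raise ``ValueError`` on any invariant violation."""
        if not _PEPTIDE_RE.match(self.peptide):
            raise ValueError(f"peptide {self.peptide!r} contains non-standard residues")
        if self.charge < 1:
            raise ValueError(f"charge must be positive, got {self.charge}")
        if not self.peak_area >= 0:
            raise ValueError(f"peak_area must be non-negative, got {self.peak_area}")
        if not self.protein_accessions:
            raise ValueError("protein_accessions must be non-empty")
        for pos, name in self.modifications:
            if not 1 <= pos <= len(self.peptide):
                raise ValueError(
                    f"modification position {pos} outside peptide of length {len(self.peptide)}"
                )
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")
        if self.search_score != self.search_score:  # NaN
            raise ValueError("search_score is NaN")


@dataclass(frozen=True)
class SecretionScores:
    """SignalP D-score and SecretomeP NN-score for one accession."""

    accession: str
    signalp_d: float
    secretomep_nn: float

    def validate(self) -> None:
        for label, score in (("signalp_d", self.signalp_d), ("secretomep_nn", self.secretomep_nn)):
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"{label} must lie in [0, 1], got {score}")


class PipelineConfig(BaseModel):
    """All thresholds of the filter cascade, with the study's defaults.

    Parameters
    ----------
    fdr_alpha
        PSM-level q-value cut-off of the target-decoy filter.
    min_replicates, n_replicates
        A protein must be detected in at least ``min_replicates`` of the
        ``n_replicates`` runs of a condition.
    min_unique_peptides, min_psms, max_percent_cv
        Evidence filter: at least two unique peptides, four PSMs, and a
        replicate %CV of at most 30 are required for a protein to be
        documented in a condition.
    shortlist_cv, shortlist_fc
        Candidate shortlisting: %CV strictly below 10 for single-condition
        scenarios, fold change strictly above 3 for mono-vs-co scenarios.
    signalp_d_cutoff, secretomep_nn_cutoff
        Inclusive score cut-offs for calling classical (CSP) and
        non-classical (NCSP) secretion.
    fc_magnitude_mode
        When true (default) a fold change below ``1/shortlist_fc`` also
        shortlists, so strong down-regulation is kept alongside
        up-regulation.
    label_names
        Modification names recognised as heavy SILAC labels.
    label_tolerance
        Tolerated fraction of wrong-channel PSMs in a monoculture table
        before a labeling-efficiency warning is emitted.
    """

    fdr_alpha: float = 0.01
    min_replicates: int = 2
    n_replicates: int = 3
    min_unique_peptides: int = 2
    min_psms: int = 4
    max_percent_cv: float = 30.0
    shortlist_cv: float = 10.0
    shortlist_fc: float = 3.0
    signalp_d_cutoff: float = 0.45
    secretomep_nn_cutoff: float = 0.5
    fc_magnitude_mode: bool = True
    label_names: frozenset[str] = frozenset({"Label:13C(6)"})
    label_tolerance: float = 0.02
    seed: int = 0

    model_config = {"frozen": True}

    @field_validator(
        "min_replicates", "n_replicates", "min_unique_peptides", "min_psms",
        "max_percent_cv", "shortlist_cv", "shortlist_fc",
        "signalp_d_cutoff", "secretomep_nn_cutoff",
    )
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError("thresholds must be positive")
        return v

    @field_validator("fdr_alpha")
    @classmethod
    def _alpha_range(cls, v):
        if not 0.0 < v <= 1.0:
            raise ValueError(f"fdr_alpha must lie in (0, 1], got {v}")
        return v

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a configuration from a JSON key/value file."""
        with open(path) as fh:
            return cls(**json.load(fh))


class TableDialect(BaseModel):
    """Column-name mapping and encoding conventions of a PSM export.

    ``columns`` maps canonical names (the :class:`PsmRecord` field names)
    to the names used in the file.  Decoy status is read from
    ``decoy_column`` when present in the file, otherwise inferred from
    ``decoy_prefix`` on the accessions.
    """

    columns: dict[str, str] = Field(default_factory=dict)
    decoy_column: str | None = "is_decoy"
    decoy_prefix: str | None = None
    accession_sep: str = ";"
    mod_sep: str = ","
    fasta_accession_pipe_field: int | None = None

    def resolve(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


_REQUIRED_PSM_COLUMNS = (
    "spectrum_id", "peptide", "charge", "search_score",
    "protein_accessions", "peak_area", "condition", "replicate",
)

#: Fraction of unparseable rows tolerated before the whole read aborts.
#: Allows stray footer lines without masking a corrupt file.
ROW_FAILURE_TOLERANCE = 0.01


def _parse_modifications(text: str, mod_sep: str) -> tuple[tuple[int, str], ...]:
    text = (text or "").strip()
    if not text or text.lower() == "nan":
        return ()
    mods = []
    for token in text.split(mod_sep):
        token = token.strip()
        if not token:
            continue
        pos_text, _, name = token.partition(":")
        mods.append((int(pos_text), name))
    return tuple(mods)


def _format_modifications(mods: Sequence[tuple[int, str]], mod_sep: str = ",") -> str:
    return mod_sep.join(f"{pos}:{name}" for pos, name in mods)


def read_psm_table(
    path: str | Path,
    dialect: TableDialect | None = None,
) -> tuple[list[PsmRecord], list[RowDiagnostic]]:
    """Read a PSM export table into validated records.

    Every input row becomes either a :class:`PsmRecord` or a
    :class:`RowDiagnostic`; the two counts always add up to the number of
    data rows.  The read aborts with :class:`PsmParseError` when more than
    ``ROW_FAILURE_TOLERANCE`` of rows fail.
    """
    dialect = dialect or TableDialect()
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    for canonical in _REQUIRED_PSM_COLUMNS:
        if dialect.resolve(canonical) not in frame.columns:
            raise SchemaError(
                f"required column {dialect.resolve(canonical)!r} (for {canonical!r}) "
                f"missing from {path}"
            )
    decoy_col = dialect.decoy_column if (
        dialect.decoy_column and dialect.decoy_column in frame.columns
    ) else None
    if decoy_col is None and dialect.decoy_prefix is None:
        raise SchemaError(
            "no decoy encoding available: decoy column absent and no decoy_prefix set"
        )
    mods_col = dialect.resolve("modifications")

    records: list[PsmRecord] = []
    diagnostics: list[RowDiagnostic] = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        row = dict(zip(frame.columns, row))
        try:
            accessions = tuple(
                a.strip() for a in row[dialect.resolve("protein_accessions")].split(
                    dialect.accession_sep
                ) if a.strip()
            )
            if decoy_col is not None:
                is_decoy = row[decoy_col].strip().lower() in ("true", "1", "yes")
            else:
                flags = [a.startswith(dialect.decoy_prefix) for a in accessions]
                if any(flags) and not all(flags):
                    raise ValueError("decoy and target accessions mixed in one record")
                is_decoy = bool(flags) and all(flags)
            record = PsmRecord(
                spectrum_id=row[dialect.resolve("spectrum_id")],
                peptide=row[dialect.resolve("peptide")].strip().upper(),
                modifications=_parse_modifications(
                    row.get(mods_col, ""), dialect.mod_sep
                ),
                charge=int(row[dialect.resolve("charge")]),
                search_score=float(row[dialect.resolve("search_score")]),
                is_decoy=is_decoy,
                protein_accessions=accessions,
                peak_area=float(row[dialect.resolve("peak_area")]),
                condition=Condition(row[dialect.resolve("condition")].strip()),
                replicate=int(row[dialect.resolve("replicate")]),
            )
            record.validate()
            records.append(record)
        except (ValueError, KeyError) as exc:
            diagnostics.append(RowDiagnostic(row_number=idx + 2, message=str(exc)))

    if diagnostics and len(diagnostics) > ROW_FAILURE_TOLERANCE * len(frame):
        raise PsmParseError(
            f"{len(diagnostics)} of {len(frame)} rows failed to parse "
            f"(tolerance {ROW_FAILURE_TOLERANCE:.0%}); first: "
            f"row {diagnostics[0].row_number}: {diagnostics[0].message}",
            diagnostics,
        )
    return records, diagnostics


def read_fasta_db(
    path: str | Path,
    dialect: TableDialect | None = None,
) -> dict[str, str]:
    """Read a protein FASTA into an accession -> uppercase-sequence map.

    The accession is the first whitespace-delimited header token, or — for
    ``sp|P01234|NAME``-style headers — the pipe-delimited field selected by
    ``dialect.fasta_accession_pipe_field``.
    """
    pipe_field = dialect.fasta_accession_pipe_field if dialect else None
    db: dict[str, str] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        accession = entry.id
        if pipe_field is not None and "|" in accession:
            accession = accession.split("|")[pipe_field]
        if accession in db:
            raise SchemaError(f"duplicate accession {accession!r} in {path}")
        sequence = str(entry.seq).upper()
        if not sequence:
            raise SchemaError(f"empty sequence for accession {accession!r} in {path}")
        db[accession] = sequence
    return db


def read_secretion_scores(path: str | Path) -> dict[str, SecretionScores]:
    """Read the per-accession SignalP/SecretomeP score table."""
    frame = pd.read_csv(path, sep="\t")
    for column in ("accession", "signalp_d", "secretomep_nn"):
        if column not in frame.columns:
            raise SchemaError(f"required column {column!r} missing from {path}")
    scores: dict[str, SecretionScores] = {}
    for row in frame.itertuples(index=False):
        if row.accession in scores:
            raise SchemaError(f"duplicate accession {row.accession!r} in {path}")
        entry = SecretionScores(
            accession=str(row.accession),
            signalp_d=float(row.signalp_d),
            secretomep_nn=float(row.secretomep_nn),
        )
        entry.validate()
        scores[entry.accession] = entry
    return scores


# ---------------------------------------------------------------------------
# generic TSV round-trip for the package's dataclass record types


def _encode_value(value):
    if isinstance(value, enum.Enum):
        return value.value
    if isinstance(value, tuple) and value and isinstance(value[0], tuple):
        return _format_modifications(value)
    if isinstance(value, tuple):
        return ";".join(str(v) for v in value)
    if isinstance(value, dict):
        return ";".join(f"{k}={v!r}" for k, v in sorted(value.items()))
    if value is None:
        return ""
    return value


def _default_sort_key(record):
    key = []
    for attr in ("accession", "condition", "cell_of_origin", "scenario",
                 "spectrum_id", "replicate", "peptide"):
        if hasattr(record, attr):
            value = getattr(record, attr)
            key.append(value.value if isinstance(value, enum.Enum) else str(value))
    return tuple(key)


def write_table(records: Iterable, path: str | Path, schema: Sequence[str] | None = None) -> None:
    """Write dataclass records as a TSV with a stable column and row order.

    ``schema`` restricts/reorders columns; by default all dataclass fields
    are written in declaration order.  Rows are sorted on accession,
    condition and related identity fields so re-exports are byte-identical.
    An empty record list yields a header-only file (``schema`` required).
    """
    records = sorted(records, key=_default_sort_key)
    if not records and schema is None:
        raise SchemaError("schema required to write an empty table")
    if schema is None:
        schema = [f.name for f in dataclasses.fields(records[0])]
    rows = [
        {name: _encode_value(getattr(record, name)) for name in schema}
        for record in records
    ]
    frame = pd.DataFrame(rows, columns=list(schema))
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])


def psms_to_table(records: Iterable[PsmRecord], path: str | Path) -> None:
    """Write PSM records in the same dialect :func:`read_psm_table` reads."""
    schema = [f.name for f in dataclasses.fields(PsmRecord)]
    write_table(records, path, schema=schema)


def scores_to_table(scores: Mapping[str, SecretionScores], path: str | Path) -> None:
    write_table(
        list(scores.values()), path, schema=["accession", "signalp_d", "secretomep_nn"]
    )
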