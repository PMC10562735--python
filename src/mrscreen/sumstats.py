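"""Data model and TSV I/O for GWAS summary statistics.

A summary-statistics study is a table with one row per SNP carrying the
additive association of the effect allele with the trait: identifier,
location, allele pair, effect-allele frequency, beta, standard error,
p-value and sample size.  Betas are log-odds for binary traits and SD
units for continuous traits.  Files are tab-separated text with a header
row; gzip-compressed input is accepted.  Column-name dialects (e.g.
``rsid``/``A1`` style headers from different consortia) are mapped onto
the canonical names at read time.
"""

from __future__ import annotations

import csv
import gzip
import io
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CANONICAL_COLUMNS",
    "VALID_ALLELES",
    "SummaryRecord",
    "StudyMeta",
    "Study",
    "SumstatsFormatError",
    "SumstatsValidationError",
    "read_sumstats",
    "write_sumstats",
    "records_to_frame",
    "frame_to_records",
]

CANONICAL_COLUMNS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)

VALID_ALLELES = frozenset("ACGT")

TAXON_LEVELS = ("phylum", "class", "order", "family", "genus", "none")


class SumstatsFormatError(ValueError):
    """A file-level problem: missing columns, unparseable rows."""


class SumstatsValidationError(ValueError):
    """One or more rows violate a record invariant.

    Attributes
    ----------
    row_errors : list of (row_number, message)
        1-based data-row numbers (header not counted).
    """

    def __init__(self, row_errors: Sequence[tuple[int, str]]):
        self.row_errors = list(row_errors)
        lines = "; ".join(f"row {i}: {msg}" for i, msg in self.row_errors)
        super().__init__(f"invalid summary-statistic rows: {lines}")


@dataclass(frozen=True)
class SummaryRecord:
    """One SNP's association statistics in one study."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int

    def validate(self) -> list[str]:
        """Return the list of invariant violations (empty when valid)."""
        problems: list[str] = []
        for name in ("effect_allele", "other_allele"):
            a = getattr(self, name)
            if a not in VALID_ALLELES:
                problems.append(f"{name} {a!r} is not a single A/C/G/T base")
        if (
            self.effect_allele in VALID_ALLELES
            and self.effect_allele == self.other_allele
        ):
            problems.append("effect_allele equals other_allele")
        if not 0.0 < self.eaf < 1.0:
            problems.append(f"eaf {self.eaf} outside (0, 1)")
        if not self.se > 0.0:
            problems.append(f"se {self.se} must be > 0")
        if not 0.0 < self.pvalue <= 1.0:
            problems.append(f"pvalue {self.pvalue} outside (0, 1]")
        if not self.n > 0:
            problems.append(f"n {self.n} must be > 0")
        if not self.pos > 0:
            problems.append(f"pos {self.pos} must be a positive 1-based coordinate")
        return problems


@dataclass(frozen=True)
class StudyMeta:
    """Study-level metadata: what trait, what role, what taxonomic slot."""

    trait_name: str = ""
    trait_role: str = "exposure"  # exposure | outcome
    trait_type: str = "continuous"  # continuous | binary
    taxon_level: str = "none"  # phylum|class|order|family|genus|none
    taxon_id: str = ""

    def __post_init__(self) -> None:
        if self.trait_role not in ("exposure", "outcome"):
            raise ValueError(f"trait_role {self.trait_role!r} invalid")
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type {self.trait_type!r} invalid")
        if self.taxon_level not in TAXON_LEVELS:
            raise ValueError(f"taxon_level {self.taxon_level!r} invalid")


@dataclass
class Study:
    """A validated record list plus its metadata."""

    records: list[SummaryRecord]
    meta: StudyMeta = field(default_factory=StudyMeta)

    @property
    def frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode, newline="" if "w" in mode else None)


_META_PREFIX = "##"

_FLOAT_FIELDS = {"eaf", "beta", "se", "pvalue"}
_INT_FIELDS = {"pos", "n"}


def _parse_value(name: str, raw: str):
    if name in _FLOAT_FIELDS:
        return float(raw)
    if name in _INT_FIELDS:
        return int(raw)
    if name in ("effect_allele", "other_allele"):
        return raw.strip().upper()
    return raw


def read_sumstats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> Study:
    """Read a summary-statistics TSV into a validated :class:`Study`.

    Parameters
    ----------
    path
        TSV (optionally gzip-compressed) with a header row.  Leading
        ``##key=value`` comment lines populate :class:`StudyMeta`.
    dialect
        Optional mapping from canonical field name to the column name used
        in this file, e.g. ``{"snp_id": "rsid", "effect_allele": "A1"}``.
        Unmapped fields use their canonical names.

    Raises
    ------
    SumstatsFormatError
        Missing required column, or a cell that cannot be parsed.
    SumstatsValidationError
        Rows violating record invariants, reported with row numbers.
    """
    dialect = dict(dialect or {})
    colname = {f: dialect.get(f, f) for f in CANONICAL_COLUMNS}

    meta_kv: dict[str, str] = {}
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    body_start = 0
    for line in lines:
        if line.startswith(_META_PREFIX):
            body_start += 1
            key, _, value = line[len(_META_PREFIX):].partition("=")
            meta_kv[key.strip()] = value.strip()
        else:
            break
    rows = list(csv.reader(io.StringIO("\n".join(lines[body_start:])), delimiter="\t"))
    if not rows:
        raise SumstatsFormatError(f"{path}: empty file (no header)")
    header = rows[0]
    missing = [colname[f] for f in CANONICAL_COLUMNS if colname[f] not in header]
    if missing:
        raise SumstatsFormatError(f"{path}: missing required columns {missing}")
    index = {colname[f]: header.index(colname[f]) for f in CANONICAL_COLUMNS}

    records: list[SummaryRecord] = []
    errors: list[tuple[int, str]] = []
    for i, row in enumerate(rows[1:], start=1):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != len(header):
            raise SumstatsFormatError(
                f"{path}: row {i} has {len(row)} fields, header has {len(header)}"
            )
        kwargs = {}
        try:
            for f in CANONICAL_COLUMNS:
                kwargs[f] = _parse_value(f, row[index[colname[f]]])
        except ValueError as exc:
            raise SumstatsFormatError(f"{path}: row {i}: {exc}") from exc
        rec = SummaryRecord(**kwargs)
        problems = rec.validate()
        if problems:
            errors.extend((i, p) for p in problems)
        else:
            records.append(rec)
    if errors:
        raise SumstatsValidationError(errors)

    meta_fields = {f.name for f in fields(StudyMeta)}
    meta = StudyMeta(**{k: v for k, v in meta_kv.items() if k in meta_fields})
    return Study(records, meta)


def _format_value(value) -> str:
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_sumstats(
    records: Iterable[SummaryRecord],
    path: str | Path,
    meta: StudyMeta | None = None,
) -> None:
    """Write records as a canonical-column TSV; inverse of :func:`read_sumstats`.

    Floats are written in shortest round-trip representation so that
    read → write → read is the identity at field level and write → read →
    write is byte-stable.
    """
    with _open_text(path, "wt") as fh:
        if meta is not None:
            for f in fields(StudyMeta):
                fh.write(f"{_META_PREFIX}{f.name}={getattr(meta, f.name)}\n")
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for rec in records:
            fh.write(
                "\t".join(
                    _format_value(getattr(rec, f)) for f in CANONICAL_COLUMNS
                )
                + "\n"
            )


def records_to_frame(records: Iterable[SummaryRecord]) -> pd.DataFrame:
    """Record list → DataFrame with canonical columns (the pipeline currency)."""
    records = list(records)
    if not records:
        return pd.DataFrame(columns=list(CANONICAL_COLUMNS))
    return pd.DataFrame([vars(r) for r in records], columns=list(CANONICAL_COLUMNS))


def frame_to_records(frame: pd.DataFrame, validate: bool = True) -> list[SummaryRecord]:
    """DataFrame with canonical columns → validated record list."""
    records = [
        SummaryRecord(
            snp_id=str(row.snp_id),
            chrom=str(row.chrom),
            pos=int(row.pos),
            effect_allele=str(row.effect_allele),
            other_allele=str(row.other_allele),
            eaf=float(row.eaf),
            beta=float(row.beta),
            se=float(row.se),
            pvalue=float(row.pvalue),
            n=int(row.n),
        )
        for row in frame.itertuples(index=False)
    ]
    if validate:
        errors = [
            (i, p) for i, rec in enumerate(records, start=1) for p in rec.validate()
        ]
        if errors:
            raise SumstatsValidationError(errors)
    return records
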