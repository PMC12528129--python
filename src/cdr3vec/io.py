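"""Reading, curating and writing TCRβ clonotype tables and CDR3 FASTA.

Clonotype tables are plain CSV files as exported from IgBlast-style
annotation (one row per rearrangement, with the CDR3 amino-acid sequence,
V-gene call, productive flag and sample metadata). Column names differ
between annotation dialects, so the reader takes a configurable column
mapping with AIRR-flavoured defaults.

Curation enforces the conventional definition of a usable CDR3: a
productive rearrangement whose junction is written over the 20 standard
amino acids, starts at the conserved cysteine and ends at the conserved
phenylalanine or glycine, and is long enough to be tokenized downstream.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: drop reasons, in the order they are checked (first failing rule wins)
DROP_REASONS = ("non-productive", "bad alphabet", "bad boundary", "too short")

_TRUE_STRINGS = {"true", "t", "1", "yes", "y", "productive"}
_FALSE_STRINGS = {"false", "f", "0", "no", "n", "non-productive", "unproductive",
                  "out_of_frame", "stop_codon"}


class FormatError(ValueError):
    """A required column is missing or a field cannot be interpreted."""


class EmptyInputError(ValueError):
    """The input file contains no records."""


class FastaParseError(ValueError):
    """Malformed FASTA input; message carries the offending line number."""


@dataclass
class ClonotypeRecord:
    """One CDR3 entry with its sample/group metadata.

    ``v_gene`` is carried as metadata only; it plays no role in the
    embedding or clustering pipeline.
    """

    sequence_id: str
    cdr3_aa: str
    v_gene: str = ""
    productive: bool = True
    sample_id: str = ""
    group: str = ""


#: logical field -> default CSV column name
DEFAULT_COLUMNS = {
    "sequence_id": "sequence_id",
    "cdr3_aa": "cdr3_aa",
    "v_gene": "v_gene",
    "productive": "productive",
    "sample_id": "sample_id",
    "group": "group",
}


@dataclass
class CurationReport:
    """Bookkeeping for :func:`curate`: disjoint drop counts per reason."""

    n_input: int = 0
    n_kept: int = 0
    dropped: dict[str, int] = field(default_factory=lambda: {r: 0 for r in DROP_REASONS})

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())

    def as_dict(self) -> dict:
        return {"n_input": self.n_input, "n_kept": self.n_kept,
                "dropped": dict(self.dropped)}


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)):
        return bool(value)
    text = str(value).strip().lower()
    if text in _TRUE_STRINGS:
        return True
    if text in _FALSE_STRINGS:
        return False
    raise FormatError(f"cannot interpret productive flag {value!r}")


def read_clonotype_table(path, columns: dict[str, str] | None = None) -> list[ClonotypeRecord]:
    """Read a clonotype CSV into records, one per row, in file order.

    No filtering is applied; use :func:`curate` afterwards. Only the CDR3
    column is strictly required — missing metadata columns fall back to
    defaults (``productive=True``, empty strings, synthesized sequence ids).
    Unknown extra columns are ignored.

    Raises
    ------
    FormatError
        If the CDR3 column (per the mapping) is absent.
    EmptyInputError
        If the file holds no data rows.
    """
    mapping = {**DEFAULT_COLUMNS, **(columns or {})}
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"no records in {path}") from None
    if df.empty:
        raise EmptyInputError(f"no records in {path}")
    if mapping["cdr3_aa"] not in df.columns:
        raise FormatError(f"required column {mapping['cdr3_aa']!r} (cdr3_aa) "
                          f"not found in {path}")

    def col(name, default):
        c = mapping[name]
        return df[c] if c in df.columns else pd.Series([default] * len(df))

    records = []
    ids = col("sequence_id", "")
    for i in range(len(df)):
        seq_id = str(ids.iloc[i]) or f"seq{i + 1}"
        records.append(ClonotypeRecord(
            sequence_id=seq_id,
            cdr3_aa=str(df[mapping["cdr3_aa"]].iloc[i]).strip().upper(),
            v_gene=str(col("v_gene", "").iloc[i]),
            productive=_parse_bool(col("productive", True).iloc[i]),
            sample_id=str(col("sample_id", "").iloc[i]),
            group=str(col("group", "").iloc[i]),
        ))
    return records


def write_clonotype_table(records: list[ClonotypeRecord], path,
                          columns: dict[str, str] | None = None) -> None:
    """Write records as a clonotype CSV (inverse of :func:`read_clonotype_table`)."""
    mapping = {**DEFAULT_COLUMNS, **(columns or {})}
    fieldnames = [mapping[k] for k in DEFAULT_COLUMNS]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(fieldnames)
        for r in records:
            writer.writerow([r.sequence_id, r.cdr3_aa, r.v_gene,
                             r.productive, r.sample_id, r.group])


def curate(records: list[ClonotypeRecord], min_length: int = 3,
           boundary_rule: bool = True) -> tuple[list[ClonotypeRecord], CurationReport]:
    """Filter records down to analyzable CDR3s.

    A record is kept when it is productive, its CDR3 uses only the 20
    standard amino-acid letters (no ``*``, ``X`` or gap characters), it
    starts with C and ends with F or G (the conserved junction boundaries;
    disable with ``boundary_rule=False`` for pre-trimmed input), and it is
    at least ``min_length`` residues long so that k-mer tokenization emits
    at least one token.

    Each dropped record is counted under exactly one reason — the first
    failing rule in the order non-productive, bad alphabet, bad boundary,
    too short. Curation is idempotent: re-curating the kept records drops
    nothing.
    """
    kept: list[ClonotypeRecord] = []
    report = CurationReport(n_input=len(records))
    for rec in records:
        seq = rec.cdr3_aa.strip().upper()
        if not rec.productive:
            report.dropped["non-productive"] += 1
        elif not seq or not set(seq) <= AMINO_ACIDS:
            report.dropped["bad alphabet"] += 1
        elif boundary_rule and not (seq.startswith("C") and seq[-1] in "FG"):
            report.dropped["bad boundary"] += 1
        elif len(seq) < min_length:
            report.dropped["too short"] += 1
        else:
            kept.append(replace(rec, cdr3_aa=seq))
    report.n_kept = len(kept)
    return kept, report


def read_fasta(path) -> list[ClonotypeRecord]:
    """Read CDR3 sequences from FASTA; sequences are uppercased.

    Blank lines between records are tolerated. The first non-blank line
    must be a ``>`` header; anything else raises :class:`FastaParseError`
    with the line number.
    """
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        if line.strip():
            if not line.startswith(">"):
                raise FastaParseError(
                    f"line {lineno}: expected FASTA header starting with '>', "
                    f"got {line.strip()[:30]!r}")
            break
    else:
        raise EmptyInputError(f"no records in {path}")
    # Biopython's strict fasta parser rejects blank lines before the first
    # header; we tolerate them (and interior blanks) by filtering
    content = io.StringIO("".join(ln for ln in lines if ln.strip()))
    records = []
    for rec in SeqIO.parse(content, "fasta"):
        records.append(ClonotypeRecord(sequence_id=rec.id,
                                       cdr3_aa=str(rec.seq).upper()))
    if not records:
        raise EmptyInputError(f"no records in {path}")
    return records


def write_fasta(records: list[ClonotypeRecord], path) -> None:
    """Write CDR3 sequences to FASTA, ids preserved (round-trips with read_fasta)."""
    seq_records = [SeqRecord(Seq(r.cdr3_aa), id=r.sequence_id, description="")
                   for r in records]
    SeqIO.write(seq_records, path, "fasta")
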