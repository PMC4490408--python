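"""Readers and writers for every table the pipeline touches.

All tabular inputs are UTF-8 tab-separated files with a fixed set of column
names (column order is free). Protein databases are plain FASTA. Masses are
neutral monoisotopic Da throughout; any charge / m-z conversion is the
responsibility of the upstream search-engine export.

Peptide identification confidence is consumed as a column (a posterior
probability in [0, 1] from the upstream search pipeline); filtering against
the confidence threshold lives in :func:`read_psm_table`, default 0.98.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("glycosurf")

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

CONDITIONS = frozenset({"DOXH", "DOXL-", "DOXH-", "MEF", "ESC", "iPSC"})

DEFAULT_CONFIDENCE_THRESHOLD = 0.98

PSM_COLUMNS = (
    "peptide_sequence",
    "modifications",
    "observed_mass",
    "confidence",
    "protein_accessions",
    "sample_id",
    "replicate_id",
)

DESIGN_COLUMNS = ("sample_id", "day", "condition", "replicate")


class FormatError(ValueError):
    """A file-level problem: missing column, bad header, duplicate key."""


class RowError(FormatError):
    """A row-level problem, carrying the 1-based line number of the row."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


class Modification(NamedTuple):
    """One residue modification: 1-based position, mass delta (Da), label."""

    position: int
    delta_mass: float
    label: str


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match.

    ``observed_mass`` is the neutral monoisotopic peptide mass in Da;
    ``confidence`` is the upstream identification probability.
    """

    peptide_sequence: str
    modifications: tuple[Modification, ...]
    observed_mass: float
    confidence: float
    protein_accessions: tuple[str, ...]
    sample_id: str
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if not self.peptide_sequence:
            raise ValueError("empty peptide sequence")
        bad = set(self.peptide_sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"non-standard residues {sorted(bad)} in {self.peptide_sequence!r}"
            )
        n = len(self.peptide_sequence)
        for mod in self.modifications:
            if not 1 <= mod.position <= n:
                raise ValueError(
                    f"modification position {mod.position} outside peptide of length {n}"
                )
        if self.observed_mass <= 0:
            raise ValueError("observed_mass must be positive")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


class DesignEntry(NamedTuple):
    sample_id: str
    day: int
    condition: str
    replicate: int


@dataclass
class TimecourseDesign:
    """Sample sheet: one row per mass-spectrometry replicate run."""

    samples: list[DesignEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for s in self.samples:
            if s.sample_id in seen:
                raise FormatError(f"duplicate sample_id {s.sample_id!r}")
            seen.add(s.sample_id)
            if s.day < 0:
                raise FormatError(f"negative day for sample {s.sample_id!r}")
            if s.condition not in CONDITIONS:
                raise FormatError(
                    f"unknown condition {s.condition!r} for sample {s.sample_id!r}; "
                    f"allowed: {sorted(CONDITIONS)}"
                )
            if s.replicate < 1:
                raise FormatError(f"replicate must be >= 1 for {s.sample_id!r}")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def points(self) -> list[tuple[int, str]]:
        """Distinct (day, condition) points, ordered by day then condition."""
        return sorted({(s.day, s.condition) for s in self.samples})

    def replicates_at(self, day: int, condition: str) -> list[DesignEntry]:
        return [s for s in self.samples if s.day == day and s.condition == condition]


# ---------------------------------------------------------------------------
# modification string codec: "pos:delta:label;pos:delta:label"
# ---------------------------------------------------------------------------

def format_modifications(mods: tuple[Modification, ...] | list[Modification]) -> str:
    return ";".join(f"{m.position}:{m.delta_mass:.5f}:{m.label}" for m in mods)


def parse_modifications(text: str) -> tuple[Modification, ...]:
    text = (text or "").strip()
    if not text or text == "-":
        return ()
    out = []
    for chunk in text.split(";"):
        pos_s, delta_s, label = chunk.split(":", 2)
        out.append(Modification(int(pos_s), float(delta_s), label))
    return tuple(out)


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: tuple[str, ...], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_psm_table(
    path,
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
    *,
    return_rejected: bool = False,
):
    """Read a PSM table, keeping records with confidence >= threshold.

    Malformed rows raise :class:`RowError` with the file line number.
    With ``return_rejected=True`` also returns the below-threshold records,
    so that retained + rejected always accounts for every input row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, PSM_COLUMNS, path)
    retained: list[PSMRecord] = []
    rejected: list[PSMRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after the header
        try:
            mass = float(row.observed_mass)
        except ValueError:
            raise RowError(line, f"unparseable observed_mass {row.observed_mass!r}")
        try:
            conf = float(row.confidence)
        except ValueError:
            raise RowError(line, f"unparseable confidence {row.confidence!r}")
        try:
            rec = PSMRecord(
                peptide_sequence=row.peptide_sequence.strip().upper(),
                modifications=parse_modifications(row.modifications),
                observed_mass=mass,
                confidence=conf,
                protein_accessions=tuple(
                    a for a in row.protein_accessions.split(";") if a
                ),
                sample_id=row.sample_id,
                replicate_id=row.replicate_id,
            )
        except ValueError as exc:
            raise RowError(line, str(exc)) from exc
        if rec.confidence >= confidence_threshold:
            retained.append(rec)
        else:
            rejected.append(rec)
    logger.info(
        "read %d PSMs from %s: %d >= confidence %.3g, %d below",
        len(retained) + len(rejected), path, len(retained),
        confidence_threshold, len(rejected),
    )
    if return_rejected:
        return retained, rejected
    return retained


def write_psm_table(records, path) -> None:
    rows = [
        {
            "peptide_sequence": r.peptide_sequence,
            "modifications": format_modifications(r.modifications),
            "observed_mass": f"{r.observed_mass:.5f}",
            "confidence": f"{r.confidence:.6g}",
            "protein_accessions": ";".join(r.protein_accessions),
            "sample_id": r.sample_id,
            "replicate_id": r.replicate_id,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(PSM_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# design tables
# ---------------------------------------------------------------------------

def read_design(path) -> TimecourseDesign:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, DESIGN_COLUMNS, path)
    entries = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            day = int(row.day)
            rep = int(row.replicate)
        except ValueError as exc:
            raise RowError(line, str(exc)) from exc
        entries.append(DesignEntry(row.sample_id, day, row.condition, rep))
    return TimecourseDesign(entries)


def write_design(design: TimecourseDesign, path) -> None:
    pd.DataFrame(design.samples, columns=list(DESIGN_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Protein FASTA -> {accession: uppercase sequence}; duplicates rejected."""
    db: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in db:
            raise FormatError(f"duplicate accession {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for accession {rec.id!r}")
        db[rec.id] = seq
    return db


def write_fasta(db: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for acc, seq in db.items():
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# isoform index, annotations, Ct tables
# ---------------------------------------------------------------------------

def read_isoform_index(path) -> dict[str, tuple[str, str]]:
    """TSV (accession, gene, primary_id) -> {accession: (gene, primary_id)}."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ("accession", "gene", "primary_id"), path)
    index: dict[str, tuple[str, str]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        if row.accession in index:
            raise RowError(i + 2, f"duplicate accession {row.accession!r}")
        index[row.accession] = (row.gene, row.primary_id)
    return index


def write_isoform_index(index: dict[str, tuple[str, str]], path) -> None:
    rows = [
        {"accession": acc, "gene": g, "primary_id": p}
        for acc, (g, p) in index.items()
    ]
    pd.DataFrame(rows, columns=["accession", "gene", "primary_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_annotation(path) -> dict[str, str]:
    """Functional-category table: one category per primary_id."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ("primary_id", "category"), path)
    out: dict[str, str] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        if row.primary_id in out:
            raise RowError(i + 2, f"duplicate primary_id {row.primary_id!r}")
        out[row.primary_id] = row.category
    return out


def read_ct_table(path) -> pd.DataFrame:
    """qPCR cycle-threshold table with columns gene, sample_id, ct_target,
    ct_reference; Ct values must be positive."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ("gene", "sample_id", "ct_target", "ct_reference"), path)
    for col in ("ct_target", "ct_reference"):
        df[col] = pd.to_numeric(df[col], errors="raise")
        if (df[col] <= 0).any():
            raise FormatError(f"{path}: non-positive Ct in column {col}")
    return df
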