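"""Readers and writers for every file the pipeline touches.

All tabular files are TSV with a header row, UTF-8, and ``.`` for missing
values. Readers validate strictly and raise instead of coercing: a malformed
input should stop a run, not silently skew it.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd


class PanfamError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(PanfamError):
    """Malformed input file (message carries file and line context)."""


class SchemaError(PanfamError):
    """Tabular file does not match its declared schema."""


class ConfigError(PanfamError):
    """Invalid configuration."""


# IUPAC nucleotide alphabet accepted in FASTA input; codon statistics and
# alignment scoring treat anything other than A/C/G/T as an N-like mismatch.
IUPAC_NT = frozenset("ACGTUNRYSWKMBDHV")
CDS_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class GeneRecord:
    """One coding sequence with its accession and population of origin."""

    gene_id: str
    accession_id: str
    population: str  # population label, or "unknown"
    cds: str  # uppercase DNA over {A,C,G,T,N}

    def __post_init__(self) -> None:
        if len(self.cds) < 3:
            raise ParseError(f"gene {self.gene_id!r}: CDS shorter than one codon")
        bad = set(self.cds) - CDS_ALPHABET
        if bad:
            raise ParseError(
                f"gene {self.gene_id!r}: CDS contains non-ACGTN characters {sorted(bad)}"
            )


@dataclass
class DatasetManifest:
    """All genes of a dataset, indexed, with a stable accession ordering.

    The accession ordering is recorded because the orthologous-group builder
    iterates accessions in this order when electing new references; runs are
    reproducible only if the order is explicit.
    """

    accessions: list[str]
    population_map: dict[str, str]
    gene_index: dict[str, GeneRecord] = field(default_factory=dict)

    def genes_of(self, accession_id: str) -> list[GeneRecord]:
        return [g for g in self.gene_index.values() if g.accession_id == accession_id]

    def __len__(self) -> int:
        return len(self.gene_index)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse a (plain or gzipped) FASTA file into (id, sequence) pairs.

    Record ids are the first whitespace-delimited header token; sequences are
    uppercased. Duplicate ids, empty sequences and non-IUPAC characters are
    rejected with the offending line number.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    current_id: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if current_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"{path}:{header_line}: record {current_id!r} has an empty sequence")
        records.append((current_id, seq))

    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                token = line[1:].split()
                if not token:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                current_id = token[0]
                if current_id in seen:
                    raise ParseError(f"{path}:{lineno}: duplicate sequence id {current_id!r}")
                seen.add(current_id)
                chunks = []
                header_line = lineno
            else:
                if current_id is None:
                    raise ParseError(f"{path}:{lineno}: sequence data before first header")
                seq = line.upper()
                bad = set(seq) - IUPAC_NT
                if bad:
                    raise ParseError(
                        f"{path}:{lineno}: non-IUPAC characters {sorted(bad)} in record {current_id!r}"
                    )
                chunks.append(seq)
        flush()
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as handle:
        for rid, seq in records:
            handle.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Uniform tabular contract


_CASTS = {
    "str": str,
    "int": int,
    "float": float,
}


def write_table(
    rows: Sequence[Mapping[str, object]],
    schema: Mapping[str, str],
    path: str | Path,
) -> None:
    """Write rows as TSV under a declared schema; None becomes ``.``."""
    for kind in schema.values():
        if kind not in _CASTS:
            raise SchemaError(f"unknown column kind {kind!r}")
    cols = list(schema)
    out_rows = []
    for i, row in enumerate(rows):
        extra = set(row) - set(cols)
        missing = set(cols) - set(row)
        if extra or missing:
            raise SchemaError(
                f"row {i}: columns do not match schema (extra={sorted(extra)}, missing={sorted(missing)})"
            )
        out_rows.append(["." if row[c] is None else str(row[c]) for c in cols])
    frame = pd.DataFrame(out_rows, columns=cols)
    frame.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path, schema: Mapping[str, str]) -> list[dict[str, object]]:
    """Read a TSV written by :func:`write_table`; ``.`` reads back as None."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = list(schema)
    if list(frame.columns) != cols:
        raise SchemaError(
            f"{path}: columns {list(frame.columns)} do not match schema columns {cols}"
        )
    rows: list[dict[str, object]] = []
    for _, rec in frame.iterrows():
        row: dict[str, object] = {}
        for col in cols:
            raw = rec[col]
            if raw == ".":
                row[col] = None
            else:
                try:
                    row[col] = _CASTS[schema[col]](raw)
                except ValueError as exc:
                    raise SchemaError(f"{path}: column {col!r}: cannot cast {raw!r}") from exc
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# Dataset manifest


POPULATIONS_SCHEMA = {"accession_id": "str", "population": "str"}
DOMAINS_SCHEMA = {"gene_id": "str", "ap2_count": "int", "b3_count": "int"}
DEG_SCHEMA = {"gene_id": "str", "leaf_status": "str", "root_status": "str"}


def load_manifest(
    directory: str | Path,
    accession_order: Sequence[str] | None = None,
) -> DatasetManifest:
    """Load per-accession ``<accession>.cds.fa`` files plus ``populations.tsv``.

    Accession order defaults to sorted accession ids; an explicit
    ``accession_order`` (e.g. from a run config) overrides it and must list
    every accession exactly once.
    """
    directory = Path(directory)
    pop_rows = read_table(directory / "populations.tsv", POPULATIONS_SCHEMA)
    population_map = {r["accession_id"]: r["population"] for r in pop_rows}

    fasta_paths = sorted(directory.glob("*.cds.fa")) + sorted(directory.glob("*.cds.fa.gz"))
    found = {}
    for path in fasta_paths:
        name = path.name
        accession = name[: -len(".cds.fa.gz")] if name.endswith(".gz") else name[: -len(".cds.fa")]
        found[accession] = path
    missing_from_table = sorted(set(found) - set(population_map))
    if missing_from_table:
        raise ParseError(
            f"accessions with FASTA but absent from populations.tsv: {missing_from_table}"
        )

    accessions = sorted(found)
    if accession_order is not None:
        if sorted(accession_order) != accessions:
            raise ConfigError(
                "accession_order override must list every accession exactly once"
            )
        accessions = list(accession_order)

    manifest = DatasetManifest(accessions=accessions, population_map=dict(population_map))
    for accession in accessions:
        for gene_id, seq in read_fasta(found[accession]):
            if gene_id in manifest.gene_index:
                raise ParseError(f"gene id {gene_id!r} occurs in more than one accession")
            manifest.gene_index[gene_id] = GeneRecord(
                gene_id=gene_id,
                accession_id=accession,
                population=population_map.get(accession, "unknown"),
                cds=seq,
            )
    return manifest
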