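"""Readers and writers for the plain-text formats used across the pipeline.

All genomic coordinates are normalized on read to the internal 0-based
half-open convention; user-facing reports are written 1-based inclusive.
FASTA parsing is deliberately strict (duplicate IDs and illegal characters
are reported with line numbers) because downstream stages assume a clean
{A,C,G,T,N} alphabet.
"""

from __future__ import annotations

import textwrap
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised for malformed on-disk records; message names the offending line."""


@dataclass
class GenomeRecord:
    """One chromosome (or any FASTA sequence) of one species."""

    chrom_id: str
    sequence: str
    species_id: str = ""

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


@dataclass
class FeatureRecord:
    """A genomic feature in 0-based half-open coordinates."""

    chrom_id: str
    start: int
    end: int
    strand: str
    feature_kind: str  # gene, exon, intron
    feature_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"feature {self.feature_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise FormatError(f"feature {self.feature_id}: bad strand {self.strand!r}")


def read_fasta(path: str | Path, species_id: str = "") -> list[GenomeRecord]:
    """Read a FASTA file into GenomeRecords.

    IDs are taken up to the first whitespace; sequences are uppercased.
    Raises :class:`FormatError` on empty files, duplicate IDs or characters
    outside {A,C,G,T,N}, naming the line.
    """
    path = Path(path)
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    name: str | None = None
    chunks: list[str] = []

    def flush(lineno: int) -> None:
        if name is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{path}:{lineno}: record {name!r} has empty sequence")
        records.append(GenomeRecord(chrom_id=name, sequence=seq, species_id=species_id))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError(f"{path}:{lineno}: empty record ID")
                if name in seen:
                    raise FormatError(f"{path}:{lineno}: duplicate record ID {name!r}")
                seen.add(name)
                chunks = []
            else:
                if name is None:
                    raise FormatError(f"{path}:{lineno}: sequence before first header")
                seq = line.upper()
                bad = set(seq) - DNA_ALPHABET
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: illegal characters {sorted(bad)} in record {name!r}"
                    )
                chunks.append(seq)
    flush(lineno if records or name else 0)
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | Path, records: Iterable[GenomeRecord], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.chrom_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_features(path: str | Path, dialect: str) -> list[FeatureRecord]:
    """Read gene/exon features from GFF3 (1-based closed) or BED (0-based half-open).

    All coordinates are normalized to 0-based half-open. Records whose interval
    is empty after normalization are rejected with a :class:`FormatError`.
    A line that does not match the declared dialect's column count raises an
    error naming the line.
    """
    if dialect not in ("gff3", "bed"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    feats: list[FeatureRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if dialect == "gff3":
                if len(cols) < 9:
                    raise FormatError(
                        f"{path}:{lineno}: expected ≥9 GFF3 columns, got {len(cols)}"
                    )
                chrom, _src, kind, start_s, end_s, _score, strand, _frame, attrs = cols[:9]
                start = int(start_s) - 1  # GFF3 is 1-based inclusive
                end = int(end_s)
                fid = _gff3_attr(attrs, "ID") or f"{kind}:{chrom}:{start}"
            else:
                if len(cols) < 3:
                    raise FormatError(f"{path}:{lineno}: expected ≥3 BED columns")
                if len(cols) >= 9 and not cols[1].isdigit():
                    raise FormatError(
                        f"{path}:{lineno}: line looks like GFF3, not BED (mixed dialect?)"
                    )
                chrom = cols[0]
                start = int(cols[1])
                end = int(cols[2])
                fid = cols[3] if len(cols) > 3 else f"feat:{chrom}:{start}"
                strand = cols[5] if len(cols) > 5 else "+"
                kind = cols[6] if len(cols) > 6 else "gene"
            if end <= start:
                raise FormatError(
                    f"{path}:{lineno}: empty interval after normalization ({start}, {end})"
                )
            feats.append(
                FeatureRecord(
                    chrom_id=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    feature_kind=kind.lower(),
                    feature_id=fid,
                )
            )
    return feats


def _gff3_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


def write_gff3(path: str | Path, feats: Iterable[FeatureRecord], source: str = "oryzamir") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in feats:
            fh.write(
                "\t".join(
                    [
                        f.chrom_id,
                        source,
                        f.feature_kind,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        f"ID={f.feature_id}",
                    ]
                )
                + "\n"
            )


def derive_introns(features: list[FeatureRecord]) -> list[FeatureRecord]:
    """Derive intron features from gene/exon records where absent.

    For each gene, the gaps between its exons (sorted by coordinate) become
    intron features.
    """
    genes = [f for f in features if f.feature_kind == "gene"]
    exons = [f for f in features if f.feature_kind == "exon"]
    introns: list[FeatureRecord] = []
    for gene in genes:
        own = sorted(
            (e for e in exons if e.chrom_id == gene.chrom_id and e.start >= gene.start and e.end <= gene.end),
            key=lambda e: e.start,
        )
        for a, b in zip(own, own[1:]):
            if b.start > a.end:
                introns.append(
                    FeatureRecord(
                        chrom_id=gene.chrom_id,
                        start=a.end,
                        end=b.start,
                        strand=gene.strand,
                        feature_kind="intron",
                        feature_id=f"{gene.feature_id}.intron{len(introns)}",
                    )
                )
    return introns


def extract_sequence(genome: dict[str, str], chrom: str, start: int, end: int, strand: str) -> str:
    """Extract [start, end) from a chromosome; minus-strand returns the reverse complement."""
    seq = genome[chrom][start:end]
    return revcomp(seq) if strand == "-" else seq
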