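"""Readers and writers for every external format the pipeline touches.

Reads come in as FASTA, paired FASTA/QUAL or FASTQ (PHRED+33); the
experimental fingerprint is a two-column CSV of (fragment size in bp,
relative abundance); the taxonomy-annotated reference database is a FASTA
whose headers carry ``otu_id|accession|taxonomy`` with rank prefixes
``P:/C:/O:/F:/G:/S:``.  All report outputs are plain UTF-8 CSV.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.SeqIO.QualityIO import PairedFastaQualIterator

from ._seq import validate_nucleotides

logger = logging.getLogger(__name__)

#: Electropherogram window of the experimental method, in bp.
DEFAULT_SIZE_RANGE: tuple[int, int] = (50, 500)

ProfileKind = Literal["experimental", "digital"]


@dataclass
class Read:
    """One amplicon read, optionally with per-base PHRED qualities."""

    id: str
    sequence: str
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"read {self.id!r} has an empty sequence")
        validate_nucleotides(self.sequence, context=f"read {self.id!r}")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mean_quality(self) -> float | None:
        if self.qualities is None:
            return None
        return sum(self.qualities) / len(self.qualities)


@dataclass
class ReferenceRecord:
    """A reference 16S sequence with its ranked taxonomy."""

    otu_id: str
    accession: str
    taxonomy: tuple[str, ...]
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.taxonomy:
            raise ValueError(f"reference {self.accession!r}: taxonomy is empty")

    @property
    def taxonomy_string(self) -> str:
        return ";".join(self.taxonomy)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class TRFLPProfile:
    """A T-RFLP fingerprint: (fragment size bp, relative abundance %) peaks.

    ``kind`` distinguishes the capillary-electrophoresis fingerprint
    (``experimental``) from the one computed in silico from reads
    (``digital``).  Sizes are integer bp and strictly increasing; abundances
    are non-negative and sum to 100.
    """

    sample_id: str
    kind: ProfileKind
    peaks: list[tuple[int, float]]
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE

    def __post_init__(self) -> None:
        lo, hi = self.size_range
        sizes = [s for s, _ in self.peaks]
        if sizes != sorted(set(sizes)):
            raise ValueError("peak sizes must be strictly increasing and unique")
        for s, a in self.peaks:
            if not lo <= s <= hi:
                raise ValueError(f"peak size {s} outside range {self.size_range}")
            if a < 0:
                raise ValueError(f"negative abundance {a} at size {s}")
        if self.peaks:
            total = sum(a for _, a in self.peaks)
            if abs(total - 100.0) > 1e-6:
                raise ValueError(f"abundances sum to {total}, expected 100")

    @classmethod
    def from_abundances(
        cls,
        sample_id: str,
        kind: ProfileKind,
        abundances: dict[int, float],
        size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
    ) -> "TRFLPProfile":
        """Build a profile from raw (possibly unnormalized) peak heights.

        Peaks outside ``size_range`` are dropped; the remainder is
        renormalized to sum to 100.
        """
        lo, hi = size_range
        kept = {s: a for s, a in abundances.items() if lo <= s <= hi and a > 0}
        total = sum(kept.values())
        if total <= 0:
            raise ValueError("empty profile: no peaks within size range")
        peaks = [(s, 100.0 * a / total) for s, a in sorted(kept.items())]
        return cls(sample_id, kind, peaks, size_range)

    @property
    def sizes(self) -> list[int]:
        return [s for s, _ in self.peaks]

    @property
    def abundances(self) -> dict[int, float]:
        return dict(self.peaks)


# ---------------------------------------------------------------------------
# sequence reading


def _from_seqrecord(rec, index: int, with_quals: bool) -> Read:
    seq = str(rec.seq)
    if not seq:
        raise ValueError(f"record {index} ({rec.id!r}) has an empty sequence")
    quals = None
    if with_quals:
        quals = list(rec.letter_annotations.get("phred_quality", []))
        if not quals:
            quals = None
    try:
        return Read(rec.id, seq, quals)
    except ValueError as exc:
        raise ValueError(f"record {index}: {exc}") from exc


def read_sequences(
    path: str | Path,
    format: Literal["fasta", "fastq", "fasta+qual"] = "fasta",
    qual_path: str | Path | None = None,
) -> list[Read]:
    """Parse amplicon reads, preserving input order.

    ``fasta+qual`` pairs *path* (FASTA) with *qual_path* (defaults to the
    FASTA path with a ``.qual`` suffix); records are matched by id and a
    mismatch is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "fasta":
        records = SeqIO.parse(path, "fasta")
        return [_from_seqrecord(r, i, False) for i, r in enumerate(records, 1)]
    if format == "fastq":
        records = SeqIO.parse(path, "fastq")
        return [_from_seqrecord(r, i, True) for i, r in enumerate(records, 1)]
    if format == "fasta+qual":
        qpath = Path(qual_path) if qual_path is not None else path.with_suffix(".qual")
        if not qpath.exists():
            raise FileNotFoundError(qpath)
        with open(path) as fh, open(qpath) as qh:
            try:
                records = list(PairedFastaQualIterator(fh, qh))
            except ValueError as exc:  # Biopython raises on id mismatch
                raise ValueError(f"fasta/qual mismatch: {exc}") from exc
        return [_from_seqrecord(r, i, True) for i, r in enumerate(records, 1)]
    raise ValueError(f"unknown format {format!r}")


def write_fasta(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for r in reads:
            fh.write(f">{r.id}\n{r.sequence}\n")


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for r in reads:
            quals = r.qualities if r.qualities is not None else [40] * len(r)
            qstr = "".join(chr(min(q, 93) + 33) for q in quals)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qstr}\n")


# ---------------------------------------------------------------------------
# fingerprint CSV


def read_profile(
    path: str | Path,
    sample_id: str | None = None,
    kind: ProfileKind = "experimental",
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
) -> TRFLPProfile:
    """Read a two-column (size bp, abundance) CSV fingerprint.

    Abundances may be percentages or raw peak areas; they are renormalized
    to sum to 100 after restriction to ``size_range``.  Sizes are rounded
    half-up to integer bp; duplicate sizes after rounding are summed with a
    warning.  An optional header row is auto-detected by a non-numeric
    first cell.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw: dict[int, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            cells = [c.strip() for c in line.split(",")]
            if len(cells) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 comma-separated columns")
            try:
                size_f = float(cells[0])
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ValueError(f"{path}:{lineno}: non-numeric size {cells[0]!r}")
            abundance = float(cells[1])
            if abundance < 0:
                raise ValueError(f"{path}:{lineno}: negative abundance {abundance}")
            size = _round_half_up(size_f)
            if size in raw:
                logger.warning(
                    "%s: duplicate size %d bp after rounding; abundances summed",
                    path,
                    size,
                )
            raw[size] = raw.get(size, 0.0) + abundance
    if not raw:
        raise ValueError(f"{path}: no peaks parsed")
    return TRFLPProfile.from_abundances(
        sample_id or path.stem, kind, raw, size_range
    )


def read_etrflp(
    path: str | Path,
    sample_id: str | None = None,
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
) -> TRFLPProfile:
    """Read an experimental T-RFLP electropherogram CSV (50–500 bp window)."""
    return read_profile(path, sample_id, "experimental", size_range)


def write_profile(profile: TRFLPProfile, path: str | Path) -> None:
    """Write a fingerprint as CSV (integer sizes, 6-decimal abundances)."""
    with open(path, "w", newline="\n") as fh:
        fh.write("size_bp,relative_abundance\n")
        for size, abundance in profile.peaks:
            fh.write(f"{size},{abundance:.6f}\n")


# ---------------------------------------------------------------------------
# reference database


def parse_reference_header(header: str) -> tuple[str, str, tuple[str, ...]]:
    """Split a ``otu_id|accession|taxonomy`` FASTA header.

    Taxonomy ranks are ``;``-separated with ``P:/C:/O:/F:/G:/S:`` prefixes.
    A header without a taxonomy field yields ``("unclassified",)``.
    """
    parts = [p.strip() for p in header.split("|")]
    if len(parts) < 2:
        raise ValueError(f"reference header {header!r}: expected otu_id|accession|taxonomy")
    otu_id, accession = parts[0], parts[1]
    if len(parts) < 3 or not parts[2]:
        logger.warning("reference %s: missing taxonomy, kept as 'unclassified'", accession)
        taxonomy: tuple[str, ...] = ("unclassified",)
    else:
        taxonomy = tuple(t.strip() for t in parts[2].split(";") if t.strip())
    return otu_id, accession, taxonomy


def read_reference_db(path: str | Path) -> list[ReferenceRecord]:
    """Parse a taxonomy-annotated reference FASTA.

    Accessions must be unique within the database; an empty file is an
    error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ReferenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        otu_id, accession, taxonomy = parse_reference_header(rec.description)
        if accession in seen:
            raise ValueError(f"duplicate accession {accession!r} in reference database")
        seen.add(accession)
        records.append(ReferenceRecord(otu_id, accession, taxonomy, str(rec.seq)))
    if not records:
        raise ValueError("empty database")
    return records


def write_reference_db(records: Iterable[ReferenceRecord], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for r in records:
            fh.write(f">{r.otu_id}|{r.accession}|{r.taxonomy_string}\n{r.sequence}\n")
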