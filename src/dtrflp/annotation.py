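"""Peak-annotation tables: ranked phylotype contributions per digital T-RF.

For each digital fragment the contributing clusters are grouped by their
best-hit reference (accession), producing rows of taxonomy, read count,
relative contribution (percent of the fragment's reads), alignment scores
and accession — the table a user consults to decide what a fingerprint
peak *is*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .comparison import PeakMatch
from .digestion import DigitalTRF

UNMAPPED_LABEL = "unmapped"


@dataclass
class AnnotationRow:
    taxonomy: str
    count: int
    relative_contribution: float  # percent, 1 decimal
    sw_score: int | None
    norm_score: float | None
    accession: str | None
    otu_id: str | None


@dataclass
class PeakAnnotation:
    """One digital T-RF with its ranked phylotype contributions.

    ``shifted_size`` and ``etrf_size`` are absent in no-eT-RFLP mode
    (no drift correction, no experimental counterpart).
    """

    dtrf_size: int
    total_count: int
    rows: list[AnnotationRow]
    shifted_size: int | None = None
    etrf_size: int | None = None


def annotate(
    trfs: Sequence[DigitalTRF],
    lag: int | None = None,
    matches: Sequence[PeakMatch] | None = None,
) -> list[PeakAnnotation]:
    """Build the annotation table for every digital T-RF.

    Contributions are grouped by reference accession (distinct accessions
    of one species stay distinct), sorted by descending read count, and
    expressed as percentages of the fragment's total count rounded to one
    decimal.  When a lag is given, shifted sizes are attached; matched
    experimental sizes come from *matches* (keyed on shifted size).
    """
    etrf_by_shifted: dict[int, int] = {}
    if matches:
        etrf_by_shifted = {m.shifted_dtrf_size: m.etrf_size for m in matches}
    annotations: list[PeakAnnotation] = []
    for trf in trfs:
        grouped: dict[str, dict] = {}
        order: list[str] = []
        for hit, count in trf.contributors:
            key = hit.reference.accession if hit is not None else UNMAPPED_LABEL
            if key not in grouped:
                order.append(key)
                grouped[key] = {
                    "taxonomy": hit.taxonomy_string if hit else UNMAPPED_LABEL,
                    "count": 0,
                    "sw_score": hit.sw_score if hit else None,
                    "norm_score": round(hit.norm_score, 3) if hit else None,
                    "accession": hit.reference.accession if hit else None,
                    "otu_id": hit.reference.otu_id if hit else None,
                }
            grouped[key]["count"] += count
        rows = [
            AnnotationRow(
                taxonomy=g["taxonomy"],
                count=g["count"],
                relative_contribution=round(100.0 * g["count"] / trf.count, 1),
                sw_score=g["sw_score"],
                norm_score=g["norm_score"],
                accession=g["accession"],
                otu_id=g["otu_id"],
            )
            for g in (grouped[k] for k in order)
        ]
        rows.sort(key=lambda r: (-r.count, r.taxonomy))
        shifted = trf.size + lag if lag is not None else None
        etrf = etrf_by_shifted.get(shifted) if shifted is not None else None
        annotations.append(
            PeakAnnotation(
                dtrf_size=trf.size,
                total_count=trf.count,
                rows=rows,
                shifted_size=shifted,
                etrf_size=etrf,
            )
        )
    return annotations


def annotations_frame(annotations: Iterable[PeakAnnotation]) -> pd.DataFrame:
    records = []
    for ann in annotations:
        for row in ann.rows:
            records.append(
                {
                    "etrf_bp": ann.etrf_size,
                    "dtrf_bp": ann.dtrf_size,
                    "dtrf_shifted_bp": ann.shifted_size,
                    "counts": row.count,
                    "relative_contribution_pct": row.relative_contribution,
                    "phylogenetic_affiliation": row.taxonomy,
                    "reference_otu": row.otu_id,
                    "reference_accession": row.accession,
                    "sw_score": row.sw_score,
                    "norm_sw_score": row.norm_score,
                }
            )
    return pd.DataFrame.from_records(records)


def write_annotations(
    annotations: Iterable[PeakAnnotation], path: str | Path
) -> None:
    """Peak-annotation CSV, one row per (T-RF, phylotype) contribution."""
    annotations_frame(annotations).to_csv(path, index=False)


def taxon_trf_table(
    annotations: Sequence[PeakAnnotation], taxon: str
) -> pd.DataFrame:
    """All T-RFs carrying a taxon (case-insensitive substring match).

    One fragment can split into several sizes when reads carry indels
    before the cut site; the table flags the predominant size (max read
    count).  An unknown taxon yields an empty table.
    """
    query = taxon.lower()
    records = []
    for ann in annotations:
        for row in ann.rows:
            if query in row.taxonomy.lower():
                records.append(
                    {
                        "dtrf_bp": ann.dtrf_size,
                        "dtrf_shifted_bp": ann.shifted_size,
                        "counts": row.count,
                        "relative_contribution_pct": row.relative_contribution,
                        "reference_accession": row.accession,
                        "sw_score": row.sw_score,
                        "norm_sw_score": row.norm_score,
                    }
                )
    frame = pd.DataFrame.from_records(
        records,
        columns=[
            "dtrf_bp",
            "dtrf_shifted_bp",
            "counts",
            "relative_contribution_pct",
            "reference_accession",
            "sw_score",
            "norm_sw_score",
        ],
    )
    if len(frame):
        frame = frame.sort_values("dtrf_bp", ignore_index=True)
        frame["predominant"] = frame["counts"] == frame["counts"].max()
    else:
        frame["predominant"] = pd.Series(dtype=bool)
    return frame
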