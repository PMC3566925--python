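"""Smith-Waterman search of cluster centroids against the reference database.

Each denoised centroid is locally aligned (affine gaps) against every
reference record; the best-scoring reference supplies the taxonomy.
Centroids whose best score falls below the threshold (default 150) are
routed to an unmapped list and leave the pipeline.  Scores normalized by
query length allow comparison across read lengths.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio import Align

from ._seq import revcomp, validate_nucleotides
from .preprocess import SequenceCluster
from .seqio import ReferenceRecord

logger = logging.getLogger(__name__)

#: Typical user range for the score threshold is 100-250; 150 is the default.
DEFAULT_MIN_SCORE = 150

Span = tuple[int, int]


@dataclass
class ScoringScheme:
    """Affine-gap local alignment scores.

    A gap of length k costs ``gap_open + (k-1) * gap_extend``.  The unit
    match reward means a perfect full-length hit scores the read length
    (a ~450 bp read maxes out around 450).
    """

    match: int = 1
    mismatch: int = 3
    gap_open: int = 5
    gap_extend: int = 2

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if min(self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise ValueError("penalties must be non-negative")

    def aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = self.match
        aligner.mismatch_score = -self.mismatch
        aligner.open_gap_score = -self.gap_open
        aligner.extend_gap_score = -self.gap_extend
        return aligner


@dataclass
class MappingHit:
    """Best reference match for one query centroid."""

    query_id: str
    reference: ReferenceRecord
    sw_score: int
    norm_score: float
    query_span: Span
    ref_span: Span
    strand: str = "+"

    @property
    def taxonomy_string(self) -> str:
        return self.reference.taxonomy_string


@dataclass
class MappingStats:
    total: int
    mapped: int
    unmapped: int
    median_sw_score: float | None
    median_norm_score: float | None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def sw_align(
    query: str,
    reference: str,
    scheme: ScoringScheme | None = None,
) -> tuple[int, Span, Span]:
    """Optimal local alignment score and spans (half-open, 0-based).

    Returns ``(score, query_span, ref_span)``.  A score of 0 (no positive
    local alignment) yields empty spans.  Traceback is deterministic: the
    first optimal alignment of the aligner's enumeration is reported.
    """
    if not query or not reference:
        raise ValueError("query and reference must be non-empty")
    validate_nucleotides(query, context="query")
    validate_nucleotides(reference, context="reference")
    scheme = scheme or ScoringScheme()
    aligner = scheme.aligner()
    score = int(aligner.score(query, reference))
    if score <= 0:
        return 0, (0, 0), (0, 0)
    alignment = aligner.align(query, reference)[0]
    q_blocks, r_blocks = alignment.aligned
    q_span = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    r_span = (int(r_blocks[0][0]), int(r_blocks[-1][1]))
    return score, q_span, r_span


def map_clusters(
    clusters: Sequence[SequenceCluster],
    db: Sequence[ReferenceRecord],
    scheme: ScoringScheme | None = None,
    min_score: int = DEFAULT_MIN_SCORE,
    search_reverse_complement: bool = True,
) -> tuple[list[MappingHit], list[str], MappingStats]:
    """Best-hit mapping of every cluster centroid against the database.

    Ties between references are resolved toward the earlier database
    record (logged).  The reverse complement of each query is also tried
    and the better orientation wins (forward on a tie).  Clusters whose
    best score is below *min_score* go to the unmapped list.
    """
    if not db:
        raise ValueError("reference database is empty")
    scheme = scheme or ScoringScheme()
    aligner = scheme.aligner()
    hits: list[MappingHit] = []
    unmapped: list[str] = []
    for cluster in clusters:
        query = cluster.centroid.sequence
        orientations = [("+", query)]
        if search_reverse_complement:
            orientations.append(("-", revcomp(query)))
        best: MappingHit | None = None
        tie = False
        for ref in db:
            for strand, seq in orientations:
                score = int(aligner.score(seq, ref.sequence))
                if best is not None and score == best.sw_score and ref is not best.reference:
                    tie = True
                if best is None or score > best.sw_score:
                    best = MappingHit(
                        query_id=cluster.centroid.id,
                        reference=ref,
                        sw_score=score,
                        norm_score=score / len(query),
                        query_span=(0, 0),
                        ref_span=(0, 0),
                        strand=strand,
                    )
        assert best is not None
        if best.sw_score < min_score:
            unmapped.append(cluster.centroid.id)
            continue
        # fill spans only for the winning pair (alignment traceback is the
        # expensive part; scores suffice for the search itself)
        seq = query if best.strand == "+" else revcomp(query)
        _, q_span, r_span = sw_align(seq, best.reference.sequence, scheme)
        best.query_span = q_span
        best.ref_span = r_span
        if tie:
            logger.info(
                "query %s: score tie at %d; earliest database record %s kept",
                cluster.centroid.id,
                best.sw_score,
                best.reference.accession,
            )
        hits.append(best)
    stats = MappingStats(
        total=len(clusters),
        mapped=len(hits),
        unmapped=len(unmapped),
        median_sw_score=statistics.median(h.sw_score for h in hits) if hits else None,
        median_norm_score=(
            round(statistics.median(h.norm_score for h in hits), 3) if hits else None
        ),
    )
    return hits, unmapped, stats


def write_mapping_stats(stats: MappingStats, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("metric,value\n")
        for key, value in stats.as_dict().items():
            fh.write(f"{key},{'' if value is None else value}\n")


def write_unmapped(unmapped: Sequence[str], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for qid in unmapped:
            fh.write(f"{qid}\n")
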