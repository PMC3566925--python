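"""Primer trimming, PHRED/length filtering, and identity-based denoising.

Pyrosequencing error modes (homopolymer length miscalls, single-base
insertions) inflate the apparent number of distinct fragments.  The
denoiser collapses reads into clusters of >= 97% pairwise identity and
keeps one representative (centroid) per cluster, weighted by the cluster
size — singletons are retained as size-1 clusters, so no read is lost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

from Bio import Align

from ._seq import iupac_match, revcomp
from .seqio import Read

logger = logging.getLogger(__name__)


@dataclass
class QualityFilterConfig:
    """Thresholds for read filtering: mean PHRED and length window (bp)."""

    min_phred: int = 20
    min_len: int = 300
    max_len: int = 500

    def __post_init__(self) -> None:
        if not 0 <= self.min_phred <= 60:
            raise ValueError(f"min_phred {self.min_phred} outside [0, 60]")
        if not 0 < self.min_len <= self.max_len:
            raise ValueError(
                f"invalid length window [{self.min_len}, {self.max_len}]"
            )


@dataclass
class SequenceCluster:
    """A denoised cluster: centroid read plus member count (its weight)."""

    centroid: Read
    size: int
    member_ids: list[str]

    def __post_init__(self) -> None:
        if self.size != len(self.member_ids):
            raise ValueError("cluster size must equal number of member ids")
        if self.centroid.id not in self.member_ids:
            raise ValueError("centroid id must be among member ids")


@dataclass
class FilterStats:
    total: int = 0
    kept: int = 0
    too_short: int = 0
    too_long: int = 0
    low_quality: int = 0
    without_qualities: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def phred_error_prob(q: int) -> float:
    """Base-calling error probability for a PHRED score: 10^(−q/10)."""
    if q < 0:
        raise ValueError(f"PHRED score must be non-negative, got {q}")
    return 10.0 ** (-q / 10.0)


# ---------------------------------------------------------------------------
# primer trimming


def _count_mismatches(primer: str, segment: str) -> int:
    if len(segment) < len(primer):
        return len(primer)
    return sum(
        0 if iupac_match(p, b) else 1 for p, b in zip(primer, segment)
    )


def trim_primers(
    read: Read,
    fwd: str,
    rev: str | None = None,
    max_mismatches: int = 1,
) -> Read | None:
    """Remove primer bases; return ``None`` if the forward primer is absent.

    *fwd* and *rev* are given 5'→3'.  The forward primer is matched at the
    read start with IUPAC ambiguity (e.g. M = A/C); the reverse primer is
    searched as its reverse complement near the 3' end and trimmed when
    found.  Rejection (no forward primer within *max_mismatches*) is a
    reported outcome, not an error.
    """
    fwd = fwd.upper()
    if _count_mismatches(fwd, read.sequence[: len(fwd)]) > max_mismatches:
        return None
    start = len(fwd)
    seq = read.sequence[start:]
    quals = read.qualities[start:] if read.qualities is not None else None
    if rev:
        target = revcomp(rev.upper())
        m = len(target)
        # scan the tail window for the best match position
        best_pos, best_mm = None, max_mismatches + 1
        lo = max(0, len(seq) - m - 10)
        for pos in range(lo, len(seq) - m + 1):
            mm = _count_mismatches(target, seq[pos : pos + m])
            if mm < best_mm:
                best_pos, best_mm = pos, mm
        if best_pos is not None:
            seq = seq[:best_pos]
            if quals is not None:
                quals = quals[:best_pos]
    if not seq:
        return None
    return Read(read.id, seq, quals)


# ---------------------------------------------------------------------------
# quality filtering


def quality_filter(
    reads: Sequence[Read], cfg: QualityFilterConfig | None = None
) -> tuple[list[Read], FilterStats]:
    """Keep reads inside the length window with mean PHRED >= threshold.

    Reads without qualities are judged on length only (counted in
    ``stats.without_qualities``).
    """
    cfg = cfg or QualityFilterConfig()
    stats = FilterStats(total=len(reads))
    kept: list[Read] = []
    for read in reads:
        if len(read) < cfg.min_len:
            stats.too_short += 1
            continue
        if len(read) > cfg.max_len:
            stats.too_long += 1
            continue
        mq = read.mean_quality
        if mq is None:
            stats.without_qualities += 1
        elif mq < cfg.min_phred:
            stats.low_quality += 1
            continue
        kept.append(read)
        stats.kept += 1
    return kept, stats


# ---------------------------------------------------------------------------
# denoising by greedy identity clustering


def _identity_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    # end-free: reads from one template differ in length at the 3' end
    aligner.end_insertion_score = 0
    aligner.end_deletion_score = 0
    return aligner


_ALIGNER = _identity_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical columns in an end-free global alignment.

    Internal gaps count as columns (homopolymer indels must depress the
    identity); the free terminal overhangs do not.  The denominator is at
    least the shorter sequence length, so a short accidental overlap
    between unrelated sequences cannot masquerade as high identity while
    3'-truncated reads of one template still score 1.0.
    """
    if a == b:
        return 1.0
    alignment = _ALIGNER.align(a, b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    # trim terminal gap runs (the "free" ends); gap-gap columns cannot occur
    start = 0
    end = len(row_a)
    while start < end and (row_a[start] == "-" or row_b[start] == "-"):
        start += 1
    while end > start and (row_a[end - 1] == "-" or row_b[end - 1] == "-"):
        end -= 1
    columns = max(end - start, min(len(a), len(b)))
    if columns <= 0:
        return 0.0
    matches = sum(
        1 for x, y in zip(row_a[start:end], row_b[start:end]) if x == y and x != "-"
    )
    return matches / columns


#: Distinct sequences considered when electing a cluster's representative.
_MEDOID_SAMPLE = 12


def _elect_centroid(groups: list[tuple[str, int]]) -> str:
    """Medoid of a cluster: the member sequence most similar to the rest.

    Candidates and comparison partners are the most abundant distinct
    sequences (capped for cost); similarity is count-weighted pairwise
    identity.  This re-election matters under noise: the greedy founder is
    an arbitrary error variant, while the medoid is the variant the other
    members agree with — in particular one without an indel in front of
    the restriction site.
    """
    if len(groups) == 1:
        return groups[0][0]
    sample = sorted(groups, key=lambda g: (-g[1], g[0]))[:_MEDOID_SAMPLE]
    best_seq = None
    best_key: tuple[float, int, str] | None = None
    for seq, count in sample:
        score = sum(
            c * (1.0 if other == seq else pairwise_identity(seq, other))
            for other, c in sample
        )
        key = (-score, -count, seq)
        if best_key is None or key < best_key:
            best_key = key
            best_seq = seq
    assert best_seq is not None
    return best_seq


def denoise_cluster(
    reads: Sequence[Read],
    identity: float = 0.97,
    seed_order: Literal["abundance", "input"] = "abundance",
) -> list[SequenceCluster]:
    """Greedy incremental clustering at a pairwise-identity threshold.

    Identical sequences are dereplicated first; groups are then processed
    in descending duplicate count (ties broken lexicographically by
    sequence, so the outcome needs no seed).  A group joins the first
    existing centroid at >= *identity*, otherwise it founds a new cluster.
    After assignment each cluster's representative is re-elected as the
    count-weighted medoid of its distinct member sequences.  Every input
    read ends up in exactly one cluster.
    """
    if not 0 < identity <= 1:
        raise ValueError(f"identity {identity} outside (0, 1]")
    groups: dict[str, list[Read]] = {}
    order: list[str] = []
    for read in reads:
        if read.sequence not in groups:
            groups[read.sequence] = []
            order.append(read.sequence)
        groups[read.sequence].append(read)
    if seed_order == "abundance":
        order = sorted(order, key=lambda s: (-len(groups[s]), s))
    elif seed_order != "input":
        raise ValueError(f"unknown seed_order {seed_order!r}")

    centroids: list[str] = []
    members: list[list[Read]] = []
    for seq in order:
        placed = False
        for i, centroid in enumerate(centroids):
            if pairwise_identity(seq, centroid) >= identity:
                members[i].extend(groups[seq])
                placed = True
                break
        if not placed:
            centroids.append(seq)
            members.append(list(groups[seq]))
    clusters = []
    for reads_in in members:
        counts: dict[str, int] = {}
        for r in reads_in:
            counts[r.sequence] = counts.get(r.sequence, 0) + 1
        medoid = _elect_centroid(sorted(counts.items()))
        rep = next(r for r in reads_in if r.sequence == medoid)
        clusters.append(
            SequenceCluster(rep, len(reads_in), [r.id for r in reads_in])
        )
    return clusters


def singleton_clusters(reads: Sequence[Read]) -> list[SequenceCluster]:
    """Wrap each read as its own size-1 cluster (the no-denoise variants)."""
    return [SequenceCluster(r, 1, [r.id]) for r in reads]
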