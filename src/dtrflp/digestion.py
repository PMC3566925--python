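"""Restriction-enzyme registry and in-silico terminal digestion.

A terminal restriction fragment (T-RF) runs from the labeled 5' end of the
processed read to the first cut site of the enzyme.  Reads without a
recognition site yield no fragment and are discarded (counted).  Grouping
fragments by integer size and weighting by cluster size produces the
digital T-RFLP profile.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Sequence

from ._seq import IUPAC_SETS
from .preprocess import SequenceCluster
from .mapping import MappingHit
from .seqio import TRFLPProfile, DEFAULT_SIZE_RANGE

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RestrictionEnzyme:
    """An endonuclease: recognition site (IUPAC) and cut position within it.

    ``cut_offset`` is the cleavage position on the labeled strand, counted
    from the start of the recognition site (HaeIII GG^CC has offset 2).
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.recognition.upper()
        object.__setattr__(self, "recognition", site)
        if len(site) < 4:
            raise ValueError(f"{self.name}: recognition site shorter than 4 bp")
        if any(c not in IUPAC_SETS for c in site):
            raise ValueError(f"{self.name}: non-IUPAC site {site!r}")
        if not 0 <= self.cut_offset <= len(site):
            raise ValueError(f"{self.name}: cut offset {self.cut_offset} out of bounds")

    def pattern(self) -> re.Pattern[str]:
        """Regex matching the site against concrete A/C/G/T bases only.

        Ambiguous bases (N etc.) in the read never match, so uncertain
        base calls cannot create fragments.
        """
        classes = []
        for c in self.recognition:
            bases = sorted(IUPAC_SETS[c])
            classes.append(bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]")
        return re.compile("".join(classes))


#: Standard panel commonly used for bacterial community T-RFLP.
ENZYMES: dict[str, RestrictionEnzyme] = {
    e.name: e
    for e in [
        RestrictionEnzyme("HaeIII", "GGCC", 2),
        RestrictionEnzyme("AluI", "AGCT", 2),
        RestrictionEnzyme("MspI", "CCGG", 1),
        RestrictionEnzyme("HhaI", "GCGC", 3),
        RestrictionEnzyme("RsaI", "GTAC", 2),
        RestrictionEnzyme("TaqI", "TCGA", 1),
    ]
}


def get_enzyme(name: str) -> RestrictionEnzyme:
    for key, enzyme in ENZYMES.items():
        if key.lower() == name.lower():
            return enzyme
    raise KeyError(
        f"unknown enzyme {name!r}; registered: {', '.join(ENZYMES)}"
    )


@dataclass
class DigitalTRF:
    """One digital T-RF: integer size, read count, and its contributors.

    ``contributors`` pairs each contributing cluster's best mapping hit
    (``None`` when digestion ran without mapping) with that cluster's read
    count.
    """

    size: int
    count: int
    contributors: list[tuple[MappingHit | None, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"T-RF size must be >= 1 bp, got {self.size}")
        if self.contributors and self.count != sum(c for _, c in self.contributors):
            raise ValueError("T-RF count must equal the sum of contributor counts")


@dataclass
class DigestionResult:
    trfs: list[DigitalTRF]
    digested_reads: int
    discarded_reads: int  # reads in clusters without a recognition site


def first_cut(
    sequence: str,
    enzyme: RestrictionEnzyme,
    origin_offset: int = 0,
) -> int | None:
    """Terminal-fragment size for one read, or ``None`` if no site exists.

    The size is the 0-based index of the first recognition-site occurrence
    plus the enzyme's cut offset, plus *origin_offset* (use the trimmed
    forward-primer length to restore primer-inclusive sizes).
    """
    m = enzyme.pattern().search(sequence.upper())
    if m is None:
        return None
    return m.start() + enzyme.cut_offset + origin_offset


def digest_dataset(
    clusters: Sequence[SequenceCluster],
    hits: Sequence[MappingHit] | None,
    enzyme: RestrictionEnzyme,
    origin_offset: int = 0,
) -> DigestionResult:
    """Digest cluster centroids and aggregate fragments by integer size.

    When *hits* is given, only clusters with a mapping hit participate
    (the standard procedure); pass ``None`` to digest every cluster (the
    raw/filtered variants that bypass score filtering).  Each fragment is
    weighted by its cluster's read count.
    """
    hit_by_id: dict[str, MappingHit] | None = None
    if hits is not None:
        hit_by_id = {h.query_id: h for h in hits}
    by_size: dict[int, list[tuple[MappingHit | None, int]]] = {}
    digested = 0
    discarded = 0
    for cluster in clusters:
        hit: MappingHit | None = None
        if hit_by_id is not None:
            hit = hit_by_id.get(cluster.centroid.id)
            if hit is None:
                continue  # removed by mapping; not a digestion discard
        size = first_cut(cluster.centroid.sequence, enzyme, origin_offset)
        if size is None or size < 1:
            discarded += cluster.size
            continue
        by_size.setdefault(size, []).append((hit, cluster.size))
        digested += cluster.size
    trfs = [
        DigitalTRF(size, sum(c for _, c in contribs), contribs)
        for size, contribs in sorted(by_size.items())
    ]
    if discarded:
        logger.info("digestion (%s): %d reads without a site discarded", enzyme.name, discarded)
    return DigestionResult(trfs, digested, discarded)


def build_profile(
    trfs: Sequence[DigitalTRF],
    sample_id: str,
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
) -> TRFLPProfile:
    """Digital fingerprint from T-RF counts: abundance = 100·count/Σcounts.

    Only fragments inside *size_range* participate; pass a (1, 500) range
    to keep sub-50 bp fragments (the no-eT-RFLP mode).
    """
    counts = {t.size: t.count for t in trfs}
    if sum(counts.values()) == 0:
        raise ValueError("empty profile")
    return TRFLPProfile.from_abundances(
        sample_id, "digital", {s: float(c) for s, c in counts.items()}, size_range
    )
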