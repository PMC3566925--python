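"""Community indices and enzyme-screening reports for T-RFLP fingerprints.

Richness is the number of distinct fragments in a profile; Shannon's H'
(natural log) additionally weighs the evenness of their abundances.  The
50-bp density histogram with its cumulative curve shows how an enzyme
spreads fragments along the size axis — the basis for choosing the
best-suited enzyme for a community.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .digestion import RestrictionEnzyme, digest_dataset, build_profile
from .mapping import MappingHit
from .preprocess import SequenceCluster
from .seqio import TRFLPProfile


@dataclass
class ProfileIndices:
    richness: int
    shannon: float  # natural-log units


@dataclass
class DensityReport:
    """Fragment counts per 50-bp size class with the cumulative curve."""

    enzyme: str
    class_edges: list[tuple[int, int]]
    class_counts: list[int]
    cumulative: list[int]
    indices: ProfileIndices

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class_start_bp": [lo for lo, _ in self.class_edges],
                "class_end_bp": [hi for _, hi in self.class_edges],
                "trf_count": self.class_counts,
                "cumulative_trf_count": self.cumulative,
            }
        )


def indices(profile: TRFLPProfile, min_abundance: float = 0.0) -> ProfileIndices:
    """Richness and Shannon H' of a fingerprint.

    Richness counts peaks with abundance above *min_abundance* (default:
    any positive peak); H' = −Σ p_i ln p_i over the same peaks with
    p_i = abundance_i / 100.
    """
    peaks = [a for _, a in profile.peaks if a > min_abundance]
    if not peaks:
        raise ValueError("empty profile")
    total = sum(peaks)
    shannon = -sum((a / total) * math.log(a / total) for a in peaks)
    return ProfileIndices(richness=len(peaks), shannon=shannon)


def density_report(
    profile: TRFLPProfile,
    enzyme: str,
    class_width: int = 50,
    domain: tuple[int, int] = (0, 500),
) -> DensityReport:
    """Distinct-fragment counts per size class over [0, 500] bp.

    Classes are half-open except the last, which includes the upper
    bound; the cumulative curve ends at the richness.
    """
    lo, hi = domain
    edges = [(start, start + class_width) for start in range(lo, hi, class_width)]
    counts = [0] * len(edges)
    for size, abundance in profile.peaks:
        if abundance <= 0 or not lo <= size <= hi:
            continue
        idx = min((size - lo) // class_width, len(edges) - 1)
        counts[idx] += 1
    cumulative = []
    running = 0
    for c in counts:
        running += c
        cumulative.append(running)
    if any(a > 0 for _, a in profile.peaks):
        idx = indices(profile)
    else:
        idx = ProfileIndices(0, 0.0)
    return DensityReport(enzyme, edges, counts, cumulative, idx)


@dataclass
class ScreenEntry:
    profile: TRFLPProfile
    report: DensityReport
    discarded_reads: int


def screen_enzymes(
    clusters: Sequence[SequenceCluster],
    hits: Sequence[MappingHit] | None,
    enzymes: Sequence[RestrictionEnzyme],
    sample_id: str = "sample",
    origin_offset: int = 0,
    size_range: tuple[int, int] = (1, 500),
) -> dict[str, ScreenEntry]:
    """Digest the same dataset with each enzyme and report per-enzyme indices.

    Runs without experimental data (full 1-500 bp window by default) so an
    enzyme panel can be screened before any electropherogram exists.
    Enzymes whose site is absent from every read yield an entry with an
    empty profile marker (richness 0).
    """
    if not enzymes:
        raise ValueError("empty enzyme list")
    results: dict[str, ScreenEntry] = {}
    for enzyme in enzymes:
        digestion = digest_dataset(clusters, hits, enzyme, origin_offset)
        if not digestion.trfs:
            empty = TRFLPProfile(sample_id, "digital", [], size_range)
            report = DensityReport(
                enzyme.name,
                [(s, s + 50) for s in range(0, 500, 50)],
                [0] * 10,
                [0] * 10,
                ProfileIndices(0, 0.0),
            )
            results[enzyme.name] = ScreenEntry(empty, report, digestion.discarded_reads)
            continue
        profile = build_profile(digestion.trfs, sample_id, size_range)
        results[enzyme.name] = ScreenEntry(
            profile,
            density_report(profile, enzyme.name),
            digestion.discarded_reads,
        )
    return results


def ranking_table(results: dict[str, ScreenEntry]) -> pd.DataFrame:
    """Enzymes ranked by richness then diversity, to support enzyme choice."""
    frame = pd.DataFrame.from_records(
        [
            {
                "enzyme": name,
                "richness": entry.report.indices.richness,
                "shannon_h": round(entry.report.indices.shannon, 4),
                "reads_without_site": entry.discarded_reads,
            }
            for name, entry in results.items()
        ]
    )
    return frame.sort_values(
        ["richness", "shannon_h"], ascending=False, ignore_index=True
    )
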