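"""Synthetic fixtures: reference database, error-bearing reads, drifted
experimental fingerprint — with the ground truth carried alongside.

The generator emulates the inputs the pipeline expects from a real study:
a taxonomy-annotated 16S reference FASTA, amplicon reads drawn from a
known community with substitution and homopolymer-length errors (the
dominant pyrosequencing error mode), and the electropherogram CSV the lab
method would produce, i.e. the true digital fingerprint shifted a few bp
short (electrophoretic drift) with faint peaks below the detection floor
removed.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .digestion import ENZYMES, RestrictionEnzyme, first_cut
from .seqio import (
    Read,
    ReferenceRecord,
    TRFLPProfile,
    write_fastq,
    write_profile,
    write_reference_db,
)

_RANK_PREFIXES = ("P", "C", "O", "F", "G", "S")
_BASES = np.array(list("ACGT"))

#: Error rates a 454-era amplicon run would plausibly show: ~0.5% substitutions
#: and ~1% of homopolymer runs mis-called by one base.
DEFAULT_SUBSTITUTION_RATE = 0.005
DEFAULT_HOMOPOLYMER_INDEL_RATE = 0.01

CLEAN_QUALITY = 40
EDITED_QUALITY = 10


@dataclass
class GroundTruth:
    """What the generator knows: sources, true fragment sizes, expectation."""

    enzyme: str
    trf_sizes: dict[str, int]  # accession -> true terminal-fragment size (bp)
    taxonomies: dict[str, str]  # accession -> taxonomy string
    read_sources: dict[str, str] = field(default_factory=dict)  # read id -> accession
    expected_counts: dict[int, int] = field(default_factory=dict)  # size -> reads

    def expected_profile(
        self, sample_id: str = "truth", size_range: tuple[int, int] = (1, 500)
    ) -> TRFLPProfile:
        if not self.expected_counts:
            raise ValueError("ground truth carries no read counts yet")
        return TRFLPProfile.from_abundances(
            sample_id,
            "digital",
            {s: float(c) for s, c in self.expected_counts.items()},
            size_range,
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "enzyme": self.enzyme,
            "trf_sizes": self.trf_sizes,
            "taxonomies": self.taxonomies,
            "read_sources": self.read_sources,
            "expected_counts": {str(k): v for k, v in self.expected_counts.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1), newline="\n")


@dataclass
class CommunitySpec:
    """Parameters of a simulated amplicon run on a known community."""

    taxa: list[tuple[ReferenceRecord, float]]
    read_count: int = 500
    substitution_rate: float = DEFAULT_SUBSTITUTION_RATE
    homopolymer_indel_rate: float = DEFAULT_HOMOPOLYMER_INDEL_RATE
    length_range: tuple[int, int] = (300, 450)
    enzyme: RestrictionEnzyme = ENZYMES["HaeIII"]
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(a for _, a in self.taxa)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"taxon abundances sum to {total}, expected 1")
        for rate in (self.substitution_rate, self.homopolymer_indel_rate):
            if not 0 <= rate < 1:
                raise ValueError(f"rate {rate} outside [0, 1)")


_RANK_NAMES = ("Phylum", "Class", "Order", "Family", "Genus", "Species")


def _taxonomy_for(i: int) -> tuple[str, ...]:
    return tuple(
        f"{p}:Synthetic{name}_{i + 1}"
        for p, name in zip(_RANK_PREFIXES, _RANK_NAMES)
    )


def _random_seq_without_site(
    rng: np.random.Generator, length: int, pattern
) -> list[str]:
    seq = list(rng.choice(_BASES, size=length))
    # mutate away accidental recognition sites
    for _ in range(100):
        m = pattern.search("".join(seq))
        if m is None:
            return seq
        pos = m.start()
        current = seq[pos]
        seq[pos] = str(rng.choice([b for b in "ACGT" if b != current]))
    raise RuntimeError("could not scrub recognition sites from random sequence")


def make_reference_db(
    n_taxa: int,
    length: int = 480,
    enzyme: RestrictionEnzyme = ENZYMES["HaeIII"],
    site_positions: Sequence[int] | None = None,
    seed: int = 0,
) -> tuple[list[ReferenceRecord], GroundTruth]:
    """Reference records with one pinned recognition site each.

    *site_positions* pins the first (and only) recognition site of each
    taxon, so true terminal-fragment sizes (site index + cut offset) are
    known and distinct; defaults to evenly spaced positions in [80, 280],
    inside every read of the default length range so each read reaches
    its site.  Sizes outside [50, 500] or positions beyond the sequence
    are an error.
    """
    if site_positions is None:
        site_positions = [
            80 + round(i * 200 / max(n_taxa - 1, 1)) for i in range(n_taxa)
        ]
    if len(site_positions) != n_taxa:
        raise ValueError("need one site position per taxon")
    sizes = [p + enzyme.cut_offset for p in site_positions]
    if len(set(sizes)) != n_taxa:
        raise ValueError("pinned sites give non-distinct fragment sizes")
    site_len = len(enzyme.recognition)
    rng = np.random.default_rng(seed)
    pattern = enzyme.pattern()
    records: list[ReferenceRecord] = []
    trf_sizes: dict[str, int] = {}
    taxonomies: dict[str, str] = {}
    for i, pos in enumerate(site_positions):
        size = pos + enzyme.cut_offset
        if not 50 <= size <= 500:
            raise ValueError(f"taxon {i}: fragment size {size} outside [50, 500]")
        if pos + site_len > length:
            raise ValueError(f"taxon {i}: site at {pos} does not fit in {length} bp")
        for _ in range(50):
            seq = _random_seq_without_site(rng, length, pattern)
            seq[pos : pos + site_len] = list(enzyme.recognition)
            joined = "".join(seq)
            if pattern.search(joined).start() == pos:
                break
        else:
            raise RuntimeError("failed to plant a clean recognition site")
        accession = f"SYN{i + 1:05d}"
        record = ReferenceRecord(
            otu_id=str(1000 + i),
            accession=accession,
            taxonomy=_taxonomy_for(i),
            sequence=joined,
        )
        records.append(record)
        trf_sizes[accession] = size
        taxonomies[accession] = record.taxonomy_string
    truth = GroundTruth(enzyme.name, trf_sizes, taxonomies)
    return records, truth


def _inject_errors(
    rng: np.random.Generator,
    seq: str,
    substitution_rate: float,
    homopolymer_indel_rate: float,
) -> tuple[str, list[int]]:
    """Apply homopolymer ±1 indels (runs >= 3 bp) then substitutions.

    Returns the edited sequence and per-base PHRED qualities (clean bases
    high, edited bases low).
    """
    bases = list(seq)
    quals = [CLEAN_QUALITY] * len(bases)
    if homopolymer_indel_rate > 0:
        out: list[str] = []
        out_q: list[int] = []
        i = 0
        while i < len(bases):
            j = i
            while j < len(bases) and bases[j] == bases[i]:
                j += 1
            run = bases[i:j]
            run_q = quals[i:j]
            if len(run) >= 3 and rng.random() < homopolymer_indel_rate:
                if rng.random() < 0.5:
                    run = run + [run[0]]  # over-call
                    run_q = run_q + [EDITED_QUALITY]
                else:
                    run = run[:-1]  # under-call
                    run_q = run_q[:-1]
                run_q = [EDITED_QUALITY] * len(run_q)
            out.extend(run)
            out_q.extend(run_q)
            i = j
        bases, quals = out, out_q
    if substitution_rate > 0:
        hit = rng.random(len(bases)) < substitution_rate
        for k in np.flatnonzero(hit):
            current = bases[k]
            bases[k] = str(rng.choice([b for b in "ACGT" if b != current]))
            quals[k] = EDITED_QUALITY
    return "".join(bases), quals


def simulate_reads(spec: CommunitySpec) -> tuple[list[Read], GroundTruth]:
    """Draw reads from the community and inject sequencing errors.

    Each read is a 5'-anchored prefix of its source reference (the labeled
    primer end), with length uniform over ``length_range``.  The returned
    ground truth records every read's source accession and the expected
    fragment counts given the *realized* taxon draw (error-free digestion
    of the sources).
    """
    rng = np.random.default_rng(spec.seed)
    refs = [r for r, _ in spec.taxa]
    probs = np.array([a for _, a in spec.taxa])
    trf_sizes = {
        r.accession: first_cut(r.sequence, spec.enzyme) for r in refs
    }
    truth = GroundTruth(
        spec.enzyme.name,
        {a: s for a, s in trf_sizes.items() if s is not None},
        {r.accession: r.taxonomy_string for r in refs},
    )
    lo, hi = spec.length_range
    reads: list[Read] = []
    for i in range(spec.read_count):
        idx = int(rng.choice(len(refs), p=probs))
        ref = refs[idx]
        length = int(rng.integers(lo, hi + 1))
        template = ref.sequence[: min(length, len(ref.sequence))]
        seq, quals = _inject_errors(
            rng, template, spec.substitution_rate, spec.homopolymer_indel_rate
        )
        read_id = f"read_{i + 1:05d}"
        reads.append(Read(read_id, seq, quals))
        truth.read_sources[read_id] = ref.accession
        # a read contributes a fragment only if it reaches its cut site
        size = first_cut(template, spec.enzyme)
        if size is not None:
            truth.expected_counts[size] = truth.expected_counts.get(size, 0) + 1
    return reads, truth


def derive_etrflp(
    truth: GroundTruth,
    drift: int = 5,
    detection_floor: float = 0.0,
    sample_id: str = "synthetic_etrflp",
) -> TRFLPProfile:
    """The electropherogram the lab method would yield for this community.

    True fragment sizes are shifted by −*drift* bp (capillary sizing runs
    short of the sequence length); peaks whose relative abundance falls
    below *detection_floor* percent vanish; the rest renormalizes.  Sizes
    shifted below 50 bp are dropped with a warning by the profile window.
    """
    total = sum(truth.expected_counts.values())
    if total == 0:
        raise ValueError("ground truth carries no read counts")
    shifted = {
        size - drift: 100.0 * count / total
        for size, count in truth.expected_counts.items()
    }
    kept = {s: a for s, a in shifted.items() if a >= detection_floor}
    if not kept:
        raise ValueError("detection floor removed every peak")
    return TRFLPProfile.from_abundances(sample_id, "experimental", kept, (50, 500))


def write_fixture_set(
    out_dir: str | Path,
    n_taxa: int = 6,
    read_count: int = 300,
    drift: int = 5,
    substitution_rate: float = DEFAULT_SUBSTITUTION_RATE,
    homopolymer_indel_rate: float = DEFAULT_HOMOPOLYMER_INDEL_RATE,
    detection_floor: float = 0.0,
    enzyme: RestrictionEnzyme = ENZYMES["HaeIII"],
    seed: int = 0,
) -> dict[str, str]:
    """Write a complete input set (reads, reference DB, eT-RFLP CSV, truth).

    Community abundances follow a geometric series (a few dominant taxa,
    a tail of rare ones), the shape real fingerprints show.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, _ = make_reference_db(n_taxa, enzyme=enzyme, seed=seed)
    weights = np.array([0.6**i for i in range(n_taxa)])
    weights /= weights.sum()
    spec = CommunitySpec(
        taxa=list(zip(records, weights.tolist())),
        read_count=read_count,
        substitution_rate=substitution_rate,
        homopolymer_indel_rate=homopolymer_indel_rate,
        enzyme=enzyme,
        seed=seed + 1,
    )
    reads, truth = simulate_reads(spec)
    eprofile = derive_etrflp(truth, drift, detection_floor)
    paths = {
        "reads": str(out / "reads.fastq"),
        "reference_db": str(out / "reference.fasta"),
        "etrflp": str(out / "etrflp.csv"),
        "ground_truth": str(out / "ground_truth.json"),
    }
    write_fastq(reads, paths["reads"])
    write_reference_db(records, paths["reference_db"])
    write_profile(eprofile, paths["etrflp"])
    truth.to_json(paths["ground_truth"])
    return paths
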