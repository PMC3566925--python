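import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dtrflp import digestion
from dtrflp._seq import IUPAC_SETS
from dtrflp.digestion import (
    ENZYMES,
    DigitalTRF,
    RestrictionEnzyme,
    build_profile,
    digest_dataset,
    first_cut,
    get_enzyme,
)
from dtrflp.mapping import MappingHit
from dtrflp.preprocess import SequenceCluster
from dtrflp.seqio import ReferenceRecord

from conftest import make_read


def naive_first_cut(seq: str, enzyme: RestrictionEnzyme) -> int | None:
    """Left-to-right per-position set-membership scan (oracle)."""
    site = enzyme.recognition
    for i in range(len(seq) - len(site) + 1):
        if all(
            seq[i + k] in "ACGT" and seq[i + k] in IUPAC_SETS[site[k]]
            for k in range(len(site))
        ):
            return i + enzyme.cut_offset
    return None


def _cluster(seq: str, rid: str, size: int = 1) -> SequenceCluster:
    members = [rid] + [f"{rid}_{i}" for i in range(1, size)]
    return SequenceCluster(make_read(seq, rid), size, members)


def _hit(rid: str, accession: str, taxon: str) -> MappingHit:
    ref = ReferenceRecord("1", accession, (taxon,), "ACGT" * 100)
    return MappingHit(rid, ref, 300, 0.9, (0, 300), (0, 300))


class TestRegistry:
    @pytest.mark.parametrize(
        "name,site,offset",
        [
            ("HaeIII", "GGCC", 2),
            ("AluI", "AGCT", 2),
            ("MspI", "CCGG", 1),
            ("HhaI", "GCGC", 3),
            ("RsaI", "GTAC", 2),
            ("TaqI", "TCGA", 1),
        ],
    )
    def test_standard_panel(self, name, site, offset):
        enzyme = get_enzyme(name)
        assert enzyme.recognition == site
        assert enzyme.cut_offset == offset

    def test_unknown_enzyme(self):
        with pytest.raises(KeyError):
            get_enzyme("NoSuchI")

    def test_user_defined_enzyme_with_iupac_site(self):
        enzyme = RestrictionEnzyme("Custom", "GGNC", 2)
        assert first_cut("TTGGACAA", enzyme) == 4


class TestFirstCut:
    def test_haeiii_interior_site(self):
        assert first_cut("AAAAGGCCTT", ENZYMES["HaeIII"]) == 6  # index 4 + offset 2

    def test_no_site_returns_none(self):
        assert first_cut("ATATATATAT", ENZYMES["HaeIII"]) is None

    def test_mspi_site_at_start(self):
        assert first_cut("CCGGAA", ENZYMES["MspI"]) == 1

    def test_origin_offset_restores_primer_length(self):
        assert first_cut("AAAAGGCCTT", ENZYMES["HaeIII"], origin_offset=20) == 26

    def test_ambiguous_read_base_never_matches(self):
        assert first_cut("AAGGNCCTT", ENZYMES["HaeIII"]) is None

    def test_matches_naive_scan_on_random_sequences(self, rng):
        enzymes = list(ENZYMES.values())
        for i in range(1000):
            length = int(rng.integers(20, 200))
            seq = "".join(rng.choice(list("ACGTN"), size=length, p=[0.24] * 4 + [0.04]))
            enzyme = enzymes[i % len(enzymes)]
            assert first_cut(seq, enzyme) == naive_first_cut(seq, enzyme)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        seq=st.text(alphabet="ACGTN", min_size=1, max_size=120),
        enzyme_name=st.sampled_from(sorted(ENZYMES)),
    )
    def test_first_cut_equals_naive_scan_hypothesis(self, seq, enzyme_name):
        enzyme = ENZYMES[enzyme_name]
        assert first_cut(seq, enzyme) == naive_first_cut(seq, enzyme)

    def test_matches_biopython_restriction_positions(self, rng, random_seq):
        """Independent cross-check against Bio.Restriction's site search."""
        from Bio.Restriction import HaeIII
        from Bio.Seq import Seq

        for _ in range(50):
            seq = random_seq(300)
            ours = first_cut(seq, ENZYMES["HaeIII"])
            # Bio.Restriction reports 1-based positions after the cut
            cuts = HaeIII.search(Seq(seq))
            theirs = (cuts[0] - 1) if cuts else None
            assert ours == theirs


class TestDigestDataset:
    def test_aggregates_contributors_by_size(self, random_seq):
        # a dominant phylotype plus three singletons all cutting at 219 bp
        body = ("AT" * 108) + "A" + "GGCC" + random_seq(100)
        assert first_cut(body, ENZYMES["HaeIII"]) == 219
        clusters = [
            _cluster(body, "dominant", 769),
            _cluster(body, "s1"),
            _cluster(body, "s2"),
            _cluster(body, "s3"),
        ]
        hits = [
            _hit("dominant", "AB200295", "S:Rhodocyclus_tenuis"),
            _hit("s1", "DQ066958", "G:Methyloversatilis"),
            _hit("s2", "DQ413103", "G:Dechloromonas"),
            _hit("s3", "EU937892", "G:Nitrosomonas"),
        ]
        result = digest_dataset(clusters, hits, ENZYMES["HaeIII"])
        (trf,) = result.trfs
        assert trf.size == 219
        assert trf.count == 772
        assert len(trf.contributors) == 4

    def test_empty_cluster_list(self):
        result = digest_dataset([], None, ENZYMES["HaeIII"])
        assert result.trfs == []
        assert result.discarded_reads == 0

    def test_all_site_free_clusters_discarded(self):
        clusters = [_cluster("AT" * 200, "a", 3), _cluster("TA" * 200, "b", 2)]
        result = digest_dataset(clusters, None, ENZYMES["HaeIII"])
        assert result.trfs == []
        assert result.discarded_reads == 5

    def test_count_conservation(self, rng, random_seq):
        clusters = [
            _cluster(random_seq(300), f"c{i}", int(rng.integers(1, 20)))
            for i in range(20)
        ]
        total = sum(c.size for c in clusters)
        result = digest_dataset(clusters, None, ENZYMES["HaeIII"])
        assert sum(t.count for t in result.trfs) + result.discarded_reads == total

    def test_planted_site_yields_single_trf(self):
        k = 150
        clusters = [
            _cluster("AT" * (k // 2) + "GGCC" + "AT" * 50, f"c{i}") for i in range(5)
        ]
        result = digest_dataset(clusters, None, ENZYMES["HaeIII"])
        assert [t.size for t in result.trfs] == [k + 2]
        assert result.trfs[0].count == 5

    def test_unmapped_clusters_excluded_when_hits_given(self, random_seq):
        body = "A" * 100 + "GGCC" + "A" * 100
        clusters = [_cluster(body, "mapped"), _cluster(body, "unmapped")]
        hits = [_hit("mapped", "ACC1", "G:X")]
        result = digest_dataset(clusters, hits, ENZYMES["HaeIII"])
        assert result.trfs[0].count == 1


class TestBuildProfile:
    def test_normalization(self):
        trfs = [DigitalTRF(100, 750), DigitalTRF(200, 250)]
        profile = build_profile(trfs, "s")
        assert profile.abundances[100] == pytest.approx(75.0)
        assert profile.abundances[200] == pytest.approx(25.0)
        assert profile.kind == "digital"

    def test_single_trf(self):
        profile = build_profile([DigitalTRF(100, 5)], "s")
        assert profile.peaks == [(100, 100.0)]

    def test_range_filter_then_renormalize(self):
        trfs = [DigitalTRF(60, 1), DigitalTRF(510, 1)]
        with pytest.raises(ValueError):
            build_profile([], "s")
        profile = build_profile(trfs, "s", (50, 500))
        assert profile.peaks == [(60, 100.0)]

    def test_sub50_kept_with_wide_range(self):
        profile = build_profile([DigitalTRF(30, 1), DigitalTRF(60, 1)], "s", (1, 500))
        assert profile.sizes == [30, 60]
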