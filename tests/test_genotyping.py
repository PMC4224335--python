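"""In-silico digestion, RFLP genotype calling and haplogroup clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitonuclear import (
    AlleleModel,
    BandPattern,
    DigestSpec,
    HPYCH4IV,
    RS8875_MODEL,
    cluster_haplogroup,
    digest,
    genotype_from_bands,
)

REVCOMP = str.maketrans("ACGT", "TGCA")


def brute_force_digest(seq: str, motif: str, cut_offset: int) -> list[int]:
    """Independent oracle: enumerate motif starts by scanning every index,
    greedily skipping overlaps, then split at the cut positions."""
    cuts, i = [], 0
    while i <= len(seq) - len(motif):
        if seq[i : i + len(motif)] == motif:
            cuts.append(i + cut_offset + 1)
            i += len(motif)
        else:
            i += 1
    bounds = [0] + cuts + [len(seq)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


class TestDigest:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("AAACGTAA", [3, 5]),  # one site at index 2, cut after its A
            ("AAAA", [4]),  # no site: single fragment
            ("ACGT", [1, 3]),
            ("ACGTACGT", [1, 4, 3]),
        ],
    )
    def test_known_patterns(self, seq, expected):
        assert digest(seq, HPYCH4IV) == expected

    def test_planted_sites_in_random_sequence(self, rng):
        """A 60-mer with two planted non-overlapping sites yields 3 fragments."""
        body = "".join(rng.choice(list("ACT"), size=60))  # no G -> no chance sites
        seq = body[:15] + "ACGT" + body[15:40] + "ACGT" + body[40:52]
        frags = digest(seq, HPYCH4IV)
        assert len(frags) == 3
        assert sum(frags) == 60
        assert frags == brute_force_digest(seq, "ACGT", 0)

    @given(st.text(alphabet="ACGT", min_size=1, max_size=120))
    @settings(max_examples=150, derandomize=True)
    def test_fragments_partition_sequence(self, seq):
        frags = digest(seq, HPYCH4IV)
        assert sum(frags) == len(seq)
        assert all(f > 0 for f in frags)
        assert frags == brute_force_digest(seq, "ACGT", 0)

    @given(st.text(alphabet="ACGT", min_size=1, max_size=120))
    @settings(max_examples=100, derandomize=True)
    def test_palindromic_strand_symmetry(self, seq):
        """ACGT equals its reverse complement, so fragment multisets match."""
        rc = seq.translate(REVCOMP)[::-1]
        assert sorted(digest(seq, HPYCH4IV)) == sorted(digest(rc, HPYCH4IV))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            digest("ACGN", HPYCH4IV)
        with pytest.raises(ValueError):
            digest("", HPYCH4IV)
        with pytest.raises(ValueError):
            DigestSpec("ACGT", cut_offset=4)
        with pytest.raises(ValueError):
            DigestSpec("")


class TestGenotypeFromBands:
    @pytest.mark.parametrize(
        "bands, expected",
        [
            ((326,), "CC"),  # intact amplicon: uncut homozygote
            ((215, 111), "GG"),  # fully cut
            ((326, 215, 111), "CG"),  # heterozygote shows all three bands
        ],
    )
    def test_expected_patterns(self, bands, expected):
        assert genotype_from_bands(BandPattern(bands), RS8875_MODEL) == expected

    def test_tolerance_window(self):
        assert genotype_from_bands(BandPattern((321,), tolerance_bp=5)) == "CC"
        assert genotype_from_bands(BandPattern((318,), tolerance_bp=5)) is None

    @pytest.mark.parametrize("bands", [(500,), (326, 111), (215,), (326, 215, 111, 50)])
    def test_unrecognised_patterns_are_missing_calls(self, bands):
        assert genotype_from_bands(BandPattern(bands), RS8875_MODEL) is None

    def test_digest_roundtrip_recovers_planted_genotype(self, rng):
        """Amplicons built with 0/1/2 cut-allele chromosomes genotype back."""
        flank_l = "".join(rng.choice(list("ACT"), size=214))
        flank_r = "".join(rng.choice(list("ACT"), size=108))
        cut_amp = flank_l + "ACGT" + flank_r  # 326 bp, cut -> 215 + 111
        uncut_amp = flank_l + "AGCT" + flank_r  # same length, no site
        for chrom_pair, expected in [
            ((uncut_amp, uncut_amp), "CC"),
            ((uncut_amp, cut_amp), "CG"),
            ((cut_amp, cut_amp), "GG"),
        ]:
            bands = sorted({f for chrom in chrom_pair for f in digest(chrom)}, reverse=True)
            call = genotype_from_bands(BandPattern(tuple(bands)), RS8875_MODEL)
            assert call == expected

    def test_allele_model_validation(self):
        with pytest.raises(ValueError):
            AlleleModel("C", "C", 326, (215, 111))
        with pytest.raises(ValueError):
            AlleleModel("C", "G", 326, (215, 110))


class TestClusterHaplogroup:
    @pytest.mark.parametrize(
        "haplogroup, cluster",
        [
            ("K", "UK"),
            ("N1", "IW"),
            ("H1a", "HV"),
            ("U5b1", "UK"),
            ("J2a1", "JT"),
            ("V7", "HV"),
            ("W6", "IW"),
            ("X2", "IW"),
            ("N1b", "IW"),  # longest-prefix: matches N1, not a bare N
            ("t2b", "JT"),  # case-insensitive
        ],
    )
    def test_cluster_assignment(self, haplogroup, cluster):
        assert cluster_haplogroup(haplogroup) == cluster

    @pytest.mark.parametrize("haplogroup", ["L3", "M", "A2", "N9a"])
    def test_unmapped_haplogroups_are_missing(self, haplogroup, caplog):
        assert cluster_haplogroup(haplogroup) is None
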