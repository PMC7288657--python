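"""Guide enumeration and filters vs exhaustive oracles; strand symmetry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonescreen import (
    GuideCandidate,
    count_offtargets,
    cut_distance_filter,
    enumerate_candidates,
    gc_filter,
    simulate_genome_with_snp,
)
from clonescreen.guides import reverse_complement

from conftest import SEED

PROTO_LEN = 19


def oracle_sites(window: str, protospacer_len: int = PROTO_LEN):
    """Independent exhaustive oracle: every (start, strand) whose
    protospacer+NGG fits, written as plainly as possible."""
    window = window.upper()
    rc = reverse_complement(window)
    L = len(window)
    sites = set()
    for s, strand in [(window, "+"), (rc, "-")]:
        for i in range(L):
            proto = s[i : i + protospacer_len]
            pam = s[i + protospacer_len : i + protospacer_len + 3]
            if len(pam) < 3 or pam[1:3] != "GG":
                continue
            if set(proto + pam) <= set("ACGT"):
                if strand == "+":
                    sites.add((i, "+"))
                else:
                    # map the reverse-complement start back to window frame
                    sites.add((L - i - protospacer_len, "-"))
    return sites


def random_window(seed, length=120):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))


class TestEnumeration:
    def test_poly_a_window_has_no_candidates(self):
        assert enumerate_candidates("A" * 60, 30) == []

    def test_planted_sites_found_exactly(self):
        # A/T background with one + NGG and one - CCN planted
        seq = list("AT" * 40)
        seq[30], seq[31] = "G", "G"  # + PAM (NGG) at 29..31
        seq[50], seq[51] = "C", "C"  # - PAM (CCN) at 50..52
        cands = enumerate_candidates("".join(seq), 40)
        assert len(cands) == 2
        strands = sorted(c.strand for c in cands)
        assert strands == ["+", "-"]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle(self, seed):
        window = random_window(seed)
        got = {(c.protospacer_start, c.strand) for c in enumerate_candidates(window, 60)}
        assert got == oracle_sites(window)

    @pytest.mark.parametrize("seed", range(3))
    def test_strand_symmetry(self, seed):
        window = random_window(seed)
        L = len(window)
        fwd = enumerate_candidates(window, 60)
        rev = enumerate_candidates(reverse_complement(window), L - 1 - 60)
        def canon(cands, mirror):
            out = set()
            for c in cands:
                cut = L - 1 - c.cut_pos if mirror else c.cut_pos
                strand = {"+": "-", "-": "+"}[c.strand] if mirror else c.strand
                out.add((c.protospacer, strand, cut, c.snp_distance))
            return out
        assert canon(fwd, False) == canon(rev, True)

    def test_deterministic_order(self):
        window = random_window(11)
        cands = enumerate_candidates(window, 60)
        keys = [(c.protospacer_start, c.strand) for c in cands]
        assert keys == sorted(keys, key=lambda k: (k[0], k[1] == "-"))

    def test_ambiguous_bases_excluded(self):
        window = random_window(3)
        sites = oracle_sites(window)
        assert sites, "fixture must contain at least one site"
        start, strand = sorted(sites)[0]
        broken = list(window)
        broken[start + 2] = "N"
        got = {(c.protospacer_start, c.strand) for c in enumerate_candidates("".join(broken), 60)}
        assert (start, strand) not in got

    def test_snp_outside_window_rejected(self):
        with pytest.raises(ValueError):
            enumerate_candidates("ACGT" * 20, 99)


def _cand(protospacer="A" * PROTO_LEN, gc=0.5, cut=10, snp=10, strand="+", start=0):
    return GuideCandidate(
        protospacer=protospacer,
        pam="AGG",
        strand=strand,
        protospacer_start=start,
        cut_pos=cut,
        gc_fraction=gc,
        snp_distance=abs(cut - snp),
    )


class TestFilters:
    def test_gc_boundaries(self):
        kept = gc_filter(
            [
                _cand(protospacer="G" * PROTO_LEN, gc=1.0),
                _cand(gc=1 / PROTO_LEN),  # one G in 19 ~ 0.053 < 0.10
                _cand(gc=0.80),
                _cand(gc=0.10),
                _cand(gc=0.45),
            ]
        )
        assert [c.gc_fraction for c in kept] == [0.80, 0.10, 0.45]

    def test_gc_computed_over_protospacer_only(self):
        window = "ATATATATATATATATATATATAGGGGG" + "ATATATATATATATATATATAT"
        cands = enumerate_candidates(window, 10)
        for c in cands:
            proto = c.protospacer
            assert c.gc_fraction == pytest.approx(
                (proto.count("G") + proto.count("C")) / len(proto)
            )

    def test_cut_distance_boundaries(self):
        cands = [_cand(cut=20, snp=20), _cand(cut=30, snp=20), _cand(cut=31, snp=20)]
        kept = cut_distance_filter(cands, 20)
        assert [c.snp_distance for c in kept] == [0, 10]

    @pytest.mark.parametrize("seed", range(3))
    def test_survivors_match_brute_force_recomputation(self, seed):
        window = random_window(seed, length=200)
        snp = 100
        cands = enumerate_candidates(window, snp)
        kept = cut_distance_filter(gc_filter(cands), snp)
        brute = [
            c
            for c in cands
            if 0.10 <= c.gc_fraction <= 0.80 and abs(c.cut_pos - snp) <= 10
        ]
        assert kept == brute

    @pytest.mark.parametrize("seed", range(3))
    def test_filter_composition_order_independent(self, seed):
        cands = enumerate_candidates(random_window(seed, length=200), 100)
        a = cut_distance_filter(gc_filter(cands), 100)
        b = gc_filter(cut_distance_filter(cands, 100))
        assert a == b


def _hamming_oracle(proto, genome):
    """Independent off-target oracle using numpy array comparison."""
    counts = {0: 0, 1: 0, 2: 0}
    n = len(proto)
    pv = np.frombuffer(proto.encode(), dtype="S1")
    for s in (genome, reverse_complement(genome)):
        arr = np.frombuffer(s.encode(), dtype="S1")
        for i in range(len(s) - n - 2):
            if s[i + n + 1 : i + n + 3] == "GG":
                d = int((arr[i : i + n] != pv).sum())
                if d <= 2:
                    counts[d] += 1
    return counts


class TestOffTargets:
    @staticmethod
    def _plant(genome: list, site: str, pos: int):
        genome[pos : pos + len(site)] = list(site)

    def test_planted_guide_is_unique(self):
        rng = np.random.default_rng(SEED)
        genome = list(rng.choice(list("AT"), size=10_000))  # G/C-free background
        guide = "ACGTACGTACGTACGTACG"
        self._plant(genome, guide + "TGG", 4000)
        counts = count_offtargets(guide, "".join(genome))
        assert counts == {0: 1, 1: 0, 2: 0}

    def test_one_mismatch_copy_counted(self):
        rng = np.random.default_rng(SEED + 1)
        genome = list(rng.choice(list("AT"), size=10_000))
        guide = "ACGTACGTACGTACGTACG"
        self._plant(genome, guide + "TGG", 2000)
        variant = "T" + guide[1:]
        self._plant(genome, variant + "AGG", 7000)
        g = "".join(genome)
        counts = count_offtargets(guide, g)
        assert counts == {0: 1, 1: 1, 2: 0}
        assert counts == _hamming_oracle(guide, g)

    def test_empty_genome_all_zero(self):
        assert count_offtargets("ACGTACGTACGTACGTACG", "") == {0: 0, 1: 0, 2: 0}

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_independent_oracle_on_random_genomes(self, seed):
        rng = np.random.default_rng(seed)
        genome = "".join(rng.choice(list("ACGT"), size=3000))
        guide = "".join(rng.choice(list("ACGT"), size=PROTO_LEN))
        assert count_offtargets(guide, genome) == _hamming_oracle(guide, genome)

    def test_multiple_sequences_and_mapping_inputs(self):
        guide = "ACGTACGTACGTACGTACG"
        site = guide + "TGG"
        counts = count_offtargets(guide, {"chr1": site, "chr2": site})
        assert counts[0] == 2


class TestCoordinateRoundTrip:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), length=st.integers(80, 200))
    def test_fasta_round_trip_preserves_candidates(self, tmp_path_factory, seed, length):
        from clonescreen.io import read_fasta, write_fasta

        tmp = tmp_path_factory.mktemp("fa")
        snp = length // 2
        seq, rec = simulate_genome_with_snp(length, snp, seed)
        path = tmp / "w.fa"
        write_fasta({rec["chrom"]: seq}, path)
        back = read_fasta(path)[rec["chrom"]]
        assert back == seq
        assert back[rec["pos"] - 1] == rec["ref"]  # 1-based VCF convention
        assert enumerate_candidates(back, snp) == enumerate_candidates(seq, snp)
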