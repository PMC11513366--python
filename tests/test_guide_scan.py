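"""Guide enumeration and per-guide metrics, checked against brute force."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cas9tiling import (
    CriteriaConfig,
    FixtureSpec,
    GenomicRegion,
    GuideCandidate,
    GuideMetrics,
    PlantedSite,
    SequenceRecord,
    count_offtargets,
    efficiency_score,
    enumerate_candidates,
    gc_percent,
    make_reference,
    passes_criteria,
    revcomp,
    self_complementarity,
)

dna = st.text(alphabet="ACGT", min_size=20, max_size=20)


def brute_force_candidates(seq, offset=0, name="s"):
    """Independent window-by-window PAM scan (no shared code with the scanner)."""
    found = []
    for i in range(len(seq) - 22):
        w = seq[i : i + 23]
        if "N" in w:
            continue
        if w[21:23] == "GG":
            found.append(("+", offset + i, w[:20]))
        if w[0:2] == "CC":
            rc = revcomp(w)
            found.append(("-", offset + i + 3, rc[:20]))
    return sorted(found)


def brute_force_offtargets(protospacer, genome, max_mm=3, exclude=None):
    """Per-window mismatch counting oracle; exclude = (name, start, strand)."""
    counts = [0] * (max_mm + 1)
    for rec in genome:
        seq = rec.sequence
        for i in range(len(seq) - 22):
            w = seq[i : i + 23]
            if w[21:23] == "GG" and (rec.name, i, "+") != (exclude or ()):
                mm = sum(a != b for a, b in zip(w[:20], protospacer))
                if mm <= max_mm:
                    counts[mm] += 1
            if w[0:2] == "CC" and (rec.name, i + 3, "-") != (exclude or ()):
                mm = sum(a != b for a, b in zip(revcomp(w)[:20], protospacer))
                if mm <= max_mm:
                    counts[mm] += 1
    return tuple(counts)


class TestEnumerate:
    def test_single_planted_plus_pam(self):
        ref = SequenceRecord("s", "A" * 20 + "AGG" + "A" * 977)
        cands = [
            c
            for c in enumerate_candidates(ref, GenomicRegion("s", 0, 1000))
            if c.strand == "+"
        ]
        assert len(cands) == 1
        assert cands[0].protospacer == "A" * 20
        assert cands[0].pam == "AGG"
        assert cands[0].protospacer_start == 0
        assert cands[0].cut_pos == 17  # blunt cut between bases 17 and 18

    def test_no_gg_or_cc_yields_nothing(self):
        ref = SequenceRecord("s", "AGAGAGATAT" * 10)
        assert enumerate_candidates(ref, GenomicRegion("s", 0, 100)) == []

    def test_minus_strand_cut_coordinate(self):
        # CC at offset 10 -> minus-strand PAM; cut between +strand bases 15/16
        seq = "T" * 10 + "CCA" + "G" * 2 + "A" * 18 + "T" * 17
        ref = SequenceRecord("s", seq)
        minus = [
            c
            for c in enumerate_candidates(ref, GenomicRegion("s", 0, len(seq)))
            if c.strand == "-" and c.protospacer_start == 13
        ]
        assert len(minus) == 1
        assert minus[0].cut_pos == 16
        assert minus[0].protospacer == revcomp(seq[13:33])

    def test_agrees_with_brute_force_on_random_reference(self):
        ref = make_reference(FixtureSpec(seed=5, length=2000, gc_fraction=0.5))
        region = GenomicRegion(ref.name, 100, 1500)
        got = sorted(
            (c.strand, c.protospacer_start, c.protospacer)
            for c in enumerate_candidates(ref, region)
        )
        assert got == brute_force_candidates(
            ref.sequence[region.start : region.end], offset=region.start
        )

    def test_windows_with_n_are_skipped(self):
        ref = SequenceRecord("s", "A" * 10 + "N" + "A" * 9 + "AGG" + "T" * 977)
        assert enumerate_candidates(ref, GenomicRegion("s", 0, 1000)) == []

    def test_region_outside_reference_rejected(self):
        ref = SequenceRecord("s", "ACGT" * 100)
        with pytest.raises(ValueError):
            enumerate_candidates(ref, GenomicRegion("s", 0, 401))

    @given(st.text(alphabet="ACGT", min_size=30, max_size=80))
    def test_reverse_complement_mirror(self, seq):
        """Scanning the reverse complement swaps strands and mirrors coordinates."""
        n = len(seq)
        fwd = enumerate_candidates(SequenceRecord("s", seq), GenomicRegion("s", 0, n))
        rev = enumerate_candidates(
            SequenceRecord("s", revcomp(seq)), GenomicRegion("s", 0, n)
        )
        flip = {"+": "-", "-": "+"}
        mirrored = sorted(
            (flip[c.strand], n - (c.protospacer_start + 20), c.protospacer)
            for c in fwd
        )
        assert mirrored == sorted(
            (c.strand, c.protospacer_start, c.protospacer) for c in rev
        )


class TestGcPercent:
    @pytest.mark.parametrize(
        "proto,expected",
        [
            ("GTATCAATGTTCTTCCTGGG", 45.0),
            ("CCCGTACGTAAGCATCAGTG", 55.0),
            ("AAAAAAAAAAAAAAAAAAAA", 0.0),
        ],
    )
    def test_worked_examples(self, proto, expected):
        assert gc_percent(proto) == expected

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            gc_percent("ACGT")

    @given(dna)
    def test_complement_identity(self, proto):
        """GC% equals 100*(1 - AT fraction) and is complement-invariant."""
        at = sum(proto.count(b) for b in "AT")
        assert gc_percent(proto) == pytest.approx(100.0 * (1 - at / 20))
        assert gc_percent(revcomp(proto)) == gc_percent(proto)


class TestSelfComplementarity:
    def test_clean_guide_scores_zero(self):
        assert self_complementarity("CCCGTACGTAAGCATCAGTG") == 0

    def test_hairpin_seed_detected(self):
        # AAAA at 0-3 pairs with TTTT at 11-14: loop >= 3
        assert self_complementarity("AAAACGCGCGCTTTTGCATG") >= 1

    def test_short_loop_pairs_not_counted(self):
        # reverse-complement 4-mers closer than 7 positions form no hairpin
        assert self_complementarity("AAAATTTTGAGAGAGAGAGA", backbone="") == 0

    def test_backbone_contribution(self):
        # ACGGACTA reverse-complements into backbone AGGCTAGTCCGT twice
        proto = "ACGGACTAGCATATATATAT"
        only_intra = self_complementarity(proto, backbone="")
        with_backbone = self_complementarity(proto)
        assert with_backbone > only_intra

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            self_complementarity("ACGTACGTACGTACGTACG")

    @given(dna)
    def test_empty_backbone_never_exceeds_default(self, proto):
        assert self_complementarity(proto, backbone="") <= self_complementarity(proto)


class TestEfficiency:
    def test_homopolymer_low_gc_guide(self):
        assert efficiency_score("AAAAAAAAAAAAAAAAAAAA", 0) == pytest.approx(0.15)

    def test_terminal_g_mid_gc_guide(self):
        assert efficiency_score("CCCGTACGTAAGCATCAGTG", 0) == pytest.approx(0.80)

    def test_terminal_t_penalty(self):
        assert efficiency_score("CGAGTACGTAAGCATCAGAT", 0) == pytest.approx(0.5)

    @given(dna, st.integers(min_value=0, max_value=5))
    def test_clamped_to_unit_interval(self, proto, sc):
        assert 0.0 <= efficiency_score(proto, sc) <= 1.0


class TestOfftargets:
    def _candidate(self, proto, name="chrS", start=0, strand="+"):
        return GuideCandidate(proto, "AGG", strand, start, start + 17, name)

    def test_on_target_only_genome_counts_zero(self):
        proto = "GATTACAGATTACAGATTAC"
        ref = make_reference(
            FixtureSpec(seed=2, length=3000, planted_sites=(PlantedSite(proto, "+", 1000),))
        )
        cand = GuideCandidate(proto, ref.sequence[1020:1023], "+", 1000, 1017, ref.name)
        assert count_offtargets(cand, [ref]) == (0, 0, 0, 0)

    def test_planted_exact_copy_is_mm0(self):
        proto = "GATTACAGATTACAGATTAC"
        ref = make_reference(
            FixtureSpec(
                seed=2,
                length=5000,
                planted_sites=(PlantedSite(proto, "+", 1000), PlantedSite(proto, "+", 3000)),
            )
        )
        cand = GuideCandidate(proto, ref.sequence[1020:1023], "+", 1000, 1017, ref.name)
        counts = count_offtargets(cand, [ref])
        assert counts[0] == 1
        assert counts == brute_force_offtargets(proto, [ref], exclude=(ref.name, 1000, "+"))

    def test_planted_reverse_strand_two_mismatch_site(self):
        proto = "GATTACAGATTACAGATTAC"
        ref = make_reference(
            FixtureSpec(
                seed=9,
                length=5000,
                planted_sites=(
                    PlantedSite(proto, "+", 1000),
                    PlantedSite(proto, "-", 3000, n_mismatches=2),
                ),
            )
        )
        cand = GuideCandidate(proto, ref.sequence[1020:1023], "+", 1000, 1017, ref.name)
        counts = count_offtargets(cand, [ref])
        assert counts[2] >= 1
        assert counts == brute_force_offtargets(proto, [ref], exclude=(ref.name, 1000, "+"))

    def test_multi_record_genome_and_synthetic_candidate(self):
        genome = [
            make_reference(FixtureSpec(seed=s, length=2000, gc_fraction=0.5, name=f"c{s}"))
            for s in (1, 2)
        ]
        cand = self._candidate("ACGTACGTACGTACGTACGT", name="elsewhere")
        assert count_offtargets(cand, genome) == brute_force_offtargets(
            "ACGTACGTACGTACGTACGT", genome
        )

    def test_max_mm_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            count_offtargets(self._candidate("A" * 20), [SequenceRecord("s", "ACGT" * 10)], 21)

    @given(st.integers(min_value=0, max_value=10**6))
    def test_matches_brute_force_on_random_genomes(self, seed):
        """Vectorised scan equals the naive oracle, at GC 0.6 where PAMs abound."""
        ref = make_reference(FixtureSpec(seed=seed, length=1500, gc_fraction=0.6))
        cands = enumerate_candidates(ref, GenomicRegion(ref.name, 0, 1500))
        if not cands:
            return
        cand = cands[seed % len(cands)]
        expected = brute_force_offtargets(
            cand.protospacer,
            [ref],
            exclude=(ref.name, cand.protospacer_start, cand.strand),
        )
        assert count_offtargets(cand, [ref]) == expected


class TestCriteria:
    def _metrics(self, gc=45.0, sc=0, mm=(0, 0, 0, 7), eff=0.69):
        return GuideMetrics(gc, sc, mm, eff)

    def test_published_style_row_passes(self):
        assert passes_criteria(self._metrics())

    @pytest.mark.parametrize(
        "metrics",
        [
            {"gc": 25.0},  # GC below 30
            {"gc": 85.0},  # GC above 80
            {"sc": 1},  # self-complementarity must be 0
            {"mm": (0, 0, 5, 5)},  # off-target total 10 fails strict <10
            {"eff": 0.19},  # efficiency below 0.2
        ],
    )
    def test_each_criterion_rejects(self, metrics):
        assert not passes_criteria(self._metrics(**metrics))

    def test_boundary_values_pass(self):
        assert passes_criteria(self._metrics(gc=30.0, eff=0.2, mm=(0, 0, 4, 5)))
        assert passes_criteria(self._metrics(gc=80.0))

    def test_custom_thresholds(self):
        relaxed = CriteriaConfig(max_self_complementarity=2)
        assert passes_criteria(self._metrics(sc=2), relaxed)
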