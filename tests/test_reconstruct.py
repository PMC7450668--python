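"""Candidate reconstruction: chimera geometry, CIGAR rewrite, the
rotation test, and clustering."""

import numpy as np
import pytest

from itdscan.formats_io import AlignmentRecord, parse_cigar, parse_sa_tag, query_length
from itdscan.reconstruct import (
    InsertionContext,
    ItdCandidate,
    classify_insertion,
    cluster_candidates,
    count_mismatches,
    infer_itd_from_chimera,
    insertion_inspector,
    insertion_inspector_oracle,
    left_normalize,
    redefine_cigar_as_insertion,
    rotation_cutoff,
    tag_large_itd,
)
from itdscan.formats_io import extract_chimeric_pairs


def rnd(n, seed=0):
    return "".join(np.random.default_rng(seed).choice(list("ACGT"), size=n))


def chimeric_record(pos, cigar, sa, name="r1", chrom="c"):
    ops = parse_cigar(cigar)
    return AlignmentRecord(
        query_name=name, chrom=chrom, pos=pos, strand="+", mapq=60,
        cigar=ops, seq="A" * query_length(ops), sa_entries=parse_sa_tag(sa),
    )


def infer(rec, **kw):
    (pair,) = extract_chimeric_pairs(rec)
    return infer_itd_from_chimera(pair, **kw)


class TestChimeraGeometry:
    def test_basic_small_event(self):
        # MS prefix maps [110,160), SM suffix maps [100,150), 100 bp read
        rec = chimeric_record(110, "50M50S", "c,101,+,50S50M,60,0;")
        cand = infer(rec, read_length=100)
        assert (cand.start, cand.end, cand.size, cand.event_class) == (100, 160, 60, "small")

    def test_large_event_and_sv_tag(self):
        rec = chimeric_record(1200, "50M50S", "c,1001,+,50S50M,60,0;")
        cand = infer(rec, read_length=100)
        assert (cand.start, cand.end, cand.size, cand.event_class) == (1000, 1250, 250, "large")
        tagged = tag_large_itd(rec, cand)
        assert tagged.tags["SV"] == "TDUP,1001,250"
        # idempotent: tagging twice leaves a single, identical tag
        again = tag_large_itd(tagged, cand)
        assert again.tags == tagged.tags

    def test_zero_offset_is_no_event(self):
        rec = chimeric_record(100, "50M50S", "c,151,+,50S50M,60,0;")
        assert infer(rec, read_length=100) is None

    def test_deletion_like_geometry_is_no_event(self):
        rec = chimeric_record(100, "50M50S", "c,301,+,50S50M,60,0;")
        assert infer(rec, read_length=100) is None

    def test_size_bounds(self):
        rec = chimeric_record(110, "50M50S", "c,101,+,50S50M,60,0;")
        assert infer(rec, read_length=100, min_size=61) is None
        assert infer(rec, read_length=100, max_size=59) is None

    def test_query_overlap_shrinks_size(self):
        # pieces share 5 read bases (junction homology): MS spans query
        # [0,55) -> ref [100,155); SM spans query [50,100) -> ref [95,145)
        rec = chimeric_record(100, "55M45S", "c,96,+,50S50M,60,0;")
        cand = infer(rec, read_length=100)
        assert (cand.start, cand.size) == (95, 55)

    def test_sv_tag_contract(self):
        rec = chimeric_record(110, "50M50S", "c,101,+,50S50M,60,0;")
        small = infer(rec, read_length=100)
        with pytest.raises(ValueError):
            tag_large_itd(rec, small)


class TestCigarRewrite:
    ref = rnd(400, seed=3)

    def mutant_read(self, x, L=100, s=100, e=160):
        mut = self.ref[:e] + self.ref[s:e] + self.ref[e:]
        return mut[x : x + L]

    def candidate(self, s=100, e=160):
        return ItdCandidate(chrom="c", start=s, end=e, event_class="small",
                            supporting_read_names={"r1"})

    def test_rewrite_layout_against_read_construction(self):
        """Brute-force layout oracle: for every junction-spanning read
        of a 60-bp duplication, the rewrite must be aM 60I bM with
        a+60+b == 100, the M blocks reference-concordant, and the
        rewrite must be refused exactly when the read does not span the
        whole segment plus one base on each side."""
        s, e, L = 100, 160, 100
        for x in range(40, 160):  # read start in the mutant genome
            read = self.mutant_read(x, L=L, s=s, e=e)
            a_prefix = e - x  # query offset of the junction
            if not 0 < a_prefix < L:
                continue
            rec = AlignmentRecord(
                query_name="r1", chrom="c", pos=x, strand="+", mapq=60,
                cigar=parse_cigar(f"{a_prefix}M{L - a_prefix}S"), seq=read,
            )
            new = redefine_cigar_as_insertion(rec, self.candidate(s, e))
            spans = a_prefix >= (e - s) + 1 and (L - a_prefix) >= 1
            if not spans:
                assert new.rewrite_refused and new.cigar == rec.cigar
                continue
            kinds = [(op.length, op.kind) for op in new.cigar]
            a = a_prefix - (e - s)
            assert kinds == [(a, "M"), (60, "I"), (L - a_prefix, "M")]
            assert sum(l for l, k in kinds if k in "MI") == L
            assert new.pos == x
            # inserted bases are exactly the duplicated segment
            assert new.seq[a : a + 60] == self.ref[s:e]
            # M blocks match the reference
            assert new.seq[:a] == self.ref[new.pos : new.pos + a]
            assert new.seq[a + 60 :] == self.ref[s : s + (L - a_prefix)]

    def test_rewrite_from_sm_side_record(self):
        s, e, L = 100, 160, 100
        x = 80  # read spans [80, 180) in the mutant: 20 flank + 60 copy + 20
        read = self.mutant_read(x, L=L, s=s, e=e)
        rec = AlignmentRecord(
            query_name="r1", chrom="c", pos=s, strand="+", mapq=60,
            cigar=parse_cigar("80S20M"), seq=read,
        )
        new = redefine_cigar_as_insertion(rec, self.candidate(s, e))
        assert [(op.length, op.kind) for op in new.cigar] == [(20, "M"), (60, "I"), (20, "M")]
        assert new.pos == s - 20

    def test_large_event_rejected(self):
        cand = ItdCandidate(chrom="c", start=0, end=300, event_class="large")
        rec = chimeric_record(0, "50M50S", "c,1,+,50S50M,60,0;")
        with pytest.raises(ValueError):
            redefine_cigar_as_insertion(rec, cand)


class TestCountMismatches:
    @pytest.mark.parametrize("a,b,n", [("ACGT", "ACGT", 0), ("ACGT", "ACGA", 1),
                                       ("ACGT", "TGCA", 4), ("ANGT", "AAGT", 1),
                                       ("NNNN", "NNNN", 4)])
    def test_examples(self, a, b, n):
        assert count_mismatches(a, b) == n

    def test_unequal_lengths(self):
        with pytest.raises(ValueError):
            count_mismatches("AC", "ACG")


def independent_schedule(ctx):
    """Non-incremental recomputation of the rotation schedule the
    stepwise inspector visits (independent oracle for its behavior)."""
    n = len(ctx.seq_ins)
    half = n // 2
    for i in range(1, half + 1):
        rot = ctx.seq_ins[n - i :] + ctx.seq_ins[: n - i]
        win = ctx.seq_l[len(ctx.seq_l) - i :] + ctx.seq_r[: n - i]
        if count_mismatches(rot, win) < ctx.cutoff:
            return True
    for i in range(1, half + 1):
        r = (half - i) % n
        rot = ctx.seq_ins[n - r :] + ctx.seq_ins[: n - r] if r else ctx.seq_ins
        win = ctx.seq_l[len(ctx.seq_l) - (n - i) :] + ctx.seq_r[:i]
        if count_mismatches(rot, win) < ctx.cutoff:
            return True
    return False


class TestInsertionInspector:
    def test_left_aligned_duplication_is_found_at_first_rotation(self):
        # reference TTTTACGTGGGG with ACGT duplicated at [4, 8)
        ctx = InsertionContext(seq_ins="ACGT", seq_l="TTT", seq_r="ACG", cutoff=1)
        assert insertion_inspector(ctx) is True

    def test_length_one_never_a_duplication(self):
        ctx = InsertionContext(seq_ins="A", seq_l="", seq_r="", cutoff=5)
        assert insertion_inspector(ctx) is False
        assert insertion_inspector_oracle(ctx) is False

    def test_agrees_with_independent_schedule_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(2000):
            n = int(rng.integers(2, 25))
            ctx = InsertionContext(
                seq_ins="".join(rng.choice(list("ACGT"), size=n)),
                seq_l="".join(rng.choice(list("ACGT"), size=n - 1)),
                seq_r="".join(rng.choice(list("ACGT"), size=n - 1)),
                cutoff=rotation_cutoff(n),
            )
            assert insertion_inspector(ctx) == independent_schedule(ctx)

    def test_positive_implies_broad_oracle(self):
        rng = np.random.default_rng(23)
        ref = rnd(4000, seed=5)
        for _ in range(300):
            n = int(rng.integers(2, 40))
            s = int(rng.integers(n, 3000))
            ctx = InsertionContext(
                seq_ins=ref[s : s + n],
                seq_l=ref[s - (n - 1) : s],
                seq_r=ref[s : s + n - 1],
                cutoff=rotation_cutoff(n),
            )
            if insertion_inspector(ctx):
                assert insertion_inspector_oracle(ctx)

    def test_random_insertions_mostly_novel(self):
        rng = np.random.default_rng(29)
        hits = 0
        trials = 500
        for _ in range(trials):
            ctx = InsertionContext(
                seq_ins="".join(rng.choice(list("ACGT"), size=20)),
                seq_l="".join(rng.choice(list("ACGT"), size=19)),
                seq_r="".join(rng.choice(list("ACGT"), size=19)),
                cutoff=rotation_cutoff(20),
            )
            hits += insertion_inspector(ctx)
        assert hits / trials < 0.05


class TestClassifyInsertion:
    ref = rnd(600, seed=7)

    def record_with_insertion(self, s, size, flank=20, ins_seq=None):
        ins = ins_seq if ins_seq is not None else self.ref[s : s + size]
        seq = self.ref[s - flank : s] + ins + self.ref[s : s + flank]
        return AlignmentRecord(
            query_name="r", chrom="c", pos=s - flank, strand="+", mapq=60,
            cigar=parse_cigar(f"{flank}M{size}I{flank}M"), seq=seq,
        )

    @pytest.mark.parametrize("size", [2, 3, 5, 10, 25, 60, 120])
    def test_perfect_duplication_detected(self, size):
        rec = self.record_with_insertion(250, size)
        assert classify_insertion(rec, {"c": self.ref}) == "duplication"

    def test_all_n_insertion_is_novel(self):
        rec = self.record_with_insertion(250, 4, ins_seq="NNNN")
        assert classify_insertion(rec, {"c": self.ref}) == "novel"

    def test_single_base_insertion_is_novel(self):
        rec = self.record_with_insertion(250, 1)
        assert classify_insertion(rec, {"c": self.ref}) == "novel"

    def test_contig_edge_is_novel(self):
        rec = self.record_with_insertion(25, 60)
        # left flank of 59 bases does not exist before position 25
        assert classify_insertion(rec, {"c": self.ref}) == "novel"


class TestNormalizeAndCluster:
    def test_left_normalize_shifts_through_homology(self):
        ref = "TTTTACGTGGGG"
        assert left_normalize(ref, 4, 8) == (3, 7)
        assert left_normalize(ref, 8, 10) == (8, 10)

    def cand(self, start, end, names, seed="", cls="small"):
        return ItdCandidate(chrom="c", start=start, end=end, event_class=cls,
                            supporting_read_names=set(names), seed_clip_seq=seed)

    def test_identical_keys_merge(self):
        out = cluster_candidates(
            [self.cand(100, 160, {"a"}, "ACG"), self.cand(100, 160, {"b"}, "ACGTT")],
            min_support=2,
        )
        assert len(out) == 1
        assert out[0].supporting_read_names == {"a", "b"}
        assert out[0].seed_clip_seq == "ACGTT"

    def test_nearby_keys_stay_distinct(self):
        out = cluster_candidates(
            [self.cand(100, 160, {"a", "c"}), self.cand(100, 161, {"b", "d"})],
            min_support=2,
        )
        assert [(c.start, c.end) for c in out] == [(100, 160), (100, 161)]

    def test_support_filter(self):
        assert cluster_candidates([self.cand(100, 160, {"a"})], min_support=2) == []

    def test_supporter_partition_preserved(self):
        rng = np.random.default_rng(4)
        cands = []
        names = set()
        for i in range(50):
            start = int(rng.integers(0, 5)) * 10
            nm = {f"r{i}"}
            names |= nm
            cands.append(self.cand(start, start + 30, nm))
        out = cluster_candidates(cands, min_support=1)
        got = set()
        for c in out:
            assert got.isdisjoint(c.supporting_read_names)
            got |= c.supporting_read_names
        assert got == names
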