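"""Alignment engine vs independent oracles: brute-force MEM enumeration,
exhaustive chain search, and full dynamic-programming identity."""

import itertools

import numpy as np
import pytest

from pseudoref import alignkit, simulate
from pseudoref.alignkit import AlignParams, Anchor, ReferenceIndex
from pseudoref.seqio import revcomp

from conftest import random_seq


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def brute_force_mems(query: str, ref: str, min_len: int) -> set[tuple[int, int, int, str]]:
    """All maximal exact matches by per-diagonal scan, both strands.

    Returns {(q_start, r_start, length, strand)} with query coordinates on
    the oriented query, matching the engine's convention.
    """
    out = set()
    for strand, q in (("+", query), ("-", revcomp(query))):
        n, m = len(q), len(ref)
        for diag in range(-n + 1, m):
            i0 = max(0, -diag)
            j0 = i0 + diag
            run = 0
            for t in range(min(n - i0, m - j0) + 1):
                i, j = i0 + t, j0 + t
                if t < min(n - i0, m - j0) and q[i] == ref[j] and q[i] in "ACGT":
                    run += 1
                else:
                    if run >= min_len:
                        out.add((i - run, j - run, run, strand))
                    run = 0
    return out


def exhaustive_best_chain(anchors: list[Anchor], max_gap: int) -> int:
    """Maximum chain weight over all collinear subsets (exponential search)."""
    best = 0
    n = len(anchors)
    for mask in range(1, 1 << n):
        subset = sorted(
            (anchors[i] for i in range(n) if mask & (1 << i)),
            key=lambda a: (a.q_start, a.r_start),
        )
        ok = True
        for a, b in zip(subset, subset[1:]):
            if not (a.q_start < b.q_start and a.r_start < b.r_start
                    and a.q_end < b.q_end and a.r_end < b.r_end
                    and b.q_start - a.q_end <= max_gap
                    and b.r_start - a.r_end <= max_gap):
                ok = False
                break
        if ok:
            best = max(best, sum(a.length for a in subset))
    return best


def full_dp_identity(a: str, b: str, match=1, mismatch=-1, gap=-2) -> float:
    """Unbanded global alignment; identity = matches / alignment columns."""
    la, lb = len(a), len(b)
    H = np.zeros((la + 1, lb + 1), dtype=np.int64)
    H[:, 0] = np.arange(la + 1) * gap
    H[0, :] = np.arange(lb + 1) * gap
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i, j] = max(H[i - 1, j - 1] + s, H[i - 1, j] + gap, H[i, j - 1] + gap)
    # traceback
    i, j = la, lb
    matches = columns = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch):
            matches += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and H[i, j] == H[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
        columns += 1
    return matches / columns if columns else 0.0


# ---------------------------------------------------------------------------
# MEM finding
# ---------------------------------------------------------------------------

class TestFindAnchors:
    def test_embedded_exact_segment(self):
        rng = np.random.default_rng(0)
        ref = random_seq(rng, 3000)
        contig = ref[1000:1500]
        idx = ReferenceIndex({"c": ref}, k=20)
        anchors = [a for a in alignkit.find_anchors("q", contig, idx) if a.strand == "+"]
        spans = [(a.q_start, a.q_end, a.r_start, a.r_end) for a in anchors]
        assert (0, 500, 1000, 1500) in spans

    def test_point_substitution_splits_anchor(self):
        rng = np.random.default_rng(1)
        ref = random_seq(rng, 3000)
        contig = list(ref[1000:1500])
        old = contig[250]
        contig[250] = "ACGT"[("ACGT".index(old) + 1) % 4]
        contig = "".join(contig)
        idx = ReferenceIndex({"c": ref}, k=20)
        anchors = [a for a in alignkit.find_anchors("q", contig, idx) if a.strand == "+"]
        lens = sorted(a.length for a in anchors if a.r_start >= 990)
        assert 250 in lens and 249 in lens

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_brute_force_enumeration(self, seed):
        """Engine MEMs equal the O(n*m) per-diagonal oracle on random pairs."""
        rng = np.random.default_rng(seed)
        ref = random_seq(rng, 400)
        # make the query a mutated slice so real MEMs exist
        q = list(ref[50:350])
        for p in rng.integers(0, len(q), 6):
            q[p] = "ACGT"[("ACGT".index(q[p]) + 1) % 4]
        q = "".join(q)
        idx = ReferenceIndex({"c": ref}, k=13, max_occ=10_000)
        got = {
            (a.q_start, a.r_start, a.length, a.strand)
            for a in alignkit.find_anchors("q", q, idx, min_len=13)
        }
        assert got == brute_force_mems(q, ref, 13)

    def test_empty_and_short_queries(self):
        idx = ReferenceIndex({"c": "ACGTACGTACGTACGTACGTACGT"}, k=12)
        assert alignkit.find_anchors("q", "", idx) == []
        assert alignkit.find_anchors("q", "ACGT", idx) == []

    def test_min_len_below_k_rejected(self):
        idx = ReferenceIndex({"c": "A" * 100}, k=20)
        with pytest.raises(ValueError):
            alignkit.find_anchors("q", "A" * 30, idx, min_len=12)


# ---------------------------------------------------------------------------
# Chaining
# ---------------------------------------------------------------------------

class TestChainAnchors:
    def _anchor(self, qs, qe, rs, re, strand="+", chrom="c"):
        return Anchor("q", qs, qe, chrom, rs, re, strand)

    def test_single_anchor_single_chain(self):
        a = self._anchor(0, 100, 0, 100)
        chains = alignkit.chain_anchors([a], min_chain_weight=1)
        assert chains == [[a]]

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_exhaustive_search(self, seed):
        """DP chain weight equals exponential search over all collinear subsets."""
        rng = np.random.default_rng(seed)
        anchors = []
        for _ in range(12):
            qs = int(rng.integers(0, 900))
            rs = int(rng.integers(0, 900))
            ln = int(rng.integers(15, 60))
            anchors.append(self._anchor(qs, qs + ln, rs, rs + ln))
        chains = alignkit.chain_anchors(anchors, max_chain_gap=300, min_chain_weight=1,
                                        max_candidates=1)
        got = sum(a.length for a in chains[0])
        assert got == exhaustive_best_chain(anchors, max_gap=300)

    def test_deletion_signature_splits_blocks_not_candidates(self):
        """Anchors 4 kb apart on the reference, adjacent on the query, stay in
        one candidate but produce two blocks."""
        rng = np.random.default_rng(3)
        left, right = random_seq(rng, 600), random_seq(rng, 600)
        ref = random_seq(rng, 500) + left + random_seq(rng, 4000) + right + random_seq(rng, 500)
        contig = left + right
        idx = ReferenceIndex({"c": ref}, k=20)
        cands = alignkit.align_query("q", contig, idx, AlignParams(max_join_gap=1000))
        assert len(cands) == 1
        assert len(cands[0].blocks) == 2
        b1, b2 = cands[0].blocks
        assert b2.r_start - b1.r_end == 4000
        assert b2.q_start - b1.q_end == 0

    def test_no_anchor_in_two_chains(self):
        rng = np.random.default_rng(9)
        anchors = []
        for _ in range(20):
            qs = int(rng.integers(0, 500))
            rs = int(rng.integers(0, 500))
            ln = int(rng.integers(15, 40))
            anchors.append(self._anchor(qs, qs + ln, rs, rs + ln))
        chains = alignkit.chain_anchors(anchors, min_chain_weight=1, max_candidates=4)
        seen = set()
        for ch in chains:
            for a in ch:
                key = id(a)
                assert key not in seen
                seen.add(key)


# ---------------------------------------------------------------------------
# Extension / identity
# ---------------------------------------------------------------------------

class TestExtendAndScore:
    def test_perfect_chain_identity_one(self):
        rng = np.random.default_rng(4)
        ref = random_seq(rng, 2000)
        contig = ref[500:1500]
        idx = ReferenceIndex({"c": ref}, k=20)
        cands = alignkit.align_query("q", contig, idx)
        assert cands[0].identity == 1.0
        assert cands[0].coverage == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_identity_matches_full_dp(self, seed):
        """Segment identity equals the unbanded-DP oracle on <=500 bp pairs."""
        rng = np.random.default_rng(seed + 100)
        ref = random_seq(rng, 1500)
        q = list(ref[200:700])
        for p in rng.choice(len(q), size=10, replace=False):
            q[p] = "ACGT"[("ACGT".index(q[p]) + int(rng.integers(1, 4))) % 4]
        q = "".join(q)
        idx = ReferenceIndex({"c": ref}, k=20)
        cands = alignkit.align_query("q", q, idx)
        got = cands[0].identity
        # the oracle aligns exactly the aligned span of the candidate
        b0, b1 = cands[0].blocks[0], cands[0].blocks[-1]
        expect = full_dp_identity(q[b0.q_start : b1.q_end], ref[b0.r_start : b1.r_end])
        assert got == pytest.approx(expect, abs=1e-9)

    def test_one_sided_gap_adds_gap_columns(self):
        """A query-only segment between anchors adds gap columns, no matches."""
        rng = np.random.default_rng(12)
        left, right = random_seq(rng, 400), random_seq(rng, 400)
        ref = left + right
        contig = left + random_seq(rng, 60) + right  # 60 bp donor-only
        idx = ReferenceIndex({"c": ref}, k=20)
        cands = alignkit.align_query("q", contig, idx)
        b = cands[0].blocks[0]
        assert b.aln_columns == b.matches + 60

    def test_strand_symmetry(self):
        """Aligning the reverse complement mirrors coordinates, same identity."""
        rng = np.random.default_rng(6)
        ref = random_seq(rng, 3000)
        q = list(ref[800:1800])
        for p in rng.choice(len(q), size=8, replace=False):
            q[p] = "ACGT"[("ACGT".index(q[p]) + 1) % 4]
        q = "".join(q)
        idx = ReferenceIndex({"c": ref}, k=20)
        fwd = alignkit.align_query("q", q, idx)[0]
        rev = alignkit.align_query("q", revcomp(q), idx)[0]
        assert fwd.strand == "+" and rev.strand == "-"
        assert fwd.identity == rev.identity
        assert (fwd.r_start, fwd.r_end) == (rev.r_start, rev.r_end)
        assert fwd.blocks[0].q_forward() == (
            len(q) - rev.blocks[-1].q_end, len(q) - rev.blocks[-1].q_start,
        )[::1] or fwd.blocks[0].q_forward() == rev.blocks[0].q_forward()


# ---------------------------------------------------------------------------
# Placement filtering
# ---------------------------------------------------------------------------

def _mock_candidate(cid, score, r_start, r_end, identity=1.0, coverage=1.0, chrom="c"):
    cols = score
    matches = int(round(identity * cols))
    qlen = int(round(score / coverage))
    block = alignkit.AlignmentBlock(
        contig_id=cid, q_start=0, q_end=score, r_chrom=chrom, r_start=r_start,
        r_end=r_end, strand="+", matches=matches, aln_columns=cols, contig_len=qlen,
    )
    return alignkit.PlacementCandidate(cid, chrom, "+", [block], qlen)


class TestFilterPlacements:
    def test_identity_below_threshold_rejected(self):
        c = _mock_candidate("a", 1000, 0, 1000, identity=0.89, coverage=0.95)
        accepted, rejected = alignkit.filter_placements([c])
        assert accepted == [] and rejected == [c]

    def test_perfect_unique_accepted(self):
        c = _mock_candidate("a", 1000, 0, 1000)
        accepted, _ = alignkit.filter_placements([c])
        assert accepted == [c]

    def test_coverage_boundary(self):
        low = _mock_candidate("a", 790, 0, 790, coverage=0.79)
        ok = _mock_candidate("b", 800, 2000, 2800, coverage=0.80)
        accepted, _ = alignkit.filter_placements([low, ok])
        assert [c.contig_id for c in accepted] == ["b"]

    def test_best_of_two_disjoint_candidates_wins(self):
        big = _mock_candidate("a", 100, 0, 100)
        small = _mock_candidate("a", 40, 5000, 5040, coverage=0.4)
        accepted, rejected = alignkit.filter_placements([small, big])
        assert accepted == [big] and small in rejected

    def test_ambiguous_contig_rejected(self):
        c1 = _mock_candidate("a", 1000, 0, 1000)
        c2 = _mock_candidate("a", 980, 50_000, 51_000)  # within 5%, distinct locus
        accepted, _ = alignkit.filter_placements([c1, c2])
        assert accepted == []

    def test_tandem_shifted_self_alignment_not_ambiguous(self):
        c1 = _mock_candidate("a", 1000, 0, 1000)
        c2 = _mock_candidate("a", 980, 350, 1350)  # same locus, unit-shifted
        accepted, _ = alignkit.filter_placements([c1, c2])
        assert accepted == [c1]

    def test_reference_interval_claimed_once(self):
        c1 = _mock_candidate("a", 1000, 0, 1000)
        c2 = _mock_candidate("b", 900, 500, 1400)  # overlaps a's span by 500
        accepted, rejected = alignkit.filter_placements([c1, c2])
        assert accepted == [c1] and c2 in rejected


class TestRecoveryOnSimulatedData:
    def test_contigs_accepted_at_true_locus(self):
        """>=95% of error-free contigs >=5 kb are accepted within +-50 bp of truth."""
        p = simulate.SimParams(ref_length=500_000, seed=13)
        ref, tracts = simulate.generate_reference(p)
        donor, truth = simulate.mutate_reference(ref, p, tracts)
        contigs, placements = simulate.shear_contigs(donor, p, truth)
        accepted, _ = alignkit.align_contigs(
            {c: s for c, s in contigs.items() if len(s) >= 5000}, ref
        )
        truth_by_id = {pl.contig_id: pl for pl in placements}
        eligible = [c for c, s in contigs.items() if len(s) >= 5000]
        good = 0
        for cand in accepted:
            pl = truth_by_id[cand.contig_id]
            if cand.r_chrom == pl.chrom and abs(cand.r_start - pl.ref_start) <= 50:
                good += 1
        assert good / len(eligible) >= 0.95
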