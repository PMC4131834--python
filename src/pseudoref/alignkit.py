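"""Anchor-based whole-genome alignment of contigs against a reference.

The engine follows the classic seed-chain-extend design: maximal exact
matches (MEMs) found through a sorted k-mer index seed the search, a
maximum-weight collinear chain is selected per contig x chromosome x strand
by dynamic programming, inter-anchor segments are closed by global alignment,
and candidates are filtered on identity/coverage thresholds with one-to-one
tiling on both the query and the reference.

Coordinates: 0-based half-open.  Anchor and block query coordinates are on
the *oriented* query (the reverse complement for minus-strand hits), so that
query and reference positions increase together within a chain; helpers
convert back to forward-contig coordinates where needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import revcomp

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i


def encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class AlignParams:
    min_anchor_len: int = 20
    max_occ: int = 64
    max_join_gap: int = 90       # larger same-side gaps split alignment blocks
    max_chain_gap: int = 100_000
    min_chain_weight: int = 50
    max_candidates: int = 4
    match: int = 1
    mismatch: int = -1
    gap: int = -2
    xdrop_mismatch: int = -3
    xdrop: int = 8
    min_identity: float = 0.90
    min_coverage: float = 0.80
    ambiguity_margin: float = 0.05
    tiling_overlap_tol: int = 100

    def __post_init__(self) -> None:
        if self.min_anchor_len < 12:
            raise ValueError("min_anchor_len must be >= 12")


@dataclass
class Anchor:
    contig_id: str
    q_start: int
    q_end: int
    r_chrom: str
    r_start: int
    r_end: int
    strand: str

    @property
    def length(self) -> int:
        return self.q_end - self.q_start


@dataclass
class AlignmentBlock:
    contig_id: str
    q_start: int
    q_end: int
    r_chrom: str
    r_start: int
    r_end: int
    strand: str
    matches: int
    aln_columns: int
    contig_len: int
    mismatches: list[tuple[int, str, str]] = field(default_factory=list)

    @property
    def identity(self) -> float:
        return self.matches / self.aln_columns if self.aln_columns else 0.0

    def q_forward(self) -> tuple[int, int]:
        """Block query interval in forward-contig coordinates."""
        if self.strand == "+":
            return self.q_start, self.q_end
        return self.contig_len - self.q_end, self.contig_len - self.q_start


@dataclass
class PlacementCandidate:
    contig_id: str
    r_chrom: str
    strand: str
    blocks: list[AlignmentBlock]
    contig_len: int

    @property
    def coverage(self) -> float:
        return sum(b.q_end - b.q_start for b in self.blocks) / self.contig_len

    @property
    def identity(self) -> float:
        cols = sum(b.aln_columns for b in self.blocks)
        return sum(b.matches for b in self.blocks) / cols if cols else 0.0

    @property
    def score(self) -> int:
        return sum(b.matches for b in self.blocks)

    @property
    def r_start(self) -> int:
        return self.blocks[0].r_start

    @property
    def r_end(self) -> int:
        return self.blocks[-1].r_end


# ---------------------------------------------------------------------------
# Reference k-mer index and MEM finding
# ---------------------------------------------------------------------------

class ReferenceIndex:
    """Sorted k-mer index over a genome for exact-match seeding."""

    def __init__(self, genome: dict[str, str], k: int = 20, max_occ: int = 64):
        if not (0 < k <= 31):
            raise ValueError("k must be in 1..31")
        self.genome = genome
        self.k = k
        self.max_occ = max_occ
        self.names = list(genome)
        self.offsets = np.zeros(len(self.names) + 1, dtype=np.int64)
        parts = []
        for i, name in enumerate(self.names):
            arr = encode(genome[name])
            parts.append(arr)
            self.offsets[i + 1] = self.offsets[i] + len(arr)
        self.cat = np.concatenate(parts) if parts else np.zeros(0, dtype=np.uint8)
        self._build()

    def _build(self) -> None:
        n, k = len(self.cat), self.k
        if n < k:
            self.sorted_codes = np.zeros(0, dtype=np.uint64)
            self.order = np.zeros(0, dtype=np.int64)
            return
        codes = _kmer_codes(self.cat, k)
        # windows containing N or crossing a chromosome boundary are invalid
        invalid = _invalid_windows(self.cat, k, self.offsets)
        valid = ~invalid
        pos = np.flatnonzero(valid).astype(np.int64)
        codes = codes[valid]
        order = np.argsort(codes, kind="stable")
        self.sorted_codes = codes[order]
        self.order = pos[order]

    def chrom_of(self, gpos: int) -> int:
        return int(np.searchsorted(self.offsets, gpos, side="right") - 1)

    def lookup(self, qcodes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (query_positions, global_ref_positions) for all k-mer hits."""
        lo = np.searchsorted(self.sorted_codes, qcodes, side="left")
        hi = np.searchsorted(self.sorted_codes, qcodes, side="right")
        counts = hi - lo
        keep = (counts > 0) & (counts <= self.max_occ)
        qpos = np.flatnonzero(keep)
        lo, counts = lo[keep], counts[keep]
        if len(qpos) == 0:
            return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
        qrep = np.repeat(qpos, counts)
        idx = np.repeat(lo, counts) + _ragged_arange(counts)
        return qrep.astype(np.int64), self.order[idx]


def _kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    n = len(arr)
    codes = np.zeros(n - k + 1, dtype=np.uint64)
    a = arr.astype(np.uint64)
    for i in range(k):
        codes = (codes << np.uint64(2)) | (a[i : n - k + 1 + i] & np.uint64(3))
    return codes


def _invalid_windows(arr: np.ndarray, k: int, offsets: np.ndarray) -> np.ndarray:
    n = len(arr)
    bad = (arr > 3).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(bad)])
    has_n = (cs[k:] - cs[: n - k + 1]) > 0
    invalid = has_n
    starts = np.arange(n - k + 1)
    for off in offsets[1:-1]:
        invalid = invalid | ((starts > off - k) & (starts < off))
    return invalid


def _ragged_arange(counts: np.ndarray) -> np.ndarray:
    total = int(counts.sum())
    out = np.ones(total, dtype=np.int64)
    out[0] = 0
    ends = np.cumsum(counts)[:-1]
    out[ends] = -(counts[:-1] - 1)
    return np.cumsum(out)


def find_anchors(
    contig_id: str,
    seq: str,
    index: ReferenceIndex,
    min_len: int | None = None,
    both_strands: bool = True,
) -> list[Anchor]:
    """All maximal exact matches of length >= min_len between query and genome.

    min_len defaults to the index k; it may exceed k (shorter MEMs are
    filtered) but not undercut it, since a MEM shorter than k has no seed.
    """
    min_len = index.k if min_len is None else min_len
    if min_len < index.k:
        raise ValueError("min_len below index k would miss matches")
    anchors: list[Anchor] = []
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        oriented = seq if strand == "+" else revcomp(seq)
        anchors.extend(_strand_anchors(contig_id, oriented, strand, index, min_len))
    return anchors


def _strand_anchors(
    contig_id: str, oriented: str, strand: str, index: ReferenceIndex, min_len: int
) -> list[Anchor]:
    k = index.k
    qarr = encode(oriented)
    n = len(qarr)
    if n < k:
        return []
    qcodes = _kmer_codes(qarr, k)
    qvalid = ~_invalid_windows(qarr, k, np.array([0, n]))
    qcodes = np.where(qvalid, qcodes, np.uint64(0xFFFFFFFFFFFFFFFF))
    qpos, gpos = index.lookup(qcodes)
    # drop hits whose query window was invalid (sentinel collisions are absent
    # for k<=31 since the sentinel is not a valid 2-bit code for k<32)
    keep = qvalid[qpos]
    qpos, gpos = qpos[keep], gpos[keep]
    if len(qpos) == 0:
        return []
    diag = gpos - qpos
    order = np.lexsort((qpos, diag))
    qpos, gpos, diag = qpos[order], gpos[order], diag[order]
    new_run = np.ones(len(qpos), dtype=bool)
    if len(qpos) > 1:
        new_run[1:] = (np.diff(diag) != 0) | (np.diff(qpos) > k)
    starts = np.flatnonzero(new_run)
    ends = np.append(starts[1:], len(qpos))
    cat = index.cat
    seen: set[tuple[int, int]] = set()
    out: list[Anchor] = []
    for s, e in zip(starts, ends):
        q0 = int(qpos[s])
        g0 = int(gpos[s])
        q1 = int(qpos[e - 1]) + k
        ci = index.chrom_of(g0)
        c_lo, c_hi = int(index.offsets[ci]), int(index.offsets[ci + 1])
        g1 = g0 + (q1 - q0)
        # extend to true maximality (seeds may be missing under max_occ)
        while q0 > 0 and g0 > c_lo and qarr[q0 - 1] == cat[g0 - 1] and qarr[q0 - 1] < 4:
            q0 -= 1
            g0 -= 1
        while q1 < n and g1 < c_hi and qarr[q1] == cat[g1] and qarr[q1] < 4:
            q1 += 1
            g1 += 1
        if q1 - q0 < min_len:
            continue
        key = (int(diag[s]), q0)
        if key in seen:
            continue
        seen.add(key)
        out.append(
            Anchor(
                contig_id=contig_id,
                q_start=q0,
                q_end=q1,
                r_chrom=index.names[ci],
                r_start=g0 - c_lo,
                r_end=g1 - c_lo,
                strand=strand,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Collinear chaining
# ---------------------------------------------------------------------------

def chain_anchors(
    anchors: list[Anchor],
    max_chain_gap: int = 100_000,
    min_chain_weight: int = 50,
    max_candidates: int = 4,
) -> list[list[Anchor]]:
    """Partition anchors into maximum-weight collinear chains.

    Within each (chromosome, strand) group the heaviest chain (sum of anchor
    lengths; starts and ends strictly increasing in both query and reference,
    same-coordinate gaps bounded by ``max_chain_gap``) is peeled off
    repeatedly.  Chains from all groups are pooled and the heaviest
    ``max_candidates`` returned; no anchor appears in two chains.
    """
    groups: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        groups.setdefault((a.r_chrom, a.strand), []).append(a)
    chains: list[list[Anchor]] = []
    for group in groups.values():
        remaining = group
        for _ in range(max_candidates):
            if not remaining:
                break
            chain, remaining = _best_chain(remaining, max_chain_gap)
            if sum(a.length for a in chain) < max(min_chain_weight, 1):
                break
            chains.append(chain)
    chains.sort(key=lambda c: -sum(a.length for a in c))
    return chains[:max_candidates]


def _best_chain(anchors: list[Anchor], max_gap: int) -> tuple[list[Anchor], list[Anchor]]:
    anchors = sorted(anchors, key=lambda a: (a.q_start, a.r_start))
    n = len(anchors)
    qs = np.array([a.q_start for a in anchors])
    qe = np.array([a.q_end for a in anchors])
    rs = np.array([a.r_start for a in anchors])
    re_ = np.array([a.r_end for a in anchors])
    w = qe - qs
    dp = w.astype(np.int64).copy()
    back = np.full(n, -1)
    for i in range(1, n):
        ok = (
            (qs[:i] < qs[i])
            & (rs[:i] < rs[i])
            & (qe[:i] < qe[i])
            & (re_[:i] < re_[i])
            & (qs[i] - qe[:i] <= max_gap)
            & (rs[i] - re_[:i] <= max_gap)
        )
        if ok.any():
            cand = np.where(ok, dp[:i], np.int64(-1))
            j = int(np.argmax(cand))
            if cand[j] >= 0:
                dp[i] = cand[j] + w[i]
                back[i] = j
    best = int(np.argmax(dp))
    chain_idx = []
    i = best
    while i != -1:
        chain_idx.append(i)
        i = int(back[i])
    chain_idx.reverse()
    in_chain = set(chain_idx)
    chain = [anchors[i] for i in chain_idx]
    rest = [a for i, a in enumerate(anchors) if i not in in_chain]
    return chain, rest


# ---------------------------------------------------------------------------
# Gap closing: global alignment of inter-anchor segments
# ---------------------------------------------------------------------------

def global_align(
    a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2
) -> tuple[int, int, list[tuple[int, int]]]:
    """Needleman-Wunsch with linear gaps.

    Returns (matches, alignment_columns, substitution_columns) where
    substitution columns are (i, j) index pairs into a and b at which the
    aligned bases differ.
    """
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return 0, la + lb, []
    H = [[0] * (lb + 1) for _ in range(la + 1)]
    P = [[0] * (lb + 1) for _ in range(la + 1)]  # 0 diag, 1 up(del in b), 2 left
    for i in range(1, la + 1):
        H[i][0] = i * gap
        P[i][0] = 1
    for j in range(1, lb + 1):
        H[0][j] = j * gap
        P[0][j] = 2
    for i in range(1, la + 1):
        ai = a[i - 1]
        Hi, Hi1, Pi = H[i], H[i - 1], P[i]
        for j in range(1, lb + 1):
            d = Hi1[j - 1] + (match if ai == b[j - 1] and ai != "N" else mismatch)
            u = Hi1[j] + gap
            l = Hi[j - 1] + gap
            if d >= u and d >= l:
                Hi[j], Pi[j] = d, 0
            elif u >= l:
                Hi[j], Pi[j] = u, 1
            else:
                Hi[j], Pi[j] = l, 2
    matches = 0
    columns = 0
    subs: list[tuple[int, int]] = []
    i, j = la, lb
    while i > 0 or j > 0:
        p = P[i][j]
        columns += 1
        if p == 0:
            i -= 1
            j -= 1
            if a[i] == b[j] and a[i] != "N":
                matches += 1
            else:
                subs.append((i, j))
        elif p == 1:
            i -= 1
        else:
            j -= 1
    return matches, columns, subs


def _xdrop_extend(
    qarr: str,
    rarr: str,
    q0: int,
    r0: int,
    limit: int,
    forward: bool,
    match: int = 1,
    mismatch: int = -3,
    drop: int = 8,
) -> tuple[int, int, list[tuple[int, int]]]:
    """Greedy diagonal extension with an X-drop stop.

    Returns (steps, matches, substitution (q,r) index pairs) for the
    best-scoring prefix of the extension.
    """
    best = score = best_t = 0
    matches = 0
    best_matches = 0
    subs: list[tuple[int, int]] = []
    best_subs: list[tuple[int, int]] = []
    for t in range(limit):
        qi = q0 + t if forward else q0 - 1 - t
        ri = r0 + t if forward else r0 - 1 - t
        qa, ra = qarr[qi], rarr[ri]
        if qa == ra and qa != "N":
            score += match
            matches += 1
        else:
            score += mismatch
            subs.append((qi, ri))
        if score > best:
            best, best_t = score, t + 1
            best_matches = matches
            best_subs = list(subs)
        elif best - score > drop:
            break
    return best_t, best_matches, best_subs


def extend_and_score(
    chain: list[Anchor],
    oriented_seq: str,
    ref_seq: str,
    contig_len: int,
    params: AlignParams,
) -> list[AlignmentBlock]:
    """Close inter-anchor gaps and emit scored alignment blocks.

    Consecutive anchors with a query or reference gap above
    ``params.max_join_gap`` start a new block; smaller gaps are closed by
    global alignment.  Block edges facing an inter-block junction are then
    refined by X-drop extension so that an isolated substitution near a
    breakpoint does not leave an unaligned sliver.
    """
    if not chain:
        return []
    chain = _trim_overlaps(chain)
    groups: list[list[Anchor]] = [[chain[0]]]
    for a in chain[1:]:
        prev = groups[-1][-1]
        if (a.q_start - prev.q_end > params.max_join_gap) or (
            a.r_start - prev.r_end > params.max_join_gap
        ):
            groups.append([a])
        else:
            groups[-1].append(a)
    blocks: list[AlignmentBlock] = []
    for grp in groups:
        matches = sum(a.length for a in grp)
        columns = matches
        mms: list[tuple[int, str, str]] = []
        for prev, nxt in zip(grp, grp[1:]):
            qseg = oriented_seq[prev.q_end : nxt.q_start]
            rseg = ref_seq[prev.r_end : nxt.r_start]
            if len(qseg) == 1 and len(rseg) == 1:
                m, cols, subs = (
                    (1, 1, []) if qseg == rseg and qseg != "N" else (0, 1, [(0, 0)])
                )
            else:
                m, cols, subs = global_align(qseg, rseg, params.match, params.mismatch, params.gap)
            matches += m
            columns += cols
            for qi, rj in subs:
                r_pos = prev.r_end + rj
                mms.append((r_pos, ref_seq[r_pos], oriented_seq[prev.q_end + qi]))
        blocks.append(
            AlignmentBlock(
                contig_id=grp[0].contig_id,
                q_start=grp[0].q_start,
                q_end=grp[-1].q_end,
                r_chrom=grp[0].r_chrom,
                r_start=grp[0].r_start,
                r_end=grp[-1].r_end,
                strand=grp[0].strand,
                matches=matches,
                aln_columns=columns,
                contig_len=contig_len,
                mismatches=mms,
            )
        )
    _refine_junctions(blocks, oriented_seq, ref_seq, params)
    return blocks


def _trim_overlaps(chain: list[Anchor]) -> list[Anchor]:
    out = [chain[0]]
    for a in chain[1:]:
        prev = out[-1]
        d = max(prev.q_end - a.q_start, prev.r_end - a.r_start, 0)
        if d > 0:
            a = Anchor(
                a.contig_id, a.q_start + d, a.q_end, a.r_chrom, a.r_start + d, a.r_end, a.strand
            )
            if a.length <= 0:
                continue
        out.append(a)
    return out


def _refine_junctions(
    blocks: list[AlignmentBlock], oriented_seq: str, ref_seq: str, params: AlignParams
) -> None:
    for left, right in zip(blocks, blocks[1:]):
        qgap = right.q_start - left.q_end
        rgap = right.r_start - left.r_end
        limit = min(qgap, rgap)
        if limit > 0:
            t, m, subs = _xdrop_extend(
                oriented_seq, ref_seq, left.q_end, left.r_end, limit,
                True, params.match, params.xdrop_mismatch, params.xdrop,
            )
            if t > 0:
                for qi, ri in subs:
                    left.mismatches.append((ri, ref_seq[ri], oriented_seq[qi]))
                left.q_end += t
                left.r_end += t
                left.matches += m
                left.aln_columns += t
                qgap -= t
                rgap -= t
        limit = min(qgap, rgap)
        if limit > 0:
            t, m, subs = _xdrop_extend(
                oriented_seq, ref_seq, right.q_start, right.r_start, limit,
                False, params.match, params.xdrop_mismatch, params.xdrop,
            )
            if t > 0:
                for qi, ri in subs:
                    right.mismatches.append((ri, ref_seq[ri], oriented_seq[qi]))
                right.q_start -= t
                right.r_start -= t
                right.matches += m
                right.aln_columns += t


# ---------------------------------------------------------------------------
# Query -> candidate pipeline and placement filtering
# ---------------------------------------------------------------------------

def align_query(
    query_id: str,
    seq: str,
    index: ReferenceIndex,
    params: AlignParams | None = None,
) -> list[PlacementCandidate]:
    """Seed, chain and extend one query; returns unfiltered candidates."""
    params = params or AlignParams()
    anchors = find_anchors(query_id, seq, index, min_len=max(params.min_anchor_len, index.k))
    chains = chain_anchors(
        anchors, params.max_chain_gap, params.min_chain_weight, params.max_candidates
    )
    cands: list[PlacementCandidate] = []
    for chain in chains:
        strand = chain[0].strand
        oriented = seq if strand == "+" else revcomp(seq)
        blocks = extend_and_score(
            chain, oriented, index.genome[chain[0].r_chrom], len(seq), params
        )
        if blocks:
            cands.append(
                PlacementCandidate(
                    contig_id=query_id,
                    r_chrom=chain[0].r_chrom,
                    strand=strand,
                    blocks=blocks,
                    contig_len=len(seq),
                )
            )
    cands.sort(key=lambda c: -c.score)
    return cands


def same_locus(a: PlacementCandidate, b: PlacementCandidate, min_overlap_frac: float = 0.5) -> bool:
    """Two candidates share a locus when their reference spans overlap by at
    least half of the shorter span.  Shifted self-alignments inside tandem
    repeats land on the same locus and must not be read as ambiguity."""
    if a.r_chrom != b.r_chrom:
        return False
    ov = min(a.r_end, b.r_end) - max(a.r_start, b.r_start)
    shorter = max(1, min(a.r_end - a.r_start, b.r_end - b.r_start))
    return ov >= min_overlap_frac * shorter


def filter_placements(
    candidates: list[PlacementCandidate],
    min_identity: float = 0.90,
    min_coverage: float = 0.80,
    ambiguity_margin: float = 0.05,
    overlap_tol: int = 100,
) -> tuple[list[PlacementCandidate], list[PlacementCandidate]]:
    """Threshold filter plus one-to-one tiling.

    A candidate passes if weighted identity >= min_identity and query
    coverage >= min_coverage.  A contig whose two best candidates at
    distinct loci score within ``ambiguity_margin`` of each other is
    rejected as non-unique.  Surviving best-per-contig candidates are then
    tiled greedily by score so no reference interval (beyond
    ``overlap_tol`` bp of slack) is claimed twice.
    """
    from intervaltree import IntervalTree

    by_contig: dict[str, list[PlacementCandidate]] = {}
    for c in candidates:
        by_contig.setdefault(c.contig_id, []).append(c)
    winners: list[PlacementCandidate] = []
    rejected: list[PlacementCandidate] = []
    for cands in by_contig.values():
        cands = sorted(cands, key=lambda c: -c.score)
        passing = [c for c in cands if c.identity >= min_identity and c.coverage >= min_coverage]
        if not passing:
            rejected.extend(cands)
            continue
        top = passing[0]
        runner_up = next((c for c in cands if c is not top and not same_locus(c, top)), None)
        if runner_up is not None and runner_up.score >= (1 - ambiguity_margin) * top.score:
            rejected.extend(cands)  # ambiguous: two near-equal homes
            continue
        winners.append(top)
        rejected.extend(c for c in cands if c is not top)
    winners.sort(key=lambda c: -c.score)
    claimed: dict[str, IntervalTree] = {}
    accepted: list[PlacementCandidate] = []
    for c in winners:
        tree = claimed.setdefault(c.r_chrom, IntervalTree())
        overlap = sum(
            min(iv.end, c.r_end) - max(iv.begin, c.r_start)
            for iv in tree.overlap(c.r_start, c.r_end)
        )
        if overlap > overlap_tol:
            rejected.append(c)
            continue
        if c.r_end > c.r_start:
            tree.addi(c.r_start, c.r_end)
        accepted.append(c)
    return accepted, rejected


def align_contigs(
    contigs: dict[str, str],
    ref: dict[str, str],
    params: AlignParams | None = None,
    min_contig_len: int = 500,
    index: ReferenceIndex | None = None,
) -> tuple[list[PlacementCandidate], list[PlacementCandidate]]:
    """Align every contig of at least ``min_contig_len`` bp and filter."""
    params = params or AlignParams()
    if index is None:
        index = ReferenceIndex(ref, k=params.min_anchor_len, max_occ=params.max_occ)
    all_cands: list[PlacementCandidate] = []
    for cid, seq in contigs.items():
        if len(seq) < min_contig_len:
            continue
        all_cands.extend(align_query(cid, seq, index, params))
    return filter_placements(
        all_cands,
        params.min_identity,
        params.min_coverage,
        params.ambiguity_margin,
        params.tiling_overlap_tol,
    )


# ---------------------------------------------------------------------------
# Light-weight read mapper (for BES reads and mapping-rate reports)
# ---------------------------------------------------------------------------

def map_reads(
    reads: list[tuple[str, str, str]],
    index: ReferenceIndex,
    sam_path: str,
    min_weight_frac: float = 0.9,
    ambiguity_margin: float = 0.05,
) -> None:
    """Map short reads by seeding and chaining; write a SAM file.

    A read is reported uniquely (MAPQ 60) when its best chain covers
    ``min_weight_frac`` of the read length in exact-match anchors and the runner-up chain scores
    below ``1 - ambiguity_margin`` of it; an ambiguous read gets MAPQ 0 and a
    secondary record at the runner-up locus.
    """
    import pysam

    from .seqio import sam_header

    header = sam_header({n: len(s) for n, s in index.genome.items()})
    with pysam.AlignmentFile(sam_path, "w", header=dict(header)) as out:
        for rid, seq, qual in reads:
            anchors = find_anchors(rid, seq, index, min_len=index.k)
            chains = chain_anchors(anchors, max_chain_gap=1000, min_chain_weight=index.k, max_candidates=3)
            weights = [sum(a.length for a in c) for c in chains]
            if not chains or weights[0] < min_weight_frac * len(seq):
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = rid
                rec.is_unmapped = True
                rec.query_sequence = seq
                rec.query_qualities = pysam.qualitystring_to_array(qual)
                out.write(rec)
                continue
            unique = len(chains) == 1 or weights[1] < (1 - ambiguity_margin) * weights[0]
            _write_chain_record(out, rid, seq, qual, chains[0], index, 60 if unique else 0, False)
            if not unique:
                _write_chain_record(out, rid, seq, qual, chains[1], index, 0, True)


def _write_chain_record(out, rid, seq, qual, chain, index, mapq, secondary) -> None:
    import pysam

    a0 = chain[0]
    strand = a0.strand
    oriented = seq if strand == "+" else revcomp(seq)
    oq = qual if strand == "+" else qual[::-1]
    L = len(seq)
    chrom_len = len(index.genome[a0.r_chrom])
    pos0 = a0.r_start - a0.q_start
    left_clip = max(0, -pos0)
    pos = pos0 + left_clip
    right_clip = max(0, pos + (L - left_clip) - chrom_len)
    mlen = L - left_clip - right_clip
    if mlen <= 0:
        return
    cigar = []
    if left_clip:
        cigar.append((4, left_clip))
    cigar.append((0, mlen))
    if right_clip:
        cigar.append((4, right_clip))
    rec = pysam.AlignedSegment(out.header)
    rec.query_name = rid
    rec.reference_id = out.header.references.index(a0.r_chrom)
    rec.reference_start = pos
    rec.mapping_quality = mapq
    rec.cigartuples = cigar
    rec.is_reverse = strand == "-"
    rec.is_secondary = secondary
    rec.query_sequence = oriented
    rec.query_qualities = pysam.qualitystring_to_array(oq)
    out.write(rec)
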