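"""Inter-genome SNP and large-indel calling from split contig alignments.

SNPs are the substitution columns of accepted one-to-one alignment blocks.
Large indels come from the junctions between consecutive blocks of one
placement: a query-side gap >= 100 bp with a near-zero reference gap is an
insertion in the donor; a reference-side gap of 100-50,000 bp with a
near-zero query gap is a deletion; both require >= 200 aligned bp on each
flank.  Junctions with large gaps on both sides are classified COMPLEX and
excluded from the insertion/deletion counts.  Breakpoints can be validated
against read alignments on the donor contigs: each breakpoint must be
crossed by at least five reads and straddled by at least one read pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .alignkit import PlacementCandidate

logger = logging.getLogger(__name__)


@dataclass
class SNPCall:
    r_chrom: str
    r_pos: int
    ref_base: str
    alt_base: str
    contig_id: str
    location_class: str = ""


@dataclass
class LargeIndelCall:
    r_chrom: str
    r_pos: int
    type: str            # INS or DEL (COMPLEX calls are reported separately)
    size: int
    left_flank: int      # aligned bp
    right_flank: int
    contig_id: str
    contig_break_left: int   # forward-contig coordinate of the junction
    contig_break_right: int
    sequence: str = ""   # inserted sequence (INS)
    validated: bool = False
    support_reads: int = 0
    validation_flag: str = ""


@dataclass
class VariantSummary:
    per_chrom: pd.DataFrame
    total_snps: int
    total_indels: int
    aligned_bp: int
    snp_frequency_pct: float
    n_ins: int
    n_del: int
    ins_bp: int
    del_bp: int
    mean_indel_len: int


# ---------------------------------------------------------------------------
# SNPs
# ---------------------------------------------------------------------------

def call_snps(
    placements: Sequence[PlacementCandidate],
) -> tuple[list[SNPCall], int]:
    """Collect substitution columns from one-to-one placements.

    Returns the SNP list and the total number of reference columns compared
    (the aligned length over which the SNP frequency is computed).
    Ambiguous (N) columns were already excluded during alignment scoring.
    """
    snps: list[SNPCall] = []
    aligned_bp = 0
    for cand in placements:
        if not cand.blocks:
            raise ValueError(f"placement for {cand.contig_id} has no blocks")
        for b in cand.blocks:
            aligned_bp += b.r_end - b.r_start
            for r_pos, ref_base, alt_base in b.mismatches:
                if ref_base in "ACGT" and alt_base in "ACGT" and ref_base != alt_base:
                    snps.append(SNPCall(b.r_chrom, r_pos, ref_base, alt_base, cand.contig_id))
    snps.sort(key=lambda s: (s.r_chrom, s.r_pos))
    return snps, aligned_bp


# ---------------------------------------------------------------------------
# Large indels from block junctions
# ---------------------------------------------------------------------------

def _junctions(cand: PlacementCandidate):
    for left, right in zip(cand.blocks, cand.blocks[1:]):
        qgap = right.q_start - left.q_end
        rgap = right.r_start - left.r_end
        yield left, right, qgap, rgap


def _forward_break(cand: PlacementCandidate, q_oriented: int) -> int:
    if cand.strand == "+":
        return q_oriented
    return cand.contig_len - q_oriented


def classify_insertions(
    placements: Sequence[PlacementCandidate],
    contigs: dict[str, str] | None = None,
    min_unaligned: int = 100,
    min_flank: int = 200,
    other_gap_tol: int = 10,
) -> list[LargeIndelCall]:
    """Donor insertions: unaligned query fragments between aligned flanks.

    A junction is an insertion when the query gap is >= ``min_unaligned``,
    the reference gap is <= ``other_gap_tol``, and both flanking blocks have
    at least ``min_flank`` aligned bp.  Contig-terminal unaligned tails are
    never called.
    """
    out: list[LargeIndelCall] = []
    for cand in placements:
        for left, right, qgap, rgap in _junctions(cand):
            if qgap < min_unaligned or rgap > other_gap_tol:
                continue
            if left.aln_columns < min_flank or right.aln_columns < min_flank:
                continue
            seq = ""
            if contigs is not None:
                oriented = contigs[cand.contig_id]
                if cand.strand == "-":
                    from .seqio import revcomp

                    oriented = revcomp(oriented)
                seq = oriented[left.q_end : right.q_start]
            out.append(
                LargeIndelCall(
                    r_chrom=left.r_chrom,
                    r_pos=left.r_end,
                    type="INS",
                    size=qgap,
                    left_flank=left.aln_columns,
                    right_flank=right.aln_columns,
                    contig_id=cand.contig_id,
                    contig_break_left=min(
                        _forward_break(cand, left.q_end), _forward_break(cand, right.q_start)
                    ),
                    contig_break_right=max(
                        _forward_break(cand, left.q_end), _forward_break(cand, right.q_start)
                    ),
                    sequence=seq,
                )
            )
    out.sort(key=lambda v: (v.r_chrom, v.r_pos))
    return out


def classify_deletions(
    placements: Sequence[PlacementCandidate],
    min_size: int = 100,
    max_size: int = 50_000,
    min_flank: int = 200,
    other_gap_tol: int = 10,
) -> tuple[list[LargeIndelCall], list[LargeIndelCall]]:
    """Donor deletions: gapped alignments of ``min_size``..``max_size`` bp.

    A junction is a deletion when the reference gap falls in the size window
    and the query gap is <= ``other_gap_tol``, with both flanks >=
    ``min_flank`` aligned bp.  Junctions where both gaps are >=
    ``min_size`` are returned separately as COMPLEX and excluded from
    deletion counts.
    """
    dels: list[LargeIndelCall] = []
    complexes: list[LargeIndelCall] = []
    for cand in placements:
        for left, right, qgap, rgap in _junctions(cand):
            if left.aln_columns < min_flank or right.aln_columns < min_flank:
                continue
            if rgap >= min_size and qgap >= min_size:
                complexes.append(
                    LargeIndelCall(
                        r_chrom=left.r_chrom, r_pos=left.r_end, type="COMPLEX", size=rgap,
                        left_flank=left.aln_columns, right_flank=right.aln_columns,
                        contig_id=cand.contig_id,
                        contig_break_left=_forward_break(cand, min(left.q_end, right.q_start)),
                        contig_break_right=_forward_break(cand, max(left.q_end, right.q_start)),
                    )
                )
                continue
            if not (min_size <= rgap <= max_size) or qgap > other_gap_tol:
                continue
            bp = _forward_break(cand, left.q_end)
            dels.append(
                LargeIndelCall(
                    r_chrom=left.r_chrom,
                    r_pos=left.r_end,
                    type="DEL",
                    size=rgap,
                    left_flank=left.aln_columns,
                    right_flank=right.aln_columns,
                    contig_id=cand.contig_id,
                    contig_break_left=bp,
                    contig_break_right=bp,
                )
            )
    dels.sort(key=lambda v: (v.r_chrom, v.r_pos))
    return dels, complexes


# ---------------------------------------------------------------------------
# Breakpoint validation against read alignments
# ---------------------------------------------------------------------------

def validate_boundaries(
    indels: list[LargeIndelCall],
    sam_path: str | Path,
    min_span_reads: int = 5,
) -> list[LargeIndelCall]:
    """Flag indels whose breakpoints are supported by read alignments.

    An indel is validated when each of its contig-coordinate breakpoints is
    crossed by at least ``min_span_reads`` read alignments and at least one
    properly paired fragment straddles the whole event.  Calls failing the
    check are kept but flagged (NO_DATA when no read covers the region).
    """
    by_contig: dict[str, list[LargeIndelCall]] = {}
    for v in indels:
        by_contig.setdefault(v.contig_id, []).append(v)
    spans: dict[str, list[tuple[int, int]]] = {c: [] for c in by_contig}
    frags: dict[str, list[tuple[int, int]]] = {c: [] for c in by_contig}
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            cid = rec.reference_name
            if cid not in spans:
                continue
            spans[cid].append((rec.reference_start, rec.reference_end))
            if rec.is_proper_pair and rec.template_length > 0:
                frags[cid].append((rec.reference_start, rec.reference_start + rec.template_length))
    for cid, calls in by_contig.items():
        read_iv = spans[cid]
        frag_iv = frags[cid]
        for v in calls:
            bps = sorted({v.contig_break_left, v.contig_break_right})
            cover = [sum(1 for s, e in read_iv if s < bp < e) for bp in bps]
            v.support_reads = min(cover) if cover else 0
            if all(c == 0 for c in cover):
                v.validation_flag = "NO_DATA"
                v.validated = False
                continue
            crossed = all(c >= min_span_reads for c in cover)
            straddled = any(
                s < v.contig_break_left and v.contig_break_right < e for s, e in frag_iv
            )
            v.validated = bool(crossed and straddled)
            v.validation_flag = "" if v.validated else "LOW_SUPPORT"
    return indels


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def snp_frequency_pct(total_snps: int, aligned_bp: int) -> float:
    """SNP sites over aligned length, as a percentage with two decimals."""
    return round(100.0 * total_snps / aligned_bp, 2) if aligned_bp else 0.0


def mean_indel_len(total_indel_bp: float, n_sites: int) -> int:
    """Total indel nucleotides over indel sites, rounded to integer bp."""
    return int(round(total_indel_bp / n_sites)) if n_sites else 0

def summarize_variants(
    snps: Sequence[SNPCall],
    indels: Sequence[LargeIndelCall],
    aligned_bp: int,
    chroms: Sequence[str],
) -> VariantSummary:
    """Per-chromosome counts, totals, SNP frequency and mean indel length.

    The SNP frequency is total SNPs over aligned reference columns, as a
    percentage with two decimals; the mean indel length is total indel
    nucleotides over indel sites, rounded to integer bp.
    """
    snp_counts = {c: 0 for c in chroms}
    indel_counts = {c: 0 for c in chroms}
    for s in snps:
        snp_counts[s.r_chrom] = snp_counts.get(s.r_chrom, 0) + 1
    ins_bp = del_bp = n_ins = n_del = 0
    for v in indels:
        if v.type == "COMPLEX":
            continue
        indel_counts[v.r_chrom] = indel_counts.get(v.r_chrom, 0) + 1
        if v.type == "INS":
            n_ins += 1
            ins_bp += v.size
        else:
            n_del += 1
            del_bp += v.size
    per_chrom = pd.DataFrame(
        {
            "chrom": list(chroms),
            "snps": [snp_counts[c] for c in chroms],
            "large_indels": [indel_counts[c] for c in chroms],
        }
    )
    total_snps = int(per_chrom["snps"].sum())
    total_indels = int(per_chrom["large_indels"].sum())
    freq = snp_frequency_pct(total_snps, aligned_bp)
    mean_len = mean_indel_len(ins_bp + del_bp, n_ins + n_del)
    return VariantSummary(
        per_chrom=per_chrom,
        total_snps=total_snps,
        total_indels=total_indels,
        aligned_bp=aligned_bp,
        snp_frequency_pct=freq,
        n_ins=n_ins,
        n_del=n_del,
        ins_bp=ins_bp,
        del_bp=del_bp,
        mean_indel_len=mean_len,
    )


def write_bed(indels: Sequence[LargeIndelCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        for v in sorted(indels, key=lambda v: (v.r_chrom, v.r_pos)):
            end = v.r_pos + (v.size if v.type == "DEL" else 1)
            fh.write(f"{v.r_chrom}\t{v.r_pos}\t{end}\t{v.type}_{v.size}\n")
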