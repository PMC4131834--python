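"""Pileup-based contig error correction.

Reads aligned to draft contigs are tallied into per-position pileup columns;
a position is corrected when the majority non-contig allele is effectively
homozygous: frequency >= 70% of quality-filtered coverage, depth >= 10, and
a Phred-scaled consensus quality >= 30.  The procedure runs for a fixed
number of rounds (two by default) with round r+1 operating on the output of
round r.

The consensus quality is a deliberately simple monotone surrogate for a full
genotype-likelihood model: min(999, sum of supporting base qualities minus
sum of conflicting base qualities).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

_ALLELES = "ACGT"
_DEL = 4  # deletion allele index in the tally


@dataclass
class CorrectionRule:
    min_qual: int = 30
    min_depth: int = 10
    min_freq: float = 0.70
    rounds: int = 2
    min_map_qual: int = 20
    min_base_qual: int = 20

    def __post_init__(self) -> None:
        if not 0 < self.min_freq <= 1:
            raise ValueError("min_freq must be in (0, 1]")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")


@dataclass
class ContigPileup:
    """Dense pileup over one contig: allele counts and quality sums."""

    contig_id: str
    counts: np.ndarray     # (5, L) A C G T del
    qual_sum: np.ndarray   # (5, L)
    insertions: dict[int, dict[str, list[int]]] = field(default_factory=dict)
    # insertions[pos][seq] -> [count, qual_sum]; inserted before contig pos

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass
class Correction:
    contig_id: str
    pos: int
    kind: str        # SUB, DEL or INS
    old: str
    new: str
    qual: int
    freq: float
    depth: int
    round: int = 0


def build_pileup(
    sam_path: str | Path,
    contigs: dict[str, str],
    rule: CorrectionRule,
) -> dict[str, ContigPileup]:
    """Tally base/deletion/insertion observations per contig position.

    Unmapped, secondary, supplementary and duplicate-flagged records are
    skipped, as are reads below ``min_map_qual`` and bases below
    ``min_base_qual``.
    """
    piles = {
        cid: ContigPileup(
            cid,
            np.zeros((5, len(seq)), dtype=np.int32),
            np.zeros((5, len(seq)), dtype=np.int64),
        )
        for cid, seq in contigs.items()
    }
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
        lut[b + 32] = i
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.is_duplicate:
                continue
            if rec.mapping_quality < rule.min_map_qual:
                continue
            cid = rec.reference_name
            pile = piles.get(cid)
            if pile is None:
                continue
            L = pile.counts.shape[1]
            seq = rec.query_sequence
            quals = rec.query_qualities
            if seq is None or quals is None:
                continue
            rpos = rec.reference_start
            qpos = 0
            if rpos < 0 or rec.reference_end is not None and rec.reference_end > L:
                logger.warning("record %s overflows contig %s; skipped", rec.query_name, cid)
                continue
            for op, ln in rec.cigartuples:
                if op in (0, 7, 8):  # M/=/X
                    sub = np.frombuffer(seq[qpos : qpos + ln].encode(), dtype=np.uint8)
                    codes = lut[sub]
                    q = np.asarray(quals[qpos : qpos + ln], dtype=np.int64)
                    ok = (codes >= 0) & (q >= rule.min_base_qual)
                    idx = np.flatnonzero(ok)
                    np.add.at(pile.counts, (codes[idx], rpos + idx), 1)
                    np.add.at(pile.qual_sum, (codes[idx], rpos + idx), q[idx])
                    rpos += ln
                    qpos += ln
                elif op == 2:  # D: deletion allele over the gap
                    q = quals[qpos - 1] if qpos > 0 else 30
                    if q >= rule.min_base_qual:
                        pile.counts[_DEL, rpos : rpos + ln] += 1
                        pile.qual_sum[_DEL, rpos : rpos + ln] += int(q)
                    rpos += ln
                elif op == 1:  # I: inserted sequence before rpos
                    ins = seq[qpos : qpos + ln].upper()
                    q = int(np.mean(quals[qpos : qpos + ln]))
                    if q >= rule.min_base_qual:
                        slot = pile.insertions.setdefault(rpos, {}).setdefault(ins, [0, 0])
                        slot[0] += 1
                        slot[1] += q * ln
                    qpos += ln
                elif op == 4:  # S
                    qpos += ln
                elif op == 3:  # N
                    rpos += ln
                elif op == 5 or op == 6:  # H/P
                    pass
    return piles


def call_corrections(
    piles: dict[str, ContigPileup],
    contigs: dict[str, str],
    rule: CorrectionRule,
) -> list[Correction]:
    """Emit a correction wherever the majority non-contig allele passes the rule."""
    out: list[Correction] = []
    for cid, pile in piles.items():
        seq = contigs[cid]
        depth = pile.depth
        candidates = np.flatnonzero(depth >= rule.min_depth)
        if len(candidates):
            top = pile.counts[:, candidates].argmax(axis=0)
            for pos, allele in zip(candidates, top):
                pos = int(pos)
                allele = int(allele)
                old = seq[pos].upper()
                allele_sym = "ACGT-"[allele]
                if allele_sym == old:
                    continue
                cnt = int(pile.counts[allele, pos])
                d = int(depth[pos])
                freq = cnt / d
                if freq < rule.min_freq:
                    continue
                # exact 50/50 two-allele tie: no call
                others = np.delete(pile.counts[:, pos], allele)
                if cnt == others.max() and freq == 0.5:
                    continue
                qual = int(pile.qual_sum[allele, pos] - (pile.qual_sum[:, pos].sum() - pile.qual_sum[allele, pos]))
                qual = min(999, qual)
                if qual < rule.min_qual:
                    continue
                kind = "DEL" if allele == _DEL else "SUB"
                out.append(
                    Correction(cid, pos, kind, old, "" if kind == "DEL" else allele_sym,
                               qual, freq, d)
                )
        for pos, obs in pile.insertions.items():
            d = int(depth[pos]) if pos < len(seq) else int(depth[-1])
            if d < rule.min_depth:
                continue
            # most frequent inserted sequence; ties broken lexicographically
            best = sorted(obs.items(), key=lambda kv: (-kv[1][0], kv[0]))[0]
            ins_seq, (cnt, qsum) = best
            freq = cnt / d
            if freq < rule.min_freq:
                continue
            qual = min(999, qsum // max(1, len(ins_seq)))
            if qual < rule.min_qual:
                continue
            out.append(Correction(cid, int(pos), "INS", "", ins_seq, qual, freq, d))
    out.sort(key=lambda c: (c.contig_id, c.pos))
    return out


def apply_corrections(contigs: dict[str, str], corrections: list[Correction]) -> dict[str, str]:
    by_contig: dict[str, list[Correction]] = {}
    for c in corrections:
        by_contig.setdefault(c.contig_id, []).append(c)
    out = dict(contigs)
    for cid, corrs in by_contig.items():
        seq = list(out[cid])
        # apply right-to-left so indels do not shift later coordinates
        for c in sorted(corrs, key=lambda c: -c.pos):
            if c.kind == "SUB":
                seq[c.pos] = c.new
            elif c.kind == "DEL":
                del seq[c.pos]
            else:
                seq.insert(c.pos, c.new)
        out[cid] = "".join(seq)
    return out


def polish_contigs(
    contigs: dict[str, str],
    alignments: str | Path | Callable[[dict[str, str]], str | Path],
    rule: CorrectionRule | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Run the full multi-round correction procedure.

    ``alignments`` is either a SAM path (reused every round; valid as long
    as corrections are substitutions, which keep coordinates fixed) or a
    callable mapping the current contigs to a fresh SAM path per round.
    Returns the corrected contigs and a log with one row per applied
    correction, tagged by round; rounds that find nothing still appear in
    the log's round accounting (see the ``round`` column plus attrs).
    """
    rule = rule or CorrectionRule()
    current = dict(contigs)
    rows: list[Correction] = []
    rounds_run = 0
    indel_applied = False
    for rnd in range(1, rule.rounds + 1):
        sam_path = alignments(current) if callable(alignments) else alignments
        if indel_applied and not callable(alignments):
            logger.warning(
                "static SAM after indel corrections: coordinates downstream of the "
                "indel are not re-examined in round %d", rnd
            )
        piles = build_pileup(sam_path, current, rule)
        if all(p.depth.sum() == 0 for p in piles.values()):
            logger.warning("round %d: empty alignment set, zero corrections", rnd)
        corrections = call_corrections(piles, current, rule)
        for c in corrections:
            c.round = rnd
            if c.kind != "SUB":
                indel_applied = True
        current = apply_corrections(current, corrections)
        rows.extend(corrections)
        rounds_run += 1
    log = pd.DataFrame(
        [
            dict(round=c.round, contig_id=c.contig_id, pos=c.pos, kind=c.kind,
                 old=c.old, new=c.new, qual=c.qual, freq=c.freq, depth=c.depth)
            for c in rows
        ],
        columns=["round", "contig_id", "pos", "kind", "old", "new", "qual", "freq", "depth"],
    )
    log.attrs["rounds_run"] = rounds_run
    return current, log
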