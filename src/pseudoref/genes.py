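"""Gene-level comparative analysis.

Covers four questions asked of a donor genome against an annotated reference:
which reference genes are covered by aligned donor sequence (presence/absence
via an exon-coverage threshold), what effect each inter-genome SNP has on a
gene model (with nonsense and splice-site changes flagged as harmful), which
donor transcripts have no credible home on the reference, and how absence
calls distribute across chromosomes and donors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .seqio import revcomp

# Standard genetic code, written out so effect classification does not share a
# code path with the translation libraries used as oracles in the test suite.
_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
CODON_TABLE = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}

HARMFUL_CATEGORIES = {"nonsense", "splice_site"}


@dataclass
class GeneModel:
    """One transcript model: sorted, non-overlapping exons with a CDS inside.

    All intervals are 0-based half-open on the forward reference strand;
    ``strand`` says which strand is coding.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if c < b:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exon_bp(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(b, c) for (a, b), (c, d) in zip(self.exons, self.exons[1:])]

    def coding_sequence(self, genome: dict[str, str]) -> str:
        seq = "".join(genome[self.chrom][a:b] for a, b in self.cds)
        return revcomp(seq) if self.strand == "-" else seq


@dataclass
class GeneCoverage:
    gene_id: str
    exon_bp: int
    covered_bp: int
    coverage_fraction: float
    present: bool


@dataclass
class SNPEffect:
    r_chrom: str
    r_pos: int
    ref_base: str
    alt_base: str
    gene_id: str | None
    category: str
    harmful: bool


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            fh.write(
                f"{g.chrom}\t.\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\t.\tmRNA\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.transcript_id};Parent={g.gene_id}\n"
            )
            for a, b in g.exons:
                fh.write(
                    f"{g.chrom}\t.\texon\t{a + 1}\t{b}\t.\t{g.strand}\t.\tParent={g.transcript_id}\n"
                )
            phase = 0
            cds = g.cds if g.strand == "+" else list(reversed(g.cds))
            rows = []
            for a, b in cds:
                rows.append((a, b, phase))
                phase = (3 - ((b - a) - phase) % 3) % 3
            for a, b, ph in sorted(rows):
                fh.write(
                    f"{g.chrom}\t.\tCDS\t{a + 1}\t{b}\t.\t{g.strand}\t{ph}\tParent={g.transcript_id}\n"
                )


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from the GFF3 subset this package writes."""
    meta: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "mRNA":
                tid = fields["ID"]
                meta[tid] = dict(
                    gene_id=fields.get("Parent", tid),
                    chrom=chrom,
                    strand=strand,
                    exons=[],
                    cds=[],
                )
                order.append(tid)
            elif ftype in ("exon", "CDS"):
                tid = fields["Parent"]
                key = "exons" if ftype == "exon" else "cds"
                meta[tid][key].append((int(start) - 1, int(end)))
    return [
        GeneModel(
            gene_id=m["gene_id"],
            transcript_id=tid,
            chrom=m["chrom"],
            strand=m["strand"],
            exons=m["exons"],
            cds=m["cds"],
        )
        for tid, m in ((t, meta[t]) for t in order)
    ]


# ---------------------------------------------------------------------------
# Exon coverage / presence-absence
# ---------------------------------------------------------------------------

def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def _intersection_bp(sorted_a: list[tuple[int, int]], sorted_b: list[tuple[int, int]]) -> int:
    total = 0
    i = j = 0
    while i < len(sorted_a) and j < len(sorted_b):
        lo = max(sorted_a[i][0], sorted_b[j][0])
        hi = min(sorted_a[i][1], sorted_b[j][1])
        if lo < hi:
            total += hi - lo
        if sorted_a[i][1] < sorted_b[j][1]:
            i += 1
        else:
            j += 1
    return total


def exon_coverage(
    genes: Sequence[GeneModel],
    aligned_intervals: dict[str, list[tuple[int, int]]],
    absent_threshold: float = 0.05,
    per_gene: bool = True,
) -> list[GeneCoverage]:
    """Fraction of each model's exon bases covered by reference-aligned blocks.

    ``aligned_intervals`` maps chromosome -> reference intervals covered by
    accepted alignment blocks.  A model with coverage below
    ``absent_threshold`` is called absent in the donor.  With ``per_gene``
    (default) multi-transcript genes are reduced to one record per gene by
    taking the best-covered transcript; otherwise one record per transcript is
    returned under its transcript_id.
    """
    merged = {c: _merge_intervals(iv) for c, iv in aligned_intervals.items()}
    records: list[GeneCoverage] = []
    for g in genes:
        if g.chrom not in merged:
            continue
        covered = _intersection_bp(g.exons, merged[g.chrom])
        frac = covered / g.exon_bp if g.exon_bp else 0.0
        records.append(
            GeneCoverage(
                gene_id=g.gene_id if per_gene else g.transcript_id,
                exon_bp=g.exon_bp,
                covered_bp=covered,
                coverage_fraction=frac,
                present=frac >= absent_threshold,
            )
        )
    if per_gene:
        best: dict[str, GeneCoverage] = {}
        order: list[str] = []
        for r in records:
            if r.gene_id not in best:
                order.append(r.gene_id)
                best[r.gene_id] = r
            elif r.coverage_fraction > best[r.gene_id].coverage_fraction:
                best[r.gene_id] = r
        records = [best[g] for g in order]
    return records


# ---------------------------------------------------------------------------
# SNP effect classification
# ---------------------------------------------------------------------------

def _classify_cds_snp(gene: GeneModel, pos: int, alt: str, genome: dict[str, str]) -> str:
    cds_seq = gene.coding_sequence(genome)
    if len(cds_seq) % 3 != 0 or len(cds_seq) < 6:
        return "UNKNOWN"
    # index of pos within the spliced CDS, in coding orientation
    offset = 0
    idx = None
    for a, b in gene.cds:
        if a <= pos < b:
            idx = offset + (pos - a)
            break
        offset += b - a
    if idx is None:
        return "UNKNOWN"
    if gene.strand == "-":
        idx = len(cds_seq) - 1 - idx
        alt = revcomp(alt)
    codon_i = idx // 3
    codon = cds_seq[codon_i * 3 : codon_i * 3 + 3]
    new_codon = codon[: idx % 3] + alt + codon[idx % 3 + 1 :]
    old_aa = CODON_TABLE.get(codon)
    new_aa = CODON_TABLE.get(new_codon)
    if old_aa is None or new_aa is None:
        return "UNKNOWN"
    if codon_i == 0 and codon == "ATG" and new_codon != "ATG":
        return "start_loss"
    if old_aa != "*" and new_aa == "*":
        return "nonsense"
    if old_aa == "*" and new_aa != "*":
        return "stop_loss"
    return "synonymous" if old_aa == new_aa else "missense"


def classify_snp_effects(snps, genes: Sequence[GeneModel], genome: dict[str, str]) -> list[SNPEffect]:
    """Assign each SNP a positional/functional category against gene models.

    Positional classes (intergenic, intron, UTRs) come from interval lookups;
    CDS SNPs are translated in frame on the coding strand; splice-site means a
    change within the first or last 2 bases of an intron (the GT..AG motif).
    A SNP hitting several transcripts takes the most severe category
    (splice_site/nonsense > start_loss/stop_loss > missense > UTR > synonymous
    > intron).
    """
    severity = {
        "nonsense": 0,
        "splice_site": 0,
        "start_loss": 1,
        "stop_loss": 1,
        "missense": 2,
        "5'UTR": 3,
        "3'UTR": 3,
        "synonymous": 4,
        "intron": 5,
        "UNKNOWN": 6,
    }
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: g.span)

    out: list[SNPEffect] = []
    for s in snps:
        chrom, pos, alt = s.r_chrom, s.r_pos, s.alt_base
        hits: list[tuple[str, str]] = []  # (category, gene_id)
        for g in by_chrom.get(chrom, []):
            lo, hi = g.span
            if not (lo <= pos < hi):
                continue
            category = None
            for a, b in g.introns:
                if a <= pos < b:
                    category = "splice_site" if (pos - a < 2 or b - pos <= 2) else "intron"
                    break
            if category is None:
                in_cds = any(a <= pos < b for a, b in g.cds)
                if in_cds:
                    category = _classify_cds_snp(g, pos, alt, genome)
                else:
                    cds_lo, cds_hi = g.cds[0][0], g.cds[-1][1]
                    if pos < cds_lo:
                        category = "5'UTR" if g.strand == "+" else "3'UTR"
                    else:
                        category = "3'UTR" if g.strand == "+" else "5'UTR"
            hits.append((category, g.gene_id))
        if not hits:
            cat, gid = "intergenic", None
        else:
            cat, gid = min(hits, key=lambda h: severity.get(h[0], 9))
        out.append(
            SNPEffect(
                r_chrom=chrom,
                r_pos=pos,
                ref_base=s.ref_base,
                alt_base=s.alt_base,
                gene_id=gid,
                category=cat,
                harmful=cat in HARMFUL_CATEGORIES,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Transcript uniqueness
# ---------------------------------------------------------------------------

def transcript_uniqueness(
    transcripts: dict[str, str],
    genome: dict[str, str],
    min_identity: float = 0.90,
    min_coverage: float = 0.70,
    unique_max_coverage: float = 0.50,
    index=None,
) -> dict[str, str]:
    """Classify each transcript as mapped / unmapped / unique on a genome.

    A transcript maps if its best alignment reaches both identity and
    coverage thresholds; an unmapped transcript whose best coverage stays
    below ``unique_max_coverage`` is donor-unique (no credible partial home).
    Alignment blocks split at reference gaps above 60 bp so that introns
    (>= ~67 bp in rice annotation) delimit exon blocks rather than being
    charged as gap columns against identity.
    """
    from . import alignkit

    params = alignkit.AlignParams(max_join_gap=60)
    if index is None:
        index = alignkit.ReferenceIndex(genome)
    out: dict[str, str] = {}
    for tid, seq in transcripts.items():
        cands = alignkit.align_query(tid, seq, index, params)
        best_cov = 0.0
        mapped = False
        for c in cands:
            best_cov = max(best_cov, c.coverage)
            if c.identity >= min_identity and c.coverage >= min_coverage:
                mapped = True
        if mapped:
            out[tid] = "mapped"
        elif best_cov < unique_max_coverage:
            out[tid] = "unique"
        else:
            out[tid] = "unmapped"
    return out


# ---------------------------------------------------------------------------
# Presence matrix across donors
# ---------------------------------------------------------------------------

def presence_matrix(
    coverages: dict[str, Sequence[GeneCoverage]],
    genes: Sequence[GeneModel],
    chrom_lengths: dict[str, int],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x donor presence table plus absent-gene density per chromosome.

    Returns (matrix, density) where ``matrix`` has one boolean column per
    donor and ``density`` reports absent genes per Mb by chromosome, counting
    a gene absent when it is absent in at least one donor.
    """
    matrix = pd.DataFrame(
        {
            donor: pd.Series({r.gene_id: r.present for r in recs})
            for donor, recs in coverages.items()
        }
    )
    gene_chrom = {}
    for g in genes:
        gene_chrom.setdefault(g.gene_id, g.chrom)
    absent_any = ~matrix.all(axis=1)
    counts = {c: 0 for c in chrom_lengths}
    for gid, absent in absent_any.items():
        if absent and gene_chrom.get(gid) in counts:
            counts[gene_chrom[gid]] += 1
    density = pd.DataFrame(
        {
            "chrom": list(chrom_lengths),
            "absent_genes": [counts[c] for c in chrom_lengths],
            "length_mb": [chrom_lengths[c] / 1e6 for c in chrom_lengths],
        }
    )
    density["absent_per_mb"] = density["absent_genes"] / density["length_mb"]
    return matrix, density
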