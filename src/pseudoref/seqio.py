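"""Readers and writers for the interchange formats used across the package.

Genomes are held in memory as plain ``dict[str, str]`` (uppercase A/C/G/T/N),
with 0-based half-open coordinates everywhere internally.  1-based coordinates
appear only in emitted VCF/GFF3/AGP records, per those standards.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in genome.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")  # 60-column wrap


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """Write (read_id, sequence, quality-string) triples as Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    out = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            out.append((header.strip()[1:].split()[0], seq, qual))
    return out


# ---------------------------------------------------------------------------
# SAM (via pysam; text SAM only, subset of flags/CIGAR ops)
# ---------------------------------------------------------------------------

def sam_header(ref_lengths: dict[str, int]) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in ref_lengths.items()],
    }


# ---------------------------------------------------------------------------
# AGP v2.0
# ---------------------------------------------------------------------------

@dataclass
class AgpRow:
    object: str
    obj_start: int  # 1-based inclusive
    obj_end: int
    part_number: int
    component_type: str  # W, N or U
    # W rows:
    component_id: str = ""
    comp_start: int = 0
    comp_end: int = 0
    orientation: str = "+"
    # N/U rows:
    gap_length: int = 0
    gap_type: str = "scaffold"
    linkage: str = "yes"
    evidence: str = "align_genus"


def write_agp(rows: Sequence[AgpRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.0\n")
        for r in rows:
            if r.component_type == "W":
                tail = [r.component_id, r.comp_start, r.comp_end, r.orientation]
            else:
                tail = [r.gap_length, r.gap_type, r.linkage, r.evidence]
            fh.write(
                "\t".join(
                    str(x)
                    for x in [r.object, r.obj_start, r.obj_end, r.part_number, r.component_type, *tail]
                )
                + "\n"
            )


def read_agp(path: str | Path) -> list[AgpRow]:
    rows: list[AgpRow] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            base = dict(
                object=f[0],
                obj_start=int(f[1]),
                obj_end=int(f[2]),
                part_number=int(f[3]),
                component_type=f[4],
            )
            if f[4] == "W":
                rows.append(
                    AgpRow(**base, component_id=f[5], comp_start=int(f[6]), comp_end=int(f[7]), orientation=f[8])
                )
            else:
                rows.append(
                    AgpRow(**base, gap_length=int(f[5]), gap_type=f[6], linkage=f[7], evidence=f[8])
                )
    return rows


def rebuild_from_agp(rows: Sequence[AgpRow], components: dict[str, str]) -> dict[str, str]:
    """Reconstruct object sequences from AGP rows plus component sequences."""
    objects: dict[str, list[str]] = {}
    for r in rows:
        parts = objects.setdefault(r.object, [])
        if r.component_type == "W":
            seq = components[r.component_id][r.comp_start - 1 : r.comp_end]
            if r.orientation == "-":
                seq = revcomp(seq)
            parts.append(seq)
        else:
            parts.append("N" * r.gap_length)
    return {name: "".join(parts) for name, parts in objects.items()}


# ---------------------------------------------------------------------------
# VCF 4.2 (text emission; read back with pysam.VariantFile)
# ---------------------------------------------------------------------------

def write_vcf(
    snps,
    indels,
    ref_lengths: dict[str, int],
    path: str | Path,
    sample: str = "donor",
) -> None:
    """Emit SNPs as plain records and large indels as symbolic <DEL>/<INS> SVs."""
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    for name, length in ref_lengths.items():
        buf.write(f"##contig=<ID={name},length={length}>\n")
    buf.write('##ALT=<ID=DEL,Description="Deletion relative to the reference">\n')
    buf.write('##ALT=<ID=INS,Description="Insertion relative to the reference">\n')
    buf.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End of the variant">\n')
    buf.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed SV length">\n')
    buf.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
    buf.write('##INFO=<ID=VALIDATED,Number=0,Type=Flag,Description="Breakpoints read-validated">\n')
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    recs = []
    for s in snps:
        recs.append((s.r_chrom, s.r_pos, f"{s.ref_base}\t{s.alt_base}\t.\tPASS\t."))
    for v in indels:
        # SV convention: POS is the base before the event (1-based), which is
        # the 0-based coordinate of the first affected base; END is the last
        # affected base, 1-based inclusive.
        if v.type == "DEL":
            info = f"SVTYPE=DEL;END={v.r_pos + v.size};SVLEN=-{v.size}"
            alt = "<DEL>"
        else:
            info = f"SVTYPE=INS;END={max(1, v.r_pos)};SVLEN={v.size}"
            alt = "<INS>"
        if getattr(v, "validated", False):
            info += ";VALIDATED"
        recs.append((v.r_chrom, max(0, v.r_pos - 1), f"N\t{alt}\t.\tPASS\t{info}"))
    order = {name: i for i, name in enumerate(ref_lengths)}
    recs.sort(key=lambda r: (order.get(r[0], len(order)), r[1]))
    for chrom, pos, tail in recs:
        buf.write(f"{chrom}\t{pos + 1}\t.\t{tail}\n")
    Path(path).write_text(buf.getvalue())
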