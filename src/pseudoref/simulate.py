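"""Synthetic genome simulator with machine-readable truth.

Generates a reference chromosome set, a donor genome carrying planted SNPs
(~1% by default), small indels, and large insertions/deletions whose deletion
sizes follow a bimodal mixture (modes near 4 kb and 12.5 kb, the size
structure typical of LTR-retrotransposon turnover between rice cultivars),
then shears the donor into contigs and simulates paired-end reads and
BAC-end-sequence (BES) clone pairs.  Every downstream stage can be scored
against the truth tables.

All truth coordinates are 0-based half-open on the forward reference strand.
A fixed seed makes every output byte-identical across runs.
"""

from __future__ import annotations

from bisect import bisect_right, insort
from dataclasses import dataclass, field

import numpy as np

from .genes import GeneModel, CODON_TABLE
from .seqio import revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# rng stream ids, one per operation, so ops are independently reproducible
_RNG_REF, _RNG_MUT, _RNG_SHEAR, _RNG_READS, _RNG_BES, _RNG_GENES, _RNG_FX = range(7)


@dataclass
class SimParams:
    """Study conditions for the simulator.

    Rates are per reference bp.  Defaults: 1% SNP divergence; large-indel
    rates follow the observed inter-cultivar counts over alignment length
    (deletions 1.8e-5/bp, insertions 0.85e-5/bp); deletion sizes are a
    0.55*N(4 kb, 0.5 kb) + 0.30*N(12.5 kb, 1 kb) + 0.15*lognormal-tail
    mixture truncated to [100, 50000] bp; insertion sizes are lognormal
    (mean ~550 bp) truncated to [100, 5000] bp; 58.5% of large-indel events
    are composed of tandem-repeat copies.
    """

    ref_length: int = 1_000_000
    n_chroms: int = 1
    snp_rate: float = 0.01
    small_indel_rate: float = 1e-4
    small_indel_max: int = 50
    large_del_rate: float = 1.8e-5
    large_ins_rate: float = 0.85e-5
    del_mix_weights: tuple[float, float, float] = (0.55, 0.30, 0.15)
    del_mix_normals: tuple[tuple[float, float], tuple[float, float]] = ((4000.0, 500.0), (12500.0, 1000.0))
    del_tail_lognorm: tuple[float, float] = (7.0, 1.0)
    del_size_bounds: tuple[int, int] = (100, 50_000)
    ins_lognorm: tuple[float, float] = (6.0, 0.8)
    ins_size_bounds: tuple[int, int] = (100, 5_000)
    repeat_fraction: float = 0.585
    repeat_unit_range: tuple[int, int] = (300, 500)
    repeat_divergence: float = 0.10
    contig_n50: int = 20_000
    contig_min_emit: int = 100
    contig_error_rate: float = 0.0
    read_length: int = 100
    read_depth: float = 30.0
    read_error_rate: float = 0.0
    insert_mean: float = 350.0
    insert_sd: float = 35.0
    bes_insert_mean: float = 100_000.0
    bes_insert_sd: float = 10_000.0
    bes_read_len: int = 500
    n_bes_clones: int = 0
    seed: int = 0

    def validate(self) -> None:
        for name in ("snp_rate", "small_indel_rate", "large_del_rate", "large_ins_rate",
                     "repeat_fraction", "contig_error_rate", "read_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("ref_length", "n_chroms", "contig_n50", "read_length", "bes_read_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.del_size_bounds[0] < 100 or self.ins_size_bounds[0] < 100:
            raise ValueError("large-indel sizes must be >= 100 bp")
        if self.read_length >= self.insert_mean:
            raise ValueError("read_length must be below the insert mean")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class PlantedSNP:
    chrom: str
    pos: int
    ref_base: str
    alt_base: str


@dataclass
class PlantedIndel:
    chrom: str
    pos: int          # reference position of the event
    type: str         # INS or DEL
    size: int
    repeat_tag: bool = False
    seq: str = ""     # inserted sequence (INS only)


@dataclass
class TruePlacement:
    contig_id: str
    chrom: str
    donor_start: int
    donor_end: int
    ref_start: int
    ref_end: int
    strand: str = "+"


@dataclass
class TruthSet:
    planted_snps: list[PlantedSNP] = field(default_factory=list)
    planted_indels: list[PlantedIndel] = field(default_factory=list)
    planted_small_indels: list[PlantedIndel] = field(default_factory=list)
    true_placements: list[TruePlacement] = field(default_factory=list)
    planted_contig_errors: list[tuple[str, int, str]] = field(default_factory=list)

    def all_indels(self) -> list[PlantedIndel]:
        return sorted(self.planted_indels + self.planted_small_indels, key=lambda e: (e.chrom, e.pos))

    def coord_map(self) -> "CoordMap":
        return CoordMap(self.all_indels())


class CoordMap:
    """Piecewise-linear map between donor and reference coordinates."""

    def __init__(self, indels: list[PlantedIndel]):
        self.segs: dict[str, tuple[list[int], list[int], list[str]]] = {}
        by_chrom: dict[str, list[PlantedIndel]] = {}
        for e in indels:
            by_chrom.setdefault(e.chrom, []).append(e)
        for chrom, events in by_chrom.items():
            d_starts, r_starts, kinds = [0], [0], ["M"]
            cur_r = cur_d = 0
            for e in sorted(events, key=lambda e: e.pos):
                seg = e.pos - cur_r
                cur_d += seg
                cur_r = e.pos
                if e.type == "DEL":
                    cur_r += e.size
                else:
                    d_starts.append(cur_d)
                    r_starts.append(cur_r)
                    kinds.append("I")
                    cur_d += e.size
                d_starts.append(cur_d)
                r_starts.append(cur_r)
                kinds.append("M")
            self.segs[chrom] = (d_starts, r_starts, kinds)

    def donor_to_ref(self, chrom: str, pos: int) -> int:
        if chrom not in self.segs:
            return pos
        d_starts, r_starts, kinds = self.segs[chrom]
        i = bisect_right(d_starts, pos) - 1
        if kinds[i] == "I":
            return r_starts[i]
        return r_starts[i] + (pos - d_starts[i])

    def ref_to_donor(self, chrom: str, pos: int) -> int:
        """Donor coordinate of a reference position.

        Positions inside deleted reference sequence map to the deletion's
        donor junction; an insertion point maps to the donor position just
        before the inserted sequence.
        """
        if chrom not in self.segs:
            return pos
        d_starts, r_starts, kinds = self.segs[chrom]
        n = len(d_starts)
        for i in range(n):
            if kinds[i] == "I":
                if pos == r_starts[i]:
                    return d_starts[i]  # start of the inserted donor segment
                continue
            if pos < r_starts[i]:
                return d_starts[i]  # inside a deleted gap preceding this segment
            seg_len = (d_starts[i + 1] - d_starts[i]) if i + 1 < n else None
            if seg_len is None or pos < r_starts[i] + seg_len:
                return d_starts[i] + (pos - r_starts[i])
        return d_starts[-1]


# ---------------------------------------------------------------------------
# Reference generation (with tandem-repeat tracts destined for deletion)
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _sample_del_sizes(rng: np.random.Generator, n: int, params: SimParams) -> np.ndarray:
    w = np.asarray(params.del_mix_weights, dtype=float)
    w = w / w.sum()
    comp = rng.choice(3, size=n, p=w)
    out = np.empty(n)
    for i, (mu, sd) in enumerate(params.del_mix_normals):
        m = comp == i
        out[m] = rng.normal(mu, sd, size=int(m.sum()))
    m = comp == 2
    mu, sigma = params.del_tail_lognorm
    out[m] = rng.lognormal(mu, sigma, size=int(m.sum()))
    lo, hi = params.del_size_bounds
    return np.clip(np.round(out), lo, hi).astype(int)


def _sample_ins_sizes(rng: np.random.Generator, n: int, params: SimParams) -> np.ndarray:
    mu, sigma = params.ins_lognorm
    out = rng.lognormal(mu, sigma, size=n)
    lo, hi = params.ins_size_bounds
    return np.clip(np.round(out), lo, hi).astype(int)


def _tandem(rng: np.random.Generator, size: int, params: SimParams) -> str:
    """Tandem copies of a fresh repeat unit, each copy independently diverged.

    Copy-to-copy divergence (default 10% substitutions) mirrors real repeat
    families, whose members are similar but not identical; without it every
    window of a repeat tract would be exactly ambiguous between copies.
    """
    lo, hi = params.repeat_unit_range
    unit = np.frombuffer(_random_seq(rng, int(rng.integers(lo, hi + 1))).encode(), dtype=np.uint8)
    copies = []
    total = 0
    while total < size:
        c = unit.copy()
        n_mut = int(rng.binomial(len(c), params.repeat_divergence))
        if n_mut:
            pos = rng.choice(len(c), size=n_mut, replace=False)
            lut = {ord(b): i for i, b in enumerate("ACGT")}
            for p in pos:
                c[p] = _BASES[(lut[int(c[p])] + int(rng.integers(1, 4))) % 4]
        copies.append(c)
        total += len(c)
    return np.concatenate(copies)[:size].tobytes().decode()


class _Claims:
    """Sorted claimed intervals with a separation margin, for rejection sampling."""

    def __init__(self, margin: int):
        self.margin = margin
        self.ivals: list[tuple[int, int]] = []

    def free(self, start: int, end: int) -> bool:
        i = bisect_right(self.ivals, (start, start))
        for j in (i - 1, i):
            if 0 <= j < len(self.ivals):
                a, b = self.ivals[j]
                if start < b + self.margin and a < end + self.margin:
                    return False
        return True

    def add(self, start: int, end: int) -> None:
        insort(self.ivals, (start, end))


def generate_reference(params: SimParams) -> tuple[dict[str, str], dict[str, list[tuple[int, int]]]]:
    """Random reference chromosomes with planted tandem-repeat tracts.

    The tracts are sized from the deletion mixture and later become the
    repeat-tagged share of planted deletions, so that deleted bases are
    genuinely repetitive sequence.
    """
    params.validate()
    rng = params.rng(_RNG_REF)
    ref: dict[str, str] = {}
    tracts: dict[str, list[tuple[int, int]]] = {}
    for c in range(params.n_chroms):
        name = f"chr{c + 1:02d}"
        L = params.ref_length
        arr = _BASES[rng.integers(0, 4, size=L)].copy()
        n_tracts = int(round(params.repeat_fraction * params.large_del_rate * L))
        sizes = _sample_del_sizes(rng, n_tracts, params)
        claims = _Claims(margin=1000)
        placed: list[tuple[int, int]] = []
        for s in sizes:
            s = int(s)
            if s + 2000 > L:
                raise ValueError("reference too short for requested repeat tract")
            for _ in range(100):
                p = int(rng.integers(1000, L - s - 1000))
                if claims.free(p, p + s):
                    claims.add(p, p + s)
                    arr[p : p + s] = np.frombuffer(_tandem(rng, s, params).encode(), dtype=np.uint8)
                    placed.append((p, p + s))
                    break
            else:
                raise RuntimeError("could not place repeat tract after 100 retries")
        ref[name] = arr.tobytes().decode()
        tracts[name] = sorted(placed)
    return ref, tracts


# ---------------------------------------------------------------------------
# Donor mutation
# ---------------------------------------------------------------------------

def mutate_reference(
    ref: dict[str, str],
    params: SimParams,
    repeat_tracts: dict[str, list[tuple[int, int]]] | None = None,
) -> tuple[dict[str, str], TruthSet]:
    """Plant SNPs, small indels and large indels; return donor + truth.

    Events never overlap (rejection sampling, 100x retry cap).  When
    ``repeat_tracts`` is given, repeat-tagged deletions remove exactly those
    tracts; remaining deletions remove unique sequence.  Repeat-tagged
    insertions insert tandem copies of a fresh repeat unit.
    """
    params.validate()
    rng = params.rng(_RNG_MUT)
    truth = TruthSet()
    donor: dict[str, str] = {}
    for chrom, seq in ref.items():
        L = len(seq)
        claims = _Claims(margin=600)
        events: list[PlantedIndel] = []

        tract_list = (repeat_tracts or {}).get(chrom, [])
        for a, b in tract_list:
            claims.add(a, b)
            events.append(PlantedIndel(chrom, a, "DEL", b - a, repeat_tag=True))

        n_del = int(rng.poisson(params.large_del_rate * L))
        n_del_extra = max(0, n_del - len(tract_list))
        for s in _sample_del_sizes(rng, n_del_extra, params):
            s = int(s)
            if s + 2000 > L:
                raise ValueError("reference too short for requested deletion size")
            for _ in range(100):
                p = int(rng.integers(1000, L - s - 1000))
                if claims.free(p, p + s):
                    claims.add(p, p + s)
                    events.append(PlantedIndel(chrom, p, "DEL", s))
                    break
            else:
                raise RuntimeError("deletion placement failed after 100 retries")

        n_ins = int(rng.poisson(params.large_ins_rate * L))
        sizes = _sample_ins_sizes(rng, n_ins, params)
        tags = rng.random(n_ins) < params.repeat_fraction
        for s, tag in zip(sizes, tags):
            s = int(s)
            for _ in range(100):
                p = int(rng.integers(1000, L - 1000))
                if claims.free(p, p + 1):
                    claims.add(p, p + 1)
                    ins_seq = _tandem(rng, s, params) if tag else _random_seq(rng, s)
                    events.append(PlantedIndel(chrom, p, "INS", s, repeat_tag=bool(tag), seq=ins_seq))
                    break
            else:
                raise RuntimeError("insertion placement failed after 100 retries")

        n_small = int(rng.poisson(params.small_indel_rate * L))
        for _ in range(n_small):
            s = int(min(params.small_indel_max, 1 + rng.geometric(0.4)))
            is_del = bool(rng.random() < 0.5)
            for _ in range(100):
                p = int(rng.integers(1000, L - s - 1000))
                if claims.free(p, p + (s if is_del else 1)):
                    claims.add(p, p + (s if is_del else 1))
                    if is_del:
                        events.append(PlantedIndel(chrom, p, "DEL", s))
                    else:
                        events.append(PlantedIndel(chrom, p, "INS", s, seq=_random_seq(rng, s)))
                    break
            else:
                raise RuntimeError("small-indel placement failed after 100 retries")

        events.sort(key=lambda e: e.pos)
        for e in events:
            (truth.planted_indels if e.size >= 100 else truth.planted_small_indels).append(e)

        # SNPs anywhere outside deleted intervals
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        allowed = np.ones(L, dtype=bool)
        for e in events:
            if e.type == "DEL":
                allowed[e.pos : e.pos + e.size] = False
        allowed[arr == ord("N")] = False
        pool = np.flatnonzero(allowed)
        n_snp = int(rng.binomial(len(pool), params.snp_rate))
        pos = np.sort(rng.choice(pool, size=n_snp, replace=False))
        shift = rng.integers(1, 4, size=n_snp)
        lut = np.full(256, -1, dtype=np.int64)
        for i, b in enumerate(b"ACGT"):
            lut[b] = i
        base_idx = lut[arr[pos]]
        new_idx = (base_idx + shift) % 4
        for p, old_i, new_i in zip(pos, base_idx, new_idx):
            truth.planted_snps.append(
                PlantedSNP(chrom, int(p), chr(_BASES[old_i]), chr(_BASES[new_i]))
            )
        arr[pos] = _BASES[new_idx]

        pieces: list[str] = []
        snp_seq = arr.tobytes().decode()
        cur = 0
        for e in events:
            pieces.append(snp_seq[cur : e.pos])
            if e.type == "DEL":
                cur = e.pos + e.size
            else:
                pieces.append(e.seq)
                cur = e.pos
        pieces.append(snp_seq[cur:])
        donor[chrom] = "".join(pieces)

    truth.planted_snps.sort(key=lambda s: (s.chrom, s.pos))
    truth.planted_indels.sort(key=lambda e: (e.chrom, e.pos))
    truth.planted_small_indels.sort(key=lambda e: (e.chrom, e.pos))
    return donor, truth


# ---------------------------------------------------------------------------
# Contig shearing
# ---------------------------------------------------------------------------

def shear_contigs(
    donor: dict[str, str],
    params: SimParams,
    truth: TruthSet | None = None,
) -> tuple[dict[str, str], list[TruePlacement]]:
    """Cut the donor into contigs with roughly the requested N50.

    Lengths are exponential with mean N50/1.678 (the length-weighted median
    of an exponential assembly), floored at ``contig_min_emit`` so that
    sub-500 bp contigs are still emitted for the downstream length filter to
    remove.  Optional substitution errors are planted at
    ``contig_error_rate`` and recorded in the truth placements.  If a
    TruthSet is given, placements carry projected reference coordinates.
    """
    params.validate()
    for seq in donor.values():
        if params.contig_n50 > len(seq):
            raise ValueError("contig_n50 exceeds chromosome length")
    rng = params.rng(_RNG_SHEAR)
    cmap = truth.coord_map() if truth is not None else None
    contigs: dict[str, str] = {}
    placements: list[TruePlacement] = []
    errors: list[tuple[str, int, str]] = []
    idx = 0
    mean_len = params.contig_n50 / 1.678
    for chrom, seq in donor.items():
        L = len(seq)
        cur = 0
        while cur < L:
            ln = max(params.contig_min_emit, int(rng.exponential(mean_len)))
            end = min(L, cur + ln)
            cid = f"ctg{idx:05d}"
            idx += 1
            sub = seq[cur:end]
            if params.contig_error_rate > 0:
                arr = np.frombuffer(sub.encode(), dtype=np.uint8).copy()
                n_err = int(rng.binomial(len(arr), params.contig_error_rate))
                if n_err:
                    pos = np.sort(rng.choice(len(arr), size=n_err, replace=False))
                    for p in pos:
                        old = chr(arr[p])
                        if old not in "ACGT":
                            continue
                        new = "ACGT"[("ACGT".index(old) + int(rng.integers(1, 4))) % 4]
                        arr[p] = ord(new)
                        errors.append((cid, int(p), old))
                    sub = arr.tobytes().decode()
            contigs[cid] = sub
            placements.append(
                TruePlacement(
                    contig_id=cid,
                    chrom=chrom,
                    donor_start=cur,
                    donor_end=end,
                    ref_start=cmap.donor_to_ref(chrom, cur) if cmap else cur,
                    ref_end=cmap.donor_to_ref(chrom, end) if cmap else end,
                )
            )
            cur = end
    if truth is not None:
        truth.true_placements = placements
        truth.planted_contig_errors = errors
    return contigs, placements


# ---------------------------------------------------------------------------
# Paired-end reads
# ---------------------------------------------------------------------------

@dataclass
class ReadPair:
    read_id: str
    chrom: str
    start: int    # donor coordinate of fragment start
    end: int      # donor coordinate of fragment end
    seq1: str
    qual1: str
    seq2: str
    qual2: str


def simulate_reads(donor: dict[str, str], params: SimParams) -> list[ReadPair]:
    """Simulate paired-end reads at ``read_depth`` fold coverage.

    Read 1 is the forward end of the fragment, read 2 the reverse complement
    of the other end.  Substitution errors occur at ``read_error_rate``;
    correct bases carry Q35, injected errors Q15, so quality-aware consumers
    can be exercised deterministically.
    """
    params.validate()
    rng = params.rng(_RNG_READS)
    rl = params.read_length
    q_good, q_bad = chr(35 + 33), chr(15 + 33)
    pairs: list[ReadPair] = []
    idx = 0
    for chrom, seq in donor.items():
        L = len(seq)
        n_pairs = int(round(params.read_depth * L / (2 * rl)))
        min_ins = rl + 1
        for _ in range(n_pairs):
            ins = max(min_ins, int(round(rng.normal(params.insert_mean, params.insert_sd))))
            ins = min(ins, L - 1)
            p = int(rng.integers(0, L - ins + 1))
            frag_end = p + ins
            s1 = seq[p : p + rl]
            s2 = revcomp(seq[frag_end - rl : frag_end])
            q1 = [q_good] * rl
            q2 = [q_good] * rl
            if params.read_error_rate > 0:
                s1, q1 = _inject_errors(rng, s1, q1, params.read_error_rate, q_bad)
                s2, q2 = _inject_errors(rng, s2, q2, params.read_error_rate, q_bad)
            pairs.append(
                ReadPair(f"rd{idx:07d}", chrom, p, frag_end, s1, "".join(q1), s2, "".join(q2))
            )
            idx += 1
    return pairs


def _inject_errors(rng, seq: str, qual: list[str], rate: float, q_bad: str):
    arr = list(seq)
    n = int(rng.binomial(len(arr), rate))
    if n:
        pos = rng.choice(len(arr), size=n, replace=False)
        for p in pos:
            old = arr[p]
            if old not in "ACGT":
                continue
            arr[p] = "ACGT"[("ACGT".index(old) + int(rng.integers(1, 4))) % 4]
            qual[p] = q_bad
    return "".join(arr), qual


def write_read_pairs_fastq(pairs: list[ReadPair], r1_path, r2_path) -> None:
    from .seqio import write_fastq

    write_fastq(((p.read_id, p.seq1, p.qual1) for p in pairs), r1_path)
    write_fastq(((p.read_id, p.seq2, p.qual2) for p in pairs), r2_path)


def write_truth_sam(pairs: list[ReadPair], donor: dict[str, str], path) -> None:
    """SAM of generating coordinates on the donor (both mates, proper pairs)."""
    import pysam

    from .seqio import sam_header

    rl = len(pairs[0].seq1) if pairs else 0
    header = sam_header({n: len(s) for n, s in donor.items()})
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tid = {n: i for i, n in enumerate(donor)}
        for p in pairs:
            for is_r1 in (True, False):
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = p.read_id
                rec.reference_id = tid[p.chrom]
                rec.next_reference_id = tid[p.chrom]
                rec.mapping_quality = 60
                if is_r1:
                    rec.flag = 99
                    rec.reference_start = p.start
                    rec.next_reference_start = p.end - rl
                    rec.template_length = p.end - p.start
                    rec.query_sequence = p.seq1
                    rec.query_qualities = pysam.qualitystring_to_array(p.qual1)
                else:
                    rec.flag = 147
                    rec.reference_start = p.end - rl
                    rec.next_reference_start = p.start
                    rec.template_length = -(p.end - p.start)
                    rec.query_sequence = revcomp(p.seq2)
                    rec.query_qualities = pysam.qualitystring_to_array(p.qual2[::-1])
                rec.cigartuples = [(0, rl)]
                out.write(rec)


def project_reads_to_contigs(
    pairs: list[ReadPair],
    placements: list[TruePlacement],
    contigs: dict[str, str],
    path,
) -> None:
    """Project truth read coordinates into contig coordinates and write SAM.

    Reads overhanging a contig boundary are soft-clipped to the contig (as a
    local aligner would report them); overlaps under 20 bp are dropped.
    Mate links are preserved when both mates land on the same contig, which
    is what breakpoint validation consumes.
    """
    import pysam

    from .seqio import sam_header

    by_chrom: dict[str, list[TruePlacement]] = {}
    for pl in placements:
        by_chrom.setdefault(pl.chrom, []).append(pl)
    for lst in by_chrom.values():
        lst.sort(key=lambda p: p.donor_start)
    starts = {c: [p.donor_start for p in lst] for c, lst in by_chrom.items()}

    def locate(chrom: str, lo: int, hi: int, min_overlap: int = 20) -> TruePlacement | None:
        """Placement holding the larger part of [lo, hi), if >= min_overlap bp."""
        lst = by_chrom.get(chrom)
        if not lst:
            return None
        best = None
        best_ov = 0
        i = bisect_right(starts[chrom], hi) - 1
        while i >= 0 and lst[i].donor_end > lo:
            pl = lst[i]
            ov = min(hi, pl.donor_end) - max(lo, pl.donor_start)
            if ov > best_ov:
                best, best_ov = pl, ov
            i -= 1
        return best if best_ov >= min_overlap else None

    header = sam_header({c: len(s) for c, s in contigs.items()})
    rl = len(pairs[0].seq1) if pairs else 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tid = {n: i for i, n in enumerate(contigs)}
        for p in pairs:
            pl1 = locate(p.chrom, p.start, p.start + rl)
            pl2 = locate(p.chrom, p.end - rl, p.end)
            same = pl1 is not None and pl2 is not None and pl1.contig_id == pl2.contig_id
            for is_r1, pl in ((True, pl1), (False, pl2)):
                if pl is None:
                    continue
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = p.read_id
                rec.reference_id = tid[pl.contig_id]
                rec.mapping_quality = 60
                d_lo = p.start if is_r1 else p.end - rl
                clip_l = max(0, pl.donor_start - d_lo)
                clip_r = max(0, (d_lo + rl) - pl.donor_end)
                pos = d_lo + clip_l - pl.donor_start
                rec.reference_start = pos
                cig = []
                if clip_l:
                    cig.append((4, clip_l))
                cig.append((0, rl - clip_l - clip_r))
                if clip_r:
                    cig.append((4, clip_r))
                rec.cigartuples = cig
                flag = 1 | (64 if is_r1 else 128) | (16 if not is_r1 else 0) | (32 if is_r1 else 0)
                if same:
                    flag |= 2
                    mate_lo = p.end - rl if is_r1 else p.start
                    mate_pos = max(mate_lo, pl.donor_start) - pl.donor_start
                    rec.next_reference_id = tid[pl.contig_id]
                    rec.next_reference_start = mate_pos
                    rec.template_length = (p.end - p.start) * (1 if is_r1 else -1)
                else:
                    flag |= 8
                rec.flag = rec.flag | flag
                rec.query_sequence = p.seq1 if is_r1 else revcomp(p.seq2)
                rec.query_qualities = pysam.qualitystring_to_array(
                    p.qual1 if is_r1 else p.qual2[::-1]
                )
                out.write(rec)


# ---------------------------------------------------------------------------
# BES clone pairs
# ---------------------------------------------------------------------------

@dataclass
class BESRead:
    bes_id: str
    clone_id: str
    end: str  # F or R
    seq: str


@dataclass
class BESCloneTruth:
    clone_id: str
    chrom: str
    start: int
    end: int

    @property
    def distance(self) -> int:
        return self.end - self.start


def simulate_bes(donor: dict[str, str], params: SimParams) -> tuple[list[BESRead], list[BESCloneTruth]]:
    """Simulate BAC-clone end pairs on the donor.

    Each clone yields a forward end read at the clone start and a
    reverse-complemented end read at the clone end, separated by roughly the
    clone insert size; the truth distance is recorded per clone.
    """
    params.validate()
    rng = params.rng(_RNG_BES)
    reads: list[BESRead] = []
    truths: list[BESCloneTruth] = []
    if params.n_bes_clones == 0:
        return reads, truths
    chroms = list(donor)
    lengths = np.array([len(donor[c]) for c in chroms], dtype=float)
    if params.bes_insert_mean >= lengths.max():
        raise ValueError("bes insert mean exceeds chromosome length")
    probs = lengths / lengths.sum()
    blen = params.bes_read_len
    for i in range(params.n_bes_clones):
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        L = len(donor[chrom])
        ins = int(round(rng.normal(params.bes_insert_mean, params.bes_insert_sd)))
        ins = max(2 * blen + 100, min(ins, L - 1))
        s = int(rng.integers(0, L - ins))
        e = s + ins
        cid = f"CL{i:06d}"
        reads.append(BESRead(f"{cid}_F", cid, "F", donor[chrom][s : s + blen]))
        reads.append(BESRead(f"{cid}_R", cid, "R", revcomp(donor[chrom][e - blen : e])))
        truths.append(BESCloneTruth(cid, chrom, s, e))
    return reads, truths


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

_NON_STOP = [c for c, aa in CODON_TABLE.items() if aa != "*"]
_STOPS = ["TAA", "TAG", "TGA"]


def simulate_genes(
    ref: dict[str, str], n_genes: int, params: SimParams
) -> tuple[list[GeneModel], dict[str, str]]:
    """Install ``n_genes`` multi-exon gene models into a copy of the reference.

    Models carry 5'/3' UTRs, a complete CDS (ATG .. stop, no internal stops)
    and GT..AG introns; genes never overlap.  The modified reference is
    returned alongside the models because a random background sequence cannot
    otherwise carry valid coding structure.
    """
    params.validate()
    rng = params.rng(_RNG_GENES)
    genome = {c: s for c, s in ref.items()}
    arrs = {c: np.frombuffer(s.encode(), dtype=np.uint8).copy() for c, s in ref.items()}
    claims = {c: _Claims(margin=200) for c in ref}
    genes: list[GeneModel] = []
    chroms = list(ref)
    for gi in range(n_genes):
        n_codons = int(rng.integers(60, 301))
        cds = "ATG" + "".join(_NON_STOP[int(i)] for i in rng.integers(0, len(_NON_STOP), n_codons - 2))
        cds += _STOPS[int(rng.integers(0, 3))]
        utr5 = _random_seq(rng, int(rng.integers(50, 201)))
        utr3 = _random_seq(rng, int(rng.integers(50, 201)))
        transcript = utr5 + cds + utr3
        n_exons = int(rng.integers(2, 7))
        cuts = sorted(
            int(c) for c in rng.choice(
                np.arange(20, len(transcript) - 20), size=n_exons - 1, replace=False
            )
        )
        # drop cuts closer than 10 bp to each other
        filtered = []
        for c in cuts:
            if not filtered or c - filtered[-1] >= 10:
                filtered.append(c)
        cuts = filtered
        introns = [
            "GT" + _random_seq(rng, int(rng.integers(76, 397))) + "AG" for _ in cuts
        ]
        # genomic layout on the plus strand of the gene
        gene_seq_parts = []
        exon_iv: list[tuple[int, int]] = []
        t_prev = 0
        g_cursor = 0
        t_bounds = cuts + [len(transcript)]
        t_to_g: list[tuple[int, int, int]] = []  # (t_start, t_end, g_start)
        for i, t_end in enumerate(t_bounds):
            seg = transcript[t_prev:t_end]
            exon_iv.append((g_cursor, g_cursor + len(seg)))
            t_to_g.append((t_prev, t_end, g_cursor))
            gene_seq_parts.append(seg)
            g_cursor += len(seg)
            if i < len(introns):
                gene_seq_parts.append(introns[i])
                g_cursor += len(introns[i])
            t_prev = t_end
        gene_seq = "".join(gene_seq_parts)
        glen = len(gene_seq)

        def t2g(t: int) -> int:
            for ts, te, gs in t_to_g:
                if ts <= t < te:
                    return gs + (t - ts)
            ts, te, gs = t_to_g[-1]
            return gs + (te - ts)

        cds_t0, cds_t1 = len(utr5), len(utr5) + len(cds)
        cds_iv: list[tuple[int, int]] = []
        for ts, te, gs in t_to_g:
            lo, hi = max(ts, cds_t0), min(te, cds_t1)
            if lo < hi:
                cds_iv.append((gs + (lo - ts), gs + (hi - ts)))

        chrom = chroms[int(rng.integers(0, len(chroms)))]
        L = len(ref[chrom])
        if glen + 400 > L:
            raise ValueError("chromosome too short for gene model")
        placed = False
        for _ in range(200):
            p = int(rng.integers(200, L - glen - 200))
            if claims[chrom].free(p, p + glen):
                claims[chrom].add(p, p + glen)
                placed = True
                break
        if not placed:
            raise RuntimeError(f"could not place gene {gi}: chromosomes overcrowded")
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            arrs[chrom][p : p + glen] = np.frombuffer(gene_seq.encode(), dtype=np.uint8)
            exons = [(p + a, p + b) for a, b in exon_iv]
            cds_g = [(p + a, p + b) for a, b in cds_iv]
        else:
            arrs[chrom][p : p + glen] = np.frombuffer(revcomp(gene_seq).encode(), dtype=np.uint8)
            exons = sorted((p + glen - b, p + glen - a) for a, b in exon_iv)
            cds_g = sorted((p + glen - b, p + glen - a) for a, b in cds_iv)
        genes.append(
            GeneModel(
                gene_id=f"gene{gi:04d}",
                transcript_id=f"gene{gi:04d}.1",
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds=cds_g,
            )
        )
    genome = {c: a.tobytes().decode() for c, a in arrs.items()}
    genes.sort(key=lambda g: (g.chrom, g.span))
    return genes, genome


def plant_effect_snps(
    genome: dict[str, str], genes: list[GeneModel], seed: int = 0
) -> list[tuple[str, int, str, str, str]]:
    """Plant SNPs with known effect categories into gene models.

    For each gene this tries to construct one nonsense, one splice-site, one
    synonymous and one missense substitution (by direct codon-table
    construction, strand-aware), returning
    (chrom, ref_pos, ref_base, alt_base, expected_category) tuples.
    """
    rng = np.random.default_rng([seed, _RNG_FX])
    out: list[tuple[str, int, str, str, str]] = []
    for g in genes:
        cds_seq = g.coding_sequence(genome)
        if len(cds_seq) % 3 != 0:
            continue
        # map coding index -> genomic position
        coding_pos: list[int] = []
        for a, b in g.cds:
            coding_pos.extend(range(a, b))
        if g.strand == "-":
            coding_pos = coding_pos[::-1]
        wanted = {"nonsense": None, "synonymous": None, "missense": None}
        codon_order = rng.permutation(len(cds_seq) // 3 - 1)[1:]  # skip start, stop
        for ci in codon_order:
            ci = int(ci)
            codon = cds_seq[ci * 3 : ci * 3 + 3]
            aa = CODON_TABLE[codon]
            if aa == "*":
                continue
            for off in range(3):
                for nb in "ACGT":
                    if nb == codon[off]:
                        continue
                    new = codon[:off] + nb + codon[off + 1 :]
                    new_aa = CODON_TABLE[new]
                    cat = (
                        "nonsense" if new_aa == "*" else
                        "synonymous" if new_aa == aa else "missense"
                    )
                    if wanted.get(cat) is None:
                        gpos = coding_pos[ci * 3 + off]
                        ref_b = genome[g.chrom][gpos]
                        alt_b = nb if g.strand == "+" else revcomp(nb)
                        wanted[cat] = (g.chrom, gpos, ref_b, alt_b, cat)
            if all(v is not None for v in wanted.values()):
                break
        out.extend(v for v in wanted.values() if v is not None)
        introns = g.introns
        if introns:
            a, b = introns[int(rng.integers(0, len(introns)))]
            gpos = a if rng.random() < 0.5 else b - 1
            ref_b = genome[g.chrom][gpos]
            alt_b = "ACGT"[("ACGT".index(ref_b) + 1) % 4] if ref_b in "ACGT" else "A"
            out.append((g.chrom, gpos, ref_b, alt_b, "splice_site"))
    return out
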