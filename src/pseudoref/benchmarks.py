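"""End-to-end recovery benchmarks on simulated genomes with planted truth.

Each function freezes one study scenario — sizes, rates and thresholds are
the scenario definition, not tunables — runs the relevant pipeline stages
from scratch, and scores the result against the simulator's truth tables.
The same functions back the acceptance test suite and the acceptance
script.
"""

from __future__ import annotations

import itertools
import tempfile
from pathlib import Path

import numpy as np

from . import alignkit, genes, mapping_rate, pipeline, polish, scaffold, seqio, simulate, variants


# ---------------------------------------------------------------------------
# Printed-statistic fixtures
# ---------------------------------------------------------------------------

def fixture_verification() -> dict:
    """Recompute the published summary statistics from packaged fixtures."""
    report = pipeline.verify_paper_stats()
    targets = report[report["is_target"]].set_index("target")
    out = {name: float(row["recomputed"]) for name, row in targets.iterrows()}
    out["all_match"] = bool(targets["match"].all())
    out["n_targets"] = int(len(targets))
    return out


# ---------------------------------------------------------------------------
# SNP recovery: 2 Mb, 1% SNPs, error-free contigs at N50 20 kb
# ---------------------------------------------------------------------------

def snp_recovery(seed: int = 1) -> dict:
    params = simulate.SimParams(ref_length=2_000_000, seed=seed)
    ref, tracts = simulate.generate_reference(params)
    donor, truth = simulate.mutate_reference(ref, params, tracts)
    contigs, _ = simulate.shear_contigs(donor, params, truth)
    accepted, _ = alignkit.align_contigs(contigs, ref)
    snps, aligned_bp = variants.call_snps(accepted)
    called = {(s.r_chrom, s.r_pos, s.ref_base, s.alt_base) for s in snps}
    planted = {(s.chrom, s.pos, s.ref_base, s.alt_base) for s in truth.planted_snps}
    tp = len(called & planted)
    # recall within uniquely placed regions: planted SNPs under accepted blocks
    covered: dict[str, list[tuple[int, int]]] = {}
    for cand in accepted:
        for b in cand.blocks:
            covered.setdefault(b.r_chrom, []).append((b.r_start, b.r_end))
    for ivs in covered.values():
        ivs.sort()
    in_region = 0
    recovered_in_region = 0
    for s in truth.planted_snps:
        ivs = covered.get(s.chrom, [])
        import bisect

        i = bisect.bisect_right(ivs, (s.pos, 10**12)) - 1
        if i >= 0 and ivs[i][0] <= s.pos < ivs[i][1]:
            in_region += 1
            if (s.chrom, s.pos, s.ref_base, s.alt_base) in called:
                recovered_in_region += 1
    return dict(
        recall=recovered_in_region / in_region if in_region else 0.0,
        precision=tp / len(called) if called else 0.0,
        overall_recall=tp / len(planted) if planted else 0.0,
        n_planted=len(planted),
        n_called=len(called),
        aligned_bp=aligned_bp,
    )


# ---------------------------------------------------------------------------
# Large-indel recovery: >=200 deletions from the bimodal mixture, >=50 insertions
# ---------------------------------------------------------------------------

def indel_recovery(seed: int = 1, breakpoint_tol: int = 20) -> dict:
    params = simulate.SimParams(
        ref_length=3_000_000, n_chroms=2, seed=seed,
        large_del_rate=4e-5, large_ins_rate=1.2e-5,
    )
    ref, tracts = simulate.generate_reference(params)
    donor, truth = simulate.mutate_reference(ref, params, tracts)
    contigs, _ = simulate.shear_contigs(donor, params, truth)
    accepted, _ = alignkit.align_contigs(contigs, ref)
    dels, _ = variants.classify_deletions(accepted)
    ins = variants.classify_insertions(accepted, contigs)
    calls = dels + ins
    matched = 0
    for e in truth.planted_indels:
        if any(
            v.type == e.type and v.r_chrom == e.chrom
            and abs(v.r_pos - e.pos) <= breakpoint_tol
            and abs(v.size - e.size) <= breakpoint_tol
            for v in calls
        ):
            matched += 1
    sizes = np.array([v.size for v in dels])
    hist, _ = np.histogram(sizes, bins=np.arange(0, 20_001, 1_000))
    valley = hist[6:10].sum()
    mode_low = hist[3:5].sum()    # 3-5 kb
    mode_high = hist[11:14].sum() # 11-14 kb
    return dict(
        recall=matched / len(truth.planted_indels),
        n_planted_del=sum(1 for e in truth.planted_indels if e.type == "DEL"),
        n_planted_ins=sum(1 for e in truth.planted_indels if e.type == "INS"),
        n_called_del=len(dels),
        n_called_ins=len(ins),
        modes_detected=int(mode_low > valley) + int(mode_high > valley),
    )


# ---------------------------------------------------------------------------
# Polishing: 0.1% planted contig errors, 30x perfect reads, two rounds
# ---------------------------------------------------------------------------

def polishing_recovery(seed: int = 1) -> dict:
    params = simulate.SimParams(ref_length=300_000, seed=seed,
                                contig_error_rate=0.001, read_depth=30.0)
    ref, tracts = simulate.generate_reference(params)
    donor, truth = simulate.mutate_reference(ref, params, tracts)
    contigs, placements = simulate.shear_contigs(donor, params, truth)
    pairs = simulate.simulate_reads(donor, params)
    with tempfile.TemporaryDirectory() as tmp:
        sam = Path(tmp) / "reads.sam"
        simulate.project_reads_to_contigs(pairs, placements, contigs, sam)
        corrected, log = polish.polish_contigs(contigs, sam, polish.CorrectionRule())
    donor_contigs = {
        pl.contig_id: donor[pl.chrom][pl.donor_start : pl.donor_end] for pl in placements
    }
    planted_sites = {(c, pos) for c, pos, _ in truth.planted_contig_errors}
    remaining = 0
    new_errors = 0
    for cid in corrected:
        for i, (a, b) in enumerate(zip(corrected[cid], donor_contigs[cid])):
            if a != b:
                if (cid, i) in planted_sites:
                    remaining += 1
                else:
                    new_errors += 1
    n = len(truth.planted_contig_errors)
    return dict(
        reversion_pct=100.0 * (n - remaining) / n if n else 100.0,
        new_errors=new_errors,
        n_planted=n,
        rounds_run=int(log.attrs["rounds_run"]),
    )


# ---------------------------------------------------------------------------
# Oracle agreements (exact algorithmic cross-checks)
# ---------------------------------------------------------------------------

def _brute_force_mems(query, ref, min_len):
    from pseudoref.seqio import revcomp

    out = set()
    for strand, q in (("+", query), ("-", revcomp(query))):
        n, m = len(q), len(ref)
        for diag in range(-n + 1, m):
            i0 = max(0, -diag)
            j0 = i0 + diag
            lim = min(n - i0, m - j0)
            run = 0
            for t in range(lim + 1):
                i, j = i0 + t, j0 + t
                if t < lim and q[i] == ref[j] and q[i] in "ACGT":
                    run += 1
                else:
                    if run >= min_len:
                        out.add((i - run, j - run, run, strand))
                    run = 0
    return out


def _full_dp_identity(a, b, match=1, mismatch=-1, gap=-2):
    la, lb = len(a), len(b)
    H = np.zeros((la + 1, lb + 1), dtype=np.int64)
    H[:, 0] = np.arange(la + 1) * gap
    H[0, :] = np.arange(lb + 1) * gap
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i, j] = max(H[i - 1, j - 1] + s, H[i - 1, j] + gap, H[i, j - 1] + gap)
    i, j = la, lb
    matches = columns = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + (
            match if a[i - 1] == b[j - 1] else mismatch
        ):
            matches += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and H[i, j] == H[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
        columns += 1
    return matches / columns if columns else 0.0


def oracle_checks(seed: int = 1) -> dict:
    rng = np.random.default_rng(seed)

    def rand(n):
        return "".join("ACGT"[i] for i in rng.integers(0, 4, n))

    # MEM finder vs brute force
    mem_ok = 0
    trials = 5
    for _ in range(trials):
        ref = rand(350)
        q = list(ref[40:300])
        for p in rng.integers(0, len(q), 5):
            q[p] = "ACGT"[("ACGT".index(q[p]) + 1) % 4]
        q = "".join(q)
        idx = alignkit.ReferenceIndex({"c": ref}, k=13, max_occ=100_000)
        got = {
            (a.q_start, a.r_start, a.length, a.strand)
            for a in alignkit.find_anchors("q", q, idx, min_len=13)
        }
        mem_ok += got == _brute_force_mems(q, ref, 13)

    # extension identity vs full DP on <=500 bp segments
    max_diff = 0.0
    for _ in range(3):
        ref = rand(1500)
        q = list(ref[200:700])
        for p in rng.choice(len(q), size=10, replace=False):
            q[p] = "ACGT"[("ACGT".index(q[p]) + int(rng.integers(1, 4))) % 4]
        q = "".join(q)
        idx = alignkit.ReferenceIndex({"c": ref}, k=20)
        cand = alignkit.align_query("q", q, idx)[0]
        b0, b1 = cand.blocks[0], cand.blocks[-1]
        oracle = _full_dp_identity(q[b0.q_start : b1.q_end], ref[b0.r_start : b1.r_end])
        max_diff = max(max_diff, abs(cand.identity - oracle))

    # AGP round-trip byte identity on a simulated assembly
    p = simulate.SimParams(ref_length=100_000, seed=seed)
    ref_g, tracts = simulate.generate_reference(p)
    donor, truth = simulate.mutate_reference(ref_g, p, tracts)
    contigs, _ = simulate.shear_contigs(donor, p, truth)
    accepted, _ = alignkit.align_contigs(contigs, ref_g)
    placements = scaffold.placements_from_candidates(accepted, contigs)
    fasta, agp, _ = scaffold.build_pseudomolecules(placements, contigs, ref_g)
    agp_ok = seqio.rebuild_from_agp(agp, contigs) == fasta

    # codon-effect classifier vs exhaustive translation enumeration
    from Bio.Seq import Seq

    codon_ok = codon_total = 0
    pad = rand(30)
    tail = rand(141)
    for codon in map("".join, itertools.product("ACGT", repeat=3)):
        seq = pad + "ATG" + codon + "TAA" + tail
        genome = {"c": seq}
        model = genes.GeneModel("g", "g.1", "c", "+", [(30, 39)], [(30, 39)])
        for off in range(3):
            for nb in "ACGT":
                if nb == codon[off]:
                    continue
                new_codon = codon[:off] + nb + codon[off + 1 :]
                old_aa = str(Seq(codon).translate())
                new_aa = str(Seq(new_codon).translate())
                if old_aa == "*":
                    expect = "stop_loss" if new_aa != "*" else "synonymous"
                elif new_aa == "*":
                    expect = "nonsense"
                elif new_aa == old_aa:
                    expect = "synonymous"
                else:
                    expect = "missense"

                class _S:
                    r_chrom, r_pos = "c", 33 + off
                    ref_base, alt_base = codon[off], nb

                (eff,) = genes.classify_snp_effects([_S()], [model], genome)
                codon_total += 1
                codon_ok += eff.category == expect

    return dict(
        mem_agreement_pct=100.0 * mem_ok / trials,
        dp_identity_max_abs_diff=max_diff,
        agp_roundtrip_identical=int(agp_ok),
        codon_agreement_pct=100.0 * codon_ok / codon_total,
        n_codon_cases=codon_total,
    )


# ---------------------------------------------------------------------------
# BES rescue of insertion-only contigs with 100 kb clones
# ---------------------------------------------------------------------------

def bes_rescue(seed: int = 11) -> dict:
    params = simulate.SimParams(
        ref_length=1_500_000, seed=seed, contig_n50=5_000,
        large_ins_rate=1e-5, ins_lognorm=(9.4, 0.3), ins_size_bounds=(8_000, 25_000),
        n_bes_clones=2_500, read_depth=0,
    )
    ref, tracts = simulate.generate_reference(params)
    donor, truth = simulate.mutate_reference(ref, params, tracts)
    contigs, placements_truth = simulate.shear_contigs(donor, params, truth)
    bes_reads, _ = simulate.simulate_bes(donor, params)
    cmap = truth.coord_map()
    ins_iv: dict[str, list[tuple[int, int, int]]] = {}
    for e in truth.planted_indels:
        if e.type == "INS":
            d0 = cmap.ref_to_donor(e.chrom, e.pos)
            ins_iv.setdefault(e.chrom, []).append((d0, d0 + e.size, e.pos))
    targets: dict[str, int] = {}
    for pl in placements_truth:
        if pl.donor_end - pl.donor_start < 500:
            continue
        for a, b, rp in ins_iv.get(pl.chrom, []):
            if a <= pl.donor_start and pl.donor_end <= b:
                targets[pl.contig_id] = rp
                break
    accepted, _ = alignkit.align_contigs(contigs, ref)
    placements = scaffold.placements_from_candidates(accepted, contigs)
    placed_ids = {p.contig_id for p in placements}
    unplaced = {
        c: s for c, s in contigs.items() if c not in placed_ids and len(s) >= 500
    }
    contig_hits, ref_hits = scaffold.map_bes(bes_reads, contigs, ref)
    rescued = scaffold.rescue_anchor(
        unplaced, contig_hits, ref_hits, placements,
        clone_insert_mean=params.bes_insert_mean,
    )
    rd = {r.contig_id: r for r in rescued}
    window = 3 * params.bes_insert_mean
    ok = sum(
        1 for cid, rp in targets.items()
        if cid in rd and abs((rd[cid].r_start + rd[cid].r_end) / 2 - rp) <= window
    )
    return dict(
        rescue_pct=100.0 * ok / len(targets) if targets else 0.0,
        n_targets=len(targets),
        n_rescued=len(rescued),
        targets_aligned_by_mistake=sum(1 for t in targets if t in placed_ids),
    )


# ---------------------------------------------------------------------------
# Unique mapping rate, donor vs distant reference
# ---------------------------------------------------------------------------

def mapping_rate_contrast(seed: int = 1, n_reads: int = 800) -> dict:
    params = simulate.SimParams(ref_length=120_000, seed=seed, read_depth=1.5)
    ref, tracts = simulate.generate_reference(params)
    donor, truth = simulate.mutate_reference(ref, params, tracts)
    pairs = simulate.simulate_reads(donor, params)
    reads = [(pr.read_id, pr.seq1, pr.qual1) for pr in pairs[:n_reads]]
    with tempfile.TemporaryDirectory() as tmp:
        s1, s2 = Path(tmp) / "d.sam", Path(tmp) / "r.sam"
        alignkit.map_reads(reads, alignkit.ReferenceIndex(donor), str(s1))
        alignkit.map_reads(reads, alignkit.ReferenceIndex(ref), str(s2))
        reports = {
            r.reference_id: r
            for r in mapping_rate.unique_mapping_rate(
                {("sim", "donor"): s1, ("sim", "distant"): s2}
            )
        }
    return dict(
        donor_rate_pct=reports["donor"].unique_rate_pct,
        distant_rate_pct=reports["distant"].unique_rate_pct,
        n_reads=len(reads),
    )
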