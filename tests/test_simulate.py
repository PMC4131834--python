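"""Simulator contracts: planted truth must exactly explain the donor."""

import numpy as np
import pytest
from scipy import stats

from pseudoref import simulate
from pseudoref.seqio import revcomp


def apply_truth(ref: dict[str, str], truth: simulate.TruthSet) -> dict[str, str]:
    """Independent event applier used as the round-trip oracle."""
    donor = {}
    snps = {}
    for s in truth.planted_snps:
        snps.setdefault(s.chrom, []).append(s)
    indels = {}
    for e in truth.all_indels():
        indels.setdefault(e.chrom, []).append(e)
    for chrom, seq in ref.items():
        arr = list(seq)
        for s in snps.get(chrom, []):
            assert arr[s.pos] == s.ref_base
            arr[s.pos] = s.alt_base
        out = []
        cur = 0
        for e in sorted(indels.get(chrom, []), key=lambda e: e.pos):
            out.append("".join(arr[cur : e.pos]))
            if e.type == "DEL":
                cur = e.pos + e.size
            else:
                out.append(e.seq)
                cur = e.pos
        out.append("".join(arr[cur:]))
        donor[chrom] = "".join(out)
    return donor


class TestMutateReference:
    def test_zero_rates_yield_identity(self):
        p = simulate.SimParams(ref_length=20_000, snp_rate=0, small_indel_rate=0,
                               large_del_rate=0, large_ins_rate=0, repeat_fraction=0, seed=1)
        ref, tracts = simulate.generate_reference(p)
        donor, truth = simulate.mutate_reference(ref, p, tracts)
        assert donor == ref
        assert not truth.planted_snps and not truth.planted_indels
        assert not truth.planted_small_indels

    def test_snp_count_is_binomial(self):
        p = simulate.SimParams(ref_length=1_000_000, seed=7, small_indel_rate=0,
                               large_del_rate=0, large_ins_rate=0, repeat_fraction=0)
        ref, tracts = simulate.generate_reference(p)
        _, truth = simulate.mutate_reference(ref, p, tracts)
        n, rate = 1_000_000, p.snp_rate
        sigma = np.sqrt(n * rate * (1 - rate))
        assert abs(len(truth.planted_snps) - n * rate) < 3 * sigma

    def test_single_deletion_conserves_length_and_suffix(self):
        p = simulate.SimParams(ref_length=50_000, snp_rate=0, small_indel_rate=0,
                               large_del_rate=0, large_ins_rate=0, repeat_fraction=0, seed=3)
        ref, _ = simulate.generate_reference(p)
        chrom = next(iter(ref))
        truth = simulate.TruthSet(
            planted_indels=[simulate.PlantedIndel(chrom, 10_000, "DEL", 4_000)]
        )
        donor = apply_truth(ref, truth)
        assert len(donor[chrom]) == len(ref[chrom]) - 4_000
        assert donor[chrom][10_000:] == ref[chrom][14_000:]

    def test_round_trip_reconstruction(self, small_world):
        """Applying the truth table to the reference reproduces the donor byte-for-byte."""
        rebuilt = apply_truth(small_world["ref"], small_world["truth"])
        assert rebuilt == small_world["donor"]

    def test_truth_sorted_and_in_bounds(self, small_world):
        truth, ref = small_world["truth"], small_world["ref"]
        positions = [(s.chrom, s.pos) for s in truth.planted_snps]
        assert positions == sorted(positions)
        for e in truth.planted_indels:
            assert 0 <= e.pos < len(ref[e.chrom])
            assert e.size >= 100
            if e.type == "INS":
                assert len(e.seq) == e.size

    def test_deletion_sizes_are_bimodal(self):
        p = simulate.SimParams(ref_length=1_000_000, seed=5)
        rng = p.rng(99)
        sizes = simulate._sample_del_sizes(rng, 500, p)
        hist, edges = np.histogram(sizes, bins=np.arange(0, 20_001, 1_000))
        assert hist[3] + hist[4] > hist[6]          # 3-5 kb mode
        assert hist[11] + hist[12] + hist[13] > hist[8]  # 11-14 kb mode
        assert sizes.min() >= 100 and sizes.max() <= 50_000

    def test_repeat_tagged_deletion_removes_tract(self, small_world):
        truth, tracts = small_world["truth"], small_world["tracts"]
        tract_set = {(c, a, b) for c, ivs in tracts.items() for a, b in ivs}
        tagged = [e for e in truth.planted_indels if e.type == "DEL" and e.repeat_tag]
        assert tagged, "expected repeat-tagged deletions at default rates"
        for e in tagged:
            assert (e.chrom, e.pos, e.pos + e.size) in tract_set

    def test_determinism(self):
        p = simulate.SimParams(ref_length=60_000, seed=11)
        out = []
        for _ in range(2):
            ref, tracts = simulate.generate_reference(p)
            donor, truth = simulate.mutate_reference(ref, p, tracts)
            out.append((ref, donor, [vars(s) for s in truth.planted_snps]))
        assert out[0] == out[1]

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            simulate.SimParams(snp_rate=1.5).validate()
        with pytest.raises(ValueError):
            simulate.SimParams(ref_length=0).validate()
        with pytest.raises(ValueError):
            simulate.SimParams(read_length=400, insert_mean=350).validate()


class TestShearContigs:
    def test_partition_conserves_sequence(self, small_world):
        donor, contigs, placements = (
            small_world["donor"], small_world["contigs"], small_world["placements"],
        )
        assert sum(len(s) for s in contigs.values()) >= sum(len(s) for s in donor.values())
        for pl in placements:
            assert contigs[pl.contig_id] == donor[pl.chrom][pl.donor_start : pl.donor_end]

    def test_n50_near_target(self):
        from pseudoref.scaffold import n50

        p = simulate.SimParams(ref_length=3_000_000, seed=2, snp_rate=0,
                               large_del_rate=0, large_ins_rate=0,
                               small_indel_rate=0, repeat_fraction=0)
        ref, tracts = simulate.generate_reference(p)
        donor, truth = simulate.mutate_reference(ref, p, tracts)
        contigs, _ = simulate.shear_contigs(donor, p, truth)
        observed = n50([len(s) for s in contigs.values()])
        assert abs(observed - p.contig_n50) / p.contig_n50 < 0.20

    def test_single_contig_when_n50_is_chromosome(self):
        p = simulate.SimParams(ref_length=30_000, seed=1, snp_rate=0, small_indel_rate=0,
                               large_del_rate=0, large_ins_rate=0, repeat_fraction=0,
                               contig_n50=30_000)
        ref, tracts = simulate.generate_reference(p)
        donor, truth = simulate.mutate_reference(ref, p, tracts)
        # n50 larger than the chromosome fails
        p_bad = simulate.SimParams(ref_length=30_000, contig_n50=60_000)
        with pytest.raises(ValueError):
            simulate.shear_contigs(donor, p_bad)

    def test_determinism(self, small_world):
        contigs2, _ = simulate.shear_contigs(
            small_world["donor"], small_world["params"], small_world["truth"]
        )
        assert contigs2 == small_world["contigs"]


class TestSimulateReads:
    def test_error_free_reads_are_donor_substrings(self, small_world):
        p = simulate.SimParams(ref_length=200_000, seed=42, read_depth=0.5)
        pairs = simulate.simulate_reads(small_world["donor"], p)
        for pr in pairs[:200]:
            seq = small_world["donor"][pr.chrom]
            assert pr.seq1 == seq[pr.start : pr.start + p.read_length]
            assert pr.seq2 == revcomp(seq[pr.end - p.read_length : pr.end])

    def test_pair_count_matches_depth(self):
        p = simulate.SimParams(ref_length=100_000, seed=9, read_depth=30.0)
        ref, tracts = simulate.generate_reference(p)
        donor, truth = simulate.mutate_reference(ref, p, tracts)
        pairs = simulate.simulate_reads(donor, p)
        L = sum(len(s) for s in donor.values())
        expected = 30.0 * L / (2 * p.read_length)
        assert abs(len(pairs) - expected) / expected < 0.10

    def test_error_rate_and_quality_tagging(self):
        p = simulate.SimParams(ref_length=100_000, seed=9, read_depth=5.0,
                               read_error_rate=0.01)
        ref, tracts = simulate.generate_reference(p)
        donor, truth = simulate.mutate_reference(ref, p, tracts)
        pairs = simulate.simulate_reads(donor, p)
        n_bases = n_err = 0
        for pr in pairs:
            truth_seq = donor[pr.chrom][pr.start : pr.start + p.read_length]
            diffs = [i for i, (a, b) in enumerate(zip(pr.seq1, truth_seq)) if a != b]
            n_bases += len(pr.seq1)
            n_err += len(diffs)
            for i in diffs:
                assert pr.qual1[i] == chr(15 + 33)  # injected errors carry Q15
        rate = n_err / n_bases
        assert 0.005 < rate < 0.015

    def test_fastq_bytes_deterministic(self, tmp_path):
        p = simulate.SimParams(ref_length=50_000, seed=4, read_depth=2.0)
        ref, tracts = simulate.generate_reference(p)
        donor, truth = simulate.mutate_reference(ref, p, tracts)
        payloads = []
        for tag in ("a", "b"):
            pairs = simulate.simulate_reads(donor, p)
            r1, r2 = tmp_path / f"{tag}_1.fq", tmp_path / f"{tag}_2.fq"
            simulate.write_read_pairs_fastq(pairs, r1, r2)
            payloads.append(r1.read_bytes() + r2.read_bytes())
        assert payloads[0] == payloads[1]


class TestSimulateBes:
    def test_fixed_insert_distances(self):
        p = simulate.SimParams(ref_length=300_000, seed=6, bes_insert_mean=100_000,
                               bes_insert_sd=0.0, n_bes_clones=25)
        ref, tracts = simulate.generate_reference(p)
        donor, truth = simulate.mutate_reference(ref, p, tracts)
        reads, clones = simulate.simulate_bes(donor, p)
        assert len(reads) == 2 * len(clones) == 50
        assert all(t.distance == 100_000 for t in clones)

    def test_end_reads_match_truth_coordinates(self):
        p = simulate.SimParams(ref_length=300_000, seed=6, n_bes_clones=10)
        ref, tracts = simulate.generate_reference(p)
        donor, truth = simulate.mutate_reference(ref, p, tracts)
        reads, clones = simulate.simulate_bes(donor, p)
        by_id = {r.bes_id: r for r in reads}
        for t in clones:
            seq = donor[t.chrom]
            assert by_id[t.clone_id + "_F"].seq == seq[t.start : t.start + p.bes_read_len]
            assert by_id[t.clone_id + "_R"].seq == revcomp(seq[t.end - p.bes_read_len : t.end])

    def test_zero_clones_is_empty_not_error(self, small_world):
        reads, clones = simulate.simulate_bes(
            small_world["donor"], small_world["params"]
        )
        assert reads == [] and clones == []


class TestSimulateGenes:
    def test_models_translate_cleanly(self):
        from pseudoref.genes import CODON_TABLE

        p = simulate.SimParams(ref_length=200_000, seed=8)
        ref, _ = simulate.generate_reference(p)
        models, genome = simulate.simulate_genes(ref, 15, p)
        assert len(models) == 15
        for g in models:
            cds = g.coding_sequence(genome)
            assert len(cds) % 3 == 0
            aas = [CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds), 3)]
            assert aas[0] == "M" and aas[-1] == "*"
            assert "*" not in aas[:-1]
            exon_starts = [a for a, _ in g.exons]
            assert exon_starts == sorted(exon_starts)

    def test_splice_motifs_on_coding_strand(self):
        p = simulate.SimParams(ref_length=200_000, seed=8)
        ref, _ = simulate.generate_reference(p)
        models, genome = simulate.simulate_genes(ref, 15, p)
        for g in models:
            for a, b in g.introns:
                if g.strand == "+":
                    motif = genome[g.chrom][a : a + 2] + genome[g.chrom][b - 2 : b]
                else:
                    motif = revcomp(genome[g.chrom][b - 2 : b]) + revcomp(genome[g.chrom][a : a + 2])
                assert motif == "GTAG"

    def test_zero_genes_gives_empty_gff(self, tmp_path):
        from pseudoref import genes as genes_mod

        p = simulate.SimParams(ref_length=50_000, seed=1)
        ref, _ = simulate.generate_reference(p)
        models, genome = simulate.simulate_genes(ref, 0, p)
        path = tmp_path / "empty.gff3"
        genes_mod.write_gff3(models, path)
        text = path.read_text()
        assert text.startswith("##gff-version 3") and len(text.splitlines()) == 1


class TestCoordMap:
    def test_round_trip_outside_events(self, small_world):
        cmap = small_world["truth"].coord_map()
        chrom = next(iter(small_world["donor"]))
        rng = np.random.default_rng(0)
        for d in rng.integers(0, len(small_world["donor"][chrom]), 200):
            r = cmap.donor_to_ref(chrom, int(d))
            d2 = cmap.ref_to_donor(chrom, r)
            # identical except for positions inside insertions, which collapse
            assert cmap.donor_to_ref(chrom, d2) == r

    def test_insertion_interval_matches_sequence(self, small_world):
        cmap = small_world["truth"].coord_map()
        donor = small_world["donor"]
        for e in small_world["truth"].planted_indels:
            if e.type != "INS":
                continue
            d0 = cmap.ref_to_donor(e.chrom, e.pos)
            assert donor[e.chrom][d0 : d0 + e.size] == e.seq
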