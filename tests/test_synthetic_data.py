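"""Simulator correctness: genome evolution, reads, mixing, emulated alignments."""

import numpy as np
import pysam
import pytest

from graftfilter.synthetic_data import (
    evaluate_classification,
    evolve_pair,
    emulate_alignments,
    mix_read_sets,
    simulate_reads,
)

SEED = 20260929 % 100000


def seq_diff_positions(a: str, b: str) -> np.ndarray:
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    return aa != bb


class TestEvolvePair:
    def test_zero_divergence_is_identity(self):
        pair = evolve_pair(2000, divergence=0.0, conserved_fraction=0.0,
                           conserved_divergence=0.0, indel_rate=0.0, seed=SEED)
        assert pair.graft_genome == pair.ancestor == pair.host_genome

    def test_same_seed_reproduces_sequences(self):
        a = evolve_pair(5000, seed=SEED)
        b = evolve_pair(5000, seed=SEED)
        assert a.graft_genome == b.graft_genome
        assert a.host_genome == b.host_genome

    def test_pairwise_divergence_matches_two_branch_binomial_oracle(self):
        """Site-wise oracle: two independent branches each substitute with
        probability d (uniform among the 3 other bases), so a site differs
        between the genomes with probability 2d(1-d) + (2/3)d^2."""
        L, d = 100_000, 0.08
        pair = evolve_pair(L, divergence=d, conserved_fraction=0.0,
                           conserved_divergence=0.0, indel_rate=0.0, seed=SEED)
        p_diff = 2 * d * (1 - d) + (2.0 / 3.0) * d * d
        observed = int(seq_diff_positions(pair.graft_genome, pair.host_genome).sum())
        expected = L * p_diff
        sd = np.sqrt(L * p_diff * (1 - p_diff))
        assert abs(observed - expected) <= 5 * sd

    def test_conserved_intervals_diverge_at_their_own_rate(self):
        L = 200_000
        pair = evolve_pair(L, divergence=0.08, conserved_fraction=0.2,
                           conserved_divergence=0.01, indel_rate=0.0, seed=SEED)
        diffs = seq_diff_positions(pair.graft_genome, pair.host_genome)
        cons = np.zeros(L, dtype=bool)
        for s, e in pair.conserved_intervals:
            cons[s:e] = True
        assert abs(cons.sum() - 0.2 * L) <= 0.01 * L
        for mask, d in ((cons, 0.01), (~cons, 0.08)):
            p = 2 * d * (1 - d) + (2.0 / 3.0) * d * d
            n = int(mask.sum())
            obs = int(diffs[mask].sum())
            assert abs(obs - n * p) <= 5 * np.sqrt(n * p * (1 - p))

    def test_coordinate_maps_are_mutually_inverse(self):
        pair = evolve_pair(20_000, indel_rate=1e-3, seed=SEED)
        for g2a, a2g, genome in (
            (pair.graft2anc, pair.anc2graft, pair.graft_genome),
            (pair.host2anc, pair.anc2host, pair.host_genome),
        ):
            assert g2a.size == len(genome)
            kept = np.nonzero(a2g >= 0)[0]
            assert np.array_equal(g2a[a2g[kept]], kept)

    @pytest.mark.parametrize("bad", [
        {"divergence": 1.5}, {"indel_rate": -0.1}, {"conserved_fraction": 2.0},
    ])
    def test_invalid_probabilities_are_fatal(self, bad):
        with pytest.raises(ValueError):
            evolve_pair(2000, **bad)


class TestSimulateReads:
    def test_error_free_reads_are_exact_substrings(self):
        pair = evolve_pair(10_000, indel_rate=0.0, seed=SEED)
        rs = simulate_reads(pair.graft_genome, 100, read_length=80, paired=False,
                            error_rate=0.0, seed=SEED)
        for seq, start, rev in zip(rs.sequences(), rs.starts1, rs.rev1):
            window = pair.graft_genome[start : start + 80]
            if rev:
                comp = str.maketrans("ACGT", "TGCA")
                window = window.translate(comp)[::-1]
            assert seq == window

    def test_realized_error_rate_within_binomial_bounds(self):
        pair = evolve_pair(50_000, indel_rate=0.0, seed=SEED)
        n, rl, e = 10_000, 100, 0.01
        rs = simulate_reads(pair.graft_genome, n, read_length=rl, paired=False,
                            error_rate=e, seed=SEED)
        gcodes = pair.genome_codes("graft")
        idx = rs.starts1[:, None] + np.arange(rl)
        fwd = np.where(rs.rev1[:, None], (3 - rs.codes1)[:, ::-1], rs.codes1)
        mismatches = int((fwd != gcodes[idx]).sum())
        total = n * rl
        assert abs(mismatches - total * e) <= 5 * np.sqrt(total * e * (1 - e))

    def test_paired_mates_face_each_other_at_sane_inserts(self):
        pair = evolve_pair(20_000, indel_rate=0.0, seed=SEED)
        rs = simulate_reads(pair.graft_genome, 500, read_length=100, paired=True,
                            insert_mean=300, insert_sd=30, error_rate=0.0, seed=SEED)
        assert np.array_equal(rs.rev1, ~rs.rev2)
        inserts = np.abs(rs.starts2 - rs.starts1) + 100
        assert inserts.min() >= 100
        assert 250 < inserts.mean() < 350

    def test_truth_covers_every_read_exactly_once(self):
        pair = evolve_pair(5_000, seed=SEED)
        rs = simulate_reads(pair.graft_genome, 200, seed=SEED, species="graft")
        truth = rs.truth()
        assert len(truth) == 200
        assert set(truth) == set(map(str, rs.names))

    def test_nonpositive_n_is_fatal(self):
        pair = evolve_pair(5_000, seed=SEED)
        with pytest.raises(ValueError):
            simulate_reads(pair.graft_genome, 0, seed=SEED)


@pytest.fixture(scope="module")
def sets():
    pair = evolve_pair(20_000, seed=SEED)
    g = simulate_reads(pair.graft_genome, 800, seed=SEED + 1, species="graft")
    h = simulate_reads(pair.host_genome, 800, seed=SEED + 2, species="host")
    return g, h


class TestMixReadSets:

    def test_exact_composition(self, sets):
        mix = mix_read_sets(*sets, graft_fraction=0.75, total_n=1000, seed=SEED)
        species = list(mix.species)
        assert species.count("graft") == 750
        assert species.count("host") == 250

    def test_all_graft_fraction(self, sets):
        mix = mix_read_sets(*sets, graft_fraction=1.0, total_n=500, seed=SEED)
        assert set(mix.species) == {"graft"}

    def test_seed_changes_order_not_composition(self, sets):
        g, h = sets
        m1 = mix_read_sets(g, h, graft_fraction=0.5, total_n=1600, seed=1)
        m2 = mix_read_sets(g, h, graft_fraction=0.5, total_n=1600, seed=2)
        # exhaustive subsample: identical membership, seed-dependent order
        assert sorted(m1.names) == sorted(m2.names)
        assert list(m1.names) != list(m2.names)
        assert list(m1.species).count("graft") == list(m2.species).count("graft") == 800

    def test_insufficient_source_is_fatal(self, sets):
        with pytest.raises(ValueError):
            mix_read_sets(*sets, graft_fraction=0.5, total_n=10_000, seed=SEED)


class TestEmulateAlignments:
    def test_identical_genomes_give_full_match_nm_zero(self, tmp_path):
        pair = evolve_pair(5_000, divergence=0.0, conserved_fraction=0.0,
                           conserved_divergence=0.0, indel_rate=0.0, seed=SEED)
        rs = simulate_reads(pair.graft_genome, 50, read_length=60, paired=False,
                            error_rate=0.0, seed=SEED, species="graft")
        gp, hp = emulate_alignments(rs, pair, str(tmp_path / "g.bam"), str(tmp_path / "h.bam"))
        for path in (gp, hp):
            with pysam.AlignmentFile(path, check_sq=False) as bam:
                for seg in bam:
                    assert seg.cigarstring == "60M"
                    assert seg.get_tag("NM") == 0

    def test_cross_species_nm_counts_substituted_sites(self, tmp_path):
        """With colinear genomes (no indels) and error-free reads, the host-side
        NM of a graft read equals the inter-genome differences in its window,
        counted independently from the sequences."""
        pair = evolve_pair(20_000, indel_rate=0.0, seed=SEED)
        rs = simulate_reads(pair.graft_genome, 100, read_length=100, paired=False,
                            error_rate=0.0, seed=SEED, species="graft")
        _, hp = emulate_alignments(rs, pair, str(tmp_path / "g.bam"), str(tmp_path / "h.bam"))
        diffs = seq_diff_positions(pair.graft_genome, pair.host_genome)
        expected = {
            str(name): int(diffs[s : s + 100].sum())
            for name, s in zip(rs.names, rs.starts1)
        }
        with pysam.AlignmentFile(hp, check_sq=False) as bam:
            n_mapped = 0
            for seg in bam:
                if seg.is_unmapped:
                    assert expected[seg.query_name] > 20  # below identity floor
                    continue
                n_mapped += 1
                assert seg.cigarstring == "100M"
                assert seg.get_tag("NM") == expected[seg.query_name]
        assert n_mapped > 80

    def test_indel_region_reads_are_unmapped_or_gapped(self, tmp_path):
        pair = evolve_pair(20_000, indel_rate=2e-3, seed=SEED)
        rs = simulate_reads(pair.graft_genome, 300, read_length=100, paired=False,
                            error_rate=0.0, seed=SEED, species="graft")
        _, hp = emulate_alignments(rs, pair, str(tmp_path / "g.bam"), str(tmp_path / "h.bam"))
        gapped = unmapped = 0
        with pysam.AlignmentFile(hp, check_sq=False) as bam:
            for seg in bam:
                if seg.is_unmapped:
                    unmapped += 1
                elif any(op in (1, 2, 4) for op, _ in seg.cigartuples):
                    gapped += 1
        assert gapped + unmapped > 0

    def test_emulated_nm_is_sam_conforming(self, tmp_path):
        """Walk each gapped CIGAR against the genome: NM must equal
        mismatches + inserted + deleted bases (soft clips excluded)."""
        pair = evolve_pair(20_000, indel_rate=2e-3, seed=SEED + 7)
        rs = simulate_reads(pair.graft_genome, 200, read_length=100, paired=False,
                            error_rate=0.01, seed=SEED + 7, species="graft")
        _, hp = emulate_alignments(rs, pair, str(tmp_path / "g.bam"), str(tmp_path / "h.bam"))
        host = pair.host_genome
        checked = 0
        with pysam.AlignmentFile(hp, check_sq=False) as bam:
            for seg in bam:
                if seg.is_unmapped:
                    continue
                read = seg.query_sequence
                rpos, gpos = 0, seg.reference_start
                mm = ins = dele = 0
                for op, length in seg.cigartuples:
                    if op == 0:  # M
                        mm += sum(
                            1 for a, b in zip(read[rpos : rpos + length],
                                              host[gpos : gpos + length]) if a != b
                        )
                        rpos += length
                        gpos += length
                    elif op == 1:
                        ins += length
                        rpos += length
                    elif op == 2:
                        dele += length
                        gpos += length
                    elif op == 4:
                        rpos += length
                assert seg.get_tag("NM") == mm + ins + dele
                checked += 1
        assert checked > 150


class TestEvaluateClassification:
    def test_perfect_and_degenerate_outcomes(self, tmp_path):
        pair = evolve_pair(20_000, indel_rate=0.0, seed=SEED)
        g = simulate_reads(pair.graft_genome, 50, seed=SEED + 1, species="graft")
        h = simulate_reads(pair.host_genome, 50, seed=SEED + 2, species="host")
        mix = mix_read_sets(g, h, 0.5, 100, seed=SEED)
        truth = mix.truth()
        # simulate a perfect filter: graft output holds exactly the graft names
        import conftest

        graft_names = [n for n, rec in truth.items() if rec[0] == "graft"]
        host_names = [n for n, rec in truth.items() if rec[0] == "host"]
        gp = conftest.write_sam(tmp_path / "g.bam",
                                [conftest.make_segment(n) for n in graft_names])
        hp = conftest.write_sam(tmp_path / "h.bam",
                                [conftest.make_segment(n) for n in host_names])
        res = evaluate_classification(truth, gp, hp)
        assert res.host_removal_pct == 100.0
        assert res.graft_retention_pct == 100.0
        assert res.confusion["host"]["in_host_output"] == 50

        empty = conftest.write_sam(tmp_path / "e.bam", [])
        res2 = evaluate_classification(truth, empty, None)
        assert res2.graft_retention_pct == 0.0
        assert res2.host_removal_pct == 100.0

    def test_unknown_output_name_is_fatal(self, tmp_path):
        import conftest

        gp = conftest.write_sam(tmp_path / "g.bam", [conftest.make_segment("ghost")])
        with pytest.raises(ValueError, match="truth"):
            evaluate_classification({"known": ("graft", 1, "+")}, gp)
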