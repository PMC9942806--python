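import numpy as np
import pandas as pd
import pytest

from macsome.alnio import read_paf, write_paf
from macsome.dnds import CodonAlignment, GeneticCode, ng86
from macsome.simulate import (
    Junction,
    annotations_from_truth,
    sample_read_layout,
    simulate_codon_pair,
    simulate_expression,
    simulate_mac_genome,
    simulate_reads,
)


class TestGenome:
    def test_zero_density_gives_zero_junctions(self):
        g = simulate_mac_genome(n_contigs=1, contig_length=50_000, junction_density=0.0, seed=1)
        assert g.junction_table().empty
        assert len(g.contigs["contig_1"]) == 50_000

    def test_determinism(self):
        a = simulate_mac_genome(seed=9)
        b = simulate_mac_genome(seed=9)
        assert a.contigs == b.contigs
        assert a.junction_table().equals(b.junction_table())

    def test_junction_count_is_poisson(self):
        # 1 junction per 10 kbp on 100 kbp -> mean 10; check the mean of
        # 150 independent draws against a 4-sigma band of the Poisson SE
        counts = [
            len(simulate_mac_genome(
                n_contigs=1, contig_length=100_000, junction_density=1e-4, seed=s
            ).junctions["contig_1"])
            for s in range(150)
        ]
        se = np.sqrt(10.0 / len(counts))
        assert abs(np.mean(counts) - 10.0) < 4 * se

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            simulate_mac_genome(n_contigs=1, contig_length=-5, seed=0)
        with pytest.raises(ValueError):
            simulate_mac_genome(usage_range=(0.0, 0.5), seed=0)
        with pytest.raises(ValueError):
            Junction(pos=100, side="left", usage=0.0)

    def test_at_fraction_of_simulated_genome(self):
        from macsome.arch import at_fraction

        g = simulate_mac_genome(n_contigs=2, contig_length=200_000, seed=4)
        assert at_fraction(g.contigs) == pytest.approx(0.66, abs=0.01)


class TestReads:
    def test_determinism(self):
        g = simulate_mac_genome(n_contigs=2, contig_length=60_000, seed=0)
        a = simulate_reads(g, n_reads=300, seed=5)
        b = simulate_reads(g, n_reads=300, seed=5)
        assert a.reads == b.reads
        assert a.truth.equals(b.truth)
        assert [r.to_paf_line() for r in a.alignments] == [r.to_paf_line() for r in b.alignments]

    def test_interior_reads_have_no_telomere(self):
        g = simulate_mac_genome(n_contigs=1, contig_length=200_000, junction_density=0.0, seed=2)
        sim = simulate_reads(g, n_reads=500, error_rate=0.0, seed=3)
        interior = sim.truth[
            (sim.truth.frag_start > 100) & (sim.truth.frag_end < sim.truth.frag_end.max() - 100)
        ]
        assert not interior.has_telo_5p.any() and not interior.has_telo_3p.any()

    def test_molecule_end_reads_carry_tract(self):
        g = simulate_mac_genome(n_contigs=1, contig_length=50_000, junction_density=0.0, seed=2)
        sim = simulate_reads(g, n_reads=400, error_rate=0.0, seed=3)
        ends = sim.truth[sim.truth.frag_start == 0]
        assert len(ends) > 0
        assert (ends.telo_5p_span >= 24).all() if (ends.strand == "+").all() else True
        capped = ends[ends.strand == "+"]
        assert (capped.n_repeats_5p >= 3).all()

    def test_telo_fraction_matches_closed_form(self):
        # p -> 2*Lbar/M for molecules much longer than reads
        g = simulate_mac_genome(n_contigs=10, contig_length=130_000, junction_density=0.0, seed=7)
        lay = sample_read_layout(g, 20_000, seed=8)
        t = lay.truth
        p = (t.has_telo_5p | t.has_telo_3p).mean()
        lbar = (t.read_len - t.telo_5p_span - t.telo_3p_span).mean()
        expected = 2 * lbar / 130_000
        se = np.sqrt(expected * (1 - expected) / len(t))
        assert abs(p - expected) < 3 * se

    def test_truth_paf_round_trips(self, tmp_path):
        g = simulate_mac_genome(n_contigs=2, contig_length=40_000, seed=1)
        sim = simulate_reads(g, n_reads=200, seed=2)
        path = tmp_path / "truth.paf"
        write_paf(sim.alignments, path)
        back = read_paf(path)
        assert back == sim.alignments

    def test_empty_genome_rejected(self):
        from macsome.simulate import SimGenomeTruth

        empty = SimGenomeTruth(contigs={}, junctions={}, seed=0, at_frac=0.66)
        with pytest.raises(ValueError):
            simulate_reads(empty, 10)

    def test_annotations_from_truth_match_scanner(self, motif):
        from macsome.telomere import classify_read, find_runs

        g = simulate_mac_genome(n_contigs=1, contig_length=60_000, seed=11)
        sim = simulate_reads(g, n_reads=300, error_rate=0.0, seed=12)
        direct = {
            rid: classify_read(rid, len(seq), find_runs(seq, motif)).cls
            for rid, seq in sim.reads
        }
        rebuilt = {a.read_id: a.cls for a in annotations_from_truth(sim.truth)}
        assert direct == rebuilt


class TestCodonPair:
    def test_t_zero_identical(self):
        a, b, truth = simulate_codon_pair(0.5, 0.0, 100, "standard", seed=1)
        assert a == b and len(a) == 300

    def test_no_stop_codons_either_code(self):
        for code_name in ("standard", "uga_trp"):
            code = GeneticCode.from_name(code_name)
            a, b, _ = simulate_codon_pair(1.0, 0.5, 300, code_name, seed=2)
            for seq in (a, b):
                assert all(seq[i : i + 3] not in code.stops for i in range(0, len(seq), 3))

    def test_omega_ordering_preserved(self):
        lows, highs = [], []
        for rep in range(5):
            a, b, _ = simulate_codon_pair(0.05, 0.4, 800, "standard", seed=30 + rep)
            lows.append(ng86(CodonAlignment.from_sequences(a, b)).omega)
            a, b, _ = simulate_codon_pair(0.5, 0.4, 800, "standard", seed=60 + rep)
            highs.append(ng86(CodonAlignment.from_sequences(a, b)).omega)
        assert max(lows) < min(highs)


class TestExpression:
    def test_determinism(self):
        a = simulate_expression(n_genes=200, n_planted=10, seed=5)
        b = simulate_expression(n_genes=200, n_planted=10, seed=5)
        assert a.counts.equals(b.counts) and a.planted.equals(b.planted)

    def test_low_dispersion_recovers_planted_fc(self):
        sim = simulate_expression(
            n_genes=2_000,
            n_planted=20,
            fc_range=(100.0, 100.0),
            dispersion=1e-4,
            base_mean_log_mu=5.0,
            libsize_sigma=0.0,
            seed=6,
        )
        mat = sim.counts
        fc = (mat[sim.target] + 0.5) / (mat[sim.baselines].mean(axis=1) + 0.5)
        got = fc.loc[sim.planted.index]
        assert got.mean() == pytest.approx(100.0, rel=0.10)
        assert np.median(got) == pytest.approx(100.0, rel=0.10)

    def test_no_planted_genes_fcs_near_one(self):
        sim = simulate_expression(
            n_genes=2_000, n_planted=0, dispersion=0.02, base_mean_log_mu=5.0,
            libsize_sigma=0.0, seed=7,
        )
        fc = (sim.counts[sim.target] + 0.5) / (sim.counts[sim.baselines].mean(axis=1) + 0.5)
        assert fc.sort_values(ascending=False).head(20).max() < 3.0
        assert np.median(fc) == pytest.approx(1.0, abs=0.1)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            simulate_expression(dispersion=0.0)
        with pytest.raises(ValueError):
            simulate_expression(n_genes=10, n_planted=20)
        with pytest.raises(ValueError):
            simulate_expression(fc_range=(0.5, 2.0))
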