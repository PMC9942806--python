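import math

import numpy as np
import pytest

from macsome.dnds import (
    CodonAlignment,
    GeneticCode,
    back_align,
    ng86,
    omega,
    pair_codon_alignment,
    pairwise_matrix,
)

from .oracles import oracle_ng86_codon, sense_codons


class TestGeneticCode:
    def test_uga_trp_differs_only_at_tga(self):
        std, uga = GeneticCode.standard(), GeneticCode.uga_trp()
        assert uga.table["TGA"] == "W"
        assert std.stops - uga.stops == {"TGA"}
        assert all(uga.table[c] == std.table[c] for c in std.table)

    def test_unknown_name(self):
        with pytest.raises(ValueError):
            GeneticCode.from_name("vertebrate-mito")


class TestCodonAlignment:
    def test_rejects_mismatched_or_out_of_frame(self):
        with pytest.raises(ValueError):
            CodonAlignment.from_sequences("ATGAAA", "ATG")
        with pytest.raises(ValueError):
            CodonAlignment.from_sequences("ATGA", "ATGA")

    def test_whole_codon_gaps_dropped_pairwise(self):
        aln = CodonAlignment.from_sequences("ATG---AAA", "ATGTTTAAA")
        assert aln.n_codons == 2

    def test_partial_codon_gap_rejected(self):
        with pytest.raises(ValueError, match="partial-codon gap"):
            CodonAlignment.from_sequences("ATGA--AAA", "ATGTTTAAA")

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            CodonAlignment.from_sequences("ATGTAAAAA", "ATGTTTAAA")

    def test_shared_terminal_stop_stripped(self):
        aln = CodonAlignment.from_sequences("ATGTAA", "ATGTGA")
        assert aln.n_codons == 1


class TestNG86:
    def test_identical_sequences(self):
        r = ng86(CodonAlignment.from_sequences("ATGGCTAAA", "ATGGCTAAA"))
        assert (r.Nd, r.Sd, r.dN, r.dS) == (0.0, 0.0, 0.0, 0.0)
        assert math.isnan(r.omega)  # 0/0 undefined

    def test_phe_phe_synonymous_saturation(self):
        # TTT vs TTC: one synonymous difference on 1/3 synonymous site;
        # pS = 3 >= 3/4 saturates the JC correction
        r = ng86(CodonAlignment.from_sequences("TTT", "TTC"))
        assert (r.Nd, r.Sd) == (0.0, 1.0)
        assert r.S == pytest.approx(1 / 3)
        assert r.pS == pytest.approx(3.0)
        assert math.isnan(r.dS) and "dS_saturated" in r.flags

    def test_site_conservation(self):
        rng = np.random.default_rng(2)
        for code_name in ("standard", "uga_trp"):
            code = GeneticCode.from_name(code_name)
            sense = sense_codons(code.id)
            s = "".join(rng.choice(sense, size=50))
            t = "".join(rng.choice(sense, size=50))
            try:
                r = ng86(CodonAlignment.from_sequences(s, t, code))
            except ValueError:
                continue
            assert r.N + r.S == pytest.approx(3 * r.n_codons)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        code = GeneticCode.uga_trp()
        sense = sense_codons(code.id)
        for _ in range(10):
            s = "".join(rng.choice(sense, size=30))
            t = "".join(rng.choice(sense, size=30))
            a, b = ng86(CodonAlignment.from_sequences(s, t, code)), ng86(
                CodonAlignment.from_sequences(t, s, code)
            )
            for f in ("N", "S", "Nd", "Sd", "pN", "pS"):
                assert getattr(a, f) == pytest.approx(getattr(b, f))

    def test_matches_enumeration_oracle_on_codon_pairs(self):
        """Single-codon alignments across a seeded sample of sense-codon
        pairs agree with the independent pathway-enumeration oracle (the
        full exhaustive sweep runs in the acceptance suite)."""
        rng = np.random.default_rng(4)
        for code_name in ("standard", "UGA_to_Trp"):
            code = GeneticCode.from_name(code_name)
            sense = sense_codons(code.id)
            pairs = [(rng.choice(sense), rng.choice(sense)) for _ in range(150)]
            for c1, c2 in pairs:
                r = ng86(CodonAlignment.from_sequences(c1, c2, code))
                o = oracle_ng86_codon(c1, c2, code.id)
                assert r.S == pytest.approx((o["S1"] + o["S2"]) / 2)
                assert r.Nd == pytest.approx(o["Nd"])
                assert r.Sd == pytest.approx(o["Sd"])

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            ng86(CodonAlignment(codons1=[], codons2=[], code=GeneticCode.standard()))


class TestOmega:
    @pytest.mark.parametrize(
        "dn,ds,expected",
        [(0.02, 0.2, 0.1), (0.0, 0.5, 0.0)],
    )
    def test_ratio(self, dn, ds, expected):
        assert omega(dn, ds) == pytest.approx(expected)

    def test_markers(self):
        assert math.isnan(omega(0.0, 0.0))
        assert omega(0.1, 0.0) == math.inf
        with pytest.raises(ValueError):
            omega(-0.1, 0.2)


class TestBackAlign:
    def test_gapless_identity(self):
        aln = {"a": "MK", "b": "MK"}
        cds = {"a": "ATGAAA", "b": "ATGAAG"}
        out = back_align(aln, cds)
        assert out == {"a": "ATGAAA", "b": "ATGAAG"}

    def test_two_residue_gap_drops_six_nt(self):
        aln = {"a": "MKLF", "b": "M--F"}
        cds = {"a": "ATGAAACTTTTT", "b": "ATGTTC"}
        out = back_align(aln, cds)
        pair = CodonAlignment.from_sequences(out["a"], out["b"])
        assert pair.n_codons == 2  # 6 nt dropped

    def test_terminal_stop_stripped_under_standard(self):
        out = back_align({"a": "MK"}, {"a": "ATGAAATGA"})
        assert out["a"] == "ATGAAA"

    def test_terminal_tga_retained_under_uga_trp(self):
        # TGA is Trp under the reassigned code: a coding codon, not a stop
        out = back_align({"a": "MKW"}, {"a": "ATGAAATGA"}, GeneticCode.uga_trp())
        assert out["a"] == "ATGAAATGA"

    def test_translation_mismatch_names_residue(self):
        with pytest.raises(ValueError, match="residue 2"):
            back_align({"a": "MF"}, {"a": "ATGAAA"})


class TestPairwiseMatrix:
    def _alignments(self):
        code = GeneticCode.standard()
        mk = lambda s, t: CodonAlignment.from_sequences(s, t, code)
        return {
            frozenset({"ref", "x"}): mk("ATGAAACCC", "ATGAAGCCA"),
            frozenset({"ref", "y"}): mk("ATGAAACCC", "ATGCAACCC"),
        }

    def test_row_per_pair_and_missing_na(self):
        df = pairwise_matrix("ref", ["x", "y", "z"], self._alignments())
        assert list(df["other"]) == ["x", "y", "z"]
        assert df.loc[2, "flags"] == "missing_alignment"
        assert math.isnan(df.loc[2, "omega"])

    def test_swap_symmetry(self):
        s, t = "ATGAAACCCGGGTTTGCA", "ATGAAGCCCGGGTCTGCA"  # one syn + one nonsyn diff
        a = pairwise_matrix("ref", ["x"], {frozenset({"ref", "x"}): CodonAlignment.from_sequences(s, t)}).loc[0]
        b = pairwise_matrix("x", ["ref"], {frozenset({"x", "ref"}): CodonAlignment.from_sequences(t, s)}).loc[0]
        assert a["omega"] == pytest.approx(b["omega"])
        assert a["Nd"] == pytest.approx(b["Nd"]) and a["Sd"] == pytest.approx(b["Sd"])

    def test_planted_omega_rank_order(self):
        """Estimates across a planted-omega panel preserve the planted
        order in every seeded replicate."""
        from macsome.simulate import simulate_codon_pair

        n_correct = 0
        reps = 10
        for rep in range(reps):
            ests = []
            for i, w in enumerate((0.05, 0.2, 1.0)):
                a, b, _ = simulate_codon_pair(w, 0.4, 600, "standard", seed=rep * 10 + i)
                ests.append(ng86(CodonAlignment.from_sequences(a, b)).omega)
            n_correct += ests[0] < ests[1] < ests[2]
        assert n_correct >= 0.95 * reps
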