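"""Mutation load: codon-level effect classification (both strands, splice
sites, reference mismatches), impact-stratified genotype accounting, the
unfolded SFS, and the Rxy relative-load statistic with its exact identities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from founderpop import mutation_load as ml
from founderpop.variant_store import GenotypeMatrix, MISSING, PopulationSpec
from .conftest import make_matrix

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_RC = str.maketrans("ACGT", "TGCA")


def write_gene(tmp_path, cds_seq, strand="+", upstream="GGGGGGGGGG",
               downstream="CCCCCCCCCC", name="g1"):
    """One single-exon gene on a small contig; returns (gff, fasta, cds_start)."""
    if strand == "-":
        genomic_cds = cds_seq.translate(_RC)[::-1]
    else:
        genomic_cds = cds_seq
    contig = upstream + genomic_cds + downstream
    fasta = tmp_path / f"{name}.fa"
    fasta.write_text(f">chr1\n{contig}\n")
    start = len(upstream) + 1
    end = start + len(genomic_cds) - 1
    gff = tmp_path / f"{name}.gff3"
    gff.write_text(
        "##gff-version 3\n"
        f"chr1\tsrc\tgene\t{start}\t{end}\t.\t{strand}\t.\tID=gene_{name}\n"
        f"chr1\tsrc\tmRNA\t{start}\t{end}\t.\t{strand}\t.\tID=t_{name};"
        f"Parent=gene_{name}\n"
        f"chr1\tsrc\tCDS\t{start}\t{end}\t.\t{strand}\t0\tID=c_{name};"
        f"Parent=t_{name}\n")
    return gff, fasta, start


def site_matrix(contig_fa, positions, alts):
    from pyfaidx import Fasta

    fa = Fasta(str(contig_fa), rebuild=False)
    refs = [str(fa["chr1"][p - 1]).upper() for p in positions]
    sites = pd.DataFrame({"chrom": "chr1", "pos": positions, "ref": refs,
                          "alt": alts, "ancestral": "ref"})
    g = np.ones((1, len(positions)), dtype=np.int8)
    return GenotypeMatrix(["s1"], sites, g,
                          contig_lengths={"chr1": 10_000})


class TestClassifyEffects:
    def test_stop_gain_is_high(self, tmp_path):
        gff, fa, start = write_gene(tmp_path, "ATG" + "CAA" + "TGG" + "TAA")
        # CAA -> TAA at codon 2 position 1 (genomic start+3)
        gm = site_matrix(fa, [start + 3], ["T"])
        cats = ml.classify_effects(gm, gff, fa)
        assert cats.iloc[0] == "HIGH"

    def test_synonymous_and_missense(self, tmp_path):
        gff, fa, start = write_gene(tmp_path, "ATG" + "CTT" + "GAA" + "TAA")
        gm = site_matrix(fa, [start + 5, start + 7], ["C", "T"])
        cats = ml.classify_effects(gm, gff, fa)
        assert cats.iloc[0] == "LOW"       # CTT -> CTC (Leu -> Leu)
        assert cats.iloc[1] == "MODERATE"  # GAA -> GTA (Glu -> Val)

    def test_stop_loss_and_start_loss_are_high(self, tmp_path):
        gff, fa, start = write_gene(tmp_path, "ATG" + "AAA" + "TAA")
        gm = site_matrix(fa, [start + 1, start + 7], ["C", "C"])
        cats = ml.classify_effects(gm, gff, fa)
        assert cats.iloc[0] == "HIGH"      # ATG -> ACG start-loss
        assert cats.iloc[1] == "HIGH"      # TAA -> TCA stop-loss

    def test_minus_strand_matches_plus_strand_construction(self, tmp_path):
        """A gene and its reverse-complement placement classify identically."""
        cds = "ATGCATCGTGCTTGGAGTTTGCCAGAGTAA"
        for codon_pos in range(3, len(cds) - 3):
            base = cds[codon_pos]
            for alt in "ACGT":
                if alt == base:
                    continue
                gffp, fap, sp = write_gene(tmp_path, cds, "+",
                                           name=f"p{codon_pos}")
                gmp = site_matrix(fap, [sp + codon_pos], [alt])
                plus = ml.classify_effects(gmp, gffp, fap).iloc[0]
                gffm, fam, sm = write_gene(tmp_path, cds, "-",
                                           name=f"m{codon_pos}")
                # genomic coordinate of the same CDS base on the minus strand
                gpos = sm + (len(cds) - 1 - codon_pos)
                galt = alt.translate(_RC)
                gmm = site_matrix(fam, [gpos], [galt])
                minus = ml.classify_effects(gmm, gffm, fam).iloc[0]
                assert plus == minus, (codon_pos, base, alt)
                break  # one alt per position keeps this quick

    def test_splice_site_disruption_high(self, tmp_path):
        # two-exon gene; +-2 bp around the intron boundary is HIGH
        contig = "G" * 10 + "ATGAAA" + "GTAAGTTTTTAG" + "CCGTAA" + "C" * 10
        fa = tmp_path / "sp.fa"
        fa.write_text(f">chr1\n{contig}\n")
        gff = tmp_path / "sp.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tmRNA\t11\t34\t.\t+\t.\tID=t1\n"
            "chr1\tsrc\tCDS\t11\t16\t.\t+\t0\tID=c1;Parent=t1\n"
            "chr1\tsrc\tCDS\t29\t34\t.\t+\t0\tID=c2;Parent=t1\n")
        gm = site_matrix(fa, [17, 18, 19, 27, 28], ["C", "C", "C", "C", "T"])
        cats = ml.classify_effects(gm, gff, fa)
        assert list(cats[[0, 1, 3, 4]]) == ["HIGH"] * 4  # donor/acceptor +-2 bp
        assert cats.iloc[2] is None                      # deeper intronic

    def test_noncoding_and_reference_mismatch_excluded(self, tmp_path):
        gff, fa, start = write_gene(tmp_path, "ATGAAATAA")
        gm = site_matrix(fa, [2, start + 4], ["A", "C"])
        gm.sites.loc[1, "ref"] = "T" if gm.sites.loc[1, "ref"] != "T" else "G"
        cats = ml.classify_effects(gm, gff, fa)
        assert cats.iloc[0] is None   # upstream of the gene
        assert cats.iloc[1] is None   # REF mismatch -> excluded

    def test_agrees_with_naive_translation_oracle(self, tmp_path, rng):
        """Random single-exon genes: classification matches an independent
        direct-translation oracle at every coding position."""
        bases = np.array(list("ACGT"))
        n_checked = 0
        for gi in range(25):
            n_codons = int(rng.integers(4, 12))
            mid = "".join(rng.choice(bases, 3 * n_codons))
            cds = "ATG" + mid + "TAA"
            strand = "+" if gi % 2 == 0 else "-"
            gff, fa, start = write_gene(tmp_path, cds, strand, name=f"r{gi}")
            length = len(cds)
            pos_in_cds = int(rng.integers(0, length))
            genomic = (start + pos_in_cds if strand == "+"
                       else start + (length - 1 - pos_in_cds))
            cds_base = cds[pos_in_cds]
            alt_cds = str(rng.choice(bases[bases != cds_base]))
            alt_genomic = alt_cds if strand == "+" else alt_cds.translate(_RC)
            gm = site_matrix(fa, [genomic], [alt_genomic])
            got = ml.classify_effects(gm, gff, fa).iloc[0]

            # oracle: translate the whole CDS before/after the edit
            edited = cds[:pos_in_cds] + alt_cds + cds[pos_in_cds + 1:]
            def protein(s):
                return "".join(CODON_TABLE[s[i:i + 3]]
                               for i in range(0, len(s), 3))
            ref_aa, alt_aa = protein(cds), protein(edited)
            ci = pos_in_cds // 3
            if ci == 0 and edited[:3] != "ATG":
                expect = "HIGH"
            elif alt_aa[ci] == "*" and ref_aa[ci] != "*":
                expect = "HIGH"
            elif ref_aa[ci] == "*" and alt_aa[ci] != "*":
                expect = "HIGH"
            elif ref_aa[ci] == alt_aa[ci]:
                expect = "LOW"
            else:
                expect = "MODERATE"
            assert got == expect, (gi, strand, pos_in_cds, cds_base, alt_cds)
            n_checked += 1
        assert n_checked == 25


def two_pop_spec(gm, n_a):
    return PopulationSpec({s: ("A" if i < n_a else "B")
                           for i, s in enumerate(gm.samples)})


class TestLoadTable:
    def test_hand_counts(self):
        gm = make_matrix([[2, 1, 1, 0]], ancestral=["ref"] * 4)
        spec = PopulationSpec({"s1": "A"})
        cats = pd.Series(["HIGH"] * 4)
        tab = ml.load_table(gm, cats, spec)
        row = tab.per_sample.set_index("category").loc["HIGH"]
        assert row["hom"] == 1 and row["het"] == 2
        assert row["hom_proportion"] == pytest.approx(1 / 3)

    def test_all_ancestral_sample_zero(self):
        gm = make_matrix([[0, 0, 0]], ancestral=["ref"] * 3)
        spec = PopulationSpec({"s1": "A"})
        tab = ml.load_table(gm, pd.Series(["HIGH", "MODERATE", "LOW"]), spec)
        assert (tab.per_sample["hom"] == 0).all()
        assert (tab.per_sample["het"] == 0).all()

    def test_alt_ancestral_orientation_counts_reference_homozygote(self):
        gm = make_matrix([[0]], ancestral=["alt"])
        spec = PopulationSpec({"s1": "A"})
        tab = ml.load_table(gm, pd.Series(["HIGH"]), spec)
        assert tab.per_sample["hom"].iloc[0] == 1

    def test_unpolarized_sites_excluded_and_counted(self):
        gm = make_matrix([[2, 2]], ancestral=["ref", "unknown"])
        spec = PopulationSpec({"s1": "A"})
        tab = ml.load_table(gm, pd.Series(["HIGH", "HIGH"]), spec)
        assert tab.per_sample["hom"].iloc[0] == 1
        assert tab.n_unpolarized_excluded == 1

    def test_welch_t_test_detects_mean_shift(self, rng):
        g_a = rng.binomial(2, 0.8, size=(8, 300))
        g_b = rng.binomial(2, 0.2, size=(8, 300))
        gm = make_matrix(np.vstack([g_a, g_b]).tolist(),
                         ancestral=["ref"] * 300)
        spec = two_pop_spec(gm, 8)
        tab = ml.load_table(gm, pd.Series(["MODERATE"] * 300), spec)
        t_row = tab.t_tests.set_index("category").loc["MODERATE"]
        assert t_row["p"] < 1e-6

    def test_category_counts_partition_coding_genotypes(self, rng):
        cats = pd.Series(rng.choice(["HIGH", "MODERATE", "LOW"], 200))
        g = rng.integers(0, 3, size=(4, 200))
        gm = make_matrix(g.tolist(), ancestral=["ref"] * 200)
        spec = PopulationSpec({s: "A" for s in gm.samples})
        tab = ml.load_table(gm, cats, spec)
        per = tab.per_sample.groupby("sample")[["hom", "het"]].sum()
        for i, s in enumerate(gm.samples):
            carriers = int(((g[i] == 1) | (g[i] == 2)).sum())
            assert per.loc[s, "hom"] + per.loc[s, "het"] == carriers


class TestSFS:
    def test_hand_spectrum(self):
        # 4 diploids, derived counts {1, 1, 2} -> spectrum {1: 2, 2: 1}
        g = np.zeros((4, 3), dtype=int)
        g[0, 0] = 1
        g[1, 1] = 1
        g[0, 2] = g[1, 2] = 1
        gm = make_matrix(g.tolist(), ancestral=["ref"] * 3)
        spec = PopulationSpec({s: "A" for s in gm.samples})
        s = ml.sfs(gm, pd.Series(["LOW"] * 3), "A", spec, "LOW")
        assert s.n_copies == 8
        assert s.spectrum[1] == 2 and s.spectrum[2] == 1
        assert s.total_sites == 3

    def test_fixed_classes_excluded(self):
        g = [[2, 0], [2, 0]]
        gm = make_matrix(g, ancestral=["ref", "ref"])
        spec = PopulationSpec({s: "A" for s in gm.samples})
        s = ml.sfs(gm, pd.Series(["LOW", "LOW"]), "A", spec, "LOW")
        assert s.total_sites == 0

    def test_projection_preserves_site_mass(self):
        g = np.array([[1, 1], [0, 1], [MISSING, 1]])
        gm = make_matrix(g.tolist(), ancestral=["ref", "ref"])
        spec = PopulationSpec({s: "A" for s in gm.samples})
        s = ml.sfs(gm, pd.Series(["LOW", "LOW"]), "A", spec, "LOW",
                   n_copies=4, deviating="project")
        # site 2 (6 copies, 3 derived) projects into classes 1..3 of n=4
        assert s.total_sites == pytest.approx(
            1 + (1 - _fixed_mass(3, 6, 4)), abs=1e-10)

    def test_neutral_spectrum_tracks_theta_over_i(self):
        from founderpop import synthetic_data as sd

        res = sd.simulate(sd.neutral_single_population_config(
            seed=2, theta=0.004, chromosome_length=100_000, n_generations=5))
        gm = res.genotypes
        gm.sites["ancestral"] = "ref"
        pop = [s for s in gm.samples if s.startswith("pop")]
        spec = PopulationSpec({**{s: "pop" for s in pop},
                               **{s: "og" for s in gm.samples if s not in pop}})
        cats = pd.Series(["LOW"] * gm.n_sites)
        s = ml.sfs(gm, cats, "pop", spec, "LOW")
        i = np.arange(1, 16)
        observed = s.spectrum[1:16]
        expected = observed[0] * (1.0 / i)
        # log-log slope close to -1 over the low-frequency tail
        slope = np.polyfit(np.log(i[observed > 0]),
                           np.log(observed[observed > 0]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.25)

    def test_binned_display_rule(self):
        spectrum = np.zeros(41)
        spectrum[1:10] = np.arange(1, 10)
        spectrum[10:40] = 5.0
        s = ml.SFS("LOW", 40, spectrum, 0)
        b = s.binned(threshold=10, width=10)
        assert list(b["bin"][:9]) == [str(i) for i in range(1, 10)]
        assert b.loc[b["bin"] == "10-19", "sites"].iloc[0] == 5.0


def _fixed_mass(j, n_from, n_to):
    from scipy.stats import hypergeom

    return hypergeom.pmf(0, n_from, j, n_to) + hypergeom.pmf(n_to, n_from, j, n_to)


class TestRxy:
    def test_closed_form_example(self):
        # d^X = (0.5, 0.2), d^Y = (0.1, 0.4) -> Rxy = 0.57 / 0.37
        gm = make_matrix([[2, 0], [0, 0], [0, 2], [0, 0], [0, 0],
                          [0, 2], [0, 2], [2, 2], [0, 2], [0, 0]],
                         ancestral=["ref", "ref"])
        # construct exact frequencies: X = 5 diploids with dX = (0.5, 0.2)?
        # simpler: use frequency vectors directly through a crafted matrix
        gx = [[1, 1], [1, 0], [2, 1], [1, 0], [0, 0]]   # freqs (0.5, 0.2)
        gy = [[0, 1], [1, 1], [0, 1], [0, 1], [0, 0]]   # freqs (0.1, 0.4)
        gm = make_matrix(gx + gy, ancestral=["ref", "ref"])
        spec = two_pop_spec(gm, 5)
        res = ml.rxy(gm, pd.Series(["HIGH", "HIGH"]), "A", "B", spec, "HIGH")
        assert res.l_x_not_y == pytest.approx(0.5 * 0.9 + 0.2 * 0.6, abs=1e-12)
        assert res.l_y_not_x == pytest.approx(0.1 * 0.5 + 0.4 * 0.8, abs=1e-12)
        assert res.rxy == pytest.approx(0.57 / 0.37, abs=1e-12)

    def test_identical_frequencies_give_unity(self, rng):
        g = rng.binomial(2, rng.uniform(0.1, 0.9, 50), size=(6, 50))
        gm = make_matrix(np.vstack([g, g]).tolist(), ancestral=["ref"] * 50)
        spec = two_pop_spec(gm, 6)
        res = ml.rxy(gm, pd.Series(["LOW"] * 50), "A", "B", spec, "LOW")
        assert res.rxy == pytest.approx(1.0, abs=1e-12)

    @given(st.integers(min_value=0, max_value=10 ** 6))
    @settings(max_examples=20, deadline=None)
    def test_reciprocal_identity_exact(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 3, size=(8, 40))
        gm = make_matrix(g.tolist(), ancestral=["ref"] * 40)
        spec = two_pop_spec(gm, 4)
        cats = pd.Series(["HIGH"] * 40)
        fwd = ml.rxy(gm, cats, "A", "B", spec, "HIGH")
        rev = ml.rxy(gm, cats, "B", "A", spec, "HIGH")
        if np.isfinite(fwd.rxy) and np.isfinite(rev.rxy):
            assert fwd.rxy * rev.rxy == pytest.approx(1.0, abs=1e-12)

    def test_zero_denominator_reported(self):
        gm = make_matrix([[2], [0]], ancestral=["ref"])
        spec = two_pop_spec(gm, 1)
        res = ml.rxy(gm, pd.Series(["HIGH"]), "A", "B", spec, "HIGH")
        assert np.isnan(res.rxy)

    def test_low_normalization_mode(self, rng):
        g = rng.integers(0, 3, size=(8, 100))
        gm = make_matrix(g.tolist(), ancestral=["ref"] * 100)
        spec = two_pop_spec(gm, 4)
        cats = pd.Series(["HIGH"] * 50 + ["LOW"] * 50)
        raw = ml.rxy(gm, cats, "A", "B", spec, "HIGH")
        norm = ml.rxy(gm, cats, "A", "B", spec, "HIGH", normalize_by_low=True)
        low = ml.rxy(gm, cats, "A", "B", spec, "LOW")
        assert norm.rxy == pytest.approx(raw.rxy / low.rxy, abs=1e-10)
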