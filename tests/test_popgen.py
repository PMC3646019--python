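import numpy as np
import pytest

from coremk.popgen import (
    diversity_stats,
    harmonic_number,
    nucleotide_diversity,
    outgroup_representative,
    segregating_sites,
    site_frequency_spectrum,
    watterson_theta,
)
from coremk.sequence_io import get_code

from conftest import make_alignment


def random_biallelic_alignment(rng, n=6, n_codons=20, n_snps=8):
    """Gap-free ingroup + outgroup where every SNP is polarizable."""
    base = "".join(rng.choice(list("ACGT"), size=3 * n_codons))
    rows = {f"i{k}": list(base) for k in range(n)}
    rows["out"] = list(base)
    sites = rng.choice(3 * n_codons, size=n_snps, replace=False)
    for pos in sites:
        old = base[pos]
        new = rng.choice([c for c in "ACGT" if c != old])
        k = int(rng.integers(1, n))  # derived in k of n ingroup strains
        for strain in rng.choice(n, size=k, replace=False):
            rows[f"i{strain}"][pos] = new
    return make_alignment("g", **{lab: "".join(s) for lab, s in rows.items()})


class TestSegregatingSites:
    def test_identical_sequences(self):
        aln = make_alignment("g", a="ATGAAA", b="ATGAAA", o="ATGAAA")
        S, used = segregating_sites(aln, ["a", "b"])
        assert S == 0 and used == 6

    def test_hand_placed_biallelic_columns(self):
        rows = {
            "a": "AAAAAAAAA",
            "b": "AAGAAAAAA",
            "c": "AAGATAACA",
            "d": "AAAATAACT",
        }
        aln = make_alignment("g", **rows)
        S, _ = segregating_sites(aln)
        # columns 2, 4, 7, 8 vary -> 4 segregating sites
        assert S == 4

    def test_triallelic_column_counts_once(self):
        aln = make_alignment("g", a="ATA", b="ACA", c="AGA")
        S, _ = segregating_sites(aln)
        assert S == 1

    def test_gapped_columns_excluded(self):
        aln = make_alignment("g", a="A-TAAA", b="AGTAAA")
        S, used = segregating_sites(aln)
        assert used == 5 and S == 0


class TestPi:
    def test_two_sequences(self):
        a = "A" * 30
        b = "G" * 3 + "A" * 27
        aln = make_alignment("g", a=a, b=b)
        assert nucleotide_diversity(aln) == pytest.approx(0.1)

    def test_identical(self):
        aln = make_alignment("g", a="ATGAAA", b="ATGAAA")
        assert nucleotide_diversity(aln) == 0.0

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(20)
        for _ in range(10):
            aln = random_biallelic_alignment(rng)
            labels = [l for l in aln.labels if l.startswith("i")]
            n = len(labels)
            vals = []
            for i in range(n):
                for j in range(i + 1, n):
                    si, sj = aln[labels[i]], aln[labels[j]]
                    diffs = sum(x != y for x, y in zip(si, sj))
                    vals.append(diffs / len(si))
            assert nucleotide_diversity(aln, labels) == pytest.approx(np.mean(vals))


class TestTheta:
    def test_closed_form(self):
        assert watterson_theta(5, 4, 100) == pytest.approx(5 / ((1 + 0.5 + 1 / 3) * 100))

    def test_zero_segregating_sites(self):
        assert watterson_theta(0, 10, 50) == 0.0

    def test_n2_normalization(self):
        assert watterson_theta(30, 2, 30) == pytest.approx(1.0)

    def test_pi_equals_theta_for_two_sequences(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            aln = random_biallelic_alignment(rng, n=2)
            labels = ["i0", "i1"]
            S, used = segregating_sites(aln, labels)
            assert nucleotide_diversity(aln, labels) == pytest.approx(
                watterson_theta(S, 2, used)
            )


class TestSFS:
    def test_singleton_site(self):
        aln = make_alignment("g", i0="ATA", i1="AAA", i2="AAA", i3="AAA", out="AAA")
        sfs = site_frequency_spectrum(aln, ["i0", "i1", "i2", "i3"], ["out"])
        assert sfs["unfolded"] == (1, 0, 0)

    def test_sum_equals_polarizable_segregating_sites(self):
        rng = np.random.default_rng(22)
        for _ in range(10):
            aln = random_biallelic_alignment(rng)
            ing = [l for l in aln.labels if l.startswith("i")]
            sfs = site_frequency_spectrum(aln, ing, ["out"])
            assert sum(sfs["unfolded"]) == sfs["n_polarizable"]
            S, _ = segregating_sites(aln, ing)
            # outgroup always carries an ingroup allele in this generator
            assert sfs["n_polarizable"] == S

    def test_unpolarizable_site_goes_to_folded_only(self):
        aln = make_alignment("g", i0="ATA", i1="ACA", i2="ACA", i3="ATA", out="AGA")
        sfs = site_frequency_spectrum(aln, ["i0", "i1", "i2", "i3"], ["out"])
        assert sum(sfs["unfolded"]) == 0
        assert sfs["folded"] == (0, 1)

    def test_pi_matches_sfs_closed_form_on_gap_free_fixture(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            aln = random_biallelic_alignment(rng)
            ing = [l for l in aln.labels if l.startswith("i")]
            n = len(ing)
            sfs = site_frequency_spectrum(aln, ing, ["out"])
            L = aln.length
            expected_pi = sum(
                2 * k * (n - k) / (n * (n - 1)) * sfs["unfolded"][k - 1] / L
                for k in range(1, n)
            )
            assert nucleotide_diversity(aln, ing) == pytest.approx(expected_pi)

    def test_syn_nonsyn_split_classification(self, code):
        # codon AAA -> AAG is synonymous (K), AAA -> AGA non-synonymous (R)
        aln = make_alignment(
            "g", i0="AAAAGA", i1="AAGAAA", i2="AAAAAA", i3="AAAAAA", out="AAAAAA"
        )
        sfs = site_frequency_spectrum(aln, ["i0", "i1", "i2", "i3"], ["out"])
        assert sum(sfs["unfolded_syn"]) == 1
        assert sum(sfs["unfolded_nonsyn"]) == 1

    def test_exact_spectrum_recovery_from_known_derived_counts(self):
        rng = np.random.default_rng(24)
        n, n_codons = 6, 30
        base = "".join(rng.choice(list("ACGT"), size=3 * n_codons))
        rows = {f"i{k}": list(base) for k in range(n)}
        rows["out"] = list(base)
        expected = [0] * (n - 1)
        for pos, k in [(4, 1), (10, 2), (17, 2), (25, 5), (40, 3)]:
            old = base[pos]
            new = {"A": "G", "G": "A", "C": "T", "T": "C"}[old]
            for strain in range(k):
                rows[f"i{strain}"][pos] = new
            expected[k - 1] += 1
        aln = make_alignment("g", **{lab: "".join(s) for lab, s in rows.items()})
        sfs = site_frequency_spectrum(aln, [f"i{k}" for k in range(n)], ["out"])
        assert list(sfs["unfolded"]) == expected


class TestDiversityStats:
    def test_bundle_is_consistent(self):
        rng = np.random.default_rng(25)
        aln = random_biallelic_alignment(rng)
        ing = [l for l in aln.labels if l.startswith("i")]
        d = diversity_stats(aln, ing, ["out"])
        assert d.S == sum(d.sfs_folded)
        assert d.theta_w == pytest.approx(watterson_theta(d.S, d.n_sequences, d.sites_used))

    def test_outgroup_representative_consensus(self):
        aln = make_alignment("g", a="AAA", b="AAA", o1="AGA", o2="AGA", o3="ACA")
        assert outgroup_representative(aln, ["o1", "o2", "o3"]) == "AGA"
        aln2 = make_alignment("g", a="AAA", b="AAA", o1="AGA", o2="ACA")
        assert outgroup_representative(aln2, ["o1", "o2"]) == "NNN"
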