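from fractions import Fraction
from itertools import product

import numpy as np
import pytest
from scipy import stats

from coremk.errors import AggregateError, CountError, InputError
from coremk.mk_engine import (
    MKCounts,
    benjamini_hochberg,
    count_mk,
    direction_of_selection,
    mk_significance,
    neutrality_index,
    ni_tg,
    pathway_counts,
    run_direction,
)
from coremk.phylo import TaxonSplit
from coremk.sequence_io import get_code

from conftest import make_alignment, oracle_count_single_codon, oracle_pathway_counts


def counts(pn, ps, dn, ds, gene_id="g"):
    return MKCounts(gene_id, pn, ps, dn, ds)


class TestPathwayCounts:
    def test_matches_enumeration_oracle(self, code):
        rng = np.random.default_rng(10)
        codons = ["".join(c) for c in product("ACGT", repeat=3)]
        sense = [c for c in codons if not code.is_stop(c)]
        for _ in range(300):
            a, b = rng.choice(sense, size=2)
            assert pathway_counts(a, b, code) == pytest.approx(
                oracle_pathway_counts(a, b, code), abs=1e-12
            )

    def test_single_step_synonymous(self, code):
        assert pathway_counts("AAA", "AAG", code) == (0.0, 1.0)  # K -> K

    def test_single_step_nonsynonymous(self, code):
        assert pathway_counts("AAA", "AGA", code) == (1.0, 0.0)  # K -> R

    def test_total_steps_conserved(self, code):
        rng = np.random.default_rng(11)
        sense = code.sense_codons
        for _ in range(100):
            a, b = rng.choice(sense, size=2)
            n, s = pathway_counts(a, b, code)
            assert n + s == pytest.approx(sum(x != y for x, y in zip(a, b)))

    def test_stop_avoiding_path_preferred(self, code):
        # TGT -> TAA-adjacent pairs: ensure no intermediate stop is used when
        # a stop-free ordering exists (oracle enforces the same rule).
        n, s = pathway_counts("TGT", "TAA", code)
        assert (n, s) == pytest.approx(oracle_pathway_counts("TGT", "TAA", code))


class TestCountMK:
    def test_synonymous_polymorphism(self):
        aln = make_alignment("g", i1="AAA", i2="AAA", i3="AAG", o1="AAA")
        c = count_mk(aln, ["i1", "i2", "i3"], ["o1"])
        assert (c.P_N, c.P_S, c.D_N, c.D_S) == (0.0, 1.0, 0.0, 0.0)

    def test_nonsynonymous_divergence(self):
        aln = make_alignment("g", i1="AAA", i2="AAA", o1="AGA")
        c = count_mk(aln, ["i1", "i2"], ["o1"])
        # K (ingroup) vs R (outgroup) is a fixed non-synonymous difference
        assert (c.P_N, c.P_S, c.D_N, c.D_S) == (0.0, 0.0, 1.0, 0.0)

    def test_identical_sequences_count_nothing(self):
        aln = make_alignment("g", i1="ATG", i2="ATG", o1="ATG")
        c = count_mk(aln, ["i1", "i2"], ["o1"])
        assert (c.P_N, c.P_S, c.D_N, c.D_S) == (0.0, 0.0, 0.0, 0.0)
        assert c.codons_used == 1

    def test_segregating_codon_never_counts_divergence(self):
        # ingroup polymorphic at a codon where the outgroup also differs:
        # polymorphism priority means no D contribution from that codon
        aln = make_alignment("g", i1="AAA", i2="AAG", o1="AGA")
        c = count_mk(aln, ["i1", "i2"], ["o1"])
        assert c.D_N == 0.0 and c.D_S == 0.0
        assert c.P_S == 1.0

    def test_gapped_codon_skipped(self):
        aln = make_alignment("g", i1="---AAA", i2="AAGAAA", o1="AAAAAA")
        c = count_mk(aln, ["i1", "i2"], ["o1"])
        assert c.codons_used == 1
        assert (c.P_N, c.P_S, c.D_N, c.D_S) == (0.0, 0.0, 0.0, 0.0)

    def test_all_columns_gapped_is_count_error(self):
        aln = make_alignment("g", i1="---", i2="AAA", o1="AAA")
        with pytest.raises(CountError):
            count_mk(aln, ["i1", "i2"], ["o1"])

    def test_outgroup_consensus_tie_skips_divergence(self):
        aln = make_alignment("g", i1="AAA", i2="AAA", o1="AGA", o2="ACA")
        c = count_mk(aln, ["i1", "i2"], ["o1", "o2"])
        assert (c.D_N, c.D_S) == (0.0, 0.0)

    def test_outgroup_majority_wins(self):
        aln = make_alignment("g", i1="AAA", i2="AAA", o1="AGA", o2="AGA", o3="ACA")
        c = count_mk(aln, ["i1", "i2"], ["o1", "o2", "o3"])
        assert (c.D_N, c.D_S) == (1.0, 0.0)

    def test_first_strain_mode(self):
        aln = make_alignment("g", i1="AAA", i2="AAA", o1="AGA", o2="AAA")
        c = count_mk(aln, ["i1", "i2"], ["o1", "o2"], outgroup_mode="first")
        assert (c.D_N, c.D_S) == (1.0, 0.0)

    def test_swap_of_clades_swaps_polymorphism_source(self):
        # asymmetric fixture: clade A is polymorphic, clade B is monomorphic
        aln = make_alignment(
            "g", a1="AAAAAA", a2="AAGAAA", a3="AAAAAA", b1="AAAAGA", b2="AAAAGA"
        )
        c_ab = count_mk(aln, ["a1", "a2", "a3"], ["b1", "b2"])
        assert c_ab.P_S == 1.0 and c_ab.P_N == 0.0  # AAA/AAG within A
        assert c_ab.D_N == 1.0  # AAA vs AGA at codon 2
        c_ba = count_mk(aln, ["b1", "b2"], ["a1", "a2", "a3"])
        assert c_ba.P_S == 0.0 and c_ba.P_N == 0.0  # B has no polymorphism
        assert c_ba.D_N == 1.0  # divergence is symmetric here

    def test_matches_single_codon_oracle(self, code):
        rng = np.random.default_rng(12)
        sense = code.sense_codons
        pool = list(rng.choice(sense, size=6))  # small pool forces collisions
        for _ in range(2000):
            n_in = int(rng.integers(2, 6))
            n_out = int(rng.integers(1, 3))
            ing = [pool[i] for i in rng.integers(0, len(pool), size=n_in)]
            out = [pool[i] for i in rng.integers(0, len(pool), size=n_out)]
            rows = {f"i{k}": c for k, c in enumerate(ing)}
            rows.update({f"o{k}": c for k, c in enumerate(out)})
            aln = make_alignment("g", **rows)
            expected = oracle_count_single_codon(ing, out, code)
            got = count_mk(aln, [f"i{k}" for k in range(n_in)],
                           [f"o{k}" for k in range(n_out)], code=code)
            assert (got.P_N, got.P_S, got.D_N, got.D_S) == pytest.approx(expected, abs=1e-12)

    def test_label_validation(self):
        aln = make_alignment("g", a="AAA", b="AAA", c="AAA")
        with pytest.raises(InputError):
            count_mk(aln, ["a"], ["b"])  # ingroup too small
        with pytest.raises(InputError):
            count_mk(aln, ["a", "b"], ["z"])  # unknown label


class TestPerGeneStatistics:
    def test_neutral_table_gives_one(self):
        assert neutrality_index(counts(1, 1, 1, 1)) == 1.0

    def test_ni_exact_rational_value(self):
        assert neutrality_index(counts(2, 42, 7, 17)) == pytest.approx(
            float(Fraction(2, 42) / Fraction(7, 17)), abs=0
        )

    def test_dos_exact_rational_value(self):
        assert direction_of_selection(counts(2, 42, 7, 17)) == pytest.approx(
            float(Fraction(7, 24) - Fraction(2, 44)), abs=0
        )

    def test_dos_zero_for_symmetric_counts(self):
        assert direction_of_selection(counts(1, 1, 1, 1)) == 0.0

    @pytest.mark.parametrize("zeros", list(product([0, 3], repeat=4)))
    def test_undefined_contract_over_all_zero_patterns(self, zeros):
        pn, ps, dn, ds = zeros
        c = counts(pn, ps, dn, ds)
        ni = neutrality_index(c)
        dos = direction_of_selection(c)
        assert (ni is None) == (dn == 0 or ps == 0)
        assert (dos is None) == (pn + ps == 0 or dn + ds == 0)

    def test_significance_identical_ratios(self):
        p, test = mk_significance(counts(10, 10, 10, 10))
        assert p == pytest.approx(1.0)
        assert test == "chi2"

    def test_significance_matches_independent_chi2(self):
        c = counts(20, 42, 37, 17)
        p, test = mk_significance(c)
        table = np.array([[20, 42], [37, 17]], dtype=float)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2 = ((table - expected) ** 2 / expected).sum()
        assert test == "chi2"
        assert p == pytest.approx(float(stats.chi2.sf(chi2, df=1)), rel=1e-12)

    def test_significance_fisher_fallback_for_sparse_table(self):
        c = counts(2, 42, 7, 17)
        p, test = mk_significance(c)
        assert test == "fisher"
        assert p == pytest.approx(float(stats.fisher_exact([[2, 42], [7, 17]])[1]))
        assert p < 0.05

    def test_significance_all_zero_undefined(self):
        assert mk_significance(counts(0, 0, 0, 0)) == (None, None)

    def test_benjamini_hochberg_passes_none_through(self):
        q = benjamini_hochberg([0.01, None, 0.04, 0.03])
        assert q[1] is None
        assert all(v is not None for i, v in enumerate(q) if i != 1)


class TestNITG:
    def test_single_gene_reduces_to_ni(self):
        c = counts(2, 42, 7, 17)
        r = ni_tg([c], n_bootstrap=0)
        assert r.NI_TG == neutrality_index(c)

    def test_replicating_a_gene_leaves_value_unchanged(self):
        c = counts(3, 11, 6, 9)
        single = ni_tg([c], n_bootstrap=0).NI_TG
        for k in (2, 5, 17):
            assert ni_tg([c] * k, n_bootstrap=0).NI_TG == pytest.approx(single, abs=0)

    def test_matches_term_by_term_oracle(self):
        rng = np.random.default_rng(13)
        tables = [
            counts(*(int(x) for x in rng.integers(0, 30, size=4)), gene_id=f"g{i}")
            for i in range(20)
        ]
        kept = [c for c in tables if c.P_S + c.D_S > 0]
        num = sum(Fraction(int(c.D_S) * int(c.P_N), int(c.P_S) + int(c.D_S)) for c in kept)
        den = sum(Fraction(int(c.P_S) * int(c.D_N), int(c.P_S) + int(c.D_S)) for c in kept)
        r = ni_tg(tables, n_bootstrap=0)
        assert r.NI_TG == pytest.approx(float(num / den), abs=1e-12)
        assert r.n_genes_included == len(kept)

    def test_zero_weight_genes_are_skipped(self):
        r = ni_tg([counts(5, 0, 5, 0), counts(2, 4, 3, 5)], n_bootstrap=0)
        assert r.n_genes_included == 1
        assert r.n_genes_excluded == 1

    def test_aggregate_undefined_raises(self):
        with pytest.raises(AggregateError):
            ni_tg([counts(5, 0, 5, 0)], n_bootstrap=0)
        with pytest.raises(AggregateError):
            ni_tg([counts(3, 4, 0, 5)], n_bootstrap=0)  # denominator sum zero

    def test_bootstrap_is_seeded_and_contains_point(self):
        rng = np.random.default_rng(14)
        tables = [
            counts(*(int(x) + 1 for x in rng.integers(0, 20, size=4)), gene_id=f"g{i}")
            for i in range(30)
        ]
        r1 = ni_tg(tables, n_bootstrap=2000, seed=99)
        r2 = ni_tg(tables, n_bootstrap=2000, seed=99)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        assert r1.ci_low <= r1.NI_TG <= r1.ci_high


class TestRunDirection:
    def _fixture_genes(self):
        genes = []
        rng = np.random.default_rng(15)
        code = get_code()
        sense = code.sense_codons
        for i in range(4):
            base = "".join(rng.choice(sense, size=30))
            # fixed differences shared by the whole b clade
            diverged = list(base)
            for _ in range(8):
                pos = int(rng.integers(0, len(diverged)))
                diverged[pos] = "ACGT"[int(rng.integers(0, 4))]
            diverged = "".join(diverged)
            rows = {}
            for lab in ("a1", "a2", "a3", "b1", "b2", "b3"):
                seq = list(base if lab.startswith("a") else diverged)
                for _ in range(2):  # private polymorphism
                    pos = int(rng.integers(0, len(seq)))
                    seq[pos] = "ACGT"[int(rng.integers(0, 4))]
                rows[lab] = "".join(seq)
            genes.append(make_alignment(f"g{i}", **rows))
        return genes

    def test_both_directions_runnable_for_multistrain_clades(self):
        from coremk.mk_engine import MKConfig

        genes = self._fixture_genes()
        split = TaxonSplit(frozenset(["a1", "a2", "a3"]), frozenset(["b1", "b2", "b3"]))
        cfg = MKConfig(n_bootstrap=200, run_phi=False, check_congruency=False)
        r1 = run_direction(genes, split, split.clade_a, cfg)
        r2 = run_direction(genes, split, split.clade_b, cfg)
        assert len(r1.per_gene) == len(genes)
        assert r1.ingroup != r2.ingroup

    def test_singleton_ingroup_rejected(self):
        from coremk.mk_engine import MKConfig

        genes = self._fixture_genes()
        split = TaxonSplit(frozenset(["a1"]), frozenset(["a2", "a3", "b1", "b2", "b3"]))
        with pytest.raises(InputError):
            run_direction(genes, split, split.clade_a, MKConfig(run_phi=False))
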