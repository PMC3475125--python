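"""Patristic distances, phylogenetic spread, codon alignment, NG86 dN/dS."""

import itertools

import numpy as np
import pytest

from ferronich import molevo, synthetic as syn
from ferronich.molevo import (
    codon_align_from_protein,
    dnds_pairwise_ng86,
    gene_dnds_summary,
    ng86_difference_counts,
    ng86_site_counts,
    patristic_distances,
    phylogenetic_spread,
)
from ferronich.profile_hmm import MultipleAlignment
from ferronich.validation import brute_force_pathway_counts


class TestPatristic:
    def test_two_leaf_path(self):
        names, D = patristic_distances("(a:0.1,b:0.2);")
        assert D[names.index("a"), names.index("b")] == pytest.approx(0.3)

    def test_star_tree_all_pairs_2b(self):
        names, D = patristic_distances("(a:0.5,b:0.5,c:0.5,d:0.5);")
        off = D[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_matches_simulator_truth(self):
        for seed in range(10):
            tr = syn.simulate_tree(8, seed=seed)
            names, D = patristic_distances(tr.newick)
            order = [names.index(t) for t in tr.taxa]
            assert np.allclose(tr.distances, D[np.ix_(order, order)], atol=1e-8)

    def test_matches_dendropy_distance_matrix(self):
        import dendropy

        tr = syn.simulate_tree(7, seed=3)
        names, D = patristic_distances(tr.newick)
        t = dendropy.Tree.get(data=tr.newick, schema="newick",
                              preserve_underscores=True)
        pdm = t.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in t.taxon_namespace}
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i < j:
                    assert D[i, j] == pytest.approx(
                        pdm.patristic_distance(taxa[a], taxa[b]), abs=1e-9
                    )

    def test_four_point_condition(self):
        tr = syn.simulate_tree(8, seed=4)
        D = tr.distances
        rng = np.random.default_rng(0)
        for _ in range(40):
            i, j, k, l = rng.choice(8, size=4, replace=False)
            sums = sorted([D[i, j] + D[k, l], D[i, k] + D[j, l], D[i, l] + D[j, k]])
            assert sums[1] == pytest.approx(sums[2], abs=1e-9)

    def test_missing_branch_length_rejected(self):
        with pytest.raises(ValueError, match="branch length"):
            patristic_distances("(a:0.1,(b,c:0.2):0.1);")


class TestPhylogeneticSpread:
    def _tree(self):
        # ((a:0.1, b:0.1):0.1, c:0.2): d(a,b)=0.2, d(a,c)=d(b,c)=0.4
        return patristic_distances("((a:0.1,b:0.1):0.1,c:0.2);")

    def test_hand_mean_over_three_leaves(self):
        names, D = self._tree()
        (res,) = phylogenetic_spread({"g": {"a", "b", "c"}}, names, D)
        assert res.P == pytest.approx((0.2 + 0.4 + 0.4) / 3)
        assert res.n_genomes == 3

    def test_two_genomes_equals_their_distance(self):
        names, D = self._tree()
        (res,) = phylogenetic_spread({"g": {"a", "c"}}, names, D)
        assert res.P == pytest.approx(0.4)

    def test_single_genome_undefined_not_error(self):
        names, D = self._tree()
        (res,) = phylogenetic_spread({"g": {"b"}}, names, D)
        assert res.P is None and res.n_genomes == 1

    def test_gene_in_all_leaves_equals_grand_mean(self):
        tr = syn.simulate_tree(9, seed=6)
        names, D = patristic_distances(tr.newick)
        (res,) = phylogenetic_spread({"g": set(names)}, names, D)
        iu = np.triu_indices(len(names), k=1)
        assert res.P == pytest.approx(float(D[iu].mean()), abs=1e-12)

    def test_unknown_genome_rejected_by_name(self):
        names, D = self._tree()
        with pytest.raises(ValueError, match="zz"):
            phylogenetic_spread({"g": {"a", "zz"}}, names, D)


class TestCodonAlign:
    def test_ungapped_pair_concatenates_codons(self):
        aln = MultipleAlignment(("x",), ("MK",))
        out = codon_align_from_protein(aln, {"x": "ATGAAA"})
        assert out["x"] == "ATGAAA"

    def test_gap_expands_to_triple_gap(self):
        aln = MultipleAlignment(("x", "y"), ("MK-F", "MKEF"))
        out = codon_align_from_protein(
            aln, {"x": "ATGAAATTT", "y": "ATGAAAGAATTT"}
        )
        assert out["x"] == "ATGAAA---TTT"
        assert len(out["x"]) == len(out["y"])

    def test_round_trip_translation(self):
        rng = np.random.default_rng(1)
        prot = "MKLVDEF"
        cds = syn.back_translate(prot, rng)
        aln = MultipleAlignment(("x",), (prot,))
        out = codon_align_from_protein(aln, {"x": cds})
        back = "".join(
            syn.CODON_TABLE[out["x"][i : i + 3]] for i in range(0, len(cds), 3)
        )
        assert back == prot

    def test_translation_mismatch_names_position(self):
        aln = MultipleAlignment(("x",), ("MK",))
        with pytest.raises(ValueError, match="column 1"):
            codon_align_from_protein(aln, {"x": "ATGCTG"})  # L != K


class TestNg86:
    def test_site_counts_sum_to_three_per_codon(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            prot = "".join("ACDEFGHIKLMNPQRSTVWY"[j] for j in rng.integers(20, size=40))
            seq = syn.back_translate(prot, rng)
            S, N = ng86_site_counts(seq)
            assert S + N == pytest.approx(3 * 40, abs=1e-9)

    def test_identical_sequences_omega_undefined(self):
        seq = "ATGAAATTT" * 12
        est = dnds_pairwise_ng86(seq, seq)
        assert est.dN == 0.0 and est.dS == 0.0 and est.omega is None

    def test_synonymous_only_differences(self):
        # TTT -> TTC is a synonymous Phe change; keep the fraction of changed
        # codons below Jukes-Cantor saturation (pS < 3/4 on ~1/3 of all sites)
        s1 = "TTT" * 50
        s2 = ("TTC" + "TTT" * 9) * 5
        est = dnds_pairwise_ng86(s1, s2)
        assert est.dN == 0.0 and est.dS > 0.0 and est.omega == 0.0

    def test_fully_saturated_synonymous_divergence_undefined(self):
        # every codon changed synonymously: pS = 3 exceeds the correction's
        # domain, so dS (and omega) are undefined rather than fabricated
        est = dnds_pairwise_ng86("TTT" * 50, "TTC" * 50)
        assert est.dS is None and est.omega is None

    def test_pathway_counts_match_enumeration(self):
        pairs = [
            (a, b)
            for a, b in itertools.product(syn.SENSE_CODONS, repeat=2)
            if sum(x != y for x, y in zip(a, b)) in (2, 3)
        ]
        rng = np.random.default_rng(3)
        for idx in rng.choice(len(pairs), size=150, replace=False):
            c1, c2 = pairs[idx]
            assert ng86_difference_counts(c1, c2) == pytest.approx(
                brute_force_pathway_counts(c1, c2), abs=1e-12
            )

    def test_symmetry_in_arguments(self):
        s1, s2 = syn.simulate_codon_pair(
            syn.CodonPairSimSpec(n_codons=100, omega=0.7, branch_length=0.4, seed=5)
        )
        a = dnds_pairwise_ng86(s1, s2)
        b = dnds_pairwise_ng86(s2, s1)
        assert a.dN == pytest.approx(b.dN) and a.dS == pytest.approx(b.dS)

    def test_close_to_independent_counting_implementation(self):
        pytest.importorskip("Bio.codonalign")
        import warnings

        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        s1, s2 = syn.simulate_codon_pair(
            syn.CodonPairSimSpec(n_codons=200, omega=1.0, branch_length=0.3, seed=6)
        )
        mine = dnds_pairwise_ng86(s1, s2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dn, ds = cal_dn_ds(CodonSeq(s1), CodonSeq(s2), method="NG86")
        # conventions differ slightly in stop-codon handling
        assert mine.dN == pytest.approx(dn, rel=0.1)
        assert mine.dS == pytest.approx(ds, rel=0.1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dnds_pairwise_ng86("ATG" * 40, "ATG" * 41)

    def test_gapped_codons_skipped(self):
        s1 = "TTT" * 40
        s2 = "---" + "TTC" * 39
        est = dnds_pairwise_ng86(s1, s2 + "")
        assert est.n_codons == 39


class TestGeneSummary:
    def test_selection_classes(self):
        rng = np.random.default_rng(7)
        seqs = {}
        base_prot = "".join("ACDEFGHIKLMNPQRSTVWY"[j] for j in rng.integers(20, size=80))
        base = syn.back_translate(base_prot, rng)
        spec = syn.CodonPairSimSpec(n_codons=80, omega=3.0, branch_length=0.4, seed=8)
        a, b = syn.simulate_codon_pair(spec)
        est = gene_dnds_summary("g", {"s1": a, "s2": b})
        assert est.n_pairs == 1
        assert est.selection_class in {"positive", "purifying"}
        assert est.selection_class == ("positive" if est.mean_omega > 1 else "purifying")

    def test_single_sequence_undefined_contract(self):
        est = gene_dnds_summary("g", {"s1": "ATG" * 40})
        assert est.selection_class == "undefined" and est.mean_omega is None

    def test_undefined_pairs_counted_not_averaged(self):
        seq = "ATGAAATTT" * 12
        est = gene_dnds_summary("g", {"a": seq, "b": seq, "c": seq})
        assert est.n_pairs == 0 and est.n_undefined == 3
        assert est.selection_class == "undefined"

    def test_omega_rank_order_preserved_across_planted_values(self):
        means = {}
        for w_i, omega in enumerate((0.2, 1.0, 3.0)):
            ests = []
            for rep in range(8):
                s1, s2 = syn.simulate_codon_pair(
                    syn.CodonPairSimSpec(n_codons=300, omega=omega,
                                         branch_length=0.3, seed=900 + 50 * w_i + rep)
                )
                e = dnds_pairwise_ng86(s1, s2)
                if e.omega is not None:
                    ests.append(e.omega)
            means[omega] = np.mean(ests)
        assert means[0.2] < means[1.0] < means[3.0]
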