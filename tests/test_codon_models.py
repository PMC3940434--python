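"""Codon models: counting estimators, GY94 matrix, pruning, fitting, LRT."""

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import chi2

from genomeflux._codes import AA_OF, CODON_INDEX, CODONS, STOP_CODONS, f3x4_frequencies
from genomeflux.codon_models import (
    CodonAlignment,
    CodonBranchModel,
    branch_model_loglik,
    compare_models,
    gy94_rate_matrix,
    ng86_pairwise,
    per_genome_dn_to_outgroup,
    yn00_hky_pairwise,
)
from genomeflux.synthetic_data import CodonSimTruth, simulate_codon_alignment
from genomeflux.trees import LabeledTree

PAD = "ATGGAC" * 8  # constant context so proportions stay below saturation


def brute_force_ng86_differences(a, b):
    """Path-enumeration oracle for substitution counts between codons."""
    diff = [p for p in range(3) if a[p] != b[p]]
    syn = non = 0.0
    paths = 0
    for order in itertools.permutations(diff):
        cur = a
        steps = []
        ok = True
        for p in order:
            nxt = cur[:p] + b[p] + cur[p + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            steps.append((cur, nxt))
            cur = nxt
        if not ok:
            continue
        paths += 1
        for x, y in steps:
            if AA_OF[x] == AA_OF[y]:
                syn += 1
            else:
                non += 1
    return (syn / paths, non / paths) if paths else (0.0, 0.0)


class TestNG86:
    def test_identical_sequences(self):
        r = ng86_pairwise(PAD, PAD)
        assert r.dn == 0 and r.ds == 0

    def test_synonymous_only_difference(self):
        r = ng86_pairwise("GGG" + PAD, "GGA" + PAD)
        syn, non = brute_force_ng86_differences("GGG", "GGA")
        assert (syn, non) == (1.0, 0.0)
        assert r.dn == 0 and r.ds > 0 and r.omega == 0

    def test_nonsynonymous_only_difference(self):
        r = ng86_pairwise("TTT" + PAD, "TTA" + PAD)
        syn, non = brute_force_ng86_differences("TTT", "TTA")
        assert (syn, non) == (0.0, 1.0)
        assert r.dn > 0 and r.ds == 0 and r.omega is None

    def test_two_step_codon_paths_averaged(self):
        for a, b in (("TTT", "GGT"), ("ATG", "CTA"), ("AAA", "AGG")):
            syn, non = brute_force_ng86_differences(a, b)
            r = ng86_pairwise(a + PAD, b + PAD)
            # differences recovered from corrected rates are monotone in counts
            assert syn + non == pytest.approx(len([p for p in range(3) if a[p] != b[p]]))
            if syn == 0:
                assert r.ds == 0
            if non == 0:
                assert r.dn == 0

    def test_site_counts_sum_to_three_per_codon(self):
        r = ng86_pairwise(PAD, PAD)
        assert r.s_sites + r.n_sites == pytest.approx(len(PAD) / 3 * 3)

    def test_saturation_flagged_missing(self):
        r = ng86_pairwise("GGG", "GGA")  # single fourfold site: p = 1
        assert r.saturated and r.omega is None


class TestYN00:
    def test_identical_sequences(self):
        r = yn00_hky_pairwise(PAD, PAD)
        assert r.dn == 0 and r.ds == 0

    def test_recovers_simulated_omega_within_ten_percent(self, uniform_freqs, two_leaf_tree):
        for node in two_leaf_tree.nodes.values():
            if node.parent is not None:
                node.length = 0.15
        for omega in (0.1, 0.5, 1.0):
            est = []
            for seed in range(8):
                truth = CodonSimTruth(
                    tree=two_leaf_tree, kappa=2.0,
                    omega_by_class=dict.fromkeys(set(two_leaf_tree.branch_labels()), omega),
                    codon_freqs=uniform_freqs, n_codons=5000, seed=seed,
                )
                aln, _ = simulate_codon_alignment(truth)
                r = yn00_hky_pairwise(aln.sequences["A"], aln.sequences["B"])
                est.append(r.omega)
            assert abs(np.mean(est) - omega) <= 0.1 * omega

    def test_kappa_one_collapses_to_ng86(self, uniform_freqs, two_leaf_tree):
        for node in two_leaf_tree.nodes.values():
            if node.parent is not None:
                node.length = 0.2
        diffs = []
        for seed in range(4):
            truth = CodonSimTruth(
                tree=two_leaf_tree, kappa=1.0,
                omega_by_class=dict.fromkeys(set(two_leaf_tree.branch_labels()), 0.4),
                codon_freqs=uniform_freqs, n_codons=4000, seed=seed,
            )
            aln, _ = simulate_codon_alignment(truth)
            a, b = aln.sequences["A"], aln.sequences["B"]
            r_ng = ng86_pairwise(a, b)
            r_yn = yn00_hky_pairwise(a, b)
            diffs.append(abs(r_yn.dn - r_ng.dn) / r_ng.dn)
            diffs.append(abs(r_yn.ds - r_ng.ds) / r_ng.ds)
        assert max(diffs) < 0.02


class TestGY94Matrix:
    def test_omega_zero_kills_nonsynonymous_rates(self, uniform_freqs):
        from genomeflux._codes import SINGLE_DIFF, SYNONYMOUS

        q = gy94_rate_matrix(2.0, 0.0, uniform_freqs)
        assert np.all(q[SINGLE_DIFF & ~SYNONYMOUS] == 0)

    def test_detailed_balance(self):
        rng = np.random.default_rng(5)
        freqs = rng.dirichlet(np.ones(61))
        q = gy94_rate_matrix(3.0, 0.4, freqs)
        flow = freqs[:, None] * q
        assert np.abs(flow - flow.T).max() < 1e-14

    def test_transition_matrices_are_stochastic(self, uniform_freqs):
        q = gy94_rate_matrix(2.0, 0.3, uniform_freqs)
        for t in (0.01, 0.1, 1.0):
            p = expm(q * t)
            assert np.abs(p.sum(axis=1) - 1).max() < 1e-10
            assert p.min() > -1e-12

    def test_scaling_gives_unit_substitution_rate(self, uniform_freqs):
        q = gy94_rate_matrix(2.0, 0.3, uniform_freqs)
        assert -(uniform_freqs * np.diag(q)).sum() == pytest.approx(1.0)


class TestPruningLikelihood:
    def test_zero_lengths_identical_sequences_closed_form(self, uniform_freqs):
        t = LabeledTree()
        r = t.add_node()
        t.add_node("A", r, 0.0, "x")
        t.add_node("B", r, 0.0, "x")
        seq = "ATGGGGAAA"
        aln = CodonAlignment({"A": seq, "B": seq})
        lnl = branch_model_loglik(aln, t, {"x": "w"}, 2.0, {"w": 0.5}, codon_freqs=uniform_freqs)
        expect = sum(math.log(uniform_freqs[CODON_INDEX[seq[i : i + 3]]]) for i in range(0, 9, 3))
        assert lnl == pytest.approx(expect, abs=1e-9)

    def test_two_taxon_matrix_exponential_oracle(self, uniform_freqs):
        t = LabeledTree()
        r = t.add_node()
        t.add_node("A", r, 0.1, "x")
        t.add_node("B", r, 0.25, "x")
        rng = np.random.default_rng(2)
        seqs = {n: "".join(rng.choice(CODONS, 30)) for n in "AB"}
        aln = CodonAlignment(seqs)
        lnl = branch_model_loglik(aln, t, {"x": "w"}, 2.0, {"w": 0.3}, codon_freqs=uniform_freqs)
        q = gy94_rate_matrix(2.0, 0.3, uniform_freqs)
        p = expm(q * 0.35)
        expect = sum(
            math.log(uniform_freqs[CODON_INDEX[a]] * p[CODON_INDEX[a], CODON_INDEX[b]])
            for a, b in zip(aln.codons("A"), aln.codons("B"))
        )
        assert lnl == pytest.approx(expect, abs=1e-8)

    def test_three_taxon_brute_force_oracle(self, uniform_freqs):
        t = LabeledTree()
        r = t.add_node()
        t.add_node("A", r, 0.2, "x")
        t.add_node("B", r, 0.15, "x")
        t.add_node("C", r, 0.3, "y")
        rng = np.random.default_rng(3)
        seqs = {n: "".join(rng.choice(CODONS, 5)) for n in "ABC"}
        aln = CodonAlignment(seqs)
        lnl = branch_model_loglik(aln, t, {"x": "x", "y": "y"}, 2.0, {"x": 0.3, "y": 1.2}, codon_freqs=uniform_freqs)
        qx = gy94_rate_matrix(2.0, 0.3, uniform_freqs)
        qy = gy94_rate_matrix(2.0, 1.2, uniform_freqs)
        pa, pb, pc = expm(qx * 0.2), expm(qx * 0.15), expm(qy * 0.3)
        codes = aln.codes(["A", "B", "C"])
        brute = 0.0
        for s in range(5):
            a, b, c = codes[:, s]
            brute += math.log(sum(uniform_freqs[z] * pa[z, a] * pb[z, b] * pc[z, c] for z in range(61)))
        assert lnl == pytest.approx(brute, abs=1e-9)

    def test_gap_codons_are_missing_data(self, uniform_freqs):
        t = LabeledTree()
        r = t.add_node()
        t.add_node("A", r, 0.1, "x")
        t.add_node("B", r, 0.1, "x")
        full = CodonAlignment({"A": "ATGAAA", "B": "ATGAAA"})
        gapped = CodonAlignment({"A": "ATG---", "B": "ATGAAA"})
        lnl_full = branch_model_loglik(full, t, {"x": "w"}, 2.0, {"w": 0.5}, codon_freqs=uniform_freqs)
        lnl_gap = branch_model_loglik(gapped, t, {"x": "w"}, 2.0, {"w": 0.5}, codon_freqs=uniform_freqs)
        # the gapped column contributes only the marginal of B's codon
        assert lnl_gap > lnl_full

    def test_unmapped_label_is_named(self, uniform_freqs):
        t = LabeledTree()
        r = t.add_node()
        t.add_node("A", r, 0.1, "weird")
        t.add_node("B", r, 0.1, "x")
        aln = CodonAlignment({"A": "ATG", "B": "ATG"})
        with pytest.raises(ValueError, match="weird"):
            branch_model_loglik(aln, t, {"x": "w"}, 2.0, {"w": 0.5}, codon_freqs=uniform_freqs)


class TestFitBranchModel:
    def test_one_ratio_recovery(self, uniform_freqs):
        t = LabeledTree()
        r = t.add_node()
        a = t.add_node(None, r, 0.1, "x")
        t.add_node("A", a, 0.1, "x")
        t.add_node("B", a, 0.1, "x")
        b = t.add_node(None, r, 0.1, "x")
        t.add_node("C", b, 0.1, "x")
        t.add_node("D", b, 0.1, "x")
        truth = CodonSimTruth(
            tree=t, kappa=2.0, omega_by_class={"x": 0.2}, codon_freqs=uniform_freqs,
            n_codons=2000, seed=5,
        )
        aln, _ = simulate_codon_alignment(truth)
        fit = CodonBranchModel(aln, t, {"x": "w"}, codon_freqs=uniform_freqs).fit(n_starts=1)
        assert 0.15 <= fit.omegas["w"] <= 0.25
        assert fit.converged

    def test_refit_from_truth_never_decreases_loglik(self, uniform_freqs):
        t = LabeledTree()
        r = t.add_node()
        t.add_node("A", r, 0.2, "x")
        t.add_node("B", r, 0.2, "x")
        truth = CodonSimTruth(
            tree=t, kappa=2.0, omega_by_class={"x": 0.3}, codon_freqs=uniform_freqs,
            n_codons=500, seed=6,
        )
        aln, _ = simulate_codon_alignment(truth)
        model = CodonBranchModel(aln, t, {"x": "w"}, codon_freqs=uniform_freqs)
        start = {
            "kappa": 2.0, "omegas": {"w": 0.3},
            "branch_lengths": {e.id: 0.2 for e in model.engine.edges},
        }
        lnl0 = model.loglik(2.0, {"w": 0.3}, start["branch_lengths"])
        fit = model.fit(start=start, n_starts=1)
        assert fit.lnl >= lnl0 - 1e-6

    def test_np_counting(self, uniform_freqs):
        t = LabeledTree()
        r = t.add_node()
        t.add_node("A", r, 0.1, "x")
        t.add_node("B", r, 0.1, "y")
        aln = CodonAlignment({"A": "ATGAAATTC", "B": "ATGAAATTT"})
        model = CodonBranchModel(aln, t, {"x": "w1", "y": "w2"}, codon_freqs=uniform_freqs)
        fit = model.fit(n_starts=1, max_cycles=2)
        assert fit.np == 1 + 2 + 2  # kappa + 2 omegas + 2 branch lengths
        fit2 = model.fit(n_starts=1, max_cycles=2, count_freq_params=True)
        assert fit2.np == fit.np + 9


class TestModelComparison:
    def test_printed_table_worked_example(self):
        cmp = compare_models((30, -9300717.05), (31, -9266700.48))
        assert cmp.delta_aic == pytest.approx(-68031.14, abs=0.005)
        assert cmp.lrt == pytest.approx(68033.14, abs=0.005)
        assert cmp.df == 1 and cmp.p_value < 1e-6

    def test_identical_fits(self):
        cmp = compare_models((30, -100.0), (30, -100.0))
        assert cmp.lrt == 0 and cmp.delta_aic == 0 and cmp.p_value is None

    def test_chi2_quantile(self):
        cmp = compare_models((30, -100.0), (31, -100.0 + 3.841 / 2))
        assert cmp.p_value == pytest.approx(chi2.sf(3.841, 1), abs=1e-12)
        assert cmp.p_value == pytest.approx(0.05, abs=0.001)

    def test_non_nested_requires_aic(self):
        with pytest.raises(ValueError, match="AIC"):
            compare_models((31, -100.0), (31, -99.0), require_lrt=True)
        cmp = compare_models((31, -100.0), (31, -99.0))
        assert cmp.better and cmp.p_value is None and cmp.delta_aic == -2.0

    def test_nested_loglik_ordering_sanity(self, uniform_freqs):
        t = LabeledTree()
        r = t.add_node()
        t.add_node("A", r, 0.15, "x")
        t.add_node("B", r, 0.15, "y")
        truth = CodonSimTruth(
            tree=t, kappa=2.0, omega_by_class={"x": 0.3, "y": 0.3},
            codon_freqs=uniform_freqs, n_codons=400, seed=9,
        )
        aln, _ = simulate_codon_alignment(truth)
        null = CodonBranchModel(aln, t, {"x": "w", "y": "w"}, codon_freqs=uniform_freqs).fit(n_starts=1)
        alt = CodonBranchModel(aln, t, {"x": "w1", "y": "w2"}, codon_freqs=uniform_freqs).fit(n_starts=1)
        assert alt.lnl >= null.lnl - 1e-4


class TestPerGenomeDn:
    def test_outgroup_identical_taxon_has_zero_dn(self, uniform_freqs):
        aln = CodonAlignment({"OUT": PAD, "A": PAD, "B": "TTA" + PAD[3:]})
        table = per_genome_dn_to_outgroup({"fam1": aln}, "OUT")
        by_taxon = table.set_index("taxon")
        assert by_taxon.loc["A", "dn"] == 0
        assert by_taxon.loc["B", "dn"] > 0
        assert len(table) == 2  # one row per (family, in-group taxon)

    def test_elevated_group_has_higher_dn(self, uniform_freqs):
        t = LabeledTree()
        r = t.add_node()
        t.add_node("OUT", r, 0.2, "bg")
        t.add_node("HL", r, 0.2, "hot")
        t.add_node("LL", r, 0.2, "bg")
        alns = {}
        for i in range(4):
            truth = CodonSimTruth(
                tree=t, kappa=2.0, omega_by_class={"bg": 0.05, "hot": 0.8},
                codon_freqs=uniform_freqs, n_codons=600, seed=40 + i,
            )
            alns[f"fam{i}"], _ = simulate_codon_alignment(truth)
        table, summary = per_genome_dn_to_outgroup(alns, "OUT", groups={"HL": "HL", "LL": "LL"})
        med = summary.set_index("group")["median"]
        assert med["HL"] > med["LL"]

    def test_missing_outgroup_raises(self):
        aln = CodonAlignment({"A": PAD, "B": PAD})
        with pytest.raises(ValueError, match="OUT"):
            per_genome_dn_to_outgroup({"f": aln}, "OUT")


def test_neutral_data_not_rejected_against_fixed_omega_one(uniform_freqs):
    """A free one-ratio fit on neutrally simulated data is not
    significantly better than the fixed omega = 1 null."""
    rejections = 0
    seeds = 6
    for seed in range(seeds):
        t = LabeledTree()
        r = t.add_node()
        t.add_node("A", r, 0.2, "x")
        t.add_node("B", r, 0.2, "x")
        t.add_node("C", r, 0.2, "x")
        truth = CodonSimTruth(
            tree=t, kappa=2.0, omega_by_class={"x": 1.0},
            codon_freqs=uniform_freqs, n_codons=500, seed=70 + seed,
        )
        aln, _ = simulate_codon_alignment(truth)
        model = CodonBranchModel(aln, t, {"x": "w"}, codon_freqs=uniform_freqs)
        null = model.fit(n_starts=1, max_cycles=25, fixed_omegas={"w": 1.0})
        alt = model.fit(n_starts=1, max_cycles=25)
        assert alt.np == null.np + 1
        cmp = compare_models(null, alt)
        rejections += cmp.p_value < 0.01
    assert rejections <= 1


def test_duplication_rate_creates_multi_copy_states():
    from genomeflux.synthetic_data import study_topology, simulate_gene_content

    tree = study_topology(0.2).rooted_at_outgroup("RCC307")
    truth = simulate_gene_content(tree, 100, 0.0, 0.0, seed=8, duplication_rate=1.0)
    matrix = truth.leaf_matrix()
    assert (matrix > 1).any().any()
    none = simulate_gene_content(tree, 100, 0.0, 0.0, seed=8)
    assert (none.leaf_matrix() <= 1).all().all()
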