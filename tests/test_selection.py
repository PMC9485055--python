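"""NG86 site/difference counting, Fitch reconstruction, per-branch omega."""

from __future__ import annotations

import math
import random

import pytest

from fadevo.codes import genetic_code
from fadevo.selection import (
    branch_omega,
    fitch_ancestral,
    ng86_codons,
    ng86_pair,
    ng86_sites,
)
from fadevo.seqio import Phylogeny, TreeNode, read_newick
from fadevo.simulate import CodonModel, SimulationConfig, simulate_alignment

from .conftest import make_cds, random_codons
from .oracles import min_changes_bruteforce, ng86_pair_naive, ng86_sites_naive


class TestNg86Sites:
    def test_met_has_no_synonymous_sites(self, code1):
        assert ng86_sites("ATG", code1) == (0.0, 3.0)

    def test_phe_third_position(self, code1):
        s, n = ng86_sites("TTT", code1)
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    @pytest.mark.parametrize("table_id", [1, 6])
    def test_all_sense_codons_match_oracle(self, table_id):
        code = genetic_code(table_id)
        for codon in code.sense_codons:
            s, n = ng86_sites(codon, code)
            s_o, n_o = ng86_sites_naive(codon, code)
            assert s == pytest.approx(s_o, abs=1e-12)
            assert n == pytest.approx(n_o, abs=1e-12)
            assert 0 < s + n <= 3 + 1e-9

    def test_stop_codon_rejected(self, code1):
        with pytest.raises(ValueError, match="stop"):
            ng86_sites("TAA", code1)


class TestNg86Pair:
    def test_identical_sequences(self, code1):
        a = make_cds("ATGTTTGGA", code1, "a")
        b = make_cds("ATGTTTGGA", code1, "b")
        res = ng86_pair(a, b)
        assert res.Sd == res.Nd == 0
        assert res.dS == res.dN == 0
        assert res.omega is None

    def test_single_synonymous_difference(self, code1):
        from fadevo.selection import pathway_differences

        assert pathway_differences("TTT", "TTC", code1) == (1.0, 0.0)

    def test_gapped_codons_dropped_pairwise(self, code1):
        res = ng86_codons(["TTT", "---", "GGA"], ["TTT", "AAA", "GGA"], code1)
        assert res.n_codons == 2
        assert res.skipped_gap == 1

    def test_length_mismatch_rejected(self, code1):
        with pytest.raises(ValueError, match="length"):
            ng86_codons(["TTT"], ["TTT", "TTC"], code1)

    def test_too_divergent_correction_error_names_distance(self, code1):
        # saturated proportions make the Jukes-Cantor log undefined; the
        # error names the offending distance
        with pytest.raises(ValueError, match=r"d[SN] correction undefined"):
            ng86_codons(["ATG"] * 5, ["CCC"] * 5, code1)

    @pytest.mark.parametrize("table_id", [1, 6])
    @pytest.mark.parametrize("seed", range(5))
    def test_random_pairs_match_pathway_oracle(self, table_id, seed):
        code = genetic_code(table_id)
        rng = random.Random(1000 * table_id + seed)
        ca = random_codons(rng, code, 50)
        cb = random_codons(rng, code, 50)
        oracle = ng86_pair_naive(ca, cb, code)
        try:
            res = ng86_codons(ca, cb, code)
        except ValueError:
            assert math.isnan(oracle["dS"]) or math.isnan(oracle["dN"])
            return
        assert res.S == pytest.approx(oracle["S"], abs=1e-10)
        assert res.N == pytest.approx(oracle["N"], abs=1e-10)
        assert res.Sd == pytest.approx(oracle["Sd"], abs=1e-10)
        assert res.Nd == pytest.approx(oracle["Nd"], abs=1e-10)
        assert res.dS == pytest.approx(oracle["dS"], abs=1e-10)
        assert res.dN == pytest.approx(oracle["dN"], abs=1e-10)

    def test_symmetry_under_relabeling(self, code1):
        rng = random.Random(8)
        tree = read_newick("(a:0.2,b:0.2);")
        model = CodonModel(code=code1, kappa=2.0, omega_default=0.3)
        aln = simulate_alignment(
            SimulationConfig(seed=8, n_codons=400, tree=tree, model=model)
        )
        a = make_cds(aln["a"], code1, "a")
        b = make_cds(aln["b"], code1, "b")
        r1, r2 = ng86_pair(a, b), ng86_pair(b, a)
        assert r1.omega == pytest.approx(r2.omega)
        assert r1.dS == pytest.approx(r2.dS)


def _tree_3taxon() -> Phylogeny:
    return read_newick("((a:0.1,b:0.1)ab:0.1,c:0.1)root;")


class TestFitchAncestral:
    def test_identical_tips(self, code1):
        tips = {lab: ["TTT", "GGA"] for lab in ("a", "b", "c")}
        seqs, changes = fitch_ancestral(_tree_3taxon(), tips, code1)
        assert changes == 0
        assert seqs["root"] == ["TTT", "GGA"]
        assert seqs["ab"] == ["TTT", "GGA"]

    def test_three_taxon_single_change(self, code1):
        """Root set is the union {TTC, TTT}; the lexicographic tie rule
        assigns the root TTC, the (a,b) ancestor keeps TTT, one change."""
        tips = {"a": ["TTT"], "b": ["TTT"], "c": ["TTC"]}
        seqs, changes = fitch_ancestral(_tree_3taxon(), tips, code1)
        assert changes == 1
        assert seqs["root"] == ["TTC"]
        assert seqs["ab"] == ["TTT"]

    def test_missing_tip_rejected(self, code1):
        with pytest.raises(ValueError, match="without tip sequences"):
            fitch_ancestral(_tree_3taxon(), {"a": ["TTT"], "b": ["TTT"]}, code1)

    def test_gapped_columns_dropped(self, code1):
        tips = {"a": ["TTT", "---"], "b": ["TTT", "GGA"], "c": ["TTC", "GGA"]}
        seqs, _ = fitch_ancestral(_tree_3taxon(), tips, code1)
        assert len(seqs["root"]) == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_change_count_is_global_minimum(self, code1, seed):
        """Fitch parsimony length equals the exhaustive minimum over all
        internal labelings (small trees, small state set)."""
        rng = random.Random(seed)
        states = ["TTT", "TTC", "TTA"]
        n_tips = rng.choice([3, 4, 5])
        newick = {
            3: "((a:1,b:1)i1:1,c:1)r;",
            4: "(((a:1,b:1)i1:1,c:1)i2:1,d:1)r;",
            5: "((((a:1,b:1)i1:1,c:1)i2:1,d:1)i3:1,e:1)r;",
        }[n_tips]
        tree = read_newick(newick)
        n_cols = rng.randint(1, 3)
        tips = {
            lab: [rng.choice(states) for _ in range(n_cols)]
            for lab in tree.leaf_labels()
        }
        _, changes = fitch_ancestral(tree, tips, code1)
        expected = sum(
            min_changes_bruteforce(
                tree, {k: v[col] for k, v in tips.items()}, states
            )
            for col in range(n_cols)
        )
        assert changes == expected


class TestBranchOmega:
    def test_star_tree_identical_tips_all_na(self, code1):
        root = TreeNode(label="r")
        for lab in "abc":
            child = TreeNode(label=lab, length=0.1, parent=root)
            root.children.append(child)
        tree = Phylogeny(root)
        tips = {lab: ["TTT", "GGA", "ATG"] for lab in "abc"}
        table = branch_omega(tree, tips, code1)
        assert table.branches["omega"].isna().all()

    def test_two_taxon_pooling_approximates_pairwise(self, code1):
        tree = read_newick("(a:0.1,b:0.1)root;")
        model = CodonModel(code=code1, kappa=2.0, omega_default=0.3)
        aln = simulate_alignment(
            SimulationConfig(seed=17, n_codons=600, tree=tree, model=model)
        )
        tips = {k: [v[i : i + 3] for i in range(0, len(v), 3)] for k, v in aln.items()}
        table = branch_omega(
            tree, tips, code1, clades={"all": ["a", "b"]}
        )
        pooled = table.clades.set_index("clade").loc["all", "omega"]
        pair = ng86_codons(tips["a"], tips["b"], code1).omega
        # the root sequence is one of the two tips under Fitch, so pooled
        # differences equal the pairwise ones; site totals double, and the
        # Jukes-Cantor nonlinearity leaves a small gap
        assert pooled == pytest.approx(pair, rel=0.05)

    def test_clade_with_unknown_label_rejected(self, code1):
        tree = read_newick("(a:0.1,b:0.1)root;")
        tips = {"a": ["TTT"], "b": ["TTC"]}
        with pytest.raises(ValueError, match="unknown node labels"):
            branch_omega(tree, tips, code1, clades={"bad": ["a", "zzz"]})

    def test_uniform_omega_clades_within_twofold(self, code1):
        """Clock-like uniform-omega simulation: pooled clade omegas agree."""
        from fadevo.simulate import duplication_scenario

        agree = 0
        for rep in range(5):
            bundle = duplication_scenario(
                seed=300 + rep, stem_omega=0.06, background_omega=0.06
            )
            tips = {
                k: [v[i : i + 3] for i in range(0, len(v), 3)]
                for k, v in bundle.alignment.items()
            }
            a_tips = [l for l in bundle.alignment if l.startswith("a")]
            b_tips = [l for l in bundle.alignment if l.startswith("b")]
            table = branch_omega(
                bundle.tree, tips, bundle.model.code,
                clades={"A": a_tips, "B": b_tips},
            )
            omegas = table.clades.set_index("clade")["omega"]
            ratio = omegas["A"] / omegas["B"]
            agree += 0.5 <= ratio <= 2.0
        assert agree >= 4
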