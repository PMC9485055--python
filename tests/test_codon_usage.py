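"""Codon-usage statistics: RSCU, GC3s, ENc, PR2, neutrality plot, RSCU PCA."""

from __future__ import annotations

import random

import numpy as np
import pytest

from fadevo.codon_usage import (
    compute_stats,
    count_codons,
    enc,
    enc_expected,
    gc3s,
    hgt_screen,
    neutrality_fit,
    pr2,
    rscu,
    rscu_pca,
)
from fadevo.simulate import sample_biased_genome

from .conftest import make_cds, random_codons


def cds_from_codons(codons, code, seq_id="g"):
    return make_cds("".join(codons), code, seq_id)


class TestCountCodons:
    def test_exact_counts(self, code1):
        t = count_codons(make_cds("ATGTTTTTC", code1))
        assert t.counts["ATG"] == t.counts["TTT"] == t.counts["TTC"] == 1
        assert t.n == 3

    def test_empty_gene_rejected(self, code1):
        from fadevo.seqio import validate_cds

        cds = validate_cds(("g", "TAA"), code1)  # only a terminal stop
        with pytest.raises(ValueError, match="no codons"):
            count_codons(cds)

    def test_n_equals_length_over_three(self, code1):
        rng = random.Random(0)
        codons = random_codons(rng, code1, 57)
        t = count_codons(cds_from_codons(codons, code1))
        assert t.n == 57


class TestRscu:
    def test_phe_family_ratio(self, code1):
        t = count_codons(cds_from_codons(["TTT"] * 3 + ["TTC"], code1))
        r = rscu(t)
        assert r["TTT"] == pytest.approx(1.5)
        assert r["TTC"] == pytest.approx(0.5)

    def test_uniform_leucine_family(self, code1):
        fam = code1.families["L"]
        t = count_codons(cds_from_codons(list(fam) * 2, code1))
        r = rscu(t)
        for c in fam:
            assert r[c] == pytest.approx(1.0)

    def test_unobserved_family_is_na(self, code1):
        t = count_codons(make_cds("ATGTTT", code1))
        r = rscu(t)
        assert r["TGT"] is None and r["TGC"] is None

    def test_family_sums_equal_degeneracy(self, code1, code6):
        rng = random.Random(1)
        for code in (code1, code6):
            t = count_codons(cds_from_codons(random_codons(rng, code, 400), code))
            r = rscu(t)
            for fam in code.families.values():
                vals = [r[c] for c in fam]
                if all(v is not None for v in vals):
                    assert sum(vals) == pytest.approx(len(fam), abs=1e-9)


class TestGc3s:
    def test_half_gc(self, code1):
        t = count_codons(cds_from_codons(["TTT", "TTT", "TTC", "TTC"], code1))
        assert gc3s(t) == pytest.approx(0.5)

    def test_only_onefold_codons_is_na(self, code1):
        t = count_codons(make_cds("ATGTGG", code1))
        assert gc3s(t) is None

    def test_matches_per_codon_classification_oracle(self, code1):
        rng = random.Random(2)
        codons = random_codons(rng, code1, 300)
        t = count_codons(cds_from_codons(codons, code1))
        # oracle: classify each codon independently
        degen = [c for c in codons if len(code1.family_of(c)) >= 2]
        expected = sum(c[2] in "GC" for c in degen) / len(degen)
        assert gc3s(t) == pytest.approx(expected)


class TestEnc:
    def test_maximal_bias_limit_is_20(self, code1):
        codons = [fam[0] for fam in code1.families.values() for _ in range(2)]
        t = count_codons(cds_from_codons(codons, code1))
        assert enc(t) == pytest.approx(20.0, abs=1e-12)

    def test_uniform_usage_capped_at_sense_count(self, code1, code6):
        for code, cap in ((code1, 61), (code6, 63)):
            codons = [c for c in code.sense_codons for _ in range(100)]
            t = count_codons(cds_from_codons(codons, code))
            assert enc(t) == cap

    def test_uniform_uncapped_value_by_hand(self, code1):
        """With every sense codon at count 100, F_k = 99/(100k-1) per class;
        the raw class formula gives 2 + sum_k N_k/F_k > 61, hence the cap."""
        raw = 2.0
        for k, n_fam in ((2, 9), (3, 1), (4, 5), (6, 3)):
            raw += n_fam * (100 * k - 1) / 99
        assert raw > 61  # 61.41...: the cap must bind

    def test_relabeling_within_family_invariance(self, code1):
        rng = random.Random(3)
        codons = random_codons(rng, code1, 200)
        t1 = count_codons(cds_from_codons(codons, code1))
        # swap the counts of two synonymous codons (Leu family)
        fam = code1.families["L"]
        swapped = []
        for c in codons:
            if c == fam[0]:
                swapped.append(fam[1])
            elif c == fam[1]:
                swapped.append(fam[0])
            else:
                swapped.append(c)
        t2 = count_codons(cds_from_codons(swapped, code1))
        assert enc(t1) == pytest.approx(enc(t2), abs=1e-12)

    def test_short_gene_warns(self, code1, caplog):
        t = count_codons(make_cds("ATGTTT", code1))
        with caplog.at_level("WARNING", logger="fadevo"):
            enc(t)
        assert any("noisy" in r.message for r in caplog.records)


class TestEncExpected:
    @pytest.mark.parametrize("s,val", [(0.5, 60.5), (0.0, 31.0), (1.0, 32.0)])
    def test_closed_form(self, s, val):
        assert enc_expected(s) == pytest.approx(val)

    def test_domain_check(self):
        with pytest.raises(ValueError):
            enc_expected(1.5)


class TestPr2:
    def test_balanced_center(self, code1):
        fam = code1.families["G"]  # GGA GGC GGG GGT
        t = count_codons(cds_from_codons(list(fam), code1))
        point = pr2(t)
        assert point.at_bias == pytest.approx(0.5)
        assert point.gc_bias == pytest.approx(0.5)

    def test_all_a_third_positions(self, code1):
        t = count_codons(cds_from_codons(["GGA", "CCA"], code1))
        assert pr2(t).at_bias == pytest.approx(1.0)

    def test_no_fourfold_codons_is_na(self, code1):
        t = count_codons(make_cds("ATGTGGTTT", code1))
        point = pr2(t)
        assert point.at_bias is None and point.gc_bias is None


class TestNeutrality:
    def _stats(self, gc_mix, code):
        """Gene of GGG/TTT mixture: GC12 == GC3 == fraction of GGG."""
        n = 50
        k = round(gc_mix * n)
        codons = ["GGG"] * k + ["TTT"] * (n - k)
        return compute_stats(cds_from_codons(codons, code, f"g{k}"))

    def test_perfect_mutation_pressure_line(self, code1):
        stats = [self._stats(f, code1) for f in (0.1, 0.3, 0.5, 0.7, 0.9)]
        fit = neutrality_fit(stats)
        assert fit.slope == pytest.approx(1.0)
        assert fit.r == pytest.approx(1.0)

    def test_constant_gc12_gives_slope_zero(self, code1):
        stats = []
        for i, frac in enumerate((0.0, 0.25, 0.5, 0.75, 1.0)):
            n = 40
            k = round(frac * n)
            codons = ["GGC"] * k + ["GGT"] * (n - k)  # GC12 fixed at 1.0
            stats.append(compute_stats(cds_from_codons(codons, code1, f"g{i}")))
        fit = neutrality_fit(stats)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_ols(self, code1):
        stats = [self._stats(f, code1) for f in (0.1, 0.2, 0.4, 0.8, 0.9)]
        fit = neutrality_fit(stats)
        x = np.array([s.gc3 for s in stats])
        y = np.array([s.gc12 for s in stats])
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        assert fit.slope == pytest.approx(slope)
        assert fit.intercept == pytest.approx(intercept)

    def test_zero_variance_rejected(self, code1):
        stats = [self._stats(0.5, code1) for _ in range(3)]
        with pytest.raises(ValueError, match="variance"):
            neutrality_fit(stats)

    def test_too_few_genes_rejected(self, code1):
        with pytest.raises(ValueError, match=">= 3"):
            neutrality_fit([self._stats(0.1, code1), self._stats(0.9, code1)])


class TestRscuPca:
    def _profiles(self, code, n=6, length=200, seed=4):
        genes = sample_biased_genome(n, length, 0.4, seed=seed, code=code)
        return [rscu(count_codons(g)) for g in genes]

    def test_duplicate_genes_have_identical_scores(self, code1):
        prof = self._profiles(code1)
        prof.append(dict(prof[0]))
        res = rscu_pca(prof, code1)
        assert np.allclose(res.scores[0], res.scores[-1], atol=1e-10)

    def test_variance_fractions_sum_to_one(self, code1):
        res = rscu_pca(self._profiles(code1), code1)
        assert res.variance_fractions.sum() == pytest.approx(1.0)
        assert (res.variance_fractions >= 0).all()

    def test_reconstruction(self, code1):
        prof = self._profiles(code1)
        res = rscu_pca(prof, code1)
        mat = np.array(
            [[p[c] if p[c] is not None else np.nan for c in res.codons] for p in prof]
        )
        col_means = np.nanmean(mat, axis=0)
        inds = np.where(np.isnan(mat))
        mat[inds] = col_means[inds[1]]
        centered = mat - mat.mean(axis=0)
        assert np.abs(res.scores @ res.loadings.T - centered).max() < 1e-8

    def test_sign_convention(self, code1):
        res = rscu_pca(self._profiles(code1), code1)
        for j in range(res.loadings.shape[1] - 1):
            imax = np.argmax(np.abs(res.loadings[:, j]))
            assert res.loadings[imax, j] >= 0

    def test_needs_two_genes(self, code1):
        with pytest.raises(ValueError, match=">= 2"):
            rscu_pca(self._profiles(code1)[:1], code1)


class TestHgtScreen:
    def test_empty_family_rejected(self, code1):
        bg = sample_biased_genome(12, 100, 0.3, seed=1, code=code1)
        with pytest.raises(ValueError, match="family"):
            hgt_screen([], bg)

    def test_report_fields(self, code1):
        bg = sample_biased_genome(30, 150, 0.25, seed=2, code=code1, id_prefix="bg")
        fam = sample_biased_genome(5, 150, 0.25, seed=3, code=code1, id_prefix="fam")
        rep = hgt_screen(fam, bg)
        assert set(rep.table["set"]) == {"family", "background"}
        assert 0 <= rep.enc_pvalue <= 1 and 0 <= rep.gc3s_pvalue <= 1
        assert "consistent" in rep.verdict or "outlier" in rep.verdict

    def test_shifted_family_is_outlier(self, code1):
        bg = sample_biased_genome(60, 200, 0.2, seed=5, code=code1, id_prefix="bg")
        fam = sample_biased_genome(8, 200, 0.8, seed=6, code=code1, id_prefix="fam")
        rep = hgt_screen(fam, bg)
        assert rep.is_outlier
        assert rep.gc3s_pvalue < 0.01


class TestGeneratorTracksWrightCurve:
    def test_at_rich_genes_scatter_near_curve_with_small_positive_offset(self, code1):
        """Mutation-only AT-rich genes track Wright's expectation closely.

        The class-structured expectation sits slightly above the lumped
        Wright curve (about +1 to +2 ENc units at GC3 0.25), because the
        curve treats all multi-fold families as two-fold; the generator is
        mutation-only, so genes scatter tightly around that offset rather
        than falling below the curve the way selection-shaped genomes do.
        """
        genes = sample_biased_genome(150, 300, 0.25, seed=7, code=code1)
        offsets = []
        for g in genes:
            t = count_codons(g)
            offsets.append(enc(t) - enc_expected(gc3s(t)))
        mean_off = float(np.mean(offsets))
        assert 0.5 < mean_off < 3.0
        assert float(np.std(offsets)) < 4.0
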