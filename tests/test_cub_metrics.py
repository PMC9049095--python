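import math

import numpy as np
import pytest

from cubkit.composition import CodonCountTable, codon_counts
from cubkit.cub_metrics import (
    CaiWeights,
    amino_acid_usage,
    aromaticity,
    cai,
    derive_weights,
    enc,
    gravy,
    pooled_rscu,
    rscu,
)
from cubkit.sequence_io import CodingSequence

from oracles import cai_oracle, enc_oracle, random_count_table, rscu_oracle


class TestEnc:
    @pytest.mark.parametrize("estimator", ["corrected", "plugin"])
    def test_lower_limit_one_codon_per_family(self, one_codon_per_family_counts,
                                              code, estimator):
        res = enc(one_codon_per_family_counts, code, estimator=estimator)
        assert res.enc == 20.0
        assert res.n_missing_classes == 0

    @pytest.mark.parametrize("estimator", ["corrected", "plugin"])
    def test_upper_limit_uniform_usage(self, uniform_counts, code, estimator):
        assert enc(uniform_counts, code, estimator=estimator).enc == 61.0

    @pytest.mark.parametrize("estimator", ["corrected", "plugin"])
    def test_matches_oracle_on_random_tables(self, rng, code, estimator):
        for _ in range(25):
            counts = random_count_table(rng, code, n_codons=300)
            got = enc(CodonCountTable("g", counts), code, estimator=estimator).enc
            assert got == pytest.approx(enc_oracle(counts, code, estimator),
                                        abs=1e-9)

    def test_plugin_scale_invariance(self, rng, code):
        counts = random_count_table(rng, code, 300)
        scaled = {c: 7 * n for c, n in counts.items()}
        a = enc(CodonCountTable("g", counts), code, estimator="plugin").enc
        b = enc(CodonCountTable("g", scaled), code, estimator="plugin").enc
        assert a == pytest.approx(b, abs=1e-12)

    def test_corrected_converges_to_plugin(self, rng, code):
        counts = random_count_table(rng, code, 300)
        big = {c: 100 * n for c, n in counts.items()}
        plugin = enc(CodonCountTable("g", counts), code, estimator="plugin").enc
        corr1 = enc(CodonCountTable("g", counts), code, estimator="corrected").enc
        corr100 = enc(CodonCountTable("g", big), code, estimator="corrected").enc
        assert abs(corr100 - plugin) < abs(corr1 - plugin) or corr1 == plugin

    def test_stronger_bias_lowers_mean_enc(self, code):
        from cubkit.synthetic_data import RegimeSpec, generate

        encs = {}
        for conc in (0.3, 200.0):
            spec = RegimeSpec(n_genes=50, length_range=(300, 400),
                              regime="selection", bias_concentration=conc, seed=5)
            gs = generate(spec)
            encs[conc] = np.mean([enc(codon_counts(g), code).enc for g in gs.genes])
        assert encs[0.3] < encs[200.0]

    def test_missing_class_imputed_deterministically(self, code):
        counts = {}
        for aa, fam in code.degenerate_families.items():
            if aa == "I":  # drop the only 3-fold family
                continue
            for c in fam:
                counts[c] = 4
        t = CodonCountTable("g", counts)
        a = enc(t, code)
        b = enc(t, code)
        assert a == b and a.n_missing_classes == 1
        theo = enc(t, code, missing_class_policy="theoretical")
        assert 20 <= theo.enc <= 61

    def test_class_homozygosities_in_range(self, rng, code):
        counts = random_count_table(rng, code, 400)
        res = enc(CodonCountTable("g", counts), code)
        for f in res.family_homozygosities.values():
            assert 0 < f <= 1

    def test_all_classes_missing_errors(self, code):
        with pytest.raises(ValueError, match="too short"):
            enc(CodonCountTable("g", {"ATG": 3}), code)


class TestRscu:
    def test_uniform_usage_all_one(self, uniform_counts, code):
        vec = rscu(uniform_counts, code)
        assert all(v == pytest.approx(1.0) for v in vec.values.values())
        assert all(c == "typical" for c in vec.classes.values())

    def test_twofold_4_0(self, code):
        t = CodonCountTable("g", {"AAA": 4, "AAG": 0})
        vec = rscu(t, code)
        assert vec.values["AAA"] == pytest.approx(2.0)
        assert vec.values["AAG"] == pytest.approx(0.0)
        assert vec.classes["AAA"] == "over" and vec.classes["AAG"] == "under"

    def test_fourfold_2_1_1_0(self, code):
        t = CodonCountTable("g", {"GCA": 2, "GCC": 1, "GCG": 1, "GCT": 0})
        vec = rscu(t, code)
        got = [vec.values[c] for c in ("GCA", "GCC", "GCG", "GCT")]
        assert got == pytest.approx([2.0, 1.0, 1.0, 0.0])

    def test_family_sums_equal_family_size(self, small_gene_set, code):
        _, tables = small_gene_set
        for t in tables:
            vec = rscu(t, code)
            for aa, fam in code.degenerate_families.items():
                tot = sum(t.counts.get(c, 0) for c in fam)
                if tot:
                    assert sum(vec.values[c] for c in fam) == pytest.approx(
                        len(fam), abs=1e-9)

    def test_unused_family_nan_unclassified(self, code):
        t = CodonCountTable("g", {"AAA": 3})
        vec = rscu(t, code)
        assert math.isnan(vec.values["GCA"])
        assert "GCA" not in vec.classes

    def test_matches_oracle(self, rng, code):
        counts = random_count_table(rng, code, 250)
        vec = rscu(CodonCountTable("g", counts), code)
        for c, v in rscu_oracle(counts, code).items():
            assert vec.values[c] == pytest.approx(v, abs=1e-12)

    def test_met_trp_optional_carried_as_one(self, uniform_counts, code):
        t = CodonCountTable("g", {**uniform_counts.counts, "ATG": 3, "TGG": 2})
        vec = rscu(t, code, include_nondegenerate=True)
        assert vec.values["ATG"] == 1.0 and vec.values["TGG"] == 1.0
        assert "ATG" not in vec.classes


class TestPooledRscu:
    def test_single_gene_identity(self, small_gene_set, code):
        _, tables = small_gene_set
        single = rscu(tables[0], code)
        pooled = pooled_rscu(tables[:1], code)
        assert pooled.values == single.values

    def test_duplicate_gene_scale_invariance(self, small_gene_set, code):
        _, tables = small_gene_set
        one = pooled_rscu(tables[:1], code)
        two = pooled_rscu([tables[0], tables[0]], code)
        for c in one.values:
            a, b = one.values[c], two.values[c]
            assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b)

    def test_matches_oracle_on_summed_counts(self, small_gene_set, code):
        _, tables = small_gene_set
        pooled = pooled_rscu(tables, code)
        summed: dict[str, int] = {}
        for t in tables:
            for c, n in t.counts.items():
                summed[c] = summed.get(c, 0) + n
        for c, v in rscu_oracle(summed, code).items():
            got = pooled.values[c]
            assert (math.isnan(v) and math.isnan(got)) or got == pytest.approx(
                v, abs=1e-12)


class TestCaiWeights:
    def test_uniform_reference_all_one(self, uniform_counts, code):
        w = derive_weights(uniform_counts, code)
        assert all(v == 1.0 for v in w.w.values())

    def test_twofold_10_5(self, code):
        ref = CodonCountTable("r", {c: 1 for c in code.degenerate_codons})
        ref.counts.update({"AAA": 10, "AAG": 5})
        w = derive_weights(ref, code)
        assert w.w["AAA"] == 1.0 and w.w["AAG"] == 0.5

    def test_zero_count_floored_with_warning(self, code):
        counts = {c: 3 for c in code.degenerate_codons}
        counts["AAG"] = 0
        with pytest.warns(UserWarning, match="floored"):
            w = derive_weights(CodonCountTable("r", counts), code)
        assert w.w["AAG"] == 0.01

    def test_empty_family_errors_naming_it(self, code):
        counts = {c: 3 for c in code.degenerate_codons}
        for c in code.families["K"]:
            counts[c] = 0
        with pytest.raises(ValueError, match="K"):
            derive_weights(CodonCountTable("r", counts), code)

    def test_every_family_has_unit_weight(self, rng, code):
        counts = random_count_table(rng, code, 500)
        w = derive_weights(CodonCountTable("r", counts), code)
        for aa, fam in code.degenerate_families.items():
            assert max(w.w[c] for c in fam) == 1.0

    def test_nonpositive_weight_rejected(self, code):
        w = {c: 1.0 for c in code.degenerate_codons}
        w["AAA"] = 0.0
        with pytest.raises(ValueError):
            CaiWeights.from_mapping(w, code)


class TestCai:
    def test_all_maximal_codons_gives_one(self, code):
        w = CaiWeights(w={c: 1.0 for c in code.degenerate_codons})
        t = CodonCountTable("g", {"AAA": 5, "GCC": 3})
        assert cai(t, w) == pytest.approx(1.0)

    def test_geometric_mean_half(self, code):
        w = {c: 1.0 for c in code.degenerate_codons}
        w["AAG"] = 0.25
        t = CodonCountTable("g", {"AAA": 4, "AAG": 4})
        assert cai(t, CaiWeights(w=w)) == pytest.approx(0.5)

    def test_matches_log_domain_oracle(self, rng, code):
        for _ in range(20):
            counts = random_count_table(rng, code, 200)
            wmap = {c: float(rng.uniform(0.05, 1.0)) for c in code.degenerate_codons}
            weights = CaiWeights(w=wmap)
            got = cai(CodonCountTable("g", counts), weights)
            assert got == pytest.approx(cai_oracle(counts, weights.w, code),
                                        rel=1e-10)

    def test_range_bounds(self, rng, code):
        counts = random_count_table(rng, code, 150)
        wmap = {c: float(rng.uniform(0.1, 1.0)) for c in code.degenerate_codons}
        weights = CaiWeights(w=wmap)
        v = cai(CodonCountTable("g", counts), weights)
        assert min(weights.w.values()) <= v <= 1.0

    def test_met_trp_excluded(self, code):
        w = CaiWeights(w={c: 0.5 for c in code.degenerate_codons})
        with_met = CodonCountTable("g", {"AAA": 2, "ATG": 50})
        without = CodonCountTable("g", {"AAA": 2})
        assert cai(with_met, w) == pytest.approx(cai(without, w))


class TestProteinMetrics:
    def test_gravy_ile(self):
        assert gravy("III") == pytest.approx(4.5)

    def test_gravy_arg(self):
        assert gravy("RRR") == pytest.approx(-4.5)

    def test_gravy_permutation_invariant(self, rng):
        prot = "".join(rng.permutation(list("ACDEFGHIKLMNPQRSTVWY")))
        assert gravy(prot) == pytest.approx(gravy(prot[::-1]))

    def test_gravy_errors(self):
        with pytest.raises(ValueError):
            gravy("")
        with pytest.raises(ValueError, match="unknown residue"):
            gravy("AXZ")

    def test_aromaticity_examples(self):
        assert aromaticity("FYWA") == pytest.approx(0.75)
        assert aromaticity("AAAA") == 0.0
        assert aromaticity("W") == 1.0
        with pytest.raises(ValueError):
            aromaticity("")


class TestAminoAcidUsage:
    def test_single_gene(self, code):
        t = codon_counts(CodingSequence("g", "ATGAAATAA"))
        usage = amino_acid_usage([t], code)
        assert usage["M"] == pytest.approx(0.5)
        assert usage["K"] == pytest.approx(0.5)

    def test_all_leu(self, code):
        t = CodonCountTable("g", {"CTG": 9, "TTA": 1})
        usage = amino_acid_usage([t], code)
        assert usage["L"] == pytest.approx(1.0)

    def test_sums_to_one_and_matches_direct_count(self, small_gene_set, code):
        _, tables = small_gene_set
        usage = amino_acid_usage(tables, code)
        assert usage.sum() == pytest.approx(1.0)
        direct: dict[str, int] = {}
        for t in tables:
            for c, n in t.counts.items():
                aa = code.codon_to_aa[c]
                direct[aa] = direct.get(aa, 0) + n
        total = sum(direct.values())
        for aa, n in direct.items():
            assert usage[aa] == pytest.approx(n / total)
        assert list(usage.values) == sorted(usage.values, reverse=True)
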