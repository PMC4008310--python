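"""Single-codon indices: counts, frequencies, GC partitions, RSCU, ENC, CAI."""

import math

import numpy as np
import pytest

import codonpatterns as cp
from codonpatterns.genetic_code import STANDARD_CODE
from conftest import make_cds


def wright_enc_oracle(counts):
    """Independent re-statement of Wright's formula: per-family F from raw
    arithmetic, class means, 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6."""
    code = STANDARD_CODE
    class_fs = {}
    for k, aas in code.degeneracy_classes.items():
        for aa in aas:
            xs = [counts.get(c, 0) for c in code.families[aa]]
            n = sum(xs)
            if n < 2:
                continue
            f = (n * sum((x / n) ** 2 for x in xs) - 1) / (n - 1)
            class_fs.setdefault(k, []).append(f)
    fbar = {k: sum(v) / len(v) for k, v in class_fs.items()}
    if 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2
    value = 2 + 9 / fbar[2] + 1 / fbar[3] + 5 / fbar[4] + 3 / fbar[6]
    return min(value, 61.0)


class TestGeneticCode:
    def test_family_structure(self):
        code = STANDARD_CODE
        assert sum(len(f) for f in code.families.values()) == 64
        assert code.single_codon_aas == ("M", "W")
        assert {k: len(v) for k, v in code.degeneracy_classes.items()} == {
            2: 9, 3: 1, 4: 5, 6: 3,
        }
        assert len(code.sense_codons) == 61
        assert len(code.synonymous_codons) == 59


class TestCountsAndFrequencies:
    def test_count_exclusions(self):
        seq = make_cds("AUG GCU AAG UAA")
        t = cp.count_codons([seq])
        assert t.counts["GCU"] == 1 and t.counts["AAG"] == 1 and t.n == 2
        t2 = cp.count_codons([seq], exclude_start=False, exclude_stop=False)
        assert t2.n == 4 and t2.counts["AUG"] == 1 and t2.counts["UAA"] == 1

    def test_internal_aug_counted(self):
        t = cp.count_codons([make_cds("AUG AUG GCU UAA")])
        assert t.counts["AUG"] == 1

    def test_permille(self):
        t = cp.CodonCountTable({"AAA": 1, "AAG": 3})
        f = cp.codon_frequencies_permille(t)
        assert f["AAG"] == 750.0
        assert math.isclose(sum(f.values()), 1000.0)

    def test_permille_uniform(self):
        t = cp.CodonCountTable({c: 5 for c in cp.ALL_CODONS})
        f = cp.codon_frequencies_permille(t)
        assert all(math.isclose(v, 1000 / 64) for v in f.values())

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            cp.codon_frequencies_permille(cp.CodonCountTable({}))


class TestGCPartitions:
    def test_positional_gc(self):
        t = cp.CodonCountTable.from_codons(["AAA", "GGG"])
        p = cp.gc_partitions(t)
        assert p.gc1 == p.gc2 == p.gc3 == 0.5

    def test_gc3s_excludes_nonsynonymous(self):
        t = cp.CodonCountTable.from_codons(["AUG", "AAA", "AAG", "UAA"])
        p = cp.gc_partitions(t)
        assert p.gc3s == 0.5  # AUG and UAA excluded; AAA->A, AAG->G

    def test_gc_identity(self, null_reference):
        table, _ = null_reference
        p = cp.gc_partitions(table)
        assert math.isclose(p.gc, (p.gc1 + p.gc2 + p.gc3) / 3)


class TestRSCU:
    def test_lys_63_percent_share(self):
        # AAG at a 63.0% family share -> RSCU = 2 x 0.630 = 1.26
        t = cp.CodonCountTable({"AAG": 630, "AAA": 370})
        assert math.isclose(cp.rscu(t)["AAG"], 1.26)

    def test_equal_counts_give_one(self):
        t = cp.CodonCountTable({c: 7 for c in STANDARD_CODE.families["L"]})
        assert all(math.isclose(v, 1.0) for c, v in cp.rscu(t).items() if c in STANDARD_CODE.families["L"])

    def test_family_sums_equal_degeneracy(self, null_reference):
        table, _ = null_reference
        values = cp.rscu(table)
        for aa, fam in STANDARD_CODE.families.items():
            if fam[0] in values:
                assert math.isclose(sum(values[c] for c in fam), len(fam))

    def test_stop_family_included_but_missing_family_absent(self):
        t = cp.CodonCountTable({"UAA": 1, "UGA": 2, "UAG": 0})
        values = cp.rscu(t)
        assert math.isclose(values["UGA"], 2.0)
        assert "AAA" not in values  # Lys family unobserved -> missing, not 0


class TestENC:
    def test_family_homozygosity_example(self):
        t = cp.CodonCountTable({"AAG": 3, "AAA": 1})
        fh = cp.family_homozygosity(t)
        n, f = fh.per_family["K"]
        assert n == 4 and math.isclose(f, 0.5)  # sum p^2 = 0.625

    def test_exclusive_codon_gives_f_one(self):
        t = cp.CodonCountTable({"AAG": 50})
        _, f = cp.family_homozygosity(t).per_family["K"]
        assert f == 1.0

    def test_uniform_two_fold_limit(self):
        t = cp.CodonCountTable({"AAG": 10_000, "AAA": 10_000})
        _, f = cp.family_homozygosity(t).per_family["K"]
        assert abs(f - 0.5) < 1e-4

    def test_enc_20_when_one_codon_per_aa(self):
        counts = {fam[0]: 100 for aa, fam in STANDARD_CODE.families.items() if aa != "*"}
        assert cp.enc(cp.CodonCountTable(counts)) == 20.0

    def test_enc_61_under_uniform_usage(self):
        t = cp.CodonCountTable({c: 1000 for c in STANDARD_CODE.sense_codons})
        assert cp.enc(t) == 61.0

    def test_enc_matches_formula_oracle_on_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            counts = {
                c: int(x)
                for c, x in zip(
                    STANDARD_CODE.sense_codons,
                    rng.integers(0, 40, len(STANDARD_CODE.sense_codons)),
                )
            }
            got = cp.enc(cp.CodonCountTable(counts))
            if got is None:
                continue
            assert math.isclose(got, wright_enc_oracle(counts), abs_tol=1e-12)

    def test_enc_range_and_concentration_monotonicity(self):
        prev = None
        for share in np.linspace(0.5, 0.99, 12):
            counts = {"AAG": int(10_000 * share), "AAA": int(10_000 * (1 - share))}
            # fill the other families uniformly so ENC is defined
            for aa, fam in STANDARD_CODE.families.items():
                if aa in ("*", "K"):
                    continue
                for c in fam:
                    counts[c] = 500
            value = cp.enc(cp.CodonCountTable(counts))
            assert 20.0 <= value <= 61.0
            if prev is not None:
                assert value <= prev + 1e-9
            prev = value


class TestExpectedENC:
    def test_reference_points(self):
        assert math.isclose(cp.expected_enc(0.5), 60.5)
        assert math.isclose(cp.expected_enc(0.0), 31.0)

    def test_asymmetry_is_exactly_the_linear_term(self):
        for s in (0.1, 0.25, 0.4):
            assert math.isclose(
                cp.expected_enc(s) - cp.expected_enc(1 - s), s - (1 - s)
            )

    def test_domain(self):
        with pytest.raises(ValueError):
            cp.expected_enc(1.5)


class TestCAI:
    def test_weights_ratio(self):
        t = cp.CodonCountTable({"AAG": 63, "AAA": 37})
        w = cp.cai_weights(t)
        assert w["AAG"] == 1.0 and math.isclose(w["AAA"], 37 / 63)

    def test_uniform_reference_all_ones(self):
        t = cp.CodonCountTable({c: 9 for c in STANDARD_CODE.sense_codons})
        w = cp.cai_weights(t)
        assert all(v == 1.0 for v in w.weights.values())

    def test_zero_count_pseudo_count_policy(self):
        t = cp.CodonCountTable({"AAG": 80, "AAA": 0})
        w = cp.cai_weights(t)
        assert math.isclose(w["AAA"], 0.5 / 80)

    def test_max_weight_is_one_per_family(self, null_reference):
        _, weights = null_reference
        for aa, fam in STANDARD_CODE.families.items():
            ws = [weights.weights[c] for c in fam if c in weights]
            if ws:
                assert math.isclose(max(ws), 1.0)

    def test_no_weights_for_start_stop_trp(self, null_reference):
        _, weights = null_reference
        for c in ("AUG", "UGG", "UAA", "UAG", "UGA"):
            assert c not in weights

    def test_geometric_mean(self):
        w = cp.CAIWeights({"AAG": 1.0, "AAA": 0.25})
        assert math.isclose(cp.cai(["AAG", "AAA"], w), 0.5)

    def test_all_maximal_gene_has_cai_one(self):
        w = cp.CAIWeights({"AAG": 1.0, "GCU": 1.0})
        assert cp.cai(["AAG", "GCU", "AAG"], w) == 1.0

    def test_duplication_invariance(self, null_dataset, null_reference):
        _, weights = null_reference
        seq = null_dataset.cds[0]
        doubled = cp.CodingSequence(
            id="dbl", codons=seq.codons[:-1] + seq.internal_codons + (seq.codons[-1],)
        )
        assert math.isclose(cp.cai(seq, weights), cp.cai(doubled, weights))

    def test_log_form_matches_product_form(self):
        w = cp.CAIWeights({"AAG": 1.0, "AAA": 0.3, "GCU": 0.7})
        codons = ["AAG", "AAA", "GCU", "AAA"]
        product = (1.0 * 0.3 * 0.7 * 0.3) ** 0.25
        assert math.isclose(cp.cai(codons, w), product)

    def test_reference_from_top_rpkm_picks_highest(self, null_dataset):
        table, name = cp.reference_from_top_rpkm(null_dataset.cds, 0.05)
        assert "top-rpkm" in name and table.n > 0


class TestOtherIndices:
    def test_ncg_ncc_equal_counts(self):
        counts = {n + "CG": 4 for n in "UCAG"}
        counts.update({n + "CC": 4 for n in "UCAG"})
        assert cp.ncg_ncc_ratio(cp.CodonCountTable(counts)) == 1.0

    def test_ncg_ncc_zero_numerator(self):
        counts = {n + "CC": 4 for n in "UCAG"}
        assert cp.ncg_ncc_ratio(cp.CodonCountTable(counts)) == 0.0

    def test_ncg_ncc_zero_denominator_undefined(self):
        counts = {n + "CG": 4 for n in "UCAG"}
        assert cp.ncg_ncc_ratio(cp.CodonCountTable(counts)) is None

    def test_high_frequency_uniform_empty(self):
        t = cp.CodonCountTable({c: 10 for c in STANDARD_CODE.sense_codons})
        assert cp.high_frequency_codons(t) == set()

    def test_high_frequency_share_rule(self):
        # 2-fold family at shares (0.61, 0.39): RSCU 1.22 < 1.5 but share > 60%
        t = cp.CodonCountTable({"AAG": 61, "AAA": 39})
        assert cp.high_frequency_codons(t) == {"AAG"}

    def test_high_frequency_rscu_rule(self):
        counts = {"GCU": 60, "GCC": 20, "GCA": 10, "GCG": 10}  # RSCU(GCU)=2.4
        assert cp.high_frequency_codons(cp.CodonCountTable(counts)) == {"GCU"}

    def test_singletons_never_high_frequency(self):
        t = cp.CodonCountTable({"AUG": 1000, "UGG": 1000, "AAG": 1, "AAA": 1})
        assert cp.high_frequency_codons(t) == set()


class TestSummaryAndGeneMetrics:
    def test_single_pass_summary_consistency(self, null_reference):
        table, weights = null_reference
        df = cp.summarize_codon_table(table, weights)
        assert len(df) == 64
        assert df["count"].sum() == table.n
        assert math.isclose(df["frequency_permille"].sum(), 1000.0)
        # per-family RSCU sums equal degeneracy where observed
        for aa, grp in df.groupby("amino_acid"):
            if grp["rscu"].notna().all() and grp["count"].sum() > 0:
                assert math.isclose(grp["rscu"].sum(), len(grp))
                assert math.isclose(grp["family_share"].sum(), 1.0)

    def test_gene_metrics_fields(self, null_dataset, null_reference):
        _, weights = null_reference
        df = cp.gene_metrics(null_dataset.cds[:20], weights)
        assert set(df.columns) >= {"id", "n_codons", "gc3s", "enc", "cai"}
        assert df["cai"].between(0, 1).all()
        assert df["enc"].dropna().between(20, 61).all()
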