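import math

import numpy as np
import pytest

from cubkit.codonio import CodonCountTable, codon_counts
from cubkit.composition import composition_profile
from cubkit.cub_indices import (
    FLAVOUR_CLASSES,
    OptimalCodonSet,
    ReferenceWeights,
    cai,
    cbi,
    cub_indices,
    derive_optimal_codons,
    enc,
    fop,
    mean_rscu,
    read_codon_value_file,
    rscu,
    weights_from_rscu,
    write_codon_value_file,
)
from cubkit.bias_analysis import expected_enc
from cubkit.errors import UndefinedStatisticError, ValidationError
from cubkit.synthetic_data import SyntheticSpec, generate_cds


class TestRSCU:
    def test_single_codon_aa_is_one(self, code):
        t = CodonCountTable("g", {"ATG": 110})
        assert rscu(t, code).rscu_of("AUG") == 1.0

    def test_phe_by_hand(self, code):
        t = CodonCountTable("g", {"TTT": 3, "TTC": 1})
        table = rscu(t, code)
        assert table.rscu_of("UUU") == pytest.approx(1.5)
        assert table.rscu_of("UUC") == pytest.approx(0.5)

    def test_uniform_sixfold_all_one(self, code):
        t = CodonCountTable("g", {c: 4 for c in code.family_of["Leu"]})
        table = rscu(t, code)
        for c in code.family_of["Leu"]:
            assert table.rscu_of(c.replace("T", "U")) == pytest.approx(1.0)

    def test_unobserved_family_undefined_not_zero(self, code):
        t = CodonCountTable("g", {"TTT": 1})
        table = rscu(t, code)
        assert table.rscu_of("GGG") is None

    def test_stop_family_included_on_request(self, code):
        t = CodonCountTable("g", {"TAA": 1, "TGA": 2})
        with_stops = rscu(t, code, include_stops=True)
        assert with_stops.rscu_of("UGA") == pytest.approx(2 * 3 / 3)
        without = rscu(t, code)
        with pytest.raises(KeyError):
            without.rscu_of("UGA")

    def test_family_sums_equal_degeneracy(self, code, random_table_factory):
        for _ in range(200):
            t = random_table_factory()
            table = rscu(t, code, include_stops=True)
            sums = {}
            for row in table.rows:
                if row.rscu is not None:
                    sums.setdefault(row.amino_acid, 0.0)
                    sums[row.amino_acid] += row.rscu
            for aa, total in sums.items():
                assert total == pytest.approx(code.degeneracy[aa], abs=1e-9)

    def test_scale_invariance(self, code, random_table_factory):
        t = random_table_factory()
        r1, r2 = rscu(t, code), rscu(t.scaled(5), code)
        for a, b in zip(r1.rows, r2.rows):
            if a.rscu is None:
                assert b.rscu is None
            else:
                assert a.rscu == pytest.approx(b.rscu, abs=1e-12)

    def test_preference_flags(self, code):
        t = CodonCountTable("g", {"TTT": 9, "TTC": 1, "CTG": 11, "CTT": 1})
        rows = {r.codon: r for r in rscu(t, code).rows}
        assert rows["UUU"].rscu == pytest.approx(1.8)
        assert rows["UUU"].preference == "preferred"
        assert rows["UUC"].preference == "none"
        assert rows["CUG"].rscu == pytest.approx(11 * 6 / 12)  # 5.5 > 2
        assert rows["CUG"].preference == "strong"

    def test_flavour_tags(self, code):
        t = CodonCountTable("g", {"ATT": 1, "CTT": 1, "GTT": 1})
        rows = {r.codon: r for r in rscu(t, code).rows}
        assert set(rows["AUU"].flavour) == {"DAA", "SAA", "BCAA"}  # Ile in all three
        assert set(rows["CUU"].flavour) == {"SAA", "BCAA"}  # Leu
        assert set(rows["GUU"].flavour) == {"BCAA"}  # Val


class TestMeanRSCU:
    def test_idempotent_on_identical_tables(self, code, random_table_factory):
        t = random_table_factory()
        table = rscu(t, code)
        averaged = mean_rscu([table, table, table])
        for a, b in zip(averaged.rows, table.rows):
            if b.rscu is None:
                assert a.rscu is None
            else:
                assert a.rscu == pytest.approx(b.rscu)
            assert a.count == 3 * b.count

    def test_mean_matches_hand_average(self, code):
        tables = [
            rscu(CodonCountTable("a", {"TTT": 3, "TTC": 1}), code),  # 1.5, 0.5
            rscu(CodonCountTable("b", {"TTT": 1, "TTC": 3}), code),  # 0.5, 1.5
            rscu(CodonCountTable("c", {"TTT": 1, "TTC": 1}), code),  # 1.0, 1.0
        ]
        averaged = mean_rscu(tables)
        assert averaged.rscu_of("UUU") == pytest.approx((1.5 + 0.5 + 1.0) / 3)
        assert averaged.count_of("UUU") == 5

    def test_skips_unobserved_species(self, code):
        tables = [
            rscu(CodonCountTable("a", {"TTT": 3, "TTC": 1}), code),
            rscu(CodonCountTable("b", {"GGG": 4}), code),  # Phe unobserved
        ]
        averaged = mean_rscu(tables)
        assert averaged.rscu_of("UUU") == pytest.approx(1.5)

    def test_family_sum_preserved(self, code, random_table_factory):
        tables = [rscu(random_table_factory(), code) for _ in range(5)]
        averaged = mean_rscu(tables)
        sums = {}
        for row in averaged.rows:
            if row.rscu is not None:
                sums.setdefault(row.amino_acid, 0.0)
                sums[row.amino_acid] += row.rscu
        for aa, total in sums.items():
            assert total == pytest.approx(code.degeneracy[aa], abs=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            mean_rscu([])


class TestENC:
    def test_minimum_20_single_codon_per_family(self, code):
        counts = {code.family_of[aa][0]: 10 for aa in code.amino_acids()}
        assert enc(CodonCountTable("g", counts), code) == pytest.approx(20.0)

    def test_uniform_59_caps_at_61(self, code):
        t = CodonCountTable("g", {c: 100 for c in code.synonymous_codons()})
        assert enc(t, code) == 61.0
        # raw Wright value exceeds the cap: F_2 = 99/199 etc.
        raw = 2 + 9 / (99 / 199) + 1 / (99 / 299) + 5 / (99 / 399) + 3 / (99 / 599)
        assert raw > 61

    def test_imputes_threefold_class(self, code):
        # no Ile codons at all: F3 imputed from (F2+F4)/2
        counts = {}
        for aa in code.amino_acids():
            if aa == "Ile":
                continue
            for c in code.family_of[aa]:
                counts[c] = 10
        value = enc(CodonCountTable("g", counts), code)
        assert 20 <= value <= 61

    def test_undefined_when_all_empty(self, code):
        with pytest.raises(UndefinedStatisticError):
            enc(CodonCountTable("g", {"ATG": 5}), code)

    def test_monotone_under_concentration(self, code):
        # interpolate from uniform usage to single-codon usage
        values = []
        for lam in np.linspace(0, 1, 8):
            counts = {}
            for aa in code.amino_acids():
                fam = code.family_of[aa]
                n = 600
                for k, c in enumerate(fam):
                    uniform = n / len(fam)
                    point = n if k == 0 else 0
                    counts[c] = int(round((1 - lam) * uniform + lam * point))
            values.append(enc(CodonCountTable("g", counts), code))
        assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))
        assert values[-1] == pytest.approx(20.0, abs=0.01)

    @pytest.mark.parametrize("theta", [0.3, 0.5, 0.7])
    def test_tracks_expected_curve_without_selection(self, code, theta):
        spec = SyntheticSpec(n_genes=1, n_codons=10_000, seed=5, gc3_pressure=theta)
        t = codon_counts(generate_cds(spec)[0], code)
        gc3s = composition_profile(t, code).gc3s
        assert abs(enc(t, code) - expected_enc(gc3s)) < 2.0


class TestCAI:
    def test_all_weights_one(self, code):
        w = ReferenceWeights({c: 1.0 for c in code.synonymous_codons()})
        t = CodonCountTable("g", {"TTT": 5, "GGG": 5})
        assert cai(t, w) == pytest.approx(1.0)

    def test_constant_half_weights(self, code):
        w = ReferenceWeights({c: 0.5 for c in code.synonymous_codons()})
        t = CodonCountTable("g", {"TTT": 5, "GGG": 5})
        assert cai(t, w) == pytest.approx(0.5)

    def test_geometric_mean_by_hand(self, code):
        weights = {c: 1.0 for c in code.synonymous_codons()}
        weights["TTC"] = 0.25
        w = ReferenceWeights(weights)
        t = CodonCountTable("g", {"TTT": 1, "TTC": 1})  # w = 1 and 0.25
        assert cai(t, w) == pytest.approx(math.sqrt(0.25))

    def test_met_trp_stops_excluded(self, code):
        w = ReferenceWeights({c: 0.5 for c in code.synonymous_codons()})
        t = CodonCountTable("g", {"TTT": 2, "ATG": 50, "TGG": 50, "TAA": 5})
        assert cai(t, w) == pytest.approx(0.5)

    def test_floor_applied_to_missing_weight(self, code):
        w = ReferenceWeights({"TTT": 1.0})
        t = CodonCountTable("g", {"TTT": 1, "TTC": 1})
        assert cai(t, w, floor=0.01) == pytest.approx(math.sqrt(0.01))

    def test_undefined_without_eligible_codons(self, code):
        w = ReferenceWeights({"TTT": 1.0})
        with pytest.raises(UndefinedStatisticError):
            cai(CodonCountTable("g", {"ATG": 3}), w)

    def test_weight_validation(self):
        with pytest.raises(ValidationError):
            ReferenceWeights({"TTT": 0.0})
        with pytest.raises(ValidationError):
            ReferenceWeights({"TTT": 1.5})


class TestFopCbi:
    @pytest.fixture
    def optimal(self, code):
        return OptimalCodonSet.from_codons(["TTC"], "test", code)

    def test_fop_all_optimal(self, code, optimal):
        assert fop(CodonCountTable("g", {"TTC": 10}), optimal, code) == 1.0

    def test_fop_none_optimal(self, code, optimal):
        assert fop(CodonCountTable("g", {"TTT": 10}), optimal, code) == 0.0

    def test_fop_ratio(self, code, optimal):
        t = CodonCountTable("g", {"TTC": 30, "TTT": 30, "GGG": 60})
        assert fop(t, optimal, code) == pytest.approx(30 / 120)

    def test_fop_undefined(self, code, optimal):
        with pytest.raises(UndefinedStatisticError):
            fop(CodonCountTable("g", {"ATG": 1}), optimal, code)

    def test_cbi_all_optimal(self, code, optimal):
        assert cbi(CodonCountTable("g", {"TTC": 10}), optimal, code) == pytest.approx(1.0)

    def test_cbi_uniform_usage_zero(self, code):
        optimal = OptimalCodonSet.from_codons(["TTC", "GGG"], "test", code)
        t = CodonCountTable("g", {"TTT": 5, "TTC": 5,
                                  "GGT": 5, "GGC": 5, "GGA": 5, "GGG": 5})
        assert cbi(t, optimal, code) == pytest.approx(0.0)

    def test_cbi_by_hand_negative(self, code, optimal):
        # one 2-fold family, counts (optimal 1, other 3)
        t = CodonCountTable("g", {"TTC": 1, "TTT": 3})
        # N_tot=4, N_opt=1, N_ran=2 -> (1-2)/(4-2) = -0.5
        assert cbi(t, optimal, code) == pytest.approx(-0.5)

    def test_cbi_degenerate_denominator(self, code, optimal):
        with pytest.raises(UndefinedStatisticError):
            cbi(CodonCountTable("g", {"ATG": 4}), optimal, code)

    def test_optimal_set_rejects_nonsynonymous(self, code):
        with pytest.raises(ValidationError):
            OptimalCodonSet.from_codons(["ATG"], code=code)
        with pytest.raises(ValidationError):
            OptimalCodonSet.from_codons(["TAA"], code=code)

    def test_scale_invariance(self, code, random_table_factory, optimal):
        t = random_table_factory()
        w = ReferenceWeights({c: 0.8 for c in code.synonymous_codons()})
        try:
            base = cub_indices(t, w, optimal, code)
            scaled = cub_indices(t.scaled(3), w, optimal, code)
        except UndefinedStatisticError:
            pytest.skip("degenerate random table")
        assert base.cai == pytest.approx(scaled.cai, abs=1e-12)
        assert base.fop == pytest.approx(scaled.fop, abs=1e-12)
        assert base.cbi == pytest.approx(scaled.cbi, abs=1e-12)


class TestDeriveOptimal:
    def test_single_table_argmax(self, code):
        table = rscu(CodonCountTable("g", {"TTT": 3, "TTC": 1}), code)
        chosen = derive_optimal_codons([table], code)
        assert "TTT" in chosen.codons
        assert "TTC" not in chosen.codons

    def test_uniform_tie_breaks_canonical(self, code):
        t = CodonCountTable("g", {c: 2 for c in code.synonymous_codons()})
        chosen = derive_optimal_codons([rscu(t, code)], code)
        for aa in code.amino_acids():
            fam = code.family_of[aa]
            if len(fam) < 2:
                continue
            assert fam[0] in chosen.codons  # first codon in canonical order

    def test_matches_argmax_oracle(self, code, random_table_factory):
        tables = [rscu(random_table_factory(), code) for _ in range(7)]
        chosen = derive_optimal_codons(tables, code)
        # oracle: brute-force mean and argmax per family
        for aa in code.amino_acids():
            fam = code.family_of[aa]
            if len(fam) < 2:
                continue
            best, best_val = None, -1.0
            for c in fam:
                vals = [t.rscu_of(c.replace("T", "U")) for t in tables]
                vals = [v for v in vals if v is not None]
                if not vals:
                    continue
                mean = sum(vals) / len(vals)
                if mean > best_val + 1e-15:
                    best, best_val = c, mean
            if best is not None:
                assert best in chosen.codons, aa


class TestWeightFiles:
    def test_roundtrip(self, tmp_path, code):
        table = rscu(CodonCountTable("g", {"TTT": 3, "TTC": 1, "GGG": 2, "GGC": 2}), code)
        w = weights_from_rscu(table, code)
        assert w.weights["TTT"] == 1.0
        assert w.weights["TTC"] == pytest.approx(1 / 3)
        path = tmp_path / "w.tsv"
        write_codon_value_file(w.weights, path)
        back = read_codon_value_file(path)
        for codon, value in w.weights.items():
            assert back[codon] == pytest.approx(value, abs=1e-6)

    def test_flavour_classes_fixed(self):
        assert FLAVOUR_CLASSES["DAA"] == {"Glu", "Gly", "Ser", "Asp", "Arg", "Ile"}
        assert FLAVOUR_CLASSES["SAA"] == {"Phe", "Cys", "Ile", "Leu"}
        assert FLAVOUR_CLASSES["BCAA"] == {"Leu", "Ile", "Val"}
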