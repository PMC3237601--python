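"""Pair/single contact propensities and their chi-squared statistics."""

import numpy as np
import pytest
from scipy.integrate import quad

from pairface.alphabet import AA_ALPHABET, AA_INDEX
from pairface.propensity import (PropensityModel, chi_squared,
                                 chi_squared_pvalue, count_pairs,
                                 expected_contacts, pair_propensity,
                                 single_residue_propensity)
from pairface.structure import ContactTable


def table_from_sequences(lig_seq, rec_seq, labels, cid="c"):
    return ContactTable(
        cid,
        [("L", i + 1, aa) for i, aa in enumerate(lig_seq)],
        [("R", j + 1, aa) for j, aa in enumerate(rec_seq)],
        labels=np.asarray(labels),
    )


class TestCountPairs:
    def test_two_by_two_enumeration(self):
        # ligand DR x receptor RY enumerates pairs D-R, D-Y, R-R, R-Y
        t = table_from_sequences("DR", "RY", np.zeros((2, 2)))
        s = count_pairs([t])
        D, R, Y = AA_INDEX["D"], AA_INDEX["R"], AA_INDEX["Y"]
        assert s.pair_count[D, R] == 1  # D(lig) x R(rec); no R(lig) x D(rec)
        assert s.pair_count[R, R] == 1
        assert s.pair_count[D, Y] == 1
        assert s.pair_count[R, Y] == 1
        assert s.total_pairs == 4

    def test_duplicated_complex_doubles_counts(self, small_fixture_set):
        _, _, tables, _ = small_fixture_set
        once = count_pairs(tables[:2])
        twice = count_pairs(tables[:2] + tables[:2])
        assert (twice.pair_count == 2 * once.pair_count).all()
        assert (twice.observed == 2 * once.observed).all()

    def test_totals_match_brute_force_recount(self, small_fixture_set):
        _, _, tables, _ = small_fixture_set
        s = count_pairs(tables)
        brute_pairs = np.zeros((20, 20), dtype=int)
        brute_obs = np.zeros((20, 20), dtype=int)
        for t in tables:
            for i, (_, _, la) in enumerate(t.ligand_residues):
                for j, (_, _, ra) in enumerate(t.receptor_residues):
                    a, b = sorted((AA_INDEX[la], AA_INDEX[ra]))
                    brute_pairs[a, b] += 1
                    brute_obs[a, b] += t.labels[i, j]
        iu = np.triu_indices(20)
        assert (s.pair_count[iu] == brute_pairs[iu]).all()
        assert (s.observed[iu] == brute_obs[iu]).all()
        assert s.total_pairs == sum(t.n_pairs for t in tables)
        assert s.total_contacts == sum(t.n_contacts for t in tables)

    def test_unknown_residue_type_rejected(self):
        t = ContactTable("c", [("L", 1, "A")], [("R", 1, "G")], [[0]])
        t.ligand_residues = [("L", 1, "X")]
        with pytest.raises(ValueError, match="unknown residue type"):
            count_pairs([t])


class TestExpectedPropensityChi2:
    def test_expected_equals_total_when_pair_count_is_total(self):
        assert expected_contacts(500, 500, 123) == pytest.approx(123.0)

    def test_zero_total_pairs_rejected(self):
        with pytest.raises(ValueError):
            expected_contacts(10, 0, 5)

    def test_propensity_one_at_no_enrichment(self):
        assert pair_propensity(55.0, 55.0) == pytest.approx(1.0)

    def test_propensity_flagged_missing_for_zero_expected(self):
        assert np.isnan(pair_propensity(3.0, 0.0))

    def test_chi_squared_zero_at_no_enrichment(self):
        assert chi_squared(90.0, 90.0) == 0.0

    def test_chi_squared_rejects_nonpositive_expected(self):
        with pytest.raises(ValueError):
            chi_squared(10.0, 0.0)

    def test_chi_squared_symmetric_in_side_labelling(self, small_fixture_set):
        # transposing every table (swap ligand/receptor roles) leaves the
        # symmetrized counts, hence chi-squared, unchanged
        _, _, tables, _ = small_fixture_set
        s = count_pairs(tables)
        s_t = count_pairs([t.transpose() for t in tables])
        assert (s.pair_count == s_t.pair_count).all()
        assert (s.observed == s_t.observed).all()


class TestChiSquaredPvalue:
    def test_zero_statistic_gives_one(self):
        assert chi_squared_pvalue(0.0) == 1.0

    def test_classical_five_percent_point(self):
        # independent oracle: numerical integration of the 1-df density
        density = lambda x: np.exp(-x / 2) / np.sqrt(2 * np.pi * x)
        expected, _ = quad(density, 3.8415, np.inf)
        assert expected == pytest.approx(0.05, abs=1e-4)
        assert chi_squared_pvalue(3.8415) == pytest.approx(expected, rel=1e-6)

    def test_strictly_decreasing_in_chi2(self):
        grid = np.linspace(0, 50, 201)
        p = chi_squared_pvalue(grid)
        assert (np.diff(p) < 0).all()

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_pvalue(-1.0)


class TestSingleResiduePropensity:
    def test_everything_in_interface_gives_unit_propensity(self):
        t = table_from_sequences("ACD", "ACD", np.ones((3, 3)))
        prop = single_residue_propensity([t])
        for aa in "ACD":
            assert prop[aa] == pytest.approx(1.0)

    def test_only_arg_interface_is_enriched(self):
        # R residues carry the only contacts; all other types excluded
        t = table_from_sequences("RAAA", "RGGG",
                                 np.eye(4, 4, dtype=int) * 0)
        t.labels[0, 0] = 1
        prop = single_residue_propensity([t])
        assert prop["R"] > 1
        assert prop["A"] < 1 and prop["G"] < 1

    def test_absent_type_flagged_missing(self):
        t = table_from_sequences("AA", "GG", [[1, 0], [0, 0]])
        prop = single_residue_propensity([t])
        assert np.isnan(prop["W"])


class TestPropensityResults:
    def test_expected_contacts_conserved(self, small_fixture_set):
        _, _, tables, _ = small_fixture_set
        res = PropensityModel(tables).fit()
        assert res.pair_table["expected"].sum() == pytest.approx(
            res.total_contacts, rel=1e-12
        )

    def test_scale_invariance_of_propensity(self, small_fixture_set):
        _, _, tables, _ = small_fixture_set
        s = count_pairs(tables)
        doubled = s + s
        e1 = expected_contacts(s.pair_count, s.total_pairs, s.total_contacts)
        e2 = expected_contacts(doubled.pair_count, doubled.total_pairs,
                               doubled.total_contacts)
        with np.errstate(invalid="ignore"):
            p1 = pair_propensity(s.observed, e1)
            p2 = pair_propensity(doubled.observed, e2)
        mask = np.isfinite(p1)
        assert np.allclose(p1[mask], p2[mask])

    def test_table_sorted_by_pvalue(self, small_fixture_set):
        _, _, tables, _ = small_fixture_set
        res = PropensityModel(tables).fit()
        p = res.pair_table["p_value"].dropna().to_numpy()
        assert (np.diff(p) >= 0).all()
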