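"""Isotope-pattern simulation, MS1 matching, rank aggregation."""

import itertools
import math

import numpy as np
import pytest

from specfp.fingerprints import FingerprintVector
from specfp.isotopes import (
    ISOTOPE_TABLE,
    ElementIsotopes,
    aggregate_ranks,
    element_pattern,
    isotope_match_score,
    molecule_pattern,
    monoisotopic_mass,
    parse_formula,
    pattern_to_spectrum,
    rank_by_isotopes,
)
from specfp.kernels import KernelParams, kernel_value
from specfp.retrieval import CandidateRecord, RankedList
from specfp.spectra import Spectrum


class TestElementPattern:
    def test_carbon_single_atom_abundances(self):
        pat = element_pattern(ISOTOPE_TABLE["C"], 1)
        assert len(pat) == 2
        assert pat.abundances[0] == pytest.approx(0.98890)
        assert pat.abundances[1] == pytest.approx(0.01110)

    def test_carbon_two_atoms_multinomial(self):
        pat = element_pattern(ISOTOPE_TABLE["C"], 2)
        assert len(pat) == 3
        a = [0.98890**2, 2 * 0.98890 * 0.01110, 0.01110**2]
        assert np.allclose(pat.abundances, a, atol=1e-12)

    def test_zero_atoms(self):
        pat = element_pattern(ISOTOPE_TABLE["C"], 0)
        assert pat.entries == [(0.0, 1.0)]

    def test_negative_count_errors(self):
        with pytest.raises(ValueError):
            element_pattern(ISOTOPE_TABLE["C"], -1)

    @pytest.mark.parametrize("symbol", ["P", "C", "O", "K"])  # r = 1, 2, 3, 3
    def test_entry_count_is_multiset_coefficient(self, symbol):
        el = ISOTOPE_TABLE[symbol]
        r = el.r
        for l in range(0, 21):
            pat = element_pattern(el, l)
            assert len(pat) == math.comb(l + r - 1, r - 1)
            assert pat.abundances.sum() == pytest.approx(1.0, abs=1e-9)


def brute_force_pattern(formula, table=ISOTOPE_TABLE):
    """Exhaustive enumeration over all per-atom isotope choices."""
    atoms = []
    for el, count in parse_formula(formula).items():
        atoms.extend([table[el]] * count)
    agg = {}
    for choice in itertools.product(*[range(a.r) for a in atoms]):
        mass = sum(a.isotopes[c][0] for a, c in zip(atoms, choice))
        prob = math.prod(a.isotopes[c][1] for a, c in zip(atoms, choice))
        key = round(mass, 6)
        agg[key] = agg.get(key, 0.0) + prob
    masses = np.array(sorted(agg))
    return masses, np.array([agg[m] for m in masses])


class TestMoleculePattern:
    def test_glucose_total_abundance_and_monoisotopic_mass(self):
        pat = molecule_pattern("C6H12O6", prune_below=0.0, merge_tol=1e-9)
        assert pat.abundances.sum() == pytest.approx(1.0, abs=1e-9)
        assert pat.masses[0] == pytest.approx(180.0634, abs=1e-3)

    def test_single_element_reduction(self):
        pat = molecule_pattern("C2", prune_below=0.0, merge_tol=1e-9)
        ref = element_pattern(ISOTOPE_TABLE["C"], 2)
        assert np.allclose(pat.masses, ref.masses)
        assert np.allclose(pat.abundances, ref.abundances)

    def test_matches_exhaustive_enumeration(self):
        for formula in ["C3N2", "C2H2O", "Cl2S"]:
            pat = molecule_pattern(formula, prune_below=0.0, merge_tol=1e-7)
            masses, abund = brute_force_pattern(formula)
            # align by nearest mass
            assert len(pat) == len(masses)
            assert np.allclose(pat.masses, masses, atol=1e-5)
            assert np.allclose(pat.abundances, abund, atol=1e-10)

    def test_pyteomics_oracle(self):
        """Cross-check convolution against pyteomics' isotopologue engine,
        using pyteomics' own element data so both sides share inputs."""
        pyteomics_mass = pytest.importorskip("pyteomics.mass")
        nist = pyteomics_mass.nist_mass

        def table_from_nist(symbol):
            isos = sorted(
                (m, ab) for num, (m, ab) in nist[symbol].items() if num != 0 and ab > 0
            )
            return ElementIsotopes(symbol, tuple((m, ab / sum(a for _, a in isos))
                                                 for m, ab in isos))

        table = {s: table_from_nist(s) for s in ["C", "H", "O"]}
        formula = "C3H6O2"
        pat = molecule_pattern(formula, isotope_table=table, prune_below=0.0,
                               merge_tol=1e-7)
        agg = {}
        for comp, abundance in pyteomics_mass.isotopologues(
            formula, report_abundance=True, overall_threshold=0.0
        ):
            m = round(pyteomics_mass.calculate_mass(comp), 6)
            agg[m] = agg.get(m, 0.0) + abundance
        ref_masses = np.array(sorted(agg))
        ref_ab = np.array([agg[m] for m in ref_masses])
        ours = {round(m, 5): a for m, a in pat.entries}
        for m, a in zip(ref_masses, ref_ab):
            assert ours.get(round(m, 5), 0.0) == pytest.approx(a, rel=1e-6, abs=1e-12)

    def test_convolution_commutes_across_element_order(self):
        a = molecule_pattern("C4Cl2", prune_below=0.0, merge_tol=1e-9)
        # parse_formula order differs but result must not
        b = molecule_pattern("Cl2C4", prune_below=0.0, merge_tol=1e-9)
        assert np.allclose(a.masses, b.masses)
        assert np.allclose(a.abundances, b.abundances)

    def test_unknown_element_errors(self):
        with pytest.raises(ValueError, match="Xx"):
            molecule_pattern("C2Xx3")

    def test_pruning_renormalizes(self):
        pat = molecule_pattern("C20H30O5", prune_below=1e-3)
        assert pat.abundances.sum() == pytest.approx(1.0, abs=1e-12)
        assert (pat.abundances >= 1e-3 / 2).all()


class TestFormulaParsing:
    @pytest.mark.parametrize(
        "formula,counts",
        [
            ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
            ("CH4", {"C": 1, "H": 4}),
            ("Na2SO4", {"Na": 2, "S": 1, "O": 4}),
            ("ClH", {"Cl": 1, "H": 1}),
        ],
    )
    def test_valid(self, formula, counts):
        assert parse_formula(formula) == counts

    @pytest.mark.parametrize("bad", ["", "6CH", "C6H12o6", "C-2"])
    def test_invalid(self, bad):
        with pytest.raises(ValueError):
            parse_formula(bad)

    def test_monoisotopic_mass_glucose(self):
        assert monoisotopic_mass("C6H12O6") == pytest.approx(180.0634, abs=1e-3)


class TestIsotopeMatching:
    def test_self_match_is_one(self):
        pat = molecule_pattern("C10H14O3")
        observed = pattern_to_spectrum(pat, "positive")
        assert isotope_match_score(observed, pat, "positive") == pytest.approx(1.0)

    def test_far_shifted_pattern_scores_near_zero(self):
        pat = molecule_pattern("C10H14O3")
        observed = pattern_to_spectrum(pat, "positive")
        far = molecule_pattern("C30H44O9")
        assert isotope_match_score(observed, far, "positive") < 1e-6

    def test_delegates_to_kernel(self):
        pat = molecule_pattern("C5H8O2")
        params = KernelParams(sigma_mass=0.02, sigma_intensity=0.1, variants=("peaks",))
        observed = pattern_to_spectrum(molecule_pattern("C5H10O2"), "positive")
        simulated = pattern_to_spectrum(pat, "positive")
        expected = kernel_value(observed, simulated, "peaks", params) / math.sqrt(
            kernel_value(observed, observed, "peaks", params)
            * kernel_value(simulated, simulated, "peaks", params)
        )
        assert isotope_match_score(observed, pat, "positive", params) == pytest.approx(expected)

    def test_true_formula_beats_carbon_decoys(self):
        true_formula = "C12H16O4"
        observed = pattern_to_spectrum(molecule_pattern(true_formula), "positive")
        scores = {
            f: isotope_match_score(observed, molecule_pattern(f), "positive")
            for f in [true_formula, "C11H16O4", "C13H16O4", "C14H16O4"]
        }
        assert max(scores, key=scores.get) == true_formula

    def test_adduct_shift(self):
        pat = molecule_pattern("C2H4O2")
        pos = pattern_to_spectrum(pat, "positive")
        neg = pattern_to_spectrum(pat, "negative")
        assert pos.mz[0] - pat.masses[0] == pytest.approx(1.007276466)
        assert pat.masses[0] - neg.mz[0] == pytest.approx(1.007276466)

    def test_empty_observed_errors(self):
        with pytest.raises(ValueError):
            isotope_match_score(Spectrum(peaks=[], ms_level="MS1"),
                                molecule_pattern("CH4"))


def ranked(entries, query_id="q"):
    return RankedList(entries=entries, query_id=query_id)


def make_rec(mid, formula="C2H4O2"):
    return CandidateRecord(
        molecule_id=mid, exact_mass=100.0, formula=formula,
        fingerprint=FingerprintVector(np.array([1, -1], dtype=np.int8),
                                      key_names=("bit:0", "bit:1")),
    )


class TestAggregation:
    def setup_method(self):
        self.recs = {m: make_rec(m) for m in "abcd"}

    def lists(self, fp_order, iso_order, fp_scores=None, iso_scores=None):
        fp_scores = fp_scores or {m: -i for i, m in enumerate(fp_order)}
        iso_scores = iso_scores or {m: -i for i, m in enumerate(iso_order)}
        fp = ranked([(self.recs[m], fp_scores[m], i + 1) for i, m in enumerate(fp_order)])
        iso = ranked([(self.recs[m], iso_scores[m], i + 1) for i, m in enumerate(iso_order)])
        return fp, iso

    @pytest.mark.parametrize("method", ["average", "minrank", "rerank"])
    def test_identical_orderings_unchanged(self, method):
        fp, iso = self.lists("abcd", "abcd")
        out = aggregate_ranks(fp, iso, method)
        assert out.ids() == list("abcd")
        assert [r for _, _, r in out.entries] == [1, 2, 3, 4]

    def test_average_tie_broken_by_id(self):
        # candidate ranked (2, 4) vs one ranked (3, 3): both average 3
        fp, iso = self.lists("dacb", "adbc")
        # ranks: fp: d1 a2 c3 b4 ; iso: a1 d2 b3 c4
        # averages: a=1.5, d=1.5, b=3.5, c=3.5 -> ties broken by id
        out = aggregate_ranks(fp, iso, "average")
        assert out.ids() == ["a", "d", "b", "c"]

    def test_minrank(self):
        fp, iso = self.lists("abcd", "dcba")
        out = aggregate_ranks(fp, iso, "minrank")
        # min ranks: a=1, b=2, c=2, d=1 -> a, d (tie by id), then b, c
        assert out.ids() == ["a", "d", "b", "c"]

    def test_rerank_with_all_iso_ties_equals_fp_order(self):
        fp, iso = self.lists("cabd", "abcd",
                             iso_scores={m: -1.0 for m in "abcd"})
        out = aggregate_ranks(fp, iso, "rerank")
        assert out.ids() == list("cabd")

    def test_candidate_set_mismatch_errors(self):
        fp, _ = self.lists("abcd", "abcd")
        other = ranked([(make_rec("zz"), 0.0, 1)])
        with pytest.raises(ValueError):
            aggregate_ranks(fp, other, "average")

    def test_rank_by_isotopes_shares_scores_within_formula(self):
        recs = [make_rec("a", "C2H4O2"), make_rec("b", "C2H4O2"), make_rec("c", "C3H6O2")]
        observed = pattern_to_spectrum(molecule_pattern("C2H4O2"), "positive")
        out = rank_by_isotopes(recs, observed, "positive")
        scores = {rec.molecule_id: s for rec, s, _ in out.entries}
        assert scores["a"] == scores["b"]
        assert scores["a"] > scores["c"]
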