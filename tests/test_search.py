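"""Fragment index, Morpheus scoring, mass-gap assignment and
target-decoy FDR, checked against hand computations and brute-force
oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stageglyco import chem, preprocess, proteo, search
from stageglyco.chem import GlycanComposition
from stageglyco.proteo import PeptideForm, ProteinRecord
from stageglyco.search import PSM, SearchConfig
from conftest import make_spectrum


def preprocessed(spec, **kw):
    return preprocess.preprocess_spectrum(spec, floor_fraction=0.0, **kw)


class TestFragmentIndex:
    def test_dipeptide_has_two_backbone_entries(self):
        idx = search.build_index([PeptideForm("GG")], max_charge=1)
        assert idx.mz.size == 2

    def test_query_at_exact_mz_returns_entry(self):
        form = PeptideForm("PEPTIDEK")
        idx = search.build_index([form], max_charge=1)
        hits = idx.query(float(idx.mz[3]), tol_ppm=0.01)
        assert 0 in hits

    def test_empty_form_list_rejected(self):
        with pytest.raises(ValueError):
            search.build_index([])

    def test_query_outside_tolerance_empty(self):
        idx = search.build_index([PeptideForm("GG")], max_charge=1)
        assert idx.query(float(idx.mz[0]) * 1.001, tol_ppm=1.0).size == 0


class TestMatchSpectrum:
    def _self_spectrum(self, form, n_noise=0):
        mz, _ = proteo.fragment_mz_arrays(form, max_charge=1)
        ints = np.full(mz.size, 100.0)
        if n_noise:
            rng = np.random.default_rng(0)
            mz = np.concatenate([mz, rng.uniform(2000, 3000, n_noise)])
            ints = np.concatenate([ints, np.full(n_noise, 10.0)])
        return make_spectrum(np.sort(mz), ints[np.argsort(mz)],
                             precursor_mz=form.mz(2), charge=2)

    def test_pure_noise_gives_no_candidates(self):
        idx = search.build_index([PeptideForm("ELVISLIVESK")], max_charge=1)
        rng = np.random.default_rng(1)
        s = make_spectrum(np.sort(rng.uniform(100, 900, 50)), np.ones(50))
        assert search.match_spectrum(preprocessed(s), idx) == []

    def test_self_spectrum_qualifies(self):
        form = PeptideForm("ELVISLIVESK")
        idx = search.build_index([form], max_charge=1)
        spec = self._self_spectrum(form)
        assert search.match_spectrum(preprocessed(spec), idx) == [0]

    def test_five_matches_excluded_six_included(self):
        form = PeptideForm("ELVISLIVESK")
        idx = search.build_index([form], max_charge=1)
        mz, _ = proteo.fragment_mz_arrays(form, max_charge=1)
        for n, expected in [(5, []), (6, [0])]:
            sub = np.sort(mz)[:n]
            s = make_spectrum(sub, np.full(n, 100.0))
            assert search.match_spectrum(preprocessed(s), idx) == expected


class TestMorpheusScore:
    def test_zero_matched_peaks_scores_zero(self):
        form = PeptideForm("GGG")
        s = make_spectrum([2000.0], [10.0])
        score, n, frac = search._score_form(preprocessed(s), form, 1, 20.0, False)
        assert (score, n, frac) == (0.0, 0, 0.0)

    def test_three_of_four_peaks_with_ninety_percent_intensity(self):
        # peptide GGG has 4 backbone ions (b1,b2,y1,y2); place peaks on 3 of
        # them carrying 90% of sqrt intensity plus one unmatched peak
        form = PeptideForm("GGG")
        frags = proteo.theoretical_fragments(form, 1, include_oxonium=False)
        by = {(f.series, f.index): f.mz for f in frags}
        mzs = [by[("b", 1)], by[("b", 2)], by[("y", 1)], 1500.0]
        ints = [9.0, 9.0, 9.0, 1.0]  # sqrt -> 3,3,3,1: matched share 9/10
        s = make_spectrum(mzs, ints)
        score, n, frac = search._score_form(preprocessed(s), form, 1, 20.0, False)
        assert n == 3
        assert frac == pytest.approx(0.9)
        assert score == pytest.approx(3.9)

    def test_all_peaks_matched_gives_count_plus_one(self):
        form = PeptideForm("GGG")
        frags = proteo.theoretical_fragments(form, 1, include_oxonium=False)
        mzs = sorted({round(f.mz, 6) for f in frags})
        s = make_spectrum(mzs, np.full(len(mzs), 4.0))
        score, n, frac = search._score_form(preprocessed(s), form, 1, 20.0, False)
        assert frac == pytest.approx(1.0)
        assert score == pytest.approx(n + 1)

    def test_isotope_companion_counts_as_match(self):
        form = PeptideForm("GGG")
        frags = proteo.theoretical_fragments(form, 1, include_oxonium=False)
        y1 = next(f.mz for f in frags if (f.series, f.index) == ("y", 1))
        s = make_spectrum([y1 + search.ISOTOPE_SPACING], [10.0])
        _, n_without, _ = search._score_form(preprocessed(s), form, 1, 20.0, False)
        _, n_with, _ = search._score_form(preprocessed(s), form, 1, 20.0, True)
        assert n_without == 0
        assert n_with == 1

    def test_deterministic_tie_break_prefers_smaller_sequence(self):
        # two isobaric forms (I/L swap) match identically; smaller sequence wins
        forms = [PeptideForm("GLG"), PeptideForm("GIG")]
        frags = proteo.theoretical_fragments(forms[0], 1, include_oxonium=False)
        mzs = sorted({round(f.mz, 6) for f in frags})
        s = make_spectrum(mzs, np.full(len(mzs), 4.0))
        psm = search.score_candidates(preprocessed(s), forms, 1, 20.0, False)
        assert psm.form.sequence == "GIG"


class TestMassGap:
    def _psm(self, form, precursor_mz, charge=2):
        return PSM("s1", form, 10.0, 10, 0.5, precursor_mz, charge)

    def test_zero_gap_is_valid_without_glycan(self):
        form = PeptideForm("PEPTIDEK")
        psm = search.assign_mass_gap(self._psm(form, form.mz(2)), [])
        assert psm.valid and psm.glycan is None

    def test_gap_matching_composition_assigned(self):
        form = PeptideForm("DSYPDGNITWYR")
        comp = GlycanComposition.from_string("N4H5F1S1")
        mz = chem.peptide_mz(form.mass + comp.mass, 2)
        psm = search.assign_mass_gap(self._psm(form, mz), [comp])
        assert psm.valid
        assert psm.glycan == comp

    def test_unmatched_gap_flagged_invalid(self):
        form = PeptideForm("PEPTIDEK")
        mz = chem.peptide_mz(form.mass + 100.0, 2)
        psm = search.assign_mass_gap(self._psm(form, mz), search.default_glycan_database())
        assert not psm.valid

    def test_negative_gap_beyond_tolerance_invalid(self):
        form = PeptideForm("PEPTIDEK")
        mz = chem.peptide_mz(form.mass - 50.0, 2)
        psm = search.assign_mass_gap(self._psm(form, mz), [])
        assert not psm.valid


class TestPrecursorIsotopeFit:
    def test_model_envelope_scores_one(self):
        import math

        mass = 1500.0
        lam = 4.7547e-4 * mass
        model = [math.exp(-lam) * lam**k / math.factorial(k) for k in range(4)]
        assert search.precursor_isotope_fit(model, mass) == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_envelope_scores_zero(self):
        assert search.precursor_isotope_fit([0.0, 0.0, 0.0], 1500.0) == 0.0

    def test_empty_envelope_scores_zero(self):
        assert search.precursor_isotope_fit([], 1500.0) == 0.0


class TestCoverageFilter:
    @pytest.mark.parametrize("fraction,kept", [(0.5, True), (0.05, False), (0.10, False)])
    def test_strict_ten_percent_rule(self, fraction, kept):
        psm = PSM("s", PeptideForm("GG"), 1.0, 1, fraction, 500.0, 2)
        assert search.coverage_filter(psm) is kept


def brute_force_q_values(scores, decoys):
    """Oracle: q(s) = min over thresholds s' <= s of FDP(s')."""
    qs = []
    for s in scores:
        fdps = []
        for t in scores:
            if t <= s:
                d = sum(1 for sc, dec in zip(scores, decoys) if sc >= t and dec)
                n = sum(1 for sc, dec in zip(scores, decoys) if sc >= t and not dec)
                fdps.append(d / n if n else np.inf)
        qs.append(min(fdps))
    return qs


class TestFDR:
    def _psms(self, scores, decoys):
        out = []
        for i, (s, d) in enumerate(zip(scores, decoys)):
            acc = f"DECOY_P{i}" if d else f"P{i}"
            form = PeptideForm("PEPTIDEK", protein_refs=((acc, 1),))
            out.append(PSM(f"s{i}", form, float(s), 5, 0.5, 500.0, 2))
        return out

    def test_targets_above_single_decoy_get_q_zero(self):
        psms = self._psms([10, 9, 8, 1], [False, False, False, True])
        kept = search.fdr_filter(psms, level=0.01)
        assert [p.score for p in kept] == [10, 9, 8]
        assert all(p.q_value == 0.0 for p in kept)

    def test_equal_target_decoy_lists_give_q_one(self):
        psms = self._psms([5, 5, 3, 3], [False, True, False, True])
        search.fdr_filter(psms, level=1.1)
        assert all(p.q_value == 1.0 for p in psms)

    def test_no_decoys_rejected_unless_db_searched(self):
        psms = self._psms([5, 4], [False, False])
        with pytest.raises(ValueError):
            search.fdr_filter(psms)
        kept = search.fdr_filter(psms, decoys_searched=True)
        assert len(kept) == 2

    @given(
        scores=st.lists(st.integers(0, 30), min_size=2, max_size=25),
        seed=st.integers(0, 1000),
    )
    @settings(derandomize=True, max_examples=60)
    def test_q_values_match_brute_force_oracle(self, scores, seed):
        rng = np.random.default_rng(seed)
        decoys = [bool(b) for b in rng.integers(0, 2, len(scores))]
        if not any(decoys):
            decoys[0] = True
        psms = self._psms(scores, decoys)
        search.fdr_filter(psms, level=1.1)
        expected = brute_force_q_values(scores, decoys)
        got = [p.q_value for p in psms]
        assert got == pytest.approx(expected)

    def test_q_monotone_in_score(self):
        rng = np.random.default_rng(7)
        scores = rng.integers(0, 20, 30).tolist()
        decoys = [bool(b) for b in rng.integers(0, 2, 30)]
        decoys[0] = True
        psms = self._psms(scores, decoys)
        search.fdr_filter(psms, level=1.1)
        ranked = sorted(psms, key=lambda p: -p.score)
        qs = [p.q_value for p in ranked]
        assert all(a <= b for a, b in zip(qs, qs[1:]))


class TestSearchDeterminism:
    def test_result_invariant_to_spectrum_order(self, small_dataset):
        ds = small_dataset
        spectra = ds.spectra[:40]
        cfg = SearchConfig()
        fwd = search.search_dataset(ds.proteins, spectra, cfg)
        rev = search.search_dataset(ds.proteins, list(reversed(spectra)), cfg)
        key = lambda psms: [(p.spectrum_id, p.form.form_id(), round(p.score, 9)) for p in psms]
        assert key(fwd) == key(rev)

    def test_index_matching_equals_exhaustive_all_pairs(self, small_dataset):
        # oracle: for a small candidate set, index lookup == brute force
        ds = small_dataset
        forms = []
        prot_map = {p.accession: p for p in ds.proteins}
        mods = chem.default_modifications()
        for pep in proteo.digest_proteins(ds.proteins[:2], length_range=(6, 30))[:20]:
            forms.extend(proteo.enumerate_modforms(pep, prot_map, [mods["carbamidomethyl"]], []))
        idx = search.build_index(forms, max_charge=1)
        spec = ds.spectra[0]
        pre = preprocess.preprocess_spectrum(spec)
        got = search.match_spectrum(pre, idx, tol_ppm=20.0, min_matches=1)
        # brute force over every (peak, form-fragment) pair
        expected = set()
        for fi, form in enumerate(forms):
            mz, _ = proteo.fragment_mz_arrays(form, 1)
            count = 0
            for peak in pre.mz[pre.top_k]:
                if np.any(np.abs(mz - peak) <= peak * 20e-6):
                    count += 1
            if count >= 1:
                expected.add(fi)
        assert set(got) == expected
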