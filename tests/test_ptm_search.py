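"""Peptidoform enumeration, MS1 matching, set selection and classification."""

import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from hptmkit.digestion import digest
from hptmkit.ptm import (
    AnnotationRecord,
    CandidateMatch,
    classify_annotations,
    enumerate_peptidoforms,
    match_features,
    select_ptm_sets,
)
from hptmkit.sequences import HistoneVariant


class TestEnumeration:
    def test_no_valid_target_yields_only_unmodified(self, registry):
        v = HistoneVariant("X", "H3", "AAR")
        (pep,) = digest(v, 0)
        forms = enumerate_peptidoforms(pep, {"ac": registry["ac"]}, 2)
        assert len(forms) == 1 and not forms[0].located_mods

    def test_k27_k36_k37_me3_placements(self, peptide_27_40, registry):
        forms = enumerate_peptidoforms(peptide_27_40, {"me3": registry["me3"]}, 1)
        placed = sorted(
            pos for f in forms for pos, _ in f.located_mods
        )
        assert len(forms) == 4  # unmodified + me3 at each of K27/K36/K37
        assert placed == [27, 36, 37]

    def test_count_matches_exhaustive_placement_oracle(self, h3_variants, registry):
        pep = next(p for p in digest(h3_variants["H31"], 0) if p.span == (9, 17))
        mods = [registry[n] for n in ("me", "me2", "me3", "ac")]
        forms = enumerate_peptidoforms(pep, mods, 2)
        # oracle: exhaustive placement over each site's valid mods
        # (KSTGGKAPR offers K9, K14 with 4 mods each and R17 with me/me2)
        options = {
            pos: [m for m in mods if pep.residue(pos) in m.targets]
            for pos in range(pep.start, pep.end + 1)
        }
        options = {pos: opts for pos, opts in options.items() if opts}
        oracle = 1  # unmodified
        for r in (1, 2):
            for combo in itertools.combinations(sorted(options), r):
                count = 1
                for pos in combo:
                    count *= len(options[pos])
                oracle += count
        assert sorted(options) == [9, 14, 17]
        assert len(forms) == oracle == 1 + (4 + 4 + 2) + (16 + 8 + 8)

    def test_order_is_deterministic(self, peptide_27_40, registry):
        a = enumerate_peptidoforms(peptide_27_40, registry, 2)
        b = enumerate_peptidoforms(peptide_27_40, registry, 2)
        assert [f.describe() for f in a] == [f.describe() for f in b]


class TestMatching:
    def _single_form(self, registry, peptide):
        return enumerate_peptidoforms(peptide, {}, 0)

    def test_ppm_window_boundaries(self, peptide_27_40):
        forms = enumerate_peptidoforms(peptide_27_40, {}, 0)
        theo = forms[0].mono_mass
        inside = theo * (1 - 9.9e-6)
        outside = theo * (1 - 10.1e-6)
        assert len(match_features([("in", inside)], forms, 10.0)) == 1
        m = match_features([("in", inside)], forms, 10.0)[0]
        assert m.ppm_error == pytest.approx(-9.9, abs=1e-6)
        assert match_features([("out", outside)], forms, 10.0) == []

    def test_random_matching_equals_quadratic_scan(self, h3_variants, registry):
        rng = random.Random(7)
        forms = []
        for pep in digest(h3_variants["H31"], 1, 4, 30):
            forms.extend(enumerate_peptidoforms(pep, registry, 1))
        features = [
            (f"F{i}", rng.choice(forms).mono_mass * (1 + rng.uniform(-2e-5, 2e-5)))
            for i in range(150)
        ]
        got = {
            (m.feature_id, m.peptidoform.describe())
            for m in match_features(features, forms, 10.0)
        }
        oracle = {
            (fid, pf.describe())
            for fid, obs in features
            for pf in forms
            if abs(1e6 * (obs - pf.mono_mass) / pf.mono_mass) <= 10.0
        }
        assert got == oracle

    def test_matches_at_tol_subset_of_wider_tol(self, h3_variants, registry):
        rng = random.Random(11)
        forms = []
        for pep in digest(h3_variants["H31"], 0, 4, 30):
            forms.extend(enumerate_peptidoforms(pep, registry, 1))
        features = [
            (f"F{i}", rng.choice(forms).mono_mass * (1 + rng.uniform(-3e-5, 3e-5)))
            for i in range(100)
        ]
        narrow = {
            (m.feature_id, m.peptidoform.describe())
            for m in match_features(features, forms, 5.0)
        }
        wide = {
            (m.feature_id, m.peptidoform.describe())
            for m in match_features(features, forms, 15.0)
        }
        assert narrow <= wide


def _candidates(combos):
    return [
        CandidateMatch(
            feature_id=f"F{i}", peptidoform=None, ppm_error=0.0, ptm_combination=c
        )
        for i, c in enumerate(combos)
    ]


def brute_force_round1(combos, set_size):
    """Oracle: exhaustive maximum coverage over all name subsets of size <= k."""
    names = sorted(set(itertools.chain.from_iterable(combos)))
    best = 0
    for r in range(0, min(set_size, len(names)) + 1):
        for chosen in itertools.combinations(names, r):
            cset = set(chosen)
            best = max(best, sum(1 for c in combos if set(c) <= cset))
    return best


class TestSetSelection:
    def test_single_dominating_set(self):
        combos = [("ac",)] * 5 + [("me3",)] * 3 + [("ac", "me3")]
        sel = select_ptm_sets(_candidates(combos), set_size=2, n_rounds=1)
        assert sel.rounds == (frozenset({"ac", "me3"}),)
        assert sel.comprehensiveness == pytest.approx(1.0)

    def test_forced_greedy_order_with_singletons(self):
        combos = [("ac",)] * 5 + [("me3",)] * 3 + [("ac", "me3")]
        sel = select_ptm_sets(_candidates(combos), set_size=1, n_rounds=2)
        assert sel.rounds == (frozenset({"ac"}), frozenset({"me3"}))
        assert sel.covered_per_round == (5, 3)
        assert sel.comprehensiveness == pytest.approx(8 / 9)

    def test_empty_candidates_vacuously_comprehensive(self, caplog):
        with caplog.at_level("WARNING"):
            sel = select_ptm_sets([], set_size=2, n_rounds=3)
        assert sel.comprehensiveness == 1.0
        assert any("empty" in r.message for r in caplog.records)

    @pytest.mark.parametrize("seed", range(30))
    def test_round1_greedy_equals_exhaustive_optimum(self, seed):
        rng = random.Random(seed)
        names = ["ac", "me", "me2", "me3", "cr", "hib", "ph", "su"][: rng.randint(2, 8)]
        combos = [
            tuple(sorted(rng.sample(names, rng.randint(0, min(3, len(names))))))
            for _ in range(rng.randint(1, 40))
        ]
        set_size = rng.randint(1, 3)
        sel = select_ptm_sets(_candidates(combos), set_size=set_size, n_rounds=1)
        covered = sel.covered_per_round[0] if sel.covered_per_round else 0
        assert covered == brute_force_round1(combos, set_size)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        data=st.lists(
            st.lists(
                st.sampled_from(["ac", "me", "me2", "me3", "cr"]),
                min_size=0,
                max_size=3,
                unique=True,
            ),
            min_size=1,
            max_size=25,
        ),
        set_size=st.integers(min_value=1, max_value=3),
        rounds=st.integers(min_value=1, max_value=3),
    )
    def test_comprehensiveness_monotone_in_rounds_and_set_size(
        self, data, set_size, rounds
    ):
        combos = [tuple(sorted(c)) for c in data]
        cands = _candidates(combos)
        a = select_ptm_sets(cands, set_size, rounds)
        b = select_ptm_sets(cands, set_size, rounds + 1)
        c = select_ptm_sets(cands, set_size + 1, rounds)
        assert b.comprehensiveness >= a.comprehensiveness - 1e-12
        assert c.comprehensiveness >= a.comprehensiveness - 1e-12
        # per-selection, comprehensiveness is non-decreasing over rounds
        by_round = a.comprehensiveness_by_round
        assert all(x <= y + 1e-12 for x, y in zip(by_round, by_round[1:]))


class TestAnnotationClassification:
    def _rec(self, candidate, support, curated=True, above=True):
        return AnnotationRecord(
            feature_id="F1",
            candidate=candidate,
            n_msms_support=support,
            curated=curated,
            biologically_modified=True,
            score_above_threshold=above,
        )

    def test_single_curated_with_multi_spectrum_support_is_reproducible(self):
        assert classify_annotations([self._rec("K27me3", 3)]) == "curated_reproducible"

    def test_no_records_is_unannotated(self):
        assert classify_annotations([]) == "unannotated"

    def test_two_curated_above_threshold_is_ambiguous(self):
        recs = [self._rec("K27me3", 2), self._rec("K27ac+me", 2)]
        assert classify_annotations(recs) == "ambiguous"

    def test_single_support_and_non_curated_classes(self):
        assert classify_annotations([self._rec("K27me3", 1)]) == "curated_single_support"
        assert (
            classify_annotations([self._rec("K27me3", 3, curated=False)])
            == "non_curated"
        )
        assert (
            classify_annotations([self._rec("K27me3", 3, above=False)]) == "non_curated"
        )
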