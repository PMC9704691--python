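import numpy as np
import pytest

from gelamatch.data_model import AnalysisConfig, FstMatrix, PopulationPanel
from gelamatch.heuristics import (
    AlignmentProfile,
    _bootstrap_delta_ci,
    alignment_profile,
    alignment_profiles,
    classify_all_enclaves,
    classify_enclave,
    enclave_eligibility,
    misalignment_summary,
)
from gelamatch.popgen import flag_drifted
from conftest import make_record

DEG = 111.195  # km per degree of longitude at the equator


def km(x):
    return x / DEG


def enclave_fixture():
    """One panel holding the three canonical enclave configurations.

    * himba: nearest genetic relative is same-family, 1500 km away (colony
      that kept genes and language) -> matching enclave.
    * hungar: closest genetic relative other-family at ~30 km; same-family
      relatives 2000 km away and genetically far -> linguistic enclave.
    * jewgeo: closest genetic relative other-family at 1800 km; own family
      local but genetically distant -> genetic enclave.
    """
    recs = [
        # himba and its remote family
        make_record("himba", 0, 0, "famH"),
        make_record("h_far1", 0, km(1500), "famH"),
        make_record("h_far2", 0, km(1560), "famH"),
        # local neighbours in another family
        make_record("n1", 0, km(60), "famN"),
        make_record("n2", 0, km(120), "famN"),
        # hungarian-like: local genetics, remote family
        make_record("hungar", 2, 0, "famU"),
        make_record("u_near", 2, km(30), "famN2"),
        make_record("u_far1", 2, km(2000), "famU"),
        make_record("u_far2", 2, km(2060), "famU"),
        # jewish-georgian-like: local family, remote genetics
        make_record("jewgeo", 4, 0, "famK"),
        make_record("k2", 4, km(30), "famK"),
        make_record("k3", 4, km(60), "famK"),
        make_record("g_kin", 4, km(1800), "famG"),
    ]
    panel = PopulationPanel(recs)
    ids = panel.pop_ids
    n = len(ids)
    v = np.full((n, n), 0.08)
    np.fill_diagonal(v, 0.0)
    m = FstMatrix(ids, v)

    def set_(a, b, val):
        i, j = m.pop_ids.index(a), m.pop_ids.index(b)
        m.values[i, j] = m.values[j, i] = val

    set_("himba", "h_far1", 0.01)
    set_("himba", "h_far2", 0.015)
    set_("himba", "n1", 0.05)
    set_("himba", "n2", 0.055)
    set_("hungar", "u_near", 0.008)
    set_("hungar", "u_far1", 0.06)
    set_("hungar", "u_far2", 0.065)
    set_("jewgeo", "g_kin", 0.009)
    set_("jewgeo", "k2", 0.04)
    set_("jewgeo", "k3", 0.045)
    return panel, m


class TestEnclaveClassification:
    @pytest.mark.parametrize("pop,expected", [
        ("himba", "matching_enclave"),
        ("hungar", "linguistic_enclave"),
        ("jewgeo", "genetic_enclave"),
    ])
    def test_canonical_configurations(self, pop, expected):
        panel, fst = enclave_fixture()
        report = classify_enclave(pop, panel, fst, AnalysisConfig())
        assert report.classification == expected

    def test_family_of_two_is_ineligible(self):
        panel, fst = enclave_fixture()
        ok, reason = enclave_eligibility("n1", panel, fst, AnalysisConfig())
        assert not ok and "<= 2" in reason

    def test_locally_related_in_both_dimensions_ineligible(self):
        panel, fst = enclave_fixture()
        # k2 has a same-family neighbour at 30 km and its closest-FST
        # population is also local
        ok, reason = enclave_eligibility("k2", panel, fst, AnalysisConfig())
        assert not ok

    def test_outcomes_mutually_exclusive_and_exhaustive(self, scenario):
        _, panel, _, fst = scenario
        cfg = AnalysisConfig(rng_seed=11)
        for r in classify_all_enclaves(panel, fst, cfg):
            if r.eligible:
                assert r.classification in (
                    "matching_enclave", "genetic_enclave",
                    "linguistic_enclave", "local_match")
            else:
                assert r.classification == "ineligible"

    def test_planted_remote_colony_is_matching_enclave(self, scenario):
        _, panel, truth, fst = scenario
        cfg = AnalysisConfig(rng_seed=11)
        reports = {r.pop_id: r for r in classify_all_enclaves(panel, fst, cfg)}
        colonies = [p for p, e in truth.event_label.items() if e == "remote_colony"]
        for pid in colonies:
            assert reports[pid].classification == "matching_enclave"


def alignment_fixture():
    """Two families of four, all within 300 km, with a1's distributions set
    by hand: within {0.01, 0.02, 0.03}, between {0.02, 0.03, 0.04}."""
    recs = [make_record(f"a{i}", 0, km(40 * i), "famA") for i in range(1, 5)]
    recs += [make_record(f"b{i}", km(100), km(40 * i), "famB") for i in range(1, 5)]
    panel = PopulationPanel(recs)
    ids = panel.pop_ids
    v = np.full((8, 8), 0.05)
    np.fill_diagonal(v, 0.0)
    m = FstMatrix(ids, v)

    def set_(a, b, val):
        i, j = ids.index(a), ids.index(b)
        m.values[i, j] = m.values[j, i] = val

    for i, val in zip((2, 3, 4), (0.01, 0.02, 0.03)):
        set_("a1", f"a{i}", val)
    for i, val in zip((1, 2, 3), (0.02, 0.03, 0.04)):
        set_("a1", f"b{i}", val)
    set_("a1", "b4", 0.05)
    return panel, m


class TestAlignmentProfile:
    def test_aligned_when_between_median_larger(self):
        panel, fst = alignment_fixture()
        prof = alignment_profile("a1", panel, fst, AnalysisConfig(rng_seed=1))
        assert prof.assessable
        assert prof.median_within == pytest.approx(0.02)
        # between set: {0.02, 0.03, 0.04, 0.05} within the 500 km span floor
        assert prof.median_between == pytest.approx(0.035)
        assert prof.delta == pytest.approx(0.015)
        assert prof.misaligned is False
        assert prof.ci_low <= prof.delta <= prof.ci_high

    def test_misaligned_when_within_median_larger(self):
        panel, fst = alignment_fixture()
        ids = fst.pop_ids
        # invert a1's two distributions
        for i, val in zip((2, 3, 4), (0.04, 0.05, 0.06)):
            a, b = ids.index("a1"), ids.index(f"a{i}")
            fst.values[a, b] = fst.values[b, a] = val
        for i, val in zip((1, 2, 3, 4), (0.01, 0.02, 0.03, 0.03)):
            a, b = ids.index("a1"), ids.index(f"b{i}")
            fst.values[a, b] = fst.values[b, a] = val
        prof = alignment_profile("a1", panel, fst, AnalysisConfig(rng_seed=1))
        assert prof.misaligned is True

    def test_equal_medians_count_as_aligned(self):
        panel, fst = alignment_fixture()
        ids = fst.pop_ids
        for i, val in zip((1, 2, 3, 4), (0.01, 0.02, 0.03, 0.05)):
            a, b = ids.index("a1"), ids.index(f"b{i}")
            fst.values[a, b] = fst.values[b, a] = val
        # within median 0.02, between median (0.01,0.02,0.03,0.05) -> 0.025
        prof = alignment_profile("a1", panel, fst, AnalysisConfig(rng_seed=1))
        assert prof.misaligned is (prof.median_within > prof.median_between)

    def test_undersized_sets_not_assessable(self, tiny_panel, tiny_fst):
        # famA has only 2 other members: below min_distribution_size=3
        prof = alignment_profile("a1", tiny_panel, tiny_fst, AnalysisConfig())
        assert not prof.assessable

    def test_bootstrap_is_reproducible(self):
        panel, fst = alignment_fixture()
        cfg = AnalysisConfig(rng_seed=99, bootstrap_reps=500)
        p1 = alignment_profile("a1", panel, fst, cfg)
        p2 = alignment_profile("a1", panel, fst, cfg)
        assert (p1.ci_low, p1.ci_high) == (p2.ci_low, p2.ci_high)

    def test_ci_width_shrinks_with_set_size(self):
        rng = np.random.default_rng(5)
        within = rng.normal(0.02, 0.005, 100).clip(0)
        between = rng.normal(0.05, 0.005, 100).clip(0)
        lo10, hi10 = _bootstrap_delta_ci(within[:10], between[:10], 2000,
                                         np.random.default_rng(1))
        lo100, hi100 = _bootstrap_delta_ci(within, between, 2000,
                                           np.random.default_rng(1))
        assert (hi100 - lo100) < (hi10 - lo10)

    def test_drifted_populations_excluded(self, scenario):
        _, panel, _, fst = scenario
        cfg = AnalysisConfig(rng_seed=11)
        n = len(panel)
        flags = {p: p == panel.pop_ids[0] for p in panel.pop_ids}
        marked = panel.with_drifted(flags)
        profiles = alignment_profiles(marked, fst, cfg)
        assert profiles[0].reason == "drifted"
        assert not profiles[0].assessable


class TestMisalignmentSummary:
    def _profiles(self, flags):
        return [
            AlignmentProfile(f"p{i}", True, misaligned=f, delta=0.0)
            for i, f in enumerate(flags)
        ]

    def test_all_aligned_is_zero(self, tiny_panel):
        panel = PopulationPanel(
            [make_record(f"p{i}", 0, i, "F") for i in range(4)])
        s = misalignment_summary(self._profiles([False] * 4), panel)
        assert s.proportion == 0.0

    def test_two_of_ten(self):
        panel = PopulationPanel(
            [make_record(f"p{i}", 0, i * 0.1, "F") for i in range(10)])
        s = misalignment_summary(
            self._profiles([True, True] + [False] * 8), panel)
        assert s.proportion == pytest.approx(0.2)
        assert s.per_family.loc[0, "n_misaligned"] == 2

    def test_planted_shifts_recovered_as_misaligned(self, scenario):
        _, panel, truth, fst = scenario
        cfg = AnalysisConfig(rng_seed=11)
        marked = flag_drifted(panel, fst, cfg)
        profs = {p.pop_id: p for p in alignment_profiles(marked, fst, cfg)}
        shifted = [p for p, e in truth.event_label.items() if e == "shift"]
        assert shifted
        for pid in shifted:
            assert profs[pid].assessable and profs[pid].misaligned
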