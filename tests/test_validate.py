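"""Cross-tabulation and test-characteristic arithmetic."""

import numpy as np
import pandas as pd
import pytest

from namecohort import (
    CrossTab,
    ListCollection,
    bootstrap_ci,
    build_list,
    compare_lists,
    cross_tabulate,
    datasets,
    stratified_characteristics,
    test_characteristics,
)
from namecohort.validate import METRICS
from conftest import LABELS, brute_force_metrics, random_population


def test_reference_crosstab_marginals(reference_population):
    assignments, gold, survey = reference_population
    tab = cross_tabulate(assignments, gold, survey, labels=LABELS)
    assert tab.n_respondents == 69_859
    col = tab.col_totals()
    assert col[datasets.SOUTH_ASIAN] == 1_400
    assert col[datasets.CHINESE] == 1_129
    assert col[datasets.GENERAL] == 67_330
    # cells round-trip exactly
    pd.testing.assert_frame_equal(
        tab.unweighted, datasets.ontario_reference_crosstab(),
        check_names=False,
    )


def test_single_respondent_crosstab():
    a = pd.DataFrame({"person_id": ["1"], "group": ["Chinese"]})
    g = pd.DataFrame({"person_id": ["1"], "gold": ["South Asian"]})
    s = pd.DataFrame({"person_id": ["1"], "weight": [2.5]})
    tab = cross_tabulate(a, g, s, labels=("South Asian", "Chinese"))
    assert tab.unweighted.loc["Chinese", "South Asian"] == 1
    assert tab.unweighted.to_numpy().sum() == 1
    assert tab.weighted.loc["Chinese", "South Asian"] == 2.5


def test_crosstab_missing_assignment_is_an_error():
    a = pd.DataFrame({"person_id": ["1"], "group": ["Chinese"]})
    g = pd.DataFrame({"person_id": ["1", "2"], "gold": ["Chinese", "Chinese"]})
    s = pd.DataFrame({"person_id": ["1", "2"], "weight": [1.0, 1.0]})
    with pytest.raises(ValueError, match="2"):
        cross_tabulate(a, g, s)


def test_crosstab_equals_brute_force_double_loop():
    rng = np.random.default_rng(21)
    assignments, gold, survey = random_population(rng, n=100)
    tab = cross_tabulate(assignments, gold, survey, labels=LABELS)
    for r in LABELS:
        for c in LABELS:
            expected = sum(
                1
                for g, gl in zip(assignments["group"], gold["gold"])
                if g == r and gl == c
            )
            assert tab.unweighted.loc[r, c] == expected


def test_identity_table_gives_perfect_metrics():
    counts = pd.DataFrame(np.diag([5, 7, 11]), index=LABELS, columns=LABELS)
    tab = CrossTab.from_counts(counts)
    tc = test_characteristics(tab, datasets.CHINESE)
    assert tc.as_dict() == {m: 1.0 for m in METRICS}


def test_reference_unweighted_metrics(reference_population):
    # PPV = 654/787, sensitivity = 654/1400 on the published counts
    assignments, gold, survey = reference_population
    tab = cross_tabulate(assignments, gold, survey, labels=LABELS)
    tc = test_characteristics(tab, datasets.SOUTH_ASIAN, weighted=False)
    assert tc.ppv == pytest.approx(654 / 787, abs=1e-12)
    assert tc.sensitivity == pytest.approx(654 / 1400, abs=1e-12)
    assert tc.as_percentages()["ppv"] == 83.1
    assert tc.as_percentages()["sensitivity"] == 46.7


def test_two_by_two_hand_arithmetic():
    counts = pd.DataFrame(
        [[8, 1], [2, 89]], index=["T", "Other"], columns=["T", "Other"]
    )
    tc = test_characteristics(CrossTab.from_counts(counts), "T")
    assert tc.sensitivity == pytest.approx(0.8)
    assert tc.specificity == pytest.approx(89 / 90)
    assert tc.ppv == pytest.approx(8 / 9)
    assert tc.npv == pytest.approx(89 / 91)


def test_metrics_match_brute_force_loop():
    rng = np.random.default_rng(42)
    for _ in range(20):
        assignments, gold, survey = random_population(rng, n=200)
        tab = cross_tabulate(assignments, gold, survey, labels=LABELS)
        rows = list(zip(assignments["group"], gold["gold"], survey["weight"]))
        for target in LABELS:
            for weighted in (False, True):
                tc = test_characteristics(tab, target, weighted=weighted)
                expected = brute_force_metrics(rows, target, weighted)
                for m in METRICS:
                    assert getattr(tc, m) == pytest.approx(
                        expected[m], abs=1e-12
                    ), (target, m, weighted)


def test_zero_denominators_are_undefined_not_zero():
    counts = pd.DataFrame([[0, 0], [0, 10]], index=["T", "O"], columns=["T", "O"])
    tc = test_characteristics(CrossTab.from_counts(counts), "T")
    assert tc.sensitivity is None  # no gold positives
    assert tc.ppv is None          # no predicted positives
    assert tc.specificity == 1.0 and tc.npv == 1.0
    assert tc.as_percentages()["ppv"] is None


def test_two_group_complementarity():
    rng = np.random.default_rng(9)
    labels = ("T", "O")
    n = 150
    a = pd.DataFrame({"person_id": [str(i) for i in range(n)],
                      "group": rng.choice(labels, size=n)})
    g = pd.DataFrame({"person_id": a["person_id"],
                      "gold": rng.choice(labels, size=n)})
    s = pd.DataFrame({"person_id": a["person_id"],
                      "weight": rng.lognormal(0, 1, size=n)})
    tab = cross_tabulate(a, g, s, labels=labels)
    for weighted in (False, True):
        t = test_characteristics(tab, "T", weighted=weighted)
        o = test_characteristics(tab, "O", weighted=weighted)
        assert t.sensitivity == pytest.approx(o.specificity, abs=1e-12)
        assert t.specificity == pytest.approx(o.sensitivity, abs=1e-12)


def test_weight_scale_invariance():
    rng = np.random.default_rng(4)
    assignments, gold, survey = random_population(rng, n=180)
    tab = cross_tabulate(assignments, gold, survey, labels=LABELS)
    scaled = survey.assign(weight=survey["weight"] * 37.5)
    tab2 = cross_tabulate(assignments, gold, scaled, labels=LABELS)
    for target in LABELS:
        a = test_characteristics(tab, target, weighted=True)
        b = test_characteristics(tab2, target, weighted=True)
        for m in METRICS:
            assert getattr(a, m) == pytest.approx(getattr(b, m), abs=1e-12)


def _strat_population():
    rng = np.random.default_rng(17)
    a, g, s = random_population(rng, n=160)
    s = s.assign(
        sex=rng.choice(["Male", "Female"], size=len(s)),
        age_band="45 to 64",
        immigration=rng.choice(["Born in Canada", "Immigrant <=10 years"], size=len(s)),
    )
    return a, g, s


def test_single_stratum_equals_overall():
    a, g, s = _strat_population()
    overall = test_characteristics(
        cross_tabulate(a, g, s, labels=LABELS), datasets.SOUTH_ASIAN, weighted=True
    )
    strata = stratified_characteristics(a, g, s, "age_band", datasets.SOUTH_ASIAN)
    assert list(strata) == ["45 to 64"]
    assert strata["45 to 64"].as_dict() == overall.as_dict()


def test_stratum_without_predicted_positives_has_undefined_ppv():
    a, g, s = _strat_population()
    # force one sex stratum to carry no predicted positives
    a = a.copy()
    male = s["sex"] == "Male"
    a.loc[male.values, "group"] = datasets.GENERAL
    strata = stratified_characteristics(a, g, s, "sex", datasets.SOUTH_ASIAN)
    assert strata["Male"].ppv is None
    assert strata["Female"].ppv is not None


def test_unknown_stratum_field_rejected():
    a, g, s = _strat_population()
    with pytest.raises(ValueError):
        stratified_characteristics(a, g, s, "province", datasets.SOUTH_ASIAN)


def _comparison_setup():
    """Roster/gold/survey where one extra list name flips known cells."""
    rows = [
        # person, surname, gold
        ("1", "Patel", "T"), ("2", "Patel", "T"), ("3", "Singh", "O"),
        ("4", "Zeta", "O"), ("5", "Qrst", "T"), ("6", "Smith", "O"),
    ]
    roster = pd.DataFrame(
        {"person_id": [r[0] for r in rows], "surname": [r[1] for r in rows]}
    )
    gold = pd.DataFrame(
        {"person_id": [r[0] for r in rows], "gold": [r[2] for r in rows]}
    )
    survey = pd.DataFrame(
        {"person_id": [r[0] for r in rows], "weight": [1.0] * len(rows)}
    )
    base = ListCollection(lists=(build_list(["Patel", "Singh"], "T"),),
                          default_label="O")
    return roster, gold, survey, base


def test_compare_identical_lists_zero_difference():
    roster, gold, survey, base = _comparison_setup()
    report = compare_lists(base, base, roster, gold, survey, "T")
    assert all(d == 0 for d in report["difference"].values())


def test_compare_extra_name_on_non_target_respondents_hurts_ppv_only():
    roster, gold, survey, base = _comparison_setup()
    wider = ListCollection(
        lists=(build_list(["Patel", "Singh", "Zeta"], "T"),), default_label="O"
    )
    report = compare_lists(base, wider, roster, gold, survey, "T")
    assert report["B"].ppv <= report["A"].ppv
    assert report["difference"]["ppv"] < 0
    assert report["difference"]["sensitivity"] == 0


def test_compare_extra_name_on_target_respondents_raises_sensitivity():
    roster, gold, survey, base = _comparison_setup()
    wider = ListCollection(
        lists=(build_list(["Patel", "Singh", "Qrst"], "T"),), default_label="O"
    )
    report = compare_lists(base, wider, roster, gold, survey, "T")
    assert report["B"].sensitivity > report["A"].sensitivity


def test_bootstrap_deterministic_and_degenerate():
    n = 60
    a = pd.DataFrame({"person_id": [str(i) for i in range(n)],
                      "group": ["T"] * n})
    g = pd.DataFrame({"person_id": a["person_id"], "gold": ["T"] * n})
    s = pd.DataFrame({"person_id": a["person_id"], "weight": [1.0] * n})
    ci1 = bootstrap_ci(a, g, s, "T", "ppv", B=100, seed=5)
    ci2 = bootstrap_ci(a, g, s, "T", "ppv", B=100, seed=5)
    assert ci1 == ci2                      # same seed, same interval
    assert ci1 == (1.0, 1.0)               # constant metric: zero width


def test_bootstrap_errors_when_metric_mostly_undefined():
    # two respondents, none predicted positive: PPV undefined in most draws
    a = pd.DataFrame({"person_id": ["1", "2"], "group": ["O", "O"]})
    g = pd.DataFrame({"person_id": ["1", "2"], "gold": ["T", "O"]})
    s = pd.DataFrame({"person_id": ["1", "2"], "weight": [1.0, 1.0]})
    with pytest.raises(ValueError, match="undefined"):
        bootstrap_ci(a, g, s, "T", "ppv", B=50, seed=1)


def test_bootstrap_interval_covers_generating_sensitivity():
    # repeated simulations: the 95% interval should almost always cover
    # the generating sensitivity of 0.7
    rng = np.random.default_rng(2024)
    true_sens, n, covered, sims = 0.7, 1500, 0, 40
    for k in range(sims):
        gold = rng.random(n) < 0.3
        group = np.where(
            gold, rng.random(n) < true_sens, rng.random(n) < 0.05
        )
        pid = [str(i) for i in range(n)]
        a = pd.DataFrame({"person_id": pid,
                          "group": np.where(group, "T", "O")})
        g = pd.DataFrame({"person_id": pid, "gold": np.where(gold, "T", "O")})
        s = pd.DataFrame({"person_id": pid, "weight": np.ones(n)})
        lo, hi = bootstrap_ci(a, g, s, "T", "sensitivity", B=250,
                              seed=int(rng.integers(2**31)), weighted=False)
        covered += lo <= true_sens <= hi
    assert covered >= int(0.8 * sims)
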