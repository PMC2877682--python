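import numpy as np
import pandas as pd
import pytest

from namecohort import datasets

LABELS = (datasets.SOUTH_ASIAN, datasets.CHINESE, datasets.GENERAL)


def brute_force_metrics(rows, target, weighted):
    """Independent per-respondent loop computing the four test
    characteristics; rows are (surname_group, gold_group, weight)."""
    tp = fp = fn = tn = 0.0
    for group, gold, w in rows:
        x = w if weighted else 1.0
        if group == target and gold == target:
            tp += x
        elif group == target:
            fp += x
        elif gold == target:
            fn += x
        else:
            tn += x

    def ratio(num, den):
        return None if den == 0 else num / den

    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }


def random_population(rng, n=200, labels=LABELS):
    """A random linked (assignments, gold, survey) triple with skewed
    group probabilities and lognormal weights."""
    pid = np.array([f"R{i:05d}" for i in range(n)])
    group = rng.choice(labels, size=n, p=[0.08, 0.07, 0.85])
    gold = rng.choice(labels, size=n, p=[0.10, 0.05, 0.85])
    weight = rng.lognormal(4.0, 0.9, size=n)
    assignments = pd.DataFrame({"person_id": pid, "group": group})
    gold_df = pd.DataFrame({"person_id": pid, "gold": gold})
    survey = pd.DataFrame({"person_id": pid, "weight": weight})
    return assignments, gold_df, survey


def run_pipeline(params):
    """Generate a synthetic survey and push it through the full
    assign → resolve → cross-tabulate pipeline with the packaged lists."""
    from namecohort import ListCollection, assign, goldstd, simulate, validate

    res = simulate.generate_survey(params)
    lists = tuple(datasets.load_starter_list(t) for t in params.targets)
    coll = ListCollection(lists=lists, default_label=params.default_label)
    ar = assign.assign_roster(res.roster, coll)
    survey = goldstd.pool_weights(res.survey, params.cycles)
    gold = goldstd.resolve_respondents(
        survey, coll.group_labels, coll.default_label
    )
    tab = validate.cross_tabulate(ar.assignments, gold, survey)
    return res, ar, gold, survey, tab


def metric_denominator_weights(assignments, gold, survey, target):
    """Pooled weights of each metric's denominator set, for Monte-Carlo
    standard errors of the weighted metrics."""
    df = survey.merge(gold, on="person_id").merge(assignments, on="person_id")
    w = df["weight"].to_numpy(dtype=float)
    gp = (df["group"] == target).to_numpy()
    gl = (df["gold"] == target).to_numpy()
    return {
        "sensitivity": w[gl],
        "specificity": w[~gl],
        "ppv": w[gp],
        "npv": w[~gp],
    }


@pytest.fixture(scope="session")
def starter_collection():
    return datasets.load_starter_collection()


@pytest.fixture(scope="session")
def reference_population():
    """The published Ontario confusion counts expanded to one row per
    respondent (unit weights)."""
    tab = datasets.ontario_reference_crosstab()
    rows = []
    for r in tab.index:
        for c in tab.columns:
            rows.extend([(r, c)] * int(tab.loc[r, c]))
    pid = [f"C{i:05d}" for i in range(len(rows))]
    assignments = pd.DataFrame({"person_id": pid, "group": [g for g, _ in rows]})
    gold = pd.DataFrame({"person_id": pid, "gold": [g for _, g in rows]})
    survey = pd.DataFrame({"person_id": pid, "weight": np.ones(len(rows))})
    return assignments, gold, survey
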