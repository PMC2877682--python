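"""Synthetic rosters and weighted surveys with known ground truth.

Because registry rosters and health-survey microdata are restricted, the
package ships a generative model that emulates their joint structure: a
population with a small ethnic-minority prevalence, a group-dependent
probability of bearing a surname on that group's list (*capture*, the
driver of sensitivity), a small probability that outsiders bear a listed
name (*contamination*, the driver of PPV loss), immigration-category
multipliers on those probabilities (native-born members of the majority
population are the most likely to carry an adopted or inherited listed
surname, which is what degrades PPV in that stratum), a probability that a
true member self-reports outside the target token (*misreport*), lognormal
person-level weights drawn independently of group, and survey cycles.

Generative model, per respondent (all draws independent given the
parameters; deterministic given the seed):

1. true group ``g`` ~ categorical(prevalence);
2. immigration category, sex, age band ~ per-group composition tables;
3. list membership: for each list ``L``, bears a name on ``L`` with
   probability ``capture[g]·cap_mult[imm]`` when ``L == g`` else
   ``contamination[(L, g)]·con_mult[imm]`` (at most one list);
4. surname: drawn from the matching packaged 200-name fixture with
   rank-frequency (Zipf-extrapolated) weights; off-list respondents draw
   from the general-population fixture;
5. self-report: a true member of a target group answers a single target
   token with probability ``1 − misreport``, otherwise (and for everyone
   else) a distractor pattern that never resolves to a target group;
6. weight ~ lognormal; cycle ~ categorical.

Closed-form expected test characteristics follow by summing the joint cell
probabilities over groups g and immigration categories k (π = prevalence,
q = composition, s = capture, c = contamination, m = stratum multiplier,
r = misreport; T the target group):

    A = P(test+, gold+) = Σ_k π_T q_{T,k} s m^cap_k (1 − r)
    P(test+)            = Σ_{g,k} π_g q_{g,k} p_test(g, k)
    P(gold+)            = π_T (1 − r)
    B = P(test+) − A,  C = P(gold+) − A,  D = 1 − A − B − C

    sensitivity = A/(A+C)   specificity = D/(B+D)
    PPV         = A/(A+B)   NPV         = D/(C+D)

Any metric with a vanishing denominator is undefined.  Person-level
weights are independent of every other draw, so expected weighted metrics
equal these probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import datasets
from .datasets import CHINESE, GENERAL, SOUTH_ASIAN
from .validate import TestCharacteristics

__all__ = [
    "SimulationParams",
    "SimulationResult",
    "ontario_defaults",
    "generate_survey",
    "expected_metrics",
    "recover_parameters",
    "weighted_proportion_se",
    "IMMIGRATION_CATEGORIES",
]

IMMIGRATION_CATEGORIES = (
    "Born in Canada",
    "Immigrant <=10 years",
    "Immigrant 11 to 20 years",
    "Immigrant > 20 years",
)
SEXES = ("Male", "Female")
AGE_BANDS = ("44 or younger", "45 to 64", "65 or older")

# Weighted demographic composition of each group among Ontario survey
# respondents (immigration mix is what makes minority members mostly
# immigrants and the general population mostly native-born).
_IMMIGRATION_MIX = {
    SOUTH_ASIAN: (0.070, 0.472, 0.259, 0.199),
    CHINESE: (0.096, 0.381, 0.283, 0.240),
    GENERAL: (0.737, 0.060, 0.048, 0.155),
}
_SEX_MIX = {
    SOUTH_ASIAN: (0.547, 0.453),
    CHINESE: (0.525, 0.475),
    GENERAL: (0.484, 0.516),
}
_AGE_MIX = {
    SOUTH_ASIAN: (0.644, 0.292, 0.064),
    CHINESE: (0.626, 0.276, 0.098),
    GENERAL: (0.520, 0.314, 0.166),
}

_DISTRACTOR_PATTERNS = (
    # (ancestry answers, background answers) — none resolves to a target
    (("English",), ("White",)),
    (("French",), ("White",)),
    (("Scottish", "Irish"), ("White",)),
    (("Southeast Asian",), ("Southeast Asian",)),
    (("Aboriginal",), ("Aboriginal",)),
    (("Scottish", "South Asian"), ("White",)),
    (("Chinese", "English"), ("White", "Chinese")),
    (("Filipino",), ("Filipino",)),
)


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the synthetic survey generator.

    ``prevalence`` are unweighted sampling proportions over all groups
    (targets plus the residual) and must sum to 1.  ``capture`` maps each
    target group to the probability a member bears a name on that group's
    list; ``contamination`` maps (list group, bearer group) to the
    probability a non-member bears a name on the list group's list.
    ``strata_effects`` maps an immigration category to
    ``(capture multiplier, contamination multiplier)``.  ``misreport`` is
    the probability a true member self-reports outside the target token.
    ``weight_lognormal`` is (mean, sd) of log weight.
    """

    n: int
    prevalence: Mapping[str, float]
    capture: Mapping[str, float]
    contamination: Mapping[tuple[str, str], float]
    misreport: float = 0.0
    weight_lognormal: tuple[float, float] = (5.0, 0.8)
    cycles: Mapping[str, float] = field(
        default_factory=lambda: {"2001": 1 / 3, "2002": 1 / 3, "2003": 1 / 3}
    )
    strata_effects: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {k: (1.0, 1.0) for k in IMMIGRATION_CATEGORIES}
    )
    seed: int = 0
    default_label: str = GENERAL
    immigration_mix: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(_IMMIGRATION_MIX)
    )
    # sensitivity-analysis knob: per-group multiplicative shift of the
    # weight distribution.  Weights are independent of group by default
    # (the survey's weighting does not involve ethnicity); non-unit values
    # break the closed-form oracle's weighted/unweighted equivalence.
    weight_group_multiplier: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        total = sum(self.prevalence.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"prevalences must sum to 1, got {total}")
        for label, p in {**self.prevalence, **dict(self.capture)}.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of range for {label!r}: {p}")
        for key, p in self.contamination.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"contamination out of range for {key!r}: {p}")
        if not 0.0 <= self.misreport <= 1.0:
            raise ValueError(f"misreport out of range: {self.misreport}")
        for grp in self.groups:
            mix = self.immigration_mix.get(grp)
            if mix is None or abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"immigration mix for {grp!r} must sum to 1")
        # adjusted per-stratum probabilities must stay in [0, 1]
        for k, (mc, mx) in self.strata_effects.items():
            for t in self.targets:
                if not 0.0 <= self.capture[t] * mc <= 1.0:
                    raise ValueError(
                        f"capture for {t!r} out of [0,1] in stratum {k!r}"
                    )
            for (lst, grp), c in self.contamination.items():
                if not 0.0 <= c * mx <= 1.0:
                    raise ValueError(
                        f"contamination for {(lst, grp)!r} out of [0,1] in stratum {k!r}"
                    )

    @property
    def targets(self) -> tuple[str, ...]:
        return tuple(self.capture)

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.prevalence)

    def membership_prob(self, list_group: str, bearer_group: str, imm: str) -> float:
        """P(bearing a name on ``list_group``'s list | bearer group, stratum)."""
        cap_mult, con_mult = self.strata_effects.get(imm, (1.0, 1.0))
        if list_group == bearer_group:
            return self.capture[list_group] * cap_mult
        return self.contamination.get((list_group, bearer_group), 0.0) * con_mult


def ontario_defaults(n: int = 50_000, seed: int = 0, **overrides) -> SimulationParams:
    """Default calibration emulating the Ontario validation regime.

    Minority prevalences of 5.4% and 4.0%, capture probabilities of 0.504
    and 0.802 (so expected sensitivity matches the regime's 50%/80%),
    contamination of a few per mille concentrated among the native-born
    (multiplier 1.2 versus 0.2 for recent immigrants), and a 2.5%
    misreport rate, which together put expected PPV near 0.89/0.92.  These
    are generator inputs describing a plausible study regime, not targets.
    """
    base = SimulationParams(
        n=n,
        prevalence={SOUTH_ASIAN: 0.054, CHINESE: 0.040, GENERAL: 0.906},
        capture={SOUTH_ASIAN: 0.504, CHINESE: 0.802},
        contamination={
            (SOUTH_ASIAN, GENERAL): 0.0028,
            (SOUTH_ASIAN, CHINESE): 0.0035,
            (CHINESE, GENERAL): 0.0021,
            (CHINESE, SOUTH_ASIAN): 0.0064,
        },
        misreport=0.025,
        strata_effects={
            "Born in Canada": (1.0, 1.2),
            "Immigrant <=10 years": (1.0, 0.2),
            "Immigrant 11 to 20 years": (1.0, 0.4),
            "Immigrant > 20 years": (1.0, 0.5),
        },
        seed=seed,
    )
    return replace(base, **overrides) if overrides else base


@dataclass
class SimulationResult:
    roster: pd.DataFrame  # person_id, surname
    survey: pd.DataFrame  # standard survey schema
    truth: pd.DataFrame   # person_id, true_group, on_list, misreported, ...
    params: SimulationParams

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.roster.to_csv(outdir / "roster.csv", index=False)
        self.survey.to_csv(outdir / "survey.csv", index=False)
        self.truth.to_csv(outdir / "truth.csv", index=False)


def _name_frequencies(group: str) -> tuple[np.ndarray, np.ndarray]:
    """Fixture names in rank order with Zipf-extrapolated sampling weights.

    The ten most common names carry their registrant counts; counts for the
    remaining ranks follow a power law ``count ∝ rank^(-s)`` fitted by
    least squares to the log-log top ten.
    """
    names = np.array(datasets.starter_names_ordered(group), dtype=object)
    counts_df = datasets.top10_registrant_counts()
    top = counts_df[counts_df["group"] == group]
    top_counts = top.set_index("name")["count"].reindex(names[:10]).to_numpy(dtype=float)
    ranks = np.arange(1, 11)
    slope, intercept = np.polyfit(np.log(ranks), np.log(top_counts), 1)
    tail_ranks = np.arange(11, len(names) + 1)
    tail_counts = np.exp(intercept + slope * np.log(tail_ranks))
    weights = np.concatenate([top_counts, tail_counts])
    return names, weights / weights.sum()


def generate_survey(params: SimulationParams) -> SimulationResult:
    """Draw a synthetic roster, survey and truth table.

    Deterministic given ``params.seed``; identical parameters produce
    byte-identical output files.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n
    groups = list(params.groups)
    targets = list(params.targets)

    true_group = rng.choice(groups, size=n, p=[params.prevalence[g] for g in groups])

    imm = np.empty(n, dtype=object)
    sex = np.empty(n, dtype=object)
    age = np.empty(n, dtype=object)
    for g in groups:
        mask = true_group == g
        m = int(mask.sum())
        if m == 0:
            continue
        imm[mask] = rng.choice(
            IMMIGRATION_CATEGORIES, size=m, p=list(params.immigration_mix[g])
        )
        sex[mask] = rng.choice(SEXES, size=m, p=list(_SEX_MIX.get(g, (0.5, 0.5))))
        age[mask] = rng.choice(
            AGE_BANDS, size=m, p=list(_AGE_MIX.get(g, (1 / 3, 1 / 3, 1 / 3)))
        )

    # membership: categorical over (each target list, no list)
    u = rng.random(n)
    on_list = np.full(n, "", dtype=object)
    prob_cache: dict[tuple[str, str], np.ndarray] = {}
    for g in groups:
        for k in IMMIGRATION_CATEGORIES:
            probs = np.array(
                [params.membership_prob(t, g, k) for t in targets], dtype=float
            )
            if probs.sum() > 1.0:
                raise ValueError(
                    f"membership probabilities exceed 1 for group {g!r}, stratum {k!r}"
                )
            prob_cache[(g, k)] = probs
    for i in range(n):
        probs = prob_cache[(true_group[i], imm[i])]
        cum = 0.0
        for t, p in zip(targets, probs):
            cum += p
            if u[i] < cum:
                on_list[i] = t
                break

    # surnames from the packaged fixtures
    freq = {g: _name_frequencies(g) for g in targets + [GENERAL]}
    surname = np.empty(n, dtype=object)
    for pool in targets + [GENERAL]:
        mask = on_list == pool if pool in targets else on_list == ""
        m = int(mask.sum())
        if m:
            names, w = freq[pool]
            surname[mask] = rng.choice(names, size=m, p=w)

    # self-report
    misreported = np.zeros(n, dtype=bool)
    is_target = np.isin(true_group, targets)
    misreported[is_target] = rng.random(int(is_target.sum())) < params.misreport
    honest = is_target & ~misreported
    q_anc = np.empty(n, dtype=object)
    q_bkg = np.empty(n, dtype=object)
    # honest members: single target token to the ancestry question; the
    # background question repeats it or adds an extra token (still resolved
    # by the ancestry single response)
    repeat_bkg = rng.random(n) < 0.7
    distractor_idx = rng.integers(0, len(_DISTRACTOR_PATTERNS), size=n)
    for i in range(n):
        if honest[i]:
            token = true_group[i]
            q_anc[i] = token
            q_bkg[i] = token if repeat_bkg[i] else f"{token};White"
        else:
            anc, bkg = _DISTRACTOR_PATTERNS[distractor_idx[i]]
            q_anc[i] = ";".join(anc)
            q_bkg[i] = ";".join(bkg)

    mean_log, sd_log = params.weight_lognormal
    weight = rng.lognormal(mean_log, sd_log, size=n)
    if params.weight_group_multiplier:
        mult = np.array(
            [params.weight_group_multiplier.get(g, 1.0) for g in true_group]
        )
        weight = weight * mult
    cycle_labels = list(params.cycles)
    cycle = rng.choice(cycle_labels, size=n, p=[params.cycles[c] for c in cycle_labels])

    pid = np.array([f"P{i:07d}" for i in range(n)])
    roster = pd.DataFrame({"person_id": pid, "surname": surname})
    survey = pd.DataFrame(
        {
            "person_id": pid,
            "cycle": cycle,
            "weight": weight,
            "q_ancestry": q_anc,
            "q_background": q_bkg,
            "sex": sex,
            "age_band": age,
            "immigration": imm,
        }
    )
    truth = pd.DataFrame(
        {
            "person_id": pid,
            "true_group": true_group,
            "on_list": on_list,
            "misreported": misreported,
            "immigration": imm,
            "weight": weight,
        }
    )
    return SimulationResult(roster, survey, truth, params)


def _joint_cells(
    params: SimulationParams, target_group: str, immigration: str | None = None
) -> tuple[float, float, float, float]:
    """Joint probabilities (A, B, C, D) of (test, gold) for one target,
    optionally restricted to one immigration category (renormalized)."""
    cats = [immigration] if immigration is not None else list(IMMIGRATION_CATEGORIES)
    mass = a = test_pos = gold_pos = 0.0
    for g in params.groups:
        mix = dict(zip(IMMIGRATION_CATEGORIES, params.immigration_mix[g]))
        for k in cats:
            p_cell = params.prevalence[g] * mix[k]
            mass += p_cell
            p_test = params.membership_prob(target_group, g, k)
            test_pos += p_cell * p_test
            if g == target_group:
                honest = 1.0 - params.misreport
                gold_pos += p_cell * honest
                a += p_cell * p_test * honest
    if mass == 0.0:
        raise ValueError(f"no probability mass in stratum {immigration!r}")
    a, test_pos, gold_pos = a / mass, test_pos / mass, gold_pos / mass
    b = test_pos - a
    c = gold_pos - a
    d = 1.0 - a - b - c
    return a, b, c, d


def expected_metrics(
    params: SimulationParams, target_group: str, immigration: str | None = None
) -> TestCharacteristics:
    """Closed-form expected test characteristics under the generative model
    (module docstring gives the formula sheet).  With ``immigration`` set,
    the expectation is conditional on that stratum — the oracle for
    stratified PPV.  Degenerate denominators yield undefined metrics."""
    if target_group not in params.targets:
        raise KeyError(f"{target_group!r} is not a simulated target group")
    a, b, c, d = _joint_cells(params, target_group, immigration)

    def ratio(num: float, den: float) -> float | None:
        return None if den <= 0 else num / den

    return TestCharacteristics(
        sensitivity=ratio(a, a + c),
        specificity=ratio(d, b + d),
        ppv=ratio(a, a + b),
        npv=ratio(d, c + d),
        n_effective={
            "sensitivity": a + c,
            "specificity": b + d,
            "ppv": a + b,
            "npv": c + d,
        },
    )


def recover_parameters(
    truth: pd.DataFrame, target_group: str, prob_col: str | None = None
) -> dict[str, float]:
    """Moment estimates of (prevalence π, capture s, aggregate
    contamination c) from a truth table.

    With ``prob_col`` naming a column of cell probabilities the estimates
    are computed on that exact distribution (enumeration mode, no sampling
    noise); otherwise each row counts once.
    """
    w = truth[prob_col].to_numpy(dtype=float) if prob_col else np.ones(len(truth))
    member = (truth["true_group"] == target_group).to_numpy()
    on = (truth["on_list"] == target_group).to_numpy()
    total = w.sum()
    pi = float(w[member].sum() / total)
    s = float(w[member & on].sum() / w[member].sum()) if w[member].sum() else np.nan
    c = (
        float(w[~member & on].sum() / w[~member].sum())
        if w[~member].sum()
        else np.nan
    )
    return {"pi": pi, "s": s, "c": c}


def weighted_proportion_se(p: float, weights: np.ndarray) -> float:
    """Approximate Monte-Carlo standard error of a weighted proportion with
    expected value ``p`` over the denominator respondents ``weights``
    (ratio-estimator approximation; reduces to sqrt(p(1−p)/n) for unit
    weights)."""
    w = np.asarray(weights, dtype=float)
    if w.size == 0 or w.sum() == 0:
        return np.inf
    return float(np.sqrt(max(p * (1.0 - p), 1e-12) * (w**2).sum()) / w.sum())
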