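"""Resolve two multi-response self-reported ethnicity questions into a
gold-standard group.

The rule: a respondent belongs to a target group exactly when at least one
of the two questions has a single response equal to that group's token;
every other pattern falls to the General Population.  Weights pooled over
three survey cycles are divided by 3 so they still sum to one population.
"""

import pandas as pd

from namecohort import pool_weights, resolve_self_report

TARGETS = ("South Asian", "Chinese")
DEFAULT = "General Population"

cases = [
    ({"South Asian"}, {"South Asian"}),        # single response, both questions
    ({"Scottish"}, {"Chinese"}),               # single response to one question
    ({"Scottish", "South Asian"}, {"White"}),  # multi-response: no trigger
    ({"South Asian"}, {"Chinese"}),            # conflicting singles -> residual
    (set(), set()),                            # no answers -> residual
]
for ancestry, background in cases:
    label = resolve_self_report(ancestry, background, TARGETS, DEFAULT)
    print(f"ancestry={sorted(ancestry)!s:30} background={sorted(background)!s:15} -> {label}")

survey = pd.DataFrame(
    {
        "person_id": ["1", "2", "3"],
        "cycle": ["2001", "2002", "2003"],
        "weight": [1.5, 3.0, 9.0],
        "q_ancestry": ["South Asian", "Chinese", "English"],
        "q_background": ["South Asian", "Chinese", "White"],
        "sex": ["F", "M", "F"],
        "age_band": ["45 to 64"] * 3,
        "immigration": ["Born in Canada"] * 3,
    }
)
pooled = pool_weights(survey, {"2001", "2002", "2003"})
print(f"\nweights {survey['weight'].tolist()} pooled over 3 cycles -> "
      f"{pooled['weight'].tolist()}")
print("downstream metrics are ratios of weighted sums, so pooling never changes them")
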