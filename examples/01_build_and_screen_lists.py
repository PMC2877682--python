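"""Build a surname list from raw spellings, screen exclusions, and check
that two lists stay disjoint.

Raw registry spellings are normalized to a canonical form (diacritics
folded, apostrophes/periods removed, uppercased) so that variant spellings
of the same surname collapse before matching.
"""

from namecohort import (
    ListCollection,
    build_list,
    check_disjoint,
    normalize_surname,
    screen_exclusions,
)

for raw in ("Patel", "Bélanger", "D'Souza  ", "Sidhu-Gill"):
    print(f"{raw!r:15} -> {normalize_surname(raw)}")

# duplicates after normalization collapse: three spellings, one name
chinese = build_list(["Wong", "WONG", "wong", "Chan", "Li", "Lí", "Jain"], "Chinese")
print(f"\nChinese candidate list: {len(chinese)} unique canonical names")

# screening removes names judged not unique to the group (here: JAIN,
# which is common among South Asians); provenance records the removal
chinese = screen_exclusions(chinese, {"JAIN"})
print(f"after screening: {len(chinese)} names; note: {chinese.provenance[-1]}")

south_asian = build_list(["Patel", "Singh", "Jain"], "South Asian")
collection = ListCollection(lists=(south_asian, chinese))
overlap = check_disjoint(collection)
print(f"\noverlap report (empty means the lists are safely disjoint): {overlap}")
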