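"""Apply surname lists to a population roster.

This produces the surname-derived ethnic identification file: every roster
record (person id, raw surname) receives exactly one group label — the
label of the list containing its canonical surname, or the residual label
when no list matches.  The output is a total partition of the roster, so
per-group counts always sum to the roster size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .names import ListCollection, UnnormalizableNameError, check_disjoint, normalize_surname

logger = logging.getLogger(__name__)

__all__ = [
    "RosterRecord",
    "AssignmentResult",
    "assign_one",
    "assign_roster",
    "surname_frequency",
    "read_roster",
    "write_assignments",
]


@dataclass(frozen=True)
class RosterRecord:
    person_id: str
    surname_raw: str


@dataclass
class AssignmentResult:
    """Assignments in roster order plus bookkeeping counters."""

    assignments: pd.DataFrame  # columns: person_id, group
    counts: dict[str, int]
    n_unnormalizable: int = 0

    def __len__(self) -> int:
        return len(self.assignments)


def _validate_collection(collection: ListCollection) -> None:
    if len(collection.lists) >= 2 and collection.precedence is None:
        overlap = check_disjoint(collection)
        if overlap:
            pairs = {k: sorted(v)[:5] for k, v in overlap.items()}
            raise ValueError(
                "surname lists overlap and no precedence order is declared; "
                f"overlapping pairs (first names shown): {pairs}"
            )


def _match(canonical: str, collection: ListCollection, match_components: bool = False) -> str:
    order = collection.precedence or collection.group_labels
    for label in order:
        if canonical in collection.get(label).names:
            return label
    if match_components and "-" in canonical:
        # optional mode: a hyphenated compound classifies only when every
        # component falls on the same single list (default keeps full-string
        # matching, which preserves PPV)
        parts = [p for p in canonical.split("-") if p]
        if parts:
            labels = set()
            for part in parts:
                for label in order:
                    if part in collection.get(label).names:
                        labels.add(label)
                        break
                else:
                    labels.add(collection.default_label)
            if len(labels) == 1 and (lab := labels.pop()) != collection.default_label:
                return lab
    return collection.default_label


def assign_one(surname_raw: str, collection: ListCollection, match_components: bool = False) -> str:
    """Assign a single raw surname to a group label.

    The surname is normalized then matched by exact whole-name equality
    against each list; a name on no list falls into the residual group.
    An unnormalizable surname (no letters) also falls into the residual
    group with a logged warning — on a registry-scale roster a blank or
    garbled name must never abort the run, and the residual group is by
    construction "everyone not positively identified".
    """
    _validate_collection(collection)
    try:
        canonical = normalize_surname(surname_raw)
    except UnnormalizableNameError:
        logger.warning("unnormalizable surname %r assigned to %s",
                       surname_raw, collection.default_label)
        return collection.default_label
    return _match(canonical, collection, match_components)


def assign_roster(
    roster: pd.DataFrame | Sequence[RosterRecord],
    collection: ListCollection,
    match_components: bool = False,
) -> AssignmentResult:
    """Assign every roster record to a group.

    Parameters
    ----------
    roster:
        DataFrame with columns ``person_id`` and ``surname`` (or
        ``surname_raw``), or a sequence of :class:`RosterRecord`.
    collection:
        Lists to match against; must be pairwise disjoint or carry a
        declared precedence order.

    Returns
    -------
    AssignmentResult
        Assignments in input order, per-group counts summing to the roster
        size, and the number of unnormalizable surnames defaulted.

    Raises
    ------
    ValueError
        On duplicate person ids (naming them) or on overlapping lists
        without declared precedence.
    """
    _validate_collection(collection)
    if not isinstance(roster, pd.DataFrame):
        roster = pd.DataFrame(
            [(r.person_id, r.surname_raw) for r in roster],
            columns=["person_id", "surname"],
        )
    else:
        roster = roster.rename(columns={"surname_raw": "surname"})
        missing = {"person_id", "surname"} - set(roster.columns)
        if missing:
            raise ValueError(f"roster is missing columns: {sorted(missing)}")

    dupes = roster["person_id"][roster["person_id"].duplicated()]
    if len(dupes):
        raise ValueError(
            f"duplicate person_id in roster: {sorted(set(dupes.astype(str)))[:10]}"
        )

    n_bad = 0
    groups: list[str] = []
    # normalize each distinct spelling once; registry rosters are heavily repetitive
    cache: dict[str, str] = {}
    for raw in roster["surname"].astype(str):
        group = cache.get(raw)
        if group is None:
            try:
                group = _match(normalize_surname(raw), collection, match_components)
            except UnnormalizableNameError:
                group = collection.default_label
                n_bad += 1
                logger.warning("unnormalizable surname %r assigned to %s",
                               raw, group)
            cache[raw] = group
        groups.append(group)

    out = pd.DataFrame({"person_id": roster["person_id"].values, "group": groups})
    counts = {label: 0 for label in collection.all_labels}
    counts.update(out["group"].value_counts().to_dict())
    return AssignmentResult(out, counts, n_unnormalizable=n_bad)


def surname_frequency(
    roster: pd.DataFrame | Sequence[RosterRecord],
    collection: ListCollection,
) -> dict[str, list[tuple[str, int]]]:
    """Per-group ranked canonical-surname counts for a roster.

    For each group (including the residual) returns ``(name, count)`` pairs
    sorted by descending count, ties broken lexicographically — the
    computation behind "the N most common surnames from each group".
    """
    if not isinstance(roster, pd.DataFrame):
        roster = pd.DataFrame(
            [(r.person_id, r.surname_raw) for r in roster],
            columns=["person_id", "surname"],
        )
    ranking: dict[str, dict[str, int]] = {l: {} for l in collection.all_labels}
    for raw in roster["surname"].astype(str) if len(roster) else []:
        try:
            canonical = normalize_surname(raw)
        except UnnormalizableNameError:
            continue
        group = _match(canonical, collection)
        bucket = ranking[group]
        bucket[canonical] = bucket.get(canonical, 0) + 1
    return {
        group: sorted(bucket.items(), key=lambda kv: (-kv[1], kv[0]))
        for group, bucket in ranking.items()
    }


def read_roster(path: str | Path) -> pd.DataFrame:
    """Read a roster CSV with header ``person_id,surname``."""
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = {"person_id", "surname"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: roster is missing columns {sorted(missing)}")
    return df


def write_assignments(result: AssignmentResult, path: str | Path) -> None:
    """Write assignments as CSV with header ``person_id,group``."""
    result.assignments.to_csv(path, index=False)
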