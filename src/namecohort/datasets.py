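"""Packaged reference data.

Starter surname lists
    The 200 most common surnames per group among Ontario health-registry
    registrants: a South Asian list, a Chinese list, and — for contrast and
    for the simulator's off-list name pool — the 200 most common
    general-population surnames (names on neither minority list, including
    shared names such as Khan, Ahmed, Lee or Fernandes that a
    PPV-maximizing list deliberately leaves off).

Reference cross-tabulation
    The unweighted confusion counts from the Ontario validation of the full
    production lists against self-reported ethnicity in a population health
    survey (69,859 respondents), used as a worked example and as a
    regression fixture for the cross-tabulation arithmetic.
"""

from __future__ import annotations

import csv
from importlib import resources

import pandas as pd

from .names import ListCollection, SurnameList, read_list_file

__all__ = [
    "SOUTH_ASIAN",
    "CHINESE",
    "GENERAL",
    "load_starter_list",
    "load_starter_collection",
    "load_general_names",
    "top10_registrant_counts",
    "ontario_reference_crosstab",
]

SOUTH_ASIAN = "South Asian"
CHINESE = "Chinese"
GENERAL = "General Population"

_FILES = {
    SOUTH_ASIAN: "southasian_top200.txt",
    CHINESE: "chinese_top200.txt",
    GENERAL: "general_top200.txt",
}


def _data_path(filename: str):
    return resources.files("namecohort.data").joinpath(filename)


def load_starter_list(group: str) -> SurnameList:
    """Load one packaged 200-name starter list (``"South Asian"``,
    ``"Chinese"`` or ``"General Population"``)."""
    try:
        filename = _FILES[group]
    except KeyError:
        raise KeyError(f"no packaged list for group {group!r}") from None
    with resources.as_file(_data_path(filename)) as path:
        return read_list_file(path, group_label=group)


def load_starter_collection() -> ListCollection:
    """The two minority starter lists as a ready-to-use collection with the
    general population as the residual group."""
    return ListCollection(
        lists=(load_starter_list(SOUTH_ASIAN), load_starter_list(CHINESE)),
        default_label=GENERAL,
    )


def load_general_names() -> SurnameList:
    """The general-population name fixture (NOT a classifier list; it is the
    simulator's pool of off-list surnames)."""
    return load_starter_list(GENERAL)


def starter_names_ordered(group: str) -> list[str]:
    """The raw names of one packaged fixture in file (rank) order: the ten
    most common names first, the remaining 190 alphabetical."""
    try:
        filename = _FILES[group]
    except KeyError:
        raise KeyError(f"no packaged list for group {group!r}") from None
    text = _data_path(filename).read_text(encoding="utf-8")
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]


def top10_registrant_counts() -> pd.DataFrame:
    """Registrant counts for the ten most common names per group, columns
    ``group,name,count``.  Anchors the simulator's rank-frequency model."""
    with resources.as_file(_data_path("top10_counts.csv")) as path:
        return pd.read_csv(path)


def ontario_reference_crosstab() -> pd.DataFrame:
    """Unweighted counts of surname-derived (rows) versus self-identified
    (columns) ethnicity for the 69,859 respondents of the Ontario
    validation of the full production lists.

    Rows and columns are ordered South Asian, Chinese, General Population.
    """
    labels = [SOUTH_ASIAN, CHINESE, GENERAL]
    counts = [
        [654, 4, 129],
        [9, 899, 139],
        [737, 226, 67062],
    ]
    return pd.DataFrame(counts, index=labels, columns=labels)
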