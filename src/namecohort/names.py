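"""Surname normalization, list construction, screening and list file I/O.

A surname list is the entire "model" of a surname-based ethnicity
classifier: a named set of canonical surnames believed to be unique to one
ethnic group.  Classification downstream is exact whole-surname equality on
canonical form — no prefix, substring or phonetic matching — because the
design goal of such lists is to maximize positive predictive value, at the
cost of sensitivity, so that cohorts built from administrative rosters
contain almost exclusively true members of the target group.

Canonical form is defined here as: Unicode compatibility decomposition with
combining marks stripped (``é`` → ``E``), uppercased, apostrophes and
periods removed, any remaining non-letter character other than a hyphen
treated as a separator, runs of whitespace collapsed to a single space, and
surrounding whitespace trimmed.  Hyphens are kept, so a hyphenated compound
surname matches only as the full string.
"""

from __future__ import annotations

import csv
import io
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "UnnormalizableNameError",
    "ListFormatError",
    "normalize_surname",
    "is_canonical",
    "SurnameList",
    "ListCollection",
    "build_list",
    "screen_exclusions",
    "check_disjoint",
    "read_list_file",
    "write_list_file",
]

_APOSTROPHES = "'’ʼ`"


class UnnormalizableNameError(ValueError):
    """Raised when a raw surname contains no letters after cleaning."""

    def __init__(self, raw: str, message: str | None = None):
        self.raw = raw
        super().__init__(message or f"unnormalizable name: {raw!r}")


class ListFormatError(ValueError):
    """Raised for unreadable or malformed surname-list files."""


def normalize_surname(raw: str) -> str:
    """Return the canonical form of a raw surname.

    Deterministic and idempotent: canonical strings map to themselves.

    Raises
    ------
    UnnormalizableNameError
        If ``raw`` contains no letters once non-letter characters are
        stripped (e.g. an empty string, ``"123"`` or ``"--"``).
    """
    if not isinstance(raw, str):
        raise UnnormalizableNameError(repr(raw), "surname must be a string")
    decomposed = unicodedata.normalize("NFKD", raw)
    chars = []
    for ch in decomposed:
        if unicodedata.combining(ch):
            continue
        if ch in _APOSTROPHES or ch == ".":
            continue
        up = ch.upper()
        if "A" <= up <= "Z":
            chars.append(up)
        elif ch == "-":
            chars.append("-")
        else:
            chars.append(" ")  # digits, punctuation, whitespace all separate
    canonical = " ".join("".join(chars).split())
    if not any("A" <= c <= "Z" for c in canonical):
        raise UnnormalizableNameError(raw)
    return canonical


def is_canonical(value: str) -> bool:
    """True iff ``value`` is already in canonical form."""
    try:
        return normalize_surname(value) == value
    except UnnormalizableNameError:
        return False


@dataclass(frozen=True)
class SurnameList:
    """A named, duplicate-free set of canonical surnames.

    Parameters
    ----------
    group_label:
        The ethnic group the list identifies, e.g. ``"South Asian"``.
    names:
        Canonical surnames; set semantics, must be non-empty.
    provenance:
        Free-text notes recording how the list was built (input counts,
        screening steps, source files).
    """

    group_label: str
    names: frozenset[str]
    # free-text audit trail; not part of list identity/equality
    provenance: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self):
        if not self.group_label:
            raise ValueError("group_label must be non-empty")
        names = frozenset(self.names)
        if not names:
            raise ValueError(f"surname list {self.group_label!r} is empty")
        bad = sorted(n for n in names if not is_canonical(n))
        if bad:
            raise ValueError(
                f"non-canonical names in list {self.group_label!r}: {bad[:5]}"
            )
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "provenance", tuple(self.provenance))

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def with_note(self, note: str) -> "SurnameList":
        return SurnameList(self.group_label, self.names, self.provenance + (note,))


@dataclass(frozen=True)
class ListCollection:
    """An ordered collection of surname lists plus a residual group label.

    Every person not matched by any list falls into the residual group
    (``default_label``).  Member lists must either be pairwise disjoint or
    the collection must declare an explicit precedence order; assignment
    refuses to run otherwise, because a silently resolved overlap would
    corrupt the positive-predictive-value semantics of the lists.
    """

    lists: tuple[SurnameList, ...]
    default_label: str = "General Population"
    precedence: tuple[str, ...] | None = None

    def __post_init__(self):
        lists = tuple(self.lists)
        if not lists:
            raise ValueError("collection needs at least one list")
        labels = [sl.group_label for sl in lists]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate group labels: {labels}")
        if self.default_label in labels:
            raise ValueError(
                f"default label {self.default_label!r} collides with a group label"
            )
        if self.precedence is not None:
            prec = tuple(self.precedence)
            if sorted(prec) != sorted(labels):
                raise ValueError(
                    "precedence must be a permutation of the group labels"
                )
            object.__setattr__(self, "precedence", prec)
        object.__setattr__(self, "lists", lists)

    @property
    def group_labels(self) -> tuple[str, ...]:
        return tuple(sl.group_label for sl in self.lists)

    @property
    def all_labels(self) -> tuple[str, ...]:
        """Group labels followed by the residual label — the full partition."""
        return self.group_labels + (self.default_label,)

    def get(self, label: str) -> SurnameList:
        for sl in self.lists:
            if sl.group_label == label:
                return sl
        raise KeyError(label)


def build_list(
    raw_names: Sequence[str], group_label: str, provenance: Iterable[str] = ()
) -> SurnameList:
    """Normalize raw surnames into a :class:`SurnameList`.

    Duplicates after normalization collapse; provenance records the raw
    input count versus the unique canonical count.

    Raises
    ------
    UnnormalizableNameError
        Listing every offending entry, if any raw name has no letters.
    ValueError
        If ``raw_names`` is empty.
    """
    raw_names = list(raw_names)
    if not raw_names:
        raise ValueError("raw_names is empty")
    canonical: list[str] = []
    bad: list[str] = []
    for raw in raw_names:
        try:
            canonical.append(normalize_surname(raw))
        except UnnormalizableNameError:
            bad.append(raw)
    if bad:
        raise UnnormalizableNameError(
            repr(bad), f"unnormalizable names in input: {bad}"
        )
    unique = frozenset(canonical)
    note = f"built from {len(raw_names)} raw names -> {len(unique)} unique canonical"
    return SurnameList(group_label, unique, tuple(provenance) + (note,))


def screen_exclusions(
    candidates: SurnameList, exclusions: Iterable[str]
) -> SurnameList:
    """Remove an exclusion set from a candidate list.

    This is the mechanical half of list screening: candidate names judged
    not to be unique to the target group (because they are common in other
    populations) are subtracted.  The judgement producing the exclusion set
    is a human consensus process and is outside this package's scope.

    The result satisfies ``len(candidates) == len(result) +
    len(candidates ∩ exclusions)``; the count removed is recorded in
    provenance.  An empty result is an error — a usable list must retain at
    least one name.
    """
    excl = frozenset(exclusions)
    bad = sorted(n for n in excl if not is_canonical(n))
    if bad:
        raise ValueError(f"exclusion set contains non-canonical names: {bad[:5]}")
    removed = candidates.names & excl
    remaining = candidates.names - excl
    if not remaining:
        raise ValueError(
            f"screening removed every name from list {candidates.group_label!r}"
        )
    note = f"screened: {len(removed)} of {len(candidates)} candidates excluded"
    return SurnameList(
        candidates.group_label, remaining, candidates.provenance + (note,)
    )


def check_disjoint(
    collection: ListCollection,
) -> dict[tuple[str, str], frozenset[str]]:
    """Report names shared between any pair of lists in a collection.

    Returns a mapping ``(label_a, label_b) -> shared names`` containing only
    pairs with a non-empty intersection; an empty dict means the collection
    is pairwise disjoint.  Uniqueness of each name to one group is the core
    design requirement of a PPV-maximizing surname list, so overlaps are
    surfaced rather than resolved.
    """
    if len(collection.lists) < 2:
        raise ValueError("disjointness check needs at least two lists")
    report: dict[tuple[str, str], frozenset[str]] = {}
    lists = collection.lists
    for i, a in enumerate(lists):
        for b in lists[i + 1 :]:
            shared = a.names & b.names
            if shared:
                report[(a.group_label, b.group_label)] = frozenset(shared)
    return report


def read_list_file(path: str | Path, group_label: str | None = None) -> SurnameList:
    """Read a surname list from a text or CSV file.

    Two formats are supported, chosen by extension:

    * ``.txt`` — UTF-8, one surname per line, ``#``-prefixed comment lines
      and blank lines ignored;
    * ``.csv`` — UTF-8 CSV with header ``name,group``; all rows must carry
      the same group, which becomes the list label.

    ``group_label`` overrides the label inferred from the file (for ``.txt``
    the default label is the file stem).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    text = path.read_text(encoding="utf-8")
    if suffix == ".txt":
        raws, file_label = [], None
        for line in text.splitlines():
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                comment = stripped.lstrip("#").strip()
                if comment.lower().startswith("group:"):
                    file_label = comment[len("group:") :].strip()
                continue
            raws.append(stripped)
        label = group_label or file_label or path.stem
    elif suffix == ".csv":
        reader = csv.reader(io.StringIO(text))
        try:
            header = next(reader)
        except StopIteration:
            raise ListFormatError(f"{path}: empty CSV file") from None
        if [h.strip().lower() for h in header] != ["name", "group"]:
            raise ListFormatError(
                f"{path}: expected CSV header 'name,group', got {header!r}"
            )
        raws, groups = [], set()
        for row in reader:
            if not row or not any(cell.strip() for cell in row):
                continue
            if len(row) != 2:
                raise ListFormatError(f"{path}: malformed CSV row {row!r}")
            raws.append(row[0].strip())
            groups.add(row[1].strip())
        if len(groups) > 1:
            raise ListFormatError(f"{path}: multiple groups in one file: {groups}")
        label = group_label or (groups.pop() if groups else None)
        if not label:
            raise ListFormatError(f"{path}: no group label in file or argument")
    else:
        raise ListFormatError(f"{path}: unknown list file extension {suffix!r}")
    if not raws:
        raise ListFormatError(f"{path}: file contains no surnames")
    return build_list(raws, label, provenance=(f"read from {path.name}",))


def write_list_file(surname_list: SurnameList, path: str | Path) -> None:
    """Write a surname list to ``.txt`` or ``.csv`` (round-trips with
    :func:`read_list_file`).  Names are written in sorted canonical form."""
    path = Path(path)
    suffix = path.suffix.lower()
    names = sorted(surname_list.names)
    if suffix == ".txt":
        lines = [f"# group: {surname_list.group_label}"]
        lines += [f"# {note}" for note in surname_list.provenance]
        lines += names
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif suffix == ".csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["name", "group"])
            for n in names:
                writer.writerow([n, surname_list.group_label])
    else:
        raise ListFormatError(f"{path}: unknown list file extension {suffix!r}")
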