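"""Selectivity classification by distinct-active-target count.

A tested compound is *inactive* when it hit no target, *black* when it is
active on exactly one target, *gray* on two to four, and *white* on more
than four.  The black/gray boundaries are configurable; the defaults (1, 4)
were chosen to split a large screening library into comparably sized
classes.  Compounds with no activity evidence at all are *unclassified* and
excluded from class statistics.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from polyprofile.chemio import ActivityRecord, CompoundRecord, resolve_activities

logger = logging.getLogger(__name__)


class SelectivityClass(str, Enum):
    INACTIVE = "inactive"
    BLACK = "black"
    GRAY = "gray"
    WHITE = "white"
    UNCLASSIFIED = "unclassified"


#: The four classes that partition the tested library.
CLASS_ORDER = (
    SelectivityClass.INACTIVE,
    SelectivityClass.BLACK,
    SelectivityClass.GRAY,
    SelectivityClass.WHITE,
)


@dataclass(frozen=True)
class ClassThresholds:
    """Upper bounds of the black and gray classes (inclusive)."""

    black_max: int = 1
    gray_max: int = 4

    def __post_init__(self) -> None:
        if not 1 <= self.black_max < self.gray_max:
            raise ValueError(
                f"require 1 <= black_max < gray_max, got ({self.black_max}, {self.gray_max})"
            )


def active_target_counts(activities: Sequence[ActivityRecord]) -> dict[str, int]:
    """Distinct active targets per compound, over resolved records."""
    targets: dict[str, set[str]] = {}
    for rec in resolve_activities(activities):
        if rec.outcome == "active":
            targets.setdefault(rec.compound_id, set()).add(rec.target_id)
    return {cid: len(ts) for cid, ts in targets.items()}


def count_active_targets(
    compound_id: str, activities: Sequence[ActivityRecord]
) -> int:
    """Number of distinct targets on which ``compound_id`` is active."""
    return active_target_counts(activities).get(compound_id, 0)


def classify(
    n_active_targets: int,
    was_tested: bool = True,
    thresholds: ClassThresholds = ClassThresholds(),
) -> SelectivityClass:
    """Map a distinct-active-target count to a selectivity class."""
    if n_active_targets < 0:
        raise ValueError("negative target count")
    if n_active_targets == 0:
        return SelectivityClass.INACTIVE if was_tested else SelectivityClass.UNCLASSIFIED
    if n_active_targets <= thresholds.black_max:
        return SelectivityClass.BLACK
    if n_active_targets <= thresholds.gray_max:
        return SelectivityClass.GRAY
    return SelectivityClass.WHITE


def classify_library(
    compounds: Iterable[CompoundRecord | str],
    activities: Sequence[ActivityRecord],
    thresholds: ClassThresholds = ClassThresholds(),
    tested_tags: frozenset[str] = frozenset({"dcm"}),
) -> dict[str, SelectivityClass]:
    """Classify every compound in a library.

    A compound counts as tested when it has at least one activity record of
    any outcome, or when its source tag marks it as a member of a panel of
    compounds known to have been screened (e.g. a dark-chemical-matter list,
    tag ``"dcm"``).
    """
    counts = active_target_counts(activities)
    tested_ids = {rec.compound_id for rec in activities}

    result: dict[str, SelectivityClass] = {}
    for comp in compounds:
        if isinstance(comp, str):
            cid, tag = comp, ""
        else:
            cid, tag = comp.compound_id, comp.source_tag
        tested = cid in tested_ids or tag in tested_tags
        result[cid] = classify(counts.get(cid, 0), tested, thresholds)

    summary = Counter(c.value for c in result.values())
    logger.info("class sizes: %s", dict(summary))
    return result


def class_sizes(
    classification: Mapping[str, SelectivityClass],
) -> dict[SelectivityClass, int]:
    """Sizes of the four classes (unclassified compounds excluded)."""
    counter = Counter(classification.values())
    return {cls: counter.get(cls, 0) for cls in CLASS_ORDER}
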