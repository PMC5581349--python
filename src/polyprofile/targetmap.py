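"""Target-family assignment and cross-family polypharmacology statistics.

Targets are mapped to protein superfamilies (GPCR, kinase, protease,
ion_channel, other) from user-supplied accession catalogs.  Family ligand
sets — compounds active on at least one member — support three summaries:
family composition of the target space, per-family selectivity-class
distributions, and the off-target overlap report (how often ligands of one
family also hit another).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from polyprofile.chemio import ActivityRecord, FamilyCatalog, resolve_activities
from polyprofile.selectivity import CLASS_ORDER, SelectivityClass

logger = logging.getLogger(__name__)

#: Priority used to resolve targets present in more than one catalog.
DEFAULT_PRIORITY = ("GPCR", "kinase", "protease", "ion_channel")

OTHER = "other"

#: Off-target histogram bins (matching pie-chart granularity: 0..4 and >4).
OFFTARGET_BINS = ("0", "1", "2", "3", "4", ">4")


@dataclass
class FamilyAssignment:
    """Primary family label per accession, plus multi-membership records."""

    primary: dict[str, str] = field(default_factory=dict)
    multi: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def label(self, accession: str) -> str:
        return self.primary.get(accession, OTHER)


def assign_families(
    targets: Sequence[str] | set[str],
    catalog: FamilyCatalog,
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> FamilyAssignment:
    """Assign each target accession a primary family label.

    An accession found in several catalogs takes the highest-priority family
    as its primary label, with full membership recorded in ``multi``; one
    found in no catalog is labeled ``other``.
    """
    assignment = FamilyAssignment()
    order = list(priority) + [f for f in catalog.families if f not in priority]
    for acc in targets:
        memberships = tuple(f for f in order if acc in catalog.families.get(f, ()))
        if not memberships:
            assignment.primary[acc] = OTHER
        else:
            assignment.primary[acc] = memberships[0]
            if len(memberships) > 1:
                assignment.multi[acc] = memberships
    if assignment.multi:
        logger.info("%d targets belong to more than one family catalog", len(assignment.multi))
    return assignment


def family_composition(assignment: FamilyAssignment) -> dict[str, float]:
    """Percentage of distinct targets per family label (sums to 100)."""
    if not assignment.primary:
        raise ValueError("no targets assigned")
    counts = Counter(assignment.primary.values())
    total = sum(counts.values())
    labels = list(DEFAULT_PRIORITY) + [OTHER]
    return {f: 100.0 * counts.get(f, 0) / total for f in labels}


def _active_targets_by_compound(
    activities: Sequence[ActivityRecord],
) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for rec in resolve_activities(activities):
        if rec.outcome == "active":
            out.setdefault(rec.compound_id, set()).add(rec.target_id)
    return out


def family_ligands(
    activities: Sequence[ActivityRecord],
    assignment: FamilyAssignment,
) -> dict[str, set[str]]:
    """Compounds active on >= 1 member of each family (active records only)."""
    ligands: dict[str, set[str]] = {f: set() for f in DEFAULT_PRIORITY}
    ligands[OTHER] = set()
    for cid, targets in _active_targets_by_compound(activities).items():
        for t in targets:
            ligands.setdefault(assignment.label(t), set()).add(cid)
    return ligands


def class_distribution_by_family(
    classes: Mapping[str, SelectivityClass],
    assignment: FamilyAssignment,
    activities: Sequence[ActivityRecord],
    families: Sequence[str] = DEFAULT_PRIORITY,
) -> pd.DataFrame:
    """Per-family selectivity-class percentages.

    A ligand is counted in every family it hits, so rows are computed over
    overlapping ligand sets.  Families without ligands give a null row.
    """
    ligands = family_ligands(activities, assignment)
    class_labels = [c.value for c in CLASS_ORDER if c != SelectivityClass.INACTIVE]
    rows = {}
    for fam in families:
        members = ligands.get(fam, set())
        if not members:
            logger.warning("family %s has no ligands", fam)
            rows[fam] = [float("nan")] * len(class_labels)
            continue
        counts = Counter(
            classes[cid].value for cid in members if cid in classes
        )
        n = sum(counts.get(c, 0) for c in class_labels)
        rows[fam] = [100.0 * counts.get(c, 0) / n if n else float("nan") for c in class_labels]
    return pd.DataFrame.from_dict(rows, orient="index", columns=class_labels)


@dataclass
class LigandOverlap:
    """Per-ligand hit split for one family: inside vs outside the family."""

    compound_id: str
    intra_family_hits: int
    off_target_hits: int


@dataclass
class OverlapReport:
    """Cross-family promiscuity statistics.

    ``ligand_overlaps[F]`` holds, for every ligand of family F, the count of
    its active targets inside F (>= 1 by construction) and outside F.
    ``cross_fraction[(F, G)]`` is the fraction of F ligands active on at
    least one member of G; the diagonal is 1 for any non-empty family.
    """

    ligand_overlaps: dict[str, list[LigandOverlap]] = field(default_factory=dict)
    cross_fraction: dict[tuple[str, str], float | None] = field(default_factory=dict)

    def off_target_histogram(self, family: str) -> dict[str, int]:
        return _binned_histogram(
            [o.off_target_hits for o in self.ligand_overlaps.get(family, [])]
        )

    def intra_family_histogram(self, family: str) -> dict[str, int]:
        return _binned_histogram(
            [o.intra_family_hits for o in self.ligand_overlaps.get(family, [])]
        )

    def to_frame(self) -> pd.DataFrame:
        """Flat one-row-per-family-pair view of the cross fractions."""
        rows = [
            {"family": f, "other_family": g, "cross_fraction": v}
            for (f, g), v in sorted(self.cross_fraction.items())
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "families": {
                fam: {
                    "n_ligands": len(overlaps),
                    "off_target_histogram": self.off_target_histogram(fam),
                    "intra_family_histogram": self.intra_family_histogram(fam),
                }
                for fam, overlaps in self.ligand_overlaps.items()
            },
            "cross_fraction": {
                f"{f}->{g}": v for (f, g), v in sorted(self.cross_fraction.items())
            },
        }


def _binned_histogram(values: Sequence[int]) -> dict[str, int]:
    hist = {b: 0 for b in OFFTARGET_BINS}
    for v in values:
        hist[str(v) if v <= 4 else ">4"] += 1
    return hist


def overlap_report(
    activities: Sequence[ActivityRecord],
    assignment: FamilyAssignment,
    families: Sequence[str] = DEFAULT_PRIORITY,
) -> OverlapReport:
    """Compute the full per-family overlap report.

    For every ligand of family F the report splits its distinct active
    targets into intra-family and off-target hits, and for every ordered
    family pair (F, G) records the fraction of F ligands that also hit G.
    """
    by_compound = _active_targets_by_compound(activities)
    report = OverlapReport()
    fam_ligands = family_ligands(activities, assignment)
    for fam in families:
        members = sorted(fam_ligands.get(fam, set()))
        overlaps = []
        for cid in members:
            targets = by_compound[cid]
            intra = sum(1 for t in targets if assignment.label(t) == fam)
            overlaps.append(LigandOverlap(cid, intra, len(targets) - intra))
        report.ligand_overlaps[fam] = overlaps
        for other in families:
            if not members:
                logger.warning("family %s has no ligands; cross fractions are null", fam)
                report.cross_fraction[(fam, other)] = None
                continue
            n_cross = sum(
                1
                for cid in members
                if any(assignment.label(t) == other for t in by_compound[cid])
            )
            report.cross_fraction[(fam, other)] = n_cross / len(members)
    return report


def cross_family_fraction(
    family: str,
    other_family: str,
    activities: Sequence[ActivityRecord],
    assignment: FamilyAssignment,
) -> float | None:
    """Fraction of ``family`` ligands active on >= 1 ``other_family`` member."""
    report = overlap_report(activities, assignment, families=(family, other_family))
    return report.cross_fraction[(family, other_family)]
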