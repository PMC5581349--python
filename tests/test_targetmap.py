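"""Family assignment, composition, class mix per family, overlap report."""

from __future__ import annotations

import numpy as np
import pytest

from polyprofile.chemio import ActivityRecord, FamilyCatalog
from polyprofile.selectivity import classify_library
from polyprofile.synthgen import SimConfig, generate_dataset
from polyprofile.targetmap import (
    assign_families,
    class_distribution_by_family,
    cross_family_fraction,
    family_composition,
    family_ligands,
    overlap_report,
)

from conftest import make_activities


@pytest.fixture()
def catalog() -> FamilyCatalog:
    return FamilyCatalog(
        families={
            "GPCR": {"G1", "G2"},
            "kinase": {"K1", "K2", "X1"},
            "protease": {"P1", "X1"},  # X1 is in two catalogs
            "ion_channel": {"I1"},
        }
    )


class TestAssignFamilies:
    def test_single_membership(self, catalog):
        a = assign_families(["G1", "K1"], catalog)
        assert a.label("G1") == "GPCR" and a.label("K1") == "kinase"

    def test_unknown_is_other(self, catalog):
        assert assign_families(["Z9"], catalog).label("Z9") == "other"

    def test_multi_membership_resolved_by_priority(self, catalog):
        a = assign_families(["X1"], catalog)
        assert a.label("X1") == "kinase"  # kinase before protease in priority
        assert a.multi["X1"] == ("kinase", "protease")

    def test_custom_priority(self, catalog):
        a = assign_families(["X1"], catalog, priority=("protease", "kinase"))
        assert a.label("X1") == "protease"


class TestFamilyComposition:
    def test_simple_percentages(self, catalog):
        comp = family_composition(assign_families(["G1", "G2", "K1", "Z9"], catalog))
        assert comp == {
            "GPCR": 50.0, "kinase": 25.0, "protease": 0.0,
            "ion_channel": 0.0, "other": 25.0,
        }

    def test_all_other(self, catalog):
        comp = family_composition(assign_families(["Z1", "Z2"], catalog))
        assert comp["other"] == 100.0

    def test_sums_to_100(self, catalog):
        rng = np.random.default_rng(0)
        targets = [f"T{i}" for i in range(200)] + ["G1", "K1", "P1", "I1"]
        comp = family_composition(assign_families(targets, catalog))
        assert sum(comp.values()) == pytest.approx(100.0, abs=1e-9)


def _hand_fixture(catalog):
    """Six ligands with hand-enumerable intra/off-target counts."""
    acts = make_activities(
        {
            "a": {"G1": "active", "G2": "active"},              # GPCR intra 2, off 0
            "b": {"G1": "active", "K1": "active"},              # GPCR intra 1, off 1
            "c": {"K1": "active", "K2": "active", "P1": "active",
                  "I1": "active", "G1": "active", "T9": "active"},
            "d": {"P1": "active"},
            "e": {"I1": "active", "T9": "active"},
            "f": {"G2": "inactive", "K1": "active"},            # inactive != membership
        }
    )
    assignment = assign_families(
        {r.target_id for r in acts}, catalog
    )
    return acts, assignment


class TestOverlapReport:
    def test_hand_enumerated_histograms(self, catalog):
        acts, assignment = _hand_fixture(catalog)
        report = overlap_report(acts, assignment)
        ligs = {o.compound_id: o for o in report.ligand_overlaps["GPCR"]}
        assert set(ligs) == {"a", "b", "c"}
        assert (ligs["a"].intra_family_hits, ligs["a"].off_target_hits) == (2, 0)
        assert (ligs["b"].intra_family_hits, ligs["b"].off_target_hits) == (1, 1)
        assert (ligs["c"].intra_family_hits, ligs["c"].off_target_hits) == (1, 5)
        hist = report.off_target_histogram("GPCR")
        assert hist == {"0": 1, "1": 1, "2": 0, "3": 0, "4": 0, ">4": 1}
        assert report.intra_family_histogram("GPCR") == {
            "0": 0, "1": 2, "2": 1, "3": 0, "4": 0, ">4": 0,
        }

    def test_intra_at_least_one_and_sum_identity(self, catalog):
        acts, assignment = _hand_fixture(catalog)
        report = overlap_report(acts, assignment)
        totals = {}
        for rec in acts:
            if rec.outcome == "active":
                totals.setdefault(rec.compound_id, set()).add(rec.target_id)
        for fam, overlaps in report.ligand_overlaps.items():
            for o in overlaps:
                assert o.intra_family_hits >= 1
                assert o.intra_family_hits + o.off_target_hits == len(totals[o.compound_id])

    def test_diagonal_cross_fraction_is_one(self, catalog):
        acts, assignment = _hand_fixture(catalog)
        report = overlap_report(acts, assignment)
        for fam in ("GPCR", "kinase", "protease", "ion_channel"):
            assert report.cross_fraction[(fam, fam)] == 1.0

    def test_cross_fraction_hand_values(self, catalog):
        acts, assignment = _hand_fixture(catalog)
        # GPCR ligands {a,b,c}; b and c also hit kinases -> 2/3
        assert cross_family_fraction("GPCR", "kinase", acts, assignment) == pytest.approx(2 / 3)
        # protease ligands {c,d}; only c hits a GPCR -> 1/2
        assert cross_family_fraction("protease", "GPCR", acts, assignment) == pytest.approx(0.5)

    def test_zero_cross_fraction(self, catalog):
        acts = make_activities({"d": {"P1": "active"}})
        assignment = assign_families({"P1"}, catalog)
        assert cross_family_fraction("protease", "GPCR", acts, assignment) == 0.0

    def test_empty_family_is_null(self, catalog):
        acts = make_activities({"d": {"P1": "active"}})
        assignment = assign_families({"P1"}, catalog)
        report = overlap_report(acts, assignment, families=("GPCR", "protease"))
        assert report.cross_fraction[("GPCR", "protease")] is None

    def test_matrix_consistent_with_per_ligand_report(self, catalog):
        """Cross fractions recomputed from the per-ligand overlaps agree."""
        dataset = generate_dataset(SimConfig(n_compounds=400, seed=19))
        targets = {r.target_id for r in dataset.activities}
        assignment = assign_families(targets, dataset.catalog)
        report = overlap_report(dataset.activities, assignment)
        ligands = family_ligands(dataset.activities, assignment)
        by_compound = {}
        for rec in dataset.activities:
            if rec.outcome == "active":
                by_compound.setdefault(rec.compound_id, set()).add(rec.target_id)
        for (f, g), frac in report.cross_fraction.items():
            members = ligands.get(f, set())
            if not members:
                assert frac is None
                continue
            recomputed = sum(
                1 for cid in members
                if any(assignment.label(t) == g for t in by_compound[cid])
            ) / len(members)
            assert frac == pytest.approx(recomputed)


class TestClassDistributionByFamily:
    def test_two_ligand_family(self, catalog):
        acts = make_activities(
            {
                "solo": {"G1": "active"},
                "promiscuous": {"G2": "active", "K1": "active", "K2": "active",
                                 "P1": "active", "I1": "active", "T9": "active"},
            }
        )
        assignment = assign_families({r.target_id for r in acts}, catalog)
        classes = classify_library(["solo", "promiscuous"], acts)
        table = class_distribution_by_family(classes, assignment, acts)
        assert table.loc["GPCR", "black"] == pytest.approx(50.0)
        assert table.loc["GPCR", "white"] == pytest.approx(50.0)
        assert table.loc["GPCR", "gray"] == pytest.approx(0.0)

    def test_ligand_counted_in_every_family_it_hits(self, catalog):
        acts = make_activities({"both": {"G1": "active", "K1": "active"}})
        assignment = assign_families({"G1", "K1"}, catalog)
        classes = classify_library(["both"], acts)
        table = class_distribution_by_family(classes, assignment, acts)
        assert table.loc["GPCR", "gray"] == 100.0
        assert table.loc["kinase", "gray"] == 100.0

    def test_family_without_ligands_is_null_row(self, catalog):
        acts = make_activities({"solo": {"G1": "active"}})
        assignment = assign_families({"G1"}, catalog)
        classes = classify_library(["solo"], acts)
        table = class_distribution_by_family(classes, assignment, acts)
        assert table.loc["protease"].isna().all()
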