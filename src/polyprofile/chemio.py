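"""Structure, activity-table and family-catalog I/O.

Compounds are identified chemically by an isomeric canonical SMILES key, so
deduplication is invariant to atom ordering and SMILES dialect while still
distinguishing defined stereoisomers.  Salts and mixtures are reduced to the
largest covalent fragment before keying — the usual convention for
screening-library data.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

# RDKit is chatty about every parse failure; we log rejections ourselves.
RDLogger.DisableLog("rdApp.error")

FAMILY_NAMES = ("GPCR", "kinase", "protease", "ion_channel")


class StructureError(ValueError):
    """Raised when a structure cannot be parsed or is otherwise invalid."""


@dataclass(frozen=True)
class CompoundRecord:
    """One molecule: identifier, structure text and canonical chemical key."""

    compound_id: str
    structure: str
    canonical_key: str
    source_tag: str = ""


@dataclass(frozen=True)
class ActivityRecord:
    """One (compound, target, outcome) bioactivity assertion."""

    compound_id: str
    target_id: str
    outcome: str  # "active" | "inactive"


@dataclass
class FamilyCatalog:
    """Mapping from target-family name to its set of accessions.

    Accession sets may overlap between families; resolution of multi-family
    targets happens downstream, in family assignment.
    """

    families: dict[str, set[str]] = field(default_factory=dict)

    def family_of(self, accession: str) -> list[str]:
        return [f for f, accs in self.families.items() if accession in accs]


def _mol_from_smiles(structure: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise StructureError(f"unparseable SMILES: {structure!r}")
    return mol


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol
    return max(frags, key=lambda m: m.GetNumHeavyAtoms())


def canonical_key(structure: str) -> str:
    """Isomeric canonical SMILES of the largest covalent fragment.

    Deterministic, invariant to atom ordering and kekulization of the input,
    and stereo-aware: enantiomers with specified parity get distinct keys.

    Raises
    ------
    StructureError
        If the SMILES does not parse.
    """
    mol = _largest_fragment(_mol_from_smiles(structure))
    return Chem.MolToSmiles(mol)


def read_structures(
    path: str | Path,
    fmt: str | None = None,
    sdf_id_property: str = "_Name",
) -> list[CompoundRecord]:
    """Read a SMILES (.smi, one ``SMILES<ws>ID`` per line) or SDF file.

    Unparseable entries are counted and logged, never fatal; an input with
    zero parseable entries is an error, as is a missing file.

    Parameters
    ----------
    fmt:
        "smi" or "sdf"; inferred from the suffix when omitted.
    sdf_id_property:
        SDF property used for the compound id when the title line is empty.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "sdf" if path.suffix.lower() == ".sdf" else "smi"
    if fmt not in ("smi", "sdf"):
        raise ValueError(f"unknown structure format: {fmt!r}")

    records: list[CompoundRecord] = []
    n_rejected = 0
    if fmt == "smi":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            cid = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
            try:
                key = canonical_key(smiles)
            except StructureError:
                n_rejected += 1
                logger.warning("rejected line %d of %s: unparseable %r", lineno, path, smiles)
                continue
            records.append(CompoundRecord(cid, smiles, key))
    else:
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                n_rejected += 1
                logger.warning("rejected SDF entry %d of %s: unparseable", i, path)
                continue
            cid = mol.GetProp("_Name") if mol.GetProp("_Name") else ""
            if not cid and sdf_id_property != "_Name" and mol.HasProp(sdf_id_property):
                cid = mol.GetProp(sdf_id_property)
            if not cid:
                cid = f"mol{i + 1}"
            smiles = Chem.MolToSmiles(mol)
            records.append(
                CompoundRecord(cid, smiles, Chem.MolToSmiles(_largest_fragment(mol)))
            )
    if n_rejected:
        logger.info("%s: %d entries rejected as unparseable", path, n_rejected)
    if not records:
        raise StructureError(f"no parseable structures in {path}")
    _check_id_collisions(records)
    return records


def _check_id_collisions(records: Iterable[CompoundRecord]) -> None:
    seen: dict[str, str] = {}
    for rec in records:
        prev = seen.setdefault(rec.compound_id, rec.canonical_key)
        if prev != rec.canonical_key:
            raise ValueError(
                f"compound_id {rec.compound_id!r} maps to two different structures"
            )


def deduplicate(
    records: Sequence[CompoundRecord],
) -> tuple[list[CompoundRecord], int]:
    """Keep the first record per canonical key, preserving input order.

    Returns the kept records and the number removed.  Idempotent.
    """
    seen: set[str] = set()
    kept: list[CompoundRecord] = []
    for rec in records:
        if rec.canonical_key in seen:
            continue
        seen.add(rec.canonical_key)
        kept.append(rec)
    n_removed = len(records) - len(kept)
    if n_removed:
        logger.info("deduplicate: removed %d duplicate structures", n_removed)
    return kept, n_removed


_MISSING_TARGET = {"", "-", "na", "n/a", "none", "null"}


def _has_target(target_id: str) -> bool:
    return target_id.strip().lower() not in _MISSING_TARGET


def filter_untargeted_actives(
    compounds: Sequence[CompoundRecord],
    activities: Sequence[ActivityRecord],
) -> tuple[list[CompoundRecord], int]:
    """Drop compounds that are active but only on unspecified targets.

    A compound is removed when it has at least one active record and every
    one of its active records lacks a resolvable target accession.  Compounds
    with no activity records at all (untested) are kept, as are compounds
    with only inactive records.
    """
    active_targets: dict[str, list[str]] = {}
    for rec in activities:
        if rec.outcome == "active":
            active_targets.setdefault(rec.compound_id, []).append(rec.target_id)
    doomed = {
        cid
        for cid, targets in active_targets.items()
        if not any(_has_target(t) for t in targets)
    }
    kept = [c for c in compounds if c.compound_id not in doomed]
    n_removed = len(compounds) - len(kept)
    if n_removed:
        logger.info(
            "filter_untargeted_actives: removed %d active compounds without targets",
            n_removed,
        )
    return kept, n_removed


def load_activity_table(path: str | Path) -> list[ActivityRecord]:
    """Load a compound–target activity CSV.

    Expects columns ``compound_id,target_id,outcome``.  Outcomes are parsed
    case-insensitively; duplicate triples are collapsed; a (compound, target)
    pair carrying both outcomes resolves to active — any positive evidence
    counts the target as hit.  Malformed rows are logged and skipped.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"compound_id", "target_id", "outcome"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"{path}: activity table must have columns {sorted(required)}"
            )
        pair_outcome: dict[tuple[str, str], str] = {}
        order: list[tuple[str, str]] = []
        n_bad = 0
        for row in reader:
            cid = (row["compound_id"] or "").strip()
            tid = (row["target_id"] or "").strip()
            outcome = (row["outcome"] or "").strip().lower()
            if not cid or outcome not in ("active", "inactive"):
                n_bad += 1
                logger.warning("%s: skipping malformed row %r", path, row)
                continue
            pair = (cid, tid)
            if pair not in pair_outcome:
                order.append(pair)
                pair_outcome[pair] = outcome
            elif outcome == "active":
                pair_outcome[pair] = "active"
    if n_bad:
        logger.info("%s: %d malformed rows skipped", path, n_bad)
    return [ActivityRecord(cid, tid, pair_outcome[(cid, tid)]) for cid, tid in order]


def write_activity_table(path: str | Path, activities: Sequence[ActivityRecord]) -> None:
    """Write records in the same CSV dialect ``load_activity_table`` reads."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["compound_id", "target_id", "outcome"])
        for rec in activities:
            writer.writerow([rec.compound_id, rec.target_id, rec.outcome])


def resolve_activities(activities: Sequence[ActivityRecord]) -> list[ActivityRecord]:
    """Collapse duplicates and apply active-beats-inactive per pair in memory."""
    pair_outcome: dict[tuple[str, str], str] = {}
    order: list[tuple[str, str]] = []
    for rec in activities:
        pair = (rec.compound_id, rec.target_id)
        if pair not in pair_outcome:
            order.append(pair)
            pair_outcome[pair] = rec.outcome
        elif rec.outcome == "active":
            pair_outcome[pair] = "active"
    return [ActivityRecord(c, t, pair_outcome[(c, t)]) for c, t in order]


def load_family_catalogs(paths: Mapping[str, str | Path] | str | Path) -> FamilyCatalog:
    """Load per-family accession lists (one accession per line).

    Accepts either a directory (each ``*.txt`` file is a family named after
    the file stem) or an explicit mapping ``{family: path}``.
    """
    if isinstance(paths, (str, Path)):
        directory = Path(paths)
        if not directory.is_dir():
            raise FileNotFoundError(directory)
        paths = {p.stem: p for p in sorted(directory.glob("*.txt"))}
    catalog = FamilyCatalog()
    for family, path in paths.items():
        accs = {
            line.strip()
            for line in Path(path).read_text().splitlines()
            if line.strip() and not line.startswith("#")
        }
        catalog.families[family] = accs
    return catalog
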