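"""2D molecular descriptors linked to target selectivity.

The panel covers the structural features that separate selective from
promiscuous chemotypes: tetrahedral R/S stereocenters (defined and
undefined), non-aromatic C=C / C=N double bonds, non-ring non-terminal sp3
CH2 carbons ([CX4;H2;!R]), single vs fused aromatic and aliphatic ring
counts over the smallest ring basis, Lipinski hydrogen-bond donors and
acceptors, molecular weight, Wildman–Crippen atom-contribution logP (SlogP)
and an estimated aqueous solubility logS.

Conventions
-----------
* Implicit-hydrogen model throughout; explicit hydrogens are suppressed on
  input.
* Aromaticity is RDKit's default perception, applied after parsing, so a
  kekulized and an aromatic SMILES of the same molecule give identical
  values and aromatic bonds never count as C=C/C=N double bonds.
* "Fused" means sharing at least one bond with another basis ring; spiro
  rings (shared atom only) count as single.
* logS is the ESOL linear model (Delaney 2004, J Chem Inf Comput Sci 44:1000),
  log10 of the aqueous solubility in mol/L; the model is pluggable via
  ``LOGS_MODELS`` and the model name travels with every panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors as RDDescriptors, Lipinski
from rdkit.Chem.rdMolDescriptors import CalcNumRotatableBonds

from polyprofile.chemio import StructureError

logger = logging.getLogger(__name__)

_SP3_CHAIN_QUERY = Chem.MolFromSmarts("[CX4;H2;!R]")


def as_mol(structure: str | Chem.Mol) -> Chem.Mol:
    """Parse a SMILES (or pass through an already-parsed molecule)."""
    if isinstance(structure, Chem.Mol):
        return structure
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise StructureError(f"unparseable SMILES: {structure!r}")
    return mol


def _require_atoms(mol: Chem.Mol) -> None:
    if mol.GetNumAtoms() == 0:
        raise StructureError("empty molecule")


@dataclass(frozen=True)
class RingProfile:
    """Single/fused counts of aromatic and aliphatic basis rings."""

    single_aromatic: int = 0
    fused_aromatic: int = 0
    single_aliphatic: int = 0
    fused_aliphatic: int = 0

    @property
    def total(self) -> int:
        return (
            self.single_aromatic
            + self.fused_aromatic
            + self.single_aliphatic
            + self.fused_aliphatic
        )


@dataclass(frozen=True)
class DescriptorPanel:
    """Per-compound descriptor vector.

    A descriptor that could not be computed is ``None``, never silently zero.
    """

    n_stereo_defined: int | None
    n_stereo_undefined: int | None
    n_double_cc_cn: int | None
    n_sp3_chain_carbons: int | None
    rings: RingProfile | None
    hbd: int | None
    hba: int | None
    mw: float | None
    logp: float | None
    logs: float | None
    logs_model: str = "esol"

    def as_dict(self) -> dict[str, float | int | None]:
        rings = self.rings or RingProfile()
        return {
            "n_stereo_defined": self.n_stereo_defined,
            "n_stereo_undefined": self.n_stereo_undefined,
            "n_double_cc_cn": self.n_double_cc_cn,
            "n_sp3_chain_carbons": self.n_sp3_chain_carbons,
            "single_aromatic": rings.single_aromatic if self.rings else None,
            "fused_aromatic": rings.fused_aromatic if self.rings else None,
            "single_aliphatic": rings.single_aliphatic if self.rings else None,
            "fused_aliphatic": rings.fused_aliphatic if self.rings else None,
            "hbd": self.hbd,
            "hba": self.hba,
            "mw": self.mw,
            "logp": self.logp,
            "logs": self.logs,
        }


#: Fixed column order of batch descriptor output.
PANEL_COLUMNS = [
    "n_stereo_defined",
    "n_stereo_undefined",
    "n_double_cc_cn",
    "n_sp3_chain_carbons",
    "single_aromatic",
    "fused_aromatic",
    "single_aliphatic",
    "fused_aliphatic",
    "hbd",
    "hba",
    "mw",
    "logp",
    "logs",
]


def count_stereocenters(mol: str | Chem.Mol) -> tuple[int, int]:
    """Count (defined, undefined) tetrahedral R/S stereocenters.

    Defined centers have specified parity resolvable to R/S; undefined ones
    are potential tetrahedral stereocenters with no parity in the input.
    Double-bond E/Z stereogenicity is not counted here.
    """
    mol = as_mol(mol)
    defined = undefined = 0
    for si in Chem.FindPotentialStereo(mol):
        if si.type != Chem.StereoType.Atom_Tetrahedral:
            continue
        if si.specified == Chem.StereoSpecified.Specified:
            defined += 1
        elif si.specified == Chem.StereoSpecified.Unspecified:
            undefined += 1
    return defined, undefined


def count_double_cc_cn(mol: str | Chem.Mol) -> int:
    """Count non-aromatic double bonds between C–C or C–N atom pairs.

    C=O, N=N and triple bonds are excluded, as are bonds inside aromatic
    rings regardless of how the input SMILES was written.
    """
    mol = as_mol(mol)
    n = 0
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.DOUBLE or bond.GetIsAromatic():
            continue
        symbols = {bond.GetBeginAtom().GetSymbol(), bond.GetEndAtom().GetSymbol()}
        if symbols == {"C"} or symbols == {"C", "N"}:
            n += 1
    return n


def count_sp3_chain_carbons(mol: str | Chem.Mol) -> int:
    """Count non-ring, non-terminal sp3 carbons: SMARTS ``[CX4;H2;!R]``."""
    mol = as_mol(mol)
    return len(mol.GetSubstructMatches(_SP3_CHAIN_QUERY))


def ring_profile(mol: str | Chem.Mol) -> RingProfile:
    """Classify each smallest-ring-basis ring as single/fused, aromatic/aliphatic.

    A ring is aromatic when all of its bonds are aromatic, and fused when it
    shares at least one bond with another basis ring.  Counts are of
    individual rings, not ring systems; acyclic molecules give all zeros.
    """
    mol = as_mol(mol)
    bond_rings = [frozenset(r) for r in mol.GetRingInfo().BondRings()]
    profile = {"sa": 0, "fa": 0, "sl": 0, "fl": 0}
    for i, ring in enumerate(bond_rings):
        aromatic = all(mol.GetBondWithIdx(b).GetIsAromatic() for b in ring)
        fused = any(ring & other for j, other in enumerate(bond_rings) if j != i)
        key = ("f" if fused else "s") + ("a" if aromatic else "l")
        profile[key] += 1
    return RingProfile(
        single_aromatic=profile["sa"],
        fused_aromatic=profile["fa"],
        single_aliphatic=profile["sl"],
        fused_aliphatic=profile["fl"],
    )


def logp(mol: str | Chem.Mol) -> float:
    """Wildman–Crippen atom-contribution logP (the SlogP descriptor).

    Each atom is assigned a type from the published pattern hierarchy and the
    type contributions are summed, so the value is additive over disconnected
    fragments.
    """
    mol = as_mol(mol)
    _require_atoms(mol)
    return Crippen.MolLogP(mol)


def _logs_esol(mol: Chem.Mol) -> float:
    # ESOL: logS = 0.16 - 0.63 clogP - 0.0062 MW + 0.066 RB - 0.74 AP
    mw = RDDescriptors.MolWt(mol)
    rb = CalcNumRotatableBonds(mol)
    heavy = mol.GetNumHeavyAtoms()
    ap = sum(a.GetIsAromatic() for a in mol.GetAtoms()) / heavy if heavy else 0.0
    return 0.16 - 0.63 * Crippen.MolLogP(mol) - 0.0062 * mw + 0.066 * rb - 0.74 * ap


#: Registry of aqueous-solubility models; each maps a molecule to log10 mol/L.
LOGS_MODELS: dict[str, Callable[[Chem.Mol], float]] = {"esol": _logs_esol}


def logs(mol: str | Chem.Mol, model: str = "esol") -> float:
    """Estimated aqueous solubility, log10 mol/L, via a published model.

    The default is the ESOL linear model; alternatives can be registered in
    ``LOGS_MODELS``.
    """
    mol = as_mol(mol)
    _require_atoms(mol)
    try:
        fn = LOGS_MODELS[model]
    except KeyError:
        raise ValueError(f"unknown logS model {model!r}") from None
    return fn(mol)


def hbond_counts(mol: str | Chem.Mol) -> tuple[int, int]:
    """Lipinski hydrogen-bond counts: (donors, acceptors).

    Donors are N–H and O–H hydrogens; acceptors are all N and O atoms.
    """
    mol = as_mol(mol)
    return Lipinski.NHOHCount(mol), Lipinski.NOCount(mol)


def molecular_weight(mol: str | Chem.Mol) -> float:
    """Average-isotopic molecular weight in daltons, hydrogens included."""
    mol = as_mol(mol)
    return RDDescriptors.MolWt(mol)


def panel(structure: str | Chem.Mol, logs_model: str = "esol") -> DescriptorPanel:
    """Compute the full descriptor panel for one molecule.

    Individual descriptor failures are recorded as ``None`` with a logged
    reason; an unparseable structure is a panel-level error.
    """
    mol = as_mol(structure)
    mol = Chem.RemoveHs(mol)

    values: dict[str, object] = {}

    def attempt(name: str, fn: Callable[[], object]) -> None:
        try:
            values[name] = fn()
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("descriptor %s failed: %s", name, exc)
            values[name] = None

    attempt("stereo", lambda: count_stereocenters(mol))
    attempt("double", lambda: count_double_cc_cn(mol))
    attempt("sp3", lambda: count_sp3_chain_carbons(mol))
    attempt("rings", lambda: ring_profile(mol))
    attempt("hbond", lambda: hbond_counts(mol))
    attempt("mw", lambda: molecular_weight(mol))
    attempt("logp", lambda: logp(mol))
    attempt("logs", lambda: logs(mol, logs_model))

    stereo = values["stereo"]
    hbond = values["hbond"]
    return DescriptorPanel(
        n_stereo_defined=stereo[0] if stereo else None,
        n_stereo_undefined=stereo[1] if stereo else None,
        n_double_cc_cn=values["double"],
        n_sp3_chain_carbons=values["sp3"],
        rings=values["rings"],
        hbd=hbond[0] if hbond else None,
        hba=hbond[1] if hbond else None,
        mw=values["mw"],
        logp=values["logp"],
        logs=values["logs"],
        logs_model=logs_model,
    )


def panel_frame(
    structures: Iterable[tuple[str, str]] | Sequence,
    logs_model: str = "esol",
) -> pd.DataFrame:
    """Batch descriptor computation.

    Accepts ``(compound_id, smiles)`` pairs or ``CompoundRecord`` objects and
    returns a DataFrame indexed by compound_id with ``PANEL_COLUMNS`` columns
    (missing values as NaN/None).
    """
    rows = {}
    for item in structures:
        if hasattr(item, "compound_id"):
            cid, smiles = item.compound_id, item.structure
        else:
            cid, smiles = item
        rows[cid] = panel(smiles, logs_model=logs_model).as_dict()
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=PANEL_COLUMNS)
    frame.index.name = "compound_id"
    return frame
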