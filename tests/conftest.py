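from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem

from polyprofile.chemio import ActivityRecord
from polyprofile.synthgen import SimConfig, generate_structures

# Curated edge cases exercising every branch of the counting descriptors.
CURATED_SMILES = [
    "C",                    # methane
    "CCO",                  # ethanol
    "CCCC",                 # n-butane
    "CC(C)(C)C",            # neopentane
    "C=CC=C",               # 1,3-butadiene
    "CC(=O)C",              # acetone
    "CC(=O)N",              # acetamide
    "C[C@@H](N)C(=O)O",     # L-alanine
    "C[C@H](N)C(=O)O",      # D-alanine
    "CC(F)Cl",              # undefined stereocenter
    "c1ccccc1",             # benzene
    "C1=CC=CC=C1",          # benzene, kekulized
    "c1ccncc1",             # pyridine
    "c1ccc2ccccc2c1",       # naphthalene
    "c1ccc(-c2ccccc2)cc1",  # biphenyl (no fusion)
    "C1CCCCC1",             # cyclohexane
    "C1CCC2CCCCC2C1",       # decalin
    "C1CCC2(CC1)CCCC2",     # spiro (shared atom only)
    "C1=CCCCC1",            # cyclohexene (aliphatic ring w/ double bond)
    "O",                    # water
    "N#Cc1ccccc1",          # benzonitrile (triple bond excluded)
    "N=Nc1ccccc1",          # azo (N=N excluded)
    "CC(CCc1ccccc1)C(=O)NCCCN1CCC(O)CC1",  # worked-example stand-in
]


@pytest.fixture(scope="session")
def fixture_smiles() -> list[str]:
    """~100 diverse SMILES: curated edge cases plus generated structures."""
    config = SimConfig(n_compounds=90, seed=421)
    records, _ = generate_structures(config, np.random.default_rng(421))
    return CURATED_SMILES + [r.structure for r in records]


@pytest.fixture(scope="session")
def fixture_mols(fixture_smiles) -> list[Chem.Mol]:
    return [Chem.MolFromSmiles(s) for s in fixture_smiles]


def make_activities(spec: dict[str, dict[str, str]]) -> list[ActivityRecord]:
    """Build records from {compound: {target: outcome}}."""
    return [
        ActivityRecord(cid, tid, outcome)
        for cid, targets in spec.items()
        for tid, outcome in targets.items()
    ]
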