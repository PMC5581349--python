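"""Synthetic stand-in for the selective-GPCR-ligand worked example.

``SELECTIVE_GPCR_STANDIN`` is a synthetic molecule constructed to carry the
structural signature of a prototypical black (single-target) GPCR ligand:
one tetrahedral stereocenter left configurationally undefined, one
aliphatic ring, exactly five non-ring non-terminal sp3 CH2 carbons, an
aromatic ring joined to a basic-nitrogen-bearing ring by an alkyl chain,
and a moderate lipophilicity (Wildman–Crippen logP ~ 2.2).  It is not a
structure retrieved from any compound database.
"""

from __future__ import annotations

from polyprofile.descriptors import DescriptorPanel, panel

#: 2-methyl-4-phenyl-N-[3-(4-hydroxypiperidin-1-yl)propyl]butanamide.
SELECTIVE_GPCR_STANDIN = "CC(CCc1ccccc1)C(=O)NCCCN1CCC(O)CC1"


def standin_panel() -> DescriptorPanel:
    """Descriptor panel of the stand-in, computed from its structure."""
    return panel(SELECTIVE_GPCR_STANDIN)
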