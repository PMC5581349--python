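"""Independent brute-force oracles for the counting descriptors.

These deliberately avoid the code paths the package uses (SMARTS matching,
RDKit ring info, RDKit stereo perception, Lipinski SMARTS): rings come from
a networkx minimum cycle basis over the bond graph, double bonds are read
out of a V2000 ctab text block, stereocenters from Weisfeiler–Lehman
refinement of the molecular graph plus the input parity tags, and H-bond
counts from plain atom enumeration.  RDKit is used only to parse the SMILES
and expose atoms/bonds.
"""

from __future__ import annotations

import networkx as nx
from rdkit import Chem


def _graph(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(atom.GetIdx())
    for bond in mol.GetBonds():
        g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
    return g


def ring_basis_bonds(mol: Chem.Mol) -> list[frozenset[tuple[int, int]]]:
    """Smallest-ring-basis rings as bond (edge) sets, via networkx."""
    g = _graph(mol)
    rings = []
    for nodes in nx.minimum_cycle_basis(g):
        sub = g.subgraph(nodes)
        edges = frozenset(frozenset(e) for e in sub.edges)
        # a basis ring's induced subgraph is the cycle itself for the
        # fixture chemotypes used here
        assert len(edges) == len(nodes), f"chorded cycle {nodes}"
        rings.append(edges)
    return rings


def ring_profile_oracle(mol: Chem.Mol) -> tuple[int, int, int, int]:
    """(single_aromatic, fused_aromatic, single_aliphatic, fused_aliphatic)."""
    aromatic_edges = {
        frozenset((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        for b in mol.GetBonds()
        if b.GetIsAromatic()
    }
    rings = ring_basis_bonds(mol)
    sa = fa = sl = fl = 0
    for i, ring in enumerate(rings):
        aromatic = ring <= aromatic_edges
        fused = any(ring & other for j, other in enumerate(rings) if j != i)
        if aromatic:
            fa, sa = (fa + 1, sa) if fused else (fa, sa + 1)
        else:
            fl, sl = (fl + 1, sl) if fused else (fl, sl + 1)
    return sa, fa, sl, fl


def double_cc_cn_oracle(mol: Chem.Mol) -> int:
    """Count C=C / C=N double bonds by parsing a V2000 ctab text block."""
    block = Chem.MolToMolBlock(mol, kekulize=False)
    lines = block.splitlines()
    n_atoms = int(lines[3][0:3])
    n_bonds = int(lines[3][3:6])
    symbols = [lines[4 + i][31:34].strip() for i in range(n_atoms)]
    n = 0
    for i in range(n_bonds):
        line = lines[4 + n_atoms + i]
        a = int(line[0:3]) - 1
        b = int(line[3:6]) - 1
        order = int(line[6:9])
        if order == 2 and {symbols[a], symbols[b]} in ({"C"}, {"C", "N"}):
            n += 1
    return n


def _ring_atoms(mol: Chem.Mol) -> set[int]:
    atoms: set[int] = set()
    for nodes in nx.cycle_basis(_graph(mol)):
        atoms.update(nodes)
    return atoms


def sp3_chain_oracle(mol: Chem.Mol) -> int:
    """Atom-by-atom enumeration of [CX4;H2;!R] carbons."""
    ring_atoms = _ring_atoms(mol)
    n = 0
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "C" or atom.GetIdx() in ring_atoms:
            continue
        if atom.GetTotalNumHs() != 2:
            continue
        bonds = atom.GetBonds()
        if atom.GetDegree() + atom.GetTotalNumHs() != 4:
            continue
        if any(b.GetBondTypeAsDouble() != 1.0 for b in bonds):
            continue
        n += 1
    return n


def _wl_colors(mol: Chem.Mol, rounds: int = 12) -> dict[int, int]:
    """Stable Weisfeiler–Lehman atom colors of the molecular graph."""
    colors = {
        a.GetIdx(): hash(
            (
                a.GetSymbol(),
                a.GetFormalCharge(),
                a.GetDegree(),
                a.GetTotalNumHs(),
                a.GetIsAromatic(),
            )
        )
        for a in mol.GetAtoms()
    }
    adj = {
        a.GetIdx(): [
            (n.GetIdx(), mol.GetBondBetweenAtoms(a.GetIdx(), n.GetIdx()).GetBondTypeAsDouble())
            for n in a.GetNeighbors()
        ]
        for a in mol.GetAtoms()
    }
    for _ in range(rounds):
        colors = {
            idx: hash((colors[idx], tuple(sorted((colors[j], order) for j, order in neigh))))
            for idx, neigh in adj.items()
        }
    return colors


def stereocenter_oracle(mol: Chem.Mol) -> tuple[int, int]:
    """(defined, undefined) tetrahedral stereocenters by WL symmetry.

    A carbon with four substituents (heavy neighbors plus implicit
    hydrogens), at most one hydrogen and only single bonds is a *constitutive*
    stereocenter when all heavy-neighbor WL colors are pairwise distinct.  A
    ring atom whose only violation is a single WL-equivalent pair of ring
    neighbors is a *dependent* ring-stereocenter candidate (cis/trans ring
    isomerism): it counts when another candidate or constitutive center lies
    in the same ring system.  A center is defined when the input SMILES
    carried a parity tag for it.
    """
    colors = _wl_colors(mol)
    ring_atoms = _ring_atoms(mol)
    g = _graph(mol)
    constitutive: list[int] = []
    candidates: list[int] = []
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "C":
            continue
        n_h = atom.GetTotalNumHs()
        if atom.GetDegree() + n_h != 4 or n_h > 1:
            continue
        if any(b.GetBondTypeAsDouble() != 1.0 for b in atom.GetBonds()):
            continue
        neigh = list(atom.GetNeighbors())
        neigh_colors = [colors[n.GetIdx()] for n in neigh]
        if len(set(neigh_colors)) == len(neigh_colors):
            constitutive.append(atom.GetIdx())
        elif len(set(neigh_colors)) == len(neigh_colors) - 1 and atom.GetIdx() in ring_atoms:
            dup = [c for c in neigh_colors if neigh_colors.count(c) == 2]
            pair = [n for n in neigh if colors[n.GetIdx()] == dup[0]]
            if all(n.GetIdx() in ring_atoms for n in pair):
                candidates.append(atom.GetIdx())

    # ring-system membership via ring *bonds* only (a plain bond between two
    # ring atoms, as in biphenyl, must not merge the systems)
    ring_bond_graph = nx.Graph()
    ring_bond_graph.add_nodes_from(ring_atoms)
    for cycle in nx.cycle_basis(g):
        closed = cycle + [cycle[0]]
        ring_bond_graph.add_edges_from(zip(closed, closed[1:]))
    systems = list(nx.connected_components(ring_bond_graph))

    def system_of(idx: int) -> frozenset[int] | None:
        for s in systems:
            if idx in s:
                return frozenset(s)
        return None

    accepted = set(constitutive)
    for idx in candidates:
        system = system_of(idx)
        if any(
            other != idx and system_of(other) == system
            for other in candidates + constitutive
        ):
            accepted.add(idx)

    defined = undefined = 0
    for idx in accepted:
        if mol.GetAtomWithIdx(idx).GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED:
            defined += 1
        else:
            undefined += 1
    return defined, undefined


def hbond_oracle(mol: Chem.Mol) -> tuple[int, int]:
    """(donor hydrogens on N/O, count of N and O atoms) by atom enumeration."""
    hbd = hba = 0
    for atom in mol.GetAtoms():
        if atom.GetSymbol() in ("N", "O"):
            hba += 1
            hbd += atom.GetTotalNumHs()
    return hbd, hba
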