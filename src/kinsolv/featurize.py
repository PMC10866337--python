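"""Featurized molecular graphs and the condensed graph of reaction (CGR).

A molecule becomes a graph of per-atom feature vectors plus both directed
arcs of every bond.  A reaction becomes a CGR: one node per atom-map number
carrying ``[reactant features | product - reactant difference]``, and one
edge per atom pair bonded on either side, with a bond absent from one side
contributing a null-bond vector to the difference block.  An identity
reaction therefore has all-zero difference blocks, and reversing a reaction
flips the sign of every difference block.

Hydrogens stay implicit except for the mapped (reacting) hydrogens the input
spells out explicitly, which become graph nodes; this keeps solvent graphs
small while making hydrogen transfers visible to the encoder.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from rdkit import Chem

from .errors import FeatureError, ShapeError
from .reactions import MappedReaction, _mol_from_smiles

__all__ = [
    "FeatureSchema",
    "MolGraph",
    "CGRGraph",
    "build_mol_graph",
    "build_cgr",
    "inject_extra_features",
    "batch_graphs",
    "GraphBatch",
    "dump_graphs",
]

_ELEMENTS = ("H", "C", "N", "O", "S")
_DEGREES = (0, 1, 2, 3, 4, 5)
_CHARGES = (-2, -1, 0, 1, 2)
_HYBRID = (
    Chem.HybridizationType.S,
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
)
_NUM_HS = (0, 1, 2, 3, 4)
_CHIRAL = (
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
)
_BOND_ORDERS = (
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
)
# Pauling electronegativities for the supported elements
_ELECTRONEG = {"H": 2.20, "C": 2.55, "N": 3.04, "O": 3.44, "S": 2.58}


def _one_hot(value, choices) -> List[float]:
    vec = [0.0] * (len(choices) + 1)
    try:
        vec[choices.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0  # "other" fallback
    return vec


@dataclass(frozen=True)
class FeatureSchema:
    """Deterministic atom/bond feature vocabulary.

    The base set is the published D-MPNN default: element one-hot over
    {H, C, N, O, S, other}, degree 0-5, formal charge -2..+2, hybridization,
    aromaticity, total hydrogen count 0-4 and scaled atomic mass; bonds carry
    a bond-order one-hot {single, double, triple, aromatic}, conjugation and
    ring flags, and a null-bond flag used by the CGR for bonds absent from
    one side.  Chirality and the additional RDKit atom block (radical
    electrons, ring size, lone pairs, H-bond donor/acceptor, electronegativity)
    are optional and default-off.
    """

    include_chirality: bool = False
    extra_atom_features: bool = False
    version: str = "kinsolv-features-1"

    @property
    def atom_width(self) -> int:
        width = (len(_ELEMENTS) + 1) + (len(_DEGREES) + 1) + (len(_CHARGES) + 1)
        width += (len(_HYBRID) + 1) + 1 + (len(_NUM_HS) + 1) + 1
        if self.include_chirality:
            width += len(_CHIRAL) + 1
        if self.extra_atom_features:
            width += 6
        return width

    @property
    def bond_width(self) -> int:
        return len(_BOND_ORDERS) + 3  # order one-hot + conjugated + ring + null

    @property
    def cgr_atom_width(self) -> int:
        return 2 * self.atom_width

    @property
    def cgr_bond_width(self) -> int:
        return 2 * self.bond_width

    def atom_features(self, atom: Chem.Atom, mol: Chem.Mol) -> List[float]:
        vec = _one_hot(atom.GetSymbol(), _ELEMENTS)
        vec += _one_hot(atom.GetDegree(), _DEGREES)
        vec += _one_hot(atom.GetFormalCharge(), _CHARGES)
        vec += _one_hot(atom.GetHybridization(), _HYBRID)
        vec.append(1.0 if atom.GetIsAromatic() else 0.0)
        vec += _one_hot(atom.GetTotalNumHs(), _NUM_HS)
        vec.append(atom.GetMass() * 0.01)
        if self.include_chirality:
            vec += _one_hot(atom.GetChiralTag(), _CHIRAL)
        if self.extra_atom_features:
            vec += self._extra_atom_block(atom, mol)
        return vec

    @staticmethod
    def _extra_atom_block(atom: Chem.Atom, mol: Chem.Mol) -> List[float]:
        sym = atom.GetSymbol()
        n_h = atom.GetTotalNumHs(includeNeighbors=True)
        ring_info = mol.GetRingInfo()
        ring_size = 0
        for size in range(3, 9):
            if ring_info.IsAtomInRingOfSize(atom.GetIdx(), size):
                ring_size = size
                break
        outer = Chem.GetPeriodicTable().GetNOuterElecs(sym)
        bond_order = sum(b.GetBondTypeAsDouble() for b in atom.GetBonds())
        lone_pairs = max(
            0.0,
            (outer - bond_order - atom.GetNumImplicitHs() - atom.GetNumExplicitHs()
             - atom.GetNumRadicalElectrons() - atom.GetFormalCharge()) / 2.0,
        )
        is_donor = 1.0 if sym in ("N", "O") and n_h > 0 else 0.0
        is_acceptor = 1.0 if sym in ("N", "O") else 0.0
        return [
            float(atom.GetNumRadicalElectrons()),
            ring_size * 0.1,
            lone_pairs * 0.5,
            is_donor,
            is_acceptor,
            _ELECTRONEG.get(sym, 2.5) * 0.25,
        ]

    def bond_features(self, bond: Chem.Bond) -> List[float]:
        vec = [0.0] * self.bond_width
        try:
            vec[_BOND_ORDERS.index(bond.GetBondType())] = 1.0
        except ValueError:
            pass
        vec[len(_BOND_ORDERS)] = 1.0 if bond.GetIsConjugated() else 0.0
        vec[len(_BOND_ORDERS) + 1] = 1.0 if bond.IsInRing() else 0.0
        return vec

    def null_bond(self) -> List[float]:
        vec = [0.0] * self.bond_width
        vec[-1] = 1.0
        return vec


@dataclass
class MolGraph:
    """A featurized molecular graph with both directed arcs of every bond."""

    atom_features: np.ndarray  # (n_atoms, atom_width)
    arc_src: np.ndarray  # (n_arcs,) source atom of each directed arc
    arc_dst: np.ndarray  # (n_arcs,)
    arc_features: np.ndarray  # (n_arcs, bond_width)
    rev: np.ndarray  # (n_arcs,) index of the reverse arc
    component_count: int = 1

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_arcs(self) -> int:
        return self.arc_src.shape[0]


@dataclass
class CGRGraph(MolGraph):
    """Condensed graph of reaction; nodes are indexed by sorted atom-map
    number and features are ``[reactant | product - reactant]`` blocks."""

    map_order: Tuple[int, ...] = ()


def _arcs_from_bonds(
    bonds: Sequence[Tuple[int, int, List[float]]], width: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    src, dst, feats = [], [], []
    for i, j, vec in bonds:
        src += [i, j]
        dst += [j, i]
        feats += [vec, vec]
    n = len(src)
    rev = np.arange(n, dtype=np.int64)
    rev[0::2] += 1
    rev[1::2] -= 1
    feat_arr = (
        np.array(feats, dtype=np.float64) if n else np.zeros((0, width))
    )
    return (
        np.array(src, dtype=np.int64),
        np.array(dst, dtype=np.int64),
        feat_arr,
        rev,
    )


def build_mol_graph(smiles_or_mol: Union[str, Chem.Mol], schema: FeatureSchema) -> MolGraph:
    """Featurize a molecule (atom order = toolkit atom order)."""
    if isinstance(smiles_or_mol, Chem.Mol):
        mol = smiles_or_mol
    else:
        mol = _mol_from_smiles(smiles_or_mol)
    atoms = np.array(
        [schema.atom_features(a, mol) for a in mol.GetAtoms()], dtype=np.float64
    )
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), schema.bond_features(b))
        for b in mol.GetBonds()
    ]
    src, dst, feats, rev = _arcs_from_bonds(bonds, schema.bond_width)
    return MolGraph(
        atom_features=atoms,
        arc_src=src,
        arc_dst=dst,
        arc_features=feats,
        rev=rev,
        component_count=len(Chem.GetMolFrags(mol)),
    )


def build_cgr(r: MappedReaction, schema: FeatureSchema) -> CGRGraph:
    """Superpose the reactant and product graphs over the atom-map bijection."""
    r_mol, p_mol = r.reactant_graph, r.product_graph
    r_map, p_map = r.reactant_map_index, r.product_map_index
    map_order = tuple(sorted(r_map))
    node_of = {num: i for i, num in enumerate(map_order)}

    r_feats = {num: schema.atom_features(r_mol.GetAtomWithIdx(i), r_mol)
               for num, i in r_map.items()}
    p_feats = {num: schema.atom_features(p_mol.GetAtomWithIdx(i), p_mol)
               for num, i in p_map.items()}
    atoms = np.array(
        [
            r_feats[num] + [p - q for p, q in zip(p_feats[num], r_feats[num])]
            for num in map_order
        ],
        dtype=np.float64,
    )

    def bond_map(mol: Chem.Mol) -> Dict[frozenset, List[float]]:
        out = {}
        for b in mol.GetBonds():
            key = frozenset(
                (b.GetBeginAtom().GetAtomMapNum(), b.GetEndAtom().GetAtomMapNum())
            )
            out[key] = schema.bond_features(b)
        return out

    rb, pb = bond_map(r_mol), bond_map(p_mol)
    null = schema.null_bond()
    bonds = []
    for key in sorted(set(rb) | set(pb), key=sorted):
        a, b = sorted(key)
        fr = rb.get(key, null)
        fp = pb.get(key, null)
        vec = fr + [p - q for p, q in zip(fp, fr)]
        bonds.append((node_of[a], node_of[b], vec))
    src, dst, feats, rev = _arcs_from_bonds(bonds, schema.cgr_bond_width)
    return CGRGraph(
        atom_features=atoms,
        arc_src=src,
        arc_dst=dst,
        arc_features=feats,
        rev=rev,
        component_count=len(Chem.GetMolFrags(r_mol)),
        map_order=map_order,
    )


def inject_extra_features(
    graph: MolGraph,
    atom_extras: Optional[Union[np.ndarray, Dict[int, Sequence[float]]]] = None,
    bond_extras: Optional[np.ndarray] = None,
) -> MolGraph:
    """Append user-supplied per-atom / per-bond feature blocks.

    For a CGR, ``atom_extras`` may be a dict keyed by atom-map number.
    Per-bond extras are given per undirected bond, in the graph's bond order
    (arc pairs ``2k, 2k+1``).  Molecular-level extras are not handled here:
    they ride on the record and are concatenated with the embeddings at the
    regression head.
    """
    atoms = graph.atom_features
    arcs = graph.arc_features
    if atom_extras is not None:
        if isinstance(atom_extras, dict):
            if not isinstance(graph, CGRGraph):
                raise FeatureError("dict atom extras require a CGR graph")
            missing = [m for m in graph.map_order if m not in atom_extras]
            if missing:
                raise FeatureError(f"atom extras missing for map numbers {missing}")
            extra = np.array(
                [atom_extras[m] for m in graph.map_order], dtype=np.float64
            )
        else:
            extra = np.asarray(atom_extras, dtype=np.float64)
        if extra.ndim != 2 or extra.shape[0] != graph.n_atoms:
            raise FeatureError(
                f"atom extras shape {extra.shape} does not match "
                f"{graph.n_atoms} atoms"
            )
        atoms = np.concatenate([atoms, extra], axis=1)
    if bond_extras is not None:
        extra = np.asarray(bond_extras, dtype=np.float64)
        n_bonds = graph.n_arcs // 2
        if extra.ndim != 2 or extra.shape[0] != n_bonds:
            raise FeatureError(
                f"bond extras shape {extra.shape} does not match {n_bonds} bonds"
            )
        arcs = np.concatenate([arcs, np.repeat(extra, 2, axis=0)], axis=1)
    return replace(graph, atom_features=atoms, arc_features=arcs)


@dataclass
class GraphBatch:
    """Several graphs merged into one disjoint graph for batched encoding."""

    atom_features: np.ndarray
    arc_src: np.ndarray
    arc_dst: np.ndarray
    arc_features: np.ndarray
    rev: np.ndarray
    atom_graph_id: np.ndarray  # (n_atoms,) graph index of each atom
    n_graphs: int
    atom_counts: np.ndarray  # (n_graphs,)

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]


def batch_graphs(graphs: Sequence[MolGraph]) -> GraphBatch:
    widths = {(g.atom_features.shape[1], g.arc_features.shape[1]) for g in graphs}
    if len(widths) != 1:
        raise ShapeError(f"inconsistent feature widths in batch: {widths}")
    atom_offset = 0
    arc_offset = 0
    atoms, srcs, dsts, feats, revs, gids, counts = [], [], [], [], [], [], []
    for gid, g in enumerate(graphs):
        atoms.append(g.atom_features)
        srcs.append(g.arc_src + atom_offset)
        dsts.append(g.arc_dst + atom_offset)
        feats.append(g.arc_features)
        revs.append(g.rev + arc_offset)
        gids.append(np.full(g.n_atoms, gid, dtype=np.int64))
        counts.append(g.n_atoms)
        atom_offset += g.n_atoms
        arc_offset += g.n_arcs
    return GraphBatch(
        atom_features=np.concatenate(atoms, axis=0),
        arc_src=np.concatenate(srcs),
        arc_dst=np.concatenate(dsts),
        arc_features=np.concatenate(feats, axis=0),
        rev=np.concatenate(revs),
        atom_graph_id=np.concatenate(gids),
        n_graphs=len(graphs),
        atom_counts=np.array(counts, dtype=np.int64),
    )


def dump_graphs(graphs: Sequence[MolGraph], path) -> None:
    """Debug dump: one JSON object per graph with nodes, edges, and widths."""
    with open(path, "w", encoding="utf-8") as fh:
        for g in graphs:
            obj = {
                "nodes": g.atom_features.tolist(),
                "edges": [
                    [int(s), int(d), g.arc_features[k].tolist()]
                    for k, (s, d) in enumerate(zip(g.arc_src, g.arc_dst))
                ],
                "widths": [g.atom_features.shape[1], g.arc_features.shape[1]],
            }
            fh.write(json.dumps(obj) + "\n")
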