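"""Atom-mapped reaction parsing, canonical keys, and bond-change typing.

A reaction is given as an atom-mapped reaction SMILES ``reactants>>products``
(Daylight dialect, ``:n`` atom maps, ``.``-separated components).  Every
explicit atom on both sides must carry an atom-map number and the map numbers
must form a bijection between the two sides; spectator hydrogens may stay
implicit, but any hydrogen that changes its bonding has to be written as an
explicit mapped atom (e.g. ``[CH3:1][H:2]``) so the transfer is visible to the
condensed graph of reaction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Set, Tuple

from rdkit import Chem

from .errors import BalanceError, MappingError, ParseError

__all__ = [
    "MappedReaction",
    "BondChangeSignature",
    "parse_mapped_reaction",
    "reverse_reaction",
    "reaction_key",
    "directed_key",
    "bond_change_signature",
    "classify_reaction_family",
    "canonical_smiles",
]

_BOND_SYMBOL = {1.0: "-", 1.5: ":", 2.0: "=", 3.0: "#"}

# parser that keeps explicit (mapped) hydrogens as graph nodes
_PARSER_PARAMS = Chem.SmilesParserParams()
_PARSER_PARAMS.removeHs = False


def _mol_from_smiles(text: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(text, _PARSER_PARAMS)
    if mol is None:
        raise ParseError(f"unparsable SMILES: {text!r}")
    return mol


def canonical_smiles(smiles: str) -> str:
    """Canonical (unmapped, implicit-H) SMILES of a single species string."""
    mol = _mol_from_smiles(smiles)
    mol = Chem.RWMol(mol)
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(Chem.RemoveHs(mol))


def _canonical_side(mol: Chem.Mol) -> str:
    """Canonical unmapped SMILES of one reaction side, components sorted."""
    work = Chem.RWMol(mol)
    for atom in work.GetAtoms():
        atom.SetAtomMapNum(0)
    stripped = Chem.RemoveHs(work)
    parts = sorted(
        Chem.MolToSmiles(frag) for frag in Chem.GetMolFrags(stripped, asMols=True)
    )
    return ".".join(parts)


def _element_counts(mol: Chem.Mol) -> Counter:
    counts: Counter = Counter()
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] += 1
        counts["H"] += atom.GetNumImplicitHs() + atom.GetNumExplicitHs()
    return counts


def _map_index(mol: Chem.Mol, side: str) -> Dict[int, int]:
    """map number -> atom index; raises MappingError on missing/duplicate maps."""
    index: Dict[int, int] = {}
    for atom in mol.GetAtoms():
        num = atom.GetAtomMapNum()
        if num <= 0:
            raise MappingError(
                f"unmapped {atom.GetSymbol()} atom on {side} side"
            )
        if num in index:
            raise MappingError(f"duplicate atom-map number {num} on {side} side")
        index[num] = atom.GetIdx()
    return index


@dataclass
class MappedReaction:
    """An atom-mapped reaction with a map-number bijection between sides.

    ``reactant_graph``/``product_graph`` are RDKit Mols in which mapped
    hydrogens are explicit nodes.  ``map_pairs`` holds (reactant atom index,
    product atom index) tuples keyed by the shared atom-map number.
    """

    reactant_graph: Chem.Mol
    product_graph: Chem.Mol
    map_pairs: Set[Tuple[int, int]]
    direction_tag: str = "forward"
    source_text: str = ""
    _key_cache: str = field(default="", repr=False, compare=False)

    @property
    def reactant_map_index(self) -> Dict[int, int]:
        return {a.GetAtomMapNum(): a.GetIdx() for a in self.reactant_graph.GetAtoms()}

    @property
    def product_map_index(self) -> Dict[int, int]:
        return {a.GetAtomMapNum(): a.GetIdx() for a in self.product_graph.GetAtoms()}

    @property
    def map_numbers(self) -> Tuple[int, ...]:
        return tuple(sorted(self.reactant_map_index))

    @property
    def smiles(self) -> str:
        """Mapped reaction SMILES regenerated from the graphs."""
        return (
            Chem.MolToSmiles(self.reactant_graph)
            + ">>"
            + Chem.MolToSmiles(self.product_graph)
        )

    @property
    def n_reactant_components(self) -> int:
        return len(Chem.GetMolFrags(self.reactant_graph))

    @property
    def n_product_components(self) -> int:
        return len(Chem.GetMolFrags(self.product_graph))


def parse_mapped_reaction(text: str) -> MappedReaction:
    """Parse and validate an atom-mapped reaction SMILES.

    Raises
    ------
    ParseError
        if the string does not contain exactly one ``>>`` or a side fails to
        parse.
    MappingError
        if any explicit atom lacks a map number, a map number is duplicated,
        the two sides do not share the same map-number set, or a map number
        points at different elements on the two sides.
    BalanceError
        if the element multisets (including implicit hydrogens) differ.
    """
    parts = text.split(">>")
    if len(parts) != 2:
        raise ParseError(f"expected exactly one '>>' separator in {text!r}")
    r_text, p_text = parts
    reactant = _mol_from_smiles(r_text)
    product = _mol_from_smiles(p_text)

    r_index = _map_index(reactant, "reactant")
    p_index = _map_index(product, "product")
    if set(r_index) != set(p_index):
        missing = set(r_index) ^ set(p_index)
        raise MappingError(
            f"atom-map numbers are not a bijection; unpaired maps: {sorted(missing)}"
        )
    for num, r_idx in r_index.items():
        r_sym = reactant.GetAtomWithIdx(r_idx).GetSymbol()
        p_sym = product.GetAtomWithIdx(p_index[num]).GetSymbol()
        if r_sym != p_sym:
            raise MappingError(
                f"map {num} is {r_sym} on the reactant side but {p_sym} on the "
                "product side"
            )

    if _element_counts(reactant) != _element_counts(product):
        raise BalanceError(
            f"unbalanced reaction: {dict(_element_counts(reactant))} >> "
            f"{dict(_element_counts(product))}"
        )

    pairs = {(r_index[num], p_index[num]) for num in r_index}
    return MappedReaction(
        reactant_graph=reactant,
        product_graph=product,
        map_pairs=pairs,
        direction_tag="forward",
        source_text=text,
    )


def reverse_reaction(r: MappedReaction) -> MappedReaction:
    """Swap the two sides; the graphs are shared, not copied, so reversing
    twice reproduces the original graphs exactly."""
    parts = r.source_text.split(">>")
    source = f"{parts[1]}>>{parts[0]}" if len(parts) == 2 else ""
    return MappedReaction(
        reactant_graph=r.product_graph,
        product_graph=r.reactant_graph,
        map_pairs={(p, q) for (q, p) in r.map_pairs},
        direction_tag="reverse" if r.direction_tag == "forward" else "forward",
        source_text=source,
    )


def directed_key(r: MappedReaction) -> str:
    """Direction-sensitive canonical identifier (reactants>>products)."""
    return _canonical_side(r.reactant_graph) + ">>" + _canonical_side(r.product_graph)


def reaction_key(r: MappedReaction) -> str:
    """Direction-agnostic canonical identifier of a reaction.

    The unordered pair of canonical unmapped side SMILES, joined with ``>>``
    after lexicographic sorting, so that ``reaction_key(r) ==
    reaction_key(reverse_reaction(r))`` and atom-map renumbering has no
    effect.
    """
    if r._key_cache:
        return r._key_cache
    sides = sorted([_canonical_side(r.reactant_graph), _canonical_side(r.product_graph)])
    key = ">>".join(sides)
    r._key_cache = key
    return key


def _bond_table(mol: Chem.Mol) -> Dict[FrozenSet[int], float]:
    """Bond orders keyed by the frozen pair of atom-map numbers."""
    table: Dict[FrozenSet[int], float] = {}
    for bond in mol.GetBonds():
        a = bond.GetBeginAtom().GetAtomMapNum()
        b = bond.GetEndAtom().GetAtomMapNum()
        table[frozenset((a, b))] = bond.GetBondTypeAsDouble()
    return table


@dataclass
class BondChangeSignature:
    """Multisets of formed/broken bonds and bond-order changes.

    Keys are element-pair labels such as ``C-H`` (elements sorted); order
    changes are keyed by (pair label, old order, new order).
    """

    formed: Counter
    broken: Counter
    order_changed: Counter

    def __eq__(self, other) -> bool:
        return (
            self.formed == other.formed
            and self.broken == other.broken
            and self.order_changed == other.order_changed
        )

    @property
    def is_empty(self) -> bool:
        return not (self.formed or self.broken or self.order_changed)

    def swapped(self) -> "BondChangeSignature":
        """Signature of the reverse reaction: formed and broken exchange and
        order changes flip direction."""
        flipped = Counter()
        for (pair, old, new), count in self.order_changed.items():
            flipped[(pair, new, old)] = count
        return BondChangeSignature(
            formed=Counter(self.broken),
            broken=Counter(self.formed),
            order_changed=flipped,
        )

    def label(self) -> str:
        """Human-readable rendering, e.g. ``+O-H, -C-H``.

        Formed bonds are prefixed ``+``, broken bonds ``-``; an order change
        is rendered as the old bond broken plus the new bond formed with the
        matching bond symbol (``-`` single, ``=`` double, ``#`` triple,
        ``:`` aromatic).  One carbon-hydrogen bond formed, one broken and one
        carbon-carbon bond broken therefore reads ``+C-H, -C-C, -C-H``.
        """
        plus, minus = [], []
        for (pair, order), count in sorted(self.formed.items()):
            a, b = pair.split("-")
            plus.extend([f"+{a}{_BOND_SYMBOL[order]}{b}"] * count)
        for (pair, order), count in sorted(self.broken.items()):
            a, b = pair.split("-")
            minus.extend([f"-{a}{_BOND_SYMBOL[order]}{b}"] * count)
        for (pair, old, new), count in sorted(self.order_changed.items()):
            a, b = pair.split("-")
            plus.extend([f"+{a}{_BOND_SYMBOL[new]}{b}"] * count)
            minus.extend([f"-{a}{_BOND_SYMBOL[old]}{b}"] * count)
        return ", ".join(sorted(plus) + sorted(minus))


def _pair_label(mol_r: Chem.Mol, r_map: Dict[int, int], pair: FrozenSet[int]) -> str:
    # heavy atom first, hydrogen last: C-H, O-H, C-O
    syms = sorted(
        (mol_r.GetAtomWithIdx(r_map[num]).GetSymbol() for num in pair),
        key=lambda s: (s == "H", s),
    )
    return "-".join(syms)


def bond_change_signature(r: MappedReaction) -> BondChangeSignature:
    """Compare bonds between mapped atom pairs on the two sides.

    ``formed``/``broken`` are keyed by (element-pair label, bond order);
    ``order_changed`` by (element-pair label, old order, new order).
    """
    r_bonds = _bond_table(r.reactant_graph)
    p_bonds = _bond_table(r.product_graph)
    r_map = r.reactant_map_index
    formed: Counter = Counter()
    broken: Counter = Counter()
    changed: Counter = Counter()
    for pair in set(r_bonds) | set(p_bonds):
        label = _pair_label(r.reactant_graph, r_map, pair)
        old = r_bonds.get(pair, 0.0)
        new = p_bonds.get(pair, 0.0)
        if old == new:
            continue
        if old == 0.0:
            formed[(label, new)] += 1
        elif new == 0.0:
            broken[(label, old)] += 1
        else:
            changed[(label, old, new)] += 1
    return BondChangeSignature(formed=formed, broken=broken, order_changed=changed)


def _is_h_transfer(sig: BondChangeSignature) -> bool:
    if sig.order_changed or sum(sig.formed.values()) != 1 or sum(sig.broken.values()) != 1:
        return False
    (f_pair, f_order), = sig.formed.keys()
    (b_pair, b_order), = sig.broken.keys()
    return (
        f_order == 1.0
        and b_order == 1.0
        and "H" in f_pair.split("-")
        and "H" in b_pair.split("-")
    )


def classify_reaction_family(r: MappedReaction) -> str:
    """One of ``H-abstraction``, ``H-migration``, ``R-addition``, ``other``.

    Templates use only sigma/pi bond changes (charge and radical bookkeeping
    ignored).  A reverse direction inherits the forward family label: a
    beta-scission therefore classifies as ``R-addition``.
    """
    sig = bond_change_signature(r)
    if _is_h_transfer(sig):
        if r.n_reactant_components == 2 and r.n_product_components == 2:
            return "H-abstraction"
        if r.n_reactant_components == 1 and r.n_product_components == 1:
            return "H-migration"
        return "other"
    # radical addition: one pi-bond order decrease plus one new sigma bond;
    # the reverse scission shows the mirrored pattern
    if len(sig.order_changed) == 1 and sum(sig.order_changed.values()) == 1:
        (_, old, new), = sig.order_changed.keys()
        n_formed = sum(sig.formed.values())
        n_broken = sum(sig.broken.values())
        if new == old - 1 and n_formed == 1 and n_broken == 0:
            (_, f_order), = sig.formed.keys()
            if f_order == 1.0:
                return "R-addition"
        if new == old + 1 and n_broken == 1 and n_formed == 0:
            (_, b_order), = sig.broken.keys()
            if b_order == 1.0:
                return "R-addition"
    return "other"
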