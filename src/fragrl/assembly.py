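"""Molecule <-> ordered fragment decomposition, replacement and reassembly.

A :class:`MoleculeState` is the policy's view of one molecule: an ordered list
of library fragment indices, a scaffold mask (rings and linkers are scaffold,
side chains are not), and a bond graph pairing numbered attachment points
between positions.  States are immutable; :func:`replace_fragment` returns a
new state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .fragmentation import (
    RING,
    LINKER,
    DecompositionMap,
    FragmentLibrary,
    FragmentationError,
    fragment_molecule,
)

__all__ = [
    "MoleculeState",
    "AssemblyError",
    "InvalidMoleculeError",
    "IncompatibleFragmentError",
    "decompose",
    "replace_fragment",
    "rewire_fragment",
    "assemble",
    "assemble_raw",
    "check_validity",
    "canonical_smiles",
    "bemis_murcko_scaffold",
]


class AssemblyError(ValueError):
    pass


class InvalidMoleculeError(AssemblyError):
    """Assembled structure fails valence/aromaticity sanitization."""


class IncompatibleFragmentError(AssemblyError):
    """Replacement fragment cannot host the position's bonds."""


@dataclass(frozen=True)
class MoleculeState:
    """Ordered fragment decomposition of one molecule (the RL state)."""

    fragments: tuple[int, ...]                      # library indices
    scaffold_mask: tuple[bool, ...]                 # True for ring/linker positions
    bond_graph: tuple[tuple[int, int, int, int], ...]  # (pos_a, point_a, pos_b, point_b)
    source: str                                     # canonical SMILES of the assembly

    def __post_init__(self):
        if len(self.fragments) != len(self.scaffold_mask):
            raise AssemblyError("scaffold_mask length must match fragments")

    def bonds_at(self, position: int) -> list[tuple[int, int, int, int]]:
        """Bond records touching ``position``, ordered by local point index."""
        touching = [b for b in self.bond_graph if position in (b[0], b[2])]
        return sorted(touching, key=lambda b: b[1] if b[0] == position else b[3])

    def to_json(self) -> dict:
        return {
            "fragments": list(self.fragments),
            "scaffold_mask": list(self.scaffold_mask),
            "bond_graph": [list(b) for b in self.bond_graph],
            "source": self.source,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "MoleculeState":
        return cls(
            fragments=tuple(obj["fragments"]),
            scaffold_mask=tuple(obj["scaffold_mask"]),
            bond_graph=tuple(tuple(b) for b in obj["bond_graph"]),
            source=obj["source"],
        )


def canonical_smiles(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidMoleculeError(f"unparsable structure: {smiles!r}")
    return Chem.MolToSmiles(mol)


def check_validity(smiles: str) -> bool:
    """True iff the string parses and sanitizes as a non-empty molecule."""
    if not smiles:
        return False
    mol = Chem.MolFromSmiles(smiles)
    return mol is not None and mol.GetNumAtoms() > 0


def decompose(
    mol: str | Chem.Mol,
    lib: FragmentLibrary,
    frozen: bool = False,
) -> MoleculeState:
    """Decompose ``mol`` against ``lib``; unseen fragments are added unless frozen."""
    frags, dmap = fragment_molecule(mol)
    indices = []
    for f in frags:
        if frozen and f.structure not in lib.index:
            raise FragmentationError(f"fragment not in frozen library: {f.structure}")
        indices.append(lib.add(f))
    mask = tuple(f.frag_class in (RING, LINKER) for f in frags)
    state = MoleculeState(
        fragments=tuple(indices),
        scaffold_mask=mask,
        bond_graph=tuple(dmap.bonds),
        source="",
    )
    return dc_replace(state, source=assemble(state, lib))


def _assemble_mol(state: MoleculeState, lib: FragmentLibrary) -> Chem.Mol:
    """Bonded union of the state's fragments with all placeholders removed."""
    pieces = [lib[i].mol() for i in state.fragments]
    offsets = []
    combo = None
    total = 0
    for p in pieces:
        offsets.append(total)
        total += p.GetNumAtoms()
        combo = p if combo is None else Chem.CombineMols(combo, p)
    em = Chem.RWMol(combo)

    def find_dummy(pos: int, point: int) -> int:
        lo, hi = offsets[pos], offsets[pos] + pieces[pos].GetNumAtoms()
        for idx in range(lo, hi):
            a = em.GetAtomWithIdx(idx)
            if a.GetAtomicNum() == 0 and a.GetAtomMapNum() == point:
                return idx
        raise AssemblyError(f"position {pos} has no attachment point {point}")

    to_remove = set()
    for pos_a, pt_a, pos_b, pt_b in state.bond_graph:
        da, db = find_dummy(pos_a, pt_a), find_dummy(pos_b, pt_b)
        na = next(n.GetIdx() for n in em.GetAtomWithIdx(da).GetNeighbors())
        nb = next(n.GetIdx() for n in em.GetAtomWithIdx(db).GetNeighbors())
        em.AddBond(na, nb, Chem.BondType.SINGLE)
        to_remove.update((da, db))
    # open attachment points are capped with (implicit) hydrogen
    to_remove.update(
        a.GetIdx() for a in em.GetAtoms() if a.GetAtomicNum() == 0
    )
    for idx in sorted(to_remove, reverse=True):
        em.RemoveAtom(idx)
    for a in em.GetAtoms():
        a.SetAtomMapNum(0)
    return em.GetMol()


def assemble(state: MoleculeState, lib: FragmentLibrary) -> str:
    """Canonical SMILES of the assembled state; raises on invalid chemistry."""
    try:
        mol = _assemble_mol(state, lib)
        Chem.SanitizeMol(mol)
    except AssemblyError:
        raise
    except Exception as exc:
        # valence violations, duplicate bonds, kekulization failures, ...
        raise InvalidMoleculeError(str(exc)) from exc
    return Chem.MolToSmiles(mol)


def assemble_raw(state: MoleculeState, lib: FragmentLibrary) -> str:
    """Best-effort SMILES without sanitization (may be chemically invalid).

    Used to report attempted molecules that fail valence rules; downstream
    validity checks will classify them.
    """
    try:
        mol = _assemble_mol(state, lib)
        return Chem.MolToSmiles(mol, canonical=False)
    except Exception:
        return ""


def rewire_fragment(
    state: MoleculeState,
    position: int,
    new_frag: int,
    lib: FragmentLibrary,
) -> MoleculeState:
    """Swap the fragment and rewire bonds without validating the assembly.

    The returned state has an empty ``source``; callers are expected to
    :func:`assemble` (or :func:`assemble_raw`) it themselves.
    """
    if not 0 <= position < len(state.fragments):
        raise AssemblyError(f"position {position} out of range")
    incoming = lib[new_frag]
    bonds = state.bonds_at(position)
    if incoming.n_attachments < len(bonds):
        raise IncompatibleFragmentError(
            f"fragment {incoming.structure} has {incoming.n_attachments} "
            f"attachment point(s); position {position} needs {len(bonds)}"
        )
    new_points = [p for p, _ in incoming.attachment_points]
    rewired = list(state.bond_graph)
    for bond, np_ in zip(bonds, new_points):
        i = rewired.index(bond)
        pos_a, pt_a, pos_b, pt_b = bond
        if pos_a == position:
            rewired[i] = (pos_a, np_, pos_b, pt_b)
        else:
            rewired[i] = (pos_a, pt_a, pos_b, np_)

    fragments = list(state.fragments)
    fragments[position] = new_frag
    mask = list(state.scaffold_mask)
    mask[position] = incoming.frag_class in (RING, LINKER)
    return MoleculeState(
        fragments=tuple(fragments),
        scaffold_mask=tuple(mask),
        bond_graph=tuple(rewired),
        source="",
    )


def replace_fragment(
    state: MoleculeState,
    position: int,
    new_frag: int,
    lib: FragmentLibrary,
) -> MoleculeState:
    """Swap the fragment at ``position`` for library fragment ``new_frag``.

    Bonds at the position are rewired to the incoming fragment's attachment
    points in ascending index order; surplus incoming points stay open (capped
    with hydrogen at assembly).  Raises :class:`IncompatibleFragmentError` if
    the incoming fragment has fewer attachment points than the position has
    bonds, and :class:`InvalidMoleculeError` if the rewired state does not
    assemble into a valid molecule.
    """
    new_state = rewire_fragment(state, position, new_frag, lib)
    return dc_replace(new_state, source=assemble(new_state, lib))


def reassemble(dmap: DecompositionMap, frags, lib: FragmentLibrary | None = None) -> str:
    """Rebuild the parent molecule from fragment_molecule output (round trip)."""
    local = FragmentLibrary()
    indices = tuple(local.add(f) for f in frags)
    state = MoleculeState(
        fragments=indices,
        scaffold_mask=tuple(True for _ in indices),
        bond_graph=tuple(dmap.bonds),
        source="",
    )
    return assemble(state, local)


def bemis_murcko_scaffold(smiles: str) -> str:
    """Canonical Bemis-Murcko framework; empty string for acyclic molecules."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidMoleculeError(f"unparsable structure: {smiles!r}")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ""
    return Chem.MolToSmiles(scaffold)
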