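"""Fragment combination library construction.

Molecules are cleaved into ring systems, linkers and side chains by breaking
every acyclic single bond that has at least one end atom inside a ring.  Each
cleavage leaves a pair of numbered attachment-point placeholders (dummy atoms
carrying atom-map numbers) so that the fragments can later be reassembled
exactly.  Fragment-to-fragment similarity is the Tanimoto coefficient computed
over maximum-common-substructure heavy-atom counts:

    sim(f1, f2) = mcs / (a1 + a2 - mcs)

where ``mcs`` is the heavy-atom count of the MCS and ``a1``, ``a2`` are the
fragments' heavy-atom counts (attachment placeholders never count).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFMCS

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

__all__ = [
    "Fragment",
    "FragmentLibrary",
    "DecompositionMap",
    "SimilarityMatrix",
    "FragmentationError",
    "fragment_molecule",
    "build_fragment_library",
    "mcs_atom_count",
    "tmcs_similarity",
    "pairwise_similarity",
    "canonicalize_fragment_smiles",
    "fragment_from_smiles",
]

RING = "ring"
LINKER = "linker"
SIDE_CHAIN = "side_chain"


class FragmentationError(ValueError):
    """Raised for unparsable molecules or empty libraries."""


@dataclass(frozen=True)
class Fragment:
    """One library fragment.

    ``structure`` is a canonical SMILES containing ``[*:n]`` placeholders whose
    map numbers run contiguously from 1 in canonical-rank order.  ``atom_count``
    counts heavy atoms only (placeholders excluded).
    """

    structure: str
    atom_count: int
    frag_class: str
    attachment_points: tuple[tuple[int, int], ...]  # (placeholder index, bond order)

    @property
    def n_attachments(self) -> int:
        return len(self.attachment_points)

    def mol(self) -> Chem.Mol:
        """RDKit mol including placeholder atoms."""
        m = Chem.MolFromSmiles(self.structure)
        if m is None:  # pragma: no cover - structure is canonical by construction
            raise FragmentationError(f"fragment does not parse: {self.structure}")
        return m

    def core_mol(self) -> Chem.Mol:
        """RDKit mol with placeholder atoms stripped (implicit H caps)."""
        return _strip_dummies(self.mol())


@dataclass
class DecompositionMap:
    """Bond bookkeeping captured at fragmentation time.

    ``bonds`` holds one record per cleaved bond:
    ``(position_a, point_a, position_b, point_b)`` where positions index the
    fragment list and points are placeholder map numbers within each fragment.
    """

    bonds: list[tuple[int, int, int, int]] = field(default_factory=list)

    def to_json(self) -> dict:
        return {"bonds": [list(b) for b in self.bonds]}

    @classmethod
    def from_json(cls, obj: dict) -> "DecompositionMap":
        return cls(bonds=[tuple(b) for b in obj["bonds"]])


class FragmentLibrary:
    """Ordered, deduplicated collection of fragments."""

    def __init__(self, fragments: list[Fragment] | None = None):
        self.fragments: list[Fragment] = []
        self.index: dict[str, int] = {}
        for f in fragments or []:
            self.add(f)

    def add(self, frag: Fragment) -> int:
        """Insert ``frag`` if new; return its library position either way."""
        pos = self.index.get(frag.structure)
        if pos is None:
            pos = len(self.fragments)
            self.fragments.append(frag)
            self.index[frag.structure] = pos
        return pos

    def position(self, structure: str) -> int:
        try:
            return self.index[structure]
        except KeyError:
            raise KeyError(f"fragment not in library: {structure}") from None

    def __len__(self) -> int:
        return len(self.fragments)

    def __getitem__(self, i: int) -> Fragment:
        return self.fragments[i]

    def __iter__(self):
        return iter(self.fragments)

    def to_json(self) -> list[dict]:
        return [
            {
                "structure": f.structure,
                "frag_class": f.frag_class,
                "atom_count": f.atom_count,
                "attachment_points": [list(p) for p in f.attachment_points],
            }
            for f in self.fragments
        ]

    @classmethod
    def from_json(cls, records: list[dict]) -> "FragmentLibrary":
        lib = cls()
        for r in records:
            lib.add(
                Fragment(
                    structure=r["structure"],
                    atom_count=r["atom_count"],
                    frag_class=r["frag_class"],
                    attachment_points=tuple(tuple(p) for p in r["attachment_points"]),
                )
            )
        return lib


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of pairwise fragment similarities in [0, 1]."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        self.values = v

    def __len__(self) -> int:
        return self.values.shape[0]

    def __getitem__(self, ij):
        return self.values[ij]


# ---------------------------------------------------------------------------
# fragmentation
# ---------------------------------------------------------------------------


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FragmentationError(f"unparsable structure: {smiles!r}")
    return mol


def _strip_dummies(mol: Chem.Mol) -> Chem.Mol:
    em = Chem.RWMol(mol)
    for idx in sorted(
        (a.GetIdx() for a in em.GetAtoms() if a.GetAtomicNum() == 0), reverse=True
    ):
        em.RemoveAtom(idx)
    out = em.GetMol()
    Chem.SanitizeMol(out)
    return out


def _cleavable_bonds(mol: Chem.Mol) -> list[int]:
    """Acyclic single bonds with at least one end atom in a ring."""
    out = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetIsAromatic() and b.GetIsAromatic() and not (a.IsInRing() and b.IsInRing()):
            continue  # defensive; aromatic atoms are ring atoms
        if a.IsInRing() or b.IsInRing():
            out.append(bond.GetIdx())
    return out


def canonicalize_fragment_smiles(smiles: str) -> str:
    """Canonical fragment SMILES with placeholder maps renumbered 1..k.

    Placeholders are renumbered by their canonical atom rank in the unlabeled
    graph, so the numbering is independent of the input's labeling; the
    function is idempotent.
    """
    mol = _mol_from_smiles(smiles)
    return _fragment_smiles(mol)


def _fragment_smiles(frag_mol: Chem.Mol) -> str:
    mol = Chem.Mol(frag_mol)
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
        if atom.GetAtomicNum() == 0:
            atom.SetIsotope(0)
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    dummies = sorted(
        (a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0),
        key=lambda i: ranks[i],
    )
    for n, idx in enumerate(dummies, start=1):
        mol.GetAtomWithIdx(idx).SetAtomMapNum(n)
    return Chem.MolToSmiles(mol)


def _classify(frag_mol: Chem.Mol, n_attach: int) -> str:
    if any(a.IsInRing() for a in frag_mol.GetAtoms() if a.GetAtomicNum() > 0):
        return RING
    return LINKER if n_attach >= 2 else SIDE_CHAIN


def _make_fragment(frag_mol: Chem.Mol) -> Fragment:
    smiles = _fragment_smiles(frag_mol)
    mol = _mol_from_smiles(smiles)
    heavy = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 0)
    points = tuple(
        (a.GetAtomMapNum(), 1)
        for a in sorted(
            (a for a in mol.GetAtoms() if a.GetAtomicNum() == 0),
            key=lambda a: a.GetAtomMapNum(),
        )
    )
    return Fragment(
        structure=smiles,
        atom_count=heavy,
        frag_class=_classify(mol, len(points)),
        attachment_points=points,
    )


def fragment_from_smiles(smiles: str) -> Fragment:
    """Build a :class:`Fragment` from a SMILES with ``[*:n]`` placeholders."""
    return _make_fragment(_mol_from_smiles(smiles))


def fragment_molecule(mol: str | Chem.Mol) -> tuple[list[Fragment], DecompositionMap]:
    """Cleave ``mol`` into ring / linker / side-chain fragments.

    Returns the fragments in ascending order of their minimum canonical atom
    rank in the parent, together with a :class:`DecompositionMap` that suffices
    to reassemble the parent exactly.  A molecule with no cleavable bonds comes
    back as a single fragment.
    """
    if isinstance(mol, str):
        mol = _mol_from_smiles(mol)
    bonds = _cleavable_bonds(mol)
    if not bonds:
        return [_make_fragment(mol)], DecompositionMap()

    # dummy isotope label i+1 marks both ends of cleaved bond i
    labels = [(i + 1, i + 1) for i in range(len(bonds))]
    broken = Chem.FragmentOnBonds(mol, bonds, addDummies=True, dummyLabels=labels)
    frag_atom_ids: list[tuple[int, ...]] = []
    frag_mols = Chem.GetMolFrags(
        broken, asMols=True, sanitizeFrags=True, fragsMolAtomMapping=frag_atom_ids
    )

    # deterministic fragment order: min canonical rank (in parent) of member atoms
    parent_ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    n_parent = mol.GetNumAtoms()

    def sort_key(item):
        _, atom_ids = item
        return min(parent_ranks[i] for i in atom_ids if i < n_parent)

    ordered = sorted(zip(frag_mols, frag_atom_ids), key=sort_key)

    fragments: list[Fragment] = []
    # per cleaved bond: [(frag position, placeholder map number), ...] (two entries)
    ends: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(bonds))}
    for pos, (fmol, _) in enumerate(ordered):
        # Match dummy atoms between the isotope-labeled fragment and its
        # canonical relabeling via canonical atom ranks of the unlabeled graph.
        canon_mol = _mol_from_smiles(_fragment_smiles(fmol))
        iso_by_rank = _dummy_attr_by_rank(fmol, "isotope")
        map_by_rank = _dummy_attr_by_rank(canon_mol, "map")
        fragments.append(_make_fragment(fmol))
        for rank, iso in iso_by_rank.items():
            bond_i = iso - 1
            ends[bond_i].append((pos, map_by_rank[rank]))

    dmap = DecompositionMap()
    for i in range(len(bonds)):
        (pa, na), (pb, nb) = sorted(ends[i])
        dmap.bonds.append((pa, na, pb, nb))
    return fragments, dmap


def _dummy_attr_by_rank(mol: Chem.Mol, attr: str) -> dict[int, int]:
    """Map canonical-rank-of-dummy -> isotope or map number.

    Ranks are computed on a copy with all dummy labels cleared so that both the
    isotope-labeled and map-labeled versions of a fragment agree.
    """
    bare = Chem.Mol(mol)
    for a in bare.GetAtoms():
        a.SetAtomMapNum(0)
        if a.GetAtomicNum() == 0:
            a.SetIsotope(0)
    ranks = list(Chem.CanonicalRankAtoms(bare, breakTies=True))
    out = {}
    for a in mol.GetAtoms():
        if a.GetAtomicNum() != 0:
            continue
        value = a.GetIsotope() if attr == "isotope" else a.GetAtomMapNum()
        out[ranks[a.GetIdx()]] = value
    return out


def build_fragment_library(mols: list[str | Chem.Mol]) -> FragmentLibrary:
    """Union of fragments over all molecules, deduplicated, first-seen order."""
    if not mols:
        raise FragmentationError("empty molecule list")
    lib = FragmentLibrary()
    n_ok = 0
    for m in mols:
        try:
            frags, _ = fragment_molecule(m)
        except FragmentationError:
            logger.warning("skipping unparsable molecule %r", m)
            continue
        n_ok += 1
        for f in frags:
            lib.add(f)
    if n_ok == 0:
        raise FragmentationError("no molecule could be fragmented")
    return lib


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------

_MCS_PARAMS = dict(
    atomCompare=rdFMCS.AtomCompare.CompareElements,
    bondCompare=rdFMCS.BondCompare.CompareAny,
    matchValences=False,
    ringMatchesRingOnly=False,
    completeRingsOnly=False,
    maximizeBonds=False,  # Tanimoto-MCS counts atoms, so maximize atoms
)


def mcs_atom_count(f1: Fragment, f2: Fragment, timeout: int = 10) -> int:
    """Heavy-atom count of the maximum common substructure.

    Atoms match on element only; bonds match regardless of order (so aromatic
    and Kekulé forms agree).  Placeholder atoms are stripped before matching.
    On MCS timeout the best bound found so far is used and a warning logged.
    """
    m1, m2 = f1.core_mol(), f2.core_mol()
    if Chem.MolToSmiles(m1) == Chem.MolToSmiles(m2):
        return m1.GetNumAtoms()
    res = rdFMCS.FindMCS([m1, m2], timeout=timeout, **_MCS_PARAMS)
    if res.canceled:
        logger.warning(
            "MCS timed out for %s vs %s; using lower bound %d",
            f1.structure, f2.structure, res.numAtoms,
        )
    return max(res.numAtoms, 0)


def tmcs_similarity(f1: Fragment, f2: Fragment, timeout: int = 10) -> float:
    """Tanimoto over MCS atom counts: mcs / (a1 + a2 - mcs)."""
    if f1.atom_count < 1 or f2.atom_count < 1:
        raise ValueError("fragments must have at least one heavy atom")
    mcs = mcs_atom_count(f1, f2, timeout=timeout)
    return mcs / (f1.atom_count + f2.atom_count - mcs)


def pairwise_similarity(lib: FragmentLibrary, timeout: int = 10) -> SimilarityMatrix:
    """Full symmetric similarity matrix over the library."""
    n = len(lib)
    if n == 0:
        raise FragmentationError("empty library")
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = tmcs_similarity(lib[i], lib[j], timeout=timeout)
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(values)
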