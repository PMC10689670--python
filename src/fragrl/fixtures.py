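"""Seeded synthetic molecule generator.

Composes test molecules from a built-in catalog of ring cores, acyclic linkers
and side chains using the same attachment-point assembly machinery as the rest
of the package, so every fixture molecule is valid and decomposes back into
ring / linker / side-chain fragments.  The catalog spans light one-ring
molecules through heavy multi-ring ones so that molecular weight (and the
other gated properties) straddle the default property ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assembly import AssemblyError, MoleculeState, assemble
from .fragmentation import FragmentLibrary, fragment_from_smiles

__all__ = ["FixtureSet", "generate_fixtures", "CORES", "LINKERS", "SIDE_CHAINS"]

CORES: tuple[str, ...] = (
    "c1ccc([*:1])cc1",
    "C1CCC([*:1])CC1",
    "C1CCC([*:1])C1",
    "c1ccnc([*:1])c1",
    "c1csc([*:1])c1",
    "c1cnc([*:1])nc1",
    "c1cnc([*:1])cn1",
    "c1ccc2cc([*:1])ccc2c1",
    "C1CCN([*:1])CC1",
    "C1CCC([*:1])OC1",
    "C1CCC([*:1])O1",
    "O=C1CCC([*:1])C1",
    "c1coc([*:1])c1",
    "c1cc([*:1])[nH]c1",
    "c1oc([*:1])nc1",
    "c1sc([*:1])nc1",
    "c1ccc2[nH]c([*:1])cc2c1",
    "c1ccc2nc([*:1])ccc2c1",
    "c1ccc2sc([*:1])cc2c1",
    "[*:1]c1ccc([*:2])cc1",
    "[*:1]C1CCC([*:2])CC1",
    "[*:1]c1ccc([*:2])nc1",
    "[*:1]c1ccc2cc([*:2])ccc2c1",
    "[*:1]C1CCN([*:2])CC1",
    "[*:1]N1CCN([*:2])CC1",
)

LINKERS: tuple[str, ...] = (
    "[*:1]C[*:2]",
    "[*:1]CC[*:2]",
    "[*:1]CCC[*:2]",
    "[*:1]CCCC[*:2]",
    "[*:1]COC[*:2]",
    "[*:1]CNC[*:2]",
    "[*:1]C(=O)[*:2]",
    "[*:1]C(=O)N[*:2]",
    "[*:1]C(=O)NC[*:2]",
    "[*:1]CC(=O)C[*:2]",
    "[*:1]CS[*:2]",
    "[*:1]CCOCC[*:2]",
    "[*:1]CN(C)C[*:2]",
)

SIDE_CHAINS: tuple[str, ...] = (
    "[*:1]C",
    "[*:1]CC",
    "[*:1]CCC",
    "[*:1]CCCC",
    "[*:1]C(C)C",
    "[*:1]C(C)(C)C",
    "[*:1]O",
    "[*:1]OC",
    "[*:1]OCC",
    "[*:1]OCCO",
    "[*:1]N",
    "[*:1]N(C)C",
    "[*:1]CCN",
    "[*:1]F",
    "[*:1]Cl",
    "[*:1]Br",
    "[*:1]I",
    "[*:1]CCl",
    "[*:1]CCF",
    "[*:1]C(F)(F)F",
    "[*:1]C#N",
    "[*:1]CC#N",
    "[*:1]C=C",
    "[*:1]C#C",
    "[*:1]S",
    "[*:1]SC",
    "[*:1]S(C)(=O)=O",
    "[*:1][N+](=O)[O-]",
    "[*:1]C(=O)O",
    "[*:1]C(=O)OC",
    "[*:1]C(=O)N",
)


@dataclass
class FixtureSet:
    molecules: list[str]
    seed: int
    complexity: str


def _compose(rng: np.random.Generator, lib: FragmentLibrary,
             core_idx: list[int], linker_idx: list[int], side_idx: list[int],
             n_cores: int, max_sides: int) -> str:
    """One random core-linker-core chain with random side chains."""
    positions: list[int] = []
    bonds: list[tuple[int, int, int, int]] = []
    open_points: list[tuple[int, int]] = []  # (position, placeholder)

    def add(frag_lib_idx: int) -> int:
        positions.append(frag_lib_idx)
        pos = len(positions) - 1
        for point, _ in lib[frag_lib_idx].attachment_points:
            open_points.append((pos, point))
        return pos

    cores = [int(rng.choice(core_idx)) for _ in range(n_cores)]
    add(cores[0])
    for c in cores[1:]:
        # bridge the previous component to the next core through a linker
        lpos = add(int(rng.choice(linker_idx)))
        l_points = [pt for p, pt in open_points if p == lpos]
        prev = [(p, pt) for p, pt in open_points if p != lpos]
        if not prev:
            raise AssemblyError("no open attachment point left for a linker")
        a = prev[int(rng.integers(len(prev)))]
        bonds.append((a[0], a[1], lpos, l_points[0]))
        open_points.remove(a)
        open_points.remove((lpos, l_points[0]))
        cpos = add(c)
        c_point = next(pt for p, pt in open_points if p == cpos)
        bonds.append((lpos, l_points[1], cpos, c_point))
        open_points.remove((lpos, l_points[1]))
        open_points.remove((cpos, c_point))
    n_sides = int(rng.integers(0, max_sides + 1))
    for _ in range(n_sides):
        if not open_points:
            break
        target = open_points[int(rng.integers(len(open_points)))]
        spos = add(int(rng.choice(side_idx)))
        s_point = next(pt for p, pt in open_points if p == spos)
        bonds.append((target[0], target[1], spos, s_point))
        open_points.remove(target)
        open_points.remove((spos, s_point))

    mask = tuple(lib[i].frag_class in ("ring", "linker") for i in positions)
    state = MoleculeState(fragments=tuple(positions), scaffold_mask=mask,
                          bond_graph=tuple(bonds), source="")
    return assemble(state, lib)


def generate_fixtures(n: int, seed: int = 0, complexity: str = "small") -> FixtureSet:
    """Deterministic set of ``n`` valid synthetic molecules.

    ``complexity`` controls size: "small" mixes 1-2 ring systems, "medium"
    2-3.  Molecules are drawn from light / mid / heavy size classes so that MW
    spans both sides of the 200-500 Da default gate.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if complexity not in ("small", "medium"):
        raise ValueError(f"unknown complexity {complexity!r}")
    rng = np.random.default_rng(seed)
    lib = FragmentLibrary()
    core_idx = [lib.add(fragment_from_smiles(s)) for s in CORES]
    linker_idx = [lib.add(fragment_from_smiles(s)) for s in LINKERS]
    side_idx = [lib.add(fragment_from_smiles(s)) for s in SIDE_CHAINS]

    classes = (
        [(1, 1), (2, 2), (2, 4)] if complexity == "small"
        else [(2, 2), (3, 4), (4, 6)]
    )
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        n_cores, max_sides = classes[int(rng.integers(len(classes)))]
        try:
            smiles = _compose(rng, lib, core_idx, linker_idx, side_idx,
                              n_cores, max_sides)
        except AssemblyError:
            continue
        if smiles in seen:
            continue
        seen.add(smiles)
        out.append(smiles)
    return FixtureSet(molecules=out, seed=seed, complexity=complexity)
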