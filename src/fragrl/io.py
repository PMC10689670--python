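"""Molecule file reading and small serialization helpers."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from rdkit import Chem

from .fragmentation import FragmentLibrary, SimilarityMatrix
from .tree import FragmentTree

logger = logging.getLogger(__name__)

__all__ = ["read_molecules", "write_molecules", "save_library", "load_library",
           "save_matrix", "load_matrix", "save_tree", "load_tree"]


def read_molecules(
    path: str | Path,
    fmt: str | None = None,
    smiles_column: str = "smiles",
) -> list[str]:
    """Order-preserving SMILES list from a .smi or CSV file.

    Blank and ``#`` comment lines are skipped; lines that fail to parse are
    logged with their line number and dropped.  A file with zero parseable
    molecules is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or ("csv" if path.suffix.lower() == ".csv" else "smi")
    raw: list[tuple[int, str]] = []
    if fmt == "smi":
        for ln, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            raw.append((ln, line.split("\t")[0].split(" ")[0]))
    elif fmt == "csv":
        df = pd.read_csv(path)
        if smiles_column not in df.columns:
            raise ValueError(f"CSV has no column {smiles_column!r}")
        raw = [(i + 2, s) for i, s in enumerate(df[smiles_column].astype(str))]
    else:
        raise ValueError(f"unknown format {fmt!r}")

    out, bad = [], []
    for ln, smi in raw:
        if Chem.MolFromSmiles(smi) is None:
            bad.append(ln)
            continue
        out.append(smi)
    if bad:
        logger.warning("%d unparsable line(s) skipped: %s", len(bad), bad[:20])
    if not out:
        raise ValueError(
            f"no parseable molecules in {path} (bad lines: {bad[:20]})"
        )
    return out


def write_molecules(path: str | Path, smiles: list[str]):
    Path(path).write_text("".join(s + "\n" for s in smiles))


def save_library(path: str | Path, lib: FragmentLibrary):
    Path(path).write_text(json.dumps(lib.to_json(), indent=2))


def load_library(path: str | Path) -> FragmentLibrary:
    return FragmentLibrary.from_json(json.loads(Path(path).read_text()))


def save_matrix(path: str | Path, sim: SimilarityMatrix):
    np.savetxt(path, sim.values, delimiter=",", fmt="%.10g")


def load_matrix(path: str | Path) -> SimilarityMatrix:
    return SimilarityMatrix(np.atleast_2d(np.loadtxt(path, delimiter=",")))


def save_tree(path: str | Path, tree: FragmentTree):
    Path(path).write_text(json.dumps(tree.to_json(), indent=2))


def load_tree(path: str | Path) -> FragmentTree:
    return FragmentTree.from_json(json.loads(Path(path).read_text()))
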