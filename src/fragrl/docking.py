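"""Master/worker docking task farm behind a generic executor contract.

Roles from the scheduling scheme (a master distributing targets, ligand
managers feeding compute workers) are modeled over a thread-pool work queue:
tasks are the cartesian product of targets and ligands, every task yields
exactly one result, failed engine calls are retried up to a limit, and with a
deterministic engine the results are identical for any worker count.

Engines are adapters: the bundled mock engine is a pure seeded function of
(target_ref, ligand_ref, seed); a command adapter shells out to an external
docking binary and parses the score with an adapter-supplied regex.
"""

from __future__ import annotations

import hashlib
import re
import subprocess
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

from rdkit import Chem

__all__ = ["DockingTask", "DockingResult", "MockEngine", "CommandEngine",
           "plan_tasks", "run_farm", "mock_engine"]


@dataclass(frozen=True)
class DockingTask:
    task_id: int
    target_ref: str
    ligand_ref: str
    pocket: tuple[float, ...] = ()  # (cx, cy, cz, ex, ey, ez) when known


@dataclass
class DockingResult:
    task_id: int
    score: float
    status: str  # "ok" | "failed"
    attempts: int


SCORE_RANGE = (-12.0, -2.0)


def mock_engine(task: DockingTask, seed: int = 0, atom_bias: float = 0.0) -> float:
    """Deterministic pseudo-score in [-12, -2].

    A stable hash of (target_ref, ligand_ref, seed) is mapped into the score
    range; ``atom_bias`` optionally shifts the score by the ligand's heavy-atom
    count (when the ligand_ref parses as SMILES) so that activity labels
    derived from scores are learnable.
    """
    key = f"{task.target_ref}|{task.ligand_ref}|{seed}".encode()
    digest = hashlib.sha256(key).digest()
    u = int.from_bytes(digest[:8], "big") / 2**64
    lo, hi = SCORE_RANGE
    score = lo + u * (hi - lo)
    if atom_bias:
        mol = Chem.MolFromSmiles(task.ligand_ref)
        if mol is not None:
            score -= atom_bias * mol.GetNumHeavyAtoms()
    return min(max(score, lo - 10.0), hi)


@dataclass
class MockEngine:
    """Adapter wrapping :func:`mock_engine`; optionally fails injected tasks."""

    seed: int = 0
    atom_bias: float = 0.0
    fail_once: set[int] = field(default_factory=set)
    deterministic: bool = True
    _failed: set[int] = field(default_factory=set)

    def __call__(self, task: DockingTask) -> float:
        if task.task_id in self.fail_once and task.task_id not in self._failed:
            self._failed.add(task.task_id)
            raise RuntimeError(f"injected failure for task {task.task_id}")
        return mock_engine(task, seed=self.seed, atom_bias=self.atom_bias)


@dataclass
class CommandEngine:
    """Run an external docking command; ``{target}``/``{ligand}`` templated.

    ``score_pattern`` must capture the score as group 1 of the command's
    stdout.  The binary itself is never bundled.
    """

    command_template: str
    score_pattern: str = r"Score:\s*(-?\d+(?:\.\d+)?)"
    timeout: float = 300.0
    deterministic: bool = False

    def __call__(self, task: DockingTask) -> float:
        cmd = self.command_template.format(target=task.target_ref,
                                           ligand=task.ligand_ref)
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True,
                              timeout=self.timeout)
        if proc.returncode != 0:
            raise RuntimeError(f"engine exited {proc.returncode}: {proc.stderr}")
        m = re.search(self.score_pattern, proc.stdout)
        if not m:
            raise RuntimeError("no score in engine output")
        return float(m.group(1))


def plan_tasks(
    targets: list[str],
    ligand_sets: list[list[str]],
    pockets: dict[str, tuple[float, ...]] | None = None,
) -> list[DockingTask]:
    """Cartesian product target x ligand, batched by ligand set, stable order."""
    if not targets or not any(ligand_sets):
        raise ValueError("need at least one target and one ligand")
    pockets = pockets or {}
    tasks = []
    tid = 0
    for ligands in ligand_sets:
        for target in targets:
            for ligand in ligands:
                tasks.append(DockingTask(
                    task_id=tid,
                    target_ref=target,
                    ligand_ref=ligand,
                    pocket=tuple(pockets.get(target, ())),
                ))
                tid += 1
    return tasks


def run_farm(
    tasks: list[DockingTask],
    engine,
    workers: int = 1,
    retry_limit: int = 2,
) -> list[DockingResult]:
    """Execute every task exactly once per attempt, ordered results.

    Each task is retried up to ``retry_limit`` attempts; a task that keeps
    failing yields a ``failed`` result (score NaN) and the farm continues.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")

    def run_one(task: DockingTask) -> DockingResult:
        last_err = None
        for attempt in range(1, retry_limit + 1):
            try:
                score = engine(task)
                return DockingResult(task.task_id, float(score), "ok", attempt)
            except Exception as err:  # engine failures are data, not crashes
                last_err = err
        return DockingResult(task.task_id, float("nan"), "failed", retry_limit) \
            if last_err else None

    if workers == 1:
        results = [run_one(t) for t in tasks]
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(run_one, tasks))
    return sorted(results, key=lambda r: r.task_id)


def aggregate_scores(
    results: list[DockingResult],
    tasks: list[DockingTask],
    how: str = "best",
) -> dict[str, float]:
    """Per-ligand score across targets: 'best' (minimum) or 'mean'."""
    by_ligand: dict[str, list[float]] = {}
    task_by_id = {t.task_id: t for t in tasks}
    for r in results:
        if r.status != "ok":
            continue
        by_ligand.setdefault(task_by_id[r.task_id].ligand_ref, []).append(r.score)
    if how == "best":
        return {k: min(v) for k, v in by_ligand.items()}
    if how == "mean":
        return {k: sum(v) / len(v) for k, v in by_ligand.items()}
    raise ValueError(f"unknown aggregator: {how!r}")
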