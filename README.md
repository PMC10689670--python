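# fragrl

Fragment-based de novo molecular generation with an advantage actor-critic
(A2C) replacement policy.

Molecules are cleaved into **rings, linkers and side chains** (every acyclic
single bond touching a ring atom is cut, attachment points recorded), pooled
into a deduplicated fragment library, and encoded through a **similarity-driven
balanced binary tree**: fragments are paired bottom-up by Tanimoto-MCS
similarity and each fragment's binary code is its root-to-leaf path (left = 1,
right = 0), so similar fragments share code prefixes.

A small **transformer encoder + DNN policy** (implemented on an in-package
NumPy autodiff engine — no deep-learning framework required) maps a molecule's
fragment decomposition to a joint distribution over *(position to replace,
replacement fragment)*; a critic value head drives one-step TD advantage
updates.  Rewards combine chemical validity, an inclusive-bounds
**physicochemical property gate** (defaults: MW 200–500 Da, logP 1.5–5.5,
TPSA 40–120 Å², ≤ 2 toxicophore alerts), and optionally a perceptron activity
classifier over docking-derived features (docking score, heavy-atom count,
their ratio) fed by a master/worker **docking task farm** (seeded mock engine
bundled; external binaries attach through a command adapter).

A full metric suite evaluates generated sets: validity, uniqueness, novelty,
internal diversity (IntDiv_p), Bemis–Murcko scaffold-frequency cosine
similarity, Fréchet distance over pluggable feature extractors, SA and QED.

## Tests

```bash
python -m pytest -q tests/
```

The suite is self-contained: all molecule sets are produced by the seeded
synthetic fixture generator (`fragrl.fixtures`).  `tests/test_acceptance.py`
holds the acceptance criteria (oracle equivalences, tree/code invariants,
A2C recovery on toy tasks, docking-farm contracts, ablation checks).

## CLI

```bash
fragrl fixtures -n 50 --seed 1 --out mols.smi            # synthetic molecules
fragrl fragment --input mols.smi --out library.json --sim-matrix sim.csv
fragrl tree build --library library.json --sim sim.csv --out tree.json
fragrl train --config cfg.yaml --seeds mols.smi --seed 17 --out runs/exp1/
fragrl generate --checkpoint runs/exp1/policy.ckpt -n 10000 --time 3 --out gen.smi
fragrl evaluate --gen gen.smi --ref mols.smi --out metrics.json
fragrl dock --targets targets.txt --ligands gen.smi --engine mock --workers 8 --out scores.csv
```

Configuration is YAML with strict key checking; all defaults (property
ranges, reward weights, model dims, RL hyperparameters, the per-episode
`time` replacement count and its optional plateau schedule, and the
`use_property_optimization` ablation switch) are materialized and echoed into
the run directory.  Example:

```yaml
seed: 17
model: {heads: 4, blocks: 2, d_f: 64, d_p: 16}
reward:
  ranges: {MW: [200, 500], logP: [1.5, 5.5], PSA: [40, 120], T: [0, 2]}
train: {epochs: 100, batch_size: 32, time: 2, use_property_optimization: true}
```

Note: ligand efficiency (LE) is defined here as `-score/heavy_atoms` (the
negated perceptron ratio feature) and participates in the gate only when
docking is enabled and an LE range is configured.

## Layout

```
src/fragrl/
  fragmentation.py  cleavage, fragment library, Tanimoto-MCS similarity
  tree.py           balanced-binary-tree fragment encoding
  assembly.py       decomposition state, replacement, reassembly, scaffolds
  nn.py             minimal NumPy reverse-mode autodiff + Adam
  policy.py         transformer encoders, actor/critic heads, sampling
  rewards.py        property gate, toxicophore screen, perceptron, reward mix
  a2c.py            episodes, advantages, updates, training loop, generation
  metrics.py        validity/uniqueness/novelty/IntDiv/Scaff/FCD/SA/QED
  docking.py        task farm, mock + command engine adapters
  fixtures.py       seeded synthetic molecule generator
  config.py, io.py, cli.py
```
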