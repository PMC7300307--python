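# topofold

Topological feature vectors for protein-folding trajectories:
alpha-complex persistent homology with volume-optimal cycles,
nonnegative matrix factorization of the resulting features, and
flow-field analysis of the reduced-space dynamics.

## The problem

Identifying folding states in a molecular-dynamics trajectory requires a
representation of molecular shape that (i) responds to *global*
structural change — a hairpin closing, a sheet forming — rather than to
the large but uninformative Cartesian fluctuations of an unfolded chain,
and (ii) has a fixed dimension, so that standard machine-learning
methods apply even though the number of structural motifs varies from
snapshot to snapshot.

`topofold` builds such a representation from persistent homology.  For
a snapshot of n atoms (typically the C&alpha; trace), grow a ball of
radius r around every atom; as r increases, loops appear ("birth" b)
and are filled in ("death" d).  Each loop — a *generator* of degree-1
homology — is resolved to its **volume-optimal cycle**: the boundary of
the smallest set of triangles that fills it, which names the exact
atom-pair edges forming the loop.  The **topological feature vector**
(TFV) v has one slot per unordered atom pair, M = n(n&minus;1)/2 slots
in total:

        v[(i,j)] = sum of d_k over generators g_k whose
                   volume-optimal cycle contains edge (i,j)

(with births b_k or lifetimes d_k&minus;b_k as alternative weights), and
0 for edges used by no cycle.  A trajectory becomes a nonnegative
M&times;N matrix **V** of TFV columns, factorized as **V** &asymp; **WH**
by NMF (Frobenius objective, deterministic NNDSVD initialization,
coordinate descent): the columns of **W** (rescaled to unit norm) are
interpretable loop patterns — e.g. "the hairpin closed at pair 2&ndash;9" —
and the rows of **H** are &Aring;-scale coordinates of every frame in
the reduced space.  The rank L is chosen at the inflection of the
residual-sum-of-squares curve over L = 1..L_max.  Finally the one-step
displacements &delta;h(t) = h(t+&delta;t) &minus; h(t), grid-averaged
over 1.5&times;1.5 &Aring; cells, give a flow field whose stable fixed
points are the metastable folding states and whose saddle is the
transition state.

Everything is testable without external data: a synthetic generator
produces 10-bead hairpin chains with two alternative contact states
(a native-like loop closed at pair 1&ndash;8, 0-based, and a misfolded
loop at 1&ndash;7), an extended unfolded state, and Markov switching
between them.

## Worked example

```python
import numpy as np
from topofold import (TrajectorySpec, generate_two_state_trajectory,
                      TopologicalFeaturizer, nmf_decompose, basis_report)

spec = TrajectorySpec(seed=7, n_frames=500)
traj = generate_two_state_trajectory(spec)
X = TopologicalFeaturizer(mode="death").transform(traj.coords)
print(f"TFV matrix: {X.shape[0]} frames x {X.shape[1]} edge slots")

model = nmf_decompose(X.T, rank=2)
print(f"rank-2 NMF residual: {model.rss / (X**2).sum():.4f} (relative)")
for k, entries in enumerate(basis_report(model, n=spec.n)):
    top = ", ".join(f"{i}-{j}: {w:.2f}" for (i, j), w in entries[:3])
    print(f"w{k+1} leading edges  {top}")
```

prints

```
TFV matrix: 500 frames x 45 edge slots
rank-2 NMF residual: 0.0430 (relative)
w1 leading edges  1-8: 0.36, 7-8: 0.36, 2-3: 0.35
w2 leading edges  1-2: 0.38, 6-7: 0.38, 1-7: 0.38
```

The 10-bead chain has 45 atom pairs, so every frame maps to a 45-slot
TFV regardless of how many loops it contains.  Two NMF bases explain
96% of the signal; each loads on the backbone edges of one hairpin
*plus its distinguishing contact* — basis w1 on pair 1&ndash;8 (the
native-like loop), basis w2 on pair 1&ndash;7 (the misfolded loop).
Classifying frames by the larger coefficient (argmax over h) recovers
the planted state label of every folded frame in this run, and
unfolded frames sit near h &asymp; 0 because an extended chain forms
no loops.

The same pipeline runs from the shell:

```sh
topofold simulate -o run/ --seed 7 --frames 2000
topofold report -i run/trajectory.xyz -o run/out --rank auto --seed 7
```

writing persistence pairs and cycles, the TFV matrix, NMF/PCA models,
the rank-scan curve, the flow field and a fixed-point summary as CSV
(plus a `tfv.npz` NumPy container mirroring `tfv.csv`).  Every header
records the edge-index convention `slot(i,j) = i*n - i(i+1)/2 +
(j-i-1)` and the units (&Aring;, ps).

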