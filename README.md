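# sfstrat

Similarity-stratified benchmarking of protein–ligand binding-affinity
scoring functions.

## The problem

Machine-learning scoring functions (random forests, gradient-boosted
trees) outperform classical linear scoring functions on community
benchmarks such as CASF — but training sets compiled from the PDBbind
refined set inevitably contain complexes similar, sometimes nearly
identical, to the test complexes. How much of the ML advantage survives
when that similarity is controlled?

`sfstrat` answers this by *stratifying* the training set. Given a fixed
test set TS, the full training set OT, and a train×test similarity
matrix, it builds nested training sets over a cutoff grid *c*:

- dissimilar-first (`ds`), for a similarity metric *s* ∈ [0, 1]:
  NT(c) = { p ∈ OT : ∀ q ∈ TS, s(p, q) ≤ c },  so NT(1) = OT;
- for a dissimilarity metric *d* ∈ [0, ∞):
  NT(c) = { p ∈ OT : ∀ q ∈ TS, d(p, q) ≥ c },  so NT(0) = OT;
- similar-first (`sd`): the complementary sets
  { p : ∃ q, s(p, q) > c } and { p : ∃ q, d(p, q) < c }.

At every cutoff the `ds` and `sd` sets partition OT. Three similarity
channels are supported: protein-structure similarity (TM-score from
whole-complex alignment, ingested as a precomputed matrix), ligand
ECFP4-fingerprint Tanimoto similarity, and binding-pocket topology
city-block dissimilarity (both computed here). Default cutoff grids:
protein 0.40→1.00 step 0.01 (61 cutoffs), ligand 0.50→1.00 step 0.01
(51), pocket 10.0→0.0 step 0.2 (51).

Eight scoring functions are retrained on every nested set and evaluated
on the held-out test set by Pearson correlation (Rp), Spearman
correlation (Rs) and RMSE in pK units:

| name | model | features |
|---|---|---|
| `MLR::Xscore` | consensus of three OLS fits (hydrophobic term HP/HM/HS varies) | VDW, HB, RT, HP, HM, HS |
| `MLR::Vina` | OLS on five terms normalized by 1 + w·Nrot (w fixed at 0.05846) | gauss1, gauss2, repulsion, hydrophobic, hbond, Nrot |
| `MLR::Cyscore` | OLS | 4 Cyscore terms |
| `RF::Xscore` / `RF::Vina` / `RF::Cyscore` | random forest, 500 trees | same subsets |
| `RF::XVC` | random forest | all 16 combined |
| `XGB::XVC` | gradient boosting, 500 rounds | all 16 combined |

The sweep traces performance against the cutoff and reports *crossing
points* (the first cutoff where an ML variant strictly beats its linear
counterpart) and *sharp leaps* (the per-step increments, typically
maximal over the final (0.99, 1] band where near-duplicate training
complexes concentrate).

A fully synthetic benchmark generator (`sfstrat.synthetic`) reproduces
the statistical structure this analysis depends on — clustered
complexes, a skewed similarity distribution with a planted near-duplicate
band, affinities with linear plus cluster-specific nonlinear components —
so the entire pipeline runs and is testable without any download.

## Worked example

```python
import numpy as np
from sfstrat import (SynthConfig, generate_benchmark, build_family,
                     CutoffSchedule, ModelSpec, sweep, find_crossing)

bench = generate_benchmark(SynthConfig(seed=1))      # 3000 train / 300 test
family = build_family(bench.matrices["protein_structure"],
                      CutoffSchedule(0.40, 1.00, 0.05), "ds")
curves = sweep([ModelSpec("MLR::Xscore"), ModelSpec("RF::Xscore")],
               family, bench.train_features, bench.train_affinities,
               bench.test_features, bench.test_affinities, global_seed=1)
for c in curves:
    rp = c.series("rp")
    print(f"{c.sf_name}: Rp {rp[0]:.3f} at c=0.40 -> {rp[-1]:.3f} at c=1.00")
print(find_crossing(curves[1], curves[0], "rp"))
```

prints

```
MLR::Xscore: Rp 0.656 at c=0.40 -> 0.675 at c=1.00
RF::Xscore: Rp 0.596 at c=0.40 -> 0.925 at c=1.00
CrossingPoint(sf_a='RF::Xscore', sf_b='MLR::Xscore', metric='rp',
              cutoff=0.55, n_train=1212, sustained=True)
```

The linear recalibration is flat across the sweep (it has no capacity to
exploit increasingly similar training complexes), while the forest's Rp
rises by 0.33 — overtaking the linear model at cutoff 0.55, long before
near-duplicates enter — and takes its largest single step over the final
(0.95, 1.00] increment, where the planted 25% near-duplicate mass joins
the training set.

The same analysis runs from the shell on a YAML config:

```sh
sfstrat synth   --config run.yaml --out bench/   # write benchmark files
sfstrat report  --config run.yaml                # families, sweep, crossings, manifest
```

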