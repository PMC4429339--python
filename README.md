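# phagenet

Structure analysis of binary phage–bacteria infection networks: nestedness,
bipartite modularity, null-model significance testing and two-way cluster
analysis.

## The problem

Bacteriophage typing schemes classify bacterial strains (phage types, PTs)
by their lysis profile across a fixed panel of typing phages (TPs).  The
resulting presence/absence table is a bipartite network `A_ij ∈ {0,1}`
("does phage *j* lyse type *i*?") whose architecture carries biological
signal: **modularity** (groups of phages specialised on groups of hosts)
and **nestedness** (specialists' host ranges contained within
generalists').  `phagenet` quantifies both, judges them against chance,
and reproduces the classical two-way cluster layout of such schemes — for
microbiologists and network ecologists working with infection assays like
the *E. coli* O157 typing scheme (66 PTs × 16 TPs).

## What it computes

* **Nestedness** (all scored so 0 = perfectly nested):
  rescaled NODF = `100 − NODF`; nestedness temperature (NTC) from the
  fill-matched isocline of perfect nestedness; BR, the Brualdi–Sanderson
  discrepancy against the maximally packed matrix.
* **Bipartite modularity**: Barber's
  `Q_B = (1/F) Σ_ij (A_ij − k_i d_j/F) δ(g_i, h_j)`, maximised by LPAb+
  (label propagation + greedy agglomeration, best of many seeded trials).
* **Null models**: model 1, Bernoulli `p_ij = F/M`; model 2, Bernoulli
  `p_ij = 0.5(d_j/r + k_i/c)`; one-sided p-values `(b+1)/(N+1)` and
  z-scores in each measure's structured direction (z > 0 = more modular,
  z < 0 = more nested than the ensemble).
* **Two-way clustering**: Euclidean/Ward dendrograms of both axes,
  Wishart information-remaining scaling, MRPP A-statistic screening of
  group number, and the reordered matrix.
* **Synthetic matrices** with planted structure (random, nested,
  modular, and a 66×16 typing-scheme analogue with phage groups of sizes
  6/4/4/2) so every stage is testable with known ground truth.

## Worked example

```python
from phagenet import (AnalysisConfig, gen_typing_like, run_full_analysis)

matrix, planted = gen_typing_like(seed=1)      # 66 PTs x 16 TPs
cfg = AnalysisConfig(trials=200, null_trials=5, ensemble_size=200,
                     adaptive=False, seed=1)
report = run_full_analysis(matrix, cfg)
print(report.table())
```

```
measure    score       model  N      p-value     z-score
QB         0.2684      1      200    <1/200      12.2168
QB         0.2684      2      200    <1/200      14.5928
NODF       36.4205     1      200    <1/200      -8.9383
NODF       36.4205     2      200    <1/200      -5.1646
NTC        25.8931     1      200    <1/200      -14.3276
NTC        25.8931     2      200    <1/200      -7.6632
BR         99.0000     1      200    <1/200      -20.0953
BR         99.0000     2      200    <1/200      -11.6075
```

Reading this: the analogue scheme is weakly but highly significantly
modular (`Q_B = 0.27`, four modules, z ≈ +12 against the uniform null)
*and* significantly nested (all three nestedness scores far below their
null means, z ≈ −5 to −20) — the modular-plus-nested coexistence typical
of designed typing panels.  No null replicate matched either structure,
so p-values are bounded at `< 1/N`.  The same pipeline runs on any
labelled CSV/TSV binary matrix via `read_matrix` or the CLI:

```sh
phagenet simulate --kind typing-like --seed 1 --out matrix.csv
phagenet analyse --matrix matrix.csv --seed 1 --ensemble-size 200 \
    --trials 200 --null-trials 5 --out-dir results/
phagenet cluster --matrix matrix.csv --seed 1 --out-dir results/
```

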