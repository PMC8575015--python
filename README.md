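# markerpanel

Selecting a small panel of marker genes that can tell many cell types apart
is a core step in designing cell-sorting experiments (FACS antibody panels,
lineage-reporter sets) and in summarizing large expression atlases. Picking
each cell type's single most specific gene ignores two things: markers work
in *combinations*, and the cell types themselves sit in a hierarchy whose
structure a good panel should preserve. `markerpanel` selects a fixed-size
panel by solving a mixed-integer linear program that does both at once.

## The model

Given expression profiles S (m cell types × n genes), every unordered pair
of cell types (i, j) and gene l gets a distinguishability score

    y_ijl = (S_il + 1)/(S_jl + 1)  (the larger-over-smaller, pseudocounted
                                    fold change, always ≥ 1)
    z_ijl = 1 / (1 + exp(−θ (y_ijl − y₀)))        θ = 10, y₀ = 3

so z ≈ 0 when the gene cannot separate the pair and z ≈ 1 when it can.
Each gene also gets a specificity score ss_l = max_j −log₁₀ JSD(u_jl, v_jl),
comparing its observed expression pattern in cell type j against an
idealized "all mass in j" pattern (JSD in base 2; the background is the
gene's third-quartile expression across cell types).

With binary selection variables w_l and pair slacks ξ_ij, the panel of size
k minimizes

    D − Σ_{i<j} d_ij  +  λ Σ_{i<j} ξ_ij  −  μ Σ_l w_l ss_l
    s.t.  d_ij = Σ_l w_l z_ijl,   Σ_l w_l = k,
          (1/k) d_ij + ξ_ij ≥ (1/n) Σ_l z_ijl,   w_l ∈ {0,1}, ξ_ij ≥ 0

— keep the total and per-pair normalized cell-type distances of the panel
close to those of the full gene set (topology preservation) while rewarding
individually specific genes. μ = 0 gives pure distance-preserving feature
selection; μ = λ = 0 is multidimensional-scaling-style feature selection.
For genome-scale inputs an LP relaxation replaces w ∈ {0,1} with w ≥ 0 and
an L1 penalty λ Σ w_l, solvable in seconds for millions of candidates.

Panels are scored by three accuracy criteria (fraction of cell-type pairs
with panel distance > 0.5; with ≥ 1 distinguishing gene; with ≥ 2), and a
selected panel can be turned into a cell-type association network (kernel
mutual information between panel-restricted profiles, greedy modularity
modules).

## Worked example

Simulate 8 cell types on a balanced hierarchy with one planted marker per
internal split (fold change 8, log-normal noise σ = 0.2) plus 50 background
genes, then select a 7-gene panel:

```bash
$ markerpanel simulate --cell-types 8 --background 50 --seed 1 --out demo
simulated 8 cell types × 57 genes (7 planted markers); outputs at demo.*

$ markerpanel select demo.matrix.tsv --k 7 --lambda 100 --mu 10 --out demo.panel.tsv
selected 7 genes: marker0, marker1, marker2, marker3, marker4, marker5, marker6
objective -67.9108 (optimal); report at demo.panel.tsv
```

The solver recovers exactly the 7 planted markers: the objective −67.91 is
dominated by the −μ Σ ss_l specificity reward, and the panel's accuracy
criteria (written to the JSON sidecar) are C1 = 1.0 and C2 = 1.0 — every
pair of cell types is separated by at least one selected gene — with
C3 = 0.75: sibling leaves are split by only their single subtree marker, so
a second corroborating gene exists for 21 of the 28 pairs. The same
library calls are available in Python:

```python
import markerpanel as mp

em, truth = mp.simulate_expression(mp.default_spec(seed=1))
zt = mp.difference_tensor(em)
ss = mp.specificity_scores(em)
sol = mp.solve_mip(mp.PanelProblem(zt, ss.ss_l, k=7, lambda_=100, mu=10))
panel = [em.gene_ids[i] for i in sol.selected]
mp.recovery_report(panel, truth).recall   # 1.0
```

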