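# gfex

Gene-family extension (GFE) analysis for prokaryotic genome × COG count
matrices: how strongly has each genome's gene complement been extended by
duplication, how do genomes rank by that, and which genomes are atypical
for their size?

The input is a matrix `A` whose entry `A[i, j]` counts the genes of genome
*i* in orthologous group (COG) *j* — genome *i*'s gene-family size in that
group — plus a metadata table of genome sizes in Mbp. From it the package
computes, per genome with family sizes `s_1..s_K'` (zeros = absent family,
always ignored):

* **ave** `= (Σ s_j) / K'` — mean gene-family size (singletons included);
* **p.i.** `= P / K'` — paralog index, the fraction of families with ≥ 2
  copies;
* **mp** `= P2 / P` — multi-paralog index, the fraction of duplicated
  families with > 2 copies (undefined for all-singleton genomes);
* **rank** — a consensus genome ranking (1 = fewest paralogs) aggregating
  the partial rankings induced by every COG, by minimising the summed
  Kendall tau disagreement (the Kemeny objective) with a restarted
  adjacent-swap sorting heuristic; an exhaustive exact solver is included
  for small instances.

Each measure is then regressed on genome size (polynomial degree 1–10,
AIC- or BIC-selected), genomes falling outside the boxplot whiskers of the
residuals (`Q1 − 1.5·IQR`, `Q3 + 1.5·IQR`, Tukey hinges) are flagged as
atypical, and the measures' pairwise agreement is quantified by partial
Kendall tau-b controlling for genome size. A seeded synthetic-matrix
generator with planted atypical genomes makes the whole pipeline testable
without external data. See `docs/methods.md` for the full model account.

## Worked example

The package ships a published 3-genome × 5-COG illustration on which the
measures deliberately disagree (family sizes A: 1,1,1,1,16 — B: 1,1,2,2,4 —
C: 1,1,1,6,6):

```python
import gfex
from gfex.datasets import load_fictional_example

matrix, metadata = load_fictional_example()
print(gfex.gfe_profile_table(matrix).to_string(index=False))
result = gfex.s_rank(matrix, n_restarts=10, seed=17)
print("consensus:", " < ".join(result.consensus_order),
      "objective:", result.objective)
```

prints

```
genome_id  K_prime  P  P2  ave  p_i       mp
        A        5  1   1  4.0  0.2 1.000000
        B        5  3   1  2.0  0.6 0.333333
        C        5  2   2  3.0  0.4 1.000000
consensus: A < B < C objective: 3
```

Reading: genome A has one duplicated family out of five (p.i. 0.2) but it
is huge (16 copies), so A tops the `ave` ordering while sitting lowest on
`p.i.`; B is the opposite. The consensus ranking A < B < C attains Kemeny
objective 3 — three pairwise contradictions against the five per-COG
rankings — which the exhaustive solver (`gfex.exact_kemeny`) confirms is
the unique optimum. No single measure tells the whole story, which is why
all four are computed side by side.

The same stages run from the shell via the `gfe` CLI
(`gfe simulate`, `gfe indices`, `gfe rank`, `gfe trend`, `gfe pcor`, and
`gfe run` for the full pipeline writing TSVs plus a manifest).

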