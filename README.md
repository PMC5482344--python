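# dtnet — edge-colored bipartite drug-target network analysis

`dtnet` analyses drug-target interaction data as an **edge-colored bipartite
network**: a set of drugs D = {d₁…dₙ}, a disjoint set of targets
T = {t₁…tₘ}, and for every one of the n·m pairs exactly one of three edge
colors — *active* (green: the measured or estimated activity meets the
threshold), *inactive* (red: it does not), or *unknown* (black: the pair has
never been determined). It is aimed at cheminformaticians and chemogenomics
researchers who need to quantify how much a public interaction dataset
actually says — and how much it leaves open — before drawing conclusions
about drug promiscuity or target selectivity.

## The model

The ternary status matrix decomposes into three binary biadjacency matrices
that partition the pair set:

    a₊(dᵢ,tⱼ) + a₋(dᵢ,tⱼ) + a⋆(dᵢ,tⱼ) = 1   for all i, j.

Row and column sums of the active matrix **A₊** are the degrees of
**polypharmacology** π̂_PP(dᵢ) (how many targets a drug hits) and
**polyspecificity** π̂_PS(tⱼ) (how many drugs hit a target). The two are
mathematical duals: transposing the network swaps the drug and target
perspectives without losing information, so the polyspecificity of a target
equals its polypharmacology in the transposed network.

Because databases report mostly actives, absent pairs are *unknown by
omission*, and the package quantifies the resulting uncertainty:

- **Global completeness** C_DT = (μ̂₊ + μ̂₋)/(n·m), the fraction of all
  pairs that has been determined.
- **Local uncertainty** ε̂(x) = number of an entity's unknown pairs,
  equivalently |T| − π̂_PP(dᵢ) − k̂₋(dᵢ) for a drug (and symmetrically for
  targets).
- **Degree bounds**: if the determinations themselves are correct, the true
  degree satisfies π̂ ≤ π ≤ π̂ + ε̂ — the observed active degree assumes all
  unknowns inactive, the upper bound assumes them all active. Every new
  determination tightens (never widens) these intervals.

## Worked example

The package ships an illustrative 8-drug × 4-target network with 19 active,
7 inactive and 6 unknown pairs:

```python
>>> import dtnet
>>> net = dtnet.load_worked_example()
>>> net
EdgeColoredNetwork(8 drugs x 4 targets, 19 active / 7 inactive / 6 unknown)
>>> rep = dtnet.global_completeness(net)
>>> (rep.mu_plus, rep.mu_minus, rep.mu_star, rep.c_dt)
(19, 7, 6, 0.8125)
>>> dtnet.degree_bounds(net, "d3", "drug")
DegreeBounds(entity_id='d3', side='drug', lower=1, upper=3)
```

Drug d3 is observed active against one target with two pairs undetermined,
so its true polypharmacology lies between 1 and 3. The same analysis from
the shell:

```sh
$ dtnet completeness -i fixture.csv -f matrix
mu_plus	19
mu_minus	7
mu_star	6
c_dt	0.813
$ dtnet summarize -i fixture.csv -f matrix
entity	side	active	inactive	unknown	lower_bound	upper_bound
d1	drug	3	0	1	3	4
d2	drug	2	1	1	2	3
d3	drug	1	1	2	1	3
...
```

26 of the 32 pairs are determined, so C_DT = 26/32 = 0.8125, printed as
0.813 at three decimals (half-up). Other subcommands: `bounds`, `profile`,
`decompose`, `convert` (edge list ↔ status matrix), `export-graphml`, and
the seeded `simulate` / `mask` generators that fabricate ground-truth
networks and database-style incomplete views of them.

## File formats

- **Edge list** (TSV/CSV, header required): columns `drug`, `target`, and a
  `status` token (`active`/`inactive`/`unknown`, or `1`/`0`/`?`) or a
  numeric `value` with optional `unit` (canonical μM; nM/mM converted).
  `#` lines are comments. Unlisted pairs become unknown.
- **Status matrix** (CSV): target labels across the top, drug labels down
  the first column, cells `1`/`0`/`?`.
- **GraphML**: bipartite graph with node attribute `part` and edge
  attributes `status` and `color` (green/red/black).

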