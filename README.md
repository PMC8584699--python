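# comgapfill

Community-level gap-filling for genome-scale metabolic models.

Draft metabolic reconstructions — especially of organisms that only grow in
consortia — usually contain gaps: missing reactions that leave the model
unable to produce biomass. Classical gap-filling repairs each model in
isolation, which over-adds reactions precisely when the organism in nature
relies on its neighbours for metabolites. `comgapfill` instead gap-fills
all members of a community **together**: organisms share a common
extracellular metabolite pool, so a metabolite secreted by one member can
substitute for a missing pathway in another, and the repair set the method
proposes is the smallest one consistent with the whole community growing.
Alongside the repairs, the method predicts which metabolites are
cross-fed — a hypothesis generator for interactions that are hard to
observe experimentally.

## The optimization problem

For a community of `N` organisms, each member `n` contributes a compartment
holding its own reactions `J_Model^n` plus candidate reactions
`J_Database^n` from a curated universal database. A binary `y_j^n` gates
each candidate. The MILP is

```
min  Σ_n Σ_{j ∈ J_Database^n}  y_j^n
s.t. Σ_j S_ij^n v_j^n = 0                      ∀ i ∈ I^n, ∀ n   (steady state)
     lb_j^n ≤ v_j^n ≤ ub_j^n                   ∀ j ∈ J_Model^n
     y_j^n lb_j^n ≤ v_j^n ≤ y_j^n ub_j^n       ∀ j ∈ J_Database^n
     v_Biomass^n ≥ v_Biomass^n,min             ∀ n               (growth floors)
     −v_ex(i)^c + Σ_n w_n v_ex(i)^n = 0        ∀ i ∈ I^c         (pool balance)
     y_j^n ∈ {0, 1}
```

where `v_ex(i)^n` is member `n`'s transfer of pool metabolite `i`,
`v_ex(i)^c` the environment exchange bounded by the medium, and `w_n = 1`
(or the member's relative abundance in the weighted variant, which restores
a community-level mass balance when member fluxes are per-gDW).

Before the MILP, every candidate's flux range is computed by per-compartment
FVA under a sound relaxation (growth floor dropped to zero, all pool
transfers open): candidates that can never carry flux are deleted and the
rest get tight bounds, which shrinks the MILP without changing its optimum.
Alternative optima are enumerated with integer cuts on the added-reaction
support, so results are reproducible with free solvers (HiGHS via scipy).

## Worked example

Two chain-metabolism organisms, one planted gap each; member 1 can obtain a
bypass metabolite that member 0 secretes, so only one database reaction is
truly needed:

```python
from comgapfill import build_community
from comgapfill.fixtures import FixtureSpec, make_linear_fixture
from comgapfill.fva import reduce_community
from comgapfill.gapfill import formulate, enumerate_alternatives
from comgapfill.reporting import extract_exchanges

fx = make_linear_fixture(FixtureSpec(
    n_members=2, chain_length=4, n_db_total=4,
    planted_gaps={0: [2], 1: [1]}, planted_exchanges=[(0, 1)], seed=2))
cm, _ = reduce_community(build_community(fx.members(), fx.database, fx.medium))
res = enumerate_alternatives(formulate(cm), k=3)
print(res.best.objective_value, res.best.added)
print(extract_exchanges(res, cm).edges)
```

prints

```
1 {'org0': ['CH0_2'], 'org1': []}
   solution_rank producer consumer metabolite  magnitude
0              1     org0     org1      x0_01        0.1
```

— one reaction repairs member 0's own gap, while member 1's gap is covered
by cross-feeding of the planted metabolite `x0_01` (0.1 flux units, exactly
its growth requirement), not by another addition.

The same pipeline is available from the shell
(`comgapfill make-fixture | curate-db | build-community | fva-prune |
gapfill | report | run`); `comgapfill run config.json -o out/` writes
solution JSONs, exchange/addition tables, gap-filled models, and a run
manifest.

`scripts/reproduce_toy_ecoli.py` rebuilds the classic two-strain *E. coli*
acetate cross-feeding community from the bundled core model and gap-fills
it (optionally against the downloadable BiGG universal database); run it
with `--help` for details and caveats.

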