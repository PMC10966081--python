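# ben4topo

Degree-based topological indices, graph entropies and logarithmic
regression for the beryllonitrene **BeN4(m, n)** network — with a full,
audited reproduction of the reference tabulations for that network,
including the places where they are internally inconsistent.

## The problem

Beryllonitrene is a planar Be–N sheet. For a patch of `m × n` unit
cells its molecular graph has `5mn + m + n + 1` vertices and `8mn − n`
edges, and — because every index treated here is degree-based — it is
fully described by its *edge partition*: the count of edges joining
each unordered pair of endpoint degrees, e.g. `(3,3): 4mn − 3n`.

Three layers are built on that partition:

1. **Topological indices.** Fourteen descriptors of the form
   `TI(G) = Σ_{uv ∈ E} w(d_u, d_v)` with symmetric weights `w`:
   the Randić family `(d_u·d_v)^α` for α ∈ {1, −1, ½, −½}, ABC
   `√((d_u+d_v−2)/(d_u·d_v))`, GA `2√(d_u·d_v)/(d_u+d_v)`, the Zagreb
   indices M₁ `d_u+d_v`, M₂ `d_u·d_v`, HM `(d_u+d_v)²`, the forgotten
   index F `d_u²+d_v²`, AZI `((d_u·d_v)/(d_u+d_v−2))³`, and the
   redefined Zagreb indices ReZG₁–₃. Each index is computed two ways:
   **canonical** (edge partition × weights) and **published** (the
   closed-form polynomial `c_mn·mn + c_m·m + c_n·n + c₀` printed for
   this network, transcribed verbatim). The two provably disagree —
   canonical M₁(1,1) = 30 vs published 24 — and the package quantifies
   that gap in a *discrepancy ledger* rather than hiding it.
2. **Graph entropy.** The Shannon entropy of the edge-weight
   distribution `p(e) = w(e)/W`,
   `ENT = ln W − (1/W)·Σ Θ_i·w_i·ln w_i` (natural log), maximal at
   `ln|E|` exactly when all weights are equal.
3. **Regression.** OLS fits of `ENT = β₀ + β₁·ln(TI)` (and a
   comparison power model `ENT = a·TI^b`) over the diagonal grid
   m = n = 1…10, with curve-estimation goodness statistics
   (R, R², SE, F, p). GA's entropy is almost exactly log-linear in GA,
   making it the best complexity predictor among the 14.

Arbitrary simple graphs (plain-text edge lists, networkx graphs) go
through the identical pipeline via `partitions_from_graph`.

## Worked example

```python
from ben4topo import discrepancy, ben4_entropy, index_series, entropy_series, log_fit

d = discrepancy("M1", 1, 1)
print(d.canonical, d.published, d.difference)   # 30.0 24.0 6.0

print(ben4_entropy("GA", 1, 1, mode="published"))  # 1.7838614070292427

grid = [(i, i) for i in range(1, 11)]
fit = log_fit(index_series("GA", grid).to_numpy(),
              entropy_series("GA", grid).to_numpy())
print(round(fit.beta1, 3), round(fit.beta0, 3), round(fit.SE, 4))
# 0.989 0.072 0.0107
```

The first line shows the canonical/published gap for the first Zagreb
index on the single unit cell; the second reproduces the GA entropy
anchor value; the fit says the GA entropy series is `0.072 + 0.989·ln(GA)`
to a residual standard error of ~0.011 over the ten diagonal patches.

Longer narrative scripts live in `examples/` (one per capability:
indices, entropies, regression, the one-shot table reproduction, and
the generic-graph path). `examples/04_reproduce_tables.py` writes every
recomputed table plus the discrepancy ledger and the cell-level audit to
CSV.

## A note on the (3,3) edge class

The tabulated (3,3)-class count is `4mn − 3n`, but the published
polynomials and entropy/goodness tables are mutually consistent with
`4mn − 4n` instead (exactly so for every integer-coefficient index
except ReZG₃). The tabulated count stays the default everywhere; pass
`freq33=ben4topo.reconciled_freq33` to reproduce the published surface.
The GA rows are insensitive to this choice (GA's (3,3) weight is
exactly 1), which is why they anchor the audit. See `docs/methods.md`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the slope and intercept of the GA
logarithmic fit (published-mode full-precision series, diagonal grid
m = n = 1…10) and writes them as JSON. The computation is
deterministic; the seed is accepted for interface uniformity.
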