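# Methods

## The model: degree partitions as the structure

Every quantity in this package is a function of the degree-level
summary of a graph, not of its embedding. For BeN4(m, n) the package
deliberately does **not** construct an explicit lattice adjacency: the
published description of the network consists of a picture plus the
partition tables, and any concrete embedding consistent with them would
be guesswork. The partitions *are* the structure:

| quantity | closed form (m, n ≥ 1) |
|---|---|
| vertices | 5mn + m + n + 1 |
| edges | 8mn − n |
| degree-1 vertices | 4 |
| degree-2 vertices | 2m + 4n − 4 |
| degree-3 vertices | 4mn − 2n |
| degree-4 vertices | mn − m − n + 1 |
| (1,2) edges | 2 |
| (1,3) edges | 2 |
| (2,2) edges | 2n − 2 |
| (2,3) edges | 4m + 4n − 6 |
| (3,3) edges | 4mn − 3n (tabulated; see below) |
| (3,4) edges | 4mn − 4m − 4n + 4 = 4(m−1)(n−1) |

Restricting m, n ≥ 1 makes every count provably non-negative. The
partitions satisfy the handshake identity
(Σ d·V_d = 16mn − 2n = 2|E|) and the second-moment identity
(Σ Θ·(a+b) = Σ d²·V_d = 52mn − 8m − 18n + 4); `validate_partitions`
re-derives both numerically for any partition pair, and the test suite
confirms them for all m, n ≤ 20.

Degree pairs are stored unordered, min-first: all fourteen edge
weights are symmetric, so ordered pairs would carry no information.

## Canonical vs published index values

Two evaluation modes are first-class and never silently merged:

* **canonical** — `Σ_classes Θ·w(a,b)` over the tabulated partition.
  This is the mathematically forced value given the partition.
* **published** — the closed-form polynomial printed for this network,
  coefficients transcribed verbatim (`indices.PUBLISHED_POLYNOMIALS`),
  including their defects.

They disagree: the published n-coefficients are systematically offset
from the canonical expansion. `discrepancy()` reports the gap per
index and grid point; `reproduce_all()` writes the full ledger. The
reproduction of the printed tables must use the published mode;
correctness arguments must use the canonical one.

### The (3,3)-frequency finding

Solving `Θ₃₃ = (published − other classes) / w(3,3)` per index
(`reconciling_freq33`) shows the published polynomials correspond to a
(3,3) count of **4mn − 4n**, exactly so for every index whose printed
coefficients are exact integers (R₁, M₁, M₂, HM, F) and to rounding
error for the 4-decimal ones — with one exception: ReZG₃'s polynomial
is inconsistent with *any* single (3,3) count (residual 8(m−1)(n−1),
pointing at an additional slip in its (3,4) term). The same 4mn − 4n
reproduces all fourteen reference entropy rows to ≤ 1.2×10⁻⁴ and the
reference goodness table to its printed 3 decimals.

This is reported as a finding, not adopted as fact: the default
(3,3) count everywhere is the tabulated 4mn − 3n, and the override is
an explicit opt-in (`freq33=reconciled_freq33`). Pass/fail gating of
non-GA entropy cells happens only under the explicit override, so no
acceptance decision rests on a value the source renders ambiguous.

## Entropy

`ENT = ln W − (1/W)·Σ Θ·w·ln w`, natural logarithm throughout. The
source alternates between "log" and "log₂" in display; recomputation
shows the natural log reproduces the GA entropy row to ~10⁻⁴ while
base 2 and base 10 do not, so the natural log is frozen as the
convention (it also makes the regression's ln-transform internally
consistent). Classes with weight 1 contribute zero; the entropy is
invariant under jointly rescaling all weights and W by a positive
constant (checked property-style); and with the canonical normalizer
it is bounded by ln|E| with equality exactly on equal weights — the
published normalizer may violate the bound marginally because W is
then not the true weight total.

The GA row is the audit anchor: GA's (3,3) weight is exactly
`2·√9/6 = 1`, so the GA entropy is provably insensitive to the
ambiguous (3,3) count, and its printed row is reproducible without
taking a side. Comparison tolerance against printed entropy cells is
absolute 2×10⁻³ (the source's own rounding is inconsistent in the 4th
decimal).

## Regression

`log_fit` is OLS of y on ln x (statsmodels); `SE = √(RSS/(n−2))`; F is
the model F statistic with (1, n−2) degrees of freedom, satisfying the
identity `F = (n−2)·R²/(1−R²)`; R carries the slope's sign. The power
model is fitted as OLS of ln y on ln x with `a = exp(intercept)`; its
goodness statistics live on the log-log scale and are not directly
comparable to the log model's (the source's own comparison is
qualitative and so is ours).

Regression inputs are always the full-precision recomputed series,
never the 2- or 4-decimal display values: slope and intercept are
robust to that choice (≤ 10⁻³) but F is hypersensitive — which is why
F is reported but never gated, and asserted only as F > 10⁴ for GA.
The fitted grid is the diagonal m = n = 1…10, exactly as tabulated.
The goodness-table comparison (and the "GA is the best predictor"
check) runs under the reconciled (3,3) count, the configuration that
reproduces the reference goodness table; under the tabulated default
count ABC would edge out GA — a consequence of the same ambiguity,
recorded here rather than resolved.

## Synthetic data

`make_graph` provides path/cycle/star/complete fixtures (closed-form
index values: for a k-regular graph GA = |E|, ReZG₂ = |E|·k/2,
R_α = |E|·k^(2α), entropy = ln|E| for every index) and seeded
Erdős–Rényi G(n, p) graphs for oracle equivalence: the partition-based
sum must match a direct edge-by-edge sum (`brute_force_index`) to
10⁻¹⁰ on 100 seeded graphs, all 14 indices, skipping ABC/AZI when a
pendant–pendant edge occurs (their weights are undefined there — the
implementation rejects a = b = 1 explicitly). Isolated vertices are
kept: they carry no edges and cannot affect any degree-based quantity.

`synthetic_log_data` draws `y = β₀ + β₁·ln x + ε` with Gaussian ε —
the OLS-consistent default, since the model's error term is otherwise
unspecified — on the strictly increasing design x = 1…n;
`synthetic_power_data` uses multiplicative log-normal noise, the
structure under which log-log OLS is the natural estimator. What a
green test establishes: exact recovery at σ = 0, unbiasedness across
200 seeded replicates at σ > 0, and the F identity. What it does not:
anything about real measurement error in chemical data, which these
generators do not emulate.

## Numerical choices and degenerate inputs

* Printed-cell comparison at display precision accepts truncation or
  half-up rounding: the source mixes both conventions, even within one
  row (the fractional Randić rows). Rows verified to be uniformly
  truncated are held to truncation exactly.
* The R₋₁ index row is excluded from gating (duplicated row label; its
  (7,7) entry matches neither convention — a misprint).
* AZI uses the cubed weight `((ab)/(a+b−2))³` throughout; an
  intermediate display in the source drops the cube, but the final
  polynomial and tables are consistent with the cubed form.
* `log_fit` rejects non-positive x, constant x, and n < 3; entropy
  rejects non-positive weights and W ≤ 0; grid parameters must be
  integers ≥ 1 (booleans rejected).
* Zero-count edge classes are skipped in sums, so partitions listing
  an empty (1,1) class do not trip the ABC/AZI domain check.
* The reproduction path contains no randomness; `reproduce_all` output
  is byte-identical across runs.

## Known limitations

* No explicit BeN4 lattice is constructed; whether a concrete periodic
  graph realises the tabulated partitions for all m, n is not verified
  here.
* The (3,3)-count question is documented, not adjudicated; ReZG₃'s
  published polynomial remains inconsistent under every single-count
  hypothesis.
* Distance-based indices (Wiener, Szeged, Balaban) and multi-predictor
  regression are out of scope; plotting is omitted entirely.
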