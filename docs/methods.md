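# Methods

## Molecular graph model

Molecules are hydrogen-suppressed simple graphs: heavy atoms as vertices,
one edge per bonded heavy-atom pair. Bond orders, aromaticity, charges and
isotopes are ignored. This convention is what makes the classic worked
examples in the field come out: a carbonyl carbon bonded to two other heavy
atoms has degree 3 and its oxygen degree 1, so C=O is a (1,3) edge. The
convention is validated for organic drug-like molecules; it is not
extended to charged or organometallic species, where degree bookkeeping on
a bond-order-blind skeleton stops being meaningful.

Graphs must be connected. Multi-fragment SMILES (salts, solvates) are
rejected by default; an explicit `largest_fragment` flag keeps the
component with the most heavy atoms, ties broken by the lexicographically
smallest vertex label, making the choice deterministic.

All indices factor through the **edge partition** — the edge tally keyed by
sorted endpoint-degree pair. Keys are stored `(min, max)`; zero counts are
dropped on construction so the partition is a sparse, canonical summary.
Defining the indices on the partition (with graph-level entry points
delegating) makes hand-published partitions directly computable and keeps
each kernel a two-argument function registered in an extensible registry.

Two identities are used as permanent cross-checks: counts sum to |E|, and
Σ_edges (d(u)+d(v)) = Σ_vertices d(v)² (the handshake-square identity).
`compute_all` additionally asserts HZ = F + 2·M₂ on every call; this is
exact in integer arithmetic because all degrees are integers.

## Index values and precision

Values are stored at full double precision. Published reference values are
compared at the precision they are conventionally printed: integers for
M₁, M₂, HZ, F; five decimals for H; four for SCI. One quirk worth
recording: for the donepezil example the harmonic index is the sum
2(2/3) + 1(2/4) + 6(2/4) + 18(2/5) + 4(2/6) = 13.36667 — the (1,3) term is
1×(2/4), which is easy to mis-transcribe; the total fixes the reading.
Likewise SCI is the full five-term sum 2/√3 + 1/2 + 6/2 + 18/√5 + 4/√6 =
14.3375.

## Entropy weighting

Each criterion column is normalized over alternatives to proportions
r_ij = x_ij/Σ_i x_ij. Normalizing within the column (not within the row)
is the only reading under which the entropy
E_j = −(1/ln m) Σ_i r_ij ln r_ij is well defined on [0, 1]; the package
commits to it. The 0·ln 0 := 0 convention handles the one-hot limit.
Weights are w_j = (1−E_j)/Σ_k (1−E_k): a uniform column (E = 1) gets zero
weight; dispersion raises weight. Weights attach to *criteria* (the
indices), never to alternatives.

Degenerate cases: the decision matrix type rejects non-positive entries
outright (an optional preprocessing shift, ε = 10⁻⁶ × column max, is not
applied implicitly anywhere). If every column is uniform no objective
weights exist; this errors unless the caller opts into the equal-weights
(1/n) fallback, and the fallback is logged.

## TOPSIS

Vector (Euclidean) column normalization, multiplication by the weights,
per-column ideal/anti-ideal points (max/min for benefit criteria, swapped
for cost), Euclidean separation measures P⁺, P⁻, and closeness
C = P⁻/(P⁺+P⁻) ∈ [0, 1]. Rank 1 is the largest closeness. The distance
metric is Euclidean only; a Manhattan variant was deliberately excluded to
keep the result single-valued.

Directions default to all-benefit — for pure topological criteria no sign
is intrinsic — and can be overridden per criterion from a JSON file or
derived from property correlations (below). Both paths are exercised in
the demo, and every defaulted direction is logged at warning level.

Ties: closeness values within 10⁻¹² share the minimum (competition) rank
and subsequent ranks are skipped; tie groups are reported in the audit
trail. An alternative simultaneously at the ideal and anti-ideal point
(only possible when all columns are constant) is a degenerate instance and
errors rather than returning 0/0.

## SAW

Benefit columns are max-normalized (x/max), cost columns inverted
(min/x), so every normalized column attains 1 and total scores
TS_i = Σ_j w_j n_ij lie in (0, 1] under unit-sum weights, with TS = 1
exactly for an alternative best on every criterion. This linear scheme is
the textbook choice consistent with converting minimizing criteria into
maximizing ones before weighting; a vector-normalization variant is
available behind a flag for sensitivity analysis. Ranking and tie policy
are shared with TOPSIS. Agreement between the two methods is reported as
tie-aware Kendall τ-b plus the list of alternatives ranked identically —
a diagnostic, not a thresholded assertion, since the two methods need not
agree in general.

## QSPR

Pearson correlations (Spearman behind a flag) between every index and
every property over shared alternatives, with pairwise deletion of missing
property values and the used n reported per cell. A property constant
across alternatives yields an undefined correlation and is flagged missing
— never coerced to 0. Simple OLS fits property = slope·index + intercept
use the closed-form solution (`scipy.stats.linregress`); r² = r² of the
Pearson coefficient by construction.

Each index is allocated the property with the largest |r|, ties broken by
a fixed property order (melting point, boiling point, molecular weight,
density, flash point, complexity). The allocated property then fixes the
criterion direction: boiling point, molecular weight and flash point are
benefits (less volatile, better absorbed, less flammable); melting point,
density and complexity are costs (lower melting point and density favour
absorption; regimen complexity is a risk factor). Unallocated indices
default to benefit with a warning. The whole allocation is configurable
and can be bypassed with a hand-written direction file.

## Synthetic data

The generator emulates the statistical shape of a small-molecule drug
panel without claiming chemical validity (no valence or aromaticity
rules):

- **Graphs**: a random spanning tree grown under a degree cap (default 4,
  organic-valence-like), plus Poisson-many ring-closing edges with mean
  0.15·n — roughly the ring density of drug-like skeletons. Defaults: 12
  molecules of 10–30 vertices, matching the bundled panel's size range
  (11–31 heavy atoms).
- **Decision matrices**: log-normal entries (all strictly positive).
- **Property tables**: each property is a planted linear function of one
  designated index plus Gaussian noise, ground truth recorded. Default
  plants assign each of the six properties a distinct index with slopes,
  intercepts and noise SDs sized so that planted correlations at n = 12
  land around 0.95–0.99 (e.g. boiling point = 2·M₁ + 150 ± 8 °C) —
  strong but not deterministic, which is the regime the recovery tests
  probe.

One master seed is split (`numpy.random.SeedSequence.spawn`) into a graph
stream and one noise stream per property, so enlarging a panel appends
molecules without perturbing existing draws. Everything downstream of a
seed is bit-reproducible.

What passing tests on synthetic panels show — and what they do not: they
verify the estimators and rankers recover planted structure under the
generator's idealized linear-plus-Gaussian relations and independent
molecules. Real property–descriptor relations are noisier, nonlinear and
confounded by correlated descriptors (M₁, M₂, F, HZ are strongly
collinear on real skeletons), so recovery here does not certify predictive
validity on laboratory data.

## Numerical and design choices

- Weights must sum to 1 within 10⁻⁹ at construction; weights re-read from
  a 6-significant-digit CSV are renormalized if within 10⁻⁴ of 1 and
  rejected otherwise.
- Output CSVs use 6 significant digits with a full-precision JSON sidecar;
  row order is fixed by input order, making reruns byte-identical.
- The parameter-recovery harness uses 200 replicates of 12-molecule panels
  (the panel size of the bundled study design); the 3-standard-error
  criterion should hold in ≥ 95% of replicates under correct coverage.
- The twelve bundled drug structures were curated by compound name and
  verified against each compound's molecular formula; stereochemistry is
  omitted because the graph build discards it.

## Known limitations

- All-benefit is an assumption, not a derived fact, when no property table
  is supplied; rankings under it order molecules largely by size and
  branching, since all six indices grow with both.
- Only simple (non-fuzzy) TOPSIS and SAW are implemented; interval or
  linguistic ratings are out of scope, as are criterion-interaction
  models.
- Distance-based and spectral topological indices (Wiener, ABC, Randić
  beyond sum-connectivity) are not built in, though the kernel registry
  accepts any degree-pair index.
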