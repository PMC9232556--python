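# Methods

This note documents the model, the numerical choices, and what the synthetic
generator does and does not establish. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Curve construction

For each habitat parameter (velocity, depth, substrate), organism group
(community or guild) and campaign scope:

1. **Standardization.** Each microhabitat's group-projected abundance is
   divided by the maximum group abundance of its field campaign. This puts
   campaigns with very different overall abundance (medium vs low flow) on a
   common [0, 1] scale before pooling, and makes the utilization curve
   invariant to rescaling any one campaign's counts.
2. **Availability** `P[E](i) = a_i / Σ a_i` sums sampled area per bin. When
   no per-microhabitat areas were recorded the default area is 1.0 m², and
   `P[E]` degrades to a sample-frequency estimate. This is documented
   prominently because it changes the interpretation: preference is then
   use per *sampling visit*, not per unit area.
3. **Utilization** `P[E/F](i) = u_i / Σ u_i` sums standardized abundance per
   bin. Both curves sum to 1 by construction (enforced to 1e-9 in tests).
4. **Preference** `P_r = P[E/F] / P[E]` only where `P[E] > 0`. Bins with no
   availability are *masked as undefined*, never imputed as SI = 0:
   preference is unknowable where the habitat did not exist. Use recorded in
   a zero-availability bin is inconsistent input and raises.
5. **SI** divides by the maximum over defined bins, so every SI vector
   attains 1.

Bin convention: half-open `[lo, hi)` with the last bin closed, preventing
double counting at shared edges. Velocity bins are 0.05 m/s wide; depth bins
0.05 m by analogy (both configurable). No smoothing is applied anywhere —
curves are reported piecewise, exactly as tallied.

## Combining campaigns

Organisms only demonstrate suitability for conditions that were on offer, so
curves from different discharges are offset along the parameter axis and the
true suitable range is wider than any single campaign shows. Two explicit,
configurable strategies resolve this (the choice is recorded in the run
manifest):

- `pointwise_max`: final SI(i) = max over campaigns of max(si_huc(i),
  si_hpc(i)); masked bins are treated as absent and stay masked only if no
  campaign defines them.
- `envelope_fill` (default, continuous parameters only): after
  `pointwise_max`, the result is normalized to max 1, then every bin between
  the first and last bin with SI ≥ 0.8 is set to SI = 1, widening the
  plateau across the span the campaigns jointly support. Normalizing
  *before* thresholding makes the operation idempotent. The 0.8 threshold is
  the default that reproduces the plateau-widening behaviour this step is
  meant to capture; it is a judgment encoded as a parameter, because the
  underlying field practice resolves the HUC/HPC disagreement by expert
  inspection rather than a stated rule.

For the categorical substrate parameter, the pipeline always uses
`pointwise_max` (bridging between unordered categories is meaningless).

## ANOSIM pooling check

Before pooling, community structure is compared between campaigns: counts
are ln(1+x)-transformed, Bray–Curtis dissimilarities computed, and Clarke's
R evaluated on the joint ranks (average ranks for ties):
`R = (r̄_between − r̄_within) / (M/2)`, `M = n(n−1)/2`. The permutation
p-value uses the (b+1)/(m+1) estimator (999 label permutations by default),
which cannot return 0. An exact mode enumerates all distinct label
assignments for small designs and is what the test suite compares against a
brute-force oracle. A pair of all-zero samples has no defined Bray–Curtis
dissimilarity; it is set to 0 with a warning (identical emptiness), a case
field data cannot produce but synthetic data can.

ANOSIM runs on counts (not per-area densities): sampled area enters the
analysis only through the availability curve.

## The K coefficient

`k_raw = 0.4·n + 0.3·H + 0.2·EPT + 0.1·α` per microhabitat (family richness,
Shannon diversity, EPT *individuals*, density in ind./m²), normalized by the
dataset-wide maximum so max K = 1; the maximum is taken across both
campaigns. Components enter unscaled, exactly as the formula is printed,
although the density term then dominates numerically in rich samples; a
`normalize_components` switch (each component divided by its dataset maximum
before weighting) is provided but off by default. Two ambiguities in the
source material are surfaced rather than resolved: secondary discussion of
the coefficient assigns EPT a weight of 0.4 where the formula says 0.2 (the
formula is followed), and some related indices use EPT *richness* where this
definition counts individuals.

## Functional feeding groups

Guild membership is binary: allocation ≥ 3 of 10 points. A taxon in several
guilds contributes its full count to each (the binary coding rules out
fractional splitting). Parasites and "others" are excluded from curve
analyses by default (overridable); taxa whose allocation reaches 3 in no
guild (possible when spread 2+2+2+2+2) are reported as unassigned and count
only toward the community group.

## Synthetic data: what it emulates

The generator reproduces the statistical structure the analysis assumes,
with known ground truth:

- two campaigns with truncated-normal availability over velocity and depth,
  the low-flow campaign shifted toward slower/shallower habitat and lower
  abundance (default 20 + 30 samples; per-campaign exposures 19.0 and 2.3
  chosen once so expected totals match a ~900 vs ~300 individual contrast);
- a 22-taxon roster spanning all guilds (six EPT taxa, two parasites), each
  taxon driven by its guild's truth;
- guild truths as 1–2 Gaussian bumps over velocity and depth plus substrate
  weights: gatherers/grazers dominant and bimodal, filter feeders on a
  single narrow bump at 0.30 m/s (suitable range ≈ 0.20–0.40 m/s);
- negative-binomial counts (dispersion 2.0 — field macroinvertebrate counts
  are overdispersed; `dispersion=None` gives the Poisson limit) with mean =
  exposure · area · suitability, the truth evaluated pointwise at the
  sampled habitat so generator and estimator share no binning code.

What it does **not** emulate: spatial autocorrelation between microhabitats,
taxon interactions, measured (non-unit) sampled areas, or hydraulic
structure of the reach. A green recovery test therefore establishes that the
estimator inverts the stated sampling model, not that it is robust to every
feature of real field data.

## Numerical choices and degenerate inputs

- Continuous bin lookup: `searchsorted` on rounded edges; a value equal to
  the final edge falls in the last bin.
- Curve sums checked to 1e-9; SI maxima exact up to float division.
- All-zero group in a campaign: standardized abundances are zeros with a
  warning; a group absent everywhere has no utilization curve (error, or
  skipped with a machine-readable warning by the pipeline).
- Empty microhabitats: all K components 0 (Shannon mapped to 0), K = 0.
- Single RNG (`numpy.random.default_rng(seed)`) per run; the seed is echoed
  in `anosim.json` and the manifest, and identical seeds give byte-identical
  outputs.

## Known limitations

- Univariate curves assume velocity, depth and substrate act independently;
  organisms in fact select joint habitat types, so the marginal curves can
  misstate suitability of unobserved combinations.
- With unit areas, availability is sampling frequency; any sampling bias in
  the field design propagates into `P[E]`.
- The K coefficient aggregates community-quality indices that are poorly
  suited to small guilds (few families, uneven EPT occurrence); its envelope
  comparison is reported but not used to build the HSCs.
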