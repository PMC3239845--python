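# Methods notes

## Model and procedure

netdiff addresses the two-network differential clustering problem: given
symmetric weight matrices `A` and `B` on one node set, find node subsets that
are densely, positively interconnected in one network and not in the other,
and attach a significance statement to each find.

The core is the generalized singular value decomposition
`A = U C X⁻¹`, `B = V S X⁻¹` with the convention `c` nondecreasing and `s`
nonincreasing (`c² + s² = 1` elementwise in the CS-based construction used
here).  The generalized singular values `λᵢ = cᵢ/sᵢ` are stationary values of
`‖Ax‖/‖Bx‖`; relabelling nodes by the sorted components of a column of `X⁻ᵀ`
is a spectral reordering that contrasts the two networks rather than
clustering either alone.  First columns (small `λ`) favor structure
exclusive to `B`; last columns (large `λ`) favor structure exclusive to `A`.
The derivation assumes invertibility, but the construction — full QR of the
stacked `[A; B]` followed by `scipy.linalg.cossin` — is defined for
rank-deficient inputs, and `X⁻ᵀ` falls out as `(V₁ᴴR)ᵀ` without any matrix
inversion.

### Degenerate spectra

Sparse binary networks routinely contain isolated or duplicate-row nodes and
are then exactly rank deficient, which makes several generalized singular
values coincide (e.g. `λ = ∞` for every direction in `null(B)`).  Within
such a tied block the factorization is unique only up to an orthogonal
rotation, and an arbitrary basis of a null space carries no ordering
information — in practice the extreme columns then fail to reveal planted
clusters.  netdiff canonicalizes each exactly-tied block (angle
`atan2(c, s)` equal to within 1e-9) by rotating it to diagonalize the
block's Rayleigh quotient in the network that end of the spectrum favors,
ordered so the most clustered direction sits outermost.  This is the natural
extension of the `‖Ax‖/‖Bx‖` objective to tied values, preserves the
factorization identity (the tied `C`/`S` entries act as scalars), and is
deterministic.

*Nearly* tied values are left alone — rotating them would break the
factorization — but they have a visible consequence: a planted direction can
surface in the second column from an end rather than the first.  Candidate
searches therefore inspect a configurable number of columns per end
(`n_columns`); the recovery benchmarks use two.

### Sign and tie conventions

Each reordering column is normalized so its largest-magnitude component is
positive, which removes the ±x ambiguity; sorting is descending with ties
broken by original node index.  A genuine cluster may still legitimately
appear at either end of a sorted column (both orientations are
informationally identical), so candidate generation always offers head and
tail runs.

## Cluster quality and the Monte-Carlo null

Density is `|E(s)|/|s|` for binary blocks and the mean off-diagonal weight
for weighted blocks, diagonal always excluded; `|s| = τ(τ−1)/2`.  Quality
combines the target-network and other-network densities as a ratio (default)
or difference.  The ratio is the natural choice for binary and non-negative
weights (the `|s|` denominator cancels, leaving a raw edge-count ratio).
For signed weights it is unreliable: the mean weight of a random null block
concentrates near zero, so the ratio's sign flips and its magnitude
explodes, flooding the null with spurious exceedances.  The pipeline and the
correlation benchmarks therefore use the difference combiner for signed
data; both combiners remain available everywhere.

The permutation scheme draws one uniform node relabelling per replicate,
applied identically to both networks, and scores the first `τ` nodes — no
refactorization is needed because the factorization is permutation
equivariant.  The Erdős–Rényi and redistribution schemes (binary inputs
only) rebuild random graphs and refactorize each replicate, scoring the run
at the candidate's own (column, end, offset).  p-values are raw exceedance
proportions with ties and `+inf` counting as exceedances (conservative); the
bias-corrected `(x+1)/(M+1)` value is reported alongside.  All results are
bit-reproducible from `(seed, M, scheme)`.

### Calibration and an honest caveat about selection

The tested candidate is *chosen by the reordering*, then compared against
unselected random subsets, so even under a structureless null the nominal
p-value is mildly anti-conservative.  On independent Erdős–Rényi pairs
(20 nodes, density 0.3, τ = 10, M = 200) the measured fraction of nominal
p < 0.05 is ≈ 0.10 — inflated above 0.05 but within the package's accepted
calibration band [0.01, 0.12].  The effect grows with the noise level of the
weights: for correlation networks estimated from very few samples per group
(e.g. 5), sample correlations have standard error ≈ 0.45 and the selection
step reliably finds extreme-looking blocks, so a nominal p < 0.05 on such
data should not be read at face value.  This is a property of the published
select-then-permute construction itself, not of this implementation; the
tie rule at least guarantees that literally identical groups (A = B) always
give p = 1.

## Synthetic designs

**Binary (20 nodes).**  Nodes 1–5 clustered in both networks, 6–15 only in
A, 15–20 only in B (node 15 in both planted clusters); within-cluster edge
probability `p_in = 0.85`, background `p_out = 0.08`.  These rates give
clusters with visible false negatives and a sparse noisy background.  With
them, roughly one pair in two has an isolated node in `B` — the degenerate
case discussed above, which the tie canonicalization handles.

**Correlation (20 nodes × 50 samples).**  Nine source signals — seven unit
sinusoids of distinct frequency and phase, a square wave, a ramp — mixed
with strictly positive Uniform(0.5, 1.5) coefficients (so planted
correlations are positive) plus additive Gaussian noise of scale 0.2;
remaining rows are pure standard normal noise.  Rows 1–5 of both data
matrices share signals 1–7; rows 6–15 of the first share signals 7 and 8;
rows 15–20 of the second share signals 4 and 9.  The planted blocks
deliberately share one signal with the common block, so the exclusive
clusters are embedded in realistic cross-correlation.

**Intensity table.**  Log-normal peak intensities (log10 base level
Uniform(4, 7), per-sample noise 0.15 on the log scale) for two groups;
defaults of 98 metabolites and 5 samples per group mirror a small two-group
LC-MS study.  A planted block shares a latent per-sample factor (loading
≈ 0.4 on the log scale, within-block correlation ≈ 0.9) in the first group
only, and one annotated pathway.  What these generators do *not* emulate:
missing peaks, intensity-dependent variance, batch effects, or correlated
pathway structure outside the planted block — so passing benchmarks
demonstrate recovery of idealized group-exclusive covariance, not robustness
to real LC-MS artifacts.

**Validation design for the pipeline.**  End-to-end ground-truth recovery is
benchmarked at 20 samples per group (not the 5 of the default), because
correlation matrices estimated from n = 5 are dominated by sampling noise
and no method can reliably recover a planted block from them; with n = 20
and two inspected columns per end the planted pathway is the top enrichment
hit in ≈ 97/100 seeds.

## Metabolomics layer

Correlations are computed per group across that group's samples on log10
intensities by default (peak intensities are multiplicative), plain pairwise
Pearson; precision-matrix partial correlation is available via
``correlation_pair(..., partial=True)`` but is off by default.  The Fisher
transform
`z = arctanh(r)` is applied off-diagonal with `|r|` clipped to `1 − 1e−12`;
diagonals are kept at 1 (a flag removes them).  The per-metabolite screen is
the fold ratio of group mean intensities plus Welch's unequal-variance
t-test on log10 intensities, flagged at `p < 0.05` and/or fold change
outside [0.5, 2].  Enrichment uses the upper-tail hypergeometric probability
with the universe `N` equal to *all* detected metabolites, including
unannotated ones; metabolites on several pathways count in each; the 0.05
threshold is applied per pathway with a Benjamini–Hochberg column reported
but not used for the flag (matching the original analysis convention).

## Numerical choices

- Symmetry tolerance on input matrices: 1e-8 absolute; asymmetric input is
  an error unless symmetrization is requested explicitly.
- Factorization reconstruction residuals are ≤ 1e-8 relative on inputs with
  condition number < 1e6 (measured ~1e-15 in practice).
- `X` itself is only materialized on demand; condition estimate > 1e12
  triggers a warning and a pseudo-inverse.
- Ratio quality with a zero denominator returns `+inf` (or 0 for 0/0, which
  carries no evidence); rank comparisons handle `inf` naturally.
- Monte-Carlo seeds are spawned from a single integer; every derived seed is
  below 2³¹.

## Benchmark problem sizes

The seed-sweep benchmarks use 100 regenerated pairs per design with M = 1000
permutation replicates, and 200 pairs with M = 200 for the null calibration;
these sizes put the Monte-Carlo error of the reported fractions near ±3%
while keeping each sweep under a minute on one core.

## Known limitations

- Cluster size τ is a user choice (in the original analysis it was read off
  the reordered heatmaps); no automatic selection is attempted.
- No multiple-testing correction is applied across (τ, column, end)
  candidates, matching the original procedure; with many candidates the
  selection caveat above compounds.
- The ratio combiner should not be used on signed weights (see above), and
  the mean-weight density assumes clusters dominated by positive weights; a
  cluster of strong *negative* weights needs the absolute-value variant.
- Directed networks and eigenvector methods for single-network clustering
  are out of scope.
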