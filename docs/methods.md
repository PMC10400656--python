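# Methods

This note documents the models and numerical choices behind `phosnet`,
what the synthetic test bed does and does not emulate, and the known
limitations a user should weigh before trusting an inferred edge.

## Input model and missingness

The unit of analysis is the phosphosite: a phosphorylated S/T/Y residue
at a 1-based position on a protein, in a peptide form of multiplicity
1–3 (number of phosphate groups). Label-free MS1 intensities carry two
kinds of missingness. Dropouts unrelated to abundance (poor ionization,
competition for charge) are missing completely at random and only add
noise; values below the detection limit are missing not at random and
are biologically meaningful — a site switched off in one condition.

The valid-value rule separates the two using replicate agreement per
(condition, time point) cell: with `min_valid = ceil(0.75 × replicates)`
(3 of 4 in the reference design), a cell is VALID at ≥ min_valid
detections, ABSENT at ≥ min_valid zeros, otherwise ambiguous. A site
with an ambiguous cell — e.g. 2 detections + 2 zeros — cannot be told
apart from a technical dropout and is discarded outright. A site that
is ABSENT somewhere and VALID elsewhere is kept as an absence/presence
site; it skips the per-site model (no variance to model in an absent
cell) but can enter the network when one condition's cell is VALID at a
time point where another condition's is ABSENT. A site ABSENT in every
cell shows no evidence of presence at all and is discarded. Zeros and
blank cells in the input both mean "not detected"; intensity values are
never imputed.

## Normalization

Intensities are put on a log2-comparable scale by a variance-stabilizing
transform in two parts:

1. **Per-sample affine calibration** `x → (x − α_s)/β_s`, fitted by
   iteratively reweighted least squares against a reference profile (the
   row median of the calibrated data), under the assumption that most
   sites do not change between samples. Weights are inverse variances of
   the two-component error model `var ≈ x0² + σ_m²·ref²` (additive +
   multiplicative), and a least-trimmed-squares-style influence set
   keeps the 90% of rows with the smallest weighted residuals, so
   genuinely changing sites do not tilt the calibration. Iteration stops
   after 20 rounds or a relative parameter change below 1e-8.
2. **Generalized log** `h(z) = arsinh(z/x0)/ln 2`, which is `log2`
   at high intensity and linear below the additive-noise scale `x0`.

Two stabilizing choices matter here. The offsets α_s are shrunk strongly
toward zero (a pseudo-observation at the origin with 100× the data
weight): integrated MS1 intensities are baseline-subtracted, a free
intercept would be an extrapolation far below the measured range, and
its sampling error alone can swallow the lowest observed intensities.
And the glog offset `x0` is kept only when the additive variance
component clears both its own sampling noise and 25% of the
multiplicative variance at the low end of the intensity range —
otherwise `x0` collapses to a token floor and the transform degenerates
to a pure log, which is the correct limit for purely multiplicative
noise. Without that gate the estimated offset tends to land inside the
intensity bulk and silently linearizes (and thereby flattens) the
dynamics of low-abundance sites.

The calibration is exactly invariant to rescaling any single sample
(the weighted regression is linear), identical samples map to identical
columns, and `method="log2-median"` provides the plain fallback.

## Per-site model and selection

Each quantified site is modelled by a linear mixed model chosen from the
design: time effects only (one condition), condition effects only (one
time point), or the full two-way model
`Y = μ + αᵢ + βⱼ + (αβ)ᵢⱼ + γₖ + ε` with a random intercept γₖ per
replicate (plants grown and processed together are correlated). The
tested hypothesis drops the condition main effect and the
condition × time interaction jointly; with one condition, the time
effect is tested instead.

The default p-value comes from an exact within-block F-test: replicate
intercepts are absorbed as fixed block effects in both nested models, so
the test conditions on the random intercepts and needs no variance-ratio
estimate. For treatment designs crossed with replicates this F reference
is exact under the mixed model. The asymptotic chi-square likelihood
ratio of the profiled-ML fits is available as `statistic="lrt"`, but at
the reference size (88 observations, 22 fixed parameters, 11 test df)
its type-I error is badly inflated (~14% at α = 0.05 in simulation,
versus ~4.4% for the F-test), so it is not the default. Variance
components are reported from REML at the full model; the profiled
random-intercept likelihood is computed analytically (grouped whitening
plus a one-dimensional search over the variance ratio), which keeps a
thousand-site analysis in seconds.

Degenerate inputs are handled explicitly: effects below the numerical
precision of the input scale count as zero (exactly constant data gives
p = 1 rather than 0/0), and a vanishing full-model residual with a real
effect gives p = 0.

Multiple testing uses Storey q-values: π₀ is estimated on the λ grid
0.05…0.95 with a cubic polynomial smoother evaluated at λ = 0.95 and
clipped to (0, 1]; q(p₍ᵢ₎) = min over j ≥ i of π₀·m·p₍ⱼ₎/j. Selection
requires both p < 0.05 and q ≤ 0.05.

## Discretization

Network inference consumes two discrete views per condition. The
**delta events** work on replicate-mean profiles of the median-centered
matrix (absent cells set to 0, the condition median): a transition is
unchanged if |Δ| falls below the 10%-quantile of all |Δ| pooled over the
condition's selected sites, +1 if Δ > 0.25·|p(t−1)|, −1 if
Δ < −0.25·|p(t−1)|, evaluated in that order. The magnitude |p(t−1)| is
used as the baseline because on the centered scale the raw value can be
negative, which would flip the threshold's sign; from a baseline of
exactly zero any change surviving the quantile gate takes its sign. The
**3-level states** are computed per replicate: at or below the condition
median → LOW, above → HIGH, masked → ABSENT (a countable state of its
own — the pattern of absence is signal, not missing data). Values tied
with the median go LOW.

Note a structural property of the relative 25% rule: its sensitivity
depends on where a site sits relative to the condition median. Near the
median almost any fluctuation passes; far from it only large fold
changes do. Its flip side is that a fixed-size jump can fail the
threshold at the extremes of the dynamic range.

## Candidate discovery, BDeu, signs

Only phosphosites on proteins in the regulator list (kinases and
phosphatases, from classifier/HMM/ortholog/user sources) may have
out-edges; self-edges and edges between two sites of the same protein
are excluded. Candidate parents must match the target's delta events for
strictly more than half of the comparable transitions — at lapse 0 all
T−1 transitions, at lapse 1 the T−2 shifted pairs — with 0 = 0 counting
as agreement (co-stability is evidence too; it is also what makes
anti-directional dephosphorylation targets of a sparsely-switching
regulator discoverable at all, since their active transitions always
disagree).

Each single candidate and each unordered pair of candidates on distinct
regulators (each member keeping its own qualifying lapse) is scored with
the BDeu marginal likelihood over replicate-level data vectors pairing
the target's 3-level state at t with each parent's state at t − lapse.
The Dirichlet hyperparameter is α = 10⁻¹⁵; the default
`formula_variant="as_printed"` places α/qᵢ inside the per-level gamma
terms, the canonical `"standard"` variant uses α/(rᵢ·qᵢ); at this α the
two differ only through zero-count terms. The j-sum runs over all qᵢ
parent configurations, observed or not. With α this small the score
strongly rewards near-deterministic parent→child level mappings and
penalizes every additional occupied configuration, so a single
deterministic parent beats any superset.

Parent sets tie frequently in floating point (deterministic mappings of
different data-vector counts are mathematically equal), so scores are
compared after quantization to 1e-6 and ties break toward fewer parents,
then higher mean concordance, then a fixed lexicographic order. Without
the concordance step the winner of a mathematical tie would be decided
by ~1e-13 of rounding noise.

Every selected site is tried as a target and its best-scoring candidate
set always yields edges — there is no empty-parent baseline. (An
empty-set comparison would be uninformative here anyway: for a target
with a constant level series the empty score always exceeds any parent's.)
The practical consequence: any null site that slips through the q-value
gate is guaranteed to acquire a parent. At FDR 0.05 with ~15 true
positives that is ~0.8 spurious targets per run on average, which sets a
floor under the false-edge count that no scoring can remove.

Signs count co-directional versus anti-directional event pairs over
transitions where both are nonzero, aligned at the edge's lapse:
majority same → phosphorylation, majority opposite → dephosphorylation,
tie (or no joint events) → undetermined. Per-condition networks are
combined into one graph whose nodes and edges carry membership labels
(first condition / second / both).

## Synthetic test bed

`phosnet.synthetic` generates the study-shaped ground truth the test
suite and acceptance checks rely on: 2 conditions × 11 time points
(6-minute spacing) × 4 replicates, with log-normal replicate noise
(default SD 0.25 log2), per-sample calibration offsets at half that SD,
optional detection-limit censoring (MNAR) and random dropout (MCAR).

Regulator sites follow piecewise-constant trajectories that toggle
between activity states 2.7 log2 units (~6.5-fold) apart at 3–4 of the
10 transitions; targets copy their parent's trajectory at the edge's
lapse, mirrored for dephosphorylation edges; kinases phosphorylate and
phosphatases dephosphorylate. Each site sits at a baseline 5.0–5.4 log2
units above or below the experiment median and receives a ±0.5 log2
condition shift with balanced signs (so per-sample calibration cannot
absorb it); 150 flat background sites with baselines near the median
anchor the normalization (they are the "unchanged majority" the
calibration assumes — at least ~90% of rows must be stable or the
trimmed fit has no clean influence set) and give the statistics genuine
nulls. The geometry is chosen from the delta rule itself: jumps must
exceed 25% of the largest visited |centered level| while flat stretches
need 25% of the smallest visited |level| to exceed ≈2.5σ of replicate-
mean noise at the default noise level.

Regulator jump patterns are resampled jointly until (a) every possible
edge type is discoverable — the mirrored and lagged images of each
pattern stay concordant with it above the candidate threshold — and (b)
no regulator, nor the mirrored/lagged target of another regulator,
reaches concordance above 0.5 with a different regulator. Under this
admissibility the noiseless pipeline recovers the ground-truth edge set
exactly.

What the generator does **not** emulate: peptide-level effects
(multiplicity is fixed at 1), correlated noise between sites, drifting
baselines, hidden fast kinetics between observation times, regulators
whose sites sit near the condition median (where the 25% rule is
noise-prone), or kinase cascades (regulators regulating regulators).
Passing the recovery tests therefore shows the pipeline implements its
rules correctly and is robust at realistic noise — not that real cold-
stress data are this clean. Two honest imperfections surface even here:
with replicate noise, FDR-admitted background sites acquire spurious
in-edges (precision ≈ 0.75–1.0 across seeds, median 1.0), and an edge
recovered at the wrong lapse usually also gets a wrong or undetermined
sign, since sign comparison is aligned at the selected lapse.

## Evaluation utilities

Classifier probability thresholds are scanned over 100 evenly spaced
points 0.01…1.00 (predictions count positive at probability ≥ the
threshold, so 1.00 is meaningful); Cost = FDR − 3·TPR with FDR defined
as 0 when there are no positives; the largest threshold attaining the
minimal cost is selected (most stringent at equal cost). Overlap
statistics report exclusive upset-style region counts plus pairwise
"% of A shared with B" and "% of A missed by B" to one decimal, with an
empty reference set reported as undefined rather than 0. Family
composition reports counts with half-up integer percentages and a
one-decimal column. Betweenness centrality is computed on the undirected
projection (matching what a default Cytoscape analysis reports for mixed
networks); a directed variant is a flag away.

## Problem sizes used in the checks

The shipped checks run the full pipeline on 3 regulators / 12 targets /
150 background sites (≈1.5 s per run), the BDeu oracle on 200 random
instances of ≤ 4 replicates × ≤ 6 time points × ≤ 2 parents against a
60-digit arbitrary-precision evaluation, parent selection against
exhaustive enumeration on 100 instances with ≤ 6 candidates, and the
type-I calibration on 1000 simulated null sites of the full study size.
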