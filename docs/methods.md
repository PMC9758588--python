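# Methods

This note documents the models, conventions, and numerical choices behind
`sampeeg`, and what the synthetic validation experiments do and do not show.

## Task design

A choice problem pairs two two-outcome lotteries over the digits 1..9 with
outcome probabilities on the grid {0.1, …, 0.9}, all four outcome values
pairwise distinct, and an expected-value difference of exactly 0.9 points.
Probabilities are stored as integer tenths, so grid membership and the EV
constraint are exact integer arithmetic; EV comparisons elsewhere use an
absolute tolerance of 1e−9. Enumeration canonicalizes each lottery (smaller
outcome first) and lists each unordered pair once, in lexicographic order;
left/right orientation is randomized per trial at session-build time, since
orientation balancing is not part of the design constraints and a fixed
orientation would confound side with EV.

Sessions (default 100 trials in 5 blocks) are drawn by a greedy balancing
heuristic: for each trial slot, 20 candidate problems are sampled uniformly
from the enumeration and the one minimizing the squared deviation of the
cumulative *expected* per-value occurrence shares from uniform (1/9) is
kept. "Approximately equal probability" is a property, not an algorithm, so
the heuristic is a design choice; empirically it keeps every expected share
within ±0.03 of 1/9 for sessions of a few hundred trials.

## Sampling agent

No generative behavioral model is part of the analysis chain itself; the
agent exists to produce realistic trial streams with known ground truth. It
combines:

* **Leaky accumulation.** Signed, rescaled sample values
  (value − 5 ∈ −4..4; right positive, left negative) accumulate as
  A_n = Σ_i λ^(n−i) s_i, with retention λ ∈ (0, 1]. λ < 1 produces a recency
  effect whose magnitude is analytically known for fixed-length trials.
* **Threshold stopping** (full control only): stop once |A_n| ≥ θ, at the
  latest after 19 samples; partial control always draws exactly 12. The
  default θ = 6 was chosen so that full-control agents draw ≈9 samples per
  trial on average (median 8), matching the sampling counts such experiments
  report.
* **Stop-after-large bias**: an extra stop probability (default 0.05) after
  samples ≥ 8, yielding the positive linear trend of a value's mean relative
  stop position on its magnitude.
* **Softmax choice** P(right) = σ(A_n / τ), default temperature τ = 0.5.
* **Side policies**: alternating, single-switch blocked, or random —
  the first two reproduce the stereotypical "a-b-a-b" and "a-a-…-b-b"
  routines; their prevalence is a free property of the simulation, not a
  calibrated quantity.

A minimum of one sample is always drawn (a stop decision requires having
seen something). Yoked replay copies sides, values, and lengths verbatim and
re-generates only the final choice from the same accumulator.

## Behavioral analyses

**Accuracy** is the proportion of trials where the chosen option's
experienced arithmetic mean exceeded the other option's. Trials where an
option was never sampled or the means tie are excluded from the denominator:
the ideal-observer criterion is undefined there.

**Decision weights** come from one joint logistic regression of choice
(left = 0, right = 1) on three window regressors — the summed signed
rescaled values of the first 2 (early), last 2 (late), and remaining (mid)
samples — plus an intercept, after discarding trials with fewer than 5
samples. A joint fit is the standard reverse-correlation formulation and
avoids omitted-variable bias; per-window fits and mean (rather than sum)
window evidence are available behind keyword switches, since either reading
of "per-window regression" is defensible. Maximum likelihood is tried
first; on separation or non-convergence a ridge-penalized fit
(strength 1e−4, the smallest perturbation that guarantees a finite estimate)
is used and flagged. Recency is defined as w_late − w_early.

**Stop-position trend**: per trial, each sample's relative position is
index / n_samples; positions are averaged per value across trials, and an
OLS slope of mean position on value (1..9) is tested two-tailed. Values
never observed are dropped and reported.

## Synthetic EEG generator

Each sample event yields one epoch, 64 channels (extended 10% system,
actiCap-style labels) × 250 points (−0.2 to 0.8 s at 250 Hz). Planted
components, each with a raised-cosine temporal envelope:

| component    | topography                                   | amplitude                          | envelope     |
|--------------|----------------------------------------------|------------------------------------|--------------|
| numberline   | random unit vector per participant           | gain × v(value; k, b)              | 160–800 ms   |
| extremity    | unit vector orthogonal to the numberline one | gain × \|v(value) − v(5)\|         | 260–800 ms   |
| CPP ramp     | 1 on the 11 centro-parietal channels         | gain × {1, 2, 3} for early/mid/late| 300–600 ms   |
| lateralized  | 1 on contralateral occipitoparietal channels | gain                               | 80–200 ms    |

with v(value) = sign(x + b)·|x + b|^k and x = (value − 5)/4 ∈ [−1, 1].
The extremity amplitude uses the *distorted* extremity |v(value) − v(5)| so
that a planted (k, b) is expressed coherently in both codes; at k = 1,
b = 0 this reduces to |value − 5|/4, the undistorted extremity. Envelope
windows were set to the analysis windows the pipeline uses, so that planted
effects are detectable where the analyses look.

Noise is spatially correlated Gaussian: channels are embedded at random 3D
positions and the channel covariance decays exponentially with embedding
distance (correlation length 2.0). This produces realistic correlated
topographic noise without claiming real head geometry. Condition-specific
gain multipliers on the numberline and CPP amplitudes implement
"full-control amplification" (default 1.5× under full control); amplitudes
are arbitrary microvolt-scale units with noise SD 1, i.e. single-epoch SNR
of order 1 concentrated in the component envelopes.

What the generator does **not** emulate: volume-conducted forward physics,
1/f background spectra, ocular/cardiac artifacts, latency jitter, and
autocorrelated trial-to-trial drifts. Passing recovery tests therefore shows
the *analysis chain* is correct and calibrated under its own assumptions,
not that real recordings satisfy those assumptions.

## ERP and RSA analyses

Baseline correction subtracts each epoch's per-channel mean over [−0.2, 0) s
and is idempotent. All window means include both endpoints on the sample
grid. The lateralized visual ERP is the double difference
(ERP_left-stimuli − ERP_right-stimuli), then mean of left-hemisphere minus
right-hemisphere occipitoparietal channels, with P1 = 80–130 ms and
N1 = 140–200 ms window means. CPP amplitudes average the 11 centro-parietal
channels over 300–600 ms per early/mid/late window class; the <5-sample
trial filter is applied here too, keeping the window definition consistent
with the behavioral one (whether that filter belongs in the EEG averages is
ambiguous; applying it is logged as this package's convention).

For RSA, ERPs are smoothed with a Gaussian kernel parameterized by half
duration at half maximum (default 35 ms; σ = HWHM/√(2 ln 2)), reflection
edge handling. The ERP-RDM at each time point is the 9×9 matrix of Euclidean
distances between per-value mean topographies. Because baseline correction,
smoothing, and the RDM act only through those means, heavy simulations may
collapse an epoch set to its 9 per-value means first
(`value_mean_epochs`) — this is an exact equivalence, verified by test.

Model RDMs are |v_i − v_j| (distance) and ||v_i − v(5)| − |v_j − v(5)||
(extremity) of transformed values, reported on the raw value scale (so the
untransformed distance between "3" and "7" is 4); Pearson correlation is
scale-invariant, making the unit convention presentational. Each model is
orthogonalized to a sample-frequency RDM with entries |f_i − f_j| (the
simplest RDM whose lower triangle carries occurrence-frequency information —
the cell formula is a package convention). Residualization is ordinary least
squares with intercept over the 36 lower-triangle entries, making the
residual exactly uncorrelated with the frequency vector. Model–data
agreement is the lower-triangle Pearson r per time point; a zero-variance
ERP-RDM yields NaN, recorded as missing. Unequal per-value event counts
make noisy mean topographies systematically more dissimilar for rarer
values; the frequency orthogonalization mitigates exactly this class of
confound.

## Neurometric fitting

The (k, b) grid spans k ∈ [0.5, 10] (40 log-spaced points with k = 1
inserted, so the linear parameterization lies exactly on the grid) and
b ∈ [−0.75, 0.75] (31 linear points, containing 0). For each grid point both
model families are built, orthogonalized, and correlated with the
window-averaged (default 300–600 ms) ERP-RDM; the surface is the mean of the
two correlations and the per-participant estimate is its argmax, with ties
broken toward (1, 0) and then lexicographically. Grid resolution and the
averaging window are conventions, exposed as arguments.

One systematic property worth knowing: because the Euclidean ERP-RDM of data
containing *both* codes combines them under a square root rather than
additively, the averaged-family argmax is not an unbiased estimator of the
generating (k, b) — recovery experiments at (k = 2, b = 0.3) find group
means near (2.5, 0.43), shifted but directionally and categorically correct
(anti-compressed, positively biased). Exact self-consistency holds within a
single family: noise-free single-code data recover their generating
parameters exactly, which the tests assert.

## Group inference

The mixed 2×2 ANOVA (within: self-controlled vs yoked; between: full vs
partial group) is computed by the exact two-level reduction: ordinary
regressions of the per-participant within-difference and within-mean on an
intercept plus a ±0.5 group code. This reproduces the classical split-plot
F tests (F = t² for these 1-df effects; verified against an independent
implementation), handles mildly unbalanced groups in the Type III
(unweighted-means) convention, and makes η_p² = F/(F + df_error) exact.

Cluster-based permutation tests use per-time-point t statistics, a
two-tailed cluster-forming threshold at P = 0.05 (the reported tests in this
literature are two-tailed), clusters as maximal same-signed supra-threshold
runs, cluster mass (summed t) as the statistic — the field-standard default
— and p = (1 + #{null ≥ observed}) / (1 + n_perm), so the smallest
attainable p is 1/(n_perm + 1). The one-sample null flips participant signs;
the interaction null permutes group labels of the within-participant
(self − yoked) difference time courses, exploiting the exact 2×2 identity
interaction = between-group difference of within differences. The
interaction statistic is a Welch t with the cluster-forming critical value
taken at the pooled df = n − 2; since validity comes from the permutation,
this choice affects only sensitivity. Default 10,000 permutations.

## Validation experiment sizes

The validation experiments (`sampeeg.experiments`) run at deliberately
scaled-down cohort sizes chosen as the smallest that make the checks sharp:
neurometric recovery with 20 participants × 40 trials; recency recovery with
20 participants × 300 fixed-length trials; cluster calibration on 200 null
cohorts of 20 × 100 time points with 500 permutations; interaction-cluster
power on 100 simulated studies of 12 participants per group × 20 trials per
condition (200 permutations), false-positive rate on 100 null studies of 6
per group × 15 trials. In very small sessions a sample value may never
occur; the experiment harness then redraws that participant's session from
the same stream, a degenerate-input guard that does not bias recovery.

## Known limitations

* The agent is a stand-in; none of its parameters are fitted to real data.
* The generator's additive-pattern-plus-stationary-noise model is far
  simpler than real EEG; calibration results transfer to real data only to
  the extent the exchangeability assumptions of the permutation tests hold
  there (they are the same assumptions practitioners already make).
* The averaged-family neurometric argmax carries the estimation pull
  described above; between-condition *comparisons* of (k, b) are unaffected
  by a common pull.
* The BIDS adapter reads events tables only; it does not read raw EEG.
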