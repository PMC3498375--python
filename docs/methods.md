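# Methods

This note documents the models, conventions and design choices behind
`sealassoc`, in the spirit of a model-description appendix.

## The measurement system being modelled

Each animal carries (a) a 69 kHz acoustic transceiver that transmits its
unique code on an irregular 60–180 s schedule, listens the rest of the
time, blanks its own receiver while transmitting (so it never detects
itself), and detects other tags within roughly 300 m; and (b) an archival
GPS tag taking fixes every 5 or 15 minutes, each graded by satellite count
and residual error. A detection of one animal's transmission normally
leaves records on *both* units within seconds of each other; occasionally
(3% of cases) only one unit logs it. False detections — code collisions
decoding to a legal ID — occur rarely and arrive flagged.

## Association definition

Detection events of a dyad are clustered by a gap rule: a gap **strictly
greater than** 30 minutes ends an association (a gap of exactly 30 min
does not — the rule is stated as ">30 min ends it", and we follow that
wording at the boundary). Clustering is per-dyad; aggregations of three
or more animals appear as overlapping dyadic associations. Single-event
associations are assigned a 3-minute duration: given the ≤180 s
transmission schedule, another detection would have been logged had the
pair stayed together. The 3-min constant and 30-min threshold are
configurable. The association is located by component-wise linear
interpolation of each animal's lon/lat fixes at the association *midpoint*
(a symmetric, stable choice; the instant is not otherwise prescribed), and
per-event separations are interpolated at event times. A seal whose fixes
do not bracket the midpoint yields a missing location, never a dropped
association.

Reciprocal records are matched greedily: driving from the
lexicographically smaller ID's log (so the result is invariant to input
order), each record is matched to the nearest unmatched counterpart within
±180 s; matched pairs become one two-way event at the earlier timestamp,
the rest become one-way events. Greedy nearest-in-time matching is
deterministic and order-stable; it is not a maximum matching, but with
reciprocal offsets of seconds (see below) the distinction is immaterial.

## Track processing

Fixes from fewer than 5 satellites or with residual error above 30 are
removed (boundary values kept). Steps are half-open 60-min windows
aligned to UTC hours — alignment is a reproducibility choice, independent
of deployment start. Positions are averaged arithmetically in lon/lat
(adequate at mid-latitudes and sub-degree scales; the antimeridian is not
handled). The travel rate of step *i* is the haversine distance between
the mean positions of steps *i−1* and *i* divided by the time between
window centres, so it measures displacement over an hour rather than
within-step path length; it is missing when the preceding window is empty.
Earth is a sphere of radius 6371.0088 km. Bathymetry lookup is
nearest-cell without interpolation: the 0.25-arc-min grid is fine relative
to GPS noise.

## Movement-state model

Hourly displacements are modelled as a 2-state HMM with exponential
emissions, f(y|λ_j) = λ_j⁻¹ e^(−y/λ_j); λ_j is the mean hourly
displacement of state j, with λ_slow < λ_fast enforced by relabelling.
The slow state is read as area-restricted search (ARS). Likelihood uses
the scaled forward recursion; smoothing uses forward–backward; fitting is
Baum–Welch EM (M-step λ_j = Σγ_t(j)y_t / Σγ_t(j)) with quantile-anchored
restarts (25th/75th percentile initial λ, first restart unjittered),
convergence at Δloglik < 1e-6, at most 500 iterations. Exact zero rates
are kept — the exponential density is positive at 0. Missing steps split
sequences into independent segments; nothing is imputed. The pipeline
default fits one pooled model (shared λ and chain, animals as independent
segments), with a per-animal option. Classification is slow iff
p(ARS) > 0.5, strictly: exactly 0.5 is fast.

With emission means in ratio 5 (e.g. 300 vs 1500 m/h) the emission
distributions overlap substantially; the per-step accuracy ceiling of the
Bayes-optimal smoother at those parameters is ≈ 0.88, which the fitted
model attains (the test suite compares the fit against that oracle rather
than against an unreachable constant).

## Availability sampling

Per track, a product bivariate normal KDE on a 500 (lon) × 220 (lat) grid
of cell centres, computed in degrees (matching the classical reference
implementation, which this package's version reproduces to 1e-8 in the
cross-check test). Bandwidths per axis follow the normal reference rule,
kernel sd = 1.06·min(sd, IQR/1.34)·n^(−1/5). The grid spans the track
bounding box padded by one bandwidth per side (extent is otherwise
unspecified; per-track extent is used rather than one shelf-wide frame).
Sample totals (default 5000) are apportioned across animals proportionally
to track length by largest remainder; cells are drawn with probability
proportional to density mass and positions jittered uniformly within the
cell, so sampled depths are not quantised to cell centres.

## Inference

Depth and rate models are Gaussian linear mixed models with a random
intercept per animal and AR(1) residual correlation within each animal's
serially ordered steps, fitted by **exact marginal maximum likelihood**
rather than PQL: for an identity-link Gaussian response the two target the
same model, and exact ML admits a closed-form oracle (the assembled
multivariate normal density) plus a direct cross-check against
`nlme::lme(correlation = corAR1, method = "ML")`, both in the test suite.
Each likelihood evaluation exploits the AR(1) innovations transform and
the Woodbury identity (O(n) per group); β is profiled by GLS and
(log σ_b, log σ_e, atanh φ) optimised by Nelder–Mead. The depth model's
availability ("random") rows have no natural serial order; they form one
pseudo-group in sampled order — an explicit modelling convention.
Standard errors come from the GLS information matrix; p-values use a t
reference with n−p degrees of freedom.

The sex-pair composition test uses G = 2ΣO_i ln(O_i/E_i) with the
Williams correction q = 1 + (k²−1)/(6n(k−1)), G_adj = G/q, and a χ²_{k−1}
tail, uniform expected proportions by default. Applied to the published
counts (94, 52, 55) under a uniform null this gives G_adj ≈ 15.5 — about
double the value originally reported alongside those counts; the standard
formula is implemented and the discrepancy left as is.
Quantiles everywhere are linear-interpolation quantiles; depths are
positive metres down.

## Synthetic deployments

The generator mirrors the measurement system rather than any richer
behavioural theory: hourly latent states follow a 2-state Markov chain,
hourly step lengths are Exponential(λ_state) — deliberately the same
family the HMM fits, so parameter recovery is well-posed — with headings
persisting (wrapped-normal noise, sd (1−persistence)·π) and optionally
biased toward the nearest shallow bank centre. Positions are linear
within hours and stored at 1-min resolution; ground truth (states and
maximal dyad proximity intervals at 1-min resolution) is retained.

Defaults are the study conditions this emulates: 13 animals, 79 days,
15-min GPS schedule, 60–180 s transmission gaps, 300 m hard detection
range (a logistic range curve with 50 m scale is available; no measured
range curve exists for these tags, so both are placeholders), 97%
reciprocal records, GPS noise sd 25 m (typical snapshot-GPS accuracy),
fix dropout 0.075 (matching ~3.7 fixes/h observed at a 4/h protocol),
degraded-fix fraction 0.05, false detections 0.025 per receiver-day
(≈26 over 13 receivers × 79 d). Where the emulated study reports no
value (λs, persistence, bank geometry) values were chosen once to bracket
its observed travel rates (λ_slow = 800, λ_fast = 4000 m/h ≈ 0.22 and
1.1 m s⁻¹) and not revisited. Reciprocal records are offset by
U(0, 10) s — the pair is the same transmission logged on two clocks —
which keeps greedy pairing essentially lossless, as observed in the real
system.

What the generator does **not** emulate: acoustic propagation physics
(detection is a pure range threshold), haul-out periods ashore, diving
(and hence GPS gaps from submergence), tides and currents, and clock
drift beyond seconds. Passing recovery tests therefore shows the
*analysis chain* is correct under the stated generative assumptions, not
that those assumptions capture every feature of field data.

## Problem sizes and determinism

Tests and the acceptance script run scaled deployments (3–8 animals,
3–14 days) and simulation sizes (5,000-step HMM sequences, 13×150
mixed-model observations, 10⁴–10⁵-draw sampling checks) chosen so the
whole suite completes in a few minutes while keeping Monte-Carlo error
well inside each stated tolerance; calibration checks that quote a
tolerance (e.g. 2% on emission means) use enough simulated hours that
sampling noise is a fraction of the band. Every random quantity flows
from explicit integer seeds: same configuration, same bytes.
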