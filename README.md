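# sealassoc

Analysis of at-sea associations among marine predators carrying
transmit-and-listen acoustic transceivers and archival GPS tags.

Animal-borne acoustic transceivers log the unique codes of other tagged
animals within a few hundred metres, turning pairwise proximity into a
time-stamped record. Combined with archival GPS tracks, this lets movement
ecologists ask when, where and between whom at-sea associations occur —
behaviour that satellite tracks alone cannot resolve. `sealassoc`
implements the full analysis chain for such deployments (the motivating
system is grey seals foraging over shallow offshore banks), together with
a synthetic deployment generator with known ground truth so every stage
can be validated.

## What the package computes

- **Detection cleaning and pairing** — flagged false detections are
  removed; the reciprocal records a detection leaves on both units are
  collapsed into single events by greedy nearest-in-time matching
  (±180 s), so each detection between two animals is counted once.
- **Gap-rule associations** — an association between two animals is a
  maximal run of detection events with no inter-event gap exceeding
  30 min; single-detection associations get a nominal 3-min duration.
  Locations are linearly interpolated from each animal's GPS track at the
  association midpoint.
- **Track discretisation** — Fastloc-style fixes from <5 satellites or
  with residual error >30 are dropped; tracks are averaged into 60-min
  UTC-aligned steps; travel rate is the distance between consecutive step
  positions over elapsed time; bathymetric depth is attached by
  nearest-cell lookup from an ESRI ASCII grid.
- **Movement states** — hourly displacements y_t are modelled as a
  two-state hidden Markov model with exponential emissions
  f(y|λ_j) = λ_j⁻¹ exp(−y/λ_j), where λ_j is the mean hourly displacement
  of state j. Fitting is by Baum–Welch EM; a step is area-restricted
  search (ARS) when the smoothed p(ARS) > 0.5.
- **Availability sampling** — a bivariate normal-kernel density surface
  (500×220 grid, normal-reference bandwidths) fitted to each track weights
  random sampling of locations, whose depths characterise available
  habitat; samples are apportioned across animals by track length.
- **Inference** — depth and travel rate are compared across association
  categories with a Gaussian mixed model (random intercept per animal,
  AR(1) residual correlation φ within each animal's ordered steps) fitted
  by exact maximum likelihood; sex-pair composition of associations
  (MM/MF/FF) is tested with the Williams-corrected G statistic.

## Worked example

`examples/` holds one short script per capability. Running
`python examples/02_detect_associations.py` (a 4-animal, 5-day simulated
deployment) prints:

```
false detections removed: 0
detection events: 976 (97.6% two-way)
associations: 46
median detections per association: 10
median duration: 0.15 h
median separation at events: 0.19 km
```

Reading: the reciprocal-pairing step matched 97.6% of detections to their
partner record on the other unit; the gap rule grouped the 976 events into
46 associations, typically lasting a few tenths of an hour; and the
GPS-interpolated separation at detection times (~0.2 km) confirms the
events reflect genuine sub-detection-range proximity.
`examples/06_full_pipeline.py` runs the whole chain and prints the final
report with the fitted movement-state, depth and travel-rate models.

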