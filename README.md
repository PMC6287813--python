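# kymokin

Kymograph extraction and binding-kinetics quantification for single-filament
TIRF microscopy.

## The problem

Proteins such as tropomyosin polymerise head-to-tail along each of the two
grooves of an actin filament. In a TIRF movie of one filament, a kymograph
(intensity along the filament backbone versus time) then shows three distinct
levels — background, single-bound and double-bound — and the *boundaries*
between these regions carry the kinetics: where binding nucleates, how fast
strands elongate toward the barbed and pointed ends, where same-side strands
meet, and where dissociation initiates and terminates. `kymokin` implements a
semi-automated, scriptable version of this analysis for straight filaments:

1. **Registration** — association and dissociation movies are acquired
   separately (typically 10 Hz and 1 Hz); a rigid transform (rotation +
   translation, regular-step gradient descent on the mean-squared intensity
   difference) maps them into one frame of reference.
2. **Kymograph extraction** — average intensity along a straight path,
   optional perpendicular averaging width.
3. **Boundary detection** — per intensity level: thresholding, 2-D median
   filtering, morphological erosion / hole-fill / re-dilation, then the
   transition-time curve τ(x) (first bound frame during association, last
   bound frame during dissociation). Boundaries are cross-validated by a
   per-pixel least-squares fit of two step transitions of *identical*
   magnitude, f(t) = b + m·[t≥t₁] + m·[t≥t₂].
4. **Editing** — scripted cut / join / delete / side-assignment /
   artifact-masking operations with a replayable edit log, replacing the
   manual curation step (crossing strands on opposite sides are found
   automatically as opposite-facing "V" pairs of the two τ curves).
5. **Events** — nucleations and meetings as extrema of τ(x) during
   association, dissociation initiation and end points (DIP/DEP) during
   dissociation, with prominence/separation controls.
6. **Rates** — linear fits of boundary position versus time between a
   nucleation and its neighbouring end points; weighted per-direction
   averages; through-origin concentration fits (slope = Σcᵢrᵢ/Σcᵢ²).
   A calibration on simulated movies of filaments growing at known rates
   A quantifies the minimum measurable rate: the measured rate M follows
   M = R_cutoff + (A − R_cutoff)·H(A − R_cutoff), and R_cutoff is fitted by
   piecewise least squares.
7. **Nucleation kinetics** — Kaplan–Meier estimator
   S(t) = Π_{i<t} (1 − dᵢ/nᵢ), where dᵢ counts nucleations at frame i and
   nᵢ the *available* sites (pixels neither occupied nor adjacent to an
   occupied pixel); the nucleation time t_nuc comes from a least-squares fit
   of exp(−t/t_nuc) to the estimator steps, with pooling across filaments.

A fully parameterised synthetic-data module generates (a) PSF-blurred movies
of elongating filaments with camera noise, for the cutoff calibration, and
(b) two-sided lattice kymographs with complete ground truth (occupancy,
boundary curves and all event types), on which every pipeline stage is
tested.

## Worked example

```python
from kymokin import (
    LatticeSimConfig, ThresholdSettings, simulate_two_sided_kymograph,
    detect_boundaries, detect_all, rates_from_events, weighted_average_rate,
    km_estimator, fit_nucleation_time, available_sites, pool_estimators,
)

# synthetic filament: two-sided lattice, moderate noise, 92 nm pixels at 1 Hz
cfg = LatticeSimConfig(
    lattice_length=120, n_frames_assoc=250, nucleation_rate=3e-4,
    elongation_rate=0.5, noise_sigma=1.0, seed=8,
)
kymo, truth = simulate_two_sided_kymograph(cfg)

settings = ThresholdSettings(low_threshold=10.0, high_threshold=20.0,
                             median_window=(3, 3), structuring_element=("disk", 0))
bounds = detect_boundaries(kymo, settings, phase="association")
events = detect_all(bounds)
print(f"nucleations: {len(events.nucleations)} (planted {len(truth.nucleations)})")
print(f"meetings:    {len(events.meetings)} (planted {len(truth.meetings)})")

records = rates_from_events(bounds, events, polarity="p0-barbed",
                            pixel_size_nm=92.0, frame_interval_s=1.0)
for d in ("toward_barbed", "toward_pointed"):
    print(f"weighted mean elongation {d:>14}: {weighted_average_rate(records, d):5.1f} nm/s")

curves = []
for side in (0, 1):
    occ = truth.occupancy[side, :, :cfg.n_frames_assoc]
    frames = [f for s, _, f in truth.nucleations if s == side]
    curves.append(km_estimator(frames, available_sites(occ), cfg.n_frames_assoc,
                               frame_interval_s=1.0))
fit = fit_nucleation_time(pool_estimators(curves))
print(f"nucleation time t_nuc = {fit.t_nuc_s:.0f} s from {fit.n_events} events")
```

prints

```
nucleations: 5 (planted 6)
meetings:    4 (planted 4)
weighted mean elongation  toward_barbed:  51.8 nm/s
weighted mean elongation toward_pointed:  48.1 nm/s
nucleation time t_nuc = 2010 s from 6 events
```

The configured elongation rate is 0.5 px/frame per direction = 46 nm/s at
92 nm pixels and 1 Hz; the recovered per-direction averages bracket it to
within the pixelation error of a noisy single filament. The nucleation-time
estimate from a single filament rests on six events and is correspondingly
uncertain (the configured per-site mean waiting time is 3333 s); pooling
estimators from many filaments recovers the configured time to within a few
percent (see the acceptance script).

A command-line front end mirrors the library
(`kymokin simulate|register|concat|kymo|detect|edit|events|rates|calibrate-cutoff|nucleation-time|run`),
each subcommand a thin wrapper reading/writing TIFF + YAML/JSON/CSV.

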