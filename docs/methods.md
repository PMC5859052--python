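# Methods

This note documents the models behind `restcompare`, the parameters that
matter, and what the synthetic validation does and does not establish.

## Forward model

The head is three concentric spherical shells (brain, skull, scalp) with
radii 8.7 / 9.2 / 10.0 cm and conductivities 0.33 / 0.0042 / 0.33 S/m —
conventional adult values with an ~80× resistive skull.  The scalp
potential of a current dipole is expanded in Legendre harmonics; per degree
n the five radial-profile coefficients (one regular term in the brain
shell, two in each outer shell) are fixed by potential/current continuity
at the interfaces and zero radial current at the scalp.  The per-degree
systems are solved exactly in units of the scalp radius, so truncation is
the only approximation: the default 100 terms leave a relative tail below
1e-12 for the deepest geometry used here, and a last-term check rejects
sources too close to the brain boundary, naming the offender.  In the
equal-conductivity limit the solution reduces to the homogeneous-sphere
transfer factor (2n+1)/n per degree; the test suite verifies the full
solver against an independently derived closed form (generating-function
summation of the series) to machine precision.  Lead fields are expressed
against infinity (no row centring) in µV per nA·m.

Electrode positions come from the extended 10-05 template bundled with
MNE, re-centred by a least-squares sphere fit and projected radially onto
the scalp shell.  The mm-level left/right asymmetries of the template
survive this projection; they are negligible for every measure used here.

## Synthetic EEG generator

Twelve radial dipoles sit on a shell at 0.8× the brain radius in a fixed
fronto-occipital layout: frontal alpha pair (10 Hz), occipital alpha pair,
parietal alpha pair, fronto-central theta pair (6 Hz), temporal beta pair
(20 Hz), central gamma pair (40 Hz).  Rhythms are unit-RMS Gaussian noise
band-passed to ±1 Hz around the centre frequency (zero-phase), scaled to
RMS dipole moments of 40–300 nA·m — chosen so scalp signals land in the
few-to-tens-of-µV range through this head model.  Sensor noise is white
Gaussian, default 2 µV per sample and channel (pink noise is a known
omission).

Phase couplings make target source j the renormalized mixture
`c·shift(source_i, δ) + (1−c)·independent`, where `shift` delays every
spectral component by δ radians via the analytic signal.  Strength c = 1
therefore yields strict phase locking (PLI 1 between the sources) and
c = 0 independence (PLI at the sampling floor).  Default couplings: a
strongly locked posterior alpha cluster (strengths 0.85–0.95, lags π/4–π/3),
mirror-symmetric parietal→frontal alpha couplings (0.6, π/5), a theta pair,
and weaker beta/gamma pairs.  The frontal couplings are deliberately
mirror-symmetric: an asymmetric coupling graph lets interference with the
posterior cluster (whose far-field gain at frontal electrodes is negative)
dominate the frontal power asymmetry, overriding the amplitude gains.

State effects, all exposed in `SourceConfig`:

* **eyes_open** multiplies alpha-band source amplitudes by 0.3 and
  alpha-coupling strengths by 0.5.  The amplitude factor reproduces alpha
  blocking; the coupling factor is needed because PLI is amplitude-invariant
  — without it, eyes-open connectivity would differ from eyes-closed only
  through the lower signal-to-noise ratio.
* Frontal alpha amplitudes carry separate hemispheric gains, 1.0 left vs
  1.5 right by default, producing the right-dominant resting asymmetry
  (LI ≈ −0.13 under AR, −0.17 under REST on the default cohort).
* **music** raises the theta-pair coupling to 0.9 and theta amplitude by
  1.5× (slow frontal rhythms during listening).  These effect sizes are
  placeholders — no quantitative target exists for them — and should be
  treated as configurable, not calibrated.

## Referencing

AR subtracts the instantaneous channel mean; if the recording is
referenced at a named electrode absent from the data, a zero trace is
restored first.  REST builds an equivalent-source model — 300 radial
dipoles spread evenly (golden-spiral lattice) on a shell at 0.86× the
brain radius — computes its infinity-referenced gain G, and maps
average-referenced data through `V_inf = G · pinv(G_ar) · V_ar`, where
G_ar is G with the channel mean removed and the pseudoinverse truncates
singular values below 1e-4 of the largest (G_ar is always rank-deficient
by one, having lost the common mode).

A structural point the tests make explicit: with more equivalent sources
than electrodes, the model spans all of channel space, including patterns
that are a pure common-mode offset.  AR destroys that component
irreversibly, so exact recovery holds for data whose sources lie in the
row space of G_ar (there it is exact to machine precision); for generic
dipole data REST restores the infinity potentials approximately
(channel-wise r > 0.998 noiseless, > 0.95 at 20 dB per-channel SNR for the
default generator).  Head radii, layer density and the SVD cutoff are
conventional choices, not fitted ones; results in this package are not
sensitive to doubling the source count or moving the cutoff a decade.

## Preprocessing and spectra

Filters are 4th-order Butterworth applied forward-backward (zero-phase):
0.5–100 Hz band-pass, 2 Hz-wide band-stop at 50 Hz, and analysis bands
delta 0.5–4, theta 4–8, alpha 8–12, beta 12–30, gamma 30–80, full
0.5–80 Hz (only the alpha edges are canonical; the rest are conventional).
Segments drop 10 s at each state boundary.  Spectra are Welch averaged
periodograms: Hann taper, 1 s segments (1 Hz resolution), 50% overlap.

Alpha blocking sums integer bins 8–12 Hz (five bins at the default grid).
The per-bin normalization printed in the index's definition divides each
bin's log-power difference by that bin's closed-state log power; this is
numerically unstable whenever a channel's power crosses 1 µV²/Hz
(log₁₀ → 0), which synthetic REST-referenced data do occasionally.  The
cohort pipeline therefore uses the band-sum variant (summed difference
over summed closed-state log power), which is stable and matches the
band-level description the source study attaches to its own figure; the
per-bin form remains the function's default for fidelity to the printed
formula.  The lateralization index rescales band powers so the minimum is
1 before taking logs — otherwise sub-unit powers give negative logs and an
unbounded index — keeping LI in [−1, 1] without affecting the
equal-power symmetry point.

## Phase connectivity and graphs

PLI uses analytic-signal phases of the band-filtered recording, wrapped
differences in (−π, π], and discards 5% of samples at each end against
transform edge artifacts.  `sign(0)` is defined as 0 (zeros still count in
N), so identical channels give PLI 0 rather than an undefined value.  The
default estimate uses the whole retained segment as one window; an
epoch-averaged mode exists.  For independent channels the estimator's
sampling floor is √(2/(πN)) for N independent samples — note that
band-limited signals have autocorrelated sign sequences, so their
effective N is duration × bandwidth, not the sample count.

Networks keep PLI as edge weight where it exceeds the threshold.  The
clustering coefficient uses the triangle-intensity form (numerator termwise
≤ denominator for weights ≤ 1, so C ∈ [0, 1]; vertices with degree < 2
contribute 0).  Path length is the reciprocal of global efficiency with
edge lengths 1/w and unreachable pairs contributing zero efficiency; a
network with no finite path is flagged disconnected and its SW value set
to 0.  The sweep runs thresholds 0.01–0.99 in steps of 0.01 (99 points);
the summary area sums SW over the 31 grid points in [0.2, 0.5].  The FCD
threshold Tc has no reconstructible defining rule, so it is an explicit
parameter, default 0.3 (interior of the summary band); the LFCD
neighbourhood is straight-line 3-D distance ≤ 5 cm, not geodesic.

## Statistics and pipeline

One-way ANOVA is computed from the standard sums-of-squares decomposition
with explicit degenerate cases (all values identical → F = 0, p = 1; zero
within-group variance with unequal means → F = ∞, p = 0); it matches
`scipy.stats.f_oneway` and equals the squared pooled-variance t statistic
for two groups.  Cohort contrasts are unpaired (two cohorts of n give
F(1, 2n−2), i.e. F(1, 74) at the reference study's n = 38), although the
same synthetic subjects underlie both references; a paired analysis would
be more powerful and is a deliberate omission to mirror the reported
design.  No multiple-testing correction is applied, matching the source
analysis.  The pipeline derives one seed per (subject, state) from the
study seed, and the whole report — metric tables, ANOVA table, run log —
is a pure function of the configuration; reruns are byte-identical.

Problem sizes used by the shipped drivers and the validation suite:
8-subject cohorts, 60 s per state at 1,000 Hz (40 s analysed after
trimming), alpha band, 300 equivalent sources.  These are deliberate
desk-scale choices; nothing in the implementation caps n_subjects, bands
or durations.

## What passing tests show — and what they don't

The suite establishes internal correctness (analytic PLI anchors,
brute-force graph oracles on ≥500 random graphs, exact in-span REST
recovery, ANOVA calibration within 5% ± 1%) and that the pipeline recovers
the generator's imposed structure in the expected directions: positive
alpha blocking, negative LI, denser and more small-world eyes-closed
networks.  On this synthetic cohort REST also happens to show the larger
lateralization and eyes-closed connectivity density than AR — the same
direction the reference study reports on humans — but the generator was
not built to enforce reference-contrast directions, and no test asserts
them.  Real EEG differs in ways the generator does not emulate: non-white
(pink) noise, artifacts (blinks, EMG), non-spherical head geometry,
extended and non-radial sources, and nonstationary rhythms.  Conclusions
about real-data reference choice should rest on the measures' definitions
validated here, not on the synthetic effect sizes.
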