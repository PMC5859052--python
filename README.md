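# restcompare

How much does the choice of EEG reference change what you conclude about
brain activity?  `restcompare` implements a complete, testable version of a
classic comparison: the **average reference (AR)** — subtract the
instantaneous mean of all electrodes — against the **infinity reference**
obtained by the reference electrode standardization technique (**REST**),
which maps average-referenced scalp potentials back through an
equivalent-source head model to potentials against an ideally neutral point
at infinity.  The comparison is exercised end-to-end on synthetic 64-channel
EEG produced by a three-shell spherical-head forward model with fully
controlled ground truth, so every downstream claim can be checked against
what was actually simulated.

The measures compared under the two references:

* **Alpha blocking** — the reduction of 8–12 Hz power when the eyes open,
  per channel `ΔPᾱ = Σ_f [log₁₀P_close(f) − log₁₀P_open(f)] / log₁₀P_close(f)`
  averaged over channels (a band-sum variant normalizes the summed log
  difference by the summed closed-state log power).
* **Lateralization index** — `LI = (P_left − P_right)/(P_left + P_right)`
  over summed log alpha power of the prefrontal sets
  {Fp1, AF7, AF3, F7, F5, F3, F1} and {Fp2, AF8, AF4, F8, F6, F4, F2};
  negative LI means right-dominant alpha.
* **Phase lag index (PLI)** — for each channel pair,
  `PLI = |⟨sign(φ_a(t) − φ_b(t))⟩|` with phases from the analytic signal;
  insensitive to the zero-lag correlations produced by volume conduction.
* **Functional connectivity density** — per-channel count of partners with
  PLI above a threshold Tc, over the whole montage (GFCD) or within a 5 cm
  neighbourhood (LFCD).
* **Weighted small-world property** — clustering coefficient
  `C_i = Σ w_ij w_ik w_jk / Σ w_ij w_ik` and characteristic path length
  `L = 1/E` (E = global efficiency, edge length 1/w) of the thresholded PLI
  network, combined as `SW = C/L` and swept over thresholds 0.01…0.99;
  the sum of SW over thresholds 0.2–0.5 summarizes the curve.
* **One-way ANOVA** contrasts between references and behavioural states.

## Worked example

`analysis/` contains the study as numbered drivers.  `01_simulate.py`
writes a synthetic subject to disk (EDF/BrainVision); `02` and `03` compute
the spectral and network measures for a small cohort and a single subject;
`04_cohort_anova.py` runs the full comparison.  For example:

```
$ python analysis/03_connectivity_networks.py
subject 0 (seed 11), alpha band, Tc = 0.3:
  eyes_closed  ar    mean GFCD  56.50  mean LFCD  3.94  sw_area[0.2,0.5]  18.476
  eyes_closed  rest  mean GFCD  58.22  mean LFCD  4.22  sw_area[0.2,0.5]  18.628
  eyes_open    ar    mean GFCD  31.12  mean LFCD  2.12  sw_area[0.2,0.5]   2.863
  eyes_open    rest  mean GFCD  29.12  mean LFCD  2.25  sw_area[0.2,0.5]   2.584
```

Reading: with eyes closed each channel has ~57 suprathreshold alpha-band
PLI partners and the small-world curve integrates to ~18.5; opening the
eyes (which attenuates and decouples the simulated alpha sources) roughly
halves the connection density and collapses the small-world area — the
alpha-blocking analogue in network terms.  On the 8-subject cohort
(`04_cohort_anova.py`) the state contrast is significant for every network
metric (e.g. sw_area: F(1,14) = 1494.8 under AR), while AR-vs-REST is
significant for the spectral indices (REST shows the stronger lateralization,
LI −0.171 vs −0.130, F(1,14) = 92.7) and for eyes-closed connectivity
density (REST 58.0 vs AR 55.9, F(1,14) = 89.1).

The same stages are scriptable via the `restcompare` CLI
(`simulate`, `preprocess`, `reref`, `spectrum`, `pli`, `network`, `run`).

## Layout

```
src/restcompare/   library: montage, head model, generator, I/O, filters,
                   referencing, spectra, PLI, graph metrics, stats, pipeline
analysis/          numbered study drivers writing tables under results/
tests/             pytest suite (unit, property and end-to-end)
docs/methods.md    model assumptions, parameter choices, limitations
```
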