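# Methods

`nfkbe2f` models the two-way coupling between TNFα-driven NF-κB (RelA)
signalling and the E2F cell-cycle program in single cells, and implements the
analysis pipeline used to quantify that coupling: virtual synchronization of
asynchronous cells, per-cell response descriptors, rank-based group
statistics, and fluorescence-spectroscopy quantification. A seeded synthetic
data generator stands in for live-cell imaging and FCS/FCCS measurements, so
the whole pipeline is testable end-to-end with known ground truth.

## The ODE model family

Three nested deterministic mass-action/Hill models, time in minutes,
concentrations in nM, equal effective compartment volumes (so summed
concentrations are conserved quantities).

**base** — the canonical dual-feedback NF-κB oscillator. TNFα converts
neutral IKK to its active form (`k_ikk_act`, scaled multiplicatively by the
dose, 1 ≡ saturating 10 ng/ml); active IKK is inactivated (`k_ikk_inact`) and
slowly recycled (`k_ikk_cycle`). Active IKK degrades IκBα both free and in
the NF-κB:IκBα complex, releasing NF-κB, which is imported into the nucleus
and drives Hill-type transcription of IκBα (fast negative feedback, Hill
coefficient 3) and A20 (slow negative feedback attenuating IKK activation).
Newly made IκBα enters the nucleus, binds NF-κB and exports it. Total RelA
(80 nM, matching a ~300k-molecule cell) has no synthesis or degradation
terms and is conserved to solver precision.

**e2f1** — adds nuclear E2F-1, which competes with IκBα for free NF-κB:
reversible E2F-1·NF-κB binding (Kd 5 nM vs 1 nM for IκBα, so IκBα binds
tighter), multiplicative repression of IκBα transcription by E2F-1
(factor 1/(1+[E2F-1]/K)), repression of E2F-1 synthesis by nuclear NF-κB
(same form), and first-order E2F-1 turnover acting on free and bound
E2F-1 alike (bound turnover releases NF-κB). Setting E2F-1 synthesis and
initial E2F-1 to zero reduces this variant exactly to `base`.

**revised** — adds E2F-4, synthesized under E2F-1 drive, which binds the
*cytoplasmic* NF-κB:IκBα complex into a ternary complex whose IκBα is not a
substrate for IKK-driven degradation. This IκBα stabilization is what
delays and damps the NF-κB response in S-phase, when E2F-4 peaks. Setting
the E2F-4 binding rate to zero reduces the variant exactly to `e2f1`.
E2F-4 binds only the complex, never free RelA: whether E2F-4 also competes
for the RelA binding site is left open, and the simplest consistent
formulation is used.

Phospho-Ser536 RelA is not an explicit species; reduced RelA phosphorylation
under E2F co-expression is an emergent readout of reduced IKK flux through
protected complexes.

### Default parameters and their calibration

Default rates were fixed once against the qualitative behaviours the system
is known for, and are exposed for override via `build_model` / YAML configs:

- unstimulated equilibrium is strongly cytoplasmic (N:C ≈ 0.08);
- sustained saturating TNFα produces nuclear-RelA oscillations with a first
  inter-peak interval of ~98 min that persist (amplitude ~0.6 in N:C) for
  at least 30 h;
- high constitutive E2F-1 shifts the unstimulated equilibrium nuclear
  (N:C > 1), and raising IκBα expression restores N:C < 1 — the
  co-transfection localization pattern;
- E2F-1 turnover (t½ ≈ 50 min by default; sweepable) sets the timescale on
  which RelA relocalizes to the cytoplasm after transient co-expression,
  monotonically and with Spearman ρ > 0.9 across a 30-point half-life sweep.

Integration uses LSODA with rtol 1e-8 / atol 1e-10 nM by default (the
population generator uses 1e-6/1e-8; halving tolerances moves N:C series by
<0.1%), dense output onto the caller's grid, splitting at stimulus and
mitosis discontinuities. Negative concentrations are never clipped; values
below −10·atol abort with the failing time.

## Cell-cycle program

A `CycleProgram` carries the population's timing: log-normal
mitosis-to-mitosis durations (mean 20 h, SD 1.9 h), phase boundaries at
fractions 0.40 / 0.50 / 0.85 of the realized duration (G1 ≈ 8 h, a ~2 h
G1/S window, S ≈ 7 h, G2 ≈ 3 h — anchored on a double-thymidine release
landing at G1/S and mid-S four hours later), and smooth log-normal-shaped
synthesis-drive bumps for E2F-1 (peak at fraction 0.45, within the G1/S
band) and E2F-4 (peak lagged 0.22 of a cycle into S-phase; narrower so both
profiles are <5% of peak at mitosis). FUCCI-like red/green reporter ramps
cross at the middle of the G1/S band; `fucci_crossing` locates the first
positive-to-negative sign change of (red − green) by linear interpolation,
optionally after moving-average smoothing.

## Synthetic populations

Each synthetic cell realizes a mitosis schedule (asynchronous start),
per-cell log-normal kinetic multipliers (CV 0.1 on TNF→IKK activation and
IκBα transcription), a reporter scale (CV 0.15) that halves at each
division, and runs the `revised` model with E2F synthesis gated by its own
cycle clock. Reported intensities are scale·(concentration + background)
with 5% multiplicative measurement noise (the imaging noise level is a
package decision; the study does not quantify it). The background term
plays the role of cellular autofluorescence and keeps measured N:C ratios
in the imaging range (rest ≈ 0.4, first-peak normalized amplitudes ≈ 3–4).

Three generator defaults encode the imaging line's response regime and were
calibrated once, before freezing, against the study's qualitative pattern
(G1/S-enhanced, S-suppressed first response): partial rather than complete
first translocation (`k_complex_deg_ikk` 0.002), strong E2F-1 repression of
IκBα transcription (`K_rep_ikba` 12 nM), and weak pre-stimulus E2F-1·RelA
capture (`kf_nfkb_e2f1` 0.01). With complete translocation the first-peak
amplitude saturates in every phase and no G1/S enhancement is possible;
partial translocation lets the repressed IκBα resynthesis at G1/S deepen
the peak while accumulated E2F-4 damps it in S.

**Programmed cycle effect.** Cells stimulated with cycle-clock fraction in
[0.22, 0.50) — late G1 through the G1/S band, reflecting the observation
that late-G1 cells are the susceptible ones — pause at the S-entry boundary
for a truncated-normal delay (mean 6.8 h, SD 3 h). These two numbers encode
the three reported population effects simultaneously at 200 cells/arm:
0.28 × 6.8 ≈ +1.9 h mean shift, a mixture-variance SD ratio ≈ 2, and a
G1/S-subset lengthening ≈ 6.8/20 ≈ 1/3. Because the pause is inserted at
the boundary rather than stretching the cycle, the phase position at
treatment is unaffected, which keeps ground truth and phase assignment
coherent. Ground truth (phase, durations, multipliers, applied delay) lives
in a JSON sidecar so the analysis runs blind on the CSV alone.

The cycle-effect analysis uses matched arms (same seed for the untreated and
treated populations): base durations and treatment phases coincide, so the
contrast isolates the applied TNFα effect — a paired-simulation
variance-reduction device; the bootstrap CIs are computed unpaired.

Timing-only analyses (cycle durations) can set `simulate: false`, which
skips the ODE and emits flat reporter channels; mitosis schedules, the
cycle effect, FUCCI channels and ground truth are identical to the full
mode. The shipped duration scenarios use it.

**Spectroscopy inputs.** FCCS triplets satisfy
[A][B] = Kd·[AB] exactly before 10% multiplicative per-channel noise, with
free abundances uniform on 5–200 nM. FCS inputs invert the counting formula
(below) for a target whole-cell count, with each compartment's particle
number the average of 10 Poisson draws, mirroring the instrument's averaging
over repeated runs.

## Virtual synchronization

*Mitosis timing*: phase at treatment = (treatment − last pre-treatment
mitosis) mapped through the program boundaries, using either the cell's
observed spanning-cycle duration (`realized`, exact on untreated cells) or
the program mean (`mean`, the right choice for treated populations whose
spanning cycle includes the induced pause). Assignments within 0.02 of a
boundary fraction are flagged and excluded from grouping by default.

*E2F-1 peak*: each cell is registered on the maximum of its smoothed
(window 5) E2F-1 reporter within the treatment-spanning cycle; cells whose
maximum sits on the window edge are excluded with a count. Treatment time
relative to the peak, plus the program boundaries with the peak placed at
the G1/S band midpoint, yields the phase band. A cubic smoothing spline
(GCV-selected penalty) of peak-normalized level against relative time
summarizes the pooled population; on defaults it is unimodal with its
maximum at relative time 0.

## Trace features and statistics

Features are computed on the N:C ratio series (invariant under common
rescaling of the channels): normalized first-peak amplitude (max N:C within
120 min post-treatment ÷ N:C at treatment; 1.0 with censored time-to-peak
when nothing rises), peak lists from `scipy.signal.find_peaks` with
prominence 0.2 and 40-min separation (configurable; the refractory analysis
detects on the raw N:C series because its baseline is itself nuclear),
refractory delay (treatment to second post-treatment peak; censored below
two peaks), nuclear-occupancy and E2F half-times (fall halfway to the
plateau = median of the last 10% of samples, by linear interpolation), and
mitosis-to-mitosis durations. All censoring is explicit flags; group
statistics receive only uncensored values with counts reported.

Group tests: Kruskal–Wallis H with tie correction plus Dunn's rank-based
pairwise z tests with Bonferroni (optionally Holm) adjustment — implemented
directly (no post-hoc package in the stack) and verified against an
explicit rank-table enumeration; Levene's W (mean-centred by default) for
variance equality; seeded bootstrap (2000 resamples) for effect CIs. The
variability effect is reported on the SD scale.

Theil–Sen: median of all pairwise slopes (equal-x pairs skipped), CI from
the normal-approximation rank interval on the slope order statistics;
verified against full pairwise enumeration and `scipy.stats.theilslopes`.
Kd estimation regresses y = freeA·freeB on x = complex, so the slope *is*
the dissociation constant; the estimator tolerates wild outlying
measurements. Molecule counting:
count = n_nuc·(V_nuc/V_conf) + n_cyt·(V_cyt/V_conf), with the calibrated
0.59 fL confocal and 1420/6110 fL nuclear/cytoplasmic volumes as defaults.

## Scenarios

Six one-command scenarios (`nfkbe2f run <name>` or `analysis/0*.py`), each
deterministic given (config, seed), with YAML configs packaged under
`nfkbe2f/configs/`:

| scenario | design | headline |
|---|---|---|
| fig3_cycle_effects | 200 + 200 matched cells, timing-only | mean shift, SD ratio, subset effects |
| fig2_phase_response | 240 treated cells, mitosis sync | phase-wise amplitudes, Dunn contrast |
| fig6_refractory | 20 + 20 cells, CV 0.03, E2F-1 pool 150 nM | delay ratio ≈ 4 |
| fig8_alignment | 128 treated cells, E2F-1-peak sync | spline, phase contrast |
| fccs_kd | 46 triplets, truth 12 nM, 10% noise | Theil–Sen Kd |
| fcs_counting | 20 Poisson replicates | molecules per cell |

The refractory cohort starts from 95% of RelA in the nuclear E2F-1 complex
plus a 150 nM free E2F-1 pool (transient co-expression), sustained
saturating TNFα from t = 0; the resumption of oscillations — and hence the
delay ratio — is set by the E2F-1 clearance and E2F-4 protection kinetics
and is sensitive to the E2F-1 turnover rate (a ±5% change in that rate
moves the ratio by roughly ∓15%).

## Problem sizes and runtime

Shipped sizes (200/arm, 240, 128, 20/arm, 46, 20) are the study's regimes;
full-simulation populations cost ~0.5 s/cell, so the complete scenario set
runs in a few minutes on one CPU and the timing-only scenarios in seconds.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the pipeline relies on —
cycle-position-gated E2F drive, phase-dependent response modulation, the
programmed timing effects, reporter halving at division, multiplicative
noise, mass-action-consistent FCCS triplets. It does not emulate
segmentation error, photobleaching, uneven illumination, apoptosis or
lineage correlations beyond one division's inheritance, fold-change
response encoding, or cell-to-cell variability beyond log-normal rate
multipliers. Passing recovery tests therefore demonstrates that the
pipeline is correct and well-calibrated on data with the assumed structure,
not that the biological conclusions re-derive from raw imaging.

## Known limitations

- Appendix-level rate constants for the published oscillator were not
  available to this implementation; the defaults are package-owned
  calibrations with the documented behavioural anchors, and every value can
  be overridden from config.
- Equal effective nuclear/cytoplasmic volumes (no transport volume
  correction); N:C ratios are therefore internally consistent but not
  directly comparable to models that carry a volume ratio.
- The e2f1-variant equilibrium with strong constitutive E2F-1 relaxes
  slowly (hours); `equilibrate` needs the longer horizon used in the tests.
- Dunn CI / p-values use the normal approximation; at very small n the
  adjusted p-values are conservative.
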