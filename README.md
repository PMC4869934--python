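# nfkbe2f

Single cells must arbitrate between responding to inflammation and
continuing to divide. `nfkbe2f` is an analysis package for studying how
that arbitration works: it models the coupling between TNFα-driven NF-κB
(RelA) signalling and the E2F-1/E2F-4 cell-cycle transcription factors, and
implements the single-cell analysis pipeline that quantifies it —
"virtual synchronization" of asynchronous cells (inferring each cell's
cycle phase at stimulation from its own mitosis timing or E2F-1 reporter
peak, instead of chemical arrest), per-cell response descriptors from
nuclear:cytoplasmic (N:C) fluorescence ratios, rank-based group statistics,
and FCS/FCCS quantification (molecule counting, binding-constant
estimation). It is written for systems biologists who want to simulate,
re-analyse or power-test this class of live-cell experiment; a seeded
synthetic-data generator emulates the imaging and spectroscopy inputs with
known ground truth, so every stage is testable end-to-end.

## The models and estimators at the core

Three nested ODE variants (minutes, nM), built by `kinetics.build_model`:

- **base** — the NF-κB oscillator: TNFα → IKK cycle
  (neutral → active → inactive), IKK-driven IκBα degradation, nuclear
  import of free NF-κB, Hill-type NF-κB-driven transcription of IκBα
  (fast feedback) and A20 (slow feedback on IKK activation), IκBα-mediated
  export. Total RelA is conserved exactly.
- **e2f1** — adds nuclear E2F-1 competing with IκBα for free NF-κB,
  mutual transcriptional repression (E2F-1 ⊣ IκBα transcription,
  NF-κB ⊣ E2F-1 synthesis) and first-order E2F-1 turnover.
- **revised** — adds E2F-4 (an E2F-1 target peaking in S-phase) which
  binds the cytoplasmic NF-κB:IκBα complex into a ternary complex whose
  IκBα is protected from IKK-driven degradation — the mechanism that
  suppresses the NF-κB response in S-phase.

Key estimators: normalized first-peak amplitude
A = max N:C(t)/N:C(t₀) over the 2 h after treatment t₀; Kruskal–Wallis H
with Dunn's pairwise z = (R̄ᵢ−R̄ⱼ)/√((N(N+1)/12−T)(1/nᵢ+1/nⱼ)); the
Theil–Sen slope (median of pairwise slopes) of [A][B] against [AB], which
at equilibrium equals the dissociation constant K_d; and whole-cell
molecule counts n_nuc·V_nuc/V_conf + n_cyt·V_cyt/V_conf from confocal
particle numbers.

See `docs/methods.md` for the full model description, parameter defaults
and calibration rationale.

## Worked example

Each analysis is one command (equivalently `nfkbe2f run <scenario>`):

```bash
python analysis/01_cycle_effects.py
```

```
n per arm:            200
mean lengthening:     +1.88 h (95% CI 1.28..2.49)
SD ratio:             2.17-fold (Levene p = 7.8e-15)
G1/S subset (n=21): 30% longer
S subset    (n=66):  mean 20.3 h (no shift expected)
```

TNFα given to a matched synthetic population lengthens the average cell
cycle by ~1.9 h, roughly doubles the spread of division times, and the
cells that were in late G1/S at stimulation carry almost the whole effect
(~1/3 longer cycles), while S-phase-treated cells divide on schedule.

```bash
python analysis/02_phase_response.py
```

```
group sizes:   {'G2': 18, 'S': 65, 'G1': 97, 'G1/S': 13}
group means:   {'G2': 3.09, 'S': 2.77, 'G1': 3.37, 'G1/S': 3.34}
Kruskal-Wallis H = 74.6, p = 4.4e-16
G1/S vs S (Dunn): z = 4.39, adjusted p = 6.9e-05
```

Virtually synchronized cells show the complementary signalling-side
picture: the first NF-κB translocation is strongest around G1/S and
significantly suppressed in S-phase.

```bash
python analysis/03_refractory_period.py   # delay ratio ~3.8-4x
python analysis/04_e2f1_alignment.py      # E2F-1-peak sync, spline peak at 0 h
python analysis/05_spectroscopy.py        # Kd 11.8 nM (truth 12); 310,951 and
                                          # 23,920 molecules/cell
```

## Layout

```
src/nfkbe2f/        kinetics, cellcycle, synthetic_data, trace_features,
                    virtual_sync, stats_quant, pipeline, cli (+ YAML configs)
analysis/           numbered one-command drivers for each analysis
tests/              unit, property and end-to-end recovery tests
scripts/            acceptance.py
docs/methods.md     models, parameters, calibration, limitations
```
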