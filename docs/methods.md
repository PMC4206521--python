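# Methods

## The model

The package simulates the core negative-feedback loop of HiF-1α
regulation: oxygen-dependent capture of HiF-1α by pVHL, proteasomal
degradation of the captured HiF-1α in two compartments, and
transcriptional feedback of HiF-1 on pVHL expression. Seven mass-action
ODEs track free HiF-1α, free pVHL and the pVHL/HiF-1α complex in nucleus
and cytoplasm, plus one pVHL-mRNA pool (equations in the README). The
modeling assumptions, shared with the p53/MdM2 literature the rate
constants borrow from, are:

* **Oxygen acts only on complex formation.** Prolyl-hydroxylase chemistry
  is folded into the bimolecular rate `k_form`: 1000 nM⁻¹h⁻¹ in normoxia,
  small (≤ 10) under hypoxia. No explicit PHD/FIH enzymes, and no
  quantitative map from % O₂ to `k_form` — the rate itself is the oxygen
  proxy.
* **Synthesis is compartment-assigned.** HiF-1α appears in the nucleus
  (it is constitutively imported after translation); pVHL, carrying a
  nuclear-localization signal, likewise appears in the nucleus. Free
  species do not shuttle by default; the complex shuttles with
  export/import rates `k_export`/`k_import`. Two structural flags expose
  the alternative readings: `free_pvhl_shuttles` (free pVHL uses the same
  shuttle) and `mrna_driver` (feedback driven by free nuclear HiF-1α, the
  default, or by total HiF-1α).
* **Degradation releases the partner.** α (pVHL-independent) and γₙ/γ_c
  (pVHL-dependent, proteasomal) destroy the HiF-1α moiety and release
  pVHL; β destroys pVHL, free or complexed, and releases HiF-1α.
* **One reference volume.** Concentrations in the two compartments share a
  volume scale; shuttle rates are first-order in the source compartment.

## Parameters

| name | default | unit | origin |
|------|---------|------|--------|
| k_syn_hif | 1000 | nM·h⁻¹ | p53-analogy scale; sweep range 200–8000 |
| alpha_deg_hif | 0.27 | h⁻¹ | 160-min half-life of ODD-mutant HiF-1α (Moroz et al., 2009) |
| k_form | 1000 | nM⁻¹·h⁻¹ | normoxic value; the oxygen dial, range 0–1000 |
| k_dis | 7200 | h⁻¹ | p53/MdM2 complex (Hunziker et al., 2010); held fixed — only k_form/k_dis matters |
| beta_deg_vhl | 0.2 | h⁻¹ | 3.8-h pVHL half-life (Yang et al., 2013); 0.8 retained as the alternative reading |
| k_feedback | 2.966 | nM mRNA·(nM HiF)⁻¹·h⁻¹ | calibrated (below) |
| beta_deg_mrna | 0.6 | h⁻¹ | ~1 h mRNA half-life; dynamics insensitive |
| k_transl | 1.4 | h⁻¹ | p53/MdM2 value |
| gamma_nuc | 1 | h⁻¹ | nuclear proteasomal rate |
| gamma_cyt | 7 | h⁻¹ | cytoplasmic proteasomal rate; sets the ~6 min fast chase half-time |
| k_import | 10 | h⁻¹ | complex import |
| k_export | 1000 | h⁻¹ | complex export; range 10–1000, low values model proliferating cells |

### Calibration of the feedback rate

`k_feedback` is the one constant this package determines itself, by a
minimal-repair principle: one free constant pinned by one quantitative
anchor. The anchor is the normoxic equilibrium level of nuclear HiF-1α,
141 nM; `k_feedback = 2.966` is the root of
`nuclear_equilibrium(k_feedback) − 141 nM` with every other constant at
its tabulated value. Two observations then serve as independent checks:
the simulated cycloheximide chase decays bi-exponentially with a 5.79 min
fast half-time (reference: 6 min) and a fast-component weight of 0.49,
consistent with the roughly equal nuclear and cytoplasmic pools at
equilibrium (nuclear/cytoplasmic ratio 1.07).

A value of 0.001 is sometimes quoted for this constant in the source
literature. It is retained as a documented discarded candidate because it
is dimensionally and dynamically untenable here: pVHL production is
`k_transl·k_feedback·[driver]/beta_deg_mrna ≈ 0.0023·[driver]` nM·h⁻¹,
at most a few nM/h, while the 141 nM equilibrium at `k_syn = 1000 nM·h⁻¹`
requires a pVHL-dependent degradation flux near 960 nM·h⁻¹; total pVHL
loss is `β·(free + complexed)`, so no recycling arrangement of so small a
supply can carry that flux. With 0.001 the model relaxes to
`k_syn/α ≈ 3700 nM` and shows no pVHL-dependent behavior at all.

The `ChaseCalibration` class reproduces the general parameter-search
procedure (seeded log-space Latin hypercube plus Nelder–Mead refinement
over the free rate constants, objective = squared distance between the
simulated chase and a reference bi-exponential law). Its curve-only
optimum over `k_feedback` lies near 2.1; the shipped default deliberately
uses the equilibrium anchor instead, trading a small amount of curve
misfit for the exact 141 nM level.

### The β candidates

The tabulated pVHL degradation rate admits two readings, 0.2 h⁻¹
(= ln 2 / 3.8 h, the measured half-life) and 0.8 h⁻¹. Both give the same
equilibrium (within 0.2 nM) and chase fit (SSE within 1%), so the anchors
do not discriminate; the shipped default is the half-life-derived 0.2,
with 0.8 documented in the config reference.

## Protocols and their constants

* **Stationary state** — integrate 2000 h from a near-empty cell
  (10⁻³ nM everywhere), test the final 200 h window for sustained
  oscillation of nuclear HiF-1α (peak-to-peak > 10⁻⁴ of the mean, with an
  absolute floor of 100·atol so empty cells are not flagged), then polish
  with a damped Newton step; convergence requires ‖f‖∞ < 10⁻⁹ nM·h⁻¹.
  Oscillatory attractors are reported as a distinct status, not an error.
* **Cycloheximide chase** — from the normoxic stationary state, set
  `k_syn_hif = k_transl = 0`; 6 h at 1-min sampling; fit
  `w·2^(−t/τ₁) + (1−w)·2^(−t/τ₂)` by constrained multi-start least
  squares (half-times in log space, ordering enforced, deterministic per
  seed). Fits with τ₂/τ₁ < 1.5 or w outside [0.01, 0.99] are flagged
  degenerate and refitted mono-exponentially.
* **Hypoxic step** — switch `k_form` to a preset (10, 5 or 1) from the
  normoxic state; 30 h at 0.01 h sampling.
* **Reoxygenation** — 30 h of hypoxia (long enough to reach the hypoxic
  stationary state) then restore `k_form = 1000`; 30 h more; the switch
  instant is stored as an event marker. Oscillation onset = delay to the
  first peak with prominence ≥ 1% of the normoxic baseline; the early dip
  is reported separately as time-to-minimum.
* **Non-compartmentalized control** — same protocol with
  `k_export = k_import = 0` and the cytoplasm emptied; equivalent to the
  5-species nuclear subsystem (verified against an independently coded
  reduced system in the tests).
* **Equilibrium sweeps** — one stationary state per grid point;
  non-convergent cells are masked, never interpolated. The nuclear-switch
  threshold is the `k_form` at which the nuclear equilibrium reaches a
  criterion fold (default 2×) of its normoxic value, found by bisection
  in log `k_form`.

## Numerics

The system is stiff twice over: the complex pools relax at
`k_dis + k_export ≈ 8200 h⁻¹`, and the bilinear capture terms give
Jacobian entries up to `k_form·V_c ≈ 5·10⁶ h⁻¹` at the normoxic
equilibrium. The integrator is LSODA at rtol 10⁻⁸ / atol 10⁻¹⁰ nM with a
hard restart at every schedule breakpoint. Integrator undershoot below
zero is clipped only within 10·atol; larger negativity raises an error.
The solver is cross-validated against a fixed-step classical RK4 oracle,
which those Jacobian scales force to dt = 5·10⁻⁷ h (the explicit
stability bound |λ|·dt ≲ 2.79); agreement on a 10 h run is ~3·10⁻⁸
relative. Conservation of total HiF-1α and total pVHL is checked by
comparing a high-order Savitzky–Golay derivative of the stored totals
(never differentiating across a schedule breakpoint) against the net
source terms; on 30-s-sampled runs at tightened tolerance the interior
residuals stay below 10⁻³ nM·h⁻¹, and a deliberately corrupted state
column is detected at >10⁻¹ nM·h⁻¹.

## What the shipped operating point does and does not reproduce

Reproduced: the 141 nM normoxic nuclear equilibrium; near-equal nuclear
and cytoplasmic pools in normoxia; the bi-exponential chase with ~6 min
fast half-time; nuclear accumulation at low `k_form` that is monotone in
`k_form` and steeper for low-export (proliferating-type) parameter sets;
damped post-reoxygenation oscillations of nuclear HiF-1α that are
strongly attenuated (amplitude ratio ≈ 0.31) when compartmentalization is
removed.

Not reproduced, and why. The slow chase half-time cannot exceed
ln 2 / α ≈ 154 min, because every HiF-1α molecule is subject to α; a
217-min reference value is therefore out of reach of this reaction set at
the tabulated α. More broadly, with pVHL translated into the nucleus and
`k_form·H_n` far exceeding every other fate of free nuclear pVHL, each
pVHL molecule is captured the moment it is made, so the nuclear
degradation flux equals the pVHL supply and is nearly independent of
`k_form` ("supply-limited" regime). In consequence the hypoxic induction
at the shipped point is weak (peak nuclear fold 1.1–1.4 versus several
fold in experiments), the post-reoxygenation peak is 1.4× rather than
~2.5× baseline, and the equilibrium fold-changes of the
overexpression/pVHL-mutation scenarios are respectively linear (3× for a
tripled synthesis rate) and nearly flat in `k_form`. Structural variants
explored during development (the `free_pvhl_shuttles` flag with a weaker
feedback) do produce strong, correctly timed hypoxic induction — at the
cost of the bi-exponential chase, which collapses to a single fast
exponential, and of stationarity in the overexpression scenarios (limit
cycles appear). No single configuration of this reaction set reproduces
all of the target observations simultaneously; the shipped default
prioritizes the degradation-law and equilibrium anchors and documents the
rest as model limitations.

## Limitations

Beyond the above: no explicit PHD/FIH kinetics or O₂ concentration; no
compartment-volume corrections; deterministic mass action only (no
stochastic simulation); the reference chase curve's fast/slow amplitude
split is not published and defaults to w = 0.5; therapy scenarios are
pure parameter transformations and carry no pharmacokinetics.
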