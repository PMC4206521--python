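# Default rate constants of the HiF-1a / pVHL shuttle model.
# Concentrations in nM, time in hours. Edit a copy of this file and pass it
# to the CLI with --config, or override single values with --param.
parameters:
  # HiF-1a synthesis rate (nM/h); oxygen-independent, deposits HiF-1a in the
  # nucleus. Same magnitude as the p53 synthesis rate of the analogous
  # p53/MdM2 model (Hunziker et al., 2010). Sweep range [200, 8000].
  k_syn_hif: 1000.0
  # pVHL-independent HiF-1a degradation (1/h); from the 160 min half-life of
  # HiF-1a in ODD-mutant cells, which cannot bind pVHL (Moroz et al., 2009).
  alpha_deg_hif: 0.27
  # pVHL/HiF-1a complex formation rate (1/nM/h); the oxygen proxy. 1000 in
  # normoxia, <= 10 under hypoxia; range [0, 1000].
  k_form: 1000.0
  # Complex dissociation rate (1/h); p53/MdM2 value (Hunziker et al., 2010).
  k_dis: 7200.0
  # pVHL degradation rate (1/h); from the 3.8 h pVHL half-life measured by
  # Yang et al. (2013): ln 2 / 3.8 h ~= 0.2. The alternative reading 0.8 of
  # the same source is the discarded calibration candidate.
  beta_deg_vhl: 0.2
  # HiF-1-dependent pVHL-mRNA synthesis rate (nM mRNA per nM HiF per h);
  # calibrated: pinned by the 141 nM normoxic nuclear equilibrium (see
  # docs/methods.md). The literature value 0.001 cannot sustain the pVHL
  # pool and is the discarded candidate.
  k_feedback: 2.966
  # pVHL-mRNA degradation rate (1/h); ~1 h mRNA half-life (Hunziker et al.,
  # 2010); the dynamics is insensitive to it.
  beta_deg_mrna: 0.6
  # pVHL translation rate (nM protein per nM mRNA per h) (Hunziker et al.,
  # 2010); translated pVHL appears in the nucleus (NLS).
  k_transl: 1.4
  # pVHL-dependent proteasomal degradation of complexed HiF-1a (1/h):
  # nuclear and cytoplasmic. The cytoplasmic proteasome is the stronger in
  # resting cells (Zheng et al., 2006); gamma_cyt sets the ~6 min fast
  # chase half-time.
  gamma_nuc: 1.0
  gamma_cyt: 7.0
  # Nucleo-cytoplasmic shuttle of the complex (1/h); export-dominated in
  # slowly proliferating cells (Lee et al., 1999). k_export range [10, 1000]
  # (low values model proliferating cells).
  k_import: 10.0
  k_export: 1000.0
protocol:
  name: steady
  k_form: 1000.0
seed: 0
tolerances:
  rtol: 1.0e-8   # relative integrator tolerance
  atol: 1.0e-10  # absolute integrator tolerance, nM
output_dir: out
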