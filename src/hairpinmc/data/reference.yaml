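# Literature reference values for the GB1p hairpin series, used as worked-
# example inputs and by the report stage for side-by-side comparison.
# Folded populations are NMR chemical-shift estimates at 298 K; the 270 K
# thermodynamic table and the energy-component decomposition are values
# reported for replica-exchange MD in an optimized GBSW implicit solvent.
# Units: kcal/mol for free energies/enthalpies, cal/mol/K for entropies, K
# for temperatures.
folded_population_298K:
  GB1p: 0.30
  HP5A: 0.21
  GB1m3: 0.86
thermo_270K:
  HP5A:
    dG_md: 0.35
    dG_md_se: 0.1
    dG_exp: 0.82
    dG_exp_se: 0.4
    dU_md: -2.4
    dU_md_se: 0.4
    dS_md: -7.6
    tm_md: "<270"
    tm_exp: "<273"
  GB1p:
    dG_md: -0.44
    dG_md_se: 0.3
    dG_exp: -0.8
    dG_exp_se: 0.6
    dU_md: -9.9
    dU_md_se: 0.8
    dU_exp: -11.6
    dS_md: -38.0
    dS_md_se: 4.0
    dS_exp: -39.0
    tm_md: "~273"
    tm_exp: "<278"
  GB1m3:
    dG_md: -1.3
    dG_md_se: 0.2
    dG_exp: -1.1
    dG_exp_se: 0.2
    dS_md_note: "est. similar to HP5A (~-7.6)"
    tm_md: "~330"
    tm_exp: 333.0
energy_components_270K:
  HP5A:
    vdw: -3.5
    asp: -0.10
    elec: 12.2
    gb: -9.7
    elec_gb: 2.5
    total: -2.4
  GB1p:
    vdw: -0.50
    asp: -0.40
    elec: -14.9
    gb: 7.9
    elec_gb: -7.0
    total: -9.9
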