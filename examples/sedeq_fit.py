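"""Global monomer-dimer-tetramer fit of sedimentation-equilibrium data.

Simulates a three-speed, two-detector equilibrium experiment for a
p18m-like restriction factor (11.5 kDa monomer, 45 µM loading) and
recovers the dissociation constants by global fitting.
"""

from dimerswap import sedeq, synthetic

truth = sedeq.AssociationModel(
    monomer_mass=11500.0,  # Da
    kd12=0.71e-6,          # monomer-dimer Kd, M
    kd24=30.5e-6,          # dimer-tetramer Kd, M
)
scenario = synthetic.AUCScenario(
    model=truth, loading_concs=(45.0,), noise_sd=0.01, seed=1
)
profiles = synthetic.simulate_se_profiles(scenario)
print(f"simulated {len(profiles)} profiles "
      f"(3 speeds x absorbance + interference, 1 % noise)")

fit = sedeq.fit_global_mdt(
    profiles,
    sedeq.AssociationModel(monomer_mass=11500.0),
    baseline_per="none",  # the simulated optics carry no offsets
)
print(f"Kd(1-2) = {fit.kd12_hat * 1e6:.2f} uM  (generating value 0.71)")
print(f"Kd(2-4) = {fit.kd24_hat * 1e6:.1f} uM  (generating value 30.5)")
print(f"reduced chi^2 = {fit.reduced_chi2:.3f}")
# A sub-micromolar Kd(1-2) means the protein is almost entirely dimeric at
# the loading concentration; the weaker Kd(2-4) adds a tetramer shoulder
# that grows toward the cell base.  Reduced chi^2 near 1 indicates the fit
# reproduces the gradients to within the detector noise.
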