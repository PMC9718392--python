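run_name: optimised-method-demo
seed: 11
out_dir: aragsim_out
water: artificial
omega: 11.3
seed_mass_mg: 200
target_dose_mL: 5.0
n_replicates: 2
raman_groups:
  seed:
    fwhm_mean: 1.5
    n_spectra: 10
  precipitate:
    fwhm_mean: 2.5
    n_spectra: 10
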