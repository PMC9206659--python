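# Default synthetic group presets: qualitative normal-vs-tumor contrasts
# of collagen in breast tissue P-SHG.  Tumor stroma: lower SHG amplitude
# and fiber (pixel) density, higher susceptibility ratio R (hence higher
# DCP), straighter and less dispersed fibers (narrower SHG-CD / SHG-LD
# spreads).  Normal tissue additionally gets a second incoherently summed
# crossing-fiber layer, the mechanism producing DCP < 1.
#
# Units: r_* dimensionless; orientation_dispersion in degrees per walk
# step; alpha_sd in degrees; amplitude_* in detector counts per unit
# squared polarization; noise in counts.
normal:
  r_mean: 1.7
  r_sd: 0.15
  fiber_density_target: 0.30
  orientation_dispersion: 6.0
  alpha_sd: 30.0
  amplitude_mean: 60.0
  amplitude_sd: 12.0
  chirality: 0.3
  n_layers: 2
  noise:
    background_mean: 10.0
    background_sd: 2.0
    shot_noise: true
    shot_scale: 4.0
tumor:
  r_mean: 2.2
  r_sd: 0.15
  fiber_density_target: 0.12
  orientation_dispersion: 1.5
  alpha_sd: 12.0
  amplitude_mean: 25.0
  amplitude_sd: 6.0
  chirality: 0.3
  n_layers: 1
  noise:
    background_mean: 10.0
    background_sd: 2.0
    shot_noise: true
    shot_scale: 4.0
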