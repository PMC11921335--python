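n_homes: 124
seed: 0
urban_fraction: 0.7
urban_aromatic_multiplier: 2.0
spike_prob: 0.05
spike_multiplier: 50.0
volume_range:
- 20.0
- 120.0
adult_choices:
- 1
- 2
child_choices:
- 0
- 1
- 2
- 3
occupancy_fraction_range:
- 0.3
- 0.8
start_date: '2023-03-01'
n_days: 366
co2_noise_gsd: 1.0
acr_params:
  g_adult: 0.312
  g_child: 0.174
  co2_outdoor: 450.0
  furnishing_fraction: 0.07
seasonal_acr:
  winter:
    median: 0.7
    gsd: 1.35
  spring:
    median: 1.0
    gsd: 1.4
  summer:
    median: 1.2
    gsd: 1.5
  autumn:
    median: 0.8
    gsd: 1.35
voc_panel:
  ethanol:
    indoor_median: 320.0
    indoor_gsd: 3.0
    outdoor_median: 5.0
    outdoor_gsd: 2.0
  methanol:
    indoor_median: 30.0
    indoor_gsd: 2.5
    outdoor_median: 3.0
    outdoor_gsd: 1.8
  isopropanol:
    indoor_median: 20.0
    indoor_gsd: 3.0
    outdoor_median: 1.0
    outdoor_gsd: 2.0
  butane:
    indoor_median: 50.0
    indoor_gsd: 3.0
    outdoor_median: 2.0
    outdoor_gsd: 2.0
  propane:
    indoor_median: 30.0
    indoor_gsd: 3.0
    outdoor_median: 1.5
    outdoor_gsd: 2.0
  benzene:
    indoor_median: 0.7
    indoor_gsd: 1.8
    outdoor_median: 0.35
    outdoor_gsd: 1.8
  toluene:
    indoor_median: 2.0
    indoor_gsd: 2.2
    outdoor_median: 0.8
    outdoor_gsd: 2.0
  ethylbenzene:
    indoor_median: 0.45
    indoor_gsd: 2.0
    outdoor_median: 0.15
    outdoor_gsd: 2.0
  xylene:
    indoor_median: 1.22
    indoor_gsd: 2.2
    outdoor_median: 0.5
    outdoor_gsd: 2.0
  1,2,4-trimethylbenzene:
    indoor_median: 0.35
    indoor_gsd: 2.2
    outdoor_median: 0.12
    outdoor_gsd: 2.0
  1,2,3-trimethylbenzene:
    indoor_median: 0.15
    indoor_gsd: 2.2
    outdoor_median: 0.05
    outdoor_gsd: 2.0
  alpha-pinene:
    indoor_median: 3.0
    indoor_gsd: 2.5
    outdoor_median: 0.1
    outdoor_gsd: 2.0
  limonene:
    indoor_median: 12.0
    indoor_gsd: 2.8
    outdoor_median: 0.1
    outdoor_gsd: 2.0
  acetaldehyde:
    indoor_median: 15.0
    indoor_gsd: 2.0
    outdoor_median: 1.5
    outdoor_gsd: 1.8
  1,3-butadiene:
    indoor_median: 2.5
    indoor_gsd: 2.2
    outdoor_median: 0.3
    outdoor_gsd: 2.0
  carbon tetrachloride:
    indoor_median: 15.5
    indoor_gsd: 1.5
    outdoor_median: 0.6
    outdoor_gsd: 1.3
  chloroform:
    indoor_median: 1.0
    indoor_gsd: 2.0
    outdoor_median: 0.1
    outdoor_gsd: 1.8
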