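# Physiological and simulation parameters.
#
# Half-saturation constants K are one tenth of the physiological (tank)
# concentration of each metabolite, except lactate whose K equals that of
# glucose.  Diffusion coefficients are tissue values; glucose sits at the
# low end of reported tumor-spheroid measurements (~0.6-2.6e-10 m^2/s),
# calibrated so the oxygen and glucose Krogh lengths cross at Warburg
# number ~10.  The tank oxygen concentration (dissolved O2 at ~55 mmHg)
# is calibrated jointly with the tissue biomass density so the oxygen
# Krogh length at WN = 2 is ~40 um.
metabolites:
  glucose:
    molecular_weight: 0.18016     # g/mmol
    tank: 0.9                     # g/L (5 mM blood glucose)
    K: 0.09                       # g/L
    D: 7.7e-11                    # m^2/s
  oxygen:
    molecular_weight: 0.032
    tank: 0.0023                  # g/L dissolved
    K: 2.3e-4
    D: 2.0e-9
  lactate:
    molecular_weight: 0.09008
    tank: 0.09                    # g/L (1 mM blood lactate)
    K: 0.09                       # same as glucose
    D: 9.0e-10
  glutamine:
    molecular_weight: 0.14615
    tank: 0.073                   # g/L (0.5 mM)
    K: 0.0073
    D: 7.0e-10

growth:
  mu_aerobic: 0.018               # 1/hr, proliferative tumor phenotypes
  mu_quiescent: 1.0e-6            # 1/hr, stromal / hypoxic / hypoglycemic

fba:
  maintenance_rate: 5.0           # mmol ATP/g-DW-hr
  wn_tolerance: 0.01              # bisection stop on |WN - target|
  gln_glc_molar_ratio: 0.3        # glutamine-addiction uptake constraint

tissue:
  grid_h_um: 10.0                 # grid spacing, one cell diameter
  boundary_layer_um: 20.0         # endothelium-like diffusive layer
  cell_dry_density_g_per_L: 764.0 # 400 pg dry mass in a 10-um sphere
  krogh_tissue_density_g_per_L: 400.0  # dry biomass per tissue volume

abm:
  dt_hours: 1.0
  division_diameter_um: 10.0
  split_fraction_low: 0.45
  split_fraction_high: 0.55
  shove_tolerance: 0.05           # max residual overlap / radius
  shove_max_iter: 60
  domain_width_elements: 32
  domain_depth_elements: 96
  tumor_layers: 2                 # seeded rows of tumor cells
  seed_biomass_low: 0.5           # initial biomass as fraction of division mass
  seed_biomass_high: 0.9
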