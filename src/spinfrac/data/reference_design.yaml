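# Stock fractionation disk: 60 mm radius lane, five 7 mm Histopaque-1077
# gradient sections (A distal ... E) plus the 7 mm sample section F,
# 1 x 7 mm capillary valves at each section boundary, and the stock
# 500 RCF spin protocol.  Units: mm, g/mL, mPa.s, degrees, mN/m, s.
schema_version: 1
fluid:
  surface_tension_mn_per_m: 58.0
  contact_angle_deg: 110.0
  density_g_per_ml: 1.06
  viscosity_mpa_s: 4.0
lane:
  disk_radius_mm: 60.0
  sections:  # ordered proximal (sample) -> distal
    - {label: F, r_proximal_mm: 18.0, r_distal_mm: 25.0, medium_density_g_per_ml: 1.077, medium_viscosity_mpa_s: 1.5, volume_ul: 12.0}
    - {label: E, r_proximal_mm: 25.0, r_distal_mm: 32.0, medium_density_g_per_ml: 1.077, medium_viscosity_mpa_s: 1.5, volume_ul: 12.0}
    - {label: D, r_proximal_mm: 32.0, r_distal_mm: 39.0, medium_density_g_per_ml: 1.077, medium_viscosity_mpa_s: 1.5, volume_ul: 12.0}
    - {label: C, r_proximal_mm: 39.0, r_distal_mm: 46.0, medium_density_g_per_ml: 1.077, medium_viscosity_mpa_s: 1.5, volume_ul: 12.0}
    - {label: B, r_proximal_mm: 46.0, r_distal_mm: 53.0, medium_density_g_per_ml: 1.077, medium_viscosity_mpa_s: 1.5, volume_ul: 12.0}
    - {label: A, r_proximal_mm: 53.0, r_distal_mm: 60.0, medium_density_g_per_ml: 1.077, medium_viscosity_mpa_s: 1.5, volume_ul: 12.0}
  valves:  # footprint contained within the section boundary
    - {height_mm: 0.67, width_mm: 7.0, radial_position_mm: 25.0}
    - {height_mm: 0.67, width_mm: 7.0, radial_position_mm: 32.0}
    - {height_mm: 0.67, width_mm: 7.0, radial_position_mm: 39.0}
    - {height_mm: 0.67, width_mm: 7.0, radial_position_mm: 46.0}
    - {height_mm: 0.67, width_mm: 7.0, radial_position_mm: 53.0}
protocol:
  plateau_rcf: 500.0
  accel_rcf_per_min: 500.0
  decel_rcf_per_min: 322.0
  plateau_duration_s: 240.0
  reference_radius_mm: 60.0
panel:  # representative densities/radii (range midpoints)
  - {name: Monocyte, density_g_per_ml: 1.072, radius_um: 6.75, agglutination_factor: 1.0}
  - {name: Lymphocyte, density_g_per_ml: 1.075, radius_um: 4.5, agglutination_factor: 1.0}
  - {name: Basophil, density_g_per_ml: 1.075, radius_um: 4.75, agglutination_factor: 1.0}
  - {name: Neutrophil, density_g_per_ml: 1.085, radius_um: 6.75, agglutination_factor: 1.0}
  - {name: Eosinophil, density_g_per_ml: 1.095, radius_um: 6.75, agglutination_factor: 1.0}
  - {name: RBC, density_g_per_ml: 1.098, radius_um: 2.63, agglutination_factor: 1.0}
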