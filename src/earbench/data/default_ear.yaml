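bm:
  length_m: 0.0319
  n_sections: 400
  width_base_m: 0.0001
  width_apex_m: 0.0005
  thickness_base_m: 7.5e-06
  thickness_apex_m: 2.5e-06
  density_kg_m3: 1200.0
  strip_stiffness_constant: 3.0
scalae:
  area_base_m2: 2.0e-06
  area_apex_m2: 1.0e-06
  helicotrema_area_m2: 2.5e-07
  helicotrema_length_m: 0.001
  fluid_density_kg_m3: 1000.0
  fluid_sound_speed_m_s: 1500.0
  compressible: true
windows:
  footplate_axis_long_m: 0.00281
  footplate_axis_short_m: 0.00127
  footplate_area_rule: ellipse
  rw_height_m: 0.00162
  rw_width_m: 0.00115
  rw_thickness_m: 6.0e-05
  rw_youngs_pa: 350000.0
  rw_density_kg_m3: 1200.0
  rw_poisson: 0.3
  rw_loss_factor: 0.3
  vestibulum_volume_m3: 3.78e-08
  vestibule_duct_length_m: 0.004
greenwood:
  A: 165.0
  alpha: 2.1
  k: 1.0
  length_m: 0.0319
middle_ear:
  ec_length_m: 0.009
  ec_area_m2: 4.43e-05
  air_density_kg_m3: 1.204
  air_sound_speed_m_s: 343.0
  excitation_velocity_m_s: 1.0e-05
  tm:
    area_m2: 6.0e-05
    effectiveness: 0.6
    mass_kg: 6.0e-06
    stiffness_n_m: 250.0
    damping_ns_m: 0.05
    coupling_stiffness_n_m: 20000.0
    coupling_damping_ns_m: 0.02
  cavity:
    volume_m3: 6.3e-07
    mastoid_volume_m3: 5.0e-06
    neck_length_m: 0.005
    neck_area_m2: 1.0e-05
    neck_resistance_pas_m3: 500000.0
    recess_conductance_m3_pas: 1.18e-08
    enable_mastoid_branch: true
  ossicles:
    malleus:
      name: malleus
      mass_kg: 2.5e-05
      semi_axes_mm:
      - 1.0
      - 0.8
      - 4.0
      com_mm:
      - 0.5
      - 1.0
      - 2.0
      ref_mm: null
    incus:
      name: incus
      mass_kg: 2.8e-05
      semi_axes_mm:
      - 1.5
      - 1.5
      - 2.5
      com_mm:
      - 2.5
      - 2.0
      - 3.0
      ref_mm: null
    stapes:
      name: stapes
      mass_kg: 3.0e-06
      semi_axes_mm:
      - 1.4
      - 0.6
      - 1.0
      com_mm:
      - 3.5
      - 4.6
      - 0.8
      ref_mm:
      - 3.5
      - 5.0
      - 0.8
  joints:
    AML:
      name: AML
      body_a: null
      body_b: malleus
      point_mm:
      - -2.0
      - 1.5
      - 3.0
      stiffness:
      - 5000.0
      - 5000.0
      - 5000.0
      - 1.0e-05
      - 1.0e-05
      - 1.0e-05
      damping:
      - 0.02
      - 0.02
      - 0.02
      - 1.0e-09
      - 1.0e-09
      - 1.0e-09
    PIL:
      name: PIL
      body_a: null
      body_b: incus
      point_mm:
      - 4.0
      - 1.5
      - 4.0
      stiffness:
      - 5000.0
      - 5000.0
      - 5000.0
      - 1.0e-05
      - 1.0e-05
      - 1.0e-05
      damping:
      - 0.02
      - 0.02
      - 0.02
      - 1.0e-09
      - 1.0e-09
      - 1.0e-09
    SML:
      name: SML
      body_a: null
      body_b: malleus
      point_mm:
      - 0.5
      - 1.5
      - 4.5
      stiffness:
      - 0
      - 0
      - 50.0
      - 0
      - 0
      - 0
      damping:
      - 0
      - 0
      - 0.01
      - 0
      - 0
      - 0
    LML:
      name: LML
      body_a: null
      body_b: malleus
      point_mm:
      - 0.5
      - 0.5
      - 2.0
      stiffness:
      - 0
      - 50.0
      - 0
      - 0
      - 0
      - 0
      damping:
      - 0
      - 0.01
      - 0
      - 0
      - 0
      - 0
    TT:
      name: TT
      body_a: null
      body_b: malleus
      point_mm:
      - 0.5
      - 2.0
      - 1.5
      stiffness:
      - 0
      - 100.0
      - 0
      - 0
      - 0
      - 0
      damping:
      - 0
      - 0.01
      - 0
      - 0
      - 0
      - 0
    IMJ:
      name: IMJ
      body_a: malleus
      body_b: incus
      point_mm:
      - 1.5
      - 1.5
      - 3.5
      stiffness:
      - 100000.0
      - 100000.0
      - 100000.0
      - 0.1
      - 0.1
      - 0.1
      damping:
      - 0.05
      - 0.05
      - 0.05
      - 1.0e-06
      - 1.0e-06
      - 1.0e-06
    ISJ:
      name: ISJ
      body_a: incus
      body_b: stapes
      point_mm:
      - 3.5
      - 3.5
      - 0.8
      stiffness:
      - 5000.0
      - 5000.0
      - 5000.0
      - 1.0e-06
      - 1.0e-06
      - 1.0e-06
      damping:
      - 0.02
      - 0.02
      - 0.02
      - 1.0e-09
      - 1.0e-09
      - 1.0e-09
    annular:
      name: annular
      body_a: null
      body_b: stapes
      point_mm:
      - 3.5
      - 5.0
      - 0.8
      stiffness:
      - 0
      - 600.0
      - 0
      - 0.0002
      - 0
      - 0.0002
      damping:
      - 0
      - 0.02
      - 0
      - 1.0e-09
      - 0
      - 1.0e-09
  umbo_mm:
  - 0.0
  - 0.0
  - 0.0
  stiffness_scale: 10.0
  tm_compliance_scale: 2.226
  annular_stiffness_scale: 0.179
  damping_scale: 1.663
prosthesis:
  piston_diameter_m: 0.0006
  piston_length_m: 0.002
  wire_diameter_m: 0.0002
  wire_length_m: 0.004
  hole_diameter_m: 0.0008
  density_kg_m3: 4500.0
  gap_state: sealed
  seal_youngs_pa: 3000000.0
  seal_thickness_m: 0.0001
  seal_poisson: 0.3
  plate_thickness_m: 0.0002
frequency:
  f_min_hz: 100.0
  f_max_hz: 10000.0
  n_points: 60
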