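# Reference gothic coarctation network: a 1-D rigid-wall arterial tree
# matching the gothic arch phantom's junction geometry (lengths/diameters in
# mm) with the flow-model constants of the simulated case: blood density
# 1050 kg/m^3, dynamic viscosity 0.0035 Pa.s, inlet peak velocity 1.2 m/s,
# cardiac period 0.8 s, time step 0.005 s, laminar rigid-wall flow,
# arm/leg puncture pressures as outlet boundaries.
fluid:
  density_kg_m3: 1050.0
  viscosity_pa_s: 0.0035
boundary:
  inlet_peak_velocity_m_s: 1.2
  period_s: 0.8
  systolic_fraction: 0.35
  upper_limb_pressure_mmhg: 120.0
  lower_limb_pressure_mmhg: 65.0
solver:
  dt_s: 0.005
  max_newton_iterations: 200
  max_cycles: 10
main_segments:
  - {name: ascending, length_mm: 46.749, d_prox_mm: 12.000, d_dist_mm: 10.247}
  - {name: proximal_arch, length_mm: 13.169, d_prox_mm: 10.247, d_dist_mm: 9.600}
  - {name: distal_arch, length_mm: 13.169, d_prox_mm: 9.600, d_dist_mm: 7.157}
  - {name: isthmus, length_mm: 7.583, d_prox_mm: 7.157, d_dist_mm: 7.037,
     stenosis: {area_ratio: 0.25, length_mm: 8.0}}
  - {name: descending, length_mm: 20.203, d_prox_mm: 7.037, d_dist_mm: 7.800}
branches:
  - {name: brachiocephalic, attach_after: 0, length_mm: 25.0, d_prox_mm: 6.000, d_dist_mm: 5.100}
  - {name: LCCA, attach_after: 1, length_mm: 25.0, d_prox_mm: 4.500, d_dist_mm: 3.825}
  - {name: LSCA, attach_after: 2, length_mm: 25.0, d_prox_mm: 4.500, d_dist_mm: 3.825}
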