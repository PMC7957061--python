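# Astrocytic glutamate transporter (EAAT/GLT-1 type) kinetic cycle.
#
# 13-step ring with separate binding/unbinding of 3 Na+, 1 H+ and 1 Glu
# on the extracellular side, K+ countertransport on the return leg.
# Units: first-order rates ms^-1; ligand-dependent rates mM^-order ms^-1.
# H+ binding/unbinding rates are pseudo-first-order (fixed pH folded in).
#
# These default rate values are authored for this package: they are
# literature-plausible magnitudes (Glu on-rate ~1e7 /M/s, micromolar-range
# apparent Glu affinity, net +2 elementary charges translocated inward per
# cycle) constrained to exact cycle detailed balance (the product of
# forward base rates equals the product of reverse base rates, so the
# transporter's directionality is purely thermodynamic).  Edit freely;
# the loader validates structure, not values.
#
# z is the elementary charge moved *inward* when the transition fires;
# rates carry symmetric Eyring voltage factors exp(-z F V / (2 R T)).

name: eaat
states:
  - out_apo
  - out_na
  - out_na_h
  - out_na_h_glu
  - out_na2_h_glu
  - out_na3_h_glu
  - in_na3_h_glu
  - in_na2_h_glu
  - in_na2_h
  - in_na_h
  - in_na
  - in_apo
  - in_k
forward_cycle:
  - out_apo
  - out_na
  - out_na_h
  - out_na_h_glu
  - out_na2_h_glu
  - out_na3_h_glu
  - in_na3_h_glu
  - in_na2_h_glu
  - in_na2_h
  - in_na_h
  - in_na
  - in_apo
  - in_k
  - out_apo
transitions:
  # ---- outward-facing binding leg ----
  - {name: na1_bind_out,  from: out_apo,      to: out_na,        rate: 0.05, ligand: na_e, z: 0.5}
  - {name: na1_unbind_out, from: out_na,      to: out_apo,       rate: 20.0, z: -0.5}
  - {name: h_bind_out,    from: out_na,       to: out_na_h,      rate: 50.0}
  - {name: h_unbind_out,  from: out_na_h,     to: out_na,        rate: 10.0}
  - {name: glu_bind_out,  from: out_na_h,     to: out_na_h_glu,  rate: 0.3,  ligand: glu_e,
     particle: {action: bind, species: glu, source: pool}}
  - {name: glu_unbind_out, from: out_na_h_glu, to: out_na_h,     rate: 0.06,
     particle: {action: release, species: glu, dest: pool}}
  - {name: na2_bind_out,  from: out_na_h_glu, to: out_na2_h_glu, rate: 0.05, ligand: na_e, z: 0.5}
  - {name: na2_unbind_out, from: out_na2_h_glu, to: out_na_h_glu, rate: 10.0, z: -0.5}
  - {name: na3_bind_out,  from: out_na2_h_glu, to: out_na3_h_glu, rate: 0.05, ligand: na_e, z: 0.5}
  - {name: na3_unbind_out, from: out_na3_h_glu, to: out_na2_h_glu, rate: 10.0, z: -0.5}
  # ---- translocation of the fully loaded carrier ----
  - {name: translocate_loaded, from: out_na3_h_glu, to: in_na3_h_glu, rate: 2.0, z: 1.5}
  - {name: translocate_loaded_rev, from: in_na3_h_glu, to: out_na3_h_glu, rate: 0.5, z: -1.5}
  # ---- inward-facing release leg ----
  - {name: na1_release_in, from: in_na3_h_glu, to: in_na2_h_glu, rate: 20.0, ions: {na: 1}}
  - {name: na1_rebind_in, from: in_na2_h_glu, to: in_na3_h_glu,  rate: 0.5,  ligand: na_i, ions: {na: -1}}
  - {name: glu_release_in, from: in_na2_h_glu, to: in_na2_h,     rate: 5.0,  ions: {glu: 1},
     particle: {action: release, species: glu, dest: bath}}
  - {name: glu_rebind_in, from: in_na2_h,     to: in_na2_h_glu,  rate: 0.1,  ligand: glu_i, ions: {glu: -1},
     particle: {action: bind, species: glu, source: bath}}
  - {name: na2_release_in, from: in_na2_h,    to: in_na_h,       rate: 20.0, ions: {na: 1}}
  - {name: na2_rebind_in, from: in_na_h,      to: in_na2_h,      rate: 0.5,  ligand: na_i, ions: {na: -1}}
  - {name: h_release_in,  from: in_na_h,      to: in_na,         rate: 10.0, ions: {h: 1}}
  - {name: h_rebind_in,   from: in_na,        to: in_na_h,       rate: 100.0, ions: {h: -1}}
  - {name: na3_release_in, from: in_na,       to: in_apo,        rate: 20.0, ions: {na: 1}}
  - {name: na3_rebind_in, from: in_apo,       to: in_na,         rate: 0.5,  ligand: na_i, ions: {na: -1}}
  # ---- K+ countertransport return leg ----
  - {name: k_bind_in,     from: in_apo,       to: in_k,          rate: 0.05, ligand: k_i, ions: {k: -1}}
  - {name: k_unbind_in,   from: in_k,         to: in_apo,        rate: 5.0,  ions: {k: 1}}
  - {name: k_translocate_out, from: in_k,     to: out_apo,       rate: 5.0,  z: -1.0}
  - {name: k_translocate_in, from: out_apo,   to: in_k,          rate: 0.1,  ligand: k_e, z: 1.0}
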