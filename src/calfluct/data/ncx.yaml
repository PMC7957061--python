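# Na+/Ca2+ exchanger (NCX) kinetic cycle: 6-step consecutive (ping-pong)
# ring exchanging 3 Na+ for 1 Ca2+.  The forward cycle extrudes one Ca2+
# and imports three Na+ (net +1 elementary charge inward); the reverse
# cycle mediates Ca2+ entry.  Near rest the exchanger sits close to its
# reversal point, so small shifts in [Na+]i or [Ca2+]i flip its direction.
#
# Units: first-order rates ms^-1; na-dependent rates mM^-3 ms^-1 (the
# three Na+ bind in a single step), ca-dependent rates mM^-1 ms^-1.
# Default values are authored for this package: magnitudes chosen to give
# near-equilibrium turnover of order 1e2/s per molecule at rest while
# satisfying exact cycle detailed balance (product of base rates equal in
# both directions, so the reversal potential follows the 3:1 Nernst
# condition).  z is the elementary charge moved inward per transition;
# charge movement is split between the Na translocation/occlusion steps
# (-1.5 each outward leg) and the Ca translocation (+2).

name: ncx
states:
  - in_apo
  - in_3na
  - out_3na
  - out_apo
  - out_ca
  - in_ca
forward_cycle:
  - in_apo
  - in_ca
  - out_ca
  - out_apo
  - out_3na
  - in_3na
  - in_apo
transitions:
  # ---- Na+ limb ----
  - {name: na_bind_in,        from: in_apo,  to: in_3na,  rate: 1.0e-05, ligand: na_i, order: 3, ions: {na: -3}}
  - {name: na_unbind_in,      from: in_3na,  to: in_apo,  rate: 50.0,    ions: {na: 3}}
  - {name: na_translocate_out, from: in_3na, to: out_3na, rate: 5.0,     z: -1.5}
  - {name: na_translocate_in, from: out_3na, to: in_3na,  rate: 5.0,     z: 1.5}
  - {name: na_release_out,    from: out_3na, to: out_apo, rate: 100.0,   z: -1.5}
  - {name: na_rebind_out,     from: out_apo, to: out_3na, rate: 3.0e-06, ligand: na_e, order: 3, z: 1.5}
  # ---- Ca2+ limb ----
  - {name: ca_bind_out,       from: out_apo, to: out_ca,  rate: 10.0,    ligand: ca_e,
     particle: {action: bind, species: ca, source: bath}}
  - {name: ca_unbind_out,     from: out_ca,  to: out_apo, rate: 100.0,
     particle: {action: release, species: ca, dest: bath}}
  - {name: ca_translocate_in, from: out_ca,  to: in_ca,   rate: 5.0,     z: 2.0}
  - {name: ca_translocate_out, from: in_ca,  to: out_ca,  rate: 5.0,     z: -2.0}
  - {name: ca_release_in,     from: in_ca,   to: in_apo,  rate: 150.0,   ions: {ca: 1},
     particle: {action: release, species: ca, dest: pool}}
  - {name: ca_rebind_in,      from: in_apo,  to: in_ca,   rate: 100.0,   ligand: ca_i, ions: {ca: -1},
     particle: {action: bind, species: ca, source: pool}}
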