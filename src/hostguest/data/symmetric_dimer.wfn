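# Synthetic model wavefunction (hostguest keyed text format).
# Not a DFT output: constructed for testing the density-topology machinery.
# Format: 'centers n' then n lines 'Z x y z' (bohr);
#         'basis n' then n lines 'center_idx alpha coeff' (s-type primitives);
#         'orbitals n_mo n_basis' then per-MO 'occupation c_1 ... c_nbasis'.
# Two identical 1s-like sites 2 bohr apart; one localized orbital each.
centers 2
1 0.0 0.0 0.0
1 0.0 0.0 2.0
basis 2
0 1.0 0.7127054703549902
1 1.0 0.7127054703549902
orbitals 2 2
1.0 1.0 0.0
1.0 0.0 1.0
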