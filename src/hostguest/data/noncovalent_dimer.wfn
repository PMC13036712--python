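# Synthetic model wavefunction (hostguest keyed text format).
# Not a DFT output: constructed for testing the density-topology machinery.
# Format: 'centers n' then n lines 'Z x y z' (bohr);
#         'basis n' then n lines 'center_idx alpha coeff' (s-type primitives);
#         'orbitals n_mo n_basis' then per-MO 'occupation c_1 ... c_nbasis'.
# Two closed-shell sites 3 bohr apart; the intermolecular (3,-1) CP
# satisfies lap(rho)>0, H>0, -G/V>1 with rho ~ 0.012 e a0^-3.
centers 2
10 0.0 0.0 0.0
10 0.0 0.0 3.0
basis 2
0 1.2 0.817139165538358
1 1.2 0.817139165538358
orbitals 2 2
2.0 1.0 0.0
2.0 0.0 1.0
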