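# Sextic Landau-Devonshire coefficients for single-crystal BaTiO3 (BTO).
# NOTE: literature-sourced values (the classic Bell-Cross single-crystal
# parameterization), not fitted in this package.
# alpha(T) = slope * (T - t_ref) + offset, T in kelvin.
# Units: alpha1 in C^-2 m^2 N; alpha11, alpha12 in C^-4 m^6 N;
#        alpha111, alpha112, alpha123 in C^-6 m^10 N.
material_id = "bto"
source = "Bell-Cross literature parameterization for single-crystal BaTiO3 (non-composition-specific)"

[alpha1]
slope = 3.34e5
t_ref = 381.0
offset = 0.0

[alpha11]
slope = 4.69e6
t_ref = 393.0
offset = -2.02e8

[alpha12]
slope = 0.0
t_ref = 0.0
offset = 3.23e8

[alpha111]
slope = -5.52e7
t_ref = 393.0
offset = 2.76e9

[alpha112]
slope = 0.0
t_ref = 0.0
offset = 4.47e9

[alpha123]
slope = 0.0
t_ref = 0.0
offset = 4.91e9
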