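# Sextic Landau-Devonshire coefficients for Ba(Ti0.85Zr0.15)O3 (BTZ).
# Each coefficient follows alpha(T) = slope * (T - t_ref) + offset with T in kelvin.
# Units: alpha1 in C^-2 m^2 N; alpha11, alpha12 in C^-4 m^6 N;
#        alpha111, alpha112, alpha123 in C^-6 m^10 N.
material_id = "btz"
source = "composition-specific parameterization fitted to phase-transition temperatures and dielectric data"

[alpha1]
slope = 3.11e5
t_ref = 293.0
offset = 0.0

[alpha11]
slope = 4.43e6
t_ref = 333.0
offset = 0.0

[alpha12]
slope = 0.0
t_ref = 0.0
offset = -2.15e8

[alpha111]
slope = -5.16e7
t_ref = 333.0
offset = 2.61e9

[alpha112]
slope = 0.0
t_ref = 0.0
offset = 2.95e9

[alpha123]
slope = 0.0
t_ref = 0.0
offset = 5.65e9
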