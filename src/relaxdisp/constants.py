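"""Physical constants pinned for bit-reproducible output.

CODATA 2018 exact values where they exist. NMR-specific values (bond
length, CSA) are the conventional literature choices used by the
synthetic generator and the rigid-rotor inversion alike.
"""

# Gas constant, J/(mol K)
R_GAS = 8.314462618

# Boltzmann constant, J/K (exact)
K_B = 1.380649e-23

# Planck constant, J s (exact)
PLANCK_H = 6.62607015e-34

# Vacuum permeability, T^2 m^3 / J
MU_0 = 1.25663706212e-6

# Gyromagnetic ratios, rad s^-1 T^-1.  gamma_N is negative for 15N.
GAMMA_H = 2.6752218744e8
GAMMA_N = -2.7126e7

# |gamma_N / gamma_H|: nitrogen Larmor frequency as a fraction of the
# proton frequency.  Used for ppm -> rad/s conversion of 15N shifts.
NU_N_OVER_NU_H = 0.10136767

# N-H bond length, m
R_NH = 1.02e-10

# 15N CSA, ppm
DELTA_SIGMA_N = -160.0
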