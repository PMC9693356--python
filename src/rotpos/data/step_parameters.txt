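# Dimer-step elastic parameters used by the bending/shearing energy model.
# Columns: dimer, equilibrium twist tilt roll (deg) shift slide rise (Angstrom),
# then the 21 upper-triangle entries of the 6x6 stiffness matrix (kT per squared unit),
# row-major over (twist, tilt, roll, shift, slide, rise).
# Sign convention: positive roll bends toward the histone-proximal minor groove;
# A/T-rich steps carry positive equilibrium roll, G/C-rich steps negative roll.
AA 35.6 -1 2.2 0.05 -0.15 3.32 0.048 0 0 0 0 0 0.07 0 0 0 0 0.042 0 0 0 1.8 0 0 2.5 0 8
AC 34 -0.5 0.5 0.1 -0.5 3.36 0.042 0 0 0 0 0 0.06 0 0 0 0 0.033 0 0 0 1.6 0 0 2 0 7.5
AG 34.5 -0.8 0.8 0.05 -0.25 3.34 0.04 0 0 0 0 0 0.058 0 0 0 0 0.032 0 0 0 1.6 0 0 2 0 7.5
AT 34.6 0 1.2 0 -0.6 3.31 0.045 0 0 0 0 0 0.068 0 0 0 0 0.038 0 0 0 1.7 0 0 2.3 0 8
CA 35.8 0.3 0.4 -0.1 0.3 3.35 0.035 0 0 0 0 0 0.05 0 0 0 0 0.024 0 0 0 1.4 0 0 1.6 0 7
CC 33.7 -0.3 -2.4 0.05 -0.1 3.39 0.042 0 0 0 0 0 0.06 0 0 0 0 0.036 0 0 0 1.7 0 0 2.1 0 7.8
CG 35.4 0 -3 0 0.4 3.38 0.034 0 0 0 0 0 0.05 0 0 0 0 0.022 0 0 0 1.4 0 0 1.6 0 7.2
CT 34.5 0.8 0.8 -0.05 -0.25 3.34 0.04 0 0 0 0 0 0.058 0 0 0 0 0.032 0 0 0 1.6 0 0 2 0 7.5
GA 36.3 -0.6 0.6 -0.05 0.1 3.37 0.041 0 0 0 0 0 0.06 0 0 0 0 0.034 0 0 0 1.6 0 0 2.1 0 7.5
GC 34.4 0 -2 0 0.25 3.4 0.043 0 0 0 0 0 0.062 0 0 0 0 0.035 0 0 0 1.7 0 0 2.2 0 7.8
GG 33.7 0.3 -2.4 -0.05 -0.1 3.39 0.042 0 0 0 0 0 0.06 0 0 0 0 0.036 0 0 0 1.7 0 0 2.1 0 7.8
GT 34 0.5 0.5 -0.1 -0.5 3.36 0.042 0 0 0 0 0 0.06 0 0 0 0 0.033 0 0 0 1.6 0 0 2 0 7.5
TA 36 0 2.6 0 0.05 3.33 0.032 0 0 0 0 0 0.048 0 0 0 0 0.02 0 0 0 1.3 0 0 1.5 0 7
TC 36.3 0.6 0.6 0.05 0.1 3.37 0.041 0 0 0 0 0 0.06 0 0 0 0 0.034 0 0 0 1.6 0 0 2.1 0 7.5
TG 35.8 -0.3 0.4 0.1 0.3 3.35 0.035 0 0 0 0 0 0.05 0 0 0 0 0.024 0 0 0 1.4 0 0 1.6 0 7
TT 35.6 1 2.2 -0.05 -0.15 3.32 0.048 0 0 0 0 0 0.07 0 0 0 0 0.042 0 0 0 1.8 0 0 2.5 0 8
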