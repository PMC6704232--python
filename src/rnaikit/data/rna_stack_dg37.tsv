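# RNA nearest-neighbor helix stacking free energies, dG37 in kcal/mol.
# Key XY/ZW: X,Y are consecutive bases on one strand written 5'->3';
# Z,W are the bases paired to X and Y on the opposite strand (written 3'->5'
# directly underneath, i.e. X pairs Z and Y pairs W).
# Watson-Crick values: Xia et al. (1998) dG37 set, expanded to all 16 keys
# by the 180-degree rotational symmetry XY/ZW == WZ/YX.
# GU wobble values: Turner-rules dG37 set; used only by the secondary-
# structure folding model, never for siRNA duplex ends (those are
# Watson-Crick by construction).
#
# Watson-Crick / Watson-Crick
AA/UU	-0.93
UU/AA	-0.93
AU/UA	-1.10
UA/AU	-1.33
CU/GA	-2.08
AG/UC	-2.08
CA/GU	-2.11
UG/AC	-2.11
GU/CA	-2.24
AC/UG	-2.24
GA/CU	-2.35
UC/AG	-2.35
CG/GC	-2.36
GG/CC	-3.26
CC/GG	-3.26
GC/CG	-3.42
# Stacks containing at least one GU wobble pair
AG/UU	-0.55
UU/GA	-0.55
AU/UG	-1.36
GU/UA	-1.36
CG/GU	-1.41
UG/GC	-1.41
CU/GG	-2.11
GG/UC	-2.11
GG/CU	-1.53
UC/GG	-1.53
GU/CG	-2.51
GC/UG	-2.51
UG/AU	-1.27
UA/GU	-1.27
UU/AG	-1.00
GA/UU	-1.00
GG/UU	-0.50
UU/GG	-0.50
GU/UG	1.29
UG/GU	0.30
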