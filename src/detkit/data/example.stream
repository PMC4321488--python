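CrystFEL stream format 2.3
Generated by detkit (synthetic example; not from a real experiment)
----- Begin chunk -----
Image filename: example_0001.h5
Event: //0
indexed_by = mosflm-nolatt-nocell
photon_energy_eV = 9537.1
wavelength = 1.3000 A
--- Begin crystal
Cell parameters 6.90000 16.90000 28.80000 nm, 90.00000 90.00000 90.00000 deg
astar = +0.1449275 +0.0000000 +0.0000000 nm^-1
bstar = +0.0000000 +0.0591716 +0.0000000 nm^-1
cstar = +0.0000000 +0.0000000 +0.0347222 nm^-1
lattice_type = orthorhombic
Reflections measured after indexing
   h    k    l          I   sigma(I)       peak background  fs/px  ss/px panel
   1    2    3     1234.50      35.10     1300.0      5.0  100.0  200.0 q0a0
   2    0    1      845.20      29.00      900.0      4.0  110.0  210.0 q0a0
   0    4    2      512.75      22.60      540.0      3.5  120.0  220.0 q0a1
  -1    3    5      101.30      11.90      120.0      2.0  130.0  230.0 q0a1
End of reflections
--- End crystal
----- End chunk -----
----- Begin chunk -----
Image filename: example_0002.h5
Event: //0
indexed_by = mosflm-nolatt-nocell
photon_energy_eV = 9537.1
wavelength = 1.3000 A
--- Begin crystal
Cell parameters 6.90000 14.60000 17.00000 nm, 90.00000 90.00000 90.00000 deg
astar = +0.1024448 +0.1024448 +0.0000000 nm^-1
bstar = -0.0484330 +0.0484330 +0.0000000 nm^-1
cstar = +0.0000000 +0.0000000 +0.0588235 nm^-1
lattice_type = orthorhombic
Reflections measured after indexing
   h    k    l          I   sigma(I)       peak background  fs/px  ss/px panel
   3    1    0      678.90      31.20      700.0      6.0  140.0  240.0 q1a0
   0    2    4      234.10      18.40      250.0      3.0  150.0  250.0 q1a0
   1    1    1       98.60      10.70      110.0      1.5  160.0  260.0 q1a1
End of reflections
--- End crystal
----- End chunk -----
----- Begin chunk -----
Image filename: example_0003.h5
Event: //0
indexed_by = none
photon_energy_eV = 9537.1
----- End chunk -----
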