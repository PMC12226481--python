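# Idealized 10-20/10-10 scalp electrode coordinates (spherical, degrees).
# theta: polar angle from the vertex (Cz = 0); phi: azimuth measured clockwise
# from the anterior midline. Constructed from the canonical topographic grid
# layout via the inverse azimuthal-equidistant map (18 deg per 10% arc step),
# so projecting back yields a regular grid with left/right mirror symmetry.
channel,theta,phi
Fp1,74.2159,-14.0362
Fpz,72.0000,0.0000
Fp2,74.2159,14.0362
AF7,76.3675,-45.0000
AF3,56.9210,-18.4349
AFz,54.0000,0.0000
AF4,56.9210,18.4349
AF8,76.3675,45.0000
F7,80.4984,-63.4349
F5,64.8999,-56.3099
F3,50.9117,-45.0000
F1,40.2492,-26.5651
Fz,36.0000,0.0000
F2,40.2492,26.5651
F4,50.9117,45.0000
F6,64.8999,56.3099
F8,80.4984,63.4349
FT7,74.2159,-75.9638
FC5,56.9210,-71.5651
FC3,40.2492,-63.4349
FC1,25.4558,-45.0000
FCz,18.0000,0.0000
FC2,25.4558,45.0000
FC4,40.2492,63.4349
FC6,56.9210,71.5651
FT8,74.2159,75.9638
T7,72.0000,-90.0000
C5,54.0000,-90.0000
C3,36.0000,-90.0000
C1,18.0000,-90.0000
Cz,0.0000,0.0000
C2,18.0000,90.0000
C4,36.0000,90.0000
C6,54.0000,90.0000
T8,72.0000,90.0000
TP7,74.2159,-104.0362
CP5,56.9210,-108.4349
CP3,40.2492,-116.5651
CP1,25.4558,-135.0000
CPz,18.0000,180.0000
CP2,25.4558,135.0000
CP4,40.2492,116.5651
CP6,56.9210,108.4349
TP8,74.2159,104.0362
P7,80.4984,-116.5651
P5,64.8999,-123.6901
P3,50.9117,-135.0000
P1,40.2492,-153.4349
Pz,36.0000,180.0000
P2,40.2492,153.4349
P4,50.9117,135.0000
P6,64.8999,123.6901
P8,80.4984,116.5651
PO7,76.3675,-135.0000
PO3,56.9210,-161.5651
POz,54.0000,180.0000
PO4,56.9210,161.5651
PO8,76.3675,135.0000
O1,74.2159,-165.9638
Oz,72.0000,180.0000
O2,74.2159,165.9638
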