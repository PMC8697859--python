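symbol,Z,group,period,mass,radius,IP,EA,chi,mass_number
H,1,1,1,1.008,0.25,13.598,0.754,2.20,
D,1,1,1,2.014,0.25,13.602,0.754,2.20,2
T,1,1,1,3.016,0.25,13.603,0.754,2.20,3
He,2,18,1,4.003,0.31,24.587,0.0,4.16,
Li,3,1,2,6.94,1.45,5.392,0.618,0.98,
Be,4,2,2,9.012,1.05,9.323,0.0,1.57,
B,5,13,2,10.81,0.85,8.298,0.280,2.04,
C,6,14,2,12.011,0.70,11.260,1.262,2.55,
N,7,15,2,14.007,0.65,14.534,0.0,3.04,
O,8,16,2,15.999,0.60,13.618,1.461,3.44,
F,9,17,2,18.998,0.50,17.423,3.401,3.98,
Ne,10,18,2,20.180,0.38,21.565,0.0,4.79,
Na,11,1,3,22.990,1.80,5.139,0.548,0.93,
Mg,12,2,3,24.305,1.50,7.646,0.0,1.31,
Al,13,13,3,26.982,1.25,5.986,0.433,1.61,
Si,14,14,3,28.085,1.10,8.152,1.390,1.90,
P,15,15,3,30.974,1.00,10.487,0.746,2.19,
S,16,16,3,32.06,1.00,10.360,2.077,2.58,
Cl,17,17,3,35.45,1.00,12.968,3.613,3.16,
Ar,18,18,3,39.948,0.71,15.760,0.0,3.24,
K,19,1,4,39.098,2.20,4.341,0.501,0.82,
Ca,20,2,4,40.078,1.80,6.113,0.025,1.00,
Sc,21,3,4,44.956,1.60,6.561,0.188,1.36,
Ti,22,4,4,47.867,1.40,6.828,0.079,1.54,
V,23,5,4,50.942,1.35,6.746,0.525,1.63,
Cr,24,6,4,51.996,1.40,6.767,0.666,1.66,
Mn,25,7,4,54.938,1.40,7.434,0.0,1.55,
Fe,26,8,4,55.845,1.40,7.902,0.151,1.83,
Co,27,9,4,58.933,1.35,7.881,0.662,1.88,
Ni,28,10,4,58.693,1.35,7.640,1.156,1.91,
Cu,29,11,4,63.546,1.35,7.726,1.236,1.90,
Zn,30,12,4,65.38,1.35,9.394,0.0,1.65,
Ga,31,13,4,69.723,1.30,5.999,0.430,1.81,
Ge,32,14,4,72.630,1.25,7.899,1.233,2.01,
As,33,15,4,74.922,1.15,9.789,0.804,2.18,
Se,34,16,4,78.971,1.15,9.752,2.021,2.55,
Br,35,17,4,79.904,1.15,11.814,3.364,2.96,
Kr,36,18,4,83.798,0.88,14.000,0.0,3.00,
Rb,37,1,5,85.468,2.35,4.177,0.486,0.82,
Sr,38,2,5,87.62,2.00,5.695,0.048,0.95,
Y,39,3,5,88.906,1.80,6.217,0.307,1.22,
Zr,40,4,5,91.224,1.55,6.634,0.426,1.33,
Nb,41,5,5,92.906,1.45,6.759,0.893,1.60,
Mo,42,6,5,95.95,1.45,7.092,0.748,2.16,
Tc,43,7,5,98.0,1.35,7.280,0.550,1.90,
Ru,44,8,5,101.07,1.30,7.360,1.050,2.20,
Rh,45,9,5,102.906,1.35,7.459,1.137,2.28,
Pd,46,10,5,106.42,1.40,8.337,0.562,2.20,
Ag,47,11,5,107.868,1.60,7.576,1.302,1.93,
Cd,48,12,5,112.414,1.55,8.994,0.0,1.69,
In,49,13,5,114.818,1.55,5.786,0.300,1.78,
Sn,50,14,5,118.710,1.45,7.344,1.112,1.96,
Sb,51,15,5,121.760,1.45,8.608,1.046,2.05,
Te,52,16,5,127.60,1.40,9.010,1.971,2.10,
I,53,17,5,126.904,1.40,10.451,3.059,2.66,
Xe,54,18,5,131.293,1.08,12.130,0.0,2.60,
Cs,55,1,6,132.905,2.60,3.894,0.472,0.79,
Ba,56,2,6,137.327,2.15,5.212,0.145,0.89,
La,57,3,6,138.905,1.95,5.577,0.470,1.10,
Ce,58,3,6,140.116,1.85,5.539,0.650,1.12,
Pr,59,3,6,140.908,1.85,5.473,0.962,1.13,
Nd,60,3,6,144.242,1.85,5.525,0.100,1.14,
Pm,61,3,6,145.0,1.85,5.582,0.120,1.13,
Sm,62,3,6,150.36,1.85,5.644,0.160,1.17,
Eu,63,3,6,151.964,1.85,5.670,0.120,1.20,
Gd,64,3,6,157.25,1.80,6.150,0.140,1.20,
Tb,65,3,6,158.925,1.75,5.864,0.110,1.10,
Dy,66,3,6,162.500,1.75,5.939,0.350,1.22,
Ho,67,3,6,164.930,1.75,6.021,0.340,1.23,
Er,68,3,6,167.259,1.75,6.108,0.310,1.24,
Tm,69,3,6,168.934,1.75,6.184,1.030,1.25,
Yb,70,3,6,173.045,1.75,6.254,0.0,1.10,
Lu,71,3,6,174.967,1.75,5.426,0.340,1.27,
Hf,72,4,6,178.49,1.55,6.825,0.017,1.30,
Ta,73,5,6,180.948,1.45,7.550,0.322,1.50,
W,74,6,6,183.84,1.35,7.864,0.815,2.36,
Re,75,7,6,186.207,1.35,7.834,0.150,1.90,
Os,76,8,6,190.23,1.30,8.438,1.100,2.20,
Ir,77,9,6,192.217,1.35,8.967,1.564,2.20,
Pt,78,10,6,195.084,1.35,8.959,2.128,2.28,
Au,79,11,6,196.967,1.35,9.226,2.309,2.54,
Hg,80,12,6,200.592,1.50,10.437,0.0,2.00,
Tl,81,13,6,204.38,1.90,6.108,0.377,1.62,
Pb,82,14,6,207.2,1.80,7.417,0.356,2.33,
Bi,83,15,6,208.980,1.60,7.286,0.942,2.02,
Po,84,16,6,209.0,1.90,8.414,1.900,2.00,
At,85,17,6,210.0,1.27,9.318,2.800,2.20,
Rn,86,18,6,222.0,1.20,10.749,0.0,2.20,
Fr,87,1,7,223.0,2.60,4.073,0.486,0.70,
Ra,88,2,7,226.0,2.15,5.278,0.100,0.90,
Ac,89,3,7,227.0,1.95,5.380,0.350,1.10,
Th,90,3,7,232.038,1.80,6.307,0.600,1.30,
Pa,91,3,7,231.036,1.80,5.890,0.550,1.50,
U,92,3,7,238.029,1.75,6.194,0.530,1.38,
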