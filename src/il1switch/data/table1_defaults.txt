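# Reference parameter set of the IL-1beta switch model.
# Units: time d, glucose mM, insulin pM, beta-cell mass mg, IL-1beta/IL-1Ra pg/ml.
# k1-k6 are reference values of the original steady-state calibration; re-derive
# them with `il1switch calibrate` when using this package's functional forms.
r0 = 48
dG = 1.44
h = 300.02
dI = 432
KG = 7.86
dA = 166.36
dL = 55.45
KA = 1300
KL = 1300
k1 = 9.47e5
k2 = 3.12e7
k3 = 2.65e4
k4 = 0.047
k5 = 3.745e3
k6 = 1.048e9
u = 5.8
r = 2
s = 2.77
v = 3.52
t_hill = 3
KF = 0.1575
ap = -0.048
bp = -0.46
cp = 0.62
aa = 0.047
ba = 0.57
ca = 2.36
lam = 2.33
tau = 0.00052
R0 = 9.643
m = 1.688
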