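# Fitted parameters of the revised phase-type stroke recovery model
# (13 free parameters; nu1, nu2, rho1 pinned at zero, mu4 = nu4 = 0
# structurally).  Rates are per year; ages in years.
gamma1: 6.63570
beta1: -0.03652
gamma2: -3.06931
beta2: 0.07153
theta0: -8.66118
theta1: 0.08801
mu1: 22.10156
mu2: 2.48820
mu3: 1.56162
nu3: 1.27849
rho2: 11.76860
rho3: 3.41989
rho4: 63.92514
zero_mask: [nu1, nu2, rho1]
days_per_year: 365.25
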