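# Single-delay blowflies model whose mortality and saturation coefficients
# both decay to zero: alpha(t) = gamma(t) = 1/(1+t).  Positive solutions
# exist globally but are unbounded — production outruns the vanishing
# mortality.  Simulated from t = -1 so the initial segment is visible.
label = "eq9"
t0 = 0.0
tau_max = 1.0
alpha = "1/(1+t)"
beta = ["1"]
gamma = ["1/(1+t)"]
tau = ["1"]
phi = "exp(s)"

[meta.alpha]
is_uniformly_positive = false
integral_diverges = true
declared_limsup = 0.0
declared_liminf = 0.0
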