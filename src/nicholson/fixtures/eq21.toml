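# Two-delay blowflies model with time-varying delays that occasionally
# vanish.  The per-capita mortality alpha(t) = 2/(2+t) is not uniformly
# positive, but its integral diverges and the production/mortality ratio
# (beta1+beta2)/alpha is constantly 1/2 < 1, so every positive solution
# converges to zero inside the generalized envelope
# |phi| * exp(-lambda* * 2*log((2+t)/2)) = |phi| * (2/(2+t))^(2 lambda*).
# Since int alpha / t -> 0, no classical rate M exp(-eta t) exists.
label = "eq21"
t0 = 0.0
tau_max = 1.0
alpha = "2/(2+t)"
beta = ["0.5/(2+t)", "0.5/(2+t)"]
gamma = ["1", "1"]
tau = ["0.5*(1+sin(t))", "0.5*(1+cos(t))"]
phi = "exp(s)"

[meta]
ratio_limsup = 0.5
ratio_is_constant = true

[meta.alpha]
is_uniformly_positive = false
integral_diverges = true
declared_limsup = 0.0
declared_liminf = 0.0
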