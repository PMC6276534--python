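"""Choosing the delay and dimension for phase-space reconstruction.

The delay tau comes from the first local minimum of the average mutual
information (AMI) between the signal and its lagged copy; for a sinusoid
this sits at the quarter period.  The embedding dimension m comes from
Cao's E1 criterion: E1(m) saturates near 1 once m is large enough to
unfold the attractor, and a one-dimensional map saturates almost
immediately.
"""

import numpy as np

from rqadetect import (ami_curve, cao_curves, gen_logistic, gen_sine,
                       select_delay, select_dim)

# period-64 sine with measurement noise: expect tau close to 64/4 = 16
sine = gen_sine(freq=1.0, rate=64.0, n=8192, noise_sd=0.2, rng=0)
curve = ami_curve(sine, max_lag=40, n_bins=16)
tau = select_delay(curve)
print(f"sine, period 64 samples: first AMI minimum at lag {tau} "
      "(quarter period)")

# chaotic logistic map: a 1-D attractor, so E1 saturates by m = 2
logistic = gen_logistic(r=4.0, x0=0.37, n=1000)
e1, e2 = cao_curves(logistic, tau=1, m_max=6)
m = select_dim(e1)
print(f"logistic map: E1 = {np.round(e1, 3)} -> embedding dimension m = {m}")
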