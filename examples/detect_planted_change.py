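"""Detect a planted change-point from privatized observations only.

Simulate a Gaussian stream that shifts mean 0 -> 1 at time 500, run the
LDP-CUSUM detector (alpha = 1) at a threshold calibrated for an average
run length of about 1000, and compare with the non-private exact CUSUM
on the same raw stream.
"""

import numpy as np

from ldpcusum import (
    ChangeModel,
    StreamSpec,
    generate_stream,
    run_exact_cusum,
    run_ldp_cusum,
)

model = ChangeModel.gaussian_mean_1d(0.0, 1.0)
tau = 500
stream = generate_stream(StreamSpec(model, n=2000, tau=tau, seed=42))

b_ldp = 3.72     # ARL ~ 1000 for the privatized detector at alpha = 1
b_exact = 6.91   # log(1000), the classical choice for the exact CUSUM

ldp = run_ldp_cusum(model, alpha=1.0, stream=stream, b=b_ldp,
                    rng=np.random.default_rng(7))
exact = run_exact_cusum(model, stream, b=b_exact)

print(f"change planted at tau = {tau}")
print(f"exact CUSUM alarm at t = {exact.stopping_time} "
      f"(delay {exact.stopping_time - tau})")
print(f"LDP-CUSUM  alarm at t = {ldp.stopping_time} "
      f"(delay {ldp.stopping_time - tau})")
print(
    "\nBoth detectors alarm shortly after the change; the privatized "
    "detector pays extra delay for the alpha = 1 privacy guarantee but "
    "never saw a raw observation."
)
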