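"""Closed-form Neyman-Pearson regions and their probabilities.

For each study change model, print the structured decision region
A = {x : f1(x) > f0(x)}, the region probabilities p0, p1 under the two
laws, and the total variation distance (which equals p1 - p0 because A
is the most-powerful region).
"""

import numpy as np

from ldpcusum import ChangeModel, np_region, region_probabilities, tv_distance

models = {
    "Gaussian mean shift N(0,1) -> N(1,1)": ChangeModel.gaussian_mean_1d(0, 1),
    "Laplace mean shift Lap(0,1) -> Lap(0.5,1)":
        ChangeModel.laplace_mean_1d(0, 0.5),
    "Gaussian variance shift N(0,1) -> N(0,4)":
        ChangeModel.gaussian_var_1d(1, 4),
    "5-d Gaussian mean shift 0 -> 0.5*1":
        ChangeModel.gaussian_mean_kd(np.zeros(5), 0.5 * np.ones(5)),
    "5-d spiked covariance, r=0.8, u=[1,1.5,2,2.5,3]":
        ChangeModel.gaussian_cov_spike_kd([1, 1.5, 2, 2.5, 3], 0.8),
}

for name, model in models.items():
    region = np_region(model)
    p0, p1 = region_probabilities(model, region)
    print(name)
    print(f"  {region.describe()}")
    print(f"  p0 = {p0:.4f}, p1 = {p1:.4f}, TV = p1 - p0 = "
          f"{tv_distance(model):.4f}")

print(
    "\np0 and p1 are the weights of the privatized Laplace mixture; the "
    "wider their gap, the more information the indicator retains."
)
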