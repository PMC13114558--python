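"""Delay-privacy tradeoff at matched false-alarm budget.

For the unit Gaussian mean shift, calibrate each detector to an average
run length of 200 (kept small so the example runs in seconds) and
estimate the worst-case detection delay across a grid of privacy
levels.  Larger runs simply raise target_arl / replications.
"""

from ldpcusum import (
    ChangeModel,
    ExactCusumDetector,
    LdpCusumDetector,
    MCConfig,
    TruncationLaplaceMechanism,
    delay_privacy_curve,
)
from ldpcusum.detection import TruncationCusumDetector
from ldpcusum.montecarlo import curves_to_frame

model = ChangeModel.gaussian_mean_1d(0.0, 1.0)
cfg = MCConfig(replications=200, seed=1, target_arl=200.0)

factories = [
    ("exact", lambda a: ExactCusumDetector(model)),
    ("ldp", lambda a: LdpCusumDetector(model, a)),
    ("truncation K=1", lambda a: TruncationCusumDetector(
        model, TruncationLaplaceMechanism(a, K=1.0))),
]

curves = delay_privacy_curve(model, factories, [0.5, 1.0, 1.5, 2.0], cfg)
df = curves_to_frame(curves)
print(df[["detector", "axis_value", "delay", "delay_se", "arl"]]
      .rename(columns={"axis_value": "alpha"})
      .to_string(index=False, float_format=lambda v: f"{v:.2f}"))

print(
    "\nAt every privacy level the ordering is exact <= LDP-CUSUM <= "
    "truncation baseline, and delays fall as alpha grows (weaker privacy)."
)
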