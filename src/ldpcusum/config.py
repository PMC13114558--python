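"""Experiment configuration: a single YAML file describing the change
model, the privatization mechanism, the detectors to run and the Monte
Carlo settings.

Parsing is strict (unknown keys are rejected) and round-trippable:
``parse(serialize(parse(text)))`` is the identity once defaults have
been filled in on the first parse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .models import ChangeModel

__all__ = ["ExperimentConfig", "load_config", "build_model"]

_MODEL_PARAMS = {
    "gaussian_mean_1d": {"mu0", "mu1", "sigma"},
    "laplace_mean_1d": {"loc0", "loc1", "scale"},
    "gaussian_var_1d": {"var0", "var1", "mean"},
    "gaussian_mean_kd": {"mean0", "mean1", "sigma"},
    "gaussian_cov_spike_kd": {"u", "r"},
    "gaussian_full_kd": {"mean0", "cov0", "mean1", "cov1"},
}

_DETECTOR_NAMES = {"exact", "ldp", "truncation"}
_MECHANISM_KINDS = {"indicator", "truncation", "none"}


def _reject_unknown(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")


@dataclass(frozen=True)
class ExperimentConfig:
    model_family: str
    model_params: dict
    mechanism_kind: str = "indicator"
    alpha: float = 1.0
    K: Optional[float] = None
    detectors: tuple = ("ldp",)
    target_arl: float = 1000.0
    replications: int = 1000
    seed: int = 0
    cap: Optional[int] = None
    threshold: Optional[float] = None
    alpha_grid: tuple = ()
    b_grid: tuple = ()
    output_dir: str = "results"

    # ---- validation / construction ----

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        _reject_unknown(
            raw,
            {
                "model", "mechanism", "detectors", "target_arl", "mc",
                "grids", "threshold", "output_dir",
            },
            "config",
        )
        model = dict(raw.get("model") or {})
        _reject_unknown(model, {"family", "params"}, "model")
        family = model.get("family")
        if family not in _MODEL_PARAMS:
            raise ValueError(f"unknown model family {family!r}")
        params = dict(model.get("params") or {})
        _reject_unknown(params, _MODEL_PARAMS[family], f"model.params ({family})")

        mech = dict(raw.get("mechanism") or {})
        _reject_unknown(mech, {"kind", "alpha", "K"}, "mechanism")
        kind = mech.get("kind", "indicator")
        if kind not in _MECHANISM_KINDS:
            raise ValueError(f"unknown mechanism kind {kind!r}")
        alpha = float(mech.get("alpha", 1.0))
        K = mech.get("K")
        if kind == "truncation" and K is None:
            raise ValueError("truncation mechanism requires a level K")

        detectors = tuple(raw.get("detectors") or ("ldp",))
        bad = set(detectors) - _DETECTOR_NAMES
        if bad:
            raise ValueError(f"unknown detector(s): {sorted(bad)}")

        mc = dict(raw.get("mc") or {})
        _reject_unknown(mc, {"replications", "seed", "cap"}, "mc")
        grids = dict(raw.get("grids") or {})
        _reject_unknown(grids, {"alpha", "b"}, "grids")

        return cls(
            model_family=family,
            model_params=params,
            mechanism_kind=kind,
            alpha=alpha,
            K=None if K is None else float(K),
            detectors=detectors,
            target_arl=float(raw.get("target_arl", 1000.0)),
            replications=int(mc.get("replications", 1000)),
            seed=int(mc.get("seed", 0)),
            cap=None if mc.get("cap") is None else int(mc["cap"]),
            threshold=(
                None if raw.get("threshold") is None else float(raw["threshold"])
            ),
            alpha_grid=tuple(float(a) for a in (grids.get("alpha") or ())),
            b_grid=tuple(float(b) for b in (grids.get("b") or ())),
            output_dir=str(raw.get("output_dir", "results")),
        )

    def to_dict(self) -> dict:
        mech = {"kind": self.mechanism_kind, "alpha": self.alpha}
        if self.K is not None:
            mech["K"] = self.K
        return {
            "model": {"family": self.model_family, "params": dict(self.model_params)},
            "mechanism": mech,
            "detectors": list(self.detectors),
            "target_arl": self.target_arl,
            "mc": {
                "replications": self.replications,
                "seed": self.seed,
                "cap": self.cap,
            },
            "grids": {"alpha": list(self.alpha_grid), "b": list(self.b_grid)},
            "threshold": self.threshold,
            "output_dir": self.output_dir,
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    # ---- builders ----

    def build_model(self) -> ChangeModel:
        return build_model(self.model_family, self.model_params)


def build_model(family: str, params: dict) -> ChangeModel:
    p = params
    if family == "gaussian_mean_1d":
        return ChangeModel.gaussian_mean_1d(
            p["mu0"], p["mu1"], p.get("sigma", 1.0)
        )
    if family == "laplace_mean_1d":
        return ChangeModel.laplace_mean_1d(
            p["loc0"], p["loc1"], p.get("scale", 1.0)
        )
    if family == "gaussian_var_1d":
        return ChangeModel.gaussian_var_1d(
            p["var0"], p["var1"], p.get("mean", 0.0)
        )
    if family == "gaussian_mean_kd":
        return ChangeModel.gaussian_mean_kd(
            p["mean0"], p["mean1"], p.get("sigma", 1.0)
        )
    if family == "gaussian_cov_spike_kd":
        return ChangeModel.gaussian_cov_spike_kd(p["u"], p["r"])
    if family == "gaussian_full_kd":
        return ChangeModel.gaussian_full_kd(
            np.asarray(p["mean0"]), np.asarray(p["cov0"]),
            np.asarray(p["mean1"]), np.asarray(p["cov1"]),
        )
    raise ValueError(f"unknown model family {family!r}")


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    return ExperimentConfig.from_dict(raw)
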