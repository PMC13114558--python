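"""Change models, likelihood ratios and Neyman-Pearson regions.

A change model is a pair of fully specified densities (f0, f1) on R^k:
the stream follows f0 up to an unknown change-point and f1 afterwards.
Everything downstream of this module -- the indicator privatization
mechanism, the privatized CUSUM detector and the information bounds --
is driven by three primitives defined here:

* the log-likelihood ratio ``log f1(x) - log f0(x)``,
* the Neyman-Pearson region ``A = {x : f1(x) > f0(x)}`` in closed form,
* the region probabilities ``p_i = P_{f_i}(X in A)``.

The named parametric families cover the standard mean-shift and
variance-shift scenarios (univariate Gaussian and Laplace location
shifts, a Gaussian variance inflation, a multivariate Gaussian mean
shift with identity covariance, and a rank-one spiked-covariance
shift).  Fitted general Gaussians (full mean/covariance) and arbitrary
user-supplied densities are also supported; for those the region is
the generic sign-of-LLR set and probabilities fall back to Monte
Carlo integration.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import integrate, stats

__all__ = [
    "ChangeModel",
    "Region",
    "StreamSpec",
    "log_likelihood_ratio",
    "np_region",
    "region_probabilities",
    "tv_distance",
    "kl_divergence_raw",
    "generate_stream",
]

_NAMED_FAMILIES = (
    "gaussian_mean_1d",
    "laplace_mean_1d",
    "gaussian_var_1d",
    "gaussian_mean_kd",
    "gaussian_cov_spike_kd",
    "gaussian_full_kd",
    "custom",
)


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Region:
    """A structured decision region in R^k.

    Forms
    -----
    half_line_upper
        ``{x : x > c}`` (k = 1), parameter ``threshold``.
    two_sided_outer
        ``{x : |x - center| > c}`` (k = 1), parameters ``threshold`` and
        ``center``.
    half_space
        ``{x : v^T x > c}``, parameters ``normal`` and ``offset``.
    quadratic_projection
        ``{x : (u^T x)^2 > q}``, parameters ``direction`` and
        ``sq_threshold``.
    generic
        membership given by a user predicate (vectorized over rows).

    Membership uses strict inequality, so the measure-zero boundary is
    assigned to the complement.
    """

    form: str
    threshold: Optional[float] = None
    center: float = 0.0
    normal: Optional[np.ndarray] = None
    offset: Optional[float] = None
    direction: Optional[np.ndarray] = None
    sq_threshold: Optional[float] = None
    predicate: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def contains(self, x) -> np.ndarray:
        """Vectorized 0/1 membership; accepts a point or an array of points."""
        x = np.asarray(x, dtype=float)
        if self.form == "half_line_upper":
            return x > self.threshold
        if self.form == "two_sided_outer":
            return np.abs(x - self.center) > self.threshold
        if self.form == "half_space":
            v = np.asarray(self.normal, dtype=float).ravel()
            if v.size == 1 and x.ndim <= 1:
                return x * v[0] > self.offset
            return x @ v > self.offset
        if self.form == "quadratic_projection":
            return (x @ self.direction) ** 2 > self.sq_threshold
        if self.form == "generic":
            return np.asarray(self.predicate(x), dtype=bool)
        raise ValueError(f"unknown region form {self.form!r}")

    def describe(self) -> str:
        if self.form == "half_line_upper":
            return f"half_line_upper: {{x : x > {self.threshold:.6g}}}"
        if self.form == "two_sided_outer":
            return (
                f"two_sided_outer: {{x : |x - {self.center:.6g}| > "
                f"{self.threshold:.6g}}}"
            )
        if self.form == "half_space":
            v = np.array2string(np.asarray(self.normal), precision=6)
            return f"half_space: {{x : v^T x > {self.offset:.6g}}}, v = {v}"
        if self.form == "quadratic_projection":
            u = np.array2string(np.asarray(self.direction), precision=6)
            return (
                f"quadratic_projection: {{x : (u^T x)^2 > "
                f"{self.sq_threshold:.6g}}}, u = {u}"
            )
        return "generic: {x : f1(x) > f0(x)} (predicate)"


# ---------------------------------------------------------------------------
# Change models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChangeModel:
    """Pre/post-change distribution pair from a named parametric family.

    Use the classmethod constructors rather than filling fields by hand;
    they validate the family-specific parameter records.
    """

    family: str
    k: int
    params_f0: dict = field(default_factory=dict)
    params_f1: dict = field(default_factory=dict)

    # ---- constructors ----

    @classmethod
    def gaussian_mean_1d(cls, mu0: float, mu1: float, sigma: float = 1.0):
        """N(mu0, sigma^2) -> N(mu1, sigma^2), shared known variance."""
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        if mu0 == mu1:
            raise ValueError("f0 and f1 must differ (mu0 != mu1)")
        return cls(
            "gaussian_mean_1d",
            1,
            {"mean": float(mu0), "sigma": float(sigma)},
            {"mean": float(mu1), "sigma": float(sigma)},
        )

    @classmethod
    def laplace_mean_1d(cls, loc0: float, loc1: float, scale: float = 1.0):
        """Laplace(loc0, scale) -> Laplace(loc1, scale), shared scale."""
        if scale <= 0:
            raise ValueError("scale must be positive")
        if loc0 == loc1:
            raise ValueError("f0 and f1 must differ (loc0 != loc1)")
        return cls(
            "laplace_mean_1d",
            1,
            {"loc": float(loc0), "scale": float(scale)},
            {"loc": float(loc1), "scale": float(scale)},
        )

    @classmethod
    def gaussian_var_1d(cls, var0: float, var1: float, mean: float = 0.0):
        """N(mean, var0) -> N(mean, var1) with var1 > var0 (variance inflation)."""
        if var0 <= 0 or var1 <= 0:
            raise ValueError("variances must be positive")
        if var1 <= var0:
            raise ValueError("variance inflation requires var1 > var0")
        return cls(
            "gaussian_var_1d",
            1,
            {"mean": float(mean), "var": float(var0)},
            {"mean": float(mean), "var": float(var1)},
        )

    @classmethod
    def gaussian_mean_kd(cls, mean0, mean1, sigma: float = 1.0):
        """N(mean0, sigma^2 I_k) -> N(mean1, sigma^2 I_k)."""
        mean0 = np.atleast_1d(np.asarray(mean0, dtype=float))
        mean1 = np.atleast_1d(np.asarray(mean1, dtype=float))
        if mean0.shape != mean1.shape or mean0.ndim != 1:
            raise ValueError("mean vectors must be 1-d and of equal length")
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        if np.array_equal(mean0, mean1):
            raise ValueError("f0 and f1 must differ")
        return cls(
            "gaussian_mean_kd",
            mean0.size,
            {"mean": mean0, "sigma": float(sigma)},
            {"mean": mean1, "sigma": float(sigma)},
        )

    @classmethod
    def gaussian_cov_spike_kd(cls, u, r: float):
        """N(0, I_k) -> N(0, I_k + r u u^T), a rank-one spiked covariance."""
        u = np.atleast_1d(np.asarray(u, dtype=float))
        if u.ndim != 1 or not np.any(u != 0):
            raise ValueError("spike direction u must have a nonzero entry")
        if r <= 0:
            raise ValueError("spike magnitude r must be positive")
        return cls(
            "gaussian_cov_spike_kd",
            u.size,
            {},
            {"u": u, "r": float(r)},
        )

    @classmethod
    def gaussian_full_kd(cls, mean0, cov0, mean1, cov1):
        """General multivariate Gaussians with full covariances (fitted models)."""
        mean0 = np.atleast_1d(np.asarray(mean0, dtype=float))
        mean1 = np.atleast_1d(np.asarray(mean1, dtype=float))
        cov0 = np.atleast_2d(np.asarray(cov0, dtype=float))
        cov1 = np.atleast_2d(np.asarray(cov1, dtype=float))
        k = mean0.size
        if mean1.size != k or cov0.shape != (k, k) or cov1.shape != (k, k):
            raise ValueError("inconsistent dimensions")
        if np.allclose(mean0, mean1) and np.allclose(cov0, cov1):
            raise ValueError("f0 and f1 must differ")
        return cls(
            "gaussian_full_kd",
            k,
            {"mean": mean0, "cov": cov0},
            {"mean": mean1, "cov": cov1},
        )

    @classmethod
    def custom(
        cls,
        k: int,
        logpdf0: Callable,
        logpdf1: Callable,
        sampler0: Optional[Callable] = None,
        sampler1: Optional[Callable] = None,
        region_predicate: Optional[Callable] = None,
    ):
        """User-supplied log-densities, optional samplers ``f(n, rng)`` and
        optional region predicate (defaults to the sign-of-LLR set)."""
        return cls(
            "custom",
            int(k),
            {"logpdf": logpdf0, "sampler": sampler0},
            {"logpdf": logpdf1, "sampler": sampler1, "predicate": region_predicate},
        )

    # ---- densities, ratio, sampling ----

    def _frozen(self, which: int):
        p = self.params_f1 if which else self.params_f0
        if self.family == "gaussian_mean_1d":
            return stats.norm(p["mean"], p["sigma"])
        if self.family == "laplace_mean_1d":
            return stats.laplace(p["loc"], p["scale"])
        if self.family == "gaussian_var_1d":
            return stats.norm(p["mean"], math.sqrt(p["var"]))
        raise ValueError("no univariate frozen law for this family")

    def llr(self, x) -> np.ndarray:
        """Vectorized log f1(x) - log f0(x).

        1-d families accept scalars or arrays; k-d families accept a
        single k-vector or an (n, k) array of rows.
        """
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite observation")
        fam = self.family
        if fam == "gaussian_mean_1d":
            m0, m1 = self.params_f0["mean"], self.params_f1["mean"]
            s2 = self.params_f0["sigma"] ** 2
            return ((m1 - m0) * x - 0.5 * (m1**2 - m0**2)) / s2
        if fam == "laplace_mean_1d":
            l0, l1 = self.params_f0["loc"], self.params_f1["loc"]
            b = self.params_f0["scale"]
            return (np.abs(x - l0) - np.abs(x - l1)) / b
        if fam == "gaussian_var_1d":
            mu = self.params_f0["mean"]
            v0, v1 = self.params_f0["var"], self.params_f1["var"]
            return 0.5 * math.log(v0 / v1) + (x - mu) ** 2 * (
                0.5 / v0 - 0.5 / v1
            )
        self._check_dim(x)
        if fam == "gaussian_mean_kd":
            m0, m1 = self.params_f0["mean"], self.params_f1["mean"]
            s2 = self.params_f0["sigma"] ** 2
            return (x @ (m1 - m0) - 0.5 * (m1 @ m1 - m0 @ m0)) / s2
        if fam == "gaussian_cov_spike_kd":
            u = self.params_f1["u"]
            r = self.params_f1["r"]
            d = 1.0 + r * float(u @ u)
            s = x @ u
            return -0.5 * math.log(d) + (r / (2.0 * d)) * s**2
        if fam == "gaussian_full_kd":
            mvn0 = stats.multivariate_normal(
                self.params_f0["mean"], self.params_f0["cov"]
            )
            mvn1 = stats.multivariate_normal(
                self.params_f1["mean"], self.params_f1["cov"]
            )
            return mvn1.logpdf(x) - mvn0.logpdf(x)
        if fam == "custom":
            return np.asarray(self.params_f1["logpdf"](x)) - np.asarray(
                self.params_f0["logpdf"](x)
            )
        raise ValueError(f"unknown family {fam!r}")

    def _check_dim(self, x: np.ndarray) -> None:
        if self.k == 1:
            return
        if x.ndim == 0 or x.shape[-1] != self.k:
            raise ValueError(
                f"dimension mismatch: expected k={self.k}"
            )

    def sample(self, which: int, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n i.i.d. observations from f0 (which=0) or f1 (which=1).

        Returns shape (n,) for univariate families, (n, k) otherwise.
        """
        fam = self.family
        p = self.params_f1 if which else self.params_f0
        if fam == "gaussian_mean_1d":
            return rng.normal(p["mean"], p["sigma"], size=n)
        if fam == "laplace_mean_1d":
            return rng.laplace(p["loc"], p["scale"], size=n)
        if fam == "gaussian_var_1d":
            return rng.normal(p["mean"], math.sqrt(p["var"]), size=n)
        if fam == "gaussian_mean_kd":
            return rng.normal(p["mean"], p["sigma"], size=(n, self.k))
        if fam == "gaussian_cov_spike_kd":
            g = rng.normal(size=(n, self.k))
            if which == 0:
                return g
            u = self.params_f1["u"]
            nu2 = float(u @ u)
            r = self.params_f1["r"]
            # I + r uu^T has square root I + c uu^T with
            # c = (sqrt(1 + r |u|^2) - 1) / |u|^2
            c = (math.sqrt(1.0 + r * nu2) - 1.0) / nu2
            return g + np.outer(g @ u, c * u)
        if fam == "gaussian_full_kd":
            L = np.linalg.cholesky(p["cov"])
            g = rng.normal(size=(n, self.k))
            return p["mean"] + g @ L.T
        if fam == "custom":
            sampler = p.get("sampler")
            if sampler is None:
                raise ValueError("custom family has no sampler")
            return np.asarray(sampler(n, rng))
        raise ValueError(f"unknown family {fam!r}")

    def sample_f0(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.sample(0, n, rng)

    def sample_f1(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.sample(1, n, rng)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def log_likelihood_ratio(model: ChangeModel, x) -> np.ndarray:
    """log f1(x) - log f0(x); the per-observation CUSUM increment on raw data."""
    return model.llr(x)


def np_region(model: ChangeModel) -> Region:
    """The Neyman-Pearson most-powerful region ``A = {x : f1(x) > f0(x)}``.

    For the named families the region is returned in structured closed
    form; for fitted/custom models it is the generic sign-of-LLR set.
    Half-space normals are scaled so the largest-magnitude component is
    ±1, which makes the canonical equal-shift case read ``1^T x > 0.25 k``.
    """
    fam = model.family
    if fam == "gaussian_mean_1d":
        m0, m1 = model.params_f0["mean"], model.params_f1["mean"]
        c = 0.5 * (m0 + m1)
        if m1 > m0:
            return Region("half_line_upper", threshold=c)
        return Region("half_space", normal=np.array([-1.0]), offset=-c)
    if fam == "laplace_mean_1d":
        l0, l1 = model.params_f0["loc"], model.params_f1["loc"]
        c = 0.5 * (l0 + l1)
        if l1 > l0:
            return Region("half_line_upper", threshold=c)
        return Region("half_space", normal=np.array([-1.0]), offset=-c)
    if fam == "gaussian_var_1d":
        mu = model.params_f0["mean"]
        v0, v1 = model.params_f0["var"], model.params_f1["var"]
        # solve log f1 = log f0:  x^2 (1/v0 - 1/v1) = log(v1/v0)
        c2 = math.log(v1 / v0) / (1.0 / v0 - 1.0 / v1)
        return Region("two_sided_outer", threshold=math.sqrt(c2), center=mu)
    if fam == "gaussian_mean_kd":
        m0, m1 = model.params_f0["mean"], model.params_f1["mean"]
        s2 = model.params_f0["sigma"] ** 2
        v = (m1 - m0) / s2
        c = 0.5 * (m1 @ m1 - m0 @ m0) / s2
        scale = np.max(np.abs(v))
        return Region("half_space", normal=v / scale, offset=float(c / scale))
    if fam == "gaussian_cov_spike_kd":
        u = model.params_f1["u"]
        r = model.params_f1["r"]
        d = 1.0 + r * float(u @ u)
        q = (d / r) * math.log(d)
        return Region("quadratic_projection", direction=u, sq_threshold=q)
    if fam == "gaussian_full_kd":
        return Region("generic", predicate=lambda x: model.llr(x) > 0)
    if fam == "custom":
        pred = model.params_f1.get("predicate")
        if pred is not None:
            return Region("generic", predicate=pred)
        return Region("generic", predicate=lambda x: model.llr(x) > 0)
    raise ValueError(f"unknown family {fam!r}")


def region_probabilities(
    model: ChangeModel,
    region: Optional[Region] = None,
    *,
    mc_draws: int = 200_000,
    mc_seed: int = 0,
) -> tuple[float, float]:
    """``(p0, p1)`` with ``p_i = P_{X ~ f_i}(X in A)``.

    Closed form for the named families: univariate Normal/Laplace CDFs,
    a 1-d Gaussian projection for half-spaces, and a chi-square(1) law
    for the spiked-covariance quadratic region.  Generic regions fall
    back to seeded Monte Carlo with ``mc_draws`` samples per law.
    """
    if region is None:
        region = np_region(model)
    fam = model.family
    form = region.form
    if form == "half_line_upper":
        return (
            float(model._frozen(0).sf(region.threshold)),
            float(model._frozen(1).sf(region.threshold)),
        )
    if form == "two_sided_outer":
        out = []
        for i in (0, 1):
            law = model._frozen(i)
            c, mu = region.threshold, region.center
            out.append(float(law.sf(mu + c) + law.cdf(mu - c)))
        return tuple(out)
    if form == "half_space" and fam in ("gaussian_mean_kd", "gaussian_mean_1d",
                                        "laplace_mean_1d"):
        v, c = np.asarray(region.normal), region.offset
        if fam == "gaussian_mean_kd":
            s = model.params_f0["sigma"]
            out = []
            for p in (model.params_f0, model.params_f1):
                mu = float(v @ p["mean"])
                sd = s * float(np.linalg.norm(v))
                out.append(float(stats.norm.sf((c - mu) / sd)))
            return tuple(out)
        # 1-d half-space {v1 x > c} with v1 = ±1 (descending mean shift)
        t = c / float(v[0])
        out = []
        for i in (0, 1):
            law = model._frozen(i)
            out.append(float(law.sf(t) if v[0] > 0 else law.cdf(t)))
        return tuple(out)
    if form == "quadratic_projection":
        u = np.asarray(region.direction)
        q = region.sq_threshold
        nu2 = float(u @ u)
        r = model.params_f1["r"]
        # s = u^T x: var nu2 under f0, nu2 (1 + r nu2) under f1;
        # s^2 / var ~ chi^2_1
        p0 = float(stats.chi2.sf(q / nu2, df=1))
        p1 = float(stats.chi2.sf(q / (nu2 * (1.0 + r * nu2)), df=1))
        return p0, p1
    # Monte Carlo fallback for generic regions / fitted models
    rng = np.random.default_rng(mc_seed)
    out = []
    for which in (0, 1):
        x = model.sample(which, mc_draws, rng)
        out.append(float(np.mean(region.contains(x))))
    return tuple(out)


def tv_distance(model: ChangeModel, **mc_kwargs) -> float:
    """Total variation distance ``TV(f0, f1) = 1/2 int |f1 - f0|``.

    Because A is the Neyman-Pearson region, TV equals ``p1 - p0``; Gaussian
    mean shifts use the equivalent closed form ``2 Phi(|dmu| / (2 sigma)) - 1``.
    """
    fam = model.family
    if fam == "gaussian_mean_1d":
        d = abs(model.params_f1["mean"] - model.params_f0["mean"])
        return float(2.0 * stats.norm.cdf(d / (2.0 * model.params_f0["sigma"])) - 1.0)
    if fam == "gaussian_mean_kd":
        d = float(np.linalg.norm(model.params_f1["mean"] - model.params_f0["mean"]))
        return float(2.0 * stats.norm.cdf(d / (2.0 * model.params_f0["sigma"])) - 1.0)
    p0, p1 = region_probabilities(model, **mc_kwargs)
    return float(p1 - p0)


def kl_divergence_raw(model: ChangeModel) -> float:
    """KL(f1 || f0) of the raw-data laws, in closed form for named families.

    This is the information number governing the first-order detection
    delay of the non-private CUSUM.
    """
    fam = model.family
    if fam == "gaussian_mean_1d":
        d = model.params_f1["mean"] - model.params_f0["mean"]
        return 0.5 * d**2 / model.params_f0["sigma"] ** 2
    if fam == "laplace_mean_1d":
        d = abs(model.params_f1["loc"] - model.params_f0["loc"])
        d /= model.params_f0["scale"]
        return d + math.exp(-d) - 1.0
    if fam == "gaussian_var_1d":
        rho = model.params_f1["var"] / model.params_f0["var"]
        return 0.5 * (rho - 1.0 - math.log(rho))
    if fam == "gaussian_mean_kd":
        d = np.linalg.norm(model.params_f1["mean"] - model.params_f0["mean"])
        return 0.5 * float(d) ** 2 / model.params_f0["sigma"] ** 2
    if fam == "gaussian_cov_spike_kd":
        u = model.params_f1["u"]
        r = model.params_f1["r"]
        d = r * float(u @ u)
        return 0.5 * (d - math.log1p(d))
    if fam == "gaussian_full_kd":
        m0, c0 = model.params_f0["mean"], model.params_f0["cov"]
        m1, c1 = model.params_f1["mean"], model.params_f1["cov"]
        k = model.k
        c0i = np.linalg.inv(c0)
        dm = m0 - m1
        val = 0.5 * (
            np.trace(c0i @ c1)
            - k
            + dm @ c0i @ dm
            + math.log(np.linalg.det(c0) / np.linalg.det(c1))
        )
        return float(val)
    if fam == "custom":
        if model.k != 1:
            raise ValueError("quadrature fallback only for k = 1 custom models")
        lp0, lp1 = model.params_f0["logpdf"], model.params_f1["logpdf"]

        def integrand(x):
            return math.exp(lp1(x)) * (lp1(x) - lp0(x))

        val, _ = integrate.quad(integrand, -np.inf, np.inf, limit=200)
        return float(val)
    raise ValueError(f"unknown family {fam!r}")


# ---------------------------------------------------------------------------
# Stream generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StreamSpec:
    """A simulated stream with a planted change-point.

    Observations 1..tau are drawn i.i.d. from f0 and tau+1..n from f1.
    ``tau = n`` means no change within the window; ``tau = 0`` means the
    whole stream is post-change.  ``tau = None`` is shorthand for no
    change (tau = n).
    """

    model: ChangeModel
    n: int
    tau: Optional[int] = None
    seed: int = 0

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("stream length must be positive")
        tau = self.n if self.tau is None else self.tau
        if tau < 0 or tau > self.n:
            raise ValueError("change-point must lie in [0, n]")
        object.__setattr__(self, "tau", tau)


def generate_stream(spec: StreamSpec) -> np.ndarray:
    """Simulate the stream; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    pre = spec.model.sample_f0(spec.tau, rng) if spec.tau > 0 else None
    post = (
        spec.model.sample_f1(spec.n - spec.tau, rng)
        if spec.n - spec.tau > 0
        else None
    )
    if pre is None:
        return post
    if post is None:
        return pre
    return np.concatenate([pre, post], axis=0)
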