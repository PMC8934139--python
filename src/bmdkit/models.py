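"""The seven continuous dose-response models and their normal likelihood.

All models are standard EPA-style continuous parameterizations of the mean
response f(x) on the (log-scale) expression axis, with dose x rescaled to
[0, 1] by the maximum dose before fitting:

=========  ==========================================  params (+ sigma)
linear     a + s*b*x                                   a, b
power      a + s*b*x**g                                a, b, g
hill       a + s*b*x**g / (c**g + x**g)                a, b, c, g
exp2       a * exp(s*b*x)                              a, b
exp3       a * exp(s*(b*x)**g)                         a, b, g
exp4       a * (c - (c-1)*exp(-b*x))                   a, b, c
exp5       a * (c - (c-1)*exp(-(b*x)**g))              a, b, c, g
=========  ==========================================  ==================

``s`` is the adversity direction (+1 increasing, -1 decreasing), fixed per
probe from the observed trend; for exp4/exp5 the direction is carried by the
plateau parameter c (c > 1 increasing, 0 < c < 1 decreasing) and s plays no
role. ``b >= 0`` throughout and every power/shape parameter ``g`` is bounded
below by 1, so each curve is monotone in x by construction. Responses are
modeled as Normal(f(x), sigma).

Priors (all proper; defaults are configuration, not code constants):
``a ~ Normal(control mean, wide)``, ``b ~ HalfNormal``, ``g ~ Uniform[1, 18]``,
Hill ``c ~ Uniform(0, 30]`` on the rescaled dose axis, exp4/5
``c ~ Uniform(1, 30]`` (increasing) or ``Uniform(0, 1)`` (decreasing), and
``sigma ~ HalfNormal`` scaled from the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["MODEL_IDS", "PriorConfig", "ModelSpec", "make_model_spec",
           "predict", "log_likelihood"]

MODEL_IDS = ("linear", "power", "hill", "exp2", "exp3", "exp4", "exp5")

_PARAM_NAMES = {
    "linear": ("a", "b"),
    "power": ("a", "b", "g"),
    "hill": ("a", "b", "c", "g"),
    "exp2": ("a", "b"),
    "exp3": ("a", "b", "g"),
    "exp4": ("a", "b", "c"),
    "exp5": ("a", "b", "c", "g"),
}

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the default priors, normally derived from the data.

    ``a_loc``/``a_scale``: normal prior on the background a. ``b_scale``:
    half-normal scale for the increment parameter b of linear/power/hill.
    ``rate_scale``: half-normal scale for the exponential rate b of exp2-5
    (on the rescaled dose axis, where x = 1 is the top dose). ``g_max``:
    upper bound of the uniform prior on shape parameters (lower bound 1).
    ``c_max``: upper bound for Hill's half-maximal dose c and for the exp4/5
    plateau factor. ``sigma_scale``: half-normal scale for the residual SD.
    """

    a_loc: float = 0.0
    a_scale: float = 10.0
    b_scale: float = 10.0
    rate_scale: float = 5.0
    g_max: float = 18.0
    c_max: float = 30.0
    sigma_scale: float = 1.0

    @classmethod
    def from_data(cls, x: np.ndarray, y: np.ndarray) -> "PriorConfig":
        """Weakly-informative defaults scaled from one probe's data.

        The background prior centers on the control-group mean; the slope and
        sigma scales are set from the response range and the pooled
        within-group SD so that the priors stay diffuse relative to any signal
        the data can support.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ctrl = y[x == x.min()]
        m0 = float(ctrl.mean())
        rng_y = float(y.max() - y.min())
        # pooled within-group SD; fall back to total SD for degenerate designs
        levels = np.unique(x)
        ss, n = 0.0, 0
        for d in levels:
            g = y[x == d]
            if g.size > 1:
                ss += float(((g - g.mean()) ** 2).sum())
                n += g.size - 1
        sd_w = math.sqrt(ss / n) if n > 0 and ss > 0 else float(max(y.std(), 1e-3))
        return cls(
            a_loc=m0,
            a_scale=2.0 * max(float(y.std()), 0.5),
            b_scale=2.0 * max(rng_y, 1.0),
            rate_scale=5.0,
            sigma_scale=2.0 * max(sd_w, 0.1),
        )


@dataclass(frozen=True)
class ModelSpec:
    """One dose-response model bound to an adversity direction and priors."""

    model_id: str
    direction: int  # +1 increasing, -1 decreasing
    priors: PriorConfig = field(default_factory=PriorConfig)

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model {self.model_id!r}")
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")

    @property
    def param_names(self) -> tuple:
        return _PARAM_NAMES[self.model_id]

    @property
    def n_params(self) -> int:
        """Mean-function parameters, excluding sigma."""
        return len(self.param_names)

    @property
    def ndim(self) -> int:
        """Sampling dimension: mean-function parameters plus sigma."""
        return self.n_params + 1

    def bounds(self) -> list:
        """Box constraints per parameter (sigma last)."""
        pc = self.priors
        eps = 1e-9
        out = []
        for name in self.param_names:
            if name == "a":
                if self.model_id.startswith("exp"):
                    out.append((eps, np.inf))  # exponential forms need a > 0
                else:
                    out.append((-np.inf, np.inf))
            elif name == "b":
                out.append((0.0, np.inf))
            elif name == "g":
                out.append((1.0, pc.g_max))
            elif name == "c":
                if self.model_id == "hill":
                    out.append((eps, pc.c_max))
                elif self.direction > 0:
                    out.append((1.0 + eps, pc.c_max))
                else:
                    out.append((eps, 1.0 - eps))
        out.append((eps, np.inf))  # sigma
        return out

    # -- priors ------------------------------------------------------------

    def log_prior(self, theta: np.ndarray) -> np.ndarray:
        """Log prior density, vectorized over leading axes of theta
        (shape ``(..., ndim)``); -inf outside the box constraints."""
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        pc = self.priors
        lp = np.zeros(theta.shape[:-1])
        ok = np.ones(theta.shape[:-1], dtype=bool)
        for j, (lo, hi) in enumerate(self.bounds()):
            v = theta[..., j]
            ok &= (v >= lo) & (v <= hi) & np.isfinite(v)
        names = self.param_names + ("sigma",)
        for j, name in enumerate(names):
            v = theta[..., j]
            if name == "a":
                lp += -0.5 * ((v - pc.a_loc) / pc.a_scale) ** 2 \
                      - math.log(pc.a_scale) - 0.5 * _LOG_2PI
            elif name == "b":
                scale = pc.b_scale if self.model_id in ("linear", "power", "hill") \
                    else pc.rate_scale
                lp += _half_normal_logpdf(v, scale)
            elif name == "g":
                lp += -math.log(pc.g_max - 1.0)
            elif name == "c":
                if self.model_id == "hill":
                    lp += -math.log(pc.c_max)
                elif self.direction > 0:
                    lp += -math.log(pc.c_max - 1.0)
                # decreasing exp4/5: Uniform(0,1) has log-density 0
            elif name == "sigma":
                lp += _half_normal_logpdf(v, pc.sigma_scale)
        out = np.where(ok, lp, -np.inf)
        return out if out.shape else float(out)

    def initial_point(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Data-driven starting point inside the constraint box."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        m0 = float(y[x == x.min()].mean())
        m_top = float(y[x == x.max()].mean())
        delta = abs(m_top - m0)
        resid_sd = float(np.std(y - np.interp(x, *_group_curve(x, y))))
        # designs without replicates interpolate exactly (resid 0); fall back
        # to a fraction of the total spread only then
        sd0 = resid_sd if resid_sd > 1e-12 else max(0.25 * float(y.std()), 1e-2)
        sd0 = max(sd0, 1e-4)
        a0 = max(m0, 1e-3) if self.model_id.startswith("exp") else m0
        vals = {"a": a0, "g": 1.5, "sigma": sd0}
        if self.model_id in ("linear", "power", "hill"):
            vals["b"] = max(delta, 1e-2)
            vals["c"] = 0.5
        elif self.model_id in ("exp2", "exp3"):
            vals["b"] = max(math.log1p(delta / a0), 1e-3)
        else:  # exp4 / exp5
            frac = min(delta / a0, 2.0)
            vals["c"] = 1.0 + max(frac, 0.05) if self.direction > 0 \
                else max(1.0 - max(frac, 0.05), 0.05)
            vals["b"] = 2.0
        theta = np.array([vals[n] for n in self.param_names] + [vals["sigma"]])
        return _clip_to_bounds(theta, self.bounds())


def _group_curve(x, y):
    levels = np.unique(x)
    means = np.array([y[x == d].mean() for d in levels])
    return levels, means


def _clip_to_bounds(theta, bounds):
    out = theta.copy()
    for j, (lo, hi) in enumerate(bounds):
        pad = 1e-6 * (1.0 + abs(out[j]))
        out[j] = np.clip(out[j], lo + pad if np.isfinite(lo) else lo,
                         hi - pad if np.isfinite(hi) else hi)
    return out


def _half_normal_logpdf(v, scale):
    return math.log(2.0) - math.log(scale) - 0.5 * _LOG_2PI - 0.5 * (v / scale) ** 2


def make_model_spec(model_id: str, direction: int = +1,
                    priors: PriorConfig | None = None) -> ModelSpec:
    return ModelSpec(model_id, direction, priors or PriorConfig())


def predict(spec: ModelSpec, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Mean response f(x | theta), vectorized over draws and doses.

    ``theta`` has shape ``(..., n_params)`` (sigma, if present as a trailing
    column, is ignored) and ``x`` shape ``(m,)``; the result broadcasts to
    ``(..., m)``.
    """
    theta = np.asarray(theta, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("doses must be non-negative")
    p = theta[..., : len(_PARAM_NAMES[spec.model_id])]
    s = float(spec.direction)
    a = p[..., 0:1]
    b = p[..., 1:2]
    xb = x[None, :] if theta.ndim > 1 else x
    mid = spec.model_id
    with np.errstate(over="ignore", invalid="ignore"):
        if mid == "linear":
            out = a + s * b * xb
        elif mid == "power":
            g = p[..., 2:3]
            out = a + s * b * np.power(xb, g)
        elif mid == "hill":
            c, g = p[..., 2:3], p[..., 3:4]
            xg = np.power(xb, g)
            out = a + s * b * xg / (np.power(c, g) + xg)
        elif mid == "exp2":
            out = a * np.exp(s * b * xb)
        elif mid == "exp3":
            g = p[..., 2:3]
            out = a * np.exp(s * np.power(b * xb, g))
        elif mid == "exp4":
            c = p[..., 2:3]
            out = a * (c - (c - 1.0) * np.exp(-b * xb))
        else:  # exp5
            c, g = p[..., 2:3], p[..., 3:4]
            out = a * (c - (c - 1.0) * np.exp(-np.power(b * xb, g)))
    return out


def log_likelihood(spec: ModelSpec, theta: np.ndarray, x: np.ndarray,
                   y: np.ndarray) -> np.ndarray:
    """Normal log-likelihood sum over samples; sigma is the last theta column.

    Vectorized over leading axes of theta.
    """
    theta = np.asarray(theta, dtype=float)
    sigma = theta[..., -1:]
    mu = predict(spec, theta[..., :-1], x)
    if theta.ndim == 1:
        sigma = float(theta[-1])
        if sigma <= 0:
            return -np.inf
        r = (np.asarray(y) - mu) / sigma
        return float(-0.5 * np.sum(r * r) - y.size * (math.log(sigma) + 0.5 * _LOG_2PI))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (np.asarray(y)[None, :] - mu) / sigma
        ll = -0.5 * np.sum(r * r, axis=-1) - np.asarray(y).size * (
            np.log(sigma[..., 0]) + 0.5 * _LOG_2PI)
    return np.where(sigma[..., 0] > 0, ll, -np.inf)
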