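"""The random-sites model family (M0, M1a, M2a, M2a_rel, M3, M7, M8a, M8).

Each model describes among-site variation in omega = dN/dS as a finite
mixture of site classes: a proportion vector and an omega per class.
The beta models (M7/M8/M8a) discretize Beta(p, q) into K equal-probability
classes, each represented by its conditional mean (computed from
regularized incomplete-beta ratios), the convention used by codeml with
ncatG = K; the default K is 10.

Model parameters are exposed on their natural scale, with bijective
transforms to an unconstrained vector for optimization: proportions via
stick-breaking logits, strictly positive parameters via log, the M8
positive-class omega_s via log(omega_s - 1) bounded in [1, 999].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import betainc, expit, logit
from scipy.stats import beta as beta_dist

from .errors import ValidationError

DEFAULT_N_BETA_CLASSES = 10

_EPS = 1e-12


@dataclass(frozen=True)
class ClassDistribution:
    """Site-class mixture: proportions summing to 1 and omega per class."""

    proportions: np.ndarray
    omegas: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.proportions, dtype=float)
        w = np.asarray(self.omegas, dtype=float)
        if p.shape != w.shape:
            raise ValidationError("proportions and omegas must have equal length")
        if p.min() < -_EPS or abs(p.sum() - 1.0) > 1e-12:
            raise ValidationError("proportions must be >= 0 and sum to 1 within 1e-12")
        object.__setattr__(self, "proportions", np.maximum(p, 0.0))
        object.__setattr__(self, "omegas", w)

    @property
    def n_classes(self) -> int:
        return len(self.proportions)


def discretize_beta(p: float, q: float, k: int) -> np.ndarray:
    """K equal-probability class means of Beta(p, q), strictly inside (0,1).

    Class i spans the (i/K, (i+1)/K) quantile interval; its representative
    value is the conditional mean
    ``E[X | bin] = K * p/(p+q) * (I(x_hi; p+1, q) - I(x_lo; p+1, q))``
    with I the regularized incomplete beta function.
    """
    if p <= 0 or q <= 0:
        raise ValidationError("beta shape parameters must be > 0")
    if k < 1:
        raise ValidationError("need at least one class")
    edges = beta_dist.ppf(np.linspace(0.0, 1.0, k + 1), p, q)
    upper = betainc(p + 1.0, q, edges[1:])
    lower = betainc(p + 1.0, q, edges[:-1])
    means = (p / (p + q)) * (upper - lower) * k
    means = np.clip(means, 1e-9, 1.0 - 1e-9)
    return np.maximum.accumulate(means)


# ---------------------------------------------------------------------------
# Transform helpers

_LOG_BOUND = (-16.0, 9.0)  # natural scale roughly [1e-7, 8e3]


def _stick_break(z: np.ndarray) -> np.ndarray:
    """Logits -> first len(z) entries of a probability vector."""
    out = []
    remaining = 1.0
    for zi in z:
        frac = expit(zi)
        out.append(remaining * frac)
        remaining *= 1.0 - frac
    return np.array(out)


def _stick_unbreak(props: np.ndarray) -> np.ndarray:
    z = []
    remaining = 1.0
    for p in props:
        frac = np.clip(p / max(remaining, _EPS), 1e-12, 1 - 1e-12)
        z.append(logit(frac))
        remaining *= 1.0 - frac
    return np.array(z)


@dataclass(frozen=True)
class _Param:
    name: str
    kind: str  # 'log' | 'logit' | 'stick' | 'omega_s'


@dataclass(frozen=True)
class SiteClassSpec:
    """Parameterization of one random-sites model.

    ``free_parameters`` lists the model's own parameters (kappa and branch
    lengths are engine-level); ``df_against`` gives the chi-square degrees
    of freedom for each nested null this model is tested against.
    """

    name: str
    params: tuple[_Param, ...]
    df_against: dict[str, int] = field(default_factory=dict)
    n_beta_classes: int = DEFAULT_N_BETA_CLASSES

    @property
    def free_parameters(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.params)

    @property
    def n_free_params(self) -> int:
        return len(self.params)

    @property
    def n_classes(self) -> int:
        return len(self.class_distribution(self.default_starts()[0]).proportions)

    # -- transforms ---------------------------------------------------------

    def to_unconstrained(self, theta: dict[str, float]) -> np.ndarray:
        z = []
        for p in self.params:
            v = float(theta[p.name])
            if p.kind == "log":
                z.append(np.log(max(v, 1e-12)))
            elif p.kind in ("logit", "stick"):
                z.append(logit(np.clip(v, 1e-12, 1 - 1e-12)))
            elif p.kind == "omega_s":
                z.append(np.log(max(v - 1.0, 1e-9)))
            else:  # pragma: no cover
                raise ValueError(p.kind)
        # stick-breaking couples successive proportions
        stick_idx = [i for i, p in enumerate(self.params) if p.kind == "stick"]
        if len(stick_idx) > 1:
            props = np.array([theta[self.params[i].name] for i in stick_idx])
            zs = _stick_unbreak(props)
            for i, zi in zip(stick_idx, zs):
                z[i] = zi
        return np.array(z)

    def from_unconstrained(self, z: np.ndarray) -> dict[str, float]:
        theta: dict[str, float] = {}
        stick_idx = [i for i, p in enumerate(self.params) if p.kind == "stick"]
        sticks = _stick_break(np.array([z[i] for i in stick_idx])) if stick_idx else []
        s_iter = iter(sticks)
        for i, p in enumerate(self.params):
            if p.kind == "log":
                theta[p.name] = float(np.exp(np.clip(z[i], *_LOG_BOUND)))
            elif p.kind == "logit":
                theta[p.name] = float(expit(z[i]))
            elif p.kind == "stick":
                theta[p.name] = float(next(s_iter))
            elif p.kind == "omega_s":
                theta[p.name] = float(1.0 + np.exp(np.clip(z[i], -20.7, 6.9)))
        return theta

    # -- mixture ------------------------------------------------------------

    def class_distribution(self, theta: dict[str, float]) -> ClassDistribution:
        return site_class_distribution(self, theta)

    def default_starts(self) -> list[dict[str, float]]:
        return _DEFAULT_STARTS[self.name]

    def validate_theta(self, theta: dict[str, float]) -> None:
        missing = set(self.free_parameters) - set(theta)
        if missing:
            raise ValidationError(f"{self.name}: missing parameters {sorted(missing)}")


def site_class_distribution(spec: SiteClassSpec, theta: dict[str, float]) -> ClassDistribution:
    """Evaluate a model's (proportions, omegas) at a parameter point."""
    spec.validate_theta(theta)
    name, k = spec.name, spec.n_beta_classes
    if name == "M0":
        return ClassDistribution(np.array([1.0]), np.array([theta["omega"]]))
    if name == "M1a":
        p0 = theta["p0"]
        _check_simplex([p0])
        return ClassDistribution(
            np.array([p0, 1.0 - p0]), np.array([theta["omega0"], 1.0])
        )
    if name in ("M2a", "M2a_rel"):
        p0, p1 = theta["p0"], theta["p1"]
        _check_simplex([p0, p1])
        return ClassDistribution(
            np.array([p0, p1, 1.0 - p0 - p1]),
            np.array([theta["omega0"], 1.0, theta["omega2"]]),
        )
    if name == "M3":
        p0, p1 = theta["p0"], theta["p1"]
        _check_simplex([p0, p1])
        return ClassDistribution(
            np.array([p0, p1, 1.0 - p0 - p1]),
            np.array([theta["omega0"], theta["omega1"], theta["omega2"]]),
        )
    if name == "M7":
        means = discretize_beta(theta["p"], theta["q"], k)
        return ClassDistribution(np.full(k, 1.0 / k), means)
    if name in ("M8", "M8a"):
        p0 = theta["p0"]
        _check_simplex([p0])
        omega_s = 1.0 if name == "M8a" else theta["omega_s"]
        if omega_s < 1.0:
            raise ValidationError("M8 positive-class omega_s must be >= 1")
        means = discretize_beta(theta["p"], theta["q"], k)
        props = np.concatenate([np.full(k, p0 / k), [1.0 - p0]])
        return ClassDistribution(props, np.concatenate([means, [omega_s]]))
    raise ValidationError(f"unknown model {name!r}")


def _check_simplex(props) -> None:
    arr = np.asarray(props, dtype=float)
    if arr.min() < 0 or arr.sum() > 1.0 + 1e-12:
        raise ValidationError(f"class proportions outside the simplex: {arr}")


# ---------------------------------------------------------------------------
# Registry

MODEL_NAMES = ("M0", "M1a", "M2a", "M2a_rel", "M3", "M7", "M8a", "M8")

_DEFAULT_STARTS: dict[str, list[dict[str, float]]] = {
    # the omega start grid {0.05, 0.5, 1.5, 3.0} implements varying starts
    "M0": [{"omega": w} for w in (0.05, 0.5, 1.5, 3.0)],
    "M1a": [{"p0": 0.8, "omega0": 0.1}, {"p0": 0.5, "omega0": 0.5}],
    "M2a": [
        {"p0": 0.8, "p1": 0.15, "omega0": 0.1, "omega2": 1.5},
        {"p0": 0.6, "p1": 0.3, "omega0": 0.3, "omega2": 3.0},
    ],
    "M2a_rel": [
        {"p0": 0.7, "p1": 0.2, "omega0": 0.1, "omega2": 0.5},
        {"p0": 0.5, "p1": 0.3, "omega0": 0.3, "omega2": 3.0},
    ],
    "M3": [
        {"p0": 0.6, "p1": 0.3, "omega0": 0.05, "omega1": 0.5, "omega2": 1.5},
        {"p0": 0.4, "p1": 0.4, "omega0": 0.01, "omega1": 0.2, "omega2": 3.0},
    ],
    "M7": [{"p": 0.5, "q": 1.5}, {"p": 1.0, "q": 1.0}],
    "M8a": [{"p0": 0.9, "p": 0.5, "q": 1.5}, {"p0": 0.7, "p": 1.0, "q": 1.0}],
    "M8": [
        {"p0": 0.9, "p": 0.5, "q": 1.5, "omega_s": 1.5},
        {"p0": 0.9, "p": 0.5, "q": 1.5, "omega_s": 3.0},
    ],
}


def _make_models(k: int = DEFAULT_N_BETA_CLASSES) -> dict[str, SiteClassSpec]:
    P = _Param
    return {
        "M0": SiteClassSpec("M0", (P("omega", "log"),)),
        "M1a": SiteClassSpec(
            "M1a", (P("p0", "stick"), P("omega0", "logit")), {"M0": 1}
        ),
        "M2a": SiteClassSpec(
            "M2a",
            (P("p0", "stick"), P("p1", "stick"), P("omega0", "logit"), P("omega2", "omega_s")),
            {"M1a": 2},
        ),
        "M2a_rel": SiteClassSpec(
            "M2a_rel",
            (P("p0", "stick"), P("p1", "stick"), P("omega0", "logit"), P("omega2", "log")),
            {"M1a": 2},
        ),
        "M3": SiteClassSpec(
            "M3",
            (
                P("p0", "stick"),
                P("p1", "stick"),
                P("omega0", "log"),
                P("omega1", "log"),
                P("omega2", "log"),
            ),
            {"M0": 4},
        ),
        "M7": SiteClassSpec("M7", (P("p", "log"), P("q", "log")), {}, k),
        "M8a": SiteClassSpec(
            "M8a", (P("p0", "stick"), P("p", "log"), P("q", "log")), {}, k
        ),
        "M8": SiteClassSpec(
            "M8",
            (P("p0", "stick"), P("p", "log"), P("q", "log"), P("omega_s", "omega_s")),
            {"M7": 2, "M8a": 1},
        ),
    }


MODELS: dict[str, SiteClassSpec] = _make_models()


def get_model(name: str, n_beta_classes: int = DEFAULT_N_BETA_CLASSES) -> SiteClassSpec:
    if name not in MODELS:
        raise ValidationError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    if n_beta_classes == DEFAULT_N_BETA_CLASSES:
        return MODELS[name]
    return _make_models(n_beta_classes)[name]


def seed_from_null(
    alt: SiteClassSpec, null_name: str, null_theta: dict[str, float]
) -> dict[str, float] | None:
    """Starting point for ``alt`` at (numerically) the null's optimum.

    Guarantees lnL(alt) >= lnL(null) - 1e-4 when used as an extra start:
    the alternative's extra class gets weight ~1e-8, leaving the mixture
    effectively identical to the null.
    """
    tiny = 1e-8
    if alt.name == "M8" and null_name == "M7":
        return {
            "p0": 1.0 - tiny,
            "p": null_theta["p"],
            "q": null_theta["q"],
            "omega_s": 2.0,
        }
    if alt.name == "M8" and null_name == "M8a":
        return dict(null_theta, omega_s=1.0 + 1e-7)
    if alt.name == "M8a" and null_name == "M7":
        return {"p0": 1.0 - tiny, "p": null_theta["p"], "q": null_theta["q"]}
    if alt.name in ("M2a", "M2a_rel") and null_name == "M1a":
        p0 = null_theta["p0"]
        return {
            "p0": p0 * (1 - tiny),
            "p1": (1 - p0) * (1 - tiny),
            "omega0": null_theta["omega0"],
            "omega2": 1.0 + 1e-7 if alt.name == "M2a" else 1.0,
        }
    if alt.name == "M3" and null_name == "M0":
        w = null_theta["omega"]
        return {
            "p0": 1.0 / 3,
            "p1": 1.0 / 3,
            "omega0": max(w * 0.5, 1e-4),
            "omega1": w,
            "omega2": w * 2.0,
        }
    if alt.name == "M1a" and null_name == "M0":
        return {"p0": 0.9, "omega0": min(max(null_theta["omega"], 1e-4), 0.9)}
    return None
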