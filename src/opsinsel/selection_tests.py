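"""Likelihood-ratio tests and per-site positive-selection posteriors.

Nested random-sites models are compared with 2*(lnL_alt - lnL_null)
against a plain chi-square reference distribution (including the
one-degree M8a-vs-M8 comparison). Individual sites are ranked by the
posterior probability of membership in the positively selected class,
either at the maximum-likelihood parameter point (NEB, naive empirical
Bayes) or integrating over mixture-parameter uncertainty on a uniform
grid (BEB, Bayes empirical Bayes). Reports list sites reaching a
posterior-probability threshold (default 0.80) under any method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import ValidationError
from .io_formats import CodonAlignment, Phylogeny
from .likelihood import (
    FitResult,
    PruningEngine,
    class_pattern_logliks,
    mixture_rate_normalizer,
    unroot_to_trichotomy,
)
from .site_models import discretize_beta

_LRT_FLOOR = -2e-4  # numerical tolerance before clipping a negative LRT to 0


@dataclass(frozen=True)
class LRTResult:
    """One likelihood-ratio test row (the Null/LRT/df/p columns)."""

    null_model: str
    alt_model: str
    lnL_null: float
    lnL_alt: float
    LRT: float
    df: int
    p_value: float


def chi_square_survival(x: float, df: int) -> float:
    """Upper-tail chi-square probability; for df=2 this is exp(-x/2)."""
    if x < 0:
        raise ValidationError("test statistic must be >= 0")
    if df < 1:
        raise ValidationError("degrees of freedom must be >= 1")
    return float(chi2.sf(x, df))


def likelihood_ratio_test(
    lnL_null: float,
    lnL_alt: float,
    df: int,
    null_model: str = "null",
    alt_model: str = "alt",
) -> LRTResult:
    """LRT = 2*(lnL_alt - lnL_null) against chi-square with ``df`` degrees.

    A slightly negative statistic (within numerical tolerance of the
    optimizer) is clipped to 0; a substantially negative one indicates the
    alternative was not fitted to at least the null's likelihood and
    raises.
    """
    if df < 1:
        raise ValidationError("degrees of freedom must be >= 1")
    stat = 2.0 * (lnL_alt - lnL_null)
    if stat < _LRT_FLOOR:
        raise ValidationError(
            f"negative LRT {stat:.6f}: alternative fits worse than its null"
        )
    stat = max(stat, 0.0)
    return LRTResult(
        null_model=null_model,
        alt_model=alt_model,
        lnL_null=lnL_null,
        lnL_alt=lnL_alt,
        LRT=stat,
        df=df,
        p_value=chi_square_survival(stat, df),
    )


# ---------------------------------------------------------------------------
# Site posteriors


def _positive_class_index(fit: FitResult) -> int:
    omegas = fit.class_distribution.omegas
    if len(omegas) == 1:
        return 0  # degenerate single-class model: its only class
    if fit.model_name in ("M2a", "M2a_rel", "M8"):
        idx = len(omegas) - 1
        if omegas[idx] > 1.0 or fit.model_name == "M8":
            return idx
    raise ValidationError(
        f"model {fit.model_name} has no positively selected class to report"
    )


def _posterior_table(
    pp_pos: np.ndarray,
    mean_w: np.ndarray,
    sd_w: np.ndarray,
    method: str,
    numbering: dict[int, int] | None = None,
) -> pd.DataFrame:
    n = len(pp_pos)
    table = pd.DataFrame(
        {
            "site": np.arange(1, n + 1),
            "pp_positive": pp_pos,
            "mean_omega": mean_w,
            "sd_omega": sd_w,
            "method": method,
        }
    )
    if numbering is not None:
        table["reference_position"] = [numbering.get(s, None) for s in table["site"]]
    return table


def neb_site_posteriors(
    aln: CodonAlignment,
    tree: Phylogeny,
    fit: FitResult,
    numbering: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Naive empirical Bayes site posteriors at the ML parameter point.

    Per site, class posteriors are proportional to
    proportion_c * P(column | omega_c) evaluated at theta-hat; the table
    reports the positive-class posterior and the posterior mean +/- SD of
    omega across classes.
    """
    tree = unroot_to_trichotomy(tree)
    engine = PruningEngine(aln, tree)
    dist = fit.class_distribution
    mu_bar = mixture_rate_normalizer(fit.theta_hat["kappa"], fit.pi, dist, aln.code)
    logl = class_pattern_logliks(
        engine, fit.theta_hat["kappa"], fit.pi, dist.omegas,
        fit.branch_lengths_hat, mu_bar,
    )
    logl = engine.expand(logl)
    pos = _positive_class_index(fit)
    with np.errstate(divide="ignore"):
        logpost = logl + np.log(np.maximum(dist.proportions, 1e-300))[None, :]
    m = logpost.max(axis=1, keepdims=True)
    post = np.exp(logpost - m)
    post /= post.sum(axis=1, keepdims=True)
    mean_w = post @ dist.omegas
    var_w = post @ dist.omegas**2 - mean_w**2
    return _posterior_table(
        post[:, pos], mean_w, np.sqrt(np.maximum(var_w, 0.0)), "NEB", numbering
    )


def _beb_grid(fit: FitResult, d: int):
    """Uniform parameter grid for BEB; d=1 degenerates to theta-hat (NEB)."""
    th = fit.theta_hat
    mid = (2 * np.arange(1, d + 1) - 1) / (2.0 * d)
    if fit.model_name == "M8":
        if d == 1:
            return [(th["p0"], th["p"], th["q"], th["omega_s"])]
        return [
            (p0, p, q, ws)
            for p0 in mid
            for p in 2.0 * mid
            for q in 2.0 * mid
            for ws in 1.0 + 10.0 * mid
        ]
    if fit.model_name in ("M2a", "M2a_rel"):
        if d == 1:
            return [(th["p0"], th["p1"], th["omega0"], th["omega2"])]
        pts = []
        for p0 in mid:
            for p1 in mid:
                if p0 + p1 < 1.0:
                    pts.append((p0, p1, None, None))
        return [
            (p0, p1, w0, w2)
            for (p0, p1, _, _) in pts
            for w0 in mid
            for w2 in 1.0 + 10.0 * mid
        ]
    raise ValidationError(f"BEB is defined for M2a/M8 fits, not {fit.model_name}")


def beb_site_posteriors(
    aln: CodonAlignment,
    tree: Phylogeny,
    fit: FitResult,
    grid_points_per_dim: int = 10,
    numbering: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Bayes empirical Bayes site posteriors for an M8 (or M2a) fit.

    Mixture parameters are integrated over a uniform grid (M8: p0, p, q,
    omega_s; M2a: p0, p1, omega0, omega2), each grid point weighted by its
    full-data likelihood; kappa and branch lengths stay fixed at their
    MLEs, and class rate matrices keep the normalization frozen at
    theta-hat so omega is the only moving part. With a 1-point grid the
    procedure reduces exactly to NEB.
    """
    if grid_points_per_dim < 1:
        raise ValidationError("grid_points_per_dim must be >= 1")
    tree = unroot_to_trichotomy(tree)
    engine = PruningEngine(aln, tree)
    kappa, pi = fit.theta_hat["kappa"], fit.pi
    ts = fit.branch_lengths_hat
    dist_hat = fit.class_distribution
    mu_hat = mixture_rate_normalizer(kappa, pi, dist_hat, aln.code)
    k_beta = fit.spec.n_beta_classes if fit.spec is not None else 10
    counts = engine.pattern_counts

    cache: dict[float, np.ndarray] = {}

    def loglik_col(omega: float) -> np.ndarray:
        key = round(float(omega), 12)
        if key not in cache:
            cache[key] = class_pattern_logliks(
                engine, kappa, pi, [omega], ts, mu_hat
            )[:, 0]
        return cache[key]

    grid = _beb_grid(fit, grid_points_per_dim)

    def grid_class_columns(point):
        if fit.model_name == "M8":
            p0, p, q, ws = point
            if grid_points_per_dim == 1:
                omegas = dist_hat.omegas
                weights = dist_hat.proportions
            else:
                betas = discretize_beta(p, q, k_beta)
                omegas = np.concatenate([betas, [ws]])
                weights = np.concatenate([np.full(k_beta, p0 / k_beta), [1.0 - p0]])
        else:
            p0, p1, w0, w2 = point
            omegas = np.array([w0, 1.0, w2])
            weights = np.array([p0, p1, 1.0 - p0 - p1])
        cols = np.stack([loglik_col(w) for w in omegas], axis=1)
        return cols, np.asarray(weights, float), np.asarray(omegas, float)

    # pass 1: marginal data log-likelihood of each grid point
    grid_loglik = np.empty(len(grid))
    for g, point in enumerate(grid):
        cols, weights, _ = grid_class_columns(point)
        with np.errstate(divide="ignore"):
            m = cols + np.log(np.maximum(weights, 1e-300))[None, :]
        mx = m.max(axis=1)
        per_pat = mx + np.log(np.exp(m - mx[:, None]).sum(axis=1))
        grid_loglik[g] = float(per_pat @ counts)
    gw = np.exp(grid_loglik - grid_loglik.max())
    gw /= gw.sum()

    # pass 2: posterior-weighted per-site quantities
    n_pat = engine.n_patterns
    pp_pos = np.zeros(n_pat)
    mom1 = np.zeros(n_pat)
    mom2 = np.zeros(n_pat)
    for g, point in enumerate(grid):
        if gw[g] < 1e-14:
            continue
        cols, weights, omegas = grid_class_columns(point)
        with np.errstate(divide="ignore"):
            m = cols + np.log(np.maximum(weights, 1e-300))[None, :]
        mx = m.max(axis=1, keepdims=True)
        post = np.exp(m - mx)
        post /= post.sum(axis=1, keepdims=True)
        pp_pos += gw[g] * post[:, -1]
        mom1 += gw[g] * (post @ omegas)
        mom2 += gw[g] * (post @ omegas**2)
    sd = np.sqrt(np.maximum(mom2 - mom1**2, 0.0))
    return _posterior_table(
        engine.expand(pp_pos),
        engine.expand(mom1),
        engine.expand(sd),
        "BEB",
        numbering,
    )


# ---------------------------------------------------------------------------
# Reporting


def positive_site_report(
    tables: list[pd.DataFrame],
    threshold: float = 0.80,
) -> pd.DataFrame:
    """Union of sites reaching the posterior threshold under any method.

    One row per qualifying site with per-method posterior-probability and
    omega columns; a method under which the site did not qualify still
    shows its values when available, and an em-dash when not.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValidationError("threshold must be in (0, 1]")
    methods = []
    by_method: dict[str, pd.DataFrame] = {}
    for table in tables:
        (method,) = table["method"].unique()
        methods.append(method)
        by_method[method] = table.set_index("site")
    qualifying: set[int] = set()
    for method in methods:
        t = by_method[method]
        qualifying |= set(t.index[t["pp_positive"] >= threshold])
    rows = []
    for site in sorted(qualifying):
        row: dict = {"site": site}
        for method in methods:
            t = by_method[method]
            if site in t.index:
                row[f"{method}_pp"] = round(float(t.loc[site, "pp_positive"]), 3)
                row[f"{method}_omega"] = round(float(t.loc[site, "mean_omega"]), 3)
                sd = t.loc[site, "sd_omega"] if "sd_omega" in t.columns else np.nan
                row[f"{method}_omega_sd"] = (
                    round(float(sd), 3) if np.isfinite(sd) else "–"
                )
                if "reference_position" in t.columns:
                    row["reference_position"] = t.loc[site, "reference_position"]
            else:
                row[f"{method}_pp"] = "–"
                row[f"{method}_omega"] = "–"
                row[f"{method}_omega_sd"] = "–"
        rows.append(row)
    columns = ["site"] + [
        f"{m}_{suffix}" for m in methods for suffix in ("pp", "omega", "omega_sd")
    ]
    report = pd.DataFrame(rows)
    if report.empty:
        return pd.DataFrame(columns=columns)
    return report
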