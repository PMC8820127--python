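"""FUBAR-style Bayesian grid analysis of per-site selection.

Unlike the random-sites models, which tie the synonymous rate to 1 at
every site, this analysis places each site on a two-dimensional grid of
(alpha, beta) = (synonymous, nonsynonymous) rates, so dS varies freely
across sites. A hierarchical Dirichlet prior over grid-point weights is
sampled by a collapsed Gibbs sampler (alternating per-site grid
allocations and conjugate Dirichlet weight draws), and each site is
summarized by Pr(beta > alpha | data) averaged over the retained weight
samples.

Nuisance parameters (kappa, codon frequencies, branch lengths) are fixed
beforehand from an M0 fit on the same alignment and tree, mirroring the
method's two-stage design. The per-site omega column reports
(posterior mean beta) / (posterior mean alpha) — a ratio-of-means
convention, recorded in the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon_model import decompose_rate_matrix, get_structure
from .errors import ValidationError
from .io_formats import CodonAlignment, Phylogeny
from .likelihood import FitResult, PruningEngine, unroot_to_trichotomy

DEFAULT_POINTS_PER_AXIS = 20
DEFAULT_MAX_RATE = 50.0
DEFAULT_CONCENTRATION = 0.5


@dataclass
class FubarGrid:
    """The (alpha, beta) rate grid and, once filled, per-site likelihoods."""

    alpha_values: np.ndarray
    beta_values: np.ndarray
    points: np.ndarray  # (N, 2) columns alpha, beta
    prior_concentration: float = DEFAULT_CONCENTRATION
    site_logliks: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def site_likelihoods(self) -> np.ndarray:
        """Per-site likelihoods rescaled so each site's maximum is 1."""
        if self.site_logliks is None:
            raise ValidationError("grid likelihoods not filled yet")
        m = self.site_logliks.max(axis=1, keepdims=True)
        return np.exp(self.site_logliks - m)


def build_fubar_grid(
    points_per_axis: int = DEFAULT_POINTS_PER_AXIS,
    max_rate: float = DEFAULT_MAX_RATE,
    prior_concentration: float = DEFAULT_CONCENTRATION,
) -> FubarGrid:
    """Quadratically spaced rate grid on [0, max_rate] per axis.

    Values are squares of an even grid on [0, sqrt(max_rate)], so density
    concentrates near 0 where most sites sit; the grid always contains the
    diagonal (beta = alpha) including (0, 0).
    """
    if points_per_axis < 2:
        raise ValidationError("points_per_axis must be >= 2")
    if max_rate <= 0:
        raise ValidationError("max_rate must be > 0")
    values = np.linspace(0.0, np.sqrt(max_rate), points_per_axis) ** 2
    alpha, beta = np.meshgrid(values, values, indexing="ij")
    points = np.column_stack([alpha.ravel(), beta.ravel()])
    return FubarGrid(
        alpha_values=values,
        beta_values=values.copy(),
        points=points,
        prior_concentration=prior_concentration,
    )


def fubar_site_grid_likelihoods(
    aln: CodonAlignment,
    tree: Phylogeny,
    grid: FubarGrid,
    kappa: float,
    pi: np.ndarray,
    branch_lengths: np.ndarray | None = None,
) -> FubarGrid:
    """Fill the grid with per-site log-likelihoods.

    At grid point (alpha, beta) the rate matrix is the M0-normalized
    (omega = 1) matrix with its synonymous component scaled by alpha and
    its nonsynonymous component by beta, so alpha = beta = r is exactly
    the omega = 1 process with branch lengths multiplied by r.
    """
    tree = unroot_to_trichotomy(tree)
    engine = PruningEngine(aln, tree)
    ts = branch_lengths if branch_lengths is not None else engine.edge_lengths_template
    pi = np.asarray(pi, dtype=float)
    struct = get_structure(aln.code)
    q1 = struct.unscaled_rates(kappa, 1.0, pi)
    mu1 = float(pi @ q1.sum(axis=1))
    syn = np.where(struct.single & ~struct.nonsyn, q1, 0.0) / mu1
    nonsyn = np.where(struct.nonsyn, q1, 0.0) / mu1

    n_sites = aln.n_sites
    logl = np.empty((n_sites, grid.n_points))
    for g, (alpha, beta) in enumerate(grid.points):
        q = alpha * syn + beta * nonsyn
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        if alpha == 0.0 and beta == 0.0:
            # no substitutions: likelihood is pi at the observed state when
            # all leaves agree, 0 otherwise; the identity matrix handles it
            p_edges = np.tile(np.eye(len(pi)), (engine.n_edges, 1, 1))
            logl[:, g] = engine.expand(engine.pattern_log_likelihoods(p_edges, pi))
            continue
        dec = decompose_rate_matrix(q, pi)
        p_edges = dec.transition_matrices(ts)
        logl[:, g] = engine.expand(engine.pattern_log_likelihoods(p_edges, pi))
    # sites impossible at a grid point get a large negative, not -inf
    logl = np.where(np.isfinite(logl), logl, -1e300)
    grid.site_logliks = logl
    return grid


def fubar_nuisance_from_m0(m0_fit: FitResult) -> dict:
    """Extract (kappa, pi, branch lengths) from a fitted M0 model."""
    return {
        "kappa": m0_fit.theta_hat["kappa"],
        "pi": m0_fit.pi,
        "branch_lengths": m0_fit.branch_lengths_hat,
    }


def fubar_gibbs_weights(
    grid: FubarGrid,
    n_samples: int = 5000,
    burn_in: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Posterior samples of grid weights by collapsed Gibbs sampling.

    Alternates per-site categorical allocation draws (proportional to
    weight x site likelihood) with conjugate Dirichlet weight draws
    (concentration prior + allocation counts). Returns the retained
    (n_samples, n_points) weight samples; identical seeds give identical
    chains.
    """
    if burn_in < 0 or n_samples <= 0:
        raise ValidationError("need n_samples > 0 and burn_in >= 0")
    lik = grid.site_likelihoods()  # (n_sites, N), per-site max 1
    n_sites, n_points = lik.shape
    conc = grid.prior_concentration
    rng = np.random.default_rng(seed)
    weights = np.full(n_points, 1.0 / n_points)
    samples = np.empty((n_samples, n_points))
    for it in range(burn_in + n_samples):
        probs = lik * weights[None, :]
        cum = probs.cumsum(axis=1)
        tot = cum[:, -1]
        if (tot <= 0).any():
            raise ValidationError("a site has zero likelihood over the whole grid")
        u = rng.random(n_sites) * tot
        alloc = (cum < u[:, None]).sum(axis=1)
        counts = np.bincount(alloc, minlength=n_points)
        weights = rng.dirichlet(conc + counts)
        if it >= burn_in:
            samples[it - burn_in] = weights
    return samples


def fubar_site_summary(
    grid: FubarGrid,
    weight_samples: np.ndarray,
    numbering: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Per-site posterior summary table.

    ``pp_positive`` is Pr(beta > alpha | data) averaged over weight
    samples; ``mean_omega`` is (posterior mean beta)/(posterior mean
    alpha). Pr(beta>alpha) + Pr(beta<alpha) + Pr(beta=alpha) = 1 per site.
    """
    lik = grid.site_likelihoods()  # (n_sites, N)
    theta = np.asarray(weight_samples, dtype=float)  # (S, N)
    alpha = grid.points[:, 0]
    beta = grid.points[:, 1]
    above = beta > alpha
    below = beta < alpha

    denom = theta @ lik.T  # (S, n_sites)
    pp_above = ((theta * above[None, :]) @ lik.T / denom).mean(axis=0)
    pp_below = ((theta * below[None, :]) @ lik.T / denom).mean(axis=0)
    mean_beta = ((theta * beta[None, :]) @ lik.T / denom).mean(axis=0)
    mean_alpha = ((theta * alpha[None, :]) @ lik.T / denom).mean(axis=0)
    omega = mean_beta / np.maximum(mean_alpha, 1e-9)

    n = lik.shape[0]
    table = pd.DataFrame(
        {
            "site": np.arange(1, n + 1),
            "pp_positive": pp_above,
            "pp_negative": pp_below,
            "pp_neutral": 1.0 - pp_above - pp_below,
            "mean_omega": omega,
            "mean_alpha": mean_alpha,
            "mean_beta": mean_beta,
            "sd_omega": np.nan,
            "method": "FUBAR",
        }
    )
    table.attrs["omega_convention"] = "posterior_mean_beta / posterior_mean_alpha"
    if numbering is not None:
        table["reference_position"] = [numbering.get(s) for s in table["site"]]
    return table


def run_fubar(
    aln: CodonAlignment,
    tree: Phylogeny,
    m0_fit: FitResult,
    points_per_axis: int = DEFAULT_POINTS_PER_AXIS,
    max_rate: float = DEFAULT_MAX_RATE,
    n_samples: int = 5000,
    burn_in: int = 1000,
    seed: int = 0,
    numbering: dict[int, int] | None = None,
) -> tuple[pd.DataFrame, FubarGrid, np.ndarray]:
    """Two-stage FUBAR pipeline: fill the grid under M0 nuisance
    parameters, run the Gibbs sampler, summarize per site."""
    nuisance = fubar_nuisance_from_m0(m0_fit)
    grid = build_fubar_grid(points_per_axis, max_rate)
    grid = fubar_site_grid_likelihoods(
        aln, tree, grid, nuisance["kappa"], nuisance["pi"], nuisance["branch_lengths"]
    )
    samples = fubar_gibbs_weights(grid, n_samples=n_samples, burn_in=burn_in, seed=seed)
    return fubar_site_summary(grid, samples, numbering), grid, samples
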