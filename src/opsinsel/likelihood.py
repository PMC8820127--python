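"""Site-class mixture likelihoods by pruning, and maximum-likelihood fits.

The likelihood of a codon alignment under a random-sites model is

    lnL = sum_sites log sum_classes w_c * P(column | omega_c)

with P(column | omega_c) computed by post-order pruning over the 61
sense-codon states. Site columns are compressed to unique patterns with
multiplicities; ambiguous codons (gaps, Ns) contribute a partial vector of
ones over their compatible states, so a fully ambiguous leaf is
marginalized out exactly.

Rate scaling follows the codeml convention for site models: all class
matrices share one scale factor, chosen so the *mixture-average*
substitution rate is 1. Branch lengths therefore read as expected
substitutions per codon site averaged over site classes, and a model whose
extra class has zero weight is numerically identical to its nested null.

Fitting uses bounded quasi-Newton optimization (L-BFGS-B) on transformed
parameters. For the beta-mixture models (M7/M8/M8a) the optimization runs
in two stages: an inner search on a precomputed per-site log-likelihood
surface over (omega, rate multiplier), then an exact-likelihood polish
from the best candidate. Every reported lnL is an exact re-evaluation at
the returned parameter point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .codon_model import (
    decompose_rate_matrix,
    estimate_codon_frequencies,
    get_structure,
)
from .errors import ConvergenceError, ValidationError
from .genetic_code import GeneticCode
from .io_formats import (
    CodonAlignment,
    Phylogeny,
    check_tree_alignment_match,
    unroot_to_trichotomy,
)
from .site_models import ClassDistribution, SiteClassSpec, seed_from_null

DEFAULT_MISSING_BRANCH_LENGTH = 0.1

_LOG_KAPPA_BOUNDS = (math.log(0.05), math.log(50.0))
_LOG_SCALE_BOUNDS = (-6.0, 6.0)
_LOG_BRANCH_BOUNDS = (math.log(1e-6), math.log(30.0))


# ---------------------------------------------------------------------------
# Pruning engine


class PruningEngine:
    """Pattern-compressed pruning over a fixed (alignment, tree) pair."""

    def __init__(self, aln: CodonAlignment, tree: Phylogeny):
        check_tree_alignment_match(tree, aln)
        self.aln = aln
        self.code: GeneticCode = aln.code
        self.tree = tree
        n_states = self.code.n_states

        # --- compress columns to patterns
        state_sets = aln.state_sets()  # taxon -> site -> list of states
        n_sites = aln.n_sites
        keys = [
            tuple(tuple(state_sets[t][s]) for t in range(aln.n_taxa))
            for s in range(n_sites)
        ]
        pattern_index: dict[tuple, int] = {}
        site_to_pattern = np.empty(n_sites, dtype=np.int64)
        for s, key in enumerate(keys):
            if key not in pattern_index:
                pattern_index[key] = len(pattern_index)
            site_to_pattern[s] = pattern_index[key]
        n_pat = len(pattern_index)
        self.n_patterns = n_pat
        self.site_to_pattern = site_to_pattern
        self.pattern_counts = np.bincount(site_to_pattern, minlength=n_pat).astype(float)

        # --- per-taxon codes and ambiguity masks
        patterns = [None] * n_pat
        for key, idx in pattern_index.items():
            patterns[idx] = key
        taxon_of = {name: i for i, name in enumerate(aln.taxon_names)}
        self.leaf_codes = np.zeros((aln.n_taxa, n_pat), dtype=np.int64)
        self.leaf_masks: list[np.ndarray | None] = [None] * aln.n_taxa
        self.leaf_ambig_rows: list[np.ndarray | None] = [None] * aln.n_taxa
        for t in range(aln.n_taxa):
            ambig = []
            for p in range(n_pat):
                states = patterns[p][t]
                if len(states) == 1:
                    self.leaf_codes[t, p] = states[0]
                else:
                    self.leaf_codes[t, p] = 0
                    ambig.append(p)
            if ambig:
                mask = np.zeros((len(ambig), n_states))
                for row, p in enumerate(ambig):
                    mask[row, list(patterns[p][t])] = 1.0
                self.leaf_masks[t] = mask
                self.leaf_ambig_rows[t] = np.array(ambig, dtype=np.int64)

        # --- flatten the tree: postorder internal nodes, edge indices
        non_root = [n for n in tree.root.postorder() if n is not tree.root]
        edge_of = {id(n): e for e, n in enumerate(non_root)}
        self.n_edges = len(non_root)
        self.edge_lengths_template = np.array(
            [
                DEFAULT_MISSING_BRANCH_LENGTH if n.length is None else n.length
                for n in non_root
            ]
        )
        internal_slot: dict[int, int] = {}
        self.traversal: list[list[tuple[bool, int, int]]] = []
        for node in tree.root.postorder():
            if node.is_leaf:
                continue
            children = []
            for child in node.children:
                e = edge_of[id(child)]
                if child.is_leaf:
                    children.append((True, taxon_of[child.label], e))
                else:
                    children.append((False, internal_slot[id(child)], e))
            internal_slot[id(node)] = len(self.traversal)
            self.traversal.append(children)

    # -- core recursion -----------------------------------------------------

    def pattern_log_likelihoods(self, p_edges: np.ndarray, pi: np.ndarray) -> np.ndarray:
        """Per-pattern log-likelihood given transition matrices per edge."""
        n_pat = self.n_patterns
        parts: dict[int, np.ndarray] = {}
        logscale = np.zeros(n_pat)
        for slot, children in enumerate(self.traversal):
            f = None
            for is_leaf, idx, e in children:
                p = p_edges[e]
                if is_leaf:
                    contrib = p[:, self.leaf_codes[idx]].T
                    rows = self.leaf_ambig_rows[idx]
                    if rows is not None:
                        contrib = contrib.copy()
                        contrib[rows] = self.leaf_masks[idx] @ p.T
                else:
                    contrib = parts.pop(idx) @ p.T
                f = contrib if f is None else f * contrib
            m = f.max(axis=1)
            safe = np.where(m > 0, m, 1.0)
            f = f / safe[:, None]
            with np.errstate(divide="ignore"):
                logscale += np.where(m > 0, np.log(safe), -np.inf)
            parts[slot] = f
        root = parts[len(self.traversal) - 1]
        with np.errstate(divide="ignore"):
            return np.log(root @ pi) + logscale

    def expand(self, per_pattern: np.ndarray) -> np.ndarray:
        """Map a per-pattern array back to per-site order (axis 0)."""
        return per_pattern[self.site_to_pattern]


# ---------------------------------------------------------------------------
# Class matrices under the mixture normalization


def mixture_rate_normalizer(
    kappa: float, pi: np.ndarray, dist: ClassDistribution, code: GeneticCode
) -> float:
    """Mixture-average substitution rate of the unscaled class matrices."""
    struct = get_structure(code)
    mu_bar = 0.0
    for w, omega in zip(dist.proportions, dist.omegas):
        if w <= 0:
            continue
        qu = struct.unscaled_rates(kappa, omega, pi)
        mu_bar += w * float(pi @ qu.sum(axis=1))
    if mu_bar <= 0:
        raise ValidationError("mixture has zero average rate")
    return mu_bar


def _class_decompositions(kappa, pi, omegas, code, mu_bar):
    struct = get_structure(code)
    out = []
    for omega in omegas:
        q = struct.unscaled_rates(kappa, omega, pi) / mu_bar
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        out.append(decompose_rate_matrix(q, pi))
    return out


def class_pattern_logliks(
    engine: PruningEngine,
    kappa: float,
    pi: np.ndarray,
    omegas: np.ndarray,
    ts: np.ndarray,
    mu_bar: float,
) -> np.ndarray:
    """(n_patterns, n_classes) log-likelihood matrix at branch lengths ts."""
    cols = []
    for dec in _class_decompositions(kappa, pi, omegas, engine.code, mu_bar):
        p_edges = dec.transition_matrices(ts)
        cols.append(engine.pattern_log_likelihoods(p_edges, pi))
    return np.stack(cols, axis=1)


def conditional_site_likelihoods(
    aln: CodonAlignment,
    tree: Phylogeny,
    kappa: float,
    pi: np.ndarray,
    omegas,
    weights=None,
) -> np.ndarray:
    """Per-site, per-class conditional likelihoods P(column | omega_c).

    With ``weights`` given, class matrices share the mixture-average
    normalization; otherwise each class matrix is normalized to mean rate 1
    on its own. Entries are in (0, 1].
    """
    engine = PruningEngine(aln, tree)
    omegas = np.asarray(omegas, dtype=float)
    ts = engine.edge_lengths_template
    pi = np.asarray(pi, dtype=float)
    if weights is not None:
        dist = ClassDistribution(np.asarray(weights, float), omegas)
        mu_bar = mixture_rate_normalizer(kappa, pi, dist, aln.code)
        logl = class_pattern_logliks(engine, kappa, pi, omegas, ts, mu_bar)
    else:
        struct = get_structure(aln.code)
        cols = []
        for omega in omegas:
            qu = struct.unscaled_rates(kappa, omega, pi)
            mu = float(pi @ qu.sum(axis=1))
            logl_c = class_pattern_logliks(engine, kappa, pi, [omega], ts, mu)
            cols.append(logl_c[:, 0])
        logl = np.stack(cols, axis=1)
    return np.exp(engine.expand(logl))


# ---------------------------------------------------------------------------
# Mixture log-likelihood


def _mixture_lnl_from_logliks(
    logliks: np.ndarray, weights: np.ndarray, counts: np.ndarray
) -> tuple[float, np.ndarray]:
    active = weights > 0
    lw = np.log(weights[active])
    m = logliks[:, active] + lw[None, :]
    mx = m.max(axis=1)
    with np.errstate(invalid="ignore"):
        per_pattern = mx + np.log(np.exp(m - mx[:, None]).sum(axis=1))
    per_pattern = np.where(np.isfinite(mx), per_pattern, -np.inf)
    return float(per_pattern @ counts), per_pattern


def mixture_log_likelihood(
    aln: CodonAlignment,
    tree: Phylogeny,
    spec: SiteClassSpec,
    theta: dict[str, float],
    pi: np.ndarray | None = None,
    engine: PruningEngine | None = None,
) -> float:
    """lnL of a random-sites model at ``theta``.

    ``theta`` holds the model parameters plus ``kappa`` and optionally
    ``scale`` (a multiplier on the tree's branch lengths, default 1).
    """
    engine = engine or PruningEngine(aln, tree)
    if pi is None:
        pi = estimate_codon_frequencies(aln, "F3x4")
    kappa = float(theta["kappa"])
    scale = float(theta.get("scale", 1.0))
    dist = spec.class_distribution(theta)
    mu_bar = mixture_rate_normalizer(kappa, pi, dist, engine.code)
    ts = engine.edge_lengths_template * scale
    active = dist.proportions > 0
    logl = class_pattern_logliks(engine, kappa, pi, dist.omegas[active], ts, mu_bar)
    lw = np.log(dist.proportions[active])
    m = logl + lw[None, :]
    mx = m.max(axis=1)
    per_pattern = mx + np.log(np.exp(m - mx[:, None]).sum(axis=1))
    if not np.isfinite(per_pattern).all():
        bad = engine.expand(per_pattern)
        sites = np.where(~np.isfinite(bad))[0] + 1
        raise ValidationError(f"zero likelihood at codon site(s) {sites.tolist()}")
    return float(per_pattern @ engine.pattern_counts)


def site_class_logliks(
    aln: CodonAlignment,
    tree: Phylogeny,
    spec: SiteClassSpec,
    theta: dict[str, float],
    pi: np.ndarray,
    engine: PruningEngine | None = None,
) -> tuple[np.ndarray, ClassDistribution]:
    """Per-site (not pattern) log-likelihoods for every class at ``theta``."""
    engine = engine or PruningEngine(aln, tree)
    kappa = float(theta["kappa"])
    scale = float(theta.get("scale", 1.0))
    dist = spec.class_distribution(theta)
    mu_bar = mixture_rate_normalizer(kappa, pi, dist, engine.code)
    ts = engine.edge_lengths_template * scale
    logl = class_pattern_logliks(engine, kappa, pi, dist.omegas, ts, mu_bar)
    return engine.expand(logl), dist


# ---------------------------------------------------------------------------
# Omega surface (grid-accelerated inner optimization)


@dataclass
class OmegaSurface:
    """Per-pattern log-likelihood surface over (omega, branch multiplier).

    The surface is computed with *unnormalized* class matrices; a mixture
    evaluation at parameters theta corresponds to querying multiplier
    v = scale / mu_bar(theta), so one surface serves every beta-mixture
    model at a fixed kappa.
    """

    omega_grid: np.ndarray
    v_grid: np.ndarray
    logliks: np.ndarray  # (n_pat, n_omega, n_v)
    kappa: float

    def query(self, omegas: np.ndarray, v: float) -> np.ndarray:
        """Bilinear interpolation -> (n_pat, n_classes) log-likelihoods."""
        og, vg = self.omega_grid, self.v_grid
        omegas = np.clip(omegas, og[0], og[-1])
        v = float(np.clip(v, vg[0], vg[-1]))
        iw = np.clip(np.searchsorted(og, omegas) - 1, 0, len(og) - 2)
        fw = (omegas - og[iw]) / (og[iw + 1] - og[iw])
        jv = int(np.clip(np.searchsorted(vg, v) - 1, 0, len(vg) - 2))
        fv = (math.log(v) - math.log(vg[jv])) / (
            math.log(vg[jv + 1]) - math.log(vg[jv])
        )
        a = self.logliks[:, iw, jv] * (1 - fw) + self.logliks[:, iw + 1, jv] * fw
        b = self.logliks[:, iw, jv + 1] * (1 - fw) + self.logliks[:, iw + 1, jv + 1] * fw
        return a * (1 - fv) + b * fv


def _default_omega_grid() -> np.ndarray:
    low = np.concatenate([[1e-8], np.geomspace(1e-4, 1.0, 26)])
    high = np.concatenate([np.linspace(1.25, 8.0, 12), [10.0, 13.0, 17.0, 22.0]])
    return np.concatenate([low, high])


def build_omega_surface(
    engine: PruningEngine,
    kappa: float,
    pi: np.ndarray,
    ts: np.ndarray,
    v_center: float,
    omega_grid: np.ndarray | None = None,
    v_span: tuple[float, float, int] = (0.45, 2.3, 6),
) -> OmegaSurface:
    omega_grid = _default_omega_grid() if omega_grid is None else omega_grid
    v_grid = v_center * np.geomspace(v_span[0], v_span[1], v_span[2])
    struct = get_structure(engine.code)
    n_pat = engine.n_patterns
    logl = np.empty((n_pat, len(omega_grid), len(v_grid)))
    for i, omega in enumerate(omega_grid):
        qu = struct.unscaled_rates(kappa, omega, pi)
        np.fill_diagonal(qu, 0.0)
        np.fill_diagonal(qu, -qu.sum(axis=1))
        dec = decompose_rate_matrix(qu, pi)
        for j, v in enumerate(v_grid):
            p_edges = dec.transition_matrices(ts * v)
            logl[:, i, j] = engine.pattern_log_likelihoods(p_edges, pi)
    return OmegaSurface(omega_grid=omega_grid, v_grid=v_grid, logliks=logl, kappa=kappa)


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class FitResult:
    """A fitted random-sites model (one row of a Table-4/5-style summary).

    ``np`` counts free parameters the codeml way: (2*n_tips - 3) branch
    lengths + kappa + the model's own parameters, regardless of how the
    branch lengths were handled in this fit.
    """

    model_name: str
    lnL: float
    np: int
    theta_hat: dict[str, float]
    class_distribution: ClassDistribution
    branch_lengths_hat: np.ndarray
    starts_used: list[tuple[dict[str, float], float]]
    converged: bool
    message: str = ""
    pi: np.ndarray | None = None
    spec: SiteClassSpec | None = None

    def summary_parameters(self) -> dict[str, float]:
        out = dict(self.theta_hat)
        return out


def _pack(spec, theta, branch_mode, n_edges):
    z = list(spec.to_unconstrained(theta))
    z.append(math.log(theta.get("kappa", 2.0)))
    if branch_mode == "scale":
        z.append(math.log(theta.get("scale", 1.0)))
    return np.array(z)


def _unpack(spec, z, branch_mode):
    theta = spec.from_unconstrained(np.asarray(z[: spec.n_free_params]))
    theta["kappa"] = float(np.exp(np.clip(z[spec.n_free_params], *_LOG_KAPPA_BOUNDS)))
    if branch_mode == "scale":
        theta["scale"] = float(
            np.exp(np.clip(z[spec.n_free_params + 1], *_LOG_SCALE_BOUNDS))
        )
    return theta


def _exact_objective(engine, spec, pi, branch_mode, base_ts):
    code = engine.code
    counts = engine.pattern_counts

    def fun(z):
        theta = _unpack(spec, z, branch_mode)
        if branch_mode == "full":
            ts = np.exp(np.clip(z[spec.n_free_params + 1 :], *_LOG_BRANCH_BOUNDS))
            scale = 1.0
        else:
            ts = base_ts
            scale = theta.get("scale", 1.0)
        dist = spec.class_distribution(theta)
        try:
            mu_bar = mixture_rate_normalizer(theta["kappa"], pi, dist, code)
        except ValidationError:
            return 1e12
        active = dist.proportions > 0
        logl = class_pattern_logliks(
            engine, theta["kappa"], pi, dist.omegas[active], ts * scale, mu_bar
        )
        lnl, _ = _mixture_lnl_from_logliks(
            logl, dist.proportions[active] / dist.proportions[active].sum(), counts
        )
        if not np.isfinite(lnl):
            return 1e12
        return -lnl

    return fun


def fit_site_model(
    aln: CodonAlignment,
    tree: Phylogeny,
    spec: SiteClassSpec,
    starts: list[dict[str, float]] | None = None,
    seed: int = 0,
    pi: np.ndarray | None = None,
    freq_scheme: str = "F3x4",
    branch_mode: str = "scale",
    strategy: str = "auto",
    null_fits: list[FitResult] | None = None,
    surface: OmegaSurface | None = None,
    max_iter: int = 500,
    ftol: float = 1e-8,
) -> FitResult:
    """Fit one random-sites model by maximum likelihood.

    ``branch_mode``: ``"fixed"`` uses the input tree's lengths as given,
    ``"scale"`` (default) adds one free multiplier on all of them, and
    ``"full"`` frees every branch length (initialized from the tree, or
    0.1 where absent). ``null_fits`` supplies fitted nested nulls whose
    optima are added as extra starting points, which guarantees
    lnL(alternative) >= lnL(null) - 1e-4.

    Deterministic given the starts; ``seed`` controls only optional
    start-jitter (none by default).
    """
    del seed  # reserved for stochastic restart jitter; fits are deterministic
    tree = unroot_to_trichotomy(tree)
    engine = PruningEngine(aln, tree)
    if pi is None:
        pi = estimate_codon_frequencies(aln, freq_scheme)
    pi = np.asarray(pi, dtype=float)
    if branch_mode not in ("fixed", "scale", "full"):
        raise ValidationError(f"unknown branch_mode {branch_mode!r}")
    if strategy == "auto":
        strategy = "grid" if spec.name in ("M7", "M8", "M8a") else "exact"

    base_ts = engine.edge_lengths_template
    kappa_default, scale_default = 2.0, 1.0
    if null_fits:
        kappa_default = null_fits[0].theta_hat.get("kappa", 2.0)
        scale_default = null_fits[0].theta_hat.get("scale", 1.0)
    start_list: list[dict[str, float]] = []
    for s in starts if starts is not None else spec.default_starts():
        s = dict(s)
        s.setdefault("kappa", kappa_default)
        s.setdefault("scale", scale_default)
        start_list.append(s)
    for null_fit in null_fits or []:
        seeded = seed_from_null(spec, null_fit.model_name, null_fit.theta_hat)
        if seeded is not None:
            seeded["kappa"] = null_fit.theta_hat.get("kappa", kappa_default)
            seeded["scale"] = null_fit.theta_hat.get("scale", scale_default)
            start_list.append(seeded)
    if not start_list:
        raise ValidationError("no starting points")

    exact_fun = _exact_objective(engine, spec, pi, branch_mode, base_ts)
    n_extra = 1 + (1 if branch_mode == "scale" else 0)
    bounds_head = [(-14.0, 14.0)] * spec.n_free_params + [_LOG_KAPPA_BOUNDS]
    if branch_mode == "scale":
        bounds_head.append(_LOG_SCALE_BOUNDS)

    candidates: list[tuple[np.ndarray, dict]] = []
    starts_used: list[tuple[dict[str, float], float]] = []
    any_converged = False

    if strategy == "grid" and branch_mode != "full":
        # fix kappa at the best available estimate, search on the surface
        kappa0 = kappa_default
        if surface is None or abs(surface.kappa - kappa0) > 1e-9:
            dist0 = spec.class_distribution(start_list[0])
            mu0 = mixture_rate_normalizer(kappa0, pi, dist0, engine.code)
            surface = build_omega_surface(engine, kappa0, pi, base_ts, 1.0 / mu0)
        counts = engine.pattern_counts

        def grid_fun(zv):
            theta = spec.from_unconstrained(zv[:-1])
            v = math.exp(np.clip(zv[-1], -14, 14))
            try:
                dist = spec.class_distribution(theta)
            except ValidationError:
                return 1e12
            active = dist.proportions > 0
            logl = surface.query(dist.omegas[active], v)
            lnl, _ = _mixture_lnl_from_logliks(
                logl, dist.proportions[active] / dist.proportions[active].sum(), counts
            )
            return -lnl if np.isfinite(lnl) else 1e12

        vg_bounds = (
            math.log(surface.v_grid[0]) + 1e-9,
            math.log(surface.v_grid[-1]) - 1e-9,
        )
        for s in start_list:
            dist_s = spec.class_distribution(s)
            mu_s = mixture_rate_normalizer(s["kappa"], pi, dist_s, engine.code)
            v0 = np.clip(
                s.get("scale", 1.0) / mu_s,
                surface.v_grid[0] * 1.0001,
                surface.v_grid[-1] * 0.9999,
            )
            z0 = np.concatenate([spec.to_unconstrained(s), [math.log(v0)]])
            res = minimize(
                grid_fun,
                z0,
                method="L-BFGS-B",
                bounds=[(-14.0, 14.0)] * spec.n_free_params + [vg_bounds],
                options={"maxiter": 300, "ftol": 1e-10},
            )
            theta_g = spec.from_unconstrained(res.x[:-1])
            v_g = math.exp(res.x[-1])
            mu_g = mixture_rate_normalizer(
                kappa0, pi, spec.class_distribution(theta_g), engine.code
            )
            theta_g["kappa"] = kappa0
            theta_g["scale"] = v_g * mu_g
            z_exact = _pack(spec, theta_g, branch_mode, engine.n_edges)
            candidates.append((z_exact, {"start": s}))
            starts_used.append((s, -res.fun))
        # the raw seeds are candidates too (protects the nesting guarantee)
        for s in start_list:
            candidates.append((_pack(spec, s, branch_mode, engine.n_edges), {"start": s}))
    else:
        for s in start_list:
            z0 = _pack(spec, s, branch_mode, engine.n_edges)
            if branch_mode == "full":
                z0 = np.concatenate([z0, np.log(np.maximum(base_ts, 1e-6))])
            candidates.append((z0, {"start": s}))

    bounds = list(bounds_head)
    if branch_mode == "full":
        bounds = bounds + [_LOG_BRANCH_BOUNDS] * engine.n_edges

    best = None
    if strategy == "grid" and branch_mode != "full":
        # exact-evaluate every candidate once, polish only the best
        scored = [(exact_fun(z0), z0) for z0, _ in candidates]
        scored.sort(key=lambda t: t[0])
        res = minimize(
            exact_fun,
            scored[0][1],
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 60, "ftol": ftol},
        )
        any_converged = bool(res.success)
        best = min((res.fun, res.x), scored[0], key=lambda t: t[0])
        best = (best[0], np.asarray(best[1]))
    else:
        for z0, meta in candidates:
            res = minimize(
                exact_fun,
                z0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": max_iter, "ftol": ftol},
            )
            any_converged = any_converged or bool(res.success)
            starts_used.append((meta["start"], -res.fun))
            if best is None or res.fun < best[0]:
                best = (res.fun, res.x)
    neg_lnl, z_hat = best

    theta_hat = _unpack(spec, z_hat, branch_mode)
    if branch_mode == "full":
        ts_hat = np.exp(np.clip(z_hat[spec.n_free_params + 1 :], *_LOG_BRANCH_BOUNDS))
    else:
        ts_hat = base_ts * theta_hat.get("scale", 1.0)
    lnl = -float(exact_fun(z_hat))
    dist = spec.class_distribution(theta_hat)
    n_params = (2 * aln.n_taxa - 3) + 1 + spec.n_free_params
    result = FitResult(
        model_name=spec.name,
        lnL=lnl,
        np=n_params,
        theta_hat=theta_hat,
        class_distribution=dist,
        branch_lengths_hat=ts_hat,
        starts_used=starts_used,
        converged=any_converged,
        message="" if any_converged else "optimizer reported non-convergence at every start",
        pi=pi,
        spec=spec,
    )
    if not any_converged and lnl <= -1e11:
        raise ConvergenceError(f"{spec.name}: optimization failed at every start")
    return result


def fit_model_series(
    aln: CodonAlignment,
    tree: Phylogeny,
    specs: list[SiteClassSpec],
    pi: np.ndarray | None = None,
    freq_scheme: str = "F3x4",
    branch_mode: str = "scale",
    starts: dict[str, list[dict[str, float]]] | None = None,
    seed: int = 0,
    max_iter: int = 500,
) -> dict[str, FitResult]:
    """Fit several models on the same data, seeding alternatives with their
    nested nulls' optima and sharing the beta-model likelihood surface."""
    if pi is None:
        pi = estimate_codon_frequencies(aln, freq_scheme)
    tree = unroot_to_trichotomy(tree)
    fits: dict[str, FitResult] = {}
    surface_box: dict[str, OmegaSurface] = {}
    order = {name: i for i, name in enumerate(["M0", "M1a", "M2a", "M2a_rel", "M3", "M7", "M8a", "M8"])}
    for spec in sorted(specs, key=lambda s: order.get(s.name, 99)):
        nulls = [fits[n] for n in spec.df_against if n in fits]
        if spec.name in ("M8", "M8a") and "M7" in fits and "M7" not in spec.df_against:
            nulls.append(fits["M7"])
        kwargs = {}
        if spec.name in ("M7", "M8", "M8a"):
            kwargs["surface"] = surface_box.get("surface")
        fit = fit_site_model(
            aln,
            tree,
            spec,
            starts=(starts or {}).get(spec.name),
            seed=seed,
            pi=pi,
            branch_mode=branch_mode,
            null_fits=nulls or ([fits["M0"]] if "M0" in fits else None),
            max_iter=max_iter,
            **kwargs,
        )
        fits[spec.name] = fit
        # build/share the beta surface lazily at the kappa used by M7-family
        if spec.name in ("M7", "M8a", "M8") and "surface" not in surface_box:
            engine = PruningEngine(aln, tree)
            dist = fit.class_distribution
            mu = mixture_rate_normalizer(fit.theta_hat["kappa"], pi, dist, aln.code)
            surface_box["surface"] = build_omega_surface(
                engine,
                fit.theta_hat["kappa"],
                pi,
                engine.edge_lengths_template,
                fit.theta_hat.get("scale", 1.0) / mu,
            )
    return fits
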