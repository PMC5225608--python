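"""Maximum-likelihood fitting of GY94 codon model families.

Families
--------
``one-ratio``
    A single dN/dS ratio for the whole tree (M0).
``two-ratio``
    One dN/dS per branch class (e.g. whale vs non-whale branches).
``M1``
    Neutral site mixture: a class with omega0 <= 1 and a class with omega = 1.
``M2``
    Selection site mixture: M1 plus a class with omega2 >= 1.
``branch-site`` / ``branch-site-null``
    Branch-site model A: the positively selected class applies only on
    foreground branches; the null fixes omega2 = 1.

Parameters are optimized on transformed scales (log kappa, log omega,
stick-breaking logits for mixture proportions) with bounded quasi-Newton
iterations and jittered restarts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.special

from .alignment import CodonAlignment
from .likelihood import PruningEngine, codon_frequencies
from .phylo import Phylogeny

FAMILIES = (
    "one-ratio",
    "two-ratio",
    "M1",
    "M2",
    "branch-site",
    "branch-site-null",
)
MIXTURE_FAMILIES = ("M1", "M2", "branch-site", "branch-site-null")

_LOG_K_BOUNDS = (np.log(0.02), np.log(100.0))
_LOG_W_BOUNDS = (np.log(1e-4), np.log(999.0))
_LOG_W0_BOUNDS = (np.log(1e-4), 0.0)  # omega0 <= 1
_LOG_W2_BOUNDS = (0.0, np.log(999.0))  # omega2 >= 1
_LOGIT_BOUNDS = (-15.0, 15.0)
_LOG_T_BOUNDS = (np.log(1e-7), np.log(20.0))


def _sigmoid(x: float) -> float:
    return float(scipy.special.expit(x))


@dataclass
class SitePosterior:
    """Naive-empirical-Bayes class membership probabilities per codon site."""

    probs: np.ndarray  # (n_sites, n_classes)
    class_labels: tuple[str, ...]

    def argmax(self) -> np.ndarray:
        return self.probs.argmax(axis=1)


@dataclass
class FitResult:
    """A fitted codon model and its optimizer diagnostics."""

    family: str
    lnL: float
    kappa: float
    site_classes: list[tuple[float, dict[int, float]]]
    proportions: tuple[float, ...]
    omegas: dict[str, float]
    pi: np.ndarray
    tree: Phylogeny
    converged: bool
    n_iter: int
    n_restarts: int
    foreground_class: int | None = None
    theta: np.ndarray | None = None
    n_sites: int = 0

    @property
    def n_params(self) -> int:
        return 0 if self.theta is None else len(self.theta)

    def summary(self, gene: str = "") -> dict:
        """Flat record following the published site-model table layout."""
        rec: dict[str, object] = {"gene": gene, "length_nt": self.n_sites * 3}
        for i, p in enumerate(self.proportions):
            rec[f"p{i}"] = round(p, 4)
        rec.update({k: round(v, 4) for k, v in self.omegas.items()})
        rec["lnL"] = round(self.lnL, 2)
        rec["model"] = self.family
        rec["converged"] = self.converged
        return rec


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# family parameterizations
# ---------------------------------------------------------------------------

def _branch_classes(tree: Phylogeny) -> list[int]:
    return sorted({e.cls for e in tree.edges()})


def _family_layout(family: str, tree: Phylogeny, foreground_class: int):
    """Return (theta0, bounds, unpack) for one family.

    ``unpack(theta)`` yields ``(kappa, site_classes, proportions, omegas)``
    where ``site_classes`` is a list of (weight, omega-by-branch-class).
    """
    bcls = _branch_classes(tree)

    if family == "one-ratio":
        theta0 = np.array([np.log(2.0), np.log(0.3)])
        bounds = [_LOG_K_BOUNDS, _LOG_W_BOUNDS]

        def unpack(th):
            k, w = np.exp(th[0]), np.exp(th[1])
            return k, [(1.0, {b: w for b in bcls})], (1.0,), {"omega": w}

    elif family == "two-ratio":
        if len(bcls) < 2:
            raise ModelError("two-ratio model needs >=2 branch classes on the tree")
        theta0 = np.array([np.log(2.0)] + [np.log(0.3)] * len(bcls))
        bounds = [_LOG_K_BOUNDS] + [_LOG_W_BOUNDS] * len(bcls)

        def unpack(th):
            k = np.exp(th[0])
            ws = {b: float(np.exp(th[1 + i])) for i, b in enumerate(bcls)}
            omegas = {f"omega_class{b}": ws[b] for b in bcls}
            return k, [(1.0, ws)], (1.0,), omegas

    elif family == "M1":
        theta0 = np.array([np.log(2.0), np.log(0.1), 1.0])
        bounds = [_LOG_K_BOUNDS, _LOG_W0_BOUNDS, _LOGIT_BOUNDS]

        def unpack(th):
            k, w0 = np.exp(th[0]), np.exp(th[1])
            p0 = _sigmoid(th[2])
            classes = [
                (p0, {b: w0 for b in bcls}),
                (1.0 - p0, {b: 1.0 for b in bcls}),
            ]
            return k, classes, (p0, 1.0 - p0), {"omega0": w0}

    elif family == "M2":
        theta0 = np.array([np.log(2.0), np.log(0.1), np.log(3.0), 1.5, 2.0])
        bounds = [
            _LOG_K_BOUNDS,
            _LOG_W0_BOUNDS,
            _LOG_W2_BOUNDS,
            _LOGIT_BOUNDS,
            _LOGIT_BOUNDS,
        ]

        def unpack(th):
            k, w0, w2 = np.exp(th[0]), np.exp(th[1]), np.exp(th[2])
            p0 = _sigmoid(th[3])
            p1 = (1.0 - p0) * _sigmoid(th[4])
            p2 = 1.0 - p0 - p1
            classes = [
                (p0, {b: w0 for b in bcls}),
                (p1, {b: 1.0 for b in bcls}),
                (p2, {b: w2 for b in bcls}),
            ]
            return k, classes, (p0, p1, p2), {"omega0": w0, "omega2": w2}

    elif family in ("branch-site", "branch-site-null"):
        fg = foreground_class
        if fg not in bcls:
            raise ModelError(
                f"foreground branch class {fg} is not present on the tree"
            )
        est_w2 = family == "branch-site"
        theta0 = [np.log(2.0), np.log(0.1)]
        bounds = [_LOG_K_BOUNDS, _LOG_W0_BOUNDS]
        if est_w2:
            theta0.append(np.log(3.0))
            bounds.append(_LOG_W2_BOUNDS)
        theta0 += [1.5, 1.0]
        bounds += [_LOGIT_BOUNDS, _LOGIT_BOUNDS]
        theta0 = np.array(theta0)

        def unpack(th):
            k, w0 = np.exp(th[0]), np.exp(th[1])
            if est_w2:
                w2 = float(np.exp(th[2]))
                a, b = th[3], th[4]
            else:
                w2 = 1.0
                a, b = th[2], th[3]
            q = _sigmoid(a)  # total weight of classes 0 and 1
            r = _sigmoid(b)  # split between the omega0-track and the 1-track
            p0, p1 = q * r, q * (1.0 - r)
            p2a, p2b = (1.0 - q) * r, (1.0 - q) * (1.0 - r)
            bg = {b_: w0 for b_ in bcls}
            classes = [
                (p0, dict(bg)),
                (p1, {b_: 1.0 for b_ in bcls}),
                (p2a, {b_: (w2 if b_ == fg else w0) for b_ in bcls}),
                (p2b, {b_: (w2 if b_ == fg else 1.0) for b_ in bcls}),
            ]
            omegas = {"omega0": w0, "omega2": w2}
            return k, classes, (p0, p1, p2a, p2b), omegas

    else:
        raise ModelError(f"unknown model family '{family}'")

    return theta0, bounds, unpack


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def log_likelihood(
    alignment: CodonAlignment,
    tree: Phylogeny,
    *,
    kappa: float,
    site_classes: list[tuple[float, dict[int, float]]],
    pi: np.ndarray,
) -> float:
    """Fixed-parameter mixture log-likelihood (spec'd model evaluation)."""
    engine = PruningEngine(alignment, tree, pi)
    return engine.mixture_log_likelihood(kappa, site_classes)


def fit_model(
    alignment: CodonAlignment,
    tree: Phylogeny,
    family: str,
    *,
    foreground_class: int = 1,
    freq: str = "F3x4",
    pi: np.ndarray | None = None,
    estimate_branch_lengths: bool = False,
    n_restarts: int = 3,
    seed: int = 0,
    max_iter: int = 500,
) -> FitResult:
    """Fit one model family by bounded quasi-Newton with jittered restarts.

    Branch lengths are taken from the tree unless
    ``estimate_branch_lengths=True`` (one-ratio only), in which case they are
    optimized jointly and written to the returned result's tree — the usual
    first step before site/branch-site/per-site fits.
    """
    if family not in FAMILIES:
        raise ModelError(f"unknown model family '{family}'")
    if estimate_branch_lengths and family != "one-ratio":
        raise ModelError(
            "branch lengths are estimated under the one-ratio model and "
            "then held fixed for other families"
        )
    tree = tree.copy()
    if pi is None:
        pi = codon_frequencies(alignment, freq)
    engine = PruningEngine(alignment, tree, pi)
    theta0, bounds, unpack = _family_layout(family, tree, foreground_class)

    edges = tree.edges()
    n_model = len(theta0)
    if estimate_branch_lengths:
        t0 = np.log(np.clip([e.length for e in edges], 1e-6, None))
        theta0 = np.concatenate([theta0, t0])
        bounds = bounds + [_LOG_T_BOUNDS] * len(edges)

    def apply_lengths(th: np.ndarray) -> None:
        if estimate_branch_lengths:
            for e, logt in zip(edges, th[n_model:]):
                e.length = float(np.exp(logt))

    # per-class conditional likelihood vectors depend only on (kappa, omega
    # map); memoizing them makes finite-difference gradients cheap, since a
    # single-parameter perturbation leaves most classes untouched
    from .likelihood import edge_transition_matrices  # local to avoid cycle

    cache: dict[tuple, np.ndarray] = {}

    def class_loglik(kappa: float, omega_map: dict[int, float]) -> np.ndarray:
        key = (kappa, tuple(sorted(omega_map.items())))
        hit = cache.get(key)
        if hit is None:
            if len(cache) > 256:
                cache.clear()
            P = edge_transition_matrices(tree, kappa, omega_map, pi)
            hit = cache[key] = engine.pattern_log_likelihoods(P)
        return hit

    def neg_ll(th: np.ndarray) -> float:
        if estimate_branch_lengths:
            cache.clear()
            apply_lengths(th)
        kappa, classes, _, _ = unpack(th[:n_model])
        cond = np.stack([class_loglik(kappa, m) for _, m in classes])
        w = np.array([max(wc, 0.0) for wc, _ in classes])
        with np.errstate(divide="ignore"):
            logw = np.where(w > 0, np.log(np.maximum(w, 1e-300)), -np.inf)
        site_log = scipy.special.logsumexp(cond + logw[:, None], axis=0)
        ll = float(engine.weights @ site_log)
        if not np.isfinite(ll):
            return 1e10
        return -ll

    rng = np.random.default_rng(seed)
    best = None
    total_iters = 0
    any_converged = False
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    for r in range(max(1, n_restarts)):
        x0 = theta0 if r == 0 else np.clip(
            theta0 + rng.normal(scale=0.75, size=len(theta0)), lo, hi
        )
        res = scipy.optimize.minimize(
            neg_ll,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-6},
        )
        total_iters += int(res.nit)
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun - 0.0:
            best = res

    assert best is not None
    # derivative-free polish: finite-difference gradients bottom out on
    # near-flat boundary ridges (e.g. omega2 -> 1 with p2 -> 0), which can
    # leave nested fits a few 1e-6 apart
    if not estimate_branch_lengths and n_model >= 4:
        polish = scipy.optimize.minimize(
            lambda th: neg_ll(np.clip(th, lo, hi)),
            best.x,
            method="Nelder-Mead",
            options={"maxfev": 100 * n_model, "fatol": 1e-10, "xatol": 1e-8},
        )
        if polish.fun < best.fun:
            polish.x = np.clip(polish.x, lo, hi)
            polish.nit = best.nit
            best = polish
    apply_lengths(best.x)
    kappa, classes, proportions, omegas = unpack(best.x[:n_model])
    return FitResult(
        family=family,
        lnL=-float(best.fun),
        kappa=float(kappa),
        site_classes=classes,
        proportions=tuple(float(p) for p in proportions),
        omegas={k: float(v) for k, v in omegas.items()},
        pi=pi,
        tree=tree,
        converged=any_converged,
        n_iter=total_iters,
        n_restarts=max(1, n_restarts),
        foreground_class=foreground_class if family.startswith("branch-site") else None,
        theta=best.x.copy(),
        n_sites=alignment.n_sites,
    )


def site_class_posteriors(
    fit: FitResult,
    alignment: CodonAlignment,
    tree: Phylogeny | None = None,
) -> SitePosterior:
    """Per-site NEB posterior class memberships under a fitted mixture.

    Classes with zero mixture weight get exactly zero posterior everywhere.
    """
    if fit.family not in MIXTURE_FAMILIES:
        raise ModelError(
            f"site-class posteriors require a mixture family, not '{fit.family}'"
        )
    tree = tree or fit.tree
    engine = PruningEngine(alignment, tree, fit.pi)
    cond = engine.class_pattern_log_likelihoods(fit.kappa, fit.site_classes)
    w = np.array([max(p, 0.0) for p, _ in fit.site_classes])
    with np.errstate(divide="ignore"):
        logw = np.where(w > 0, np.log(np.maximum(w, 1e-300)), -np.inf)
    joint = cond + logw[:, None]
    norm = scipy.special.logsumexp(joint, axis=0)
    post = np.exp(joint - norm[None, :])
    post[w == 0.0, :] = 0.0
    post /= post.sum(axis=0, keepdims=True)
    labels = tuple(f"class{i}" for i in range(len(fit.site_classes)))
    return SitePosterior(engine.expand(post).T, labels)
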