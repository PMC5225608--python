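"""Mixed-effects episodic selection scan (MEME-style).

Each codon site gets its own synonymous rate alpha (shared by all branches)
and a two-point mixture for the nonsynonymous rate: a constrained component
beta- <= alpha with weight p-, and an unconstrained component beta+.  Branch
assignments are independent across branches, so the site likelihood uses the
branch-averaged propagator  p- * P_{beta-}(t) + (1 - p-) * P_{beta+}(t)
inside pruning, which is exact under the model.  The null constrains
beta+ <= alpha; the per-site statistic 2*dL is referred to a chi-square with
2 df, an upper bound on significance (the asymptotic null is a mixture, so
this is conservative).  Per-branch empirical Bayes factors compare the site
likelihood with that branch clamped to beta+ versus clamped to beta-.

Branch lengths, kappa and codon frequencies are fixed from a baseline
(one-ratio) fit, so they are in units of expected substitutions per codon at
alpha = beta = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.special
import scipy.stats

from .alignment import MISSING, CodonAlignment
from .likelihood import (
    PruningEngine,
    eig_rate_matrix,
    syn_nonsyn_parts,
    transition_probabilities,
)
from .models import FitResult
from .phylo import Phylogeny

_LOGIT_BOUNDS = (-12.0, 12.0)
_LOG_RATE_BOUNDS = (np.log(1e-4), np.log(999.0))


@dataclass
class SiteSelectionResult:
    site: int  # 1-based codon position
    alpha: float
    beta_minus: float
    beta_plus: float
    p_minus: float
    statistic: float
    p_value: float
    bayes_factors: dict[str, float] = field(default_factory=dict)
    testable: bool = True

    def top_branches(self, k: int = 3) -> list[tuple[str, float]]:
        return sorted(self.bayes_factors.items(), key=lambda kv: -kv[1])[:k]


def _site_generator(alpha: float, beta: float, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    Q = alpha * A + beta * B
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


class _SiteModel:
    """Likelihood machinery for one codon column."""

    def __init__(
        self,
        column: np.ndarray,
        names: tuple[str, ...],
        tree: Phylogeny,
        pi: np.ndarray,
        A: np.ndarray,
        B: np.ndarray,
    ):
        aln = CodonAlignment(names, column.reshape(-1, 1).astype(np.int16))
        self.engine = PruningEngine(aln, tree, pi)
        self.tree = tree
        self.pi = pi
        self.A, self.B = A, B
        self._cache: dict[tuple[float, float], dict[int, np.ndarray]] = {}

    def _propagators(self, alpha: float, beta: float) -> dict[int, np.ndarray]:
        key = (alpha, beta)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        if len(self._cache) > 128:
            self._cache.clear()
        Q = _site_generator(alpha, beta, self.A, self.B)
        eig = eig_rate_matrix(Q, self.pi)
        out = {}
        for e in self.tree.edges():
            out[e.index] = transition_probabilities(Q, e.length, eig=eig)
        self._cache[key] = out
        return out

    def log_likelihood(
        self,
        alpha: float,
        beta_minus: float,
        beta_plus: float,
        p_minus: float,
        clamp: dict[int, str] | None = None,
    ) -> float:
        """Branch-averaged mixture likelihood; ``clamp`` pins named edges
        (by node index) to 'plus' or 'minus'."""
        Pm = self._propagators(alpha, beta_minus)
        if beta_plus == beta_minus:
            Pp = Pm
        else:
            Pp = self._propagators(alpha, beta_plus)
        mix = {}
        for e in self.tree.edges():
            kind = (clamp or {}).get(e.index)
            if kind == "plus":
                mix[e.index] = Pp[e.index]
            elif kind == "minus":
                mix[e.index] = Pm[e.index]
            else:
                mix[e.index] = p_minus * Pm[e.index] + (1.0 - p_minus) * Pp[e.index]
        return float(self.engine.pattern_log_likelihoods(mix)[0])


def _fit(site: _SiteModel, null: bool, x0: np.ndarray | None = None):
    """Optimize (alpha, beta-, beta+, p-); the null caps beta+ at alpha."""

    def unpack(th):
        alpha = float(np.exp(th[0]))
        bm = alpha * float(scipy.special.expit(th[1]))
        if null:
            bp = alpha * float(scipy.special.expit(th[2]))
        else:
            bp = float(np.exp(th[2]))
        pm = float(scipy.special.expit(th[3]))
        return alpha, bm, bp, pm

    def neg(th):
        ll = site.log_likelihood(*unpack(th))
        return -ll if np.isfinite(ll) else 1e10

    starts = [np.array([0.0, 2.0, (2.0 if null else np.log(2.0)), 1.5])]
    if x0 is not None:
        starts.insert(0, x0)
    bounds = [
        _LOG_RATE_BOUNDS,
        _LOGIT_BOUNDS,
        (_LOGIT_BOUNDS if null else _LOG_RATE_BOUNDS),
        _LOGIT_BOUNDS,
    ]
    best = None
    for s0 in starts:
        res = scipy.optimize.minimize(
            neg,
            np.clip(s0, [b[0] for b in bounds], [b[1] for b in bounds]),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 200, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best, unpack(best.x)


def meme_scan(
    alignment: CodonAlignment,
    tree: Phylogeny,
    baseline: FitResult,
    *,
    sites: list[int] | None = None,
) -> list[SiteSelectionResult]:
    """Per-codon episodic selection test over ``sites`` (1-based; default all).

    Uses the baseline fit's kappa, codon frequencies and branch lengths
    (held fixed).  Sites with no observed codons are flagged untestable.
    """
    pi = baseline.pi
    A, B = syn_nonsyn_parts(baseline.kappa, pi)
    tree = baseline.tree if tree is None else tree
    site_list = sites or list(range(1, alignment.n_sites + 1))
    results: list[SiteSelectionResult] = []
    for s in site_list:
        column = alignment.matrix[:, s - 1]
        if np.all(column == MISSING):
            results.append(
                SiteSelectionResult(
                    site=s,
                    alpha=float("nan"),
                    beta_minus=float("nan"),
                    beta_plus=float("nan"),
                    p_minus=float("nan"),
                    statistic=float("nan"),
                    p_value=float("nan"),
                    testable=False,
                )
            )
            continue
        model = _SiteModel(column, alignment.names, tree, pi, A, B)
        null_res, (na, nbm, nbp, npm) = _fit(model, null=True)
        # seed the alternative from the null optimum (beta+ on its raw scale)
        x0 = np.array(
            [
                null_res.x[0],
                null_res.x[1],
                np.log(max(nbp, 1e-4)),
                null_res.x[3],
            ]
        )
        alt_res, (aa, abm, abp, apm) = _fit(model, null=False, x0=x0)
        stat = max(0.0, 2.0 * (-alt_res.fun + null_res.fun))
        p = float(scipy.stats.chi2.sf(stat, df=2)) if stat > 0 else 1.0
        bf: dict[str, float] = {}
        for e in tree.edges():
            lp = model.log_likelihood(aa, abm, abp, apm, clamp={e.index: "plus"})
            lm = model.log_likelihood(aa, abm, abp, apm, clamp={e.index: "minus"})
            bf[e.name] = float(np.exp(np.clip(lp - lm, -700, 700)))
        results.append(
            SiteSelectionResult(
                site=s,
                alpha=aa,
                beta_minus=abm,
                beta_plus=abp,
                p_minus=apm,
                statistic=stat,
                p_value=p,
                bayes_factors=bf,
            )
        )
    return results
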