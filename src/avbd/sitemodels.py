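"""Site-class ω mixture models (M1a, M2a, M7, M8, M8a) and their LRTs.

These are the standard nested codon models used to test for positive
selection among sites of a gene family:

- M1a (nearly neutral): classes ω0 < 1 and ω1 = 1;
- M2a (selection): M1a plus a class ω2 ≥ 1;
- M7: ω ~ Beta(p, q) on (0, 1), discretised;
- M8: M7 plus an extra class with free ωs ≥ 1;
- M8a: M8 with ωs fixed at 1 (the null of the M8a-vs-M8 test).

:class:`CodonSiteModel` follows the statsmodels shape: build from data
(codon alignment + tree), call :meth:`~CodonSiteModel.fit`, and receive a
:class:`SiteModelResult` carrying log-likelihood, parameter estimates,
per-site class posteriors and a ``summary()`` table. Positive-selection
inference proceeds by likelihood-ratio tests between nested fits
(:func:`lrt`) and by naive empirical Bayes posteriors for the ω > 1 class
(:func:`positively_selected_sites`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import optimize
from scipy.stats import beta as beta_dist
from scipy.stats import chi2

from ._codons import f3x4_frequencies
from .alignment import CodonAlignment
from .gy94 import GY94, TreeLikelihood

SITE_MODELS = ("M1a", "M2a", "M7", "M8", "M8a")

KAPPA_BOUNDS = (0.05, 50.0)
BETA_BOUNDS = (0.005, 99.0)
OMEGA_POS_BOUNDS = (1.0, 50.0)
PROB_BOUNDS = (1e-4, 1.0 - 1e-4)
OMEGA01_BOUNDS = (1e-6, 1.0)


def discretize_beta(p: float, q: float, k: int, representative: str = "mean") -> np.ndarray:
    """k equal-probability classes of Beta(p, q), each summarised by a point.

    With ``representative="mean"`` the class value is the conditional mean of
    the distribution on that quantile slice (computed from the incomplete
    beta function); ``"median"`` uses the slice midpoint quantile.
    """
    edges = beta_dist.ppf(np.linspace(0.0, 1.0, k + 1), p, q)
    if representative == "median":
        vals = beta_dist.ppf((np.arange(k) + 0.5) / k, p, q)
    elif representative == "mean":
        mass1 = beta_dist.cdf(edges, p + 1.0, q)
        vals = (p / (p + q)) * np.diff(mass1) * k
    else:
        raise ValueError(f"unknown representative {representative!r}")
    return np.clip(vals, 1e-9, 1.0)


@dataclass
class _ModelSpec:
    names: list[str]              # free parameter names, kappa first
    bounds: list[tuple[float, float]]
    init: list[float]


def _model_spec(model: str) -> _ModelSpec:
    kb, bb, ob = KAPPA_BOUNDS, BETA_BOUNDS, OMEGA_POS_BOUNDS
    pb, wb = PROB_BOUNDS, OMEGA01_BOUNDS
    if model == "M1a":
        return _ModelSpec(["kappa", "p0", "omega0"], [kb, pb, wb], [2.0, 0.7, 0.2])
    if model == "M2a":
        return _ModelSpec(
            ["kappa", "p0", "p1_frac", "omega0", "omega2"],
            [kb, pb, pb, wb, ob],
            [2.0, 0.6, 0.5, 0.2, 2.5],
        )
    if model == "M7":
        return _ModelSpec(["kappa", "beta_p", "beta_q"], [kb, bb, bb], [2.0, 0.5, 1.0])
    if model == "M8":
        return _ModelSpec(
            ["kappa", "p0", "beta_p", "beta_q", "omega_s"],
            [kb, pb, bb, bb, ob],
            [2.0, 0.8, 0.5, 1.0, 2.5],
        )
    if model == "M8a":
        return _ModelSpec(
            ["kappa", "p0", "beta_p", "beta_q"], [kb, pb, bb, bb], [2.0, 0.8, 0.5, 1.0]
        )
    raise ValueError(f"unknown site model {model!r}; expected one of {SITE_MODELS}")


def _mixture(model: str, params: dict, k_beta: int, representative: str):
    """(class probabilities, class omegas) for a parameter dict."""
    if model == "M1a":
        probs = np.array([params["p0"], 1.0 - params["p0"]])
        omegas = np.array([params["omega0"], 1.0])
    elif model == "M2a":
        p0 = params["p0"]
        p1 = (1.0 - p0) * params["p1_frac"]
        probs = np.array([p0, p1, 1.0 - p0 - p1])
        omegas = np.array([params["omega0"], 1.0, params["omega2"]])
    elif model == "M7":
        probs = np.full(k_beta, 1.0 / k_beta)
        omegas = discretize_beta(params["beta_p"], params["beta_q"], k_beta, representative)
    elif model in ("M8", "M8a"):
        p0 = params["p0"]
        probs = np.concatenate([np.full(k_beta, p0 / k_beta), [1.0 - p0]])
        omega_s = params["omega_s"] if model == "M8" else 1.0
        omegas = np.concatenate(
            [discretize_beta(params["beta_p"], params["beta_q"], k_beta, representative), [omega_s]]
        )
    else:
        raise ValueError(model)
    return probs, omegas


class CodonSiteModel:
    """A site-class ω mixture model bound to one alignment and tree.

    Parameters
    ----------
    alignment : CodonAlignment
    tree : dendropy.Tree or newick string; must carry branch lengths
        (expected substitutions per codon) and leaf labels matching the
        alignment ids.
    model : one of M1a, M2a, M7, M8, M8a.
    k_beta : number of equal-probability classes discretising the beta.
    codon_freqs : optional explicit equilibrium frequencies; the default is
        F3×4 estimated from the alignment.
    """

    def __init__(
        self,
        alignment: CodonAlignment,
        tree,
        model: str = "M8",
        k_beta: int = 10,
        beta_representative: str = "mean",
        codon_freqs: np.ndarray | None = None,
    ):
        if model not in SITE_MODELS:
            raise ValueError(f"unknown site model {model!r}")
        self.alignment = alignment
        if isinstance(tree, str):
            tree = dendropy.Tree.get(data=tree, schema="newick")
        self.tree = tree
        self.model = model
        self.k_beta = int(k_beta)
        self.beta_representative = beta_representative
        self.pi = (
            np.asarray(codon_freqs, dtype=float)
            if codon_freqs is not None
            else f3x4_frequencies(alignment.codon_states, alignment.code)
        )
        self.pi = self.pi / self.pi.sum()
        self.gy94 = GY94(self.pi, table_id=alignment.code.table_id)
        self.likelihood = TreeLikelihood(alignment, self.tree)
        self.spec = _model_spec(model)
        self._n_evals = 0

    # -- likelihood ---------------------------------------------------------

    def _params_dict(self, x: np.ndarray) -> dict:
        return dict(zip(self.spec.names, (float(v) for v in x)))

    def loglike(self, x: np.ndarray) -> float:
        params = self._params_dict(np.asarray(x, dtype=float))
        probs, omegas = _mixture(self.model, params, self.k_beta, self.beta_representative)
        kappa = params["kappa"]
        eigs = [self.gy94.eigensystem(kappa, float(w)) for w in omegas]
        self._n_evals += 1
        return self.likelihood.mixture_loglik(eigs, probs, self.pi)

    # -- fitting ------------------------------------------------------------

    def _random_start(self, rng: np.random.Generator) -> np.ndarray:
        out = []
        for name, (lo, hi) in zip(self.spec.names, self.spec.bounds):
            if name == "kappa":
                out.append(rng.uniform(0.5, 8.0))
            elif name in ("beta_p", "beta_q"):
                out.append(np.exp(rng.uniform(np.log(0.05), np.log(5.0))))
            elif name == "omega_s" or name == "omega2":
                out.append(rng.uniform(1.0, 8.0))
            else:
                out.append(rng.uniform(lo + 0.05 * (hi - lo), hi - 0.05 * (hi - lo)))
        return np.clip(out, [b[0] for b in self.spec.bounds], [b[1] for b in self.spec.bounds])

    def fit(self, n_restarts: int = 5, seed: int = 0, tol: float = 1e-8) -> "SiteModelResult":
        """Maximise the likelihood with bounded quasi-Newton (L-BFGS-B).

        One deterministic start from model-specific defaults plus
        ``n_restarts − 1`` random restarts drawn from a seeded generator;
        the best optimum is kept.
        """
        rng = np.random.default_rng(seed)
        starts = [np.array(self.spec.init)]
        for _ in range(max(0, n_restarts - 1)):
            starts.append(self._random_start(rng))

        def nll(x):
            return -self.loglike(x)

        best = None
        for x0 in starts:
            res = optimize.minimize(
                nll,
                x0,
                method="L-BFGS-B",
                bounds=self.spec.bounds,
                options={"ftol": tol, "maxiter": 500},
            )
            if best is None or res.fun < best.fun:
                best = res
        params = self._params_dict(best.x)
        probs, omegas = _mixture(self.model, params, self.k_beta, self.beta_representative)
        eigs = [self.gy94.eigensystem(params["kappa"], float(w)) for w in omegas]
        lnl, posteriors = self.likelihood.mixture_loglik(
            eigs, probs, self.pi, return_posteriors=True
        )
        return SiteModelResult(
            model=self.model,
            lnl=float(lnl),
            params=params,
            class_probs=probs,
            class_omegas=omegas,
            kappa=params["kappa"],
            site_posteriors=posteriors,
            codon_freqs=self.pi,
            k_beta=self.k_beta,
            n_free_params=len(self.spec.names),
            converged=bool(best.success),
            n_function_evals=self._n_evals,
            seed=seed,
        )


@dataclass
class SiteModelResult:
    """Fitted site-class mixture: estimates, likelihood and site posteriors."""

    model: str
    lnl: float
    params: dict
    class_probs: np.ndarray
    class_omegas: np.ndarray
    kappa: float
    site_posteriors: np.ndarray       # (n_sites, n_classes), NEB
    codon_freqs: np.ndarray
    k_beta: int
    n_free_params: int
    converged: bool
    n_function_evals: int = 0
    seed: int = 0
    notes: tuple[str, ...] = (
        "site posteriors are naive empirical Bayes (MLEs plugged in)",
        "M8a-vs-M8 tested against chi2 with df=1; boundary mixture refinement not applied",
    )

    def __post_init__(self) -> None:
        if not np.isfinite(self.lnl):
            raise ValueError("non-finite log-likelihood")
        if abs(self.class_probs.sum() - 1.0) > 1e-8:
            raise ValueError("class probabilities must sum to 1")

    @property
    def dnds(self) -> float:
        """Model-averaged dN/dS, Σ_k p_k ω_k."""
        return float(np.dot(self.class_probs, self.class_omegas))

    @property
    def positive_class_mask(self) -> np.ndarray:
        return self.class_omegas > 1.0 + 1e-9

    def summary(self) -> str:
        lines = [
            f"Site-class codon model {self.model}",
            "=" * 44,
            f"log-likelihood      {self.lnl:12.4f}",
            f"free parameters     {self.n_free_params:d}",
            f"kappa (ts/tv)       {self.kappa:12.4f}",
            f"model dN/dS         {self.dnds:12.4f}",
            f"converged           {self.converged}",
            "",
            "  class   prob      omega",
        ]
        for k, (p, w) in enumerate(zip(self.class_probs, self.class_omegas)):
            lines.append(f"  {k:5d}   {p:6.4f}   {w:8.4f}")
        est = ", ".join(f"{k}={v:.4g}" for k, v in self.params.items())
        lines += ["", f"estimates: {est}"]
        return "\n".join(lines)


@dataclass
class LRTResult:
    """Likelihood-ratio test of nested codon models."""

    statistic: float
    df: int
    p_value: float

    def __post_init__(self) -> None:
        if self.statistic < 0 or self.df < 1 or not 0 <= self.p_value <= 1:
            raise ValueError("invalid LRT result")


def lrt(lnl_null: float, lnl_alt: float, df: int, tol: float = 1e-6) -> LRTResult:
    """2Δℓ = 2(ℓ_alt − ℓ_null) against the χ²(df) upper tail.

    Slightly negative statistics (within optimiser tolerance) are clamped to
    zero; anything more negative indicates non-nested models or a failed fit
    and raises.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * (lnl_alt - lnl_null)
    if stat < -tol:
        raise ValueError(
            f"2*delta-lnL = {stat:.6g} < 0: models not nested or null fit better than alternative"
        )
    stat = max(stat, 0.0)
    return LRTResult(statistic=stat, df=df, p_value=float(chi2.sf(stat, df)))


def positively_selected_sites(
    fit: SiteModelResult, threshold: float = 0.95
) -> list[tuple[int, float]]:
    """Sites whose NEB posterior mass on ω > 1 classes exceeds ``threshold``.

    Site indices are 0-based alignment columns. Only models that admit an
    ω > 1 class are meaningful: M2a and M8 (and M8a, which yields an empty
    list since its extra class is pinned at ω = 1).
    """
    if fit.model in ("M1a", "M7"):
        raise ValueError(f"model {fit.model} has no omega > 1 class")
    mask = fit.positive_class_mask
    if not mask.any():
        return []
    pos_mass = fit.site_posteriors[:, mask].sum(axis=1)
    return [(int(i), float(p)) for i, p in enumerate(pos_mass) if p > threshold]
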