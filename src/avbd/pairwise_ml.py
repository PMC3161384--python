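"""Maximum-likelihood pairwise dN/dS under the GY94 codon model.

For two in-frame sequences the likelihood depends only on the total
divergence t (expected substitutions per codon), κ and ω:

    ln L(t, κ, ω) = Σ_sites ln( π_a · P_ab(t) )

by reversibility. dN and dS are derived from the fitted rate-matrix flows:
the nonsynonymous substitutions per codon are t·ρ_N/(ρ_N+ρ_S), and sites of
each kind are counted by the mutational opportunity of the same model at
ω = 1, so that dN/dS equals the fitted ω exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from ._codons import f3x4_frequencies
from .alignment import CodonAlignment
from .gy94 import GY94
from .ng86 import PairwiseRates

T_BOUNDS = (1e-9, 50.0)
KAPPA_BOUNDS = (0.05, 50.0)
OMEGA_BOUNDS = (1e-6, 50.0)


@dataclass
class PairwiseMLResult:
    rates: PairwiseRates
    lnl: float
    converged: bool
    n_codons: int

    def summary(self) -> str:
        r = self.rates
        return (
            "Pairwise GY94 ML fit\n"
            "====================\n"
            f"codons compared   {self.n_codons}\n"
            f"log-likelihood    {self.lnl:.4f}\n"
            f"t (subs/codon)    {r.t:.6f}\n"
            f"kappa             {r.kappa:.4f}\n"
            f"omega (dN/dS)     {r.omega:.4f}\n"
            f"dN                {r.dn:.6f}\n"
            f"dS                {r.ds:.6f}\n"
            f"converged         {self.converged}\n"
        )


class PairwiseCodonML:
    """GY94 model for exactly two aligned coding sequences."""

    def __init__(self, alignment: CodonAlignment, codon_freqs: np.ndarray | None = None):
        if alignment.n_seqs != 2:
            raise ValueError("pairwise model needs exactly two sequences")
        a, b = alignment.pairwise_ungapped(0, 1)
        if a.size == 0:
            raise ValueError("no ungapped codon overlap between the two sequences")
        # joint codon-pair counts are a sufficient statistic
        pair_codes = a * alignment.code.n_states + b
        uniq, counts = np.unique(pair_codes, return_counts=True)
        self._ia = uniq // alignment.code.n_states
        self._ib = uniq % alignment.code.n_states
        self._w = counts.astype(float)
        self.n_codons = int(a.size)
        self.alignment = alignment
        self.pi = (
            np.asarray(codon_freqs, dtype=float)
            if codon_freqs is not None
            else f3x4_frequencies(alignment.codon_states, alignment.code)
        )
        self.pi = self.pi / self.pi.sum()
        self.gy94 = GY94(self.pi, table_id=alignment.code.table_id)

    def loglike(self, t: float, kappa: float, omega: float) -> float:
        eig = self.gy94.eigensystem(kappa, omega)
        P = eig.transition_matrix(t / eig.rate)  # t in expected subs/codon
        vals = self.pi[self._ia] * P[self._ia, self._ib]
        return float(np.dot(self._w, np.log(np.maximum(vals, 1e-310))))

    def fit(self, n_restarts: int = 3, seed: int = 0, tol: float = 1e-8) -> PairwiseMLResult:
        rng = np.random.default_rng(seed)
        # moment-style start: raw proportion of differing codons
        p_diff = float(self._w[self._ia != self._ib].sum() / self._w.sum())
        t0 = max(3.0 * p_diff, 1e-3)
        starts = [np.array([t0, 2.0, 0.5])]
        for _ in range(max(0, n_restarts - 1)):
            starts.append(
                np.array(
                    [
                        np.exp(rng.uniform(np.log(1e-3), np.log(5.0))),
                        rng.uniform(0.5, 8.0),
                        np.exp(rng.uniform(np.log(0.05), np.log(5.0))),
                    ]
                )
            )
        bounds = [T_BOUNDS, KAPPA_BOUNDS, OMEGA_BOUNDS]

        def nll(x):
            return -self.loglike(*x)

        best = None
        for x0 in starts:
            res = optimize.minimize(
                nll, x0, method="L-BFGS-B", bounds=bounds, options={"ftol": tol}
            )
            if best is None or res.fun < best.fun:
                best = res
        t, kappa, omega = (float(v) for v in best.x)
        eig = self.gy94.eigensystem(kappa, omega)
        eig1 = self.gy94.eigensystem(kappa, 1.0)
        rate = eig.rate
        # substitutions per codon of each kind, and sites from ω=1 opportunity
        subs_n = t * eig.nonsyn_flow / rate
        subs_s = t * eig.syn_flow / rate
        frac_n1 = eig1.nonsyn_flow / eig1.rate
        sites_n = 3.0 * frac_n1
        sites_s = 3.0 * (1.0 - frac_n1)
        dn = subs_n / sites_n
        ds = subs_s / sites_s
        rates = PairwiseRates(
            dn=dn,
            ds=ds,
            omega=omega if ds > 0 else None,
            method="ML",
            n_sites=sites_n * self.n_codons,
            s_sites=sites_s * self.n_codons,
            t=t,
            kappa=kappa,
        )
        return PairwiseMLResult(
            rates=rates, lnl=-float(best.fun), converged=bool(best.success), n_codons=self.n_codons
        )
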