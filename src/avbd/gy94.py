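"""Goldman–Yang (GY94) codon substitution model and pruning likelihood.

The instantaneous rate from codon i to codon j (single-nucleotide changes
only) is q_ij = π_j · κ^[transition] · ω^[nonsynonymous], with π the F3×4
codon frequencies, κ the transition/transversion rate ratio and ω the
nonsynonymous/synonymous rate ratio. The chain is reversible, so transition
probabilities come from a symmetric eigendecomposition, and likelihoods on a
tree are computed by Felsenstein pruning over the 61 sense codons with
per-pattern rescaling.

Branch lengths are expected substitutions per codon; in a site-class mixture
all class matrices share one scale so that the *mixture-averaged* rate is 1,
matching the convention of mainstream codon-model software.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from ._codons import get_pair_structure
from .alignment import GAP_STATE, CodonAlignment

MIN_FREQ = 1e-12


@dataclass
class Eigensystem:
    """Spectral form of one (unnormalised) rate matrix: Q = A diag(lam) B."""

    lam: np.ndarray
    A: np.ndarray
    B: np.ndarray
    rate: float          # total flow Σ_i π_i (−q_ii) of the unnormalised Q
    nonsyn_flow: float   # nonsynonymous part of that flow
    syn_flow: float

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) for the unnormalised Q; rescale t externally for mixtures."""
        P = (self.A * np.exp(self.lam * t)) @ self.B
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


class GY94:
    """Rate-matrix factory for a fixed codon frequency vector."""

    def __init__(self, pi: np.ndarray, table_id: int = 1):
        structure = get_pair_structure(table_id)
        self.structure = structure
        self.code = structure.code
        pi = np.asarray(pi, dtype=float)
        if pi.shape != (self.code.n_states,):
            raise ValueError("pi must have one entry per sense codon")
        pi = np.maximum(pi, MIN_FREQ)
        self.pi = pi / pi.sum()
        self._sqrt_pi = np.sqrt(self.pi)

    def rate_matrix(self, kappa: float, omega: float) -> np.ndarray:
        """Unnormalised Q (zero row sums, stationary distribution π)."""
        st = self.structure
        Q = np.where(st.single_diff, self.pi[None, :], 0.0)
        Q = Q * np.where(st.transition, kappa, 1.0) * np.where(st.nonsyn, omega, 1.0)
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def flows(self, kappa: float, omega: float) -> tuple[float, float]:
        """(nonsynonymous, synonymous) equilibrium flow of the unnormalised Q."""
        st = self.structure
        base = np.where(st.single_diff, self.pi[None, :] * self.pi[:, None], 0.0)
        base = base * np.where(st.transition, kappa, 1.0)
        nonsyn = float((base * np.where(st.nonsyn, omega, 0.0)).sum())
        syn = float((base * np.where(st.nonsyn, 0.0, 1.0)).sum())
        return nonsyn, syn

    def eigensystem(self, kappa: float, omega: float) -> Eigensystem:
        Q = self.rate_matrix(kappa, omega)
        # reversibility: D^1/2 Q D^-1/2 is symmetric
        S = Q * (self._sqrt_pi[:, None] / self._sqrt_pi[None, :])
        S = 0.5 * (S + S.T)
        lam, V = np.linalg.eigh(S)
        A = V / self._sqrt_pi[:, None]
        B = V.T * self._sqrt_pi[None, :]
        nonsyn, syn = self.flows(kappa, omega)
        return Eigensystem(lam=lam, A=A, B=B, rate=nonsyn + syn, nonsyn_flow=nonsyn, syn_flow=syn)


def mixture_rate(eigs: list[Eigensystem], probs: np.ndarray) -> float:
    """Mixture-averaged substitution rate used to calibrate branch lengths."""
    return float(sum(p * e.rate for p, e in zip(probs, eigs)))


@dataclass
class _Node:
    children: list      # (node index, branch length) pairs
    leaf_row: int | None


class TreeLikelihood:
    """Felsenstein pruning for a codon alignment on a fixed tree.

    Site patterns are compressed once; :meth:`class_site_logliks` returns the
    per-site log-likelihood under each ω class, from which mixture models
    assemble their total likelihood and site posteriors.
    """

    def __init__(self, aln: CodonAlignment, tree: dendropy.Tree):
        self.aln = aln
        self.n_states = aln.code.n_states
        leaf_labels = sorted(
            lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon is not None
        )
        if leaf_labels != sorted(aln.ids):
            raise ValueError(
                "tree leaves and alignment ids differ: "
                f"{sorted(set(leaf_labels) ^ set(aln.ids))}"
            )
        # compress columns into unique patterns
        cols = aln.codon_states.T  # (n_sites, n_seqs)
        patterns, self.pattern_index, counts = np.unique(
            cols, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = patterns  # (n_patterns, n_seqs)
        self.weights = counts.astype(float)
        self.n_patterns = patterns.shape[0]

        row_of = {sid: k for k, sid in enumerate(aln.ids)}
        self.nodes: list[_Node] = []
        self.branch_lengths: list[float] = []

        def build(nd) -> int:
            if nd.is_leaf():
                idx = len(self.nodes)
                self.nodes.append(_Node(children=[], leaf_row=row_of[nd.taxon.label]))
                return idx
            child_entries = []
            for ch in nd.child_nodes():
                ci = build(ch)
                bl = ch.edge.length
                if bl is None:
                    raise ValueError("tree must have branch lengths on all edges")
                child_entries.append((ci, max(float(bl), 0.0)))
            idx = len(self.nodes)
            self.nodes.append(_Node(children=child_entries, leaf_row=None))
            return idx

        self.root_index = build(tree.seed_node)
        if self.nodes[self.root_index].leaf_row is not None:
            raise ValueError("tree must have at least one internal node")
        # leaf partial likelihoods, fixed across classes
        self._leaf_partials: dict[int, np.ndarray] = {}
        for idx, node in enumerate(self.nodes):
            if node.leaf_row is not None:
                states = self.patterns[:, node.leaf_row]
                L = np.zeros((self.n_patterns, self.n_states))
                gap = states == GAP_STATE
                L[gap, :] = 1.0
                L[~gap, states[~gap]] = 1.0
                self._leaf_partials[idx] = L

    @property
    def n_branches(self) -> int:
        return sum(len(n.children) for n in self.nodes)

    def site_logliks(self, eig: Eigensystem, pi: np.ndarray, scale: float) -> np.ndarray:
        """Per-pattern log-likelihood for one class; branch lengths / scale."""
        partials: dict[int, np.ndarray] = {}
        logscale = np.zeros(self.n_patterns)
        for idx, node in enumerate(self.nodes):
            if node.leaf_row is not None:
                partials[idx] = self._leaf_partials[idx]
                continue
            L = np.ones((self.n_patterns, self.n_states))
            for ci, bl in node.children:
                P = eig.transition_matrix(bl / scale)
                L *= partials.pop(ci) @ P.T
            m = L.max(axis=1)
            m = np.where(m > 0, m, 1.0)
            L /= m[:, None]
            logscale += np.log(m)
            partials[idx] = L
        root = partials[self.root_index]
        site_l = root @ pi
        return np.log(np.maximum(site_l, 1e-310)) + logscale

    def mixture_loglik(
        self,
        eigs: list[Eigensystem],
        probs: np.ndarray,
        pi: np.ndarray,
        return_posteriors: bool = False,
    ):
        """Total log-likelihood of a site-class mixture (and NEB posteriors).

        Branch lengths are interpreted as expected substitutions per codon
        under the mixture, i.e. every class matrix is divided by the
        mixture-averaged rate.
        """
        probs = np.asarray(probs, dtype=float)
        scale = mixture_rate(eigs, probs)
        if scale <= 0:
            raise ValueError("degenerate mixture: zero substitution rate")
        per_class = np.empty((len(eigs), self.n_patterns))
        for k, eig in enumerate(eigs):
            per_class[k] = self.site_logliks(eig, pi, scale)
        with np.errstate(divide="ignore"):
            log_probs = np.log(np.maximum(probs, 0.0))[:, None]
        joint = log_probs + per_class
        m = joint.max(axis=0)
        site_log = m + np.log(np.exp(joint - m[None, :]).sum(axis=0))
        total = float(np.dot(self.weights, site_log))
        if not return_posteriors:
            return total
        post = np.exp(joint - site_log[None, :])
        post /= post.sum(axis=0, keepdims=True)
        site_posteriors = post[:, self.pattern_index].T  # (n_sites, n_classes)
        return total, site_posteriors
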