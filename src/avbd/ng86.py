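"""Nei–Gojobori (1986) counting estimator of dN and dS.

The transparent baseline for pairwise rate estimation: synonymous and
nonsynonymous *sites* are counted per codon as the fraction of single-
nucleotide neighbours (stop codons excluded from the neighbourhood) whose
amino acid is unchanged; *differences* between two codons are resolved by
averaging the synonymous/nonsynonymous step counts over all minimal
substitution pathways that avoid stop codons; multiple hits are corrected
with the Jukes–Cantor transform d = −3/4 ln(1 − 4p/3).

Proportions at or beyond the Jukes–Cantor singularity (p ≥ 3/4) leave the
distance undefined and the result flagged saturated, mirroring the practice
of excluding saturated paralog comparisons from summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np

from ._codons import NUCLEOTIDES, GeneticCode, get_genetic_code
from .alignment import CodonAlignment


@dataclass(frozen=True)
class PairwiseRates:
    """dN/dS estimates for one sequence pair."""

    dn: float | None
    ds: float | None
    omega: float | None          # undefined when dS = 0 or either rate saturated
    method: str
    n_sites: float | None = None   # N̄: nonsynonymous sites
    s_sites: float | None = None   # S̄: synonymous sites
    n_diffs: float | None = None
    s_diffs: float | None = None
    saturated: bool = False
    t: float | None = None       # ML only: branch length, subs/codon
    kappa: float | None = None   # ML only


def _syn_site_fractions(codon: str, code: GeneticCode) -> float:
    """Synonymous site count of one codon (sum of per-position fractions)."""
    aa = code.translate_codon(codon)
    total = 0.0
    for pos in range(3):
        syn = 0
        non_stop = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if code.is_stop(alt):
                continue
            non_stop += 1
            if code.translate_codon(alt) == aa:
                syn += 1
        if non_stop:
            total += syn / non_stop
    return total


@lru_cache(maxsize=None)
def _codon_sites(codon: str, table_id: int) -> float:
    return _syn_site_fractions(codon, get_genetic_code(table_id))


@lru_cache(maxsize=None)
def _pathway_counts(a: str, b: str, table_id: int) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two codons.

    Averaged over all orderings of the differing positions; pathways passing
    through a stop codon are excluded, falling back to all pathways when
    every ordering is stop-blocked.
    """
    code = get_genetic_code(table_id)
    diffs = [p for p in range(3) if a[p] != b[p]]
    if not diffs:
        return (0.0, 0.0)

    def walk(order):
        cur = a
        syn = nonsyn = 0
        blocked = False
        for p in order:
            nxt = cur[:p] + b[p] + cur[p + 1 :]
            if code.is_stop(nxt):
                blocked = True
            elif not code.is_stop(cur):
                if code.translate_codon(cur) == code.translate_codon(nxt):
                    syn += 1
                else:
                    nonsyn += 1
            else:
                nonsyn += 1
            cur = nxt
        return syn, nonsyn, blocked

    results = [walk(order) for order in permutations(diffs)]
    valid = [(s, n) for s, n, blocked in results if not blocked]
    if not valid:
        valid = [(s, n) for s, n, _ in results]
    syn = float(np.mean([s for s, _ in valid]))
    nonsyn = float(np.mean([n for _, n in valid]))
    # renormalise so counted steps always sum to the number of differences
    scale = len(diffs) / (syn + nonsyn) if syn + nonsyn else 1.0
    return syn * scale, nonsyn * scale


def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; None at or beyond saturation (p >= 3/4)."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return None
    return -0.75 * float(np.log1p(-4.0 * p / 3.0))


def ng86_pairwise(a: str, b: str, table_id: int = 1) -> PairwiseRates:
    """NG86 dN and dS between two equal-length in-frame codon sequences.

    Codon positions where either sequence is gapped ('---') are dropped
    pairwise before counting.
    """
    a, b = a.upper().replace("U", "T"), b.upper().replace("U", "T")
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    if len(a) % 3:
        raise ValueError("length must be a multiple of 3")
    code = get_genetic_code(table_id)
    s_sites = 0.0
    sd = nd = 0.0
    n_codons = 0
    for k in range(0, len(a), 3):
        ca, cb = a[k : k + 3], b[k : k + 3]
        if "-" in ca or "-" in cb or code.is_stop(ca) or code.is_stop(cb):
            continue
        if ca not in code.index or cb not in code.index:
            continue
        n_codons += 1
        s_sites += 0.5 * (_codon_sites(ca, code.table_id) + _codon_sites(cb, code.table_id))
        s_step, n_step = _pathway_counts(ca, cb, code.table_id)
        sd += s_step
        nd += n_step
    if n_codons == 0:
        raise ValueError("no comparable codons after gap removal")
    n_sites = 3.0 * n_codons - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ds = jukes_cantor(ps)
    dn = jukes_cantor(pn)
    saturated = ds is None or dn is None
    omega = None
    if not saturated and ds is not None and ds > 0 and dn is not None:
        omega = dn / ds
    return PairwiseRates(
        dn=dn,
        ds=ds,
        omega=omega,
        method="NG86",
        n_sites=n_sites,
        s_sites=s_sites,
        n_diffs=nd,
        s_diffs=sd,
        saturated=saturated,
    )


@dataclass
class PairwiseMatrixResult:
    ids: list[str]
    dn: np.ndarray      # NaN off-diagonal where undefined; NaN diagonal
    ds: np.ndarray
    omega: np.ndarray
    pairs: dict         # (id_i, id_j) -> PairwiseRates

    def summary(self) -> dict:
        """Means and standard errors over defined (non-saturated) pairs."""
        out = {}
        for name, mat in (("dn", self.dn), ("ds", self.ds), ("omega", self.omega)):
            iu = np.triu_indices_from(mat, k=1)
            vals = mat[iu]
            vals = vals[~np.isnan(vals)]
            out[f"mean_{name}"] = float(np.mean(vals)) if vals.size else float("nan")
            out[f"se_{name}"] = (
                float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else float("nan")
            )
            out[f"n_{name}"] = int(vals.size)
        return out


def pairwise_matrix(
    aln: CodonAlignment, method: str = "NG86", **ml_kwargs
) -> PairwiseMatrixResult:
    """All unordered pairwise dN/dS estimates over an alignment.

    ``method`` is "NG86" (counting) or "ML" (GY94 maximum likelihood via
    :class:`avbd.pairwise_ml.PairwiseCodonML`).
    """
    if aln.n_seqs < 2:
        raise ValueError("need at least two sequences")
    n = aln.n_seqs
    dn = np.full((n, n), np.nan)
    ds = np.full((n, n), np.nan)
    om = np.full((n, n), np.nan)
    pairs: dict = {}
    for i in range(n):
        for j in range(i + 1, n):
            if method == "NG86":
                sa = _strip_shared_gaps(aln, i, j)
                rates = ng86_pairwise(sa[0], sa[1], table_id=aln.code.table_id)
            elif method == "ML":
                from .pairwise_ml import PairwiseCodonML

                sub = aln.subset([aln.ids[i], aln.ids[j]])
                rates = PairwiseCodonML(sub, **ml_kwargs).fit().rates
            else:
                raise ValueError(f"unknown method {method!r}")
            pairs[(aln.ids[i], aln.ids[j])] = rates
            for mat, val in ((dn, rates.dn), (ds, rates.ds), (om, rates.omega)):
                if val is not None:
                    mat[i, j] = mat[j, i] = val
    return PairwiseMatrixResult(ids=list(aln.ids), dn=dn, ds=ds, omega=om, pairs=pairs)


def _strip_shared_gaps(aln: CodonAlignment, i: int, j: int) -> tuple[str, str]:
    a, b = aln.pairwise_ungapped(i, j)
    code = aln.code
    return (
        "".join(code.codons[int(s)] for s in a),
        "".join(code.codons[int(s)] for s in b),
    )
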