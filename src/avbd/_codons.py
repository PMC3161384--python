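"""Genetic-code bookkeeping shared by the codon-evolution machinery.

Precomputes, for a given NCBI translation table, the list of sense codons,
their amino-acid translations, and the pairwise structure (single-nucleotide
neighbourhood, transition vs. transversion, synonymous vs. nonsynonymous)
that both the NG86 counting estimator and the GY94 rate matrix consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "TCAG"
PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


def is_transition(a: str, b: str) -> bool:
    """True when the single-nucleotide change a->b is a transition."""
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


@dataclass(frozen=True)
class GeneticCode:
    """Sense-codon state space of one NCBI translation table."""

    table_id: int
    codons: tuple[str, ...]               # sense codons, fixed order
    amino_acids: tuple[str, ...]          # translation of each sense codon
    stop_codons: frozenset[str]
    index: dict[str, int] = field(repr=False)

    @property
    def n_states(self) -> int:
        return len(self.codons)

    def translate_codon(self, codon: str) -> str:
        """One-letter amino acid; '*' for stop, 'X' for anything ambiguous."""
        codon = codon.upper().replace("U", "T")
        if codon in self.stop_codons:
            return "*"
        i = self.index.get(codon)
        return "X" if i is None else self.amino_acids[i]

    def is_stop(self, codon: str) -> bool:
        return codon.upper() in self.stop_codons


@lru_cache(maxsize=8)
def get_genetic_code(table_id: int = 1) -> GeneticCode:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    stops = frozenset(table.stop_codons)
    codons, aas = [], []
    for c in ("".join(p) for p in product(NUCLEOTIDES, repeat=3)):
        if c in stops:
            continue
        codons.append(c)
        aas.append(table.forward_table[c])
    return GeneticCode(
        table_id=table_id,
        codons=tuple(codons),
        amino_acids=tuple(aas),
        stop_codons=stops,
        index={c: i for i, c in enumerate(codons)},
    )


@dataclass(frozen=True)
class CodonPairStructure:
    """Pairwise structure of the sense-codon space as boolean matrices."""

    code: GeneticCode
    single_diff: np.ndarray    # (n, n) bool: codons differ at exactly one site
    transition: np.ndarray     # (n, n) bool: that one difference is a transition
    nonsyn: np.ndarray         # (n, n) bool: amino acids differ


@lru_cache(maxsize=8)
def get_pair_structure(table_id: int = 1) -> CodonPairStructure:
    code = get_genetic_code(table_id)
    n = code.n_states
    single = np.zeros((n, n), dtype=bool)
    trans = np.zeros((n, n), dtype=bool)
    nonsyn = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(code.codons):
        for j, cj in enumerate(code.codons):
            if i == j:
                continue
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            if len(diffs) != 1:
                continue
            p = diffs[0]
            single[i, j] = True
            trans[i, j] = is_transition(ci[p], cj[p])
            nonsyn[i, j] = code.amino_acids[i] != code.amino_acids[j]
    return CodonPairStructure(code=code, single_diff=single, transition=trans, nonsyn=nonsyn)


def f3x4_frequencies(codon_columns: np.ndarray, code: GeneticCode) -> np.ndarray:
    """F3x4 equilibrium codon frequencies from observed codon states.

    Parameters
    ----------
    codon_columns : integer array of sense-codon indices (any shape); negative
        entries (gaps / ambiguous codons) are ignored.
    """
    states = codon_columns[codon_columns >= 0].ravel()
    if states.size == 0:
        raise ValueError("no ungapped codons to estimate frequencies from")
    pos_freq = np.full((3, 4), 0.0)
    nt_index = {nt: k for k, nt in enumerate(NUCLEOTIDES)}
    for s in states:
        codon = code.codons[int(s)]
        for p in range(3):
            pos_freq[p, nt_index[codon[p]]] += 1
    # one pseudo-observation per nucleotide per position guards zero frequencies
    pos_freq += 0.25
    pos_freq /= pos_freq.sum(axis=1, keepdims=True)
    pi = np.empty(code.n_states)
    for i, codon in enumerate(code.codons):
        pi[i] = (
            pos_freq[0, nt_index[codon[0]]]
            * pos_freq[1, nt_index[codon[1]]]
            * pos_freq[2, nt_index[codon[2]]]
        )
    return pi / pi.sum()
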