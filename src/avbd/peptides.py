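"""Peptide physicochemistry: net charge, isoelectric point, hydrophilicity.

Defensins are short cationic peptides; their antimicrobial activity tracks
net positive charge at physiological pH and amphipathicity. Charge is the
Henderson–Hasselbalch sum over ionisable groups; the isoelectric point is the
root of that sum in pH; hydrophilicity is the Hopp–Woods scale average.

The default pKa set (Lehninger-style) is an explicit, printable choice —
different published tables shift charge and pI by a few tenths, so reported
values are only comparable under a stated table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.optimize import brentq

POSITIVE_RESIDUES = "HKR"
NEGATIVE_RESIDUES = "DECY"

DEFAULT_SIDECHAIN_PKA = {
    "D": 3.65,
    "E": 4.25,
    "C": 8.30,
    "Y": 10.07,
    "H": 6.00,
    "K": 10.53,
    "R": 12.48,
}

# Hopp & Woods (1981) hydrophilicity values
HOPP_WOODS = {
    "R": 3.0, "D": 3.0, "E": 3.0, "K": 3.0, "S": 0.3, "N": 0.2, "Q": 0.2,
    "G": 0.0, "P": 0.0, "T": -0.4, "A": -0.5, "H": -0.5, "C": -1.0,
    "M": -1.3, "V": -1.5, "I": -1.8, "L": -1.8, "Y": -2.3, "F": -2.5,
    "W": -3.4,
}


@dataclass(frozen=True)
class PkaTable:
    side_chain: dict = field(default_factory=lambda: dict(DEFAULT_SIDECHAIN_PKA))
    n_terminus: float = 9.0
    c_terminus: float = 3.1

    def __post_init__(self) -> None:
        for name, value in list(self.side_chain.items()) + [
            ("N-terminus", self.n_terminus),
            ("C-terminus", self.c_terminus),
        ]:
            if not 0.0 < value < 14.0:
                raise ValueError(f"pKa for {name} out of range: {value}")


def _check_peptide(peptide: str, allowed: set[str]) -> str:
    if not peptide:
        raise ValueError("empty peptide")
    peptide = peptide.upper()
    bad = sorted(set(peptide) - allowed)
    if bad:
        raise ValueError(f"unknown residues: {bad}")
    return peptide


def net_charge(peptide: str, ph: float, pka: PkaTable | None = None) -> float:
    """Net charge of a linear peptide at the given pH.

    Basic groups (H, K, R, N-terminus) contribute 1/(1+10^(pH−pKa)); acidic
    groups (D, E, C, Y, C-terminus) contribute −1/(1+10^(pKa−pH)). Cysteines
    are treated as free thiols regardless of disulphide context.
    """
    pka = pka or PkaTable()
    if not 0.0 < ph < 14.0:
        raise ValueError(f"pH out of range: {ph}")
    peptide = _check_peptide(peptide, set("ACDEFGHIKLMNPQRSTVWY"))
    charge = 1.0 / (1.0 + 10.0 ** (ph - pka.n_terminus))
    charge -= 1.0 / (1.0 + 10.0 ** (pka.c_terminus - ph))
    for aa in peptide:
        if aa in POSITIVE_RESIDUES:
            charge += 1.0 / (1.0 + 10.0 ** (ph - pka.side_chain[aa]))
        elif aa in NEGATIVE_RESIDUES:
            charge -= 1.0 / (1.0 + 10.0 ** (pka.side_chain[aa] - ph))
    return charge


def isoelectric_point(peptide: str, pka: PkaTable | None = None, tol: float = 1e-4) -> float:
    """pH at which the net charge vanishes, by bisection on (0, 14).

    Every peptide carries both termini, so a root exists unless the charge
    keeps one sign across the whole pH range (possible only with extreme
    custom pKa tables), which raises.
    """
    pka = pka or PkaTable()
    lo, hi = 1e-3, 14.0 - 1e-3
    f_lo, f_hi = net_charge(peptide, lo, pka), net_charge(peptide, hi, pka)
    if f_lo < 0 or f_hi > 0:
        raise ValueError("net charge does not change sign in (0, 14); no isoelectric point")
    return float(brentq(lambda ph: net_charge(peptide, ph, pka), lo, hi, xtol=tol))


def avg_hydrophilicity(peptide: str, scale: dict | None = None) -> float:
    """Arithmetic mean of per-residue hydrophilicity (Hopp–Woods by default)."""
    scale = scale or HOPP_WOODS
    peptide = _check_peptide(peptide, set(scale))
    return sum(scale[aa] for aa in peptide) / len(peptide)
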