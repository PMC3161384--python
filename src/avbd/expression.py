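"""Digital expression profiling: TPM and the tissue-specificity index τ.

The 454 cDNA survey behind this module counts, per locus and per tissue,
the sequencing reads assigned to that locus. With no transcript-length
normalisation (read counts, not coverage), expression is expressed as
transcripts per million: ``TPM = count / library_size × 1e6``.

Tissue specificity follows the log-ratio index

    τ = Σ_i (1 − log x_i / log x_max) / (N − 1)

over N tissues, where x_i is the (unrounded) TPM with a pseudo-count floor
of 2 substituted for tissues with zero detected reads. τ is 0 for uniform
expression and approaches 1 for single-tissue expression. Estimates based on
3 or fewer reads in total are flagged as discarded rather than reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PSEUDO_TPM = 2.0
MIN_TOTAL_READS = 4  # τ from ≤ 3 reads is discarded


def counts_to_tpm(count: int, library_size: int) -> float:
    """Reads per million library reads (no length normalisation)."""
    if library_size <= 0:
        raise ValueError(f"library size must be positive, got {library_size}")
    if count < 0:
        raise ValueError("negative read count")
    return count / library_size * 1e6


def counts_from_reported_tpm(tpm_values, library_sizes) -> np.ndarray:
    """Invert rounded, printed TPM values back to integer read counts.

    Published expression tables print TPM to one decimal; the underlying
    integer counts are recovered as round(TPM × library_size / 1e6), which is
    exact whenever libraries are ≲ 5M reads.
    """
    tpm = np.asarray(tpm_values, dtype=float)
    lib = np.asarray(library_sizes, dtype=float)
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")
    return np.rint(tpm * lib / 1e6).astype(int)


@dataclass
class TauResult:
    locus_id: str
    tpm: np.ndarray          # unrounded TPM per tissue (no pseudo-count)
    total_reads: int
    discarded: bool
    tau: float | None        # None when discarded

    def __post_init__(self) -> None:
        if self.discarded != (self.tau is None):
            raise ValueError("tau must be undefined exactly for discarded loci")
        if self.tau is not None and not 0.0 <= self.tau <= 1.0 + 1e-12:
            raise ValueError(f"tau out of [0, 1]: {self.tau}")


def compute_tau(
    counts_by_tissue,
    library_sizes,
    locus_id: str = "locus",
    pseudo_tpm: float = PSEUDO_TPM,
) -> TauResult:
    """Tissue-specificity index τ from per-tissue read counts.

    TPM is computed unrounded; tissues with zero reads get the pseudo-count
    floor ``pseudo_tpm`` before the log transform. The log-ratio makes τ
    independent of the logarithm base.
    """
    counts = np.asarray(counts_by_tissue, dtype=int)
    lib = np.asarray(library_sizes, dtype=int)
    if counts.shape != lib.shape or counts.ndim != 1 or counts.size < 2:
        raise ValueError("need matching count/library vectors over at least two tissues")
    if np.any(counts < 0) or np.any(lib <= 0):
        raise ValueError("counts must be >= 0 and library sizes > 0")
    tpm = counts / lib * 1e6
    total = int(counts.sum())
    if total < MIN_TOTAL_READS:
        return TauResult(locus_id=locus_id, tpm=tpm, total_reads=total, discarded=True, tau=None)
    x = np.where(counts == 0, pseudo_tpm, tpm)
    if np.any(x <= 0):
        raise AssertionError("pseudo-counted TPM must be positive")
    log_x = np.log(x)
    log_max = log_x.max()
    if log_max == 0.0:
        # every tissue at the pseudo-count floor exactly; define τ = 0 (uniform)
        tau = 0.0
    else:
        tau = float(np.sum(1.0 - log_x / log_max) / (counts.size - 1))
        # the log-ratio index presumes x >= 1; sub-unit TPMs (libraries beyond
        # ~500k reads) can push individual terms outside [0, 1], so clip
        tau = min(1.0, max(0.0, tau))
    return TauResult(locus_id=locus_id, tpm=tpm, total_reads=total, discarded=False, tau=tau)


@dataclass
class ExpressionTable:
    """Per-locus × per-tissue read counts with per-tissue library sizes."""

    counts: pd.DataFrame        # index: locus_id, columns: tissue
    library_sizes: pd.Series    # index: tissue

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.library_sizes.index):
            raise ValueError("count columns and library-size index must match")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if (self.library_sizes <= 0).any():
            raise ValueError("non-positive library size")
        if (self.counts.values > self.library_sizes.values[None, :]).any():
            raise ValueError("locus count exceeds its tissue library size")

    @property
    def tissues(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def loci(self) -> list[str]:
        return list(self.counts.index)

    def tau_table(self, pseudo_tpm: float = PSEUDO_TPM) -> pd.DataFrame:
        """TPM per tissue plus τ (NaN where discarded) for every locus."""
        rows = {}
        for locus in self.loci:
            res = compute_tau(
                self.counts.loc[locus].values,
                self.library_sizes.values,
                locus_id=locus,
                pseudo_tpm=pseudo_tpm,
            )
            rows[locus] = list(res.tpm) + [np.nan if res.discarded else res.tau, res.total_reads]
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=self.tissues + ["tau", "total_reads"]
        )


def build_expression_table(
    assignments: pd.DataFrame,
    library_sizes: dict | pd.Series,
    loci: list[str] | None = None,
) -> ExpressionTable:
    """Aggregate read→locus assignments into an :class:`ExpressionTable`.

    ``assignments`` needs columns read_id, locus_id, tissue. Loci listed in
    ``loci`` but never observed are retained with all-zero rows, so absence
    of expression is reported rather than silently dropped.
    """
    lib = pd.Series(library_sizes).astype(int)
    required = {"read_id", "locus_id", "tissue"}
    if not required.issubset(assignments.columns):
        raise ValueError(f"assignments must have columns {sorted(required)}")
    unknown = set(assignments["tissue"]) - set(lib.index)
    if unknown:
        raise ValueError(f"unknown tissue labels: {sorted(unknown)}")
    all_loci = list(loci) if loci is not None else sorted(set(assignments["locus_id"]))
    counts = (
        assignments.groupby(["locus_id", "tissue"]).size().unstack(fill_value=0)
    )
    counts = counts.reindex(index=all_loci, columns=lib.index, fill_value=0).astype(int)
    return ExpressionTable(counts=counts, library_sizes=lib)
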