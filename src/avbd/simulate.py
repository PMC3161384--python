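"""Synthetic data with the statistical structure the pipeline assumes.

Three generators, one per pipeline stage:

- :func:`simulate_defensin_cluster` plants motif-bearing genes (mature
  peptide with the six-cysteine spacing, conserved signal peptide a few
  hundred bp upstream) on a motif-free background chromosome, returning the
  sequence together with its truth annotations;
- :func:`simulate_codon_alignment` evolves codon sites down a tree under a
  GY94 site-class ω mixture using exact matrix-exponential transition
  probabilities, returning the alignment and each site's true class;
- :func:`simulate_expression_counts` draws per-locus per-tissue read counts
  as independent Poissons with mean TPM × library_size / 1e6, the sampling
  model under which the τ index is later computed.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from ._codons import get_genetic_code
from .alignment import CodonAlignment
from .expression import ExpressionTable, build_expression_table
from .gy94 import GY94, mixture_rate
from .scan import DEFAULT_GAP_BOUNDS, GeneAnnotation, MotifPattern, scan_nucleotide

AA_NO_CYS = "ADEFGHIKLMNPQRSTVWY"
# synthetic stand-in for a conserved avian defensin signal peptide (exon 2);
# cysteine-free so it can never satisfy the mature-peptide motif
DEFAULT_SIGNAL_PEPTIDE = "MRILYLLFALLFLALQVSPG"


# ---------------------------------------------------------------------------
# gene cluster


@dataclass
class ClusterConfig:
    n_ancestral_genes: int = 8
    duplications: list = field(default_factory=list)  # (ancestral gene index, n copies)
    spacing_bp: tuple[int, int] = (2000, 8000)        # inter-gene gap, uniform
    signal_offset_mean: float = 700.0                 # bp upstream of mature peptide
    signal_offset_sd: float = 200.0
    signal_offset_cap: int = 2500
    prob_plus_strand: float = 0.5
    gc_content: float = 0.5
    signal_peptides: list = field(default_factory=lambda: [DEFAULT_SIGNAL_PEPTIDE])
    gap_bounds: tuple = DEFAULT_GAP_BOUNDS
    flank_residues: int = 3                           # residues around the motif
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ancestral_genes < 1:
            raise ValueError("need at least one gene")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        if self.signal_offset_cap > 2500:
            raise ValueError("signal offsets beyond 2500 bp are outside the search contract")
        lo, hi = self.spacing_bp
        if lo < 1 or hi <= lo:
            raise ValueError("inter-gene spacing bounds must satisfy 0 < lo < hi")
        for _, count in self.duplications:
            if count < 0:
                raise ValueError("duplication counts must be >= 0")


@dataclass
class ClusterTruth:
    chromosome_id: str
    sequence: str
    annotations: list            # GeneAnnotation per planted gene
    mature_peptides: dict        # locus_id -> amino-acid sequence
    signal_peptides: dict        # locus_id -> amino-acid sequence
    motif_spans: dict            # locus_id -> (start, end, strand) of the 6-cysteine core


def _random_codon(rng: np.random.Generator, aa: str, code) -> str:
    options = [c for c, a in zip(code.codons, code.amino_acids) if a == aa]
    return options[rng.integers(0, len(options))]


def _encode_peptide(rng: np.random.Generator, peptide: str, code) -> str:
    return "".join(_random_codon(rng, aa, code) for aa in peptide)


def _random_mature_peptide(rng: np.random.Generator, cfg: ClusterConfig) -> str:
    gaps = [int(rng.integers(lo, hi + 1)) for lo, hi in cfg.gap_bounds]
    parts = ["".join(rng.choice(list(AA_NO_CYS), cfg.flank_residues))]
    for g in gaps:
        parts.append("C")
        parts.append("".join(rng.choice(list(AA_NO_CYS), g)))
    parts.append("C")
    parts.append("".join(rng.choice(list(AA_NO_CYS), cfg.flank_residues)))
    return "".join(parts)


def _random_background(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[c] for c in reversed(seq))


def simulate_defensin_cluster(cfg: ClusterConfig) -> ClusterTruth:
    """Plant defensin-like genes on a motif-free background chromosome.

    The background is rejection-sampled: the assembled chromosome is
    re-scanned and rebuilt (continuing the same seeded stream) until the
    motif scan recovers exactly the planted genes, so noise-free recall and
    precision against the truth annotations are 1.0 by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    code = get_genetic_code(1)
    pattern = MotifPattern(tuple(cfg.gap_bounds))

    # gene roster: ancestral genes plus verbatim duplicates
    matures = [_random_mature_peptide(rng, cfg) for _ in range(cfg.n_ancestral_genes)]
    signals = [
        cfg.signal_peptides[rng.integers(0, len(cfg.signal_peptides))]
        for _ in range(cfg.n_ancestral_genes)
    ]
    roster = [(f"locus{i + 1:03d}", matures[i], signals[i]) for i in range(cfg.n_ancestral_genes)]
    for src, count in cfg.duplications:
        for c in range(count):
            roster.append((f"locus{src + 1:03d}dup{c + 1}", matures[src], signals[src]))

    for _attempt in range(20):
        chrom_parts: list[str] = []
        annotations: list[GeneAnnotation] = []
        pos = int(rng.integers(*cfg.spacing_bp))
        chrom_parts.append(_random_background(rng, pos, cfg.gc_content))
        mature_map, signal_map, motif_map = {}, {}, {}
        for locus_id, mature_aa, signal_aa in roster:
            strand = "+" if rng.random() < cfg.prob_plus_strand else "-"
            offset = int(
                np.clip(
                    rng.normal(cfg.signal_offset_mean, cfg.signal_offset_sd),
                    len(signal_aa) * 3 + 30,
                    cfg.signal_offset_cap,
                )
            )
            signal_nt = _encode_peptide(rng, signal_aa, code)
            mature_nt = _encode_peptide(rng, mature_aa, code)
            gap_nt = _random_background(rng, offset - len(signal_nt), cfg.gc_content)
            block = signal_nt + gap_nt + mature_nt  # transcription orientation
            if strand == "+":
                sig_span = (pos, pos + len(signal_nt))
                mat_span = (pos + offset, pos + offset + len(mature_nt))
                chrom_parts.append(block)
            else:
                chrom_parts.append(_revcomp(block))
                end = pos + len(block)
                mat_span = (pos, pos + len(mature_nt))
                sig_span = (end - len(signal_nt), end)
            pos += len(block)
            spacer = int(rng.integers(*cfg.spacing_bp))
            chrom_parts.append(_random_background(rng, spacer, cfg.gc_content))
            pos += spacer
            annotations.append(
                GeneAnnotation(
                    locus_id=locus_id,
                    chromosome_id="chrSim",
                    mature_peptide_span=mat_span,
                    signal_peptide_span=sig_span,
                    strand=strand,
                )
            )
            mature_map[locus_id] = mature_aa
            signal_map[locus_id] = signal_aa
            # flanks are equal length on both sides, so the six-cysteine core
            # occupies the same forward-strand window on either strand
            motif_map[locus_id] = (
                mat_span[0] + 3 * cfg.flank_residues,
                mat_span[1] - 3 * cfg.flank_residues,
                strand,
            )
        chromosome = "".join(chrom_parts)
        hits = scan_nucleotide(chromosome, pattern, sequence_id="chrSim")
        expected = {tuple(v) for v in motif_map.values()}
        found = {(m.start, m.end, m.strand) for m in hits}
        if found == expected:
            return ClusterTruth(
                chromosome_id="chrSim",
                sequence=chromosome,
                annotations=annotations,
                mature_peptides=mature_map,
                signal_peptides=signal_map,
                motif_spans=motif_map,
            )
    raise RuntimeError("could not assemble a motif-clean background in 20 attempts")


# ---------------------------------------------------------------------------
# codon alignments under a site-class mixture


@dataclass
class EvolConfig:
    tree: str                       # newick with branch lengths (subs/codon)
    n_codons: int = 100
    kappa: float = 2.0
    class_probs: tuple = (1.0,)
    class_omegas: tuple = (0.3,)
    codon_freqs: np.ndarray | None = None  # default: uniform over sense codons
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.class_probs, dtype=float)
        if abs(probs.sum() - 1.0) > 1e-8 or (probs < 0).any():
            raise ValueError("class probabilities must be a distribution")
        if len(self.class_probs) != len(self.class_omegas):
            raise ValueError("one omega per class")
        if any(w < 0 for w in self.class_omegas):
            raise ValueError("omegas must be non-negative")
        if self.n_codons < 1 or self.kappa <= 0:
            raise ValueError("invalid n_codons or kappa")


@dataclass
class SimulatedAlignment:
    alignment: CodonAlignment
    site_classes: np.ndarray    # true mixture class per codon site
    class_omegas: np.ndarray
    tree: dendropy.Tree


def simulate_codon_alignment(cfg: EvolConfig) -> SimulatedAlignment:
    """Evolve codon sites down a tree under a GY94 ω mixture.

    Each site draws its class once (shared across the whole tree); root
    codons come from the equilibrium frequencies and children are sampled
    from exact transition matrices, with branch lengths in expected
    substitutions per codon under the mixture.
    """
    rng = np.random.default_rng(cfg.seed)
    tree = dendropy.Tree.get(data=cfg.tree, schema="newick")
    code = get_genetic_code(1)
    pi = (
        np.asarray(cfg.codon_freqs, dtype=float)
        if cfg.codon_freqs is not None
        else np.full(code.n_states, 1.0 / code.n_states)
    )
    pi = pi / pi.sum()
    gy = GY94(pi, table_id=1)
    probs = np.asarray(cfg.class_probs, dtype=float)
    omegas = np.asarray(cfg.class_omegas, dtype=float)
    eigs = [gy.eigensystem(cfg.kappa, float(w)) for w in omegas]
    scale = mixture_rate(eigs, probs)
    if scale <= 0:
        raise ValueError("mixture has zero substitution rate")

    site_classes = rng.choice(len(omegas), size=cfg.n_codons, p=probs)
    states: dict = {}
    states[tree.seed_node] = rng.choice(code.n_states, size=cfg.n_codons, p=pi)
    leaf_ids, rows = [], []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            raise ValueError("every branch needs a length")
        t = max(float(node.edge.length), 0.0) / scale
        parent_states = states[node.parent_node]
        child = np.empty(cfg.n_codons, dtype=np.int64)
        for k in range(len(omegas)):
            mask = site_classes == k
            if not mask.any():
                continue
            P = eigs[k].transition_matrix(t)
            cum = P.cumsum(axis=1)
            u = rng.random(int(mask.sum()))
            rows_p = cum[parent_states[mask]]
            child[mask] = (u[:, None] > rows_p).sum(axis=1)
        states[node] = child
        if node.is_leaf():
            leaf_ids.append(node.taxon.label)
            rows.append(child)
    aln = CodonAlignment(
        ids=leaf_ids, codon_states=np.vstack(rows), code=code
    )
    return SimulatedAlignment(
        alignment=aln, site_classes=site_classes, class_omegas=omegas, tree=tree
    )


# ---------------------------------------------------------------------------
# expression counts


@dataclass
class ExprConfig:
    expected_tpm: pd.DataFrame           # index locus, columns tissue
    library_sizes: dict
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.expected_tpm.values < 0).any():
            raise ValueError("expected TPM must be >= 0")
        if any(v <= 0 for v in self.library_sizes.values()):
            raise ValueError("library sizes must be positive")


def simulate_expression_counts(cfg: ExprConfig) -> tuple[pd.DataFrame, ExpressionTable]:
    """Poisson read counts per locus × tissue plus the assignment table.

    count[l, t] ~ Poisson(TPM[l, t] × library_size[t] / 1e6), independent
    across cells; the per-read assignment table (read_id, locus_id, tissue)
    is what the aggregation step of the pipeline consumes.
    """
    rng = np.random.default_rng(cfg.seed)
    lib = pd.Series(cfg.library_sizes).astype(int)
    tpm = cfg.expected_tpm.reindex(columns=lib.index)
    lam = tpm.values * lib.values[None, :] / 1e6
    counts = rng.poisson(lam)
    records = []
    read_no = 0
    for li, locus in enumerate(tpm.index):
        for ti, tissue in enumerate(lib.index):
            for _ in range(int(counts[li, ti])):
                records.append((f"read{read_no:07d}", locus, tissue))
                read_no += 1
    assignments = pd.DataFrame(records, columns=["read_id", "locus_id", "tissue"])
    table = build_expression_table(assignments, lib, loci=list(tpm.index))
    return assignments, table
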