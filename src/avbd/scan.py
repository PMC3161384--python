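"""Motif-based discovery of β-defensin genes.

β-defensin mature peptides are recognisable by six cysteines with a
characteristic spacing, C-X(4-6)-C-X(3-5)-C-X(9-10)-C-X(5-6)-CC, where X is
any residue. :func:`scan_protein` finds every placement of that pattern in an
amino-acid sequence; :func:`scan_nucleotide` applies it to all six reading
frames of genomic DNA; :func:`find_signal_peptide` then looks for the export
signal (exon 2 of the avian gene model) in a bounded window upstream of each
mature-peptide hit, exploiting the strong conservation of defensin signal
peptides across birds.

All coordinates are 0-based half-open internally; GFF3 export converts to
1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

from Bio.Seq import Seq

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "*"}
DEFAULT_GAP_BOUNDS = ((4, 6), (3, 5), (9, 10), (5, 6), (0, 0))
SIGNAL_SEARCH_WINDOW = 2500  # bp upstream in transcription orientation


@dataclass(frozen=True)
class MotifPattern:
    """Inter-cysteine spacing bounds of the six-cysteine defensin motif."""

    gap_bounds: tuple[tuple[int, int], ...] = DEFAULT_GAP_BOUNDS

    def __post_init__(self) -> None:
        if len(self.gap_bounds) != 5:
            raise ValueError("a six-cysteine motif has exactly five inter-cysteine gaps")
        for lo, hi in self.gap_bounds:
            if lo < 0 or lo > hi:
                raise ValueError(f"invalid gap bounds ({lo}, {hi})")

    def gap_choices(self):
        return product(*(range(lo, hi + 1) for lo, hi in self.gap_bounds))


@dataclass(frozen=True)
class MotifMatch:
    """One placement of the motif.

    For protein scans ``start``/``end`` and ``cysteine_positions`` are residue
    coordinates. For nucleotide scans they are forward-strand nucleotide
    coordinates (codon starts), with ``frame`` and ``strand`` recording the
    reading frame the match was translated in.
    """

    sequence_id: str
    start: int
    end: int
    cysteine_positions: tuple[int, ...]
    frame: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.cysteine_positions) != 6:
            raise ValueError("expected six cysteine positions")
        if list(self.cysteine_positions) != sorted(set(self.cysteine_positions)):
            raise ValueError("cysteine positions must be strictly increasing")


@dataclass(frozen=True)
class GeneAnnotation:
    """A located defensin gene: mature-peptide span plus optional signal span."""

    locus_id: str
    chromosome_id: str
    mature_peptide_span: tuple[int, int]
    strand: str = "+"
    signal_peptide_span: tuple[int, int] | None = None
    signal_identity: float | None = None

    def __post_init__(self) -> None:
        s, e = self.mature_peptide_span
        if not 0 <= s < e:
            raise ValueError("invalid mature peptide span")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


def _validate_protein(seq: str) -> str:
    seq = seq.upper()
    bad = sorted(set(seq) - AA_ALPHABET)
    if bad:
        raise ValueError(f"non-amino-acid characters in protein sequence: {bad}")
    return seq


def scan_protein(seq: str, pattern: MotifPattern | None = None, sequence_id: str = "seq") -> list[MotifMatch]:
    """All placements of the six-cysteine motif in an amino-acid sequence.

    Overlapping matches are all reported; 'X' never matches a cysteine.
    """
    pattern = pattern or MotifPattern()
    seq = _validate_protein(seq)
    cys = [i for i, a in enumerate(seq) if a == "C"]
    matches: list[MotifMatch] = []
    cys_set = set(cys)
    for c0 in cys:
        for gaps in pattern.gap_choices():
            pos = [c0]
            for g in gaps:
                pos.append(pos[-1] + g + 1)
            if pos[-1] >= len(seq):
                continue
            if all(p in cys_set for p in pos[1:]):
                matches.append(
                    MotifMatch(
                        sequence_id=sequence_id,
                        start=c0,
                        end=pos[-1] + 1,
                        cysteine_positions=tuple(pos),
                    )
                )
    matches.sort(key=lambda m: (m.start, m.end, m.cysteine_positions))
    return matches


def _translate_frame(nt: str, frame: int) -> str:
    """Frame translation where stops stay as '*' and Ns yield 'X'."""
    sub = nt[frame : frame + 3 * ((len(nt) - frame) // 3)]
    if not sub:
        return ""
    return str(Seq(sub).translate(table=1)).replace("J", "X")


def scan_nucleotide(
    seq: str,
    pattern: MotifPattern | None = None,
    sequence_id: str = "seq",
    table_id: int = 1,
) -> list[MotifMatch]:
    """Six-frame motif scan of genomic DNA.

    Matches are reported in forward-strand nucleotide coordinates; a match on
    the reverse strand carries strand '-'. Translation stops do not abort the
    scan — '*' simply never matches a cysteine.
    """
    pattern = pattern or MotifPattern()
    seq = seq.upper().replace("U", "T")
    bad = sorted(set(seq) - set("ACGTN"))
    if bad:
        raise ValueError(f"non-nucleotide characters: {bad}")
    if len(seq) < 3:
        return []
    matches: list[MotifMatch] = []
    rc = str(Seq(seq).reverse_complement())
    n = len(seq)
    for strand, text in (("+", seq), ("-", rc)):
        for frame in range(3):
            aa = _translate_frame(text, frame)
            for m in scan_protein(aa, pattern, sequence_id=sequence_id):
                # residue i of this frame occupies text[frame+3i : frame+3i+3]
                if strand == "+":
                    nt_pos = tuple(frame + 3 * p for p in m.cysteine_positions)
                    start, end = frame + 3 * m.start, frame + 3 * m.end
                else:
                    # map reverse-strand codons back to forward coordinates;
                    # a codon at rc[o:o+3] covers forward [n-o-3, n-o)
                    nt_pos = tuple(
                        sorted(n - (frame + 3 * p) - 3 for p in m.cysteine_positions)
                    )
                    start, end = n - (frame + 3 * m.end), n - (frame + 3 * m.start)
                matches.append(
                    MotifMatch(
                        sequence_id=sequence_id,
                        start=start,
                        end=end,
                        cysteine_positions=nt_pos,
                        frame=frame,
                        strand=strand,
                    )
                )
    matches.sort(key=lambda m: (m.start, m.end, m.strand, m.frame))
    return matches


def _ungapped_identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    if not a:
        return 0.0
    return sum(x == y for x, y in zip(a, b)) / len(a)


def find_signal_peptide(
    chromosome: str,
    mature: GeneAnnotation,
    references: list[str],
    max_upstream: int = SIGNAL_SEARCH_WINDOW,
    min_identity: float = 0.70,
) -> GeneAnnotation:
    """Locate the signal peptide upstream of a mature-peptide annotation.

    Scans the ``max_upstream`` bp window upstream of the mature peptide (in
    transcription orientation), in all three frames, for the subsequence of
    highest ungapped amino-acid identity to any reference signal peptide.
    The span is attached only when the best identity reaches ``min_identity``.
    """
    if not references:
        raise ValueError("at least one reference signal peptide is required")
    chromosome = chromosome.upper()
    s, e = mature.mature_peptide_span
    if not (0 <= s < e <= len(chromosome)):
        raise ValueError("mature peptide span outside chromosome")
    if mature.strand == "+":
        win_start, win_end = max(0, s - max_upstream), s
        window = chromosome[win_start:win_end]
    else:
        win_start, win_end = e, min(len(chromosome), e + max_upstream)
        window = str(Seq(chromosome[win_start:win_end]).reverse_complement())

    best = (0.0, None)  # identity, forward-strand span
    for ref in references:
        ref = _validate_protein(ref)
        m = len(ref)
        for frame in range(3):
            aa = _translate_frame(window, frame)
            for i in range(0, len(aa) - m + 1):
                ident = _ungapped_identity(aa[i : i + m], ref)
                if ident > best[0]:
                    lo = frame + 3 * i
                    hi = lo + 3 * m
                    if mature.strand == "+":
                        span = (win_start + lo, win_start + hi)
                    else:
                        span = (win_end - hi, win_end - lo)
                    best = (ident, span)
    identity, span = best
    if span is not None and identity >= min_identity:
        return replace(mature, signal_peptide_span=span, signal_identity=identity)
    return replace(mature, signal_peptide_span=None, signal_identity=identity or None)


@dataclass
class ClusterSummary:
    chromosome_id: str
    n_genes: int
    span_bp: int
    strand_counts: dict = field(default_factory=dict)


def annotate_cluster(annotations: list[GeneAnnotation]) -> tuple[ClusterSummary, list[str]]:
    """Summarise a gene cluster and emit its GFF3 records.

    Returns the summary (gene count, cluster span in bp, per-strand counts)
    and GFF3 lines: one gene row per annotation plus mature-peptide and
    signal-peptide subfeatures.
    """
    if not annotations:
        raise ValueError("no annotations")
    chroms = {a.chromosome_id for a in annotations}
    if len(chroms) != 1:
        raise ValueError(f"annotations span multiple chromosomes: {sorted(chroms)}")
    (chrom,) = chroms

    def full_span(a: GeneAnnotation) -> tuple[int, int]:
        spans = [a.mature_peptide_span] + (
            [a.signal_peptide_span] if a.signal_peptide_span else []
        )
        return min(s for s, _ in spans), max(e for _, e in spans)

    starts = [full_span(a)[0] for a in annotations]
    ends = [full_span(a)[1] for a in annotations]
    summary = ClusterSummary(
        chromosome_id=chrom,
        n_genes=len(annotations),
        span_bp=max(ends) - min(starts),
        strand_counts={
            "+": sum(a.strand == "+" for a in annotations),
            "-": sum(a.strand == "-" for a in annotations),
        },
    )
    lines = ["##gff-version 3"]

    def row(type_, span, a, parent=None):
        s, e = span
        attrs = f"ID={a.locus_id}.{type_};Parent={a.locus_id}" if parent else f"ID={a.locus_id}"
        return "\t".join(
            [chrom, "avbd", type_, str(s + 1), str(e), ".", a.strand, ".", attrs]
        )

    for a in sorted(annotations, key=lambda x: full_span(x)):
        lines.append(row("gene", full_span(a), a))
        if a.signal_peptide_span:
            lines.append(row("signal_peptide", a.signal_peptide_span, a, parent=True))
        lines.append(row("mature_peptide", a.mature_peptide_span, a, parent=True))
    return summary, lines
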