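"""In-frame codon alignments.

A :class:`CodonAlignment` stores an aligned set of coding sequences as a
matrix of sense-codon indices (gap or ambiguous codons encoded as -1).
Rows are sequences, columns are codon sites. Internal stop codons are
rejected at construction: β-defensin exons, like any protein-coding data
fed to a codon model, must be stop-free in frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

from ._codons import GeneticCode, get_genetic_code

GAP_STATE = -1


@dataclass
class CodonAlignment:
    ids: list[str]
    codon_states: np.ndarray  # (n_seqs, n_sites) int, -1 for gap/ambiguous
    code: GeneticCode

    def __post_init__(self) -> None:
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("duplicate sequence ids in alignment")
        if self.codon_states.ndim != 2 or self.codon_states.shape[0] != len(self.ids):
            raise ValueError("codon_states shape does not match ids")

    @property
    def n_seqs(self) -> int:
        return self.codon_states.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codon_states.shape[1]

    @classmethod
    def from_sequences(
        cls,
        ids: list[str],
        sequences: list[str],
        table_id: int = 1,
        allow_final_stop: bool = True,
    ) -> "CodonAlignment":
        code = get_genetic_code(table_id)
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must share one length")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError(f"alignment length {length} is not a multiple of 3")
        n_sites = length // 3
        states = np.full((len(sequences), n_sites), GAP_STATE, dtype=np.int64)
        for r, seq in enumerate(sequences):
            seq = seq.upper().replace("U", "T")
            for s in range(n_sites):
                codon = seq[3 * s : 3 * s + 3]
                if "-" in codon:
                    if codon != "---":
                        raise ValueError(
                            f"partial codon gap {codon!r} in {ids[r]} at site {s}; "
                            "gaps must span whole codons"
                        )
                    continue
                if code.is_stop(codon):
                    if allow_final_stop and s == n_sites - 1:
                        continue  # treated as missing, not part of the peptide
                    raise ValueError(f"internal stop codon {codon} in {ids[r]} at site {s}")
                states[r, s] = code.index.get(codon, GAP_STATE)
        return cls(ids=list(ids), codon_states=states, code=code)

    @classmethod
    def from_fasta(cls, path, table_id: int = 1) -> "CodonAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls.from_sequences(
            [r.id for r in records], [str(r.seq) for r in records], table_id=table_id
        )

    def sequence(self, i: int) -> str:
        """Reconstruct row i as nucleotide text ('---' for gap codons)."""
        out = []
        for s in self.codon_states[i]:
            out.append("---" if s == GAP_STATE else self.code.codons[int(s)])
        return "".join(out)

    def subset(self, ids: list[str]) -> "CodonAlignment":
        pos = {sid: k for k, sid in enumerate(self.ids)}
        rows = [pos[i] for i in ids]
        return CodonAlignment(
            ids=list(ids), codon_states=self.codon_states[rows].copy(), code=self.code
        )

    def resample_sites(self, rng: np.random.Generator) -> "CodonAlignment":
        """Bootstrap replicate: codon columns drawn with replacement."""
        cols = rng.integers(0, self.n_sites, size=self.n_sites)
        return CodonAlignment(
            ids=list(self.ids), codon_states=self.codon_states[:, cols].copy(), code=self.code
        )

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, sid in enumerate(self.ids):
                fh.write(f">{sid}\n{self.sequence(i)}\n")

    def pairwise_ungapped(self, i: int, j: int) -> tuple[np.ndarray, np.ndarray]:
        """Codon states of rows i, j restricted to sites where both are ungapped."""
        a, b = self.codon_states[i], self.codon_states[j]
        keep = (a >= 0) & (b >= 0)
        return a[keep], b[keep]
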