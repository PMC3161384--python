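"""Published reference values for the zebra finch β-defensin cluster.

Small constants transcribed from the published expression and selection
survey of the 22-gene zebra finch AvBD cluster: the per-tissue TPM table of
the nine expressed loci from the 454 cDNA screen (with per-tissue library
sizes and the reported τ values), and the site-model log-likelihoods of the
cluster-B positive-selection analysis. These are *inputs* for re-deriving
the downstream statistics (read counts, τ, likelihood-ratio tests); the
underlying reads and alignments are not redistributed here.
"""

from __future__ import annotations

import pandas as pd

TISSUES = ["embryo", "liver", "muscle", "skin", "spleen", "testes"]

LIBRARY_SIZES = {
    "embryo": 323897,
    "liver": 392890,
    "muscle": 325646,
    "skin": 252349,
    "spleen": 287902,
    "testes": 299755,
}

# TPM per tissue as printed (1 decimal); τ as printed, None where the locus
# had ≤ 3 reads in total and the estimate was discarded
REPORTED_TPM = {
    "AvBD2": [0.0, 7.6, 0.0, 83.2, 59.0, 0.0],
    "AvBD7": [0.0, 0.0, 0.0, 0.0, 13.9, 0.0],
    "AvBD8": [3.1, 7.6, 0.0, 0.0, 0.0, 0.0],
    "AvBD9": [6.2, 4357.5, 0.0, 4.0, 41.7, 23.4],
    "AvBD10": [43.2, 1338.8, 0.0, 4.0, 3.5, 20.0],
    "AvBD13": [0.0, 0.0, 0.0, 7.9, 0.0, 0.0],
    "AvBD115": [0.0, 0.0, 0.0, 0.0, 6.9, 0.0],
    "AvBD123": [0.0, 0.0, 0.0, 0.0, 0.0, 3.3],
    "AvBD125": [0.0, 0.0, 0.0, 0.0, 6.9, 0.0],
}

REPORTED_TAU = {
    "AvBD2": 0.630,
    "AvBD7": 0.737,
    "AvBD8": 0.616,
    "AvBD9": 0.743,
    "AvBD10": 0.720,
    "AvBD13": None,
    "AvBD115": None,
    "AvBD123": None,
    "AvBD125": None,
}

TOTAL_MAPPED_READS = 2338

# log-likelihoods of the site-class models fitted to the duplicated cluster B
SITE_MODEL_LOGLIK = {
    "M1a": -966.38,
    "M2a": -954.24,
    "M8a": -966.38,
    "M7": -967.36,
    "M8": -957.15,
}


def expression_survey() -> tuple[pd.DataFrame, pd.Series]:
    """Reported TPM table (loci × tissues) and library sizes as pandas objects."""
    tpm = pd.DataFrame.from_dict(REPORTED_TPM, orient="index", columns=TISSUES)
    lib = pd.Series(LIBRARY_SIZES)[TISSUES]
    return tpm, lib
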