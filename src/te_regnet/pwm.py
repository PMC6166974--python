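"""PWM log-odds scanning of TE insertion-junction sequences.

A transcription-factor motif is a position x {A,C,G,T} probability matrix.
Scores are log2-odds of the (pseudocount-smoothed) motif probability over
a background base composition, summed over the window; a hit is any window
on either strand scoring at or above the threshold (default 8, the common
log-odds cutoff for curated PWM collections).  Upstream of scanning, TFs
are restricted to those expressed at >= 10 TPM in every sample, so only
factors actually present in the tissue are scanned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import TEElement
from .expression import ExpressionMatrix

__all__ = [
    "PWM",
    "MotifHit",
    "filter_expressed_tfs",
    "logodds_from_pwm",
    "scan_sequence",
    "junction_sequence",
    "reverse_complement",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Position probability matrix with background and smoothing.

    ``probabilities`` has shape (length, 4) in A, C, G, T order and each
    row sums to 1; ``background`` is the genomic base composition used in
    the log-odds denominator; ``pseudocount`` is the background-
    proportional probability mass mixed into each cell to avoid -inf
    scores on zero entries.
    """

    tf_name: str
    probabilities: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probabilities.ndim != 2 or self.probabilities.shape[1] != 4:
            raise ValueError(f"{self.tf_name}: probabilities must be L x 4")
        if not np.allclose(self.probabilities.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"{self.tf_name}: each position must sum to 1")
        if (self.background <= 0).any():
            raise ValueError("background frequencies must be strictly positive")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return self.probabilities.shape[0]


@dataclass(frozen=True)
class MotifHit:
    tf_name: str
    sequence_id: str
    offset: int  # 0-based window start on the forward sequence
    strand: str
    score: float  # bits (log2 odds)


def filter_expressed_tfs(
    expr: ExpressionMatrix,
    tf_ids,
    min_tpm: float = 10.0,
) -> set[str]:
    """TFs whose minimum TPM across ALL samples is >= min_tpm (boundary
    inclusive).  Ids absent from the matrix are dropped with a warning."""
    import logging
    tf_ids = list(dict.fromkeys(tf_ids))
    known = [t for t in tf_ids if t in expr.gene_ids]
    if len(known) < len(tf_ids):
        logging.getLogger(__name__).warning(
            "%d TF ids not in expression matrix; dropped", len(tf_ids) - len(known))
    if not known:
        return set()
    mins = expr.values.loc[known].min(axis=1)
    return set(mins.index[mins >= min_tpm])


def logodds_from_pwm(pwm: PWM) -> np.ndarray:
    """Position x base log2-odds score matrix (bits).

    score(i, b) = log2( ((p_ib + c*bg_b) / (1 + c)) / bg_b )
    with pseudocount c applied as background-proportional smoothing.
    """
    c = pwm.pseudocount
    smoothed = (pwm.probabilities + c * pwm.background) / (1.0 + c)
    return np.log2(smoothed / pwm.background)


def scan_sequence(
    sequence: str,
    lod: np.ndarray,
    threshold: float = 8.0,
    both_strands: bool = True,
    sequence_id: str = "seq",
    tf_name: str = "motif",
) -> list[MotifHit]:
    """Score every window of the sequence with a log-odds matrix and emit
    hits with score >= threshold, sorted by (sequence_id, offset, strand).

    Windows containing N (or any non-ACGT letter) are skipped.  The minus-
    strand score of a window is the plus-strand score of its reverse
    complement; the reported offset is always on the forward sequence.
    """
    seq = sequence.upper()
    L = lod.shape[0]
    n = len(seq)
    hits: list[MotifHit] = []
    if n < L:
        return hits
    codes = np.fromiter((_BASE_INDEX.get(ch, -1) for ch in seq), dtype=np.int64, count=n)
    lod_rc = lod[::-1, ::-1]  # minus-strand scoring matrix on forward bases
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (windows >= 0).all(axis=1)
    for off in np.nonzero(valid)[0]:
        w = windows[off]
        # left-to-right accumulation: scores reproduce a per-position
        # scalar evaluation bit for bit
        score = sum(float(lod[i, w[i]]) for i in range(L))
        if score >= threshold:
            hits.append(MotifHit(tf_name, sequence_id, int(off), "+", score))
        if both_strands:
            # accumulate in the reverse-complement window's own 5'->3'
            # order so the score is bit-identical to scoring that window
            score_rc = sum(float(lod_rc[i, w[i]]) for i in reversed(range(L)))
            if score_rc >= threshold:
                hits.append(MotifHit(tf_name, sequence_id, int(off), "-", score_rc))
    hits.sort(key=lambda h: (h.sequence_id, h.offset, h.strand))
    return hits


def junction_sequence(
    element: TEElement,
    contigs: dict[str, str],
    flank_bp: int,
) -> str:
    """Sequence spanning the TE's 5' insertion junction: ``flank_bp`` of
    flanking DNA followed by the first ``flank_bp`` of the element, strand-
    adjusted (minus-strand elements return the reverse complement of the
    mirrored window)."""
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    if flank_bp == 0:
        return ""
    if element.chrom not in contigs:
        raise KeyError(f"contig {element.chrom!r} not in genome")
    contig = contigs[element.chrom]
    if element.strand == "-":
        lo, hi = element.end - flank_bp, element.end + flank_bp
    else:
        lo, hi = element.start - flank_bp, element.start + flank_bp
    if lo < 0 or hi > len(contig):
        raise ValueError(
            f"junction window [{lo}, {hi}) of {element.te_id} outside contig "
            f"{element.chrom} (length {len(contig)})")
    window = contig[lo:hi].upper()
    return reverse_complement(window) if element.strand == "-" else window
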