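"""Six-frame longest-ORF prediction and a composition-preserving shuffling null.

Assembled 454 contigs are partial cDNAs, so an "ORF" here is the longest
maximal run of consecutive stop-free codons over all six reading frames —
no start codon is required and runs may abut the sequence ends.  Whether
observed ORF lengths exceed chance is assessed by shuffling each sequence
(preserving its base composition, hence GC content) and recomputing the
statistic, giving a one-sided permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import SequenceRecord

_STOPS = frozenset(("TAA", "TAG", "TGA"))
_RC = str.maketrans("ACGTN", "TGCAN")

#: frame scan order used for tie-breaking
_FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class OrfResult:
    """Longest stop-free codon run of one record.

    ``start``/``end`` are 1-based inclusive on the *forward* strand of the
    input; the frame sign carries the strand.  A sequence with no complete
    codon in any frame gets length 0 (start = end = 0, frame +1).
    """

    record_id: str | None
    frame: int
    start: int
    end: int
    length: int


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _best_run(codes: np.ndarray, offset: int, prefer_last: bool) -> tuple[int, int]:
    """Longest maximal stop-free codon run in one frame.

    Returns (codon_start, n_codons); (0, 0) if the frame holds no complete
    non-stop codon.  Codons containing N never count as stops.  Among
    equally long runs the first is taken, or the last when ``prefer_last``
    (reverse frames: the last run on the reverse complement is the one with
    the smallest forward-strand start).
    """
    n_codons = (codes.size - offset) // 3
    if n_codons <= 0:
        return 0, 0
    tri = codes[offset : offset + 3 * n_codons].reshape(n_codons, 3)
    c0, c1, c2 = tri[:, 0], tri[:, 1], tri[:, 2]
    # TAA, TAG, TGA with A=0, G=2, T=3
    stop = (c0 == 3) & (
        ((c1 == 0) & ((c2 == 0) | (c2 == 2))) | ((c1 == 2) & (c2 == 0))
    )
    bounds = np.concatenate(([-1], np.flatnonzero(stop), [n_codons]))
    lengths = np.diff(bounds) - 1
    if prefer_last:
        bi = int(lengths.size - 1 - lengths[::-1].argmax())
    else:
        bi = int(lengths.argmax())
    if lengths[bi] == 0:
        return 0, 0
    return int(bounds[bi]) + 1, int(lengths[bi])


def longest_orf(sequence: str, record_id: str | None = None) -> OrfResult:
    """Longest maximal stop-free codon run over all six frames.

    Stops are TAA, TAG, TGA; codons containing N are treated as non-stop.
    The terminating stop codon is not part of the run.  Ties are broken by
    frame order +1, +2, +3, -1, -2, -3, then by smallest forward-strand
    start.
    """
    seq = sequence.upper()
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if seq and not (set(seq) <= set("ACGTN")):
        raise ValueError("sequence must be over ACGTN")
    L = len(seq)
    rc_codes = (3 - codes.astype(np.int8))[::-1]  # N (4) maps to -1, also non-stop
    rc_codes = np.where(rc_codes < 0, 4, rc_codes).astype(np.uint8)
    best: tuple[int, int, int] | None = None  # (-length, frame_idx, fwd_start)
    best_coords = (0, 0)
    for fi, frame in enumerate(_FRAMES):
        work = codes if frame > 0 else rc_codes
        offset = abs(frame) - 1
        run_start, run_len = _best_run(work, offset, prefer_last=frame < 0)
        if run_len == 0:
            continue
        length = 3 * run_len
        w_start = offset + 3 * run_start  # 0-based on `work`
        w_end = w_start + length - 1
        if frame > 0:
            f_start, f_end = w_start + 1, w_end + 1
        else:
            f_start, f_end = L - w_end, L - w_start
        key = (-length, fi, f_start)
        if best is None or key < best:
            best = key
            best_coords = (f_start, f_end)
    if best is None:
        return OrfResult(record_id, 1, 0, 0, 0)
    length = -best[0]
    return OrfResult(record_id, _FRAMES[best[1]], best_coords[0], best_coords[1], length)


def shuffle_sequence(sequence: str, rng: np.random.Generator) -> str:
    """Uniform random permutation of the nucleotides (composition preserved)."""
    if not sequence:
        raise ValueError("empty sequence")
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return rng.permutation(arr).tobytes().decode("ascii")


@dataclass
class NullTestResult:
    """Observed statistic vs its shuffling null.

    ``p_value`` is the one-sided permutation p, (1 + #{null >= observed}) /
    (n_shuffles + 1).
    """

    observed_fraction: float
    null_fractions: list
    p_value: float
    n_shuffles: int
    threshold: int
    statistic: str


def orf_null_test(
    records: Sequence[SequenceRecord],
    threshold: int = 90,
    n_shuffles: int = 100,
    rng: np.random.Generator | None = None,
    statistic: str = "fraction",
) -> NullTestResult:
    """Compare observed longest-ORF lengths with those of shuffled sequences.

    ``statistic`` is either ``"fraction"`` (share of records whose longest
    ORF is at least ``threshold`` nt — the headline number) or
    ``"mean_length"`` (mean longest-ORF length, threshold ignored).
    """
    if not records:
        raise ValueError("no records supplied")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if statistic not in ("fraction", "mean_length"):
        raise ValueError("statistic must be 'fraction' or 'mean_length'")
    rng = rng if rng is not None else np.random.default_rng()

    def stat(seqs):
        lengths = [longest_orf(s).length for s in seqs]
        if statistic == "fraction":
            return sum(l >= threshold for l in lengths) / len(lengths)
        return float(np.mean(lengths))

    observed = stat([r.sequence for r in records])
    nulls = []
    for _ in range(n_shuffles):
        nulls.append(stat([shuffle_sequence(r.sequence, rng) for r in records]))
    exceed = sum(v >= observed for v in nulls)
    p = (1 + exceed) / (n_shuffles + 1)
    return NullTestResult(
        observed_fraction=observed,
        null_fractions=nulls,
        p_value=p,
        n_shuffles=n_shuffles,
        threshold=threshold,
        statistic=statistic,
    )


def predict_orfs(records: Sequence[SequenceRecord]) -> list[OrfResult]:
    """Longest ORF per record."""
    return [longest_orf(r.sequence, record_id=r.id) for r in records]
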