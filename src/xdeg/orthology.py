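"""Pairwise sequence search and reciprocal-best-hit ortholog pairing.

The internal search is a desk-scale stand-in for megablast-style nucleotide
search: exact k-mer seeds, ungapped bidirectional x-drop extension with
match +1 / mismatch -2, and best-segment reporting per query/subject pair.
It carries no e-value statistics (the ``evalue`` column is 0 for internal
hits); externally computed hit tables can be substituted wherever a list of
:class:`~xdeg.io_formats.HitRecord` is accepted, and are then filtered by
the e-value threshold instead.

The hot loops (seed lookup, diagonal grouping, x-drop extension) are
compiled with numba; sequences are packed into sentinel-padded uint8 arrays
so the extension scans need no bounds checks — a run of sentinels always
triggers the x-drop stop before a scan can cross a sequence boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from numba import njit

from .io_formats import HitRecord, SequenceRecord

# base encoding: A,C,G,T -> 0..3, N -> 4, sentinel 5 never matches anything
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
_ENC[ord("N")] = 4
_COMP = np.array([3, 2, 1, 0, 4, 5], dtype=np.uint8)

_MAX_TABLE_CODES = 1 << 24  # direct-address seed table up to k = 12


@dataclass
class SearchParams:
    """Thresholds for the internal search and for external hit filtering.

    ``max_evalue_external`` reproduces the cross-species search threshold
    used on real data (1e-15); it only applies to hits that carry a genuine
    e-value, i.e. externally supplied tables.
    """

    k: int = 11
    min_aln_length: int = 50
    min_pct_identity: float = 80.0
    max_evalue_external: float = 1e-15
    xdrop: int = 10

    def __post_init__(self) -> None:
        if self.k < 4:
            raise ValueError("seed size k must be >= 4")
        if self.min_aln_length < 1 or self.max_evalue_external <= 0 or self.xdrop < 1:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class BestHit:
    subject_id: str
    score: float
    evalue: float
    pct_identity: float
    aln_length: int


@dataclass(frozen=True)
class OrthologPair:
    """Reciprocal-best-hit pair carrying the read counts of both orthologs."""

    id_a: str
    id_b: str
    reads_a: int
    reads_b: int
    pct_identity: float
    aln_length: int


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _kmer_scan(arr, k, out_codes, out_pos):
    """Rolling k-mer codes over an encoded sequence; windows with any
    non-ACGT symbol are skipped.  Returns the number of valid windows."""
    mask = (1 << (2 * k)) - 1
    code = 0
    run = 0  # consecutive plain bases ending here
    n = 0
    for i in range(arr.size):
        b = arr[i]
        if b < 4:
            code = ((code << 2) | b) & mask
            run += 1
        else:
            run = 0
        if run >= k:
            out_codes[n] = code
            out_pos[n] = i - k + 1
            n += 1
    return n


@njit(cache=True, inline="always")
def _extend_side(q, s, qi, si, step, xdrop):
    """Greedy x-drop scan from (qi, si) moving by ``step``.

    Returns (gain, length, matches) of the best extension.  Sentinel padding
    guarantees the loop terminates inside the arrays.
    """
    best = 0
    best_len = 0
    best_m = 0
    cur = 0
    m = 0
    i = 0
    while True:
        qb = q[qi + step * i]
        sb = s[si + step * i]
        if qb == sb and qb < 4:
            cur += 1
            m += 1
        else:
            cur -= 2
        if cur > best:
            best = cur
            best_len = i + 1
            best_m = m
        if best - cur > xdrop:
            break
        i += 1
    return best, best_len, best_m


@njit(cache=True)
def _scan_query(
    qmega,
    k,
    xdrop,
    table_off,
    table_cnt,
    ucodes,
    uoff,
    ucnt,
    sid_sorted,
    spos_sorted,
    scat,
    offsets,
):
    """All best-per-subject ungapped segments for one (two-strand) query.

    ``qmega`` holds both query strands separated by sentinel runs.  Seeds
    are grouped by (subject, diagonal); the leftmost seed of each group is
    extended, later seeds are re-extended only if they fall outside the
    segment already found on that diagonal.  Returns columns
    (sid, score, qs, qe, ss, se, matches) of the best candidate per subject.
    """
    codes = np.empty(qmega.size, dtype=np.int64)
    pos = np.empty(qmega.size, dtype=np.int64)
    nk = _kmer_scan(qmega, k, codes, pos)

    # count matches
    total = 0
    for i in range(nk):
        c = codes[i]
        if table_off.size > 0:
            if table_off[c] >= 0:
                total += table_cnt[c]
        else:
            j = np.searchsorted(ucodes, c)
            if j < ucodes.size and ucodes[j] == c:
                total += ucnt[j]
    if total == 0:
        return np.empty((7, 0), dtype=np.int64)

    m_sid = np.empty(total, dtype=np.int64)
    m_spos = np.empty(total, dtype=np.int64)
    m_qpos = np.empty(total, dtype=np.int64)
    w = 0
    for i in range(nk):
        c = codes[i]
        if table_off.size > 0:
            off = table_off[c]
            cnt = table_cnt[c] if off >= 0 else 0
        else:
            j = np.searchsorted(ucodes, c)
            if j < ucodes.size and ucodes[j] == c:
                off = uoff[j]
                cnt = ucnt[j]
            else:
                cnt = 0
        for t in range(cnt):
            m_sid[w] = sid_sorted[off + t]
            m_spos[w] = spos_sorted[off + t]
            m_qpos[w] = pos[i]
            w += 1

    # sort by (sid, diagonal, qpos) via one composite key
    stride_q = qmega.size + 1
    stride_d = (qmega.size + scat.size + 1) * stride_q
    key = m_sid * stride_d + (m_qpos - m_spos + scat.size) * stride_q + m_qpos
    order = np.argsort(key)

    out = np.empty((7, total), dtype=np.int64)
    n_out = 0
    cur_sid = np.int64(-1)
    cur_diag = np.int64(0)
    seg_qe = np.int64(-1)
    have_cur = False
    # best for the subject currently being scanned
    b_score = np.int64(-1)

    for oi in range(total):
        idx = order[oi]
        sid = m_sid[idx]
        qpos = m_qpos[idx]
        spos = m_spos[idx]
        diag = qpos - spos
        if sid != cur_sid:
            if have_cur:
                n_out += 1
            cur_sid = sid
            cur_diag = diag
            seg_qe = np.int64(-1)
            have_cur = False
            b_score = np.int64(-1)
        elif diag != cur_diag:
            cur_diag = diag
            seg_qe = np.int64(-1)
        if qpos + k - 1 <= seg_qe:
            continue  # seed lies inside the segment already found here
        gq = qpos
        gs = spos + offsets[sid]
        rg, rl, rm = _extend_side(qmega, scat, gq + k, gs + k, 1, xdrop)
        lg, ll, lm = _extend_side(qmega, scat, gq - 1, gs - 1, -1, xdrop)
        score = k + lg + rg
        seg_qe = qpos + k - 1 + rl
        if score > b_score:
            b_score = score
            out[0, n_out] = sid
            out[1, n_out] = score
            out[2, n_out] = qpos - ll
            out[3, n_out] = seg_qe
            out[4, n_out] = spos - ll
            out[5, n_out] = spos + k - 1 + rl
            out[6, n_out] = k + lm + rm
            have_cur = True
    if have_cur:
        n_out += 1
    return out[:, :n_out]


def kmer_search(
    queries: Sequence[SequenceRecord],
    subjects: Sequence[SequenceRecord],
    params: SearchParams | None = None,
) -> list[HitRecord]:
    """Seeded ungapped search of every query against every subject.

    For each query/subject pair sharing at least one exact k-mer (on either
    strand of the query) the best-scoring ungapped segment found by x-drop
    extension is reported, then suppressed if shorter than
    ``min_aln_length`` or below ``min_pct_identity``.  The ``bitscore``
    column carries the raw +1/-2 segment score and ``evalue`` is 0.
    """
    params = params or SearchParams()
    k, xdrop = params.k, params.xdrop
    if not queries or not subjects:
        return []
    shortest = min(min(len(r) for r in queries), min(len(r) for r in subjects))
    if k > shortest:
        raise ValueError(f"k={k} exceeds the shortest sequence length {shortest}")

    pad = xdrop // 2 + 2  # sentinel run long enough to force an x-drop stop
    gap = np.full(pad, 5, dtype=np.uint8)

    # concatenated subject arrays separated by sentinel gaps
    sub_arrays = [_encode(r.sequence) for r in subjects]
    pieces = [gap]
    offsets = np.empty(len(subjects), dtype=np.int64)
    pos = pad
    for i, arr in enumerate(sub_arrays):
        offsets[i] = pos
        pieces.append(arr)
        pieces.append(gap)
        pos += arr.size + pad
    scat = np.concatenate(pieces)

    # global k-mer index over all subjects, sorted by code
    code_parts, sid_parts, spos_parts = [], [], []
    for i, arr in enumerate(sub_arrays):
        if arr.size < k:
            continue
        codes = np.empty(arr.size, dtype=np.int64)
        posv = np.empty(arr.size, dtype=np.int64)
        n = _kmer_scan(arr, k, codes, posv)
        code_parts.append(codes[:n].copy())
        sid_parts.append(np.full(n, i, dtype=np.int64))
        spos_parts.append(posv[:n].copy())
    codes_all = np.concatenate(code_parts)
    order = np.argsort(codes_all, kind="stable")
    sid_sorted = np.concatenate(sid_parts)[order]
    spos_sorted = np.concatenate(spos_parts)[order]
    ucodes, uoff, ucnt = np.unique(
        codes_all[order], return_index=True, return_counts=True
    )
    n_codes = 1 << (2 * k)
    if n_codes <= _MAX_TABLE_CODES:
        # direct-address table: code -> (offset, count) in the sorted index
        table_off = np.full(n_codes, -1, dtype=np.int64)
        table_cnt = np.zeros(n_codes, dtype=np.int64)
        table_off[ucodes] = uoff
        table_cnt[ucodes] = ucnt
    else:
        table_off = np.empty(0, dtype=np.int64)
        table_cnt = np.empty(0, dtype=np.int64)

    # composite sort key must fit in int64
    max_q = 2 * (max(len(r) for r in queries)) + 3 * pad + 2
    if len(subjects) * (max_q + scat.size + 1) * (max_q + 1) >= 2**62:
        raise ValueError("dataset too large for the composite seed sort key")

    hits: list[HitRecord] = []
    for qrec in queries:
        fwd = _encode(qrec.sequence)
        lq = fwd.size
        rc = _COMP[fwd][::-1]
        qmega = np.concatenate([gap, fwd, gap, rc, gap])
        rc_off = pad + lq + pad  # start of the reverse strand block
        cand = _scan_query(
            qmega, k, xdrop, table_off, table_cnt, ucodes, uoff, ucnt,
            sid_sorted, spos_sorted, scat, offsets,
        )
        if cand.shape[1] == 0:
            continue
        length = cand[3] - cand[2] + 1
        ident = 100.0 * cand[6] / length
        keep = (length >= params.min_aln_length) & (ident >= params.min_pct_identity)
        for sid, score, qs, qe, ss, se, matches in cand[:, keep].T:
            length_i = int(qe - qs + 1)
            ss_l, se_l = int(ss), int(se)  # subject positions are subject-local
            if qs >= rc_off:
                # segment found on the reverse complement of the query
                qs_l, qe_l = int(qs - rc_off), int(qe - rc_off)
                q_start, q_end = lq - qe_l, lq - qs_l
                s_start, s_end = se_l + 1, ss_l + 1
            else:
                q_start, q_end = int(qs - pad) + 1, int(qe - pad) + 1
                s_start, s_end = ss_l + 1, se_l + 1
            hits.append(
                HitRecord(
                    query_id=qrec.id,
                    subject_id=subjects[int(sid)].id,
                    pct_identity=round(100.0 * int(matches) / length_i, 2),
                    aln_length=length_i,
                    mismatches=length_i - int(matches),
                    gap_opens=0,
                    q_start=q_start,
                    q_end=q_end,
                    s_start=s_start,
                    s_end=s_end,
                    evalue=0.0,
                    bitscore=float(score),
                )
            )
    return hits


def best_hits(hits: Iterable[HitRecord]) -> dict[str, BestHit]:
    """Best subject per query: max score, ties by min e-value then subject id."""
    best: dict[str, BestHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if (
            cur is None
            or h.bitscore > cur.score
            or (
                h.bitscore == cur.score
                and (h.evalue, h.subject_id) < (cur.evalue, cur.subject_id)
            )
        ):
            best[h.query_id] = BestHit(
                h.subject_id, h.bitscore, h.evalue, h.pct_identity, h.aln_length
            )
    return best


def reciprocal_best_hits(
    map_ab: Mapping[str, BestHit],
    map_ba: Mapping[str, BestHit],
    records_a: Sequence[SequenceRecord],
    records_b: Sequence[SequenceRecord],
) -> list[OrthologPair]:
    """Pairs (a, b) where a's best hit is b and b's best hit is a."""
    by_id_a = {r.id: r for r in records_a}
    by_id_b = {r.id: r for r in records_b}
    pairs = []
    for a, hit in map_ab.items():
        if a not in by_id_a:
            raise KeyError(f"query id {a!r} not among species-A records")
        b = hit.subject_id
        if b not in by_id_b:
            raise KeyError(f"subject id {b!r} not among species-B records")
        back = map_ba.get(b)
        if back is not None and back.subject_id == a:
            pairs.append(
                OrthologPair(
                    id_a=a,
                    id_b=b,
                    reads_a=by_id_a[a].read_count,
                    reads_b=by_id_b[b].read_count,
                    pct_identity=hit.pct_identity,
                    aln_length=hit.aln_length,
                )
            )
    pairs.sort(key=lambda p: p.id_a)
    return pairs


def transpose_hits(hits: Iterable[HitRecord]) -> list[HitRecord]:
    """Swap query and subject roles of each hit.

    The ungapped +1/-2 score is symmetric, so a search in the opposite
    direction finds the same segments; this lets one all-vs-all search stand
    in for both directions.  Minus-strand orientation is preserved by keeping
    the descending coordinate pair on the subject side.
    """
    out = []
    for h in hits:
        minus = h.s_start > h.s_end
        out.append(
            HitRecord(
                query_id=h.subject_id,
                subject_id=h.query_id,
                pct_identity=h.pct_identity,
                aln_length=h.aln_length,
                mismatches=h.mismatches,
                gap_opens=h.gap_opens,
                q_start=min(h.s_start, h.s_end),
                q_end=max(h.s_start, h.s_end),
                s_start=h.q_end if minus else h.q_start,
                s_end=h.q_start if minus else h.q_end,
                evalue=h.evalue,
                bitscore=h.bitscore,
            )
        )
    return out


def reference_coverage(
    hits: Iterable[HitRecord], reference_lengths: Mapping[str, int]
) -> dict[str, float]:
    """Fraction of each reference covered by at least one aligned segment.

    ``hits`` map query contigs onto reference sequences (references on the
    subject side); overlapping segments are counted once.  References with
    no hits get 0.0.
    """
    intervals: dict[str, list[tuple[int, int]]] = {r: [] for r in reference_lengths}
    for h in hits:
        if h.subject_id not in reference_lengths:
            raise KeyError(f"hit subject {h.subject_id!r} not a known reference")
        lo, hi = sorted((h.s_start, h.s_end))
        if lo < 1 or hi > reference_lengths[h.subject_id]:
            raise ValueError(
                f"hit on {h.subject_id!r} spans {lo}-{hi}, outside length "
                f"{reference_lengths[h.subject_id]}"
            )
        intervals[h.subject_id].append((lo, hi))
    out = {}
    for ref, ivs in intervals.items():
        if not ivs:
            out[ref] = 0.0
            continue
        ivs.sort()
        covered = 0
        cur_lo, cur_hi = ivs[0]
        for lo, hi in ivs[1:]:
            if lo > cur_hi + 1:
                covered += cur_hi - cur_lo + 1
                cur_lo, cur_hi = lo, hi
            else:
                cur_hi = max(cur_hi, hi)
        covered += cur_hi - cur_lo + 1
        out[ref] = covered / reference_lengths[ref]
    return out
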