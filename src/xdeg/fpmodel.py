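"""Zero-truncated Poisson model of sampling zeros in PDEG sets.

A gene observed with j reads in one species but zero in the other is not
necessarily differentially expressed: with finite sequencing depth the
ortholog may simply have escaped sampling.  Because ortholog read counts are
strongly correlated across species, the probability of such a sampling zero
depends on j.  Within each conditioning bin (ortholog has j reads in species
s) the other species' counts are modeled as Poisson(λ(j, s)); zeros are
unobservable (a gene with no reads leaves no contig), so λ is estimated from
the zero-truncated likelihood.  The expected number of false-positive PDEG
calls is then

    Σ_j  k(j, s) · p(0, j, s),       p(0, j, s) = exp(-λ(j, s)),

where k(j, s) is the number of contigs with j reads in species s.  The
difference between observed PDEG counts and expected false positives, per
bin, estimates the number of genes truly expressed in one species only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .orthology import OrthologPair
from .pdeg import CoverageHistogram

_BISECT_TOL = 1e-10


def _ztp_mean(lam: float) -> float:
    # mean of the zero-truncated Poisson: lambda / (1 - exp(-lambda))
    return lam / -math.expm1(-lam)


def ztp_mle(counts: Sequence[int]) -> float:
    """Maximum-likelihood λ of a zero-truncated Poisson sample.

    The MLE solves mean(counts) = λ / (1 - e^{-λ}); the root is bracketed in
    (0, mean] and found by bisection to 1e-10 absolute tolerance.  A sample
    mean of exactly 1 sits on the boundary and yields λ = 0.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0:
        raise ValueError("empty sample")
    if (arr < 1).any():
        raise ValueError("zero-truncated counts must all be >= 1")
    m = float(arr.mean())
    if m <= 1.0:
        return 0.0
    lo, hi = 0.0, m  # ztp_mean(m) > m, ztp_mean(0+) = 1 < m
    while hi - lo > _BISECT_TOL:
        mid = 0.5 * (lo + hi)
        if _ztp_mean(mid) < m:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def ztp_sf(x: int, lam: float) -> float:
    """P(X >= x) for X ~ zero-truncated Poisson(λ), x >= 1."""
    if x <= 1:
        return 1.0
    if lam <= 0.0:
        return 0.0  # λ -> 0 degenerates to a point mass at 1
    return float(stats.poisson.sf(x - 1, lam) / -math.expm1(-lam))


def filter_outliers(
    counts: Sequence[int], tail_p: float = 1e-4, max_iter: int = 5
) -> tuple[list[int], list[int]]:
    """Iteratively drop counts far in the upper tail of their own ZTP fit.

    At each pass the sample is refit and counts whose upper-tail probability
    under the fit falls below ``tail_p`` are removed; iteration stops when a
    pass removes nothing, after ``max_iter`` passes, or when removal would
    leave fewer than two counts.
    """
    kept = list(counts)
    removed: list[int] = []
    if not kept:
        raise ValueError("empty sample")
    for _ in range(max_iter):
        lam = ztp_mle(kept)
        out = [c for c in kept if ztp_sf(c, lam) < tail_p]
        if not out:
            break
        if len(kept) - len(out) < 2:
            break
        out_set = set(out)
        removed.extend(c for c in kept if c in out_set)
        kept = [c for c in kept if c not in out_set]
    return kept, removed


@dataclass
class TruncatedPoissonFit:
    """λ(j, s) for one conditioning bin, with p0 = P(0 reads) = exp(-λ)."""

    bin_label: str  # "2".."8" or an open ">N"
    conditioning_j: int  # lower bound of the bin's conditioning read count
    is_open: bool
    target_species: str
    n_used: int
    n_outliers_removed: int
    lambda_hat: float
    p0: float
    converged: bool


def fit_bins(
    pairs: Sequence[OrthologPair],
    conditioning: str = "a",
    target_species: str = "",
    min_bin_n: int = 30,
    min_conditioning_count: int = 2,
    tail_p: float = 1e-4,
) -> list[TruncatedPoissonFit]:
    """Fit λ(j, s) per conditioning read-count bin.

    Pairs are grouped by the conditioning species' count j (``conditioning``
    selects which side of each pair conditions, ``"a"`` or ``"b"``); within a
    group the other species' counts are outlier-trimmed and ZTP-fitted.
    Walking j upward, bins stay standalone while they hold at least
    ``min_bin_n`` pairs; the first short or missing bin and everything above
    it are pooled into an open top bin.  Conditioning counts below
    ``min_conditioning_count`` (default: singletons) are excluded.
    """
    if conditioning not in ("a", "b"):
        raise ValueError("conditioning must be 'a' or 'b'")
    if not pairs:
        raise ValueError("no ortholog pairs supplied")
    groups: dict[int, list[int]] = {}
    for p in pairs:
        j = p.reads_a if conditioning == "a" else p.reads_b
        i = p.reads_b if conditioning == "a" else p.reads_a
        if j < min_conditioning_count:
            continue
        groups.setdefault(j, []).append(i)
    if not groups:
        raise ValueError("no pairs at or above the minimum conditioning count")

    standalone: list[int] = []
    j = min(groups)
    while j in groups and len(groups[j]) >= min_bin_n:
        standalone.append(j)
        j += 1
    open_min = j  # everything with conditioning count >= open_min pools here

    fits: list[TruncatedPoissonFit] = []

    def _fit(label: str, jlow: int, is_open: bool, values: list[int]) -> None:
        kept, removed = filter_outliers(values, tail_p=tail_p)
        lam = ztp_mle(kept)
        fits.append(
            TruncatedPoissonFit(
                bin_label=label,
                conditioning_j=jlow,
                is_open=is_open,
                target_species=target_species,
                n_used=len(kept),
                n_outliers_removed=len(removed),
                lambda_hat=lam,
                p0=math.exp(-lam),
                converged=True,
            )
        )

    for jj in standalone:
        _fit(str(jj), jj, False, groups[jj])
    pooled = [i for j2, vals in groups.items() if j2 >= open_min for i in vals]
    if pooled:
        _fit(f">{open_min - 1}", open_min, True, pooled)
    return fits


def expected_false_positives(
    histogram: CoverageHistogram, fits: Sequence[TruncatedPoissonFit]
) -> tuple[dict[str, float], float]:
    """Per-bin and total expected sampling-zero PDEG counts: Σ k(j,s)·p(0,j,s).

    Histogram bins pooled into the open top bin use the pooled fit; a
    histogram bin with no covering fit is an error.
    """
    by_j = {f.conditioning_j: f for f in fits if not f.is_open}
    open_fit = next((f for f in fits if f.is_open), None)
    fp: dict[str, float] = {f.bin_label: 0.0 for f in fits}
    for j, k in histogram.counts.items():
        if j in by_j:
            fp[by_j[j].bin_label] += k * by_j[j].p0
        elif open_fit is not None and j >= open_fit.conditioning_j:
            fp[open_fit.bin_label] += k * open_fit.p0
        else:
            raise ValueError(f"histogram bin j={j} has no covering fit")
    return fp, sum(fp.values())


@dataclass
class FPTableRow:
    bin_label: str
    observed_pdeg: int
    expected_fp: float
    expected_de: float
    expected_de_raw: float  # observed - FP before clipping at zero


@dataclass
class FalsePositiveTable:
    """Per-bin observed PDEG, expected false positives and expected truly-DE."""

    species: str
    rows: list

    @property
    def total_observed(self) -> int:
        return sum(r.observed_pdeg for r in self.rows)

    @property
    def total_expected_de(self) -> float:
        return sum(r.expected_de for r in self.rows)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                (r.bin_label, r.observed_pdeg, r.expected_fp, r.expected_de, r.expected_de_raw)
                for r in self.rows
            ],
            columns=["bin", "observed_pdeg", "expected_fp", "expected_de", "expected_de_raw"],
        )


def _bin_sort_key(label: str) -> tuple[int, int]:
    # numeric bins in order, open ">N" bins last
    if label.startswith(">"):
        return (1, int(label[1:]))
    return (0, int(label))


def aggregate_pdeg_bins(
    pdeg_bins: Mapping[int, int], fits: Sequence[TruncatedPoissonFit]
) -> dict[str, int]:
    """Map a per-j PDEG histogram onto the fit bin labels (pooling the open bin)."""
    by_j = {f.conditioning_j: f for f in fits if not f.is_open}
    open_fit = next((f for f in fits if f.is_open), None)
    out: dict[str, int] = {f.bin_label: 0 for f in fits}
    for j, n in pdeg_bins.items():
        if j in by_j:
            out[by_j[j].bin_label] += n
        elif open_fit is not None and j >= open_fit.conditioning_j:
            out[open_fit.bin_label] += n
        else:
            raise ValueError(f"PDEG bin j={j} has no covering fit")
    return out


def build_fp_table(
    pdeg_bins: Mapping[str, int],
    fp_per_bin: Mapping[str, float],
    species: str = "",
    open_bin_fp_zero: bool = True,
) -> FalsePositiveTable:
    """Assemble the per-bin observed / expected-FP / expected-DE table.

    ``expected_de`` is observed minus expected false positives, clipped at
    zero (the unclipped difference is kept in a diagnostic column).  In the
    open top bin the Poisson zero-probability is negligible and the printed
    convention is expected = observed; with ``open_bin_fp_zero`` the open
    bin's FP is forced to 0 to reproduce that.
    """
    labels = set(pdeg_bins)
    fp_labels = set(fp_per_bin)
    open_labels = {l for l in labels if l.startswith(">")}
    if labels - fp_labels - (open_labels if open_bin_fp_zero else set()):
        raise ValueError(
            f"bins {sorted(labels - fp_labels)} have observed counts but no FP estimate"
        )
    if fp_labels - labels:
        raise ValueError(f"FP estimates for unknown bins {sorted(fp_labels - labels)}")
    rows = []
    for label in sorted(labels, key=_bin_sort_key):
        observed = int(pdeg_bins[label])
        is_open = label.startswith(">")
        fp = 0.0 if (is_open and open_bin_fp_zero) else float(fp_per_bin[label])
        raw = observed - fp
        rows.append(
            FPTableRow(
                bin_label=label,
                observed_pdeg=observed,
                expected_fp=fp,
                expected_de=max(raw, 0.0),
                expected_de_raw=raw,
            )
        )
    return FalsePositiveTable(species=species, rows=rows)


def rescaled_pair_histogram(
    pairs: Sequence[OrthologPair],
    fits: Sequence[TruncatedPoissonFit],
    conditioning: str = "a",
) -> dict[str, float]:
    """Alternative k(j, s): observed pair counts rescaled by 1/(1 - p0).

    Sensitivity-analysis companion to the default definition (all contigs
    with j reads): the number of RBH pairs per bin underestimates the number
    of genes because pairs whose partner drew zero reads are unobservable;
    dividing by 1 - p0 undoes that truncation.
    """
    by_j = {f.conditioning_j: f for f in fits if not f.is_open}
    open_fit = next((f for f in fits if f.is_open), None)
    out: dict[str, float] = {f.bin_label: 0.0 for f in fits}
    for p in pairs:
        j = p.reads_a if conditioning == "a" else p.reads_b
        if j in by_j:
            f = by_j[j]
        elif open_fit is not None and j >= open_fit.conditioning_j:
            f = open_fit
        else:
            continue
        out[f.bin_label] += 1.0 / (1.0 - f.p0) if f.p0 < 1.0 else 1.0
    return out
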