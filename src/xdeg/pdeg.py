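"""Presence/absence differential-expression calling.

A contig of one species with no qualifying sequence match among the other
species' contigs *or* singletons is a potential differentially expressed
gene (PDEG).  Only presence/absence is assessed here — with normalized
libraries the read counts carry no usable quantitative signal — so the
companion statistics live in :mod:`xdeg.fpmodel`, which estimates how many
PDEG calls are mere sampling zeros.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

from scipy import stats

from .io_formats import HitRecord, SequenceRecord
from .orthology import OrthologPair, SearchParams


@dataclass
class PDEGSet:
    """Contigs of one species with no qualifying cross-species match."""

    species: str
    ids: frozenset
    bins: dict  # read count j -> number of PDEG contigs with j reads

    @property
    def total(self) -> int:
        return len(self.ids)


@dataclass
class CoverageHistogram:
    """k(j, s): number of contigs with exactly j constituent reads."""

    species: str
    counts: dict  # read count j -> number of contigs

    @property
    def n_contigs(self) -> int:
        return sum(self.counts.values())

    def mean_reads_per_contig(self) -> float:
        """The sequencing-coverage statistic: mean reads per contig."""
        n = self.n_contigs
        if n == 0:
            raise ValueError("empty histogram")
        return sum(j * k for j, k in self.counts.items()) / n


class CorrelationResult(NamedTuple):
    rho: float
    n_used: int


def qualifying(hit: HitRecord, params: SearchParams) -> bool:
    """Whether a hit protects its query from being called PDEG.

    Internal hits carry evalue 0 and were already filtered by length and
    identity; external tables are held to the e-value threshold and the
    segment-length cut-off.
    """
    return (
        hit.evalue <= params.max_evalue_external
        and hit.aln_length >= params.min_aln_length
    )


def identify_pdeg(
    contigs_s: Sequence[SequenceRecord],
    hits_vs_other: Iterable[HitRecord],
    threshold_params: SearchParams | None = None,
) -> PDEGSet:
    """Contigs of species s with zero qualifying hits against the other species.

    ``hits_vs_other`` must come from searches against both the other
    species' contigs and its singletons; a singleton match protects a contig
    from the PDEG call just as a contig match does.
    """
    params = threshold_params or SearchParams()
    if not contigs_s:
        raise ValueError("no contigs supplied")
    species = contigs_s[0].species
    contig_ids = set()
    for rec in contigs_s:
        if rec.species != species:
            raise ValueError("contigs of mixed species supplied")
        if rec.kind != "contig":
            raise ValueError(f"{rec.id}: singletons are not PDEG candidates")
        contig_ids.add(rec.id)
    matched = set()
    for h in hits_vs_other:
        if h.query_id not in contig_ids:
            raise KeyError(f"hit query {h.query_id!r} is not among the contigs")
        if qualifying(h, params):
            matched.add(h.query_id)
    pdeg_ids = contig_ids - matched
    bins = Counter(r.read_count for r in contigs_s if r.id in pdeg_ids)
    return PDEGSet(species=species, ids=frozenset(pdeg_ids), bins=dict(sorted(bins.items())))


def coverage_histogram(records: Sequence[SequenceRecord]) -> CoverageHistogram:
    """Tally read counts of a single species' records into k(j, s)."""
    if not records:
        return CoverageHistogram(species="", counts={})
    species = records[0].species
    if any(r.species != species for r in records):
        raise ValueError("records of mixed species supplied")
    counts = Counter(r.read_count for r in records)
    return CoverageHistogram(species=species, counts=dict(sorted(counts.items())))


def ortholog_count_correlation(
    pairs: Sequence[OrthologPair],
    lengths: Mapping[str, int] | None = None,
    min_length: int = 300,
    min_pct_identity: float = 90.0,
) -> CorrelationResult:
    """Spearman correlation of ortholog read counts across species.

    Mirrors the scatter of read counts in orthologous contigs: only pairs
    whose sequences exceed ``min_length`` (when lengths are supplied) and
    whose identity exceeds ``min_pct_identity`` enter the statistic.
    """
    used = []
    for p in pairs:
        if p.pct_identity <= min_pct_identity:
            continue
        if lengths is not None and (
            lengths[p.id_a] <= min_length or lengths[p.id_b] <= min_length
        ):
            continue
        used.append((p.reads_a, p.reads_b))
    if len(used) < 3:
        raise ValueError(f"only {len(used)} pairs pass the filters; need >= 3")
    xs, ys = zip(*used)
    rho = stats.spearmanr(xs, ys).statistic
    return CorrelationResult(rho=float(rho), n_used=len(used))
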