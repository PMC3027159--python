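"""End-to-end orchestration of the comparative analysis.

Stages, in order: load or simulate the two species' records; all-vs-all
sequence search in both directions; reciprocal-best-hit pairing; PDEG
identification per species; coverage histograms; zero-truncated Poisson fits
per conditioning bin; false-positive tables; ortholog count correlation; ORF
shuffling null; term enrichment.  Every intermediate is a plain table so any
stage can be swapped for real tool output (e.g. genuine BLAST hit tables at
the 1e-15 threshold).  One top-level seed drives all stochastic stages via
deterministically spawned substreams; identical config gives byte-identical
output files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import fpmodel, orf, pdeg
from .io_formats import (
    SequenceRecord,
    read_annotation_map,
    read_fasta,
    read_hit_table,
    write_fasta,
    write_hit_table,
)
from .orthology import (
    SearchParams,
    best_hits,
    kmer_search,
    reciprocal_best_hits,
    transpose_hits,
)
from .simulate import SimulationConfig, generate_annotations, generate_dataset

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """Raised when a stage fails; carries the stage name and input summary."""


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Exactly one input mode is active: ``simulate`` (uses ``sim``) or
    ``files`` (uses ``fasta_a``/``fasta_b`` and optional precomputed hit
    tables and annotations).
    """

    mode: str = "simulate"
    sim: SimulationConfig | None = None
    fasta_a: str | None = None
    fasta_b: str | None = None
    species_a: str = "A"
    species_b: str = "B"
    hits_ab: str | None = None  # optional external 12-column hit tables
    hits_ba: str | None = None
    annotations: str | None = None
    search: SearchParams = field(default_factory=SearchParams)
    min_bin_n: int = 30
    k_from_all_contigs: bool = True  # k(j,s) = all contigs vs rescaled pairs
    orf_threshold: int = 90
    orf_n_shuffles: int = 100
    orf_max_records: int = 500  # subsample cap for the shuffling null
    corr_min_length: int = 300
    corr_min_pct_identity: float = 90.0
    alpha: float = 0.05
    reference_includes_test: bool = False
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ValueError("mode must be 'simulate' or 'files'")
        if self.mode == "files" and (self.fasta_a is None or self.fasta_b is None):
            raise ValueError("files mode requires fasta_a and fasta_b")


@dataclass
class SpeciesResult:
    pdeg: pdeg.PDEGSet
    histogram: pdeg.CoverageHistogram
    fits: list
    fp_table: fpmodel.FalsePositiveTable
    enrichment: list | None


@dataclass
class PipelineResult:
    config: RunConfig
    records_a: list
    records_b: list
    pairs: list
    species_a: SpeciesResult
    species_b: SpeciesResult
    correlation: pdeg.CorrelationResult | None
    orf_null: orf.NullTestResult
    truth: pd.DataFrame | None
    summary: dict


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc


def _fits_frame(fits) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (f.bin_label, f.conditioning_j, f.is_open, f.target_species,
             f.n_used, f.n_outliers_removed, f.lambda_hat, f.p0)
            for f in fits
        ],
        columns=["bin", "conditioning_j", "is_open", "target_species",
                 "n_used", "n_outliers", "lambda_hat", "p0"],
    )


def _species_stats(
    label: str,
    contigs: list,
    hits_vs_other: list,
    pairs: list,
    conditioning: str,
    target_species: str,
    config: RunConfig,
) -> SpeciesResult:
    pdeg_set = _stage(
        f"pdeg_{label}",
        pdeg.identify_pdeg,
        contigs,
        [h for h in hits_vs_other if h.query_id in {c.id for c in contigs}],
        config.search,
    )
    hist = _stage(f"histogram_{label}", pdeg.coverage_histogram, contigs)
    fits = _stage(
        f"fits_{label}",
        fpmodel.fit_bins,
        pairs,
        conditioning=conditioning,
        target_species=target_species,
        min_bin_n=config.min_bin_n,
    )
    if config.k_from_all_contigs:
        fp_bins, _ = _stage(
            f"fp_{label}", fpmodel.expected_false_positives, hist, fits
        )
    else:
        fp_bins = _stage(
            f"fp_{label}", fpmodel.rescaled_pair_histogram, pairs, fits, conditioning
        )
        fp_bins = {lbl: k * f.p0 for (lbl, k), f in zip(fp_bins.items(), fits)}
    observed = _stage(
        f"fp_table_{label}", fpmodel.aggregate_pdeg_bins, pdeg_set.bins, fits
    )
    table = _stage(
        f"fp_table_{label}",
        fpmodel.build_fp_table,
        observed,
        fp_bins,
        species=pdeg_set.species,
    )
    return SpeciesResult(pdeg=pdeg_set, histogram=hist, fits=fits, fp_table=table, enrichment=None)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage and (optionally) persist all tables under ``outdir``."""
    ss = np.random.SeedSequence(config.seed)
    sim_seed, orf_seed, ann_seed = (int(s) for s in ss.generate_state(3) % (2**31))

    truth = None
    annotations: Mapping[str, set] | None = None
    if config.mode == "simulate":
        sim = config.sim or SimulationConfig()
        sim = dataclasses.replace(sim, seed=sim_seed)
        logger.info("simulating dataset: %s", sim)
        records_a, records_b, truth = _stage("simulate", generate_dataset, sim)
        annotations = generate_annotations(truth, np.random.default_rng(ann_seed))
    else:
        records_a = _stage(
            "load_a", read_fasta, config.fasta_a, species=config.species_a
        )
        records_b = _stage(
            "load_b", read_fasta, config.fasta_b, species=config.species_b
        )
        if config.annotations:
            annotations = _stage("load_annotations", read_annotation_map, config.annotations)
    logger.info(
        "records: %d (%s), %d (%s)",
        len(records_a), records_a[0].species if records_a else "?",
        len(records_b), records_b[0].species if records_b else "?",
    )

    if config.hits_ab:
        hits_ab = _stage("load_hits_ab", read_hit_table, config.hits_ab)
    else:
        hits_ab = _stage("search_ab", kmer_search, records_a, records_b, config.search)
    if config.hits_ba:
        hits_ba = _stage("load_hits_ba", read_hit_table, config.hits_ba)
    else:
        # the ungapped segment score is symmetric, so the reverse search is
        # the transpose of the forward one
        hits_ba = transpose_hits(hits_ab)
    logger.info("hits: %d A->B, %d B->A", len(hits_ab), len(hits_ba))

    map_ab = _stage("best_hits_ab", best_hits, hits_ab)
    map_ba = _stage("best_hits_ba", best_hits, hits_ba)
    pairs = _stage("rbh", reciprocal_best_hits, map_ab, map_ba, records_a, records_b)
    logger.info("reciprocal best hit pairs: %d", len(pairs))

    contigs_a = [r for r in records_a if r.kind == "contig"]
    contigs_b = [r for r in records_b if r.kind == "contig"]
    res_a = _species_stats(
        "a", contigs_a, hits_ab, pairs, "a", config.species_b, config
    )
    res_b = _species_stats(
        "b", contigs_b, hits_ba, pairs, "b", config.species_a, config
    )

    lengths = {r.id: len(r) for r in records_a + records_b}
    try:
        correlation = pdeg.ortholog_count_correlation(
            pairs, lengths, config.corr_min_length, config.corr_min_pct_identity
        )
    except ValueError as exc:
        logger.warning("correlation skipped: %s", exc)
        correlation = None

    orf_rng = np.random.default_rng(orf_seed)
    orf_pool = contigs_a + contigs_b
    if len(orf_pool) > config.orf_max_records:
        idx = orf_rng.choice(len(orf_pool), size=config.orf_max_records, replace=False)
        orf_pool = [orf_pool[i] for i in sorted(idx)]
    orf_null = _stage(
        "orf_null",
        orf.orf_null_test,
        orf_pool,
        threshold=config.orf_threshold,
        n_shuffles=config.orf_n_shuffles,
        rng=orf_rng,
    )

    if annotations is not None:
        for res, contigs in ((res_a, contigs_a), (res_b, contigs_b)):
            try:
                res.enrichment = enr.enrich_terms(
                    res.pdeg.ids,
                    {c.id for c in contigs},
                    annotations,
                    alpha=config.alpha,
                    reference_includes_test=config.reference_includes_test,
                )
            except ValueError as exc:
                logger.warning("enrichment skipped for %s: %s", res.pdeg.species, exc)

    summary = {
        "seed": config.seed,
        "n_records_a": len(records_a),
        "n_records_b": len(records_b),
        "n_contigs_a": len(contigs_a),
        "n_contigs_b": len(contigs_b),
        "n_pairs": len(pairs),
        "pdeg_total_a": res_a.pdeg.total,
        "pdeg_total_b": res_b.pdeg.total,
        "lambda_a": {f.bin_label: f.lambda_hat for f in res_a.fits},
        "lambda_b": {f.bin_label: f.lambda_hat for f in res_b.fits},
        "expected_de_a": res_a.fp_table.total_expected_de,
        "expected_de_b": res_b.fp_table.total_expected_de,
        "correlation_rho": None if correlation is None else correlation.rho,
        "correlation_n": None if correlation is None else correlation.n_used,
        "orf_observed_fraction": orf_null.observed_fraction,
        "orf_p": orf_null.p_value,
        "search": dataclasses.asdict(config.search),
    }

    result = PipelineResult(
        config=config,
        records_a=records_a,
        records_b=records_b,
        pairs=pairs,
        species_a=res_a,
        species_b=res_b,
        correlation=correlation,
        orf_null=orf_null,
        truth=truth,
        summary=summary,
    )
    if config.outdir is not None:
        _write_bundle(result, hits_ab, annotations)
    return result


def _write_bundle(result: PipelineResult, hits_ab, annotations) -> None:
    out = Path(result.config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(result.records_a, out / "speciesA.fasta")
    write_fasta(result.records_b, out / "speciesB.fasta")
    write_hit_table(hits_ab, out / "hits_ab.tsv")
    pd.DataFrame(
        [(p.id_a, p.id_b, p.reads_a, p.reads_b, p.pct_identity, p.aln_length) for p in result.pairs],
        columns=["id_a", "id_b", "reads_a", "reads_b", "pct_identity", "aln_length"],
    ).to_csv(out / "rbh_pairs.tsv", sep="\t", index=False)
    if result.truth is not None:
        result.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    for label, res in (("a", result.species_a), ("b", result.species_b)):
        (out / f"pdeg_{label}.txt").write_text(
            "".join(f"{i}\n" for i in sorted(res.pdeg.ids))
        )
        pd.DataFrame(
            sorted(res.histogram.counts.items()), columns=["j", "k"]
        ).to_csv(out / f"histogram_{label}.tsv", sep="\t", index=False)
        _fits_frame(res.fits).to_csv(out / f"fits_{label}.tsv", sep="\t", index=False)
        res.fp_table.to_frame().to_csv(out / f"fp_table_{label}.tsv", sep="\t", index=False)
        if res.enrichment is not None:
            enr.enrichment_frame(res.enrichment).to_csv(
                out / f"enrichment_{label}.tsv", sep="\t", index=False
            )
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
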