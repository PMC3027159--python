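"""Two-species synthetic transcriptome datasets with known truth.

The generator emulates the contig-level statistical structure of a pair of
normalized 454 cDNA libraries from two closely related species: a shared
set of orthologous genes whose expression level is common to both species
(this shared level is the sole source of the strong cross-species read-count
correlation), species-specific genes expressed in one species only, lognormal
expression, power-law normalization compression, and Poisson read sampling.
Genes drawing zero reads vanish from the observable data; one read yields a
singleton, two or more a contig — exactly the censoring the downstream
zero-truncated model corrects for.  The truth table records what the
pipeline cannot observe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """World description for one synthetic dataset.

    Defaults emulate the real libraries: ~700 nt mean contig length within
    [100, 3600]; lognormal expression with unit log-sd; normalization as a
    power compression ``expression**norm_alpha`` (alpha < 1, a monotone
    stand-in for duplex-specific-nuclease normalization); depth chosen so
    the mean reads per contig lands near 8; ortholog divergence ~3%
    (sub_rate is the *pairwise* substitution rate between the two species'
    orthologs; each copy is mutated from the ancestor at half that rate).
    """

    n_ortholog_pairs: int = 5000
    n_specific_a: int = 625
    n_specific_b: int = 625
    depth_a: float = 6.0
    depth_b: float = 6.0
    expr_mu: float = 0.0
    expr_sigma: float = 1.0
    norm_alpha: float = 0.7
    sub_rate: float = 0.03
    indel_rate: float = 0.005
    len_mean: float = 700.0
    len_sd: float = 300.0
    len_min: int = 100
    len_max: int = 3600
    min_contig_reads: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_ortholog_pairs, self.n_specific_a, self.n_specific_b) < 0:
            raise ValueError("gene counts must be non-negative")
        if not (0.0 <= self.sub_rate <= 1.0 and 0.0 <= self.indel_rate <= 1.0):
            raise ValueError("mutation rates must lie in [0, 1]")
        if self.len_min < 3 or self.len_max < self.len_min:
            raise ValueError("invalid length range")
        if not 0.0 < self.norm_alpha <= 1.0:
            raise ValueError("norm_alpha must lie in (0, 1]")
        if self.depth_a <= 0 or self.depth_b <= 0:
            raise ValueError("depths must be positive")
        if self.expr_sigma < 0:
            raise ValueError("expr_sigma must be non-negative")
        if self.min_contig_reads < 2:
            raise ValueError("min_contig_reads must be >= 2")


def sample_expression_profile(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-gene expression levels and class labels.

    Shared genes draw one lognormal level used in both species; specific
    genes draw a level for their own species and 0 for the other.
    """
    n_sh, n_a, n_b = config.n_ortholog_pairs, config.n_specific_a, config.n_specific_b
    gene_ids = (
        [f"g{i:06d}" for i in range(n_sh)]
        + [f"sa{i:06d}" for i in range(n_a)]
        + [f"sb{i:06d}" for i in range(n_b)]
    )
    classes = ["shared"] * n_sh + ["specific_a"] * n_a + ["specific_b"] * n_b
    shared = rng.lognormal(config.expr_mu, config.expr_sigma, n_sh)
    only_a = rng.lognormal(config.expr_mu, config.expr_sigma, n_a)
    only_b = rng.lognormal(config.expr_mu, config.expr_sigma, n_b)
    expr_a = np.concatenate([shared, only_a, np.zeros(n_b)])
    expr_b = np.concatenate([shared, np.zeros(n_a), only_b])
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "cls": pd.Categorical(classes, categories=["shared", "specific_a", "specific_b"]),
            "expression_a": expr_a,
            "expression_b": expr_b,
        }
    )


def sample_read_counts(
    expression, depth: float, norm_alpha: float, rng: np.random.Generator
):
    """Read counts ~ Poisson(depth * expression**norm_alpha); 0 stays 0.

    Accepts a scalar or an array of expression levels.
    """
    expr = np.asarray(expression, dtype=float)
    if (expr < 0).any() or depth < 0:
        raise ValueError("expression and depth must be non-negative")
    lam = depth * np.where(expr > 0, np.power(np.where(expr > 0, expr, 1.0), norm_alpha), 0.0)
    counts = rng.poisson(lam)
    return int(counts) if np.ndim(counts) == 0 else counts


def mutate_sequence(
    seq: str, sub_rate: float, indel_rate: float, rng: np.random.Generator
) -> str:
    """Independent per-site substitutions and length-1 indels.

    A substituted site always changes to a different base (uniform over the
    other three); indel sites delete the base or insert a random base before
    it with equal odds.  N sites are left untouched.
    """
    if not seq:
        raise ValueError("empty sequence")
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    base_idx = np.full(codes.shape, 4, dtype=np.int8)
    for i, b in enumerate(_BASES):
        base_idx[codes == b] = i
    L = codes.size
    sub_mask = (rng.random(L) < sub_rate) & (base_idx < 4)
    shifts = rng.integers(1, 4, size=L)
    new_idx = (base_idx + shifts) % 4
    codes[sub_mask] = _BASES[new_idx[sub_mask]]
    indel_mask = rng.random(L) < indel_rate
    if not indel_mask.any():
        return codes.tobytes().decode("ascii")
    positions = np.nonzero(indel_mask)[0]
    is_insert = rng.random(positions.size) < 0.5
    ins_bases = _BASES[rng.integers(0, 4, size=positions.size)]
    pieces = []
    prev = 0
    for pos, ins, base in zip(positions, is_insert, ins_bases):
        pieces.append(codes[prev:pos])
        if ins:
            pieces.append(np.array([base], dtype=np.uint8))
            prev = pos
        else:
            prev = pos + 1
    pieces.append(codes[prev:])
    return np.concatenate(pieces).tobytes().decode("ascii")


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _sample_lengths(config: SimulationConfig, n: int, rng: np.random.Generator):
    a = (config.len_min - config.len_mean) / config.len_sd
    b = (config.len_max - config.len_mean) / config.len_sd
    draws = stats.truncnorm.rvs(
        a, b, loc=config.len_mean, scale=config.len_sd, size=n, random_state=rng
    )
    return np.rint(draws).astype(int)


def _status(count: int, min_contig_reads: int) -> str:
    if count == 0:
        return "absent"
    if count < min_contig_reads:
        return "singleton"
    return "contig"


def generate_dataset(
    config: SimulationConfig,
) -> tuple[list[SequenceRecord], list[SequenceRecord], pd.DataFrame]:
    """Simulate both species' observable records plus the full truth table.

    Each gene gets an ancestral sequence (truncated-normal length); each
    species' ortholog is an independently mutated copy.  Counts are sampled
    per species; genes with zero reads are omitted from that species'
    records, one read becomes a singleton, two or more a contig.  Record ids
    are the gene id prefixed with ``A_`` / ``B_``.
    """
    rng = np.random.default_rng(config.seed)
    truth = sample_expression_profile(config, rng)
    n = len(truth)
    lengths = _sample_lengths(config, n, rng)
    count_a = sample_read_counts(
        truth["expression_a"].to_numpy(), config.depth_a, config.norm_alpha, rng
    )
    count_b = sample_read_counts(
        truth["expression_b"].to_numpy(), config.depth_b, config.norm_alpha, rng
    )
    records_a: list[SequenceRecord] = []
    records_b: list[SequenceRecord] = []
    half_sub, half_indel = config.sub_rate / 2.0, config.indel_rate / 2.0
    for row, length, ca, cb in zip(truth.itertuples(), lengths, count_a, count_b):
        ancestral = _random_sequence(int(length), rng)
        if ca > 0:
            seq_a = mutate_sequence(ancestral, half_sub, half_indel, rng)
            records_a.append(SequenceRecord(f"A_{row.gene_id}", "A", seq_a, int(ca)))
        if cb > 0:
            seq_b = mutate_sequence(ancestral, half_sub, half_indel, rng)
            records_b.append(SequenceRecord(f"B_{row.gene_id}", "B", seq_b, int(cb)))
    truth = truth.assign(
        count_a=count_a,
        count_b=count_b,
        status_a=[_status(c, config.min_contig_reads) for c in count_a],
        status_b=[_status(c, config.min_contig_reads) for c in count_b],
    )
    return records_a, records_b, truth


def generate_annotations(
    truth: pd.DataFrame,
    rng: np.random.Generator,
    n_terms: int = 30,
    max_terms_per_gene: int = 3,
    biased_term: str = "T_SPECIFIC",
    bias_prob: float = 0.3,
) -> dict:
    """Synthetic record-id -> term-set map for exercising enrichment.

    Every gene draws 1..max_terms_per_gene terms from a flat pool; species-
    specific genes additionally carry ``biased_term`` with probability
    ``bias_prob``, planting one genuinely enriched category in the PDEG
    sets.  Terms are assigned to both species' record ids for the gene.
    """
    pool = [f"T{i:03d}" for i in range(n_terms)]
    mapping: dict = {}
    for row in truth.itertuples():
        k = int(rng.integers(1, max_terms_per_gene + 1))
        terms = set(rng.choice(pool, size=k, replace=False))
        if row.cls != "shared" and rng.random() < bias_prob:
            terms.add(biased_term)
        mapping[f"A_{row.gene_id}"] = set(terms)
        mapping[f"B_{row.gene_id}"] = set(terms)
    return mapping


def truth_summary(truth: pd.DataFrame) -> dict:
    """Bookkeeping counts used in calibration checks."""
    return {
        "n_genes": len(truth),
        "true_specific_contigs_a": int(
            ((truth["cls"] == "specific_a") & (truth["status_a"] == "contig")).sum()
        ),
        "true_specific_contigs_b": int(
            ((truth["cls"] == "specific_b") & (truth["status_b"] == "contig")).sum()
        ),
    }
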