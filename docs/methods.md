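# Methods

## Problem setting and model

Two closely related species are sequenced from *normalized* cDNA libraries
at shallow coverage and assembled de novo.  Each observable unit (contig or
singleton) carries the number of reads that built it.  Normalization
flattens abundances, so counts are useless for quantitative comparison; the
only robust differential-expression signal is a gene observed in one species
with *no sequence match at all* in the other (a "potential differentially
expressed gene", PDEG).  The statistical problem is that absence is
confounded with sampling: at a mean of ~8 reads per contig, a lowly sampled
gene's ortholog frequently draws zero reads.

The correction exploits the strong cross-species correlation of ortholog
read counts.  Conditional on the ortholog having `j` reads in species `s`,
the partner's count is modeled as Poisson with rate λ(j, s).  Genes whose
partner drew zero reads are missing from the data, so λ(j, s) is estimated
from the observed (necessarily positive) partner counts by zero-truncated
maximum likelihood: λ̂ solves

    mean(counts) = λ / (1 − e^(−λ)).

The sampling-zero probability is p(0, j, s) = e^(−λ̂(j, s)), and the
expected number of false-positive PDEG calls is Σ_j k(j, s)·p(0, j, s) with
k(j, s) the number of contigs with exactly `j` reads in species `s`.
Observed PDEG per bin minus expected false positives, clipped at zero,
estimates the genes genuinely expressed in one species only.

Assumptions worth keeping in mind:

- Per conditioning bin the partner counts are treated as a single Poisson.
  In reality they are a Poisson *mixture* over the residual expression
  spread within the bin, i.e. overdispersed; the fitted e^(−λ̂) then
  understates the zero probability somewhat.  Normalization compression
  (below) narrows the mixture and the end-to-end calibration test bounds the
  aggregate effect (within 15% on the default synthetic world).
- k(j, s) is taken as *all* contigs with `j` reads — including truly
  species-specific ones, which cannot be false positives.  This overstates
  FP slightly and partially offsets the understatement above.  The
  alternative definition (observed RBH pairs per bin rescaled by
  1/(1 − p₀)) is available via `RunConfig(k_from_all_contigs=False)` for
  sensitivity analysis.
- Conditioning bins default to contigs only (j ≥ 2); singleton conditioning
  (j = 1) can be enabled with `min_conditioning_count=1`.

## Estimation details

- **ZTP MLE** (`fpmodel.ztp_mle`): the root is bracketed in (0, mean] — the
  truncated mean is strictly increasing in λ with limit 1 as λ→0 — and found
  by bisection to 1e-10 absolute tolerance.  A sample mean ≤ 1 returns the
  boundary λ̂ = 0 (point mass at one read).
- **Outlier trimming** (`fpmodel.filter_outliers`): a handful of pairs sit
  far in the upper tail of their bin (paralog collapse, repeat sequences).
  Counts whose upper-tail probability under the current fit is below 1e-4
  are removed and the bin refit, for at most 5 passes, never reducing a bin
  below 2 counts.  The cutoff and pass limit are this package's
  concretization of an otherwise unquantified trimming step.
- **Binning** (`fpmodel.fit_bins`): walking j upward from 2, bins stay
  standalone while they hold ≥ `min_bin_n` (default 30) pairs *and* are
  contiguous; the first short or missing bin and everything above it pool
  into an open top bin ("> N").  In the table the open bin's FP is set to 0
  (expected DE = observed): p₀ is already negligible at high coverage, and
  this reproduces the printed convention of published tables of this form.
- **expected_de** is clipped at zero per bin; the unclipped difference is
  kept in a diagnostic column (`expected_de_raw`).

## Sequence search

The internal search exists so the pipeline is self-contained at desk scale;
real BLAST tabular output (outfmt 6) can be substituted anywhere hits are
consumed and is then filtered by the e ≤ 1e-15 / segment ≥ 50 nt rule.

- Exact k-mer seeds (default k = 11), both query strands; ungapped
  bidirectional extension with match +1 / mismatch −2 and x-drop 10; the
  best segment per query/subject pair is reported, filtered at ≥ 50 nt and
  ≥ 80% identity.  Scores carry no e-value calibration (Karlin–Altschul is
  out of scope); internal hits set `evalue = 0`, which always passes the
  external threshold.
- Ungapped only: an indel splits a hit.  At the ≥ 90% identity of
  congeneric orthologs the flanking segments comfortably clear the length
  and identity filters, so RBH pairing is unaffected.
- Per diagonal, extension starts from the leftmost seed; later seeds are
  re-extended only if they fall outside the segment already found.  N never
  matches anything (including N).  Sequences are packed into sentinel-padded
  arrays so the x-drop condition, not a bounds check, terminates every scan;
  the hot loops are numba-compiled.
- Minus-strand hits report descending subject coordinates, as in the
  tabular dialect.  Coordinates are 1-based inclusive everywhere outside
  the internals.
- Because the segment score is symmetric in query and subject, the pipeline
  searches A→B once and transposes the hits for B→A.  `kmer_search` itself
  is direction-agnostic; the RBH symmetry test runs it both ways.
- Best-hit ties break by smaller e-value, then lexicographically smaller
  subject id — arbitrary but deterministic.

## ORF prediction and shuffling null

An ORF is the longest maximal run of stop-free codons over all six frames —
no start codon required, since shallow-coverage contigs are partial cDNAs;
the terminating stop is excluded from the length; codons containing N count
as non-stop (conservative).  Ties break by frame order +1, +2, +3, −1, −2,
−3, then smallest forward-strand start.

The null shuffles each sequence's nucleotides uniformly (mononucleotide
shuffling preserves GC content, which sets the chance stop density;
dinucleotide shuffling is out of scope).  The statistic is the fraction of
records whose longest ORF reaches a threshold (default 90 nt), with the mean
longest-ORF length available as an alternative; the one-sided permutation
p-value is (1 + #{null ≥ observed}) / (n_shuffles + 1).  Caveat: on
sequences much longer than the threshold the fraction statistic saturates —
a ≥ 90 nt ORF arises by chance in nearly every 600 nt shuffle — so
discrimination should be assessed with a threshold commensurate with the
sequence length, or with the mean-length statistic.

## Enrichment

Per term, the 2×2 table (test with/without term × reference with/without
term) is tested two-sided by Fisher's exact point-probability rule (via
scipy), with Benjamini–Hochberg q-values (via statsmodels) and a
significance flag at q ≤ α (default 0.05).  The reference defaults to the
overall set *minus* the test set, keeping the margins disjoint;
`reference_includes_test=True` reproduces the literal "overall set as
reference" convention (the difference is slight and conservative either
way).  Records without annotations are excluded from both margins.  Terms
are flat labels; ontology ancestor propagation is out of scope.

## Synthetic worlds

`SimulationConfig` defaults state one fixed world modeled on a pair of
normalized 454 floral transcriptomes from congeneric species:

| parameter | default | rationale |
|---|---|---|
| n_ortholog_pairs | 5000 | shared genes = 80% of the 6250 simulated |
| n_specific_a/b | 625 each | 20% of genes species-specific |
| expr_mu, expr_sigma | 0, 1 | lognormal expression, unit log-sd |
| norm_alpha | 0.7 | normalization as power compression e^α; the one qPCR datum available for such libraries (a ~32-fold knockdown of a high-expressed gene) fixes only that α < 1, so α is a documented free choice |
| depth_a/b | 6.0 | reads per unit normalized expression; yields ~8 mean reads per contig, matching the real libraries' 7.5–8.2 |
| sub_rate | 0.03 | *pairwise* ortholog divergence (~97% identity); each species' copy is mutated from the ancestor at half this rate |
| indel_rate | 0.005 | a few 1-nt indels per 700 nt contig |
| len_mean/sd, min/max | 700/300, [100, 3600] | truncated normal matching the real contig-length profile (only mean/min/max are known; the sd is a choice) |
| min_contig_reads | 2 | 0 reads → absent, 1 → singleton, ≥2 → contig |

Cross-species count correlation arises *solely* from the shared expression
level — counts are conditionally independent Poisson draws given expression
— which is the weakest structure consistent with the observed correlation
and with per-bin Poisson fitting.  The generator emits full-length gene
sequences for singletons and contigs alike: no read-level simulation, no
assembly or homopolymer errors, no chimeras, no paralogs, no alternative
splicing.  A green end-to-end test therefore establishes that the
statistical machinery is calibrated under the stated sampling model — not
that it is robust to assembly artifacts or paralogy, which real data add on
top.  `generate_annotations` plants one term enriched among species-specific
genes so the enrichment stage has a recoverable signal; all other terms are
uniform background.

Determinism: one top-level seed; `run_pipeline` spawns per-stage substreams
from it (simulation, ORF subsampling, annotations), and identical
configurations produce byte-identical output files.

## Pipeline notes

- Every intermediate is plain text (FASTA / TSV / JSON), so any stage can be
  re-run from persisted inputs or swapped for real tool output.
- The ORF null runs on a seeded subsample of contigs (default cap 500):
  it is a per-dataset diagnostic whose statistic stabilizes well below that,
  and shuffling every contig 100 times would dominate runtime.
- Correlation (Spearman, robust to the heavy-tailed counts) uses pairs with
  both sequences > 300 nt and identity > 90%; with fewer than 3 qualifying
  pairs the stage records no value rather than an unstable one.

## Known limitations

- Presence/absence only; no quantitative DE, by design.
- The Poisson-per-bin model ignores within-bin expression spread (see
  above); the FP totals are estimates with a built-in few-percent bias, not
  exact expectations.
- No paralog handling: RBH collapses recent duplicates to one pair and the
  synthetic worlds contain none.
- The internal search is not BLAST: no gapped extension, no e-values, and
  hit boundaries can differ slightly from BLAST's around indels.
- Enrichment treats annotation terms as independent flat labels.
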