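"""Term enrichment of a test set against a reference set.

Each term occurring in either group is tested with Fisher's exact test on
the 2x2 table (in test & has term, in test & lacks term, in reference & has
term, in reference & lacks term); two-sided p-values are corrected by
Benjamini-Hochberg.  Terms are flat labels — no ontology structure is
assumed.  Records without any annotation are excluded from both groups so
the margins count only annotatable genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy import stats
from statsmodels.stats.multitest import multipletests


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Two-sided by the point-probability rule: the sum of probabilities of all
    tables with the observed margins whose probability does not exceed the
    observed table's.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be non-negative integers")
    if a + b + c + d == 0:
        raise ValueError("at least one margin must be positive")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


@dataclass
class EnrichmentRow:
    term: str
    a: int  # test records with the term
    b: int  # test records without it
    c: int  # reference records with the term
    d: int  # reference records without it
    odds_ratio: float
    p_value: float
    q_value: float
    significant: bool


def enrich_terms(
    test_ids: Iterable[str],
    all_ids: Iterable[str],
    annotations: Mapping[str, set],
    alpha: float = 0.05,
    reference_includes_test: bool = False,
) -> list[EnrichmentRow]:
    """Fisher enrichment of every term, BH-corrected, sorted by p.

    By default the reference group is ``all_ids`` minus ``test_ids``
    (disjoint margins); ``reference_includes_test`` reproduces the literal
    "overall set as reference" convention instead.
    """
    test = set(test_ids)
    universe = set(all_ids)
    if not test <= universe:
        raise ValueError("test_ids must be a subset of all_ids")
    reference = universe if reference_includes_test else universe - test
    test_ann = {i for i in test if annotations.get(i)}
    ref_ann = {i for i in reference if annotations.get(i)}
    if not test_ann or not ref_ann:
        raise ValueError("annotated test and reference groups must be non-empty")

    terms = sorted({t for i in test_ann | ref_ann for t in annotations[i]})
    n_test, n_ref = len(test_ann), len(ref_ann)
    rows = []
    for term in terms:
        a = sum(1 for i in test_ann if term in annotations[i])
        c = sum(1 for i in ref_ann if term in annotations[i])
        b, d = n_test - a, n_ref - c
        p = fisher_exact_2x2(a, b, c, d)
        rows.append((term, a, b, c, d, odds_ratio(a, b, c, d), p))

    _, qvals, _, _ = multipletests([r[6] for r in rows], method="fdr_bh")
    out = [
        EnrichmentRow(
            term=r[0], a=r[1], b=r[2], c=r[3], d=r[4],
            odds_ratio=r[5], p_value=r[6], q_value=float(q),
            significant=bool(q <= alpha),
        )
        for r, q in zip(rows, qvals)
    ]
    out.sort(key=lambda r: (r.p_value, r.term))
    return out


def enrichment_frame(rows: list):
    import pandas as pd

    return pd.DataFrame(
        [
            (r.term, r.a, r.b, r.c, r.d, r.odds_ratio, r.p_value, r.q_value, r.significant)
            for r in rows
        ],
        columns=["term", "a", "b", "c", "d", "odds_ratio", "p", "q", "significant"],
    )
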