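"""Rank-based evidence integration across discovery data sources.

Each data source (demethylation reactivation, methylation-capture peak
evidence, tumor differential expression) contributes a per-gene rank.
Ranks are converted to scores on a common scale running from tan(1) for
the best rank down to ~0 for the worst, the per-source scores are
summed with equal weight, and the top-k genes are selected — avoiding
per-source significance cutoffs.
"""

from __future__ import annotations

import math
import warnings
from typing import Callable, Mapping

import pandas as pd

from .core_io import GenomicInterval


def rank_to_score(rank: int, n: int) -> float:
    """Score of a rank among ``n``: tan((n - rank + 1) / n).

    Rank 1 scores tan(1) ~ 1.5574; rank n scores tan(1/n), approaching 0
    for large n.  The argument decays linearly with rank.
    """
    if not 1 <= rank <= n:
        raise ValueError(f"rank {rank} outside [1, {n}]")
    return math.tan((n - rank + 1) / n)


def combine_and_select(
    sources: Mapping[str, Mapping[str, int]],
    k: int = 43,
    score_fn: Callable[[int, int], float] = rank_to_score,
) -> pd.DataFrame:
    """Combine per-source gene ranks into one prioritised candidate list.

    Every source is given the same weight: a gene's combined score is
    the sum of its per-source scores, with 0 for sources it is absent
    from.  Ties are broken by the number of sources a gene appears in,
    then by gene id.  Returns the top ``k`` genes with per-source ranks
    and scores, combined score and final rank.
    """
    if not sources:
        raise ValueError("need at least one source")
    genes = sorted({g for ranks in sources.values() for g in ranks})
    rows = []
    for gene in genes:
        row: dict[str, object] = {"gene": gene}
        combined = 0.0
        n_present = 0
        for name, ranks in sources.items():
            if gene in ranks:
                n = len(ranks)
                score = score_fn(ranks[gene], n)
                row[f"rank_{name}"] = ranks[gene]
                row[f"score_{name}"] = score
                combined += score
                n_present += 1
            else:
                row[f"rank_{name}"] = pd.NA
                row[f"score_{name}"] = 0.0
        row["combined_score"] = combined
        row["n_sources"] = n_present
        rows.append(row)
    table = pd.DataFrame(rows).set_index("gene")
    table = table.sort_values(
        by=["combined_score", "n_sources", "gene"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    table["final_rank"] = range(1, len(table) + 1)
    if k > len(table):
        warnings.warn(
            f"requested top {k} but only {len(table)} genes", stacklevel=2
        )
        return table
    return table.head(k)


def region_filter(
    genes: list[str],
    regions: list[GenomicInterval],
    annotations: pd.DataFrame,
) -> list[str]:
    """Genes whose TSS falls inside any of the supplied genomic regions
    (half-open intervals, e.g. recurrent copy-number-altered regions)."""
    ann = annotations.set_index("gene")
    kept = []
    for gene in genes:
        if gene not in ann.index:
            continue
        chrom, tss = ann.loc[gene, "chrom"], int(ann.loc[gene, "tss"])
        if any(r.contains(chrom, tss) for r in regions):
            kept.append(gene)
    return kept
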