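"""Inter-tumor landscape comparison and germline-vs-somatic enrichment.

Two independent primaries from one patient share almost no somatic mutations;
this module quantifies overlap at the site and gene level, tallies mutated
genes against curated lists (significantly-mutated-gene sets, cancer
pathways), and tests whether truncating mutations (nonsense, nonstop,
splicing, frameshift and other indels) are enriched among pathogenic
germline variants relative to somatic mutations via a two-sided Fisher
exact test on the 2x2 truncating/missense table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ConfigurationError, DataIntegrityError
from .variantio import VariantCall

logger = logging.getLogger(__name__)

TRUNCATING_TERMS = frozenset({"nonsense", "nonstop", "splicing", "frameshift_indel", "inframe_indel"})


@dataclass
class OverlapSummary:
    level: str  # "site" or "gene"
    n_only_a: int
    n_only_b: int
    n_shared: int
    shared_items: list

    @property
    def jaccard(self) -> float:
        denom = self.n_only_a + self.n_only_b + self.n_shared
        return self.n_shared / denom if denom else 0.0


def _keys(variants: Iterable, level: str) -> set:
    if level == "site":
        return {v.site_key for v in variants}
    if level == "gene":
        return {v.gene for v in variants if v.gene is not None}
    raise ConfigurationError(f"level must be 'site' or 'gene', got {level!r}")


def overlap_summary(variants_a: Iterable, variants_b: Iterable, level: str = "site") -> OverlapSummary:
    """Exact set overlap between two samples' mutations at site or gene level."""
    a, b = _keys(variants_a, level), _keys(variants_b, level)
    shared = a & b
    return OverlapSummary(
        level=level,
        n_only_a=len(a - b),
        n_only_b=len(b - a),
        n_shared=len(shared),
        shared_items=sorted(shared),
    )


@dataclass
class GeneListTally:
    list_name: str
    mutated_genes: dict  # sample -> sorted list of genes in the list
    counts: dict  # sample -> count
    recurrent_genes: dict  # sample -> subset flagged as recurrent


def gene_list_tally(
    variants_by_sample: Mapping[str, Sequence[VariantCall]],
    gene_lists: Mapping[str, set],
    recurrent: set | None = None,
) -> list[GeneListTally]:
    """Per-sample mutated-gene intersections with each curated list."""
    out = []
    for name, genes in gene_lists.items():
        if not genes:
            raise ConfigurationError(f"gene list {name!r} is empty")
        mutated = {
            sample: sorted({v.gene for v in vs if v.gene in genes})
            for sample, vs in variants_by_sample.items()
        }
        out.append(
            GeneListTally(
                list_name=name,
                mutated_genes=mutated,
                counts={s: len(g) for s, g in mutated.items()},
                recurrent_genes={
                    s: sorted(set(g) & recurrent) if recurrent else [] for s, g in mutated.items()
                },
            )
        )
    return out


def classify_truncating(consequence: str) -> str:
    """Map a consequence term to truncating / missense / other.

    Indels (frameshift and inframe) count as truncating, matching the
    convention that groups all indels with protein-truncating events.
    """
    if consequence in TRUNCATING_TERMS:
        return "truncating"
    if consequence == "missense":
        return "missense"
    if consequence not in {"synonymous", "noncoding", None}:
        logger.warning("unknown consequence %r classified as other", consequence)
    return "other"


@dataclass
class ContingencyTable2x2:
    """Rows: germline, somatic; columns: truncating, missense."""

    a: int  # germline truncating
    b: int  # germline missense
    c: int  # somatic truncating
    d: int  # somatic missense

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DataIntegrityError("contingency cells must be non-negative")
        if self.total == 0:
            raise DataIntegrityError("empty contingency table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class EnrichmentResult:
    odds_ratio: float
    p_value: float
    test_name: str = "fisher_exact_two_sided"
    chi2_p: float | None = None


def fisher_test(table: ContingencyTable2x2, compute_chi2: bool = True) -> EnrichmentResult:
    """Two-sided Fisher exact test with Haldane–Anscombe odds ratio on zeros.

    The p-value is reported exactly as computed (possibly far below any
    display floor), never truncated to a string convention.  A chi-square
    p-value (with continuity correction) is reported alongside unless
    disabled.
    """
    arr = table.as_array()
    _, p = scipy.stats.fisher_exact(arr, alternative="two-sided")
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    chi2_p = None
    if compute_chi2 and (arr.sum(axis=0) > 0).all() and (arr.sum(axis=1) > 0).all():
        chi2_p = float(scipy.stats.chi2_contingency(arr, correction=True)[1])
    return EnrichmentResult(odds_ratio=float(odds), p_value=float(max(p, 0.0)), chi2_p=chi2_p)


def _consequences(variants: Iterable) -> list[str]:
    out = []
    for v in variants:
        out.append(v if isinstance(v, str) else v.consequence)
    return out


def truncating_enrichment(
    germline_variants: Iterable, somatic_variants: Iterable
) -> tuple[ContingencyTable2x2, EnrichmentResult]:
    """2x2 germline/somatic x truncating/missense table plus Fisher test.

    Accepts VariantCalls or bare consequence strings; variants classified as
    "other" (silent, noncoding) are excluded from the table.
    """
    counts = {"germline": {"truncating": 0, "missense": 0}, "somatic": {"truncating": 0, "missense": 0}}
    for origin, variants in (("germline", germline_variants), ("somatic", somatic_variants)):
        for cons in _consequences(variants):
            cls = classify_truncating(cons)
            if cls != "other":
                counts[origin][cls] += 1
    table = ContingencyTable2x2(
        a=counts["germline"]["truncating"],
        b=counts["germline"]["missense"],
        c=counts["somatic"]["truncating"],
        d=counts["somatic"]["missense"],
    )
    return table, fisher_test(table)


def position_summary(
    germline_variants: Sequence[VariantCall],
    somatic_variants: Sequence[VariantCall],
    protein_length: int,
) -> pd.DataFrame:
    """Per-codon mutation table split by truncating/missense and origin.

    The data table behind a lollipop diagram: one row per (position, class,
    origin) with a count; variants without a protein position are tallied
    under a missing position.
    """
    rows: dict[tuple, int] = {}
    for origin, variants in (("germline", germline_variants), ("somatic", somatic_variants)):
        for v in variants:
            if v.protein_pos is not None and v.protein_pos > protein_length:
                raise DataIntegrityError(
                    f"protein position {v.protein_pos} beyond protein length {protein_length}"
                )
            key = (v.protein_pos, classify_truncating(v.consequence), origin)
            rows[key] = rows.get(key, 0) + 1
    records = [
        {"position": pos, "class": cls, "origin": origin, "count": n}
        for (pos, cls, origin), n in sorted(rows.items(), key=lambda kv: (kv[0][0] is None, kv[0]))
    ]
    return pd.DataFrame(records, columns=["position", "class", "origin", "count"])
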