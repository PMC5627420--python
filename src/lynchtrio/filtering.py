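"""Somatic-mutation retention: multi-caller consensus, population-frequency
filtering, non-silent classification and mutation burden.

The retention logic mirrors standard practice for multi-caller somatic
pipelines: keep a mutation only when more than one program calls it, drop
candidates whose population allele frequency exceeds 1% (likely germline),
and report burden over the non-silent subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, DataIntegrityError
from .variantio import VariantCall

logger = logging.getLogger(__name__)

DEFAULT_NONSILENT = frozenset(
    {"missense", "nonsense", "nonstop", "splicing", "frameshift_indel", "inframe_indel"}
)


@dataclass
class ConsensusConfig:
    min_callers: int = 2  # "more than one software program"
    max_pop_freq: float = 0.01  # strictly greater than 1% is removed
    nonsilent_terms: frozenset = DEFAULT_NONSILENT
    keep_unannotated: bool = False

    def __post_init__(self) -> None:
        if self.min_callers < 1:
            raise ConfigurationError("min_callers must be >= 1")
        if not 0.0 < self.max_pop_freq < 1.0:
            raise ConfigurationError("max_pop_freq must be in (0,1)")


def consensus_merge(
    callsets: Mapping[str, Sequence[VariantCall]],
    config: ConsensusConfig | None = None,
) -> list[VariantCall]:
    """Merge per-caller call sets of one sample, keeping multi-caller variants.

    One output call per (chrom, pos, ref, alt, sample) key supported by at
    least ``min_callers`` programs; ``callers`` records the full supporting
    set for audit.  Depths come from the first caller (in input order) that
    reports them.
    """
    config = config or ConsensusConfig()
    merged: dict[tuple, VariantCall] = {}
    samples = set()
    for caller, calls in callsets.items():
        for v in calls:
            samples.add(v.sample)
            if len(samples) > 1:
                raise DataIntegrityError(f"mixed samples in consensus input: {sorted(samples)}")
            existing = merged.get(v.key)
            if existing is None:
                c = v.copy()
                c.callers = set(v.callers) or {caller}
                merged[v.key] = c
            else:
                existing.callers |= v.callers or {caller}
                if existing.depth is None and v.depth is not None:
                    existing.depth, existing.alt_depth = v.depth, v.alt_depth
    out = [v for v in merged.values() if len(v.callers) >= config.min_callers]
    return sorted(out, key=lambda v: v.key)


def frequency_filter(
    variants: Sequence[VariantCall], config: ConsensusConfig | None = None
) -> list[VariantCall]:
    """Drop likely-germline variants: population frequency strictly above the cap.

    An absent frequency means no record of the variant being common, so it is
    retained.  Order is preserved.
    """
    config = config or ConsensusConfig()
    return [v for v in variants if v.pop_freq is None or v.pop_freq <= config.max_pop_freq]


def nonsilent_subset(
    variants: Sequence[VariantCall], config: ConsensusConfig | None = None
) -> list[VariantCall]:
    """Keep variants whose consequence is protein-affecting (non-silent)."""
    config = config or ConsensusConfig()
    out = []
    for v in variants:
        if v.consequence is None:
            if config.keep_unannotated:
                out.append(v)
            else:
                logger.warning("dropping unannotated variant %s:%d %s>%s", v.chrom, v.pos, v.ref, v.alt)
        elif v.consequence in config.nonsilent_terms:
            out.append(v)
    return out


def burden_report(
    variants_by_sample: Mapping[str, Sequence[VariantCall]],
    genome_size_bp: int,
    config: ConsensusConfig | None = None,
) -> pd.DataFrame:
    """Per-sample mutation counts and rates per megabase.

    When a config is given, the non-silent subset is taken first; otherwise
    the lists are counted as provided.
    """
    if genome_size_bp <= 0:
        raise ConfigurationError("genome size must be positive")
    mb = genome_size_bp / 1e6
    rows = []
    for sample, variants in variants_by_sample.items():
        counted = nonsilent_subset(variants, config) if config is not None else list(variants)
        rows.append({"sample": sample, "n_mutations": len(counted), "per_mb": len(counted) / mb})
    return pd.DataFrame(rows, columns=["sample", "n_mutations", "per_mb"])
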