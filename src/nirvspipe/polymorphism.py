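"""Multi-caller variant consensus and the level-of-polymorphism statistic.

Four variant callers are run over each region of interest; their calls are
left-normalized onto shared keys and a variant is retained when its allele
frequency exceeds 0.1 OR at least two callers report it.  The level of
polymorphism (LoP) of a region is the retained SNP+indel count divided by
the region length (events per bp).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    EnsembleVariant,
    NirvsLocus,
    RefLookup,
    VariantRecord,
    decompose_record,
    median_af,
)


@dataclass(frozen=True)
class FilterPolicy:
    """Retention rule: AF strictly above ``min_af`` OR >= ``min_callers``."""

    min_af: float = 0.1
    min_callers: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_af <= 1.0):
            raise ValueError("min_af must be in [0, 1]")
        if self.min_callers < 1:
            raise ValueError("min_callers must be >= 1")

    def retains(self, variant: EnsembleVariant) -> bool:
        af_ok = (
            variant.allele_frequency is not None
            and variant.allele_frequency > self.min_af
        )
        return af_ok or len(variant.callers) >= self.min_callers


def merge_callers(
    calls: Mapping[str, Sequence[VariantRecord]],
    region: NirvsLocus | None = None,
    fetch: RefLookup | None = None,
) -> list[EnsembleVariant]:
    """Collapse per-caller call lists onto normalized ensemble variants.

    Records are left-normalized (and MNPs decomposed to per-base SNPs)
    before keying, so caller-specific indel encodings of the same event
    merge.  Consensus AF is the median over reporting callers' non-missing
    AFs.  Output is sorted by (contig, pos, ref, alt).
    """
    if not calls:
        raise ValueError("at least one caller list required")
    grouped: dict[tuple[str, int, str, str], dict[str, list[float | None]]] = {}
    for caller_id in sorted(calls):
        seen_keys: set[tuple[str, int, str, str]] = set()
        for record in calls[caller_id]:
            for norm in decompose_record(record, fetch):
                if region is not None:
                    if norm.contig != region.contig:
                        continue
                    if not (region.start <= norm.pos < region.end):
                        continue
                key = norm.key
                entry = grouped.setdefault(key, {})
                if key not in seen_keys:
                    entry.setdefault(caller_id, []).append(norm.allele_frequency)
                    seen_keys.add(key)
    out = []
    for key in sorted(grouped):
        contig, pos, ref, alt = key
        per_caller = grouped[key]
        afs = [af for lst in per_caller.values() for af in lst]
        out.append(
            EnsembleVariant(
                contig=contig,
                pos=pos,
                ref=ref,
                alt=alt,
                callers=frozenset(per_caller),
                allele_frequency=median_af(afs),
            )
        )
    return out


def merge_callers_by_locus(
    calls: Mapping[str, Sequence[VariantRecord]],
    loci: Sequence[NirvsLocus],
    fetch: RefLookup | None = None,
) -> dict[str, list[EnsembleVariant]]:
    """Merge once and bucket ensemble variants by the locus containing them.

    Equivalent to calling :func:`merge_callers` per locus but with a single
    normalization pass; loci must not overlap.
    """
    merged = merge_callers(calls, region=None, fetch=fetch)
    ordered = sorted(loci, key=lambda l: (l.contig, l.start))
    out: dict[str, list[EnsembleVariant]] = {l.locus_id: [] for l in loci}
    by_contig: dict[str, list[NirvsLocus]] = {}
    for locus in ordered:
        by_contig.setdefault(locus.contig, []).append(locus)
    import bisect

    for variant in merged:
        contig_loci = by_contig.get(variant.contig)
        if not contig_loci:
            continue
        starts = [l.start for l in contig_loci]
        idx = bisect.bisect_right(starts, variant.pos) - 1
        if idx >= 0 and contig_loci[idx].start <= variant.pos < contig_loci[idx].end:
            out[contig_loci[idx].locus_id].append(variant)
    return out


def apply_filter(
    variants: Iterable[EnsembleVariant], policy: FilterPolicy = FilterPolicy()
) -> list[EnsembleVariant]:
    """Retained variants in input order: AF > min_af OR callers >= min_callers."""
    return [v for v in variants if policy.retains(v)]


def lop(retained: Sequence[EnsembleVariant] | int, locus_length: int) -> float:
    """Level of polymorphism: retained event count / locus length (per bp).

    An indel counts as one event regardless of its span.
    """
    if locus_length <= 0:
        raise ValueError("locus_length must be >= 1")
    count = retained if isinstance(retained, int) else len(retained)
    return count / locus_length


def lop_matrix(
    retained_by_sample: Mapping[str, Mapping[str, Sequence[EnsembleVariant]]],
    loci: Sequence[NirvsLocus],
    presence: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Loci x samples table of LoP values.

    ``retained_by_sample[sample][locus_id]`` holds the retained variants.
    Loci called absent in a sample (per ``presence``) are recorded as
    missing (NaN), never as 0.
    """
    lengths = {l.locus_id: l.length for l in loci}
    if len(lengths) != len(loci):
        raise ValueError("duplicate locus ids")
    samples = list(retained_by_sample)
    index = pd.Index([l.locus_id for l in loci], name="locus")
    table = pd.DataFrame(np.nan, index=index, columns=samples)
    for sample in samples:
        per_sample = retained_by_sample[sample]
        for locus_id in index:
            if presence is not None and not bool(presence.loc[locus_id, sample]):
                continue
            variants = per_sample.get(locus_id, ())
            table.loc[locus_id, sample] = lop(len(variants), lengths[locus_id])
    return table
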