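"""Distribution comparisons and enrichment tests on LoP tables.

Each locus's LoP distribution across samples is compared with a per-sample
reference built from slow-evolving genes (SGs): the reference value for a
sample is the median LoP of the SGs in that sample.  Loci are scored with a
two-sample Kolmogorov-Smirnov test and a fold change of medians, with
Bonferroni-adjusted significance; the core locus set is tested for
enrichment of annotation categories with a one-sided hypergeometric test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import NirvsLocus


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    n_tests: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_tests < 1:
            raise ValueError("n_tests must be >= 1")


@dataclass(frozen=True)
class VolcanoRow:
    locus_id: str
    log2_fold_change: float
    neg_log10_p: float
    significant: bool
    d_statistic: float
    p_value: float
    fold_change: float


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample KS statistic (sup ECDF distance) and asymptotic p-value."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    result = sps.ks_2samp(x, y, method="asymp")
    return float(result.statistic), float(result.pvalue)


def sg_reference(lop_table: pd.DataFrame, sg_ids: Iterable[str]) -> pd.Series:
    """Per-sample reference: the median LoP over the slow-gene loci."""
    sg_ids = list(sg_ids)
    missing = [sid for sid in sg_ids if sid not in lop_table.index]
    if missing:
        raise ValueError(f"SG ids not in table: {missing}")
    sub = lop_table.loc[sg_ids]
    medians = sub.median(axis=0, skipna=True)
    empty = medians.index[sub.notna().sum(axis=0) == 0]
    if len(empty):
        raise ValueError(f"samples with no SG values: {list(empty)}")
    medians.name = "sg_reference"
    return medians


def bonferroni_threshold(config: StatsConfig) -> float:
    """Adjusted per-test significance level alpha / m."""
    return config.alpha / config.n_tests


def compare_locus(
    locus_id: str,
    locus_values: Sequence[float],
    reference: Sequence[float],
    config: StatsConfig,
) -> VolcanoRow:
    """KS + fold-change comparison of one locus against the SG reference.

    FC is the ratio of medians; a locus of all zeros gives FC 0 and
    ``log2FC = -inf`` (sentinel).  A zero reference median is an error.
    """
    values = np.asarray([v for v in locus_values if not np.isnan(v)], dtype=float)
    ref = np.asarray(list(reference), dtype=float)
    if values.size < 2:
        raise ValueError(f"locus {locus_id!r}: need >=2 non-missing values")
    ref_median = float(np.median(ref))
    if ref_median == 0:
        raise ValueError("reference median is zero; fold change undefined")
    fc = float(np.median(values)) / ref_median
    log2fc = math.log2(fc) if fc > 0 else float("-inf")
    d, p = ks_two_sample(values, ref)
    threshold = bonferroni_threshold(config)
    neg_log10_p = -math.log10(p) if p > 0 else float("inf")
    return VolcanoRow(
        locus_id=locus_id,
        log2_fold_change=log2fc,
        neg_log10_p=neg_log10_p,
        significant=p < threshold,
        d_statistic=d,
        p_value=p,
        fold_change=fc,
    )


def volcano_table(
    lop_table: pd.DataFrame,
    sg_ids: Iterable[str],
    config: StatsConfig | None = None,
    test_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Volcano rows for every testable locus against the SG reference."""
    sg_ids = list(sg_ids)
    if test_ids is None:
        test_ids = [lid for lid in lop_table.index if lid not in sg_ids]
    test_ids = list(test_ids)
    if config is None:
        config = StatsConfig(n_tests=max(len(test_ids), 1))
    ref = sg_reference(lop_table, sg_ids)
    rows = []
    for lid in test_ids:
        values = lop_table.loc[lid]
        if values.notna().sum() < 2:
            continue
        row = compare_locus(lid, values.to_numpy(), ref.to_numpy(), config)
        rows.append(
            {
                "locus": row.locus_id,
                "log2_fold_change": row.log2_fold_change,
                "neg_log10_p": row.neg_log10_p,
                "significant": row.significant,
                "d_statistic": row.d_statistic,
                "p_value": row.p_value,
            }
        )
    return pd.DataFrame(rows).set_index("locus") if rows else pd.DataFrame()


def hypergeometric_enrichment(
    universe: Mapping[str, Hashable],
    subset: Iterable[str],
    level: Hashable,
) -> float:
    """Upper-tail hypergeometric p for enrichment of ``level`` in ``subset``.

    ``universe`` maps every locus id to its attribute level; ``subset`` must
    be contained in the universe.  Returns P(X >= k) for
    X ~ Hypergeom(N=|universe|, K=#universe at level, n=|subset|).
    """
    subset = set(subset)
    if not subset <= set(universe):
        raise ValueError("subset must be contained in the universe")
    N = len(universe)
    K = sum(1 for v in universe.values() if v == level)
    n = len(subset)
    k = sum(1 for lid in subset if universe[lid] == level)
    return float(sps.hypergeom.sf(k - 1, N, K, n))


LENGTH_CUTOFF_BP = 500  # loci of exactly 500 bp count as "short"


def locus_attribute(locus: NirvsLocus, attribute: str) -> Hashable:
    """Annotation level of one locus for an enrichment attribute."""
    if attribute == "family":
        return locus.viral_family
    if attribute == "orf":
        return locus.viral_orf
    if attribute == "length":
        return "short" if locus.length <= LENGTH_CUTOFF_BP else "long"
    if attribute == "context":
        return locus.context
    raise ValueError(f"unknown attribute {attribute!r}")


def enrichment_report(
    loci: Sequence[NirvsLocus],
    subset: Iterable[str],
    attributes: Sequence[str] = ("family", "orf", "length", "context"),
) -> pd.DataFrame:
    """Hypergeometric enrichment of the subset for each annotation level.

    Mirrors the four tested partitions: viral family, viral ORF, the 500-bp
    length dichotomy, and genomic context.
    """
    subset = set(subset)
    rows = []
    for attribute in attributes:
        universe = {l.locus_id: locus_attribute(l, attribute) for l in loci}
        levels = sorted({v for v in universe.values() if v is not None}, key=str)
        for level in levels:
            p = hypergeometric_enrichment(universe, subset, level)
            rows.append(
                {
                    "attribute": attribute,
                    "level": level,
                    "N": len(universe),
                    "K": sum(1 for v in universe.values() if v == level),
                    "n": len(subset),
                    "k": sum(1 for lid in subset if universe[lid] == level),
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)
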