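"""Presence/absence calling of integration loci from read-depth profiles.

A locus is called present in a sample when its depth profile contains a run
of at least ``min_run`` consecutive positions each covered by at least
``min_depth`` reads (defaults 30 and 5).  From the resulting loci x samples
matrix the core set (present everywhere), the universally absent set and
per-family prevalence are derived.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import DepthProfile, NirvsLocus


@dataclass(frozen=True)
class PresenceCriteria:
    min_depth: int = 5
    min_run: int = 30

    def __post_init__(self) -> None:
        if self.min_depth < 1 or self.min_run < 1:
            raise ValueError("min_depth and min_run must be >= 1")


@dataclass(frozen=True)
class PresenceCall:
    present: bool
    #: leftmost maximal qualifying run as a half-open interval in locus
    #: coordinates, or None when absent
    interval: tuple[int, int] | None = None


def call_presence(
    profile: DepthProfile, criteria: PresenceCriteria = PresenceCriteria()
) -> PresenceCall:
    """Present iff >= min_run consecutive positions each reach min_depth.

    Returns the leftmost maximal qualifying run.  Loci shorter than
    ``min_run`` are always absent and trigger a warning.
    """
    depths = profile.depths
    if depths.size == 0:
        raise ValueError(f"empty depth profile for locus {profile.locus_id!r}")
    if depths.size < criteria.min_run:
        warnings.warn(
            f"locus {profile.locus_id!r} is shorter ({depths.size}) than the "
            f"required run length ({criteria.min_run}); calling absent",
            stacklevel=2,
        )
        return PresenceCall(False, None)
    ok = depths >= criteria.min_depth
    run_start = None
    for i, flag in enumerate(ok):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start >= criteria.min_run:
                return PresenceCall(True, (run_start, i))
            run_start = None
    if run_start is not None and ok.size - run_start >= criteria.min_run:
        return PresenceCall(True, (run_start, ok.size))
    return PresenceCall(False, None)


def build_presence_matrix(
    profiles: Mapping[str, Mapping[str, DepthProfile]],
    criteria: PresenceCriteria = PresenceCriteria(),
) -> pd.DataFrame:
    """Loci x samples boolean matrix from ``profiles[sample][locus_id]``.

    Every sample must provide a profile for every locus.
    """
    samples = list(profiles)
    if not samples:
        raise ValueError("no samples")
    loci = list(profiles[samples[0]])
    data: dict[str, list[bool]] = {}
    for sample in samples:
        per_sample = profiles[sample]
        column = []
        for locus_id in loci:
            if locus_id not in per_sample:
                raise ValueError(f"missing profile for sample {sample!r}, locus {locus_id!r}")
            column.append(call_presence(per_sample[locus_id], criteria).present)
        data[sample] = column
    return pd.DataFrame(data, index=pd.Index(loci, name="locus"))


def core_and_absent_sets(matrix: pd.DataFrame) -> tuple[set[str], set[str]]:
    """(loci present in all samples, loci absent in all samples)."""
    if matrix.isna().any().any():
        raise ValueError("presence matrix has missing cells")
    core = set(matrix.index[matrix.all(axis=1)])
    universal_absent = set(matrix.index[~matrix.any(axis=1)])
    return core, universal_absent


def prevalence(
    matrix: pd.DataFrame,
    sample: str,
    family: str,
    loci: Iterable[NirvsLocus],
    total_in_family: int,
) -> float:
    """Fraction of a viral family's annotated loci detected in one sample.

    The denominator is the annotated total for the family (40 R, 32 F in the
    reference genome), not the number of loci in the matrix.
    """
    if total_in_family <= 0:
        raise ValueError("total_in_family must be positive")
    family_ids = [l.locus_id for l in loci if l.viral_family == family]
    in_matrix = [lid for lid in family_ids if lid in matrix.index]
    if len(in_matrix) > total_in_family:
        raise ValueError(
            f"matrix holds {len(in_matrix)} {family} loci but total_in_family={total_in_family}"
        )
    n_present = int(matrix.loc[in_matrix, sample].sum()) if in_matrix else 0
    return n_present / total_in_family


def write_presence_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.astype(int).to_csv(path, sep="\t")


def read_presence_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0).astype(bool)
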