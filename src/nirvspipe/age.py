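"""Molecular-clock dating of viral integrations.

Given a multiple alignment of one integration locus across individuals, all
gap-containing columns are removed, mutations are counted against the
majority-rule consensus, and the integration age in years is

    age = (tot_mut / n_seqs) / (MR * L * GpY)

with MR the per-site per-generation mutation rate, L the ungapped alignment
length and GpY generations per year.  MR and GpY are scanned over a grid —
by default the Drosophila-like rate range 3.5e-9..8.4e-9 and 4..17
generations per year — giving a minimum and maximum age.  All mutations are
assumed neutral.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import AlignIO

GAP = "-"
AMBIGUOUS = "N"


@dataclass(frozen=True)
class ParameterGrid:
    """Mutation-rate (per site per generation) and generations-per-year ranges."""

    mr_low: float = 3.5e-9
    mr_high: float = 8.4e-9
    gpy_low: float = 4.0
    gpy_high: float = 17.0

    def __post_init__(self) -> None:
        if not (0 < self.mr_low <= self.mr_high):
            raise ValueError("need 0 < mr_low <= mr_high")
        if not (0 < self.gpy_low <= self.gpy_high):
            raise ValueError("need 0 < gpy_low <= gpy_high")


@dataclass(frozen=True)
class AgeModel:
    tot_mut: int
    n_seqs: int
    seq_length: int
    mr: float
    gpy: float

    def __post_init__(self) -> None:
        if self.n_seqs < 2:
            raise ValueError("need >= 2 sequences")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        if self.mr <= 0 or self.gpy <= 0:
            raise ValueError("mr and gpy must be positive")
        if self.tot_mut < 0:
            raise ValueError("tot_mut must be >= 0")


def load_alignment(source: str | Path | Sequence[str]) -> list[str]:
    """Alignment rows as upper-case strings, from FASTA or from sequences."""
    if isinstance(source, (str, Path)):
        aln = AlignIO.read(str(source), "fasta")
        rows = [str(rec.seq).upper() for rec in aln]
    else:
        rows = [s.upper() for s in source]
    if len({len(r) for r in rows}) > 1:
        raise ValueError("alignment rows have unequal lengths")
    return rows


def filter_gap_columns(rows: Sequence[str]) -> tuple[list[str], int]:
    """Drop every column containing a gap; return (rows, remaining length L)."""
    rows = [r.upper() for r in rows]
    if not rows:
        raise ValueError("empty alignment")
    if len({len(r) for r in rows}) > 1:
        raise ValueError("alignment rows have unequal lengths")
    keep = [i for i in range(len(rows[0])) if all(r[i] != GAP for r in rows)]
    if not keep:
        raise ValueError("no ungapped columns remain")
    out = ["".join(r[i] for i in keep) for r in rows]
    return out, len(keep)


def consensus_sequence(rows: Sequence[str]) -> str:
    """Majority-rule consensus; N never wins; ties go to the earliest row's base."""
    if len(rows) < 2:
        raise ValueError("need >= 2 sequences")
    length = len(rows[0])
    out = []
    for i in range(length):
        counts: dict[str, int] = {}
        for r in rows:
            base = r[i]
            if base == AMBIGUOUS or base == GAP:
                continue
            counts[base] = counts.get(base, 0) + 1
        if not counts:
            out.append(AMBIGUOUS)
            continue
        best = max(counts.values())
        tied = {b for b, c in counts.items() if c == best}
        if len(tied) == 1:
            out.append(tied.pop())
        else:
            for r in rows:  # first row whose base is among the tied wins
                if r[i] in tied:
                    out.append(r[i])
                    break
    return "".join(out)


def count_mutations(rows: Sequence[str], reference: str | None = None) -> int:
    """Total mutations: per-sequence mismatches against the consensus.

    ``reference`` substitutes a designated sequence for the majority-rule
    consensus.  Positions where the sequence or the consensus carries N are
    never counted.
    """
    cons = reference.upper() if reference is not None else consensus_sequence(rows)
    if any(len(r) != len(cons) for r in rows):
        raise ValueError("reference length differs from alignment length")
    total = 0
    for r in rows:
        for a, b in zip(r.upper(), cons):
            if a != b and a != AMBIGUOUS and b != AMBIGUOUS:
                total += 1
    return total


def estimate_age(model: AgeModel) -> float:
    """Integration age in years under the neutral molecular clock."""
    mean_mut = model.tot_mut / model.n_seqs
    return mean_mut / (model.mr * model.seq_length * model.gpy)


def age_bounds(
    tot_mut: int,
    n_seqs: int,
    seq_length: int,
    grid: ParameterGrid = ParameterGrid(),
) -> tuple[float, float]:
    """(min, max) age over the parameter grid corners.

    The youngest estimate uses the fastest clock (max MR, max GpY); the
    oldest uses the slowest (min MR, min GpY).
    """
    if tot_mut == 0:
        return (0.0, 0.0)
    youngest = estimate_age(AgeModel(tot_mut, n_seqs, seq_length, grid.mr_high, grid.gpy_high))
    oldest = estimate_age(AgeModel(tot_mut, n_seqs, seq_length, grid.mr_low, grid.gpy_low))
    return (youngest, oldest)


def age_from_alignment(
    source: str | Path | Sequence[str],
    grid: ParameterGrid = ParameterGrid(),
    reference: str | None = None,
) -> dict:
    """Full dating of one locus alignment: gap filter, count, grid bounds."""
    rows = load_alignment(source)
    if reference is not None:
        combined, L = filter_gap_columns([reference] + list(rows))
        ref, ungapped = combined[0], combined[1:]
    else:
        ungapped, L = filter_gap_columns(rows)
        ref = None
    tot_mut = count_mutations(ungapped, ref)
    lo, hi = age_bounds(tot_mut, len(ungapped), L, grid)
    return {
        "n_seqs": len(ungapped),
        "seq_length": L,
        "tot_mut": tot_mut,
        "mean_mut_per_seq": tot_mut / len(ungapped),
        "age_min_years": lo,
        "age_max_years": hi,
    }
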