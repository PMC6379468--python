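"""Ranking ortholog groups by interspecies protein divergence.

For each ortholog group the mean pairwise Smith-Waterman identity across
species is computed and normalized by the mean identity over all
interspecies best-reciprocal-hit (BRH) pairs; the extreme 0.1% tails of the
normalized distribution mark the slowest- and fastest-evolving genes.

Alignment is local with affine gaps (BLOSUM62, gap open 11, extend 1, BLAST
convention: a gap of length k costs open + k*extend).  Identity is identical
aligned residue pairs over all alignment columns, gap columns included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices


@dataclass(frozen=True)
class SWResult:
    score: float
    aligned_a: str
    aligned_b: str
    identity: float


@dataclass(frozen=True)
class OrthologGroup:
    group_id: str
    members: Mapping[str, str]  # species -> amino-acid sequence

    def __post_init__(self) -> None:
        if any(not seq for seq in self.members.values()):
            raise ValueError(f"group {self.group_id!r}: empty member sequence")


@dataclass(frozen=True)
class DivergenceScore:
    group_id: str
    raw_identity: float
    normalized: float


def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # BLAST convention: first gap position costs open + extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def smith_waterman(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> SWResult:
    """Optimal local protein alignment with affine gap penalties."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _aligner(matrix, gap_open, gap_extend)
    alignments = aligner.align(a.upper(), b.upper())
    try:
        best = alignments[0]
    except IndexError:
        return SWResult(0.0, "", "", 0.0)
    if best.score <= 0:
        return SWResult(max(best.score, 0.0), "", "", 0.0)
    counts = best.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    identity = counts.identities / columns if columns else 0.0
    return SWResult(float(best.score), str(best[0]), str(best[1]), identity)


def sw_identity(a: str, b: str, **kwargs) -> float:
    return smith_waterman(a, b, **kwargs).identity


def best_reciprocal_hits(
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    **align_kwargs,
) -> list[tuple[str, str, float]]:
    """BRH pairs between two proteomes with their alignment identities.

    (x, y) is a BRH iff y is x's top-scoring hit in b and x is y's
    top-scoring hit in a; score ties break lexicographically by id.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("proteomes must be non-empty")
    results: dict[tuple[str, str], SWResult] = {}
    for ida in proteome_a:
        for idb in proteome_b:
            results[(ida, idb)] = smith_waterman(
                proteome_a[ida], proteome_b[idb], **align_kwargs
            )
    top_in_b = {
        ida: min(proteome_b, key=lambda idb: (-results[(ida, idb)].score, idb))
        for ida in proteome_a
    }
    top_in_a = {
        idb: min(proteome_a, key=lambda ida: (-results[(ida, idb)].score, ida))
        for idb in proteome_b
    }
    pairs = []
    for ida, idb in sorted(top_in_b.items()):
        if top_in_a[idb] == ida:
            pairs.append((ida, idb, results[(ida, idb)].identity))
    return pairs


def brh_mean_identity(
    proteomes: Mapping[str, Mapping[str, str]], **align_kwargs
) -> float:
    """Mean identity over BRH pairs across every species pair."""
    identities = []
    for sp_a, sp_b in combinations(sorted(proteomes), 2):
        for _, _, ident in best_reciprocal_hits(
            proteomes[sp_a], proteomes[sp_b], **align_kwargs
        ):
            identities.append(ident)
    if not identities:
        raise ValueError("no BRH pairs found")
    return sum(identities) / len(identities)


def group_divergence(
    group: OrthologGroup, brh_mean: float, **align_kwargs
) -> DivergenceScore:
    """Mean interspecies SW identity of a group, normalized by the BRH mean."""
    if brh_mean <= 0:
        raise ValueError("brh_mean must be positive")
    species = sorted(group.members)
    if len(species) < 2:
        raise ValueError(f"group {group.group_id!r} has a single species")
    identities = [
        sw_identity(group.members[a], group.members[b], **align_kwargs)
        for a, b in combinations(species, 2)
    ]
    raw = sum(identities) / len(identities)
    return DivergenceScore(group.group_id, raw, raw / brh_mean)


def select_tails(
    scores: Sequence[DivergenceScore], tail_fraction: float = 0.001
) -> tuple[list[DivergenceScore], list[DivergenceScore]]:
    """(slow, fast) tails of the normalized-identity distribution.

    ``slow`` holds the ceil(tail_fraction*N) most conserved groups (highest
    normalized identity), ``fast`` the most divergent.  Ties break on
    group_id.
    """
    if not scores:
        raise ValueError("no scores")
    k = math.ceil(tail_fraction * len(scores))
    if 2 * k > len(scores):
        raise ValueError("tails would overlap: 2*ceil(frac*N) > N")
    ranked = sorted(scores, key=lambda s: (-s.normalized, s.group_id))
    return ranked[:k], list(reversed(ranked[-k:]))


def score_groups(
    groups: Sequence[OrthologGroup],
    proteomes: Mapping[str, Mapping[str, str]] | None = None,
    brh_mean: float | None = None,
    **align_kwargs,
) -> list[DivergenceScore]:
    """Score every group; the BRH normalizer may be given or computed."""
    if brh_mean is None:
        if proteomes is None:
            raise ValueError("need proteomes or an explicit brh_mean")
        brh_mean = brh_mean_identity(proteomes, **align_kwargs)
    return [group_divergence(g, brh_mean, **align_kwargs) for g in groups]
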