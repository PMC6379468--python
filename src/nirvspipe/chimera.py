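"""Screening host-virus chimeric read candidates and soft-clip evidence.

Candidate chimeric pairs (host read + viral mate) are screened with two
false-positive rules: the viral segment must be at least 50 nt, and its
low-complexity fraction — the largest share of positions covered by tandem
repeats of any single mono- or di-nucleotide unit — must not exceed 80%.
Soft-clipped read tails anchored at locus boundaries are collapsed into a
consensus extension sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pysam

LOW_COMPLEXITY = "low_complexity"
SHORT_VIRAL = "short_viral"

_MONO = ("A", "C", "G", "T")
_DI = tuple(a + b for a in _MONO for b in _MONO if a != b)


@dataclass(frozen=True)
class ChimeraCandidate:
    read_id: str
    host_contig: str
    host_pos: int
    host_seq: str
    virus_id: str
    viral_seq: str

    def __post_init__(self) -> None:
        if not self.host_seq or not self.viral_seq:
            raise ValueError(f"candidate {self.read_id!r}: empty segment")


@dataclass(frozen=True)
class ScreenResult:
    retained: list[ChimeraCandidate]
    rejected: list[tuple[ChimeraCandidate, str]]


def _tandem_coverage(seq: str, unit: str) -> int:
    """Positions of ``seq`` covered by runs of >= 2 consecutive copies of
    ``unit`` (any phase)."""
    k = len(unit)
    n = len(seq)
    covered = [False] * n
    pattern = unit * (n // k + 2)
    for phase in range(k):
        i = phase
        while i < n:
            j = i
            while j < n and seq[j] == pattern[j - i]:
                j += 1
            if j - i >= 2 * k:
                for p in range(i, j):
                    covered[p] = True
                i = j
            else:
                i += k
    return sum(covered)


def low_complexity_fraction(seq: str) -> float:
    """Max fraction of positions inside tandem repeats of one 1- or 2-mer.

    A run must contain at least two consecutive copies of the unit; partial
    trailing copies extend the run.  The 12 heterogeneous dinucleotides and
    the 4 mononucleotides are all tried; the best coverage wins.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    best = 0
    for unit in _MONO + _DI:
        best = max(best, _tandem_coverage(seq, unit))
    return best / len(seq)


def filter_candidates(
    candidates: Iterable[ChimeraCandidate],
    complexity_threshold: float = 0.8,
    min_viral_len: int = 50,
) -> ScreenResult:
    """Apply the false-positive rules; every rejection carries its reason.

    A candidate passes iff the viral segment is >= ``min_viral_len`` nt and
    its low-complexity fraction is <= ``complexity_threshold`` (strictly
    above 80% is rejected; exactly 80% is retained).
    """
    retained: list[ChimeraCandidate] = []
    rejected: list[tuple[ChimeraCandidate, str]] = []
    for cand in candidates:
        if len(cand.viral_seq) < min_viral_len:
            rejected.append((cand, SHORT_VIRAL))
        elif low_complexity_fraction(cand.viral_seq) > complexity_threshold:
            rejected.append((cand, LOW_COMPLEXITY))
        else:
            retained.append(cand)
    return ScreenResult(retained, rejected)


def read_candidates_tsv(source: str | Path | Iterable[str]) -> list[ChimeraCandidate]:
    """TSV: read_id, host_contig, host_pos, host_seq, virus_id, viral_seq."""
    if isinstance(source, (str, Path)):
        lines: Iterable[str] = Path(source).read_text().splitlines()
    else:
        lines = source
    out = []
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("read_id"):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise ValueError(f"candidate line needs 6 columns: {line!r}")
        out.append(
            ChimeraCandidate(
                read_id=fields[0],
                host_contig=fields[1],
                host_pos=int(fields[2]),
                host_seq=fields[3],
                virus_id=fields[4],
                viral_seq=fields[5],
            )
        )
    return out


def write_screen_result(result: ScreenResult, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("read_id\tvirus_id\tstatus\treason\n")
        for cand in result.retained:
            handle.write(f"{cand.read_id}\t{cand.virus_id}\tretained\t.\n")
        for cand, reason in result.rejected:
            handle.write(f"{cand.read_id}\t{cand.virus_id}\trejected\t{reason}\n")


# ---------------------------------------------------------------------------
# Soft-clip consensus extension
# ---------------------------------------------------------------------------

def _clipped_tails(
    reads: Iterable[pysam.AlignedSegment],
    contig: str,
    position: int,
    side: str,
    min_clip_len: int,
) -> list[str]:
    tails = []
    for seg in reads:
        if seg.is_unmapped or seg.reference_name != contig or seg.cigartuples is None:
            continue
        cig = seg.cigartuples
        if side == "right":
            # soft clip at the read's 3' alignment end, anchored at position
            if cig[-1][0] == 4 and seg.reference_end == position:
                clip_len = cig[-1][1]
                if clip_len >= min_clip_len:
                    tails.append(seg.query_sequence[-clip_len:])
        elif side == "left":
            if cig[0][0] == 4 and seg.reference_start == position:
                clip_len = cig[0][1]
                if clip_len >= min_clip_len:
                    # stored reversed so position 0 is adjacent to the boundary
                    tails.append(seg.query_sequence[:clip_len][::-1])
        else:
            raise ValueError("side must be 'left' or 'right'")
    return tails


def softclip_extension(
    reads: Iterable[pysam.AlignedSegment] | str | Path,
    contig: str,
    position: int,
    side: str = "right",
    min_clip_len: int = 20,
    min_support: int = 3,
    consensus_frac: float = 0.8,
) -> str | None:
    """Consensus of soft-clipped tails anchored at a locus boundary.

    Tails of >= ``min_clip_len`` whose clip starts exactly at ``position``
    on the given side are stacked outward from the boundary; the consensus
    extends while >= ``min_support`` tails cover a position and the
    majority base reaches ``consensus_frac`` of the covering tails.  For
    ``side='left'`` the returned sequence reads in genome orientation
    (ending at the boundary).  Returns None when unsupported.
    """
    if isinstance(reads, (str, Path)):
        with pysam.AlignmentFile(str(reads), "r") as handle:
            tails = _clipped_tails(handle.fetch(until_eof=True), contig, position, side, min_clip_len)
    else:
        tails = _clipped_tails(reads, contig, position, side, min_clip_len)
    if len(tails) < min_support:
        return None
    consensus = []
    for i in range(max(len(t) for t in tails)):
        covering = [t[i] for t in tails if len(t) > i]
        if len(covering) < min_support:
            break
        counts: dict[str, int] = {}
        for base in covering:
            counts[base] = counts.get(base, 0) + 1
        base, count = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
        if count / len(covering) < consensus_frac:
            break
        consensus.append(base)
    if not consensus:
        return None
    seq = "".join(consensus)
    return seq[::-1] if side == "left" else seq
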