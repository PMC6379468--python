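"""Domain types and standard-format I/O shared by every pipeline stage.

Coordinates are 0-based half-open throughout the package: BED files are
native, VCF positions are converted on load and converted back on write.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pysam

VIRAL_FAMILIES = ("Flavivirus", "Rhabdovirus")
CONTEXTS = ("exon", "piRNA_cluster", "intergenic")

#: Looks up the reference base (upper case, single character) at a 0-based
#: position of a contig.  Needed only for left-aligning indels.
RefLookup = Callable[[str, int], str]


class ParseError(ValueError):
    """A malformed line or record in an input file."""


@dataclass(frozen=True)
class NirvsLocus:
    """An annotated viral-integration region of the host genome."""

    locus_id: str
    contig: str
    start: int
    end: int
    strand: str = "unknown"
    viral_family: str | None = None
    viral_orf: str | None = None
    context: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"locus {self.locus_id!r}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-", "unknown"):
            raise ValueError(f"locus {self.locus_id!r}: bad strand {self.strand!r}")
        if self.viral_family is not None and self.viral_family not in VIRAL_FAMILIES:
            raise ValueError(
                f"locus {self.locus_id!r}: viral_family must be one of {VIRAL_FAMILIES}"
            )
        if self.context is not None and self.context not in CONTEXTS:
            raise ValueError(f"locus {self.locus_id!r}: context must be one of {CONTEXTS}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DepthProfile:
    """Per-position read depth over a locus after mapping-quality filtering."""

    locus_id: str
    depths: np.ndarray
    min_mapq_applied: int = 20

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=int)
        if self.depths.ndim != 1:
            raise ValueError("depths must be one-dimensional")
        if (self.depths < 0).any():
            raise ValueError("depths must be non-negative")

    def __len__(self) -> int:
        return self.depths.size


@dataclass(frozen=True)
class VariantRecord:
    """A single-caller variant call, position 0-based after loading."""

    contig: str
    pos: int
    ref: str
    alt: str
    caller_id: str
    allele_frequency: float | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.contig}:{self.pos} ref equals alt ({self.ref!r})")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty (anchored representation)")
        if self.allele_frequency is not None and not (0.0 <= self.allele_frequency <= 1.0):
            raise ValueError(f"allele frequency {self.allele_frequency} outside [0, 1]")

    @property
    def vtype(self) -> str:
        return "SNP" if len(self.ref) == len(self.alt) == 1 else "INDEL"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class EnsembleVariant:
    """A left-normalized variant with the set of callers that reported it."""

    contig: str
    pos: int
    ref: str
    alt: str
    callers: frozenset[str]
    allele_frequency: float | None = None

    def __post_init__(self) -> None:
        if not self.callers:
            raise ValueError("an ensemble variant needs at least one caller")

    @property
    def vtype(self) -> str:
        return "SNP" if len(self.ref) == len(self.alt) == 1 else "INDEL"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class Sample:
    sample_id: str
    role: str = "SSM"

    def __post_init__(self) -> None:
        if self.role not in ("SSM", "population_individual"):
            raise ValueError(f"bad sample role {self.role!r}")


# ---------------------------------------------------------------------------
# BED loci
# ---------------------------------------------------------------------------

def _parse_name_field(token: str) -> tuple[str, dict[str, str]]:
    parts = token.split(";")
    attrs: dict[str, str] = {}
    for part in parts[1:]:
        if "=" not in part:
            raise ValueError(f"bad attribute token {part!r} (expected key=value)")
        key, value = part.split("=", 1)
        attrs[key] = value
    return parts[0], attrs


def read_loci(bed_source: str | Path | Iterable[str]) -> list[NirvsLocus]:
    """Read NIRVS loci from a BED file (>=4 columns).

    Column 4 carries the locus id plus optional ``key=value`` tokens
    separated by semicolons: ``family``, ``orf``, ``context``.  Column 6, if
    present, is the strand.
    """
    if isinstance(bed_source, (str, Path)):
        lines: Iterable[str] = Path(bed_source).read_text().splitlines()
    else:
        lines = list(bed_source)

    loci: list[NirvsLocus] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 4:
            raise ParseError(f"line {lineno}: expected >=4 BED columns, got {len(fields)}")
        try:
            contig, start, end = fields[0], int(fields[1]), int(fields[2])
            locus_id, attrs = _parse_name_field(fields[3])
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "unknown"
            locus = NirvsLocus(
                locus_id=locus_id,
                contig=contig,
                start=start,
                end=end,
                strand=strand,
                viral_family=attrs.get("family"),
                viral_orf=attrs.get("orf"),
                context=attrs.get("context"),
            )
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
        if locus.locus_id in seen:
            raise ParseError(f"line {lineno}: duplicate locus_id {locus.locus_id!r}")
        seen.add(locus.locus_id)
        loci.append(locus)
    return loci


def write_loci(loci: Iterable[NirvsLocus], path: str | Path) -> None:
    """Write loci back to BED, preserving the attribute tokens of column 4."""
    with open(path, "w") as handle:
        for locus in loci:
            name = locus.locus_id
            if locus.viral_family:
                name += f";family={locus.viral_family}"
            if locus.viral_orf:
                name += f";orf={locus.viral_orf}"
            if locus.context:
                name += f";context={locus.context}"
            strand = locus.strand if locus.strand in ("+", "-") else "."
            handle.write(
                f"{locus.contig}\t{locus.start}\t{locus.end}\t{name}\t0\t{strand}\n"
            )


# ---------------------------------------------------------------------------
# Depth
# ---------------------------------------------------------------------------

def depth_from_alignments(
    reads: str | Path | pysam.AlignmentFile | Iterable[pysam.AlignedSegment],
    locus: NirvsLocus,
    min_mapq: int = 20,
    *,
    contigs: Sequence[str] | None = None,
) -> DepthProfile:
    """Depth profile over ``locus`` counting reads with MAPQ strictly above
    ``min_mapq``; only aligned (M/=/X) bases contribute, never soft clips.
    """
    close = False
    if isinstance(reads, (str, Path)):
        reads = pysam.AlignmentFile(str(reads), "r")
        close = True
    try:
        if isinstance(reads, pysam.AlignmentFile):
            if locus.contig not in reads.references:
                raise ValueError(
                    f"contig {locus.contig!r} absent from alignment header"
                )
            segments: Iterable[pysam.AlignedSegment] = reads.fetch(until_eof=True)
        else:
            segments = reads
            if contigs is not None and locus.contig not in contigs:
                raise ValueError(f"contig {locus.contig!r} absent from alignment header")
        depths = np.zeros(locus.length, dtype=int)
        for seg in segments:
            if seg.is_unmapped or seg.reference_name != locus.contig:
                continue
            if seg.mapping_quality <= min_mapq:
                continue
            for block_start, block_end in seg.get_blocks():
                lo = max(block_start, locus.start)
                hi = min(block_end, locus.end)
                if lo < hi:
                    depths[lo - locus.start : hi - locus.start] += 1
    finally:
        if close:
            reads.close()  # type: ignore[union-attr]
    return DepthProfile(locus_id=locus.locus_id, depths=depths, min_mapq_applied=min_mapq)


def read_depth_tsv(source: str | Path | Iterable[str]) -> dict[str, dict[int, int]]:
    """Read a samtools-depth-style TSV (``contig<TAB>1-based pos<TAB>depth``).

    Returns ``{contig: {0-based position: depth}}``; positions not listed are
    depth 0.
    """
    if isinstance(source, (str, Path)):
        lines: Iterable[str] = Path(source).read_text().splitlines()
    else:
        lines = source
    table: dict[str, dict[int, int]] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"line {lineno}: expected 3 columns")
        try:
            contig, pos1, depth = fields[0], int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
        table.setdefault(contig, {})[pos1 - 1] = depth
    return table


def depth_profile_from_table(
    table: Mapping[str, Mapping[int, int]], locus: NirvsLocus, min_mapq_applied: int = 20
) -> DepthProfile:
    per_contig = table.get(locus.contig, {})
    depths = np.array(
        [per_contig.get(pos, 0) for pos in range(locus.start, locus.end)], dtype=int
    )
    return DepthProfile(locus.locus_id, depths, min_mapq_applied)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_variants(vcf_source: str | Path, caller_id: str) -> list[VariantRecord]:
    """Read a VCF 4.x file into per-alt :class:`VariantRecord` objects.

    Multi-allelic records are split; the allele frequency is taken from the
    AF INFO field, falling back to AD/DP of the first sample, else missing.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(vcf_source)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            afs = _allele_frequencies(rec, len(alts))
            for alt, af in zip(alts, afs):
                if alt is None or alt.startswith("<"):
                    continue
                records.append(
                    VariantRecord(
                        contig=rec.contig,
                        pos=rec.pos - 1,
                        ref=rec.ref,
                        alt=alt,
                        caller_id=caller_id,
                        allele_frequency=af,
                    )
                )
    return records


def _allele_frequencies(rec, n_alts: int) -> list[float | None]:
    info_af = rec.info.get("AF") if "AF" in rec.info else None
    if info_af is not None:
        if not isinstance(info_af, (tuple, list)):
            info_af = (info_af,)
        out = [min(max(float(a), 0.0), 1.0) if a is not None else None for a in info_af]
        return out + [None] * (n_alts - len(out))
    if rec.samples:
        sample = rec.samples[0]
        ad = sample.get("AD")
        dp = sample.get("DP")
        if ad is not None and dp:
            out = []
            for i in range(n_alts):
                try:
                    out.append(min(max(float(ad[i + 1]) / float(dp), 0.0), 1.0))
                except (IndexError, TypeError, ZeroDivisionError):
                    out.append(None)
            return out
    return [None] * n_alts


def write_variants_vcf(
    variants: Iterable[EnsembleVariant],
    path: str | Path,
    contigs: Mapping[str, int],
) -> None:
    """Write ensemble variants to a plain-text VCF with the caller set in INFO."""
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        for contig, length in contigs.items():
            handle.write(f"##contig=<ID={contig},length={length}>\n")
        handle.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        handle.write('##INFO=<ID=CALLERS,Number=.,Type=String,Description="Reporting callers">\n')
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for var in variants:
            info = "CALLERS=" + ",".join(sorted(var.callers))
            if var.allele_frequency is not None:
                info = f"AF={var.allele_frequency:.4g};" + info
            handle.write(
                f"{var.contig}\t{var.pos + 1}\t.\t{var.ref}\t{var.alt}\t.\tPASS\t{info}\n"
            )


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_variant(
    contig: str,
    pos: int,
    ref: str,
    alt: str,
    fetch: RefLookup | None = None,
) -> tuple[str, int, str, str]:
    """Left-normalize one (contig, 0-based pos, ref, alt) representation.

    Trailing shared bases are trimmed, the allele is shifted left through the
    reference context when one is available, and finally the shared prefix is
    trimmed.  Two caller-specific encodings of the same indel collapse onto
    one key.
    """
    ref, alt = ref.upper(), alt.upper()
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            if min(len(ref), len(alt)) == 1 and fetch is None:
                break  # already anchored; cannot shift further without the reference
            ref, alt = ref[:-1], alt[:-1]
        elif not ref or not alt:
            if fetch is None or pos <= 0:
                raise ValueError(
                    f"{contig}:{pos}: allele ran off the contig start during normalization"
                )
            base = fetch(contig, pos - 1).upper()
            ref, alt, pos = base + ref, base + alt, pos - 1
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    return contig, pos, ref, alt


def decompose_record(
    record: VariantRecord, fetch: RefLookup | None = None
) -> list[VariantRecord]:
    """Normalize one record; multi-nucleotide substitutions become per-base SNPs."""
    contig, pos, ref, alt = normalize_variant(
        record.contig, record.pos, record.ref, record.alt, fetch
    )
    if len(ref) == len(alt) and len(ref) > 1:
        out = []
        for offset, (r, a) in enumerate(zip(ref, alt)):
            if r != a:
                out.append(replace(record, pos=pos + offset, ref=r, alt=a))
        return out
    return [replace(record, pos=pos, ref=ref, alt=alt)]


def median_af(values: Sequence[float]) -> float | None:
    """Median of non-missing allele frequencies; None when all are missing."""
    present = [v for v in values if v is not None]
    if not present:
        return None
    return float(statistics.median(present))
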