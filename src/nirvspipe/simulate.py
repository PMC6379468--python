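"""Seeded generators for every input the pipeline consumes.

The defaults emulate the study design the pipeline targets: 16 singly
sequenced mosquitoes, 72 integration loci (32 with Flavivirus similarity,
40 with Rhabdovirus similarity, lengths 151-3206 bp) of which 20 form a
core present in every individual and 11 are universally absent, four
variant callers with imperfect concordance, five geographic populations in
two divergence clusters, and small multi-species proteome sets with a
graded divergence spectrum.

Every generator derives its own RNG stream from the top-level seed plus a
fixed stream id, so adding a generator never shifts another's draws and the
same seed reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DepthProfile, NirvsLocus, VariantRecord
from .chimera import ChimeraCandidate
from .popgen import NULL_ALLELE, AlleleTable

_BASES = np.array(list("ACGT"))
_AMINO = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# fixed stream ids; never renumber
_STREAM_GENOME = 1
_STREAM_DEPTH = 2
_STREAM_VARIANTS = 3
_STREAM_AGE = 4
_STREAM_POPS = 5
_STREAM_PROTEOMES = 6
_STREAM_CHIMERAS = 7


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults for the whole synthetic dataset."""

    seed: int = 0
    n_samples: int = 16
    n_flavi: int = 32
    n_rhabdo: int = 40
    n_core: int = 20
    n_universal_absent: int = 11
    locus_length_range: tuple[int, int] = (151, 3206)
    mean_depth: float = 30.0
    variable_presence_prob: float = 0.6
    caller_ids: tuple[str, ...] = ("freebayes", "gatk_ug", "platypus", "vardict")
    #: callers that emit indels in a padded, unnormalized representation
    unnormalized_callers: tuple[str, ...] = ("vardict",)
    caller_sensitivity: float = 0.9
    caller_fp_rate: float = 0.5  # expected false positives per caller per locus
    af_noise_sd: float = 0.05
    #: per-bp true mutation density range across loci (Table-1-like magnitudes)
    lop_range: tuple[float, float] = (0.0004, 0.0258)
    indel_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.n_core + self.n_universal_absent > self.n_flavi + self.n_rhabdo:
            raise ValueError("core + absent exceeds total loci")


# ---------------------------------------------------------------------------
# Loci and genome
# ---------------------------------------------------------------------------

def make_loci(config: SimulationConfig) -> list[NirvsLocus]:
    """Annotated locus set laid head-to-tail on one contig with spacers.

    The core loci lean to Rhabdovirus/exon annotations and the universally
    absent loci to Flavivirus, mirroring the enrichment structure the
    pipeline is meant to detect.
    """
    rng = _rng(config.seed, _STREAM_GENOME)
    total = config.n_flavi + config.n_rhabdo
    families = ["Flavivirus"] * config.n_flavi + ["Rhabdovirus"] * config.n_rhabdo
    orf_by_family = {
        "Flavivirus": ["NS5", "NS3", "capsid"],
        "Rhabdovirus": ["nucleocapsid", "RdRP", "glycoprotein"],
    }
    contexts = ["exon", "piRNA_cluster", "intergenic"]
    loci = []
    cursor = 100
    # core indices biased to Rhabdovirus (last n_rhabdo entries), absent to Flavivirus
    core_idx = list(range(total - config.n_core, total))
    absent_idx = list(range(config.n_universal_absent))
    for i in range(total):
        family = families[i]
        length = int(rng.integers(config.locus_length_range[0], config.locus_length_range[1] + 1))
        if i in core_idx:
            context = "exon" if rng.random() < 0.5 else str(rng.choice(contexts))
        else:
            context = str(rng.choice(contexts))
        prefix = "SynFlavi" if family == "Flavivirus" else "SynRha"
        loci.append(
            NirvsLocus(
                locus_id=f"{prefix}{i + 1}",
                contig="contig1",
                start=cursor,
                end=cursor + length,
                strand="+" if rng.random() < 0.5 else "-",
                viral_family=family,
                viral_orf=str(rng.choice(orf_by_family[family])),
                context=context,
            )
        )
        cursor += length + int(rng.integers(50, 200))
    return loci


def planted_presence(config: SimulationConfig, loci: Sequence[NirvsLocus]) -> pd.DataFrame:
    """Loci x samples truth table with planted core/absent/variable structure."""
    rng = _rng(config.seed, _STREAM_DEPTH)
    total = len(loci)
    samples = [f"SSM{i + 1}" for i in range(config.n_samples)]
    core_idx = set(range(total - config.n_core, total))
    absent_idx = set(range(config.n_universal_absent))
    truth = pd.DataFrame(
        False, index=pd.Index([l.locus_id for l in loci], name="locus"), columns=samples
    )
    for i, locus in enumerate(loci):
        if i in core_idx:
            truth.loc[locus.locus_id] = True
        elif i in absent_idx:
            truth.loc[locus.locus_id] = False
        else:
            truth.loc[locus.locus_id] = rng.random(config.n_samples) < config.variable_presence_prob
    return truth


def make_genome(config: SimulationConfig, loci: Sequence[NirvsLocus]) -> dict[str, str]:
    rng = _rng(config.seed, _STREAM_GENOME + 100)
    length = max(l.end for l in loci) + 100
    return {"contig1": "".join(rng.choice(_BASES, size=length))}


def simulate_depth_profiles(
    config: SimulationConfig, loci: Sequence[NirvsLocus] | None = None
) -> tuple[dict[str, dict[str, DepthProfile]], pd.DataFrame]:
    """Per-sample per-locus depth profiles plus the planted presence truth.

    Present loci draw Poisson(mean_depth) depth per position; absent loci a
    sparse background capped below the presence threshold, so no run of 30
    positions at depth 5 can arise.
    """
    if loci is None:
        loci = make_loci(config)
    truth = planted_presence(config, loci)
    rng = _rng(config.seed, _STREAM_DEPTH + 100)
    profiles: dict[str, dict[str, DepthProfile]] = {}
    for sample in truth.columns:
        per_sample = {}
        for locus in loci:
            if truth.loc[locus.locus_id, sample]:
                depths = rng.poisson(config.mean_depth, size=locus.length)
            else:
                depths = np.minimum(rng.poisson(0.5, size=locus.length), 4)
            per_sample[locus.locus_id] = DepthProfile(locus.locus_id, depths)
        profiles[sample] = per_sample
    return profiles, truth


def write_depth_tsv(
    profiles: Mapping[str, DepthProfile], loci: Sequence[NirvsLocus], path: str | Path
) -> None:
    """samtools-depth dialect: contig, 1-based position, depth."""
    by_id = {l.locus_id: l for l in loci}
    with open(path, "w") as handle:
        for locus_id, profile in profiles.items():
            locus = by_id[locus_id]
            for offset, depth in enumerate(profile.depths):
                if depth > 0:
                    handle.write(f"{locus.contig}\t{locus.start + offset + 1}\t{depth}\n")


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrueVariant:
    contig: str
    pos: int
    ref: str
    alt: str
    allele_frequency: float


def plant_true_variants(
    config: SimulationConfig,
    loci: Sequence[NirvsLocus],
    genome: Mapping[str, str],
    densities: Mapping[str, float] | None = None,
) -> dict[str, list[TrueVariant]]:
    """Per-locus true variant sets at planted per-bp densities.

    Densities default to log-uniform draws over ``config.lop_range``; true
    allele frequencies sit above the 0.1 retention threshold.
    """
    rng = _rng(config.seed, _STREAM_VARIANTS)
    lo, hi = config.lop_range
    out: dict[str, list[TrueVariant]] = {}
    for locus in loci:
        density = (
            densities[locus.locus_id]
            if densities is not None
            else float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        )
        n_var = rng.binomial(locus.length, density)
        positions = sorted(rng.choice(locus.length, size=min(n_var, locus.length), replace=False))
        variants = []
        seq = genome[locus.contig]
        for offset in positions:
            pos = locus.start + offset
            ref_base = seq[pos]
            af = float(rng.uniform(0.15, 0.95))
            if rng.random() < config.indel_fraction and pos + 3 < locus.end:
                if rng.random() < 0.5:  # deletion of 1-2 bp anchored at pos
                    span = int(rng.integers(1, 3))
                    variants.append(
                        TrueVariant(locus.contig, pos, seq[pos : pos + span + 1], ref_base, af)
                    )
                else:  # insertion of 1-2 bp after pos
                    ins = "".join(rng.choice(_BASES, size=int(rng.integers(1, 3))))
                    variants.append(
                        TrueVariant(locus.contig, pos, ref_base, ref_base + ins, af)
                    )
            else:
                alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
                variants.append(TrueVariant(locus.contig, pos, ref_base, alt, af))
        out[locus.locus_id] = variants
    return out


def simulate_caller_calls(
    config: SimulationConfig,
    loci: Sequence[NirvsLocus],
    genome: Mapping[str, str],
    true_variants: Mapping[str, Sequence[TrueVariant]],
    sample: str,
) -> dict[str, list[VariantRecord]]:
    """One sample's per-caller call lists with planted discordance.

    Each caller reports each true variant with probability
    ``caller_sensitivity``, perturbs its AF with truncated Gaussian noise,
    and adds Poisson false positives at sub-threshold frequencies.  Callers
    listed in ``unnormalized_callers`` pad indels with an anchor base to
    exercise left-normalization.
    """
    rng = _rng(config.seed, _STREAM_VARIANTS + 100 + _stable_hash(sample))
    calls: dict[str, list[VariantRecord]] = {}
    for caller in config.caller_ids:
        records: list[VariantRecord] = []
        for locus in loci:
            for tv in true_variants.get(locus.locus_id, ()):
                if rng.random() > config.caller_sensitivity:
                    continue
                af = float(np.clip(tv.allele_frequency + rng.normal(0, config.af_noise_sd), 0.0, 1.0))
                pos, ref, alt = tv.pos, tv.ref, tv.alt
                if len(ref) != len(alt) and caller in config.unnormalized_callers and pos > 0:
                    anchor = genome[tv.contig][pos - 1]
                    pos, ref, alt = pos - 1, anchor + ref, anchor + alt
                records.append(VariantRecord(tv.contig, pos, ref, alt, caller, af))
            n_fp = rng.poisson(config.caller_fp_rate)
            for _ in range(n_fp):
                offset = int(rng.integers(0, locus.length))
                pos = locus.start + offset
                ref_base = genome[locus.contig][pos]
                alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
                af = float(rng.uniform(0.01, 0.09))
                records.append(VariantRecord(locus.contig, pos, ref_base, alt, caller, af))
        calls[caller] = records
    return calls


def _stable_hash(text: str) -> int:
    value = 0
    for ch in text:
        value = (value * 31 + ord(ch)) % 100_000
    return value


def write_caller_vcf(
    records: Sequence[VariantRecord], genome: Mapping[str, str], path: str | Path
) -> None:
    """Plain-text VCF 4.2 with AF in INFO, sorted by position."""
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        for contig, seq in genome.items():
            handle.write(f"##contig=<ID={contig},length={len(seq)}>\n")
        handle.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in sorted(records, key=lambda r: (r.contig, r.pos, r.ref, r.alt)):
            af = f"AF={rec.allele_frequency:.4f}" if rec.allele_frequency is not None else "."
            handle.write(
                f"{rec.contig}\t{rec.pos + 1}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t{af}\n"
            )


# ---------------------------------------------------------------------------
# Sequence families for age estimation
# ---------------------------------------------------------------------------

def evolve_locus_sequences(
    seq_length: int,
    mr: float,
    gpy: float,
    true_age: float,
    n_seqs: int,
    seed: int | np.random.Generator = 0,
    ancestor: str | None = None,
) -> list[str]:
    """Pre-aligned sequence family under a neutral Poisson clock.

    Each sequence receives Poisson(mr * L * gpy * true_age) independent
    substitutions from the common ancestor (uniform substitution model,
    positions drawn with replacement).
    """
    rng = seed if isinstance(seed, np.random.Generator) else _rng(int(seed), _STREAM_AGE)
    if ancestor is None:
        ancestor = "".join(rng.choice(_BASES, size=seq_length))
    if len(ancestor) != seq_length:
        raise ValueError("ancestor length must equal seq_length")
    expected = mr * seq_length * gpy * true_age
    out = []
    for _ in range(n_seqs):
        seq = list(ancestor)
        n_mut = rng.poisson(expected)
        for _ in range(n_mut):
            pos = int(rng.integers(0, seq_length))
            seq[pos] = str(rng.choice([b for b in "ACGT" if b != seq[pos]]))
        out.append("".join(seq))
    return out


def write_alignment_fasta(rows: Sequence[str], path: str | Path, prefix: str = "seq") -> None:
    with open(path, "w") as handle:
        for i, row in enumerate(rows, start=1):
            handle.write(f">{prefix}{i}\n{row}\n")


# ---------------------------------------------------------------------------
# Population allele tables
# ---------------------------------------------------------------------------

def simulate_population_alleles(
    clusters: Sequence[Sequence[str]] = (("China", "Thailand", "LaReunion"), ("Italy", "USA")),
    n_loci: int = 13,
    cluster_drift: float = 0.8,
    pop_drift: float = 0.1,
    null_prob: float = 0.05,
    seed: int = 0,
) -> tuple[AlleleTable, list[frozenset[str]]]:
    """Allele table drifting from a root pool along a two-level topology.

    Returns the table and the true population clusters.  With strong
    ``cluster_drift`` and weak ``pop_drift`` the between-cluster bipartition
    dominates the shared-allele distances.
    """
    rng = _rng(seed, _STREAM_POPS)
    loci = [f"locus{i + 1}" for i in range(n_loci)]
    data: dict[str, dict[str, set[str]]] = {}
    for ci, cluster in enumerate(clusters):
        cluster_alleles = {}
        for locus in loci:
            alleles = {f"{locus}_root"}
            if rng.random() < cluster_drift:
                alleles = {f"{locus}_c{ci}"}
            cluster_alleles[locus] = alleles
        for pop in cluster:
            per_locus: dict[str, set[str]] = {}
            for locus in loci:
                alleles = set(cluster_alleles[locus])
                if rng.random() < pop_drift:
                    alleles.add(f"{locus}_{pop}")
                if rng.random() < null_prob:
                    alleles = {NULL_ALLELE}
                per_locus[locus] = alleles
            data[pop] = per_locus
    truth = [frozenset(cluster) for cluster in clusters]
    return AlleleTable(data), truth


# ---------------------------------------------------------------------------
# Proteomes
# ---------------------------------------------------------------------------

def simulate_proteomes(
    n_species: int = 5,
    n_groups: int = 20,
    protein_length: int = 80,
    max_rate: float = 0.3,
    paralog_rate: float = 0.6,
    n_paralog_groups: int = 2,
    seed: int = 0,
) -> tuple[dict[str, dict[str, str]], dict[str, dict[str, str]], dict[str, float]]:
    """Species proteomes with ortholog groups of graded divergence.

    Returns (proteomes[species][protein_id], group map
    ``{group_id: {species: protein_id}}``, planted per-group substitution
    rates spanning 0..max_rate).  A few paralog decoys mutated at
    ``paralog_rate`` are added to the proteomes but not to any group.
    """
    rng = _rng(seed, _STREAM_PROTEOMES)
    species = [f"sp{i + 1}" for i in range(n_species)]
    rates = {
        f"G{g + 1:03d}": max_rate * g / max(n_groups - 1, 1) for g in range(n_groups)
    }
    proteomes: dict[str, dict[str, str]] = {sp: {} for sp in species}
    groups: dict[str, dict[str, str]] = {}
    for group_id, rate in rates.items():
        ancestor = "".join(rng.choice(_AMINO, size=protein_length))
        groups[group_id] = {}
        for sp in species:
            seq = _mutate_protein(ancestor, rate, rng)
            pid = f"{sp}_{group_id}"
            proteomes[sp][pid] = seq
            groups[group_id][sp] = pid
        if int(group_id[1:]) <= n_paralog_groups:
            for sp in species:
                proteomes[sp][f"{sp}_{group_id}_par"] = _mutate_protein(
                    ancestor, paralog_rate, rng
                )
    return proteomes, groups, rates


def _mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = str(rng.choice(_AMINO))
    return "".join(out)


def write_proteome_fasta(proteome: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as handle:
        for pid in sorted(proteome):
            handle.write(f">{pid}\n{proteome[pid]}\n")


def write_group_map(groups: Mapping[str, Mapping[str, str]], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("group_id\tspecies\tprotein_id\n")
        for group_id in sorted(groups):
            for sp in sorted(groups[group_id]):
                handle.write(f"{group_id}\t{sp}\t{groups[group_id][sp]}\n")


# ---------------------------------------------------------------------------
# Chimeric candidates
# ---------------------------------------------------------------------------

def simulate_chimeras(
    n_positives: int = 10,
    n_short_decoys: int = 5,
    n_lowcomp_decoys: int = 5,
    seed: int = 0,
) -> tuple[list[ChimeraCandidate], dict[str, str]]:
    """Chimeric candidates with planted truth labels.

    Positives carry complex viral segments of >= 50 nt; each decoy violates
    exactly one rule (viral segment < 50 nt, or > 80% covered by a
    homopolymer run).  Returns (candidates, {read_id: label}) with labels
    ``true_positive``, ``short_viral``, ``low_complexity``.
    """
    rng = _rng(seed, _STREAM_CHIMERAS)
    candidates = []
    truth: dict[str, str] = {}

    def random_seq(n: int) -> str:
        return "".join(rng.choice(_BASES, size=n))

    for i in range(n_positives):
        rid = f"pos{i + 1}"
        candidates.append(
            ChimeraCandidate(rid, "contig1", int(rng.integers(0, 10_000)),
                             random_seq(80), f"virus{int(rng.integers(1, 6))}",
                             random_seq(int(rng.integers(60, 150))))
        )
        truth[rid] = "true_positive"
    for i in range(n_short_decoys):
        rid = f"short{i + 1}"
        candidates.append(
            ChimeraCandidate(rid, "contig1", int(rng.integers(0, 10_000)),
                             random_seq(80), "virus1",
                             random_seq(int(rng.integers(20, 50))))
        )
        truth[rid] = "short_viral"
    for i in range(n_lowcomp_decoys):
        rid = f"lowc{i + 1}"
        n_total = 120
        run = "A" * 105  # 87.5% homopolymer coverage
        seq = run + random_seq(n_total - len(run))
        candidates.append(
            ChimeraCandidate(rid, "contig1", int(rng.integers(0, 10_000)),
                             random_seq(80), "virus2", seq)
        )
        truth[rid] = "low_complexity"
    return candidates, truth


def write_chimeras_tsv(candidates: Sequence[ChimeraCandidate], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("read_id\thost_contig\thost_pos\thost_seq\tvirus_id\tviral_seq\n")
        for cand in candidates:
            handle.write(
                f"{cand.read_id}\t{cand.host_contig}\t{cand.host_pos}\t"
                f"{cand.host_seq}\t{cand.virus_id}\t{cand.viral_seq}\n"
            )
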