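"""Synthetic pedigree and cohort simulator.

Generates the statistical structure the curation and benchmarking
modules assume, at the variant level only (no reads): a uniform-random
reference, sites with Beta-distributed cohort allele frequencies,
parental genotypes drawn under Hardy–Weinberg equilibrium, Mendelian
transmission to an offspring, an injected genotype-error process (each
member's genotype replaced, with probability ``genotype_error_rate``, by
a uniformly chosen different genotype), a de novo process (a child
allele mutated to a novel alt with probability ``de_novo_rate``),
genotype qualities with a lower mean at erroneous calls, FILTER tranche
labels, and per-sample callable-region gaps.

Everything is deterministic from the seed. The ground truth of every
simulated locus, including whether an injected perturbation is
*detectable* as a Mendelian inconsistency, is recorded in a per-locus
table so tests can compare what a pipeline removed against what was
actually planted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .core_io import (
    Call,
    GenomeIndex,
    Genotype,
    IntervalSet,
    Trio,
    VariantRecord,
)
from .mendelian import VerdictStatus, is_consistent

__all__ = [
    "SimConfig",
    "TRIO",
    "simulate_reference",
    "write_reference",
    "simulate_trio_cohort",
    "simulate_callable_bed",
    "offspring_from_parent_haplotypes",
    "extract_haplotype",
]

TRIO = Trio(child="child", father="father", mother="mother")

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Simulation parameters.

    Defaults describe a desk-scale trio study: a 3-Mb genome (two
    autosomes plus X), 10,000 variant loci with a U-shaped Beta(0.8, 0.8)
    site-frequency spectrum, a 2% per-member genotype-error rate, a
    0.1% de novo rate, ~15% indels, a 200-sample cohort for allele
    frequencies, GQ means of 50 (concordant) vs 20 (erroneous) with SD
    10, 5% of sites tranche-labeled, and 10% callable-region gaps.
    """

    seed: int
    n_contigs: int = 3
    contig_length: int = 1_000_000
    include_x: bool = True
    n_loci: int = 10_000
    af_alpha: float = 0.8
    af_beta: float = 0.8
    af_fixed: float | None = None
    genotype_error_rate: float = 0.02
    de_novo_rate: float = 0.001
    indel_fraction: float = 0.15
    multiallelic_fraction: float = 0.02
    n_cohort_samples: int = 200
    gq_mean_concordant: float = 50.0
    gq_mean_error: float = 20.0
    gq_dispersion: float = 10.0
    tranche_fraction: float = 0.05
    tranche_label: str = "Tranche99.7"
    callable_gap_fraction: float = 0.10
    callable_tile: int = 1_000

    def __post_init__(self) -> None:
        for name in (
            "genotype_error_rate",
            "de_novo_rate",
            "indel_fraction",
            "multiallelic_fraction",
            "tranche_fraction",
            "callable_gap_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.callable_gap_fraction >= 1.0:
            raise ValueError("callable_gap_fraction must be < 1")
        if self.n_loci > self.n_contigs * self.contig_length:
            raise ValueError("n_loci exceeds total genome length")
        if self.contig_length < 1_000:
            raise ValueError("contig_length must be at least 1 kb")

    @property
    def contig_names(self) -> list[str]:
        names = [str(i + 1) for i in range(self.n_contigs)]
        if self.include_x:
            names[-1] = "X"
        return names


def simulate_reference(cfg: SimConfig) -> tuple[dict[str, str], GenomeIndex]:
    """Uniform-random DNA contigs plus the matching genome index."""
    rng = np.random.default_rng([cfg.seed, 0])
    sequences = {
        name: "".join(rng.choice(_BASES, size=cfg.contig_length))
        for name in cfg.contig_names
    }
    genome = GenomeIndex([(name, len(seq)) for name, seq in sequences.items()])
    return sequences, genome


def write_reference(sequences: Mapping[str, str], path: str | Path) -> Path:
    """Write a FASTA (60-column lines) and index it; returns the .fai path."""
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    pysam.faidx(str(path))
    return Path(str(path) + ".fai")


def _draw_sites(cfg: SimConfig, sequences: Mapping[str, str], rng) -> list[tuple[str, int]]:
    lengths = np.array([len(sequences[c]) for c in cfg.contig_names], dtype=float)
    per_contig = rng.multinomial(cfg.n_loci, lengths / lengths.sum())
    sites: list[tuple[str, int]] = []
    for contig, k in zip(cfg.contig_names, per_contig):
        # keep 10 bp headroom at the contig end for deletion alleles
        positions = rng.choice(len(sequences[contig]) - 10, size=k, replace=False)
        sites.extend((contig, int(p) + 1) for p in np.sort(positions))
    return sites


def _novel_snv_alt(ref: str, taken: set[str], rng) -> str | None:
    options = [b for b in "ACGT" if b != ref[0] and b not in taken]
    if not options:
        return None
    return options[rng.integers(len(options))]


def _make_alleles(
    cfg: SimConfig, contig_seq: str, pos: int, rng
) -> tuple[str, tuple[str, ...]]:
    base = contig_seq[pos - 1].upper()
    is_indel = rng.random() < cfg.indel_fraction
    if is_indel:
        size = int(rng.integers(1, 6))
        if rng.random() < 0.5:  # insertion
            ref = base
            alt = base + "".join(rng.choice(_BASES, size=size))
        else:  # deletion
            ref = contig_seq[pos - 1 : pos - 1 + size + 1].upper()
            alt = base
        alts = (alt,)
    else:
        ref = base
        alt = _novel_snv_alt(ref, set(), rng)
        alts = (alt,)  # type: ignore[assignment]
    if rng.random() < cfg.multiallelic_fraction:
        extra = _novel_snv_alt(ref[0], {a[0] for a in alts if len(a) == 1}, rng)
        if extra is not None and len(ref) == 1:
            alts = (*alts, extra)
    return ref, alts


def _allele_freqs(cfg: SimConfig, n_alts: int, rng) -> np.ndarray:
    """Per-allele frequency vector [ref, alt1, ...] for one site."""
    p = cfg.af_fixed if cfg.af_fixed is not None else rng.beta(cfg.af_alpha, cfg.af_beta)
    p = min(max(p, 1e-6), 1 - 1e-6)
    if n_alts == 1:
        return np.array([1 - p, p])
    shares = rng.dirichlet(np.ones(n_alts))
    return np.concatenate([[1 - p], p * shares])


def _hwe_genotype(freqs: np.ndarray, rng) -> tuple[int, int]:
    a, b = rng.choice(len(freqs), size=2, p=freqs)
    return int(a), int(b)


def _random_other_genotype(
    current: tuple[int, int], n_alleles: int, rng
) -> tuple[int, int]:
    genotypes = [
        (i, j)
        for i in range(n_alleles)
        for j in range(i, n_alleles)
        if (i, j) != tuple(sorted(current))
    ]
    return genotypes[rng.integers(len(genotypes))]


def _draw_gq(cfg: SimConfig, erroneous: bool, rng) -> int:
    mean = cfg.gq_mean_error if erroneous else cfg.gq_mean_concordant
    return int(np.clip(round(rng.normal(mean, cfg.gq_dispersion)), 0, 99))


def simulate_trio_cohort(
    cfg: SimConfig, sequences: Mapping[str, str]
) -> tuple[list[VariantRecord], list[VariantRecord], pd.DataFrame]:
    """Simulate trio and cohort genotypes over shared sites.

    Returns (trio records, cohort records, per-locus truth table). The
    truth table records the true (pre-perturbation) trio genotypes, which
    members received injected errors, whether a de novo allele was
    introduced, and whether the observed trio is detectably discordant
    under the Mendelian transmission rule.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    sites = _draw_sites(cfg, sequences, rng)
    cohort_names = [f"S{i:04d}" for i in range(cfg.n_cohort_samples)]

    trio_records: list[VariantRecord] = []
    cohort_records: list[VariantRecord] = []
    truth_rows: list[dict] = []

    for contig, pos in sites:
        ref, alts = _make_alleles(cfg, sequences[contig], pos, rng)
        freqs = _allele_freqs(cfg, len(alts), rng)

        father_true = _hwe_genotype(freqs, rng)
        mother_true = _hwe_genotype(freqs, rng)
        child_true = (
            father_true[rng.integers(2)],
            mother_true[rng.integers(2)],
        )

        # de novo: mutate one child allele to a novel alt allele
        de_novo = bool(rng.random() < cfg.de_novo_rate)
        child_observed = child_true
        if de_novo:
            novel = _novel_snv_alt(ref[0], {a[0] for a in alts if len(a) == 1}, rng)
            if novel is not None and len(ref) == 1:
                alts = (*alts, novel)
                which = int(rng.integers(2))
                gt = list(child_true)
                gt[which] = len(alts)  # index of the new alt
                child_observed = (gt[0], gt[1])
            else:
                de_novo = False

        n_alleles = 1 + len(alts)
        observed = {
            "child": child_observed,
            "father": father_true,
            "mother": mother_true,
        }
        errors = {}
        for member in ("child", "father", "mother"):
            err = bool(rng.random() < cfg.genotype_error_rate)
            errors[member] = err
            if err:
                observed[member] = _random_other_genotype(
                    observed[member], n_alleles, rng
                )

        verdict = is_consistent(
            Genotype(observed["child"]),
            Genotype(observed["father"]),
            Genotype(observed["mother"]),
        )
        detectable = verdict.status is VerdictStatus.DISCORDANT

        filters = (
            frozenset({cfg.tranche_label})
            if rng.random() < cfg.tranche_fraction
            else frozenset({"PASS"})
        )
        samples = {
            member: Call(
                Genotype(observed[member]),
                gq=_draw_gq(cfg, errors[member] or (member == "child" and de_novo), rng),
            )
            for member in ("child", "father", "mother")
        }
        trio_records.append(
            VariantRecord(
                contig=contig, pos=pos, ref=ref, alts=alts,
                filters=filters, samples=samples,
            )
        )

        draws = rng.choice(len(freqs), size=(cfg.n_cohort_samples, 2), p=freqs)
        cohort_samples = {
            name: Call(Genotype((int(a), int(b))))
            for name, (a, b) in zip(cohort_names, draws)
        }
        cohort_records.append(
            VariantRecord(
                contig=contig, pos=pos, ref=ref, alts=alts,
                filters=frozenset({"PASS"}), samples=cohort_samples,
            )
        )

        truth_rows.append(
            {
                "contig": contig,
                "pos": pos,
                "ref": ref,
                "alts": ",".join(alts),
                "af": float(freqs[1:].sum()),
                "child_true": "/".join(map(str, sorted(child_true))),
                "father_true": "/".join(map(str, sorted(father_true))),
                "mother_true": "/".join(map(str, sorted(mother_true))),
                "child_observed": "/".join(map(str, sorted(observed["child"]))),
                "father_observed": "/".join(map(str, sorted(observed["father"]))),
                "mother_observed": "/".join(map(str, sorted(observed["mother"]))),
                "error_child": errors["child"],
                "error_father": errors["father"],
                "error_mother": errors["mother"],
                "de_novo": de_novo,
                "is_pass": filters == frozenset({"PASS"}),
                "detectable_discordance": detectable,
            }
        )

    return trio_records, cohort_records, pd.DataFrame(truth_rows)


def simulate_callable_bed(
    cfg: SimConfig,
    genome: GenomeIndex,
    samples: Sequence[str] = tuple(TRIO),
) -> dict[str, IntervalSet]:
    """Per-sample callable regions with random gaps.

    Each contig is tiled at ``callable_tile`` resolution and tiles are
    dropped independently with probability ``callable_gap_fraction``;
    deterministic from the seed and the sample's position in ``samples``.
    """
    out: dict[str, IntervalSet] = {}
    for i, sample in enumerate(samples):
        rng = np.random.default_rng([cfg.seed, 2, i])
        intervals = []
        for contig, length in genome.contigs:
            for start in range(0, length, cfg.callable_tile):
                if rng.random() >= cfg.callable_gap_fraction:
                    intervals.append((contig, start, min(start + cfg.callable_tile, length)))
        out[sample] = IntervalSet(intervals, genome=genome)
    return out


# --------------------------------------------------------------------------
# synthetic-diploid (SynDip-style) offspring from parental haplotypes
# --------------------------------------------------------------------------


def extract_haplotype(
    records: Iterable[VariantRecord], sample: str, hap_index: int,
    hap_sample: str = "hap",
) -> list[VariantRecord]:
    """One parental haplotype as a haploid callset (alt-carrying sites only)."""
    out = []
    for rec in records:
        g = rec.samples[sample].genotype
        if g.is_missing or hap_index >= g.ploidy:
            continue
        allele = g.alleles[hap_index]
        if allele == 0 or allele is None:
            continue
        out.append(
            VariantRecord(
                contig=rec.contig, pos=rec.pos, ref=rec.ref, alts=rec.alts,
                filters=rec.filters,
                samples={hap_sample: Call(Genotype((allele,)))},
            )
        )
    return out


def offspring_from_parent_haplotypes(
    hap_a: Iterable[VariantRecord],
    hap_b: Iterable[VariantRecord],
    offspring_sample: str = "offspring",
) -> list[VariantRecord]:
    """Combine two parental haplotypes into a diploid offspring truth set.

    At each site in the union, the offspring genotype is (allele from
    haplotype A, allele from haplotype B); a site absent from one
    haplotype contributes the ref allele. Inputs must be haploid and from
    one reference: conflicting ref alleles at a position are an error.
    """

    def index(stream: Iterable[VariantRecord], name: str) -> dict:
        idx = {}
        for rec in stream:
            for call in rec.samples.values():
                if call.genotype.ploidy != 1:
                    raise ValueError(
                        f"{name} input must be haploid at {rec.contig}:{rec.pos}"
                    )
            idx[(rec.contig, rec.pos)] = rec
        return idx

    a_idx = index(hap_a, "haplotype A")
    b_idx = index(hap_b, "haplotype B")
    out = []
    for key in sorted(set(a_idx) | set(b_idx)):
        a_rec, b_rec = a_idx.get(key), b_idx.get(key)
        if a_rec is not None and b_rec is not None and a_rec.ref != b_rec.ref:
            raise ValueError(
                f"inconsistent ref alleles at {key[0]}:{key[1]}: "
                f"{a_rec.ref!r} vs {b_rec.ref!r}"
            )
        template = a_rec or b_rec
        assert template is not None
        alts = list(template.alts)

        def allele_of(rec: VariantRecord | None) -> int:
            if rec is None:
                return 0
            a = next(iter(rec.samples.values())).genotype.alleles[0]
            assert a is not None
            if a == 0:
                return 0
            alt = rec.alts[a - 1]
            if alt not in alts:
                alts.append(alt)
            return alts.index(alt) + 1

        ga, gb = allele_of(a_rec), allele_of(b_rec)
        out.append(
            VariantRecord(
                contig=key[0], pos=key[1], ref=template.ref, alts=tuple(alts),
                filters=frozenset({"PASS"}),
                samples={offspring_sample: Call(Genotype((ga, gb)))},
            )
        )
    return out
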