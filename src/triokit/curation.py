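"""Truth-label curation for trio-based training.

Turns three single-sample callsets plus a pedigree into per-sample truth
VCFs: merge into a family view, drop non-PASS sites, drop every position
showing a Mendelian-discordant trio genotype from all three individuals,
restrict to autosomes + X and each sample's callable regions, and remove
homozygous-reference genotypes from the final single-sample outputs.

Single-sample truth callsets omit hom-ref sites, so a site absent from one
family member is interpreted as hom-ref (with absent GQ) in that member.
That reading is only valid inside the member's callable regions, which is
why callable masks are applied in the finalization step and the audit
tracks the flow of every input record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

from .core_io import (
    Call,
    GenomeIndex,
    Genotype,
    IntervalSet,
    Trio,
    VariantRecord,
)
from .mendelian import (
    GenotypeClass,
    TrioVerdict,
    VerdictStatus,
    genotype_class,
    is_consistent,
)

__all__ = ["FamilyRecord", "CurationAudit", "annotate_family", "merge_trio",
           "curate_family", "finalize_truth_labels"]

_ABSENT_HOMREF = Call(Genotype((0, 0)), gq=None)


@dataclass(frozen=True)
class FamilyRecord:
    """A trio-joined view of one site: the record plus its trio verdict."""

    site: VariantRecord
    trio: Trio
    verdict: TrioVerdict

    def __post_init__(self) -> None:
        if set(self.site.samples) != set(self.trio):
            raise ValueError("family record must carry exactly the trio samples")

    @property
    def child_call(self) -> Call:
        return self.site.samples[self.trio.child]


@dataclass
class CurationAudit:
    """Per-stage accounting: every input record lands in exactly one bin."""

    sites_read: int = 0
    dropped_filter: int = 0
    dropped_discordant: int = 0
    retained_family: int = 0
    dropped_outside_callable: dict[str, int] = field(default_factory=dict)
    homref_genotypes_removed: dict[str, int] = field(default_factory=dict)
    dropped_non_autosome_x: dict[str, int] = field(default_factory=dict)
    retained_per_sample: dict[str, int] = field(default_factory=dict)

    def reconciles(self) -> bool:
        return self.sites_read == (
            self.dropped_filter + self.dropped_discordant + self.retained_family
        )

    def as_rows(self) -> list[tuple[str, str, int]]:
        rows = [
            ("family", "sites_read", self.sites_read),
            ("family", "dropped_filter", self.dropped_filter),
            ("family", "dropped_discordant", self.dropped_discordant),
            ("family", "retained_family", self.retained_family),
        ]
        for name, counts in (
            ("dropped_non_autosome_x", self.dropped_non_autosome_x),
            ("dropped_outside_callable", self.dropped_outside_callable),
            ("homref_genotypes_removed", self.homref_genotypes_removed),
            ("retained", self.retained_per_sample),
        ):
            for sample in sorted(counts):
                rows.append((sample, name, counts[sample]))
        return rows


def annotate_family(
    records: Iterable[VariantRecord], trio: Trio
) -> Iterator[FamilyRecord]:
    """Wrap a multi-sample trio stream as verdict-annotated family records.

    Use this when the trio was jointly called into one VCF; use
    :func:`merge_trio` when starting from three single-sample callsets.
    """
    for rec in records:
        samples = {s: rec.samples[s] for s in trio}
        site = rec.with_samples(samples)
        verdict = is_consistent(
            samples[trio.child].genotype,
            samples[trio.father].genotype,
            samples[trio.mother].genotype,
        )
        yield FamilyRecord(site=site, trio=trio, verdict=verdict)


def _site_key(rec: VariantRecord, rank: Mapping[str, int]) -> tuple:
    return (rank.get(rec.contig, len(rank)), rec.contig, rec.pos, rec.ref, rec.alts)


def merge_trio(
    child: Iterable[VariantRecord],
    father: Iterable[VariantRecord],
    mother: Iterable[VariantRecord],
    trio: Trio,
    genome: GenomeIndex | None = None,
) -> Iterator[FamilyRecord]:
    """Join three sorted single-sample streams into family records.

    One record is emitted per (contig, pos, ref, alt-set) seen in any
    member; members lacking the site are assigned a hom-ref genotype with
    absent GQ. The trio verdict is populated from the joined genotypes.
    Two records at one position with different ref alleles is an error
    (the inputs should come from one reference).
    """
    rank = genome._rank if genome is not None else {}

    merged: dict[tuple, dict[str, VariantRecord]] = {}
    for sample, stream in ((trio.child, child), (trio.father, father),
                           (trio.mother, mother)):
        for rec in stream:
            merged.setdefault(_site_key(rec, rank), {})[sample] = rec

    refs_at_pos: dict[tuple[str, int], str] = {}
    for (_, contig, pos, ref, _alts) in merged:
        prev = refs_at_pos.setdefault((contig, pos), ref)
        if prev != ref:
            raise ValueError(
                f"conflicting ref alleles at {contig}:{pos}: {prev!r} vs {ref!r}"
            )

    for key in sorted(merged):
        _, contig, pos, ref, alts = key
        members = merged[key]
        template = next(iter(members.values()))
        samples: dict[str, Call] = {}
        for sample in trio:
            rec = members.get(sample)
            if rec is None:
                samples[sample] = _ABSENT_HOMREF
            else:
                samples[sample] = rec.samples[sample]
        # a site failing FILTER in any member taints the family record;
        # '.' (unfiltered) is kept as-is and will not survive PASS curation
        filters = frozenset().union(*(r.filters for r in members.values()))
        if filters != {"PASS"}:
            filters = filters - {"PASS"}
        site = VariantRecord(
            contig=contig, pos=pos, ref=ref, alts=alts,
            filters=filters,
            samples=samples, info=dict(template.info),
        )
        verdict = is_consistent(
            samples[trio.child].genotype,
            samples[trio.father].genotype,
            samples[trio.mother].genotype,
        )
        yield FamilyRecord(site=site, trio=trio, verdict=verdict)


def curate_family(
    fam: Iterable[FamilyRecord],
    tranche_pass_label: str = "PASS",
    audit: CurationAudit | None = None,
) -> tuple[list[FamilyRecord], CurationAudit]:
    """Apply FILTER and Mendelian-discordance curation to a family stream.

    Drops every record whose FILTER set is not exactly ``{PASS}`` and every
    record at a (contig, pos) where any trio genotype is discordant — the
    position is removed from all three individuals, including co-located
    multiallelic splits. Unassessed records (missing genotypes) are
    retained: curation removes only demonstrated violations. Idempotent.
    """
    if audit is None:
        audit = CurationAudit()
    fam = list(fam)
    audit.sites_read += len(fam)

    passing: list[FamilyRecord] = []
    for fr in fam:
        if fr.site.filters == frozenset({tranche_pass_label}):
            passing.append(fr)
        else:
            audit.dropped_filter += 1

    discordant_positions = {
        (fr.site.contig, fr.site.pos)
        for fr in passing
        if fr.verdict.status is VerdictStatus.DISCORDANT
    }
    retained = [
        fr for fr in passing
        if (fr.site.contig, fr.site.pos) not in discordant_positions
    ]
    audit.dropped_discordant += len(passing) - len(retained)
    audit.retained_family += len(retained)
    return retained, audit


def finalize_truth_labels(
    fam: Iterable[FamilyRecord],
    callable_regions: Mapping[str, IntervalSet],
    genome: GenomeIndex,
    audit: CurationAudit | None = None,
) -> dict[str, list[VariantRecord]]:
    """Split a curated family stream into per-sample truth records.

    Each sample's output is restricted to autosomes + X, intersected with
    that sample's callable regions, and stripped of hom-ref genotypes
    (single-sample truth VCFs carry variant genotypes only). Outputs are
    sorted by (contig order, pos).
    """
    fam = list(fam)
    if audit is None:
        audit = CurationAudit()
    trio = fam[0].trio if fam else None
    samples = list(trio) if trio else list(callable_regions)
    for sample in samples:
        if sample not in callable_regions:
            raise KeyError(f"no callable region set for sample {sample!r}")

    out: dict[str, list[VariantRecord]] = {s: [] for s in samples}
    for sample in samples:
        audit.retained_per_sample.setdefault(sample, 0)
        audit.dropped_outside_callable.setdefault(sample, 0)
        audit.homref_genotypes_removed.setdefault(sample, 0)
        audit.dropped_non_autosome_x.setdefault(sample, 0)

    for fr in fam:
        site = fr.site
        for sample in samples:
            if not genome.is_autosome_or_x(site.contig):
                audit.dropped_non_autosome_x[sample] += 1
                continue
            if not callable_regions[sample].contains(site.contig, site.pos - 1):
                audit.dropped_outside_callable[sample] += 1
                continue
            call = site.samples[sample]
            if genotype_class(call.genotype) is GenotypeClass.HOM_REF:
                audit.homref_genotypes_removed[sample] += 1
                continue
            out[sample].append(
                replace(site, samples={sample: call})
            )
            audit.retained_per_sample[sample] += 1

    rank = genome._rank
    for sample in out:
        out[sample].sort(key=lambda r: (rank.get(r.contig, len(rank)), r.pos))
    return out
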