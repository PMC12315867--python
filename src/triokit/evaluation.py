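"""Benchmarking: genotype concordance, checkpoint selection, Mendelian
inheritance error (MIE) assessment, GQ calibration curves, callset QC
summaries, and population allele-frequency (PopVCF) construction.

Concordance uses exact-match semantics: a true positive is an exact match
of site, alleles, and (unordered) genotype between truth and query; a
query-only call is a false positive and a truth-only call a false
negative. A shared site+alleles with a different genotype is tallied as
both one FP and one FN plus a separate genotype-mismatch count (so both
precision and recall are penalized); a hap.py-style FP-only accounting is
available via ``gt_mismatch_mode``. No indel normalization is performed —
matching is on the caller's representation.

The F1 score is TP / (TP + ½(FP + FN)), the harmonic mean of precision
and recall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from .core_io import Call, GenomeIndex, Genotype, IntervalSet, VariantRecord
from .curation import FamilyRecord
from .mendelian import GenotypeClass, VerdictStatus, genotype_class

__all__ = [
    "StratumCounts",
    "ConcordanceReport",
    "MIEResult",
    "CurvePoint",
    "SummaryStats",
    "classify_variant_type",
    "compare_callsets",
    "f1_score",
    "select_best_checkpoint",
    "mie_assess",
    "mie_calibration_curve",
    "summary_stats",
    "make_popvcf",
]

_LONG_ALLELE = 50  # bp; at or above this, not a short indel


def classify_variant_type(r: VariantRecord) -> str:
    """Classify a record as ``SNV``, ``indel`` (<50 bp) or ``other``."""
    if not r.alts:
        return "other"
    alleles = (r.ref, *r.alts)
    if all(len(a) == 1 for a in alleles):
        return "SNV"
    if any(len(a) >= _LONG_ALLELE for a in alleles):
        return "other"
    if any(len(a) != len(r.ref) for a in r.alts):
        return "indel"
    return "other"  # same-length multi-base substitution (MNP)


def f1_score(tp: int, fp: int, fn: int) -> float | None:
    """F1 = TP / (TP + ½(FP + FN)); ``None`` when no calls were assessed."""
    if tp < 0 or fp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp + fn == 0:
        return None
    return tp / (tp + 0.5 * (fp + fn))


@dataclass
class StratumCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    gt_mismatch: int = 0

    @property
    def precision(self) -> float | None:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else None

    @property
    def recall(self) -> float | None:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else None

    @property
    def f1(self) -> float | None:
        return f1_score(self.tp, self.fp, self.fn)

    def __iadd__(self, other: "StratumCounts") -> "StratumCounts":
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn
        self.gt_mismatch += other.gt_mismatch
        return self


Stratum = tuple[str, str, str | None]  # (variant type, genotype class, region)


@dataclass
class ConcordanceReport:
    """TP/FP/FN tallies keyed by (variant type, genotype class, region).

    The region key ``None`` holds the unstratified tally; user-supplied
    region labels add parallel tallies restricted to those intervals.
    ``pooled()`` sums the unstratified strata and therefore reconciles
    with per-stratum counts by construction.
    """

    counts: dict[Stratum, StratumCounts] = field(default_factory=dict)

    def at(self, vtype: str, gclass: str, region: str | None = None) -> StratumCounts:
        return self.counts.setdefault((vtype, gclass, region), StratumCounts())

    def pooled(self, region: str | None = None) -> StratumCounts:
        total = StratumCounts()
        for (vt, gc, reg), c in self.counts.items():
            if reg == region:
                total += c
        return total

    @property
    def overall_f1(self) -> float | None:
        return self.pooled().f1

    def strata(self) -> list[Stratum]:
        return sorted(
            self.counts,
            key=lambda s: (s[2] is not None, s[2] or "", s[0], s[1]),
        )


def _genotype_key(g: Genotype) -> tuple:
    return g.unordered()


def _index_callset(
    records: Iterable[VariantRecord], name: str
) -> dict[tuple, VariantRecord]:
    indexed: dict[tuple, VariantRecord] = {}
    for rec in records:
        if len(rec.samples) != 1:
            raise ValueError(
                f"{name} callset must be single-sample; "
                f"got {len(rec.samples)} samples at {rec.contig}:{rec.pos}"
            )
        indexed[(rec.contig, rec.pos, rec.ref, frozenset(rec.alts))] = rec
    return indexed


def _only_call(rec: VariantRecord) -> Call:
    return next(iter(rec.samples.values()))


def compare_callsets(
    truth: Iterable[VariantRecord],
    query: Iterable[VariantRecord],
    strat: Mapping[str, IntervalSet] | None = None,
    gt_mismatch_mode: str = "fp_and_fn",
) -> ConcordanceReport:
    """Exact-match concordance between a truth and a query callset.

    The match key is (contig, pos, ref, alt-set, unordered genotype).
    ``gt_mismatch_mode`` controls the accounting for a shared site+alleles
    with different genotypes: ``"fp_and_fn"`` (default) counts one FP and
    one FN; ``"fp_only"`` counts one FP. Both modes tally ``gt_mismatch``
    separately. Optional region strata add tallies keyed by label, decided
    on the record's anchor base.
    """
    if gt_mismatch_mode not in ("fp_and_fn", "fp_only"):
        raise ValueError(f"unknown gt_mismatch_mode {gt_mismatch_mode!r}")
    truth_idx = _index_callset(truth, "truth")
    query_idx = _index_callset(query, "query")
    strat = strat or {}
    report = ConcordanceReport()

    def region_labels(rec: VariantRecord) -> list[str | None]:
        labels: list[str | None] = [None]
        labels.extend(
            label
            for label, regions in strat.items()
            if regions.contains(rec.contig, rec.pos - 1)
        )
        return labels

    def tally(rec: VariantRecord, which: str, n: int = 1) -> None:
        vtype = classify_variant_type(rec)
        gclass = genotype_class(_only_call(rec).genotype).value
        for region in region_labels(rec):
            counts = report.at(vtype, gclass, region)
            setattr(counts, which, getattr(counts, which) + n)

    for key, trec in truth_idx.items():
        qrec = query_idx.get(key)
        if qrec is None:
            tally(trec, "fn")
        elif _genotype_key(_only_call(trec).genotype) == _genotype_key(
            _only_call(qrec).genotype
        ):
            tally(trec, "tp")
        else:
            # same site and alleles, different genotype
            tally(trec, "gt_mismatch")
            if gt_mismatch_mode == "fp_and_fn":
                tally(trec, "fn")
            tally(qrec, "fp")
    for key, qrec in query_idx.items():
        if key not in truth_idx:
            tally(qrec, "fp")
    return report


def select_best_checkpoint(
    reports: Sequence[tuple[str, ConcordanceReport]],
    per_stratum: Stratum | None = None,
) -> str:
    """Pick the checkpoint with the best F1 on the shared offspring truth.

    By default all strata are pooled; pass ``per_stratum`` to select on a
    single stratum's F1 instead. Ties go to the earliest checkpoint in
    the list (training-iteration order).
    """
    if not reports:
        raise ValueError("no checkpoint reports supplied")
    best_id, best_f1 = None, -math.inf
    for ckpt_id, report in reports:
        if per_stratum is None:
            f1 = report.overall_f1
        else:
            f1 = report.counts.get(per_stratum, StratumCounts()).f1
        f1 = -math.inf if f1 is None else f1
        if f1 > best_f1:
            best_id, best_f1 = ckpt_id, f1
    assert best_id is not None
    return best_id


@dataclass(frozen=True)
class CurvePoint:
    rank: int
    gq: int | None
    cum_variants: int
    cum_errors: int


@dataclass
class MIEResult:
    """Mendelian-inheritance-error tally over assessed trio sites.

    ``assessed`` counts PASS autosome+X sites where all three genotypes
    are called and diploid; ``rate`` is ``None`` when nothing was
    assessed. ``curve`` (optional) is the offspring-GQ-sorted cumulative
    (variants, errors) calibration curve.
    """

    assessed: int
    discordant: int
    curve: list[CurvePoint] = field(default_factory=list)

    @property
    def rate(self) -> float | None:
        return self.discordant / self.assessed if self.assessed else None


def _assessable(
    fam: Iterable[FamilyRecord], genome: GenomeIndex, snv_only: bool
) -> Iterator[FamilyRecord]:
    for fr in fam:
        if not fr.site.is_pass:
            continue
        if not genome.is_autosome_or_x(fr.site.contig):
            continue
        if not fr.verdict.is_assessed:
            continue
        if snv_only and classify_variant_type(fr.site) != "SNV":
            continue
        yield fr


def mie_assess(
    fam: Iterable[FamilyRecord], genome: GenomeIndex, snv_only: bool = False
) -> MIEResult:
    """MIE rate over PASS autosome+X sites with fully called diploid trios.

    ``snv_only`` restricts the tally to SNVs, matching discordant-SNV
    reporting conventions.
    """
    assessed = discordant = 0
    for fr in _assessable(fam, genome, snv_only):
        assessed += 1
        if fr.verdict.status is VerdictStatus.DISCORDANT:
            discordant += 1
    return MIEResult(assessed=assessed, discordant=discordant)


def mie_calibration_curve(
    fam: Iterable[FamilyRecord],
    genome: GenomeIndex,
    snv_only: bool = False,
) -> MIEResult:
    """Cumulative MIE curve with sites ranked by offspring GQ, descending.

    Absent GQ sorts last (below GQ 0); ties break on (contig order, pos).
    The final curve point equals the (assessed, discordant) totals of
    :func:`mie_assess` on the same input.
    """
    entries = list(_assessable(fam, genome, snv_only))
    rank = genome._rank

    def key(fr: FamilyRecord) -> tuple:
        gq = fr.child_call.gq
        return (
            gq is None,
            -(gq if gq is not None else 0),
            rank.get(fr.site.contig, len(rank)),
            fr.site.pos,
        )

    entries.sort(key=key)
    curve: list[CurvePoint] = []
    cum_err = 0
    for i, fr in enumerate(entries, 1):
        if fr.verdict.status is VerdictStatus.DISCORDANT:
            cum_err += 1
        curve.append(
            CurvePoint(
                rank=i,
                gq=fr.child_call.gq,
                cum_variants=i,
                cum_errors=cum_err,
            )
        )
    return MIEResult(assessed=len(entries), discordant=cum_err, curve=curve)


_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


@dataclass
class SummaryStats:
    """Callset QC summary: the distributions worth comparing against the
    data a model checkpoint was trained on (variant density, SNV:indel,
    Het:HomAlt, Ti:Tv)."""

    n_variants: int
    snv_count: int
    indel_count: int
    het_count: int
    homalt_count: int
    ti: int
    tv: int
    variant_density_per_mb: float

    @property
    def snv_indel_ratio(self) -> float | None:
        return self.snv_count / self.indel_count if self.indel_count else None

    @property
    def het_homalt_ratio(self) -> float | None:
        return self.het_count / self.homalt_count if self.homalt_count else None

    @property
    def titv_ratio(self) -> float | None:
        return self.ti / self.tv if self.tv else None


def summary_stats(
    records: Iterable[VariantRecord], sample: str, genome_span: int
) -> SummaryStats:
    """Summarize one sample's variant calls.

    Only records where the sample carries at least one alt allele are
    counted. Ti (A<->G, C<->T) and Tv tallies consider single-base
    ref->alt pairs, one per distinct carried alt allele per record (not
    per haplotype).
    """
    n = snv = indel = het = homalt = ti = tv = 0
    for rec in records:
        call = rec.samples[sample]
        gclass = genotype_class(call.genotype)
        if gclass in (GenotypeClass.HOM_REF, GenotypeClass.MISSING):
            continue
        n += 1
        vtype = classify_variant_type(rec)
        if vtype == "SNV":
            snv += 1
        elif vtype == "indel":
            indel += 1
        if gclass is GenotypeClass.HET:
            het += 1
        elif gclass is GenotypeClass.HOM_ALT:
            homalt += 1
        carried = {a for a in call.genotype.alleles if a not in (None, 0)}
        for allele_idx in carried:
            alt = rec.alts[allele_idx - 1]
            if len(rec.ref) == 1 and len(alt) == 1:
                pair = frozenset((rec.ref.upper(), alt.upper()))
                if pair in _TRANSITIONS:
                    ti += 1
                else:
                    tv += 1
    density = n / (genome_span / 1e6) if genome_span else 0.0
    return SummaryStats(
        n_variants=n,
        snv_count=snv,
        indel_count=indel,
        het_count=het,
        homalt_count=homalt,
        ti=ti,
        tv=tv,
        variant_density_per_mb=density,
    )


def make_popvcf(
    cohort: Iterable[VariantRecord],
) -> Iterator[VariantRecord]:
    """Drop genotypes, retaining only per-alt allele frequencies.

    AF for each alt = called alt allele count / total called alleles at
    the site; missing alleles are excluded from the denominator. A site
    with zero called alleles is retained with AF absent. Output records
    carry no sample columns.
    """
    for rec in cohort:
        if not rec.samples:
            raise ValueError("PopVCF construction needs a cohort with samples")
        alt_counts = [0] * len(rec.alts)
        called = 0
        for call in rec.samples.values():
            for allele in call.genotype.alleles:
                if allele is None:
                    continue
                called += 1
                if allele > 0:
                    alt_counts[allele - 1] += 1
        info: dict[str, object] = {}
        if called:
            info["AF"] = tuple(c / called for c in alt_counts)
        yield VariantRecord(
            contig=rec.contig,
            pos=rec.pos,
            ref=rec.ref,
            alts=rec.alts,
            filters=rec.filters,
            samples={},
            info=info,
        )
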