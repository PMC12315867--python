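"""Domain types and readers/writers for VCF, BED, PED and FASTA-index files.

Conventions used throughout the package:

* VCF positions are 1-based (as in the file format); BED intervals are
  0-based half-open. A variant's membership in a region is decided by its
  anchor base (``pos - 1``) only, so a multi-base deletion does not need to
  fit entirely inside an interval.
* An absent GQ is represented as ``None`` and is distinct from ``GQ == 0``.
* Contig ordering follows the genome index (FASTA ``.fai`` order) when one
  is available, never lexicographic order.
"""

from __future__ import annotations

import itertools
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import pysam

__all__ = [
    "Genotype",
    "Call",
    "VariantRecord",
    "VcfHeader",
    "VcfReader",
    "GenomeIndex",
    "IntervalSet",
    "Pedigree",
    "Trio",
    "VcfParseError",
    "BedParseError",
    "read_vcf",
    "write_vcf",
    "read_bed",
    "write_bed",
    "read_fai",
    "read_ped",
    "intersect_with_regions",
]


class VcfParseError(ValueError):
    """Raised when a VCF header or record cannot be parsed."""


class BedParseError(ValueError):
    """Raised when a BED line is malformed."""


# --------------------------------------------------------------------------
# genotypes and variant records
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Genotype:
    """A called or partially called genotype.

    ``alleles`` holds allele indices (0 = ref) with ``None`` marking a
    missing allele. A genotype with *any* missing allele is treated as
    missing for all trio assessments. Phasing is carried through I/O but
    ignored by consistency checks.
    """

    alleles: tuple[int | None, ...]
    phased: bool = False

    @property
    def ploidy(self) -> int:
        return len(self.alleles)

    @property
    def is_diploid(self) -> bool:
        return len(self.alleles) == 2

    @property
    def is_missing(self) -> bool:
        return any(a is None for a in self.alleles) or not self.alleles

    @property
    def is_called_diploid(self) -> bool:
        return self.is_diploid and not self.is_missing

    def unordered(self) -> tuple[int | None, ...]:
        """Allele multiset as a sorted tuple (missing sorts last)."""
        return tuple(sorted(self.alleles, key=lambda a: (a is None, a)))

    def __str__(self) -> str:
        sep = "|" if self.phased else "/"
        return sep.join("." if a is None else str(a) for a in self.alleles)


class Call(NamedTuple):
    """One sample's genotype call at a site, with its genotype quality."""

    genotype: Genotype
    gq: int | None = None


@dataclass(frozen=True)
class VariantRecord:
    """One VCF site with per-sample genotype calls.

    ``filters`` is the set of FILTER labels; ``{"PASS"}`` marks a passing
    site and an empty set an unfiltered ('.') one. ``info`` carries only
    the fields this toolkit consumes (AF for population VCFs).
    """

    contig: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    filters: frozenset[str] = frozenset({"PASS"})
    samples: Mapping[str, Call] = field(default_factory=dict)
    info: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref:
            raise ValueError("ref allele must be non-empty")
        for alt in self.alts:
            if alt == self.ref:
                raise ValueError(
                    f"alt allele equals ref at {self.contig}:{self.pos}"
                )

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alts)

    @property
    def is_pass(self) -> bool:
        return self.filters == frozenset({"PASS"})

    def call(self, sample: str) -> Call:
        return self.samples[sample]

    def with_samples(self, samples: Mapping[str, Call]) -> "VariantRecord":
        return replace(self, samples=dict(samples))


def _is_symbolic(allele: str) -> bool:
    return "<" in allele or allele == "*" or "]" in allele or "[" in allele


# --------------------------------------------------------------------------
# genome index
# --------------------------------------------------------------------------

_X_NAMES = {"x", "chrx"}
_EXCLUDED_NAMES = {"y", "chry", "mt", "m", "chrm", "chrmt"}


@dataclass
class GenomeIndex:
    """Ordered contigs with lengths, with autosome / X annotation.

    By default contigs whose name (minus any ``chr`` prefix) is an integer
    are autosomes and ``X`` is the X Chromosome; Y, MT and unplaced
    scaffolds are neither. Pass explicit ``autosomes`` / ``x_contigs`` sets
    to override the heuristic for unconventional naming.
    """

    contigs: list[tuple[str, int]]
    autosomes: frozenset[str] = None  # type: ignore[assignment]
    x_contigs: frozenset[str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.contigs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate contig names in genome index")
        for name, length in self.contigs:
            if length <= 0:
                raise ValueError(f"contig {name} has non-positive length")
        if self.autosomes is None or self.x_contigs is None:
            autosomes, x_contigs = set(), set()
            for name in names:
                base = name.lower().removeprefix("chr")
                if base.isdigit():
                    autosomes.add(name)
                elif name.lower() in _X_NAMES:
                    x_contigs.add(name)
            if self.autosomes is None:
                self.autosomes = frozenset(autosomes)
            if self.x_contigs is None:
                self.x_contigs = frozenset(x_contigs)
        self._rank = {name: i for i, name in enumerate(names)}
        self._length = dict(self.contigs)

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.contigs]

    def length(self, contig: str) -> int:
        return self._length[contig]

    def rank(self, contig: str) -> int:
        """Sort key for contig order; unknown contigs sort last."""
        return self._rank.get(contig, len(self._rank))

    def __contains__(self, contig: str) -> bool:
        return contig in self._rank

    def is_autosome_or_x(self, contig: str) -> bool:
        return contig in self.autosomes or contig in self.x_contigs

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.contigs)


def read_fai(path: str | Path) -> GenomeIndex:
    """Read a FASTA index (``samtools faidx`` output) into a GenomeIndex."""
    contigs: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 tab-separated fields")
            contigs.append((fields[0], int(fields[1])))
    return GenomeIndex(contigs)


# --------------------------------------------------------------------------
# interval sets
# --------------------------------------------------------------------------


class IntervalSet:
    """A normalized set of genomic intervals (0-based, half-open).

    Intervals are stored sorted and merged per contig, so membership tests
    are O(log n) and normalization is idempotent by construction.
    """

    def __init__(
        self,
        intervals: Iterable[tuple[str, int, int]] = (),
        genome: GenomeIndex | None = None,
    ):
        self._genome = genome
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, start, end in intervals:
            if start >= end:
                raise ValueError(
                    f"invalid interval {contig}:{start}-{end} (start >= end)"
                )
            by_contig.setdefault(contig, []).append((start, end))
        self._by_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, ivs in by_contig.items():
            ivs.sort()
            merged: list[tuple[int, int]] = []
            for start, end in ivs:
                if merged and start <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], end))
                else:
                    merged.append((start, end))
            self._by_contig[contig] = merged
        self._starts = {
            contig: [s for s, _ in ivs] for contig, ivs in self._by_contig.items()
        }

    def _contig_order(self) -> list[str]:
        if self._genome is not None:
            return sorted(self._by_contig, key=self._genome.rank)
        return sorted(self._by_contig)

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        for contig in self._contig_order():
            for start, end in self._by_contig[contig]:
                yield contig, start, end

    def __len__(self) -> int:
        return sum(len(ivs) for ivs in self._by_contig.values())

    def __bool__(self) -> bool:
        return bool(self._by_contig)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._by_contig == other._by_contig

    def __repr__(self) -> str:
        return f"IntervalSet({list(self)!r})"

    @property
    def total_length(self) -> int:
        return sum(
            end - start for ivs in self._by_contig.values() for start, end in ivs
        )

    def contains(self, contig: str, pos0: int) -> bool:
        """Is 0-based position ``pos0`` covered by some interval?"""
        starts = self._starts.get(contig)
        if not starts:
            return False
        i = bisect_right(starts, pos0) - 1
        return i >= 0 and pos0 < self._by_contig[contig][i][1]

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(
            itertools.chain(self, other), genome=self._genome or other._genome
        )

    def intersection(self, other: "IntervalSet") -> "IntervalSet":
        out: list[tuple[str, int, int]] = []
        for contig, ivs in self._by_contig.items():
            theirs = other._by_contig.get(contig)
            if not theirs:
                continue
            i = j = 0
            while i < len(ivs) and j < len(theirs):
                s = max(ivs[i][0], theirs[j][0])
                e = min(ivs[i][1], theirs[j][1])
                if s < e:
                    out.append((contig, s, e))
                if ivs[i][1] <= theirs[j][1]:
                    i += 1
                else:
                    j += 1
        return IntervalSet(out, genome=self._genome or other._genome)

    @classmethod
    def whole_genome(cls, genome: GenomeIndex) -> "IntervalSet":
        return cls(
            ((name, 0, length) for name, length in genome.contigs), genome=genome
        )


def read_bed(path: str | Path, genome: GenomeIndex | None = None) -> IntervalSet:
    """Read a BED3+ file into a normalized (sorted, merged) IntervalSet."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise BedParseError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            intervals.append((fields[0], start, end))
    return IntervalSet(intervals, genome=genome)


def write_bed(regions: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for contig, start, end in regions:
            fh.write(f"{contig}\t{start}\t{end}\n")


# --------------------------------------------------------------------------
# pedigree
# --------------------------------------------------------------------------


class Trio(NamedTuple):
    child: str
    father: str
    mother: str


@dataclass
class Pedigree:
    """PED-format pedigree: per sample, family / parents / sex."""

    records: dict[str, dict[str, str]]

    def trios(self) -> list[Trio]:
        """Complete trios: child whose father and mother are both in the pedigree."""
        out = []
        for sample, rec in self.records.items():
            father, mother = rec["father"], rec["mother"]
            if father in self.records and mother in self.records:
                out.append(Trio(sample, father, mother))
        return out

    def _check_no_ancestor_cycles(self) -> None:
        for start in self.records:
            seen = {start}
            frontier = [start]
            while frontier:
                sample = frontier.pop()
                rec = self.records.get(sample)
                if rec is None:
                    continue
                for parent in (rec["father"], rec["mother"]):
                    if parent == "0" or parent not in self.records:
                        continue
                    if parent in seen and parent == start:
                        raise ValueError(f"sample {start} is its own ancestor")
                    if parent not in seen:
                        seen.add(parent)
                        frontier.append(parent)


def read_ped(path: str | Path) -> Pedigree:
    """Read a 6-column PED file (family, id, father, mother, sex, phenotype)."""
    records: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: fewer than 5 PED columns")
            family, sample, father, mother, sex = fields[:5]
            records[sample] = {
                "family": family,
                "father": father,
                "mother": mother,
                "sex": sex,
            }
    ped = Pedigree(records)
    ped._check_no_ancestor_cycles()
    return ped


# --------------------------------------------------------------------------
# VCF reading / writing
# --------------------------------------------------------------------------


@dataclass
class VcfHeader:
    samples: list[str]
    contigs: list[tuple[str, int | None]]
    filters: set[str] = field(default_factory=set)

    @property
    def contig_rank(self) -> dict[str, int]:
        return {name: i for i, (name, _) in enumerate(self.contigs)}


class VcfReader:
    """Iterator over VariantRecords with skip counters.

    Records containing symbolic alleles (``<NON_REF>``, ``*``, breakends)
    are rejected and counted in ``skipped_symbolic`` rather than yielded;
    non-diploid genotypes are kept on the record but counted in
    ``non_diploid_calls`` so downstream assessments can report them.
    """

    def __init__(self, path: str | Path):
        self._path = str(path)
        try:
            verbosity = pysam.set_verbosity(0)  # silence missing-index chatter
            try:
                self._vf = pysam.VariantFile(self._path)
            finally:
                pysam.set_verbosity(verbosity)
        except (ValueError, OSError) as exc:
            raise VcfParseError(f"{path}: cannot parse VCF header: {exc}") from exc
        self.header = VcfHeader(
            samples=list(self._vf.header.samples),
            contigs=[
                (c.name, c.length) for c in self._vf.header.contigs.values()
            ],
            filters=set(self._vf.header.filters.keys()),
        )
        self.skipped_symbolic = 0
        self.non_diploid_calls = 0

    def __iter__(self) -> Iterator[VariantRecord]:
        record_no = 0
        try:
            for rec in self._vf:
                record_no += 1
                parsed = self._convert(rec)
                if parsed is not None:
                    yield parsed
        except (ValueError, OSError) as exc:
            raise VcfParseError(
                f"{self._path}: malformed record #{record_no + 1}: {exc}"
            ) from exc

    def _convert(self, rec: "pysam.VariantRecord") -> VariantRecord | None:
        alts = tuple(rec.alts or ())
        if _is_symbolic(rec.ref) or any(_is_symbolic(a) for a in alts):
            self.skipped_symbolic += 1
            return None
        samples: dict[str, Call] = {}
        for name in self.header.samples:
            call = rec.samples[name]
            gt = call.get("GT")
            if gt is None or gt == (None,):
                genotype = Genotype((None, None))
            else:
                genotype = Genotype(tuple(gt), phased=bool(call.phased))
            if genotype.ploidy != 2:
                self.non_diploid_calls += 1
            gq = call.get("GQ")
            if isinstance(gq, (tuple, list)):
                gq = gq[0] if gq else None
            samples[name] = Call(genotype, None if gq is None else int(gq))
        info: dict[str, object] = {}
        if "AF" in rec.info:
            af = rec.info["AF"]
            if not isinstance(af, tuple):
                af = (af,)
            info["AF"] = tuple(None if x is None else float(x) for x in af)
        return VariantRecord(
            contig=rec.contig,
            pos=rec.pos,
            ref=rec.ref,
            alts=alts,
            filters=frozenset(rec.filter.keys()),
            samples=samples,
            info=info,
        )


def read_vcf(path: str | Path) -> VcfReader:
    """Open a VCF (plain or bgzipped) and return an iterable reader.

    The reader exposes ``.header`` (samples + contigs) and yields
    :class:`VariantRecord` objects in file order. Absent GQ values are
    reported as ``None``, never 0.
    """
    return VcfReader(path)


def write_vcf(
    header: VcfHeader,
    records: Iterable[VariantRecord],
    path: str | Path,
    extra_header_lines: Sequence[str] = (),
) -> None:
    """Write records as VCF v4.2 with GT and GQ FORMAT fields.

    Records must arrive sorted by (contig order in ``header``, pos);
    unsorted input raises rather than silently re-sorting. A ``.gz``
    suffix selects bgzip compression.
    """
    records = list(records)
    rank = header.contig_rank
    keys = [(rank.get(r.contig, len(rank)), r.contig, r.pos) for r in records]
    for prev, cur, rec in zip(keys, keys[1:], records[1:]):
        if cur < prev:
            raise ValueError(
                f"records not sorted: {rec.contig}:{rec.pos} after "
                f"{prev[1]}:{prev[2]}"
            )

    hdr = pysam.VariantHeader()
    for line in extra_header_lines:
        hdr.add_line(line)
    known = {name for name, _ in header.contigs}
    for name, length in header.contigs:
        hdr.contigs.add(name, length=length)
    for rec in records:
        if rec.contig not in known:
            hdr.contigs.add(rec.contig)
            known.add(rec.contig)
    filters = set(header.filters) | {f for rec in records for f in rec.filters}
    for f in sorted(filters - {"PASS"}):
        hdr.filters.add(f, None, None, "tranche or caller filter label")
    hdr.info.add("AF", "A", "Float", "Allele frequency among called alleles")
    if header.samples:
        hdr.formats.add("GT", 1, "String", "Genotype")
        hdr.formats.add("GQ", 1, "Integer", "Genotype quality (Phred)")
        for sample in header.samples:
            hdr.add_sample(sample)

    mode = "wz" if str(path).endswith(".gz") else "w"
    with pysam.VariantFile(str(path), mode, header=hdr) as out:
        for rec in records:
            vrec = out.new_record(
                contig=rec.contig,
                start=rec.pos - 1,
                alleles=(rec.ref, *rec.alts) if rec.alts else (rec.ref,),
            )
            for f in sorted(rec.filters):
                vrec.filter.add(f)
            if "AF" in rec.info:
                vrec.info["AF"] = tuple(rec.info["AF"])  # type: ignore[arg-type]
            for sample in header.samples:
                call = rec.samples.get(sample)
                if call is None:
                    call = Call(Genotype((None, None)))
                vrec.samples[sample]["GT"] = tuple(call.genotype.alleles)
                vrec.samples[sample].phased = call.genotype.phased
                if call.gq is not None:
                    vrec.samples[sample]["GQ"] = call.gq
            out.write(vrec)


# --------------------------------------------------------------------------
# region intersection
# --------------------------------------------------------------------------


def intersect_with_regions(
    records: Iterable[VariantRecord], regions: IntervalSet
) -> Iterator[VariantRecord]:
    """Keep records whose anchor base (pos, 0-based) lies in a region.

    Order is preserved; an empty region set yields nothing.
    """
    for rec in records:
        if regions.contains(rec.contig, rec.pos - 1):
            yield rec
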