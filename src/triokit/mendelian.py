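"""Trio genotype consistency: the Mendelian-inheritance engine.

A trio genotype (child, father, mother) is *consistent* when the child's
two alleles can be ordered so that one is drawn from the father's allele
multiset and the other from the mother's. Any missing or non-diploid
genotype makes the trio *unassessed* — curation only removes demonstrable
violations. Diploid rules are applied uniformly on all contigs, including
X, because upstream callers emit diploid genotypes there.

De novo variants are deliberately not whitelisted: a violation of the
transmission rule is treated as error, which is the conservative choice
when the trio genotypes come from short-read calls where genotyping error
vastly outnumbers true de novo mutation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum

from .core_io import Genotype

__all__ = [
    "GenotypeClass",
    "VerdictStatus",
    "TrioVerdict",
    "genotype_class",
    "is_consistent",
    "enumerate_consistent",
]


class GenotypeClass(str, Enum):
    HOM_REF = "HomRef"
    HET = "Het"
    HOM_ALT = "HomAlt"
    MISSING = "Missing"


class VerdictStatus(str, Enum):
    CONSISTENT = "consistent"
    DISCORDANT = "discordant"
    UNASSESSED = "unassessed"


@dataclass(frozen=True)
class TrioVerdict:
    """Outcome of a trio consistency check.

    ``reason`` explains *why* a trio was not assessed; it is ``ok`` exactly
    when the trio was assessed (consistent or discordant).
    """

    status: VerdictStatus
    reason: str = "ok"

    def __post_init__(self) -> None:
        unassessed = self.status is VerdictStatus.UNASSESSED
        if unassessed != (self.reason != "ok"):
            raise ValueError("status unassessed iff reason != ok")

    @property
    def is_discordant(self) -> bool:
        return self.status is VerdictStatus.DISCORDANT

    @property
    def is_assessed(self) -> bool:
        return self.status is not VerdictStatus.UNASSESSED


CONSISTENT = TrioVerdict(VerdictStatus.CONSISTENT)
DISCORDANT = TrioVerdict(VerdictStatus.DISCORDANT)


def genotype_class(g: Genotype) -> GenotypeClass:
    """Classify a genotype as HomRef / Het / HomAlt / Missing.

    Classification ignores allele order and phasing: 0/1 and 1/0 are both
    Het; 1/2 is Het (two distinct called alleles); 2/2 is HomAlt.
    """
    if g.is_missing:
        return GenotypeClass.MISSING
    alleles = set(g.alleles)
    if alleles == {0}:
        return GenotypeClass.HOM_REF
    if len(alleles) > 1:
        return GenotypeClass.HET
    return GenotypeClass.HOM_ALT


def is_consistent(child: Genotype, father: Genotype, mother: Genotype) -> TrioVerdict:
    """Check Mendelian transmission for one site's trio of genotypes.

    Consistent iff some ordering (a, b) of the child's alleles has
    ``a in father.alleles`` and ``b in mother.alleles``. Phase is ignored;
    the rule is symmetric in the parents. Missing or non-diploid genotypes
    yield an unassessed verdict, never a discordant one.
    """
    for g in (child, father, mother):
        if g.is_missing:
            return TrioVerdict(VerdictStatus.UNASSESSED, "missing-genotype")
    for g in (child, father, mother):
        if not g.is_diploid:
            return TrioVerdict(VerdictStatus.UNASSESSED, "non-diploid")
    a, b = child.alleles
    if (a in father.alleles and b in mother.alleles) or (
        b in father.alleles and a in mother.alleles
    ):
        return CONSISTENT
    return DISCORDANT


def _unordered_genotypes(n_alleles: int) -> list[tuple[int, int]]:
    return [
        (i, j) for i in range(n_alleles) for j in range(i, n_alleles)
    ]


def enumerate_consistent(
    n_alt_alleles: int,
) -> set[tuple[tuple[int, int], tuple[int, int], tuple[int, int]]]:
    """All Mendelian-consistent (child, father, mother) genotype triples.

    Genotypes are unordered allele pairs ``(a, b)`` with ``a <= b`` over
    allele indices ``0..n_alt_alleles``. The set is exhaustive and
    duplicate-free; every member passes :func:`is_consistent` and every
    non-member fails it. Intended as a public test oracle.
    """
    if not 1 <= n_alt_alleles <= 3:
        raise ValueError(f"n_alt_alleles must be in 1..3, got {n_alt_alleles}")
    genotypes = _unordered_genotypes(1 + n_alt_alleles)
    out = set()
    for child, father, mother in itertools.product(genotypes, repeat=3):
        verdict = is_consistent(
            Genotype(child), Genotype(father), Genotype(mother)
        )
        if verdict.status is VerdictStatus.CONSISTENT:
            out.add((child, father, mother))
    return out
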