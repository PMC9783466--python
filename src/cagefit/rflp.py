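"""In-silico RFLP genotyping of the ace-1 amplicon.

A ~600-bp PCR fragment of ace-1 is digested with a diagnostic enzyme whose
recognition site is created by a resistance SNP, so alleles differ in their
cut positions and genotypes differ in their fragment-length patterns. A
heterozygote carries both alleles' amplicons, so its pattern is the union of
the two homozygote patterns (co-migrating fragments collapse on a gel).

Two assays are built in:

* ``AluI`` — the G119S resistance mutation creates an AluI site. Patterns:
  SS -> {597}; RR -> {496, 101}; RS -> {597, 496, 101}.
* ``BfaI`` — a SNP distinguishing the R2 from the R1 resistance allele
  creates a BfaI site in R2. Patterns: R1R1 -> {597};
  R2R2 -> {73, 132, 392}; R1R2 -> {597, 73, 132, 392}.

Cut coordinates inside the amplicon are chosen to reproduce these published
fragment sets; the fragment sets, not the coordinates, are the contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "RflpAssay",
    "GenotypeCall",
    "ASSAYS",
    "digest_fragments",
    "genotype_pattern",
    "call_genotype",
    "load_assays",
]


def digest_fragments(amplicon_length: int, cut_positions: Iterable[int]) -> tuple[int, ...]:
    """Fragment lengths from digesting an amplicon at the given cut offsets.

    Positions are bp offsets strictly inside (0, amplicon_length); duplicates
    or out-of-range positions are rejected. The sorted fragment lengths always
    sum to the amplicon length.
    """
    cuts = sorted(cut_positions)
    if len(set(cuts)) != len(cuts):
        raise ValueError(f"duplicate cut positions: {cuts}")
    if any(not (0 < c < amplicon_length) for c in cuts):
        raise ValueError(f"cut positions {cuts} outside (0, {amplicon_length})")
    edges = [0, *cuts, amplicon_length]
    return tuple(sorted(b - a for a, b in zip(edges, edges[1:])))


@dataclass(frozen=True)
class RflpAssay:
    """One enzyme digest: amplicon length and per-allele cut positions."""

    enzyme: str
    amplicon_length: int
    allele_cuts: Mapping[str, tuple[int, ...]]

    def fragments(self, allele: str) -> tuple[int, ...]:
        if allele not in self.allele_cuts:
            raise KeyError(f"allele {allele!r} not defined for {self.enzyme} assay")
        return digest_fragments(self.amplicon_length, self.allele_cuts[allele])

    @property
    def genotypes(self) -> list[tuple[str, str]]:
        alleles = list(self.allele_cuts)
        return [(a, b) for i, a in enumerate(alleles) for b in alleles[i:]]


@dataclass(frozen=True)
class GenotypeCall:
    """A genotype label with its expected (distinct) fragment lengths."""

    label: str
    fragments: frozenset[int]


def genotype_pattern(assay: RflpAssay, alleles: tuple[str, str]) -> GenotypeCall:
    """Expected band pattern of a genotype: union of the two alleles' fragments.

    Equal-length fragments from the two alleles co-migrate, so duplicates are
    collapsed. The label concatenates the allele names (e.g. ``R1R2``, ``SS``,
    with heterozygotes written resistant-first as ``RS``).
    """
    a1, a2 = alleles
    frags = frozenset(assay.fragments(a1)) | frozenset(assay.fragments(a2))
    if a1 == a2:
        label = a1 + a2
    else:
        # stable orientation: order as defined in the assay's allele registry
        order = list(assay.allele_cuts)
        first, second = sorted(alleles, key=order.index)
        label = first + second
    return GenotypeCall(label=label, fragments=frags)


def call_genotype(
    assay: RflpAssay, observed: Sequence[int], tolerance: int = 5
) -> str | None | list[str]:
    """Map an observed fragment-length set back to a genotype.

    Every expected band must be matched by an observed length within
    ``tolerance`` bp and vice versa. Returns the unique matching genotype
    label, ``None`` when nothing matches (no-call), or the sorted list of
    candidate labels when the pattern is ambiguous.
    """
    observed = sorted(set(observed))
    matches = []
    for pair in assay.genotypes:
        call = genotype_pattern(assay, pair)
        expected = sorted(call.fragments)
        if len(expected) != len(observed):
            continue
        if all(abs(e - o) <= tolerance for e, o in zip(expected, observed)):
            matches.append(call.label)
    if not matches:
        return None
    if len(matches) == 1:
        return matches[0]
    return sorted(matches)


# Built-in assays; cut coordinates reproduce the published fragment patterns.
ASSAYS: dict[str, RflpAssay] = {
    "AluI": RflpAssay(
        enzyme="AluI",
        amplicon_length=597,
        allele_cuts={"R": (101,), "S": ()},
    ),
    "BfaI": RflpAssay(
        enzyme="BfaI",
        amplicon_length=597,
        allele_cuts={"R1": (), "R2": (73, 205)},
    ),
}


def load_assays(config: Mapping) -> dict[str, RflpAssay]:
    """Build an assay registry from a plain mapping (e.g. parsed YAML).

    Expected shape::

        {"AluI": {"amplicon_length": 597, "alleles": {"S": [], "R": [101]}}}
    """
    registry = {}
    for name, spec in config.items():
        registry[name] = RflpAssay(
            enzyme=name,
            amplicon_length=int(spec["amplicon_length"]),
            allele_cuts={
                str(a): tuple(int(c) for c in cuts) for a, cuts in spec["alleles"].items()
            },
        )
    return registry
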