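"""Named null-mutant genotypes resolved to zeroed transcription constants.

A null allele is simulated by setting its gene's transcription rate
constant(s) to zero: ``el`` (the evening-complex proxy for *elf3*) zeroes
``v4``; ``prr9``/``prr7`` zero the corresponding split copy's ``v2A`` (and,
by default, ``v2L``).  On the merged BASE variant only the *prr9/prr7* pair
is expressible.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .clock_models import ModelVariant, ParameterSet, get_variant

__all__ = [
    "ALLELES",
    "Genotype",
    "KnockoutMode",
    "GenotypeError",
    "InexpressibleGenotypeError",
    "UnknownAlleleError",
    "parse_genotype",
    "genotype_panel",
    "apply_knockout",
]

ALLELES = ("el", "prr9", "prr7")
_ALIASES = {"elf3": "el", "el": "el", "prr9": "prr9", "prr7": "prr7", "wt": None}


class GenotypeError(Exception):
    pass


class UnknownAlleleError(GenotypeError):
    pass


class InexpressibleGenotypeError(GenotypeError):
    pass


class KnockoutMode(enum.Enum):
    """Which transcription constants a P-gene null zeroes.

    BASAL_AND_LIGHT (default): both the basal constant and the acute
    light-induction constant -- a null produces no mRNA by any route.
    BASAL_ONLY: only the basal constant.
    """

    BASAL_ONLY = "basal_only"
    BASAL_AND_LIGHT = "basal_and_light"


@dataclass(frozen=True)
class Genotype:
    alleles: frozenset

    def __post_init__(self) -> None:
        bad = set(self.alleles) - set(ALLELES)
        if bad:
            raise UnknownAlleleError(f"unknown alleles: {sorted(bad)}")

    @property
    def label(self) -> str:
        if not self.alleles:
            return "WT"
        order = {a: i for i, a in enumerate(ALLELES)}
        return "/".join(sorted(self.alleles, key=order.__getitem__))

    @property
    def is_wild_type(self) -> bool:
        return not self.alleles

    def expressible_in(self, variant: ModelVariant) -> bool:
        if variant.split:
            return True
        # merged P97: prr9 and prr7 are only expressible together
        has9 = "prr9" in self.alleles
        has7 = "prr7" in self.alleles
        return has9 == has7

    def __str__(self) -> str:
        return self.label


def parse_genotype(label: str) -> Genotype:
    """Parse a slash-joined allele label ('elf3/prr9/prr7', 'WT', ...)."""
    text = label.strip()
    if not text or text.lower() in ("wt", "wild-type", "wildtype"):
        return Genotype(frozenset())
    alleles = set()
    for token in text.split("/"):
        key = token.strip().lower()
        if key not in _ALIASES:
            raise UnknownAlleleError(f"unknown allele {token!r} in {label!r}")
        mapped = _ALIASES[key]
        if mapped is not None:
            alleles.add(mapped)
    return Genotype(frozenset(alleles))


def genotype_panel() -> list[Genotype]:
    """The eight-genotype study panel, wild type first.

    All combinations of presence/absence of el with the four prr states
    ({}, {prr9}, {prr7}, {prr9, prr7}), in a fixed display order.
    """
    order = [
        (), ("el",), ("prr9",), ("prr7",), ("prr9", "prr7"),
        ("el", "prr9"), ("el", "prr7"), ("el", "prr9", "prr7"),
    ]
    return [Genotype(frozenset(a)) for a in order]


def apply_knockout(
    params: ParameterSet,
    genotype: Genotype,
    variant: ModelVariant | str,
    mode: KnockoutMode = KnockoutMode.BASAL_AND_LIGHT,
) -> ParameterSet:
    """Return a copy of ``params`` with the genotype's constants zeroed.

    Pure transformation: the input set is never modified.  Raises
    InexpressibleGenotypeError for a lone prr9 or prr7 on the BASE variant.
    """
    if isinstance(variant, str):
        variant = get_variant(variant)
    if not genotype.expressible_in(variant):
        raise InexpressibleGenotypeError(
            f"{genotype.label} is not expressible in {variant.name}: "
            "the merged P97 component cannot carry a single prr null"
        )
    updates: dict[str, float] = {}
    zero_light = mode is KnockoutMode.BASAL_AND_LIGHT

    if "el" in genotype.alleles:
        updates["v4"] = 0.0
    if variant.split:
        if "prr9" in genotype.alleles:
            updates["v2A_p9"] = 0.0
            if zero_light:
                updates["v2L_p9"] = 0.0
        if "prr7" in genotype.alleles:
            updates["v2A_p7"] = 0.0
            if zero_light:
                updates["v2L_p7"] = 0.0
    else:
        if {"prr9", "prr7"} <= genotype.alleles:
            updates["v2A"] = 0.0
            if zero_light:
                updates["v2L"] = 0.0
    if not updates:
        return params
    return params.replace(**updates)
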