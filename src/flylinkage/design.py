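"""Autosome-substitution genetic design for the house fly linkage panel.

The house fly (*Musca domestica*) carries five autosomes. The resistant
parental strain (ALHF) contributes wild-type "R" autosomes; the susceptible
marker strain (aabys) contributes "S" autosomes, each tagged by a recessive
morphological marker. A substitution line named ``A<digits>`` retains the
listed autosomes from ALHF and carries the single remaining autosome from
aabys — e.g. A1234 is ALHF everywhere except autosome 5.

Substitution lines are modeled as homozygous for the retained R autosomes;
heterozygosity is outside the design's resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AUTOSOMES: tuple[int, ...] = (1, 2, 3, 4, 5)

#: Canonical panel order: both parents followed by the five single-substitution
#: lines in order of the substituted autosome (A2345 lacks 1, ... A1234 lacks 5).
LINE_NAMES: tuple[str, ...] = ("ALHF", "aabys", "A2345", "A1345", "A1245", "A1235", "A1234")
SUBSTITUTION_LINE_NAMES: tuple[str, ...] = LINE_NAMES[2:]


class LineNameError(ValueError):
    """Raised for a line name that does not describe a valid panel genotype."""


@dataclass(frozen=True)
class Genotype:
    """Per-autosome allele state: 'R' (from ALHF) or 'S' (from aabys)."""

    alleles: dict[int, str]

    def __post_init__(self) -> None:
        if set(self.alleles) != set(AUTOSOMES):
            raise ValueError(f"genotype must cover autosomes {AUTOSOMES}, got {sorted(self.alleles)}")
        bad = {a: s for a, s in self.alleles.items() if s not in ("R", "S")}
        if bad:
            raise ValueError(f"alleles must be 'R' or 'S', got {bad}")

    def __getitem__(self, autosome: int) -> str:
        return self.alleles[autosome]

    @property
    def r_autosomes(self) -> frozenset[int]:
        return frozenset(a for a in AUTOSOMES if self.alleles[a] == "R")

    @property
    def s_autosomes(self) -> frozenset[int]:
        return frozenset(a for a in AUTOSOMES if self.alleles[a] == "S")


@dataclass(frozen=True)
class LineDesign:
    name: str
    genotype: Genotype = field(repr=False)

    @property
    def substituted_autosome(self) -> int | None:
        """The single aabys autosome of a substitution line; None for parents."""
        s = self.genotype.s_autosomes
        return next(iter(s)) if len(s) == 1 else None


def parse_line_name(name: str) -> Genotype:
    """Translate a panel line name into its per-autosome genotype.

    ``ALHF`` is all-R, ``aabys`` all-S; ``A<digits>`` has R exactly at the
    listed autosomes. A BC1 substitution line must substitute exactly one
    autosome, so the digit run must be a strictly increasing subset of 1-5
    of length four (names like ``A12345`` or ``A135`` are rejected).
    """
    if name == "ALHF":
        return Genotype({a: "R" for a in AUTOSOMES})
    if name == "aabys":
        return Genotype({a: "S" for a in AUTOSOMES})
    if not name.startswith("A") or len(name) < 2:
        raise LineNameError(f"unrecognized line name {name!r}")
    digits = name[1:]
    if not digits.isdigit():
        raise LineNameError(f"line name {name!r} must be 'A' followed by autosome digits")
    idx = [int(c) for c in digits]
    if any(a not in AUTOSOMES for a in idx):
        raise LineNameError(f"line name {name!r} lists autosomes outside 1-5")
    if len(set(idx)) != len(idx) or idx != sorted(idx):
        raise LineNameError(f"line name {name!r} must list distinct increasing autosomes")
    if len(idx) != 4:
        raise LineNameError(
            f"line name {name!r} substitutes {5 - len(idx)} autosomes; a BC1 line substitutes exactly one"
        )
    return Genotype({a: ("R" if a in idx else "S") for a in AUTOSOMES})


def substituted_autosome(line_name: str) -> int:
    """The autosome replaced by aabys in a substitution line (A2345 → 1, ... A1234 → 5)."""
    geno = parse_line_name(line_name)
    s = geno.s_autosomes
    if len(s) != 1:
        raise LineNameError(f"{line_name!r} is not a single-substitution line")
    return next(iter(s))


def build_line_designs() -> list[LineDesign]:
    """The seven canonical panel members: ALHF, aabys and the five substitution lines."""
    return [LineDesign(name, parse_line_name(name)) for name in LINE_NAMES]
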