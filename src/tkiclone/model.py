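"""Core data model: variant calls, subline samples, and replicate trios.

Coordinate conventions (applied once, at read time, never re-converted):
VCF positions are 1-based inclusive; BED exon intervals are 0-based
half-open. ``VariantCall.pos`` is always the 1-based VCF position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InputError

#: Variant identity used throughout the pipeline: (chrom, pos, ref, alt, gene).
VariantKey = tuple[str, int, str, str, str]

CONSEQUENCES = ("missense", "stop_gain", "frameshift", "synonymous", "intronic", "other")

DRUGS = ("imatinib", "nilotinib")
DRUG_SHORT = {"imatinib": "IM", "nilotinib": "N"}
LEVELS = ("sensitive", "low", "high")


@dataclass(frozen=True)
class VariantCall:
    """One called variant in one sample."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    depth: int
    alt_depth: int
    consequence: str = "other"
    distance_to_exon: int = 0  # 0 if exonic

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputError(f"position must be >= 1, got {self.pos}")
        if not 0 <= self.alt_depth <= self.depth:
            raise InputError(
                f"alt depth {self.alt_depth} outside [0, depth={self.depth}] "
                f"at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt, self.gene)

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref in "ACGT"
            and self.alt in "ACGT"
        )

    @property
    def vaf(self) -> float | None:
        """Alternate allele fraction; None when depth is zero (undefined)."""
        if self.depth == 0:
            return None
        return self.alt_depth / self.depth


@dataclass
class SublineSample:
    """All variant calls of one subline (one VCF sample)."""

    drug: str  # imatinib | nilotinib | none
    level: str  # sensitive | low | high
    replicate: int
    calls: list[VariantCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise InputError(f"unknown level {self.level!r}")
        if (self.drug == "none") != (self.level == "sensitive"):
            raise InputError("drug='none' if and only if level='sensitive'")
        if self.drug not in DRUGS and self.drug != "none":
            raise InputError(f"unknown drug {self.drug!r}")

    @property
    def label(self) -> str:
        return subline_label(self.drug, self.level, self.replicate)

    def by_key(self) -> dict[VariantKey, VariantCall]:
        return {c.key: c for c in self.calls}


@dataclass
class SublineTrio:
    """Sensitive parent plus the low/high resistant derivatives of one replicate."""

    drug: str
    replicate: int
    sensitive: SublineSample
    low: SublineSample
    high: SublineSample

    def __post_init__(self) -> None:
        for stage, sample in (("sensitive", self.sensitive), ("low", self.low), ("high", self.high)):
            if sample.level != stage:
                raise InputError(f"sample in slot {stage!r} has level {sample.level!r}")
        for sample in (self.low, self.high):
            if sample.drug != self.drug or sample.replicate != self.replicate:
                raise InputError("resistant samples must match the trio's drug/replicate")

    @property
    def trio_id(self) -> str:
        return f"{DRUG_SHORT[self.drug]}-R{self.replicate}"

    def subline(self, level: str) -> str:
        """Label of the low or high resistant subline, e.g. ``highIM-R2``."""
        return subline_label(self.drug, level, self.replicate)


def subline_label(drug: str, level: str, replicate: int) -> str:
    """Fixed naming convention: low/high + IM/N + replicate, e.g. ``lowN-R2``."""
    if level == "sensitive":
        return "sensitive"
    return f"{level}{DRUG_SHORT[drug]}-R{replicate}"


def parse_subline_label(label: str) -> tuple[str, str, int]:
    """Invert :func:`subline_label` → (drug, level, replicate)."""
    if label == "sensitive":
        return ("none", "sensitive", 0)
    for level in ("low", "high"):
        if label.startswith(level):
            rest = label[len(level):]
            for drug, short in DRUG_SHORT.items():
                prefix = f"{short}-R"
                if rest.startswith(prefix):
                    return (drug, level, int(rest[len(prefix):]))
    raise InputError(f"unparseable subline label {label!r}")
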