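"""VAF filter cascade and clonal trajectory classification.

Each variant observed anywhere in a sensitive/low/high trio is tracked across
the three stages. The cascade removes, in order: (1) variants under-covered
in every sample where they are called, (2) variants already present in the
TKI-sensitive parent (VAF >= 0.05), (3) deep-intronic variants, and
(4) variants whose VAF gain over the parent never exceeds 15% in either
resistant stage. Survivors are classified by trajectory shape: acquired in
the high-dose subline, present only in the low-dose subline, shared with
reduced VAF at high dose, or shared at constant VAF.

A stage in which a variant was never called is ABSENT (encoded as None) and
contributes VAF 0 to the deltas: zero alternate reads, not missing data.

All threshold comparisons are strict in the direction of the ">" rules, so a
variant sitting exactly on a threshold fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .errors import ConfigurationError, InputError
from .model import SublineTrio, VariantCall, VariantKey

PASS = "PASS"
FAIL_DEPTH = "FAIL_depth"
FAIL_SENSITIVE = "FAIL_sensitive"
FAIL_INTRONIC = "FAIL_intronic"
FAIL_DELTA = "FAIL_delta"

ACQUIRED_HIGH = "ACQUIRED_HIGH"
SHARED_REDUCED_HIGH = "SHARED_REDUCED_HIGH"
SHARED_CONSTANT = "SHARED_CONSTANT"
LOW_ONLY = "LOW_ONLY"
NONE_CLASS = "NONE"

CLONAL_CLASSES = (ACQUIRED_HIGH, SHARED_REDUCED_HIGH, SHARED_CONSTANT, LOW_ONLY)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filter cascade.

    min_depth: minimum read depth a variant must reach in at least one sample
        where it is called (default 10). With ``coverage_mode='fraction_of_mean'``
        the threshold is instead ``min_depth_fraction`` of the sample's mean
        depth — an alternative reading of a per-variant coverage cut.
    sensitive_vaf_max: variants at or above this VAF in the sensitive parent
        are treated as pre-existing and removed (default 0.05).
    delta_vaf_min: minimum VAF gain over the parent required in at least one
        resistant stage (default 0.15, strict).
    deep_intronic_distance: intronic variants farther than this many bases
        from any exon boundary are removed (default 20).
    """

    min_depth: int = 10
    sensitive_vaf_max: float = 0.05
    delta_vaf_min: float = 0.15
    deep_intronic_distance: int = 20
    coverage_mode: str = "depth"  # "depth" | "fraction_of_mean"
    min_depth_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.min_depth < 0 or self.deep_intronic_distance < 0:
            raise ConfigurationError("thresholds must be non-negative")
        if not 0 <= self.sensitive_vaf_max < 1:
            raise ConfigurationError("sensitive_vaf_max must be in [0, 1)")
        if not 0 <= self.delta_vaf_min <= 1:
            raise ConfigurationError("delta_vaf_min must be in [0, 1]")
        if self.coverage_mode not in ("depth", "fraction_of_mean"):
            raise ConfigurationError(f"unknown coverage_mode {self.coverage_mode!r}")


@dataclass
class VariantTrajectory:
    """One variant's VAF across the trio plus its filter verdict and clonal class."""

    key: VariantKey
    vaf_sensitive: float | None  # None = ABSENT
    vaf_low: float | None
    vaf_high: float | None
    delta_low: float
    delta_high: float
    verdict: str
    clonal_class: str = NONE_CLASS
    consequence: str = "other"
    distance_to_exon: int = 0

    @property
    def gene(self) -> str:
        return self.key[4]

    @property
    def passed(self) -> bool:
        return self.verdict == PASS


def compute_vaf(call: VariantCall) -> float:
    """Variant allele frequency alt/depth at full precision."""
    if call.depth <= 0:
        raise InputError(f"VAF undefined at zero depth ({call.chrom}:{call.pos})")
    return call.alt_depth / call.depth


def format_vaf_percent(vaf: float, decimals: int = 1) -> str:
    """Render a VAF as a percentage with half-up rounding (reporting only).

    0.3333 → "33.3%"; 0.6929 → "69%" at integer rendering.
    """
    quantum = Decimal(1).scaleb(-decimals) if decimals > 0 else Decimal(1)
    pct = (Decimal(str(vaf)) * 100).quantize(quantum, rounding=ROUND_HALF_UP)
    return f"{pct}%"


def classify_vafs(
    vaf_sensitive: float | None,
    vaf_low: float | None,
    vaf_high: float | None,
    cfg: FilterConfig,
) -> str:
    """Clonal class implied by three stage VAFs that already passed the cascade.

    This is the definition of the trajectory classes; the synthetic generator
    applies it to true VAFs to record ground truth.
    """
    vs = vaf_sensitive or 0.0
    vl = vaf_low or 0.0
    vh = vaf_high or 0.0
    t = cfg.delta_vaf_min
    delta_low, delta_high = vl - vs, vh - vs
    if delta_high > t and delta_low <= t:
        return ACQUIRED_HIGH
    if delta_low > t and delta_high <= t:
        return LOW_ONLY
    if delta_low > t and delta_high > t:
        return SHARED_REDUCED_HIGH if (vl - vh) > t else SHARED_CONSTANT
    return NONE_CLASS


def filter_and_classify(trio: SublineTrio, cfg: FilterConfig | None = None) -> list[VariantTrajectory]:
    """Run the filter cascade over the union of variants of a trio.

    Returns one trajectory per distinct variant key, in deterministic
    (chrom, pos, ref, alt, gene) order.
    """
    cfg = cfg or FilterConfig()
    samples = {"sensitive": trio.sensitive, "low": trio.low, "high": trio.high}
    by_key = {stage: s.by_key() for stage, s in samples.items()}
    mean_depth = {
        stage: (sum(c.depth for c in s.calls) / len(s.calls) if s.calls else 0.0)
        for stage, s in samples.items()
    }

    keys: set[VariantKey] = set()
    for stage_map in by_key.values():
        keys.update(stage_map)

    trajectories: list[VariantTrajectory] = []
    for key in sorted(keys):
        calls = {stage: by_key[stage].get(key) for stage in samples}
        present = [(stage, c) for stage, c in calls.items() if c is not None]
        vafs = {stage: (c.vaf if c is not None else None) for stage, c in calls.items()}

        vs = vafs["sensitive"] or 0.0  # ABSENT and zero-depth → 0
        vl = vafs["low"] or 0.0
        vh = vafs["high"] or 0.0
        delta_low, delta_high = vl - vs, vh - vs
        first_call = present[0][1]

        if cfg.coverage_mode == "depth":
            covered = any(c.depth >= cfg.min_depth for _, c in present)
        else:
            covered = any(
                c.depth >= cfg.min_depth_fraction * mean_depth[stage] for stage, c in present
            )

        if not covered:
            verdict = FAIL_DEPTH
        elif vs >= cfg.sensitive_vaf_max:
            verdict = FAIL_SENSITIVE
        elif (
            first_call.consequence == "intronic"
            and first_call.distance_to_exon > cfg.deep_intronic_distance
        ):
            verdict = FAIL_INTRONIC
        elif max(delta_low, delta_high) <= cfg.delta_vaf_min:
            verdict = FAIL_DELTA
        else:
            verdict = PASS

        clonal_class = NONE_CLASS
        if verdict == PASS:
            clonal_class = classify_vafs(vafs["sensitive"], vafs["low"], vafs["high"], cfg)

        trajectories.append(
            VariantTrajectory(
                key=key,
                vaf_sensitive=vafs["sensitive"],
                vaf_low=vafs["low"],
                vaf_high=vafs["high"],
                delta_low=delta_low,
                delta_high=delta_high,
                verdict=verdict,
                clonal_class=clonal_class,
                consequence=first_call.consequence,
                distance_to_exon=first_call.distance_to_exon,
            )
        )
    return trajectories


def subline_pass_keys(
    trajectories: list[VariantTrajectory], level: str, cfg: FilterConfig | None = None
) -> set[VariantKey]:
    """Keys of PASS variants whose VAF gain in the given stage exceeds the threshold."""
    cfg = cfg or FilterConfig()
    delta = {"low": lambda t: t.delta_low, "high": lambda t: t.delta_high}[level]
    return {t.key for t in trajectories if t.passed and delta(t) > cfg.delta_vaf_min}


def burden_table(
    trajectories_by_trio: dict[str, list[VariantTrajectory]],
    cfg: FilterConfig | None = None,
) -> pd.DataFrame:
    """Per-resistant-subline mutation burden.

    ``n_pass`` counts PASS variants whose VAF gain in that subline exceeds the
    threshold (per-stage occurrences); ``n_pass_unique_trio`` is the trio-level
    distinct PASS count (both totals are reported because either convention
    can be meant by a per-subline total). Class columns break n_pass down.
    """
    cfg = cfg or FilterConfig()
    rows = []
    for trio_id, trajectories in trajectories_by_trio.items():
        unique_pass = sum(1 for t in trajectories if t.passed)
        for level in ("low", "high"):
            keys = subline_pass_keys(trajectories, level, cfg)
            counted = [t for t in trajectories if t.key in keys]
            row: dict[str, object] = {
                "subline": f"{level}{trio_id}",
                "trio": trio_id,
                "level": level,
                "n_pass": len(counted),
                "n_pass_unique_trio": unique_pass,
            }
            for cls in CLONAL_CLASSES:
                row[f"n_{cls}"] = sum(1 for t in counted if t.clonal_class == cls)
            rows.append(row)
    columns = ["subline", "trio", "level", "n_pass", "n_pass_unique_trio"] + [
        f"n_{cls}" for cls in CLONAL_CLASSES
    ]
    return pd.DataFrame(rows, columns=columns)


def trajectories_to_frame(trajectories: list[VariantTrajectory]) -> pd.DataFrame:
    """Tabular form of trajectories (one row per variant) for TSV output."""
    rows = []
    for t in trajectories:
        chrom, pos, ref, alt, gene = t.key
        rows.append(
            {
                "chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "gene": gene,
                "vaf_sensitive": t.vaf_sensitive, "vaf_low": t.vaf_low, "vaf_high": t.vaf_high,
                "delta_low": t.delta_low, "delta_high": t.delta_high,
                "verdict": t.verdict, "clonal_class": t.clonal_class,
                "consequence": t.consequence, "distance_to_exon": t.distance_to_exon,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "gene", "vaf_sensitive", "vaf_low", "vaf_high",
            "delta_low", "delta_high", "verdict", "clonal_class", "consequence",
            "distance_to_exon",
        ],
    )


def trajectories_from_frame(df: pd.DataFrame) -> list[VariantTrajectory]:
    """Inverse of :func:`trajectories_to_frame` (ABSENT stages round-trip as NaN)."""
    out = []
    for row in df.itertuples(index=False):
        out.append(
            VariantTrajectory(
                key=(row.chrom, int(row.pos), row.ref, row.alt, row.gene),
                vaf_sensitive=None if pd.isna(row.vaf_sensitive) else float(row.vaf_sensitive),
                vaf_low=None if pd.isna(row.vaf_low) else float(row.vaf_low),
                vaf_high=None if pd.isna(row.vaf_high) else float(row.vaf_high),
                delta_low=float(row.delta_low),
                delta_high=float(row.delta_high),
                verdict=row.verdict,
                clonal_class=row.clonal_class,
                consequence=row.consequence,
                distance_to_exon=int(row.distance_to_exon),
            )
        )
    return out
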