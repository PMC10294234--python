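"""Synthetic inputs with known ground truth for the whole pipeline.

The generator emulates the study design this pipeline analyses: one
TKI-sensitive K-562-like parental line and twelve resistant sublines (four
imatinib replicates at low/high dose, two nilotinib replicates at low/high
dose). Each replicate trio carries planted driver variants with fixed
stage-wise true VAFs, hitchhikers co-segregating with them, acquired
background variants whose trinucleotide contexts follow a configured
signature mixture, parental decoys (present in the sensitive line, removed
by the cascade), and deep-intronic decoys (removed by the intronic rule).
Reads are sampled per stage as depth ~ max(1, Poisson(depth_mean)) and
alt ~ Binomial(depth, true VAF); a variant with zero sampled alternate reads
is simply not called in that subline's VCF, so an ABSENT stage carries
exactly zero alternate reads.

One contig per gene keeps gene assignment trivial (gene of a variant = its
contig). All randomness flows from a single integer seed through
``numpy.random.SeedSequence``; child streams are spawned in a fixed order —
reference, signature matrix, PPI graph, gene sets/catalogue, then one stream
per trio in trio-id order — so outputs are byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .filtering import FilterConfig, classify_vafs
from .io import ExonMap
from .model import DRUG_SHORT, SublineSample, SublineTrio, subline_label
from .signatures import CHANNELS_96, parse_channel

STAGES = ("sensitive", "low", "high")


@dataclass(frozen=True)
class PlantedVariant:
    """A driver planted with fixed true VAFs per stage (None = ABSENT)."""

    gene: str
    stage_vafs: tuple[float | None, float | None, float | None]
    consequence: str = "missense"
    context: str | None = None  # optional 96-channel label constraint
    clinvar_id: str | None = None

    def __post_init__(self) -> None:
        if all(v is None for v in self.stage_vafs):
            raise ConfigurationError(f"{self.gene}: at least one stage VAF must be present")
        for v in self.stage_vafs:
            if v is not None and not 0 <= v <= 1:
                raise ConfigurationError(f"{self.gene}: VAF {v} outside [0, 1]")


def default_planted_drivers() -> dict[str, list[PlantedVariant]]:
    """Driver trajectories emulating those recovered in the K-562 TKI model.

    Includes an acquired-high RAS-pathway driver per imatinib replicate, a
    two-variant (multihit) gene in IM-R1, shared low/high variants, and a
    low-only variant in N-R1.
    """
    pv = PlantedVariant
    return {
        "IM-R1": [
            pv("LRP1B", (0.0, None, 0.3881)),
            pv("LRP1B", (0.0, None, 0.304)),
            pv("IKBKB", (0.0, None, 0.5152)),
            pv("MCM3AP", (0.0, 0.25, 0.25), consequence="stop_gain"),
        ],
        "IM-R2": [
            pv("PTPN11", (0.0, None, 0.6929), clinvar_id="13328"),
            pv("PDGFRB", (0.0, None, 0.283)),
            pv("RELA", (0.0, 0.2828, 0.2923)),
            pv("TNC", (0.0, 0.2, 0.2222)),
        ],
        "IM-R3": [
            pv("KRAS", (0.0, 0.087, 0.6667), clinvar_id="12581"),
            pv("KMT2D", (0.0, 0.09, 0.371), clinvar_id="449928"),
            pv("CACNA1D", (0.0, 0.3429, 0.3429)),
        ],
        "IM-R4": [
            pv("KRAS", (0.0, None, 0.2927), clinvar_id="12582"),
            pv("BIRC6", (0.0, None, 0.2222)),
            pv("CACNA1D", (0.0, 0.4444, 0.4444)),
        ],
        "N-R1": [
            pv("ABL1", (0.0, 0.2648, None)),
            pv("MB21D2", (0.0, None, 0.5682)),
            pv("MYH9", (0.0, None, 0.381)),
        ],
        "N-R2": [
            pv("NRAS", (0.0, 0.2917, 0.3333), clinvar_id="73058"),
            pv("TRRAP", (0.0, 0.2993, 0.2685)),
            pv("PDE4DIP", (0.0, 0.3, 0.1961)),
        ],
    }


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults mirror the modelled experiment: 60x mean exome coverage, four
    imatinib and two nilotinib replicate trios, and a per-trio acquired
    burden (140 background variants plus drivers and hitchhikers) in the
    100-200 range observed per subline.
    """

    seed: int = 0
    replicates: dict[str, int] = field(
        default_factory=lambda: {"imatinib": 4, "nilotinib": 2}
    )
    depth_mean: float = 60.0
    n_genes: int = 80
    contig_length: int = 3000
    n_background_variants: int = 140
    n_parental_variants: int = 40
    n_hitchhikers_per_driver: int = 2
    planted_drivers: dict[str, list[PlantedVariant]] | None = None  # None → defaults
    signature_mix: dict[str, float] = field(
        default_factory=lambda: {"SIG1": 0.7, "SIG2": 0.3}
    )
    n_signatures: int = 4
    exon_fraction: float = 0.5
    deep_intronic_fraction: float = 0.1
    deep_intronic_distance: int = 20  # same threshold the filter uses, by design
    ppi_communities: int = 2
    ppi_p_intra: float = 0.3
    ppi_p_inter: float = 0.02
    community_bias: float = 0.9  # fraction of acquired variants drawn from the trio's home community

    def __post_init__(self) -> None:
        if self.depth_mean <= 0:
            raise ConfigurationError("depth_mean must be positive")
        for name in ("exon_fraction", "deep_intronic_fraction", "community_bias"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if abs(sum(self.signature_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("signature_mix weights must sum to 1")
        if any(w < 0 for w in self.signature_mix.values()):
            raise ConfigurationError("signature_mix weights must be non-negative")
        if not 1 <= self.ppi_communities <= self.n_genes:
            raise ConfigurationError("need n_genes >= ppi_communities >= 1")
        for drug in self.replicates:
            if drug not in DRUG_SHORT:
                raise InputError(f"unknown drug label {drug!r}")

    @property
    def drivers(self) -> dict[str, list[PlantedVariant]]:
        return self.planted_drivers if self.planted_drivers is not None else default_planted_drivers()

    @property
    def trio_ids(self) -> list[str]:
        return [
            f"{DRUG_SHORT[drug]}-R{r}"
            for drug in ("imatinib", "nilotinib")
            if drug in self.replicates
            for r in range(1, self.replicates[drug] + 1)
        ]

    def drug_of(self, trio_id: str) -> str:
        short = trio_id.split("-")[0]
        for drug, s in DRUG_SHORT.items():
            if s == short:
                return drug
        raise InputError(f"unknown trio id {trio_id!r}")


class VcfRecord(NamedTuple):
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    consequence: str
    depth: int
    alt_depth: int


@dataclass
class TruthVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    trio_id: str
    kind: str  # driver | hitchhiker | background | parental | deep_intronic
    consequence: str
    stage_vafs: tuple[float | None, float | None, float | None]
    true_class: str
    context: str | None = None
    clinvar_id: str | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class GroundTruth:
    """Everything needed for parameter-recovery tests, recoverable by variant key."""

    variants: list[TruthVariant] = field(default_factory=list)
    exposures: dict[str, dict[str, float]] = field(default_factory=dict)  # subline → mix
    communities: dict[str, int] = field(default_factory=dict)  # gene → community
    trio_home_community: dict[str, int] = field(default_factory=dict)

    def by_key(self) -> dict[tuple[str, int, str, str], TruthVariant]:
        return {v.key: v for v in self.variants}

    def to_json(self) -> str:
        payload = {
            "variants": [asdict(v) for v in self.variants],
            "exposures": self.exposures,
            "communities": self.communities,
            "trio_home_community": self.trio_home_community,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        payload = json.loads(text)
        variants = [
            TruthVariant(**{**v, "stage_vafs": tuple(v["stage_vafs"])})
            for v in payload["variants"]
        ]
        return cls(
            variants=variants,
            exposures=payload["exposures"],
            communities=payload["communities"],
            trio_home_community=payload["trio_home_community"],
        )


# ---------------------------------------------------------------------------
# reference, exons and position pools


def _gene_names(config: SimulationConfig) -> list[str]:
    driver_genes: list[str] = []
    for planted in config.drivers.values():
        for pv in planted:
            if pv.gene not in driver_genes:
                driver_genes.append(pv.gene)
    if len(driver_genes) > config.n_genes:
        raise ConfigurationError("n_genes smaller than the number of planted driver genes")
    fillers = [f"GENE{i:03d}" for i in range(1, config.n_genes - len(driver_genes) + 1)]
    return driver_genes + fillers


def simulate_reference(
    config: SimulationConfig,
) -> tuple[list[str], dict[str, str], ExonMap]:
    """One random contig per gene plus tiled exon intervals.

    Exons are 100 bp blocks separated by introns sized so that approximately
    ``exon_fraction`` of each contig is exonic; intervals are 0-based
    half-open and lie within contig bounds.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[0])
    genes = _gene_names(config)
    L = config.contig_length
    exon_len = 100
    if config.exon_fraction <= 0:
        raise ConfigurationError("exon_fraction must be positive to place variants")
    intron_len = int(round(exon_len * (1 - config.exon_fraction) / config.exon_fraction))
    reference: dict[str, str] = {}
    exons: ExonMap = {}
    bases = np.array(list("ACGT"))
    for gene in genes:
        reference[gene] = "".join(rng.choice(bases, size=L))
        intervals = []
        pos = intron_len // 2
        while pos + exon_len <= L:
            intervals.append((pos, pos + exon_len))
            pos += exon_len + intron_len
            if intron_len == 0 and pos >= L:
                break
        exons[gene] = intervals
    return genes, reference, exons


@dataclass
class _ContigPools:
    exonic: np.ndarray  # 1-based exonic positions with both flanks
    by_triplet: dict[str, np.ndarray]  # pyrimidine-centred triplet → exonic positions
    deep_intronic: np.ndarray  # 1-based, farther than the distance threshold


def _build_pools(seq: str, intervals: list[tuple[int, int]], deep_distance: int) -> _ContigPools:
    L = len(seq)
    exon_mask = np.zeros(L, dtype=bool)
    near_mask = np.zeros(L, dtype=bool)
    for start, end in intervals:
        exon_mask[start:end] = True
        near_mask[max(0, start - deep_distance) : min(L, end + deep_distance)] = True
    valid = np.zeros(L, dtype=bool)
    valid[1 : L - 1] = True  # need both flanking bases
    exonic0 = np.flatnonzero(exon_mask & valid)
    deep0 = np.flatnonzero(~near_mask & valid)
    by_triplet: dict[str, list[int]] = {}
    for i in exonic0:
        if seq[i] in "CT":
            by_triplet.setdefault(seq[i - 1 : i + 2], []).append(i + 1)
    return _ContigPools(
        exonic=exonic0 + 1,
        by_triplet={t: np.asarray(p) for t, p in by_triplet.items()},
        deep_intronic=deep0 + 1,
    )


def _draw_unused(pool: np.ndarray, used: set[int], rng: np.random.Generator) -> int | None:
    if len(pool) == 0:
        return None
    for _ in range(200):
        pos = int(pool[rng.integers(len(pool))])
        if pos not in used:
            used.add(pos)
            return pos
    for pos in pool[rng.permutation(len(pool))]:
        if int(pos) not in used:
            used.add(int(pos))
            return int(pos)
    return None


# ---------------------------------------------------------------------------
# signatures, graph, gene sets


def simulate_signature_matrix(config: SimulationConfig) -> pd.DataFrame:
    """Synthetic spiky signature matrix (96 x n_signatures, columns sum to 1).

    Columns are Dirichlet draws with small concentration, giving distinct
    near-sparse spectra that an NNLS fit can separate. Column names SIG1..SIGk.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[1])
    k = max(config.n_signatures, len(config.signature_mix))
    cols = {}
    for j in range(1, k + 1):
        cols[f"SIG{j}"] = rng.dirichlet(np.full(96, 0.08))
    df = pd.DataFrame(cols, index=pd.Index(list(CHANNELS_96), name="Type"))
    missing = set(config.signature_mix) - set(df.columns)
    if missing:
        raise ConfigurationError(f"signature_mix refers to unknown signatures {sorted(missing)}")
    return df


def mixture_spectrum(signature_matrix: pd.DataFrame, mix: Mapping[str, float]) -> pd.Series:
    """Channel distribution implied by a signature mixture."""
    p = np.zeros(96)
    for sig, w in mix.items():
        p += w * signature_matrix[sig].to_numpy()
    return pd.Series(p / p.sum(), index=signature_matrix.index)


def sample_contexts(
    n: int,
    signature_matrix: pd.DataFrame,
    mix: Mapping[str, float],
    rng: np.random.Generator,
) -> list[str]:
    """Draw n channel labels from the signature-mixture distribution."""
    p = mixture_spectrum(signature_matrix, mix).to_numpy()
    counts = rng.multinomial(n, p)
    labels: list[str] = []
    for channel, count in zip(CHANNELS_96, counts):
        labels.extend([channel] * int(count))
    order = rng.permutation(len(labels))
    return [labels[i] for i in order]


def assign_communities(genes: list[str], k: int) -> dict[str, int]:
    """Deterministic round-robin community labels (planted partition)."""
    return {gene: i % k for i, gene in enumerate(genes)}


def simulate_ppi(
    config: SimulationConfig, genes: list[str], communities: dict[str, int]
) -> nx.Graph:
    """Planted-partition PPI graph: dense intra-community, sparse inter-community."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[2])
    n = len(genes)
    labels = np.array([communities[g] for g in genes])
    same = labels[:, None] == labels[None, :]
    p = np.where(same, config.ppi_p_intra, config.ppi_p_inter)
    draw = rng.random((n, n))
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    iu, ju = np.triu_indices(n, k=1)
    for i, j in zip(iu[draw[iu, ju] < p[iu, ju]], ju[draw[iu, ju] < p[iu, ju]]):
        graph.add_edge(genes[i], genes[j])
    return graph


def simulate_genesets(
    config: SimulationConfig, genes: list[str], communities: dict[str, int]
) -> dict[str, set[str]]:
    """One gene set per planted community plus a few random sets."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[3])
    sets: dict[str, set[str]] = {}
    for c in range(config.ppi_communities):
        sets[f"COMMUNITY_{c + 1}"] = {g for g in genes if communities[g] == c}
    for i in range(1, 4):
        size = min(15, len(genes))
        sets[f"RANDSET_{i}"] = set(rng.choice(genes, size=size, replace=False))
    return sets


# ---------------------------------------------------------------------------
# trios


@dataclass
class _PlanItem:
    gene: str
    pos: int
    ref: str
    alt: str
    consequence: str
    stage_vafs: tuple[float | None, float | None, float | None]
    kind: str
    context: str | None = None
    clinvar_id: str | None = None


def _jitter_vafs(
    vafs: tuple[float | None, float | None, float | None], rng: np.random.Generator
) -> tuple[float | None, float | None, float | None]:
    out = []
    for v in vafs:
        if v is None:
            out.append(None)
        else:
            out.append(float(np.clip(v + rng.uniform(-0.05, 0.05), 0.0, 1.0)))
    return tuple(out)


def _background_trajectory(rng: np.random.Generator) -> tuple[float | None, float | None, float | None]:
    """Acquired trajectory with clear margin to the 0.05/0.15 thresholds."""
    shape = rng.choice(["acquired_high", "shared_constant", "low_only"], p=[0.4, 0.4, 0.2])
    v = float(rng.uniform(0.25, 0.5))
    minor = None if rng.random() < 0.6 else float(rng.uniform(0.0, 0.08))
    if shape == "acquired_high":
        return (0.0, minor, v)
    if shape == "low_only":
        return (0.0, v, minor)
    v2 = float(np.clip(v + rng.uniform(-0.05, 0.05), 0.25, 0.6))
    return (0.0, v, v2)


def simulate_subline_trio(
    config: SimulationConfig,
    trio_id: str,
    genes: list[str],
    reference: dict[str, str],
    exons: ExonMap,
    communities: dict[str, int],
    signature_matrix: pd.DataFrame,
    rng: np.random.Generator,
    pools: dict[str, _ContigPools],
    used: dict[str, set[int]],
) -> tuple[dict[str, list[VcfRecord]], list[TruthVariant]]:
    """Generate the three per-stage VCF record lists of one replicate trio."""
    # home community of this replicate: replicate parity (the planted design)
    home = (int(trio_id.split("-R")[1]) - 1) % config.ppi_communities
    home_genes = [g for g in genes if communities[g] == home]
    other_genes = [g for g in genes if communities[g] != home] or home_genes

    def pick_gene() -> str:
        source = home_genes if rng.random() < config.community_bias else other_genes
        return source[rng.integers(len(source))]

    plan: list[_PlanItem] = []

    def place_exonic(gene: str, consequence: str, vafs, kind: str,
                     context: str | None = None, clinvar_id: str | None = None) -> bool:
        pool = pools[gene]
        if context is not None:
            triplet, alt = parse_channel(context)
            candidates = pool.by_triplet.get(triplet)
            if candidates is None:
                return False
            pos = _draw_unused(candidates, used[gene], rng)
            if pos is None:
                return False
            ref = reference[gene][pos - 1]
        else:
            pos = _draw_unused(pool.exonic, used[gene], rng)
            if pos is None:
                return False
            ref = reference[gene][pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        plan.append(_PlanItem(gene, pos, ref, alt, consequence, tuple(vafs), kind,
                              context=context, clinvar_id=clinvar_id))
        return True

    # planted drivers, in configured order, then their hitchhikers
    for pv in config.drivers.get(trio_id, []):
        ok = place_exonic(pv.gene, pv.consequence, pv.stage_vafs, "driver",
                          context=pv.context, clinvar_id=pv.clinvar_id)
        if not ok:
            raise ConfigurationError(f"could not place driver {pv.gene} in {trio_id}")
        for _ in range(config.n_hitchhikers_per_driver):
            context = sample_contexts(1, signature_matrix, config.signature_mix, rng)[0]
            for _attempt in range(20):
                if place_exonic(pick_gene(), "missense", _jitter_vafs(pv.stage_vafs, rng),
                                "hitchhiker", context=context):
                    break

    # acquired background variants with signature-mixture contexts
    contexts = sample_contexts(
        config.n_background_variants, signature_matrix, config.signature_mix, rng
    )
    for context in contexts:
        for _attempt in range(50):
            if place_exonic(pick_gene(), "missense", _background_trajectory(rng),
                            "background", context=context):
                break
        else:
            raise ConfigurationError(
                "context position pool exhausted; increase contig_length or n_genes"
            )

    # parental decoys: present in the sensitive line, removed by the cascade
    for _ in range(config.n_parental_variants):
        v = float(rng.uniform(0.3, 0.6))
        for _attempt in range(20):
            gene = genes[rng.integers(len(genes))]
            if place_exonic(gene, "missense", (v, v, v), "parental"):
                break

    # deep-intronic decoys: acquired but beyond the intronic distance threshold
    n_deep = int(round(config.deep_intronic_fraction * config.n_background_variants))
    for _ in range(n_deep):
        gene = pick_gene()
        pos = _draw_unused(pools[gene].deep_intronic, used[gene], rng)
        if pos is None:
            continue
        ref = reference[gene][pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        plan.append(_PlanItem(gene, pos, ref, alt, "intronic",
                              _background_trajectory(rng), "deep_intronic"))

    # sample reads per stage and emit records
    chrom_rank = {g: i for i, g in enumerate(genes)}
    records: dict[str, list[VcfRecord]] = {stage: [] for stage in STAGES}
    cfg_default = FilterConfig()
    truth: list[TruthVariant] = []
    for item in plan:
        for stage_index, stage in enumerate(STAGES):
            vaf = item.stage_vafs[stage_index]
            if vaf is None:
                continue  # ABSENT: zero alternate reads, no call
            depth = max(1, int(rng.poisson(config.depth_mean)))
            alt_depth = int(rng.binomial(depth, vaf))
            if alt_depth == 0:
                continue
            records[stage].append(
                VcfRecord(item.gene, item.pos, item.ref, item.alt, item.gene,
                          item.consequence, depth, alt_depth)
            )
        truth.append(
            TruthVariant(
                chrom=item.gene, pos=item.pos, ref=item.ref, alt=item.alt, gene=item.gene,
                trio_id=trio_id, kind=item.kind, consequence=item.consequence,
                stage_vafs=item.stage_vafs,
                true_class=classify_vafs(*item.stage_vafs, cfg_default),
                context=item.context, clinvar_id=item.clinvar_id,
            )
        )
    for stage in STAGES:
        records[stage].sort(key=lambda r: (chrom_rank[r.chrom], r.pos, r.alt))
    return records, truth


# ---------------------------------------------------------------------------
# full dataset


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genes: list[str]
    reference: dict[str, str]
    exons: ExonMap
    communities: dict[str, int]
    graph: nx.Graph
    signature_matrix: pd.DataFrame
    genesets: dict[str, set[str]]
    catalogue: set[str]
    clinvar: dict[tuple[str, int, str, str], dict[str, str]]
    trios: dict[str, dict[str, list[VcfRecord]]]
    truth: GroundTruth

    def trio_samples(self, trio_id: str) -> SublineTrio:
        """In-memory SublineTrio equivalent of the written VCFs."""
        drug = self.config.drug_of(trio_id)
        replicate = int(trio_id.split("-R")[1])
        samples = {}
        for stage in STAGES:
            calls = []
            for r in self.trios[trio_id][stage]:
                calls.append(
                    _record_to_call(r, self.exons)
                )
            samples[stage] = SublineSample(
                drug="none" if stage == "sensitive" else drug,
                level=stage,
                replicate=0 if stage == "sensitive" else replicate,
                calls=calls,
            )
        return SublineTrio(
            drug=drug, replicate=replicate,
            sensitive=samples["sensitive"], low=samples["low"], high=samples["high"],
        )


def _record_to_call(record: VcfRecord, exons: ExonMap):
    from .io import distance_to_exon
    from .model import VariantCall

    return VariantCall(
        chrom=record.chrom, pos=record.pos, ref=record.ref, alt=record.alt,
        gene=record.gene, depth=record.depth, alt_depth=record.alt_depth,
        consequence=record.consequence,
        distance_to_exon=distance_to_exon(record.chrom, record.pos, exons),
    )


def simulate_all(config: SimulationConfig) -> SimulatedDataset:
    """Generate every pipeline input with ground truth."""
    genes, reference, exons = simulate_reference(config)
    communities = assign_communities(genes, config.ppi_communities)
    graph = simulate_ppi(config, genes, communities)
    signature_matrix = simulate_signature_matrix(config)
    genesets = simulate_genesets(config, genes, communities)

    trio_ids = config.trio_ids
    children = np.random.SeedSequence(config.seed).spawn(5 + len(trio_ids))
    pools = {
        g: _build_pools(reference[g], exons[g], config.deep_intronic_distance) for g in genes
    }

    truth = GroundTruth(communities=dict(communities))
    trios: dict[str, dict[str, list[VcfRecord]]] = {}
    clinvar: dict[tuple[str, int, str, str], dict[str, str]] = {}
    for i, trio_id in enumerate(trio_ids):
        rng = np.random.default_rng(children[5 + i])
        used: dict[str, set[int]] = {g: set() for g in genes}
        records, trio_truth = simulate_subline_trio(
            config, trio_id, genes, reference, exons, communities,
            signature_matrix, rng, pools, used,
        )
        trios[trio_id] = records
        truth.variants.extend(trio_truth)
        truth.trio_home_community[trio_id] = (int(trio_id.split("-R")[1]) - 1) % config.ppi_communities
        drug = config.drug_of(trio_id)
        replicate = int(trio_id.split("-R")[1])
        for level in ("low", "high"):
            truth.exposures[subline_label(drug, level, replicate)] = dict(config.signature_mix)
        for tv in trio_truth:
            if tv.clinvar_id:
                clinvar[tv.key] = {"clinvar_id": tv.clinvar_id, "significance": "Pathogenic"}

    driver_genes = sorted({pv.gene for planted in config.drivers.values() for pv in planted})
    rng_cat = np.random.default_rng(children[3])
    fillers = [g for g in genes if g not in driver_genes]
    extra = list(rng_cat.choice(fillers, size=min(20, len(fillers)), replace=False))
    catalogue = set(driver_genes) | set(extra)

    return SimulatedDataset(
        config=config, genes=genes, reference=reference, exons=exons,
        communities=communities, graph=graph, signature_matrix=signature_matrix,
        genesets=genesets, catalogue=catalogue, clinvar=clinvar, trios=trios, truth=truth,
    )


# ---------------------------------------------------------------------------
# writers (plain-text external interfaces)


def write_fasta(reference: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bed(exons: ExonMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in exons:
            for start, end in exons[chrom]:
                fh.write(f"{chrom}\t{start}\t{end}\n")


def write_vcf(
    records: Iterable[VcfRecord],
    path: str | Path,
    sample: str,
    contig_lengths: Mapping[str, int],
) -> None:
    """Minimal single-sample VCF v4.2 with FORMAT DP and AD (ref,alt)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for r in records:
            info = f"GENE={r.gene};CSQ={r.consequence}"
            ad = f"{r.depth - r.alt_depth},{r.alt_depth}"
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}\t"
                f"GT:DP:AD\t0/1:{r.depth}:{ad}\n"
            )


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{b}\n")


def write_gmt(genesets: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in genesets:
            members = "\t".join(sorted(genesets[name]))
            fh.write(f"{name}\tsynthetic\t{members}\n")


def write_catalogue(catalogue: set[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\trole\n")
        for gene in sorted(catalogue):
            fh.write(f"{gene}\tdriver\n")


def write_clinvar(
    clinvar: Mapping[tuple[str, int, str, str], Mapping[str, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tclinvar_id\tsignificance\n")
        for (chrom, pos, ref, alt), ann in sorted(clinvar.items()):
            fh.write(
                f"{chrom}\t{pos}\t{ref}\t{alt}\t{ann['clinvar_id']}\t{ann['significance']}\n"
            )


def write_signature_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="Type")


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict:
    """Write every input file plus truth.json and a manifest for the CLI."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "vcf").mkdir(exist_ok=True)
    contig_lengths = {g: len(dataset.reference[g]) for g in dataset.genes}

    write_fasta(dataset.reference, outdir / "reference.fa")
    write_bed(dataset.exons, outdir / "exons.bed")
    write_edge_list(dataset.graph, outdir / "ppi_edges.tsv")
    write_gmt(dataset.genesets, outdir / "genesets.gmt")
    write_catalogue(dataset.catalogue, outdir / "driver_catalogue.tsv")
    write_clinvar(dataset.clinvar, outdir / "clinvar_lookup.tsv")
    write_signature_matrix(dataset.signature_matrix, outdir / "signatures.tsv")
    (outdir / "truth.json").write_text(dataset.truth.to_json())

    manifest: dict = {
        "reference": str(outdir / "reference.fa"),
        "exons": str(outdir / "exons.bed"),
        "graph": str(outdir / "ppi_edges.tsv"),
        "genesets": str(outdir / "genesets.gmt"),
        "catalogue": str(outdir / "driver_catalogue.tsv"),
        "clinvar": str(outdir / "clinvar_lookup.tsv"),
        "signatures": str(outdir / "signatures.tsv"),
        "truth": str(outdir / "truth.json"),
        "trios": {},
    }
    for trio_id, stage_records in dataset.trios.items():
        drug = dataset.config.drug_of(trio_id)
        replicate = int(trio_id.split("-R")[1])
        entry = {"drug": drug, "replicate": replicate}
        for stage in STAGES:
            label = subline_label(drug, stage, replicate) if stage != "sensitive" else f"sensitive-{trio_id}"
            vcf_path = outdir / "vcf" / f"{label}.vcf"
            write_vcf(stage_records[stage], vcf_path, label, contig_lengths)
            entry[stage] = str(vcf_path)
        manifest["trios"][trio_id] = entry
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
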