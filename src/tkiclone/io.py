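"""Readers that normalise all external inputs into the pipeline data model.

Formats: VCF v4.2 (pysam; per-sample DP and AD required), BED exon intervals
(0-based half-open), FASTA (pyfaidx), COSMIC-layout signature TSV, edge-list
TSV, GMT gene sets, driver-catalogue TSV, ClinVar-style lookup TSV.

VAF is always recomputed as AD/DP — an AF tag, if present, is ignored — so
synthetic and real inputs agree by construction.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd
import pysam
from pyfaidx import Fasta

from .errors import FormatError, InputError
from .model import SublineSample, VariantCall
from .signatures import CHANNELS_96

logger = logging.getLogger(__name__)

#: Distance assigned when a contig carries no exon at all.
NO_EXON_DISTANCE = 10**9

ExonMap = dict[str, list[tuple[int, int]]]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (small) reference FASTA into a chrom → sequence dict."""
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def read_bed(path: str | Path) -> ExonMap:
    """Read exon intervals (BED, 0-based half-open) grouped and sorted per contig."""
    exons: ExonMap = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected at least 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer interval") from exc
            if not 0 <= start < end:
                raise FormatError(f"{path}:{lineno}: invalid interval [{start},{end})")
            exons.setdefault(fields[0], []).append((start, end))
    for chrom in exons:
        exons[chrom].sort()
    return exons


def distance_to_exon(chrom: str, pos: int, exons: ExonMap) -> int:
    """Distance in bases from a 1-based position to the nearest exon (0 if inside).

    For a position past an exon end the distance counts from the last exonic
    base, so pos 250 against exon [100,200) gives 50.
    """
    pos0 = pos - 1
    best = NO_EXON_DISTANCE
    for start, end in exons.get(chrom, ()):
        if start <= pos0 < end:
            return 0
        if pos0 < start:
            best = min(best, start - pos0)
        else:
            best = min(best, pos0 - end + 1)
    return best


def _info(rec, key: str):
    """INFO field value or None; tolerates keys absent from the header."""
    try:
        value = rec.info.get(key)
    except (KeyError, ValueError):
        return None
    if isinstance(value, tuple):
        value = value[0]
    return value


def read_vcf(
    path: str | Path,
    exons: ExonMap,
    drug: str,
    level: str,
    replicate: int,
    sample: str | None = None,
) -> SublineSample:
    """Read one subline's VCF into a :class:`SublineSample`.

    Gene symbols come from a GENE (or ANN) INFO tag when present, else from
    the contig name (the synthetic one-contig-per-gene convention).
    Multi-allelic records are split into one call per alternate allele; AD is
    interpreted as (ref, alt1, alt2, ...). Zero-depth calls are retained with
    an undefined VAF and fall to the coverage filter downstream.
    """
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        if not sample_names:
            raise FormatError(f"{path}: VCF has no sample columns")
        name = sample or sample_names[0]
        if name not in sample_names:
            raise InputError(f"{path}: sample {name!r} not in VCF ({sample_names})")
        for rec in vcf:
            fmt = rec.samples[name]
            if "DP" not in fmt or fmt["DP"] is None:
                raise FormatError(f"{path}: record {rec.chrom}:{rec.pos} lacks FORMAT/DP")
            if "AD" not in fmt or fmt["AD"] is None:
                raise FormatError(f"{path}: record {rec.chrom}:{rec.pos} lacks FORMAT/AD")
            depth = int(fmt["DP"])
            ad = [0 if v is None else int(v) for v in fmt["AD"]]
            gene = _info(rec, "GENE") or _info(rec, "ANN") or rec.chrom
            consequence = _info(rec, "CSQ") or "other"
            for i, alt in enumerate(rec.alts or ()):
                alt_depth = ad[i + 1] if i + 1 < len(ad) else 0
                calls.append(
                    VariantCall(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        gene=str(gene).upper(),
                        depth=depth,
                        alt_depth=min(alt_depth, depth),
                        consequence=str(consequence),
                        distance_to_exon=distance_to_exon(rec.chrom, rec.pos, exons),
                    )
                )
    return SublineSample(drug=drug, level=level, replicate=replicate, calls=calls)


def read_signature_matrix(path: str | Path) -> pd.DataFrame:
    """Read a COSMIC-layout signature TSV (Type column + one column per signature).

    Rows are reordered to the canonical 96-channel order; columns whose sum is
    within 1e-3 of 1 are renormalised to exactly 1, anything further off is an
    error, as are missing/extra contexts and negative weights.
    """
    df = pd.read_csv(path, sep="\t")
    type_col = df.columns[0]
    df = df.set_index(type_col)
    if sorted(df.index) != sorted(CHANNELS_96):
        raise FormatError(
            f"{path}: expected exactly the 96 canonical trinucleotide contexts, "
            f"got {len(df.index)} rows"
        )
    df = df.reindex(list(CHANNELS_96)).astype(float)
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative signature weights")
    sums = df.sum(axis=0)
    off = sums[(sums - 1.0).abs() > 1e-3]
    if not off.empty:
        raise FormatError(f"{path}: signature columns not normalised: {dict(off)}")
    df = df / sums
    df.index.name = "Type"
    return df


def read_graph(path: str | Path) -> nx.Graph:
    """Read an undirected PPI edge list (two tab-separated gene symbols per line).

    Duplicate edges (either orientation) collapse; self-loops are dropped;
    symbols are upper-cased.
    """
    graph = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected two tab-separated genes")
            a, b = fields[0].upper(), fields[1].upper()
            if a == b:
                continue
            graph.add_edge(a, b)
    return graph


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene sets: name, description, then one gene per column."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description, genes")
            sets[fields[0]] = {g.upper() for g in fields[2:] if g}
    return sets


def read_driver_catalogue(path: str | Path) -> set[str]:
    """Read a driver-gene catalogue TSV (first column: gene symbol; header allowed)."""
    genes: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            symbol = line.split("\t")[0].strip()
            if lineno == 1 and symbol.lower() in {"gene", "symbol", "gene_symbol"}:
                continue
            if not symbol:
                raise FormatError(f"{path}:{lineno}: empty gene symbol")
            genes.add(symbol.upper())
    return genes


def read_clinvar_lookup(path: str | Path) -> dict[tuple[str, int, str, str], dict[str, str]]:
    """Read a ClinVar-style lookup TSV: chrom, pos, ref, alt, clinvar_id, significance."""
    lookup: dict[tuple[str, int, str, str], dict[str, str]] = {}
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"chrom", "pos", "ref", "alt", "clinvar_id"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    for _, row in df.iterrows():
        key = (str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))
        lookup[key] = {
            "clinvar_id": str(row["clinvar_id"]),
            "significance": str(row.get("significance", "")),
        }
    return lookup


def read_enrichment_matrix(path: str | Path) -> pd.DataFrame:
    """Read a precomputed expression-enrichment matrix (gene sets x sublines)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def reference_from_mapping(reference: Mapping[str, str]) -> dict[str, str]:
    """Accept either an in-memory dict or anything mapping chrom → sequence."""
    return {k: str(v) for k, v in reference.items()}
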