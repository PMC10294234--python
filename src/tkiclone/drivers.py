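"""Driver-gene annotation and oncoplot matrix construction.

PASS variants are intersected with a driver-gene catalogue (case-insensitive
on symbols), flagged with ClinVar annotations on exact (chrom, pos, ref, alt)
match, and assembled into a gene x subline categorical matrix whose cells
carry subsets of {MISSENSE, TRUNCATING, CLINVAR, MULTIHIT}. MULTIHIT means
at least two distinct qualifying variants of one gene in one subline; genes
recurrently hit across different replicates are reported in a separate
recurrence table instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .filtering import FilterConfig, VariantTrajectory
from .model import VariantKey

MISSENSE = "MISSENSE"
TRUNCATING = "TRUNCATING"
OTHER = "OTHER"
CLINVAR = "CLINVAR"
MULTIHIT = "MULTIHIT"

_TRUNCATING_CONSEQUENCES = {"stop_gain", "frameshift"}


def consequence_class(consequence: str) -> str:
    if consequence in _TRUNCATING_CONSEQUENCES:
        return TRUNCATING
    if consequence == "missense":
        return MISSENSE
    return OTHER


@dataclass
class DriverHit:
    """One PASS variant annotated against the catalogue and ClinVar lookup."""

    key: VariantKey
    gene: str
    in_catalogue: bool
    consequence_class: str
    clinvar_id: str | None = None
    sublines: list[str] = field(default_factory=list)  # labels where the variant is acquired
    vafs: dict[str, float] = field(default_factory=dict)  # subline label → VAF


@dataclass
class OncoplotMatrix:
    """Gene x subline categorical mutation matrix plus summary counts."""

    cells: pd.DataFrame  # comma-joined labels, "" for NONE
    genes_per_subline: pd.Series  # distinct driver genes per subline
    variants_per_subline: pd.Series  # distinct driver variants per subline
    recurrence: pd.Series  # gene → number of distinct replicates hit


def annotate_drivers(
    trajectories_by_trio: dict[str, list[VariantTrajectory]],
    catalogue: set[str],
    clinvar_lookup: dict[tuple[str, int, str, str], dict[str, str]] | None = None,
    cfg: FilterConfig | None = None,
) -> list[DriverHit]:
    """Annotate PASS trajectories of every trio against the driver catalogue.

    A variant marks a subline when its VAF gain there exceeds the filter's
    delta threshold, so a variant present in both low and high of one
    replicate marks both columns.
    """
    cfg = cfg or FilterConfig()
    clinvar_lookup = clinvar_lookup or {}
    catalogue_upper = {g.upper() for g in catalogue}
    hits: list[DriverHit] = []
    for trio_id, trajectories in trajectories_by_trio.items():
        for t in trajectories:
            if not t.passed:
                continue
            sublines, vafs = [], {}
            for level, delta, vaf in (
                ("low", t.delta_low, t.vaf_low),
                ("high", t.delta_high, t.vaf_high),
            ):
                if delta > cfg.delta_vaf_min:
                    label = f"{level}{trio_id}"
                    sublines.append(label)
                    vafs[label] = 0.0 if vaf is None else vaf
            chrom, pos, ref, alt, gene = t.key
            clinvar = clinvar_lookup.get((chrom, pos, ref, alt))
            hits.append(
                DriverHit(
                    key=t.key,
                    gene=gene.upper(),
                    in_catalogue=gene.upper() in catalogue_upper,
                    consequence_class=consequence_class(t.consequence),
                    clinvar_id=clinvar["clinvar_id"] if clinvar else None,
                    sublines=sublines,
                    vafs=vafs,
                )
            )
    return hits


def build_oncoplot(hits: list[DriverHit], sublines: list[str] | None = None) -> OncoplotMatrix:
    """Assemble the oncoplot matrix from catalogue hits.

    Gene rows are ordered by the number of mutated sublines (descending),
    ties alphabetical. Only hits with ``in_catalogue`` contribute.
    """
    driver_hits = [h for h in hits if h.in_catalogue]
    cell_variants: dict[tuple[str, str], list[DriverHit]] = {}
    for hit in driver_hits:
        for label in hit.sublines:
            cell_variants.setdefault((hit.gene, label), []).append(hit)

    if sublines is None:
        sublines = sorted({label for _, label in cell_variants})
    genes = sorted({gene for gene, _ in cell_variants})

    n_sublines_mutated = {
        g: sum(1 for (gene, _label) in cell_variants if gene == g) for g in genes
    }
    genes.sort(key=lambda g: (-n_sublines_mutated[g], g))

    cells = pd.DataFrame("", index=genes, columns=sublines, dtype=object)
    for (gene, label), cell_hits in cell_variants.items():
        if label not in cells.columns:
            continue
        labels = set()
        for h in cell_hits:
            if h.consequence_class in (MISSENSE, TRUNCATING):
                labels.add(h.consequence_class)
            if h.clinvar_id:
                labels.add(CLINVAR)
        if len({h.key for h in cell_hits}) >= 2:
            labels.add(MULTIHIT)
        cells.loc[gene, label] = ",".join(sorted(labels))

    genes_per_subline = pd.Series(
        {s: len({g for (g, label) in cell_variants if label == s}) for s in sublines},
        name="n_driver_genes",
    ).reindex(sublines, fill_value=0)
    variants_per_subline = pd.Series(
        {
            s: len({h.key for (g, label), hs in cell_variants.items() if label == s for h in hs})
            for s in sublines
        },
        name="n_driver_variants",
    ).reindex(sublines, fill_value=0)

    # Recurrence across replicates: distinct trios in which a gene is hit.
    recurrence: dict[str, set[str]] = {}
    for (gene, label) in cell_variants:
        trio = label.removeprefix("low").removeprefix("high")
        recurrence.setdefault(gene, set()).add(trio)
    recurrence_series = pd.Series(
        {g: len(trios) for g, trios in recurrence.items()}, name="n_replicates", dtype=int
    ).sort_values(ascending=False)

    return OncoplotMatrix(
        cells=cells,
        genes_per_subline=genes_per_subline,
        variants_per_subline=variants_per_subline,
        recurrence=recurrence_series,
    )


def hits_to_frame(hits: list[DriverHit]) -> pd.DataFrame:
    """Driver-hit table (one row per variant, samples and VAFs semicolon-joined)."""
    rows = []
    for h in hits:
        chrom, pos, ref, alt, _ = h.key
        rows.append(
            {
                "gene": h.gene,
                "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                "consequence_class": h.consequence_class,
                "in_catalogue": h.in_catalogue,
                "clinvar_id": h.clinvar_id or "",
                "samples": ";".join(h.sublines),
                "vafs": ";".join(f"{h.vafs[s]:.4f}" for s in h.sublines),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "chrom", "pos", "ref", "alt", "consequence_class",
            "in_catalogue", "clinvar_id", "samples", "vafs",
        ],
    )


def hits_from_table(path: str | Path | None = None) -> list[DriverHit]:
    """Load a curated driver-hit table (gene, classification, samples, clinvar_id, vafs).

    Without a path, loads the packaged worked example: the driver variants
    acquired across twelve TKI-resistant K-562 sublines (four imatinib and two
    nilotinib replicate pairs at low/high dose). ``samples`` and ``vafs`` are
    semicolon-separated and aligned. Each row becomes one DriverHit with a
    synthetic key (rows are distinct variants even within one gene).
    """
    if path is None:
        source = resources.files("tkiclone").joinpath("data/k562_tki_driver_hits.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    hits = []
    for i, row in df.iterrows():
        sublines = [s for s in str(row["samples"]).split(";") if s]
        vafs = [float(v) for v in str(row["vafs"]).split(";") if v]
        clinvar = row.get("clinvar_id")
        clinvar = None if pd.isna(clinvar) or not str(clinvar).strip() else str(clinvar).strip()
        gene = str(row["gene"]).upper()
        hits.append(
            DriverHit(
                key=(gene, i + 1, "N", "N", gene),  # synthetic per-row identity
                gene=gene,
                in_catalogue=True,
                consequence_class=str(row["classification"]).upper(),
                clinvar_id=clinvar,
                sublines=sublines,
                vafs=dict(zip(sublines, vafs)),
            )
        )
    return hits
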