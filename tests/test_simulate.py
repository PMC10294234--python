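"""Generator: construction invariants, determinism, and convergence to truth."""

import filecmp

import networkx as nx
import numpy as np
import pytest

from tkiclone.errors import ConfigurationError
from tkiclone.model import VariantCall
from tkiclone.signatures import context_of
from tkiclone.simulate import (
    PlantedVariant,
    SimulationConfig,
    assign_communities,
    mixture_spectrum,
    sample_contexts,
    simulate_all,
    simulate_ppi,
    simulate_reference,
    simulate_signature_matrix,
    write_dataset,
)


def test_reference_layout_and_exon_fraction():
    config = SimulationConfig(seed=3, n_genes=5, exon_fraction=0.5, contig_length=3000,
                              planted_drivers={})
    genes, reference, exons = simulate_reference(config)
    assert len(reference) == 5 and set(genes) == set(reference)
    for gene in genes:
        L = len(reference[gene])
        assert L == 3000
        covered = sum(end - start for start, end in exons[gene])
        assert abs(covered / L - 0.5) < 0.1
        assert all(0 <= s < e <= L for s, e in exons[gene])


def test_planted_variant_matches_reference(deep_dataset):
    for tv in deep_dataset.truth.variants:
        assert deep_dataset.reference[tv.chrom][tv.pos - 1] == tv.ref


def test_same_seed_byte_identical_outputs(tmp_path):
    config = SimulationConfig(seed=5, n_genes=30, n_background_variants=20,
                              n_parental_variants=5,
                              replicates={"imatinib": 1, "nilotinib": 1})
    write_dataset(simulate_all(config), tmp_path / "a")
    write_dataset(simulate_all(config), tmp_path / "b")
    for name in ("reference.fa", "exons.bed", "ppi_edges.tsv", "signatures.tsv",
                 "truth.json", "vcf/highIM-R1.vcf", "vcf/lowN-R1.vcf"):
        assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False), name


def test_absent_stage_emits_no_alternate_reads(deep_dataset):
    """A stage planted as ABSENT or VAF 0 never appears in that subline's calls."""
    stage_index = {"sensitive": 0, "low": 1, "high": 2}
    by_key = deep_dataset.truth.by_key()
    for trio_id, stage_records in deep_dataset.trios.items():
        for stage, records in stage_records.items():
            for r in records:
                tv = by_key[(r.chrom, r.pos, r.ref, r.alt)]
                if tv.trio_id != trio_id:
                    continue
                true_vaf = tv.stage_vafs[stage_index[stage]]
                assert true_vaf is not None and true_vaf > 0
                assert r.alt_depth >= 1


def test_empirical_vaf_converges_to_truth_at_high_depth(deep_dataset):
    """At 10,000x the sampled VAF estimator is tight around the true stage VAF.

    Binomial sampling puts the per-variant standard error near 0.005 here, so
    the aggregate deviation must sit well under 0.01 with no gross outliers.
    """
    stage_index = {"sensitive": 0, "low": 1, "high": 2}
    by_key = deep_dataset.truth.by_key()
    deviations = []
    for trio_id, stage_records in deep_dataset.trios.items():
        for stage, records in stage_records.items():
            for r in records:
                tv = by_key[(r.chrom, r.pos, r.ref, r.alt)]
                if tv.trio_id != trio_id:
                    continue
                true_vaf = tv.stage_vafs[stage_index[stage]]
                deviations.append(abs(r.alt_depth / r.depth - true_vaf))
    deviations = np.asarray(deviations)
    assert len(deviations) > 1000
    assert deviations.mean() < 0.01
    assert np.quantile(deviations, 0.9) < 0.01
    assert deviations.max() < 0.05


def test_background_spectrum_matches_signature_mixture():
    """TV distance between the generated background spectrum and the mixture < 0.05."""
    config = SimulationConfig(
        seed=21, n_genes=50, contig_length=20_000, n_background_variants=20_000,
        n_parental_variants=0, n_hitchhikers_per_driver=0, deep_intronic_fraction=0.0,
        planted_drivers={}, replicates={"imatinib": 1},
    )
    ds = simulate_all(config)
    expected = mixture_spectrum(ds.signature_matrix, config.signature_mix)
    counts = expected * 0.0
    for tv in ds.truth.variants:
        if tv.kind != "background":
            continue
        call = VariantCall(chrom=tv.chrom, pos=tv.pos, ref=tv.ref, alt=tv.alt,
                           gene=tv.gene, depth=1, alt_depth=1)
        channel = context_of(call, ds.reference)
        assert channel == tv.context  # planted context is real on the reference
        counts[channel] += 1
    assert counts.sum() == 20_000
    tv_distance = 0.5 * (counts / counts.sum() - expected).abs().sum()
    assert tv_distance < 0.05


def test_sampled_contexts_follow_mixture():
    config = SimulationConfig(seed=2)
    matrix = simulate_signature_matrix(config)
    rng = np.random.default_rng(9)
    labels = sample_contexts(20_000, matrix, {"SIG1": 1.0}, rng)
    counts = mixture_spectrum(matrix, {"SIG1": 1.0}) * 0.0
    for label in labels:
        counts[label] += 1
    tv_distance = 0.5 * (counts / counts.sum() - matrix["SIG1"]).abs().sum()
    assert tv_distance < 0.05


def test_ppi_planted_partition_modularity():
    config = SimulationConfig(seed=7, n_genes=40, ppi_communities=2,
                              ppi_p_intra=0.5, ppi_p_inter=0.01)
    genes = [f"G{i}" for i in range(40)]
    communities = assign_communities(genes, 2)
    graph = simulate_ppi(config, genes, communities)
    assert set(graph.nodes) == set(genes)
    assert not any(a == b for a, b in graph.edges)
    parts = [{g for g in genes if communities[g] == c} for c in (0, 1)]
    assert nx.community.modularity(graph, parts) > 0.3


def test_ppi_single_community_and_determinism():
    config = SimulationConfig(seed=8, n_genes=25, ppi_communities=1)
    genes = [f"G{i}" for i in range(25)]
    communities = assign_communities(genes, 1)
    g1 = simulate_ppi(config, genes, communities)
    g2 = simulate_ppi(config, genes, communities)
    assert sorted(g1.edges) == sorted(g2.edges)
    assert g1.number_of_edges() > 0


@pytest.mark.parametrize(
    "kwargs",
    [
        {"depth_mean": 0},
        {"exon_fraction": 1.5},
        {"signature_mix": {"SIG1": 0.5, "SIG2": 0.4}},
        {"n_genes": 1, "ppi_communities": 2},
    ],
)
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        SimulationConfig(seed=1, **kwargs)


def test_planted_variant_requires_a_stage():
    with pytest.raises(ConfigurationError):
        PlantedVariant("KRAS", (None, None, None))
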