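"""Independent brute-force oracles used only by tests.

These reimplementations share no code with the package: the filter oracle is
a naive transcription of the cascade rules, the propagation oracle is a dense
linear solve, and the exposure oracle is a grid search over the 2-simplex.
"""

import numpy as np

from tkiclone.model import SublineSample, SublineTrio, VariantCall


def brute_force_cascade(rows, min_depth=10, sens_max=0.05, delta_min=0.15, intron_dist=20):
    """Naive per-variant cascade. ``rows`` are dicts with per-stage (depth, alt)
    tuples (None = absent), consequence and distance_to_exon. Returns
    (verdict, clonal_class) per row, in order."""
    out = []
    for row in rows:
        stages = {}
        for stage in ("sensitive", "low", "high"):
            da = row[stage]
            if da is None:
                stages[stage] = None
            else:
                depth, alt = da
                stages[stage] = (depth, alt)
        depths = [da[0] for da in stages.values() if da is not None]

        def vaf(stage):
            da = stages[stage]
            if da is None or da[0] == 0:
                return 0.0
            return da[1] / da[0]

        vs, vl, vh = vaf("sensitive"), vaf("low"), vaf("high")
        dl, dh = vl - vs, vh - vs
        if all(d < min_depth for d in depths):
            out.append(("FAIL_depth", "NONE"))
            continue
        if vs >= sens_max:
            out.append(("FAIL_sensitive", "NONE"))
            continue
        if row["consequence"] == "intronic" and row["distance_to_exon"] > intron_dist:
            out.append(("FAIL_intronic", "NONE"))
            continue
        if not (dl > delta_min or dh > delta_min):
            out.append(("FAIL_delta", "NONE"))
            continue
        if dh > delta_min and dl <= delta_min:
            cls = "ACQUIRED_HIGH"
        elif dl > delta_min and dh <= delta_min:
            cls = "LOW_ONLY"
        elif (vl - vh) > delta_min:
            cls = "SHARED_REDUCED_HIGH"
        else:
            cls = "SHARED_CONSTANT"
        out.append(("PASS", cls))
    return out


def random_trajectory_rows(n, rng):
    """Randomised per-variant stage observations exercising every cascade branch."""
    rows = []
    for i in range(n):
        row = {"consequence": rng.choice(["missense", "intronic", "synonymous"]),
               "distance_to_exon": int(rng.integers(0, 60))}
        for stage in ("sensitive", "low", "high"):
            if rng.random() < 0.25:
                row[stage] = None
            else:
                depth = int(rng.integers(0, 80))
                alt = int(rng.integers(0, depth + 1)) if depth else 0
                row[stage] = (depth, alt)
        if all(row[s] is None for s in ("sensitive", "low", "high")):
            row["high"] = (30, int(rng.integers(0, 31)))
        rows.append(row)
    return rows


def rows_to_trio(rows):
    """Build a SublineTrio whose i-th variant matches rows[i] (contig Gi)."""
    samples = {}
    for stage in ("sensitive", "low", "high"):
        calls = []
        for i, row in enumerate(rows):
            if row[stage] is None:
                continue
            depth, alt = row[stage]
            calls.append(
                VariantCall(
                    chrom=f"G{i}", pos=100, ref="C", alt="T", gene=f"G{i}",
                    depth=depth, alt_depth=alt, consequence=row["consequence"],
                    distance_to_exon=row["distance_to_exon"],
                )
            )
        samples[stage] = SublineSample(
            drug="none" if stage == "sensitive" else "imatinib",
            level=stage,
            replicate=0 if stage == "sensitive" else 1,
            calls=calls,
        )
    return SublineTrio(drug="imatinib", replicate=1, **samples)


def rwr_linear_solve(graph, f0, alpha):
    """Closed form (1-alpha) (I - alpha W')^{-1} F0 with dense algebra."""
    import networkx as nx

    nodes = list(f0.index)
    A = nx.to_numpy_array(graph, nodelist=nodes, weight=None)
    deg = A.sum(axis=1)
    with np.errstate(divide="ignore"):
        dinv = np.where(deg > 0, 1 / np.sqrt(deg), 0.0)
    W = dinv[:, None] * A * dinv[None, :]
    n = len(nodes)
    return np.linalg.solve(np.eye(n) - alpha * W, (1 - alpha) * f0.to_numpy())


def grid_search_exposures(S, p, step=0.001):
    """Best mixture a*S1 + (1-a)*S2 on the 2-simplex by exhaustive grid."""
    best_a, best_err = 0.0, np.inf
    for a in np.arange(0.0, 1.0 + step / 2, step):
        err = np.linalg.norm(S @ np.array([a, 1 - a]) - p)
        if err < best_err:
            best_a, best_err = a, err
    return best_a, best_err
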