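"""Desk-scale simulation studies validating every stage of the pipeline.

Each function generates its own seeded synthetic data with
:mod:`saltnet.synthdata`, runs the corresponding analysis stage, and returns
summary statistics: null calibration and power of the interaction LRT,
closed-form agreement of the LASSO solver, ground-truth recovery of the
decision algorithm and its permutation null, VIP and BH exactness against
independent oracles, clustering agreement with a brute-force agglomeration,
and byte-level determinism of the full pipeline.  The problem sizes are
fixed desk-scale defaults chosen so the whole battery runs in minutes on a
single CPU.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust, estimate_size_factors, lrt_sset
from .io_model import write_matrix, write_network, write_results_table
from .multivariate import plsda_fit, vip_scores
from .netlasso import (
    DecisionConfig,
    assemble_network,
    classify_and_select,
    decision_loop,
    frequency_table,
    kkt_violation,
    results_table,
    run_decision_algorithm,
    solve_lasso,
)
from .pipeline import expression_for_network, run_network_pipeline
from .synthdata import SimConfig, evaluate_recovery, simulate_counts, simulate_dataset
from .tempcluster import cut_clusters, hclust_tree

# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------


def lrt_null_calibration(seed: int, n_genes: int = 2000, alpha: float = 0.2) -> dict:
    """Type-I error and p-value uniformity of the interaction LRT on a null
    simulation (no stress:time effect) analysed within one ecotype."""
    cfg = SimConfig(
        n_genes=n_genes, ecotypes=("HLZY",), sset_fraction=0.0,
        dispersion=alpha, seed=seed,
    )
    counts, _, _ = simulate_counts(cfg)
    from .synthdata import make_design

    sheet = make_design(cfg)
    res = lrt_sset(counts, sheet)
    p = res.pvalue.to_numpy()
    p = p[np.isfinite(p)]
    return {
        "type1_at_0.05": float(np.mean(p < 0.05)),
        "ks_uniformity_p": float(stats.kstest(p, "uniform").pvalue),
        "n": int(p.size),
    }


def lrt_power(seed: int, n_genes: int = 2000, sset_fraction: float = 0.25) -> dict:
    """Recall of planted interaction genes (log2FC 2 at >=3 post-baseline
    times) at FDR < 0.01."""
    cfg = SimConfig(
        n_genes=n_genes, ecotypes=("HLZY",), sset_fraction=sset_fraction,
        seed=seed,
    )
    counts, _, truth = simulate_counts(cfg)
    from .synthdata import make_design

    sheet = make_design(cfg)
    res = lrt_sset(counts, sheet)
    called = set(res.gene[res.is_sset])
    recall = len(called & truth.sset_genes) / len(truth.sset_genes)
    return {"recall_at_fdr01": float(recall), "n_planted": len(truth.sset_genes)}


# ---------------------------------------------------------------------------
# LASSO solver
# ---------------------------------------------------------------------------


def lasso_orthonormal_check(seed: int, n_instances: int = 200) -> dict:
    """Coordinate descent vs the orthonormal-design soft-threshold closed
    form, plus the worst KKT violation over all instances."""
    rng = np.random.default_rng(seed)
    max_gap = 0.0
    max_kkt = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(20, 80))
        p = int(rng.integers(2, min(12, n // 2)))
        q, _ = np.linalg.qr(rng.normal(size=(n, p)))
        X = q * np.sqrt(n)  # X'X/n = I
        y = X @ rng.normal(size=p) + rng.normal(size=n)
        y -= y.mean()
        lam = float(rng.uniform(0.01, 1.0))
        beta = solve_lasso(X, y, lam)
        ols = X.T @ y / n
        closed = np.sign(ols) * np.maximum(np.abs(ols) - lam, 0.0)
        max_gap = max(max_gap, float(np.abs(beta - closed).max()))
        max_kkt = max(max_kkt, kkt_violation(X, y, beta, lam))
    return {"max_abs_gap": max_gap, "max_kkt_violation": max_kkt, "n": n_instances}


# ---------------------------------------------------------------------------
# decision algorithm
# ---------------------------------------------------------------------------


def _benchmark_config(seed: int, n_genes: int = 500, n_metabolites: int = 20) -> SimConfig:
    return SimConfig(
        n_genes=n_genes, n_metabolites=n_metabolites, ecotypes=("HLZY",),
        sset_fraction=0.1, r2_target=0.9, seed=seed,
    )


def network_recovery(seed: int) -> dict:
    """Edge-level recovery of the planted regulator network (20 metabolites,
    3 regulators each among 500 genes, n = 56, R^2 = 0.9, 100 repeats)."""
    ds = simulate_dataset(_benchmark_config(seed))
    expr = expression_for_network(ds.tpm)
    config = DecisionConfig(seed=seed)
    results = run_decision_algorithm(expr, ds.metabolites.data, config)
    _, regulators = classify_and_select(results, config)
    net = assemble_network(regulators, results, hub_degree=config.hub_degree)
    out = evaluate_recovery(net, ds.truth)
    out.update(
        n_predictable=sum(r.status == "predictable" for r in results),
        n_edges=len(net.edges),
    )
    return out


def permutation_null(seed: int, n_permutations: int = 50) -> dict:
    """Decision algorithm on permuted metabolite responses: fraction of
    permuted responses called predictable (expected 0)."""
    ds = simulate_dataset(_benchmark_config(seed))
    expr = expression_for_network(ds.tpm)
    config = DecisionConfig(seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 777)))
    mets = ds.metabolites.data
    n_pred = 0
    for i in range(n_permutations):
        met = mets.index[i % len(mets)]
        y = mets.loc[met].to_numpy()[rng.permutation(mets.shape[1])]
        res = decision_loop(expr, y, f"{met}_perm{i}", config, rng)
        n_pred += res.status == "predictable"
    return {"fraction_predictable": n_pred / n_permutations, "n": n_permutations}


# ---------------------------------------------------------------------------
# VIP / BH / clustering oracles
# ---------------------------------------------------------------------------


def vip_exactness(seed: int) -> dict:
    """Largest |sum VIP^2 - p| over PLS-DA fits of a simulated metabolome."""
    ds = simulate_dataset(SimConfig(n_genes=60, n_metabolites=25, seed=seed))
    worst = 0.0
    for factor in ("time", "ecotype", "stress"):
        for ncomp in (1, 2, 3, 5):
            model = plsda_fit(ds.metabolites, ds.sheet, factor, n_components=ncomp)
            vips = vip_scores(model)
            worst = max(worst, abs(float(np.sum(vips**2)) - len(vips)))
    return {"max_abs_sumsq_deviation": worst}


def bh_stepup_reference(p: np.ndarray) -> np.ndarray:
    """Independent BH step-up: q_(i) = min(1, min_{j>=i} m p_(j) / j)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def bh_oracle_check(seed: int, n_vectors: int = 1000) -> dict:
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        p = rng.uniform(size=int(rng.integers(1, 60)))
        worst = max(worst, float(np.abs(bh_adjust(p) - bh_stepup_reference(p)).max()))
    return {"max_abs_difference": worst, "n": n_vectors}


def reference_agglomeration(X: np.ndarray, linkage: str = "complete") -> np.ndarray:
    """Brute-force O(n^3) agglomeration; returns sorted merge heights."""
    clusters = [[i] for i in range(len(X))]
    d = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None, None)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                pair = d[np.ix_(clusters[a], clusters[b])]
                dist = pair.max() if linkage == "complete" else pair.mean()
                if dist < best[0]:
                    best = (dist, a, b)
        dist, a, b = best
        heights.append(dist)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return np.array(heights)


def clustering_checks(seed: int) -> dict:
    """Merge-height agreement with the brute-force oracle on 50-row random
    fixtures, and planted 8-cluster recovery (ARI) at the height-14 cut."""
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(3):
        X = rng.normal(size=(50, 8))
        dend = hclust_tree(pd.DataFrame(X, index=[f"g{i}" for i in range(50)]))
        ref = reference_agglomeration(X)
        worst = max(worst, float(np.abs(np.sort(dend.heights) - ref).max()))

    centers = np.zeros((8, 28))
    for i in range(8):
        centers[i, i] = 15.0
    labels = rng.integers(0, 8, size=120)
    X = centers[labels] + rng.normal(0, 0.5, size=(120, 28))
    dend = hclust_tree(pd.DataFrame(X, index=[f"g{i}" for i in range(120)]))
    assign = cut_clusters(dend, height=14.0)
    ari = adjusted_rand_score(labels, assign.labels.to_numpy())
    return {"max_height_gap": worst, "planted_ari": float(ari)}


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------


def _run_pipeline_once(out_dir: Path, seed: int) -> dict[str, bytes]:
    cfg = SimConfig(
        n_genes=250, n_metabolites=5, ecotypes=("HLZY",), sset_fraction=0.15,
        seed=seed,
    )
    ds = simulate_dataset(cfg)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_matrix(ds.counts, out_dir / "counts.tsv")
    sf = estimate_size_factors(ds.counts)
    sset = lrt_sset(ds.counts, ds.sheet, size_factors=sf)
    write_results_table(sset, out_dir / "sset.tsv")
    genes = list(sset.gene[sset.is_sset]) or list(ds.counts.genes[:20])
    from .tempcluster import cluster_genes

    _, assign = cluster_genes(ds.tpm, ds.sheet, genes=genes, height=5.0)
    write_results_table(
        assign.labels.rename_axis("gene").reset_index(), out_dir / "clusters.tsv"
    )
    results, net = run_network_pipeline(
        ds.tpm, ds.metabolites, ds.sheet, DecisionConfig(seed=seed)
    )
    write_results_table(results_table(results), out_dir / "metabolites.tsv")
    write_results_table(frequency_table(results), out_dir / "frequency.tsv")
    write_network(net, out_dir / "network.tsv", fmt="tsv")
    write_network(net, out_dir / "network.graphml", fmt="graphml")
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out_dir.iterdir())
    }


def determinism_check(seed: int, work_dir: str | Path) -> dict:
    """Run simulate -> SSET -> clustering -> network twice with one seed and
    compare every exported file byte-for-byte (via digests)."""
    work_dir = Path(work_dir)
    d1 = _run_pipeline_once(work_dir / "run1", seed)
    d2 = _run_pipeline_once(work_dir / "run2", seed)
    mismatched = [k for k in d1 if d1[k] != d2.get(k)]
    return {
        "n_files": len(d1),
        "n_mismatched": len(mismatched),
        "identical": int(not mismatched and set(d1) == set(d2)),
    }
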