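"""Seeded synthetic data with the structure every analysis stage assumes.

The generator emulates a 2-ecotype x 2-treatment x 14-time-point factorial
with replicated sampling:

* counts are negative binomial around log-scale means composed of a
  gene baseline, batch, ecotype and stress offsets and a temporal
  programme; genes belong to co-expression modules that share a latent
  time profile (gene-specific loadings plus idiosyncratic wiggle), the
  way transcriptional programmes make real stress-response genes move
  together over time;
* a configurable subset of genes carries a salt-specific temporal effect
  (a stress:time interaction): from a random onset onward, salt samples at
  each affected time are shifted by the configured log2 fold change with an
  independently drawn direction per time point, so the planted signal
  genuinely varies over time (a constant same-sign shift would be a
  treatment main effect, not an interaction);
* TPM is derived from the realized counts (library-size normalised to 1e6),
  so expression estimates carry the same sampling noise a quantifier's
  paired outputs would;
* metabolites are sparse linear combinations of standardized log2(TPM+1)
  of k regulator genes (drawn from one co-expression module by default)
  plus Gaussian noise scaled to a target signal fraction R^2.

Everything is a pure function of (config, seed), and ground truth (SSET
genes, affected times, regulatory edges) is returned for recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_model import (
    CountMatrix,
    MetaboliteMatrix,
    RegulatoryNetwork,
    SaltnetError,
    SampleSheet,
    TpmMatrix,
)

LN2 = float(np.log(2.0))

DEFAULT_TIME_LABELS = (
    "0h", "0.5h", "1h", "2h", "4h", "8h", "12h", "24h",
    "4DAS", "5DAS", "9DAS", "12DAS", "15DAS", "18DAS",
)


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults mirror the study's sampling grid
    (2 ecotypes x 2 treatments x 14 time points x 2 replicates)."""

    n_genes: int = 2000
    n_metabolites: int = 20
    ecotypes: tuple[str, ...] = ("HLZY", "JI853")
    treatments: tuple[str, ...] = ("control", "salt")
    time_labels: tuple[str, ...] = DEFAULT_TIME_LABELS
    n_reps: int = 2
    # expression model (natural-log scale unless noted)
    baseline_log_mean: float = float(np.log(200.0))
    baseline_log_sd: float = 1.0
    dispersion: float = 0.2
    batch_sd: float = 0.05
    ecotype_sd: float = 0.1
    stress_sd: float = 0.1
    library_log_sd: float = 0.15
    module_size: int = 4
    module_profile_sd: float = 0.40
    loading_sd: float = 0.1
    idio_time_sd: float = 0.25
    # planted stress:time interaction
    sset_fraction: float = 0.1
    interaction_log2fc: float = 2.0
    min_affected_times: int = 3
    # metabolite model
    regulators_per_metabolite: int = 3
    regulator_mode: str = "module"  # or "random"
    weight_value: float = 1.0
    r2_target: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.r2_target <= 1:
            raise SaltnetError("r2_target must be in (0, 1]")
        if self.min_affected_times < 1:
            raise SaltnetError("min_affected_times must be >= 1")
        if self.regulators_per_metabolite > self.n_genes:
            raise SaltnetError("more regulators per metabolite than genes")


@dataclass(frozen=True)
class GroundTruth:
    gene_ids: tuple[str, ...]
    metabolite_ids: tuple[str, ...] = ()
    sset_genes: frozenset[str] = frozenset()
    affected_times: dict = field(default_factory=dict)  # gene -> tuple of times
    modules: dict = field(default_factory=dict)  # gene -> module index
    regulatory_edges: frozenset = frozenset()  # (gene, metabolite, weight)

    @property
    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(g, m) for g, m, _ in self.regulatory_edges}


def make_design(config: SimConfig) -> SampleSheet:
    """Full-factorial sample sheet: ecotype x treatment x time x replicate,
    with batch assigned per replicate."""
    rows = []
    for eco in config.ecotypes:
        for treat in config.treatments:
            for t in config.time_labels:
                for rep in range(1, config.n_reps + 1):
                    rows.append(
                        {
                            "sample_id": f"{eco}_{treat}_{t}_r{rep}",
                            "ecotype": eco,
                            "treatment": treat,
                            "time": t,
                            "batch": f"b{rep}",
                        }
                    )
    return SampleSheet(pd.DataFrame(rows))


def simulate_counts(
    config: SimConfig, sheet: SampleSheet | None = None
) -> tuple[CountMatrix, TpmMatrix, GroundTruth]:
    """Simulate NB counts (and derived TPM) with planted interaction genes."""
    sheet = sheet or make_design(config)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 101)))
    tbl = sheet.table
    n_samples = len(tbl)
    n_genes = config.n_genes
    genes = [f"g{i:05d}" for i in range(n_genes)]
    times = list(sheet.time_levels)
    n_times = len(times)
    time_idx = tbl["time"].cat.codes.to_numpy()
    eco_idx = tbl["ecotype"].cat.codes.to_numpy()
    treat_idx = tbl["treatment"].cat.codes.to_numpy()  # >0 = stressed
    batch_idx = tbl["batch"].cat.codes.to_numpy()
    n_batches = len(sheet.batch_levels)
    n_ecotypes = len(sheet.ecotype_levels)

    n_modules = max(1, int(np.ceil(n_genes / config.module_size)))
    module_of = np.arange(n_genes) // config.module_size
    module_profiles = np.zeros((n_modules, n_times))
    raw = rng.normal(0.0, 1.0, size=(n_modules, n_times - 1))
    # fixed RMS amplitude per module so co-expression strength is homogeneous
    rms = np.sqrt((raw**2).mean(axis=1, keepdims=True))
    module_profiles[:, 1:] = config.module_profile_sd * raw / np.maximum(rms, 1e-12)
    loadings = rng.normal(1.0, config.loading_sd, size=n_genes)
    idio = np.zeros((n_genes, n_times))
    idio[:, 1:] = rng.normal(0.0, config.idio_time_sd, size=(n_genes, n_times - 1))
    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, n_genes)
    batch_eff = np.zeros((n_genes, n_batches))
    batch_eff[:, 1:] = rng.normal(0.0, config.batch_sd, size=(n_genes, n_batches - 1))
    eco_eff = np.zeros((n_genes, n_ecotypes))
    eco_eff[:, 1:] = rng.normal(0.0, config.ecotype_sd, size=(n_genes, n_ecotypes - 1))
    stress_eff = rng.normal(0.0, config.stress_sd, n_genes)
    lib_offset = rng.normal(0.0, config.library_log_sd, n_samples)

    n_sset = int(round(config.sset_fraction * n_genes))
    sset_idx = rng.choice(n_genes, size=n_sset, replace=False) if n_sset else np.array([], dtype=int)
    interaction = np.zeros((n_genes, n_times))
    affected_times: dict[str, tuple[str, ...]] = {}
    max_onset = n_times - config.min_affected_times
    for gi in sset_idx:
        onset = int(rng.integers(1, max_onset + 1))
        signs = rng.choice([-1.0, 1.0], size=n_times - onset)
        interaction[gi, onset:] = signs * config.interaction_log2fc * LN2
        affected_times[genes[gi]] = tuple(times[onset:])

    time_term = loadings[:, None] * module_profiles[module_of] + idio
    log_mu = (
        baseline[:, None]
        + batch_eff[:, batch_idx]
        + eco_eff[:, eco_idx]
        + np.where(treat_idx[None, :] > 0, stress_eff[:, None], 0.0)
        + time_term[:, time_idx]
        + np.where(treat_idx[None, :] > 0, interaction[:, time_idx], 0.0)
        + lib_offset[None, :]
    )
    mu = np.exp(np.clip(log_mu, -30, 30))
    if config.dispersion < 1e-8:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / config.dispersion
        counts = rng.poisson(rng.gamma(shape, mu / shape))

    count_df = pd.DataFrame(counts, index=genes, columns=sheet.sample_ids)
    lib = counts.sum(axis=0).astype(float)
    lib[lib == 0] = 1.0
    tpm = counts / lib[None, :] * 1e6
    tpm_df = pd.DataFrame(tpm, index=genes, columns=sheet.sample_ids)
    truth = GroundTruth(
        gene_ids=tuple(genes),
        sset_genes=frozenset(genes[i] for i in sset_idx),
        affected_times=affected_times,
        modules={g: int(m) for g, m in zip(genes, module_of)},
    )
    return CountMatrix(count_df), TpmMatrix(tpm_df), truth


def simulate_metabolome(
    tpm: TpmMatrix, truth: GroundTruth, config: SimConfig
) -> tuple[MetaboliteMatrix, GroundTruth]:
    """Metabolites as sparse linear combinations of standardized log2(TPM+1)
    expression of k regulator genes, with noise scaled to the target R^2."""
    k = config.regulators_per_metabolite
    if k > len(tpm.genes):
        raise SaltnetError("regulators_per_metabolite exceeds gene count")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 202)))
    logx = np.log2(tpm.values + 1.0)
    sd = logx.std(axis=1)
    ok = sd > 0
    z = np.zeros_like(logx)
    z[ok] = (logx[ok] - logx[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
    genes = np.asarray(tpm.genes)

    modules: dict[int, list[int]] = {}
    for i, g in enumerate(genes):
        if ok[i]:
            modules.setdefault(truth.modules.get(g, 0), []).append(i)
    usable_modules = [m for m, idx in sorted(modules.items()) if len(idx) >= k]
    if config.regulator_mode == "module" and not usable_modules:
        raise SaltnetError("no co-expression module has enough variable genes")

    mets = [f"m{i:04d}" for i in range(config.n_metabolites)]
    values = np.empty((config.n_metabolites, z.shape[1]))
    edges: set[tuple[str, str, float]] = set()
    for mi, met in enumerate(mets):
        if config.regulator_mode == "module":
            mod = usable_modules[int(rng.integers(len(usable_modules)))]
            pool = np.asarray(modules[mod])
        else:
            pool = np.flatnonzero(ok)
        reg_idx = rng.choice(pool, size=k, replace=False)
        w = np.full(k, config.weight_value)
        signal = w @ z[reg_idx]
        if config.r2_target >= 1.0:
            noise = np.zeros_like(signal)
        else:
            var_sig = signal.var()
            sigma = np.sqrt(var_sig * (1.0 - config.r2_target) / config.r2_target)
            noise = rng.normal(0.0, sigma, size=signal.size)
        values[mi] = signal + noise
        for gi, wi in zip(reg_idx, w):
            edges.add((str(genes[gi]), met, float(wi)))

    met_df = pd.DataFrame(values, index=mets, columns=tpm.samples)
    new_truth = replace(
        truth, metabolite_ids=tuple(mets), regulatory_edges=frozenset(edges)
    )
    return MetaboliteMatrix(met_df), new_truth


@dataclass(frozen=True)
class SimulatedDataset:
    sheet: SampleSheet
    counts: CountMatrix
    tpm: TpmMatrix
    metabolites: MetaboliteMatrix
    truth: GroundTruth


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Full paired dataset: design -> counts/TPM -> metabolome."""
    sheet = make_design(config)
    counts, tpm, truth = simulate_counts(config, sheet)
    metabolites, truth = simulate_metabolome(tpm, truth, config)
    return SimulatedDataset(sheet, counts, tpm, metabolites, truth)


def evaluate_recovery(predicted: RegulatoryNetwork, truth: GroundTruth) -> dict:
    """Edge-level and gene-level precision/recall/F1 against ground truth.

    Convention for an empty prediction: precision = 1, recall = 0.
    """
    genes = set(truth.gene_ids)
    mets = set(truth.metabolite_ids)
    bad = [g for g in predicted.gene_nodes if g not in genes] + [
        m for m in predicted.metabolite_nodes if m not in mets
    ]
    if bad:
        raise SaltnetError(f"predicted node(s) outside the simulated universe: {bad[:5]}")
    pred_edges = predicted.edge_set
    true_edges = truth.edge_pairs
    out = {}
    for level, pred, true in (
        ("edge", pred_edges, true_edges),
        ("gene", {g for g, _ in pred_edges}, {g for g, _ in true_edges}),
    ):
        tp = len(pred & true)
        precision = tp / len(pred) if pred else 1.0
        recall = tp / len(true) if true else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        out[f"{level}_precision"] = precision
        out[f"{level}_recall"] = recall
        out[f"{level}_f1"] = f1
    return out
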