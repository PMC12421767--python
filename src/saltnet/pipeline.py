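"""End-to-end conveniences tying the analysis stages together."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffexpr import filter_expressed
from .io_model import (
    MetaboliteMatrix,
    RegulatoryNetwork,
    SampleSheet,
    TpmMatrix,
    align_check,
)
from .multivariate import vip_table
from .netlasso import (
    DecisionConfig,
    DecisionModelResult,
    assemble_network,
    classify_and_select,
    run_decision_algorithm,
)


def expression_for_network(
    tpm: TpmMatrix, min_mean_tpm: float = 1.0, transform: str = "log2"
) -> pd.DataFrame:
    """Expressed-gene expression matrix fed to the decision algorithm:
    log2(TPM+1) by default (``transform`` in {log2, log, none})."""
    expressed = filter_expressed(tpm, min_mean_tpm)
    sub = tpm.subset_features(expressed).data.astype(float)
    if transform == "log2":
        return np.log2(sub + 1.0)
    if transform == "log":
        return np.log(sub + 1.0)
    if transform == "none":
        return sub
    raise ValueError(f"unknown transform {transform!r}")


def run_network_pipeline(
    tpm: TpmMatrix,
    metabolites: MetaboliteMatrix,
    sheet: SampleSheet,
    config: DecisionConfig,
    restrict_salt_responsive: bool = False,
    min_mean_tpm: float = 1.0,
    n_components: int = 3,
) -> tuple[list[DecisionModelResult], RegulatoryNetwork]:
    """Decision algorithm over all metabolites and network assembly,
    optionally restricted to salt-responsive metabolites (VIP_stress > 1)."""
    align_check(tpm, sheet)
    align_check(metabolites, sheet)
    expr = expression_for_network(tpm, min_mean_tpm=min_mean_tpm)
    results = run_decision_algorithm(expr, metabolites.data, config)
    _, regulators = classify_and_select(results, config)
    vip_stress = None
    if restrict_salt_responsive:
        vips = vip_table(
            metabolites, sheet, factors=("stress",), n_components=n_components
        )
        vip_stress = vips["VIP_stress"]
    return results, assemble_network(
        regulators, results, vip_stress=vip_stress, hub_degree=config.hub_degree
    )
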