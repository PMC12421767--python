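"""PCA and PLS-DA with VIP scoring on the metabolite matrix.

Samples are described by three factor dimensions (time, ecotype, stress);
for each dimension a PLS2 discriminant model is fitted against the one-hot
class matrix and each metabolite receives a variable-importance-in-
projection (VIP) score

    VIP_j = sqrt( p * sum_a SSY_a w_aj^2 / sum_a SSY_a ),

where w_a are the unit-norm X weights and SSY_a the Y variance explained by
component a.  VIP scores satisfy sum_j VIP_j^2 = p, so VIP > 1 marks
metabolites contributing more than an average variable; metabolites with
VIP > 1 in the stress dimension are called salt-responsive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .io_model import MetaboliteMatrix, SaltnetError, SampleSheet, align_check

logger = logging.getLogger("saltnet.multivariate")

FACTOR_COLUMNS = {"time": "time", "ecotype": "ecotype", "stress": "treatment"}


def _standardize(X: np.ndarray, scale: bool) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    return Xc


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def pca_variance(
    metabolites: MetaboliteMatrix, n_components: int | None = None, scale: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """SVD-based PCA of samples in metabolite space.

    Returns (scores, loadings, explained-variance fractions); fractions are
    over ALL principal axes and therefore sum to 1.
    """
    X = metabolites.values.T.astype(float)  # samples x metabolites
    if X.shape[0] < 2:
        raise SaltnetError("PCA needs at least 2 samples")
    if np.allclose(X.std(axis=0), 0):
        raise SaltnetError("constant matrix: PCA undefined")
    Xc = _standardize(X, scale)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (X.shape[0] - 1)
    frac = var / var.sum()
    k = len(s) if n_components is None else min(n_components, len(s))
    pcs = [f"PC{i+1}" for i in range(k)]
    scores = pd.DataFrame((u[:, :k] * s[:k]), index=metabolites.samples, columns=pcs)
    loadings = pd.DataFrame(vt[:k].T, index=metabolites.metabolites, columns=pcs)
    return scores, loadings, frac


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlsdaModel:
    """Fitted PLS2 discriminant model for one factor dimension."""

    factor: str
    metabolite_ids: tuple[str, ...]
    classes: tuple[str, ...]
    weights: np.ndarray = field(repr=False)  # p x A, unit columns
    scores: np.ndarray = field(repr=False)  # n x A, mutually orthogonal
    x_loadings: np.ndarray = field(repr=False)  # p x A
    y_loadings: np.ndarray = field(repr=False)  # q x A
    ssy: np.ndarray = field(repr=False)  # per-component explained Y variance

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]


def plsda_fit(
    metabolites: MetaboliteMatrix,
    sheet: SampleSheet,
    factor: str,
    n_components: int = 3,
    scale: bool = True,
) -> PlsdaModel:
    """NIPALS PLS2 of metabolite profiles against a one-hot class matrix.

    X columns are centred (and unit-variance scaled by default); Y is the
    centred one-hot coding of the factor.  Deterministic: no randomness.
    """
    align_check(metabolites, sheet)
    if factor not in FACTOR_COLUMNS:
        raise SaltnetError(f"factor must be one of {sorted(FACTOR_COLUMNS)}")
    y_cat = sheet.table[FACTOR_COLUMNS[factor]]
    classes = list(y_cat.cat.categories)
    if len(classes) < 2:
        raise SaltnetError(f"factor {factor!r} has fewer than 2 levels")
    counts = y_cat.value_counts()
    small = [c for c in classes if counts.get(c, 0) < 2]
    if small:
        logger.warning("factor %s has classes with <2 samples: %s", factor, small)
    X = metabolites.values.T.astype(float)
    n, p = X.shape
    Xs = _standardize(X, scale)
    Y = np.column_stack([(y_cat == c).to_numpy(dtype=float) for c in classes])
    Yc = Y - Y.mean(axis=0)
    a = min(n_components, p, n - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls = PLSRegression(n_components=a, scale=False).fit(Xs, Yc)
    W = pls.x_weights_  # unit-norm columns
    T = pls.x_scores_
    P = pls.x_loadings_
    Q = pls.y_loadings_
    ssy = (T**2).sum(axis=0) * (Q**2).sum(axis=0)
    return PlsdaModel(
        factor=factor,
        metabolite_ids=tuple(metabolites.metabolites),
        classes=tuple(classes),
        weights=W,
        scores=T,
        x_loadings=P,
        y_loadings=Q,
        ssy=ssy,
    )


def vip_scores(model: PlsdaModel) -> pd.Series:
    """Per-metabolite VIP; satisfies sum(VIP^2) = p exactly."""
    total = model.ssy.sum()
    if total <= 0:
        raise SaltnetError("model explains no Y variance; VIP undefined")
    p = len(model.metabolite_ids)
    w2 = model.weights**2  # columns already unit norm
    vip = np.sqrt(p * (w2 @ model.ssy) / total)
    return pd.Series(vip, index=list(model.metabolite_ids), name=f"VIP_{model.factor}")


def vip_table(
    metabolites: MetaboliteMatrix,
    sheet: SampleSheet,
    factors: tuple[str, ...] = ("time", "ecotype", "stress"),
    n_components: int = 3,
    scale: bool = True,
    vip_threshold: float = 1.0,
) -> pd.DataFrame:
    """VIP scores for every factor dimension plus the VIP > threshold flags."""
    out = {}
    for f in factors:
        model = plsda_fit(metabolites, sheet, f, n_components=n_components, scale=scale)
        out[f"VIP_{f}"] = vip_scores(model)
    df = pd.DataFrame(out)
    for f in factors:
        df[f"selected_{f}"] = df[f"VIP_{f}"] > vip_threshold
    return df


def select_salt_responsive(
    vips: pd.DataFrame,
    predictable: set[str] | None = None,
    vip_threshold: float = 1.0,
) -> dict:
    """Per-factor VIP selections, their intersections (Venn counts) and,
    when a predictable set is supplied, the salt-responsive predictable set
    (VIP_stress > threshold intersected with predictable metabolites)."""
    sets: dict[str, set[str]] = {}
    for col in vips.columns:
        if col.startswith("VIP_"):
            factor = col[len("VIP_"):]
            sets[factor] = set(vips.index[vips[col] > vip_threshold])
    factors = sorted(sets)
    venn: dict[str, int] = {f: len(sets[f]) for f in factors}
    for i, f1 in enumerate(factors):
        for f2 in factors[i + 1:]:
            venn[f"{f1}&{f2}"] = len(sets[f1] & sets[f2])
    if len(factors) >= 3:
        inter_all = set.intersection(*(sets[f] for f in factors))
        venn["&".join(factors)] = len(inter_all)
    result = {"sets": sets, "venn_counts": venn}
    if "stress" in sets and predictable is not None:
        result["salt_responsive_predictable"] = sets["stress"] & set(predictable)
    return result
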