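"""LASSO-based decision algorithm for gene-metabolite network inference.

For each metabolite the algorithm:

1. keeps genes whose Pearson correlation with the metabolite is >= 0.5
   (signed by default) as candidate predictors;
2. repeats 100 times: randomly split samples 80/20, choose the LASSO
   penalty on the training set by 10-fold cross-validation with the one-
   standard-error rule over the grid 0.01, 0.02, ..., 1.00, refit at the
   chosen penalty, predict the held-out test set, and record the Pearson
   correlation r between predicted and observed values together with the
   selected (nonzero-coefficient) genes;
3. declares the metabolite *predictable* when the mean test-set r over
   valid repeats exceeds 0.8, and calls a candidate gene a *regulator*
   when it is selected in more than 50% of the valid repeats.

Regulator edges over all predictable (optionally also salt-responsive)
metabolites form a bipartite network; genes linked to 5 or more metabolites
are hub genes.

The LASSO solver minimises (1/(2n))||y - X beta||^2 + lambda * ||beta||_1
without an intercept (columns standardized, response centred) by cyclic
coordinate descent with soft-thresholding and active-set sweeps, warm-
started along the descending penalty grid.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_model import NetworkEdge, RegulatoryNetwork, SaltnetError

logger = logging.getLogger("saltnet.netlasso")

DEFAULT_LAMBDA_GRID = tuple(np.round(np.arange(1, 101) * 0.01, 10))


@dataclass(frozen=True)
class DecisionConfig:
    """All tunables of the decision algorithm (defaults follow the study
    protocol: PCC >= 0.5 prefilter, 80/20 split x 100, 10-fold CV over
    lambda in {0.01..1.00} with the one-SE rule, no intercept, r > 0.8,
    frequency > 0.5, hub degree >= 5)."""

    pcc_threshold: float = 0.5
    absolute_pcc: bool = False
    train_fraction: float = 0.8
    n_repeats: int = 100
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    n_folds: int = 10
    one_se_rule: bool = True
    r_threshold: float = 0.8
    freq_threshold: float = 0.5
    hub_degree: int = 5
    min_valid_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        grid = np.asarray(self.lambda_grid, dtype=float)
        if (np.diff(grid) <= 0).any() or (grid <= 0).any():
            raise SaltnetError("lambda grid must be strictly increasing and positive")
        if not 0 < self.train_fraction < 1:
            raise SaltnetError("train_fraction must be in (0, 1)")


# ---------------------------------------------------------------------------
# coordinate-descent LASSO
# ---------------------------------------------------------------------------


def _soft(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


def _cd_path_py(
    G: np.ndarray, b: np.ndarray, lams: np.ndarray, tol: float, max_sweeps: int
) -> np.ndarray:
    p = b.size
    beta = np.zeros(p)
    gbeta = np.zeros(p)  # G @ beta, maintained incrementally
    out = np.empty((lams.size, p))
    for li in range(lams.size):
        lam = lams[li]
        sweeps = 0
        while sweeps < max_sweeps:
            # full sweep
            delta = 0.0
            for j in range(p):
                dj = G[j, j]
                if dj <= 0.0:
                    continue
                rho = b[j] - gbeta[j] + dj * beta[j]
                new = _soft(rho, lam) / dj
                d = new - beta[j]
                if d != 0.0:
                    gbeta += G[:, j] * d
                    beta[j] = new
                    delta = max(delta, abs(d))
            sweeps += 1
            if delta < tol:
                break
            # iterate on the active set until stable
            active = np.flatnonzero(beta)
            while sweeps < max_sweeps:
                delta = 0.0
                for j in active:
                    dj = G[j, j]
                    rho = b[j] - gbeta[j] + dj * beta[j]
                    new = _soft(rho, lam) / dj
                    d = new - beta[j]
                    if d != 0.0:
                        gbeta += G[:, j] * d
                        beta[j] = new
                        delta = max(delta, abs(d))
                sweeps += 1
                if delta < tol:
                    break
        out[li] = beta
    return out


try:  # compiled kernel; the pure-Python path above is the reference fallback
    from numba import njit

    @njit(cache=True)
    def _cd_path_nb(G, b, lams, tol, max_sweeps):  # pragma: no cover
        p = b.size
        beta = np.zeros(p)
        gbeta = np.zeros(p)
        active = np.empty(p, dtype=np.int64)
        out = np.empty((lams.size, p))
        for li in range(lams.size):
            lam = lams[li]
            sweeps = 0
            while sweeps < max_sweeps:
                delta = 0.0
                for j in range(p):
                    dj = G[j, j]
                    if dj <= 0.0:
                        continue
                    rho = b[j] - gbeta[j] + dj * beta[j]
                    if rho > lam:
                        new = (rho - lam) / dj
                    elif rho < -lam:
                        new = (rho + lam) / dj
                    else:
                        new = 0.0
                    d = new - beta[j]
                    if d != 0.0:
                        for k in range(p):
                            gbeta[k] += G[k, j] * d
                        beta[j] = new
                        if abs(d) > delta:
                            delta = abs(d)
                sweeps += 1
                if delta < tol:
                    break
                na = 0
                for j in range(p):
                    if beta[j] != 0.0:
                        active[na] = j
                        na += 1
                while sweeps < max_sweeps:
                    delta = 0.0
                    for ji in range(na):
                        j = active[ji]
                        dj = G[j, j]
                        rho = b[j] - gbeta[j] + dj * beta[j]
                        if rho > lam:
                            new = (rho - lam) / dj
                        elif rho < -lam:
                            new = (rho + lam) / dj
                        else:
                            new = 0.0
                        d = new - beta[j]
                        if d != 0.0:
                            for k in range(p):
                                gbeta[k] += G[k, j] * d
                            beta[j] = new
                            if abs(d) > delta:
                                delta = abs(d)
                    sweeps += 1
                    if delta < tol:
                        break
            out[li] = beta
        return out

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _cd_path(
    G: np.ndarray,
    b: np.ndarray,
    lams: np.ndarray,
    tol: float = 1e-10,
    max_sweeps: int = 100_000,
) -> np.ndarray:
    """Coordinate-descent solution path over a DESCENDING penalty sequence.

    G = X'X/n (Gram of standardized predictors), b = X'y/n.  Returns a
    (len(lams), p) array of coefficient vectors, warm-starting each penalty
    from the previous solution.  Inner iterations sweep the active set;
    a full sweep confirms convergence (standard active-set strategy).
    """
    G = np.ascontiguousarray(G, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    lams = np.ascontiguousarray(lams, dtype=np.float64)
    if _HAVE_NUMBA:
        return _cd_path_nb(G, b, lams, tol, max_sweeps)
    return _cd_path_py(G, b, lams, tol, max_sweeps)


def solve_lasso(
    X: np.ndarray, y: np.ndarray, lam: float, tol: float = 1e-10
) -> np.ndarray:
    """Solve min (1/(2n))||y - X beta||^2 + lam ||beta||_1 (no intercept).

    X is expected standardized (mean 0, variance 1 with the 1/n convention)
    and y centred; the caller owns that preprocessing.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise SaltnetError("non-finite values in LASSO inputs")
    if lam < 0:
        raise SaltnetError("lambda must be non-negative")
    n = X.shape[0]
    G = X.T @ X / n
    b = X.T @ y / n
    return _cd_path(G, b, np.array([lam]), tol=tol)[0]


def kkt_violation(X: np.ndarray, y: np.ndarray, beta: np.ndarray, lam: float) -> float:
    """Largest violation of the LASSO stationarity conditions (0 if exact)."""
    n = X.shape[0]
    grad = X.T @ (y - X @ beta) / n
    viol = 0.0
    for j in range(beta.size):
        if beta[j] == 0.0:
            viol = max(viol, abs(grad[j]) - lam)
        else:
            viol = max(viol, abs(grad[j] - lam * np.sign(beta[j])))
    return max(viol, 0.0)


def lasso_objective(X: np.ndarray, y: np.ndarray, beta: np.ndarray, lam: float) -> float:
    n = X.shape[0]
    resid = y - X @ beta
    return float(resid @ resid / (2 * n) + lam * np.abs(beta).sum())


# ---------------------------------------------------------------------------
# standardization helpers (training statistics only)
# ---------------------------------------------------------------------------


def _train_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # 1/n convention, matching the (1/(2n)) objective
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


# ---------------------------------------------------------------------------
# prefilter
# ---------------------------------------------------------------------------


def pcc_prefilter(
    expr: pd.DataFrame,
    y: np.ndarray,
    threshold: float = 0.5,
    absolute: bool = False,
) -> pd.Series:
    """Per-gene Pearson correlation with the metabolite; keep r >= threshold
    (signed by default, |r| with ``absolute=True``).  Zero-variance genes are
    excluded with a warning."""
    y = np.asarray(y, dtype=float)
    if expr.shape[1] < 3:
        raise SaltnetError("need at least 3 samples for correlation prefilter")
    if expr.shape[1] != y.size:
        raise SaltnetError("expression and metabolite sample counts differ")
    vals = expr.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    const = sd == 0
    if const.any():
        logger.warning("excluding %d constant gene(s) from prefilter", const.sum())
    yc = y - y.mean()
    ysd = yc.std()
    if ysd == 0:
        return pd.Series(dtype=float)
    xc = vals - vals.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / (vals.shape[1] * sd * ysd)
    r[const] = np.nan
    stat = np.abs(r) if absolute else r
    keep = ~const & (stat >= threshold)
    return pd.Series(r[keep], index=expr.index[keep].astype(str), name="pcc")


# ---------------------------------------------------------------------------
# cross-validated penalty choice
# ---------------------------------------------------------------------------


def cv_select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
    n_folds: int = 10,
    one_se: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[float, pd.DataFrame]:
    """K-fold CV over the penalty grid; fold assignment by seeded shuffle.

    Each training fold is standardized with its own statistics.  With the
    one-SE rule the chosen lambda is the LARGEST grid value whose mean CV
    error is within one standard error (taken at the CV minimum) of the
    minimum mean error; the grid is scanned in descending order so ties
    resolve deterministically toward stronger regularisation.
    """
    rng = rng or np.random.default_rng()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < n_folds:
        logger.warning("n=%d < %d folds; reducing folds to n", n, n_folds)
        n_folds = n
    grid_arr = np.asarray(grid, dtype=float)
    order = np.argsort(grid_arr)[::-1]  # descending for warm starts
    lams_desc = grid_arr[order]
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    errors = np.empty((n_folds, grid_arr.size))
    for fi, val_idx in enumerate(folds):
        mask = np.ones(n, dtype=bool)
        mask[val_idx] = False
        Xtr, ytr = X[mask], y[mask]
        mean, sd = _train_stats(Xtr)
        Xs = (Xtr - mean) / sd
        ym = ytr.mean()
        G = Xs.T @ Xs / Xs.shape[0]
        b = Xs.T @ (ytr - ym) / Xs.shape[0]
        betas = _cd_path(G, b, lams_desc)
        Xv = (X[val_idx] - mean) / sd
        preds = Xv @ betas.T + ym
        errors[fi, order] = ((preds - y[val_idx][:, None]) ** 2).mean(axis=0)
    mean_err = errors.mean(axis=0)
    se_err = errors.std(axis=0, ddof=1) / np.sqrt(n_folds)
    chosen = one_se_lambda(grid_arr, mean_err, se_err) if one_se else float(
        grid_arr[int(np.argmin(mean_err))]
    )
    curve = pd.DataFrame({"lambda": grid_arr, "mean_error": mean_err, "se": se_err})
    return chosen, curve


def one_se_lambda(grid: np.ndarray, mean_err: np.ndarray, se_err: np.ndarray) -> float:
    """One-standard-error rule: largest penalty whose mean CV error is
    within one SE (taken at the CV minimum) of the minimum mean error."""
    grid = np.asarray(grid, dtype=float)
    i_min = int(np.argmin(mean_err))
    band = mean_err[i_min] + se_err[i_min]
    for i in np.argsort(grid)[::-1]:
        if mean_err[i] <= band:
            return float(grid[i])
    return float(grid[i_min])


# ---------------------------------------------------------------------------
# decision loop
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RepeatRecord:
    selected: tuple[str, ...]
    chosen_lambda: float
    r: float
    valid: bool


@dataclass(frozen=True)
class DecisionModelResult:
    """Outcome of the repeated-resampling LASSO loop for one metabolite."""

    metabolite: str
    candidate_genes: tuple[str, ...]
    repeats: tuple[RepeatRecord, ...] = ()
    status: str = "non-modelable"  # predictable | unpredictable | non-modelable | non-converged

    @property
    def n_valid(self) -> int:
        return sum(r.valid for r in self.repeats)

    @property
    def mean_r(self) -> float:
        rs = [r.r for r in self.repeats if r.valid]
        return float(np.mean(rs)) if rs else float("nan")

    @property
    def gene_frequency(self) -> dict[str, float]:
        nv = self.n_valid
        if nv == 0:
            return {}
        counts: dict[str, int] = {}
        for rec in self.repeats:
            if rec.valid:
                for g in rec.selected:
                    counts[g] = counts.get(g, 0) + 1
        return {g: c / nv for g, c in counts.items()}


def decision_loop(
    expr: pd.DataFrame,
    y: np.ndarray,
    metabolite: str,
    config: DecisionConfig,
    rng: np.random.Generator,
) -> DecisionModelResult:
    """Run the full per-metabolite loop of the decision algorithm."""
    y = np.asarray(y, dtype=float)
    cand = pcc_prefilter(
        expr, y, threshold=config.pcc_threshold, absolute=config.absolute_pcc
    )
    if cand.empty:
        return DecisionModelResult(metabolite=metabolite, candidate_genes=())
    genes = tuple(cand.index)
    X_full = expr.loc[list(genes)].to_numpy(dtype=float).T  # samples x p
    n = X_full.shape[0]
    n_train = int(round(config.train_fraction * n))
    n_test = n - n_train
    if n_test < 3:
        raise SaltnetError(
            f"test split has {n_test} samples (<3); more samples are needed"
        )
    records: list[RepeatRecord] = []
    for _ in range(config.n_repeats):
        perm = rng.permutation(n)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        Xtr, ytr = X_full[train_idx], y[train_idx]
        lam, _ = cv_select_lambda(
            Xtr,
            ytr,
            grid=config.lambda_grid,
            n_folds=config.n_folds,
            one_se=config.one_se_rule,
            rng=rng,
        )
        mean, sd = _train_stats(Xtr)
        Xs = (Xtr - mean) / sd
        ym = ytr.mean()
        beta = solve_lasso(Xs, ytr - ym, lam)
        pred = (X_full[test_idx] - mean) / sd @ beta + ym
        valid = bool(np.isfinite(pred).all() and np.std(pred) > 0)
        if valid:
            r = float(np.corrcoef(pred, y[test_idx])[0, 1])
            valid = np.isfinite(r)
        else:
            r = float("nan")
        selected = tuple(g for g, bb in zip(genes, beta) if bb != 0.0)
        records.append(RepeatRecord(selected, lam, r, valid))
    result = DecisionModelResult(
        metabolite=metabolite, candidate_genes=genes, repeats=tuple(records)
    )
    if result.n_valid < config.min_valid_fraction * config.n_repeats:
        status = "non-converged"
    elif result.mean_r > config.r_threshold:
        status = "predictable"
    else:
        status = "unpredictable"
    return replace(result, status=status)


def metabolite_rng(master_seed: int, metabolite: str) -> np.random.Generator:
    """Deterministic per-metabolite substream, independent of processing
    order: the metabolite id is hashed into the seed sequence."""
    digest = hashlib.sha256(metabolite.encode()).digest()
    sub = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence((master_seed, sub)))


def run_decision_algorithm(
    expr: pd.DataFrame,
    metabolites: pd.DataFrame,
    config: DecisionConfig,
) -> list[DecisionModelResult]:
    """Decision loop over every metabolite (rows of ``metabolites``), with
    per-metabolite seeded substreams derived from ``config.seed``."""
    if list(expr.columns) != list(metabolites.columns):
        raise SaltnetError("expression and metabolite matrices are not sample-aligned")
    results = []
    for met in metabolites.index.astype(str):
        rng = metabolite_rng(config.seed, met)
        results.append(
            decision_loop(expr, metabolites.loc[met].to_numpy(), met, config, rng)
        )
    return results


# ---------------------------------------------------------------------------
# classification and network assembly
# ---------------------------------------------------------------------------


def classify_and_select(
    results: list[DecisionModelResult], config: DecisionConfig
) -> tuple[set[str], dict[str, dict[str, float]]]:
    """Predictable metabolites (mean r strictly > 0.8) and their regulator
    genes (selection frequency strictly > 0.5)."""
    predictable: set[str] = set()
    regulators: dict[str, dict[str, float]] = {}
    for res in results:
        if res.status != "predictable":
            continue
        predictable.add(res.metabolite)
        regulators[res.metabolite] = {
            g: f for g, f in res.gene_frequency.items() if f > config.freq_threshold
        }
    return predictable, regulators


def assemble_network(
    regulators: dict[str, dict[str, float]],
    results: list[DecisionModelResult],
    vip_stress: pd.Series | None = None,
    hub_degree: int = 5,
    vip_threshold: float = 1.0,
) -> RegulatoryNetwork:
    """Bipartite gene-metabolite network over predictable metabolites,
    optionally restricted to salt-responsive ones (VIP_stress > threshold).
    Hub genes are linked to ``hub_degree`` or more metabolites."""
    mean_r = {r.metabolite: r.mean_r for r in results}
    edges = []
    for met, genes in sorted(regulators.items()):
        if vip_stress is not None:
            if met not in vip_stress.index or vip_stress[met] <= vip_threshold:
                continue
        for g, freq in sorted(genes.items()):
            edges.append(NetworkEdge(g, met, float(freq), float(mean_r[met])))
    return RegulatoryNetwork(tuple(edges), hub_degree=hub_degree)


def results_table(results: list[DecisionModelResult]) -> pd.DataFrame:
    """Per-metabolite summary of the decision loop."""
    return pd.DataFrame(
        {
            "metabolite": [r.metabolite for r in results],
            "n_candidates": [len(r.candidate_genes) for r in results],
            "n_valid": [r.n_valid for r in results],
            "mean_r": [r.mean_r for r in results],
            "status": [r.status for r in results],
        }
    )


def frequency_table(results: list[DecisionModelResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for g, f in sorted(res.gene_frequency.items()):
            rows.append({"metabolite": res.metabolite, "gene": g, "frequency": f})
    return pd.DataFrame(rows, columns=["metabolite", "gene", "frequency"])
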