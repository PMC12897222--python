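"""PLS-driven wavelength selection: CARS, SPA, UVE, IRIV and SPA chaining.

Four complementary strategies for pruning a highly collinear NIR band set
down to the informative wavelengths, all scored by the pooled k-fold
RMSECV of a PLS1 regression on the class code:

* CARS — Monte-Carlo competitive adaptive reweighted sampling: an
  exponentially decreasing enforced-retention schedule plus weighted
  resampling by |PLS coefficient|, keeping the subset with minimal RMSECV.
* SPA — successive projections: forward chains that, at each step, add
  the band with the largest norm orthogonal to the span of the already
  selected bands, minimising collinearity.
* UVE — uninformative variable elimination: bands whose coefficient
  stability (mean/sd across cross-validation refits) does not beat a
  quantile of the stability of appended artificial-noise bands are dropped.
* IRIV — iterative retention of informative variables: random binary
  inclusion matrices classify each band as strongly/weakly informative,
  uninformative or interfering; informative bands are retained and the
  procedure iterates, ending with a backward elimination pass.

Chained variants (cars_spa, uve_spa, iriv_spa) run SPA on the survivors
of a first-stage selector.  Every selector is deterministic given
(X, y, params, seed).
"""

from __future__ import annotations

import logging
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional

import numpy as np
from scipy.stats import ranksums

from .core import ParameterError, WavelengthGrid
from .pls import CVPlan, cv_pairs, fit_pls, rmsecv

log = logging.getLogger(__name__)

METHODS = ("cars", "spa", "uve", "iriv", "cars_spa", "uve_spa", "iriv_spa")


@dataclass
class SelectionResult:
    """Outcome of one selector run, with full RNG/parameter provenance."""

    method: str
    selected: np.ndarray          # ordered unique band indices (0-based)
    selected_nm: np.ndarray       # wavelengths of the selected bands
    trace: list                   # per-iteration records
    seed: Optional[int]
    params: dict
    rmsecv: Optional[float] = None  # RMSECV of the selected subset

    def __post_init__(self):
        self.selected = np.asarray(self.selected, dtype=int)
        self.selected_nm = np.asarray(self.selected_nm, dtype=float)
        if np.unique(self.selected).size != self.selected.size:
            raise ParameterError("selected indices must be unique")

    @property
    def n_selected(self) -> int:
        return int(self.selected.size)

    def to_json(self, path=None) -> str:
        payload = {
            "method": self.method,
            "selected": self.selected.tolist(),
            "selected_nm": [round(float(w), 1) for w in self.selected_nm],
            "trace": self.trace,
            "seed": self.seed,
            "params": self.params,
            "rmsecv": self.rmsecv,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _nm(grid: Optional[WavelengthGrid], idx: np.ndarray) -> np.ndarray:
    if grid is None:
        return np.asarray(idx, dtype=float)
    return grid.nm[np.asarray(idx, dtype=int)]


# --------------------------------------------------------------------------
# CARS
# --------------------------------------------------------------------------

def cars_schedule(n_bands: int, n_runs: int) -> np.ndarray:
    """Enforced retention counts ceil(B * r_i) for runs i = 1..n_runs.

    The retention ratio decays exponentially, r_i = a * exp(-k i), with
    the closed-form constants fixed by r_1 = 1 (keep everything on the
    first run) and r_N = 2/B (keep two bands on the last): this is the
    "rapid elimination then fine optimisation" schedule.
    """
    if n_bands < 2 or n_runs < 2:
        raise ParameterError("need n_bands >= 2 and n_runs >= 2")
    k = math.log(n_bands / 2.0) / (n_runs - 1)
    a = math.exp(k)  # so that a * exp(-k * 1) = 1
    i = np.arange(1, n_runs + 1)
    r = a * np.exp(-k * i)
    # round-before-ceil guards against exp/log round-off at the endpoints
    return np.ceil(np.round(n_bands * r, 9)).astype(int)


def cars(X, y, n_runs: int = 50, max_pc: int = 8,
         plan: CVPlan = CVPlan(n_folds=10), subset_frac: float = 0.8,
         ars_oversample: int = 5, seed: int = 0,
         grid: Optional[WavelengthGrid] = None) -> SelectionResult:
    """Competitive adaptive reweighted sampling.

    Each Monte-Carlo run fits a PLS model (component count chosen by
    RMSECV, capped at ``max_pc``) on a random ``subset_frac`` of the
    samples, weights every surviving band by its normalised |coefficient|,
    applies the exponentially decreasing enforced-retention schedule via
    adaptive reweighted sampling, and records the RMSECV of the surviving
    band set on the full data.  The run with minimal RMSECV wins.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, B = X.shape
    if B < 2:
        raise ParameterError("CARS needs at least 2 bands")
    if not (0 < subset_frac <= 1):
        raise ParameterError("subset_frac must be in (0, 1]")
    rng = np.random.default_rng(seed)
    counts = cars_schedule(B, n_runs)
    current = np.arange(B)
    trace = []
    best = None  # (rmsecv, best_a, indices)
    n_sub = max(2, int(round(subset_frac * n)))
    for i in range(1, n_runs + 1):
        sub = rng.choice(n, size=n_sub, replace=False)
        if np.ptp(y[sub]) == 0:  # degenerate draw, redraw deterministic-ly
            sub = rng.choice(n, size=n_sub, replace=False)
        a_cap = min(max_pc, len(current), n_sub - 1)
        cv_sub = rmsecv(X[np.ix_(sub, current)], y[sub], a_cap, plan)
        model = fit_pls(X[np.ix_(sub, current)], y[sub], cv_sub.best_a)
        w = np.abs(model.b)
        if w.sum() == 0:
            w = np.ones_like(w)
        w = w / w.sum()
        n_keep = min(counts[i - 1], len(current))
        # adaptive reweighted sampling: weighted draws with replacement,
        # unique survivors, truncated to the enforced count by weight
        draws = rng.choice(len(current), size=n_keep * ars_oversample,
                           replace=True, p=w)
        uniq = np.unique(draws)
        order = uniq[np.argsort(-w[uniq], kind="stable")]
        kept = np.sort(current[order[:n_keep]])
        if kept.size < 2:
            log.warning("cars: run %d left <2 bands, stopping early", i)
            break
        current = kept
        a_cap = min(max_pc, len(current), n - max(1, n // plan.n_folds) - 1)
        cv = rmsecv(X[:, current], y, a_cap, plan)
        trace.append({"run": i, "n_vars": int(current.size),
                      "rmsecv": cv.best_rmsecv, "best_a": cv.best_a})
        if best is None or cv.best_rmsecv < best[0]:
            best = (cv.best_rmsecv, cv.best_a, current.copy())
    if best is None:
        raise ParameterError("CARS produced no evaluable subset")
    params = {"n_runs": n_runs, "max_pc": max_pc, "n_folds": plan.n_folds,
              "cv_seed": plan.seed, "subset_frac": subset_frac,
              "ars_oversample": ars_oversample}
    return SelectionResult(method="cars", selected=best[2],
                           selected_nm=_nm(grid, best[2]), trace=trace,
                           seed=seed, params=params, rmsecv=best[0])


# --------------------------------------------------------------------------
# SPA
# --------------------------------------------------------------------------

def spa_chain(X: np.ndarray, start: int, length: int) -> np.ndarray:
    """Successive-projections chain from one starting column.

    At every step each unselected column is projected onto the orthogonal
    complement of the span of the selected columns and the column with the
    largest residual norm is added; ties break to the lowest band index.
    The chain truncates early if all residual norms fall below 1e-12
    (collinear exhaustion).
    """
    X = np.asarray(X, dtype=float)
    B = X.shape[1]
    chain = [start]
    # residuals of all columns against the growing orthonormal basis
    R = X.copy()
    basis_vec = X[:, start].copy()
    for _ in range(length - 1):
        nb = np.linalg.norm(basis_vec)
        if nb < 1e-12:
            log.warning("spa: collinear exhaustion, chain truncated at %d",
                        len(chain))
            break
        u = basis_vec / nb
        R = R - np.outer(R.T @ u, u).T
        norms = np.linalg.norm(R, axis=0)
        norms[chain] = -1.0
        best = int(np.argmax(norms))  # argmax returns the lowest tying index
        if norms[best] < 1e-12:
            log.warning("spa: collinear exhaustion, chain truncated at %d",
                        len(chain))
            break
        chain.append(best)
        basis_vec = R[:, best].copy()
    return np.asarray(chain, dtype=int)


def spa(X, y, n_min: int = 5, n_max: Optional[int] = None,
        plan: CVPlan = CVPlan(n_folds=10), max_pc: int = 10,
        grid: Optional[WavelengthGrid] = None) -> SelectionResult:
    """Successive projections algorithm.

    Builds a projection chain from every starting band, evaluates each
    (start, length) prefix with length in [n_min, n_max] by PLS-RMSECV,
    and returns the global minimiser.  Deterministic: no randomness
    beyond the cross-validation plan's fixed seed.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, B = X.shape
    if n_max is None:
        n_max = min(30, n - 2, B)
    n_max = min(n_max, B, n - 2)
    if not 1 <= n_min <= n_max:
        raise ParameterError(f"need 1 <= n_min <= n_max, got {n_min}..{n_max}")
    strat = y if np.unique(y).size == 2 else None
    folds = plan.folds(n, strat)
    best = None  # (rmsecv, best_a, indices)
    trace = []
    for start in range(B):
        chain = spa_chain(X, start, n_max)
        for length in range(n_min, chain.size + 1):
            sel = chain[:length]
            cv = rmsecv(X[:, sel], y, min(max_pc, length), folds=folds)
            if best is None or cv.best_rmsecv < best[0]:
                best = (cv.best_rmsecv, cv.best_a, np.sort(sel))
                trace.append({"start": start, "length": length,
                              "rmsecv": cv.best_rmsecv})
    params = {"n_min": n_min, "n_max": int(n_max), "max_pc": max_pc,
              "n_folds": plan.n_folds, "cv_seed": plan.seed}
    return SelectionResult(method="spa", selected=best[2],
                           selected_nm=_nm(grid, best[2]), trace=trace,
                           seed=None, params=params, rmsecv=best[0])


# --------------------------------------------------------------------------
# UVE
# --------------------------------------------------------------------------

def uve(X, y, max_pc: int = 8, plan: CVPlan = CVPlan(n_folds=10),
        noise_count: Optional[int] = None, threshold_quantile: float = 0.99,
        seed: int = 0, grid: Optional[WavelengthGrid] = None) -> SelectionResult:
    """Uninformative variable elimination.

    The spectra are augmented with ``noise_count`` artificial uniform
    noise bands (scaled to 1e-10 of the data magnitude so they cannot
    influence the fit).  PLS models with ``max_pc`` latent variables are
    refitted across the plan's deletion groups (leave-one-fold-out);
    each band's stability is c_j = mean(b_j) / sd(b_j) over the refits.
    Real bands are kept when |c_j| exceeds the ``threshold_quantile``
    quantile of |c| over the noise bands (a symmetric threshold).

    The deletion-group models are fitted at the full ``max_pc`` order
    rather than an RMSECV-chosen one: the stability contrast needs
    enough latent variables to localise coefficients onto individual
    informative bands, and a parsimonious model constrains the
    coefficient vector to a low-dimensional smooth subspace in which
    every band inherits stable chance structure.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, B = X.shape
    if noise_count is None:
        noise_count = B
    if noise_count < 1:
        raise ParameterError("noise_count must be >= 1")
    rng = np.random.default_rng(seed)
    scale = 1e-10 * float(np.max(np.abs(X)) or 1.0)
    noise = rng.uniform(0.0, 1.0, size=(n, noise_count)) * scale
    Xa = np.hstack([X, noise])
    strat = y if np.unique(y).size == 2 else None
    folds = plan.folds(n, strat)
    min_train = n - max(f.size for f in folds)
    a_pick = int(min(max_pc, B, min_train - 1))
    coefs = np.empty((len(folds), B + noise_count))
    for g, test_idx in enumerate(folds):
        train = np.setdiff1d(np.arange(n), test_idx)
        coefs[g] = fit_pls(Xa[train], y[train], a_pick).b
    mean_b = coefs.mean(axis=0)
    sd_b = coefs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(sd_b == 0, np.inf, mean_b / sd_b)
    if np.any(sd_b == 0):
        log.warning("uve: %d band(s) with sd(b)=0, stability set to +inf",
                    int((sd_b == 0).sum()))
    thr = float(np.quantile(np.abs(c[B:]), threshold_quantile))
    keep = np.where(np.abs(c[:B]) > thr)[0]
    sub_cv = (rmsecv(X[:, keep], y, min(max_pc, keep.size), folds=folds)
              if keep.size >= 1 else None)
    trace = [{"threshold": thr, "a": a_pick, "n_kept": int(keep.size),
              "stability_real_max": float(np.nanmax(np.abs(c[:B])))}]
    params = {"max_pc": max_pc, "n_folds": plan.n_folds, "cv_seed": plan.seed,
              "noise_count": int(noise_count),
              "threshold_quantile": threshold_quantile}
    return SelectionResult(method="uve", selected=keep,
                           selected_nm=_nm(grid, keep), trace=trace, seed=seed,
                           params=params,
                           rmsecv=None if sub_cv is None else sub_cv.best_rmsecv)


def uve_stability(X, y, max_pc: int = 8, plan: CVPlan = CVPlan(n_folds=10)):
    """Stability vector mean(b)/sd(b) of the real bands alone (no noise).

    Exposed for diagnostics and oracle tests.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, B = X.shape
    strat = y if np.unique(y).size == 2 else None
    folds = plan.folds(n, strat)
    min_train = n - max(f.size for f in folds)
    a_pick = int(min(max_pc, B, min_train - 1))
    coefs = np.empty((len(folds), B))
    for g, test_idx in enumerate(folds):
        train = np.setdiff1d(np.arange(n), test_idx)
        coefs[g] = fit_pls(X[train], y[train], a_pick).b
    sd_b = coefs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(sd_b == 0, np.inf, coefs.mean(axis=0) / sd_b)


# --------------------------------------------------------------------------
# IRIV
# --------------------------------------------------------------------------

def _iriv_classify(rmse_rows: np.ndarray, M: np.ndarray, alpha: float):
    """Classify each variable from one binary-inclusion round.

    DMEAN_j = mean RMSECV of rows excluding j minus rows including j:
    positive means including the variable helps.  Significance by the
    two-sided Wilcoxon rank-sum test.  Returns (dmean, pvals, category)
    with categories 'strong', 'weak', 'uninformative', 'interfering'.
    """
    m, p = M.shape
    dmean = np.empty(p)
    pvals = np.empty(p)
    cats = np.empty(p, dtype=object)
    for j in range(p):
        inc = rmse_rows[M[:, j] == 1]
        exc = rmse_rows[M[:, j] == 0]
        dmean[j] = exc.mean() - inc.mean()
        pvals[j] = ranksums(exc, inc).pvalue
        if dmean[j] > 0:
            cats[j] = "strong" if pvals[j] < alpha else "weak"
        else:
            cats[j] = "interfering" if pvals[j] < alpha else "uninformative"
    return dmean, pvals, cats


def iriv(X, y, max_pc: int = 40, plan: CVPlan = CVPlan(n_folds=11),
         m_rows: int = 500, alpha: float = 0.05, seed: int = 0,
         grid: Optional[WavelengthGrid] = None) -> SelectionResult:
    """Iterative retention of informative variables.

    Each round draws an ``m_rows`` x p binary inclusion matrix
    (inclusion probability 0.5), scores every row-subset by RMSECV, and
    classifies each variable by comparing the RMSECV distributions of
    rows excluding vs including it.  Strongly and weakly informative
    variables are retained; rounds repeat until no variable is dropped,
    then a backward elimination removes any variable whose deletion
    lowers the subset RMSECV.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, B = X.shape
    if m_rows < 50:
        raise ParameterError("m_rows must be >= 50")
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    rng = np.random.default_rng(seed)
    strat = y if np.unique(y).size == 2 else None
    folds = plan.folds(n, strat)
    pairs = cv_pairs(n, folds)
    current = np.arange(B)
    trace = []
    iteration = 0
    while True:
        iteration += 1
        p = current.size
        M = rng.integers(0, 2, size=(m_rows, p))
        # rows need >= 2 included variables to be evaluable
        deficient = M.sum(axis=1) < 2
        while deficient.any():
            M[deficient] = rng.integers(0, 2, size=(int(deficient.sum()), p))
            deficient = M.sum(axis=1) < 2
        rmse_rows = np.empty(m_rows)
        for r in range(m_rows):
            cols = current[M[r] == 1]
            cv = rmsecv(X[:, cols], y, min(max_pc, cols.size), pairs=pairs)
            rmse_rows[r] = cv.best_rmsecv
        dmean, pvals, cats = _iriv_classify(rmse_rows, M, alpha)
        keep_mask = (cats == "strong") | (cats == "weak")
        retained = current[keep_mask]
        trace.append({"iteration": iteration, "n_vars": int(p),
                      "n_strong": int((cats == "strong").sum()),
                      "n_weak": int((cats == "weak").sum()),
                      "n_retained": int(retained.size),
                      "mean_rmsecv": float(rmse_rows.mean())})
        if retained.size == 0:
            log.warning("iriv: no informative variables retained")
            return SelectionResult(
                method="iriv", selected=retained, selected_nm=_nm(grid, retained),
                trace=trace, seed=seed,
                params={"max_pc": max_pc, "n_folds": plan.n_folds,
                        "cv_seed": plan.seed, "m_rows": m_rows, "alpha": alpha})
        if retained.size == current.size:
            current = retained
            break
        current = retained
        if current.size <= 2:
            break

    # backward elimination: drop any variable whose removal lowers RMSECV
    def subset_rmsecv(cols):
        return rmsecv(X[:, cols], y, min(max_pc, cols.size),
                      pairs=pairs).best_rmsecv

    best_rmse = subset_rmsecv(current)
    improved = True
    while improved and current.size > 2:
        improved = False
        drop_rmse = np.array([subset_rmsecv(np.delete(current, j))
                              for j in range(current.size)])
        j_best = int(np.argmin(drop_rmse))
        if drop_rmse[j_best] < best_rmse:
            current = np.delete(current, j_best)
            best_rmse = float(drop_rmse[j_best])
            improved = True
    trace.append({"backward_final_n": int(current.size),
                  "rmsecv": float(best_rmse)})
    params = {"max_pc": max_pc, "n_folds": plan.n_folds, "cv_seed": plan.seed,
              "m_rows": m_rows, "alpha": alpha}
    return SelectionResult(method="iriv", selected=np.sort(current),
                           selected_nm=_nm(grid, np.sort(current)),
                           trace=trace, seed=seed, params=params,
                           rmsecv=float(best_rmse))


# --------------------------------------------------------------------------
# Chaining
# --------------------------------------------------------------------------

def chain(first: SelectionResult, then: Callable, X, y,
          grid: Optional[WavelengthGrid] = None, **then_kwargs) -> SelectionResult:
    """Run a second selector on the bands surviving a first stage.

    ``then`` is called on the column-subset matrix and its indices are
    mapped back to the original grid; the method tag becomes
    '<first>_<second>' (e.g. cars_spa).
    """
    if first.n_selected == 0:
        raise ParameterError("cannot chain from an empty first-stage selection")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    sub = X[:, first.selected]
    second = then(sub, y, **then_kwargs)
    mapped = first.selected[second.selected]
    order = np.argsort(mapped)
    result = SelectionResult(
        method=f"{first.method}_{second.method}",
        selected=mapped[order],
        selected_nm=_nm(grid, mapped[order]),
        trace=[{"stage": first.method, "n": first.n_selected},
               {"stage": second.method, "n": second.n_selected}],
        seed=first.seed,
        params={"first": first.params, "second": second.params},
        rmsecv=second.rmsecv)
    return result


def run_selector(method: str, X, y, grid: Optional[WavelengthGrid] = None,
                 seed: int = 0, **kwargs) -> SelectionResult:
    """Dispatch a selector (or SPA-chained combination) by name."""
    if method not in METHODS:
        raise ParameterError(f"unknown selector {method!r}; one of {METHODS}")
    if method == "cars":
        return cars(X, y, seed=seed, grid=grid, **kwargs)
    if method == "spa":
        return spa(X, y, grid=grid, **kwargs)
    if method == "uve":
        return uve(X, y, seed=seed, grid=grid, **kwargs)
    if method == "iriv":
        return iriv(X, y, seed=seed, grid=grid, **kwargs)
    first_name = method.split("_")[0]
    spa_keys = {"n_min", "n_max", "plan", "max_pc"}
    first_kwargs = {k: v for k, v in kwargs.items() if k not in spa_keys}
    spa_kwargs = {k: v for k, v in kwargs.items() if k in spa_keys}
    first = run_selector(first_name, X, y, grid=grid, seed=seed, **first_kwargs)
    return chain(first, spa, X, y, grid=grid, **spa_kwargs)
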