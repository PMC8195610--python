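"""Multinomial discriminant analysis of four-class categorization responses.

Observers assign each stimulus of the (e, s) style lattice to one of four
classes (1 human-angry, 2 human-fear, 3 monkey-threat, 4 monkey-fear). The
class probabilities are modeled by a softmax (multinomial logistic) GLM

    P_i(e, s) = exp(y_i) / Σ_j exp(y_j),   y_j = β0j + β1j·X1 + … + βNj·XN

with class 4 (monkey-fear) as the zero-coefficient reference. Candidate
predictor sets {1}, {1,e}, {1,s}, {1,e,s}, {1,e,s,e·s}, {1,e,s,flow} are
compared by in-sample argmax accuracy and BIC; a larger model is kept only if
accuracy does not decrease and BIC does not increase, which singles out the
most compact adequate model.

Fitting is delegated to statsmodels' MNLogit; a lightly ridge-penalized
(1e-6) direct optimization serves as fallback when responses are completely
separated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import statsmodels.api as sm

__all__ = [
    "DiscriminantModel",
    "PREDICTOR_CHOICES",
    "DEFAULT_CANDIDATE_SETS",
    "build_design",
    "fit_multinomial",
    "predict_probabilities",
    "predict_surface",
    "stepwise_compare",
    "attach_flow",
    "cell_histograms",
]

PREDICTOR_CHOICES = ("1", "e", "s", "e*s", "flow")

DEFAULT_CANDIDATE_SETS = (
    ("1",),
    ("1", "e"),
    ("1", "s"),
    ("1", "e", "s"),
    ("1", "e", "s", "e*s"),
    ("1", "e", "s", "flow"),
)

_REQUIRED_COLUMNS = ("participant_id", "avatar", "view_deg", "e", "s", "rep", "response_class")


@dataclass(frozen=True)
class DiscriminantModel:
    """Fitted softmax discriminant model.

    ``beta`` has shape (n_predictors, 4); column j holds the coefficients of
    class j+1 and the reference column (class 4) is identically zero.
    """

    beta: np.ndarray
    predictor_names: tuple[str, ...]
    log_likelihood: float
    n_obs: int
    bic: float
    accuracy: float
    converged: bool = True
    separation_flag: bool = False
    beta_se: np.ndarray | None = None

    @property
    def n_free_coefficients(self) -> int:
        return len(self.predictor_names) * 3


def _validate_responses(responses: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED_COLUMNS if c not in responses.columns]
    if missing:
        raise ValueError(f"response table lacks columns: {missing}")
    if len(responses) == 0:
        raise ValueError("response table is empty")
    bad = ~responses["response_class"].isin([1, 2, 3, 4])
    if bad.any():
        raise ValueError(
            f"response_class outside 1..4 in rows {responses.index[bad].tolist()[:5]}"
        )
    return responses


def build_design(
    responses: pd.DataFrame, predictor_set: tuple[str, ...]
) -> np.ndarray:
    """Design-matrix columns for the requested predictors, in the given order."""
    cols = []
    for name in predictor_set:
        if name == "1":
            cols.append(np.ones(len(responses)))
        elif name in ("e", "s"):
            cols.append(responses[name].to_numpy(dtype=float))
        elif name == "e*s":
            cols.append((responses["e"] * responses["s"]).to_numpy(dtype=float))
        elif name == "flow":
            if "flow" not in responses.columns:
                raise ValueError(
                    "predictor 'flow' requested but the response table has no "
                    "'flow' column; attach one with attach_flow()"
                )
            cols.append(responses["flow"].to_numpy(dtype=float))
        else:
            raise ValueError(f"unknown predictor {name!r}; choose from {PREDICTOR_CHOICES}")
    return np.column_stack(cols)


def _softmax_rows(y: np.ndarray) -> np.ndarray:
    y = y - y.max(axis=1, keepdims=True)
    p = np.exp(y)
    return p / p.sum(axis=1, keepdims=True)


def _ridge_softmax_fit(X: np.ndarray, codes: np.ndarray, ridge: float = 1e-6) -> np.ndarray:
    """Direct penalized MLE used when the likelihood has no finite maximum
    (complete separation). Returns params (n_predictors, 3) for codes 1..3."""
    n, k = X.shape
    onehot = np.zeros((n, 4))
    onehot[np.arange(n), codes] = 1.0

    def negll(flat):
        b = flat.reshape(k, 3)
        y = np.column_stack([np.zeros(n), X @ b])
        p = _softmax_rows(y)
        ll = np.sum(onehot * np.log(np.clip(p, 1e-300, None)))
        return -(ll - 0.5 * ridge * np.sum(b**2))

    def grad(flat):
        b = flat.reshape(k, 3)
        y = np.column_stack([np.zeros(n), X @ b])
        p = _softmax_rows(y)
        g = X.T @ (p[:, 1:] - onehot[:, 1:])
        return (g + ridge * b).ravel()

    res = scipy.optimize.minimize(
        negll, np.zeros(k * 3), jac=grad, method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    return res.x.reshape(k, 3)


def fit_multinomial(
    responses: pd.DataFrame,
    predictor_set: tuple[str, ...] = ("1", "e", "s"),
    expected_cells: list[tuple[float, float]] | None = None,
) -> DiscriminantModel:
    """Maximum-likelihood softmax fit of the response table.

    ``predictor_set`` must include the constant "1". BIC is
    k·ln(n) − 2·lnL with k the free coefficients (3 per predictor); accuracy
    is the in-sample fraction of trials whose observed class equals the
    argmax of the fitted probabilities at the trial's predictors.
    """
    responses = _validate_responses(responses)
    if "1" not in predictor_set:
        raise ValueError("predictor_set must include the constant predictor '1'")
    if expected_cells is not None:
        present = set(map(tuple, responses[["e", "s"]].drop_duplicates().to_numpy()))
        empty = [c for c in expected_cells if tuple(c) not in present]
        if empty:
            raise ValueError(f"designed cells without observations: {empty}")

    X = build_design(responses, predictor_set)
    # class 4 → code 0 so that monkey-fear is MNLogit's reference category
    codes = responses["response_class"].to_numpy() % 4
    separation = False
    params = None
    params_se = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            model = sm.MNLogit(codes, X)
            res = model.fit(method="newton", maxiter=200, disp=False)
            params = np.asarray(res.params)  # (k, 3) for codes 1..3
            params_se = np.asarray(res.bse).reshape(params.shape, order="F")
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            params, converged = None, False
        if params is not None and (
            not np.all(np.isfinite(params)) or np.abs(params).max() > 50.0
        ):
            params = None
        if any("separation" in str(w.message).lower() for w in caught):
            separation = True
    if params is None:
        separation = True
        params = _ridge_softmax_fit(X, codes)
        params_se = None
        converged = True

    # assemble beta in class order 1..4 (reference class 4 = zeros)
    k = X.shape[1]
    beta = np.zeros((k, 4))
    beta[:, 0:3] = params  # MNLogit columns are codes 1,2,3 = classes 1,2,3
    y = np.column_stack([X @ beta[:, j] for j in range(4)])
    p = _softmax_rows(y)
    onehot_idx = responses["response_class"].to_numpy() - 1
    llf = float(np.log(np.clip(p[np.arange(len(p)), onehot_idx], 1e-300, None)).sum())
    n = len(responses)
    bic = float(3 * k * np.log(n) - 2.0 * llf)
    accuracy = float(np.mean(np.argmax(p, axis=1) == onehot_idx))
    beta_se = None
    if params_se is not None and np.all(np.isfinite(params_se)):
        beta_se = np.zeros((k, 4))
        beta_se[:, 0:3] = params_se
    return DiscriminantModel(
        beta=beta,
        predictor_names=tuple(predictor_set),
        log_likelihood=llf,
        n_obs=n,
        bic=bic,
        accuracy=accuracy,
        converged=converged,
        separation_flag=separation,
        beta_se=beta_se,
    )


def predict_probabilities(
    model: DiscriminantModel, e: np.ndarray, s: np.ndarray
) -> np.ndarray:
    """Class probabilities P_1..P_4 at style coordinates (e, s).

    Non-style predictors (e·s is derived; flow is z-scored across the grid)
    are evaluated at e·s and 0 respectively.
    """
    e = np.asarray(e, dtype=float).ravel()
    s = np.asarray(s, dtype=float).ravel()
    cols = []
    for name in model.predictor_names:
        if name == "1":
            cols.append(np.ones_like(e))
        elif name == "e":
            cols.append(e)
        elif name == "s":
            cols.append(s)
        elif name == "e*s":
            cols.append(e * s)
        else:  # flow and other stimulus covariates held at their (z-scored) mean
            cols.append(np.zeros_like(e))
    X = np.column_stack(cols)
    return _softmax_rows(X @ model.beta)


def predict_surface(model: DiscriminantModel, grid_resolution: int = 101) -> dict:
    """Class-probability surfaces on an equidistant grid over [0,1]².

    Returns ``{"e": axis, "s": axis, "P": (4, n_s, n_e)}`` with
    ``P[j, i_s, i_e] = P_{j+1}(e[i_e], s[i_s])``; rows sum to one everywhere.
    """
    axis = np.linspace(0.0, 1.0, grid_resolution)
    ee, ss = np.meshgrid(axis, axis)  # (n_s, n_e)
    p = predict_probabilities(model, ee.ravel(), ss.ravel())
    P = p.T.reshape(4, grid_resolution, grid_resolution)
    return {"e": axis, "s": axis, "P": P}


def stepwise_compare(
    responses: pd.DataFrame,
    candidate_sets: tuple[tuple[str, ...], ...] = DEFAULT_CANDIDATE_SETS,
) -> tuple[pd.DataFrame, DiscriminantModel]:
    """Fit candidate predictor sets in order and apply the discard rule.

    Starting from the first candidate, each subsequent model is accepted only
    if its accuracy does not decrease *and* its BIC does not increase
    relative to the best accepted model so far; the final best accepted model
    is the most compact adequate one. Returns the comparison table and that
    model.
    """
    if len(candidate_sets) == 0:
        raise ValueError("need at least one candidate predictor set")
    rows = []
    models = []
    best_idx = 0
    for i, pset in enumerate(candidate_sets):
        m = fit_multinomial(responses, tuple(pset))
        models.append(m)
        if i == 0:
            accepted = True
        else:
            best = models[best_idx]
            accepted = m.accuracy >= best.accuracy and m.bic <= best.bic
        if accepted:
            best_idx = i
        rows.append(
            {
                "predictors": "+".join(pset),
                "n_predictors": len(pset),
                "log_likelihood": m.log_likelihood,
                "bic": m.bic,
                "accuracy": m.accuracy,
                "accepted": accepted,
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["selected"] = rows[best_idx]["predictors"]
    return table, models[best_idx]


def attach_flow(responses: pd.DataFrame, flow_by_cell: dict[tuple[float, float], float]) -> pd.DataFrame:
    """Join a per-stimulus optic-flow value to trials by (e, s) cell,
    z-scored across the lattice, as the 'flow' predictor column."""
    cells = list(flow_by_cell)
    vals = np.array([flow_by_cell[c] for c in cells], dtype=float)
    sd = vals.std()
    z = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
    zmap = {c: float(v) for c, v in zip(cells, z)}
    out = responses.copy()
    key = list(zip(out["e"].round(12), out["s"].round(12)))
    zkeys = {(round(c[0], 12), round(c[1], 12)): v for c, v in zmap.items()}
    missing = sorted({k for k in key if k not in zkeys})
    if missing:
        raise ValueError(f"no flow value for lattice cells: {missing[:5]}")
    out["flow"] = [zkeys[k] for k in key]
    return out


def cell_histograms(responses: pd.DataFrame) -> pd.DataFrame:
    """Relative class frequencies Ĉ_i(e, s) per lattice cell (rows sum to 1)."""
    responses = _validate_responses(responses)
    counts = (
        responses.groupby(["e", "s"])["response_class"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=[1, 2, 3, 4], fill_value=0)
    )
    freq = counts.div(counts.sum(axis=1), axis=0)
    freq.columns = [f"C{j}" for j in (1, 2, 3, 4)]
    return freq.reset_index()
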