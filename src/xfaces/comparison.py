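"""Similarity of categorization across stimulus conditions.

Two complementary statistics compare the discriminant surfaces and the raw
responses across the avatar × view conditions:

* the **variance ratio q** — the integrated squared deviation of each
  condition's class-probability surfaces from the condition mean, divided by
  the integrated squared mean surfaces, in percent. q = 0 iff all condition
  surfaces are identical; small q means shape/view had little effect on the
  perceptual read-out.
* a **per-cell contingency analysis** — at each lattice point the
  conditions × classes response counts are tested for independence of the
  class distribution from condition, with a Pearson χ² test when all
  expected counts are ≥ 5 and a parametric bootstrap of the χ² statistic
  otherwise; p-values are Bonferroni-corrected across the lattice cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import simpson
from scipy.stats import chi2_contingency

from .discriminant import DiscriminantModel, fit_multinomial, predict_surface

__all__ = [
    "ConditionComparison",
    "variance_ratio_q",
    "contingency_cell_test",
    "compare_conditions",
]


def _integral_2d(z: np.ndarray, e_axis: np.ndarray, s_axis: np.ndarray) -> float:
    return float(simpson(simpson(z, x=e_axis, axis=-1), x=s_axis, axis=-1))


def variance_ratio_q(
    surfaces: list[np.ndarray] | np.ndarray,
    e_axis: np.ndarray | None = None,
    s_axis: np.ndarray | None = None,
) -> float:
    """Different-vs-shared variance ratio of condition surfaces, in percent.

    ``surfaces`` stacks K condition surface sets of shape (4, n_s, n_e) on a
    common grid. With P̄_j the mean surface of class j across conditions,

        q = Σ_k Σ_j ∬ (P_kj − P̄_j)² de ds / (K Σ_j ∬ P̄_j² de ds) × 100.

    Double integrals use 2D composite Simpson quadrature on the surface grid.
    """
    arr = np.asarray(surfaces, dtype=float)
    if arr.ndim != 4 or arr.shape[1] != 4:
        raise ValueError(f"surfaces must stack to (K, 4, n_s, n_e), got {arr.shape}")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 condition surfaces")
    n_s, n_e = arr.shape[2], arr.shape[3]
    e_axis = np.linspace(0.0, 1.0, n_e) if e_axis is None else np.asarray(e_axis)
    s_axis = np.linspace(0.0, 1.0, n_s) if s_axis is None else np.asarray(s_axis)
    if len(e_axis) != n_e or len(s_axis) != n_s:
        raise ValueError("axis lengths do not match surface grid")
    mean = arr.mean(axis=0)  # (4, n_s, n_e)
    num = sum(
        _integral_2d((arr[k, j] - mean[j]) ** 2, e_axis, s_axis)
        for k in range(arr.shape[0])
        for j in range(4)
    )
    den = arr.shape[0] * sum(_integral_2d(mean[j] ** 2, e_axis, s_axis) for j in range(4))
    return 100.0 * num / den


def _chi2_stat(table: np.ndarray) -> float:
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    total = table.sum()
    expected = row * col / total
    mask = expected > 0
    return float((((table - expected) ** 2)[mask] / expected[mask]).sum())


def contingency_cell_test(
    cell_counts: np.ndarray,
    bootstrap_reps: int = 10000,
    seed: int | None = None,
    force_bootstrap: bool = False,
) -> tuple[float, str]:
    """Independence test of class counts across conditions at one cell.

    ``cell_counts`` is a (conditions × 4 classes) count table. When every
    expected count is ≥ 5 the analytic Pearson χ² p-value is returned;
    otherwise the null is simulated by resampling each condition's responses
    from the pooled class distribution and the p-value is
    (1 + #{χ²* ≥ χ²_obs}) / (B + 1). Returns (p, method).
    """
    table = np.asarray(cell_counts, dtype=float)
    if table.ndim != 2:
        raise ValueError("cell_counts must be a 2D (conditions × classes) table")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if table.sum() == 0:
        raise ValueError("all-zero contingency table")
    row_tot = table.sum(axis=1)
    active = row_tot > 0
    if active.sum() < 2:
        raise ValueError("need at least two conditions with observations")
    table = table[active]
    row_tot = row_tot[active]
    col_tot = table.sum(axis=0)
    nonzero_cols = col_tot > 0
    reduced = table[:, nonzero_cols]
    if reduced.shape[1] < 2:  # all mass in one class → trivially independent
        return 1.0, "degenerate"
    expected = np.outer(row_tot, reduced.sum(axis=0)) / reduced.sum()
    if not force_bootstrap and np.all(expected >= 5.0):
        _, p, _, _ = chi2_contingency(reduced, correction=False)
        return float(p), "chi2"
    if bootstrap_reps < 1:
        raise ValueError("bootstrap_reps must be >= 1")
    rng = np.random.default_rng(seed)
    obs = _chi2_stat(reduced)
    pooled = reduced.sum(axis=0) / reduced.sum()
    n_cond, n_cls = reduced.shape
    sim = np.empty((bootstrap_reps, n_cond, n_cls))
    for k in range(n_cond):
        sim[:, k, :] = rng.multinomial(int(row_tot[k]), pooled, size=bootstrap_reps)
    col_b = sim.sum(axis=1)  # (B, n_cls)
    exp_b = row_tot[None, :, None] * col_b[:, None, :] / reduced.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (sim - exp_b) ** 2 / exp_b
    stats = np.nansum(np.where(exp_b > 0, terms, 0.0), axis=(1, 2))
    p = (1.0 + float(np.sum(stats >= obs - 1e-12))) / (bootstrap_reps + 1.0)
    return p, "bootstrap"


@dataclass(frozen=True)
class ConditionComparison:
    """Outcome of the across-condition similarity analysis."""

    q_percent: float
    cell_table: pd.DataFrame  # e, s, p_raw, p_corrected, method, significant
    n_significant: int
    alpha: float
    models: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.cell_table)


def compare_conditions(
    responses: pd.DataFrame,
    predictor_set: tuple[str, ...] = ("1", "e", "s"),
    alpha: float = 0.05,
    grid_resolution: int = 101,
    bootstrap_reps: int = 10000,
    seed: int | None = None,
) -> ConditionComparison:
    """Full across-condition analysis of a response table.

    Fits the discriminant model separately per (avatar, view) condition,
    computes the variance ratio q of the fitted surfaces, and runs the
    per-cell contingency test with Bonferroni correction over the lattice.
    """
    conditions = sorted(
        map(tuple, responses[["avatar", "view_deg"]].drop_duplicates().to_numpy()),
        key=str,
    )
    if len(conditions) < 2:
        raise ValueError("condition comparison needs at least 2 (avatar, view) conditions")
    models = {}
    surfaces = []
    for cond in conditions:
        sub = responses[
            (responses["avatar"] == cond[0]) & (responses["view_deg"] == cond[1])
        ]
        m = fit_multinomial(sub, predictor_set)
        models[cond] = m
        surfaces.append(predict_surface(m, grid_resolution)["P"])
    q = variance_ratio_q(np.stack(surfaces))

    cells = sorted(map(tuple, responses[["e", "s"]].drop_duplicates().to_numpy()))
    n_cells = len(cells)
    rng = np.random.default_rng(seed)
    rows = []
    for e, s in cells:
        cell = responses[(responses["e"] == e) & (responses["s"] == s)]
        counts = np.zeros((len(conditions), 4))
        for k, cond in enumerate(conditions):
            sub = cell[(cell["avatar"] == cond[0]) & (cell["view_deg"] == cond[1])]
            vc = sub["response_class"].value_counts()
            for j in (1, 2, 3, 4):
                counts[k, j - 1] = vc.get(j, 0)
        p_raw, method = contingency_cell_test(
            counts, bootstrap_reps, seed=int(rng.integers(2**31 - 1))
        )
        p_corr = min(1.0, p_raw * n_cells)
        rows.append(
            {
                "e": e,
                "s": s,
                "p_raw": p_raw,
                "p_corrected": p_corr,
                "method": method,
                "significant": p_corr < alpha,
            }
        )
    cell_table = pd.DataFrame(rows)
    return ConditionComparison(
        q_percent=q,
        cell_table=cell_table,
        n_significant=int(cell_table["significant"].sum()),
        alpha=alpha,
        models=models,
    )
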