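"""Item-level psychometric indicators for the fitted MGRM-C.

Covers multidimensional discrimination (MDISC) and difficulty (MDIFF)
with their published quality cut-points, threshold-ordering checks,
Yen's Q3 residual correlations for local-independence screening,
expected-score / information / standard-error surfaces, and sample
moments of the raw item distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .mgrm import (
    AbilityEstimates,
    ItemResponseMatrix,
    MGRMParameters,
    _category_prob_grid,
)

__all__ = [
    "ItemDiagnostics",
    "ResidualCorrelationMatrix",
    "mdisc",
    "mdisc_class",
    "mdiff",
    "item_diagnostics_table",
    "ordered_thresholds_report",
    "expected_item_score",
    "q3_residual_correlations",
    "information_surfaces",
    "item_moments",
]


def mdisc(a_row: np.ndarray) -> float:
    """Multidimensional discrimination: Euclidean norm of the slope vector."""
    a_row = np.asarray(a_row, dtype=float)
    if not np.isfinite(a_row).all():
        raise ValueError("slopes must be finite")
    return float(np.sqrt((a_row**2).sum()))


def mdisc_class(value: float) -> str:
    """Quality label for an MDISC value.

    Cut-points: below 0.5 poor; 0.5-1.0 moderate; above 1.0 up to 1.5
    good; above 1.5 excellent.  Exact boundary values take the lower
    label (1.0 is moderate, 1.5 is good).
    """
    if value < 0:
        raise ValueError("MDISC cannot be negative")
    if value < 0.5:
        return "poor"
    if value <= 1.0:
        return "moderate"
    if value <= 1.5:
        return "good"
    return "excellent"


def mdiff(d_row: np.ndarray, mdisc_value: float) -> np.ndarray:
    """Multidimensional difficulty per category boundary: ``-d_k / MDISC``.

    The signed distance from the origin, along the direction of steepest
    ascent, to the point where the k-th cumulative probability is 0.5.
    """
    if mdisc_value <= 0:
        raise ValueError("MDIFF undefined for an item with zero discrimination")
    return -np.asarray(d_row, dtype=float) / mdisc_value


@dataclass
class ItemDiagnostics:
    """Per-item MDISC/MDIFF summary."""

    item_ids: list[str]
    mdisc: np.ndarray
    mdisc_class: list[str]
    mdiff: np.ndarray  # (I, K-1)
    thresholds_ordered: np.ndarray  # bool per item

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "item": self.item_ids,
                "mdisc": self.mdisc,
                "mdisc_class": self.mdisc_class,
                "thresholds_ordered": self.thresholds_ordered,
            }
        )
        for k in range(self.mdiff.shape[1]):
            frame[f"mdiff_{k + 2}"] = self.mdiff[:, k]
        return frame


def item_diagnostics_table(
    params: MGRMParameters, item_ids: list[str] | None = None
) -> ItemDiagnostics:
    """MDISC, MDISC class, MDIFF and threshold ordering for every item."""
    I = params.n_items
    ids = item_ids or [f"item{i + 1:02d}" for i in range(I)]
    values = np.array([mdisc(params.a[i]) for i in range(I)])
    classes = [mdisc_class(v) for v in values]
    diffs = np.vstack([mdiff(params.d[i], values[i]) for i in range(I)])
    ordered = np.array([bool((np.diff(row) > 0).all() or (np.diff(row) < 0).all()) for row in diffs])
    return ItemDiagnostics(ids, values, classes, diffs, ordered)


def ordered_thresholds_report(params: MGRMParameters) -> pd.DataFrame:
    """Per-item monotonicity flag and direction for the MDIFF sequence.

    A strictly monotone MDIFF sequence in either direction counts as
    ordered; any violation is a "disordered threshold" and argues for
    category merging.  The direction is reported rather than assumed,
    since the sign convention of the difficulty axis is not fixed.
    """
    diag = item_diagnostics_table(params)
    directions = []
    for row in diag.mdiff:
        steps = np.diff(row)
        if (steps > 0).all():
            directions.append("ascending")
        elif (steps < 0).all():
            directions.append("descending")
        else:
            directions.append("disordered")
    return pd.DataFrame(
        {
            "item": diag.item_ids,
            "ordered": diag.thresholds_ordered,
            "direction": directions,
        }
    )


def expected_item_score(params: MGRMParameters, theta: np.ndarray) -> np.ndarray:
    """Model-implied expected category score per item at each theta row."""
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    P = _category_prob_grid(params.a, params.d, theta)  # (I, G, K)
    cats = np.arange(1, params.n_categories + 1, dtype=float)
    return (P @ cats).T  # (G, I)


@dataclass
class ResidualCorrelationMatrix:
    """Yen's Q3 residual correlations with local-dependence flags.

    ``values`` holds the raw pairwise correlations.  By default, flags
    are raised on the *centered* statistic (Q3 minus the mean
    off-diagonal Q3, often written Q3*): for a short test the raw Q3 has
    a structural expectation near ``-1/(I-1)`` even under perfect local
    independence, and centering removes that artifact before the
    published 0.20 cut is applied.
    """

    values: np.ndarray
    item_ids: list[str]
    threshold: float = 0.20
    undefined_items: list[str] | None = None
    center: bool = True

    @property
    def offdiag_mean(self) -> float:
        iu = np.triu_indices(self.values.shape[0], 1)
        off = self.values[iu]
        return float(np.nanmean(off))

    @property
    def flagged_pairs(self) -> list[tuple[str, str, float]]:
        shift = self.offdiag_mean if self.center else 0.0
        out = []
        I = self.values.shape[0]
        for i in range(I):
            for j in range(i + 1, I):
                r = self.values[i, j]
                if np.isfinite(r) and abs(r - shift) >= self.threshold:
                    out.append((self.item_ids[i], self.item_ids[j], float(r)))
        return out

    @property
    def flagged_proportion(self) -> float:
        I = self.values.shape[0]
        return len(self.flagged_pairs) / (I * (I - 1) / 2)


def q3_residual_correlations(
    params: MGRMParameters,
    ability: AbilityEstimates,
    data: ItemResponseMatrix,
    threshold: float = 0.20,
    center: bool = True,
) -> ResidualCorrelationMatrix:
    """Local-independence screen: correlations of expected-score residuals.

    Residual ``e_ij = x_ij - E[x_ij | theta_hat_j]`` with the expectation
    taken under the fitted model at the person's EAP score; item pairs
    whose (by default mean-centered, see
    :class:`ResidualCorrelationMatrix`) correlation exceeds ``threshold``
    in absolute value are flagged as locally dependent.
    """
    expected = expected_item_score(params, ability.theta)
    resid = data.values - expected
    sd = resid.std(axis=0)
    undefined = [data.item_ids[i] for i in np.where(sd < 1e-12)[0]]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(resid, rowvar=False)
    for i, item in enumerate(data.item_ids):
        if item in undefined:
            corr[i, :] = np.nan
            corr[:, i] = np.nan
    np.fill_diagonal(corr, 1.0)
    return ResidualCorrelationMatrix(
        corr, list(data.item_ids), threshold, undefined or None, center
    )


def _grm_item_information(params: MGRMParameters, theta: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Directional item information at each theta row, summed over items.

    Samejima's graded-response information with the squared directional
    slope ``(a_i . u)^2`` in place of the scalar ``a^2``:
    ``I_i = (a_i.u)^2 * sum_k (w_k - w_{k+1})^2 / P_k`` where
    ``w_k = P*_k (1 - P*_k)``.
    """
    theta = np.atleast_2d(theta)
    G = theta.shape[0]
    z = theta @ params.a.T  # (G, I)
    info = np.zeros(G)
    for i in range(params.n_items):
        c = special.expit(z[:, i][:, None] + params.d[i][None, :])  # (G, K-1)
        w = c * (1 - c)
        w_pad = np.concatenate([np.zeros((G, 1)), w, np.zeros((G, 1))], axis=1)
        p_pad = np.concatenate([np.ones((G, 1)), c, np.zeros((G, 1))], axis=1)
        P = np.clip(p_pad[:, :-1] - p_pad[:, 1:], 1e-12, 1.0)
        a_dir = float(params.a[i] @ direction)
        info += a_dir**2 * (((w_pad[:, :-1] - w_pad[:, 1:]) ** 2) / P).sum(axis=1)
    return info


def information_surfaces(
    params: MGRMParameters,
    theta_grid: np.ndarray,
    direction: np.ndarray | None = None,
) -> pd.DataFrame:
    """Expected total score, directional test information and SE over a grid.

    ``theta_grid`` is an (G, F) array of evaluation points.  The default
    direction weights both factors equally (normalized); information is
    the sum of directional item informations and the conditional standard
    error is ``1/sqrt(information)``.
    """
    theta_grid = np.atleast_2d(np.asarray(theta_grid, dtype=float))
    if not np.isfinite(theta_grid).all():
        raise ValueError("theta grid must be finite")
    F = params.n_factors
    if direction is None:
        direction = np.full(F, 1.0)
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("direction must be non-zero")
    direction = direction / norm
    expected_total = expected_item_score(params, theta_grid).sum(axis=1)
    info = _grm_item_information(params, theta_grid, direction)
    se = 1.0 / np.sqrt(np.maximum(info, 1e-12))
    frame = pd.DataFrame(
        {f"theta{f + 1}": theta_grid[:, f] for f in range(F)}
    )
    frame["expected_total"] = expected_total
    frame["information"] = info
    frame["se"] = se
    return frame


def default_theta_grid(lo: float = -4.0, hi: float = 4.0, step: float = 0.1) -> np.ndarray:
    """Square two-dimensional evaluation grid (default [-4, 4] step 0.1)."""
    axis = np.arange(lo, hi + step / 2, step)
    g1, g2 = np.meshgrid(axis, axis, indexing="ij")
    return np.column_stack([g1.ravel(), g2.ravel()])


def item_moments(data: ItemResponseMatrix) -> pd.DataFrame:
    """Per-item mean, sd, skewness and excess kurtosis (sample moments)."""
    if data.n_persons < 2:
        raise ValueError("at least two persons required for moments")
    x = data.values.astype(float)
    mean = x.mean(axis=0)
    centered = x - mean
    m2 = (centered**2).mean(axis=0)
    m3 = (centered**3).mean(axis=0)
    m4 = (centered**4).mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = np.where(m2 > 0, m3 / np.maximum(m2, 1e-300) ** 1.5, np.nan)
        kurt = np.where(m2 > 0, m4 / np.maximum(m2, 1e-300) ** 2.0 - 3.0, np.nan)
    return pd.DataFrame(
        {
            "item": data.item_ids,
            "mean": mean,
            "sd": np.sqrt(m2),
            "skewness": skew,
            "excess_kurtosis": kurt,
            "defined": m2 > 0,
        }
    )
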