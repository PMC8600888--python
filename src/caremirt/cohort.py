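"""Synthetic caregiver cohorts with the structure the analysis assumes.

The study data behind the resilience-scale validation are not publicly
available, so every downstream stage is exercised on cohorts generated
here: two correlated latent resilience traits (*Generic* and
*Shift-Persist*), ten five-category items following the compensatory
multidimensional graded response model, categorical covariates matched to
the published cohort margins, eight SF-36-style quality-of-life domain
scores, and a monotone (optionally non-linear) link from the resilience
total score to the probability of high QoL.

One global seed is expanded into per-stage child seeds
(:func:`stage_seeds`), so individual stages can be regenerated
independently and every draw is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .mgrm import (
    ItemResponseMatrix,
    MGRMParameters,
    ScaleStructure,
    _category_prob_grid,
    _gh_grid,
    _prior_logweights,
)

__all__ = [
    "TABLE1_TOTAL_COUNTS",
    "default_margins",
    "default_true_params",
    "QoLLinkSpec",
    "DIFInjection",
    "ClassMixtureSpec",
    "CohortConfig",
    "SyntheticCohort",
    "stage_seeds",
    "sample_thetas",
    "sample_responses",
    "sample_covariates",
    "sample_qol",
    "sample_class_indicators",
    "inject_dif",
    "total_score_moments",
    "generate_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
]

SF36_DOMAINS = ["pf", "gh", "rp", "bp", "sf", "vt", "re", "mh"]

#: Published cohort column totals (N = 382) used as default covariate margins.
TABLE1_TOTAL_COUNTS: dict[str, dict[str, int]] = {
    "sex": {"female": 229, "man": 153},
    "age_band": {"<40": 32, "40-50": 147, "50-60": 126, ">60": 77},
    "education": {"middle_or_lower": 227, "high_or_higher": 155},
    "income": {"<5000": 130, "5000-10000": 159, ">10000": 93},
    "relationship": {"spouse": 288, "non_spouse": 94},
    "religion": {"yes": 111, "none": 271},
    "employment": {"employed": 146, "unemployed": 236},
    "months_caregiving": {"<6": 108, "6-12": 129, "13-24": 87, ">24": 58},
    "comorbidities": {"none": 184, "one": 132, "two_or_more": 66},
    "cancer_type": {"lung": 81, "gastric": 108, "colorectal": 92, "breast": 101},
}


def default_margins() -> dict[str, dict[str, float]]:
    """Covariate category probabilities derived from the published counts."""
    out = {}
    for cov, counts in TABLE1_TOTAL_COUNTS.items():
        total = sum(counts.values())
        out[cov] = {k: v / total for k, v in counts.items()}
    return out


def default_true_params(rho: float = 0.5) -> MGRMParameters:
    """Reference generating parameters for the ten-item two-factor scale.

    Items 1-5 load on the Generic factor, 6-10 on Shift-Persist (the
    5/5 split is an assumption; the published item-factor table is not
    reproduced in the source article, so the split is configurable
    everywhere downstream).  Slopes sit in the well-discriminating
    1.4-2.4 range and intercepts are strictly decreasing with mild
    per-item shifts, so most items classify as "excellent" by the MDISC
    rule and no thresholds are disordered.
    """
    structure = ScaleStructure.between_item([0] * 5 + [1] * 5)
    a_loaded = np.array([1.6, 1.9, 2.2, 1.4, 2.0, 1.8, 2.4, 1.5, 2.1, 1.7])
    a = structure.loading_pattern * a_loaded[:, None]
    base = np.array([2.2, 0.9, -0.4, -1.8])
    offsets = np.array([0.0, 0.3, -0.2, 0.5, -0.4, 0.2, -0.3, 0.4, -0.1, 0.1])
    d = base[None, :] + offsets[:, None]
    cov = np.array([[1.0, rho], [rho, 1.0]])
    return MGRMParameters(a, d, cov, structure)


@dataclass
class QoLLinkSpec:
    """Monotone link from the resilience total score to P(high QoL).

    ``kind="logistic"``: ``p = expit(intercept + slope * z)`` with
    ``z = (total - center)/scale`` the standardized total.  A slope of
    ``log(OR)`` makes the true per-SD odds ratio equal ``OR``.
    ``kind="plateau"``: flat at ``expit(intercept)`` below ``knot`` (in z
    units), then rising logistically — a saturating, clearly non-linear
    dose-response.  ``kind="flat"``: constant probability.
    Slopes must be non-negative (the link must be monotone non-decreasing).
    """

    kind: Literal["logistic", "plateau", "flat"] = "logistic"
    intercept: float = 0.0
    slope: float = float(np.log(1.6))
    knot: float = 0.0
    center: float = 30.0
    scale: float = 8.0
    domain_noise_sd: float = 10.0

    def __post_init__(self):
        if self.kind not in ("logistic", "plateau", "flat"):
            raise ValueError(f"unknown link kind {self.kind!r}")
        if self.kind != "flat" and self.slope < 0:
            raise ValueError("link must be monotone non-decreasing: slope >= 0")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def prob(self, total: np.ndarray) -> np.ndarray:
        z = (np.asarray(total, dtype=float) - self.center) / self.scale
        if self.kind == "flat":
            return np.full(z.shape, special.expit(self.intercept))
        if self.kind == "logistic":
            return special.expit(self.intercept + self.slope * z)
        return special.expit(self.intercept + self.slope * np.maximum(z - self.knot, 0.0))


@dataclass
class DIFInjection:
    """Group-specific perturbation of one item.

    ``uniform_shift`` is subtracted from every intercept of the target
    item in the focal group (positive shift = item harder for the focal
    group); ``nonuniform_scale`` multiplies the target item's slopes.
    """

    item: int
    group_covariate: str = "sex"
    focal_level: str = "man"
    uniform_shift: float = 0.0
    nonuniform_scale: float = 1.0


@dataclass
class ClassMixtureSpec:
    """True-class mixture over continuous indicators for LPA scenarios."""

    weights: np.ndarray
    means: np.ndarray  # (K, p)
    sd: float = 1.0

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if len(self.weights) != self.means.shape[0]:
            raise ValueError("one mean profile per class required")
        if self.sd <= 0:
            raise ValueError("sd must be positive")


@dataclass
class CohortConfig:
    """Everything needed to generate one synthetic cohort.

    Defaults reproduce the published study conditions: n = 382
    caregivers, a 5/5 item-factor split, latent correlation 0.5,
    covariate margins equal to the published cohort proportions, and a
    logistic QoL link whose true per-SD odds ratio is 1.6.
    """

    n_persons: int = 382
    true_params: MGRMParameters = field(default_factory=default_true_params)
    covariate_margins: Mapping[str, Mapping[str, float]] = field(default_factory=default_margins)
    qol_link: QoLLinkSpec = field(default_factory=QoLLinkSpec)
    dif_injection: DIFInjection | None = None
    class_structure: ClassMixtureSpec | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_persons < 1:
            raise ValueError("n_persons must be at least 1")
        for cov, margin in self.covariate_margins.items():
            total = sum(margin.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"margins for {cov!r} sum to {total}, not 1")
        rho = self.true_params.latent_cov[0, 1] if self.true_params.n_factors == 2 else 0.0
        if not -1 < rho < 1:
            raise ValueError("latent correlation must lie in (-1, 1)")

    @property
    def latent_correlation(self) -> float:
        return float(self.true_params.latent_cov[0, 1])


@dataclass
class SyntheticCohort:
    responses: ItemResponseMatrix
    covariates: pd.DataFrame
    sf36: pd.DataFrame
    qol_binary: np.ndarray
    true_thetas: np.ndarray
    true_class: np.ndarray | None = None
    config: CohortConfig | None = None

    def __post_init__(self):
        if (self.sf36.to_numpy() < 0).any() or (self.sf36.to_numpy() > 100).any():
            raise ValueError("SF-36 domain scores must lie in [0, 100]")

    @property
    def n_persons(self) -> int:
        return self.responses.n_persons

    def total_scores(self) -> np.ndarray:
        return self.responses.total_scores()


_STAGES = ("thetas", "responses", "covariates", "qol", "classes", "dif")


def stage_seeds(seed: int) -> dict[str, int]:
    """Expand one global seed into named per-stage child seeds (< 2**31)."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


def sample_thetas(n: int, rho: float, seed: int) -> np.ndarray:
    """Draw n rows from a bivariate standard normal with correlation rho."""
    if not -1 < rho < 1:
        raise ValueError(f"correlation must lie strictly in (-1, 1), got {rho}")
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    return rng.multivariate_normal(np.zeros(2), cov, size=int(n), method="cholesky")


def sample_responses(params: MGRMParameters, thetas: np.ndarray, seed: int) -> ItemResponseMatrix:
    """Draw item responses from the MGRM-C category distributions at each theta."""
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    if thetas.shape[1] != params.n_factors:
        raise ValueError("theta dimension does not match the parameter set")
    rng = np.random.default_rng(seed)
    P = _category_prob_grid(params.a, params.d, thetas)  # (I, n, K)
    n, I, K = thetas.shape[0], params.n_items, params.n_categories
    u = rng.uniform(size=(n, I))
    cum = np.cumsum(P, axis=2)  # (I, n, K)
    values = np.empty((n, I), dtype=np.int64)
    # inverse-CDF draw per item column
    for i in range(I):
        values[:, i] = 1 + (u[:, i][:, None] > cum[i]).sum(axis=1)
    values = np.clip(values, 1, K)
    return ItemResponseMatrix(values)


def sample_covariates(
    margins: Mapping[str, Mapping[str, float]], n: int, seed: int
) -> pd.DataFrame:
    """Independent categorical draws per covariate matching the margins."""
    rng = np.random.default_rng(seed)
    data = {}
    for cov, margin in margins.items():
        levels = list(margin.keys())
        probs = np.array([margin[level] for level in levels], dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"margins for {cov!r} sum to {probs.sum()}, not 1")
        idx = rng.choice(len(levels), size=int(n), p=probs / probs.sum())
        data[cov] = pd.Categorical.from_codes(idx, categories=levels)
    return pd.DataFrame(data, index=pd.RangeIndex(int(n)))


def sample_qol(
    total_scores: np.ndarray, link: QoLLinkSpec, seed: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """High/low QoL indicator and SF-36-style domain scores from the link.

    ``qol_binary`` is Bernoulli with probability ``link(total)``.  Domain
    scores are the latent QoL probability scaled to 0-100 plus
    independent Gaussian noise (sd ``link.domain_noise_sd``), clipped to
    the instrument's 0-100 range.
    """
    total_scores = np.asarray(total_scores, dtype=float)
    rng = np.random.default_rng(seed)
    p = link.prob(total_scores)
    qol_binary = (rng.uniform(size=total_scores.shape[0]) < p).astype(np.int64)
    latent = 100.0 * p
    noise = rng.normal(scale=link.domain_noise_sd, size=(total_scores.shape[0], len(SF36_DOMAINS)))
    domains = np.clip(latent[:, None] + noise, 0.0, 100.0)
    sf36 = pd.DataFrame(domains, columns=SF36_DOMAINS)
    return sf36, qol_binary


def sample_class_indicators(
    spec: ClassMixtureSpec, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous indicator matrix and true labels from a class mixture."""
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(spec.weights), size=int(n), p=spec.weights)
    x = spec.means[labels] + rng.normal(scale=spec.sd, size=(int(n), spec.means.shape[1]))
    return x, labels


def inject_dif(
    params: MGRMParameters, spec: DIFInjection
) -> tuple[MGRMParameters, MGRMParameters]:
    """Reference and focal parameter sets differing only on the target item."""
    if not 0 <= spec.item < params.n_items:
        raise KeyError(f"target item {spec.item} does not exist")
    reference = params.copy()
    focal = params.copy()
    focal.d[spec.item] = focal.d[spec.item] - spec.uniform_shift
    focal.a[spec.item] = focal.a[spec.item] * spec.nonuniform_scale
    return reference, focal


def total_score_moments(params: MGRMParameters, nodes: int = 21) -> tuple[float, float]:
    """Population mean and sd of the total score under the model, by quadrature."""
    grid, base_logw = _gh_grid(params.n_factors, nodes)
    w = np.exp(_prior_logweights(grid, base_logw, params.latent_cov))
    P = _category_prob_grid(params.a, params.d, grid)  # (I, G, K)
    cats = np.arange(1, params.n_categories + 1, dtype=float)
    e_item = P @ cats  # (I, G) E[x_i | theta]
    e_item2 = P @ cats**2  # (I, G)
    e_total_theta = e_item.sum(axis=0)  # (G,)
    mean = float(w @ e_total_theta)
    # E[T^2] = sum_i E[x_i^2] + sum_{i != j} E_theta[E[x_i|t] E[x_j|t]]
    cross = e_total_theta**2 - (e_item**2).sum(axis=0)
    e_t2 = float(w @ (e_item2.sum(axis=0) + cross))
    var = max(e_t2 - mean**2, 1e-12)
    return mean, float(np.sqrt(var))


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort from one config and one seed.

    If a DIF injection is present, responses of focal-group members are
    drawn from the perturbed parameter set.  If a class mixture is
    present, latent trait means are shifted per class (classes act on
    theta; continuous LPA indicators can instead be drawn directly with
    :func:`sample_class_indicators`).
    """
    seeds = stage_seeds(config.seed)
    rho = config.latent_correlation
    thetas = sample_thetas(config.n_persons, rho, seeds["thetas"])
    true_class = None
    if config.class_structure is not None:
        spec = config.class_structure
        if spec.means.shape[1] != config.true_params.n_factors:
            raise ValueError("class means must match the latent dimension")
        rng = np.random.default_rng(seeds["classes"])
        true_class = rng.choice(len(spec.weights), size=config.n_persons, p=spec.weights)
        thetas = thetas * spec.sd + spec.means[true_class]

    covariates = sample_covariates(config.covariate_margins, config.n_persons, seeds["covariates"])

    if config.dif_injection is not None:
        inj = config.dif_injection
        reference, focal = inject_dif(config.true_params, inj)
        focal_mask = (covariates[inj.group_covariate] == inj.focal_level).to_numpy()
        responses_ref = sample_responses(reference, thetas, seeds["responses"])
        responses_foc = sample_responses(focal, thetas, seeds["dif"])
        values = np.where(focal_mask[:, None], responses_foc.values, responses_ref.values)
        responses = ItemResponseMatrix(values)
    else:
        responses = sample_responses(config.true_params, thetas, seeds["responses"])

    sf36, qol_binary = sample_qol(responses.total_scores(), config.qol_link, seeds["qol"])
    return SyntheticCohort(
        responses=responses,
        covariates=covariates,
        sf36=sf36,
        qol_binary=qol_binary,
        true_thetas=thetas,
        true_class=true_class,
        config=config,
    )


def write_cohort_csv(cohort: SyntheticCohort, path, truth_path=None) -> None:
    """Write the cohort as CSV; truth values go to a separate sidecar CSV."""
    n = cohort.n_persons
    frame = pd.DataFrame({"id": np.arange(1, n + 1)})
    for j, item_id in enumerate(cohort.responses.item_ids):
        frame[item_id] = cohort.responses.values[:, j]
    for col in cohort.covariates.columns:
        frame[col] = cohort.covariates[col].astype(str).to_numpy()
    for col in SF36_DOMAINS:
        frame[col] = cohort.sf36[col].to_numpy()
    frame["qol_high"] = cohort.qol_binary
    frame.to_csv(path, index=False)
    if truth_path is not None:
        truth = pd.DataFrame({"id": np.arange(1, n + 1)})
        for f in range(cohort.true_thetas.shape[1]):
            truth[f"theta{f + 1}"] = cohort.true_thetas[:, f]
        if cohort.true_class is not None:
            truth["true_class"] = cohort.true_class
        truth.to_csv(truth_path, index=False)


def read_cohort_csv(path, item_prefix: str = "item") -> SyntheticCohort:
    """Read a cohort CSV written by :func:`write_cohort_csv`."""
    frame = pd.read_csv(path)
    item_cols = [c for c in frame.columns if c.startswith(item_prefix)]
    responses = ItemResponseMatrix(frame[item_cols].to_numpy(), item_ids=item_cols)
    sf36 = frame[[c for c in SF36_DOMAINS if c in frame.columns]]
    cov_cols = [
        c for c in frame.columns
        if c not in item_cols + SF36_DOMAINS + ["id", "qol_high"]
    ]
    covariates = frame[cov_cols].astype("category")
    qol = frame["qol_high"].to_numpy() if "qol_high" in frame.columns else np.zeros(len(frame), dtype=int)
    return SyntheticCohort(
        responses=responses,
        covariates=covariates,
        sf36=sf36,
        qol_binary=qol,
        true_thetas=np.full((len(frame), 2), np.nan),
    )
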