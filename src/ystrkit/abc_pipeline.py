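"""Approximate Bayesian Computation over the STR simulator.

Pipeline: sample demographic parameters from priors, simulate Y-STR tables,
reduce each to an 8-component summary vector (mean and sd over loci of the
number of distinct alleles, unbiased gene diversity, allelic range and the
Garza–Williamson index), then perform model choice (rejection and weighted
multinomial logistic regression) and parameter estimation (local-linear
regression after a logtan transform) against the observed summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError
from scipy.stats import gaussian_kde
from sklearn.linear_model import LogisticRegression

from .haplotype_io import MutationRateTable, StrHaplotypeTable
from .synthetic_data import DemographicModel, simulate_alleles

__all__ = [
    "PriorSpec",
    "SUMMARY_NAMES",
    "EXTRA_SUMMARY_NAMES",
    "summarize",
    "summarize_matrix",
    "ReferenceTable",
    "build_reference",
    "model_choice_rejection",
    "model_choice_regression",
    "estimate_parameters",
    "gof_pca",
    "AbcResult",
    "fit",
]

SUMMARY_NAMES = (
    "K_mean", "K_sd", "H_mean", "H_sd", "R_mean", "R_sd", "M_mean", "M_sd",
)

#: Optional haplotype-level components (distinct haplotype count and
#: unbiased haplotype diversity), enabled by ``extra_haplotype_stats``.
EXTRA_SUMMARY_NAMES = ("Khap", "Hhap")

_MAX_SEED = 2**31 - 1


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Priors for the demographic and mutation parameters.

    Population sizes are log-uniform on ``size_bounds`` (a bounded
    order-of-magnitude prior; a truncated lognormal alternative is
    available), applied to N (constant) and to Na, Nc (growth, conditioned
    on Na < Nc by rejection). Tstart is uniform on ``tstart_bounds`` and the
    GSM geometric parameter uniform on ``gsm_bounds``.
    """

    size_bounds: tuple[float, float] = (100.0, 100000.0)
    tstart_bounds: tuple[float, float] = (50.0, 350.0)
    gsm_bounds: tuple[float, float] = (0.0, 0.8)
    size_prior: str = "loguniform"  # or "truncated-lognormal"

    def __post_init__(self) -> None:
        for low, high in (self.size_bounds, self.tstart_bounds, self.gsm_bounds):
            if not low < high:
                raise ValueError("prior bounds must be increasing")
        if self.size_prior not in ("loguniform", "truncated-lognormal"):
            raise ValueError(f"unknown size prior {self.size_prior!r}")

    def sample_size(self, rng: np.random.Generator) -> float:
        low, high = self.size_bounds
        if self.size_prior == "loguniform":
            return float(np.exp(rng.uniform(np.log(low), np.log(high))))
        mu = 0.5 * (np.log(low) + np.log(high))
        sigma = 0.25 * (np.log(high) - np.log(low))
        while True:
            draw = float(np.exp(rng.normal(mu, sigma)))
            if low <= draw <= high:
                return draw

    def sample_constant(self, rng: np.random.Generator) -> dict[str, float]:
        n = self.sample_size(rng)
        return {"Na": n, "Nc": n, "Tstart": np.nan,
                "p_geom": float(rng.uniform(*self.gsm_bounds))}

    def sample_growth(self, rng: np.random.Generator) -> dict[str, float]:
        while True:  # condition Na < Nc by rejection
            na, nc = self.sample_size(rng), self.sample_size(rng)
            if na < nc:
                break
        return {"Na": na, "Nc": nc,
                "Tstart": float(rng.uniform(*self.tstart_bounds)),
                "p_geom": float(rng.uniform(*self.gsm_bounds))}

    def bounds_for(self, model: str) -> dict[str, tuple[float, float]]:
        """Prior support per estimated parameter, used by the logtan transform."""
        if model == "constant":
            return {"N": self.size_bounds, "p_geom": self.gsm_bounds}
        return {"Na": self.size_bounds, "Nc": self.size_bounds,
                "Tstart": self.tstart_bounds, "p_geom": self.gsm_bounds}


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def summarize_matrix(alleles: np.ndarray, *,
                     extra_haplotype_stats: bool = False) -> np.ndarray:
    """Summary vector from an (individuals × loci) integer allele matrix.

    The 8 base components are the mean and sd over loci of the per-locus
    number of distinct alleles (K), unbiased gene diversity (H), allelic
    range (R) and Garza–Williamson index M = K/(R+1). With
    ``extra_haplotype_stats`` the haplotype-level distinct-haplotype count
    and unbiased haplotype diversity are appended.
    """
    n, n_loci = alleles.shape
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    k = np.empty(n_loci)
    h = np.empty(n_loci)
    r = np.empty(n_loci)
    for j in range(n_loci):
        _, counts = np.unique(alleles[:, j], return_counts=True)
        k[j] = counts.size
        freqs = counts / n
        h[j] = n / (n - 1) * (1.0 - np.sum(freqs**2))
        r[j] = alleles[:, j].max() - alleles[:, j].min()
    m = k / (r + 1.0)
    if n_loci >= 2:
        sds = [k.std(ddof=1), h.std(ddof=1), r.std(ddof=1), m.std(ddof=1)]
    else:
        warnings.warn("single locus: sd-over-loci components undefined (NaN)")
        sds = [np.nan] * 4
    out = [k.mean(), sds[0], h.mean(), sds[1], r.mean(), sds[2],
           m.mean(), sds[3]]
    if extra_haplotype_stats:
        _, hap_counts = np.unique(alleles, axis=0, return_counts=True)
        hap_freqs = hap_counts / n
        out.append(hap_counts.size)
        out.append(n / (n - 1) * (1.0 - np.sum(hap_freqs**2)))
    return np.array(out)


def summarize(haps: StrHaplotypeTable, *,
              extra_haplotype_stats: bool = False) -> np.ndarray:
    """Summary vector for a haplotype table (complete cases only)."""
    return summarize_matrix(haps.alleles(),
                            extra_haplotype_stats=extra_haplotype_stats)


# ---------------------------------------------------------------------------
# Reference table
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTable:
    """Reference set of (model, parameter draw, summary vector) rows."""

    frame: pd.DataFrame
    n_sample: int
    loci: tuple[str, ...]
    priors: PriorSpec = field(default_factory=PriorSpec)
    summary_names: tuple[str, ...] = SUMMARY_NAMES

    @property
    def summaries(self) -> np.ndarray:
        return self.frame[list(self.summary_names)].to_numpy(dtype=float)

    def component_sd(self) -> np.ndarray:
        """Per-component standardization scale (zero sds mapped to 1)."""
        sd = self.summaries.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        return sd

    def distances(self, observed: np.ndarray) -> np.ndarray:
        """Euclidean distances on sd-standardized summaries."""
        sd = self.component_sd()
        diff = (self.summaries - np.asarray(observed, dtype=float)) / sd
        return np.sqrt(np.sum(diff**2, axis=1))

    def subset(self, mask) -> "ReferenceTable":
        return ReferenceTable(self.frame[np.asarray(mask)].reset_index(drop=True),
                              self.n_sample, self.loci, self.priors,
                              self.summary_names)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, n_sample: int, loci: Sequence[str],
                 priors: PriorSpec | None = None) -> "ReferenceTable":
        frame = pd.read_csv(path, sep="\t")
        names = SUMMARY_NAMES
        if all(n in frame.columns for n in EXTRA_SUMMARY_NAMES):
            names = SUMMARY_NAMES + EXTRA_SUMMARY_NAMES
        return cls(frame, n_sample, tuple(loci), priors or PriorSpec(), names)


def build_reference(
    models: Sequence[str],
    priors: PriorSpec,
    n_sims: int,
    n_sample: int,
    rates: MutationRateTable,
    rng_seed: int,
    *,
    ancestral_allele: int = 20,
    extra_haplotype_stats: bool = False,
) -> ReferenceTable:
    """Simulate ``n_sims`` parameter draws per model and summarize each.

    Reproducible under ``rng_seed``; chunk-parallel runs can derive disjoint
    seeds from a parent ``SeedSequence`` and concatenate frames.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    for model in models:
        if model not in ("constant", "growth"):
            raise ValueError(f"unknown model {model!r}")
    rng = np.random.default_rng(rng_seed)
    rate_arr = rates.to_array()
    names = SUMMARY_NAMES + (EXTRA_SUMMARY_NAMES if extra_haplotype_stats
                             else ())
    rows = []
    for model in models:
        for _ in range(int(n_sims)):
            params = (priors.sample_constant(rng) if model == "constant"
                      else priors.sample_growth(rng))
            demo = (DemographicModel.constant(params["Na"])
                    if model == "constant" else
                    DemographicModel.growth(params["Na"], params["Nc"],
                                            params["Tstart"]))
            seeds = (int(rng.integers(_MAX_SEED)), int(rng.integers(_MAX_SEED)))
            alleles = simulate_alleles(n_sample, demo, rate_arr,
                                       params["p_geom"], ancestral_allele, seeds)
            summary = summarize_matrix(
                alleles, extra_haplotype_stats=extra_haplotype_stats)
            rows.append({"model": model, **params,
                         **dict(zip(names, summary))})
    return ReferenceTable(pd.DataFrame(rows), n_sample, rates.loci, priors,
                          names)


# ---------------------------------------------------------------------------
# Model choice
# ---------------------------------------------------------------------------

def _retained(table: ReferenceTable, observed: np.ndarray, tolerance: float):
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must lie in (0, 1]")
    d = table.distances(observed)
    n_keep = max(1, int(round(tolerance * len(d))))
    if n_keep < 10:
        warnings.warn(f"tolerance retains only {n_keep} rows")
    idx = np.argsort(d, kind="stable")[:n_keep]
    return idx, d[idx]


def model_choice_rejection(
    table: ReferenceTable, observed: np.ndarray, tolerance: float
) -> dict[str, float]:
    """Posterior model probabilities by the simple rejection algorithm."""
    idx, _ = _retained(table, observed, tolerance)
    kept = table.frame["model"].to_numpy()[idx]
    models = sorted(table.frame["model"].unique())
    return {m: float(np.mean(kept == m)) for m in models}


def _epanechnikov(d: np.ndarray) -> np.ndarray:
    dmax = d.max()
    if dmax == 0:
        return np.ones_like(d)
    w = 1.0 - (d / dmax) ** 2
    if not w.any():
        return np.ones_like(d)
    return w


def model_choice_regression(
    table: ReferenceTable, observed: np.ndarray, tolerance: float
) -> dict[str, float]:
    """Posterior model probabilities by weighted multinomial logistic regression.

    The model label is regressed on (standardized summaries − observed) over
    the retained rows with Epanechnikov weights in distance; the fitted
    probability at the observed point (zero offset) is reported. Falls back
    to rejection probabilities if only one model survives retention.
    """
    idx, d = _retained(table, observed, tolerance)
    kept = table.frame["model"].to_numpy()[idx]
    models = sorted(table.frame["model"].unique())
    if len(np.unique(kept)) < 2:
        warnings.warn("one model absent from retained set; "
                      "falling back to rejection probabilities")
        return model_choice_rejection(table, observed, tolerance)
    sd = table.component_sd()
    x = (table.summaries[idx] - np.asarray(observed, dtype=float)) / sd
    weights = _epanechnikov(d)
    # boundary rows get zero weight; sklearn needs at least some mass per class
    for m in np.unique(kept):
        if weights[kept == m].sum() == 0:
            weights[kept == m] = 1e-8
    clf = LogisticRegression(C=np.inf, max_iter=5000)
    clf.fit(x, kept, sample_weight=weights)
    probs = clf.predict_proba(np.zeros((1, x.shape[1])))[0]
    out = {m: 0.0 for m in models}
    for cls_name, p in zip(clf.classes_, probs):
        out[str(cls_name)] = float(p)
    return out


# ---------------------------------------------------------------------------
# Parameter estimation
# ---------------------------------------------------------------------------

def _logtan(theta: np.ndarray, low: float, high: float) -> np.ndarray:
    span = high - low
    eps = 1e-9 * span
    clipped = np.clip(theta, low + eps, high - eps)
    return np.log(np.tan(0.5 * np.pi * (clipped - low) / span))

def _inv_logtan(z: np.ndarray, low: float, high: float) -> np.ndarray:
    span = high - low
    return low + span * (2.0 / np.pi) * np.arctan(np.exp(z))


def _weighted_quantile(values, weights, q) -> float:
    order = np.argsort(values)
    v, w = np.asarray(values)[order], np.asarray(weights)[order]
    cum = np.cumsum(w) / np.sum(w)
    return float(v[np.searchsorted(cum, q, side="left").clip(0, len(v) - 1)])


def _weighted_hpd(values, weights, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval holding ``mass`` of the weighted empirical posterior."""
    order = np.argsort(values)
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    total = w.sum()
    cum = np.concatenate([[0.0], np.cumsum(w)])
    best = (v[0], v[-1])
    best_len = v[-1] - v[0]
    j = 0
    for i in range(len(v)):
        j = max(j, i)
        while j < len(v) and cum[j + 1] - cum[i] < mass * total:
            j += 1
        if j == len(v):
            break
        if v[j] - v[i] <= best_len:
            best_len = v[j] - v[i]
            best = (v[i], v[j])
    return float(best[0]), float(best[1])


def _weighted_mode(values, weights) -> float:
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.ptp(v) <= 1e-12 * max(1.0, abs(v).max()):
        return _weighted_quantile(v, w, 0.5)
    try:
        kde = gaussian_kde(v, weights=w / w.sum())
        grid = np.linspace(v.min(), v.max(), 512)
        return float(grid[np.argmax(kde(grid))])
    except np.linalg.LinAlgError:
        return _weighted_quantile(v, w, 0.5)


def estimate_parameters(
    table: ReferenceTable,
    observed: np.ndarray,
    model: str = "growth",
    retain_fraction: float = 0.05,
    priors: PriorSpec | None = None,
) -> dict[str, dict[str, float]]:
    """Posterior summaries for the chosen model's parameters.

    The ``retain_fraction`` of the model's rows closest to the observed
    summaries is kept; each bounded parameter is logtan-transformed,
    adjusted by Epanechnikov-weighted local-linear regression on
    (summaries − observed), back-transformed (so prior bounds are respected
    by construction) and summarized by weighted mean, median, mode and the
    95% HPD interval.
    """
    priors = priors or table.priors
    sub = table.subset(table.frame["model"].to_numpy() == model)
    if not len(sub.frame):
        raise ValueError(f"no rows for model {model!r}")
    d = sub.distances(observed)
    n_keep = max(1, int(round(retain_fraction * len(d))))
    if n_keep < 50:
        raise ValueError(f"retention yields {n_keep} rows; need >= 50")
    idx = np.argsort(d, kind="stable")[:n_keep]
    d_kept = d[idx]
    weights = _epanechnikov(d_kept)
    sd = sub.component_sd()
    x = (sub.summaries[idx] - np.asarray(observed, dtype=float)) / sd
    design = np.column_stack([np.ones(len(idx)), x])
    sw = np.sqrt(weights)

    bounds = priors.bounds_for(model)
    out: dict[str, dict[str, float]] = {}
    for param, (low, high) in bounds.items():
        column = "Na" if (param == "N" and model == "constant") else param
        theta = sub.frame[column].to_numpy(dtype=float)[idx]
        z = _logtan(theta, low, high)
        beta, *_ = np.linalg.lstsq(design * sw[:, None], z * sw, rcond=None)
        z_adj = z - x @ beta[1:]
        adjusted = _inv_logtan(z_adj, low, high)
        assert np.all((adjusted >= low) & (adjusted <= high))
        hpd_low, hpd_high = _weighted_hpd(adjusted, weights)
        out[param] = {
            "mean": float(np.average(adjusted, weights=weights)),
            "median": _weighted_quantile(adjusted, weights, 0.5),
            "mode": _weighted_mode(adjusted, weights),
            "hpd_low": hpd_low,
            "hpd_high": hpd_high,
        }
    return out


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------

def gof_pca(
    table: ReferenceTable,
    observed: np.ndarray,
    best_k: int = 3000,
    favoured: str | None = None,
) -> tuple[pd.DataFrame, np.ndarray, bool]:
    """2-D PCA embedding of the best simulations per model plus the observed point.

    Returns (embedding frame with model labels, observed (x, y), flag for
    whether the observed point lies inside the convex hull of the favoured
    model's cloud). Principal components are sign-canonicalized: the
    largest-magnitude loading of each component is positive.
    """
    d_all = table.distances(observed)
    models = sorted(table.frame["model"].unique())
    parts = []
    for m in models:
        mask = table.frame["model"].to_numpy() == m
        if mask.sum() < 10:
            raise ValueError(f"model {m!r} has fewer than 10 rows")
        order = np.argsort(d_all[mask], kind="stable")[:best_k]
        parts.append(np.flatnonzero(mask)[order])
    idx = np.concatenate(parts)
    pool = table.summaries[idx]
    mean = pool.mean(axis=0)
    sd = pool.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (pool - mean) / sd
    _, _, vt = np.linalg.svd(z - z.mean(axis=0), full_matrices=False)
    comps = vt[:2]
    for i in range(2):  # sign canonicalization
        lead = np.argmax(np.abs(comps[i]))
        if comps[i, lead] < 0:
            comps[i] = -comps[i]
    xy = (z - z.mean(axis=0)) @ comps.T
    obs_xy = (((np.asarray(observed, dtype=float) - mean) / sd)
              - z.mean(axis=0)) @ comps.T
    labels = table.frame["model"].to_numpy()[idx]
    if favoured is None:
        favoured = labels[np.argmin(d_all[idx])]
    cloud = xy[labels == favoured]
    try:
        inside = bool(Delaunay(cloud).find_simplex(obs_xy) >= 0)
    except QhullError:
        inside = False
    frame = pd.DataFrame({"model": labels, "pc1": xy[:, 0], "pc2": xy[:, 1]})
    return frame, obs_xy, inside


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class AbcResult:
    """Model choice and parameter estimation results.

    ``model_probs[method][tolerance][model]`` holds posterior model
    probabilities; ``parameters[name]`` the posterior summaries for the
    chosen model.
    """

    model_probs: dict[str, dict[float, dict[str, float]]]
    chosen_model: str
    parameters: dict[str, dict[str, float]]

    def to_dict(self) -> dict:
        return {
            "model_probabilities": {
                method: {str(tol): probs for tol, probs in by_tol.items()}
                for method, by_tol in self.model_probs.items()
            },
            "chosen_model": self.chosen_model,
            "parameters": self.parameters,
        }


def fit(
    table: ReferenceTable,
    observed: np.ndarray,
    tolerances: Sequence[float] = (0.005, 0.01, 0.05),
    retain_fraction: float = 0.05,
    priors: PriorSpec | None = None,
) -> AbcResult:
    """Run model choice across a tolerance grid, then estimate parameters.

    The chosen model maximizes the mean posterior probability over the
    tolerance grid and both methods.
    """
    probs: dict[str, dict[float, dict[str, float]]] = {
        "rejection": {}, "regression": {},
    }
    for tol in tolerances:
        probs["rejection"][tol] = model_choice_rejection(table, observed, tol)
        probs["regression"][tol] = model_choice_regression(table, observed, tol)
    models = sorted(table.frame["model"].unique())
    mean_prob = {
        m: float(np.mean([probs[meth][tol][m]
                          for meth in probs for tol in tolerances]))
        for m in models
    }
    chosen = max(mean_prob, key=mean_prob.get)
    params = estimate_parameters(table, observed, chosen, retain_fraction, priors)
    return AbcResult(probs, chosen, params)
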