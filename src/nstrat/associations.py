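"""Association analyses over the per-genome strategy matrix.

Covers: OLS scaling of strategy counts with log genome length,
Kruskal-Wallis + pairwise rank-sum group comparisons (Holm-adjusted),
logistic presence/absence models with optional family-level adjustment,
Poisson models of organic-strategy counts across ecosystems, a Welch
two-sample contrast of inorganic fractions between host-associated and
free-living genomes, and linear / logistic PCA ordination of the binary
strategy matrix.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError


class FitError(ValueError):
    """Raised when a model cannot be fitted on the given data."""


@dataclass
class AssociationResult:
    model_id: str
    formula: str
    coefficients: dict[str, float] = field(default_factory=dict)
    standard_errors: dict[str, float] = field(default_factory=dict)
    statistics: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    p_values_adjusted: dict[str, float] = field(default_factory=dict)
    n_observations: int = 0
    grouping: str = ""
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def clean(d):
            return {k: (None if isinstance(v, float) and not np.isfinite(v) else v)
                    for k, v in d.items()}
        return {
            "model_id": self.model_id,
            "formula": self.formula,
            "coefficients": clean(self.coefficients),
            "standard_errors": clean(self.standard_errors),
            "statistics": clean(self.statistics),
            "p_values": clean(self.p_values),
            "p_values_adjusted": clean(self.p_values_adjusted),
            "n_observations": self.n_observations,
            "grouping": self.grouping,
            "converged": self.converged,
            "diagnostics": self.diagnostics,
        }


@dataclass
class MetabolismCoding:
    """Respiration/trophic coding for one genome; ``coded`` is False when the
    lineage is uncharacterized and the genome is excluded from
    metabolism-based analyses."""

    genome_id: str
    respiration_mode: str | None = None
    trophic_mode: str | None = None

    @property
    def coded(self) -> bool:
        return bool(self.respiration_mode) and bool(self.trophic_mode)


@dataclass
class OrdinationResult:
    method: str
    scores: np.ndarray
    loadings: np.ndarray
    explained: list[float]
    k: int
    converged: bool = True
    n_iter: int = 0
    dropped_columns: list[str] = field(default_factory=list)
    deviance_trace: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Count scaling
# ---------------------------------------------------------------------------

def fit_count_scaling(counts, genome_lengths) -> AssociationResult:
    """OLS of strategy count on log10 genome length (bp)."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(genome_lengths, dtype=float)
    if counts.size < 3:
        raise FitError("need at least 3 genomes")
    if np.any(lengths <= 0):
        raise FitError("genome lengths must be positive")
    x = np.log10(lengths)
    if np.ptp(x) == 0:
        raise FitError("zero variance in log genome length")
    X = sm.add_constant(x)
    res = sm.OLS(counts, X).fit()
    return AssociationResult(
        model_id="count_scaling",
        formula="strategy_count ~ log10(genome_length_bp)",
        coefficients={"intercept": float(res.params[0]), "slope": float(res.params[1])},
        standard_errors={"intercept": float(res.bse[0]), "slope": float(res.bse[1])},
        statistics={"t_slope": float(res.tvalues[1]), "r_squared": float(res.rsquared)},
        p_values={"slope": float(res.pvalues[1])},
        n_observations=int(res.nobs),
    )


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def group_compare(values, groups) -> AssociationResult:
    """Kruskal-Wallis across groups plus pairwise two-sided rank-sum tests
    with Holm adjustment.  Groups with fewer than 2 members are excluded
    with a warning."""
    s = pd.Series(np.asarray(values, dtype=float))
    g = pd.Series(np.asarray(groups))
    samples: dict[str, np.ndarray] = {}
    for label, sub in s.groupby(g.values):
        if len(sub) < 2:
            warnings.warn(f"group {label!r} has < 2 members; excluded")
            continue
        samples[str(label)] = sub.to_numpy()
    if len(samples) < 2:
        raise FitError("need at least 2 groups with >= 2 members")
    labels = sorted(samples)
    H, kw_p = scipy.stats.kruskal(*[samples[l] for l in labels])
    pair_p: dict[str, float] = {}
    pair_stat: dict[str, float] = {}
    directions: dict[str, int] = {}
    for a, b in itertools.combinations(labels, 2):
        res = scipy.stats.mannwhitneyu(samples[a], samples[b], alternative="two-sided")
        key = f"{a}|{b}"
        pair_p[key] = float(res.pvalue)
        pair_stat[key] = float(res.statistic)
        directions[key] = int(np.sign(np.median(samples[a]) - np.median(samples[b])))
    keys = list(pair_p)
    adjusted = multipletests([pair_p[k] for k in keys], method="holm")[1]
    return AssociationResult(
        model_id="group_compare",
        formula="value ~ group (Kruskal-Wallis + pairwise rank-sum, Holm)",
        statistics={"H": float(H), **{f"U[{k}]": v for k, v in pair_stat.items()}},
        p_values={"kruskal": float(kw_p), **pair_p},
        p_values_adjusted=dict(zip(keys, map(float, adjusted))),
        n_observations=int(sum(len(v) for v in samples.values())),
        grouping=",".join(labels),
        diagnostics={"directions": directions},
    )


# ---------------------------------------------------------------------------
# Presence/absence and count GLMs
# ---------------------------------------------------------------------------

def _mode_design(modes: pd.Series, reference: str) -> pd.DataFrame:
    dummies = pd.get_dummies(modes, prefix="mode", dtype=float)
    ref_col = f"mode_{reference}"
    if ref_col in dummies.columns:
        dummies = dummies.drop(columns=[ref_col])
    else:
        warnings.warn(f"reference category {reference!r} absent; dropping first column")
        dummies = dummies.iloc[:, 1:]
    return dummies


def _family_design(family_ids: pd.Series) -> pd.DataFrame:
    dummies = pd.get_dummies(family_ids.astype(str), prefix="family", dtype=float)
    return dummies.iloc[:, 1:]  # first family is the reference


def fit_presence_model(
    presence,
    respiration_mode,
    family_ids=None,
    model: str = "logistic",
    reference: str = "anaerobic",
) -> AssociationResult:
    """Logistic regression of strategy presence on respiration-mode
    indicators, optionally with family fixed effects
    (``model="logistic_with_family"``).

    Complete separation is detected and reported via ``converged=False``
    with a diagnostic rather than raised.
    """
    y = np.asarray(presence, dtype=float)
    if y.min() == y.max():
        raise FitError("presence is constant; degenerate outcome")
    modes = pd.Series(np.asarray(respiration_mode))
    X = _mode_design(modes, reference)
    if model == "logistic_with_family":
        if family_ids is None:
            raise FitError("family_ids required for logistic_with_family")
        X = pd.concat([X, _family_design(pd.Series(np.asarray(family_ids)))], axis=1)
    elif model != "logistic":
        raise ValueError(f"unknown model {model!r}")
    X = sm.add_constant(X)
    result = AssociationResult(
        model_id=f"presence_{model}",
        formula=f"presence ~ respiration_mode (ref={reference})"
                + (" + C(family)" if model == "logistic_with_family" else ""),
        n_observations=int(y.size),
        grouping="family" if model == "logistic_with_family" else "",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            result.converged = False
            result.diagnostics["separation"] = str(exc)
            return result
    result.coefficients = {k: float(v) for k, v in res.params.items()}
    result.standard_errors = {k: float(v) for k, v in res.bse.items()}
    result.statistics = {f"z[{k}]": float(v) for k, v in res.tvalues.items()}
    result.p_values = {k: float(v) for k, v in res.pvalues.items()}
    mode_coefs = [abs(v) for k, v in res.params.items() if k.startswith("mode_")]
    if (not res.converged) or (mode_coefs and max(mode_coefs) > 15.0):
        result.converged = False
        result.diagnostics["separation"] = (
            "IRLS did not converge or produced extreme coefficients; "
            "possible complete separation"
        )
    return result


def fit_habitat_counts(
    organic_counts,
    ecosystem,
    family_ids=None,
    reference: str | None = None,
) -> AssociationResult:
    """Poisson log-linear model of organic-strategy counts (0-5) on
    ecosystem indicators with optional family fixed effects.  The reference
    ecosystem defaults to the largest category."""
    y = np.asarray(organic_counts, dtype=float)
    if np.any(y < 0):
        raise FitError("counts must be nonnegative")
    eco = pd.Series(np.asarray(ecosystem))
    categories = eco.value_counts()
    if len(categories) < 2:
        raise FitError("need at least 2 ecosystems")
    if reference is None:
        reference = str(categories.index[0])
    dummies = pd.get_dummies(eco, prefix="eco", dtype=float).drop(
        columns=[f"eco_{reference}"]
    )
    X = dummies
    if family_ids is not None:
        X = pd.concat([X, _family_design(pd.Series(np.asarray(family_ids)))], axis=1)
    X = sm.add_constant(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=100)
    unstable = [
        str(c) for c in categories.index
        if c != reference and y[(eco == c).to_numpy()].sum() == 0
    ]
    return AssociationResult(
        model_id="habitat_counts_poisson",
        formula=f"organic_count ~ ecosystem (ref={reference})"
                + (" + C(family)" if family_ids is not None else ""),
        coefficients={k: float(v) for k, v in res.params.items()},
        standard_errors={k: float(v) for k, v in res.bse.items()},
        statistics={f"z[{k}]": float(v) for k, v in res.tvalues.items()
                    if k.startswith("eco_") or k == "const"},
        p_values={k: float(v) for k, v in res.pvalues.items()},
        n_observations=int(y.size),
        grouping="family" if family_ids is not None else "",
        diagnostics={"unstable_ecosystems": unstable, "reference": reference},
    )


# ---------------------------------------------------------------------------
# Host contrast
# ---------------------------------------------------------------------------

def host_contrast(inorganic_fractions, host_flag) -> AssociationResult:
    """Welch two-sample t-test of the inorganic fraction, free-living minus
    host-associated (positive t means free-living genomes carry relatively
    more inorganic strategies)."""
    vals = np.asarray(inorganic_fractions, dtype=float)
    host = np.asarray(host_flag, dtype=bool)
    free, assoc = vals[~host], vals[host]
    if free.size < 2 or assoc.size < 2:
        raise FitError("both groups need >= 2 members")
    if free.var(ddof=1) == 0 and assoc.var(ddof=1) == 0 and free.mean() == assoc.mean():
        raise FitError("t statistic undefined: zero variance and equal means")
    res = scipy.stats.ttest_ind(free, assoc, equal_var=False)
    return AssociationResult(
        model_id="host_contrast_welch",
        formula="inorganic_fraction ~ host_associated (Welch t)",
        coefficients={
            "mean_free_living": float(free.mean()),
            "mean_host_associated": float(assoc.mean()),
        },
        statistics={"t": float(res.statistic), "df": float(res.df)},
        p_values={"welch": float(res.pvalue)},
        n_observations=int(vals.size),
    )


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------

def _bernoulli_deviance(X: np.ndarray, theta: np.ndarray) -> float:
    # Numerically stable -2 log-likelihood via log(1 + exp(theta)).
    log1pexp = np.logaddexp(0.0, theta)
    return float(2.0 * np.sum(log1pexp - X * theta))


def ordinate(matrix: pd.DataFrame, method: str = "pca", k: int = 2) -> OrdinationResult:
    """Ordination of a genome x strategy boolean matrix.

    ``pca``: column-centred SVD with explained-variance ratios.
    ``logistic_pca``: projection-form logistic PCA fitted by
    majorization-minimization on the Bernoulli deviance (natural-parameter
    scale constant m = 4, monotone objective); constant columns are dropped
    with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = matrix.to_numpy(dtype=float)
    n_distinct = np.unique(X, axis=0).shape[0]
    if n_distinct < k + 1:
        raise ValueError(f"matrix needs >= k+1 distinct rows (has {n_distinct})")
    if method == "pca":
        Xc = X - X.mean(axis=0)
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        total = float(np.sum(S**2))
        ratios = (S**2 / total).tolist() if total > 0 else [0.0] * len(S)
        return OrdinationResult(
            method="pca",
            scores=U[:, :k] * S[:k],
            loadings=Vt.T[:, :k],
            explained=[float(r) for r in ratios[:k]],
            k=k,
        )
    if method != "logistic_pca":
        raise ValueError(f"unknown ordination method {method!r}")

    keep = [c for c in matrix.columns if matrix[c].nunique() > 1]
    dropped = [str(c) for c in matrix.columns if str(c) not in map(str, keep)]
    if dropped:
        warnings.warn(f"constant columns dropped for logistic_pca: {dropped}")
    X = matrix[keep].to_numpy(dtype=float)
    if k > X.shape[1]:
        raise ValueError("k exceeds the number of informative strategies")

    m = 4.0
    Theta = m * (2.0 * X - 1.0)
    mu = Theta.mean(axis=0)
    _, _, Vt = np.linalg.svd(Theta - mu, full_matrices=False)
    U = Vt.T[:, :k]

    max_iter, tol = 200, 1e-6
    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        P = U @ U.T
        theta_hat = mu + (Theta - mu) @ P
        dev = _bernoulli_deviance(X, theta_hat)
        trace.append(dev)
        if len(trace) > 1 and abs(trace[-2] - dev) <= tol * max(abs(trace[-2]), 1.0):
            converged = True
            break
        # MM step: quadratic majorizer target Z, then exact mu / U updates.
        Z = theta_hat + 4.0 * (X - scipy.special.expit(theta_hat))
        mu = (Z - Theta @ P).mean(axis=0)
        Tc = Theta - mu
        Zc = Z - mu
        B = Tc.T @ Tc - Tc.T @ Zc - Zc.T @ Tc
        B = 0.5 * (B + B.T)
        eigvals, eigvecs = np.linalg.eigh(B)
        U = eigvecs[:, :k]  # eigenvectors of the k smallest eigenvalues
    final_theta = mu + (Theta - mu) @ (U @ U.T)
    trace.append(_bernoulli_deviance(X, final_theta))
    return OrdinationResult(
        method="logistic_pca",
        scores=(Theta - mu) @ U,
        loadings=U,
        explained=[float(trace[-1])],
        k=k,
        converged=converged,
        n_iter=n_iter,
        dropped_columns=dropped,
        deviance_trace=[float(d) for d in trace],
    )
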