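"""Trait associations for EV phenotypes.

Each anthropometric trait Y is standardized to Y* = (Y - mean)/sd; each EV
abundance X is mapped to standard-normal scores X* by a rank-based inverse
normal transform. The model

    Y* = mu + X* b_ev + sex b_sex + age b_age + X*.sex b_int + e

is fit by ordinary least squares (sex coded male = 1, female = 0), so b_int > 0
means the exposure's effect is weaker in men than in women. P-values from all
trait-exposure fits are adjusted jointly by Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests


def standardize(values: np.ndarray) -> np.ndarray:
    """Center and scale to unit sample (n-1) standard deviation."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D vector with at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


def inverse_gaussian_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform: Phi^{-1}((rank - 0.5)/n).

    Ties receive average ranks, so the output is a monotone, rank-preserving
    map of the input onto standard-normal quantiles with mean ~0.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need a 1-D vector with at least 3 values")
    ranks = scipy.stats.rankdata(x, method="average")
    if np.ptp(x) == 0:
        raise ValueError("cannot transform an all-tied vector")
    return scipy.stats.norm.ppf((ranks - 0.5) / x.size)


@dataclass(frozen=True)
class AssociationResult:
    """One exposure-trait fit: coefficients, tests, and variance explained."""

    trait: str
    exposure: str
    n: int
    beta_ev: float
    se_ev: float
    p_ev: float
    beta_sex: float
    se_sex: float
    p_sex: float
    beta_age: float
    se_age: float
    p_age: float
    beta_interaction: float
    se_interaction: float
    p_interaction: float
    partial_r2: float
    full_r2: float
    q_value: float = float("nan")

    def ci_ev(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided confidence interval for the EV main effect."""
        t = scipy.stats.t.ppf(0.5 + level / 2, self.n - 5)
        return self.beta_ev - t * self.se_ev, self.beta_ev + t * self.se_ev


def fit_association(
    trait: np.ndarray,
    exposure: np.ndarray,
    sex: np.ndarray,
    age: np.ndarray,
    trait_name: str = "trait",
    exposure_name: str = "exposure",
    pre_transformed: bool = False,
) -> AssociationResult:
    """OLS fit of standardized trait on transformed exposure, sex, age, and the
    exposure-by-sex interaction.

    Missing values are dropped listwise; the n actually used is reported.
    ``pre_transformed`` skips the internal standardize/INT step when the caller
    already supplies Y* and X*. The reported partial R-squared of the EV term is
    t^2 / (t^2 + df_resid); the full-model R-squared is also returned.
    """
    trait = np.asarray(trait, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    sex = np.asarray(sex, dtype=float)
    age = np.asarray(age, dtype=float)
    if not (len(trait) == len(exposure) == len(sex) == len(age)):
        raise ValueError("input vectors must share length")
    ok = np.isfinite(trait) & np.isfinite(exposure) & np.isfinite(sex) & np.isfinite(age)
    trait, exposure, sex, age = trait[ok], exposure[ok], sex[ok], age[ok]
    n = trait.size
    if n <= 5:
        raise ValueError(f"n={n} leaves no residual degrees of freedom for 5 parameters")
    y = trait if pre_transformed else standardize(trait)
    x = exposure if pre_transformed else inverse_gaussian_transform(exposure)
    X = np.column_stack([np.ones(n), x, sex, age, x * sex])
    names = ["const", "ev", "sex", "age", "ev_by_sex"]
    rank_ok = np.linalg.matrix_rank(X) == X.shape[1]
    if not rank_ok:
        for j, name in enumerate(names[1:], start=1):
            if np.ptp(X[:, j]) == 0:
                raise np.linalg.LinAlgError(f"singular design: column {name!r} is constant")
        raise np.linalg.LinAlgError("singular design: collinear columns")
    fit = sm.OLS(y, pd.DataFrame(X, columns=names)).fit()
    t_ev = fit.tvalues["ev"]
    partial_r2 = float(t_ev**2 / (t_ev**2 + fit.df_resid))
    return AssociationResult(
        trait=trait_name,
        exposure=exposure_name,
        n=n,
        beta_ev=float(fit.params["ev"]),
        se_ev=float(fit.bse["ev"]),
        p_ev=float(fit.pvalues["ev"]),
        beta_sex=float(fit.params["sex"]),
        se_sex=float(fit.bse["sex"]),
        p_sex=float(fit.pvalues["sex"]),
        beta_age=float(fit.params["age"]),
        se_age=float(fit.bse["age"]),
        p_age=float(fit.pvalues["age"]),
        beta_interaction=float(fit.params["ev_by_sex"]),
        se_interaction=float(fit.bse["ev_by_sex"]),
        p_interaction=float(fit.pvalues["ev_by_sex"]),
        partial_r2=partial_r2,
        full_r2=float(fit.rsquared),
    )


def fdr_adjust(
    results: Sequence[AssociationResult], family: str = "pooled"
) -> list[AssociationResult]:
    """Benjamini-Hochberg q-values for the EV main-effect P-values.

    ``pooled`` (default) adjusts across every result in one family — total
    protein levels and marker-specific EV types together; ``per_analysis``
    adjusts within each exposure's results separately.
    """
    if family not in ("pooled", "per_analysis"):
        raise ValueError("family must be 'pooled' or 'per_analysis'")
    pvals = np.array([r.p_ev for r in results], dtype=float)
    if ((pvals < 0) | (pvals > 1)).any() or not np.isfinite(pvals).all():
        raise ValueError("P-values must lie in [0, 1]")
    if len(results) == 0:
        return []
    if family == "pooled":
        q = multipletests(pvals, method="fdr_bh")[1]
    else:
        q = np.empty_like(pvals)
        groups = pd.Series(range(len(results))).groupby([r.exposure for r in results])
        for _, idx in groups:
            q[idx.to_numpy()] = multipletests(pvals[idx.to_numpy()], method="fdr_bh")[1]
    return [replace(r, q_value=float(qi)) for r, qi in zip(results, q)]


def associate_all(
    phenotypes: pd.DataFrame,
    exposures: pd.DataFrame,
    trait_names: Sequence[str],
    sex_col: str = "sex",
    age_col: str = "age",
    family: str = "pooled",
    traits_standardized: bool = False,
) -> pd.DataFrame:
    """Fit every exposure against every trait and BH-adjust the results.

    ``phenotypes`` holds traits plus sex/age columns indexed by sample id;
    ``exposures`` holds one column per EV type or protein level on the same
    index. Exposures are always rank-transformed here (the transform is
    idempotent, so already-transformed columns pass through unchanged). Set
    ``traits_standardized`` when traits are already on the standardized scale
    (e.g. simulated directly on the model scale); otherwise each trait is
    standardized before fitting. Returns a tidy results table.
    """
    common = phenotypes.index.intersection(exposures.index)
    if len(common) == 0:
        raise ValueError("no shared sample ids between phenotypes and exposures")
    ph = phenotypes.loc[common]
    ex = exposures.loc[common]
    results = []
    sex = ph[sex_col].to_numpy(dtype=float)
    age = ph[age_col].to_numpy(dtype=float)
    for col in ex.columns:
        x_raw = ex[col].to_numpy(dtype=float)
        for trait in trait_names:
            y_raw = ph[trait].to_numpy(dtype=float)
            # transforms are rank/moment based, so apply them after listwise
            # deletion of incomplete records
            ok = (
                np.isfinite(y_raw) & np.isfinite(x_raw) & np.isfinite(sex) & np.isfinite(age)
            )
            y = y_raw[ok] if traits_standardized else standardize(y_raw[ok])
            results.append(
                fit_association(
                    y,
                    inverse_gaussian_transform(x_raw[ok]),
                    sex[ok],
                    age[ok],
                    trait_name=trait,
                    exposure_name=col,
                    pre_transformed=True,
                )
            )
    results = fdr_adjust(results, family=family)
    return pd.DataFrame(
        {
            "exposure": [r.exposure for r in results],
            "trait": [r.trait for r in results],
            "n": [r.n for r in results],
            "beta_ev": [r.beta_ev for r in results],
            "se": [r.se_ev for r in results],
            "p": [r.p_ev for r in results],
            "beta_int": [r.beta_interaction for r in results],
            "se_int": [r.se_interaction for r in results],
            "p_int": [r.p_interaction for r in results],
            "partial_r2": [r.partial_r2 for r in results],
            "q": [r.q_value for r in results],
        }
    )
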