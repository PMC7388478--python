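"""Cohort-level comparison statistics and empirical-probability rules.

Contains the exact two-sided binomial test (minimum-likelihood convention),
the Welch two-sample t-test from group summaries, a Spearman correlation
matrix with tie-aware average ranks, and the guideline empirical-probability
(EP) assignment computed from an index patient's clinical flags and family
cancer counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import StatsError

__all__ = [
    "BinomialTestResult",
    "COVARIATE_COLUMNS",
    "EP_VALUES",
    "exact_binomial_two_sided",
    "welch_t_from_summary",
    "spearman_matrix",
    "assign_empirical_probability",
]

#: Canonical covariate column names for the per-subject table.
COVARIATE_COLUMNS = [
    "Age",
    "BBC",
    "FDR.BC",
    "FDR.OC",
    "SDR.BC",
    "SDR.OC",
    "TDR.BC",
    "TDR.OC",
    "MBC",
    "TNBC",
]

#: Guideline EP fractions, highest applicable rule wins.
EP_VALUES = {
    "bc_and_oc": 0.484,
    "three_bc_two_early": 0.307,
    "bilateral_early": 0.248,
    "three_bc_any_age": 0.224,
    "tnbc": 0.112,
}

# Point probabilities within this relative tolerance of P(X=k) count as
# "at most as likely" in the two-sided tail sum.
_MINLIKE_RELTOL = 1e-7


@dataclass(frozen=True)
class BinomialTestResult:
    k: int
    n: int
    p0: float
    p_value: float

    def to_dict(self) -> dict:
        return {"k": self.k, "n": self.n, "p0": self.p0, "p_value": self.p_value}


def exact_binomial_two_sided(k: int, n: int, p0: float) -> BinomialTestResult:
    """Exact two-sided binomial test, minimum-likelihood convention.

    p = sum of P(X = x) over all x with P(X = x) <= P(X = k) * (1 + 1e-7),
    X ~ Binomial(n, p0), capped at 1.
    """
    if not (0 <= k <= n):
        raise StatsError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not (0 < p0 < 1):
        raise StatsError(f"null proportion must be in (0, 1), got {p0}")
    pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
    p = float(pmf[pmf <= pmf[k] * (1 + _MINLIKE_RELTOL)].sum())
    return BinomialTestResult(k=int(k), n=int(n), p0=float(p0), p_value=min(p, 1.0))


def welch_t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> float:
    """Two-sided Welch t-test p-value from group means, SDs and sizes."""
    if s1 <= 0 or s2 <= 0:
        raise StatsError("group SDs must be positive")
    if n1 < 2 or n2 < 2:
        raise StatsError("group sizes must be >= 2")
    v1, v2 = s1**2 / n1, s2**2 / n2
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(2.0 * stats.t.sf(abs(t), df))


def spearman_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlations with average ranks for ties.

    Constant columns yield NaN against every other column (undefined rank
    correlation); the diagonal is 1 for non-constant columns.
    """
    if table.shape[0] < 3:
        raise StatsError("need >= 3 subjects for a correlation matrix")
    num = table.apply(pd.to_numeric)
    ranks = num.apply(lambda c: stats.rankdata(c.to_numpy()))
    constant = num.nunique() <= 1
    with np.errstate(invalid="ignore"):  # constant columns handled below
        corr = np.corrcoef(ranks.to_numpy(), rowvar=False)
    out = pd.DataFrame(corr, index=table.columns, columns=table.columns)
    out.loc[constant.to_numpy(), :] = np.nan
    out.loc[:, constant.to_numpy()] = np.nan
    np.fill_diagonal(out.values, np.where(constant.to_numpy(), np.nan, 1.0))
    return out


_EP_REQUIRED = ["Age", "BBC", "TNBC", "FDR.BC", "FDR.OC", "SDR.BC", "SDR.OC", "TDR.BC", "TDR.OC"]


def assign_empirical_probability(subject: Mapping[str, float]) -> float:
    """Maximum guideline EP over satisfied criteria for one index patient.

    ``subject`` must carry the covariate columns; two optional fields refine
    the age-dependent rules: ``Rel.BC.before.51`` (number of affected
    relatives diagnosed before 51; missing = 0, i.e. the rule cannot fire on
    relatives of unknown onset age) and the index ``Age`` itself (age at first
    tumor).  The index case always counts as one breast tumor, two if
    bilateral; with bilateral disease plus at least one affected relative the
    pedigree counts as three independent tumors at EP 0.307.
    """
    missing = [f for f in _EP_REQUIRED if f not in subject or pd.isna(subject[f])]
    if missing:
        raise StatsError(f"EP assignment missing required fields: {missing}")

    age = float(subject["Age"])
    bilateral = bool(subject["BBC"])
    tnbc = bool(subject["TNBC"])
    rel_bc = float(subject["FDR.BC"]) + float(subject["SDR.BC"]) + float(subject["TDR.BC"])
    rel_oc = float(subject["FDR.OC"]) + float(subject["SDR.OC"]) + float(subject["TDR.OC"])
    rel_bc_early = float(subject.get("Rel.BC.before.51", 0) or 0)

    index_tumors = 2 if bilateral else 1
    total_bc_tumors = index_tumors + rel_bc
    early_bc = rel_bc_early + (index_tumors if age < 51 else 0)

    candidates = [0.0]
    if rel_oc >= 1:  # index contributes the breast cancer case
        candidates.append(EP_VALUES["bc_and_oc"])
    if total_bc_tumors >= 3 and early_bc >= 2:
        candidates.append(EP_VALUES["three_bc_two_early"])
    if bilateral and rel_bc >= 1:  # counted as three independent tumors
        candidates.append(EP_VALUES["three_bc_two_early"])
    if bilateral and age < 51:
        candidates.append(EP_VALUES["bilateral_early"])
    if total_bc_tumors >= 3:
        candidates.append(EP_VALUES["three_bc_any_age"])
    if tnbc:
        candidates.append(EP_VALUES["tnbc"])
    return max(candidates)
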