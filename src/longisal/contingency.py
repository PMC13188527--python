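"""Cohort-level contingency statistics: chi-square, Fisher's exact and
Cochran-Mantel-Haenszel tests on genotype x diagnosis tables."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class ContingencyResult:
    test: str
    statistic: float
    p_value: float


def _check_table(table: np.ndarray) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValueError("expected a 2xK table")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must hold nonnegative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("empty margin")
    return t


def chi_square(table, correction: bool = False) -> ContingencyResult:
    """Pearson chi-square test of independence (no Yates correction by
    default); warns when an expected count falls below 5."""
    t = _check_table(table)
    stat, p, _, expected = stats.chi2_contingency(t, correction=correction)
    if (expected < 5).any():
        warnings.warn("expected count below 5; consider Fisher's exact test")
    return ContingencyResult("chi-square", float(stat), float(p))


def fisher_exact(table) -> ContingencyResult:
    """Two-sided Fisher's exact test (hypergeometric enumeration) on 2x2."""
    t = _check_table(table)
    if t.shape != (2, 2):
        raise ValueError("Fisher's exact test requires a 2x2 table")
    odds, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
    return ContingencyResult("fisher-exact", float(odds), float(p))


def cmh_test(tables) -> ContingencyResult:
    """Cochran-Mantel-Haenszel test across >= 2 strata of 2x2 tables."""
    from statsmodels.stats.contingency_tables import StratifiedTable

    arrs = [np.asarray(_check_table(t), dtype=float) for t in tables]
    if len(arrs) < 2:
        raise ValueError("CMH requires >= 2 strata")
    st = StratifiedTable(np.stack(arrs, axis=-1))
    res = st.test_null_odds(correction=False)
    return ContingencyResult("cmh", float(res.statistic), float(res.pvalue))


def contingency_tests(diagnosis_by_genotype: dict) -> dict:
    """Run the full battery on per-sex genotype x diagnosis 2x2 tables.

    ``diagnosis_by_genotype`` maps sex -> 2x2 array with rows (WT, KO) and
    columns (ED/CIS, OSCC).  Returns chi-square and Fisher per stratum,
    chi-square on the pooled table, and CMH across the sex strata.
    """
    out = {}
    strata = []
    for sex, tab in diagnosis_by_genotype.items():
        t = _check_table(tab)
        strata.append(t)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[f"chi_square_{sex}"] = chi_square(t)
        if t.shape == (2, 2):
            out[f"fisher_{sex}"] = fisher_exact(t)
    pooled = np.sum(strata, axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["chi_square_pooled"] = chi_square(pooled)
    if len(strata) >= 2:
        out["cmh"] = cmh_test(strata)
    return out
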