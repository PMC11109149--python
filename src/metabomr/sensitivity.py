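"""Heterogeneity and pleiotropy diagnostics.

Cochran's Q measures dispersion of the per-variant Wald ratios around the
fixed-effect IVW estimate (chi-square with J-1 df under homogeneity); the
MR-Egger intercept estimates average directional pleiotropy; the
MR-PRESSO global test (see :mod:`metabomr.estimators`) detects it via the
residual sum of squares.  A candidate is considered clean when all three
p-values sit at or above 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientInstrumentsError
from .estimators import _ivw_core, mr_egger
from .harmonize import HarmonizedSet

ALPHA = 0.05


@dataclass(frozen=True)
class SensitivityReport:
    q_stat: float
    q_df: int
    q_p: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_p: float
    presso_global_p: float

    @property
    def heterogeneity_ok(self) -> bool:
        return self.q_p >= ALPHA

    @property
    def pleiotropy_ok(self) -> bool:
        return self.egger_intercept_p >= ALPHA and self.presso_global_p >= ALPHA


def cochran_q(h: HarmonizedSet) -> tuple[float, int, float]:
    """Q, its degrees of freedom (J-1), and the chi-square tail p."""
    j = len(h)
    if j < 2:
        raise InsufficientInstrumentsError(f"Cochran's Q needs >= 2 variants, got {j}")
    g, _, G, sG = h.arrays()
    w = 1.0 / sG**2
    _, _, q = _ivw_core(g, G, w)  # Q about the fixed-effect IVW center
    df = j - 1
    return float(q), df, float(stats.chi2.sf(q, df))


def egger_intercept_test(h: HarmonizedSet) -> tuple[float, float, float]:
    """(intercept, SE, two-sided p) from the MR-Egger fit."""
    fit = mr_egger(h)
    return fit.intercept, fit.intercept_se, fit.intercept_p


def sensitivity_report(h: HarmonizedSet, presso_global_p: float) -> SensitivityReport:
    q, df, q_p = cochran_q(h)
    intercept, se, p_int = egger_intercept_test(h)
    return SensitivityReport(
        q_stat=q, q_df=df, q_p=q_p,
        egger_intercept=intercept, egger_intercept_se=se, egger_intercept_p=p_int,
        presso_global_p=presso_global_p,
    )
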