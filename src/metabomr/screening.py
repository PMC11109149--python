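"""Candidate-selection logic across the metabolite screen.

A metabolite passes the screen when (1) its IVW p-value is below 0.05,
(2) no horizontal pleiotropy is detected (Egger intercept and PRESSO
global tests both at or above 0.05; heterogeneity is a reported flag and
only excludes in strict mode), and (3) the four estimators (IVW,
MR-Egger, weighted median, MR-PRESSO) agree in sign.  A Bonferroni tier
(alpha / m, m = 486 metabolites by default) marks which of the passing
candidates survive multiple-testing correction.  Reverse MR swaps the
exposure and outcome roles with identical settings and confirms the
absence of reverse causation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .errors import ConfigurationError, InsufficientInstrumentsError
from .estimators import MrResult, ivw, mr_egger, mr_presso, weighted_median
from .harmonize import harmonize
from .instruments import PairwiseLd, SelectionParams, build_instrument_set
from .sensitivity import ALPHA, SensitivityReport
from .sumstats_io import StudyTable

#: estimators whose signs must agree for direction consistency
REQUIRED_METHODS = ("ivw", "mr_egger", "weighted_median", "mr_presso")


@dataclass(frozen=True)
class CandidateDecision:
    exposure_id: str
    outcome_id: str
    ivw_p: float = 1.0
    directions: dict = field(default_factory=dict)
    direction_consistent: bool = False
    heterogeneity_ok: bool = False
    pleiotropy_ok: bool = False
    passes_screen: bool = False
    bonferroni_significant: bool = False
    evaluable: bool = True
    reverse_mr_null: Optional[bool] = None


def bonferroni_threshold(alpha: float = 0.05, m: int = 486) -> float:
    """Corrected significance threshold alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ConfigurationError(f"m must be >= 1, got {m}")
    return alpha / m


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def screen_candidates(
    results: Mapping[str, Mapping[str, MrResult]],
    sens: Mapping[str, SensitivityReport],
    outcome_id: str = "outcome",
    strict_heterogeneity: bool = False,
    alpha: float = 0.05,
    bonferroni_m: int = 486,
) -> list[CandidateDecision]:
    """One decision per exposure.

    ``results[exposure]`` must map each name in :data:`REQUIRED_METHODS`
    to an :class:`MrResult` (use the PRESSO outlier-corrected estimate
    when outliers were removed, the raw one otherwise).  An exposure with
    a missing method or missing sensitivity report is marked unevaluable,
    never passed.
    """
    thr = bonferroni_threshold(alpha, bonferroni_m)
    decisions: list[CandidateDecision] = []
    for exposure_id, methods in results.items():
        missing = [m for m in REQUIRED_METHODS if m not in methods]
        report = sens.get(exposure_id)
        if missing or report is None:
            decisions.append(
                CandidateDecision(exposure_id=exposure_id, outcome_id=outcome_id, evaluable=False)
            )
            continue
        ivw_res = methods["ivw"]
        signs = {m: _sign(methods[m].beta) for m in REQUIRED_METHODS}
        consistent = len(set(signs.values())) == 1 and 0 not in signs.values()
        passes = (
            ivw_res.pval < alpha
            and consistent
            and report.pleiotropy_ok
            and (report.heterogeneity_ok or not strict_heterogeneity)
        )
        decisions.append(
            CandidateDecision(
                exposure_id=exposure_id,
                outcome_id=outcome_id,
                ivw_p=ivw_res.pval,
                directions=signs,
                direction_consistent=consistent,
                heterogeneity_ok=report.heterogeneity_ok,
                pleiotropy_ok=report.pleiotropy_ok,
                passes_screen=passes,
                bonferroni_significant=passes and ivw_res.pval < thr,
            )
        )
    return decisions


def run_four_methods(
    h,
    n_boot: int = 1000,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
):
    """All four estimators plus the PRESSO report on one harmonized set.

    Returns ``(methods, presso_report)`` where ``methods`` feeds
    :func:`screen_candidates` ('mr_presso' is the corrected estimate when
    outliers were removed, the raw estimate otherwise).
    """
    report, raw, corrected = mr_presso(h, n_sim=n_sim, seed=seed, outlier_alpha=outlier_alpha)
    methods = {
        "ivw": ivw(h, model="random"),
        "mr_egger": mr_egger(h).result,
        "weighted_median": weighted_median(h, n_boot=n_boot, seed=seed),
        "mr_presso": corrected if corrected is not None else raw,
    }
    return methods, report


def reverse_mr(
    outcome_as_exposure: StudyTable,
    candidates: Sequence[StudyTable],
    params: SelectionParams = SelectionParams(),
    ld: Optional[PairwiseLd] = None,
    palindrome_policy: str = "infer_by_eaf",
    n_boot: int = 1000,
    n_sim: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[CandidateDecision]:
    """Role-swapped MR of the outcome on each candidate metabolite.

    Uses the same instrument selection, harmonization and estimators as
    the forward analysis.  ``reverse_mr_null`` is True when the reverse
    IVW p-value is >= alpha and the three complementary methods are
    concordantly non-significant.
    """
    iv_set = build_instrument_set(outcome_as_exposure, params, ld)
    decisions: list[CandidateDecision] = []
    for cand in candidates:
        if len(iv_set) == 0:
            decisions.append(
                CandidateDecision(
                    exposure_id=outcome_as_exposure.trait_id,
                    outcome_id=cand.trait_id,
                    evaluable=False,
                )
            )
            continue
        h = harmonize(iv_set, cand, palindrome_policy)
        try:
            methods, _ = run_four_methods(h, n_boot=n_boot, n_sim=n_sim, seed=seed)
        except InsufficientInstrumentsError:
            decisions.append(
                CandidateDecision(
                    exposure_id=outcome_as_exposure.trait_id,
                    outcome_id=cand.trait_id,
                    evaluable=False,
                )
            )
            continue
        null = all(methods[m].pval >= alpha for m in REQUIRED_METHODS)
        signs = {m: _sign(methods[m].beta) for m in REQUIRED_METHODS}
        decisions.append(
            CandidateDecision(
                exposure_id=outcome_as_exposure.trait_id,
                outcome_id=cand.trait_id,
                ivw_p=methods["ivw"].pval,
                directions=signs,
                direction_consistent=len(set(signs.values())) == 1 and 0 not in signs.values(),
                reverse_mr_null=null,
            )
        )
    return decisions
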