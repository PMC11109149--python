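"""Synthetic paired GWAS summary statistics with known causal structure.

The generator emulates the statistical shape of a metabolite GWAS used as
exposure (continuous trait, N = 7824) against a large binary outcome GWAS
(N = 486,484 with a low case fraction, effects on the log-odds scale).
For each instrument j:

* a minor-allele frequency is drawn uniformly from ``maf_range``;
* the true SNP-exposure effect gamma_j ~ Normal(0, gamma_sd) is resampled
  until its expected F-statistic, N_exp * R2 / (1 - R2) with
  R2 = 2*maf*(1-maf)*gamma^2, exceeds ``f_expected_min`` — mirroring the
  strong-instrument regime of per-variant F well above the 10 cutoff;
* the observed exposure effect adds Normal(0, se) noise with
  se = 1/sqrt(2*maf*(1-maf)*N_exp);
* the true outcome effect is beta_causal * gamma_j + alpha_j, where
  alpha_j ~ Normal(pleiotropy_mean, pleiotropy_sd) is horizontal
  pleiotropy, inflated by ``outlier_scale`` standard errors for planted
  outliers; observed outcome effects add noise with
  se = 1/sqrt(2*maf*(1-maf)*N_out*cf*(1-cf)) (normal approximation to a
  logistic GWAS — no individual-level genotypes are simulated).

Optional extras exercise specific pipeline stages: LD decoy variants
placed inside an instrument's clumping window (``ld_block_size`` > 1),
and outcome-specific loci (``n_outcome_snps``) that instrument the
*outcome* for reverse-MR scenarios, with ``reverse_beta`` their effect on
the exposure.  Outcome rows are re-oriented at random (allele swap or
strand complement) so harmonization is exercised end-to-end.

All randomness flows from ``seed`` through numpy's SeedSequence; the same
config reproduces identical tables byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .harmonize import HarmonizedSet, harmonize
from .instruments import IndependentLd, PairwiseLd, SelectionParams, build_instrument_set
from .sumstats_io import StudyTable, VariantAssociation

#: non-palindromic allele pairs the generator draws from
_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"), ("A", "C"), ("G", "T"))
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

_MAX_RESAMPLE = 1000


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic exposure-outcome pair.

    Defaults follow the emulated design: exposure N = 7824, outcome
    N = 486,484 with 11,643 cases, instrument counts in the 7-37 range
    (22 by default), and per-variant strength comfortably above the weak
    instrument cutoff (the emulated screen's weakest retained IV had
    F = 17.41, so truncation sits at an expected F of 30).
    """

    seed: int
    n_snps: int = 22
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_sd: float = 0.3
    n_exposure: int = 7824
    n_outcome: int = 486_484
    case_fraction: float = 11_643 / 486_484
    beta_causal: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    outlier_frac: float = 0.0
    outlier_scale: float = 10.0
    n_outcome_snps: int = 0
    reverse_beta: float = 0.0
    ld_block_size: int = 1
    ld_r2: float = 0.8
    f_expected_min: float = 30.0
    exposure_id: str = "exposure"
    outcome_id: str = "outcome"
    id_offset: int = 0
    pos_offset: int = 0

    def validate(self) -> None:
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ConfigurationError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not 0.0 < self.case_fraction < 1.0:
            raise ConfigurationError("case_fraction must be in (0, 1)")
        for name in ("gamma_sd", "pleiotropy_sd", "outlier_scale"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.outlier_frac <= 1.0:
            raise ConfigurationError("outlier_frac must be in [0, 1]")
        if self.ld_block_size < 1:
            raise ConfigurationError("ld_block_size must be >= 1")


@dataclass(frozen=True)
class TruthRecord:
    variant_id: str
    role: str              # instrument | decoy | outcome_locus
    maf: float
    gamma_true: float      # true SNP-exposure effect
    alpha: float           # horizontal pleiotropy on the outcome
    big_gamma_true: float  # true SNP-outcome effect (log-odds)
    is_outlier: bool


@dataclass
class ScenarioTruth:
    beta_causal: float
    seed: int
    records: list[TruthRecord]
    ld_pairs: dict[tuple[str, str], float] = field(default_factory=dict)

    def instrument_ids(self) -> list[str]:
        return [r.variant_id for r in self.records if r.role == "instrument"]

    def ld_source(self) -> PairwiseLd:
        return PairwiseLd(self.ld_pairs) if self.ld_pairs else IndependentLd()


def _two_sided_p(beta: float, se: float) -> float:
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return float(min(max(p, 5e-324), 1.0))


def _draw_strong_gamma(rng: np.random.Generator, maf: float, cfg: ScenarioConfig, n_eff: float) -> float:
    """Resample a true effect until its expected F exceeds the truncation bound."""
    two_pq = 2.0 * maf * (1.0 - maf)
    for _ in range(_MAX_RESAMPLE):
        gamma = rng.normal(0.0, cfg.gamma_sd)
        r2 = two_pq * gamma**2
        if r2 >= 1.0:
            continue
        if n_eff * r2 / (1.0 - r2) > cfg.f_expected_min:
            # report the trait-increasing allele as the effect allele, the
            # usual degree of freedom in GWAS labeling; directional
            # pleiotropy is then defined relative to that orientation
            return float(abs(gamma))
    raise ConfigurationError(
        f"gamma_sd={cfg.gamma_sd} too small to reach expected F > {cfg.f_expected_min} "
        f"at n={n_eff:.0f} within {_MAX_RESAMPLE} draws"
    )


def simulate_pair(cfg: ScenarioConfig) -> tuple[StudyTable, StudyTable, ScenarioTruth]:
    """One exposure/outcome pair of summary-statistic tables plus the truth."""
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    cf = cfg.case_fraction
    n_eff_out = cfg.n_outcome * cf * (1.0 - cf)

    exp_records: list[VariantAssociation] = []
    out_records: list[VariantAssociation] = []
    truth_records: list[TruthRecord] = []
    ld_pairs: dict[tuple[str, str], float] = {}

    n_out = int(round(cfg.outlier_frac * cfg.n_snps))
    outlier_idx = set(rng.choice(cfg.n_snps, size=n_out, replace=False).tolist()) if n_out else set()

    counter = cfg.id_offset
    block = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"rs{counter:08d}"

    def place(block_idx: int, within: int = 0) -> tuple[str, int]:
        chrom = "1" if block_idx % 2 == 0 else "2"
        pos = cfg.pos_offset + 10_000_000 + (block_idx // 2) * 2_000_000 + within * 10_000
        return chrom, pos

    def emit(vid, chrom, pos, maf, b_exp, se_exp, b_out, se_out):
        """Append matching exposure and outcome rows, randomly re-orienting
        the outcome row (allele swap / strand complement)."""
        ea, oa = _ALLELE_PAIRS[rng.integers(len(_ALLELE_PAIRS))]
        exp_records.append(VariantAssociation(
            vid, chrom, pos, ea, oa, round(float(maf), 6),
            float(b_exp), float(se_exp), _two_sided_p(b_exp, se_exp), cfg.n_exposure,
        ))
        u = rng.random()
        o_ea, o_oa, o_eaf, o_beta = ea, oa, maf, b_out
        if u < 0.25:   # swapped allele labels
            o_ea, o_oa, o_eaf, o_beta = oa, ea, 1.0 - maf, -b_out
        elif u < 0.5:  # opposite strand, same orientation
            o_ea, o_oa = _COMPLEMENT[ea], _COMPLEMENT[oa]
        out_records.append(VariantAssociation(
            vid, chrom, pos, o_ea, o_oa, round(float(o_eaf), 6),
            float(o_beta), float(se_out), _two_sided_p(o_beta, se_out), cfg.n_outcome,
        ))

    for j in range(cfg.n_snps):
        maf = float(rng.uniform(*cfg.maf_range))
        two_pq = 2.0 * maf * (1.0 - maf)
        se_g = 1.0 / math.sqrt(two_pq * cfg.n_exposure)
        se_G = 1.0 / math.sqrt(two_pq * n_eff_out)
        gamma = _draw_strong_gamma(rng, maf, cfg, cfg.n_exposure)
        alpha = float(rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd))
        is_outlier = j in outlier_idx
        if is_outlier:
            alpha += float(rng.choice((-1.0, 1.0))) * cfg.outlier_scale * se_G
        big_gamma = cfg.beta_causal * gamma + alpha
        b_exp = gamma + rng.normal(0.0, se_g)
        b_out = big_gamma + rng.normal(0.0, se_G)

        chrom, pos = place(block)
        lead_id = new_id()
        emit(lead_id, chrom, pos, maf, b_exp, se_g, b_out, se_G)
        truth_records.append(TruthRecord(lead_id, "instrument", maf, gamma, alpha, big_gamma, is_outlier))

        # correlated decoys inside the lead's clumping window
        block_ids = [lead_id]
        for d in range(1, cfg.ld_block_size):
            r = math.sqrt(cfg.ld_r2)
            b_exp_d = r * b_exp + rng.normal(0.0, se_g * math.sqrt(1.0 - cfg.ld_r2))
            b_out_d = r * b_out + rng.normal(0.0, se_G * math.sqrt(1.0 - cfg.ld_r2))
            chrom_d, pos_d = place(block, within=d)
            did = new_id()
            emit(did, chrom_d, pos_d, maf, b_exp_d, se_g, b_out_d, se_G)
            truth_records.append(TruthRecord(did, "decoy", maf, r * gamma, 0.0, r * big_gamma, False))
            block_ids.append(did)
        for a_i in range(len(block_ids)):
            for b_i in range(a_i + 1, len(block_ids)):
                ld_pairs[(block_ids[a_i], block_ids[b_i])] = cfg.ld_r2
        block += 1

    # outcome-specific loci (instruments of the outcome, for reverse MR)
    for _ in range(cfg.n_outcome_snps):
        maf = float(rng.uniform(*cfg.maf_range))
        two_pq = 2.0 * maf * (1.0 - maf)
        se_g = 1.0 / math.sqrt(two_pq * cfg.n_exposure)
        se_G = 1.0 / math.sqrt(two_pq * n_eff_out)
        g_out = _draw_strong_gamma(rng, maf, cfg, n_eff_out)
        gamma_exp = cfg.reverse_beta * g_out
        b_exp = gamma_exp + rng.normal(0.0, se_g)
        b_out = g_out + rng.normal(0.0, se_G)
        chrom, pos = place(block)
        vid = new_id()
        emit(vid, chrom, pos, maf, b_exp, se_g, b_out, se_G)
        truth_records.append(TruthRecord(vid, "outcome_locus", maf, gamma_exp, 0.0, g_out, False))
        block += 1

    exposure = StudyTable(
        trait_id=cfg.exposure_id, records=exp_records,
        trait_type="continuous", n_total=cfg.n_exposure,
    )
    outcome = StudyTable(
        trait_id=cfg.outcome_id, records=out_records,
        trait_type="binary", n_total=cfg.n_outcome,
        n_cases=int(round(cf * cfg.n_outcome)),
    )
    exposure.validate()
    outcome.validate()
    truth = ScenarioTruth(
        beta_causal=cfg.beta_causal, seed=cfg.seed,
        records=truth_records, ld_pairs=ld_pairs,
    )
    return exposure, outcome, truth


@dataclass
class BatchResult:
    exposures: dict[str, StudyTable]
    outcome: StudyTable
    truths: dict[str, ScenarioTruth]
    manifest: pd.DataFrame
    ld: PairwiseLd


def simulate_batch(
    n_exposures: int,
    causal_betas: Optional[Mapping[str, float]] = None,
    cfg: Optional[ScenarioConfig] = None,
    n_snps_range: tuple[int, int] = (7, 37),
) -> BatchResult:
    """A reduced-scale metabolite screen: ``n_exposures`` exposure studies
    against one shared binary outcome study.

    ``causal_betas`` maps exposure ids (``met_001`` ...) to true causal
    log-odds effects; unlisted exposures are generated under the null.
    Per-exposure instrument counts are drawn uniformly from
    ``n_snps_range`` (the emulated screen's 7-37)."""
    if cfg is None:
        raise ConfigurationError("simulate_batch requires a template ScenarioConfig (with seed)")
    causal_betas = dict(causal_betas or {})
    ids = [f"met_{i+1:03d}" for i in range(n_exposures)]
    unknown = set(causal_betas) - set(ids)
    if unknown:
        raise ConfigurationError(f"causal ids not in the batch: {sorted(unknown)}")

    master = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    children = np.random.SeedSequence(cfg.seed).spawn(n_exposures)
    exposures: dict[str, StudyTable] = {}
    truths: dict[str, ScenarioTruth] = {}
    out_records: list[VariantAssociation] = []
    ld_pairs: dict[tuple[str, str], float] = {}
    rows = []
    for i, (eid, child) in enumerate(zip(ids, children)):
        n_snps = int(master.integers(n_snps_range[0], n_snps_range[1] + 1))
        child_seed = int(child.generate_state(1)[0] % 2**31)
        sub_cfg = replace(
            cfg,
            seed=child_seed,
            n_snps=n_snps,
            beta_causal=causal_betas.get(eid, 0.0),
            exposure_id=eid,
            id_offset=cfg.id_offset + i * 100_000,
            pos_offset=cfg.pos_offset + i * 1_000_000_000,
        )
        exposure, outcome, truth = simulate_pair(sub_cfg)
        exposures[eid] = exposure
        truths[eid] = truth
        out_records.extend(outcome.records)
        ld_pairs.update(truth.ld_pairs)
        rows.append({
            "exposure_id": eid, "beta_causal": sub_cfg.beta_causal,
            "n_snps": n_snps, "seed": child_seed,
        })

    outcome_all = StudyTable(
        trait_id=cfg.outcome_id, records=out_records,
        trait_type="binary", n_total=cfg.n_outcome,
        n_cases=int(round(cfg.case_fraction * cfg.n_outcome)),
    )
    outcome_all.validate()
    manifest = pd.DataFrame(rows)
    ld = PairwiseLd(ld_pairs) if ld_pairs else IndependentLd()
    return BatchResult(exposures=exposures, outcome=outcome_all, truths=truths,
                       manifest=manifest, ld=ld)


def harmonized_truth_set(
    exposure: StudyTable,
    outcome: StudyTable,
    truth: ScenarioTruth,
    palindrome_policy: str = "infer_by_eaf",
) -> HarmonizedSet:
    """Harmonize exactly the intended instruments, bypassing selection.

    Used for estimator operating-characteristic experiments where the
    quantity under study is the estimator itself, not the selection
    pipeline."""
    sub = exposure.subset(truth.instrument_ids())
    iv = build_instrument_set(
        sub, SelectionParams(p_threshold=1.0 - 1e-12, f_min=0.0), IndependentLd()
    )
    return harmonize(iv, outcome, palindrome_policy)
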