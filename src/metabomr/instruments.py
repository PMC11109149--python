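"""Instrument selection for one exposure.

Pipeline: genome-wide filter (p < 1e-5 by default), greedy LD clumping
(r-squared < 0.01 within 500 kb), per-variant variance explained and
F-statistic, and removal of weak instruments (F < 10).

The variance explained by one variant, with EAF the effect-allele
frequency, beta/se its estimated effect, and N the study size::

    R2 = 2*EAF*(1-EAF)*beta^2 / (2*EAF*(1-EAF)*beta^2 + 2*EAF*(1-EAF)*N*se^2)

and instrument strength, for K variants jointly explaining R2::

    F = ((N - K - 1) / K) * (R2 / (1 - R2))

The weak-instrument filter applies F per variant (K = 1, that variant's
R2); for large N and small R2 this is asymptotically (beta/se)^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import ConfigurationError, DegenerateInputError, LdLookupError
from .sumstats_io import StudyTable, VariantAssociation


@dataclass(frozen=True)
class SelectionParams:
    """Thresholds of the instrument-selection pipeline (defaults as used
    throughout: p < 1e-5, clump r2 < 0.01 within 500 kb, keep F >= 10)."""

    p_threshold: float = 1e-5
    r2_max: float = 0.01
    window_kb: float = 500.0
    f_min: float = 10.0


@dataclass(frozen=True)
class InstrumentRecord:
    variant: VariantAssociation
    r2: float
    f_stat: float


@dataclass
class InstrumentSet:
    exposure_id: str
    instruments: list[InstrumentRecord]
    selection_params: SelectionParams
    #: variant counts after each stage: input -> pvalue -> clump -> strength
    stage_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.instruments)

    @property
    def variant_ids(self) -> list[str]:
        return [rec.variant.variant_id for rec in self.instruments]


class PairwiseLd:
    """Pluggable pairwise r-squared source.

    Holds a symmetric mapping of variant-id pairs to r2.  A pair the
    clumping rule needs but the source does not know is an error: silent
    zeros would let correlated instruments through.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float]):
        self._pairs: dict[frozenset, float] = {}
        for (a, b), r2 in pairs.items():
            if not 0.0 <= r2 <= 1.0:
                raise ConfigurationError(f"LD r2 for ({a}, {b}) outside [0, 1]: {r2}")
            self._pairs[frozenset((a, b))] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        key = frozenset((a, b))
        try:
            return self._pairs[key]
        except KeyError:
            raise LdLookupError(f"LD source has no r2 for pair ({a}, {b})") from None

    @classmethod
    def from_table(cls, path: str) -> "PairwiseLd":
        df = pd.read_csv(path, sep="\t", dtype={"variant_id_a": str, "variant_id_b": str})
        need = {"variant_id_a", "variant_id_b", "r2"}
        if not need <= set(df.columns):
            raise ConfigurationError(f"{path}: LD table must have columns {sorted(need)}")
        return cls({(r.variant_id_a, r.variant_id_b): r.r2 for r in df.itertuples()})

    def to_table(self, path: str) -> str:
        rows = [sorted(k) + [v] for k, v in self._pairs.items()]
        rows.sort()
        pd.DataFrame(rows, columns=["variant_id_a", "variant_id_b", "r2"]).to_csv(
            path, sep="\t", index=False
        )
        return path


class IndependentLd(PairwiseLd):
    """LD source asserting all pairs independent (r2 = 0).

    Only appropriate for inputs known to be pre-pruned or, as in the
    synthetic generator, laid out so that no two variants share a window.
    """

    def __init__(self) -> None:
        super().__init__({})

    def r2(self, a: str, b: str) -> float:  # noqa: D102 - documented in class
        return 1.0 if a == b else 0.0


def select_by_pvalue(table: StudyTable, p_threshold: float = 1e-5) -> StudyTable:
    """Records with pval strictly below the threshold, order preserved."""
    if not 0.0 < p_threshold < 1.0:
        raise ConfigurationError(f"p_threshold must be in (0, 1), got {p_threshold}")
    return table.subset(r.variant_id for r in table.records if r.pval < p_threshold)


def ld_clump(
    table: StudyTable,
    ld: PairwiseLd,
    r2_max: float = 0.01,
    window_kb: float = 500.0,
) -> StudyTable:
    """Greedy clumping: repeatedly keep the lowest-p remaining variant and
    drop same-chromosome variants within ``window_kb`` whose r2 with it is
    >= ``r2_max``.  Ties on p break on (chrom, pos)."""
    remaining = sorted(table.records, key=lambda r: (r.pval, r.chrom, r.pos))
    window_bp = window_kb * 1000.0
    kept: list[VariantAssociation] = []
    while remaining:
        lead = remaining.pop(0)
        kept.append(lead)
        survivors = []
        for r in remaining:
            if r.chrom == lead.chrom and abs(r.pos - lead.pos) <= window_bp:
                if ld.r2(lead.variant_id, r.variant_id) >= r2_max:
                    continue
            survivors.append(r)
        remaining = survivors
    return table.subset(r.variant_id for r in kept)


def variance_explained(v: VariantAssociation) -> float:
    """Proportion of exposure variance explained by one variant."""
    if v.eaf <= 0.0 or v.eaf >= 1.0:
        raise DegenerateInputError(
            f"{v.variant_id}: eaf {v.eaf} degenerate for variance explained"
        )
    num = 2.0 * v.eaf * (1.0 - v.eaf) * v.beta**2
    den = num + 2.0 * v.eaf * (1.0 - v.eaf) * v.n * v.se**2
    return num / den


def f_statistic(r2: float, n: int, k: int = 1) -> float:
    """Instrument-strength F for K variants jointly explaining R2."""
    if not 0.0 <= r2 < 1.0:
        raise DegenerateInputError(f"r2 must be in [0, 1), got {r2}")
    if k < 1 or n <= k + 1:
        raise DegenerateInputError(f"need n > k + 1 >= 2, got n={n}, k={k}")
    return (n - k - 1) / k * (r2 / (1.0 - r2))


def build_instrument_set(
    table: StudyTable,
    params: SelectionParams = SelectionParams(),
    ld: Optional[PairwiseLd] = None,
) -> InstrumentSet:
    """Full selection pipeline; an exposure with nothing surviving yields an
    empty set (callers skip it downstream rather than erroring)."""
    if ld is None:
        ld = IndependentLd()
    counts = {"input": len(table)}
    sig = select_by_pvalue(table, params.p_threshold)
    counts["after_pvalue"] = len(sig)
    clumped = ld_clump(sig, ld, params.r2_max, params.window_kb)
    counts["after_clump"] = len(clumped)
    instruments = []
    for v in clumped.records:
        r2 = variance_explained(v)
        f = f_statistic(r2, v.n, k=1)
        if f >= params.f_min:  # "excluded those with an F-statistic lower than 10"
            instruments.append(InstrumentRecord(variant=v, r2=r2, f_stat=f))
    counts["after_strength"] = len(instruments)
    return InstrumentSet(
        exposure_id=table.trait_id,
        instruments=instruments,
        selection_params=params,
        stage_counts=counts,
    )
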