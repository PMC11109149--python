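"""Allele harmonization of exposure instruments with outcome associations.

Two-sample MR needs, per variant, the SNP-exposure effect gamma and the
SNP-outcome effect Gamma expressed for the *same* allele.  Outcome rows
reported for the swapped allele have their effect negated; rows reported
on the opposite strand are complemented first.  Palindromic variants
(A/T or C/G) cannot be resolved from alleles alone and are handled by an
explicit policy:

``drop``
    always excluded;
``infer_by_eaf`` (default)
    excluded when either study's minor-allele frequency is within 0.08 of
    0.5 (ambiguous), otherwise oriented so the allele-frequency sides
    agree;
``keep``
    assume both studies report the same strand and orientation.

Exposure allele frequency stays authoritative for downstream strength
calculations; the outcome frequency is consulted only for palindrome
inference.  Instruments absent from the outcome are dropped and logged
(no proxy lookup).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigurationError
from .instruments import InstrumentSet
from .sumstats_io import StudyTable

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: half-width of the allele-frequency ambiguity window around 0.5
PALINDROME_AMBIGUITY = 0.08


def _comp(allele: str) -> str:
    return allele.translate(_COMPLEMENT)


def _is_palindromic(a: str, b: str) -> bool:
    return _comp(a) == b


@dataclass(frozen=True)
class HarmonizedVariant:
    variant_id: str
    gamma: float = 0.0          # SNP-exposure effect
    se_gamma: float = 0.0
    big_gamma: float = 0.0      # SNP-outcome effect (log-odds for binary)
    se_big_gamma: float = 0.0
    eaf: float = 0.0            # exposure effect-allele frequency
    flipped: bool = False
    dropped_reason: Optional[str] = None  # missing_in_outcome | palindromic_ambiguous | allele_mismatch


@dataclass
class HarmonizedSet:
    exposure_id: str
    outcome_id: str
    variants: list[HarmonizedVariant]
    drop_log: list[HarmonizedVariant] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.variants)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(gamma, se_gamma, big_gamma, se_big_gamma) as float arrays."""
        g = np.array([v.gamma for v in self.variants])
        sg = np.array([v.se_gamma for v in self.variants])
        G = np.array([v.big_gamma for v in self.variants])
        sG = np.array([v.se_big_gamma for v in self.variants])
        return g, sg, G, sG


def from_arrays(
    gamma, se_gamma, big_gamma, se_big_gamma,
    exposure_id: str = "exposure", outcome_id: str = "outcome",
) -> HarmonizedSet:
    """Assemble a HarmonizedSet straight from effect arrays (already aligned)."""
    variants = [
        HarmonizedVariant(
            variant_id=f"v{i+1}", gamma=float(g), se_gamma=float(sg),
            big_gamma=float(G), se_big_gamma=float(sG),
        )
        for i, (g, sg, G, sG) in enumerate(zip(gamma, se_gamma, big_gamma, se_big_gamma))
    ]
    return HarmonizedSet(exposure_id=exposure_id, outcome_id=outcome_id, variants=variants)


def harmonize(
    instruments: InstrumentSet,
    outcome: StudyTable,
    palindrome_policy: str = "infer_by_eaf",
) -> HarmonizedSet:
    """Align each instrument with the outcome study; every exclusion is
    recorded in the drop log with its reason."""
    if palindrome_policy not in ("drop", "infer_by_eaf", "keep"):
        raise ConfigurationError(f"unknown palindrome_policy {palindrome_policy!r}")

    kept: list[HarmonizedVariant] = []
    dropped: list[HarmonizedVariant] = []
    for rec in instruments.instruments:
        exp = rec.variant
        out = outcome.get(exp.variant_id)
        if out is None:
            dropped.append(HarmonizedVariant(exp.variant_id, dropped_reason="missing_in_outcome"))
            continue

        e_pair = (exp.effect_allele, exp.other_allele)
        o_pair = (out.effect_allele, out.other_allele)

        if _is_palindromic(*e_pair):
            if set(o_pair) != set(e_pair):
                dropped.append(HarmonizedVariant(exp.variant_id, dropped_reason="allele_mismatch"))
                continue
            if palindrome_policy == "drop":
                dropped.append(
                    HarmonizedVariant(exp.variant_id, dropped_reason="palindromic_ambiguous")
                )
                continue
            if palindrome_policy == "keep":
                # same two letters either way round; trust the reported labels
                flip = o_pair[0] == e_pair[1]
            else:  # infer_by_eaf
                if abs(exp.eaf - 0.5) < PALINDROME_AMBIGUITY or abs(out.eaf - 0.5) < PALINDROME_AMBIGUITY:
                    dropped.append(
                        HarmonizedVariant(exp.variant_id, dropped_reason="palindromic_ambiguous")
                    )
                    continue
                # orient so both studies put the effect allele on the same
                # side of 0.5
                flip = (exp.eaf < 0.5) != (out.eaf < 0.5)
        else:
            if o_pair == e_pair:
                flip = False
            elif o_pair == e_pair[::-1]:
                flip = True
            else:
                c_pair = (_comp(o_pair[0]), _comp(o_pair[1]))
                if c_pair == e_pair:
                    flip = False
                elif c_pair == e_pair[::-1]:
                    flip = True
                else:
                    dropped.append(
                        HarmonizedVariant(exp.variant_id, dropped_reason="allele_mismatch")
                    )
                    continue

        big_gamma = -out.beta if flip else out.beta
        kept.append(
            HarmonizedVariant(
                variant_id=exp.variant_id,
                gamma=exp.beta,
                se_gamma=exp.se,
                big_gamma=big_gamma,
                se_big_gamma=out.se,
                eaf=exp.eaf,
                flipped=flip,
            )
        )
    return HarmonizedSet(
        exposure_id=instruments.exposure_id,
        outcome_id=outcome.trait_id,
        variants=kept,
        drop_log=dropped,
    )
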