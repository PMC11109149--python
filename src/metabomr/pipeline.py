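"""End-to-end orchestration from one YAML configuration.

Stages per outcome: instrument selection -> harmonization -> four
estimators (IVW primary; MR-Egger, weighted median, MR-PRESSO
complementary) -> sensitivity diagnostics -> candidate screening with a
Bonferroni tier -> reverse MR on passing candidates -> pathway
over-representation of IVW-significant metabolites.

Outputs are tab-separated reports plus a plain-text run log recording
every parameter, seed and per-stage count.  Reruns with an identical
configuration reproduce every output byte-for-byte (no timestamps are
written).
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, InsufficientInstrumentsError, PipelineError
from .harmonize import harmonize
from .instruments import IndependentLd, PairwiseLd, SelectionParams, build_instrument_set
from .pathway import load_library, over_representation
from .screening import (
    REQUIRED_METHODS,
    bonferroni_threshold,
    reverse_mr,
    run_four_methods,
    screen_candidates,
)
from .sensitivity import sensitivity_report
from .sumstats_io import StudyTable, read_sumstats


@dataclass
class RunConfig:
    out_dir: str
    seed: int
    exposures: list[dict]          # id, path, optional name / group / dialect
    outcomes: list[dict]           # id, path, optional dialect
    ld: str                        # path to LD TSV, or the literal "independent"
    selection: SelectionParams = field(default_factory=SelectionParams)
    alpha: float = 0.05
    bonferroni_m: Optional[int] = None   # default: number of exposures tested
    n_boot: int = 1000
    n_sim: int = 1000
    palindrome_policy: str = "infer_by_eaf"
    strict_heterogeneity: bool = False
    do_reverse_mr: bool = True
    pathway_library: Optional[str] = None
    compound_map: dict = field(default_factory=dict)
    impact: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        if not os.path.exists(path):
            raise ConfigurationError(f"config file not found: {path}")
        with open(path, "rt") as fh:
            raw = yaml.safe_load(fh) or {}
        params = raw.get("params", {})
        sel = SelectionParams(
            p_threshold=float(params.get("p_threshold", 1e-5)),
            r2_max=float(params.get("r2_max", 0.01)),
            window_kb=float(params.get("window_kb", 500.0)),
            f_min=float(params.get("f_min", 10.0)),
        )
        pathway = raw.get("pathway") or {}
        for key in ("out_dir", "seed", "exposures", "outcomes", "ld"):
            if key not in raw:
                raise ConfigurationError(f"{path}: missing required config key {key!r}")
        cfg = cls(
            out_dir=raw["out_dir"],
            seed=int(raw["seed"]),
            exposures=list(raw["exposures"]),
            outcomes=list(raw["outcomes"]),
            ld=str(raw["ld"]),
            selection=sel,
            alpha=float(params.get("alpha", 0.05)),
            bonferroni_m=params.get("bonferroni_m"),
            n_boot=int(params.get("n_boot", 1000)),
            n_sim=int(params.get("n_sim", 1000)),
            palindrome_policy=str(params.get("palindrome_policy", "infer_by_eaf")),
            strict_heterogeneity=bool(params.get("strict_heterogeneity", False)),
            do_reverse_mr=bool(raw.get("reverse_mr", True)),
            pathway_library=pathway.get("library"),
            compound_map=dict(pathway.get("compound_map", {})),
            impact=dict(pathway.get("impact", {})),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for spec_list, kind in ((self.exposures, "exposure"), (self.outcomes, "outcome")):
            for item in spec_list:
                if "id" not in item or "path" not in item:
                    raise ConfigurationError(f"every {kind} needs 'id' and 'path': {item}")
                if not os.path.exists(item["path"]):
                    raise ConfigurationError(f"{kind} table not found: {item['path']}")
        if self.ld != "independent" and not os.path.exists(self.ld):
            raise ConfigurationError(f"LD table not found: {self.ld}")
        if self.pathway_library and not os.path.exists(self.pathway_library):
            raise ConfigurationError(f"pathway library not found: {self.pathway_library}")


def _result_row(exposure_id: str, name: str, res) -> dict:
    return {
        "exposure": exposure_id, "metabolite": name, "method": res.method,
        "n_snp": res.n_snp, "beta": res.beta, "se": res.se,
        "or": res.odds_ratio, "or_ci_low": res.or_ci_low, "or_ci_high": res.or_ci_high,
        "pval": res.pval,
    }


def run_full(cfg: RunConfig) -> str:
    """Run the whole analysis; returns the output directory."""
    cfg.validate()
    os.makedirs(cfg.out_dir, exist_ok=True)
    log: list[str] = []
    log.append("metabomr run")
    log.append(f"seed={cfg.seed}")
    log.append(
        "params: p_threshold={p} r2_max={r} window_kb={w} f_min={f} alpha={a} "
        "bonferroni_m={m} n_boot={nb} n_sim={ns} palindrome_policy={pp} "
        "strict_heterogeneity={sh}".format(
            p=cfg.selection.p_threshold, r=cfg.selection.r2_max, w=cfg.selection.window_kb,
            f=cfg.selection.f_min, a=cfg.alpha,
            m=cfg.bonferroni_m if cfg.bonferroni_m else len(cfg.exposures),
            nb=cfg.n_boot, ns=cfg.n_sim, pp=cfg.palindrome_policy,
            sh=cfg.strict_heterogeneity,
        )
    )

    ld = IndependentLd() if cfg.ld == "independent" else PairwiseLd.from_table(cfg.ld)
    m_tests = cfg.bonferroni_m if cfg.bonferroni_m else len(cfg.exposures)

    exposure_tables: dict[str, StudyTable] = {}
    names: dict[str, str] = {}
    for item in cfg.exposures:
        exposure_tables[item["id"]] = read_sumstats(
            item["path"], dialect=item.get("dialect"), trait_id=item["id"]
        )
        names[item["id"]] = item.get("name", item["id"])

    lib = load_library(cfg.pathway_library) if cfg.pathway_library else None

    ivw_matrix: dict[str, dict[str, float]] = {}

    for out_item in cfg.outcomes:
        oid = out_item["id"]
        outcome = read_sumstats(out_item["path"], dialect=out_item.get("dialect"), trait_id=oid)
        # stable per-outcome spawn key (process-independent, unlike hash())
        okey = zlib.crc32(oid.encode()) % 2**31
        seed_seq = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(okey,))
        child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in
                       seed_seq.spawn(len(cfg.exposures))]

        est_rows, sens_rows, skipped = [], [], []
        results_by_exposure: dict[str, dict] = {}
        sens_by_exposure: dict[str, object] = {}
        for (eid, table), child_seed in zip(exposure_tables.items(), child_seeds):
            stage = "instruments"
            try:
                iv = build_instrument_set(table, cfg.selection, ld)
                counts = dict(iv.stage_counts)
                stage = "harmonize"
                h = harmonize(iv, outcome, cfg.palindrome_policy)
                counts["harmonized"] = len(h)
                log.append(
                    f"outcome={oid} exposure={eid} seed={child_seed} "
                    + " ".join(f"{k}={v}" for k, v in counts.items())
                )
                if len(h) < 4:
                    skipped.append({"exposure": eid, "outcome": oid,
                                    "n_harmonized": len(h),
                                    "reason": "fewer than 4 harmonized instruments"})
                    continue
                stage = "estimators"
                methods, presso_rep = run_four_methods(
                    h, n_boot=cfg.n_boot, n_sim=cfg.n_sim, seed=child_seed
                )
                stage = "sensitivity"
                rep = sensitivity_report(h, presso_rep.global_p)
            except InsufficientInstrumentsError as exc:
                skipped.append({"exposure": eid, "outcome": oid, "n_harmonized": len(h),
                                "reason": str(exc)})
                continue
            except Exception as exc:
                raise PipelineError(f"stage {stage!r} failed for exposure {eid!r}: {exc}") from exc

            results_by_exposure[eid] = methods
            sens_by_exposure[eid] = rep
            for mname in REQUIRED_METHODS:
                est_rows.append(_result_row(eid, names[eid], methods[mname]))
            sens_rows.append({
                "outcome": oid, "metabolite": names[eid],
                "super_pathway": next((x.get("group", "") for x in cfg.exposures
                                       if x["id"] == eid), ""),
                "p_global_test": rep.presso_global_p,
                "p_heterogeneity": rep.q_p,
                "p_intercept": rep.egger_intercept_p,
            })
            ivw_matrix.setdefault(eid, {})[oid] = methods["ivw"].beta

        decisions = screen_candidates(
            results_by_exposure, sens_by_exposure, outcome_id=oid,
            strict_heterogeneity=cfg.strict_heterogeneity,
            alpha=cfg.alpha, bonferroni_m=m_tests,
        )
        dec_rows = [{
            "exposure": d.exposure_id, "outcome": d.outcome_id, "ivw_p": d.ivw_p,
            **{f"dir_{m}": d.directions.get(m, 0) for m in REQUIRED_METHODS},
            "direction_consistent": d.direction_consistent,
            "heterogeneity_ok": d.heterogeneity_ok, "pleiotropy_ok": d.pleiotropy_ok,
            "passes_screen": d.passes_screen,
            "bonferroni_significant": d.bonferroni_significant,
            "evaluable": d.evaluable,
        } for d in decisions]

        pd.DataFrame(est_rows).to_csv(_p(cfg, f"estimates_{oid}.tsv"), sep="\t", index=False)
        pd.DataFrame(sens_rows).to_csv(_p(cfg, f"sensitivity_{oid}.tsv"), sep="\t", index=False)
        pd.DataFrame(dec_rows).to_csv(_p(cfg, f"decisions_{oid}.tsv"), sep="\t", index=False)
        pd.DataFrame(skipped, columns=["exposure", "outcome", "n_harmonized", "reason"]).to_csv(
            _p(cfg, f"skipped_{oid}.tsv"), sep="\t", index=False
        )
        log.append(f"outcome={oid} screened={len(decisions)} "
                   f"pass={sum(d.passes_screen for d in decisions)} "
                   f"bonferroni={sum(d.bonferroni_significant for d in decisions)} "
                   f"skipped={len(skipped)}")

        if cfg.do_reverse_mr:
            candidates = [exposure_tables[d.exposure_id] for d in decisions if d.passes_screen]
            rev = reverse_mr(
                outcome, candidates, cfg.selection, ld, cfg.palindrome_policy,
                n_boot=cfg.n_boot, n_sim=cfg.n_sim, seed=cfg.seed, alpha=cfg.alpha,
            )
            rev_rows = [{
                "exposure": d.exposure_id, "outcome": d.outcome_id, "ivw_p": d.ivw_p,
                "reverse_mr_null": d.reverse_mr_null, "evaluable": d.evaluable,
            } for d in rev]
            pd.DataFrame(rev_rows, columns=["exposure", "outcome", "ivw_p",
                                            "reverse_mr_null", "evaluable"]).to_csv(
                _p(cfg, f"reverse_{oid}.tsv"), sep="\t", index=False
            )

        if lib is not None:
            sig_ids = [eid for eid, mm in results_by_exposure.items()
                       if mm["ivw"].pval < cfg.alpha]
            query = []
            for eid in sig_ids:
                cid = cfg.compound_map.get(eid, cfg.compound_map.get(names[eid]))
                if cid:
                    query.append(cid)
            enr, unmapped = over_representation(query, lib, impact=cfg.impact or None)
            enr_rows = [{
                "trait": oid, "pathway_name": r.pathway_name, "total": r.total,
                "expected": r.expected, "hits": r.hits,
                "impact": "" if r.impact is None else r.impact,
                "pval": r.pval, "significant": r.significant,
            } for r in enr]
            pd.DataFrame(enr_rows, columns=["trait", "pathway_name", "total", "expected",
                                            "hits", "impact", "pval", "significant"]).to_csv(
                _p(cfg, f"enrichment_{oid}.tsv"), sep="\t", index=False
            )
            log.append(f"outcome={oid} enrichment: query={len(query)} unmapped={len(unmapped)}")

    mat = pd.DataFrame(ivw_matrix).T
    mat.index.name = "exposure"
    mat.to_csv(_p(cfg, "ivw_beta_matrix.tsv"), sep="\t")

    with open(_p(cfg, "run_log.txt"), "wt") as fh:
        fh.write("\n".join(log) + "\n")
    return cfg.out_dir


def _p(cfg: RunConfig, name: str) -> str:
    return os.path.join(cfg.out_dir, name)
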