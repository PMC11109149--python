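"""Reading, validating and writing GWAS summary-statistic tables.

The canonical on-disk format is plain tab-separated text with a fixed
header.  Trait-level metadata (trait id/name/type, total and case counts)
lives in a ``<path>.meta`` sidecar of ``key=value`` lines so the variant
table itself stays a clean rectangle.  A *dialect* mapping lets other
column spellings (e.g. ``SNP`` -> ``variant_id``) be ingested without
rewriting files.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import ConfigurationError, ValidationError

#: canonical column order of the on-disk format
CANONICAL_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's summary association with one trait.

    ``beta`` is on the linear scale for continuous traits and on the
    log-odds scale for binary traits; ``pos`` is 1-based.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int

    def validate(self) -> None:
        if not self.variant_id:
            raise ValidationError("variant_id must be non-empty")
        if self.pos < 1:
            raise ValidationError(f"{self.variant_id}: pos must be >= 1 (1-based)")
        for label, allele in (("effect_allele", self.effect_allele),
                              ("other_allele", self.other_allele)):
            if not allele or not set(allele) <= _VALID_BASES:
                raise ValidationError(
                    f"{self.variant_id}: {label} {allele!r} is not a sequence over ACGT"
                )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.variant_id}: effect and other allele are identical")
        if not 0.0 <= self.eaf <= 1.0:
            raise ValidationError(f"{self.variant_id}: eaf {self.eaf} outside [0, 1]")
        if not self.se > 0.0:
            raise ValidationError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if not 0.0 < self.pval <= 1.0:
            raise ValidationError(f"{self.variant_id}: pval {self.pval} outside (0, 1]")
        if self.n < 1:
            raise ValidationError(f"{self.variant_id}: n must be a positive integer")
        for name in ("eaf", "beta", "se", "pval"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"{self.variant_id}: {name} is not finite")


@dataclass
class StudyTable:
    """An ordered collection of variant associations for one trait."""

    trait_id: str
    records: list[VariantAssociation]
    trait_name: str = ""
    trait_type: str = "continuous"  # or "binary"
    n_total: int = 0
    n_cases: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.trait_name:
            self.trait_name = self.trait_id
        if self.n_total == 0 and self.records:
            self.n_total = max(r.n for r in self.records)

    def validate(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValidationError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "binary":
            if self.n_cases is None:
                raise ValidationError(f"{self.trait_id}: binary trait requires n_cases")
            if not 0 < self.n_cases < self.n_total:
                raise ValidationError(
                    f"{self.trait_id}: n_cases must lie strictly between 0 and n_total"
                )
        seen: dict[str, int] = {}
        dups = []
        for i, rec in enumerate(self.records):
            rec.validate()
            if rec.variant_id in seen:
                dups.append(rec.variant_id)
            seen[rec.variant_id] = i
        if dups:
            raise ValidationError(f"duplicate variant_id values: {sorted(set(dups))}")

    def __len__(self) -> int:
        return len(self.records)

    def get(self, variant_id: str) -> Optional[VariantAssociation]:
        if not hasattr(self, "_index") or len(self._index) != len(self.records):
            self._index = {r.variant_id: r for r in self.records}
        return self._index.get(variant_id)

    def subset(self, keep: Iterable[str]) -> "StudyTable":
        """New table with only the given variant ids, input order preserved."""
        keep = set(keep)
        sub = replace(self)
        sub.records = [r for r in self.records if r.variant_id in keep]
        return sub

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[getattr(r, c) for c in CANONICAL_COLUMNS] for r in self.records],
            columns=list(CANONICAL_COLUMNS),
        )


def _detect_delimiter(path: str, declared: Optional[str]) -> str:
    if declared is not None:
        return declared
    with open(path, "rt") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_sumstats(
    path: str,
    dialect: Optional[Mapping[str, str]] = None,
    trait_id: Optional[str] = None,
) -> StudyTable:
    """Read a summary-statistics table.

    ``dialect`` maps source column names to canonical names and may carry a
    ``"delimiter"`` key; unmapped canonical names must already be present.
    Trait metadata is taken from a ``<path>.meta`` sidecar when it exists.
    """
    if not os.path.exists(path):
        raise ConfigurationError(f"summary-statistics file not found: {path}")
    dialect = dict(dialect or {})
    delim = _detect_delimiter(path, dialect.pop("delimiter", None))
    df = pd.read_csv(path, sep=delim, dtype=str)
    df = df.rename(columns=dialect)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing mandatory column(s) {missing}; present: {list(df.columns)}"
        )

    records: list[VariantAssociation] = []
    bad_rows: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = dict(zip(df.columns, row))
        try:
            rec = VariantAssociation(
                variant_id=str(d["variant_id"]),
                chrom=str(d["chrom"]),
                pos=int(d["pos"]),
                effect_allele=str(d["effect_allele"]).upper(),
                other_allele=str(d["other_allele"]).upper(),
                eaf=float(d["eaf"]),
                beta=float(d["beta"]),
                se=float(d["se"]),
                pval=float(d["pval"]),
                n=int(float(d["n"])),
            )
            rec.validate()
        except (ValueError, ValidationError) as exc:
            bad_rows.append((i, str(exc)))
            continue
        records.append(rec)
    if bad_rows:
        listing = "; ".join(f"row {i}: {msg}" for i, msg in bad_rows[:20])
        raise ValidationError(f"{path}: {len(bad_rows)} invalid row(s): {listing}")

    meta = _read_meta(path + ".meta")
    table = StudyTable(
        trait_id=trait_id or meta.get("trait_id", os.path.splitext(os.path.basename(path))[0]),
        records=records,
        trait_name=meta.get("trait_name", ""),
        trait_type=meta.get("trait_type", "continuous"),
        n_total=int(meta["n_total"]) if "n_total" in meta else 0,
        n_cases=int(meta["n_cases"]) if "n_cases" in meta else None,
    )
    table.validate()
    return table


def write_sumstats(table: StudyTable, path: str) -> str:
    """Write a table (and its metadata sidecar) in the canonical TSV dialect."""
    table.validate()
    buf = io.StringIO()
    buf.write("\t".join(CANONICAL_COLUMNS) + "\n")
    for r in table.records:
        buf.write(
            "\t".join(
                [r.variant_id, r.chrom, str(r.pos), r.effect_allele, r.other_allele,
                 repr(r.eaf), repr(r.beta), repr(r.se), repr(r.pval), str(r.n)]
            )
            + "\n"
        )
    try:
        with open(path, "wt") as fh:
            fh.write(buf.getvalue())
    except OSError as exc:
        raise ConfigurationError(f"cannot write {path}: {exc}") from exc
    meta_lines = [
        f"trait_id={table.trait_id}",
        f"trait_name={table.trait_name}",
        f"trait_type={table.trait_type}",
        f"n_total={table.n_total}",
    ]
    if table.n_cases is not None:
        meta_lines.append(f"n_cases={table.n_cases}")
    with open(path + ".meta", "wt") as fh:
        fh.write("\n".join(meta_lines) + "\n")
    return path


def _read_meta(path: str) -> dict[str, str]:
    if not os.path.exists(path):
        return {}
    out: dict[str, str] = {}
    with open(path, "rt") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigurationError(f"{path}: malformed metadata line {line!r}")
            k, v = line.split("=", 1)
            out[k.strip()] = v.strip()
    return out
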