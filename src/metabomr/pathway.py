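"""Metabolite-set over-representation analysis (ORA).

Given a query of significant metabolites mapped to compound identifiers
(e.g. KEGG C-numbers) and a library of pathways over a background
metabolome of size ``N_bg``, the over-representation p-value for a
pathway with ``m`` members of which ``k`` occur among the ``n`` mapped
query compounds is the hypergeometric upper tail P(X >= k); the expected
overlap is n*m/N_bg.

The pathway-topology "impact" score used by MetaboAnalyst (relative
betweenness centrality on the KEGG graph) is consumed as an externally
supplied number when available, never computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from scipy.stats import hypergeom

from .errors import ConfigurationError, ValidationError


@dataclass
class PathwayLibrary:
    """Mapping pathway name -> compound set, over a background metabolome."""

    pathways: dict[str, frozenset[str]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        for name, members in self.pathways.items():
            if len(members) < 1:
                raise ValidationError(f"pathway {name!r} is empty")
            stray = members - self.background
            if stray:
                raise ValidationError(
                    f"pathway {name!r} has compounds outside the background: {sorted(stray)[:5]}"
                )

    def __len__(self) -> int:
        return len(self.pathways)


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_name: str
    total: int          # pathway size m
    query_size: int     # mapped significant metabolites n
    expected: float     # n * m / N_bg
    hits: int           # observed overlap k
    pval: float         # one-sided upper-tail hypergeometric
    impact: Optional[float] = None

    @property
    def significant(self) -> bool:
        """p < 0.05 and, when an impact score was supplied, impact > 0.1."""
        if self.impact is None:
            return self.pval < 0.05
        return self.pval < 0.05 and self.impact > 0.1


def over_representation(
    query: Iterable[str],
    lib: PathwayLibrary,
    impact: Optional[Mapping[str, float]] = None,
) -> tuple[list[EnrichmentResult], list[str]]:
    """ORA of a compound query against every pathway in the library.

    Query ids absent from the background are excluded from n and returned
    as the second element.  Results are sorted by ascending p-value.
    """
    query = set(query)
    unmapped = sorted(query - lib.background)
    mapped = query & lib.background
    n = len(mapped)
    results: list[EnrichmentResult] = []
    if n == 0:
        return results, unmapped
    n_bg = len(lib.background)
    for name, members in lib.pathways.items():
        m = len(members)
        k = len(mapped & members)
        # P(X >= k) over draws of n from a population of N_bg with m successes
        p = float(hypergeom.sf(k - 1, n_bg, m, n)) if k > 0 else 1.0
        results.append(
            EnrichmentResult(
                pathway_name=name,
                total=m,
                query_size=n,
                expected=n * m / n_bg,
                hits=k,
                pval=min(p, 1.0),
                impact=None if impact is None else impact.get(name),
            )
        )
    results.sort(key=lambda r: (r.pval, r.pathway_name))
    return results, unmapped


def load_library(path: str) -> PathwayLibrary:
    """Read a compound-set file.

    One pathway per line: ``name<TAB>description<TAB>member ids...``.  An
    optional ``#BACKGROUND<TAB>id...`` line declares the background
    metabolome; without it the background is the union of all members.
    """
    pathways: dict[str, frozenset[str]] = {}
    declared_bg: Optional[frozenset[str]] = None
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if fields[0] == "#BACKGROUND":
                declared_bg = frozenset(f for f in fields[1:] if f)
                continue
            if line.startswith("#"):
                continue
            if len(fields) < 3:
                raise ConfigurationError(
                    f"{path}:{lineno}: expected name<TAB>description<TAB>members..., got {line!r}"
                )
            name = fields[0]
            members = frozenset(f for f in fields[2:] if f)
            if not name or not members:
                raise ConfigurationError(f"{path}:{lineno}: empty pathway name or member list")
            if name in pathways:
                raise ConfigurationError(f"{path}:{lineno}: duplicate pathway {name!r}")
            pathways[name] = members
    union = frozenset().union(*pathways.values()) if pathways else frozenset()
    return PathwayLibrary(pathways=pathways, background=declared_bg or union)


def write_library(lib: PathwayLibrary, path: str, descriptions: Optional[Mapping[str, str]] = None) -> str:
    """Writer for the compound-set dialect; round-trips with load_library."""
    descriptions = descriptions or {}
    with open(path, "wt") as fh:
        fh.write("#BACKGROUND\t" + "\t".join(sorted(lib.background)) + "\n")
        for name in sorted(lib.pathways):
            desc = descriptions.get(name, "")
            fh.write("\t".join([name, desc] + sorted(lib.pathways[name])) + "\n")
    return path
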