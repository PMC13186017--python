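"""Role stratification of high-confidence co-regulated phosphosites.

High-confidence PsOPs are assigned functional classes by matching their
protein (and, where the resource is site-specific, the exact site)
against local flat-file snapshots of curated resources:

* ``upstream_kinase``   — the PsOP's protein is reported or predicted to
  phosphorylate the target protein (site-specific when the resource names
  a target site);
* ``coregulated_kinase`` — the PsOP's protein is itself a kinase;
* ``phosphatase``        — the PsOP's protein is a phosphatase;
* ``binary_interactor``  — a curated protein-protein interaction edge
  joins the PsOP's protein and the target;
* ``substrate``          — the target protein is reported to
  phosphorylate the PsOP's protein.

Resources are consumed as frozen TSV exports with provenance tags; no
database API is queried, so runs are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .compendium import SiteKey, normalize_symbol
from .coregulation import CoRegResult

log = logging.getLogger(__name__)

RESOURCE_KINDS = (
    "kinase_substrate",
    "predicted_kinase_site",
    "interaction",
    "kinase_list",
    "phosphatase_list",
)

ROLES = (
    "upstream_kinase",
    "coregulated_kinase",
    "phosphatase",
    "binary_interactor",
    "substrate",
)

# expected header per resource kind (site columns optional)
_KIND_COLUMNS = {
    "kinase_substrate": ("kinase", "substrate"),
    "predicted_kinase_site": ("kinase", "target"),
    "interaction": ("gene_a", "gene_b"),
    "kinase_list": ("gene",),
    "phosphatase_list": ("gene",),
}


@dataclass(frozen=True)
class AnnotationResource:
    """A typed, normalized, deduplicated flat-file annotation resource.

    ``records``: for edge kinds, tuples (source_gene, target_gene,
    target_site_or_None); for list kinds, 1-tuples (gene,).  Interaction
    edges are stored undirected with lexicographically ordered endpoints.
    """

    kind: str
    records: tuple
    source_tag: str


def load_resource(
    path: str | Path,
    kind: str,
    alias_map: Optional[Mapping[str, str]] = None,
    source_tag: Optional[str] = None,
) -> AnnotationResource:
    """Read a resource TSV, normalize gene symbols and deduplicate rows."""
    if kind not in RESOURCE_KINDS:
        raise ValueError(f"unknown resource kind {kind!r}; expected one of {RESOURCE_KINDS}")
    alias_map = alias_map or {}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _KIND_COLUMNS[kind]:
        if col not in df.columns:
            raise ValueError(f"resource kind {kind!r} requires column {col!r}")
    if source_tag is None:
        source_tag = (
            str(df["source_tag"].iloc[0]) if "source_tag" in df.columns and len(df) else Path(path).stem
        )
    records: set[tuple] = set()
    for idx, row in df.iterrows():
        try:
            records.add(_parse_record(row, kind, alias_map))
        except ValueError as exc:
            raise ValueError(f"{path} line {int(idx) + 2}: {exc}") from exc
    if not records:
        log.warning("empty annotation resource: %s (%s)", path, kind)
    return AnnotationResource(kind, tuple(sorted(records, key=repr)), source_tag)


def _parse_record(row: pd.Series, kind: str, alias_map: Mapping[str, str]) -> tuple:
    def norm(col: str) -> str:
        return normalize_symbol(row[col], alias_map)

    def opt_site(col: str) -> Optional[str]:
        v = str(row.get(col, "") or "").strip()
        return v.upper() or None

    if kind == "kinase_substrate":
        return (norm("kinase"), norm("substrate"), opt_site("site"))
    if kind == "predicted_kinase_site":
        return (norm("kinase"), norm("target"), opt_site("target_site"))
    if kind == "interaction":
        a, b = sorted((norm("gene_a"), norm("gene_b")))
        return (a, b, None)
    return (norm("gene"),)


@dataclass(frozen=True)
class RoleAssignment:
    m_site: SiteKey
    o_site: SiteKey
    role: str
    sign: str  # "positive" | "negative"
    evidence_tags: tuple[str, ...]


def assign_roles(
    highconf: Sequence[CoRegResult],
    target: str,
    resources: Sequence[AnnotationResource],
    target_sites: Optional[Sequence[SiteKey]] = None,
) -> list[RoleAssignment]:
    """Assign every applicable functional role to each high-confidence pair.

    A PsOP may hold several roles simultaneously (a kinase that also
    interacts with the target yields both rows).  Evidence tags list the
    source resources supporting each role.  Site-specific upstream
    records (naming a target site) only match the corresponding m-site;
    protein-level records match every m-site.
    """
    target = target.upper()
    kinases: set[str] = set()
    phosphatases: set[str] = set()
    interactions: dict[tuple[str, str], set[str]] = {}
    upstream: dict[str, set[tuple[Optional[str], str]]] = {}  # kinase -> {(m_site or None, tag)}
    substrates: dict[str, set[tuple[Optional[str], str]]] = {}  # substrate gene -> {(site, tag)}

    for res in resources:
        if res.kind == "kinase_list":
            kinases.update(g for (g,) in res.records)
        elif res.kind == "phosphatase_list":
            phosphatases.update(g for (g,) in res.records)
        elif res.kind == "interaction":
            for a, b, _ in res.records:
                interactions.setdefault((a, b), set()).add(res.source_tag)
        elif res.kind in ("kinase_substrate", "predicted_kinase_site"):
            for src, tgt, site in res.records:
                if tgt == target:
                    upstream.setdefault(src, set()).add((site, res.source_tag))
                if res.kind == "kinase_substrate" and src == target:
                    substrates.setdefault(tgt, set()).add((site, res.source_tag))
    kinase_tags = {r.source_tag for r in resources if r.kind == "kinase_list"}
    phosphatase_tags = {r.source_tag for r in resources if r.kind == "phosphatase_list"}

    out: list[RoleAssignment] = []

    def emit(r: CoRegResult, role: str, tags: Iterable[str]) -> None:
        out.append(
            RoleAssignment(r.m_site, r.o_site, role, r.sign, tuple(sorted(set(tags))))
        )

    for r in highconf:
        if r.sign == "none":
            continue
        gene = r.o_site.gene
        m_rendered = f"{r.m_site.residue}{r.m_site.position}"

        up_tags = set()
        for site, tag in upstream.get(gene, ()):
            if site is None or site in (m_rendered, str(r.m_site)):
                up_tags.add(tag)
        if up_tags:
            emit(r, "upstream_kinase", up_tags)
        if gene in kinases:
            emit(r, "coregulated_kinase", kinase_tags)
        if gene in phosphatases:
            emit(r, "phosphatase", phosphatase_tags)
        edge = tuple(sorted((gene, target)))
        if edge in interactions:
            emit(r, "binary_interactor", interactions[edge])
        o_rendered = f"{r.o_site.residue}{r.o_site.position}"
        sub_tags = set()
        for site, tag in substrates.get(gene, ()):
            if site is None or site in (o_rendered, str(r.o_site)):
                sub_tags.add(tag)
        if sub_tags:
            emit(r, "substrate", sub_tags)

    # one row per (m_site, o_site, role): merge evidence across duplicate emits
    merged: dict[tuple, RoleAssignment] = {}
    for a in out:
        key = (a.m_site, a.o_site, a.role)
        if key in merged:
            prev = merged[key]
            merged[key] = RoleAssignment(
                a.m_site,
                a.o_site,
                a.role,
                a.sign,
                tuple(sorted(set(prev.evidence_tags) | set(a.evidence_tags))),
            )
        else:
            merged[key] = a
    return sorted(merged.values(), key=lambda a: (a.m_site, a.o_site, a.role))


@dataclass
class SharingPartition:
    """Core / pairwise / exclusive sharing of PsOPs across the major sites."""

    core: set[SiteKey]
    pairwise: dict[tuple[SiteKey, SiteKey], set[SiteKey]]
    exclusive: dict[SiteKey, set[SiteKey]]


def sharing_partition(
    assignments: Sequence[RoleAssignment],
    role: str,
    sign: str,
    target_sites: Sequence[SiteKey],
) -> SharingPartition:
    """Partition PsOP sites of one role/sign by which m-sites carry them.

    Exactly three target sites are required; the tiers (core = all three,
    pairwise = exactly two, exclusive = exactly one) are disjoint by
    construction.
    """
    if len(target_sites) != 3:
        raise ValueError("sharing_partition requires exactly three target sites")
    t = sorted(target_sites)
    carried: dict[SiteKey, set[SiteKey]] = {}
    for a in assignments:
        if a.role != role or a.sign != sign or a.m_site not in target_sites:
            continue
        carried.setdefault(a.o_site, set()).add(a.m_site)
    part = SharingPartition(
        core=set(),
        pairwise={(a, b): set() for i, a in enumerate(t) for b in t[i + 1 :]},
        exclusive={s: set() for s in t},
    )
    for o_site, msites in carried.items():
        if len(msites) == 3:
            part.core.add(o_site)
        elif len(msites) == 2:
            a, b = sorted(msites)
            part.pairwise[(a, b)].add(o_site)
        else:
            part.exclusive[next(iter(msites))].add(o_site)
    return part


def roles_to_frame(assignments: Sequence[RoleAssignment]) -> pd.DataFrame:
    rows = [
        {
            "m_site": str(a.m_site),
            "o_site": str(a.o_site),
            "role": a.role,
            "sign": a.sign,
            "evidence_tags": ";".join(a.evidence_tags),
        }
        for a in assignments
    ]
    return pd.DataFrame(rows, columns=["m_site", "o_site", "role", "sign", "evidence_tags"])
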