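"""High-confidence co-regulation of phosphosites on other proteins (PsOPs).

Each phosphosite on another protein ("o") is compared against a major
target-protein site ("m") across every condition where both carry a
significant call.  Joint events fall into four orientation-fixed
categories — UmUo, UmDo, DmUo, DmDo — and a candidate pair must pass four
gates to be called high-confidence:

1. two-sided Fisher's exact test on the 2x2 direction table, p < alpha;
2. sign-appropriate co-regulation ratio >= min_ratio, where
   ratio_pos = (n_UmUo + n_DmDo) / (n_UmDo + n_DmUo) and ratio_neg is its
   reciprocal, plus dominance of the corresponding event categories;
3. events in >= min_conditions distinct conditions;
4. events supported by >= min_pmids distinct publications.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Set

import pandas as pd
from scipy import stats

from .compendium import Direction, DirectionMap, SiteKey, StudyRef, calls_by_condition
from .cooccurrence import UNDEFINED


@dataclass(frozen=True)
class CategoryCounts:
    """Orientation-fixed joint event tally: m (target) first, o second."""

    n_um_uo: int = 0
    n_um_do: int = 0
    n_dm_uo: int = 0
    n_dm_do: int = 0

    def __post_init__(self) -> None:
        if min(self.n_um_uo, self.n_um_do, self.n_dm_uo, self.n_dm_do) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_um_uo + self.n_um_do + self.n_dm_uo + self.n_dm_do

    @property
    def concordant(self) -> int:
        return self.n_um_uo + self.n_dm_do

    @property
    def discordant(self) -> int:
        return self.n_um_do + self.n_dm_uo

    def as_table(self) -> list[list[int]]:
        return [[self.n_um_uo, self.n_um_do], [self.n_dm_uo, self.n_dm_do]]


@dataclass
class HighConfidenceConfig:
    """Gates for calling a PsOP high-confidence co-regulated.

    ``strict_evidence`` counts only conditions in the sign-supporting
    categories toward the evidence gates (default counts all informative
    events).  ``bh_correct`` applies Benjamini-Hochberg across a scan
    before the alpha gate (off by default: the filter is on raw p).
    """

    alpha: float = 0.05
    min_ratio: float = 0.15
    min_conditions: int = 2
    min_pmids: int = 2
    strict_evidence: bool = False
    bh_correct: bool = False

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.min_ratio > 0):
            raise ValueError("alpha and min_ratio must be positive")
        if self.min_conditions < 1 or self.min_pmids < 1:
            raise ValueError("evidence minima must be >= 1")


@dataclass
class CoRegResult:
    """Per (m-site, o-site) co-regulation statistics."""

    m_site: SiteKey
    o_site: SiteKey
    counts: CategoryCounts
    fet_p: float
    ratio_pos: float
    ratio_neg: float
    n_conditions: int
    n_pmids: int
    sign: str = "none"  # "positive" | "negative" | "none"


def category_counts(m_site: SiteKey, o_site: SiteKey, calls: DirectionMap) -> CategoryCounts:
    """Tally the four orientation-fixed categories over shared conditions."""
    _check_cross_protein(m_site, o_site)
    uu = ud = du = dd = 0
    for cond_sites in calls_by_condition(calls).values():
        dm = cond_sites.get(m_site)
        do = cond_sites.get(o_site)
        if dm not in (Direction.UP, Direction.DOWN) or do not in (
            Direction.UP,
            Direction.DOWN,
        ):
            continue
        if dm is Direction.UP:
            if do is Direction.UP:
                uu += 1
            else:
                ud += 1
        else:
            if do is Direction.UP:
                du += 1
            else:
                dd += 1
    return CategoryCounts(uu, ud, du, dd)


def _check_cross_protein(m_site: SiteKey, o_site: SiteKey) -> None:
    if m_site.gene == o_site.gene:
        raise ValueError(
            f"m and o sites must be on different proteins (both {m_site.gene}); "
            "within-protein pairs belong to the co-occurrence analysis"
        )


def fisher_exact_2x2(counts: CategoryCounts) -> float:
    """Two-sided Fisher's exact p for the m-direction x o-direction table.

    The p-value is the sum of hypergeometric probabilities of all tables
    with the observed margins whose probability does not exceed the
    observed table's.  Returns ``nan`` for an all-zero table (no events:
    the pair is skipped).
    """
    if counts.total == 0:
        return UNDEFINED
    _, p = stats.fisher_exact(counts.as_table(), alternative="two-sided")
    return float(min(p, 1.0))


def ratio_pos(counts: CategoryCounts) -> float:
    num, den = counts.concordant, counts.discordant
    if num == 0 and den == 0:
        return UNDEFINED
    return math.inf if den == 0 else num / den


def ratio_neg(counts: CategoryCounts) -> float:
    num, den = counts.discordant, counts.concordant
    if num == 0 and den == 0:
        return UNDEFINED
    return math.inf if den == 0 else num / den


def evidence_counts(
    m_site: SiteKey,
    o_site: SiteKey,
    calls: DirectionMap,
    supporting: Optional[str] = None,
) -> tuple[int, int]:
    """Distinct (conditions, pmids) among conditions contributing any event.

    With ``supporting='positive'``/``'negative'`` only concordant /
    discordant event conditions are counted (strict mode).
    """
    conds: set[StudyRef] = set()
    for study, cond_sites in calls_by_condition(calls).items():
        dm = cond_sites.get(m_site)
        do = cond_sites.get(o_site)
        if dm not in (Direction.UP, Direction.DOWN) or do not in (
            Direction.UP,
            Direction.DOWN,
        ):
            continue
        concordant = dm is do
        if supporting == "positive" and not concordant:
            continue
        if supporting == "negative" and concordant:
            continue
        conds.add(study)
    return len(conds), len({c.pmid for c in conds})


def call_high_confidence(result: CoRegResult, config: Optional[HighConfidenceConfig] = None) -> str:
    """Apply the four gates and return 'positive', 'negative' or 'none'.

    Positive requires concordant dominance (concordant > discordant) on
    top of the ratio gate, so a mostly-discordant pair can never be called
    positive through the permissive 0.15 ratio threshold; negative is the
    mirrored test.  An infinite ratio (no opposing events) passes its gate.
    """
    config = config or HighConfidenceConfig()
    c = result.counts
    if not math.isfinite(result.fet_p) or result.fet_p >= config.alpha:
        return "none"
    if result.n_conditions < config.min_conditions or result.n_pmids < config.min_pmids:
        return "none"
    if c.concordant > c.discordant and result.ratio_pos >= config.min_ratio:
        return "positive"
    if c.discordant > c.concordant and result.ratio_neg >= config.min_ratio:
        return "negative"
    return "none"


def scan_psops(
    calls: DirectionMap,
    m_sites: Sequence[SiteKey],
    target: str,
    config: Optional[HighConfidenceConfig] = None,
) -> list[CoRegResult]:
    """Score every PsOP against every major target site.

    Enumerates all phosphosites on proteins other than ``target`` present
    in the direction map, computes counts, FET p, ratios and evidence for
    each (m, o) pair with at least one joint event, and assigns the sign.
    Results are sorted by (m_site, o_site) for determinism.
    """
    config = config or HighConfidenceConfig()
    target = target.upper()
    o_sites = sorted({site for (_, site) in calls if site.gene != target})
    results: list[CoRegResult] = []
    for m in m_sites:
        for o in o_sites:
            c = category_counts(m, o, calls)
            if c.total == 0:
                continue
            n_cond, n_pmid = evidence_counts(
                m,
                o,
                calls,
                supporting=None,
            )
            r = CoRegResult(
                m_site=m,
                o_site=o,
                counts=c,
                fet_p=fisher_exact_2x2(c),
                ratio_pos=ratio_pos(c),
                ratio_neg=ratio_neg(c),
                n_conditions=n_cond,
                n_pmids=n_pmid,
            )
            results.append(r)

    if config.bh_correct:
        _apply_bh(results)

    for r in results:
        if config.strict_evidence:
            # re-evaluate evidence per candidate sign on supporting events only
            r.sign = _call_strict(r, calls, config)
        else:
            r.sign = call_high_confidence(r, config)
    results.sort(key=lambda r: (r.m_site, r.o_site))
    return results


def _call_strict(r: CoRegResult, calls: DirectionMap, config: HighConfidenceConfig) -> str:
    sign = call_high_confidence(r, config)
    if sign == "none":
        return sign
    n_cond, n_pmid = evidence_counts(r.m_site, r.o_site, calls, supporting=sign)
    if n_cond < config.min_conditions or n_pmid < config.min_pmids:
        return "none"
    return sign


def _apply_bh(results: list[CoRegResult]) -> None:
    """Benjamini-Hochberg adjust fet_p in place (nan-safe)."""
    idx = [i for i, r in enumerate(results) if math.isfinite(r.fet_p)]
    ps = [results[i].fet_p for i in idx]
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_last, oi in enumerate(reversed(order)):
        rank = m - rank_from_last
        prev = min(prev, ps[oi] * m / rank)
        adj[oi] = prev
    for oi, i in zip(range(m), idx):
        results[i].fet_p = adj[oi]


def high_confidence(results: Iterable[CoRegResult]) -> list[CoRegResult]:
    return [r for r in results if r.sign != "none"]


@dataclass
class VennPartition:
    """Disjoint region decomposition of 2 or 3 labelled sets."""

    region_members: dict[frozenset[str], set[str]] = field(default_factory=dict)

    @property
    def region_counts(self) -> dict[frozenset[str], int]:
        return {k: len(v) for k, v in self.region_members.items()}

    def count(self, *labels: str) -> int:
        """Size of the exact region belonging to these labels only."""
        return len(self.region_members.get(frozenset(labels), set()))


def venn_partition(sets: Mapping[str, Set[SiteKey]]) -> VennPartition:
    """Exact disjoint region decomposition of the labelled site sets.

    Keys of ``region_members`` are frozensets of set labels; every member
    is rendered to its ``GENE_R###`` string.  Designed for 3 sets (the
    three major target sites), 2 are accepted.
    """
    labels = sorted(sets)
    if len(labels) not in (2, 3):
        raise ValueError(f"venn_partition needs 2 or 3 sets, got {len(labels)}")
    rendered = {lab: {str(s) for s in sets[lab]} for lab in labels}
    part = VennPartition()
    universe = set().union(*rendered.values())
    for member in universe:
        region = frozenset(lab for lab in labels if member in rendered[lab])
        part.region_members.setdefault(region, set()).add(member)
    # materialize all nonempty-subset keys so callers see explicit zeros
    from itertools import combinations

    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            part.region_members.setdefault(frozenset(combo), set())
    return part


def results_to_frame(results: Sequence[CoRegResult]) -> pd.DataFrame:
    """Flat results table matching the documented TSV export schema."""
    rows = [
        {
            "m_site": str(r.m_site),
            "o_site": str(r.o_site),
            "n_UmUo": r.counts.n_um_uo,
            "n_UmDo": r.counts.n_um_do,
            "n_DmUo": r.counts.n_dm_uo,
            "n_DmDo": r.counts.n_dm_do,
            "fet_p": r.fet_p,
            "ratio_pos": r.ratio_pos,
            "ratio_neg": r.ratio_neg,
            "n_conditions": r.n_conditions,
            "n_pmids": r.n_pmids,
            "sign": r.sign,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "m_site",
            "o_site",
            "n_UmUo",
            "n_UmDo",
            "n_DmUo",
            "n_DmDo",
            "fet_p",
            "ratio_pos",
            "ratio_neg",
            "n_conditions",
            "n_pmids",
            "sign",
        ],
    )


def venn_to_frame(part: VennPartition) -> pd.DataFrame:
    rows = []
    for region in sorted(part.region_members, key=lambda r: (len(r), sorted(r))):
        members = part.region_members[region]
        rows.append(
            {
                "region": "&".join(sorted(region)),
                "count": len(members),
                "members": ";".join(sorted(members)),
            }
        )
    return pd.DataFrame(rows, columns=["region", "count", "members"])
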