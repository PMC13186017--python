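"""Pairwise directional co-occurrence between phosphosites of one protein.

For a pair of sites, each shared condition where *both* carry a
significant call contributes one joint event: UU, UD, DU or DD.
Positive co-regulation is summarized by the ratio
(n_UU + n_DD) / (n_UD + n_DU) and negative co-regulation by its
reciprocal.  The heatmap statistic is the bounded concordance score
(concordant - discordant) / total, exported together with raw counts so
any alternative statistic can be recomputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .compendium import Direction, DirectionMap, SiteKey, calls_by_condition

#: Sentinel for a ratio whose numerator and denominator are both zero.
UNDEFINED = math.nan


@dataclass(frozen=True)
class PairCounts:
    """Joint direction-event tally for an ordered site pair."""

    n_uu: int = 0
    n_ud: int = 0
    n_du: int = 0
    n_dd: int = 0

    def __post_init__(self) -> None:
        if min(self.n_uu, self.n_ud, self.n_du, self.n_dd) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_uu + self.n_ud + self.n_du + self.n_dd

    @property
    def concordant(self) -> int:
        return self.n_uu + self.n_dd

    @property
    def discordant(self) -> int:
        return self.n_ud + self.n_du

    def swapped(self) -> "PairCounts":
        """Counts for the pair in reversed argument order (UD/DU swap)."""
        return PairCounts(self.n_uu, self.n_du, self.n_ud, self.n_dd)


@dataclass
class CoOccurrenceMatrix:
    sites: list[SiteKey]
    score: np.ndarray  # concordance scores in [-1, 1]
    counts: np.ndarray  # total informative events per pair


def pair_counts(site_a: SiteKey, site_b: SiteKey, calls: DirectionMap) -> PairCounts:
    """Tally UU/UD/DU/DD events for (site_a, site_b) over shared conditions.

    Only conditions where both sites carry an Up or Down call contribute;
    Unchanged, Ambiguous and unmeasured conditions are skipped.
    """
    if site_a == site_b:
        raise ValueError(f"self-pairing is undefined ({site_a})")
    uu = ud = du = dd = 0
    for cond_sites in calls_by_condition(calls).values():
        da = cond_sites.get(site_a)
        db = cond_sites.get(site_b)
        if da not in (Direction.UP, Direction.DOWN) or db not in (
            Direction.UP,
            Direction.DOWN,
        ):
            continue
        if da is Direction.UP:
            if db is Direction.UP:
                uu += 1
            else:
                ud += 1
        else:
            if db is Direction.UP:
                du += 1
            else:
                dd += 1
    return PairCounts(uu, ud, du, dd)


def positive_ratio(counts: PairCounts) -> float:
    """(n_UU + n_DD) / (n_UD + n_DU).

    Returns ``inf`` when the denominator is zero with a positive numerator
    and ``nan`` (undefined) when all counts are zero.
    """
    num, den = counts.concordant, counts.discordant
    if num == 0 and den == 0:
        return UNDEFINED
    if den == 0:
        return math.inf
    return num / den


def negative_ratio(counts: PairCounts) -> float:
    """(n_UD + n_DU) / (n_UU + n_DD), with the same sentinel conventions."""
    num, den = counts.discordant, counts.concordant
    if num == 0 and den == 0:
        return UNDEFINED
    if den == 0:
        return math.inf
    return num / den


def concordance_score(counts: PairCounts) -> float:
    """Bounded score (concordant - discordant) / total, 0 when no events."""
    if counts.total == 0:
        return 0.0
    return (counts.concordant - counts.discordant) / counts.total


def cooccurrence_matrix(sites: Sequence[SiteKey], calls: DirectionMap) -> CoOccurrenceMatrix:
    """Square concordance-score and event-count matrices over ``sites``.

    Diagonal score is 1 where the site has at least one informative
    (Up/Down) condition, else 0.
    """
    sites = list(sites)
    if len(sites) < 2:
        raise ValueError("need at least 2 sites for a co-occurrence matrix")
    n = len(sites)
    score = np.zeros((n, n))
    tot = np.zeros((n, n), dtype=int)
    informative = {
        s: sum(
            1
            for (study, site), d in calls.items()
            if site == s and d in (Direction.UP, Direction.DOWN)
        )
        for s in sites
    }
    for i in range(n):
        score[i, i] = 1.0 if informative[sites[i]] > 0 else 0.0
        tot[i, i] = informative[sites[i]]
        for j in range(i + 1, n):
            c = pair_counts(sites[i], sites[j], calls)
            score[i, j] = score[j, i] = concordance_score(c)
            tot[i, j] = tot[j, i] = c.total
    return CoOccurrenceMatrix(sites, score, tot)


def matrix_to_long(matrix: CoOccurrenceMatrix, calls: DirectionMap) -> pd.DataFrame:
    """Long-format export: one row per unordered pair with raw counts and score."""
    rows = []
    n = len(matrix.sites)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = matrix.sites[i], matrix.sites[j]
            c = pair_counts(a, b, calls)
            rows.append(
                {
                    "site_a": str(a),
                    "site_b": str(b),
                    "n_uu": c.n_uu,
                    "n_ud": c.n_ud,
                    "n_du": c.n_du,
                    "n_dd": c.n_dd,
                    "score": concordance_score(c),
                }
            )
    return pd.DataFrame(
        rows, columns=["site_a", "site_b", "n_uu", "n_ud", "n_du", "n_dd", "score"]
    )


def write_matrix(matrix: CoOccurrenceMatrix, path: str | Path) -> None:
    """Square-matrix TSV of concordance scores for heatmap tools."""
    labels = [str(s) for s in matrix.sites]
    pd.DataFrame(matrix.score, index=labels, columns=labels).to_csv(path, sep="\t")
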