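"""Per-site detection frequency, major-site selection, lollipop export.

Detection frequency is counted at the *dataset* level: a dataset
contributes at most one count to a site no matter how many of its rows or
conditions report that site.  Profile and differential datasets are
counted separately; a differential dataset counts only when the site is
significantly Up or Down in at least one of its conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .compendium import Direction, DirectionMap, SiteKey, SiteObservation


@dataclass(frozen=True)
class SiteFrequency:
    site: SiteKey
    n_profile: int
    n_differential: int

    @property
    def n_total(self) -> int:
        return self.n_profile + self.n_differential


@dataclass(frozen=True)
class DomainAnnotation:
    """A named protein domain with 1-based inclusive bounds."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"need 1 <= start <= end, got {self.start}..{self.end}")

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


def read_domains(path: str | Path) -> list[DomainAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "start": int, "end": int})
    return [DomainAnnotation(r["name"], int(r["start"]), int(r["end"])) for _, r in df.iterrows()]


def detection_frequency(
    calls: DirectionMap,
    profile_obs: Iterable[SiteObservation],
    protein: str,
) -> list[SiteFrequency]:
    """Count, per site of ``protein``, distinct detecting datasets.

    ``calls`` is the condition-level direction map from the differential
    compendium; ``profile_obs`` are (Class-I filtered) profile rows.
    """
    protein = protein.upper()
    prof_datasets: dict[SiteKey, set[tuple[str, str]]] = {}
    for o in profile_obs:
        if o.dataset_kind != "profile" or o.site.gene != protein:
            continue
        prof_datasets.setdefault(o.site, set()).add((o.study.pmid, o.study.dataset_id))
    diff_datasets: dict[SiteKey, set[tuple[str, str]]] = {}
    for (study, site), d in calls.items():
        if site.gene != protein or d not in (Direction.UP, Direction.DOWN):
            continue
        diff_datasets.setdefault(site, set()).add((study.pmid, study.dataset_id))

    sites = sorted(set(prof_datasets) | set(diff_datasets))
    if not sites:
        import logging

        logging.getLogger(__name__).warning("no sites found for protein %s", protein)
    return [
        SiteFrequency(s, len(prof_datasets.get(s, ())), len(diff_datasets.get(s, ())))
        for s in sites
    ]


def select_major_sites(
    freqs: Sequence[SiteFrequency],
    k: int = 3,
    min_count: int = 2,
    rank_on: str = "total",
) -> list[SiteKey]:
    """Top-k sites by recurrence.

    Ranked by combined (profile + differential) count descending — or by
    differential count alone with ``rank_on='differential'`` — with ties
    broken by position ascending; sites below ``min_count`` are dropped.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if rank_on not in ("total", "differential"):
        raise ValueError(f"rank_on must be 'total' or 'differential', got {rank_on!r}")

    def score(f: SiteFrequency) -> int:
        return f.n_total if rank_on == "total" else f.n_differential

    eligible = [f for f in freqs if score(f) >= min_count]
    ranked = sorted(eligible, key=lambda f: (-score(f), f.site.position))
    return [f.site for f in ranked[:k]]


def lollipop_table(
    freqs: Sequence[SiteFrequency],
    domains: Sequence[DomainAnnotation],
    major: Sequence[SiteKey],
) -> pd.DataFrame:
    """One row per site, ordered by position, with domain membership.

    ``domain_name`` is empty when the position falls inside no annotated
    domain (the first matching domain wins otherwise).  Ready to feed a
    lollipop-plot tool.
    """
    major_set = set(major)
    rows = []
    for f in sorted(freqs, key=lambda f: f.site.position):
        domain_name = ""
        for d in domains:
            if d.contains(f.site.position):
                domain_name = d.name
                break
        rows.append(
            {
                "position": f.site.position,
                "residue": f.site.residue,
                "n_profile": f.n_profile,
                "n_differential": f.n_differential,
                "count": f.n_total,
                "is_major": f.site in major_set,
                "domain_name": domain_name,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "position",
            "residue",
            "n_profile",
            "n_differential",
            "count",
            "is_major",
            "domain_name",
        ],
    )
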