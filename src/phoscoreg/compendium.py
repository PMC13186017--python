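"""Compendium ingestion, quality filtering and direction calling.

A curated phosphoproteomics compendium is a long-format table in which one
row records one phosphosite observation in one experimental comparison
("condition").  Observations come from two kinds of source dataset:

* ``differential`` — a quantitative comparison of two states, carrying a
  fold change (treatment/control) and a p-value, from which an Up / Down /
  Unchanged direction call is derived;
* ``profile`` — a qualitative inventory of sites detected under one
  condition, with no paired comparison (no fold change, no p-value).

Only Class-I sites (localization probability >= 0.75 and ambiguity A-score
above threshold) are retained, so every downstream count is built on
confidently localized phosphosites.
"""

from __future__ import annotations

import enum
import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

log = logging.getLogger(__name__)

_RESIDUES = frozenset("STY")
_SITE_RE = re.compile(r"^(?P<gene>[A-Za-z0-9\-]+)_(?P<res>[STY])(?P<pos>\d+)$")


class SchemaError(ValueError):
    """A required column is missing or mis-typed in an input table."""


class RowError(ValueError):
    """A single input row could not be parsed; carries its line number."""


class Direction(enum.Enum):
    """Direction of a phosphosite's change in one condition."""

    UP = "Up"
    DOWN = "Down"
    UNCHANGED = "Unchanged"
    AMBIGUOUS = "Ambiguous"

    def opposite(self) -> "Direction":
        if self is Direction.UP:
            return Direction.DOWN
        if self is Direction.DOWN:
            return Direction.UP
        return self


@dataclass(frozen=True, order=True)
class StudyRef:
    """Identifies one experimental comparison.

    The atomic unit of evidence is the *condition* (unique experimental
    identifier); a dataset within a publication may contain several
    conditions, and independent publications are distinguished by PMID.
    """

    pmid: str
    dataset_id: str
    condition_id: str

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("pmid must be non-empty")


@dataclass(frozen=True, order=True)
class SiteKey:
    """A phosphosite: HGNC gene symbol + residue + 1-based canonical position."""

    gene: str
    residue: str
    position: int

    def __post_init__(self) -> None:
        if self.residue not in _RESIDUES:
            raise ValueError(f"residue must be one of S/T/Y, got {self.residue!r}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")

    def __str__(self) -> str:
        return f"{self.gene}_{self.residue}{self.position}"

    @classmethod
    def parse(cls, rendered: str) -> "SiteKey":
        m = _SITE_RE.match(rendered)
        if m is None:
            raise ValueError(f"cannot parse site key {rendered!r}")
        return cls(m.group("gene").upper(), m.group("res"), int(m.group("pos")))


@dataclass
class SiteObservation:
    """One phosphosite measurement in one condition."""

    study: StudyRef
    site: SiteKey
    dataset_kind: str  # "profile" | "differential"
    loc_prob: float
    ascore: Optional[float] = None
    fold_change: Optional[float] = None
    p_value: Optional[float] = None
    flanking: str = ""
    direction: Optional[Direction] = None

    def __post_init__(self) -> None:
        if self.dataset_kind not in ("profile", "differential"):
            raise ValueError(f"unknown dataset_kind {self.dataset_kind!r}")
        if not 0.0 <= self.loc_prob <= 1.0:
            raise ValueError(f"loc_prob must be in [0,1], got {self.loc_prob}")


@dataclass
class FilterConfig:
    """Quality and direction-calling thresholds.

    Defaults follow the conventional meta-analysis gates: Class-I
    localization probability >= 0.75, A-score >= 13, upregulated when fold
    change >= 1.3 with p < 0.05, downregulated when fold change <= 0.76
    with p < 0.05.  ``strict_ascore`` rejects rows with a missing A-score
    instead of letting localization probability alone decide; ``log2_fold``
    declares that the input fold changes are log2 ratios (exponentiated on
    read).
    """

    min_loc_prob: float = 0.75
    min_ascore: float = 13.0
    up_fc: float = 1.3
    down_fc: float = 0.76
    alpha: float = 0.05
    strict_ascore: bool = False
    log2_fold: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_loc_prob <= 1.0:
            raise ValueError("min_loc_prob must be in [0,1]")
        if not self.down_fc < 1.0 < self.up_fc:
            raise ValueError("need down_fc < 1 < up_fc")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0,1)")


REQUIRED_COLUMNS = (
    "pmid",
    "dataset_id",
    "condition_id",
    "gene_symbol",
    "residue",
    "position",
    "loc_prob",
)
OPTIONAL_COLUMNS = ("ascore", "fold_change", "p_value", "flanking", "dataset_kind")


def _opt_float(cell: object) -> Optional[float]:
    if cell is None:
        return None
    s = str(cell).strip()
    if s == "" or s.lower() in ("na", "nan", "none"):
        return None
    return float(s)


def normalize_symbol(raw_symbol: str, alias_map: Mapping[str, str]) -> str:
    """Map a raw gene symbol to its approved symbol.

    Aliases are resolved case-insensitively through ``alias_map`` (alias ->
    approved symbol); symbols without an alias entry are uppercased as-is.
    """
    if not raw_symbol or not str(raw_symbol).strip():
        raise ValueError("empty gene symbol")
    sym = str(raw_symbol).strip().upper()
    upper_map = {k.strip().upper(): v.strip().upper() for k, v in alias_map.items()}
    return upper_map.get(sym, sym)


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (alias, approved_symbol) TSV into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise SchemaError("alias map needs two columns: alias, approved_symbol")
    a, b = df.columns[:2]
    return {
        str(r[a]).strip().upper(): str(r[b]).strip().upper()
        for _, r in df.iterrows()
    }


def read_observations(
    path: str | Path,
    dataset_kind: Optional[str] = None,
    alias_map: Optional[Mapping[str, str]] = None,
    config: Optional[FilterConfig] = None,
) -> list[SiteObservation]:
    """Read a long-format compendium TSV into :class:`SiteObservation` rows.

    ``dataset_kind`` forces a kind for every row; otherwise a
    ``dataset_kind`` column must be present.  Missing optional cells become
    ``None`` (never zero).  Row order is preserved.
    """
    config = config or FilterConfig()
    alias_map = alias_map or {}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if dataset_kind is None and "dataset_kind" not in df.columns:
        raise SchemaError(
            "dataset_kind column required when no dataset_kind argument is given"
        )
    if len(df) == 0:
        log.warning("empty compendium file: %s", path)
        return []

    obs: list[SiteObservation] = []
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # header is line 1
        try:
            kind = dataset_kind or str(row["dataset_kind"]).strip()
            fc = _opt_float(row.get("fold_change"))
            if fc is not None and config.log2_fold:
                fc = 2.0**fc
            o = SiteObservation(
                study=StudyRef(
                    str(row["pmid"]).strip(),
                    str(row["dataset_id"]).strip(),
                    str(row["condition_id"]).strip(),
                ),
                site=SiteKey(
                    normalize_symbol(row["gene_symbol"], alias_map),
                    str(row["residue"]).strip(),
                    int(str(row["position"]).strip()),
                ),
                dataset_kind=kind,
                loc_prob=float(str(row["loc_prob"]).strip()),
                ascore=_opt_float(row.get("ascore")),
                fold_change=fc,
                p_value=_opt_float(row.get("p_value")),
                flanking=str(row.get("flanking", "") or ""),
            )
        except (ValueError, KeyError) as exc:
            raise RowError(f"line {line_no}: {exc}") from exc
        obs.append(o)
    return obs


def write_observations(observations: Sequence[SiteObservation], path: str | Path) -> None:
    """Write observations back to the long-format TSV (round-trip safe)."""
    rows = []
    for o in observations:
        rows.append(
            {
                "pmid": o.study.pmid,
                "dataset_id": o.study.dataset_id,
                "condition_id": o.study.condition_id,
                "gene_symbol": o.site.gene,
                "residue": o.site.residue,
                "position": o.site.position,
                "loc_prob": o.loc_prob,
                "ascore": "" if o.ascore is None else o.ascore,
                "fold_change": "" if o.fold_change is None else o.fold_change,
                "p_value": "" if o.p_value is None else o.p_value,
                "flanking": o.flanking,
                "dataset_kind": o.dataset_kind,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def filter_class1(
    observations: Sequence[SiteObservation], config: Optional[FilterConfig] = None
) -> list[SiteObservation]:
    """Keep Class-I observations only.

    A row passes when loc_prob >= min_loc_prob and its A-score is either
    missing (unless ``strict_ascore``) or >= min_ascore.  Idempotent; input
    order preserved.
    """
    config = config or FilterConfig()

    def ok(o: SiteObservation) -> bool:
        if o.loc_prob < config.min_loc_prob:
            return False
        if o.ascore is None:
            return not config.strict_ascore
        return o.ascore >= config.min_ascore

    kept = [o for o in observations if ok(o)]
    removed = len(observations) - len(kept)
    if removed:
        log.info("filter_class1 removed %d of %d rows", removed, len(observations))
    return kept


def call_direction(
    fold_change: Optional[float],
    p_value: Optional[float],
    config: Optional[FilterConfig] = None,
) -> Direction:
    """Call Up/Down/Unchanged from fold change and p-value.

    Up when fc >= up_fc and p < alpha; Down when fc <= down_fc and p < alpha;
    Unchanged otherwise (including a missing p-value, which can never meet
    the significance gate).
    """
    config = config or FilterConfig()
    if fold_change is None or not math.isfinite(fold_change) or fold_change <= 0:
        raise ValueError(f"differential row needs a positive fold change, got {fold_change}")
    significant = p_value is not None and p_value < config.alpha
    if significant and fold_change >= config.up_fc:
        return Direction.UP
    if significant and fold_change <= config.down_fc:
        return Direction.DOWN
    return Direction.UNCHANGED


def apply_directions(
    observations: Iterable[SiteObservation], config: Optional[FilterConfig] = None
) -> list[SiteObservation]:
    """Assign a direction to every differential observation (profile rows keep None)."""
    config = config or FilterConfig()
    out = []
    for o in observations:
        if o.dataset_kind == "differential":
            out.append(replace(o, direction=call_direction(o.fold_change, o.p_value, config)))
        else:
            out.append(o)
    return out


# A condition-level direction map: (condition, site) -> Direction.
DirectionMap = dict[tuple[StudyRef, SiteKey], Direction]


def resolve_conflicts(observations: Iterable[SiteObservation]) -> DirectionMap:
    """Merge duplicate direction-called rows per (condition, site).

    Several peptides can report the same site in the same comparison.  The
    merge rule: any significant call dominates Unchanged; agreeing
    significant calls yield that call; conflicting Up and Down yield
    Ambiguous (excluded from all downstream event counting).
    """
    groups: dict[tuple[StudyRef, SiteKey], set[Direction]] = {}
    for o in observations:
        if o.dataset_kind != "differential" or o.direction is None:
            continue
        groups.setdefault((o.study, o.site), set()).add(o.direction)
    out: DirectionMap = {}
    for key, calls in groups.items():
        signif = calls & {Direction.UP, Direction.DOWN}
        if len(signif) == 2:
            out[key] = Direction.AMBIGUOUS
        elif len(signif) == 1:
            out[key] = next(iter(signif))
        else:
            out[key] = Direction.UNCHANGED
    return out


def calls_by_condition(calls: DirectionMap) -> dict[StudyRef, dict[SiteKey, Direction]]:
    """Pivot a direction map into per-condition site->direction dicts."""
    by_cond: dict[StudyRef, dict[SiteKey, Direction]] = {}
    for (study, site), d in calls.items():
        by_cond.setdefault(study, {})[site] = d
    return by_cond
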