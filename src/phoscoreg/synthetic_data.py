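"""Synthetic compendium generator with planted co-regulation structure.

The generator emulates the statistical skeleton of a curated multi-study
phosphoproteomics compendium: several publications (each with its own
PMID), several comparisons per publication, per-condition Up / Down /
Unchanged direction states for the target protein's sites, planted
partner sites on other proteins that track (or anti-track) the target
with a stated concordance probability, independent background sites, and
realistic missingness (detection probability, sub-Class-I rows).

Each condition carries one latent "regime" direction shared by the
target's sites — phosphosites of one protein respond coherently within a
comparison — so a planted partner is genuinely co-regulated with *every*
target site, and the planted truth assigns it to all of them.

Fold changes for intended Up calls are drawn log-uniform in [1.5, 4] and
Down in [0.25, 0.67], keeping a margin from the 1.3 / 0.76 calling
boundaries so direction intent is unambiguous; significant rows get
p ~ U(0, 0.01], unchanged rows fc ~ U[0.9, 1.1] and p ~ U[0.2, 1].
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .compendium import Direction, FilterConfig, SiteKey, SiteObservation, StudyRef
from .coregulation import CoRegResult, HighConfidenceConfig

_LOG_UP = (math.log(1.5), math.log(4.0))
_LOG_DOWN = (math.log(0.25), math.log(0.67))


@dataclass
class SynthConfig:
    """Study conditions for the synthetic compendium.

    ``concordance`` is the probability that a planted positive partner
    copies the condition regime (negative partners flip with the same
    probability); 0.5 makes planted "partners" statistically null.
    """

    n_studies: int = 10
    conditions_per_study: int = 4
    target_sites: int = 3
    n_pos_partners: int = 15
    n_neg_partners: int = 15
    n_background: int = 15
    concordance: float = 0.9
    p_up: float = 0.5
    detect_prob: float = 0.9
    p_target_informative: float = 0.7
    loc_prob_range: tuple[float, float] = (0.85, 1.0)
    ascore_range: tuple[float, float] = (14.0, 40.0)
    subthreshold_frac: float = 0.05
    n_profile_studies: int = 2
    target_symbol: str = "MELK"
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.concordance, self.p_up, self.detect_prob,
                  self.p_target_informative, self.subthreshold_frac):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if not 0.5 <= self.concordance or self.concordance > 1.0:
            raise ValueError("concordance must be in [0.5, 1]")
        if min(self.n_pos_partners, self.n_neg_partners, self.n_background) < 0:
            raise ValueError("partner/background counts must be >= 0")
        if (self.n_pos_partners or self.n_neg_partners) and (
            self.n_studies * self.conditions_per_study == 0
        ):
            raise ValueError("planted partners require at least one condition")


# canonical positions of the target's major sites (extras appended after)
_TARGET_POSITIONS = (356, 505, 529)


def target_site_keys(config: SynthConfig) -> list[SiteKey]:
    keys = [
        SiteKey(config.target_symbol, "S", p)
        for p in _TARGET_POSITIONS[: config.target_sites]
    ]
    for i in range(len(keys), config.target_sites):
        keys.append(SiteKey(config.target_symbol, "T", 600 + i))
    return keys


@dataclass
class SyntheticTruth:
    """Planted ground truth: every generated PsOP appears exactly once."""

    planted: dict[SiteKey, tuple[str, tuple[SiteKey, ...]]]  # o -> (sign, m-sites)
    background: set[SiteKey]
    target_sites: tuple[SiteKey, ...]


@dataclass
class RecoveryReport:
    precision: dict[str, float]  # per sign; nan when no calls of that sign
    recall: dict[str, float]
    f1: dict[str, float]
    null_fpr: float
    n_true: dict[str, int]
    n_called: dict[str, int]


def generate_compendium(config: SynthConfig) -> tuple[list[SiteObservation], SyntheticTruth]:
    """Generate observations plus planted truth; reproducible given seed."""
    rng = np.random.default_rng(config.seed)
    targets = target_site_keys(config)
    pos = [SiteKey(f"POS{i:03d}", "S", 100 + i) for i in range(1, config.n_pos_partners + 1)]
    neg = [SiteKey(f"NEG{i:03d}", "S", 200 + i) for i in range(1, config.n_neg_partners + 1)]
    bgd = [SiteKey(f"BGD{i:03d}", "T", 300 + i) for i in range(1, config.n_background + 1)]
    truth = SyntheticTruth(
        planted={
            **{o: ("positive", tuple(targets)) for o in pos},
            **{o: ("negative", tuple(targets)) for o in neg},
        },
        background=set(bgd),
        target_sites=tuple(targets),
    )

    obs: list[SiteObservation] = []

    def emit(study: StudyRef, site: SiteKey, direction: Optional[Direction]) -> None:
        """Append one row realizing the intended direction (None = profile)."""
        sub = rng.random() < config.subthreshold_frac
        loc = (
            rng.uniform(0.30, 0.74)
            if sub
            else rng.uniform(*config.loc_prob_range)
        )
        ascore = rng.uniform(*config.ascore_range)
        if direction is None:
            obs.append(
                SiteObservation(study, site, "profile", loc_prob=loc, ascore=ascore)
            )
            return
        if direction is Direction.UP:
            fc = math.exp(rng.uniform(*_LOG_UP))
            p = rng.uniform(0.0, 0.01) or 1e-6
        elif direction is Direction.DOWN:
            fc = math.exp(rng.uniform(*_LOG_DOWN))
            p = rng.uniform(0.0, 0.01) or 1e-6
        else:
            fc = rng.uniform(0.9, 1.1)
            p = rng.uniform(0.2, 1.0)
        obs.append(
            SiteObservation(
                study, site, "differential", loc_prob=loc, ascore=ascore,
                fold_change=fc, p_value=p,
            )
        )

    for s in range(config.n_studies):
        pmid = f"PMID{1000 + s}"
        for c in range(config.conditions_per_study):
            study = StudyRef(pmid, f"DS{s}", f"C{c}")
            regime = Direction.UP if rng.random() < config.p_up else Direction.DOWN

            for site in targets:
                if rng.random() >= config.detect_prob:
                    continue
                informative = rng.random() < config.p_target_informative
                emit(study, site, regime if informative else Direction.UNCHANGED)

            for o in pos + neg + bgd:
                if rng.random() >= config.detect_prob:
                    continue
                if rng.random() >= config.p_target_informative:
                    emit(study, o, Direction.UNCHANGED)
                    continue
                if o in truth.background:
                    d = Direction.UP if rng.random() < 0.5 else Direction.DOWN
                elif truth.planted[o][0] == "positive":
                    d = regime if rng.random() < config.concordance else regime.opposite()
                else:
                    d = regime.opposite() if rng.random() < config.concordance else regime
                emit(study, o, d)

    for s in range(config.n_profile_studies):
        study = StudyRef(f"PMID{9000 + s}", f"PDS{s}", "PC0")
        for site in targets:
            emit(study, site, None)

    return obs, truth


def evaluate_recovery(
    pipeline_results: Sequence[CoRegResult],
    truth: SyntheticTruth,
    alpha: float = 0.05,
) -> RecoveryReport:
    """Score high-confidence calls against the planted truth, per sign.

    A true pair is (m-site, planted o-site) with the planted sign; it is
    recovered when the scan calls exactly that sign.  Precision counts
    any call of a sign on a pair that is not true-for-that-sign as a
    false positive (background pairs and wrong-sign calls included).
    Null FPR is the fraction of background (o x m) pairs called with any
    sign.
    """
    known = set(truth.planted) | truth.background
    for r in pipeline_results:
        if r.o_site not in known:
            raise ValueError(f"result references o-site absent from truth: {r.o_site}")

    called: dict[str, set[tuple[SiteKey, SiteKey]]] = {"positive": set(), "negative": set()}
    for r in pipeline_results:
        if r.sign in called:
            called[r.sign].add((r.m_site, r.o_site))

    true_pairs: dict[str, set[tuple[SiteKey, SiteKey]]] = {"positive": set(), "negative": set()}
    for o, (sign, msites) in truth.planted.items():
        for m in msites:
            true_pairs[sign].add((m, o))

    precision: dict[str, float] = {}
    recall: dict[str, float] = {}
    f1: dict[str, float] = {}
    for sign in ("positive", "negative"):
        tp = len(called[sign] & true_pairs[sign])
        n_called = len(called[sign])
        n_true = len(true_pairs[sign])
        precision[sign] = tp / n_called if n_called else math.nan
        recall[sign] = tp / n_true if n_true else math.nan
        if n_called and n_true and tp:
            p_, r_ = precision[sign], recall[sign]
            f1[sign] = 2 * p_ * r_ / (p_ + r_)
        else:
            f1[sign] = 0.0 if (n_called or n_true) else math.nan

    bg_pairs = {(m, o) for o in truth.background for m in truth.target_sites}
    bg_called = (called["positive"] | called["negative"]) & bg_pairs
    null_fpr = len(bg_called) / len(bg_pairs) if bg_pairs else math.nan
    return RecoveryReport(
        precision=precision,
        recall=recall,
        f1=f1,
        null_fpr=null_fpr,
        n_true={s: len(true_pairs[s]) for s in true_pairs},
        n_called={s: len(called[s]) for s in called},
    )


@dataclass
class CalibrationResult:
    fpr: float
    n_pairs: int
    n_false: int
    ci_low: float
    ci_high: float


def null_calibration(
    config: SynthConfig,
    replicates: int = 10,
    alpha: float = 0.05,
    hc_config: Optional[HighConfidenceConfig] = None,
) -> CalibrationResult:
    """Empirical false-positive rate of the full gate under independence.

    Runs ``replicates`` independent compendia with no planted partners
    (background only), scans every background pair against every target
    site, and reports the fraction passing the full high-confidence gate
    with an exact (Clopper-Pearson) 95% binomial CI.
    """
    from .pipeline import analyze_observations  # deferred: avoid import cycle

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    cfg = replace(config, n_pos_partners=0, n_neg_partners=0)
    hc = hc_config or HighConfidenceConfig(alpha=alpha)
    n_pairs = 0
    n_false = 0
    for i in range(replicates):
        obs, truth = generate_compendium(replace(cfg, seed=cfg.seed + i))
        _, _, results = analyze_observations(
            obs,
            cfg.target_symbol,
            hc_config=hc,
            explicit_sites=list(truth.target_sites),
        )
        report = evaluate_recovery(results, truth, alpha)
        n_bg = len(truth.background) * len(truth.target_sites)
        n_pairs += n_bg
        n_false += round(report.null_fpr * n_bg)
    if n_pairs < 100:
        raise ValueError(
            f"only {n_pairs} null pairs simulated; increase replicates or n_background"
        )
    ci = stats.binomtest(n_false, n_pairs).proportion_ci(0.95, method="exact")
    return CalibrationResult(n_false / n_pairs, n_pairs, n_false, ci.low, ci.high)
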