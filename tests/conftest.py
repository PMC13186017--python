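import pytest
from hypothesis import HealthCheck, settings

from phoscoreg.compendium import Direction, SiteKey, StudyRef
from phoscoreg.datasets import write_toy_fixture
from phoscoreg.pipeline import run_pipeline

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_run(tmp_path_factory):
    """Full pipeline run on the bundled toy fixture (built once per session)."""
    d = tmp_path_factory.mktemp("toy")
    config = write_toy_fixture(d)
    result = run_pipeline(config)
    return config, result


@pytest.fixture
def make_calls():
    """Build a condition-level direction map from compact per-condition dicts.

    Usage: make_calls({"c1": {site_a: UP, site_b: DOWN}, ...}) — each
    condition id becomes its own StudyRef; ``pmids`` optionally maps
    condition id -> pmid (default: one pmid per condition).
    """

    def _make(cond_dirs: dict, pmids: dict | None = None):
        calls = {}
        for cond, site_dirs in cond_dirs.items():
            pmid = (pmids or {}).get(cond, f"P_{cond}")
            study = StudyRef(pmid, "d1", cond)
            for site, d in site_dirs.items():
                calls[(study, site)] = d
        return calls

    return _make


@pytest.fixture
def sites():
    return {
        "m1": SiteKey("MELK", "S", 356),
        "m2": SiteKey("MELK", "S", 505),
        "m3": SiteKey("MELK", "S", 529),
        "o1": SiteKey("MKI67", "T", 2085),
        "o2": SiteKey("TTK", "S", 436),
    }
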