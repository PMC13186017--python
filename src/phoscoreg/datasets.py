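"""Bundled toy fixture: a hand-built 12-condition compendium with known
outcomes at every pipeline stage.

Four differential publications (three conditions each) share a latent
regime — Up in the first six conditions, Down in the last six — so the
target protein's sites and six of its planted partner sites move
coherently, one partner moves in strict opposition, one partner is only
measured in ten conditions (losing significance at the third target
site) and one site is directionally mixed (null).  Annotation resources
are small synthetic snapshots naming kinases, phosphatases, interactions
and kinase-substrate edges for the planted partners.  Expected stage
counts are hand-enumerated in :data:`TOY_EXPECTED`.

All files are synthetic stand-ins written at call time; nothing is
downloaded.
"""

from __future__ import annotations

from pathlib import Path

from .pipeline import PipelineConfig

TARGET = "MELK"

_UP = ("2.0", "0.001")  # fold_change, p_value realizing an Up call
_DOWN = ("0.5", "0.001")
_UNCH = ("1.0", "0.5")

# condition -> (pmid, regime); c01..c06 Up, c07..c12 Down
_CONDITIONS = [
    (f"c{i:02d}", f"PMID{1 + (i - 1) // 3}", "U" if i <= 6 else "D") for i in range(1, 13)
]

# target-site informativeness: S505 unchanged in c03/c09, S529 in c03/c06/c09/c12
_S505_UNCH = {"c03", "c09"}
_S529_UNCH = {"c03", "c06", "c09", "c12"}
# CDK16 not measured in c05/c11
_CDK16_MISSING = {"c05", "c11"}
# RBM12: tracks regime in c01,c02,c07,c08; opposes in c04,c05,c10,c11; unchanged else
_RBM12_TRACK = {"c01", "c02", "c07", "c08"}
_RBM12_OPPOSE = {"c04", "c05", "c10", "c11"}

#: Hand-enumerated expected outcomes for the toy run.
TOY_EXPECTED = {
    "n_rows": 142,
    "n_rows_class1": 139,
    "n_calls": 130,
    "major_sites": ["MELK_S356", "MELK_S505", "MELK_S529"],
    "n_profile_unique_sites": 4,
    "n_differential_unique_sites": 3,
    "n_results": 24,
    "n_highconf": 20,
    "n_positive": 17,
    "n_negative": 3,
    "n_assignments": 29,
    "n_nodes": 10,
    "n_edges": 20,
    "venn_positive_core": 5,
    "venn_positive_s356_s505": 1,
    "venn_negative_core": 1,
}


def _diff_row(cond: str, pmid: str, gene: str, residue: str, pos: int,
              call: tuple[str, str], loc: str = "0.99", ascore: str = "20") -> str:
    fc, p = call
    return "\t".join(
        [pmid, "d1", cond, gene, residue, str(pos), loc, ascore, fc, p, "", "differential"]
    )


def _profile_row(pmid: str, gene: str, residue: str, pos: int) -> str:
    return "\t".join(
        [pmid, "pd1", "pc1", gene, residue, str(pos), "0.99", "20", "", "", "", "profile"]
    )


def _compendium_lines() -> list[str]:
    header = "\t".join(
        [
            "pmid", "dataset_id", "condition_id", "gene_symbol", "residue",
            "position", "loc_prob", "ascore", "fold_change", "p_value",
            "flanking", "dataset_kind",
        ]
    )
    lines = [header]
    for cond, pmid, regime in _CONDITIONS:
        with_r = _UP if regime == "U" else _DOWN
        anti_r = _DOWN if regime == "U" else _UP
        # target sites (the alias KIAA0175 resolves to MELK via the alias map)
        lines.append(_diff_row(cond, pmid, "KIAA0175", "S", 356, with_r))
        lines.append(_diff_row(cond, pmid, TARGET, "S", 505,
                               _UNCH if cond in _S505_UNCH else with_r))
        lines.append(_diff_row(cond, pmid, TARGET, "S", 529,
                               _UNCH if cond in _S529_UNCH else with_r))
        # pan-condition concordant partners
        lines.append(_diff_row(cond, pmid, "mki67", "T", 2085, with_r))
        lines.append(_diff_row(cond, pmid, "TTK", "S", 436, with_r))
        lines.append(_diff_row(cond, pmid, "MARK2", "S", 456, with_r))
        lines.append(_diff_row(cond, pmid, "PTPN2", "S", 304, with_r))
        lines.append(_diff_row(cond, pmid, "CDC25C", "S", 216, with_r))
        # pan-condition discordant partner
        lines.append(_diff_row(cond, pmid, "FLNB", "S", 2107, anti_r))
        # partner with partial coverage
        if cond not in _CDK16_MISSING:
            lines.append(_diff_row(cond, pmid, "CDK16", "S", 138, with_r))
        # directionally mixed null site
        if cond in _RBM12_TRACK:
            lines.append(_diff_row(cond, pmid, "RBM12", "S", 422, with_r))
        elif cond in _RBM12_OPPOSE:
            lines.append(_diff_row(cond, pmid, "RBM12", "S", 422, anti_r))
        else:
            lines.append(_diff_row(cond, pmid, "RBM12", "S", 422, _UNCH))
    # duplicate peptide for MELK_S356 in c01 (merged by conflict resolution)
    lines.append(_diff_row("c01", "PMID1", TARGET, "S", 356, _UP))
    # sub-Class-I rows exercising the quality filter (removed, change nothing)
    lines.append(_diff_row("c01", "PMID1", "MKI67", "T", 2085, _UP, loc="0.50"))
    lines.append(_diff_row("c02", "PMID1", TARGET, "S", 356, _UP, loc="0.60"))
    lines.append(_diff_row("c01", "PMID1", "PTPN2", "S", 304, _UP, loc="0.99", ascore="5"))
    # qualitative profile inventories
    for pmid in ("PMID5", "PMID6"):
        for res, pos in (("S", 356), ("S", 505), ("S", 529), ("T", 167)):
            lines.append(_profile_row(pmid, TARGET, res, pos))
    return lines


_RESOURCES = {
    "kinase_substrate.tsv": [
        "kinase\tsubstrate\tsite\tsource_tag",
        "MELK\tCDC25C\tS216\tks-synthetic-v1",
        "MELK\tCDC25C\tS216\tks-synthetic-v1",  # duplicate row (deduplicated on load)
        "MELK\tFLNB\tS2107\tks-synthetic-v1",
    ],
    "predicted_kinase_site.tsv": [
        "kinase\ttarget\ttarget_site\tsource_tag",
        "TTK\tMELK\tS356\tpred-synthetic-v1",
        "MARK2\tMELK\tS356\tpred-synthetic-v1",
        "MARK2\tMELK\tS505\tpred-synthetic-v1",
        "NEK4\tMELK\tS356\tpred-synthetic-v1",
    ],
    "interaction.tsv": [
        "gene_a\tgene_b\tsource_tag",
        "MELK\tMKI67\tppi-synthetic-v1",
        "MKI67\tMELK\tppi-synthetic-v1",  # reversed duplicate (stored undirected)
        "TTK\tMELK\tppi-synthetic-v1",
    ],
    "kinase_list.tsv": [
        "gene\tsource_tag",
        "TTK\tklist-synthetic-v1",
        "MARK2\tklist-synthetic-v1",
        "CDK16\tklist-synthetic-v1",
        "NEK4\tklist-synthetic-v1",
        "MELK\tklist-synthetic-v1",
    ],
    "phosphatase_list.tsv": [
        "gene\tsource_tag",
        "PTPN2\tplist-synthetic-v1",
        "CDC25C\tplist-synthetic-v1",
    ],
}


def write_toy_fixture(directory: str | Path) -> PipelineConfig:
    """Write the toy compendium, alias map, domains and resources.

    Returns a ready-to-run :class:`PipelineConfig` whose ``outdir`` is
    ``<directory>/out``.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    (d / "compendium.tsv").write_text("\n".join(_compendium_lines()) + "\n")
    (d / "alias.tsv").write_text("alias\tapproved_symbol\nKIAA0175\tMELK\n")
    (d / "domains.tsv").write_text(
        "name\tstart\tend\nPkinase\t11\t263\nKA1\t607\t651\n"
    )
    for fname, lines in _RESOURCES.items():
        (d / fname).write_text("\n".join(lines) + "\n")
    return PipelineConfig(
        compendium=str(d / "compendium.tsv"),
        target=TARGET,
        outdir=str(d / "out"),
        alias_map=str(d / "alias.tsv"),
        domains=str(d / "domains.tsv"),
        resources={
            "kinase_substrate": str(d / "kinase_substrate.tsv"),
            "predicted_kinase_site": str(d / "predicted_kinase_site.tsv"),
            "interaction": str(d / "interaction.tsv"),
            "kinase_list": str(d / "kinase_list.tsv"),
            "phosphatase_list": str(d / "phosphatase_list.tsv"),
        },
    )
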