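"""End-to-end orchestration: alignment -> distances -> UPGMA delimitation ->
group evidence -> LSR classification -> flora summary.

These functions are the library surface behind the command-line interface
and the synthetic-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import ClassifierConfig, DEFAULT_CONFIG
from .lsr_inference import (
    ATLANTIC,
    PACIFIC,
    GroupEvidence,
    LSRCall,
    MorphoSpeciesComplex,
    PanelResult,
    classify_panel,
)
from .species_clustering import (
    GeneticGroup,
    delimit_groups,
    regional_composition,
    within_group_structure,
)
from .specimen_io import AlignmentSet, ChecklistRecord, Specimen
from .synthetic_flora import SyntheticFlora


def build_complex(
    name: str,
    aln: AlignmentSet,
    specimens: list[Specimen],
    checklist: ChecklistRecord | None,
    cfg: ClassifierConfig = DEFAULT_CONFIG,
    congeneric_n: dict | None = None,
) -> tuple[MorphoSpeciesComplex, list[GeneticGroup]]:
    """Cluster one morpho-species' barcodes and distill the geographic
    evidence the LSR rules consume."""
    _tree, groups = delimit_groups(aln, cfg.delimit_threshold, prefix=f"{name}.G")
    for g in groups:
        regional_composition(g, specimens)
    churchill_groups = [g for g in groups if g.composition.get("churchill", 0) > 0]
    other_groups = [g for g in groups if g.composition.get("churchill", 0) == 0]
    evidence = []
    for g in churchill_groups:
        st = within_group_structure(g, aln, specimens, cfg=cfg)
        evidence.append(GroupEvidence.from_structure(g, st))
    n_by_region = {r: 0 for r in ("pacific", "churchill", "atlantic")}
    for g in groups:
        for r, n in g.composition.items():
            n_by_region[r] += n
    conspec_elsewhere = {
        r: sum(g.composition.get(r, 0) for g in other_groups)
        for r in (ATLANTIC, PACIFIC)
    }
    complex_ = MorphoSpeciesComplex(
        name=name,
        marker=aln.marker,
        checklist=checklist,
        n_pacific=n_by_region["pacific"],
        n_churchill=n_by_region["churchill"],
        n_atlantic=n_by_region["atlantic"],
        groups=tuple(evidence) or (GroupEvidence(),),
        conspec_elsewhere=conspec_elsewhere,
        congeneric_n=congeneric_n or {ATLANTIC: 0, PACIFIC: 0},
        n_groups_atlantic=sum(
            1 for g in groups if g.composition.get(ATLANTIC, 0) > 0
        ),
        n_groups_pacific=sum(
            1 for g in groups if g.composition.get(PACIFIC, 0) > 0
        ),
    )
    return complex_, groups


@dataclass
class FloraRunResult:
    panel: PanelResult
    complexes: list[MorphoSpeciesComplex]
    groups: dict[str, list[GeneticGroup]]


def classify_flora(
    flora: SyntheticFlora, cfg: ClassifierConfig = DEFAULT_CONFIG
) -> FloraRunResult:
    """Run the full molecular pipeline over a simulated flora."""
    complexes: list[MorphoSpeciesComplex] = []
    groups: dict[str, list[GeneticGroup]] = {}
    for species, aln in flora.alignments.items():
        cx, gs = build_complex(
            species,
            aln,
            flora.specimens[species],
            flora.checklist.get(species),
            cfg=cfg,
        )
        complexes.append(cx)
        groups[species] = gs
    return FloraRunResult(
        panel=classify_panel(complexes, cfg), complexes=complexes, groups=groups
    )


def run_survey(cfg: ClassifierConfig = DEFAULT_CONFIG):
    """Classify the bundled Churchill survey panel and compute every summary
    statistic: returns a dict with the panel result, both summary tables,
    checklist percentages and scenario outcomes."""
    from importlib import resources

    import yaml

    from .flora_summary import (
        HISTORICAL_ARCTIC_CHECKLIST,
        checklist_summary,
        scenario_analysis,
        summarize_lsr,
    )
    from .specimen_io import load_survey

    panel_data = load_survey()
    complexes = [
        MorphoSpeciesComplex.from_survey_entry(e) for e in panel_data.entries
    ]
    result = classify_panel(complexes, cfg)
    n_excluded = len({c.species for c in result.excluded})
    tables = {
        basis: summarize_lsr(result.calls, basis, n_excluded=n_excluded)
        for basis in ("morphology", "molecular")
    }
    checklist = {
        "all": checklist_summary(HISTORICAL_ARCTIC_CHECKLIST, rounding="one_decimal"),
        "excl_arctic": checklist_summary(
            HISTORICAL_ARCTIC_CHECKLIST,
            exclude_arctic=True,
            rounding="nearest_integer",
        ),
    }
    scen_path = resources.files("barcodeflora").joinpath("data/scenarios.yaml")
    scen_cfg = yaml.safe_load(scen_path.read_text())
    scenarios = {}
    mol_calls = tables and [
        c for c in result.calls if c.basis == "molecular"
    ]
    for name in scen_cfg["scenarios"]:
        spec = _resolve_scenario(scen_cfg["scenarios"], name)
        scenarios[name] = scenario_analysis(
            tables["molecular"],
            add_as=[tuple(x) for x in spec.get("add_as", [])],
            reassign=[tuple(x) for x in spec.get("reassign", [])],
            rounding=spec.get("rounding"),
            region=scen_cfg.get("queried_region", PACIFIC),
            current_calls=mol_calls,
        )
    return {
        "panel": result,
        "survey": panel_data,
        "tables": tables,
        "checklist": checklist,
        "scenarios": scenarios,
    }


def _resolve_scenario(all_scenarios: dict, name: str) -> dict:
    """Flatten cumulative ("extends") scenario definitions."""
    spec = all_scenarios[name]
    if "extends" not in spec:
        return {
            "add_as": list(spec.get("add_as", [])),
            "reassign": list(spec.get("reassign", [])),
            "rounding": spec.get("rounding"),
        }
    base = _resolve_scenario(all_scenarios, spec["extends"])
    return {
        "add_as": base["add_as"] + list(spec.get("add_as", [])),
        "reassign": base["reassign"] + list(spec.get("reassign", [])),
        "rounding": spec.get("rounding", base["rounding"]),
    }


def molecular_accuracy(
    flora: SyntheticFlora, result: FloraRunResult
) -> tuple[int, int]:
    """(n_correct, n_total): molecular call (with 'excluded' as its own
    category) versus generator ground truth."""
    truth = {t.species: t.true_source for t in flora.truth}
    by_species: dict[str, str] = {}
    for call in result.panel.calls:
        if call.basis == "molecular":
            by_species[call.species] = call.call
    for call in result.panel.excluded:
        if call.basis == "molecular":
            by_species[call.species] = call.call
    correct = sum(1 for s, c in by_species.items() if c == truth[s])
    return correct, len(by_species)
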