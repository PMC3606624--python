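"""Likely-source-region (LSR) inference.

A species now present in a recently deglaciated flora (here Churchill,
western Hudson Bay) must have migrated in from the contiguous North Atlantic
or North Pacific after the last glacial retreat. Two classifiers estimate
that source region per morpho-species:

* **morphological** - from reported/observed regional presence alone: a
  single candidate source region can be named only when the species is
  known from exactly one of the two oceans, maps to a single genetic group
  there, and its name is not entangled in cryptic-species confusion;
* **molecular** - an ordered rule cascade over the genetic species group(s)
  that contain Churchill barcodes, demanding positive geographic concordance
  (shared mitotypes, diagnostic fixed differences, or positive elimination
  of the alternative) before a region is called.

Species are *excluded* from the summary when comparator evidence from some
candidate source region is inadequate - no conspecific barcodes, no
sufficiently deep congeneric screen, and no positive elimination - so that
absence of data is never mistaken for absence of the species.

Rule ids (recorded on every call for auditability):

========  ===========================================================
R0        external-evidence override (secondary marker, e.g. ITS/rbcL)
R1/R1P    Churchill barcodes share a group with one region only
          (Atlantic -> R1, Pacific -> R1P), the other region being
          adequately screened, positively eliminated, or unreported
R2        group spans both regions with >= 1 fixed difference; the
          Churchill mitotypes carry one (or both) regional signatures
R3        group spans both regions without geographic differentiation
R4        elimination: the sampled region is positively ruled out
          (conspecifics all in other groups, or the Churchill members
          are separated from it by fixed differences), leaving the
          reported alternative
R5        no usable comparator signal -> uncertain
R6        two single-region groups in opposite regions each contain
          Churchill members -> established from both oceans
RX        contradictory multi-group placements -> uncertain
========  ===========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .config import ClassifierConfig, DEFAULT_CONFIG
from .specimen_io import ChecklistRecord, SurveyEntry
from .species_clustering import (
    MATCHES_ATLANTIC,
    MATCHES_BOTH,
    MATCHES_PACIFIC,
    UNDIFFERENTIATED,
    UNIQUE,
    GeneticGroup,
    MitotypeStructure,
)

ATLANTIC = "atlantic"
PACIFIC = "pacific"
BOTH = "both"
UNCERTAIN = "uncertain"
EXCLUDED = "excluded"
CALLS = (ATLANTIC, PACIFIC, BOTH, UNCERTAIN, EXCLUDED)
POSITIVE = (ATLANTIC, PACIFIC, BOTH)

MORPHOLOGY = "morphology"
MOLECULAR = "molecular"


@dataclass(frozen=True)
class GroupEvidence:
    """Geographic evidence carried by one Churchill-containing genetic group.

    ``regions`` lists the non-Churchill source regions with members in the
    group. For two-region groups, ``n_fixed_atl_pac``/``churchill_matches``/
    ``differentiated`` summarize the mitotype structure. For single-region
    groups, ``n_fixed_churchill`` counts fixed differences between the
    Churchill members and that region and ``nearest_region`` records whether
    the Churchill mitotype is still nested among / sister to that region's
    mitotypes (None when it is well separated).
    """

    regions: frozenset = frozenset()
    n_fixed_atl_pac: int = 0
    churchill_matches: str = UNDIFFERENTIATED
    differentiated: bool = False
    nearest_region: Optional[str] = None
    n_fixed_churchill: int = 0

    @classmethod
    def from_structure(
        cls, group: GeneticGroup, structure: MitotypeStructure
    ) -> "GroupEvidence":
        regions = frozenset(
            r
            for r in (ATLANTIC, PACIFIC)
            if group.composition.get(r, 0) > 0
        )
        return cls(
            regions=regions,
            n_fixed_atl_pac=structure.n_fixed_atl_vs_pac,
            churchill_matches=structure.churchill_matches,
            differentiated=structure.differentiated,
            nearest_region=structure.nearest_region,
            n_fixed_churchill=structure.n_fixed_churchill,
        )


def parse_group_evidence(encoded: str) -> tuple[GroupEvidence, ...]:
    """Parse the compact ``|``-separated group-evidence encoding used by the
    survey TSV, e.g. ``regions=atlantic+pacific;fixed=2;matches=matches_atlantic``.

    Recognized keys: regions (``+``-joined, may be empty), fixed
    (n_fixed_atl_pac), matches, nearest, chufixed (n_fixed_churchill).
    """
    groups = []
    if not encoded.strip():
        return (GroupEvidence(),)
    for token in encoded.split("|"):
        kv = dict(item.split("=", 1) for item in token.split(";") if item)
        regions = frozenset(r for r in kv.get("regions", "").split("+") if r)
        n_fixed = int(kv.get("fixed", 0))
        matches = kv.get("matches", UNDIFFERENTIATED)
        nearest = kv.get("nearest") or None
        if nearest == "none":
            nearest = None
        groups.append(
            GroupEvidence(
                regions=regions,
                n_fixed_atl_pac=n_fixed,
                churchill_matches=matches,
                differentiated=n_fixed >= 1 or matches
                in (MATCHES_ATLANTIC, MATCHES_PACIFIC, MATCHES_BOTH),
                nearest_region=nearest,
                n_fixed_churchill=int(kv.get("chufixed", 0)),
            )
        )
    return tuple(groups)


@dataclass
class MorphoSpeciesComplex:
    """Everything the classifiers need to know about one morpho-species /
    genetic species group: sampling counts, checklist flags, the evidence of
    its Churchill-containing group(s), comparator depth, and any external
    (secondary-marker) evidence."""

    name: str
    genus: str = ""
    marker: str = "COI-5P"
    checklist: Optional[ChecklistRecord] = None
    n_pacific: int = 0
    n_churchill: int = 0
    n_atlantic: int = 0
    groups: tuple[GroupEvidence, ...] = (GroupEvidence(),)
    conspec_elsewhere: dict = field(default_factory=lambda: {ATLANTIC: 0, PACIFIC: 0})
    congeneric_n: dict = field(default_factory=lambda: {ATLANTIC: 0, PACIFIC: 0})
    comparator_adequate: dict = field(
        default_factory=lambda: {ATLANTIC: None, PACIFIC: None}
    )
    external_evidence: Optional[tuple[str, str]] = None  # (region, citation)
    n_groups_atlantic: int = 1
    n_groups_pacific: int = 1

    @classmethod
    def from_survey_entry(cls, entry: SurveyEntry) -> "MorphoSpeciesComplex":
        ext = None
        if entry.external_evidence_region:
            ext = (entry.external_evidence_region, entry.external_evidence_citation or "")
        return cls(
            name=entry.name,
            genus=entry.genus,
            marker=entry.marker,
            checklist=entry.checklist,
            n_pacific=entry.n_pacific,
            n_churchill=entry.n_churchill,
            n_atlantic=entry.n_atlantic,
            groups=parse_group_evidence(entry.groups_encoded),
            conspec_elsewhere={
                ATLANTIC: entry.conspec_elsewhere_atlantic,
                PACIFIC: entry.conspec_elsewhere_pacific,
            },
            congeneric_n={
                ATLANTIC: entry.congeneric_atlantic_n,
                PACIFIC: entry.congeneric_pacific_n,
            },
            comparator_adequate={
                ATLANTIC: entry.comparator_adequate_atlantic,
                PACIFIC: entry.comparator_adequate_pacific,
            },
            external_evidence=ext,
            n_groups_atlantic=entry.n_groups_atlantic,
            n_groups_pacific=entry.n_groups_pacific,
        )

    # -- derived evidence -------------------------------------------------

    def n_region(self, region: str) -> int:
        return {ATLANTIC: self.n_atlantic, PACIFIC: self.n_pacific}[region]

    def reported(self, region: str) -> bool:
        if self.checklist is None:
            return False
        return {
            ATLANTIC: self.checklist.reported_atlantic,
            PACIFIC: self.checklist.reported_pacific,
        }[region]

    def observed(self, region: str) -> bool:
        return self.n_region(region) > 0

    def candidate_regions(self) -> frozenset:
        cands = frozenset(
            r for r in (ATLANTIC, PACIFIC) if self.reported(r) or self.observed(r)
        )
        return cands or frozenset((ATLANTIC, PACIFIC))

    def screened_adequately(self, region: str, cfg: ClassifierConfig) -> bool:
        """Is the *absence* of this species from ``region`` credible?

        Explicit per-species flags (the analyst's case-by-case judgment)
        win; otherwise conspecific sampling depth >= min_conspecific_elim or
        a congeneric screen >= min_congeneric qualifies.
        """
        flag = self.comparator_adequate.get(region)
        if flag is not None:
            return flag
        return (
            self.n_region(region) >= cfg.min_conspecific_elim
            or self.congeneric_n.get(region, 0) >= cfg.min_congeneric
        )

    def eliminated(self, region: str, cfg: ClassifierConfig) -> bool:
        """Region positively ruled out: enough conspecifics were barcoded
        from it and every one fell into a different genetic group."""
        return self.conspec_elsewhere.get(region, 0) >= cfg.min_conspecific_elim


@dataclass(frozen=True)
class LSRCall:
    species: str
    basis: str
    call: str
    rule_id: str
    rationale: str

    def __post_init__(self) -> None:
        assert self.call in CALLS
        assert self.basis in (MORPHOLOGY, MOLECULAR)


_OTHER = {ATLANTIC: PACIFIC, PACIFIC: ATLANTIC}
_R1_ID = {ATLANTIC: "R1", PACIFIC: "R1P"}


def _evaluate_group(
    complex_: MorphoSpeciesComplex, g: GroupEvidence, cfg: ClassifierConfig
) -> tuple[str, str, str]:
    """Evaluate one Churchill-containing group -> (call, rule_id, rationale).

    The special call value "inadequate:<region>" marks an outcome blocked by
    an unscreened candidate region (grounds for exclusion).
    """
    regions = g.regions
    if regions == {ATLANTIC, PACIFIC} or regions == frozenset((ATLANTIC, PACIFIC)):
        if g.differentiated and g.n_fixed_atl_pac >= 1:
            m = g.churchill_matches
            if m == MATCHES_ATLANTIC:
                return (
                    ATLANTIC,
                    "R2",
                    f"{g.n_fixed_atl_pac} fixed difference(s) separate the regional "
                    "mitotypes; Churchill carries the Atlantic signature",
                )
            if m == MATCHES_PACIFIC:
                return (
                    PACIFIC,
                    "R2",
                    f"{g.n_fixed_atl_pac} fixed difference(s) separate the regional "
                    "mitotypes; Churchill carries the Pacific signature",
                )
            if m == MATCHES_BOTH:
                return (
                    BOTH,
                    "R2",
                    "Churchill specimens carry both the Atlantic and the Pacific "
                    "diagnostic mitotypes",
                )
            return (
                UNCERTAIN,
                "R2",
                "regional mitotypes are differentiated but the Churchill "
                "mitotype matches neither signature",
            )
        if g.differentiated:
            # sub-cluster (population) structure without fixed differences
            m = g.churchill_matches
            if m in (MATCHES_ATLANTIC, MATCHES_PACIFIC, MATCHES_BOTH):
                call = {
                    MATCHES_ATLANTIC: ATLANTIC,
                    MATCHES_PACIFIC: PACIFIC,
                    MATCHES_BOTH: BOTH,
                }[m]
                return (
                    call,
                    "R2",
                    "regional sub-clusters separate the source floras; Churchill "
                    f"resolves with the {call} cluster(s)",
                )
        return (
            UNCERTAIN,
            "R3",
            "the group spans both source regions with undifferentiated "
            "mitotypes; recent migration, direction uncertain",
        )
    if len(regions) == 1:
        (present,) = regions
        other = _OTHER[present]
        separated = (
            g.n_fixed_churchill >= cfg.min_fixed_elim
            and g.nearest_region != present
        )
        if separated:
            # Churchill positively differentiated from the only sampled region
            if complex_.reported(other):
                return (
                    other,
                    "R4",
                    f"Churchill mitotypes are separated from the {present} "
                    f"collections by {g.n_fixed_churchill} fixed differences; the "
                    f"reported {other} flora remains as the likely source",
                )
            return (
                UNCERTAIN,
                "R5",
                f"Churchill mitotypes are differentiated from the {present} "
                "collections and no alternative source region is reported",
            )
        # Churchill nested among the sampled region's mitotypes
        if (
            not complex_.reported(other) and not complex_.observed(other)
        ) or complex_.eliminated(other, cfg) or complex_.screened_adequately(other, cfg):
            return (
                present,
                _R1_ID[present],
                f"Churchill barcodes resolve with the {present} collections and "
                f"the {other} flora is unreported, screened, or positively "
                "eliminated",
            )
        return (
            f"inadequate:{other}",
            "E2",
            f"the {other} region is reported for this morpho-species but no "
            "conspecific barcodes or adequate comparator screen exist for it",
        )
    # Churchill-only group
    candidates = complex_.candidate_regions()
    eliminated = {r for r in candidates if complex_.eliminated(r, cfg)}
    remaining = candidates - eliminated
    if len(remaining) == 1 and eliminated:
        (target,) = remaining
        if complex_.reported(target):
            return (
                target,
                "R4",
                "the Churchill group was not encountered among "
                f"{sum(complex_.conspec_elsewhere.values())} conspecific barcodes "
                f"from the {'/'.join(sorted(eliminated))} region(s); the reported "
                f"{target} flora remains by elimination",
            )
    if all(complex_.screened_adequately(r, cfg) or r in eliminated for r in candidates):
        return (
            UNCERTAIN,
            "R5",
            "a Churchill-only group with adequately screened candidate regions "
            "but no positive match anywhere",
        )
    blocked = sorted(
        r
        for r in candidates
        if not complex_.screened_adequately(r, cfg) and r not in eliminated
    )
    return (
        f"inadequate:{','.join(blocked)}",
        "E2",
        "a Churchill-only group whose candidate source region(s) "
        f"({', '.join(blocked)}) lack conspecific samples and an adequate "
        "comparator screen",
    )


def _merge_group_calls(
    calls: list[tuple[str, str, str]]
) -> tuple[str, str, str]:
    """Combine the per-group outcomes for species whose Churchill barcodes
    fall in more than one genetic group."""
    if len(calls) == 1:
        return calls[0]
    positive = [(c, r, why) for c, r, why in calls if c in POSITIVE]
    pos_regions = {c for c, _, _ in positive}
    if pos_regions == {ATLANTIC, PACIFIC} or BOTH in pos_regions:
        return (
            BOTH,
            "R6",
            "distinct Churchill groups independently match the Atlantic and the "
            "Pacific floras; established from both oceans",
        )
    if len(pos_regions) == 1:
        return positive[0]
    if any(c.startswith("inadequate") for c, _, _ in calls):
        bad = next(c for c, _, _ in calls if c.startswith("inadequate"))
        return (bad, "E2", "comparator evidence inadequate for at least one group")
    return (
        UNCERTAIN,
        "RX",
        "Churchill barcodes are spread over multiple groups without a "
        "concordant geographic signal",
    )


def _evaluate(
    complex_: MorphoSpeciesComplex, cfg: ClassifierConfig, honor_disabled: bool = True
) -> tuple[str, str, str]:
    """Full molecular evaluation -> (call, rule_id, rationale); the call may
    be an ``inadequate:`` marker, which classify_panel maps to exclusion."""
    if complex_.external_evidence is not None:
        region, citation = complex_.external_evidence
        if not (honor_disabled and "R0" in cfg.disabled_rules):
            return (
                region,
                "R0",
                f"secondary-marker evidence assigns the Churchill population to "
                f"the {region} lineage ({citation})",
            )
    call, rule, why = _merge_group_calls(
        [_evaluate_group(complex_, g, cfg) for g in complex_.groups]
    )
    if honor_disabled and rule in cfg.disabled_rules and call in POSITIVE:
        return (
            UNCERTAIN,
            f"{rule}-disabled",
            f"rule {rule} disabled by configuration; call degraded to uncertain",
        )
    return call, rule, why


def eligibility(
    complex_: MorphoSpeciesComplex, cfg: ClassifierConfig = DEFAULT_CONFIG
) -> tuple[bool, str]:
    """Decide whether a species can be included in the LSR summary.

    A species is excluded exactly when its molecular evaluation is blocked by
    a candidate source region with no conspecific barcodes and no adequate
    comparator screen (and no positive elimination rescues the call).
    Eligibility ignores rule-disabling so that sensitivity analyses degrade
    calls to uncertain instead of silently changing the denominator.
    """
    if complex_.n_churchill < 1:
        raise ValueError(
            f"{complex_.name}: only Churchill-occurring species are classified"
        )
    call, rule, why = _evaluate(complex_, cfg, honor_disabled=False)
    if call.startswith("inadequate"):
        return False, why
    return True, f"comparator evidence adequate (rule {rule})"


def morphological_lsr(
    complex_: MorphoSpeciesComplex, cfg: ClassifierConfig = DEFAULT_CONFIG
) -> LSRCall:
    """Source region from reported/observed presence alone.

    Uncertain whenever presence covers both oceans, the morpho-species maps
    to more than one genetic group in either source region, or the name is
    flagged for taxonomic confusion.
    """
    present = {
        r for r in (ATLANTIC, PACIFIC) if complex_.reported(r) or complex_.observed(r)
    }
    confusion = complex_.checklist is not None and complex_.checklist.taxonomic_confusion
    if confusion:
        call, rule, why = (
            UNCERTAIN,
            "M3",
            "the morpho-species name is entangled in taxonomic confusion",
        )
    elif present == {ATLANTIC, PACIFIC}:
        call, rule, why = (
            UNCERTAIN,
            "M1",
            "the morpho-species is known from both the Atlantic and the Pacific",
        )
    elif complex_.n_groups_atlantic > 1 or complex_.n_groups_pacific > 1:
        call, rule, why = (
            UNCERTAIN,
            "M2",
            "the morpho-species maps to more than one genetic group in a "
            "source region",
        )
    elif present:
        (region,) = present
        call, rule, why = (
            region,
            "M0",
            f"reported/observed only from the {region} of the two source regions",
        )
    else:
        call, rule, why = (
            UNCERTAIN,
            "M4",
            "no reported presence in either source region",
        )
    return LSRCall(complex_.name, MORPHOLOGY, call, rule, why)


def molecular_lsr(
    complex_: MorphoSpeciesComplex, cfg: ClassifierConfig = DEFAULT_CONFIG
) -> LSRCall:
    """Source region from the genetic evidence (rule cascade; see module
    docstring). Must only be applied to species that pass eligibility."""
    call, rule, why = _evaluate(complex_, cfg)
    if call.startswith("inadequate"):
        call = UNCERTAIN
    return LSRCall(complex_.name, MOLECULAR, call, rule, why)


@dataclass
class PanelResult:
    calls: list[LSRCall]
    excluded: list[LSRCall]
    audit_log: list[str]

    def by_basis(self, basis: str) -> list[LSRCall]:
        return [c for c in self.calls if c.basis == basis]


def classify_panel(
    complexes: list[MorphoSpeciesComplex],
    cfg: ClassifierConfig = DEFAULT_CONFIG,
) -> PanelResult:
    """Apply eligibility then both classifiers to every species; excluded
    species receive paired ``excluded`` calls and are kept separate."""
    calls: list[LSRCall] = []
    excluded: list[LSRCall] = []
    audit: list[str] = []
    for cx in complexes:
        ok, reason = eligibility(cx, cfg)
        if not ok:
            for basis in (MORPHOLOGY, MOLECULAR):
                excluded.append(LSRCall(cx.name, basis, EXCLUDED, "E2", reason))
            audit.append(f"{cx.name}\texcluded\tE2\t{reason}")
            continue
        morph = morphological_lsr(cx, cfg)
        mol = molecular_lsr(cx, cfg)
        calls.extend([morph, mol])
        audit.append(f"{cx.name}\t{MORPHOLOGY}\t{morph.rule_id}\t{morph.call}")
        audit.append(f"{cx.name}\t{MOLECULAR}\t{mol.rule_id}\t{mol.call}")
    return PanelResult(calls=calls, excluded=excluded, audit_log=audit)
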