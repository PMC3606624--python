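"""Input/output for barcode floristics: aligned FASTA, specimen and checklist
tables, Newick dendrograms, and the bundled Churchill survey panel.

The survey panel (``load_survey``) encodes the 57 genetic species groups of a
DNA-barcode survey of the Churchill (western Hudson Bay) macroalgal flora:
per-group specimen counts from the Pacific, Churchill and Atlantic regions,
checklist presence flags, the mitotype evidence backing each source-region
call, and the published morphology/molecular classifications used to audit
the rule engine.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

MARKERS = ("COI-5P", "tufA", "rbcL-3P")
REGIONS = ("pacific", "churchill", "atlantic")
SUBREGIONS = ("europe", "north_america", "bering", "other")
SOURCE_REGIONS = ("pacific", "atlantic")

# Uppercase IUPAC nucleotide codes plus alignment gap.
IUPAC_CHARS = frozenset("ACGTUNRYSWKMBDHV-")
UNAMBIGUOUS = frozenset("ACGT")


class FormatError(ValueError):
    """Malformed input file (syntax, characters, schema)."""


class AlignmentError(FormatError):
    """Records of unequal length where an alignment is required."""


@dataclass(frozen=True)
class Specimen:
    """One barcoded collection."""

    specimen_id: str
    morpho_species: str
    genus: str
    marker: str
    region: str
    subregion: Optional[str] = None
    sequence_id: Optional[str] = None
    annotations: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise ValueError(f"unknown marker {self.marker!r}")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.subregion is not None and self.subregion not in SUBREGIONS:
            raise ValueError(f"unknown subregion {self.subregion!r}")


@dataclass
class AlignmentSet:
    """A per-marker multiple alignment keyed by specimen id."""

    marker: str
    records: dict[str, str]
    length: int

    def __post_init__(self) -> None:
        for sid, seq in self.records.items():
            if len(seq) != self.length:
                raise AlignmentError(
                    f"record {sid!r} has length {len(seq)}, expected {self.length}"
                )
        if self.length <= 0:
            raise AlignmentError("alignment length must be > 0")

    def subset(self, ids: Iterable[str]) -> "AlignmentSet":
        ids = list(ids)
        missing = [i for i in ids if i not in self.records]
        if missing:
            raise KeyError(f"ids not in alignment: {missing}")
        return AlignmentSet(self.marker, {i: self.records[i] for i in ids}, self.length)


@dataclass(frozen=True)
class ChecklistRecord:
    """Reported regional presence of a morpho-species, with a flag for names
    known to hide cryptic species or to be misapplied in the local floras."""

    morpho_species: str
    reported_atlantic: bool
    reported_pacific: bool
    reported_arctic: bool
    taxonomic_confusion: bool = False


def read_fasta_alignment(path: str | Path, marker: str) -> AlignmentSet:
    """Read an aligned FASTA file into an :class:`AlignmentSet`.

    Record ids are the first whitespace-delimited token of each header;
    sequence letters are uppercased. Raises :class:`AlignmentError` on
    unequal lengths and :class:`FormatError` on empty files, duplicate ids
    or non-IUPAC characters (reported with position).
    """
    if marker not in MARKERS:
        raise ValueError(f"unknown marker {marker!r}")
    path = Path(path)
    records: dict[str, str] = {}
    length = None
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if not rid.isascii():
            raise FormatError(f"non-ASCII record id {rid!r}")
        if rid in records:
            raise FormatError(f"duplicate record id {rid!r}")
        seq = str(rec.seq).upper()
        for pos, ch in enumerate(seq):
            if ch not in IUPAC_CHARS:
                raise FormatError(
                    f"record {rid!r}: non-IUPAC character {ch!r} at column {pos}"
                )
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise AlignmentError(
                f"record {rid!r} has length {len(seq)}, expected {length}"
            )
        records[rid] = seq
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return AlignmentSet(marker=marker, records=records, length=length)


def write_fasta_alignment(aln: AlignmentSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in aln.records.items():
            fh.write(f">{sid}\n{seq}\n")


_SPECIMEN_COLUMNS = ("specimen_id", "morpho_species", "genus", "marker", "region")


def read_specimen_table(path: str | Path) -> list[Specimen]:
    """Read a tab-separated specimen metadata table.

    Required columns: specimen_id, morpho_species, genus, marker, region.
    Optional: subregion. Unknown extra columns are preserved as opaque
    annotations. Row numbers in diagnostics are 1-based data rows.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _SPECIMEN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {missing}")
    extra = [c for c in df.columns if c not in _SPECIMEN_COLUMNS + ("subregion",)]
    specimens: list[Specimen] = []
    seen: dict[str, int] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        rec = row._asdict()
        sid = rec["specimen_id"]
        if not sid.isascii():
            raise FormatError(f"row {row_no}: non-ASCII specimen_id {sid!r}")
        if sid in seen:
            raise FormatError(
                f"duplicate specimen_id {sid!r} on rows {seen[sid]} and {row_no}"
            )
        seen[sid] = row_no
        if rec["region"] not in REGIONS:
            raise FormatError(
                f"row {row_no}: region {rec['region']!r} not one of {REGIONS}"
            )
        sub = rec.get("subregion") or None
        try:
            specimens.append(
                Specimen(
                    specimen_id=sid,
                    morpho_species=rec["morpho_species"],
                    genus=rec["genus"],
                    marker=rec["marker"],
                    region=rec["region"],
                    subregion=sub,
                    sequence_id=sid,
                    annotations={c: rec[c] for c in extra},
                )
            )
        except ValueError as exc:
            raise FormatError(f"row {row_no}: {exc}") from exc
    return specimens


def write_specimen_table(specimens: Iterable[Specimen], path: str | Path) -> None:
    rows = [
        {
            "specimen_id": s.specimen_id,
            "morpho_species": s.morpho_species,
            "genus": s.genus,
            "marker": s.marker,
            "region": s.region,
            "subregion": s.subregion or "",
        }
        for s in specimens
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_checklist_table(path: str | Path) -> dict[str, ChecklistRecord]:
    """Read a checklist TSV (morpho_species, reported_atlantic,
    reported_pacific, reported_arctic, taxonomic_confusion as 0/1)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("0")
    required = (
        "morpho_species",
        "reported_atlantic",
        "reported_pacific",
        "reported_arctic",
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {missing}")
    out: dict[str, ChecklistRecord] = {}
    for row in df.itertuples(index=False):
        rec = row._asdict()
        name = rec["morpho_species"]
        out[name] = ChecklistRecord(
            morpho_species=name,
            reported_atlantic=rec["reported_atlantic"] == "1",
            reported_pacific=rec["reported_pacific"] == "1",
            reported_arctic=rec["reported_arctic"] == "1",
            taxonomic_confusion=rec.get("taxonomic_confusion", "0") == "1",
        )
    return out


def write_checklist_table(
    checklist: dict[str, ChecklistRecord], path: str | Path
) -> None:
    rows = [
        {
            "morpho_species": c.morpho_species,
            "reported_atlantic": int(c.reported_atlantic),
            "reported_pacific": int(c.reported_pacific),
            "reported_arctic": int(c.reported_arctic),
            "taxonomic_confusion": int(c.taxonomic_confusion),
        }
        for c in checklist.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def write_newick(tree, path: str | Path) -> None:
    """Serialize an ultrametric dendrogram to Newick.

    Branch lengths are chosen so the root-to-tip path equals the root merge
    height. A single leaf is written parenthesized, ``(A:0);``, for parser
    compatibility.
    """
    Path(path).write_text(to_newick(tree) + "\n")


def to_newick(tree) -> str:
    node = tree.root

    def render(n, parent_height: float) -> str:
        if n.is_leaf:
            return f"{n.name}:{parent_height - 0.0:.10g}"
        inner = ",".join(render(c, n.height) for c in n.children)
        return f"({inner}):{parent_height - n.height:.10g}"

    if node.is_leaf:
        return f"({node.name}:0);"
    inner = ",".join(render(c, node.height) for c in node.children)
    return f"({inner});"


# ---------------------------------------------------------------------------
# Bundled Churchill survey panel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurveyEntry:
    """One genetic species group of the Churchill survey.

    ``n_pacific/n_churchill/n_atlantic`` are the barcoded specimen counts for
    the group from each region. ``groups`` holds the mitotype evidence for the
    Churchill-containing genetic group(s) in the compact text encoding parsed
    by :func:`barcodeflora.lsr_inference.parse_group_evidence`. The
    ``lsr_morphology``/``lsr_molecular`` fields carry the published calls the
    classifier is audited against.
    """

    name: str
    genus: str
    algal_class: str
    marker: str
    n_pacific: int
    n_churchill: int
    n_atlantic: int
    checklist: ChecklistRecord
    n_groups_atlantic: int
    n_groups_pacific: int
    groups_encoded: str
    conspec_elsewhere_atlantic: int
    conspec_elsewhere_pacific: int
    congeneric_atlantic_n: int
    congeneric_pacific_n: int
    comparator_adequate_atlantic: Optional[bool]
    comparator_adequate_pacific: Optional[bool]
    external_evidence_region: Optional[str]
    external_evidence_citation: Optional[str]
    lsr_morphology: str
    lsr_molecular: str
    note: str = ""

    @property
    def excluded(self) -> bool:
        return self.lsr_molecular == "excluded"


@dataclass(frozen=True)
class SurveyPanel:
    """The encoded Churchill survey: 57 genetic species groups plus the
    survey-level accounting (422 collections processed, 346 barcoded)."""

    entries: tuple[SurveyEntry, ...]
    n_collections: int = 422
    n_barcoded: int = 346

    def __post_init__(self) -> None:
        if len(self.entries) != 57:
            raise ValueError(f"expected 57 entries, got {len(self.entries)}")

    @property
    def included(self) -> tuple[SurveyEntry, ...]:
        return tuple(e for e in self.entries if not e.excluded)

    @property
    def excluded(self) -> tuple[SurveyEntry, ...]:
        return tuple(e for e in self.entries if e.excluded)


def _parse_flag(value: str) -> Optional[bool]:
    if value == "":
        return None
    return value == "1"


def _survey_path() -> Path:
    return Path(str(resources.files("barcodeflora").joinpath("data/churchill_survey.tsv")))


def load_survey(path: str | Path | None = None) -> SurveyPanel:
    """Load the bundled Churchill survey panel (or an equivalently formatted
    TSV from ``path``)."""
    path = Path(path) if path is not None else _survey_path()
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    entries = []
    for row in df.itertuples(index=False):
        r = row._asdict()
        checklist = ChecklistRecord(
            morpho_species=r["name"],
            reported_atlantic=r["reported_atlantic"] == "1",
            reported_pacific=r["reported_pacific"] == "1",
            reported_arctic=r["reported_arctic"] == "1",
            taxonomic_confusion=r["taxonomic_confusion"] == "1",
        )
        entries.append(
            SurveyEntry(
                name=r["name"],
                genus=r["genus"],
                algal_class=r["algal_class"],
                marker=r["marker"],
                n_pacific=int(r["n_pacific"]),
                n_churchill=int(r["n_churchill"]),
                n_atlantic=int(r["n_atlantic"]),
                checklist=checklist,
                n_groups_atlantic=int(r["n_groups_atlantic"]),
                n_groups_pacific=int(r["n_groups_pacific"]),
                groups_encoded=r["churchill_groups"],
                conspec_elsewhere_atlantic=int(r["conspec_elsewhere_atlantic"]),
                conspec_elsewhere_pacific=int(r["conspec_elsewhere_pacific"]),
                congeneric_atlantic_n=int(r["congeneric_atlantic_n"]),
                congeneric_pacific_n=int(r["congeneric_pacific_n"]),
                comparator_adequate_atlantic=_parse_flag(
                    r["comparator_adequate_atlantic"]
                ),
                comparator_adequate_pacific=_parse_flag(
                    r["comparator_adequate_pacific"]
                ),
                external_evidence_region=r["external_evidence_region"] or None,
                external_evidence_citation=r["external_evidence_citation"] or None,
                lsr_morphology=r["lsr_morphology"],
                lsr_molecular=r["lsr_molecular"],
                note=r["note"],
            )
        )
    for e in entries:
        if min(e.n_pacific, e.n_churchill, e.n_atlantic) < 0:
            raise ValueError(f"negative count in entry {e.name}")
    return SurveyPanel(entries=tuple(entries))


def export_survey_tsv(panel: SurveyPanel, path: str | Path) -> None:
    """Write the survey panel back out as TSV (round-trips ``load_survey``)."""
    src = _survey_path()
    Path(path).write_text(Path(src).read_text())


def load_survey_expected(path: str | Path | None = None) -> dict:
    """Published summary numbers stored beside the survey panel, used by the
    CLI self-check (``reproduce-survey``)."""
    if path is None:
        path = Path(str(resources.files("barcodeflora").joinpath("data/survey_expected.json")))
    return json.loads(Path(path).read_text())
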