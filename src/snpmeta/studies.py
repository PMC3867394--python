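"""Study records, study-table I/O and subgroup classification.

A *study* is one case-control comparison contributing three genotype counts
(AA/AG/GG) per arm.  Study tables are plain delimited text (comma or tab,
auto-detected from the header) with thirteen required columns::

    study_id, first_author, year, country, ethnicity, cancer_type,
    control_source, case_aa, case_ag, case_gg, control_aa, control_ag,
    control_gg

The bundled dataset transcribes the 19 case-control studies of the MCP-1
−2518A/G (rs1024611) promoter polymorphism and cancer risk, exactly as
printed in the source table (including its internal inconsistencies, which
are preserved rather than repaired; see ``docs/methods.md``).
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Sequence

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "study_id",
    "first_author",
    "year",
    "country",
    "ethnicity",
    "cancer_type",
    "control_source",
    "case_aa",
    "case_ag",
    "case_gg",
    "control_aa",
    "control_ag",
    "control_gg",
)

#: Cancer sites pooled as "digestive system" in subgroup analyses.
DIGESTIVE_SITES = frozenset({"oral", "gastric", "colorectal", "hepatocellular"})

#: Studies with more participants than this are classed "large".
LARGE_STUDY_THRESHOLD = 500

FIXTURE_RESOURCE = "mcp1_2518ag_studies.tsv"


class Ethnicity(str, Enum):
    ASIAN = "Asian"
    CAUCASIAN = "Caucasian"
    MIXED = "Mixed"


class ControlSource(str, Enum):
    HOSPITAL = "HB"
    POPULATION = "PB"


class CancerGroup(str, Enum):
    DIGESTIVE = "digestive"
    BLADDER = "bladder"
    PROSTATE = "prostate"
    OTHER = "other"


class SizeClass(str, Enum):
    LARGE = "large"
    SMALL = "small"


@dataclass(frozen=True)
class GenotypeCounts:
    """Counts of individuals per genotype at a biallelic (A/G) locus."""

    aa: int
    ag: int
    gg: int

    def __post_init__(self) -> None:
        for name in ("aa", "ag", "gg"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool) or v < 0:
                raise ValidationError(f"genotype count {name}={v!r} must be a nonnegative integer")

    @property
    def total(self) -> int:
        return self.aa + self.ag + self.gg

    @property
    def allele_a(self) -> int:
        """Number of A alleles (two per AA homozygote, one per heterozygote)."""
        return 2 * self.aa + self.ag

    @property
    def allele_g(self) -> int:
        return 2 * self.gg + self.ag


@dataclass(frozen=True)
class StudyRecord:
    """One case-control study: metadata plus genotype counts per arm."""

    study_id: str
    first_author: str
    year: int
    country: str
    ethnicity: Ethnicity
    cancer_type: str
    control_source: ControlSource
    cases: GenotypeCounts
    controls: GenotypeCounts

    def __post_init__(self) -> None:
        if not self.study_id:
            raise ValidationError("study_id must be a non-empty string")
        if not (1000 <= self.year <= 9999):
            raise ValidationError(f"study {self.study_id}: year {self.year} is not a 4-digit year")
        if self.cases.total <= 0 or self.controls.total <= 0:
            raise ValidationError(f"study {self.study_id}: both arms must contain individuals")

    @property
    def n_total(self) -> int:
        """Total participants (cases plus controls, from genotype counts)."""
        return self.cases.total + self.controls.total


@dataclass(frozen=True)
class SubgroupLabels:
    """Deterministic stratification labels for one study."""

    cancer_group: CancerGroup
    size_class: SizeClass
    ethnicity_group: Ethnicity
    source_group: ControlSource


def classify(record: StudyRecord) -> SubgroupLabels:
    """Assign the four subgroup labels used by the stratified analyses.

    Digestive-system cancers are oral, gastric, colorectal and
    hepatocellular; any cancer type outside the recognised sites maps to
    ``other`` (with a logged notice).  A study is ``large`` when it has
    strictly more than 500 participants.
    """
    site = record.cancer_type.strip().lower()
    if site in DIGESTIVE_SITES:
        group = CancerGroup.DIGESTIVE
    elif site == "bladder":
        group = CancerGroup.BLADDER
    elif site == "prostate":
        group = CancerGroup.PROSTATE
    else:
        group = CancerGroup.OTHER
        logger.debug("study %s: cancer type %r mapped to 'other'", record.study_id, record.cancer_type)
    size = SizeClass.LARGE if record.n_total > LARGE_STUDY_THRESHOLD else SizeClass.SMALL
    return SubgroupLabels(
        cancer_group=group,
        size_class=size,
        ethnicity_group=record.ethnicity,
        source_group=record.control_source,
    )


def _parse_count(raw: str, column: str, study_id: str) -> int:
    try:
        value = int(raw)
    except (TypeError, ValueError):
        raise ValidationError(f"study {study_id!r}: column {column} value {raw!r} is not an integer") from None
    if value < 0:
        raise ValidationError(f"study {study_id!r}: column {column} is negative ({value})")
    return value


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_study_table(source: str | Path | IO[str], delimiter: str | None = None) -> list[StudyRecord]:
    """Read a delimited study table into a list of :class:`StudyRecord`.

    ``source`` may be a path or an open text stream.  The delimiter is
    auto-detected from the header line (tab if present, else comma) unless
    given explicitly.

    Raises
    ------
    SchemaError
        if a required column is missing from the header.
    ValidationError
        for non-integer/negative counts (naming the study) or duplicate
        study ids.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8", newline="") as fh:
            return read_study_table(fh, delimiter=delimiter)

    text = source.read()
    if not text.strip():
        raise SchemaError("study table is empty (no header row)")
    first_line = text.splitlines()[0]
    sep = delimiter or _sniff_delimiter(first_line)
    reader = csv.DictReader(io.StringIO(text), delimiter=sep)
    header = [h.strip() for h in (reader.fieldnames or [])]
    missing = [c for c in REQUIRED_COLUMNS if c not in header]
    if missing:
        raise SchemaError(f"study table is missing required column(s): {', '.join(missing)}")

    records: list[StudyRecord] = []
    seen: set[str] = set()
    for row in reader:
        row = {(k or "").strip(): (v or "").strip() for k, v in row.items() if k is not None}
        sid = row["study_id"]
        if not sid:
            raise ValidationError("encountered a row with an empty study_id")
        if sid in seen:
            raise ValidationError(f"duplicate study_id {sid!r}")
        seen.add(sid)
        try:
            ethnicity = Ethnicity(row["ethnicity"])
        except ValueError:
            raise ValidationError(
                f"study {sid!r}: ethnicity {row['ethnicity']!r} not one of "
                f"{[e.value for e in Ethnicity]}"
            ) from None
        try:
            source_enum = ControlSource(row["control_source"])
        except ValueError:
            raise ValidationError(
                f"study {sid!r}: control_source {row['control_source']!r} not one of "
                f"{[s.value for s in ControlSource]}"
            ) from None
        try:
            year = int(row["year"])
        except ValueError:
            raise ValidationError(f"study {sid!r}: year {row['year']!r} is not an integer") from None
        cases = GenotypeCounts(
            aa=_parse_count(row["case_aa"], "case_aa", sid),
            ag=_parse_count(row["case_ag"], "case_ag", sid),
            gg=_parse_count(row["case_gg"], "case_gg", sid),
        )
        controls = GenotypeCounts(
            aa=_parse_count(row["control_aa"], "control_aa", sid),
            ag=_parse_count(row["control_ag"], "control_ag", sid),
            gg=_parse_count(row["control_gg"], "control_gg", sid),
        )
        records.append(
            StudyRecord(
                study_id=sid,
                first_author=row["first_author"],
                year=year,
                country=row["country"],
                ethnicity=ethnicity,
                cancer_type=row["cancer_type"],
                control_source=source_enum,
                cases=cases,
                controls=controls,
            )
        )
    return records


def write_study_table(records: Iterable[StudyRecord], dest: str | Path | IO[str], delimiter: str = "\t") -> None:
    """Write records in the 13-column schema (inverse of :func:`read_study_table`)."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8", newline="") as fh:
            write_study_table(records, fh, delimiter=delimiter)
        return
    writer = csv.writer(dest, delimiter=delimiter, lineterminator="\n")
    writer.writerow(REQUIRED_COLUMNS)
    for r in records:
        writer.writerow(
            [
                r.study_id,
                r.first_author,
                r.year,
                r.country,
                r.ethnicity.value,
                r.cancer_type,
                r.control_source.value,
                r.cases.aa,
                r.cases.ag,
                r.cases.gg,
                r.controls.aa,
                r.controls.ag,
                r.controls.gg,
            ]
        )


def load_fixture() -> list[StudyRecord]:
    """Load the bundled 19-study MCP-1 −2518A/G table.

    The counts are transcribed verbatim from the published study table.  Two
    entries (qin2009hcc, qin2009npc) come from a single article reporting two
    cancers against the same control series, so their control counts are
    identical; that duplication is intentional and matches how the studies
    were pooled.
    """
    ref = resources.files("snpmeta").joinpath("data").joinpath(FIXTURE_RESOURCE)
    with ref.open("r", encoding="utf-8") as fh:
        return read_study_table(fh)


def subgroup_members(
    records: Sequence[StudyRecord],
) -> dict[str, dict[str, list[StudyRecord]]]:
    """Partition records by each of the four stratification factors.

    Returns a mapping ``factor -> level -> studies`` with deterministic level
    order (order of first appearance within each factor's enum ordering is
    not needed: levels follow the enum declaration order, and only levels
    that occur are present).
    """
    out: dict[str, dict[str, list[StudyRecord]]] = {
        "cancer_group": {},
        "ethnicity_group": {},
        "source_group": {},
        "size_class": {},
    }
    enum_order = {
        "cancer_group": [g.value for g in CancerGroup],
        "ethnicity_group": [e.value for e in Ethnicity],
        "source_group": [s.value for s in ControlSource],
        "size_class": [s.value for s in SizeClass],
    }
    for rec in records:
        labels = classify(rec)
        out["cancer_group"].setdefault(labels.cancer_group.value, []).append(rec)
        out["ethnicity_group"].setdefault(labels.ethnicity_group.value, []).append(rec)
        out["source_group"].setdefault(labels.source_group.value, []).append(rec)
        out["size_class"].setdefault(labels.size_class.value, []).append(rec)
    for factor, levels in out.items():
        out[factor] = {lvl: levels[lvl] for lvl in enum_order[factor] if lvl in levels}
    return out
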