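"""Ingestion and descriptive analysis of spontaneous adverse-event reports.

Two dialects are read: a simplified ``$``-delimited quarterly-file layout with
four linked tables (DEMO/DRUG/REAC/INDI, keyed by case id and case version),
and a flat single-table TSV where drugs, reactions and indications are packed
into delimited columns.  Both map onto the same in-memory
:class:`ReportSet`, so the rest of the pipeline never sees the file format.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import pandas as pd

from .errors import FormatError, UsageError

logger = logging.getLogger(__name__)

__all__ = [
    "ReportRecord",
    "ReportSet",
    "DEFAULT_AGE_BINS",
    "read_reports",
    "deduplicate",
    "select_cases",
    "descriptive_summary",
    "rank_drugs_and_indications",
    "normalize_term",
    "percent_table",
]

#: drug role codes: primary suspect, secondary suspect, concomitant, interacting
ROLE_CODES = ("PS", "SS", "C", "I")

#: age-group boundaries (inclusive upper bounds in years) and their labels
DEFAULT_AGE_BINS: tuple[tuple[str, float, float], ...] = (
    ("<=18", 0.0, 18.0),
    ("19-40", 19.0, 40.0),
    ("41-64", 41.0, 64.0),
    (">=65", 65.0, math.inf),
)


def normalize_term(term: str) -> str:
    """Case-, hyphen- and whitespace-insensitive preferred-term key."""
    return " ".join(term.replace("-", " ").lower().split())


@dataclass(frozen=True)
class ReportRecord:
    """One spontaneous report (a single version of a case)."""

    case_id: str
    case_version: int
    quarter: str  # YYYYQn
    sex: str  # Female / Male / Unknown
    age_years: float | None
    reporter: str  # Physician / Consumer / Others / Unknown
    country: str
    drugs: tuple[tuple[str, str], ...]  # (generic name, role code)
    reactions: tuple[str, ...]  # MedDRA preferred terms
    indications: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.case_version < 0:
            raise UsageError("case_version must be non-negative")
        if not self.drugs:
            raise UsageError(f"report {self.case_id} has no drugs")
        if not self.reactions:
            raise UsageError(f"report {self.case_id} has no reactions")

    def content_key(self) -> tuple:
        """Fields used to detect distinct cases describing the same patient."""
        return (
            self.sex,
            self.age_years,
            self.country,
            tuple(sorted(self.drugs)),
            tuple(sorted(self.reactions)),
            self.quarter,
        )


@dataclass
class ReportSet:
    """A collection of report records plus ingestion provenance."""

    records: tuple[ReportRecord, ...]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _read_delim(path: Path, sep: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, engine="python")
    except FileNotFoundError:
        raise FormatError(f"input file not found: {path}")


def _require_columns(df: pd.DataFrame, cols: list[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s) {missing} in {path}")


def _parse_age(raw: str) -> float | None:
    raw = raw.strip()
    if not raw or raw.lower() == "unknown":
        return None
    try:
        v = float(raw)
    except ValueError:
        return None
    return v if v >= 0 else None


def read_reports(path, dialect: str = "faers_ascii") -> ReportSet:
    """Read report tables into a :class:`ReportSet`.

    *path* is a directory holding ``DEMO.txt``/``DRUG.txt``/``REAC.txt``/
    ``INDI.txt`` for the ``faers_ascii`` dialect, or a single file for the
    ``tsv`` dialect.  Rows that cannot be assembled into a valid record are
    counted in ``provenance["n_rejected"]`` and logged, never silently
    dropped.
    """
    path = Path(path)
    if dialect == "faers_ascii":
        records, rejected = _read_faers_ascii(path)
    elif dialect == "tsv":
        records, rejected = _read_tsv(path)
    else:
        raise UsageError(f"unknown dialect {dialect!r}")
    if rejected:
        logger.warning("%d malformed report row(s) rejected while reading %s", rejected, path)
    return ReportSet(
        records=tuple(records),
        provenance={"source": str(path), "dialect": dialect, "n_rejected": rejected},
    )


def _read_faers_ascii(directory: Path) -> tuple[list[ReportRecord], int]:
    demo = _read_delim(directory / "DEMO.txt", "$")
    drug = _read_delim(directory / "DRUG.txt", "$")
    reac = _read_delim(directory / "REAC.txt", "$")
    indi = _read_delim(directory / "INDI.txt", "$")
    _require_columns(
        demo,
        ["caseid", "caseversion", "quarter", "sex", "age", "reporter", "country"],
        directory / "DEMO.txt",
    )
    _require_columns(drug, ["caseid", "caseversion", "drugname", "role_cod"], directory / "DRUG.txt")
    _require_columns(reac, ["caseid", "caseversion", "pt"], directory / "REAC.txt")
    _require_columns(indi, ["caseid", "caseversion", "indi_pt"], directory / "INDI.txt")

    def keyed(df: pd.DataFrame):
        groups: dict[tuple[str, str], list] = {}
        for row in df.itertuples(index=False):
            groups.setdefault((row.caseid, row.caseversion), []).append(row)
        return groups

    drugs_by_key = keyed(drug)
    reac_by_key = keyed(reac)
    indi_by_key = keyed(indi)

    records: list[ReportRecord] = []
    rejected = 0
    for row in demo.itertuples(index=False):
        key = (row.caseid, row.caseversion)
        try:
            version = int(row.caseversion)
            drugs = tuple(
                (r.drugname, r.role_cod if r.role_cod in ROLE_CODES else "C")
                for r in drugs_by_key.get(key, [])
            )
            reactions = tuple(r.pt for r in reac_by_key.get(key, []))
            indications = tuple(r.indi_pt for r in indi_by_key.get(key, [])) or ("Unknown",)
            records.append(
                ReportRecord(
                    case_id=row.caseid,
                    case_version=version,
                    quarter=row.quarter,
                    sex=row.sex or "Unknown",
                    age_years=_parse_age(row.age),
                    reporter=row.reporter or "Unknown",
                    country=row.country or "Unknown",
                    drugs=drugs,
                    reactions=reactions,
                    indications=indications,
                )
            )
        except (UsageError, ValueError) as exc:
            rejected += 1
            logger.info("rejected case %s v%s: %s", row.caseid, row.caseversion, exc)
    return records, rejected


def _read_tsv(path: Path) -> tuple[list[ReportRecord], int]:
    df = _read_delim(path, "\t")
    _require_columns(
        df,
        [
            "case_id",
            "case_version",
            "quarter",
            "sex",
            "age_years",
            "reporter",
            "country",
            "drugs",
            "reactions",
            "indications",
        ],
        path,
    )
    records: list[ReportRecord] = []
    rejected = 0
    for row in df.itertuples(index=False):
        try:
            drugs = tuple(
                (name.strip(), role.strip() if role.strip() in ROLE_CODES else "C")
                for item in row.drugs.split(";")
                if item.strip()
                for name, _, role in [item.partition(":")]
            )
            reactions = tuple(r.strip() for r in row.reactions.split(";") if r.strip())
            indications = tuple(
                i.strip() for i in row.indications.split(";") if i.strip()
            ) or ("Unknown",)
            records.append(
                ReportRecord(
                    case_id=row.case_id,
                    case_version=int(row.case_version),
                    quarter=row.quarter,
                    sex=row.sex or "Unknown",
                    age_years=_parse_age(row.age_years),
                    reporter=row.reporter or "Unknown",
                    country=row.country or "Unknown",
                    drugs=drugs,
                    reactions=reactions,
                    indications=indications,
                )
            )
        except (UsageError, ValueError) as exc:
            rejected += 1
            logger.info("rejected case %s: %s", row.case_id, exc)
    return records, rejected


def deduplicate(rs: ReportSet) -> tuple[ReportSet, dict]:
    """Remove duplicate reports in two passes.

    1. Keep only the highest ``case_version`` of each ``case_id`` (FAERS
       cases are resubmitted as new versions).
    2. Collapse distinct cases whose content (sex, age, country, drugs,
       reactions, quarter) is identical, keeping the first by case id.

    Returns the deduplicated set and the counts removed at each step.
    """
    latest: dict[str, ReportRecord] = {}
    for rec in rs:
        cur = latest.get(rec.case_id)
        if cur is None or rec.case_version > cur.case_version:
            latest[rec.case_id] = rec
    versions_removed = len(rs) - len(latest)

    seen: dict[tuple, ReportRecord] = {}
    for rec in sorted(latest.values(), key=lambda r: r.case_id):
        seen.setdefault(rec.content_key(), rec)
    identical_removed = len(latest) - len(seen)

    deduped = tuple(sorted(seen.values(), key=lambda r: r.case_id))
    counts = {"versions_removed": versions_removed, "identical_removed": identical_removed}
    return ReportSet(records=deduped, provenance={**rs.provenance, "dedup": counts}), counts


def select_cases(rs: ReportSet, event_terms) -> ReportSet:
    """Keep reports carrying at least one reaction in *event_terms*.

    Matching is exact at the preferred-term level but case-insensitive and
    hyphen/whitespace-normalized.  An empty term list is a usage error; zero
    matches is a valid empty result.
    """
    terms = {normalize_term(t) for t in event_terms}
    if not terms:
        raise UsageError("event_terms must contain at least one preferred term")
    kept = tuple(
        rec for rec in rs if any(normalize_term(r) in terms for r in rec.reactions)
    )
    return ReportSet(records=kept, provenance={**rs.provenance, "event_terms": sorted(terms)})


def _round_half_up(value: float, digits: int = 2) -> float:
    return float(Decimal(repr(value)).quantize(Decimal(f"1.{'0' * digits}"), rounding=ROUND_HALF_UP))


def percent_table(counts: dict[str, int], total: int | None = None) -> list[tuple[str, int, float]]:
    """(category, count, percent) rows with percents rounded half-up to 2 dp."""
    total = total if total is not None else sum(counts.values())
    return [(k, v, _round_half_up(100.0 * v / total)) for k, v in counts.items()]


def descriptive_summary(
    cs: ReportSet,
    age_bins: tuple[tuple[str, float, float], ...] = DEFAULT_AGE_BINS,
    top_countries: int = 3,
) -> pd.DataFrame:
    """Demographic summary table: counts and percents per variable.

    Variables follow the standard clinical-characteristics layout: sex, age
    group (with an Unknown row for unparseable ages), reporter type, reported
    country (top-*k* named plus Others and Unknown) and indication clarity.
    Percent = 100*count/total, rounded half-up to two decimals.
    """
    if len(cs) == 0:
        raise UsageError("cannot summarize an empty case set")
    total = len(cs)
    rows: list[tuple[str, str, int, float]] = []

    def add(variable: str, counts: dict[str, int]) -> None:
        for cat, cnt, pct in percent_table(counts, total):
            rows.append((variable, cat, cnt, pct))

    sex_counts = {"Female": 0, "Male": 0, "Unknown": 0}
    for rec in cs:
        sex_counts[rec.sex if rec.sex in sex_counts else "Unknown"] += 1
    add("Sex", sex_counts)

    age_counts = {label: 0 for label, _, _ in age_bins}
    age_counts["Unknown"] = 0
    for rec in cs:
        if rec.age_years is None:
            age_counts["Unknown"] += 1
            continue
        for label, lo, hi in age_bins:
            if lo <= rec.age_years <= hi:
                age_counts[label] += 1
                break
        else:
            age_counts["Unknown"] += 1
    add("Age", age_counts)

    rep_counts = {"Physician": 0, "Consumer": 0, "Others": 0, "Unknown": 0}
    for rec in cs:
        rep_counts[rec.reporter if rec.reporter in rep_counts else "Others"] += 1
    add("Reporter", rep_counts)

    raw_country: dict[str, int] = {}
    unknown_country = 0
    for rec in cs:
        name = rec.country.strip()
        if not name or name.lower() == "unknown":
            unknown_country += 1
        else:
            raw_country[name] = raw_country.get(name, 0) + 1
    top = sorted(raw_country.items(), key=lambda kv: (-kv[1], kv[0]))[:top_countries]
    country_counts = dict(top)
    country_counts["Others"] = sum(raw_country.values()) - sum(country_counts.values())
    country_counts["Unknown"] = unknown_country
    add("Reported countries", country_counts)

    clear = sum(
        1 for rec in cs if any(i.strip().lower() != "unknown" for i in rec.indications)
    )
    add("Indication", {"Clear indication": clear, "Unknown": total - clear})

    return pd.DataFrame(rows, columns=["variable", "category", "count", "percent"])


def rank_drugs_and_indications(cs: ReportSet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-drug and per-indication case counts, descending, ties alphabetical.

    A case contributes at most once per drug (and per indication) no matter
    how many times the name repeats within the report.
    """
    drug_counts: dict[str, int] = {}
    indi_counts: dict[str, int] = {}
    for rec in cs:
        for name in {g.strip() for g, _ in rec.drugs}:
            drug_counts[name] = drug_counts.get(name, 0) + 1
        for name in {i.strip() for i in rec.indications}:
            indi_counts[name] = indi_counts.get(name, 0) + 1

    def ranked(counts: dict[str, int], label: str) -> pd.DataFrame:
        items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(items, columns=[label, "cases"])

    return ranked(drug_counts, "drug"), ranked(indi_counts, "indication")
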