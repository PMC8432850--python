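"""AIS lookup and Injury Severity Score computation.

The Injury Severity Score divides the body into six regions — 1 head/neck,
2 face, 3 thorax, 4 abdomen (incl. pelvic contents), 5 extremities (incl.
pelvic girdle), 6 external — takes the highest Abbreviated Injury Scale
severity (1 minor … 6 maximal) recorded in each region, and sums the squares
of the three highest regional values.  The range is 0–75 and an ISS >= 16
defines severe polytrauma.

Severities come from a GEM-style lookup table keyed on dotless ICD-10-CM
prefixes.  Historical crosswalks route ICD-10-CM through ICD-9-CM, so one
diagnosis can map to several candidate severities; that multiplicity is kept
here as a severity *set* per table row, resolved at lookup time by the
GEMmax (take the highest candidate) or GEMmin (take the lowest) strategy.
Severity 9 means "unknown" and never enters the score: it raises a flag and
is set aside.  Rows keyed on a full-length prefix (seventh character
included) take precedence over stem rows by longest-prefix matching, which
is how consciousness-duration detail can raise a subdural haematoma from
its default severity 4 to 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .agreement_stats import iss_group
from .icd_codes import CMCode

__all__ = [
    "REGIONS",
    "UNKNOWN_SEVERITY",
    "AISEntry",
    "AISTable",
    "RegionProfile",
    "ISSResult",
    "load_ais_table",
    "lookup_ais",
    "region_profile",
    "compute_iss",
    "score_cohort",
]

#: region index -> name, in fixed report order
REGIONS = {
    1: "head_neck",
    2: "face",
    3: "thorax",
    4: "abdomen",
    5: "extremities",
    6: "external",
}

UNKNOWN_SEVERITY = 9
_VALID_SEVERITIES = frozenset({1, 2, 3, 4, 5, 6, UNKNOWN_SEVERITY})


class AISTableError(ValueError):
    """Raised when an AIS lookup table fails validation."""


@dataclass(frozen=True)
class AISEntry:
    cm_prefix: str               # dotless CM prefix
    severities: frozenset[int]   # candidate AIS values, subset of {1..6, 9}
    region: int                  # ISS body region 1-6


@dataclass
class AISTable:
    entries: dict[str, AISEntry] = field(default_factory=dict)

    def match(self, dotless_code: str) -> AISEntry | None:
        best = None
        for prefix, entry in self.entries.items():
            if dotless_code.startswith(prefix) and (
                best is None or len(prefix) > len(best.cm_prefix)
            ):
                best = entry
        return best

    def __len__(self) -> int:
        return len(self.entries)


def load_ais_table(path: str | Path) -> AISTable:
    """Load an AIS lookup TSV (columns cm_prefix, severities, region).

    ``severities`` is a comma-joined set from {1..6, 9}; region must be 1–6;
    duplicate prefixes are ambiguous and rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("cm_prefix", "severities", "region") if c not in df.columns]
    if missing:
        raise AISTableError(f"AIS table {path}: missing columns {missing}")
    entries: dict[str, AISEntry] = {}
    for _, row in df.iterrows():
        prefix = row["cm_prefix"].replace(".", "").strip().upper()
        try:
            sevs = frozenset(int(s) for s in row["severities"].split(",") if s.strip())
            region = int(row["region"])
        except ValueError as exc:
            raise AISTableError(f"AIS table {path}: bad row {prefix!r}: {exc}") from exc
        if not prefix:
            raise AISTableError(f"AIS table {path}: empty cm_prefix")
        if not sevs:
            raise AISTableError(f"AIS table {path}: empty severity set for {prefix!r}")
        if not sevs <= _VALID_SEVERITIES:
            raise AISTableError(
                f"AIS table {path}: severities {sorted(sevs)} for {prefix!r} "
                "outside {1..6, 9}"
            )
        if region not in REGIONS:
            raise AISTableError(
                f"AIS table {path}: region {region} for {prefix!r} outside 1-6"
            )
        if prefix in entries:
            raise AISTableError(f"AIS table {path}: duplicate prefix {prefix!r}")
        entries[prefix] = AISEntry(prefix, sevs, region)
    return AISTable(entries)


def lookup_ais(
    code: CMCode | str, table: AISTable, mode: str = "gemmax"
) -> tuple[int, int] | None:
    """Resolve a canonical CM code to ``(severity, region)`` or None (miss).

    Longest matching prefix wins.  Among the row's candidate severities,
    GEMmax takes the highest and GEMmin the lowest; the unknown marker 9 is
    only returned when it is the row's sole candidate.
    """
    if mode not in ("gemmax", "gemmin"):
        raise ValueError(f"mode must be 'gemmax' or 'gemmin', got {mode!r}")
    key = code.dotless if isinstance(code, CMCode) else str(code).replace(".", "").upper()
    entry = table.match(key)
    if entry is None:
        return None
    known = entry.severities - {UNKNOWN_SEVERITY}
    if not known:
        return UNKNOWN_SEVERITY, entry.region
    severity = max(known) if mode == "gemmax" else min(known)
    return severity, entry.region


@dataclass(frozen=True)
class RegionProfile:
    """Per-region maximum AIS; 0 = no injury recorded in that region."""

    max_ais: tuple[int, int, int, int, int, int]
    unknown_severity_present: bool = False


def region_profile(hits: list[tuple[int, int]]) -> RegionProfile:
    """Reduce ``(severity, region)`` hits to the per-region maxima.

    Severity-9 hits never enter the maxima: they only set the
    unknown-severity flag, regardless of the order hits arrive in.
    """
    maxima = [0] * 6
    unknown = False
    for severity, region in hits:
        if region not in REGIONS:
            raise ValueError(f"region {region} outside 1-6")
        if severity == UNKNOWN_SEVERITY:
            unknown = True
            continue
        if not 1 <= severity <= 6:
            raise ValueError(f"severity {severity} outside 1-6/9")
        maxima[region - 1] = max(maxima[region - 1], severity)
    return RegionProfile(tuple(maxima), unknown)


@dataclass(frozen=True)
class ISSResult:
    iss: int
    contributing_regions: tuple[int, ...]
    group: int
    flags: frozenset[str] = frozenset()


def compute_iss(profile: RegionProfile, cap_on_ais6: bool = True) -> ISSResult:
    """Sum of squares of the three highest per-region maxima.

    With ``cap_on_ais6`` (the standard convention, on by default) any
    region at AIS 6 sets the ISS straight to 75 with flag ``ais6_cap``.
    ``contributing_regions`` is the lexicographically smallest region subset
    achieving the score, for reproducible reporting.
    """
    values = profile.max_ais
    # stable sort on (-value, region) -> smallest region indices win ties
    order = sorted(range(6), key=lambda i: (-values[i], i))
    top = [i for i in order[:3] if values[i] > 0]
    iss = sum(values[i] ** 2 for i in top)
    flags = set()
    if profile.unknown_severity_present:
        flags.add("unknown_severity_present")
    if cap_on_ais6 and any(v == 6 for v in values):
        iss = 75
        flags.add("ais6_cap")
    return ISSResult(iss, tuple(sorted(r + 1 for r in top)), iss_group(iss),
                     frozenset(flags))


def score_cohort(
    cm_table: pd.DataFrame,
    ais_table: AISTable,
    mode: str = "gemmax",
    cap_on_ais6: bool = True,
) -> pd.DataFrame:
    """Score a converted cohort: one row per patient with the six regional
    maxima, the ISS, its group, and any flags.

    Patients none of whose codes match the AIS table get a missing ISS and
    the flag ``no_mappable_injury``.
    """
    for col in ("patient_id", "cm_code"):
        if col not in cm_table.columns:
            raise AISTableError(f"scoring input: missing column {col!r}")
    rows = []
    for pid, grp in cm_table.groupby("patient_id", sort=True):
        hits, misses = [], 0
        for code in grp["cm_code"]:
            code = str(code).strip()
            hit = lookup_ais(code, ais_table, mode) if code else None
            if hit is None:
                misses += 1
            else:
                hits.append(hit)
        profile = region_profile(hits)
        row: dict = {"patient_id": pid}
        for idx, name in REGIONS.items():
            row[f"ais_{name}"] = profile.max_ais[idx - 1]
        if hits:
            result = compute_iss(profile, cap_on_ais6)
            flags = set(result.flags)
            if misses:
                flags.add("unmapped_codes")
            row.update(iss=result.iss, iss_group=result.group,
                       flags=";".join(sorted(flags)))
        else:
            row.update(iss=pd.NA, iss_group=pd.NA, flags="no_mappable_injury")
        rows.append(row)
    columns = (
        ["patient_id"]
        + [f"ais_{name}" for name in REGIONS.values()]
        + ["iss", "iss_group", "flags"]
    )
    return pd.DataFrame(rows, columns=columns)
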