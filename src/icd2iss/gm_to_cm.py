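"""Transform ICD-10-GM code lists into canonical ICD-10-CM codes.

The German and US modifications of ICD-10 diverge in two ways that matter
for injury scoring.  First, some GM subcategories mean something different
in CM (GM S22.03 is a fracture of the fifth/sixth thoracic vertebra, CM
S22.03 a fracture of the third), so a reviewed substitution table re-codes
the GM stem onto the CM stem that names the same injury.  Second, CM packs
extra clinical detail into a subcategory-specific seventh character, detail
that GM carries — when it carries it at all — in separate "!"-suffixed
secondary codes (the S06.7-! unconsciousness-duration family).  The
converter therefore works per patient: detail codes are lifted out of the
injury list as annotations, each remaining injury code is re-coded by
longest-prefix substitution, the seventh character is chosen from a policy
table (conditional rows consult the annotations, a fallback row covers the
rest), and the result is padded to the canonical eight-character form with
the configured encounter character (default 'A', initial encounter).

All three tables (recode rules, seventh-character policies, detail-code
interpretations) are data, not code: the shipped fixtures cover the worked
examples, and a full review table is a drop-in replacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .icd_codes import (
    PLACEHOLDER,
    CMCode,
    GMCode,
    ICDParseError,
    in_injury_chapter,
    normalize_cm,
    parse_gm,
)

__all__ = [
    "TableLoadError",
    "RecodeRule",
    "RecodeRuleSet",
    "SeventhCharPolicy",
    "PolicySet",
    "DetailMap",
    "DetailAnnotation",
    "ConversionResult",
    "load_recode_rules",
    "load_policies",
    "load_detail_map",
    "apply_recode",
    "collect_details",
    "to_cm",
    "convert_cohort",
]

log = logging.getLogger(__name__)


class TableLoadError(ValueError):
    """Raised when a crosswalk/policy table fails validation on load."""


def _read_tsv(path: str | Path, required: list[str], label: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableLoadError(f"{label} {path}: missing columns {missing}")
    return df


def _longest_prefix(key: str, candidates) -> str | None:
    best = None
    for pat in candidates:
        if key.startswith(pat) and (best is None or len(pat) > len(best)):
            best = pat
    return best


@dataclass(frozen=True)
class RecodeRule:
    gm_pattern: str  # dotless GM prefix
    cm_target: str   # dotless CM replacement stem
    note: str = ""


@dataclass
class RecodeRuleSet:
    """Validated set of stem substitutions with longest-prefix matching."""

    rules: dict[str, RecodeRule] = field(default_factory=dict)

    def match(self, significant: str) -> RecodeRule | None:
        pat = _longest_prefix(significant, self.rules)
        return self.rules[pat] if pat is not None else None

    def __len__(self) -> int:
        return len(self.rules)


def load_recode_rules(path: str | Path) -> RecodeRuleSet:
    """Load a recode-rules TSV (columns gm_pattern, cm_target, note).

    Patterns and targets are stored dotless and upper-case.  A duplicated
    gm_pattern is ambiguous and rejected.
    """
    df = _read_tsv(path, ["gm_pattern", "cm_target", "note"], "recode rules")
    rules: dict[str, RecodeRule] = {}
    for _, row in df.iterrows():
        pat = row["gm_pattern"].replace(".", "").strip().upper()
        tgt = row["cm_target"].replace(".", "").strip().upper()
        if not pat or not tgt:
            raise TableLoadError(f"recode rules {path}: empty pattern/target")
        if not pat[0].isalpha() or not tgt[0].isalpha():
            raise TableLoadError(
                f"recode rules {path}: malformed codes {pat!r} -> {tgt!r}"
            )
        if pat in rules:
            raise TableLoadError(f"recode rules {path}: duplicate gm_pattern {pat!r}")
        rules[pat] = RecodeRule(pat, tgt, row["note"])
    return RecodeRuleSet(rules)


@dataclass(frozen=True)
class SeventhCharPolicy:
    cm_subcategory: str  # dotless CM stem
    value: str           # the seventh character to emit
    condition: str = ""  # detail-annotation tag; empty = unconditional fallback


@dataclass
class PolicySet:
    """Seventh-character policies, one fallback per stem plus conditionals."""

    fallback: dict[str, SeventhCharPolicy] = field(default_factory=dict)
    conditional: dict[str, list[SeventhCharPolicy]] = field(default_factory=dict)

    def lookup(self, stem: str, tags: frozenset[str] | set[str]) -> str | None:
        """Seventh character for ``stem`` given annotation tags, else None.

        Longest-prefix over the policy stems; conditional rows are tried in
        file order before the fallback.
        """
        keys = set(self.fallback) | set(self.conditional)
        pat = _longest_prefix(stem, keys)
        if pat is None:
            return None
        for pol in self.conditional.get(pat, []):
            if pol.condition in tags:
                return pol.value
        fb = self.fallback.get(pat)
        return fb.value if fb is not None else None


def load_policies(path: str | Path) -> PolicySet:
    """Load seventh-character policies (columns cm_subcategory, condition,
    value); exactly one unconditional fallback row per subcategory."""
    df = _read_tsv(path, ["cm_subcategory", "condition", "value"], "policies")
    ps = PolicySet()
    for _, row in df.iterrows():
        stem = row["cm_subcategory"].replace(".", "").strip().upper()
        value = row["value"].strip().upper()
        cond = row["condition"].strip()
        if not stem or len(value) != 1:
            raise TableLoadError(
                f"policies {path}: bad row ({stem!r}, {cond!r}, {value!r})"
            )
        pol = SeventhCharPolicy(stem, value, cond)
        if cond:
            ps.conditional.setdefault(stem, []).append(pol)
        else:
            if stem in ps.fallback:
                raise TableLoadError(
                    f"policies {path}: duplicate fallback for {stem!r}"
                )
            ps.fallback[stem] = pol
    for stem in ps.conditional:
        if stem not in ps.fallback:
            raise TableLoadError(
                f"policies {path}: conditional rows for {stem!r} without a fallback"
            )
    return ps


@dataclass
class DetailMap:
    """Interpretation tags for "!"-suffixed GM detail codes."""

    tags: dict[str, str] = field(default_factory=dict)

    def interpret(self, code: GMCode) -> str:
        pat = _longest_prefix(code.significant, self.tags)
        return self.tags[pat] if pat is not None else "unknown"


def load_detail_map(path: str | Path) -> DetailMap:
    df = _read_tsv(path, ["gm_pattern", "tag"], "detail codes")
    tags: dict[str, str] = {}
    for _, row in df.iterrows():
        pat = row["gm_pattern"].replace(".", "").strip().upper()
        if pat in tags:
            raise TableLoadError(f"detail codes {path}: duplicate pattern {pat!r}")
        tags[pat] = row["tag"].strip()
    return DetailMap(tags)


@dataclass(frozen=True)
class DetailAnnotation:
    patient_id: str
    detail_code: GMCode
    interpretation: str


def apply_recode(code: GMCode, rules: RecodeRuleSet) -> GMCode:
    """Substitute the longest matching gm_pattern prefix, preserving any
    trailing characters; codes with no matching rule pass through."""
    rule = rules.match(code.significant)
    if rule is None:
        return code
    new_sig = rule.cm_target + code.significant[len(rule.gm_pattern):]
    log.debug("recode %s -> %s (%s)", code.significant, new_sig, rule.note)
    return replace(code, category=new_sig[:3], subclass=new_sig[3:])


def collect_details(
    codes: list[GMCode], detail_map: DetailMap, patient_id: str = ""
) -> tuple[list[GMCode], list[DetailAnnotation]]:
    """Split one patient's code list into injury codes and detail annotations."""
    injuries, annotations = [], []
    for code in codes:
        if code.is_detail:
            annotations.append(
                DetailAnnotation(patient_id, code, detail_map.interpret(code))
            )
        else:
            injuries.append(code)
    return injuries, annotations


@dataclass(frozen=True)
class ConversionResult:
    cm: CMCode | None
    rules_fired: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()


def to_cm(
    code: GMCode,
    annotations: list[DetailAnnotation],
    rules: RecodeRuleSet,
    policies: PolicySet,
    encounter_default: str = "A",
) -> ConversionResult:
    """Convert one injury code: recode, choose the seventh character from
    the policy table (conditionals consult the annotations), normalise.

    Codes outside the S00–T88 injury chapter pass through unmapped with a
    warning so mixed discharge exports do not abort a run; a stem with no
    policy row gets the placeholder 'X' with a warning.
    """
    fired: list[str] = []
    warnings: list[str] = []
    rule = rules.match(code.significant)
    recoded = apply_recode(code, rules)
    if rule is not None:
        fired.append(f"{rule.gm_pattern}->{rule.cm_target}")
    if not in_injury_chapter(recoded.category):
        warnings.append("out_of_profile")
        log.warning("code %s outside S00-T88; passed through unmapped", code.render())
        return ConversionResult(None, tuple(fired), tuple(warnings))
    tags = {a.interpretation for a in annotations}
    seventh = policies.lookup(recoded.significant, tags)
    if seventh is None:
        seventh = PLACEHOLDER
        warnings.append("no_seventh_char_policy")
        log.warning("no seventh-character policy for %s; using 'X'",
                    recoded.significant)
    else:
        fired.append(f"seventh:{recoded.significant}={seventh}")
    partial = CMCode(
        category=recoded.category, subclass=recoded.subclass, raw=code.raw
    )
    cm = normalize_cm(partial, encounter_default=encounter_default,
                      seventh_default=seventh)
    return ConversionResult(cm, tuple(fired), tuple(warnings))


def convert_cohort(
    records: pd.DataFrame,
    rules: RecodeRuleSet,
    policies: PolicySet,
    detail_map: DetailMap,
    encounter_default: str = "A",
    code_column: str = "icd_code",
    id_column: str = "patient_id",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convert a whole cohort (one row per patient-diagnosis).

    Returns ``(converted, errors)``: one converted row per non-detail input
    code (order: patient_id, then input order) with columns patient_id,
    gm_code, cm_code, rules_fired; per-row parse failures are channelled
    into the error frame instead of aborting the run.
    """
    for col in (id_column, code_column):
        if col not in records.columns:
            raise TableLoadError(f"cohort input: missing column {col!r}")
    out_rows, err_rows = [], []
    by_patient = records.groupby(id_column, sort=True)
    for pid, grp in by_patient:
        parsed: list[GMCode] = []
        for _, row in grp.iterrows():
            try:
                parsed.append(parse_gm(row[code_column]))
            except ICDParseError as exc:
                err_rows.append(
                    {"patient_id": pid, "icd_code": row[code_column],
                     "error": str(exc)}
                )
        injuries, annotations = collect_details(parsed, detail_map, str(pid))
        for code in injuries:
            res = to_cm(code, annotations, rules, policies, encounter_default)
            out_rows.append({
                "patient_id": pid,
                "gm_code": code.render(),
                "cm_code": res.cm.canonical if res.cm is not None else "",
                "rules_fired": ";".join(res.rules_fired + res.warnings),
            })
    converted = pd.DataFrame(
        out_rows, columns=["patient_id", "gm_code", "cm_code", "rules_fired"]
    )
    errors = pd.DataFrame(err_rows, columns=["patient_id", "icd_code", "error"])
    return converted, errors
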