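"""Parsing and normalisation of ICD-10-GM and ICD-10-CM diagnosis codes.

ICD-10-GM (the German modification, also used in Switzerland) writes a
diagnosis in at most six significant characters: a category of one letter and
two digits ("S22"), then up to three further digits after the dot
("S22.03").  Two export conventions matter for trauma data: a trailing "!"
marks an optional secondary *detail* code (the "S06.7-!" unconsciousness
family), and a trailing "-" marks an incompletely specified stem.

ICD-10-CM (the US clinical modification) extends the same stem to an
eight-character dotted form, e.g. "S06.5X0A": the subclassification occupies
two slots after the dot, right-padded with the placeholder 'X'; next comes a
subcategory-specific *seventh character* carrying extra clinical detail
('0', '1', '2', 'X', ...); the final *encounter* character is 'A' (initial
encounter), 'D' (subsequent encounter) or 'S' (sequela) and is severity
neutral.  Dots are presentation only — every comparison in this package is
done on the dotless significant characters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

__all__ = [
    "ICDParseError",
    "GMCode",
    "CMCode",
    "parse_gm",
    "parse_cm",
    "normalize_cm",
    "in_injury_chapter",
    "ENCOUNTER_CHARS",
    "PLACEHOLDER",
]

PLACEHOLDER = "X"
ENCOUNTER_CHARS = frozenset("ADS")

_GM_BODY_RE = re.compile(r"^([A-Z]\d{2})(\d{0,3})$")
_CM_CAT_RE = re.compile(r"^[A-Z]\d{2}$")


class ICDParseError(ValueError):
    """Raised when a code string cannot be interpreted; names the input."""


@dataclass(frozen=True)
class GMCode:
    """A parsed ICD-10-GM diagnosis code.

    ``category`` is the letter+digit+digit stem, ``subclass`` the 0–3 digits
    after the dot.  ``is_detail`` marks "!"-suffixed secondary detail codes,
    ``incomplete`` a stripped trailing "-" (incomplete-code marker).
    """

    category: str
    subclass: str
    is_detail: bool = False
    incomplete: bool = False
    raw: str = ""

    @property
    def significant(self) -> str:
        """Dotless significant characters (category + subclass)."""
        return self.category + self.subclass

    def render(self) -> str:
        out = self.category
        if self.subclass:
            out += "." + self.subclass
        if self.incomplete:
            out += "-"
        if self.is_detail:
            out += "!"
        return out


@dataclass(frozen=True)
class CMCode:
    """A parsed ICD-10-CM code; ``seventh``/``encounter`` are None when unset.

    A complete code renders to the canonical dotted eight-character form
    CCC.SSVE — category, subclass padded to two slots with 'X', seventh
    character, encounter character.
    """

    category: str
    subclass: str
    seventh: str | None = None
    encounter: str | None = None
    raw: str = ""

    @property
    def is_complete(self) -> bool:
        return self.seventh is not None and self.encounter is not None

    @property
    def stem(self) -> str:
        """Dotless category + subclass, the key for rule/policy tables."""
        return self.category + self.subclass

    @property
    def canonical(self) -> str:
        """Canonical dotted rendering (eight characters when complete)."""
        if not self.is_complete:
            raise ValueError(
                f"code {self.render()!r} is not normalised; call normalize_cm first"
            )
        return (
            f"{self.category}.{self.subclass.ljust(2, PLACEHOLDER)}"
            f"{self.seventh}{self.encounter}"
        )

    @property
    def dotless(self) -> str:
        """Canonical form without the presentation dot (lookup key)."""
        return self.canonical.replace(".", "")

    def render(self) -> str:
        if self.is_complete:
            return self.canonical
        out = self.category
        if self.subclass:
            out += "." + self.subclass
        if self.seventh is not None:
            out += self.seventh
        return out


def in_injury_chapter(category: str) -> bool:
    """True if the category lies in the S00–T88 injury chapter."""
    return bool(_CM_CAT_RE.match(category)) and (
        category[0] == "S" or (category[0] == "T" and category[1:] <= "88")
    )


def parse_gm(raw: str) -> GMCode:
    """Parse an ICD-10-GM code string into a :class:`GMCode`.

    Case-insensitive; stored upper-case.  A trailing "!" sets ``is_detail``,
    a trailing "-" (before the "!" if both present) sets ``incomplete`` and
    is stripped rather than rejected, since routine GM exports contain it.
    """
    s = (raw or "").strip().upper()
    if not s:
        raise ICDParseError("empty ICD-10-GM code string")
    is_detail = s.endswith("!")
    body = s[:-1] if is_detail else s
    incomplete = body.endswith("-")
    body = body.rstrip("-")
    m = _GM_BODY_RE.match(body.replace(".", ""))
    if not m:
        raise ICDParseError(f"malformed ICD-10-GM code: {raw!r}")
    category, subclass = m.group(1), m.group(2)
    return GMCode(
        category=category,
        subclass=subclass,
        is_detail=is_detail,
        incomplete=incomplete,
        raw=raw,
    )


def _split_cm_tail(tail: str, raw: str) -> tuple[str, str | None, str | None]:
    """Split the dotless characters after the category into
    (subclass, seventh, encounter).

    The placeholder 'X' in the second subclass slot marks padding, which is
    how the four-character tail of "S06.5X5A" is read back as subclass "5",
    seventh '5', encounter 'A' while "S22.05XA" keeps subclass "05".
    """
    if len(tail) <= 2:
        return tail, None, None
    if len(tail) == 3:
        if tail[1] == PLACEHOLDER:
            sub = "" if tail[0] == PLACEHOLDER else tail[0]
            return sub, tail[2], None
        return tail, None, None
    if len(tail) == 4:
        if tail[1] == PLACEHOLDER:
            sub = "" if tail[0] == PLACEHOLDER else tail[0]
        else:
            sub = tail[:2]
        seventh, encounter = tail[2], tail[3]
        if encounter not in ENCOUNTER_CHARS:
            raise ICDParseError(
                f"malformed ICD-10-CM code {raw!r}: encounter character "
                f"{encounter!r} not in {{'A','D','S'}}"
            )
        return sub, seventh, encounter
    raise ICDParseError(f"malformed ICD-10-CM code (too long): {raw!r}")


def parse_cm(raw: str, require_injury: bool = True) -> CMCode:
    """Parse an ICD-10-CM code string (dotted or dotless, possibly partial).

    With ``require_injury`` (the default converter profile) the category must
    fall in the S00–T88 injury chapter; other chapters are rejected here and
    handled as pass-through warnings at the cohort level.
    """
    s = (raw or "").strip().upper().replace(".", "")
    if len(s) < 3:
        raise ICDParseError(f"malformed ICD-10-CM code: {raw!r}")
    category, tail = s[:3], s[3:]
    if not _CM_CAT_RE.match(category):
        raise ICDParseError(f"malformed ICD-10-CM code: {raw!r}")
    if require_injury and not in_injury_chapter(category):
        raise ICDParseError(
            f"ICD-10-CM code {raw!r} outside the S00-T88 injury chapter"
        )
    subclass, seventh, encounter = _split_cm_tail(tail, raw)
    return CMCode(
        category=category,
        subclass=subclass,
        seventh=seventh,
        encounter=encounter,
        raw=raw,
    )


def normalize_cm(
    code: CMCode,
    encounter_default: str = "A",
    seventh_default: str = PLACEHOLDER,
) -> CMCode:
    """Fill the seventh/encounter characters and return a canonical code.

    Missing subclass slots are padded with 'X' at render time; a missing
    seventh character takes ``seventh_default`` (the converter passes the
    policy-table value here) and a missing encounter takes
    ``encounter_default`` ('A' = initial encounter unless overridden).
    Idempotent: normalising a complete code changes nothing.
    """
    if encounter_default not in ENCOUNTER_CHARS:
        raise ValueError(f"encounter default {encounter_default!r} not in A/D/S")
    seventh = code.seventh if code.seventh is not None else seventh_default
    encounter = code.encounter if code.encounter is not None else encounter_default
    return replace(code, seventh=seventh, encounter=encounter)
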