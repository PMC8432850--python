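"""Fixture tables and synthetic trauma cohorts for download-free testing.

Two generators cover the two validation surfaces.  ``generate_cohort``
builds patients with a known ground-truth region profile and emits GM codes
from a small curated catalogue (~30 codes spanning all six body regions and
severities 1–5, including the subdural-haematoma / unconsciousness detail
pair), so the convert→score pipeline can be checked for exact ISS recovery.
``generate_paired_scores`` builds manual/automatic ISS pairs under a
controllable disagreement model, emulating the group structure of a mixed
trauma-centre cohort (a little over half the patients below ISS 16).

The catalogue is *closed* under the shipped fixture tables: every code the
generator can emit has a conversion path and an AIS row, and every
catalogue severity set is a singleton, so ground-truth recovery is exact.
Realism beyond the region/severity structure is deliberately out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import ais_iss, gm_to_cm
from .agreement_stats import GROUP_BOUNDS, GROUP_LABELS, CrossTab, iss_group

__all__ = [
    "fixture_path",
    "default_rules",
    "default_policies",
    "default_detail_map",
    "default_ais_table",
    "load_catalogue",
    "GeneratorConfig",
    "SyntheticPatient",
    "generate_cohort",
    "cohort_frame",
    "truth_frame",
    "generate_paired_scores",
    "table3_counts",
    "table3_pairs",
]

#: representative ISS per group (each group's lower bound); only the group
#: identity is meaningful for group-level reconstructions
GROUP_REPRESENTATIVE = (0, 9, 16, 25, 41, 50)

#: manual-group mix of the validation cohort (219, 122, 155, 114, 13, 17
#: patients of 640 in groups 1-6)
DEFAULT_GROUP_WEIGHTS = (
    219 / 640, 122 / 640, 155 / 640, 114 / 640, 13 / 640, 17 / 640,
)

#: severity multisets realising each ISS group (sum of squares of the top
#: three lands inside the group's bounds)
_GROUP_TEMPLATES: dict[int, tuple[tuple[int, ...], ...]] = {
    1: ((1,), (2,), (1, 1), (2, 1), (2, 2), (2, 1, 1)),
    2: ((3,), (3, 1), (3, 2), (2, 2, 2), (3, 1, 1), (3, 2, 1)),
    3: ((4,), (4, 1), (3, 3), (4, 2), (3, 3, 1), (4, 2, 1), (3, 3, 2), (4, 2, 2)),
    4: ((5,), (4, 3), (4, 3, 1), (5, 2), (4, 4), (5, 3), (4, 3, 2), (4, 4, 1),
        (5, 2, 2), (5, 3, 1), (4, 4, 2), (5, 3, 2), (4, 3, 3)),
    5: ((5, 4), (4, 4, 3), (5, 4, 1), (5, 3, 3), (5, 4, 2), (4, 4, 4)),
    6: ((5, 5), (5, 4, 3), (5, 5, 1), (5, 5, 2), (5, 5, 3), (5, 5, 4), (5, 5, 5)),
}


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture table."""
    return Path(resources.files("icd2iss").joinpath("fixtures", name))


def default_rules() -> gm_to_cm.RecodeRuleSet:
    return gm_to_cm.load_recode_rules(fixture_path("recode_rules.tsv"))


def default_policies() -> gm_to_cm.PolicySet:
    return gm_to_cm.load_policies(fixture_path("seventh_char_policies.tsv"))


def default_detail_map() -> gm_to_cm.DetailMap:
    return gm_to_cm.load_detail_map(fixture_path("detail_codes.tsv"))


def default_ais_table() -> ais_iss.AISTable:
    return ais_iss.load_ais_table(fixture_path("ais_table.tsv"))


def load_catalogue() -> pd.DataFrame:
    """The generator's code catalogue: columns gm_codes ("|"-joined when an
    injury needs a detail code), region, severity."""
    df = pd.read_csv(fixture_path("code_catalogue.tsv"), sep="\t", dtype=str)
    df["region"] = df["region"].astype(int)
    df["severity"] = df["severity"].astype(int)
    return df


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of both synthetic generators.

    ``group_weights`` is the target mix over the six ISS groups (defaults
    to the 640-patient validation cohort's manual split).  The paired-score
    disagreement model shifts the automatic score of a random
    ``shift_prob`` fraction of patients by rounded Gaussian noise of SD
    ``shift_sd`` ISS points, clamped to [0, 75]; the defaults are
    calibrated once so the group cross-tabulation of 640 pairs lands near
    linear kappa 0.47.  ``duplicate_code_prob`` re-emits an injury code to
    exercise per-region maximum semantics.
    """

    n_patients: int = 640
    seed: int = 0
    group_weights: tuple[float, ...] = DEFAULT_GROUP_WEIGHTS
    duplicate_code_prob: float = 0.1
    shift_prob: float = 0.9
    shift_sd: float = 16.0

    def __post_init__(self) -> None:
        w = np.asarray(self.group_weights, dtype=float)
        if w.size != 6 or (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError("group_weights must be 6 non-negative values summing to 1")
        for name in ("duplicate_code_prob", "shift_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "GeneratorConfig":
        with open(path) as fh:
            data = json.load(fh)
        data.update(overrides)
        if "group_weights" in data:
            data["group_weights"] = tuple(data["group_weights"])
        return cls(**data)


@dataclass(frozen=True)
class SyntheticPatient:
    patient_id: str
    gm_codes: tuple[str, ...]
    profile: tuple[int, int, int, int, int, int]  # true per-region max AIS
    true_iss: int
    group: int


def _severity_support(catalogue: pd.DataFrame) -> dict[int, list[int]]:
    out: dict[int, set[int]] = {}
    for _, row in catalogue.iterrows():
        out.setdefault(row["severity"], set()).add(row["region"])
    return {s: sorted(r) for s, r in out.items()}


def generate_cohort(config: GeneratorConfig) -> list[SyntheticPatient]:
    """Draw a cohort of patients with known region profiles.

    Per patient: sample the target ISS group from the configured mix, pick
    a severity template realising that group, assign each severity to a
    distinct random body region that has a catalogue code of that severity,
    and emit the corresponding GM codes (shuffled, possibly with
    duplicates).  Deterministic under the seed.
    """
    rng = np.random.default_rng(config.seed)
    catalogue = load_catalogue()
    support = _severity_support(catalogue)
    by_region_sev: dict[tuple[int, int], list[str]] = {}
    for _, row in catalogue.iterrows():
        key = (int(row["region"]), int(row["severity"]))
        by_region_sev.setdefault(key, []).append(row["gm_codes"])
    patients: list[SyntheticPatient] = []
    for i in range(config.n_patients):
        group = int(rng.choice(6, p=config.group_weights)) + 1
        templates = _GROUP_TEMPLATES[group]
        template = templates[int(rng.integers(len(templates)))]
        profile = [0] * 6
        codes: list[str] = []
        used: set[int] = set()
        for severity in sorted(template, reverse=True):
            options = [r for r in support[severity] if r not in used]
            region = int(options[int(rng.integers(len(options)))])
            used.add(region)
            profile[region - 1] = severity
            entry_codes = by_region_sev[(region, severity)]
            entry = entry_codes[int(rng.integers(len(entry_codes)))]
            codes.extend(entry.split("|"))
            if rng.random() < config.duplicate_code_prob:
                codes.append(entry.split("|")[0])
        order = rng.permutation(len(codes))
        codes = [codes[k] for k in order]
        result = ais_iss.compute_iss(
            ais_iss.RegionProfile(tuple(profile)), cap_on_ais6=True
        )
        assert result.group == group, "template outside its target group"
        patients.append(SyntheticPatient(
            patient_id=f"P{i + 1:05d}",
            gm_codes=tuple(codes),
            profile=tuple(profile),
            true_iss=result.iss,
            group=group,
        ))
    return patients


def cohort_frame(patients: list[SyntheticPatient]) -> pd.DataFrame:
    """Long format for the converter: one row per patient-diagnosis."""
    rows = [
        {"patient_id": p.patient_id, "icd_code": code}
        for p in patients for code in p.gm_codes
    ]
    return pd.DataFrame(rows, columns=["patient_id", "icd_code"])


def truth_frame(patients: list[SyntheticPatient]) -> pd.DataFrame:
    rows = [
        {"patient_id": p.patient_id, "true_iss": p.true_iss, "group": p.group}
        for p in patients
    ]
    return pd.DataFrame(rows, columns=["patient_id", "true_iss", "group"])


def generate_paired_scores(config: GeneratorConfig) -> pd.DataFrame:
    """Draw paired manual/automatic ISS scores under the disagreement model.

    The manual score is uniform within its sampled group's ISS range; the
    automatic score equals the manual one except for a ``shift_prob``
    fraction of patients, whose score is shifted by rounded N(0, shift_sd)
    noise and clamped to [0, 75].
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    groups = rng.choice(6, size=n, p=config.group_weights)
    lows = np.array([b[0] for b in GROUP_BOUNDS])
    highs = np.array([b[1] for b in GROUP_BOUNDS])
    manual = rng.integers(lows[groups], highs[groups] + 1)
    shift = rng.random(n) < config.shift_prob
    noise = np.round(rng.normal(0.0, config.shift_sd, size=n)).astype(int)
    auto = np.clip(manual + shift * noise, 0, 75)
    return pd.DataFrame({
        "patient_id": [f"P{i + 1:05d}" for i in range(n)],
        "manual_iss": manual.astype(int),
        "auto_iss": auto.astype(int),
    })


def table3_counts() -> CrossTab:
    """The published 6x6 manual-vs-automatic group cross-tabulation."""
    df = pd.read_csv(fixture_path("table3_crosstab.tsv"), sep="\t", index_col=0)
    counts = df.to_numpy(dtype=int)
    if counts.shape != (6, 6):
        raise ValueError("table3 fixture must be 6x6")
    return CrossTab(counts)


def table3_pairs() -> pd.DataFrame:
    """Expand the published cross-tabulation into 640 group-level pairs.

    Scores are each group's representative value (its lower bound); only
    the group identity is meaningful.  Row-major expansion keeps the output
    deterministic.
    """
    tab = table3_counts()
    rows = []
    pid = 0
    for i in range(6):
        for j in range(6):
            for _ in range(int(tab.counts[i, j])):
                pid += 1
                rows.append({
                    "patient_id": f"T{pid:04d}",
                    "manual_iss": GROUP_REPRESENTATIVE[i],
                    "auto_iss": GROUP_REPRESENTATIVE[j],
                })
    return pd.DataFrame(rows, columns=["patient_id", "manual_iss", "auto_iss"])
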