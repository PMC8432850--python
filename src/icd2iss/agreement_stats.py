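"""Manual-vs-automatic agreement statistics for paired ISS/AIS scores.

The validation protocol compares an automatically computed score against a
manual gold standard with a dual criterion: the paired two one-sided tests
(TOST) procedure must declare the mean difference significantly inside the
equivalence bounds (here -3 to +3 ISS points), *and* a conventional null
hypothesis significance test (Wilcoxon signed-rank, since score differences
are not normal) must fail to find a systematic difference.  Equivalence is
declared only when the TOST is significant and the NHST is not.  Agreement
on the ordinal ISS group scale (1: 0-8, 2: 9-15, 3: 16-24, 4: 25-40,
5: 41-49, 6: 50-75) is quantified by weighted Cohen's kappa with the usual
interpretation bands (<=0.20 poor, 0.21-0.40 fair, 0.41-0.60 moderate,
0.61-0.80 good, 0.81-1.0 excellent), and per-group absolute differences
summarise where the methods drift apart.  A TOST power analysis gives the
paired sample size needed to demonstrate equivalence.

Sign convention: diff = auto - manual (configurable at the report level).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GROUP_BOUNDS",
    "GROUP_LABELS",
    "iss_group",
    "CrossTab",
    "crosstab",
    "KappaResult",
    "weighted_kappa",
    "kappa_band",
    "TOSTResult",
    "paired_tost",
    "nhst_wilcoxon",
    "equivalence_verdict",
    "group_abs_diff_summary",
    "tost_power",
    "tost_sample_size",
    "bonferroni",
    "compare_report",
]

#: inclusive ISS bounds of groups 1..6
GROUP_BOUNDS = ((0, 8), (9, 15), (16, 24), (25, 40), (41, 49), (50, 75))
GROUP_LABELS = ("0-8", "9-15", "16-24", "25-40", "41-49", "50-75")
N_GROUPS = len(GROUP_BOUNDS)


def iss_group(iss: int) -> int:
    """Map an ISS value 0-75 to its group 1-6 (bins are a partition)."""
    if not 0 <= iss <= 75:
        raise ValueError(f"ISS {iss} outside 0-75")
    for g, (lo, hi) in enumerate(GROUP_BOUNDS, start=1):
        if lo <= iss <= hi:
            return g
    raise AssertionError("unreachable: bins partition 0-75")


@dataclass(frozen=True)
class CrossTab:
    """6x6 contingency table; rows = manual group, columns = automatic."""

    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=GROUP_LABELS, columns=GROUP_LABELS)


def crosstab(manual_iss, auto_iss) -> CrossTab:
    """Cross-tabulate paired scores by (manual group, automatic group)."""
    manual = np.asarray(manual_iss)
    auto = np.asarray(auto_iss)
    if manual.size == 0 or manual.shape != auto.shape:
        raise ValueError("paired scores must be non-empty and equal length")
    counts = np.zeros((N_GROUPS, N_GROUPS), dtype=int)
    for m, a in zip(manual, auto):
        counts[iss_group(int(m)) - 1, iss_group(int(a)) - 1] += 1
    return CrossTab(counts)


def kappa_band(kappa: float) -> str:
    if kappa <= 0.20:
        return "poor"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "good"
    return "excellent"


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    weighting: str
    band: str


def weighted_kappa(tab: CrossTab | np.ndarray, weighting: str = "linear") -> KappaResult:
    """Weighted Cohen's kappa for two raters on ordinal categories.

    kappa = (Po - Pe) / (1 - Pe) with agreement weights
    w_ij = 1 - |i-j|/(k-1) (linear) or 1 - (i-j)^2/(k-1)^2 (quadratic);
    Po is the weighted observed proportion, Pe the weighted chance
    proportion from the marginals.
    """
    counts = tab.counts if isinstance(tab, CrossTab) else np.asarray(tab, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError("contingency table must be square")
    n = counts.sum()
    if n <= 0:
        raise ValueError("contingency table is empty")
    k = counts.shape[0]
    i, j = np.indices((k, k))
    if weighting == "linear":
        w = 1.0 - np.abs(i - j) / (k - 1)
    elif weighting == "quadratic":
        w = 1.0 - (i - j) ** 2 / (k - 1) ** 2
    else:
        raise ValueError(f"weighting must be linear or quadratic, got {weighting!r}")
    p = counts / n
    po = float((w * p).sum())
    pe = float((w * np.outer(p.sum(axis=1), p.sum(axis=0))).sum())
    if math.isclose(pe, 1.0, abs_tol=1e-12):
        raise ValueError("degenerate table: chance agreement Pe = 1, kappa undefined")
    kappa = (po - pe) / (1.0 - pe)
    return KappaResult(kappa, weighting, kappa_band(kappa))


@dataclass(frozen=True)
class TOSTResult:
    n: int
    mean_diff: float
    sd_diff: float
    p_lower: float
    p_upper: float
    p_tost: float
    ci_low: float
    ci_high: float
    flags: frozenset[str] = frozenset()


def paired_tost(diffs, low: float = -3.0, high: float = 3.0,
                alpha: float = 0.05) -> TOSTResult:
    """Paired-t two one-sided tests of the mean difference against
    [low, high]; p_tost = max of the one-sided p-values, with the matching
    (1-2*alpha) confidence interval (90% at alpha = 0.05).

    Zero-variance differences yield a flagged degenerate result whose
    verdict follows the position of the (constant) mean relative to the
    bounds rather than an exception, so all-equal cohorts still report.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError(f"paired TOST needs n >= 2, got n = {d.size}")
    if not low < high:
        raise ValueError("equivalence bounds must satisfy low < high")
    n = int(d.size)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        inside = low < mean < high
        p = 0.0 if inside else 1.0
        return TOSTResult(n, mean, sd, p, p, p, mean, mean,
                          frozenset({"zero_variance"}))
    se = sd / math.sqrt(n)
    df = n - 1
    p_lower = float(stats.t.sf((mean - low) / se, df))   # H1: mean > low
    p_upper = float(stats.t.cdf((mean - high) / se, df))  # H1: mean < high
    tcrit = float(stats.t.ppf(1.0 - alpha, df))
    return TOSTResult(
        n, mean, sd, p_lower, p_upper, max(p_lower, p_upper),
        mean - tcrit * se, mean + tcrit * se,
    )


def nhst_wilcoxon(diffs) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired differences.

    Zero differences are dropped (Wilcoxon's original convention); the
    exact null distribution is used up to n = 25 remaining pairs, the
    continuity-corrected normal approximation above.  If every difference
    is zero the test carries no evidence and p = 1 by convention.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    method = "exact" if d.size <= 25 else "approx"
    try:
        res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                             alternative="two-sided", method=method)
    except ValueError:
        res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                             alternative="two-sided", method="approx")
    return float(res.pvalue)


def equivalence_verdict(p_tost: float, p_nhst: float, alpha: float = 0.05) -> bool:
    """Dual criterion: equivalent iff the TOST is significant and the NHST
    is not."""
    for name, p in (("p_tost", p_tost), ("p_nhst", p_nhst)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} = {p} outside [0, 1]")
    return p_tost <= alpha and p_nhst > alpha


def group_abs_diff_summary(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-manual-group n, mean and sample SD of |auto - manual|, plus an
    overall row.  Empty groups keep n = 0 with missing moments."""
    manual = pairs["manual_iss"].to_numpy()
    auto = pairs["auto_iss"].to_numpy()
    absdiff = np.abs(auto - manual).astype(float)
    groups = np.array([iss_group(int(m)) for m in manual])
    rows = []
    for g, label in enumerate(GROUP_LABELS, start=1):
        sel = absdiff[groups == g]
        rows.append({
            "group": g, "iss_range": label, "n": int(sel.size),
            "mean_abs_diff": float(sel.mean()) if sel.size else np.nan,
            "sd_abs_diff": float(sel.std(ddof=1)) if sel.size > 1 else np.nan,
        })
    rows.append({
        "group": 0, "iss_range": "0-75", "n": int(absdiff.size),
        "mean_abs_diff": float(absdiff.mean()) if absdiff.size else np.nan,
        "sd_abs_diff": float(absdiff.std(ddof=1)) if absdiff.size > 1 else np.nan,
    })
    return pd.DataFrame(rows)


def tost_power(n: int, sd: float, low: float = -3.0, high: float = 3.0,
               alpha: float = 0.05, true_mean: float = 0.0) -> float:
    """Exact power of the paired-t TOST at a given true mean difference.

    Both one-sided statistics are noncentral-t distributed; the joint
    rejection probability is bounded below by
    P(T_low >= t_crit) + P(T_high <= -t_crit) - 1, which is exact whenever
    the two rejection regions overlap (the relevant regime near the design
    power).
    """
    if n < 2:
        return 0.0
    df = n - 1
    se = sd / math.sqrt(n)
    tcrit = stats.t.ppf(1.0 - alpha, df)
    ncp_low = (true_mean - low) / se
    ncp_high = (true_mean - high) / se
    p_rej_low = stats.nct.sf(tcrit, df, ncp_low)
    p_rej_high = stats.nct.cdf(-tcrit, df, ncp_high)
    return float(max(0.0, p_rej_low + p_rej_high - 1.0))


def tost_sample_size(sd: float, low: float = -3.0, high: float = 3.0,
                     alpha: float = 0.05, power: float = 0.8) -> int:
    """Smallest paired n whose TOST power at true mean difference 0 reaches
    the target, by iterating the exact noncentral-t power."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    if not (low < 0 < high):
        raise ValueError("bounds must straddle 0")
    if not 0 < alpha < power < 1:
        raise ValueError("need 0 < alpha < power < 1")
    n = 2
    while tost_power(n, sd, low, high, alpha) < power:
        n += 1
        if n > 1_000_000:
            raise RuntimeError("target power unreachable at any feasible n")
    return n


def bonferroni(pvals) -> list[float]:
    """Bonferroni adjustment: min(1, m*p) for a family of m tests."""
    p = list(pvals)
    m = len(p)
    for v in p:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"p-value {v} outside [0, 1]")
    return [min(1.0, m * v) for v in p]


_REGION_NAMES = ("head_neck", "face", "thorax", "abdomen", "extremities", "external")


def _test_block(diffs, low, high, alpha) -> dict:
    tost = paired_tost(diffs, low, high, alpha)
    p_nhst = nhst_wilcoxon(diffs)
    return {
        "n": tost.n,
        "mean_diff": tost.mean_diff,
        "sd_diff": tost.sd_diff,
        "p_tost": tost.p_tost,
        "ci90_low": tost.ci_low,
        "ci90_high": tost.ci_high,
        "p_nhst": p_nhst,
        "equivalent": equivalence_verdict(tost.p_tost, p_nhst, alpha),
        "flags": sorted(tost.flags),
    }


def compare_report(pairs: pd.DataFrame, alpha: float = 0.05,
                   bounds: tuple[float, float] = (-3.0, 3.0),
                   kappa_weights: str = "linear",
                   sign: str = "auto_minus_manual") -> dict:
    """Full validation report for a paired manual/automatic scores file.

    Runs the overall and per-group TOST + Wilcoxon with the dual
    equivalence verdict (raw p-values, plus Bonferroni-adjusted p-values
    and verdicts over the 7-test family), the group cross-tabulation with
    weighted kappa, and per-group absolute-difference summaries.  When the
    six per-region manual/auto AIS columns are present, each region gets
    its own kappa and equivalence test; otherwise that section is omitted.
    Returns a JSON-serialisable dict.
    """
    for col in ("manual_iss", "auto_iss"):
        if col not in pairs.columns:
            raise ValueError(f"paired scores: missing column {col!r}")
    if sign not in ("auto_minus_manual", "manual_minus_auto"):
        raise ValueError(f"unknown sign convention {sign!r}")
    low, high = bounds
    manual = pairs["manual_iss"].to_numpy(dtype=float)
    auto = pairs["auto_iss"].to_numpy(dtype=float)
    diffs = auto - manual if sign == "auto_minus_manual" else manual - auto
    groups = np.array([iss_group(int(m)) for m in manual])

    blocks: list[dict] = []
    for g, label in enumerate(GROUP_LABELS, start=1):
        sel = diffs[groups == g]
        block: dict = {"group": g, "iss_range": label}
        if sel.size >= 2:
            block.update(_test_block(sel, low, high, alpha))
        else:
            block.update(n=int(sel.size), equivalent=None,
                         flags=["too_few_pairs"])
        blocks.append(block)
    overall = {"group": 0, "iss_range": "0-75"}
    overall.update(_test_block(diffs, low, high, alpha))
    blocks.append(overall)

    testable = [b for b in blocks if "p_tost" in b]
    adj_tost = bonferroni([b["p_tost"] for b in testable])
    adj_nhst = bonferroni([b["p_nhst"] for b in testable])
    for b, pt, pn in zip(testable, adj_tost, adj_nhst):
        b["p_tost_bonferroni"] = pt
        b["p_nhst_bonferroni"] = pn
        b["equivalent_bonferroni"] = equivalence_verdict(pt, pn, alpha)

    tab = crosstab(manual, auto)
    kap = weighted_kappa(tab, kappa_weights)
    report = {
        "n": int(len(pairs)),
        "alpha": alpha,
        "bounds": [low, high],
        "sign": sign,
        "equivalence": blocks,
        "crosstab": {
            "labels": list(GROUP_LABELS),
            "counts": tab.counts.tolist(),
        },
        "kappa": {"kappa": kap.kappa, "weighting": kap.weighting,
                  "band": kap.band},
        "abs_diff_by_group": group_abs_diff_summary(pairs).to_dict("records"),
    }

    region_cols = [(f"manual_ais_{r}", f"auto_ais_{r}") for r in _REGION_NAMES]
    if all(c in pairs.columns for pair in region_cols for c in pair):
        regions = []
        for name, (mcol, acol) in zip(_REGION_NAMES, region_cols):
            m = pairs[mcol].to_numpy(dtype=float)
            a = pairs[acol].to_numpy(dtype=float)
            rd = a - m if sign == "auto_minus_manual" else m - a
            # AIS is ordinal 0-6: 7 categories for the kappa table
            counts = np.zeros((7, 7), dtype=int)
            for mi, ai in zip(m.astype(int), a.astype(int)):
                counts[mi, ai] += 1
            entry = {"region": name,
                     "manual_mean": float(m.mean()),
                     "auto_mean": float(a.mean())}
            try:
                rk = weighted_kappa(counts, kappa_weights)
                entry["kappa"] = rk.kappa
                entry["band"] = rk.band
            except ValueError:
                entry["kappa"] = None
            entry.update(_test_block(rd, low, high, alpha))
            regions.append(entry)
        report["regions"] = regions
    return report
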