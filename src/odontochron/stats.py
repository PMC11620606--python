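"""Group statistics for crown-chronology parameters and amelogenin sex calls.

The comparison battery mirrors standard practice in histomorphometry:
Shapiro–Wilk normality on each group gates the choice between a
parametric route (F-test on variances, then pooled-variance or Welch
t-test) and the Mann–Whitney U test. The U statistic is computed with
midranks for ties and its null distribution either exactly (small
tie-free samples) or by the tie-corrected normal approximation.

Sex determination from enamel peptides is a presence/absence rule on
the two amelogenin isoforms: AMELY peptides occur only in males, so
AMELY present => male; AMELX alone => female; neither => indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .chronology import round_days
from .tracings import ChronologyRecord

AMELX_MZ = 540.2796   # AMELX-(44-52) [M+2H]2+ marker, m/z
AMELY_MZ = 440.2233   # AMELY-(58-64) [M+2H]2+ marker, m/z

__all__ = [
    "TestResult",
    "SexCall",
    "load_table1",
    "summarize_parameters",
    "compare_two_groups",
    "mann_whitney_u",
    "cohens_d",
    "call_sex",
    "count_individual_sexes",
]


# ---------------------------------------------------------------------------
# packaged Table-1-style fixture
# ---------------------------------------------------------------------------


def _individual_of(tooth_id: str) -> str:
    """Individual identifier: the tooth id minus its arch-position suffix."""
    parts = tooth_id.rsplit(" ", 1)
    return parts[0] if len(parts) == 2 else tooth_id


def load_table1() -> list[ChronologyRecord]:
    """Load the packaged per-tooth chronology fixture.

    The source table prints each individual's sex once; here the call is
    propagated to every tooth of the same individual, since sex is an
    individual-level attribute.
    """
    with resources.files("odontochron.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh, na_values=["n.a.", ""], keep_default_na=False)
    sex_by_ind: dict[str, str] = {}
    for _, row in df.iterrows():
        sex = row["sex"]
        if isinstance(sex, str) and sex in ("M", "F"):
            sex_by_ind[_individual_of(row["id"])] = sex
    records = []
    for _, row in df.iterrows():
        ind = _individual_of(row["id"])
        records.append(
            ChronologyRecord(
                id=row["id"],
                site=row["site"],
                individual=ind,
                arch=row["arch"],
                sex=sex_by_ind.get(ind, "unknown"),
                wear_stage=int(row["wear_stage"]),
                cft=None if pd.isna(row["cft"]) else float(row["cft"]),
                ci=None if pd.isna(row["ci"]) else float(row["ci"]),
                cc=None if pd.isna(row["cc"]) else float(row["cc"]),
                inner_dsr_mean=float(row["dsr"]),
                n_accentuated=int(row["n_accentuated"]),
                cft_ci_eligible=bool(row["footnote_a"]),
                cc_excluded=bool(row["footnote_b"]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

PARAMETERS = ("cft", "ci", "cc", "dsr")


def _eligible_values(records: Sequence[ChronologyRecord], parameter: str) -> list[float]:
    vals = []
    for r in records:
        if parameter in ("cft", "ci"):
            v = getattr(r, parameter)
            if r.cft_ci_eligible and v is not None:
                vals.append(float(v))
        elif parameter == "cc":
            if not r.cc_excluded and r.cc is not None:
                vals.append(float(r.cc))
        else:
            if r.inner_dsr_mean is not None:
                vals.append(float(r.inner_dsr_mean))
    return vals


def summarize_parameters(
    records: Sequence[ChronologyRecord],
    groupings: Sequence[str] = ("overall", "arch", "sex", "site"),
) -> pd.DataFrame:
    """Group summaries (n, mean, sd, min, max) honoring exclusion flags.

    CFT and Ci are averaged only over teeth with an unworn dentine horn
    and intact cervix (``cft_ci_eligible``); Cc excludes the
    ``cc_excluded`` teeth; DSR uses every tooth. ``mean_rounded`` is the
    integer-day report value (DSR keeps 2 decimals).
    """
    rows = []
    for grouping in groupings:
        if grouping == "overall":
            groups = {"overall": list(records)}
        else:
            groups = {}
            for r in records:
                groups.setdefault(getattr(r, grouping), []).append(r)
        for gname, recs in sorted(groups.items()):
            if gname in ("", "unknown"):
                continue
            for parameter in PARAMETERS:
                vals = _eligible_values(recs, parameter)
                if not vals:
                    continue
                mean = float(np.mean(vals))
                rows.append({
                    "grouping": grouping,
                    "group": gname,
                    "parameter": parameter,
                    "n": len(vals),
                    "mean": mean,
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                    "min": float(np.min(vals)),
                    "max": float(np.max(vals)),
                    "mean_rounded": round(mean, 2) if parameter == "dsr" else round_days(mean),
                })
    return pd.DataFrame(rows)


def summary_value(summary: pd.DataFrame, grouping: str, group: str, parameter: str,
                  column: str = "mean_rounded"):
    sel = summary[
        (summary.grouping == grouping)
        & (summary.group == group)
        & (summary.parameter == parameter)
    ]
    if sel.empty:
        raise KeyError(f"no summary for {grouping}/{group}/{parameter}")
    return sel.iloc[0][column]


# ---------------------------------------------------------------------------
# Mann-Whitney U (midranks; exact DP null for small tie-free samples)
# ---------------------------------------------------------------------------


def _exact_u_cdf(n: int, m: int) -> np.ndarray:
    """Null pmf of U for sample sizes (n, m) without ties (DP recurrence)."""
    # f[k][u]: number of ways to choose ranks for the first sample of size k
    # with U = u; recurrence over the merged sequence.
    max_u = n * m
    f = np.zeros((n + 1, max_u + 1))
    f[0, 0] = 1.0
    # classic recurrence: f(n, m, u) = f(n-1, m, u-m) + f(n, m-1, u)
    # implemented over m one step at a time
    for mm in range(0, m + 1):
        g = np.zeros((n + 1, max_u + 1))
        g[0, 0] = 1.0
        for k in range(1, n + 1):
            for u in range(0, k * mm + 1):
                g[k, u] = (g[k - 1, u - mm] if u >= mm else 0.0) + (
                    f[k, u] if mm > 0 else 0.0
                )
        f = g
    pmf = f[n] / f[n].sum()
    return pmf


def mann_whitney_u(a, b, exact_limit: int = 400) -> tuple[float, float, float]:
    """Mann–Whitney U with midranks: returns (U_a, U_b, two-sided p).

    U_a + U_b = n_a * n_b always holds (ties share midranks). The
    p-value uses the exact null distribution when the samples are
    tie-free and n_a * n_b <= ``exact_limit``; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    ra = float(np.sum(ranks[:na]))
    u_a = ra - na * (na + 1) / 2.0
    u_b = na * nb - u_a

    _, counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(counts > 1)
    if not has_ties and na * nb <= exact_limit:
        pmf = _exact_u_cdf(na, nb)
        u_lo = int(round(min(u_a, u_b)))
        p = min(1.0, 2.0 * float(pmf[: u_lo + 1].sum()))
    else:
        n = na + nb
        mu = na * nb / 2.0
        tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
        sigma2 = na * nb / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            return u_a, u_b, 1.0
        z = (abs(u_a - mu) - 0.5) / np.sqrt(sigma2)
        p = 2.0 * float(sps.norm.sf(max(z, 0.0)))
        p = min(1.0, p)
    return float(u_a), float(u_b), p


# ---------------------------------------------------------------------------
# gated two-group comparison
# ---------------------------------------------------------------------------


@dataclass
class TestResult:
    test_name: str               # "student_t" | "welch_t" | "mann_whitney"
    statistic: float             # t or U_a
    df: Optional[float]          # possibly fractional (Welch); None for U
    p_value: float
    decision_trace: list[str] = field(default_factory=list)


def compare_two_groups(a, b, alpha: float = 0.05) -> TestResult:
    """Normality-gated two-sample comparison.

    Shapiro–Wilk on each group (at ``alpha``); if both look normal an
    F-test compares variances and picks pooled-variance vs Welch t;
    otherwise Mann–Whitney U. The full gate trace is recorded.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs n >= 3")
    trace = []
    wa, pa = sps.shapiro(a)
    wb, pb = sps.shapiro(b)
    trace.append(f"shapiro_a: W={wa:.4f} p={pa:.4g}")
    trace.append(f"shapiro_b: W={wb:.4f} p={pb:.4g}")
    if pa > alpha and pb > alpha:
        trace.append("both groups normal -> parametric route")
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        F = va / vb
        dfa, dfb = len(a) - 1, len(b) - 1
        p_f = 2.0 * min(sps.f.cdf(F, dfa, dfb), sps.f.sf(F, dfa, dfb))
        trace.append(f"f_test: F={F:.4f} p={p_f:.4g}")
        if p_f > alpha:
            trace.append("variances homogeneous -> pooled-variance t")
            res = sps.ttest_ind(a, b, equal_var=True)
            return TestResult("student_t", float(res.statistic), float(res.df),
                              float(res.pvalue), trace)
        trace.append("variances heterogeneous -> Welch t (fractional df)")
        res = sps.ttest_ind(a, b, equal_var=False)
        return TestResult("welch_t", float(res.statistic), float(res.df),
                          float(res.pvalue), trace)
    trace.append("non-normal group -> Mann-Whitney U")
    u_a, u_b, p = mann_whitney_u(a, b)
    trace.append(f"mann_whitney: U_a={u_a:.1f} U_b={u_b:.1f}")
    return TestResult("mann_whitney", u_a, None, p, trace)


def cohens_d(a, b) -> float:
    """Pooled-sd Cohen's d; positive when mean(a) > mean(b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        raise ValueError("zero pooled standard deviation")
    return float((np.mean(a) - np.mean(b)) / np.sqrt(sp2))


# ---------------------------------------------------------------------------
# amelogenin sex call
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SexCall:
    amelx_present: bool
    amely_present: bool
    call: str                    # "male" | "female" | "indeterminate"
    marker_mz: dict = field(
        default_factory=lambda: {"AMELX": AMELX_MZ, "AMELY": AMELY_MZ}
    )


def call_sex(amelx_present: bool, amely_present: bool) -> SexCall:
    """Presence/absence rule on the amelogenin isoform marker peptides."""
    if amely_present:
        call = "male"
    elif amelx_present:
        call = "female"
    else:
        call = "indeterminate"
    return SexCall(bool(amelx_present), bool(amely_present), call)


def count_individual_sexes(records: Sequence[ChronologyRecord]) -> dict[str, int]:
    """Individual-level sex tallies (one count per individual, not per tooth)."""
    by_ind: dict[str, str] = {}
    for r in records:
        ind = r.individual or _individual_of(r.id)
        if r.sex in ("M", "F"):
            by_ind[ind] = r.sex
        else:
            by_ind.setdefault(ind, "unknown")
    out = {"M": 0, "F": 0, "unknown": 0}
    for s in by_ind.values():
        out[s] += 1
    return out
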