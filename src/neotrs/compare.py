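"""Paired midline-vs-lateral statistical comparison.

For every derived parameter the within-subject difference is tested
two-sided at alpha = 0.05, choosing between a paired t-test and a
Wilcoxon signed-rank test by a Shapiro–Wilk normality gate on the
paired differences (the common clinical convention; the chosen test is
recorded per row).  No multiplicity correction is applied to the
significance flags; a Holm-adjusted column is emitted alongside for
reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .inversion import LATERAL, MIDLINE

PAIRED_T = "paired_t"
WILCOXON = "wilcoxon"

#: Canonical 14-parameter comparison set (wavelength-resolved where
#: applicable) in presentation order.
def parameter_order(wavelengths=(762.0, 801.0, 836.0)) -> list:
    wl = [f"{float(w):.0f}" for w in wavelengths]
    return (["count_rate", "attenuation"]
            + [f"mean_path_length_{w}" for w in wl]
            + [f"mu_s_prime_{w}" for w in wl]
            + [f"mu_a_{w}" for w in wl]
            + ["total_hb", "sco2", "cbv"])


class PairedCohort:
    """Per-subject midline and lateral derived-parameter records.

    Wraps a tidy frame with columns ``subject_id``, ``site`` and one
    column per parameter; validates that every subject carries both
    sites with identical parameter sets.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"subject_id", "site"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"paired cohort frame missing columns {missing}")
        bad_sites = set(frame["site"]) - {MIDLINE, LATERAL}
        if bad_sites:
            raise ValueError(f"unknown site labels {bad_sites}")
        counts = frame.groupby("subject_id")["site"].agg(
            lambda s: tuple(sorted(s)))
        for subject, sites in counts.items():
            if sites != (LATERAL, MIDLINE):
                raise ValueError(
                    f"subject {subject} lacks a complete midline/lateral pair")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "PairedCohort":
        return cls(pd.DataFrame(list(records)))

    @property
    def parameters(self) -> list:
        return [c for c in self.frame.columns
                if c not in ("subject_id", "site")]

    @property
    def n_subjects(self) -> int:
        return self.frame["subject_id"].nunique()

    def site_values(self, parameter: str) -> tuple:
        """(midline, lateral) arrays aligned by subject_id order."""
        wide = self.frame.pivot(index="subject_id", columns="site",
                                values=parameter).sort_index()
        return wide[MIDLINE].to_numpy(), wide[LATERAL].to_numpy()


@dataclass
class TestChoice:
    test: str
    normality_p: float
    degenerate: bool = False


@dataclass
class ComparisonResult:
    parameter: str
    test_used: str
    statistic: float
    p_value: float
    n_pairs: int
    mean_midline: float
    mean_lateral: float
    median_midline: float
    median_lateral: float
    normality_p: float
    significant: bool
    degenerate: bool = False


def choose_test(differences: Sequence[float], alpha: float = 0.05) -> TestChoice:
    """Shapiro–Wilk gate: normal-looking differences -> paired t, else
    Wilcoxon signed-rank."""
    d = np.asarray(differences, dtype=float)
    d = d[np.isfinite(d)]
    if d.size < 3:
        raise ValueError("need at least 3 finite paired differences")
    if np.all(d == d[0]):
        # constant differences: Shapiro is undefined; flag and fall back
        return TestChoice(PAIRED_T, normality_p=np.nan, degenerate=True)
    p = float(stats.shapiro(d).pvalue)
    return TestChoice(PAIRED_T if p >= alpha else WILCOXON, normality_p=p)


def _wilcoxon(d: np.ndarray) -> tuple:
    """Signed-rank test: zeros dropped, midranks for ties, exact null for
    n <= 25 without ties, else normal approximation with continuity
    correction."""
    nz = d[d != 0]
    if nz.size == 0:
        return 0.0, 1.0
    has_ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(nz, zero_method="wilcox", correction=True,
                         method=method)
    return float(res.statistic), float(res.pvalue)


def paired_compare(midline: Sequence[float], lateral: Sequence[float],
                   test: Optional[str] = None, alpha: float = 0.05,
                   parameter: str = "") -> ComparisonResult:
    """Two-sided paired comparison of one parameter between sites."""
    x = np.asarray(midline, dtype=float)
    y = np.asarray(lateral, dtype=float)
    if x.shape != y.shape:
        raise ValueError(
            f"length mismatch: {x.size} midline vs {y.size} lateral values")
    d = x - y
    if test is None:
        choice = choose_test(d, alpha)
    else:
        choice = TestChoice(test, normality_p=np.nan,
                            degenerate=bool(np.all(d == 0)))
    degenerate = bool(np.all(d == 0))
    if degenerate:
        statistic, p = 0.0, 1.0
        test_used = choice.test
    elif choice.test == PAIRED_T:
        n = d.size
        sd = np.std(d, ddof=1)
        statistic = float(np.mean(d) / (sd / np.sqrt(n)))
        p = float(2.0 * stats.t.sf(abs(statistic), df=n - 1))
        test_used = PAIRED_T
    else:
        statistic, p = _wilcoxon(d)
        test_used = WILCOXON
    return ComparisonResult(
        parameter=parameter,
        test_used=test_used,
        statistic=statistic,
        p_value=p,
        n_pairs=int(d.size),
        mean_midline=float(np.mean(x)),
        mean_lateral=float(np.mean(y)),
        median_midline=float(np.median(x)),
        median_lateral=float(np.median(y)),
        normality_p=float(choice.normality_p)
        if choice.normality_p == choice.normality_p else np.nan,
        significant=bool(p < alpha) and not degenerate,
        degenerate=degenerate,
    )


def compare_all(cohort: PairedCohort, alpha: float = 0.05,
                parameters: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """One comparison row per parameter; significance flagged at alpha
    without multiplicity correction, Holm-adjusted p-values alongside."""
    if parameters is None:
        order = [p for p in parameter_order() if p in cohort.parameters]
        extras = [p for p in cohort.parameters if p not in order]
        parameters = order + extras
    results = []
    for param in parameters:
        mid, lat = cohort.site_values(param)
        finite = np.isfinite(mid) & np.isfinite(lat)
        results.append(paired_compare(mid[finite], lat[finite],
                                      alpha=alpha, parameter=param))
    df = pd.DataFrame([r.__dict__ for r in results])
    df["p_holm"] = multipletests(df["p_value"].to_numpy(), method="holm")[1]
    return df
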