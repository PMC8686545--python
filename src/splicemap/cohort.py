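"""Cohort-level statistics: differential PSI, set overlap, direction
agreement, multiple-testing correction and PSI-stratified survival.

Differential inclusion between patient groups uses the Wilcoxon rank-sum
test with Benjamini-Hochberg adjustment; an event is called significant
when |Δ median PSI| >= 0.1 and FDR <= 0.01 (both thresholds exposed).
Survival stratification follows the common transcriptomics practice of
splitting patients at a PSI cutoff — either a fixed value or the observed
value minimizing the log-rank p — and comparing Kaplan-Meier curves.
Optimal-cutoff p-values are nominal: scanning cutoffs inflates
significance, and downstream consumers are warned accordingly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class CohortMatrix:
    """PSI (events x samples), expression (genes x samples) and sample metadata.

    ``sample_meta`` is indexed by sample id with columns ``subtype``,
    ``survival_time`` (days) and ``event_indicator`` (1 = event observed).
    """

    psi: pd.DataFrame
    expression: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self):
        samples = set(self.psi.columns)
        if not samples.issubset(self.sample_meta.index):
            missing = samples - set(self.sample_meta.index)
            raise ValueError(f"PSI samples missing from metadata: {sorted(missing)[:5]}")
        if "survival_time" in self.sample_meta:
            t = self.sample_meta["survival_time"].dropna()
            if (t <= 0).any():
                raise ValueError("survival_time must be > 0 where present")


@dataclass
class DifferentialPsiResult:
    event_id: str
    delta_median_psi: float
    p_value: float
    fdr: float = float("nan")
    significant: bool = False
    tested: bool = True


def _ranksum_p(a: np.ndarray, b: np.ndarray, exact_max_n: int = 25) -> float:
    """Two-sided Wilcoxon rank-sum p.

    Exact enumeration when both groups are small and tie-free, otherwise the
    normal approximation with tie correction (scipy's implementations).
    """
    use_exact = (
        len(a) <= exact_max_n and len(b) <= exact_max_n
        and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    )
    method = "exact" if use_exact else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def differential_psi(
    psi: pd.DataFrame,
    group_labels: pd.Series | dict,
    delta_threshold: float = 0.1,
    fdr_threshold: float = 0.01,
    min_per_group: int = 3,
    groups: tuple[str, str] | None = None,
) -> list[DifferentialPsiResult]:
    """Per-event differential PSI between exactly two sample groups.

    Δ median PSI = median(groupA) - median(groupB); ``groups`` fixes the
    (A, B) order, defaulting to sorted label order.  Events with fewer than
    ``min_per_group`` non-missing values in either group are reported
    untested.
    """
    labels = pd.Series(group_labels)
    labels = labels.loc[labels.index.intersection(psi.columns)]
    uniq = list(groups) if groups else sorted(labels.unique())
    if sorted(labels.unique()) != sorted(uniq) or len(uniq) != 2:
        raise ValueError(f"need exactly two groups {uniq}, got {sorted(labels.unique())}")
    ga = labels.index[labels == uniq[0]]
    gb = labels.index[labels == uniq[1]]
    if len(ga) == 0 or len(gb) == 0:
        raise ValueError("one group is empty")
    results: list[DifferentialPsiResult] = []
    tested_idx = []
    for event_id, row in psi.iterrows():
        a = row[ga].dropna().to_numpy(dtype=float)
        b = row[gb].dropna().to_numpy(dtype=float)
        if len(a) < min_per_group or len(b) < min_per_group:
            results.append(DifferentialPsiResult(event_id, float("nan"), float("nan"),
                                                 tested=False))
            continue
        delta = float(np.median(a) - np.median(b))
        p = 1.0 if np.array_equal(np.sort(a), np.sort(b)) else _ranksum_p(a, b)
        tested_idx.append(len(results))
        results.append(DifferentialPsiResult(event_id, delta, p))
    if tested_idx:
        qs = bh_fdr([results[i].p_value for i in tested_idx])
        for i, q in zip(tested_idx, qs):
            r = results[i]
            r.fdr = float(q)
            r.significant = abs(r.delta_median_psi) >= delta_threshold and r.fdr <= fdr_threshold
    return results


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def overlap_test(set_a: set, set_b: set, universe: set) -> tuple[int, float]:
    """Overlap count and upper-tail hypergeometric p for >= observed overlap."""
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    stray = (set_a | set_b) - universe
    if stray:
        raise ValueError(f"ids outside the universe: {sorted(stray)[:10]}")
    k = len(set_a & set_b)
    n_univ, n_a, n_b = len(universe), len(set_a), len(set_b)
    p = float(stats.hypergeom.sf(k - 1, n_univ, n_a, n_b))
    return k, min(p, 1.0)


def direction_agreement_test(shared_events, polarity: str = "same"):
    """Direction agreement of shared events between two comparisons.

    ``shared_events`` yields (direction_in_A, direction_in_B) pairs with
    directions in {up, down}.  Returns (2x2 table DataFrame, two-sided
    Fisher p, fraction agreeing).  With ``polarity='same'`` agreement means
    identical direction; ``'opposite'`` counts reversed directions as
    agreement (for comparisons with inverted sign conventions).
    """
    pairs = [(a.lower(), b.lower()) for a, b in shared_events]
    if not pairs:
        raise ValueError("need at least one shared event")
    for a, b in pairs:
        if a not in ("up", "down") or b not in ("up", "down"):
            raise ValueError(f"directions must be up/down, got ({a}, {b})")
    table = pd.DataFrame(0, index=["up", "down"], columns=["up", "down"])
    for a, b in pairs:
        table.loc[a, b] += 1
    _, p = stats.fisher_exact(table.to_numpy(), alternative="two-sided")
    same = table.loc["up", "up"] + table.loc["down", "down"]
    agreeing = same if polarity == "same" else len(pairs) - same
    return table, float(p), agreeing / len(pairs)


@dataclass
class SurvivalStratification:
    event_id: str
    endpoint: str
    psi_cutoff: float
    n_high: int
    n_low: int
    logrank_stat: float
    p_value: float
    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    cutoff_mode: str = "fixed"


def _km_curve(time, observed) -> pd.DataFrame:
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=observed)
    sf = kmf.survival_function_
    return pd.DataFrame({
        "time": sf.index.to_numpy(dtype=float),
        "survival": sf.iloc[:, 0].to_numpy(dtype=float),
    })


def _logrank(time, observed, high_mask):
    res = logrank_test(
        time[high_mask], time[~high_mask],
        event_observed_A=observed[high_mask],
        event_observed_B=observed[~high_mask],
    )
    return float(res.test_statistic), float(res.p_value)


def km_stratify(
    psi_row, survival_time, event_indicator,
    cutoff_mode: str = "optimal",
    fixed_cutoff: float = 0.5,
    min_group_frac: float = 0.1,
    event_id: str = "",
    endpoint: str = "OS",
    min_patients: int = 20,
) -> SurvivalStratification:
    """Kaplan-Meier stratification of patients by a PSI cutoff.

    High group: PSI > cutoff.  In ``optimal`` mode the cutoff minimizing the
    log-rank p is chosen among observed PSI values leaving at least
    ``min_group_frac`` of patients on each side (ties resolve to the cutoff
    closest to the median PSI); the reported p is nominal.
    """
    psi = np.asarray(psi_row, dtype=float)
    time = np.asarray(survival_time, dtype=float)
    obs = np.asarray(event_indicator, dtype=float)
    mask = ~(np.isnan(psi) | np.isnan(time) | np.isnan(obs))
    psi, time, obs = psi[mask], time[mask], obs[mask]
    n = len(psi)
    if n < min_patients:
        raise ValueError(f"need >= {min_patients} usable patients, got {n}")

    def split(cutoff):
        return psi > cutoff

    if cutoff_mode == "fixed":
        cutoff = fixed_cutoff
        high = split(cutoff)
        if high.sum() == 0 or high.sum() == n:
            raise ValueError("fixed cutoff empties one group")
        stat, p = _logrank(time, obs, high)
    elif cutoff_mode == "optimal":
        min_side = max(1, int(np.ceil(min_group_frac * n)))
        candidates = [
            c for c in np.unique(psi)
            if min_side <= (psi > c).sum() <= n - min_side
        ]
        if not candidates:
            raise ValueError("no cutoff satisfies the group-size floor")
        med = float(np.median(psi))
        best = None
        for c in candidates:
            high = split(c)
            stat, p = _logrank(time, obs, high)
            key = (p, abs(c - med))
            if best is None or key < best[0]:
                best = (key, c, stat, p)
        _, cutoff, stat, p = best
        high = split(cutoff)
        warnings.warn(
            "optimal-cutoff log-rank p is nominal; cutoff optimization "
            "inflates significance", UserWarning, stacklevel=2,
        )
    else:
        raise ValueError("cutoff_mode must be 'fixed' or 'optimal'")

    return SurvivalStratification(
        event_id=event_id,
        endpoint=endpoint,
        psi_cutoff=float(cutoff),
        n_high=int(high.sum()),
        n_low=int(n - high.sum()),
        logrank_stat=stat,
        p_value=p,
        km_curves={
            "high": _km_curve(time[high], obs[high]),
            "low": _km_curve(time[~high], obs[~high]),
        },
        cutoff_mode=cutoff_mode,
    )
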