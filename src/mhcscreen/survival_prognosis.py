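"""Kaplan-Meier estimation, log-rank testing, tertile stratification and
fixed-horizon ROC evaluation of prognostic scores.

Implemented from the standard formulas:

* KM:       S(t) = prod_{t_i <= t} (1 - d_i / n_i) over distinct event times,
            with events processed before censorings at tied times.
* log-rank: at each distinct event time j, e_Aj = n_Aj * d_j / n_j and
            v_j = d_j (n_j - d_j) n_Aj n_Bj / (n_j^2 (n_j - 1));
            chi^2 = (sum(o_Aj - e_Aj))^2 / sum(v_j), 1 df.
* ROC:      cases are events within the horizon, controls survive past it,
            censored-before-horizon subjects are excluded; AUC by trapezoid
            (equals the Mann-Whitney statistic with ties half-weighted).

Tertile stratification takes the floor(n/3) lowest scores as "low" and the
floor(n/3) highest as "high"; values tied across a group boundary fall to
"mid", so degenerate score vectors produce empty extreme groups rather than
arbitrary splits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import ClinicalTable, ExpressionMatrix

__all__ = [
    "KMCurve",
    "LogRankResult",
    "StratifiedGroups",
    "ROCResult",
    "km_estimate",
    "logrank",
    "tertile_labels",
    "expression_tertiles",
    "combined_stratify",
    "prognostic_roc",
]


@dataclass(frozen=True)
class KMCurve:
    """Survival step function over distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def __post_init__(self) -> None:
        for name in ("event_times", "survival", "at_risk", "n_events"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event times must be strictly increasing")
        s = self.survival
        if np.any(s < -1e-12) or np.any(s > 1 + 1e-12) or np.any(np.diff(s) > 1e-12):
            raise ValueError("survival must be non-increasing within [0, 1]")

    def at(self, t: float) -> float:
        """S(t); 1 before the first event time."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    df: int
    p: float
    observed: tuple[float, float]
    expected: tuple[float, float]


@dataclass(frozen=True)
class StratifiedGroups:
    """Sample -> {high, low, mid} labels; mid is excluded downstream."""

    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - {"high", "low", "mid"}
        if bad:
            raise ValueError(f"unknown stratum label(s): {sorted(bad)}")
        object.__setattr__(self, "labels", dict(self.labels))

    def _group(self, label: str) -> tuple[str, ...]:
        return tuple(s for s, v in self.labels.items() if v == label)

    @property
    def high(self) -> tuple[str, ...]:
        return self._group("high")

    @property
    def low(self) -> tuple[str, ...]:
        return self._group("low")

    @property
    def mid(self) -> tuple[str, ...]:
        return self._group("mid")


@dataclass(frozen=True)
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    horizon_months: float
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        fpr = np.asarray(self.fpr, dtype=float)
        tpr = np.asarray(self.tpr, dtype=float)
        object.__setattr__(self, "fpr", fpr)
        object.__setattr__(self, "tpr", tpr)
        if fpr[0] != 0 or tpr[0] != 0 or fpr[-1] != 1 or tpr[-1] != 1:
            raise ValueError("ROC must start at (0,0) and end at (1,1)")
        if np.any(np.diff(fpr) < 0) or np.any(np.diff(tpr) < 0):
            raise ValueError("ROC coordinates must be non-decreasing")


def km_estimate(clinical: ClinicalTable) -> KMCurve:
    """Kaplan-Meier product-limit estimate for one group."""
    if len(clinical) == 0:
        raise ValueError("cannot estimate survival for an empty group")
    time = clinical.time
    event = clinical.event.astype(bool)
    etimes = np.unique(time[event])
    survival = np.empty(etimes.size)
    at_risk = np.empty(etimes.size, dtype=int)
    n_events = np.empty(etimes.size, dtype=int)
    s = 1.0
    for i, t in enumerate(etimes):
        n_i = int(np.sum(time >= t))  # censored exactly at t still at risk
        d_i = int(np.sum(event & (time == t)))
        s *= 1.0 - d_i / n_i
        survival[i] = s
        at_risk[i] = n_i
        n_events[i] = d_i
    return KMCurve(etimes, survival, at_risk, n_events)


def logrank(group_a: ClinicalTable, group_b: ClinicalTable) -> LogRankResult:
    """Two-group Mantel-Cox log-rank test."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    ta, ea = group_a.time, group_a.event.astype(bool)
    tb, eb = group_b.time, group_b.event.astype(bool)
    all_event_times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    if all_event_times.size == 0:
        raise ValueError("no events in either group")
    o_a = e_a = e_b = var = 0.0
    for t in all_event_times:
        n_aj = int(np.sum(ta >= t))
        n_bj = int(np.sum(tb >= t))
        n_j = n_aj + n_bj
        d_aj = int(np.sum(ea & (ta == t)))
        d_bj = int(np.sum(eb & (tb == t)))
        d_j = d_aj + d_bj
        o_a += d_aj
        e_a += n_aj * d_j / n_j
        e_b += n_bj * d_j / n_j
        if n_j > 1:
            var += d_j * (n_j - d_j) * n_aj * n_bj / (n_j**2 * (n_j - 1))
    if var == 0.0:
        raise ValueError("log-rank variance is zero; groups cannot be compared")
    chi = (o_a - e_a) ** 2 / var
    p = float(stats.chi2.sf(chi, 1))
    o_b = float(np.sum(eb))
    return LogRankResult(chi_square=float(chi), df=1, p=p,
                         observed=(float(o_a), o_b), expected=(float(e_a), float(e_b)))


def tertile_labels(sample_ids: Sequence[str], scores: Sequence[float]) -> StratifiedGroups:
    """Label the bottom third of scores "low" and the top third "high".

    k = floor(n/3) samples go to each extreme; values tied across a boundary
    are demoted to "mid" so identical scores never straddle groups.
    """
    sample_ids = list(sample_ids)
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n != len(sample_ids):
        raise ValueError("scores and sample_ids must have equal length")
    if n < 3:
        raise ValueError(f"need at least 3 samples to form tertiles, got {n}")
    if np.any(~np.isfinite(scores)):
        raise ValueError("scores must be finite")
    k = n // 3
    order = np.sort(scores)
    v_low, v_high = order[k - 1], order[n - k]
    low_mask = scores < v_low
    if int(np.sum(scores <= v_low)) == k:
        low_mask = scores <= v_low
    high_mask = scores > v_high
    if int(np.sum(scores >= v_high)) == k:
        high_mask = scores >= v_high
    labels = {}
    for i, s in enumerate(sample_ids):
        labels[s] = "low" if low_mask[i] else ("high" if high_mask[i] else "mid")
    return StratifiedGroups(labels)


def expression_tertiles(
    expr: ExpressionMatrix, genes: str | Sequence[str]
) -> StratifiedGroups:
    """Tertiles of a single gene's expression or of a gene set's mean log2 value."""
    if isinstance(genes, str):
        genes = [genes]
    score = expr.subset_genes(list(genes)).values.mean(axis=0)
    return tertile_labels(expr.sample_ids, score)


def combined_stratify(
    groups1: StratifiedGroups, groups2: StratifiedGroups
) -> StratifiedGroups:
    """high = high in both, low = low in both, everything else excluded."""
    if set(groups1.labels) != set(groups2.labels):
        raise ValueError("stratifications cover different sample universes")
    labels = {}
    for s, l1 in groups1.labels.items():
        l2 = groups2.labels[s]
        labels[s] = l1 if (l1 == l2 and l1 in ("high", "low")) else "mid"
    out = StratifiedGroups(labels)
    if not out.high or not out.low:
        empty = "high" if not out.high else "low"
        raise ValueError(f"stratum empty: combined {empty} group has no samples")
    return out


def prognostic_roc(
    sample_ids: Sequence[str],
    scores: Sequence[float],
    clinical: ClinicalTable,
    horizon_months: float = 60.0,
    higher_is_protective: bool = True,
) -> ROCResult:
    """ROC of a per-sample score for death within a fixed horizon.

    Cases die within the horizon; controls are followed beyond it without an
    event before it.  Subjects censored before the horizon are excluded.  A
    protective score is negated before the sweep so that larger values point
    toward the case class.
    """
    pos = {s: i for i, s in enumerate(clinical.sample_ids)}
    scores = np.asarray(scores, dtype=float)
    idx = np.array([pos[s] for s in sample_ids])
    time = clinical.time[idx]
    event = clinical.event[idx].astype(bool)
    is_case = event & (time <= horizon_months)
    is_control = time > horizon_months
    keep = is_case | is_control
    y = is_case[keep]
    s = scores[keep]
    n_cases = int(y.sum())
    n_controls = int((~y).sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError(
            f"need >=1 case and >=1 control at horizon {horizon_months} "
            f"(got {n_cases} cases, {n_controls} controls)"
        )
    if higher_is_protective:
        s = -s
    # sweep thresholds from high to low; ties collapse onto one point
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(~y_sorted)
    last_of_block = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = np.r_[0.0, tps[last_of_block] / n_cases, 1.0]
    fpr = np.r_[0.0, fps[last_of_block] / n_controls, 1.0]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr=fpr, tpr=tpr, auc=auc, horizon_months=horizon_months,
                     n_cases=n_cases, n_controls=n_controls)
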