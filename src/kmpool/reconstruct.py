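"""Reconstruction of pseudo individual-patient data from published
Kaplan-Meier aggregates.

Published trials report a KM curve (digitized to (time, survival) pairs)
and a numbers-at-risk table. Between consecutive risk-table times the
number of patients leaving the risk set is known exactly
(n_j - n_{j+1}); what is not known is how it splits into events and
censorings. Following the curve-fitting approach of Hoyle & Henley, the
split (d_j, c_j) is chosen by exhaustive integer search so that the implied
conditional survival over the interval - with censoring treated as uniform
through the interval, approximated by removing c_j/2 from the risk set
before events - is as close as possible to the reported ratio
S(T_{j+1})/S(T_j). Events are then placed at the digitized step times
(apportioned to steps proportionally to drop sizes, largest-remainder
rounding) and censorings at evenly spaced times inside the interval.

Patients still at risk after the last risk-table time are allocated from
residual curve drops and administratively censored at the curve's end; for
that terminal block the censoring is at the very end of follow-up, so no
half-interval risk-set correction is applied.

All times are months from randomization/surgery; intervals are half-open
[T_j, T_{j+1}) for counts, with curve drops at g, T_j < g <= T_{j+1},
attributed to interval j (the reported ratio S(T_{j+1})/S(T_j) includes a
drop exactly at T_{j+1}).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import km_estimate

__all__ = [
    "DigitizedCurve",
    "RiskTable",
    "IntervalCounts",
    "FidelityReport",
    "preprocess_curve",
    "estimate_interval_counts",
    "expand_to_ipd",
    "reconstruct_arm",
]


@dataclass
class DigitizedCurve:
    """Cleaned digitized KM curve for one trial arm.

    Invariants (enforced by :func:`preprocess_curve`): times strictly
    increasing starting at 0 with survival 1.0; survival non-increasing in
    [0, 1].
    """

    arm: str
    times: np.ndarray
    survival: np.ndarray

    def survival_at(self, t) -> np.ndarray:
        """S(t) with step-function (last value carried forward) semantics."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        return self.survival[np.clip(idx, 0, None)]


@dataclass
class RiskTable:
    """Numbers at risk at scheduled follow-up times."""

    times: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.n_at_risk = np.asarray(self.n_at_risk, dtype=int)
        if self.times.size == 0 or self.times[0] != 0:
            raise ValueError("risk table must start at time 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("risk-table times must be strictly increasing")
        if np.any(self.n_at_risk < 0):
            raise ValueError("numbers at risk must be non-negative")
        if np.any(np.diff(self.n_at_risk) > 0):
            raise ValueError("numbers at risk must be non-increasing")


@dataclass
class IntervalCounts:
    """Events/censorings allocated to each inter-risk-time interval.

    The final entry is the terminal block after the last risk-table time
    (``terminal=True``): its censorings are administrative, at the curve's
    last time, rather than spread through the interval.
    """

    t_start: np.ndarray
    t_end: np.ndarray
    n_start: np.ndarray
    d: np.ndarray
    c: np.ndarray
    terminal: np.ndarray
    target_ratio: np.ndarray
    achieved_ratio: np.ndarray


@dataclass
class FidelityReport:
    """Quality control: how well the reconstruction reproduces its inputs."""

    max_km_deviation: float
    km_deviation_at: dict
    at_risk_difference: dict
    n_records: int
    n_events: int
    n_censored: int
    warnings: list = field(default_factory=list)


def preprocess_curve(points, arm: str = "") -> DigitizedCurve:
    """Clean raw digitized coordinates into a valid step function.

    Values are clipped to [0, 1], duplicate times collapsed to the lowest
    survival, (0, 1.0) prepended if absent, and survival made non-increasing
    by a running minimum (manual digitization jitters upward as well as
    downward).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be a sequence of (time, survival) pairs")
    if np.unique(pts[:, 0]).size < 2:
        raise ValueError("curve needs at least two distinct time points")
    if np.any(pts[:, 0] < 0):
        raise ValueError("times must be non-negative")
    order = np.argsort(pts[:, 0], kind="mergesort")
    t, s = pts[order, 0], np.clip(pts[order, 1], 0.0, 1.0)
    # collapse duplicate times keeping the lowest survival
    keep_t, keep_s = [], []
    for ti, si in zip(t, s):
        if keep_t and ti == keep_t[-1]:
            keep_s[-1] = min(keep_s[-1], si)
        else:
            keep_t.append(ti)
            keep_s.append(si)
    t = np.array(keep_t)
    s = np.array(keep_s)
    if t[0] != 0.0:
        t = np.insert(t, 0, 0.0)
        s = np.insert(s, 0, 1.0)
    else:
        s[0] = 1.0
    s = np.minimum.accumulate(s)
    if t.size < 2:
        raise ValueError("curve needs at least two distinct time points")
    return DigitizedCurve(arm=arm, times=t, survival=s)


def _best_split(total: int, n_start: int, target: float, correct_half: bool):
    """Exhaustive integer search for the event/censoring split of one interval.

    Minimizes |implied - target| conditional survival over d in 0..total with
    c = total - d; ``correct_half`` applies the uniform-censoring half-risk-set
    correction (off for the terminal administrative block). Ties break to the
    smaller event count.
    """
    if total <= 0 or n_start <= 0:
        return 0, max(total, 0), 1.0
    d_grid = np.arange(total + 1)
    c_grid = total - d_grid
    denom = n_start - (c_grid / 2.0 if correct_half else 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        implied = np.where(denom > 0, 1.0 - d_grid / denom, np.where(d_grid > 0, 0.0, 1.0))
    err = np.abs(implied - target)
    best = int(np.argmin(err))  # argmin returns the first (smallest d) on ties
    return best, total - best, float(implied[best])


def estimate_interval_counts(curve: DigitizedCurve, risk: RiskTable) -> IntervalCounts:
    """Allocate events and censorings to each risk-table interval.

    Survival at risk-table times not on the curve grid is carried forward
    from the last digitized value (KM step-function semantics). A terminal
    block covering [last risk time, curve end] absorbs the patients still at
    risk, using residual curve drops for events and administrative censoring
    at the curve's last time.
    """
    times = risk.times
    n = risk.n_at_risk.astype(int)
    t_end_curve = float(curve.times[-1])
    S = curve.survival_at(times)

    t0s, t1s, n0s, ds, cs, terms, targs, achs = [], [], [], [], [], [], [], []
    for j in range(times.size - 1):
        total = int(n[j] - n[j + 1])
        if total < 0:  # defensive: validated tables cannot reach this
            warnings.warn(
                f"risk table increases across [{times[j]}, {times[j+1]}); clipping to 0",
                stacklevel=2,
            )
            total = 0
        target = float(S[j + 1] / S[j]) if S[j] > 0 else 1.0
        d, c, ach = _best_split(total, int(n[j]), target, correct_half=True)
        t0s.append(times[j]); t1s.append(times[j + 1]); n0s.append(int(n[j]))
        ds.append(d); cs.append(c); terms.append(False)
        targs.append(target); achs.append(ach)

    # terminal block: everyone still at risk at the last risk-table time
    n_last = int(n[-1])
    t_last = float(times[-1])
    t_term = max(t_end_curve, t_last)
    S_last = float(S[-1])
    S_term = float(curve.survival_at(t_term)[0])
    target = S_term / S_last if S_last > 0 else 1.0
    d, c, ach = _best_split(n_last, n_last, target, correct_half=False)
    t0s.append(t_last); t1s.append(t_term); n0s.append(n_last)
    ds.append(d); cs.append(c); terms.append(True)
    targs.append(target); achs.append(ach)

    return IntervalCounts(
        t_start=np.array(t0s),
        t_end=np.array(t1s),
        n_start=np.array(n0s, dtype=int),
        d=np.array(ds, dtype=int),
        c=np.array(cs, dtype=int),
        terminal=np.array(terms, dtype=bool),
        target_ratio=np.array(targs),
        achieved_ratio=np.array(achs),
    )


def _largest_remainder(total: int, shares: np.ndarray) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``shares``."""
    shares = np.asarray(shares, dtype=float)
    if shares.sum() <= 0:
        shares = np.ones_like(shares)
    quota = total * shares / shares.sum()
    base = np.floor(quota).astype(int)
    rem = total - base.sum()
    if rem > 0:
        # distribute leftovers by largest fractional part, earlier times first
        frac = quota - base
        order = np.lexsort((np.arange(frac.size), -frac))
        base[order[:rem]] += 1
    return base


def expand_to_ipd(
    counts: IntervalCounts, curve: DigitizedCurve, arm: str, trial_id: str
) -> pd.DataFrame:
    """Turn interval counts into one record per patient.

    Events go to the digitized step times inside each interval (drops at g
    with t_start < g <= t_end), apportioned proportionally to the drop
    sizes with largest-remainder rounding; if an interval has events but no
    visible step (possible under digitization noise) they fall at the
    interval midpoint. Non-terminal censorings are spread evenly strictly
    inside the interval; terminal censorings sit at the curve's last time.
    """
    drops_t = curve.times[1:]
    drops_s = -np.diff(curve.survival)
    rec_t, rec_e = [], []
    for j in range(counts.t_start.size):
        a, b = counts.t_start[j], counts.t_end[j]
        d, c = int(counts.d[j]), int(counts.c[j])
        if d > 0:
            in_int = (drops_t > a) & (drops_t <= b) & (drops_s > 0)
            st = drops_t[in_int]
            if st.size == 0:
                st = np.array([(a + b) / 2.0 if b > a else b])
                alloc = np.array([d])
            else:
                alloc = _largest_remainder(d, drops_s[in_int])
            for ti, ki in zip(st, alloc):
                rec_t.extend([ti] * int(ki))
                rec_e.extend([1] * int(ki))
        if c > 0:
            if counts.terminal[j]:
                ct = np.full(c, b)
            else:
                ct = a + (np.arange(1, c + 1) / (c + 1)) * (b - a)
            rec_t.extend(ct.tolist())
            rec_e.extend([0] * c)
    df = pd.DataFrame(
        {
            "trial_id": trial_id,
            "arm": arm,
            "patient_id": [f"{trial_id}_{arm}_{i:05d}" for i in range(len(rec_t))],
            "time_months": rec_t,
            "event": rec_e,
        }
    )
    return df.sort_values("time_months", kind="mergesort", ignore_index=True)


def reconstruct_arm(
    curve: DigitizedCurve, risk: RiskTable, arm: str | None = None, trial_id: str = "trial"
) -> tuple[pd.DataFrame, FidelityReport]:
    """Full reconstruction of one arm: counts, expansion and a fidelity check.

    The report compares the KM curve of the reconstructed records with the
    input curve at every risk-table time, and the implied with the reported
    numbers at risk.
    """
    arm = arm if arm is not None else (curve.arm or "arm")
    counts = estimate_interval_counts(curve, risk)
    ipd = expand_to_ipd(counts, curve, arm=arm, trial_id=trial_id)
    warns = []
    if len(ipd) != int(risk.n_at_risk[0]):  # pragma: no cover - conservation guard
        warns.append(
            f"record count {len(ipd)} != initial number at risk {risk.n_at_risk[0]}"
        )

    km = km_estimate(ipd["time_months"].to_numpy(), ipd["event"].to_numpy(), label=arm)
    dev = {}
    for t in risk.times:
        dev[float(t)] = abs(km.survival_at(t) - float(curve.survival_at(t)[0]))
    atrisk_diff = {}
    rec_times = ipd["time_months"].to_numpy()
    for t, n_rep in zip(risk.times, risk.n_at_risk):
        implied = int((rec_times >= t).sum())
        atrisk_diff[float(t)] = implied - int(n_rep)
    report = FidelityReport(
        max_km_deviation=float(max(dev.values())),
        km_deviation_at=dev,
        at_risk_difference=atrisk_diff,
        n_records=int(len(ipd)),
        n_events=int(ipd["event"].sum()),
        n_censored=int((1 - ipd["event"]).sum()),
        warnings=warns,
    )
    return ipd, report
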