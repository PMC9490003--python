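"""Pseudo individual-patient data from digitized Kaplan–Meier curves.

Published KM figures plus their number-at-risk tables are enough to recover an
approximate patient-level (time, event) dataset: within each risk-table
interval, censoring is assumed uniformly spread, and event counts are chosen
so that the product-limit estimator of the output tracks the digitized
survival probabilities while the implied number at risk reconciles with the
printed risk table (the interval algorithm of Guyot and colleagues).

Digitized curves are read from two-column delimited text (time, survival)
with a separate risk-table file (time, n_at_risk), matching common
plot-digitizer exports. Pseudo-IPD is written as (id, time, event) tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = [
    "DigitizedCurve",
    "PseudoIPD",
    "ReconciliationError",
    "reconstruct_ipd",
    "km_estimate",
]


class ReconciliationError(ValueError):
    """Risk table inconsistent with any non-negative event/censor allocation."""


@dataclass
class DigitizedCurve:
    """Digitizer-style export of one KM curve: step coordinates plus the
    number-at-risk table, both on the month time axis."""

    times: np.ndarray                 # strictly increasing, months
    survival: np.ndarray              # non-increasing after monotonization
    risk_times: np.ndarray
    n_at_risk: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        self.risk_times = np.asarray(self.risk_times, dtype=float)
        self.n_at_risk = np.asarray(self.n_at_risk, dtype=int)
        if self.times.size != self.survival.size:
            raise ValueError("times and survival must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("digitized times must be strictly increasing")
        if np.any((self.survival < -1e-9) | (self.survival > 1 + 1e-9)):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if self.risk_times.size != self.n_at_risk.size or self.risk_times.size < 1:
            raise ValueError("risk table must be non-empty and rectangular")
        if np.any(np.diff(self.n_at_risk) > 0):
            raise ValueError("number at risk must be non-increasing")
        if np.any(self.n_at_risk < 0):
            raise ValueError("number at risk must be non-negative")

    # -- text I/O (plot-digitizer style) -----------------------------------

    def to_files(self, curve_path: str | Path, risk_path: str | Path,
                 sep: str = "\t") -> None:
        pd.DataFrame({"time": self.times, "survival": self.survival}).to_csv(
            curve_path, sep=sep, index=False)
        pd.DataFrame({"time": self.risk_times, "n_at_risk": self.n_at_risk}).to_csv(
            risk_path, sep=sep, index=False)

    @classmethod
    def from_files(cls, curve_path: str | Path, risk_path: str | Path,
                   label: str = "", sep: str = "\t") -> "DigitizedCurve":
        cv = pd.read_csv(curve_path, sep=sep)
        rt = pd.read_csv(risk_path, sep=sep)
        return cls(times=cv.iloc[:, 0].to_numpy(), survival=cv.iloc[:, 1].to_numpy(),
                   risk_times=rt.iloc[:, 0].to_numpy(),
                   n_at_risk=rt.iloc[:, 1].to_numpy(), label=label)


@dataclass
class PseudoIPD:
    """Reconstructed or simulated right-censored records for one arm/endpoint."""

    times: np.ndarray
    events: np.ndarray                # 1 = event, 0 = censored
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if self.times.size == 0:
            raise ValueError("PseudoIPD requires at least one record")
        if self.times.size != self.events.size:
            raise ValueError("times and events must have equal length")
        if np.any(self.times <= 0):
            raise ValueError("record times must be positive")
        if not np.isin(self.events, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": np.arange(1, len(self) + 1),
                             "time": self.times, "event": self.events})

    def to_file(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_file(cls, path: str | Path, label: str = "", sep: str = "\t") -> "PseudoIPD":
        df = pd.read_csv(path, sep=sep)
        return cls(times=df["time"].to_numpy(), events=df["event"].to_numpy(),
                   label=label)


# ---------------------------------------------------------------------------
# Guyot-style reconstruction
# ---------------------------------------------------------------------------

def reconstruct_ipd(curve: DigitizedCurve, max_iter: int = 60,
                    rise_tolerance: float = 0.02) -> PseudoIPD:
    """Recover pseudo-IPD whose KM estimate tracks the digitized curve.

    Censoring within each risk-table interval is assumed uniformly spread
    between digitized time points; the censor count per interval is adjusted
    iteratively until the implied number at risk matches the printed risk
    table at the next interval boundary. Digitizer jitter up to
    ``rise_tolerance`` is absorbed by an isotonic clamp; larger rises in the
    survival coordinates are treated as corrupt input.
    """
    if curve.risk_times.size < 2:
        raise ValueError("need at least two risk-table rows")
    if curve.n_at_risk[0] <= 0:
        raise ValueError("first risk count must be positive")
    rises = np.diff(curve.survival)
    if rises.size and float(np.max(rises, initial=0.0)) > rise_tolerance:
        raise ValueError(
            f"survival probabilities increase by {np.max(rises):.3f} "
            f"(> jitter tolerance {rise_tolerance:g}): not a KM curve")

    # isotonic clamp absorbs digitizer jitter
    t = curve.times.copy()
    s = np.minimum.accumulate(np.clip(curve.survival, 0.0, 1.0))
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        s = np.concatenate([[1.0], s])
    if s[0] < 1.0:
        s[0] = 1.0

    rt, nr = curve.risk_times, curve.n_at_risk
    K = t.size

    # digitized indices belonging to each risk interval [rt[j], rt[j+1])
    lower = np.searchsorted(t, rt, side="left")
    bounds = list(lower) + [K]

    times_out: list[float] = []
    events_out: list[int] = []

    n_cur = int(nr[0])
    s_km_prev = 1.0     # running product-limit value of the reconstruction
    for j in range(rt.size):
        lo, hi = bounds[j], bounds[j + 1]
        idx = np.arange(lo, hi)
        if idx.size == 0 or n_cur == 0:
            continue
        last_interval = j == rt.size - 1
        n_target = None if last_interval else int(nr[j + 1])
        if n_target is not None and n_target > n_cur:
            raise ReconciliationError(
                f"risk table rises from {n_cur} to {n_target} in interval {j}")

        t_end = float(rt[j + 1]) if not last_interval else float(t[-1]) + 1e-9

        def allocate(c_total: int):
            """Walk the interval with c_total censorings spread uniformly;
            returns the emitted (time, event) records, the number still at
            risk at the interval end, and the running KM value."""
            cen_times = (rt[j] + (np.arange(c_total) + 0.5) *
                         (t_end - rt[j]) / c_total) if c_total > 0 \
                else np.empty(0)
            n = n_cur
            s_prev = s_km_prev
            rec_t: list[float] = []
            rec_e: list[int] = []
            ci = 0
            for i in idx:
                while ci < c_total and cen_times[ci] < t[i] and n > 0:
                    rec_t.append(float(max(cen_times[ci], 1e-6)))
                    rec_e.append(0)
                    ci += 1
                    n -= 1
                if n > 0 and s_prev > 0:
                    d = int(round(n * (1.0 - s[i] / s_prev)))
                    d = min(max(d, 0), n)
                else:
                    d = 0
                if d > 0:
                    s_prev *= 1.0 - d / n
                    n -= d
                    rec_t.extend([float(t[i])] * d)
                    rec_e.extend([1] * d)
            while ci < c_total and n > 0:
                rec_t.append(float(max(cen_times[ci], 1e-6)))
                rec_e.append(0)
                ci += 1
                n -= 1
            return rec_t, rec_e, n, s_prev

        if last_interval:
            rec_t, rec_e, n_end, s_end = allocate(0)
        else:
            # events explain the survival drop; censorings account for the
            # residual risk-table loss. n_end(c) is (weakly) decreasing in c,
            # so bisect for the smallest c reconciling the next risk count.
            c_lo, c_hi = 0, n_cur
            for _ in range(max_iter):
                if c_lo >= c_hi:
                    break
                c_mid = (c_lo + c_hi) // 2
                if allocate(c_mid)[2] <= n_target:
                    c_hi = c_mid
                else:
                    c_lo = c_mid + 1
            best = min(range(max(c_lo - 1, 0), min(c_lo + 2, n_cur + 1)),
                       key=lambda c: (abs(allocate(c)[2] - n_target), c))
            rec_t, rec_e, n_end, s_end = allocate(best)
            if abs(n_end - n_target) > max(2, 0.02 * nr[0]):
                raise ReconciliationError(
                    f"interval {j}: cannot reconcile risk table "
                    f"(residual {n_end - n_target} patients at t={rt[j + 1]:g})")

        times_out.extend(rec_t)
        events_out.extend(rec_e)
        n_cur = n_end
        s_km_prev = s_end

    # patients still at risk after the last digitized point: administratively
    # censored at the last digitized time
    if n_cur > 0:
        times_out.extend([float(t[-1])] * n_cur)
        events_out.extend([0] * n_cur)

    times_arr = np.asarray(times_out)
    order = np.argsort(times_arr, kind="stable")
    return PseudoIPD(times=times_arr[order],
                     events=np.asarray(events_out)[order],
                     label=curve.label)


# ---------------------------------------------------------------------------
# Product-limit estimate (validation / round-trip)
# ---------------------------------------------------------------------------

def km_estimate(ipd: PseudoIPD, risk_times=None) -> DigitizedCurve:
    """Kaplan–Meier step function of a pseudo-IPD dataset, with the number at
    risk evaluated at the requested times (default: whole months to the last
    observation)."""
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.times, ipd.events)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    if times[0] == 0.0 and times.size > 1:
        times, surv = times[1:], surv[1:]
    if risk_times is None:
        risk_times = np.arange(0.0, float(np.max(ipd.times)) + 1.0, 6.0)
    risk_times = np.asarray(risk_times, dtype=float)
    n_at_risk = np.array([(ipd.times >= rt - 1e-12).sum() for rt in risk_times])
    return DigitizedCurve(times=times, survival=surv, risk_times=risk_times,
                          n_at_risk=n_at_risk, label=ipd.label)


def km_survival_at(ipd: PseudoIPD, t) -> np.ndarray:
    """KM survival probability evaluated at arbitrary times (step function)."""
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.times, ipd.events)
    return kmf.survival_function_at_times(np.asarray(t, dtype=float)).to_numpy()
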