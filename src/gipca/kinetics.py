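"""Force-plate kinetics: filtering, COP/COM kinematics, gait-initiation events
and the 11-variable feature set.

A gait-initiation (GI) trial is a six-channel force-plate recording (three
forces, three moments).  The processing chain is:

1. zero-phase low-pass filtering (2nd-order Butterworth, 10 Hz cut-off) of
   every channel;
2. centre of pressure (COP) from the plate moments and the vertical force;
3. centre of mass (COM) horizontal acceleration from Newton's second law
   (``a = F/m``) and velocity by trapezoidal integration with ``v(t0) = 0``;
4. the four temporal landmarks — GI onset ``t0``, swing heel-off ``HO``,
   swing toe-off ``TO`` and heel contact ``HC`` — from the COP and
   vertical-force traces;
5. the 11 features of :data:`gipca.registry.FEATURES`.

Axis convention (declared once, used everywhere): ``x`` = mediolateral (ML),
``y`` = anteroposterior (AP), ``z`` = vertical up; with the plate origin on
its surface, ``COP_x = -My/Fz`` and ``COP_y = Mx/Fz``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import butter, sosfilt, sosfiltfilt

from .registry import FEATURES

G = 9.81  # gravitational acceleration, m/s^2

#: minimum vertical load (N) below which COP is undefined
DEFAULT_LOAD_THRESHOLD = 10.0


class GaitEventError(RuntimeError):
    """Raised when the expected GI landmarks cannot be located in a trial."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TrialRecording:
    """One participant-trial: force/moment time series on a single plate.

    Parameters
    ----------
    t : (n,) array
        Sample times in seconds, uniformly spaced at ``1/fs``.
    F : (n, 3) array
        Forces ``(Fx, Fy, Fz)`` in newtons (ML, AP, vertical-up).
    M : (n, 3) array
        Moments ``(Mx, My, Mz)`` in newton-metres about the plate origin.
    fs : float
        Sampling rate in hertz.
    mass : float
        Participant mass in kilograms (needed for COM kinematics).
    ground_truth : dict, optional
        Populated by the simulator: configured events, features and COP
        trajectory, used by recovery tests.
    """

    t: np.ndarray
    F: np.ndarray
    M: np.ndarray
    fs: float
    mass: float
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        n = self.t.shape[0]
        if self.F.shape != (n, 3) or self.M.shape != (n, 3):
            raise ValueError(
                f"channel shape mismatch: t has {n} samples, "
                f"F is {self.F.shape}, M is {self.M.shape}"
            )
        if self.mass <= 0:
            raise ValueError(f"mass must be positive, got {self.mass}")
        dt = np.diff(self.t)
        if n > 1 and not np.allclose(dt, 1.0 / self.fs, rtol=1e-6, atol=1e-9):
            raise ValueError("t must be uniformly sampled at 1/fs")

    # channel views -----------------------------------------------------
    @property
    def fx(self) -> np.ndarray:  # ML force
        return self.F[:, 0]

    @property
    def fy(self) -> np.ndarray:  # AP force
        return self.F[:, 1]

    @property
    def fz(self) -> np.ndarray:  # vertical force
        return self.F[:, 2]

    @property
    def n_samples(self) -> int:
        return self.t.shape[0]

    # I/O ---------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write the trial as a ``t,Fx,Fy,Fz,Mx,My,Mz`` CSV (SI units)."""
        df = pd.DataFrame(
            {
                "t": self.t,
                "Fx": self.F[:, 0], "Fy": self.F[:, 1], "Fz": self.F[:, 2],
                "Mx": self.M[:, 0], "My": self.M[:, 1], "Mz": self.M[:, 2],
            }
        )
        df.to_csv(path, index=False)
        if self.ground_truth and "events" in self.ground_truth:
            ev = self.ground_truth["events"]
            side = Path(path).with_suffix("").as_posix() + ".events.csv"
            pd.DataFrame(
                {"event": ["t0", "HO", "TO", "HC"],
                 "time_s": [ev.t0, ev.HO, ev.TO, ev.HC]}
            ).to_csv(side, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, mass: float, fs: float | None = None
                 ) -> "TrialRecording":
        """Read a ``t,Fx,Fy,Fz,Mx,My,Mz`` CSV.  ``fs`` defaults to the
        reciprocal median time step."""
        df = pd.read_csv(path)
        t = df["t"].to_numpy(float)
        if fs is None:
            fs = 1.0 / float(np.median(np.diff(t)))
        return cls(
            t=t,
            F=df[["Fx", "Fy", "Fz"]].to_numpy(float),
            M=df[["Mx", "My", "Mz"]].to_numpy(float),
            fs=fs,
            mass=mass,
        )


@dataclass(frozen=True)
class GIEvents:
    """The four temporal landmarks of gait initiation (seconds)."""

    t0: float   # GI onset
    HO: float   # swing heel-off
    TO: float   # swing toe-off
    HC: float   # swing heel (foot) contact

    def __post_init__(self) -> None:
        if not (self.t0 < self.HO < self.TO < self.HC):
            raise ValueError(
                "event ordering violated: require t0 < HO < TO < HC, got "
                f"t0={self.t0:.4f}, HO={self.HO:.4f}, "
                f"TO={self.TO:.4f}, HC={self.HC:.4f}"
            )


@dataclass(frozen=True)
class GIFeatures:
    """The 11 gait-initiation variables (units in :data:`gipca.registry.UNITS`)."""

    apa_ml: float
    apa_ap: float
    cop_shift_ap: float
    cop_shift_ml: float
    vcom_ap_ho: float
    vcom_ap_to: float
    vcom_ap_hc: float
    vcom_ml_ho: float
    vcom_ml_to: float
    foot_lift: float
    fz_peak: float

    def __post_init__(self) -> None:
        if not self.foot_lift > 0:
            raise ValueError(f"foot_lift must be > 0 (TO after HO), got {self.foot_lift}")
        if not self.fz_peak > 0:
            raise ValueError(f"fz_peak must be > 0, got {self.fz_peak}")

    def as_dict(self) -> dict[str, float]:
        d = dataclasses.asdict(self)
        return {name: d[name] for name in FEATURES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURES], dtype=float)


# ---------------------------------------------------------------------------
# signal processing primitives
# ---------------------------------------------------------------------------

def lowpass_filter(
    x: np.ndarray,
    fs: float,
    fc: float = 10.0,
    order: int = 2,
    zero_phase: bool = True,
) -> np.ndarray:
    """Butterworth low-pass filter, zero-phase (forward-backward) by default.

    Zero-phase application avoids the group delay that would otherwise bias
    event times; it squares the magnitude response (the single-pass -3 dB
    point becomes -6 dB).
    """
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    if not fc < fs / 2:
        raise ValueError(f"cut-off {fc} Hz must be below Nyquist {fs / 2} Hz")
    sos = butter(order, fc, btype="low", fs=fs, output="sos")
    x = np.asarray(x, dtype=float)
    if zero_phase:
        return sosfiltfilt(sos, x, axis=0)
    return sosfilt(sos, x, axis=0)


def compute_cop(
    rec: TrialRecording,
    load_threshold: float = DEFAULT_LOAD_THRESHOLD,
    filtered: bool = False,
    fc: float = 10.0,
    order: int = 2,
) -> np.ndarray:
    """COP trajectory (n, 2) in metres: columns ``(COP_x/ML, COP_y/AP)``.

    ``COP_x = -My/Fz``, ``COP_y = Mx/Fz``.  Samples whose vertical load falls
    below ``load_threshold`` (default 10 N) are undefined and returned as NaN
    so that downstream extrema ignore them.
    """
    if filtered:
        fz = lowpass_filter(rec.fz, rec.fs, fc, order)
        mx = lowpass_filter(rec.M[:, 0], rec.fs, fc, order)
        my = lowpass_filter(rec.M[:, 1], rec.fs, fc, order)
    else:
        fz, mx, my = rec.fz, rec.M[:, 0], rec.M[:, 1]
    valid = np.abs(fz) >= load_threshold
    cop = np.full((rec.n_samples, 2), np.nan)
    cop[valid, 0] = -my[valid] / fz[valid]
    cop[valid, 1] = mx[valid] / fz[valid]
    return cop


def com_kinematics(
    rec: TrialRecording,
    t0: float | None = None,
    fc: float = 10.0,
    order: int = 2,
    baseline_s: float = 0.5,
) -> dict[str, np.ndarray]:
    """Horizontal COM acceleration and velocity from Newton's second law.

    ``a = F_horizontal / mass`` on the filtered forces, after subtracting the
    quiet-standing baseline mean (removes force-plate offsets); velocity is
    the cumulative trapezoidal integral with ``v(t0) = 0``.

    Returns a dict with keys ``acc_ap``, ``acc_ml``, ``vel_ap``, ``vel_ml``.
    """
    if rec.mass <= 0:  # defensive; TrialRecording already validates
        raise ValueError("mass must be positive")
    i0 = 0 if t0 is None else int(np.searchsorted(rec.t, t0))
    nb = max(2, min(int(round(baseline_s * rec.fs)), max(i0, 2)))
    out: dict[str, np.ndarray] = {}
    for key, raw in (("ap", rec.fy), ("ml", rec.fx)):
        f = lowpass_filter(raw, rec.fs, fc, order)
        f = f - f[:nb].mean()
        a = f / rec.mass
        v = cumulative_trapezoid(a, rec.t, initial=0.0)
        v = v - v[i0]
        out[f"acc_{key}"] = a
        out[f"vel_{key}"] = v
    return out


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------

def _sustained_crossing(dev: np.ndarray, thr: float, start: int, sustain: int
                        ) -> int | None:
    """First index >= start where ``dev > thr`` holds for ``sustain`` samples."""
    above = dev > thr
    if sustain <= 1:
        idx = np.flatnonzero(above[start:])
        return None if idx.size == 0 else start + int(idx[0])
    run = np.convolve(above.astype(np.int32), np.ones(sustain, np.int32), "valid")
    hits = np.flatnonzero(run[start:] == sustain)
    return None if hits.size == 0 else start + int(hits[0])


def detect_axis_onsets(
    rec: TrialRecording,
    k_sigma: float = 2.5,
    min_sustain_ms: float = 50.0,
    baseline_s: float = 0.5,
    cop_floor_m: float = 1e-4,
    raw_floor_m: float = 1e-9,
    fc: float = 10.0,
    order: int = 2,
) -> dict[str, float | None]:
    """Per-axis COP movement onsets (``{"ml": t | None, "ap": t | None}``).

    Detection is two-stage: a sustained crossing of
    ``max(k_sigma * baseline SD, cop_floor_m)`` on the zero-phase-filtered
    COP locates the movement coarsely, then the onset is refined by walking
    back on the *unfiltered* COP (which carries no acausal filter leakage)
    to the last sample inside the raw baseline band.
    """
    cop_f = compute_cop(rec, filtered=True, fc=fc, order=order)
    cop_r = compute_cop(rec, filtered=False)
    nb = int(round(baseline_s * rec.fs))
    if nb < 4:
        raise GaitEventError("baseline window too short for onset statistics")
    sustain = max(1, int(round(min_sustain_ms / 1000.0 * rec.fs)))
    onsets: dict[str, float | None] = {}
    for axis, col in (("ml", 0), ("ap", 1)):
        xf, xr = cop_f[:, col], cop_r[:, col]
        if np.isnan(xf[:nb]).any():
            raise GaitEventError("vertical load below threshold during baseline")
        mu_f, sd_f = xf[:nb].mean(), xf[:nb].std()
        thr = max(k_sigma * sd_f, cop_floor_m)
        cross = _sustained_crossing(np.abs(xf - mu_f), thr, nb, sustain)
        if cross is None:
            onsets[axis] = None
            continue
        mu_r, sd_r = np.nanmean(xr[:nb]), np.nanstd(xr[:nb])
        band = max(2.0 * sd_r, raw_floor_m)
        j = cross
        while j > 0 and abs(xr[j - 1] - mu_r) > band:
            j -= 1
        # j is the first deviating sample; movement starts at the last
        # sample still inside the baseline band
        onsets[axis] = float(rec.t[max(j - 1, 0)])
    return onsets


def detect_events(
    rec: TrialRecording,
    k_sigma: float = 2.5,
    min_sustain_ms: float = 50.0,
    baseline_s: float = 0.5,
    cop_floor_m: float = 1e-4,
    unload_frac: float = 0.05,
    exe_drop_frac: float = 0.25,
    fc: float = 10.0,
    order: int = 2,
) -> GIEvents:
    """Locate ``t0 < HO < TO < HC`` on a single-plate GI trial.

    Criteria (all on zero-phase-filtered traces):

    * ``t0`` — earliest sustained COP deviation from the quiet-standing
      baseline on either horizontal axis (``k_sigma`` baseline SDs for at
      least ``min_sustain_ms``), refined on the raw COP;
    * the execution phase is anchored by the first Fz drop more than
      ``exe_drop_frac`` below body weight (the plate unloads once the swing
      foot has left and weight transfers forward);
    * ``HC`` — the foot-strike force peak: Fz maximum after that drop;
    * ``TO`` — the Fz local maximum (push-off overshoot) between ``t0`` and
      the drop (end of double support);
    * ``HO`` — argmin of the first Fz unloading dip before ``TO`` exceeding
      ``unload_frac`` of body weight (swing-leg unloading).
    """
    onsets = detect_axis_onsets(
        rec, k_sigma, min_sustain_ms, baseline_s, cop_floor_m,
        fc=fc, order=order,
    )
    found = [v for v in onsets.values() if v is not None]
    if not found:
        raise GaitEventError("no gait initiation detected (COP never leaves baseline)")
    t0 = min(found)
    i_t0 = int(np.searchsorted(rec.t, t0))

    fz = lowpass_filter(rec.fz, rec.fs, fc, order)
    nb = int(round(baseline_s * rec.fs))
    bw = fz[:nb].mean()  # body weight in N from quiet standing

    # execution-phase unloading: first drop well below body weight after t0
    drops = np.flatnonzero(fz[i_t0:] < (1.0 - exe_drop_frac) * bw)
    if drops.size == 0:
        raise GaitEventError(
            "no execution-phase unloading found after t0 (vertical force "
            f"never drops {exe_drop_frac:.0%} below body weight)")
    i_drop = i_t0 + int(drops[0])
    # foot-strike peak: Fz maximum after the unloading began
    i_hc = i_drop + int(np.argmax(fz[i_drop:]))
    if fz[i_hc] - fz[i_drop:i_hc + 1].min() < 0.05 * bw:
        raise GaitEventError("no foot-strike force peak after the "
                             "execution-phase unloading")
    i_to = i_t0 + int(np.argmax(fz[i_t0:i_drop]))

    dip = bw - fz[i_t0:i_to]
    deep = dip > unload_frac * bw
    if not deep.any():
        raise GaitEventError(
            f"no heel-off unloading dip exceeding {unload_frac:.0%} body weight"
        )
    first = int(np.flatnonzero(deep)[0])
    stop = int(np.flatnonzero(~deep[first:])[0]) + first if (~deep[first:]).any() \
        else deep.size
    i_ho = i_t0 + first + int(np.argmax(dip[first:stop]))

    try:
        return GIEvents(
            t0=float(t0),
            HO=float(rec.t[i_ho]),
            TO=float(rec.t[i_to]),
            HC=float(rec.t[i_hc]),
        )
    except ValueError as exc:
        raise GaitEventError(f"landmark ordering inconsistent: {exc}") from exc


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def extract_features(
    rec: TrialRecording,
    events: GIEvents | None = None,
    fc: float = 10.0,
    order: int = 2,
    k_sigma: float = 2.5,
    min_sustain_ms: float = 50.0,
    baseline_s: float = 0.5,
    cop_floor_m: float = 1e-4,
    peak_window_s: float = 0.15,
) -> GIFeatures:
    """Compute the 11-variable GI feature set for one trial.

    The APA durations are measured per axis (that axis's COP onset to HO);
    COP shifts are the maximal absolute filtered-COP displacement from the
    baseline mean inside ``[t0, HO]``; COM velocities are linearly
    interpolated at the landmarks; ``fz_peak`` is the filtered-Fz maximum in
    a ±``peak_window_s`` window around HC.
    """
    if events is None:
        events = detect_events(
            rec, k_sigma, min_sustain_ms, baseline_s, cop_floor_m,
            fc=fc, order=order,
        )
    if events.HC > rec.t[-1] + 1e-9 or events.t0 < rec.t[0] - 1e-9:
        raise ValueError("events fall outside the recording span")

    onsets = detect_axis_onsets(
        rec, k_sigma, min_sustain_ms, baseline_s, cop_floor_m,
        fc=fc, order=order,
    )
    apa: dict[str, float] = {}
    for axis in ("ml", "ap"):
        if onsets[axis] is None:
            raise GaitEventError(f"no COP onset found on the {axis.upper()} axis")
        apa[axis] = events.HO - onsets[axis]  # type: ignore[operator]

    cop_f = compute_cop(rec, filtered=True, fc=fc, order=order)
    nb = int(round(baseline_s * rec.fs))
    i_t0 = int(np.searchsorted(rec.t, events.t0))
    i_ho = int(np.searchsorted(rec.t, events.HO))
    shifts = {}
    for axis, col in (("ml", 0), ("ap", 1)):
        base = cop_f[:nb, col].mean()
        shifts[axis] = float(np.nanmax(np.abs(cop_f[i_t0:i_ho + 1, col] - base)))

    kin = com_kinematics(rec, t0=events.t0, fc=fc, order=order,
                         baseline_s=baseline_s)
    v_ap = np.interp([events.HO, events.TO, events.HC], rec.t, kin["vel_ap"])
    v_ml = np.interp([events.HO, events.TO], rec.t, kin["vel_ml"])

    fz = lowpass_filter(rec.fz, rec.fs, fc, order)
    lo = int(np.searchsorted(rec.t, events.HC - peak_window_s))
    hi = int(np.searchsorted(rec.t, events.HC + peak_window_s)) + 1
    fz_peak = float(fz[lo:hi].max())

    return GIFeatures(
        apa_ml=float(apa["ml"]),
        apa_ap=float(apa["ap"]),
        cop_shift_ap=shifts["ap"],
        cop_shift_ml=shifts["ml"],
        vcom_ap_ho=float(v_ap[0]),
        vcom_ap_to=float(v_ap[1]),
        vcom_ap_hc=float(v_ap[2]),
        vcom_ml_ho=float(v_ml[0]),
        vcom_ml_to=float(v_ml[1]),
        foot_lift=float(events.TO - events.HO),
        fz_peak=fz_peak,
    )
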