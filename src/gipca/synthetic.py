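"""Synthetic gait-initiation data: cohorts of feature vectors and raw
force-plate trials.

The study population this emulates is two groups of ten participants —
healthy elderly controls and Parkinsonian (PD) patients in the OFF-medication
state — each described by the 11 kinetic variables of
:data:`gipca.registry.FEATURES`.  No raw cohort table is publicly available,
so the generator is the test bed for the whole analysis chain:

* :func:`simulate_cohort` draws feature tables from two multivariate normal
  populations whose mean shift is concentrated where PD affects gait
  initiation most — the heel-contact force peak, the anteroposterior COM
  velocities and the APA durations.  The shared correlation structure is a
  three-factor model (a "loading/impact" factor, an "APA/postural" factor
  and a "propulsion velocity" factor) with small uniquenesses, so the
  population spectrum is dominated by three directions, as observed for the
  real cohort.
* :func:`simulate_trial` builds a six-channel force/moment waveform with the
  canonical GI phasing (quiet standing, APA COP excursion, swing-leg
  unloading at heel-off, execution-phase unloading, foot-strike force peak)
  from piecewise raised-cosine transitions, and stores its own ground truth
  (events, features, COP trajectory) for recovery tests.

The waveforms are band-limited below the 10 Hz analysis filter by
construction; they are deliberately *not* a forward-dynamics simulation —
only the structure the extraction chain relies on is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .kinetics import G, GIEvents, GIFeatures, TrialRecording
from .registry import FEATURES, GROUPS

# ---------------------------------------------------------------------------
# population parameters (the default study conditions)
# ---------------------------------------------------------------------------

#: Healthy-control population means, in registry order and units.
CONTROL_MEANS = np.array([
    0.38,    # apa_ml (s)
    0.42,    # apa_ap (s)
    0.035,   # cop_shift_ap (m)
    0.045,   # cop_shift_ml (m)
    0.12,    # vcom_ap_ho (m/s)
    0.45,    # vcom_ap_to (m/s)
    0.95,    # vcom_ap_hc (m/s)
    0.10,    # vcom_ml_ho (m/s)
    0.14,    # vcom_ml_to (m/s)
    0.12,    # foot_lift (s)
    824.0,   # fz_peak (N), ~1.2 body weights for 70 kg
])

#: Within-group population SDs (shared between groups).
FEATURE_SDS = np.array([
    0.06, 0.06, 0.008, 0.010, 0.030, 0.080, 0.120,
    0.025, 0.030, 0.025, 60.0,
])

#: Control-minus-PD shift in within-group SD units.  PD patients show smaller
#: APAs, COP excursions, propulsion velocities and heel-strike peaks, and a
#: slightly longer foot lift.
EFFECT_SD_UNITS = np.array([
    1.0, 1.0, 0.8, 0.8, 1.2, 1.2, 1.2, 0.6, 0.6, -0.5, 1.4,
])

# Three-factor structure of the standardized variables (rows: features,
# columns: loading/impact, APA/postural, propulsion factors).
_FACTOR_LOADINGS = np.array([
    [0.05, 0.85, 0.25],   # apa_ml
    [0.05, 0.82, 0.30],   # apa_ap
    [0.10, 0.70, 0.40],   # cop_shift_ap
    [0.05, 0.75, 0.30],   # cop_shift_ml
    [0.10, 0.25, 0.85],   # vcom_ap_ho
    [0.15, 0.20, 0.90],   # vcom_ap_to
    [0.30, -0.35, 0.80],  # vcom_ap_hc
    [0.05, 0.20, 0.75],   # vcom_ml_ho
    [0.05, 0.15, 0.80],   # vcom_ml_to
    [-0.15, 0.30, -0.55], # foot_lift
    [0.95, -0.10, 0.20],  # fz_peak
])

#: Uniqueness (idiosyncratic variance fraction) per standardized variable.
UNIQUENESS = 1e-3


def default_correlation(uniqueness: float = UNIQUENESS) -> np.ndarray:
    """Population correlation matrix of the 11 features (three-factor model).

    ``R = L L' + uniqueness * I`` with the rows of ``L`` scaled to squared
    norm ``1 - uniqueness``, so ``R`` has unit diagonal and is positive
    definite with three dominant eigenvalues.
    """
    L = _FACTOR_LOADINGS / np.linalg.norm(_FACTOR_LOADINGS, axis=1, keepdims=True)
    L = L * np.sqrt(1.0 - uniqueness)
    return L @ L.T + uniqueness * np.eye(L.shape[0])


def default_covariance(uniqueness: float = UNIQUENESS) -> np.ndarray:
    """Shared within-group covariance in physical units."""
    D = np.diag(FEATURE_SDS)
    return D @ default_correlation(uniqueness) @ D


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Two-group multivariate-normal population specification.

    ``covariance`` is shared between groups unless ``covariance_pd`` is
    given.  Validation rejects non-PSD covariances, naming the offending
    eigenvalue.
    """

    n_control: int = 10
    n_pd: int = 10
    feature_means_control: np.ndarray = field(
        default_factory=lambda: CONTROL_MEANS.copy())
    feature_means_pd: np.ndarray = field(
        default_factory=lambda: CONTROL_MEANS - EFFECT_SD_UNITS * FEATURE_SDS)
    covariance: np.ndarray = field(default_factory=default_covariance)
    covariance_pd: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.feature_means_control = np.asarray(self.feature_means_control, float)
        self.feature_means_pd = np.asarray(self.feature_means_pd, float)
        self.covariance = np.asarray(self.covariance, float)
        p = len(FEATURES)
        if self.n_control < 2 or self.n_pd < 2:
            raise ValueError("need at least 2 participants per group")
        for name, v in (("control", self.feature_means_control),
                        ("pd", self.feature_means_pd)):
            if v.shape != (p,):
                raise ValueError(
                    f"feature_means_{name} must have length {p}, got {v.shape}")
        for label, cov in (("covariance", self.covariance),
                           ("covariance_pd", self.covariance_pd)):
            if cov is None:
                continue
            cov = np.asarray(cov, float)
            if cov.shape != (p, p):
                raise ValueError(f"{label} must be {p}x{p}, got {cov.shape}")
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValueError(f"{label} must be symmetric")
            w = np.linalg.eigvalsh(cov)
            tol = -1e-10 * max(1.0, float(w[-1]))
            if w[0] < tol:
                raise ValueError(
                    f"{label} is not positive semi-definite: "
                    f"smallest eigenvalue {w[0]:.3e}")


def default_cohort_spec(
    n_control: int = 10,
    n_pd: int = 10,
    effect_scale: float = 1.0,
    seed: int = 0,
) -> CohortSpec:
    """The standard two-group study condition, with the group separation
    scaled by ``effect_scale`` (0 = identical populations, 1 = full PD
    effect profile)."""
    pd_means = CONTROL_MEANS - effect_scale * EFFECT_SD_UNITS * FEATURE_SDS
    return CohortSpec(
        n_control=n_control,
        n_pd=n_pd,
        feature_means_control=CONTROL_MEANS.copy(),
        feature_means_pd=pd_means,
        covariance=default_covariance(),
        seed=seed,
    )


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a labelled feature table from the two-group MVN population.

    Returns a DataFrame with columns ``participant_id, group`` followed by
    the 11 registry features; deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    cov_pd = spec.covariance if spec.covariance_pd is None \
        else np.asarray(spec.covariance_pd, float)
    x_ctrl = rng.multivariate_normal(
        spec.feature_means_control, spec.covariance,
        size=spec.n_control, method="eigh")
    x_pd = rng.multivariate_normal(
        spec.feature_means_pd, cov_pd, size=spec.n_pd, method="eigh")
    ids = [f"C{i + 1:02d}" for i in range(spec.n_control)] + \
          [f"P{i + 1:02d}" for i in range(spec.n_pd)]
    groups = [GROUPS[0]] * spec.n_control + [GROUPS[1]] * spec.n_pd
    df = pd.DataFrame(np.vstack([x_ctrl, x_pd]), columns=list(FEATURES))
    df.insert(0, "group", groups)
    df.insert(0, "participant_id", ids)
    return df


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------

def _bump(t: np.ndarray, center: float, half_width: float) -> np.ndarray:
    """Symmetric raised-cosine bump: 1 at ``center``, 0 outside
    ``[center - half_width, center + half_width]``, C1-continuous."""
    u = (t - center) / half_width
    out = np.zeros_like(t)
    inside = np.abs(u) < 1.0
    out[inside] = 0.5 * (1.0 + np.cos(np.pi * u[inside]))
    return out


def _rc_step(t: np.ndarray, start: float, stop: float) -> np.ndarray:
    """Raised-cosine step from 0 (before ``start``) to 1 (after ``stop``)."""
    u = np.clip((t - start) / (stop - start), 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * u))


def _bump_filter_gain(half_width: float, fs: float, fc: float, order: int
                      ) -> float:
    """Peak gain of the zero-phase analysis filter on a raised-cosine bump.

    Narrow bumps are attenuated by the 10 Hz analysis filter; the simulator
    divides each bump amplitude by this gain so that configured depths and
    peaks refer to the filtered domain, where the landmarks and features are
    defined.  Measured numerically on a unit bump.
    """
    from .kinetics import lowpass_filter

    pad = 0.8  # s, lets the filter transient die out
    n = int(round((2 * half_width + 2 * pad) * fs))
    t = np.arange(n) / fs
    c = pad + half_width
    y = lowpass_filter(_bump(t, c, half_width), fs, fc, order)
    return float(y[int(round(c * fs))])


@dataclass
class TrialSpec:
    """Parameters of one synthetic force-plate GI trial.

    ``event_times`` fixes the four landmarks; the COP excursion amplitudes
    are signed (AP is typically negative: backward shift); ``noise_sd`` is
    the white-noise SD on the force channels (moments receive
    ``noise_sd * moment_arm``).  Optional per-axis onset delays let the ML
    and AP COP excursions start at different times, which is what makes the
    two APA durations distinct.
    """

    duration: float = 3.0
    fs: float = 500.0
    mass: float = 70.0
    event_times: dict[str, float] = field(
        default_factory=lambda: {"t0": 1.0, "HO": 1.3, "TO": 1.45, "HC": 1.85})
    apa_cop_amplitudes: dict[str, float] = field(
        default_factory=lambda: {"AP": -0.030, "ML": 0.040})
    noise_sd: float = 0.3
    seed: int = 0
    # --- secondary shape parameters -----------------------------------
    ap_onset_delay: float = 0.0
    ml_onset_delay: float = 0.0
    vcom_ap: tuple[float, float, float] = (0.12, 0.45, 0.95)  # at HO, TO, HC
    vcom_ml: tuple[float, float] = (0.10, 0.14)               # at HO, TO
    fz_peak: float | None = None          # default 1.2 * mass * g
    unload_frac_ho: float = 0.12          # swing-leg unloading depth at HO
    overshoot_to: float = 0.06            # push-off overshoot at TO
    unload_frac_exe: float = 0.30         # execution-phase unloading depth
    cop_origin: tuple[float, float] = (0.0, 0.0)  # (ML, AP), m
    moment_arm: float = 0.3               # m, scales moment noise
    analysis_fc: float = 10.0             # Hz, downstream filter convention
    analysis_order: int = 2

    def __post_init__(self) -> None:
        ev = self.event_times
        missing = {"t0", "HO", "TO", "HC"} - set(ev)
        if missing:
            raise ValueError(f"event_times missing {sorted(missing)}")
        if not (0.0 < ev["t0"] < ev["HO"] < ev["TO"] < ev["HC"] < self.duration):
            raise ValueError(
                "event ordering violated: require 0 < t0 < HO < TO < HC < "
                f"duration, got {ev} with duration {self.duration}")
        if self.fs <= 40.0:
            raise ValueError(
                f"fs={self.fs} Hz too low: must exceed several times the "
                "10 Hz analysis filter cut-off")
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if min(self.ap_onset_delay, self.ml_onset_delay) < 0:
            raise ValueError("onset delays must be non-negative")
        latest = ev["t0"] + max(self.ap_onset_delay, self.ml_onset_delay)
        if latest >= ev["HO"]:
            raise ValueError("COP onset delays push an onset past heel-off")
        if self.fz_peak is None:
            self.fz_peak = 1.2 * self.mass * G


def simulate_trial(spec: TrialSpec) -> TrialRecording:
    """Generate one synthetic GI trial with stored ground truth.

    The vertical force starts at body weight, shows a symmetric unloading
    dip centred at HO (swing-leg unloading) and a push-off overshoot centred
    at TO, steps down to the execution-phase load level once the swing foot
    is airborne, rises from that level as a symmetric foot-strike bump
    centred at HC, and finally steps off the plate.  Each deflection's
    support is confined to its inter-event gap, so the landmarks are exact
    local extrema of the clean waveform even after zero-phase filtering.  The COP rises along each axis as a
    raised-cosine ramp from that axis's onset to HO and then holds; the
    horizontal forces follow a C1 (PCHIP) COM-velocity profile through the
    configured landmark velocities.
    """
    ev = spec.event_times
    t0, ho, to, hc = ev["t0"], ev["HO"], ev["TO"], ev["HC"]
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    mg = spec.mass * G
    assert spec.fz_peak is not None

    # vertical force -----------------------------------------------------
    # body weight, minus a symmetric swing-leg unloading dip at HO, plus a
    # push-off overshoot at TO; after TO the load steps down to the
    # execution-phase level, the foot-strike peak rises from that level as
    # a symmetric bump at HC, and the load finally steps off the plate.
    w_ho = 0.45 * min(ho - t0, to - ho)
    w_to = min(0.45 * min(to - ho, hc - to), 0.10)
    w_hc = min(0.15, 0.40 * (hc - to), 0.95 * (spec.duration - hc))
    level_exe = (1.0 - spec.unload_frac_exe) * mg
    s1_start = to + w_to
    s1_len = min(0.15, 0.9 * ((hc - w_hc) - s1_start))
    if s1_len < 4.0 / spec.fs:
        raise ValueError("events too close: no room for the execution-phase "
                         "unloading between TO and HC")
    assert spec.fz_peak is not None
    if spec.fz_peak < level_exe + 0.05 * mg:
        raise ValueError(
            f"fz_peak={spec.fz_peak:.0f} N must exceed the execution-phase "
            f"load {level_exe:.0f} N; raise fz_peak or unload_frac_exe")

    # dip/overshoot amplitudes pre-compensated for the analysis filter
    # (boost capped at 3x; depths clipped to keep Fz positive)
    def _amp(a: float, w: float, cap: float) -> float:
        gain = _bump_filter_gain(w, spec.fs, spec.analysis_fc,
                                 spec.analysis_order)
        return float(np.clip(a / max(gain, 1.0 / 3.0), -cap, cap))

    s2_start = hc + w_hc + 0.05
    s2_len = min(0.2, 0.95 * (spec.duration - s2_start))
    fz = (
        mg
        - _amp(spec.unload_frac_ho, w_ho, 0.5) * mg * _bump(t, ho, w_ho)
        + _amp(spec.overshoot_to, w_to, 0.3) * mg * _bump(t, to, w_to)
        - (mg - level_exe) * _rc_step(t, s1_start, s1_start + s1_len)
        + _amp(spec.fz_peak - level_exe, w_hc, 2.0 * mg) * _bump(t, hc, w_hc)
    )
    if s2_len > 4.0 / spec.fs:
        fz = fz - (level_exe - 0.15 * mg) * _rc_step(t, s2_start,
                                                     s2_start + s2_len)

    # COP -----------------------------------------------------------------
    on_ap = t0 + spec.ap_onset_delay
    on_ml = t0 + spec.ml_onset_delay
    amp_ap = spec.apa_cop_amplitudes["AP"]
    amp_ml = spec.apa_cop_amplitudes["ML"]
    cop_ml = spec.cop_origin[0] + amp_ml * _rc_step(t, on_ml, ho)
    cop_ap = spec.cop_origin[1] + amp_ap * _rc_step(t, on_ap, ho)

    # horizontal forces from COM-velocity profiles ------------------------
    end = spec.duration
    v_ap_knots = ([0.0, on_ap], [0.0, 0.0])
    v_ap_knots[0].extend([ho, to, hc, end])
    v_ap_knots[1].extend([spec.vcom_ap[0], spec.vcom_ap[1],
                          spec.vcom_ap[2], spec.vcom_ap[2] * 1.05])
    pch_ap = PchipInterpolator(*v_ap_knots)
    v_ml_knots = ([0.0, on_ml, ho, to, end],
                  [0.0, 0.0, spec.vcom_ml[0], spec.vcom_ml[1], spec.vcom_ml[1]])
    pch_ml = PchipInterpolator(*v_ml_knots)
    a_ap = pch_ap.derivative()(t)
    a_ml = pch_ml.derivative()(t)
    f_ap = spec.mass * a_ap
    f_ml = spec.mass * a_ml

    # moments consistent with the COP convention --------------------------
    mx = cop_ap * fz
    my = -cop_ml * fz
    mz = np.zeros(n)

    F = np.column_stack([f_ml, f_ap, fz])
    M = np.column_stack([mx, my, mz])
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        F = F + rng.normal(0.0, spec.noise_sd, F.shape)
        M = M + rng.normal(0.0, spec.noise_sd * spec.moment_arm, M.shape)

    events = GIEvents(t0=min(on_ap, on_ml), HO=ho, TO=to, HC=hc)
    features = GIFeatures(
        apa_ml=ho - on_ml,
        apa_ap=ho - on_ap,
        cop_shift_ap=abs(amp_ap),
        cop_shift_ml=abs(amp_ml),
        vcom_ap_ho=spec.vcom_ap[0],
        vcom_ap_to=spec.vcom_ap[1],
        vcom_ap_hc=spec.vcom_ap[2],
        vcom_ml_ho=spec.vcom_ml[0],
        vcom_ml_to=spec.vcom_ml[1],
        foot_lift=to - ho,
        fz_peak=float(spec.fz_peak),
    )
    ground_truth = {
        "events": events,
        "features": features,
        "cop": np.column_stack([cop_ml, cop_ap]),
        "vel_ap": pch_ap(t),
        "vel_ml": pch_ml(t),
    }
    return TrialRecording(t=t, F=F, M=M, fs=spec.fs, mass=spec.mass,
                          ground_truth=ground_truth)


def trial_spec_from_features(
    features: GIFeatures | dict[str, float] | pd.Series,
    mass: float = 70.0,
    fs: float = 500.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    t0: float = 1.0,
    exe_time: float = 0.4,
    tail: float = 0.6,
) -> TrialSpec:
    """Build a trial whose ground-truth feature vector equals ``features``.

    This inverts the feature definitions: the landmark times follow from the
    APA and foot-lift durations, the COP amplitudes and landmark velocities
    are set directly, and the foot-strike peak equals ``fz_peak``.  Used to
    show that the raw-trial path of the pipeline agrees with the
    feature-table path.
    """
    if isinstance(features, GIFeatures):
        f = features.as_dict()
    else:
        f = {k: float(features[k]) for k in FEATURES}
    apa_max = max(f["apa_ml"], f["apa_ap"])
    ho = t0 + apa_max
    to = ho + f["foot_lift"]
    hc = to + exe_time
    return TrialSpec(
        duration=hc + tail,
        fs=fs,
        mass=mass,
        event_times={"t0": t0, "HO": ho, "TO": to, "HC": hc},
        apa_cop_amplitudes={"AP": -f["cop_shift_ap"], "ML": f["cop_shift_ml"]},
        noise_sd=noise_sd,
        seed=seed,
        ap_onset_delay=apa_max - f["apa_ap"],
        ml_onset_delay=apa_max - f["apa_ml"],
        vcom_ap=(f["vcom_ap_ho"], f["vcom_ap_to"], f["vcom_ap_hc"]),
        vcom_ml=(f["vcom_ml_ho"], f["vcom_ml_to"]),
        fz_peak=f["fz_peak"],
    )
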