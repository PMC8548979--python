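"""Synthetic two-wavelength fNIRS cohorts with known ground truth.

The generator inverts the assumptions of the analysis chain so that every
stage is testable without a real recording.  A simulated session follows
the study design: a pre-practice rest, a breathing-practice block, 20
thermal-QST trials (30 degC baseline ramped at 1 degC/s to the subject's
threshold, 10 s rests), and a post rest, all sampled at 25 Hz.

Per channel, the simulated HbO signal is the sum of

* a neural response: per-trial boxcars convolved with the canonical HRF,
  scaled by the channel's planted beta (uM);
* a low-band (0.01-0.08 Hz) background built from latent Gaussian factors
  whose loadings (the symmetric square root of the planted correlation
  matrix) induce the target edge correlations;
* a cardiac oscillation driven by a phase accumulator over a jittered R-R
  sequence, so the true SDNN is exact by construction;
* Mayer-wave (0.1 Hz) and respiratory (0.35 Hz) sinusoids with random
  per-channel phases; and
* AR(1) noise.

HbR is -1/3 of the HbO neural + background component plus independent
noise (the physiological ratio; it exists so the Beer-Lambert inversion is
a genuine 2x2 solve).  Raw intensities come from the forward modified
Beer-Lambert model exponentiated around a positive baseline.  Subject
pain thresholds are planted as a linear function of the subject's true
edge Fisher-Z plus group/visit offsets, truncated to the 30-50 degC
thermode range.

All randomness flows from a single root seed through a documented
``numpy.random.SeedSequence`` splitting scheme (one child per subject,
grandchildren per signal component), so identical configs give
bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from nirspain.activation import canonical_hrf
from nirspain.preprocess import DEFAULT_DPF, bandpass, hemoglobin_to_od
from nirspain.probe import (
    BehavioralTable,
    EventDesign,
    ProbeLayout,
    RawIntensityRecording,
    TQST_BASELINE_C,
    TQST_CEILING_C,
    default_layout,
)

HBR_RATIO = -1.0 / 3.0


def _default_active_channels() -> dict[int, float]:
    # planted tQST response on the S1 channels (contralateral somatosensory
    # activation), amplitude giving first-level t around 3-5 at 20 trials
    return {29: 0.05, 30: 0.05, 35: 0.05, 36: 0.05}


def _default_edges() -> list[tuple[int, int, float]]:
    # within-aPFC, within-PMC and PMC-S1 edges, mirroring the kinds of
    # region pairs the breathing analysis interrogates
    return [(2, 5, 0.6), (9, 13, 0.6), (13, 29, 0.6)]


@dataclass
class SimulationConfig:
    """Study-design constants and forward-model parameters.

    Defaults reproduce the study conditions: 2 groups x 20 subjects x
    2 visits, 5 min rests, 10 min breathing practice, 20 tQST trials, and
    physiological rhythms inside the bands the analysis must avoid
    (cardiac 1-1.5 Hz, Mayer 0.1 Hz, respiratory 0.3-0.5 Hz).
    """

    n_per_group: int = 20
    visits: int = 2
    layout: ProbeLayout = field(default_factory=default_layout)
    sampling_rate: float = 25.0

    # session structure (seconds)
    rest_pre_s: float = 300.0
    breathing_s: float = 600.0
    rest_post_s: float = 300.0
    n_trials: int = 20
    ramp_rate_c_per_s: float = 1.0
    trial_rest_s: float = 10.0
    trial_jitter_c: float = 0.3          # per-trial threshold wobble (degC)

    # neural response
    active_channels: dict[int, float] = field(
        default_factory=_default_active_channels
    )

    # connectivity background
    edge_set: list[tuple[int, int, float]] = field(default_factory=_default_edges)
    edge_z_sd: float = 0.3               # between-subject SD of edge Fisher-Z
    background_sd_um: float = 0.3        # low-band background amplitude

    # physiology; the pulse is the most conspicuous oscillation in raw
    # CW-fNIRS optics, comparable to or larger than the slow background
    cardiac_hz: float = 1.1
    rr_jitter_sd: float = 0.05           # seconds; the planted SDNN scale
    cardiac_amp_um: float = 0.3
    mayer_hz: float = 0.1
    mayer_amp_um: float = 0.05
    resp_hz: float = 0.35
    resp_amp_um: float = 0.05

    # noise
    ar_coefficient: float = 0.3
    noise_sd_um: float = 0.1

    # behavior coupling: threshold = intercept + slope * subject edge Z
    #                    + group/visit offsets + residual
    coupling_edge: tuple[int, int] = (2, 5)
    coupling_slope_c_per_z: float = -2.0
    coupling_intercept_c: float = 45.4
    coupling_residual_sd_c: float = 0.5
    group_offset_c: dict[str, float] = field(
        default_factory=lambda: {"TMB": 0.0, "VRB": 1.1}
    )
    visit_offset_c: dict[int, float] = field(
        default_factory=lambda: {1: 0.0, 2: 0.6}
    )

    # optics
    dpf: float = DEFAULT_DPF
    baseline_intensity: float = 1.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must be in [0, 1)")
        for a, b, r in self.edge_set:
            if not -1 < r < 1:
                raise ValueError(f"edge correlation {r} must be in (-1, 1)")
            if a == b:
                raise ValueError("edge endpoints must differ")
        if not 1.0 <= self.cardiac_hz <= 1.5:
            # the analysis bands assume a resting cardiac rhythm
            raise ValueError("cardiac_hz should lie in the 1-1.5 Hz cardiac band")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Planted quantities the analysis modules must recover."""

    betas: dict[int, float]
    edge_targets: list[tuple[int, int, float]]
    subject_edge_z: pd.DataFrame      # subject, ch_a, ch_b, z, r
    coupling: dict
    thresholds: pd.DataFrame          # subject, group, visit, threshold_c
    cardiac: dict                     # (subject, visit) -> dict with rr, sdnn,
                                      # peak_times
    hbo_true: dict = field(default_factory=dict)  # (subject, visit) -> array


def simulate_tqst_events(
    thresholds: np.ndarray,
    baseline_c: float = TQST_BASELINE_C,
    ramp_rate: float = 1.0,
    rest_s: float = 10.0,
    start_s: float = 0.0,
) -> EventDesign:
    """Trial events for a ramped thermal QST run.

    Trial i lasts ``(threshold_i - baseline_c) / ramp_rate`` seconds (the
    ramp stops at first pain) and is followed by ``rest_s`` of rest.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.ndim != 1 or len(thresholds) < 1:
        raise ValueError("need at least one trial threshold")
    if np.any(thresholds <= baseline_c):
        raise ValueError(
            f"thresholds must exceed the {baseline_c} degC baseline"
        )
    if np.any(thresholds > TQST_CEILING_C):
        raise ValueError(f"thresholds cannot exceed {TQST_CEILING_C} degC")
    durations = (thresholds - baseline_c) / ramp_rate
    onsets = start_s + np.concatenate(
        [[0.0], np.cumsum(durations[:-1] + rest_s)]
    )
    return EventDesign(
        onsets=onsets,
        durations=durations,
        labels=["tqst_trial"] * len(thresholds),
    )


def planted_correlation_matrix(
    n_channels: int, edges: list[tuple[int, int, float]]
) -> np.ndarray:
    """Identity plus planted off-diagonal correlations; PSD-checked."""
    C = np.eye(n_channels)
    for a, b, r in edges:
        C[a - 1, b - 1] = r
        C[b - 1, a - 1] = r
    w = np.linalg.eigvalsh(C)
    if w.min() < -1e-10:
        raise ValueError(
            "planted edge correlations are jointly infeasible (matrix not "
            "positive semidefinite); reduce |r| on overlapping edges"
        )
    return C


def _factor_loadings(C: np.ndarray) -> np.ndarray:
    """Latent-factor loadings A with A A' = C (symmetric square root)."""
    w, V = np.linalg.eigh(C)
    return V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T


def _band_limited_noise(rng: np.random.Generator, n_series: int, n_t: int,
                        fs: float, low: float, high: float) -> np.ndarray:
    """Unit-variance series with power confined to [low, high] Hz."""
    x = rng.standard_normal((n_series, n_t))
    y = bandpass(x, fs, low, high)
    sd = y.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return y / sd


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, int],
               rho: float, sd: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(shape)
    innov_sd = sd * np.sqrt(1 - rho**2)
    e = rng.standard_normal(shape) * innov_sd
    if rho == 0:
        return e
    from scipy.signal import lfilter

    out = lfilter([1.0], [1.0, -rho], e, axis=-1)
    return out


def _cardiac_signal(rng: np.random.Generator, n_t: int, fs: float,
                    cardiac_hz: float, jitter_sd: float):
    """Phase-accumulator cardiac oscillation; returns (signal, rr, peaks).

    The instantaneous period is the jittered R-R sequence and the signal is
    ``cos(2 pi phase)``, so waveform maxima fall exactly on the beat times:
    the intervals between successive in-recording peaks ARE the planted R-R
    intervals, making the ground-truth SDNN exact by construction.
    """
    duration = n_t / fs
    mean_rr = 1.0 / cardiac_hz
    n_beats = int(np.ceil(duration / max(mean_rr - 5 * jitter_sd, 0.3))) + 4
    rr = mean_rr + rng.standard_normal(n_beats) * jitter_sd
    rr = np.clip(rr, 0.3, None)
    beat_starts = np.concatenate([[0.0], np.cumsum(rr)])
    t = np.arange(n_t) / fs
    phase = np.interp(t, beat_starts, np.arange(len(beat_starts), dtype=float))
    signal = np.cos(2 * np.pi * phase)
    peak_times = beat_starts[beat_starts < duration]
    rr_in = np.diff(peak_times)
    return signal, rr_in if len(rr_in) >= 2 else rr[:2], peak_times


def _session_events(cfg: SimulationConfig, rng: np.random.Generator,
                    subject_threshold: float) -> tuple[EventDesign, dict]:
    trial_thr = subject_threshold + rng.standard_normal(cfg.n_trials) * \
        cfg.trial_jitter_c
    trial_thr = np.clip(trial_thr, TQST_BASELINE_C + 1.0, TQST_CEILING_C)
    tqst_start = cfg.rest_pre_s + cfg.breathing_s
    events = simulate_tqst_events(
        trial_thr, ramp_rate=cfg.ramp_rate_c_per_s, rest_s=cfg.trial_rest_s,
        start_s=tqst_start,
    )
    tqst_end = events.end_time() + cfg.trial_rest_s
    phases = {
        "rest_pre": (0.0, cfg.rest_pre_s),
        "breathing": (cfg.rest_pre_s, tqst_start),
        "tqst": (tqst_start, tqst_end),
        "rest_post": (tqst_end, tqst_end + cfg.rest_post_s),
    }
    return events, phases


def simulate_subject(
    cfg: SimulationConfig,
    events: EventDesign,
    subject_seed: int,
    phases: dict[str, tuple[float, float]] | None = None,
    subject: str = "sim01",
    group: str = "TMB",
    visit: int = 1,
    edge_z: np.ndarray | None = None,
) -> tuple[RawIntensityRecording, dict]:
    """Forward-model one recording; returns the recording and its truth.

    ``edge_z`` optionally overrides the subject-level Fisher-Z of each
    planted edge (defaults to the targets in ``cfg.edge_set``).  The truth
    dict holds the demeaned true HbO (what optical-density conversion can
    recover), the R-R sequence with its SDNN, and the pulse-peak times.
    """
    ss = np.random.SeedSequence(subject_seed)
    rng_bg, rng_card, rng_phys, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    fs = cfg.sampling_rate
    if phases is None:
        end = events.end_time() + cfg.trial_rest_s + cfg.rest_post_s
        phases = {"tqst": (0.0, end)}
        duration = end
    else:
        duration = max(stop for _, stop in phases.values())
    n_t = int(np.ceil(duration * fs - 1e-9))
    n_ch = cfg.layout.n_channels

    # neural response
    hrf = canonical_hrf(fs)
    box = np.zeros(n_t)
    for onset, dur in zip(events.onsets, events.durations):
        i0 = int(np.ceil(onset * fs - 1e-9))
        i1 = int(np.ceil((onset + dur) * fs - 1e-9))
        box[i0:min(i1, n_t)] = 1.0
    # dt-scaled convolution: matches the analysis design-matrix convention,
    # so the planted beta is what the GLM estimates
    response = np.convolve(box, hrf)[:n_t] / fs
    neural = np.zeros((n_ch, n_t))
    for ch, beta in cfg.active_channels.items():
        neural[ch - 1] = beta * response

    # connectivity background (low-band latent factors)
    background = np.zeros((n_ch, n_t))
    if cfg.background_sd_um > 0:
        edges = list(cfg.edge_set)
        if edge_z is not None:
            edges = [
                (a, b, float(np.tanh(z)))
                for (a, b, _), z in zip(edges, edge_z)
            ]
        C = planted_correlation_matrix(n_ch, edges)
        A = _factor_loadings(C)
        factors = _band_limited_noise(rng_bg, n_ch, n_t, fs, 0.01, 0.08)
        background = cfg.background_sd_um * (A @ factors)

    # cardiac with jittered R-R sequence (shared phase across channels)
    cardiac = np.zeros((n_ch, n_t))
    rr = np.array([1.0 / cfg.cardiac_hz] * 2)
    peak_times = np.array([])
    if cfg.cardiac_amp_um > 0:
        sig, rr, peak_times = _cardiac_signal(
            rng_card, n_t, fs, cfg.cardiac_hz, cfg.rr_jitter_sd
        )
        gains = 1.0 + 0.2 * (rng_card.random(n_ch) - 0.5)
        cardiac = cfg.cardiac_amp_um * gains[:, None] * sig[None, :]

    # Mayer and respiratory sinusoids, independent phase per channel so they
    # do not plant spurious cross-channel correlation
    t = np.arange(n_t) / fs
    physio = np.zeros((n_ch, n_t))
    if cfg.mayer_amp_um > 0:
        ph = rng_phys.random(n_ch)[:, None]
        physio += cfg.mayer_amp_um * np.sin(
            2 * np.pi * (cfg.mayer_hz * t[None, :] + ph)
        )
    if cfg.resp_amp_um > 0:
        ph = rng_phys.random(n_ch)[:, None]
        physio += cfg.resp_amp_um * np.sin(
            2 * np.pi * (cfg.resp_hz * t[None, :] + ph)
        )

    noise = _ar1_noise(rng_noise, (n_ch, n_t), cfg.ar_coefficient,
                       cfg.noise_sd_um)
    hbo = neural + background + cardiac + physio + noise
    hbr = HBR_RATIO * (neural + background) + _ar1_noise(
        rng_noise, (n_ch, n_t), cfg.ar_coefficient, cfg.noise_sd_um * 0.3
    )

    od = hemoglobin_to_od(
        hbo, hbr, dpf=cfg.dpf, separation_cm=cfg.layout.separation_cm(),
        wavelengths=tuple(cfg.layout.wavelengths[:2]),
    )
    intensities = cfg.baseline_intensity * np.exp(-od)

    rec = RawIntensityRecording(
        layout=cfg.layout,
        sampling_rate=fs,
        intensities=intensities,
        events=events,
        subject=subject,
        group=group,
        visit=visit,
        phases=phases,
    )
    truth = {
        "hbo_true": hbo - hbo.mean(axis=1, keepdims=True),
        "hbr_true": hbr - hbr.mean(axis=1, keepdims=True),
        "rr_intervals": rr,
        "sdnn": float(np.std(rr, ddof=1)) if len(rr) > 1 else 0.0,
        "peak_times": peak_times,
        "betas": dict(cfg.active_channels),
    }
    return rec, truth


def _feasible_edge_z(
    edge_set: list[tuple[int, int, float]],
    z: np.ndarray,
    n_channels: int,
) -> np.ndarray:
    """Shrink subject edge-Z deviations toward the targets until the
    implied correlation matrix is positive semidefinite.

    Independent per-subject draws on edges that share a channel can land on
    jointly infeasible correlations; the target configuration itself is
    validated, so contracting the deviations always terminates.
    """
    target = np.array([np.arctanh(r) for _, _, r in edge_set])
    dev = z - target
    for _ in range(100):
        edges = [
            (a, b, float(np.tanh(t + d)))
            for (a, b, _), t, d in zip(edge_set, target, dev)
        ]
        C = np.eye(n_channels)
        for a, b, r in edges:
            C[a - 1, b - 1] = C[b - 1, a - 1] = r
        if np.linalg.eigvalsh(C).min() >= 1e-8:
            return target + dev
        dev = dev * 0.9
    return target


def simulate_feature_table(
    cfg: SimulationConfig,
    n_subjects: int = 40,
    r2: float | None = 0.5,
    measurement_sd: float = 0.1,
    seed: int = 0,
):
    """Edge-feature table from the trait/coupling layer of the generator.

    Draws each subject's planted-edge Fisher-Z traits (``z ~ Normal(atanh r,
    edge_z_sd)``), adds connectivity measurement noise (``measurement_sd``,
    the empirical scale of the subject-level Z estimator) to every edge
    column, and couples the threshold to the planted edges with equal
    slopes scaled so the population coupling explains ``r2`` of the
    threshold variance (``r2=None`` or 0 gives a pure-noise response).

    This is the selection-study view of the same generative model
    :func:`simulate_cohort` realises through full recordings; it exists so
    the elastic-net stage can be exercised at cohort scale without paying
    for optics and filtering on every replicate.  Returns an
    :class:`~nirspain.brain_behavior.EdgeFeatureTable`.
    """
    import pandas as pd

    from nirspain.brain_behavior import EdgeFeatureTable
    from nirspain.connectivity import canonical_pairs

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_ch = cfg.layout.n_channels
    pairs = canonical_pairs(n_ch)
    pair_index = {(int(a), int(b)): i for i, (a, b) in enumerate(pairs)}
    n_edges = len(pairs)
    X = rng.standard_normal((n_subjects, n_edges)) * measurement_sd
    target_z = np.array([np.arctanh(r) for _, _, r in cfg.edge_set])
    z = target_z + rng.standard_normal(
        (n_subjects, len(cfg.edge_set))
    ) * cfg.edge_z_sd
    cols = []
    for (a, b, _), k in zip(cfg.edge_set, range(len(cfg.edge_set))):
        col = pair_index[(min(a, b), max(a, b))]
        X[:, col] += z[:, k] - target_z[k]
        cols.append(col)
    signal = (z - target_z).sum(axis=1)
    if r2:
        resid_sd = signal.std() * np.sqrt((1 - r2) / r2)
        y = cfg.coupling_intercept_c + signal + rng.standard_normal(
            n_subjects
        ) * resid_sd
    else:
        y = cfg.coupling_intercept_c + rng.standard_normal(n_subjects)
    y = np.clip(y, TQST_BASELINE_C + 1.0, TQST_CEILING_C)
    keys = pd.DataFrame(
        {
            "subject": [f"sim{i + 1:02d}" for i in range(n_subjects)],
            "group": ["TMB" if i < n_subjects // 2 else "VRB"
                      for i in range(n_subjects)],
            "visit": 1,
        }
    )
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    return EdgeFeatureTable(
        features=Xs, response=y, pairs=pairs, keys=keys, band="low"
    ), cols


def simulate_cohort(
    cfg: SimulationConfig, keep_true_hbo: bool = False
) -> tuple[list[RawIntensityRecording], BehavioralTable, GroundTruth]:
    """Simulate the full 2-group cohort across visits.

    Subject thresholds are drawn from the planted brain-behavior coupling
    (intercept + slope x subject edge Z + group/visit offsets + residual),
    truncated to the 30-50 degC thermode range.  Identical ``cfg.seed``
    gives an identical cohort.
    """
    recordings: list[RawIntensityRecording] = []
    behav_rows = []
    edge_rows = []
    cardiac_truth: dict = {}
    hbo_truth: dict = {}
    subj_index = 0
    coupling_idx = None
    for i, (a, b, _) in enumerate(cfg.edge_set):
        if (a, b) == tuple(cfg.coupling_edge) or (b, a) == tuple(cfg.coupling_edge):
            coupling_idx = i
    thr_rows = []
    for group in ("TMB", "VRB"):
        for k in range(cfg.n_per_group):
            subject = f"{group}{k + 1:02d}"
            subj_ss = np.random.SeedSequence(
                entropy=cfg.seed, spawn_key=(subj_index,)
            )
            rng_subj = np.random.default_rng(subj_ss)
            # subject-level edge Fisher-Z (stable trait across visits)
            target_z = np.array([np.arctanh(r) for _, _, r in cfg.edge_set])
            z_subj = target_z + rng_subj.standard_normal(len(target_z)) * \
                cfg.edge_z_sd
            z_subj = _feasible_edge_z(
                cfg.edge_set, z_subj, cfg.layout.n_channels
            )
            for (a, b, r), z in zip(cfg.edge_set, z_subj):
                edge_rows.append(
                    {"subject": subject, "ch_a": a, "ch_b": b,
                     "target_r": r, "z": float(z), "r": float(np.tanh(z))}
                )
            if coupling_idx is not None:
                # centre on the edge's target Z so the intercept stays the
                # group/visit mean threshold
                centered_z = float(z_subj[coupling_idx] - target_z[coupling_idx])
            else:
                centered_z = 0.0
            for visit in range(1, cfg.visits + 1):
                resid = rng_subj.standard_normal() * cfg.coupling_residual_sd_c
                thr = (
                    cfg.coupling_intercept_c
                    + cfg.coupling_slope_c_per_z * centered_z
                    + cfg.group_offset_c.get(group, 0.0)
                    + cfg.visit_offset_c.get(visit, 0.0)
                    + resid
                )
                thr = float(
                    np.clip(thr, TQST_BASELINE_C + 1.0, TQST_CEILING_C)
                )
                rec_seed = int(
                    np.random.SeedSequence(
                        entropy=cfg.seed, spawn_key=(subj_index, visit)
                    ).generate_state(1)[0] % (2**31 - 1)
                )
                events, phases = _session_events(cfg, rng_subj, thr)
                rec, truth = simulate_subject(
                    cfg, events, rec_seed, phases=phases, subject=subject,
                    group=group, visit=visit, edge_z=z_subj,
                )
                recordings.append(rec)
                cardiac_truth[(subject, visit)] = {
                    "rr_intervals": truth["rr_intervals"],
                    "sdnn": truth["sdnn"],
                    "peak_times": truth["peak_times"],
                }
                if keep_true_hbo:
                    hbo_truth[(subject, visit)] = truth["hbo_true"]
                behav_rows.append(
                    {"subject": subject, "group": group, "visit": visit,
                     "mean_threshold_c": thr}
                )
                thr_rows.append(
                    {"subject": subject, "group": group, "visit": visit,
                     "threshold_c": thr}
                )
            subj_index += 1
    behavior = BehavioralTable(pd.DataFrame(behav_rows))
    truth_obj = GroundTruth(
        betas=dict(cfg.active_channels),
        edge_targets=list(cfg.edge_set),
        subject_edge_z=pd.DataFrame(edge_rows),
        coupling={
            "edge": tuple(cfg.coupling_edge),
            "slope_c_per_z": cfg.coupling_slope_c_per_z,
            "intercept_c": cfg.coupling_intercept_c,
            "residual_sd_c": cfg.coupling_residual_sd_c,
        },
        thresholds=pd.DataFrame(thr_rows),
        cardiac=cardiac_truth,
        hbo_true=hbo_truth,
    )
    return recordings, behavior, truth_obj
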