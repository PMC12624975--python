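"""Synthetic multielectrode recordings linked to a strain map.

The clinical and NHP recordings behind the strain-performance correlations
are not public, so this module generates per-electrode impedances and
30 kHz broadband voltage traces whose ground truth is monotonically linked
to a per-electrode strain map.  The links emulate the observed sign
structure: in the "motor" regime impedance and spike amplitude decrease
with strain (negative Spearman correlations downstream); in the "v4"
regime the stimulus-evoked firing-rate gain increases with strain (positive
evoked-SNR correlation).  Recordings are white Gaussian noise plus Poisson
spike trains convolved with a fixed biphasic template whose peak-to-peak
amplitude varies per electrode; multiplicative lognormal session factors,
dead electrodes, and an optional shared-noise block (emulating edge
insulation failure) complete the picture.

Randomness uses numpy's PCG64 via ``default_rng``; per-session and
per-electrode substreams are spawned deterministically from the master
seed, so a dataset is bit-reproducible from (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "LinkModel",
    "SyntheticGroundTruth",
    "RecordingSet",
    "spike_template",
    "normalized_strain",
    "simulate_impedances",
    "simulate_ground_truth",
    "simulate_spontaneous",
    "simulate_evoked",
    "surrogate_strain_map",
    "IMPEDANCE_THRESHOLDS",
]

FS = 30_000.0  # Hz

# screening thresholds by electrode coating (impedance strictly above is
# deemed nonfunctional)
IMPEDANCE_THRESHOLDS = {"sirof": 1.0e6, "platinum": 2.0e6}


@dataclass(frozen=True)
class LinkModel:
    """Monotone links from normalized strain s~ in [0, 1] to ground truth.

    impedance:    Z_e = z0 * exp(beta_z * s~) * eta,  eta lognormal(sigma_z)
    amplitude:    A_e = a0 * exp(beta_a * s~) * eta,  eta lognormal(sigma_a)
    evoked gain:  g_e = g0 * (1 + beta_g * s~)

    The default "motor" regime uses beta_z, beta_a < 0 (performance falls
    with strain); the "v4" regime uses beta_g > 0.  Session-to-session
    variability is multiplicative lognormal with sd ``sigma_session`` on
    amplitude and impedance; a per-electrode sd array passed to
    :func:`simulate_ground_truth` overrides it (ring-dependent
    variability: interior rings more variable than edge, as observed
    in vivo).
    """

    z0: float = 3.0e5  # ohm
    beta_z: float = -0.8
    sigma_z: float = 0.25
    a0: float = 120.0  # uV peak-to-peak
    beta_a: float = -0.7
    sigma_a: float = 0.15
    g0: float = 1.5
    beta_g: float = 1.0
    sigma_session: float = 0.08
    noise_sd: float = 6.0  # uV
    firing_rate: float = 20.0  # Hz
    shared_noise_electrodes: tuple = ()
    shared_noise_mixing: float = 0.0

    @classmethod
    def regime(cls, name: str, **overrides) -> "LinkModel":
        if name == "motor":
            return cls(**overrides)
        if name == "v4":
            base = cls(beta_a=0.0, beta_g=1.0)
            return replace(base, **overrides)
        if name == "null":
            return cls(beta_z=0.0, beta_a=0.0, beta_g=0.0, **overrides)
        raise ValueError(f"unknown regime {name!r}")


@dataclass
class SyntheticGroundTruth:
    """Everything needed to regenerate a dataset deterministically."""

    strain: np.ndarray  # per-electrode strain map (raw)
    strain_norm: np.ndarray  # min-max normalized
    impedance: np.ndarray  # ohm
    amplitude: np.ndarray  # uV ptp
    evoked_gain: np.ndarray
    firing_rate: np.ndarray  # Hz
    noise_sd: np.ndarray  # uV
    dead: np.ndarray  # bool
    session_amp: np.ndarray  # (n_sessions, n_elec) multipliers
    session_imp: np.ndarray
    link: LinkModel = None
    seed: int = 0
    spike_times: list = field(default_factory=list)  # [session][elec] arrays (s)


@dataclass
class RecordingSet:
    """Multichannel 30 kHz traces, sessions x electrodes x samples (uV).

    For evoked sets, each session is a sequence of trials laid out
    back-to-back; ``baseline_window`` and ``stim_window`` give the
    (start, stop) seconds within each trial.
    """

    data: list  # list of (n_elec, n_samples) float32 arrays
    fs: float = FS
    truth: SyntheticGroundTruth | None = None
    n_trials: int = 0
    trial_length_s: float = 0.0
    baseline_window: tuple = ()
    stim_window: tuple = ()

    @property
    def n_sessions(self) -> int:
        return len(self.data)

    @property
    def n_electrodes(self) -> int:
        return self.data[0].shape[0]

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["fs"] = self.fs
            f.attrs["n_trials"] = self.n_trials
            f.attrs["trial_length_s"] = self.trial_length_s
            if self.baseline_window:
                f.attrs["baseline_window"] = self.baseline_window
                f.attrs["stim_window"] = self.stim_window
            g = f.create_group("sessions")
            for k, arr in enumerate(self.data):
                g.create_dataset(str(k), data=arr, dtype="f4")
            if self.truth is not None:
                t = f.create_group("truth")
                for name in ("strain", "strain_norm", "impedance",
                             "amplitude", "evoked_gain", "firing_rate",
                             "noise_sd", "session_amp", "session_imp"):
                    t.create_dataset(name, data=getattr(self.truth, name))
                t.create_dataset("dead", data=self.truth.dead.astype("i1"))
                t.attrs["seed"] = self.truth.seed

    @classmethod
    def from_hdf5(cls, path) -> "RecordingSet":
        with h5py.File(path, "r") as f:
            keys = sorted(f["sessions"].keys(), key=int)
            data = [f["sessions"][k][...] for k in keys]
            out = cls(
                data=data, fs=float(f.attrs["fs"]),
                n_trials=int(f.attrs.get("n_trials", 0)),
                trial_length_s=float(f.attrs.get("trial_length_s", 0.0)),
                baseline_window=tuple(f.attrs.get("baseline_window", ())),
                stim_window=tuple(f.attrs.get("stim_window", ())),
            )
            if "truth" in f:
                t = f["truth"]
                out.truth = SyntheticGroundTruth(
                    strain=t["strain"][...],
                    strain_norm=t["strain_norm"][...],
                    impedance=t["impedance"][...],
                    amplitude=t["amplitude"][...],
                    evoked_gain=t["evoked_gain"][...],
                    firing_rate=t["firing_rate"][...],
                    noise_sd=t["noise_sd"][...],
                    dead=t["dead"][...].astype(bool),
                    session_amp=t["session_amp"][...],
                    session_imp=t["session_imp"][...],
                    seed=int(t.attrs["seed"]),
                )
        return out


def spike_template(fs: float = FS, duration_ms: float = 1.5) -> np.ndarray:
    """Biphasic difference-of-Gaussians waveform, unit peak-to-peak.

    Negative-leading trough followed by a smaller positive rebound; only
    the amplitude varies across electrodes, not the shape.
    """
    n = int(round(duration_ms * 1e-3 * fs))
    t = (np.arange(n) - n // 3) / fs * 1e3  # ms, trough near t=0
    w = -np.exp(-0.5 * (t / 0.12) ** 2) + 0.45 * np.exp(
        -0.5 * ((t - 0.35) / 0.25) ** 2)
    return w / (w.max() - w.min())


def normalized_strain(strain: np.ndarray) -> np.ndarray:
    """Within-array min-max normalization to [0, 1]."""
    s = np.asarray(strain, dtype=float)
    rng_ = s.max() - s.min()
    if rng_ <= 0:
        return np.zeros_like(s)
    return (s - s.min()) / rng_


def surrogate_strain_map(layout, noise_sd: float = 0.05,
                         seed: int = 0) -> np.ndarray:
    """Analytic stand-in (synthetic) for a solved strain map.

    Strain falls off from the array edge toward the interior with corners
    highest, mimicking the shielding pattern of the mechanical model;
    useful for exercising the recording pipeline without a FEM solve.
    """
    t = layout.table
    ring = t["ring_label"].to_numpy().astype(float)
    corner = t["is_corner"].to_numpy()
    base = ring / ring.max() + 0.3 * corner
    rng = np.random.default_rng(seed)
    return 0.05 * (base + noise_sd * rng.standard_normal(len(base)) + 0.2)


def simulate_impedances(strain: np.ndarray, link: LinkModel,
                        coating: str = "sirof",
                        dead: np.ndarray | None = None,
                        seed: int = 0,
                        noise: bool = True) -> pd.DataFrame:
    """Per-electrode 1 kHz impedance table (ohm) linked to strain.

    Dead electrodes get impedances a few-fold above the coating's screening
    threshold so the screening stage excludes them by construction.
    """
    if coating not in IMPEDANCE_THRESHOLDS:
        raise ValueError(f"unknown coating {coating!r}")
    s = normalized_strain(strain)
    rng = np.random.default_rng(seed)
    eta = (np.exp(link.sigma_z * rng.standard_normal(len(s)))
           if noise and link.sigma_z > 0 else np.ones(len(s)))
    z = link.z0 * np.exp(link.beta_z * s) * eta
    if dead is not None:
        dead = np.asarray(dead, dtype=bool)
        thr = IMPEDANCE_THRESHOLDS[coating]
        z = np.where(
            dead,
            thr * (3.0 + 2.0 * rng.random(len(s))),
            z)
    return pd.DataFrame({
        "electrode_id": np.arange(len(s)),
        "impedance": z,
        "coating": coating,
    })


def simulate_ground_truth(strain: np.ndarray, link: LinkModel,
                          n_sessions: int = 5, coating: str = "sirof",
                          dead_fraction: float = 0.0,
                          session_sigma_per_electrode=None,
                          seed: int = 0) -> SyntheticGroundTruth:
    """Draw all per-electrode and per-session ground-truth parameters.

    ``session_sigma_per_electrode`` optionally replaces the scalar
    session-variability sd with a per-electrode array (ring-dependent
    variability).
    """
    strain = np.asarray(strain, dtype=float)
    n = len(strain)
    s = normalized_strain(strain)
    root = np.random.default_rng(seed)
    r_imp, r_amp, r_dead, r_sess = [
        np.random.default_rng(ss) for ss in
        np.random.SeedSequence(seed).spawn(4)]
    dead = np.zeros(n, dtype=bool)
    if dead_fraction > 0:
        k = int(round(dead_fraction * n))
        dead[r_dead.choice(n, size=k, replace=False)] = True
    imp = simulate_impedances(strain, link, coating=coating, dead=dead,
                              seed=seed)["impedance"].to_numpy()
    eta_a = (np.exp(link.sigma_a * r_amp.standard_normal(n))
             if link.sigma_a > 0 else np.ones(n))
    amp = link.a0 * np.exp(link.beta_a * s) * eta_a
    amp = np.where(dead, 0.0, amp)
    gain = link.g0 * (1.0 + link.beta_g * s)
    sig_s = (np.asarray(session_sigma_per_electrode, dtype=float)
             if session_sigma_per_electrode is not None
             else np.full(n, link.sigma_session))
    sess_amp = np.exp(sig_s * r_sess.standard_normal((n_sessions, n)))
    sess_imp = np.exp(sig_s * r_sess.standard_normal((n_sessions, n)))
    return SyntheticGroundTruth(
        strain=strain, strain_norm=s, impedance=imp, amplitude=amp,
        evoked_gain=gain, firing_rate=np.full(n, link.firing_rate),
        noise_sd=np.full(n, link.noise_sd), dead=dead,
        session_amp=sess_amp, session_imp=sess_imp, link=link, seed=seed)


def _poisson_spike_train(rng, rate: float, duration: float,
                         refractory_s: float = 2e-3) -> np.ndarray:
    """Homogeneous Poisson spike times with an absolute refractory period."""
    if rate <= 0 or duration <= 0:
        return np.empty(0)
    n_exp = rng.poisson(rate * duration * 1.5) + 10
    isi = rng.exponential(1.0 / rate, size=n_exp) + refractory_s
    t = np.cumsum(isi)
    return t[t < duration]


def _render_session(rng, truth: SyntheticGroundTruth, session: int,
                    duration: float, fs: float,
                    rate_scale=None) -> tuple[np.ndarray, list]:
    n = len(truth.amplitude)
    n_samp = int(round(duration * fs))
    tmpl = spike_template(fs)
    data = np.empty((n, n_samp), dtype=np.float32)
    spikes = []
    link = truth.link or LinkModel()
    shared = None
    if link.shared_noise_mixing > 0 and len(link.shared_noise_electrodes):
        shared = rng.standard_normal(n_samp)
    for e in range(n):
        trace = truth.noise_sd[e] * rng.standard_normal(n_samp)
        rate = truth.firing_rate[e]
        if rate_scale is not None:
            rate = rate * rate_scale[e]
        if truth.dead[e] or truth.amplitude[e] <= 0:
            st = np.empty(0)
        else:
            st = _poisson_spike_train(rng, rate, duration)
            a = truth.amplitude[e] * truth.session_amp[session % len(truth.session_amp), e]
            idx = (st * fs).astype(int)
            for i in idx:
                j = min(i + len(tmpl), n_samp)
                trace[i:j] += a * tmpl[: j - i]
        if shared is not None and e in link.shared_noise_electrodes:
            c = link.shared_noise_mixing
            trace = np.sqrt(1 - c**2) * trace + c * truth.noise_sd[e] * shared
        data[e] = trace
        spikes.append(st)
    return data, spikes


def simulate_spontaneous(truth: SyntheticGroundTruth,
                         duration_s: float = 30.0,
                         n_sessions: int = 5,
                         fs: float = FS,
                         seed: int | None = None) -> RecordingSet:
    """Spontaneous (restful-period) multi-session recordings."""
    if duration_s < 1.0:
        raise ValueError("duration must be >= 1 s")
    seed = truth.seed if seed is None else seed
    streams = np.random.SeedSequence((seed, 1)).spawn(n_sessions)
    data, spikes = [], []
    for k in range(n_sessions):
        rng = np.random.default_rng(streams[k])
        d, st = _render_session(rng, truth, k, duration_s, fs)
        data.append(d)
        spikes.append(st)
    truth.spike_times = spikes
    return RecordingSet(data=data, fs=fs, truth=truth)


def simulate_evoked(truth: SyntheticGroundTruth,
                    n_trials: int = 50,
                    baseline_s: float = 0.5,
                    stim_s: float = 0.5,
                    n_sessions: int = 1,
                    fs: float = FS,
                    seed: int | None = None) -> RecordingSet:
    """Stimulus-evoked trials: baseline then stimulation window per trial.

    During stimulation the firing rate is multiplied by the per-electrode
    evoked gain g_e; baseline matches spontaneous statistics.
    """
    if n_trials < 2:
        raise ValueError("need at least 2 trials")
    seed = truth.seed if seed is None else seed
    trial_len = baseline_s + stim_s
    n_trial_samp = int(round(trial_len * fs))
    streams = np.random.SeedSequence((seed, 2)).spawn(n_sessions * n_trials)
    n = len(truth.amplitude)
    data = []
    for k in range(n_sessions):
        sess = np.empty((n, n_trials * n_trial_samp), dtype=np.float32)
        for tr in range(n_trials):
            rng = np.random.default_rng(streams[k * n_trials + tr])
            base, _ = _render_session(rng, truth, k, baseline_s, fs)
            stim, _ = _render_session(rng, truth, k, stim_s, fs,
                                      rate_scale=truth.evoked_gain)
            lo = tr * n_trial_samp
            sess[:, lo:lo + base.shape[1]] = base
            sess[:, lo + base.shape[1]:lo + n_trial_samp] = stim
        data.append(sess)
    return RecordingSet(data=data, fs=fs, truth=truth, n_trials=n_trials,
                        trial_length_s=trial_len,
                        baseline_window=(0.0, baseline_s),
                        stim_window=(baseline_s, trial_len))
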