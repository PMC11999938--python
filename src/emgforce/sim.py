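"""Synthetic HD-sEMG / force simulator.

Generates grid-organized surface-EMG recordings whose per-channel amplitude
envelope is a known monotone function of exerted force, so that every stage
of the force-estimation pipeline can be tested against ground truth.

Signal model
------------
Each channel carries an amplitude-modulated noise process::

    semg[ch, t] = gain[ch] * w[ch] * f(t)**alpha * carrier[ch, t]
                  + (extra pathology terms) + noise_sd * white[ch, t]

where ``f(t)`` is the normalized force trajectory (fraction of MVC in
[0, 1]), ``alpha`` the per-subject envelope-force exponent, ``w[ch]`` a
spatial Gaussian activation bump over the electrode grid, and ``carrier``
unit-RMS Gaussian noise band-limited to the surface-EMG analysis band
(20 Hz up to min(500, 0.45*fs)).  Rectifying and low-pass filtering a
channel therefore recovers ``gain * w * f**alpha`` up to noise — the
coupling the downstream regressor is trained to invert.

Pathologies (caricatures of cerebral-palsy signal abnormalities) distort
the coupling between the neural drive and the measured force:

``tremor``
    5 Hz multiplicative ripple of depth ``0.4 * strength`` on the drive;
    the measured force carries the mechanically low-pass filtered (3 Hz)
    version, producing the "M"-shaped effort trace.
``shifted_activation``
    activation bump moved to a different grid, with a force-independent
    tonic drive component (muscle stiffness) mixed in.
``coactivation``
    second, overlapping bump whose amplitude does not follow force.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ChannelIndexError, UnknownModeError, ValidationError

FORCE_MODES = ("increasing_plateau", "sine", "constant", "random")
PATHOLOGIES = ("none", "tremor", "shifted_activation", "coactivation")
GROUPS = ("HA", "HC", "CP")

#: symptom-type label attached to each pathology in CP cohorts
SYMPTOM_OF_PATHOLOGY = {
    "shifted_activation": "I",  # stiffness / abnormal muscle tone
    "tremor": "II",             # "M"-shaped tremor during effort
    "coactivation": "III",      # compensatory co-contraction
}


@dataclass(frozen=True)
class GridLayout:
    """Electrode grid geometry: ``n_grids`` pieces of ``rows x cols``."""

    n_grids: int = 4
    rows: int = 4
    cols: int = 4
    #: spacing (in electrode pitches) between adjacent grid pieces when the
    #: pieces are laid out side by side in a common plane
    gap: float = 3.0

    @property
    def n_channels(self) -> int:
        return self.n_grids * self.rows * self.cols

    def channel_index(self, grid: int, row: int, col: int) -> int:
        if not (0 <= grid < self.n_grids and 0 <= row < self.rows and 0 <= col < self.cols):
            raise ChannelIndexError(f"position ({grid},{row},{col}) outside layout {self}")
        return grid * self.rows * self.cols + row * self.cols + col

    def position(self, channel: int) -> tuple[int, int, int]:
        if not 0 <= channel < self.n_channels:
            raise ChannelIndexError(f"channel {channel} outside layout {self}")
        grid, rem = divmod(channel, self.rows * self.cols)
        row, col = divmod(rem, self.cols)
        return grid, row, col

    def grid_of(self, channel: int) -> int:
        return self.position(channel)[0]

    def global_coords(self) -> np.ndarray:
        """(C, 2) array of (row, col) coordinates with grid pieces laid side
        by side along the column axis, in electrode-pitch units."""
        coords = np.empty((self.n_channels, 2))
        for ch in range(self.n_channels):
            g, r, c = self.position(ch)
            coords[ch] = (r, g * (self.cols + self.gap) + c)
        return coords

    def neighbors(self, channel: int) -> list[int]:
        """4-neighbourhood within the same grid piece."""
        g, r, c = self.position(channel)
        out = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < self.rows and 0 <= cc < self.cols:
                out.append(self.channel_index(g, rr, cc))
        return out


ADULT_GRID = GridLayout(n_grids=1, rows=8, cols=16)   # 128-channel adult montage
CHILD_GRID = GridLayout(n_grids=4, rows=4, cols=4)    # 4 x 16 = 64-channel child montage


@dataclass
class ForceTrace:
    """A force trajectory in normalized MVC-fraction units."""

    values: np.ndarray
    fs: float
    mode: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("force trace contains non-finite values")

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.fs

    def copy(self) -> "ForceTrace":
        return ForceTrace(self.values.copy(), self.fs, self.mode, dict(self.params))


@dataclass
class SubjectProfile:
    """Latent per-subject parameters of the signal model.

    ``noise_sd`` is the additive white-noise standard deviation expressed as
    a fraction of the clean multichannel signal's overall RMS (0.316 is a
    10 dB per-recording SNR).
    """

    subject_id: str
    group: str
    gain_map: np.ndarray
    activation_center: tuple[int, int, int]      # (grid, row, col)
    activation_sigma: float = 1.6                # electrode pitches
    nonlinearity_alpha: float = 1.0
    noise_sd: float = 10 ** (-10 / 20)           # 10 dB SNR
    #: amplitude of the grid-wide common-mode interference (cable motion,
    #: powerline residue, far-field crosstalk) relative to the clean signal
    #: RMS; this is the redundancy the PCA spatial filter removes
    common_mode_level: float = 0.35
    pathology: str = "none"
    pathology_strength: float = 1.0
    macs: int | None = None                      # 1..4 for CP
    symptom_type: str | None = None

    def __post_init__(self):
        self.gain_map = np.asarray(self.gain_map, dtype=float)
        if np.any(self.gain_map <= 0):
            raise ValidationError("gain_map entries must be positive")
        if self.nonlinearity_alpha <= 0:
            raise ValidationError("nonlinearity_alpha must be positive")
        if self.group not in GROUPS:
            raise UnknownModeError(f"unknown group {self.group!r}")
        if self.pathology not in PATHOLOGIES:
            raise UnknownModeError(f"unknown pathology {self.pathology!r}")
        if self.group in ("HA", "HC") and self.pathology != "none":
            raise ValidationError("healthy profiles must have pathology='none'")


@dataclass
class Recording:
    """One repetition of one gesture: sEMG matrix plus force trace."""

    semg: np.ndarray                 # channels x time
    force: ForceTrace
    fs: float
    grid: GridLayout
    gesture: str = "G1"
    subject_id: str = "S1"
    repetition: int = 0
    group: str = "HC"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.semg = np.asarray(self.semg, dtype=float)
        if self.semg.ndim != 2:
            raise ValidationError("semg must be a 2-D channels x time matrix")
        if self.semg.shape[0] != self.grid.n_channels:
            raise ValidationError(
                f"semg has {self.semg.shape[0]} rows but grid declares "
                f"{self.grid.n_channels} channels"
            )
        if self.semg.shape[1] != len(self.force.values):
            raise ValidationError("semg and force must cover the same time span")
        if self.fs != self.force.fs:
            raise ValidationError("semg and force sampling rates differ")

    @property
    def n_channels(self) -> int:
        return self.semg.shape[0]

    @property
    def n_samples(self) -> int:
        return self.semg.shape[1]

    def copy(self) -> "Recording":
        return Recording(
            self.semg.copy(), self.force.copy(), self.fs, self.grid,
            self.gesture, self.subject_id, self.repetition, self.group,
            dict(self.meta),
        )


# ---------------------------------------------------------------------------
# force profiles
# ---------------------------------------------------------------------------

def generate_force_profile(
    mode: str,
    duration_s: float,
    fs: float,
    params: dict | None = None,
    seed: int | None = None,
) -> ForceTrace:
    """Generate a normalized force trajectory for one effort.

    Modes
    -----
    ``increasing_plateau``
        linear ramp 0 -> ``amplitude`` over ``ramp_s`` seconds, then a
        constant plateau (default 3 s + 3 s); any remaining duration is a
        linear release back to zero.
    ``sine``
        half-wave-rectified sine between 0 and ``amplitude``.
    ``constant``
        ``amplitude`` throughout.
    ``random``
        band-limited (<= 1 Hz) nonnegative smooth trajectory, seeded.
    """
    if duration_s <= 0:
        raise ValidationError("duration_s must be positive")
    if fs <= 0:
        raise ValidationError("fs must be positive")
    params = dict(params or {})
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    if mode == "increasing_plateau":
        ramp = float(params.get("ramp_s", 3.0))
        plateau = float(params.get("plateau_s", 3.0))
        amp = float(params.get("amplitude", 0.6))
        if ramp <= 0 or plateau < 0:
            raise ValidationError("ramp_s must be > 0 and plateau_s >= 0")
        values = np.empty(n)
        rising = t < ramp
        values[rising] = amp * t[rising] / ramp
        hold = (t >= ramp) & (t < ramp + plateau)
        values[hold] = amp
        tail = t >= ramp + plateau
        if np.any(tail):
            rel = duration_s - (ramp + plateau)
            values[tail] = amp * np.clip(1 - (t[tail] - ramp - plateau) / max(rel, 1 / fs), 0, 1)
    elif mode == "sine":
        amp = float(params.get("amplitude", 0.6))
        period = float(params.get("period_s", 5.0))
        values = amp * np.maximum(0.0, np.sin(2 * np.pi * t / period))
    elif mode == "constant":
        amp = float(params.get("amplitude", 0.4))
        values = np.full(n, amp)
    elif mode == "random":
        amp = float(params.get("amplitude", 0.6))
        cutoff = float(params.get("cutoff_hz", 1.0))
        rng = np.random.default_rng(seed)
        raw = rng.standard_normal(n)
        b, a = sps.butter(4, cutoff, btype="low", fs=fs)
        smooth = sps.filtfilt(b, a, raw)
        lo, hi = smooth.min(), smooth.max()
        values = amp * (smooth - lo) / (hi - lo) if hi > lo else np.full(n, amp / 2)
    else:
        raise UnknownModeError(f"unknown force mode {mode!r}")

    params.setdefault("amplitude", float(np.max(values)) if n else 0.0)
    return ForceTrace(values, fs, mode, params)


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def _bandlimited_noise(rng, shape, fs, low=20.0, high=500.0):
    """Unit-RMS Gaussian noise band-passed to the sEMG analysis band."""
    high = min(high, 0.45 * fs)
    if high <= low:
        raise ValidationError(f"fs={fs} too low for a {low}-{high} Hz carrier")
    raw = rng.standard_normal(shape)
    b, a = sps.butter(4, [low, high], btype="band", fs=fs)
    out = sps.filtfilt(b, a, raw, axis=-1)
    rms = np.sqrt(np.mean(out ** 2, axis=-1, keepdims=True))
    return out / np.maximum(rms, 1e-30)


def _gaussian_bump(grid: GridLayout, center: tuple[int, int, int], sigma: float,
                   floor: float = 0.05) -> np.ndarray:
    coords = grid.global_coords()
    g, r, c = center
    center_xy = np.array([r, g * (grid.cols + grid.gap) + c])
    d2 = np.sum((coords - center_xy) ** 2, axis=1)
    w = np.exp(-d2 / (2.0 * sigma ** 2))
    return floor + (1 - floor) * w


def _shift_center(center, grid: GridLayout):
    g, r, c = center
    return ((g + 1) % grid.n_grids if grid.n_grids > 1 else g,
            grid.rows - 1 - r, grid.cols - 1 - c)


def generate_recording(
    profile: SubjectProfile,
    force: ForceTrace,
    seed: int | None = None,
    grid: GridLayout = CHILD_GRID,
    gesture: str = "G1",
    repetition: int = 0,
) -> Recording:
    """Synthesize one multichannel recording from a subject profile.

    The returned recording's force trace is the *measured* force (for the
    tremor pathology this differs from the commanded profile); the clean
    drive is recoverable from metadata for ground-truth checks.
    """
    if len(profile.gain_map) != grid.n_channels:
        raise ValidationError("profile gain_map length does not match grid")
    rng = np.random.default_rng(seed)
    fs = force.fs
    t = np.arange(len(force.values)) / fs
    f = np.clip(force.values, 0.0, None)
    strength = profile.pathology_strength

    measured = f.copy()
    center = profile.activation_center
    extra = 0.0

    if profile.pathology == "tremor":
        depth = min(0.4 * strength, 0.95)
        mod = 1.0 - depth * (0.5 + 0.5 * np.sin(2 * np.pi * 5.0 * t))
        drive_force = f * mod
        # limb mechanics low-pass the tremor before it reaches the sensor
        b, a = sps.butter(2, 3.0, btype="low", fs=fs)
        measured = np.clip(sps.filtfilt(b, a, drive_force), 0.0, None)
    elif profile.pathology == "shifted_activation":
        # compensatory activation at a remote site: tonic stiffness component
        # plus slow force-independent wander (inconsistent coupling between
        # the compensating muscle's drive and the measured output force)
        center = _shift_center(center, grid)
        tonic = min(0.35 * strength, 0.9)
        drive_force = (1 - tonic) * f + tonic * 0.5 * max(f.max(), 1e-12)
        b, a = sps.butter(2, 1.5, btype="low", fs=fs)
        wander = sps.filtfilt(b, a, rng.standard_normal(len(t)))
        wander /= max(np.std(wander), 1e-12)
        drive_force = np.clip(drive_force * (1.0 + 0.3 * strength * wander),
                              0.0, None)
    else:
        drive_force = f

    drive = drive_force ** profile.nonlinearity_alpha
    w = _gaussian_bump(grid, center, profile.activation_sigma)
    carrier = _bandlimited_noise(rng, (grid.n_channels, len(t)), fs)
    clean = profile.gain_map[:, None] * w[:, None] * drive[None, :] * carrier

    if profile.pathology == "coactivation":
        # second bump in the same grid, overlapping the primary activation,
        # with force-independent amplitude
        g0, r0, c0 = profile.activation_center
        co_center = (g0, (r0 + grid.rows // 2) % grid.rows,
                     (c0 + grid.cols // 2) % grid.cols)
        w2 = _gaussian_bump(grid, co_center, profile.activation_sigma * 1.5)
        amp2 = 0.5 * strength * np.mean(profile.gain_map) * max(np.max(drive), 1e-12)
        carrier2 = _bandlimited_noise(rng, (grid.n_channels, len(t)), fs)
        clean = clean + amp2 * w2[:, None] * carrier2

    clean_rms = np.sqrt(np.mean(clean ** 2))
    # additive noise at a fixed per-channel SNR: each channel's noise floor
    # scales with its own signal level (10 dB SNR at the default noise_sd)
    ch_rms = np.sqrt(np.mean(clean ** 2, axis=1, keepdims=True))
    semg = clean + profile.noise_sd * ch_rms * rng.standard_normal(clean.shape)
    # grid-wide common-mode interference: one shared broadband source coupled
    # into every channel with near-uniform gain, independent of force
    if profile.common_mode_level > 0:
        shared = _bandlimited_noise(rng, (len(t),), fs)
        coupling = 1.0 + 0.1 * rng.standard_normal(grid.n_channels)
        semg = semg + (profile.common_mode_level * clean_rms
                       * coupling[:, None] * shared[None, :])

    measured_trace = ForceTrace(measured, fs, force.mode, dict(force.params))
    return Recording(
        semg, measured_trace, fs, grid, gesture, profile.subject_id,
        repetition, profile.group,
        meta={
            "pathology": profile.pathology,
            "pathology_strength": strength,
            "macs": profile.macs,
            "symptom_type": profile.symptom_type,
            "activation_center": tuple(center),
            "alpha": profile.nonlinearity_alpha,
        },
    )


# ---------------------------------------------------------------------------
# channel faults
# ---------------------------------------------------------------------------

FAULT_KINDS = ("flatline", "saturation", "gross_noise")


def inject_channel_faults(rec: Recording, fault_spec, seed: int | None = None) -> Recording:
    """Return a copy of ``rec`` with faults applied to the listed channels.

    ``fault_spec`` is an iterable of ``(channel, kind)`` or
    ``(channel, kind, param)`` tuples.  ``param`` is the clip level for
    ``saturation`` (default: 30 % of the channel's absolute maximum, which
    saturates well over 20 % of samples of a noise-like signal) and the
    noise multiplier for ``gross_noise`` (default 10x channel SD).
    """
    out = rec.copy()
    rng = np.random.default_rng(seed)
    for entry in fault_spec:
        ch, kind, *rest = entry
        if not 0 <= ch < out.n_channels:
            raise ChannelIndexError(f"channel {ch} out of range")
        if kind == "flatline":
            out.semg[ch] = 0.0
        elif kind == "saturation":
            clip = rest[0] if rest else 0.3 * np.max(np.abs(out.semg[ch]))
            if clip <= 0:
                raise ValidationError("saturation clip level must be positive")
            out.semg[ch] = np.clip(out.semg[ch], -clip, clip)
        elif kind == "gross_noise":
            mult = rest[0] if rest else 10.0
            sd = np.std(out.semg[ch])
            out.semg[ch] = out.semg[ch] + mult * max(sd, 1e-12) * rng.standard_normal(out.n_samples)
        else:
            raise UnknownModeError(f"unknown fault kind {kind!r}")
        out.meta.setdefault("injected_faults", []).append((int(ch), kind))
    return out


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: per-group defaults of the study conditions the simulator emulates
COHORT_DEFAULTS = {
    "HA": {"grid": ADULT_GRID, "modes": ("increasing_plateau", "sine", "constant", "random")},
    "HC": {"grid": CHILD_GRID, "modes": ("increasing_plateau",)},
    "CP": {"grid": CHILD_GRID, "modes": ("increasing_plateau",)},
}

_CP_PATHOLOGY_CYCLE = ("tremor", "shifted_activation", "coactivation")


def make_subject_profile(
    subject_id: str,
    group: str,
    rng: np.random.Generator,
    grid: GridLayout = CHILD_GRID,
    pathology: str | None = None,
    pathology_strength: float | None = None,
    noise_sd: float | None = None,
) -> SubjectProfile:
    """Draw one subject's latent parameters from group-specific ranges."""
    if group not in GROUPS:
        raise UnknownModeError(f"unknown group {group!r}")
    gain = np.exp(rng.normal(0.0, 0.15, grid.n_channels))
    center = (
        int(rng.integers(grid.n_grids)),
        int(rng.integers(1, max(grid.rows - 1, 2))),
        int(rng.integers(1, max(grid.cols - 1, 2))),
    )
    sigma = float(rng.uniform(1.2, 2.2))
    # developmental domain gap: children's envelope-force relationship is
    # systematically more nonlinear than adults' (the gap the adult-to-child
    # transfer calibration bridges); both halves lie in the [0.8, 1.5] band
    alpha = float(rng.uniform(0.8, 1.15)) if group == "HA" \
        else float(rng.uniform(1.15, 1.5))
    if group == "CP":
        pathology = pathology or _CP_PATHOLOGY_CYCLE[int(rng.integers(3))]
        macs = int(rng.integers(1, 5))
        strength = pathology_strength if pathology_strength is not None \
            else 0.25 + 0.25 * macs
        symptom = SYMPTOM_OF_PATHOLOGY.get(pathology)
    else:
        pathology, macs, symptom = "none", None, None
        strength = 0.0
    return SubjectProfile(
        subject_id=subject_id, group=group, gain_map=gain,
        activation_center=center, activation_sigma=sigma,
        nonlinearity_alpha=alpha,
        noise_sd=10 ** (-10 / 20) if noise_sd is None else noise_sd,
        pathology=pathology, pathology_strength=strength,
        macs=macs, symptom_type=symptom,
    )


def make_cohort(
    n_subjects: int,
    group: str,
    gestures=("G1", "G2", "G3", "G4", "G5"),
    reps: int = 8,
    seed: int = 0,
    fs: float = 2000.0,
    ramp_s: float = 3.0,
    plateau_s: float = 3.0,
    grid: GridLayout | None = None,
    noise_sd: float | None = None,
    pathology: str | None = None,
    pathology_strength: float | None = None,
) -> list[Recording]:
    """Generate ``n_subjects x len(gestures) x reps`` recordings.

    Fully reproducible from ``seed``: subject profiles, per-repetition force
    amplitudes and all noise realizations are drawn from one seed sequence.
    """
    if n_subjects < 1 or reps < 1:
        raise ValidationError("n_subjects and reps must be >= 1")
    if group not in GROUPS:
        raise UnknownModeError(f"unknown group {group!r}")
    defaults = COHORT_DEFAULTS[group]
    grid = grid or defaults["grid"]
    modes = defaults["modes"]

    ss = np.random.SeedSequence([seed, GROUPS.index(group)])
    subj_seeds = ss.spawn(n_subjects)
    recordings: list[Recording] = []
    for si, sseq in enumerate(subj_seeds):
        rng = np.random.default_rng(sseq)
        profile = make_subject_profile(
            f"{group}{si + 1}", group, rng, grid,
            pathology=pathology, pathology_strength=pathology_strength,
            noise_sd=noise_sd,
        )
        for gesture in gestures:
            for rep in range(reps):
                mode = modes[len(recordings) % len(modes)]
                amp = float(rng.uniform(0.5, 0.7))
                duration = ramp_s + plateau_s
                if mode == "increasing_plateau":
                    params = {"ramp_s": ramp_s, "plateau_s": plateau_s, "amplitude": amp}
                elif mode == "constant":
                    # a recorded "constant-force" effort still rises from and
                    # returns to rest; a perfectly flat trace would make the
                    # min-max force normalization degenerate
                    mode = "increasing_plateau"
                    params = {"ramp_s": min(0.5, duration / 4),
                              "plateau_s": duration - 2 * min(0.5, duration / 4),
                              "amplitude": amp}
                else:
                    params = {"amplitude": amp}
                force = generate_force_profile(
                    mode, duration, fs, params,
                    seed=int(rng.integers(2 ** 31)),
                )
                recordings.append(generate_recording(
                    profile, force, seed=int(rng.integers(2 ** 31)),
                    grid=grid, gesture=gesture, repetition=rep,
                ))
    return recordings


def cohort_profiles(recordings: list[Recording]) -> dict[str, dict]:
    """Subject-level metadata (group, pathology, MACS...) from a cohort."""
    out: dict[str, dict] = {}
    for rec in recordings:
        out.setdefault(rec.subject_id, {
            "group": rec.group,
            "pathology": rec.meta.get("pathology"),
            "pathology_strength": rec.meta.get("pathology_strength"),
            "macs": rec.meta.get("macs"),
            "symptom_type": rec.meta.get("symptom_type"),
        })
    return out
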