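"""Preprocessing chain: Recording -> (1-D optimal-channel envelope, force) -> windows.

Stages, in order:

1. channel screening and repair (variance floor, clipping fraction, RMS
   outliers; defective channels replaced by their valid 4-neighbourhood mean);
2. optional linear-in-time upsampling to a common rate;
3. band-pass FIR filtering (order 100, Hann window, 20-500 Hz, applied
   forward-backward for zero phase);
4. PCA spatial filtering: reconstruct the multichannel signal without the
   principal components of highest (common-mode) and lowest (measurement
   noise) explained variance;
5. envelope extraction: full-wave rectification, 5 Hz low-pass FIR, per
   channel min-max normalization x' = (x - x_min) / (x_max - x_min);
6. NMF of the envelope matrix into activation modes (spatial weights) and
   activation coefficients (time courses); the mode with the largest summed
   coefficient row is the primary activation mode;
7. selection of the top quarter of channels by primary-mode weight and
   collapse to a single weighted-average envelope;
8. force smoothing + min-max normalization, and segmentation of envelope and
   force into fixed-length windows (default 500 samples, step 500) with one
   scalar force target per window.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import (
    DegenerateDecompositionError,
    RecordingUnusableError,
    ValidationError,
)
from .sim import ForceTrace, Recording

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# min-max normalization (used for envelopes and force alike)
# ---------------------------------------------------------------------------

def minmax_normalize(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Scale to [0, 1] per row: ``(x - min) / (max - min)``.

    Degenerate rows (max == min) come back as all zeros with a warning, so a
    dead channel cannot poison downstream averaging.
    """
    x = np.asarray(x, dtype=float)
    lo = x.min(axis=axis, keepdims=True)
    hi = x.max(axis=axis, keepdims=True)
    span = hi - lo
    degenerate = span <= 0
    if np.any(degenerate):
        logger.warning("min-max normalization: %d constant row(s) set to zero",
                       int(np.sum(degenerate)))
    safe = np.where(degenerate, 1.0, span)
    out = (x - lo) / safe
    return np.where(np.broadcast_to(degenerate, out.shape), 0.0, out)


# ---------------------------------------------------------------------------
# channel screening
# ---------------------------------------------------------------------------

@dataclass
class ChannelQualityReport:
    flagged: list[int] = field(default_factory=list)
    reasons: dict[int, list[str]] = field(default_factory=dict)
    repaired: list[int] = field(default_factory=list)

    @property
    def n_flagged(self) -> int:
        return len(self.flagged)


@dataclass
class ScreeningCriteria:
    variance_floor: float = 1e-12
    clip_fraction_ceiling: float = 0.1
    #: a sample counts as clipped when |x| >= clip_tol * max|x| of its channel
    clip_tol: float = 0.999
    #: a channel is an amplitude outlier when its RMS differs from the median
    #: RMS of its grid neighbours by more than this factor; the comparison is
    #: local because focal muscle activation makes strong channels legitimate
    #: global outliers on any healthy grid
    rms_neighbor_factor: float = 5.0
    max_flagged_fraction: float = 0.5


def screen_channels(
    rec: Recording, criteria: ScreeningCriteria | None = None
) -> tuple[ChannelQualityReport, Recording]:
    """Flag defective channels and replace them by valid-neighbour means.

    A channel is defective when its variance is below the floor (flatline),
    when more than ``clip_fraction_ceiling`` of its samples sit at its
    absolute maximum (saturation), or when its RMS differs from the median
    RMS of its grid neighbours by more than ``rms_neighbor_factor`` (gross
    noise or a loose electrode; the spatial reference keeps legitimately
    strong channels over the activation bump unflagged).
    """
    if rec.n_channels < 4:
        raise ValidationError("screening needs at least 4 channels")
    crit = criteria or ScreeningCriteria()
    x = rec.semg
    var = x.var(axis=1)
    absmax = np.abs(x).max(axis=1)
    with np.errstate(invalid="ignore"):
        clip_frac = np.where(
            absmax > 0,
            np.mean(np.abs(x) >= crit.clip_tol * absmax[:, None], axis=1),
            1.0,
        )
    rms = np.sqrt(np.mean(x ** 2, axis=1))

    report = ChannelQualityReport()
    for ch in range(rec.n_channels):
        reasons = []
        if var[ch] < crit.variance_floor:
            reasons.append("variance_floor")
        if clip_frac[ch] > crit.clip_fraction_ceiling:
            reasons.append("clipping")
        nbr = np.median(rms[rec.grid.neighbors(ch)])
        if nbr > 0 and not (nbr / crit.rms_neighbor_factor
                            <= rms[ch]
                            <= nbr * crit.rms_neighbor_factor):
            reasons.append("rms_outlier")
        if reasons:
            report.flagged.append(ch)
            report.reasons[ch] = reasons

    if report.n_flagged > crit.max_flagged_fraction * rec.n_channels:
        raise RecordingUnusableError(
            f"{report.n_flagged}/{rec.n_channels} channels defective"
        )
    if not report.flagged:
        return report, rec

    out = rec.copy()
    bad = set(report.flagged)
    valid_mean = x[[c for c in range(rec.n_channels) if c not in bad]].mean(axis=0)
    for ch in report.flagged:
        nbrs = [n for n in rec.grid.neighbors(ch) if n not in bad]
        out.semg[ch] = x[nbrs].mean(axis=0) if nbrs else valid_mean
        report.repaired.append(ch)
    logger.info("screening: repaired channels %s", report.repaired)
    return report, out


# ---------------------------------------------------------------------------
# resampling and filtering
# ---------------------------------------------------------------------------

def resample_to(rec: Recording, target_fs: float) -> Recording:
    """Upsample every channel and the force trace by linear interpolation.

    For one spatial dimension per channel, bilinear interpolation in
    (time, channel) degenerates to independent linear interpolation in time,
    which is what this implements.  Downsampling is refused.
    """
    if target_fs < rec.fs:
        raise ValidationError("resample_to only upsamples (target_fs >= fs)")
    if target_fs == rec.fs:
        return rec
    n_old = rec.n_samples
    n_new = int(round(n_old * target_fs / rec.fs))
    t_old = np.arange(n_old) / rec.fs
    t_new = np.arange(n_new) / target_fs
    semg = np.empty((rec.n_channels, n_new))
    for ch in range(rec.n_channels):
        semg[ch] = np.interp(t_new, t_old, rec.semg[ch])
    force = ForceTrace(
        np.interp(t_new, t_old, rec.force.values),
        target_fs, rec.force.mode, dict(rec.force.params),
    )
    return Recording(semg, force, target_fs, rec.grid, rec.gesture,
                     rec.subject_id, rec.repetition, rec.group, dict(rec.meta))


def _fir(numtaps: int, fs: float, low: float | None, high: float | None) -> np.ndarray:
    if low is not None and high is not None:
        return sps.firwin(numtaps, [low, high], window="hann",
                          pass_zero=False, fs=fs)
    return sps.firwin(numtaps, high, window="hann", fs=fs)


def _filtfilt(b: np.ndarray, x: np.ndarray) -> np.ndarray:
    padlen = min(3 * len(b), x.shape[-1] - 1)
    return sps.filtfilt(b, [1.0], x, axis=-1, padlen=padlen)


def bandpass_filter(
    matrix: np.ndarray, fs: float,
    low: float = 20.0, high: float = 500.0, order: int = 100,
) -> np.ndarray:
    """Zero-phase band-pass with a Hann-window FIR of the given order.

    The upper edge is clipped to ``0.45 * fs`` so the design stays valid for
    1 kHz sources before upsampling.
    """
    if fs <= 2 * low:
        raise ValidationError(f"fs={fs} too low for a {low} Hz high-pass edge")
    high_eff = min(high, 0.45 * fs)
    b = _fir(order + 1, fs, low, high_eff)
    return _filtfilt(b, np.asarray(matrix, dtype=float))


# ---------------------------------------------------------------------------
# PCA spatial filter
# ---------------------------------------------------------------------------

def pca_spatial_filter(matrix: np.ndarray) -> np.ndarray:
    """Reconstruct the multichannel signal without its extreme components.

    Channels are the variables, time samples the observations.  The
    principal component with the highest explained variance carries
    redundant common-mode information and the one with the lowest carries
    measurement noise; both are removed before reconstruction.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValidationError("PCA spatial filter needs >= 3 channels")
    mean = x.mean(axis=1, keepdims=True)
    xc = x - mean
    cov = xc @ xc.T / x.shape[1]
    evals, evecs = np.linalg.eigh(cov)       # ascending order
    keep = evecs[:, 1:-1]                    # drop smallest and largest
    return keep @ (keep.T @ xc) + mean


# ---------------------------------------------------------------------------
# envelopes
# ---------------------------------------------------------------------------

@dataclass
class EnvelopeMatrix:
    """Per-channel rectified / low-passed / min-max normalized envelopes."""

    values: np.ndarray               # channels x time, in [0, 1]
    fs: float
    channel_ids: np.ndarray
    x_min: np.ndarray                # pre-normalization bounds per channel
    x_max: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def denormalized(self) -> np.ndarray:
        """Amplitude-bearing envelope (undo the per-channel min-max scaling).

        Spatial information — which channels are strongly active — lives in
        the raw amplitudes; the normalized values are for the regressor.
        """
        return self.values * (self.x_max - self.x_min)[:, None] + self.x_min[:, None]


def compute_envelope(
    matrix: np.ndarray, fs: float, cutoff: float = 5.0, order: int = 100,
) -> EnvelopeMatrix:
    """Full-wave rectification, zero-phase 5 Hz FIR low-pass, min-max scaling."""
    x = np.abs(np.asarray(matrix, dtype=float))
    b = _fir(order + 1, fs, None, cutoff)
    env = _filtfilt(b, x)
    x_min = env.min(axis=1)
    x_max = env.max(axis=1)
    return EnvelopeMatrix(
        values=minmax_normalize(env, axis=1),
        fs=fs,
        channel_ids=np.arange(x.shape[0]),
        x_min=x_min, x_max=x_max,
    )


# ---------------------------------------------------------------------------
# NMF channel optimization
# ---------------------------------------------------------------------------

@dataclass
class ActivationDecomposition:
    """NMF factors of the envelope matrix.

    ``weights[m]`` is activation mode m's spatial pattern over channels;
    ``coefficients[m]`` its time course.  The sum of a coefficient row is
    the mode's activation intensity; the most intense mode is primary.
    """

    weights: np.ndarray              # modes x channels
    coefficients: np.ndarray         # modes x time
    objective: np.ndarray            # Frobenius reconstruction error per iteration

    @property
    def intensity(self) -> np.ndarray:
        return self.coefficients.sum(axis=1)

    @property
    def primary_mode(self) -> int:
        return int(np.argmax(self.intensity))


def nmf_decompose(
    env: EnvelopeMatrix | np.ndarray,
    rank: int = 2,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> ActivationDecomposition:
    """Multiplicative-update NMF (Frobenius objective) of the envelope matrix.

    An :class:`EnvelopeMatrix` is decomposed on its *de-normalized* values so
    the activation-mode weights rank channels by actual activation amplitude
    (per-channel unit-range scaling would make every channel look equally
    active).  The classical Lee-Seung updates guarantee a non-increasing
    objective, recorded per iteration in ``objective``.
    """
    v = env.denormalized() if isinstance(env, EnvelopeMatrix) else np.asarray(env, dtype=float)
    if np.any(v < 0):
        raise ValidationError("NMF input must be nonnegative")
    c, t = v.shape
    if not 1 <= rank <= c:
        raise ValidationError(f"rank must be in [1, {c}]")
    rng = np.random.default_rng(seed)
    scale = math.sqrt(max(v.mean(), 1e-30) / rank)
    w = scale * rng.uniform(0.1, 1.0, (c, rank))
    h = scale * rng.uniform(0.1, 1.0, (rank, t))
    eps = 1e-12
    obj = [np.linalg.norm(v - w @ h)]
    for _ in range(max_iter):
        h *= (w.T @ v) / np.maximum(w.T @ w @ h, eps)
        w *= (v @ h.T) / np.maximum(w @ (h @ h.T), eps)
        obj.append(np.linalg.norm(v - w @ h))
        if abs(obj[-2] - obj[-1]) <= tol * max(obj[-2], eps):
            break
    return ActivationDecomposition(
        weights=w.T.copy(), coefficients=h.copy(), objective=np.array(obj)
    )


@dataclass
class ChannelSelection:
    indices: np.ndarray              # selected channel ids
    weights: np.ndarray              # nonnegative, summing to 1


def select_optimal_channels(dec: ActivationDecomposition) -> ChannelSelection:
    """Keep the top quarter of channels by primary-activation-mode weight.

    Exactly ``ceil(C / 4)`` channels are kept; ties broken toward the lower
    channel index; selection weights are the primary-mode weights
    renormalized to sum to one.
    """
    w = dec.weights[dec.primary_mode]
    if np.all(w <= 0):
        raise DegenerateDecompositionError("primary activation mode is all zero")
    c = len(w)
    k = math.ceil(c / 4)
    # stable sort on (-weight, index): lower index wins ties
    order = np.lexsort((np.arange(c), -w))
    idx = np.sort(order[:k])
    sel_w = w[idx]
    total = sel_w.sum()
    if total <= 0:
        raise DegenerateDecompositionError("selected channels carry zero weight")
    return ChannelSelection(indices=idx, weights=sel_w / total)


def collapse_to_envelope(env: EnvelopeMatrix, sel: ChannelSelection) -> np.ndarray:
    """Weighted average of the selected channels, min-max renormalized."""
    if len(sel.indices) == 0:
        raise ValidationError("empty channel selection")
    if not np.all(np.isin(sel.indices, env.channel_ids)):
        raise ValidationError("selection refers to channels absent from envelope")
    rows = env.values[np.searchsorted(env.channel_ids, sel.indices)]
    avg = sel.weights @ rows
    return minmax_normalize(avg[None, :], axis=1)[0]


# ---------------------------------------------------------------------------
# force conditioning and segmentation
# ---------------------------------------------------------------------------

def smooth_and_normalize_force(force: ForceTrace, smooth_s: float = 0.05) -> np.ndarray:
    """Zero-phase moving average (burr removal) then min-max normalization."""
    x = np.asarray(force.values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("force trace contains non-finite values")
    win = max(int(round(smooth_s * force.fs)), 1)
    if win > 1:
        kernel = np.ones(win) / win
        pad = win // 2
        xp = np.pad(x, pad, mode="edge")
        sm = np.convolve(xp, kernel, mode="same")[pad:pad + len(x)]
    else:
        sm = x
    return minmax_normalize(sm[None, :], axis=1)[0]


@dataclass
class SampleSet:
    """Paired (envelope window, scalar force target) samples with provenance."""

    windows: np.ndarray              # n x L
    targets: np.ndarray              # n
    subjects: np.ndarray             # n, str
    gestures: np.ndarray             # n, str
    repetitions: np.ndarray          # n, int

    def __post_init__(self):
        n = len(self.windows)
        for name in ("targets", "subjects", "gestures", "repetitions"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"SampleSet field {name} length mismatch")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def window_length(self) -> int:
        return self.windows.shape[1] if len(self.windows) else 0

    def subset(self, mask_or_idx) -> "SampleSet":
        return SampleSet(
            self.windows[mask_or_idx], self.targets[mask_or_idx],
            self.subjects[mask_or_idx], self.gestures[mask_or_idx],
            self.repetitions[mask_or_idx],
        )

    @staticmethod
    def empty(window_length: int = 0) -> "SampleSet":
        return SampleSet(
            np.empty((0, window_length)), np.empty(0),
            np.empty(0, dtype="<U32"), np.empty(0, dtype="<U32"),
            np.empty(0, dtype=int),
        )

    @staticmethod
    def concatenate(parts: list["SampleSet"]) -> "SampleSet":
        parts = [p for p in parts if len(p)]
        if not parts:
            return SampleSet.empty()
        return SampleSet(
            np.concatenate([p.windows for p in parts]),
            np.concatenate([p.targets for p in parts]),
            np.concatenate([p.subjects for p in parts]),
            np.concatenate([p.gestures for p in parts]),
            np.concatenate([p.repetitions for p in parts]),
        )

    def by_subject(self) -> dict[str, "SampleSet"]:
        return {s: self.subset(self.subjects == s) for s in np.unique(self.subjects)}


def segment_samples(
    envelope: np.ndarray,
    force: np.ndarray,
    L: int = 500,
    step: int = 500,
    subject: str = "S1",
    gesture: str = "G1",
    repetition: int = 0,
) -> SampleSet:
    """Slide a length-``L`` window (hop ``step``) over the aligned pair.

    The per-window force target is the mean of the normalized force over the
    window; a trailing partial window is discarded.
    """
    envelope = np.asarray(envelope, dtype=float)
    force = np.asarray(force, dtype=float)
    if envelope.shape != force.shape:
        raise ValidationError("envelope and force must have the same length")
    if L <= 0 or step <= 0:
        raise ValidationError("window length and step must be positive")
    n_total = len(envelope)
    if n_total < L:
        logger.warning("segment_samples: trace shorter than one window (%d < %d)",
                       n_total, L)
        return SampleSet.empty(L)
    n = (n_total - L) // step + 1
    starts = np.arange(n) * step
    windows = np.stack([envelope[s:s + L] for s in starts])
    targets = np.array([force[s:s + L].mean() for s in starts])
    return SampleSet(
        windows, targets,
        np.full(n, subject, dtype="<U32"),
        np.full(n, gesture, dtype="<U32"),
        np.full(n, repetition, dtype=int),
    )


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

@dataclass
class PreprocessConfig:
    target_fs: float | None = None   # upsample to this rate when set
    band_low: float = 20.0
    band_high: float = 500.0
    band_order: int = 100
    envelope_cutoff: float = 5.0
    envelope_order: int = 100
    nmf_rank: int = 2
    nmf_seed: int = 0
    nmf_tol: float = 1e-5
    nmf_max_iter: int = 500
    force_smooth_s: float = 0.05
    window: int = 500
    step: int = 500
    screening: ScreeningCriteria = field(default_factory=ScreeningCriteria)


def preprocess_recording(
    rec: Recording, cfg: PreprocessConfig | None = None
) -> tuple[SampleSet, dict]:
    """Run the full chain on one recording.

    Returns the windowed samples plus a diagnostics dict (screening report,
    channel selection, 1-D envelope and normalized force) for inspection.
    """
    cfg = cfg or PreprocessConfig()
    report, rec = screen_channels(rec, cfg.screening)
    if cfg.target_fs and cfg.target_fs > rec.fs:
        rec = resample_to(rec, cfg.target_fs)
    filtered = bandpass_filter(rec.semg, rec.fs, cfg.band_low, cfg.band_high,
                               cfg.band_order)
    filtered = pca_spatial_filter(filtered)
    env = compute_envelope(filtered, rec.fs, cfg.envelope_cutoff, cfg.envelope_order)
    dec = nmf_decompose(env, cfg.nmf_rank, cfg.nmf_seed, cfg.nmf_tol,
                        cfg.nmf_max_iter)
    sel = select_optimal_channels(dec)
    envelope_1d = collapse_to_envelope(env, sel)
    force_norm = smooth_and_normalize_force(rec.force, cfg.force_smooth_s)
    samples = segment_samples(
        envelope_1d, force_norm, cfg.window, cfg.step,
        subject=rec.subject_id, gesture=rec.gesture, repetition=rec.repetition,
    )
    diagnostics = {
        "screening": report,
        "selection": sel,
        "decomposition": dec,
        "envelope": envelope_1d,
        "force": force_norm,
    }
    return samples, diagnostics


def preprocess_cohort(
    recordings: list[Recording], cfg: PreprocessConfig | None = None
) -> SampleSet:
    """Preprocess every recording and pool the windows."""
    parts = [preprocess_recording(r, cfg)[0] for r in recordings]
    return SampleSet.concatenate(parts)
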