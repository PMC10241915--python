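"""Surface-EMG envelope extraction, MVC normalization and phase curves.

The processing chain turns a raw EMG trace into the two quantities the
analysis consumes:

* the mean contraction amplitude over the reach-to-place trial, expressed as
  a fraction of the subject's maximal voluntary contraction (MVC); and
* per-phase activation envelopes resampled onto a common 1–100 time axis
  (time normalization), whose three phases concatenate into a 300-point
  "full trial" curve.

Envelope chain: zero-phase Butterworth high-pass at 3 Hz, full-wave
rectification, zero-phase Butterworth low-pass at 2 Hz.  The nominal band
extends to 1000 Hz, which is the Nyquist frequency at the 2000 Hz sampling
rate, so the upper edge is a no-op and only the high-pass is applied; the
acquisition hardware band (10–500 Hz) already limits the spectrum.  Filters
are 4th-order and run forward-backward (``scipy.signal.filtfilt``) so the
envelope stays aligned with the video-coded phase timestamps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

MUSCLES = ("OP", "FDI", "ADM")
PHASES = ("reaching", "holding", "transport")
N_POINTS = 100

DEFAULT_HIGHPASS_HZ = 3.0
DEFAULT_LOWPASS_HZ = 2.0
DEFAULT_FILTER_ORDER = 4
DEFAULT_MVC_WINDOW_S = 0.5


class DegenerateInputError(ValueError):
    """Input too short or otherwise unusable for the requested operation."""


@dataclass
class EmgTrace:
    """Raw sampled EMG for one subject/session/muscle."""

    subject: str
    session: int
    muscle: str
    samples: np.ndarray
    sampling_rate: float = 2000.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.isfinite(self.samples).all():
            raise ValueError("trace contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass
class MarbleEvents:
    """Video-coded timestamps (seconds) for one marble's reach-to-place.

    ``attempt_contacts`` lists every chopstick–marble contact, including the
    successful grasp and any re-grasp after a drop; ``drops`` lists accidental
    fallings during transport; ``aborted_lifts`` the liftings whose transport
    was aborted by a drop.  ``lift``/``place`` refer to the final, successful
    transport.
    """

    reach_start: float
    grasp_contact: float
    lift: float
    place: float
    attempt_contacts: list = field(default_factory=list)
    drops: list = field(default_factory=list)
    aborted_lifts: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.reach_start < self.grasp_contact < self.lift < self.place):
            raise ValueError(
                "marble timestamps must satisfy reach_start < grasp_contact < lift < place"
            )

    @property
    def first_contact(self) -> float:
        return min(self.attempt_contacts) if self.attempt_contacts else self.grasp_contact

    def phase_bounds(self) -> dict:
        """Half-open [start, end) phase intervals used for EMG segmentation."""
        return {
            "reaching": (self.reach_start, self.grasp_contact),
            "holding": (self.grasp_contact, self.lift),
            "transport": (self.lift, self.place),
        }


@dataclass
class PhaseAnnotation:
    """Ordered per-marble events for one execution session."""

    marbles: list

    def __post_init__(self) -> None:
        ends = 0.0
        for m in self.marbles:
            if m.reach_start < ends:
                raise ValueError("marbles must be ordered and non-overlapping")
            ends = m.place

    def validate_against(self, trace: EmgTrace) -> None:
        if self.marbles and self.marbles[-1].place > trace.duration + 1e-9:
            raise ValueError("annotation extends past the end of the trace")


@dataclass(frozen=True)
class MvcReference:
    subject: str
    muscle: str
    mvc_value: float

    def __post_init__(self) -> None:
        if self.mvc_value <= 0:
            raise ValueError("mvc_value must be positive")


def compute_envelope(
    trace: EmgTrace,
    highpass_hz: float = DEFAULT_HIGHPASS_HZ,
    lowpass_hz: float = DEFAULT_LOWPASS_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> np.ndarray:
    """Linear envelope of a raw trace: high-pass, rectify, low-pass, clip.

    Output is non-negative and the same length as the input.
    """
    fs = trace.sampling_rate
    x = trace.samples
    # filtfilt needs padding room; require a few settling lengths
    min_len = 3 * (3 * (order + 1))
    if x.size < min_len:
        raise DegenerateInputError(
            f"trace of {x.size} samples too short for order-{order} zero-phase filtering"
        )
    sos_hp = signal.butter(order, highpass_hz, btype="highpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos_hp, x)
    x = np.abs(x)
    sos_lp = signal.butter(order, lowpass_hz, btype="lowpass", fs=fs, output="sos")
    env = signal.sosfiltfilt(sos_lp, x)
    return np.clip(env, 0.0, None)


def compute_mvc(
    mvc_trace: EmgTrace,
    window_s: float = DEFAULT_MVC_WINDOW_S,
    **envelope_kwargs,
) -> MvcReference:
    """Maximal-contraction reference from a dedicated MVC block.

    The statistic is the maximum of the envelope's sliding-window mean
    (default window 500 ms, step one sample), which resists single-sample
    spikes better than a plain maximum.
    """
    if mvc_trace.duration < 2.0:
        raise DegenerateInputError("MVC block must be at least 2 s long")
    env = compute_envelope(mvc_trace, **envelope_kwargs)
    win = max(1, int(round(window_s * mvc_trace.sampling_rate)))
    smoothed = np.convolve(env, np.ones(win) / win, mode="valid")
    mvc = float(smoothed.max())
    if mvc <= 0:
        raise DegenerateInputError("all-zero MVC block: normalization undefined")
    return MvcReference(mvc_trace.subject, mvc_trace.muscle, mvc)


def _interval_to_slice(start: float, end: float, fs: float, n: int) -> slice:
    """Half-open [start, end) in seconds -> sample slice via floor(t * fs)."""
    i0 = int(np.floor(start * fs))
    i1 = int(np.floor(end * fs))
    i0 = max(0, min(i0, n))
    i1 = max(0, min(i1, n))
    return slice(i0, i1)


def mean_contraction_amplitude(
    envelope: np.ndarray,
    sampling_rate: float,
    annotation: PhaseAnnotation,
    mvc: MvcReference,
) -> float:
    """Mean envelope over the union of reach-to-place intervals, / MVC.

    The trial window is the union of each marble's [reach_start, place)
    interval; inter-marble pauses fall outside it by construction.
    """
    n = envelope.size
    parts = []
    for m in annotation.marbles:
        sl = _interval_to_slice(m.reach_start, m.place, sampling_rate, n)
        if sl.stop > sl.start:
            parts.append(envelope[sl])
    if not parts:
        raise DegenerateInputError("empty trial window: no usable marble intervals")
    return float(np.concatenate(parts).mean() / mvc.mvc_value)


def segment_phases(
    envelope: np.ndarray, sampling_rate: float, annotation: PhaseAnnotation
) -> list:
    """Cut the envelope into per-marble, per-phase segments.

    Returns a list (one entry per marble) of ``{phase: segment}`` dicts.
    Intervals are half-open so the three phases tile [reach_start, place)
    exactly, sample by sample.
    """
    n = envelope.size
    out = []
    for k, m in enumerate(annotation.marbles):
        segs = {}
        for phase, (t0, t1) in m.phase_bounds().items():
            sl = _interval_to_slice(t0, t1, sampling_rate, n)
            if sl.stop - sl.start < 2:
                raise DegenerateInputError(
                    f"marble {k}: phase '{phase}' shorter than 2 samples"
                )
            segs[phase] = envelope[sl]
        out.append(segs)
    return out


def time_normalize(segment: np.ndarray, n_points: int = N_POINTS) -> np.ndarray:
    """Resample a segment onto ``n_points`` equally spaced instants (1–100 axis).

    Linear interpolation from the first to the last sample instant; endpoints
    are preserved, and a segment already of length ``n_points`` passes through
    unchanged (the operation is idempotent).
    """
    seg = np.asarray(segment, dtype=float)
    if seg.size < 2:
        raise DegenerateInputError("segment must contain at least 2 samples")
    old = np.linspace(0.0, 1.0, seg.size)
    new = np.linspace(0.0, 1.0, n_points)
    return np.interp(new, old, seg)


def session_curve(marble_curves, how: str = "mean") -> np.ndarray:
    """Aggregate per-marble normalized curves into one session-level curve.

    Point-wise mean across marbles by default; ``how="median"`` is available
    as a robustness check.
    """
    stack = np.asarray(list(marble_curves), dtype=float)
    if stack.ndim != 2 or stack.shape[0] < 1:
        raise ValueError("need at least one marble curve")
    if how == "mean":
        return stack.mean(axis=0)
    if how == "median":
        return np.median(stack, axis=0)
    raise ValueError(f"unknown aggregation rule: {how!r}")


def concatenate_phases(
    reaching: np.ndarray, holding: np.ndarray, transport: np.ndarray
) -> np.ndarray:
    """Concatenate the three 100-point phase curves into the full-trial curve."""
    parts = [np.asarray(c, dtype=float) for c in (reaching, holding, transport)]
    for c in parts:
        if c.shape != (N_POINTS,):
            raise ValueError(f"each phase curve must have exactly {N_POINTS} points")
    return np.concatenate(parts)


def split_full_trial(full: np.ndarray) -> tuple:
    """Inverse of :func:`concatenate_phases`."""
    full = np.asarray(full, dtype=float)
    if full.shape != (3 * N_POINTS,):
        raise ValueError(f"full-trial curve must have exactly {3 * N_POINTS} points")
    return full[:N_POINTS], full[N_POINTS : 2 * N_POINTS], full[2 * N_POINTS :]
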