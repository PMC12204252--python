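"""Trial epochs -> subject/condition time-frequency matrices.

Processing contract: ROI-level trial epochs spanning -1 to 1 s around
stimulus onset are decomposed with the multitaper method into oscillatory
power at 1-45 Hz; power is converted to decibels and baseline-corrected per
trial and per frequency against the -0.3 to 0 s pre-stimulus mean; corrected
trials are averaged and the 0 to 0.7 s post-stimulus segment is decimated
onto the T=27 analysis grid.

Upstream raw-EEG cleaning (filtering, channel repair, artifact removal,
source localization) is out of scope: inputs are already ROI time courses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from mne.time_frequency import tfr_array_multitaper

from .containers import Condition, TFRMatrix, TimeFreqGrid


@dataclass
class TrialEpoch:
    """One ROI time course for one stimulation trial.

    ``data`` spans ``[t_start, t_start + n/sfreq)`` seconds relative to
    stimulus onset; the default layout is -1 to 1 s.
    """

    data: np.ndarray
    sfreq: float
    subject: str = ""
    roi: str = ""
    condition: Condition | None = None
    t_start: float = -1.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 1:
            raise ValueError("epoch data must be 1-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data must be finite")
        if self.sfreq <= 0:
            raise ValueError("sample rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.data.size) / self.sfreq

    @property
    def duration(self) -> float:
        return self.data.size / self.sfreq


@dataclass
class TaperConfig:
    """Multitaper settings.

    ``n_cycles`` per frequency sets the sliding-window length (cycles / f
    seconds); the default max(f/2, 1) keeps a half-second window at and
    above 2 Hz and a full cycle at 1 Hz. ``time_bandwidth`` is the
    time-half-bandwidth product controlling the number of tapers.
    """

    n_cycles: np.ndarray | float | None = None
    time_bandwidth: float = 4.0

    def resolve_cycles(self, freqs: np.ndarray) -> np.ndarray:
        if self.n_cycles is None:
            return np.maximum(freqs / 2.0, 1.0)
        return np.broadcast_to(np.asarray(self.n_cycles, float),
                               freqs.shape).copy()


def _check_window(freqs: np.ndarray, n_cycles: np.ndarray,
                  duration: float) -> None:
    win = n_cycles / freqs
    too_long = win > duration
    if too_long.any():
        f_bad = freqs[too_long][0]
        raise ValueError(
            f"epoch of {duration:.3f} s is shorter than the "
            f"{win[too_long][0]:.3f} s taper window required at "
            f"{f_bad:g} Hz")


def multitaper_power(epoch: TrialEpoch, freqs=None,
                     taper_config: TaperConfig | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Multitaper power of one epoch.

    Returns ``(times, power)`` with ``power`` of shape (n_times, F):
    taper-averaged spectral power on the epoch's dense time grid.
    """
    freqs = np.arange(1.0, 46.0) if freqs is None else np.asarray(freqs, float)
    times, power = _multitaper_batch([epoch], freqs, taper_config)
    return times, power[0]


def _multitaper_batch(epochs: list[TrialEpoch], freqs: np.ndarray,
                      taper_config: TaperConfig | None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Shared-settings multitaper over same-shape trials.

    Returns (times, power) with power of shape (n_trials, n_times, F).
    """
    cfg = taper_config or TaperConfig()
    sfreq = epochs[0].sfreq
    n = epochs[0].data.size
    for e in epochs:
        if e.sfreq != sfreq or e.data.size != n:
            raise ValueError("all trials must share sample rate and length")
    n_cycles = cfg.resolve_cycles(freqs)
    _check_window(freqs, n_cycles, epochs[0].duration)
    data = np.stack([e.data for e in epochs])[:, None, :]  # (n_ep, 1, n)
    out = tfr_array_multitaper(
        data, sfreq=sfreq, freqs=freqs, n_cycles=n_cycles,
        time_bandwidth=cfg.time_bandwidth, output="power", zero_mean=True)
    # (n_ep, 1, F, n_times) -> (n_ep, n_times, F)
    power = np.transpose(out[:, 0], (0, 2, 1))
    return epochs[0].times, power


def db_baseline_correct(power: np.ndarray, times: np.ndarray,
                        baseline_window: tuple[float, float] = (-0.3, 0.0)
                        ) -> np.ndarray:
    """dB transform, then subtract the per-frequency pre-stimulus mean.

    ``power`` is raw (positive) power, shape (n_times, F) or
    (n_trials, n_times, F); correction is applied per trial. After
    correction, each frequency's mean over the baseline window is 0.
    """
    power = np.asarray(power, dtype=float)
    times = np.asarray(times, dtype=float)
    squeeze = power.ndim == 2
    if squeeze:
        power = power[None]
    if power.shape[1] != times.size:
        raise ValueError("power/time axis mismatch")
    b0, b1 = baseline_window
    in_base = (times >= b0) & (times <= b1)
    if not in_base.any():
        raise ValueError(f"baseline window {baseline_window} not covered "
                         "by the epoch")
    if np.any(power[:, in_base, :] <= 0):
        raise ValueError("baseline power must be strictly positive "
                         "(log undefined)")
    if np.any(power <= 0):
        raise ValueError("power must be strictly positive for dB transform")
    db = 10.0 * np.log10(power)
    corrected = db - db[:, in_base, :].mean(axis=1, keepdims=True)
    return corrected[0] if squeeze else corrected


def average_and_downsample(trial_tfrs, times: np.ndarray,
                           grid: TimeFreqGrid | None = None,
                           subject: str = "", roi: str = "",
                           condition: Condition | None = None) -> TFRMatrix:
    """Average corrected trials, decimate onto the analysis grid.

    ``trial_tfrs`` is a sequence (or stacked array) of (n_times, F)
    corrected-dB arrays on a common dense time axis. Downsampling is
    nearest-sample decimation of the post-stimulus segment onto
    ``grid.times``.
    """
    arr = np.asarray(list(trial_tfrs) if not isinstance(trial_tfrs, np.ndarray)
                     else trial_tfrs, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[0] == 0:
        raise ValueError("no trials to average")
    times = np.asarray(times, dtype=float)
    if grid is None:
        grid = TimeFreqGrid.default()
    if arr.shape[1] != times.size:
        raise ValueError("trial TFR / time axis mismatch")
    if arr.shape[2] != grid.freqs.size:
        raise ValueError(f"trial TFRs have {arr.shape[2]} frequency bins, "
                         f"grid expects {grid.freqs.size}")
    if grid.times[0] < times[0] - 1e-9 or grid.times[-1] > times[-1] + 1e-9:
        raise ValueError("analysis grid extends beyond the epoch time axis")
    mean = arr.mean(axis=0)
    idx = np.abs(times[None, :] - grid.times[:, None]).argmin(axis=1)
    return TFRMatrix(grid=grid, values=mean[idx], subject=subject, roi=roi,
                     condition=condition, n_trials=arr.shape[0])


def epochs_to_tfr(epochs: list[TrialEpoch], grid: TimeFreqGrid | None = None,
                  taper_config: TaperConfig | None = None,
                  baseline_window: tuple[float, float] = (-0.3, 0.0),
                  analysis_window: tuple[float, float] = (-0.3, 0.7),
                  ) -> TFRMatrix:
    """Full processing chain for one subject x ROI x condition.

    Multitaper power per trial, crop to the analysis epoch, dB baseline
    correction per trial, trial averaging and decimation onto the grid.
    """
    if not epochs:
        raise ValueError("no epochs supplied")
    if grid is None:
        grid = TimeFreqGrid.default()
    times, power = _multitaper_batch(epochs, grid.freqs, taper_config)
    a0, a1 = analysis_window
    keep = (times >= a0 - 1e-9) & (times <= a1 + 1e-9)
    corrected = db_baseline_correct(power[:, keep, :], times[keep],
                                    baseline_window)
    first = epochs[0]
    return average_and_downsample(
        corrected, times[keep], grid, subject=first.subject, roi=first.roi,
        condition=first.condition)
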