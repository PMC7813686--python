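"""Pan-Tompkins QRS detection for single-lead ECG.

Classic stages: band-pass (5-15 Hz, zero-phase Butterworth here, since the
original integer filters are tied to 200 Hz sampling), five-point derivative,
squaring, moving-window integration (150 ms), then adaptive dual thresholds
on the integrated waveform with a refractory period and search-back at half
threshold when an RR interval longer than 1.66x the running average is seen.
Each accepted trigger is relocated to the extremum of the raw signal within
+/-75 ms, so the returned indices land on R peaks regardless of polarity
(the squaring stage makes detection itself polarity-blind).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps


class SignalTooShortError(ValueError):
    """Signal shorter than the detector's warm-up window."""


@dataclass(frozen=True)
class PanTompkinsConfig:
    bandpass_low: float = 5.0
    bandpass_high: float = 15.0
    bandpass_order: int = 2  # per side; applied with filtfilt (zero phase)
    integration_window: float = 0.150  # s
    refractory: float = 0.200  # s
    signal_update: float = 0.125  # SPKI <- f*peak + (1-f)*SPKI
    noise_update: float = 0.125
    threshold_gate: float = 0.25  # THR = NPKI + gate*(SPKI-NPKI)
    searchback: bool = True
    searchback_rr_factor: float = 1.66
    relocation_window: float = 0.075  # s, +/- around the trigger

    def validate(self, fs: float) -> None:
        if not (0 < self.bandpass_low < self.bandpass_high < fs / 2):
            raise ValueError("need 0 < low < high < fs/2")
        if self.integration_window <= 0:
            raise ValueError("integration_window must be positive")


def _preprocess_stages(x: np.ndarray, fs: float, cfg: PanTompkinsConfig) -> np.ndarray:
    sos = sps.butter(
        cfg.bandpass_order,
        [cfg.bandpass_low, cfg.bandpass_high],
        btype="bandpass",
        fs=fs,
        output="sos",
    )
    bp = sps.sosfiltfilt(sos, x)
    # five-point derivative, gain normalised
    kernel = np.array([2.0, 1.0, 0.0, -1.0, -2.0]) * (fs / 8.0)
    deriv = np.convolve(bp, kernel, mode="same")
    squared = deriv**2
    win = max(1, int(round(cfg.integration_window * fs)))
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")
    return integrated


def _relocate(x: np.ndarray, trigger: int, half: int, fs: float) -> int:
    lo = max(0, trigger - half)
    hi = min(x.size, trigger + half + 1)
    # baseline from a ~1 s neighbourhood: wide QRS complexes can fill the
    # relocation window itself, which would corrupt a window-local median
    blo = max(0, trigger - int(fs // 2))
    bhi = min(x.size, trigger + int(fs // 2) + 1)
    baseline = np.median(x[blo:bhi])
    centred = np.abs(x[lo:hi] - baseline)
    return lo + int(np.argmax(centred))  # argmax -> earliest on ties


def pan_tompkins(
    signal: np.ndarray,
    fs: float,
    cfg: PanTompkinsConfig = PanTompkinsConfig(),
) -> np.ndarray:
    """Return strictly increasing 0-based R-peak sample indices."""
    x = np.asarray(signal, dtype=float)
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    cfg.validate(fs)
    if x.size < int(2 * fs):
        raise SignalTooShortError("need at least 2 s of signal")

    integrated = _preprocess_stages(x, fs, cfg)
    refractory = int(round(cfg.refractory * fs))
    half_reloc = int(round(cfg.relocation_window * fs))

    # candidate fiducial marks: local maxima of the integrated waveform
    peaks, _ = sps.find_peaks(integrated, distance=refractory)
    if peaks.size == 0:
        return np.array([], dtype=int)

    # threshold warm-up from the first two seconds
    warm = integrated[: int(2 * fs)]
    spki = float(warm.max()) / 3.0
    npki = float(np.mean(warm)) / 2.0

    accepted: list[int] = []
    rr_history: list[int] = []
    pending_noise: list[int] = []  # rejected candidates since the last beat

    def threshold() -> float:
        return npki + cfg.threshold_gate * (spki - npki)

    def note_rr(interval: int) -> None:
        rr_history.append(interval)
        rr_history[:] = rr_history[-8:]

    def searchback(gap_end: int) -> None:
        # a long RR gap suggests a missed beat among the rejected candidates
        # since the last accepted one; re-examine them at half threshold
        nonlocal spki
        if not (cfg.searchback and accepted and rr_history):
            return
        if gap_end - accepted[-1] <= cfg.searchback_rr_factor * np.mean(rr_history):
            return
        candidates = [
            q
            for q in pending_noise
            if integrated[q] > threshold() / 2.0
            and q - accepted[-1] >= refractory
            and gap_end - q >= refractory
        ]
        if candidates:
            q = max(candidates, key=lambda i: integrated[i])
            spki = cfg.signal_update * integrated[q] + (1 - cfg.signal_update) * spki
            note_rr(q - accepted[-1])
            accepted.append(q)
            pending_noise.clear()

    for p in peaks:
        amp = integrated[p]
        if amp > threshold() and (not accepted or p - accepted[-1] >= refractory):
            searchback(p)  # fill a long gap before committing this beat
            if accepted:
                note_rr(p - accepted[-1])
            spki = cfg.signal_update * amp + (1 - cfg.signal_update) * spki
            accepted.append(p)
            pending_noise.clear()
        else:
            npki = cfg.noise_update * amp + (1 - cfg.noise_update) * npki
            pending_noise.append(p)
            searchback(p)

    relocated = sorted({_relocate(x, p, half_reloc, fs) for p in accepted})
    out: list[int] = []
    for idx in relocated:
        if not out or idx - out[-1] >= refractory:
            out.append(idx)
    return np.array(out, dtype=int)


@dataclass
class DetectionScore:
    """Matched-pairs detector score against ground-truth R indices."""

    true_positives: int
    false_negatives: int
    false_positives: int
    matches: list[tuple[int, int]] = field(default_factory=list)

    @property
    def sensitivity(self) -> float:
        denom = self.true_positives + self.false_negatives
        return self.true_positives / denom if denom else float("nan")

    @property
    def positive_predictivity(self) -> float:
        denom = self.true_positives + self.false_positives
        return self.true_positives / denom if denom else float("nan")


def score_detections(
    detected: np.ndarray, truth: np.ndarray, tolerance: int
) -> DetectionScore:
    """Greedy one-to-one matching of detections to truth within tolerance."""
    detected = np.asarray(detected, dtype=int)
    truth = np.asarray(truth, dtype=int)
    used = np.zeros(truth.size, dtype=bool)
    matches = []
    for d in detected:
        diffs = np.abs(truth - d)
        diffs[used] = tolerance + 1
        if diffs.size and diffs.min() <= tolerance:
            j = int(np.argmin(diffs))
            used[j] = True
            matches.append((d, int(truth[j])))
    tp = len(matches)
    return DetectionScore(
        true_positives=tp,
        false_negatives=int(truth.size - tp),
        false_positives=int(detected.size - tp),
        matches=matches,
    )
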