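"""Synthetic single-lead ECG generation for the five beat micro-classes.

Beats are built as sums of Gaussian bumps (a McSharry-style PQRST amplitude
profile without the phase ODE), one template per class:

* NOR  — normal sinus beat: upright P, narrow tall R, modest S, upright T.
* LBBB — left bundle branch block: broad, notched, predominantly negative
  QRS (lead-II QS pattern) with discordant upright T.
* RBBB — right bundle branch block: broad QRS with a late secondary R bump
  (rSR') and inverted T.
* AP   — atrial premature beat: narrow QRS, absent/ectopic P, and a short
  preceding RR interval (prematurity).
* PVC  — premature ventricular contraction: very wide QRS, no P, large
  discordant T.

The wide/narrow QRS split (≥ 0.12 s for LBBB/RBBB/PVC, < 0.12 s for NOR/AP)
encodes the clinical wide-QRS distinction so the classes are separable by
construction.  Noise is additive baseline wander (low-frequency sinusoid),
power-line interference (50/60 Hz sinusoid) and white Gaussian noise.

All randomness flows from a single ``numpy.random.Generator`` seeded
explicitly; identical seeds give bit-identical output.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

CLASS_LABELS = ("NOR", "LBBB", "RBBB", "AP", "PVC")
#: MIT-BIH single-character annotation codes for the five classes.
CLASS_SYMBOLS = {"NOR": "N", "LBBB": "L", "RBBB": "R", "AP": "A", "PVC": "V"}
SYMBOL_TO_LABEL = {v: k for k, v in CLASS_SYMBOLS.items()}

DEFAULT_FS = 360.0


class UnknownClassError(ValueError):
    """Raised when a beat class label is not one of the five known classes."""


@dataclass(frozen=True)
class WaveComponent:
    """One Gaussian bump of a beat template.

    amplitude in mV, center in seconds relative to the R peak, width is the
    Gaussian sigma in seconds.  ``wave`` tags the component (P/Q/R/S/T or a
    QRS extra such as a notch or secondary R'); components tagged as part of
    the QRS complex define the template's QRS width.
    """

    wave: str
    amplitude: float
    center: float
    width: float

    @property
    def is_qrs(self) -> bool:
        return self.wave in {"Q", "R", "S", "QS", "R'", "notch"}


@dataclass(frozen=True)
class BeatTemplate:
    """Morphology + rhythm description of one beat class."""

    class_label: str
    wave_params: tuple[WaveComponent, ...]
    rr_interval_mean: float  # seconds, interval *preceding* this beat
    rr_interval_sd: float

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise UnknownClassError(f"unknown beat class {self.class_label!r}")

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the noiseless beat on times ``t`` (seconds, R at t=0)."""
        y = np.zeros_like(t, dtype=float)
        for c in self.wave_params:
            y += c.amplitude * np.exp(-0.5 * ((t - c.center) / c.width) ** 2)
        return y

    def qrs_width(self, n_sigma: float = 2.0) -> float:
        """Q-to-S span in seconds: outer edges (±n_sigma) of QRS components."""
        qrs = [c for c in self.wave_params if c.is_qrs]
        lo = min(c.center - n_sigma * c.width for c in qrs)
        hi = max(c.center + n_sigma * c.width for c in qrs)
        return hi - lo


def _g(wave: str, a: float, c: float, w: float) -> WaveComponent:
    return WaveComponent(wave, a, c, w)


#: Default lead-II-like templates.  Amplitudes in mV, times in s.
DEFAULT_TEMPLATES: dict[str, BeatTemplate] = {
    "NOR": BeatTemplate(
        "NOR",
        (
            _g("P", 0.15, -0.20, 0.025),
            _g("Q", -0.10, -0.028, 0.010),
            _g("R", 1.20, 0.0, 0.012),
            _g("S", -0.25, 0.030, 0.012),
            _g("T", 0.35, 0.25, 0.060),
        ),
        rr_interval_mean=0.80,
        rr_interval_sd=0.04,
    ),
    "LBBB": BeatTemplate(
        "LBBB",
        (
            _g("P", 0.10, -0.22, 0.025),
            _g("QS", -1.00, 0.0, 0.035),
            _g("notch", 0.30, 0.045, 0.015),
            _g("S", -0.55, 0.085, 0.028),
            _g("T", 0.45, 0.30, 0.070),
        ),
        rr_interval_mean=0.85,
        rr_interval_sd=0.04,
    ),
    "RBBB": BeatTemplate(
        "RBBB",
        (
            _g("P", 0.12, -0.20, 0.025),
            _g("Q", -0.15, -0.035, 0.012),
            _g("R", 1.00, 0.0, 0.015),
            _g("S", -0.40, 0.040, 0.020),
            _g("R'", 0.60, 0.090, 0.030),
            _g("T", -0.30, 0.28, 0.060),
        ),
        rr_interval_mean=0.82,
        rr_interval_sd=0.04,
    ),
    "AP": BeatTemplate(
        "AP",
        (
            _g("P", -0.06, -0.16, 0.020),  # ectopic (inverted) P
            _g("Q", -0.08, -0.026, 0.010),
            _g("R", 1.10, 0.0, 0.011),
            _g("S", -0.20, 0.028, 0.011),
            _g("T", 0.30, 0.24, 0.055),
        ),
        rr_interval_mean=0.60,  # premature: shorter than NOR
        rr_interval_sd=0.03,
    ),
    # wide but steep-edged QRS: real ventricular beats keep substantial
    # 5-15 Hz energy despite their >=0.12 s duration, so the R bump is kept
    # narrow-sigma with a separated S to span the width
    "PVC": BeatTemplate(
        "PVC",
        (
            _g("R", 1.40, 0.0, 0.032),
            _g("S", -0.70, 0.085, 0.035),
            _g("T", -0.60, 0.34, 0.080),
        ),
        rr_interval_mean=0.75,
        rr_interval_sd=0.05,
    ),
}


@dataclass(frozen=True)
class NoiseSpec:
    """Additive contaminants: baseline wander, power-line hum, white noise.

    Amplitudes in mV; baseline frequency ~0.1-0.5 Hz; powerline 50 or 60 Hz.
    """

    baseline_amplitude: float = 0.0
    baseline_frequency: float = 0.3
    powerline_amplitude: float = 0.0
    powerline_frequency: float = 60.0
    white_sd: float = 0.0

    def __post_init__(self) -> None:
        if min(self.baseline_amplitude, self.powerline_amplitude, self.white_sd) < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if self.powerline_amplitude > 0 and self.powerline_frequency not in (50.0, 60.0):
            raise ValueError("powerline frequency must be 50 or 60 Hz")

    @property
    def is_zero(self) -> bool:
        return (
            self.baseline_amplitude == 0
            and self.powerline_amplitude == 0
            and self.white_sd == 0
        )


#: "Mild" contamination used by the default synthetic study configuration.
MILD_NOISE = NoiseSpec(
    baseline_amplitude=0.10,
    baseline_frequency=0.30,
    powerline_amplitude=0.05,
    powerline_frequency=60.0,
    white_sd=0.05,
)

NO_NOISE = NoiseSpec()


@dataclass
class ECGRecord:
    """A sampled single-lead waveform with beat annotations.

    annotations are (sample_index, symbol) pairs, 0-based, sorted; symbols
    use the MIT-BIH beat codes (N, L, R, A, V for the five classes here).
    ``meta`` carries generator ground truth (sampled RR intervals etc.).
    """

    samples: np.ndarray
    fs: float
    annotations: list[tuple[int, str]]
    record_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        idx = [i for i, _ in self.annotations]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("annotations must be strictly increasing")
        if idx and (idx[0] < 0 or idx[-1] >= len(self.samples)):
            raise ValueError("annotation index out of range")

    @property
    def r_indices(self) -> np.ndarray:
        return np.array([i for i, _ in self.annotations], dtype=int)

    @property
    def symbols(self) -> list[str]:
        return [s for _, s in self.annotations]


# ---------------------------------------------------------------------------
# Record synthesis
# ---------------------------------------------------------------------------

_EDGE_MARGIN = 0.6  # seconds of quiet signal before the first / after the last R


def generate_record(
    class_sequence: list[str],
    templates: dict[str, BeatTemplate] | None = None,
    noise: NoiseSpec = NO_NOISE,
    fs: float = DEFAULT_FS,
    seed: int = 0,
    record_id: str = "synthetic",
) -> ECGRecord:
    """Synthesise a record with one beat per entry of ``class_sequence``.

    The interval preceding beat *i* is drawn from beat *i*'s template RR
    distribution (so a premature class shortens its own coupling interval).
    Annotations are placed at the true R-peak samples.  All randomness is
    drawn from ``numpy.random.default_rng(seed)``.
    """
    if not class_sequence:
        raise ValueError("class_sequence must be non-empty")
    if fs <= 0:
        raise ValueError("fs must be positive")
    templates = templates if templates is not None else DEFAULT_TEMPLATES
    for label in class_sequence:
        if label not in templates:
            raise UnknownClassError(f"unknown beat class {label!r}")

    rng = np.random.default_rng(seed)
    rr: list[float] = []
    r_times = [_EDGE_MARGIN]
    for i, label in enumerate(class_sequence):
        if i > 0:
            tmpl = templates[label]
            interval = float(
                np.clip(
                    rng.normal(tmpl.rr_interval_mean, tmpl.rr_interval_sd),
                    0.25,
                    2.0,
                )
            )
            rr.append(interval)
            r_times.append(r_times[-1] + interval)

    duration = r_times[-1] + _EDGE_MARGIN
    n = math.ceil(duration * fs)
    t = np.arange(n) / fs
    x = np.zeros(n)
    annotations: list[tuple[int, str]] = []
    for label, rt in zip(class_sequence, r_times):
        tmpl = templates[label]
        # evaluate only on a local window for speed
        lo = max(0, int((rt - 0.5) * fs))
        hi = min(n, int((rt + 0.6) * fs) + 1)
        x[lo:hi] += tmpl.waveform(t[lo:hi] - rt)
        # snap the annotation to the sampled R extremum: the continuous R
        # centre can fall between samples, and neighbouring waves skew the
        # discrete peak by up to a sample (as expert annotations, the marks
        # should point at the waveform's own extremum)
        a = int(round(rt * fs))
        w0, w1 = max(0, a - 3), min(n, a + 4)
        a = w0 + int(np.argmax(np.abs(x[w0:w1])))
        annotations.append((a, CLASS_SYMBOLS[label]))

    if not noise.is_zero:
        phase_bw, phase_pl = rng.uniform(0, 2 * np.pi, size=2)
        x = x + noise.baseline_amplitude * np.sin(
            2 * np.pi * noise.baseline_frequency * t + phase_bw
        )
        x = x + noise.powerline_amplitude * np.sin(
            2 * np.pi * noise.powerline_frequency * t + phase_pl
        )
        x = x + rng.normal(0.0, noise.white_sd, size=n) if noise.white_sd > 0 else x

    return ECGRecord(
        samples=x,
        fs=fs,
        annotations=annotations,
        record_id=record_id,
        meta={
            "rr_intervals": np.array(rr),
            "true_r_times": np.array(r_times),
            "class_sequence": list(class_sequence),
        },
    )


def generate_balanced_dataset(
    n_per_class: int,
    noise: NoiseSpec = NO_NOISE,
    seed: int = 0,
    templates: dict[str, BeatTemplate] | None = None,
    fs: float = DEFAULT_FS,
) -> list[tuple[ECGRecord, str]]:
    """One record per class, each with exactly ``n_per_class`` annotated beats.

    Returns (record, class_label) pairs; each record's annotations are the
    ground-truth R locations, so downstream stages can segment without
    running the detector.  Every record starts with one unannotated lead-in
    beat so that each returned beat has a preceding beat in its window
    (uniform morphological context).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    ss = np.random.SeedSequence(seed)
    out = []
    for label, child in zip(CLASS_LABELS, ss.spawn(len(CLASS_LABELS))):
        rec = generate_record(
            [label] * (n_per_class + 1),
            templates=templates,
            noise=noise,
            fs=fs,
            seed=int(child.generate_state(1)[0] % (2**31)),
            record_id=f"synthetic-{label}",
        )
        del rec.annotations[0]  # lead-in context beat, not part of the set
        out.append((rec, label))
    return out


# ---------------------------------------------------------------------------
# CSV I/O (the package's plain-text record dialect)
# ---------------------------------------------------------------------------

def write_record_csv(record: ECGRecord, waveform_path, annotation_path) -> None:
    """Write ``sample,amplitude`` and ``sample,symbol`` CSV files."""
    wf = Path(waveform_path)
    with wf.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample", "amplitude"])
        for i, v in enumerate(record.samples):
            w.writerow([i, f"{v:.6f}"])
    with Path(annotation_path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample", "symbol"])
        for i, s in record.annotations:
            w.writerow([i, s])


def read_record_csv(
    waveform_path,
    annotation_path=None,
    fs: float = DEFAULT_FS,
    record_id: str = "",
    one_based_annotations: bool = False,
) -> ECGRecord:
    """Read the CSV dialect written by :func:`write_record_csv`."""
    data = np.genfromtxt(waveform_path, delimiter=",", names=True)
    samples = np.asarray(data["amplitude"], dtype=float)
    annotations: list[tuple[int, str]] = []
    if annotation_path is not None:
        with Path(annotation_path).open() as fh:
            reader = csv.reader(fh)
            header = next(reader)
            if [h.strip().lower() for h in header] != ["sample", "symbol"]:
                raise ValueError(f"unexpected annotation header {header!r}")
            for row in reader:
                if not row:
                    continue
                idx = int(row[0]) - (1 if one_based_annotations else 0)
                annotations.append((idx, row[1].strip()))
    return ECGRecord(
        samples=samples,
        fs=fs,
        annotations=annotations,
        record_id=record_id or Path(waveform_path).stem,
    )


def write_record_wfdb(record: ECGRecord, directory, record_name: str) -> bool:
    """Write a WFDB record+annotation if the ``wfdb`` package is importable.

    Returns True on success, False when no WFDB writer is available.
    """
    try:
        import wfdb  # noqa: F401
    except ImportError:
        return False
    import wfdb

    wfdb.wrsamp(
        record_name,
        fs=record.fs,
        units=["mV"],
        sig_name=["II"],
        p_signal=record.samples[:, None],
        write_dir=str(directory),
    )
    ann_idx = record.r_indices
    wfdb.wrann(
        record_name,
        "atr",
        sample=ann_idx,
        symbol=record.symbols,
        write_dir=str(directory),
    )
    return True
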