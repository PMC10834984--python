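"""Synthetic ECG records with class-distinct rhythm and morphology, plus signal-table I/O.

Records belong to one of three diagnostic classes:

``ARR``
    Arrhythmia — highly irregular RR intervals plus ectopic beats with an
    inverted, widened QRS complex.
``CHF``
    Congestive heart failure — attenuated R waves, very low beat-to-beat
    variability and a blunted amplitude-modulation envelope.
``NSR``
    Normal sinus rhythm — regular PQRST beats with a pronounced slow
    amplitude-modulation envelope (autonomic/respiratory modulation).

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) placed on an RR
schedule drawn from the class's :class:`BeatModel`.  A slow multiplicative
amplitude-modulation envelope carries class identity at coarse raster scale
(it survives downstream per-segment amplitude normalisation, which absolute
amplitude does not), while RR statistics carry it at beat scale.

The on-disk format is a CSV signal table with one row per record: a
``record_id`` column, a ``label`` column, and one numeric column per sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CLASSES = ("ARR", "CHF", "NSR")

#: Default per-record counts emulating the study dataset (96 + 30 + 36 = 162).
DEFAULT_COUNTS = {"ARR": 96, "CHF": 30, "NSR": 36}

DEFAULT_N_SAMPLES = 65_535
DEFAULT_SAMPLING_RATE = 128.0
DEFAULT_NOISE_SD = 0.02


@dataclass(frozen=True)
class Wave:
    """One Gaussian bump of a beat: amplitude (a.u.), center offset and width (s)."""

    amplitude: float
    center: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"wave width must be > 0, got {self.width}")


# Textbook-ish PQRST morphology, offsets relative to the R peak.
DEFAULT_WAVES: dict[str, Wave] = {
    "P": Wave(0.15, -0.20, 0.025),
    "Q": Wave(-0.10, -0.04, 0.010),
    "R": Wave(1.00, 0.00, 0.012),
    "S": Wave(-0.15, 0.04, 0.010),
    "T": Wave(0.30, 0.25, 0.050),
}


@dataclass(frozen=True)
class BeatModel:
    """Morphology and rhythm parameters of one diagnostic class.

    Parameters
    ----------
    waves
        P/Q/R/S/T Gaussian bumps.
    rr_mean, rr_sd
        Mean and SD of the RR interval (s); intervals are truncated at
        ``rr_min`` so the schedule stays causal.
    ectopic_rate
        Per-beat probability of an ectopic beat (inverted, widened QRS, no
        P wave).
    am_depth, am_freq_hz
        Depth and frequency of the slow multiplicative amplitude-modulation
        envelope ``1 + am_depth*sin(2*pi*am_freq_hz*t + phase)``.
    """

    waves: dict[str, Wave] = field(default_factory=lambda: dict(DEFAULT_WAVES))
    rr_mean: float = 0.8
    rr_sd: float = 0.04
    ectopic_rate: float = 0.0
    am_depth: float = 0.0
    am_freq_hz: float = 0.1
    rr_min: float = 0.3

    def __post_init__(self) -> None:
        if self.rr_mean <= 0:
            raise ValueError("rr_mean must be > 0")
        if not 0.0 <= self.ectopic_rate <= 1.0:
            raise ValueError("ectopic_rate must be in [0, 1]")


def _scaled_waves(waves: dict[str, Wave], r_scale: float) -> dict[str, Wave]:
    out = dict(waves)
    out["R"] = replace(out["R"], amplitude=out["R"].amplitude * r_scale)
    return out


#: Class defaults.  The RR parameters force the RR-interval coefficient of
#: variation to order ARR > NSR > CHF; the amplitude-modulation depths make
#: the classes distinguishable in rendered images even when individual beats
#: fall below raster resolution.
DEFAULT_BEAT_MODELS: dict[str, BeatModel] = {
    "NSR": BeatModel(rr_mean=0.8, rr_sd=0.04, am_depth=0.25),
    "ARR": BeatModel(rr_mean=0.8, rr_sd=0.25, ectopic_rate=0.15, am_depth=0.15),
    "CHF": BeatModel(
        waves=_scaled_waves(DEFAULT_WAVES, 0.6),
        rr_mean=0.7,
        rr_sd=0.01,
        am_depth=0.05,
    ),
}


@dataclass
class EcgRecord:
    """A raw labelled 1-D ECG signal."""

    record_id: str
    label: str
    samples: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.label not in CLASSES:
            raise ValueError(f"unknown label {self.label!r}; expected one of {CLASSES}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("record samples must all be finite")

    def __len__(self) -> int:
        return self.samples.size


def amplitude_bound(model: BeatModel, noise_sd: float = DEFAULT_NOISE_SD) -> float:
    """Envelope bound: |sample| <= (1+am_depth)*sum|wave amp| + 6*noise SD."""
    total = sum(abs(w.amplitude) for w in model.waves.values())
    return (1.0 + model.am_depth) * total + 6.0 * noise_sd


def generate_record(
    label: str,
    seed: int,
    n_samples: int = DEFAULT_N_SAMPLES,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    beat_model: BeatModel | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    record_id: str | None = None,
) -> EcgRecord:
    """Generate one labelled synthetic ECG record.

    The output is a pure function of the arguments: the same ``(label, seed,
    ...)`` always yields bit-identical samples.

    Raises
    ------
    ValueError
        For an unknown label, non-positive ``n_samples``, or a record
        shorter than two seconds of signal.
    """
    if label not in CLASSES:
        raise ValueError(f"unknown label {label!r}; expected one of {CLASSES}")
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if n_samples < 2 * sampling_rate:
        raise ValueError("n_samples must cover at least two seconds of signal")
    model = beat_model if beat_model is not None else DEFAULT_BEAT_MODELS[label]

    rng = np.random.default_rng(seed)
    duration = n_samples / sampling_rate
    # Enough intervals to cover the record even at the truncation floor.
    n_beats = int(duration / max(model.rr_min, model.rr_mean - 3 * model.rr_sd)) + 8
    rr = rng.normal(model.rr_mean, model.rr_sd, size=n_beats)
    rr = np.maximum(rr, model.rr_min)
    beat_times = np.cumsum(rr)
    ectopic = rng.random(n_beats) < model.ectopic_rate
    am_phase = rng.uniform(0.0, 2.0 * math.pi)

    keep = beat_times < duration + 0.5
    beat_times, ectopic = beat_times[keep], ectopic[keep]

    t = np.arange(n_samples) / sampling_rate
    signal = np.zeros(n_samples)
    for t_beat, is_ect in zip(beat_times, ectopic):
        for name, wave in model.waves.items():
            amp, width = wave.amplitude, wave.width
            if is_ect:
                if name == "P":  # ectopic beats lack an organised P wave
                    continue
                if name in ("Q", "R", "S"):  # inverted, widened QRS
                    amp, width = -amp, 2.5 * width
            center = t_beat + wave.center
            lo = max(0, int((center - 4 * width) * sampling_rate))
            hi = min(n_samples, int((center + 4 * width) * sampling_rate) + 1)
            if lo >= hi:
                continue
            dt = t[lo:hi] - center
            signal[lo:hi] += amp * np.exp(-0.5 * (dt / width) ** 2)

    if model.am_depth:
        signal *= 1.0 + model.am_depth * np.sin(
            2.0 * math.pi * model.am_freq_hz * t + am_phase
        )
    signal += rng.normal(0.0, noise_sd, size=n_samples)

    rid = record_id if record_id is not None else f"{label}-{seed}"
    return EcgRecord(rid, label, signal, sampling_rate)


def generate_dataset(
    counts: dict[str, int] | None = None,
    seed: int = 0,
    n_samples: int = DEFAULT_N_SAMPLES,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    beat_models: dict[str, BeatModel] | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> list[EcgRecord]:
    """Generate a labelled dataset with per-class record counts.

    Per-record seeds are derived deterministically from the master seed, so
    the same call always returns an identical dataset.  Default counts are
    96 ARR + 30 CHF + 36 NSR = 162 records.
    """
    counts = dict(DEFAULT_COUNTS) if counts is None else counts
    for label, count in counts.items():
        if label not in CLASSES:
            raise ValueError(f"unknown label {label!r}")
        if count < 0:
            raise ValueError(f"negative count for {label}: {count}")
    models = beat_models or DEFAULT_BEAT_MODELS

    total = sum(counts.values())
    child_seeds = np.random.SeedSequence(seed).generate_state(max(total, 1))
    records: list[EcgRecord] = []
    i = 0
    for label in CLASSES:  # fixed order for reproducibility
        for j in range(counts.get(label, 0)):
            records.append(
                generate_record(
                    label,
                    seed=int(child_seeds[i]),
                    n_samples=n_samples,
                    sampling_rate=sampling_rate,
                    beat_model=models.get(label),
                    noise_sd=noise_sd,
                    record_id=f"{label}{j:03d}",
                )
            )
            i += 1
    return records


def write_signal_table(records: list[EcgRecord], path) -> None:
    """Write records as a CSV signal table (one row per signal).

    Columns: ``record_id``, ``label``, then one column per sample
    (``s0000000`` ...).  A ``.csv.gz`` suffix writes gzip-compressed output.
    Sample values keep >= 9 significant digits.
    """
    if not records:
        raise ValueError("no records to write")
    lengths = {len(r) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"records have unequal lengths: {sorted(lengths)}")
    n = lengths.pop()
    width = max(7, len(str(n - 1)))
    data = {
        "record_id": [r.record_id for r in records],
        "label": [r.label for r in records],
    }
    matrix = np.stack([r.samples for r in records])
    frame = pd.DataFrame(data)
    samples = pd.DataFrame(
        matrix, columns=[f"s{i:0{width}d}" for i in range(n)], index=frame.index
    )
    pd.concat([frame, samples], axis=1).to_csv(path, index=False, float_format="%.12g")


def read_signal_table(
    path, sampling_rate: float = DEFAULT_SAMPLING_RATE
) -> list[EcgRecord]:
    """Read a CSV signal table written by :func:`write_signal_table`.

    Raises
    ------
    ValueError
        For ragged rows, missing/non-numeric cells, a missing ``label``
        column, or unknown label values.
    """
    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"ragged signal table: {exc}") from exc
    if "label" not in frame.columns:
        raise ValueError("signal table lacks a 'label' column")
    if "record_id" not in frame.columns:
        frame.insert(0, "record_id", [f"row{i}" for i in range(len(frame))])
    sample_cols = [c for c in frame.columns if c not in ("record_id", "label")]
    if not sample_cols:
        raise ValueError("signal table has no sample columns")
    try:
        matrix = frame[sample_cols].to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric sample cell: {exc}") from exc
    if not np.all(np.isfinite(matrix)):
        raise ValueError("signal table has ragged rows or non-finite cells")
    bad = set(frame["label"]) - set(CLASSES)
    if bad:
        raise ValueError(f"unknown label values: {sorted(bad)}")
    return [
        EcgRecord(str(rid), str(label), row, sampling_rate)
        for rid, label, row in zip(frame["record_id"], frame["label"], matrix)
    ]


def rhythm_features(record: EcgRecord) -> dict[str, float]:
    """Simple rhythm summary: RR-interval CV and mean R-peak amplitude.

    R peaks are taken as prominent positive local maxima; this is a
    diagnostic helper (used to verify the generator plants separable class
    structure), not a clinical QRS detector.
    """
    from scipy.signal import find_peaks

    x = record.samples
    fs = record.sampling_rate
    height = 0.4 * float(np.max(x)) if np.max(x) > 0 else None
    peaks, props = find_peaks(x, height=height, distance=max(1, int(0.3 * fs)))
    if peaks.size < 3:
        return {"rr_cv": 0.0, "mean_r_amplitude": float(np.max(x, initial=0.0))}
    rr = np.diff(peaks) / fs
    return {
        "rr_cv": float(np.std(rr) / np.mean(rr)),
        "mean_r_amplitude": float(np.mean(props["peak_heights"])),
    }
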