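"""Synthetic EHG cohort generator.

Emulates a threatened-preterm-labor study cohort: by default 140 thirty-min
two-channel recordings (30 from women delivering within 7 days, 110 from
women delivering later) at a 20 Hz analysis rate, each a colored-noise
baseline with Poisson-arriving EHG bursts (Tukey-windowed envelopes
modulating band-limited noise), plus six obstetric covariates and a time
to delivery.

The class-dependent trends reproduce what uterine electrophysiology shows
as labor approaches: the imminent class has larger burst amplitude, burst
spectral content shifted above 0.34 Hz, and more regular (less complex)
burst activity; it also gets a shorter mean cervical length. Effect sizes
default to about one SD on burst amplitude and ~0.1 Hz on center frequency
so that classification is learnable but not trivial. All randomness derives
from a single integer seed. Physiological realism of uterine conduction,
fetal ECG or respiration interference are out of scope.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .ingest import OBSTETRIC_FIELDS, RawRecording

logger = logging.getLogger(__name__)

#: Class keys: positive class = delivery within 7 days.
CLASSES = ("imminent", "control")


def _per_class(value) -> dict[str, float]:
    if isinstance(value, dict):
        return {k: float(value[k]) for k in CLASSES}
    a, b = value
    return {"imminent": float(a), "control": float(b)}


@dataclass(frozen=True)
class SynthConfig:
    """Cohort-level generator parameters.

    Per-class parameters are given as ``(imminent, control)`` pairs or
    ``{"imminent": ..., "control": ...}`` dicts. ``regularity_ar`` in [0, 1)
    narrows the burst carrier band as it grows, making bursts more
    predictable (lower entropy/complexity). ``sim_fs`` is the internal
    simulation rate; ``fs_out`` must divide it.
    """

    n_imminent: int = 30
    n_control: int = 110
    duration_s: float = 1800.0
    fs_out: float = 20.0
    sim_fs: float = 100.0
    burst_rate_per_10min: tuple = (4.0, 2.5)
    burst_amp_uV: tuple = (60.0, 40.0)
    burst_center_hz: tuple = (0.45, 0.35)
    baseline_amp: float = 10.0
    regularity_ar: tuple = (0.9, 0.7)
    cervical_length_mm: tuple = ((15.0, 5.0), (27.0, 6.0))  # (mean, sd) per class
    gestational_age_weeks: tuple = ((31.0, 2.5), (31.0, 2.5))
    maternal_age_years: tuple = ((33.0, 5.0), (33.0, 5.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_imminent <= 0 or self.n_control <= 0:
            raise ValueError("class counts must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs_out <= 0 or self.sim_fs <= 0:
            raise ValueError("sampling rates must be positive")
        if abs(self.sim_fs / self.fs_out - round(self.sim_fs / self.fs_out)) > 1e-9:
            raise ValueError("fs_out must divide sim_fs")
        for v in _per_class(self.burst_rate_per_10min).values():
            if v < 0:
                raise ValueError("burst rates must be nonnegative")
        for v in _per_class(self.burst_amp_uV).values():
            if v < 0:
                raise ValueError("burst amplitudes must be nonnegative")
        for v in _per_class(self.regularity_ar).values():
            if not (0 <= v < 1):
                raise ValueError("regularity_ar must be in [0, 1)")


@dataclass
class SynthRecording:
    """One synthetic two-channel recording with labels and annotations."""

    id: str
    fs: float
    monopolar_m1: np.ndarray
    monopolar_m2: np.ndarray
    valid_intervals: list[tuple[float, float]]
    obstetric: dict[str, float]
    ttd_days: float

    @property
    def duration_s(self) -> float:
        return self.monopolar_m1.size / self.fs

    def as_raw(self) -> RawRecording:
        """View as an ingest.RawRecording (fs_in = generator output rate)."""
        return RawRecording(
            id=self.id,
            fs_in=self.fs,
            m1=self.monopolar_m1,
            m2=self.monopolar_m2,
            valid_intervals=list(self.valid_intervals),
            obstetric=dict(self.obstetric),
            ttd_days=self.ttd_days,
        )


def _colored_baseline(n: int, fs: float, amp: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-shaped noise band-limited to 0.1-4 Hz, scaled to RMS = amp."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(f)
    in_band = (f >= 0.1) & (f <= 4.0)
    shape[in_band] = 1.0 / np.sqrt(f[in_band])
    x = np.fft.irfft(spec * shape, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x * (amp / rms) if rms > 0 else x


def _burst_carrier(
    n: int, fs: float, center: float, ar: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS band-limited noise; higher ar -> narrower band -> more regular."""
    bw = max((1.0 - ar) * 1.0, 0.02)  # Hz
    lo = max(center - bw / 2, 0.05)
    hi = min(center + bw / 2, fs / 2 * 0.9)
    sos = sps.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n + int(20 * fs)))[int(20 * fs):]
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _obstetric_draw(cfg: SynthConfig, cls: str, rng: np.random.Generator) -> dict[str, float]:
    idx = 0 if cls == "imminent" else 1
    cl_m, cl_s = cfg.cervical_length_mm[idx]
    ga_m, ga_s = cfg.gestational_age_weeks[idx]
    ma_m, ma_s = cfg.maternal_age_years[idx]
    parity = min(int(rng.poisson(0.6)), 4)
    abortions = min(int(rng.poisson(0.3)), 3)
    gestations = 1 + parity + abortions + min(int(rng.poisson(0.2)), 2)
    return {
        "cervical_length_mm": float(max(rng.normal(cl_m, cl_s), 1.0)),
        "gestational_age_weeks": float(np.clip(rng.normal(ga_m, ga_s), 24.0, 37.0)),
        "maternal_age_years": float(np.clip(rng.normal(ma_m, ma_s), 16.0, 48.0)),
        "gestations": float(gestations),
        "parity": float(parity),
        "abortions": float(abortions),
    }


def _generate_recording(
    cfg: SynthConfig, cls: str, rec_id: str, rng: np.random.Generator
) -> SynthRecording:
    n_sim = int(round(cfg.duration_s * cfg.sim_fs))
    rate = _per_class(cfg.burst_rate_per_10min)[cls]
    amp_cls = _per_class(cfg.burst_amp_uV)[cls]
    center_cls = _per_class(cfg.burst_center_hz)[cls]
    ar = _per_class(cfg.regularity_ar)[cls]

    signal = _colored_baseline(n_sim, cfg.sim_fs, cfg.baseline_amp, rng)
    # per-recording variability: ~1 SD class separation on the log scale
    amp_rec = amp_cls * float(rng.lognormal(0.0, 0.3)) if amp_cls > 0 else 0.0
    center_rec = float(np.clip(rng.normal(center_cls, 0.05), 0.22, 0.9))

    n_bursts = rng.poisson(rate * cfg.duration_s / 600.0) if amp_rec > 0 else 0
    for _ in range(n_bursts):
        dur = float(rng.uniform(30.0, 90.0))
        start = float(rng.uniform(0.0, max(cfg.duration_s - dur, 0.0)))
        i0 = int(start * cfg.sim_fs)
        nb = int(dur * cfg.sim_fs)
        if i0 + nb > n_sim:
            nb = n_sim - i0
        if nb < int(5 * cfg.sim_fs):
            continue
        carrier = _burst_carrier(nb, cfg.sim_fs, center_rec, ar, rng)
        envelope = sps.windows.tukey(nb, alpha=0.5)
        burst_amp = amp_rec * float(rng.lognormal(0.0, 0.15))
        signal[i0 : i0 + nb] += 0.5 * burst_amp * envelope * carrier

    # common-mode interference cancels in the bipolar derivation
    t = np.arange(n_sim) / cfg.sim_fs
    common = 5 * cfg.baseline_amp * np.sin(2 * np.pi * 0.05 * t + rng.uniform(0, 2 * np.pi))
    sensor1 = 0.5 * rng.standard_normal(n_sim)
    sensor2 = 0.5 * rng.standard_normal(n_sim)
    m1_sim = common + 0.5 * signal + sensor1
    m2_sim = common - 0.5 * signal + sensor2

    q = int(round(cfg.sim_fs / cfg.fs_out))
    if q > 1:
        m1 = sps.resample_poly(m1_sim, 1, q)
        m2 = sps.resample_poly(m2_sim, 1, q)
    else:
        m1, m2 = m1_sim, m2_sim

    if cls == "imminent":
        ttd = float(rng.uniform(0.5, 7.0))
    else:
        ttd = float(rng.uniform(8.0, 60.0))
    return SynthRecording(
        id=rec_id,
        fs=cfg.fs_out,
        monopolar_m1=m1,
        monopolar_m2=m2,
        valid_intervals=[(0.0, cfg.duration_s)],
        obstetric=_obstetric_draw(cfg, cls, rng),
        ttd_days=ttd,
    )


def generate_cohort(config: SynthConfig) -> list[SynthRecording]:
    """Generate the full synthetic cohort, deterministic for a fixed seed.

    Returns ``n_imminent`` recordings with TTD <= 7 days followed by
    ``n_control`` recordings with TTD > 7 days. Each recording has its own
    child RNG spawned from the config seed, so per-recording signals do not
    depend on cohort size or ordering of generation.
    """
    n_total = config.n_imminent + config.n_control
    children = np.random.SeedSequence(config.seed).spawn(n_total)
    out: list[SynthRecording] = []
    for i in range(n_total):
        cls = "imminent" if i < config.n_imminent else "control"
        rng = np.random.default_rng(children[i])
        out.append(_generate_recording(config, cls, f"rec{i:03d}", rng))
    return out


def inject_artifacts(
    rec: SynthRecording, fraction: float, seed: int
) -> SynthRecording:
    """Mark ~fraction of the duration as artifacted and superimpose transients.

    Draws non-overlapping artifact intervals (20-60 s each, the last one
    trimmed so the artifacted total is exactly fraction x duration), removes
    them from ``valid_intervals`` and adds large-amplitude transients there
    on both channels. ``fraction = 0`` returns the recording unchanged.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    if fraction == 0:
        return rec
    rng = np.random.default_rng(seed)
    duration = rec.duration_s
    target = fraction * duration
    # draw artifact intervals, rejecting overlaps
    placed: list[tuple[float, float]] = []
    total = 0.0
    attempts = 0
    while total < target - 1e-9 and attempts < 10000:
        attempts += 1
        length = min(float(rng.uniform(20.0, 60.0)), target - total)
        start = float(rng.uniform(0.0, duration - length))
        cand = (start, start + length)
        if any(not (cand[1] <= a or cand[0] >= b) for a, b in placed):
            continue
        placed.append(cand)
        total += length
    placed.sort()

    m1 = rec.monopolar_m1.copy()
    m2 = rec.monopolar_m2.copy()
    scale = 10 * max(np.abs(rec.monopolar_m1 - rec.monopolar_m2).max(), 1.0)
    for a, b in placed:
        i0, i1 = int(a * rec.fs), int(b * rec.fs)
        burst = scale * rng.standard_normal(i1 - i0)
        m1[i0:i1] += burst
        m2[i0:i1] -= burst

    # subtract artifact intervals from the valid intervals
    new_valid: list[tuple[float, float]] = []
    for a, b in rec.valid_intervals:
        segs = [(a, b)]
        for xa, xb in placed:
            nxt = []
            for sa, sb in segs:
                if xb <= sa or xa >= sb:
                    nxt.append((sa, sb))
                else:
                    if sa < xa:
                        nxt.append((sa, xa))
                    if xb < sb:
                        nxt.append((xb, sb))
            segs = nxt
        new_valid.extend(segs)
    return SynthRecording(
        id=rec.id,
        fs=rec.fs,
        monopolar_m1=m1,
        monopolar_m2=m2,
        valid_intervals=sorted(new_valid),
        obstetric=dict(rec.obstetric),
        ttd_days=rec.ttd_days,
    )


def write_cohort(recs: list[SynthRecording], out_dir: str | Path) -> Path:
    """Write per-recording CSV + JSON sidecars and a cohort manifest CSV.

    Returns the manifest path. The CSV has columns ``time_s,m1,m2``; the
    sidecar carries valid intervals, obstetric covariates and TTD.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as mh:
        writer = csv.writer(mh)
        writer.writerow(["id", "path", "ttd_days"])
        for rec in recs:
            csv_path = out_dir / f"{rec.id}.csv"
            t = np.arange(rec.monopolar_m1.size) / rec.fs
            arr = np.column_stack([t, rec.monopolar_m1, rec.monopolar_m2])
            np.savetxt(
                csv_path, arr, delimiter=",", header="time_s,m1,m2", comments="", fmt="%.6f"
            )
            with open(csv_path.with_suffix(".json"), "w") as sh:
                json.dump(
                    {
                        "valid_intervals": [list(iv) for iv in rec.valid_intervals],
                        "obstetric": rec.obstetric,
                        "ttd_days": rec.ttd_days,
                    },
                    sh,
                    indent=1,
                )
            writer.writerow([rec.id, csv_path.name, f"{rec.ttd_days:.4f}"])
    return manifest
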