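"""Synthetic intraoperative sessions with the structure the analysis assumes.

Real awake-craniotomy ECoG cannot be shared, so every downstream stage
is exercised on generated data that emulates the features the pipeline
depends on:

* 1/f-shaped broadband background per contact (spectrally shaped white
  noise, power-spectrum exponent configurable);
* band-limited oscillatory components (filtered white noise, not pure
  tones, so Hilbert envelopes behave like physiological broadband
  activity) whose variance inside each trial is scaled by the effect
  specification for that contact's network and the trial's condition;
* shared 50 Hz line noise and a 79 Hz equipment tone, with harmonics;
* a common-mode component identical within each strip (cancelled by
  bipolar re-referencing);
* strip geometry of collinear contacts at 10 mm pitch; and
* the trial schedule of the protocol: one 2-3 min rest period, then
  count (~20 s) and switch (~30 s) trials in near-strict alternation,
  2-5 trials per condition.

The acquisition chain's online filters (1 Hz high-pass, 1500 Hz
low-pass, Butterworth) are emulated as an optional order-4 post-process,
on by default; the low-pass leg is skipped when it sits at or above
Nyquist.  Identical seeds yield bit-identical sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .data_model import (
    BandDefinition,
    DEFAULT_BANDS,
    ElectrodeTable,
    EventTable,
    LabelVolume,
    Recording,
    UNASSIGNED,
    ValidationError,
)
from .network_assignment import assign_network

import pandas as pd

__all__ = ["EffectSpec", "SessionPlan", "make_parcellation", "make_strips", "make_session"]


@dataclass
class EffectSpec:
    """What the generator injects, beyond the stationary background.

    ``modulation`` maps ``(network, band_name, condition)`` to a
    multiplicative power gain applied to that band's oscillatory
    component during trials of that condition on contacts of that
    network; unlisted triples default to 1 (no modulation).  A gain of
    1.5 on ``("FPN", "HG", "switch")`` with count left at 1 injects the
    x1.5 high-gamma switch/count power ratio the analysis is designed to
    detect.

    Amplitudes are microvolt standard deviations; band component
    baselines fall with frequency the way cortical LFP spectra do, with
    the high-gamma component kept large enough relative to the 1/f
    background above 70 Hz that an injected power ratio survives as an
    observable ratio of total band power.
    """

    modulation: dict[tuple[str, str, str], float] = field(default_factory=dict)
    background_exponent: float = 2.0      # power-spectrum slope of the 1/f background
    background_std_uv: float = 15.0
    band_component_std_uv: dict[str, float] = field(default_factory=lambda: {
        "delta": 8.0, "theta": 6.0, "alpha": 5.0, "beta": 4.0, "LG": 4.0, "HG": 8.0,
    })
    line_noise_uv: dict[float, float] = field(default_factory=lambda: {50.0: 8.0})
    line_harmonics: int = 4
    artifact_tone_hz: float = 79.0
    artifact_tone_uv: float = 6.0
    artifact_harmonics: int = 3
    common_mode_uv: float = 20.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.modulation.values()):
            raise ValidationError("power modulations must be positive")
        if self.background_exponent < 0:
            raise ValidationError("background exponent must be >= 0")

    def gain(self, network: str, band: str, condition: str) -> float:
        return self.modulation.get((network, band, condition), 1.0)


@dataclass
class SessionPlan:
    """Trial counts, duration distributions and ordering of one session.

    Defaults follow the intraoperative protocol: a single 120-180 s rest
    period, then four count and four switch trials (protocol median),
    count lasting 20.1 +/- 7.4 s and switch 29.4 +/- 9.4 s, in strict
    alternation broken with probability ``repeat_probability`` (on a few
    occasions consecutive trials of one condition occur).  Durations are
    resampled until they clear ``min_duration_s`` so every trial retains
    analyzable samples after the edge exclusions.
    """

    n_trials: dict[str, int] = field(default_factory=lambda: {"rest": 1, "count": 4, "switch": 4})
    count_duration_s: tuple[float, float] = (20.1, 7.4)    # mean, sd
    switch_duration_s: tuple[float, float] = (29.4, 9.4)   # mean, sd
    rest_duration_s: tuple[float, float] = (120.0, 180.0)  # uniform range
    min_duration_s: dict[str, float] = field(default_factory=lambda: {
        "rest": 10.0, "count": 6.0, "switch": 10.0,
    })
    gap_s: tuple[float, float] = (2.0, 5.0)  # uniform inter-trial gap
    repeat_probability: float = 0.1
    lead_in_s: float = 3.0

    def draw_schedule(self, rng: np.random.Generator) -> pd.DataFrame:
        """Sample a trial table (onset_s, offset_s, condition) in
        performed order: rest first, then alternating task trials."""
        order: list[str] = ["rest"] * self.n_trials.get("rest", 0)
        remaining = {c: self.n_trials.get(c, 0) for c in ("count", "switch")}
        current = "count" if rng.random() < 0.5 else "switch"
        while remaining["count"] > 0 or remaining["switch"] > 0:
            if remaining[current] == 0:
                current = "switch" if current == "count" else "count"
            order.append(current)
            remaining[current] -= 1
            if rng.random() >= self.repeat_probability:
                current = "switch" if current == "count" else "count"
        rows, t = [], self.lead_in_s
        for cond in order:
            dur = self._draw_duration(cond, rng)
            rows.append({"onset_s": t, "offset_s": t + dur, "condition": cond})
            t += dur + rng.uniform(*self.gap_s)
        return pd.DataFrame(rows)

    def _draw_duration(self, condition: str, rng: np.random.Generator) -> float:
        floor = self.min_duration_s[condition]
        if condition == "rest":
            return float(rng.uniform(*self.rest_duration_s))
        mean, sd = self.count_duration_s if condition == "count" else self.switch_duration_s
        for _ in range(1000):
            d = rng.normal(mean, sd)
            if d >= floor:
                return float(d)
        return floor


def make_parcellation(
    shape: tuple[int, int, int],
    affine: np.ndarray,
    blob_spec: list[tuple[str, tuple[float, float, float], float]],
    seed: int | None = None,
) -> LabelVolume:
    """Toy volumetric parcellation: spherical network blobs on a grid.

    ``blob_spec`` lists ``(network_name, centre_mm, radius_mm)``; every
    voxel whose centre lies within a blob's radius takes its label, with
    overlaps resolved in favour of the first-listed blob.  Blobs falling
    partly or wholly outside the grid are clipped with a warning.  Label
    ids are assigned 1..k in listing order (re-using ids for repeated
    network names).
    """
    affine = np.asarray(affine, dtype=float)
    grid = np.zeros(shape, dtype=np.int16)
    ijk = np.indices(shape).reshape(3, -1).T.astype(float)
    mm = ijk @ affine[:3, :3].T + affine[:3, 3]
    label_names: dict[int, str] = {}
    name_to_id: dict[str, int] = {}
    flat = grid.reshape(-1)
    for network, centre, radius in blob_spec:
        if network not in name_to_id:
            name_to_id[network] = len(name_to_id) + 1
            label_names[name_to_id[network]] = network
        lid = name_to_id[network]
        inside = np.linalg.norm(mm - np.asarray(centre, dtype=float), axis=1) <= radius
        if not inside.any():
            warnings.warn(f"blob {network!r} at {centre} lies entirely outside the grid; clipped")
            continue
        # rough outside check: does the blob's bounding sphere poke out?
        centre_vox = np.linalg.inv(affine) @ np.append(np.asarray(centre, float), 1.0)
        vox_size = np.abs(np.linalg.eigvals(affine[:3, :3])).min()
        if ((centre_vox[:3] < radius / vox_size - 0.5).any()
                or (centre_vox[:3] + radius / vox_size > np.array(shape) - 0.5).any()):
            warnings.warn(f"blob {network!r} extends beyond the grid; clipped")
        flat[inside & (flat == 0)] = lid
    return LabelVolume(grid=grid, affine=affine, label_names=label_names)


def make_strips(
    n_strips: int,
    contacts_per_strip: int | list[int] = 4,
    pitch_mm: float = 10.0,
    placement: list[tuple[float, float, float]] | None = None,
    seed: int | None = None,
    origin_box: tuple[tuple[float, float], ...] = ((-60.0, 60.0), (-10.0, 60.0), (0.0, 60.0)),
) -> ElectrodeTable:
    """Collinear electrode strips at a fixed centre-to-centre pitch.

    ``contacts_per_strip`` may be a single count or one per strip (to
    model strips with unlocalized contacts).  ``placement`` optionally
    fixes each strip's centre; orientation is always drawn from the
    seeded generator.  Contact names are ``S{strip}E{contact}``.
    """
    if pitch_mm <= 0:
        raise ValidationError("pitch_mm must be positive")
    counts = ([int(contacts_per_strip)] * n_strips
              if np.isscalar(contacts_per_strip) else list(contacts_per_strip))
    if len(counts) != n_strips:
        raise ValidationError("contacts_per_strip list must have one entry per strip")
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_strips):
        k = counts[s]
        if placement is not None:
            centre = np.asarray(placement[s], dtype=float)
        else:
            centre = np.array([rng.uniform(*b) for b in origin_box])
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        offsets = (np.arange(k) - (k - 1) / 2.0) * pitch_mm
        for c in range(k):
            xyz = centre + offsets[c] * direction
            rows.append({
                "name": f"S{s + 1}E{c + 1}", "strip_id": f"S{s + 1}",
                "contact_index": c + 1, "x": xyz[0], "y": xyz[1], "z": xyz[2],
            })
    return ElectrodeTable(pd.DataFrame(rows), pitch_mm=pitch_mm)


def _one_over_f_noise(n_samples: int, fs: float, exponent: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with power spectrum proportional to f^-exponent."""
    white = rng.standard_normal(n_samples)
    if exponent == 0:
        return white
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    # flatten below 1 Hz so the variance is not dominated by a diverging DC tail
    shaping[nz] = np.maximum(freqs[nz], 1.0) ** (-exponent / 2.0)
    spec *= shaping
    out = np.fft.irfft(spec, n=n_samples)
    return out / out.std()


def _band_limited_noise(n_samples: int, fs: float, band: BandDefinition,
                        rng: np.random.Generator) -> np.ndarray:
    """Unit-variance filtered white noise confined to one band."""
    hi = min(band.hi_hz, fs / 2 * 0.95)
    sos = signal.butter(4, [band.lo_hz, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n_samples))
    return x / x.std()


def make_session(
    plan: SessionPlan,
    effects: EffectSpec,
    electrodes: ElectrodeTable,
    labels: LabelVolume | None,
    fs: float = 2000.0,
    seed: int | None = None,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    acquisition_filter: bool = True,
) -> tuple[Recording, EventTable, dict]:
    """Generate one synthetic session.

    Every contact channel is the sum of 1/f background, per-band
    oscillatory components with trial-wise variance scaling, shared
    line/artifact tones, and a per-strip common-mode component.  The
    contact's network comes from ``labels`` (5 mm modal rule) unless the
    electrode table already carries one.  ``ground_truth`` records the
    schedule, each contact's network, and every injected gain.

    The sampling rate must resolve the highest configured band
    (``fs/2 > 250`` for the default high-gamma band) or the band table
    must be reconfigured.
    """
    hi_max = max(b.hi_hz for b in bands)
    if fs / 2 <= hi_max:
        raise ValidationError(
            f"fs={fs} cannot resolve the {hi_max} Hz band edge; raise fs or reconfigure bands"
        )
    rng = np.random.default_rng(seed)
    # independent substreams so schedule and signals decouple
    rng_sched, rng_sig = (np.random.default_rng(s) for s in rng.integers(0, 2**31, size=2))

    table = electrodes
    if table.contacts["network"].isna().any():
        if labels is None:
            raise ValidationError("electrodes lack network labels and no label volume given")
        table = assign_network(table, labels)

    sched = plan.draw_schedule(rng_sched)
    events = EventTable(sched)
    total_s = float(sched["offset_s"].max() + plan.lead_in_s)
    n = int(round(total_s * fs))

    # per-sample condition gain masks are per (network, band); build per trial
    trial_windows = [
        (int(round(r.onset_s * fs)), int(round(r.offset_s * fs)), r.condition)
        for r in sched.itertuples()
    ]

    networks = table.contacts["network"].fillna(UNASSIGNED).tolist()
    strips = table.contacts["strip_id"].tolist()

    # shared components
    t = np.arange(n) / fs
    shared = np.zeros(n)
    for f0, amp in effects.line_noise_uv.items():
        for h in range(1, effects.line_harmonics + 1):
            fh = f0 * h
            if fh < fs / 2:
                shared += amp / h * np.sin(2 * np.pi * fh * t + rng_sig.uniform(0, 2 * np.pi))
    for h in range(1, effects.artifact_harmonics + 1):
        fh = effects.artifact_tone_hz * h
        if fh < fs / 2:
            shared += (effects.artifact_tone_uv / h
                       * np.sin(2 * np.pi * fh * t + rng_sig.uniform(0, 2 * np.pi)))

    common_by_strip = {
        sid: effects.common_mode_uv * _one_over_f_noise(n, fs, 1.0, rng_sig)
        for sid in dict.fromkeys(strips)
    }

    data = np.empty((len(table), n))
    gains_truth: list[dict] = []
    for ch in range(len(table)):
        net = networks[ch]
        x = effects.background_std_uv * _one_over_f_noise(n, fs, effects.background_exponent, rng_sig)
        for band in bands:
            base_std = effects.band_component_std_uv.get(band.name, 0.0)
            if base_std <= 0:
                continue
            comp = base_std * _band_limited_noise(n, fs, band, rng_sig)
            scale = np.ones(n)
            for a, b, cond in trial_windows:
                g = effects.gain(net, band.name, cond)
                if g != 1.0:
                    scale[a:b] = np.sqrt(g)
            x += comp * scale
        x += shared + common_by_strip[strips[ch]]
        data[ch] = x
        gains_truth.append({
            "name": table.contacts.at[ch, "name"], "network": net,
            "gains": {f"{band.name}:{cond}": effects.gain(net, band.name, cond)
                      for band in bands for cond in ("rest", "count", "switch")
                      if effects.gain(net, band.name, cond) != 1.0},
        })

    if acquisition_filter:
        sos_hp = signal.butter(4, 1.0, btype="highpass", fs=fs, output="sos")
        data = signal.sosfilt(sos_hp, data, axis=1)
        if fs / 2 > 1500.0:
            sos_lp = signal.butter(4, 1500.0, btype="lowpass", fs=fs, output="sos")
            data = signal.sosfilt(sos_lp, data, axis=1)

    rec = Recording(data=data, fs=fs, channel_names=table.contacts["name"].tolist())
    ground_truth = {
        "seed": seed,
        "fs": fs,
        "schedule": sched.to_dict("records"),
        "channels": gains_truth,
        "effects": {
            "background_exponent": effects.background_exponent,
            "modulation": {f"{k[0]}:{k[1]}:{k[2]}": v for k, v in effects.modulation.items()},
            "common_mode_uv": effects.common_mode_uv,
            "artifact_tone_hz": effects.artifact_tone_hz,
        },
    }
    return rec, events, ground_truth
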