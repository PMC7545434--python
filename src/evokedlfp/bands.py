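"""Band-limited Hilbert-envelope energy analysis.

The analysis chain for one epoch set is: zero-phase band-pass filter →
squared magnitude of the analytic (Hilbert) signal → mean energy within
half-second post-stimulus bins → division by a burst-free pre-stimulus
baseline bin.  Normalized energy is therefore a unitless ratio that equals
1 for a stationary signal with no stimulus-locked or induced activity.

Canonical frequency bands: δ 2–4, θ 5–7, α 8–12, β 15–29, γ 30–90 Hz;
"total" is a 2–90 Hz broadband pass.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .epochs import EpochSet

__all__ = [
    "BandDefinition",
    "CANONICAL_BANDS",
    "TOTAL_BAND",
    "BAND_BY_NAME",
    "DEFAULT_BINS_MS",
    "bandpass",
    "hilbert_energy",
    "bin_energy",
    "choose_baseline_bin",
    "normalized_energy_change",
    "energy_table",
    "contrast_ratio",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"invalid band edges: {self.low}-{self.high} Hz")


CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 2.0, 4.0),
    BandDefinition("theta", 5.0, 7.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 15.0, 29.0),
    BandDefinition("gamma", 30.0, 90.0),
)

#: Broadband pass used for "total" energy (covers all canonical bands).
TOTAL_BAND = BandDefinition("total", 2.0, 90.0)

BAND_BY_NAME = {b.name: b for b in CANONICAL_BANDS} | {"total": TOTAL_BAND}

#: Post-stimulus analysis bins in ms (half-open).
DEFAULT_BINS_MS: tuple[tuple[float, float], ...] = ((0.0, 500.0), (500.0, 1000.0), (1000.0, 1500.0))


def _as_band(band) -> BandDefinition:
    if isinstance(band, BandDefinition):
        return band
    try:
        return BAND_BY_NAME[band]
    except KeyError:
        raise ValueError(f"unknown band {band!r}; known: {sorted(BAND_BY_NAME)}") from None


def bandpass(x: np.ndarray, band, rate: float, order: int = 4, axis: int = -1) -> np.ndarray:
    """Zero-phase Butterworth band-pass filter.

    A forward-backward (``sosfiltfilt``) pass of an order-``order``
    Butterworth design: zero phase shift, so envelope latencies are not
    displaced, and ≥ 40 dB attenuation one octave outside the band.

    Parameters
    ----------
    x : array
        Signal(s); filtering runs along ``axis``.
    band : BandDefinition or str
        Band edges, or the name of a canonical band.
    rate : float
        Sampling rate in Hz; ``band.high`` must be below Nyquist.
    """
    band = _as_band(band)
    if band.high >= rate / 2:
        raise ValueError(
            f"band {band.name} ({band.low}-{band.high} Hz) reaches Nyquist at rate {rate} Hz"
        )
    sos = sps.butter(order, (band.low, band.high), btype="bandpass", fs=rate, output="sos")
    n = x.shape[axis]
    # pad ~3 cycles of the low edge so narrow-band transients settle
    padlen = int(min(n - 1, max(3 * order + 1, 3 * rate / band.low)))
    return sps.sosfiltfilt(sos, x, axis=axis, padlen=padlen)


def hilbert_energy(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Instantaneous band energy: squared magnitude of the analytic signal.

    For a band-limited input ``A(t)·sin(2πft + φ)`` with slowly varying
    ``A``, the result tracks ``A(t)²`` away from the edges.
    """
    n = x.shape[axis]
    if n == 0:
        raise ValueError("empty input")
    nfft = int(2 ** math.ceil(math.log2(n))) if (n & (n - 1)) else n
    analytic = sps.hilbert(x, N=nfft, axis=axis)
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(0, n)
    return np.abs(analytic[tuple(sl)]) ** 2


def bin_energy(
    energy: np.ndarray,
    bins_ms: Sequence[tuple[float, float]],
    stim_sample: int,
    rate: float,
) -> np.ndarray:
    """Mean energy within half-open post-stimulus bins.

    ``bins_ms`` are (start, end) pairs in ms relative to the stimulus sample;
    bins must not overlap and must lie within the post-stimulus span.
    """
    energy = np.asarray(energy)
    n = energy.shape[-1]
    pairs = [(float(a), float(b)) for a, b in bins_ms]
    for a, b in pairs:
        if not (0 <= a < b):
            raise ValueError(f"invalid bin ({a}, {b}) ms")
        if stim_sample + round(b * rate / 1000) > n:
            raise ValueError(f"bin ({a}, {b}) ms extends past the epoch end")
    for (a0, b0), (a1, b1) in zip(sorted(pairs), sorted(pairs)[1:]):
        if a1 < b0:
            raise ValueError(f"bins ({a0}, {b0}) and ({a1}, {b1}) ms overlap")
    out = []
    for a, b in pairs:
        i0 = stim_sample + round(a * rate / 1000)
        i1 = stim_sample + round(b * rate / 1000)
        out.append(energy[..., i0:i1].mean(axis=-1))
    return np.stack(out, axis=-1)


def choose_baseline_bin(
    energy: np.ndarray,
    stim_sample: int,
    rate: float,
    bin_width_s: float = 0.5,
    burst_criterion: float = 2.0,
    edge_guard_s: float = 0.25,
) -> tuple[tuple[float, float], str]:
    """Pick a pre-stimulus baseline bin free of spontaneous bursts.

    Candidate bins of ``bin_width_s`` tile backwards from the stimulus
    (staying ``edge_guard_s`` clear of the epoch start, where filter edge
    effects live).  Scanning from the latest candidate backwards, the first
    bin whose mean energy is at most ``burst_criterion`` × the median of all
    candidate energies is returned with flag ``"clean"``.  If every candidate
    looks bursty, the minimum-energy bin is returned with flag ``"forced"``.

    Returns
    -------
    ((start_s, end_s), flag)
        Interval in seconds relative to the stimulus (start < end ≤ 0).
    """
    energy = np.asarray(energy)
    wbin = round(bin_width_s * rate)
    if stim_sample < 2 * wbin:
        raise ValueError("pre-stimulus span must be at least two baseline bin widths")
    guard = round(edge_guard_s * rate)
    n_cand = (stim_sample - guard) // wbin
    if n_cand < 1:
        n_cand = stim_sample // wbin
    means = np.empty(n_cand)
    for k in range(1, n_cand + 1):
        means[k - 1] = energy[stim_sample - k * wbin : stim_sample - (k - 1) * wbin].mean()
    med = float(np.median(means))
    for k in range(1, n_cand + 1):
        if means[k - 1] <= burst_criterion * med:
            return ((-k * bin_width_s, -(k - 1) * bin_width_s), "clean")
    k = int(np.argmin(means)) + 1
    return ((-k * bin_width_s, -(k - 1) * bin_width_s), "forced")


def _baseline_mean(energy: np.ndarray, interval: tuple[float, float], stim_sample: int, rate: float) -> float:
    i0 = stim_sample + round(interval[0] * rate)
    i1 = stim_sample + round(interval[1] * rate)
    return float(energy[i0:i1].mean())


def normalized_energy_change(
    es: EpochSet,
    band,
    bins_ms: Sequence[tuple[float, float]] = DEFAULT_BINS_MS,
    mode: str = "pooled",
    bin_width_s: float = 0.5,
    burst_criterion: float = 2.0,
    edge_guard_s: float = 0.25,
) -> pd.DataFrame:
    """Stimulus-induced energy change relative to baseline, one row per bin.

    In the default ``"pooled"`` mode the envelope energy is first averaged
    across the epochs (stimulus repetitions) of one subject/condition, the
    baseline bin is chosen on that averaged series, and the post-stimulus
    bin means are divided by the baseline mean.  ``"per_epoch"`` instead
    normalizes every epoch by its own baseline bin and averages the ratios.

    Returns a tidy DataFrame with columns: subject_id, age_group, condition,
    band, bin_start_ms, bin_end_ms, normalized_energy, baseline_bin_start_s,
    baseline_flag.
    """
    if mode not in ("pooled", "per_epoch"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    band = _as_band(band)
    en = hilbert_energy(bandpass(es.epochs, band, es.sampling_rate))
    stim = es.n_pre
    rate = es.sampling_rate
    kw = dict(bin_width_s=bin_width_s, burst_criterion=burst_criterion, edge_guard_s=edge_guard_s)

    if mode == "pooled":
        ebar = en.mean(axis=0)
        interval, flag = choose_baseline_bin(ebar, stim, rate, **kw)
        base = _baseline_mean(ebar, interval, stim, rate)
        if base <= 0:
            raise ValueError(
                "baseline energy is zero (all-zero trace?); cannot normalize"
            )
        values = bin_energy(ebar, bins_ms, stim, rate) / base
        base_start = interval[0]
    else:
        ratios = []
        starts = []
        flags = []
        for row in en:
            interval, f = choose_baseline_bin(row, stim, rate, **kw)
            base = _baseline_mean(row, interval, stim, rate)
            if base <= 0:
                raise ValueError(
                    "baseline energy is zero in an epoch (all-zero trace?); cannot normalize"
                )
            ratios.append(bin_energy(row, bins_ms, stim, rate) / base)
            starts.append(interval[0])
            flags.append(f)
        values = np.mean(ratios, axis=0)
        base_start = float(np.median(starts))
        flag = "clean" if all(f == "clean" for f in flags) else "forced"

    prov = es.provenance
    return pd.DataFrame(
        {
            "subject_id": prov.get("subject_id", "NA"),
            "age_group": prov.get("age_group", "NA"),
            "condition": prov.get("condition", "NA"),
            "band": band.name,
            "bin_start_ms": [float(a) for a, _ in bins_ms],
            "bin_end_ms": [float(b) for _, b in bins_ms],
            "normalized_energy": np.asarray(values, dtype=float),
            "baseline_bin_start_s": base_start,
            "baseline_flag": flag,
        }
    )


def energy_table(
    recordings,
    bands=None,
    include_total: bool = True,
    pre: float = 5.0,
    post: float = 5.0,
    bins_ms: Sequence[tuple[float, float]] = DEFAULT_BINS_MS,
    **norm_kw,
) -> pd.DataFrame:
    """Normalized energy changes for a set of recordings, all bands.

    Each recording is segmented into ``pre``/``post``-second epochs around
    its stimuli and every requested band (plus the 2–90 Hz broadband
    "total" unless disabled) is reduced to one row per post-stimulus bin.
    """
    from .epochs import segment

    band_list = [_as_band(b) for b in (bands if bands is not None else CANONICAL_BANDS)]
    if include_total:
        band_list = band_list + [TOTAL_BAND]
    frames = []
    for rec in recordings:
        es = segment(rec, pre, post)
        for band in band_list:
            frames.append(normalized_energy_change(es, band, bins_ms=bins_ms, **norm_kw))
    return pd.concat(frames, ignore_index=True)


def contrast_ratio(
    tbl: pd.DataFrame, numerator_condition: str, denominator_condition: str
) -> pd.DataFrame:
    """Within-subject ratio of normalized energies between two conditions.

    For every subject × band × time bin, the normalized energy under
    ``numerator_condition`` is divided by that under
    ``denominator_condition`` (the A+C/A and after/before-silencing ratios).
    Subjects missing either condition are dropped with a logged warning.
    """
    keys = ["subject_id", "age_group", "band", "bin_start_ms", "bin_end_ms"]
    wide = tbl.pivot_table(
        index=keys, columns="condition", values="normalized_energy", aggfunc="mean"
    )
    for cond in (numerator_condition, denominator_condition):
        if cond not in wide.columns:
            raise ValueError(f"condition {cond!r} absent from the energy table")
    both = wide[[numerator_condition, denominator_condition]].dropna()
    dropped = sorted(
        set(wide.index.get_level_values("subject_id"))
        - set(both.index.get_level_values("subject_id"))
    )
    if dropped:
        log.warning("contrast_ratio: dropping subjects missing a condition: %s", dropped)
    if both.empty:
        raise ValueError(
            f"no subject has both conditions {numerator_condition!r} and {denominator_condition!r}"
        )
    out = both.reset_index()
    out["energy_ratio"] = out[numerator_condition] / out[denominator_condition]
    out["numerator"] = numerator_condition
    out["denominator"] = denominator_condition
    return out[keys + ["numerator", "denominator", "energy_ratio"]]
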