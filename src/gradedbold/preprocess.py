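"""From raw dual-echo tag/control ASL series to per-level responses.

A pulsed-ASL acquisition with a dual-echo readout interleaves tag and
control volumes; the short first echo is perfusion weighted and the longer
second echo BOLD weighted.  Surround subtraction/averaging — linearly
interpolating each label stream onto every TR and combining pointwise —
separates the two contrasts:

* ``perfusion_series``: control - tag at echo 1 (CBF-weighted difference);
* ``bold_series``: (control + tag) / 2 at echo 2;
* ``r2star_series``: two-point log-ratio R2* per label stream, then the two
  streams surround averaged.

Block responses are taken over steady-state windows of a block paradigm
(skipping the gas-transition part of each block), referenced to the
baseline steady-state mean after baseline-anchored linear detrending, and
paired with the end-tidal CO2 rise measured from breath-wise capnography.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .fit import HypercapniaLevel

__all__ = [
    "BASELINE",
    "Block",
    "Paradigm",
    "DualEchoSeries",
    "EndTidalTrace",
    "DetrendedSeries",
    "perfusion_series",
    "bold_series",
    "r2star_series",
    "detrend_baseline",
    "block_response",
    "endtidal_level",
    "roi_average",
    "extract_levels",
    "average_level_sets",
]

#: Condition name reserved for normocapnic baseline blocks.
BASELINE = "baseline"


@dataclass(frozen=True)
class Block:
    condition: str
    onset: float
    duration: float


@dataclass(frozen=True)
class Paradigm:
    """Ordered, non-overlapping condition blocks with steady-state windows.

    ``steady_state_offset`` discards the first part of each block, where
    the delivered gas (and hence CBF) is still settling toward its target.
    ``steady_state_guard`` additionally trims the tail of each block so
    that surround interpolation near a condition transition never mixes
    samples from adjacent blocks (two TRs is enough; the default 4.5 s
    covers a 2.2 s TR).
    """

    blocks: tuple[Block, ...]
    steady_state_offset: float = 60.0
    steady_state_guard: float = 4.5

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("paradigm needs at least one block")
        prev_end = -np.inf
        for blk in self.blocks:
            if blk.duration <= 0:
                raise ValueError(f"non-positive block duration: {blk}")
            if blk.onset < prev_end - 1e-9:
                raise ValueError(f"overlapping/unordered block: {blk}")
            prev_end = blk.onset + blk.duration
        if self.steady_state_offset < 0 or self.steady_state_guard < 0:
            raise ValueError("steady-state offset and guard must be >= 0")

    @property
    def conditions(self) -> tuple[str, ...]:
        """Distinct non-baseline conditions in order of first appearance."""
        seen: list[str] = []
        for blk in self.blocks:
            if blk.condition != BASELINE and blk.condition not in seen:
                seen.append(blk.condition)
        return tuple(seen)

    @property
    def duration(self) -> float:
        last = self.blocks[-1]
        return last.onset + last.duration

    def steady_state_windows(self, condition: str) -> list[tuple[float, float]]:
        windows = [
            (
                blk.onset + self.steady_state_offset,
                blk.onset + blk.duration - self.steady_state_guard,
            )
            for blk in self.blocks
            if blk.condition == condition
        ]
        if not windows:
            raise ValueError(f"condition {condition!r} not present in paradigm")
        if any(end <= start for start, end in windows):
            raise ValueError(
                f"steady-state window empty for {condition!r}: offset "
                f"{self.steady_state_offset} + guard {self.steady_state_guard} "
                "leave no samples"
            )
        return windows

    def condition_at(self, t: float) -> str:
        for blk in self.blocks:
            if blk.onset <= t < blk.onset + blk.duration:
                return blk.condition
        return BASELINE

    def to_dict(self) -> dict:
        return {
            "steady_state_offset_s": self.steady_state_offset,
            "steady_state_guard_s": self.steady_state_guard,
            "blocks": [
                {
                    "condition": b.condition,
                    "onset_s": b.onset,
                    "duration_s": b.duration,
                }
                for b in self.blocks
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Paradigm":
        return cls(
            blocks=tuple(
                Block(b["condition"], float(b["onset_s"]), float(b["duration_s"]))
                for b in d["blocks"]
            ),
            steady_state_offset=float(d.get("steady_state_offset_s", 60.0)),
            steady_state_guard=float(d.get("steady_state_guard_s", 4.5)),
        )


@dataclass
class DualEchoSeries:
    """Interleaved tag/control signals at two echo times on a uniform grid."""

    time: np.ndarray
    label: np.ndarray  # "tag" | "control" per time point, strictly alternating
    echo1: np.ndarray
    echo2: np.ndarray
    te1: float
    te2: float
    tr: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.label = np.asarray(self.label)
        self.echo1 = np.asarray(self.echo1, dtype=float)
        self.echo2 = np.asarray(self.echo2, dtype=float)
        n = self.time.size
        if not (self.label.size == self.echo1.size == self.echo2.size == n):
            raise ValueError("time, label, echo1, echo2 must have equal length")
        if not 0.0 < self.te1 < self.te2:
            raise ValueError(f"need 0 < te1 < te2, got ({self.te1}, {self.te2})")
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        bad = set(np.unique(self.label)) - {"tag", "control"}
        if bad:
            raise ValueError(f"labels must be 'tag'/'control', found {sorted(bad)}")
        if n >= 2 and np.any(self.label[1:] == self.label[:-1]):
            i = int(np.nonzero(self.label[1:] == self.label[:-1])[0][0])
            raise ValueError(f"labels must strictly alternate (repeat at index {i})")

    def __len__(self) -> int:
        return self.time.size

    def mask(self, which: str) -> np.ndarray:
        return self.label == which


def _interp_stream(
    time: np.ndarray, values: np.ndarray, mask: np.ndarray, what: str
) -> np.ndarray:
    """Linearly interpolate one label stream onto the full time grid."""
    if mask.sum() < 2:
        raise ValueError(f"need at least 2 {what} points for interpolation")
    return np.interp(time, time[mask], values[mask])


def perfusion_series(series: DualEchoSeries) -> np.ndarray:
    """CBF-weighted difference signal: surround subtraction at echo 1.

    Control and tag sub-series are each interpolated onto every TR and
    subtracted (control - tag); output has one value per input volume.
    """
    c = _interp_stream(series.time, series.echo1, series.mask("control"), "control")
    t = _interp_stream(series.time, series.echo1, series.mask("tag"), "tag")
    return c - t


def bold_series(series: DualEchoSeries) -> np.ndarray:
    """BOLD-weighted signal: surround averaging at echo 2."""
    c = _interp_stream(series.time, series.echo2, series.mask("control"), "control")
    t = _interp_stream(series.time, series.echo2, series.mask("tag"), "tag")
    return 0.5 * (c + t)


def r2star_series(series: DualEchoSeries) -> np.ndarray:
    """Per-volume R2* from the two echoes, tag/control surround averaged.

    Within each label stream R2* = ln(S(TE1)/S(TE2)) / (TE2 - TE1) per
    volume (the exact two-point mono-exponential inversion); the two
    streams are then interpolated onto the full grid and averaged.
    """
    nonpos = np.nonzero((series.echo1 <= 0) | (series.echo2 <= 0))[0]
    if nonpos.size:
        raise ValueError(
            f"non-positive signal at index {int(nonpos[0])}; cannot take log"
        )
    r2 = np.log(series.echo1 / series.echo2) / (series.te2 - series.te1)
    c = _interp_stream(series.time, r2, series.mask("control"), "control")
    t = _interp_stream(series.time, r2, series.mask("tag"), "tag")
    return 0.5 * (c + t)


def _window_mask(
    time: np.ndarray, windows: Sequence[tuple[float, float]]
) -> np.ndarray:
    mask = np.zeros(time.size, dtype=bool)
    for start, end in windows:
        mask |= (time >= start - 1e-9) & (time < end - 1e-9)
    return mask


@dataclass
class DetrendedSeries:
    """Series with the baseline-anchored linear trend removed.

    ``values`` has zero mean over the baseline steady-state samples; the
    removed baseline level is kept so that percent changes can still be
    referenced to it (``restored`` adds it back).
    """

    values: np.ndarray
    time: np.ndarray
    baseline_level: float
    slope: float
    intercept: float

    @property
    def restored(self) -> np.ndarray:
        return self.values + self.baseline_level


def detrend_baseline(
    values: np.ndarray, time: np.ndarray, paradigm: Paradigm
) -> DetrendedSeries:
    """Remove a linear drift estimated from baseline steady-state samples.

    An ordinary least-squares line is fitted to the samples falling inside
    the baseline blocks' steady-state windows only (so condition responses
    cannot leak into the trend estimate) and subtracted from the entire
    series.  The baseline steady-state mean of the result is zero; the
    pre-detrend baseline level is stored for percent-change referencing.
    """
    values = np.asarray(values, dtype=float)
    time = np.asarray(time, dtype=float)
    windows = paradigm.steady_state_windows(BASELINE)
    mask = _window_mask(time, windows)
    if np.unique(time[mask]).size < 2:
        raise ValueError("need >= 2 distinct baseline time points to detrend")
    slope, intercept = np.polyfit(time[mask], values[mask], deg=1)
    line = slope * time + intercept
    baseline_level = float(np.mean(line[mask]))
    return DetrendedSeries(
        values=values - line,
        time=time,
        baseline_level=baseline_level,
        slope=float(slope),
        intercept=float(intercept),
    )


def block_response(
    series: "np.ndarray | DetrendedSeries",
    time: "np.ndarray | None",
    paradigm: Paradigm,
    condition: str,
) -> float:
    """Fractional steady-state response of a condition vs baseline.

    Means are taken over the steady-state windows of all blocks of the
    condition and of baseline; the response is their ratio minus one.  For
    a detrended series the stored baseline level is used as the reference.
    ``time`` may be omitted for a :class:`DetrendedSeries` (it carries its
    own time axis).
    """
    if isinstance(series, DetrendedSeries):
        values = series.restored
        time = series.time
    else:
        values = np.asarray(series, dtype=float)
        if time is None:
            raise ValueError("time axis required for a plain array")
        time = np.asarray(time, dtype=float)
    cond_mask = _window_mask(time, paradigm.steady_state_windows(condition))
    base_mask = _window_mask(time, paradigm.steady_state_windows(BASELINE))
    if not cond_mask.any() or not base_mask.any():
        raise ValueError(f"no samples in steady-state windows for {condition!r}")
    base_mean = float(np.mean(values[base_mask]))
    if base_mean <= 0:
        raise ValueError(
            f"baseline steady-state mean must be positive for a ratio, got {base_mean}"
        )
    return float(np.mean(values[cond_mask]) / base_mean - 1.0)


@dataclass(frozen=True)
class EndTidalTrace:
    """Breath-wise end-tidal CO2 samples."""

    times: np.ndarray
    petco2: np.ndarray  # mmHg

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "petco2", np.asarray(self.petco2, dtype=float))
        if self.times.size != self.petco2.size:
            raise ValueError("times and petco2 must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("breath times must be strictly increasing")
        if np.any((self.petco2 < 10) | (self.petco2 > 80)):
            raise ValueError("PETCO2 outside the physiologic 10-80 mmHg range")


def endtidal_level(
    trace: EndTidalTrace, paradigm: Paradigm, condition: str
) -> float:
    """End-tidal CO2 rise of a condition over baseline, mmHg.

    Breath-wise PETCO2 is pooled over the condition's steady-state windows
    and over the baseline windows; the level is the difference of the two
    pooled means.  Raises if any steady-state window contains no breaths.
    """

    def pooled_mean(cond: str) -> float:
        windows = paradigm.steady_state_windows(cond)
        picks = []
        for start, end in windows:
            m = (trace.times >= start - 1e-9) & (trace.times < end - 1e-9)
            if not m.any():
                raise ValueError(
                    f"no breaths in steady-state window [{start}, {end}) of {cond!r}"
                )
            picks.append(trace.petco2[m])
        return float(np.mean(np.concatenate(picks)))

    return pooled_mean(condition) - pooled_mean(BASELINE)


def roi_average(volumes, mask) -> np.ndarray:
    """Unweighted mean over mask voxels per time point.

    ``volumes`` is a 4D array or NIfTI image (x, y, z, t); ``mask`` a 3D
    array/image, nonzero inside the ROI, on the same grid.
    """
    if hasattr(volumes, "get_fdata"):
        volumes = volumes.get_fdata()
    if hasattr(mask, "get_fdata"):
        mask = mask.get_fdata()
    volumes = np.asarray(volumes, dtype=float)
    mask = np.asarray(mask) != 0
    if volumes.ndim != 4 or mask.ndim != 3:
        raise ValueError(
            f"expected 4D volumes and 3D mask, got {volumes.ndim}D and {mask.ndim}D"
        )
    if volumes.shape[:3] != mask.shape:
        raise ValueError(
            f"grid mismatch: volumes {volumes.shape[:3]} vs mask {mask.shape}"
        )
    if not mask.any():
        raise ValueError("empty ROI mask")
    return volumes[mask].mean(axis=0)


def extract_levels(
    series: DualEchoSeries,
    paradigm: Paradigm,
    endtidal: EndTidalTrace,
    conditions: Optional[Sequence[str]] = None,
    detrend: bool = True,
) -> list[HypercapniaLevel]:
    """Full response extraction: one :class:`HypercapniaLevel` per condition.

    Runs surround subtraction/averaging, optional baseline detrending of
    both contrast series, steady-state block responses and end-tidal dose
    measurement, returning levels sorted by dose — the direct input of the
    fitting layer.
    """
    if conditions is None:
        conditions = paradigm.conditions
    perf = perfusion_series(series)
    bold = bold_series(series)
    if detrend:
        perf = detrend_baseline(perf, series.time, paradigm)
        bold = detrend_baseline(bold, series.time, paradigm)
        time = None
    else:
        time = series.time
    levels = []
    for cond in conditions:
        dp = endtidal_level(endtidal, paradigm, cond)
        b = block_response(bold, time, paradigm, cond)
        f = 1.0 + block_response(perf, time, paradigm, cond)
        levels.append(HypercapniaLevel(delta_petco2=dp, bold_frac=b, cbf_ratio=f))
    return sorted(levels, key=lambda lv: lv.delta_petco2)


def average_level_sets(
    sessions: Sequence[Sequence[HypercapniaLevel]],
) -> list[HypercapniaLevel]:
    """Average per-session levels into per-subject levels.

    Sessions must provide the same number of levels; levels are matched by
    dose rank and their dose, BOLD fraction and CBF ratio averaged.
    """
    if not sessions:
        raise ValueError("no sessions to average")
    n = len(sessions[0])
    if any(len(s) != n for s in sessions):
        raise ValueError("sessions have differing numbers of levels")
    out = []
    for i in range(n):
        ranked = [sorted(s, key=lambda lv: lv.delta_petco2)[i] for s in sessions]
        out.append(
            HypercapniaLevel(
                delta_petco2=float(np.mean([lv.delta_petco2 for lv in ranked])),
                bold_frac=float(np.mean([lv.bold_frac for lv in ranked])),
                cbf_ratio=float(np.mean([lv.cbf_ratio for lv in ranked])),
            )
        )
    return out
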