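"""Detection and temporal repair of single-sample slice artifacts.

Changing the TMS stimulator output during an EPI run can leak current
into the coil, perturbing the static field and producing short (one
sample) deflections of the baseline signal confined to a single slice
near the coil.  The detector follows the mean grey-matter signal of each
slice over time and flags a (slice, volume) sample when the robust
z-scores of the temporal difference stepping *into* and *out of* that
volume both exceed a threshold with opposite signs — a sharp one-sample
peak, by construction insensitive to drifts and step changes.  Flagged
slices are repaired by temporal interpolation from the same slice in the
neighbouring clean volumes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import VolumeSeries

__all__ = [
    "SliceTimecourses",
    "SpikeEvent",
    "SpikeReport",
    "slice_timecourses",
    "detect_spikes",
    "repair_spikes",
    "DEFAULT_Z_THRESHOLD",
]

#: default robust-z threshold on temporal differences; the leak-current
#: deflections are gross outliers, so the operating point is conservative
DEFAULT_Z_THRESHOLD = 6.0

#: consistency constant: MAD of a Gaussian ≈ sd / 1.4826
MAD_SCALE = 1.4826


@dataclass
class SliceTimecourses:
    """Mean in-mask signal per (slice, volume); NaN rows lack GM voxels."""

    values: np.ndarray            # (n_slices, n_volumes)
    gm_voxel_counts: np.ndarray   # (n_slices,)

    @property
    def n_slices(self) -> int:
        return self.values.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]

    @property
    def defined_slices(self) -> np.ndarray:
        return self.gm_voxel_counts > 0


def slice_timecourses(series: VolumeSeries, gm_mask: np.ndarray) -> SliceTimecourses:
    """Average the series over the GM voxels of each slice.

    Slices with no GM voxels get NaN timecourses and are excluded from
    detection downstream.  The slice axis is the third voxel axis.
    """
    gm_mask = np.asarray(gm_mask, dtype=bool)
    if gm_mask.shape != series.grid_shape:
        raise ValueError("GM mask grid does not match series grid")
    nz, nt = series.n_slices, series.n_volumes
    values = np.full((nz, nt), np.nan)
    counts = np.zeros(nz, dtype=int)
    for z in range(nz):
        plane = gm_mask[:, :, z]
        counts[z] = int(plane.sum())
        if counts[z] > 0:
            values[z] = series.data[:, :, z, :][plane].mean(axis=0)
    return SliceTimecourses(values, counts)


@dataclass
class SpikeEvent:
    volume: int
    slice: int
    score: float
    repaired: bool = False


@dataclass
class SpikeReport:
    """Detected (volume, slice) artifact events with provenance."""

    events: list[SpikeEvent]
    threshold: float
    n_slices: int
    n_volumes: int

    @property
    def fraction_affected(self) -> float:
        """Affected slices / total acquired slices (slices × volumes)."""
        return len(self.events) / float(self.n_slices * self.n_volumes)

    def pairs(self) -> set[tuple[int, int]]:
        return {(e.volume, e.slice) for e in self.events}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"volume": e.volume, "slice": e.slice, "score": e.score,
              "repaired": e.repaired} for e in self.events],
            columns=["volume", "slice", "score", "repaired"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_events": len(self.events),
            "fraction_affected": self.fraction_affected,
            "n_slices": self.n_slices,
            "n_volumes": self.n_volumes,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))


def _robust_z(diffs: np.ndarray) -> np.ndarray:
    """Median/MAD z-scores of one slice's temporal differences.

    Falls back to standard-deviation scaling (with a warning) when the
    MAD is zero but the differences are not all equal.
    """
    med = np.median(diffs)
    mad = np.median(np.abs(diffs - med))
    scale = MAD_SCALE * mad
    if scale == 0:
        if np.any(diffs != med):
            warnings.warn("zero MAD with nonzero differences; falling back to SD scaling")
            scale = diffs.std()
        else:
            return np.zeros_like(diffs)
    return (diffs - med) / scale


def detect_spikes(
    stc: SliceTimecourses,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> SpikeReport:
    """Flag one-sample deflections in the slice-mean timecourses.

    A volume t of slice z is flagged when the robust z of the step into t
    and the step out of t both exceed ``z_threshold`` in magnitude with
    opposite signs.  Boundary volumes use the one-sided criterion (their
    single step exceeds the threshold, and the adjacent interior volume
    was not already flagged).  The score is the smaller exceedance.
    """
    if stc.n_volumes < 5:
        raise ValueError("need at least 5 volumes for spike detection")
    events: list[SpikeEvent] = []
    for z in range(stc.n_slices):
        if not stc.defined_slices[z]:
            continue
        tc = stc.values[z]
        d = np.diff(tc)                       # d[i] = step from volume i to i+1
        zd = _robust_z(d)
        flagged_interior = set()
        for t in range(1, stc.n_volumes - 1):
            z_in, z_out = zd[t - 1], zd[t]
            if abs(z_in) > z_threshold and abs(z_out) > z_threshold and z_in * z_out < 0:
                events.append(SpikeEvent(t, z, float(min(abs(z_in), abs(z_out)))))
                flagged_interior.add(t)
        if abs(zd[0]) > z_threshold and 1 not in flagged_interior:
            events.append(SpikeEvent(0, z, float(abs(zd[0]))))
        last = stc.n_volumes - 1
        if abs(zd[-1]) > z_threshold and last - 1 not in flagged_interior:
            events.append(SpikeEvent(last, z, float(abs(zd[-1]))))
    events.sort(key=lambda e: (e.volume, e.slice))
    return SpikeReport(events, z_threshold, stc.n_slices, stc.n_volumes)


def repair_spikes(
    series: VolumeSeries,
    report: SpikeReport,
) -> tuple[VolumeSeries, SpikeReport]:
    """Replace flagged slices by temporal interpolation.

    Each flagged slice is rebuilt voxel-wise from the same slice in the
    nearest clean neighbouring volumes: the average of previous and next
    for an isolated event, linear interpolation across a run of
    consecutive flagged volumes, and a copy of the single clean
    neighbour at the series boundary.  Untouched samples are
    bit-identical.  A slice flagged in every volume is unrepairable.
    """
    nz, nt = series.n_slices, series.n_volumes
    by_slice: dict[int, list[int]] = {}
    for e in report.events:
        if not (0 <= e.volume < nt and 0 <= e.slice < nz):
            raise ValueError(f"event ({e.volume}, {e.slice}) out of bounds")
        by_slice.setdefault(e.slice, []).append(e.volume)
    out = series.copy()
    for z, vols in by_slice.items():
        flagged = np.zeros(nt, dtype=bool)
        flagged[vols] = True
        if flagged.all():
            raise ValueError(f"slice {z} flagged in every volume; unrepairable")
        t = 0
        while t < nt:
            if not flagged[t]:
                t += 1
                continue
            start = t
            while t < nt and flagged[t]:
                t += 1
            end = t - 1                      # inclusive run [start, end]
            prev = start - 1 if start > 0 else None
            nxt = end + 1 if end < nt - 1 else None
            for v in range(start, end + 1):
                if prev is None:
                    out.data[:, :, z, v] = series.data[:, :, z, nxt]
                elif nxt is None:
                    out.data[:, :, z, v] = series.data[:, :, z, prev]
                else:
                    w = (v - prev) / float(nxt - prev)
                    out.data[:, :, z, v] = (
                        (1.0 - w) * series.data[:, :, z, prev]
                        + w * series.data[:, :, z, nxt]
                    )
    repaired_events = [SpikeEvent(e.volume, e.slice, e.score, True) for e in report.events]
    new_report = SpikeReport(repaired_events, report.threshold,
                             report.n_slices, report.n_volumes)
    return out, new_report
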