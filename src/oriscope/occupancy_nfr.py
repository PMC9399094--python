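"""Anchor-aligned nucleosome-occupancy heatmaps and NFR calling.

Nucleosome-free regions (NFRs) are stretches of DNA depleted of nucleosome
occupancy, typically 80-300 bp in yeast, flanked by well-positioned
nucleosomes. This module aligns occupancy tracks at a set of anchors
(ChIP-peak centers or consensus motif sites, strand-aware), calls NFRs as
sustained depletions below a running-median baseline, and computes the
fraction of genome-wide motif hits that fall inside ChIP peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_synth import OccupancyTrack

__all__ = [
    "HeatmapMatrix",
    "NFRCall",
    "build_heatmap",
    "call_nfrs",
    "motif_occupancy_fraction",
]


@dataclass
class HeatmapMatrix:
    """rows = anchors; columns = anchor - flank ... anchor + flank (1 bp)."""

    values: np.ndarray  # (n_anchors, 2*flank+1), NaN = out of bounds
    flank_bp: int
    anchor_mode: str

    @property
    def n_anchors(self) -> int:
        return self.values.shape[0]

    def column_means(self) -> np.ndarray:
        """Per-column mean occupancy, ignoring the missing-value sentinel.

        Rows with more than 50% missing values are dropped first.
        """
        frac_missing = np.isnan(self.values).mean(axis=1)
        keep = self.values[frac_missing <= 0.5]
        with np.errstate(invalid="ignore"):
            return np.nanmean(keep, axis=0)


@dataclass
class NFRCall:
    start: int  # 0-based half-open on the track's chromosome
    end: int
    mean_occupancy: float
    width_bp: int
    left_flank_height: float
    right_flank_height: float

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


def build_heatmap(
    track: OccupancyTrack,
    anchors: list[tuple[int, str]] | list[int],
    flank_bp: int = 1000,
    anchor_mode: str = "consensus",
) -> HeatmapMatrix:
    """Extract anchor +/- flank occupancy rows, strand-aware.

    ``anchors`` is a list of positions or (position, strand) pairs in track
    coordinates; rows for minus-strand anchors are flipped so that the
    motif orientation is shared across rows. Positions outside the track
    are padded with NaN. Row order follows the input order.
    """
    if len(anchors) == 0:
        raise ValueError("at least one anchor required")
    vals = track.values
    n = len(vals)
    width = 2 * flank_bp + 1
    out = np.full((len(anchors), width), np.nan)
    for r, a in enumerate(anchors):
        pos, strand = (a, "+") if isinstance(a, (int, np.integer)) else a
        pos = int(pos) - track.start
        lo = pos - flank_bp
        hi = pos + flank_bp + 1
        src_lo, src_hi = max(lo, 0), min(hi, n)
        if src_hi <= src_lo:
            continue
        out[r, src_lo - lo: src_hi - lo] = vals[src_lo:src_hi]
        if strand == "-":
            out[r] = out[r, ::-1]
    return HeatmapMatrix(values=out, flank_bp=flank_bp, anchor_mode=anchor_mode)


def call_nfrs(
    track: OccupancyTrack,
    *,
    baseline_window: int = 2001,
    depletion_ratio: float = 0.5,
    min_width: int = 80,
) -> list[NFRCall]:
    """Maximal runs of occupancy below ``depletion_ratio`` x local baseline.

    The baseline is a running median over ``baseline_window`` bp (robust to
    both peaks and the depletions themselves); runs at least ``min_width``
    bp long are returned, with flanking-peak heights measured as the
    maximum occupancy within one baseline-window half-width on either side.
    """
    vals = np.asarray(track.values, dtype=float)
    n = len(vals)
    if n <= baseline_window:
        raise ValueError("track must be longer than baseline_window")
    baseline = (
        pd.Series(vals)
        .rolling(baseline_window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    below = vals < depletion_ratio * baseline
    calls: list[NFRCall] = []
    i = 0
    half = baseline_window // 2
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j < n and below[j]:
            j += 1
        if j - i >= min_width:
            lf = float(vals[max(0, i - half):i].max()) if i > 0 else float("nan")
            rf = float(vals[j:min(n, j + half)].max()) if j < n else float("nan")
            calls.append(
                NFRCall(
                    start=i + track.start,
                    end=j + track.start,
                    mean_occupancy=float(vals[i:j].mean()),
                    width_bp=j - i,
                    left_flank_height=lf,
                    right_flank_height=rf,
                )
            )
        i = j
    return calls


def motif_occupancy_fraction(
    hits: pd.DataFrame,
    peaks: list,
    score_cutoff: float,
    motif_width: int = 17,
) -> float:
    """Fraction of motif hits above the cutoff whose window overlaps a peak.

    ``hits`` needs columns start (0-based window start) and score; peaks
    are Peak objects with 0-based half-open intervals on the same assembly.
    Raises if no hit exceeds the cutoff (the fraction is undefined).
    """
    strong = hits[hits["score"] > score_cutoff]
    if len(strong) == 0:
        raise ValueError("no motif hits above the score cutoff")
    if not peaks:
        return 0.0
    starts = np.array([p.start for p in peaks])
    ends = np.array([p.end for p in peaks])
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    n_occ = 0
    for s in strong["start"].to_numpy():
        w_lo, w_hi = int(s), int(s) + motif_width
        # overlap iff some peak has start < w_hi and end > w_lo
        k = np.searchsorted(starts, w_hi)
        if k > 0 and (ends[:k] > w_lo).any():
            n_occ += 1
    return n_occ / len(strong)
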