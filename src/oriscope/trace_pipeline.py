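"""Detect, link, and classify fluorescent trajectories on kymographs.

Implements spot detection by Gaussian matched filtering, greedy
nearest-neighbor linking, and the per-molecule classifications used to
quantify origin-licensing experiments: stable vs. diffusive mobility,
ARS vs. non-ARS position, two-channel colocalization, high-salt-wash
response (slide / stable / dissociate), target-search arrival mode
(direct 3D vs. sliding 1D), and replicate-level fraction summaries with
an unpaired two-tailed t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .kymo_sim import KymographStack, TetherModel

__all__ = [
    "Trajectory",
    "DetectionParams",
    "MobilityCall",
    "ColocalizationCall",
    "SaltResponseCall",
    "FractionSummary",
    "detect_and_link",
    "classify_mobility",
    "classify_position",
    "call_colocalization",
    "classify_salt_response",
    "classify_arrival",
    "summarize",
    "calibrate_variance_threshold",
]


@dataclass
class Trajectory:
    """One tracked emitter: per-line positions and intensities."""

    channel: str
    lines: np.ndarray  # strictly increasing line indices (gaps allowed)
    positions_px: np.ndarray
    positions_bp: np.ndarray
    intensities: np.ndarray
    traj_id: int = -1

    @property
    def start_line(self) -> int:
        return int(self.lines[0])

    @property
    def end_line(self) -> int:
        return int(self.lines[-1])

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    def median_position_bp(self) -> float:
        return float(np.median(self.positions_bp))


@dataclass(frozen=True)
class DetectionParams:
    det_sigma_px: float = 1.0
    snr_min: float = 4.0
    max_jump_px: float = 3.0
    max_gap: int = 2
    min_length: int = 5


@dataclass(frozen=True)
class MobilityCall:
    label: str  # "stable" | "diffusive" | "unclassified"
    displacement_variance_px2: float
    msd_slope_kb2_per_s: float


@dataclass(frozen=True)
class ColocalizationCall:
    traj_ref_a: int
    traj_ref_b: int
    mean_separation_bp: float
    overlap_lines: int
    colocalized: bool


@dataclass(frozen=True)
class SaltResponseCall:
    label: str  # "slide" | "stable" | "dissociate"
    post_wash_range_bp: float
    survived: bool


@dataclass
class FractionSummary:
    groups: list
    counts: dict
    fractions: dict
    replicate_fractions: dict
    mean: dict
    sd: dict
    t_statistic: float | None = None
    p_value: float | None = None
    warnings: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.groups,
                "n": [self.counts[g] for g in self.groups],
                "fraction": [self.fractions[g] for g in self.groups],
                "mean": [self.mean[g] for g in self.groups],
                "sd": [self.sd[g] for g in self.groups],
            }
        )


# ---------------------------------------------------------------------------
# detection and linking


def _detect_line(
    profile: np.ndarray, params: DetectionParams
) -> tuple[np.ndarray, np.ndarray]:
    """Detect candidate spots on one scan line.

    Returns (sub-pixel positions, filtered amplitudes). Spots are local
    maxima of the background-subtracted, Gaussian-matched-filtered profile
    exceeding ``snr_min`` times a robust noise estimate.
    """
    prof = profile.astype(float)
    bg = np.median(prof)
    smooth = ndimage.gaussian_filter1d(prof - bg, params.det_sigma_px)
    resid = (prof - bg) - smooth
    noise = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    noise = max(noise, 1e-6)
    thresh = params.snr_min * noise
    n = len(smooth)
    pos, amp = [], []
    for i in range(1, n - 1):
        if smooth[i] >= smooth[i - 1] and smooth[i] > smooth[i + 1] and \
                smooth[i] > thresh:
            # 3-point parabolic sub-pixel interpolation
            y0, y1, y2 = smooth[i - 1], smooth[i], smooth[i + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            pos.append(i + delta)
            amp.append(float(y1))
    return np.asarray(pos), np.asarray(amp)


def detect_and_link(
    kymo: KymographStack,
    channel: str,
    params: DetectionParams | None = None,
) -> list[Trajectory]:
    """Detect spots per line and link them greedily across lines.

    Linking is nearest-neighbor subject to ``max_jump_px`` per line step and
    ``max_gap`` skipped lines; trajectories shorter than ``min_length``
    retained lines are discarded.
    """
    if kymo.tether is None:
        raise ValueError("kymograph carries no calibration")
    params = params or DetectionParams()
    raster = kymo.channels[channel]
    n_lines = raster.shape[0]
    active: list[dict] = []  # open tracks
    done: list[dict] = []
    for line in range(n_lines):
        pos, amp = _detect_line(raster[line], params)
        unused = set(range(len(pos)))
        # order candidate matches by distance (greedy, smallest first)
        pairs = []
        for ti, tr in enumerate(active):
            for si in unused:
                gap = line - tr["lines"][-1]
                d = abs(pos[si] - tr["pos"][-1])
                if gap <= params.max_gap + 1 and d <= params.max_jump_px * gap:
                    pairs.append((d, ti, si))
        pairs.sort()
        matched_t, matched_s = set(), set()
        for d, ti, si in pairs:
            if ti in matched_t or si in matched_s:
                continue
            tr = active[ti]
            tr["lines"].append(line)
            tr["pos"].append(float(pos[si]))
            tr["amp"].append(float(amp[si]))
            matched_t.add(ti)
            matched_s.add(si)
        # close stale tracks
        still = []
        for ti, tr in enumerate(active):
            if ti in matched_t or line - tr["lines"][-1] <= params.max_gap:
                still.append(tr)
            else:
                done.append(tr)
        active = still
        # new tracks from unmatched spots
        for si in unused - matched_s:
            active.append({"lines": [line], "pos": [float(pos[si])],
                           "amp": [float(amp[si])]})
    done.extend(active)

    trajs: list[Trajectory] = []
    for tr in done:
        if len(tr["lines"]) < params.min_length:
            continue
        lines = np.asarray(tr["lines"], dtype=int)
        ppx = np.asarray(tr["pos"])
        trajs.append(
            Trajectory(
                channel=channel,
                lines=lines,
                positions_px=ppx,
                positions_bp=kymo.tether.px_to_bp(ppx),
                intensities=np.asarray(tr["amp"]),
                traj_id=len(trajs),
            )
        )
    return trajs


# ---------------------------------------------------------------------------
# classifications


def _robust_position_variance(positions_px: np.ndarray) -> float:
    """Squared scaled median absolute deviation of positions (px^2)."""
    med = np.median(positions_px)
    mad = np.median(np.abs(positions_px - med))
    return float((1.4826 * mad) ** 2)


def classify_mobility(
    traj: Trajectory,
    *,
    window_lines: int = 10,
    var_threshold_px2: float = 0.1,
    line_time_s: float = 0.1,
    bp_per_pixel: float = 250.0,
) -> MobilityCall:
    """Stable iff the positional variance is at or below the threshold.

    The variance is a robust (MAD-based) estimate, so that brief passages
    of a second molecule through the same pixel do not flip the call. The
    threshold should be calibrated to the localization noise of immobile
    emitters (see :func:`calibrate_variance_threshold`); trajectories
    shorter than ``window_lines`` are left unclassified.
    """
    var = _robust_position_variance(traj.positions_px)
    # MSD slope over unit line lag, in kb^2/s
    if traj.n_lines >= 2:
        d = np.diff(traj.positions_bp) / 1000.0
        dt = np.diff(traj.lines) * line_time_s
        msd_slope = float(np.mean(d**2 / dt))
    else:
        msd_slope = 0.0
    if traj.n_lines < window_lines:
        return MobilityCall("unclassified", var, msd_slope)
    label = "stable" if var <= var_threshold_px2 else "diffusive"
    return MobilityCall(label, var, msd_slope)


def calibrate_variance_threshold(
    localization_sigma_px: float = 0.15,
    n_lines: int = 50,
    n_sim: int = 2000,
    quantile: float = 0.99,
    seed: int = 12345,
) -> float:
    """Positional-variance threshold separating stable from diffusive.

    Simulates immobile emitters observed with Gaussian localization noise
    and returns the given quantile of their robust positional variance, so
    that an immobile molecule is called stable with probability
    ~``quantile``. The same robust statistic is used by
    :func:`classify_mobility`.
    """
    rng = np.random.default_rng(seed)
    sims = rng.normal(0, localization_sigma_px, size=(n_sim, n_lines))
    vs = np.array([_robust_position_variance(row) for row in sims])
    return float(np.quantile(vs, quantile))


def classify_position(
    traj: Trajectory, tether: TetherModel, tolerance_bp: float = 1000.0
) -> str:
    """ARS iff the trajectory median lies strictly inside the ARS interval
    expanded by ``tolerance_bp`` on each side; boundary counts as non-ARS."""
    lo, hi = tether.ars_interval
    m = traj.median_position_bp()
    return "ARS" if (lo - tolerance_bp) < m < (hi + tolerance_bp) else "non-ARS"


def call_colocalization(
    trajs_a: list[Trajectory],
    trajs_b: list[Trajectory],
    *,
    cutoff_bp: float = 500.0,
    min_overlap_lines: int = 10,
    one_to_one: bool = True,
) -> list[ColocalizationCall]:
    """Colocalization between two trajectory sets.

    For every temporally overlapping pair the mean separation over
    co-existing lines is computed; pairs are assigned greedily by smallest
    mean separation. A pair is colocalized iff mean separation <= cutoff
    and overlap >= ``min_overlap_lines``.

    With ``one_to_one=False`` each trajectory in ``trajs_a`` is paired with
    its nearest partner regardless of whether that partner is shared.  Use
    this for per-site occupancy questions ("does this nucleosome have a
    stable ORC nearby?"): when a trajectory fragments into two pieces,
    exclusive pairing lets one fragment consume the partner and miscounts
    the other as unbound.
    """
    cand = []
    for ia, a in enumerate(trajs_a):
        amap = dict(zip(a.lines.tolist(), a.positions_bp.tolist()))
        for ib, b in enumerate(trajs_b):
            common = [l for l in b.lines.tolist() if l in amap]
            if not common:
                continue
            bmap = dict(zip(b.lines.tolist(), b.positions_bp.tolist()))
            sep = float(np.mean([abs(amap[l] - bmap[l]) for l in common]))
            cand.append((sep, len(common), ia, ib))
    cand.sort()
    used_a, used_b = set(), set()
    calls = []
    # assign qualifying pairs first so a distant partner cannot consume a
    # trajectory whose true partner also qualifies
    for qualifying in (True, False):
        for sep, overlap, ia, ib in cand:
            ok = sep <= cutoff_bp and overlap >= min_overlap_lines
            if ok != qualifying or ia in used_a or \
                    (one_to_one and ib in used_b):
                continue
            used_a.add(ia)
            used_b.add(ib)
            calls.append(
                ColocalizationCall(
                    traj_ref_a=ia,
                    traj_ref_b=ib,
                    mean_separation_bp=sep,
                    overlap_lines=overlap,
                    colocalized=ok,
                )
            )
    return calls


def classify_salt_response(
    traj: Trajectory,
    wash_line: int,
    *,
    range_threshold_bp: float = 2000.0,
    survival_min_lines: int = 5,
) -> SaltResponseCall | None:
    """Classify a trajectory present at the wash line.

    dissociate: the trajectory ends within ``survival_min_lines`` after the
    wash; slide: post-wash positional range exceeds the threshold; stable:
    otherwise. Returns None for trajectories absent at the wash line.
    """
    if traj.start_line > wash_line or traj.end_line < wash_line:
        return None
    post = traj.positions_bp[traj.lines >= wash_line]
    rng_bp = float(post.max() - post.min()) if post.size else 0.0
    if traj.end_line <= wash_line + survival_min_lines:
        return SaltResponseCall("dissociate", rng_bp, survived=False)
    if rng_bp > range_threshold_bp:
        return SaltResponseCall("slide", rng_bp, survived=True)
    return SaltResponseCall("stable", rng_bp, survived=True)


def classify_arrival(
    traj: Trajectory,
    nucleosome_positions_bp: np.ndarray,
    *,
    approach_window_lines: int = 10,
    slide_min_bp: float = 1000.0,
) -> str:
    """Direct 3D capture vs. 1D sliding arrival at a nucleosome.

    sliding_1D iff the first ``approach_window_lines`` of the trajectory
    show a net displacement of at least ``slide_min_bp`` toward the final
    (nucleosome-colocalized) position; else direct_3D.
    """
    target = float(traj.positions_bp[-1])
    k = min(approach_window_lines, traj.n_lines)
    head = traj.positions_bp[:k]
    net_toward = abs(head[0] - target) - abs(head[-1] - target)
    if net_toward >= slide_min_bp:
        return "sliding_1D"
    return "direct_3D"


# ---------------------------------------------------------------------------
# replicate summaries


def summarize(
    labels: list[str],
    replicate_ids: list,
    compare: tuple[str, str] | None = None,
) -> FractionSummary:
    """Per-replicate fractions with mean +/- SD and an unpaired two-tailed
    Student's t-test (equal variances) between two label groups.

    ``labels`` and ``replicate_ids`` are parallel per-molecule records; the
    fraction of each label is computed within each replicate. If a compared
    label has fewer than two replicates the test is omitted with a warning.
    """
    if len(labels) != len(replicate_ids):
        raise ValueError("labels and replicate_ids must be parallel")
    df = pd.DataFrame({"label": labels, "rep": replicate_ids})
    groups = sorted(df["label"].unique())
    counts = df["label"].value_counts().to_dict()
    total = len(df)
    fractions = {g: counts.get(g, 0) / total for g in groups}
    rep_frac: dict[str, list[float]] = {g: [] for g in groups}
    for _, sub in df.groupby("rep"):
        n = len(sub)
        for g in groups:
            rep_frac[g].append((sub["label"] == g).sum() / n)
    mean = {g: float(np.mean(rep_frac[g])) for g in groups}
    sd = {g: float(np.std(rep_frac[g], ddof=1)) if len(rep_frac[g]) > 1
          else float("nan") for g in groups}
    summary = FractionSummary(
        groups=groups,
        counts={g: int(counts.get(g, 0)) for g in groups},
        fractions=fractions,
        replicate_fractions=rep_frac,
        mean=mean,
        sd=sd,
    )
    if compare is not None:
        a, b = compare
        xa, xb = rep_frac.get(a, []), rep_frac.get(b, [])
        if len(xa) < 2 or len(xb) < 2:
            summary.warnings.append(
                "t-test omitted: fewer than two replicates in a compared group"
            )
        else:
            t, p = stats.ttest_ind(xa, xb, equal_var=True)
            summary.t_statistic = float(t)
            summary.p_value = float(p)
    return summary
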