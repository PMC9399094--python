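"""Seeded generator of ground-truthed synthetic kymographs.

Emulates confocal line-scan recordings of a ~48-kb lambda-based DNA tether
(carrying an engineered ARS1 element) sparsely loaded with nucleosomes, with
ORC and MCM binding events, per-complex fluorescent labeling, photobleaching,
Poisson photon statistics, and an optional high-salt wash phase. Every
simulation returns machine-readable truth tables so downstream detection and
classification can be scored against ground truth.

Geometry defaults follow the experimental construct: a 47,822-bp tether with
the ARS1 element at 33,499-33,999 bp (1-based, inclusive) from the left end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

NUCLEOSOME_FOOTPRINT_BP = 147

__all__ = [
    "TetherModel",
    "NucleosomeSet",
    "BindingEvent",
    "PhotophysicsModel",
    "SaltWashPlan",
    "StoichModel",
    "ProteinConfig",
    "KymographStack",
    "PlacementError",
    "simulate_tether",
    "simulate_events",
    "simulate_bleach_traces",
    "apply_salt_wash",
    "render_kymograph",
    "simulate_licensing_experiment",
]


class PlacementError(ValueError):
    """Requested nucleosome placement is geometrically impossible."""


@dataclass(frozen=True)
class TetherModel:
    """Geometry and raster calibration of a tethered DNA molecule.

    Coordinates are 1-based inclusive base pairs from the left end.
    """

    length_bp: int = 47_822
    ars_interval: tuple[int, int] = (33_499, 33_999)
    bp_per_pixel: float = 250.0
    line_time_s: float = 0.1
    n_lines: int = 200

    def __post_init__(self) -> None:
        lo, hi = self.ars_interval
        if not (1 <= lo <= hi <= self.length_bp):
            raise ValueError("ars_interval must lie within [1, length_bp]")
        if self.bp_per_pixel <= 0 or self.line_time_s <= 0:
            raise ValueError("bp_per_pixel and line_time_s must be positive")
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")

    @property
    def width_px(self) -> int:
        return math.ceil(self.length_bp / self.bp_per_pixel)

    def bp_to_px(self, bp):
        """Map 1-based bp coordinates to (fractional) pixel coordinates."""
        return (np.asarray(bp, dtype=float) - 0.5) / self.bp_per_pixel

    def px_to_bp(self, px):
        return np.asarray(px, dtype=float) * self.bp_per_pixel + 0.5


@dataclass
class NucleosomeSet:
    """Dyad positions of deposited nucleosomes plus their dye state."""

    positions_bp: np.ndarray  # int, sorted dyad positions
    dye_channel: list[str]
    labeled: np.ndarray  # bool per nucleosome

    def __len__(self) -> int:
        return len(self.positions_bp)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dyad_bp": self.positions_bp,
                "channel": self.dye_channel,
                "labeled": self.labeled,
            }
        )


@dataclass
class BindingEvent:
    """One protein binding event and its per-line trajectory on the tether.

    ``positions_bp[i]`` is the molecule position at scan line
    ``start_line + i``; stable events hold a constant position, diffusive
    events perform a reflected Gaussian random walk.
    """

    species: str  # "ORC" | "MCM"
    site_class: str  # "nucleosome" | "ARS" | "bare"
    mode: str  # "stable" | "diffusive"
    anchor_bp: float
    start_line: int
    end_line: int  # inclusive
    positions_bp: np.ndarray
    diffusion_coeff_kb2_per_s: float = 0.0
    n_hexamers: int = 1
    # one entry per hexamer: (channel, labeled, bleach_line or None)
    dye_states: list = field(default_factory=list)
    salt_response: str | None = None  # "slide" | "stay" | "dissociate"
    nucleosome_index: int | None = None

    def __post_init__(self) -> None:
        if self.end_line < self.start_line:
            raise ValueError("end_line must be >= start_line")
        if self.mode == "stable" and self.diffusion_coeff_kb2_per_s != 0:
            raise ValueError("stable events carry zero diffusion coefficient")
        if self.mode == "diffusive" and self.diffusion_coeff_kb2_per_s <= 0:
            raise ValueError("diffusive events require positive diffusion coefficient")
        if self.n_hexamers == 2 and self.species != "MCM":
            raise ValueError("only MCM forms double hexamers")
        if len(self.positions_bp) != self.end_line - self.start_line + 1:
            raise ValueError("positions_bp length must match the line span")

    @property
    def n_lines(self) -> int:
        return self.end_line - self.start_line + 1


@dataclass(frozen=True)
class PhotophysicsModel:
    """Instrument model for the confocal line scans.

    The default bleach rate corresponds to a mean fluorophore lifetime of
    ~3,000 scan lines (minutes at a 0.1-s line time), consistent with dyes
    surviving multi-minute recordings in an oxygen-scavenged imaging
    buffer; photobleaching step-count assays (scavenger omitted) should
    pass a much higher rate explicitly.
    """

    photons_per_fluor_per_line: float = 150.0
    background_per_pixel: float = 20.0
    psf_sigma_px: float = 1.0
    bleach_rate_per_line: float = 3e-4

    def __post_init__(self) -> None:
        if min(self.photons_per_fluor_per_line, self.background_per_pixel,
               self.bleach_rate_per_line) < 0:
            raise ValueError("photophysics parameters must be nonnegative")
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be positive")


@dataclass(frozen=True)
class SaltWashPlan:
    """High-salt (0.5 M NaCl) challenge applied at a given scan line."""

    wash_line_index: int
    behavior_probs: tuple[float, float, float] = (0.3, 0.3, 0.4)  # slide, stay, dissociate
    post_wash_diffusion_coeff: float = 0.2  # kb^2/s
    salt_slide_passes_nucleosome: bool = True

    def __post_init__(self) -> None:
        p = self.behavior_probs
        if any(x < 0 or x > 1 for x in p):
            raise ValueError("behavior probabilities must lie in [0, 1]")
        if abs(sum(p) - 1.0) > 1e-9:
            raise ValueError("behavior probabilities must sum to 1")


@dataclass(frozen=True)
class StoichModel:
    """Binomial labeling mixture for MCM stoichiometry.

    f_dh: fraction of complexes that are double hexamers; p_label:
    per-hexamer probability of carrying a fluorophore (single dye site per
    hexamer via the tagged subunit).
    """

    f_dh: float = 0.79
    p_label: float = 0.60

    def __post_init__(self) -> None:
        if not (0 <= self.f_dh <= 1 and 0 <= self.p_label <= 1):
            raise ValueError("f_dh and p_label must lie in [0, 1]")


@dataclass(frozen=True)
class ProteinConfig:
    """Binding behaviour of ORC/MCM in the simulated experiment."""

    include_orc: bool = True
    include_mcm: bool = False
    cdc6_present: bool = True
    p_orc_nuc_bind: float = 0.95
    p_mcm_load_at_orc: float = 0.8
    ars_stable_dwell_s: float = 1e6  # effectively for the whole record
    bare_dwell_s: float = 5.0
    D_bare_kb2_per_s: float = 0.2
    n_diffusive_orc_mean: float = 2.0
    orc_label_efficiency: float = 1.0
    mcm_stoich: StoichModel = field(default_factory=StoichModel)
    orc_channel: str = "red"
    mcm_channel: str = "far_red"


@dataclass
class KymographStack:
    """Per-channel time x position photon-count rasters with calibration."""

    channels: dict[str, np.ndarray]  # each (n_lines, width_px) uint16
    tether: TetherModel
    wash_line_index: int | None = None
    events: pd.DataFrame | None = None  # truth table
    nucleosomes: pd.DataFrame | None = None  # truth table

    @property
    def n_lines(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def width_px(self) -> int:
        return next(iter(self.channels.values())).shape[1]


# ---------------------------------------------------------------------------
# tether + nucleosomes


def simulate_tether(
    *,
    tether: TetherModel | None = None,
    nucleosome_range: tuple[int, int] = (1, 7),
    label_efficiency: float = 0.7,
    nucleosome_channel: str = "green",
    min_spacing_bp: int = 2000,
    seed: int | np.random.Generator = 0,
) -> tuple[TetherModel, NucleosomeSet]:
    """Place nucleosomes on a tether, uniformly at random subject to a
    pairwise dyad exclusion, and draw per-nucleosome labeling flags.

    The default count range (1-7) and the default 2-kb minimum spacing
    reproduce the sparse Nap1-deposited chromatin of the experiments, in
    which essentially every nucleosome is flanked by substantial
    nucleosome-free DNA (the spacing can be lowered to the 147-bp footprint
    for dense deposition). Identical seeds give identical output.
    """
    rng = np.random.default_rng(seed)
    tether = tether or TetherModel()
    lo, hi = nucleosome_range
    spacing = max(int(min_spacing_bp), NUCLEOSOME_FOOTPRINT_BP)
    max_fit = tether.length_bp // spacing
    if lo < 0 or hi < lo:
        raise ValueError("invalid nucleosome_range")
    if hi > max_fit:
        raise PlacementError(
            f"cannot place {hi} nucleosomes with {spacing}-bp "
            f"exclusion on a {tether.length_bp}-bp tether"
        )
    n = int(rng.integers(lo, hi + 1))
    half = NUCLEOSOME_FOOTPRINT_BP // 2
    positions: list[int] = []
    attempts = 0
    while len(positions) < n:
        attempts += 1
        if attempts > 10_000 * max(n, 1):
            raise PlacementError("rejection sampling failed to place nucleosomes")
        cand = int(rng.integers(1 + half, tether.length_bp - half + 1))
        if all(abs(cand - p) >= spacing for p in positions):
            positions.append(cand)
    positions_arr = np.sort(np.asarray(positions, dtype=int))
    labeled = rng.random(n) < label_efficiency
    nucs = NucleosomeSet(
        positions_bp=positions_arr,
        dye_channel=[nucleosome_channel] * n,
        labeled=labeled,
    )
    return tether, nucs


# ---------------------------------------------------------------------------
# binding events


def _reflect(x: float, lo: float, hi: float) -> float:
    """Reflect a coordinate into [lo, hi] (billiard reflection)."""
    if hi <= lo:
        return lo
    span = hi - lo
    y = (x - lo) % (2 * span)
    if y < 0:
        y += 2 * span
    return lo + (span - abs(y - span))


def _diffuse(
    start_bp: float,
    n_steps: int,
    d_kb2_s: float,
    line_time_s: float,
    lo_bp: float,
    hi_bp: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Discrete-time Gaussian random walk with reflecting walls at lo/hi.

    Step SD = sqrt(2 * D * dt), D in kb^2/s converted to bp.
    """
    sd_bp = math.sqrt(2.0 * d_kb2_s * line_time_s) * 1000.0
    pos = np.empty(n_steps)
    x = _reflect(start_bp, lo_bp, hi_bp)
    steps = rng.normal(0.0, sd_bp, size=n_steps)
    pos[0] = x
    for i in range(1, n_steps):
        x = _reflect(x + steps[i], lo_bp, hi_bp)
        pos[i] = x
    return pos


def _confinement_bounds(
    anchor_bp: float, occupied_dyads: np.ndarray, tether: TetherModel
) -> tuple[float, float]:
    """Reflecting walls for a diffusing molecule: the nearest occupied
    nucleosome dyad +/- half footprint on either side, else the tether ends."""
    half = NUCLEOSOME_FOOTPRINT_BP / 2
    lo, hi = 1.0, float(tether.length_bp)
    left = occupied_dyads[occupied_dyads < anchor_bp]
    right = occupied_dyads[occupied_dyads > anchor_bp]
    if left.size:
        lo = float(left.max()) + half
    if right.size:
        hi = float(right.min()) - half
    if hi < lo:  # degenerate gap; pin at the midpoint
        lo = hi = (lo + hi) / 2
    return lo, hi


def _draw_dyes(
    n_hexamers: int,
    p_label: float,
    channel: str,
    bleach_rate: float,
    start_line: int,
    rng: np.random.Generator,
) -> list:
    dyes = []
    for _ in range(n_hexamers):
        labeled = bool(rng.random() < p_label)
        bleach_line = None
        if labeled and bleach_rate > 0:
            bleach_line = start_line + int(rng.exponential(1.0 / bleach_rate))
        dyes.append((channel, labeled, bleach_line))
    return dyes


def simulate_events(
    tether: TetherModel,
    nucleosomes: NucleosomeSet,
    config: ProteinConfig,
    duration_s: float,
    seed: int | np.random.Generator = 0,
    bleach_rate_per_line: float = 0.0,
) -> list[BindingEvent]:
    """Generate ORC (and optionally MCM) binding events.

    ORC binds each nucleosome stably with probability ``p_orc_nuc_bind``;
    with Cdc6 present it also binds the ARS element stably. Diffusive
    bare-DNA ORC excursions are confined between flanking ORC-occupied
    nucleosomes. MCM events appear only where an ORC event exists.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    n_lines = min(tether.n_lines, int(round(duration_s / tether.line_time_s)))
    events: list[BindingEvent] = []
    occupied_dyads: list[int] = []

    if config.include_orc:
        for idx, dyad in enumerate(nucleosomes.positions_bp):
            if rng.random() < config.p_orc_nuc_bind:
                start = int(rng.integers(0, max(1, n_lines // 10)))
                ev = BindingEvent(
                    species="ORC",
                    site_class="nucleosome",
                    mode="stable",
                    anchor_bp=float(dyad),
                    start_line=start,
                    end_line=n_lines - 1,
                    positions_bp=np.full(n_lines - start, float(dyad)),
                    dye_states=_draw_dyes(1, config.orc_label_efficiency,
                                          config.orc_channel,
                                          bleach_rate_per_line, start, rng),
                    nucleosome_index=idx,
                )
                events.append(ev)
                occupied_dyads.append(int(dyad))
        if config.cdc6_present:
            ars_mid = float(sum(tether.ars_interval)) / 2
            # only if the ARS is nucleosome-free
            half = NUCLEOSOME_FOOTPRINT_BP / 2
            if not any(abs(d - ars_mid) < half for d in nucleosomes.positions_bp):
                start = int(rng.integers(0, max(1, n_lines // 10)))
                events.append(
                    BindingEvent(
                        species="ORC",
                        site_class="ARS",
                        mode="stable",
                        anchor_bp=ars_mid,
                        start_line=start,
                        end_line=n_lines - 1,
                        positions_bp=np.full(n_lines - start, ars_mid),
                        dye_states=_draw_dyes(1, config.orc_label_efficiency,
                                              config.orc_channel,
                                              bleach_rate_per_line, start, rng),
                    )
                )
        occ = np.asarray(sorted(occupied_dyads), dtype=float)
        n_diff = rng.poisson(config.n_diffusive_orc_mean)
        for _ in range(n_diff):
            anchor = float(rng.uniform(1, tether.length_bp))
            start = int(rng.integers(0, n_lines))
            dwell_lines = max(1, int(rng.exponential(
                config.bare_dwell_s / tether.line_time_s)))
            end = min(n_lines - 1, start + dwell_lines - 1)
            lo, hi = _confinement_bounds(anchor, occ, tether)
            pos = _diffuse(anchor, end - start + 1, config.D_bare_kb2_per_s,
                           tether.line_time_s, lo, hi, rng)
            events.append(
                BindingEvent(
                    species="ORC",
                    site_class="bare",
                    mode="diffusive",
                    anchor_bp=anchor,
                    start_line=start,
                    end_line=end,
                    positions_bp=pos,
                    diffusion_coeff_kb2_per_s=config.D_bare_kb2_per_s,
                    dye_states=_draw_dyes(1, config.orc_label_efficiency,
                                          config.orc_channel,
                                          bleach_rate_per_line, start, rng),
                )
            )

    if config.include_mcm:
        # MCM loading is strictly ORC-dependent: one candidate per stable
        # ORC event, at the same position.
        for ev in [e for e in events if e.species == "ORC" and e.mode == "stable"]:
            if rng.random() >= config.p_mcm_load_at_orc:
                continue
            n_hex = 2 if rng.random() < config.mcm_stoich.f_dh else 1
            start = min(n_lines - 1, ev.start_line + int(rng.integers(0, 5)))
            events.append(
                BindingEvent(
                    species="MCM",
                    site_class=ev.site_class,
                    mode="stable",
                    anchor_bp=ev.anchor_bp,
                    start_line=start,
                    end_line=n_lines - 1,
                    positions_bp=np.full(n_lines - start, ev.anchor_bp),
                    n_hexamers=n_hex,
                    dye_states=_draw_dyes(n_hex, config.mcm_stoich.p_label,
                                          config.mcm_channel,
                                          bleach_rate_per_line, start, rng),
                    nucleosome_index=ev.nucleosome_index,
                )
            )
    return events


# ---------------------------------------------------------------------------
# photobleaching traces


def simulate_bleach_traces(
    model: StoichModel,
    photophysics: PhotophysicsModel,
    n: int,
    trace_len: int,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate background-corrupted intensity traces of n MCM complexes.

    Each complex carries 1 (monomer) or 2 (double hexamer) potential
    fluorophores; each is independently labeled with ``p_label`` and, if
    labeled, bleaches at an exponential time with rate
    ``bleach_rate_per_line``. Traces are Poisson photon counts of
    background + active-fluorophore signal. The truth table flags complexes
    with zero labels as invisible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    is_dh = rng.random(n) < model.f_dh
    n_potential = np.where(is_dh, 2, 1)
    labels = rng.random((n, 2)) < model.p_label
    labels[:, 1] &= is_dh  # monomers have a single dye site
    rate = photophysics.bleach_rate_per_line
    if rate > 0:
        bleach = rng.exponential(1.0 / rate, size=(n, 2))
    else:
        bleach = np.full((n, 2), np.inf)
    bleach[~labels] = -1.0  # unlabeled: never contributes

    t = np.arange(trace_len)[None, None, :]  # (1, 1, T)
    active = (bleach[:, :, None] > t) & labels[:, :, None]
    n_active = active.sum(axis=1)  # (n, T)
    lam = photophysics.background_per_pixel + \
        photophysics.photons_per_fluor_per_line * n_active
    traces = rng.poisson(lam).astype(float)

    n_labeled = labels.sum(axis=1)
    truth = pd.DataFrame(
        {
            "n_potential_fluors": n_potential,
            "n_labeled": n_labeled,
            "visible": n_labeled > 0,
            "is_dh": is_dh,
            "bleach_line_1": np.where(labels[:, 0], bleach[:, 0], np.nan),
            "bleach_line_2": np.where(labels[:, 1], bleach[:, 1], np.nan),
        }
    )
    return traces, truth


# ---------------------------------------------------------------------------
# salt wash


def apply_salt_wash(
    events: list[BindingEvent],
    plan: SaltWashPlan,
    tether: TetherModel,
    nucleosomes: NucleosomeSet | None = None,
    seed: int | np.random.Generator = 0,
) -> list[BindingEvent]:
    """Assign each MCM event surviving to the wash line a slide/stay/
    dissociate outcome and rewrite its post-wash trajectory accordingly.

    Returns a new event list; input events are not mutated.
    """
    rng = np.random.default_rng(seed)
    w = plan.wash_line_index
    out: list[BindingEvent] = []
    for ev in events:
        if ev.species != "MCM" or ev.end_line < w or ev.start_line > w:
            out.append(ev)
            continue
        draw = rng.choice(3, p=plan.behavior_probs)
        label = ("slide", "stay", "dissociate")[draw]
        pre = ev.positions_bp[: w - ev.start_line + 1].copy()
        if label == "dissociate":
            new = replace(
                ev,
                end_line=w,
                positions_bp=pre,
                salt_response=label,
            )
        elif label == "stay":
            new = replace(ev, salt_response=label)
        else:  # slide
            n_post = ev.end_line - w
            if plan.salt_slide_passes_nucleosome or nucleosomes is None or \
                    len(nucleosomes) == 0:
                lo, hi = 1.0, float(tether.length_bp)
            else:
                lo, hi = _confinement_bounds(
                    float(pre[-1]), nucleosomes.positions_bp.astype(float), tether
                )
            post = _diffuse(float(pre[-1]), n_post + 1,
                            plan.post_wash_diffusion_coeff,
                            tether.line_time_s, lo, hi, rng)[1:]
            new = replace(
                ev,
                mode="diffusive",
                diffusion_coeff_kb2_per_s=plan.post_wash_diffusion_coeff,
                positions_bp=np.concatenate([pre, post]),
                salt_response=label,
            )
        out.append(new)
    return out


# ---------------------------------------------------------------------------
# rendering


def _active_fluor_count(ev: BindingEvent, line: int) -> int:
    n = 0
    for _, labeled, bleach_line in ev.dye_states:
        if labeled and (bleach_line is None or line < bleach_line):
            n += 1
    return n


def render_kymograph(
    tether: TetherModel,
    events: list[BindingEvent],
    nucleosomes: NucleosomeSet,
    photophysics: PhotophysicsModel,
    seed: int | np.random.Generator = 0,
    channels: tuple[str, ...] = ("green", "red", "far_red"),
    wash_line_index: int | None = None,
) -> KymographStack:
    """Render per-channel photon-count rasters.

    Each labeled emitter contributes a Gaussian PSF profile with Poisson
    photon noise; background is Poisson everywhere; bleached fluorophores
    contribute nothing after their bleach line.
    """
    rng = np.random.default_rng(seed)
    n_lines, width = tether.n_lines, tether.width_px
    lam = {c: np.full((n_lines, width), photophysics.background_per_pixel)
           for c in channels}
    x = np.arange(width)
    sig = photophysics.psf_sigma_px
    amp0 = photophysics.photons_per_fluor_per_line

    def add_emitter(channel: str, line: int, pos_bp: float, n_fluor: int) -> None:
        if channel not in lam or n_fluor <= 0:
            return
        mu = tether.bp_to_px(pos_bp)
        lo = max(0, int(mu - 5 * sig))
        hi = min(width, int(mu + 5 * sig) + 1)
        if hi <= lo:
            return
        prof = np.exp(-0.5 * ((x[lo:hi] - mu) / sig) ** 2)
        lam[channel][line, lo:hi] += amp0 * n_fluor * prof

    # nucleosomes: stationary emitters for the whole record
    nuc_bleach = {}
    for i in range(len(nucleosomes)):
        if nucleosomes.labeled[i] and photophysics.bleach_rate_per_line > 0:
            nuc_bleach[i] = rng.exponential(
                1.0 / photophysics.bleach_rate_per_line)
        else:
            nuc_bleach[i] = np.inf
    for line in range(n_lines):
        for i in range(len(nucleosomes)):
            if nucleosomes.labeled[i] and line < nuc_bleach[i]:
                add_emitter(nucleosomes.dye_channel[i], line,
                            float(nucleosomes.positions_bp[i]), 1)
        for ev in events:
            if not (ev.start_line <= line <= ev.end_line):
                continue
            per_channel: dict[str, int] = {}
            for ch, labeled, bleach_line in ev.dye_states:
                if labeled and (bleach_line is None or line < bleach_line):
                    per_channel[ch] = per_channel.get(ch, 0) + 1
            for ch, nf in per_channel.items():
                add_emitter(ch, line, float(ev.positions_bp[line - ev.start_line]), nf)

    rasters = {c: rng.poisson(lam[c]).astype(np.uint16) for c in channels}
    return KymographStack(
        channels=rasters,
        tether=tether,
        wash_line_index=wash_line_index,
        events=events_to_frame(events, tether),
        nucleosomes=nucleosomes.to_frame(),
    )


def events_to_frame(events: list[BindingEvent], tether: TetherModel) -> pd.DataFrame:
    """Flatten events into a one-row-per-event truth table."""
    rows = []
    for k, ev in enumerate(events):
        rows.append(
            {
                "event_id": k,
                "species": ev.species,
                "site_class": ev.site_class,
                "mode": ev.mode,
                "anchor_bp": ev.anchor_bp,
                "start_line": ev.start_line,
                "end_line": ev.end_line,
                "n_hexamers": ev.n_hexamers,
                "n_labeled": sum(1 for _, lab, _ in ev.dye_states if lab),
                "diffusion_coeff_kb2_per_s": ev.diffusion_coeff_kb2_per_s,
                "salt_response": ev.salt_response,
                "nucleosome_index": ev.nucleosome_index,
            }
        )
    return pd.DataFrame(rows)


def simulate_licensing_experiment(
    *,
    tether: TetherModel | None = None,
    nucleosome_range: tuple[int, int] = (1, 7),
    nucleosome_label_efficiency: float = 0.7,
    config: ProteinConfig | None = None,
    photophysics: PhotophysicsModel | None = None,
    salt_plan: SaltWashPlan | None = None,
    seed: int = 0,
) -> tuple[KymographStack, list[BindingEvent], NucleosomeSet]:
    """One-call convenience: tether + nucleosomes + events (+ optional salt
    wash) rendered to a kymograph stack with truth tables attached."""
    rng = np.random.default_rng(seed)
    tether, nucs = simulate_tether(
        tether=tether,
        nucleosome_range=nucleosome_range,
        label_efficiency=nucleosome_label_efficiency,
        seed=rng,
    )
    config = config or ProteinConfig()
    photophysics = photophysics or PhotophysicsModel()
    duration = tether.n_lines * tether.line_time_s
    events = simulate_events(tether, nucs, config, duration, seed=rng)
    wash = None
    if salt_plan is not None:
        events = apply_salt_wash(events, salt_plan, tether, nucs, seed=rng)
        wash = salt_plan.wash_line_index
    stack = render_kymograph(tether, events, nucs, photophysics, seed=rng,
                             wash_line_index=wash)
    return stack, events, nucs
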