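"""Synthetic genomic fixtures and in-silico construction of the ARS1 tether.

Provides seeded generators for (i) i.i.d. background genomes, (ii) genomes
with planted PWM motif instances, (iii) phased nucleosome-occupancy tracks
with nucleosome-free regions (NFRs), and (iv) ChIP-like coverage with
near-duplicate peak clusters - each shipping a machine-readable truth table
so downstream recovery is scored without touching generator internals.

Also performs the double-digest-and-ligate assembly of the lambda-based
ARS1 tether: a 501-bp ARS1-containing fragment inserted into a 48,502-bp
vector between its unique XhoI (CTCGAG) and NheI (GCTAGC) sites, yielding a
47,822-bp product with the insert at 33,499-33,999 (1-based inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

XHOI_SITE = "CTCGAG"   # cuts C^TCGAG (1 nt into the site, 4-nt 5' overhang)
NHEI_SITE = "GCTAGC"   # cuts G^CTAGC
XHOI_CUT_OFFSET = 1
NHEI_CUT_OFFSET = 1

__all__ = [
    "SyntheticGenome",
    "OccupancyTrack",
    "CoverageTrack",
    "ConstructRecord",
    "RestrictionError",
    "sample_genome",
    "plant_motifs",
    "simulate_occupancy",
    "simulate_chip_coverage",
    "build_lambda_ars1",
    "make_synthetic_lambda_vector",
    "make_ars1_insert",
    "reverse_complement",
]


class RestrictionError(ValueError):
    """Zero or multiple recognition sites where exactly one is required."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SyntheticGenome:
    sequence: str
    background_freqs: tuple[float, float, float, float]  # A, C, G, T
    # truth_motifs rows: position (0-based start), strand, planted score
    truth_motifs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["start", "strand", "score"])
    )
    # truth_sites rows: position (0-based), strength
    truth_sites: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["position", "strength"])
    )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class OccupancyTrack:
    """Per-bp nucleosome occupancy (arbitrary MNase-like units)."""

    values: np.ndarray
    chromosome: str = "chrSim"
    start: int = 0  # 0-based offset of values[0]


@dataclass
class CoverageTrack:
    values: np.ndarray
    chromosome: str = "chrSim"
    start: int = 0


@dataclass
class ConstructRecord:
    final_sequence: str
    final_length_bp: int
    insert_interval: tuple[int, int]  # 1-based inclusive on the product
    excised_interval: tuple[int, int]  # 1-based inclusive on the vector
    enzyme_sites: dict[str, int]  # 1-based site starts on the vector


# ---------------------------------------------------------------------------
# background genome + motifs


def sample_genome(
    length: int,
    background_freqs: tuple[float, float, float, float] = (0.31, 0.19, 0.19, 0.31),
    seed: int | np.random.Generator = 0,
) -> SyntheticGenome:
    """i.i.d. random sequence with the given base composition (A, C, G, T).

    The default composition is AT-rich, like the yeast genome.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    f = np.asarray(background_freqs, dtype=float)
    if f.min() < 0 or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("background_freqs must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(4, size=length, p=f)
    seq = "".join(BASES[i] for i in idx)
    return SyntheticGenome(sequence=seq, background_freqs=tuple(f))


def plant_motifs(
    genome: SyntheticGenome,
    pwm,
    n_sites: int,
    min_score: float,
    seed: int | np.random.Generator = 0,
    max_attempts: int = 100_000,
) -> SyntheticGenome:
    """Plant PWM-drawn motif instances scoring above ``min_score``.

    Instances are sampled from the PWM probabilities by rejection until the
    recomputed score exceeds ``min_score``, then written at random
    non-overlapping positions on random strands. The genome's truth table
    is extended; the input genome is not mutated.
    """
    from .motif_peak import score_window  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    if n_sites == 0:
        return SyntheticGenome(genome.sequence, genome.background_freqs,
                               genome.truth_motifs.copy(),
                               genome.truth_sites.copy())
    w = pwm.width
    seq = list(genome.sequence)
    taken: list[tuple[int, int]] = [
        (int(r.start), int(r.start) + w) for r in genome.truth_motifs.itertuples()
    ]
    rows = []
    for _ in range(n_sites):
        # draw an instance above min_score
        inst = None
        for _ in range(max_attempts):
            draw = "".join(
                BASES[rng.choice(4, p=pwm.probs[j])] for j in range(w)
            )
            s = score_window(draw, pwm)
            if s > min_score:
                inst, score = draw, s
                break
        if inst is None:
            raise ValueError(
                f"could not draw an instance above score {min_score}; "
                "the cutoff may exceed the PWM maximum"
            )
        # place without overlap
        pos = None
        for _ in range(max_attempts):
            cand = int(rng.integers(0, len(seq) - w + 1))
            if all(cand + w <= a or cand >= b for a, b in taken):
                pos = cand
                break
        if pos is None:
            raise ValueError("could not place motif without overlap")
        strand = "+" if rng.random() < 0.5 else "-"
        written = inst if strand == "+" else reverse_complement(inst)
        seq[pos:pos + w] = list(written)
        taken.append((pos, pos + w))
        rows.append({"start": pos, "strand": strand, "score": score})
    new_rows = pd.DataFrame(rows)
    if genome.truth_motifs.empty:
        truth = new_rows
    else:
        truth = pd.concat([genome.truth_motifs, new_rows], ignore_index=True)
    truth = truth.sort_values("start", ignore_index=True)
    return SyntheticGenome("".join(seq), genome.background_freqs, truth,
                           genome.truth_sites.copy())


# ---------------------------------------------------------------------------
# occupancy and coverage


def simulate_occupancy(
    genome_length: int,
    nfr_centers: list[int],
    *,
    nfr_width: float = 150.0,
    nucleosome_spacing: float = 165.0,
    peak_sigma: float = 40.0,
    depth: float = 100.0,
    nfr_depletion: float = 0.9,
    seed: int | np.random.Generator = 0,
    chromosome: str = "chrSim",
) -> OccupancyTrack:
    """Phased-nucleosome occupancy with multiplicative NFR depletion wells.

    Baseline: Gaussian bumps of SD ``peak_sigma`` every
    ``nucleosome_spacing`` bp. Each NFR center applies a smooth
    (Gaussian-shaped, SD = nfr_width/2) multiplicative depletion of maximal
    depth ``nfr_depletion`` (0.9 -> occupancy drops to 10% at the center).
    The track is Poisson-sampled at mean ``depth`` per bump apex.
    """
    for c in nfr_centers:
        if not (0 <= c < genome_length):
            raise ValueError("NFR center outside the genome")
    rng = np.random.default_rng(seed)
    x = np.arange(genome_length, dtype=float)
    base = np.zeros(genome_length)
    centers = np.arange(nucleosome_spacing / 2, genome_length,
                        nucleosome_spacing)
    for c in centers:
        lo = max(0, int(c - 5 * peak_sigma))
        hi = min(genome_length, int(c + 5 * peak_sigma) + 1)
        base[lo:hi] += np.exp(-0.5 * ((x[lo:hi] - c) / peak_sigma) ** 2)
    depl = np.ones(genome_length)
    sig = nfr_width / 2.0
    for c in nfr_centers:
        lo = max(0, int(c - 6 * sig))
        hi = min(genome_length, int(c + 6 * sig) + 1)
        depl[lo:hi] *= 1.0 - nfr_depletion * np.exp(
            -0.5 * ((x[lo:hi] - c) / sig) ** 2)
    lam = depth * base * depl
    vals = rng.poisson(lam).astype(float)
    return OccupancyTrack(values=vals, chromosome=chromosome)


def simulate_chip_coverage(
    genome_length: int,
    truth_sites: pd.DataFrame,
    *,
    fragment_sd: float = 100.0,
    strength_scale: float = 1.0,
    noise_rate: float = 1.0,
    cluster_prob: float = 0.3,
    satellite_area_frac: float = 0.4,
    seed: int | np.random.Generator = 0,
    chromosome: str = "chrSim",
) -> tuple[CoverageTrack, pd.DataFrame]:
    """ChIP-like coverage: a Gaussian mound per binding site plus noise.

    Each site of strength s contributes a mound of area
    s * strength_scale (SD = ``fragment_sd``). With probability
    ``cluster_prob`` a satellite mound of ``satellite_area_frac`` the area
    is added 100-400 bp away, to exercise peak-cluster collapse. Uniform
    Poisson noise of mean ``noise_rate`` is added everywhere. Returns the
    track and a truth-peak table (position, strength, has_satellite).
    """
    rng = np.random.default_rng(seed)
    x = np.arange(genome_length, dtype=float)
    lam = np.full(genome_length, float(noise_rate))

    def add_mound(center: float, area: float) -> None:
        lo = max(0, int(center - 5 * fragment_sd))
        hi = min(genome_length, int(center + 5 * fragment_sd) + 1)
        dens = np.exp(-0.5 * ((x[lo:hi] - center) / fragment_sd) ** 2)
        lam[lo:hi] += area * dens / (fragment_sd * np.sqrt(2 * np.pi))

    rows = []
    for r in truth_sites.itertuples():
        pos, strength = float(r.position), float(r.strength)
        add_mound(pos, strength * strength_scale)
        sat = bool(rng.random() < cluster_prob)
        if sat:
            off = rng.integers(100, 401) * (1 if rng.random() < 0.5 else -1)
            add_mound(pos + off, satellite_area_frac * strength * strength_scale)
        rows.append({"position": int(pos), "strength": strength,
                     "has_satellite": sat})
    vals = rng.poisson(lam).astype(float)
    return (CoverageTrack(values=vals, chromosome=chromosome),
            pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# in-silico cloning


def _unique_site(seq: str, site: str, enzyme: str) -> int:
    """0-based start of the single occurrence of ``site``; error otherwise."""
    first = seq.find(site)
    if first == -1:
        raise RestrictionError(f"no {enzyme} site ({site}) in sequence")
    if seq.find(site, first + 1) != -1:
        raise RestrictionError(f"multiple {enzyme} sites ({site}) in sequence")
    return first


def build_lambda_ars1(vector_seq: str, insert_seq: str) -> ConstructRecord:
    """Double digest (XhoI + NheI) and ligate an insert into a vector.

    The vector must carry exactly one XhoI (CTCGAG) and one NheI (GCTAGC)
    site, XhoI leftmost. Top-strand cut positions are one base into each
    recognition site (C^TCGAG, G^CTAGC); the sticky-end overhangs are
    regenerated by the ligated insert, so overhang bases are counted once.
    The insert is given as it appears on the final product between the two
    cut points: it must begin with TCGAG (regenerating CTCGAG with the
    vector's left C) and end with G (regenerating GCTAGC with the vector's
    right CTAGC). An empty insert models pure excision religation.
    """
    vector_seq = vector_seq.upper()
    insert_seq = insert_seq.upper()
    xho = _unique_site(vector_seq, XHOI_SITE, "XhoI")
    nhe = _unique_site(vector_seq, NHEI_SITE, "NheI")
    if nhe <= xho:
        raise RestrictionError("NheI site must lie right of the XhoI site")
    if insert_seq and not insert_seq.startswith("TCGAG"):
        raise RestrictionError("insert must start with TCGAG (XhoI-compatible)")
    if insert_seq and not insert_seq.endswith("G"):
        raise RestrictionError("insert must end with G (NheI-compatible)")
    cut_left = xho + XHOI_CUT_OFFSET   # bases retained on the left arm
    cut_right = nhe + NHEI_CUT_OFFSET  # 0-based start of the right arm
    left = vector_seq[:cut_left]
    right = vector_seq[cut_right:]
    product = left + insert_seq + right
    insert_interval = (cut_left + 1, cut_left + len(insert_seq)) if insert_seq \
        else (cut_left, cut_left)
    return ConstructRecord(
        final_sequence=product,
        final_length_bp=len(product),
        insert_interval=insert_interval,
        excised_interval=(cut_left + 1, cut_right),
        enzyme_sites={"XhoI": xho + 1, "NheI": nhe + 1},
    )


def _scrub_sites(seq: list[str], sites: tuple[str, ...],
                 rng: np.random.Generator,
                 keep: tuple[tuple[int, int], ...] = ()) -> None:
    """Mutate single bases until no listed site occurs outside ``keep``."""
    s = "".join(seq)
    changed = True
    while changed:
        changed = False
        s = "".join(seq)
        for site in sites:
            start = 0
            while True:
                i = s.find(site, start)
                if i == -1:
                    break
                if any(a <= i < b for a, b in keep):
                    start = i + 1
                    continue
                j = i + int(rng.integers(0, len(site)))
                old = seq[j]
                choices = [b for b in BASES if b != old]
                seq[j] = choices[int(rng.integers(0, 3))]
                changed = True
                start = i + 1


def make_synthetic_lambda_vector(seed: int = 0) -> str:
    """SYNTHETIC stand-in for the 48,502-bp phage lambda genome.

    A random sequence (lambda-like base composition) carrying exactly one
    XhoI site and one NheI site at positions chosen so that the standard
    cut-offset accounting reproduces the published construct geometry:
    a 33,498-bp left arm, a 1,181-bp excised fragment, and a 13,823-bp
    right arm. This is not the real lambda sequence - only its restriction
    geometry is reproduced.
    """
    rng = np.random.default_rng(seed)
    n = 48_502
    idx = rng.choice(4, size=n, p=[0.25, 0.25, 0.25, 0.25])
    seq = [BASES[i] for i in idx]
    # 1-based site starts 33,498 (XhoI) and 34,679 (NheI):
    # left arm = 33,497 + 1 = 33,498 bp; right arm = 48,502 - 34,679 = 13,823 bp
    xho0, nhe0 = 33_498 - 1, 34_679 - 1
    seq[xho0:xho0 + 6] = list(XHOI_SITE)
    seq[nhe0:nhe0 + 6] = list(NHEI_SITE)
    _scrub_sites(seq, (XHOI_SITE, NHEI_SITE), rng,
                 keep=((xho0, xho0 + 6), (nhe0, nhe0 + 6)))
    return "".join(seq)


def make_ars1_insert(pwm=None, seed: int = 1) -> str:
    """SYNTHETIC 501-bp ARS1-like insert, XhoI/NheI-end compatible.

    Starts with TCGAG and ends with G; if a PWM is given, a high-scoring
    ACS-like motif instance is planted near the insert center.
    """
    rng = np.random.default_rng(seed)
    n = 501
    idx = rng.choice(4, size=n, p=[0.31, 0.19, 0.19, 0.31])
    seq = [BASES[i] for i in idx]
    seq[:5] = list("TCGAG")
    seq[-1] = "G"
    if pwm is not None:
        from .motif_peak import score_window

        best, best_s = None, -np.inf
        for _ in range(500):
            draw = "".join(BASES[rng.choice(4, p=pwm.probs[j])]
                           for j in range(pwm.width))
            s = score_window(draw, pwm)
            if s > best_s:
                best, best_s = draw, s
        mid = n // 2 - pwm.width // 2
        seq[mid:mid + pwm.width] = list(best)
    _scrub_sites(seq, (XHOI_SITE, NHEI_SITE), rng)
    seq[:5] = list("TCGAG")  # scrubbing never touches these in practice
    seq[-1] = "G"
    return "".join(seq)
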