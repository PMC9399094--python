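"""File I/O: kymograph TIFF stacks with YAML calibration sidecars, TSV truth
tables and trajectories, FASTA, BED (0-based half-open) and bedGraph."""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import tifffile
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome_synth import CoverageTrack, OccupancyTrack
from .kymo_sim import KymographStack, TetherModel
from .trace_pipeline import Trajectory

__all__ = [
    "write_kymograph",
    "read_kymograph",
    "write_fasta",
    "read_fasta",
    "write_bed",
    "read_bed",
    "write_bedgraph",
    "read_bedgraph",
    "write_trajectories",
    "read_trajectories",
]


def write_kymograph(stack: KymographStack, out_dir: str, prefix: str = "kymo") -> None:
    """Write one multi-page TIFF (a page per channel), a YAML calibration
    sidecar, and TSV truth tables if present."""
    os.makedirs(out_dir, exist_ok=True)
    names = sorted(stack.channels)
    pages = np.stack([stack.channels[c] for c in names])
    tifffile.imwrite(os.path.join(out_dir, f"{prefix}.tif"), pages,
                     photometric="minisblack")
    t = stack.tether
    calib = {
        "channels": names,
        "length_bp": t.length_bp,
        "ars_interval": list(t.ars_interval),
        "bp_per_pixel": t.bp_per_pixel,
        "line_time_s": t.line_time_s,
        "n_lines": t.n_lines,
        "wash_line_index": stack.wash_line_index,
    }
    with open(os.path.join(out_dir, f"{prefix}.yaml"), "w") as fh:
        yaml.safe_dump(calib, fh)
    if stack.events is not None:
        stack.events.to_csv(os.path.join(out_dir, f"{prefix}_events.tsv"),
                            sep="\t", index=False)
    if stack.nucleosomes is not None:
        stack.nucleosomes.to_csv(
            os.path.join(out_dir, f"{prefix}_nucleosomes.tsv"),
            sep="\t", index=False)


def read_kymograph(out_dir: str, prefix: str = "kymo") -> KymographStack:
    pages = tifffile.imread(os.path.join(out_dir, f"{prefix}.tif"))
    with open(os.path.join(out_dir, f"{prefix}.yaml")) as fh:
        calib = yaml.safe_load(fh)
    if pages.ndim == 2:
        pages = pages[None]
    tether = TetherModel(
        length_bp=calib["length_bp"],
        ars_interval=tuple(calib["ars_interval"]),
        bp_per_pixel=calib["bp_per_pixel"],
        line_time_s=calib["line_time_s"],
        n_lines=calib["n_lines"],
    )
    channels = {c: pages[i] for i, c in enumerate(calib["channels"])}
    stack = KymographStack(channels=channels, tether=tether,
                           wash_line_index=calib.get("wash_line_index"))
    ev_path = os.path.join(out_dir, f"{prefix}_events.tsv")
    if os.path.exists(ev_path):
        ev = pd.read_csv(ev_path, sep="\t")
        if "salt_response" in ev.columns:
            # all-missing string columns parse as float; restore None
            col = ev["salt_response"].astype(object)
            ev["salt_response"] = col.where(col.notna(), None)
        stack.events = ev
    nuc_path = os.path.join(out_dir, f"{prefix}_nucleosomes.tsv")
    if os.path.exists(nuc_path):
        stack.nucleosomes = pd.read_csv(nuc_path, sep="\t")
    return stack


def write_fasta(path: str, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_bed(path: str, intervals: pd.DataFrame) -> None:
    """BED output, 0-based half-open; expects columns chrom, start, end and
    optionally name, score, strand."""
    cols = [c for c in ("chrom", "start", "end", "name", "score", "strand")
            if c in intervals.columns]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


def write_bedgraph(path: str, track: OccupancyTrack | CoverageTrack) -> None:
    vals = track.values
    # run-length encode constant stretches
    change = np.nonzero(np.diff(vals))[0] + 1
    bounds = np.concatenate([[0], change, [len(vals)]])
    with open(path, "w") as fh:
        for a, b in zip(bounds[:-1], bounds[1:]):
            fh.write(f"{track.chromosome}\t{a + track.start}\t{b + track.start}"
                     f"\t{vals[a]:g}\n")


def read_bedgraph(path: str) -> OccupancyTrack:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"])
    start = int(df["start"].min())
    n = int(df["end"].max()) - start
    vals = np.zeros(n)
    for r in df.itertuples():
        vals[r.start - start: r.end - start] = r.value
    return OccupancyTrack(values=vals, chromosome=str(df["chrom"].iloc[0]),
                          start=start)


def write_trajectories(path: str, trajs: list[Trajectory]) -> None:
    rows = []
    for tr in trajs:
        for i in range(tr.n_lines):
            rows.append(
                {
                    "traj_id": tr.traj_id,
                    "channel": tr.channel,
                    "line": int(tr.lines[i]),
                    "position_px": tr.positions_px[i],
                    "position_bp": tr.positions_bp[i],
                    "intensity": tr.intensities[i],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_trajectories(path: str) -> list[Trajectory]:
    df = pd.read_csv(path, sep="\t")
    trajs = []
    for tid, sub in df.groupby("traj_id"):
        sub = sub.sort_values("line")
        trajs.append(
            Trajectory(
                channel=str(sub["channel"].iloc[0]),
                lines=sub["line"].to_numpy(int),
                positions_px=sub["position_px"].to_numpy(float),
                positions_bp=sub["position_bp"].to_numpy(float),
                intensities=sub["intensity"].to_numpy(float),
                traj_id=int(tid),
            )
        )
    return trajs
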