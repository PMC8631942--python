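"""File I/O for the standard text and TIFF interchange formats."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO

from .hmm import StateSequence, Trajectory
from .localize import SpotTable
from .spr import Isotherm


# -- isotherms: analyte,ligand,concentration_nM,response_RU -----------------

def write_isotherm_csv(iso: Isotherm, path) -> None:
    pd.DataFrame({
        "analyte": iso.analyte_id,
        "ligand": iso.ligand_id,
        "concentration_nM": iso.concentrations_nM,
        "response_RU": iso.responses,
    }).to_csv(path, index=False)


def read_isotherm_csv(path) -> list[Isotherm]:
    """One Isotherm per (analyte, ligand) group in the file."""
    df = pd.read_csv(path)
    out = []
    for (analyte, ligand), grp in df.groupby(["analyte", "ligand"], sort=False):
        out.append(Isotherm(
            analyte_id=str(analyte), ligand_id=str(ligand),
            concentrations_nM=grp["concentration_nM"].to_numpy(float),
            responses=grp["response_RU"].to_numpy(float),
        ))
    return out


# -- trajectories: molecule_id,time_s,intensity -----------------------------

def write_trajectory_csv(trajs: Iterable[Trajectory], path,
                         states: dict[str, StateSequence] | None = None) -> None:
    frames = []
    for traj in trajs:
        df = pd.DataFrame({
            "molecule_id": traj.molecule_id,
            "time_s": traj.times_s,
            "intensity": traj.intensities,
        })
        if states and traj.molecule_id in states:
            df["state"] = states[traj.molecule_id].states
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectory_csv(path) -> list[Trajectory]:
    df = pd.read_csv(path)
    out = []
    for mol, grp in df.groupby("molecule_id", sort=False):
        times = grp["time_s"].to_numpy(float)
        dt = float(np.median(np.diff(times))) if times.size > 1 else 0.05
        out.append(Trajectory(intensities=grp["intensity"].to_numpy(float),
                              frame_interval=dt, molecule_id=str(mol)))
    return out


# -- spot tables ------------------------------------------------------------

def write_spot_csv(table: SpotTable, path) -> None:
    table.to_dataframe().to_csv(path, index=False)


def read_spot_csv(path, frame_rate: float = 20.0) -> SpotTable:
    return SpotTable.from_dataframe(pd.read_csv(path), frame_rate=frame_rate)


# -- image stacks -----------------------------------------------------------

def write_tiff(stack: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32),
                     photometric="minisblack")


def read_tiff(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)


# -- sequences --------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """FASTA records as {id: sequence}."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(Path(path)), "fasta")}
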