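"""Reading and writing the plain-text formats the analysis consumes.

Free-energy profiles and reaction networks travel as YAML config documents;
trajectories as tidy CSV; TCSPC traces as two-column TSV with a ``#``-header
block; sequences as FASTA (U = selenocysteine, via Biopython); spectra as
two-column m/z-intensity text or mzML (read-only, via pyteomics).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .kinetics import ConcentrationTrajectory
from .network import ReactionNetwork, stoichiometry_tsv
from .photophysics import DecayTrace
from .thermo import FreeEnergyProfile

__all__ = [
    "load_profile",
    "save_profile",
    "load_network",
    "save_network",
    "save_stoichiometry_tsv",
    "save_trajectory_csv",
    "load_decay_trace",
    "save_decay_trace",
    "read_fasta_sequences",
    "read_spectrum_text",
    "read_spectrum_mzml",
]


def load_profile(path) -> FreeEnergyProfile:
    return FreeEnergyProfile.from_yaml(Path(path).read_text())


def save_profile(profile: FreeEnergyProfile, path) -> None:
    Path(path).write_text(profile.to_yaml())


def load_network(path) -> ReactionNetwork:
    return ReactionNetwork.from_yaml(Path(path).read_text())


def save_network(network: ReactionNetwork, path) -> None:
    Path(path).write_text(network.to_yaml())


def save_stoichiometry_tsv(network: ReactionNetwork, path) -> None:
    Path(path).write_text(stoichiometry_tsv(network))


def save_trajectory_csv(trajectory: ConcentrationTrajectory, path) -> None:
    trajectory.to_frame().to_csv(path, index=False)


def save_decay_trace(trace: DecayTrace, path) -> None:
    lines = [
        f"# excitation_wavelength_nm: {trace.excitation_wavelength}",
        f"# emission_wavelength_nm: {trace.emission_wavelength}",
        f"# quencher_concentration_M: {trace.quencher_concentration}",
        f"# bin_width_ns: {trace.bin_edges[1] - trace.bin_edges[0]}",
        "bin_center_ns\tcounts",
    ]
    for c, n in zip(trace.bin_centers, trace.counts):
        lines.append(f"{c:.6g}\t{int(n)}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_decay_trace(path) -> DecayTrace:
    header: dict = {}
    centers, counts = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            header[key.strip()] = float(value)
        elif line[0].isdigit() or line[0] in "+-.":
            a, b = line.split("\t")
            centers.append(float(a))
            counts.append(int(b))
    centers = np.asarray(centers)
    width = header.get("bin_width_ns", float(np.median(np.diff(centers))))
    edges = np.concatenate([centers - width / 2, [centers[-1] + width / 2]])
    return DecayTrace(
        bin_edges=edges,
        counts=np.asarray(counts, dtype=int),
        excitation_wavelength=header.get("excitation_wavelength_nm", 415.0),
        emission_wavelength=header.get("emission_wavelength_nm", 470.0),
        quencher_concentration=header.get("quencher_concentration_M", 0.0),
    )


def read_fasta_sequences(path) -> dict:
    """FASTA records as {id: sequence}; U (selenocysteine) passes through."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_spectrum_text(path) -> pd.DataFrame:
    """Two-column (m/z, intensity) text spectrum; ``#`` lines are comments."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#",
                     names=["mz", "intensity"], header=None)
    return df.astype(float).sort_values("mz").reset_index(drop=True)


def read_spectrum_mzml(path, scan_index: int = 0) -> pd.DataFrame:
    """Centroid arrays of one spectrum from an mzML file (read-only)."""
    from pyteomics import mzml

    with mzml.read(str(path)) as reader:
        for i, spec in enumerate(reader):
            if i == scan_index:
                return pd.DataFrame(
                    {"mz": spec["m/z array"], "intensity": spec["intensity array"]}
                )
    raise IndexError(f"no spectrum with index {scan_index} in {path}")
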