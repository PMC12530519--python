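"""Delimited-table and FASTA input/output for the pipeline's data types.

All tables are plain tab-separated text with header rows:

* chromatograms: ``time_min, dRI, molar_mass_Da`` (mass empty where masked);
* AUC profiles:  ``radius_cm, signal, speed_rpm, detector, cell_id,
  loading_uM`` (long format, one row per observation);
* plate counts:  one row per replicate per condition with columns
  ``condition, his_count, his_dilution, his_volume_ml, viable_count,
  viable_dilution, viable_volume_ml``;
* exchange pair manifests: one row per mixture experiment pointing at the
  chromatogram files of the mixture and components.

Sequence families are FASTA (Biopython); coordinates are minimal PDB files
handled in :mod:`dimerswap.structcomp`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from dimerswap.exchange import Chromatogram, PairRecord
from dimerswap.mobility import MobilityExperiment
from dimerswap.sedeq import EquilibriumProfile
from dimerswap.seqcons import ProteinAlignment


def write_chromatogram(chrom: Chromatogram, path: str | Path) -> None:
    mass = (
        chrom.molar_mass
        if chrom.molar_mass is not None
        else np.full_like(chrom.time, np.nan)
    )
    pd.DataFrame(
        {"time_min": chrom.time, "dRI": chrom.signal, "molar_mass_Da": mass}
    ).to_csv(path, sep="\t", index=False, na_rep="")


def read_chromatogram(path: str | Path, label: str = "") -> Chromatogram:
    df = pd.read_csv(path, sep="\t")
    mass = None
    if "molar_mass_Da" in df.columns and not df["molar_mass_Da"].isna().all():
        mass = df["molar_mass_Da"].to_numpy(dtype=float)
    return Chromatogram(
        time=df["time_min"].to_numpy(dtype=float),
        signal=df["dRI"].to_numpy(dtype=float),
        molar_mass=mass,
        label=label or Path(path).stem,
    )


def write_auc_profiles(
    profiles: Sequence[EquilibriumProfile], path: str | Path
) -> None:
    frames = [
        pd.DataFrame(
            {
                "radius_cm": p.radius,
                "signal": p.signal,
                "speed_rpm": p.speed,
                "detector": p.detector,
                "cell_id": p.cell_id,
                "loading_uM": p.loading_uM if p.loading_uM is not None else np.nan,
            }
        )
        for p in profiles
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_auc_profiles(path: str | Path) -> list[EquilibriumProfile]:
    df = pd.read_csv(path, sep="\t")
    profiles = []
    for (cell, speed, det), group in df.groupby(
        ["cell_id", "speed_rpm", "detector"], sort=True
    ):
        group = group.sort_values("radius_cm")
        loading = group["loading_uM"].iloc[0]
        profiles.append(
            EquilibriumProfile(
                radius=group["radius_cm"].to_numpy(dtype=float),
                signal=group["signal"].to_numpy(dtype=float),
                speed=float(speed),
                detector=str(det),
                cell_id=str(cell),
                loading_uM=None if pd.isna(loading) else float(loading),
            )
        )
    return profiles


def read_counts_table(path: str | Path) -> dict[str, MobilityExperiment]:
    """Read a plate-count table into one MobilityExperiment per condition."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for condition, group in df.groupby("condition", sort=False):
        out[str(condition)] = MobilityExperiment(
            his_counts=group["his_count"].to_numpy(),
            viable_counts=group["viable_count"].to_numpy(),
            his_dilution=group["his_dilution"].to_numpy(dtype=float),
            viable_dilution=group["viable_dilution"].to_numpy(dtype=float),
            his_volume=group["his_volume_ml"].to_numpy(dtype=float),
            viable_volume=group["viable_volume_ml"].to_numpy(dtype=float),
            label=str(condition),
        )
    return out


def read_pair_manifest(path: str | Path) -> list[PairRecord]:
    """Read an exchange pair manifest; chromatogram paths are relative to it.

    Columns: ``mix_file, comp_a_file, comp_b_file, ca_label, rf_label`` and
    optionally ``dimer1_motif_a, dimer1_motif_b, is_background``.
    """
    base = Path(path).parent
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        records.append(
            PairRecord(
                mix=read_chromatogram(base / row["mix_file"]),
                comp_a=read_chromatogram(base / row["comp_a_file"]),
                comp_b=read_chromatogram(base / row["comp_b_file"]),
                ca_label=str(row["ca_label"]),
                rf_label=str(row["rf_label"]),
                dimer1_motif_a=row.get("dimer1_motif_a"),
                dimer1_motif_b=row.get("dimer1_motif_b"),
                is_background=(
                    bool(row["is_background"]) if "is_background" in row else None
                ),
            )
        )
    return records


def write_fasta(
    sequences: Sequence[str], path: str | Path, labels: Sequence[str] | None = None
) -> None:
    labels = labels or [f"seq{i + 1}" for i in range(len(sequences))]
    records = [
        SeqRecord(Seq(s), id=lab, description="")
        for s, lab in zip(sequences, labels)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> tuple[list[str], list[str]]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return [str(r.seq) for r in records], [r.id for r in records]


def read_alignment(path: str | Path, offset: int = 0) -> ProteinAlignment:
    seqs, labels = read_fasta(path)
    return ProteinAlignment(sequences=seqs, labels=labels, offset=offset)
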