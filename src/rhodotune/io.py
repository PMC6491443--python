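"""Readers and writers for the package's tabular formats.

All formats are plain text: two-column CSV for spectra and pH traces, a
matrix CSV for transient absorption (first row wavelengths, first column
times), TSV for point-charge environments, chromophore state charges and
geometry reports. Everything round-trips losslessly at float precision.
"""

from __future__ import annotations

from typing import IO, Mapping, Union

import numpy as np
import pandas as pd

from .assays import AbsorptionSpectrum, PhTrace
from .electrostatics import ChromophoreChargeModel, PointChargeEnvironment, Site
from .kinetics import TransientAbsorptionData
from .spectral import SpectralBand

PathOrBuf = Union[str, IO]

__all__ = [
    "read_band_table",
    "write_spectrum",
    "read_spectrum",
    "write_ph_trace",
    "read_ph_trace",
    "write_ta_matrix",
    "read_ta_matrix",
    "write_charge_env",
    "read_charge_env",
    "write_chromophore_charges",
    "read_chromophore_charges",
    "write_geometry_report",
]


def read_band_table(source: PathOrBuf) -> list[SpectralBand]:
    """CSV with columns ``label,lambda_max_nm`` -> list of bands."""
    df = pd.read_csv(source)
    return [
        SpectralBand(str(row["label"]), float(row["lambda_max_nm"]))
        for _, row in df.iterrows()
    ]


def write_spectrum(spectrum: AbsorptionSpectrum, dest: PathOrBuf) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "absorbance": spectrum.absorbance}
    ).to_csv(dest, index=False)


def read_spectrum(source: PathOrBuf, label: str = "") -> AbsorptionSpectrum:
    df = pd.read_csv(source)
    return AbsorptionSpectrum(
        wavelengths=df["wavelength_nm"].to_numpy(float),
        absorbance=df["absorbance"].to_numpy(float),
        label=label,
    )


def write_ph_trace(trace: PhTrace, dest: PathOrBuf) -> None:
    df = pd.DataFrame({"time_s": trace.times, "pH": trace.ph})
    df.attrs["illumination_window"] = trace.illumination_window
    df.to_csv(dest, index=False)


def read_ph_trace(
    source: PathOrBuf, illumination_window: tuple[float, float]
) -> PhTrace:
    df = pd.read_csv(source)
    return PhTrace(
        times=df["time_s"].to_numpy(float),
        ph=df["pH"].to_numpy(float),
        illumination_window=illumination_window,
    )


def write_ta_matrix(data: TransientAbsorptionData, dest: PathOrBuf) -> None:
    """Matrix CSV: header row of wavelengths, first column of times."""
    df = pd.DataFrame(data.delta_A, index=data.times, columns=data.wavelengths)
    df.to_csv(dest, index_label="time_s")


def read_ta_matrix(source: PathOrBuf) -> TransientAbsorptionData:
    df = pd.read_csv(source, index_col=0)
    return TransientAbsorptionData(
        wavelengths=np.array([float(c) for c in df.columns]),
        times=df.index.to_numpy(float),
        delta_A=df.to_numpy(float),
    )


def write_charge_env(env: PointChargeEnvironment, dest: PathOrBuf) -> None:
    """TSV with columns residue_id,residue_name,atom_name,x,y,z,charge,formal_charge."""
    rows = [
        {
            "residue_id": s.residue_id,
            "residue_name": s.residue_name,
            "atom_name": s.atom_name,
            "x": s.position[0],
            "y": s.position[1],
            "z": s.position[2],
            "charge": s.charge,
            "formal_charge": float(dict(env.formal_charges).get(s.residue_id, 0.0)),
        }
        for s in env.sites
    ]
    pd.DataFrame(rows).to_csv(dest, sep="\t", index=False)


def read_charge_env(source: PathOrBuf) -> PointChargeEnvironment:
    df = pd.read_csv(source, sep="\t")
    sites = tuple(
        Site(
            residue_id=int(r["residue_id"]),
            residue_name=str(r["residue_name"]),
            atom_name=str(r["atom_name"]),
            position=np.array([r["x"], r["y"], r["z"]], dtype=float),
            charge=float(r["charge"]),
        )
        for _, r in df.iterrows()
    )
    if "formal_charge" in df.columns:
        formal = {
            int(rid): float(g["formal_charge"].iloc[0])
            for rid, g in df.groupby("residue_id")
        }
    else:  # fall back to the summed site charges
        formal = {
            int(rid): float(g["charge"].sum()) for rid, g in df.groupby("residue_id")
        }
    return PointChargeEnvironment(sites=sites, formal_charges=formal)


def write_chromophore_charges(model: ChromophoreChargeModel, dest: PathOrBuf) -> None:
    """TSV with columns atom,q_S0,q_S1 (charges in e)."""
    pd.DataFrame(
        {"atom": model.atoms, "q_S0": model.q_s0, "q_S1": model.q_s1}
    ).to_csv(dest, sep="\t", index=False)


def read_chromophore_charges(source: PathOrBuf) -> ChromophoreChargeModel:
    df = pd.read_csv(source, sep="\t")
    return ChromophoreChargeModel(
        atoms=tuple(df["atom"].astype(str)),
        q_s0=df["q_S0"].to_numpy(float),
        q_s1=df["q_S1"].to_numpy(float),
    )


def write_geometry_report(metrics, dest: PathOrBuf) -> None:
    """TSV of bonds and dihedrals for one :class:`ConjugationMetrics`."""
    rows = [("bla", "", metrics.bla)]
    rows += [("bond_length", k, v) for k, v in metrics.bond_lengths.items()]
    rows += [("dihedral", k, v) for k, v in metrics.dihedrals.items()]
    rows += [("distortion", k, v) for k, v in metrics.distortions.items()]
    pd.DataFrame(rows, columns=["quantity", "key", "value"]).to_csv(
        dest, sep="\t", index=False
    )
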