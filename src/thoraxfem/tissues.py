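"""Frequency-resolved tissue dielectric properties and admittivity.

Each tissue carries a real conductivity ``sigma`` (S/m) and a relative
permittivity ``eps_r`` per frequency.  The 10 kHz row of every tissue is the
literature value used for the single-frequency studies (inflated lung
0.0932 S/m / 17,174; thoracic soft tissue 0.18233 / 13,497; rib — average of
cancellous and cortical bone — 0.0515 / 1,089; heart 0.1542 / 70,054; body
fluid 1.5 / 98; stainless-steel electrode 4e6 / 1).  Rows at the other
frequencies are representative values following the beta-dispersion trends
of the published tissue-dielectric database family (sigma non-decreasing,
eps_r non-increasing with frequency); they can be overridden by loading a
user table from CSV.

Admittivity: kappa = sigma (real mode) or sigma + i*2*pi*f*eps0*eps_r
(complex mode).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EPS0",
    "FREQUENCIES_HZ",
    "TissueProperties",
    "PropertyTable",
    "default_table",
    "uniform_table",
]

EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m

FREQUENCIES_HZ = (5e3, 10e3, 50e3, 100e3, 200e3, 500e3, 1000e3)

# tissue, frequency_Hz, sigma_S_per_m, eps_r, provenance
_DEFAULT_CSV = """\
tissue,frequency_Hz,sigma_S_per_m,eps_r,provenance
lung,5000,0.0907,24000,representative beta-dispersion value
lung,10000,0.0932,17174,literature value at 10 kHz
lung,50000,0.1030,6000,representative beta-dispersion value
lung,100000,0.1080,3500,representative beta-dispersion value
lung,200000,0.1150,2100,representative beta-dispersion value
lung,500000,0.1290,1200,representative beta-dispersion value
lung,1000000,0.1450,800,representative beta-dispersion value
soft_tissue,5000,0.1780,18500,representative beta-dispersion value
soft_tissue,10000,0.18233,13497,literature value at 10 kHz
soft_tissue,50000,0.1950,5600,representative beta-dispersion value
soft_tissue,100000,0.2050,3400,representative beta-dispersion value
soft_tissue,200000,0.2200,2200,representative beta-dispersion value
soft_tissue,500000,0.2500,1400,representative beta-dispersion value
soft_tissue,1000000,0.2800,950,representative beta-dispersion value
rib,5000,0.0505,1400,representative beta-dispersion value
rib,10000,0.0515,1089,literature value at 10 kHz
rib,50000,0.0540,650,representative beta-dispersion value
rib,100000,0.0560,520,representative beta-dispersion value
rib,200000,0.0580,420,representative beta-dispersion value
rib,500000,0.0620,330,representative beta-dispersion value
rib,1000000,0.0670,280,representative beta-dispersion value
heart,5000,0.1450,120000,representative beta-dispersion value
heart,10000,0.1542,70054,literature value at 10 kHz
heart,50000,0.1950,20000,representative beta-dispersion value
heart,100000,0.2150,12000,representative beta-dispersion value
heart,200000,0.2350,7500,representative beta-dispersion value
heart,500000,0.2700,4500,representative beta-dispersion value
heart,1000000,0.3280,3200,representative beta-dispersion value
fluid,5000,1.5,99,non-dispersive ionic fluid
fluid,10000,1.5,98,literature value at 10 kHz
fluid,50000,1.5,98,non-dispersive ionic fluid
fluid,100000,1.5,98,non-dispersive ionic fluid
fluid,200000,1.5,98,non-dispersive ionic fluid
fluid,500000,1.5,98,non-dispersive ionic fluid
fluid,1000000,1.5,98,non-dispersive ionic fluid
electrode,5000,4e6,1,stainless steel AISI-4340
electrode,10000,4e6,1,stainless steel AISI-4340
electrode,50000,4e6,1,stainless steel AISI-4340
electrode,100000,4e6,1,stainless steel AISI-4340
electrode,200000,4e6,1,stainless steel AISI-4340
electrode,500000,4e6,1,stainless steel AISI-4340
electrode,1000000,4e6,1,stainless steel AISI-4340
"""

# map mesh region names onto table tissue names
REGION_TISSUE = {
    "soft_tissue": "soft_tissue",
    "lung_left": "lung",
    "lung_right": "lung",
    "heart": "heart",
    "rib": "rib",
    "fluid": "fluid",
    "medium": "medium",
}


@dataclass(frozen=True)
class TissueProperties:
    tissue: str
    frequency: float  # Hz
    sigma: float      # S/m
    eps_r: float
    interpolated: bool = False

    def admittivity(self, mode: str = "real") -> complex | float:
        return admittivity(self, mode)


def admittivity(props: TissueProperties, mode: str = "real"):
    """kappa = sigma (real) or sigma + i*omega*eps0*eps_r (complex)."""
    if mode == "real":
        return props.sigma
    if mode == "complex":
        return props.sigma + 1j * 2.0 * math.pi * props.frequency * EPS0 * \
            props.eps_r
    raise ValueError(f"unknown admittivity mode {mode!r}")


class PropertyTable:
    """Table of (tissue, frequency) -> (sigma, eps_r) with interpolation."""

    def __init__(self, df: pd.DataFrame):
        required = {"tissue", "frequency_Hz", "sigma_S_per_m", "eps_r"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"property table missing columns {missing}")
        if "provenance" not in df.columns:
            df = df.assign(provenance="")
        self.df = df.sort_values(["tissue", "frequency_Hz"]).reset_index(
            drop=True)

    # ------------------------------------------------------------------- io
    @classmethod
    def from_csv(cls, path_or_buf) -> "PropertyTable":
        return cls(pd.read_csv(path_or_buf))

    def to_csv(self, path_or_buf) -> None:
        self.df.to_csv(path_or_buf, index=False)

    def tissues(self) -> list[str]:
        return sorted(self.df["tissue"].unique())

    def frequencies(self, tissue: str) -> np.ndarray:
        return self.df.loc[self.df["tissue"] == tissue,
                           "frequency_Hz"].to_numpy(dtype=float)

    # --------------------------------------------------------------- lookup
    def lookup(self, tissue: str, frequency: float,
               interpolate: bool = True) -> TissueProperties:
        """Exact row when present, else log-log linear interpolation.

        No extrapolation: frequencies outside the tabulated range for the
        tissue raise.
        """
        sub = self.df[self.df["tissue"] == tissue]
        if sub.empty:
            raise KeyError(f"unknown tissue {tissue!r}")
        f = sub["frequency_Hz"].to_numpy(dtype=float)
        exact = np.isclose(f, frequency, rtol=1e-9)
        if exact.any():
            row = sub.iloc[int(np.argmax(exact))]
            return TissueProperties(tissue, float(row["frequency_Hz"]),
                                    float(row["sigma_S_per_m"]),
                                    float(row["eps_r"]))
        if not interpolate:
            raise KeyError(f"no {tissue} row at {frequency} Hz")
        if frequency < f.min() or frequency > f.max():
            raise ValueError(
                f"frequency {frequency} Hz outside tabulated range "
                f"[{f.min():g}, {f.max():g}] for {tissue!r}; "
                "extrapolation is not supported")
        lf = np.log(f)
        sigma = math.exp(np.interp(math.log(frequency), lf,
                                   np.log(sub["sigma_S_per_m"])))
        eps = math.exp(np.interp(math.log(frequency), lf,
                                 np.log(sub["eps_r"])))
        return TissueProperties(tissue, frequency, sigma, eps,
                                interpolated=True)

    def lookup_region(self, region: str, frequency: float) -> TissueProperties:
        tissue = REGION_TISSUE.get(region, region)
        return self.lookup(tissue, frequency)

    # ------------------------------------------------------------ validation
    def validate(self) -> list[str]:
        """Report invariant violations (positivity, monotonicity,
        completeness over the seven study frequencies)."""
        problems: list[str] = []
        for _, row in self.df.iterrows():
            if row["sigma_S_per_m"] <= 0:
                problems.append(
                    f"{row['tissue']} @ {row['frequency_Hz']:g} Hz: "
                    f"sigma must be positive")
            if row["eps_r"] < 1:
                problems.append(
                    f"{row['tissue']} @ {row['frequency_Hz']:g} Hz: "
                    f"eps_r must be >= 1")
        for tissue, sub in self.df.groupby("tissue"):
            sub = sub.sort_values("frequency_Hz")
            if np.any(np.diff(sub["sigma_S_per_m"]) < 0):
                problems.append(f"{tissue}: sigma decreases with frequency")
            if np.any(np.diff(sub["eps_r"]) > 0):
                problems.append(f"{tissue}: eps_r increases with frequency")
            have = set(np.round(sub["frequency_Hz"].to_numpy()).astype(int))
            want = {int(f) for f in FREQUENCIES_HZ}
            for f in sorted(want - have):
                problems.append(f"{tissue}: missing row at {f} Hz")
        return problems


def default_table() -> PropertyTable:
    return PropertyTable.from_csv(io.StringIO(_DEFAULT_CSV))


def uniform_table(sigma: float, eps_r: float = 1.0,
                  tissue: str = "medium") -> PropertyTable:
    """Single-tissue table at the seven study frequencies (oracle domains)."""
    df = pd.DataFrame({
        "tissue": tissue,
        "frequency_Hz": list(FREQUENCIES_HZ),
        "sigma_S_per_m": sigma,
        "eps_r": eps_r,
        "provenance": "uniform synthetic medium",
    })
    return PropertyTable(df)
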