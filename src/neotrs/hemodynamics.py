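"""Hemoglobin chromophore decomposition and cerebral hemodynamic indices.

Fitted absorption coefficients at the three TRS wavelengths are
decomposed into oxy- and deoxy-hemoglobin concentrations through the
linear system

    mu_a(lambda) = eps_oxy(lambda) [oxyHb] + eps_deoxy(lambda) [deoxyHb]
                   + mu_a_background(lambda)

solved in the least-squares sense over the overdetermined 3x2 system
(the near-isosbestic 801 nm row contributes rather than being
eliminated).  From the concentrations:

    totalHb = oxyHb + deoxyHb                              (uM)
    ScO2    = oxyHb / (oxyHb + deoxyHb) * 100              (%)
    CBV     = totalHb * MW_Hb * 1e-6
              / (venous_tHb * 1e-2 * Dt * 10)              (mL / 100 g)

with MW_Hb = 64500 g/mol, brain tissue density Dt = 1.05 g/mL and the
subject's venous hemoglobin concentration in g/dL.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional

import numpy as np
import pandas as pd

MW_HB_G_PER_MOL = 64500.0
BRAIN_TISSUE_DENSITY_G_PER_ML = 1.05
DEFAULT_WAVELENGTHS = (762.0, 801.0, 836.0)


def _read_table(name: str) -> pd.DataFrame:
    with resources.files("neotrs.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


@dataclass(frozen=True)
class ExtinctionTable:
    """Hemoglobin extinction coefficients per wavelength, uM^-1 mm^-1."""

    wavelengths_nm: tuple
    eps_oxy: tuple
    eps_deoxy: tuple
    source_label: str = "unspecified"

    def __post_init__(self) -> None:
        if not (len(self.wavelengths_nm) == len(self.eps_oxy)
                == len(self.eps_deoxy)):
            raise ValueError("extinction table columns differ in length")
        if any(e <= 0 for e in self.eps_oxy + self.eps_deoxy):
            raise ValueError("extinction coefficients must be > 0")

    @classmethod
    def default(cls) -> "ExtinctionTable":
        df = _read_table("hb_extinction.tsv")
        return cls(tuple(df["wavelength_nm"].astype(float)),
                   tuple(df["eps_oxy"].astype(float)),
                   tuple(df["eps_deoxy"].astype(float)),
                   source_label="compiled literature tabulation (shipped)")

    @classmethod
    def from_file(cls, path) -> "ExtinctionTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        for col in ("wavelength_nm", "eps_oxy", "eps_deoxy"):
            if col not in df.columns:
                raise ValueError(f"extinction file missing column {col!r}")
        return cls(tuple(df["wavelength_nm"].astype(float)),
                   tuple(df["eps_oxy"].astype(float)),
                   tuple(df["eps_deoxy"].astype(float)),
                   source_label=str(path))

    def matrix(self, wavelengths) -> np.ndarray:
        """3x2 extinction matrix [eps_oxy, eps_deoxy] rows in given order."""
        rows = []
        for wl in wavelengths:
            try:
                i = self.wavelengths_nm.index(float(wl))
            except ValueError:
                raise KeyError(f"no extinction entry for {wl} nm") from None
            rows.append((self.eps_oxy[i], self.eps_deoxy[i]))
        return np.asarray(rows, dtype=float)

    def condition_number(self, wavelengths=None) -> float:
        wl = wavelengths if wavelengths is not None else self.wavelengths_nm
        return float(np.linalg.cond(self.matrix(wl)))


@dataclass(frozen=True)
class BackgroundAbsorption:
    """Non-hemoglobin background absorption per wavelength, mm^-1."""

    values: Mapping[float, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.values.values()):
            raise ValueError("background absorption must be >= 0")

    @classmethod
    def water(cls, fraction: float = 0.90) -> "BackgroundAbsorption":
        """Water spectrum scaled by a tissue water volume fraction."""
        if not (0 <= fraction <= 1):
            raise ValueError("water fraction must lie in [0, 1]")
        df = _read_table("water_absorption.tsv")
        return cls({float(w): fraction * float(m)
                    for w, m in zip(df["wavelength_nm"], df["mu_a_water"])})

    @classmethod
    def zero(cls, wavelengths=DEFAULT_WAVELENGTHS) -> "BackgroundAbsorption":
        return cls({float(w): 0.0 for w in wavelengths})

    def at(self, wavelength_nm: float) -> float:
        try:
            return self.values[float(wavelength_nm)]
        except KeyError:
            raise KeyError(
                f"no background absorption for {wavelength_nm} nm") from None


@dataclass(frozen=True)
class CBVConstants:
    """Constants of the cerebral blood volume formula."""

    venous_thb_g_dl: float
    mw_hb: float = MW_HB_G_PER_MOL
    tissue_density: float = BRAIN_TISSUE_DENSITY_G_PER_ML

    def __post_init__(self) -> None:
        if self.venous_thb_g_dl <= 0:
            raise ValueError("venous tHb must be > 0 g/dL")


@dataclass(frozen=True)
class ChromophoreFit:
    oxy_hb_uM: float
    deoxy_hb_uM: float
    residual: float
    negative: bool  # any concentration came out < 0 (reported, not clipped)


@dataclass(frozen=True)
class HemodynamicState:
    """The clinical endpoint bundle derived from one site's fits."""

    oxy_hb_uM: float
    deoxy_hb_uM: float
    total_hb_uM: float
    sco2_pct: float
    cbv_ml_per_100g: float


def forward_mu_a(oxy_hb_uM: float, deoxy_hb_uM: float,
                 table: ExtinctionTable,
                 background: BackgroundAbsorption,
                 wavelengths=DEFAULT_WAVELENGTHS) -> dict:
    """Absorption per wavelength implied by a chromophore pair, mm^-1."""
    E = table.matrix(wavelengths)
    mu = E @ np.array([oxy_hb_uM, deoxy_hb_uM])
    return {float(wl): float(m + background.at(wl))
            for wl, m in zip(wavelengths, mu)}


def invert_chromophores(mu_a_by_wavelength: Mapping[float, float],
                        table: ExtinctionTable,
                        background: BackgroundAbsorption,
                        *, max_condition: float = 1e8) -> ChromophoreFit:
    """Least-squares solve of the 3x2 extinction system for (oxyHb, deoxyHb).

    Background absorption is subtracted first.  Negative concentrations
    are returned as-is with ``negative=True`` — clipping would silently
    break the totalHb = oxyHb + deoxyHb identity.
    """
    wavelengths = sorted(mu_a_by_wavelength)
    if len(wavelengths) < 2:
        raise ValueError("need mu_a at >= 2 wavelengths")
    E = table.matrix(wavelengths)
    cond = np.linalg.cond(E)
    if cond > max_condition:
        raise ValueError(
            f"extinction matrix is rank-deficient (condition number {cond:.3e})")
    b = np.array([mu_a_by_wavelength[wl] - background.at(wl)
                  for wl in wavelengths])
    sol, *_ = np.linalg.lstsq(E, b, rcond=None)
    residual = float(np.linalg.norm(E @ sol - b))
    oxy, deoxy = float(sol[0]), float(sol[1])
    return ChromophoreFit(oxy, deoxy, residual,
                          negative=bool(oxy < 0 or deoxy < 0))


def total_hb(oxy_hb_uM: float, deoxy_hb_uM: float) -> float:
    """Total hemoglobin concentration, uM (exact sum)."""
    return oxy_hb_uM + deoxy_hb_uM


def sco2(oxy_hb_uM: float, deoxy_hb_uM: float) -> float:
    """Hemoglobin oxygen saturation, percent."""
    tot = oxy_hb_uM + deoxy_hb_uM
    if tot <= 0:
        raise ValueError("ScO2 undefined for nonpositive total hemoglobin")
    return 100.0 * oxy_hb_uM / tot


def cbv(total_hb_uM: float, constants: CBVConstants) -> float:
    """Cerebral blood volume, mL per 100 g brain tissue.

    Literal evaluation of
    totalHb * MW_Hb * 1e-6 / (venous_tHb * 1e-2 * Dt * 10): the
    numerator is grams of tissue hemoglobin per liter of tissue, the
    denominator converts the venous blood hemoglobin (g/dL) and tissue
    density into the per-100-g normalization.
    """
    return (total_hb_uM * constants.mw_hb * 1e-6
            / (constants.venous_thb_g_dl * 1e-2 * constants.tissue_density * 10.0))


def hemodynamic_state(oxy_hb_uM: float, deoxy_hb_uM: float,
                      constants: CBVConstants) -> HemodynamicState:
    """Bundle all derived hemodynamic indices for one measurement site."""
    tot = total_hb(oxy_hb_uM, deoxy_hb_uM)
    return HemodynamicState(
        oxy_hb_uM=oxy_hb_uM,
        deoxy_hb_uM=deoxy_hb_uM,
        total_hb_uM=tot,
        sco2_pct=sco2(oxy_hb_uM, deoxy_hb_uM),
        cbv_ml_per_100g=cbv(tot, constants),
    )
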