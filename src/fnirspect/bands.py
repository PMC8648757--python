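"""Band energy densities over the four physiological bands.

The time-averaged energy density of a band [f1, f2] is

    eps(f1, f2) = (1/T) * double-integral of |W(s, t)|^2 / s^2
                  over the band's scale range and the record duration,

evaluated by the trapezoidal rule on the log-spaced scale grid (the band
edges are interpolated onto the grid so the four bands partition the
full range exactly). The relative energy density is

    rel_eps = eps_band / eps_total_average,

where ``eps_total_average`` is the across-band mean of the four band
energies, so the four rel_eps values of a cell average to exactly 1 and
individual values may exceed 1 (VLF typically does).

Bands: cardiac [0.4, 2], respiratory [0.15, 0.4], myogenic [0.06, 0.15],
VLF [0.009, 0.06] Hz; shared endpoints belong to the upper band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral import Scalogram

BAND_ORDER = ("VLF", "myogenic", "respiratory", "cardiac")


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f1: float
    f2: float

    def __post_init__(self) -> None:
        if not 0 < self.f1 < self.f2:
            raise ValueError(f"band {self.name}: need 0 < f1 < f2")


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("VLF", 0.009, 0.06),
    BandDefinition("myogenic", 0.06, 0.15),
    BandDefinition("respiratory", 0.15, 0.4),
    BandDefinition("cardiac", 0.4, 2.0),
)


def _scale_integrand(sg: Scalogram, exclude_coi: bool) -> np.ndarray:
    """Time-averaged |W|^2 / s^2 per scale (COI-masked samples excluded
    by default; rows fully inside the cone fall back to all samples)."""
    mag2 = sg.magnitude**2
    if exclude_coi:
        valid = sg.coi_mask
        n_valid = valid.sum(axis=1)
        mean_t = np.where(
            n_valid > 0,
            np.where(valid, mag2, 0.0).sum(axis=1) / np.maximum(n_valid, 1),
            mag2.mean(axis=1),
        )
    else:
        mean_t = mag2.mean(axis=1)
    return mean_t / sg.scales**2


def band_epsilon(
    sg: Scalogram, band: BandDefinition, exclude_coi: bool = True
) -> float:
    """Time-averaged energy density of one band.

    Integrates the per-scale time-averaged energy over the scale range
    whose centre frequencies f0/s lie inside [f1, f2], with the exact
    band edges interpolated onto the log-spaced grid.
    """
    q = _scale_integrand(sg, exclude_coi)
    return _integrate_band(sg, q, band.f1, band.f2)


def _integrate_band(sg: Scalogram, q: np.ndarray, f1: float, f2: float) -> float:
    fgrid = sg.freqs
    if f2 <= fgrid[0] or f1 >= fgrid[-1]:
        raise ValueError(
            f"band [{f1}, {f2}] Hz lies outside the scalogram grid "
            f"[{fgrid[0]:.4g}, {fgrid[-1]:.4g}] Hz"
        )
    f1c, f2c = max(f1, fgrid[0]), min(f2, fgrid[-1])
    # scales ascend as frequency descends; integrate over s in [f0/f2, f0/f1]
    s_grid = sg.f0 / fgrid  # descending
    s_lo, s_hi = sg.f0 / f2c, sg.f0 / f1c
    s_asc = s_grid[::-1]
    q_asc = q[::-1]
    inside = (s_asc > s_lo) & (s_asc < s_hi)
    s_pts = np.concatenate([[s_lo], s_asc[inside], [s_hi]])
    q_pts = np.concatenate(
        [
            [np.interp(s_lo, s_asc, q_asc)],
            q_asc[inside],
            [np.interp(s_hi, s_asc, q_asc)],
        ]
    )
    return float(np.trapezoid(q_pts, s_pts))


def band_epsilon_table(
    sg: Scalogram,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    exclude_coi: bool = True,
) -> dict[str, float]:
    """Energy density for every band of one scalogram (shared scale
    integrand, so the bands tile the spectrum consistently)."""
    q = _scale_integrand(sg, exclude_coi)
    return {b.name: _integrate_band(sg, q, b.f1, b.f2) for b in bands}


def rel_epsilon(eps_band: float, eps_all_bands: dict[str, float] | np.ndarray) -> float:
    """Relative energy density: band energy over the across-band mean.

    The four values of a cell average to exactly 1; an all-zero energy
    vector has no defined normalisation and yields NaN with a warning.
    """
    values = np.asarray(
        list(eps_all_bands.values()) if isinstance(eps_all_bands, dict) else eps_all_bands,
        dtype=float,
    )
    if np.any(values < 0):
        raise ValueError("band energies must be >= 0")
    total_avg = values.mean()
    if total_avg == 0:
        warnings.warn("all band energies are zero; rel_epsilon undefined", stacklevel=2)
        return float("nan")
    return float(eps_band / total_avg)


def build_table(
    spectra,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    exclude_coi: bool = True,
) -> pd.DataFrame:
    """Assemble the tidy band-energy table feeding the statistics layer.

    ``spectra`` is an iterable (list or generator) of records with keys ``subject``, ``condition``,
    ``sds``, ``hemisphere``, ``biomarker`` and ``scalogram``; one output
    row is produced per record x band with columns ``subject, condition,
    sds, hemisphere, band, biomarker, epsilon, rel_epsilon``. Records of
    missing regions are simply absent (never zero-filled).
    """
    rows = []
    for rec in spectra:
        eps = band_epsilon_table(rec["scalogram"], bands, exclude_coi=exclude_coi)
        for b in bands:
            rows.append(
                {
                    "subject": rec["subject"],
                    "condition": rec["condition"],
                    "sds": rec["sds"],
                    "hemisphere": rec["hemisphere"],
                    "band": b.name,
                    "biomarker": rec["biomarker"],
                    "epsilon": eps[b.name],
                    "rel_epsilon": rel_epsilon(eps[b.name], eps),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "subject",
            "condition",
            "sds",
            "hemisphere",
            "band",
            "biomarker",
            "epsilon",
            "rel_epsilon",
        ],
    )
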