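"""Bundled cultivar-mean reference measurements.

Published cultivar-mean values for four spelt wheat (*Triticum aestivum*
ssp. *spelta*) cultivars — Oberkulmer Rotkorn, Schwabenkorn, Franckenkorn,
Zollernspelz — and one common wheat cultivar (Bombona), from a laboratory
milling study of organically grown grain. They serve as worked-example
inputs: the shape descriptors, SPAN, gelatinization range and correlation
checks in this package recompute derived columns from the measured ones.

All tables are means over replicate kernels/runs; dispersion is not
carried here.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "CULTIVARS",
    "grain_table",
    "endosperm_table",
    "mechanics_table",
    "flour_table",
]

CULTIVARS = [
    "Oberkulmer Rotkorn",
    "Schwabenkorn",
    "Franckenkorn",
    "Zollernspelz",
    "Common wheat",
]


def grain_table() -> pd.DataFrame:
    """Kernel hardness, weight and geometry means.

    Columns: hardness index HI (-), kernel weight KW (mg), length L,
    width W, thickness T (mm), projection areas A_a, A_b (mm²), perimeters
    P_a, P_b (mm), and the derived mean diameter Dm (mm), thinness ratio
    Rs (-) and circularity Rc (-) as printed.
    """
    data = {
        "HI": [21.4, 71.2, 26.1, 21.4, 70.6],
        "KW_mg": [44.5, 44.5, 28.2, 31.3, 37.4],
        "L_mm": [8.35, 7.01, 6.42, 6.91, 6.50],
        "W_mm": [3.36, 3.52, 2.86, 3.12, 3.26],
        "T_mm": [2.89, 2.90, 2.61, 2.81, 2.97],
        "A_a_mm2": [16.91, 14.68, 12.65, 14.39, 14.24],
        "A_b_mm2": [20.48, 18.44, 14.12, 16.71, 15.84],
        "P_a_mm": [19.82, 17.23, 16.25, 17.43, 16.40],
        "P_b_mm": [20.46, 17.89, 16.66, 18.21, 16.58],
        "Dm_mm": [4.32, 4.15, 3.63, 3.92, 3.98],
        "Rs": [1.63, 1.39, 1.57, 1.59, 1.39],
        "Rc": [0.78, 0.85, 0.80, 0.79, 0.85],
    }
    return pd.DataFrame(data, index=pd.Index(CULTIVARS, name="cultivar"))


def endosperm_table() -> pd.DataFrame:
    """Endosperm microstructure means from binary SEM maps.

    Granule cross-sectional areas (µm²), per-type shares (%), Minkowski
    measures (solid/void/boundary shares in %, Euler–Poincaré value on the
    ×10⁻³ scale), coverage rate (µm⁻²) and texture metrics (Str, D,
    tau_c in µm).
    """
    data = {
        "mean_area_um2": [17.531, 14.093, 9.658, 21.391, 11.662],
        "min_area_um2": [0.009, 0.018, 0.009, 0.009, 0.018],
        "max_area_um2": [259.675, 236.774, 177.004, 510.429, 321.742],
        "type_A_pct": [0.90, 0.36, 0.04, 2.46, 0.31],
        "type_B_pct": [16.85, 15.95, 9.72, 20.49, 13.45],
        "type_C_pct": [82.25, 83.69, 90.24, 77.05, 86.24],
        "solid_pct": [84.71, 86.19, 80.38, 85.46, 83.39],
        "void_pct": [15.29, 13.81, 19.62, 14.54, 16.61],
        "boundary_pct": [4.79, 5.34, 6.96, 4.34, 5.69],
        "starch_boundary_pct": [1.38, 1.75, 1.60, 1.07, 1.87],
        "coverage_per_um2": [0.060, 0.071, 0.104, 0.047, 0.086],
        "chi_e3": [-0.374, -0.479, -0.470, -0.275, -0.510],
        "Str": [0.49, 0.86, 0.91, 0.88, 0.64],
        "D": [2.49, 2.59, 2.45, 2.48, 2.58],
        "tau_c_um": [2.22, 1.28, 1.66, 2.98, 1.75],
    }
    return pd.DataFrame(data, index=pd.Index(CULTIVARS, name="cultivar"))


def mechanics_table() -> pd.DataFrame:
    """Kernel compression and milling means: rupture force F_r (N),
    displacement (mm), rupture energy R_e (mJ), specific milling energy
    E_r (kJ/kg)."""
    data = {
        "F_r_N": [78.4, 80.1, 62.1, 75.4, 88.8],
        "displacement_mm": [0.78, 0.80, 0.67, 0.72, 0.62],
        "R_e_mJ": [30.7, 31.7, 19.8, 25.8, 21.0],
        "E_r_kJ_kg": [57.1, 73.0, 47.2, 54.8, 69.5],
    }
    return pd.DataFrame(data, index=pd.Index(CULTIVARS, name="cultivar"))


def flour_table() -> pd.DataFrame:
    """Flour particle-size and gelatinization means.

    Volume-weighted mean size d_f and percentiles d10/d50/d90 (µm), SPAN,
    damaged starch (%), gelatinization onset/peak/end temperatures (°C),
    their range dT, and enthalpy dH (J/g).
    """
    data = {
        "d_f_um": [96.5, 116.5, 87.5, 90.5, 115.5],
        "d10_um": [17.9, 42.8, 13.7, 16.1, 40.1],
        "d50_um": [97.9, 123.5, 85.0, 89.6, 126.3],
        "d90_um": [212.1, 247.3, 204.1, 209.1, 266.6],
        "span": [1.98, 1.66, 2.24, 2.15, 1.79],
        "damaged_starch_pct": [3.84, 6.14, 3.69, 4.11, 5.00],
        "T_o_C": [59.4, 56.3, 57.9, 58.4, 61.0],
        "T_p_C": [64.1, 62.3, 63.8, 63.2, 65.1],
        "T_e_C": [68.8, 68.0, 68.4, 68.4, 69.8],
        "dT_C": [9.4, 11.7, 10.6, 10.0, 8.8],
        "dH_J_g": [5.3, 5.8, 6.3, 5.6, 5.4],
    }
    return pd.DataFrame(data, index=pd.Index(CULTIVARS, name="cultivar"))
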