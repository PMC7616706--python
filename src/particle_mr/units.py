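"""Unit conversions and derived lipid quantities.

Lipoprotein particle comparisons require molar units: every LDL, VLDL/remnant
and Lp(a) particle carries exactly one apolipoprotein B-100, so molar apoB is
a particle count.  Clinical panels, however, report apoB in g/L and Lp(a)
either in mg/dL or nmol/L depending on assay calibration.  This module holds
the conversion constants, the immunoassay working-range censoring rule, and
the remnant-cholesterol derivation.  All internal computation elsewhere in
the package is molar (nmol/L); conversions happen only at I/O boundaries.

Notes
-----
The mass-to-molar factor for Lp(a) (1 mg/dL = 2.2 nmol/L) is an empirical
calibration-comparison value, not a physical constant: Lp(a) has no single
molecular weight because apo(a) isoform size varies.  It is therefore exposed
as a module constant that callers may override rather than baked into call
sites.
"""

from __future__ import annotations

import numpy as np

#: Empirical Lp(a) mass-to-molar conversion: 1 mg/dL = 2.2 nmol/L.
LPA_NMOL_PER_MG_DL: float = 2.2

#: Molecular weight of apolipoprotein B-100 in kilodaltons.
APOB_MOLECULAR_WEIGHT_KDA: float = 550.0

#: Working range of the Lp(a) immunoturbidimetric assay, nmol/L.
ASSAY_RANGE_NMOL_L: tuple[float, float] = (3.8, 189.0)


def _check_nonnegative(x, name: str):
    x = np.asarray(x, dtype=float)
    if np.any(x[~np.isnan(x)] < 0):
        raise ValueError(f"{name} must be non-negative, got {x!r}")
    return x


def convert_lpa_mass_to_molar(x_mg_dl, factor: float = LPA_NMOL_PER_MG_DL):
    """Convert Lp(a) mass concentration (mg/dL) to molar concentration (nmol/L).

    Parameters
    ----------
    x_mg_dl : float or array-like
        Lp(a) in mg/dL; must be non-negative (NaN propagates).
    factor : float
        nmol/L per mg/dL; default 2.2.

    Returns
    -------
    float or ndarray
        Lp(a) in nmol/L.
    """
    x = _check_nonnegative(x_mg_dl, "lpa mass (mg/dL)")
    out = x * factor
    return float(out) if np.isscalar(x_mg_dl) else out


def convert_lpa_molar_to_mass(x_nmol_l, factor: float = LPA_NMOL_PER_MG_DL):
    """Inverse of :func:`convert_lpa_mass_to_molar` (nmol/L -> mg/dL)."""
    x = _check_nonnegative(x_nmol_l, "lpa molar (nmol/L)")
    out = x / factor
    return float(out) if np.isscalar(x_nmol_l) else out


def convert_apob_mass_to_molar(x_g_l, mw_kda: float = APOB_MOLECULAR_WEIGHT_KDA):
    """Convert apoB mass concentration (g/L) to molar concentration (nmol/L).

    Uses ``x / (mw_kda * 1000 g/mol)`` expressed in nmol/L, i.e.
    ``x * 1e9 / (mw_kda * 1000)``.  With the default 550 kDa,
    1.03 g/L -> 1872.7 nmol/L.
    """
    x = _check_nonnegative(x_g_l, "apoB mass (g/L)")
    out = x * 1e9 / (mw_kda * 1e3)
    return float(out) if np.isscalar(x_g_l) else out


def convert_apob_molar_to_mass(x_nmol_l, mw_kda: float = APOB_MOLECULAR_WEIGHT_KDA):
    """Inverse of :func:`convert_apob_mass_to_molar` (nmol/L -> g/L)."""
    x = _check_nonnegative(x_nmol_l, "apoB molar (nmol/L)")
    out = x * (mw_kda * 1e3) / 1e9
    return float(out) if np.isscalar(x_nmol_l) else out


def apply_assay_censoring(lpa, lo: float | None = None, hi: float | None = None):
    """Censor Lp(a) values outside the assay working range to missing (NaN).

    Values strictly below ``lo`` or strictly above ``hi`` are classified
    'not available'; in-range values pass through unchanged.

    Parameters
    ----------
    lpa : float or array-like, nmol/L
    lo, hi : float
        Working-range bounds; default the assay range (3.8, 189) nmol/L.

    Returns
    -------
    float or ndarray with NaN marking censored values.
    """
    if lo is None:
        lo = ASSAY_RANGE_NMOL_L[0]
    if hi is None:
        hi = ASSAY_RANGE_NMOL_L[1]
    if not lo < hi:
        raise ValueError(f"assay range lower bound {lo} must be < upper bound {hi}")
    x = np.asarray(lpa, dtype=float)
    out = np.where((x < lo) | (x > hi), np.nan, x)
    return float(out) if np.isscalar(lpa) else out


def derive_remnant_c(total_c, ldl_c, hdl_c):
    """Remnant (TRL) cholesterol: total cholesterol minus LDL-C minus HDL-C.

    All arguments and the result in mmol/L.  Missing inputs propagate as NaN.
    """
    return np.asarray(total_c, dtype=float) - np.asarray(ldl_c, dtype=float) - np.asarray(
        hdl_c, dtype=float
    )
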