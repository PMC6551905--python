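"""Band-level biochemical profiling of FTIR spectra.

Reads peak intensities at the canonical band positions of microbial
biomass spectra (acyl C-H stretches near 3010/2955/2925/2850 cm^-1, the
TAG ester carbonyl at 1745 cm^-1, the free-fatty-acid carboxyl carbonyl
near 1710 cm^-1, amide I/II, the carbohydrate C-O complex, and the
phosphate bands), and derives two simple per-sample indicators:

* the FFA indicator — the baseline-offset ratio A(1710)/A(1745); a ratio
  strictly above 1 marks samples whose accumulated lipid is dominated by
  free fatty acids rather than triacylglycerols;
* the unsaturation index — A(3010)/A(2925), tracking =C-H per CH2, i.e.
  the average unsaturation of the acyl chains.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .spectra import ReferenceTable, SpectraError, SpectrumSet

__all__ = [
    "BAND_TABLE",
    "band_absorbance",
    "ffa_indicator",
    "unsaturation_index",
    "cross_correlation",
]

#: Tentative peak assignments for FTIR spectra of oleaginous fungi/yeasts.
#: Ranged bands (amide I/II, phosphodiester, carbohydrate complex) are
#: represented by their window midpoint.
BAND_TABLE = pd.DataFrame(
    [
        (1, 3010.0, "=C-H stretching", "lipid"),
        (2, 2955.0, "C-H asymmetric stretching of -CH3", "lipid"),
        (3, 2925.0, "asymmetric stretching of >CH2 of acyl chains", "lipid"),
        (4, 2850.0, "symmetric stretching of CH2 of acyl chains", "lipid"),
        (5, 1745.0, "C=O stretching (ester)", "lipid"),
        (6, 1660.0, "amide I (C=O stretching), 1680-1640", "protein"),
        (7, 1550.0, "amide II (CONH bending), 1580-1520", "protein"),
        (8, 1465.0, "CH2 deformation", "lipid"),
        (9, 1410.0, "amide III (C-N stretching)", "protein"),
        (10, 1380.0, "CH3 bending", "lipid"),
        (11, 1252.0, "P=O asymmetric stretching of >PO2, 1240-1265",
         "polyphosphate/phospholipid"),
        (12, 1155.0, "C-O-C stretching", "lipid"),
        (13, 1080.0, "P-O symmetric stretching of >PO2",
         "polyphosphate/phospholipid"),
        (14, 1050.0, "C-O/C-C stretching, C-O-H/C-O-C deformation, 900-1200",
         "carbohydrate"),
        (15, 875.0, "P-O-P stretching", "polyphosphate/phospholipid"),
        (16, 725.0, "CH2 rocking", "lipid"),
    ],
    columns=["peak_nr", "center", "assignment", "biomolecule"],
)
assert BAND_TABLE["center"].is_unique
assert BAND_TABLE["center"].between(500, 4000).all()


def _window_values(sset: SpectrumSet, hi: float, lo: float) -> np.ndarray:
    mask = (sset.wavenumbers >= lo) & (sset.wavenumbers <= hi)
    if not mask.any():
        raise SpectraError(f"window ({hi:g}, {lo:g}) cm^-1 is outside the grid")
    return sset.absorbance[:, mask]


def band_absorbance(sset: SpectrumSet, center: float,
                    half_width: float = 6.0) -> np.ndarray:
    """Per-sample maximum absorbance within center +/- half_width cm^-1.

    The window is clipped at the grid edges; a window entirely off-grid is
    an error.
    """
    return _window_values(sset, center + half_width, center - half_width).max(axis=1)


def ffa_indicator(sset: SpectrumSet) -> pd.DataFrame:
    """Free-fatty-acid dominance indicator per sample.

    Both carbonyl bands are offset by the local minimum of the 1800-1700
    cm^-1 window (a local baseline), then ratio = A(1710)/A(1745). The
    ``flag`` is True when the ratio strictly exceeds 1 — the FFA carboxyl
    band overtopping the TAG ester band. Samples whose offset ester band
    is <= 0 get a NaN ratio and ``degenerate=True``.
    """
    base = _window_values(sset, 1800.0, 1700.0).min(axis=1)
    a1710 = band_absorbance(sset, 1710.0) - base
    a1745 = band_absorbance(sset, 1745.0) - base
    degenerate = a1745 <= 0
    if degenerate.any():
        warnings.warn(
            f"FFA indicator undefined for {int(degenerate.sum())} sample(s): "
            "non-positive ester band after baseline offset",
            stacklevel=2,
        )
    ratio = np.where(degenerate, np.nan, a1710 / np.where(degenerate, 1.0, a1745))
    flag = np.where(degenerate, False, ratio > 1.0)
    return pd.DataFrame({
        "sample_id": sset.sample_ids,
        "ffa_ratio": ratio,
        "ffa_flag": flag.astype(bool),
        "degenerate": degenerate,
    })


def unsaturation_index(sset: SpectrumSet) -> pd.DataFrame:
    """A(3010)/A(2925) per sample — the olefinic =C-H band relative to the
    CH2 stretch, a proxy for average acyl-chain unsaturation."""
    a3010 = band_absorbance(sset, 3010.0)
    a2925 = band_absorbance(sset, 2925.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        idx = np.where(a2925 > 0, a3010 / np.where(a2925 > 0, a2925, 1.0), np.nan)
    return pd.DataFrame({"sample_id": sset.sample_ids, "unsaturation_index": idx})


def band_profile(sset: SpectrumSet, half_width: float = 6.0) -> pd.DataFrame:
    """Per-sample intensity for every band in :data:`BAND_TABLE` that lies
    on the grid, plus the FFA and unsaturation indicators."""
    out = pd.DataFrame({"sample_id": sset.sample_ids})
    wn_hi, wn_lo = sset.wavenumbers.max(), sset.wavenumbers.min()
    for _, row in BAND_TABLE.iterrows():
        c = row["center"]
        if c + half_width < wn_lo or c - half_width > wn_hi:
            continue
        out[f"A{c:.0f}"] = band_absorbance(sset, c, half_width)
    out = out.merge(ffa_indicator(sset), on="sample_id")
    return out.merge(unsaturation_index(sset), on="sample_id")


def cross_correlation(reference: ReferenceTable | pd.DataFrame,
                      columns=None, method: str = "pearson") -> pd.DataFrame:
    """Correlation matrix over reference-chemistry columns (default: total
    lipid and the three summed fatty-acid classes).

    Pearson by default (Spearman available); symmetric with unit diagonal.
    A zero-variance column yields NaN on its row/column with a warning.
    """
    df = reference.frame if isinstance(reference, ReferenceTable) else reference
    if columns is None:
        columns = ["total_lipid", "sat", "mufa", "pufa"]
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SpectraError(f"columns not in reference table: {missing}")
    sub = df[list(columns)].astype(float)
    if len(sub) < 3:
        raise SpectraError("cross-correlation needs at least 3 rows")
    if method == "spearman":
        sub = sub.rank()
    elif method != "pearson":
        raise SpectraError(f"unknown correlation method {method!r}")
    vals = sub.to_numpy()
    sd = vals.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"zero-variance column(s) {list(np.array(columns)[zero])}: "
            "correlations undefined",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(vals, rowvar=False)
    corr[zero, :] = np.nan
    corr[:, zero] = np.nan
    np.fill_diagonal(corr, np.where(zero, np.nan, 1.0))
    return pd.DataFrame(corr, index=list(columns), columns=list(columns))
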