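"""Spectral preprocessing: EMSC, Savitzky-Golay derivatives, replicate
averaging and region extraction.

Two preprocessing strategies are provided, matching standard practice for
lipid calibration from infrared spectra of microbial biomass:

* strategy ``a`` (total lipid): extended multiplicative signal correction
  (EMSC) with linear and quadratic baseline components, spectrally inactive
  windows up-weighted, followed by averaging of technical and biological
  replicates;
* strategy ``b`` (fatty-acid classes): Savitzky-Golay second derivative
  (2nd-degree polynomial, window 9 or 15 points), followed by EMSC.

EMSC models each measured spectrum z as

    z = a + b * m + d * t + e * t**2 + residual,

where m is a reference spectrum and t is the wavenumber axis affinely
scaled to [-1, 1] for conditioning. The corrected spectrum is
(z - a - d*t - e*t**2) / b, i.e. the baseline removed and the
multiplicative scatter factor divided out.

The heavy lifting lives in scikit-learn-style transformers (:class:`EMSC`,
:class:`SavitzkyGolayDerivative`, :class:`RegionSelector`) operating on
plain S x C arrays; the module-level functions wrap them for
:class:`~lipidir.spectra.SpectrumSet` pipelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .spectra import RegionSpec, SpectraError, SpectrumSet

__all__ = [
    "EMSC",
    "EMSCModel",
    "SGParams",
    "SavitzkyGolayDerivative",
    "RegionSelector",
    "default_weights",
    "fit_emsc",
    "savgol_derivative",
    "average_replicates",
    "extract_regions",
    "preprocess_strategy",
]

#: Windows (hi, lo) in cm^-1 with no fundamental absorption bands of
#: cellular biomass; up-weighting them anchors the EMSC baseline estimate.
INACTIVE_WINDOWS = ((3700.0, 3100.0), (2700.0, 1800.0))
INACTIVE_WEIGHT = 10.0


def scaled_axis(wavenumbers: np.ndarray) -> np.ndarray:
    """Affine map of the wavenumber grid onto [-1, 1]."""
    wn = np.asarray(wavenumbers, dtype=float)
    lo, hi = wn.min(), wn.max()
    if hi == lo:
        return np.zeros_like(wn)
    return 2.0 * (wn - lo) / (hi - lo) - 1.0


def default_weights(grid, windows=INACTIVE_WINDOWS, value=INACTIVE_WEIGHT):
    """EMSC channel weights: ``value`` on spectrally inactive windows, 1
    elsewhere. Windows partly outside the grid are clipped; a warning is
    emitted if no inactive channel is present at all."""
    wn = np.asarray(grid, dtype=float)
    w = np.ones_like(wn)
    hit = np.zeros_like(wn, dtype=bool)
    for hi, lo in windows:
        hit |= (wn >= lo) & (wn <= hi)
    if not hit.any():
        warnings.warn(
            "no spectrally inactive channels on this grid; EMSC weights are uniform",
            stacklevel=2,
        )
    w[hit] = float(value)
    return w


@dataclass
class EMSCModel:
    """Fitted EMSC state: the reference spectrum, channel weights, the
    scaled baseline axis and per-sample coefficients.

    ``coefficients`` has one row per sample with columns a (offset),
    b (multiplicative scatter), d (linear baseline), e (quadratic
    baseline); omitted baseline orders are zero. ``flagged`` lists samples
    whose scatter factor was at or below tolerance and were therefore left
    uncorrected.
    """

    reference: np.ndarray
    weights: np.ndarray
    scaled_axis: np.ndarray
    polyorder: int
    coefficients: "np.ndarray"  # shape (S, 4): a, b, d, e
    flagged: list[int]

    def coefficient(self, name: str) -> np.ndarray:
        return self.coefficients[:, "abde".index(name)]


class EMSC(BaseEstimator, TransformerMixin):
    """Extended multiplicative signal correction as a transformer.

    Parameters
    ----------
    reference : "mean" or array of shape (C,)
        Reference spectrum m. ``"mean"`` (default) uses the column mean of
        the data passed to :meth:`fit`.
    weights : None or array of shape (C,)
        Non-negative channel weights for the least-squares fit; ``None``
        means uniform.
    polyorder : int in {0, 1, 2}
        Highest baseline polynomial order (0 = offset only, 2 adds linear
        and quadratic terms on the scaled axis).
    wavenumbers : None or array of shape (C,)
        Grid used to build the scaled baseline axis; channel index is used
        when absent (identical up to an affine map on uniform grids).
    b_tol : float
        Scatter factors b <= b_tol flag the sample; it is returned
        uncorrected.

    Attributes
    ----------
    reference_ : ndarray of shape (C,)
    weights_ : ndarray of shape (C,)
    axis_ : ndarray of shape (C,)
    coefficients_ : ndarray of shape (S, 4)
        a, b, d, e per sample of the last ``fit_transform``/``correct``.
    flagged_ : list of int
    """

    def __init__(self, reference="mean", weights=None, polyorder=2,
                 wavenumbers=None, b_tol=1e-8):
        self.reference = reference
        self.weights = weights
        self.polyorder = polyorder
        self.wavenumbers = wavenumbers
        self.b_tol = b_tol

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n_channels = X.shape[1]
        if self.polyorder not in (0, 1, 2):
            raise SpectraError(f"polyorder must be 0, 1 or 2, got {self.polyorder}")
        if isinstance(self.reference, str):
            if self.reference != "mean":
                raise SpectraError(f"unknown reference spec {self.reference!r}")
            self.reference_ = X.mean(axis=0)
        else:
            self.reference_ = np.asarray(self.reference, dtype=float).ravel()
            if self.reference_.size != n_channels:
                raise SpectraError(
                    f"reference length {self.reference_.size} != C={n_channels}"
                )
        if self.weights is None:
            self.weights_ = np.ones(n_channels)
        else:
            self.weights_ = np.asarray(self.weights, dtype=float).ravel()
            if self.weights_.size != n_channels:
                raise SpectraError(
                    f"weights length {self.weights_.size} != C={n_channels}"
                )
            if np.any(self.weights_ < 0):
                raise SpectraError("EMSC weights must be non-negative")
            if not np.any(self.weights_ > 0):
                raise SpectraError("EMSC weights are all zero")
        if self.wavenumbers is None:
            # descending index axis keeps orientation consistent with cm^-1
            self.axis_ = scaled_axis(np.arange(n_channels, 0, -1, dtype=float))
        else:
            self.axis_ = scaled_axis(self.wavenumbers)
        self._design_ = self._build_design()
        return self

    def _build_design(self) -> np.ndarray:
        cols = [np.ones_like(self.reference_), self.reference_]
        if self.polyorder >= 1:
            cols.append(self.axis_)
        if self.polyorder >= 2:
            cols.append(self.axis_**2)
        D = np.column_stack(cols)
        sw = np.sqrt(self.weights_)
        Dw = D * sw[:, None]
        rank = np.linalg.matrix_rank(Dw)
        if rank < D.shape[1]:
            names = ["offset", "reference", "linear", "quadratic"][: D.shape[1]]
            raise SpectraError(
                f"EMSC design is rank deficient (rank {rank} < {D.shape[1]}); "
                f"collinear terms among {names} — is the reference constant?"
            )
        return D

    def correct(self, X):
        """Fit per-sample coefficients and return (corrected, coefficients,
        flagged row indices)."""
        if not hasattr(self, "reference_"):
            raise SpectraError("EMSC is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.reference_.size:
            raise SpectraError(
                f"X has {X.shape[1]} channels, model expects {self.reference_.size}"
            )
        D = self._design_
        sw = np.sqrt(self.weights_)
        beta, *_ = np.linalg.lstsq(D * sw[:, None], (X * sw[None, :]).T, rcond=None)
        beta = beta.T  # (S, p)
        p = D.shape[1]
        coef = np.zeros((X.shape[0], 4))
        coef[:, 0] = beta[:, 0]
        coef[:, 1] = beta[:, 1]
        if p >= 3:
            coef[:, 2] = beta[:, 2]
        if p >= 4:
            coef[:, 3] = beta[:, 3]

        baseline = coef[:, [0]] + np.outer(coef[:, 2], self.axis_) + np.outer(
            coef[:, 3], self.axis_**2
        )
        flagged = [int(i) for i in np.nonzero(coef[:, 1] <= self.b_tol)[0]]
        corrected = X.copy()
        ok = np.ones(X.shape[0], dtype=bool)
        ok[flagged] = False
        corrected[ok] = (X[ok] - baseline[ok]) / coef[ok, 1][:, None]
        if flagged:
            warnings.warn(
                f"EMSC: {len(flagged)} sample(s) with scatter factor b <= "
                f"{self.b_tol:g} left uncorrected",
                stacklevel=2,
            )
        return corrected, coef, flagged

    def transform(self, X):
        corrected, _, _ = self.correct(X)
        return corrected

    def fit_transform(self, X, y=None, **fit_params):
        self.fit(X, y)
        corrected, coef, flagged = self.correct(X)
        self.coefficients_ = coef
        self.flagged_ = flagged
        return corrected


@dataclass(frozen=True)
class SGParams:
    """Savitzky-Golay settings: odd ``window`` (9 or 15 are the usual
    choices here), polynomial degree ``polyorder`` (2), derivative order
    ``deriv`` (2 for second-derivative spectra)."""

    window: int = 9
    polyorder: int = 2
    deriv: int = 2

    def __post_init__(self) -> None:
        if self.window % 2 == 0:
            raise SpectraError(f"S-G window must be odd, got {self.window}")
        if self.window <= self.polyorder:
            raise SpectraError(
                f"S-G window ({self.window}) must exceed polyorder "
                f"({self.polyorder})"
            )
        if self.deriv > self.polyorder:
            raise SpectraError(
                f"S-G deriv ({self.deriv}) cannot exceed polyorder "
                f"({self.polyorder})"
            )


class SavitzkyGolayDerivative(BaseEstimator, TransformerMixin):
    """Savitzky-Golay derivative filter along the channel axis.

    The derivative is taken with respect to channel index (on a uniform
    grid this differs from d/d(cm^-1) only by a constant factor, which a
    subsequent regression absorbs). Edge channels are served by the local
    polynomial fitted to the terminal window, so the grid length is
    preserved.
    """

    def __init__(self, window=9, polyorder=2, deriv=2):
        self.window = window
        self.polyorder = polyorder
        self.deriv = deriv

    def fit(self, X, y=None):
        SGParams(self.window, self.polyorder, self.deriv)  # validates
        return self

    def transform(self, X):
        self.fit(X)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] < self.window:
            raise SpectraError(
                f"window {self.window} exceeds channel count {X.shape[1]}"
            )
        return savgol_filter(
            X, self.window, self.polyorder, deriv=self.deriv, delta=1.0,
            axis=1, mode="interp",
        )


class RegionSelector(BaseEstimator, TransformerMixin):
    """Column selector for a :class:`~lipidir.spectra.RegionSpec` on a fixed
    wavenumber grid; composes with sklearn pipelines."""

    def __init__(self, region: RegionSpec, wavenumbers=None):
        self.region = region
        self.wavenumbers = wavenumbers

    def fit(self, X, y=None):
        if self.wavenumbers is None:
            raise SpectraError("RegionSelector needs the wavenumber grid")
        wn = np.asarray(self.wavenumbers, dtype=float)
        for hi, lo in self.region.intervals:
            if not np.any((wn >= lo) & (wn <= hi)):
                raise SpectraError(
                    f"region {self.region.label!r}: interval ({hi:g}, {lo:g}) "
                    "is outside grid"
                )
        self.mask_ = self.region.mask(wn)
        if not self.mask_.any():
            raise SpectraError(f"region {self.region.label!r} selects no channels")
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X[:, self.mask_]


# ---------------------------------------------------------------------------
# SpectrumSet-level operations
# ---------------------------------------------------------------------------


def fit_emsc(sset: SpectrumSet, reference="mean", weights=None, polyorder=2,
             b_tol=1e-8) -> tuple[EMSCModel, SpectrumSet]:
    """EMSC-correct every spectrum of a set.

    ``weights`` may be ``None`` (uniform), ``"default"`` (inactive-region
    up-weighting via :func:`default_weights`) or an explicit vector.
    Returns the fitted :class:`EMSCModel` and the corrected set
    (stage ``emsc``).
    """
    if isinstance(weights, str):
        if weights != "default":
            raise SpectraError(f"unknown weight spec {weights!r}")
        weights = default_weights(sset.wavenumbers)
    est = EMSC(reference=reference, weights=weights, polyorder=polyorder,
               wavenumbers=sset.wavenumbers, b_tol=b_tol)
    corrected = est.fit_transform(sset.absorbance)
    model = EMSCModel(
        reference=est.reference_,
        weights=est.weights_,
        scaled_axis=est.axis_,
        polyorder=polyorder,
        coefficients=est.coefficients_,
        flagged=est.flagged_,
    )
    out = sset.evolve(absorbance=corrected).with_stage("emsc", "emsc")
    return model, out


def savgol_derivative(sset: SpectrumSet, params: SGParams = SGParams()) -> SpectrumSet:
    """Savitzky-Golay derivative of every spectrum (stage ``deriv2``)."""
    est = SavitzkyGolayDerivative(params.window, params.polyorder, params.deriv)
    out = est.transform(sset.absorbance)
    return sset.evolve(absorbance=out).with_stage(
        "deriv2", f"savgol(w={params.window},p={params.polyorder},d={params.deriv})"
    )


def _average_by(sset: SpectrumSet, keyfunc, rep_fields) -> SpectrumSet:
    from .spectra import SampleMeta

    order: list[tuple] = []
    members: dict[tuple, list[int]] = {}
    for i, s in enumerate(sset.samples):
        k = keyfunc(s)
        if k not in members:
            members[k] = []
            order.append(k)
        members[k].append(i)
    rows, metas = [], []
    for k in order:
        idx = members[k]
        rows.append(sset.absorbance[idx].mean(axis=0))
        proto = sset.samples[idx[0]]
        fields = dict(
            strain=proto.strain, substrate=proto.substrate,
            bio_rep=proto.bio_rep, tech_rep=proto.tech_rep,
        )
        for f in rep_fields:
            fields[f] = 0
        sid = "{}-{}".format(fields["strain"], fields["substrate"])
        if fields["bio_rep"]:
            sid += f"-b{fields['bio_rep']}"
        metas.append(SampleMeta(sample_id=sid, **fields))
    return sset.evolve(absorbance=np.vstack(rows), samples=metas)


def average_replicates(sset: SpectrumSet, level: str = "both") -> SpectrumSet:
    """Average spectra over replicates.

    ``technical`` pools tech_rep within (strain, substrate, bio_rep);
    ``biological`` pools everything within (strain, substrate); ``both``
    applies technical first, then biological (equal to the grand per-
    condition mean on a balanced design). Averaged-out replicate indices
    are set to 0.
    """
    if level not in ("technical", "biological", "both"):
        raise SpectraError(f"unknown averaging level {level!r}")
    out = sset
    if level in ("technical", "both"):
        out = _average_by(out, lambda s: (s.strain, s.substrate, s.bio_rep),
                          ("tech_rep",))
    if level in ("biological", "both"):
        out = _average_by(out, lambda s: (s.strain, s.substrate),
                          ("tech_rep", "bio_rep"))
    return out.with_stage("averaged", f"average({level})")


def extract_regions(sset: SpectrumSet, region: RegionSpec) -> SpectrumSet:
    """Keep only the channels inside the region's closed intervals, in
    descending-wavenumber order (stage ``region``)."""
    sel = RegionSelector(region, wavenumbers=sset.wavenumbers).fit(sset.absorbance)
    out = sset.evolve(
        wavenumbers=sset.wavenumbers[sel.mask_],
        absorbance=sel.transform(sset.absorbance),
    )
    return out.with_stage("region", f"region({region.label or region.intervals})")


def preprocess_strategy(sset: SpectrumSet, strategy: str,
                        sg: SGParams = SGParams(),
                        emsc_reference="mean", emsc_weights="default",
                        emsc_polyorder=2,
                        average: bool = True) -> SpectrumSet:
    """Apply preprocessing strategy ``a`` or ``b`` to a raw set.

    ``a``: EMSC (inactive-region weighting) then replicate averaging —
    used for total-lipid calibration. ``b``: Savitzky-Golay second
    derivative then EMSC against the mean derivative spectrum — used for
    SAT/MUFA/PUFA calibration. ``average=False`` skips the averaging step
    of strategy ``a``.
    """
    if strategy == "a":
        _, corrected = fit_emsc(sset, reference=emsc_reference,
                                weights=emsc_weights, polyorder=emsc_polyorder)
        return average_replicates(corrected, "both") if average else corrected
    if strategy == "b":
        deriv = savgol_derivative(sset, sg)
        _, corrected = fit_emsc(deriv, reference="mean", weights=None,
                                polyorder=emsc_polyorder)
        return corrected
    raise SpectraError(f"unknown preprocessing strategy {strategy!r}")
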