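"""Domain types and file I/O for FTIR spectral data.

The central container is :class:`SpectrumSet`: a wavenumber grid (cm^-1,
stored high-to-low as FTIR instruments export it), an S x C absorbance
matrix, and per-sample metadata describing the experimental design
(strain, growth substrate, biological and technical replicate).

Reference chemistry — gravimetric total lipid (% of cell dry weight) and
GC-derived summed fatty-acid classes (% of total fatty acids) — travels in
a :class:`ReferenceTable` keyed by (strain, substrate, bio_rep).

File formats are plain CSV:

* spectra: wide table, first column ``wavenumber``, one column per sample;
* metadata: ``sample_id,strain,substrate,bio_rep,tech_rep``;
* reference: ``strain,substrate,bio_rep,total_lipid,sat,mufa,pufa[,...]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectraError",
    "SampleMeta",
    "SpectrumSet",
    "RegionSpec",
    "ReferenceTable",
    "read_spectra",
    "write_spectra",
    "read_reference_table",
]

#: Growth substrates used in the screening design: lipid-rich pre-culture
#: medium (P) and nitrogen-limited media with glucose (G), xylose (X) or a
#: 1:1 glucose/xylose mixture (M).
SUBSTRATES = ("P", "G", "X", "M")

STAGES = ("raw", "emsc", "deriv2", "averaged", "region")

#: GC percentages are rounded and a fraction of fatty acids goes
#: unidentified, so sat+mufa+pufa may exceed 100 by a little.
FA_SUM_TOLERANCE = 2.0


class SpectraError(ValueError):
    """Raised for any malformed spectral input or invalid operation."""


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one measured spectrum within the experimental design.

    ``bio_rep``/``tech_rep`` of 0 denote a replicate-averaged spectrum.
    """

    sample_id: str
    strain: str
    substrate: str
    bio_rep: int
    tech_rep: int

    def __post_init__(self) -> None:
        if self.substrate not in SUBSTRATES:
            raise SpectraError(
                f"sample {self.sample_id!r}: substrate {self.substrate!r} "
                f"not one of {SUBSTRATES}"
            )
        if self.bio_rep < 0 or self.tech_rep < 0:
            raise SpectraError(
                f"sample {self.sample_id!r}: replicate indices must be >= 0"
            )

    @property
    def group(self) -> tuple[str, str, int]:
        """Biological-replicate group key (strain, substrate, bio_rep)."""
        return (self.strain, self.substrate, self.bio_rep)


@dataclass
class SpectrumSet:
    """A set of absorbance spectra on a shared, descending wavenumber grid.

    Parameters
    ----------
    wavenumbers : ndarray, shape (C,)
        Strictly decreasing wavenumber grid in cm^-1.
    absorbance : ndarray, shape (S, C)
        One row per sample, finite values only.
    samples : list of SampleMeta
        Length S; sample ids and (strain, substrate, bio_rep, tech_rep)
        tuples must be unique.
    stage : str
        Processing stage, one of ``raw, emsc, deriv2, averaged, region``.
    provenance : tuple of str
        Names of the operations applied so far, oldest first.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    samples: list[SampleMeta]
    stage: str = "raw"
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float).ravel()
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.validate()

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        wn, ab = self.wavenumbers, self.absorbance
        if ab.shape != (len(self.samples), wn.size):
            raise SpectraError(
                f"absorbance shape {ab.shape} does not match "
                f"{len(self.samples)} samples x {wn.size} channels"
            )
        if wn.size < 1 or len(self.samples) < 1:
            raise SpectraError("SpectrumSet must have >= 1 channel and >= 1 sample")
        if wn.size > 1 and not np.all(np.diff(wn) < 0):
            raise SpectraError("wavenumbers must be strictly decreasing")
        if not np.all(np.isfinite(wn)):
            raise SpectraError("wavenumbers contain non-finite values")
        if not np.all(np.isfinite(ab)):
            bad = np.argwhere(~np.isfinite(ab))[0]
            raise SpectraError(
                f"non-finite absorbance at sample {self.samples[bad[0]].sample_id!r}, "
                f"channel {self.wavenumbers[bad[1]]:g} cm^-1"
            )
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SpectraError(f"duplicate sample ids: {dup}")
        keys = [(s.strain, s.substrate, s.bio_rep, s.tech_rep) for s in self.samples]
        if len(set(keys)) != len(keys):
            raise SpectraError("duplicate (strain, substrate, bio_rep, tech_rep) keys")
        if self.stage not in STAGES:
            raise SpectraError(f"unknown stage {self.stage!r}")

    # -- convenience ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.wavenumbers.size

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def meta_frame(self) -> pd.DataFrame:
        """Sample metadata as a DataFrame in row order."""
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "strain": [s.strain for s in self.samples],
                "substrate": [s.substrate for s in self.samples],
                "bio_rep": [s.bio_rep for s in self.samples],
                "tech_rep": [s.tech_rep for s in self.samples],
            }
        )

    def groups(self) -> list[tuple[str, str, int]]:
        """Biological-replicate group key per sample, in row order."""
        return [s.group for s in self.samples]

    def evolve(self, **changes) -> "SpectrumSet":
        """Copy with fields replaced (validation re-runs)."""
        return replace(self, **changes)

    def with_stage(self, stage: str, step: str) -> "SpectrumSet":
        return replace(self, stage=stage, provenance=self.provenance + (step,))

    def subset(self, indices: Sequence[int]) -> "SpectrumSet":
        idx = list(indices)
        return replace(
            self,
            absorbance=self.absorbance[idx],
            samples=[self.samples[i] for i in idx],
        )


@dataclass(frozen=True)
class RegionSpec:
    """A named union of closed wavenumber intervals, e.g. the lipid-relevant
    region (b): 3100-2800 cm^-1 combined with 1800-700 cm^-1.

    Intervals are (hi, lo) with hi > lo; overlapping intervals are merged so
    channel selection never duplicates a channel.
    """

    intervals: tuple[tuple[float, float], ...]
    label: str = ""

    def __post_init__(self) -> None:
        norm = []
        for hi, lo in self.intervals:
            hi, lo = float(hi), float(lo)
            if not hi > lo:
                raise SpectraError(
                    f"region {self.label!r}: interval ({hi}, {lo}) needs hi > lo"
                )
            norm.append((hi, lo))
        norm.sort(key=lambda p: -p[0])
        merged: list[tuple[float, float]] = []
        for hi, lo in norm:
            if merged and hi >= merged[-1][1]:  # touches/overlaps previous
                merged[-1] = (merged[-1][0], min(lo, merged[-1][1]))
            else:
                merged.append((hi, lo))
        object.__setattr__(self, "intervals", tuple(merged))

    def mask(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Boolean mask of grid channels falling inside any interval
        (bounds inclusive)."""
        wn = np.asarray(wavenumbers, dtype=float)
        m = np.zeros(wn.shape, dtype=bool)
        for hi, lo in self.intervals:
            m |= (wn >= lo) & (wn <= hi)
        return m


class ReferenceTable:
    """Per-sample reference chemistry keyed by (strain, substrate, bio_rep).

    Columns: ``total_lipid`` (% of cell dry weight), ``sat``, ``mufa``,
    ``pufa`` (% of total fatty acids) and optionally named fatty acids.
    """

    REQUIRED = ("total_lipid", "sat", "mufa", "pufa")
    KEY = ("strain", "substrate", "bio_rep")

    def __init__(self, frame: pd.DataFrame):
        self.frame = self._validate(frame)

    @staticmethod
    def _validate(frame: pd.DataFrame) -> pd.DataFrame:
        df = frame.copy()
        missing = [c for c in ReferenceTable.KEY + ReferenceTable.REQUIRED
                   if c not in df.columns]
        if missing:
            raise SpectraError(f"reference table missing columns: {missing}")
        df["bio_rep"] = df["bio_rep"].astype(int)
        for col in df.columns:
            if col in ("strain", "substrate"):
                continue
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                row = int(np.argmax(vals.isna().to_numpy()))
                raise SpectraError(
                    f"reference table: non-numeric value in column {col!r}, row {row}"
                )
            df[col] = vals
        bad_sub = ~df["substrate"].isin(SUBSTRATES)
        if bad_sub.any():
            raise SpectraError(
                f"reference table: unknown substrate in rows "
                f"{df.index[bad_sub].tolist()}"
            )
        pct_cols = [c for c in df.columns if c not in ReferenceTable.KEY]
        for col in pct_cols:
            out = (df[col] < 0) | (df[col] > 100)
            if out.any():
                row = int(np.argmax(out.to_numpy()))
                raise SpectraError(
                    f"reference table: {col!r} out of [0, 100] at row {row} "
                    f"(value {df[col].iloc[row]})"
                )
        fa_sum = df["sat"] + df["mufa"] + df["pufa"]
        over = fa_sum > 100.0 + FA_SUM_TOLERANCE
        if over.any():
            row = int(np.argmax(over.to_numpy()))
            raise SpectraError(
                f"reference table: sat+mufa+pufa = {fa_sum.iloc[row]:.2f} > "
                f"{100 + FA_SUM_TOLERANCE} at row {row}"
            )
        dup = df.duplicated(subset=list(ReferenceTable.KEY))
        if dup.any():
            key = tuple(df.loc[dup.idxmax(), list(ReferenceTable.KEY)])
            raise SpectraError(f"reference table: duplicate key {key}")
        return df.reset_index(drop=True)

    # -- lookup --------------------------------------------------------

    def lookup(self, strain: str, substrate: str, bio_rep: int, column: str) -> float:
        df = self.frame
        sel = (
            (df["strain"] == strain)
            & (df["substrate"] == substrate)
            & (df["bio_rep"] == int(bio_rep))
        )
        if not sel.any():
            raise SpectraError(
                f"no reference row for ({strain}, {substrate}, {bio_rep})"
            )
        return float(df.loc[sel, column].iloc[0])

    def align_to(self, sset: SpectrumSet, column: str) -> np.ndarray:
        """Reference values in the sample order of ``sset``.

        Replicate-averaged samples (bio_rep == 0) receive the mean of the
        column over that (strain, substrate)'s biological replicates.
        """
        df = self.frame
        out = np.empty(sset.n_samples)
        for i, s in enumerate(sset.samples):
            if s.bio_rep == 0:
                sel = (df["strain"] == s.strain) & (df["substrate"] == s.substrate)
                if not sel.any():
                    raise SpectraError(
                        f"no reference rows for sample {s.sample_id!r} "
                        f"({s.strain}, {s.substrate})"
                    )
                out[i] = float(df.loc[sel, column].mean())
            else:
                out[i] = self.lookup(s.strain, s.substrate, s.bio_rep, column)
        return out

    @property
    def columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in self.KEY]


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _default_metadata_path(path) -> str:
    path = str(path)
    if path.endswith(".csv"):
        return path[:-4] + ".meta.csv"
    return path + ".meta.csv"


def read_spectra(path, metadata_path=None) -> SpectrumSet:
    """Read a wide spectral CSV plus its metadata sidecar.

    The first spectral column is the wavenumber axis; every other column is
    one sample. Ascending grids are silently re-sorted to the descending
    FTIR convention.
    """
    if metadata_path is None:
        metadata_path = _default_metadata_path(path)
    try:
        wide = pd.read_csv(path)
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise SpectraError(f"cannot parse spectral file {path}: {exc}") from exc
    if wide.shape[1] < 2:
        raise SpectraError(f"spectral file {path} has no sample columns")
    meta = pd.read_csv(metadata_path, dtype={"sample_id": str, "strain": str,
                                             "substrate": str})
    need = {"sample_id", "strain", "substrate", "bio_rep", "tech_rep"}
    if not need.issubset(meta.columns):
        raise SpectraError(
            f"metadata file missing columns: {sorted(need - set(meta.columns))}"
        )

    wn_col = wide.columns[0]
    for col in wide.columns:
        vals = pd.to_numeric(wide[col], errors="coerce")
        if vals.isna().any():
            row = int(np.argmax(vals.isna().to_numpy()))
            raise SpectraError(
                f"non-numeric cell at row {row}, column {col!r} of {path}"
            )
        wide[col] = vals

    wn = wide[wn_col].to_numpy(dtype=float)
    order = np.argsort(-wn, kind="stable")
    wn = wn[order]
    if np.any(np.diff(wn) >= 0):
        raise SpectraError("wavenumbers contain duplicates; grid must be strict")

    sample_ids = [str(c) for c in wide.columns[1:]]
    meta_ids = set(meta["sample_id"])
    for sid in sample_ids:
        if sid not in meta_ids:
            raise SpectraError(f"metadata missing sample {sid!r}")
    extra = meta_ids - set(sample_ids)
    if extra:
        raise SpectraError(f"metadata rows without spectral column: {sorted(extra)}")

    meta_by_id = {row.sample_id: row for row in meta.itertuples(index=False)}
    samples = [
        SampleMeta(
            sample_id=sid,
            strain=str(meta_by_id[sid].strain),
            substrate=str(meta_by_id[sid].substrate),
            bio_rep=int(meta_by_id[sid].bio_rep),
            tech_rep=int(meta_by_id[sid].tech_rep),
        )
        for sid in sample_ids
    ]
    absorbance = wide[wide.columns[1:]].to_numpy(dtype=float).T[:, order]
    return SpectrumSet(wn, absorbance, samples, stage="raw",
                       provenance=("read_spectra",))


def write_spectra(sset: SpectrumSet, path, metadata_path=None) -> None:
    """Write a SpectrumSet to the wide-CSV format (plus metadata sidecar).

    Round-trips through :func:`read_spectra` to 1e-12 relative (pandas
    writes shortest-round-trip float representations).
    """
    if sset.n_samples == 0:  # defensive; constructor already refuses
        raise SpectraError("refusing to write an empty SpectrumSet")
    if metadata_path is None:
        metadata_path = _default_metadata_path(path)
    wide = pd.DataFrame({"wavenumber": sset.wavenumbers})
    for i, sid in enumerate(sset.sample_ids):
        wide[sid] = sset.absorbance[i]
    try:
        wide.to_csv(path, index=False)
        sset.meta_frame().to_csv(metadata_path, index=False)
    except OSError as exc:
        raise SpectraError(f"cannot write {path}: {exc}") from exc


def read_reference_table(path) -> ReferenceTable:
    """Read and validate the reference chemistry CSV."""
    df = pd.read_csv(path, dtype={"strain": str, "substrate": str})
    return ReferenceTable(df)
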