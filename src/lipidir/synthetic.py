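"""Synthetic FTIR spectra of oleaginous yeast biomass with known ground
truth.

The generator emulates a high-throughput FTIR screen of 13 oleaginous
yeast strains grown on four substrates — lipid-rich pre-culture medium (P)
and nitrogen-limited media with glucose (G), xylose (X) or a 1:1
glucose/xylose mix (M) — with two biological replicate cultures per
strain-condition and three technical replicate spectra per culture
(13 x 4 x 2 x 3 = 312 spectra on the default settings). Spectra cover
4000-500 cm^-1 on a uniform 2 cm^-1 grid, a digitisation consistent with
a 6 cm^-1 optical resolution.

Each pure biomass spectrum is a Beer-Lambert linear mixture of
non-negative Gaussian-band component spectra:

* class-specific acyl-chain components (saturated, monounsaturated,
  polyunsaturated) sharing the canonical band centres (2955, 2925, 2850,
  1465, 1380, 1155, 725 cm^-1) with class-dependent amplitude ratios; the
  olefinic =C-H band at 3010 cm^-1 grows with the number of double bonds,
  so its summed weight is approximately proportional to mufa + 2*pufa;
* carbonyl bands: the TAG ester C=O at 1745 cm^-1 and the free-fatty-acid
  carboxyl C=O at 1710 cm^-1, mixed by the FFA share of the lipid pool;
* protein (amide I/II/III), carbohydrate (broad 1200-900 complex) and
  polyphosphate/phospholipid components for the non-lipid biomass.

On top of the pure mixture every technical replicate receives the
distortions that EMSC is designed to remove — a multiplicative scatter
factor b (log-normal), an additive offset and linear/quadratic baseline on
the scaled wavenumber axis — plus a small multiplicative replicate
perturbation and white channel noise. The zero-noise setting reproduces
the pure mixtures exactly, and the emitted reference table is exactly the
latent truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .spectra import ReferenceTable, SampleMeta, SpectraError, SpectrumSet

__all__ = [
    "NoiseModel",
    "SyntheticTruth",
    "default_grid",
    "component_library",
    "sample_truth",
    "generate_spectra",
    "simulate_study",
]

DEFAULT_SUBSTRATES = ("P", "G", "X", "M")

#: Overall gain of the lipid part of the spectrum relative to lipid mass
#: fraction; chosen so a 40 %CDW sample shows acyl peaks near 0.8 AU.
LIPID_GAIN = 2.0
#: Gain of the non-lipid components.
NONLIPID_GAIN = 1.2
#: Carbonyl amplitudes per unit lipid: ester (TAG) and carboxyl (FFA).
ESTER_GAIN = 0.6
FFA_GAIN = 0.9


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def default_grid() -> np.ndarray:
    """Descending 4000..500 cm^-1 grid at 2 cm^-1 spacing (1751 channels)."""
    return np.arange(4000.0, 499.0, -2.0)


def _bands(grid: np.ndarray, bands: list[tuple[float, float, float]]) -> np.ndarray:
    """Sum of Gaussians (center, amplitude, sd) on the grid, max-normalised."""
    y = np.zeros_like(grid)
    for center, amp, sd in bands:
        y += amp * np.exp(-0.5 * ((grid - center) / sd) ** 2)
    m = y.max()
    if m <= 0:
        raise SpectraError("component has no intensity on this grid")
    return y / m


def component_library(grid: np.ndarray) -> dict[str, np.ndarray]:
    """Unit-max, non-negative component spectra on the given grid.

    Keys: ``acyl_sat``, ``acyl_mufa``, ``acyl_pufa`` (fatty-acyl chains by
    saturation class), ``ester_co`` (1745), ``ffa_co`` (1710), ``protein``,
    ``carbohydrate``, ``phosphate``, plus composite ``tag`` and ``ffa``
    lipid spectra for convenience. Acyl bands are narrow (sd ~10 cm^-1),
    amide and carbohydrate bands broad (sd ~25-30 cm^-1).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.max() < 1800.0 or grid.min() > 700.0:
        raise SpectraError("grid too narrow: must span at least 1800-700 cm^-1")

    acyl_common = [
        (2955.0, None, 10.0), (2925.0, None, 10.0), (2850.0, None, 10.0),
        (1465.0, None, 10.0), (1380.0, None, 10.0), (1155.0, None, 12.0),
        (725.0, None, 10.0),
    ]

    def acyl(amp3010, amps):
        spec = [(c, a, sd) for (c, _, sd), a in zip(acyl_common, amps)]
        if amp3010 > 0:
            spec.append((3010.0, amp3010, 10.0))
        return _bands(grid, spec)

    lib = {
        # CH2/CH3 ratios fall and the 3010 =C-H band grows with unsaturation
        "acyl_sat": acyl(0.0, (0.55, 1.0, 0.45, 0.30, 0.18, 0.22, 0.10)),
        "acyl_mufa": acyl(0.20, (0.45, 1.0, 0.42, 0.26, 0.22, 0.25, 0.09)),
        "acyl_pufa": acyl(0.42, (0.40, 1.0, 0.38, 0.22, 0.26, 0.28, 0.08)),
        "ester_co": _bands(grid, [(1745.0, 1.0, 10.0)]),
        "ffa_co": _bands(grid, [(1710.0, 1.0, 10.0)]),
        "protein": _bands(grid, [(1654.0, 1.0, 25.0), (1545.0, 0.75, 25.0),
                                 (1410.0, 0.30, 15.0)]),
        "carbohydrate": _bands(grid, [(1150.0, 0.55, 30.0), (1080.0, 0.85, 30.0),
                                      (1030.0, 1.0, 30.0), (995.0, 0.70, 30.0)]),
        "phosphate": _bands(grid, [(1240.0, 0.80, 20.0), (1080.0, 1.0, 20.0),
                                   (875.0, 0.35, 12.0)]),
    }
    acyl_mean = (lib["acyl_sat"] + lib["acyl_mufa"] + lib["acyl_pufa"]) / 3.0
    lib["tag"] = _bands_renorm(acyl_mean + ESTER_GAIN * lib["ester_co"])
    lib["ffa"] = _bands_renorm(acyl_mean + FFA_GAIN * lib["ffa_co"])
    return lib


def _bands_renorm(y: np.ndarray) -> np.ndarray:
    return y / y.max()


@dataclass
class NoiseModel:
    """Distortion magnitudes applied per technical replicate.

    scatter_sd — sd of log b, the multiplicative scatter factor;
    baseline_sd — sd of the additive offset and of the linear/quadratic
    baseline coefficients on the scaled axis (absorbance units);
    channel_noise_sd — white noise per channel (absorbance units);
    replicate_sd — sd of the scalar multiplicative replicate perturbation.
    """

    scatter_sd: float = 0.15
    baseline_sd: float = 0.02
    channel_noise_sd: float = 5e-4
    replicate_sd: float = 0.01

    def __post_init__(self) -> None:
        for name in ("scatter_sd", "baseline_sd", "channel_noise_sd",
                     "replicate_sd"):
            if getattr(self, name) < 0:
                raise SpectraError(f"{name} must be non-negative")

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0)

    def scaled(self, factor: float) -> "NoiseModel":
        return replace(
            self,
            scatter_sd=self.scatter_sd * factor,
            baseline_sd=self.baseline_sd * factor,
            channel_noise_sd=self.channel_noise_sd * factor,
            replicate_sd=self.replicate_sd * factor,
        )


@dataclass
class SyntheticTruth:
    """Latent biochemical composition per biological sample.

    ``frame`` columns: strain, substrate, bio_rep, total_lipid (%CDW),
    sat/mufa/pufa (% of total FAs), ffa_share (fraction of the lipid pool
    present as free fatty acids), protein/carbohydrate/phosphate loadings
    (arbitrary units).
    """

    frame: pd.DataFrame

    def reference_table(self) -> ReferenceTable:
        cols = ["strain", "substrate", "bio_rep", "total_lipid",
                "sat", "mufa", "pufa"]
        return ReferenceTable(self.frame[cols].copy())


def _substrate_offset(rng, substrate: str) -> float:
    # nitrogen limitation drives lipid accumulation: P lowest, G highest
    lo, hi = {"P": (0.0, 0.0), "G": (18.0, 32.0),
              "X": (4.0, 18.0), "M": (10.0, 26.0)}[substrate]
    return rng.uniform(lo, hi)


def sample_truth(n_strains: int = 13, substrates=DEFAULT_SUBSTRATES,
                 bio_reps: int = 2, seed=None,
                 ffa_share=None) -> SyntheticTruth:
    """Draw a ground-truth composition table for the screening design.

    Per strain: a baseline lipid content; per (strain, substrate): a
    substrate-dependent lipid offset (pre-culture lowest, glucose highest),
    a fatty-acid composition drawn independently of lipid content, an FFA
    share (high in pre-cultures, lower under nitrogen limitation) and the
    non-lipid biomass split; per biological replicate: small jitter on all
    of these. ``ffa_share`` forces a fixed FFA share everywhere (used for
    detector validation). Deterministic under ``seed``; draws are
    hierarchical so adding replicates does not perturb strain-level truth.
    """
    if n_strains < 1 or bio_reps < 1:
        raise SpectraError("n_strains and bio_reps must be >= 1")
    root = _as_seedseq(seed)
    strain_seeds = root.spawn(n_strains)
    rows = []
    for si in range(n_strains):
        strain = f"S{si + 1:02d}"
        s_rng = np.random.default_rng(strain_seeds[si])
        base_lipid = s_rng.uniform(8.0, 20.0)
        cond_seeds = strain_seeds[si].spawn(len(substrates))
        for ci, sub in enumerate(substrates):
            c_rng = np.random.default_rng(cond_seeds[ci])
            lipid = np.clip(base_lipid + _substrate_offset(c_rng, sub)
                            + c_rng.normal(0.0, 2.0), 5.0, 60.0)
            sat = c_rng.uniform(10.0, 45.0)
            pufa = c_rng.uniform(2.0, 25.0)
            mufa = (100.0 - sat - pufa) * c_rng.uniform(0.85, 0.98)
            if ffa_share is None:
                ffa = (c_rng.uniform(0.25, 0.41) if sub == "P"
                       else c_rng.uniform(0.06, 0.28))
            else:
                ffa = float(ffa_share)
                if not 0.0 <= ffa <= 0.45:
                    raise SpectraError("ffa_share must be in [0, 0.45]")
            w = np.array([c_rng.uniform(0.35, 0.55), c_rng.uniform(0.30, 0.50),
                          c_rng.uniform(0.05, 0.15)])
            w /= w.sum()
            rep_seeds = cond_seeds[ci].spawn(bio_reps)
            for bi in range(bio_reps):
                r_rng = np.random.default_rng(rep_seeds[bi])
                tl = float(np.clip(lipid + r_rng.normal(0.0, 1.5), 5.0, 60.0))
                fa = np.array([sat, mufa, pufa]) + r_rng.normal(0.0, 1.2, 3)
                fa = np.clip(fa, 0.5, None)
                if fa.sum() > 100.0:
                    fa *= 100.0 / fa.sum()
                fs = float(np.clip(ffa + (0.0 if ffa_share is not None
                                          else r_rng.normal(0.0, 0.02)),
                                   0.0, 0.45))
                nonlipid = 1.0 - tl / 100.0
                rows.append({
                    "strain": strain, "substrate": sub, "bio_rep": bi + 1,
                    "total_lipid": tl, "sat": float(fa[0]),
                    "mufa": float(fa[1]), "pufa": float(fa[2]),
                    "ffa_share": fs,
                    "protein": nonlipid * w[0],
                    "carbohydrate": nonlipid * w[1],
                    "phosphate": nonlipid * w[2],
                })
    return SyntheticTruth(pd.DataFrame(rows))


def pure_spectrum(row, lib: dict[str, np.ndarray]) -> np.ndarray:
    """Beer-Lambert pure mixture for one truth row."""
    f_l = row["total_lipid"] / 100.0
    f_sat, f_mufa, f_pufa = (row["sat"] / 100.0, row["mufa"] / 100.0,
                             row["pufa"] / 100.0)
    f_other = max(0.0, 1.0 - f_sat - f_mufa - f_pufa)
    acyl = ((f_sat + f_other) * lib["acyl_sat"]
            + f_mufa * lib["acyl_mufa"] + f_pufa * lib["acyl_pufa"])
    ffa = row["ffa_share"]
    carbonyl = (1.0 - ffa) * ESTER_GAIN * lib["ester_co"] + ffa * FFA_GAIN * lib["ffa_co"]
    lipid = LIPID_GAIN * f_l * (acyl + carbonyl)
    nonlipid = NONLIPID_GAIN * (row["protein"] * lib["protein"]
                                + row["carbohydrate"] * lib["carbohydrate"]
                                + row["phosphate"] * lib["phosphate"])
    return lipid + nonlipid


def generate_spectra(truth: SyntheticTruth, noise: NoiseModel | None = None,
                     tech_reps: int = 3, grid=None, seed=None
                     ) -> tuple[SpectrumSet, ReferenceTable]:
    """Render noisy technical-replicate spectra from a truth table.

    Returns the SpectrumSet (stage ``raw``) and the matching reference
    table (exactly the latent truth). ``pure_spectra(truth)`` gives the
    distortion-free mixtures for scoring recovery.
    """
    if noise is None:
        noise = NoiseModel()
    if tech_reps < 1:
        raise SpectraError("tech_reps must be >= 1")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    lib = component_library(grid)
    axis = _scaled(grid)
    root = _as_seedseq(seed)
    row_seeds = root.spawn(len(truth.frame))

    spectra, metas = [], []
    for i, (_, row) in enumerate(truth.frame.iterrows()):
        pure = pure_spectrum(row, lib)
        rep_seeds = row_seeds[i].spawn(tech_reps)
        for t in range(tech_reps):
            rng = np.random.default_rng(rep_seeds[t])
            b = float(np.exp(rng.normal(0.0, noise.scatter_sd)))
            a = rng.normal(0.0, noise.baseline_sd)
            d = rng.normal(0.0, noise.baseline_sd)
            e = rng.normal(0.0, noise.baseline_sd)
            rep = 1.0 + rng.normal(0.0, noise.replicate_sd)
            z = b * rep * pure + a + d * axis + e * axis**2
            if noise.channel_noise_sd > 0:
                z = z + rng.normal(0.0, noise.channel_noise_sd, grid.size)
            spectra.append(z)
            metas.append(SampleMeta(
                sample_id=f"{row['strain']}-{row['substrate']}-"
                          f"b{int(row['bio_rep'])}-t{t + 1}",
                strain=row["strain"], substrate=row["substrate"],
                bio_rep=int(row["bio_rep"]), tech_rep=t + 1,
            ))
    sset = SpectrumSet(grid, np.vstack(spectra), metas, stage="raw",
                       provenance=("simulate",))
    return sset, truth.reference_table()


def pure_spectra(truth: SyntheticTruth, grid=None) -> np.ndarray:
    """Distortion-free mixture per truth row (one row per biological
    sample, not per technical replicate)."""
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    lib = component_library(grid)
    return np.vstack([pure_spectrum(row, lib) for _, row in truth.frame.iterrows()])


def _scaled(grid: np.ndarray) -> np.ndarray:
    lo, hi = grid.min(), grid.max()
    return 2.0 * (grid - lo) / (hi - lo) - 1.0 if hi > lo else np.zeros_like(grid)


def simulate_study(seed=None, n_strains: int = 13, bio_reps: int = 2,
                   tech_reps: int = 3, noise: NoiseModel | None = None,
                   grid=None, ffa_share=None
                   ) -> tuple[SpectrumSet, ReferenceTable, SyntheticTruth]:
    """One-call simulation of the full screening study.

    A single seed drives two independent substreams (truth draws, spectral
    noise), so the truth is unchanged by noise settings and vice versa.
    """
    root = np.random.SeedSequence(seed)
    truth_seed, noise_seed = root.spawn(2)
    truth = sample_truth(n_strains=n_strains, bio_reps=bio_reps,
                         seed=truth_seed, ffa_share=ffa_share)
    sset, ref = generate_spectra(truth, noise=noise, tech_reps=tech_reps,
                                 grid=grid, seed=noise_seed)
    return sset, ref, truth
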