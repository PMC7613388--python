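"""Synthetic validation sets and scenes for end-to-end, download-free runs.

The in-situ generator emulates a small senescent-soybean campaign: dry brown
leaf mass per area (``dmb``, the leaf-level carbon proxy) times brown area
index (``bai``) gives the measured biomass, and the matching spectrum comes
from the forward model at senescent-stage parameters plus sensor resampling
and additive noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import forward_model as fm
from .database import default_distributions
from .exceptions import ValidationError
from .scene_pipeline import (DEFAULT_LEGEND, ClassMap, HyperCube, SensorSpec,
                             prisma_like_sensor, resample_matrix)

#: senescent stands have little chlorophyll left
SENESCENT_CAB_MAX = 10.0


@dataclass(frozen=True)
class InSituRecord:
    spectrum: np.ndarray        # sensor-sampled reflectance
    npv_meas: float             # g/m^2
    dmb: float                  # g/cm^2
    bai: float                  # m^2/m^2


@dataclass(frozen=True)
class SceneSpec:
    """Patchwork scene layout: rectangles (r0, r1, c0, c1) per class code."""

    rows: int = 60
    cols: int = 60
    patches: tuple = ()
    noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        cover = np.zeros((self.rows, self.cols), dtype=int)
        for _, (r0, r1, c0, c1), _ in self.patches:
            if not (0 <= r0 < r1 <= self.rows and 0 <= c0 < c1 <= self.cols):
                raise ValidationError(f"patch region {(r0, r1, c0, c1)} "
                                      "outside the scene")
            cover[r0:r1, c0:c1] += 1
        if np.any(cover > 1):
            raise ValidationError("patches overlap")
        if np.any(cover == 0):
            raise ValidationError("patches do not tile the scene")


def add_noise(spectra: np.ndarray, noise_sd: float, seed: int) -> np.ndarray:
    """Additive i.i.d. Gaussian perturbation, clipped to [0, 1]."""
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    spectra = np.asarray(spectra, dtype=float)
    if noise_sd == 0:
        return spectra.copy()
    rng = np.random.default_rng(seed)
    return np.clip(spectra + rng.normal(0.0, noise_sd, spectra.shape), 0.0, 1.0)


def make_synthetic_insitu(n: int = 14, seed: int = 0,
                          target_mean: float = 55.9, target_sd: float = 31.0,
                          bounds: tuple = (15.7, 111.7),
                          sensor: SensorSpec | None = None,
                          noise_sd: float = 0.005,
                          geom: fm.ViewGeometry = fm.DEFAULT_GEOMETRY
                          ) -> list[InSituRecord]:
    """Emulated field campaign: ``n`` labelled (spectrum, biomass) records."""
    if n < 2:
        raise ValidationError("need n >= 2 records")
    lo, hi = bounds
    if not (lo < target_mean < hi):
        raise ValidationError(
            f"target mean {target_mean} outside bounds {bounds}")
    if target_sd <= 0 or target_sd >= (hi - lo):
        raise ValidationError(f"target sd {target_sd} infeasible for {bounds}")

    rng = np.random.default_rng(seed)
    a, b = (lo - target_mean) / target_sd, (hi - target_mean) / target_sd
    raw = truncnorm.rvs(a, b, loc=target_mean, scale=target_sd, size=n,
                        random_state=rng)
    # affine re-standardization toward the targets, shrinking the spread
    # until every value respects the printed min/max
    scale = target_sd
    std = raw.std()
    for _ in range(200):
        npv = target_mean + (raw - raw.mean()) / std * scale
        if npv.min() >= lo and npv.max() <= hi:
            break
        scale *= 0.95
    else:  # pragma: no cover
        npv = np.clip(npv, lo, hi)

    dists = default_distributions()
    records = []
    for i, value in enumerate(npv):
        bai_lo = max(value / 1.0e4 / fm.LeafParams.BOUNDS["CBC"][1], 0.8)
        bai = float(rng.uniform(bai_lo, 4.0))
        dmb = float(value / (bai * 1.0e4))
        leaf = fm.LeafParams(
            N=float(dists["N"].sample(rng, 1)[0]),
            Cab=float(rng.uniform(0.0, SENESCENT_CAB_MAX)),
            Cxc=float(dists["Cxc"].sample(rng, 1)[0]),
            Cant=float(dists["Cant"].sample(rng, 1)[0]),
            Cbrown=float(dists["Cbrown"].sample(rng, 1)[0]),
            Cw=float(dists["Cw"].sample(rng, 1)[0]),
            Cp=float(dists["Cp"].sample(rng, 1)[0]),
            CBC=dmb,
        )
        canopy = fm.CanopyParams(
            LAI=bai,
            ALIA=float(dists["ALIA"].sample(rng, 1)[0]),
            hotspot=float(dists["hotspot"].sample(rng, 1)[0]),
            psoil=float(dists["psoil"].sample(rng, 1)[0]),
        )
        spec = fm.simulate_canopy(leaf, canopy, geom)
        sens = sensor if sensor is not None else prisma_like_sensor()
        sampled = resample_matrix(spec.wavelengths, spec.reflectance[None, :],
                                  sens)[0]
        sampled = add_noise(sampled, noise_sd, seed=int(rng.integers(2 ** 31)))
        records.append(InSituRecord(spectrum=sampled,
                                    npv_meas=float(dmb * bai * 1.0e4),
                                    dmb=dmb, bai=bai))
    return records


def insitu_to_frame(records: list[InSituRecord],
                    sensor: SensorSpec | None = None) -> pd.DataFrame:
    sens = sensor if sensor is not None else prisma_like_sensor()
    cols = {"npv_meas": [r.npv_meas for r in records],
            "dmb": [r.dmb for r in records],
            "bai": [r.bai for r in records]}
    spectra = np.array([r.spectrum for r in records])
    for j, c in enumerate(sens.band_centers):
        cols[f"{c:g}"] = spectra[:, j]
    return pd.DataFrame(cols)


def save_insitu(records: list[InSituRecord], path: str | Path,
                sensor: SensorSpec | None = None) -> None:
    insitu_to_frame(records, sensor).to_csv(path, index=False)


def load_insitu(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns ``(band_centers, spectra, labels)`` from an in-situ CSV."""
    df = pd.read_csv(path)
    bands = [c for c in df.columns if c not in ("npv_meas", "dmb", "bai")]
    return (np.array([float(c) for c in bands]),
            df[bands].to_numpy(dtype=float),
            df["npv_meas"].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# scenes


def default_scene_spec(rows: int = 60, cols: int = 60, noise_sd: float = 0.005,
                       seed: int = 0) -> SceneSpec:
    """Five vertical strips, one per legend class."""
    edges = np.linspace(0, cols, 6).astype(int)
    patches = tuple(
        (code, (0, rows, int(edges[i]), int(edges[i + 1])), {})
        for i, code in enumerate(sorted(DEFAULT_LEGEND)))
    return SceneSpec(rows, cols, patches, noise_sd, seed)


def _water_spectrum(wl):
    return 0.012 + 0.05 * np.exp(-(wl - 400.0) / 500.0)


def _manmade_spectrum(wl):
    return 0.18 + 4e-5 * (wl - 400.0)


def make_synthetic_scene(spec: SceneSpec | None = None,
                         sensor: SensorSpec | None = None,
                         geom: fm.ViewGeometry = fm.DEFAULT_GEOMETRY
                         ) -> tuple[HyperCube, ClassMap]:
    """Patchwork cube plus its ground-truth class map.

    Senescent-crop pixels are forward-simulated with varying CBC and LAI,
    bare-soil pixels are endmember mixes, green vegetation uses high
    chlorophyll/water, water and man-made surfaces are low/flat spectra.
    """
    spec = spec if spec is not None else default_scene_spec()
    sens = sensor if sensor is not None else prisma_like_sensor()
    rng = np.random.default_rng(spec.seed)
    wl_model = fm.WAVELENGTHS
    dists = default_distributions()

    data = np.zeros((spec.rows, spec.cols, len(sens)))
    labels = np.full((spec.rows, spec.cols), -1, dtype=int)

    for code, (r0, r1, c0, c1), _params in spec.patches:
        npix = (r1 - r0) * (c1 - c0)
        name = DEFAULT_LEGEND.get(code, "")
        if name == "water":
            block = np.tile(resample_matrix(
                wl_model, _water_spectrum(wl_model)[None, :], sens),
                (npix, 1))
        elif name == "man-made":
            block = np.tile(resample_matrix(
                wl_model, _manmade_spectrum(wl_model)[None, :], sens),
                (npix, 1))
        elif name == "bare soils":
            psoils = rng.uniform(0.0, 1.0, npix)
            block = resample_matrix(
                wl_model,
                np.array([fm.mix_soil(p).reflectance for p in psoils]), sens)
        elif name == "forest-natural vegetation":
            rows = []
            for _ in range(npix):
                leaf = fm.LeafParams(Cab=float(rng.uniform(15.0, 20.0)),
                                     Cw=float(rng.uniform(0.012, 0.02)),
                                     CBC=float(rng.uniform(0.001, 0.003)))
                canopy = fm.CanopyParams(LAI=float(rng.uniform(3.0, 4.0)))
                rows.append(fm.simulate_canopy(leaf, canopy, geom).reflectance)
            block = resample_matrix(wl_model, np.array(rows), sens)
        else:  # senescent crops and grasslands
            rows = []
            for _ in range(npix):
                leaf = fm.LeafParams(
                    Cab=float(rng.uniform(0.0, SENESCENT_CAB_MAX)),
                    Cw=float(rng.uniform(0.0, 0.01)),
                    CBC=float(dists["CBC"].sample(rng, 1)[0]),
                    Cbrown=float(rng.uniform(0.1, 0.5)),
                )
                canopy = fm.CanopyParams(
                    LAI=float(dists["LAI"].sample(rng, 1)[0]),
                    psoil=float(rng.uniform(0.0, 1.0)),
                )
                rows.append(fm.simulate_canopy(leaf, canopy, geom).reflectance)
            block = resample_matrix(wl_model, np.array(rows), sens)
        data[r0:r1, c0:c1, :] = block.reshape(r1 - r0, c1 - c0, len(sens))
        labels[r0:r1, c0:c1] = code

    flat = data.reshape(-1, len(sens))
    flat[:] = add_noise(flat, spec.noise_sd, seed=spec.seed + 1)
    cube = HyperCube(data, np.asarray(sens.band_centers, dtype=float))
    return cube, ClassMap(labels, dict(DEFAULT_LEGEND))


def scene_training_samples(cube: HyperCube, truth: ClassMap,
                           per_class: int = 44, seed: int = 0):
    """Random labelled pixels per class, as (spectra, codes)."""
    rng = np.random.default_rng(seed)
    flat = cube.pixels()
    lab = truth.labels.reshape(-1)
    spectra, codes = [], []
    for code in sorted(set(lab[lab >= 0])):
        idx = np.flatnonzero(lab == code)
        pick = rng.choice(idx, size=min(per_class, len(idx)), replace=False)
        spectra.append(flat[pick])
        codes.extend([code] * len(pick))
    return np.vstack(spectra), np.asarray(codes, dtype=int)


def extract_nonvegetated(cube: HyperCube, truth: ClassMap, n: int = 24,
                         seed: int = 0) -> np.ndarray:
    """Sample non-vegetated pixel spectra (man-made, water, bare soil)."""
    nv_codes = truth.codes_for({"man-made", "water", "bare soils"})
    rng = np.random.default_rng(seed)
    lab = truth.labels.reshape(-1)
    idx = np.flatnonzero(np.isin(lab, list(nv_codes)))
    pick = rng.choice(idx, size=min(n, len(idx)), replace=False)
    return cube.pixels()[pick]
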