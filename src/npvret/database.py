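"""Simulated training database: parameter sampling, forward runs, labelling.

The retrieval target is aboveground carbon-based-constituent content
("NPV", g/m^2), defined as the product of the leaf CBC content (g/cm^2) and
the leaf area index, converted from cm^2 to m^2 of leaf area.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import forward_model as fm
from .exceptions import DimensionError, UndefinedValueError, ValidationError

#: canonical column order of the simulated parameter matrix
PARAM_ORDER = ("N", "Cab", "Cxc", "Cant", "Cbrown", "Cw", "Cp", "CBC",
               "LAI", "ALIA", "hotspot", "psoil")


@dataclass(frozen=True)
class ParameterDistribution:
    """Marginal sampling distribution of one simulation variable."""

    kind: str                  # "uniform" | "truncated-gaussian"
    lower: float
    upper: float
    mean: float | None = None
    sd: float | None = None

    def __post_init__(self):
        if self.kind not in ("uniform", "truncated-gaussian"):
            raise ValidationError(f"unknown distribution kind {self.kind!r}")
        if not self.lower < self.upper:
            raise ValidationError(
                f"lower={self.lower!r} must be < upper={self.upper!r}")
        if self.kind == "truncated-gaussian":
            if self.mean is None or self.sd is None:
                raise ValidationError("truncated-gaussian requires mean and sd")
            if not self.lower <= self.mean <= self.upper:
                raise ValidationError(
                    f"mean={self.mean!r} outside [{self.lower}, {self.upper}]")
            if not self.sd > 0:
                raise ValidationError(f"sd={self.sd!r} must be > 0")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "uniform":
            return rng.uniform(self.lower, self.upper, n)
        # truncation by rejection: redraw until inside the bounds, which keeps
        # the Gaussian shape inside the interval
        out = rng.normal(self.mean, self.sd, n)
        bad = (out < self.lower) | (out > self.upper)
        while np.any(bad):
            out[bad] = rng.normal(self.mean, self.sd, int(bad.sum()))
            bad = (out < self.lower) | (out > self.upper)
        return out


def default_distributions() -> dict[str, ParameterDistribution]:
    """Per-variable sampling defaults for senescent cropland states."""
    u = lambda lo, hi: ParameterDistribution("uniform", lo, hi)
    return {
        "N": u(1.0, 2.0),
        "Cab": u(0.0, 20.0),
        "Cxc": u(0.0, 15.0),
        "Cant": u(0.0, 2.0),
        "Cbrown": u(0.0, 0.5),
        "Cw": u(0.0, 0.02),
        "Cp": u(0.0, 0.0025),
        "CBC": ParameterDistribution("truncated-gaussian", 0.0, 0.007,
                                     mean=0.004, sd=0.001),
        "LAI": ParameterDistribution("truncated-gaussian", 0.0, 4.0,
                                     mean=2.0, sd=2.0),
        "ALIA": u(30.0, 70.0),
        "hotspot": u(0.01, 0.5),
        "psoil": u(0.0, 1.0),
    }


def sample_parameters(config: dict[str, ParameterDistribution] | None,
                      n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` joint parameter vectors; deterministic in ``seed``."""
    if n < 1:
        raise ValidationError(f"n={n!r} must be >= 1")
    config = dict(default_distributions(), **(config or {}))
    missing = [v for v in PARAM_ORDER if v not in config]
    if missing:
        raise ValidationError(f"variables without a distribution: {missing}")
    rng = np.random.default_rng(seed)
    # draw in canonical order so the output is independent of dict ordering
    cols = {name: config[name].sample(rng, n) for name in PARAM_ORDER}
    return pd.DataFrame(cols, columns=list(PARAM_ORDER))


def compute_npv(cbc, lai):
    """Aboveground CBC content in g/m^2: ``cbc [g/cm^2] * lai * 1e4``."""
    cbc = np.asarray(cbc, dtype=float)
    lai = np.asarray(lai, dtype=float)
    if np.any(cbc < 0) or np.any(lai < 0):
        raise ValidationError("cbc and lai must be non-negative")
    out = cbc * lai * 1.0e4
    return float(out) if out.ndim == 0 else out


def ndvi(nir, red):
    """Normalized difference vegetation index (NIR - red) / (NIR + red)."""
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    denom = nir + red
    if np.any(denom <= 0):
        raise UndefinedValueError("ndvi undefined for nir + red <= 0")
    out = (nir - red) / denom
    return float(out) if out.ndim == 0 else out


@dataclass
class TrainingSet:
    """Spectra, simulation parameters and NPV labels with provenance flags.

    Non-vegetated rows carry label 0 and all-NaN parameter rows.
    """

    wavelengths: np.ndarray
    spectra: np.ndarray                 # (samples, bands)
    params: pd.DataFrame                # NaN rows for non-vegetated samples
    labels: np.ndarray                  # NPV, g/m^2
    provenance: np.ndarray              # "sim" | "nonvegetated" per row
    manifest: dict = field(default_factory=dict)

    def __post_init__(self):
        n = self.spectra.shape[0]
        if not (len(self.params) == n == len(self.labels) == len(self.provenance)):
            raise DimensionError("row counts disagree across TrainingSet fields")
        if self.spectra.shape[1] != len(self.wavelengths):
            raise DimensionError("spectra width does not match wavelength grid")
        if np.any(self.labels < 0):
            raise ValidationError("labels must be non-negative")

    def __len__(self):
        return self.spectra.shape[0]

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        wide = pd.DataFrame(self.spectra,
                            columns=[f"{w:g}" for w in self.wavelengths])
        wide.to_csv(d / "spectra.csv", index=False)
        self.params.to_csv(d / "params.csv", index=False)
        pd.DataFrame({"npv_g_m2": self.labels,
                      "provenance": self.provenance}).to_csv(
            d / "labels.csv", index=False)
        (d / "manifest.json").write_text(json.dumps(self.manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "TrainingSet":
        d = Path(directory)
        wide = pd.read_csv(d / "spectra.csv")
        labels = pd.read_csv(d / "labels.csv")
        manifest = json.loads((d / "manifest.json").read_text())
        return cls(
            wavelengths=np.array([float(c) for c in wide.columns]),
            spectra=wide.to_numpy(dtype=float),
            params=pd.read_csv(d / "params.csv"),
            labels=labels["npv_g_m2"].to_numpy(dtype=float),
            provenance=labels["provenance"].to_numpy(dtype=object),
            manifest=manifest,
        )


def build_training_set(config: dict[str, ParameterDistribution] | None = None,
                       n: int = 1000, seed: int = 0,
                       geom: fm.ViewGeometry = fm.DEFAULT_GEOMETRY,
                       sensor=None) -> TrainingSet:
    """Sample parameters, run the forward model and label every sample.

    With a :class:`~npvret.scene_pipeline.SensorSpec` passed as ``sensor``,
    spectra are convolved to the sensor bands; otherwise they stay on the
    1 nm model grid.
    """
    params = sample_parameters(config, n, seed)
    leaf_fields = list(PARAM_ORDER[:8])
    canopy_fields = list(PARAM_ORDER[8:])

    rows = []
    for _, row in params.iterrows():
        leaf = fm.LeafParams(**{k: float(row[k]) for k in leaf_fields})
        canopy = fm.CanopyParams(**{k: float(row[k]) for k in canopy_fields})
        rows.append(fm.simulate_canopy(leaf, canopy, geom).reflectance)
    spectra = np.asarray(rows)
    wavelengths = fm.WAVELENGTHS.copy()

    if sensor is not None:
        from .scene_pipeline import resample_matrix
        spectra = resample_matrix(wavelengths, spectra, sensor)
        wavelengths = np.asarray(sensor.band_centers, dtype=float)

    labels = compute_npv(params["CBC"].to_numpy(), params["LAI"].to_numpy())
    manifest = {
        "n": n,
        "seed": seed,
        "geometry": {"sza": geom.sza, "vza": geom.vza, "raa": geom.raa},
        "sensor_bands": None if sensor is None else len(wavelengths),
    }
    return TrainingSet(wavelengths, spectra, params, labels,
                       np.array(["sim"] * n, dtype=object), manifest)


def add_nonvegetated(ts: TrainingSet, nv_spectra: np.ndarray) -> TrainingSet:
    """Append non-vegetated spectra with label 0 g/m^2."""
    nv_spectra = np.atleast_2d(np.asarray(nv_spectra, dtype=float))
    if nv_spectra.size == 0:
        return ts
    if nv_spectra.shape[1] != len(ts.wavelengths):
        raise DimensionError(
            f"non-vegetated spectra have {nv_spectra.shape[1]} bands, "
            f"training set has {len(ts.wavelengths)}")
    k = nv_spectra.shape[0]
    nan_rows = pd.DataFrame(np.full((k, ts.params.shape[1]), np.nan),
                            columns=ts.params.columns)
    return TrainingSet(
        wavelengths=ts.wavelengths,
        spectra=np.vstack([ts.spectra, nv_spectra]),
        params=pd.concat([ts.params, nan_rows], ignore_index=True),
        labels=np.concatenate([ts.labels, np.zeros(k)]),
        provenance=np.concatenate([ts.provenance,
                                   np.array(["nonvegetated"] * k, dtype=object)]),
        manifest=dict(ts.manifest, nonvegetated_added=int(k)),
    )
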