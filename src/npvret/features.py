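"""SWIR band masking and principal-component feature compression."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA

from .exceptions import DimensionError, NoOverlapError, ValidationError

#: lignocellulose analysis window (nm)
SWIR_WINDOW = (1500.0, 2500.0)
#: atmospheric water-vapour windows dropped from every spectrum (nm, open)
WATER_WINDOWS = ((1350.0, 1510.0), (1795.0, 2000.0))


@dataclass(frozen=True)
class BandMask:
    """Keep closed ``keep_windows``, then drop open ``excluded_windows``."""

    keep_windows: tuple = (SWIR_WINDOW,)
    excluded_windows: tuple = WATER_WINDOWS

    def __post_init__(self):
        for windows in (self.keep_windows, self.excluded_windows):
            prev_hi = -np.inf
            for lo, hi in windows:
                if lo >= hi:
                    raise ValidationError(f"window [{lo}, {hi}] is empty")
                if lo < prev_hi:
                    raise ValidationError("windows overlap or are unordered")
                prev_hi = hi

    def selector(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        keep = np.zeros(wl.shape, dtype=bool)
        for lo, hi in self.keep_windows:
            keep |= (wl >= lo) & (wl <= hi)
        for lo, hi in self.excluded_windows:
            keep &= ~((wl > lo) & (wl < hi))
        return keep

    def to_dict(self) -> dict:
        return {"keep_windows": [list(w) for w in self.keep_windows],
                "excluded_windows": [list(w) for w in self.excluded_windows]}

    @classmethod
    def from_dict(cls, d: dict) -> "BandMask":
        return cls(tuple(tuple(w) for w in d["keep_windows"]),
                   tuple(tuple(w) for w in d["excluded_windows"]))


def apply_band_mask(wavelengths: np.ndarray, spectra: np.ndarray,
                    mask: BandMask = BandMask()):
    """Restrict spectra to the masked bands.

    Returns ``(kept_wavelengths, kept_spectra)``; raises
    :class:`NoOverlapError` when nothing survives the mask.
    """
    keep = mask.selector(wavelengths)
    if not np.any(keep):
        raise NoOverlapError("band mask leaves no wavelengths of the input grid")
    spectra = np.asarray(spectra, dtype=float)
    return np.asarray(wavelengths, dtype=float)[keep], spectra[..., keep]


@dataclass
class FeatureBasis:
    """Mean-centred principal-component basis fitted on masked reflectance."""

    wavelengths: np.ndarray             # masked grid the basis lives on
    mean_spectrum: np.ndarray
    loadings: np.ndarray                # (components, bands), orthonormal rows
    explained_variance_ratio: np.ndarray
    explained_variance: np.ndarray      # per-component eigenvalues
    n_components: int
    band_mask: BandMask = field(default_factory=BandMask)

    def save(self, path: str | Path) -> None:
        payload = {
            "n_components": self.n_components,
            "band_mask": self.band_mask.to_dict(),
            "wavelengths": self.wavelengths.tolist(),
            "mean_spectrum": self.mean_spectrum.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "explained_variance": self.explained_variance.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "FeatureBasis":
        d = json.loads(Path(path).read_text())
        return cls(
            wavelengths=np.array(d["wavelengths"], dtype=float),
            mean_spectrum=np.array(d["mean_spectrum"], dtype=float),
            loadings=np.array(d["loadings"], dtype=float),
            explained_variance_ratio=np.array(d["explained_variance_ratio"]),
            explained_variance=np.array(d["explained_variance"]),
            n_components=int(d["n_components"]),
            band_mask=BandMask.from_dict(d["band_mask"]),
        )


def fit_pca(wavelengths: np.ndarray, spectra: np.ndarray,
            n_components: int = 20,
            band_mask: BandMask = BandMask()) -> FeatureBasis:
    """Fit the feature basis on band-masked, mean-centred reflectance.

    Reflectance is not rescaled before the decomposition, so loadings and
    component values stay in reflectance units.
    """
    wl, x = apply_band_mask(wavelengths, spectra, band_mask)
    x = np.atleast_2d(x)
    if x.shape[0] < n_components:
        raise ValidationError(
            f"{x.shape[0]} samples cannot support {n_components} components")
    rank = np.linalg.matrix_rank(x - x.mean(axis=0))
    if rank < n_components:
        raise ValidationError(
            f"input rank {rank} below requested {n_components} components")
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(x)
    return FeatureBasis(
        wavelengths=wl,
        mean_spectrum=pca.mean_,
        loadings=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        explained_variance=pca.explained_variance_,
        n_components=n_components,
        band_mask=band_mask,
    )


def transform(basis: FeatureBasis, spectra: np.ndarray) -> np.ndarray:
    """Project band-masked spectra onto the basis: ``(x - mean) @ loadings.T``."""
    x = np.atleast_2d(np.asarray(spectra, dtype=float))
    if x.shape[1] != len(basis.wavelengths):
        raise DimensionError(
            f"spectra have {x.shape[1]} bands, basis expects "
            f"{len(basis.wavelengths)}")
    return (x - basis.mean_spectrum) @ basis.loadings.T


def features_from_full_grid(basis: FeatureBasis, wavelengths: np.ndarray,
                            spectra: np.ndarray) -> np.ndarray:
    """Band-mask full-grid spectra with the basis mask, then project.

    The masked grid must match the grid the basis was fitted on.
    """
    wl, x = apply_band_mask(wavelengths, spectra, basis.band_mask)
    if len(wl) != len(basis.wavelengths) or not np.allclose(wl, basis.wavelengths):
        raise DimensionError("masked grid differs from the basis grid")
    return transform(basis, x)
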