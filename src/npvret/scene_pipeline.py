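"""Hyperspectral cube preprocessing, classification and per-pixel mapping.

Cubes are exchanged in ENVI style: a flat binary payload next to a plain-text
header carrying the wavelength list, interleave and nodata sentinel.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import UnivariateSpline
from scipy.spatial.distance import cdist
from sklearn.metrics import accuracy_score, cohen_kappa_score
from sklearn.model_selection import StratifiedKFold

from .exceptions import DimensionError, ValidationError
from .features import FeatureBasis, features_from_full_grid
from .forward_model import CanopySpectrum
from .regression import GPRModel, predict

NODATA = -9999.0

#: legend used throughout: code -> surface type
DEFAULT_LEGEND = {
    0: "man-made",
    1: "water",
    2: "forest-natural vegetation",
    3: "crops and grasslands",
    4: "bare soils",
}

#: classes processed by the retrieval model
DEFAULT_MASK_CLASSES = frozenset({"crops and grasslands", "bare soils"})


@dataclass
class HyperCube:
    """rows x cols x bands reflectance raster with a wavelength axis."""

    data: np.ndarray
    wavelengths: np.ndarray
    nodata: float = NODATA
    crs: str | None = None
    geotransform: tuple | None = None

    def __post_init__(self):
        if self.data.ndim != 3:
            raise DimensionError("cube data must be rows x cols x bands")
        if self.data.shape[2] != len(self.wavelengths):
            raise DimensionError("band count does not match wavelength list")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValidationError("wavelengths must be strictly increasing")

    @property
    def shape(self):
        return self.data.shape

    def pixels(self) -> np.ndarray:
        """(rows*cols, bands) view of the cube."""
        r, c, b = self.data.shape
        return self.data.reshape(r * c, b)


@dataclass(frozen=True)
class SensorSpec:
    """Band centers and full-width-half-maximum of a target sensor."""

    band_centers: np.ndarray
    fwhm: np.ndarray

    def __post_init__(self):
        centers = np.asarray(self.band_centers, dtype=float)
        fwhm = np.asarray(self.fwhm, dtype=float)
        if np.any(np.diff(centers) <= 0):
            raise ValidationError("band centers must be strictly increasing")
        if np.any(fwhm <= 0) or len(fwhm) != len(centers):
            raise ValidationError("fwhm must be positive, one per band")
        object.__setattr__(self, "band_centers", centers)
        object.__setattr__(self, "fwhm", fwhm)

    def __len__(self):
        return len(self.band_centers)


def prisma_like_sensor() -> SensorSpec:
    """A 234-band, ~9 nm sampling, 10 nm FWHM spectrometer on 400-2500 nm."""
    centers = np.linspace(405.0, 2495.0, 234)
    return SensorSpec(centers, np.full(234, 10.0))


@dataclass
class ClassMap:
    labels: np.ndarray                  # rows x cols integer codes
    legend: dict = field(default_factory=lambda: dict(DEFAULT_LEGEND))
    nodata: int = -1

    def codes_for(self, names) -> set[int]:
        by_name = {v: k for k, v in self.legend.items()}
        return {by_name[n] for n in names if n in by_name}


@dataclass
class NPVMap:
    estimate: np.ndarray
    sd: np.ndarray
    cv: np.ndarray
    mask_classes: tuple
    nodata: float = NODATA

    def valid_mask(self) -> np.ndarray:
        return self.estimate != self.nodata


# ---------------------------------------------------------------------------
# spectrum-level preprocessing


def despike(spectrum: np.ndarray, threshold: float = 0.018) -> np.ndarray:
    """Replace isolated spikes by linear interpolation of their neighbours.

    A band is a spike when it protrudes above (or below) both neighbours by
    more than ``threshold``.  The sweep repeats until no spike remains, so the
    operation is idempotent.
    """
    x = np.asarray(spectrum, dtype=float).copy()
    if x.size < 3:
        raise ValidationError("despike needs at least 3 bands")
    flagged_total = 0
    for _ in range(x.size):
        up = np.minimum(x[1:-1] - x[:-2], x[1:-1] - x[2:]) > threshold
        down = np.minimum(x[:-2] - x[1:-1], x[2:] - x[1:-1]) > threshold
        spikes = up | down
        if not spikes.any():
            break
        idx = np.flatnonzero(spikes) + 1
        x[idx] = 0.5 * (x[idx - 1] + x[idx + 1])
        flagged_total += len(idx)
    if flagged_total > x.size // 2:
        warnings.warn("more than half of the bands were flagged as spikes; "
                      "the spectrum is likely degenerate")
    return x


def smooth_spline(wavelengths: np.ndarray, spectrum: np.ndarray,
                  stiffness: float = 1.0) -> np.ndarray:
    """Smoothing spline across valid (finite) bands, evaluated on the full
    grid, which also fills masked gaps.

    The smoothing factor adapts to a robust noise estimate from second
    differences, scaled by ``stiffness``; noise-free smooth spectra are
    reproduced nearly exactly.
    """
    wl = np.asarray(wavelengths, dtype=float)
    x = np.asarray(spectrum, dtype=float)
    valid = np.isfinite(x)
    if valid.sum() < 4:
        raise ValidationError("smooth_spline needs at least 4 valid bands")
    w, v = wl[valid], x[valid]
    d2 = np.diff(v, 2)
    sigma = 1.4826 * np.median(np.abs(d2)) / math.sqrt(6.0) if d2.size else 0.0
    s = stiffness * len(v) * sigma ** 2
    spl = UnivariateSpline(w, v, s=s, k=3)
    return spl(wl)


def resample_to_sensor(model_spectrum: CanopySpectrum,
                       sensor: SensorSpec) -> np.ndarray:
    """Convolve a fine-grid spectrum with Gaussian band responses."""
    return resample_matrix(model_spectrum.wavelengths,
                           model_spectrum.reflectance[None, :], sensor)[0]


def _srf_matrix(wl_in: np.ndarray, sensor: SensorSpec) -> np.ndarray:
    wl_in = np.asarray(wl_in, dtype=float)
    lo, hi = wl_in[0], wl_in[-1]
    outside = [(c, f) for c, f in zip(sensor.band_centers, sensor.fwhm)
               if not lo <= c <= hi]
    if outside:
        raise ValidationError(
            f"band centers outside the model grid: "
            f"{[c for c, _ in outside]}")
    step = np.min(np.diff(wl_in)) if wl_in.size > 1 else 1.0
    weights = np.zeros((len(sensor), len(wl_in)))
    for i, (c, f) in enumerate(zip(sensor.band_centers, sensor.fwhm)):
        sigma = f / 2.355
        if sigma < 0.5 * step:
            weights[i, np.argmin(np.abs(wl_in - c))] = 1.0
            continue
        w = np.exp(-0.5 * ((wl_in - c) / sigma) ** 2)
        weights[i] = w / w.sum()
    return weights


def resample_matrix(wl_in: np.ndarray, spectra: np.ndarray,
                    sensor: SensorSpec) -> np.ndarray:
    """Sensor-resample many spectra at once: ``spectra @ W.T``."""
    return np.atleast_2d(np.asarray(spectra, dtype=float)) \
        @ _srf_matrix(wl_in, sensor).T


def preprocess_cube(cube: HyperCube, threshold: float = 0.018,
                    smooth: bool = False, stiffness: float = 1.0) -> HyperCube:
    """Despike (and optionally spline-smooth) every valid pixel spectrum."""
    out = cube.data.copy()
    r, c, b = out.shape
    flat = out.reshape(r * c, b)
    valid = ~np.any(flat == cube.nodata, axis=1)
    for i in np.flatnonzero(valid):
        flat[i] = despike(flat[i], threshold)
        if smooth:
            flat[i] = smooth_spline(cube.wavelengths, flat[i], stiffness)
    return HyperCube(out, cube.wavelengths.copy(), cube.nodata,
                     cube.crs, cube.geotransform)


# ---------------------------------------------------------------------------
# classification


def classify_scene(cube: HyperCube, sample_spectra: np.ndarray,
                   sample_codes: np.ndarray, basis: FeatureBasis,
                   legend: dict | None = None, seed: int = 0):
    """1-nearest-neighbour surface classification in feature space.

    Returns ``(ClassMap, cv_report)`` where the report holds overall accuracy
    and Cohen's kappa from a stratified 3-fold cross-validation of the
    labelled samples.  Nearest-neighbour ties resolve to the lowest sample
    index.
    """
    legend = dict(DEFAULT_LEGEND) if legend is None else dict(legend)
    codes = np.asarray(sample_codes, dtype=int)
    counts = {int(c): int((codes == c).sum()) for c in np.unique(codes)}
    thin = {c: k for c, k in counts.items() if k < 3}
    if thin:
        raise ValidationError(
            f"classes with fewer than 3 samples cannot be stratified "
            f"3-fold: {thin}")

    train_feats = features_from_full_grid(basis, cube.wavelengths,
                                          np.asarray(sample_spectra, float))

    # stratified 3-fold cross-validation report
    skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    truths, preds = [], []
    for fit_idx, test_idx in skf.split(train_feats, codes):
        d = cdist(train_feats[test_idx], train_feats[fit_idx])
        preds.extend(codes[fit_idx][np.argmin(d, axis=1)])
        truths.extend(codes[test_idx])
    cv_report = {
        "overall_accuracy": float(accuracy_score(truths, preds)),
        "kappa": float(cohen_kappa_score(truths, preds)),
        "n_samples": int(len(codes)),
        "n_folds": 3,
    }

    flat = cube.pixels()
    valid = ~np.any(flat == cube.nodata, axis=1)
    labels = np.full(flat.shape[0], -1, dtype=int)
    if valid.any():
        feats = features_from_full_grid(basis, cube.wavelengths, flat[valid])
        d = cdist(feats, train_feats)
        labels[valid] = codes[np.argmin(d, axis=1)]
    r, c, _ = cube.shape
    return ClassMap(labels.reshape(r, c), legend), cv_report


# ---------------------------------------------------------------------------
# mapping


def map_npv(cube: HyperCube, classmap: ClassMap, model: GPRModel,
            basis: FeatureBasis,
            mask_classes=DEFAULT_MASK_CLASSES) -> NPVMap:
    """Apply the retrieval model to the pixels of the masked classes.

    All other pixels are nodata in the estimate, SD and CV layers.
    """
    mask_classes = tuple(mask_classes)
    wanted = classmap.codes_for(mask_classes)
    present = set(np.unique(classmap.labels)) & wanted
    r, c, _ = cube.shape
    est = np.full((r, c), NODATA)
    sd = np.full((r, c), NODATA)
    cv = np.full((r, c), NODATA)
    if not present:
        warnings.warn("none of the mask classes occur in the class map; "
                      "the output is empty")
        return NPVMap(est, sd, cv, mask_classes)

    flat = cube.pixels()
    sel = np.isin(classmap.labels.reshape(-1), list(wanted))
    sel &= ~np.any(flat == cube.nodata, axis=1)
    feats = features_from_full_grid(basis, cube.wavelengths, flat[sel])
    p = predict(model, feats)
    est.reshape(-1)[sel] = p.mean
    sd.reshape(-1)[sel] = p.sd
    cv_flat = np.where(np.isnan(p.cv), NODATA, p.cv)
    cv.reshape(-1)[sel] = cv_flat
    return NPVMap(est, sd, cv, mask_classes)


# ---------------------------------------------------------------------------
# ENVI-style cube I/O


def write_envi(cube: HyperCube, stem: str | Path) -> Path:
    """Write ``<stem>.img`` (float32 BSQ) and ``<stem>.hdr``."""
    stem = Path(stem)
    r, c, b = cube.shape
    np.ascontiguousarray(cube.data.transpose(2, 0, 1),
                         dtype="<f4").tofile(stem.with_suffix(".img"))
    wl = ", ".join(f"{w:.12g}" for w in cube.wavelengths)
    hdr = (
        "ENVI\n"
        f"samples = {c}\nlines = {r}\nbands = {b}\n"
        "header offset = 0\nfile type = ENVI Standard\n"
        "data type = 4\ninterleave = bsq\nbyte order = 0\n"
        f"data ignore value = {cube.nodata:.12g}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    if cube.crs:
        hdr += f"coordinate system string = {{{cube.crs}}}\n"
    if cube.geotransform:
        gt = ", ".join(f"{v:.12g}" for v in cube.geotransform)
        hdr += f"map info = {{ {gt} }}\n"
    stem.with_suffix(".hdr").write_text(hdr)
    return stem.with_suffix(".img")


def read_envi(stem: str | Path) -> HyperCube:
    stem = Path(stem)
    fields = {}
    text = stem.with_suffix(".hdr").read_text()
    # fold multi-line { } values onto one line
    text = text.replace("\n", " \n")
    import re
    for m in re.finditer(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)",
                         text, re.MULTILINE | re.DOTALL):
        fields[m.group(1).strip().lower()] = m.group(2).strip()
    r = int(fields["lines"])
    c = int(fields["samples"])
    b = int(fields["bands"])
    wl = np.array([float(v) for v in
                   fields["wavelength"].strip("{} ").split(",")])
    nodata = float(fields.get("data ignore value", NODATA))
    raw = np.fromfile(stem.with_suffix(".img"), dtype="<f4")
    interleave = fields.get("interleave", "bsq").lower()
    if interleave != "bsq":
        raise ValidationError(f"unsupported interleave {interleave!r}")
    data = raw.reshape(b, r, c).transpose(1, 2, 0).astype(float)
    crs = fields.get("coordinate system string", "").strip("{} ") or None
    gt = fields.get("map info")
    geotransform = tuple(float(v) for v in gt.strip("{} ").split(",")) \
        if gt else None
    return HyperCube(data, wl, nodata, crs, geotransform)


def write_classmap(classmap: ClassMap, stem: str | Path) -> Path:
    """Persist a class map as single-band ENVI plus a JSON legend sidecar."""
    stem = Path(stem)
    cube = HyperCube(classmap.labels[:, :, None].astype(float),
                     np.array([0.0]), nodata=float(classmap.nodata))
    write_envi(cube, stem)
    stem.with_suffix(".json").write_text(json.dumps(
        {"legend": {str(k): v for k, v in classmap.legend.items()},
         "nodata": classmap.nodata}, indent=2))
    return stem.with_suffix(".img")


def read_classmap(stem: str | Path) -> ClassMap:
    stem = Path(stem)
    cube = read_envi(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    return ClassMap(cube.data[:, :, 0].astype(int),
                    {int(k): v for k, v in meta["legend"].items()},
                    int(meta.get("nodata", -1)))


def write_npv_map(npv: NPVMap, stem: str | Path,
                  provenance: dict | None = None) -> Path:
    """Persist the three layers as an ENVI cube plus a JSON provenance file."""
    stem = Path(stem)
    data = np.stack([npv.estimate, npv.sd, npv.cv], axis=-1)
    cube = HyperCube(data, np.array([1.0, 2.0, 3.0]), nodata=npv.nodata)
    write_envi(cube, stem)
    meta = {"layers": ["estimate_g_m2", "sd_g_m2", "cv"],
            "mask_classes": list(npv.mask_classes),
            "nodata": npv.nodata}
    if provenance:
        meta.update(provenance)
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return stem.with_suffix(".img")
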