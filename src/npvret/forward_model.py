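"""Coupled leaf/canopy radiative transfer on a 400-2500 nm, 1 nm grid.

The leaf model is a generalized plate model with eight absorbers (structure
parameter ``N`` plus seven specific-absorption coefficients, including protein
and carbon-based constituents).  The canopy model is the classical four-stream
turbid-medium solution for arbitrarily inclined leaves, with a hot-spot
correction and a two-endmember (dry/wet) soil background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from functools import lru_cache
from importlib import resources

import numpy as np
from scipy.special import exp1

from .exceptions import ConfigurationError, DimensionError, ValidationError

WL_MIN, WL_MAX, WL_STEP = 400, 2500, 1

#: canonical 1 nm simulation grid
WAVELENGTHS = np.arange(WL_MIN, WL_MAX + 1, WL_STEP, dtype=float)

#: leaf inclination quadrature angles (degrees) used by the canopy model
_LITAB = np.array([5, 15, 25, 35, 45, 55, 65, 75, 81, 83, 85, 87, 89], dtype=float)


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class LeafParams:
    """Leaf biochemistry and structure driving the plate model."""

    N: float = 1.5          # structure parameter, unitless
    Cab: float = 10.0       # chlorophyll, ug/cm^2
    Cxc: float = 5.0        # carotenoids, ug/cm^2
    Cant: float = 1.0       # anthocyanins, ug/cm^2
    Cbrown: float = 0.25    # brown pigments, unitless
    Cw: float = 0.01        # equivalent water thickness, cm
    Cp: float = 0.00125     # protein, g/cm^2
    CBC: float = 0.0035     # carbon-based constituents, g/cm^2

    BOUNDS = {
        "N": (1.0, 2.0),
        "Cab": (0.0, 20.0),
        "Cxc": (0.0, 15.0),
        "Cant": (0.0, 2.0),
        "Cbrown": (0.0, 0.5),
        "Cw": (0.0, 0.02),
        "Cp": (0.0, 0.0025),
        "CBC": (0.0, 0.007),
    }

    def __post_init__(self):
        _check_bounds(self)


@dataclass(frozen=True)
class CanopyParams:
    """Canopy structure and soil background."""

    LAI: float = 2.0        # leaf area index, m^2/m^2
    ALIA: float = 50.0      # average leaf inclination angle, degree
    hotspot: float = 0.1    # hot-spot size parameter, unitless
    psoil: float = 0.5      # soil brightness factor in [0, 1]

    BOUNDS = {
        "LAI": (0.0, 4.0),
        "ALIA": (30.0, 70.0),
        "hotspot": (0.01, 0.5),
        "psoil": (0.0, 1.0),
    }

    def __post_init__(self):
        _check_bounds(self)


@dataclass(frozen=True)
class ViewGeometry:
    """Sun/view geometry in degrees."""

    sza: float = 30.0
    vza: float = 0.0
    raa: float = 0.0

    def __post_init__(self):
        for name in ("sza", "vza"):
            v = getattr(self, name)
            if not 0.0 <= v < 90.0:
                raise ValidationError(f"{name}={v!r} outside [0, 90)")


DEFAULT_GEOMETRY = ViewGeometry()


def _check_bounds(obj):
    for f in fields(obj):
        lo, hi = obj.BOUNDS[f.name]
        v = getattr(obj, f.name)
        if not np.isfinite(v) or v < lo or v > hi:
            raise ValidationError(
                f"{type(obj).__name__}.{f.name}={v!r} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class LeafOptics:
    wavelengths: np.ndarray
    reflectance: np.ndarray
    transmittance: np.ndarray


@dataclass(frozen=True)
class CanopySpectrum:
    wavelengths: np.ndarray
    reflectance: np.ndarray


# ---------------------------------------------------------------------------
# package data


@lru_cache(maxsize=1)
def _coefficients():
    try:
        path = resources.files("npvret") / "data" / "leaf_coefficients.csv"
        raw = np.genfromtxt(str(path), delimiter=",", names=True)
    except (FileNotFoundError, OSError) as exc:  # pragma: no cover
        raise ConfigurationError("leaf coefficient table missing") from exc
    if not np.array_equal(raw["wavelength_nm"], WAVELENGTHS):  # pragma: no cover
        raise ConfigurationError("coefficient table grid differs from 400-2500/1 nm")
    return raw


@lru_cache(maxsize=1)
def _soil_endmembers():
    try:
        path = resources.files("npvret") / "data" / "soil_endmembers.csv"
        raw = np.genfromtxt(str(path), delimiter=",", names=True)
    except (FileNotFoundError, OSError) as exc:  # pragma: no cover
        raise ConfigurationError("soil endmember table missing") from exc
    return raw["dry"].copy(), raw["wet"].copy()


# ---------------------------------------------------------------------------
# leaf model


def _tav(theta_deg: float, n: np.ndarray) -> np.ndarray:
    """Average transmissivity of a dielectric interface for isotropic light
    restricted to a cone of half-angle ``theta_deg`` (Stern's integral)."""
    if theta_deg == 0.0:
        return 4.0 * n / (n + 1.0) ** 2
    theta = math.radians(theta_deg)
    n2 = n * n
    a = (n + 1.0) ** 2 / 2.0
    k = -((n2 - 1.0) ** 2) / 4.0
    ds = math.sin(theta)
    ds2 = ds * ds
    if theta == math.pi / 2.0:
        b1 = np.zeros_like(n)
    else:
        b1 = np.sqrt((ds2 - (n2 + 1.0) / 2.0) ** 2 + k)
    b2 = ds2 - (n2 + 1.0) / 2.0
    b = b1 - b2
    ts = (k ** 2 / (6.0 * b ** 3) + k / b - b / 2.0) \
        - (k ** 2 / (6.0 * a ** 3) + k / a - a / 2.0)
    tp1 = -2.0 * n2 * (b - a) / (n2 + 1.0) ** 2
    tp2 = -2.0 * n2 * (n2 + 1.0) * np.log(b / a) / (n2 - 1.0) ** 2
    tp3 = n2 * (1.0 / b - 1.0 / a) / 2.0
    q = (n2 - 1.0) ** 2
    p = 2.0 * (n2 + 1.0)
    tp4 = 16.0 * n2 ** 2 * (n2 ** 2 + 1.0) \
        * np.log((p * b - q) / (p * a - q)) / ((n2 + 1.0) ** 3 * q)
    tp5 = 16.0 * n2 ** 3 * (1.0 / (p * b - q) - 1.0 / (p * a - q)) / (n2 + 1.0) ** 3
    tp = tp1 + tp2 + tp3 + tp4 + tp5
    return (ts + tp) / (2.0 * ds2)


def _layer_transmission(kall: np.ndarray) -> np.ndarray:
    """Isotropic transmission through one elementary absorbing layer."""
    tau = np.ones_like(kall)
    j = kall > 0.0
    kj = kall[j]
    tau[j] = (1.0 - kj) * np.exp(-kj) + kj ** 2 * exp1(kj)
    return tau


def prospect_pro(leaf: LeafParams) -> LeafOptics:
    """Simulate leaf hemispherical reflectance and transmittance."""
    c = _coefficients()
    nr = c["refractive_index"]
    kall = (leaf.Cab * c["kab"] + leaf.Cxc * c["kcar"] + leaf.Cant * c["kant"]
            + leaf.Cbrown * c["kbrown"] + leaf.Cw * c["kw"]
            + leaf.Cp * c["kp"] + leaf.CBC * c["kcbc"]) / leaf.N
    tau = _layer_transmission(kall)

    talf = _tav(40.0, nr)
    ralf = 1.0 - talf
    t12 = _tav(90.0, nr)
    r12 = 1.0 - t12
    t21 = t12 / nr ** 2
    r21 = 1.0 - t21

    # top (air-interface) layer
    denom = 1.0 - r21 ** 2 * tau ** 2
    Ta = talf * tau * t21 / denom
    Ra = ralf + r21 * tau * Ta
    # generic internal layer
    t = t12 * tau * t21 / denom
    r = r12 + r21 * tau * t

    # Stokes solution for a stack of N-1 internal layers
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.sqrt(np.maximum(
            (1.0 + r + t) * (1.0 + r - t) * (1.0 - r + t) * (1.0 - r - t), 0.0))
        rq = r ** 2
        tq = t ** 2
        a = (1.0 + rq - tq + D) / (2.0 * r)
        b = (1.0 - rq + tq + D) / (2.0 * t)
        bNm1 = b ** (leaf.N - 1.0)
        bN2 = bNm1 ** 2
        a2 = a ** 2
        denom = a2 * bN2 - 1.0
        Rsub = a * (bN2 - 1.0) / denom
        Tsub = bNm1 * (a2 - 1.0) / denom

    # non-absorbing limit (r + t -> 1): algebraic, not exponential, stack
    j = (r + t) >= 1.0
    if np.any(j):
        Tsub[j] = t[j] / (t[j] + (1.0 - t[j]) * (leaf.N - 1.0))
        Rsub[j] = 1.0 - Tsub[j]

    denom = 1.0 - Rsub * r
    tran = Ta * Tsub / denom
    refl = Ra + Ta * Rsub * t / denom
    return LeafOptics(WAVELENGTHS.copy(), refl, tran)


# ---------------------------------------------------------------------------
# soil


def mix_soil(psoil: float) -> CanopySpectrum:
    """Linear mix ``psoil * dry + (1 - psoil) * wet`` of the soil endmembers."""
    if not (np.isfinite(psoil) and 0.0 <= psoil <= 1.0):
        raise ValidationError(f"psoil={psoil!r} outside [0, 1]")
    dry, wet = _soil_endmembers()
    return CanopySpectrum(WAVELENGTHS.copy(), psoil * dry + (1.0 - psoil) * wet)


# ---------------------------------------------------------------------------
# canopy model


def _campbell_lidf(alia: float) -> np.ndarray:
    """Ellipsoidal leaf-inclination distribution for a mean angle (degrees),
    integrated over the 13 quadrature bins."""
    excent = math.exp(-1.6184e-5 * alia ** 3 + 2.1145e-3 * alia ** 2
                      - 1.2390e-1 * alia + 3.2491)
    bounds = [(i * 10.0, (i + 1) * 10.0) for i in range(8)]
    bounds += [(80.0 + 2.0 * i, 82.0 + 2.0 * i) for i in range(5)]
    freq = np.empty(13)
    for i, (tl1d, tl2d) in enumerate(bounds):
        tl1 = math.radians(tl1d)
        tl2 = math.radians(tl2d)
        x1 = excent / math.sqrt(1.0 + excent ** 2 * math.tan(tl1) ** 2)
        x2 = excent / math.sqrt(1.0 + excent ** 2 * math.tan(tl2) ** 2)
        if excent == 1.0:
            freq[i] = abs(math.cos(tl1) - math.cos(tl2))
        else:
            alph = excent / math.sqrt(abs(1.0 - excent ** 2))
            alph2 = alph ** 2
            x12, x22 = x1 ** 2, x2 ** 2
            if excent > 1.0:
                alpx1 = math.sqrt(alph2 + x12)
                alpx2 = math.sqrt(alph2 + x22)
                dum = x1 * alpx1 + alph2 * math.log(x1 + alpx1)
                freq[i] = abs(dum - (x2 * alpx2 + alph2 * math.log(x2 + alpx2)))
            else:
                almx1 = math.sqrt(alph2 - x12)
                almx2 = math.sqrt(alph2 - x22)
                dum = x1 * almx1 + alph2 * math.asin(x1 / alph)
                freq[i] = abs(dum - (x2 * almx2 + alph2 * math.asin(x2 / alph)))
    return freq / freq.sum()


def _volscatt(tts: float, tto: float, psi: float, ttl: float):
    """Geometric factors of one leaf-inclination class: projections in the sun
    and view directions and the bidirectional scattering fractions."""
    cts = math.cos(math.radians(tts))
    cto = math.cos(math.radians(tto))
    sts = math.sin(math.radians(tts))
    sto = math.sin(math.radians(tto))
    cospsi = math.cos(math.radians(psi))
    psir = math.radians(psi)
    cttl = math.cos(math.radians(ttl))
    sttl = math.sin(math.radians(ttl))
    cs = cttl * cts
    co = cttl * cto
    ss = sttl * sts
    so = sttl * sto

    cosbts = 5.0
    if abs(ss) > 1e-6:
        cosbts = -cs / ss
    cosbto = 5.0
    if abs(so) > 1e-6:
        cosbto = -co / so

    if abs(cosbts) < 1.0:
        bts = math.acos(cosbts)
        ds = ss
    else:
        bts = math.pi
        ds = cs
    chi_s = 2.0 / math.pi * ((bts - math.pi * 0.5) * cs + math.sin(bts) * ss)

    if abs(cosbto) < 1.0:
        bto = math.acos(cosbto)
        do_ = so
    else:
        if tto < 90.0:
            bto = math.pi
            do_ = co
        else:
            bto = 0.0
            do_ = -co
    chi_o = 2.0 / math.pi * ((bto - math.pi * 0.5) * co + math.sin(bto) * so)

    btran1 = abs(bts - bto)
    btran2 = math.pi - abs(bts + bto - math.pi)
    if psir <= btran1:
        bt1, bt2, bt3 = psir, btran1, btran2
    else:
        bt1 = btran1
        if psir <= btran2:
            bt2, bt3 = psir, btran2
        else:
            bt2, bt3 = btran2, psir

    t1 = 2.0 * cs * co + ss * so * cospsi
    t2 = 0.0
    if bt2 > 0.0:
        t2 = math.sin(bt2) * (2.0 * ds * do_ + ss * so * math.cos(bt1) * math.cos(bt3))
    denom = 2.0 * math.pi ** 2
    frho = max(((math.pi - bt2) * t1 + t2) / denom, 0.0)
    ftau = max((-bt2 * t1 + t2) / denom, 0.0)
    return chi_s, chi_o, frho, ftau


def _jfunc1(k: float, m: np.ndarray, lai: float) -> np.ndarray:
    d = (k - m) * lai
    out = np.empty_like(m)
    near = np.abs(d) < 1e-3
    far = ~near
    out[far] = (np.exp(-m[far] * lai) - math.exp(-k * lai)) / (k - m[far])
    out[near] = 0.5 * lai * (math.exp(-k * lai) + np.exp(-m[near] * lai)) \
        * (1.0 - d[near] ** 2 / 12.0)
    return out


def _jfunc2(k: float, m: np.ndarray, lai: float) -> np.ndarray:
    return (1.0 - np.exp(-(k + m) * lai)) / (k + m)


def foursail(leaf_optics: LeafOptics, canopy: CanopyParams,
             geom: ViewGeometry = DEFAULT_GEOMETRY,
             soil: CanopySpectrum | None = None) -> CanopySpectrum:
    """Bidirectional canopy reflectance from leaf optics over a soil background.

    With ``soil=None`` the background is built internally from
    ``mix_soil(canopy.psoil)``.
    """
    if soil is None:
        soil = mix_soil(canopy.psoil)
    if not np.array_equal(soil.wavelengths, leaf_optics.wavelengths):
        raise DimensionError("soil spectrum not on the leaf optics wavelength grid")

    rho = leaf_optics.reflectance
    tau = leaf_optics.transmittance
    rsoil = soil.reflectance
    lai = canopy.LAI
    if lai <= 0.0:
        return CanopySpectrum(soil.wavelengths.copy(), rsoil.copy())

    tts, tto, psi = geom.sza, geom.vza, abs(geom.raa) % 360.0
    if psi > 180.0:
        psi = 360.0 - psi

    lidf = _campbell_lidf(canopy.ALIA)
    cts = math.cos(math.radians(tts))
    cto = math.cos(math.radians(tto))
    ctscto = cts * cto

    ks = ko = bf = sob = sof = 0.0
    for i, ttl in enumerate(_LITAB):
        chi_s, chi_o, frho, ftau = _volscatt(tts, tto, psi, ttl)
        ks += chi_s / cts * lidf[i]
        ko += chi_o / cto * lidf[i]
        sob += frho * math.pi / ctscto * lidf[i]
        sof += ftau * math.pi / ctscto * lidf[i]
        bf += math.cos(math.radians(ttl)) ** 2 * lidf[i]

    sdb = 0.5 * (ks + bf)
    sdf = 0.5 * (ks - bf)
    dob = 0.5 * (ko + bf)
    dof = 0.5 * (ko - bf)
    ddb = 0.5 * (1.0 + bf)
    ddf = 0.5 * (1.0 - bf)

    sigb = ddb * rho + ddf * tau
    sigf = ddf * rho + ddb * tau
    att = 1.0 - sigf
    m = np.sqrt(np.maximum((att + sigb) * (att - sigb), 0.0))
    sb = sdb * rho + sdf * tau
    sf = sdf * rho + sdb * tau
    vb = dob * rho + dof * tau
    vf = dof * rho + dob * tau
    w = sob * rho + sof * tau

    e1 = np.exp(-m * lai)
    e2 = e1 ** 2
    rinf = (att - m) / sigb
    rinf2 = rinf ** 2
    re = rinf * e1
    denom = 1.0 - rinf2 * e2

    J1ks = _jfunc1(ks, m, lai)
    J2ks = _jfunc2(ks, m, lai)
    J1ko = _jfunc1(ko, m, lai)
    J2ko = _jfunc2(ko, m, lai)

    Ps = (sf + sb * rinf) * J1ks
    Qs = (sf * rinf + sb) * J2ks
    Pv = (vf + vb * rinf) * J1ko
    Qv = (vf * rinf + vb) * J2ko

    tdd = (1.0 - rinf2) * e1 / denom
    rdd = rinf * (1.0 - e2) / denom
    tsd = (Ps - re * Qs) / denom
    rsd = (Qs - re * Ps) / denom
    tdo = (Pv - re * Qv) / denom
    rdo = (Qv - re * Pv) / denom

    tss = math.exp(-ks * lai)
    too = math.exp(-ko * lai)
    z = _jfunc2(ks, np.full_like(m, ko), lai)
    g1 = (z - J1ks * too) / (ko + m)
    g2 = (z - J1ko * tss) / (ks + m)

    Tv1 = (vf * rinf + vb) * g1
    Tv2 = (vf + vb * rinf) * g2
    T1 = Tv1 * (sf + sb * rinf)
    T2 = Tv2 * (sf * rinf + sb)
    T3 = (rdo * Qs + tdo * Ps) * rinf
    # multiple-scattering bidirectional contribution
    rsod = (T1 + T2 - T3) / (1.0 - rinf2)

    # hot-spot single-scattering contribution
    tants = math.tan(math.radians(tts))
    tanto = math.tan(math.radians(tto))
    cospsi = math.cos(math.radians(psi))
    dso = math.sqrt(tants ** 2 + tanto ** 2 - 2.0 * tants * tanto * cospsi)

    alf = 1e36
    if canopy.hotspot > 0.0:
        alf = (dso / canopy.hotspot) * 2.0 / (ks + ko)
    if alf == 0.0:
        tsstoo = tss
        sumint = (1.0 - tss) / (ks * lai)
    else:
        fhot = lai * math.sqrt(ko * ks)
        x1 = y1 = 0.0
        f1 = 1.0
        fint = (1.0 - math.exp(-alf)) * 0.05
        sumint = 0.0
        for istep in range(1, 21):
            if istep < 20:
                x2 = -math.log(1.0 - istep * fint) / alf
            else:
                x2 = 1.0
            y2 = -(ko + ks) * lai * x2 + fhot * (1.0 - math.exp(-alf * x2)) / alf
            f2 = math.exp(y2)
            if y2 != y1:
                sumint += (f2 - f1) * (x2 - x1) / (y2 - y1)
            x1, y1, f1 = x2, y2, f2
        tsstoo = f1
        if math.isnan(sumint):
            sumint = 0.0

    rsos = w * lai * sumint
    rso = rsos + rsod

    # couple with the soil background
    dn = 1.0 - rsoil * rdd
    rsot = rso \
        + tsstoo * rsoil \
        + ((tss + tsd) * tdo + (tsd + tss * rsoil * rdd) * too) * rsoil / dn
    return CanopySpectrum(leaf_optics.wavelengths.copy(), rsot)


def simulate_canopy(leaf: LeafParams, canopy: CanopyParams,
                    geom: ViewGeometry = DEFAULT_GEOMETRY) -> CanopySpectrum:
    """Full leaf-to-canopy simulation with the internally mixed soil."""
    return foursail(prospect_pro(leaf), canopy, geom, mix_soil(canopy.psoil))


# ---------------------------------------------------------------------------
# one-at-a-time sensitivity


def sensitivity_oat(base_leaf: LeafParams, base_canopy: CanopyParams,
                    param_name: str, n_steps: int,
                    geom: ViewGeometry = DEFAULT_GEOMETRY) -> list[CanopySpectrum]:
    """Sweep one parameter across its bound, all others held at base values."""
    if n_steps < 1:
        raise ValidationError(f"n_steps={n_steps!r} must be >= 1")
    if param_name in LeafParams.BOUNDS:
        target, bounds = "leaf", LeafParams.BOUNDS[param_name]
    elif param_name in CanopyParams.BOUNDS:
        target, bounds = "canopy", CanopyParams.BOUNDS[param_name]
    else:
        raise ValidationError(f"unknown parameter name {param_name!r}")

    if n_steps == 1:
        values = [getattr(base_leaf if target == "leaf" else base_canopy, param_name)]
    else:
        values = np.linspace(bounds[0], bounds[1], n_steps)

    out = []
    for v in values:
        leaf, canopy = base_leaf, base_canopy
        if target == "leaf":
            leaf = LeafParams(**{**_asdict(base_leaf), param_name: float(v)})
        else:
            canopy = CanopyParams(**{**_asdict(base_canopy), param_name: float(v)})
        out.append(simulate_canopy(leaf, canopy, geom))
    return out


def oat_sweep_values(param_name: str, n_steps: int) -> np.ndarray:
    """The parameter values used by :func:`sensitivity_oat` for n_steps > 1."""
    bounds = LeafParams.BOUNDS.get(param_name) or CanopyParams.BOUNDS.get(param_name)
    if bounds is None:
        raise ValidationError(f"unknown parameter name {param_name!r}")
    return np.linspace(bounds[0], bounds[1], n_steps)


def _asdict(obj) -> dict:
    return {f.name: getattr(obj, f.name) for f in fields(obj)}
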