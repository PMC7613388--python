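"""Independent scalar re-implementation of the coupled leaf/canopy model.

Everything here is computed per wavelength with plain Python floats and
explicit loops, reading the coefficient tables with the csv module — no code
or arrays shared with the package implementation.  It exists to cross-check
the vectorized model, including an adding-method alternative for integer
layer counts that does not use the closed-form stack solution at all.
"""

import csv
import math
from importlib import resources

from scipy.special import exp1

_LITAB = [5, 15, 25, 35, 45, 55, 65, 75, 81, 83, 85, 87, 89]


def load_tables():
    rows = []
    path = resources.files("npvret") / "data" / "leaf_coefficients.csv"
    with open(str(path), newline="") as fh:
        reader = csv.DictReader(fh)
        for rec in reader:
            rows.append({k: float(v) for k, v in rec.items()})
    soil = []
    path = resources.files("npvret") / "data" / "soil_endmembers.csv"
    with open(str(path), newline="") as fh:
        reader = csv.DictReader(fh)
        for rec in reader:
            soil.append({k: float(v) for k, v in rec.items()})
    return rows, soil


def tav_scalar(theta_deg, n):
    if theta_deg == 0.0:
        return 4.0 * n / (n + 1.0) ** 2
    theta = math.radians(theta_deg)
    n2 = n * n
    a = (n + 1.0) ** 2 / 2.0
    k = -((n2 - 1.0) ** 2) / 4.0
    ds = math.sin(theta)
    if theta == math.pi / 2.0:
        b1 = 0.0
    else:
        b1 = math.sqrt((ds * ds - (n2 + 1.0) / 2.0) ** 2 + k)
    b2 = ds * ds - (n2 + 1.0) / 2.0
    b = b1 - b2
    ts = (k * k / (6.0 * b ** 3) + k / b - b / 2.0) \
        - (k * k / (6.0 * a ** 3) + k / a - a / 2.0)
    tp1 = -2.0 * n2 * (b - a) / (n2 + 1.0) ** 2
    tp2 = -2.0 * n2 * (n2 + 1.0) * math.log(b / a) / (n2 - 1.0) ** 2
    tp3 = n2 * (1.0 / b - 1.0 / a) / 2.0
    q = (n2 - 1.0) ** 2
    p = 2.0 * (n2 + 1.0)
    tp4 = 16.0 * n2 ** 2 * (n2 ** 2 + 1.0) \
        * math.log((p * b - q) / (p * a - q)) / ((n2 + 1.0) ** 3 * q)
    tp5 = 16.0 * n2 ** 3 * (1.0 / (p * b - q) - 1.0 / (p * a - q)) \
        / (n2 + 1.0) ** 3
    return (ts + tp1 + tp2 + tp3 + tp4 + tp5) / (2.0 * ds * ds)


def elementary_layer(row, leaf):
    """(r, t) of one internal layer and (Ra-part, Ta-part) of the top layer."""
    kall = (leaf["Cab"] * row["kab"] + leaf["Cxc"] * row["kcar"]
            + leaf["Cant"] * row["kant"] + leaf["Cbrown"] * row["kbrown"]
            + leaf["Cw"] * row["kw"] + leaf["Cp"] * row["kp"]
            + leaf["CBC"] * row["kcbc"]) / leaf["N"]
    if kall <= 0.0:
        tau = 1.0
    else:
        tau = (1.0 - kall) * math.exp(-kall) + kall * kall * float(exp1(kall))
    n = row["refractive_index"]
    talf = tav_scalar(40.0, n)
    ralf = 1.0 - talf
    t12 = tav_scalar(90.0, n)
    r12 = 1.0 - t12
    t21 = t12 / (n * n)
    r21 = 1.0 - t21
    denom = 1.0 - r21 * r21 * tau * tau
    Ta = talf * tau * t21 / denom
    Ra = ralf + r21 * tau * Ta
    t = t12 * tau * t21 / denom
    r = r12 + r21 * tau * t
    return r, t, Ra, Ta


def leaf_rt(row, leaf):
    """Leaf reflectance/transmittance via the closed-form continuous stack."""
    r, t, Ra, Ta = elementary_layer(row, leaf)
    if r + t >= 1.0:
        Tsub = t / (t + (1.0 - t) * (leaf["N"] - 1.0))
        Rsub = 1.0 - Tsub
    else:
        D = math.sqrt((1.0 + r + t) * (1.0 + r - t)
                      * (1.0 - r + t) * (1.0 - r - t))
        a = (1.0 + r * r - t * t + D) / (2.0 * r)
        b = (1.0 - r * r + t * t + D) / (2.0 * t)
        bNm1 = b ** (leaf["N"] - 1.0)
        bN2 = bNm1 * bNm1
        a2 = a * a
        denom = a2 * bN2 - 1.0
        Rsub = a * (bN2 - 1.0) / denom
        Tsub = bNm1 * (a2 - 1.0) / denom
    denom = 1.0 - Rsub * r
    tran = Ta * Tsub / denom
    refl = Ra + Ta * Rsub * t / denom
    return refl, tran


def leaf_rt_adding(row, leaf):
    """Same leaf stack but built by sequentially adding integer layers;
    requires integer ``N``.  Completely independent of the closed form."""
    n_layers = leaf["N"]
    assert float(n_layers).is_integer() and n_layers >= 1
    r, t, Ra, Ta = elementary_layer(row, leaf)
    # stack of (N - 1) internal layers, added one at a time
    R, T = 0.0, 1.0
    for _ in range(int(n_layers) - 1):
        denom = 1.0 - R * r
        T_new = t * T / denom
        R_new = r + t * t * R / denom
        R, T = R_new, T_new
    denom = 1.0 - R * r
    tran = Ta * T / denom
    refl = Ra + Ta * R * t / denom
    return refl, tran


def campbell_lidf(alia):
    excent = math.exp(-1.6184e-5 * alia ** 3 + 2.1145e-3 * alia ** 2
                      - 1.2390e-1 * alia + 3.2491)
    bounds = [(i * 10.0, (i + 1) * 10.0) for i in range(8)] \
        + [(80.0 + 2.0 * i, 82.0 + 2.0 * i) for i in range(5)]
    freq = []
    for tl1d, tl2d in bounds:
        tl1, tl2 = math.radians(tl1d), math.radians(tl2d)
        x1 = excent / math.sqrt(1.0 + excent ** 2 * math.tan(tl1) ** 2)
        x2 = excent / math.sqrt(1.0 + excent ** 2 * math.tan(tl2) ** 2)
        if excent == 1.0:
            freq.append(abs(math.cos(tl1) - math.cos(tl2)))
            continue
        alph = excent / math.sqrt(abs(1.0 - excent ** 2))
        alph2 = alph * alph
        if excent > 1.0:
            alpx1 = math.sqrt(alph2 + x1 * x1)
            alpx2 = math.sqrt(alph2 + x2 * x2)
            dum = x1 * alpx1 + alph2 * math.log(x1 + alpx1)
            freq.append(abs(dum - (x2 * alpx2 + alph2 * math.log(x2 + alpx2))))
        else:
            almx1 = math.sqrt(alph2 - x1 * x1)
            almx2 = math.sqrt(alph2 - x2 * x2)
            dum = x1 * almx1 + alph2 * math.asin(x1 / alph)
            freq.append(abs(dum - (x2 * almx2 + alph2 * math.asin(x2 / alph))))
    s = sum(freq)
    return [f / s for f in freq]


def volscatt(tts, tto, psi, ttl):
    cts, cto = math.cos(math.radians(tts)), math.cos(math.radians(tto))
    sts, sto = math.sin(math.radians(tts)), math.sin(math.radians(tto))
    psir = math.radians(psi)
    cttl, sttl = math.cos(math.radians(ttl)), math.sin(math.radians(ttl))
    cs, co = cttl * cts, cttl * cto
    ss, so = sttl * sts, sttl * sto
    cosbts = -cs / ss if abs(ss) > 1e-6 else 5.0
    cosbto = -co / so if abs(so) > 1e-6 else 5.0
    if abs(cosbts) < 1.0:
        bts, ds = math.acos(cosbts), ss
    else:
        bts, ds = math.pi, cs
    chi_s = 2.0 / math.pi * ((bts - math.pi / 2.0) * cs + math.sin(bts) * ss)
    if abs(cosbto) < 1.0:
        bto, do_ = math.acos(cosbto), so
    elif tto < 90.0:
        bto, do_ = math.pi, co
    else:
        bto, do_ = 0.0, -co
    chi_o = 2.0 / math.pi * ((bto - math.pi / 2.0) * co + math.sin(bto) * so)
    btran1 = abs(bts - bto)
    btran2 = math.pi - abs(bts + bto - math.pi)
    if psir <= btran1:
        bt1, bt2, bt3 = psir, btran1, btran2
    elif psir <= btran2:
        bt1, bt2, bt3 = btran1, psir, btran2
    else:
        bt1, bt2, bt3 = btran1, btran2, psir
    t1 = 2.0 * cs * co + ss * so * math.cos(psir)
    t2 = 0.0
    if bt2 > 0.0:
        t2 = math.sin(bt2) * (2.0 * ds * do_
                              + ss * so * math.cos(bt1) * math.cos(bt3))
    denom = 2.0 * math.pi ** 2
    frho = max(((math.pi - bt2) * t1 + t2) / denom, 0.0)
    ftau = max((-bt2 * t1 + t2) / denom, 0.0)
    return chi_s, chi_o, frho, ftau


def _j1(k, m, lai):
    d = (k - m) * lai
    if abs(d) > 1e-3:
        return (math.exp(-m * lai) - math.exp(-k * lai)) / (k - m)
    return 0.5 * lai * (math.exp(-k * lai) + math.exp(-m * lai)) \
        * (1.0 - d * d / 12.0)


def _j2(k, m, lai):
    return (1.0 - math.exp(-(k + m) * lai)) / (k + m)


def canopy_brf(row, soil_row, leaf, canopy, geom):
    """Scalar bidirectional reflectance factor at one wavelength."""
    rho, tau = leaf_rt(row, leaf)
    psoil = canopy["psoil"]
    rsoil = psoil * soil_row["dry"] + (1.0 - psoil) * soil_row["wet"]
    lai = canopy["LAI"]
    if lai <= 0.0:
        return rsoil

    tts, tto = geom["sza"], geom["vza"]
    psi = abs(geom["raa"]) % 360.0
    if psi > 180.0:
        psi = 360.0 - psi
    lidf = campbell_lidf(canopy["ALIA"])
    cts, cto = math.cos(math.radians(tts)), math.cos(math.radians(tto))

    ks = ko = bf = sob = sof = 0.0
    for w, ttl in zip(lidf, _LITAB):
        chi_s, chi_o, frho, ftau = volscatt(tts, tto, psi, ttl)
        ks += w * chi_s / cts
        ko += w * chi_o / cto
        sob += w * frho * math.pi / (cts * cto)
        sof += w * ftau * math.pi / (cts * cto)
        bf += w * math.cos(math.radians(ttl)) ** 2

    sdb, sdf = 0.5 * (ks + bf), 0.5 * (ks - bf)
    dob, dof = 0.5 * (ko + bf), 0.5 * (ko - bf)
    ddb, ddf = 0.5 * (1.0 + bf), 0.5 * (1.0 - bf)

    sigb = ddb * rho + ddf * tau
    sigf = ddf * rho + ddb * tau
    att = 1.0 - sigf
    m = math.sqrt(max((att + sigb) * (att - sigb), 0.0))
    sb, sf = sdb * rho + sdf * tau, sdf * rho + sdb * tau
    vb, vf = dob * rho + dof * tau, dof * rho + dob * tau
    w_ = sob * rho + sof * tau

    e1 = math.exp(-m * lai)
    e2 = e1 * e1
    rinf = (att - m) / sigb
    rinf2 = rinf * rinf
    re = rinf * e1
    denom = 1.0 - rinf2 * e2

    J1ks, J2ks = _j1(ks, m, lai), _j2(ks, m, lai)
    J1ko, J2ko = _j1(ko, m, lai), _j2(ko, m, lai)
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

    tss, too = math.exp(-ks * lai), math.exp(-ko * lai)
    z = _j2(ks, ko, lai)
    g1 = (z - J1ks * too) / (ko + m)
    g2 = (z - J1ko * tss) / (ks + m)
    Tv1 = (vf * rinf + vb) * g1
    Tv2 = (vf + vb * rinf) * g2
    T1 = Tv1 * (sf + sb * rinf)
    T2 = Tv2 * (sf * rinf + sb)
    T3 = (rdo * Qs + tdo * Ps) * rinf
    rsod = (T1 + T2 - T3) / (1.0 - rinf2)

    tants, tanto = math.tan(math.radians(tts)), math.tan(math.radians(tto))
    dso = math.sqrt(tants ** 2 + tanto ** 2
                    - 2.0 * tants * tanto * math.cos(math.radians(psi)))
    alf = 1e36
    if canopy["hotspot"] > 0.0:
        alf = (dso / canopy["hotspot"]) * 2.0 / (ks + ko)
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
            x2 = 1.0 if istep == 20 else -math.log(1.0 - istep * fint) / alf
            y2 = -(ko + ks) * lai * x2 \
                + fhot * (1.0 - math.exp(-alf * x2)) / alf
            f2 = math.exp(y2)
            if y2 != y1:
                sumint += (f2 - f1) * (x2 - x1) / (y2 - y1)
            x1, y1, f1 = x2, y2, f2
        tsstoo = f1
    rsos = w_ * lai * sumint

    dn = 1.0 - rsoil * rdd
    return rsos + rsod + tsstoo * rsoil \
        + ((tss + tsd) * tdo + (tsd + tss * rsoil * rdd) * too) * rsoil / dn
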