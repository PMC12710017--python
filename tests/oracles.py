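"""Independent numerical oracles shared by the leaf-model test suites.

Everything here deliberately avoids the package's closed-form code paths:
interface transmissivities and slab transmission come from brute-force
quadrature, and the multi-layer pile is assembled by the adding-doubling
recurrence rather than the closed-form pile solution.
"""

import math

import numpy as np
from scipy.integrate import quad


def fresnel_transmission(theta, n):
    """Unpolarised Fresnel transmission at incidence theta."""
    st_, ct = math.sin(theta), math.cos(theta)
    stp = st_ / n
    ctp = math.sqrt(1.0 - stp * stp)
    rs = ((ct - n * ctp) / (ct + n * ctp)) ** 2
    rp = ((n * ct - ctp) / (n * ct + ctp)) ** 2
    return 1.0 - 0.5 * (rs + rp)


def tav_numeric(alpha_deg, n):
    """Brute-force solid-angle integration of Fresnel transmission."""
    a = math.radians(alpha_deg)
    num, _ = quad(
        lambda t: fresnel_transmission(t, n) * math.sin(t) * math.cos(t),
        0.0,
        a,
        limit=200,
    )
    return num / (math.sin(a) ** 2 / 2.0)


def layer_transmission_numeric(k):
    """Isotropic slab transmission by direct hemispherical integration."""
    if k == 0.0:
        return 1.0
    val, _ = quad(
        lambda t: math.exp(-k / math.cos(t)) * 2.0 * math.sin(t) * math.cos(t),
        0.0,
        math.pi / 2.0 - 1e-9,
        limit=400,
    )
    return val


def plate_reference(biochem, coeffs, alpha=40.0):
    """Independent scalar plate-model oracle for integer layer counts.

    Uses numerically integrated interface transmissivities and slab
    transmission, and builds the (N-1)-layer substack by the
    adding-doubling recurrence instead of the closed-form pile solution.
    """
    n_layers = int(biochem.n_struct)
    assert n_layers == biochem.n_struct, "oracle handles integer N only"
    refl = np.empty_like(coeffs.wavelength)
    tran = np.empty_like(coeffs.wavelength)
    ks = coeffs.compound_k(biochem)
    for i, (nidx, k) in enumerate(zip(coeffs.refractive_index, ks)):
        tau = layer_transmission_numeric(float(k))
        talf = tav_numeric(alpha, nidx)
        t12 = tav_numeric(90.0, nidx)
        t21 = t12 / nidx**2
        r12, r21, ralf = 1.0 - t12, 1.0 - t12 / nidx**2, 1.0 - talf
        denom = 1.0 - r21**2 * tau**2
        Ta = talf * tau * t21 / denom
        Ra = ralf + r21 * tau * Ta
        t = t12 * tau * t21 / denom
        r = r12 + r21 * tau * t
        # substack of N-1 identical plates via adding-doubling
        Rs, Ts = 0.0, 1.0
        for _ in range(n_layers - 1):
            common = 1.0 / (1.0 - Rs * r)
            Ts, Rs = Ts * t * common, r + t * t * Rs * common
        common = 1.0 / (1.0 - Rs * r)
        tran[i] = Ta * Ts * common
        refl[i] = Ra + Ta * Rs * t * common
    return refl, tran
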