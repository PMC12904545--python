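"""Monte-Carlo photon-packet transport through a layered slab.

Implements the classic multilayer hop/drop/spin random walk (Henyey-Greenstein
scattering, unpolarized Fresnel boundaries) specialised for an OCT geometry:
an infinitely thin pencil beam enters the slab at normal incidence and a disc
detector of radius ``radius_cm`` sits ``height_um`` above the surface.
Boundary events are probabilistic -- a packet wholly reflects or wholly
transmits by comparing a uniform draw against the Fresnel reflectance -- so
with zero absorption every packet keeps weight exactly 1 and the phasor
amplitudes fed to the OCT synthesis stage are homogeneous.

Units: layer thicknesses and all internal geometry are in micrometres;
scattering/absorption coefficients cross the module boundary in mm^-1 and are
converted to um^-1 internally.  Depth ``z`` increases downward from the top
surface (z = 0); the detector plane is at z = -height_um.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "OpticalProperties",
    "LayerStack",
    "DetectorSpec",
    "PhotonRecord",
    "TransportTally",
    "sample_step",
    "sample_scatter_cosine",
    "fresnel",
    "trace_photon",
    "run_simulation",
]

# Russian-roulette constants (standard multilayer defaults); inert at mu_a = 0.
WEIGHT_THRESHOLD = 1e-4
ROULETTE_SURVIVAL = 0.1

# terminal outcome codes shared with the jitted core
TRANSMITTED = 0
DETECTED = 1
BACKSCATTERED_UNDETECTED = 2
ABSORBED = 3
ABORTED = 4

OUTCOME_NAMES = {
    TRANSMITTED: "transmitted",
    DETECTED: "detected",
    BACKSCATTERED_UNDETECTED: "escaped-undetected",
    ABSORBED: "absorbed",
    ABORTED: "aborted",
}


@dataclass(frozen=True)
class OpticalProperties:
    """Optical properties of one homogeneous layer.

    mu_s, mu_a in mm^-1; g is the scattering anisotropy factor (mean cosine
    of the single-scattering deflection); n the refractive index.
    """

    mu_s: float
    mu_a: float = 0.0
    g: float = 0.9
    n: float = 1.376

    def __post_init__(self) -> None:
        if self.mu_s < 0 or self.mu_a < 0:
            raise ValueError("mu_s and mu_a must be non-negative")
        if not (-1.0 < self.g <= 1.0):
            raise ValueError("g must lie in (-1, 1] (g = 1 is the forward limit)")
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")


# corneal defaults: single 600 um stromal slab (n = 1.376) between air and
# aqueous humor (n = 1.33)
def _default_layers() -> tuple:
    return ((600.0, OpticalProperties(mu_s=0.1, mu_a=0.0, g=0.99)),)


@dataclass(frozen=True)
class LayerStack:
    """Ordered stack of (thickness_um, OpticalProperties), top to bottom."""

    layers: tuple = field(default_factory=_default_layers)
    n_above: float = 1.0
    n_below: float = 1.33

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("at least one layer required")
        object.__setattr__(self, "layers", tuple(self.layers))
        for thickness, props in self.layers:
            if thickness <= 0:
                raise ValueError("layer thickness must be positive")
            if not isinstance(props, OpticalProperties):
                raise TypeError("layer properties must be OpticalProperties")

    @classmethod
    def single_layer(
        cls,
        mu_s: float,
        g: float,
        mu_a: float = 0.0,
        n: float = 1.376,
        thickness_um: float = 600.0,
        n_above: float = 1.0,
        n_below: float = 1.33,
    ) -> "LayerStack":
        props = OpticalProperties(mu_s=mu_s, mu_a=mu_a, g=g, n=n)
        return cls(layers=((thickness_um, props),), n_above=n_above, n_below=n_below)

    def as_arrays(self):
        """Boundary depths (um) and per-layer coefficient arrays (um^-1)."""
        nl = len(self.layers)
        z = np.empty(nl + 1)
        mu_s = np.empty(nl)
        mu_a = np.empty(nl)
        g = np.empty(nl)
        n = np.empty(nl)
        z[0] = 0.0
        for i, (thickness, props) in enumerate(self.layers):
            z[i + 1] = z[i] + thickness
            mu_s[i] = props.mu_s * 1e-3  # mm^-1 -> um^-1
            mu_a[i] = props.mu_a * 1e-3
            g[i] = props.g
            n[i] = props.n
        return z, mu_s, mu_a, g, n


@dataclass(frozen=True)
class DetectorSpec:
    """Disc detector above the sample surface."""

    radius_cm: float = 0.2
    height_um: float = 100.0

    def __post_init__(self) -> None:
        if self.radius_cm <= 0:
            raise ValueError("detector radius must be positive")
        if self.height_um < 0:
            raise ValueError("detector height must be non-negative")

    @property
    def radius_um(self) -> float:
        return self.radius_cm * 1e4


@dataclass(frozen=True)
class PhotonRecord:
    """One traced packet: weight, accumulated optical pathlength and exit state.

    ``optical_pathlength`` is the sum over traversed segments of geometric
    length times the local refractive index (um), i.e. the interferometric
    sample-arm delay.
    """

    weight: float
    optical_pathlength: float
    exit_position: tuple
    exit_direction: tuple
    detected: bool
    outcome: str


@dataclass
class TransportTally:
    """Counts and detected-packet records from one simulation run."""

    n_launched: int
    n_backscattered: int
    n_detected: int
    n_transmitted: int
    n_absorbed: int
    n_scattered_once: int  # packets with >= 1 scattering event
    n_aborted: int  # non-finite state aborts; must be 0
    weights: np.ndarray  # (n_detected,)
    pathlengths: np.ndarray  # optical pathlength, um

    def __post_init__(self) -> None:
        if not (self.n_detected <= self.n_backscattered <= self.n_launched):
            raise ValueError("tally counting invariant violated")
        if len(self.weights) != self.n_detected:
            raise ValueError("records must match n_detected")

    @property
    def backscattered_fraction(self) -> float:
        return self.n_backscattered / self.n_launched

    @property
    def detected_fraction(self) -> float:
        return self.n_detected / self.n_launched


# ----------------------------------------------------------------------------
# elementary sampling laws (pure functions, exposed for direct testing)
# ----------------------------------------------------------------------------

def sample_step(mu_t: float, u: float) -> float:
    """Free pathlength (mm) from the exponential step law s = -ln(u)/mu_t."""
    if mu_t <= 0:
        raise ValueError(
            "mu_t = 0 signals a ballistic medium; route the packet straight "
            "to the next boundary instead of sampling a step"
        )
    return -math.log(u) / mu_t


def sample_scatter_cosine(g: float, u: float) -> float:
    """Henyey-Greenstein deflection cosine via the closed-form inverse CDF."""
    if abs(g) >= 1.0:
        raise ValueError("HG sampling requires |g| < 1")
    return _hg_cosine(g, u)


def fresnel(n1: float, n2: float, cos_incident: float):
    """Unpolarized Fresnel reflectance and refracted cosine.

    Returns (R, cos_transmitted); beyond the critical angle R = 1 and the
    refracted cosine is reported as 0.
    """
    if not (0.0 < cos_incident <= 1.0):
        raise ValueError("cos_incident must lie in (0, 1]")
    return _fresnel(n1, n2, cos_incident)


@njit(cache=True)
def _hg_cosine(g: float, u: float) -> float:
    if g == 0.0:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    c = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True)
def _fresnel(n1, n2, ci):
    if n1 == n2:
        return 0.0, ci
    si = math.sqrt(max(0.0, 1.0 - ci * ci))
    st = n1 * si / n2
    if st >= 1.0:
        return 1.0, 0.0
    ct = math.sqrt(1.0 - st * st)
    rs_num = n1 * ci - n2 * ct
    rs_den = n1 * ci + n2 * ct
    rp_num = n1 * ct - n2 * ci
    rp_den = n1 * ct + n2 * ci
    r = 0.5 * ((rs_num / rs_den) ** 2 + (rp_num / rp_den) ** 2)
    if r > 1.0:
        r = 1.0
    return r, ct


# ----------------------------------------------------------------------------
# jitted transport core
# ----------------------------------------------------------------------------

@njit(cache=True)
def _trace_one(z_bounds, mu_s, mu_a, g_arr, n_arr, n_above, n_below,
               det_r_um, det_h_um):
    """Trace a single packet; numba np.random state must be seeded by caller.

    Returns (outcome, weight, optical_pathlength, exit_x, exit_y,
             ux, uy, uz, n_scatter_events).
    """
    n_layers = len(mu_s)
    x = 0.0
    y = 0.0
    z = 0.0
    ux = 0.0
    uy = 0.0
    uz = 1.0
    w = 1.0
    layer = 0
    opl = 0.0
    nscat = 0

    # dimensionless leftover step carried across boundaries
    s_left = 0.0
    have_step = False

    for _ in range(100000000):
        mu_t = mu_s[layer] + mu_a[layer]
        if not have_step:
            u = np.random.random()
            while u <= 0.0:
                u = np.random.random()
            s_left = -math.log(u)
            have_step = True
        if mu_t > 0.0:
            step = s_left / mu_t
        else:
            step = 1.0e30

        # distance to the layer boundary along the current direction
        if uz > 0.0:
            db = (z_bounds[layer + 1] - z) / uz
        elif uz < 0.0:
            db = (z_bounds[layer] - z) / uz
        else:
            db = 1.0e30

        if db < step:
            # hop to the boundary
            x += ux * db
            y += uy * db
            z += uz * db
            opl += db * n_arr[layer]
            s_left -= db * mu_t
            if s_left < 0.0:
                s_left = 0.0

            going_down = uz > 0.0
            n1 = n_arr[layer]
            if going_down:
                n2 = n_arr[layer + 1] if layer + 1 < n_layers else n_below
            else:
                n2 = n_arr[layer - 1] if layer > 0 else n_above
            ci = abs(uz)
            r, ct = _fresnel(n1, n2, ci)
            if np.random.random() < r:
                uz = -uz  # total (probabilistic) reflection
            else:
                scale = n1 / n2
                ux *= scale
                uy *= scale
                uz = ct if going_down else -ct
                if going_down:
                    if layer + 1 < n_layers:
                        layer += 1
                    else:
                        return (TRANSMITTED, w, opl, x, y, ux, uy, uz, nscat)
                else:
                    if layer > 0:
                        layer -= 1
                    else:
                        # backscattered into the ambient medium; detector test:
                        # straight-line continuation to the plane z = -det_h_um
                        sa = det_h_um / ct
                        px = x + ux * sa
                        py = y + uy * sa
                        if px * px + py * py <= det_r_um * det_r_um:
                            return (DETECTED, w, opl, x, y, ux, uy, uz, nscat)
                        return (BACKSCATTERED_UNDETECTED, w, opl, x, y,
                                ux, uy, uz, nscat)
            if not (math.isfinite(z) and math.isfinite(uz)):
                return (ABORTED, w, opl, x, y, ux, uy, uz, nscat)
            continue

        if mu_t <= 0.0:
            # ballistic medium but boundary unreachable (uz == 0): lost
            return (ABORTED, w, opl, x, y, ux, uy, uz, nscat)

        # hop to the interaction site
        x += ux * step
        y += uy * step
        z += uz * step
        opl += step * n_arr[layer]
        have_step = False

        # drop (inert at mu_a = 0)
        if mu_a[layer] > 0.0:
            w -= w * mu_a[layer] / mu_t
            if w < WEIGHT_THRESHOLD:
                if np.random.random() < ROULETTE_SURVIVAL:
                    w /= ROULETTE_SURVIVAL
                else:
                    return (ABSORBED, w, opl, x, y, ux, uy, uz, nscat)

        # spin: Henyey-Greenstein deflection, uniform azimuth
        g = g_arr[layer]
        if g >= 1.0:
            cost = 1.0  # forward limit
        else:
            cost = _hg_cosine(g, np.random.random())
        sint = math.sqrt(max(0.0, 1.0 - cost * cost))
        phi = 2.0 * math.pi * np.random.random()
        cosp = math.cos(phi)
        sinp = math.sin(phi)
        if abs(uz) > 0.99999:
            ux = sint * cosp
            uy = sint * sinp
            uz = cost if uz > 0.0 else -cost
        else:
            denom = math.sqrt(1.0 - uz * uz)
            ux_n = sint * (ux * uz * cosp - uy * sinp) / denom + ux * cost
            uy_n = sint * (uy * uz * cosp + ux * sinp) / denom + uy * cost
            uz_n = -sint * cosp * denom + uz * cost
            ux = ux_n
            uy = uy_n
            uz = uz_n
        nscat += 1
        if not (math.isfinite(x) and math.isfinite(y) and math.isfinite(z)
                and math.isfinite(uz)):
            return (ABORTED, w, opl, x, y, ux, uy, uz, nscat)

    return (ABORTED, w, opl, x, y, ux, uy, uz, nscat)


@njit(cache=True)
def _run_batch(n_packets, seed, z_bounds, mu_s, mu_a, g_arr, n_arr,
               n_above, n_below, det_r_um, det_h_um):
    np.random.seed(seed)
    n_back = 0
    n_det = 0
    n_trans = 0
    n_abs = 0
    n_scat1 = 0
    n_abort = 0
    det_w = [0.0][:0]
    det_opl = [0.0][:0]
    for _ in range(n_packets):
        outcome, w, opl, x, y, ux, uy, uz, nscat = _trace_one(
            z_bounds, mu_s, mu_a, g_arr, n_arr, n_above, n_below,
            det_r_um, det_h_um)
        if nscat > 0:
            n_scat1 += 1
        if outcome == TRANSMITTED:
            n_trans += 1
        elif outcome == ABSORBED:
            n_abs += 1
        elif outcome == ABORTED:
            n_abort += 1
        else:
            n_back += 1
            if outcome == DETECTED:
                n_det += 1
                det_w.append(w)
                det_opl.append(opl)
    wts = np.empty(n_det)
    opls = np.empty(n_det)
    for i in range(n_det):
        wts[i] = det_w[i]
        opls[i] = det_opl[i]
    return n_back, n_det, n_trans, n_abs, n_scat1, n_abort, wts, opls


def trace_photon(stack: LayerStack, detector: DetectorSpec, seed: int) -> PhotonRecord:
    """Trace a single packet launched at (0, 0) straight down."""
    z_bounds, mu_s, mu_a, g_arr, n_arr = stack.as_arrays()
    outcome, w, opl, x, y, ux, uy, uz, _ = _trace_one_seeded(
        int(seed) & 0xFFFFFFFF, z_bounds, mu_s, mu_a, g_arr, n_arr,
        stack.n_above, stack.n_below, detector.radius_um, detector.height_um)
    return PhotonRecord(
        weight=w,
        optical_pathlength=opl,
        exit_position=(x, y),
        exit_direction=(ux, uy, uz),
        detected=outcome == DETECTED,
        outcome=OUTCOME_NAMES[int(outcome)],
    )


@njit(cache=True)
def _trace_one_seeded(seed, z_bounds, mu_s, mu_a, g_arr, n_arr,
                      n_above, n_below, det_r_um, det_h_um):
    np.random.seed(seed)
    return _trace_one(z_bounds, mu_s, mu_a, g_arr, n_arr, n_above, n_below,
                      det_r_um, det_h_um)


def run_simulation(
    stack: LayerStack,
    detector: DetectorSpec,
    n_packets: int,
    seed: int,
) -> TransportTally:
    """Trace ``n_packets`` independent packets with a seeded generator.

    Reproducible bit-for-bit for a fixed seed.  A tally with zero detected
    packets is valid (the downstream A-scan is simply empty).
    """
    if n_packets < 1:
        raise ValueError("n_packets must be >= 1")
    z_bounds, mu_s, mu_a, g_arr, n_arr = stack.as_arrays()
    n_back, n_det, n_trans, n_abs, n_scat1, n_abort, wts, opls = _run_batch(
        int(n_packets), int(seed) & 0xFFFFFFFF, z_bounds, mu_s, mu_a,
        g_arr, n_arr, stack.n_above, stack.n_below,
        detector.radius_um, detector.height_um)
    return TransportTally(
        n_launched=int(n_packets),
        n_backscattered=int(n_back),
        n_detected=int(n_det),
        n_transmitted=int(n_trans),
        n_absorbed=int(n_abs),
        n_scattered_once=int(n_scat1),
        n_aborted=int(n_abort),
        weights=wts,
        pathlengths=opls,
    )
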