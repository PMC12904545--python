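"""Coherence-gated OCT signal synthesis from detected-packet records.

Each detected packet carries its optical pathlength L_i (the sample-arm
interferometric delay) and weight W_i.  For a depth pixel j with reference
optical delay L_ref(j) = 2 n z_j the complex amplitude is a phasor sum

    U(j) = sum_i sqrt(W_i) * G(L_i - L_ref(j)) * exp(i 2 pi (L_i - L_ref(j)) / lambda0)

with G a Gaussian coherence gate whose FWHM equals the source coherence
length l_c = 2 ln2 lambda0^2 / (pi dlambda).  The raw A-scan is Re U (it
oscillates about zero with the carrier); the envelope is |U|, which removes
the carrier.  A B-scan stacks 40 independent A-scan realizations, each from
its own Monte-Carlo run with an independent random substream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mc_transport import DetectorSpec, LayerStack, TransportTally, run_simulation

__all__ = [
    "SourceSpec",
    "DepthGrid",
    "AScan",
    "BScanEnvelope",
    "coherence_length",
    "synthesize_ascan",
    "build_bscan",
    "extract_sim_roi",
    "ascan_seeds",
]

DEFAULT_N_ASCANS = 40
DEFAULT_ROI_DEPTH_PX = 193


def coherence_length(lambda0_nm: float, delta_lambda_nm: float) -> float:
    """Coherence length l_c = 2 ln2 lambda0^2 / (pi dlambda), returned in um."""
    if lambda0_nm <= 0 or delta_lambda_nm <= 0:
        raise ValueError("wavelength and bandwidth must be positive")
    lc_nm = 2.0 * math.log(2.0) * lambda0_nm**2 / (math.pi * delta_lambda_nm)
    return lc_nm * 1e-3


@dataclass(frozen=True)
class SourceSpec:
    """Broadband source: central wavelength and FWHM bandwidth (nm)."""

    lambda0_nm: float = 850.0
    delta_lambda_nm: float = 50.0

    def __post_init__(self) -> None:
        if self.lambda0_nm <= 0 or self.delta_lambda_nm <= 0:
            raise ValueError("lambda0 and delta_lambda must be positive")

    @property
    def lc_um(self) -> float:
        return coherence_length(self.lambda0_nm, self.delta_lambda_nm)


@dataclass(frozen=True)
class DepthGrid:
    """Axial pixel grid; 223 pixels of 2.7 um cover ~600 um of stroma."""

    pixel_um: float = 2.7
    n_pixels: int = 223
    sample_n: float = 1.376  # depth -> reference optical delay conversion

    def __post_init__(self) -> None:
        if self.pixel_um <= 0 or self.n_pixels < 1:
            raise ValueError("invalid depth grid")

    @property
    def depths_um(self) -> np.ndarray:
        """Geometric depth of each pixel centre; pixel j maps to (j+1)*pixel."""
        return (np.arange(self.n_pixels) + 1.0) * self.pixel_um

    @property
    def reference_delays_um(self) -> np.ndarray:
        """Round-trip reference-arm optical delay per pixel: 2 n z_j."""
        return 2.0 * self.sample_n * self.depths_um


@dataclass
class AScan:
    """One depth column: raw carrier-bearing signal and its envelope."""

    raw: np.ndarray
    envelope: np.ndarray
    n_detected: int


@dataclass
class BScanEnvelope:
    """Envelope image (n_pixels x n_ascans) plus simulation provenance."""

    pixels: np.ndarray
    mu_s: float
    g: float
    seed: int
    n_packets: int
    column_counts: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def n_ascans(self) -> int:
        return self.pixels.shape[1]


def synthesize_ascan(
    tally: TransportTally,
    grid: DepthGrid | None = None,
    source: SourceSpec | None = None,
    reference_delays_um: np.ndarray | None = None,
) -> AScan:
    """Phasor-sum the detected packets into a coherence-gated A-scan.

    An empty tally yields an identically zero A-scan.
    ``reference_delays_um`` overrides the grid's reference-arm delays (used
    e.g. to express a reference-arm shift).
    """
    grid = grid or DepthGrid()
    source = source or SourceSpec()
    l_ref = (grid.reference_delays_um if reference_delays_um is None
             else np.asarray(reference_delays_um, dtype=float))
    if tally.n_detected == 0:
        z = np.zeros(grid.n_pixels)
        return AScan(raw=z, envelope=z.copy(), n_detected=0)
    lam = source.lambda0_nm * 1e-3  # um
    lc = source.lc_um
    # (n_pixels, n_detected) path differences; small enough to broadcast
    dl = tally.pathlengths[None, :] - l_ref[:, None]
    gate = np.exp(-4.0 * math.log(2.0) * (dl / lc) ** 2)
    amp = np.sqrt(tally.weights)[None, :] * gate
    phase = 2.0 * math.pi * dl / lam
    u = (amp * np.exp(1j * phase)).sum(axis=1)
    return AScan(raw=u.real, envelope=np.abs(u), n_detected=tally.n_detected)


def ascan_seeds(master_seed: int, n_ascans: int) -> np.ndarray:
    """Independent per-A-scan substream seeds derived from a master seed."""
    ss = np.random.SeedSequence(int(master_seed))
    return ss.generate_state(n_ascans, dtype=np.uint32)


def build_bscan(
    stack: LayerStack,
    detector: DetectorSpec | None = None,
    source: SourceSpec | None = None,
    grid: DepthGrid | None = None,
    n_ascans: int = DEFAULT_N_ASCANS,
    n_packets: int = 15_000_000,
    seed: int = 0,
) -> BScanEnvelope:
    """Simulate a B-scan: ``n_ascans`` independent Monte-Carlo realizations.

    Physical parameters are identical across columns; only the random
    substream differs, so the columns are exchangeable.
    """
    if n_ascans < 1:
        raise ValueError("n_ascans must be >= 1")
    detector = detector or DetectorSpec()
    source = source or SourceSpec()
    grid = grid or DepthGrid()
    seeds = ascan_seeds(seed, n_ascans)
    pixels = np.empty((grid.n_pixels, n_ascans))
    counts = np.empty(n_ascans, dtype=int)
    for col, sub in enumerate(seeds):
        tally = run_simulation(stack, detector, n_packets, int(sub))
        ascan = synthesize_ascan(tally, grid, source)
        pixels[:, col] = ascan.envelope
        counts[col] = tally.n_detected
    props = stack.layers[0][1]
    return BScanEnvelope(
        pixels=pixels,
        mu_s=props.mu_s,
        g=props.g,
        seed=int(seed),
        n_packets=int(n_packets),
        column_counts=counts,
    )


def extract_sim_roi(bscan: BScanEnvelope | np.ndarray,
                    depth_pixels: int = DEFAULT_ROI_DEPTH_PX) -> np.ndarray:
    """Top ``depth_pixels`` rows of the B-scan, all columns.

    The default 193 rows (~521 um) exclude the bright deepest rows produced
    by internal reflection at the stroma-aqueous interface.
    """
    pixels = bscan.pixels if isinstance(bscan, BScanEnvelope) else np.asarray(bscan)
    if depth_pixels > pixels.shape[0]:
        raise ValueError(
            f"ROI depth {depth_pixels} exceeds image depth {pixels.shape[0]}"
        )
    return pixels[:depth_pixels, :]
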