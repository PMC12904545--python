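"""Build, persist and load the multi-reference look-up map.

The map holds one simulated B-scan ROI per (mu_s, g) grid pair -- with the
default grids 11 x 15 = 165 references -- together with each entry's
precomputed speckle summary and full provenance (grids, seeds, packet
budget, source and detector specifications), so a map can never be silently
matched against a sample simulated under different system assumptions.

All entry densities are evaluated on one map-wide grid spanning
[0, 1.05 x max] over every entry's normalized ROI; this is the shared
analysis grid required by the density distances.

Sub-seeds are derived as SeedSequence((master_seed, k)) so any single entry
can be rebuilt in isolation and the build is order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .mc_transport import DetectorSpec, LayerStack
from .oct_synthesis import (
    DEFAULT_N_ASCANS,
    DEFAULT_ROI_DEPTH_PX,
    DepthGrid,
    SourceSpec,
    build_bscan,
    extract_sim_roi,
)
from .speckle_stats import (
    DensityEstimate,
    SpeckleSummary,
    estimate_density,
    normalize_sim,
    contrast_ratio,
    shared_grid,
)

__all__ = [
    "ParameterGrid",
    "ReferenceEntry",
    "LookupMap",
    "enumerate_grid",
    "entry_seed",
    "build_map",
    "save_map",
    "load_map",
    "MapFormatError",
]

SCHEMA_VERSION = 1


class MapFormatError(RuntimeError):
    """Raised when a map file is unreadable or has the wrong schema."""


def _default_mu_s() -> tuple:
    # 0.10 .. 0.20 mm^-1, step 0.01 (11 values)
    return tuple(np.round(np.arange(0.10, 0.201, 0.01), 2))


def _default_g() -> tuple:
    # 0.85 .. 0.99, step 0.01 (15 values)
    return tuple(np.round(np.arange(0.85, 0.991, 0.01), 2))


@dataclass(frozen=True)
class ParameterGrid:
    """The (mu_s, g) grid the map is built over."""

    mu_s_values: tuple = field(default_factory=_default_mu_s)
    g_values: tuple = field(default_factory=_default_g)

    def __post_init__(self) -> None:
        for name, vals in (("mu_s", self.mu_s_values), ("g", self.g_values)):
            arr = np.asarray(vals, dtype=float)
            if arr.size == 0:
                raise ValueError(f"{name} values must be non-empty")
            if np.unique(arr).size != arr.size:
                raise ValueError(f"duplicate {name} values in grid")
            if not np.all(np.diff(arr) > 0):
                raise ValueError(f"{name} values must be strictly increasing")
            object.__setattr__(self, f"{name}_values", tuple(arr))

    @property
    def n_sim(self) -> int:
        return len(self.mu_s_values) * len(self.g_values)


def enumerate_grid(grid: ParameterGrid) -> list:
    """Cartesian product of the grid, row-major in mu_s then g."""
    return [(mu, g) for mu in grid.mu_s_values for g in grid.g_values]


def entry_seed(master_seed: int, k: int) -> int:
    """Stable sub-seed for entry k: SeedSequence((master_seed, k))."""
    return int(np.random.SeedSequence((int(master_seed), int(k))).generate_state(1)[0])


@dataclass
class ReferenceEntry:
    """One grid point: ROI block, its summary, and build provenance."""

    mu_s: float
    g: float
    roi: np.ndarray
    seed: int
    column_counts: np.ndarray
    valid: bool
    summary: SpeckleSummary | None = None

    def compute_summary(self, grid: np.ndarray) -> None:
        block = normalize_sim(self.roi)
        self.summary = SpeckleSummary(
            cr=contrast_ratio(block), density=estimate_density(block, grid)
        )


@dataclass
class LookupMap:
    """All reference entries plus the provenance needed to reproduce them."""

    entries: list
    grid: ParameterGrid
    master_seed: int
    n_packets: int
    n_ascans: int
    roi_depth_px: int
    source: SourceSpec
    detector: DetectorSpec
    depth_grid: DepthGrid
    density_grid: np.ndarray

    @property
    def n_sim(self) -> int:
        return len(self.entries)

    def valid_entries(self) -> list:
        return [e for e in self.entries if e.valid]


def build_map(
    grid: ParameterGrid | None = None,
    n_packets: int = 15_000_000,
    master_seed: int = 0,
    n_ascans: int = DEFAULT_N_ASCANS,
    roi_depth_px: int = DEFAULT_ROI_DEPTH_PX,
    source: SourceSpec | None = None,
    detector: DetectorSpec | None = None,
    depth_grid: DepthGrid | None = None,
    mu_a: float = 0.0,
    progress: bool = False,
) -> LookupMap:
    """Simulate one B-scan ROI per grid point and summarize it.

    Entry content depends only on (mu_s, g, sub-seed), never on build order.
    A grid point with zero detected photons in every column is kept but
    flagged invalid and excluded from matching.
    """
    grid = grid or ParameterGrid()
    source = source or SourceSpec()
    detector = detector or DetectorSpec()
    depth_grid = depth_grid or DepthGrid()
    entries: list = []
    pairs = enumerate_grid(grid)
    for k, (mu_s, g) in enumerate(pairs):
        stack = LayerStack.single_layer(mu_s=mu_s, g=g, mu_a=mu_a)
        sub = entry_seed(master_seed, k)
        bscan = build_bscan(
            stack, detector, source, depth_grid,
            n_ascans=n_ascans, n_packets=n_packets, seed=sub,
        )
        roi = extract_sim_roi(bscan, roi_depth_px)
        valid = bool(roi.max() > 0)
        entries.append(
            ReferenceEntry(mu_s=mu_s, g=g, roi=roi, seed=sub,
                           column_counts=bscan.column_counts, valid=valid)
        )
        if progress:
            print(f"[{k + 1}/{len(pairs)}] mu_s={mu_s:.2f} g={g:.2f} "
                  f"detected/column={bscan.column_counts.mean():.1f}")
    lookup = LookupMap(
        entries=entries, grid=grid, master_seed=int(master_seed),
        n_packets=int(n_packets), n_ascans=int(n_ascans),
        roi_depth_px=int(roi_depth_px), source=source, detector=detector,
        depth_grid=depth_grid, density_grid=np.empty(0),
    )
    _refresh_summaries(lookup)
    return lookup


def _refresh_summaries(lookup: LookupMap) -> None:
    """(Re)compute all entry summaries on the map-wide shared grid."""
    valid = lookup.valid_entries()
    if not valid:
        lookup.density_grid = np.empty(0)
        return
    blocks = [normalize_sim(e.roi) for e in valid]
    grid = shared_grid(*blocks)
    lookup.density_grid = grid
    for entry, block in zip(valid, blocks):
        entry.summary = SpeckleSummary(
            cr=contrast_ratio(block), density=estimate_density(block, grid)
        )


def save_map(lookup: LookupMap, path) -> None:
    """Persist the map losslessly (pixels, metadata, provenance) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["master_seed"] = lookup.master_seed
        f.attrs["n_packets"] = lookup.n_packets
        f.attrs["n_ascans"] = lookup.n_ascans
        f.attrs["roi_depth_px"] = lookup.roi_depth_px
        gg = f.create_group("grid")
        gg.create_dataset("mu_s", data=np.asarray(lookup.grid.mu_s_values))
        gg.create_dataset("g", data=np.asarray(lookup.grid.g_values))
        prov = f.create_group("provenance")
        prov.attrs["lambda0_nm"] = lookup.source.lambda0_nm
        prov.attrs["dlambda_nm"] = lookup.source.delta_lambda_nm
        prov.attrs["detector_radius_cm"] = lookup.detector.radius_cm
        prov.attrs["detector_height_um"] = lookup.detector.height_um
        prov.attrs["pixel_um"] = lookup.depth_grid.pixel_um
        prov.attrs["n_pixels"] = lookup.depth_grid.n_pixels
        prov.attrs["sample_n"] = lookup.depth_grid.sample_n
        f.create_dataset("density_grid", data=lookup.density_grid)
        ee = f.create_group("entries")
        for k, entry in enumerate(lookup.entries):
            grp = ee.create_group(f"{k:04d}")
            grp.attrs["mu_s"] = entry.mu_s
            grp.attrs["g"] = entry.g
            grp.attrs["seed"] = entry.seed
            grp.attrs["valid"] = entry.valid
            grp.create_dataset("roi", data=entry.roi)
            grp.create_dataset("column_counts", data=entry.column_counts)


def load_map(path) -> LookupMap:
    """Load a map written by :func:`save_map`; summaries are recomputed.

    Raises :class:`MapFormatError` for truncated files or schema mismatches.
    """
    try:
        f = h5py.File(path, "r")
    except (OSError, IOError) as exc:
        raise MapFormatError(f"cannot open map file {path!r}: {exc}") from exc
    with f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise MapFormatError(
                f"map schema version mismatch: found {version!r}, "
                f"expected {SCHEMA_VERSION}"
            )
        try:
            grid = ParameterGrid(
                mu_s_values=tuple(f["grid/mu_s"][()]),
                g_values=tuple(f["grid/g"][()]),
            )
            prov = f["provenance"]
            source = SourceSpec(
                lambda0_nm=float(prov.attrs["lambda0_nm"]),
                delta_lambda_nm=float(prov.attrs["dlambda_nm"]),
            )
            detector = DetectorSpec(
                radius_cm=float(prov.attrs["detector_radius_cm"]),
                height_um=float(prov.attrs["detector_height_um"]),
            )
            depth_grid = DepthGrid(
                pixel_um=float(prov.attrs["pixel_um"]),
                n_pixels=int(prov.attrs["n_pixels"]),
                sample_n=float(prov.attrs["sample_n"]),
            )
            entries = []
            ee = f["entries"]
            for key in sorted(ee.keys()):
                grp = ee[key]
                entries.append(
                    ReferenceEntry(
                        mu_s=float(grp.attrs["mu_s"]),
                        g=float(grp.attrs["g"]),
                        roi=grp["roi"][()],
                        seed=int(grp.attrs["seed"]),
                        column_counts=grp["column_counts"][()],
                        valid=bool(grp.attrs["valid"]),
                    )
                )
            lookup = LookupMap(
                entries=entries, grid=grid,
                master_seed=int(f.attrs["master_seed"]),
                n_packets=int(f.attrs["n_packets"]),
                n_ascans=int(f.attrs["n_ascans"]),
                roi_depth_px=int(f.attrs["roi_depth_px"]),
                source=source, detector=detector, depth_grid=depth_grid,
                density_grid=f["density_grid"][()],
            )
        except KeyError as exc:
            raise MapFormatError(f"map file {path!r} is incomplete: {exc}") from exc
    if lookup.n_sim != grid.n_sim:
        raise MapFormatError(
            f"entry count {lookup.n_sim} does not match grid size {grid.n_sim}"
        )
    _refresh_summaries(lookup)
    return lookup
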