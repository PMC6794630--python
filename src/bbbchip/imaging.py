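"""Synthetic dextran-influx assays and fluorescence time-lapse rendering.

The influx assay loads the endothelialized channel (``bec_barrier_mc``) with
10 uM fluorescent dextran at t=0 and images the adjacent collagen scaffold as
tracer crosses the endothelial monolayer. Here the assay is simulated with a
*known* membrane permeability P_true (the monolayer conductance is set to
P_true directly), and frames are rendered with a linear intensity model

    pixel = gain * C + background  (+ optional Poisson shot and Gaussian read noise)

clipped to the detector range. Intensity linear in concentration, with no
photobleaching or depth attenuation, is exactly the regime the control-volume
permeability equation presumes; the noise model is configurable because the
original acquisitions do not constrain it.

Cohorts of devices ("wild-type-like" vs "AD-like" groups) draw per-device
permeabilities from a log-normal distribution with specified group mean and
coefficient of variation, mirroring positive, right-skewed barrier
permeabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .geometry import DeviceLayout, build_default_layout
from .transport import (
    ConfigurationError,
    SimulationConfig,
    SimulationHistory,
    run,
)
from .units import cm_s_to_m_s, molar_to_mol_m3

__all__ = [
    "AssayGroundTruth",
    "ImagingModel",
    "TimeLapse",
    "simulate_dextran_assay",
    "render_timelapse",
    "draw_cohort_permeabilities",
    "generate_cohort",
    "DEFAULT_LUMINAL_CONCENTRATION_MOL_M3",
]

#: 10 uM luminal dextran = 1e-2 mol m^-3.
DEFAULT_LUMINAL_CONCENTRATION_MOL_M3 = molar_to_mol_m3(10e-6)

#: Frames every 5 min; 25 frames cover the full 2 h acquisition.
DEFAULT_FRAME_INTERVAL_S = 300.0
DEFAULT_N_FRAMES = 25


@dataclass(frozen=True)
class AssayGroundTruth:
    """Known-truth description of one synthetic influx assay."""

    p_true_cm_s: float
    solute: str = "dextran_40kda"
    luminal_concentration_mol_m3: float = DEFAULT_LUMINAL_CONCENTRATION_MOL_M3
    layout: DeviceLayout | None = None
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    n_frames: int = DEFAULT_N_FRAMES
    seed: int = 0
    device_id: str = "device0"
    group: str = ""

    def __post_init__(self) -> None:
        if self.p_true_cm_s < 0:
            raise ConfigurationError("P_true must be >= 0")
        if not self.luminal_concentration_mol_m3 > 0:
            raise ConfigurationError("luminal concentration must be > 0")
        if not self.frame_interval_s > 0:
            raise ConfigurationError("frame interval must be > 0")
        if self.n_frames < 2:
            raise ConfigurationError("need at least 2 frames")


@dataclass(frozen=True)
class ImagingModel:
    """Linear camera model for rendering concentration into intensity."""

    gain: float = 2.0e5  # intensity units per (mol m^-3); ~2000 counts at 10 uM
    background: float = 100.0
    gaussian_sigma: float = 20.0
    poisson_enabled: bool = True
    pixel_size_um: float | None = None  # None: use the simulation grid spacing
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise ConfigurationError("gain must be > 0")
        if self.background < 0 or self.gaussian_sigma < 0:
            raise ConfigurationError("background and sigma must be >= 0")

    @property
    def ceiling(self) -> float:
        return float(2**self.bit_depth - 1)

    def noiseless(self) -> "ImagingModel":
        return replace(self, gaussian_sigma=0.0, poisson_enabled=False)


@dataclass
class TimeLapse:
    """A rendered or loaded fluorescence stack with frame clock and scale."""

    frames: np.ndarray  # (n_frames, ny, nx), float
    timestamps_s: np.ndarray
    pixel_size_um: float
    metadata: dict = field(default_factory=dict)

    def validate(self) -> "TimeLapse":
        if self.frames.ndim != 3:
            raise ConfigurationError("frames must be a (t, y, x) stack")
        if len(self.timestamps_s) != len(self.frames):
            raise ConfigurationError("one timestamp per frame required")
        dt = np.diff(self.timestamps_s)
        if len(dt) and not np.all(dt > 0):
            raise ConfigurationError("timestamps must be strictly increasing")
        if self.timestamps_s[0] != 0:
            raise ConfigurationError("timestamps must start at 0")
        return self

    # -- OME-TIFF persistence ----------------------------------------------

    def to_ome_tiff(self, path) -> None:
        """Write frames as OME-TIFF planes with DeltaT timestamps and the
        pixel size in the OME pixels element; package metadata goes into the
        image description."""
        import tifffile

        with tifffile.TiffWriter(path, ome=True) as tw:
            tw.write(
                self.frames.astype(np.float32),
                photometric="minisblack",
                metadata={
                    "axes": "TYX",
                    "PhysicalSizeX": float(self.pixel_size_um),
                    "PhysicalSizeXUnit": "µm",
                    "PhysicalSizeY": float(self.pixel_size_um),
                    "PhysicalSizeYUnit": "µm",
                    "Plane": {"DeltaT": [float(t) for t in self.timestamps_s]},
                    "Description": json.dumps(self.metadata),
                },
            )

    @classmethod
    def from_ome_tiff(cls, path) -> "TimeLapse":
        import xml.etree.ElementTree as ET

        import tifffile

        with tifffile.TiffFile(path) as tf:
            frames = tf.asarray()
            ome = tf.ome_metadata
        root = ET.fromstring(ome)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        pixels = root.find(".//ome:Pixels", ns)
        pixel_size = float(pixels.attrib["PhysicalSizeX"])
        timestamps = np.array(
            [float(p.attrib["DeltaT"]) for p in pixels.findall("ome:Plane", ns)]
        )
        desc = root.find(".//ome:Image/ome:Description", ns)
        meta = json.loads(desc.text) if desc is not None and desc.text else {}
        return cls(
            frames=np.asarray(frames, dtype=float),
            timestamps_s=timestamps,
            pixel_size_um=pixel_size,
            metadata=meta,
        ).validate()


# ---------------------------------------------------------------------------
# assay simulation
# ---------------------------------------------------------------------------


def simulate_dextran_assay(
    truth: AssayGroundTruth,
    dx_um: float = 25.0,
    dt_s: float | None = None,
    scheme: str = "implicit",
) -> SimulationHistory:
    """Simulate one influx assay with membrane conductance K = P_true.

    The luminal channel starts uniformly at the ground-truth concentration and
    every other channel at zero; snapshots are taken on the frame clock. The
    run is deterministic (all randomness lives in rendering).
    """
    layout = truth.layout if truth.layout is not None else build_default_layout()
    t_end = truth.frame_interval_s * (truth.n_frames - 1)
    if dt_s is None:
        dt_s = min(truth.frame_interval_s / 10.0, 30.0)
    config = SimulationConfig(
        layout=layout,
        solute=truth.solute,
        dx_um=dx_um,
        dt_s=dt_s,
        t_end_s=t_end,
        initial_values={"bec_barrier_mc": truth.luminal_concentration_mol_m3},
        snapshot_interval_s=truth.frame_interval_s,
        scheme=scheme,
        membrane_conductance_m_s=cm_s_to_m_s(truth.p_true_cm_s),
    )
    return run(config)


def render_timelapse(
    history: SimulationHistory,
    model: ImagingModel,
    seed: int,
    frame_times_s: Sequence[float] | None = None,
    metadata: Mapping | None = None,
) -> TimeLapse:
    """Render a concentration history into a fluorescence time-lapse.

    Pure function of (history, model, seed): identical inputs give
    bit-identical stacks. Raises if a requested frame time has no snapshot.
    """
    if frame_times_s is None:
        frame_times_s = history.times_s
    rng = np.random.default_rng(seed)
    frames = []
    for t in frame_times_s:
        snap = history.snapshot_at(float(t))  # KeyError on clock mismatch
        img = model.gain * snap.values + model.background
        if model.poisson_enabled:
            img = rng.poisson(np.maximum(img, 0.0)).astype(float)
        if model.gaussian_sigma > 0:
            img = img + rng.normal(0.0, model.gaussian_sigma, size=img.shape)
        frames.append(np.clip(img, 0.0, model.ceiling))
    pixel = model.pixel_size_um or history.grid.dx_um
    meta = dict(metadata or {})
    meta.setdefault("seed", int(seed))
    meta.setdefault("bit_depth", model.bit_depth)
    return TimeLapse(
        frames=np.asarray(frames),
        timestamps_s=np.asarray(frame_times_s, dtype=float)
        - float(frame_times_s[0]),
        pixel_size_um=float(pixel),
        metadata=meta,
    ).validate()


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and CV."""
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def draw_cohort_permeabilities(
    n: int, mean_cm_s: float, cv: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-device true permeabilities, log-normal with arithmetic mean/CV."""
    if n <= 0:
        raise ConfigurationError("cohort size must be > 0")
    if not mean_cm_s > 0:
        raise ConfigurationError("group mean permeability must be > 0")
    if cv < 0:
        raise ConfigurationError("dispersion (CV) must be >= 0")
    if cv == 0:
        return np.full(n, mean_cm_s)
    mu, sigma = _lognormal_params(mean_cm_s, cv)
    return rng.lognormal(mu, sigma, size=n)


def derive_subseeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-device seeds spawned from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def generate_cohort(
    n_wt: int = 13,
    n_ad: int = 25,
    p_means_cm_s: Mapping[str, float] = None,
    dispersion: float = 0.25,
    model: ImagingModel | None = None,
    seed: int = 0,
    layout: DeviceLayout | None = None,
    solute: str = "dextran_40kda",
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
    n_frames: int = DEFAULT_N_FRAMES,
    dx_um: float = 25.0,
) -> list[tuple[TimeLapse, AssayGroundTruth]]:
    """Simulate and render a two-group cohort of synthetic assays.

    Default cohort sizes (13 wild-type-like, 25 AD-like) and 40 kDa group
    means follow the measured study design; per-device truths are drawn
    log-normally with coefficient of variation ``dispersion`` and each device
    gets a deterministic sub-seed derived from ``seed``.
    """
    if p_means_cm_s is None:
        p_means_cm_s = {"wt": 1.96e-6, "ad": 6.45e-6}
    model = model if model is not None else ImagingModel()
    rng = np.random.default_rng(seed)
    p_wt = draw_cohort_permeabilities(n_wt, p_means_cm_s["wt"], dispersion, rng)
    p_ad = draw_cohort_permeabilities(n_ad, p_means_cm_s["ad"], dispersion, rng)
    subseeds = derive_subseeds(seed, n_wt + n_ad)

    out: list[tuple[TimeLapse, AssayGroundTruth]] = []
    i = 0
    for group, p_vals in (("wt", p_wt), ("ad", p_ad)):
        for p in p_vals:
            truth = AssayGroundTruth(
                p_true_cm_s=float(p),
                solute=solute,
                layout=layout,
                frame_interval_s=frame_interval_s,
                n_frames=n_frames,
                seed=subseeds[i],
                device_id=f"{group}_{i:03d}",
                group=group,
            )
            history = simulate_dextran_assay(truth, dx_um=dx_um)
            stack = render_timelapse(
                history,
                model,
                truth.seed,
                metadata={"device_id": truth.device_id, "group": group,
                          "solute": solute},
            )
            out.append((stack, truth))
            i += 1
    return out
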