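"""Synthetic voxel skull phantoms, sensor layouts, and reference FRFs.

The phantom is a desk-scale stand-in for a CT-derived whale skull
volume.  It reproduces the *topology* that drives bone-conduction
mechanics rather than anatomical shape: a bone plate ("basicranium")
from which two stiff, dense tympanoperiotic-complex (TPC) blocks hang
on compliant connective-tissue pedicles, plus an optional mandible
joined to the cranium only through temporomandibular-joint (TMJ) and
symphysis tissue.  The pedicle suspension gives each bulla a resonant
swinging mode inside the measurement band — the signature the pipeline
is built to detect.

Voxel labels: 0 empty/water, 1 skull+mandible bone, 2 TPC, 3
TMJ/symphysis/pedicle connective tissue.  Axes: x = mediolateral (ML),
y = dorsoventral (DV), z = anteroposterior (AP).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .frf import FRFSet
from .materials import LABEL_BONE, LABEL_TPC, LABEL_TMJ

#: Unit anatomical axes in world coordinates.
AXIS_ML = np.array([1.0, 0.0, 0.0])
AXIS_DV = np.array([0.0, 1.0, 0.0])
AXIS_AP = np.array([0.0, 0.0, 1.0])

#: Sensor and lead-wire masses, kg.  AP channels carry the heavier
#: piezo accelerometer (7.5 g), ML channels the lighter one (3 g); each
#: sensor trails 0.25 m of lead at 12 g/m, lumped at the sensor node.
SENSOR_MASS_AP = 7.5e-3
SENSOR_MASS_ML = 3.0e-3
LEAD_MASS = 0.25 * 12.0e-3


@dataclass
class VoxelPhantom:
    """Labeled voxel volume with world-coordinate geometry.

    ``labels[i, j, k]`` is the material class of the half-open voxel
    ``origin + [i, i+1) * spacing`` (per axis), labels in {0, 1, 2, 3}.
    ``region`` distinguishes cranium from mandible voxels, which share
    the bone material class.
    """

    labels: np.ndarray
    spacing: np.ndarray  # mm, per axis
    origin: np.ndarray  # mm, world coords of voxel (0,0,0) corner
    region: np.ndarray | None = None  # same shape; 0 none, 1 cranium, 2 mandible
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if not np.isin(self.labels, [0, 1, 2, 3]).all():
            raise ValueError("labels must be in {0, 1, 2, 3}")
        if self.nonempty_count == 0:
            raise ValueError("phantom contains no solid voxels")

    @property
    def shape(self):
        return self.labels.shape

    @property
    def nonempty_count(self) -> int:
        return int(np.count_nonzero(self.labels))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def save(self, path) -> None:
        """Write the labeled volume (compressed array container) with a
        JSON sidecar holding spacing, origin and the label legend."""
        path = Path(path)
        np.savez_compressed(
            path.with_suffix(".npz"),
            labels=self.labels,
            region=self.region if self.region is not None else np.zeros(0, np.int8),
        )
        sidecar = {
            "spacing_mm": self.spacing.tolist(),
            "origin_mm": self.origin.tolist(),
            "labels": {"0": "empty/water", "1": "bone", "2": "TPC", "3": "TMJ/pedicle"},
            "meta": self.meta,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    def export_vtk(self, path) -> None:
        """Legacy-ASCII VTK image data of the label volume (cell data),
        for visual inspection."""
        n = self.labels.shape
        with open(path, "w") as f:
            f.write("# vtk DataFile Version 3.0\nskullvibe phantom labels\n"
                    "ASCII\nDATASET STRUCTURED_POINTS\n")
            f.write(f"DIMENSIONS {n[0] + 1} {n[1] + 1} {n[2] + 1}\n")
            f.write(f"ORIGIN {self.origin[0]} {self.origin[1]} {self.origin[2]}\n")
            f.write(f"SPACING {self.spacing[0]} {self.spacing[1]} "
                    f"{self.spacing[2]}\n")
            f.write(f"CELL_DATA {self.labels.size}\n"
                    "SCALARS label int 1\nLOOKUP_TABLE default\n")
            np.savetxt(f, self.labels.ravel(order="F"), fmt="%d")

    @classmethod
    def load(cls, path) -> "VoxelPhantom":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        sidecar = json.loads(path.with_suffix(".json").read_text())
        region = arrays["region"]
        return cls(
            arrays["labels"],
            np.array(sidecar["spacing_mm"]),
            np.array(sidecar["origin_mm"]),
            region if region.size else None,
            sidecar.get("meta", {}),
        )


@dataclass(frozen=True)
class SensorSpec:
    """A uniaxial accelerometer channel bound to a world location."""

    name: str
    location: np.ndarray  # mm
    axis: np.ndarray  # unit vector
    mass: float  # kg

    def __post_init__(self) -> None:
        object.__setattr__(self, "location", np.asarray(self.location, float))
        object.__setattr__(self, "axis", np.asarray(self.axis, float))
        if abs(np.linalg.norm(self.axis) - 1.0) > 1e-9:
            raise ValueError(f"sensor {self.name}: axis must be a unit vector")
        if self.mass < 0:
            raise ValueError(f"sensor {self.name}: mass must be nonnegative")


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry of the synthetic skull, in base-resolution voxel units.

    All extents are half-open ``(start, stop)`` index ranges on the base
    grid; ``refine`` scales the grid (and shrinks the spacing) so the
    world-space solid is identical across refinement levels.
    """

    shape: tuple = (24, 24, 48)  # (ML, DV, AP) voxels
    spacing_mm: float = 5.0
    cranium_x: tuple = (2, 22)
    cranium_y: tuple = (16, 22)
    cranium_z: tuple = (4, 44)
    bulla_size: tuple = (4, 4, 6)  # (ML, DV, AP) voxels
    bulla_y: tuple = (10, 14)
    bulla_z: tuple = (21, 27)
    left_bulla_x: tuple = (6, 10)
    right_bulla_x: tuple = (14, 18)
    pedicle_z: tuple = ((22, 23), (25, 26))  # two columns per bulla
    mandible: bool = True
    mandible_y: tuple = (10, 14)
    mandible_z: tuple = (6, 42)
    rail_halfwidth: int = 2  # mandible rails hug the x faces
    tmj_z: tuple = (39, 42)
    symphysis_z: tuple = (6, 8)
    roughness: float = 0.0  # probability of carving a bone surface voxel
    refine: int = 1

    def scaled(self, refine: int) -> "PhantomConfig":
        d = asdict(self)
        d["refine"] = refine
        return PhantomConfig(**d)


def _check_config(cfg: PhantomConfig) -> None:
    nx, ny, nz = cfg.shape
    if min(cfg.shape) < 8:
        raise ValueError(f"grid dims must be >= 8 per axis, got {cfg.shape}")
    bx, by, bz = cfg.bulla_size
    for side, xr in (("left", cfg.left_bulla_x), ("right", cfg.right_bulla_x)):
        if xr[1] - xr[0] != bx:
            raise ValueError(f"{side} bulla x-extent {xr} does not match bulla_size x={bx}")
        if xr[0] < 0 or xr[1] > nx:
            raise ValueError(f"{side} bulla x-extent {xr} exceeds grid x-dimension {nx}")
        if cfg.mandible:
            inner = (cfg.cranium_x[0] + cfg.rail_halfwidth,
                     cfg.cranium_x[1] - cfg.rail_halfwidth)
            if xr[0] < inner[0] or xr[1] > inner[1]:
                raise ValueError(
                    f"{side} bulla x-extent {xr} collides with the mandible "
                    f"rails; must lie within {inner}")
    if cfg.bulla_y[1] > cfg.cranium_y[0]:
        raise ValueError(
            f"bulla y-extent {cfg.bulla_y} overlaps cranium y-extent {cfg.cranium_y}"
        )
    if cfg.bulla_y[1] - cfg.bulla_y[0] != by or cfg.bulla_z[1] - cfg.bulla_z[0] != bz:
        raise ValueError("bulla y/z extents inconsistent with bulla_size")
    if cfg.bulla_z[0] < 0 or cfg.bulla_z[1] > nz:
        raise ValueError(f"bulla z-extent {cfg.bulla_z} exceeds grid z-dimension {nz}")
    if cfg.cranium_x[1] > nx or cfg.cranium_y[1] > ny or cfg.cranium_z[1] > nz:
        raise ValueError(
            f"cranium extents exceed grid: x{cfg.cranium_x} y{cfg.cranium_y} "
            f"z{cfg.cranium_z} vs shape {cfg.shape}"
        )
    for zc in cfg.pedicle_z:
        if not (cfg.bulla_z[0] <= zc[0] and zc[1] <= cfg.bulla_z[1]):
            raise ValueError(f"pedicle z-extent {zc} not above the bulla {cfg.bulla_z}")


def _fill(grid, xr, yr, zr, value, s):
    grid[xr[0] * s : xr[1] * s, yr[0] * s : yr[1] * s, zr[0] * s : zr[1] * s] = value


def generate_phantom(config: PhantomConfig | None = None, seed: int = 0) -> VoxelPhantom:
    """Build the synthetic skull volume.

    Deterministic for a given ``(config, seed)``; the seed only matters
    when ``config.roughness > 0``, which carves isolated voxels from the
    cranium surface to emulate segmentation raggedness.
    """
    cfg = config or PhantomConfig()
    _check_config(cfg)
    s = cfg.refine
    if s < 1:
        raise ValueError("refine must be >= 1")
    shape = tuple(n * s for n in cfg.shape)
    labels = np.zeros(shape, dtype=np.int8)
    region = np.zeros(shape, dtype=np.int8)

    # Basicranium plate.
    _fill(labels, cfg.cranium_x, cfg.cranium_y, cfg.cranium_z, LABEL_BONE, s)
    _fill(region, cfg.cranium_x, cfg.cranium_y, cfg.cranium_z, 1, s)

    # Two TPC blocks hanging below the plate on connective pedicles.
    pedicle_y = (cfg.bulla_y[1], cfg.cranium_y[0])
    for xr in (cfg.left_bulla_x, cfg.right_bulla_x):
        _fill(labels, xr, cfg.bulla_y, cfg.bulla_z, LABEL_TPC, s)
        xmid = (xr[0] + xr[1]) // 2
        for zc in cfg.pedicle_z:
            _fill(labels, (xmid - 1, xmid), pedicle_y, zc, LABEL_TMJ, s)

    if cfg.mandible:
        nx = cfg.shape[0]
        left_rail = (cfg.cranium_x[0], cfg.cranium_x[0] + cfg.rail_halfwidth)
        right_rail = (cfg.cranium_x[1] - cfg.rail_halfwidth, cfg.cranium_x[1])
        for rail in (left_rail, right_rail):
            _fill(labels, rail, cfg.mandible_y, cfg.mandible_z, LABEL_BONE, s)
            _fill(region, rail, cfg.mandible_y, cfg.mandible_z, 2, s)
            # TMJ pad joins the rail top to the cranium underside.
            _fill(labels, rail, (cfg.mandible_y[1], cfg.cranium_y[0]), cfg.tmj_z,
                  LABEL_TMJ, s)
        # Symphysis bridges the two rails anteriorly.
        _fill(labels, (left_rail[1], right_rail[0]), cfg.mandible_y,
              cfg.symphysis_z, LABEL_TMJ, s)

    if cfg.roughness > 0:
        rng = np.random.default_rng(seed)
        bone = labels == LABEL_BONE
        eroded = ndimage.binary_erosion(bone)
        surface = np.argwhere(bone & ~eroded)
        carve = surface[rng.random(len(surface)) < cfg.roughness]
        labels[tuple(carve.T)] = 0

    spacing = np.full(3, cfg.spacing_mm / s)
    ph = VoxelPhantom(labels, spacing, np.zeros(3), region,
                      meta={"seed": int(seed), "refine": int(s)})
    return ph


def _bulla_boxes(phantom: VoxelPhantom):
    """Bounding boxes of the two TPC components, sorted left (low x)
    to right.  Raises if a side is missing."""
    comps, n = ndimage.label(phantom.labels == LABEL_TPC)
    if n < 2:
        missing = "right" if n == 1 else "left and right"
        raise ValueError(f"phantom is missing the {missing} bulla "
                         f"(found {n} TPC component(s), need 2)")
    if n > 2:
        raise ValueError(f"expected 2 TPC components, found {n}")
    boxes = ndimage.find_objects(comps)
    boxes = sorted(boxes, key=lambda sl: sl[0].start)
    return boxes


def place_sensors(phantom: VoxelPhantom) -> list[SensorSpec]:
    """The seven-channel accelerometer layout of the validation
    experiments.

    Skull channels S/ML, S/AP, S/DV sit at the center of the dorsal
    cranium surface; their mass is negligible relative to the skull and
    is not added to the model.  Each bulla carries an ML channel on its
    posterior apex and an AP channel on its ventral keel, with sensor
    plus lead-wire mass lumped at the attachment point.
    """
    h = phantom.spacing
    o = phantom.origin

    def world(idx):  # voxel-corner index -> world mm
        return o + np.asarray(idx, float) * h

    bone = np.argwhere(phantom.labels == LABEL_BONE)
    if bone.size == 0:
        raise ValueError("phantom has no bone voxels")
    if phantom.region is not None:
        cr = np.argwhere((phantom.labels == LABEL_BONE) & (phantom.region == 1))
        bone = cr if cr.size else bone
    top_y = bone[:, 1].max() + 1
    cx = 0.5 * (bone[:, 0].min() + bone[:, 0].max() + 1)
    cz = 0.5 * (bone[:, 2].min() + bone[:, 2].max() + 1)
    skull_pt = world([cx, top_y, cz])

    sensors = [
        SensorSpec("S/ML", skull_pt, AXIS_ML, 0.0),
        SensorSpec("S/AP", skull_pt, AXIS_AP, 0.0),
        SensorSpec("S/DV", skull_pt, AXIS_DV, 0.0),
    ]
    for side, box in zip(("L", "R"), _bulla_boxes(phantom)):
        xs, ys, zs = box
        bcx = 0.5 * (xs.start + xs.stop)
        bcy = 0.5 * (ys.start + ys.stop)
        # posterior apex: center of the max-z face
        ml_pt = world([bcx, bcy, zs.stop])
        # ventral keel: center of the min-y face
        ap_pt = world([bcx, ys.start, 0.5 * (zs.start + zs.stop)])
        sensors.append(SensorSpec(f"{side}/ML", ml_pt, AXIS_ML,
                                  SENSOR_MASS_ML + LEAD_MASS))
        sensors.append(SensorSpec(f"{side}/AP", ap_pt, AXIS_AP,
                                  SENSOR_MASS_AP + LEAD_MASS))
    order = ["S/ML", "S/AP", "S/DV", "L/ML", "L/AP", "R/ML", "R/AP"]
    sensors.sort(key=lambda sp: order.index(sp.name))
    return sensors


@dataclass
class SyntheticFRFSpec:
    """Recipe for synthetic "experimental" FRFs built from modal
    resonances.

    ``modes`` is a list of ``(f_r, eta_r, participation)`` where
    ``participation`` maps channel names to modal participation factors
    a_r (m/s^2/Pa at resonance scale).  Channels are the union of all
    participation keys.  Noise emulates smoothed pool measurements:
    log-normal multiplicative magnitude error (``sd_db``), uniform phase
    jitter, and an additive complex floor.
    """

    modes: list
    freq: np.ndarray
    sd_db: float = 1.0
    phase_jitter: float = 0.2  # radians, half-width of uniform jitter
    floor: float = 1e-4  # m/s^2/Pa additive noise scale

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if not np.all(np.diff(self.freq) > 0):
            raise ValueError("frequency grid must be strictly increasing")
        for f_r, eta_r, part in self.modes:
            if f_r <= 0:
                raise ValueError(f"natural frequency must be positive, got {f_r}")
            if eta_r < 0:
                raise ValueError(f"loss factor must be nonnegative, got {eta_r}")
            if eta_r == 0 and np.any(np.isclose(self.freq, f_r, rtol=0, atol=1e-12)):
                raise ValueError(
                    f"grid hits the undamped pole at {f_r} Hz (loss factor 0)"
                )

    @property
    def channel_names(self) -> list:
        names = []
        for _, _, part in self.modes:
            for k in part:
                if k not in names:
                    names.append(k)
        return names


def modal_frf(freq: np.ndarray, modes: list, channel: str) -> np.ndarray:
    """Closed-form acceleration FRF of a sum of structurally damped
    modes: H(w) = sum_r (-w^2 a_r) / (w_r^2 (1 + i eta_r) - w^2)."""
    w2 = (2 * np.pi * np.asarray(freq, float)) ** 2
    H = np.zeros(len(freq), dtype=complex)
    for f_r, eta_r, part in modes:
        a = part.get(channel, 0.0)
        if a == 0.0:
            continue
        wr2 = (2 * np.pi * f_r) ** 2
        H += (-w2 * a) / (wr2 * (1.0 + 1j * eta_r) - w2)
    return H


def generate_reference_frf(spec: SyntheticFRFSpec, seed: int = 0) -> FRFSet:
    """Realize a noisy synthetic "measurement" from the modal recipe."""
    rng = np.random.default_rng(seed)
    channels = {}
    for name in spec.channel_names:
        H = modal_frf(spec.freq, spec.modes, name)
        if spec.sd_db > 0:
            gain = 10.0 ** (rng.normal(0.0, spec.sd_db, len(spec.freq)) / 20.0)
            H = H * gain
        if spec.phase_jitter > 0:
            H = H * np.exp(1j * rng.uniform(-spec.phase_jitter, spec.phase_jitter,
                                            len(spec.freq)))
        if spec.floor > 0:
            H = H + spec.floor * (rng.standard_normal(len(spec.freq))
                                  + 1j * rng.standard_normal(len(spec.freq))) / np.sqrt(2)
        channels[name] = H
    return FRFSet(spec.freq, channels)


def default_reference_spec(freq: np.ndarray, channels=None) -> SyntheticFRFSpec:
    """A plausible seven-channel modal recipe at phantom scale.

    Three resonance groups emulate the measured structure: a low bulla
    swing resonance dominating the ML channels, a mid-band axial bulla
    resonance on the AP channels, and a high skull-plate resonance on
    the skull channels.
    """
    if channels is None:
        channels = ["S/ML", "S/AP", "S/DV", "L/ML", "L/AP", "R/ML", "R/AP"]
    # Participation factors (m/s^2/Pa) at the response scale of the
    # desk-scale phantom: bulla channels peak at a few 1e-3 near the
    # pedicle swing resonance, skull in-plane motion is orders weaker.
    swing = {"L/ML": 3.5e-4, "R/ML": 3.5e-4, "L/AP": 6.0e-4, "R/AP": 6.0e-4,
             "S/AP": 1.0e-4, "S/DV": 3.0e-6, "S/ML": 1.0e-6}
    axial = {"L/AP": 1.0e-5, "R/AP": 1.0e-5, "L/ML": 8.0e-6, "R/ML": 8.0e-6,
             "S/AP": 5.0e-5, "S/DV": 1.0e-6, "S/ML": 2.0e-7}
    plate = {"S/AP": 3.0e-4, "S/DV": 2.0e-6, "S/ML": 3.0e-7,
             "L/ML": 5.0e-6, "R/ML": 5.0e-6, "L/AP": 6.0e-5, "R/AP": 6.0e-5}
    modes = [(330.0, 0.1, swing), (650.0, 0.08, axial), (1100.0, 0.12, plate)]
    modes = [(f, eta, {c: part[c] for c in channels if c in part})
             for f, eta, part in modes]
    return SyntheticFRFSpec(modes=modes, freq=freq)
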