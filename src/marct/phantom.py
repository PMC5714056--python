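"""Digital Gammex-467-style phantom in its three study configurations.

The phantom is a water-equivalent cylinder with two opposed insert slots
(A and B) that hold, depending on configuration, 1 cm titanium rods
(low-Z metal), 3 cm Cerrobend rods (high-Z metal), or 3 cm solid-water rods
(the metal-free scan from which the artifact-free ground truth is built by
software substitution).  An outer ring of tissue-surrogate inserts emulates
the remaining occupied slots of the physical phantom.

Three cylindrical 4 cm planning target volumes probe different artifact
regions: PTV1 between the slots (strongest streak corridor), PTV2 off-axis in
a streaked but metal-free area, PTV3 centered on slot A so it contains metal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .materials import AttenuationTable, Material, hu_from_mu, linear_attenuation
from .volumes import LabeledVolume, StructureMask, Volume


@dataclass(frozen=True)
class Slot:
    name: str
    center_cm: tuple[float, float]  # (x, y)
    diameter_cm: float
    material: str


@dataclass(frozen=True)
class GridSpec:
    n_xy: int = 256
    spacing_mm: float = 1.5
    n_slices: int = 3
    slice_thickness_mm: float = 2.5

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (self.slice_thickness_mm, self.spacing_mm, self.spacing_mm)

    @property
    def origin(self) -> tuple[float, float, float]:
        half = self.n_xy * self.spacing_mm / 2.0
        return (-self.n_slices * self.slice_thickness_mm / 2.0, -half, -half)


@dataclass(frozen=True)
class PhantomSpec:
    body_diameter_cm: float = 20.0
    body_material: str = "solid_water"
    slots: tuple[Slot, ...] = ()
    grid: GridSpec = field(default_factory=GridSpec)


# slot A/B geometry shared by all configurations (cm, world x-y)
SLOT_A_CENTER = (-5.0, 0.0)
SLOT_B_CENTER = (5.0, 0.0)

_SURROGATE_SLOTS = (
    Slot("lung", (4.95, 4.95), 2.8, "lung_ln300"),
    Slot("adipose", (-4.95, 4.95), 2.8, "adipose"),
    Slot("liver", (-4.95, -4.95), 2.8, "liver"),
    Slot("bone", (4.95, -4.95), 2.8, "cortical_bone"),
)

#: PTV presets (cm): PTV3 overlaps slot A metal, PTV1/PTV2 sit in streak regions
PTV_PRESETS = {"PTV1": (0.0, 0.0), "PTV2": (0.0, 3.5), "PTV3": SLOT_A_CENTER}
PTV_DIAMETER_CM = 4.0


def configuration_spec(configuration: int, grid: GridSpec | None = None,
                       surrogates: bool = True) -> PhantomSpec:
    """Phantom spec for study configuration 1 (Ti), 2 (Cerrobend) or 3 (solid water)."""
    inserts = {
        1: ("titanium", 1.0),
        2: ("cerrobend", 3.0),
        3: ("solid_water", 3.0),
    }
    if configuration not in inserts:
        raise ValueError("configuration must be 1, 2 or 3")
    material, diameter = inserts[configuration]
    slots = (Slot("A", SLOT_A_CENTER, diameter, material),
             Slot("B", SLOT_B_CENTER, diameter, material))
    if surrogates:
        slots = slots + _SURROGATE_SLOTS
    return PhantomSpec(slots=slots, grid=grid or GridSpec())


def _disk_mask(spec_grid: GridSpec, center_cm, diameter_cm) -> np.ndarray:
    n = spec_grid.n_xy
    half = n * spec_grid.spacing_mm / 2.0
    coords = -half + (np.arange(n) + 0.5) * spec_grid.spacing_mm  # mm
    xx, yy = np.meshgrid(coords, coords)
    cx, cy = center_cm[0] * 10.0, center_cm[1] * 10.0
    r = diameter_cm * 10.0 / 2.0
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2


def build_phantom(spec: PhantomSpec) -> LabeledVolume:
    """Voxelize a phantom spec; a voxel takes an insert label iff its center
    lies inside the insert disk (no partial-volume averaging)."""
    g = spec.grid
    for i, a in enumerate(spec.slots):
        ax, ay = a.center_cm
        if np.hypot(ax, ay) + a.diameter_cm / 2.0 > spec.body_diameter_cm / 2.0:
            raise ValueError(f"slot {a.name!r} extends outside the body")
        for b in spec.slots[i + 1:]:
            gap = np.hypot(ax - b.center_cm[0], ay - b.center_cm[1])
            if gap < (a.diameter_cm + b.diameter_cm) / 2.0:
                raise ValueError(f"slots {a.name!r} and {b.name!r} overlap")

    body = _disk_mask(g, (0.0, 0.0), spec.body_diameter_cm)
    plane = np.zeros((g.n_xy, g.n_xy), dtype=np.int16)
    plane[body] = 1
    names = ["air", spec.body_material]
    slot_labels: dict[str, int] = {}
    for slot in spec.slots:
        label = len(names)
        names.append(slot.material)
        slot_labels[slot.name] = label
        plane[_disk_mask(g, slot.center_cm, slot.diameter_cm)] = label
    labels = np.broadcast_to(plane, (g.n_slices, g.n_xy, g.n_xy)).copy()
    return LabeledVolume(labels, names, g.spacing, g.origin, slot_labels)


def body_mask(labels: LabeledVolume, exclude_labels: tuple[int, ...] = ()) -> StructureMask:
    mask = labels.labels > 0
    for lab in exclude_labels:
        mask &= labels.labels != lab
    return StructureMask("body", mask, labels.spacing, labels.origin)


METAL_MATERIALS = ("titanium", "cerrobend")


def metal_slot_mask(labels: LabeledVolume) -> StructureMask:
    """True metal voxel set (the planning structure for beam avoidance).

    Empty for the metal-free configuration (slots holding solid water).
    """
    mask = np.zeros(labels.shape, dtype=bool)
    for name in ("A", "B"):
        if name in labels.slot_labels:
            label = labels.slot_labels[name]
            if labels.material_names[label] in METAL_MATERIALS:
                mask |= labels.mask_of(label)
    return StructureMask("metal", mask, labels.spacing, labels.origin)


def make_ground_truth(solid_water_volume: Volume, labels: LabeledVolume,
                      substitutions: list[tuple[str, Material]],
                      table: AttenuationTable,
                      reference_energy_kev: float) -> Volume:
    """Software-substituted ground truth: overwrite slot voxels of the
    metal-free image with the HU of the substituted metal.

    ``labels`` must carry the slot geometry of the metal configuration; only
    the listed slots change, every other voxel is returned bit-for-bit.
    """
    out = solid_water_volume.values.copy()
    mu_water = linear_attenuation("water", reference_energy_kev, table)
    for slot_name, material in substitutions:
        if slot_name not in labels.slot_labels:
            raise KeyError(f"slot {slot_name!r} not present in labels "
                           f"(have {sorted(labels.slot_labels)})")
        mu = linear_attenuation(material, reference_energy_kev, table)
        hu = float(hu_from_mu(np.array(mu), mu_water))
        out[labels.mask_of(labels.slot_labels[slot_name])] = hu
    gt = solid_water_volume.copy_with(out)
    gt.meta["stage"] = "ground_truth"
    return gt


def define_ptv(center_cm: tuple[float, float], diameter_cm: float,
               reference: Volume, name: str = "PTV") -> StructureMask:
    """Cylindrical PTV mask (all slices) on the reference grid."""
    nz, ny, nx = reference.shape
    x = reference.origin[2] + (np.arange(nx) + 0.5) * reference.spacing[2]
    y = reference.origin[1] + (np.arange(ny) + 0.5) * reference.spacing[1]
    xx, yy = np.meshgrid(x, y)
    r_mm = diameter_cm * 10.0 / 2.0
    plane = ((xx - center_cm[0] * 10.0) ** 2
             + (yy - center_cm[1] * 10.0) ** 2) <= r_mm**2
    mask = np.broadcast_to(plane, (nz, ny, nx)).copy()
    return StructureMask(name, mask, reference.spacing,
                         reference.origin).require_nonempty()


def ptv_preset(name: str, reference: Volume) -> StructureMask:
    """One of the three preset PTVs (4 cm diameter) by name."""
    if name not in PTV_PRESETS:
        raise KeyError(f"unknown PTV preset {name!r}; have {sorted(PTV_PRESETS)}")
    return define_ptv(PTV_PRESETS[name], PTV_DIAMETER_CM, reference, name=name)
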