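"""HU-to-density calibration, photon dose engines and 5-beam fluence plans.

The planning chain mirrors a static IMRT workflow at desk scale: Hounsfield
units are converted to relative electron density through a piecewise-linear
calibration curve; five parallel beams are placed to avoid the metal along
their path to the target (where possible); per-beamlet dose-influence is
computed with a kerma-approximation primary engine (monoenergetic 2 MeV
photons, a 6 MV-like surrogate, exponentially attenuated along exact
radiological paths); beamlet weights are optimized by projected gradient to
deliver the prescription to the PTV; and the resulting fluence is recomputed
without re-optimization on the uncorrected, MAR-corrected and ground-truth
volumes.  A simple Compton Monte Carlo engine is available as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ct_sim import parallel_ray_segments
from .materials import AttenuationTable, Material, electron_density
from .volumes import StructureMask, Volume

MEC2_KEV = 510.99895


# ---------------------------------------------------------------------------
# Calibration


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone piecewise-linear HU -> relative electron density curve."""

    hu: tuple[float, ...]
    density: tuple[float, ...]

    def __post_init__(self):
        hu = np.asarray(self.hu)
        rho = np.asarray(self.density)
        if hu.size < 2:
            raise ValueError("need at least 2 calibration points")
        if np.any(np.diff(hu) <= 0):
            raise ValueError("calibration HU values must be strictly increasing")
        if np.any(rho < 0) or np.any(np.diff(rho) < 0):
            raise ValueError("calibration densities must be non-negative and "
                             "monotone non-decreasing")

    def __call__(self, hu_values):
        return np.interp(hu_values, self.hu, self.density)


def calibrate_hu_density(points) -> CalibrationCurve:
    """Build a curve from (HU, relative electron density) control points."""
    pts = sorted((float(h), float(d)) for h, d in points)
    return CalibrationCurve(tuple(h for h, _ in pts), tuple(d for _, d in pts))


def default_calibration(table: AttenuationTable, reference_energy_kev: float,
                        metal_relative_electron_density: float | None = None
                        ) -> CalibrationCurve:
    """Calibration anchored on the phantom materials at the reference energy.

    The last control point maps the saturated scanner value (3071 HU) to a
    metal electron density; clinical stoichiometric curves end near titanium
    (~3.76 relative), which is the default cap.
    """
    from .materials import HU_MAX, hu_from_mu, linear_attenuation

    mu_w = linear_attenuation("water", reference_energy_kev, table)
    # the flat segment to -950 HU maps reconstruction noise around air to
    # true air, as planning systems do, instead of rectifying it into a
    # spurious attenuating haze
    points = [(-1000.0, 0.0), (-950.0, 0.0)]
    for name in ("lung_ln300", "adipose", "water", "liver", "cortical_bone"):
        mat = table.material(name)
        hu = float(hu_from_mu(
            np.array(linear_attenuation(name, reference_energy_kev, table)),
            mu_w))
        points.append((hu, electron_density(mat)))
    if metal_relative_electron_density is None:
        metal_relative_electron_density = electron_density(
            table.material("titanium"))
    points.append((HU_MAX, metal_relative_electron_density))
    return calibrate_hu_density(points)


def hu_to_density(image: Volume, curve: CalibrationCurve) -> Volume:
    """Voxelwise curve evaluation; grid metadata preserved."""
    out = image.copy_with(curve(image.values), kind="density")
    out.meta["stage"] = "density"
    return out


# ---------------------------------------------------------------------------
# Plans, beamlets, fluence


@dataclass
class PlanSpec:
    """A 5-beam plan: angles in degrees, prescription in Gy."""

    beam_angles_deg: tuple[float, ...]
    target: StructureMask
    prescription_gy: float = 10.0
    beamlet_width_mm: float = 5.0
    beam_energy_mev: float = 2.0
    aperture_margin_mm: float = 5.0

    def __post_init__(self):
        if len(self.beam_angles_deg) != 5:
            raise ValueError("a plan has exactly 5 beam angles")
        if self.prescription_gy <= 0:
            raise ValueError("prescription must be > 0")


@dataclass
class FluenceMap:
    """Per-beam beamlet weights with their detector-axis edges (mm)."""

    beam_angles_deg: tuple[float, ...]
    beamlet_edges_mm: list[np.ndarray]   # per beam, length n_b + 1
    weights: list[np.ndarray]            # per beam, length n_b, >= 0

    def __post_init__(self):
        for w in self.weights:
            if np.any(np.asarray(w) < 0):
                raise ValueError("fluence weights must be >= 0")

    @property
    def total_beamlets(self) -> int:
        return int(sum(len(w) for w in self.weights))

    def flat(self) -> np.ndarray:
        return np.concatenate([np.asarray(w, float) for w in self.weights])

    def with_flat(self, flat: np.ndarray) -> "FluenceMap":
        parts, i = [], 0
        for w in self.weights:
            parts.append(np.asarray(flat[i:i + len(w)], float).copy())
            i += len(w)
        return FluenceMap(self.beam_angles_deg, list(self.beamlet_edges_mm),
                          parts)

    def scaled(self, factor: float) -> "FluenceMap":
        return self.with_flat(self.flat() * factor)


def _beam_axes(angle_deg: float):
    """Unit travel direction and detector axis of a beam.

    The detector axis matches the offsets convention of
    :func:`marct.ct_sim.parallel_ray_segments` at ``theta = angle - 90 deg``.
    """
    a = np.deg2rad(angle_deg)
    direction = np.array([np.cos(a), np.sin(a)])   # (x, y)
    detector = np.array([np.sin(a), -np.cos(a)])
    return direction, detector


def beamlet_layout(plan: PlanSpec) -> FluenceMap:
    """Beamlet edges covering the target's projection plus margin, per beam.

    Defined purely by target geometry so the same layout applies to every
    density volume the plan is recomputed on.
    """
    mask2d = plan.target.mask[0]
    ny, nx = mask2d.shape
    x = plan.target.origin[2] + (np.arange(nx) + 0.5) * plan.target.spacing[2]
    y = plan.target.origin[1] + (np.arange(ny) + 0.5) * plan.target.spacing[1]
    xx, yy = np.meshgrid(x, y)
    px, py = xx[mask2d], yy[mask2d]
    edges, weights = [], []
    for angle in plan.beam_angles_deg:
        _, det = _beam_axes(angle)
        s = px * det[0] + py * det[1]
        lo = s.min() - plan.aperture_margin_mm
        hi = s.max() + plan.aperture_margin_mm
        n_b = max(1, int(np.ceil((hi - lo) / plan.beamlet_width_mm)))
        e = lo + np.arange(n_b + 1) * plan.beamlet_width_mm
        edges.append(e)
        weights.append(np.zeros(n_b))
    return FluenceMap(tuple(plan.beam_angles_deg), edges, weights)


def fluence_to_text(fluence: FluenceMap, plan: PlanSpec | None = None) -> str:
    """Serialize a plan's fluence map as documented structured text."""
    lines = ["[plan]"]
    if plan is not None:
        lines += [f"prescription_gy {plan.prescription_gy}",
                  f"beam_energy_mev {plan.beam_energy_mev}",
                  f"beamlet_width_mm {plan.beamlet_width_mm}"]
    for b, angle in enumerate(fluence.beam_angles_deg):
        lines.append(f"[beam {angle}]")
        lines.append("edges_mm " + " ".join(
            f"{e:.3f}" for e in fluence.beamlet_edges_mm[b]))
        lines.append("weights " + " ".join(
            f"{w:.8e}" for w in fluence.weights[b]))
    return "\n".join(lines) + "\n"


def fluence_from_text(text: str) -> FluenceMap:
    """Parse the structured-text fluence format written by fluence_to_text."""
    angles: list[float] = []
    edges: list[np.ndarray] = []
    weights: list[np.ndarray] = []
    current: dict | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[beam "):
            angles.append(float(line.strip("[]").split()[1]))
            current = {}
            edges.append(None)
            weights.append(None)
        elif line.startswith("["):
            current = None
        elif current is not None:
            key, rest = line.split(maxsplit=1)
            if key == "edges_mm":
                edges[-1] = np.array(rest.split(), dtype=float)
            elif key == "weights":
                weights[-1] = np.array(rest.split(), dtype=float)
    if not angles or any(e is None for e in edges) \
            or any(w is None for w in weights):
        raise ValueError("malformed fluence text")
    return FluenceMap(tuple(angles), edges, weights)


# ---------------------------------------------------------------------------
# Primary (kerma) engine


def _beam_theta(angle_deg: float) -> float:
    """Angle parameter for parallel_ray_segments giving travel direction
    (cos a, sin a): rays travel along (-sin t, cos t) with t = a - 90 deg."""
    return np.deg2rad(angle_deg - 90.0)


def radiological_path(density2d: np.ndarray, spacing_mm, origin_mm,
                      angle_deg: float, offsets_mm: np.ndarray) -> np.ndarray:
    """Water-equivalent path length (cm) across the whole grid per ray."""
    theta = _beam_theta(angle_deg)
    lengths, iy, ix, inside = parallel_ray_segments(
        theta, offsets_mm, density2d.shape, spacing_mm, origin_mm)
    return (lengths * inside * density2d[iy, ix]).sum(axis=1) / 10.0


def _mu_and_kerma(plan: PlanSpec, table: AttenuationTable) -> tuple[float, float]:
    e_kev = plan.beam_energy_mev * 1000.0
    mu_eff = table.mass_attenuation("water", e_kev)  # 1/cm per unit rel. density
    muen = table.mass_energy_absorption("water", e_kev)
    return float(mu_eff), float(muen)


def _primary_beam_dose(density2d: np.ndarray, spacing_mm, origin_mm,
                       angle_deg: float, edges_mm: np.ndarray,
                       mu_eff: float, muen: float,
                       subray_step_mm: float | None = None):
    """Per-beamlet unit-fluence dose planes for one beam.

    Returns an array (n_beamlets, ny, nx): dose deposited per unit beamlet
    fluence weight, kerma approximation D = w * muen * exp(-mu * t_rad).
    """
    ny, nx = density2d.shape
    dy, dx = spacing_mm
    step = min(dx, dy) / 2.0 if subray_step_mm is None else subray_step_mm
    offsets = np.arange(edges_mm[0] + step / 2.0, edges_mm[-1], step)
    beamlet_of = np.clip(np.searchsorted(edges_mm, offsets) - 1,
                         0, len(edges_mm) - 2)
    theta = _beam_theta(angle_deg)
    lengths, iy, ix, inside = parallel_ray_segments(
        theta, offsets, (ny, nx), spacing_mm, origin_mm)
    lengths = lengths * inside
    rho = density2d[iy, ix]
    seg_rad = rho * lengths / 10.0  # cm of water-equivalent per segment
    t_mid = np.cumsum(seg_rad, axis=1) - 0.5 * seg_rad
    # area-weight: subray width * intersection length / voxel area
    contrib = muen * np.exp(-mu_eff * t_mid) * (lengths * step) / (dx * dy)
    contrib *= inside
    n_b = len(edges_mm) - 1
    dose = np.zeros((n_b, ny, nx))
    flat_idx = iy * nx + ix
    for r in range(len(offsets)):
        np.add.at(dose[beamlet_of[r]].reshape(-1), flat_idx[r], contrib[r])
    return dose


def dose_influence(density: Volume, plan: PlanSpec, table: AttenuationTable,
                   layout: FluenceMap | None = None) -> np.ndarray:
    """Influence array (total_beamlets, nz, ny, nx), unit fluence per beamlet."""
    layout = layout or beamlet_layout(plan)
    mu_eff, muen = _mu_and_kerma(plan, table)
    nz = density.shape[0]
    planes = []
    for b, angle in enumerate(layout.beam_angles_deg):
        per_slice = [_primary_beam_dose(
            density.values[k], density.spacing[1:], density.origin[1:],
            angle, layout.beamlet_edges_mm[b], mu_eff, muen)
            for k in range(nz)]
        planes.append(np.stack(per_slice, axis=1))  # (n_b, nz, ny, nx)
    return np.concatenate(planes, axis=0)


def compute_dose(density: Volume, plan: PlanSpec, fluence: FluenceMap,
                 table: AttenuationTable, mode: str = "primary",
                 seed: int = 0, histories: int = 200_000) -> Volume:
    """Dose volume in Gy for a fluence map on a density volume.

    ``primary``: deterministic kerma engine, linear in the fluence.
    ``mc``: Compton-only Monte Carlo photon transport (Klein-Nishina
    sampling, kerma deposition), deterministic given ``seed``.
    """
    if np.any(density.values < 0):
        raise ValueError("density must be >= 0")
    if mode == "primary":
        flat = fluence.flat()
        if flat.size == 0 or not np.any(flat):
            dose = np.zeros(density.shape)
        else:
            infl = dose_influence(density, plan, table, layout=fluence)
            dose = np.tensordot(flat, infl, axes=1)
    elif mode == "mc":
        dose = _mc_dose(density, plan, fluence, table, seed, histories)
    else:
        raise ValueError("mode must be 'primary' or 'mc'")
    out = density.copy_with(dose, kind="Gy")
    out.meta.update(stage="dose", engine=mode)
    return out


# ---------------------------------------------------------------------------
# Monte Carlo cross-check engine (Compton only, kerma deposition)


def _sample_kn(e_kev: np.ndarray, rng) -> np.ndarray:
    """Sample the Compton scattering angle cosine via rejection on the
    Klein-Nishina differential cross section."""
    n = e_kev.size
    mu = np.empty(n)
    todo = np.arange(n)
    alpha = e_kev / MEC2_KEV
    while todo.size:
        u = rng.uniform(-1.0, 1.0, todo.size)
        ratio = 1.0 / (1.0 + alpha[todo] * (1.0 - u))
        # dsigma ~ ratio^2 (ratio + 1/ratio - (1 - u^2)), bounded by 2
        f = ratio**2 * (ratio + 1.0 / ratio - (1.0 - u**2))
        accept = rng.uniform(0.0, 2.0, todo.size) < f
        mu[todo[accept]] = u[accept]
        todo = todo[~accept]
    return mu


def _mc_dose(density: Volume, plan: PlanSpec, fluence: FluenceMap,
             table: AttenuationTable, seed: int, histories: int) -> np.ndarray:
    """2-D Woodcock-tracked photon transport per slice, energy binned as
    kerma at interaction sites.  Dose shares the primary engine's units
    (fluence weight x muen), so narrow-beam depth doses are comparable."""
    rng = np.random.default_rng(seed)
    nz, ny, nx = density.shape
    dy, dx = density.spacing[1:]
    y0, x0 = density.origin[1:]
    e0_kev = plan.beam_energy_mev * 1000.0
    flat = fluence.flat()
    total_w = flat.sum()
    edep = np.zeros((nz, ny, nx))
    if total_w == 0 or histories == 0:
        return edep

    # beamlet sampling table
    beam_idx, s_lo, s_wid, angles = [], [], [], []
    i = 0
    for b, angle in enumerate(fluence.beam_angles_deg):
        e = fluence.beamlet_edges_mm[b]
        for j in range(len(e) - 1):
            beam_idx.append(i)
            s_lo.append(e[j])
            s_wid.append(e[j + 1] - e[j])
            angles.append(angle)
            i += 1
    s_lo, s_wid = np.array(s_lo), np.array(s_wid)
    angles = np.array(angles)
    prob = flat / total_w

    for k in range(nz):
        rho = density.values[k]
        rho_max = float(rho.max())
        if rho_max <= 0:
            continue
        n = histories
        choice = rng.choice(len(prob), size=n, p=prob)
        s = s_lo[choice] + rng.uniform(0.0, 1.0, n) * s_wid[choice]
        a = np.deg2rad(angles[choice])
        dxy = np.stack([np.cos(a), np.sin(a)], axis=1)
        det = np.stack([np.sin(a), -np.cos(a)], axis=1)
        half_diag = float(np.hypot(nx * dx, ny * dy))
        pos = s[:, None] * det - half_diag * dxy
        e_kev = np.full(n, e0_kev)
        weight = np.full(n, total_w / n)
        alive = np.ones(n, dtype=bool)

        for _ in range(60):
            if not alive.any():
                break
            idx = np.flatnonzero(alive)
            mu_w_e = np.array([table.mass_attenuation("water", e)
                               for e in np.clip(e_kev[idx], 20.0, None)])
            mu_max = mu_w_e * rho_max
            step_cm = rng.exponential(1.0 / mu_max)
            pos[idx] += dxy[idx] * step_cm[:, None] * 10.0
            ixv = np.floor((pos[idx, 0] - x0) / dx).astype(int)
            iyv = np.floor((pos[idx, 1] - y0) / dy).astype(int)
            out = (ixv < 0) | (ixv >= nx) | (iyv < 0) | (iyv >= ny)
            gone = np.hypot(pos[idx, 0], pos[idx, 1]) > 2.0 * half_diag
            alive[idx[out & gone]] = False
            inside = ~out
            ii = idx[inside]
            rho_here = rho[iyv[inside], ixv[inside]]
            real = rng.uniform(0.0, 1.0, ii.size) < rho_here / rho_max
            hit = ii[real]
            if hit.size == 0:
                continue
            cos_t = _sample_kn(e_kev[hit], rng)
            alpha = e_kev[hit] / MEC2_KEV
            e_new = e_kev[hit] / (1.0 + alpha * (1.0 - cos_t))
            transfer = weight[hit] * (e_kev[hit] - e_new) / e0_kev
            np.add.at(edep[k], (iyv[inside][real], ixv[inside][real]), transfer)
            # rotate direction by +/- theta in the slice plane
            sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, 1.0))
            sign = np.where(rng.uniform(size=hit.size) < 0.5, 1.0, -1.0)
            c, s_ = cos_t, sign * sin_t
            dx_new = c * dxy[hit, 0] - s_ * dxy[hit, 1]
            dy_new = s_ * dxy[hit, 0] + c * dxy[hit, 1]
            dxy[hit, 0], dxy[hit, 1] = dx_new, dy_new
            e_kev[hit] = e_new
            low = hit[e_new < 20.0]
            if low.size:
                lx = np.floor((pos[low, 0] - x0) / dx).astype(int)
                ly = np.floor((pos[low, 1] - y0) / dy).astype(int)
                ok = (lx >= 0) & (lx < nx) & (ly >= 0) & (ly < ny)
                np.add.at(edep[k], (ly[ok], lx[ok]),
                          weight[low][ok] * e_kev[low][ok] / e0_kev)
                alive[low] = False

    # energy per voxel -> dose: divide by relative mass, normalize so a
    # broad beam's entrance dose matches the primary engine's muen scale
    e_kev = plan.beam_energy_mev * 1000.0
    muen = table.mass_energy_absorption("water", e_kev)
    mu_w = table.mass_attenuation("water", e_kev)
    voxel_area_cm2 = (dx / 10.0) * (dy / 10.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dose = np.where(density.values > 1e-6,
                        edep / np.maximum(density.values, 1e-6), 0.0)
    # expected fraction of photon energy transferred per unit path is
    # mu_en; a Woodcock step deposits transfer per collision, so convert
    # "energy per voxel" to the primary engine's fluence*muen scale:
    dose *= muen / mu_w / voxel_area_cm2
    return dose


# ---------------------------------------------------------------------------
# Beam angle selection


def select_beam_angles(candidates_deg, metal: StructureMask,
                       target: StructureMask,
                       n_beams: int = 5) -> tuple[tuple[float, ...], str]:
    """Pick ``n_beams`` angles avoiding metal on the source side of the target.

    Returns (angles, flag); flag is ``"ok"`` when all selected beams are
    metal-free and ``"unavoidable"`` when fewer than ``n_beams`` metal-free
    candidates exist (metal inside the target), in which case the most
    spread subset of all candidates is returned.
    """
    candidates = sorted(float(c) % 360.0 for c in candidates_deg)
    if not candidates:
        raise ValueError("empty candidate list")
    if metal.mask.any():
        blocked = _blocked_angles(candidates, metal, target)
        feasible = [c for c in candidates if c not in blocked]
    else:
        feasible = list(candidates)
    if len(feasible) >= n_beams:
        return _max_spread_subset(feasible, n_beams), "ok"
    return _max_spread_subset(candidates, n_beams), "unavoidable"


def _blocked_angles(candidates, metal: StructureMask, target: StructureMask
                    ) -> set:
    """Candidates whose rays toward any target voxel cross metal upstream.

    The metal is expanded by one voxel: the partial-volume shell around an
    implant perturbs dose like the implant itself, so beams keep a safety
    margin (as clinical guidance on planning around implants prescribes).
    """
    from scipy import ndimage

    mask2d = ndimage.binary_dilation(metal.mask[0])
    tgt2d = target.mask[0]
    ny, nx = mask2d.shape
    dy, dx = metal.spacing[1:]
    y0, x0 = metal.origin[1:]
    x = x0 + (np.arange(nx) + 0.5) * dx
    y = y0 + (np.arange(ny) + 0.5) * dy
    xx, yy = np.meshgrid(x, y)
    pts = np.stack([xx[tgt2d], yy[tgt2d]], axis=1)[::2]  # thin for speed
    step = min(dx, dy) / 2.0
    n_steps = int(np.hypot(nx * dx, ny * dy) / step)
    blocked = set()
    for angle in candidates:
        a = np.deg2rad(angle)
        d = np.array([np.cos(a), np.sin(a)])
        hit = False
        for k in range(1, n_steps + 1):
            q = pts - d * (k * step)  # march upstream (toward the source)
            ix = np.floor((q[:, 0] - x0) / dx).astype(int)
            iy = np.floor((q[:, 1] - y0) / dy).astype(int)
            ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
            if not ok.any():
                break
            if mask2d[iy[ok], ix[ok]].any():
                hit = True
                break
        if hit:
            blocked.add(angle)
    return blocked


def _max_spread_subset(angles, k: int) -> tuple[float, ...]:
    """Lexicographically-smallest k-subset maximizing the minimal circular gap."""
    angles = sorted(angles)
    if len(angles) <= k:
        return tuple(angles)

    def greedy(start_idx: int, gap: float):
        chosen = [angles[start_idx]]
        for a in angles[start_idx + 1:]:
            if len(chosen) == k:
                break
            if a - chosen[-1] >= gap:
                chosen.append(a)
        if len(chosen) == k and (chosen[0] + 360.0 - chosen[-1]) >= gap:
            return chosen
        return None

    lo, hi = 0.0, 360.0 / k
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if any(greedy(i, mid) for i in range(len(angles))):
            lo = mid
        else:
            hi = mid
    for i in range(len(angles)):
        sel = greedy(i, lo)
        if sel:
            return tuple(sel)
    return tuple(angles[:k])  # unreachable fallback


# ---------------------------------------------------------------------------
# Fluence optimization and plan recomputation


def optimize_fluence(density: Volume, plan: PlanSpec,
                     table: AttenuationTable, gamma: float = 0.1,
                     iterations: int = 500,
                     body: StructureMask | None = None,
                     return_objectives: bool = False):
    """Nonnegative least-squares fluence by projected gradient.

    Minimizes ``||D w - p 1_PTV||^2 + gamma ||D_out w||^2`` s.t. ``w >= 0``
    with a fixed iteration budget and a 1/L step from a power-iteration
    Lipschitz estimate (deterministic).
    """
    plan.target.require_nonempty()
    layout = beamlet_layout(plan)
    infl = dose_influence(density, plan, table, layout=layout)
    n_b = infl.shape[0]
    infl_flat = infl.reshape(n_b, -1)
    tgt = plan.target.mask.ravel()
    if body is None:
        body_mask = density.values.ravel() > 0.2
    else:
        body_mask = body.mask.ravel()
    out_mask = body_mask & ~tgt

    # per-voxel mean weighting keeps gamma meaningful independent of how
    # many voxels each region holds
    a_tgt = infl_flat[:, tgt].T / np.sqrt(max(int(tgt.sum()), 1))
    a_out = (infl_flat[:, out_mask].T
             * np.sqrt(gamma / max(int(out_mask.sum()), 1)))
    if not np.any(a_tgt):
        raise ValueError("beams miss the target: all-zero influence matrix")
    b_tgt = np.full(a_tgt.shape[0],
                    plan.prescription_gy / np.sqrt(max(int(tgt.sum()), 1)))

    def grad(w):
        r1 = a_tgt @ w - b_tgt
        r2 = a_out @ w
        return 2.0 * (a_tgt.T @ r1 + a_out.T @ r2)

    def objective(w):
        r1 = a_tgt @ w - b_tgt
        r2 = a_out @ w
        return float(r1 @ r1 + r2 @ r2)

    # Lipschitz estimate by power iteration on A^T A
    v = np.ones(n_b)
    for _ in range(30):
        v = a_tgt.T @ (a_tgt @ v) + a_out.T @ (a_out @ v)
        nv = np.linalg.norm(v)
        if nv == 0:
            break
        v /= nv
    lip = 2.0 * max(nv, 1e-12)

    w = np.zeros(n_b)
    objectives = [objective(w)]
    for _ in range(iterations):
        w = np.maximum(0.0, w - grad(w) / lip)
        objectives.append(objective(w))

    fluence = beamlet_layout(plan).with_flat(w)
    if return_objectives:
        return fluence, objectives
    return fluence


def recompute_plans(fluence: FluenceMap, plan: PlanSpec,
                    volumes: dict[str, Volume], table: AttenuationTable,
                    mode: str = "primary", seed: int = 0,
                    histories: int = 200_000) -> dict[str, Volume]:
    """Same fluence on each density volume; never re-optimized per volume."""
    vols = list(volumes.values())
    for v in vols[1:]:
        vols[0].require_same_grid(v, "plan recomputation volumes")
    return {name: compute_dose(vol, plan, fluence, table, mode=mode,
                               seed=seed, histories=histories)
            for name, vol in volumes.items()}
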