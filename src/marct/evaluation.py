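"""Image and dose accuracy metrics: difference statistics, DVH/D_x,
relative accuracy error, rank-sum testing and study report assembly.

The central quantity is the relative accuracy error of a dose-volume metric
against the ground truth, ``Acc_x = |D_x - D_x^GT| / D_x^GT * 100`` with
``D_x`` the dose received by at least x% of the PTV volume (D100 is the
minimum target dose).  Voxelwise statistics use the population standard
deviation convention (divide by n).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .volumes import StructureMask, Volume

DVH_BIN_WIDTH_GY = 0.05


@dataclass(frozen=True)
class DiffStats:
    mean: float
    std: float   # population convention
    min: float
    max: float
    n: int


@dataclass(frozen=True)
class DVH:
    """Cumulative DVH: V(d) = fraction of structure receiving >= d."""

    edges_gy: tuple[float, ...]
    volume_fraction: tuple[float, ...]

    def __post_init__(self):
        v = np.asarray(self.volume_fraction)
        if v.size and (v[0] > 1.0 + 1e-12 or np.any(np.diff(v) > 1e-12)):
            raise ValueError("DVH volume fraction must start <= 1 and be "
                             "non-increasing")


@dataclass(frozen=True)
class DoseMetrics:
    d95: float
    d98: float
    d100: float

    def __post_init__(self):
        if not (self.d100 <= self.d98 + 1e-9 and self.d98 <= self.d95 + 1e-9):
            raise ValueError("expected D100 <= D98 <= D95")


@dataclass(frozen=True)
class RankSumResult:
    u_statistic: float
    p_value: float
    method: str  # "exact" | "normal-approximation"


def diff_stats(a: Volume, b: Volume, region: StructureMask) -> DiffStats:
    """Statistics of (a - b) restricted to a region."""
    a.require_same_grid(b, "difference volumes")
    region.require_nonempty()
    if a.shape != region.mask.shape:
        raise ValueError("region grid does not match volumes")
    d = (a.values - b.values)[region.mask]
    return DiffStats(float(d.mean()), float(d.std()), float(d.min()),
                     float(d.max()), int(d.size))


def cumulative_dvh(dose: Volume, mask: StructureMask,
                   bin_width_gy: float = DVH_BIN_WIDTH_GY) -> DVH:
    """Cumulative DVH evaluated at bin edges 0, w, 2w, ... beyond the max."""
    mask.require_nonempty()
    d = dose.values[mask.mask]
    n_bins = int(np.ceil(d.max() / bin_width_gy)) + 2 if d.max() > 0 else 2
    edges = np.arange(n_bins + 1) * bin_width_gy
    frac = (d[None, :] >= edges[:, None]).mean(axis=1)
    return DVH(tuple(edges), tuple(frac))


def dose_at_volume(dvh: DVH, x: float) -> float:
    """D_x = max dose received by at least x% of the volume, interpolated.

    D100 is the minimum structure dose (the last edge where V = 1).
    """
    if not (0.0 < x <= 100.0):
        raise ValueError("x must be in (0, 100]")
    edges = np.asarray(dvh.edges_gy)
    v = np.asarray(dvh.volume_fraction)
    level = x / 100.0
    above = v >= level - 1e-12
    if not above.any():
        return 0.0
    i = int(np.flatnonzero(above)[-1])
    if i == len(edges) - 1 or v[i] <= level + 1e-12:
        return float(edges[i])
    # interpolate the crossing of V(d) = level inside [edges[i], edges[i+1]]
    v0, v1 = v[i], v[i + 1]
    if v1 >= v0:
        return float(edges[i])
    t = (v0 - level) / (v0 - v1)
    return float(edges[i] + t * (edges[i + 1] - edges[i]))


def dose_metrics(dose: Volume, mask: StructureMask,
                 bin_width_gy: float = DVH_BIN_WIDTH_GY) -> DoseMetrics:
    dvh = cumulative_dvh(dose, mask, bin_width_gy)
    return DoseMetrics(dose_at_volume(dvh, 95.0), dose_at_volume(dvh, 98.0),
                       dose_at_volume(dvh, 100.0))


def accuracy_error(d: float, d_gt: float) -> float:
    """Relative accuracy error in percent: |d - d_gt| / d_gt * 100."""
    if d_gt <= 0:
        raise ValueError("ground-truth dose must be > 0")
    return abs(d - d_gt) / d_gt * 100.0


def rank_sum_test(a, b) -> RankSumResult:
    """Wilcoxon-Mann-Whitney two-sided test.

    Exact p by full enumeration when min(n, m) <= 8 and there are no ties;
    otherwise a normal approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    exact = min(a.size, b.size) <= 8 and not ties
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact else "asymptotic",
                             use_continuity=True)
    return RankSumResult(float(res.statistic), float(res.pvalue),
                         "exact" if exact else "normal-approximation")


def dose_difference_map(a: Volume, b: Volume,
                        region: StructureMask | None = None
                        ) -> tuple[Volume, float, float]:
    """Signed voxelwise a - b plus (min, max) over the region (whole grid
    when no region is given)."""
    a.require_same_grid(b, "dose volumes")
    diff = a.values - b.values
    sel = diff if region is None else diff[region.mask]
    out = a.copy_with(diff, kind=a.kind)
    out.meta["stage"] = "dose_difference"
    return out, float(sel.min()), float(sel.max())


# ---------------------------------------------------------------------------
# Study report


def evaluate_study(artifacts: dict, bin_width_gy: float = DVH_BIN_WIDTH_GY
                   ) -> dict:
    """Assemble the full study report from pipeline artifacts.

    ``artifacts`` maps configuration name ("low_z" / "high_z") to a dict:

    - ``images``: {"uncorrected", "corrected", "gt"} HU volumes
    - ``body``: StructureMask for image statistics (metal excluded)
    - ``plans``: {ptv_name: {"masks": StructureMask, "doses": {"uncorrected",
      "corrected", "gt"} dose volumes, "angles", "flag"}}
    - ``provenance``: free-form dict (seeds, config hash)

    Returns a JSON-serializable dict shaped like the study's results table:
    per configuration, image difference statistics (uncorrected vs GT and
    corrected vs GT), then per PTV the D_x metrics, Acc_x values, rank-sum
    tests and dose-difference extremes.
    """
    report: dict = {"configurations": {}}
    for config_name, art in artifacts.items():
        images = art["images"]
        body = art["body"]
        entry: dict = {"image": {}, "ptvs": {}}
        for label in ("uncorrected", "corrected"):
            entry["image"][f"{label}_minus_gt"] = asdict(
                diff_stats(images[label], images["gt"], body))
        for ptv_name, plan_art in art["plans"].items():
            mask = plan_art["mask"]
            doses = plan_art["doses"]
            gt_metrics = dose_metrics(doses["gt"], mask, bin_width_gy)
            ptv_entry: dict = {
                "beam_angles_deg": list(plan_art.get("angles", ())),
                "metal_flag": plan_art.get("flag", ""),
                "gt": asdict(gt_metrics),
            }
            for label in ("uncorrected", "corrected"):
                m = dose_metrics(doses[label], mask, bin_width_gy)
                ptv_entry[label] = asdict(m)
                ptv_entry[f"acc_{label}"] = {
                    "acc95": accuracy_error(m.d95, gt_metrics.d95),
                    "acc98": accuracy_error(m.d98, gt_metrics.d98),
                    "acc100": accuracy_error(m.d100, gt_metrics.d100),
                }
                _, lo, hi = dose_difference_map(doses["gt"], doses[label],
                                                body)
                ptv_entry[f"dose_diff_gt_minus_{label}"] = {
                    "min_gy": lo, "max_gy": hi,
                }
                rs = rank_sum_test(doses[label].values[mask.mask],
                                   doses["gt"].values[mask.mask])
                ptv_entry[f"rank_sum_{label}_vs_gt"] = asdict(rs)
            entry["ptvs"][ptv_name] = ptv_entry
        entry["provenance"] = art.get("provenance", {})
        report["configurations"][config_name] = entry
    return report


def report_to_json(report: dict) -> str:
    """Deterministic JSON serialization (sorted keys, fixed float format)."""
    def round_floats(obj):
        if isinstance(obj, float):
            return round(obj, 6)
        if isinstance(obj, dict):
            return {k: round_floats(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [round_floats(v) for v in obj]
        return obj

    return json.dumps(round_floats(report), sort_keys=True, indent=1)


def accuracy_table(report: dict) -> pd.DataFrame:
    """Acc_x table (percent, 2 decimals) shaped like the study's Table 1."""
    rows = []
    for config_name, entry in sorted(report["configurations"].items()):
        for ptv_name, ptv in sorted(entry["ptvs"].items()):
            for x in (95, 98, 100):
                rows.append({
                    "configuration": config_name,
                    "ptv": ptv_name,
                    "metric": f"Acc{x}",
                    "uncorrected_pct": round(
                        ptv["acc_uncorrected"][f"acc{x}"], 2),
                    "corrected_pct": round(
                        ptv["acc_corrected"][f"acc{x}"], 2),
                })
    return pd.DataFrame(rows)
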