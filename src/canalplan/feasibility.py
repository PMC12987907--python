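"""Accessibility classification, fenestration sweeps, mutual three-
trajectory optimization and per-case / cohort reporting.

An *accessible* trajectory keeps a safety margin above the threshold
(default 1 mm) to every obstacle and enters the canal at less than 80
degrees.  The *accessibility* of a canal is the percentage of accessible
entry points.  The mutual plan selects one accessible entry point per
canal, with all pairwise entry distances below 12.5 mm, minimizing
``sum_i (alpha_i - 30 deg)^2`` — the quadratic penalty drives the
superior canal toward its lowest feasible angle while keeping lateral and
posterior approaches near the ideal 30 degrees.  A case is feasible when
the three chosen entries fit within a 15 mm diameter mastoidectomy
circle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .centreline import Centreline, locate_targets
from .clearance import DrillProfile, Trajectory, entry_angle
from .errors import ConfigurationError, ParameterError
from .geometry import min_enclosing_circle_3pts

__all__ = [
    "AccessMap",
    "MutualPlan",
    "CaseReport",
    "classify_access",
    "compute_access_map",
    "fenestration_sweep",
    "optimize_mutual",
    "case_report",
    "cohort_summary",
]

MAX_ENTRY_ANGLE = 80.0  # degrees; above this, retrograde insertion risk
IDEAL_ENTRY_ANGLE = 30.0  # degrees
DEFAULT_MARGIN = 1.0  # mm
MASTOIDECTOMY_DIAMETER = 15.0  # mm
MAX_PAIRWISE = 12.5  # mm


def classify_access(
    margin: float,
    angle: float,
    margin_threshold: float = DEFAULT_MARGIN,
    max_angle: float = MAX_ENTRY_ANGLE,
):
    """A trajectory is accessible iff its safety margin exceeds the
    threshold and its canal entry angle is strictly below ``max_angle``."""
    margin = np.asarray(margin, dtype=float)
    angle = np.asarray(angle, dtype=float)
    out = (margin > margin_threshold) & (angle < max_angle)
    return bool(out) if out.ndim == 0 else out


@dataclass
class AccessMap:
    """Per-entry-point accessibility of one canal.

    One record per entry point: per-obstacle minimum clearance, safety
    margin (minimum over obstacles), canal entry angle and the accessible
    flag at ``threshold``.
    """

    canal: str
    entry_points: np.ndarray  # (n, 3)
    uv: np.ndarray  # (n, 2)
    fenestration_site: np.ndarray  # (3,)
    margins: np.ndarray  # (n,)
    angles: np.ndarray  # (n,) degrees
    per_obstacle: dict  # name -> (n,) minimum clearance
    threshold: float = DEFAULT_MARGIN
    max_angle: float = MAX_ENTRY_ANGLE

    @property
    def accessible(self) -> np.ndarray:
        return classify_access(self.margins, self.angles, self.threshold, self.max_angle)

    def accessible_at(self, threshold: float) -> np.ndarray:
        return classify_access(self.margins, self.angles, threshold, self.max_angle)

    def accessibility(self, threshold: Optional[float] = None) -> float:
        """Percentage of accessible entry points."""
        flags = self.accessible_at(self.threshold if threshold is None else threshold)
        return 100.0 * float(np.mean(flags))

    def min_accessible_angle(self, threshold: Optional[float] = None) -> float:
        flags = self.accessible_at(self.threshold if threshold is None else threshold)
        return float(self.angles[flags].min()) if np.any(flags) else float("nan")

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            "u": self.uv[:, 0],
            "v": self.uv[:, 1],
            "x": self.entry_points[:, 0],
            "y": self.entry_points[:, 1],
            "z": self.entry_points[:, 2],
            "margin_mm": self.margins,
            "entry_angle_deg": self.angles,
            "accessible": self.accessible,
        }
        for name, vals in self.per_obstacle.items():
            data[f"clearance_{name}_mm"] = vals
        return pd.DataFrame(data)


def compute_access_map(
    region,
    targets,
    fields: dict,
    obstacles,
    canal: str = "",
    profile: DrillProfile = DrillProfile(),
    threshold: float = DEFAULT_MARGIN,
    max_angle: float = MAX_ENTRY_ANGLE,
    sample_step: float = 0.125,
) -> AccessMap:
    """Evaluate one trajectory per entry point (entry -> fenestration site)
    against the named obstacle distance fields.

    ``obstacles`` lists the field names to use (the target canal itself is
    excluded by the caller: the drill must enter it).  All trajectories
    are sampled at ``sample_step`` and evaluated vectorized per field.
    """
    missing = [o for o in obstacles if o not in fields]
    if missing:
        raise ConfigurationError(f"missing distance fields for obstacles: {missing}")
    entries = region.points
    fen = np.asarray(targets.fenestration_site, dtype=float)
    n = len(entries)
    lengths = np.linalg.norm(fen[None, :] - entries, axis=1)
    dirs = (fen[None, :] - entries) / lengths[:, None]
    counts = np.maximum(2, np.ceil(lengths / sample_step).astype(int) + 1)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    total = int(offsets[-1])
    samples = np.empty((total, 3))
    tipdist = np.empty(total)
    for i in range(n):
        t = np.linspace(0.0, lengths[i], counts[i])
        sl = slice(offsets[i], offsets[i + 1])
        samples[sl] = entries[i] + t[:, None] * dirs[i]
        tipdist[sl] = lengths[i] - t
    radius = profile.radius_at(tipdist)
    per_obstacle = {}
    margins = np.full(n, np.inf)
    for name in obstacles:
        clear = fields[name].query(samples) - radius
        mins = np.minimum.reduceat(clear, offsets[:-1])
        per_obstacle[name] = mins
        margins = np.minimum(margins, mins)
    cosang = dirs @ np.asarray(targets.tangent, dtype=float)
    angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return AccessMap(
        canal=canal,
        entry_points=entries,
        uv=region.uv,
        fenestration_site=fen,
        margins=margins,
        angles=angles,
        per_obstacle=per_obstacle,
        threshold=threshold,
        max_angle=max_angle,
    )


def fenestration_sweep(
    centreline: Centreline,
    nerve_target,
    region,
    fields: dict,
    obstacles,
    offsets,
    canal: str = "",
    profile: DrillProfile = DrillProfile(),
    threshold: float = DEFAULT_MARGIN,
    max_angle: float = MAX_ENTRY_ANGLE,
    sample_step: float = 0.125,
) -> pd.DataFrame:
    """Accessibility and minimal accessible entry angle as the fenestration
    site is shifted along the canal away from the ampulla."""
    rows = []
    for off in offsets:
        targets = locate_targets(centreline, nerve_target, off)
        amap = compute_access_map(
            region,
            targets,
            fields,
            obstacles,
            canal=canal,
            profile=profile,
            threshold=threshold,
            max_angle=max_angle,
            sample_step=sample_step,
        )
        rows.append(
            {
                "offset_mm": float(off),
                "accessibility_pct": amap.accessibility(),
                "min_accessible_angle_deg": amap.min_accessible_angle(),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MutualPlan:
    """Jointly selected trajectories to the three canals."""

    trajectories: dict  # canal -> Trajectory (empty when infeasible)
    angles: dict  # canal -> entry angle (deg)
    margins: dict  # canal -> safety margin (mm)
    entry_indices: dict  # canal -> entry-point index
    objective: float  # sum (alpha_i - ideal)^2, deg^2
    max_pairwise: float  # mm
    enclosing_diameter: float  # mm, minimal enclosing circle of the entries
    feasible: bool
    constraints: dict = field(default_factory=dict)
    diagnostics: str = ""

    def verify_constraints(
        self,
        margin_threshold: float = DEFAULT_MARGIN,
        max_angle: float = MAX_ENTRY_ANGLE,
        max_pairwise: float = MAX_PAIRWISE,
    ) -> dict:
        """Re-verify the printed constraints directly from the plan."""
        return {
            "margins_above_threshold": all(
                m > margin_threshold for m in self.margins.values()
            ),
            "angles_below_max": all(a < max_angle for a in self.angles.values()),
            "pairwise_below_max": self.max_pairwise < max_pairwise,
        }


def optimize_mutual(
    maps: dict,
    max_pairwise: float = MAX_PAIRWISE,
    ideal_angle: float = IDEAL_ENTRY_ANGLE,
    threshold: Optional[float] = None,
) -> MutualPlan:
    """Exact discrete optimization over accessible entry-point triples.

    Enumerates (with cost-ordered pruning) all triples of accessible entry
    points, one per canal, whose pairwise entry distances are all below
    ``max_pairwise``, and returns the triple minimizing
    ``sum_i (alpha_i - ideal_angle)^2``.  Ties are broken by smaller
    maximum pairwise distance, then lexicographic entry indices, so the
    result is deterministic.  Equivalent to exhaustive search.
    """
    canals = list(maps)
    if len(canals) != 3:
        raise ConfigurationError("mutual optimization needs exactly three maps")
    pts0 = maps[canals[0]].entry_points
    for c in canals[1:]:
        if maps[c].entry_points.shape != pts0.shape or not np.allclose(
            maps[c].entry_points, pts0
        ):
            raise ConfigurationError("access maps do not share one entry-point set")
    acc_idx = {}
    costs = {}
    for c in canals:
        m = maps[c]
        flags = m.accessible if threshold is None else m.accessible_at(threshold)
        idx = np.flatnonzero(flags)
        cost = (m.angles[idx] - ideal_angle) ** 2
        order = np.argsort(cost, kind="stable")
        acc_idx[c] = idx[order]
        costs[c] = cost[order]
    if any(len(acc_idx[c]) == 0 for c in canals):
        empty = [c for c in canals if len(acc_idx[c]) == 0]
        return MutualPlan(
            trajectories={},
            angles={},
            margins={},
            entry_indices={},
            objective=float("inf"),
            max_pairwise=float("inf"),
            enclosing_diameter=float("inf"),
            feasible=False,
            diagnostics=f"no accessible entry points for: {empty}",
        )
    # order canals by fewest candidates first to maximize pruning
    c0, c1, c2 = sorted(canals, key=lambda c: (len(acc_idx[c]), c))
    tree1 = cKDTree(pts0[acc_idx[c1]])
    tree2 = cKDTree(pts0[acc_idx[c2]])
    min_c1 = costs[c1][0]
    min_c2 = costs[c2][0]
    best_key = None  # (objective, max pairwise, canal-sorted indices)
    best_choice = None
    for a_pos, ia in enumerate(acc_idx[c0]):
        ca = costs[c0][a_pos]
        if best_key is not None and ca + min_c1 + min_c2 > best_key[0]:
            break
        pa = pts0[ia]
        nb1 = np.asarray(tree1.query_ball_point(pa, max_pairwise), dtype=int)
        nb2 = np.asarray(tree2.query_ball_point(pa, max_pairwise), dtype=int)
        if nb1.size == 0 or nb2.size == 0:
            continue
        d1a = np.linalg.norm(pts0[acc_idx[c1][nb1]] - pa, axis=1)
        nb1 = nb1[d1a < max_pairwise]  # the constraint is strict
        d2a = np.linalg.norm(pts0[acc_idx[c2][nb2]] - pa, axis=1)
        keep2 = d2a < max_pairwise
        nb2 = nb2[keep2]
        d2a = d2a[keep2]
        if nb1.size == 0 or nb2.size == 0:
            continue
        nb1 = nb1[np.argsort(costs[c1][nb1], kind="stable")]
        p2n = pts0[acc_idx[c2][nb2]]
        c2n = costs[c2][nb2]
        for b_pos in nb1:
            cb = costs[c1][b_pos]
            if best_key is not None and ca + cb + min_c2 > best_key[0]:
                break
            ib = acc_idx[c1][b_pos]
            pb = pts0[ib]
            dab = float(np.linalg.norm(pa - pb))
            d2b = np.linalg.norm(p2n - pb, axis=1)
            feas = np.flatnonzero(d2b < max_pairwise)
            if feas.size == 0:
                continue
            cmin = c2n[feas].min()
            obj = ca + cb + cmin
            if best_key is not None and obj > best_key[0]:
                continue
            # all cost-minimal third points participate in tie-breaking
            for pos in feas[c2n[feas] == cmin]:
                ic = acc_idx[c2][nb2[pos]]
                pair_max = max(dab, float(d2a[pos]), float(d2b[pos]))
                by_canal = dict(zip((c0, c1, c2), (int(ia), int(ib), int(ic))))
                tie = tuple(by_canal[c] for c in sorted(canals))
                key = (obj, pair_max, tie)
                if best_key is None or key < best_key:
                    best_key = key
                    best_choice = by_canal
    if best_choice is None:
        return MutualPlan(
            trajectories={},
            angles={},
            margins={},
            entry_indices={},
            objective=float("inf"),
            max_pairwise=float("inf"),
            enclosing_diameter=float("inf"),
            feasible=False,
            diagnostics="no accessible triple satisfies the pairwise constraint",
        )
    chosen = best_choice
    pair_max = best_key[1]
    entries = {c: pts0[chosen[c]] for c in canals}
    angles = {c: float(maps[c].angles[chosen[c]]) for c in canals}
    margins = {c: float(maps[c].margins[chosen[c]]) for c in canals}
    trajectories = {
        c: Trajectory(entry=entries[c], fenestration=maps[c].fenestration_site)
        for c in canals
    }
    diam = min_enclosing_circle_3pts(*(entries[c] for c in canals))
    plan = MutualPlan(
        trajectories=trajectories,
        angles=angles,
        margins=margins,
        entry_indices=chosen,
        objective=float(best_key[0]),
        max_pairwise=float(pair_max),
        enclosing_diameter=float(diam),
        feasible=True,
    )
    plan.constraints = plan.verify_constraints(
        margin_threshold=maps[canals[0]].threshold if threshold is None else threshold,
        max_pairwise=max_pairwise,
    )
    return plan


@dataclass
class CaseReport:
    """Per-case metrics in the style of the cohort summary tables."""

    case_id: str
    per_canal: dict  # canal -> dict of metrics
    mutual: dict  # canal -> dict of mutual-plan metrics (empty if infeasible)
    feasible: bool
    enclosing_diameter: float
    mutual_obstacle_clearances: dict = field(default_factory=dict)

    def to_rows(self) -> pd.DataFrame:
        rows = []
        for canal, metrics in self.per_canal.items():
            for k, v in metrics.items():
                rows.append(
                    {"case": self.case_id, "canal": canal, "metric": k, "value": v}
                )
        for canal, metrics in self.mutual.items():
            for k, v in metrics.items():
                rows.append(
                    {
                        "case": self.case_id,
                        "canal": canal,
                        "metric": f"mutual_{k}",
                        "value": v,
                    }
                )
        for canal, clearances in self.mutual_obstacle_clearances.items():
            for obstacle, v in clearances.items():
                rows.append(
                    {
                        "case": self.case_id,
                        "canal": canal,
                        "metric": f"mutual_clearance_{obstacle}",
                        "value": v,
                    }
                )
        rows.append(
            {
                "case": self.case_id,
                "canal": "all",
                "metric": "feasible",
                "value": float(self.feasible),
            }
        )
        return pd.DataFrame(rows)


def case_report(
    case_id: str,
    maps_by_threshold: dict,
    plan: MutualPlan,
    ci_trajectory=None,
    thresholds=(0.5, 1.0, 2.0),
    mastoidectomy_diameter: float = MASTOIDECTOMY_DIAMETER,
) -> CaseReport:
    """Assemble the per-case summary.

    ``maps_by_threshold`` maps each margin threshold to a dict
    canal -> AccessMap (the same maps may be shared across thresholds
    since the flag is re-derived).  CI-referenced metrics are omitted
    (None) when no CI trajectory is given.  The case is feasible when the
    mutual plan exists and its three entries fit in the mastoidectomy
    circle.
    """
    base_thr = thresholds[1] if len(thresholds) > 1 else thresholds[0]
    maps = maps_by_threshold[base_thr]
    canals = list(maps)
    ci_entry = ci_dir = None
    if ci_trajectory is not None:
        ci_entry = np.asarray(ci_trajectory[0], dtype=float)
        ci_dir = np.asarray(ci_trajectory[1], dtype=float)
        ci_dir = ci_dir / np.linalg.norm(ci_dir)
    per_canal = {}
    for c in canals:
        m = maps[c]
        metrics = {}
        for thr in thresholds:
            metrics[f"accessibility_{thr}mm_pct"] = m.accessibility(thr)
        flags = m.accessible_at(base_thr)
        metrics["min_accessible_angle_deg"] = m.min_accessible_angle(base_thr)
        if ci_entry is not None and np.any(flags):
            dirs = m.fenestration_site[None, :] - m.entry_points[flags]
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            offs = np.degrees(np.arccos(np.clip(dirs @ ci_dir, -1.0, 1.0)))
            metrics["min_accessible_ci_angle_deg"] = float(offs.min())
            dists = np.linalg.norm(m.entry_points[flags] - ci_entry, axis=1)
            metrics["min_accessible_ci_entry_distance_mm"] = float(dists.min())
        else:
            metrics["min_accessible_ci_angle_deg"] = None
            metrics["min_accessible_ci_entry_distance_mm"] = None
        per_canal[c] = metrics
    mutual = {}
    if plan.feasible:
        for c in canals:
            traj = plan.trajectories[c]
            entry = {
                "entry_angle_deg": plan.angles[c],
                "margin_mm": plan.margins[c],
                "drill_length_mm": traj.length,
            }
            if ci_entry is not None:
                entry["ci_angle_deg"] = float(
                    np.degrees(
                        np.arccos(np.clip(np.dot(traj.direction, ci_dir), -1, 1))
                    )
                )
                entry["ci_entry_distance_mm"] = float(
                    np.linalg.norm(traj.entry - ci_entry)
                )
            else:
                entry["ci_angle_deg"] = None
                entry["ci_entry_distance_mm"] = None
            mutual[c] = entry
    feasible = plan.feasible and plan.enclosing_diameter <= mastoidectomy_diameter
    return CaseReport(
        case_id=case_id,
        per_canal=per_canal,
        mutual=mutual,
        feasible=feasible,
        enclosing_diameter=plan.enclosing_diameter,
    )


def cohort_summary(reports) -> pd.DataFrame:
    """Median, interquartile range and range per metric across cases."""
    reports = list(reports)
    if len(reports) == 0:
        raise ParameterError("cohort summary needs at least one report")
    df = pd.concat([r.to_rows() for r in reports], ignore_index=True)
    df = df.dropna(subset=["value"])
    df["value"] = df["value"].astype(float)
    g = df.groupby(["canal", "metric"])["value"]
    out = g.agg(
        median="median",
        q1=lambda x: x.quantile(0.25),
        q3=lambda x: x.quantile(0.75),
        min="min",
        max="max",
        n="count",
    ).reset_index()
    return out.sort_values(["canal", "metric"]).reset_index(drop=True)
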