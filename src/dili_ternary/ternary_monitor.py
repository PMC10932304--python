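"""Ternary phenotype coordinates, residual-DILI flags, transitions, plots.

The three one-vs-rest predicted values ``(y_C, y_H, y_R)`` are mapped onto
the 2-simplex by clipping negatives to zero and renormalising to unit sum
(softmax available for comparison). The resulting coordinate reads directly
as percentages: (0.30, 0.30, 0.40) is 30% cholestatic, 30% hepatocellular,
40% recovered. A triple with no positive component is placed at the
barycentre and flagged degenerate.

Residual DILI: a sample whose *clinical* call is recovered but whose
metabolome still carries a cholestatic or hepatocellular component beyond
``minor`` (default 0.20) or ``major`` (default 0.40) is flagged, with the
driving component recorded.

Transitions between consecutive timepoints are labelled toward-recovery
(recovered coordinate rises by >= delta), H->C or C->H shifts (opposite
moves of the two injury coordinates by >= delta), or stable.

Plots use the simplex -> plane affine map with vertices C = (0, 0),
H = (1, 0), R = (1/2, sqrt(3)/2) and the conventional colour scheme (green
cholestatic, orange hepatocellular, white mixed, blue recovered), with the
timepoint number printed inside each marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

LABEL_COLORS = {"cholestatic": "#2ca02c", "hepatocellular": "#ff7f0e",
                "mixed": "#ffffff", "recovered": "#1f77b4",
                "unclassifiable": "#999999"}

# simplex corners in the plane: C, H, R
_CORNERS = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3.0) / 2.0]])


@dataclass(frozen=True)
class TernaryCoordinate:
    """(c, h, r) nonnegative proportions summing to one."""

    c: float
    h: float
    r: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        total = self.c + self.h + self.r
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"coordinates sum to {total}, not 1")
        if min(self.c, self.h, self.r) < -1e-12:
            raise ValueError("negative ternary coordinate")

    @property
    def percentages(self) -> tuple[float, float, float]:
        return (100.0 * self.c, 100.0 * self.h, 100.0 * self.r)

    def as_array(self) -> np.ndarray:
        return np.array([self.c, self.h, self.r])

    def to_xy(self) -> tuple[float, float]:
        x, y = self.as_array() @ _CORNERS
        return float(x), float(y)


def to_ternary(raw_triple, method: str = "clip") -> TernaryCoordinate:
    """Map a raw (y_C, y_H, y_R) prediction triple onto the simplex.

    ``clip`` (default): negatives to zero, then divide by the sum; an
    all-nonpositive triple returns the barycentre flagged degenerate.
    ``softmax``: exp-normalise (never degenerate), for comparison.
    """
    v = np.asarray(raw_triple, dtype=float)
    if v.shape != (3,) or not np.all(np.isfinite(v)):
        raise ValueError("raw triple must be 3 finite numbers")
    if method == "softmax":
        e = np.exp(v - v.max())
        w = e / e.sum()
        return TernaryCoordinate(*w)
    if method != "clip":
        raise ValueError(f"unknown method {method!r}")
    w = np.clip(v, 0.0, None)
    s = w.sum()
    if s == 0.0:
        return TernaryCoordinate(1 / 3, 1 / 3, 1 / 3, degenerate=True)
    w = w / s
    return TernaryCoordinate(*w)


def ternary_frame(raw: pd.DataFrame, method: str = "clip") -> pd.DataFrame:
    """Apply :func:`to_ternary` to a frame with columns y_c, y_h, y_r."""
    coords = [to_ternary(t, method) for t in
              raw[["y_c", "y_h", "y_r"]].to_numpy()]
    return pd.DataFrame(
        {"c": [k.c for k in coords], "h": [k.h for k in coords],
         "r": [k.r for k in coords],
         "degenerate": [k.degenerate for k in coords]}, index=raw.index)


# ---------------------------------------------------------------------------
# residual-DILI flags
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidualFlag:
    sample_id: str
    level: str                # none / minor / major
    driver: str | None        # C / H / both / None


def residual_dili_flag(coord: TernaryCoordinate, clinical_label: str,
                       sample_id: str = "", minor: float = 0.20,
                       major: float = 0.40) -> ResidualFlag:
    """Flag lingering injury signal in a clinically recovered sample."""
    if clinical_label != "recovered":
        return ResidualFlag(sample_id, "none", None)
    top = max(coord.c, coord.h)
    if top >= major:
        level = "major"
    elif top >= minor:
        level = "minor"
    else:
        return ResidualFlag(sample_id, "none", None)
    cutoff = minor
    c_hit, h_hit = coord.c >= cutoff, coord.h >= cutoff
    driver = "both" if (c_hit and h_hit) else ("C" if coord.c >= coord.h else "H")
    return ResidualFlag(sample_id, level, driver)


# ---------------------------------------------------------------------------
# trajectories and transitions
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Ordered per-patient sequence of ternary coordinates."""

    patient_id: str
    timepoints: list[int]
    coords: list[TernaryCoordinate]
    clinical_labels: list[str]
    annotations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.timepoints:
            raise ValueError("trajectory needs at least one point")
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")


def classify_transition(trajectory: Trajectory, delta: float = 0.15,
                        ) -> tuple[list[str], str]:
    """Label consecutive moves and summarise the dominant pattern.

    Per pair: ``toward-recovery`` if the recovered coordinate rises by at
    least delta; ``H->C shift`` if c rises and h falls by at least delta;
    ``C->H shift`` for the reverse; else ``stable``. The whole-trajectory
    summary is the most frequent non-stable move (earliest on ties), or
    ``stable``. A single-point trajectory yields no annotations and the
    summary ``single-point``.
    """
    if len(trajectory.coords) < 2:
        trajectory.annotations = []
        return [], "single-point"
    moves = []
    for a, b in zip(trajectory.coords, trajectory.coords[1:]):
        dc, dh, dr = b.c - a.c, b.h - a.h, b.r - a.r
        if dr >= delta:
            moves.append("toward-recovery")
        elif dc >= delta and dh <= -delta:
            moves.append("H->C shift")
        elif dh >= delta and dc <= -delta:
            moves.append("C->H shift")
        else:
            moves.append("stable")
    non_stable = [m for m in moves if m != "stable"]
    if non_stable:
        counts = pd.Series(non_stable).value_counts()
        summary = counts.index[0]
    else:
        summary = "stable"
    trajectory.annotations = moves
    return moves, str(summary)


def build_trajectories(coords: pd.DataFrame, clinical: pd.DataFrame,
                       ) -> list[Trajectory]:
    """Group per-sample coordinates into per-patient trajectories.

    ``coords`` has columns c, h, r indexed by sample_id; ``clinical`` must
    provide patient_id, timepoint_index and label for the same samples.
    """
    merged = coords.join(clinical[["patient_id", "timepoint_index", "label"]])
    out = []
    for pid, grp in merged.groupby("patient_id", sort=True):
        grp = grp.sort_values("timepoint_index")
        out.append(Trajectory(
            patient_id=str(pid),
            timepoints=[int(t) for t in grp["timepoint_index"]],
            coords=[TernaryCoordinate(row.c, row.h, row.r)
                    for row in grp.itertuples()],
            clinical_labels=list(grp["label"])))
    return out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def simplex_to_xy(coords: pd.DataFrame) -> np.ndarray:
    """Affine barycentric -> Cartesian map for columns c, h, r."""
    return coords[["c", "h", "r"]].to_numpy() @ _CORNERS


def render_ternary(coords: pd.DataFrame, clinical_labels: pd.Series,
                   out_path: str | Path, timepoints: pd.Series | None = None,
                   title: str = "") -> pd.DataFrame:
    """Write an SVG ternary plot plus its companion TSV; returns the table.

    Markers are coloured by clinical call (green cholestatic, orange
    hepatocellular, white mixed, blue recovered); with ``timepoints`` given,
    the collection order is printed inside each marker.
    """
    if coords.empty:
        raise ValueError("no coordinates to render")
    out_path = Path(out_path)
    xy = simplex_to_xy(coords)
    fig, ax = plt.subplots(figsize=(5, 4.6))
    tri = np.vstack([_CORNERS, _CORNERS[0]])
    ax.plot(tri[:, 0], tri[:, 1], color="black", lw=1)
    for frac in (0.2, 0.4, 0.6, 0.8):  # gridlines parallel to each edge
        for i in range(3):
            a, b, c = _CORNERS[i], _CORNERS[(i + 1) % 3], _CORNERS[(i + 2) % 3]
            p1 = a + frac * (c - a)
            p2 = b + frac * (c - b)
            ax.plot([p1[0], p2[0]], [p1[1], p2[1]], color="0.85", lw=0.5,
                    zorder=0)
    for (x, y), sid in zip(xy, coords.index):
        lab = clinical_labels.get(sid, "unclassifiable")
        ax.scatter([x], [y], s=180, facecolor=LABEL_COLORS.get(lab, "0.6"),
                   edgecolor="black", linewidth=0.8, zorder=3)
        if timepoints is not None and sid in timepoints.index:
            ax.text(x, y, str(int(timepoints.loc[sid])), ha="center",
                    va="center", fontsize=7, zorder=4)
    ax.text(-0.04, -0.04, "C", ha="right", va="top", fontsize=11)
    ax.text(1.04, -0.04, "H", ha="left", va="top", fontsize=11)
    ax.text(0.5, np.sqrt(3) / 2 + 0.04, "R", ha="center", va="bottom",
            fontsize=11)
    ax.set_xlim(-0.1, 1.1)
    ax.set_ylim(-0.1, 1.0)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    fig.savefig(out_path, format=out_path.suffix.lstrip(".") or "svg",
                bbox_inches="tight")
    plt.close(fig)

    table = coords[["c", "h", "r"]].copy()
    table["clinical_label"] = clinical_labels.reindex(coords.index)
    if timepoints is not None:
        table["timepoint_index"] = timepoints.reindex(coords.index)
    tsv_path = out_path.with_suffix(".tsv")
    table.round(6).to_csv(tsv_path, sep="\t")
    return table
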