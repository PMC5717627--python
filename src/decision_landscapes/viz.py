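"""3D rendering of fitted decision landscapes.

Surfaces are tabulated on a regular grid and drawn with matplotlib
(static PNG/PDF).  An interactive variant writes a self-contained HTML
document embedding the surface data as JSON together with a small inline
canvas renderer, so landscapes can be rotated in a browser without any
external dependency.  Trajectory overlays are lifted onto the surface
(z = V(x, y) along the path).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .landscape import LandscapeParams, potential
from .trajectories import Trajectory

__all__ = ["SurfaceGrid", "evaluate_surface", "plot_landscape", "export_grid"]

DEFAULT_X_RANGE = (-1.2, 1.2)
DEFAULT_Y_RANGE = (-0.2, 1.2)
DEFAULT_RESOLUTION = 101


@dataclass
class SurfaceGrid:
    """Tabulation of V on a regular grid; ``values[r, c] = V(xs[c], ys[r])``."""

    xs: np.ndarray
    ys: np.ndarray
    values: np.ndarray
    label: str = ""


def evaluate_surface(
    params: LandscapeParams,
    x_range: tuple[float, float] = DEFAULT_X_RANGE,
    y_range: tuple[float, float] = DEFAULT_Y_RANGE,
    resolution: int = DEFAULT_RESOLUTION,
    label: str = "",
) -> SurfaceGrid:
    """Evaluate the potential on a ``resolution x resolution`` regular grid."""
    if resolution < 2:
        raise ParameterError("resolution must be >= 2")
    if not (x_range[1] > x_range[0] and y_range[1] > y_range[0]):
        raise ParameterError("ranges must be nonempty (max > min)")
    xs = np.linspace(*x_range, resolution)
    ys = np.linspace(*y_range, resolution)
    gx, gy = np.meshgrid(xs, ys)
    values = potential(params, gx, gy)
    if not np.all(np.isfinite(values)):
        raise ParameterError("potential is non-finite on the requested grid")
    return SurfaceGrid(xs=xs, ys=ys, values=values, label=label)


def export_grid(grid: SurfaceGrid, path) -> None:
    """Write the value matrix as delimited text (rows = y, columns = x)."""
    header = "\t".join(f"{x:.6g}" for x in grid.xs)
    np.savetxt(path, grid.values, delimiter="\t", header=header, comments="# x:\t")


def _lift(grid_params: LandscapeParams, traj: Trajectory) -> np.ndarray:
    return np.asarray(potential(grid_params, traj.xs, traj.ys))


def plot_landscape(
    grids: SurfaceGrid | list[SurfaceGrid],
    out_path,
    trajectories: list[Trajectory] | None = None,
    params_for_lift: LandscapeParams | None = None,
    elev: float = 35.0,
    azim: float = -60.0,
    cmaps: tuple[str, ...] = ("viridis", "Greys"),
    alpha: float = 0.85,
) -> None:
    """Render one or more surfaces (comparison overlay) to a file.

    A ``.html`` suffix selects the self-contained interactive export;
    anything else is written as a static image via matplotlib.  Overlaid
    trajectories are drawn at z = V(x, y) along the path, using
    ``params_for_lift`` (required when trajectories are given).
    """
    if isinstance(grids, SurfaceGrid):
        grids = [grids]
    if not grids:
        raise ParameterError("at least one surface required")
    if trajectories and params_for_lift is None:
        raise ParameterError("params_for_lift is required to overlay trajectories")
    out_path = str(out_path)
    if out_path.endswith(".html"):
        _write_html(grids, out_path, trajectories, params_for_lift)
        return
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(111, projection="3d")
    for k, grid in enumerate(grids):
        gx, gy = np.meshgrid(grid.xs, grid.ys)
        ax.plot_surface(
            gx,
            gy,
            grid.values,
            cmap=cmaps[k % len(cmaps)],
            alpha=alpha if k == 0 else 0.45,
            linewidth=0,
            antialiased=True,
        )
    if trajectories:
        for traj in trajectories:
            zs = _lift(params_for_lift, traj)
            ax.plot(traj.xs, traj.ys, zs, color="crimson", lw=1.8)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.set_zlabel("V(x, y)")
    ax.view_init(elev=elev, azim=azim)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


_HTML_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Decision landscape</title></head>
<body style="margin:0;background:#111;color:#ddd;font-family:sans-serif">
<div style="padding:4px 8px">drag to rotate &mdash; decision landscape</div>
<canvas id="c" width="900" height="700"></canvas>
<script type="application/json" id="scene">__SCENE__</script>
<script>
const scene = JSON.parse(document.getElementById('scene').textContent);
const cv = document.getElementById('c'), ctx = cv.getContext('2d');
let az = -1.0, el = 0.6;
function draw() {
  ctx.clearRect(0, 0, cv.width, cv.height);
  const ca = Math.cos(az), sa = Math.sin(az), ce = Math.cos(el), se = Math.sin(el);
  const proj = (x, y, z) => {
    const u = x * ca - y * sa, v = x * sa + y * ca;
    return [cv.width / 2 + 260 * u, cv.height / 2 - 260 * (z * ce + v * se) + 100];
  };
  for (const s of scene.surfaces) {
    ctx.strokeStyle = s.color; ctx.lineWidth = 0.5; ctx.globalAlpha = 0.75;
    const nx = s.xs.length, ny = s.ys.length, step = Math.max(1, Math.floor(nx / 40));
    for (let r = 0; r < ny; r += step) {
      ctx.beginPath();
      for (let c = 0; c < nx; c++) {
        const p = proj(s.xs[c], s.ys[r], s.values[r][c]);
        c ? ctx.lineTo(p[0], p[1]) : ctx.moveTo(p[0], p[1]);
      }
      ctx.stroke();
    }
    for (let c = 0; c < nx; c += step) {
      ctx.beginPath();
      for (let r = 0; r < ny; r++) {
        const p = proj(s.xs[c], s.ys[r], s.values[r][c]);
        r ? ctx.lineTo(p[0], p[1]) : ctx.moveTo(p[0], p[1]);
      }
      ctx.stroke();
    }
  }
  ctx.globalAlpha = 1; ctx.lineWidth = 1.6; ctx.strokeStyle = '#e33';
  for (const t of scene.trajectories || []) {
    ctx.beginPath();
    for (let i = 0; i < t.xs.length; i++) {
      const p = proj(t.xs[i], t.ys[i], t.zs[i]);
      i ? ctx.lineTo(p[0], p[1]) : ctx.moveTo(p[0], p[1]);
    }
    ctx.stroke();
  }
}
let drag = null;
cv.onmousedown = e => drag = [e.clientX, e.clientY];
window.onmouseup = () => drag = null;
window.onmousemove = e => {
  if (!drag) return;
  az += (e.clientX - drag[0]) * 0.01; el += (e.clientY - drag[1]) * 0.01;
  drag = [e.clientX, e.clientY]; draw();
};
draw();
</script></body></html>
"""

_SURFACE_COLORS = ("#7fd4ff", "#999999", "#c79fff", "#8fe58f")


def _write_html(grids, out_path, trajectories, params_for_lift) -> None:
    scene = {
        "surfaces": [
            {
                "name": g.label or f"surface-{k}",
                "color": _SURFACE_COLORS[k % len(_SURFACE_COLORS)],
                "xs": [float(v) for v in g.xs],
                "ys": [float(v) for v in g.ys],
                "values": [[float(v) for v in row] for row in g.values],
            }
            for k, g in enumerate(grids)
        ],
        "trajectories": [
            {
                "trial": traj.trial_id,
                "xs": [float(v) for v in traj.xs],
                "ys": [float(v) for v in traj.ys],
                "zs": [float(v) for v in _lift(params_for_lift, traj)],
            }
            for traj in (trajectories or [])
        ],
    }
    with open(out_path, "w") as fh:
        fh.write(_HTML_TEMPLATE.replace("__SCENE__", json.dumps(scene)))


def read_html_scene(path) -> dict:
    """Parse the JSON scene back out of an interactive export (round-trip
    helper for validating what a rendered document contains)."""
    with open(path) as fh:
        text = fh.read()
    start = text.index('id="scene">') + len('id="scene">')
    end = text.index("</script>", start)
    return json.loads(text[start:end])
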