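"""Serialization: HDF5 k-space bundles, NIfTI images, CSV orders and traces.

The HDF5 bundle stores the samples, the profile-order table, the coil maps,
the noise level and the generating configuration (as a JSON attribute), so
an acquisition round-trips bit-exactly.
"""

from __future__ import annotations

import json

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .motion import MotionTrace
from .operators import CoilMaps, KSpaceBundle
from .orders import PEGrid, Tiling, ViewOrder


# -- view orders ------------------------------------------------------------


def order_to_frame(order: ViewOrder) -> pd.DataFrame:
    return pd.DataFrame({
        "t": np.arange(order.n_profiles),
        "k2": order.profiles[:, 0],
        "k3": order.profiles[:, 1],
        "segment": order.segment_of,
        "tile": order.tile_ids(),
    })


def save_order_csv(order: ViewOrder, path) -> None:
    order_to_frame(order).to_csv(path, index=False)


def load_order_csv(path, grid: PEGrid, traversal: str = "random_checkered",
                   tile_order: str = "zigzag", seed: int = 0,
                   tiling: Tiling | None = None) -> ViewOrder:
    df = pd.read_csv(path).sort_values("t")
    profiles = df[["k2", "k3"]].to_numpy(dtype=np.int64)
    return ViewOrder(grid, profiles, df["segment"].to_numpy(dtype=np.int64),
                     traversal, tile_order, seed, tiling)


# -- motion traces ----------------------------------------------------------


def trace_to_frame(trace: MotionTrace, weights=None) -> pd.DataFrame:
    cols = (("tx", "ty", "rot") if trace.ndim == 2 else
            ("tx", "ty", "tz", "rz", "ry", "rx"))
    df = pd.DataFrame(trace.params, columns=list(cols))
    df.insert(0, "segment", np.arange(trace.n_states))
    df["effective"] = trace.effective_map
    df["weight"] = 1.0 if weights is None else np.asarray(weights)
    return df


def save_trace_csv(trace: MotionTrace, path, weights=None) -> None:
    trace_to_frame(trace, weights).to_csv(path, index=False)


def load_trace_csv(path) -> MotionTrace:
    df = pd.read_csv(path).sort_values("segment")
    cols = [c for c in ("tx", "ty", "tz", "rz", "ry", "rx", "rot")
            if c in df.columns]
    params = df[cols].to_numpy(dtype=float)
    ndim = 2 if params.shape[1] == 3 else 3
    eff = df["effective"].to_numpy() if "effective" in df else None
    return MotionTrace(params, ndim, effective_map=eff)


def save_trace_json(trace: MotionTrace, path, weights=None) -> None:
    with open(path, "w") as f:
        json.dump(trace_to_frame(trace, weights).to_dict(orient="list"), f)


def save_masks_h5(order: ViewOrder, path) -> None:
    """Export per-segment sampling masks as an HDF5 dataset (M, K2, K3)."""
    from .orders import segment_masks
    with h5py.File(path, "w") as f:
        f.create_dataset("masks", data=segment_masks(order),
                         compression="gzip")
        f.attrs["traversal"] = order.traversal
        f.attrs["n_segments"] = order.n_segments


def plot_trace(trace: MotionTrace, path, weights=None, spacing_s: float = 1.0):
    """Render a motion-trace figure: translations and rotations over time,
    segment opacity given by the robustness weight."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    w = np.ones(trace.n_states) if weights is None else np.asarray(weights)
    t = np.arange(trace.n_states) * spacing_s
    d = trace.ndim
    labels = (["t2 (mm)", "t3 (mm)", "rot (deg)"] if d == 2 else
              ["t1", "t2", "t3", "rz", "ry", "rx"])
    fig, axes = plt.subplots(2, 1, figsize=(7, 5), sharex=True)
    for j in range(d):
        axes[0].scatter(t, trace.params[:, j], s=12, alpha=np.clip(w, 0.1, 1),
                        label=labels[j])
    for j in range(d, trace.params.shape[1]):
        axes[1].scatter(t, trace.params[:, j], s=12, alpha=np.clip(w, 0.1, 1),
                        label=labels[j])
    axes[0].set_ylabel("translation (mm)")
    axes[1].set_ylabel("rotation (deg)")
    axes[1].set_xlabel("segment time")
    for ax in axes:
        ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# -- HDF5 bundles -----------------------------------------------------------


def save_bundle(path, bundle: KSpaceBundle, maps: CoilMaps | None = None,
                extras: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("y", data=bundle.y)
        order = bundle.order
        f.create_dataset("order/profiles", data=order.profiles)
        f.create_dataset("order/segment_of", data=order.segment_of)
        g = f["order"]
        g.attrs["traversal"] = order.traversal
        g.attrs["tile_order"] = order.tile_order
        g.attrs["seed"] = order.seed
        g.attrs["grid"] = json.dumps({
            "k2": order.grid.k2, "k3": order.grid.k3, "r2": order.grid.r2,
            "r3": order.grid.r3, "elliptical": order.grid.elliptical})
        if order.tiling is not None:
            g.attrs["tiling"] = json.dumps({
                "u2": order.tiling.u2, "u3": order.tiling.u3,
                "k2s": order.tiling.k2s, "k3s": order.tiling.k3s})
        f.attrs["spacing"] = bundle.spacing
        f.attrs["noise_std"] = bundle.noise_std
        f.attrs["config"] = json.dumps(bundle.attrs.get("config", ""))
        if maps is not None:
            f.create_dataset("maps", data=maps.maps)
        for k, v in (extras or {}).items():
            f.create_dataset(k, data=v)


def load_bundle(path):
    """Returns ``(bundle, maps_or_None)``."""
    with h5py.File(path, "r") as f:
        y = f["y"][()]
        g = f["order"]
        grid = PEGrid(**json.loads(g.attrs["grid"]))
        tiling = None
        if "tiling" in g.attrs:
            tiling = Tiling(**json.loads(g.attrs["tiling"]))
        order = ViewOrder(grid, g["profiles"][()], g["segment_of"][()],
                          str(g.attrs["traversal"]), str(g.attrs["tile_order"]),
                          int(g.attrs["seed"]), tiling)
        attrs = {}
        cfg = json.loads(f.attrs["config"])
        if cfg:
            attrs["config"] = cfg
        bundle = KSpaceBundle(y, order, float(f.attrs["spacing"]),
                              float(f.attrs["noise_std"]), attrs)
        maps = CoilMaps(f["maps"][()]) if "maps" in f else None
    return bundle, maps


# -- NIfTI images -----------------------------------------------------------


def save_nifti(path, img: np.ndarray, spacing: float = 1.0) -> None:
    """Save a (complex) image; complex data are stored as a trailing
    real/imaginary axis."""
    data = img
    if np.iscomplexobj(img):
        data = np.stack([img.real, img.imag], axis=-1)
    affine = np.diag([spacing] * min(data.ndim, 3) + [1] * (4 - min(data.ndim, 3)))
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), path)


def load_nifti(path, complex_pair: bool = True):
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float32)
    spacing = float(img.affine[0, 0])
    if complex_pair and data.shape[-1] == 2:
        data = data[..., 0] + 1j * data[..., 1]
    return data, spacing
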