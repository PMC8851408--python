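"""Disk formats: TIFF recordings with JSON sidecars, surrogate archives, maps.

Recordings travel as multi-page TIFF stacks next to a ``.json`` sidecar
carrying timing, geometry and the delivered stimulus, so real recordings can
be dropped in with the same layout the simulator writes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from focalstim.stimulus import PulseParams, make_pulse
from focalstim.surrogate import SurrogatePair, TanhNet
from focalstim.synthetic import FluorescenceRecording


def save_recording(rec: FluorescenceRecording, path: str | Path) -> None:
    """Write a recording as <path>.tif plus <path>.json sidecar."""
    path = Path(path)
    tif = path.with_suffix(".tif")
    tifffile.imwrite(tif, rec.frames.astype(np.float32))
    sidecar = {
        "frame_rate": rec.frame_rate,
        "pre_stim_duration": rec.pre_stim_duration,
        "stim_duration": rec.stim_duration,
        "pixel_size": rec.pixel_size,
        "electrode_center": list(rec.electrode_center),
        "electrode_diameter": rec.electrode_diameter,
        "stimulus": rec.stimulus.as_dict() if rec.stimulus else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_recording(path: str | Path) -> FluorescenceRecording:
    """Read a TIFF + JSON sidecar pair written by :func:`save_recording`."""
    path = Path(path)
    frames = tifffile.imread(path.with_suffix(".tif")).astype(float)
    meta = json.loads(path.with_suffix(".json").read_text())
    stim = meta.get("stimulus")
    pulse = None
    if stim:
        pulse = make_pulse(stim["cathodic_amplitude_uA"], stim["duration_ratio"])
    return FluorescenceRecording(
        frames=frames,
        frame_rate=meta["frame_rate"],
        pre_stim_duration=meta["pre_stim_duration"],
        stim_duration=meta["stim_duration"],
        pixel_size=meta["pixel_size"],
        electrode_center=tuple(meta["electrode_center"]),
        electrode_diameter=meta["electrode_diameter"],
        stimulus=pulse,
    )


def _clip_to_json(clip):
    if clip is None:
        return None
    return [None if c is None or not np.isfinite(c) else float(c) for c in clip]


def _clip_from_json(clip):
    if clip is None:
        return None
    return tuple(np.inf if c is None else c for c in clip)


def save_surrogates(pair: SurrogatePair, path: str | Path) -> None:
    """Serialize a surrogate pair (weights + scaling) as portable JSON."""
    d = pair.to_dict()
    for key in ("area_net", "ecc_net"):
        d[key]["clip"] = _clip_to_json(d[key]["clip"])
    Path(path).write_text(json.dumps(d, indent=2))


def load_surrogates(path: str | Path) -> SurrogatePair:
    d = json.loads(Path(path).read_text())
    nets = {}
    for key in ("area_net", "ecc_net"):
        nd = d[key]
        nets[key] = TanhNet(np.asarray(nd["theta"]), np.asarray(nd["input_lo"]),
                            np.asarray(nd["input_hi"]), _clip_from_json(nd["clip"]))
    return SurrogatePair(
        area_net=nets["area_net"], ecc_net=nets["ecc_net"],
        region_area_max=d["region_area_max"], C=d["C"],
        box=(tuple(d["box"][0]), tuple(d["box"][1])),
        split_sizes=tuple(d["split_sizes"]), metrics=d["metrics"],
        architecture=d["architecture"],
    )


def save_objective_heatmap(surface, path: str | Path, iterates=None) -> None:
    """Export an objective map as a PNG heatmap, optionally with the
    optimizer trace overlaid (start red, intermediates yellow, final green)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(
        surface.values, origin="lower", aspect="auto", cmap="viridis",
        extent=(surface.amplitudes[0], surface.amplitudes[-1],
                surface.types[0], surface.types[-1]),
    )
    fig.colorbar(im, ax=ax, label="f(a, t)")
    if iterates:
        a, t, _ = zip(*iterates)
        ax.plot(a, t, "-", color="w", lw=0.8)
        ax.plot(a[0], t[0], "o", color="red", label="start")
        if len(a) > 2:
            ax.plot(a[1:-1], t[1:-1], ".", color="yellow", label="intermediate")
        ax.plot(a[-1], t[-1], "o", color="lime", label="optimum")
        ax.legend(loc="upper right", fontsize=7)
    ax.set_xlabel("pulse amplitude (µA)")
    ax.set_ylabel("pulse type (index)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
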