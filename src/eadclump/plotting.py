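"""Optional pseudocolor rendering of voltage fields (requires matplotlib)."""

from __future__ import annotations

import numpy as np

#: display range used by the study's pseudocolor plots, mV
VMIN_MV = -100.0
VMAX_MV = 50.0


def render_field(field: np.ndarray, path, vmin: float = VMIN_MV,
                 vmax: float = VMAX_MV, obstacle=None, title: str = "") -> None:
    """Write one Vm field as a PNG pseudocolor plot (origin lower-left)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = np.array(field, dtype=float)
    if obstacle is not None:
        shown[obstacle] = np.nan
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(shown, origin="lower", vmin=vmin, vmax=vmax, cmap="jet")
    fig.colorbar(im, ax=ax, label="Vm (mV)")
    if title:
        ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def render_snapshots(recorder, out_dir, every: int = 1, **kwargs) -> list:
    """Render every ``every``-th stored snapshot; returns written paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for k in range(0, len(recorder.times), every):
        p = out / f"vm_{int(recorder.times[k]):07d}ms.png"
        render_field(recorder.fields[k], p,
                     title=f"t = {recorder.times[k]:.0f} ms", **kwargs)
        paths.append(p)
    return paths
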