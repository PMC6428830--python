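"""Overview figures for a completed pipeline run."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def render_report(run_dir: str | Path, out_file: str | Path | None = None) -> Path:
    """Render the standard overview: the reconstructed track colored by
    velocity and by rotational frequency, plus the velocity-frequency scatter
    against the quadratic-flow theory curves."""
    run_dir = Path(run_dir)
    track = pd.read_csv(run_dir / "track.csv")
    kin = pd.read_csv(run_dir / "kinematics.csv")
    import json

    cfg = json.loads((run_dir / "manifest.json").read_text())["config"]
    v0 = 2.0 * cfg["flow"]["flow_rate"] / (
        np.pi * (cfg["phantom"]["tube_diameter"] / 2.0) ** 2
    )
    d_tube = cfg["phantom"]["tube_diameter"]

    fig, axes = plt.subplots(1, 3, figsize=(14, 4))
    for ax, c, label in ((axes[0], kin["v"], "velocity (m/s)"),
                         (axes[1], kin["f_rot"], "f_rot (Hz)")):
        sc = ax.scatter(track["x"] * 1e3, track["y"] * 1e3, c=c, s=4, cmap="viridis")
        fig.colorbar(sc, ax=ax, label=label)
        ax.set_xlabel("x (mm)")
        ax.set_ylabel("y (mm)")
        ax.set_title(f"track colored by {label.split()[0]}")

    ax = axes[2]
    ax.scatter(kin["f_rot"], kin["v"], s=4, alpha=0.5, label="estimates")
    f = np.linspace(0, max(kin["f_rot"].max(), 1.0), 200)
    from mmtrack.kinematics import v_f_theory

    for scale, style in ((1.0, "k--"), (0.65, "b-")):
        ax.plot(f, np.clip(v_f_theory(f, v0, d_tube, scale), 0, None), style,
                label=f"theory x {scale:g}")
    ax.set_xlabel("f_rot (Hz)")
    ax.set_ylabel("v (m/s)")
    ax.legend()
    ax.set_title("velocity-frequency relation")

    fig.tight_layout()
    out_file = Path(out_file) if out_file else run_dir / "report.png"
    fig.savefig(out_file, dpi=130)
    plt.close(fig)
    return out_file
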