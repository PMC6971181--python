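"""Centroid-cloud visualization: normalized transformation centroids in the unit cube."""

from __future__ import annotations

import itertools
import os

import pandas as pd

SUBGROUP_COLORS = {
    "oligodendroglioma": "tab:red",
    "astro_idh_mut": "tab:green",
    "astro_idh_wt": "tab:blue",
    "lgg_nos": "tab:gray",
}


def plot_centroid_cloud(cloud: pd.DataFrame, path: str | os.PathLike) -> None:
    """3D scatter of normalized centroid offsets inside a wireframe unit cube.

    Dots at the origin are transformations at the preoperative tumor
    center; dots at the cube faces sit at the border of the tumor extent.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(projection="3d")
    for a, b in itertools.combinations(itertools.product([-1, 1], repeat=3), 2):
        if sum(x != y for x, y in zip(a, b)) == 1:  # cube edge
            ax.plot(*zip(a, b), color="0.7", linewidth=0.8)
    for subgroup, sub in cloud.groupby("subgroup"):
        ax.scatter(
            sub["u_x"], sub["u_y"], sub["u_z"],
            label=f"{subgroup} (n={len(sub)})",
            color=SUBGROUP_COLORS.get(str(subgroup), "black"),
            s=30, depthshade=False,
        )
    ax.set_xlabel("u_x"), ax.set_ylabel("u_y"), ax.set_zlabel("u_z")
    ax.set_title("Transformation centroid in preoperative unit cube")
    ax.legend(loc="upper left", fontsize=8)
    fig.savefig(os.fspath(path), dpi=150, bbox_inches="tight")
    plt.close(fig)
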