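"""Two-panel result figures: survival and observed heterozygosity versus generation.

For each initial-heterozygosity level one figure is produced.  The left panel
shows the survival rate of the 20 replicates, the right the mean observed
heterozygosity among survivors, with one line per propagule-size ×
extinction-rate combination.  The geometric survival oracle ``(1 - e)^t`` can
be overlaid for comparison.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .oracles import survival_curve
from .scenario import GridResult

__all__ = ["plot_panels"]


def plot_panels(
    result: GridResult,
    out_dir: str | Path,
    oracle_overlay: bool = False,
) -> list[Path]:
    """One survival/heterozygosity figure per initial Ho level; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = result.summary()
    paths: list[Path] = []
    for ho0, block in summary.groupby("target_ho"):
        fig, (ax_s, ax_h) = plt.subplots(1, 2, figsize=(11, 4.2), sharex=True)
        oracle_rates = set()
        for (n, e), cell in block.groupby(["propagule_size", "extinction_rate"]):
            cell = cell.sort_values("generation")
            label = f"n={n}, e={e:g}"
            ax_s.plot(cell["generation"], 100 * cell["survival_rate"], label=label, lw=1)
            alive = cell[cell["n_survivors"] > 0]
            ax_h.plot(alive["generation"], alive["mean_ho"], lw=1)
            oracle_rates.add(float(e))
        if oracle_overlay:
            T = int(block["generation"].max())
            for e in sorted(oracle_rates):
                ax_s.plot(
                    range(T + 1),
                    100 * survival_curve(e, T).values,
                    ls="--", color="k", alpha=0.4, lw=0.8,
                )
        ax_s.set_xlabel("generation")
        ax_s.set_ylabel("survival rate (%)")
        ax_h.set_xlabel("generation")
        ax_h.set_ylabel("observed heterozygosity (survivors)")
        ax_s.legend(fontsize=6, ncol=2)
        fig.suptitle(f"Initial heterozygosity {ho0:g}")
        fig.tight_layout()
        path = out / f"panels_ho{ho0:g}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        paths.append(path)
    return paths
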