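"""Figure generation for level and efficiency summaries.

Panels follow the conventional colouring of hairpin methylation analyses:
red = both strands modified, dark green = top strand only, light green =
bottom strand only, blue = unmodified; 5hmC pairing classes use light
green (h with C), dark green (h with 5mC) and yellow (symmetric h);
efficiency panels use red for maintenance, blue for de novo, yellow for
hydroxylation and dark red for the combined activity on hemimethylated
substrates.  Figures are drawn on a fixed canvas so regeneration with the
same inputs is deterministic.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .model import CountData, DivisionSchedule, FitResult, hydroxylation_summary

_CLASS_STYLE = {
    "both": "#c81e1e",
    "hemi_top": "#146e14",
    "hemi_bottom": "#8cdc8c",
    "unmod": "#2846c8",
}
_HMC_STYLE = {
    "h_with_u": "#8cdc8c",
    "h_with_m": "#146e14",
    "h_symmetric": "#e6c800",
}
_EFF_STYLE = {
    "maintenance": "#c81e1e",
    "de_novo": "#2846c8",
    "hydroxylation": "#e6c800",
    "total_hemi": "#780a0a",
}


def observed_class_fractions(counts: CountData, treatment: str) -> pd.DataFrame:
    """Read-class fractions per time for one treatment channel.

    CC -> both, CT -> hemi_top, TC -> hemi_bottom, TT -> unmod (read C =
    modified strand under that treatment's chemistry).
    """
    arr = counts.counts[treatment].astype(float)
    frac = arr / arr.sum(axis=1, keepdims=True)
    return pd.DataFrame(frac, columns=["both", "hemi_top", "hemi_bottom", "unmod"])


def write_estimate_plots(
    counts: CountData,
    schedule: DivisionSchedule,
    fit_result: FitResult,
    out_path: str | Path,
    amplicon: str = "amplicon",
    naive_total: float | None = None,
) -> Path:
    """Four panels: BS levels, oxBS levels, model 5hmC classes, efficiencies."""
    days = list(schedule.days)
    fig, axes = plt.subplots(2, 2, figsize=(10, 7), dpi=100)
    for ax, treatment in zip(axes[0], ("BS", "oxBS")):
        if treatment in counts.counts:
            frac = observed_class_fractions(counts, treatment)
            for cls, color in _CLASS_STYLE.items():
                ax.plot(days, frac[cls], "o-", color=color, label=cls)
        ax.set_title(f"{amplicon}: {treatment} dyad classes")
        ax.set_xlabel("day")
        ax.set_ylabel("fraction")
        ax.set_ylim(-0.02, 1.02)
        ax.legend(fontsize=7)

    ax = axes[1][0]
    hmc = [hydroxylation_summary(fit_result, t) for t in range(schedule.n_times)]
    for key, color in _HMC_STYLE.items():
        ax.plot(days, [h[key] for h in hmc], "o-", color=color, label=key)
    ax.plot(
        days,
        [h["total_5hmc_per_strand"] for h in hmc],
        "k--",
        label="total 5hmC / strand",
    )
    if naive_total is not None:
        ax.axhline(naive_total, color="gray", ls=":", label="naive subtraction (mean)")
    ax.set_title("model 5hmC pairing classes")
    ax.set_xlabel("day")
    ax.set_ylabel("probability")
    ax.legend(fontsize=7)

    ax = axes[1][1]
    if fit_result.efficiencies.size:
        mids = [(a + b) / 2 for a, b in zip(days, days[1:])]
        eff = fit_result.efficiencies
        total = eff[:, 0] + (1 - eff[:, 0]) * eff[:, 1]
        series = {
            "maintenance": eff[:, 0],
            "de_novo": eff[:, 1],
            "hydroxylation": eff[:, 2],
            "total_hemi": total,
        }
        for key, color in _EFF_STYLE.items():
            ax.plot(mids, series[key], "s-", color=color, label=key)
        ax.set_ylim(-0.02, 1.02)
    ax.set_title("enzyme efficiencies per interval")
    ax.set_xlabel("day (interval midpoint)")
    ax.set_ylabel("efficiency")
    ax.legend(fontsize=7)

    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path)
    plt.close(fig)
    return out_path
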