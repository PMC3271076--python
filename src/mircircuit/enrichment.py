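"""Sliding-window enrichment of predicted TF targets along a ranked probe list.

Probes are ordered from most up- to most down-regulated and flagged 1 when
the probe's miRNA gene is a predicted TF target (any pri-miRNA locus of its
mature miRNA carries >= 1 selected binding site). The enrichment curve is
the mean flag within each w-probe sliding window (default w = 300, step 1),
compared against the expected average: the overall fraction of flagged
probes among all interrogated probes. A permutation envelope from random
flag shuffles gives a pointwise significance band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_WINDOW = 300
DEFAULT_STEP = 1


@dataclass
class RankedProbeList:
    """Probes ordered up->down with binary TF-target flags."""

    probes: list
    flags: np.ndarray
    window: int = DEFAULT_WINDOW
    step: int = DEFAULT_STEP

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=float)
        if len(self.probes) != self.flags.size:
            raise ValueError("probes and flags must have equal length")
        if not np.isin(self.flags, (0.0, 1.0)).all():
            raise ValueError("flags must be binary")


def rank_order_probes(
    results, target_flags: dict | None = None, by: str = "rank_product"
) -> RankedProbeList:
    """Order probes most-up first, most-down last.

    ``results`` is a :class:`~mircircuit.expression.DifferentialTable` (or its
    DataFrame). Ordering statistic: ascending up-direction rank product
    (default) or descending fold change; ties break by probe id. Idempotent:
    reordering an already-ordered table returns the same order.
    """
    table = getattr(results, "table", results)
    if by == "rank_product":
        keys = [(table.at[p, "rp_up"], str(p)) for p in table.index]
    elif by == "fold_change":
        keys = [(-table.at[p, "fold_change"], str(p)) for p in table.index]
    else:
        raise ValueError(f"unknown ordering statistic {by!r}")
    order = [p for _, p in sorted(zip(keys, table.index))]
    flags = np.array(
        [1.0 if target_flags and target_flags.get(p) else 0.0 for p in order]
    )
    return RankedProbeList(order, flags)


def sliding_window_frequency(flags, w: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP) -> np.ndarray:
    """Mean flag in each w-length window: element j = mean(flags[j*step : j*step + w])."""
    flags = np.asarray(flags, dtype=float)
    n = flags.size
    if w > n:
        raise ValueError(f"window {w} larger than list length {n}")
    csum = np.concatenate([[0.0], np.cumsum(flags)])
    starts = np.arange(0, n - w + 1, step)
    return (csum[starts + w] - csum[starts]) / w


def background_frequency(flags) -> float:
    """Expected average: flagged probes over all interrogated probes."""
    flags = np.asarray(flags, dtype=float)
    if flags.size == 0:
        raise ValueError("empty flag vector")
    return float(flags.sum() / flags.size)


def enrichment_permutation_band(
    flags,
    w: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    n_perm: int = 1000,
    quantiles: tuple = (0.025, 0.975),
    seed: int | None = None,
) -> pd.DataFrame:
    """Pointwise quantile envelope of the window-frequency curve under flag shuffles."""
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    flags = np.asarray(flags, dtype=float)
    rng = np.random.default_rng(seed)
    n_windows = (flags.size - w) // step + 1
    sims = np.empty((n_perm, n_windows))
    for i in range(n_perm):
        sims[i] = sliding_window_frequency(rng.permutation(flags), w, step)
    qs = np.quantile(sims, quantiles, axis=0)
    return pd.DataFrame(
        {f"q{q:g}": qs[i] for i, q in enumerate(quantiles)},
        index=pd.RangeIndex(n_windows, name="window_start"),
    )


@dataclass
class EnrichmentCurve:
    """Observed curve, background and optional envelope, window-start indexed."""

    frequencies: np.ndarray
    background: float
    window: int
    step: int
    band: pd.DataFrame | None = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        n = self.frequencies.size
        starts = np.arange(n) * self.step
        df = pd.DataFrame(
            {
                "window_start": starts,
                "window_center": starts + self.window // 2,
                "frequency": self.frequencies,
                "background": self.background,
            }
        )
        if self.band is not None:
            for col in self.band.columns:
                df[col] = self.band[col].to_numpy()
        return df


def enrichment_curve(
    ranked: RankedProbeList,
    n_perm: int | None = None,
    seed: int | None = None,
    quantiles: tuple = (0.025, 0.975),
) -> EnrichmentCurve:
    freq = sliding_window_frequency(ranked.flags, ranked.window, ranked.step)
    bg = background_frequency(ranked.flags)
    band = None
    if n_perm:
        band = enrichment_permutation_band(
            ranked.flags, ranked.window, ranked.step, n_perm, quantiles, seed
        )
    return EnrichmentCurve(freq, bg, ranked.window, ranked.step, band)


def plot_enrichment(curve: EnrichmentCurve, ax=None, title: str | None = None):
    """Curve vs probe rank at window center, dashed background line, optional band."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    centers = np.arange(curve.frequencies.size) * curve.step + curve.window // 2
    if curve.band is not None:
        cols = list(curve.band.columns)
        ax.fill_between(
            centers, curve.band[cols[0]], curve.band[cols[-1]],
            color="0.85", label="permutation band",
        )
    ax.plot(centers, curve.frequencies, color="tab:blue", label="target frequency")
    ax.axhline(curve.background, ls="--", color="k", label="expected average")
    ax.set_xlabel("probe rank (window center), up → down")
    ax.set_ylabel(f"target frequency / {curve.window}-probe window")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    return ax
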