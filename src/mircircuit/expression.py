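"""Differential miRNA expression: normalization, fold change, rank product.

The probe intensity matrix (growth medium GM vs differentiation medium DM,
two biological replicates each in the emulated design) is quantile
normalized, fold changes are DM/GM ratios of replicate means, and probes
are ranked by the rank-product statistic: per replicate pair, per-probe
fold changes are ranked across probes (rank 1 = most changed in the chosen
direction) and the statistic is the geometric mean of those ranks.
Significance comes from within-pair probe-label permutations with +1
smoothing; tiny problems can be enumerated exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .formats import ExpressionMatrix

INTENSITY_FLOOR = 1e-6


def normalize_quantile(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile normalization: every column gets the mean sorted-value vector.

    Ties within a column receive the average of the corresponding mean
    quantiles, which makes the transform idempotent.
    """
    values = matrix.values.to_numpy(dtype=float)
    order_stats = np.sort(values, axis=0)
    mean_quant = order_stats.mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average")  # 1..N, ties averaged
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (mean_quant[lo] + mean_quant[hi])
    df = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(df, dict(matrix.conditions), dict(matrix.replicates))


def normalize_quantile_within(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile normalization applied separately within each condition group.

    Replicates of one condition are forced onto their common quantile
    vector, which removes technical between-array variation without also
    erasing genuine between-condition distributional differences — global
    quantile normalization compresses true fold changes at the tails when
    a sizable fraction of probes is regulated.
    """
    out = matrix.values.copy()
    for cond in matrix.condition_names:
        samples = matrix.samples_for(cond)
        sub = ExpressionMatrix(
            matrix.values[samples],
            {s: cond for s in samples},
            {s: matrix.replicates[s] for s in samples},
        )
        out[samples] = normalize_quantile(sub).values
    return ExpressionMatrix(out, dict(matrix.conditions), dict(matrix.replicates))


def fold_changes(
    matrix: ExpressionMatrix,
    numerator_condition: str = "DM3",
    denominator_condition: str = "GM",
    floor: float = INTENSITY_FLOOR,
) -> pd.Series:
    """Per-probe ratio of replicate-mean intensities, numerator over denominator."""
    num = matrix.values[matrix.samples_for(numerator_condition)].mean(axis=1)
    den = matrix.values[matrix.samples_for(denominator_condition)].mean(axis=1)
    den = den.clip(lower=floor)
    num = num.clip(lower=floor)
    return num / den


def _pair_fold_change_ranks(
    matrix: ExpressionMatrix, direction: str, numerator: str, denominator: str,
    pairing: str = "matched",
) -> np.ndarray:
    """(N, k) matrix of per-pair fold-change ranks; rank 1 = most changed.

    ``pairing="matched"`` (default) pairs the r-th numerator replicate with
    the r-th denominator replicate (k = min of the replicate counts): pairs
    share no samples, so under the null the per-pair fold changes are
    independent and the within-pair permutation null is exact.
    ``pairing="cross"`` forms all numerator x denominator pairs; pairs then
    share replicates and the permutation p-values are only approximate.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    num_samples = sorted(matrix.samples_for(numerator), key=lambda s: matrix.replicates[s])
    den_samples = sorted(matrix.samples_for(denominator), key=lambda s: matrix.replicates[s])
    if pairing == "matched":
        pairs = list(zip(num_samples, den_samples))
    elif pairing == "cross":
        pairs = list(itertools.product(num_samples, den_samples))
    else:
        raise ValueError(f"pairing must be 'matched' or 'cross', got {pairing!r}")
    cols = []
    for ns, ds in pairs:
        fc = matrix.values[ns].to_numpy(float) / np.clip(
            matrix.values[ds].to_numpy(float), INTENSITY_FLOOR, None
        )
        # up: largest fold change gets rank 1; down: smallest gets rank 1
        keyed = -fc if direction == "up" else fc
        cols.append(rankdata(keyed, method="average"))
    return np.column_stack(cols)


def _geometric_mean_rows(ranks: np.ndarray) -> np.ndarray:
    return np.exp(np.log(ranks).mean(axis=1))


def rank_product(
    matrix: ExpressionMatrix,
    direction: str = "up",
    n_perm: int = 1000,
    seed: int | None = None,
    numerator_condition: str = "DM3",
    denominator_condition: str = "GM",
    exact: bool = False,
    pairing: str = "matched",
) -> pd.DataFrame:
    """Rank-product statistic and permutation p-value per probe.

    p = (1 + #{permutations with null RP <= observed RP}) / (n_perm + 1),
    where each permutation shuffles probe labels independently within each
    replicate pair. With ``exact=True`` all within-pair rank assignments are
    enumerated (tiny N only) instead of sampled.
    """
    ranks = _pair_fold_change_ranks(
        matrix, direction, numerator_condition, denominator_condition, pairing
    )
    n, k = ranks.shape
    rp = _geometric_mean_rows(ranks)

    if exact:
        # enumerate all (N!)^k joint within-pair probe-label permutations
        # (tiny N only) and compare each probe's null RP to its observed RP
        counts = np.zeros(n)
        total = 0
        for perms in itertools.product(list(itertools.permutations(range(n))), repeat=k):
            null = np.column_stack(
                [ranks[list(perms[j]), j] for j in range(k)]
            )
            counts += _geometric_mean_rows(null) <= rp + 1e-12
            total += 1
        pvals = (counts + 1.0) / (total + 1.0)
        n_used = total
    else:
        if n_perm < 1:
            raise ValueError(f"n_perm must be >= 1, got {n_perm}")
        rng = np.random.default_rng(seed)
        counts = np.zeros(n)
        for _ in range(n_perm):
            null = np.column_stack([rng.permutation(ranks[:, j]) for j in range(k)])
            counts += _geometric_mean_rows(null) <= rp + 1e-12
        pvals = (counts + 1.0) / (n_perm + 1.0)
        n_used = n_perm
    out = pd.DataFrame(
        {"RP": rp, "p_value": pvals}, index=matrix.values.index
    )
    out.attrs["direction"] = direction
    out.attrs["n_perm"] = n_used
    return out


@dataclass
class DifferentialTable:
    """Per-probe differential-expression summary joining both directions."""

    table: pd.DataFrame  # columns: mean_GM, mean_DM, fold_change, rp_up, p_up, rp_down, p_down, rank

    def __len__(self) -> int:
        return len(self.table)


def differential_expression(
    matrix: ExpressionMatrix,
    numerator_condition: str = "DM3",
    denominator_condition: str = "GM",
    n_perm: int = 1000,
    seed: int | None = None,
    normalize: str | bool = "within",
    fdr: bool = False,
) -> DifferentialTable:
    """Full differential pipeline: normalize, fold changes, both-direction rank product.

    ``normalize`` is ``"within"`` (per-condition quantile, default),
    ``"global"`` (all columns onto one quantile vector) or ``False``.
    ``rank`` is the 1..N position in the up->down ordering (ascending rp_up,
    ties by probe id). Raw permutation p-values are reported; ``fdr=True``
    adds Benjamini-Hochberg adjusted columns.
    """
    if normalize == "within":
        matrix = normalize_quantile_within(matrix)
    elif normalize == "global" or normalize is True:
        matrix = normalize_quantile(matrix)
    elif normalize:
        raise ValueError(f"normalize must be 'within', 'global' or False, got {normalize!r}")
    fc = fold_changes(matrix, numerator_condition, denominator_condition)
    up = rank_product(matrix, "up", n_perm, seed, numerator_condition, denominator_condition)
    down = rank_product(
        matrix, "down", n_perm, None if seed is None else seed + 1,
        numerator_condition, denominator_condition,
    )
    mean_den = matrix.values[matrix.samples_for(denominator_condition)].mean(axis=1)
    mean_num = matrix.values[matrix.samples_for(numerator_condition)].mean(axis=1)
    table = pd.DataFrame(
        {
            "mean_GM": mean_den,
            "mean_DM": mean_num,
            "fold_change": fc,
            "rp_up": up["RP"],
            "p_up": up["p_value"],
            "rp_down": down["RP"],
            "p_down": down["p_value"],
        }
    )
    order = table.sort_values(["rp_up"], kind="mergesort").index
    # deterministic tie-break by probe id
    order = sorted(order, key=lambda p: (table.at[p, "rp_up"], str(p)))
    table["rank"] = pd.Series(
        np.arange(1, len(table) + 1), index=pd.Index(order)
    ).reindex(table.index)
    if fdr:
        from statsmodels.stats.multitest import multipletests

        for col in ("p_up", "p_down"):
            table[col + "_bh"] = multipletests(table[col], method="fdr_bh")[1]
    return DifferentialTable(table)


def select_regulated(
    results: DifferentialTable | pd.DataFrame,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
) -> tuple[list, list]:
    """Split probes into up- and down-regulated sets at the stated thresholds.

    up: fold_change > fc_threshold and p_up <= p_threshold;
    down: fold_change < 1/fc_threshold and p_down <= p_threshold.
    """
    table = results.table if isinstance(results, DifferentialTable) else results
    up_mask = (table["fold_change"] > fc_threshold) & (table["p_up"] <= p_threshold)
    if fc_threshold > 0:
        down_mask = (table["fold_change"] < 1.0 / fc_threshold) & (
            table["p_down"] <= p_threshold
        )
    else:
        down_mask = table["p_down"] <= p_threshold
    return list(table.index[up_mask]), list(table.index[down_mask])
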