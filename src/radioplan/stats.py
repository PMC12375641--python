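"""Paired-condition statistics: Friedman omnibus, Dunnett-style post hoc.

The unit of analysis is a complete block matrix (patients as blocks, the
six calculation conditions as treatments). The omnibus test is the Friedman
rank-sum test with mean-rank ties and the standard tie correction; post-hoc
pairwise comparisons use paired t statistics with a family-wise adjustment
against the equicorrelated multivariate-t reference distribution (Dunnett's
many-to-one construction), evaluated by seeded Monte Carlo; a Bonferroni
fallback is available. Post-hoc results are produced even when the omnibus
is not significant, flagged accordingly.

Star convention: * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001,
"ns" for p>=0.05 (strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "friedman_test",
    "dunnett_posthoc",
    "star_label",
    "compare_cohort",
    "block_matrix",
    "FriedmanResult",
]

_STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))

DEFAULT_MC_REPS = 200_000


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    p_value: float
    n_blocks: int
    n_treatments: int


def _as_block_array(data) -> np.ndarray:
    arr = data.to_numpy(dtype=float) if isinstance(data, pd.DataFrame) else np.asarray(data, float)
    if arr.ndim != 2:
        raise ValueError("block matrix must be 2D (blocks x treatments)")
    if np.isnan(arr).any():
        raise ValueError(
            "block matrix has missing cells; the omnibus test requires complete "
            "blocks — drop incomplete blocks first"
        )
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need at least 2 blocks and 2 treatments")
    return arr


def friedman_test(data) -> FriedmanResult:
    """Friedman rank-sum test over related columns.

    Mean ranks for ties, tie-corrected chi-square statistic with k-1
    degrees of freedom.
    """
    arr = _as_block_array(data)
    n, k = arr.shape
    ranks = sps.rankdata(arr, axis=1)
    # tie correction: sum of (t^3 - t) over tie groups of every block
    ties = 0.0
    for row in arr:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    c = 1.0 - ties / (n * k * (k**2 - 1))
    if c <= 0:  # all values identical in every block
        return FriedmanResult(0.0, 1.0, n, k)
    col_rank_sums = ranks.sum(axis=0)
    ssbn = float(np.sum(col_rank_sums**2))
    statistic = (12.0 / (n * k * (k + 1)) * ssbn - 3.0 * n * (k + 1)) / c
    statistic = max(statistic, 0.0)
    p = float(sps.chi2.sf(statistic, k - 1))
    return FriedmanResult(float(statistic), p, n, k)


# cached sorted samples of max|T| under the equicorrelated multivariate-t null
_MAXT_CACHE: dict[tuple[int, int, int, int], np.ndarray] = {}


def _max_abs_t_reference(n_pairs: int, df: int, reps: int, seed: int) -> np.ndarray:
    key = (n_pairs, df, reps, seed)
    if key not in _MAXT_CACHE:
        rng = np.random.default_rng(seed)
        # Z_i = (G_i + G_0)/sqrt(2) gives the rho = 0.5 equicorrelated
        # normal of Dunnett's many-to-one construction; divide by a shared
        # chi factor for the multivariate t with `df` degrees of freedom.
        g = rng.standard_normal((reps, n_pairs))
        g0 = rng.standard_normal((reps, 1))
        z = (g + g0) / np.sqrt(2.0)
        s = np.sqrt(rng.chisquare(df, size=(reps, 1)) / df)
        _MAXT_CACHE[key] = np.sort(np.max(np.abs(z / s), axis=1))
    return _MAXT_CACHE[key]


def paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t statistic and raw p."""
    d = np.asarray(x, float) - np.asarray(y, float)
    n = d.size
    if n < 2:
        raise ValueError("paired t needs at least 2 blocks")
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
    else:
        t = d.mean() / (sd / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), n - 1)) if np.isfinite(t) else 0.0
    return float(t), p


def dunnett_posthoc(
    data: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    control: str | None = None,
    method: str = "mvt",
    mc_reps: int = DEFAULT_MC_REPS,
    seed: int = 0,
) -> pd.DataFrame:
    """Family-wise adjusted paired comparisons between condition columns.

    Parameters
    ----------
    data : DataFrame, blocks x conditions (complete).
    pairs : explicit list of (a, b) column pairs; if omitted, every
        non-control column is compared against ``control``.
    method : "mvt" (equicorrelated multivariate-t reference, Monte Carlo)
        or "bonferroni".

    Returns a frame with columns pair_a, pair_b, t, raw_p, adjusted_p,
    stars. Pair order within the family does not affect the adjustment.
    """
    if not isinstance(data, pd.DataFrame):
        raise TypeError("data must be a DataFrame with condition columns")
    cols = list(data.columns)
    if pairs is None:
        if control is None:
            raise ValueError("provide either explicit pairs or a control condition")
        if control not in cols:
            raise KeyError(f"control condition {control!r} not among columns {cols}")
        pairs = [(c, control) for c in cols if c != control]
    for a, b in pairs:
        for name in (a, b):
            if name not in cols:
                raise KeyError(f"pair condition {name!r} not among columns {cols}")
    _as_block_array(data)

    n = len(data)
    df = n - 1
    results = []
    tstats = []
    for a, b in pairs:
        t, raw_p = paired_t(data[a].to_numpy(), data[b].to_numpy())
        tstats.append(t)
        results.append({"pair_a": a, "pair_b": b, "t": t, "raw_p": raw_p})

    k = len(pairs)
    for row, t in zip(results, tstats):
        if k == 1:
            adj = row["raw_p"]
        elif method == "bonferroni":
            adj = min(1.0, k * row["raw_p"])
        elif method == "mvt":
            ref = _max_abs_t_reference(k, df, mc_reps, seed)
            exceed = ref.size - np.searchsorted(ref, abs(t), side="left")
            adj = float(exceed / ref.size)
        else:
            raise ValueError(f"unknown adjustment method {method!r}")
        adj = min(1.0, max(adj, row["raw_p"]))  # adjustment never below raw p
        row["adjusted_p"] = adj
        row["stars"] = star_label(adj)
    return pd.DataFrame(results)


def star_label(p: float) -> str:
    """Significance stars: strict thresholds, "ns" at p >= 0.05."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    for threshold, label in _STAR_THRESHOLDS:
        if p < threshold:
            return label
    return "ns"


def block_matrix(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Pivot a tidy metric table to blocks (patients) x conditions."""
    sub = table[table["metric"] == metric]
    if sub.empty:
        raise KeyError(f"metric {metric!r} not present in table")
    mat = sub.pivot(index="patient", columns="condition", values="value")
    if mat.isna().any().any():
        raise ValueError(f"metric {metric!r} has missing patient x condition cells")
    return mat


def compare_cohort(
    table: pd.DataFrame,
    control: str = "AAA",
    pairs: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
    method: str = "mvt",
    mc_reps: int = DEFAULT_MC_REPS,
    seed: int = 0,
) -> pd.DataFrame:
    """Omnibus-then-post-hoc comparison for every metric in a tidy table.

    Input columns: patient, condition, metric, value. For each metric one
    "friedman" row plus one row per post-hoc pair is emitted; post hoc is
    always computed, with ``omnibus_significant`` flagging whether the
    Friedman p cleared ``alpha``.
    """
    out = []
    for metric in sorted(table["metric"].unique()):
        mat = block_matrix(table, metric)
        fr = friedman_test(mat)
        omnibus_sig = fr.p_value < alpha
        out.append(
            {
                "metric": metric,
                "kind": "friedman",
                "pair_a": "",
                "pair_b": "",
                "statistic": fr.statistic,
                "raw_p": fr.p_value,
                "adjusted_p": np.nan,
                "stars": star_label(fr.p_value),
                "omnibus_significant": omnibus_sig,
            }
        )
        post = dunnett_posthoc(
            mat, pairs=pairs, control=control, method=method, mc_reps=mc_reps, seed=seed
        )
        for _, row in post.iterrows():
            out.append(
                {
                    "metric": metric,
                    "kind": "posthoc",
                    "pair_a": row["pair_a"],
                    "pair_b": row["pair_b"],
                    "statistic": row["t"],
                    "raw_p": row["raw_p"],
                    "adjusted_p": row["adjusted_p"],
                    "stars": row["stars"],
                    "omnibus_significant": omnibus_sig,
                }
            )
    return pd.DataFrame(out)
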