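"""Per-protein significance testing and differential-expression calls.

Each protein's pooled spectral counts form a 2x2 contingency table against
the condition totals::

    [[n_ctrl, t_ctrl - n_ctrl],
     [n_kd,   t_kd   - n_kd  ]]

tested with a two-sided Fisher exact test (two-sidedness by summing all
outcomes whose point probability does not exceed the observed outcome's).
Raw p-values are corrected within each compartment by the Benjamini-Hochberg
step-up procedure, and a protein is called differential when it clears both
a fold-change gate (|Rsc| > 1.8 by default) and a significance gate
(BH-adjusted value < 0.05 by default; a raw-p mode is kept as a switch).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .quantitation import CountMatrix, compute_rsc, pool_replicates

__all__ = [
    "fisher_exact_protein",
    "benjamini_hochberg",
    "differential_table",
    "call_differential",
]


def fisher_exact_protein(n_ctrl: int, t_ctrl: int, n_kd: int, t_kd: int) -> float:
    """Two-sided Fisher exact p-value for one protein's 2x2 count table.

    A table with a degenerate margin (e.g. the protein unobserved in both
    conditions) carries no evidence and returns p = 1.
    """
    if n_ctrl < 0 or n_kd < 0:
        raise ValueError("counts must be non-negative")
    if n_ctrl > t_ctrl or n_kd > t_kd:
        raise ValueError("protein count exceeds condition total")
    if t_ctrl == 0 and t_kd == 0:
        raise ValueError("both condition totals are zero")
    table = [[n_ctrl, t_ctrl - n_ctrl], [n_kd, t_kd - n_kd]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (q-values), input order.

    On p-values sorted ascending, ``q_(i) = min_{j >= i} p_(j) * m / j``,
    capped at 1, then mapped back to the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def differential_table(
    matrix: CountMatrix,
    compartment: str,
    conditions: tuple[str, str] = ("control", "kd"),
    f: float = 0.5,
) -> pd.DataFrame:
    """Pool, test and adjust one compartment; returns the per-protein results.

    Columns: accession, compartment, n_ctrl, t_ctrl, n_kd, t_kd, rsc,
    p_raw, q_bh.  BH correction is applied within the compartment (each
    compartment is reported as an independent comparison).
    """
    ctrl_label, kd_label = conditions
    pooled_ctrl = pool_replicates(matrix, ctrl_label, compartment)
    pooled_kd = pool_replicates(matrix, kd_label, compartment)
    rsc = compute_rsc(pooled_ctrl, pooled_kd, f=f)
    t1, t2 = pooled_ctrl.t, pooled_kd.t
    p_raw = np.array(
        [
            fisher_exact_protein(int(n1), t1, int(n2), t2)
            for n1, n2 in zip(pooled_ctrl.n.to_numpy(), pooled_kd.n.to_numpy())
        ]
    )
    q_bh = benjamini_hochberg(p_raw)
    return pd.DataFrame(
        {
            "accession": pooled_ctrl.n.index,
            "compartment": compartment,
            "n_ctrl": pooled_ctrl.n.to_numpy(),
            "t_ctrl": t1,
            "n_kd": pooled_kd.n.to_numpy(),
            "t_kd": t2,
            "rsc": rsc.to_numpy(),
            "p_raw": p_raw,
            "q_bh": q_bh,
        }
    ).reset_index(drop=True)


def call_differential(
    results: pd.DataFrame,
    rsc_threshold: float = 1.8,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Attach up/down/none calls: |Rsc| strictly above the threshold AND the
    significance value (q_bh by default, p_raw otherwise) strictly below alpha."""
    out = results.copy()
    sig = out["q_bh"] if use_adjusted else out["p_raw"]
    passed = sig < alpha
    call = np.where(
        passed & (out["rsc"] > rsc_threshold),
        "up",
        np.where(passed & (out["rsc"] < -rsc_threshold), "down", "none"),
    )
    out["call"] = call
    return out
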