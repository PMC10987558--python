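"""Per-metabolite bioavailability index between a case and a control group.

The index is the log2 fold change of the group-summarized community
boundary fluxes.  Boundary fluxes are signed (positive = secretion), and a
ratio across a sign change is meaningless, so the fold change is computed
on magnitudes with a small pseudo-flux and the case-group sign attached; a
separate switch flag marks metabolites whose group summaries have opposite
signs (production in one group, consumption in the other).  Group
differences are tested per metabolite with a two-sided rank-sum test on the
per-individual fluxes, corrected with the permutation-based FDR; the
significance filter is p < 0.05 together with FDR < 0.1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._stats import permutation_fdr, ranksum_pvalues

P_THRESHOLD = 0.05
FDR_THRESHOLD = 0.1


def bioavailability(
    profiles: pd.DataFrame,
    groups: pd.Series,
    case_group: str,
    control_group: str,
    n_perm: int = 1000,
    seed: int | None = None,
    pseudo: float = 1e-6,
    summary: str = "mean",
) -> pd.DataFrame:
    """Bioavailability index per metabolite.

    Parameters
    ----------
    profiles:
        samples × metabolites boundary-flux matrix (secretion positive).
    groups:
        group label per sample; only ``case_group`` and ``control_group``
        rows are used.
    summary:
        per-group summary of the per-individual fluxes, ``mean`` (default)
        or ``median``.
    """
    if seed is None:
        raise ValueError("a seed is required for the permutation FDR")
    if pseudo <= 0:
        raise ValueError("pseudo-flux must be > 0")
    if summary not in ("mean", "median"):
        raise ValueError("summary must be 'mean' or 'median'")
    groups = groups.loc[profiles.index]
    keep = groups.isin([case_group, control_group])
    X = profiles.loc[keep].to_numpy(dtype=float)
    labels = np.where(groups[keep] == case_group, "case", "control")
    if (labels == "case").sum() < 2 or (labels == "control").sum() < 2:
        raise ValueError("need at least 2 samples per group")
    dead = np.flatnonzero((X == 0).all(axis=0))
    if dead.size == profiles.shape[1]:
        raise ValueError("no metabolite has exchange activity in any profile")

    summarize = np.mean if summary == "mean" else np.median
    s_case = summarize(X[labels == "case"], axis=0)
    s_ctrl = summarize(X[labels == "control"], axis=0)
    magnitude = np.log2((np.abs(s_case) + pseudo) / (np.abs(s_ctrl) + pseudo))
    sign = np.where(s_case < 0, -1.0, 1.0)
    log2fc = sign * magnitude
    switch = (np.sign(s_case) != np.sign(s_ctrl)) & (s_case != 0) & (s_ctrl != 0)

    p = ranksum_pvalues(X, labels)
    rng = np.random.default_rng(seed)
    q = permutation_fdr(p, X, labels, n_perm, rng)
    return pd.DataFrame(
        {
            f"{summary}_case": s_case,
            f"{summary}_control": s_ctrl,
            "log2_fold_change": log2fc,
            "switch": switch,
            "p_value": p,
            "q_value": q,
            "significant": (p < P_THRESHOLD) & (q < FDR_THRESHOLD),
        },
        index=profiles.columns,
    )
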