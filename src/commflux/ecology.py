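"""Dysbiosis statistics for genus-level abundance tables.

Covers the community-ecology layer of the pipeline: alpha diversity
(Shannon index in nats, specific richness), Bray–Curtis dissimilarity,
PERMANOVA with either sampled or exhaustively enumerated label permutations,
principal-coordinates analysis, per-genus differential abundance with a
permutation-based FDR, cross-compartment Spearman correlation, shared-genus
compartmentalization summaries, age–diversity association and qPCR ΔΔCt
relative quantification.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from ._stats import permutation_fdr, ranksum_pvalues, spearman_with_p
from .abundance import AbundanceTable


# ---------------------------------------------------------------------------
# alpha diversity


def shannon(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample Shannon index H = −Σ p ln p (nats) and specific richness.

    Requires a row-normalized table; 0·ln 0 is taken as 0.  Richness counts
    genera with strictly positive abundance, so H <= ln(richness) always
    holds, with equality on uniform support.
    """
    if not table.normalized:
        raise ValueError("shannon requires a normalized table (use to_relative)")
    p = table.values
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    H = -plogp.sum(axis=1)
    richness = (p > 0).sum(axis=1)
    return pd.DataFrame(
        {"shannon": H, "richness": richness}, index=table.data.index
    )


# ---------------------------------------------------------------------------
# beta diversity


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with zero diagonal."""

    sample_ids: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.sample_ids)
        if self.D.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(self.D, self.D.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.D), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray–Curtis dissimilarity D_jk = Σ|x_j − x_k| / Σ(x_j + x_k)."""
    values = table.values
    sums = values.sum(axis=1)
    if (sums <= 0).sum() >= 2:
        raise ValueError("Bray-Curtis undefined between two all-zero samples")
    D = squareform(pdist(values, metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, D)


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    seed: int | None
    method: str = "sampled"


def _pseudo_f(D2: np.ndarray, masks: list[np.ndarray], n: int) -> float:
    # Anderson's formulation from pairwise squared distances:
    # SS_total = sum_{i<j} d^2 / n ; SS_within = sum_g sum_{i<j in g} d^2 / n_g
    ss_total = D2.sum() / (2.0 * n)
    ss_within = 0.0
    for m in masks:
        ng = int(m.sum())
        ss_within += (m @ D2 @ m) / (2.0 * ng)
    a = len(masks)
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        return np.inf  # perfectly separated groups
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(
    dm: DistanceMatrix,
    labels,
    n_perm: int = 1000,
    seed: int | None = None,
    method: str = "sampled",
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    ``method='sampled'`` draws ``n_perm`` free label permutations with the
    mandatory seed and reports p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    ``method='exhaustive'`` enumerates every distinct assignment of the label
    multiset (identity included) and reports the exact tail fraction.
    """
    labels = np.asarray(labels)
    n = len(dm.sample_ids)
    if labels.shape[0] != n:
        raise ValueError("labels length does not match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    D2 = dm.D**2
    masks = [(labels == u).astype(float) for u in uniq]
    F_obs = _pseudo_f(D2, masks, n)

    if method == "exhaustive":
        assignments = set(itertools.permutations(labels.tolist()))
        hits = 0
        for perm in assignments:
            pl = np.asarray(perm)
            pm = [(pl == u).astype(float) for u in uniq]
            if _pseudo_f(D2, pm, n) >= F_obs - 1e-12:
                hits += 1
        p = hits / len(assignments)
        return PermanovaResult(F_obs, p, len(assignments), seed, "exhaustive")

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for sampled permutations")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        pl = labels[rng.permutation(n)]
        pm = [(pl == u).astype(float) for u in uniq]
        if _pseudo_f(D2, pm, n) >= F_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(F_obs, p, n_perm, seed, "sampled")


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples × retained axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray


def pcoa(dm: DistanceMatrix, k: int = 2, cailliez: bool = False) -> PCoAResult:
    """Classical metric scaling of a dissimilarity matrix.

    Eigen-decomposition of the Gower-centred matrix −½·J D² J.  Axes are
    ordered by eigenvalue; negative eigenvalues are reported but never
    returned as coordinates.  ``cailliez=True`` adds the smallest constant to
    all off-diagonal dissimilarities that renders the matrix Euclidean.
    """
    D = dm.D
    n = D.shape[0]
    if cailliez:
        D = D + _cailliez_constant(D) * (1 - np.eye(n))
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_pos = int((evals > 1e-10).sum())
    if k > n_pos:
        raise ValueError(f"requested {k} axes but only {n_pos} positive eigenvalues")
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    pos_sum = evals[evals > 0].sum()
    return PCoAResult(
        pd.DataFrame(
            coords,
            index=dm.sample_ids,
            columns=[f"PCo{i + 1}" for i in range(k)],
        ),
        evals,
        evals[:k] / pos_sum,
    )


def _cailliez_constant(D: np.ndarray) -> float:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    d1 = -0.5 * J @ (D**2) @ J
    d2 = -0.5 * J @ D @ J
    upper = np.hstack([np.zeros((n, n)), 2 * d1])
    lower = np.hstack([-np.eye(n), -4 * d2])
    eigs = np.linalg.eigvals(np.vstack([upper, lower]))
    return float(max(0.0, np.max(eigs.real)))


# ---------------------------------------------------------------------------
# differential abundance


def diff_abundance(
    table: AbundanceTable,
    labels,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-genus two-group rank-sum tests with permutation-based FDR.

    Returns a DataFrame indexed by genus with group means, the rank-sum
    statistic, the two-sided p-value and the permutation q-value.
    """
    if not table.normalized:
        raise ValueError("diff_abundance expects relative abundances")
    if seed is None:
        raise ValueError("a seed is required for the permutation FDR")
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError("exactly two groups required")
    for u in uniq:
        if (labels == u).sum() < 2:
            raise ValueError(f"group {u!r} has fewer than 2 samples")

    X = table.values
    mask = labels == uniq[0]
    p_obs = ranksum_pvalues(X, labels)
    rng = np.random.default_rng(seed)
    q = permutation_fdr(p_obs, X, labels, n_perm, rng)
    # rank-sum statistic (sum of ranks in the first group)
    ranks = stats.rankdata(X, axis=0)
    W = ranks[mask].sum(axis=0)
    return pd.DataFrame(
        {
            f"mean_{uniq[0]}": X[mask].mean(axis=0),
            f"mean_{uniq[1]}": X[~mask].mean(axis=0),
            "statistic": W,
            "p_value": p_obs,
            "q_value": q,
        },
        index=table.data.columns,
    )


# ---------------------------------------------------------------------------
# cross-compartment structure


@dataclass
class CrossCompartmentResult:
    rho: pd.DataFrame  # oral genera × faecal genera
    p: pd.DataFrame
    n_subjects: int

    def stars(self) -> pd.DataFrame:
        """Display stars at the conventional thresholds (* p<0.05, ** p<0.01)."""
        s = self.p.map(lambda v: "**" if v < 0.01 else "*" if v < 0.05 else "")
        return s


def _paired_subjects(
    oral: AbundanceTable, faecal: AbundanceTable, metadata: pd.DataFrame
) -> list[tuple[str, str, str]]:
    """(subject, oral sample, faecal sample) for subjects with both compartments."""
    by_subject: dict[str, dict[str, str]] = {}
    for sid in list(oral.sample_ids) + list(faecal.sample_ids):
        rec = metadata.loc[sid]
        by_subject.setdefault(rec["subject_id"], {})[rec["compartment"]] = sid
    pairs = []
    for subj in sorted(by_subject):
        comps = by_subject[subj]
        if "oral" in comps and "faecal" in comps:
            if comps["oral"] in oral.data.index and comps["faecal"] in faecal.data.index:
                pairs.append((subj, comps["oral"], comps["faecal"]))
    return pairs


def cross_compartment_correlation(
    oral: AbundanceTable, faecal: AbundanceTable, metadata: pd.DataFrame
) -> CrossCompartmentResult:
    """Spearman rho between every oral genus and every faecal genus.

    Computed over subjects sampled in both compartments; needs >= 3 complete
    pairs.  Degenerate (constant) genera give rho = 0, p = 1.
    """
    pairs = _paired_subjects(oral, faecal, metadata)
    if len(pairs) < 3:
        raise ValueError(f"need >=3 paired subjects, found {len(pairs)}")
    O = oral.data.loc[[p[1] for p in pairs]].to_numpy(dtype=float)
    F = faecal.data.loc[[p[2] for p in pairs]].to_numpy(dtype=float)
    nO = O.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        rho_full, p_full = stats.spearmanr(O, F)
    rho = np.nan_to_num(rho_full[:nO, nO:], nan=0.0)
    p = np.where(np.isnan(p_full[:nO, nO:]), 1.0, p_full[:nO, nO:])
    return CrossCompartmentResult(
        pd.DataFrame(rho, index=oral.genus_ids, columns=faecal.genus_ids),
        pd.DataFrame(p, index=oral.genus_ids, columns=faecal.genus_ids),
        len(pairs),
    )


@dataclass
class VennSummary:
    group: str
    oral_only: int
    faecal_only: int
    shared: int
    per_individual_shared_pct: list[float] = field(default_factory=list)


def shared_genus_analysis(
    oral: AbundanceTable,
    faecal: AbundanceTable,
    metadata: pd.DataFrame,
    presence_threshold: float = 0.0,
) -> tuple[dict[str, VennSummary], float]:
    """Oral/faecal compartmentalization summary per group.

    Pooled Venn counts treat a genus as present in a compartment-group when
    its abundance exceeds ``presence_threshold`` in at least one sample of
    that compartment and group.  Per-individual shared percentage is
    100·|oral_i ∩ faecal_i| / |oral_i ∪ faecal_i| over within-individual
    presences.  The second return value is the two-sided rank-sum p-value
    comparing individual percentages between the two groups (NaN if the
    number of groups differs from two).
    """
    pairs = _paired_subjects(oral, faecal, metadata)
    if not pairs:
        raise ValueError("no subjects with both compartments")
    summaries: dict[str, VennSummary] = {}
    groups = sorted(metadata.loc[[p[1] for p in pairs], "group"].unique())
    for g in groups:
        gpairs = [p for p in pairs if metadata.loc[p[1], "group"] == g]
        o_present: set[str] = set()
        f_present: set[str] = set()
        pcts = []
        for _, o_sid, f_sid in gpairs:
            o_i = {
                gn
                for gn, v in oral.data.loc[o_sid].items()
                if v > presence_threshold
            }
            f_i = {
                gn
                for gn, v in faecal.data.loc[f_sid].items()
                if v > presence_threshold
            }
            if not o_i or not f_i:
                raise ValueError(f"empty compartment for subject pair {o_sid}/{f_sid}")
            o_present |= o_i
            f_present |= f_i
            pcts.append(100.0 * len(o_i & f_i) / len(o_i | f_i))
        summaries[g] = VennSummary(
            group=g,
            oral_only=len(o_present - f_present),
            faecal_only=len(f_present - o_present),
            shared=len(o_present & f_present),
            per_individual_shared_pct=pcts,
        )
    p_between = math.nan
    if len(groups) == 2:
        a = summaries[groups[0]].per_individual_shared_pct
        b = summaries[groups[1]].per_individual_shared_pct
        if np.ptp(a + b) == 0:
            p_between = 1.0
        else:
            p_between = float(
                stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
            )
    return summaries, p_between


def age_diversity_association(
    diversity: pd.DataFrame, metadata: pd.DataFrame, group: str
) -> tuple[float, float, bool]:
    """Spearman correlation of the Shannon index with age within one group.

    Returns (rho, p, tied); a constant Shannon vector is degenerate and is
    reported as rho = 0, p = 1, tied = True.
    """
    samples = [
        s
        for s in diversity.index
        if s in metadata.index and metadata.loc[s, "group"] == group
    ]
    if len(samples) < 4:
        raise ValueError(f"need >=4 samples with age in group {group!r}")
    ages = metadata.loc[samples, "age"].to_numpy(dtype=float)
    if np.isnan(ages).any():
        missing = [s for s, a in zip(samples, ages) if np.isnan(a)]
        raise ValueError(f"missing ages for samples: {missing}")
    H = diversity.loc[samples, "shannon"].to_numpy(dtype=float)
    tied = bool(np.ptp(H) == 0 or np.ptp(ages) == 0)
    rho, p = spearman_with_p(H, ages)
    return rho, p, tied


# ---------------------------------------------------------------------------
# qPCR


def delta_delta_ct(
    ct_target: pd.Series,
    ct_reference: pd.Series,
    group_labels: pd.Series,
    baseline_group: str,
) -> pd.Series:
    """ΔΔCt relative quantification: level = 2^(−ΔΔCt).

    ΔCt = Ct_target − Ct_reference per sample; ΔΔCt subtracts the mean ΔCt
    of the baseline group.  Missing Ct values are rejected.
    """
    ct_target, ct_reference = ct_target.align(ct_reference, join="outer")
    if ct_target.isna().any() or ct_reference.isna().any():
        bad = ct_target.index[ct_target.isna() | ct_reference.isna()].tolist()
        raise ValueError(f"missing Ct values for samples: {bad}")
    delta = ct_target - ct_reference
    base = delta[group_labels.loc[delta.index] == baseline_group]
    if base.empty:
        raise ValueError(f"baseline group {baseline_group!r} is empty")
    ddct = delta - base.mean()
    return np.power(2.0, -ddct)
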