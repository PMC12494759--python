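"""Pre/post session matching and plasticity statistics.

Cells are matched across sessions within each field of view by a composite
similarity score (mask overlap, segment-correlation-matrix similarity,
spike-template correlation, firing-rate similarity) maximized by optimal
one-to-one assignment; unconfident pairs are excluded, exactly as cells the
experimenter cannot re-identify are excluded.  Plasticity is quantified per
cell as the change in mean IPSP amplitude and as the log amplitude ratio
ln(post/pre); groups are compared with a linear mixed-effects model with
random intercepts for animal and for FOV nested in animal (delegated to
statsmodels, two-sided Wald test on the group coefficient).  Spatial
correlation of plasticity between neighboring cells is tested against a
within-mouse shuffle null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import linregress, mannwhitneyu, wilcoxon

__all__ = [
    "CellRecord",
    "SessionRecord",
    "MatchedPair",
    "match_cells",
    "PlasticityComparison",
    "compare_pre_post",
    "GroupDifference",
    "group_difference",
    "NeighborCorrelation",
    "neighbor_correlation",
    "CvChangeResult",
    "cv_change_test",
]


@dataclass
class CellRecord:
    """Per-cell summary of one imaging session."""

    cell_id: str
    fov_id: str
    mouse_id: str
    mask: np.ndarray | None = None  # (H, W) weight image
    corr_matrix: np.ndarray | None = None  # segment-wise correlation matrix
    spike_template: np.ndarray | None = None  # mean spike waveform
    firing_rate_hz: float = float("nan")
    ipsp_trial_amplitudes: np.ndarray = field(default_factory=lambda: np.zeros(0))
    segment_map: np.ndarray = field(default_factory=lambda: np.zeros(0))
    cv: float = float("nan")

    @property
    def mean_amplitude(self) -> float:
        a = self.ipsp_trial_amplitudes
        return float(np.nanmean(a)) if len(a) else float("nan")


@dataclass
class SessionRecord:
    cells: list[CellRecord]

    def __post_init__(self) -> None:
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            raise ValueError("cell ids must be unique within a session")

    def by_fov(self) -> dict[str, list[CellRecord]]:
        out: dict[str, list[CellRecord]] = {}
        for c in self.cells:
            out.setdefault(c.fov_id, []).append(c)
        return out


@dataclass
class MatchedPair:
    pre: CellRecord
    post: CellRecord
    score: float


def _weighted_jaccard(a: np.ndarray | None, b: np.ndarray | None) -> float:
    if a is None or b is None or a.shape != b.shape:
        return 0.5
    num = np.minimum(a, b).sum()
    den = np.maximum(a, b).sum()
    return float(num / den) if den > 0 else 0.0


def _corr_similarity(a: np.ndarray | None, b: np.ndarray | None) -> float:
    if a is None or b is None:
        return 0.5
    n = min(a.shape[0], b.shape[0])
    if n < 2:
        return 0.5
    iu = np.triu_indices(n, k=1)
    x, y = a[:n, :n][iu], b[:n, :n][iu]
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return 0.5
    r = float(np.corrcoef(x, y)[0, 1])
    return (r + 1) / 2


def _template_similarity(a: np.ndarray | None, b: np.ndarray | None) -> float:
    if a is None or b is None or len(a) < 3 or len(b) < 3:
        return 0.5
    n = max(len(a), len(b))
    ai = np.interp(np.linspace(0, 1, n), np.linspace(0, 1, len(a)), a)
    bi = np.interp(np.linspace(0, 1, n), np.linspace(0, 1, len(b)), b)
    if np.std(ai) == 0 or np.std(bi) == 0:
        return 0.5
    r = float(np.corrcoef(ai, bi)[0, 1])
    return (r + 1) / 2


def _rate_similarity(a: float, b: float) -> float:
    if not (np.isfinite(a) and np.isfinite(b)):
        return 0.5
    m = max(abs(a), abs(b), 1e-12)
    return float(np.clip(1.0 - abs(a - b) / m, 0.0, 1.0))


def match_score(pre: CellRecord, post: CellRecord, weights=(0.4, 0.3, 0.2, 0.1)) -> float:
    """Composite similarity in [0, 1]: mask overlap, correlation-matrix
    similarity, spike-template correlation, firing-rate similarity."""
    parts = (
        _weighted_jaccard(pre.mask, post.mask),
        _corr_similarity(pre.corr_matrix, post.corr_matrix),
        _template_similarity(pre.spike_template, post.spike_template),
        _rate_similarity(pre.firing_rate_hz, post.firing_rate_hz),
    )
    return float(np.dot(weights, parts))


def match_cells(
    pre: SessionRecord,
    post: SessionRecord,
    threshold: float = 0.6,
    weights: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1),
    greedy_above: int = 20,
) -> list[MatchedPair]:
    """Optimal one-to-one cell matching within each shared FOV.

    Pairs scoring below ``threshold`` are rejected (cells that cannot be
    confidently re-identified are excluded from further analysis).  FOVs
    with more than ``greedy_above`` cells fall back to greedy matching.
    """
    if not pre.cells or not post.cells:
        raise ValueError("sessions must be non-empty")
    pre_fov, post_fov = pre.by_fov(), post.by_fov()
    pairs: list[MatchedPair] = []
    for fov in sorted(set(pre_fov) & set(post_fov)):
        a, b = pre_fov[fov], post_fov[fov]
        score = np.array([[match_score(p, q, weights) for q in b] for p in a])
        if max(len(a), len(b)) > greedy_above:
            used_r, used_c = set(), set()
            for idx in np.argsort(score, axis=None)[::-1]:
                r, c = divmod(int(idx), score.shape[1])
                if r in used_r or c in used_c:
                    continue
                used_r.add(r)
                used_c.add(c)
                if score[r, c] >= threshold:
                    pairs.append(MatchedPair(a[r], b[c], float(score[r, c])))
        else:
            rows, cols = linear_sum_assignment(-score)
            for r, c in zip(rows, cols):
                if score[r, c] >= threshold:
                    pairs.append(MatchedPair(a[r], b[c], float(score[r, c])))
    return pairs


@dataclass
class PlasticityComparison:
    pre_means: np.ndarray
    post_means: np.ndarray
    delta: np.ndarray
    log_ratios: np.ndarray  # only cells with positive pre and post means
    log_ratio_cells: np.ndarray  # indices of the cells entering log_ratios
    statistic: float
    p_value: float
    n: int


def compare_pre_post(
    pre_amplitudes: list[np.ndarray] | np.ndarray,
    post_amplitudes: list[np.ndarray] | np.ndarray,
) -> PlasticityComparison:
    """Paired two-sided Wilcoxon signed-rank test on per-cell mean amplitudes.

    Inputs are per-cell trial amplitude arrays (or already-averaged scalars).
    The test is exact for n <= 25 without zeros/ties, otherwise the midrank
    normal approximation.  Log ratios ln(post/pre) are computed for cells
    with positive means on both sides; other cells stay in the paired delta.
    """
    pre_m = np.array([np.nanmean(np.atleast_1d(a)) for a in pre_amplitudes], dtype=float)
    post_m = np.array([np.nanmean(np.atleast_1d(a)) for a in post_amplitudes], dtype=float)
    if len(pre_m) != len(post_m):
        raise ValueError("pre and post must have the same number of cells")
    n = len(pre_m)
    if n < 6:
        raise ValueError("need at least 6 matched cells")
    d = post_m - pre_m
    if np.all(d == 0):
        stat, p = float(np.sum(np.arange(1, n + 1)) / 2), 1.0
    else:
        method = "exact" if (n <= 25 and not np.any(d == 0)) else "approx"
        try:
            res = wilcoxon(post_m, pre_m, alternative="two-sided", method=method)
        except ValueError:
            res = wilcoxon(post_m, pre_m, alternative="two-sided", method="approx",
                           zero_method="zsplit")
        stat, p = float(res.statistic), float(res.pvalue)
    ok = (pre_m > 0) & (post_m > 0)
    return PlasticityComparison(
        pre_means=pre_m,
        post_means=post_m,
        delta=d,
        log_ratios=np.log(post_m[ok] / pre_m[ok]),
        log_ratio_cells=np.flatnonzero(ok),
        statistic=stat,
        p_value=p,
        n=n,
    )


@dataclass
class GroupDifference:
    estimate: float
    p_value: float
    method: str  # "mixed" or "cluster_robust"
    flagged: bool
    n: int


def group_difference(
    values: np.ndarray,
    groups: np.ndarray,
    mouse_ids: np.ndarray,
    fov_ids: np.ndarray,
) -> GroupDifference:
    """Two-group comparison via a linear mixed-effects model.

    Fixed effect: group; random intercepts: animal, and FOV nested in
    animal.  Delegates to ``statsmodels`` MixedLM; the reported p is the
    two-sided Wald t-test on the group coefficient, referred to a t
    distribution with between-cluster degrees of freedom at the finest
    grouping level (number of FOVs minus the number of fixed effects) - a
    small-sample correction of the asymptotic z-test.  A singular
    random-effects fit falls back to an OLS with cluster-robust (by animal)
    errors, flagged.
    """
    import statsmodels.formula.api as smf
    from scipy.stats import t as tdist

    df = pd.DataFrame(
        {
            "y": np.asarray(values, dtype=float),
            "group": np.asarray(groups).astype(str),
            "mouse": np.asarray(mouse_ids).astype(str),
            "fov": [f"{m}:{f}" for m, f in zip(mouse_ids, fov_ids)],
        }
    )
    levels = sorted(df["group"].unique())
    if len(levels) != 2:
        raise ValueError("need exactly 2 groups")
    if df["mouse"].nunique() < 2:
        raise ValueError("need at least 2 animals")
    coef = f"C(group)[T.{levels[1]}]"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm(
                "y ~ C(group)", df, groups=df["mouse"], re_formula="1",
                vc_formula={"fov": "0 + C(fov)"},
            )
            res = md.fit(reml=True)
        est = float(res.params[coef])
        tval = est / float(res.bse[coef])
        dof = max(df["fov"].nunique() - 2, 1)
        p = float(2 * tdist.sf(abs(tval), dof))
        if np.isfinite(p):
            return GroupDifference(est, p, "mixed", flagged=False, n=len(df))
    except Exception:
        pass
    ols = smf.ols("y ~ C(group)", df).fit(
        cov_type="cluster", cov_kwds={"groups": df["mouse"]}
    )
    return GroupDifference(
        float(ols.params[coef]), float(ols.pvalues[coef]), "cluster_robust",
        flagged=True, n=len(df),
    )


@dataclass
class NeighborCorrelation:
    r: float
    p_value: float  # two-sided Wald test of the regression slope
    percentile: float  # of the observed r in the shuffle null, in [0, 1]
    null: np.ndarray
    n_pairs: int


def neighbor_correlation(
    features: np.ndarray,
    fov_ids: np.ndarray,
    mouse_ids: np.ndarray,
    n_shuffles: int = 500,
    seed: int = 0,
) -> NeighborCorrelation:
    """Correlation of a feature between neighboring cells (same FOV).

    All ordered within-FOV pairs (i, j), i != j, enter symmetrically.  The
    null distribution shuffles cell identities across FOVs *within each
    mouse* (preserving per-mouse cell counts and the pairing topology) and
    recomputes r; the observed r's mid-percentile in that null is reported.
    """
    f = np.asarray(features, dtype=float)
    fov = np.asarray(fov_ids)
    mouse = np.asarray(mouse_ids)

    def pair_idx() -> tuple[np.ndarray, np.ndarray]:
        ii, jj = [], []
        for v in np.unique(fov):
            members = np.flatnonzero(fov == v)
            for i in members:
                for j in members:
                    if i != j:
                        ii.append(i)
                        jj.append(j)
        return np.asarray(ii), np.asarray(jj)

    ii, jj = pair_idx()
    if len(ii) < 6:  # 6 ordered = 3 unordered pairs
        raise ValueError("need at least 3 within-FOV cell pairs")

    def corr(vals: np.ndarray) -> float:
        return float(np.corrcoef(vals[ii], vals[jj])[0, 1])

    r_obs = corr(f)
    p = float(linregress(f[ii], f[jj]).pvalue)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 505]))
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = f.copy()
        for m in np.unique(mouse):
            members = np.flatnonzero(mouse == m)
            perm[members] = perm[rng.permutation(members)]
        null[s] = corr(perm)
    pct = (np.sum(null < r_obs) + 0.5 * np.sum(null == r_obs)) / n_shuffles
    return NeighborCorrelation(r_obs, p, float(pct), null, n_pairs=len(ii) // 2)


@dataclass
class CvChangeResult:
    delta_cv: np.ndarray  # per retained cell
    groups: np.ndarray
    excluded: np.ndarray  # indices with undefined CV
    statistic: float
    p_value: float


def cv_change_test(
    pre_cvs: np.ndarray,
    post_cvs: np.ndarray,
    groups: np.ndarray,
) -> CvChangeResult:
    """Per-cell CV change, compared between groups by Mann-Whitney U.

    ``delta CV = CV_post - CV_pre``; cells with undefined CV (zero-mean
    response map) are excluded and logged in ``excluded``.
    """
    pre = np.asarray(pre_cvs, dtype=float)
    post = np.asarray(post_cvs, dtype=float)
    grp = np.asarray(groups).astype(str)
    if not (len(pre) == len(post) == len(grp)):
        raise ValueError("pre, post and groups must be aligned")
    ok = np.isfinite(pre) & np.isfinite(post)
    excluded = np.flatnonzero(~ok)
    delta = post[ok] - pre[ok]
    grp = grp[ok]
    levels = sorted(np.unique(grp))
    if len(levels) != 2:
        raise ValueError("need exactly 2 non-empty groups")
    a = delta[grp == levels[0]]
    b = delta[grp == levels[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("one group is empty")
    if np.all(delta == delta[0]):
        return CvChangeResult(delta, grp, excluded, float(len(a) * len(b) / 2), 1.0)
    res = mannwhitneyu(a, b, alternative="two-sided")
    return CvChangeResult(delta, grp, excluded, float(res.statistic), float(res.pvalue))
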