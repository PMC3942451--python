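"""Permutation-based community statistics and effect-size analysis.

Given a family × sample (or probe × sample) abundance matrix, this module
provides the standard distance-based battery for comparing sample groups:

* **Bray-Curtis** dissimilarity, d_ij = Σ|x_i − x_j| / Σ(x_i + x_j);
* **ANOSIM** — rank-based R = (mean between-group rank − mean within-group
  rank) / (M/2), M = N(N−1)/2, mid-ranks for ties;
* **adonis / PERMANOVA** — pseudo-F from the distance-based sum-of-squares
  decomposition SS_T = Σd²/N, SS_W = Σ_g Σ_{i<j∈g} d²/n_g;
* **MRPP** — weighted mean within-group distance δ with chance-corrected
  A = 1 − δ/E(δ), E(δ) the mean of all pairwise distances;
* **CA/DCA** ordination (reciprocal-averaging correspondence analysis,
  optional segment-wise detrending of higher axes);
* **response ratios** — ln(mean_treatment/mean_control) effect sizes with
  delta-method standard errors and normal-quantile confidence intervals;
* **array-vs-NGS comparison** — Pearson correlation of family profiles
  measured by the array and by shotgun sequencing.

Permutation p-values follow p = (1 + #{permuted statistic as-or-more
extreme}) / (1 + n_permutations); when the number of distinct label
arrangements is at most 10,000 the full enumeration is used instead and
p is the exact fraction of arrangements as-or-more extreme.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio import DistanceMatrix

from .array_preprocess import GeneFamilyProfile

EXHAUSTIVE_MAX = 10_000


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _as_samples_matrix(profile) -> tuple[np.ndarray, list[str]]:
    """(samples × features array, sample ids) from a profile-like input."""
    if isinstance(profile, GeneFamilyProfile):
        df = profile.values
    elif isinstance(profile, pd.DataFrame):
        df = profile
    else:
        arr = np.asarray(profile, float)
        return arr, [f"S{i}" for i in range(arr.shape[0])]
    return df.values.T.astype(float), [str(c) for c in df.columns]


def bray_curtis(profile) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples (columns of the profile).

    Inputs must be non-negative; a pair of all-zero samples gets distance 0
    with a warning.
    """
    x, ids = _as_samples_matrix(profile)
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires non-negative abundances")
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    d = np.zeros((n, n))
    for i in range(n):
        num = np.abs(x[i] - x[i + 1 :]).sum(axis=1)
        den = (x[i] + x[i + 1 :]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        if (den == 0).any():
            warnings.warn("sample pair with zero total abundance; distance set to 0")
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
    return DistanceMatrix(d, ids=ids)


def _matrix_and_labels(
    d: DistanceMatrix | np.ndarray, groups: Mapping[str, str] | Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(d, DistanceMatrix):
        mat = d.data
        labels = np.array([groups[i] for i in d.ids]) if isinstance(groups, Mapping) \
            else np.asarray(list(groups))
    else:
        mat = np.asarray(d, float)
        labels = np.asarray(list(groups))
    if mat.shape[0] != labels.size:
        raise ValueError("label count does not match distance matrix size")
    return mat, labels


@dataclass
class PermutationResult:
    statistic: str  # R, F, or delta
    observed: float
    p_value: float
    n_permutations: int  # distinct arrangements when exhaustive
    exhaustive: bool
    seed: int | None
    auxiliary: dict = field(default_factory=dict)


def _multiset_permutations(items: Sequence) -> Iterator[np.ndarray]:
    """Distinct permutations of a label multiset, lexicographic order."""
    counter = Counter(items)
    keys = sorted(counter)
    n = len(items)
    perm = [None] * n

    def rec(depth: int):
        if depth == n:
            yield np.array(perm)
            return
        for k in keys:
            if counter[k]:
                counter[k] -= 1
                perm[depth] = k
                yield from rec(depth + 1)
                counter[k] += 1

    yield from rec(0)


def _n_arrangements(labels: np.ndarray) -> int:
    total = math.factorial(labels.size)
    for _, c in Counter(labels.tolist()).items():
        total //= math.factorial(c)
    return total


def _perm_label_matrix(
    labels: np.ndarray, n_perm: int, seed: int | None
) -> tuple[np.ndarray, bool]:
    """(P × N integer label matrix, exhaustive flag)."""
    n_arr = _n_arrangements(labels)
    if n_arr <= EXHAUSTIVE_MAX:
        perms = np.array([_codes_of(p, labels) for p in _multiset_permutations(labels)])
        return perms, True
    codes = _codes_of(labels, labels)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(codes) for _ in range(n_perm)])
    return perms, False


def _codes_of(perm_labels: np.ndarray, ref_labels: np.ndarray) -> np.ndarray:
    uniq = {lab: i for i, lab in enumerate(pd.unique(ref_labels))}
    return np.array([uniq[l] for l in perm_labels])


def _group_stats_engine(
    mat: np.ndarray,
    labels: np.ndarray,
    statistic,
    n_perm: int,
    seed: int | None,
    larger_is_extreme: bool,
):
    """Shared machinery: observed statistic + permutation/exhaustive p."""
    n = mat.shape[0]
    iu, ju = np.triu_indices(n, 1)
    codes = _codes_of(labels, labels)
    observed = statistic(mat, iu, ju, codes[None, :])[0]

    perms, exhaustive = _perm_label_matrix(labels, n_perm, seed)
    stats_perm = statistic(mat, iu, ju, perms)
    tol = 1e-12
    if larger_is_extreme:
        count = int((stats_perm >= observed - tol).sum())
    else:
        count = int((stats_perm <= observed + tol).sum())
    if exhaustive:
        p = count / len(perms)
        n_eff = len(perms)
    else:
        p = (1 + count) / (1 + n_perm)
        n_eff = n_perm
    return observed, p, n_eff, exhaustive


def _check_groups(labels: np.ndarray, min_size: int = 2) -> None:
    counts = Counter(labels.tolist())
    if len(counts) < 2:
        raise ValueError("need at least two groups")
    small = [g for g, c in counts.items() if c < min_size]
    if small:
        raise ValueError(f"groups with fewer than {min_size} samples: {small}")


def anosim(
    d: DistanceMatrix | np.ndarray,
    groups: Mapping[str, str] | Sequence[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> PermutationResult:
    """Analysis of similarities (rank-based R with permutation p-value)."""
    mat, labels = _matrix_and_labels(d, groups)
    _check_groups(labels)
    n = mat.shape[0]
    iu, ju = np.triu_indices(n, 1)
    ranks = sps.rankdata(mat[iu, ju])
    m_half = (n * (n - 1) / 2) / 2

    def stat(mat_, i, j, perms):
        within = perms[:, i] == perms[:, j]
        between = ~within
        rw = (within * ranks).sum(axis=1) / within.sum(axis=1)
        rb = (between * ranks).sum(axis=1) / between.sum(axis=1)
        return (rb - rw) / m_half

    obs, p, n_eff, exh = _group_stats_engine(mat, labels, stat, n_perm, seed, True)
    return PermutationResult("R", float(obs), p, n_eff, exh, seed)


def adonis(
    d: DistanceMatrix | np.ndarray,
    groups: Mapping[str, str] | Sequence[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> PermutationResult:
    """Permutational multivariate analysis of variance (one-way pseudo-F)."""
    mat, labels = _matrix_and_labels(d, groups)
    _check_groups(labels, min_size=1)
    n = mat.shape[0]
    a = len(set(labels.tolist()))
    if n <= a:
        raise ValueError("need more samples than groups")
    iu, ju = np.triu_indices(n, 1)
    d2 = mat[iu, ju] ** 2
    ss_t = d2.sum() / n
    group_sizes = np.bincount(_codes_of(labels, labels))

    def stat(mat_, i, j, perms):
        ss_w = np.zeros(perms.shape[0])
        for g, n_g in enumerate(group_sizes):
            ing = perms == g
            pair = ing[:, i] & ing[:, j]
            ss_w += (pair * d2).sum(axis=1) / n_g
        num = (ss_t - ss_w) / (a - 1)
        with np.errstate(divide="ignore"):
            return np.where(ss_w > 0, num / (ss_w / (n - a)), np.inf)

    obs, p, n_eff, exh = _group_stats_engine(mat, labels, stat, n_perm, seed, True)
    # recompute aux for the observed labelling
    codes = _codes_of(labels, labels)[None, :]
    ss_w = 0.0
    for g, n_g in enumerate(group_sizes):
        ing = codes == g
        pair = ing[:, iu] & ing[:, ju]
        ss_w += float((pair * d2).sum()) / n_g
    if ss_w == 0:
        warnings.warn("zero within-group sum of squares; F is infinite")
    r2 = (ss_t - ss_w) / ss_t if ss_t > 0 else float("nan")
    return PermutationResult(
        "F", float(obs), p, n_eff, exh, seed,
        auxiliary={"R2": float(r2), "SS_total": float(ss_t), "SS_within": float(ss_w)},
    )


def mrpp(
    d: DistanceMatrix | np.ndarray,
    groups: Mapping[str, str] | Sequence[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> PermutationResult:
    """Multi-response permutation procedure (δ, chance-corrected A).

    Small δ means tight groups, so the permutation p-value counts permuted
    δ at or below the observed one.  E(δ) under permutation equals the
    mean of all pairwise distances (group weights n_g/N sum to one).
    """
    mat, labels = _matrix_and_labels(d, groups)
    _check_groups(labels)
    n = mat.shape[0]
    iu, ju = np.triu_indices(n, 1)
    dist = mat[iu, ju]
    group_sizes = np.bincount(_codes_of(labels, labels))
    pair_counts = group_sizes * (group_sizes - 1) // 2

    def stat(mat_, i, j, perms):
        delta = np.zeros(perms.shape[0])
        for g, n_g in enumerate(group_sizes):
            ing = perms == g
            pair = ing[:, i] & ing[:, j]
            delta += (n_g / n) * (pair * dist).sum(axis=1) / pair_counts[g]
        return delta

    obs, p, n_eff, exh = _group_stats_engine(mat, labels, stat, n_perm, seed, False)
    expected = dist.mean()
    a_stat = 1.0 - obs / expected if expected > 0 else 0.0
    return PermutationResult(
        "delta", float(obs), p, n_eff, exh, seed,
        auxiliary={"A": float(a_stat), "expected_delta": float(expected)},
    )


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

def ordinate(
    profile, method: str = "ca", segments: int = 26, n_axes: int = 2
) -> pd.DataFrame:
    """Correspondence-analysis sample scores, optionally detrended (DCA).

    CA is computed by singular value decomposition of the chi-square
    standardized matrix (equivalent to reciprocal averaging); sample scores
    are column principal coordinates ordered by eigenvalue, with the sign
    convention that each axis's first non-zero score is positive.  DCA
    detrends every axis beyond the first by segment-wise centering against
    axis 1 (default 26 segments; nonlinear rescaling is not applied).
    """
    if isinstance(profile, GeneFamilyProfile):
        df = profile.values
    elif isinstance(profile, pd.DataFrame):
        df = profile
    else:
        df = pd.DataFrame(np.asarray(profile, float))
    x = df.values.astype(float)
    if (x < 0).any():
        raise ValueError("ordination requires a non-negative matrix")
    keep_rows = x.sum(axis=1) > 0
    keep_cols = x.sum(axis=0) > 0
    x = x[keep_rows][:, keep_cols]
    ids = [str(c) for c in df.columns[keep_cols]]
    if x.size == 0 or x.sum() == 0:
        raise ValueError("degenerate matrix: nothing to ordinate")

    p = x / x.sum()
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    _, sv, vt = np.linalg.svd(s, full_matrices=False)
    tol = 1e-10
    nz = sv > tol
    sv, vt = sv[nz], vt[nz]
    if sv.size == 0:
        raise ValueError("degenerate matrix: rank 0 after standardization")
    k = min(n_axes, sv.size)
    scores = (vt[:k] / np.sqrt(c)) * sv[:k, None]  # column principal coords
    scores = scores.T  # samples × axes
    for ax in range(scores.shape[1]):
        col = scores[:, ax]
        nzi = np.nonzero(np.abs(col) > tol)[0]
        if nzi.size and col[nzi[0]] < 0:
            scores[:, ax] = -col

    if method == "dca" and scores.shape[1] > 1:
        ax1 = scores[:, 0]
        edges = np.linspace(ax1.min(), ax1.max() + 1e-12, segments + 1)
        seg = np.clip(np.searchsorted(edges, ax1, side="right") - 1, 0, segments - 1)
        for ax in range(1, scores.shape[1]):
            for g in np.unique(seg):
                m = seg == g
                scores[m, ax] -= scores[m, ax].mean()
    elif method not in ("ca", "dca"):
        raise ValueError(f"unknown ordination method {method!r}")

    cols = [f"axis{i+1}" for i in range(scores.shape[1])]
    out = pd.DataFrame(scores, index=ids, columns=cols)
    out.attrs["eigenvalues"] = (sv[:k] ** 2).tolist()
    return out


# ---------------------------------------------------------------------------
# response ratios
# ---------------------------------------------------------------------------

@dataclass
class ResponseRatio:
    name: str
    rr: float  # ln(mean_treatment / mean_control)
    se: float
    ci_low: float
    ci_high: float
    n_treatment: int
    n_control: int
    significant: bool
    defined: bool = True


def response_ratio(
    profile,
    groups: Mapping[str, str] | pd.Series,
    treatment: str,
    control: str,
    confidence: float = 95.0,
) -> list[ResponseRatio]:
    """Log response ratio per family/category row with normal-quantile CI.

    RR = ln(x̄_t/x̄_c), SE = sqrt(s_t²/(n_t·x̄_t²) + s_c²/(n_c·x̄_c²))
    (delta method, sample variances), CI = RR ± z·SE; a row is significant
    when the CI excludes 0.  A zero group mean leaves RR undefined for that
    row (reported with ``defined=False``).
    """
    df = profile.values if isinstance(profile, GeneFamilyProfile) else pd.DataFrame(profile)
    gs = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    t_cols = [s for s in df.columns if gs.get(s) == treatment]
    c_cols = [s for s in df.columns if gs.get(s) == control]
    if len(t_cols) < 2 or len(c_cols) < 2:
        raise ValueError("both groups need at least two samples")
    z = sps.norm.ppf(0.5 + confidence / 200.0)
    out = []
    for name, row in df.iterrows():
        xt = row[t_cols].astype(float).values
        xc = row[c_cols].astype(float).values
        mt, mc = xt.mean(), xc.mean()
        if mt <= 0 or mc <= 0:
            out.append(ResponseRatio(str(name), math.nan, math.nan, math.nan,
                                     math.nan, len(xt), len(xc), False, defined=False))
            continue
        rr = math.log(mt / mc)
        st2 = xt.var(ddof=1)
        sc2 = xc.var(ddof=1)
        se = math.sqrt(st2 / (len(xt) * mt**2) + sc2 / (len(xc) * mc**2))
        lo, hi = rr - z * se, rr + z * se
        out.append(ResponseRatio(str(name), rr, se, lo, hi, len(xt), len(xc),
                                 significant=not (lo <= 0.0 <= hi)))
    return out


# ---------------------------------------------------------------------------
# array vs NGS comparison
# ---------------------------------------------------------------------------

@dataclass
class NGSComparison:
    pooled_r: float
    pooled_p: float
    n_shared: int
    per_family: pd.DataFrame  # family, r, p, significant
    n_significant: int
    detection_floor: float  # min NGS rel. abundance among array-detected families
    dropped: list[str]


def compare_to_ngs(
    array: GeneFamilyProfile,
    ngs: GeneFamilyProfile,
    alpha: float = 0.05,
    mode: str = "pooled",
) -> NGSComparison:
    """Pearson correlation of array and shotgun-sequencing family profiles.

    Pooled mode averages each profile over its samples and correlates the
    two family vectors; per-family mode correlates across shared samples
    for each family.  Also reports the minimum NGS relative abundance among
    families the array detected (non-zero signal) — the detection floor.
    """
    a, g = array.values, ngs.values
    shared = sorted(set(a.index) & set(g.index))
    dropped = sorted((set(a.index) | set(g.index)) - set(shared))
    if len(shared) < 3:
        raise ValueError("need at least three shared gene families")
    a, g = a.loc[shared], g.loc[shared]

    a_vec = a.mean(axis=1)
    g_vec = g.mean(axis=1)
    pooled_r, pooled_p = sps.pearsonr(a_vec, g_vec)

    rows = []
    if mode == "per_family":
        shared_samples = sorted(set(a.columns) & set(g.columns))
        if len(shared_samples) < 3:
            raise ValueError("per-family mode needs at least three shared samples")
        for fam in shared:
            xa = a.loc[fam, shared_samples].astype(float)
            xg = g.loc[fam, shared_samples].astype(float)
            if xa.std() == 0 or xg.std() == 0:
                rows.append((fam, math.nan, math.nan, False))
                continue
            r, p = sps.pearsonr(xa, xg)
            rows.append((fam, float(r), float(p), bool(p <= alpha)))
    elif mode != "pooled":
        raise ValueError(f"unknown mode {mode!r}")
    per_family = pd.DataFrame(rows, columns=["family", "r", "p", "significant"])
    detected = a_vec > 0
    floor = float(g_vec[detected].min()) if detected.any() else math.nan
    return NGSComparison(
        pooled_r=float(pooled_r), pooled_p=float(pooled_p), n_shared=len(shared),
        per_family=per_family,
        n_significant=int(per_family["significant"].sum()) if rows else 0,
        detection_floor=floor, dropped=dropped,
    )
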