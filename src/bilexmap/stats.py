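"""Semantic-convergence analysis battery over empirical and simulated naming.

The pipeline mirrors the standard naming-norm analyses:

1. name-distribution tables (objects x names, counts or simulated agreements);
2. similarity profiles — all n(n-1)/2 pairwise Pearson correlations between
   objects' name distributions within a group;
3. group comparison — Pearson correlation between two groups' profiles,
   Fisher r-to-z transformed (z = arctanh r) and compared across group pairs
   with the two-sample statistic Z = (z1 - z2) / sqrt(1/(n1-3) + 1/(n2-3));
4. category centers — activation-weighted mean (boundary-dependent) and
   median (boundary-independent) of member BMU coordinates, plus the
   indirect/direct distance ratio between monolingual and bilingual centers;
5. boundary complexity — forward-stepwise discriminant analysis counting the
   features needed to separate two categories (Wilks' lambda tests);
6. outliers — members lying closer to another category's center than their own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dataset import NamingDataset
from .som import neighborhood_field
from .trainer import MAP_PHONOLOGICAL, MAP_SEMANTIC, ModelState

__all__ = [
    "NameDistributionTable",
    "SimilarityProfile",
    "GroupCorrelation",
    "CategoryGeometry",
    "DFAResult",
    "build_distribution_table",
    "simulated_distribution_table",
    "similarity_profile",
    "fisher_z",
    "fisher_z_inverse",
    "profile_correlation",
    "compare_group_correlations",
    "typicality_activation",
    "typicality_correlation",
    "category_geometry",
    "indirect_direct_ratio",
    "stepwise_dfa",
    "outlier_proportions",
]


# --------------------------------------------------------------------------
# distribution tables and similarity profiles
# --------------------------------------------------------------------------

@dataclass
class NameDistributionTable:
    """Objects x names matrix of response counts (or simulated agreements)."""

    group: str
    table: pd.DataFrame  # index: objects, columns: the group's name inventory

    @property
    def empty_objects(self) -> list[str]:
        zero = self.table.sum(axis=1) == 0
        return [str(o) for o in self.table.index[zero]]


@dataclass
class SimilarityProfile:
    """All pairwise Pearson correlations between objects' name distributions.

    Entries follow the row-major upper triangle of the object x object
    correlation matrix; undefined correlations (a constant distribution) are
    stored as NaN and counted in ``n_excluded``.
    """

    group: str
    values: np.ndarray
    n_objects: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.n_objects
        if self.values.size != n * (n - 1) // 2:
            raise ValueError("profile length must be n(n-1)/2")

    @property
    def n_excluded(self) -> int:
        return int(np.isnan(self.values).sum())


@dataclass(frozen=True)
class GroupCorrelation:
    """A correlation with its Fisher transform and sample size."""

    r: float
    n: int

    @property
    def z(self) -> float:
        return fisher_z(self.r)


def build_distribution_table(
    dataset: NamingDataset, group: str, language: str
) -> NameDistributionTable:
    """Raw response counts per object over the language's full name inventory."""
    sub = dataset.responses[
        (dataset.responses["group"] == group)
        & (dataset.responses["language"] == language)
    ]
    known = set(dataset.words(language))
    unknown = set(sub["name"].astype(str)) - known
    if unknown:
        raise ValueError(f"unknown names in responses: {sorted(unknown)[:5]}")
    table = (
        sub.pivot_table(index="object", columns="name", values="count",
                        aggfunc="sum", fill_value=0.0)
        .reindex(index=dataset.object_ids, fill_value=0.0)
        .reindex(columns=dataset.words(language), fill_value=0.0)
        .astype(float)
    )
    return NameDistributionTable(group=f"{group}/{language}", table=table)


def simulated_distribution_table(
    model: ModelState, language: str
) -> NameDistributionTable:
    """Simulated name agreements arranged like a distribution table."""
    from .production import simulated_distribution

    mat = simulated_distribution(model, language)
    table = pd.DataFrame(mat, index=model.object_ids,
                         columns=model.words_of(language))
    return NameDistributionTable(
        group=f"model:{model.config.condition}/{language}", table=table
    )


def similarity_profile(table: NameDistributionTable) -> SimilarityProfile:
    """Pairwise Pearson correlations between object rows, upper triangle order."""
    mat = table.table.to_numpy(dtype=float)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least two objects")
    sd = mat.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat)
    constant = sd == 0
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    iu = np.triu_indices(n, k=1)
    return SimilarityProfile(group=table.group, values=corr[iu], n_objects=n)


# --------------------------------------------------------------------------
# Fisher r-to-z machinery
# --------------------------------------------------------------------------

def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Variance-stabilizing transform z = 0.5 ln((1+r)/(1-r)) = arctanh r."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("Fisher transform undefined for |r| >= 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def fisher_z_inverse(z: float | np.ndarray) -> float | np.ndarray:
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def profile_correlation(
    profile1: SimilarityProfile, profile2: SimilarityProfile
) -> GroupCorrelation:
    """Pearson correlation between two groups' similarity profiles.

    Pairs where either profile is undefined are excluded pairwise; the
    retained count is the n used for Fisher-z inference.
    """
    a, b = profile1.values, profile2.values
    if a.size != b.size:
        raise ValueError("profiles must have equal length")
    mask = ~(np.isnan(a) | np.isnan(b))
    n = int(mask.sum())
    if n < 4:
        raise ValueError(f"only {n} valid profile pairs; need at least 4")
    r = float(np.corrcoef(a[mask], b[mask])[0, 1])
    return GroupCorrelation(r=r, n=n)


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample comparison of correlations on the Fisher-z scale."""

    corr1: GroupCorrelation
    corr2: GroupCorrelation
    Z: float
    p_value: float


def compare_group_correlations(
    profile1: SimilarityProfile,
    profile2: SimilarityProfile,
    profile3: SimilarityProfile,
    profile4: SimilarityProfile,
) -> GroupComparison:
    """Is corr(profile1, profile2) larger than corr(profile3, profile4)?

    Both correlations are Fisher transformed and compared with
    Z = (z1 - z2) / sqrt(1/(n1-3) + 1/(n2-3)); the p-value is two-sided.
    """
    c1 = profile_correlation(profile1, profile2)
    c2 = profile_correlation(profile3, profile4)
    se = np.sqrt(1.0 / (c1.n - 3) + 1.0 / (c2.n - 3))
    Z = (c1.z - c2.z) / se
    p = 2.0 * sps.norm.sf(abs(Z))
    return GroupComparison(corr1=c1, corr2=c2, Z=float(Z), p_value=float(p))


# --------------------------------------------------------------------------
# typicality via reverse (name -> semantic) propagation
# --------------------------------------------------------------------------

def typicality_activation(model: ModelState, word: str) -> np.ndarray:
    """Per-object semantic activation when the name is presented to the
    phonological map.

    The word's BMU bump is pushed backwards through the transpose of its
    language's semantic-phonological pathway (Hebbian links are treated as
    bidirectional); the value read at each object's semantic BMU is that
    object's simulated typicality for the category name.
    """
    if word not in model.word_bmu_phon:
        raise KeyError(f"unknown word {word!r}")
    lang = model.word_langs[model.word_ids.index(word)]
    p_grid = model.maps[MAP_PHONOLOGICAL]
    bump = neighborhood_field(p_grid, model.word_bmu_phon[word],
                              model.radius[MAP_PHONOLOGICAL].radius)
    weights = model.assoc[f"S->P/{lang}"].weights
    sem = np.clip(bump @ weights.T, 0.0, 1.0)
    return np.array([sem[model.object_bmu[o]] for o in model.object_ids])


def typicality_correlation(
    model_pair: tuple[ModelState, ModelState],
    name_pair: tuple[str, str],
) -> GroupCorrelation:
    """Correlation across objects between two names' typicality vectors.

    For the bilingual situation both names come from the same model; for the
    monolingual situation each name comes from its own single-language model.
    """
    model_a, model_b = model_pair
    name_a, name_b = name_pair
    ta = typicality_activation(model_a, name_a)
    tb = typicality_activation(model_b, name_b)
    if ta.std() == 0 or tb.std() == 0:
        raise ValueError("zero-variance typicality vector; correlation undefined")
    r = float(np.corrcoef(ta, tb)[0, 1])
    return GroupCorrelation(r=r, n=len(ta))


# --------------------------------------------------------------------------
# category geometry
# --------------------------------------------------------------------------

def _weighted_mean(coords: np.ndarray, w: np.ndarray) -> np.ndarray:
    return (coords * w[:, None]).sum(axis=0) / w.sum()


def _weighted_median(coords: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Per-coordinate weighted median (lower weighted median convention)."""
    out = np.empty(coords.shape[1])
    for j in range(coords.shape[1]):
        order = np.argsort(coords[:, j], kind="stable")
        cw = np.cumsum(w[order])
        k = int(np.searchsorted(cw, 0.5 * w.sum()))
        out[j] = coords[order[min(k, len(order) - 1)], j]
    return out


@dataclass
class CategoryGeometry:
    """Activation-weighted centers, members, and outlier flags per category."""

    language: str
    names: list[str]
    center_mean: dict[str, np.ndarray]  # boundary-dependent
    center_median: dict[str, np.ndarray]  # boundary-independent
    members: dict[str, list[str]]
    outliers: dict[str, list[str]]


def category_geometry(
    model: ModelState, names: list[str], language: str
) -> CategoryGeometry:
    """Geometry of the given category names on the semantic map.

    Centers are computed across all objects, weighting each object's semantic
    BMU coordinate by the typicality activation the name elicits for it; an
    object is a member of the category whose name it activates most strongly
    in forward naming, and an outlier if it lies closer (in grid coordinates)
    to another listed category's boundary-dependent center than to its own.
    """
    from .production import name_object

    for nm in names:
        if nm not in model.word_bmu_phon:
            raise KeyError(f"unknown category name {nm!r}")
    coords = model.maps[MAP_SEMANTIC].coordinates
    obj_xy = np.array([coords[model.object_bmu[o]] for o in model.object_ids])

    weights = {nm: typicality_activation(model, nm) for nm in names}
    center_mean, center_median = {}, {}
    for nm in names:
        w = weights[nm]
        if w.sum() == 0:
            raise ValueError(f"category {nm!r} is empty: no activation anywhere")
        center_mean[nm] = _weighted_mean(obj_xy, w)
        center_median[nm] = _weighted_median(obj_xy, w)

    members: dict[str, list[str]] = {nm: [] for nm in names}
    for i, obj in enumerate(model.object_ids):
        scores = name_object(model, obj, language).simulated_agreement
        if not scores or max(scores.values()) <= 0:
            continue
        best = max(sorted(scores), key=lambda w: scores[w])
        if best in members:
            members[best].append(obj)

    outliers: dict[str, list[str]] = {nm: [] for nm in names}
    for nm in names:
        c_own = center_mean[nm]
        for obj in members[nm]:
            xy = obj_xy[model.object_ids.index(obj)]
            d_own = float(np.linalg.norm(xy - c_own))
            for other in names:
                if other == nm:
                    continue
                if float(np.linalg.norm(xy - center_mean[other])) < d_own:
                    outliers[nm].append(obj)
                    break
    return CategoryGeometry(
        language=language, names=list(names), center_mean=center_mean,
        center_median=center_median, members=members, outliers=outliers,
    )


def indirect_direct_ratio(
    mono_a_center: np.ndarray,
    mono_b_center: np.ndarray,
    bi_a_center: np.ndarray,
    bi_b_center: np.ndarray,
) -> float:
    """(b + c + d) / a for one translation-equivalent name pair.

    a = distance between the two monolingual centers; b, c = distances from
    each monolingual center to the bilingual center in the same language;
    d = distance between the two bilingual centers.  Equals 1 exactly when
    the bilingual centers sit on the segment between the monolingual ones,
    and is >= 1 always (triangle inequality along the three-segment path).
    """
    a = float(np.linalg.norm(np.asarray(mono_a_center) - np.asarray(mono_b_center)))
    if a == 0:
        raise ValueError("monolingual centers coincide; ratio undefined")
    b = float(np.linalg.norm(np.asarray(mono_a_center) - np.asarray(bi_a_center)))
    c = float(np.linalg.norm(np.asarray(mono_b_center) - np.asarray(bi_b_center)))
    d = float(np.linalg.norm(np.asarray(bi_a_center) - np.asarray(bi_b_center)))
    return (b + c + d) / a


def ratio_t_test(ratios: "list[float] | np.ndarray") -> tuple[float, float]:
    """One-sample t of replicate ratios against 1; returns (t, two-sided p)."""
    res = sps.ttest_1samp(np.asarray(ratios, dtype=float), popmean=1.0)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# stepwise discriminant analysis
# --------------------------------------------------------------------------

@dataclass
class DFAResult:
    """Outcome of forward-stepwise discriminant feature selection."""

    selected: list[int]
    canonical_correlation: float
    wilks_lambda: float
    p_value: float
    separable: bool
    ridge: float = 0.0

    @property
    def n_dims(self) -> int:
        return len(self.selected)


def _wilks_lambda(X: np.ndarray, y: np.ndarray, cols: list[int], ridge: float) -> float:
    """Wilks' lambda det(W)/det(T) for the feature subset, with optional ridge."""
    Xs = X[:, cols]
    total_mean = Xs.mean(axis=0)
    T = (Xs - total_mean).T @ (Xs - total_mean)
    W = np.zeros_like(T)
    for g in np.unique(y):
        Xg = Xs[y == g]
        m = Xg.mean(axis=0)
        W += (Xg - m).T @ (Xg - m)
    if ridge > 0:
        eye = np.eye(len(cols))
        T = T + ridge * eye
        W = W + ridge * eye
    sign_t, logdet_t = np.linalg.slogdet(T)
    sign_w, logdet_w = np.linalg.slogdet(W)
    if sign_t <= 0 or sign_w <= 0:
        return np.nan
    return float(np.exp(logdet_w - logdet_t))


def stepwise_dfa(
    features: np.ndarray,
    labels: np.ndarray,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    cc_stable_tol: float = 0.01,
    max_ridge_tries: int = 6,
) -> DFAResult:
    """Forward-stepwise two-group discriminant analysis on Wilks' lambda.

    Features enter one at a time by the largest F-to-enter with p <= p_enter,
    and leave when their F-to-remove p >= p_remove; selection also stops once
    the canonical correlation changes by less than ``cc_stable_tol`` between
    steps.  A singular within-class covariance triggers a recorded ridge.
    Returns the selected features, the canonical correlation sqrt(1 - lambda),
    and the exact-F Wilks significance of the final function.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    groups = np.unique(y)
    if len(groups) != 2:
        raise ValueError(f"need exactly two categories, got {len(groups)}")
    for g in groups:
        if (y == g).sum() < 2:
            raise ValueError(f"category {g!r} has fewer than 2 members")
    n, n_feat = X.shape
    g_count = 2

    ridge = 0.0

    def lam(cols: list[int]) -> float:
        nonlocal ridge
        val = _wilks_lambda(X, y, cols, ridge)
        tries = 0
        while np.isnan(val) and tries < max_ridge_tries:
            ridge = 1e-8 if ridge == 0 else ridge * 100
            val = _wilks_lambda(X, y, cols, ridge)
            tries += 1
        return val

    selected: list[int] = []
    lambda_current = 1.0
    while True:
        entered = removed = False
        # ---- entry
        p = len(selected)
        df2 = n - g_count - p
        if df2 < 1:
            break
        best_j, best_F, best_lam = None, -np.inf, None
        for j in range(n_feat):
            if j in selected:
                continue
            lam_new = lam(selected + [j])
            if not np.isfinite(lam_new) or lam_new <= 0:
                continue
            F = df2 * (lambda_current / lam_new - 1.0)
            if F > best_F:
                best_j, best_F, best_lam = j, F, lam_new
        if best_j is not None and best_F >= 0:
            p_val = float(sps.f.sf(best_F, g_count - 1, df2))
            if p_val <= p_enter:
                # stability stop: a candidate that no longer moves the
                # canonical correlation does not enter
                cc_new = float(np.sqrt(max(0.0, 1.0 - best_lam)))
                cc_cur = float(np.sqrt(max(0.0, 1.0 - lambda_current)))
                if selected and abs(cc_new - cc_cur) < cc_stable_tol:
                    break
                selected.append(best_j)
                lambda_current = best_lam
                entered = True
        # ---- removal
        if len(selected) > 1:
            worst_j, worst_p, worst_lam = None, -np.inf, None
            p = len(selected)
            df2r = n - g_count - (p - 1)
            for j in selected:
                rest = [k for k in selected if k != j]
                lam_rest = lam(rest)
                if not np.isfinite(lam_rest) or lambda_current <= 0:
                    continue
                F = df2r * (lam_rest / lambda_current - 1.0)
                p_val = float(sps.f.sf(max(F, 0.0), g_count - 1, df2r))
                if p_val > worst_p:
                    worst_j, worst_p, worst_lam = j, p_val, lam_rest
            if worst_j is not None and worst_p >= p_remove:
                selected.remove(worst_j)
                lambda_current = worst_lam
                removed = True
        if not entered and not removed:
            break

    if not selected:
        return DFAResult(selected=[], canonical_correlation=0.0,
                         wilks_lambda=1.0, p_value=1.0, separable=False,
                         ridge=ridge)
    p = len(selected)
    cc = float(np.sqrt(max(0.0, 1.0 - lambda_current)))
    df2 = n - p - 1
    F = ((1.0 - lambda_current) / lambda_current) * (df2 / p)
    p_val = float(sps.f.sf(F, p, df2)) if df2 > 0 else np.nan
    return DFAResult(selected=selected, canonical_correlation=cc,
                     wilks_lambda=float(lambda_current), p_value=p_val,
                     separable=True, ridge=ridge)


# --------------------------------------------------------------------------
# outliers
# --------------------------------------------------------------------------

def outlier_proportions(geometry: CategoryGeometry) -> dict[str, float]:
    """Outlier count divided by member count, per category name."""
    out = {}
    for nm in geometry.names:
        members = geometry.members[nm]
        if not members:
            raise ValueError(f"category {nm!r} has no members")
        out[nm] = len(geometry.outliers[nm]) / len(members)
    return out
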