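"""Two-step inference of clone-specific gene activity from gene-body NO.

Step 1 removes genes unlikely to be expressed in any clone: a classifier on
binned gene-body NO, per-bin GC content and log gene length estimates the
probability that a gene is not expressed (NE); genes with P(NE) >= 0.9 in
every clone are filtered out. Step 2 tests the remaining (and SCNA-masked)
genes for differential NO between two cell populations, either with a
negative-binomial GLM Wald test per gene (default; each cell is a replicate,
library size enters as a median-of-ratios size-factor offset), or — for small
subclones, below 10% clonal frequency — with PLS-DA variable importance and
permutation p-values. The differential gene activity score is
sign(log2 FC) * (-log10 p). Because occupancy falls when a gene is active, a
drop in gene-body NO reads as an activity increase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, activity_score
from .tracks import CountMatrix, NormalizedMatrix, total_cn_profile, _per_bp_coverage
from .fragments import FragmentSet
from .plsda import plsda_permutation_test


# ---------------------------------------------------------------------------
# Step 1: gene features and the not-expressed (NE) classifier


def gene_features(
    frags: FragmentSet,
    genes: pd.DataFrame,
    gc: Optional[dict] = None,
    n_bins: int = 150,
    chrom_lengths: Optional[dict] = None,
) -> pd.DataFrame:
    """Per-gene feature vectors: binned NO profile, binned GC, log length.

    The gene body is split into ``n_bins`` equal sub-intervals with per-bin
    mean coverage; genes shorter than ``n_bins`` bp are resampled per bp. GC
    is looked up from a per-kb GC dictionary (chrom -> array); absent GC
    yields 0.5 everywhere. The feature vector has length 2 * n_bins + 1.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if (genes["end"] <= genes["start"]).any():
        raise ValueError("zero/negative-length gene")
    lengths = chrom_lengths or {c: int(g["end"].max()) for c, g in frags.df.groupby("chrom")}
    cov = {c: _per_bp_coverage(frags.df[frags.df["chrom"] == c], L) for c, L in lengths.items()}
    rows = []
    for _, g in genes.iterrows():
        L = int(g["end"] - g["start"])
        v = cov.get(g["chrom"], np.zeros(L + int(g["start"])))[g["start"]: g["end"]]
        if L >= n_bins:
            idx = np.arange(L) * n_bins // L
            no = np.bincount(idx, weights=v, minlength=n_bins) / np.bincount(idx, minlength=n_bins)
        else:
            centers = ((np.arange(n_bins) + 0.5) * L / n_bins).astype(int)
            no = v[centers]
        pos = (g["start"] + (np.arange(n_bins) + 0.5) * L / n_bins).astype(int)
        if gc is not None and g["chrom"] in gc:
            gcv = gc[g["chrom"]][np.minimum(pos // 1000, len(gc[g["chrom"]]) - 1)]
        else:
            gcv = np.full(n_bins, 0.5)
        rows.append(np.concatenate([no, gcv, [np.log(L)]]))
    cols = [f"no_{i}" for i in range(n_bins)] + [f"gc_{i}" for i in range(n_bins)] + ["log_length"]
    return pd.DataFrame(rows, index=genes["gene_id"].to_numpy(), columns=cols)


class NEClassifier:
    """Classifier for the probability that a gene is not expressed.

    A regularized logistic regression on the gene feature vectors; any
    estimator exposing fit/predict_proba can be substituted. Training is
    seeded and deterministic.
    """

    def __init__(self, threshold: float = 0.9, C: float = 1.0, seed: int = 0, estimator=None):
        self.threshold = threshold
        self.seed = seed
        if estimator is None:
            from sklearn.linear_model import LogisticRegression
            from sklearn.pipeline import make_pipeline
            from sklearn.preprocessing import StandardScaler

            estimator = make_pipeline(
                StandardScaler(),
                LogisticRegression(C=C, max_iter=2000, random_state=seed),
            )
        self.estimator = estimator
        self.fitted_ = False

    def fit(self, features: pd.DataFrame, ne_labels) -> "NEClassifier":
        y = np.asarray(ne_labels).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("need both expressed and not-expressed genes for training")
        self.estimator.fit(features.to_numpy(), y)
        self.fitted_ = True
        return self

    def predict_proba(self, features: pd.DataFrame) -> pd.Series:
        if not self.fitted_:
            raise ValueError("classifier not fitted")
        p = self.estimator.predict_proba(features.to_numpy())[:, 1]
        return pd.Series(p, index=features.index, name="p_ne")


def train_ne_classifier(features: pd.DataFrame, ne_labels, **kwargs) -> NEClassifier:
    """Fit the NE classifier on labelled gene features (1 = not expressed)."""
    return NEClassifier(**kwargs).fit(features, ne_labels)


def retain_by_ne_probability(prob_by_clone: pd.DataFrame, threshold: float = 0.9) -> list:
    """Keep a gene unless P(NE) >= threshold in every clone (inclusive bound)."""
    if prob_by_clone.shape[1] == 0:
        raise ValueError("no clones")
    drop = (prob_by_clone >= threshold).all(axis=1)
    return list(prob_by_clone.index[~drop])


def filter_ne_genes(model: NEClassifier, features_by_clone: dict, threshold: Optional[float] = None) -> list:
    """Apply the NE filter: per-clone P(NE), drop genes NE in all clones."""
    if not features_by_clone:
        raise ValueError("no clones provided")
    probs = {}
    for clone, feats in features_by_clone.items():
        if feats is None or len(feats) == 0:
            raise ValueError(f"clone {clone!r} has no features")
        probs[clone] = model.predict_proba(feats)
    return retain_by_ne_probability(pd.DataFrame(probs), threshold if threshold is not None else model.threshold)


# ---------------------------------------------------------------------------
# Step 2: size factors, dispersions and the NB-GLM Wald test


def compute_size_factors(counts) -> pd.Series:
    """Median-of-ratios size factors.

    For genes with all-positive counts, s_j = median_g( k_gj / gm_g ) where
    gm_g is the geometric mean of gene g across cells.
    """
    k = counts.counts if isinstance(counts, CountMatrix) else counts
    k = k.astype(float)
    allpos = (k > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene with all-positive counts; consider a pseudo-reference")
    ref = k[allpos]
    log_gm = np.log(ref).mean(axis=1)
    ratios = np.log(ref).sub(log_gm, axis=0)
    s = np.exp(ratios.median(axis=0))
    return pd.Series(s, index=k.columns, name="size_factor")


def estimate_dispersions(counts, groups=None, size_factors: Optional[pd.Series] = None) -> pd.Series:
    """Per-gene NB dispersion alpha (variance = mu + alpha mu^2), method of moments.

    Counts are size-factor normalized; the variance is pooled within groups
    when a design is given. alpha is floored at 0; a constant gene gets 0.
    """
    k = counts.counts if isinstance(counts, CountMatrix) else counts
    k = k.astype(float)
    s = size_factors if size_factors is not None else compute_size_factors(k)
    s = s.reindex(k.columns)
    q = k.div(s, axis=1)
    inv_s_mean = float((1.0 / s).mean())
    mu = q.mean(axis=1)
    if groups is None:
        var = q.var(axis=1, ddof=1)
    else:
        groups = pd.Series(np.asarray(groups), index=k.columns)
        ss, dof = 0.0, 0
        parts = []
        for gname, cols in groups.groupby(groups).groups.items():
            sub = q[list(cols)]
            if sub.shape[1] >= 2:
                parts.append(sub.sub(sub.mean(axis=1), axis=0).pow(2).sum(axis=1))
                dof += sub.shape[1] - 1
        if dof == 0:
            raise ValueError("need >= 2 cells in at least one group")
        var = sum(parts) / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var - mu * inv_s_mean) / mu.pow(2)
    alpha = alpha.replace([np.inf, -np.inf], np.nan).fillna(0.0).clip(lower=0.0)
    return pd.Series(alpha, index=k.index, name="dispersion")


def _nb_irls(y, group2, offset, alpha, tol=1e-8, max_iter=100):
    """Fit log mu = offset + b0 + b1*group2 for NB(alpha) counts via IRLS.

    Returns (b0, b1, se_b1, converged).
    """
    X = np.column_stack([np.ones_like(offset), group2.astype(float)])
    s = np.exp(offset)
    m1 = max(np.sum(y[group2 == 0]) / np.sum(s[group2 == 0]), 1e-8)
    m2 = max(np.sum(y[group2 == 1]) / np.sum(s[group2 == 1]), 1e-8)
    beta = np.array([np.log(m1), np.log(m2) - np.log(m1)])
    converged = False
    for _ in range(max_iter):
        eta = X @ beta + offset
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu / (1.0 + alpha * mu)
        z = (X @ beta) + (y - mu) / mu
        XtW = X.T * w
        A = XtW @ X
        try:
            beta_new = np.linalg.solve(A, XtW @ z)
        except np.linalg.LinAlgError:
            return beta[0], beta[1], np.nan, False
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    eta = X @ beta + offset
    mu = np.exp(np.clip(eta, -30, 30))
    w = mu / (1.0 + alpha * mu)
    A = (X.T * w) @ X
    try:
        cov = np.linalg.inv(A)
        se = float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        se = np.nan
    return float(beta[0]), float(beta[1]), se, converged


@dataclass
class DGEResults:
    """Differential gene-activity results between two cell populations."""

    frame: pd.DataFrame  # gene_id, base_mean, log2fc, se, stat, p, q, score, mode
    mode: str
    groups: tuple
    fdr: float = 0.1

    def significant(self) -> pd.DataFrame:
        return self.frame[self.frame["q"] < self.fdr]

    def summary(self) -> str:
        f = self.frame
        n_sig = int((f["q"] < self.fdr).sum())
        lines = [
            f"Differential gene activity ({self.mode}): {self.groups[0]} vs {self.groups[1]}",
            f"  genes tested: {int(f['p'].notna().sum())} of {len(f)}",
            f"  significant at {int(self.fdr * 100)}% FDR: {n_sig}",
        ]
        top = f.dropna(subset=["p"]).reindex(f["score"].abs().sort_values(ascending=False).index).head(5)
        for _, r in top.iterrows():
            lines.append(
                f"    {r['gene_id']}: log2FC={r['log2fc']:+.2f}, p={r['p']:.2e}, q={r['q']:.2e}, score={r['score']:+.2f}"
            )
        return "\n".join(lines)


class NBDifferential:
    """Negative-binomial GLM model for gene-body NO counts between two groups.

    Per gene the model is log mu_j = log s_j + b0 + b1 * 1[cell j in group 2]
    with NB variance mu + alpha mu^2; b1 is tested with a two-sided Wald test.
    """

    def __init__(self, counts, groups, size_factors=None, dispersions=None):
        k = counts.counts if isinstance(counts, CountMatrix) else counts
        self.counts = k.astype(float)
        groups = pd.Series(np.asarray(groups), index=k.columns)
        uniq = sorted(groups.unique())
        if len(uniq) != 2:
            raise ValueError("exactly two groups required (iterate pairs externally)")
        self.groups = groups
        self.group_names = tuple(uniq)
        self.size_factors = size_factors
        self.dispersions = dispersions

    def fit(self, tol: float = 1e-8, max_iter: int = 100) -> DGEResults:
        k = self.counts
        s = self.size_factors if self.size_factors is not None else compute_size_factors(k)
        s = s.reindex(k.columns)
        d = (
            self.dispersions
            if self.dispersions is not None
            else estimate_dispersions(k, self.groups.to_numpy(), s)
        )
        g2 = (self.groups == self.group_names[1]).to_numpy()
        offset = np.log(s.to_numpy())
        rows = []
        for gene in k.index:
            y = k.loc[gene].to_numpy()
            base_mean = float((y / s.to_numpy()).mean())
            if y[~g2].sum() == 0 or y[g2].sum() == 0:
                rows.append((gene, base_mean, np.nan, np.nan, np.nan, np.nan))
                continue
            b0, b1, se, conv = _nb_irls(y, g2, offset, float(d.loc[gene]), tol, max_iter)
            if not conv or not np.isfinite(se) or se == 0:
                rows.append((gene, base_mean, np.nan, np.nan, np.nan, np.nan))
                continue
            z = b1 / se
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append((gene, base_mean, b1 / np.log(2.0), se / np.log(2.0), z, p))
        out = pd.DataFrame(rows, columns=["gene_id", "base_mean", "log2fc", "se", "stat", "p"])
        out["q"] = bh_adjust(out["p"])
        out["score"] = activity_score(out["log2fc"], out["p"])
        out["mode"] = "NB_GLM"
        return DGEResults(out, "NB_GLM", self.group_names)


def nb_wald_test(counts, groups, size_factors=None, dispersions=None) -> DGEResults:
    """Functional wrapper around :class:`NBDifferential`."""
    return NBDifferential(counts, groups, size_factors, dispersions).fit()


def plsda_alt_mode(
    normalized,
    groups,
    n_perm: int = 199,
    seed: int = 0,
    n_components: int = 2,
) -> DGEResults:
    """PLS-DA/VIP differential mode for low-CF subclones.

    VIP per gene from a PLS-DA of the two clone labels on the normalized
    (log-scale) NO matrix; permutation p-values under label shuffling; fold
    change from group means of the normalized values.
    """
    x = normalized.values if isinstance(normalized, NormalizedMatrix) else normalized
    groups = pd.Series(np.asarray(groups), index=x.columns)
    uniq = sorted(groups.unique())
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    counts = groups.value_counts()
    if counts.min() < 2:
        warnings.warn("a group has < 2 cells; PLS-DA test is unreliable")
    res = plsda_permutation_test(
        x.T, groups.to_numpy(), n_components=n_components, n_perm=n_perm, seed=seed,
        min_class_size=1 if counts.min() < 2 else 2,
    )
    m1 = x.loc[:, groups == uniq[0]].mean(axis=1)
    m2 = x.loc[:, groups == uniq[1]].mean(axis=1)
    out = pd.DataFrame(
        {
            "gene_id": x.index,
            "base_mean": x.mean(axis=1).to_numpy(),
            "log2fc": (m2 - m1).to_numpy(),  # log2-scale input: difference of means
            "se": np.nan,
            "stat": res["vip"].reindex(x.index).to_numpy(),
            "p": res["p"].reindex(x.index).to_numpy(),
        }
    )
    out["q"] = bh_adjust(out["p"])
    out["score"] = activity_score(out["log2fc"], out["p"])
    out["mode"] = "PLSDA"
    return DGEResults(out.reset_index(drop=True), "PLSDA", tuple(uniq))


def mask_scna_genes(genes: pd.DataFrame, cn: pd.DataFrame, clone_a: str, clone_b: str) -> list:
    """Drop genes whose copy number differs between two clones over >= 1 bp.

    Returns the retained gene ids. Clones missing from the CN table inherit
    the germline profile (i.e. no somatic change).
    """
    profiles = {}
    for clone in (clone_a, clone_b):
        scope = clone if (cn["scope"] == clone).any() else "germline"
        profiles[clone] = total_cn_profile(cn, scope)

    def cn_at(profile, chrom, lo, hi):
        seg = profile[(profile["chrom"] == chrom) & (profile["start"] < hi) & (profile["end"] > lo)]
        return seg

    retained = []
    for _, g in genes.iterrows():
        cuts = {g["start"], g["end"]}
        for clone in (clone_a, clone_b):
            seg = cn_at(profiles[clone], g["chrom"], g["start"], g["end"])
            cuts.update(np.clip(seg["start"], g["start"], g["end"]))
            cuts.update(np.clip(seg["end"], g["start"], g["end"]))
        cuts = sorted(cuts)
        differs = False
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            if hi <= lo:
                continue
            vals = []
            for clone in (clone_a, clone_b):
                seg = cn_at(profiles[clone], g["chrom"], lo, hi)
                vals.append(int(seg.iloc[0]["cn"]) if len(seg) else 2)
            if vals[0] != vals[1]:
                differs = True
                break
        if not differs:
            retained.append(g["gene_id"])
    return retained


def differential_activity(
    counts,
    groups,
    minor_cf: Optional[float] = None,
    mode: Optional[str] = None,
    cf_switch: float = 0.1,
    normalized=None,
    n_perm: int = 199,
    seed: int = 0,
) -> DGEResults:
    """Mode dispatch: NB-GLM Wald by default, PLS-DA below the CF switch.

    ``minor_cf`` is the clonal frequency of the smaller group; when it is
    below ``cf_switch`` (default 10%) the PLS-DA permutation mode is used.
    """
    if mode is None:
        if minor_cf is None:
            g = pd.Series(np.asarray(groups))
            minor_cf = g.value_counts().min() / len(g)
        mode = "NB_GLM" if minor_cf >= cf_switch else "PLSDA"
    if mode == "NB_GLM":
        return nb_wald_test(counts, groups)
    if mode == "PLSDA":
        if normalized is None:
            k = counts.counts if isinstance(counts, CountMatrix) else counts
            s = compute_size_factors(k)
            normalized = np.log2(k.div(s, axis=1) + 1.0)
        return plsda_alt_mode(normalized, groups, n_perm=n_perm, seed=seed)
    raise ValueError(f"unknown mode {mode!r}")
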