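"""Gene-set machinery: over-representation, pathway-level NO, contingency tests.

Over-representation of a TF-target or pathway gene set among differentially
active genes is scored with the upper-tail hypergeometric test (equivalent to
a one-sided Fisher exact test on the corresponding 2x2 table). Pathway-level
NO summarizes, per single cell, the mean median-of-ratios-normalized NO over
the variable members of a pathway; the activity transform reports
(-1) x Z score so that higher values mean higher inferred pathway activity
(occupancy and activity are inversely related). Pathway differences between
SV and non-SV cells are tested with a linear mixed model (SV status fixed,
library batch as a random intercept) via a likelihood-ratio test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust


@dataclass
class GeneSetCollection:
    """Named gene sets with optional annotation (e.g. the TF they belong to)."""

    sets: dict  # name -> list of unique member gene ids
    annotation: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.sets)

    def restrict(self, universe) -> "GeneSetCollection":
        uni = set(universe)
        return GeneSetCollection(
            {k: [g for g in v if g in uni] for k, v in self.sets.items()},
            dict(self.annotation),
        )


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name, description, members...); dedupe, drop empty sets."""
    sets, ann = {}, {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {i}: malformed GMT record")
            name, desc, members = parts[0], parts[1], parts[2:]
            seen, uniq = set(), []
            for m in members:
                if m and m not in seen:
                    seen.add(m)
                    uniq.append(m)
            if not uniq:
                warnings.warn(f"{path}: line {i}: empty set {name!r} dropped")
                continue
            sets[name] = uniq
            ann[name] = desc
    return GeneSetCollection(sets, ann)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.annotation.get(name, "")
            fh.write("\t".join([name, desc] + list(members)) + "\n")


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if k <= 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def overrepresentation_test(hits, universe, sets: GeneSetCollection, fdr: float = 0.1) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of each set among the hits.

    ``hits`` must be a subset of ``universe``; sets are intersected with the
    universe before testing. BH-adjusted q-values at the configured FDR.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(hits)
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    restricted = sets.restrict(universe)
    N, n = len(universe), len(hits)
    rows = []
    for name, members in restricted.sets.items():
        K = len(members)
        if K == 0:
            rows.append((name, 0, 0, np.nan, np.nan))
            continue
        k = len(hits.intersection(members))
        p = hypergeom_upper_tail(k, N, K, n)
        rows.append((name, K, k, k / K, p))
    out = pd.DataFrame(rows, columns=["set_id", "set_size", "overlap", "overlap_frac", "p"])
    out["q"] = bh_adjust(out["p"])
    out["significant"] = out["q"] < fdr
    return out


@dataclass
class PathwayScoreMatrix:
    """Cells x pathways matrix of mean normalized NO (or its activity transform)."""

    scores: pd.DataFrame
    activity_transform: bool
    members_used: dict


def pathway_no_scores(
    normalized: pd.DataFrame,
    sets: GeneSetCollection,
    variability_quantile: float = 0.8,
    sd_mode: str = "percentile",
    activity_transform: bool = False,
) -> PathwayScoreMatrix:
    """Per-cell mean normalized NO over the variable members of each pathway.

    Lowly variable genes are removed first: with ``sd_mode='percentile'``
    (default) genes whose across-cell s.d. falls below the
    ``variability_quantile`` quantile of all genes' s.d. are dropped; with
    ``sd_mode='absolute'`` the threshold is the value itself. With
    ``activity_transform`` the score is (-1) x Z across cells, so per pathway
    the mean is 0 and the s.d. is 1.
    """
    x = normalized.values if hasattr(normalized, "values") and not isinstance(normalized, pd.DataFrame) else normalized
    sd = x.std(axis=1, ddof=1)
    if sd_mode == "percentile":
        thr = float(np.quantile(sd, variability_quantile))
    elif sd_mode == "absolute":
        thr = float(variability_quantile)
    else:
        raise ValueError("sd_mode must be 'percentile' or 'absolute'")
    variable = set(sd.index[sd >= thr]) if thr > 0 else set(sd.index[sd > 0])
    cols, used = {}, {}
    for name, members in sets.sets.items():
        keep = [g for g in members if g in x.index and (g in variable)]
        used[name] = keep
        if not keep:
            warnings.warn(f"pathway {name!r}: no member survives the variability filter")
            cols[name] = pd.Series(np.nan, index=x.columns)
            continue
        cols[name] = x.loc[keep].mean(axis=0)
    scores = pd.DataFrame(cols)
    if activity_transform:
        mu = scores.mean(axis=0)
        sdp = scores.std(axis=0, ddof=1).replace(0, np.nan)
        scores = -(scores - mu) / sdp
    return PathwayScoreMatrix(scores, activity_transform, used)


def _lmm_lrt(y, sv, batch):
    """LRT p-value for the SV fixed effect with a batch random intercept (ML fits)."""
    import statsmodels.api as sm

    df = pd.DataFrame({"y": y, "sv": sv.astype(float), "batch": batch})
    if df["batch"].nunique() < 2:
        x1 = sm.add_constant(df[["sv"]])
        full = sm.OLS(df["y"], x1).fit()
        null = sm.OLS(df["y"], np.ones((len(df), 1))).fit()
        lrt = 2.0 * (full.llf - null.llf)
        return max(lrt, 0.0), float(sps.chi2.sf(max(lrt, 0.0), 1)), "ols"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.MixedLM(df["y"], sm.add_constant(df[["sv"]]), groups=df["batch"]).fit(reml=False)
        null = sm.MixedLM(df["y"], np.ones((len(df), 1)), groups=df["batch"]).fit(reml=False)
    lrt = 2.0 * (full.llf - null.llf)
    return max(lrt, 0.0), float(sps.chi2.sf(max(lrt, 0.0), 1)), "lmm"


def pathway_lmm_test(
    scores: PathwayScoreMatrix,
    sv_status,
    batch,
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Per-pathway LRT of the SV fixed effect in a mixed model with batch intercepts.

    Both nested models are fitted by maximum likelihood; the statistic is
    referred to chi-square with 1 df. A single batch degenerates to the
    ordinary linear-model LRT (recorded in the ``engine`` column).
    """
    sv = pd.Series(np.asarray(sv_status), index=scores.scores.index)
    if sv.astype(bool).sum() < 2 or (~sv.astype(bool)).sum() < 2:
        raise ValueError("need >= 2 cells per SV-status group")
    batch = pd.Series(np.asarray(batch), index=scores.scores.index)
    rows = []
    for name in scores.scores.columns:
        y = scores.scores[name]
        ok = y.notna()
        if ok.sum() < 4 or y[ok].nunique() == 1:
            effect = float(y[ok & sv.astype(bool)].mean() - y[ok & ~sv.astype(bool)].mean()) if ok.sum() else np.nan
            rows.append((name, effect, np.nan, np.nan, "na"))
            continue
        eff = float(y[ok & sv.astype(bool)].mean() - y[ok & ~sv.astype(bool)].mean())
        lrt, p, engine = _lmm_lrt(y[ok].to_numpy(), sv[ok].to_numpy(), batch[ok].to_numpy())
        rows.append((name, eff, lrt, p, engine))
    out = pd.DataFrame(rows, columns=["set_id", "effect", "stat", "p", "engine"])
    out["q"] = bh_adjust(out["p"])
    out["significant"] = out["q"] < fdr
    return out


def fisher_exact(table, alternative: str = "two_sided") -> float:
    """Exact p-value for a 2x2 table of non-negative integer counts.

    Two-sided p sums the probabilities of all tables at least as extreme
    (probability <= observed) under the hypergeometric null.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("negative entries in contingency table")
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}.get(alternative, alternative)
    _, p = sps.fisher_exact(t, alternative=alt)
    return float(p)
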