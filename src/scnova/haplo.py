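"""Haplotype-specific nucleosome occupancy analysis around structural variants.

On chromosomes with a mixed template-strand configuration (WC/CW) every read
of a Strand-seq cell can be assigned to one of the two homologs, so the
nucleosome occupancy of haplotype 1 (H1) and haplotype 2 (H2) can be compared
directly. A cis-acting SV (deletion, duplication, balanced translocation)
changes occupancy on the rearranged homolog only, which this module detects
at several scales:

* gene bodies, via per-cell Wilcoxon rank-sum tests with BH correction;
* a +/- 1 Mb scan around SV breakpoints that re-adjusts FDR locally;
* sliding windows across a breakpoint region, scored with a binomial
  likelihood-ratio test whose p-values are adjusted by permuting fragment
  haplotype labels;
* cis-regulatory elements (CREs), via an exact binomial test against the
  copy-number-expected allelic ratio;
* TADs, flagged as outliers with two-sample Kolmogorov-Smirnov tests on
  window-level fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .fragments import FragmentSet, StrandStateMap, UNPHASED
from .stats import bh_adjust

SV_CLASSES = ("DEL", "DUP", "INV", "INVDUP", "TRA", "COMPLEX")


@dataclass
class SVCall:
    """A structural-variant call attached to a subclone."""

    sv_id: str
    sv_class: str
    chrom: str
    start: int
    end: int
    haplotype: str = "UNKNOWN"  # H1 | H2 | UNKNOWN
    clone_id: str = ""
    cf: float = 1.0
    chrom2: Optional[str] = None
    pos2: Optional[int] = None

    def __post_init__(self):
        if self.sv_class not in SV_CLASSES:
            raise ValueError(f"unknown SV class {self.sv_class!r}")
        if not (0 < self.cf <= 1):
            raise ValueError("CF must lie in (0, 1]")

    def breakpoints(self):
        pts = [(self.chrom, self.start), (self.chrom, self.end)]
        if self.chrom2 is not None and self.pos2 is not None and self.pos2 >= 0:
            pts.append((self.chrom2, self.pos2))
        return pts


@dataclass
class HaplotypeCounts:
    """Phased fragment counts per unit and cell, restricted to WC/CW chromosomes.

    ``counts`` is long-form: unit_id, cell, h1, h2, unphased — with one row per
    informative cell per unit (zero counts included). ``cn`` holds the
    per-unit per-haplotype copy number used for normalization.
    """

    counts: pd.DataFrame
    cn: pd.DataFrame  # unit_id, cn_h1, cn_h2
    units: pd.DataFrame  # unit_id, chrom, start, end


@dataclass
class WindowProfile:
    """Sliding-window haplotype counts and tests across a breakpoint region."""

    windows: pd.DataFrame  # chrom, start, end, h1, h2, fc, p_analytic, p_perm
    chrom: str
    breakpoint: int
    p0: float
    n_perm: int


def sv_table_from_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "chrom2": str})
    svs = []
    for _, r in df.iterrows():
        svs.append(
            SVCall(
                sv_id=str(r["sv_id"]),
                sv_class=str(r["class"]),
                chrom=str(r["chrom"]),
                start=int(r["start"]),
                end=int(r["end"]),
                haplotype=str(r.get("haplotype", "UNKNOWN")),
                clone_id=str(r.get("clone_id", "")),
                cf=float(r.get("cf", 1.0)),
                chrom2=None if str(r.get("chrom2", ".")) == "." else str(r["chrom2"]),
                pos2=None if int(r.get("pos2", -1)) < 0 else int(r["pos2"]),
            )
        )
    return svs


def haplotype_unit_counts(
    frags: FragmentSet,
    units: pd.DataFrame,
    states: StrandStateMap,
    cn: Optional[pd.DataFrame] = None,
) -> HaplotypeCounts:
    """Count phased fragments per unit, cell and haplotype.

    Only cells whose chromosome is in a mixed (WC/CW) template state
    contribute; for those cells a row is emitted for every unit on that
    chromosome, so uncovered units appear with zero counts. ``units`` needs
    columns unit_id, chrom, start, end. ``cn`` (unit_id, cn_h1, cn_h2)
    defaults to 1:1.
    """
    mixed = states.entries[states.entries["state"].isin(["WC", "CW"])]
    informative = {}  # chrom -> list of cells
    for chrom, grp in mixed.groupby("chrom"):
        informative[chrom] = sorted(grp["cell"].unique())
    df = frags.df
    rows = []
    for chrom, usub in units.groupby("chrom"):
        cells = informative.get(chrom, [])
        if not cells:
            continue
        sub = df[(df["chrom"] == chrom) & (df["cell"].isin(cells))]
        for _, u in usub.iterrows():
            hit = sub[(sub["start"] < u["end"]) & (sub["end"] > u["start"])]
            tab = hit.groupby(["cell", "haplotype"]).size()
            for cell in cells:
                rows.append(
                    (
                        u["unit_id"],
                        cell,
                        int(tab.get((cell, "H1"), 0)),
                        int(tab.get((cell, "H2"), 0)),
                        int(tab.get((cell, UNPHASED), 0)),
                    )
                )
    counts = pd.DataFrame(rows, columns=["unit_id", "cell", "h1", "h2", "unphased"])
    if cn is None:
        cn = pd.DataFrame({"unit_id": units["unit_id"], "cn_h1": 1, "cn_h2": 1})
    return HaplotypeCounts(counts, cn, units[["unit_id", "chrom", "start", "end"]].copy())


def test_haplotype_no(
    hc: HaplotypeCounts,
    min_cells: int = 5,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-unit two-sided Wilcoxon rank-sum test of H1 vs H2 normalized counts.

    Per informative cell the H1 and H2 counts are divided by the respective
    haplotype copy number; the two per-cell samples are compared with an
    unpaired rank-sum test and BH-adjusted across units. Effect size is
    log2((mean H1 + pc) / (mean H2 + pc)).
    """
    cn = hc.cn.set_index("unit_id")
    rows = []
    for unit, grp in hc.counts.groupby("unit_id", sort=True):
        n = len(grp)
        cn1 = float(cn.loc[unit, "cn_h1"]) if unit in cn.index else 1.0
        cn2 = float(cn.loc[unit, "cn_h2"]) if unit in cn.index else 1.0
        x = grp["h1"].to_numpy(float) / max(cn1, 1e-9)
        y = grp["h2"].to_numpy(float) / max(cn2, 1e-9)
        if n < min_cells or (x.sum() == 0 and y.sum() == 0):
            rows.append((unit, n, np.nan, np.nan, np.nan))
            continue
        mx, my = x.mean(), y.mean()
        effect = float(np.log2((mx + pseudocount) / (my + pseudocount)))
        if np.array_equal(np.sort(x), np.sort(y)) and np.all(x == x[0]) and np.all(y == y[0]):
            stat, p = float(n * n / 2), 1.0
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", use_continuity=False)
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append((unit, n, effect, stat, p))
    out = pd.DataFrame(rows, columns=["unit_id", "n_cells", "effect", "stat", "p"])
    out["q"] = bh_adjust(out["p"])
    return out


def local_scan(
    svs: list,
    results: pd.DataFrame,
    units: pd.DataFrame,
    radius: int = 1_000_000,
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Scan +/- radius around each SV breakpoint for haplotype-specific units.

    ``results`` is the genome-wide table from :func:`test_haplotype_no`;
    ``units`` supplies coordinates. Units whose body overlaps the window
    around any breakpoint of an SV are selected and their p-values re-adjusted
    (BH) within the scan set of that SV.
    """
    coord = units.set_index("unit_id")
    res = results.set_index("unit_id")
    rows = []
    for sv in svs:
        selected = []
        for chrom, pos in sv.breakpoints():
            lo, hi = pos - radius, pos + radius
            sub = coord[(coord["chrom"] == chrom) & (coord["start"] < hi) & (coord["end"] > lo)]
            selected.extend(sub.index.tolist())
        selected = sorted(set(selected))
        if not selected:
            continue
        ps = np.array([res.loc[u, "p"] if u in res.index else np.nan for u in selected])
        qs = bh_adjust(ps)
        for u, p, q in zip(selected, ps, qs):
            eff = res.loc[u, "effect"] if u in res.index else np.nan
            rows.append((sv.sv_id, u, eff, p, q, bool(q < fdr) if np.isfinite(q) else False))
    return pd.DataFrame(rows, columns=["sv_id", "unit_id", "effect", "p", "q_local", "significant"])


def _binomial_lrt(n1, n2, p0):
    """LRT statistic of a binomial proportion against p0 (0*log0 := 0)."""
    n = n1 + n2
    if n == 0:
        return np.nan
    g = 0.0
    if n1 > 0:
        g += n1 * np.log(n1 / (n * p0))
    if n2 > 0:
        g += n2 * np.log(n2 / (n * (1.0 - p0)))
    return 2.0 * g


def sliding_window_scan(
    frags: FragmentSet,
    chrom: str,
    breakpoint: int,
    region: tuple,
    window: int = 50_000,
    step: int = 10_000,
    p0: float = 0.5,
    n_perm: int = 1_000,
    seed: int = 0,
    pseudocount: float = 1.0,
    states: Optional[StrandStateMap] = None,
) -> WindowProfile:
    """Sliding-window haplotype imbalance across a breakpoint region.

    Pooled phased counts (n_H1, n_H2) are computed per window (a fragment
    contributes to every window it overlaps). Each window gets an analytic
    p-value from the binomial likelihood-ratio test of the H1 proportion
    against ``p0``, and a permutation-adjusted p-value obtained by shuffling
    the haplotype labels of the phased fragments within the region.
    """
    if window < step:
        raise ValueError("window must be >= step")
    lo, hi = region
    df = frags.df
    mask = (df["chrom"] == chrom) & (df["start"] < hi) & (df["end"] > lo) & (df["haplotype"] != UNPHASED)
    if states is not None:
        mix = states.mixed_mask(df.loc[mask, "cell"].tolist(), df.loc[mask, "chrom"].tolist())
        idx = np.flatnonzero(mask.to_numpy())
        keep = np.zeros(len(df), dtype=bool)
        keep[idx[mix]] = True
        mask = pd.Series(keep, index=df.index)
    sub = df.loc[mask]
    starts = np.arange(lo, max(lo + 1, hi - window + 1), step)
    wdf = pd.DataFrame({"chrom": chrom, "start": starts, "end": np.minimum(starts + window, hi)})
    n_win = len(wdf)

    # expand fragment -> overlapped window indices
    fs = sub["start"].to_numpy()
    fe = sub["end"].to_numpy()
    is_h1 = (sub["haplotype"] == "H1").to_numpy()
    ws_start = wdf["start"].to_numpy()
    ws_end = wdf["end"].to_numpy()
    i_first = np.maximum((fs - lo - window) // step, 0).astype(int)
    i_last = np.minimum((np.maximum(fe - lo, 0)) // step, n_win - 1).astype(int)
    exp_frag, exp_win = [], []
    for j in range(len(sub)):
        for w in range(int(i_first[j]), int(i_last[j]) + 1):
            if ws_start[w] < fe[j] and ws_end[w] > fs[j]:
                exp_frag.append(j)
                exp_win.append(w)
    exp_frag = np.asarray(exp_frag, dtype=int)
    exp_win = np.asarray(exp_win, dtype=int)

    def window_counts(h1_labels):
        h1 = np.bincount(exp_win[h1_labels[exp_frag]], minlength=n_win)
        tot = np.bincount(exp_win, minlength=n_win)
        return h1, tot - h1

    h1, h2 = window_counts(is_h1)
    g_obs = np.array([_binomial_lrt(a, b, p0) for a, b in zip(h1, h2)])
    p_analytic = stats.chi2.sf(g_obs, df=1)
    p_analytic[~np.isfinite(g_obs)] = np.nan

    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_win)
    labels = is_h1.copy()
    for _ in range(n_perm):
        rng.shuffle(labels)
        ph1, ph2 = window_counts(labels)
        g_perm = np.array([_binomial_lrt(a, b, p0) for a, b in zip(ph1, ph2)])
        exceed += (np.nan_to_num(g_perm, nan=-np.inf) >= np.nan_to_num(g_obs, nan=np.inf)).astype(float)
    p_perm = (1.0 + exceed) / (n_perm + 1.0)
    p_perm[~np.isfinite(g_obs)] = np.nan

    wdf["h1"] = h1
    wdf["h2"] = h2
    # exact count ratio; the pseudocount only guards zero denominators/numerators
    wdf["fc"] = np.maximum(h1, pseudocount) / np.maximum(h2, pseudocount)
    wdf["lrt"] = g_obs
    wdf["p_analytic"] = p_analytic
    wdf["p_perm"] = p_perm
    return WindowProfile(wdf, chrom, breakpoint, p0, n_perm)


def cre_exact_test(
    frags: FragmentSet,
    cres: pd.DataFrame,
    cn_h1: int = 1,
    cn_h2: int = 1,
    states: Optional[StrandStateMap] = None,
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Exact binomial test of pooled phased counts per CRE.

    Under no haplotype effect the H1 read count among phased reads is
    binomial with p0 = cn_H1 / (cn_H1 + cn_H2); two-sided exact p-values are
    BH-adjusted at the configured FDR. ``cres`` needs columns chrom, start,
    end and optionally cre_id.
    """
    p0 = cn_h1 / (cn_h1 + cn_h2)
    df = frags.df[frags.df["haplotype"] != UNPHASED]
    if states is not None and len(df):
        mix = states.mixed_mask(df["cell"].tolist(), df["chrom"].tolist())
        df = df.loc[mix]
    rows = []
    for i, cre in cres.reset_index(drop=True).iterrows():
        cid = cre.get("cre_id", f"cre{i}")
        hit = df[(df["chrom"] == cre["chrom"]) & (df["start"] < cre["end"]) & (df["end"] > cre["start"])]
        n1 = int((hit["haplotype"] == "H1").sum())
        n2 = int((hit["haplotype"] == "H2").sum())
        if n1 + n2 == 0:
            rows.append((cid, n1, n2, np.nan, np.nan))
            continue
        p = stats.binomtest(n1, n1 + n2, p0, alternative="two-sided").pvalue
        fc = max(n1, 1.0) / max(n2, 1.0)
        rows.append((cid, n1, n2, fc, float(p)))
    out = pd.DataFrame(rows, columns=["unit_id", "h1", "h2", "fc", "p"])
    out["q"] = bh_adjust(out["p"])
    out["significant"] = out["q"] < fdr
    return out


def tad_outlier_test(profile: WindowProfile, tads: pd.DataFrame, min_windows: int = 3) -> pd.DataFrame:
    """Two-sample KS test of window log fold changes inside each TAD vs outside.

    A window belongs to the TAD containing its midpoint. TADs covered by
    fewer than ``min_windows`` windows get an NA row.
    """
    w = profile.windows.dropna(subset=["fc"]).copy()
    w = w[(w["h1"] + w["h2"]) > 0]
    mid = (w["start"] + w["end"]) // 2
    logfc = np.log2(w["fc"].to_numpy(float))
    rows = []
    tsub = tads[tads["chrom"] == profile.chrom] if "chrom" in tads.columns else tads
    covered = 0
    for i, tad in tsub.reset_index(drop=True).iterrows():
        tid = tad.get("tad_id", f"tad{i}")
        inside = ((mid >= tad["start"]) & (mid < tad["end"])).to_numpy()
        if inside.sum() > 0:
            covered += 1
        if inside.sum() < min_windows or (~inside).sum() < 1:
            rows.append((tid, int(inside.sum()), np.nan, np.nan))
            continue
        d, p = stats.ks_2samp(logfc[inside], logfc[~inside])
        rows.append((tid, int(inside.sum()), float(d), float(p)))
    if covered < 2:
        raise ValueError("need windows covering >= 2 TADs")
    out = pd.DataFrame(rows, columns=["unit_id", "n_windows", "stat", "p"])
    out["q"] = bh_adjust(out["p"])
    return out
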