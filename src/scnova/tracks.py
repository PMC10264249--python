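"""Pseudobulk nucleosome-occupancy tracks, gene-body count matrices, normalization.

Nucleosome occupancy (NO) at a base pair is the number of sequenced
nucleosome-protected fragments covering it. Tracks report the mean per-bp
coverage in fixed-size bins; no peak calling or smoothing is applied. The
gene-body count matrix (genes x cells, fragments overlapping the gene body by
at least 1 bp) is the feature space for cell typing and differential
gene-activity inference, after copy-number, library-size (reads per million)
and log2 normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .fragments import FragmentSet, UNPHASED


@dataclass
class NOTrack:
    """Binned mean per-bp coverage per chromosome."""

    values: dict  # chrom -> np.ndarray of bin means
    bin_size: int
    haplotype_filter: str  # ALL | H1 | H2 | UNPHASED
    n_fragments_used: int
    chrom_lengths: dict

    def concat(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in sorted(self.values)])


@dataclass
class CountMatrix:
    """Gene-body fragment counts, genes x cells, with per-cell library sizes.

    Library size is the total number of retained fragments of the cell, not
    only those falling in genes.
    """

    counts: pd.DataFrame  # index gene_id, columns cell
    library_sizes: pd.Series
    genes: pd.DataFrame  # gene_id, chrom, start, end, strand


@dataclass
class NormalizedMatrix:
    values: pd.DataFrame  # genes x cells, real
    steps: tuple  # provenance flags, subset of ("cn", "rpm", "log2")
    cn_table: Optional[pd.DataFrame] = None
    log: list = field(default_factory=list)


def _chrom_lengths(frags: FragmentSet, chrom_lengths: Optional[dict]) -> dict:
    if chrom_lengths is not None:
        return dict(chrom_lengths)
    return {c: int(g["end"].max()) for c, g in frags.df.groupby("chrom")}


def _per_bp_coverage(df: pd.DataFrame, length: int) -> np.ndarray:
    diff = np.zeros(length + 1)
    np.add.at(diff, np.clip(df["start"].to_numpy(), 0, length), 1.0)
    np.add.at(diff, np.clip(df["end"].to_numpy(), 0, length), -1.0)
    return np.cumsum(diff[:-1])


def _hap_subset(frags: FragmentSet, haplotype_filter: str) -> pd.DataFrame:
    if haplotype_filter == "ALL":
        return frags.df
    if haplotype_filter in ("H1", "H2"):
        return frags.df[frags.df["haplotype"] == haplotype_filter]
    if haplotype_filter == "UNPHASED":
        return frags.df[frags.df["haplotype"] == UNPHASED]
    raise ValueError(f"unknown haplotype filter {haplotype_filter!r}")


def pseudobulk_track(
    frags: FragmentSet,
    bin_size: int = 10,
    haplotype_filter: str = "ALL",
    chrom_lengths: Optional[dict] = None,
) -> NOTrack:
    """Mean per-bp fragment coverage in ``bin_size`` bins, per chromosome."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    lengths = _chrom_lengths(frags, chrom_lengths)
    df = _hap_subset(frags, haplotype_filter)
    values = {}
    for chrom, L in lengths.items():
        cov = _per_bp_coverage(df[df["chrom"] == chrom], L)
        n_bins = -(-L // bin_size)
        padded = np.zeros(n_bins * bin_size)
        padded[:L] = cov
        sums = padded.reshape(n_bins, bin_size).sum(axis=1)
        widths = np.full(n_bins, bin_size, dtype=float)
        if L % bin_size:
            widths[-1] = L % bin_size
        values[chrom] = sums / widths
    return NOTrack(values, bin_size, haplotype_filter, len(df), lengths)


def average_profile_at_sites(
    frags: FragmentSet,
    sites: pd.DataFrame,
    flank: int = 3_000,
    bin_size: int = 10,
    scale_at: int = -2_000,
    chrom_lengths: Optional[dict] = None,
) -> pd.DataFrame:
    """Anchor-averaged NO profile around oriented sites (e.g. bound CTCF motifs).

    Coverage is averaged per offset across sites (minus-strand anchors are
    flipped so that offsets run in the anchor's orientation), binned, and
    scaled so that the bin at offset ``scale_at`` (by convention -2,000 bp
    from the site center) equals 1. Returns a frame with columns offset, no.
    """
    if flank < abs(scale_at):
        raise ValueError("flank must cover the scaling offset")
    lengths = _chrom_lengths(frags, chrom_lengths)
    cov = {c: _per_bp_coverage(frags.df[frags.df["chrom"] == c], L) for c, L in lengths.items()}
    acc = np.zeros(2 * flank)
    n_used = 0
    for _, s in sites.iterrows():
        c = s["chrom"]
        if c not in cov:
            continue
        center = (int(s["start"]) + int(s["end"])) // 2
        lo, hi = center - flank, center + flank
        if lo < 0 or hi > lengths[c]:
            continue
        window = cov[c][lo:hi]
        if s.get("strand", "+") == "-":
            window = window[::-1]
        acc += window
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable anchor sites")
    mean = acc / n_used
    n_bins = 2 * flank // bin_size
    binned = mean[: n_bins * bin_size].reshape(n_bins, bin_size).mean(axis=1)
    offsets = np.arange(-flank, flank, bin_size)
    scale_idx = int((scale_at + flank) // bin_size)
    scale = binned[scale_idx]
    if scale == 0:
        raise ValueError(f"zero coverage in scaling bin at offset {scale_at}")
    return pd.DataFrame({"offset": offsets, "no": binned / scale})


def gene_body_counts(frags: FragmentSet, genes: pd.DataFrame) -> CountMatrix:
    """Count fragments overlapping each gene body by >= 1 bp, per cell.

    A fragment spanning two genes is counted in both. Gene identifiers must
    be unique.
    """
    if genes["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in gene models")
    genes = genes.reset_index(drop=True)
    cells = frags.cells
    cell_code = {c: i for i, c in enumerate(cells)}
    mat = np.zeros((len(genes), len(cells)), dtype=int)
    df = frags.df
    for chrom, gsub in genes.groupby("chrom"):
        sub = df[df["chrom"] == chrom]
        if sub.empty:
            continue
        fs = sub["start"].to_numpy()
        fe = sub["end"].to_numpy()
        codes = sub["cell"].map(cell_code).to_numpy()
        for gi, g in zip(gsub.index, gsub.itertuples()):
            mask = (fs < g.end) & (fe > g.start)
            if mask.any():
                mat[gi] += np.bincount(codes[mask], minlength=len(cells))
    counts = pd.DataFrame(mat, index=genes["gene_id"].to_numpy(), columns=cells)
    lib = df.groupby("cell").size().reindex(cells).fillna(0).astype(int)
    return CountMatrix(counts, lib, genes.reset_index(drop=True))


def total_cn_profile(cn: pd.DataFrame, scope: str) -> pd.DataFrame:
    """Total copy number segments for one scope (clone id or 'germline').

    Rows with haplotype BOTH carry the total directly; otherwise H1 and H2
    rows are summed on their common breakpoint grid.
    """
    sub = cn[cn["scope"] == scope]
    both = sub[sub["haplotype"] == "BOTH"]
    if len(both):
        return both[["chrom", "start", "end", "cn"]].reset_index(drop=True)
    rows = []
    for chrom, grp in sub.groupby("chrom"):
        cuts = sorted(set(grp["start"]).union(grp["end"]))
        for s, e in zip(cuts[:-1], cuts[1:]):
            tot = 0
            for _, r in grp.iterrows():
                if r["start"] <= s and r["end"] >= e:
                    tot += r["cn"]
            rows.append((chrom, s, e, tot))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "cn"])


def gene_cn(genes: pd.DataFrame, cn_profile: pd.DataFrame, default: int = 2) -> pd.Series:
    """Copy number per gene by majority overlap; ties go to the lower-coordinate segment."""
    out = {}
    for _, g in genes.iterrows():
        seg = cn_profile[(cn_profile["chrom"] == g["chrom"]) & (cn_profile["start"] < g["end"]) & (cn_profile["end"] > g["start"])]
        if seg.empty:
            out[g["gene_id"]] = default
            continue
        ov = np.minimum(seg["end"], g["end"]) - np.maximum(seg["start"], g["start"])
        seg = seg.assign(ov=ov).sort_values(["ov", "start"], ascending=[False, True])
        out[g["gene_id"]] = int(seg.iloc[0]["cn"])
    return pd.Series(out)


def normalize_counts(
    m: CountMatrix,
    cn: Optional[pd.DataFrame] = None,
    clone_of_cell: Optional[dict] = None,
    steps: tuple = ("cn", "rpm", "log2"),
    pseudo_cn: float = 0.5,
) -> NormalizedMatrix:
    """Copy-number, library-size (RPM) and log2 normalization of gene-body counts.

    With all steps enabled the value is
    log2( count * (2 / CN_gc) / library_size_c * 1e6 + 1 ). Steps compose and
    are individually skippable. CN 0 with a nonzero count is floored at
    ``pseudo_cn`` and logged rather than raising.
    """
    x = m.counts.astype(float).copy()
    log = []
    if "cn" in steps and cn is not None:
        scopes = sorted(cn["scope"].unique())
        cn_by_scope = {s: gene_cn(m.genes, total_cn_profile(cn, s)) for s in scopes}
        for cell in x.columns:
            scope = (clone_of_cell or {}).get(cell, "germline")
            if scope not in cn_by_scope:
                scope = "germline" if "germline" in cn_by_scope else scopes[0]
            cn_g = cn_by_scope[scope].reindex(x.index).fillna(2).astype(float)
            zero = cn_g == 0
            if zero.any():
                n_hit = int(((x[cell] > 0) & zero).sum())
                if n_hit:
                    log.append(f"cell {cell}: {n_hit} genes with CN 0 and nonzero count, floored at {pseudo_cn}")
            cn_g = cn_g.where(~zero, pseudo_cn)
            x[cell] = x[cell] * (2.0 / cn_g)
    if "rpm" in steps:
        lib = m.library_sizes.reindex(x.columns).replace(0, np.nan)
        x = x.div(lib, axis=1) * 1e6
        x = x.fillna(0.0)
    if "log2" in steps:
        x = np.log2(x + 1.0)
    return NormalizedMatrix(x, tuple(s for s in steps if s != "cn" or cn is not None), cn, log)


def batch_adjust(nm: NormalizedMatrix, batch_of_cell: dict) -> NormalizedMatrix:
    """Location-only batch adjustment on the log scale.

    Per gene, cells of each batch are re-centered to the gene's grand mean.
    Batches with fewer than 2 cells are passed through with a warning.
    """
    x = nm.values.copy()
    batches = pd.Series({c: batch_of_cell.get(c) for c in x.columns})
    if batches.isna().any():
        raise ValueError("every cell needs a batch label")
    grand = x.mean(axis=1)
    for b in batches.unique():
        cols = batches.index[batches == b]
        if len(cols) < 2:
            warnings.warn(f"batch {b!r} has < 2 cells; passed through unadjusted")
            continue
        shift = x[cols].mean(axis=1) - grand
        x[cols] = x[cols].sub(shift, axis=0)
    return NormalizedMatrix(x, nm.steps + ("batch",), nm.cn_table, list(nm.log))


def correlate_tracks(a, b) -> float:
    """Spearman rank correlation (average ranks for ties) of two tracks or vectors.

    Returns NaN (with a warning) when either input is constant, where the
    rank correlation is undefined.
    """
    va = a.concat() if isinstance(a, NOTrack) else np.asarray(a, dtype=float)
    vb = b.concat() if isinstance(b, NOTrack) else np.asarray(b, dtype=float)
    if va.shape != vb.shape:
        raise ValueError("tracks must have equal length")
    if va.size < 3:
        raise ValueError("need >= 3 entries")
    if np.all(va == va[0]) or np.all(vb == vb[0]):
        warnings.warn("constant track: Spearman correlation undefined")
        return float("nan")
    rho, _ = stats.spearmanr(va, vb)
    return float(rho)


def track_to_bedgraph(track: NOTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            vals = track.values[chrom]
            L = track.chrom_lengths[chrom]
            for i, v in enumerate(vals):
                s = i * track.bin_size
                fh.write(f"{chrom}\t{s}\t{min(s + track.bin_size, L)}\t{v:.6g}\n")


def counts_to_mtx(m: CountMatrix, prefix) -> None:
    """Write counts as MatrixMarket MTX plus row (genes) and column (cells) files."""
    from scipy import io as sio
    from scipy.sparse import csr_matrix

    sio.mmwrite(f"{prefix}.mtx", csr_matrix(m.counts.to_numpy()))
    pd.Series(m.counts.index).to_csv(f"{prefix}.genes.txt", index=False, header=False)
    pd.Series(m.counts.columns).to_csv(f"{prefix}.cells.txt", index=False, header=False)


def read_genes_bed(path) -> pd.DataFrame:
    """Read gene models from BED (>=4 columns; strand from column 6 when present)."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            p = line.split("\t")
            if len(p) < 4:
                raise ValueError(f"{path}: line {i}: expected >=4 BED fields for gene models")
            rows.append((p[3], p[0], int(p[1]), int(p[2]), p[5] if len(p) >= 6 else "+"))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def read_bed_intervals(path, id_prefix: str = "iv") -> pd.DataFrame:
    """Read BED3/BED6 intervals into chrom/start/end (+ name when present)."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            p = line.split("\t")
            if len(p) < 3:
                raise ValueError(f"{path}: line {i}: expected >=3 BED fields")
            name = p[3] if len(p) >= 4 else f"{id_prefix}{i}"
            strand = p[5] if len(p) >= 6 else "+"
            rows.append((p[0], int(p[1]), int(p[2]), name, strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
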