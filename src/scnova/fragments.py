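"""Single-cell fragment ingest, QC filtering, blacklisting and strand-state calling.

Strand-seq libraries retain the identity of the DNA template strand, so every
mono-nucleosomal fragment maps to either the Watson (W) or Crick (C) strand of
the reference. Per cell and chromosome the two parental homologs each
contribute one template strand, giving WW, CC or mixed (WC/CW) configurations;
mixed chromosomes allow direct haplotype separation of reads.

Fragments are held as a pandas DataFrame with one row per fragment and the
columns of :data:`FRAGMENT_COLUMNS`. Coordinates are 0-based half-open (BED
convention). The strand convention is fixed but arbitrary: W denotes the
reverse genome strand, C the forward strand; downstream logic only relies on
the distinction being consistent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

FRAGMENT_COLUMNS = [
    "chrom",
    "start",
    "end",
    "cell",
    "strand",
    "haplotype",
    "mapq",
    "dup",
    "suppl",
]

UNPHASED = "."


class StrandState(str, Enum):
    WW = "WW"
    CC = "CC"
    WC = "WC"
    CW = "CW"
    UNKNOWN = "UNKNOWN"

    @property
    def is_mixed(self) -> bool:
        return self in (StrandState.WC, StrandState.CW)


class FragmentParseError(ValueError):
    pass


@dataclass
class FragmentSet:
    """A QC-filtered collection of single-cell fragments.

    Attributes
    ----------
    df : pandas.DataFrame
        One row per fragment, columns ``FRAGMENT_COLUMNS``.
    provenance : list of str
        Human-readable log of the filters applied and records dropped.
    """

    df: pd.DataFrame
    provenance: list = field(default_factory=list)

    @property
    def cells(self) -> list:
        return sorted(self.df["cell"].unique())

    @property
    def n_fragments(self) -> int:
        return len(self.df)

    def subset(self, mask) -> "FragmentSet":
        return FragmentSet(self.df.loc[mask].reset_index(drop=True), list(self.provenance))

    def library_sizes(self) -> pd.Series:
        return self.df.groupby("cell").size()


@dataclass
class BlacklistRegions:
    """Artifact regions to exclude, as 0-based half-open intervals."""

    intervals: list  # of (chrom, start, end)

    @classmethod
    def from_bed(cls, path) -> "BlacklistRegions":
        ivs = []
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise FragmentParseError(f"{path}: line {i}: expected >=3 BED fields")
                ivs.append((parts[0], int(parts[1]), int(parts[2])))
        return cls(ivs)

    def trees(self) -> dict:
        out: dict = {}
        for chrom, start, end in self.intervals:
            out.setdefault(chrom, IntervalTree()).addi(start, end)
        return out


@dataclass
class StrandStateMap:
    """Per (cell, chromosome) template-strand state calls.

    ``entries`` has columns cell, chrom, state, n_fragments, watson_fraction.
    """

    entries: pd.DataFrame
    min_fragments: int

    def state(self, cell, chrom) -> StrandState:
        hit = self.entries[(self.entries["cell"] == cell) & (self.entries["chrom"] == chrom)]
        if hit.empty:
            return StrandState.UNKNOWN
        return StrandState(hit["state"].iloc[0])

    def mixed_mask(self, cells, chroms) -> np.ndarray:
        """Boolean per (cell, chrom) pair: True where the state is WC/CW."""
        key = self.entries.set_index(["cell", "chrom"])["state"]
        states = [key.get((c, ch), StrandState.UNKNOWN.value) for c, ch in zip(cells, chroms)]
        return np.array([s in ("WC", "CW") for s in states])


def _validate_frame(df: pd.DataFrame, origin: str) -> pd.DataFrame:
    missing = [c for c in FRAGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FragmentParseError(f"{origin}: missing columns {missing}")
    df = df[FRAGMENT_COLUMNS].copy()
    for col, dtype in [("start", int), ("end", int), ("mapq", int), ("dup", int), ("suppl", int)]:
        try:
            df[col] = df[col].astype(dtype)
        except (ValueError, TypeError) as exc:
            raise FragmentParseError(f"{origin}: column {col!r} not integer: {exc}") from exc
    bad = df["start"] >= df["end"]
    if bad.any():
        raise FragmentParseError(f"{origin}: {int(bad.sum())} records with start >= end")
    bad_strand = ~df["strand"].isin(["W", "C"])
    if bad_strand.any():
        raise FragmentParseError(f"{origin}: invalid strand values {sorted(df.loc[bad_strand, 'strand'].unique())}")
    df["haplotype"] = df["haplotype"].fillna(UNPHASED).replace({"": UNPHASED})
    bad_hap = ~df["haplotype"].isin(["H1", "H2", UNPHASED])
    if bad_hap.any():
        raise FragmentParseError(f"{origin}: invalid haplotype values {sorted(df.loc[bad_hap, 'haplotype'].unique())}")
    return df


def _read_fragment_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "cell": str})
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed file
        raise FragmentParseError(f"{path}: cannot parse fragment TSV: {exc}") from exc
    return _validate_frame(df, str(path))


def _read_fragment_bam(path) -> pd.DataFrame:
    """BAM reader: cell from CB tag or read group, haplotype from HP tag.

    A template is represented once by its leftmost (forward) alignment; the
    fragment interval is the full paired-end insert. Watson corresponds to the
    reverse genome strand.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_read2:
                continue
            if rec.is_paired:
                tlen = rec.template_length
                if tlen == 0:
                    continue
                if tlen > 0:
                    start, end = rec.reference_start, rec.reference_start + tlen
                else:
                    end = rec.reference_end
                    start = end + tlen
            else:
                start, end = rec.reference_start, rec.reference_end
            cell = rec.get_tag("CB") if rec.has_tag("CB") else (rec.get_tag("RG") if rec.has_tag("RG") else "cell0")
            hap = UNPHASED
            if rec.has_tag("HP"):
                hap = {1: "H1", 2: "H2"}.get(rec.get_tag("HP"), UNPHASED)
            rows.append(
                (
                    rec.reference_name,
                    int(start),
                    int(end),
                    str(cell),
                    "W" if rec.is_reverse else "C",
                    hap,
                    int(rec.mapping_quality),
                    int(rec.is_duplicate),
                    int(rec.is_supplementary),
                )
            )
    df = pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)
    return _validate_frame(df, str(path)) if len(df) else df


def read_fragments(
    path,
    mapq_min: int = 10,
    drop_dups: bool = True,
    drop_supplementary: bool = True,
) -> FragmentSet:
    """Read fragments from TSV (or BAM) and apply the standard QC filters.

    Records with MAPQ below ``mapq_min`` (default 10), duplicates and
    supplementary alignments are removed; per-category drop counts are logged
    in the returned set's provenance.
    """
    path = Path(path)
    if path.suffix.lower() == ".bam":
        df = _read_fragment_bam(path)
    else:
        df = _read_fragment_tsv(path)
    prov = [f"read {len(df)} records from {path}"]
    n0 = len(df)
    low_q = df["mapq"] < mapq_min
    df = df[~low_q]
    prov.append(f"dropped {int(low_q.sum())} records with mapq < {mapq_min}")
    if drop_dups:
        dups = df["dup"] == 1
        df = df[~dups]
        prov.append(f"dropped {int(dups.sum())} duplicate records")
    if drop_supplementary:
        sup = df["suppl"] == 1
        df = df[~sup]
        prov.append(f"dropped {int(sup.sum())} supplementary records")
    prov.append(f"retained {len(df)} of {n0} records")
    logger.info("; ".join(prov))
    return FragmentSet(df.reset_index(drop=True), prov)


def fragments_from_frame(df: pd.DataFrame) -> FragmentSet:
    """Wrap an in-memory DataFrame (already in the fragment schema)."""
    return FragmentSet(_validate_frame(df, "<frame>").reset_index(drop=True), ["from frame"])


def apply_blacklist(frags: FragmentSet, bl: BlacklistRegions) -> FragmentSet:
    """Drop fragments overlapping any blacklisted interval by >= 1 bp."""
    if not bl.intervals:
        return FragmentSet(frags.df.copy(), frags.provenance + ["blacklist: empty, no-op"])
    trees = bl.trees()
    df = frags.df
    unmatched = set(t for t in {c for c, _, _ in bl.intervals}) - set(df["chrom"].unique())
    if unmatched:
        warnings.warn(f"blacklist chromosomes absent from fragments: {len(unmatched)}")
    keep = np.ones(len(df), dtype=bool)
    for chrom, tree in trees.items():
        idx = np.flatnonzero((df["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            continue
        starts = df["start"].to_numpy()[idx]
        ends = df["end"].to_numpy()[idx]
        hit = np.array([bool(tree.overlap(s, e)) for s, e in zip(starts, ends)])
        keep[idx[hit]] = False
    dropped = int((~keep).sum())
    out = frags.df.loc[keep].reset_index(drop=True)
    return FragmentSet(out, frags.provenance + [f"blacklist: dropped {dropped} fragments"])


def classify_strand_states(
    frags: FragmentSet,
    min_fragments: int = 20,
    upper: float = 0.8,
    lower: float = 0.2,
) -> StrandStateMap:
    """Call WW/CC/WC/CW template-strand states per (cell, chromosome).

    A chromosome is WW when the Watson read fraction is >= ``upper``, CC when
    <= ``lower``, and mixed otherwise. Mixed chromosomes are labelled WC or CW
    using the haplotype tags when present (H1 reads predominantly Watson ->
    WC; predominantly Crick -> CW); without tags both mixed configurations are
    reported as WC, which is sufficient for the mixed-versus-pure gating used
    downstream. Pairs with fewer than ``min_fragments`` fragments are UNKNOWN.
    """
    if not (0.5 < upper <= 1.0) or not (0.0 <= lower < 0.5):
        raise ValueError(f"invalid strand-state thresholds upper={upper}, lower={lower}")
    if min_fragments < 1:
        raise ValueError("min_fragments must be >= 1")
    rows = []
    df = frags.df
    for (cell, chrom), grp in df.groupby(["cell", "chrom"], sort=True):
        n = len(grp)
        wfrac = float((grp["strand"] == "W").mean()) if n else np.nan
        if n < min_fragments:
            state = StrandState.UNKNOWN
        elif wfrac >= upper:
            state = StrandState.WW
        elif wfrac <= lower:
            state = StrandState.CC
        else:
            phased = grp[grp["haplotype"] != UNPHASED]
            h1 = phased[phased["haplotype"] == "H1"]
            if len(h1) >= 1:
                state = StrandState.WC if (h1["strand"] == "W").mean() >= 0.5 else StrandState.CW
            else:
                state = StrandState.WC
        rows.append((cell, chrom, state.value, n, wfrac))
    entries = pd.DataFrame(rows, columns=["cell", "chrom", "state", "n_fragments", "watson_fraction"])
    return StrandStateMap(entries, min_fragments)
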