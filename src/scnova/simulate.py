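"""Synthetic Strand-seq-like fragment data with known ground truth.

The generator emulates the data-generating process that nucleosome-occupancy
(NO) inference relies on: each cell belongs to a subclone (drawn by clonal
frequency, CF), each chromosome of each cell has a fixed template-strand
configuration (WW/CC/WC/CW), and mono-nucleosomal fragments of 140-180 bp are
sampled from the two haplotypes at a per-bp rate shaped by gene activity
(expressed genes are nucleosome-depleted relative to silent genes), subclonal
copy-number changes (a heterozygous deletion silences one haplotype, a
duplication doubles its rate) and per-gene activity or haplotype-specific
shifts carried by a clone. Library size varies per cell and per batch.

Every fragment is traceable to its clone and haplotype of origin through the
returned :class:`TruthTables`, which makes each downstream inference stage
testable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fragments import FragmentSet, UNPHASED
from .haplo import SVCall


class ConfigError(ValueError):
    pass


@dataclass
class CloneSpec:
    """A subclone: its clonal frequency, SVs and gene-activity effects.

    ``activity_shifts`` multiplies the NO sampling rate of a gene on both
    haplotypes (values > 1 mean more occupancy, i.e. lower activity);
    ``haplotype_effects`` maps gene -> {"H1": f, "H2": f} for cis effects.
    """

    clone_id: str
    cf: float
    svs: list = field(default_factory=list)
    activity_shifts: dict = field(default_factory=dict)
    haplotype_effects: dict = field(default_factory=dict)


@dataclass
class SimulationConfig:
    n_chroms: int = 1
    chrom_length: int = 2_000_000
    n_genes: int = 100
    gene_length_range: tuple = (5_000, 15_000)
    n_cells: int = 60
    fragments_per_cell: int = 8_000
    library_dispersion: float = 0.15  # lognormal sigma of per-cell depth
    nucleosome_repeat: int = 190
    fragment_length_range: tuple = (140, 180)
    expressed_fraction: float = 0.5
    no_depletion_factor: float = 2.0  # NO rate ratio silent / expressed
    clones: list = field(default_factory=lambda: [CloneSpec("clone1", 1.0)])
    batches: list = field(default_factory=lambda: [("batch1", 0.0)])  # (label, log-rate effect)
    phased_fraction: float = 1.0
    tad_size: int = 500_000
    cre_width: int = 500
    position_jitter: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        cfs = [c.cf for c in self.clones]
        if abs(sum(cfs) - 1.0) > 1e-9:
            raise ConfigError(f"clone CFs must sum to 1 (got {sum(cfs)})")
        if any(cf <= 0 for cf in cfs):
            raise ConfigError("clone CFs must be positive")
        for name in ("n_chroms", "chrom_length", "n_cells", "fragments_per_cell", "nucleosome_repeat", "tad_size"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_genes < 0:
            raise ConfigError("n_genes must be >= 0")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise ConfigError("invalid gene_length_range")
        if not (0.0 <= self.expressed_fraction <= 1.0):
            raise ConfigError("expressed_fraction must lie in [0, 1]")
        if self.no_depletion_factor <= 1.0:
            raise ConfigError("no_depletion_factor must be > 1")
        if not (0.0 <= self.phased_fraction <= 1.0):
            raise ConfigError("phased_fraction must lie in [0, 1]")
        # feasibility of gene packing
        per_chrom = -(-self.n_genes // self.n_chroms)
        if per_chrom * (hi + 1_000) > self.chrom_length:
            raise ConfigError("too many genes for the genome size")


@dataclass
class Genome:
    genes: pd.DataFrame  # gene_id, chrom, start, end, strand
    cres: pd.DataFrame  # chrom, start, end, cre_id
    tads: pd.DataFrame  # chrom, start, end, tad_id
    cn: pd.DataFrame  # scope, chrom, start, end, haplotype, cn (germline baseline)
    gene_truth: pd.DataFrame  # gene_id, expressed, expr_level, no_weight
    gc: dict  # chrom -> per-kb GC fraction
    chrom_lengths: dict


@dataclass
class TruthTables:
    cells: pd.DataFrame  # cell, clone, batch, lib_factor
    strand_states: pd.DataFrame  # cell, chrom, state (WW/CC/WC/CW)
    fragment_haplotype: np.ndarray  # true haplotype per fragment row
    gene_truth: pd.DataFrame
    clone_cn: pd.DataFrame  # scope=clone_id per-haplotype CN segments


def simulate_genome(cfg: SimulationConfig) -> Genome:
    """Lay out an abstract genome: genes, CREs, TADs, baseline copy number.

    Gene intervals are non-overlapping and evenly spaced; CREs sit in
    intergenic gaps; TADs tile each chromosome. Deterministic given the seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    chrom_lengths = {c: cfg.chrom_length for c in chroms}

    genes_rows, cre_rows, tad_rows, cn_rows = [], [], [], []
    lo, hi = cfg.gene_length_range
    gene_counter = 0
    per_chrom = np.full(cfg.n_chroms, cfg.n_genes // cfg.n_chroms)
    per_chrom[: cfg.n_genes % cfg.n_chroms] += 1
    for ci, chrom in enumerate(chroms):
        k = int(per_chrom[ci])
        if k > 0:
            lengths = rng.integers(lo, hi + 1, size=k)
            total = int(lengths.sum())
            if total >= cfg.chrom_length:
                raise ConfigError("too many genes for the genome size")
            gap = (cfg.chrom_length - total) // (k + 1)
            pos = gap
            prev_end = 0
            for L in lengths:
                strand = "+" if rng.random() < 0.5 else "-"
                genes_rows.append((f"g{gene_counter:05d}", chrom, int(pos), int(pos + L), strand))
                if pos - prev_end >= 4 * cfg.cre_width:
                    mid = (prev_end + pos) // 2
                    cre_rows.append((chrom, int(mid - cfg.cre_width // 2), int(mid + cfg.cre_width // 2), f"cre{len(cre_rows):05d}"))
                prev_end = pos + L
                pos = prev_end + gap
                gene_counter += 1
        for ti, ts in enumerate(range(0, cfg.chrom_length, cfg.tad_size)):
            tad_rows.append((chrom, ts, min(ts + cfg.tad_size, cfg.chrom_length), f"{chrom}_tad{ti}"))
        for hap in ("H1", "H2"):
            cn_rows.append(("germline", chrom, 0, cfg.chrom_length, hap, 1))

    genes = pd.DataFrame(genes_rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    expressed = rng.random(len(genes)) < cfg.expressed_fraction
    expr_level = np.where(expressed, rng.lognormal(0.0, 0.75, size=len(genes)), 0.0)
    # silent genes sample at no_depletion_factor x the per-bp rate of an
    # average expressed gene; occupancy decreases monotonically in expression
    no_weight = cfg.no_depletion_factor / (1.0 + expr_level)
    gene_truth = pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "expressed": expressed,
            "expr_level": expr_level,
            "no_weight": no_weight,
        }
    )
    gc = {c: rng.uniform(0.3, 0.7, size=-(-cfg.chrom_length // 1000)) for c in chroms}
    return Genome(
        genes=genes,
        cres=pd.DataFrame(cre_rows, columns=["chrom", "start", "end", "cre_id"]),
        tads=pd.DataFrame(tad_rows, columns=["chrom", "start", "end", "tad_id"]),
        cn=pd.DataFrame(cn_rows, columns=["scope", "chrom", "start", "end", "haplotype", "cn"]),
        gene_truth=gene_truth,
        gc=gc,
        chrom_lengths=chrom_lengths,
    )


def _segment_table(genome: Genome, cfg: SimulationConfig) -> pd.DataFrame:
    """Partition each chromosome at gene and SV boundaries.

    Every segment is homogeneous: it lies fully inside or outside any gene and
    any SV interval, so per-clone rates are piecewise constant on segments.
    """
    sv_bounds: dict = {}
    for clone in cfg.clones:
        for sv in clone.svs:
            sv_bounds.setdefault(sv.chrom, set()).update((sv.start, sv.end))
    rows = []
    for chrom, L in genome.chrom_lengths.items():
        cuts = {0, L}
        sub = genome.genes[genome.genes["chrom"] == chrom]
        cuts.update(sub["start"].tolist())
        cuts.update(sub["end"].tolist())
        cuts.update(b for b in sv_bounds.get(chrom, ()) if 0 <= b <= L)
        cuts = sorted(cuts)
        gene_iv = list(zip(sub["start"], sub["end"], sub["gene_id"]))
        for s, e in zip(cuts[:-1], cuts[1:]):
            gid = None
            for gs, ge, g in gene_iv:
                if s >= gs and e <= ge:
                    gid = g
                    break
            rows.append((chrom, s, e, gid))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def _clone_rates(segments: pd.DataFrame, genome: Genome, clone: CloneSpec, cfg: SimulationConfig):
    """Per-segment per-haplotype sampling weights and per-haplotype CN for a clone."""
    wmap = dict(zip(genome.gene_truth["gene_id"], genome.gene_truth["no_weight"]))
    base = segments["gene_id"].map(lambda g: wmap.get(g, 1.0)).to_numpy(float)
    shift = segments["gene_id"].map(lambda g: clone.activity_shifts.get(g, 1.0)).to_numpy(float)
    w = {h: base * shift for h in ("H1", "H2")}
    cn = {h: np.ones(len(segments)) for h in ("H1", "H2")}
    for hap in ("H1", "H2"):
        he = segments["gene_id"].map(
            lambda g: clone.haplotype_effects.get(g, {}).get(hap, 1.0) if g else 1.0
        ).to_numpy(float)
        w[hap] = w[hap] * he
    for sv in clone.svs:
        inside = (
            (segments["chrom"] == sv.chrom)
            & (segments["start"] >= sv.start)
            & (segments["end"] <= sv.end)
        ).to_numpy()
        haps = ("H1", "H2") if sv.haplotype == "UNKNOWN" else (sv.haplotype,)
        for hap in haps:
            if sv.sv_class == "DEL":
                w[hap][inside] = 0.0
                cn[hap][inside] = 0
            elif sv.sv_class in ("DUP", "INVDUP"):
                w[hap][inside] *= 2.0
                cn[hap][inside] = 2
            # INV/TRA/COMPLEX are copy-neutral: rates unchanged
    return w, cn


def simulate_cells(genome: Genome, cfg: SimulationConfig):
    """Sample per-cell fragments from the genome under the configured clones.

    Returns a :class:`FragmentSet` plus :class:`TruthTables`. Fragment starts
    sit on a nucleosome lattice (spacing ``nucleosome_repeat``) with Gaussian
    jitter; lengths are uniform on ``fragment_length_range``; the strand of a
    fragment is the template strand of its haplotype in that cell.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 1])
    chroms = list(genome.chrom_lengths)
    segments = _segment_table(genome, cfg)
    seg_len = (segments["end"] - segments["start"]).to_numpy(float)

    clone_ids = [c.clone_id for c in cfg.clones]
    cfs = np.array([c.cf for c in cfg.clones])
    cell_clone = rng.choice(len(cfg.clones), size=cfg.n_cells, p=cfs / cfs.sum())
    batch_labels = [b[0] for b in cfg.batches]
    batch_eff = {b[0]: b[1] for b in cfg.batches}
    cell_batch = rng.choice(len(batch_labels), size=cfg.n_cells)
    lib_factor = rng.lognormal(0.0, cfg.library_dispersion, size=cfg.n_cells)

    # per-clone categorical over (segment, haplotype)
    probs, clone_cn_rows = {}, []
    for clone in cfg.clones:
        w, cn = _clone_rates(segments, genome, clone, cfg)
        mass = np.concatenate([w["H1"] * seg_len, w["H2"] * seg_len])
        probs[clone.clone_id] = mass / mass.sum()
        for hap in ("H1", "H2"):
            for i, row in segments.iterrows():
                clone_cn_rows.append((clone.clone_id, row["chrom"], row["start"], row["end"], hap, int(cn[hap][i])))
    clone_cn = _merge_cn_rows(clone_cn_rows)

    # template strand per (cell, chrom, haplotype)
    templates = rng.choice(["W", "C"], size=(cfg.n_cells, len(chroms), 2))
    state_rows = []
    for i in range(cfg.n_cells):
        for j, chrom in enumerate(chroms):
            t1, t2 = templates[i, j, 0], templates[i, j, 1]
            state = {"WW": "WW", "CC": "CC", "WC": "WC", "CW": "CW"}[t1 + t2]
            state_rows.append((f"cell{i:04d}", chrom, state))

    flo, fhi = cfg.fragment_length_range
    seg_start = segments["start"].to_numpy()
    seg_chrom_idx = segments["chrom"].map({c: k for k, c in enumerate(chroms)}).to_numpy()
    n_lattice = np.maximum(1, (seg_len // cfg.nucleosome_repeat).astype(int))

    cols: dict = {k: [] for k in ("chrom", "start", "end", "cell", "strand", "haplotype", "mapq", "dup", "suppl")}
    true_hap_all = []
    n_seg = len(segments)
    for i in range(cfg.n_cells):
        cell = f"cell{i:04d}"
        clone = cfg.clones[cell_clone[i]]
        lam = cfg.fragments_per_cell * lib_factor[i] * np.exp(batch_eff[batch_labels[cell_batch[i]]])
        n = rng.poisson(lam)
        if n == 0:
            continue
        counts = rng.multinomial(n, probs[clone.clone_id])
        idx = np.repeat(np.arange(2 * n_seg), counts)
        seg_idx = idx % n_seg
        hap_idx = idx // n_seg  # 0 -> H1, 1 -> H2
        k = (rng.random(len(idx)) * n_lattice[seg_idx]).astype(int)
        centers = (
            seg_start[seg_idx]
            + cfg.nucleosome_repeat // 2
            + k * cfg.nucleosome_repeat
            + rng.normal(0.0, cfg.position_jitter, size=len(idx))
        )
        lens = rng.integers(flo, fhi + 1, size=len(idx))
        cidx = seg_chrom_idx[seg_idx]
        clen = np.array([genome.chrom_lengths[chroms[c]] for c in cidx])
        starts = np.clip(np.round(centers - lens / 2).astype(int), 0, clen - lens)
        strands = templates[i, cidx, hap_idx]
        true_hap = np.where(hap_idx == 0, "H1", "H2")
        tagged = rng.random(len(idx)) < cfg.phased_fraction
        hap_col = np.where(tagged, true_hap, UNPHASED)
        cols["chrom"].append(np.array(chroms)[cidx])
        cols["start"].append(starts)
        cols["end"].append(starts + lens)
        cols["cell"].append(np.full(len(idx), cell))
        cols["strand"].append(strands)
        cols["haplotype"].append(hap_col)
        cols["mapq"].append(np.full(len(idx), 60))
        cols["dup"].append(np.zeros(len(idx), dtype=int))
        cols["suppl"].append(np.zeros(len(idx), dtype=int))
        true_hap_all.append(true_hap)

    df = pd.DataFrame({k: np.concatenate(v) if v else np.array([], dtype=object) for k, v in cols.items()})
    if len(df):
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        df["mapq"] = df["mapq"].astype(int)
    frags = FragmentSet(df, [f"simulated {len(df)} fragments, seed={cfg.seed}"])
    truth = TruthTables(
        cells=pd.DataFrame(
            {
                "cell": [f"cell{i:04d}" for i in range(cfg.n_cells)],
                "clone": [clone_ids[c] for c in cell_clone],
                "batch": [batch_labels[b] for b in cell_batch],
                "lib_factor": lib_factor,
            }
        ),
        strand_states=pd.DataFrame(state_rows, columns=["cell", "chrom", "state"]),
        fragment_haplotype=np.concatenate(true_hap_all) if true_hap_all else np.array([], dtype=object),
        gene_truth=genome.gene_truth.copy(),
        clone_cn=clone_cn,
    )
    return frags, truth


def _merge_cn_rows(rows) -> pd.DataFrame:
    """Collapse adjacent equal-CN segments into maximal runs per scope/chrom/hap."""
    df = pd.DataFrame(rows, columns=["scope", "chrom", "start", "end", "haplotype", "cn"])
    out = []
    for (scope, chrom, hap), grp in df.groupby(["scope", "chrom", "haplotype"], sort=True):
        grp = grp.sort_values("start")
        cur = None
        for _, r in grp.iterrows():
            if cur is not None and r["start"] == cur[3] and r["cn"] == cur[5]:
                cur[3] = r["end"]
            else:
                if cur is not None:
                    out.append(tuple(cur))
                cur = [scope, chrom, r["start"], r["end"], hap, r["cn"]]
        if cur is not None:
            out.append(tuple(cur))
    return pd.DataFrame(out, columns=["scope", "chrom", "start", "end", "haplotype", "cn"])


def write_dataset(outdir, genome: Genome, frags: FragmentSet, truth: TruthTables, cfg: SimulationConfig) -> None:
    """Write the simulated dataset as plain-text files under one directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    frags.df.to_csv(out / "fragments.tsv", sep="\t", index=False)
    genome.genes[["chrom", "start", "end", "gene_id", "strand"]].assign(score=0)[
        ["chrom", "start", "end", "gene_id", "score", "strand"]
    ].to_csv(out / "genes.bed", sep="\t", index=False, header=False)
    genome.cres[["chrom", "start", "end", "cre_id"]].to_csv(out / "cres.bed", sep="\t", index=False, header=False)
    genome.tads[["chrom", "start", "end", "tad_id"]].to_csv(out / "tads.bed", sep="\t", index=False, header=False)
    pd.concat([genome.cn, truth.clone_cn]).to_csv(out / "cn_segments.tsv", sep="\t", index=False)
    truth.cells.to_csv(out / "clones.tsv", sep="\t", index=False)
    truth.strand_states.to_csv(out / "truth_strand_states.tsv", sep="\t", index=False)
    truth.gene_truth.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    sv_rows = []
    for clone in cfg.clones:
        for sv in clone.svs:
            sv_rows.append(
                (sv.sv_id, sv.sv_class, sv.chrom, sv.start, sv.end, sv.chrom2 or ".", sv.pos2 if sv.pos2 is not None else -1, sv.haplotype, clone.clone_id, clone.cf)
            )
    pd.DataFrame(
        sv_rows, columns=["sv_id", "class", "chrom", "start", "end", "chrom2", "pos2", "haplotype", "clone_id", "cf"]
    ).to_csv(out / "svs.tsv", sep="\t", index=False)
    with open(out / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["clones"] = [
        {
            "clone_id": c.clone_id,
            "cf": c.cf,
            "svs": [asdict(sv) for sv in c.svs],
            "activity_shifts": dict(c.activity_shifts),
            "haplotype_effects": {g: dict(v) for g, v in c.haplotype_effects.items()},
        }
        for c in cfg.clones
    ]
    d["gene_length_range"] = list(d["gene_length_range"])
    d["fragment_length_range"] = list(d["fragment_length_range"])
    d["batches"] = [list(b) for b in d["batches"]]
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "clones" in d:
        clones = []
        for c in d["clones"]:
            svs = [SVCall(**sv) for sv in c.get("svs", [])]
            clones.append(
                CloneSpec(
                    clone_id=c["clone_id"],
                    cf=float(c["cf"]),
                    svs=svs,
                    activity_shifts=c.get("activity_shifts", {}) or {},
                    haplotype_effects=c.get("haplotype_effects", {}) or {},
                )
            )
        d["clones"] = clones
    for key in ("gene_length_range", "fragment_length_range"):
        if key in d:
            d[key] = tuple(d[key])
    if "batches" in d:
        d["batches"] = [tuple(b) for b in d["batches"]]
    cfg = SimulationConfig(**d)
    cfg.validate()
    return cfg
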