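"""Synthetic ZW-chromosome datasets with known truth.

Generates a fully self-contained bundle — VCF, reference FASTA, toy CDS
GFF3, repeat BED, per-sample depth tracks, a sex-specific genetic map, a
rho track and truth tables — whose statistical structure matches the
analysis assumptions: a Z chromosome carrying a recombining PAR and a
non-recombining SLR separated by an assembly gap, a saddle-shaped female
recombination landscape (high at the distal end, a mid-PAR valley,
elevated again toward the PAR boundary), females hemizygous for Z inside
the SLR, optional W-linked scaffolds, and 5 + 5 diploid samples at ~35x.

Genotypes come from the package's own structured coalescent: one
genealogy per window at that window's (Ne, r_f), with infinite-sites
mutations dropped on branches at rate theta/2 per unit branch length.
Windows are independent — the design the site-by-site theory assumes — so
LD *between* generation windows is not modeled; :func:`ld_fixture`
provides small block-linked genotype panels for exercising the LD code.

Defaults are a 1:10 physical scale of an ostrich-like Z chromosome (5 Mb
PAR, 2 Mb SLR, 7.6 Kb gap) so a full pipeline run takes minutes; the
composite population-genetic parameters (theta = 4*Ne*mu = 0.0016 per
site, the rho/Kb landscape, the female:male map-length asymmetry) stay at
realistic values, with Ne reduced and mu raised to compensate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import zw_coalescent as zw
from .recmap import GenomicTrack, GeneticMapTable, kosambi
from .winstats import ANNOTATIONS, IntervalSet

__all__ = ["SynthConfig", "SynthBundle", "generate_dataset", "coverage_tracks",
           "map_fixture", "rho_track_from_landscape", "ld_fixture"]

FEMALES = [f"F{i}" for i in range(1, 6)]
MALES = [f"M{i}" for i in range(1, 6)]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the synthetic chromosome.

    The rho landscape is piecewise linear through ``rho_knots`` (bp,
    rho/Kb): 0.8 at the distal end, a 0.02 valley mid-PAR, rising to a
    0.65/Kb peak right at the PAR boundary, then declining to a 0.01
    floor just inside the SLR (held flat beyond the last knot) — the
    saddle shape produced when crossovers in the heterogametic sex are
    squeezed into the PAR.  The interior knots are the true change-points
    the segmentation analysis should recover.
    """

    par_length: int = 5_000_000
    slr_length: int = 2_000_000
    gap_length: int = 7_600
    ne: float = 2_500.0
    mu: float = 1.6e-7
    rho_knots: tuple = ((0, 0.80), (2_230_000, 0.02), (5_000_000, 0.65),
                        (5_360_000, 0.01))
    n_females: int = 5
    n_males: int = 5
    mean_depth: float = 35.0
    gen_window: int = 200_000          # one genealogy per this many bp
    rho_track_window: int = 50_000
    depth_bin: int = 5_000
    marker_spacing: int = 250_000
    male_map_factor: float = 0.53      # male/female total map-length ratio
    linked_selection_strength: float = 0.0  # theta ~ (rho/rho_mean)^strength
    fail_fraction: float = 0.02        # planted hard-filter failures
    slr_het_artifact_rate: float = 0.02  # planted female-het calls in the SLR
    include_w_scaffold: bool = True
    w_scaffold_length: int = 400_000
    chrom: str = "chrZ"
    w_chrom: str = "scaffold_W1"
    seed: int = 0

    def __post_init__(self):
        if min(self.par_length, self.slr_length, self.gap_length) <= 0:
            raise ValueError("all lengths must be positive")
        if self.gap_length >= self.slr_length:
            raise ValueError("assembly gap cannot exceed the SLR")
        if any(v < 0 for _, v in self.rho_knots):
            raise ValueError("rho landscape must be non-negative")

    @property
    def boundary(self) -> int:
        """PAR/SLR boundary bp; the assembly gap starts here."""
        return self.par_length

    @property
    def slr_start(self) -> int:
        return self.par_length + self.gap_length

    @property
    def chrom_length(self) -> int:
        return self.par_length + self.gap_length + self.slr_length

    @property
    def theta_site(self) -> float:
        return 4.0 * self.ne * self.mu

    def rho_per_kb(self, pos) -> np.ndarray:
        pos = np.asarray(pos, dtype=float)
        kx = np.array([k for k, _ in self.rho_knots], dtype=float)
        kv = np.array([v for _, v in self.rho_knots], dtype=float)
        return np.interp(pos, kx, kv)


@dataclass
class SynthBundle:
    """Paths and truth of one generated dataset."""

    outdir: Path
    vcf: Path
    fasta: Path
    gff: Path
    repeats_bed: Path
    depth_tsvs: dict[str, Path]
    map_tsv: Path
    rho_tsv: Path
    truth_windows: Path
    truth_json: Path
    config: SynthConfig = field(repr=False, default=None)

    @property
    def sexes(self) -> dict[str, str]:
        return {**{s: "F" for s in FEMALES[: self.config.n_females]},
                **{s: "M" for s in MALES[: self.config.n_males]}}

    @property
    def truth(self) -> dict:
        return json.loads(self.truth_json.read_text())


# ---------------------------------------------------------------------------
# component fixtures
# ---------------------------------------------------------------------------

def rho_track_from_landscape(cfg: SynthConfig) -> GenomicTrack:
    """Non-overlapping windowed rho/Kb track (window mean of the landscape)."""
    edges = np.unique(np.append(
        np.arange(0, cfg.chrom_length, cfg.rho_track_window), cfg.chrom_length))
    starts, ends = edges[:-1], edges[1:]
    vals = np.empty(len(starts))
    for i, (s, e) in enumerate(zip(starts, ends)):
        vals[i] = float(np.mean(cfg.rho_per_kb(np.linspace(s, e, 21))))
    return GenomicTrack.from_arrays(cfg.chrom, starts, ends, vals)


def _female_morgans(cfg: SynthConfig, pos) -> np.ndarray:
    """Cumulative female map distance (Morgans) from bp 0: integrates
    r per bp = (rho per bp)/(4 Ne); flat inside the SLR."""
    pos = np.asarray(pos, dtype=float)
    grid = np.linspace(0, cfg.boundary, 2001)
    r_bp = cfg.rho_per_kb(grid) / 1000.0 / (4.0 * cfg.ne)
    cum = np.concatenate([[0.0], np.cumsum((r_bp[1:] + r_bp[:-1]) / 2.0 * np.diff(grid))])
    return np.interp(np.minimum(pos, cfg.boundary), grid, cum)


def map_fixture(cfg: SynthConfig) -> GeneticMapTable:
    """Sex-specific genetic map with markers every ``marker_spacing`` bp.

    Female cM integrates the configured landscape (saddle-shaped, flat
    through the SLR, elevated near the boundary); the male map is a
    flatter linear profile that keeps recombining through the SLR.
    """
    pos = np.arange(0, cfg.chrom_length + 1, cfg.marker_spacing)
    if pos[-1] != cfg.chrom_length:
        pos = np.append(pos, cfg.chrom_length)
    cm_f = _female_morgans(cfg, pos) * 100.0
    total_f = float(_female_morgans(cfg, [cfg.boundary])[0] * 100.0)
    cm_m = cfg.male_map_factor * total_f / cfg.chrom_length * pos
    return GeneticMapTable(pd.DataFrame({
        "chrom": cfg.chrom, "pos": pos.astype(np.int64),
        "cm_female": np.round(cm_f, 6), "cm_male": np.round(cm_m, 6),
    }))


def coverage_tracks(cfg: SynthConfig, rng: np.random.Generator | None = None
                    ) -> dict[str, GenomicTrack]:
    """Per-sample binned depth tracks.

    Each bin's value is the mean per-bp depth over the bin, drawn as
    Poisson(mean * bin length) / bin length — read sampling averaged over
    the bin, so wider bins are smoother.  Female depth halves in the SLR
    (one Z instead of two), every sample drops to zero across the assembly
    gap, and on the W scaffold males retain only trace coverage
    (mismapping) while females sit at half depth.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    samples = [*FEMALES[: cfg.n_females], *MALES[: cfg.n_males]]
    edges = np.unique(np.append(
        np.arange(0, cfg.chrom_length, cfg.depth_bin), cfg.chrom_length))
    starts, ends = edges[:-1], edges[1:]
    mids = (starts + ends) / 2.0
    gap_frac = (np.clip(np.minimum(ends, cfg.slr_start)
                        - np.maximum(starts, cfg.boundary), 0, None)
                / (ends - starts))
    in_slr = mids >= cfg.boundary
    out: dict[str, GenomicTrack] = {}
    for s in samples:
        female = s.startswith("F")
        mean = np.full(len(mids), cfg.mean_depth)
        if female:
            mean[in_slr] = cfg.mean_depth / 2.0
        mean = mean * (1.0 - gap_frac)
        lens = (ends - starts).astype(float)
        depth = np.round(rng.poisson(np.maximum(mean, 0.0) * lens) / lens, 3)
        frames = [pd.DataFrame({"chrom": cfg.chrom, "start": starts,
                                "end": ends, "value": depth})]
        if cfg.include_w_scaffold:
            we = np.unique(np.append(
                np.arange(0, cfg.w_scaffold_length, cfg.depth_bin),
                cfg.w_scaffold_length))
            wmean = cfg.mean_depth / 2.0 if female else 0.02 * cfg.mean_depth
            wlens = (we[1:] - we[:-1]).astype(float)
            wd = np.round(rng.poisson(np.full(len(we) - 1, wmean) * wlens) / wlens, 3)
            frames.append(pd.DataFrame({"chrom": cfg.w_chrom, "start": we[:-1],
                                        "end": we[1:], "value": wd}))
        out[s] = GenomicTrack(pd.concat(frames, ignore_index=True))
    return out


def ld_fixture(n_individuals: int, n_blocks: int, block_len: int,
               theta_block: float, rng: np.random.Generator,
               ne: float = 1000.0) -> tuple[np.ndarray, np.ndarray]:
    """Diploid genotype panel with block-structured linkage.

    One single-population genealogy per ``block_len``-bp block, shared by
    all mutations inside the block: r^2 is therefore high within a block
    and at the sampling background between blocks, giving LD that decays
    with distance on the block scale.  Returns (positions bp, dosage
    matrix of shape n_sites x n_individuals).
    """
    labels = [(h // 2, "M", zw.Z) for h in range(2 * n_individuals)]
    model = zw.ZWDemeModel(ne=ne, r_f=0.0)
    positions, genos = [], []
    for b in range(n_blocks):
        gen = zw.simulate_genealogy(model, labels, rng)
        for carriers in zw.drop_mutations(gen, theta_block, rng):
            positions.append(int(b * block_len + rng.integers(block_len)))
            genos.append(carriers.reshape(n_individuals, 2).sum(axis=1))
    if not positions:
        return np.array([], dtype=int), np.zeros((0, n_individuals), dtype=int)
    order = np.argsort(positions)
    return (np.asarray(positions)[order],
            np.asarray(genos, dtype=np.int8)[order])


# ---------------------------------------------------------------------------
# the full bundle
# ---------------------------------------------------------------------------

_PASS_RANGES = {
    "QUAL": (60.0, 400.0), "QD": (10.0, 30.0), "MQ": (50.0, 60.0),
    "MQRankSum": (-2.0, 2.0), "FS": (0.0, 10.0),
    "ReadPosRankSum": (-2.0, 2.0), "SOR": (0.5, 2.0),
}
_FAIL_VALUES = {
    "QUAL": 10.0, "QD": 1.0, "MQ": 30.0, "MQRankSum": -20.0,
    "FS": 80.0, "ReadPosRankSum": -10.0, "SOR": 5.0,
}


def _generation_windows(cfg: SynthConfig) -> list[tuple[int, int]]:
    """Tiling of PAR and SLR by gen_window, never straddling boundary/gap."""
    windows = []
    pos0 = 0
    while pos0 < cfg.chrom_length:
        end = min(pos0 + cfg.gen_window, cfg.chrom_length)
        if pos0 < cfg.boundary < end:
            end = cfg.boundary
        if pos0 >= cfg.boundary and pos0 < cfg.slr_start:
            pos0 = cfg.slr_start
            continue
        windows.append((pos0, end))
        pos0 = end
    return windows


def _simulate_window_variants(cfg: SynthConfig, start: int, end: int,
                              r_f: float, rng: np.random.Generator,
                              theta_factor: float = 1.0):
    """One genealogy for [start, end) plus its mutations.

    PAR windows use the two-deme sample (each female one Z + one W
    lineage, each male two Z).  SLR windows use a Z-only sample in which
    each female contributes a single lineage; the per-individual dosage of
    a hemizygous female is doubled so the VCF shows the homozygous diploid
    call a naive caller would emit.  Returns (positions, per-sample dosage,
    hemizygous-female flag, realized TimeSummary).
    """
    in_slr = start >= cfg.boundary
    if in_slr:
        labels = ([(i, "F", zw.Z) for i in range(cfg.n_females)]
                  + [(cfg.n_females + h // 2, "M", zw.Z)
                     for h in range(2 * cfg.n_males)])
        model = zw.ZWDemeModel(ne=cfg.ne, r_f=0.0)
    else:
        labels = zw.SampleConfig(cfg.n_females, cfg.n_males).lineages()
        model = zw.ZWDemeModel(ne=cfg.ne, r_f=max(r_f, 1e-9))
    gen = zw.simulate_genealogy(model, labels, rng)
    summary = zw.summarize_times([gen])
    theta = cfg.theta_site * theta_factor * (end - start)
    muts = zw.drop_mutations(gen, theta, rng)
    n_samp = cfg.n_females + cfg.n_males
    positions = np.sort(rng.integers(start, end, size=len(muts)))
    dosages = np.zeros((len(muts), n_samp), dtype=np.int8)
    for mi, carriers in enumerate(muts):
        for li, (ind, _, _) in enumerate(labels):
            if carriers[li]:
                dosages[mi, ind] += 2 if (in_slr and ind < cfg.n_females) else 1
    return positions, dosages, in_slr, summary


def generate_dataset(cfg: SynthConfig, outdir) -> SynthBundle:
    """Write the complete synthetic bundle to ``outdir``.

    Deterministic for a given config (the seed is part of the config and
    echoed in every file header).  ``truth_windows.tsv`` records, per
    generation window, the model (Ne, r_f) and the REALIZED mean
    coalescence times of the simulated genealogy (T_t and the F_FM formula
    value) — the quantity window statistics should recover up to
    mutational sampling; ``truth.json`` records the boundary, gap,
    landscape knots, repeat intervals and every planted filter failure.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    prov = f"zwpar synth seed={cfg.seed}"

    gmap = map_fixture(cfg)
    rho = rho_track_from_landscape(cfg)
    depth_tracks = coverage_tracks(cfg, np.random.default_rng(cfg.seed + 1))

    repeats_bed = outdir / "repeats.bed"
    repeat_ivs = _write_repeats(cfg, repeats_bed, np.random.default_rng(cfg.seed + 3))
    repeat_set = IntervalSet(repeat_ivs)

    # --- genotypes, one genealogy per window ------------------------------
    map_pos = gmap.df["pos"].to_numpy(dtype=float)
    map_cm = gmap.df["cm_female"].to_numpy(dtype=float)
    cm_boundary = float(np.interp(cfg.boundary, map_pos, map_cm))
    all_pos, all_dose, all_hap = [], [], []
    truth_rows = []
    rho_ref = float(np.mean(cfg.rho_per_kb(
        np.linspace(0, cfg.boundary, 200))))
    for start, end in _generation_windows(cfg):
        mid = (start + end) / 2.0
        x = abs(cm_boundary - float(np.interp(mid, map_pos, map_cm))) / 100.0
        r_f = kosambi(x)
        # optional linked-selection emulation: local theta tracks local rho
        theta_factor = 1.0
        if cfg.linked_selection_strength:
            theta_factor = float(
                (max(cfg.rho_per_kb(mid), 1e-3) / rho_ref)
                ** cfg.linked_selection_strength)
        p, d, hap, summ = _simulate_window_variants(cfg, start, end, r_f, rng,
                                                    theta_factor=theta_factor)
        all_pos.append(p)
        all_dose.append(d)
        all_hap.append(np.full(len(p), hap))
        # SLR: the locus is Z-linked only, so the population mean pair time
        # is the Z-deme mean (expectation 0.75 in 2Ne units)
        t_t = summ.t_zz if hap else summ.t_t
        truth_rows.append({
            "chrom": cfg.chrom, "start": start, "end": end,
            "region": "SLR" if hap else "PAR",
            "r_f": 0.0 if hap else r_f, "ne": cfg.ne,
            "t_t": t_t, "expected_pi": cfg.theta_site * theta_factor * t_t,
            "fst_fm": np.nan if hap else zw.fst_from_times(summ),
            "n_snps": len(p),
        })
    positions = np.concatenate(all_pos)
    dosages = np.vstack(all_dose)
    hap_flags = np.concatenate(all_hap)
    # unique positions (infinite sites on a finite grid) outside repeats
    _, keep = np.unique(positions, return_index=True)
    keep = keep[~repeat_set.contains(cfg.chrom, positions[keep])]
    keep.sort()
    positions, dosages, hap_flags = positions[keep], dosages[keep], hap_flags[keep]

    # --- site annotations, depths, planted failures ------------------------
    n_sites = len(positions)
    n_samp = cfg.n_females + cfg.n_males
    ann = {a: rng.uniform(*_PASS_RANGES[a], size=n_sites)
           for a in ("QUAL",) + ANNOTATIONS}
    site_depth = rng.poisson(cfg.mean_depth, size=(n_sites, n_samp)).astype(np.int32)
    hemi = hap_flags[:, None] & (np.arange(n_samp) < cfg.n_females)[None, :]
    half = rng.poisson(cfg.mean_depth / 2.0, size=(n_sites, n_samp)).astype(np.int32)
    site_depth = np.where(hemi, half, site_depth)
    site_depth = np.maximum(site_depth, 6)  # keep unplanted sites inside bounds
    depth_hi = int(2 * cfg.mean_depth * n_samp)
    rules = list(_FAIL_VALUES) + ["depth_low", "depth_high"]
    n_fail = int(round(cfg.fail_fraction * n_sites))
    fail_idx = (rng.choice(n_sites, size=n_fail, replace=False)
                if n_fail else np.array([], dtype=int))
    planted = []
    for i in fail_idx:
        rule = rules[int(rng.integers(len(rules)))]
        if rule == "depth_low":
            site_depth[i] = 0
            site_depth[i, 0] = 3
        elif rule == "depth_high":
            site_depth[i] = depth_hi // n_samp + 5
        else:
            ann[rule][i] = _FAIL_VALUES[rule]
        planted.append({"pos": int(positions[i]) + 1, "rule": rule})

    # --- planted SLR female-het artifacts ----------------------------------
    genotypes = dosages.copy()
    slr_sites = np.where(hap_flags)[0]
    n_art = int(round(cfg.slr_het_artifact_rate * len(slr_sites) * cfg.n_females))
    artifacts = []
    if n_art and len(slr_sites):
        si = rng.choice(slr_sites, size=n_art, replace=False)
        fj = rng.integers(cfg.n_females, size=n_art)
        for i, j in zip(si, fj):
            genotypes[i, j] = 1           # impossible het for a hemizygous Z
            artifacts.append({"pos": int(positions[i]) + 1, "sample": FEMALES[j]})

    # --- write everything ---------------------------------------------------
    fasta = outdir / "reference.fa"
    _write_fasta(cfg, fasta, np.random.default_rng(cfg.seed + 2))
    gff = outdir / "annotation.gff3"
    _write_gff(cfg, gff)
    vcf = outdir / "variants.vcf"
    _write_vcf(cfg, vcf, positions, genotypes, ann, site_depth, prov)
    map_tsv = outdir / "genetic_map.tsv"
    gmap.write_tsv(map_tsv, header_comment=(
        f"{prov}; female map length {float(map_cm[-1]):.3f} cM"))
    rho_tsv = outdir / "rho_track.tsv"
    rho.write_tsv(rho_tsv, header_comment=prov)
    depth_paths = {}
    for s, tr in depth_tracks.items():
        path = outdir / f"depth_{s}.tsv"
        tr.write_tsv(path, header_comment=prov)
        depth_paths[s] = path
    truth_windows = outdir / "truth_windows.tsv"
    with open(truth_windows, "w") as fh:
        fh.write(f"# {prov}\n")
        pd.DataFrame(truth_rows).to_csv(fh, sep="\t", index=False)
    truth_json = outdir / "truth.json"
    truth_json.write_text(json.dumps({
        "seed": cfg.seed,
        "boundary_bp": cfg.boundary,
        "gap": [cfg.boundary, cfg.slr_start],
        "gap_length": cfg.gap_length,
        "slr": [cfg.slr_start, cfg.chrom_length],
        "rho_knots": [list(k) for k in cfg.rho_knots],
        "breakpoints_bp": [int(k) for k, _ in cfg.rho_knots[1:]],
        "theta_site": cfg.theta_site,
        "planted_failures": planted,
        "slr_het_artifacts": artifacts,
        "repeat_intervals": [list(iv) for iv in repeat_ivs],
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
    }, indent=1))
    return SynthBundle(outdir=outdir, vcf=vcf, fasta=fasta, gff=gff,
                       repeats_bed=repeats_bed, depth_tsvs=depth_paths,
                       map_tsv=map_tsv, rho_tsv=rho_tsv,
                       truth_windows=truth_windows, truth_json=truth_json,
                       config=cfg)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _write_fasta(cfg: SynthConfig, path: Path, rng: np.random.Generator,
                 gc: float = 0.41, line: int = 80) -> None:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    with open(path, "w") as fh:
        fh.write(f">{cfg.chrom}\n")
        seq = rng.choice(alphabet, size=cfg.chrom_length, p=p)
        seq[cfg.boundary: cfg.slr_start] = ord("N")  # assembly gap
        _dump_seq(fh, seq, line)
        if cfg.include_w_scaffold:
            fh.write(f">{cfg.w_chrom}\n")
            _dump_seq(fh, rng.choice(alphabet, size=cfg.w_scaffold_length, p=p), line)


def _dump_seq(fh, seq: np.ndarray, line: int) -> None:
    for i in range(0, len(seq), line):
        fh.write(seq[i: i + line].tobytes().decode("ascii"))
        fh.write("\n")


def _write_gff(cfg: SynthConfig, path: Path, rng: np.random.Generator | None = None,
               mean_spacing: int = 50_000, mean_cds: int = 1_000) -> None:
    """Toy gene models with variable spacing/length so CDS density differs
    between windows."""
    rng = np.random.default_rng(cfg.seed + 4) if rng is None else rng
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {cfg.chrom} 1 {cfg.chrom_length}\n")
        gid = 0
        start = 10_000
        while start < cfg.chrom_length - 3 * mean_cds:
            cds_len = max(int(rng.exponential(mean_cds)), 150)
            if cfg.boundary - cds_len < start < cfg.slr_start:
                start = cfg.slr_start + int(rng.exponential(mean_spacing))
                continue
            gid += 1
            s, e = start + 1, min(start + cds_len, cfg.chrom_length)  # 1-based incl.
            fh.write(f"{cfg.chrom}\tsynth\tgene\t{s}\t{e}\t.\t+\t.\tID=gene{gid}\n")
            fh.write(f"{cfg.chrom}\tsynth\tmRNA\t{s}\t{e}\t.\t+\t.\t"
                     f"ID=mrna{gid};Parent=gene{gid}\n")
            fh.write(f"{cfg.chrom}\tsynth\tCDS\t{s}\t{e}\t.\t+\t0\t"
                     f"ID=cds{gid};Parent=mrna{gid}\n")
            start += cds_len + int(rng.exponential(mean_spacing))


def _write_repeats(cfg: SynthConfig, path: Path, rng: np.random.Generator,
                   density: float = 0.08, mean_len: int = 400) -> list:
    """Random repeat intervals covering ~density of the chromosome."""
    ivs = []
    pos = 0
    while pos < cfg.chrom_length:
        start = pos + int(rng.exponential(mean_len * (1 - density) / density))
        if start >= cfg.chrom_length:
            break
        end = min(start + max(int(rng.exponential(mean_len)), 50), cfg.chrom_length)
        ivs.append((cfg.chrom, int(start), int(end)))
        pos = end
    with open(path, "w") as fh:
        for chrom, s, e in ivs:
            fh.write(f"{chrom}\t{s}\t{e}\n")
    return ivs


def _write_vcf(cfg: SynthConfig, path: Path, positions, genotypes,
               ann, site_depth, prov: str) -> None:
    samples = [*FEMALES[: cfg.n_females], *MALES[: cfg.n_males]]
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={prov}\n")
        fh.write(f"##contig=<ID={cfg.chrom},length={cfg.chrom_length}>\n")
        for a in ANNOTATIONS:
            fh.write(f'##INFO=<ID={a},Number=1,Type=Float,Description="{a}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for i, pos in enumerate(positions):
            info = ";".join(f"{a}={ann[a][i]:.3f}" for a in ANNOTATIONS)
            gts = "\t".join(f"{gt_codes[int(genotypes[i, j])]}:{int(site_depth[i, j])}"
                            for j in range(len(samples)))
            fh.write(f"{cfg.chrom}\t{pos + 1}\t.\tA\tT\t{ann['QUAL'][i]:.1f}\t.\t"
                     f"{info}\tGT:DP\t{gts}\n")
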