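"""Window-based population-genomic statistics from genotype data.

Implements the statistics computed in 200-Kb windows along the Z
chromosome: nucleotide diversity pi, Watterson's theta, Tajima's D,
female-male F_ST (Weir & Cockerham), pairwise LD (r^2) with decay curves,
and GC / CDS annotation fractions — together with the hard-filtering rules
applied to the variant calls (GATK-style site annotations, depth bounds,
repeat masking, and haploidization of female calls inside the sex-linked
region, where females carry a single Z).

Coordinate conventions: VCF positions are 1-based; all internal intervals
(windows, BED, interval sets) are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .recmap import GenomicTrack

logger = logging.getLogger(__name__)

__all__ = [
    "IntervalSet",
    "VariantTable",
    "FilterConfig",
    "make_windows",
    "apply_variant_filters",
    "accessible_sites",
    "diversity_window",
    "windowed_diversity",
    "fst_fm_window",
    "windowed_fst_fm",
    "hwe_exact_p",
    "ld_pairs",
    "ld_decay",
    "annotation_tracks",
]

MISSING = -1  # sentinel in alt-count / ploidy arrays


# ---------------------------------------------------------------------------
# intervals and windows
# ---------------------------------------------------------------------------

class IntervalSet:
    """Merged 0-based half-open intervals per chromosome (BED semantics)."""

    def __init__(self, intervals):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if end < start:
                raise ValueError(f"inverted interval {chrom}:{start}-{end}")
            by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            self._starts[chrom] = np.array([s for s, _ in merged], dtype=np.int64)
            self._ends[chrom] = np.array([e for _, e in merged], dtype=np.int64)

    @classmethod
    def read_bed(cls, path) -> "IntervalSet":
        ivs = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                ivs.append((f[0], int(f[1]), int(f[2])))
        return cls(ivs)

    def contains(self, chrom: str, pos0) -> np.ndarray:
        """Membership of 0-based positions (vectorized)."""
        pos0 = np.atleast_1d(np.asarray(pos0, dtype=np.int64))
        starts = self._starts.get(chrom)
        if starts is None or len(starts) == 0:
            return np.zeros(len(pos0), dtype=bool)
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = idx >= 0
        out = np.zeros(len(pos0), dtype=bool)
        out[ok] = pos0[ok] < self._ends[chrom][idx[ok]]
        return out

    def overlap_mask(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Boolean per-bp mask of [start, end) covered by the set."""
        mask = np.zeros(end - start, dtype=bool)
        starts = self._starts.get(chrom)
        if starts is None:
            return mask
        ends = self._ends[chrom]
        for s, e in zip(starts, ends):
            lo, hi = max(s, start), min(e, end)
            if lo < hi:
                mask[lo - start: hi - start] = True
        return mask


def make_windows(chrom_lengths: dict[str, int], size: int, step: int | None = None):
    """Window grid anchored at 0: list of (chrom, start, end).

    ``step < size`` yields overlapping windows (e.g. 200 Kb / 50 Kb overlap
    uses step = 150 Kb); the terminal window is truncated at the
    chromosome end.
    """
    step = size if step is None else step
    out = []
    for chrom, length in chrom_lengths.items():
        start = 0
        while start < length:
            out.append((chrom, start, min(start + size, length)))
            if start + size >= length:
                break
            start += step
    return out


# ---------------------------------------------------------------------------
# variant container
# ---------------------------------------------------------------------------

ANNOTATIONS = ("QD", "MQ", "MQRankSum", "FS", "ReadPosRankSum", "SOR")


@dataclass
class VariantTable:
    """Biallelic SNP genotypes with sex labels and mixed ploidy.

    ``sites`` holds chrom, pos (1-based), ref, alt, QUAL and the GATK site
    annotations.  ``alt_counts[i, j]`` is the number of alternate alleles
    carried by sample j at site i (-1 = missing call) and ``ploidy[i, j]``
    the number of called chromosomes (2 diploid, 1 haploid, 0 missing);
    ``depth[i, j]`` the per-sample read depth.
    """

    sites: pd.DataFrame = field(repr=False)
    samples: list[str]
    sexes: np.ndarray                       # 'F' / 'M' per sample
    alt_counts: np.ndarray = field(repr=False)
    ploidy: np.ndarray = field(repr=False)
    depth: np.ndarray = field(repr=False)

    def __post_init__(self):
        n, m = self.alt_counts.shape
        if len(self.sites) != n or len(self.samples) != m:
            raise ValueError("inconsistent VariantTable shapes")
        if set(np.unique(self.sexes)) - {"F", "M"}:
            raise ValueError("sex labels must be 'F' or 'M'")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def subset(self, mask: np.ndarray) -> "VariantTable":
        return replace(
            self,
            sites=self.sites[mask].reset_index(drop=True),
            alt_counts=self.alt_counts[mask],
            ploidy=self.ploidy[mask],
            depth=self.depth[mask],
        )

    def in_window(self, chrom: str, start: int, end: int) -> "VariantTable":
        pos0 = self.sites["pos"].to_numpy() - 1
        mask = (self.sites["chrom"].to_numpy() == chrom) & (pos0 >= start) & (pos0 < end)
        return self.subset(mask)

    @classmethod
    def from_vcf(cls, path, sexes: dict[str, str]) -> "VariantTable":
        """Read biallelic SNPs from a VCF (other records are skipped)."""
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=True)
        samples = list(vcf.samples)
        missing_sex = [s for s in samples if s not in sexes]
        if missing_sex:
            raise ValueError(f"no sex label for samples: {missing_sex}")
        sex_arr = np.array([sexes[s] for s in samples])
        rows, acs, pls, dps = [], [], [], []
        for v in vcf:
            if not v.is_snp or len(v.ALT) != 1:
                continue
            rec = {"chrom": v.CHROM, "pos": v.POS, "ref": v.REF, "alt": v.ALT[0],
                   "QUAL": v.QUAL if v.QUAL is not None else np.nan}
            for ann in ANNOTATIONS:
                val = v.INFO.get(ann)
                rec[ann] = float(val) if val is not None else np.nan
            rows.append(rec)
            ac = np.full(len(samples), MISSING, dtype=np.int8)
            pl = np.zeros(len(samples), dtype=np.int8)
            for j, gt in enumerate(v.genotypes):
                alleles = [a for a in gt[:-1] if a >= 0]
                if alleles:
                    ac[j] = sum(alleles)
                    pl[j] = len(alleles)
            acs.append(ac)
            pls.append(pl)
            d = v.format("DP")
            if d is None:
                dps.append(np.zeros(len(samples), dtype=np.int32))
            else:
                dps.append(np.where(d[:, 0] < 0, 0, d[:, 0]).astype(np.int32))
        sites = pd.DataFrame(rows) if rows else pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "QUAL", *ANNOTATIONS])
        shape = (len(rows), len(samples))
        return cls(
            sites=sites, samples=samples, sexes=sex_arr,
            alt_counts=np.array(acs, dtype=np.int8).reshape(shape),
            ploidy=np.array(pls, dtype=np.int8).reshape(shape),
            depth=np.array(dps, dtype=np.int32).reshape(shape),
        )


# ---------------------------------------------------------------------------
# hard filters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterConfig:
    """Hard-filter thresholds.  A site is REMOVED when QUAL < qual_min,
    QD < qd_min, MQ < mq_min, MQRankSum < mqranksum_min, FS > fs_max,
    ReadPosRankSum < readpos_min, SOR > sor_max, or its summed depth falls
    outside [depth_min, depth_max] (bounds inclusive: depth_max reads kept,
    depth_max + 1 removed)."""

    qual_min: float = 30.0
    qd_min: float = 2.0
    mq_min: float = 40.0
    mqranksum_min: float = -12.5
    fs_max: float = 60.0
    readpos_min: float = -8.0
    sor_max: float = 3.0
    depth_min: int = 5
    depth_max: int = 70


def apply_variant_filters(raw: VariantTable,
                          repeats: IntervalSet | None = None,
                          slr: IntervalSet | None = None,
                          config: FilterConfig = FilterConfig()):
    """Hard-filter a variant table; returns (filtered table, removal counts).

    Filters are pure site predicates, so the surviving set is independent
    of application order.  A missing annotation passes that criterion
    (logged).  Inside the SLR, female genotypes are haploidized: females
    carry a single Z there, so a homozygous diploid call becomes a haploid
    call and a heterozygous call — necessarily an artifact (often
    cross-mapping from a diverged W gametolog) — is dropped; counts of
    haploidized and dropped calls are reported alongside per-rule site
    counts.
    """
    s = raw.sites
    n = raw.n_sites

    def low(col, thr):
        v = s[col].to_numpy(dtype=float)
        nm = np.isnan(v)
        if nm.any():
            logger.info("%d sites missing %s; they pass that filter", nm.sum(), col)
        return np.where(nm, False, v < thr)

    def high(col, thr):
        v = s[col].to_numpy(dtype=float)
        return np.where(np.isnan(v), False, v > thr)

    total_depth = raw.depth.sum(axis=1)
    fails = {
        "QUAL": low("QUAL", config.qual_min),
        "QD": low("QD", config.qd_min),
        "MQ": low("MQ", config.mq_min),
        "MQRankSum": low("MQRankSum", config.mqranksum_min),
        "FS": high("FS", config.fs_max),
        "ReadPosRankSum": low("ReadPosRankSum", config.readpos_min),
        "SOR": high("SOR", config.sor_max),
        "depth": (total_depth < config.depth_min) | (total_depth > config.depth_max),
    }
    if repeats is not None:
        rep = np.zeros(n, dtype=bool)
        for chrom in s["chrom"].unique():
            m = (s["chrom"] == chrom).to_numpy()
            rep[m] = repeats.contains(chrom, s.loc[m, "pos"].to_numpy() - 1)
        fails["repeat"] = rep

    removed = np.zeros(n, dtype=bool)
    counts = {}
    for rule, mask in fails.items():
        counts[rule] = int(mask.sum())
        removed |= mask
    out = raw.subset(~removed)

    counts["slr_female_het_dropped"] = 0
    counts["slr_female_haploidized"] = 0
    if slr is not None and out.n_sites:
        females = out.sexes == "F"
        in_slr = np.zeros(out.n_sites, dtype=bool)
        for chrom in out.sites["chrom"].unique():
            m = (out.sites["chrom"] == chrom).to_numpy()
            in_slr[m] = slr.contains(chrom, out.sites.loc[m, "pos"].to_numpy() - 1)
        ac = out.alt_counts.copy()
        pl = out.ploidy.copy()
        region = np.ix_(np.where(in_slr)[0], np.where(females)[0])
        sub_ac, sub_pl = ac[region], pl[region]
        het = (sub_pl == 2) & (sub_ac == 1)
        hom = (sub_pl == 2) & ((sub_ac == 0) | (sub_ac == 2))
        counts["slr_female_het_dropped"] = int(het.sum())
        counts["slr_female_haploidized"] = int(hom.sum())
        sub_ac[het] = MISSING
        sub_pl[het] = 0
        sub_ac[hom] //= 2
        sub_pl[hom] = 1
        ac[region], pl[region] = sub_ac, sub_pl
        out = replace(out, alt_counts=ac, ploidy=pl)
    counts["removed_sites"] = int(removed.sum())
    counts["kept_sites"] = out.n_sites
    return out, counts


def accessible_sites(depth_tracks: dict[str, GenomicTrack],
                     repeat_mask: IntervalSet | None,
                     windows,
                     depth_min: int = 5, depth_max: int = 70) -> np.ndarray:
    """Per-window count of accessible (callable) positions.

    A position is accessible when it is not repeat-masked and the summed
    depth across samples lies within [depth_min, depth_max].  This count is
    the denominator L of per-site diversity statistics; using it rather
    than the window length keeps pi comparable between windows with
    different callable fractions.  Depth tracks are run-length encoded
    (chrom, start, end, value) per sample.
    """
    out = np.zeros(len(windows), dtype=np.int64)
    for wi, (chrom, start, end) in enumerate(windows):
        total = np.zeros(end - start)
        seen = np.zeros(end - start, dtype=bool)
        for track in depth_tracks.values():
            sub = track.on(chrom)
            for s0, e0, v in zip(sub["start"].to_numpy(), sub["end"].to_numpy(),
                                 sub["value"].to_numpy()):
                lo, hi = max(s0, start), min(e0, end)
                if lo < hi:
                    total[lo - start: hi - start] += v
                    seen[lo - start: hi - start] = True
        if not seen.all():
            raise ValueError(
                f"window {chrom}:{start}-{end} extends beyond the depth tracks")
        ok = (total >= depth_min) & (total <= depth_max)
        if repeat_mask is not None:
            ok &= ~repeat_mask.overlap_mask(chrom, start, end)
        out[wi] = int(ok.sum())
    return out


# ---------------------------------------------------------------------------
# diversity statistics
# ---------------------------------------------------------------------------

def _harmonics(n: int) -> tuple[float, float]:
    i = np.arange(1, n)
    return float(np.sum(1.0 / i)), float(np.sum(1.0 / i**2))


def _site_counts(vt: VariantTable):
    """Per-site alternate-allele count k and called chromosome number n."""
    called = vt.alt_counts != MISSING
    k = np.where(called, vt.alt_counts, 0).sum(axis=1)
    n = np.where(called, vt.ploidy, 0).sum(axis=1)
    return k.astype(np.int64), n.astype(np.int64)


def diversity_window(vt: VariantTable, L: int, chrom: str, start: int, end: int):
    """(S, pi, theta_W, Tajima's D) for one window.

    Per segregating site with k alternate alleles among n called
    chromosomes, pi_site = 2 k (n-k) / (n (n-1)); window pi and Watterson's
    theta are per accessible site (denominator ``L``).  Tajima's D uses the
    standard normalization constants evaluated at the modal n among the
    window's segregating sites, and is reported as NaN when S = 0.
    """
    if L <= 0:
        raise ValueError("accessible length L must be positive")
    sub = vt.in_window(chrom, start, end)
    k, n = _site_counts(sub)
    usable = n >= 2
    if (~usable & (n > 0)).any() or (n == 0).any():
        skipped = int((~usable).sum())
        if skipped:
            logger.info("window %s:%d-%d: %d sites with <2 called chromosomes skipped",
                        chrom, start, end, skipped)
    k, n = k[usable], n[usable]
    seg = (k > 0) & (k < n)
    k, n = k[seg], n[seg]
    S = int(seg.sum())
    if S == 0:
        return {"S": 0, "pi": 0.0, "theta_w": 0.0, "tajima_d": np.nan}
    pi_sites = 2.0 * k * (n - k) / (n * (n - 1.0))
    pi_sum = float(pi_sites.sum())
    n_modal = int(np.bincount(n).argmax())
    a1, a2 = _harmonics(n_modal)
    theta_sum = S / a1
    nn = n_modal
    b1 = (nn + 1.0) / (3.0 * (nn - 1.0))
    b2 = 2.0 * (nn * nn + nn + 3.0) / (9.0 * nn * (nn - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (nn + 2.0) / (a1 * nn) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1.0)
    d = (pi_sum - theta_sum) / np.sqrt(var) if var > 0 else np.nan
    return {"S": S, "pi": pi_sum / L, "theta_w": theta_sum / L, "tajima_d": float(d)}


def windowed_diversity(vt: VariantTable, windows, L: np.ndarray) -> pd.DataFrame:
    rows = []
    for (chrom, start, end), l in zip(windows, L):
        if l <= 0:
            rows.append({"chrom": chrom, "start": start, "end": end, "L": int(l),
                         "S": 0, "pi": np.nan, "theta_w": np.nan, "tajima_d": np.nan})
            continue
        stats = diversity_window(vt, int(l), chrom, start, end)
        rows.append({"chrom": chrom, "start": start, "end": end, "L": int(l), **stats})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# female-male F_ST
# ---------------------------------------------------------------------------

def _wc_components(k_pop, n_pop, h_pop):
    """Weir & Cockerham (1984) per-site variance components for 2 pops.

    ``n_pop`` are sample sizes in diploid-individual equivalents (called
    chromosomes / 2, so haploid calls contribute 1/2), ``k_pop`` alternate
    allele counts and ``h_pop`` observed heterozygote frequencies.
    """
    r = 2.0
    n_i = np.asarray(n_pop, dtype=float)
    p_i = np.asarray(k_pop, dtype=float) / (2.0 * n_i)
    h_i = np.asarray(h_pop, dtype=float)
    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1.0)
    pbar = (n_i * p_i).sum() / (r * nbar)
    s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1.0) * nbar)
    hbar = (n_i * h_i).sum() / (r * nbar)
    if nbar <= 1 or nc <= 0:
        return np.nan, np.nan, np.nan
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
    c = hbar / 2.0
    return a, b, c


def fst_fm_window(vt: VariantTable, chrom: str, start: int, end: int) -> float:
    """Weir & Cockerham F_ST between females and males over one window.

    Ratio-of-sums estimator (summed variance components across sites, as
    in vcftools' weighted F_ST); negative values are retained.  NaN when
    the window has no site polymorphic with data in both sexes.
    """
    sub = vt.in_window(chrom, start, end)
    if sub.n_sites == 0:
        return np.nan
    females = sub.sexes == "F"
    num = den = 0.0
    any_site = False
    for i in range(sub.n_sites):
        ac, pl = sub.alt_counts[i], sub.ploidy[i]
        called = ac != MISSING
        k_pop, n_pop, h_pop = [], [], []
        for mask in (females, ~females):
            m = mask & called
            chroms = int(pl[m].sum())
            if chroms == 0:
                break
            k_pop.append(int(ac[m].sum()))
            n_pop.append(chroms / 2.0)
            dip = m & (pl == 2)
            h_pop.append(float(np.mean(ac[dip] == 1)) if dip.any() else 0.0)
        else:
            k_tot, n_tot = sum(k_pop), 2 * sum(n_pop)
            if k_tot == 0 or k_tot == n_tot:
                continue
            a, b, c = _wc_components(k_pop, n_pop, h_pop)
            if np.isnan(a):
                continue
            num += a
            den += a + b + c
            any_site = True
    if not any_site or den == 0:
        return np.nan
    return num / den


def windowed_fst_fm(vt: VariantTable, windows) -> pd.DataFrame:
    rows = [{"chrom": c, "start": s, "end": e, "fst_fm": fst_fm_window(vt, c, s, e)}
            for c, s, e in windows]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p-value (Wigginton et al. 2005).

    Sums the probabilities of all heterozygote counts, conditional on the
    allele counts, that are no more likely than the observed one.
    """
    n = n_het + n_hom1 + n_hom2
    n_rare = n_het + 2 * min(n_hom1, n_hom2)
    if n == 0 or n_rare == 0:
        return 1.0
    # unnormalized probabilities over feasible het counts (parity fixed)
    hets = list(range(n_rare % 2, n_rare + 1, 2))
    logp = {}
    for h in hets:
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        if common_hom < 0:
            continue
        # log multinomial coefficient terms
        logp[h] = (_lfact(n) - _lfact(h) - _lfact(rare_hom) - _lfact(common_hom)
                   + h * np.log(2.0))
    mx = max(logp.values())
    probs = {h: np.exp(v - mx) for h, v in logp.items()}
    tot = sum(probs.values())
    obs = probs.get(n_het, 0.0)
    p = sum(v for v in probs.values() if v <= obs * (1 + 1e-12)) / tot
    return min(1.0, p)


def _lfact(n: int) -> float:
    from scipy.special import gammaln
    return float(gammaln(n + 1))


def ld_pairs(vt: VariantTable, chrom: str, chrom_length: int,
             window_size: int = 200_000, overlap: int = 50_000,
             hwe_p: float = 0.01,
             max_snps_per_window: int | None = None) -> pd.DataFrame:
    """Pairwise r^2 for SNP pairs within overlapping windows.

    r^2 is the squared Pearson correlation of diploid genotype dosages
    (the composite genotypic measure, appropriate for unphased data).
    Sites failing the exact HWE test at ``hwe_p`` and sites with any
    haploid call are excluded; pairs seen in several overlapping windows
    are emitted once.  ``max_snps_per_window`` thins dense windows to an
    evenly spaced subset before pairing.
    """
    sub = vt.subset((vt.sites["chrom"] == chrom).to_numpy())
    if sub.n_sites == 0:
        return pd.DataFrame(columns=["pos_i", "pos_j", "distance", "r2"])
    diploid = (sub.ploidy == 2) | (sub.alt_counts == MISSING)
    keep = diploid.all(axis=1)
    sub = sub.subset(keep)
    # HWE filter on diploid genotype counts
    hwe_ok = np.ones(sub.n_sites, dtype=bool)
    for i in range(sub.n_sites):
        ac = sub.alt_counts[i]
        called = ac != MISSING
        het = int(np.sum(ac[called] == 1))
        hom_r = int(np.sum(ac[called] == 0))
        hom_a = int(np.sum(ac[called] == 2))
        hwe_ok[i] = hwe_exact_p(het, hom_r, hom_a) >= hwe_p
    sub = sub.subset(hwe_ok)
    pos = sub.sites["pos"].to_numpy() - 1
    dosage = np.ma.masked_equal(sub.alt_counts.astype(float), float(MISSING))
    windows = make_windows({chrom: chrom_length}, window_size, window_size - overlap)
    seen: set[tuple[int, int]] = set()
    frames = []
    for _, start, end in windows:
        idx = np.where((pos >= start) & (pos < end))[0]
        if max_snps_per_window is not None and len(idx) > max_snps_per_window:
            take = np.linspace(0, len(idx) - 1, max_snps_per_window).astype(int)
            idx = idx[take]
        if len(idx) < 2:
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.ma.corrcoef(dosage[idx])
        r2 = np.asarray(np.ma.filled(corr, np.nan)) ** 2
        iu, ju = np.triu_indices(len(idx), k=1)
        pi_, pj_ = pos[idx[iu]], pos[idx[ju]]
        vals = r2[iu, ju]
        for a, b, v in zip(pi_, pj_, vals):
            key = (int(a), int(b))
            if key in seen or not np.isfinite(v):
                continue
            seen.add(key)
            frames.append((key[0], key[1], key[1] - key[0], v))
    return (pd.DataFrame(frames, columns=["pos_i", "pos_j", "distance", "r2"])
            if frames else pd.DataFrame(columns=["pos_i", "pos_j", "distance", "r2"]))


def ld_decay(pairs: pd.DataFrame, bin_width: int = 1000,
             background_r2: float = 0.15, smooth_bins: int = 5):
    """Mean r^2 per distance bin and the LD decay distance.

    The decay distance is the smallest bin midpoint at which the lightly
    smoothed (centered rolling mean over ``smooth_bins`` bins) curve first
    drops to or below the background level — by default the autosomal mean
    r^2, the natural floor for within-chromosome LD.  NaN when the curve
    never reaches the background.
    """
    if pairs.empty:
        raise ValueError("no LD pairs supplied")
    dist = pairs["distance"].to_numpy()
    r2 = pairs["r2"].to_numpy()
    bins = (dist // bin_width).astype(np.int64)
    df = (pd.DataFrame({"bin": bins, "r2": r2})
          .groupby("bin")["r2"].agg(["mean", "size"]).reset_index())
    df["midpoint"] = (df["bin"] + 0.5) * bin_width
    df["smoothed"] = (df["mean"].rolling(smooth_bins, center=True, min_periods=1).mean())
    below = df[df["smoothed"] <= background_r2]
    decay = float(below["midpoint"].iloc[0]) if not below.empty else np.nan
    return df[["midpoint", "mean", "smoothed", "size"]], decay


# ---------------------------------------------------------------------------
# annotation tracks
# ---------------------------------------------------------------------------

def annotation_tracks(fasta_path, gff_path, windows) -> pd.DataFrame:
    """Per-window GC fraction and CDS fraction.

    GC = (G+C)/(A+C+G+T) ignoring Ns (NaN for all-N windows); CDS fraction
    covers the union of CDS intervals from the GFF3.
    """
    from pyfaidx import Fasta

    fasta = Fasta(str(fasta_path))
    cds = _read_cds_intervals(gff_path)
    rows = []
    for chrom, start, end in windows:
        if chrom not in fasta:
            raise ValueError(f"{chrom} absent from FASTA")
        if end > len(fasta[chrom]):
            raise ValueError(f"window {chrom}:{start}-{end} beyond sequence end")
        seq = str(fasta[chrom][start:end]).upper()
        counts = {b: seq.count(b) for b in "ACGTN"}
        atgc = sum(counts[b] for b in "ACGT")
        gc = (counts["G"] + counts["C"]) / atgc if atgc else np.nan
        cds_bp = int(cds.overlap_mask(chrom, start, end).sum())
        rows.append({"chrom": chrom, "start": start, "end": end,
                     "gc": gc, "cds_frac": cds_bp / (end - start)})
    return pd.DataFrame(rows)


def _read_cds_intervals(gff_path) -> IntervalSet:
    """CDS feature intervals from a GFF3, as a merged 0-based set."""
    import gffutils

    db = gffutils.create_db(str(gff_path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    ivs = [(f.seqid, f.start - 1, f.end) for f in db.features_of_type("CDS")]
    return IntervalSet(ivs)
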