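"""Structured coalescent for a partially sex-linked (pseudoautosomal) locus.

In a ZW system the chromosome copies of a PAR locus fall into two classes:
those currently on a Z and those currently on a W.  Backward in time these
classes behave as two demes of a structured coalescent: lineages coalesce
only within a class, and female recombination between the locus and the PAR
boundary moves lineages between classes.  With autosomal diploid effective
size ``Ne``, the deme sizes are ``N_Z = 3 Ne / 4`` and ``N_W = Ne / 4``
(three quarters of the copies of a Z-linked locus reside on Z chromosomes).

All times are in units of ``2 Ne`` generations, so the expected coalescence
time of two lineages at an autosomal locus is exactly 1.  In these units the
pair-coalescence rate is ``4/3`` within Z and ``4`` within W, and a lineage
migrates (backward in time) from W to Z at rate ``2 Ne r_f`` and from Z to W
at rate ``2 Ne r_f / 3``, where ``r_f`` is the female recombination fraction
between the locus and the PAR boundary.  At ``r_f`` near 1/2 the two classes
mix freely and the process converges to the unstructured autosomal
coalescent; at small ``r_f`` the W class behaves like a diverging population
of size ``Ne/4``, inflating diversity and female-male differentiation.

Predictions are mapped to observables through mean coalescence times:
``pi_PAR = pi_auto * T_t`` and ``F_FM ~ 1 - T_w^fm / T_t^fm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import recmap

__all__ = [
    "ZWDemeModel",
    "SampleConfig",
    "Genealogy",
    "TimeSummary",
    "RatePack",
    "PARProfile",
    "NonCoalescingError",
    "scaled_rates",
    "simulate_genealogy",
    "pair_time_groups",
    "summarize_times",
    "summarize_each",
    "expected_pi",
    "fst_from_times",
    "drop_mutations",
    "site_profile",
    "envelope_test",
]

Z, W = 0, 1  # deme codes
FEMALE, MALE = "F", "M"


class NonCoalescingError(ValueError):
    """Raised when lineages occupy both demes but r_f = 0: with no
    migration the last Z and last W lineage can never meet."""


# ---------------------------------------------------------------------------
# model and sample
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZWDemeModel:
    """Two-deme parameterization of one PAR site.

    Parameters
    ----------
    ne : float
        Autosomal diploid effective population size (individuals).
    r_f : float
        Female recombination fraction between the site and the PAR
        boundary, per meiosis; in [0, 0.5].
    """

    ne: float
    r_f: float

    def __post_init__(self):
        if self.ne <= 0:
            raise ValueError("Ne must be positive")
        if not (0.0 <= self.r_f <= 0.5):
            raise ValueError("r_f must be in [0, 0.5]")

    @property
    def n_z(self) -> float:
        return 3.0 * self.ne / 4.0

    @property
    def n_w(self) -> float:
        return self.ne / 4.0


@dataclass(frozen=True)
class SampleConfig:
    """Sampled individuals: each female contributes one Z and one W lineage,
    each male two Z lineages."""

    n_females: int = 5
    n_males: int = 5

    def __post_init__(self):
        if self.n_females < 0 or self.n_males < 0:
            raise ValueError("negative sample size")
        if 2 * (self.n_females + self.n_males) < 2:
            raise ValueError("need at least 2 lineages")

    @property
    def n_lineages(self) -> int:
        return 2 * (self.n_females + self.n_males)

    def lineages(self) -> list[tuple[int, str, int]]:
        """(individual id, sex, starting deme) for every sampled chromosome."""
        out = []
        ind = 0
        for _ in range(self.n_females):
            out.append((ind, FEMALE, Z))
            out.append((ind, FEMALE, W))
            ind += 1
        for _ in range(self.n_males):
            out.append((ind, MALE, Z))
            out.append((ind, MALE, Z))
            ind += 1
        return out


@dataclass(frozen=True)
class RatePack:
    """Event rates of the two-deme coalescent, time unit 2*Ne generations."""

    coal_z: float          # pair-coalescence rate within Z  (= 2Ne / 2N_Z)
    coal_w: float          # pair-coalescence rate within W  (= 2Ne / 2N_W)
    mig_w_to_z: float      # per-lineage backward migration rate W -> Z
    mig_z_to_w: float      # per-lineage backward migration rate Z -> W


def scaled_rates(model: ZWDemeModel, orientation: str = "w_gains_from_z") -> RatePack:
    """Coalescence and migration rates of the model, scaled to 2*Ne generations.

    With the default orientation a W-sampled lineage's ancestor was on a Z
    with probability ``r_f`` per meiosis (every W sits in a female, who
    recombines with probability r_f), while only 1/3 of Z copies sit in
    females, giving the Z->W backward rate ``r_f/3``.  Both orientations
    satisfy the deme flux balance (3/4)(r_f/3) = (1/4) r_f; pass
    ``orientation="z_gains_from_w"`` to flip them.
    """
    m_fast = 2.0 * model.ne * model.r_f
    m_slow = m_fast / 3.0
    if orientation == "w_gains_from_z":
        mig_w_to_z, mig_z_to_w = m_fast, m_slow
    elif orientation == "z_gains_from_w":
        mig_w_to_z, mig_z_to_w = m_slow, m_fast
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return RatePack(coal_z=4.0 / 3.0, coal_w=4.0,
                    mig_w_to_z=mig_w_to_z, mig_z_to_w=mig_z_to_w)


# ---------------------------------------------------------------------------
# genealogy container
# ---------------------------------------------------------------------------

@dataclass
class Genealogy:
    """A binary coalescent tree over the sampled chromosomes.

    Nodes 0..n-1 are leaves at time 0; internal nodes follow in coalescence
    order with strictly increasing times; the last node is the root.
    ``leaf_labels[i]`` is (individual id, sex, starting deme).
    """

    leaf_labels: list[tuple[int, str, int]]
    node_times: np.ndarray            # length 2n-1
    children: np.ndarray              # (n-1, 2) child node ids per internal node
    _pairwise: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def root_time(self) -> float:
        return float(self.node_times[-1])

    def pairwise_times(self) -> np.ndarray:
        """Symmetric (n, n) matrix of pairwise coalescence (MRCA) times."""
        if self._pairwise is None:
            n = self.n_leaves
            mat = np.zeros((n, n))
            # descendant leaf sets, built bottom-up
            desc: list[list[int]] = [[i] for i in range(n)]
            for k, (a, b) in enumerate(self.children):
                t = self.node_times[n + k]
                da, db = desc[a], desc[b]
                for i in da:
                    for j in db:
                        mat[i, j] = mat[j, i] = t
                desc.append(da + db)
            self._pairwise = mat
        return self._pairwise

    def total_branch_length(self) -> float:
        """Sum of all branch lengths (2*Ne generations)."""
        n = self.n_leaves
        parent_time = np.empty(2 * n - 2)
        for k, (a, b) in enumerate(self.children):
            t = self.node_times[n + k]
            for c in (a, b):
                parent_time[c] = t
        return float(np.sum(parent_time - self.node_times[: 2 * n - 2]))


# ---------------------------------------------------------------------------
# exact Gillespie simulation
# ---------------------------------------------------------------------------

def simulate_genealogy(model: ZWDemeModel, sample,
                       rng: np.random.Generator,
                       orientation: str = "w_gains_from_z") -> Genealogy:
    """Exact continuous-time simulation of the two-deme coalescent.

    Repeatedly draws an exponential waiting time at the total event rate,
    then picks the event by cumulative-rate inversion on a fixed ordering
    (coalescence in Z, coalescence in W, migrations of W lineages by index,
    migrations of Z lineages by index) so that runs are reproducible for a
    given random stream.  Coalescences merge two uniformly chosen lineages
    of the deme; migrations relabel a lineage's deme.  Stops at one lineage.

    ``sample`` is a :class:`SampleConfig` or an explicit list of
    (individual id, sex, starting deme) lineage labels.
    """
    labels = sample.lineages() if isinstance(sample, SampleConfig) else list(sample)
    if len(labels) < 2:
        raise ValueError("need at least 2 lineages")
    n = len(labels)
    rates = scaled_rates(model, orientation=orientation)

    deme_members: list[list[int]] = [[], []]  # active node ids per deme
    for i, (_, _, d) in enumerate(labels):
        deme_members[d].append(i)
    if model.r_f == 0.0 and deme_members[Z] and deme_members[W]:
        raise NonCoalescingError(
            "r_f = 0 with lineages in both demes: the configuration cannot "
            "fully coalesce; use r_f > 0 or a single-deme sample"
        )

    node_times = np.zeros(2 * n - 1)
    children = np.empty((n - 1, 2), dtype=np.int64)
    next_node = n
    t = 0.0
    mig_rate = (rates.mig_z_to_w, rates.mig_w_to_z)  # indexed by current deme

    while len(deme_members[Z]) + len(deme_members[W]) > 1:
        k_z = len(deme_members[Z])
        k_w = len(deme_members[W])
        r_cz = rates.coal_z * k_z * (k_z - 1) / 2.0
        r_cw = rates.coal_w * k_w * (k_w - 1) / 2.0
        r_mw = rates.mig_w_to_z * k_w
        r_mz = rates.mig_z_to_w * k_z
        total = r_cz + r_cw + r_mw + r_mz
        if total <= 0.0:
            raise NonCoalescingError("no events possible (both demes singleton, r_f = 0)")
        t += rng.exponential(1.0 / total)
        u = rng.random() * total
        if u < r_cz:
            deme = Z
        elif u < r_cz + r_cw:
            deme = W
        elif u < r_cz + r_cw + r_mw:
            idx = int((u - r_cz - r_cw) / rates.mig_w_to_z)
            idx = min(idx, k_w - 1)
            node = deme_members[W].pop(idx)
            deme_members[Z].append(node)
            continue
        else:
            idx = int((u - r_cz - r_cw - r_mw) / rates.mig_z_to_w)
            idx = min(idx, k_z - 1)
            node = deme_members[Z].pop(idx)
            deme_members[W].append(node)
            continue
        # coalescence: merge two uniformly chosen lineages of `deme`
        members = deme_members[deme]
        i = int(rng.integers(len(members)))
        j = int(rng.integers(len(members) - 1))
        if j >= i:
            j += 1
        a, b = members[i], members[j]
        for x in sorted((i, j), reverse=True):
            members.pop(x)
        node_times[next_node] = t
        children[next_node - n] = (a, b)
        members.append(next_node)
        next_node += 1

    return Genealogy(leaf_labels=labels, node_times=node_times, children=children)


# ---------------------------------------------------------------------------
# grouped coalescence times
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeSummary:
    """Mean pairwise coalescence times grouped by starting deme and by the
    sex of the carrying individuals; units of 2*Ne generations.

    Derived quantities follow the standard within/total decomposition for a
    random pair of chromosomes drawn with the population class frequencies
    (Z with probability 3/4, W with 1/4), and the female/male analogue used
    for the between-sex F_ST prediction.
    """

    t_zz: float
    t_ww: float
    t_zw: float
    t_ff: float
    t_mm: float
    t_fm: float
    n_pairs: dict = field(default_factory=dict, compare=False)

    @property
    def t_w(self) -> float:
        """Within-deme mean: (T_ZZ + T_WW) / 2."""
        return (self.t_zz + self.t_ww) / 2.0

    @property
    def t_t(self) -> float:
        """Total mean for a population pair: (T_ZZ + T_WW)/4 + T_ZW/2."""
        return (self.t_zz + self.t_ww) / 4.0 + self.t_zw / 2.0

    @property
    def t_w_fm(self) -> float:
        """Within-sex mean: (T_ff + T_mm) / 2."""
        return (self.t_ff + self.t_mm) / 2.0

    @property
    def t_t_fm(self) -> float:
        """Total mean for the sex grouping: (T_ff + T_mm + 2 T_fm) / 4."""
        return (self.t_ff + self.t_mm + 2.0 * self.t_fm) / 4.0


_DEME_KEYS = ("zz", "zw", "ww")
_SEX_KEYS = ("ff", "fm", "mm")


def _pair_group_indices(labels: Sequence[tuple[int, str, int]]):
    """Condensed-pair group codes for the deme and sex groupings."""
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    demes = np.array([lab[2] for lab in labels])
    sexes = np.array([0 if lab[1] == FEMALE else 1 for lab in labels])
    deme_code = demes[iu] + demes[ju]          # 0=ZZ, 1=ZW, 2=WW
    sex_code = sexes[iu] + sexes[ju]           # 0=ff, 1=fm, 2=mm
    return iu, ju, deme_code, sex_code


def pair_time_groups(gen: Genealogy):
    """Per-genealogy sums and counts of pairwise times by group."""
    iu, ju, deme_code, sex_code = _pair_group_indices(gen.leaf_labels)
    tv = gen.pairwise_times()[iu, ju]
    deme_sum = np.bincount(deme_code, weights=tv, minlength=3)
    deme_cnt = np.bincount(deme_code, minlength=3)
    sex_sum = np.bincount(sex_code, weights=tv, minlength=3)
    sex_cnt = np.bincount(sex_code, minlength=3)
    return deme_sum, deme_cnt, sex_sum, sex_cnt


def _summary_from_sums(deme_sum, deme_cnt, sex_sum, sex_cnt) -> TimeSummary:
    with np.errstate(invalid="ignore", divide="ignore"):
        dm = np.where(deme_cnt > 0, deme_sum / np.maximum(deme_cnt, 1), np.nan)
        sm = np.where(sex_cnt > 0, sex_sum / np.maximum(sex_cnt, 1), np.nan)
    return TimeSummary(
        t_zz=float(dm[0]), t_zw=float(dm[1]), t_ww=float(dm[2]),
        t_ff=float(sm[0]), t_fm=float(sm[1]), t_mm=float(sm[2]),
        n_pairs={"zz": int(deme_cnt[0]), "zw": int(deme_cnt[1]), "ww": int(deme_cnt[2]),
                 "ff": int(sex_cnt[0]), "fm": int(sex_cnt[1]), "mm": int(sex_cnt[2])},
    )


def summarize_times(replicates: Iterable[Genealogy]) -> TimeSummary:
    """Pooled grouped means over replicate genealogies sharing one layout."""
    deme_sum = np.zeros(3)
    deme_cnt = np.zeros(3, dtype=np.int64)
    sex_sum = np.zeros(3)
    sex_cnt = np.zeros(3, dtype=np.int64)
    layout = None
    n_rep = 0
    for gen in replicates:
        if layout is None:
            layout = gen.leaf_labels
        elif gen.leaf_labels != layout:
            raise ValueError("replicates have mismatched sample layouts")
        ds, dc, ss, sc = pair_time_groups(gen)
        deme_sum += ds
        deme_cnt += dc
        sex_sum += ss
        sex_cnt += sc
        n_rep += 1
    if n_rep == 0:
        raise ValueError("no replicates supplied")
    return _summary_from_sums(deme_sum, deme_cnt, sex_sum, sex_cnt)


def summarize_each(replicates: Iterable[Genealogy]) -> list[TimeSummary]:
    """Per-replicate grouped means (for percentile envelopes)."""
    return [_summary_from_sums(*pair_time_groups(g)) for g in replicates]


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

def expected_pi(summary: TimeSummary | float, pi_auto: float) -> float:
    """Predicted mean pairwise diversity per site: pi_PAR = pi_auto * T_t."""
    t_t = summary.t_t if isinstance(summary, TimeSummary) else float(summary)
    if pi_auto < 0 or t_t < 0:
        raise ValueError("negative input to expected_pi")
    return pi_auto * t_t


def fst_from_times(summary: TimeSummary) -> float:
    """Female-male F_ST prediction: F_FM = 1 - T_w^fm / T_t^fm.

    Not clipped at zero: Monte-Carlo noise can push the estimate slightly
    negative when the true value is ~0.
    """
    if not summary.t_t_fm > 0:
        raise ValueError("T_t^fm must be positive")
    return 1.0 - summary.t_w_fm / summary.t_t_fm


def drop_mutations(gen: Genealogy, theta: float, rng: np.random.Generator) -> list[np.ndarray]:
    """Infinite-sites mutations on the genealogy at rate theta/2 per unit
    branch; returns, per mutation, the boolean leaf vector carrying the
    derived allele.  ``theta = 4 Ne mu L`` for a window of L sites."""
    if theta < 0:
        raise ValueError("theta must be non-negative")
    n = gen.n_leaves
    # branch lengths, indexed by child node
    parent_time = np.empty(2 * n - 2)
    for k, (a, b) in enumerate(gen.children):
        for c in (a, b):
            parent_time[c] = gen.node_times[n + k]
    blen = parent_time - gen.node_times[: 2 * n - 2]
    total = blen.sum()
    n_mut = rng.poisson(theta / 2.0 * total)
    if n_mut == 0:
        return []
    # leaf sets below each node
    desc = [np.zeros(n, dtype=bool) for _ in range(2 * n - 1)]
    for i in range(n):
        desc[i][i] = True
    for k, (a, b) in enumerate(gen.children):
        desc[n + k] = desc[a] | desc[b]
    nodes = rng.choice(2 * n - 2, size=n_mut, p=blen / total)
    return [desc[v].copy() for v in nodes]


# ---------------------------------------------------------------------------
# per-site profile along the PAR
# ---------------------------------------------------------------------------

@dataclass
class PARProfile:
    """Per-site predictions and 95% simulation envelopes along the PAR.

    Columns of ``df``: pos, ne, r_f, pi_point, pi_lo, pi_hi,
    fst_point, fst_lo, fst_hi.  Envelope bounds are the 2.5 and 97.5
    percentiles over replicate simulations; the point prediction is the
    mean over replicates.
    """

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df.sort_values("pos").reset_index(drop=True)
        for stat in ("pi", "fst"):
            lo, pt, hi = df[f"{stat}_lo"], df[f"{stat}_point"], df[f"{stat}_hi"]
            if not ((lo <= pt + 1e-12) & (pt <= hi + 1e-12)).all():
                raise ValueError(f"envelope does not bracket the {stat} point prediction")
        self.df = df

    def write_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "PARProfile":
        return cls(pd.read_csv(path, sep="\t", comment="#"))


def site_profile(sites: Sequence[float],
                 rho_track: recmap.GenomicTrack,
                 genetic_map: recmap.GeneticMapTable,
                 pi_auto: float,
                 boundary_bp: float,
                 n_reps: int = 1000,
                 sample: SampleConfig = SampleConfig(5, 5),
                 rng: np.random.Generator | None = None,
                 chrom: str | None = None,
                 clamp_rf: float | None = None,
                 orientation: str = "w_gains_from_z") -> PARProfile:
    """Simulated diversity and F_FM expectations at sites along the PAR.

    For each site the female recombination fraction to the PAR boundary is
    taken from the genetic map (Kosambi), the local Ne from
    ``Ne = rho/(4 r)`` with rho accumulated between the site and the
    boundary, and ``n_reps`` replicate genealogies are simulated.  Per
    replicate, pi = pi_auto * T_t and F_FM = 1 - T_w^fm/T_t^fm are computed
    from that replicate's grouped means; the profile reports the mean and
    the 2.5/97.5 percentiles across replicates.

    Sites with r_f = 0 (at or beyond the boundary) are rejected unless
    ``clamp_rf`` provides an explicit positive floor.
    """
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    for pos in sites:
        r_f = recmap.rf_at(genetic_map, pos, boundary_bp, chrom=chrom, sex="female")
        if r_f <= 0.0:
            if clamp_rf is None:
                raise ValueError(
                    f"site {pos}: r_f = 0 (at/inside the SLR); pass clamp_rf to floor it"
                )
            r_f = max(r_f, clamp_rf)
        r_f = min(r_f, 0.5)
        rho = recmap.cumulative_rho(rho_track, min(pos, boundary_bp),
                                    max(pos, boundary_bp), chrom=chrom)
        ne = recmap.ne_from_rho_r(rho, r_f) if rho > 0 else None
        if ne is None or ne <= 0:
            raise ValueError(f"site {pos}: non-positive Ne from rho={rho}, r={r_f}")
        model = ZWDemeModel(ne=ne, r_f=r_f)
        pis = np.empty(n_reps)
        fsts = np.empty(n_reps)
        for k in range(n_reps):
            gen = simulate_genealogy(model, sample, rng, orientation=orientation)
            s = _summary_from_sums(*pair_time_groups(gen))
            pis[k] = pi_auto * s.t_t
            fsts[k] = 1.0 - s.t_w_fm / s.t_t_fm
        rows.append({
            "pos": float(pos), "ne": float(ne), "r_f": float(r_f),
            "pi_point": pis.mean(),
            "pi_lo": float(np.percentile(pis, 2.5)),
            "pi_hi": float(np.percentile(pis, 97.5)),
            "fst_point": fsts.mean(),
            "fst_lo": float(np.percentile(fsts, 2.5)),
            "fst_hi": float(np.percentile(fsts, 97.5)),
        })
    return PARProfile(pd.DataFrame(rows))


def envelope_test(empirical: recmap.GenomicTrack, profile: PARProfile,
                  stat: str = "pi") -> pd.DataFrame:
    """Flag each empirical window against the simulation envelope.

    The envelope is interpolated linearly at the window midpoint; windows
    whose midpoint falls outside the profile's site range are dropped.
    Returns a frame with midpoint, value, interpolated bounds and a flag in
    {"below", "inside", "above"}.
    """
    if stat not in ("pi", "fst"):
        raise ValueError("stat must be 'pi' or 'fst'")
    pos = profile.df["pos"].to_numpy()
    lo = profile.df[f"{stat}_lo"].to_numpy()
    hi = profile.df[f"{stat}_hi"].to_numpy()
    mids = empirical.midpoints
    vals = empirical.values
    keep = (mids >= pos.min()) & (mids <= pos.max()) & np.isfinite(vals)
    if not keep.any():
        raise ValueError("no empirical window overlaps the profile's site range")
    mids, vals = mids[keep], vals[keep]
    lo_i = np.interp(mids, pos, lo)
    hi_i = np.interp(mids, pos, hi)
    flag = np.where(vals < lo_i, "below", np.where(vals > hi_i, "above", "inside"))
    return pd.DataFrame({
        "midpoint": mids, "value": vals,
        "env_lo": lo_i, "env_hi": hi_i, "flag": flag,
    })
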