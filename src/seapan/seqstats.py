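"""Mitochondrial-sequence population statistics.

Covers the sequence side of the genetic analyses: haplotype collapsing
(H, UH, S), Nei's haplotype and nucleotide diversities with their standard
deviations, pairwise Phi_ST with permutation tests and Benjamini–Hochberg
FDR, hierarchical AMOVA (Excoffier–Smouse–Quattro variance decomposition
with Phi_CT / Phi_SC / Phi_ST and stratum-specific permutation schemes),
and the spatial analysis of shared alleles (SAShA), which compares the
observed mean geographic distance between copies of the same haplotype (OM)
with the all-pairs expectation under panmixia (EM).

Distances between sequences default to the count of nucleotide differences
over comparable (both-ACGT) sites, with pairwise deletion of gaps and
ambiguity codes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SequenceDataset",
    "HaplotypeTable",
    "AMOVAResult",
    "SAShAResult",
    "read_fasta_with_pops",
    "write_fasta_with_pops",
    "collapse_haplotypes",
    "haplotype_diversity",
    "nucleotide_diversity",
    "diversity_table",
    "pairwise_phist",
    "amova",
    "sasha",
    "pairwise_difference_matrix",
    "great_circle_km",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
EARTH_RADIUS_KM = 6371.0


class SequenceDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------

@dataclass
class SequenceDataset:
    """Aligned, population-labelled sequences with optional site coordinates.

    ``coords`` is a DataFrame with columns ``pop_id`` and either
    ``lat``/``lon`` (geographic) or ``x``/``y`` (cartesian km).
    ``groups`` optionally maps each population to a higher-level group.
    """

    ids: list[str]
    pops: list[str]
    seqs: list[str]
    coords: pd.DataFrame | None = None
    groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not (len(self.ids) == len(self.pops) == len(self.seqs)):
            raise SequenceDataError("ids, pops and seqs must have equal length")
        self.seqs = [s.upper() for s in self.seqs]
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            offenders = [
                i for i, s in zip(self.ids, self.seqs)
                if len(s) != len(self.seqs[0])
            ]
            raise SequenceDataError(
                f"sequences are not aligned to one length; offenders: {offenders}"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    @property
    def pop_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pops:
            seen.setdefault(p)
        return list(seen)

    def subset(self, keep: np.ndarray) -> "SequenceDataset":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return SequenceDataset(
            ids=[self.ids[i] for i in idx],
            pops=[self.pops[i] for i in idx],
            seqs=[self.seqs[i] for i in idx],
            coords=self.coords,
            groups=self.groups,
        )

    def encoded(self) -> np.ndarray:
        """``(n, L)`` uint8 matrix: A,C,G,T -> 0..3, everything else 255."""
        arr = np.frombuffer(
            "".join(self.seqs).encode("ascii"), dtype=np.uint8
        ).reshape(self.n, self.length)
        out = np.full(arr.shape, 255, dtype=np.uint8)
        for base, code in _BASE_CODE.items():
            out[arr == ord(base)] = code
        return out


def read_fasta_with_pops(path, pops_path=None) -> SequenceDataset:
    """Read an aligned FASTA; population labels from ``>{id}|{pop}`` headers
    or a sidecar CSV with columns ``indiv_id,pop_id``.

    An optional sidecar may also carry coordinates (``pop_id,lat,lon`` or
    ``pop_id,x,y``), picked up when present.
    """
    ids, pops, seqs = [], [], []
    mapping = None
    coords = None
    if pops_path is not None:
        side = pd.read_csv(pops_path)
        if {"indiv_id", "pop_id"}.issubset(side.columns):
            mapping = dict(zip(side["indiv_id"].astype(str), side["pop_id"].astype(str)))
        coord_cols = [c for c in ("lat", "lon", "x", "y") if c in side.columns]
        if coord_cols and "pop_id" in side.columns:
            coords = side[["pop_id", *coord_cols]].drop_duplicates("pop_id")
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        if mapping is not None:
            indiv = header.split("|")[0]
            if indiv not in mapping:
                raise SequenceDataError(f"unknown population for record {indiv!r}")
            ids.append(indiv)
            pops.append(mapping[indiv])
        else:
            if "|" not in header:
                raise SequenceDataError(
                    f"header {header!r} lacks '|pop' and no sidecar table given"
                )
            indiv, pop = header.split("|", 1)
            ids.append(indiv)
            pops.append(pop)
        seqs.append(str(rec.seq))
    if not ids:
        raise SequenceDataError(f"no FASTA records in {path}")
    return SequenceDataset(ids=ids, pops=pops, seqs=seqs, coords=coords)


def write_fasta_with_pops(ds: SequenceDataset, path) -> None:
    records = [
        SeqRecord(Seq(s), id=f"{i}|{p}", description="")
        for i, p, s in zip(ds.ids, ds.pops, ds.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Haplotypes and diversity
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeTable:
    sequences: list[str]           # representative sequence per haplotype id
    counts: pd.DataFrame           # haplotype x population counts
    H: int                         # total number of haplotypes
    UH: int                        # haplotypes confined to one population
    S: int                         # polymorphic (segregating) sites
    uh_per_pop: pd.Series = field(repr=False, default=None)


def collapse_haplotypes(ds: SequenceDataset) -> HaplotypeTable:
    """Collapse identical sequences into haplotypes and count per population.

    Haplotype identity is exact string identity of the normalized (upper
    case) sequence, ambiguity codes included.  ``S`` counts alignment
    columns at which at least two distinct unambiguous nucleotides occur.
    """
    hap_ids: dict[str, int] = {}
    assign = []
    for s in ds.seqs:
        assign.append(hap_ids.setdefault(s, len(hap_ids)))
    pops = ds.pop_names
    counts = np.zeros((len(hap_ids), len(pops)), dtype=int)
    pop_index = {p: j for j, p in enumerate(pops)}
    for hap, pop in zip(assign, ds.pops):
        counts[hap, pop_index[pop]] += 1
    counts_df = pd.DataFrame(
        counts, index=[f"H{i+1}" for i in range(len(hap_ids))], columns=pops
    )
    enc = ds.encoded()
    valid = enc != 255
    poly = 0
    for j in range(enc.shape[1]):
        col = enc[valid[:, j], j]
        if col.size and np.unique(col).size >= 2:
            poly += 1
    private = (counts > 0).sum(axis=1) == 1
    uh_per_pop = pd.Series(0, index=pops, dtype=int)
    for hap in np.flatnonzero(private):
        uh_per_pop[pops[int(np.argmax(counts[hap] > 0))]] += 1
    return HaplotypeTable(
        sequences=list(hap_ids),
        counts=counts_df,
        H=len(hap_ids),
        UH=int(private.sum()),
        S=poly,
        uh_per_pop=uh_per_pop,
    )


def haplotype_diversity(counts) -> tuple[float, float]:
    """Nei's haplotype (gene) diversity with its standard deviation.

    ``h = n (1 - sum p_i^2) / (n - 1)``; the variance follows Nei (1987,
    eq. 8.12).  Requires n >= 2.
    """
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    n = counts.sum()
    if n < 2:
        raise SequenceDataError("haplotype diversity needs n >= 2")
    p = counts / n
    sp2 = float(np.sum(p**2))
    sp3 = float(np.sum(p**3))
    h = n * (1.0 - sp2) / (n - 1.0)
    var = (2.0 / (n * (n - 1.0))) * (
        2.0 * (n - 2.0) * (sp3 - sp2**2) + sp2 - sp2**2
    )
    return h, math.sqrt(max(var, 0.0))


def pairwise_difference_matrix(ds: SequenceDataset) -> np.ndarray:
    """Counts of nucleotide differences over both-ACGT sites, all pairs."""
    enc = ds.encoded()
    valid = enc != 255
    n = ds.n
    d = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        diff = (enc[i] != enc[i + 1:]) & both
        d[i, i + 1:] = diff.sum(axis=1)
    return d + d.T


def nucleotide_diversity(ds: SequenceDataset, pop: str | None = None
                         ) -> tuple[float, float]:
    """Nucleotide diversity pi with standard deviation (Nei 1987).

    ``pi = sum_{i<j} d_ij / (C(n,2) * L)`` with pairwise deletion of
    non-ACGT sites; the variance is Nei (1987, eq. 10.7), which includes
    the stochastic (sampling-over-loci) term used by standard software.
    """
    sub = ds if pop is None else ds.subset(np.array([p == pop for p in ds.pops]))
    n, L = sub.n, sub.length
    if n < 2 or L == 0:
        raise SequenceDataError("nucleotide diversity needs n >= 2 and L > 0")
    d = pairwise_difference_matrix(sub)
    npairs = n * (n - 1) / 2
    pi = d[np.triu_indices(n, 1)].sum() / (npairs * L)
    var = (n + 1.0) / (3.0 * (n - 1.0) * L) * pi \
        + 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0)) * pi**2
    return pi, math.sqrt(max(var, 0.0))


def diversity_table(ds: SequenceDataset) -> pd.DataFrame:
    """Per-population summary: n, H, UH, h +/- SD, pi +/- SD."""
    table = collapse_haplotypes(ds)
    rows = []
    for pop in ds.pop_names:
        counts = table.counts[pop].values
        n = int(counts.sum())
        hap_here = int((counts > 0).sum())
        if n >= 2:
            h, h_sd = haplotype_diversity(counts)
            pi, pi_sd = nucleotide_diversity(ds, pop)
        else:
            h = h_sd = pi = pi_sd = np.nan
        rows.append(
            dict(pop_id=pop, n=n, H=hap_here, UH=int(table.uh_per_pop[pop]),
                 h=h, h_sd=h_sd, pi=pi, pi_sd=pi_sd)
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# AMOVA machinery
# ---------------------------------------------------------------------------

def _ssd_within(d2: np.ndarray, parts: list[np.ndarray]) -> float:
    """Sum over index groups of (sum of squared distances)/group size."""
    total = 0.0
    for idx in parts:
        if idx.size:
            block = d2[np.ix_(idx, idx)]
            total += block.sum() / (2.0 * idx.size)
    return total


def _two_level_phist(d2: np.ndarray, labels: np.ndarray) -> float:
    """Phi_ST of a one-level (populations within total) AMOVA."""
    n = d2.shape[0]
    pops, inv = np.unique(labels, return_inverse=True)
    sizes = np.bincount(inv)
    parts = [np.flatnonzero(inv == k) for k in range(len(pops))]
    ssd_t = d2.sum() / (2.0 * n)
    ssd_wp = _ssd_within(d2, parts)
    ssd_ap = ssd_t - ssd_wp
    df_ap = len(pops) - 1
    df_wp = n - len(pops)
    if df_ap == 0 or df_wp == 0:
        return 0.0
    sigma_w = ssd_wp / df_wp
    n_c = (n - np.sum(sizes**2) / n) / df_ap
    sigma_a = (ssd_ap / df_ap - sigma_w) / n_c
    total = sigma_a + sigma_w
    if total <= 0:
        return 0.0
    return sigma_a / total


@dataclass
class AMOVAResult:
    table: pd.DataFrame          # stratum rows: df, ssd, sigma2, pct
    phi_ct: float
    phi_sc: float
    phi_st: float
    p_ct: float
    p_sc: float
    p_st: float
    n_perm: int


def amova(
    ds: SequenceDataset,
    groups: dict[str, str] | None = None,
    n_perm: int = 10100,
    seed: int = 0,
    d2: np.ndarray | None = None,
) -> AMOVAResult:
    """Hierarchical AMOVA: among groups / among populations within groups /
    within populations, with Phi-statistics and permutation p-values.

    The variance decomposition follows the distance-based sums of squared
    deviations with unequal-sample-size coefficients; each Phi statistic is
    tested by its own permutation scheme (Phi_ST: individuals among
    populations; Phi_SC: individuals among populations within groups;
    Phi_CT: whole populations among groups).
    """
    groups = groups if groups is not None else ds.groups
    if groups is None:
        raise SequenceDataError("amova needs a population->group mapping")
    pop_labels = np.asarray(ds.pops)
    pops = ds.pop_names
    if len(pops) < 2:
        raise SequenceDataError("amova needs at least two populations")
    grp_of_pop = {p: groups[p] for p in pops}
    grp_labels = np.asarray([grp_of_pop[p] for p in pop_labels])
    n = ds.n
    if d2 is None:
        d2 = pairwise_difference_matrix(ds) ** 2

    def decompose(pop_lab: np.ndarray, grp_lab: np.ndarray):
        upops, pinv = np.unique(pop_lab, return_inverse=True)
        ugrps, ginv = np.unique(grp_lab, return_inverse=True)
        P, G = len(upops), len(ugrps)
        pop_parts = [np.flatnonzero(pinv == k) for k in range(P)]
        grp_parts = [np.flatnonzero(ginv == k) for k in range(G)]
        ssd_t = d2.sum() / (2.0 * n)
        ssd_wg = _ssd_within(d2, grp_parts)
        ssd_wp = _ssd_within(d2, pop_parts)
        ssd_ag = ssd_t - ssd_wg
        ssd_ap = ssd_wg - ssd_wp
        df_ag, df_ap, df_wp = G - 1, P - G, n - P
        pop_sizes = np.array([idx.size for idx in pop_parts], dtype=float)
        grp_sizes = np.array([idx.size for idx in grp_parts], dtype=float)
        # group id of each population
        pop_grp = np.array([ginv[idx[0]] for idx in pop_parts])
        sum_np2_over_ng = sum(
            pop_sizes[pop_grp == g].dot(pop_sizes[pop_grp == g]) / grp_sizes[g]
            for g in range(G)
        )
        sigma_c = ssd_wp / df_wp if df_wp > 0 else 0.0
        if df_ap > 0:
            n1 = (n - sum_np2_over_ng) / df_ap
            sigma_b = (ssd_ap / df_ap - sigma_c) / n1
        else:
            sigma_b = 0.0
        if df_ag > 0:
            n2 = (sum_np2_over_ng - pop_sizes.dot(pop_sizes) / n) / df_ag
            n3 = (n - grp_sizes.dot(grp_sizes) / n) / df_ag
            sigma_a = (ssd_ag / df_ag - sigma_c - n2 * sigma_b) / n3
        else:
            sigma_a = 0.0
        return (ssd_ag, ssd_ap, ssd_wp, df_ag, df_ap, df_wp,
                sigma_a, sigma_b, sigma_c)

    (ssd_ag, ssd_ap, ssd_wp, df_ag, df_ap, df_wp,
     sigma_a, sigma_b, sigma_c) = decompose(pop_labels, grp_labels)
    total_var = sigma_a + sigma_b + sigma_c
    if total_var < 0:
        raise SequenceDataError("negative total variance in AMOVA")
    if total_var == 0:
        # all sequences identical: by convention 100% within, Phi = 0
        phi_ct = phi_sc = phi_st = 0.0
        pct = np.array([0.0, 0.0, 100.0])
    else:
        phi_ct = sigma_a / total_var
        phi_st = (sigma_a + sigma_b) / total_var
        phi_sc = sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) > 0 else 0.0
        pct = 100.0 * np.array([sigma_a, sigma_b, sigma_c]) / total_var

    # ---- permutation tests -------------------------------------------------
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA40A]))
    order = np.arange(n)
    grp_of_index = grp_labels.copy()
    count_st = count_sc = count_ct = 0
    pop_list = np.array(pops)
    pop_group_arr = np.array([grp_of_pop[p] for p in pops])
    for _ in range(n_perm):
        # Phi_ST: permute individuals among populations (whole dataset)
        perm = rng.permutation(order)
        st = decompose(pop_labels[perm], grp_labels[perm])
        tv = st[6] + st[7] + st[8]
        phi_st_p = (st[6] + st[7]) / tv if tv > 0 else 0.0
        if phi_st_p >= phi_st - 1e-12:
            count_st += 1
        # Phi_SC: permute individuals among populations within groups
        perm2 = order.copy()
        for g in np.unique(grp_of_index):
            idx = np.flatnonzero(grp_of_index == g)
            perm2[idx] = idx[rng.permutation(idx.size)]
        sc = decompose(pop_labels[perm2], grp_labels)
        phi_sc_p = sc[7] / (sc[7] + sc[8]) if (sc[7] + sc[8]) > 0 else 0.0
        if phi_sc_p >= phi_sc - 1e-12:
            count_sc += 1
        # Phi_CT: permute populations among groups
        shuffled_groups = pop_group_arr[rng.permutation(len(pop_list))]
        gmap = dict(zip(pop_list, shuffled_groups))
        ct = decompose(pop_labels, np.asarray([gmap[p] for p in pop_labels]))
        tv = ct[6] + ct[7] + ct[8]
        phi_ct_p = ct[6] / tv if tv > 0 else 0.0
        if phi_ct_p >= phi_ct - 1e-12:
            count_ct += 1
    p_st = (count_st + 1) / (n_perm + 1)
    p_sc = (count_sc + 1) / (n_perm + 1)
    p_ct = (count_ct + 1) / (n_perm + 1)

    table = pd.DataFrame(
        {
            "source": ["Among groups", "Among populations within groups",
                       "Within populations", "Total"],
            "df": [df_ag, df_ap, df_wp, n - 1],
            "ssd": [ssd_ag, ssd_ap, ssd_wp, ssd_ag + ssd_ap + ssd_wp],
            "sigma2": [sigma_a, sigma_b, sigma_c, total_var],
            "pct_variation": [*pct, 100.0],
        }
    )
    return AMOVAResult(table=table, phi_ct=phi_ct, phi_sc=phi_sc,
                       phi_st=phi_st, p_ct=p_ct, p_sc=p_sc, p_st=p_st,
                       n_perm=n_perm)


# ---------------------------------------------------------------------------
# Pairwise Phi_ST
# ---------------------------------------------------------------------------

@dataclass
class PhiStResult:
    phi: pd.DataFrame
    p: pd.DataFrame
    p_adj: pd.DataFrame
    n_perm: int


def pairwise_phist(
    ds: SequenceDataset,
    n_perm: int = 10100,
    seed: int = 0,
    distance: str = "pdiff",
) -> PhiStResult:
    """Pairwise Phi_ST between populations with permutation p-values.

    Each pair is a two-population AMOVA on squared pairwise differences;
    the permutation shuffles individuals between the two populations and
    p-values carry the +1/(n+1) correction.  Negative Phi_ST values are
    reported as computed.  A Benjamini–Hochberg-adjusted p matrix is
    attached (the multiple-testing correction applied across all pairs).
    """
    if distance != "pdiff":
        raise SequenceDataError(f"unsupported distance {distance!r}")
    pops = ds.pop_names
    if len(pops) < 2:
        raise SequenceDataError("need >= 2 populations")
    d_full = pairwise_difference_matrix(ds)
    labels = np.asarray(ds.pops)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF157]))
    phi = pd.DataFrame(np.nan, index=pops, columns=pops)
    pval = pd.DataFrame(np.nan, index=pops, columns=pops)
    raw = []
    pairs = []
    for a_i in range(len(pops)):
        for b_i in range(a_i + 1, len(pops)):
            a, b = pops[a_i], pops[b_i]
            idx = np.flatnonzero((labels == a) | (labels == b))
            if not ((labels == a).any() and (labels == b).any()):
                raise SequenceDataError(f"population of size 0 in pair ({a},{b})")
            # canonical order so p-values are invariant to input row order
            order = sorted(range(idx.size),
                           key=lambda k: (labels[idx[k]], ds.ids[idx[k]]))
            idx = idx[np.array(order)]
            sub_labels = (labels[idx] == b).astype(int)
            d2 = d_full[np.ix_(idx, idx)] ** 2
            # report Phi_ST unclipped even when variance components are <= 0
            obs = _phist_unclipped(d2, sub_labels)
            count = 0
            m = idx.size
            for _ in range(n_perm):
                perm_lab = sub_labels[rng.permutation(m)]
                if _phist_unclipped(d2, perm_lab) >= obs - 1e-12:
                    count += 1
            p = (count + 1) / (n_perm + 1)
            phi.loc[a, b] = phi.loc[b, a] = obs
            pval.loc[a, b] = pval.loc[b, a] = p
            raw.append(p)
            pairs.append((a, b))
    adj = multipletests(raw, method="fdr_bh")[1]
    p_adj = pd.DataFrame(np.nan, index=pops, columns=pops)
    for (a, b), q in zip(pairs, adj):
        p_adj.loc[a, b] = p_adj.loc[b, a] = q
    return PhiStResult(phi=phi, p=pval, p_adj=p_adj, n_perm=n_perm)


def _phist_unclipped(d2: np.ndarray, labels: np.ndarray) -> float:
    """Two-population Phi_ST without the non-negative clipping of totals."""
    n = d2.shape[0]
    sizes = np.bincount(labels)
    parts = [np.flatnonzero(labels == k) for k in range(len(sizes))]
    ssd_t = d2.sum() / (2.0 * n)
    ssd_wp = _ssd_within(d2, parts)
    ssd_ap = ssd_t - ssd_wp
    df_ap = len(sizes) - 1
    df_wp = n - len(sizes)
    if df_wp == 0:
        return 0.0
    sigma_w = ssd_wp / df_wp
    n_c = (n - np.sum(sizes.astype(float) ** 2) / n) / df_ap
    sigma_a = (ssd_ap / df_ap - sigma_w) / n_c
    total = sigma_a + sigma_w
    if total == 0:
        return 0.0
    return sigma_a / total


# ---------------------------------------------------------------------------
# SAShA
# ---------------------------------------------------------------------------

def great_circle_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Haversine great-circle distance in km (array-friendly)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


@dataclass
class SAShAResult:
    om: float          # observed mean distance between shared-haplotype pairs (km)
    em: float          # expected mean distance (all pairs) under panmixia (km)
    p_value: float
    n_perm: int


def sasha(
    ds: SequenceDataset,
    coords: pd.DataFrame | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "geographic",
) -> SAShAResult:
    """Spatial analysis of shared alleles on a haplotype dataset.

    OM is the mean geographic distance over all unordered pairs of
    individuals carrying the same haplotype; EM is the mean over all
    unordered pairs (the expectation when haplotypes are spatially random).
    The permutation test reassigns haplotypes to individuals at random and
    uses a two-sided tail on OM - EM with the +1/(n+1) correction.
    """
    coords = coords if coords is not None else ds.coords
    if coords is None:
        raise SequenceDataError("sasha needs per-population coordinates")
    coords = coords.set_index("pop_id") if "pop_id" in coords.columns else coords
    missing = [p for p in ds.pop_names if p not in coords.index]
    if missing:
        raise SequenceDataError(f"populations lacking coordinates: {missing}")
    if mode == "geographic":
        lat = coords.loc[ds.pops, "lat"].to_numpy(float)
        lon = coords.loc[ds.pops, "lon"].to_numpy(float)
        d = great_circle_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    else:
        xy = coords.loc[ds.pops, ["x", "y"]].to_numpy(float)
        diff = xy[:, None, :] - xy[None, :, :]
        d = np.sqrt((diff**2).sum(-1))
    n = ds.n
    iu = np.triu_indices(n, 1)
    em = float(d[iu].mean())

    hap_ids: dict[str, int] = {}
    hap = np.array([hap_ids.setdefault(s, len(hap_ids)) for s in ds.seqs])

    def observed_mean(h: np.ndarray) -> float:
        same = h[iu[0]] == h[iu[1]]
        if not same.any():
            return np.nan
        return float(d[iu][same].mean())

    om = observed_mean(hap)
    if np.isnan(om):
        warnings.warn("no shared haplotypes: OM undefined", stacklevel=2)
        return SAShAResult(om=np.nan, em=em, p_value=np.nan, n_perm=n_perm)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5A5A]))
    dev_obs = abs(om - em)
    count = 0
    for _ in range(n_perm):
        om_p = observed_mean(hap[rng.permutation(n)])
        if np.isnan(om_p):
            continue
        if abs(om_p - em) >= dev_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return SAShAResult(om=om, em=em, p_value=p, n_perm=n_perm)
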