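"""Microsatellite population statistics.

Diploid multi-allelic genotypes (integer allele sizes, 0 = missing) are
summarised per population (unbiased expected heterozygosity, observed
heterozygosity, F_IS with a multi-locus HWE permutation test, rarefied
allelic richness, unique alleles) and compared between populations with
Weir & Cockerham's theta and Jost's D_est, both with bootstrap-over-loci
confidence intervals, plus a proportion-of-shared-alleles neighbour-joining
tree.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from skbio import DistanceMatrix
from skbio.tree import nj

__all__ = [
    "GenotypeDataset",
    "read_genotypes",
    "write_genotypes",
    "het_stats",
    "hwe_permutation_test",
    "allelic_richness",
    "unique_alleles",
    "msat_summary_table",
    "pairwise_fst_jostd",
    "weir_cockerham_theta",
    "jost_d",
    "shared_allele_distance",
    "shared_allele_nj",
    "PairwiseMatrix",
]


class GenotypeDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------

@dataclass
class GenotypeDataset:
    """Diploid genotypes: ``alleles[i, l, :]`` are the two allele sizes of
    individual ``i`` at locus ``l`` (positive integers; 0,0 = missing)."""

    ids: list[str]
    pops: list[str]
    alleles: np.ndarray          # (n, n_loci, 2) int
    locus_names: list[str]
    coords: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=int)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise GenotypeDataError("alleles must have shape (n, loci, 2)")
        if self.alleles.shape[0] != len(self.ids):
            raise GenotypeDataError("allele rows do not match individuals")
        if self.alleles.shape[1] != len(self.locus_names):
            raise GenotypeDataError("allele columns do not match locus names")
        half_missing = (self.alleles == 0).sum(axis=2) == 1
        if half_missing.any():
            raise GenotypeDataError("missing genotypes must be missing-pairs (0,0)")
        if (self.alleles < 0).any():
            raise GenotypeDataError("allele sizes must be positive or 0 (missing)")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def pop_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pops:
            seen.setdefault(p)
        return list(seen)

    def missingness(self) -> pd.Series:
        """Fraction of missing genotypes per locus."""
        miss = (self.alleles[:, :, 0] == 0).mean(axis=0)
        return pd.Series(miss, index=self.locus_names)

    def pop_mask(self, pop: str) -> np.ndarray:
        return np.array([p == pop for p in self.pops])

    def drop_loci(self, names: list[str]) -> "GenotypeDataset":
        keep = [i for i, nm in enumerate(self.locus_names) if nm not in names]
        return GenotypeDataset(
            ids=self.ids, pops=self.pops,
            alleles=self.alleles[:, keep, :],
            locus_names=[self.locus_names[i] for i in keep],
            coords=self.coords,
        )


def read_genotypes(path, missing_threshold: float = 0.05
                   ) -> tuple[GenotypeDataset, list[str]]:
    """Read a genotype CSV (pop_id, indiv_id, two integer columns per locus).

    Returns the dataset and the list of loci whose missingness exceeds
    ``missing_threshold`` (flagged for exclusion, not silently dropped).
    """
    df = pd.read_csv(path)
    fixed = ["pop_id", "indiv_id"]
    if df.columns[:2].tolist() != fixed:
        raise GenotypeDataError("first two columns must be pop_id, indiv_id")
    allele_cols = df.columns[2:]
    if len(allele_cols) % 2 != 0:
        raise GenotypeDataError(
            f"odd number of allele columns ({len(allele_cols)})"
        )
    loci = []
    for i in range(0, len(allele_cols), 2):
        loci.append(str(allele_cols[i]).rsplit("_", 1)[0])
    try:
        arr = df[allele_cols].to_numpy(dtype=int)
    except (TypeError, ValueError) as exc:
        bad = None
        for col in allele_cols:
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any():
                bad = (col, int(coerced.isna().idxmax()))
                break
        if bad is not None:
            raise GenotypeDataError(
                f"non-integer allele in column {bad[0]!r}, row {bad[1]}"
            ) from exc
        raise GenotypeDataError(str(exc)) from exc
    alleles = arr.reshape(len(df), len(loci), 2)
    ds = GenotypeDataset(
        ids=df["indiv_id"].astype(str).tolist(),
        pops=df["pop_id"].astype(str).tolist(),
        alleles=alleles,
        locus_names=loci,
    )
    miss = ds.missingness()
    flagged = miss.index[miss > missing_threshold].tolist()
    return ds, flagged


def write_genotypes(ds: GenotypeDataset, path) -> None:
    cols = {"pop_id": ds.pops, "indiv_id": ds.ids}
    for l, name in enumerate(ds.locus_names):
        cols[f"{name}_1"] = ds.alleles[:, l, 0]
        cols[f"{name}_2"] = ds.alleles[:, l, 1]
    pd.DataFrame(cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Per-population statistics
# ---------------------------------------------------------------------------

def _locus_het(alleles_l: np.ndarray) -> tuple[float, float] | None:
    """(He_unbiased, Ho) at one locus from a (n, 2) allele block."""
    scored = alleles_l[:, 0] > 0
    if not scored.any():
        return None
    a = alleles_l[scored]
    n = a.shape[0]
    copies = a.ravel()
    _, counts = np.unique(copies, return_counts=True)
    p = counts / (2 * n)
    he = (2 * n) / (2 * n - 1) * (1.0 - float(np.sum(p**2))) if n > 0 else 0.0
    ho = float(np.mean(a[:, 0] != a[:, 1]))
    return he, ho


def het_stats(ds: GenotypeDataset, pop: str) -> tuple[float, float, float]:
    """(He, Ho, F_IS) for one population, averaged over scored loci.

    He uses Nei's unbiased 2n/(2n-1) correction; F_IS = 1 - mean(Ho)/mean(He)
    with the convention F_IS = 0 when mean He = 0.
    """
    mask = ds.pop_mask(pop)
    if not mask.any():
        raise GenotypeDataError(f"unknown population {pop!r}")
    block = ds.alleles[mask]
    hes, hos = [], []
    for l in range(ds.n_loci):
        res = _locus_het(block[:, l, :])
        if res is not None:
            hes.append(res[0])
            hos.append(res[1])
    if not hes:
        raise GenotypeDataError(f"population {pop!r} has no scored loci")
    he, ho = float(np.mean(hes)), float(np.mean(hos))
    fis = 1.0 - ho / he if he > 0 else 0.0
    return he, ho, fis


def hwe_permutation_test(ds: GenotypeDataset, pop: str, n_perm: int = 10000,
                         seed: int = 0) -> float:
    """Two-sided permutation test of Hardy–Weinberg equilibrium.

    Allele copies are shuffled among individuals within the population,
    locus by locus; the statistic is the multi-locus F_IS; the p-value uses
    the +1/(n+1) correction on |F_IS|.  Monomorphic populations give p = 1.
    """
    mask = ds.pop_mask(pop)
    block = ds.alleles[mask]
    if block.shape[0] < 2:
        raise GenotypeDataError("HWE test needs >= 2 individuals")

    def multilocus_fis(b: np.ndarray) -> float:
        hes, hos = [], []
        for l in range(b.shape[1]):
            res = _locus_het(b[:, l, :])
            if res is not None:
                hes.append(res[0])
                hos.append(res[1])
        he = float(np.mean(hes)) if hes else 0.0
        ho = float(np.mean(hos)) if hos else 0.0
        return 1.0 - ho / he if he > 0 else 0.0

    mono = all(
        np.unique(block[block[:, l, 0] > 0, l, :]).size <= 1
        for l in range(ds.n_loci)
    )
    if mono:
        return 1.0
    obs = abs(multilocus_fis(block))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x17E]))
    count = 0
    perm_block = block.copy()
    for _ in range(n_perm):
        for l in range(ds.n_loci):
            scored = perm_block[:, l, 0] > 0
            copies = block[scored, l, :].ravel()
            shuffled = copies[rng.permutation(copies.size)]
            perm_block[scored, l, :] = shuffled.reshape(-1, 2)
        if abs(multilocus_fis(perm_block)) >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def _rarefied_locus(counts: np.ndarray, g: int) -> float:
    """Expected allele count in a sample of g gene copies (hypergeometric)."""
    N = int(counts.sum())
    if g > N:
        return np.nan
    # 1 - C(N - Na, g)/C(N, g) per allele, via log-gammas for stability
    def log_comb(a, b):
        if b > a:
            return -np.inf
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
    total = 0.0
    for na in counts:
        lc = log_comb(N - na, g) - log_comb(N, g)
        total += 1.0 - (math.exp(lc) if np.isfinite(lc) else 0.0)
    return total


def allelic_richness(ds: GenotypeDataset, pop: str, g: int) -> float:
    """Rarefied allelic richness A(g): mean over loci of the expected number
    of alleles in a hypergeometric subsample of ``g`` gene copies."""
    if g < 2:
        raise GenotypeDataError("rarefaction depth g must be >= 2")
    mask = ds.pop_mask(pop)
    block = ds.alleles[mask]
    vals = []
    for l in range(ds.n_loci):
        scored = block[:, l, 0] > 0
        if not scored.any():
            continue
        copies = block[scored, l, :].ravel()
        _, counts = np.unique(copies, return_counts=True)
        vals.append(_rarefied_locus(counts, g))
    vals = [v for v in vals if not np.isnan(v)]
    return float(np.mean(vals)) if vals else np.nan


def unique_alleles(ds: GenotypeDataset) -> pd.Series:
    """Number of alleles private to each population (summed over loci)."""
    out = pd.Series(0, index=ds.pop_names, dtype=int)
    for l in range(ds.n_loci):
        presence: dict[int, set[str]] = {}
        for i, pop in enumerate(ds.pops):
            for a in ds.alleles[i, l, :]:
                if a > 0:
                    presence.setdefault(int(a), set()).add(pop)
        for pops_with in presence.values():
            if len(pops_with) == 1:
                out[next(iter(pops_with))] += 1
    return out


def msat_summary_table(ds: GenotypeDataset, rarefy_to: tuple[int, ...] = (),
                       n_perm: int = 10000, seed: int = 0) -> pd.DataFrame:
    """Per-population summary: N, He, Ho, mean alleles/locus, rarefied
    richness at the requested gene-copy depths, F_IS, HWE p, unique alleles."""
    ua = unique_alleles(ds)
    rows = []
    for k, pop in enumerate(ds.pop_names):
        mask = ds.pop_mask(pop)
        he, ho, fis = het_stats(ds, pop)
        block = ds.alleles[mask]
        nall = []
        for l in range(ds.n_loci):
            scored = block[:, l, 0] > 0
            if scored.any():
                nall.append(np.unique(block[scored, l, :]).size)
        row = dict(pop_id=pop, N=int(mask.sum()), He=he, Ho=ho,
                   A_mean=float(np.mean(nall)) if nall else np.nan,
                   Fis=fis,
                   hwe_p=hwe_permutation_test(ds, pop, n_perm=n_perm,
                                              seed=seed + k),
                   UA=int(ua[pop]))
        for g in rarefy_to:
            row[f"A_rarefied_{g}"] = allelic_richness(ds, pop, g)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Differentiation: Weir-Cockerham theta and Jost's D
# ---------------------------------------------------------------------------

def _locus_freqs(ds: GenotypeDataset, pops: list[str], locus: int):
    """Per-population sample sizes, allele freqs and het freqs at a locus."""
    allele_ids = np.unique(ds.alleles[:, locus, :])
    allele_ids = allele_ids[allele_ids > 0]
    ns, ps, hs = [], [], []
    for pop in pops:
        block = ds.alleles[ds.pop_mask(pop), locus, :]
        scored = block[:, 0] > 0
        a = block[scored]
        n = a.shape[0]
        ns.append(n)
        if n == 0:
            ps.append(np.zeros(allele_ids.size))
            hs.append(np.zeros(allele_ids.size))
            continue
        p = np.array([(a == al).sum() for al in allele_ids]) / (2.0 * n)
        # frequency of heterozygotes carrying exactly one copy of each allele
        het = a[:, 0] != a[:, 1]
        h = np.array([
            (((a == al).sum(axis=1) == 1) & het).sum() for al in allele_ids
        ]) / n
        ps.append(p)
        hs.append(h)
    return np.array(ns, float), np.array(ps), np.array(hs)


def _wc_components(ns, ps, hs) -> tuple[float, float, float]:
    """Summed Weir & Cockerham (1984) a, b, c components over alleles."""
    r = ns.size
    if (ns < 1).any() or r < 2:
        return 0.0, 0.0, 0.0
    nbar = ns.mean()
    nc = (r * nbar - np.sum(ns**2) / (r * nbar)) / (r - 1)
    if nc <= 0 or nbar <= 1:
        return 0.0, 0.0, 0.0
    A = B = C = 0.0
    for al in range(ps.shape[1]):
        p = ps[:, al]
        h = hs[:, al]
        pbar = np.sum(ns * p) / (r * nbar)
        s2 = np.sum(ns * (p - pbar) ** 2) / ((r - 1) * nbar)
        hbar = np.sum(ns * h) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        A += a
        B += b
        C += c
    return A, B, C


def weir_cockerham_theta(ds: GenotypeDataset, pops: list[str] | None = None,
                         loci: list[int] | None = None) -> float:
    """Multi-locus, multi-allelic Weir & Cockerham theta (ratio of sums)."""
    pops = pops if pops is not None else ds.pop_names
    loci = loci if loci is not None else list(range(ds.n_loci))
    num = den = 0.0
    for l in loci:
        ns, ps, hs = _locus_freqs(ds, pops, l)
        a, b, c = _wc_components(ns, ps, hs)
        num += a
        den += a + b + c
    return num / den if den != 0 else 0.0


def jost_d(ds: GenotypeDataset, pops: list[str] | None = None,
           loci: list[int] | None = None) -> float:
    """Jost's D_est across loci.

    Per locus: ``D = (k/(k-1)) (Ht_est - Hs_est)/(1 - Hs_est)`` with the
    Nei & Chesser small-sample estimators (harmonic-mean sample size).
    Across loci the harmonic mean of per-locus D is taken; when any
    per-locus D is <= 0 the arithmetic mean is used instead (the harmonic
    mean is undefined there).
    """
    pops = pops if pops is not None else ds.pop_names
    loci = loci if loci is not None else list(range(ds.n_loci))
    k = len(pops)
    ds_per_locus = []
    for l in loci:
        ns, ps, _ = _locus_freqs(ds, pops, l)
        if (ns < 1).any():
            continue
        n_harm = k / np.sum(1.0 / ns)
        hs = 1.0 - np.mean(np.sum(ps**2, axis=1))
        pbar = ps.mean(axis=0)
        ht = 1.0 - float(np.sum(pbar**2))
        hs_est = (2 * n_harm) / (2 * n_harm - 1) * hs
        ht_est = ht + hs_est / (2 * n_harm * k)
        if 1.0 - hs_est <= 0:
            continue
        d = (k / (k - 1)) * (ht_est - hs_est) / (1.0 - hs_est)
        ds_per_locus.append(d)
    if not ds_per_locus:
        return np.nan
    arr = np.array(ds_per_locus)
    if (arr <= 0).any():
        return float(arr.mean())
    return float(len(arr) / np.sum(1.0 / arr))


@dataclass
class PairwiseMatrix:
    statistic: str
    est: pd.DataFrame
    lo: pd.DataFrame
    hi: pd.DataFrame
    n_boot: int


def pairwise_fst_jostd(ds: GenotypeDataset, n_boot: int = 1000, seed: int = 0
                       ) -> tuple[PairwiseMatrix, PairwiseMatrix]:
    """Pairwise Weir–Cockerham theta and Jost's D with 95% bootstrap CIs.

    CIs are percentile intervals from resampling loci with replacement;
    differentiation is deemed non-significant when the CI spans 0.
    """
    pops = ds.pop_names
    if len(pops) < 2:
        raise GenotypeDataError("need >= 2 populations")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB007]))
    mats = {name: {k: pd.DataFrame(np.nan, index=pops, columns=pops)
                   for k in ("est", "lo", "hi")}
            for name in ("theta", "jostd")}
    L = ds.n_loci
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            pair = [pops[i], pops[j]]
            scored = [
                l for l in range(L)
                if all((ds.alleles[ds.pop_mask(p), l, 0] > 0).any() for p in pair)
            ]
            if not scored:
                warnings.warn(f"pair {pair} shares no scored locus", stacklevel=2)
                continue
            theta = weir_cockerham_theta(ds, pair, scored)
            d = jost_d(ds, pair, scored)
            boots_t, boots_d = [], []
            for _ in range(n_boot):
                res = [scored[k] for k in rng.integers(0, len(scored), len(scored))]
                boots_t.append(weir_cockerham_theta(ds, pair, res))
                boots_d.append(jost_d(ds, pair, res))
            for name, est, boots in (("theta", theta, boots_t),
                                     ("jostd", d, boots_d)):
                lo, hi = (np.nanpercentile(boots, [2.5, 97.5])
                          if n_boot else (np.nan, np.nan))
                for a, b in ((pops[i], pops[j]), (pops[j], pops[i])):
                    mats[name]["est"].loc[a, b] = est
                    mats[name]["lo"].loc[a, b] = lo
                    mats[name]["hi"].loc[a, b] = hi
    theta_m = PairwiseMatrix("FST", mats["theta"]["est"], mats["theta"]["lo"],
                             mats["theta"]["hi"], n_boot)
    d_m = PairwiseMatrix("JostD", mats["jostd"]["est"], mats["jostd"]["lo"],
                         mats["jostd"]["hi"], n_boot)
    return theta_m, d_m


# ---------------------------------------------------------------------------
# Shared-allele distance and NJ tree
# ---------------------------------------------------------------------------

def shared_allele_distance(ds: GenotypeDataset) -> pd.DataFrame:
    """``D_SA = 1 - mean over loci of sum_a min(p1_a, p2_a)`` between pops."""
    pops = ds.pop_names
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    freqs: dict[tuple[str, int], dict[int, float]] = {}
    for pop in pops:
        block = ds.alleles[ds.pop_mask(pop)]
        for l in range(ds.n_loci):
            scored = block[:, l, 0] > 0
            copies = block[scored, l, :].ravel()
            if copies.size:
                als, cnts = np.unique(copies, return_counts=True)
                freqs[(pop, l)] = dict(zip(als.tolist(),
                                           (cnts / copies.size).tolist()))
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            shares = []
            for l in range(ds.n_loci):
                fa = freqs.get((a, l))
                fb = freqs.get((b, l))
                if fa is None or fb is None:
                    continue
                common = set(fa) | set(fb)
                shares.append(sum(min(fa.get(al, 0.0), fb.get(al, 0.0))
                                  for al in common))
            dsa = 1.0 - float(np.mean(shares)) if shares else np.nan
            out.loc[a, b] = out.loc[b, a] = dsa
    return out


def shared_allele_nj(ds: GenotypeDataset, n_boot: int = 0, seed: int = 0):
    """Neighbour-joining tree on the shared-allele distance matrix.

    Returns the newick string; with ``n_boot`` > 0 also a list of
    bootstrap-replicate newicks (loci resampled with replacement, the
    paper-style 999 replicates being the conventional choice).
    """
    pops = ds.pop_names
    if len(pops) < 3:
        raise GenotypeDataError("NJ needs >= 3 populations")
    dm = shared_allele_distance(ds)
    tree = nj(DistanceMatrix(dm.values, ids=pops))
    newick = str(tree)
    if not n_boot:
        return newick
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x13]))
    reps = []
    for _ in range(n_boot):
        loci = rng.integers(0, ds.n_loci, ds.n_loci).tolist()
        sub = GenotypeDataset(
            ids=ds.ids, pops=ds.pops,
            alleles=ds.alleles[:, loci, :],
            locus_names=[f"L{k}" for k in range(len(loci))],
            coords=ds.coords,
        )
        reps.append(str(nj(DistanceMatrix(shared_allele_distance(sub).values,
                                          ids=pops))))
    return newick, reps
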