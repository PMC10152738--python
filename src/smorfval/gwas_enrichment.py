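"""MAF-stratified permutation test for GWAS-variant enrichment in smORFs.

Trait-associated SNVs (genome-wide significant, biallelic, deduplicated) are
counted inside high-confidence smORF coding exons. The background universe is
the union of genotyping-array SNVs and their linkage-disequilibrium proxies
(r^2 >= 0.8 within 1 Mb), restricted to common variants (MAF >= 0.01) and
stratified into five MAF bins. Per bin, the null draws as many SNVs (with
replacement) from the bin's universe as the catalog contributed, counts
smORF-exon overlaps, and the empirical p-value uses the add-one
(Phipson-Smyth) formula so that a finite number of permutations never yields
p = 0. Bin p-values are combined with Fisher's method
(T = -2 * sum(ln p) ~ chi-square with 2k degrees of freedom).

A second permutation asks whether GWAS hits are enriched for damaging
protein predictions (functional scores are consumed as an input column,
never computed here; scores > 0.85 count as damaging).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

logger = logging.getLogger(__name__)

#: left-closed, right-open MAF bins; the last bin is closed at 0.50
MAF_BINS: tuple[tuple[float, float], ...] = (
    (0.01, 0.10),
    (0.10, 0.20),
    (0.20, 0.30),
    (0.30, 0.40),
    (0.40, 0.50),
)
COMMON_MAF_MIN = 0.01
DAMAGING_THRESHOLD = 0.85


def maf_bin_index(maf) -> np.ndarray:
    """Bin index (0..4) per MAF; -1 for values outside [0.01, 0.50]."""
    maf = np.asarray(maf, dtype=float)
    out = np.full(maf.shape, -1, dtype=np.int64)
    for i, (lo, hi) in enumerate(MAF_BINS):
        if i == len(MAF_BINS) - 1:
            mask = (maf >= lo) & (maf <= hi)
        else:
            mask = (maf >= lo) & (maf < hi)
        out[mask] = i
    return out


def filter_catalog(catalog: pd.DataFrame, p_max: float = 5e-8) -> pd.DataFrame:
    """GWAS-catalog hygiene: drop missing p, duplicates, multi-allelic sites,
    and keep strictly genome-wide-significant records (p < p_max)."""
    df = catalog.copy()
    missing = df["p_value"].isna()
    if missing.any():
        logger.warning("dropping %d catalog records with missing p-value", missing.sum())
        df = df[~missing]
    df = df.drop_duplicates(subset=["rsid", "pos"])
    multi_allele = df["ref"].str.contains(",") | df["alt"].str.contains(",")
    site_counts = df.groupby(["chrom", "pos"])["alt"].transform("nunique")
    df = df[~multi_allele & (site_counts == 1)]
    return df[df["p_value"] < p_max].reset_index(drop=True)


@dataclass
class BackgroundUniverse:
    """Common-variant background (arrays + LD proxies), stratified by MAF bin."""

    snvs: pd.DataFrame  # rsid, chrom, pos, maf, bin
    bins: dict[int, pd.DataFrame] = field(init=False)

    def __post_init__(self):
        self.bins = {
            i: sub.reset_index(drop=True)
            for i, sub in self.snvs.groupby("bin")
            if i >= 0
        }

    def bin_sizes(self) -> dict[int, int]:
        return {i: len(df) for i, df in self.bins.items()}


def ld_expand(
    array_snvs: pd.DataFrame,
    ld_pairs: pd.DataFrame,
    r2_min: float = 0.8,
    window: int = 1_000_000,
) -> BackgroundUniverse:
    """Array SNVs plus LD proxies with r^2 >= r2_min within ``window`` bp.

    ``array_snvs`` needs columns rsid, chrom, pos, maf; ``ld_pairs`` needs
    snv_a (an array rsid), snv_b, chrom_b, pos_b, maf_b, r2. Proxies whose
    anchor is not in the array list are ignored. The merged universe is
    deduplicated by (chrom, pos) and restricted to MAF in [0.01, 0.50].
    """
    anchors = array_snvs.set_index("rsid")["pos"]
    pairs = ld_pairs[ld_pairs["r2"] >= r2_min]
    pairs = pairs[pairs["snv_a"].isin(anchors.index)]
    if len(pairs):
        anchor_pos = anchors.loc[pairs["snv_a"]].to_numpy()
        pairs = pairs[np.abs(pairs["pos_b"].to_numpy() - anchor_pos) <= window]
    universe = array_snvs[["rsid", "chrom", "pos", "maf"]]
    if len(pairs):
        proxies = pd.DataFrame(
            {
                "rsid": pairs["snv_b"].to_numpy(),
                "chrom": pairs["chrom_b"].to_numpy(),
                "pos": pairs["pos_b"].to_numpy(),
                "maf": pairs["maf_b"].to_numpy(),
            }
        )
        universe = pd.concat([universe, proxies], ignore_index=True)
    universe = universe.drop_duplicates(subset=["chrom", "pos"])
    universe = universe[
        (universe["maf"] >= COMMON_MAF_MIN) & (universe["maf"] <= 0.50)
    ].reset_index(drop=True)
    universe["bin"] = maf_bin_index(universe["maf"].to_numpy())
    return BackgroundUniverse(universe)


class ExonIndex:
    """Sorted-interval index for half-open exon overlap queries."""

    def __init__(self, exons: list[tuple[str, int, int]]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        grouped: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in exons:
            grouped.setdefault(chrom, []).append((int(s), int(e)))
        for chrom, ivs in grouped.items():
            merged: list[list[int]] = []
            for s, e in sorted(ivs):
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            starts = np.array([m[0] for m in merged], np.int64)
            ends = np.array([m[1] for m in merged], np.int64)
            self._by_chrom[chrom] = (starts, ends)

    def contains(self, chrom, pos: np.ndarray) -> np.ndarray:
        """Boolean mask: position falls inside an exon ([start, end))."""
        pos = np.asarray(pos, np.int64)
        if np.ndim(chrom) == 0:
            entry = self._by_chrom.get(str(chrom))
            if entry is None:
                return np.zeros(len(pos), dtype=bool)
            starts, ends = entry
            idx = np.searchsorted(starts, pos, side="right") - 1
            ok = idx >= 0
            idx_c = np.clip(idx, 0, len(starts) - 1)
            return ok & (pos < ends[idx_c])
        out = np.zeros(len(pos), dtype=bool)
        for ch in np.unique(chrom):
            m = np.asarray(chrom) == ch
            out[m] = self.contains(str(ch), pos[m])
        return out


def overlap_count(snvs: pd.DataFrame, exon_index: ExonIndex) -> tuple[int, pd.DataFrame]:
    """SNVs falling inside smORF exons: count plus the hit records."""
    mask = exon_index.contains(snvs["chrom"].to_numpy(), snvs["pos"].to_numpy())
    hits = snvs[mask].reset_index(drop=True)
    return int(mask.sum()), hits


@dataclass
class BinResult:
    bin_index: int
    maf_lo: float
    maf_hi: float
    n_draw: int
    observed: int
    null_mean: float
    null_sd: float
    p: float


@dataclass
class EnrichmentResult:
    bins: list[BinResult]
    fisher_t: float
    df: int
    meta_p: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "bin": f"[{b.maf_lo:.2f},{b.maf_hi:.2f})",
                    "n_draw": b.n_draw,
                    "observed": b.observed,
                    "null_mean": b.null_mean,
                    "null_sd": b.null_sd,
                    "p": b.p,
                }
                for b in self.bins
            ]
        )


def empirical_upper_p(null_counts: np.ndarray, observed: int) -> float:
    """Add-one empirical upper-tail p: (#{null >= observed} + 1) / (n + 1)."""
    n = len(null_counts)
    return (int((null_counts >= observed).sum()) + 1) / (n + 1)


def permutation_bin_test(
    universe_hits: np.ndarray,
    n_draw: int,
    observed: int,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, np.ndarray]:
    """Permutation null for one MAF bin.

    ``universe_hits`` is the boolean smORF-overlap indicator over the bin's
    universe. Each permutation draws ``n_draw`` SNVs with replacement and
    counts overlaps. Returns (empirical p, null count distribution).
    """
    if len(universe_hits) == 0:
        raise DataError("permutation test on an empty universe bin")
    if n_draw <= 0:
        raise DataError("n_draw must be positive")
    rng = np.random.default_rng() if rng is None else rng
    hits = np.asarray(universe_hits, dtype=np.int8)
    draws = rng.integers(0, len(hits), size=(n_perm, n_draw))
    null_counts = hits[draws].sum(axis=1)
    return empirical_upper_p(null_counts, observed), null_counts


def fishers_meta(p_values) -> tuple[float, int, float]:
    """Fisher's method: T = -2 sum(ln p), df = 2k, upper-tail chi-square p."""
    ps = np.asarray(list(p_values), dtype=float)
    if len(ps) == 0:
        raise DataError("Fisher's method needs at least one p-value")
    if (ps <= 0).any() or (ps > 1).any():
        raise DataError("p-values must lie in (0, 1]")
    t = float(-2.0 * np.log(ps).sum())
    df = 2 * len(ps)
    return t, df, float(stats.chi2.sf(t, df))


def run_enrichment(
    catalog: pd.DataFrame,
    universe: BackgroundUniverse,
    exon_index: ExonIndex,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> EnrichmentResult:
    """The full MAF-stratified enrichment analysis.

    The catalog is binned by its folded MAF column; bins with an empty
    universe or no catalog SNVs are skipped with a warning and excluded from
    the meta-analysis degrees of freedom.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    cat = catalog.copy()
    cat["bin"] = maf_bin_index(cat["maf"].to_numpy())
    results: list[BinResult] = []
    for i, (lo, hi) in enumerate(MAF_BINS):
        cat_bin = cat[cat["bin"] == i]
        uni_bin = universe.bins.get(i)
        if uni_bin is None or len(uni_bin) == 0 or len(cat_bin) == 0:
            logger.warning("skipping MAF bin [%.2f,%.2f): empty", lo, hi)
            continue
        observed, _ = overlap_count(cat_bin, exon_index)
        uni_hits = exon_index.contains(
            uni_bin["chrom"].to_numpy(), uni_bin["pos"].to_numpy()
        )
        p, null_counts = permutation_bin_test(uni_hits, len(cat_bin), observed, n_perm, rng)
        results.append(
            BinResult(
                bin_index=i,
                maf_lo=lo,
                maf_hi=hi,
                n_draw=len(cat_bin),
                observed=observed,
                null_mean=float(null_counts.mean()),
                null_sd=float(null_counts.std()),
                p=p,
            )
        )
    if not results:
        raise DataError("no usable MAF bin for enrichment")
    t, df, meta_p = fishers_meta([b.p for b in results])
    return EnrichmentResult(results, t, df, meta_p)


def damaging_permutation(
    scored_pool: np.ndarray,
    n_total: int,
    observed_damaging: int,
    threshold: float = DAMAGING_THRESHOLD,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> float:
    """Permutation test for enrichment of damaging functional predictions.

    ``scored_pool`` holds functional scores in [0, 1] of the eligible SNV pool
    (common nonsynonymous smORF variants). Each permutation draws ``n_total``
    scores with replacement and counts those above ``threshold``; the
    empirical upper-tail p uses the add-one formula.
    """
    pool = np.asarray(scored_pool, dtype=float)
    if pool.size == 0:
        raise DataError("empty scored pool")
    if (pool < 0).any() or (pool > 1).any():
        raise DataError("functional scores must lie in [0, 1]")
    if not 0 <= observed_damaging <= n_total:
        raise DataError("observed_damaging must lie in [0, n_total]")
    if rng is None:
        rng = np.random.default_rng(seed)
    damaging = (pool > threshold).astype(np.int8)
    draws = rng.integers(0, len(pool), size=(n_perm, n_total))
    null_counts = damaging[draws].sum(axis=1)
    return empirical_upper_p(null_counts, observed_damaging)


def fisher_exact_damaging(
    observed_damaging: int,
    n_total: int,
    background_damaging: int,
    background_total: int,
) -> float:
    """Optional exact-test path: requires the user to supply the background
    contingency (damaging / total in the eligible pool)."""
    table = [
        [observed_damaging, n_total - observed_damaging],
        [background_damaging, background_total - background_damaging],
    ]
    return float(stats.fisher_exact(table, alternative="greater")[1])
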