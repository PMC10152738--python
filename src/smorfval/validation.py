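"""Calibration and power experiments on synthetic cohorts.

These routines measure whether the pipeline's statistics behave as designed:
constraint recovery of planted depletion factors, confidence-bound coverage,
reading-frame control power and null calibration, and permutation-test
calibration and power for the GWAS enrichment. They are used both by the
test suite and by the acceptance script; every experiment is fully seeded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import constraint_model as cm, frame_control as fc, gwas_enrichment as ge
from .synthetic_cohort import (
    SelectionProfile,
    SimulationConfig,
    simulate_cohort,
)


def _derive_seed(seed: int, offset: int) -> int:
    return int((seed * 1_000_003 + offset) % (2**31 - 1))


# ---------------------------------------------------------------------------
# MOEUF oracle


def moeuf_fine_grid_oracle(observed: int, expected: float, ci: float = 0.90,
                           grid_max: float = 2.0, step: float = 1e-5) -> float:
    """Independent fine-grid recomputation of the MOEUF bound."""
    lam = np.arange(0.0, grid_max + step / 2, step)
    rate = lam * expected
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = observed * np.log(rate) - rate
    if observed == 0:
        ll[0] = 0.0
    ll -= np.max(ll)
    w = np.exp(ll)
    cum = np.cumsum(w) / w.sum()
    return float(lam[np.searchsorted(cum, (1 + ci) / 2)])


def moeuf_oracle_comparison(seed: int, n_pairs: int = 100) -> pd.DataFrame:
    """Grid MOEUF vs fine-grid oracle over random (observed, expected) pairs."""
    rng = np.random.default_rng(_derive_seed(seed, 11))
    rows = []
    for _ in range(n_pairs):
        expected = float(rng.uniform(2.0, 200.0))
        oe_true = float(rng.uniform(0.05, 1.5))
        observed = int(rng.poisson(oe_true * expected))
        grid = cm.moeuf_upper_bound(observed, expected)
        fine = moeuf_fine_grid_oracle(observed, expected)
        rows.append(
            {"observed": observed, "expected": expected, "grid": grid,
             "fine": fine, "abs_dev": abs(grid - fine)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# constraint recovery


def _constraint_cfg(seed: int, n_entities: int = 200) -> SimulationConfig:
    """Entities long enough for ~50 expected missense each, half constrained."""
    return SimulationConfig(
        genome_length=60 + int(n_entities * 560),
        n_genes=0,
        n_smorfs=n_entities,
        smorf_length_range=(120, 120),
        selection_profile=SelectionProfile(
            smorf_constrained_fraction=0.5, f_mis_constrained=0.3, f_lof_constrained=0.3
        ),
        fraction_exact=0.0,
        fraction_jitter=0.0,
        unique_a_share=1.0,
        fraction_refseq_decoy=0.0,
        fraction_reverse_decoy=0.0,
        fraction_peptide_decoy=0.0,
        fraction_offlist_category=0.0,
        max_exons_smorf=1,
        gap_range=(60, 120),
        seed=_derive_seed(seed, 23),
    )


def constraint_recovery_experiment(seed: int, n_entities: int = 200) -> dict:
    """Score planted entities and compare o/e and MOEUF coverage with truth.

    Returns mean o/e per planted class, the MOEUF coverage (fraction of
    entities whose true depletion lies strictly below the bound), the
    calibration constant relative to the generator's emission constant, and
    the synonymous fit correlation.
    """
    cfg = _constraint_cfg(seed, n_entities)
    cohort = simulate_cohort(cfg, with_conservation=False, with_gwas=False)
    models = [e.model for e in cohort.plant.smorfs]
    truth_f = {e.model.id: e.f_mis for e in cohort.plant.smorfs}
    calib = cm.fit_calibration(
        models, cohort.genome, cohort.variants, cohort.rate_table, cohort.methylation
    )
    scored = cm.score_entities(
        models, cohort.genome, cohort.variants, cohort.rate_table, calib,
        cohort.methylation,
    )
    scored["f_true"] = scored["id"].map(truth_f)
    by_class = scored.groupby("f_true")["oe_mis"].mean().to_dict()
    coverage = float((scored["f_true"] < scored["moeuf"]).mean())
    return {
        "mean_oe_by_class": {float(k): float(v) for k, v in by_class.items()},
        "coverage": coverage,
        "k_ratio": calib.k / cfg.emission_constant,
        "syn_correlation": calib.correlation,
        "mean_expected_mis": float(scored["exp_mis"].mean()),
        "n_entities": len(scored),
        "scored": scored,
    }


# ---------------------------------------------------------------------------
# reading-frame control


def _frame_cfg(seed: int, n_entities: int, f_mis: float) -> SimulationConfig:
    return SimulationConfig(
        genome_length=400 + int(n_entities * 360),
        n_genes=0,
        n_smorfs=n_entities,
        smorf_length_range=(40, 80),
        selection_profile=SelectionProfile(
            smorf_constrained_fraction=1.0, f_mis_constrained=f_mis,
            f_lof_constrained=f_mis,
        ),
        fraction_exact=0.0,
        fraction_jitter=0.0,
        unique_a_share=1.0,
        fraction_refseq_decoy=0.0,
        fraction_reverse_decoy=0.0,
        fraction_peptide_decoy=0.0,
        fraction_offlist_category=0.0,
        max_exons_smorf=1,
        gap_range=(40, 100),
        seed=seed,
    )


def frame_replicate(seed: int, n_entities: int = 150, f_mis: float = 0.3) -> dict:
    """One frame-control replicate: plant selection in the correct frame only,
    profile all six frames, and run the paired tests.

    Returns the per-frame Wilcoxon p-values on MOEUF, whether the correct
    frame had the lowest median N/S, and the per-frame p-values on N/S.
    """
    cfg = _frame_cfg(seed, n_entities, f_mis)
    cohort = simulate_cohort(cfg, with_conservation=False, with_gwas=False)
    models = [e.model for e in cohort.plant.smorfs]
    calib = cm.fit_calibration(
        models, cohort.genome, cohort.variants, cohort.rate_table, cohort.methylation
    )
    table = fc.run_frame_analysis(
        models, cohort.genome, cohort.variants, cohort.rate_table, calib,
        cohort.methylation,
    )
    tests_moeuf = fc.paired_frame_test(table, "moeuf", min_pairs=10)
    medians_ns = (
        table.dropna(subset=["ns_ratio"]).groupby("frame")["ns_ratio"].median()
    )
    correct_lowest = bool(medians_ns.get("correct", np.inf) == medians_ns.min())
    try:
        tests_ns = fc.paired_frame_test(table, "ns_ratio", min_pairs=10)
        p_ns = tests_ns.set_index("frame")["p"].to_dict()
    except Exception:
        p_ns = {}
    return {
        "p_moeuf": tests_moeuf.set_index("frame")["p"].to_dict(),
        "p_ns": p_ns,
        "correct_ns_lowest": correct_lowest,
        "median_ns": medians_ns.to_dict(),
    }


def frame_power_experiment(seed: int, n_replicates: int = 100,
                           n_entities: int = 150, f_mis: float = 0.3) -> dict:
    """Fraction of replicates where every incorrect frame is significantly
    worse than the correct frame (MOEUF Wilcoxon p < 0.05) and the correct
    frame has the lowest median N/S."""
    hits = 0
    for r in range(n_replicates):
        rep = frame_replicate(_derive_seed(seed, 1000 + r), n_entities, f_mis)
        ok = all(p < 0.05 for p in rep["p_moeuf"].values()) and rep["correct_ns_lowest"]
        hits += int(ok)
    return {"success_fraction": hits / n_replicates, "n_replicates": n_replicates}


def frame_null_experiment(seed: int, n_replicates: int = 60,
                          n_entities: int = 150) -> dict:
    """Null calibration: with no selection, the paired MOEUF test p-values
    should be uniform across replicates (checked per incorrect frame)."""
    ps: dict[str, list[float]] = {f: [] for f in fc.INCORRECT_FRAMES}
    for r in range(n_replicates):
        rep = frame_replicate(_derive_seed(seed, 5000 + r), n_entities, f_mis=1.0)
        for f in fc.INCORRECT_FRAMES:
            ps[f].append(rep["p_moeuf"][f])
    ks_p = float(stats.kstest(np.array(ps[fc.INCORRECT_FRAMES[0]]), "uniform").pvalue)
    return {"ks_p_first_frame": ks_p, "p_by_frame": ps}


# ---------------------------------------------------------------------------
# GWAS enrichment calibration / power


def _synthetic_universe(rng: np.random.Generator, m_per_bin: int = 4000,
                        hit_fraction: float = 0.3):
    """A constructed background universe with a known smORF-overlap fraction.

    Positions are laid on a line with a contiguous 'smORF exon' block whose
    width gives the requested overlap fraction per bin.
    """
    length = 1_000_000
    exon_hi = int(length * hit_fraction)
    index = ge.ExonIndex([("chrU", 0, exon_hi)])
    rows = []
    for b, (lo, hi) in enumerate(ge.MAF_BINS):
        pos = rng.integers(0, length, size=m_per_bin)
        maf = rng.uniform(lo, min(hi, 0.499999), size=m_per_bin)
        rows.append(pd.DataFrame({
            "rsid": [f"b{b}s{i}" for i in range(m_per_bin)],
            "chrom": "chrU", "pos": pos, "maf": maf,
        }))
    snvs = pd.concat(rows, ignore_index=True)
    snvs["bin"] = ge.maf_bin_index(snvs["maf"].to_numpy())
    return ge.BackgroundUniverse(snvs), index


def enrichment_null_experiment(seed: int, n_replicates: int = 500,
                               n_draw: int = 800, n_perm: int = 1000) -> dict:
    """Meta p-value calibration under the null.

    Each replicate draws a catalog uniformly from the universe (no
    enrichment), runs the five per-bin permutation tests and Fisher's
    method. Returns the meta p-values and their KS uniformity p.

    Draw sizes matter here: the overlap count is discrete, so its add-one
    empirical p-value is super-uniform (conservative) on a coarse grid. The
    default draw size and background overlap mass keep the attainable
    p-value grid fine relative to the KS test's sensitivity, so the check
    probes calibration rather than granularity.
    """
    rng = np.random.default_rng(_derive_seed(seed, 77))
    universe, index = _synthetic_universe(rng)
    meta_ps = []
    for _ in range(n_replicates):
        bin_ps = []
        for b, uni in sorted(universe.bins.items()):
            hits = index.contains(uni["chrom"].to_numpy(), uni["pos"].to_numpy())
            draw = rng.integers(0, len(uni), size=n_draw)
            observed = int(hits[draw].sum())
            p, _ = ge.permutation_bin_test(hits, n_draw, observed, n_perm, rng)
            bin_ps.append(p)
        meta_ps.append(ge.fishers_meta(bin_ps)[2])
    meta_ps = np.array(meta_ps)
    return {
        "meta_ps": meta_ps,
        "ks_p": float(stats.kstest(meta_ps, "uniform").pvalue),
        "n_replicates": n_replicates,
    }


def enrichment_power_experiment(seed: int, n_replicates: int = 100,
                                enrichment_ratio: float = 3.0,
                                n_draw: int = 100, n_perm: int = 2000) -> dict:
    """Detection power: catalogs drawn with extra weight inside smORF exons
    should yield meta p < 0.05 in most replicates."""
    rng = np.random.default_rng(_derive_seed(seed, 99))
    universe, index = _synthetic_universe(rng, hit_fraction=0.1)
    n_sig = 0
    for _ in range(n_replicates):
        bin_ps = []
        for b, uni in sorted(universe.bins.items()):
            hits = index.contains(uni["chrom"].to_numpy(), uni["pos"].to_numpy())
            w = np.where(hits, enrichment_ratio, 1.0)
            draw = rng.choice(len(uni), size=n_draw, replace=True, p=w / w.sum())
            observed = int(hits[draw].sum())
            p, _ = ge.permutation_bin_test(hits, n_draw, observed, n_perm, rng)
            bin_ps.append(p)
        meta_p = ge.fishers_meta(bin_ps)[2]
        n_sig += int(meta_p < 0.05)
    return {"power": n_sig / n_replicates, "n_replicates": n_replicates}


# ---------------------------------------------------------------------------
# published supplementary tables


def supplementary_table_counts(high_confidence_path, gwas_hits_path) -> dict:
    """Tallies of the published supplementary tables, when provided.

    The first table lists high-confidence smORFs (one row per smORF); the
    second lists smORFs carrying trait-associated SNVs, with a consequence
    column from which nonsynonymous hits are counted.
    """
    hc = pd.read_csv(high_confidence_path, sep=None, engine="python")
    hits = pd.read_csv(gwas_hits_path, sep=None, engine="python")
    csq_col = next(
        (c for c in hits.columns if "conseq" in c.lower() or "function" in c.lower()),
        None,
    )
    n_nonsyn = (
        int(hits[csq_col].str.lower().str.contains("nonsyn|missense").sum())
        if csq_col is not None
        else 0
    )
    return {
        "n_high_confidence": len(hc),
        "n_gwas_hits": len(hits),
        "n_nonsynonymous_hits": n_nonsyn,
    }
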