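"""Expected variant counts and observed/expected constraint with MOEUF.

The model follows the gnomAD-style observed/expected framework: a
trinucleotide-context mutation-rate table gives each possible SNV a relative
rate mu; the expected number of observed variants of a consequence class in an
entity is ``k * sum(mu)`` over the class's possible SNVs, with the single
scaling constant ``k`` calibrated by least squares (through the origin) on
synonymous variation, which is assumed neutral. MOEUF is the upper bound of
the 90% confidence interval of the missense observed/expected ratio, obtained
from the normalised Poisson likelihood on a lambda grid [0, 2] with step
0.001 — the convention used for published OEUF/LOEUF scores. No coverage
correction is applied (the observed set is whole-genome calling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import _seq, variant_effects as ve
from ._seq import Genome
from .errors import DataError

#: CpG methylation levels (0 = unmethylated / non-CpG, 2 = highly methylated)
METHYL_LEVELS = (0, 1, 2)


def _is_transition(ref: int, alt: int) -> bool:
    return (ref + alt) % 2 == 0 and ref != alt


def _context_str(idx: int) -> str:
    b = _seq.BASE_LETTERS
    return b[(idx >> 4) & 3] + b[(idx >> 2) & 3] + b[idx & 3]


def _cpg_transition_mask() -> np.ndarray:
    """Boolean (64, 4): context/alt pairs that are CpG transitions.

    A CpG transition is C>T where the mutated C is followed by G on its own
    strand; on the reference plus strand that is either the C of a 'CG'
    dinucleotide mutating to T, or the G of a 'CG' mutating to A (the
    complementary-strand C>T).
    """
    mask = np.zeros((64, 4), dtype=bool)
    for idx in range(64):
        mid = (idx >> 2) & 3
        left = (idx >> 4) & 3
        right = idx & 3
        if mid == _seq.C and right == _seq.G:
            mask[idx, _seq.T] = True
        if mid == _seq.G and left == _seq.C:
            mask[idx, _seq.A] = True
    return mask


CPG_TRANSITION = _cpg_transition_mask()


@dataclass
class MutationRateTable:
    """Relative per-site SNV rates keyed by (context, alt, methylation level).

    All 192 (context, alt) pairs must be present at level 0; CpG-transition
    pairs additionally carry rows for levels 1 and 2. Internally a dense
    (3, 64, 4) tensor is built, with non-CpG entries at levels > 0 falling
    back to level 0.
    """

    df: pd.DataFrame
    _tensor: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        df = self.df
        required = {"context", "alt", "methyl_level", "mu"}
        if not required.issubset(df.columns):
            raise DataError(f"rate table needs columns {sorted(required)}")
        if (df["mu"] <= 0).any():
            raise DataError("all mutation rates must be positive")
        tensor = np.full((3, 64, 4), np.nan)
        for row in df.itertuples(index=False):
            ctx = _seq.encode(row.context)
            alt = _seq.encode(row.alt)[0]
            idx = int(ctx[0]) * 16 + int(ctx[1]) * 4 + int(ctx[2])
            if alt == ctx[1]:
                raise DataError(f"alt equals reference middle base in {row.context}>{row.alt}")
            tensor[int(row.methyl_level), idx, alt] = row.mu
        level0 = tensor[0]
        for idx in range(64):
            mid = (idx >> 2) & 3
            for alt in range(4):
                if alt == mid:
                    continue
                if np.isnan(level0[idx, alt]):
                    raise DataError(
                        f"rate table is missing context {_context_str(idx)} "
                        f"alt {_seq.BASE_LETTERS[alt]}"
                    )
        for lev in (1, 2):
            missing_cpg = CPG_TRANSITION & np.isnan(tensor[lev])
            if missing_cpg.any():
                idx, alt = np.argwhere(missing_cpg)[0]
                raise DataError(
                    f"missing CpG methylation level {lev} row for context "
                    f"{_context_str(int(idx))} alt {_seq.BASE_LETTERS[int(alt)]}"
                )
            fallback = np.isnan(tensor[lev])
            tensor[lev][fallback] = level0[fallback]
        tensor[np.isnan(tensor)] = np.inf  # alt == ref, never queried
        self._tensor = tensor

    def mu(self, ctx_idx: np.ndarray, alt: np.ndarray, level: np.ndarray) -> np.ndarray:
        """Vectorised rate lookup (context index 0..63, alt code, methyl level)."""
        # methylation only modulates CpG transitions; other sites use level 0
        lev = np.where(CPG_TRANSITION[ctx_idx, alt], level, 0)
        out = self._tensor[lev, ctx_idx, alt]
        if np.isinf(out).any():
            bad = int(np.argmax(np.isinf(out)))
            raise DataError(
                f"rate lookup with alt equal to reference middle base at "
                f"context {_context_str(int(np.asarray(ctx_idx).reshape(-1)[bad]))}"
            )
        return out

    @property
    def max_mu(self) -> float:
        t = self._tensor[np.isfinite(self._tensor)]
        return float(t.max())

    @classmethod
    def from_tsv(cls, path) -> "MutationRateTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def default(cls) -> "MutationRateTable":
        """A context-dependent table with human-like structure.

        Transitions run ~3x faster than transversions and CpG transitions
        faster still, increasing with methylation level; a fixed-seed
        multiplicative jitter per (context, alt) makes every context distinct
        while keeping the table deterministic. Rates are scaled so that, at
        the gnomAD-scale diploid sample size, per-site observation
        probabilities stay well below 1.
        """
        rng = np.random.default_rng(20230501)
        mu_tv, mu_ts = 3.0e-7, 9.0e-7
        cpg_levels = {0: 1.8e-6, 1: 2.4e-6, 2: 3.0e-6}
        rows = []
        for idx in range(64):
            mid = (idx >> 2) & 3
            for alt in range(4):
                if alt == mid:
                    continue
                jitter = rng.uniform(0.85, 1.15)
                if CPG_TRANSITION[idx, alt]:
                    for lev, base in cpg_levels.items():
                        rows.append(
                            (_context_str(idx), _seq.BASE_LETTERS[alt], lev, base * jitter)
                        )
                else:
                    base = mu_ts if _is_transition(mid, alt) else mu_tv
                    rows.append((_context_str(idx), _seq.BASE_LETTERS[alt], 0, base * jitter))
        return cls(pd.DataFrame(rows, columns=["context", "alt", "methyl_level", "mu"]))


@dataclass
class Calibration:
    """Scaling from summed mu to expected observed count, with fit diagnostics."""

    k: float
    n_entities: int
    correlation: float

    def __post_init__(self):
        if self.k <= 0:
            raise DataError("calibration constant k must be positive")


def possible_mu_by_class(
    orf: ve.OrfModel, genome: Genome, rate_table: MutationRateTable, methylation=None
) -> np.ndarray:
    """Sum of mu over possible SNVs, per consequence class (length-7 vector)."""
    view = ve.coding_view(orf, genome)
    return view_mu_by_class(view, orf, genome, rate_table, methylation)


def view_mu_by_class(
    view: ve.CodingView,
    orf: ve.OrfModel | None,
    genome: Genome,
    rate_table: MutationRateTable,
    methylation=None,
) -> np.ndarray:
    out = np.zeros(len(ve.CONSEQUENCES))
    _, _, _, cls, mu = ve.possible_snv_arrays(view, genome, rate_table, methylation)
    np.add.at(out, cls, mu)
    if orf is not None:
        _, _, _, scls, smu = ve.splice_snv_arrays(orf, genome, rate_table, methylation)
        np.add.at(out, scls, smu)
    return out


def fit_calibration(
    reference_entities: list[ve.OrfModel],
    genome: Genome,
    variants: pd.DataFrame,
    rate_table: MutationRateTable,
    methylation=None,
    maf_max: float = 0.001,
    min_entities: int = 20,
) -> Calibration:
    """Fit k on synonymous variation: least squares through the origin of
    observed synonymous counts against summed synonymous mu per entity."""
    xs, ys = [], []
    for orf in reference_entities:
        mu_sums = possible_mu_by_class(orf, genome, rate_table, methylation)
        x = mu_sums[ve.SYNONYMOUS]
        if x <= 0:
            continue
        obs = ve.tabulate_observed(orf, genome, variants, maf_max)
        xs.append(x)
        ys.append(obs.n_syn)
    xs = np.array(xs)
    ys = np.array(ys, dtype=float)
    usable = ys > 0
    if int(usable.sum()) < min_entities:
        raise DataError(
            f"calibration needs >= {min_entities} reference entities with "
            f"observed synonymous variants, got {int(usable.sum())}"
        )
    k = float((xs * ys).sum() / (xs * xs).sum())
    if len(xs) >= 2 and np.std(xs) > 0 and np.std(ys) > 0:
        r = float(np.corrcoef(xs, ys)[0, 1])
    else:
        r = float("nan")
    return Calibration(k=k, n_entities=len(xs), correlation=r)


def expected_counts(
    orf: ve.OrfModel,
    genome: Genome,
    rate_table: MutationRateTable,
    calibration: Calibration,
    methylation=None,
) -> dict[str, float]:
    """Expected observed count per consequence class, k * sum(mu)."""
    mu_sums = possible_mu_by_class(orf, genome, rate_table, methylation)
    out = {ve.CONSEQUENCES[i]: calibration.k * mu_sums[i] for i in range(len(mu_sums))}
    # mirror the observed N/S convention: N pools missense and stop-loss
    out["nonsynonymous"] = sum(out[ve.CONSEQUENCES[c]] for c in ve.N_CLASSES)
    return out


@dataclass
class ConstraintResult:
    """Observed/expected missense constraint for one entity."""

    id: str
    observed_mis: int
    expected_mis: float
    oe: float
    moeuf: float
    flags: tuple[str, ...] = ()


GRID_STEP = 0.001
GRID_MAX = 2.0


def _moeuf_grid(ci: float, grid_max: float, grid_step: float) -> np.ndarray:
    return np.arange(0.0, grid_max + grid_step / 2, grid_step)


def moeuf_upper_bound(
    observed: int,
    expected: float,
    ci: float = 0.90,
    grid_max: float = GRID_MAX,
    grid_step: float = GRID_STEP,
) -> float:
    """Upper CI bound of observed/expected from the normalised Poisson
    likelihood on a lambda grid.

    L(lambda) = Poisson(observed; lambda * expected) is normalised to sum to 1
    over the grid; the bound is the smallest grid lambda whose cumulative
    normalised likelihood reaches (1 + ci) / 2.
    """
    if expected <= 0:
        raise DataError("expected count must be positive")
    lam = _moeuf_grid(ci, grid_max, grid_step)
    rate = lam * expected
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = observed * np.log(rate) - rate - gammaln(observed + 1)
    if observed == 0:
        ll[0] = -rate[0]
    ll -= ll.max()
    w = np.exp(ll)
    cum = np.cumsum(w) / w.sum()
    thr = (1.0 + ci) / 2.0
    idx = int(np.searchsorted(cum, thr))
    idx = min(idx, len(lam) - 1)
    return float(lam[idx])


def oe_and_moeuf(
    observed: int,
    expected: float,
    ci: float = 0.90,
    grid_max: float = GRID_MAX,
    grid_step: float = GRID_STEP,
    entity_id: str = "",
) -> ConstraintResult:
    if expected <= 0:
        raise DataError("expected count must be positive")
    oe = observed / expected
    moeuf = moeuf_upper_bound(observed, expected, ci, grid_max, grid_step)
    flags = []
    if observed >= grid_max * expected:
        flags.append("saturated")
        moeuf = grid_max
    return ConstraintResult(
        id=entity_id,
        observed_mis=int(observed),
        expected_mis=float(expected),
        oe=float(oe),
        moeuf=moeuf,
        flags=tuple(flags),
    )


def score_entities(
    entities: list[ve.OrfModel],
    genome: Genome,
    variants: pd.DataFrame,
    rate_table: MutationRateTable,
    calibration: Calibration,
    methylation=None,
    maf_max: float = 0.001,
    low_expected_floor: float = 10.0,
    ci: float = 0.90,
) -> pd.DataFrame:
    """MOEUF and observed-count table, one row per entity.

    Entities with expected missense below ``low_expected_floor`` are flagged
    low-power: their MOEUF is expected to be high regardless of true
    constraint.
    """
    rows = []
    for orf in entities:
        obs = ve.tabulate_observed(orf, genome, variants, maf_max)
        exp = expected_counts(orf, genome, rate_table, calibration, methylation)
        exp_mis = exp["nonsynonymous"]
        exp_syn = exp["synonymous"]
        if exp_mis > 0:
            res = oe_and_moeuf(obs.n_mis, exp_mis, ci=ci, entity_id=orf.id)
            flags = list(res.flags)
            oe, moeuf = res.oe, res.moeuf
        else:
            oe, moeuf, flags = np.nan, np.nan, ["no_missense_sites"]
        if exp_mis < low_expected_floor:
            flags.append("low_power")
        rows.append(
            {
                "id": orf.id,
                "n_syn_obs": obs.n_syn,
                "n_mis_obs": obs.n_mis,
                "n_lof_obs": obs.n_lof,
                "exp_syn": exp_syn,
                "exp_mis": exp_mis,
                "oe_mis": oe,
                "moeuf": moeuf,
                "ns_ratio": obs.ns_ratio,
                "lofs_ratio": obs.lofs_ratio,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)
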