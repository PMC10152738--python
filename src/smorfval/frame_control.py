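"""Alternate-reading-frame negative controls for protein-level conservation.

Every coding entity has five "incorrect" readings of its spliced sequence:
shifts of +1 and +2 on the same strand, and shifts of +0/+1/+2 on the
reverse complement. These are not ORF calls — they need no ATG and may carry
internal stops — but they share the entity's genomic footprint, so under
purifying selection acting on the encoded peptide (rather than on the DNA),
only the correct frame should show depleted nonsynonymous variation. N/S and
MOEUF are recomputed per frame with the same rules and the same calibration
constant as the correct frame, and correct-vs-incorrect differences are
tested with the paired two-sided Wilcoxon signed-rank test.

Frames shift on the spliced transcript, preserving exon chains for
multi-exon entities; trailing partial codons are dropped. Splice-region
variants are excluded from frame profiles (they are frame-independent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import constraint_model as cm, variant_effects as ve
from ._seq import COMP, Genome
from .errors import DataError

FRAME_LABELS = ("correct", "same+1", "same+2", "opp+0", "opp+1", "opp+2")
INCORRECT_FRAMES = FRAME_LABELS[1:]


@dataclass(frozen=True)
class FrameVariant:
    """One reading frame of a parent entity, as a concrete coding view."""

    parent_id: str
    label: str
    view: ve.CodingView
    offset: int
    opposite: bool

    @property
    def n_codons(self) -> int:
        return self.view.n_codons


def alternate_frames(orf: ve.OrfModel, genome: Genome) -> dict[str, FrameVariant]:
    """The correct frame plus the five incorrect frames of an entity."""
    base = ve.coding_view(orf, genome)
    L = len(base.codes)
    if L < 6:
        raise DataError(f"{orf.id}: spliced length {L} too short for frame analysis")
    if L % 3 != 0:
        raise DataError(f"{orf.id}: spliced length {L} not a multiple of 3")
    out: dict[str, FrameVariant] = {}
    rc_codes = COMP[base.codes][::-1]
    rc_positions = base.positions[::-1]
    for label in FRAME_LABELS:
        if label == "correct":
            opposite, k = False, 0
        elif label.startswith("same"):
            opposite, k = False, int(label[-1])
        else:
            opposite, k = True, int(label[-1])
        codes = rc_codes if opposite else base.codes
        positions = rc_positions if opposite else base.positions
        n = (L - k) // 3
        sel = slice(k, k + 3 * n)
        view = ve.CodingView(
            id=f"{orf.id}:{label}",
            chrom=orf.chrom,
            positions=positions[sel],
            codes=codes[sel],
            flip=base.flip ^ opposite,
        )
        out[label] = FrameVariant(orf.id, label, view, k, opposite)
    return out


def frame_profile(
    frame: FrameVariant,
    genome: Genome,
    variants: pd.DataFrame,
    rate_table: cm.MutationRateTable,
    calibration: cm.Calibration,
    methylation=None,
    maf_max: float = 0.001,
) -> tuple[ve.ObservedCounts, cm.ConstraintResult]:
    """Observed N/S counts and MOEUF for one reading frame."""
    counts = ve.observed_class_counts(frame.view, genome, variants, maf_max)
    obs = ve.ObservedCounts(
        id=frame.view.id,
        n_syn=int(counts[ve.SYNONYMOUS]),
        n_mis=int(sum(counts[c] for c in ve.N_CLASSES)),
        n_lof=int(sum(counts[c] for c in ve.LOF_CLASSES)),
        per_class={ve.CONSEQUENCES[i]: int(counts[i]) for i in range(len(counts))},
    )
    mu_sums = cm.view_mu_by_class(frame.view, None, genome, rate_table, methylation)
    exp_mis = calibration.k * sum(mu_sums[c] for c in ve.N_CLASSES)
    if exp_mis > 0:
        res = cm.oe_and_moeuf(obs.n_mis, exp_mis, entity_id=frame.view.id)
    else:
        res = cm.ConstraintResult(
            frame.view.id, obs.n_mis, 0.0, np.nan, np.nan, ("no_missense_sites",)
        )
    return obs, res


def run_frame_analysis(
    orfs: list[ve.OrfModel],
    genome: Genome,
    variants: pd.DataFrame,
    rate_table: cm.MutationRateTable,
    calibration: cm.Calibration,
    methylation=None,
    maf_max: float = 0.001,
) -> pd.DataFrame:
    """Per-entity, per-frame N/S and MOEUF (long format)."""
    rows = []
    for orf in orfs:
        try:
            frames = alternate_frames(orf, genome)
        except DataError:
            continue
        for label, frame in frames.items():
            obs, res = frame_profile(
                frame, genome, variants, rate_table, calibration, methylation, maf_max
            )
            rows.append(
                {
                    "id": orf.id,
                    "frame": label,
                    "n_codons": frame.n_codons,
                    "n_syn": obs.n_syn,
                    "n_mis": obs.n_mis,
                    "ns_ratio": obs.ns_ratio,
                    "oe_mis": res.oe,
                    "moeuf": res.moeuf,
                }
            )
    return pd.DataFrame(rows)


def paired_wilcoxon(correct: np.ndarray, other: np.ndarray) -> float:
    """Two-sided paired Wilcoxon signed-rank p; p = 1 for identical vectors."""
    correct = np.asarray(correct, float)
    other = np.asarray(other, float)
    if len(correct) != len(other) or len(correct) == 0:
        raise DataError("paired test needs equal-length non-empty vectors")
    diffs = correct - other
    if np.all(diffs == 0):
        return 1.0
    return float(stats.wilcoxon(correct, other, zero_method="wilcox").pvalue)


def paired_frame_test(
    frame_table: pd.DataFrame,
    metric: str = "moeuf",
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Compare each incorrect frame against the correct frame.

    For every incorrect frame, entities with a defined metric in both members
    of the pair are retained; reported are the number of complete pairs, the
    medians of both members, and the two-sided paired Wilcoxon signed-rank p.
    """
    wide = frame_table.pivot_table(index="id", columns="frame", values=metric, aggfunc="first")
    if "correct" not in wide.columns:
        raise DataError("frame table has no correct-frame rows")
    rows = []
    for label in INCORRECT_FRAMES:
        if label not in wide.columns:
            continue
        pair = wide[["correct", label]].dropna()
        if len(pair) < min_pairs:
            raise DataError(
                f"frame {label}: only {len(pair)} complete pairs (need >= {min_pairs})"
            )
        p = paired_wilcoxon(pair["correct"].to_numpy(), pair[label].to_numpy())
        rows.append(
            {
                "frame": label,
                "metric": metric,
                "n_pairs": len(pair),
                "median_correct": float(pair["correct"].median()),
                "median_frame": float(pair[label].median()),
                "p": p,
            }
        )
    return pd.DataFrame(rows)
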