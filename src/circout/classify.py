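"""Transcriptional-output classification of assigned peaks.

Each peak assigned to a gene inherits that gene's transcriptional output,
decided from its circadian nascent-RNA series (12 points at 4-h spacing
over 48 h) and, for the arrhythmic branch, its mRNA series:

1. no expression record at all            -> NO_SIGNAL
2. mean nascent signal < 1 read/bp        -> NE (not transcribed)
3. expressed but below the rhythm-test
   expression floor                       -> LOW_EXPRESSION
4. nascent rhythmic, peak in [ZT2, ZT12)  -> RIN_PHI (in-phase cycler)
   nascent rhythmic, peak elsewhere       -> RO_PHI (out-of-phase cycler)
5. nascent arrhythmic, mRNA rhythmic      -> POST_TRANSCRIPTIONAL
   nascent arrhythmic, mRNA not           -> AR

Step 5's mRNA gate removes false-positive "arrhythmic" calls: a gene whose
mRNA cycles while its transcription does not is post-transcriptionally
regulated, not a trustworthy arrhythmic example.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import PeakAssignment
from .rhythms import RhythmFit, detect_rhythm

__all__ = [
    "OutputClass",
    "ClassifyConfig",
    "ClassifiedPeak",
    "classify_peak",
    "classify_peaks",
    "class_counts",
    "classified_to_frame",
    "select_matched_controls",
]


class OutputClass(str, Enum):
    RIN_PHI = "Rin_phi"                    # rhythmic, in phase with TF binding
    RO_PHI = "Ro_phi"                      # rhythmic, out of phase
    AR = "AR"                              # arrhythmically transcribed
    NE = "NE"                              # not transcribed
    POST_TRANSCRIPTIONAL = "post_transcriptional"
    LOW_EXPRESSION = "low_expression"
    NO_SIGNAL = "no_signal"


#: the four headline classes analysed throughout
HEADLINE_CLASSES = (
    OutputClass.RIN_PHI,
    OutputClass.RO_PHI,
    OutputClass.AR,
    OutputClass.NE,
)


@dataclass(frozen=True)
class ClassifyConfig:
    """Thresholds of the classification flowchart.

    ``phase_window`` is the half-open [ZT2, ZT12) interval of "in-phase"
    transcription peaks, matching the daytime window of maximal TF DNA
    binding.  ``ne_threshold`` (reads/bp, mean over the 12 nascent samples)
    separates non-transcribed genes; ``low_expression_floor`` is the
    expression level below which the rhythm test is not trusted (defaults
    to the rhythm test's own ``min_level``).
    """

    phase_window: tuple[float, float] = (2.0, 12.0)
    ne_threshold: float = 1.0
    low_expression_floor: float = 1.0
    alpha: float = 0.05
    min_fold: float = 1.5
    min_level: float = 1.0
    period: float = 24.0


@dataclass(frozen=True)
class ClassifiedPeak:
    assignment: PeakAssignment
    output_class: OutputClass
    mean_nascent_level: float | None = None
    nascent_fit: RhythmFit | None = None
    mrna_fit: RhythmFit | None = None


def _in_phase(phase: float, window: tuple[float, float], period: float) -> bool:
    lo, hi = window
    phase = phase % period
    if lo <= hi:
        return lo <= phase < hi
    return phase >= lo or phase < hi


def classify_peak(
    assignment: PeakAssignment,
    nascent: pd.DataFrame | None,
    mrna: pd.DataFrame | None,
    cfg: ClassifyConfig = ClassifyConfig(),
) -> ClassifiedPeak:
    """Apply the flowchart to one assigned peak.

    ``nascent``/``mrna`` are long-format frames with ``time`` and ``value``
    columns (replicates averaged per time point), or ``None`` when the gene
    has no record in the corresponding dataset.
    """
    if nascent is None:
        return ClassifiedPeak(assignment, OutputClass.NO_SIGNAL)

    n_means = nascent.groupby("time")["value"].mean().sort_index()
    mean_level = float(n_means.mean())
    if mean_level < cfg.ne_threshold:
        return ClassifiedPeak(assignment, OutputClass.NE, mean_level)
    if mean_level < cfg.low_expression_floor:
        return ClassifiedPeak(assignment, OutputClass.LOW_EXPRESSION, mean_level)

    nfit, n_rhythmic = detect_rhythm(
        n_means.index.to_numpy(), n_means.to_numpy(),
        period=cfg.period, alpha=cfg.alpha,
        min_fold=cfg.min_fold, min_level=cfg.min_level,
    )
    if n_rhythmic:
        assert nfit.phase_zt is not None
        cls = (
            OutputClass.RIN_PHI
            if _in_phase(nfit.phase_zt, cfg.phase_window, cfg.period)
            else OutputClass.RO_PHI
        )
        return ClassifiedPeak(assignment, cls, mean_level, nfit)

    if mrna is not None:
        m_means = mrna.groupby("time")["value"].mean().sort_index()
        if nascent["time"].nunique() != m_means.size and m_means.size >= 4:
            raise ValueError(
                "nascent and mRNA series sampled on different grids for "
                f"gene {assignment.gene_id!r}"
            )
        mfit, m_rhythmic = detect_rhythm(
            m_means.index.to_numpy(), m_means.to_numpy(),
            period=cfg.period, alpha=cfg.alpha,
            min_fold=cfg.min_fold, min_level=0.0,
        )
        if m_rhythmic:
            return ClassifiedPeak(
                assignment, OutputClass.POST_TRANSCRIPTIONAL, mean_level, nfit, mfit
            )
        return ClassifiedPeak(assignment, OutputClass.AR, mean_level, nfit, mfit)
    return ClassifiedPeak(assignment, OutputClass.AR, mean_level, nfit)


def classify_peaks(
    assignments: Sequence[PeakAssignment],
    nascent: pd.DataFrame,
    mrna: pd.DataFrame | None,
    cfg: ClassifyConfig = ClassifyConfig(),
) -> list[ClassifiedPeak]:
    """Classify every gene-assigned peak; intergenic peaks are skipped.

    ``nascent``/``mrna`` are long-format frames with columns
    (series_id, time, replicate, value) keyed by gene id.
    """
    n_by_gene = dict(tuple(nascent.groupby("series_id")))
    m_by_gene = dict(tuple(mrna.groupby("series_id"))) if mrna is not None else {}
    out = []
    for a in assignments:
        if a.gene_id is None:
            continue
        out.append(
            classify_peak(a, n_by_gene.get(a.gene_id), m_by_gene.get(a.gene_id), cfg)
        )
    return out


def class_counts(classified: Sequence[ClassifiedPeak]) -> pd.DataFrame:
    """Counts and percentages per output class (all seven, zero-filled),
    with a per-location breakdown."""
    classes = [c.value for c in OutputClass]
    counts = pd.Series(0, index=classes, dtype=int)
    loc_cols: dict[str, pd.Series] = {}
    for cp in classified:
        counts[cp.output_class.value] += 1
        loc = cp.assignment.location.value
        if loc not in loc_cols:
            loc_cols[loc] = pd.Series(0, index=classes, dtype=int)
        loc_cols[loc][cp.output_class.value] += 1
    total = counts.sum()
    out = pd.DataFrame({"count": counts})
    out["percent"] = 100 * counts / total if total else 0.0
    for loc, s in sorted(loc_cols.items()):
        out[f"n_{loc}"] = s
    out.index.name = "output_class"
    return out


def classified_to_frame(classified: Sequence[ClassifiedPeak]) -> pd.DataFrame:
    rows = []
    for cp in classified:
        p = cp.assignment.peak
        rows.append(
            {
                "chrom": p.chrom,
                "start": p.start,
                "end": p.end,
                "peak_id": p.name,
                "gene_id": cp.assignment.gene_id,
                "location": cp.assignment.location.value,
                "output_class": cp.output_class.value,
                "mean_nascent_level": cp.mean_nascent_level,
                "nascent_phase_zt": (
                    cp.nascent_fit.phase_zt
                    if cp.nascent_fit is not None and cp.nascent_fit.phase_zt is not None
                    else np.nan
                ),
                "nascent_pvalue": (
                    cp.nascent_fit.pvalue if cp.nascent_fit is not None else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def select_matched_controls(
    pool_levels: pd.DataFrame,
    target_levels: pd.DataFrame,
    n_per_class: int = 125,
    seed: int = 0,
    alpha: float = 0.05,
    max_retries: int = 100,
) -> dict[str, list[str]]:
    """Expression-matched control genes per output class.

    ``pool_levels`` (non-target genes) and ``target_levels`` are frames with
    columns (gene_id, output_class, level).  For each class present in the
    targets, ``n_per_class`` pool genes of the same class are sampled
    (seeded); the sample is accepted when a Kruskal-Wallis test cannot
    distinguish control from target expression levels (p >= ``alpha``),
    otherwise it is redrawn up to ``max_retries`` times.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, list[str]] = {}
    for cls, tgt in target_levels.groupby("output_class"):
        pool = pool_levels[pool_levels["output_class"] == cls]
        if len(pool) < n_per_class:
            raise ValueError(
                f"control pool for class {cls!r} has {len(pool)} genes; "
                f"{n_per_class} required"
            )
        tgt_vals = tgt["level"].to_numpy()
        accepted = None
        for _ in range(max_retries):
            sample = pool.sample(n=n_per_class, random_state=rng)
            ctl_vals = sample["level"].to_numpy()
            if np.array_equal(np.sort(ctl_vals), np.sort(tgt_vals)):
                p = 1.0
            else:
                p = sps.kruskal(ctl_vals, tgt_vals).pvalue
            if p >= alpha:
                accepted = sample["gene_id"].tolist()
                break
        if accepted is None:
            raise RuntimeError(
                f"no expression-matched control sample found for class {cls!r} "
                f"after {max_retries} draws"
            )
        out[cls] = accepted
    return out
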