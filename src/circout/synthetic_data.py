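"""Seeded generators for synthetic genomes, peak sets, circadian expression
series and read files with known ground truth.

The generator emulates the data structure of a circadian TF-binding
meta-analysis in a compact mock genome: non-overlapping single-span genes;
co-bound peak pairs for two factors (with configurable center jitter)
placed inside the -10 kb/+1 kb assignment window of "target" genes, plus
factor-specific decoy peaks that never co-occur; 12-point/48-h nascent and
mRNA series whose transcriptional-output class, phase, amplitude and mesor
are recorded in a truth table; and Poisson read sets whose expected
window signal equals a prescribed truth value.

Noise on expression is multiplicative log-normal (exp of Gaussian with
standard deviation ``sigma``), which keeps signal positive.  Every output
is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import OutputClass
from .intervals import GeneModel, GenomicInterval
from .signal import LIBRARY_SCALE, ReadSet

__all__ = [
    "SimulationConfig",
    "simulate_annotation",
    "simulate_expression",
    "simulate_reads",
    "simulate_cohort",
]

DEFAULT_PROPORTIONS = {
    OutputClass.RIN_PHI: 0.2,
    OutputClass.RO_PHI: 0.1,
    OutputClass.AR: 0.5,
    OutputClass.NE: 0.2,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the desk-scale study
    conditions every recovery test runs under."""

    seed: int = 0
    n_genes: int = 2000
    chrom: str = "chrS"
    chrom_size: int = 250_000_000
    gene_length: tuple[int, int] = (5_000, 20_000)
    gene_spacing: int = 40_000          # minimum gap between gene windows
    peak_width: int = 200
    cobind_jitter: int = 50             # center offset between the two factors
    n_decoys_per_factor: int = 200
    class_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    phase_window: tuple[float, float] = (2.0, 12.0)
    rel_amp_range: tuple[float, float] = (0.5, 0.9)
    mesor_log_mean: float = np.log(10.0)  # expressed genes: lognormal reads/bp
    mesor_log_sd: float = 0.5
    ne_mesor_range: tuple[float, float] = (0.05, 0.5)
    sigma: float = 0.1                  # log-normal noise SD on expression
    nascent_times: tuple = tuple(range(0, 48, 4))   # 12 points over 48 h
    chip_times: tuple = tuple(range(2, 24, 4))      # 6 points over 24 h
    period: float = 24.0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"class proportions sum to {total}, expected 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (0 < self.rel_amp_range[0] <= self.rel_amp_range[1] <= 1):
            raise ValueError("relative amplitudes must lie in (0, 1]")


def _draw_classes(cfg: SimulationConfig, rng: np.random.Generator) -> list[OutputClass]:
    classes = [OutputClass(k) if not isinstance(k, OutputClass) else k
               for k in cfg.class_proportions]
    probs = np.array(list(cfg.class_proportions.values()), dtype=float)
    idx = rng.choice(len(classes), size=cfg.n_genes, p=probs / probs.sum())
    return [classes[i] for i in idx]


def _draw_phase(cls: OutputClass, cfg: SimulationConfig, rng) -> float:
    lo, hi = cfg.phase_window
    if cls is OutputClass.RIN_PHI:
        return float(rng.uniform(lo, hi))
    # out-of-phase: uniform over the complement [hi, lo + period)
    return float(rng.uniform(hi, lo + cfg.period) % cfg.period)


def simulate_annotation(
    cfg: SimulationConfig,
) -> tuple[list[GeneModel], list[GenomicInterval], list[GenomicInterval], pd.DataFrame]:
    """Genes, factor-A peaks, factor-B peaks and the truth table.

    Every gene carries an output class and one co-bound peak pair whose
    factor-B member lies inside the gene's strand-aware assignment window;
    decoy peaks for each factor are placed beyond the gene region and never
    overlap each other, so intersecting the two factors recovers exactly
    the co-bound set.
    """
    rng = np.random.default_rng(cfg.seed)
    classes = _draw_classes(cfg, rng)

    genes: list[GeneModel] = []
    peaks_a: list[GenomicInterval] = []
    peaks_b: list[GenomicInterval] = []
    truth_rows = []
    half = cfg.peak_width // 2

    pos = 20_000
    for i, cls in enumerate(classes):
        length = int(rng.integers(*cfg.gene_length))
        if pos + length + cfg.gene_spacing > cfg.chrom_size:
            raise ValueError(
                "chromosome too small for the requested gene count/spacing"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        gene = GeneModel(cfg.chrom, pos, pos + length, strand, f"gene{i:05d}")
        genes.append(gene)

        # peak anchor uniform in the strand-aware window [TSS-10kb, TTS+1kb]
        if strand == "+":
            lo, hi = gene.tss - 10_000, gene.tts + 1_000
        else:
            lo, hi = gene.tts - 1_000, gene.tss + 10_000
        center_b = int(rng.integers(lo + half, hi - half))
        jitter = int(rng.integers(-cfg.cobind_jitter, cfg.cobind_jitter + 1))
        center_a = center_b + jitter
        peak_id = f"peak{i:05d}"
        peaks_b.append(
            GenomicInterval(cfg.chrom, center_b - half, center_b + half, name=peak_id)
        )
        peaks_a.append(
            GenomicInterval(cfg.chrom, center_a - half, center_a + half, name=peak_id)
        )

        phase = (
            _draw_phase(cls, cfg, rng)
            if cls in (OutputClass.RIN_PHI, OutputClass.RO_PHI)
            else np.nan
        )
        if cls is OutputClass.NE:
            mesor = float(rng.uniform(*cfg.ne_mesor_range))
            rel_amp = 0.0
        else:
            mesor = float(rng.lognormal(cfg.mesor_log_mean, cfg.mesor_log_sd))
            mesor = max(mesor, 1.5)  # keep expressed genes clear of the NE cut
            rel_amp = (
                float(rng.uniform(*cfg.rel_amp_range))
                if cls in (OutputClass.RIN_PHI, OutputClass.RO_PHI,
                           OutputClass.POST_TRANSCRIPTIONAL)
                else 0.0
            )
        truth_rows.append(
            {
                "gene_id": gene.gene_id,
                "peak_id": peak_id,
                "true_class": cls.value,
                "true_phase": phase,
                "true_rel_amp": rel_amp,
                "true_mesor": mesor,
            }
        )
        pos += length + int(rng.integers(cfg.gene_spacing, 2 * cfg.gene_spacing))

    # decoys: alternate non-overlapping slots beyond the gene region
    decoy_start = pos + 100_000
    slot = 3 * cfg.peak_width
    for j in range(cfg.n_decoys_per_factor):
        a0 = decoy_start + 2 * j * slot
        b0 = decoy_start + (2 * j + 1) * slot
        if b0 + cfg.peak_width > cfg.chrom_size:
            raise ValueError("chromosome too small for the requested decoy count")
        peaks_a.append(
            GenomicInterval(cfg.chrom, a0, a0 + cfg.peak_width, name=f"decoyA{j:04d}")
        )
        peaks_b.append(
            GenomicInterval(cfg.chrom, b0, b0 + cfg.peak_width, name=f"decoyB{j:04d}")
        )

    truth = pd.DataFrame(truth_rows)
    return genes, peaks_a, peaks_b, truth


def _series_frame(gene_id, times, values, replicate="rep1") -> pd.DataFrame:
    return pd.DataFrame(
        {"series_id": gene_id, "time": times, "replicate": replicate, "value": values}
    )


def simulate_expression(
    cfg: SimulationConfig, truth: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nascent and mRNA long-format series for every gene in the truth table.

    Rhythmic classes follow ``mesor * (1 + rel_amp*cos(2*pi*(t-phase)/24))``
    with multiplicative log-normal noise; AR genes are flat in nascent and
    mRNA; post-transcriptional genes are flat in nascent but rhythmic in
    mRNA; NE genes sit below 1 read/bp; NO_SIGNAL genes emit nothing.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    t = np.asarray(cfg.nascent_times, dtype=float)
    omega = 2 * np.pi / cfg.period
    nascent_frames, mrna_frames = [], []

    for row in truth.itertuples():
        cls = OutputClass(row.true_class)
        if cls is OutputClass.NO_SIGNAL:
            continue
        if row.true_rel_amp > 1:
            raise ValueError(
                f"gene {row.gene_id}: relative amplitude > 1 gives negative signal"
            )
        noise = lambda: np.exp(rng.normal(0.0, cfg.sigma, size=t.size))

        if cls in (OutputClass.RIN_PHI, OutputClass.RO_PHI):
            base = row.true_mesor * (
                1 + row.true_rel_amp * np.cos(omega * (t - row.true_phase))
            )
            nascent = base * noise()
            mrna = base * noise()
        elif cls is OutputClass.POST_TRANSCRIPTIONAL:
            phase = float(rng.uniform(0, cfg.period))
            nascent = row.true_mesor * noise()
            mrna = (
                row.true_mesor
                * (1 + row.true_rel_amp * np.cos(omega * (t - phase)))
                * noise()
            )
        else:  # AR, NE, LOW_EXPRESSION: flat at the drawn mesor
            nascent = row.true_mesor * noise()
            mrna = row.true_mesor * noise()

        nascent_frames.append(_series_frame(row.gene_id, t, nascent))
        mrna_frames.append(_series_frame(row.gene_id, t, mrna))

    empty = pd.DataFrame(columns=["series_id", "time", "replicate", "value"])
    nascent_df = pd.concat(nascent_frames, ignore_index=True) if nascent_frames else empty
    mrna_df = pd.concat(mrna_frames, ignore_index=True) if mrna_frames else empty
    return nascent_df, mrna_df


def simulate_reads(
    windows: list[GenomicInterval],
    truth_signal: pd.DataFrame,
    halfwidth_bp: int,
    library_size: int = 1_000_000,
    read_length: int = 147,
    background_reads: int = 0,
    chrom_size: int = 250_000_000,
    seed: int = 0,
) -> dict[float, ReadSet]:
    """One ReadSet per time point whose expected windowed signal matches
    ``truth_signal`` (rows = windows in order, columns = time points,
    values in reads/bp per 10^8 reads).

    Reads of ``read_length`` bp are dropped entirely inside each window
    (width ``2*halfwidth+1`` must be >= the read length); their count is
    Poisson with mean ``truth * (library_size/1e8) * width / read_length``.
    Background reads are uniform over the chromosome.
    """
    width = 2 * halfwidth_bp + 1
    if read_length > width:
        raise ValueError("read length exceeds the window width")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    if len(windows) != len(truth_signal):
        raise ValueError("one truth row per window required")

    rng = np.random.default_rng(seed)
    out: dict[float, ReadSet] = {}
    depth = library_size / LIBRARY_SCALE
    for t in truth_signal.columns:
        reads: list[GenomicInterval] = []
        for w, truth_val in zip(windows, truth_signal[t].to_numpy()):
            lo = max(0, w.center - halfwidth_bp)
            n = rng.poisson(truth_val * depth * width / read_length)
            if n == 0:
                continue
            starts = rng.integers(lo, lo + width - read_length + 1, size=n)
            strands = rng.random(n) < 0.5
            for s, fwd in zip(starts, strands):
                reads.append(
                    GenomicInterval(
                        w.chrom, int(s), int(s) + read_length,
                        strand="+" if fwd else "-",
                    )
                )
        for _ in range(background_reads):
            s = int(rng.integers(0, chrom_size - read_length))
            reads.append(
                GenomicInterval(
                    windows[0].chrom, s, s + read_length,
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
        out[float(t)] = ReadSet.from_reads(reads, library_size)
    return out


def simulate_cohort(cfg: SimulationConfig):
    """Convenience bundle: (genes, peaks_a, peaks_b, truth, nascent, mrna)."""
    genes, peaks_a, peaks_b, truth = simulate_annotation(cfg)
    nascent, mrna = simulate_expression(cfg, truth)
    return genes, peaks_a, peaks_b, truth, nascent, mrna
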