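"""End-to-end glue: scan peak summit windows, build the shuffle background,
classify, and test enrichment in one call.

This is the path the CLI and the worked examples drive; each step is a thin
composition of the module-level operations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .intervals import Peak, extract_sequences, summit_window
from .motifs import (
    PWM,
    EnrichmentResult,
    MotifHit,
    PeakMotifClass,
    classify_window,
    dinucleotide_shuffle,
    motif_class_enrichment,
)
from .thresholds import DEFAULTS, AnalysisThresholds

__all__ = ["ScanResult", "scan_peaks", "classify_sequences", "cooccurrence_analysis"]


@dataclass
class ScanResult:
    classes: list[PeakMotifClass]
    background_classes: list[PeakMotifClass]
    sox_hits: dict[str, list[MotifHit]]
    tcf_hits: dict[str, list[MotifHit]]
    enrichment: dict[str, EnrichmentResult]


def scan_peaks(
    genome: Mapping[str, str],
    peaks: Sequence[Peak],
    sox_pwms: Sequence[PWM],
    tcf_pwms: Sequence[PWM],
    thresholds: AnalysisThresholds = DEFAULTS,
    chrom_lengths: Mapping[str, int] | None = None,
) -> tuple[list[str], list[str]]:
    """Extract each peak's summit-window sequence. Returns (ids, sequences)."""
    if chrom_lengths is None and hasattr(genome, "items"):
        try:
            chrom_lengths = {c: len(s) for c, s in genome.items()}
        except Exception:
            chrom_lengths = None
    windows = [summit_window(p, thresholds.summit_window, chrom_lengths) for p in peaks]
    seqs = extract_sequences(genome, windows)
    return [p.peak_id for p in peaks], seqs


def classify_sequences(
    ids: Sequence[str],
    seqs: Sequence[str],
    sox_pwms: Sequence[PWM],
    tcf_pwms: Sequence[PWM],
    rel_threshold: float = DEFAULTS.motif_rel_threshold,
) -> tuple[list[PeakMotifClass], dict[str, list[MotifHit]], dict[str, list[MotifHit]]]:
    classes = []
    sox_hits: dict[str, list[MotifHit]] = {}
    tcf_hits: dict[str, list[MotifHit]] = {}
    for pid, seq in zip(ids, seqs):
        cls, sh, th = classify_window(seq, sox_pwms, tcf_pwms, rel_threshold, pid)
        classes.append(cls)
        sox_hits[pid] = sh
        tcf_hits[pid] = th
    return classes, sox_hits, tcf_hits


def cooccurrence_analysis(
    genome: Mapping[str, str],
    peaks: Sequence[Peak],
    sox_pwms: Sequence[PWM],
    tcf_pwms: Sequence[PWM],
    seed: int,
    thresholds: AnalysisThresholds = DEFAULTS,
    labels: Sequence[str] = ("sox_and_tcf", "sox_only", "tcf_only"),
) -> ScanResult:
    """The full motif co-occurrence pipeline on real peaks.

    Scans every peak's summit window with both PWM libraries, classifies
    peaks, builds the background by classifying ``n_shuffles``
    dinucleotide-preserving shuffles of each window identically, and runs the
    one-sided Fisher enrichment test for each requested label.
    """
    ids, seqs = scan_peaks(genome, peaks, sox_pwms, tcf_pwms, thresholds)
    classes, sox_hits, tcf_hits = classify_sequences(
        ids, seqs, sox_pwms, tcf_pwms, thresholds.motif_rel_threshold
    )
    background: list[PeakMotifClass] = []
    for pid, seq in zip(ids, seqs):
        shuffled = dinucleotide_shuffle(seq, thresholds.n_shuffles, seed, pid)
        for k, sseq in enumerate(shuffled.shuffles):
            cls, _, _ = classify_window(
                sseq, sox_pwms, tcf_pwms, thresholds.motif_rel_threshold,
                f"{pid}|shuffle{k + 1}"
            )
            background.append(cls)
    enrichment = {
        lab: motif_class_enrichment(classes, background, lab) for lab in labels
    }
    return ScanResult(classes, background, sox_hits, tcf_hits, enrichment)
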