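"""Synthetic genomes, peaks, expression and DE tables with known ground truth.

Every generator is a pure function of its parameters and an integer seed, so
outputs are byte-identical across runs. The generators emulate the structure
of the real inputs the pipeline consumes — ChIP peaks whose summit windows
carry planted Sox/Tcf site grammars at controlled co-occurrence fractions, a
first-order-Markov genomic background, dissected-tissue TPM tables with
controlled fold enrichment, and two-condition differential-expression tables
with known effects — and return truth manifests that downstream recovery
tests compare against.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval, Peak, annotate_peak, reverse_complement
from .motifs import PWM, pwm_from_consensus, scan_sequence, _dinuc_shuffle_core
from .profiles import CoverageTrack
from .stats import bh_fdr, t_two_sample

__all__ = [
    "TruthManifest",
    "PlantResult",
    "CLASS_LABELS",
    "default_sox_pwm",
    "default_tcf_pwm",
    "simulate_genome",
    "plant_peaks",
    "simulate_genes",
    "simulate_expression",
    "simulate_de",
    "simulate_coverage",
    "write_fasta",
    "write_bedgraph",
    "DEFAULT_TISSUES",
    "DEFAULT_STAGES",
]

_BASES = "ACGT"
CLASS_LABELS = ("sox_and_tcf", "sox_only", "tcf_only", "neither")

DEFAULT_TISSUES = ("ectoderm", "dorsal_mesendoderm", "ventral_mesoderm", "endoderm")
DEFAULT_STAGES = ("NF9", "NF10", "NF10.5", "NF11", "NF12")

# Near-consensus 12-mers built around the biological cores (Sox: AACAAT,
# Tcf/Lef: CTTTGA) with flanks chosen to keep the two words dissimilar on
# both strands; the plant-time verification loop below handles any residual
# cross-matching.
_SOX_CONSENSUS = "CCAACAATGGCG"
_TCF_CONSENSUS = "GCTTTGATCTAG"


def default_sox_pwm() -> PWM:
    return pwm_from_consensus(_SOX_CONSENSUS, "sox_synthetic", "sox")


def default_tcf_pwm() -> PWM:
    return pwm_from_consensus(_TCF_CONSENSUS, "tcf_synthetic", "tcf")


@dataclass
class TruthManifest:
    """Ground truth for one synthetic dataset.

    ``peaks`` maps peak_id to its planted class and site placements; ``genes``
    maps gene_id to whatever truth the expression/DE generators recorded
    (true log2FC, enriched tissue, bound-by flags). Round-trips losslessly
    through JSON.
    """

    seed: int
    params: dict = field(default_factory=dict)
    peaks: dict = field(default_factory=dict)
    genes: dict = field(default_factory=dict)

    def to_json(self, path: str | os.PathLike | None = None) -> str:
        payload = json.dumps(
            {"seed": self.seed, "params": self.params, "peaks": self.peaks,
             "genes": self.genes},
            indent=1, sort_keys=True,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source: str | os.PathLike) -> "TruthManifest":
        if os.path.exists(os.fspath(source)):
            with open(source) as fh:
                data = json.load(fh)
        else:
            data = json.loads(source)
        return cls(seed=data["seed"], params=data["params"],
                   peaks=data["peaks"], genes=data["genes"])


def _dinuc_matrix(dinuc_freqs) -> np.ndarray:
    """Accept a 16-vector (AA, AC, ..., TT order), a 4x4 array, or a dict."""
    if dinuc_freqs is None:
        return np.full((4, 4), 1 / 16)
    if isinstance(dinuc_freqs, Mapping):
        mat = np.zeros((4, 4))
        for key, v in dinuc_freqs.items():
            mat[_BASES.index(key[0]), _BASES.index(key[1])] = v
    else:
        arr = np.asarray(dinuc_freqs, dtype=float)
        mat = arr.reshape(4, 4)
    if np.any(mat < 0) or not np.isclose(mat.sum(), 1.0, atol=1e-8):
        raise ValueError("dinucleotide frequencies must be nonnegative and sum to 1")
    return mat


def simulate_genome(length: int, dinuc_freqs=None, seed: int = 0) -> str:
    """First-order Markov genome with the given dinucleotide frequencies.

    The chain starts from its stationary distribution; uniform frequencies by
    default. ``dinuc_freqs`` may be a 16-vector in AA..TT order, a 4x4 array,
    or a dict like ``{"AC": 0.1, ...}``.
    """
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    mat = _dinuc_matrix(dinuc_freqs)
    rng = np.random.default_rng(seed)
    row_sums = mat.sum(axis=1)
    support = row_sums > 0
    trans = np.zeros_like(mat)
    trans[support] = mat[support] / row_sums[support, None]
    # stationary distribution: leading left eigenvector restricted to support
    marg = mat.sum(axis=1) + mat.sum(axis=0)
    pi = marg / marg.sum()
    for _ in range(200):
        nxt = pi @ trans
        if nxt.sum() == 0:
            break
        nxt /= nxt.sum()
        if np.allclose(nxt, pi, atol=1e-12):
            pi = nxt
            break
        pi = nxt
    out = np.empty(length, dtype=np.int8)
    out[0] = rng.choice(4, p=pi)
    # vectorized chain: draw uniforms, walk with per-state cumulative rows
    cum = np.cumsum(trans, axis=1)
    u = rng.random(length - 1)
    for i in range(1, length):
        out[i] = np.searchsorted(cum[out[i - 1]], u[i - 1], side="right")
    out = np.clip(out, 0, 3)
    return "".join(_BASES[i] for i in out)


@dataclass
class PlantResult:
    peaks: list[Peak]
    genome: str
    manifest: TruthManifest


def _round_class_counts(n: int, fractions: Sequence[float]) -> list[int]:
    fr = np.asarray(fractions, dtype=float)
    if fr.size != 4 or np.any(fr < 0) or not np.isclose(fr.sum(), 1.0, atol=1e-8):
        raise ValueError("class_fractions must be 4 nonnegative values summing to 1")
    counts = [int(round(n * f)) for f in fr]
    counts[int(np.argmax(fr))] += n - sum(counts)
    return counts


def _place_sites(
    rng: np.random.Generator,
    window_len: int,
    widths: Sequence[int],
) -> list[tuple[int, str]] | None:
    """Non-overlapping (offset, strand) placements for sites of given widths."""
    for _ in range(50):
        placements = []
        ok = True
        for w in widths:
            off = int(rng.integers(0, window_len - w + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            if any(off < o + ow and o < off + w for o, _s, ow in placements):
                ok = False
                break
            placements.append((off, strand, w))
        if ok:
            return [(o, s) for o, s, _w in placements]
    return None


def _detected_sites(seq: str, pwm: PWM, threshold: float) -> set[tuple[int, str]]:
    return {(h.offset, h.strand) for h in scan_sequence(seq, pwm, threshold)}


def plant_peaks(
    genome: str,
    n_peaks: int,
    class_fractions: Sequence[float] = (0.5, 0.25, 0.0, 0.25),
    sox_pwm: PWM | None = None,
    tcf_pwm: PWM | None = None,
    n_sox_sites: int = 2,
    n_tcf_sites: int = 1,
    min_gap: int = 200,
    seed: int = 0,
    peak_width: int = 300,
    window: int = 150,
    rel_threshold: float = 0.70,
    chrom: str = "chrSim",
) -> PlantResult:
    """Plant Sox/Tcf site grammars into a genome at controlled class fractions.

    ``class_fractions`` orders (sox_and_tcf, sox_only, tcf_only, neither);
    class counts are round(n * fraction) with the rounding remainder assigned
    to the largest fraction. Each peak is ``peak_width`` bp with the summit at
    its center; PWM consensus words (relative score 1.0, so detection at the
    scan threshold is deterministic) are written at random non-overlapping
    offsets and strands within the central ``window`` bp.

    The generator *verifies* every window by rescanning it at
    ``rel_threshold`` and resamples the window background (dinucleotide
    shuffle of the original, falling back to uniform redraws) and site
    offsets until the detected (offset, strand) site sets equal the planted
    sets exactly — this is what makes the truth manifest true at the scan
    threshold rather than merely probable.
    """
    sox = sox_pwm or default_sox_pwm()
    tcf = tcf_pwm or default_tcf_pwm()
    counts = _round_class_counts(n_peaks, class_fractions)
    if len(genome) < peak_width:
        raise ValueError("genome shorter than one peak")
    if n_peaks > 1:
        step = (len(genome) - peak_width) / (n_peaks - 1)
        if step < peak_width + min_gap:
            raise ValueError(
                f"cannot fit {n_peaks} peaks of {peak_width} bp with min_gap "
                f"{min_gap} in a {len(genome)} bp genome"
            )
        starts = [int(round(i * step)) for i in range(n_peaks)]
    else:
        starts = [(len(genome) - peak_width) // 2]
    rng = np.random.default_rng(seed)
    labels = [lab for lab, c in zip(CLASS_LABELS, counts) for _ in range(c)]
    labels = [labels[i] for i in rng.permutation(n_peaks)]
    seq = list(genome.upper())
    half = window // 2
    manifest = TruthManifest(
        seed=seed,
        params={
            "n_peaks": n_peaks,
            "class_fractions": list(map(float, class_fractions)),
            "n_sox_sites": n_sox_sites,
            "n_tcf_sites": n_tcf_sites,
            "window": window,
            "rel_threshold": rel_threshold,
            "sox_consensus": sox.consensus,
            "tcf_consensus": tcf.consensus,
        },
    )
    peaks: list[Peak] = []
    for i, (start, label) in enumerate(zip(starts, labels)):
        summit = start + peak_width // 2
        wstart = summit - half
        original = "".join(seq[wstart : wstart + window])
        widths = []
        if label in ("sox_and_tcf", "sox_only"):
            widths += [len(sox)] * n_sox_sites
        n_sox_planted = len(widths)
        if label in ("sox_and_tcf", "tcf_only"):
            widths += [len(tcf)] * n_tcf_sites
        planted_window = None
        sox_sites: list[tuple[int, str]] = []
        tcf_sites: list[tuple[int, str]] = []
        for attempt in range(1000):
            if attempt == 0:
                bg = original
            elif attempt < 500:
                bg = _dinuc_shuffle_core(original, rng)
            else:
                bg = "".join(_BASES[j] for j in rng.integers(0, 4, window))
            placements = _place_sites(rng, window, widths)
            if placements is None:
                continue
            # compose: first n_sox_planted placements carry the Sox word
            w = list(bg)
            for j, (off, strand) in enumerate(placements):
                word = sox.consensus if j < n_sox_planted else tcf.consensus
                if strand == "-":
                    word = reverse_complement(word)
                w[off : off + len(word)] = list(word)
            candidate = "".join(w)
            want_sox = set(placements[:n_sox_planted])
            want_tcf = set(placements[n_sox_planted:])
            if (
                _detected_sites(candidate, sox, rel_threshold) == want_sox
                and _detected_sites(candidate, tcf, rel_threshold) == want_tcf
            ):
                planted_window = candidate
                sox_sites = sorted(want_sox)
                tcf_sites = sorted(want_tcf)
                break
        if planted_window is None:
            raise RuntimeError(
                f"could not realize class {label!r} for peak {i} after 1000 attempts"
            )
        seq[wstart : wstart + window] = list(planted_window)
        peak_id = f"peak_{i + 1:04d}"
        score = float(rng.integers(100, 1000))
        peaks.append(
            Peak(GenomicInterval(chrom, start, start + peak_width), peak_id, summit, score)
        )
        manifest.peaks[peak_id] = {
            "class": label,
            "sox_sites": [[o, s] for o, s in sox_sites],
            "tcf_sites": [[o, s] for o, s in tcf_sites],
            "window_start": wstart,
        }
    return PlantResult(peaks, "".join(seq), manifest)


def simulate_genes(
    genome_length: int,
    n_genes: int,
    span: int = 4000,
    seed: int = 0,
    chrom: str = "chrSim",
) -> list[GeneModel]:
    """Evenly spaced two-exon gene models with alternating strand."""
    if n_genes < 1 or genome_length < span:
        raise ValueError("need at least one gene fitting in the genome")
    step = (genome_length - span) / max(1, n_genes - 1) if n_genes > 1 else 0
    genes = []
    for i in range(n_genes):
        start = int(round(i * step)) if n_genes > 1 else (genome_length - span) // 2
        end = start + span
        strand = "+" if i % 2 == 0 else "-"
        exon_len = span // 5
        exons = (
            GenomicInterval(chrom, start, start + exon_len, strand),
            GenomicInterval(chrom, end - exon_len, end, strand),
        )
        tss = start if strand == "+" else end - 1
        genes.append(
            GeneModel(f"gene_{i + 1:04d}", tss, strand,
                      GenomicInterval(chrom, start, end, strand), exons)
        )
    return genes


def bound_genes(peaks: Sequence[Peak], genes: Sequence[GeneModel],
                promoter_margin: int = 1000) -> dict[str, list[str]]:
    """gene_id -> peak_ids bound to it by nearest-TSS annotation."""
    out: dict[str, list[str]] = {}
    for p in peaks:
        ann = annotate_peak(p, genes, promoter_margin)
        if ann.nearest_gene is not None:
            out.setdefault(ann.nearest_gene, []).append(p.peak_id)
    return out


def simulate_expression(
    n_genes: int,
    tissues: Sequence[str] = DEFAULT_TISSUES,
    enriched_fraction: float = 0.3,
    enrichment_factor: float = 3.0,
    noise_cv: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str | None]]:
    """Tissue TPM table with a controlled fraction of tissue-enriched genes.

    Baseline TPM is log-normal; each enriched gene is multiplied by
    ``enrichment_factor`` in one assigned tissue. Multiplicative log-normal
    noise with coefficient of variation ~ ``noise_cv`` is applied per cell
    (exactly none at ``noise_cv=0``). Returns the table (genes x tissues) and
    the truth map gene_id -> assigned tissue (None for non-enriched genes).
    """
    if enrichment_factor <= 1:
        raise ValueError("enrichment_factor must exceed 1")
    if noise_cv < 0 or not (0 <= enriched_fraction <= 1):
        raise ValueError("noise_cv must be >= 0 and enriched_fraction in [0,1]")
    if len(tissues) < 2:
        raise ValueError("need at least 2 tissues")
    rng = np.random.default_rng(seed)
    gene_ids = [f"gene_{i + 1:04d}" for i in range(n_genes)]
    n_enriched = int(round(n_genes * enriched_fraction))
    enriched_idx = rng.choice(n_genes, size=n_enriched, replace=False)
    assigned = {}
    baseline = rng.lognormal(mean=np.log(20.0), sigma=1.0, size=n_genes)
    values = np.tile(baseline[:, None], (1, len(tissues)))
    for gi in enriched_idx:
        t = int(rng.integers(len(tissues)))
        values[gi, t] *= enrichment_factor
        assigned[gene_ids[gi]] = tissues[t]
    if noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(noise_cv**2)))
        values = values * rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=values.shape)
    truth = {g: assigned.get(g) for g in gene_ids}
    df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                      columns=list(tissues))
    return df, truth


def simulate_de(
    n_genes: int,
    true_de_fraction: float = 0.2,
    log2fc_distribution: tuple[float, float] = (2.5, 0.5),
    reps_per_condition: int = 3,
    dispersion: float = 0.25,
    stages: Sequence[str] = DEFAULT_STAGES,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Two-condition DE table with known true effects.

    Per gene and stage, ``reps_per_condition`` replicate log2 abundances are
    drawn around a gene baseline with SD ``dispersion``; true-DE genes carry
    a signed log2 effect (|effect| from the given normal, truncated positive)
    from a random onset stage onward. log2FC is the mean log-ratio, p comes
    from a pooled two-sample t-test on the log abundances, and FDR is
    Benjamini–Hochberg within each stage. Returns the long-format table
    (gene_id, stage, log2FC, FDR) and the per-gene truth.
    """
    if reps_per_condition < 2:
        raise ValueError("need >= 2 replicates per condition")
    if not (0 <= true_de_fraction <= 1):
        raise ValueError("true_de_fraction must lie in [0,1]")
    rng = np.random.default_rng(seed)
    gene_ids = [f"gene_{i + 1:04d}" for i in range(n_genes)]
    n_de = int(round(n_genes * true_de_fraction))
    de_idx = set(map(int, rng.choice(n_genes, size=n_de, replace=False)))
    mu, sd = log2fc_distribution
    truth: dict[str, dict] = {}
    effects = np.zeros(n_genes)
    onsets = np.zeros(n_genes, dtype=int)
    for gi in range(n_genes):
        if gi in de_idx:
            mag = abs(rng.normal(mu, sd))
            sign = 1 if rng.random() < 0.5 else -1
            onset = int(rng.integers(len(stages)))
            effects[gi] = sign * mag
            onsets[gi] = onset
            truth[gene_ids[gi]] = {
                "de": True, "sign": sign, "log2fc": float(sign * mag),
                "onset_stage": stages[onset],
            }
        else:
            truth[gene_ids[gi]] = {"de": False, "sign": 0, "log2fc": 0.0,
                                   "onset_stage": None}
    baseline = rng.normal(5.0, 2.0, size=n_genes)
    rows = []
    for si, stage in enumerate(stages):
        lfc = np.empty(n_genes)
        pvals = np.empty(n_genes)
        for gi in range(n_genes):
            eff = effects[gi] if (gi in de_idx and si >= onsets[gi]) else 0.0
            ctrl = baseline[gi] + rng.normal(0, dispersion, reps_per_condition) \
                if dispersion > 0 else np.full(reps_per_condition, baseline[gi])
            trt = baseline[gi] + eff + (
                rng.normal(0, dispersion, reps_per_condition) if dispersion > 0
                else np.zeros(reps_per_condition)
            )
            lfc[gi] = trt.mean() - ctrl.mean()
            pvals[gi] = t_two_sample(trt, ctrl).p
        fdr = bh_fdr(pvals)
        for gi in range(n_genes):
            rows.append((gene_ids[gi], stage, float(lfc[gi]), float(fdr[gi])))
    df = pd.DataFrame(rows, columns=["gene_id", "stage", "log2FC", "FDR"])
    return df, truth


def simulate_coverage(
    chrom_lengths: Mapping[str, int],
    peaks: Sequence[Peak],
    background: float = 1.0,
    peak_height: float = 10.0,
    peak_halfwidth: int = 150,
) -> CoverageTrack:
    """Piecewise-constant coverage: flat background plus a rectangular
    enrichment of ``peak_height`` over ``+/- peak_halfwidth`` at each summit."""
    arrays = {c: np.full(n, background, dtype=float) for c, n in chrom_lengths.items()}
    for p in peaks:
        arr = arrays.get(p.chrom)
        if arr is None:
            continue
        lo = max(0, p.summit - peak_halfwidth)
        hi = min(arr.size, p.summit + peak_halfwidth)
        arr[lo:hi] += peak_height
    return CoverageTrack(arrays)


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike,
                line_width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def write_bedgraph(track: CoverageTrack, path: str | os.PathLike) -> None:
    """Run-length-encoded 4-column bedGraph (zero runs omitted)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.arrays):
            arr = track.arrays[chrom]
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
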